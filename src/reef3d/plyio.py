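"""Minimal PLY reader/writer (ascii and binary little-endian).

Handles the subset of PLY this package produces and consumes: one
``vertex`` element with scalar properties (coordinates, class ids,
per-point scalars such as ``roughness_r20``, colors) and an optional
``face`` element with triangular ``vertex_indices``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError

_NP2PLY = {
    np.dtype("float32"): "float",
    np.dtype("float64"): "double",
    np.dtype("uint8"): "uchar",
    np.dtype("int8"): "char",
    np.dtype("uint16"): "ushort",
    np.dtype("int16"): "short",
    np.dtype("uint32"): "uint",
    np.dtype("int32"): "int",
}
_PLY2NP = {v: k for k, v in _NP2PLY.items()}
_PLY2NP.update({"float32": np.dtype("float32"), "float64": np.dtype("float64"),
                "uint8": np.dtype("uint8"), "int32": np.dtype("int32"),
                "uint16": np.dtype("uint16"), "int16": np.dtype("int16"),
                "uint32": np.dtype("uint32"), "int8": np.dtype("int8")})


def write_ply(path, vertex_props: dict, faces=None, binary: bool = True,
              comments=()) -> None:
    """Write vertex properties (name -> 1D array, equal lengths) and
    optional (F, 3) triangle faces."""
    path = Path(path)
    names = list(vertex_props)
    cols = [np.asarray(vertex_props[n]) for n in names]
    n = len(cols[0])
    if any(len(c) != n for c in cols):
        raise FormatError("vertex property arrays must have equal length")
    cols = [c.astype(_canonical(c.dtype), copy=False) for c in cols]

    fmt = "binary_little_endian" if binary else "ascii"
    header = ["ply", f"format {fmt} 1.0"]
    header += [f"comment {c}" for c in comments]
    header.append(f"element vertex {n}")
    header += [f"property {_NP2PLY[c.dtype]} {name}" for name, c in zip(names, cols)]
    if faces is not None:
        faces = np.asarray(faces, dtype=np.int32)
        header.append(f"element face {len(faces)}")
        header.append("property list uchar int vertex_indices")
    header.append("end_header")

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            rec = np.empty(n, dtype=[(name, c.dtype) for name, c in zip(names, cols)])
            for name, c in zip(names, cols):
                rec[name] = c
            fh.write(rec.tobytes())
            if faces is not None:
                frec = np.empty(len(faces), dtype=[("n", "u1"), ("v", "<i4", (3,))])
                frec["n"] = 3
                frec["v"] = faces
                fh.write(frec.tobytes())
        else:
            for i in range(n):
                fh.write((" ".join(_fmt(c[i]) for c in cols) + "\n").encode("ascii"))
            if faces is not None:
                for f in faces:
                    fh.write(f"3 {f[0]} {f[1]} {f[2]}\n".encode("ascii"))


def read_ply(path):
    """Read a PLY file -> (vertex_props dict, faces (F,3) int array or None)."""
    path = Path(path)
    with open(path, "rb") as fh:
        header, offset = _read_header(fh)
    fmt = header["format"]
    v_names, v_dtypes = zip(*header["vertex_props"])
    n_vertex = header["n_vertex"]
    n_face = header.get("n_face", 0)

    if fmt == "binary_little_endian":
        rec_dtype = np.dtype([(nm, dt.newbyteorder("<")) for nm, dt in
                              zip(v_names, v_dtypes)])
        with open(path, "rb") as fh:
            fh.seek(offset)
            buf = fh.read(rec_dtype.itemsize * n_vertex)
            rec = np.frombuffer(buf, dtype=rec_dtype, count=n_vertex)
            props = {nm: np.ascontiguousarray(rec[nm]) for nm in v_names}
            faces = None
            if n_face:
                fdt = np.dtype([("n", "u1"), ("v", "<i4", (3,))])
                frec = np.frombuffer(fh.read(fdt.itemsize * n_face), dtype=fdt,
                                     count=n_face)
                if not np.all(frec["n"] == 3):
                    raise FormatError("only triangular faces are supported")
                faces = np.ascontiguousarray(frec["v"])
        return props, faces

    if fmt != "ascii":
        raise FormatError(f"unsupported PLY format {fmt!r}")
    with open(path, "rb") as fh:
        fh.seek(offset)
        lines = fh.read().decode("ascii").split("\n")
    vals = np.array([ln.split() for ln in lines[:n_vertex]], dtype=np.float64)
    props = {nm: vals[:, i].astype(dt) for i, (nm, dt) in
             enumerate(zip(v_names, v_dtypes))}
    faces = None
    if n_face:
        frows = [ln.split() for ln in lines[n_vertex:n_vertex + n_face]]
        if any(r[0] != "3" for r in frows):
            raise FormatError("only triangular faces are supported")
        faces = np.array([[int(r[1]), int(r[2]), int(r[3])] for r in frows],
                         dtype=np.int32)
    return props, faces


def _canonical(dtype):
    dtype = np.dtype(dtype)
    if dtype in _NP2PLY:
        return dtype
    if dtype.kind == "f":
        return np.dtype("float64")
    if dtype.kind in "iu":
        return np.dtype("int32")
    raise FormatError(f"cannot map dtype {dtype} to a PLY property type")


def _fmt(v):
    if isinstance(v, (np.floating, float)):
        return repr(float(v))
    return str(int(v))


def _read_header(fh):
    magic = fh.readline().strip()
    if magic != b"ply":
        raise FormatError("not a PLY file")
    header = {"vertex_props": []}
    element = None
    while True:
        line = fh.readline()
        if not line:
            raise FormatError("truncated PLY header")
        tok = line.decode("ascii").strip().split()
        if not tok:
            continue
        if tok[0] == "format":
            header["format"] = tok[1]
        elif tok[0] == "comment":
            continue
        elif tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                header["n_vertex"] = int(tok[2])
            elif element == "face":
                header["n_face"] = int(tok[2])
            else:
                raise FormatError(f"unsupported PLY element {element!r}")
        elif tok[0] == "property":
            if element == "vertex":
                if tok[1] == "list":
                    raise FormatError("list properties on vertices unsupported")
                header["vertex_props"].append((tok[2], _PLY2NP[tok[1]]))
            # face list property layout is fixed (uchar count + int indices)
        elif tok[0] == "end_header":
            return header, fh.tell()
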