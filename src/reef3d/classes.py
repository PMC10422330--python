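"""Benthic class scheme: background / live coral / dead coral.

The default scheme mirrors the three-way labelling used for branching
*Pocillopora* habitat: every pixel is background (sand, rock, algae,
other taxa), live coral, or dead coral (intact white skeleton). Display
colors follow the usual convention of dark pink for live colonies,
light pink for dead ones and grey for everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field


BACKGROUND = 0
LIVE = 1
DEAD = 2

#: nodata sentinel for label rasters (uint8)
LABEL_NODATA = 255


@dataclass(frozen=True)
class ClassScheme:
    """Mapping from class ids to names and display colors.

    Ids must be consecutive from 0. The default is the three-class
    reef scheme; extra classes may be appended for other habitats.
    """

    names: tuple[str, ...] = ("background", "live_coral", "dead_coral")
    colors: tuple[tuple[int, int, int], ...] = (
        (90, 90, 90),      # background: grey
        (199, 21, 133),    # live coral: dark pink
        (255, 182, 193),   # dead coral: light pink
    )

    def __post_init__(self) -> None:
        if len(self.names) != len(self.colors):
            raise ValueError("names and colors must have equal length")
        if len(self.names) < 1:
            raise ValueError("at least one class required")

    @property
    def n_classes(self) -> int:
        return len(self.names)

    @property
    def ids(self) -> tuple[int, ...]:
        return tuple(range(len(self.names)))

    def color_of(self, class_id: int) -> tuple[int, int, int]:
        return self.colors[class_id]


DEFAULT_SCHEME = ClassScheme()
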