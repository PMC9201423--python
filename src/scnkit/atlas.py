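"""Region atlases: ordered lists of region labels that name network nodes.

The canonical atlas here is the 90-region AAL parcellation (cortical and
subcortical regions, cerebellum excluded), whose order is preserved through
every table and matrix the pipeline writes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .errors import DataError

__all__ = ["RegionAtlas", "aal90", "generic_atlas"]


@dataclass(frozen=True)
class RegionAtlas:
    """An ordered, immutable list of unique region abbreviations.

    The order is canonical: volume tables, association matrices, adjacency
    matrices and nodal result tables all follow it.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise DataError("atlas needs at least one region label")
        if any(not lab for lab in self.labels):
            raise DataError("atlas labels must be non-empty strings")
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise DataError(f"duplicate atlas labels: {dupes}")

    @property
    def size(self) -> int:
        return len(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


def aal90() -> RegionAtlas:
    """The 90 AAL cortical/subcortical regions in standard numeric order.

    Left/right homologues are interleaved (PreCG.L, PreCG.R, ...), matching
    the ordering used for the association-matrix figures.
    """
    text = resources.files("scnkit.data").joinpath("aal90_labels.txt").read_text()
    return RegionAtlas(tuple(text.split()))


def generic_atlas(n_regions: int) -> RegionAtlas:
    """Placeholder atlas (R001, R002, ...) for simulations at non-AAL sizes."""
    width = max(3, len(str(n_regions)))
    return RegionAtlas(tuple(f"R{i + 1:0{width}d}" for i in range(n_regions)))
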