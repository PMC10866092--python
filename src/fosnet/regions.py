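"""Brain-region sets and their anatomical (meso-structure) grouping.

The default atlas covers the 24 regions of interest quantified in the
opioid-dependence FOS study this package models: seven cortical areas,
two striatal, four pallidal, two amygdalar, three thalamic, four
midbrain, one hippocampal, and one hypothalamic region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

MESO_STRUCTURES = (
    "cortex",
    "striatum",
    "pallidum",
    "amygdala",
    "thalamus",
    "midbrain",
    "hippocampus",
    "hypothalamus",
)

#: region acronym -> meso-structure, in canonical display order
DEFAULT_REGIONS: dict[str, str] = {
    "ACAd": "cortex",
    "ACAv": "cortex",
    "AId": "cortex",
    "AIv": "cortex",
    "CLA": "cortex",
    "PL": "cortex",
    "ILA": "cortex",
    "CP": "striatum",
    "NAc": "striatum",
    "BST": "pallidum",
    "PALv": "pallidum",
    "GPe": "pallidum",
    "GPi": "pallidum",
    "CeA": "amygdala",
    "BLA": "amygdala",
    "PVT": "thalamus",
    "LH": "thalamus",
    "MH": "thalamus",
    "VTA": "midbrain",
    "PAG": "midbrain",
    "SNr": "midbrain",
    "SNc": "midbrain",
    "DG": "hippocampus",
    "LHA": "hypothalamus",
}

#: region dropped by default to form the 23-node connectome (not a primary
#: injection structure); configurable wherever a Connectome is built.
DEFAULT_EXCLUDED_REGION = "SNr"


@dataclass(frozen=True)
class RegionSet:
    """An ordered set of uniquely named brain regions with anatomical grouping.

    Parameters
    ----------
    labels : sequence of str
        Region names, unique, order-preserving.
    structure_of : mapping str -> str
        Region name -> meso-structure; every label must be covered and every
        value must be one of :data:`MESO_STRUCTURES`.
    """

    labels: tuple[str, ...]
    structure_of: Mapping[str, str] = field(default_factory=dict)

    def __init__(self, labels: Sequence[str], structure_of: Mapping[str, str] | None = None):
        labels = tuple(labels)
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if structure_of is None:
            structure_of = {r: DEFAULT_REGIONS[r] for r in labels if r in DEFAULT_REGIONS}
        missing = [r for r in labels if r not in structure_of]
        if missing:
            raise ValueError(f"regions lack a meso-structure assignment: {missing}")
        bad = {s for s in structure_of.values()} - set(MESO_STRUCTURES)
        if bad:
            raise ValueError(f"unknown meso-structures: {sorted(bad)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "structure_of", dict(structure_of))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def members(self, structure: str) -> tuple[str, ...]:
        """Regions belonging to one meso-structure, in set order."""
        return tuple(r for r in self.labels if self.structure_of[r] == structure)

    @property
    def structures(self) -> tuple[str, ...]:
        """Meso-structures present, in canonical order."""
        present = {self.structure_of[r] for r in self.labels}
        return tuple(s for s in MESO_STRUCTURES if s in present)

    def subset(self, keep: Sequence[str] | None = None, drop: Sequence[str] | None = None) -> "RegionSet":
        if (keep is None) == (drop is None):
            raise ValueError("give exactly one of keep= or drop=")
        if keep is not None:
            unknown = set(keep) - set(self.labels)
            if unknown:
                raise ValueError(f"unknown regions: {sorted(unknown)}")
            labels = tuple(r for r in self.labels if r in set(keep))
        else:
            unknown = set(drop) - set(self.labels)
            if unknown:
                raise ValueError(f"unknown regions: {sorted(unknown)}")
            labels = tuple(r for r in self.labels if r not in set(drop))
        return RegionSet(labels, {r: self.structure_of[r] for r in labels})


def default_region_set() -> RegionSet:
    """The full 24-region atlas."""
    return RegionSet(tuple(DEFAULT_REGIONS), dict(DEFAULT_REGIONS))


def default_connectome_regions(excluded: str = DEFAULT_EXCLUDED_REGION) -> RegionSet:
    """The 23-region subset used for structural-connectome dynamics."""
    return default_region_set().subset(drop=[excluded])
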