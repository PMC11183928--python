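"""Stacked species distribution models: binary maps and richness surfaces.

Each species' continuous suitability surface is reclassified into a binary
suitable/unsuitable map at a per-species threshold (cells scoring at or above
the threshold are suitable); summing the binary maps of a species roster
cell-wise yields a species-richness surface. Subgroup richness surfaces
(resident/migratory, diet guilds, protected or red-listed species) are stacks
restricted to species passing a trait predicate, and any full partition of the
roster sums cell-wise back to the total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .maxent import SuitabilityMap

__all__ = ["BinaryMap", "RichnessMap", "binarize", "stack_richness", "subgroup_stack"]


@dataclass
class BinaryMap:
    """Per-cell suitable(1)/unsuitable(0) indicator for one species."""

    species: str
    values: np.ndarray  # float with NaN at nodata; 0/1 elsewhere
    threshold: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class RichnessMap:
    """Integer per-cell count of species classified suitable."""

    values: np.ndarray  # float with NaN at nodata; integer-valued elsewhere
    roster: list[str] = field(default_factory=list)
    subgroup: str = "all"

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def flat_positive(self) -> np.ndarray:
        v = self.values.ravel()
        return v[np.isfinite(v) & (v > 0)]


def binarize(suit: SuitabilityMap, threshold: float, rule: str = "geq") -> BinaryMap:
    """Reclassify a suitability surface: suitable iff score >= threshold."""
    if rule != "geq":
        raise ValueError(f"unknown binarization rule {rule!r}")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = suit.values
    out = np.where(np.isfinite(vals), (vals >= threshold).astype(float), np.nan)
    return BinaryMap(species=suit.species, values=out, threshold=float(threshold))


def stack_richness(maps: list[BinaryMap], subgroup: str = "all",
                   shape: tuple[int, int] | None = None) -> RichnessMap:
    """Cell-wise sum of binary maps. An empty list yields an all-zero map."""
    if not maps:
        if shape is None:
            raise ValueError("shape is required to stack an empty roster")
        return RichnessMap(values=np.zeros(shape), roster=[], subgroup=subgroup)
    ref = maps[0].shape
    total = np.zeros(ref)
    nodata = np.zeros(ref, dtype=bool)
    for bm in maps:
        if bm.shape != ref:
            raise ValueError(f"map for species {bm.species!r} has shape {bm.shape}, expected {ref}")
        nodata |= ~np.isfinite(bm.values)
        total += np.nan_to_num(bm.values, nan=0.0)
    total[nodata] = np.nan
    return RichnessMap(values=total, roster=[m.species for m in maps], subgroup=subgroup)


def subgroup_stack(
    maps: list[BinaryMap],
    traits: Mapping[str, Mapping[str, str]],
    selector: Callable[[Mapping[str, str]], bool],
    subgroup: str,
    shape: tuple[int, int] | None = None,
) -> RichnessMap:
    """Richness over the species passing a trait predicate.

    ``traits`` maps species name -> label mapping (residency, diet, ...);
    every stacked species must have labels.
    """
    missing = [m.species for m in maps if m.species not in traits]
    if missing:
        raise KeyError(f"species missing trait labels: {missing}")
    chosen = [m for m in maps if selector(traits[m.species])]
    if shape is None and maps:
        shape = maps[0].shape
    return stack_richness(chosen, subgroup=subgroup, shape=shape)
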