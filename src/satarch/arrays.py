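"""Satellite array reconstruction and statistics.

An array is a run of same-family monomers in which consecutive hits are
separated by at most one monomer length.  This single-linkage rule is the
fixed point of the iterative procedure "expand the annotation by up to one
monomer length, absorb any monomer found there, repeat", and is applied
strand-agnostically: a monomer orientation flip does not break an array.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .annotate import MonomerHit, SatFamily
from .core_io import Feature, Interval

if TYPE_CHECKING:  # pragma: no cover
    from .symmetry import Subarray


@dataclass
class SatArray:
    family_id: str
    interval: Interval  # strand '.'
    monomers: list[MonomerHit]
    subarrays: list["Subarray"] = field(default_factory=list)

    @property
    def monomer_count(self) -> int:
        return len(self.monomers)

    @property
    def length(self) -> int:
        return len(self.interval)

    def sort_key(self):
        return self.interval.sort_key() + (self.family_id,)


def build_arrays(hits: Iterable[MonomerHit],
                 families: Sequence[SatFamily]) -> list[SatArray]:
    """Group resolved monomer hits into arrays, per family and contig.

    Two same-family hits belong to the same array iff their gap is at most
    the family's consensus monomer length.  The array interval spans the
    first monomer start to the last monomer end.
    """
    fam_len = {f.family_id: f.monomer_length for f in families}
    by_group: dict[tuple[str, str], list[MonomerHit]] = {}
    for h in hits:
        if h.family_id not in fam_len:
            raise KeyError(f"hit references unknown family {h.family_id!r}")
        by_group.setdefault((h.family_id, h.interval.contig_id), []).append(h)

    arrays: list[SatArray] = []
    for (fam, _contig), group in by_group.items():
        gap = fam_len[fam]
        group.sort(key=MonomerHit.sort_key)
        current: list[MonomerHit] = []
        for h in group:
            if current and h.interval.start - current[-1].interval.end <= gap:
                current.append(h)
            else:
                if current:
                    arrays.append(_finish_array(fam, current))
                current = [h]
        if current:
            arrays.append(_finish_array(fam, current))
    arrays.sort(key=SatArray.sort_key)
    return arrays


def _finish_array(family_id: str, monomers: list[MonomerHit]) -> SatArray:
    iv = Interval(monomers[0].interval.contig_id,
                  monomers[0].interval.start,
                  max(m.interval.end for m in monomers), ".")
    return SatArray(family_id, iv, list(monomers))


def classify_satellite(family_id: str, arrays: Iterable[SatArray],
                       min_tandem: int = 5) -> bool:
    """True iff the family has an array of at least ``min_tandem`` monomers."""
    return any(a.family_id == family_id and a.monomer_count >= min_tandem
               for a in arrays)


@dataclass
class ArrayStats:
    family_id: str
    lengths: list[int]
    median_length: float
    max_length: int
    monomer_count_histogram: dict[int, int]

    @property
    def n_arrays(self) -> int:
        return len(self.lengths)


def array_stats(arrays: Sequence[SatArray]) -> dict[str, ArrayStats]:
    """Per-family array length statistics and monomer-count histogram."""
    out: dict[str, ArrayStats] = {}
    for fam in sorted({a.family_id for a in arrays}):
        fam_arrays = [a for a in arrays if a.family_id == fam]
        lengths = [a.length for a in fam_arrays]
        hist = Counter(a.monomer_count for a in fam_arrays)
        out[fam] = ArrayStats(
            family_id=fam,
            lengths=lengths,
            median_length=float(np.median(lengths)),
            max_length=max(lengths),
            monomer_count_histogram=dict(sorted(hist.items())),
        )
    return out


def length_kde(lengths: Sequence[int], n_grid: int = 256
               ) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of array lengths (Scott's bandwidth), for export/plots."""
    x = np.asarray(lengths, dtype=float)
    if len(x) < 2 or np.allclose(x, x[0]):
        grid = np.linspace(max(0.0, x.min() - 1), x.max() + 1, n_grid)
        dens = np.zeros_like(grid)
        return grid, dens
    kde = gaussian_kde(x)  # Scott's rule is the scipy default
    pad = 0.1 * (x.max() - x.min())
    grid = np.linspace(max(0.0, x.min() - pad), x.max() + pad, n_grid)
    return grid, kde(grid)


def arrays_to_features(arrays: Iterable[SatArray]) -> list[Feature]:
    return [Feature(a.interval, "satellite_array", {
        "family_id": a.family_id,
        "monomer_count": str(a.monomer_count),
    }) for a in arrays]
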