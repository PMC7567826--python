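"""Genomic region layout: CpG sites and equal-width subregions.

A haplotype allele spanning ``[start, end)`` is partitioned into the minimum
number K of equal-width, non-overlapping subregions such that no subregion
exceeds ``max_subregion_bp`` (default 500 bp). Each subregion carries its own
methylation propensity parameter in the Ising model, while a single
nearest-neighbour coupling applies across the whole region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RegionLayout", "partition_region"]


@dataclass(frozen=True)
class RegionLayout:
    """Coordinates of a region's CpG sites and its subregion partition.

    Attributes
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        Region bounds, 0-based half-open (BED convention).
    cpg_positions : tuple of int
        Strictly increasing genomic positions of the N CpG sites (position of
        the C on the forward strand).
    subregion_bounds : tuple of float
        K+1 coordinates splitting ``[start, end)`` into K equal-width
        subregions.
    site_to_subregion : tuple of int
        For each CpG site, the 0-based index of the subregion whose half-open
        interval contains it.
    """

    chrom: str
    start: int
    end: int
    cpg_positions: tuple = field(default_factory=tuple)
    subregion_bounds: tuple = field(default_factory=tuple)
    site_to_subregion: tuple = field(default_factory=tuple)

    @property
    def n_sites(self) -> int:
        return len(self.cpg_positions)

    @property
    def n_subregions(self) -> int:
        return len(self.subregion_bounds) - 1

    def sites_in_subregion(self, k: int) -> list:
        """0-based indices of the CpG sites assigned to subregion ``k``."""
        return [n for n, kk in enumerate(self.site_to_subregion) if kk == k]

    def per_site_field(self, alpha) -> np.ndarray:
        """Expand K subregion parameters to an N-vector, one per CpG site."""
        alpha = np.asarray(alpha, dtype=float)
        if alpha.shape != (self.n_subregions,):
            raise ValueError(
                f"expected {self.n_subregions} subregion parameters, "
                f"got {alpha.shape}"
            )
        return alpha[np.asarray(self.site_to_subregion, dtype=int)]


def partition_region(
    chrom: str,
    start: int,
    end: int,
    cpg_positions,
    max_subregion_bp: int = 500,
) -> RegionLayout:
    """Partition ``[start, end)`` into the minimum number of equal-width
    subregions of width at most ``max_subregion_bp``, and assign CpG sites.

    K = ceil((end - start) / max_subregion_bp); each subregion is the
    half-open interval [bound_k, bound_{k+1}).
    """
    if start >= end:
        raise ValueError(f"empty region: start={start} >= end={end}")
    cpg_positions = tuple(int(p) for p in cpg_positions)
    if not cpg_positions:
        raise ValueError("no CpG sites in region")
    pos = np.asarray(cpg_positions)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("cpg_positions must be strictly increasing")
    if pos[0] < start or pos[-1] >= end:
        raise ValueError("CpG positions must lie within [start, end)")

    span = end - start
    k = math.ceil(span / max_subregion_bp)
    bounds = start + (span / k) * np.arange(k + 1)
    # right-open intervals: site p belongs to subregion i iff bounds[i] <= p < bounds[i+1]
    assign = np.searchsorted(bounds, pos, side="right") - 1
    assign = np.clip(assign, 0, k - 1)
    return RegionLayout(
        chrom=chrom,
        start=int(start),
        end=int(end),
        cpg_positions=cpg_positions,
        subregion_bounds=tuple(float(b) for b in bounds),
        site_to_subregion=tuple(int(a) for a in assign),
    )
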