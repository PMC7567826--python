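"""Haplotype definition from phased heterozygous SNP clusters.

A phase cluster (heterozygous SNPs sharing a phase set) defines a raw span
from its upstream-most to its downstream-most SNP. The span is then
symmetrically expanded on both sides by the average WGBS read length, so
CpG sites just outside the SNP cluster still enter the comparison. A
haplotype whose expanded span contains more than ``n_max`` CpG sites is
divided into the minimum number of regions with equal-as-possible CpG
counts, each at most ``n_max`` (the first regions take the extra site when
the count does not divide evenly); each region is finally partitioned into
equal-width subregions of at most 500 bp.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .layout import RegionLayout, partition_region

__all__ = ["PhasedSnpCluster", "Haplotype", "AlleleReadSet", "define_haplotypes"]

logger = logging.getLogger(__name__)

N_MAX_DEFAULT = 20


@dataclass(frozen=True)
class PhasedSnpCluster:
    """Heterozygous SNPs on one chromosome sharing a phase set."""

    chrom: str
    positions: tuple
    phase_set: str = ""

    def __post_init__(self):
        pos = tuple(sorted(int(p) for p in self.positions))
        if not pos:
            raise ValueError("cluster must contain at least one SNP")
        object.__setattr__(self, "positions", pos)


@dataclass(frozen=True)
class Haplotype:
    """A haplotype region ready for allele-specific analysis.

    ``layout1`` / ``layout2`` carry each allele's CpG sites (allele-specific
    CpG sets may differ when a SNP creates or destroys a CpG);
    ``shared_sites_1`` / ``shared_sites_2`` index, within each allele's own
    site list, the CpG sites homozygous in both alleles.
    """

    id: str
    chrom: str
    snp_positions: tuple
    raw_span: tuple
    expanded_span: tuple
    layout1: RegionLayout
    layout2: RegionLayout
    shared_sites_1: tuple
    shared_sites_2: tuple

    @property
    def n_shared_sites(self) -> int:
        return len(self.shared_sites_1)


@dataclass
class AlleleReadSet:
    """Reads assigned to one allele of one haplotype."""

    haplotype_id: str
    allele: int
    reads: list = field(default_factory=list)

    def __post_init__(self):
        if self.allele not in (1, 2):
            raise ValueError("allele must be 1 or 2")

    def as_matrix(self, n_sites: int) -> np.ndarray:
        out = np.empty((len(self.reads), n_sites), dtype=np.int8)
        for i, read in enumerate(self.reads):
            if read.obs.shape != (n_sites,):
                raise ValueError("read length does not match allele CpG count")
            out[i] = read.obs
        return out


def _split_counts(total: int, n_regions: int) -> list:
    """Equal-as-possible split; the first regions take the extra site."""
    base, extra = divmod(total, n_regions)
    return [base + (1 if i < extra else 0) for i in range(n_regions)]


def define_haplotypes(
    phased_snps,
    avg_read_length: int,
    cpg_positions,
    n_max: int = N_MAX_DEFAULT,
    cpg_positions_allele2=None,
    max_subregion_bp: int = 500,
) -> list:
    """Build analysis-ready haplotypes from phase clusters and CpG sites.

    Parameters
    ----------
    phased_snps : iterable of PhasedSnpCluster (or (chrom, positions) pairs).
    avg_read_length : bp added symmetrically on both sides of each cluster.
    cpg_positions : dict chrom -> sorted CpG positions for allele 1 (also
        allele 2 unless ``cpg_positions_allele2`` is given).
    n_max : maximum CpG sites per haplotype region before splitting.
    """
    cpg2 = cpg_positions_allele2 if cpg_positions_allele2 is not None else cpg_positions
    haplotypes = []
    for idx, cluster in enumerate(phased_snps):
        if not isinstance(cluster, PhasedSnpCluster):
            cluster = PhasedSnpCluster(chrom=cluster[0], positions=tuple(cluster[1]))
        lo, hi = cluster.positions[0], cluster.positions[-1]
        span = (max(0, lo - avg_read_length), hi + avg_read_length)

        sites1 = _sites_in(cpg_positions, cluster.chrom, span)
        sites2 = _sites_in(cpg2, cluster.chrom, span)
        if not sites1 or not sites2:
            logger.info(
                "dropping haplotype %s:%d-%d (no CpG sites in expanded span)",
                cluster.chrom, span[0], span[1],
            )
            continue

        # split jointly on the union of allele site positions so both
        # alleles break at the same genomic boundaries
        union = sorted(set(sites1) | set(sites2))
        n_regions = max(
            math.ceil(len(sites1) / n_max), math.ceil(len(sites2) / n_max)
        )
        # the minimum region count whose boundaries keep both alleles <= n_max
        while True:
            boundaries = _region_boundaries(union, n_regions, span)
            per_region = [
                (
                    sum(1 for p in sites1 if rs <= p < re),
                    sum(1 for p in sites2 if rs <= p < re),
                )
                for rs, re in boundaries
            ]
            if all(c1 <= n_max and c2 <= n_max for c1, c2 in per_region):
                break
            n_regions += 1
        for r, (rs, re) in enumerate(boundaries):
            s1 = [p for p in sites1 if rs <= p < re]
            s2 = [p for p in sites2 if rs <= p < re]
            if not s1 or not s2:
                continue
            hap_id = f"{cluster.phase_set or idx}"
            if len(boundaries) > 1:
                hap_id = f"{hap_id}.{r + 1}"
            shared = sorted(set(s1) & set(s2))
            haplotypes.append(
                Haplotype(
                    id=f"{cluster.chrom}:{hap_id}",
                    chrom=cluster.chrom,
                    snp_positions=cluster.positions,
                    raw_span=(lo, hi),
                    expanded_span=span,
                    layout1=partition_region(
                        cluster.chrom, rs, re, s1, max_subregion_bp
                    ),
                    layout2=partition_region(
                        cluster.chrom, rs, re, s2, max_subregion_bp
                    ),
                    shared_sites_1=tuple(s1.index(p) for p in shared),
                    shared_sites_2=tuple(s2.index(p) for p in shared),
                )
            )
    return haplotypes


def _sites_in(cpg_positions, chrom, span) -> list:
    pos = cpg_positions.get(chrom, []) if hasattr(cpg_positions, "get") else cpg_positions
    return [int(p) for p in pos if span[0] <= p < span[1]]


def _region_boundaries(union_sites, n_regions, span) -> list:
    """Genomic bounds of the split regions: midpoints between the CpG groups."""
    counts = _split_counts(len(union_sites), n_regions)
    bounds = []
    start = span[0]
    consumed = 0
    for i, c in enumerate(counts):
        consumed += c
        if i == len(counts) - 1:
            end = span[1]
        else:
            end = (union_sites[consumed - 1] + union_sites[consumed] + 1) // 2
        bounds.append((start, end))
        start = end
    return bounds
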