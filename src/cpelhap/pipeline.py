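"""End-to-end allele-specific methylation analysis.

Glues the pieces together: for each haplotype, fit the Ising model to each
allele's reads, summarize both fits (MML, NME), compute the between-allele
statistics (T_MML, T_NME, T_PDM on the shared homozygous CpG set), look up
one-sided bootstrap P values in the per-N null distributions, and BH-adjust
each statistic's P values across haplotypes.
"""

from __future__ import annotations

import logging

from .haplotypes import Haplotype
from .models import CpelML, SaConfig
from .summaries import AlleleSummary, haplotype_stats, mml, nme
from .testing import (
    HaplotypeResult,
    NullSimConfig,
    attach_q_values,
    build_null_cdfs,
    empirical_p_value,
)

__all__ = ["analyze_haplotype", "run_analysis"]

logger = logging.getLogger(__name__)


def analyze_haplotype(
    hap: Haplotype, reads1, reads2, null_cdfs: dict, fit_cfg: SaConfig
) -> HaplotypeResult:
    """Fit both alleles of one haplotype and test the three statistics."""
    fit1 = CpelML(reads1, hap.layout1).fit(fit_cfg)
    fit2 = CpelML(reads2, hap.layout2).fit(fit_cfg)
    shared1 = hap.shared_sites_1 or None
    shared2 = hap.shared_sites_2 or None
    stats = haplotype_stats(fit1.pdm, fit2.pdm, shared1, shared2)
    return HaplotypeResult(
        haplotype_id=hap.id,
        chrom=hap.chrom,
        start=hap.layout1.start,
        end=hap.layout1.end,
        summary1=AlleleSummary(mml(fit1.pdm), nme(fit1.pdm), fit1.pdm.n_sites),
        summary2=AlleleSummary(mml(fit2.pdm), nme(fit2.pdm), fit2.pdm.n_sites),
        stats=stats,
        p_mml=empirical_p_value(null_cdfs["T_MML"], stats.t_mml),
        p_nme=empirical_p_value(null_cdfs["T_NME"], stats.t_nme),
        p_pdm=empirical_p_value(null_cdfs["T_PDM"], stats.t_pdm),
    )


def _reads_for(hap: Haplotype, allele: int, readsets: dict):
    """Reads for one allele of a haplotype, slicing cluster-level read sets
    onto a split region when needed."""
    rs = readsets.get((hap.id, allele))
    if rs is not None:
        return rs.reads
    if "." in hap.id:
        base = hap.id.rsplit(".", 1)[0]
        rs = readsets.get((base, allele))
        if rs is not None:
            raise ValueError(
                f"reads for {base} are cluster-level; slice them per region "
                "before analysis (see cli.fit)"
            )
    return None


def run_analysis(
    haplotypes,
    readsets,
    null_cfg: NullSimConfig | None = None,
    fit_cfg: SaConfig | None = None,
    q_threshold: float = 0.05,
) -> list:
    """Analyze a cohort of haplotypes.

    Parameters
    ----------
    haplotypes : list of :class:`Haplotype`.
    readsets : dict (haplotype_id, allele) -> AlleleReadSet, or iterable of
        AlleleReadSet.
    null_cfg : bootstrap-null conditions (defaults: 5 reads/allele, L=500).
    fit_cfg : annealing schedule for all fits (default: the fast schedule).
    """
    null_cfg = null_cfg or NullSimConfig()
    fit_cfg = fit_cfg or SaConfig.fast()
    if not isinstance(readsets, dict):
        readsets = {(rs.haplotype_id, rs.allele): rs for rs in readsets}

    null_by_n: dict = {}
    results = []
    for hap in haplotypes:
        reads1 = _reads_for(hap, 1, readsets)
        reads2 = _reads_for(hap, 2, readsets)
        if not reads1 or not reads2:
            logger.info("skipping %s: missing reads for one allele", hap.id)
            continue
        n = hap.n_shared_sites or hap.layout1.n_sites
        if n not in null_by_n:
            null_by_n[n] = build_null_cdfs(n, null_cfg, fit_cfg)
        results.append(
            analyze_haplotype(hap, reads1, reads2, null_by_n[n], fit_cfg)
        )
    return attach_q_values(results)
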