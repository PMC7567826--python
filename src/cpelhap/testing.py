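"""Bootstrap-calibrated hypothesis tests for allele-specific methylation.

The null hypothesis is that an observed between-allele statistic (T_MML,
T_NME or T_PDM) is explained by estimation variability alone, as in a
homozygous region where both alleles share one true methylation model. The
null distribution of each statistic is built empirically, indexed by the
CpG count N of the haplotype: L times, a true Ising model with K_max(N)
subregion fields (parameters drawn at random) generates reads for two
alleles, a model is fitted per allele, and the statistic between the two
fits is recorded. The one-sided P value of an observed value t* is then
the plain exceedance fraction (1/L) sum_l I[t_l >= t*]; its smallest
nonzero value is 1/L. Benjamini-Hochberg correction is applied separately
per statistic, and haplotypes with Q <= 0.05 are called significant.

Also provided: the tissue co-occurrence permutation test and Fisher exact
enrichment of significant haplotypes in user-supplied genomic features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .ising import CpelModel
from .layout import RegionLayout, partition_region
from .models import CpelML, SaConfig
from .summaries import AlleleSummary, HaplotypeStats, haplotype_stats, mml, nme

__all__ = [
    "STATISTICS",
    "NullCdf",
    "NullSimConfig",
    "HaplotypeResult",
    "null_region_layout",
    "build_null_cdf",
    "build_null_cdfs",
    "empirical_p_value",
    "bh_adjust",
    "cooccurrence_permutation_test",
    "fisher_enrichment",
]

STATISTICS = ("T_MML", "T_NME", "T_PDM")
_STAT_COL = {name: i for i, name in enumerate(STATISTICS)}


@dataclass(frozen=True)
class NullCdf:
    """Sorted empirical null sample of one statistic at one CpG count."""

    statistic: str
    n_sites: int
    samples: np.ndarray

    def __post_init__(self):
        if self.statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}")
        samples = np.sort(np.asarray(self.samples, dtype=float))
        if samples.size < 100:
            raise ValueError("null CDF needs at least 100 samples")
        object.__setattr__(self, "samples", samples)

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def p_value(self, t_star: float) -> float:
        return empirical_p_value(self, t_star)


@dataclass(frozen=True)
class NullSimConfig:
    """Conditions of the bootstrap null simulation.

    ``k_max_by_n`` overrides the number of subregions per CpG count; by
    default K_max = ceil(max_region_span / 500), clipped to [1, N] so every
    subregion field touches at least one CpG site. ``reads_per_allele`` is
    an int (fixed coverage, default 5) or an inclusive (low, high) range
    sampled uniformly per replicate.
    """

    k_max_by_n: tuple | None = None  # ((n, k), ...) or None
    max_region_span: int = 1000
    reads_per_allele: object = 5
    alpha_bound: float = 2.0
    beta_bound: float = 1.0
    n_null_samples: int = 500
    rng_seed: int | None = None

    def __post_init__(self):
        kmap = self.k_max_by_n
        if isinstance(kmap, dict):
            kmap = tuple(sorted(kmap.items()))
        object.__setattr__(self, "k_max_by_n", kmap)
        rpa = self.reads_per_allele
        if not isinstance(rpa, (int, np.integer)):
            rpa = (int(rpa[0]), int(rpa[1]))
            if rpa[0] > rpa[1] or rpa[0] < 1:
                raise ValueError("invalid reads_per_allele range")
        else:
            rpa = int(rpa)
            if rpa < 1:
                raise ValueError("reads_per_allele must be >= 1")
        object.__setattr__(self, "reads_per_allele", rpa)
        if self.n_null_samples < 100:
            raise ValueError("need at least 100 null samples")

    def k_max(self, n_sites: int) -> int:
        if self.k_max_by_n is not None:
            kmap = dict(self.k_max_by_n)
            if n_sites in kmap:
                return max(1, min(int(kmap[n_sites]), n_sites))
        k = math.ceil(self.max_region_span / 500)
        return max(1, min(k, n_sites))

    def draw_coverage(self, rng) -> int:
        rpa = self.reads_per_allele
        if isinstance(rpa, tuple):
            return int(rng.integers(rpa[0], rpa[1] + 1))
        return rpa


@dataclass
class HaplotypeResult:
    """Per-haplotype output row: summaries, statistics, P and Q values."""

    haplotype_id: str
    chrom: str
    start: int
    end: int
    summary1: AlleleSummary
    summary2: AlleleSummary
    stats: HaplotypeStats
    p_mml: float
    p_nme: float
    p_pdm: float
    q_mml: float = float("nan")
    q_nme: float = float("nan")
    q_pdm: float = float("nan")

    def is_significant(self, statistic: str, q_threshold: float = 0.05) -> bool:
        q = {"T_MML": self.q_mml, "T_NME": self.q_nme, "T_PDM": self.q_pdm}[statistic]
        return bool(q <= q_threshold)


def null_region_layout(n_sites: int, n_subregions: int) -> RegionLayout:
    """Synthetic layout for null simulation: K subregions of exactly 500 bp
    with N CpG sites spread evenly across the region."""
    span = n_subregions * 500
    pos = [int((i + 0.5) * span / n_sites) for i in range(n_sites)]
    return partition_region("sim", 0, span, pos, max_subregion_bp=500)


def _simulate_null_replicate(layout, cfg: NullSimConfig, fit_cfg: SaConfig, rng):
    """One null draw: shared true model, two allele fits, three statistics."""
    k = layout.n_subregions
    alpha = rng.uniform(-cfg.alpha_bound, cfg.alpha_bound, size=k)
    beta = rng.uniform(-cfg.beta_bound, cfg.beta_bound)
    truth = CpelModel(layout, tuple(alpha), float(beta))
    fits = []
    for _ in range(2):
        cov = cfg.draw_coverage(rng)
        reads = truth.sample_reads(cov, rng=rng)
        seed = int(rng.integers(2**31))
        fits.append(CpelML(reads, layout).fit(fit_cfg.with_seed(seed)))
    st = haplotype_stats(fits[0].pdm, fits[1].pdm)
    return st.t_mml, st.t_nme, st.t_pdm


_NULL_CACHE: dict = {}


def _simulate_null_stats(
    n_sites: int, cfg: NullSimConfig, fit_cfg: SaConfig
) -> np.ndarray:
    """(L, 3) null statistic draws, cached per (N, config) and shared by the
    three statistics so one simulation pass serves all of them."""
    key = (n_sites, cfg, fit_cfg)
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]
    rng = np.random.default_rng(cfg.rng_seed)
    layout = null_region_layout(n_sites, cfg.k_max(n_sites))
    out = np.empty((cfg.n_null_samples, 3))
    n_resampled = 0
    i = 0
    while i < cfg.n_null_samples:
        try:
            out[i] = _simulate_null_replicate(layout, cfg, fit_cfg, rng)
            i += 1
        except ValueError:
            n_resampled += 1  # degenerate replicate; redrawn
            if n_resampled > 10 * cfg.n_null_samples:
                raise RuntimeError("null simulation keeps failing")
    _NULL_CACHE[key] = out
    return out


def build_null_cdf(
    statistic: str,
    n_sites: int,
    cfg: NullSimConfig,
    fit_cfg: SaConfig | None = None,
) -> NullCdf:
    """Empirical null distribution of one statistic at CpG count N."""
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    fit_cfg = fit_cfg or SaConfig.fast()
    draws = _simulate_null_stats(n_sites, cfg, fit_cfg)
    return NullCdf(statistic, n_sites, draws[:, _STAT_COL[statistic]])


def build_null_cdfs(
    n_sites: int, cfg: NullSimConfig, fit_cfg: SaConfig | None = None
) -> dict:
    """All three null CDFs at CpG count N from a single simulation pass."""
    return {s: build_null_cdf(s, n_sites, cfg, fit_cfg) for s in STATISTICS}


def empirical_p_value(null: NullCdf, t_star: float) -> float:
    """One-sided exceedance P value: fraction of null draws >= t*."""
    if not np.isfinite(t_star):
        raise ValueError("t_star must be finite")
    idx = np.searchsorted(null.samples, t_star, side="left")
    return float((null.n_samples - idx) / null.n_samples)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted Q values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_q_values(results: list) -> list:
    """BH-adjust each statistic's P values separately across haplotypes."""
    if not results:
        return results
    for attr_p, attr_q in (("p_mml", "q_mml"), ("p_nme", "q_nme"), ("p_pdm", "q_pdm")):
        q = bh_adjust([getattr(r, attr_p) for r in results])
        for r, qi in zip(results, q):
            setattr(r, attr_q, float(qi))
    return results


def cooccurrence_permutation_test(
    significant_calls, n_perms: int = 1000, rng_seed=None
):
    """Are significant haplotypes shared across tissues more than by chance?

    ``significant_calls`` is a tissues x haplotypes boolean matrix. The
    observed co-occurrence is the fraction of significant haplotypes that
    are significant in more than one tissue. Each permutation places the
    same total number K of significance labels uniformly at random over the
    (tissue, haplotype) cells without duplication; P is the proportion of
    permutations whose co-occurrence is at least the observed one.
    """
    calls = np.asarray(significant_calls, dtype=bool)
    if calls.ndim != 2:
        raise ValueError("significant_calls must be a 2-D matrix")
    n_tissues, n_haps = calls.shape
    k = int(calls.sum())
    if k == 0:
        raise ValueError("no significant calls")

    def _cooccurrence(per_hap_counts):
        sig = per_hap_counts[per_hap_counts > 0]
        return float(np.mean(sig > 1)) if sig.size else 0.0

    observed = _cooccurrence(calls.sum(axis=0))
    rng = np.random.default_rng(rng_seed)
    n_cells = n_tissues * n_haps
    hits = 0
    for _ in range(n_perms):
        cells = rng.choice(n_cells, size=k, replace=False)
        counts = np.bincount(cells % n_haps, minlength=n_haps)
        if _cooccurrence(counts) >= observed:
            hits += 1
    return observed, hits / n_perms


def fisher_enrichment(counts):
    """Odds ratio and two-sided Fisher exact P for a 2x2 haplotype table.

    Rows: overlap / no overlap with the feature; columns: significant /
    not significant. The sample odds ratio (a d)/(b c) is reported, with
    +inf when b c = 0 while a d > 0; OR > 1 means enrichment.
    """
    table = np.asarray(counts, dtype=np.int64)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("counts must be a non-negative 2x2 table")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    a, b = table[0]
    c, d = table[1]
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = float(a * d) / float(b * c)
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    return odds, p
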