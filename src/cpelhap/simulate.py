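"""Synthetic-data generation and simulation benchmarks.

Reads are generated by sampling a known Ising methylation model, optionally
degraded by random masking (a random subset of reads loses the methylation
state at randomly selected CpG sites), and the three estimators are fitted
back and scored by the Jensen-Shannon distance between the fitted and the
true PDM. The benchmark grids mirror the study conditions: coverage 10-50
reads, 2-10 CpG sites, a single 500-bp subregion with field alpha_1 = 1 and
coupling beta = 0 for the uncorrelated sweeps, and alpha_1 = 0 with beta in
{0.25, 0.5, 0.75, 1} for the correlated ones; 100 replicates per cell by
default at desk scale (a flag restores larger counts).

Also here: the null-calibration experiment (fresh homozygous haplotypes
pushed through the full test; reports per-statistic Type I error at
P <= 0.05 and the Kolmogorov-Smirnov distance of the P values from
uniformity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ising import MISSING, CpelModel, ObservedRead
from .models import CpelML, NpdML, NpiML, SaConfig
from .summaries import haplotype_stats, jsd
from .testing import NullSimConfig, build_null_cdfs, empirical_p_value, null_region_layout

__all__ = [
    "BenchScenario",
    "mask_reads",
    "run_fit_benchmark",
    "run_null_calibration",
    "run_parameter_recovery",
]


@dataclass(frozen=True)
class BenchScenario:
    """One cell of the simulation grid."""

    n_sites: int
    k: int = 1
    alpha_true: tuple = (1.0,)
    beta_true: float = 0.0
    coverage: int = 20
    missing_model: tuple | None = None  # ("mask", p_read, p_site)
    n_replicates: int = 100
    rng_seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "alpha_true", tuple(float(a) for a in self.alpha_true))
        if len(self.alpha_true) != self.k:
            raise ValueError("alpha_true must have one entry per subregion")
        if self.coverage < 1 or self.n_replicates < 1:
            raise ValueError("coverage and n_replicates must be >= 1")

    def truth(self) -> CpelModel:
        layout = null_region_layout(self.n_sites, self.k)
        return CpelModel(layout, self.alpha_true, self.beta_true)


def mask_reads(reads, p_read: float, p_site: float, rng_seed=None) -> list:
    """Randomly remove methylation states from a random subset of reads.

    Each read enters the masked subset independently with probability
    ``p_read``; within a masked read each site becomes missing independently
    with probability ``p_site``. Reads left with no observed site are
    dropped.
    """
    if not (0 <= p_read <= 1 and 0 <= p_site <= 1):
        raise ValueError("masking probabilities must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    out = []
    for read in reads:
        obs = read.obs.copy()
        if rng.random() < p_read:
            hit = rng.random(obs.shape[0]) < p_site
            obs[hit] = MISSING
        if np.all(obs == MISSING):
            continue
        out.append(ObservedRead(allele=read.allele, obs=obs))
    return out


def run_fit_benchmark(scenario: BenchScenario, fit_cfg: SaConfig | None = None) -> pd.DataFrame:
    """Goodness-of-fit of NPI/NPD/CPEL against the generating model.

    Returns a tidy table (method, replicate, jsd_to_truth); NPD rows are NaN
    when masking leaves no fully observed read.
    """
    fit_cfg = fit_cfg or SaConfig.fast()
    truth = scenario.truth()
    true_pdm = truth.pdm()
    layout = truth.layout
    rng = np.random.default_rng(scenario.rng_seed)
    rows = []
    for rep in range(scenario.n_replicates):
        reads = truth.sample_reads(scenario.coverage, rng=rng)
        if scenario.missing_model is not None:
            _, p_read, p_site = scenario.missing_model
            reads = mask_reads(reads, p_read, p_site, rng_seed=int(rng.integers(2**31)))
        for method in ("NPI", "NPD", "CPEL"):
            try:
                if method == "NPI":
                    fit = NpiML(reads, layout).fit()
                elif method == "NPD":
                    fit = NpdML(reads, layout).fit()
                else:
                    seed = int(rng.integers(2**31))
                    fit = CpelML(reads, layout).fit(fit_cfg.with_seed(seed))
                score = jsd(fit.pdm, true_pdm)
            except ValueError:
                score = float("nan")  # e.g. NPD without full observations
            rows.append({"method": method, "replicate": rep, "jsd_to_truth": score})
    return pd.DataFrame(rows)


def run_null_calibration(
    n_values,
    cfg: NullSimConfig,
    n_eval: int,
    eval_coverage=(5, 20),
    eval_k: str = "random",
    fit_cfg: SaConfig | None = None,
    rng_seed=None,
):
    """Type I error and P-value uniformity of the test under the null.

    For each CpG count N: builds (or reuses) the three per-N null CDFs under
    ``cfg``, then generates ``n_eval`` fresh homozygous haplotypes and runs
    the full test, recording the P values. With the defaults each fresh
    haplotype draws a random subregion count K between 1 and K_max(N) and a
    random per-allele coverage uniform over ``eval_coverage``; since the
    null distributions are built at K_max(N) and fixed coverage, this mixed
    regime yields conservative P values (Type I error below nominal).
    ``eval_k="max"`` together with a degenerate coverage range reproduces
    the matched-conditions regime under which the P values are uniform.

    Returns
    -------
    summary : DataFrame (n_sites, statistic, rejection_rate, ks_distance)
    p_values : DataFrame (n_sites, statistic, replicate, p_value)
    """
    if eval_k not in ("random", "max"):
        raise ValueError("eval_k must be 'random' or 'max'")
    fit_cfg = fit_cfg or SaConfig.fast()
    rng = np.random.default_rng(rng_seed)
    stat_names = ("T_MML", "T_NME", "T_PDM")
    summary_rows, p_rows = [], []
    for n in n_values:
        nulls = build_null_cdfs(n, cfg, fit_cfg)
        k_max = cfg.k_max(n)
        pvals = {s: [] for s in stat_names}
        for rep in range(n_eval):
            k = k_max if eval_k == "max" else int(rng.integers(1, k_max + 1))
            layout = null_region_layout(n, k)
            alpha = rng.uniform(-cfg.alpha_bound, cfg.alpha_bound, size=k)
            beta = rng.uniform(-cfg.beta_bound, cfg.beta_bound)
            truth = CpelModel(layout, tuple(alpha), float(beta))
            fits = []
            for _ in range(2):
                cov = int(rng.integers(eval_coverage[0], eval_coverage[1] + 1))
                reads = truth.sample_reads(cov, rng=rng)
                seed = int(rng.integers(2**31))
                fits.append(CpelML(reads, layout).fit(fit_cfg.with_seed(seed)))
            st = haplotype_stats(fits[0].pdm, fits[1].pdm)
            observed = {"T_MML": st.t_mml, "T_NME": st.t_nme, "T_PDM": st.t_pdm}
            for s in stat_names:
                p = empirical_p_value(nulls[s], observed[s])
                pvals[s].append(p)
                p_rows.append(
                    {"n_sites": n, "statistic": s, "replicate": rep, "p_value": p}
                )
        for s in stat_names:
            arr = np.asarray(pvals[s])
            summary_rows.append(
                {
                    "n_sites": n,
                    "statistic": s,
                    "rejection_rate": float(np.mean(arr <= 0.05)),
                    "ks_distance": float(sps.kstest(arr, "uniform").statistic),
                }
            )
    return pd.DataFrame(summary_rows), pd.DataFrame(p_rows)


def run_parameter_recovery(
    scenarios, fit_cfg: SaConfig | None = None
) -> pd.DataFrame:
    """Median and IQR of the ML parameter estimates over replicate fits.

    Returns one row per scenario cell and parameter with the true value,
    the median estimate and the interquartile range.
    """
    fit_cfg = fit_cfg or SaConfig.fast()
    rows = []
    for sc in scenarios:
        truth = sc.truth()
        layout = truth.layout
        rng = np.random.default_rng(sc.rng_seed)
        est = np.empty((sc.n_replicates, sc.k + 1))
        for rep in range(sc.n_replicates):
            reads = truth.sample_reads(sc.coverage, rng=rng)
            if sc.missing_model is not None:
                _, p_read, p_site = sc.missing_model
                reads = mask_reads(reads, p_read, p_site, rng_seed=int(rng.integers(2**31)))
            fit = CpelML(reads, layout).fit(fit_cfg.with_seed(int(rng.integers(2**31))))
            est[rep] = list(fit.params["alpha"]) + [fit.params["beta"]]
        names = [f"alpha_{i + 1}" for i in range(sc.k)] + ["beta"]
        true_vals = list(sc.alpha_true) + [sc.beta_true]
        q25, q50, q75 = np.percentile(est, [25, 50, 75], axis=0)
        for j, name in enumerate(names):
            rows.append(
                {
                    "n_sites": sc.n_sites,
                    "coverage": sc.coverage,
                    "param": name,
                    "true": true_vals[j],
                    "median_est": float(q50[j]),
                    "iqr": float(q75[j] - q25[j]),
                }
            )
    return pd.DataFrame(rows)
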