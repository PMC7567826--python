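"""Maximum-likelihood estimators for an allele's methylation distribution.

Three model families can be fitted to the reads assigned to one haplotype
allele, mirroring the comparison at the heart of the method:

``CpelML``
    The parametric Ising model (K subregion fields + one coupling), fitted by
    maximizing the marginal likelihood of the possibly partially observed
    reads with simulated annealing followed by a bounded local polish.
``NpiML``
    Non-parametric independent: empirical per-site methylation frequencies,
    joint distribution taken as the product of independent Bernoullis.
``NpdML``
    Non-parametric dependent: empirical joint frequency of full methylation
    patterns, estimated from fully observed reads only.

Each model class is constructed from ``(reads, layout)`` and its ``fit()``
returns an :class:`AlleleFitResults` carrying the estimated PDM, parameters,
log-likelihood and the small-sample AIC used for model comparison via Akaike
weights. Deliberately, neither non-parametric estimator applies pseudo-counts:
assigning probability zero to unseen patterns is part of the behaviour being
compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .ising import CpelModel, MISSING, ObservedRead, batch_read_loglik
from .layout import RegionLayout
from .pdm import DiscretePdm, state_matrix

__all__ = [
    "SaConfig",
    "AlleleFitResults",
    "CpelML",
    "NpiML",
    "NpdML",
    "fit_cpel",
    "fit_npi",
    "fit_npd",
    "aic_small_sample",
    "akaike_weight",
]


@dataclass(frozen=True)
class SaConfig:
    """Simulated-annealing schedule for the Ising fit.

    Proposals are Gaussian with standard deviation ``proposal_scale`` times
    the current temperature; the temperature decays geometrically by
    ``cooling_rate`` per iteration. The best-ever parameters over
    ``n_restarts`` independent chains are returned, refined by a bounded
    derivative-free/quasi-Newton polish when ``polish`` is set.
    """

    n_iters: int = 2000
    initial_temperature: float = 1.0
    cooling_rate: float = 0.95
    proposal_scale: float = 0.5
    alpha_bounds: tuple = (-10.0, 10.0)
    beta_bounds: tuple = (-5.0, 5.0)
    rng_seed: int | None = None
    n_restarts: int = 3
    polish: bool = True

    def __post_init__(self):
        if not (0.0 < self.cooling_rate < 1.0):
            raise ValueError("cooling_rate must be in (0, 1)")
        for lo, hi in (self.alpha_bounds, self.beta_bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("parameter bounds must be finite and ordered")

    @classmethod
    def fast(cls, rng_seed=None) -> "SaConfig":
        """Lighter schedule used by the bootstrap-null and benchmark loops."""
        return cls(n_iters=400, n_restarts=1, rng_seed=rng_seed)

    def with_seed(self, seed) -> "SaConfig":
        return replace(self, rng_seed=seed)


@dataclass(frozen=True)
class AlleleFitResults:
    """Fitted methylation distribution for one haplotype allele."""

    model_kind: str  # "CPEL" | "NPI" | "NPD"
    pdm: DiscretePdm
    params: dict
    n_params: int
    nobs: int
    llf: float
    layout: RegionLayout | None = None
    fitted_model: CpelModel | None = None
    flags: tuple = ()

    @property
    def aicc(self) -> float:
        return aic_small_sample(self)

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "params": {
                k: (list(v) if isinstance(v, (list, tuple, np.ndarray)) else v)
                for k, v in self.params.items()
            },
            "n_params": self.n_params,
            "nobs": self.nobs,
            "log_lik": self.llf,
            "aicc": None if np.isnan(self.aicc) else self.aicc,
            "flags": list(self.flags),
        }

    def summary(self) -> str:
        lines = [
            f"{self.model_kind} allele fit",
            "=" * 32,
            f"CpG sites:        {self.pdm.n_sites}",
            f"Reads used (M):   {self.nobs}",
            f"Free params (eta): {self.n_params}",
            f"Log-likelihood:   {self.llf:.4f}",
            f"AICc:             "
            + ("NA (M <= eta + 1)" if np.isnan(self.aicc) else f"{self.aicc:.4f}"),
        ]
        if self.model_kind == "CPEL":
            alphas = ", ".join(f"{a:.4f}" for a in self.params["alpha"])
            lines += [f"alpha:            [{alphas}]",
                      f"beta:             {self.params['beta']:.4f}"]
        if self.flags:
            lines.append("flags:            " + ", ".join(self.flags))
        return "\n".join(lines)


class _AlleleModel:
    """Shared read validation/bookkeeping for the per-allele estimators."""

    def __init__(self, reads, layout: RegionLayout):
        self.layout = layout
        obs = []
        dropped = 0
        for read in reads:
            vec = read.obs if isinstance(read, ObservedRead) else np.asarray(read)
            vec = np.asarray(vec, dtype=np.int8)
            if vec.shape != (layout.n_sites,):
                raise ValueError(
                    f"read covers {vec.shape[0]} sites, layout has {layout.n_sites}"
                )
            if np.all(vec == MISSING):
                dropped += 1  # carries no likelihood information
                continue
            obs.append(vec)
        self.obs = (
            np.asarray(obs, dtype=np.int8)
            if obs
            else np.empty((0, layout.n_sites), dtype=np.int8)
        )
        self.n_dropped_empty = dropped

    @property
    def nobs(self) -> int:
        return self.obs.shape[0]


class CpelML(_AlleleModel):
    """ML fit of the Ising model to an allele's reads (annealing + polish)."""

    def fit(self, cfg: SaConfig | None = None) -> AlleleFitResults:
        if self.nobs == 0:
            raise ValueError("insufficient data: no informative reads")
        cfg = cfg or SaConfig()
        k = self.layout.n_subregions
        site_map = np.asarray(self.layout.site_to_subregion, dtype=int)
        patterns, counts = np.unique(self.obs, axis=0, return_counts=True)
        counts = counts.astype(float)

        def neg_loglik(theta):
            alpha_site = theta[:k][site_map]
            return -float(counts @ batch_read_loglik(alpha_site, theta[k], patterns))

        lo = np.array([cfg.alpha_bounds[0]] * k + [cfg.beta_bounds[0]])
        hi = np.array([cfg.alpha_bounds[1]] * k + [cfg.beta_bounds[1]])
        rng = np.random.default_rng(cfg.rng_seed)

        best_theta, best_val = None, np.inf
        for restart in range(cfg.n_restarts):
            if restart == 0:
                theta = np.zeros(k + 1)
            else:
                theta = rng.uniform(0.5 * lo, 0.5 * hi)
            val = neg_loglik(theta)
            if val < best_val:
                best_theta, best_val = theta.copy(), val
            temp = cfg.initial_temperature
            for _ in range(cfg.n_iters):
                prop = theta + rng.normal(scale=cfg.proposal_scale * temp, size=k + 1)
                prop = np.clip(prop, lo, hi)
                pval = neg_loglik(prop)
                if pval < val or rng.random() < np.exp(-(pval - val) / temp):
                    theta, val = prop, pval
                    if val < best_val:
                        best_theta, best_val = theta.copy(), val
                temp *= cfg.cooling_rate

        if cfg.polish:
            res = optimize.minimize(
                neg_loglik,
                best_theta,
                method="L-BFGS-B",
                bounds=list(zip(lo, hi)),
                # tight tolerances so monotone (separated) likelihoods run to
                # the box bound instead of stalling on the flat tail
                options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-10},
            )
            if res.fun < best_val:
                best_theta, best_val = np.clip(res.x, lo, hi), float(res.fun)

        model = CpelModel(self.layout, tuple(best_theta[:k]), float(best_theta[k]))
        flags = []
        if np.any(np.isclose(best_theta, lo)) or np.any(np.isclose(best_theta, hi)):
            flags.append("param_at_bound")
        return AlleleFitResults(
            model_kind="CPEL",
            pdm=model.pdm(),
            params={"alpha": list(model.alpha), "beta": model.beta},
            n_params=k + 1,
            nobs=self.nobs,
            llf=-best_val,
            layout=self.layout,
            fitted_model=model,
            flags=tuple(flags),
        )


class NpiML(_AlleleModel):
    """Per-site empirical frequencies; joint = product of Bernoullis."""

    def fit(self) -> AlleleFitResults:
        if self.nobs == 0:
            raise ValueError("insufficient data: no informative reads")
        n = self.layout.n_sites
        covered = self.obs != MISSING
        n_cov = covered.sum(axis=0)
        n_meth = (self.obs == 1).sum(axis=0)
        p_site = np.full(n, 0.5)
        has_cov = n_cov > 0
        p_site[has_cov] = n_meth[has_cov] / n_cov[has_cov]
        flags = tuple(
            f"zero_coverage_site_{i}" for i in np.flatnonzero(~has_cov)
        )

        states = state_matrix(n)
        probs = np.ones(2**n)
        for i in range(n):
            probs *= np.where(states[:, i] == 1, p_site[i], 1.0 - p_site[i])
        # log-likelihood over observed entries only (no imputation)
        with np.errstate(divide="ignore", invalid="ignore"):
            logp = np.where(self.obs == 1, np.log(p_site), np.log1p(-p_site))
        llf = float(np.sum(np.where(covered, logp, 0.0)))
        return AlleleFitResults(
            model_kind="NPI",
            pdm=DiscretePdm(n, probs),
            params={"p_site": list(p_site)},
            n_params=n,
            nobs=self.nobs,
            llf=llf,
            layout=self.layout,
            flags=flags,
        )


class NpdML(_AlleleModel):
    """Empirical joint over full methylation patterns (full reads only).

    ``window`` switches to the epiallele variant: sites are split into
    consecutive blocks of at most ``window`` CpG sites, each block's joint is
    estimated from the reads fully observing it, and the PDM is the product
    over blocks.
    """

    def fit(self, window: int | None = None) -> AlleleFitResults:
        n = self.layout.n_sites
        full = self.obs[np.all(self.obs != MISSING, axis=1)]
        if window is None:
            if full.shape[0] == 0:
                raise ValueError("NPD requires full observations")
            codes = full.astype(np.int64) @ (1 << np.arange(n))
            freq = np.bincount(codes, minlength=2**n) / full.shape[0]
            llf = float(np.sum(np.log(freq[codes])))
            return AlleleFitResults(
                model_kind="NPD",
                pdm=DiscretePdm(n, freq),
                params={"pattern_freq": list(freq)},
                n_params=2**n - 1,
                nobs=full.shape[0],
                llf=llf,
                layout=self.layout,
            )

        if window < 1:
            raise ValueError("window must be >= 1")
        blocks = [list(range(i, min(i + window, n))) for i in range(0, n, window)]
        probs = np.ones(1)
        llf = 0.0
        eta = 0
        for block in blocks:
            sub = self.obs[:, block]
            sub = sub[np.all(sub != MISSING, axis=1)]
            if sub.shape[0] == 0:
                raise ValueError("NPD requires full observations in every window")
            w = len(block)
            codes = sub.astype(np.int64) @ (1 << np.arange(w))
            freq = np.bincount(codes, minlength=2**w) / sub.shape[0]
            llf += float(np.sum(np.log(freq[codes])))
            eta += 2**w - 1
            # later sites occupy higher bits: kron in block order
            probs = np.kron(freq, probs)
        return AlleleFitResults(
            model_kind="NPD",
            pdm=DiscretePdm(n, probs),
            params={"window": window},
            n_params=eta,
            nobs=full.shape[0],
            llf=llf,
            layout=self.layout,
            flags=("epiallele_window",),
        )


def fit_cpel(layout, reads, cfg: SaConfig | None = None) -> AlleleFitResults:
    return CpelML(reads, layout).fit(cfg)


def fit_npi(layout, reads) -> AlleleFitResults:
    return NpiML(reads, layout).fit()


def fit_npd(layout, reads, window: int | None = None) -> AlleleFitResults:
    return NpdML(reads, layout).fit(window=window)


def aic_small_sample(fit: AlleleFitResults) -> float:
    """Small-sample (corrected) AIC: -2 llf + 2 eta + 2 eta(eta+1)/(M-eta-1).

    Returns NaN when M <= eta + 1, in which case the model is not comparable.
    """
    m, eta = fit.nobs, fit.n_params
    if m - eta - 1 <= 0:
        return float("nan")
    return -2.0 * fit.llf + 2.0 * eta + 2.0 * eta * (eta + 1.0) / (m - eta - 1.0)


def akaike_weight(aic_1: float, aic_2: float) -> float:
    """Probability-scale preference for model 1 over model 2.

    W > 0.5 means model 1 is preferred; equal AICs give exactly 0.5.
    """
    if np.isnan(aic_1) or np.isnan(aic_2):
        return float("nan")
    low = min(aic_1, aic_2)
    w1 = np.exp(-(aic_1 - low) / 2.0)
    w2 = np.exp(-(aic_2 - low) / 2.0)
    return float(w1 / (w1 + w2))
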