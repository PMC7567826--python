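"""Inhomogeneous 1D Ising model of the methylation state of a region.

The joint distribution over the N binary methylation states is

    p(x) = (1/Z) exp{-U(x)},
    U(x) = - sum_k alpha_k sum_{n in subregion k} (2 x_n - 1)
           - beta  sum_{n=1}^{N-1} (2 x_n - 1)(2 x_{n+1} - 1),

with one field parameter ``alpha_k`` per equal-width subregion and a single
nearest-neighbour coupling ``beta`` for the whole region. All exact
computations (partition function, site marginals, likelihood of partially
observed reads, sampling) run along the chain with transfer matrices in a
rescaled representation, so they are linear in N and safe for parameter
magnitudes well beyond the fitting bounds. Exhaustive enumeration over the
2^N states is provided separately and backs the dense PDM used by the
entropy/divergence summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layout import RegionLayout, partition_region
from .pdm import MAX_SITES, DiscretePdm, state_matrix

__all__ = ["CpelModel", "ObservedRead", "MISSING", "batch_read_loglik"]

#: sentinel for an unobserved CpG site in a read vector
MISSING = -1

_SPIN = np.array([-1.0, 1.0])


@dataclass(frozen=True)
class ObservedRead:
    """A methylation read over a region's CpG sites.

    ``allele`` is 1 or 2 for allele-assigned reads, 0 for unassigned.
    ``obs`` holds one entry per CpG site: 0 (unmethylated), 1 (methylated)
    or -1 (site not covered by the read).
    """

    allele: int
    obs: np.ndarray

    def __post_init__(self):
        obs = np.asarray(self.obs, dtype=np.int8)
        if not np.all(np.isin(obs, [MISSING, 0, 1])):
            raise ValueError("read entries must be 0, 1 or -1 (missing)")
        object.__setattr__(self, "obs", obs)

    @property
    def n_observed(self) -> int:
        return int(np.sum(self.obs != MISSING))

    @property
    def is_full(self) -> bool:
        return bool(np.all(self.obs != MISSING))


def _pair_matrix(beta: float) -> np.ndarray:
    """2x2 transfer factor exp(beta * s * s') over spins (-1, +1)."""
    ss = np.outer(_SPIN, _SPIN)
    return np.exp(beta * ss)


def _site_factors(alpha_site: np.ndarray) -> np.ndarray:
    """(N, 2) field factors exp(alpha_n * s) for s in (-1, +1)."""
    return np.exp(np.outer(alpha_site, _SPIN))


def _allow_mask(obs: np.ndarray) -> np.ndarray:
    """(R, N, 2) indicator of spin values compatible with each observation."""
    allow = np.ones(obs.shape + (2,))
    allow[..., 0] = obs != 1  # spin -1 allowed unless observed methylated
    allow[..., 1] = obs != 0  # spin +1 allowed unless observed unmethylated
    return allow


def batch_read_loglik(
    alpha_site: np.ndarray, beta: float, obs: np.ndarray
) -> np.ndarray:
    """Log-likelihood of each (possibly partially observed) read.

    Runs a single clamped forward pass over reads stacked with one
    all-missing row, whose forward sum is the partition function; the
    returned values are log of the marginal probability of the observed
    entries under the model.

    Parameters
    ----------
    alpha_site : (N,) per-site field (subregion parameter expanded per site).
    beta : nearest-neighbour coupling.
    obs : (R, N) int array over {0, 1, -1}.
    """
    alpha_site = np.asarray(alpha_site, dtype=float)
    obs = np.atleast_2d(np.asarray(obs))
    n = alpha_site.shape[0]
    if obs.shape[1] != n:
        raise ValueError(f"reads have {obs.shape[1]} sites, model has {n}")
    r = obs.shape[0]

    emis = _site_factors(alpha_site)  # (N, 2)
    pair = _pair_matrix(beta)  # (2, 2)
    allow = _allow_mask(obs)  # (R, N, 2)

    # stack an unclamped row: its forward sum is Z
    msg = np.empty((r + 1, 2))
    msg[:r] = emis[0] * allow[:, 0]
    msg[r] = emis[0]
    logscale = np.zeros(r + 1)
    for i in range(1, n):
        msg = (msg @ pair) * emis[i]
        msg[:r] *= allow[:, i]
        peak = msg.max(axis=1)
        msg /= peak[:, None]
        logscale += np.log(peak)

    logmarg = np.log(msg.sum(axis=1)) + logscale
    return logmarg[:r] - logmarg[r]


@dataclass(frozen=True)
class CpelModel:
    """A fully parameterized Ising methylation model over a region layout."""

    layout: RegionLayout
    alpha: tuple
    beta: float

    def __post_init__(self):
        alpha = tuple(float(a) for a in self.alpha)
        if len(alpha) != self.layout.n_subregions:
            raise ValueError(
                f"need {self.layout.n_subregions} alpha values, got {len(alpha)}"
            )
        if not all(np.isfinite(alpha)) or not np.isfinite(self.beta):
            raise ValueError("model parameters must be finite")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", float(self.beta))

    @classmethod
    def from_region(
        cls, chrom, start, end, cpg_positions, alpha, beta, max_subregion_bp=500
    ) -> "CpelModel":
        layout = partition_region(chrom, start, end, cpg_positions, max_subregion_bp)
        return cls(layout, tuple(alpha), beta)

    @property
    def n_sites(self) -> int:
        return self.layout.n_sites

    @property
    def alpha_site(self) -> np.ndarray:
        """Per-site field: alpha of the subregion containing each CpG site."""
        return self.layout.per_site_field(self.alpha)

    # -- exact chain computations ------------------------------------------

    def potential_energy(self, x) -> float:
        """U(x): field term per site plus nearest-neighbour coupling."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_sites,):
            raise ValueError(f"state has wrong length {x.shape}")
        s = 2.0 * x - 1.0
        u = -float(self.alpha_site @ s)
        if self.n_sites > 1:
            u -= self.beta * float(np.sum(s[:-1] * s[1:]))
        return u

    def log_partition(self) -> float:
        """log Z by the forward transfer-matrix recursion."""
        emis = _site_factors(self.alpha_site)
        pair = _pair_matrix(self.beta)
        msg = emis[0].copy()
        logscale = 0.0
        for i in range(1, self.n_sites):
            msg = (msg @ pair) * emis[i]
            peak = msg.max()
            msg /= peak
            logscale += np.log(peak)
        return float(np.log(msg.sum()) + logscale)

    def _backward_messages(self) -> tuple:
        """Rescaled backward messages b[n, s] with per-step log scales."""
        n = self.n_sites
        emis = _site_factors(self.alpha_site)
        pair = _pair_matrix(self.beta)
        bwd = np.empty((n, 2))
        bwd[-1] = 1.0
        for i in range(n - 2, -1, -1):
            m = pair @ (emis[i + 1] * bwd[i + 1])
            bwd[i] = m / m.max()
        return emis, pair, bwd

    def site_marginals(self) -> np.ndarray:
        """Pr[X_n = 1] per site via forward-backward messages."""
        n = self.n_sites
        emis, pair, bwd = self._backward_messages()
        marg = np.empty(n)
        fwd = emis[0].copy()
        for i in range(n):
            if i > 0:
                fwd = (fwd @ pair) * emis[i]
                fwd /= fwd.max()
            w = fwd * bwd[i]
            marg[i] = w[1] / w.sum()
        return marg

    def read_log_likelihood(self, read) -> float:
        """Log marginal probability of a read's observed entries.

        Missing entries are summed out by clamping only the observed sites
        in the transfer-matrix pass; an all-missing read has probability 1.
        """
        obs = read.obs if isinstance(read, ObservedRead) else np.asarray(read)
        return float(batch_read_loglik(self.alpha_site, self.beta, obs[None, :])[0])

    def pdm(self) -> DiscretePdm:
        """Dense PDM over all 2^N states (N <= 20) by enumeration."""
        if self.n_sites > MAX_SITES:
            raise ValueError(f"dense PDM capped at N={MAX_SITES}")
        neg_u = -self._energies()
        neg_u -= neg_u.max()
        w = np.exp(neg_u)
        return DiscretePdm(self.n_sites, w / w.sum())

    def _energies(self) -> np.ndarray:
        """U(x) for every state in encoding order (enumeration)."""
        s = 2.0 * state_matrix(self.n_sites) - 1.0
        u = -(s @ self.alpha_site)
        if self.n_sites > 1:
            u -= self.beta * np.sum(s[:, :-1] * s[:, 1:], axis=1)
        return u

    def sample_reads(self, n_reads: int, rng=None, allele: int = 1) -> list:
        """Draw fully observed reads i.i.d. from the model.

        Exact forward-filter / backward-sample along the chain (vectorized
        across reads); deterministic given the rng seed.
        """
        if n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        rng = np.random.default_rng(rng)
        n = self.n_sites
        emis, pair, bwd = self._backward_messages()

        states = np.empty((n_reads, n), dtype=np.int8)
        w = emis[0] * bwd[0]
        p1 = w[1] / w.sum()
        states[:, 0] = rng.random(n_reads) < p1
        for i in range(1, n):
            # transition from sampled spin at i-1, weighted by future messages
            w = pair[states[:, i - 1].astype(int)] * (emis[i] * bwd[i])
            p1 = w[:, 1] / w.sum(axis=1)
            states[:, i] = rng.random(n_reads) < p1
        return [ObservedRead(allele=allele, obs=row) for row in states]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        lay = self.layout
        return {
            "chrom": lay.chrom,
            "start": lay.start,
            "end": lay.end,
            "cpg_positions": list(lay.cpg_positions),
            "K": lay.n_subregions,
            "alpha": list(self.alpha),
            "beta": self.beta,
        }

    @classmethod
    def from_dict(cls, d: dict, max_subregion_bp: int = 500) -> "CpelModel":
        layout = partition_region(
            d["chrom"], d["start"], d["end"], d["cpg_positions"], max_subregion_bp
        )
        if layout.n_subregions != d.get("K", layout.n_subregions):
            raise ValueError("stored K inconsistent with region span")
        return cls(layout, tuple(d["alpha"]), d["beta"])
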