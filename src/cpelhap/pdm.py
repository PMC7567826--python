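"""Explicit probability distributions of methylation (PDMs).

A PDM is the joint distribution of the binary methylation states of a
region's N CpG sites, stored as a dense vector of length 2^N. States are
encoded as integers with site 1 in the least significant bit, so state
``s`` has site ``n`` (0-based) methylated iff bit ``n`` of ``s`` is set.

Dense enumeration is capped at N <= 20 (about one million states), matching
the maximum number of CpG sites per analysed haplotype region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretePdm", "MAX_SITES", "state_matrix"]

MAX_SITES = 20

_SUM_TOL = 1e-9


def state_matrix(n_sites: int) -> np.ndarray:
    """(2^N, N) matrix of all methylation states in encoding order."""
    if n_sites > MAX_SITES:
        raise ValueError(f"enumeration capped at N={MAX_SITES}, got {n_sites}")
    states = np.arange(2**n_sites, dtype=np.int64)
    return ((states[:, None] >> np.arange(n_sites)) & 1).astype(np.int8)


def encode_state(x) -> int:
    """Integer encoding of a 0/1 state vector (site 1 = LSB)."""
    x = np.asarray(x, dtype=np.int64)
    return int(np.sum(x << np.arange(len(x))))


@dataclass(frozen=True)
class DiscretePdm:
    """Dense probability distribution over the 2^N methylation states."""

    n_sites: int
    probs: np.ndarray

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        if self.n_sites > MAX_SITES:
            raise ValueError(f"enumeration capped at N={MAX_SITES}")
        if probs.shape != (2**self.n_sites,):
            raise ValueError(
                f"probs must have length 2^{self.n_sites}, got {probs.shape}"
            )
        if np.any(probs < -_SUM_TOL):
            raise ValueError("probabilities must be non-negative")
        total = probs.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"probabilities sum to {total}, expected 1")
        object.__setattr__(self, "probs", np.clip(probs, 0.0, None))

    @classmethod
    def point_mass(cls, n_sites: int, state) -> "DiscretePdm":
        """PDM with all mass on one state (int code or 0/1 vector)."""
        code = state if isinstance(state, (int, np.integer)) else encode_state(state)
        probs = np.zeros(2**n_sites)
        probs[code] = 1.0
        return cls(n_sites, probs)

    @classmethod
    def uniform(cls, n_sites: int) -> "DiscretePdm":
        return cls(n_sites, np.full(2**n_sites, 2.0**-n_sites))

    def prob_of(self, x) -> float:
        """Probability of a single 0/1 state vector."""
        return float(self.probs[encode_state(x)])

    def site_marginals(self) -> np.ndarray:
        """Pr[X_n = 1] for each site n."""
        return state_matrix(self.n_sites).T.astype(float) @ self.probs

    def marginalize(self, keep_sites) -> "DiscretePdm":
        """Sum out all sites not in ``keep_sites`` (0-based indices).

        The kept sites retain their relative order in the new encoding.
        """
        keep = sorted(int(i) for i in keep_sites)
        if not keep:
            raise ValueError("keep_sites must be non-empty")
        if keep[0] < 0 or keep[-1] >= self.n_sites or len(set(keep)) != len(keep):
            raise ValueError("keep_sites must be distinct sites in 0..N-1")
        states = state_matrix(self.n_sites)
        # re-encode each full state by its kept coordinates
        codes = states[:, keep].astype(np.int64) @ (1 << np.arange(len(keep)))
        probs = np.bincount(codes, weights=self.probs, minlength=2 ** len(keep))
        return DiscretePdm(len(keep), probs)

    def __eq__(self, other) -> bool:  # value semantics for tests
        return (
            isinstance(other, DiscretePdm)
            and self.n_sites == other.n_sites
            and np.array_equal(self.probs, other.probs)
        )


def marginalize_pdm(pdm: DiscretePdm, keep_sites) -> DiscretePdm:
    """Functional alias for :meth:`DiscretePdm.marginalize`."""
    return pdm.marginalize(keep_sites)
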