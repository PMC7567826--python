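"""Information-theoretic summaries of methylation distributions.

Given the PDM of a haplotype allele these compute

* MML  mu(X) = E[(1/N) sum_n X_n]            - mean methylation level,
* NME  h(X)  = -(1/N) sum_x p(x) log2 p(x)   - normalized methylation entropy,

and, between the PDMs of the two homologous alleles,

* JSD  D(p1, p2) - the Jensen-Shannon distance (square root of the base-2
  Jensen-Shannon divergence), a metric on [0, 1];
* the three test statistics for allele-specific methylation:
  T_MML = |mu_1 - mu_2|, T_NME = |h_1 - h_2|, and
  T_PDM = (1/N) D^2(p1, p2) / h(X), where h(X) is the NME of the 1/2-1/2
  allele mixture. With equiprobable alleles, D^2 equals the mutual
  information I(X; A) between methylation state and allele of origin, so
  T_PDM is the uncertainty coefficient: the fraction of methylation
  uncertainty explained by the allele.

All entropies use base-2 logarithms with the convention 0 log 0 = 0, which
also makes JSD well defined for the empirical distributions with exact
zeros produced by the non-parametric estimators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pdm import DiscretePdm

__all__ = [
    "AlleleSummary",
    "HaplotypeStats",
    "mml",
    "nme",
    "jsd",
    "mutual_information",
    "haplotype_stats",
]

_CLIP_TOL = 1e-12


@dataclass(frozen=True)
class AlleleSummary:
    """MML and NME of one allele."""

    mml: float
    nme: float
    n_sites: int


@dataclass(frozen=True)
class HaplotypeStats:
    """Between-allele statistics of a haplotype."""

    t_mml: float
    t_nme: float
    t_pdm: float
    jsd: float
    mixture_nme: float
    n_shared_sites: int


def _clip_unit(v: float) -> float:
    if v < -_CLIP_TOL or v > 1.0 + _CLIP_TOL:
        raise ValueError(f"summary {v} outside [0, 1] beyond tolerance")
    return float(min(max(v, 0.0), 1.0))


def mml(pdm: DiscretePdm) -> float:
    """Mean methylation level: expected fraction of methylated sites."""
    return _clip_unit(float(pdm.site_marginals().mean()))


def nme(pdm: DiscretePdm) -> float:
    """Normalized methylation entropy: Shannon entropy (bits) over N."""
    return _clip_unit(float(stats.entropy(pdm.probs, base=2)) / pdm.n_sites)


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence with 0 log 0 = 0."""
    m = 0.5 * (p + q)
    total = 0.0
    for comp in (p, q):
        mask = comp > 0  # 0 log 0 = 0; m > 0 wherever comp > 0
        total += float(np.sum(comp[mask] * np.log2(comp[mask] / m[mask])))
    return 0.5 * total


def jsd(p1: DiscretePdm, p2: DiscretePdm) -> float:
    """Jensen-Shannon distance between two PDMs over the same sites."""
    if p1.n_sites != p2.n_sites:
        raise ValueError(
            "PDMs span different site counts; marginalize to the shared "
            "homozygous CpG set first"
        )
    return _clip_unit(np.sqrt(max(_js_divergence(p1.probs, p2.probs), 0.0)))


def mutual_information(
    p1: DiscretePdm, p2: DiscretePdm, allele_probs=(0.5, 0.5)
) -> float:
    """I(X; A) in bits, by direct summation over the joint of (X, A)."""
    if p1.n_sites != p2.n_sites:
        raise ValueError("PDMs must span the same sites")
    w1, w2 = allele_probs
    mix = w1 * p1.probs + w2 * p2.probs
    total = 0.0
    for w, p in ((w1, p1.probs), (w2, p2.probs)):
        joint = w * p
        mask = joint > 0
        total += float(
            np.sum(joint[mask] * np.log2(joint[mask] / (mix[mask] * w)))
        )
    return max(total, 0.0)


def haplotype_stats(
    p1: DiscretePdm,
    p2: DiscretePdm,
    shared_sites_1=None,
    shared_sites_2=None,
) -> HaplotypeStats:
    """Between-allele test statistics of a haplotype.

    T_MML and T_NME are computed on each allele's full PDM. JSD, the mixture
    NME and T_PDM are computed after marginalizing each allele onto the
    shared homozygous CpG set (``shared_sites_*`` as 0-based indices into
    each allele's own site list; default: all sites, requiring equal N).
    The N normalizing T_PDM is the shared-site count.
    """
    mml1, mml2 = mml(p1), mml(p2)
    nme1, nme2 = nme(p1), nme(p2)

    q1 = p1 if shared_sites_1 is None else p1.marginalize(shared_sites_1)
    q2 = p2 if shared_sites_2 is None else p2.marginalize(shared_sites_2)
    if q1.n_sites != q2.n_sites:
        raise ValueError("shared-site lists must have equal length")
    n_shared = q1.n_sites
    if n_shared < 1:
        raise ValueError("need at least one shared CpG site")

    d = jsd(q1, q2)
    mixture = DiscretePdm(n_shared, 0.5 * (q1.probs + q2.probs))
    h_mix = nme(mixture)
    # h(X)=0 forces both alleles onto the same point mass, hence D=0
    t_pdm = 0.0 if h_mix == 0.0 else _clip_unit(d * d / (n_shared * h_mix))
    return HaplotypeStats(
        t_mml=_clip_unit(abs(mml1 - mml2)),
        t_nme=_clip_unit(abs(nme1 - nme2)),
        t_pdm=t_pdm,
        jsd=d,
        mixture_nme=h_mix,
        n_shared_sites=n_shared,
    )
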