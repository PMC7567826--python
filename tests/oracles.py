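"""Independent brute-force oracles used by the tests.

Everything here enumerates the 2^N state space directly with plain Python,
deliberately sharing no code with the package's transfer-matrix and
vectorized implementations.
"""

import math


def all_states(n):
    """States in package encoding order (site 1 = least significant bit)."""
    return [
        tuple((code >> i) & 1 for i in range(n)) for code in range(2**n)
    ]


def brute_energy(alpha_site, beta, x):
    u = -sum(a * (2 * xi - 1) for a, xi in zip(alpha_site, x))
    u -= beta * sum(
        (2 * x[i] - 1) * (2 * x[i + 1] - 1) for i in range(len(x) - 1)
    )
    return u


def brute_log_z(alpha_site, beta):
    n = len(alpha_site)
    return math.log(
        sum(math.exp(-brute_energy(alpha_site, beta, x)) for x in all_states(n))
    )


def brute_pdm(alpha_site, beta):
    """Probability per state in encoding order."""
    n = len(alpha_site)
    weights = [math.exp(-brute_energy(alpha_site, beta, x)) for x in all_states(n)]
    z = sum(weights)
    return [w / z for w in weights]


def brute_site_marginals(alpha_site, beta):
    n = len(alpha_site)
    probs = brute_pdm(alpha_site, beta)
    return [
        sum(p for p, x in zip(probs, all_states(n)) if x[i] == 1)
        for i in range(n)
    ]


def brute_read_prob(alpha_site, beta, obs):
    """Marginal probability of observed entries (-1 = missing)."""
    n = len(alpha_site)
    probs = brute_pdm(alpha_site, beta)
    total = 0.0
    for p, x in zip(probs, all_states(n)):
        if all(o == -1 or o == xi for o, xi in zip(obs, x)):
            total += p
    return total


def brute_marginalize(probs, n, keep):
    """Marginal distribution over kept sites (0-based, sorted)."""
    out = [0.0] * (2 ** len(keep))
    for p, x in zip(probs, all_states(n)):
        code = sum(x[site] << j for j, site in enumerate(keep))
        out[code] += p
    return out


def brute_entropy_bits(probs):
    return -sum(p * math.log2(p) for p in probs if p > 0)


def brute_jsd(p1, p2):
    """Jensen-Shannon distance, base-2 logs, 0 log 0 = 0."""
    total = 0.0
    for p, q in zip(p1, p2):
        m = 0.5 * (p + q)
        if p > 0:
            total += 0.5 * p * math.log2(p / m)
        if q > 0:
            total += 0.5 * q * math.log2(q / m)
    return math.sqrt(max(total, 0.0))


def brute_mutual_information(p1, p2, w1=0.5, w2=0.5):
    """I(X; A) in bits by direct double summation over the joint."""
    total = 0.0
    for p, q in zip(p1, p2):
        px = w1 * p + w2 * q
        for w, cond in ((w1, p), (w2, q)):
            joint = w * cond
            if joint > 0:
                total += joint * math.log2(joint / (px * w))
    return total


def brute_bh(p_values):
    """Step-up Benjamini-Hochberg adjusted values."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted
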