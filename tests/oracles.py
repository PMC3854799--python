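"""Independent brute-force reference implementations used by the tests.

Everything here is written from the defining formulas with naive loops and
shares no code with the package, so agreement is evidence of correctness
rather than tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_sfs_stats(alleles: np.ndarray, ancestral: np.ndarray | None):
    """pi, theta_w, theta_h, Tajima's D and Fay & Wu's H by direct formula
    evaluation on a binary (or two-state) matrix, pairwise loops and all.

    ``ancestral`` gives the ancestral allele per column (for theta_h / H);
    columns whose ancestral allele is absent from the sample are skipped for
    the polarized quantities.
    """
    n, n_sites = alleles.shape
    # segregating columns
    seg = [j for j in range(n_sites) if len(set(alleles[:, j])) == 2]
    s = len(seg)
    # pi: literal mean pairwise difference over all chromosome pairs
    total = 0
    pairs = 0
    for i, k in itertools.combinations(range(n), 2):
        pairs += 1
        total += sum(alleles[i, j] != alleles[k, j] for j in seg)
    pi = total / pairs
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    theta_w = s / a1
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    d = math.nan
    if s > 0:
        d = (pi - theta_w) / math.sqrt(e1 * s + e2 * s * (s - 1))
    theta_h = math.nan
    h = math.nan
    if ancestral is not None:
        pol = []
        for j in seg:
            anc = ancestral[j]
            if anc not in set(alleles[:, j]):
                continue
            derived = sum(alleles[i, j] != anc for i in range(n))
            if 1 <= derived <= n - 1:
                pol.append(derived)
        if pol:
            theta_h = sum(2.0 * i * i for i in pol) / (n * (n - 1))
            pi_pol = sum(2.0 * i * (n - i) for i in pol) / (n * (n - 1))
            h = pi_pol - theta_h
    return {"S": s, "pi": pi, "theta_w": theta_w, "D": d, "theta_h": theta_h, "H": h}


def brute_force_pruning_loglik(leaf_codons, branch_lengths, q_matrix, freqs):
    """Log-likelihood of a 3-leaf star tree by explicit summation over the
    internal root state, using scipy's matrix exponential directly.

    ``leaf_codons``: list over leaves of per-site codon state indices;
    ``branch_lengths``: one length per leaf.
    """
    from scipy.linalg import expm

    pmats = [expm(q_matrix * t) for t in branch_lengths]
    n_sites = len(leaf_codons[0])
    lnl = 0.0
    for s in range(n_sites):
        site = 0.0
        for root_state in range(len(freqs)):
            term = freqs[root_state]
            for leaf, pm in zip(leaf_codons, pmats):
                term *= pm[root_state, leaf[s]]
            site += term
        lnl += math.log(site)
    return lnl


def fisher_exact_enumeration(table, tail: str) -> float:
    """Fisher's exact p by full enumeration of tables with the observed
    margins, probabilities from binomial coefficients."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    if tail == "greater":
        return sum(prob(x) for x in range(a, hi + 1))
    if tail == "less":
        return sum(prob(x) for x in range(lo, a + 1))
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def minimal_protein_covers(pep_to_prots: dict[str, set[str]]) -> list[set[str]]:
    """All minimum-cardinality protein sets explaining every peptide
    (exhaustive search; fixture-sized inputs only)."""
    proteins = sorted({p for prots in pep_to_prots.values() for p in prots})
    best: list[set[str]] = []
    for size in range(1, len(proteins) + 1):
        for combo in itertools.combinations(proteins, size):
            chosen = set(combo)
            if all(prots & chosen for prots in pep_to_prots.values()):
                best.append(chosen)
        if best:
            return best
    return best
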