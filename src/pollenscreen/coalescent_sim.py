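"""Neutral coalescent simulation (Hudson-style, no recombination) and
simulation-based p-values for SFS neutrality statistics.

A genealogy for ``n`` sampled chromosomes is grown backward in time: while k
lineages remain, an exponential waiting time with rate k(k-1)/2 (time in units
of 4N generations) elapses and a uniformly chosen pair coalesces.  Mutations
are then dropped on branches in proportion to branch length, either
conditioned on a fixed number of segregating sites (the default for per-locus
tests, matching each observed locus's S) or as a Poisson draw under a scaled
mutation rate theta.

``neutrality_pvalue`` reproduces the per-locus simulation test: the p-value of
an observed Tajima's D (or Fay & Wu's H) is the proportion of neutral
replicates with a statistic strictly more extreme than the observed value, in
the direction of the locus's tail.  For H, replicates are polarized exactly
since the simulator knows every mutation's derived state.

A vectorized engine simulates replicate site-frequency spectra directly: for
each replicate it accumulates, per derived-copy-number class i, the total
branch length subtending i leaves, and then places mutations multinomially.
This is distribution-identical to building replicate haplotype matrices and
summarizing them, and orders of magnitude faster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgen_stats import HaplotypeMatrix, tajima_coefficients

__all__ = [
    "Genealogy",
    "SimPValue",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_sfs",
    "sfs_stats",
    "neutrality_pvalue",
]


@dataclass
class Genealogy:
    """A realized neutral genealogy.

    ``times`` holds the inter-coalescent waiting times T_k for k = n..2 in
    units of 4N generations.  ``branches`` is a list of (leaf_set, length)
    covering every branch except the root's (2n-2 branches).
    """

    n: int
    times: np.ndarray
    branches: list[tuple[frozenset[int], float]]

    @property
    def total_branch_length(self) -> float:
        return float(sum(length for _, length in self.branches))


def simulate_genealogy(n: int, rng: np.random.Generator) -> Genealogy:
    """Draw one neutral coalescent genealogy for ``n`` chromosomes."""
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    active: list[tuple[frozenset[int], float]] = [(frozenset([i]), 0.0) for i in range(n)]
    t = 0.0
    times = []
    branches: list[tuple[frozenset[int], float]] = []
    for k in range(n, 1, -1):
        wait = rng.exponential(2.0 / (k * (k - 1)))
        times.append(wait)
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        set_i, birth_i = active[i]
        set_j, birth_j = active[j]
        branches.append((set_i, t - birth_i))
        branches.append((set_j, t - birth_j))
        merged = (set_i | set_j, t)
        active[i] = merged
        active.pop(j)
    return Genealogy(n=n, times=np.asarray(times), branches=branches)


def drop_mutations(
    genealogy: Genealogy,
    rng: np.random.Generator,
    *,
    fixed_s: int | None = None,
    theta: float | None = None,
    locus_id: str = "sim",
) -> HaplotypeMatrix:
    """Place mutations on a genealogy under the infinite-sites model.

    Exactly one of ``fixed_s`` (condition on S mutations) or ``theta`` (draw
    Poisson(theta * L / 2), L the total branch length in 4N units) must be
    given.  Each mutation creates a new site at a uniform position in (0, 1);
    leaves below the mutated branch carry the derived allele "1".  The
    ancestral sequence is all-"0", recorded as outgroup "ancestor".
    """
    if (fixed_s is None) == (theta is None):
        raise ValueError("give exactly one of fixed_s or theta")
    if fixed_s is not None and fixed_s < 0:
        raise ValueError("fixed_s must be >= 0")
    if theta is not None and theta < 0:
        raise ValueError("theta must be >= 0")
    lengths = np.asarray([length for _, length in genealogy.branches])
    total = lengths.sum()
    if fixed_s is not None:
        s = int(fixed_s)
    else:
        s = int(rng.poisson(theta * total / 2.0))
    n = genealogy.n
    alleles = np.full((n, s), "0", dtype="U1")
    if s > 0:
        which = rng.choice(len(lengths), size=s, p=lengths / total)
        positions = np.sort(rng.uniform(size=s))
        for col, b in enumerate(which):
            for leaf in genealogy.branches[b][0]:
                alleles[leaf, col] = "1"
    else:
        positions = np.empty(0)
    return HaplotypeMatrix(
        locus_id=locus_id,
        alleles=alleles,
        positions=positions,
        outgroups={"ancestor": np.full(s, "0", dtype="U1")},
    )


# ---------------------------------------------------------------------------
# vectorized replicate engine
# ---------------------------------------------------------------------------

def _branch_class_lengths(n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate ``reps`` genealogies in lockstep and return W of shape
    (reps, n) where W[r, i] is the total branch length subtending i leaves
    (column 0 unused)."""
    sizes = np.ones((reps, n), dtype=np.int64)
    w_flat = np.zeros(reps * n)
    rows = np.arange(reps)
    for k in range(n, 1, -1):
        t_k = rng.exponential(2.0 / (k * (k - 1)), size=reps)
        flat = (rows[:, None] * n + sizes[:, :k]).ravel()
        w_flat += np.bincount(flat, weights=np.repeat(t_k, k), minlength=reps * n)
        i = rng.integers(0, k, size=reps)
        j = rng.integers(0, k - 1, size=reps)
        j = np.where(j >= i, j + 1, j)
        sj = sizes[rows, j]
        sizes[rows, i] += sj
        sizes[rows, j] = sizes[rows, k - 1]
    return w_flat.reshape(reps, n)


def simulate_sfs(
    n: int,
    reps: int,
    rng: np.random.Generator,
    *,
    fixed_s: int | None = None,
    theta: float | None = None,
) -> np.ndarray:
    """Replicate unfolded site-frequency spectra, shape (reps, n-1)."""
    if (fixed_s is None) == (theta is None):
        raise ValueError("give exactly one of fixed_s or theta")
    w = _branch_class_lengths(n, reps, rng)[:, 1:]  # classes 1..n-1
    probs = w / w.sum(axis=1, keepdims=True)
    if fixed_s is not None:
        return rng.multinomial(int(fixed_s), probs)
    totals = rng.poisson(theta * w.sum(axis=1) / 2.0)
    out = np.zeros((reps, n - 1), dtype=np.int64)
    for size in np.unique(totals):
        mask = totals == size
        if size == 0:
            continue
        out[mask] = rng.multinomial(int(size), probs[mask])
    return out


def sfs_stats(sfs: np.ndarray, n: int) -> dict[str, np.ndarray]:
    """Vectorized pi, theta_W, theta_H, Tajima's D and Fay & Wu's H from a
    batch of unfolded spectra (shape (reps, n-1)).  D and H are NaN where
    S = 0."""
    sfs = np.atleast_2d(np.asarray(sfs))
    i = np.arange(1, n)
    coef = tajima_coefficients(n)
    s = sfs.sum(axis=1)
    pi = sfs @ (i * (n - i)) / (n * (n - 1) / 2.0)
    theta_w = s / coef.a1
    theta_h = sfs @ (2.0 * i**2) / (n * (n - 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        var = coef.e1 * s + coef.e2 * s * (s - 1.0)
        d = np.where(s > 0, (pi - theta_w) / np.sqrt(np.where(var > 0, var, np.nan)), np.nan)
    h = np.where(s > 0, pi - theta_h, np.nan)
    return {"S": s, "pi": pi, "theta_w": theta_w, "theta_h": theta_h, "D": d, "H": h}


@dataclass
class SimPValue:
    """Simulation p-value for one locus's observed statistic."""

    locus_id: str
    statistic: str
    observed: float
    reps: int
    p: float
    tail: str
    n_undefined: int = 0


def neutrality_pvalue(
    observed: float,
    n: int,
    s_obs: int,
    statistic: str = "D",
    tail: str = "lower",
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
    locus_id: str = "locus",
) -> SimPValue:
    """One-sided simulation p-value under the neutral coalescent.

    Simulates ``reps`` neutral replicates at the observed sample size,
    conditioned on the observed segregating-site count, and reports the
    proportion with a statistic strictly more extreme than ``observed``
    (below it for the lower tail, above for the upper).  Replicates where the
    statistic is undefined are dropped and counted in ``n_undefined``.
    """
    if s_obs < 1:
        raise ValueError("need at least one segregating site")
    if statistic not in ("D", "H"):
        raise ValueError("statistic must be 'D' or 'H'")
    if tail not in ("lower", "upper"):
        raise ValueError("tail must be 'lower' or 'upper'")
    if rng is None:
        rng = np.random.default_rng()
    sfs = simulate_sfs(n, reps, rng, fixed_s=s_obs)
    vals = sfs_stats(sfs, n)[statistic]
    ok = ~np.isnan(vals)
    vals = vals[ok]
    n_eff = int(vals.size)
    if n_eff == 0:
        raise RuntimeError("statistic undefined on every replicate")
    if tail == "lower":
        p = float(np.sum(vals < observed)) / n_eff
    else:
        p = float(np.sum(vals > observed)) / n_eff
    return SimPValue(
        locus_id=locus_id, statistic=statistic, observed=float(observed),
        reps=n_eff, p=p, tail=tail, n_undefined=reps - n_eff,
    )
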