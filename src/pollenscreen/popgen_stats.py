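"""Per-locus site-frequency-spectrum statistics and empirical-tail outlier calls.

This module computes the classical SFS summaries used to scan a panel of loci
for departures from neutrality: Watterson's theta, nucleotide diversity (pi),
Fay & Wu's theta_H, Tajima's D, Fay & Wu's H, and per-site expected
heterozygosity.  Loci whose Tajima's D falls in the extreme empirical tails of
the panel-wide distribution are flagged as sweep (lower tail) or balancing
(upper tail) candidates.

All statistics operate on a :class:`HaplotypeMatrix` — sampled chromosomes by
variable sites — after infinite-sites filtering (biallelic columns, no missing
data).  Polarization against an outgroup is required only for theta_H / H.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HaplotypeMatrix",
    "LocusStats",
    "TajimaCoefficients",
    "TailResult",
    "tajima_coefficients",
    "filter_sites",
    "site_frequency_spectrum",
    "tajimas_d",
    "fay_wu_h",
    "expected_heterozygosity",
    "empirical_tails",
]

MISSING = "."


@dataclass
class HaplotypeMatrix:
    """One locus's sampled chromosomes x variable sites.

    ``alleles`` holds single characters ("0"/"1" for binary data, ACGT
    otherwise); ``positions`` are 1-based site coordinates (or floats in
    (0, 1) for coalescent output).  ``outgroups`` maps a taxon name to that
    taxon's allele at each site; the outgroup allele is taken as ancestral
    when polarizing.  ``missing_char`` marks no-calls.
    """

    locus_id: str
    alleles: np.ndarray
    positions: np.ndarray
    outgroups: dict[str, np.ndarray] = field(default_factory=dict)
    missing_char: str = MISSING

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype="U1")
        if self.alleles.ndim != 2:
            raise ValueError(f"locus {self.locus_id}: alleles must be 2-D")
        self.positions = np.asarray(self.positions)
        if self.positions.shape[0] != self.alleles.shape[1]:
            raise ValueError(
                f"locus {self.locus_id}: {self.positions.shape[0]} positions for "
                f"{self.alleles.shape[1]} sites"
            )
        if self.n_chrom < 2:
            raise ValueError(f"locus {self.locus_id}: need >=2 chromosomes")
        self.outgroups = {k: np.asarray(v, dtype="U1") for k, v in self.outgroups.items()}
        for taxon, vec in self.outgroups.items():
            if vec.shape[0] != self.n_sites:
                raise ValueError(
                    f"locus {self.locus_id}: outgroup {taxon!r} has {vec.shape[0]} "
                    f"alleles for {self.n_sites} sites"
                )

    @property
    def n_chrom(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def take_sites(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return HaplotypeMatrix(
            locus_id=self.locus_id,
            alleles=self.alleles[:, idx],
            positions=self.positions[idx],
            outgroups={k: v[idx] for k, v in self.outgroups.items()},
            missing_char=self.missing_char,
        )


@dataclass
class TajimaCoefficients:
    """Sample-size constants of Tajima's D variance (Tajima 1989)."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_coefficients(n: int) -> TajimaCoefficients:
    """Constants a1..e2 for a sample of ``n`` chromosomes."""
    if n < 2:
        raise ValueError("Tajima coefficients require n >= 2")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaCoefficients(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class LocusStats:
    """SFS summaries for one locus.

    ``sfs`` is the unfolded spectrum (counts of sites at derived copy number
    1..n-1) when the locus is polarized, else None.  ``D`` / ``H`` are NaN
    when undefined (S = 0, or no polarizable site for H).
    """

    locus_id: str
    n: int
    S: int
    pi: float
    theta_w: float
    D: float
    het_per_site: float = math.nan
    theta_h: float = math.nan
    H: float = math.nan
    sfs: np.ndarray | None = None
    n_polarized: int = 0


def filter_sites(matrix: HaplotypeMatrix) -> HaplotypeMatrix:
    """Apply the infinite-sites filter.

    Columns with any missing ingroup call are removed; columns with more than
    two distinct ingroup alleles (infinite-sites violations) are removed.
    Monomorphic and biallelic columns are retained (monomorphic columns
    contribute to sequence length but not to S).
    """
    keep = np.ones(matrix.n_sites, dtype=bool)
    for j in range(matrix.n_sites):
        col = matrix.alleles[:, j]
        if np.any(col == matrix.missing_char):
            keep[j] = False
            continue
        if len(set(col.tolist())) > 2:
            keep[j] = False
    return matrix.take_sites(np.nonzero(keep)[0])


def _derived_counts(matrix: HaplotypeMatrix, outgroup_taxon: str) -> np.ndarray:
    """Derived-allele count per site polarized by an outgroup; -1 where the
    site cannot be polarized (outgroup allele missing or absent from the
    ingroup)."""
    if outgroup_taxon not in matrix.outgroups:
        raise KeyError(f"locus {matrix.locus_id}: no outgroup {outgroup_taxon!r}")
    anc = matrix.outgroups[outgroup_taxon]
    n = matrix.n_chrom
    out = np.full(matrix.n_sites, -1, dtype=int)
    for j in range(matrix.n_sites):
        a = anc[j]
        col = matrix.alleles[:, j]
        if a == matrix.missing_char:
            continue
        n_anc = int(np.sum(col == a))
        if n_anc == 0:  # ancestral state absent from the sample: unpolarizable
            continue
        out[j] = n - n_anc
    return out


def site_frequency_spectrum(
    matrix: HaplotypeMatrix, outgroup_taxon: str
) -> tuple[np.ndarray, int]:
    """Unfolded SFS (length n-1; index i-1 = sites with i derived copies)
    over polarizable sites, plus the number of polarizable segregating
    sites used."""
    counts = _derived_counts(matrix, outgroup_taxon)
    n = matrix.n_chrom
    seg = counts[(counts >= 1) & (counts <= n - 1)]
    sfs = np.bincount(seg, minlength=n)[1:n]
    return sfs, int(seg.size)


def _segregating_minor_counts(matrix: HaplotypeMatrix) -> np.ndarray:
    """Count of the non-reference allele at each segregating column (folded;
    orientation arbitrary)."""
    counts = []
    for j in range(matrix.n_sites):
        col = matrix.alleles[:, j]
        alleles = sorted(set(col.tolist()))
        if len(alleles) != 2:
            continue
        counts.append(int(np.sum(col == alleles[1])))
    return np.asarray(counts, dtype=int)


def _pi_from_counts(counts: np.ndarray, n: int) -> float:
    # mean pairwise differences: sum_j k_j (n - k_j) / C(n, 2)
    if counts.size == 0:
        return 0.0
    return float(np.sum(counts * (n - counts)) / (n * (n - 1) / 2.0))


def tajimas_d(matrix: HaplotypeMatrix) -> LocusStats:
    """Tajima's D for one filtered locus.

    D = (pi - theta_W) / sqrt(e1*S + e2*S*(S-1)); NaN when S = 0 (such loci
    are excluded from downstream empirical tails).
    """
    n = matrix.n_chrom
    counts = _segregating_minor_counts(matrix)
    S = counts.size
    coef = tajima_coefficients(n)
    pi = _pi_from_counts(counts, n)
    theta_w = S / coef.a1
    if S == 0:
        d = math.nan
    else:
        d = (pi - theta_w) / math.sqrt(coef.e1 * S + coef.e2 * S * (S - 1))
    het = expected_heterozygosity(matrix)[1]
    return LocusStats(
        locus_id=matrix.locus_id, n=n, S=S, pi=pi, theta_w=theta_w, D=d,
        het_per_site=het,
    )


def fay_wu_h(
    matrix: HaplotypeMatrix, outgroup_taxon: str, normalized: bool = False
) -> LocusStats:
    """Fay & Wu's H = pi - theta_H for one filtered locus, polarized against
    one outgroup taxon.

    theta_H = sum_i 2 * S_i * i^2 / (n (n-1)) over derived copy numbers i.
    Sites that cannot be polarized (outgroup allele missing, or absent from
    the ingroup) are excluded from pi/theta_H here; they still count for D.
    H is NaN if no site is polarizable.

    With ``normalized`` the variance-standardized variant is returned
    instead: (pi - theta_L) / sqrt(Var), where theta_L = sum_i i*S_i/(n-1)
    and the variance uses theta_W and S(S-1)/(a1^2 + a2) as the theta and
    theta^2 estimates (note pi - theta_H = 2*(pi - theta_L), so the two
    versions order loci identically).  The unnormalized original is the
    default.
    """
    n = matrix.n_chrom
    sfs, n_pol = site_frequency_spectrum(matrix, outgroup_taxon)
    stats = tajimas_d(matrix)
    i = np.arange(1, n)
    if n_pol == 0:
        stats.theta_h = math.nan
        stats.H = math.nan
        stats.sfs = sfs
        return stats
    pi_pol = float(np.sum(2.0 * sfs * i * (n - i)) / (n * (n - 1)))
    theta_h = float(np.sum(2.0 * sfs * i**2) / (n * (n - 1)))
    stats.theta_h = theta_h
    stats.sfs = sfs
    stats.n_polarized = n_pol
    if not normalized:
        stats.H = pi_pol - theta_h
        return stats
    s = n_pol
    coef = tajima_coefficients(n)
    theta = s / coef.a1
    theta_sq = s * (s - 1.0) / (coef.a1**2 + coef.a2)
    bn1 = float(np.sum(1.0 / np.arange(1, n + 1) ** 2))
    var = (n - 2.0) / (6.0 * (n - 1.0)) * theta + (
        18.0 * n**2 * (3.0 * n + 2.0) * bn1 - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
    ) / (9.0 * n * (n - 1.0) ** 2) * theta_sq
    theta_l = float(np.sum(sfs * i) / (n - 1.0))
    stats.H = (pi_pol - theta_l) / math.sqrt(var) if var > 0 else math.nan
    return stats


def expected_heterozygosity(
    matrix: HaplotypeMatrix, sample_size_correction: bool = True
) -> tuple[np.ndarray, float]:
    """Per-site expected heterozygosity 2p(1-p), with the n/(n-1) small-sample
    correction by default, and its mean over all retained columns
    (monomorphic columns contribute 0)."""
    n = matrix.n_chrom
    per_site = np.zeros(matrix.n_sites)
    counts = []
    col_idx = []
    for j in range(matrix.n_sites):
        col = matrix.alleles[:, j]
        alleles = sorted(set(col.tolist()))
        if len(alleles) == 2:
            col_idx.append(j)
            counts.append(int(np.sum(col == alleles[1])))
    for j, k in zip(col_idx, counts):
        p = k / n
        h = 2.0 * p * (1.0 - p)
        if sample_size_correction:
            h *= n / (n - 1.0)
        per_site[j] = h
    mean = float(per_site.mean()) if matrix.n_sites else math.nan
    return per_site, mean


@dataclass
class TailResult:
    """One locus flagged in an empirical tail of the D distribution."""

    locus_id: str
    tail: str  # "lower" (sweep) | "upper" (balancing)
    value: float
    empirical_quantile: float
    sim_p: float | None = None
    h_confirmed: dict[str, bool] = field(default_factory=dict)


def empirical_tails(
    values: dict[str, float], alpha: float = 0.05
) -> tuple[list[TailResult], tuple[float, float]]:
    """Flag the alpha/2 most extreme loci in each tail of the empirical
    distribution.

    Exactly k = floor(alpha/2 * n_loci) loci are flagged per tail, by rank
    rather than by threshold; ties are broken by locus id so the call is
    deterministic.  Returns the flagged loci and the descriptive thresholds
    (most extreme unflagged value in each direction).
    """
    items = [(lid, v) for lid, v in values.items() if not math.isnan(v)]
    n_loci = len(items)
    k = int(math.floor(alpha / 2.0 * n_loci))
    if k < 1:
        raise ValueError(
            f"{n_loci} loci cannot populate {alpha / 2:.3%} tails (need >= {math.ceil(2 / alpha)})"
        )
    asc = sorted(items, key=lambda t: (t[1], t[0]))
    lower = asc[:k]
    desc = sorted(items, key=lambda t: (-t[1], t[0]))
    upper = desc[:k]
    lower_thr = asc[k][1]
    upper_thr = desc[k][1]
    results = []
    for rank, (lid, v) in enumerate(lower, start=1):
        results.append(TailResult(lid, "lower", v, rank / n_loci))
    for rank, (lid, v) in enumerate(upper, start=1):
        results.append(TailResult(lid, "upper", v, rank / n_loci))
    return results, (lower_thr, upper_thr)
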