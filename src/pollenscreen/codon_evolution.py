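"""Codon-model divergence screen: alignment validation, NG86 pairwise dN/dS,
neighbor-joining trees, and GY94 site-model likelihoods (M0, M8a, M8) with
the M8-vs-M8a likelihood-ratio test for positive selection.

The substitution model is Goldman-Yang style: a 61-state (universal-code
sense codons) continuous-time Markov chain in which single-nucleotide codon
changes occur at rate proportional to the target codon's equilibrium
frequency, multiplied by kappa for transitions and by omega for
nonsynonymous changes; multi-nucleotide instantaneous changes are forbidden,
and the matrix is scaled to one expected substitution per codon per unit
branch length.  Site models mix omega across sites:

* M0   — a single omega shared by all sites;
* M8a  — omega ~ discretized Beta(p, q) on (0, 1) with weight p0, plus a
         point mass at omega = 1 with weight 1 - p0;
* M8   — as M8a but the extra class has a free omega_s >= 1.

Twice the log-likelihood difference between M8 and M8a, referred to a
chi-square distribution, tests for a class of positively selected sites.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "CODONS",
    "CodonAlignment",
    "PairwiseRates",
    "CodonModelFit",
    "LRTResult",
    "validate_alignment",
    "ng86",
    "nj_tree",
    "f1x4_frequencies",
    "f61_frequencies",
    "gy94_rate_matrix",
    "gy94_loglik",
    "fit_m0",
    "fit_m8a",
    "fit_m8",
    "lrt_m8_vs_m8a",
    "m8_site_classes",
    "simulate_codon_alignment",
]

# ---------------------------------------------------------------------------
# genetic code tables
# ---------------------------------------------------------------------------

_BASES = "TCAG"
_STANDARD_STOPS = {"TAA", "TAG", "TGA"}


def _standard_code() -> dict[str, str]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return code


_CODE = _standard_code()
CODONS: list[str] = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STANDARD_STOPS
]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
AMINO = np.array([_CODE[c] for c in CODONS])
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _single_step_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean (61,61) tables: single-nucleotide neighbor, transition,
    synonymous."""
    n = len(CODONS)
    nb = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    syn = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            nb[i, j] = True
            k = diff[0]
            ts[i, j] = (ci[k], cj[k]) in _TRANSITIONS
            syn[i, j] = AMINO[i] == AMINO[j]
    return nb, ts, syn


_NEIGHBOR, _IS_TS, _IS_SYN = _single_step_tables()


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """An in-frame codon alignment ready for analysis.

    ``codons`` holds the sense-codon index per (taxon, column), or -1 where
    the codon contains a gap or ambiguity; such columns are masked from
    likelihood computation.  ``unambiguous_fraction`` is per retained taxon.
    """

    names: list[str]
    codons: np.ndarray
    unambiguous_fraction: dict[str, float]
    dropped_taxa: list[str] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return len(self.names)

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    @property
    def clean_columns(self) -> np.ndarray:
        return np.all(self.codons >= 0, axis=0)

    @property
    def site_model_eligible(self) -> bool:
        return self.n_taxa >= 3

    def sequence(self, name: str) -> str:
        row = self.codons[self.names.index(name)]
        return "".join(CODONS[c] if c >= 0 else "---" for c in row)


def _codon_row(seq: str) -> np.ndarray:
    out = np.full(len(seq) // 3, -1, dtype=np.int64)
    for i in range(len(out)):
        codon = seq[3 * i : 3 * i + 3].upper()
        out[i] = CODON_INDEX.get(codon, -1)
    return out


def validate_alignment(
    records: list[tuple[str, str]],
    min_unambiguous: float = 0.75,
    min_taxa: int = 3,
) -> CodonAlignment:
    """Validate an in-frame alignment and apply the per-taxon quality filter.

    Taxa with less than ``min_unambiguous`` unambiguous (ACGT) bases are
    dropped.  Internal stop codons in otherwise unambiguous codons are an
    error, as are ragged or out-of-frame sequences.  The returned alignment
    records whether it retains enough taxa (``min_taxa``) for site-model
    fitting; pairwise operations only need two.
    """
    if not records:
        raise ValueError("empty alignment")
    length = len(records[0][1])
    if length % 3:
        raise ValueError(f"alignment length {length} not divisible by 3")
    for name, seq in records:
        if len(seq) != length:
            raise ValueError(f"taxon {name!r}: length {len(seq)} != {length}")
    names, rows, fracs, dropped = [], [], {}, []
    for name, seq in records:
        seq = seq.upper()
        for i in range(0, length - 3, 3):
            codon = seq[i : i + 3]
            if codon in _STANDARD_STOPS:
                raise ValueError(f"taxon {name!r}: internal stop {codon} at codon {i // 3 + 1}")
        frac = sum(1 for ch in seq if ch in "ACGT") / length
        if frac < min_unambiguous:
            dropped.append(name)
            continue
        names.append(name)
        fracs[name] = frac
        rows.append(_codon_row(seq))
    if len(names) < 2:
        raise ValueError("fewer than 2 taxa pass the unambiguous-base filter")
    # a terminal stop codon (stop-inclusive CDS) is not indexable as a sense
    # codon and is therefore masked automatically
    return CodonAlignment(
        names=names,
        codons=np.vstack(rows),
        unambiguous_fraction=fracs,
        dropped_taxa=dropped,
    )


# ---------------------------------------------------------------------------
# NG86 pairwise dN/dS
# ---------------------------------------------------------------------------

def _syn_site_fraction() -> np.ndarray:
    """Per-codon count of synonymous sites: for each position, the fraction
    of non-stop single-nucleotide neighbors that are synonymous."""
    out = np.zeros(len(CODONS))
    for i, codon in enumerate(CODONS):
        s = 0.0
        for pos in range(3):
            syn = 0
            non_stop = 0
            for b in _BASES:
                if b == codon[pos]:
                    continue
                neighbor = codon[:pos] + b + codon[pos + 1 :]
                if neighbor in _STANDARD_STOPS:
                    continue
                non_stop += 1
                if _CODE[neighbor] == _CODE[codon]:
                    syn += 1
            if non_stop:
                s += syn / non_stop
        out[i] = s
    return out


_SYN_SITES = _syn_site_fraction()


def _pathway_diffs() -> tuple[np.ndarray, np.ndarray]:
    """(61,61) synonymous / nonsynonymous difference counts, averaged over
    minimal mutational pathways that avoid stop codons."""
    n = len(CODONS)
    sd = np.zeros((n, n))
    nd = np.zeros((n, n))
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            path_syn = []
            path_non = []
            for order in itertools.permutations(diff):
                cur = ci
                s = ns = 0
                ok = True
                for pos in order:
                    nxt = cur[:pos] + cj[pos] + cur[pos + 1 :]
                    if nxt in _STANDARD_STOPS:
                        ok = False
                        break
                    if _CODE[cur] == _CODE[nxt]:
                        s += 1
                    else:
                        ns += 1
                    cur = nxt
                if ok:
                    path_syn.append(s)
                    path_non.append(ns)
            if not path_syn:
                raise RuntimeError(f"no stop-free pathway {ci}->{cj}")
            sd[i, j] = float(np.mean(path_syn))
            nd[i, j] = float(np.mean(path_non))
    return sd, nd


_PATH_SD, _PATH_ND = _pathway_diffs()


@dataclass
class PairwiseRates:
    """Nei-Gojobori (1986) pairwise substitution rates with Jukes-Cantor
    correction.  ``omega`` is NaN when dS = 0; ``saturated`` flags a
    proportion >= 3/4 where the correction is undefined (the corresponding
    rate is infinity)."""

    dn: float
    ds: float
    n_sites: float
    s_sites: float
    n_diffs: float
    s_diffs: float
    saturated: bool = False

    @property
    def omega(self) -> float:
        if self.ds == 0 or not math.isfinite(self.ds):
            return math.nan
        return self.dn / self.ds


def _jc_correct(p: float) -> tuple[float, bool]:
    if p >= 0.75:
        return math.inf, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def ng86(seq1: str, seq2: str) -> PairwiseRates:
    """NG86 counting estimate of dN and dS between two in-frame sequences.

    Codon columns where either sequence is ambiguous (or a stop) are
    skipped.  Synonymous site counts are averaged between the two sequences;
    differences are partitioned by averaging over stop-free minimal
    pathways; Jukes-Cantor correction maps proportions to distances.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    if len(seq1) % 3:
        raise ValueError("sequence length not divisible by 3")
    c1 = _codon_row(seq1.upper())
    c2 = _codon_row(seq2.upper())
    ok = (c1 >= 0) & (c2 >= 0)
    c1, c2 = c1[ok], c2[ok]
    if c1.size == 0:
        raise ValueError("no jointly unambiguous codons")
    s_sites = float((_SYN_SITES[c1].sum() + _SYN_SITES[c2].sum()) / 2.0)
    n_sites = 3.0 * c1.size - s_sites
    s_diffs = float(_PATH_SD[c1, c2].sum())
    n_diffs = float(_PATH_ND[c1, c2].sum())
    ps = s_diffs / s_sites if s_sites > 0 else 0.0
    pn = n_diffs / n_sites if n_sites > 0 else 0.0
    ds, sat_s = _jc_correct(ps)
    dn, sat_n = _jc_correct(pn)
    return PairwiseRates(
        dn=dn, ds=ds, n_sites=n_sites, s_sites=s_sites,
        n_diffs=n_diffs, s_diffs=s_diffs, saturated=sat_s or sat_n,
    )


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _jc_nucleotide_distance(aln: CodonAlignment) -> np.ndarray:
    """Jukes-Cantor-corrected nucleotide distance matrix over pairwise
    unambiguous positions; raises naming the pair on saturation."""
    n = aln.n_taxa
    seqs = [aln.sequence(name) for name in aln.names]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[i], seqs[j]
            tot = diff = 0
            for x, y in zip(a, b):
                if x in "ACGT" and y in "ACGT":
                    tot += 1
                    diff += x != y
            if tot == 0:
                raise ValueError(f"no comparable sites between {aln.names[i]!r} and {aln.names[j]!r}")
            p = diff / tot
            if p >= 0.75:
                raise ValueError(
                    f"saturated distance between {aln.names[i]!r} and {aln.names[j]!r} (p = {p:.3f})"
                )
            d[i, j] = d[j, i] = -0.75 * math.log1p(-4.0 * p / 3.0)
    return d


def nj_tree(alignment: CodonAlignment):
    """Saitou-Nei neighbor-joining tree from JC-corrected nucleotide
    distances; negative branch lengths are clipped to zero.  Returns a
    scikit-bio TreeNode."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if alignment.n_taxa < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dm = DistanceMatrix(_jc_nucleotide_distance(alignment), ids=alignment.names)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# GY94 likelihood machinery
# ---------------------------------------------------------------------------

def f1x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """Equilibrium codon frequencies from position-averaged nucleotide
    frequencies (F1X4), stops excluded and renormalized."""
    counts = {b: 0 for b in "ACGT"}
    for name in alignment.names:
        for ch in alignment.sequence(name):
            if ch in counts:
                counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous bases")
    f = {b: max(counts[b] / total, 1e-6) for b in "ACGT"}
    freqs = np.array([f[c[0]] * f[c[1]] * f[c[2]] for c in CODONS])
    return freqs / freqs.sum()


def f61_frequencies(alignment: CodonAlignment, pseudocount: float = 1.0) -> np.ndarray:
    """Empirical codon frequencies (F61) with a pseudocount."""
    flat = alignment.codons[alignment.codons >= 0]
    counts = np.bincount(flat, minlength=len(CODONS)).astype(float) + pseudocount
    return counts / counts.sum()


def gy94_rate_matrix(
    kappa: float, omega: float, freqs: np.ndarray, normalize: bool = True
) -> np.ndarray:
    """GY94 instantaneous rate matrix; scaled to mean rate one when
    ``normalize`` (appropriate for a single-class model — in site-class
    mixtures one normalization constant is shared across classes so that
    selected classes genuinely evolve faster)."""
    q = np.where(_NEIGHBOR, freqs[None, :], 0.0)
    q = q * np.where(_IS_TS, kappa, 1.0) * np.where(_IS_SYN, 1.0, omega)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    if not normalize:
        return q
    rate = -float(freqs @ np.diag(q))
    if rate <= 0:
        raise ValueError("degenerate rate matrix")
    return q / rate


def _class_generators(kappa: float, omegas: np.ndarray, freqs: np.ndarray):
    """Eigendecompositions of the unnormalized per-class generators.

    Returns (evals, left, right, rates): P_k(t) = left_k exp(evals_k t)
    right_k, and rates[k] is class k's mean substitution rate (used to form
    the shared mixture normalization)."""
    n = len(CODONS)
    qs = np.empty((len(omegas), n, n))
    for k, w in enumerate(omegas):
        qs[k] = gy94_rate_matrix(kappa, w, freqs, normalize=False)
    rates = -np.einsum("i,kii->k", freqs, qs)
    sqrt_f = np.sqrt(freqs)
    sym = qs * (sqrt_f[None, :, None] / sqrt_f[None, None, :])
    sym = 0.5 * (sym + np.swapaxes(sym, 1, 2))  # enforce exact symmetry
    evals, evecs = np.linalg.eigh(sym)
    left = evecs / sqrt_f[None, :, None]
    right = np.swapaxes(evecs, 1, 2) * sqrt_f[None, None, :]
    return evals, left, right, rates


def _transition_probabilities(
    kappa: float,
    omegas: np.ndarray,
    freqs: np.ndarray,
    lengths: np.ndarray,
    class_weights: np.ndarray | None = None,
) -> np.ndarray:
    """P[k, b] = expm(Q_k * t_b) batched over site classes k and branches b.

    Branch lengths are expected substitutions per codon averaged over the
    class mixture: every class shares the normalization
    C = sum_k w_k rate_k (equal weights if none given)."""
    evals, left, right, rates = _class_generators(kappa, omegas, freqs)
    if class_weights is None:
        class_weights = np.full(len(omegas), 1.0 / len(omegas))
    c = float(np.asarray(class_weights) @ rates)
    if c <= 0:
        raise ValueError("degenerate rate matrix")
    e = np.exp(evals[:, None, :] * (np.asarray(lengths)[None, :, None] / c))
    out = np.einsum("kab,ktb,kbc->ktac", left, e, right, optimize=True)
    np.clip(out, 0.0, None, out=out)
    return out


@dataclass
class _TreeArrays:
    """Array form of a (possibly multifurcating) rooted tree for pruning."""

    parent: np.ndarray
    lengths: np.ndarray
    children: list[list[int]]
    postorder: list[int]
    leaf_of_name: dict[str, int]
    root: int
    n_nodes: int


def _tree_arrays(tree, names: list[str]) -> _TreeArrays:
    """Index a scikit-bio TreeNode against the alignment's taxa.  The root's
    own branch (if any) is ignored; missing branch lengths are zero."""
    nodes = list(tree.postorder(include_self=True))
    index = {id(node): i for i, node in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    children: list[list[int]] = [[] for _ in range(n)]
    leaf_of_name: dict[str, int] = {}
    for node in nodes:
        i = index[id(node)]
        if node.parent is not None and id(node.parent) in index:
            parent[i] = index[id(node.parent)]
            children[parent[i]].append(i)
            lengths[i] = float(node.length or 0.0)
        if node.is_tip():
            if node.name in leaf_of_name:
                raise ValueError(f"duplicate leaf {node.name!r}")
            leaf_of_name[node.name] = i
    missing = set(names) - set(leaf_of_name)
    if missing:
        raise ValueError(f"tree lacks taxa {sorted(missing)}")
    root = index[id(nodes[-1])]
    postorder = [index[id(node)] for node in nodes]
    return _TreeArrays(parent, lengths, children, postorder, leaf_of_name, root, n)


def _pattern_compress(codons: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique clean columns and their multiplicities."""
    clean = codons[:, np.all(codons >= 0, axis=0)]
    if clean.shape[1] == 0:
        raise ValueError("no unambiguous columns for likelihood computation")
    patterns, counts = np.unique(clean, axis=1, return_counts=True)
    return patterns, counts


def gy94_loglik(
    alignment: CodonAlignment,
    tree,
    kappa: float,
    site_class_omegas,
    class_weights,
    codon_freqs: np.ndarray | None = None,
    scale: float = 1.0,
    _ctx: dict | None = None,
) -> float:
    """Log-likelihood of the alignment under a GY94 site-class mixture.

    Felsenstein pruning over the 61 sense-codon states; columns containing
    any gap/ambiguity are masked.  ``scale`` multiplies every branch length
    (models are fit with a free tree-scale factor).  ``_ctx`` is a reusable
    cache of tree arrays and site patterns for repeated evaluation.
    """
    omegas = np.atleast_1d(np.asarray(site_class_omegas, dtype=float))
    weights = np.atleast_1d(np.asarray(class_weights, dtype=float))
    if omegas.shape != weights.shape:
        raise ValueError("class omegas and weights differ in shape")
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("class weights must sum to 1")
    if codon_freqs is None:
        codon_freqs = f1x4_frequencies(alignment)
    if _ctx is None:
        _ctx = {}
    if "tree" not in _ctx:
        _ctx["tree"] = _tree_arrays(tree, alignment.names)
        _ctx["patterns"], _ctx["counts"] = _pattern_compress(alignment.codons)
        _ctx["leaf_rows"] = {
            _ctx["tree"].leaf_of_name[name]: alignment.names.index(name)
            for name in alignment.names
        }
    ta: _TreeArrays = _ctx["tree"]
    patterns, counts = _ctx["patterns"], _ctx["counts"]
    leaf_rows = _ctx["leaf_rows"]

    # per-class site likelihoods depend on (kappa, omegas, scale) but not on
    # the class weights, so they are cached: weight-only perturbations (e.g.
    # the p0 component of a numerical gradient) reuse the pruning pass
    eig_key = (float(kappa), omegas.tobytes())
    eig_cache = _ctx.setdefault("eig_cache", {})
    if eig_key in eig_cache:
        evals, left, right, rates = eig_cache[eig_key]
    else:
        evals, left, right, rates = _class_generators(kappa, omegas, codon_freqs)
        if len(eig_cache) > 32:
            eig_cache.clear()
        eig_cache[eig_key] = (evals, left, right, rates)
    c = float(weights @ rates)  # shared mixture normalization
    if c <= 0:
        raise FloatingPointError("degenerate rate matrix")
    site_key = (float(kappa), omegas.tobytes(), float(scale / c))
    site_cache = _ctx.setdefault("site_cache", {})
    if site_key in site_cache:
        site_lik = site_cache[site_key]
    else:
        lengths = ta.lengths * (scale / c)
        e = np.exp(evals[:, None, :] * lengths[None, :, None])  # (K, B, 61)
        pmats = np.einsum("kab,ktb,kbc->ktac", left, e, right, optimize=True)
        np.clip(pmats, 0.0, None, out=pmats)

        n_classes = len(omegas)
        n_pat = patterns.shape[1]
        partials: dict[int, np.ndarray] = {}
        for node in ta.postorder:
            if not ta.children[node]:
                continue
            part = np.ones((n_classes, n_pat, len(CODONS)))
            for child in ta.children[node]:
                pc = pmats[:, child]
                if not ta.children[child]:
                    obs = patterns[leaf_rows[child]]
                    contrib = pc[:, :, obs].transpose(0, 2, 1)
                else:
                    contrib = np.einsum("kpj,kij->kpi", partials.pop(child), pc, optimize=True)
                part *= contrib
            partials[node] = part
        site_lik = np.einsum("kpi,i->kp", partials[ta.root], codon_freqs)
        if len(site_cache) > 32:
            site_cache.clear()
        site_cache[site_key] = site_lik
    mixed = weights @ site_lik
    if np.any(mixed <= 0) or not np.all(np.isfinite(mixed)):
        bad = int(np.argmin(np.where(np.isfinite(mixed), mixed, -np.inf)))
        raise FloatingPointError(f"non-finite site likelihood at pattern {bad}")
    return float(counts @ np.log(mixed))


# ---------------------------------------------------------------------------
# site models and fitting
# ---------------------------------------------------------------------------

DEFAULT_BETA_CATEGORIES = 10


def m8_site_classes(
    p0: float, p_beta: float, q_beta: float, omega_s: float, k: int = DEFAULT_BETA_CATEGORIES
) -> tuple[np.ndarray, np.ndarray]:
    """Discretized M8/M8a site classes: ``k`` equal-probability Beta
    categories (category omega at the quantile midpoint) with total weight
    p0, plus one class at ``omega_s`` with weight 1 - p0 (omega_s = 1 gives
    M8a)."""
    if not 0.0 <= p0 <= 1.0:
        raise ValueError("p0 must be in [0, 1]")
    quantiles = (np.arange(k) + 0.5) / k
    omegas = sps.beta.ppf(quantiles, p_beta, q_beta)
    omegas = np.append(omegas, omega_s)
    weights = np.append(np.full(k, p0 / k), 1.0 - p0)
    return omegas, weights


@dataclass
class CodonModelFit:
    """A fitted site model for one gene."""

    model: str
    lnl: float
    kappa: float
    scale: float
    omega: float | None = None
    p0: float | None = None
    p_beta: float | None = None
    q_beta: float | None = None
    omega_s: float | None = None
    converged: bool = True
    n_restarts: int = 1


def _maximize(objective, starts, bounds, maxiter=200):
    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            objective, np.asarray(x0, dtype=float), method="L-BFGS-B",
            bounds=bounds, options={"maxiter": maxiter},
        )
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return best, any_success


def _require_eligible(alignment: CodonAlignment) -> None:
    if not alignment.site_model_eligible:
        raise ValueError(
            f"site-model fitting needs >= 3 taxa (have {alignment.n_taxa})"
        )


def fit_m0(
    alignment: CodonAlignment,
    tree,
    codon_freqs: np.ndarray | None = None,
    n_restarts: int = 3,
) -> CodonModelFit:
    """Maximum-likelihood fit of the one-ratio model M0 over
    (kappa, tree scale, omega)."""
    _require_eligible(alignment)
    if codon_freqs is None:
        codon_freqs = f1x4_frequencies(alignment)
    ctx: dict = {}

    def objective(x):
        kappa, scale, omega = np.exp(x)
        try:
            return -gy94_loglik(
                alignment, tree, kappa, [omega], [1.0], codon_freqs, scale, _ctx=ctx
            )
        except FloatingPointError:
            return 1e12

    starts = [
        np.log([2.0, 1.0, 0.3]),
        np.log([1.0, 0.5, 0.05]),
        np.log([4.0, 2.0, 1.0]),
    ][:max(1, n_restarts)]
    bounds = [(-3.0, 4.0), (-7.0, 4.0), (-9.0, 3.5)]
    best, ok = _maximize(objective, starts, bounds)
    kappa, scale, omega = np.exp(best.x)
    return CodonModelFit(
        model="M0", lnl=-float(best.fun), kappa=float(kappa), scale=float(scale),
        omega=float(omega), converged=ok, n_restarts=len(starts),
    )


def _beta_mix_objective(alignment, tree, codon_freqs, ctx, k, fixed_omega_s):
    def objective(x):
        kappa = math.exp(x[0])
        scale = math.exp(x[1])
        p0 = 1.0 / (1.0 + math.exp(-x[2]))
        p_beta = math.exp(x[3])
        q_beta = math.exp(x[4])
        omega_s = fixed_omega_s if fixed_omega_s is not None else 1.0 + math.exp(x[5])
        omegas, weights = m8_site_classes(p0, p_beta, q_beta, omega_s, k)
        try:
            return -gy94_loglik(
                alignment, tree, kappa, omegas, weights, codon_freqs, scale, _ctx=ctx
            )
        except FloatingPointError:
            return 1e12

    return objective


_BETA_BOUNDS = [(-3.0, 4.0), (-7.0, 4.0), (-9.0, 9.0), (-3.0, 4.5), (-3.0, 4.5)]


def fit_m8a(
    alignment: CodonAlignment,
    tree,
    codon_freqs: np.ndarray | None = None,
    n_restarts: int = 3,
    k: int = DEFAULT_BETA_CATEGORIES,
    warm_start: CodonModelFit | None = None,
) -> CodonModelFit:
    """Fit M8a: discretized-Beta omega plus a point mass fixed at
    omega = 1.  ``warm_start`` (typically the gene's cheap M0 fit) seeds
    kappa and the tree scale in every dispersed start."""
    _require_eligible(alignment)
    if codon_freqs is None:
        codon_freqs = f1x4_frequencies(alignment)
    ctx: dict = {}
    objective = _beta_mix_objective(alignment, tree, codon_freqs, ctx, k, fixed_omega_s=1.0)
    if warm_start is not None:
        lk = min(max(math.log(warm_start.kappa), -3.0), 4.0)
        ls = min(max(math.log(warm_start.scale), -7.0), 4.0)
    else:
        lk, ls = math.log(2.0), 0.0
    starts = [
        [lk, ls, 2.0, math.log(0.5), math.log(2.0)],
        [lk, ls, 0.0, math.log(1.0), math.log(1.0)],
        [lk, ls, 4.0, math.log(0.2), math.log(3.0)],
    ][:max(1, n_restarts)]
    best, ok = _maximize(objective, starts, _BETA_BOUNDS)
    kappa, scale = math.exp(best.x[0]), math.exp(best.x[1])
    p0 = 1.0 / (1.0 + math.exp(-best.x[2]))
    return CodonModelFit(
        model="M8a", lnl=-float(best.fun), kappa=kappa, scale=scale,
        p0=p0, p_beta=math.exp(best.x[3]), q_beta=math.exp(best.x[4]),
        omega_s=1.0, converged=ok, n_restarts=len(starts),
    )


def fit_m8(
    alignment: CodonAlignment,
    tree,
    codon_freqs: np.ndarray | None = None,
    n_restarts: int = 3,
    k: int = DEFAULT_BETA_CATEGORIES,
    warm_start: CodonModelFit | None = None,
) -> CodonModelFit:
    """Fit M8: discretized-Beta omega plus a free selection class with
    omega_s >= 1.  ``warm_start`` (typically the gene's M8a fit) seeds one
    of the dispersed starting points, which also guarantees the nesting
    inequality lnL(M8) >= lnL(M8a) up to optimizer tolerance."""
    _require_eligible(alignment)
    if codon_freqs is None:
        codon_freqs = f1x4_frequencies(alignment)
    ctx: dict = {}
    objective = _beta_mix_objective(alignment, tree, codon_freqs, ctx, k, fixed_omega_s=None)
    if warm_start is not None:
        lk = min(max(math.log(warm_start.kappa), -3.0), 4.0)
        ls = min(max(math.log(warm_start.scale), -7.0), 4.0)
    else:
        lk, ls = math.log(2.0), 0.0
    starts = [
        [lk, ls, 2.0, math.log(0.5), math.log(2.0), math.log(1.0)],
        [lk, ls, 0.0, math.log(1.0), math.log(1.0), math.log(3.0)],
        [lk, ls, 4.0, math.log(0.2), math.log(3.0), math.log(0.25)],
    ][:max(1, n_restarts)]
    warm_point = None
    if warm_start is not None and warm_start.model == "M8a":
        warm_point = np.array(
            [
                math.log(warm_start.kappa), math.log(warm_start.scale),
                math.log(warm_start.p0 / max(1e-9, 1.0 - warm_start.p0))
                if 0 < warm_start.p0 < 1 else (9.0 if warm_start.p0 >= 1 else -9.0),
                math.log(warm_start.p_beta), math.log(warm_start.q_beta),
                math.log(1e-6),
            ]
        )
        starts.insert(0, list(warm_point))
    bounds = _BETA_BOUNDS + [(math.log(1e-6), math.log(50.0))]
    best, ok = _maximize(objective, starts, bounds)
    if warm_start is not None and -best.fun < warm_start.lnl:
        # omega_s = 1 lies in M8's parameter space (boundary), where M8
        # coincides with M8a: the nested MLE can never fall below the M8a
        # optimum, so return that boundary solution exactly
        return CodonModelFit(
            model="M8", lnl=warm_start.lnl, kappa=warm_start.kappa,
            scale=warm_start.scale, p0=warm_start.p0, p_beta=warm_start.p_beta,
            q_beta=warm_start.q_beta, omega_s=1.0, converged=ok,
            n_restarts=len(starts),
        )
    kappa, scale = math.exp(best.x[0]), math.exp(best.x[1])
    p0 = 1.0 / (1.0 + math.exp(-best.x[2]))
    return CodonModelFit(
        model="M8", lnl=-float(best.fun), kappa=kappa, scale=scale,
        p0=p0, p_beta=math.exp(best.x[3]), q_beta=math.exp(best.x[4]),
        omega_s=1.0 + math.exp(best.x[5]), converged=ok, n_restarts=len(starts),
    )


@dataclass
class LRTResult:
    """Likelihood-ratio test of M8 against M8a for one gene."""

    gene_id: str
    stat: float
    df: int
    p_value: float
    q_value: float | None = None


def lrt_m8_vs_m8a(
    fit_null: CodonModelFit,
    fit_alt: CodonModelFit,
    gene_id: str = "gene",
    df: int = 1,
    boundary_mixture: bool = False,
) -> LRTResult:
    """2(lnL_M8 - lnL_M8a) against chi-square.

    ``boundary_mixture`` uses the 50:50 chi2_0 : chi2_1 mixture, more
    accurate for the boundary null; the plain chi2(1) reference (default) is
    conservative.
    """
    if fit_null.model != "M8a" or fit_alt.model != "M8":
        raise ValueError("expected an (M8a, M8) fit pair")
    stat = 2.0 * (fit_alt.lnl - fit_null.lnl)
    if stat < -1e-6:
        raise ValueError(f"{gene_id}: lnL(M8) < lnL(M8a) by {-stat / 2:.3g} — refit")
    stat = max(stat, 0.0)
    if boundary_mixture:
        p = 0.5 * float(sps.chi2.sf(stat, df)) + (0.5 if stat == 0.0 else 0.0)
    else:
        p = float(sps.chi2.sf(stat, df))
    return LRTResult(gene_id=gene_id, stat=stat, df=df, p_value=p)


def fit_site_models(
    alignment: CodonAlignment,
    tree,
    codon_freqs: np.ndarray | None = None,
    n_restarts: int = 3,
    k: int = DEFAULT_BETA_CATEGORIES,
) -> tuple[CodonModelFit, CodonModelFit, CodonModelFit]:
    """Fit M0, M8a and M8 for one gene with warm-started chaining
    (M0 seeds kappa/scale for M8a; M8a seeds M8)."""
    if codon_freqs is None:
        codon_freqs = f1x4_frequencies(alignment)
    m0 = fit_m0(alignment, tree, codon_freqs, n_restarts=n_restarts)
    m8a = fit_m8a(alignment, tree, codon_freqs, n_restarts=n_restarts, k=k, warm_start=m0)
    m8 = fit_m8(alignment, tree, codon_freqs, n_restarts=n_restarts, k=k, warm_start=m8a)
    return m0, m8a, m8


# ---------------------------------------------------------------------------
# simulation under the model (used by the synthetic-data generators)
# ---------------------------------------------------------------------------

def simulate_codon_alignment(
    tree,
    site_omegas: np.ndarray,
    kappa: float,
    codon_freqs: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Evolve codon sites along a tree under GY94 with a per-site omega.

    The root sequence is drawn from the equilibrium frequencies; each branch
    applies the class-appropriate transition matrix.  Stop codons can never
    appear (the state space excludes them).  Returns (name, nucleotide
    sequence) pairs for the leaves.
    """
    site_omegas = np.asarray(site_omegas, dtype=float)
    classes, class_of = np.unique(site_omegas, return_inverse=True)
    leaf_names = [tip.name for tip in tree.tips()]
    ta = _tree_arrays(tree, leaf_names)
    class_weights = np.bincount(class_of, minlength=len(classes)) / site_omegas.size
    pmats = _transition_probabilities(kappa, classes, codon_freqs, ta.lengths, class_weights)
    n_sites = site_omegas.size
    states = np.empty((ta.n_nodes, n_sites), dtype=np.int64)
    states[ta.root] = rng.choice(len(CODONS), size=n_sites, p=codon_freqs)
    for node in reversed(ta.postorder):
        if node == ta.root:
            continue
        parent_states = states[ta.parent[node]]
        child = np.empty(n_sites, dtype=np.int64)
        for k in range(len(classes)):
            mask = class_of == k
            if not np.any(mask):
                continue
            cdf = np.cumsum(pmats[k, node], axis=1)
            cdf[:, -1] = 1.0
            u = rng.uniform(size=int(mask.sum()))
            rows = cdf[parent_states[mask]]
            child[mask] = (u[:, None] > rows).sum(axis=1)
        states[node] = child
    out = []
    for name in leaf_names:
        row = states[ta.leaf_of_name[name]]
        out.append((name, "".join(CODONS[c] for c in row)))
    return out
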