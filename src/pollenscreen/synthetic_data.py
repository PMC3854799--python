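"""Seeded generators producing inputs with the statistical structure each
pipeline stage assumes.

The study's raw data (spectral searches, exome captures, multi-taxon read
assemblies) are not desk-reproducible, so each stage is exercised on
synthetic inputs with planted truth:

* a three-replicate subtractive proteomics experiment with pollen-tube,
  style-only and shared proteins, near-empty labeled negative controls, and
  negative-binomial spectral counts;
* an ensemble of neutral coalescent loci plus loci whose site-frequency
  spectra are re-weighted toward rare or high-frequency-derived variants
  (sweep-like, Tajima's D < 0) or intermediate frequencies (balancing-like,
  D > 0);
* codon alignments simulated under M0 or under M8 with a known fraction of
  positively selected genes.

Every generator is a pure function of its config and seed, and emits truth
labels so downstream sensitivity and specificity are computable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coalescent_sim, codon_evolution
from .io_formats import SPECTRAL_COLUMNS, read_newick
from .popgen_stats import HaplotypeMatrix

__all__ = [
    "ProteomicsSimConfig",
    "PopgenSimConfig",
    "CodonSimConfig",
    "gen_proteomics_fixture",
    "gen_popgen_loci",
    "gen_codon_fixture",
    "DEFAULT_TREE_NEWICK",
]


# ---------------------------------------------------------------------------
# proteomics
# ---------------------------------------------------------------------------

@dataclass
class ProteomicsSimConfig:
    """Conditions of the subtractive proteomics experiment.

    Defaults mirror the study's scale: ~1,250 pollen-tube-only proteins,
    ~1,300 style-only, ~1,300 shared, three labeled biological replicates,
    four label-escape proteins in the pooled negative control, and a
    per-replicate detection probability of 0.75 (independent detection at
    0.75 gives the observed ~60% pairwise replicate overlap).
    """

    n_background: int = 1298
    n_ptp: int = 1244
    n_shared: int = 1310
    n_replicates: int = 3
    detection_prob: float = 0.75
    leakage_count: int = 4
    shared_peptide_frac: float = 0.05
    peptides_per_protein_mean: float = 4.0
    nb_mean: float = 6.0
    nb_dispersion: float = 1.0
    noise_peptides_per_experiment: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background", "n_ptp", "n_shared", "n_replicates", "leakage_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")
        if self.leakage_count > self.n_background:
            raise ValueError("leakage_count exceeds n_background")
        if not 0.0 <= self.shared_peptide_frac < 1.0:
            raise ValueError("shared_peptide_frac must be in [0, 1)")


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with given mean and dispersion r (variance
    mean + mean^2 / r)."""
    r = dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def gen_proteomics_fixture(config: ProteomicsSimConfig):
    """Generate spectral-evidence tables for every experiment plus truth.

    Returns ``(evidence, lengths, truth)`` where ``evidence`` maps an
    experiment name (``pollinated_rep1..k``, ``negative_control``,
    ``unpollinated_style``) to a peptide table, ``lengths`` maps protein id
    to amino-acid length, and ``truth`` labels each protein's compartment
    (pollen_tube / style / shared).
    """
    rng = np.random.default_rng(config.seed)
    proteins = (
        [f"PT{i:05d}" for i in range(config.n_ptp)]
        + [f"SH{i:05d}" for i in range(config.n_shared)]
        + [f"ST{i:05d}" for i in range(config.n_background)]
    )
    compartment = (
        ["pollen_tube"] * config.n_ptp
        + ["shared"] * config.n_shared
        + ["style"] * config.n_background
    )
    lengths = {p: int(rng.integers(80, 1200)) for p in proteins}

    # peptide universe: mostly protein-specific, a fraction shared with a
    # random partner to exercise parsimony grouping
    peptides_of: dict[str, list[str]] = {}
    pep_targets: dict[str, set[str]] = {}
    for p in proteins:
        k = 1 + rng.poisson(max(0.0, config.peptides_per_protein_mean - 1.0))
        peps = [f"pep_{p}_{i}" for i in range(k)]
        peptides_of[p] = peps
        for pep in peps:
            pep_targets[pep] = {p}
    if config.shared_peptide_frac > 0:
        all_peps = sorted(pep_targets)
        n_share = int(round(config.shared_peptide_frac * len(all_peps)))
        for pep in rng.choice(all_peps, size=n_share, replace=False):
            partner = proteins[int(rng.integers(len(proteins)))]
            pep_targets[pep].add(partner)
            if pep not in peptides_of[partner]:
                peptides_of[partner].append(pep)

    def emit(experiment: str, present: list[str], detect_p: float) -> pd.DataFrame:
        rows = []
        detected = [p for p in present if rng.uniform() < detect_p]
        for p in detected:
            peps = peptides_of[p]
            counts = _nb_counts(rng, config.nb_mean, config.nb_dispersion, len(peps))
            if counts.sum() == 0:
                counts[int(rng.integers(len(counts)))] = 1
            for pep, c in zip(peps, counts):
                if c == 0:
                    continue
                rows.append(
                    {
                        "experiment": experiment,
                        "peptide": pep,
                        "q_value": float(rng.uniform(0.0, 0.0015)),
                        "spectral_count": int(c),
                        "proteins": ";".join(sorted(pep_targets[pep])),
                    }
                )
        for i in range(config.noise_peptides_per_experiment):
            target = proteins[int(rng.integers(len(proteins)))]
            rows.append(
                {
                    "experiment": experiment,
                    "peptide": f"noise_{experiment}_{i}",
                    "q_value": float(rng.uniform(0.01, 0.5)),
                    "spectral_count": 1,
                    "proteins": target,
                }
            )
        df = pd.DataFrame(rows, columns=SPECTRAL_COLUMNS)
        return df.sort_values(["peptide"]).reset_index(drop=True)

    ptp_and_shared = proteins[: config.n_ptp + config.n_shared]
    style_and_shared = proteins[config.n_ptp :]
    evidence: dict[str, pd.DataFrame] = {}
    for r in range(1, config.n_replicates + 1):
        evidence[f"pollinated_rep{r}"] = emit(f"pollinated_rep{r}", ptp_and_shared, config.detection_prob)

    # pooled negative control: exactly leakage_count style proteins escape
    # the isotope mask, one spectrum each
    leak = (
        list(rng.choice(proteins[config.n_ptp + config.n_shared :], size=config.leakage_count, replace=False))
        if config.leakage_count
        else []
    )
    leak_rows = [
        {
            "experiment": "negative_control",
            "peptide": peptides_of[p][0],
            "q_value": float(rng.uniform(0.0, 0.0015)),
            "spectral_count": 1,
            "proteins": ";".join(sorted(pep_targets[peptides_of[p][0]])),
        }
        for p in leak
    ]
    evidence["negative_control"] = pd.DataFrame(leak_rows, columns=SPECTRAL_COLUMNS)

    evidence["unpollinated_style"] = emit("unpollinated_style", style_and_shared, config.detection_prob)

    truth = pd.DataFrame(
        {
            "protein_id": proteins,
            "compartment": compartment,
            "length": [lengths[p] for p in proteins],
            "is_leakage": [p in set(leak) for p in proteins],
        }
    )
    return evidence, lengths, truth


# ---------------------------------------------------------------------------
# population genetics
# ---------------------------------------------------------------------------

# theta per locus chosen so that the median segregating-site count at n = 56
# chromosomes is ~10, the desk-scale stand-in for the study's per-gene SNP
# yield (see docs/methods.md)
DEFAULT_THETA = 2.25


@dataclass
class PopgenSimConfig:
    """Conditions of the per-locus polymorphism ensemble: 2,352 loci sampled
    at 56 chromosomes (28 diploids), neutral unless a fraction is planted
    with sweep- or balancing-skewed spectra."""

    n_loci: int = 2352
    n_chrom: int = 56
    theta_per_locus: float = DEFAULT_THETA
    fixed_s: int | None = None
    prop_sweep: float = 0.0
    prop_balancing: float = 0.0
    skew_strength: float = 4.0
    mispolarization_rate: float = 0.0
    outgroup_taxa: tuple[str, ...] = ("tilingii", "cupriphilus")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chrom < 4:
            raise ValueError("n_chrom must be >= 4")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.prop_sweep < 0 or self.prop_balancing < 0 or self.prop_sweep + self.prop_balancing > 1:
            raise ValueError("prop_sweep + prop_balancing must be in [0, 1]")
        if self.theta_per_locus <= 0 and self.fixed_s is None:
            raise ValueError("need positive theta_per_locus or a fixed_s")
        if not 0.0 <= self.mispolarization_rate <= 1.0:
            raise ValueError("mispolarization_rate must be in [0, 1]")


def _skewed_sfs_probs(n: int, kind: str, skew: float) -> np.ndarray:
    """Site-frequency weights for planted loci.

    Starting from the neutral expectation (w_i proportional to 1/i), sweep
    loci exponentially up-weight singletons and the high-frequency-derived
    class (driving D < 0 and H < 0; in the infinite-skew limit singletons
    dominate), while balancing loci up-weight intermediate frequencies
    (D > 0).  Weights are tilted in log space so arbitrarily large skew is
    numerically safe.
    """
    i = np.arange(1, n)
    base = np.log(1.0 / i)
    if kind == "sweep":
        g = np.zeros(n - 1)
        g[0] = 1.0
        g[-1] = 0.8
        if n > 3:
            g[-2] = 0.4
    elif kind == "balancing":
        g = 1.0 - 2.0 * np.abs(i / n - 0.5)
    else:
        raise ValueError(f"unknown skew kind {kind!r}")
    logw = base + skew * g
    logw -= logw.max()
    w = np.exp(logw)
    return w / w.sum()


def _planted_locus(
    locus_id: str, n: int, s: int, probs: np.ndarray, config: PopgenSimConfig,
    rng: np.random.Generator,
) -> HaplotypeMatrix:
    alleles = np.full((n, s), "0", dtype="U1")
    counts = rng.choice(np.arange(1, n), size=s, p=probs)
    for j, c in enumerate(counts):
        carriers = rng.choice(n, size=int(c), replace=False)
        alleles[carriers, j] = "1"
    outgroups = {}
    for taxon in config.outgroup_taxa:
        anc = np.full(s, "0", dtype="U1")
        flip = rng.uniform(size=s) < config.mispolarization_rate
        anc[flip] = "1"
        outgroups[taxon] = anc
    return HaplotypeMatrix(locus_id, alleles, np.arange(1, s + 1), outgroups=outgroups)


def gen_popgen_loci(config: PopgenSimConfig) -> tuple[list[HaplotypeMatrix], pd.DataFrame]:
    """Generate the locus ensemble plus truth labels.

    Neutral loci come from the coalescent simulator (theta mode unless
    ``fixed_s`` is set); planted loci draw each variant's derived count from
    the re-weighted SFS.  Outgroup columns carry the ancestral state,
    flipped at the mispolarization rate.
    """
    rng = np.random.default_rng(config.seed)
    n_sweep = int(round(config.prop_sweep * config.n_loci))
    n_bal = int(round(config.prop_balancing * config.n_loci))
    n_neutral = config.n_loci - n_sweep - n_bal
    kinds = ["neutral"] * n_neutral + ["sweep"] * n_sweep + ["balancing"] * n_bal
    sweep_probs = _skewed_sfs_probs(config.n_chrom, "sweep", config.skew_strength)
    bal_probs = _skewed_sfs_probs(config.n_chrom, "balancing", config.skew_strength)
    a1 = float(np.sum(1.0 / np.arange(1, config.n_chrom)))

    loci: list[HaplotypeMatrix] = []
    rows = []
    width = len(str(config.n_loci))
    for idx, kind in enumerate(kinds):
        locus_id = f"locus_{idx + 1:0{width}d}"
        if kind == "neutral":
            g = coalescent_sim.simulate_genealogy(config.n_chrom, rng)
            if config.fixed_s is not None:
                m = coalescent_sim.drop_mutations(g, rng, fixed_s=config.fixed_s, locus_id=locus_id)
            else:
                m = coalescent_sim.drop_mutations(g, rng, theta=config.theta_per_locus, locus_id=locus_id)
            s = m.n_sites
            alleles = m.alleles
            positions = np.arange(1, s + 1)
            outgroups = {}
            anc = m.outgroups["ancestor"]
            for taxon in config.outgroup_taxa:
                vec = anc.copy()
                flip = rng.uniform(size=s) < config.mispolarization_rate
                vec[flip] = "1"
                outgroups[taxon] = vec
            m = HaplotypeMatrix(locus_id, alleles, positions, outgroups=outgroups)
        else:
            if config.fixed_s is not None:
                s = config.fixed_s
            else:
                s = int(rng.poisson(config.theta_per_locus * a1))
            probs = sweep_probs if kind == "sweep" else bal_probs
            m = _planted_locus(locus_id, config.n_chrom, s, probs, config, rng)
        loci.append(m)
        rows.append({"locus_id": locus_id, "class": kind, "S": m.n_sites})
    truth = pd.DataFrame(rows)
    return loci, truth


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

DEFAULT_TREE_NEWICK = "((tax1:0.08,tax2:0.08):0.04,(tax3:0.08,tax4:0.08):0.04,tax5:0.12);"


@dataclass
class CodonSimConfig:
    """Conditions of the divergence-screen fixture: five-taxon alignments of
    300 codons, background genes under a single constrained omega, positive
    genes under M8 with a selected class at omega_s."""

    n_genes: int = 20
    tree_newick: str = DEFAULT_TREE_NEWICK
    n_codons: int = 300
    kappa: float = 2.0
    omega0: float = 0.2
    prop_pos_genes: float = 0.0
    p0: float = 0.9
    p_beta: float = 0.5
    q_beta: float = 2.0
    omega_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_codons < 1:
            raise ValueError("n_genes and n_codons must be >= 1")
        if self.omega0 < 0:
            raise ValueError("omega0 must be >= 0")
        if not 0.0 <= self.prop_pos_genes <= 1.0:
            raise ValueError("prop_pos_genes must be in [0, 1]")
        if self.prop_pos_genes > 0 and self.omega_s < 1.0:
            raise ValueError("omega_s must be >= 1 (omega_s = 1 simulates the M8a boundary null)")
        if self.p_beta <= 0 or self.q_beta <= 0:
            raise ValueError("beta shape parameters must be positive")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")


def gen_codon_fixture(config: CodonSimConfig):
    """Simulate per-gene codon alignments with planted selection truth.

    Background genes evolve under M0 at ``omega0``; a ``prop_pos_genes``
    fraction evolves under M8 (per-site omega from Beta(p, q) with weight
    p0, else omega_s).  Returns ``(alignments, tree, truth)`` where
    ``alignments`` maps gene id to FASTA-ready (name, sequence) records.
    """
    from scipy import stats as sps

    rng = np.random.default_rng(config.seed)
    tree = read_newick(config.tree_newick)
    if len(list(tree.tips())) < 3:
        raise ValueError("tree must have >= 3 leaves")
    freqs = np.full(len(codon_evolution.CODONS), 1.0 / len(codon_evolution.CODONS))
    n_pos = int(round(config.prop_pos_genes * config.n_genes))
    alignments: dict[str, list[tuple[str, str]]] = {}
    rows = []
    width = len(str(config.n_genes))
    for idx in range(config.n_genes):
        gene_id = f"gene_{idx + 1:0{width}d}"
        positive = idx < n_pos
        if positive:
            from_beta = rng.uniform(size=config.n_codons) < config.p0
            site_omegas = np.where(
                from_beta,
                sps.beta.rvs(config.p_beta, config.q_beta, size=config.n_codons, random_state=rng),
                config.omega_s,
            )
            model = "M8" if config.omega_s > 1.0 else "M8a"
        else:
            site_omegas = np.full(config.n_codons, config.omega0)
            model = "M0"
        records = codon_evolution.simulate_codon_alignment(
            tree, site_omegas, config.kappa, freqs, rng
        )
        alignments[gene_id] = records
        rows.append(
            {
                "gene_id": gene_id,
                "model": model,
                "omega0": config.omega0 if not positive else math.nan,
                "omega_s": config.omega_s if positive else math.nan,
                "p0": config.p0 if positive else math.nan,
            }
        )
    truth = pd.DataFrame(rows)
    return alignments, tree, truth
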