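"""Readers and writers for every external representation the pipeline touches.

Strictness over convenience: readers reject malformed input with a specific
error rather than coercing, and each writer's output round-trips through the
matching reader.  Formats: FASTA (via Biopython), newick (via scikit-bio),
Hudson ms-format text, and the pipeline's TSV tables (haplotype matrices,
spectral evidence, results).  Positions are 1-based in user-facing tables.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .popgen_stats import MISSING, HaplotypeMatrix

__all__ = [
    "GenePanel",
    "read_fasta",
    "write_fasta",
    "read_haplotype_table",
    "write_haplotype_table",
    "read_ms_format",
    "write_ms_format",
    "read_spectral_tsv",
    "write_spectral_tsv",
    "read_newick",
    "write_newick",
    "read_results_tsv",
    "write_results_tsv",
    "read_gene_panel",
    "read_vcf_haplotypes",
]

_NUC_CHARS = set("ACGTUNRYSWKMBDHVacgtunryswkmbdhv-")
_AA_CHARS = set("ACDEFGHIKLMNPQRSTVWYXBZJUO*acdefghiklmnpqrstvwyxbzjuo-")


@dataclass
class GenePanel:
    """One gene of the search universe: CDS and protein lengths.

    ``stop_included`` records whether protein_length_aa counts the stop
    (cds/3) or not (cds/3 - 1)."""

    gene_id: str
    cds_length_nt: int
    protein_length_aa: int
    stop_included: bool

    def __post_init__(self) -> None:
        if self.cds_length_nt <= 0 or self.cds_length_nt % 3:
            raise ValueError(f"{self.gene_id}: CDS length {self.cds_length_nt} not a positive multiple of 3")
        expected = self.cds_length_nt // 3 - (0 if self.stop_included else 1)
        if self.protein_length_aa != expected:
            raise ValueError(
                f"{self.gene_id}: protein length {self.protein_length_aa} != {expected} "
                f"(cds {self.cds_length_nt}, stop_included={self.stop_included})"
            )


def read_gene_panel(path: str | Path) -> list[GenePanel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "cds_length_nt", "protein_length_aa", "stop_included"}
    if missing := required - set(df.columns):
        raise ValueError(f"gene panel missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene id {dup!r}")
    return [
        GenePanel(r.gene_id, int(r.cds_length_nt), int(r.protein_length_aa), bool(r.stop_included))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _find_bad_char_line(path: str | Path, allowed: set[str]) -> tuple[int, str]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            for ch in line.strip():
                if ch not in allowed:
                    return lineno, ch
    return -1, "?"


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[tuple[str, str]]:
    """Parse a FASTA file into (name, sequence) pairs.

    ``alphabet`` is "nucleotide" (IUPAC ambiguity allowed) or "protein".
    Duplicate record names and out-of-alphabet characters are errors.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError("alphabet must be 'nucleotide' or 'protein'")
    allowed = _NUC_CHARS if alphabet == "nucleotide" else _AA_CHARS
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty sequence for record {name!r}")
        if name in seen:
            raise ValueError(f"duplicate FASTA record name {name!r}")
        seen.add(name)
        bad = set(seq) - allowed
        if bad:
            lineno, ch = _find_bad_char_line(path, allowed)
            raise ValueError(f"illegal {alphabet} character {ch!r} at line {lineno}")
        records.append((name, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    names = [n for n, _ in records]
    if len(names) != len(set(names)):
        raise ValueError("duplicate record names")
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# haplotype tables
# ---------------------------------------------------------------------------

def read_haplotype_table(
    path: str | Path,
    outgroup_cols: list[str] | None = None,
    missing: str = MISSING,
) -> list[HaplotypeMatrix]:
    """Read a TSV of per-site haplotype calls into per-locus matrices.

    Expected columns: ``locus_id``, ``position``, then one column per sampled
    chromosome.  Columns named in ``outgroup_cols`` (or prefixed
    ``outgroup_``) are attached as outgroup allele vectors keyed by taxon
    name.  Positions must be strictly increasing within each locus.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "locus_id" not in df.columns or "position" not in df.columns:
        raise ValueError("haplotype table needs 'locus_id' and 'position' columns")
    body = [c for c in df.columns if c not in ("locus_id", "position")]
    if outgroup_cols is None:
        outgroup_cols = [c for c in body if c.startswith("outgroup_")]
        taxon_of = {c: c[len("outgroup_"):] for c in outgroup_cols}
    else:
        unknown = set(outgroup_cols) - set(body)
        if unknown:
            raise ValueError(f"outgroup columns not in table: {sorted(unknown)}")
        taxon_of = {c: c.removeprefix("outgroup_") for c in outgroup_cols}
    chrom_cols = [c for c in body if c not in outgroup_cols]
    if not chrom_cols:
        raise ValueError("no chromosome columns")
    for col in chrom_cols + list(outgroup_cols):
        bad = df[~df[col].str.fullmatch(r"[A-Za-z01.]")]
        if len(bad):
            raise ValueError(f"column {col!r}: ragged or non-allele entry at row {bad.index[0]}")
    out = []
    for locus, grp in df.groupby("locus_id", sort=True):
        pos = grp["position"].astype(int).to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"locus {locus}: positions not strictly increasing")
        alleles = grp[chrom_cols].to_numpy(dtype="U1").T
        outgroups = {taxon_of[c]: grp[c].to_numpy(dtype="U1") for c in outgroup_cols}
        out.append(
            HaplotypeMatrix(
                locus_id=str(locus), alleles=alleles, positions=pos,
                outgroups=outgroups, missing_char=missing,
            )
        )
    return out


def write_haplotype_table(matrices: list[HaplotypeMatrix], path: str | Path) -> None:
    rows = []
    for m in matrices:
        for j in range(m.n_sites):
            row = {"locus_id": m.locus_id, "position": int(m.positions[j])}
            for c in range(m.n_chrom):
                row[f"chrom_{c + 1}"] = m.alleles[c, j]
            for taxon, vec in m.outgroups.items():
                row[f"outgroup_{taxon}"] = vec[j]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# ms-format text
# ---------------------------------------------------------------------------

def write_ms_format(replicates: list[HaplotypeMatrix], path: str | Path, header: str = "ms") -> None:
    """Write binary replicates in Hudson's ms text convention: a ``//`` block
    per replicate with ``segsites:`` and ``positions:`` lines, then one 0/1
    string per chromosome."""
    with open(path, "w") as fh:
        fh.write(f"{header}\n\n")
        for m in replicates:
            bad = set(m.alleles.ravel().tolist()) - {"0", "1"}
            if bad:
                raise ValueError(f"locus {m.locus_id}: non-binary allele {bad.pop()!r}")
            fh.write("//\n")
            fh.write(f"segsites: {m.n_sites}\n")
            if m.n_sites:
                fh.write("positions: " + " ".join(f"{p:.5f}" for p in m.positions) + "\n")
                for c in range(m.n_chrom):
                    fh.write("".join(m.alleles[c]) + "\n")
            fh.write("\n")


def read_ms_format(path: str | Path) -> list[HaplotypeMatrix]:
    """Read ms-convention text back into binary haplotype matrices."""
    text = Path(path).read_text()
    blocks = text.split("//")[1:]
    out = []
    for idx, block in enumerate(blocks):
        lines = [ln.strip() for ln in block.strip().splitlines() if ln.strip()]
        if not lines or not lines[0].startswith("segsites:"):
            raise ValueError(f"replicate {idx}: missing segsites line")
        segsites = int(lines[0].split(":")[1])
        if segsites == 0:
            out.append(HaplotypeMatrix(f"rep_{idx}", np.empty((2, 0), dtype="U1"), np.empty(0)))
            continue
        if not lines[1].startswith("positions:"):
            raise ValueError(f"replicate {idx}: missing positions line")
        positions = np.asarray([float(x) for x in lines[1].split(":")[1].split()])
        haps = lines[2:]
        if any(len(h) != segsites for h in haps):
            raise ValueError(f"replicate {idx}: haplotype length != segsites")
        alleles = np.asarray([list(h) for h in haps], dtype="U1")
        out.append(HaplotypeMatrix(f"rep_{idx}", alleles, positions))
    return out


# ---------------------------------------------------------------------------
# spectral evidence tables
# ---------------------------------------------------------------------------

SPECTRAL_COLUMNS = ["experiment", "peptide", "q_value", "spectral_count", "proteins"]


def read_spectral_tsv(path: str | Path) -> pd.DataFrame:
    """Peptide-level spectral evidence: one row per (experiment, peptide),
    with its identification q-value, summed spectral count in that
    experiment, and the semicolon-separated set of proteins the peptide maps
    to."""
    df = pd.read_csv(path, sep="\t", dtype={"experiment": str, "peptide": str, "proteins": str})
    if missing := set(SPECTRAL_COLUMNS) - set(df.columns):
        raise ValueError(f"spectral table missing columns: {sorted(missing)}")
    if ((df["q_value"] < 0) | (df["q_value"] > 1)).any():
        raise ValueError("q_value outside [0, 1]")
    if (df["spectral_count"] < 0).any():
        raise ValueError("negative spectral count")
    if (df["proteins"].fillna("") == "").any():
        raise ValueError("peptide with empty protein mapping")
    return df[SPECTRAL_COLUMNS]


def write_spectral_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df[SPECTRAL_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def read_newick(path_or_text: str | Path):
    """Parse a newick tree (scikit-bio TreeNode); rejects negative branch
    lengths."""
    from skbio import TreeNode

    text = str(path_or_text)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    tree = TreeNode.read(io.StringIO(text), format="newick")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length {node.length} at node {node.name!r}")
    return tree


def write_newick(tree, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

def write_results_tsv(
    table: pd.DataFrame, path: str | Path, descriptions: dict[str, str] | None = None
) -> None:
    """Write a results table with '#'-prefixed column-description header
    lines followed by the TSV body."""
    with open(path, "w") as fh:
        for col in table.columns:
            desc = (descriptions or {}).get(col, "")
            fh.write(f"# {col}: {desc}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# minimal VCF
# ---------------------------------------------------------------------------

def read_vcf_haplotypes(path: str | Path, locus_field: str = "CHROM") -> list[HaplotypeMatrix]:
    """Minimal VCF reader: biallelic SNP records, GT fields only, each sample
    contributing two chromosomes.  Loci are grouped by CHROM.  Missing
    genotype calls become the missing sentinel."""
    header_samples: list[str] | None = None
    rows: dict[str, list[tuple[int, list[str]]]] = {}
    gt_re = re.compile(r"([0-9.])[/|]([0-9.])")
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header_samples = line.split("\t")[9:]
                continue
            if header_samples is None:
                raise ValueError("VCF data before #CHROM header")
            parts = line.split("\t")
            if len(parts) != 9 + len(header_samples):
                raise ValueError(f"ragged VCF row: {parts[:2]}")
            chrom, pos, _, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            if "," in alt:
                raise ValueError(f"multi-allelic record at {chrom}:{pos} not supported")
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError(f"non-SNP record at {chrom}:{pos}")
            alleles = []
            for sample_field in parts[9:]:
                gt = sample_field.split(":")[0]
                m = gt_re.fullmatch(gt)
                if not m:
                    raise ValueError(f"unparsable GT {gt!r} at {chrom}:{pos}")
                for g in m.groups():
                    if g == ".":
                        alleles.append(MISSING)
                    elif g == "0":
                        alleles.append(ref)
                    elif g == "1":
                        alleles.append(alt)
                    else:
                        raise ValueError(f"allele index {g} at {chrom}:{pos} exceeds biallelic")
            rows.setdefault(chrom, []).append((pos, alleles))
    out = []
    for chrom in sorted(rows):
        recs = sorted(rows[chrom])
        positions = np.asarray([p for p, _ in recs])
        if np.any(np.diff(positions) <= 0):
            raise ValueError(f"duplicate position in {chrom}")
        alleles = np.asarray([a for _, a in recs], dtype="U1").T
        out.append(HaplotypeMatrix(chrom, alleles, positions))
    return out
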