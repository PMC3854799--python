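"""Subtractive identification of pollen-tube proteins from spectral evidence.

The experimental design: maternal styles are metabolically labeled with heavy
nitrogen, so their peptides shift mass and escape light-peptide database
matching; anything identified from a pollinated labeled style is (after
subtracting negative-control identifications) attributable to the growing
pollen tube.  This module takes peptide-level evidence — peptide, q-value,
spectral counts, protein mapping — and performs:

* the peptide confidence filter (q <= 0.002 by default);
* parsimony protein inference: proteins carrying a peptide unique to them are
  reported singly, proteins with identical peptide sets merge into one
  multi-protein group, and peptides already explained by a uniquely
  identified protein do not create further groups;
* the subtractive pollen-tube-protein (PTP) call: identified in any
  pollinated labeled replicate and absent from every negative control;
* NSAF relative abundance (spectral count over length, normalized to sum to
  one per experiment) and replicate-overlap summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProteinGroup",
    "NsafRecord",
    "filter_peptides",
    "infer_proteins",
    "classify_ptps",
    "compute_nsaf",
    "overlap_stats",
    "DEFAULT_Q_MAX",
]

DEFAULT_Q_MAX = 0.002


@dataclass(frozen=True)
class ProteinGroup:
    """A reported identification: a single protein distinguished by a unique
    peptide, or an indistinguishable multi-protein group."""

    group_id: int
    member_ids: frozenset[str]
    is_unique: bool

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError("empty protein group")
        if self.is_unique != (len(self.member_ids) == 1):
            raise ValueError("is_unique must hold exactly for singletons")

    @property
    def label(self) -> str:
        return ";".join(sorted(self.member_ids))


def filter_peptides(evidence: pd.DataFrame, q_max: float = DEFAULT_Q_MAX) -> pd.DataFrame:
    """Retain peptides with identification q-value <= ``q_max`` (boundary
    inclusive); spectral counts pass through untouched."""
    if not 0 < q_max <= 1:
        raise ValueError("q_max must be in (0, 1]")
    return evidence[evidence["q_value"] <= q_max].reset_index(drop=True)


def _peptide_map(evidence: pd.DataFrame) -> dict[str, frozenset[str]]:
    """peptide -> set of proteins it maps to (union over rows)."""
    mapping: dict[str, set[str]] = {}
    for pep, prots in zip(evidence["peptide"], evidence["proteins"]):
        mapping.setdefault(pep, set()).update(p for p in str(prots).split(";") if p)
    return {p: frozenset(s) for p, s in mapping.items()}


def infer_proteins(evidence: pd.DataFrame) -> list[ProteinGroup]:
    """Parsimony protein inference from filtered peptide evidence.

    Rules, applied in order:

    1. a protein with >=1 peptide mapping only to it is reported as a
       singleton (``is_unique``);
    2. proteins whose peptide sets are identical are indistinguishable and
       merge into one multi-protein group;
    3. remaining proteins (all peptides shared, sets differ) first discard
       peptides already explained by a uniquely identified protein; proteins
       left with no unexplained peptide are not reported (parsimony), and the
       rest are grouped by connected components of the shared-peptide graph.

    Group numbering is deterministic: sorted by member label.
    """
    pep2prot = _peptide_map(evidence)
    prot2pep: dict[str, set[str]] = {}
    for pep, prots in pep2prot.items():
        for prot in prots:
            prot2pep.setdefault(prot, set()).add(pep)

    unique_prots = {next(iter(prots)) for prots in pep2prot.values() if len(prots) == 1}
    explained = {pep for prot in unique_prots for pep in prot2pep[prot]}

    remaining = [p for p in prot2pep if p not in unique_prots]
    # keep only proteins with at least one peptide not explained by a unique hit
    survivors = [p for p in remaining if prot2pep[p] - explained]

    # identical-peptide-set proteins are indistinguishable
    by_set: dict[frozenset[str], set[str]] = {}
    for p in survivors:
        by_set.setdefault(frozenset(prot2pep[p] - explained), set()).add(p)

    # connected components over shared (unexplained) peptides
    parent: dict[frozenset[str], frozenset[str]] = {s: s for s in by_set}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sets = list(by_set)
    for a, b in itertools.combinations(sets, 2):
        if a & b:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    components: dict[frozenset[str], set[str]] = {}
    for s, prots in by_set.items():
        components.setdefault(find(s), set()).update(prots)

    labels: list[tuple[frozenset[str], bool]] = [
        (frozenset([p]), True) for p in unique_prots
    ] + [(frozenset(members), False) for members in components.values()]
    labels.sort(key=lambda t: ";".join(sorted(t[0])))
    return [
        ProteinGroup(group_id=i + 1, member_ids=m, is_unique=u)
        for i, (m, u) in enumerate(labels)
    ]


def classify_ptps(
    pollinated: dict[str, set[str]], negative_controls: dict[str, set[str]]
) -> tuple[set[str], pd.DataFrame]:
    """Subtractive PTP call.

    ``pollinated`` maps replicate name -> identified protein/group labels;
    ``negative_controls`` likewise for the unpollinated labeled controls.
    The PTP set is the union over pollinated replicates minus any identifier
    seen in ANY control (a single control spectrum excludes).  Returns the
    PTP set and a per-replicate boolean presence matrix (rows = PTPs).
    """
    union: set[str] = set()
    for ids in pollinated.values():
        union |= ids
    excluded: set[str] = set()
    for ids in negative_controls.values():
        excluded |= ids
    ptps = union - excluded
    reps = sorted(pollinated)
    presence = pd.DataFrame(
        {rep: [pid in pollinated[rep] for pid in sorted(ptps)] for rep in reps},
        index=sorted(ptps),
    )
    return ptps, presence


@dataclass
class NsafRecord:
    """NSAF of one identification: per-experiment normalized abundance and
    the mean over experiments in which it was identified."""

    entry_id: str
    spc_total: int
    length: float
    per_experiment: dict[str, float]
    nsaf_mean: float


def compute_nsaf(
    counts: pd.DataFrame,
    lengths: dict[str, float],
    groups: list[ProteinGroup] | None = None,
) -> list[NsafRecord]:
    """Normalized spectral abundance factors.

    ``counts``: rows indexed by entry id (protein or group label), one column
    per experiment, summed spectral counts.  Within each experiment,
    nsaf_i = (SpC_i / L_i) / sum_j (SpC_j / L_j) over entries identified
    (count > 0) there; entries absent from an experiment get no value for it.
    A group's length is the mean of its members' lengths.  The reported
    value is the mean over experiments in which the entry was identified.
    An experiment with zero total count yields no values (flagged by
    absence).
    """
    length_of: dict[str, float] = {}
    group_members = {g.label: g.member_ids for g in groups} if groups else {}
    for entry in counts.index:
        if entry in group_members:
            member_lengths = [lengths[m] for m in group_members[entry]]
        elif entry in lengths:
            member_lengths = [lengths[entry]]
        else:
            member_lengths = [lengths[m] for m in entry.split(";")]
        length_of[entry] = float(np.mean(member_lengths))
        if length_of[entry] <= 0:
            raise ValueError(f"non-positive length for {entry!r}")

    per_exp: dict[str, dict[str, float]] = {e: {} for e in counts.index}
    for exp in counts.columns:
        col = counts[exp]
        present = col[col > 0]
        saf = present / present.index.map(length_of)
        total = saf.sum()
        if total <= 0:
            continue
        for entry, value in (saf / total).items():
            per_exp[entry][exp] = float(value)

    out = []
    for entry in counts.index:
        vals = per_exp[entry]
        mean = float(np.mean(list(vals.values()))) if vals else math.nan
        out.append(
            NsafRecord(
                entry_id=entry,
                spc_total=int(counts.loc[entry].sum()),
                length=length_of[entry],
                per_experiment=vals,
                nsaf_mean=mean,
            )
        )
    return out


def overlap_stats(presence: pd.DataFrame) -> dict[str, float]:
    """Replicate-overlap fractions from a boolean presence matrix.

    For each replicate pair, |A & B| / |A | B|; plus the all-replicate
    intersection over union.  An empty union yields NaN.
    """
    reps = list(presence.columns)
    out: dict[str, float] = {}
    for a, b in itertools.combinations(reps, 2):
        inter = int((presence[a] & presence[b]).sum())
        union = int((presence[a] | presence[b]).sum())
        out[f"{a}|{b}"] = inter / union if union else math.nan
    if len(reps) >= 2:
        all_inter = int(presence.all(axis=1).sum())
        all_union = int(presence.any(axis=1).sum())
        out["all"] = all_inter / all_union if all_union else math.nan
    return out
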