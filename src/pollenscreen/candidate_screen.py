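"""Integration of the population scan and the divergence scan into a
candidate table, plus the multiple-testing and enrichment utilities used
along the way.

A gene is a candidate if it is flagged by the empirical Tajima's D tails with
simulation support (sweep or balancing), or by the M8-vs-M8a likelihood-ratio
test at the chosen false-discovery rate (adaptive divergence).  Fay & Wu's H
confirmation per outgroup is recorded as an annotation, not a filter: a tail
locus that fails H remains a candidate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CandidateRecord",
    "qvalues",
    "fisher_exact_2x2",
    "build_candidate_table",
]


@dataclass
class CandidateRecord:
    """Per-gene outcome of the combined screen."""

    gene_id: str
    flag_sweep: bool = False
    flag_balancing: bool = False
    h_confirmed_by: set[str] = field(default_factory=set)
    flag_adaptive: bool = False
    nsaf: float = math.nan
    category: str = ""

    def __post_init__(self) -> None:
        if self.flag_sweep and self.flag_balancing:
            raise ValueError(f"{self.gene_id}: sweep and balancing flags are exclusive")

    @property
    def is_candidate(self) -> bool:
        return self.flag_sweep or self.flag_balancing or self.flag_adaptive


def qvalues(p_list, method: str = "storey") -> np.ndarray:
    """q-values for a vector of p-values.

    ``storey``: pi0 estimated with the single-lambda estimator at
    lambda = 0.5 (pi0 = #{p > 0.5} / (0.5 m), capped at 1), then
    q_(i) = min_{j >= i} pi0 * m * p_(j) / j on the sorted p-values.
    ``bh`` is the same step-up with pi0 = 1 (Benjamini-Hochberg).
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, float(np.sum(p > lam)) / ((1.0 - lam) * m))
    elif method == "bh":
        pi0 = 1.0
    else:
        raise ValueError("method must be 'storey' or 'bh'")
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def fisher_exact_2x2(table, tail: str = "two") -> float:
    """Fisher's exact test on a 2x2 contingency table.

    ``tail``: "greater" / "less" are the hypergeometric tail sums on the
    top-left cell; "two" sums all tables (at the observed margins) with
    probability <= the observed table's.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with nonnegative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: test undefined")
    alternative = {"greater": "greater", "less": "less", "two": "two-sided"}.get(tail)
    if alternative is None:
        raise ValueError("tail must be 'greater', 'less', or 'two'")
    return float(sps.fisher_exact(t, alternative=alternative).pvalue)


def build_candidate_table(
    tails: pd.DataFrame,
    h_results: pd.DataFrame | None,
    lrt_results: pd.DataFrame | None,
    nsaf: dict[str, float] | None = None,
    manual_exclude: set[str] | None = None,
    sim_alpha: float = 0.05,
    h_alpha: float = 0.05,
    fdr: float = 0.10,
    tally: str = "sum",
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Assemble the candidate table and its summary counts.

    ``tails``: columns gene_id, tail ("lower"/"upper"), sim_p.
    ``h_results``: columns gene_id, outgroup, p (simulation p for H).
    ``lrt_results``: columns gene_id, q_value (from the M8-vs-M8a LRT).
    ``manual_exclude``: gene ids whose alignments failed manual review;
    they lose the adaptive flag only.
    ``tally``: "sum" counts a gene present in both screens twice in
    n_total (population + adaptive); "union" counts distinct genes.
    """
    if tally not in ("sum", "union"):
        raise ValueError("tally must be 'sum' or 'union'")
    manual_exclude = manual_exclude or set()
    records: dict[str, CandidateRecord] = {}

    def rec(gene_id: str) -> CandidateRecord:
        return records.setdefault(gene_id, CandidateRecord(gene_id=gene_id))

    if tails is not None and len(tails):
        if tails["gene_id"].duplicated().any():
            dup = tails.loc[tails["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene id in tails: {dup!r}")
        for row in tails.itertuples():
            passed = not (isinstance(row.sim_p, float) and not math.isnan(row.sim_p)) or row.sim_p <= sim_alpha / 2
            if not passed:
                continue
            r = rec(row.gene_id)
            if row.tail == "lower":
                r.flag_sweep = True
            elif row.tail == "upper":
                r.flag_balancing = True
            else:
                raise ValueError(f"unknown tail {row.tail!r}")

    if h_results is not None and len(h_results):
        for row in h_results.itertuples():
            if row.gene_id in records and row.p <= h_alpha:
                records[row.gene_id].h_confirmed_by.add(row.outgroup)

    if lrt_results is not None and len(lrt_results):
        if lrt_results["gene_id"].duplicated().any():
            raise ValueError("duplicate gene id in LRT results")
        for row in lrt_results.itertuples():
            if row.q_value <= fdr and row.gene_id not in manual_exclude:
                rec(row.gene_id).flag_adaptive = True

    for gene_id, value in (nsaf or {}).items():
        if gene_id in records:
            records[gene_id].nsaf = value

    for r in records.values():
        parts = []
        if r.flag_sweep:
            parts.append("sweep")
        if r.flag_balancing:
            parts.append("balancing")
        if r.flag_adaptive:
            parts.append("adaptive")
        r.category = "+".join(parts)

    rows = []
    for gene_id in sorted(records):
        r = records[gene_id]
        if not r.is_candidate:
            continue
        rows.append(
            {
                "gene_id": r.gene_id,
                "flag_sweep": r.flag_sweep,
                "flag_balancing": r.flag_balancing,
                "flag_adaptive": r.flag_adaptive,
                "h_confirmed_by": ";".join(sorted(r.h_confirmed_by)),
                "nsaf": r.nsaf,
                "category": r.category,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "flag_sweep", "flag_balancing", "flag_adaptive",
            "h_confirmed_by", "nsaf", "category",
        ],
    )

    n_sweep = int(table["flag_sweep"].sum()) if len(table) else 0
    n_balancing = int(table["flag_balancing"].sum()) if len(table) else 0
    n_adaptive = int(table["flag_adaptive"].sum()) if len(table) else 0
    n_population = n_sweep + n_balancing
    overlap = (
        int((table["flag_adaptive"] & (table["flag_sweep"] | table["flag_balancing"])).sum())
        if len(table)
        else 0
    )
    h_by: dict[str, int] = {}
    for r in records.values():
        for taxon in r.h_confirmed_by:
            h_by[taxon] = h_by.get(taxon, 0) + 1
    summary = {
        "n_sweep": n_sweep,
        "n_balancing": n_balancing,
        "n_population": n_population,
        "n_adaptive": n_adaptive,
        "overlap": overlap,
        "n_h_confirmed_any": sum(1 for r in records.values() if r.h_confirmed_by),
        "n_total": (n_population + n_adaptive) if tally == "sum" else len(table),
    }
    for taxon, count in sorted(h_by.items()):
        summary[f"n_h_confirmed_{taxon}"] = count
    return table, summary
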