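"""Evolutionary-rate comparisons between gene sets.

Compares dN, dS and dN/dS distributions with the Wilcoxon rank-sum test
after set-overlap exclusion, plus proportion tests (duplicated-gene
fractions) and per-branch evolutionary-age enrichment.

Exclusion modes mirror how overlapping sets are handled before a rate
comparison: ``pairwise_vs_reference`` removes the shared genes from both
sets (used when comparing the hotspot-intersected set against e.g. the
housekeeping set); ``unique_only`` keeps, in each set, only genes absent
from every other supplied set (used for the hot/middle/cold trio).

Direction is reported relative to the first (reference) set: the sign of
``median(B) - median(A)``, so "-1" means the comparison set is lower.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .enrichment_stats import (
    EnrichmentResult,
    GeneSet,
    attach_fdr,
    enrich,
    fisher_exact_2x2,
)

__all__ = [
    "EvoRateRecord",
    "RateComparison",
    "exclude_common",
    "wilcoxon_rank_sum",
    "compare_rates",
    "proportion_test",
    "branch_enrichment",
    "read_rate_table",
    "read_branch_table",
]

METRICS = ("dn", "ds", "dnds")

# exact permutation distribution up to this combined sample size (no ties)
EXACT_CUTOFF = 20


@dataclass(frozen=True)
class EvoRateRecord:
    """Per-gene substitution rates for an ortholog pair.

    dnds is the supplied ratio; when the source table disagrees slightly
    with dn/ds (rounding), the supplied value wins.  dnds is None when
    ds = 0 (ratio undefined).
    """

    gene_symbol: str
    dn: float | None
    ds: float | None
    dnds: float | None

    def metric(self, name: str) -> float | None:
        return getattr(self, name)


@dataclass(frozen=True)
class RateComparison:
    """Rank-sum comparison of one metric between two sets (B relative to A)."""

    metric: str
    direction: int  # sign of median(B) - median(A); 0 for a null result
    p: float | None
    n_a: int
    n_b: int
    median_a: float | None = None
    median_b: float | None = None
    reason: str | None = None  # set when the comparison could not run


def exclude_common(
    set_a: GeneSet,
    set_b: GeneSet,
    mode: str = "pairwise_vs_reference",
    others: Sequence[GeneSet] = (),
) -> tuple[GeneSet, GeneSet]:
    """Apply the overlap-exclusion rule before a rate comparison.

    ``pairwise_vs_reference``: remove A∩B from both sets.
    ``unique_only``: remove from each set every symbol present in any
    other supplied set (the other of the pair plus *others*).
    ``none``: keep both sets unchanged.
    """
    if mode == "none":
        a, b = set_a, set_b
    elif mode == "pairwise_vs_reference":
        common = set_a.symbols & set_b.symbols
        a = GeneSet(set_a.name, set_a.symbols - common)
        b = GeneSet(set_b.name, set_b.symbols - common)
    elif mode == "unique_only":
        pool = [gs.symbols for gs in others]
        a = GeneSet(set_a.name, set_a.symbols - set_b.symbols.union(*pool))
        b = GeneSet(set_b.name, set_b.symbols - set_a.symbols.union(*pool))
    else:
        raise ValueError(f"unknown exclusion mode {mode!r}")
    for gs in (a, b):
        if len(gs) == 0:
            raise ValueError(f"gene set {gs.name!r} emptied by {mode} exclusion")
    return a, b


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact permutation distribution when the combined sample size is <= 20
    and the pooled values have no ties; otherwise the normal approximation
    with tie and continuity corrections.  Returns (U statistic for x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_CUTOFF and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def _rates_for(
    symbols: frozenset[str], table: Mapping[str, EvoRateRecord], metric: str
) -> np.ndarray:
    vals = [
        table[s].metric(metric)
        for s in symbols
        if s in table and table[s].metric(metric) is not None
    ]
    return np.asarray(vals, dtype=float)


def rate_lookup(rates: Sequence[EvoRateRecord]) -> dict[str, EvoRateRecord]:
    """Collapse rate records to one per gene symbol (first by sorted order)."""
    out: dict[str, EvoRateRecord] = {}
    for rec in sorted(rates, key=lambda r: r.gene_symbol):
        out.setdefault(rec.gene_symbol.upper(), rec)
    return out


def compare_rates(
    set_a: GeneSet,
    set_b: GeneSet,
    rates: Sequence[EvoRateRecord],
    exclusion_mode: str = "pairwise_vs_reference",
    others: Sequence[GeneSet] = (),
) -> list[RateComparison]:
    """Compare dN, dS and dN/dS between two gene sets.

    Missing metrics are dropped per metric (not listwise).  Direction is
    the sign of median(B) - median(A), so the reference set A plays the
    role the hotspot-intersected set plays in the published sign table.
    """
    a, b = exclude_common(set_a, set_b, exclusion_mode, others)
    table = rate_lookup(rates)
    out: list[RateComparison] = []
    for metric in METRICS:
        xa = _rates_for(a.symbols, table, metric)
        xb = _rates_for(b.symbols, table, metric)
        if xa.size < 2 or xb.size < 2:
            out.append(
                RateComparison(metric, 0, None, int(xa.size), int(xb.size),
                               reason="fewer than 2 genes with this metric")
            )
            continue
        _, p = wilcoxon_rank_sum(xa, xb)
        med_a, med_b = float(np.median(xa)), float(np.median(xb))
        direction = int(np.sign(med_b - med_a))
        out.append(RateComparison(metric, direction, p, int(xa.size), int(xb.size),
                                  med_a, med_b))
    return out


def proportion_test(
    set_a_members: int, set_a_total: int, set_b_members: int, set_b_total: int
) -> EnrichmentResult:
    """Fisher two-sided comparison of two proportions (e.g. duplicated-gene
    fractions among two transcript sets), with the signed-FE convention on
    the ratio of proportions."""
    if set_a_total <= 0 or set_b_total <= 0:
        raise ValueError("group totals must be positive")
    if set_a_members > set_a_total or set_b_members > set_b_total:
        raise ValueError("member counts must not exceed totals")
    a, b = set_a_members, set_a_total - set_a_members
    c, d = set_b_members, set_b_total - set_b_members
    p = fisher_exact_2x2(a, b, c, d)
    prop_a = set_a_members / set_a_total
    prop_b = set_b_members / set_b_total
    if prop_b == 0 or prop_a == 0:
        fe = math.nan
    elif prop_a >= prop_b:
        fe = prop_a / prop_b
    else:
        fe = -prop_b / prop_a
    # expected members in group A under a shared proportion
    pooled = (set_a_members + set_b_members) / (set_a_total + set_b_total)
    return EnrichmentResult(
        name="proportion",
        observed=set_a_members,
        expected=pooled * set_a_total,
        fe=fe,
        p=p,
        extras={"prop_a": prop_a, "prop_b": prop_b},
    )


def branch_enrichment(
    query: GeneSet,
    age_assignment: Mapping[str, int],
    background: GeneSet,
    branches: Sequence[int] = tuple(range(13)),
) -> tuple[list[EnrichmentResult], float]:
    """Per-evolutionary-branch enrichment of *query* against *background*.

    Branch 0 holds the oldest genes; the highest branches the youngest
    (primate-specific).  Each branch is tested with the 2x2 engine and
    BH-FDR is applied across branches.  Also returns the fraction of
    query genes assigned to branch 0.
    """
    valid = set(branches)
    assign = {}
    for sym, br in age_assignment.items():
        if br not in valid:
            raise ValueError(f"unknown branch label {br!r} for gene {sym!r}")
        assign[sym.upper()] = br
    unknown = set(assign) - background.symbols
    if unknown:
        raise ValueError(
            f"{len(unknown)} assigned symbols missing from background, e.g. "
            f"{sorted(unknown)[:3]}"
        )
    results = []
    for br in branches:
        members = frozenset(s for s, v in assign.items() if v == br)
        if not members:
            continue
        res = enrich(query, GeneSet(f"branch_{br}", members), background)
        res.extras["branch"] = br
        results.append(res)
    results = attach_fdr(results)
    q_assigned = [s for s in query.symbols if s in assign]
    frac0 = (
        sum(assign[s] == 0 for s in q_assigned) / len(q_assigned) if q_assigned else math.nan
    )
    return results, frac0


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def read_rate_table(path: Union[str, Path]) -> list[EvoRateRecord]:
    """Read a TSV rate table (gene_symbol, dn, ds, dnds); empty fields are
    missing values."""
    df = pd.read_csv(
        path, sep="\t", comment=None, header=0,
        names=["gene_symbol", "dn", "ds", "dnds"],
        dtype={"gene_symbol": str},
    )
    recs = []
    for row in df.itertuples(index=False):
        def _val(v):
            return None if pd.isna(v) else float(v)
        recs.append(EvoRateRecord(str(row.gene_symbol), _val(row.dn), _val(row.ds), _val(row.dnds)))
    return recs


def write_rate_table(rates: Sequence[EvoRateRecord], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("gene_symbol\tdn\tds\tdnds\n")
        for r in rates:
            def _s(v):
                return "" if v is None else f"{v:.6g}"
            fh.write(f"{r.gene_symbol}\t{_s(r.dn)}\t{_s(r.ds)}\t{_s(r.dnds)}\n")


def read_branch_table(path: Union[str, Path]) -> dict[str, int]:
    """Read a TSV (gene_symbol, branch 0-12) evolutionary-age assignment."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith("gene_symbol"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            out[fields[0].upper()] = int(fields[1])
    return out


def write_rate_comparisons(
    comparisons: Mapping[str, Sequence[RateComparison]], path: Union[str, Path]
) -> None:
    """Write one row per (comparison set, metric), sign-table layout with
    numeric p-values."""
    with open(path, "w") as fh:
        fh.write("dataset\tmetric\tn_a\tn_b\tdirection\tp\n")
        for name, comps in comparisons.items():
            for c in comps:
                p = "" if c.p is None else f"{c.p:.4g}"
                fh.write(f"{name}\t{c.metric}\t{c.n_a}\t{c.n_b}\t{c.direction:+d}\t{p}\n")
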