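"""2x2 enrichment engine: Fisher's exact test, signed fold enrichment, BH-FDR.

The signed fold-enrichment convention used throughout: with ``expected =
n_query * n_set / N`` under independence,

* ``fe = observed / expected`` when observed >= expected (enrichment),
* ``fe = -expected / observed`` otherwise (depletion),

so |fe| >= 1 whenever defined and a 4.3-fold depletion prints as -4.3.
``observed = 0`` yields NaN (undefined) rather than a pseudo-count; the
p-value is still computed.

Fisher tests are two-sided: the sum of hypergeometric probabilities not
exceeding the observed table's probability (relative tolerance 1e-7),
evaluated in log space, which stays exact to double precision for any
table size.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

_REL_TOL = 1e-7

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "fisher_exact_2x2",
    "fold_enrichment",
    "enrich",
    "bh_fdr",
    "read_gene_sets",
    "read_symbol_list",
    "write_enrichment_table",
]


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (uppercased for case-insensitive matching)."""

    name: str
    symbols: frozenset[str]

    def __init__(self, name: str, symbols: Iterable[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "symbols", frozenset(s.upper() for s in symbols))

    def __len__(self) -> int:
        return len(self.symbols)

    def intersection(self, other: "GeneSet") -> frozenset[str]:
        return self.symbols & other.symbols


@dataclass(frozen=True)
class EnrichmentResult:
    """One 2x2 enrichment test: observed/expected counts, signed FE, p (and q)."""

    name: str
    observed: int
    expected: float
    fe: float  # signed; NaN when observed == 0
    p: float
    q: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        crit = self.q if self.q is not None else self.p
        return crit < 0.05


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities over all tables with the observed
    margins whose probability is <= that of the observed table (within
    relative tolerance 1e-7).  Log-space arithmetic keeps the sum stable
    for large totals.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError(f"counts must be non-negative integers, got {(a, b, c, d)}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("at least one count must be positive")
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return 1.0  # degenerate margin: only one table possible
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logp = hypergeom.logpmf(ks, n, c1, r1)
    log_obs = logp[a - lo]
    keep = logp <= log_obs + math.log1p(_REL_TOL)
    # log-sum-exp over the kept tables
    m = float(np.max(logp[keep]))
    p = math.exp(m) * float(np.sum(np.exp(logp[keep] - m)))
    return min(1.0, p)


def fold_enrichment(observed: int, n_query: int, n_set: int, n_background: int) -> float:
    """Signed fold enrichment of *observed* against independence.

    Returns NaN when observed == 0 (undefined depletion magnitude).
    """
    if n_background <= 0:
        raise ValueError("n_background must be positive")
    if n_query > n_background or n_set > n_background:
        raise ValueError("query and set sizes must not exceed the background")
    if observed > min(n_query, n_set):
        raise ValueError("observed overlap exceeds the smaller margin")
    expected = n_query * n_set / n_background
    if observed == 0:
        return math.nan
    if observed >= expected:
        return observed / expected
    return -expected / observed


def expected_overlap(n_query: int, n_set: int, n_background: int) -> float:
    return n_query * n_set / n_background


def enrich(query: GeneSet, target: GeneSet, background: GeneSet) -> EnrichmentResult:
    """Fisher 2x2 enrichment of *target* membership within *query*.

    Both sets are first mapped onto the background: symbols outside it are
    dropped (logged).  The table is (in query & in target, in query only,
    in target only, in neither) over background symbols.
    """
    bg = background.symbols
    n_bg = len(bg)
    if n_bg == 0:
        raise ValueError("background gene set is empty")
    q_raw, t_raw = query.symbols, target.symbols
    q = q_raw & bg
    t = t_raw & bg
    for name, raw, kept in ((query.name, q_raw, q), (target.name, t_raw, t)):
        dropped = len(raw) - len(kept)
        if dropped:
            logger.info("enrich: %d/%d symbols of %r outside background, dropped",
                        dropped, len(raw), name)
        if not kept:
            raise ValueError(f"gene set {name!r} is empty after background mapping")
    a = len(q & t)
    b = len(q) - a
    c = len(t) - a
    d = n_bg - a - b - c
    p = fisher_exact_2x2(a, b, c, d)
    return EnrichmentResult(
        name=target.name,
        observed=a,
        expected=expected_overlap(len(q), len(t), n_bg),
        fe=fold_enrichment(a, len(q), len(t), n_bg),
        p=p,
        extras={"n_query": len(q), "n_set": len(t), "n_background": n_bg},
    )


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values for a batch of p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def attach_fdr(results: Sequence[EnrichmentResult]) -> list[EnrichmentResult]:
    """Return results with BH q-values attached across the batch."""
    if not results:
        return []
    qs = bh_fdr([r.p for r in results])
    return [replace(r, q=q) for r, q in zip(results, qs)]


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def read_symbol_list(path: Union[str, Path], name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene set; '#' lines are comments."""
    symbols = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s and not s.startswith("#"):
                symbols.append(s.split("\t")[0])
    return GeneSet(name or Path(path).stem, symbols)


def read_gene_sets(path: Union[str, Path]) -> list[GeneSet]:
    """Read a 2-column TSV (set_name, symbol) into named gene sets."""
    members: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns (set, symbol)")
            name, symbol = fields[0], fields[1]
            if name not in members:
                members[name] = []
                order.append(name)
            members[name].append(symbol)
    return [GeneSet(name, members[name]) for name in order]


def write_gene_sets(sets: Sequence[GeneSet], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("#set\tsymbol\n")
        for gs in sets:
            for sym in sorted(gs.symbols):
                fh.write(f"{gs.name}\t{sym}\n")


def write_enrichment_table(results: Sequence[EnrichmentResult], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("set\tobserved\texpected\tfe\tp\tq\n")
        for r in results:
            q = "" if r.q is None else f"{r.q:.4g}"
            fe = "NA" if math.isnan(r.fe) else f"{r.fe:.3f}"
            fh.write(f"{r.name}\t{r.observed}\t{r.expected:.3f}\t{fe}\t{r.p:.4g}\t{q}\n")
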