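"""Orchestrate the full analysis from one declarative config.

Stages, in order: classify map windows into spots; sample middle/cold
spots to the hot-spot count; intersect transcripts with each spot set to
derive the HI/MI/CI gene sets; merge HI transcripts and summarise hotspot
coverage of the merged regions; run the configured gene-set enrichments;
compare evolutionary rates (pairwise exclusion against expression
classes, unique-only exclusion within the spot trio); duplicated-gene
proportion test; evolutionary-age branch enrichment; motif, repeat and
fragile-site analyses.  Optional stages with missing inputs are skipped
with a logged reason; the map and gene models are required.

Each analysis table carries its own BH q-values per batch.  The
consolidated "findings" roster additionally applies BH across every
p-value in the run, so one run-level screen controls the false discovery
rate over all families jointly; null-calibration checks count findings
from that roster.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from . import __version__
from . import enrichment_stats as es
from . import evolution_compare as ec
from . import genome_intervals as gi
from . import sequence_features as sf

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "Finding", "run_pipeline", "write_report",
           "validate_summary"]

DEFAULT_MOTIF_PATTERNS = ("CCTCCCT", "CCCCACCCC", "CCNCCNTNNCCNC")

# sets compared against HI on evolutionary rates with pairwise exclusion
DEFAULT_RATE_SETS = ("HK", "TiGER", "SPD")
DEFAULT_DGD_BASELINE = "HK"


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class DataError(ValueError):
    """A required input is missing or unreadable."""


@dataclass
class RunConfig:
    """Inputs and thresholds for one pipeline run."""

    map_path: str
    genes_path: str
    sets_path: str | None = None
    rates_path: str | None = None
    branches_path: str | None = None
    fasta_path: str | None = None
    rmsk_path: str | None = None
    fragile_path: str | None = None
    hot_min: float = 10.0
    mid_lo: float = 0.1
    mid_hi: float = 1.0
    min_overlap: int = 1
    fdr: float = 0.05
    coverage_threshold: int = 1000
    sample_n: int | None = None  # middle/cold sample size; None = hot count
    motif_patterns: tuple[str, ...] = DEFAULT_MOTIF_PATTERNS
    rate_sets: tuple[str, ...] = DEFAULT_RATE_SETS
    dgd_set: str = "DGD"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mid_lo < self.mid_hi <= self.hot_min):
            raise ConfigError("thresholds must satisfy 0 <= mid_lo < mid_hi <= hot_min")
        if self.min_overlap < 1:
            raise ConfigError("min_overlap must be >= 1")
        if not (0 < self.fdr < 1):
            raise ConfigError("fdr must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("motif_patterns", "rate_sets"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def digest(self) -> str:
        doc = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class Finding:
    """One run-level significant result (q from the pooled BH screen)."""

    family: str
    name: str
    p: float
    q: float
    direction: float  # signed fe, rank-sum direction, etc.


@dataclass
class ReportBundle:
    """All tables and tallies produced by one pipeline run."""

    config: RunConfig
    hi: es.GeneSet
    mi: es.GeneSet
    ci: es.GeneSet
    n_hot_spots: int
    n_sampled_spots: int
    n_transcripts: int
    n_genes: int
    n_hi_transcripts: int
    n_hi_regions: int
    coverage: gi.CoverageSummary | None
    set_enrichments: list[es.EnrichmentResult] = field(default_factory=list)
    rate_comparisons: dict[str, list[ec.RateComparison]] = field(default_factory=dict)
    dgd_proportion: es.EnrichmentResult | None = None
    branch_results: list[es.EnrichmentResult] = field(default_factory=list)
    branch0_fraction: float | None = None
    motif_results: list[es.EnrichmentResult] = field(default_factory=list)
    repeat_results: list[es.EnrichmentResult] = field(default_factory=list)
    fragile_census: tuple[int, float, int, float] | None = None
    findings: list[Finding] = field(default_factory=list)
    skipped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _derive_spot_gene_set(
    label: str,
    transcripts: Sequence[gi.TranscriptModel],
    spots: gi.SpotSet,
    min_overlap: int,
) -> tuple[es.GeneSet, set[str]]:
    records = gi.intersect(transcripts, spots, min_overlap)
    tx_ids = {r.region_or_transcript_id for r in records}
    symbols = {t.gene_symbol for t in transcripts if t.transcript_id in tx_ids}
    return es.GeneSet(label, symbols), tx_ids


def _pool_findings(bundle: ReportBundle, fdr: float) -> list[Finding]:
    """Pool every p-value in the run into one BH screen."""
    entries: list[tuple[str, str, float, float]] = []
    for r in bundle.set_enrichments:
        entries.append(("set_enrichment", r.name, r.p, r.fe))
    for name, comps in bundle.rate_comparisons.items():
        for c in comps:
            if c.p is not None:
                entries.append(("rate_comparison", f"{name}:{c.metric}", c.p, c.direction))
    if bundle.dgd_proportion is not None:
        entries.append(("dgd_proportion", bundle.dgd_proportion.name,
                        bundle.dgd_proportion.p, bundle.dgd_proportion.fe))
    for r in bundle.branch_results:
        entries.append(("branch_enrichment", r.name, r.p, r.fe))
    for r in bundle.motif_results:
        entries.append(("motif_enrichment", r.name, r.p,
                        r.fe if not math.isnan(r.fe) else 0.0))
    for r in bundle.repeat_results:
        # the all-other-elements margin makes neutral elements look depleted
        # when others are enriched, so only fe > 1 counts as a repeat finding
        if not math.isnan(r.fe) and r.fe > 1:
            entries.append(("repeat_enrichment", r.name, r.p, r.fe))
    if not entries:
        return []
    qs = es.bh_fdr([e[2] for e in entries])
    return sorted(
        (Finding(fam, name, p, q, d)
         for (fam, name, p, d), q in zip(entries, qs) if q < fdr),
        key=lambda f: (f.q, f.family, f.name),
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages and return the consolidated report bundle."""
    for label, path in (("map", config.map_path), ("genes", config.genes_path)):
        if not path or not Path(path).exists():
            raise DataError(f"stage '{label}': required input {path!r} is missing")

    # --- spots ---
    windows = gi.read_recomb_map(config.map_path)
    spot_sets = gi.classify_spots(windows, config.hot_min, config.mid_lo, config.mid_hi)
    hot = spot_sets["hot"]
    n = config.sample_n if config.sample_n is not None else len(hot)
    sampled = {}
    for label in ("middle", "cold"):
        avail = len(spot_sets[label])
        take = min(n, avail)
        if take < n:
            logger.warning("only %d %s spots available (wanted %d); using all",
                           avail, label, n)
        sampled[label] = gi.sample_spots(spot_sets[label], take,
                                         config.seed + (1 if label == "middle" else 2))
    logger.info("spots: %d hot, %d middle sampled, %d cold sampled",
                len(hot), len(sampled["middle"]), len(sampled["cold"]))

    # --- genes and spot-intersected sets ---
    transcripts = gi.read_transcripts(config.genes_path)
    background = es.GeneSet("background", {t.gene_symbol for t in transcripts})
    hi, hi_tx = _derive_spot_gene_set("HI", transcripts, hot, config.min_overlap)
    mi, _ = _derive_spot_gene_set("MI", transcripts, sampled["middle"], config.min_overlap)
    ci, _ = _derive_spot_gene_set("CI", transcripts, sampled["cold"], config.min_overlap)
    logger.info("gene sets: %d HI, %d MI, %d CI of %d genes",
                len(hi), len(mi), len(ci), len(background))

    # --- HI regions and coverage ---
    hi_transcripts = [t for t in transcripts if t.gene_symbol.upper() in hi.symbols]
    coverage = None
    hi_regions: list[gi.GeneRegion] = []
    if hi_transcripts:
        hi_regions = gi.merge_transcripts(hi_transcripts)
        cov_records = gi.intersect(hi_regions, hot, config.min_overlap)
        coverage = gi.coverage_summary(cov_records, hi_regions, config.coverage_threshold)

    bundle = ReportBundle(
        config=config, hi=hi, mi=mi, ci=ci,
        n_hot_spots=len(hot), n_sampled_spots=len(sampled["middle"]),
        n_transcripts=len(transcripts), n_genes=len(background),
        n_hi_transcripts=len(hi_transcripts), n_hi_regions=len(hi_regions),
        coverage=coverage,
    )
    if not hi.symbols:
        bundle.skipped["enrichment"] = "HI gene set is empty"
        bundle.skipped["rates"] = "HI gene set is empty"

    # --- gene-set enrichment ---
    gene_sets: dict[str, es.GeneSet] = {}
    if config.sets_path and Path(config.sets_path).exists():
        gene_sets = {gs.name: gs for gs in es.read_gene_sets(config.sets_path)}
    elif config.sets_path:
        bundle.skipped["enrichment"] = f"sets file {config.sets_path!r} missing"
    if gene_sets and hi.symbols:
        results = []
        for name, gs in gene_sets.items():
            try:
                results.append(es.enrich(hi, gs, background))
            except ValueError as exc:
                logger.warning("enrichment for %r skipped: %s", name, exc)
        bundle.set_enrichments = es.attach_fdr(results)

    # --- evolutionary rates ---
    if config.rates_path and Path(config.rates_path).exists() and hi.symbols:
        rates = ec.read_rate_table(config.rates_path)
        comps: dict[str, list[ec.RateComparison]] = {}
        for name in config.rate_sets:
            gs = gene_sets.get(name)
            if gs is None:
                logger.info("rate comparison vs %r skipped: set not provided", name)
                continue
            try:
                comps[name] = ec.compare_rates(hi, gs, rates, "pairwise_vs_reference")
            except ValueError as exc:
                logger.warning("rate comparison vs %r skipped: %s", name, exc)
        trio = {"MI": (mi, ci), "CI": (ci, mi)}
        for name, (other, third) in trio.items():
            if not other.symbols:
                continue
            try:
                comps[name] = ec.compare_rates(hi, other, rates, "unique_only", [third])
            except ValueError as exc:
                logger.warning("rate comparison vs %r skipped: %s", name, exc)
        bundle.rate_comparisons = comps
    elif config.rates_path and hi.symbols:
        bundle.skipped["rates"] = f"rates file {config.rates_path!r} missing"

    # --- duplicated-gene proportions (HI vs a slow-evolving baseline set) ---
    dgd = gene_sets.get(config.dgd_set)
    baseline = gene_sets.get(DEFAULT_DGD_BASELINE)
    if dgd is not None and baseline is not None and hi.symbols:
        a = len(hi.symbols & dgd.symbols)
        c = len(baseline.symbols & dgd.symbols)
        try:
            res = ec.proportion_test(a, len(hi), c, len(baseline))
            bundle.dgd_proportion = dataclasses.replace(
                res, name=f"{config.dgd_set}:HI_vs_{DEFAULT_DGD_BASELINE}")
        except ValueError as exc:
            logger.warning("duplicated-gene proportion test skipped: %s", exc)

    # --- evolutionary-age branches ---
    if config.branches_path and Path(config.branches_path).exists() and hi.symbols:
        assign = ec.read_branch_table(config.branches_path)
        assign = {s: b for s, b in assign.items() if s in background.symbols}
        try:
            bundle.branch_results, bundle.branch0_fraction = ec.branch_enrichment(
                hi, assign, background)
        except ValueError as exc:
            bundle.skipped["branches"] = str(exc)
    elif config.branches_path and hi.symbols:
        bundle.skipped["branches"] = f"branches file {config.branches_path!r} missing"

    # --- motifs ---
    if config.fasta_path and Path(config.fasta_path).exists() and hi_regions:
        seqs = {rs.region_id: rs for rs in sf.read_fasta(config.fasta_path)}
        region_ids = {r.region_id for r in hi_regions}
        seq_a = [rs for rid, rs in seqs.items() if rid in region_ids]
        seq_b = list(seqs.values())
        missing = len(region_ids) - len(seq_a)
        if missing:
            logger.warning("motifs: %d HI regions missing from FASTA; skipped those",
                           missing)
        if seq_a and seq_b:
            results = [
                sf.motif_region_enrichment(seq_a, seq_b, sf.MotifSpec(p))
                for p in config.motif_patterns
            ]
            bundle.motif_results = es.attach_fdr(results)
        else:
            bundle.skipped["motifs"] = "no HI region sequences found in FASTA"
    elif config.fasta_path:
        bundle.skipped["motifs"] = f"FASTA {config.fasta_path!r} missing"

    # --- repeats: hot windows vs the rest of the mapped genome ---
    if config.rmsk_path and Path(config.rmsk_path).exists() and len(hot):
        repeats = sf.read_repeat_table(config.rmsk_path)
        extent: dict[str, int] = {}
        for w in windows:
            extent[w.interval.chrom] = max(extent.get(w.interval.chrom, 0), w.interval.end)
        complement: list[gi.GenomicInterval] = []
        hot_by_chrom: dict[str, list[gi.GenomicInterval]] = {}
        for s in hot.spots:
            hot_by_chrom.setdefault(s.chrom, []).append(s)
        for chrom, chrom_end in sorted(extent.items()):
            pos = 0
            for s in sorted(hot_by_chrom.get(chrom, []), key=lambda x: x.start):
                if s.start > pos:
                    complement.append(gi.GenomicInterval(chrom, pos, s.start))
                pos = max(pos, s.end)
            if pos < chrom_end:
                complement.append(gi.GenomicInterval(chrom, pos, chrom_end))
        if complement:
            bundle.repeat_results = sf.repeat_enrichment(repeats, hot.spots, complement)
    elif config.rmsk_path:
        bundle.skipped["repeats"] = f"repeat table {config.rmsk_path!r} missing"

    # --- fragile sites ---
    if config.fragile_path and Path(config.fragile_path).exists() and hi_transcripts:
        sites = gi.read_bed(config.fragile_path)
        bundle.fragile_census = sf.overlap_census(sites, hi_transcripts)
    elif config.fragile_path:
        bundle.skipped["fragile"] = f"fragile-site file {config.fragile_path!r} missing"

    bundle.findings = _pool_findings(bundle, config.fdr)
    bundle.provenance = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "counts": {
            "windows": len(windows),
            "hot_spots": len(hot),
            "transcripts": len(transcripts),
            "genes": len(background),
            "hi_genes": len(hi), "mi_genes": len(mi), "ci_genes": len(ci),
        },
    }
    return bundle


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

SUMMARY_REQUIRED_KEYS = {
    "provenance": dict, "counts": dict, "findings": list, "skipped": dict,
    "coverage": (dict, type(None)), "fragile_census": (dict, type(None)),
    "branch0_fraction": (float, type(None)),
}


def validate_summary(summary: Mapping[str, Any]) -> None:
    """Structural validation of a summary document; raises on violation."""
    for key, typ in SUMMARY_REQUIRED_KEYS.items():
        if key not in summary:
            raise ValueError(f"summary missing key {key!r}")
        if not isinstance(summary[key], typ):
            raise ValueError(f"summary key {key!r} has wrong type")
    for f in summary["findings"]:
        for k in ("family", "name", "p", "q", "direction"):
            if k not in f:
                raise ValueError(f"finding missing field {k!r}")


def _summary_doc(bundle: ReportBundle) -> dict:
    cov = None
    if bundle.coverage is not None:
        cov = dataclasses.asdict(bundle.coverage)
    census = None
    if bundle.fragile_census is not None:
        n_s, p_s, n_t, p_t = bundle.fragile_census
        census = {"n_sites_hit": n_s, "pct_sites_hit": p_s,
                  "n_transcripts_hit": n_t, "pct_transcripts_hit": p_t}
    return {
        "provenance": bundle.provenance,
        "counts": {
            "hot_spots": bundle.n_hot_spots,
            "sampled_spots": bundle.n_sampled_spots,
            "transcripts": bundle.n_transcripts,
            "genes": bundle.n_genes,
            "hi_genes": len(bundle.hi),
            "mi_genes": len(bundle.mi),
            "ci_genes": len(bundle.ci),
            "hi_transcripts": bundle.n_hi_transcripts,
            "hi_regions": bundle.n_hi_regions,
        },
        "coverage": cov,
        "fragile_census": census,
        "branch0_fraction": bundle.branch0_fraction,
        "findings": [dataclasses.asdict(f) for f in bundle.findings],
        "skipped": dict(sorted(bundle.skipped.items())),
    }


def write_report(bundle: ReportBundle, out_dir: str | Path) -> list[str]:
    """Write all tables, the JSON summary and gene lists; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def _add(name: str) -> Path:
        manifest.append(name)
        return out / name

    for label, gs in (("hi", bundle.hi), ("mi", bundle.mi), ("ci", bundle.ci)):
        with open(_add(f"{label}_genes.txt"), "w") as fh:
            for s in sorted(gs.symbols):
                fh.write(s + "\n")
    if bundle.set_enrichments:
        es.write_enrichment_table(bundle.set_enrichments, _add("set_enrichment.tsv"))
    if bundle.rate_comparisons:
        ec.write_rate_comparisons(bundle.rate_comparisons, _add("rate_comparisons.tsv"))
    if bundle.branch_results:
        es.write_enrichment_table(bundle.branch_results, _add("branch_enrichment.tsv"))
    if bundle.motif_results:
        es.write_enrichment_table(bundle.motif_results, _add("motif_enrichment.tsv"))
    if bundle.repeat_results:
        es.write_enrichment_table(bundle.repeat_results, _add("repeat_enrichment.tsv"))
    summary = _summary_doc(bundle)
    validate_summary(summary)
    with open(_add("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest.sort()
    return manifest
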