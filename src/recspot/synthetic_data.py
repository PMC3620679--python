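"""Synthetic inputs with planted, recorded effects.

Generates every input the pipeline consumes — recombination maps, gene
models, gene sets with planted fold enrichments, evolutionary-rate tables
with planted dN/dS shifts, region sequences with planted motif presence,
repeat annotations with planted density ratios, and fragile sites — and
records the planted ground truth so recovery tests can compare what the
pipeline reports against what was planted.

The default configuration mirrors the shape of a human autosomal analysis
at roughly 1/10 size (~1,800 genes, ~400 hot windows on a 100 Mb genome
of 10 kb map windows, giving a hotspot-intersected gene fraction near the
observed ~6%) so a full run finishes in seconds.  Genes are placed
without inter-gene overlap (transcripts of one gene do overlap/nest);
this keeps merged per-gene regions stable identifiers across the
pipeline and is the one deliberate departure from real gene annotations.

All generators are pure functions of (config, seed): one global seed fans
out to per-stage child seeds by fixed offsets, so each stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .enrichment_stats import GeneSet
from .evolution_compare import EvoRateRecord
from .genome_intervals import (
    GeneRegion,
    GenomicInterval,
    RecombinationWindow,
    TranscriptModel,
)
from .sequence_features import IUPAC, MotifSpec, RegionSequence, RepeatAnnotation

__all__ = [
    "GeneratorConfig",
    "SRRLaw",
    "RateLaw",
    "SyntheticTruth",
    "DEFAULT_MOTIFS",
    "DEFAULT_PLANTED_FE",
    "DEFAULT_RATE_SHIFTS",
    "DEFAULT_SET_SIZES",
    "gen_recomb_map",
    "gen_gene_annotation",
    "gen_gene_sets",
    "gen_rate_table",
    "gen_sequences_and_repeats",
    "gen_fragile_sites",
    "gen_branch_assignment",
    "simulate_bundle",
]

# fixed per-stage offsets for fanning the global seed out to child seeds
_STAGE_OFFSETS = {
    "map": 1, "genes": 2, "sets": 3, "rates": 4,
    "sequences": 5, "repeats": 6, "fragile": 7, "branches": 8,
}

DEFAULT_MOTIFS = (
    MotifSpec("CCTCCCT"),
    MotifSpec("CCCCACCCC"),
    MotifSpec("CCNCCNTNNCCNC"),
)

# set sizes mirroring a human autosomal gene-set collection at 1/10 scale
DEFAULT_SET_SIZES: dict[str, int] = {
    "HK": 197, "TiGER": 471, "SPD": 167, "DGD": 439,
    "OMIM": 262, "MD": 163, "CGC": 42, "TICdb": 24,
    "dbCRID": 40, "InteCR": 61,
}

# planted fold enrichments of each set within the hotspot-intersected genes:
# housekeeping genes strongly depleted, tissue-specific/secreted mildly
# enriched, rearrangement-disease sets most enriched, duplicated genes flat
DEFAULT_PLANTED_FE: dict[str, float] = {
    "HK": 1 / 4.3, "TiGER": 1.3, "SPD": 1.4, "DGD": 0.9,
    "OMIM": 1.3, "MD": 1.5, "CGC": 2.0, "TICdb": 2.5,
    "dbCRID": 2.9, "InteCR": 2.4,
}

# additive dN/dS shifts; the first matching set in this mapping wins for a
# gene in several sets (hot/middle/cold first, then expression classes)
DEFAULT_RATE_SHIFTS: dict[str, float] = {
    "HI": 0.02, "MI": 0.0, "CI": -0.01,
    "TiGER": 0.04, "SPD": 0.04, "HK": -0.05,
}

# additive dS shifts with the same priority rule: slowly evolving
# (housekeeping-like) genes also diverge less at synonymous sites
DEFAULT_DS_SHIFTS: dict[str, float] = {
    "HI": 0.0, "MI": -0.04, "CI": -0.06,
    "TiGER": 0.05, "SPD": 0.05, "HK": -0.08,
}

DEFAULT_MOTIF_RATES: dict[tuple[str, str], float] = {
    **{("hi", m.name): 0.4 for m in DEFAULT_MOTIFS},
    **{("background", m.name): 0.1 for m in DEFAULT_MOTIFS},
}

# A:B density ratios of repeat elements between hot windows and the rest
# of the genome; the first four emulate known hotspot-enriched elements
DEFAULT_REPEAT_RATIOS: dict[str, float] = {
    "THE1B": 5.0, "THE1A": 4.0, "CT-rich": 3.0, "L2": 2.0,
    "AluY": 1.0, "MIR": 1.0, "L1": 1.0,
}


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    return (_STAGE_OFFSETS[stage] * (2 ** 20) + seed) % (2 ** 31 - 1)


@dataclass(frozen=True)
class SRRLaw:
    """Distribution of standardized recombination rates across map windows.

    Hot windows draw 10 + LogNormal(hot_mu, hot_sigma) so their support is
    strictly above the hotspot threshold.  Non-hot windows are a mixture
    of an atom at 0 (cold spots) and a log-uniform low-rate component on
    [10**low_log10_min, 10**low_log10_max]; rates in (0.1, 1) of that
    component become middle spots.
    """

    hot_mu: float = 1.0
    hot_sigma: float = 0.75
    hot_shift: float = 10.0
    cold_mass: float = 0.3
    low_log10_min: float = -3.0
    low_log10_max: float = 1.0


@dataclass(frozen=True)
class RateLaw:
    """Base law for per-gene substitution rates (human-mouse ortholog scale).

    dS is log-normal around 0.5 substitutions/site; the dN/dS ratio is a
    Beta draw with mean ~0.125 (purifying selection); dN = ratio * dS.  A
    small fraction of genes draw dS = 0, leaving dN/dS undefined.
    """

    ds_log_mean: float = math.log(0.5)
    ds_log_sigma: float = 0.35
    dnds_alpha: float = 2.0
    dnds_beta: float = 14.0
    ds_zero_prob: float = 0.02


@dataclass
class GeneratorConfig:
    """Scale and shape of the synthetic genome."""

    n_chromosomes: int = 4
    chromosome_length: int = 25_000_000
    window_size: int = 10_000
    n_genes: int = 1800
    gene_length_log_median: float = math.log(8_000)
    gene_length_log_sigma: float = 0.6
    gene_length_min: int = 1_000
    gene_length_max: int = 200_000
    max_transcripts_per_gene: int = 4
    set_sizes: dict[str, int] | None = None  # None: defaults scaled to n_genes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.set_sizes is None:
            self.set_sizes = {
                k: max(5, v * self.n_genes // 1800) for k, v in DEFAULT_SET_SIZES.items()
            }
        if self.window_size > self.chromosome_length:
            raise ValueError("window_size must not exceed chromosome_length")
        mean_len = math.exp(self.gene_length_log_median + self.gene_length_log_sigma ** 2 / 2)
        if self.n_genes * mean_len >= self.n_chromosomes * self.chromosome_length:
            raise ValueError("genome too small for the requested number of genes")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class SyntheticTruth:
    """Ground truth of planted effects, written alongside generated data."""

    seed: int
    hotspot_fraction: float | None = None
    planted_fe: dict[str, float] = field(default_factory=dict)
    rate_shifts: dict[str, float] = field(default_factory=dict)
    motif_rates: dict[str, float] = field(default_factory=dict)  # "class:motif" keys
    repeat_density_ratio: dict[str, float] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    SCHEMA_VERSION = 1

    def to_json(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["schema_version"] = self.SCHEMA_VERSION
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# recombination map
# ---------------------------------------------------------------------------

def gen_recomb_map(
    config: GeneratorConfig,
    hotspot_fraction: float = 0.04,
    srr_law: SRRLaw = SRRLaw(),
    seed: int | None = None,
) -> tuple[list[RecombinationWindow], SyntheticTruth]:
    """Tile each chromosome with fixed-width windows and draw SRR values.

    A window is hot with probability *hotspot_fraction* (SRR drawn from the
    law's hot component, support > 10); otherwise its SRR comes from the
    cold-atom / low-rate mixture.
    """
    if not (0 <= hotspot_fraction < 1):
        raise ValueError("hotspot_fraction must be in [0, 1)")
    seed = child_seed(config.seed, "map") if seed is None else seed
    rng = np.random.default_rng(seed)
    windows: list[RecombinationWindow] = []
    for chrom in config.chrom_names:
        pos = 0
        while pos < config.chromosome_length:
            end = min(pos + config.window_size, config.chromosome_length)
            if rng.random() < hotspot_fraction:
                srr = srr_law.hot_shift + rng.lognormal(srr_law.hot_mu, srr_law.hot_sigma)
            elif rng.random() < srr_law.cold_mass:
                srr = 0.0
            else:
                srr = 10.0 ** rng.uniform(srr_law.low_log10_min, srr_law.low_log10_max)
            windows.append(RecombinationWindow(GenomicInterval(chrom, pos, end), srr))
            pos = end
    truth = SyntheticTruth(seed=seed, hotspot_fraction=hotspot_fraction)
    truth.extras["n_windows"] = len(windows)
    truth.extras["n_hot_windows"] = sum(w.srr > 10 for w in windows)
    return windows, truth


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def _hot_windows_by_chrom(
    windows: Sequence[RecombinationWindow], hot_min: float = 10.0
) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        if w.srr > hot_min:
            out.setdefault(w.interval.chrom, []).append((w.interval.start, w.interval.end))
    for v in out.values():
        v.sort()
    return out


def _overlaps_any(start: int, end: int, sorted_ivs: list[tuple[int, int]]) -> bool:
    import bisect

    i = bisect.bisect_right(sorted_ivs, (start, start)) - 1
    for j in range(max(i, 0), len(sorted_ivs)):
        s, e = sorted_ivs[j]
        if s >= end:
            return False
        if min(e, end) > max(s, start):
            return True
    return False


def gen_gene_annotation(
    config: GeneratorConfig,
    windows: Sequence[RecombinationWindow],
    hotspot_bias: float = 1.0,
    seed: int | None = None,
) -> list[TranscriptModel]:
    """Place genes (1-4 overlapping transcripts each) on the synthetic genome.

    With bias b > 0, the odds of a gene's midpoint landing in a hot window
    are multiplied by b relative to unbiased placement; bias 0 guarantees
    no gene overlaps a hot window by any base.  Genes never overlap each
    other, so per-gene merged regions are stable across the pipeline.
    """
    if hotspot_bias < 0:
        raise ValueError("hotspot_bias must be >= 0")
    seed = child_seed(config.seed, "genes") if seed is None else seed
    rng = np.random.default_rng(seed)
    hot = _hot_windows_by_chrom(windows)
    chrom_len = config.chromosome_length
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_names}
    hot_base_frac = {
        c: sum(e - s for s, e in hot.get(c, [])) / chrom_len for c in config.chrom_names
    }

    transcripts: list[TranscriptModel] = []
    placed = 0
    attempts_budget = config.n_genes * 2000
    while placed < config.n_genes and attempts_budget > 0:
        attempts_budget -= 1
        chrom = config.chrom_names[int(rng.integers(config.n_chromosomes))]
        length = int(np.clip(
            rng.lognormal(config.gene_length_log_median, config.gene_length_log_sigma),
            config.gene_length_min, config.gene_length_max,
        ))
        if length >= chrom_len:
            continue
        hf = hot_base_frac[chrom]
        use_hot = False
        if hotspot_bias != 1.0 and hot.get(chrom):
            # midpoint lands in hot space with biased odds b*hf : (1-hf)
            p_hot = hotspot_bias * hf / (hotspot_bias * hf + (1 - hf))
            use_hot = rng.random() < p_hot
            if use_hot:
                hs = hot[chrom]
                lens = np.array([e - s for s, e in hs])
                k = int(rng.choice(len(hs), p=lens / lens.sum()))
                mid = int(hs[k][0] + rng.integers(lens[k]))
            else:
                mid = int(rng.integers(chrom_len))
        else:
            mid = int(rng.integers(chrom_len))
        start = max(0, min(mid - length // 2, chrom_len - length))
        end = start + length
        # bias 0 must exclude any overlap, not just the midpoint
        if hotspot_bias == 0.0 and _overlaps_any(start, end, hot.get(chrom, [])):
            continue
        if _overlaps_any(start, end, occupied[chrom]):
            continue
        import bisect

        bisect.insort(occupied[chrom], (start, end))
        placed += 1
        symbol = f"G{placed:05d}"
        n_tx = int(rng.integers(1, config.max_transcripts_per_gene + 1))
        transcripts.append(TranscriptModel(f"{symbol}.1", symbol, GenomicInterval(chrom, start, end)))
        for k in range(2, n_tx + 1):
            # sub-isoform sharing the gene core so isoforms always overlap
            core = length // 3
            ts = start + int(rng.integers(0, max(core, 1)))
            te = end - int(rng.integers(0, max(core, 1)))
            if te - ts < 1:
                ts, te = start, end
            transcripts.append(
                TranscriptModel(f"{symbol}.{k}", symbol, GenomicInterval(chrom, ts, te))
            )
    if placed < config.n_genes:
        raise ValueError(
            f"genome too crowded: placed {placed} of {config.n_genes} genes"
        )
    transcripts.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.transcript_id))
    return transcripts


# ---------------------------------------------------------------------------
# gene sets with planted fold enrichment
# ---------------------------------------------------------------------------

def gen_gene_sets(
    annotation: Sequence[TranscriptModel],
    hi_symbols: GeneSet,
    planted_fe: Mapping[str, float],
    set_sizes: Mapping[str, int],
    seed: int,
) -> tuple[list[GeneSet], SyntheticTruth]:
    """Draw gene sets whose membership odds differ between HI and non-HI genes.

    For a set of target size m with planted fold enrichment f over a
    background of N genes of which h are HI, the membership probability is
    p0 = m / (f*h + (N-h)) for non-HI genes and f*p0 for HI genes, so the
    expected size is m and the expected within-HI enrichment is f.
    """
    rng = np.random.default_rng(seed)
    symbols = sorted({t.gene_symbol.upper() for t in annotation})
    n = len(symbols)
    is_hi = np.array([s in hi_symbols.symbols for s in symbols])
    h = int(is_hi.sum())
    truth = SyntheticTruth(seed=seed, planted_fe=dict(planted_fe))
    sets: list[GeneSet] = []
    arr = np.array(symbols)
    for name in set_sizes:
        m = set_sizes[name]
        f = planted_fe.get(name, 1.0)
        if f <= 0:
            raise ValueError(f"set {name!r}: planted fe must be > 0, got {f}")
        p0 = m / (f * h + (n - h))
        p_hi = f * p0
        if p_hi > 1 or p0 > 1:
            raise ValueError(
                f"set {name!r}: infeasible planted fe {f} for size {m} "
                f"(membership probability {max(p_hi, p0):.3f} > 1)"
            )
        probs = np.where(is_hi, p_hi, p0)
        members = arr[rng.random(n) < probs]
        gs = GeneSet(name, members.tolist())
        sets.append(gs)
        truth.extras.setdefault("realized_overlap", {})[name] = int(
            len(gs.symbols & hi_symbols.symbols)
        )
        truth.extras.setdefault("realized_size", {})[name] = len(gs)
    truth.extras["n_background"] = n
    truth.extras["n_hi"] = h
    return sets, truth


# ---------------------------------------------------------------------------
# evolutionary rates with planted shifts
# ---------------------------------------------------------------------------

def gen_rate_table(
    sets: Sequence[GeneSet],
    base_law: RateLaw = RateLaw(),
    rate_shifts: Mapping[str, float] = (),
    seed: int = 0,
    ds_shifts: Mapping[str, float] = (),
) -> list[EvoRateRecord]:
    """Draw one rate record per gene in the union of the supplied sets.

    Per-set additive dN/dS shifts (and optional dS shifts) are applied
    with a deterministic priority: for a gene in several shifted sets,
    the first matching set in the mapping's order wins.  dN is recomputed
    as (shifted ratio) * (shifted dS), so all three metrics move
    coherently.
    """
    rng = np.random.default_rng(seed)
    shifts = dict(rate_shifts) if rate_shifts else {}
    dshifts = dict(ds_shifts) if ds_shifts else {}
    universe = sorted(set().union(*(gs.symbols for gs in sets))) if sets else []
    by_name = {gs.name: gs for gs in sets}
    records: list[EvoRateRecord] = []
    for sym in universe:
        ds = 0.0 if rng.random() < base_law.ds_zero_prob else float(
            rng.lognormal(base_law.ds_log_mean, base_law.ds_log_sigma)
        )
        ratio = float(rng.beta(base_law.dnds_alpha, base_law.dnds_beta))
        for set_name, shift in shifts.items():
            gs = by_name.get(set_name)
            if gs is not None and sym in gs.symbols:
                ratio = max(0.0, ratio + shift)
                break
        if ds > 0:
            for set_name, dshift in dshifts.items():
                gs = by_name.get(set_name)
                if gs is not None and sym in gs.symbols:
                    ds = max(0.0, ds + dshift)
                    break
        if ds > 0:
            records.append(EvoRateRecord(sym, ratio * ds, ds, ratio))
        else:
            records.append(
                EvoRateRecord(sym, ratio * math.exp(base_law.ds_log_mean), 0.0, None)
            )
    return records


# ---------------------------------------------------------------------------
# sequences and repeats
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _concretize_motif(rng: np.random.Generator, pattern: str) -> str:
    return "".join(
        c if len(IUPAC[c]) == 1 else IUPAC[c][int(rng.integers(len(IUPAC[c])))]
        for c in pattern
    )


def gen_sequences_and_repeats(
    regions_by_class: Mapping[str, Sequence[GeneRegion]],
    motif_rates: Mapping[tuple[str, str], float],
    repeat_density_ratio: Mapping[str, float],
    seed: int,
    motifs: Sequence[MotifSpec] = DEFAULT_MOTIFS,
    hot_space: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    genome_extent: Mapping[str, int] | None = None,
    seq_len_cap: int = 2_000,
    base_repeat_per_mb: float = 2.0,
    repeat_length: int = 300,
) -> tuple[dict[str, list[RegionSequence]], list[RepeatAnnotation], SyntheticTruth]:
    """Generate region sequences with planted motif presence and a repeat table.

    Sequences are i.i.d. uniform bases over a window of each region (capped
    at *seq_len_cap* bases for tractability); for each (region class,
    motif) pair one concrete motif instance is written into the sequence
    with the class's planted probability.  Repeat instances form a marked
    Poisson process over the genome whose per-element intensity inside the
    supplied hot space is the planted ratio times the baseline.
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(
        seed=seed,
        motif_rates={f"{cls}:{m}": p for (cls, m), p in motif_rates.items()},
        repeat_density_ratio=dict(repeat_density_ratio),
    )
    sequences: dict[str, list[RegionSequence]] = {}
    skipped = 0
    for cls in sorted(regions_by_class):
        seqs = []
        for region in regions_by_class[cls]:
            length = min(len(region.interval), seq_len_cap)
            seq = _random_seq(rng, length)
            for motif in motifs:
                p = motif_rates.get((cls, motif.name), 0.0)
                if rng.random() >= p:
                    continue
                if len(motif.pattern) > length:
                    skipped += 1
                    continue
                ins = _concretize_motif(rng, motif.pattern)
                pos = int(rng.integers(0, length - len(ins) + 1))
                seq = seq[:pos] + ins + seq[pos + len(ins):]
            seqs.append(RegionSequence(region.region_id, seq))
        sequences[cls] = seqs
    truth.extras["motifs_skipped_too_long"] = skipped

    repeats: list[RepeatAnnotation] = []
    if repeat_density_ratio:
        if hot_space is None or genome_extent is None:
            raise ValueError("repeat generation needs hot_space and genome_extent")
        hot_lens = {c: sum(e - s for s, e in ivs) for c, ivs in hot_space.items()}
        tot_hot = sum(hot_lens.values())
        tot_genome = sum(genome_extent.values())
        tot_cold = tot_genome - tot_hot
        for name in sorted(repeat_density_ratio):
            ratio = repeat_density_ratio[name]
            n_hot = rng.poisson(base_repeat_per_mb * ratio * tot_hot / 1e6)
            n_cold = rng.poisson(base_repeat_per_mb * tot_cold / 1e6)
            repeats.extend(
                _place_in_space(rng, name, n_hot, hot_space, repeat_length)
            )
            repeats.extend(
                _place_in_complement(rng, name, n_cold, hot_space, genome_extent,
                                     repeat_length)
            )
        repeats.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.element_name))
    return sequences, repeats, truth


def _family_of(name: str) -> str:
    return "Simulated"


def _place_in_space(rng, name, n, space, rep_len) -> list[RepeatAnnotation]:
    segs = [(c, s, e) for c, ivs in sorted(space.items()) for s, e in ivs]
    return _place_in_segments(rng, name, n, segs, rep_len)


def _place_in_complement(rng, name, n, space, extent, rep_len) -> list[RepeatAnnotation]:
    segs = []
    for chrom in sorted(extent):
        pos = 0
        for s, e in sorted(space.get(chrom, [])):
            if s > pos:
                segs.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < extent[chrom]:
            segs.append((chrom, pos, extent[chrom]))
    return _place_in_segments(rng, name, n, segs, rep_len)


def _place_in_segments(rng, name, n, segs, rep_len) -> list[RepeatAnnotation]:
    if not segs or n == 0:
        return []
    lens = np.array([e - s for _, s, e in segs], dtype=float)
    out = []
    for _ in range(n):
        k = int(rng.choice(len(segs), p=lens / lens.sum()))
        c, s, e = segs[k]
        start = int(s + rng.integers(0, max(e - s - 1, 1)))
        end = min(start + rep_len, e)
        if end <= start:
            end = start + 1
        out.append(RepeatAnnotation(name, _family_of(name), GenomicInterval(c, start, end)))
    return out


# ---------------------------------------------------------------------------
# fragile sites and evolutionary-age branches
# ---------------------------------------------------------------------------

def gen_fragile_sites(
    config: GeneratorConfig,
    transcripts: Sequence[TranscriptModel],
    n_sites: int = 11,
    hit_fraction: float = 0.78,
    site_length: int = 200_000,
    seed: int | None = None,
) -> list[tuple[GenomicInterval, str]]:
    """Place fragile-site intervals so a target fraction overlap a transcript."""
    seed = child_seed(config.seed, "fragile") if seed is None else seed
    rng = np.random.default_rng(seed)
    n_hit = round(n_sites * hit_fraction)
    tx_by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        tx_by_chrom.setdefault(t.interval.chrom, []).append(t)
    sites: list[tuple[GenomicInterval, str]] = []
    all_tx = list(transcripts)
    for i in range(n_hit):
        t = all_tx[int(rng.integers(len(all_tx)))]
        mid = (t.interval.start + t.interval.end) // 2
        start = max(0, min(mid - site_length // 2, config.chromosome_length - site_length))
        sites.append((GenomicInterval(t.interval.chrom, start, start + site_length),
                      f"FRA{i + 1}"))
    # miss sites go into inter-gene gaps, shrunk to fit the gap when needed
    gaps: list[tuple[str, int, int]] = []
    for chrom in config.chrom_names:
        pos = 0
        ivs = sorted((t.interval.start, t.interval.end) for t in tx_by_chrom.get(chrom, []))
        for s, e in ivs:
            if s - pos >= 1000:
                gaps.append((chrom, pos, s))
            pos = max(pos, e)
        if config.chromosome_length - pos >= 1000:
            gaps.append((chrom, pos, config.chromosome_length))
    if not gaps and len(sites) < n_sites:
        raise ValueError("no gene-free gaps available for miss sites")
    gap_lens = np.array([e - s for _, s, e in gaps], dtype=float)
    while len(sites) < n_sites:
        k = int(rng.choice(len(gaps), p=gap_lens / gap_lens.sum()))
        chrom, gs, ge = gaps[k]
        length = min(site_length, ge - gs)
        start = gs if ge - gs == length else gs + int(rng.integers(0, ge - gs - length))
        sites.append((GenomicInterval(chrom, start, start + length),
                      f"FRA{len(sites) + 1}"))
    sites.sort(key=lambda x: (x[0].chrom, x[0].start))
    return sites


def gen_branch_assignment(
    annotation: Sequence[TranscriptModel],
    hi_symbols: GeneSet,
    hi_branch0_prob: float = 0.8,
    bg_branch0_prob: float = 0.5,
    n_branches: int = 13,
    seed: int = 0,
) -> dict[str, int]:
    """Assign each gene an evolutionary-age branch (0 oldest .. 12 youngest).

    HI-like genes land in branch 0 with boosted probability; the remaining
    mass decays geometrically over the younger branches.
    """
    rng = np.random.default_rng(seed)
    symbols = sorted({t.gene_symbol.upper() for t in annotation})
    decay = 0.7 ** np.arange(1, n_branches)
    decay = decay / decay.sum()
    out: dict[str, int] = {}
    for s in symbols:
        p0 = hi_branch0_prob if s in hi_symbols.symbols else bg_branch0_prob
        if rng.random() < p0:
            out[s] = 0
        else:
            out[s] = 1 + int(rng.choice(n_branches - 1, p=decay))
    return out


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------

def simulate_bundle(
    config: GeneratorConfig,
    out_dir: str | Path,
    hotspot_fraction: float = 0.04,
    hotspot_bias: float = 1.0,
    planted_fe: Mapping[str, float] | None = None,
    rate_shifts: Mapping[str, float] | None = None,
    ds_shifts: Mapping[str, float] | None = None,
    motif_rates: Mapping[tuple[str, str], float] | None = None,
    repeat_density_ratio: Mapping[str, float] | None = None,
    fragile_hit_fraction: float = 0.78,
    base_repeat_per_mb: float = 2.0,
    null: bool = False,
) -> dict:
    """Generate and write a complete input bundle plus truth.json.

    With ``null=True`` every planted effect is set to its neutral value
    (fe = 1, shifts 0, equal motif rates, unit repeat ratios) for
    calibration runs.  Returns a manifest of written files.
    """
    from . import genome_intervals as gi
    from . import evolution_compare as ec
    from . import sequence_features as sf
    from . import enrichment_stats as es

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if null:
        planted_fe = {k: 1.0 for k in DEFAULT_PLANTED_FE}
        rate_shifts = {}
        ds_shifts = {}
        motif_rates = {k: 0.1 for k in DEFAULT_MOTIF_RATES}
        repeat_density_ratio = {k: 1.0 for k in DEFAULT_REPEAT_RATIOS}
        hotspot_bias = 1.0
    planted_fe = dict(DEFAULT_PLANTED_FE if planted_fe is None else planted_fe)
    rate_shifts = dict(DEFAULT_RATE_SHIFTS if rate_shifts is None else rate_shifts)
    ds_shifts = dict(DEFAULT_DS_SHIFTS if ds_shifts is None else ds_shifts)
    motif_rates = dict(DEFAULT_MOTIF_RATES if motif_rates is None else motif_rates)
    repeat_density_ratio = dict(
        DEFAULT_REPEAT_RATIOS if repeat_density_ratio is None else repeat_density_ratio
    )

    windows, map_truth = gen_recomb_map(config, hotspot_fraction)
    transcripts = gen_gene_annotation(config, windows, hotspot_bias)

    # derive the spot-intersected sets the same way the pipeline will, so
    # planted set/rate effects can be conditioned on them
    spot_sets = gi.classify_spots(windows)
    n_hot = len(spot_sets["hot"])
    sample_n = min(n_hot, len(spot_sets["middle"]), len(spot_sets["cold"]))
    mid = gi.sample_spots(spot_sets["middle"], sample_n, child_seed(config.seed, "map") + 1)
    cold = gi.sample_spots(spot_sets["cold"], sample_n, child_seed(config.seed, "map") + 2)
    spot_genes = {}
    for label, spots in (("HI", spot_sets["hot"]), ("MI", mid), ("CI", cold)):
        recs = gi.intersect(transcripts, spots)
        tx = {r.region_or_transcript_id for r in recs}
        spot_genes[label] = es.GeneSet(
            label, {t.gene_symbol for t in transcripts if t.transcript_id in tx}
        )
    hi = spot_genes["HI"]

    sets, set_truth = gen_gene_sets(
        transcripts, hi, planted_fe, config.set_sizes, child_seed(config.seed, "sets")
    )
    background = es.GeneSet("background", {t.gene_symbol for t in transcripts})
    rate_sets = [spot_genes["HI"], spot_genes["MI"], spot_genes["CI"], background] + sets
    rates = gen_rate_table(rate_sets, RateLaw(), rate_shifts,
                           child_seed(config.seed, "rates"), ds_shifts=ds_shifts)
    branches = gen_branch_assignment(
        transcripts, hi,
        hi_branch0_prob=0.5 if null else 0.8,
        seed=child_seed(config.seed, "branches"),
    )

    regions = gi.merge_transcripts(transcripts)  # per-gene regions (genes disjoint)
    hi_region_ids = {
        r.region_id
        for r in gi.merge_transcripts([t for t in transcripts
                                       if t.gene_symbol.upper() in hi.symbols])
    }
    classes = {
        "hi": [r for r in regions if r.region_id in hi_region_ids],
        "background": [r for r in regions if r.region_id not in hi_region_ids],
    }
    hot_space = {
        c: [(s.start, s.end) for s in spot_sets["hot"].spots if s.chrom == c]
        for c in config.chrom_names
    }
    extent = {c: config.chromosome_length for c in config.chrom_names}
    seqs, repeats, seq_truth = gen_sequences_and_repeats(
        classes, motif_rates, repeat_density_ratio, child_seed(config.seed, "sequences"),
        hot_space=hot_space, genome_extent=extent,
        base_repeat_per_mb=base_repeat_per_mb,
    )
    # census targets are the HI transcripts, so plant hits on those
    hi_tx = [t for t in transcripts if t.gene_symbol.upper() in hi.symbols]
    fragile = gen_fragile_sites(config, hi_tx or transcripts,
                                hit_fraction=fragile_hit_fraction)

    # ----- write files -----
    gi.write_recomb_map(windows, out / "map.tsv")
    with open(out / "genes.bed", "w") as fh:
        for t in transcripts:
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.transcript_id}\t0\t{t.gene_symbol}\n")
    es.write_gene_sets(sets, out / "sets.tsv")
    ec.write_rate_table(rates, out / "rates.tsv")
    with open(out / "branches.tsv", "w") as fh:
        fh.write("gene_symbol\tbranch\n")
        for s in sorted(branches):
            fh.write(f"{s}\t{branches[s]}\n")
    # one FASTA covering every gene region; hi-class sequences carry the
    # hi-class planted motif rate, the rest the background rate
    all_seqs = sorted(seqs.get("hi", []) + seqs.get("background", []),
                      key=lambda rs: rs.region_id)
    sf.write_fasta(all_seqs, out / "regions.fa")
    sf.write_repeat_table(repeats, out / "rmsk.tsv")
    gi.write_bed([iv for iv, _ in fragile], out / "fragile.bed",
                 names=[name for _, name in fragile])

    truth = SyntheticTruth(
        seed=config.seed,
        hotspot_fraction=hotspot_fraction,
        planted_fe=planted_fe,
        rate_shifts=rate_shifts,
        motif_rates=seq_truth.motif_rates,
        repeat_density_ratio=repeat_density_ratio,
        extras={
            "null": null,
            "n_windows": map_truth.extras["n_windows"],
            "n_hot_windows": map_truth.extras["n_hot_windows"],
            "n_genes": len({t.gene_symbol for t in transcripts}),
            "n_transcripts": len(transcripts),
            "n_hi_genes": len(hi),
            "hotspot_bias": hotspot_bias,
            "ds_shifts": ds_shifts,
            "realized_overlap": set_truth.extras.get("realized_overlap", {}),
            "fragile_hit_fraction": fragile_hit_fraction,
        },
    )
    truth.to_json(out / "truth.json")
    files = ["map.tsv", "genes.bed", "sets.tsv", "rates.tsv", "branches.tsv",
             "regions.fa", "rmsk.tsv", "fragile.bed", "truth.json"]
    return {"dir": str(out), "files": files}
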