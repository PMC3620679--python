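"""Interval algebra and readers for recombination maps and gene models.

All coordinates are 0-based half-open ``[start, end)`` (BED convention).
A recombination map is a set of fixed-width windows carrying a
standardized recombination rate (SRR: the window's rate divided by the
genome average).  Windows are classified into hot spots (SRR > 10),
middle spots (0.1 < SRR < 1) and cold spots (SRR = 0); each passing
window is one spot — contiguous passing windows are deliberately not
merged, so spot counts stay on the map's resolution unit.

Strand is ignored throughout: recombination spots are unstranded.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "GenomicInterval",
    "RecombinationWindow",
    "SpotSet",
    "TranscriptModel",
    "GeneRegion",
    "IntersectionRecord",
    "CoverageSummary",
    "MapParseError",
    "read_recomb_map",
    "write_recomb_map",
    "read_transcripts",
    "write_bed",
    "classify_spots",
    "sample_spots",
    "merge_transcripts",
    "intersect",
    "coverage_summary",
]


class MapParseError(ValueError):
    """Raised when a tab-delimited input file cannot be parsed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 for different chromosomes or abutment."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.overlap_len(other) > 0

    def contains(self, other: "GenomicInterval") -> bool:
        """True iff *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class RecombinationWindow:
    """One fixed-width map window with its standardized recombination rate."""

    interval: GenomicInterval
    srr: float

    def __post_init__(self) -> None:
        if not (self.srr >= 0):
            raise ValueError(f"SRR must be >= 0, got {self.srr}")


@dataclass
class SpotSet:
    """A labelled collection of spot intervals (hot, middle or cold)."""

    label: str
    spots: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.spots = sorted(set(self.spots))

    def __len__(self) -> int:
        return len(self.spots)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript record: id, owning gene symbol, and genomic extent."""

    transcript_id: str
    gene_symbol: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError(f"transcript {self.transcript_id!r}: empty gene symbol")


@dataclass(frozen=True)
class GeneRegion:
    """A merged, non-overlapping region with its contributing transcripts."""

    interval: GenomicInterval
    member_transcripts: tuple[str, ...]

    @property
    def region_id(self) -> str:
        iv = self.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"


@dataclass(frozen=True)
class IntersectionRecord:
    """Overlap summary between one region/transcript and a spot set."""

    region_or_transcript_id: str
    n_spots_overlapped: int
    covered_bases: int
    contains_full_spot: bool


@dataclass(frozen=True)
class CoverageSummary:
    min_covered: int | None
    max_covered: int | None
    median_covered: float | None
    fraction_full_spot: float | None
    fraction_covered_ge_threshold: float | None
    threshold: int
    n_regions: int
    n_intersected: int


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _data_lines(path: Union[str, Path]) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_recomb_map(path: Union[str, Path]) -> list[RecombinationWindow]:
    """Read a 4-column TSV map (chrom, start, end, srr).

    Lines beginning with ``#`` are comments/headers.  A first data line
    whose numeric columns do not parse is also treated as a header.
    Windows are returned sorted by (chrom, start).
    """
    windows: list[RecombinationWindow] = []
    first = True
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise MapParseError(
                f"{path}: line {lineno}: expected 4 columns (chrom, start, end, srr), "
                f"got {len(fields)}"
            )
        chrom, start_s, end_s, srr_s = fields[:4]
        try:
            start, end, srr = int(start_s), int(end_s), float(srr_s)
        except ValueError:
            if first:
                first = False
                continue  # header line without leading '#'
            raise MapParseError(
                f"{path}: line {lineno}: non-numeric coordinates or SRR"
            ) from None
        first = False
        if srr < 0:
            raise MapParseError(f"{path}: line {lineno}: negative SRR {srr}")
        try:
            iv = GenomicInterval(chrom, start, end)
        except ValueError as exc:
            raise MapParseError(f"{path}: line {lineno}: {exc}") from None
        windows.append(RecombinationWindow(iv, srr))
    windows.sort(key=lambda w: (w.interval.chrom, w.interval.start))
    return windows


def write_recomb_map(windows: Sequence[RecombinationWindow], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tsrr\n")
        for w in windows:
            iv = w.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{float(w.srr)!r}\n")


def read_transcripts(
    path: Union[str, Path],
    symbol_map: Union[str, Path, Mapping[str, str], None] = None,
) -> list[TranscriptModel]:
    """Read transcript models from a BED-like TSV.

    Two layouts are accepted:

    * BED6 (chrom, start, end, transcript_id, score, strand) plus a
      separate 2-column ``transcript_id -> gene_symbol`` map file or dict;
    * a 6-column combined form (chrom, start, end, transcript_id, score,
      gene_symbol) when *symbol_map* is None.

    Score and strand are ignored (spot intersection is unstranded).
    """
    mapping: Mapping[str, str] | None
    if symbol_map is None:
        mapping = None
    elif isinstance(symbol_map, (str, Path)):
        mapping = {
            f[0]: f[1]
            for _, f in _data_lines(symbol_map)
            if len(f) >= 2
        }
    else:
        mapping = symbol_map

    out: list[TranscriptModel] = []
    seen: set[str] = set()
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise MapParseError(
                f"{path}: line {lineno}: expected >=4 BED columns, got {len(fields)}"
            )
        chrom, start_s, end_s, tid = fields[:4]
        try:
            iv = GenomicInterval(chrom, int(start_s), int(end_s))
        except ValueError as exc:
            raise MapParseError(f"{path}: line {lineno}: {exc}") from None
        if tid in seen:
            raise MapParseError(f"{path}: line {lineno}: duplicate transcript id {tid!r}")
        seen.add(tid)
        if mapping is not None:
            try:
                symbol = mapping[tid]
            except KeyError:
                raise MapParseError(
                    f"{path}: line {lineno}: transcript {tid!r} missing from symbol map"
                ) from None
        else:
            if len(fields) < 6:
                raise MapParseError(
                    f"{path}: line {lineno}: combined form needs 6 columns "
                    "(chrom, start, end, transcript_id, score, gene_symbol)"
                )
            symbol = fields[5]
        out.append(TranscriptModel(tid, symbol, iv))
    out.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.transcript_id))
    return out


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: Union[str, Path],
    names: Sequence[str] | None = None,
) -> None:
    """Write intervals as BED3, or BED4 when *names* is given."""
    ivs = list(intervals)
    if names is not None and len(names) != len(ivs):
        raise ValueError("names must match intervals in length")
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            row = f"{iv.chrom}\t{iv.start}\t{iv.end}"
            if names is not None:
                row += f"\t{names[i]}"
            fh.write(row + "\n")


def read_bed(path: Union[str, Path]) -> list[GenomicInterval]:
    """Read BED3+ intervals; extra columns are ignored."""
    out = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise MapParseError(f"{path}: line {lineno}: expected >=3 BED columns")
        try:
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise MapParseError(f"{path}: line {lineno}: {exc}") from None
    return sorted(out)


# ---------------------------------------------------------------------------
# spot classification and sampling
# ---------------------------------------------------------------------------

def classify_spots(
    windows: Sequence[RecombinationWindow],
    hot_min: float = 10.0,
    mid_lo: float = 0.1,
    mid_hi: float = 1.0,
    cold_val: float = 0.0,
) -> dict[str, SpotSet]:
    """Partition map windows into hot / middle / cold spot sets.

    hot: SRR > hot_min (strict); middle: mid_lo < SRR < mid_hi (both
    strict); cold: SRR == cold_val.  Windows failing all three rules are
    assigned to no set.  Each passing window is one spot.
    """
    if not (cold_val <= mid_lo < mid_hi <= hot_min):
        raise ValueError(
            f"thresholds must satisfy cold_val <= mid_lo < mid_hi <= hot_min, got "
            f"{cold_val}, {mid_lo}, {mid_hi}, {hot_min}"
        )
    hot, mid, cold = [], [], []
    for w in windows:
        if w.srr > hot_min:
            hot.append(w.interval)
        elif mid_lo < w.srr < mid_hi:
            mid.append(w.interval)
        elif w.srr == cold_val:
            cold.append(w.interval)
    return {
        "hot": SpotSet("hot", hot),
        "middle": SpotSet("middle", mid),
        "cold": SpotSet("cold", cold),
    }


def sample_spots(spotset: SpotSet, n: int, seed: int) -> SpotSet:
    """Uniform sample of *n* spots without replacement; deterministic per seed."""
    if n > len(spotset.spots):
        raise ValueError(
            f"cannot sample {n} spots from a set of {len(spotset.spots)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(spotset.spots), size=n, replace=False)
    return SpotSet(spotset.label, [spotset.spots[i] for i in idx])


# ---------------------------------------------------------------------------
# merging and intersection
# ---------------------------------------------------------------------------

def merge_transcripts(transcripts: Sequence[TranscriptModel]) -> list[GeneRegion]:
    """Merge overlapping transcript intervals into non-overlapping regions.

    Union per chromosome.  Abutting intervals (end == next start) are NOT
    merged: under half-open coordinates they share no base.  Each region
    records the transcript ids contributing at least one base to it.
    """
    regions: list[GeneRegion] = []
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.interval.chrom, []).append(t)
    for chrom in sorted(by_chrom):
        ts = sorted(by_chrom[chrom], key=lambda t: (t.interval.start, t.interval.end))
        cur_start, cur_end = ts[0].interval.start, ts[0].interval.end
        members = [ts[0].transcript_id]
        for t in ts[1:]:
            if t.interval.start < cur_end:  # strict: abutment starts a new region
                cur_end = max(cur_end, t.interval.end)
                members.append(t.transcript_id)
            else:
                regions.append(
                    GeneRegion(GenomicInterval(chrom, cur_start, cur_end), tuple(sorted(members)))
                )
                cur_start, cur_end = t.interval.start, t.interval.end
                members = [t.transcript_id]
        regions.append(
            GeneRegion(GenomicInterval(chrom, cur_start, cur_end), tuple(sorted(members)))
        )
    return regions


def _as_id_interval(item: Union[GeneRegion, TranscriptModel]) -> tuple[str, GenomicInterval]:
    if isinstance(item, GeneRegion):
        return item.region_id, item.interval
    return item.transcript_id, item.interval


def intersect(
    regions: Sequence[Union[GeneRegion, TranscriptModel]],
    spots: SpotSet,
    min_overlap: int = 1,
) -> list[IntersectionRecord]:
    """Intersect regions (or transcripts) with a spot set.

    Returns one record per input item having at least one spot with
    overlap >= *min_overlap* bases.  ``covered_bases`` is the size of the
    union of all (region ∩ spot) pieces, so overlapping spots are not
    double-counted.  ``contains_full_spot`` is true iff some qualifying
    spot lies entirely within the region.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    spots_by_chrom: dict[str, list[GenomicInterval]] = {}
    for s in spots.spots:
        spots_by_chrom.setdefault(s.chrom, []).append(s)
    for chrom_spots in spots_by_chrom.values():
        chrom_spots.sort(key=lambda s: s.start)

    records: list[IntersectionRecord] = []
    for item in regions:
        rid, iv = _as_id_interval(item)
        chrom_spots = spots_by_chrom.get(iv.chrom, [])
        pieces: list[tuple[int, int]] = []
        n_hits = 0
        full = False
        for s in chrom_spots:
            if s.start >= iv.end:
                break
            ov = iv.overlap_len(s)
            if ov >= min_overlap:
                n_hits += 1
                pieces.append((max(iv.start, s.start), min(iv.end, s.end)))
                if iv.contains(s):
                    full = True
        if n_hits == 0:
            continue
        pieces.sort()
        covered = 0
        cur_s, cur_e = pieces[0]
        for ps, pe in pieces[1:]:
            if ps <= cur_e:
                cur_e = max(cur_e, pe)
            else:
                covered += cur_e - cur_s
                cur_s, cur_e = ps, pe
        covered += cur_e - cur_s
        records.append(IntersectionRecord(rid, n_hits, covered, full))
    return records


def coverage_summary(
    records: Sequence[IntersectionRecord],
    regions: Sequence[Union[GeneRegion, TranscriptModel]],
    threshold: int = 1000,
) -> CoverageSummary:
    """Summarise covered bases over intersected regions.

    Fractions are relative to the intersected regions; the median is taken
    over intersected regions only.  Empty input yields null statistics.
    """
    n_regions = len(regions)
    if not records:
        return CoverageSummary(None, None, None, None, None, threshold, n_regions, 0)
    covered = [r.covered_bases for r in records]
    n = len(records)
    return CoverageSummary(
        min_covered=min(covered),
        max_covered=max(covered),
        median_covered=float(statistics.median(covered)),
        fraction_full_spot=sum(r.contains_full_spot for r in records) / n,
        fraction_covered_ge_threshold=sum(c >= threshold for c in covered) / n,
        threshold=threshold,
        n_regions=n_regions,
        n_intersected=n,
    )
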