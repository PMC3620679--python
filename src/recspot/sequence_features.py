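"""Degenerate motif scanning, repeat-element enrichment, fragile-site census.

Hotspot-associated motifs (e.g. CCTCCCT, CCCCACCCC, CCNCCNTNNCCNC) are
short degenerate DNA words.  Scanning counts every start position whose
window matches, so overlapping occurrences all count; by default both
strands are scanned (the reverse-complement pattern on the forward
sequence), with palindromic hits at the same start counted once.  An N in
the motif matches any base; an N in the sequence matches nothing — an
unknown base is never treated as evidence for a motif.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .enrichment_stats import EnrichmentResult, attach_fdr, fisher_exact_2x2, fold_enrichment
from .genome_intervals import GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

__all__ = [
    "MotifSpec",
    "RepeatAnnotation",
    "RegionSequence",
    "count_motif",
    "motif_region_enrichment",
    "repeat_enrichment",
    "overlap_census",
    "read_fasta",
    "write_fasta",
    "read_repeat_table",
]

# IUPAC degenerate nucleotide codes -> matched bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class MotifSpec:
    """A degenerate DNA motif (IUPAC alphabet)."""

    pattern: str
    name: str = ""

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if len(pat) < 4:
            raise ValueError(f"motif {pat!r}: pattern length must be >= 4")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {pat!r}: invalid characters {sorted(bad)}")
        if not self.name:
            object.__setattr__(self, "name", pat)

    def reverse_complement(self) -> str:
        return self.pattern.translate(_COMPLEMENT)[::-1]

    def regex(self, reverse_complement: bool = False) -> re.Pattern:
        pat = self.reverse_complement() if reverse_complement else self.pattern
        # character classes exclude N in the sequence by construction
        return re.compile("".join(f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c]
                                  for c in pat))


@dataclass(frozen=True)
class RepeatAnnotation:
    """One repeat-element instance (RepeatMasker-style)."""

    element_name: str
    family: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.element_name:
            raise ValueError("element_name must be non-empty")


@dataclass(frozen=True)
class RegionSequence:
    """DNA sequence of one region, uppercase over {A, C, G, T, N}."""

    region_id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 1:
            raise ValueError(f"region {self.region_id!r}: empty sequence")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"region {self.region_id!r}: invalid characters {sorted(bad)}")


def count_motif(seq: RegionSequence, motif: MotifSpec, both_strands: bool = True) -> int:
    """Count motif occurrences in a region sequence.

    Overlapping matches count separately.  With ``both_strands`` the
    reverse-complement pattern is also scanned on the forward sequence;
    a palindromic motif matching both orientations at one start position
    counts once (union of start positions).
    """
    s = seq.sequence
    positions = set(_overlapping_starts(motif.regex(), s))
    if both_strands:
        positions |= set(_overlapping_starts(motif.regex(reverse_complement=True), s))
    return len(positions)


def _overlapping_starts(pattern: re.Pattern, s: str) -> list[int]:
    out = []
    pos = 0
    while True:
        m = pattern.search(s, pos)
        if m is None:
            return out
        out.append(m.start())
        pos = m.start() + 1


def motif_region_enrichment(
    regions_a: Sequence[RegionSequence],
    regions_b: Sequence[RegionSequence],
    motif: MotifSpec,
    both_strands: bool = True,
) -> EnrichmentResult:
    """Fisher test on per-region motif presence between two region sets.

    The unit of analysis is the region: the 2x2 compares (regions with
    >= 1 occurrence vs without) across set A vs set B.  Raw occurrence
    counts are exposed in ``extras`` for density-based follow-up.
    """
    if not regions_a or not regions_b:
        raise ValueError("both region sets must be non-empty")
    hits_a = sum(count_motif(r, motif, both_strands) > 0 for r in regions_a)
    hits_b = sum(count_motif(r, motif, both_strands) > 0 for r in regions_b)
    na, nb = len(regions_a), len(regions_b)
    p = fisher_exact_2x2(hits_a, na - hits_a, hits_b, nb - hits_b)
    prop_a, prop_b = hits_a / na, hits_b / nb
    if hits_a == 0 or hits_b == 0:
        fe = math.nan
    elif prop_a >= prop_b:
        fe = prop_a / prop_b
    else:
        fe = -prop_b / prop_a
    return EnrichmentResult(
        name=motif.name,
        observed=hits_a,
        expected=(hits_a + hits_b) / (na + nb) * na,
        fe=fe,
        p=p,
        extras={"prop_a": prop_a, "prop_b": prop_b, "n_a": na, "n_b": nb,
                "hits_b": hits_b},
    )


def _instances_overlapping(
    repeats: Sequence[RepeatAnnotation], regions: Sequence[GenomicInterval]
) -> list[bool]:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
    flags = []
    for rep in repeats:
        hit = False
        for iv in by_chrom.get(rep.interval.chrom, []):
            if iv.start >= rep.interval.end:
                break
            if rep.interval.overlaps(iv):
                hit = True
                break
        flags.append(hit)
    return flags


def repeat_enrichment(
    repeats: Sequence[RepeatAnnotation],
    regions_a: Sequence[GenomicInterval],
    regions_b: Sequence[GenomicInterval],
) -> list[EnrichmentResult]:
    """Per-element repeat enrichment between two region sets.

    For element e, the 2x2 counts instances of e vs instances of all
    other elements, split by whether each instance overlaps set A vs set
    B (an instance overlapping both is counted in both columns).  BH-FDR
    is applied across elements; an element is flagged significant when
    q < 0.05 and fe > 1.  Elements with no instance in either set, and
    the degenerate single-element case (no "other elements" margin), are
    skipped with a log entry.
    """
    if not regions_a or not regions_b:
        raise ValueError("both region sets must be non-empty")
    names = sorted({r.element_name for r in repeats})
    if len(names) < 2:
        logger.warning("repeat_enrichment: need >= 2 distinct elements, got %d; skipped",
                       len(names))
        return []
    in_a = _instances_overlapping(repeats, regions_a)
    in_b = _instances_overlapping(repeats, regions_b)
    tot_a = sum(in_a)
    tot_b = sum(in_b)
    results = []
    for name in names:
        a = sum(1 for r, f in zip(repeats, in_a) if f and r.element_name == name)
        c = sum(1 for r, f in zip(repeats, in_b) if f and r.element_name == name)
        if a + c == 0:
            logger.info("repeat_enrichment: element %r has no instance in either set; skipped",
                        name)
            continue
        b = tot_a - a  # other elements in A
        d = tot_b - c
        p = fisher_exact_2x2(a, b, c, d)
        n_bg = a + b + c + d
        fe = fold_enrichment(a, a + b, a + c, n_bg) if a > 0 else math.nan
        results.append(EnrichmentResult(
            name=name,
            observed=a,
            expected=(a + b) * (a + c) / n_bg,
            fe=fe,
            p=p,
            extras={"instances_a": a, "instances_b": c,
                    "other_a": b, "other_b": d},
        ))
    return attach_fdr(results)


def overlap_census(
    sites: Sequence[GenomicInterval], transcripts: Sequence[TranscriptModel]
) -> tuple[int, float, int, float]:
    """Census of mutual overlap between interval sites and transcripts.

    A site is hit if it overlaps >= 1 transcript by >= 1 base, and vice
    versa.  Returns (n_sites_hit, pct_sites_hit, n_transcripts_hit,
    pct_transcripts_hit), percentages rounded to one decimal.
    """
    if not sites or not transcripts:
        return 0, 0.0, 0, 0.0
    t_by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        t_by_chrom.setdefault(t.interval.chrom, []).append(t)
    sites_hit = 0
    transcripts_hit: set[str] = set()
    for site in sites:
        hit = False
        for t in t_by_chrom.get(site.chrom, []):
            if site.overlaps(t.interval):
                hit = True
                transcripts_hit.add(t.transcript_id)
        sites_hit += hit
    pct_sites = round(100.0 * sites_hit / len(sites), 1)
    pct_tx = round(100.0 * len(transcripts_hit) / len(transcripts), 1)
    return sites_hit, pct_sites, len(transcripts_hit), pct_tx


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[RegionSequence]:
    from Bio import SeqIO

    return [RegionSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(sequences: Sequence[RegionSequence], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for rs in sequences:
            fh.write(f">{rs.region_id}\n")
            for i in range(0, len(rs.sequence), 70):
                fh.write(rs.sequence[i:i + 70] + "\n")


def read_repeat_table(path: Union[str, Path]) -> list[RepeatAnnotation]:
    """Read a RepeatMasker-style TSV subset (chrom, start, end, element_name,
    family), column-compatible with UCSC rmsk genoName/genoStart/genoEnd/
    repName/repFamily."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "element_name", "family"],
                     dtype={"chrom": str, "element_name": str, "family": str})
    return [
        RepeatAnnotation(row.element_name, row.family,
                         GenomicInterval(row.chrom, int(row.start), int(row.end)))
        for row in df.itertuples(index=False)
    ]


def write_repeat_table(repeats: Sequence[RepeatAnnotation], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\telement_name\tfamily\n")
        for r in repeats:
            iv = r.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{r.element_name}\t{r.family}\n")
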