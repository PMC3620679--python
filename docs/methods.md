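# Methods

This note documents the models, conventions and numerical choices behind
recspot, and what its synthetic-data generator does and does not emulate.

## Coordinates and spot model

All intervals are 0-based half-open `[start, end)` (BED convention).
Abutting intervals (`end == start`) share no base: they neither overlap
nor merge. Strand is ignored in every interval operation, since
recombination spots are features of double-stranded DNA.

A recombination map is a tiling of fixed-width windows (default 10 kb),
each carrying a standardized recombination rate (SRR; the window rate
divided by the genome average). Classification thresholds are strict:

| spot   | rule            |
|--------|-----------------|
| hot    | SRR > 10        |
| middle | 0.1 < SRR < 1   |
| cold   | SRR = 0         |

Windows failing all three rules belong to no class. **Each passing window
is one spot**; contiguous passing windows are not merged, keeping spot
counts on the map's resolution unit. Middle and cold spots are sampled
without replacement down to the hot-spot count before deriving the MI/CI
gene sets, mirroring the matched-count design of the hotspot analysis.

A gene is spot-intersected when any of its transcripts shares at least
`min_overlap` bases (default 1) with a spot. Gene-level statistics count
non-redundant gene symbols; transcript-level statistics count transcript
ids. For region-level analyses the transcripts of the HI genes are merged
into non-overlapping regions, and coverage is reported as the union of
region∩spot pieces (overlapping spots are never double-counted), the
fraction of regions containing at least one entire spot, and the fraction
covered by at least a configurable number of bases (default 1,000).

## Enrichment engine

Every categorical comparison runs through one 2×2 engine:

* **Fisher exact test, two-sided**: the p-value sums hypergeometric
  probabilities not exceeding the observed table's probability (relative
  tolerance 1e−7). Probabilities are evaluated in log space
  (`scipy.stats.hypergeom.logpmf` + log-sum-exp), which is exact to double
  precision at any table size. Two-sided is used throughout because the
  same framework must report both enrichment and depletion.
* **Signed fold enrichment**: `FE = O/E` when the observed overlap `O` is
  at least the independence expectation `E = n_q·n_s/N`, else
  `FE = −E/O`, so `|FE| ≥ 1` whenever defined and depletion is the
  negative reciprocal. `O = 0` yields NaN (an undefined-magnitude
  sentinel) rather than a pseudo-count; the p-value is still reported.
* **BH-FDR** (`statsmodels` step-up) within each batch of related tests:
  per-gene-set, per-branch, per-motif, per-repeat-element.

Gene symbols are uppercased on both sides before matching, and query and
target sets are intersected with the background before testing; symbols
outside the background are dropped with a logged count.

## Evolutionary-rate comparisons

Rates (dN, dS and the supplied dN/dS) are inputs, one record per gene;
when a supplied ratio disagrees with dN/dS by rounding, the supplied value
wins, and genes with dS = 0 have no ratio. Duplicate records for a symbol
collapse to the first in sorted order. Before comparing, overlapping
membership is excluded: `pairwise_vs_reference` removes the shared genes
from both sets (used against expression-class sets), `unique_only` keeps
only genes absent from every other set in the trio of spot classes, and
`none` disables exclusion. Missing values are dropped per metric, not
listwise, to maximise usable sample sizes.

The Wilcoxon rank-sum test is two-sided; the exact permutation
distribution is used when the pooled sample size is ≤ 20 with no ties,
otherwise the normal approximation with tie and continuity corrections
(`scipy.stats.mannwhitneyu`). Direction is the sign of
`median(B) − median(A)` with the HI-like set as reference A, so a "−"
means the comparison set evolves more slowly.

Proportion comparisons (e.g. duplicated-gene fractions in two transcript
sets) delegate to the same Fisher test with the signed convention applied
to the ratio of proportions. Evolutionary-age analysis tests each branch
(0 = oldest … 12 = youngest) as a 2×2 against the background with BH-FDR
across branches, and additionally reports the fraction of the query in
branch 0.

## Sequence features

Motifs are IUPAC degenerate DNA words (minimum length 4). Scanning counts
every matching start position, so overlapping occurrences all count; both
strands are scanned by default by also matching the reverse-complement
pattern on the forward sequence, with palindromic hits at one position
counted once. An `N` in the motif matches any base; an `N` in the
sequence matches nothing — an unknown base is never evidence for a motif.
The motif enrichment unit is the *region* (presence/absence of ≥ 1
occurrence), compared between two region sets by Fisher test; raw
occurrence counts are exposed for density-based follow-up.

Repeat-element enrichment compares, for each element, its instance count
against the instances of **all other elements** between two region sets
(instances touching both sets count in both); BH-FDR runs across elements
and an element is called significant when q < 0.05 *and* FE > 1. A
consequence of this margin is that strongly enriched elements make
neutral ones look depleted; depletion calls from this table are therefore
not treated as findings. The genome-wide background is represented as the
complement of the hot windows within the mapped extent.

The fragile-site census counts sites overlapping ≥ 1 HI transcript and HI
transcripts overlapping ≥ 1 site, with percentages rounded to one decimal.

## Synthetic data generator

The generator emulates every pipeline input with planted effects recorded
in `truth.json` (schema version 1):

* **Map**: windows tile each chromosome; a window is hot with probability
  `hotspot_fraction` (default 0.04), drawing SRR from
  10 + LogNormal(1, 0.75) so support is strictly above the threshold;
  otherwise SRR is 0 with probability 0.3 (cold atom) or log-uniform on
  [1e−3, 10].
* **Genes**: default 1,800 genes on 4 × 25 Mb chromosomes, lognormal
  lengths (median 8 kb, σ = 0.6, clipped to [1 kb, 200 kb]), 1–4
  overlapping transcripts per gene. This 1/10-scale shape yields ~400 hot
  windows and an HI gene fraction near the ~6% seen in human-scale
  analyses, which keeps planted fold enrichments nearly unattenuated.
  Genes never overlap *each other* (a deliberate simplification so merged
  per-gene regions are stable identifiers); a `hotspot_bias` parameter
  multiplies the odds of a gene's midpoint falling in a hot window, with
  bias 0 guaranteeing zero hot overlap.
* **Gene sets**: for a set of target size m with planted fold enrichment
  f, non-HI genes join with probability `p0 = m/(f·h + (N−h))` and HI
  genes with `f·p0`, so the expected size is m and the within-HI
  enrichment is f. Measured FE is mildly attenuated relative to f because
  the background contains the HI genes: FE ≈ f/(1 + (f−1)·h/N). Defaults
  mirror a human gene-set collection at 1/10 size with the observed
  direction of effects (housekeeping strongly depleted, rearrangement-
  disease sets most enriched).
* **Rates**: dS ~ LogNormal(ln 0.5, 0.35) with a 2% atom at 0; the
  dN/dS ratio ~ Beta(2, 14) (mean ≈ 0.125, purifying selection);
  dN = ratio × dS. Planted per-set additive shifts act on the ratio and,
  separately, on dS; a gene in several shifted sets takes the first match
  in the mapping's order (spot classes before expression classes by
  default). Defaults reproduce the expected sign table (housekeeping
  below the HI set on all three metrics, tissue-specific/secreted above).
* **Sequences and repeats**: region sequences are i.i.d. uniform bases
  over a window of each region capped at 2 kb (tractability; presence
  probabilities are defined on that window), with one concrete motif
  instance written in with the class's planted probability. Repeat
  instances are a marked Poisson process (default 2 instances/Mb/element,
  length 300 bp) whose per-element intensity inside hot windows is the
  planted ratio times baseline.
* **Fragile sites**: a planted fraction (default 0.78) of sites is
  centred on HI transcripts; the rest are placed in inter-gene gaps,
  shrunk to fit. Synthetic sites are 200 kb — much smaller than real
  megabase-scale fragile sites, matching the reduced genome.
* **Age branches**: HI genes land in branch 0 with probability 0.8
  versus 0.5 for the rest; the remaining mass decays geometrically over
  branches 1–12.

One global seed fans out to fixed per-stage child seeds, so every stage
is independently reproducible and bundles are byte-identical across runs.

What the generator does **not** emulate: real chromosome lengths and gene
density heterogeneity, GC content and k-mer composition (background
sequence is uniform), overlapping genes, linkage between nearby windows'
SRR values, correlated membership among gene sets, and any actual hotspot
motif biology. Passing recovery tests therefore demonstrate that the
statistics detect the effects they target at realistic scales — not that
real genomes satisfy the generator's independence assumptions.

## Workflow and the findings roster

`run_pipeline` executes: classify → sample middle/cold to the hot count →
intersect → derive HI/MI/CI → merge and summarise coverage → gene-set
enrichments → rate comparisons (pairwise exclusion vs expression classes,
unique-only within the spot trio) → duplicated-gene proportions → branch,
motif, repeat and fragile-site analyses. The map and gene models are
required; any other stage with a missing input is skipped with a logged
reason. Reports are deterministic for a fixed config + seed.

Each table carries BH q-values within its own family. The consolidated
**findings roster** additionally pools every p-value in the run into one
BH screen at the configured FDR (default 0.05), so "no significant
finding" is well-defined at run level: under a global null the chance of
any roster entry is ≈ the FDR itself, regardless of how many families
ran. Repeat-table entries join the roster only with FE > 1 (see above).

## Numerical and design choices

* Exact rank-sum enumeration cut-off at pooled n = 20; beyond that the
  tie/continuity-corrected normal approximation (errors < 1% there).
* Fisher two-sided tie tolerance 1e−7 (relative) when comparing table
  probabilities, matching common practice.
* `sample_spots` uses `numpy.random.default_rng(seed)` and sorts output,
  so samples are deterministic and order-independent.
* Degenerate inputs: empty maps classify to three empty spot sets; an
  empty HI set skips all downstream HI analyses with a recorded reason; a
  repeat table with a single element has no comparison margin and is
  skipped; a motif longer than its region is skipped and logged.
* The run summary is validated structurally (`validate_summary`) before
  writing; the schema is the set of required keys and finding fields.

## Known limitations

* Signed FE is undefined (NaN) at zero observed overlap; downstream
  consumers must handle the sentinel.
* The repeat 2×2's all-other-elements margin measures *relative*
  composition, not absolute density; a genuinely uniform element can be
  called depleted when others are enriched (mitigated by the FE > 1
  rule for findings).
* Motif presence (not per-base density) feeds the motif test; a density
  analysis can be built from the occurrence counts in `extras`.
* At the default 1/10 scale, small planted sets (tens of genes) have
  limited power; headline-scale scenarios are used where calibrated
  recovery is required.
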