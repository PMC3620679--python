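# recspot

Analysis toolkit for **recombination hotspot–intersected (HI) genes**:
given a standardized meiotic recombination map, classify its windows into
hot, middle and cold spots, derive the gene sets whose transcripts overlap
each spot class, and characterise the hotspot-intersected genes through
gene-set enrichment, evolutionary-rate comparison, degenerate-motif
scanning, repeat-element enrichment and fragile-site overlap.

The package is aimed at population-genetics and genome-biology analyses
where a fine-scale recombination map (windowed standardized recombination
rates, SRR) is confronted with gene annotations and curated gene sets
(housekeeping, tissue-specific, disease-associated, …). Because such
analyses depend on licensed or frequently-updated external databases, the
package ships a synthetic-data generator that emulates every input with
*planted*, recorded effects, so the whole pipeline can be exercised and
validated end to end without any external download.

## The statistics at the core

**Spot classification.** A map window of fixed width (default 10 kb) is a
*hotspot* when its SRR exceeds 10, a *middle spot* when 0.1 < SRR < 1, and
a *cold spot* when SRR = 0. A gene is an HI (MI, CI) gene when one of its
transcripts shares at least one base with a hot (middle, cold) spot;
coordinates are 0-based half-open throughout.

**Signed fold enrichment.** For a query set of size *n<sub>q</sub>*, a
target set of size *n<sub>s</sub>* and a background of *N* genes, the
expected overlap under independence is *E* = *n<sub>q</sub>n<sub>s</sub>/N*.
With observed overlap *O*,

```
FE =  O / E        if O ≥ E      (enrichment)
FE = −E / O        if 0 < O < E  (depletion; −4.3 reads "4.3-fold depleted")
```

Significance comes from the two-sided Fisher exact test on the 2×2 table
over the background; batches of tests are controlled with
Benjamini–Hochberg FDR. Evolutionary rates (dN, dS, dN/dS of
human–mouse-style ortholog tables) are compared between gene sets with the
two-sided Wilcoxon rank-sum test after removing shared genes; degenerate
IUPAC motifs (e.g. CCTCCCT, CCCCACCCC, CCNCCNTNNCCNC) are counted on both
strands with overlapping matches allowed.

## Worked example

The classic depletion computation — how strongly housekeeping genes are
depleted among hotspot-intersected genes, from the published counts
(background 18,166 genes; 1,156 HI genes; 1,974 HK genes; 29 shared):

```python
from recspot import enrichment_stats as es

syms = [f"G{i:05d}" for i in range(18166)]
bg = es.GeneSet("hg18rpa", syms)
hi = es.GeneSet("HI", syms[:1156])
hk = es.GeneSet("HK", syms[:29] + syms[1156:1156 + 1945])
r = es.enrich(hi, hk, bg)
print(f"observed={r.observed} expected={r.expected:.1f} fe={r.fe:.2f} p={r.p:.3g}")
```

prints

```
observed=29 expected=125.6 fe=-4.33 p=3.62e-28
```

i.e. 29 housekeeping genes observed where ~126 were expected: a 4.3-fold
depletion (FE = −4.3).

A full synthetic run, from simulated inputs to the consolidated report:

```sh
recspot simulate --out demo --seed 7
cat > demo/run.yaml <<'YAML'
map_path: demo/map.tsv
genes_path: demo/genes.bed
sets_path: demo/sets.tsv
rates_path: demo/rates.tsv
branches_path: demo/branches.tsv
fasta_path: demo/regions.fa
rmsk_path: demo/rmsk.tsv
fragile_path: demo/fragile.bed
seed: 7
YAML
recspot run --config demo/run.yaml --out demo/report
```

`demo/report/summary.json` then contains (seed 7):

```
"counts": {"hot_spots": 407, "genes": 1800, "hi_genes": 153,
           "mi_genes": 135, "ci_genes": 137, "hi_transcripts": 380, ...}
```

407 of 10,000 simulated windows were hotspots and 153 of 1,800 genes
intersect one. The findings roster (run-wide BH-FDR < 0.05) recovers the
planted structure — the housekeeping-like set depleted, the
rearrangement-disease-like sets (dbCRID, InteCR analogues) enriched, all
three hotspot motifs elevated in HI regions, the THE1B-like repeat
enriched in hot windows, and the old-age branch 0 overrepresented — and
`demo/report/set_enrichment.tsv` holds the per-set table, e.g.

```
set     observed  expected  fe      p          q
HK      6         16.490    -2.748  0.002477   0.006193
dbCRID  9         2.975     3.025   0.00188    0.006193
InteCR  13        4.420     2.941   0.0002487  0.001244
```

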