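# promoterpoise

Classification of gene promoters into RNAPII/Polycomb occupancy states
across a differentiation time course, and analysis of how those states
evolve and couple to expression, DNA methylation and
trans-differentiation potential.

## The problem

During differentiation from embryonic stem cells to post-mitotic
neurons, many silent developmental genes keep an RNA polymerase II
complex phosphorylated on CTD serine 5 (S5p) — a *poised* configuration —
while being repressed by Polycomb (marked by H3K27me3) and lacking the
serine-7 mark (S7p) of productive transcription. `promoterpoise`
implements the computational machinery needed to study this phenomenon
from ChIP-seq enriched regions and expression tables:

* **Non-redundant gene list** — one representative isoform per gene
  cluster per time point via a cascade: highest S5p signal in the 2-kb
  TSS window → highest S2p in the 4-kb TES window (optional) → the
  canonical isoform → a seeded random draw.
* **Promoter-state classification** — a promoter is positive for a mark
  when its TSS window overlaps an enriched region *and* its window read
  count clears the 5th percentile of the counts of all overlapping
  promoters (a 5% tail cut). The (H3K27me3, S5p, S7p) triple maps to
  one of eight states: Active (−,+,+), Inactive (−,−,−), PRC Only
  (+,−,−), PRC/S5p (+,+,−), PRC/Active (+,+,+), PRC/S7p (+,−,+),
  S5p Only and S7p Only. Promoters whose positive windows overlap
  another gene's by more than 200 bp, or whose gene body lies inside
  another positive gene, become NA and leave the analysis set.
* **Temporal dynamics** — H3K27me3 trajectories partition genes into
  PRC **Maintained** (positive at all five time points), **Lost**
  (positive at the start but not throughout), and **Acquired**
  (negative at the start, positive later), so that
  |Maintained| + |Lost| equals the count of first-time-point positives
  and adding |Acquired| the count of genes ever positive. Fates of
  poised PRC/S5p promoters (including the "Always PRC/S5p" group) are
  tracked to the final time point.
* **Expression coupling** — z-score standardization across time points
  selects genes peaking in exactly one time point (z > 1.75, > 1 TPM);
  Polycomb-knockout derepression is called at fold change > 2 with
  knockout expression > 1 FPKM, and summarized per promoter state.
* **Genomic features** — H3K27me3 region breadth over the promoter,
  GC content, CpG-island coverage, metagene coverage profiles, and DNA
  methylation valleys (DMVs): hypomethylated regions proximity-clustered
  (gap ≤ 1 kb) and filtered at ≥ 5 kb.
* **Enrichment statistics** — hypergeometric enrichment/depletion of
  promoter states in gene lists, TF influence-rank aggregation, and a
  from-scratch preranked GSEA (running-sum enrichment score, label
  permutations, NES and pooled-null FDR).
* **Synthetic cohort** — a generator that plants known state
  trajectories, count distributions, expression coupling, methylation
  tracks and rank biases on a miniature genome, so the whole pipeline
  is testable offline against ground truth.

## Worked example

```python
from promoterpoise.pipeline import run_pipeline

manifest = run_pipeline(
    {"simulate": True, "seed": 1, "gsea_permutations": 1000},
    outdir="out",
)
print(manifest["stages"]["dynamics"]["groups"])
print(manifest["stages"]["expression"]["ko_fractions"]["PRC_S5p"])
```

prints (seed 1, default 1,000-gene cohort):

```
{'NeverPRC': 530, 'Maintained': 170, 'Lost': 150, 'Acquired': 150}
0.31451612903225806
```

Of 1,000 classified genes, 320 are H3K27me3-positive at the first time
point (170 Maintained + 150 Lost) and 470 at some time point
(adding the 150 Acquired) — the partition identity the dynamics module
guarantees. Among promoters that are PRC/S5p at the first time point,
31.5% are derepressed in the simulated Polycomb knockout (planted
probability 0.30), against 6.0% for PRC Only genes (planted 0.05):
poised promoters are the most knockout-sensitive state, and the
pipeline recovers that ordering from raw synthetic inputs.

The same run is available from the shell:

```bash
promoterpoise run --config pipeline.yaml
promoterpoise simulate --seed 1 --out cohort/     # inputs as TSV/BED
promoterpoise dmv --hmrs cohort/hmr.bed --gap 1000 --min-len 5000 --out dmvs.tsv
```

## Layout

```
src/promoterpoise/
  intervals.py             half-open interval arithmetic
  annotation.py            isoform cascade, TSS/TES windows
  state_classification.py  positivity calls, tail cut, 8-state logic
  dynamics.py              Maintained/Lost/Acquired, poised fates
  expression.py            z-score peaks, knockout derepression
  features.py              breadth, GC, CGI, metagene, HMR/DMV
  enrichment.py            hypergeometric, influence ranks, GSEA
  simulate.py              synthetic cohort with planted truth
  pipeline.py              orchestration + manifest
  cli.py                   promoterpoise command-line interface
```

See `docs/methods.md` for the model, parameter and design notes.
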