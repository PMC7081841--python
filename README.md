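# msaptools

Epigenotyping without a reference genome: a tested pipeline for
**methylation-sensitive amplification polymorphism (MSAP)** band-pattern
scoring, plus the companion assay calculators of a typical aquaculture
stress-physiology study (2^−ΔΔCt relative expression, TUNEL apoptosis index,
cumulative mortality, total antioxidant capacity).

It is written for researchers who profile cytosine methylation in non-model
organisms (shrimp, molluscs, plants) with the HpaII/MspI isoschizomer pair
and score fragments from capillary-electrophoresis (CE) peak tables, and who
want that scoring to be reproducible, seeded, and unit-tested rather than a
one-off spreadsheet.

## The method

Each DNA sample is digested twice: EcoRI+HpaII (**EH**) and EcoRI+MspI
(**EM**). The two enzymes cut the same CCGG site but are blocked by
different methylation marks, so the band pair at each locus classifies the
site:

| EH | EM | band type | interpretation |
|----|----|-----------|----------------|
| +  | +  | I         | unmethylated |
| +  | −  | II        | hemi-methylated |
| −  | +  | III       | fully methylated (internal cytosine) |
| −  | −  | IV        | uninformative (excluded from ratios) |

With per-sample counts n₁…n₄ of types I–IV,

```
hemi-methylation ratio  = n2 / (n1 + n2 + n3)
full-methylation ratio  = n3 / (n1 + n2 + n3)
total methylation ratio = (n2 + n3) / (n1 + n2 + n3)
```

Group-level ratios pool the band counts over individuals and recompute the
ratios from the pooled counts (the informative-band-weighted mean of the
individual ratios), not the mean of per-individual ratios.

Upstream of the classification, sized fragments from all samples are
clustered into locus bins by single-linkage in one dimension: a new bin
starts whenever the gap between successive sorted sizes exceeds twice the
size tolerance (default ±0.5 bp). The binner is a scikit-learn style
transformer (`FragmentBinner.fit` learns the bins, `.transform` emits a
loci × samples × {EH, EM} presence tensor), so a bin layout can be reapplied
to new samples. Downstream, group differences are tested by one-way ANOVA
with Tukey's HSD, or by a seeded two-group permutation test on the mean
difference (exact enumeration when the split count is small).

Because raw MSAP traces are rarely deposited, the package ships a seeded
simulator (`msaptools.sim`) that draws per-locus methylation states, maps
them deterministically to EH/EM band patterns, and renders noisy peak tables
(size-calling jitter, band dropout, log-normal heights, Poisson spurious
peaks) — so the whole pipeline is testable end to end without external data.

## Worked example

Simulate a ten-individual cohort at 500 loci and score it:

```
$ msaptools simulate --n-individuals 10 --n-loci 500 --seed 7 --out-dir demo
wrote 8388 peaks for 10 individuals to demo

$ msaptools score --peaks demo/peaks.csv --min-height 50 \
      --size-window 50,1000 --group-label CG --out-dir demo_score
MSAP methylation report — group 'CG'
samples: 10   loci scored: 456

pooled band counts: I=3194  II=569  III=775  IV=22 (informative total 4538)
hemi-methylation ratio:  12.54%
full-methylation ratio:  17.08%
total methylation ratio: 29.62%
```

The cohort was generated with state frequencies 70% unmethylated / 12%
hemi- / 18% fully methylated, so the true total methylation is 30%; the
pooled estimate lands at 29.62% under the default CE noise (0.15 bp jitter,
2% band dropout, one spurious peak per sample × digest). `demo_score/` also
holds per-individual summaries, the long band-type table, the presence
matrix, the locus list, and a `provenance.json` sidecar recording the
parameters and input checksums.

The same scoring applied to published pooled band counts — control group
(CG) 3180/586/869 of types I/II/III, 12.5 h air-exposed group (EG)
3327/545/652 — returns total methylation ratios of 31.39% and 26.46% on
informative totals of 4635 and 4524 fragments.

Library use mirrors the CLI:

```python
from msaptools import peaks, score

records = peaks.read_peak_table("demo/peaks.csv")
records = peaks.filter_peaks(records, min_height=50, size_window=(50, 1000))
bins, matrix = peaks.bin_fragments(records, half_width_bp=0.5)
pooled = score.pool_group(score.summarize_all(matrix), "CG")
print(f"{100 * pooled.total_ratio:.2f}%")   # 29.62%
```

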