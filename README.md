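# mmcc — multi-layer multiome case–control analysis

`mmcc` is a reusable, tested implementation of a longitudinal single-cell /
single-nuclei case–control analysis for matched cohorts profiled in three
data layers — multiome nuclei (snRNA + snATAC from the same nuclei) and an
orthogonal scRNA capture — at three time points (T1 before seroconversion,
T2 after, T3 near clinical diagnosis). It was built for studies of type 1
diabetes progression in at-risk children, where the analysis must separate
robust, replicable immune-lineage signals (e.g. early monocyte activation)
from the noise of small cell populations, and stratify cases by
autoantibody-order endotype (IAA-first vs GADA-first).

## What it computes

Cells are collapsed to five parent lineages (Monocyte, B, CD4T, CD8T, NK)
and aggregated to pseudobulk read totals per (donor, time point, lineage).
The core statistic is the **observed/expected Fisher exact test**: for
feature *i* in a stratum, pool reads over case donors and control donors
and form

|          | reads in *i* | reads in all other features |
|----------|:---:|:---:|
| cases    | a | b |
| controls | c | d |

with two-sided Fisher p (point-probability rule), effect
(a/(a+b))/(c/(c+d)), and Benjamini–Hochberg FDR at q < 0.10 within each
(modality, time point). Around it the pipeline provides:

* **replication** of each discovery across the orthogonal layers (other
  modality, other time points, linked peaks/genes), requiring the same
  direction at q < 0.10 in ≥ 2 layers;
* **peak–gene cis links** within 1 Mb of the TSS: Pearson correlation of
  normalized snATAC vs snRNA pseudobulk signals (nominal at P < 0.05,
  |r| > 0.05), classified by distance bin (promoter < 5 kb, proximal
  5–20 kb, distal 20–500 kb, long-range 0.5–1 Mb) and validated in the
  unpaired layers at same sign and |r| > 0.65;
* **dosage QTLs**: Spearman rank correlation of donor-level per-million
  signals against alt-allele count (0/1/2) for features within 1 Mb of
  index SNVs, Bonferroni-corrected per (lineage, modality);
* **adjacency excess**: the number of consecutive differential peak pairs
  versus the closed-form chance expectation k(k−1)/N per chromosome;
* **directional motif tests**: 2×2 Fisher tests of motif occurrence among
  case-up vs case-down peaks at nominal P < 0.01;
* **endotype analysis**: subgroup differential runs against matched pair
  controls and overlap fractions with the overall replicated signal.

Because the original cohort data is controlled-access, the package ships a
**synthetic cohort generator** (`mmcc.simulate`) that emulates the study
design — matched pairs, three time points, three layers, five lineages —
with planted differential effects, peak–gene links, dosage QTLs, motif
hits and endotype structure, so every stage is testable against known
ground truth.

## Worked example

Run the full pipeline on a simulated recovery cohort (20 matched pairs,
2-fold Monocyte-T1 effects, 10 planted links, 5 planted QTLs):

```python
import dataclasses, json
from mmcc.pipeline import run_all
from mmcc.simulate import default_recovery_config

cfg = default_recovery_config(seed=7)
manifest = run_all({"simulate": dataclasses.asdict(cfg)}, "results/run", seed=7)
print(manifest["n_discoveries"], manifest["n_nominal_links"],
      manifest["n_validated_links"], round(manifest["adjacency"]["ratio"], 1))
```

prints

```
{'snRNA': 172, 'scRNA': 177, 'snATAC': 154} 1067 10 16.4
```

meaning: 172/177/154 feature×lineage×timepoint associations at q < 0.10 in
the three layers (the 40 planted Monocyte-T1 effects plus link/QTL-driven
donor-level structure — see `docs/methods.md` on the test's behaviour under
donor-level variation); 1067 nominal peak–gene correlations of which 10 —
the planted links — survive the strict |r| > 0.65 cross-layer validation;
and 16.4-fold more adjacent differential peak pairs than expected by
chance, because the planted differential peaks are genomically contiguous.

The same stages are exposed on the command line:

```bash
mmcc simulate --seed 7 --out bundle/
mmcc diff --bundle bundle/ --modality snRNA --fdr 0.1 --out diff_snRNA.tsv
mmcc links --bundle bundle/ --out links.tsv
mmcc run --config run.yaml --seed 7 --out results/
```

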