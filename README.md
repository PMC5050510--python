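# stressrep

Repeatability of acute-stress cortisol responses, low/high-responder
classification, and responder-exclusive transcriptome screening.

`stressrep` is for quantitative physiologists and aquaculture geneticists
working with repeated stress-challenge designs: a cohort of fish (or any
animals) nested within families, each measured for post-stress plasma
cortisol at several occasions, optionally followed by RNA-seq of extreme
responders.  The package answers, with tested and reproducible code:

* **Is the stress response repeatable?**  Two-level nested ANOVA
  (individuals within families) with the Lessells–Boag intraclass
  correlation `r = s²_among / (s²_among + s²_within)`, measurement error
  `sqrt(MS_within)`, and expected-mean-squares variance components.
* **Which individuals are consistent low/high responders (LR/HR)?**
  Per-occasion Z-scores, summed per fish, quartile classification.
* **How do responder groups differ?**  Pooled two-sample t-tests (from raw
  data or published summaries), split-plot repeated-measures ANOVA,
  free-cortisol percentages.
* **What is exclusively transcribed in each responder type?**
  Median-of-ratios normalization, an exact conditional negative-binomial
  test, a presence/absence exclusivity filter with Benjamini–Hochberg FDR,
  Fisher's exact GO enrichment, and heatmap clustering.

A synthetic-data module generates phenotype tables, count matrices and GO
annotations with known ground truth, so every stage is verifiable without
access to any study's raw data.

## Worked example

Simulate a cohort (6 families × 12 fish × 4 monthly samplings, true
repeatability 0.4) and a count matrix with planted exclusive transcripts,
then run the pipeline:

```sh
stressrep simulate cortisol --seed 9 --out demo/
stressrep simulate counts   --seed 9 --out demo/
stressrep run --phenotypes demo/phenotypes.tsv --counts demo/counts.tsv \
              --groups demo/groups.tsv --out demo/out --seed 9
```

which prints (abridged):

```json
{
  "phenotypes": {"rows": 233, "fish": 72, "families": 6},
  "classification": {"n_fish": 72, "n_LR": 18, "n_HR": 18},
  "repeatability": {
    "response": "z",
    "r": 0.43698184073840496,
    "F": 3.509851507171008,
    "df": [66, 161],
    "p": 5.338545767627647e-11,
    "measurement_error_raw": 68.04545469230965,
    "pct_family_variance": 19.659811439107887
  },
  "screen": {
    "transcripts_in": 2000,
    "transcripts_retained": 2000,
    "calls": {"none": 1670, "LR_only": 169, "HR_only": 161}
  }
}
```

Reading this: of 288 potential records, 233 survived the 20% missingness;
the 72 fish split into 18 LR / 18 HR quartile groups; the estimated
repeatability of the Z-scored cortisol response is r = 0.44 (true value
0.4), highly significant (F₆₆,₁₆₁ = 3.51), with a within-individual
measurement error of 68 ng·ml⁻¹ on the raw scale and 20% of total variance
attributable to family; and the screen recovered exactly the 169 LR-only
and 161 HR-only planted exclusive transcripts.

The same operations are available as a library:

```python
from stressrep import (CortisolSimConfig, simulate_cortisol,
                       classify_responders, nested_anova,
                       repeatability_estimate)

table = simulate_cortisol(CortisolSimConfig(seed=9))
labels = classify_responders(table, quartile=0.25)
est = repeatability_estimate(nested_anova(table, response="z"))
print(round(est.r, 3), est.df)       # 0.437 (66, 161)
```

Published summary statistics can be checked directly:

```sh
stressrep ttest --summary 93.4 63.4 16 203.3 121.1 16
# {"t": -3.215983..., "df": 30, "p": 0.003107...}
```

## Layout

| module | contents |
| --- | --- |
| `stressrep.simulate` | synthetic cortisol / count / annotation generators |
| `stressrep.responders` | Z-scores, summed-Z quartile classification, rank consistency |
| `stressrep.repeatability` | nested ANOVA, r, variance components, t-tests, split-plot ANOVA |
| `stressrep.screen` | size factors, NB test, exclusivity filter, BH, GO enrichment, clustering |
| `stressrep.io` / `stressrep.pipeline` / `stressrep.cli` | TSV/JSON formats, end-to-end driver, CLI |

See `docs/methods.md` for the statistical model, conventions and
limitations.
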