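# mirscar

Paired scar/normal skin miRNA microarray analysis: MA-lowess
normalization, per-miRNA paired t-tests with FDR q-values, and
distance-correlation sure independence screening (DC-SIS), plus a
synthetic-data generator with known ground truth and a generic
hypergeometric gene-set over-representation step.

## The problem

Hypertrophic scars and adjacent normal skin taken from the same patient
form a natural paired design for asking which miRNAs change expression
during wound healing. With only a handful of patients and hundreds of
probes, three complementary selection criteria are useful:

1. **Paired t-test** (criterion 1). For miRNA *g* with per-patient log2
   differences *d_i = scar_i − normal_i*,

       t = mean(d) / (sd(d) / √n),   df = n − 1,

   two-sided *p*, significant at *p* ≤ 0.05.
2. **FDR** (criterion 2). Benjamini–Hochberg step-up q-values over all
   miRNAs jointly; significant at *q* ≤ 0.05. Since BH never shrinks a
   p-value, the criterion-2 set is always nested in the criterion-1 set.
3. **DC-SIS** (criterion 3). Each miRNA is ranked by the squared
   distance correlation ω between its expression vector across arrays
   and the binary scar indicator,

       dCor²(x, y) = dCov²(x, y) / √(dCov²(x, x) · dCov²(y, y)),

   where dCov² is the V-statistic from double-centred pairwise distance
   matrices. The top *d* = 6⌊*n*/ln *n*⌋ miRNAs are retained (*n* =
   number of arrays). Distance correlation is zero iff the variables are
   independent, so the screen is model-free and robust to
   misspecification; the sure-screening property guarantees truly
   relevant predictors survive with high probability.

Upstream, raw scanner intensities are background-subtracted (floored so
the log stays finite), log2-transformed and normalized by a robust
locally weighted regression of M on A against a median pseudo-array,
removing smooth per-array intensity-dependent bias.

## Worked example

```python
from mirscar import (SimulationConfig, simulate_dataset,
                     subtract_background, log2_transform,
                     lowess_normalize, PairedDifferential, DCSIS,
                     criteria_summary)

cfg = SimulationConfig(seed=42)           # 513 miRNAs, 9 patients x 2 arrays
matrix, sheet, truth = simulate_dataset(cfg)
norm = lowess_normalize(log2_transform(subtract_background(matrix, 50.0)))

de = PairedDifferential(norm, sheet).fit()
screen = DCSIS(norm, sheet).fit()
print(de.summary())
print(screen.summary())
print(criteria_summary(de.table, screen.table).summary())
```

prints (abridged):

```
Paired differential expression
==============================
miRNAs tested:        513
patient pairs:        9
FDR method:           bh
p <= 0.05 (criterion 1): 49
q <= 0.05 (criterion 2): 16

DC-SIS feature screening
========================
miRNAs screened:  513
sample size n:    18
model size d:     36 (= 6 * floor(n / log n))
selected:         36

Top rows by omega:
mirna_id  omega  rank  selected
 mir-422 0.9292     1      True
 mir-157 0.9155     2      True

Criteria summary
================
criterion  n_selected  n_elevated  n_lowered  n_unchanged  pct_elevated  pct_lowered
   t_test          49          25         24            0          51.0         49.0
      fdr          16           3         13            0          18.8         81.3
    dcsis          36          17         19            0          47.2         52.8

Intersections:
  n_dcsis&fdr&t_test: 16
  fdr_in_t_test_subset: True
  fdr_in_dcsis_subset: True
```

Of the 513 simulated miRNAs, 49 pass the raw t-test at 0.05, 16 survive
FDR adjustment, and DC-SIS keeps the top 36 (6⌊18/ln 18⌋). All 16
FDR-significant miRNAs are also DC-SIS-selected, and this run recovers
all 20 planted differential miRNAs in the screened set.

The same analysis is available from the shell:

```sh
mirscar simulate --out data --seed 42
mirscar normalize --in data/raw_matrix.tsv --out norm.tsv --background 50
mirscar diffexp --matrix norm.tsv --samples data/sample_sheet.csv --out de.tsv
mirscar dcsis   --matrix norm.tsv --samples data/sample_sheet.csv --out screen.tsv
mirscar report  --de de.tsv --screen screen.tsv --out report/
mirscar run     --config pipeline.json        # everything in one step
```

`mirscar enrich --gmt sets.gmt --query genes.txt --out enrich.tsv` scores
user-supplied gene sets with the upper-tail hypergeometric probability
P(X ≥ k) and BH q-values, reporting the top 10 categories.

## Layout

- `src/mirscar/simulate.py` — generative model and ground truth
- `src/mirscar/preprocess.py` — background, log2, MA-lowess, detection filter
- `src/mirscar/diffexp.py` — `PairedDifferential` model / results
- `src/mirscar/dcsis.py` — distance correlation, model-size rule, `DCSIS`
- `src/mirscar/enrich.py` — GMT parsing and hypergeometric ORA
- `src/mirscar/report.py` — criteria summaries, listings, intersections
- `src/mirscar/pipeline.py`, `src/mirscar/cli.py` — orchestration and CLI
- `docs/methods.md` — model details, parameter choices, limitations
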