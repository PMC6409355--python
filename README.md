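# oct4expr

Quantifies how the binding intensity of the pluripotency transcription
factor Oct4 in gene promoter regions predicts gene expression across a
somatic-cell reprogramming time course, and turns the fitted relationship
into a high/low-expression classifier.

Oct4 ChIP-seq signal in a promoter window (1.5 kb upstream to 0.5 kb
downstream of the TSS, strand-aware) is summarised by three peak
characteristics per gene and developmental day *t* ∈ {0, 1, 3, 5, 7, 11,
15, 18}:

* **H** — peak height (maximum signal of the strongest promoter peak),
* **D** — distance in bp between the peak midpoint and the TSS,
* **W** — peak width in bp.

Expression is modelled by a family of linear models whose regressors are
*derived combination variables* — products of H, D, W with functions of
time:

```
Exp = β₁·H·eᵗ + β₂·D·f(t) + β₃·W·log₁₀(t+1) + ε,   f(t) ∈ {t, t², t³, 0.5ᵗ}
```

(Models 1–4 correspond to the four choices of f(t); ε is a normal
disturbance whose location is fitted as the intercept).  The package
provides the full stack around this model: genomic input handling
(bedGraph / narrowPeak / BED6 / GTF), the 18-term candidate set and
stepwise selection, least-squares fitting with F/t tests and adjusted R²,
a threshold classifier over the top/bottom 30% expression groups with
seeded 10-fold cross-validation and a 2-unit feedforward baseline, and a
synthetic-data generator with known ground truth for every stage.

## Worked example

Fitting all four models to data generated from the 0.5ᵗ distance law with
noise SD 0.5 (`python examples/02_fit_models.py`):

```
model    f(t)    beta1     beta2   beta3  resid_sd        adjR2  p2 (t test)
    1       t   0.5000    0.0024  1.4277    76.949    1.189e-12    2.418e-01
    2     t^2   0.5000    0.0000  1.4755    77.511    1.206e-12    8.428e-01
    3     t^3   0.5000   -0.0000  1.4920    77.499    1.206e-12    7.940e-01
    4   0.5^t   0.5000   -0.3000  1.2003     0.478    0.000e+00   3.684e-205
```

Model 4 — the generative form — recovers β = (0.5, −0.3, 1.2), lands on
the true noise level (residual SD ≈ 0.5) and finds the distance term
significant; the misspecified distance laws inflate the residual SD by two
orders of magnitude and lose the distance signal entirely.  The adjusted
R² (shown as 1 − adjR²) is near 1 for every model because the exponential
height term dominates the total variance.

The other examples cover the genomic round trip
(`01_simulate_and_extract.py`: 100% of peak features recovered exactly
from written tracks), stepwise recovery of the active terms
(`03_stepwise_selection.py`) and cross-validated classification
(`04_classification_cv.py`: the Model-4 classifier reaches
Acc = Sn = Sp = Mcc = 1 on populations separated by 10σ while the small
feedforward baseline stays near chance).

## Command line

The same stages are available as a thin CLI for shell use:

```sh
oct4expr template --out config.yaml     # commented configuration template
oct4expr run-all --config config.yaml --out run/
```

`run-all` chains extract → fit → classify and writes TSV tables
(coefficients, inference, per-fold coefficients, classification metrics)
plus a JSON manifest per stage; re-running a stage from its manifest with
the same seed is byte-identical.

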