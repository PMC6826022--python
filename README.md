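# fishheart

Quantitative cardiac phenotyping for adult zebrafish. The package implements,
as one tested pipeline, the measurement procedures used to characterise heart
function in small-fish cardiomyopathy models:

* **Ex vivo beating-heart video mechanics** — a paced (2 Hz), perfused heart
  filmed at 66 fps in two orthogonal planes is segmented frame by frame; the
  biplane area–length formula `V = (2/3)·A_AL·L_AL` (exact for an ellipsoidal
  chamber) gives volumes, from which per-cycle `EF = (EDV−ESV)/EDV`,
  `FS = (L_d−L_s)/L_d` and `FAC = (EDA−ESA)/EDA` follow. Radial strain — the
  fractional change of the mean center-of-mass-to-boundary radius relative to
  end-diastole — is differentiated to strain-rate, and the closed
  velocity–strain loop area serves as a contractility index.
* **Doppler indices** — E and A diastolic inflow peaks, E/A, and the
  myocardial performance (Tei) index `MPI = (IVCT+IVRT)/ET` from valve-event
  annotations.
* **Single-myofibril kinetics** — mono-exponential activation (`k_ACT`) and
  release–restretch force redevelopment (`k_TR`) fits, biphasic relaxation
  (linear phase of duration `T_LIN` and normalized slope `k_LIN`, then
  exponential `k_REL`), maximal isometric tension (nN/µm² = mN/mm²), Hill
  force–pCa analysis (`pCa50`, `n_H`), and the 20 % tension-rundown exclusion
  rule.
* **Morphometry** — ventricle-surface-area/body-weight (mm²/g), area
  fractions within an ROI (trabecular density, intact-myofibril fraction),
  percentage of stain-positive nuclei, per-cell areas.
* **Cohort statistics** — critical swimming speed
  `Ucrit = Ui + ΔU·(t/T)` from the stepwise swim-tunnel protocol
  (9 cm/s start, 8.66 cm/s increments every 150 s), with body-length
  normalization; Kaplan–Meier curves with the log-rank test; unpaired t-tests
  and one-way ANOVA with Tukey HSD.

A synthetic-data module (`fishheart.synthetic`) generates every input the
pipeline consumes — biplane videos of an ellipsoidal beating chamber, force
traces, inflow waveforms, swim/survival cohorts, labelled images — with
analytic ground truth, so each stage is validated by parameter recovery
without any animal data.

## Worked example

```python
import fishheart.synthetic as syn
from fishheart.video import summarize_heart

video, truth = syn.gen_beating_heart_video(syn.CardiacSimParams(edv=4.0, esv=2.0))
summary = summarize_heart(video)
print(summary.summary())
```

```
Heart function summary (6 cycles averaged)
  edv                         4.0491 mm^3
  esv                         2.0063 mm^3
  ef                          0.5045
  fs                          0.2154
  fac                         0.3685
  max_contraction_velocity   -1.3045 1/s
  max_relaxation_velocity     1.3045 1/s
  loop_area                   0.4102 strain^2/s
```

The simulated heart cycles between EDV = 4 mm³ and ESV = 2 mm³, so the true
ejection fraction is 0.5; the full segmentation → biplane-volume → cycle
chain recovers 0.5045 (discretization error below one percent of volume).
FS and FAC follow from the ellipsoid geometry
(FS_true = 1 − (ESV/EDV)^{1/3} ≈ 0.206), and the loop area summarises the
strain–strain-rate cycle. Myofibril kinetics work the same way:

```python
trace, truth = syn.gen_myofibril_trace(syn.MyofibrilSimParams())
from fishheart.myofibril import analyze_trace
print(analyze_trace(trace).summary())
```

```
Myofibril kinetics
  k_ACT   5 1/s
  k_TR    5 1/s
  T_LIN   0.05 s
  k_LIN   1.5 1/s
  k_REL   10 1/s
  max tension 45 mN/mm^2
```

A command-line interface mirrors the library:
`fishheart simulate video --out sim/`, `fishheart exvivo --long ... --short
... --meta ... --out results/`, `fishheart doppler`, `fishheart myofibril
fit|pca`, `fishheart morpho vsa|fraction|nuclei|cells`, and `fishheart stats
ucrit|survival|compare`.

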