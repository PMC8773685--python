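# hp13c

Analysis chain for hyperpolarized [1-13C]pyruvate MRI of renal tumors:
from multi-coil dynamic 13C images to the apparent pyruvate-to-lactate
exchange rate **kPL**, and from there to the statistics that relate kPL to
WHO/ISUP tumor grade and MCT1 transporter expression.  Written for
researchers developing or validating metabolic-MRI quantification who need
a fully testable, open reimplementation of this kind of pipeline — the
clinical scans such studies are built on are not publicly distributable,
so the package ships a first-class synthetic-data module that generates
dynamic phantoms, H-DAB immunohistochemistry micrographs and multi-patient
cohorts with known ground truth.

## What it computes

The label kinetics follow the input-driven unidirectional two-site
exchange model

```
dP/dt = b(t) − P/T1_P − kPL·P
dL/dt = kPL·P − L/T1eff
```

where `b(t)` is a gamma-variate bolus and `T1eff` is an effective lactate
decay constant absorbing relaxation, back-conversion and shared RF losses.
The stages, each its own module:

| module             | role |
|--------------------|------|
| `synthetic_data`   | dynamic phantoms (20 frames / 4 s, 34 cm FOV, 8-coil array, 15° flip), IHC micrographs, seeded multi-patient cohorts |
| `coil_combination` | SVD (matched-filter) combination from time-summed complex data; time-summed metabolite maps |
| `kinetics`         | magnitude SNR `(mean(ROI) − mean(noise)) / (√2·SD(noise))`, the SNR ≥ 5 fitting mask, frequency-domain linear least-squares kPL fitting, a time-domain nonlinear oracle |
| `roi_analysis`     | polygonal tumor/kidney ROIs, 3 cm cylindrical biopsy ROIs, per-ROI and per-patient (median) summaries with the ≥ 75% viable-tissue filter |
| `ihc_quant`        | Beer–Lambert optical density, H-DAB color deconvolution, positivity classes at OD 0.2164 / 0.3274 / 0.4938, percent positive tissue, cell density |
| `cohort_stats`     | Spearman/Pearson correlations, Wilcoxon rank tests (exact at small n), and a patient-blocked permutation F-test for clustered biopsy data |
| `pipeline`         | the end-to-end chain over a synthetic cohort |

See `docs/methods.md` for the model, the estimator design (window
boundaries, errors-in-variables correction, two-stage relaxation handling)
and known limitations.

## Worked example

Recover kPL from a noiseless simulation at the clear-cell-carcinoma median
rate:

```python
from hp13c import (AcquisitionGeometry, BolusModel, KineticModelParams,
                   simulate_two_site_exchange, fit_kpl_frequency_domain)

geometry = AcquisitionGeometry()          # 20 frames / 4 s, first frame at 12 s
bolus = BolusModel()                      # gamma-variate, peak at 8 s
truth = KineticModelParams(k_pl=0.0065, t1_eff=30.0)
pyr, lac = simulate_two_site_exchange(truth, bolus, geometry)
fit = fit_kpl_frequency_domain(pyr, lac, geometry.frame_spacing)
print(f"fitted kPL    : {fit.k_pl_hat:.4f} 1/s")
print(f"fitted 1/T1eff: {fit.inv_t1_eff_hat:.4f} 1/s")
print(f"Lac/Pyr (sum) : {lac.sum() / pyr.sum():.3f}")
```

```
fitted kPL    : 0.0066 1/s
fitted 1/T1eff: 0.0426 1/s
Lac/Pyr (sum) : 0.148
```

The fitted kPL is within 2% of the simulation truth; the fitted decay rate
is 1/30 s⁻¹ plus the RF-depletion contribution of the 15° readout, which
the estimator deliberately absorbs rather than corrects.  The summed
lactate-to-pyruvate ratio of 0.148 is the model-free metabolic index for
this rate.

A full synthetic cohort, imaged at the reported pyruvate SNR and pushed
through coil combination, masking, kPL mapping and statistics:

```python
from hp13c.synthetic_data import AcquisitionGeometry, generate_cohort
from hp13c.pipeline import analyze_cohort

geometry = AcquisitionGeometry(acq_matrix=(40, 40), recon_matrix=(40, 40),
                               n_slices=3, n_coils=2)
cohort = generate_cohort(n_patients=6, seed=1, geometry=geometry)
result = analyze_cohort(cohort)
print(result.patient_table[["patient_id", "grade", "kpl_tumor", "kpl_true",
                            "snr_pyruvate"]].round(4).to_string(index=False))
rho = result.grade_spearman
print(f"Spearman grade~kPL: rho = {rho.estimate:.3f}, p = {rho.p_value:.4f}")
```

```
patient_id  grade  kpl_tumor  kpl_true  snr_pyruvate
       P01      3     0.0115    0.0117       26.8183
       P02      2     0.0066    0.0065       27.3050
       P03      4     0.0140    0.0141       27.2909
       P04      3     0.0102    0.0102       26.5740
       P05      4     0.0144    0.0142       26.3687
       P06      2     0.0061    0.0066       27.7134
Spearman grade~kPL: rho = 0.956, p = 0.0222
```

Each patient's tumor-median kPL (`kpl_tumor`) recovers its generating
value (`kpl_true`) to within a few percent at pyruvate SNR ≈ 27, and the
monotone grade association is detected by the exact Spearman permutation
test.

A thin CLI covers the simulation and table-level entry points, e.g.
`hp13c simulate ihc --seed 3 --out out/`, `hp13c ihc-quant --image
out/ihc.png`, `hp13c cohort-stats --table biopsies.csv --test
blocked-grade --n-perm 9999 --seed 1`.

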