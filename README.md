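# relaxmap

Vendor-independent quantitative MRI relaxometry: pixelwise and ROI-mean
**T1 and T2 relaxation maps** from multi-timepoint magnitude or
phase-sensitive (PSIR) image series, for researchers who need transparent,
openly documented curve fitting instead of a scanner's undocumented inline
maps. A synthetic multi-vial phantom simulator makes the whole pipeline
testable without scanner data.

## Signal models

Each supported acquisition is a mono-exponential model of the preparation
time *t* (inversion time TI, saturation time TS, echo time TE, or
T2-preparation duration, in ms):

| model id        | 3-parameter fit                          | 2-parameter fit      |
|-----------------|------------------------------------------|----------------------|
| `ir_se_mag`     | \|A (1 − B e^(−t/T1))\|                  | \|A (1 − 2 e^(−t/T1))\| |
| `psir`          | A (1 − B e^(−t/T1))                      | A (1 − 2 e^(−t/T1))  |
| `sr_bssfp`      | A (1 − B e^(−t/T1))                      | A (1 − e^(−t/T1))    |
| `molli_mag`     | \|A (1 − B e^(−t/T1\*))\|, T1 = T1\*(B−1) | —                   |
| `molli_psir`    | A (1 − B e^(−t/T1\*)), T1 = T1\*(B−1)    | —                    |
| `se_t2`         | A e^(−t/T2) + B, B ≥ 0                   | A e^(−t/T2)          |
| `t2prep_bssfp`  | A e^(−t/T2) + B, B ≥ 0                   | A e^(−t/T2)          |

Fitting is a two-stage pipeline per pixel:

1. **Initialization.** T1: a two-pass lookup-table search over 0–4000 ms
   (50 ms coarse grid, then 5 ms within ±100 ms of the coarse winner) on
   max-normalized signals assuming ideal preparation efficiency, scored by
   sum of absolute error. T2: weighted log-linear regression of log S
   against t (weights S²), repeated under stepwise truncation of the longest
   echo down to three points; the candidate with the smallest absolute error
   over all samples wins.
2. **Refinement.** Nelder-Mead simplex over the model's 2 or 3 parameters,
   converged when the tau coordinate of the simplex moves by less than
   0.10 ms between iterations (and the simplex has geometrically collapsed).
   MOLLI fits estimate the apparent T1\* and apply the Look-Locker
   correction T1 = T1\*(B − 1) afterwards; fitted B ≤ 1 flags the pixel
   instead of emitting a non-physical value.

Initial T2 estimates outside the open interval 0 < T2 < 400 ms are excluded
and set to 0 in the map, as are pixels that never refine. Curve-fit quality
is reported as the normalized mean absolute residual (% of the pixel's peak
signal). Agreement against a reference is summarised with the modified
Bland-Altman analysis (difference vs reference, bias ± 1.96 SD limits, ms
and %).

## Worked example

```python
import numpy as np
import relaxmap as rm

spec = rm.default_eurospin_spec(model_id="sr_bssfp", variant="3p",
                                shape=(72, 96), noise_sigma=2.0, seed=7)
series, truth = rm.simulate_series(spec)          # 18-frame SR series, SNR 50
rmap = rm.fit_map(series, rm.get_model("sr_bssfp", "3p"))
for k in (1, 12):
    sel = (truth.labels == k) & rmap.refined_mask
    print(k, spec.vials[k - 1].t1, round(float(rmap.tau_map[sel].mean()), 1))
```

prints

```
1 214.0 213.4
12 1643.0 1657.5
```

— the per-vial map means of the 12-vial phantom (true T1 214–1643 ms,
emulating a Eurospin gel set at 1.5 T) land within a fraction of a percent
of the truth at this noise level; `rmap.residual_map` holds the per-pixel
misfit (~1.4 % here, the Rician noise floor). The scripts in `examples/`
walk through simulation, T1 mapping, MOLLI + Look-Locker correction,
T2-prep mapping with the SR anchor image, and Bland-Altman validation.

The same pipeline runs from the shell:

```bash
relaxmap simulate --preset eurospin-1.5T --model sr_bssfp --snr 50 --seed 7 --out sim/
relaxmap fit --model sr_bssfp --variant 3p --input sim/series.nii \
             --sidecar sim/series.json --out map/
relaxmap validate --candidate map/ --reference sim/reference.csv \
                  --vials sim/vial_labels.nii --out report/
```

`relaxmap fit` also reads DICOM series directly (times resolved from the
standard Inversion Time / Echo Time / Trigger Time tags; a JSON sidecar
overrides vendor-specific headers).

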