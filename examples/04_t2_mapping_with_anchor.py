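"""T2-prepared bSSFP mapping with the saturation-recovery anchor image.

The 3-parameter T2 model S(t) = A exp(-t/T2) + B needs its offset B pinned
down; a short-saturation SR image appended to the series acts as an
effective infinite-preparation sample whose prediction is the asymptote B.
This script fits the same noisy series with and without the anchor and
shows the exclusion rule zeroing an out-of-range vial.
"""

import numpy as np

import relaxmap as rm

spec = rm.default_eurospin_spec(model_id="t2prep_bssfp", variant="3p",
                                shape=(48, 64), noise_sigma=1.0, seed=12,
                                include_anchor=True)
series, truth = rm.simulate_series(spec)
model = rm.get_model("t2prep_bssfp", "3p")

with_anchor = rm.fit_map(series, model)
no_anchor_series = rm.ImageSeries(
    frames=series.frames[:-1], times=series.times[:-1],
    convention=series.convention)
without_anchor = rm.fit_map(no_anchor_series, model)

print(f"{'vial':>4} {'true T2':>8} {'anchored':>9} {'plain':>9}")
for k, vial in enumerate(spec.vials, start=1):
    sel = truth.labels == k
    a = with_anchor.tau_map[sel & with_anchor.refined_mask].mean()
    p = without_anchor.tau_map[sel & without_anchor.refined_mask].mean()
    print(f"{k:>4} {vial.t2:8.1f} {a:9.1f} {p:9.1f}")

# The anchor sample stabilises the offset estimate, tightening long-T2 vials
# where decay barely spans the 25-200 ms preparation window.

# Exclusion rule: initial T2 estimates outside the open interval
# (0, 400) ms are set to 0 in the map.
vials = [rm.Vial((12.0, 16.0), 6.0, t1=1000.0, t2=350.0, b=0.0),
         rm.Vial((12.0, 48.0), 6.0, t1=1000.0, t2=450.0, b=0.0)]
xs = rm.PhantomSpec(vials=vials, shape=(24, 64), model_id="se_t2", variant="2p",
                    times=rm.TIMING_PRESETS["se_t2_single"])
xseries, xtruth = rm.simulate_series(xs)
xmap = rm.fit_map(xseries, rm.get_model("se_t2", "2p"))
print("T2=350 vial map mean:", round(xmap.tau_map[xtruth.labels == 1].mean(), 1),
      "| T2=450 vial map values all zero:",
      bool((xmap.tau_map[xtruth.labels == 2] == 0).all()))
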