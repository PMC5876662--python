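#!/usr/bin/env python
"""Exercise the acquisition chain end to end on simulated raw scans:
invert the reflectance calibration to get raw counts + white/dark frames,
then calibrate, segment at 830 nm (Otsu), crop to 430-970 nm, and average
the ROI. Reports the recovery error of the planted spectrum per seed.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from seedhsi.hypercube import process_scan
from seedhsi.synthetic import NoiseSpec, make_class_profiles, simulate_hypercube

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 42


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    rows = []
    for side in ("ventral", "reverse"):
        profile = make_class_profiles(side)
        for label, mean in ((1, profile.viable_mean), (2, profile.nonviable_mean)):
            for sensor_noise in (0.0, 0.002):
                scan = simulate_hypercube(
                    mean, geometry=(32, 32),
                    noise=NoiseSpec(gain_sd=0, offset_sd=0, baseline_amp=0, white_sd=sensor_noise),
                    rng=rng,
                )
                spec = process_scan(scan.i0, scan.white, scan.black, scan.wavelengths,
                                    label=label, side=side)
                keep = (scan.wavelengths >= 430) & (scan.wavelengths <= 970)
                err = np.abs(spec.reflectance - mean[keep]).max()
                rows.append({"side": side, "label": label,
                             "sensor_noise_sd": sensor_noise,
                             "roi_pixels": int(scan.mask.sum()),
                             "max_abs_recovery_error": err})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "cube_extraction_recovery.csv", index=False, float_format="%.3e")
    print(df.to_string(index=False))
    noiseless = df[df.sensor_noise_sd == 0]["max_abs_recovery_error"].max()
    print(f"\nnoiseless scans recover the planted spectrum to {noiseless:.2e} "
          "(calibration is an exact inverse of the generator)")


if __name__ == "__main__":
    main()
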