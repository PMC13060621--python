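"""One-off calibration of the default excitation-error cutoff.

Bisects e_max on the stock four-panel configuration until the mean number of
retained peaks per sketch pattern (after random half-selection) is 162.  The
resulting value is frozen as ``sxalign.config.DEFAULT_E_MAX``.

Run from the repository root:  python scripts/calibrate_emax.py
"""

import numpy as np

from sxalign.cell import CrystalState, random_orientation
from sxalign.config import SimConfig, default_beam, default_cell, four_panel_geometry
from sxalign.sketch import make_sketch

TARGET_MEAN_PEAKS = 162.0
N_PATTERNS = 200
SEED = 20260918


def mean_peaks(e_max: float) -> float:
    geometry = four_panel_geometry()
    beam = default_beam()
    cell = default_cell()
    counts = []
    for pid in range(N_PATTERNS):
        rng = np.random.default_rng([SEED, pid])
        crystal = CrystalState(cell=cell, orientation=random_orientation(rng))
        panels, fs, ss, hkl = make_sketch(geometry, crystal, beam, rng,
                                          keep_prob=0.5, e_max=e_max)
        counts.append(len(fs))
    return float(np.mean(counts))


def main():
    lo, hi = 1e6, 1e7
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        m = mean_peaks(mid)
        print(f"e_max = {mid:.6g} 1/m  ->  mean peaks = {m:.2f}")
        if m < TARGET_MEAN_PEAKS:
            lo = mid
        else:
            hi = mid
        if abs(m - TARGET_MEAN_PEAKS) < 0.05:
            break
    print(f"calibrated e_max = {0.5 * (lo + hi):.6g} 1/m")


if __name__ == "__main__":
    main()
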