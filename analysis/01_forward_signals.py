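#!/usr/bin/env python
"""Forward-model survey: angular DDE modulation and anisotropy contrast.

Simulates powder-averaged S(b, theta) curves for stick-like, white-matter-
and gray-matter-like tensors over the study's b values, and the
parallel-vs-perpendicular contrast as a function of the unitless weighting
b*MD for a range of microscopic anisotropies.  Writes
results/forward_theta_modulation.csv and results/forward_contrast.csv.

Key finding: the theta-modulation depth grows with b and with uFA, and the
parallel (theta = 0) condition always exceeds the perpendicular one; an
isotropic substrate is flat in theta at every b.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ddes.forward_model import (
    AxisymmetricTensor,
    encoding_plane,
    powder_signal_curve,
    uniform_orientations,
)

SUBSTRATES = {
    "tNAA-like stick": AxisymmetricTensor.stick(0.5),
    "WM water": AxisymmetricTensor(1.83, 0.06),
    "GM water": AxisymmetricTensor(1.43, 0.12),
    "isotropic": AxisymmetricTensor.isotropic(1.0),
}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    ori = uniform_orientations(256)
    plane = encoding_plane(1)
    thetas = np.arange(0.0, 360.0, 45.0)

    rows = []
    for name, tensor in SUBSTRATES.items():
        for b in (918.0, 2066.0, 4050.0, 7199.0):
            s = powder_signal_curve(tensor, ori, b, thetas, plane)
            for th, v in zip(thetas, s):
                rows.append((name, b, th, v))
    mod = pd.DataFrame(rows, columns=["substrate", "b_svmm2", "theta_deg", "s_norm"])
    mod.to_csv(args.outdir / "forward_theta_modulation.csv", index=False)

    crows = []
    for ufa_target, ratio in [(1.0, 0.0), (0.8, 0.16), (0.5, 0.45), (0.0, 1.0)]:
        for bmd in np.linspace(0.2, 8.0, 25):
            md = 1.0
            d_par = 3.0 * md / (1.0 + 2.0 * ratio)
            t = AxisymmetricTensor(d_par, ratio * d_par)
            b = bmd / (1e-3 * md)
            s_par = powder_signal_curve(t, ori, b, 0.0, plane)[0]
            s_perp = powder_signal_curve(t, ori, b, 90.0, plane)[0]
            crows.append((ratio, bmd, s_par, s_perp, (s_par - s_perp) / s_perp))
    contrast = pd.DataFrame(
        crows, columns=["dperp_over_dpar", "b_md", "s_parallel", "s_perpendicular",
                        "contrast"]
    )
    contrast.to_csv(args.outdir / "forward_contrast.csv", index=False)

    stick = mod[(mod.substrate == "tNAA-like stick") & (mod.b_svmm2 == 7199.0)]
    print("theta-modulation at b = 7199 s/mm^2, tNAA-like stick (D_par = 0.5):")
    print(stick[["theta_deg", "s_norm"]].to_string(index=False))
    print(
        "\nparallel/perpendicular contrast at b*MD = 8 by anisotropy "
        "(D_perp/D_par -> contrast):"
    )
    last = contrast[contrast.b_md == contrast.b_md.max()]
    print(last[["dperp_over_dpar", "contrast"]].to_string(index=False))


if __name__ == "__main__":
    main()
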