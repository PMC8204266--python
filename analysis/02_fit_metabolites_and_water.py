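#!/usr/bin/env python
"""Single-dataset pipeline: simulate, reduce, fit, derive uFA and tortuosity.

Runs the full pipeline on noiseless synthetic data: a metabolite-protocol
stick substrate (tNAA-like) and multi-b water mixtures for white- and
gray-matter-like volumes (intracellular tensor + extracellular tensor +
isotropic CSF).  Writes results/fitted_parameters.csv.

Key findings: the metabolite fit recovers its substrate exactly; the water
fits show the extrapolated S0 falling with the b pair as extracellular water
and CSF are suppressed, while (D_par, D_perp, uFA) converge toward the
intracellular tensor at the highest pair.
"""

import argparse
from pathlib import Path

import pandas as pd

from ddes.fitting import (
    D_FREE_TNAA_37C,
    D_FREE_WATER_37C,
    fit_theta_modulation,
    fit_water_bpairs,
    tortuosity,
)
from ddes.forward_model import (
    AxisymmetricTensor,
    CompartmentMixture,
    uniform_orientations,
)
from ddes.preprocessing import reduce_to_powder_signal
from ddes.synthetic_data import build_scheme, generate_dataset

WATER_MIXTURES = {
    "WM-like": CompartmentMixture(
        [
            ("intracellular", 0.50, AxisymmetricTensor(1.83, 0.06)),
            ("extracellular", 0.48, AxisymmetricTensor(2.0, 1.0)),
            ("csf", 0.02, AxisymmetricTensor.isotropic(3.0)),
        ]
    ),
    "GM-like": CompartmentMixture(
        [
            ("intracellular", 0.40, AxisymmetricTensor(1.43, 0.12)),
            ("extracellular", 0.46, AxisymmetricTensor.isotropic(1.8)),
            ("csf", 0.14, AxisymmetricTensor.isotropic(3.0)),
        ]
    ),
}


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    ori = uniform_orientations(256)
    rows = []

    stick = AxisymmetricTensor.stick(0.47)
    table = generate_dataset(stick, build_scheme("metabolite"), orientations=ori)
    fit = fit_theta_modulation(reduce_to_powder_signal(table), orientations=ori)
    rows.append(
        (
            "tNAA stick",
            "metabolite",
            fit.b_attributed,
            fit.s0,
            fit.d_par,
            fit.d_perp,
            fit.mu_fa,
            tortuosity(D_FREE_TNAA_37C, fit.d_par),
        )
    )

    for label, mix in WATER_MIXTURES.items():
        table = generate_dataset(mix, build_scheme("water"), orientations=ori)
        for f in fit_water_bpairs(reduce_to_powder_signal(table), orientations=ori):
            rows.append(
                (
                    label,
                    "water",
                    f.b_attributed,
                    f.s0,
                    f.d_par,
                    f.d_perp,
                    f.mu_fa,
                    tortuosity(D_FREE_WATER_37C, min(f.d_par, D_FREE_WATER_37C)),
                )
            )

    out = pd.DataFrame(
        rows,
        columns=["substrate", "mode", "b", "s0", "d_par", "d_perp", "mu_fa",
                 "tortuosity"],
    )
    out.to_csv(args.outdir / "fitted_parameters.csv", index=False)
    with pd.option_context("display.float_format", "{:0.4f}".format):
        print(out.to_string(index=False))
    print(
        "\nNote the monotone fall of fitted S0 with the b pair for both water"
        " mixtures: fast isotropic compartments are progressively suppressed,"
        " and the highest-b estimates approach the intracellular tensor."
    )


if __name__ == "__main__":
    main()
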