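#!/usr/bin/env python
"""Synthetic cohort: tissue-fraction regression and group comparison.

Generates a cohort with white-matter, gray-matter and small-gray-matter
volumes of interest (tissue fractions drawn from the study-like
distributions), fits every subject's water and tNAA data, regresses D_par
on the WM fraction of (GM + WM), extrapolates the pure-tissue endpoints
with tortuosities, and compares PWM vs OGM water metrics with Welch tests
under Benjamini-Hochberg correction.  Writes results/cohort_fits.csv,
results/cohort_regression.json and results/cohort_group_comparison.csv.

Key findings: D_par rises linearly with WM fraction for both molecules; the
extrapolated pure-tissue tortuosities of water and tNAA agree closely
within each tissue despite ~4-fold different diffusivities, and are higher
in gray than in white matter.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from ddes.cohort_analysis import fit_cohort, group_compare, regress_dpar_on_wm
from ddes.forward_model import uniform_orientations
from ddes.synthetic_data import CohortSpec, generate_cohort


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--snr", type=float, default=35.0)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    ori = uniform_orientations(256)
    spec = CohortSpec(snr=args.snr, seed=args.seed)
    records = fit_cohort(generate_cohort(spec, orientations=ori), orientations=ori)

    fits = pd.DataFrame(
        [
            {
                "subject": r.subject_id,
                "voi": r.voi,
                "gm": r.gm,
                "wm": r.wm,
                "csf": r.csf,
                "wm_renorm": r.wm_renorm,
                "molecule": mol,
                **fit.to_dict(),
            }
            for r in records
            for mol, fit in r.fits.items()
        ]
    )
    fits.to_csv(args.outdir / "cohort_fits.csv", index=False)

    regs = {}
    for mol in spec.molecules:
        reg = regress_dpar_on_wm(records, mol.name, d_free=mol.d_free)
        regs[mol.name] = asdict(reg)
        print(
            f"{mol.name}: D_par = {reg.intercept:.3f} + {reg.slope:.4f} * WM%"
            f"  (R^2 = {reg.r2:.2f}, p = {reg.p_value:.2g}, n = {reg.n})"
        )
        for wmp in (100.0, 0.0):
            d, dse = reg.endpoints[wmp]
            t, tse = reg.tortuosity_endpoints[wmp]
            tissue = "pure WM" if wmp == 100.0 else "pure GM"
            print(
                f"  {tissue}: D_par = {d:.2f} +- {dse:.2f} um^2/ms,"
                f"  T = {t:.2f} +- {tse:.2f}"
            )
    (args.outdir / "cohort_regression.json").write_text(
        json.dumps(regs, indent=2, default=float) + "\n"
    )

    water = fits[fits.molecule == "water"]
    metrics = ["d_par", "d_perp", "mu_fa"]
    a = {m: water.loc[water.voi == "PWM", m].to_numpy() for m in metrics}
    b = {m: water.loc[water.voi == "OGM", m].to_numpy() for m in metrics}
    comp = group_compare(a, b, correction="benjamini_hochberg")
    comp.to_csv(args.outdir / "cohort_group_comparison.csv", index=False)
    print("\nPWM vs OGM, water metrics (Welch + Benjamini-Hochberg):")
    with pd.option_context("display.float_format", "{:0.4g}".format):
        print(comp.to_string(index=False))


if __name__ == "__main__":
    main()
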