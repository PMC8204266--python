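"""Reduction of raw condition-level amplitudes to normalized S(b, theta).

Pipeline per (b, theta): average repeats, take the geometric mean of the two
gradient polarities (cancelling multiplicative cross-terms), average across
the three first-encoding planes (the emulated powder average), and normalize
by the b = 0 amplitude.  On scalar amplitudes these steps are associative up
to noise, so one code path serves both metabolite and water modalities.

Pairs in which either polarity amplitude is nonpositive (possible at extreme
noise after the magnitude operation) are excluded from the geometric mean and
counted in the provenance rather than clipped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import SignalTable

__all__ = [
    "PowderSignal",
    "geometric_mean_polarity",
    "powder_average_planes",
    "reduce_to_powder_signal",
    "antiparallel_contrast",
]


@dataclass
class PowderSignal:
    """b0-normalized powder-averaged signal series.

    ``data`` has columns ``b_svmm2``, ``theta_deg``, ``s_norm`` and
    ``n_pairs`` (polarity pairs averaged into the point); the b = 0 row has
    ``s_norm = 1`` by construction.
    """

    data: pd.DataFrame
    s_b0: float
    provenance: dict = field(default_factory=dict)

    @property
    def nonzero_b(self) -> tuple[float, ...]:
        return tuple(sorted(self.data.loc[self.data["b_svmm2"] > 0, "b_svmm2"].unique()))

    def series(self, b: float) -> pd.DataFrame:
        """The 8-point theta series at one nonzero b, sorted by theta."""
        out = self.data[self.data["b_svmm2"] == b].sort_values("theta_deg")
        if out.empty:
            raise ValueError(f"no data at b = {b}")
        return out.reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def geometric_mean_polarity(s_plus, s_minus):
    """sqrt(S+ * S-): exact cancellation of multiplicative exp(+-c) cross-terms."""
    s_plus = np.asarray(s_plus, dtype=float)
    s_minus = np.asarray(s_minus, dtype=float)
    if np.any(s_plus <= 0) or np.any(s_minus <= 0):
        raise ValueError("geometric mean requires strictly positive amplitudes")
    out = np.sqrt(s_plus * s_minus)
    return float(out) if out.ndim == 0 else out


def powder_average_planes(table: SignalTable) -> SignalTable:
    """Arithmetic mean over the 3 planes and repeats, preserving polarity.

    The output has plane index 0 (averaged) and repeat 1, with 8 theta points
    per (b, polarity).  Raises if any plane is missing for some condition.
    """
    df = table.data
    dw = df[df["b_svmm2"] > 0]
    missing = []
    for (b, theta, pol), grp in dw.groupby(["b_svmm2", "theta_deg", "polarity"]):
        absent = {1, 2, 3} - set(grp["plane"].unique())
        if absent:
            missing.append((b, theta, pol, sorted(absent)))
    if missing:
        raise ValueError(f"missing planes for conditions: {missing}")
    avg = (
        dw.groupby(["b_svmm2", "theta_deg", "polarity"], as_index=False)["amplitude"]
        .mean()
    )
    avg["plane"] = 0
    avg["repeat"] = 1
    b0 = df[df["b_svmm2"] == 0]
    b0_row = pd.DataFrame(
        [
            {
                "b_svmm2": 0.0,
                "theta_deg": 0.0,
                "polarity": "+",
                "amplitude": b0["amplitude"].mean(),
                "plane": 0,
                "repeat": 1,
            }
        ]
    )
    cols = ["b_svmm2", "plane", "theta_deg", "polarity", "repeat", "amplitude"]
    out = pd.concat([b0_row, avg], ignore_index=True)[cols]
    meta = dict(table.meta)
    meta["plane_averaged"] = True
    return SignalTable(out, meta)


def reduce_to_powder_signal(table: SignalTable) -> PowderSignal:
    """Full reduction: repeats -> polarity geometric mean -> planes -> / S(b=0)."""
    df = table.data
    b0 = df.loc[df["b_svmm2"] == 0, "amplitude"]
    if b0.empty:
        raise ValueError("no b = 0 record; cannot normalize")
    s_b0 = float(b0.mean())
    if s_b0 <= 0:
        raise ValueError(f"nonpositive b = 0 amplitude ({s_b0})")

    dw = df[df["b_svmm2"] > 0]
    rep_mean = (
        dw.groupby(["b_svmm2", "plane", "theta_deg", "polarity"])["amplitude"]
        .mean()
        .unstack("polarity")
    )
    if not {"+", "-"}.issubset(rep_mean.columns):
        raise ValueError("both gradient polarities are required for every DW condition")

    valid = (rep_mean["+"] > 0) & (rep_mean["-"] > 0)
    n_dropped = int((~valid).sum())
    geo = pd.Series(
        geometric_mean_polarity(
            rep_mean.loc[valid, "+"].to_numpy(), rep_mean.loc[valid, "-"].to_numpy()
        ),
        index=rep_mean.index[valid],
        name="amplitude",
    ).reset_index()

    grouped = geo.groupby(["b_svmm2", "theta_deg"])["amplitude"]
    plane_avg = grouped.mean().reset_index()
    plane_avg["n_pairs"] = grouped.size().to_numpy()
    empty = [
        (b, t)
        for (b, t) in dw[["b_svmm2", "theta_deg"]].drop_duplicates().itertuples(index=False)
        if (b, t) not in set(map(tuple, plane_avg[["b_svmm2", "theta_deg"]].to_numpy()))
    ]
    if empty:
        raise ValueError(
            f"all polarity pairs nonpositive for conditions {empty}; cannot reduce"
        )

    plane_avg["s_norm"] = plane_avg["amplitude"] / s_b0
    rows = pd.concat(
        [
            pd.DataFrame(
                [
                    {
                        "b_svmm2": 0.0,
                        "theta_deg": 0.0,
                        "s_norm": 1.0,
                        "n_pairs": int((df["b_svmm2"] == 0).sum()),
                    }
                ]
            ),
            plane_avg[["b_svmm2", "theta_deg", "s_norm", "n_pairs"]],
        ],
        ignore_index=True,
    )
    provenance = {
        "n_records": int(len(df)),
        "n_b0_records": int((df["b_svmm2"] == 0).sum()),
        "n_dropped_nonpositive_pairs": n_dropped,
    }
    return PowderSignal(rows, s_b0=s_b0, provenance=provenance)


def antiparallel_contrast(powder: PowderSignal, b: float) -> float:
    """(S(0 deg) - S(180 deg)) / mean(S) at one b.

    Under the Gaussian (time-independent) forward model the expectation is 0;
    a systematic nonzero value signals time-dependent diffusion effects.
    """
    series = powder.series(b)
    by_theta = series.set_index("theta_deg")["s_norm"]
    for ang in (0.0, 180.0):
        if ang not in by_theta.index:
            raise ValueError(f"theta = {ang} missing at b = {b}")
    return float((by_theta[0.0] - by_theta[180.0]) / by_theta.mean())
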