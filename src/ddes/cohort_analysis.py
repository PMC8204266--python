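"""Tissue-fraction regression and group statistics over fitted cohorts.

Axial diffusivity at the highest b scales with the white-matter content of
the volume of interest; ordinary least squares of D_par against the WM
fraction of (GM + WM) extrapolates the pure-tissue endpoints at 0% and 100%
WM, from which pure-GM / pure-WM tortuosities follow.  CSF is excluded from
the fraction denominator because its signal is fully suppressed at the
highest b.

Group comparisons use Welch's unequal-variance t-test with
Benjamini-Hochberg false-discovery-rate control across a metric family, or
Bonferroni for small fixed families of regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fitting import FitResult, fit_theta_modulation, tortuosity
from .forward_model import OrientationSet, uniform_orientations
from .preprocessing import reduce_to_powder_signal
from .synthetic_data import SyntheticSubject

__all__ = [
    "SubjectRecord",
    "RegressionResult",
    "renormalize_fractions",
    "fit_cohort",
    "regress_dpar_on_wm",
    "regress_tortuosity_on_wm",
    "group_compare",
]


def renormalize_fractions(gm: float, wm: float, csf: float = 0.0):
    """GM/WM fractions of the GM + WM sum, in percent (CSF excluded).

    Returns (gm', wm') with gm' + wm' = 100.  Idempotent.
    """
    if gm < 0 or wm < 0:
        raise ValueError("fractions must be >= 0")
    total = gm + wm
    if total <= 0:
        raise ValueError("gm + wm must be > 0")
    gm_prime = 100.0 * gm / total
    return gm_prime, 100.0 - gm_prime


@dataclass
class SubjectRecord:
    """One subject-VOI entry: tissue fractions plus per-molecule fits."""

    subject_id: str
    voi: str
    gm: float
    wm: float
    csf: float
    fits: dict[str, FitResult] = field(default_factory=dict)

    @property
    def wm_renorm(self) -> float:
        """WM percent of GM + WM."""
        return renormalize_fractions(self.gm, self.wm, self.csf)[1]


def fit_cohort(
    subjects: Sequence[SyntheticSubject],
    orientations: OrientationSet | None = None,
    variant: str = "no_cross_term",
) -> list[SubjectRecord]:
    """Reduce and fit every subject's per-molecule signal table."""
    if orientations is None:
        orientations = uniform_orientations(256)
    records = []
    for subj in subjects:
        fits = {
            name: fit_theta_modulation(
                reduce_to_powder_signal(table),
                mode="metabolite",
                variant=variant,
                orientations=orientations,
            )
            for name, table in subj.tables.items()
        }
        records.append(
            SubjectRecord(
                subject_id=subj.subject_id,
                voi=subj.voi,
                gm=subj.gm,
                wm=subj.wm,
                csf=subj.csf,
                fits=fits,
            )
        )
    return records


@dataclass
class RegressionResult:
    """OLS of a diffusivity on WM fraction with pure-tissue extrapolation.

    ``endpoints`` maps WM percent (0.0 and 100.0) to (estimate, se);
    ``tortuosity_endpoints`` maps the same keys to (T, se) when a free
    diffusivity was supplied.  ``se_kind`` records whether the endpoint SEs
    come from the prediction-interval or the confidence-interval (mean)
    formula.
    """

    molecule: str
    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    endpoints: dict[float, tuple[float, float]]
    tortuosity_endpoints: dict[float, tuple[float, float]] | None
    se_kind: str


def _ols_endpoints(x: np.ndarray, y: np.ndarray, se_kind: str):
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    pred = res.get_prediction(np.array([[1.0, 0.0], [1.0, 100.0]]))
    if se_kind == "prediction":
        se = pred.se_obs
    elif se_kind == "confidence":
        se = pred.se_mean
    else:
        raise ValueError("se_kind must be 'prediction' or 'confidence'")
    return res, pred.predicted_mean, np.asarray(se)


def regress_dpar_on_wm(
    records: Sequence[SubjectRecord],
    molecule: str,
    d_free: float | None = None,
    se_kind: str = "prediction",
) -> RegressionResult:
    """OLS of fitted D_par on the WM fraction of (GM + WM), with endpoints.

    Endpoint standard errors default to the prediction-interval formula at
    0% and 100% WM (configurable to the narrower confidence-of-the-mean SE).
    If ``d_free`` is given, tortuosity T = sqrt(d_free / D_par) is evaluated
    at each endpoint with a delta-method SE, se_T = se_D * T / (2 D_par).
    """
    rows = [
        (r.wm_renorm, r.fits[molecule].d_par)
        for r in records
        if molecule in r.fits and np.isfinite(r.fits[molecule].d_par)
    ]
    if len(rows) < 3:
        raise ValueError("regression needs at least 3 subjects with valid fits")
    x = np.array([r[0] for r in rows])
    y = np.array([r[1] for r in rows])
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all WM fractions identical")

    res, est, se = _ols_endpoints(x, y, se_kind)
    endpoints = {0.0: (float(est[0]), float(se[0])), 100.0: (float(est[1]), float(se[1]))}
    tort = None
    if d_free is not None:
        tort = {}
        for wmp, (d_hat, d_se) in endpoints.items():
            if 0 < d_hat <= d_free:
                t_hat = tortuosity(d_free, d_hat)
                tort[wmp] = (t_hat, d_se * t_hat / (2.0 * d_hat))
            else:
                tort[wmp] = (float("nan"), float("nan"))
    return RegressionResult(
        molecule=molecule,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=len(rows),
        endpoints=endpoints,
        tortuosity_endpoints=tort,
        se_kind=se_kind,
    )


def regress_tortuosity_on_wm(
    records: Sequence[SubjectRecord],
    molecule: str,
    d_free: float,
    method: str = "fit_then_transform",
    se_kind: str = "prediction",
) -> dict[float, tuple[float, float]]:
    """Endpoint tortuosities computed two ways.

    ``fit_then_transform`` (the convention driving the headline numbers)
    regresses D_par on WM fraction and applies T = sqrt(d_free / D_par) at
    the endpoints; ``transform_then_fit`` regresses the per-subject
    tortuosities directly and reads the endpoints off that line.
    """
    if method == "fit_then_transform":
        reg = regress_dpar_on_wm(records, molecule, d_free=d_free, se_kind=se_kind)
        return reg.tortuosity_endpoints
    if method == "transform_then_fit":
        rows = [
            (r.wm_renorm, tortuosity(d_free, min(r.fits[molecule].d_par, d_free)))
            for r in records
            if molecule in r.fits and r.fits[molecule].d_par > 0
        ]
        if len(rows) < 3:
            raise ValueError("regression needs at least 3 subjects with valid fits")
        x = np.array([r[0] for r in rows])
        y = np.array([r[1] for r in rows])
        if np.ptp(x) == 0:
            raise ValueError("degenerate design: all WM fractions identical")
        _, est, se = _ols_endpoints(x, y, se_kind)
        return {0.0: (float(est[0]), float(se[0])), 100.0: (float(est[1]), float(se[1]))}
    raise ValueError("method must be 'fit_then_transform' or 'transform_then_fit'")


def group_compare(
    group_a: Mapping[str, Sequence[float]],
    group_b: Mapping[str, Sequence[float]],
    correction: str = "benjamini_hochberg",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-tests per metric with multiple-comparison correction.

    ``group_a`` / ``group_b`` map metric names to per-subject values (each
    group needs n >= 2 per metric).  Benjamini-Hochberg adjusts across the
    whole metric family at FDR ``alpha``; Bonferroni divides ``alpha`` by
    the family size (e.g. alpha 0.05 over 4 regressions -> threshold 0.0125).
    """
    metrics = list(group_a)
    if set(metrics) != set(group_b):
        raise ValueError("both groups must provide the same metrics")
    rows = []
    for m in metrics:
        a = np.asarray(group_a[m], dtype=float)
        b = np.asarray(group_b[m], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"metric {m!r}: each group needs n >= 2")
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((m, a.mean(), b.mean(), float(t), float(p)))
    df = pd.DataFrame(
        rows, columns=["metric", "mean_a", "mean_b", "t_stat", "p_raw"]
    )
    method = {"benjamini_hochberg": "fdr_bh", "bonferroni": "bonferroni"}.get(correction)
    if method is None:
        raise ValueError("correction must be 'benjamini_hochberg' or 'bonferroni'")
    reject, p_adj, _, _ = multipletests(df["p_raw"], alpha=alpha, method=method)
    df["p_adjusted"] = p_adj
    df["significant"] = reject
    df.attrs["correction"] = correction
    df.attrs["alpha"] = alpha
    df.attrs["per_test_threshold"] = (
        alpha / len(metrics) if correction == "bonferroni" else None
    )
    return df
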