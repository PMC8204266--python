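"""Synthetic DDES acquisition schemes, noisy signal tables, and cohorts.

This module emulates the study conditions of an angular DDE spectroscopy
experiment: three orthogonal encoding planes, eight equally spaced
inter-encoding angles, alternating gradient polarities, block-wise b values
with a non-diffusion-weighted (b = 0) acquisition per average, Gaussian (or
Rician) noise at a stated SNR, and multiplicative polarity cross-terms that
the downstream geometric-mean correction removes exactly.

Defaults reproduce the stored-acquisition bookkeeping of the emulated
protocol: the metabolite scheme (b = {0, 7199} s/mm^2, 6 averages) has 294
records and each single-b water block (2 averages) has 98.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .forward_model import (
    AxisymmetricTensor,
    Compartment,
    CompartmentMixture,
    OrientationSet,
    encoding_plane,
    mixture_signal_curve,
    powder_signal_curve,
    uniform_orientations,
)

__all__ = [
    "THETA_GRID",
    "TIMING_MS",
    "METABOLITE_B",
    "WATER_B",
    "AcquisitionScheme",
    "SignalTable",
    "build_scheme",
    "generate_dataset",
    "add_noise",
    "MoleculeParams",
    "CohortSpec",
    "SyntheticSubject",
    "generate_cohort",
    "DEFAULT_TISSUE_FRACTIONS",
    "DEFAULT_MOLECULES",
]

#: Second-encoding angles (degrees): 8 equally spaced steps from 0.
THETA_GRID = tuple(float(t) for t in range(0, 360, 45))

#: Sequence timing metadata in ms (bipolar DDE: single lobe delta/2 = 15.5).
TIMING_MS = {
    "delta1": 31.0,
    "delta2": 31.0,
    "tau1": 10.0,
    "tau2": 10.0,
    "Delta1": 45.0,
    "Delta2": 45.0,
    "t_m": 5.3,
}

METABOLITE_B = (0.0, 7199.0)
WATER_B = (0.0, 918.0, 2066.0, 4050.0, 7199.0)

_COLUMNS = ["b_svmm2", "plane", "theta_deg", "polarity", "repeat"]


@dataclass
class AcquisitionScheme:
    """Condition list of one DDES protocol plus timing metadata.

    ``records`` holds one row per stored acquisition with columns
    ``b_svmm2`` (s/mm^2), ``plane`` (1-3; 0 for b = 0), ``theta_deg``,
    ``polarity`` ('+'/'-'; '+' for b = 0) and ``repeat``.
    """

    records: pd.DataFrame
    b_values: tuple[float, ...]
    n_averages: int
    timing: Mapping[str, float] = field(default_factory=lambda: dict(TIMING_MS))

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def nonzero_b(self) -> tuple[float, ...]:
        return tuple(b for b in self.b_values if b > 0)


def build_scheme(
    mode: str | None = None,
    b_values: Sequence[float] | None = None,
    n_averages: int | None = None,
) -> AcquisitionScheme:
    """Build the stored-acquisition list of a DDES protocol.

    One block per nonzero b value; each block contains, per average, one
    b = 0 record plus 3 planes x 8 angles x 2 polarities of DW records,
    i.e. (3*8*2 + 1) * n_averages records per block.

    ``mode="metabolite"`` defaults to b = {0, 7199} with 6 averages (294
    records); ``mode="water"`` defaults to b = {0, 918, 2066, 4050, 7199}
    with 2 averages (4 blocks of 98 records).
    """
    if mode == "metabolite":
        b_values = METABOLITE_B if b_values is None else tuple(b_values)
        n_averages = 6 if n_averages is None else n_averages
    elif mode == "water":
        b_values = WATER_B if b_values is None else tuple(b_values)
        n_averages = 2 if n_averages is None else n_averages
    elif mode is None:
        if b_values is None or n_averages is None:
            raise ValueError("without a mode, b_values and n_averages are required")
        b_values = tuple(b_values)
    else:
        raise ValueError(f"mode must be 'metabolite', 'water' or None, got {mode!r}")
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    b_values = tuple(sorted(float(b) for b in b_values))
    if not b_values:
        raise ValueError("b_values must be nonempty")
    if any(b < 0 for b in b_values):
        raise ValueError("b values must be >= 0")

    rows: list[tuple] = []
    b0_repeat = 0
    for b in b_values:
        if b == 0:
            continue
        for rep in range(1, n_averages + 1):
            b0_repeat += 1
            rows.append((0.0, 0, 0.0, "+", b0_repeat))
            for plane in (1, 2, 3):
                for theta in THETA_GRID:
                    for pol in ("+", "-"):
                        rows.append((b, plane, theta, pol, rep))
    if not rows:
        # b = 0 only: one record per average
        rows = [(0.0, 0, 0.0, "+", rep) for rep in range(1, n_averages + 1)]
    records = pd.DataFrame(rows, columns=_COLUMNS)
    return AcquisitionScheme(records=records, b_values=b_values, n_averages=n_averages)


@dataclass
class SignalTable:
    """Measured or simulated amplitudes keyed by acquisition condition.

    ``data`` has the scheme columns plus ``amplitude`` (arbitrary units);
    ``meta`` records the substrate description, SNR, cross-term scale and seed.
    """

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        """Write the table as CSV plus a .json metadata sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        self.data.to_csv(path, index=False)
        path.with_suffix(".json").write_text(
            json.dumps(self.meta, indent=2, default=str) + "\n"
        )

    @classmethod
    def read_csv(cls, path, meta: dict | None = None) -> "SignalTable":
        import json
        from pathlib import Path

        path = Path(path)
        sidecar = path.with_suffix(".json")
        if meta is None and sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(pd.read_csv(path), meta or {})


def _noiseless_amplitudes(
    substrate,
    scheme: AcquisitionScheme,
    orientations: OrientationSet,
    s0: float,
    variant: str,
) -> np.ndarray:
    df = scheme.records
    amp = np.full(len(df), s0, dtype=float)
    if isinstance(substrate, AxisymmetricTensor):
        curve = lambda b, th, plane: powder_signal_curve(
            substrate, orientations, b, th, plane, s0, variant
        )
    elif isinstance(substrate, CompartmentMixture):
        curve = lambda b, th, plane: mixture_signal_curve(
            substrate, orientations, b, th, plane, s0, variant
        )
    else:
        raise TypeError(
            "substrate must be an AxisymmetricTensor or CompartmentMixture"
        )
    dw = df["b_svmm2"] > 0
    for k in (1, 2, 3):
        sel = dw & (df["plane"] == k)
        if not sel.any():
            continue
        amp[sel.to_numpy()] = curve(
            df.loc[sel, "b_svmm2"].to_numpy(),
            df.loc[sel, "theta_deg"].to_numpy(),
            encoding_plane(k),
        )
    return amp


def add_noise(
    amplitudes: np.ndarray,
    sigma: float,
    noise_model: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply measurement noise of standard deviation ``sigma`` per record.

    ``gaussian`` adds real-channel noise; ``rician`` takes the magnitude of
    the complex signal with independent Gaussian noise on both channels.
    """
    if sigma == 0:
        return amplitudes
    if noise_model == "gaussian":
        return amplitudes + rng.normal(0.0, sigma, size=amplitudes.shape)
    if noise_model == "rician":
        re = amplitudes + rng.normal(0.0, sigma, size=amplitudes.shape)
        im = rng.normal(0.0, sigma, size=amplitudes.shape)
        return np.hypot(re, im)
    raise ValueError(f"noise_model must be 'gaussian' or 'rician', got {noise_model!r}")


def generate_dataset(
    substrate,
    scheme: AcquisitionScheme,
    snr: float = math.inf,
    cross_term_scale: float = 0.0,
    noise_model: str = "gaussian",
    seed: int | None = None,
    s0: float = 1.0,
    orientations: OrientationSet | None = None,
    variant: str = "no_cross_term",
) -> SignalTable:
    """Simulate one noisy DDES dataset for a substrate under a scheme.

    The noiseless mean comes from the forward model (``s0`` at b = 0).
    Each DW condition (b, plane, theta) receives one multiplicative
    cross-term factor exp(+c) / exp(-c) on its '+' / '-' polarity records,
    with c ~ Normal(0, cross_term_scale); the polarity geometric mean
    cancels these exactly.  Noise sd is ``s0 / snr`` per stored acquisition
    (SNR is defined against the b = 0 amplitude of a single acquisition).
    """
    if not (snr > 0):
        raise ValueError("snr must be > 0 (may be inf)")
    if cross_term_scale < 0:
        raise ValueError("cross_term_scale must be >= 0")
    df = scheme.records
    if not (df["b_svmm2"] == 0).any():
        raise ValueError(
            "scheme has no b = 0 record; downstream normalization is impossible"
        )
    if orientations is None:
        orientations = uniform_orientations(256)
    rng = np.random.default_rng(seed)

    amp = _noiseless_amplitudes(substrate, scheme, orientations, s0, variant)

    if cross_term_scale > 0:
        dw = df["b_svmm2"] > 0
        keys = df.loc[dw, ["b_svmm2", "plane", "theta_deg"]]
        uniq = keys.drop_duplicates().reset_index(drop=True)
        c = rng.normal(0.0, cross_term_scale, size=len(uniq))
        cmap = {tuple(row): c[i] for i, row in enumerate(uniq.to_numpy())}
        sign = np.where(df["polarity"] == "+", 1.0, -1.0)
        cs = np.array(
            [
                cmap[(b, p, t)] if bb else 0.0
                for b, p, t, bb in zip(
                    df["b_svmm2"], df["plane"], df["theta_deg"], dw
                )
            ]
        )
        amp = amp * np.exp(sign * cs)

    sigma = 0.0 if math.isinf(snr) else s0 / snr
    amp = add_noise(amp, sigma, noise_model, rng)

    out = df.copy()
    out["amplitude"] = amp
    meta = {
        "substrate": repr(substrate),
        "snr": snr,
        "cross_term_scale": cross_term_scale,
        "noise_model": noise_model,
        "seed": seed,
        "s0": s0,
        "variant": variant,
        "n_orientations": orientations.n,
    }
    return SignalTable(out, meta)


# ---------------------------------------------------------------------------
# Cohorts


#: Per-VOI GM/WM/CSF volume-fraction distributions (%, mean and sd) emulating
#: a parietal-WM box, an occipital-GM box, and a smaller GM-enriched box.
DEFAULT_TISSUE_FRACTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "PWM": {"gm": (15.1, 5.1), "wm": (82.8, 5.7), "csf": (2.1, 1.2)},
    "OGM": {"gm": (50.1, 7.9), "wm": (36.2, 15.1), "csf": (13.7, 9.1)},
    "sOGM": {"gm": (67.7, 4.5), "wm": (19.8, 3.9), "csf": (12.5, 6.4)},
}


@dataclass(frozen=True)
class MoleculeParams:
    """Pure-tissue intracellular tensor endpoints for one molecule.

    ``d_par_gm``/``d_par_wm`` are the axial diffusivities (um^2/ms) at 100%
    GM and 100% WM; per-subject truth interpolates linearly in the WM
    fraction of (GM + WM).  ``d_free`` is the free diffusivity at 37 C used
    for tortuosity.
    """

    name: str
    d_par_gm: float
    d_par_wm: float
    d_perp_gm: float = 0.0
    d_perp_wm: float = 0.0
    d_free: float | None = None


#: Water (high-b intracellular) and tNAA endpoints in um^2/ms.
DEFAULT_MOLECULES: tuple[MoleculeParams, ...] = (
    MoleculeParams("water", 0.97, 1.95, 0.14, 0.05, d_free=3.0),
    MoleculeParams("tNAA", 0.25, 0.51, 0.05, 0.05, d_free=0.78),
)


@dataclass
class CohortSpec:
    """Design of a synthetic cohort: group sizes, tissue-fraction
    distributions, per-molecule tensor endpoints, SNR and seed."""

    n_subjects: Mapping[str, int] = field(
        default_factory=lambda: {"PWM": 8, "OGM": 7, "sOGM": 4}
    )
    fractions: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_TISSUE_FRACTIONS
    )
    molecules: tuple[MoleculeParams, ...] = DEFAULT_MOLECULES
    snr: float = 35.0
    seed: int | None = None
    scheme: AcquisitionScheme | None = None  # default: metabolite protocol

    def __post_init__(self) -> None:
        total = sum(self.n_subjects.values())
        if total < 3:
            raise ValueError("cohort needs at least 3 subjects for regression")
        for voi, dists in self.fractions.items():
            for tissue, (mean, sd) in dists.items():
                if not 0.0 <= mean <= 100.0:
                    raise ValueError(
                        f"fraction mean out of [0, 100] for {voi}/{tissue}"
                    )
                if sd < 0:
                    raise ValueError("fraction sd must be >= 0")


def cohort_spec_from_yaml(path) -> "CohortSpec":
    """Load a CohortSpec from YAML (scheme falls back to the metabolite default)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    molecules = tuple(
        MoleculeParams(**m) for m in raw.get("molecules", [])
    ) or DEFAULT_MOLECULES
    fractions = {
        voi: {t: tuple(v) for t, v in dists.items()}
        for voi, dists in raw.get("fractions", DEFAULT_TISSUE_FRACTIONS).items()
    }
    return CohortSpec(
        n_subjects=raw.get("n_subjects", {"PWM": 8, "OGM": 7, "sOGM": 4}),
        fractions=fractions,
        molecules=molecules,
        snr=raw.get("snr", 35.0),
        seed=raw.get("seed"),
    )


@dataclass
class SyntheticSubject:
    subject_id: str
    voi: str
    gm: float
    wm: float
    csf: float
    true_params: dict[str, tuple[float, float]]
    tables: dict[str, SignalTable]


def generate_cohort(
    spec: CohortSpec,
    orientations: OrientationSet | None = None,
    variant: str = "no_cross_term",
) -> list[SyntheticSubject]:
    """Draw per-subject tissue fractions and simulate one dataset per molecule.

    Fractions are drawn from the per-VOI normal distributions, clipped at 0
    and renormalized to sum to 100.  The per-subject true tensor of each
    molecule interpolates linearly between the pure-GM and pure-WM endpoints
    in w = WM / (GM + WM).  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    if orientations is None:
        orientations = uniform_orientations(256)
    scheme = spec.scheme if spec.scheme is not None else build_scheme("metabolite")

    subjects: list[SyntheticSubject] = []
    for voi, n in spec.n_subjects.items():
        dists = spec.fractions[voi]
        for i in range(n):
            while True:
                raw = np.array(
                    [
                        max(0.0, rng.normal(*dists["gm"])),
                        max(0.0, rng.normal(*dists["wm"])),
                        max(0.0, rng.normal(*dists["csf"])),
                    ]
                )
                if raw.sum() > 0 and raw[:2].sum() > 0:
                    break
            gm, wm, csf = 100.0 * raw / raw.sum()
            w = wm / (gm + wm)
            true_params: dict[str, tuple[float, float]] = {}
            tables: dict[str, SignalTable] = {}
            for mol in spec.molecules:
                d_par = mol.d_par_gm + (mol.d_par_wm - mol.d_par_gm) * w
                d_perp = mol.d_perp_gm + (mol.d_perp_wm - mol.d_perp_gm) * w
                true_params[mol.name] = (d_par, d_perp)
                tables[mol.name] = generate_dataset(
                    AxisymmetricTensor(d_par, d_perp),
                    scheme,
                    snr=spec.snr,
                    seed=int(rng.integers(2**31)),
                    orientations=orientations,
                    variant=variant,
                )
            subjects.append(
                SyntheticSubject(
                    subject_id=f"{voi}-{i + 1:02d}",
                    voi=voi,
                    gm=gm,
                    wm=wm,
                    csf=csf,
                    true_params=true_params,
                    tables=tables,
                )
            )
    return subjects
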