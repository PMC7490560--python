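"""DULIP (dual luminescence-based co-immunoprecipitation) quantification.

A *Renilla*-tagged bait and firefly-tagged prey are co-expressed; lysate
luminescence ("input") measures expression, luminescence retained on the
IgG-captured bait ("bound") measures co-precipitation.  The normalised
interaction ratio (NIR) corrects the bound firefly/Renilla ratio for
expression, and the corrected NIR (cNIR) further divides by a negative
control pair.  A saturation-binding fit over wells yields an assay-unit
dissociation constant, which is placed on the molar scale by a log-log
regression against FCCS K_d values from the same pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DulipWell",
    "DulipKdEstimate",
    "ScalingModel",
    "MutantEffectTest",
    "compute_nir",
    "compute_cnir",
    "estimate_dulip_kd",
    "fit_cross_platform_scaling",
    "apply_scaling",
    "invert_scaling",
    "test_mutant_effect",
    "average_triplicates",
    "wells_to_frame",
    "wells_from_frame",
]


@dataclass(frozen=True)
class DulipWell:
    """One assay well: the luminescence quadruple plus design labels."""

    pair_id: str
    fl_input: float
    rl_input: float
    fl_bound: float
    rl_bound: float
    replicate_id: int = 0
    experiment_id: int = 0
    cell_line: str = "WT"
    condition: str = "wt_bait"

    def __post_init__(self) -> None:
        for name in ("fl_input", "rl_input", "fl_bound", "rl_bound"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def compute_nir(well: DulipWell) -> float:
    """Normalised interaction ratio: (bound FL/RL) / (input FL/RL).

    1 means no enrichment of prey on the captured bait relative to input.
    Wells with zero denominators are excluded upstream; here they raise.
    """
    if well.rl_bound <= 0 or well.rl_input <= 0 or well.fl_input <= 0:
        raise ValueError("rl_bound, rl_input and fl_input must be positive")
    return (well.fl_bound / well.rl_bound) / (well.fl_input / well.rl_input)


def compute_cnir(nir_sample: float, nir_negative_control: float) -> float:
    """Corrected NIR: sample NIR relative to a negative-control pair."""
    if nir_negative_control <= 0:
        raise ValueError("negative-control NIR must be positive")
    return nir_sample / nir_negative_control


@dataclass(frozen=True)
class DulipKdEstimate:
    """Saturation-fit dissociation constant in assay units (+ scaled nM)."""

    kd_dulip: float
    sem: float
    n: int
    scaled_kd_nM: float | None = None

    def __post_init__(self) -> None:
        if not self.kd_dulip > 0:
            raise ValueError("kd_dulip must be positive")
        if self.n < 3:
            raise ValueError("need n >= 3 wells")


_SENTINEL = math.inf


def estimate_dulip_kd(
    wells: Sequence[DulipWell],
    alpha: float = 1.0,
    beta: float = 1.0,
    min_wells: int = 3,
    min_range_fold: float = 5.0,
) -> DulipKdEstimate | None:
    """Saturation-binding fit of capture-normalised bound signal over wells.

    Per well the bound-fraction proxy is ``b = fl_bound / (alpha * rl_bound)``
    (``alpha`` converts captured-bait Renilla luminescence to the firefly
    scale of a fully-bound bait) and the free-prey signal is
    ``S_free = fl_input - beta * fl_bound`` (``beta`` converts bound firefly
    to input-firefly units for the depletion correction).  ``b`` is fitted to
    ``S_free / (S_free + K)``; K is returned with its SEM from the fit
    covariance.  Wells must span at least ``min_range_fold`` in free-prey
    signal.  If there is no saturation trend (all bound signal at background),
    ``None`` is returned as the unbounded-K sentinel.
    """
    if len(wells) < min_wells:
        raise ValueError(f"need >= {min_wells} wells, got {len(wells)}")
    b = np.array([w.fl_bound / (alpha * w.rl_bound) for w in wells])
    s_free = np.array([w.fl_input - beta * w.fl_bound for w in wells])
    s_free = np.clip(s_free, 0.0, None)
    pos = s_free[s_free > 0]
    if pos.size == 0 or pos.max() / pos.min() < min_range_fold:
        raise ValueError(
            f"free-prey signal must span >= {min_range_fold}-fold; "
            f"got {pos.max() / pos.min() if pos.size else 0:.2f}"
        )
    if np.all(b < 1e-6):
        return None  # bound signal indistinguishable from background

    def model(s: np.ndarray, log10_k: float) -> np.ndarray:
        return s / (s + 10.0**log10_k)

    x0 = math.log10(np.median(pos))
    try:
        popt, pcov = optimize.curve_fit(model, s_free, b, p0=[x0], maxfev=2000)
    except RuntimeError:
        return None
    log10_k = float(popt[0])
    if log10_k > math.log10(pos.max()) + 4:
        return None  # no curvature within the sampled range: K unbounded
    k = 10.0**log10_k
    # delta method: sd(K) = K ln(10) sd(log10 K)
    sem = k * math.log(10.0) * math.sqrt(max(float(pcov[0, 0]), 0.0))
    return DulipKdEstimate(kd_dulip=k, sem=sem, n=len(wells))


@dataclass(frozen=True)
class ScalingModel:
    """log10-scale linear map from DULIP assay-unit K to molar FCCS K_d.

    ``log10(kd_nM) = slope * log10(kd_dulip) + intercept``.
    """

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    scale: str = "log10"


def fit_cross_platform_scaling(
    pairs: Sequence[tuple[float, float]]
) -> ScalingModel:
    """OLS of log10 FCCS K_d (Y) on log10 DULIP K (X) across shared pairs.

    Returns slope, intercept, Pearson r and the two-sided p-value for r.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 (dulip, fccs) pairs")
    arr = np.asarray(pairs, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("all K_d values must be positive")
    x = np.log10(arr[:, 0])
    y = np.log10(arr[:, 1])
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all DULIP K values identical")
    res = stats.linregress(x, y)
    return ScalingModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=len(pairs),
    )


def apply_scaling(model: ScalingModel, kd_dulip: float) -> float:
    """Scale an assay-unit DULIP K onto the molar (nM) axis."""
    if kd_dulip <= 0:
        raise ValueError("kd_dulip must be positive")
    return 10.0 ** (model.slope * math.log10(kd_dulip) + model.intercept)


def invert_scaling(model: ScalingModel, kd_nM: float) -> float:
    """Inverse map (nM -> assay units); apply ∘ invert is the identity."""
    if kd_nM <= 0:
        raise ValueError("kd_nM must be positive")
    if model.slope == 0:
        raise ValueError("slope 0 cannot be inverted")
    return 10.0 ** ((math.log10(kd_nM) - model.intercept) / model.slope)


@dataclass(frozen=True)
class MutantEffectTest:
    """One-sample t-test of log2 cNIR (mutant vs WT bait) against zero."""

    t: float
    df: int
    p: float
    mean_log2: float
    degenerate: bool = False


def average_triplicates(cnir: pd.DataFrame, value_col: str = "cnir",
                        experiment_col: str = "experiment_id") -> np.ndarray:
    """Mean cNIR per independent experiment (triplicates averaged first)."""
    return cnir.groupby(experiment_col)[value_col].mean().to_numpy()


def test_mutant_effect(log2_cnir: Sequence[float]) -> MutantEffectTest:
    """Two-sided one-sample t-test of log2-transformed cNIRs against 0.

    Inputs are per-experiment means (one value per independent experiment).
    Zero-variance inputs are handled exactly: p = 1 when the common value is
    0, else p = 0 with the ``degenerate`` flag set.
    """
    x = np.asarray(log2_cnir, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 independent-experiment values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    df = x.size - 1
    if sd == 0.0:
        if mean == 0.0:
            return MutantEffectTest(t=0.0, df=df, p=1.0, mean_log2=0.0, degenerate=True)
        return MutantEffectTest(t=math.copysign(math.inf, mean), df=df, p=0.0,
                                mean_log2=mean, degenerate=True)
    t = mean / (sd / math.sqrt(x.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return MutantEffectTest(t=float(t), df=df, p=float(p), mean_log2=mean)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_WELL_COLUMNS = [
    "pair_id", "fl_input", "rl_input", "fl_bound", "rl_bound",
    "replicate_id", "experiment_id", "cell_line", "condition",
]


def wells_to_frame(wells: Sequence[DulipWell]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(w, c) for c in _WELL_COLUMNS} for w in wells])


def wells_from_frame(df: pd.DataFrame) -> list[DulipWell]:
    missing = set(_WELL_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"missing DULIP well columns: {sorted(missing)}")
    return [
        DulipWell(**{c: row[c] for c in _WELL_COLUMNS if c in df.columns})
        for _, row in df.iterrows()
    ]
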