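"""Dual-colour fluorescence cross-correlation spectroscopy (FCCS) quantification.

This module turns photon-count traces or exported correlation curves into
live-cell dissociation constants:

1. analytic auto/cross-correlation models (two-component 3D diffusion with an
   optional triplet term),
2. a multi-tau correlator for raw photon traces,
3. weighted Levenberg-Marquardt-style curve fitting,
4. conversion of zero-lag amplitudes to molar concentrations and bound
   fractions through the calibrated effective confocal volume, and
5. binding-isotherm fitting of the per-cell bound fractions, in both labelling
   orientations, with bootstrap confidence intervals on the mean K_d.

Lower G(0) means more molecules in the focus; a cross-correlation amplitude
only arises from co-diffusing (complexed) green/red molecules, which is what
makes the method a live-cell affinity assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "N_AVOGADRO",
    "ConfocalVolume",
    "CorrelationCurve",
    "DiffusionFitParams",
    "CellMeasurement",
    "KdFit",
    "QcThresholds",
    "QcResult",
    "CorrelationNormalizationError",
    "eval_autocorr_model",
    "eval_crosscorr_model",
    "multitau_lag_ladder",
    "multitau_correlate",
    "fit_correlation_curve",
    "amplitudes_to_concentrations",
    "concentrations_to_amplitudes",
    "qc_cell",
    "fit_kd_isotherm",
]

#: Avogadro constant (1/mol), fixed physical constant used for amplitude ->
#: concentration conversion.
N_AVOGADRO = 6.02214076e23

CHANNELS = ("green_auto", "red_auto", "cross")


class CorrelationNormalizationError(ValueError):
    """Raised when a trace has zero mean and G(tau) cannot be normalised."""


@dataclass(frozen=True)
class ConfocalVolume:
    """Calibrated detection volume of the confocal setup.

    Parameters
    ----------
    v_eff_fL:
        Effective volume in femtolitres; converts particle numbers to molar
        concentrations via ``c = N / (V_eff * N_A)``.
    s:
        Structure parameter, the axial/lateral 1/e^2 radius ratio (> 1).
    w0_um:
        Optional lateral 1/e^2 beam-waist radius in micrometres; only needed
        by the Brownian-dynamics trace simulator and for ``tau_D = w0^2/4D``
        sanity checks.
    """

    v_eff_fL: float
    s: float
    w0_um: float | None = None

    def __post_init__(self) -> None:
        if not self.v_eff_fL > 0:
            raise ValueError(f"v_eff_fL must be > 0, got {self.v_eff_fL}")
        if not self.s > 1:
            raise ValueError(f"structure parameter s must be > 1, got {self.s}")

    @property
    def v_eff_L(self) -> float:
        return self.v_eff_fL * 1e-15

    def particles_to_nM(self, n_particles: float) -> float:
        """Mean particle number in V_eff -> concentration in nM."""
        return 1e9 * n_particles / (self.v_eff_L * N_AVOGADRO)

    def nM_to_particles(self, c_nM: float) -> float:
        return c_nM * 1e-9 * self.v_eff_L * N_AVOGADRO


@dataclass
class CorrelationCurve:
    """One correlation curve G(tau) for a single detection channel."""

    channel: str
    lags: np.ndarray
    g: np.ndarray
    sem: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if not (len(self.lags) == len(self.g) == len(self.sem)):
            raise ValueError("lags, g and sem must have equal length")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.sem < 0):
            raise ValueError("sem must be non-negative")

    def __len__(self) -> int:
        return len(self.lags)


@dataclass
class DiffusionFitParams:
    """Parameters of the two-component 3D diffusion model with triplet term.

    ``n_particles`` is the mean number of molecules in the effective volume;
    the triplet-free zero-lag amplitude is ``1/n_particles``.  Component
    fractions satisfy ``f_fast + f_slow == 1`` and diffusion times are ordered
    ``tau_d_fast <= tau_d_slow``.
    """

    n_particles: float
    f_fast: float = 1.0
    tau_d_fast: float = 1e-3
    tau_d_slow: float = 1e-2
    triplet_fraction: float = 0.0
    tau_triplet: float = 5e-6
    offset: float = 0.0
    covariance: np.ndarray | None = None
    converged: bool = True
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.n_particles > 0:
            raise ValueError("n_particles must be > 0")
        if not (0.0 <= self.f_fast <= 1.0):
            raise ValueError("f_fast must lie in [0, 1]")
        if self.tau_d_fast <= 0 or self.tau_d_slow <= 0:
            raise ValueError("diffusion times must be positive")
        if self.tau_d_fast > self.tau_d_slow:
            raise ValueError("tau_d_fast must be <= tau_d_slow")
        if not (0.0 <= self.triplet_fraction < 1.0):
            raise ValueError("triplet_fraction must lie in [0, 1)")
        if self.tau_triplet <= 0:
            raise ValueError("tau_triplet must be positive")

    @property
    def f_slow(self) -> float:
        return 1.0 - self.f_fast

    @property
    def g0(self) -> float:
        """Triplet-free zero-lag amplitude 1/N."""
        return 1.0 / self.n_particles

    def without_triplet(self) -> "DiffusionFitParams":
        return replace(self, triplet_fraction=0.0)


def _diffusion_term(lags: np.ndarray, params: DiffusionFitParams, s: float) -> np.ndarray:
    tau = np.asarray(lags, dtype=float)
    out = np.zeros_like(tau)
    for f, tau_d in ((params.f_fast, params.tau_d_fast), (params.f_slow, params.tau_d_slow)):
        if f == 0.0:
            continue
        x = tau / tau_d
        out += f / ((1.0 + x) * np.sqrt(1.0 + x / (s * s)))
    return out


def eval_autocorr_model(
    lags: np.ndarray, params: DiffusionFitParams, volume: ConfocalVolume
) -> np.ndarray:
    """Two-component 3D diffusion autocorrelation with triplet correction.

    G(tau) = offset + [1 + T/(1-T) * exp(-tau/tau_T)] * (1/N) *
             sum_i f_i * (1 + tau/tau_Di)^-1 * (1 + tau/(s^2 tau_Di))^-1/2
    """
    tau = np.asarray(lags, dtype=float)
    T = params.triplet_fraction
    triplet = 1.0 + (T / (1.0 - T)) * np.exp(-tau / params.tau_triplet)
    return params.offset + triplet * params.g0 * _diffusion_term(tau, params, volume.s)


def eval_crosscorr_model(
    lags: np.ndarray, params: DiffusionFitParams, volume: ConfocalVolume
) -> np.ndarray:
    """Cross-correlation model: same diffusion law, triplet term forced off.

    Triplet blinking is uncorrelated between the two fluorophores, so the
    cross-correlation is fitted without the triplet factor.
    """
    return eval_autocorr_model(lags, params.without_triplet(), volume)


# ---------------------------------------------------------------------------
# Multi-tau correlator
# ---------------------------------------------------------------------------


def multitau_lag_ladder(n: int, m_per_level: int = 8, n_levels: int | None = None) -> np.ndarray:
    """Integer lags of a multi-tau schedule: dense up to ``m_per_level``, then
    the spacing doubles each level (successive binning of the time axis).

    Lags are capped at ``n // 4`` so each estimate still averages over at
    least three quarters of the trace.
    """
    if m_per_level < 2 or m_per_level % 2:
        raise ValueError("m_per_level must be an even integer >= 2")
    max_lag = max(1, n // 4)
    lags: list[int] = list(range(1, m_per_level + 1))
    level = 1
    while lags[-1] < max_lag and (n_levels is None or level <= n_levels):
        step = 2**level
        start = lags[-1] + step
        stop = m_per_level * 2**level
        lags.extend(range(start, stop + 1, step))
        level += 1
    return np.array([k for k in lags if k <= max_lag], dtype=int)


def multitau_correlate(
    trace_a: np.ndarray,
    trace_b: np.ndarray | None = None,
    m_per_level: int = 8,
    n_levels: int | None = None,
    dt: float = 1.0,
    channel: str | None = None,
) -> CorrelationCurve:
    """Normalised fluctuation correlation on a multi-tau lag ladder.

    G(k) = <da(t) db(t+k)> / (<a><b>) with global-mean fluctuations,
    averaged over the n-k overlapping samples.  The lag schedule follows the
    classical multi-tau ladder; each lag value is the exact single-lag
    correlator (computed by FFT), so coarse lags are log-spaced without the
    triangular smoothing that product-of-binned-traces estimators introduce.

    ``trace_b=None`` (or the same array) gives the autocorrelation.
    """
    a = np.asarray(trace_a, dtype=float)
    auto = trace_b is None or trace_b is trace_a
    b = a if auto else np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be one-dimensional and of equal length")
    n = len(a)
    if n < 2 * m_per_level:
        raise ValueError(f"trace too short: need >= {2 * m_per_level} bins, got {n}")
    mean_a = a.mean()
    mean_b = b.mean()
    if mean_a == 0.0 or mean_b == 0.0:
        raise CorrelationNormalizationError(
            "trace mean is zero; fluctuation correlation cannot be normalised"
        )
    lags = multitau_lag_ladder(n, m_per_level=m_per_level, n_levels=n_levels)
    da = a - mean_a
    db = b - mean_b
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fa = np.fft.rfft(da, nfft)
    fb = np.fft.rfft(db, nfft)
    # corr[k] = sum_t da[t] * db[t + k]
    corr = np.fft.irfft(np.conj(fa) * fb, nfft)[: n]
    g = corr[lags] / ((n - lags) * mean_a * mean_b)
    if channel is None:
        channel = "green_auto" if auto else "cross"
    return CorrelationCurve(
        channel=channel,
        lags=lags * float(dt),
        g=g,
        sem=np.zeros_like(g),
        meta={"n_bins": n, "dt": float(dt), "mean_a": mean_a, "mean_b": mean_b},
    )


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------

_PARAM_ORDER_2C = ("n_particles", "f_fast", "tau_d_fast", "tau_d_slow",
                   "triplet_fraction", "tau_triplet", "offset")
_PARAM_ORDER_1C = ("n_particles", "tau_d_fast", "triplet_fraction", "tau_triplet", "offset")


def _pack(params: DiffusionFitParams, names: Sequence[str]) -> np.ndarray:
    return np.array([getattr(params, k) for k in names], dtype=float)


def _unpack(x: np.ndarray, names: Sequence[str], with_triplet: bool) -> DiffusionFitParams:
    d = dict(zip(names, x))
    if "f_fast" not in d:
        d["f_fast"] = 1.0
        d["tau_d_slow"] = d["tau_d_fast"]
    if not with_triplet:
        d["triplet_fraction"] = 0.0
        d.setdefault("tau_triplet", 5e-6)
    # keep components ordered fast <= slow; swap if the optimiser crossed them
    if d["tau_d_fast"] > d["tau_d_slow"]:
        d["tau_d_fast"], d["tau_d_slow"] = d["tau_d_slow"], d["tau_d_fast"]
        d["f_fast"] = 1.0 - d["f_fast"]
    d["f_fast"] = float(np.clip(d["f_fast"], 0.0, 1.0))
    d["triplet_fraction"] = float(np.clip(d["triplet_fraction"], 0.0, 1.0 - 1e-12))
    return DiffusionFitParams(**d)


def _default_init(curve: CorrelationCurve, with_triplet: bool) -> DiffusionFitParams:
    """Heuristic initialisation: amplitude from the 3 smallest lags, diffusion
    time from the half-amplitude lag, T=0.1 / tau_T=5 us when fitted."""
    g = curve.g
    g0 = float(np.mean(g[:3]))
    offset0 = float(np.mean(g[-max(3, len(g) // 20):]))
    amp = g0 - offset0
    if not np.isfinite(amp) or amp <= 0:
        amp = max(abs(g0), 1e-6)
        offset0 = 0.0
    half = offset0 + amp / 2.0
    below = np.nonzero(g <= half)[0]
    tau_half = float(curve.lags[below[0]]) if below.size else float(curve.lags[len(curve) // 2])
    return DiffusionFitParams(
        n_particles=1.0 / amp,
        f_fast=0.6,
        tau_d_fast=tau_half / 4.0,
        tau_d_slow=tau_half * 4.0,
        triplet_fraction=0.1 if with_triplet else 0.0,
        tau_triplet=5e-6,
        offset=offset0,
    )


def fit_correlation_curve(
    curve: CorrelationCurve,
    model: str = "auto",
    init: DiffusionFitParams | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    volume: ConfocalVolume | None = None,
    n_components: int = 2,
    max_restarts: int = 6,
    gtol: float = 1e-10,
) -> DiffusionFitParams:
    """Weighted least-squares fit of a correlation curve.

    ``model='auto'`` fits the two-component diffusion model with triplet term,
    ``model='cross'`` without it.  Weights are 1/sem^2 where all sem > 0, else
    the fit is unweighted.  Non-convergence is flagged on the result rather
    than raised, as is a singular parameter covariance.

    A few restarts from perturbed initialisations are attempted when the first
    solution leaves a large residual (guards against the fast/slow-component
    local minima of the two-component model).
    """
    if model not in ("auto", "cross"):
        raise ValueError("model must be 'auto' or 'cross'")
    if volume is None:
        volume = ConfocalVolume(v_eff_fL=curve.meta.get("v_eff_fL", 1.0),
                                s=curve.meta.get("s", 5.0))
    with_triplet = model == "auto"
    names = list(_PARAM_ORDER_2C if n_components == 2 else _PARAM_ORDER_1C)
    if not with_triplet:
        names = [k for k in names if k not in ("triplet_fraction", "tau_triplet")]
    n_free = len(names)
    if len(curve) < 8 * n_free:
        raise ValueError(
            f"curve has {len(curve)} lags; need >= {8 * n_free} for {n_free} free parameters"
        )

    weighted = bool(np.all(curve.sem > 0))
    w = 1.0 / curve.sem if weighted else np.ones_like(curve.g)

    lag_lo, lag_hi = curve.lags[0], curve.lags[-1]
    default_bounds = {
        "n_particles": (1e-9, 1e12),
        "f_fast": (0.0, 1.0),
        "tau_d_fast": (lag_lo / 100.0, lag_hi * 100.0),
        "tau_d_slow": (lag_lo / 100.0, lag_hi * 100.0),
        "triplet_fraction": (0.0, 0.8),
        "tau_triplet": (lag_lo / 100.0, lag_hi),
        "offset": (-1.0, 1.0),
    }
    if bounds:
        default_bounds.update(bounds)
    lo = np.array([default_bounds[k][0] for k in names])
    hi = np.array([default_bounds[k][1] for k in names])

    def residuals(x: np.ndarray) -> np.ndarray:
        p = _unpack(x, names, with_triplet)
        return (eval_autocorr_model(curve.lags, p, volume) - curve.g) * w

    base = init if init is not None else _default_init(curve, with_triplet)
    starts = [base]
    tau_geo = math.sqrt(base.tau_d_fast * base.tau_d_slow)
    for ff, rf, rs in ((0.5, 1.0, 1.0), (0.8, 0.1, 1.0), (0.3, 1.0, 10.0),
                       (0.5, 0.03, 1.0), (0.5, 1.0, 30.0), (0.9, 0.3, 3.0)):
        starts.append(replace(base, f_fast=ff,
                              tau_d_fast=min(tau_geo * rf, tau_geo),
                              tau_d_slow=max(tau_geo * rs, tau_geo)))

    g_scale = float(np.sum((curve.g * w) ** 2)) + 1e-300
    best = None
    for k, start in enumerate(starts[: max_restarts + 1]):
        x0 = np.clip(_pack(start, names), lo, hi)
        try:
            res = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=gtol, max_nfev=400 * n_free,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res
        # stop multi-starting once the fit is exact (noise-free data) or,
        # for sem-weighted fits, statistically adequate (reduced chi^2 < 3)
        dof = max(len(curve) - n_free, 1)
        if best.cost / g_scale < 1e-16 or (weighted and 2.0 * best.cost / dof < 3.0):
            break

    if best is None:
        raise RuntimeError("all fit attempts failed")

    params = _unpack(best.x, names, with_triplet)
    flags: list[str] = []
    # status 0 means the iteration budget ran out before any of the
    # optimiser's gradient/step criteria were met: no convergence claim.
    converged = bool(best.status > 0)
    if not converged:
        flags.append("max_iterations")
    # covariance from the Gauss-Newton approximation J'J
    dof = max(len(curve) - n_free, 1)
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj)
        if not weighted:
            cov *= 2.0 * best.cost / dof
        cov_full = cov
    except np.linalg.LinAlgError:
        cov_full = None
        flags.append("singular_covariance")
    return replace(params, covariance=cov_full, converged=converged, flags=tuple(flags))


# ---------------------------------------------------------------------------
# Amplitudes -> concentrations
# ---------------------------------------------------------------------------


@dataclass
class CellMeasurement:
    """Per-cell FCCS readout: amplitudes, concentrations and bound fractions."""

    g0_green: float
    g0_red: float
    g0_cross: float
    c_g_total: float
    c_r_total: float
    c_complex: float
    c_g_free: float
    c_r_free: float
    f_bound_green: float
    f_bound_red: float
    qc_pass: bool = True
    flags: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)


def amplitudes_to_concentrations(
    g0_green: float,
    g0_red: float,
    g0_cross: float,
    volume: ConfocalVolume,
    rel_tol: float = 1e-6,
) -> CellMeasurement:
    """Convert zero-lag amplitudes to nanomolar concentrations and fractions.

    c_total = 1/(V_eff N_A G_auto(0)) per channel and
    c_complex = G_cross(0)/(V_eff N_A G_green(0) G_red(0)); the bound fraction
    of the green species is G_cross(0)/G_red(0) (and symmetrically for red).
    Fractions are clipped to [0, 1] with a ``clipped`` flag; an apparent
    complex concentration exceeding the limiting total beyond ``rel_tol``
    raises an ``inconsistent`` flag and is clipped to the limiting total so
    mass balance is preserved.
    """
    if g0_green <= 0 or g0_red <= 0:
        raise ValueError("autocorrelation amplitudes must be positive")
    if g0_cross < 0:
        raise ValueError("cross-correlation amplitude must be non-negative")
    denom = volume.v_eff_L * N_AVOGADRO
    c_g_total = 1e9 / (denom * g0_green)
    c_r_total = 1e9 / (denom * g0_red)
    c_complex = 1e9 * g0_cross / (denom * g0_green * g0_red)
    flags: list[str] = []
    limit = min(c_g_total, c_r_total)
    if c_complex > limit * (1.0 + rel_tol):
        flags.append("inconsistent")
    if c_complex > limit:
        c_complex = limit
        flags.append("clipped")
    f_bound_green = g0_cross / g0_red
    f_bound_red = g0_cross / g0_green
    if f_bound_green > 1.0 or f_bound_red > 1.0:
        if "clipped" not in flags:
            flags.append("clipped")
    f_bound_green = float(np.clip(f_bound_green, 0.0, 1.0))
    f_bound_red = float(np.clip(f_bound_red, 0.0, 1.0))
    return CellMeasurement(
        g0_green=g0_green,
        g0_red=g0_red,
        g0_cross=g0_cross,
        c_g_total=c_g_total,
        c_r_total=c_r_total,
        c_complex=c_complex,
        c_g_free=c_g_total - c_complex,
        c_r_free=c_r_total - c_complex,
        f_bound_green=f_bound_green,
        f_bound_red=f_bound_red,
        flags=tuple(flags),
    )


def concentrations_to_amplitudes(
    c_g_total_nM: float, c_r_total_nM: float, c_complex_nM: float, volume: ConfocalVolume
) -> tuple[float, float, float]:
    """Inverse of :func:`amplitudes_to_concentrations` (used by simulators)."""
    n_g = volume.nM_to_particles(c_g_total_nM)
    n_r = volume.nM_to_particles(c_r_total_nM)
    g0_green = 1.0 / n_g
    g0_red = 1.0 / n_r
    g0_cross = volume.nM_to_particles(c_complex_nM) * g0_green * g0_red
    return g0_green, g0_red, g0_cross


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QcThresholds:
    """Per-cell inclusion thresholds; defaults follow ~1 kHz counts per
    molecule operating conditions with a 0.5 kHz floor."""

    min_cpm_kHz: float = 0.5
    require_convergence: bool = True


@dataclass
class QcResult:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # allows `if qc_cell(...):`
        return self.passed


def qc_cell(
    measurement: CellMeasurement,
    curves: Iterable[CorrelationCurve] = (),
    fits: Mapping[str, DiffusionFitParams] | None = None,
    thresholds: QcThresholds = QcThresholds(),
) -> QcResult:
    """Decide whether one cell enters the isotherm fit, with reason codes.

    Checks: positive autocorrelation amplitudes, counts-per-molecule above the
    threshold on every curve that reports one, and convergence of every
    supplied fit.
    """
    reasons: list[str] = []
    if measurement.g0_green <= 0 or measurement.g0_red <= 0:
        reasons.append("amplitude")
    for curve in curves:
        cpm = curve.meta.get("cpm_kHz")
        if cpm is not None and cpm < thresholds.min_cpm_kHz:
            reasons.append("cpm")
            break
    if thresholds.require_convergence and fits:
        if not all(f.converged for f in fits.values()):
            reasons.append("fit_convergence")
    if "inconsistent" in measurement.flags:
        reasons.append("inconsistent_amplitudes")
    passed = not reasons
    measurement.qc_pass = passed
    return QcResult(passed=passed, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# Binding isotherm
# ---------------------------------------------------------------------------


@dataclass
class KdFit:
    """Result of the two-orientation binding-isotherm fit."""

    kd_green_orientation: float
    kd_red_orientation: float
    kd_mean: float
    ci95: tuple[float, float]
    n_cells: int
    binder_flag: bool
    binder_threshold_nM: float = 10_000.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        lo, hi = self.ci95
        if not (lo <= self.kd_mean <= hi or math.isinf(self.kd_mean)):
            raise ValueError("ci95 must bracket kd_mean")


_LOG10_KD_RANGE = (-3.0, 9.0)
_MIN_SIGNAL = 1e-3  # bound fractions all below this -> non-binder sentinel


def _fit_single_orientation(f_bound: np.ndarray, c_free: np.ndarray) -> float:
    """Least-squares fit of f = c/(c + K) over cells; returns K in nM.

    One-dimensional in log10 K, solved by bounded scalar minimisation (fast
    enough to sit inside the bootstrap loop).
    """
    mask = np.isfinite(f_bound) & np.isfinite(c_free) & (c_free >= 0)
    f = f_bound[mask]
    c = c_free[mask]
    if f.size == 0 or np.all(f < _MIN_SIGNAL):
        return math.inf

    def sse(log10_k: float) -> float:
        k = 10.0**log10_k
        return float(np.sum((f - c / (c + k)) ** 2))

    res = optimize.minimize_scalar(sse, bounds=_LOG10_KD_RANGE, method="bounded",
                                   options={"xatol": 1e-6})
    k = 10.0 ** float(res.x)
    if res.x >= _LOG10_KD_RANGE[1] - 1e-3:
        return math.inf
    return k


def fit_kd_isotherm(
    cells: Sequence[CellMeasurement],
    binder_threshold_nM: float = 10_000.0,
    min_cells: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> KdFit:
    """Estimate K_d from per-cell bound fractions in both orientations.

    The bound fraction of the green-tagged species is fitted against the free
    red partner concentration of the *same* cell (and symmetrically for red);
    K_d is the unweighted mean of the two orientation fits.  The 95% CI is a
    nonparametric bootstrap over cells (percentile method, seeded).  Cells
    with ``qc_pass=False`` are excluded.  If neither orientation shows binding
    signal the non-binder sentinel (``kd = inf``, ``binder_flag=False``) is
    returned.
    """
    use = [c for c in cells if c.qc_pass]
    if len(use) < min_cells:
        raise ValueError(f"need >= {min_cells} qc-passing cells, got {len(use)}")
    fg = np.array([c.f_bound_green for c in use])
    fr = np.array([c.f_bound_red for c in use])
    c_g_free = np.array([c.c_g_free for c in use])
    c_r_free = np.array([c.c_r_free for c in use])

    kd_green = _fit_single_orientation(fg, c_r_free)
    kd_red = _fit_single_orientation(fr, c_g_free)
    estimates = [k for k in (kd_green, kd_red) if math.isfinite(k)]
    if not estimates:
        return KdFit(
            kd_green_orientation=math.inf,
            kd_red_orientation=math.inf,
            kd_mean=math.inf,
            ci95=(math.inf, math.inf),
            n_cells=len(use),
            binder_flag=False,
            binder_threshold_nM=binder_threshold_nM,
        )
    kd_mean = float(np.mean([kd_green, kd_red])) if len(estimates) == 2 else estimates[0]

    rng = np.random.default_rng(seed)
    n = len(use)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        kg = _fit_single_orientation(fg[idx], c_r_free[idx])
        kr = _fit_single_orientation(fr[idx], c_g_free[idx])
        vals = [k for k in (kg, kr) if math.isfinite(k)]
        boot[i] = np.mean([kg, kr]) if len(vals) == 2 else (vals[0] if vals else np.inf)
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    lo = min(float(lo), kd_mean)
    hi = max(float(hi), kd_mean)
    return KdFit(
        kd_green_orientation=kd_green,
        kd_red_orientation=kd_red,
        kd_mean=kd_mean,
        ci95=(lo, hi),
        n_cells=n,
        binder_flag=bool(kd_mean < binder_threshold_nM),
        binder_threshold_nM=binder_threshold_nM,
    )
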