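"""Ground-truth-known synthetic inputs for every pipeline stage.

Raw single-cell FCCS traces, DULIP plates, reporter screens and Y2H matrices
from the wet lab are not redistributable at desk scale, so each stage of the
analysis is exercised against simulated data whose generating parameters are
known exactly.  The generators state a world, they are not tuned to tests:

* per-cell expression levels are log-normal in each channel,
* complex formation follows 1:1 mass action at a specified K_d,
* correlation curves are the analytic diffusion models plus per-lag Gaussian
  noise shaped like averaged-segment FCS noise,
* a Brownian-dynamics photon-trace simulator provides a physics oracle that
  is independent of the analytic models,
* DULIP luminescence is proportional to input/captured protein with
  multiplicative log-normal well noise,
* reporter screens have fixed condition/cell-line/interaction effects, a
  random plate intercept and i.i.d. residuals,
* Y2H screens emit two independent assay replicates per pair with a
  controllable per-replicate reproducibility.

All randomness flows through one ``numpy.random.Generator`` per simulation
call, so identical configurations with identical seeds are bit-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dulip_quant import DulipWell
from .fccs_quant import (
    ConfocalVolume,
    CorrelationCurve,
    DiffusionFitParams,
    concentrations_to_amplitudes,
    eval_autocorr_model,
    eval_crosscorr_model,
)

__all__ = [
    "EquilibriumState",
    "SimulationConfig",
    "FccsCurveModel",
    "CellSimulation",
    "DulipGains",
    "ReporterEffects",
    "solve_equilibrium",
    "simulate_fccs_curves",
    "simulate_photon_traces",
    "simulate_cell_population",
    "simulate_dulip_assay",
    "simulate_reporter_study",
    "simulate_y2h_screen",
    "write_curve_files",
]


@dataclass(frozen=True)
class EquilibriumState:
    """1:1 binding equilibrium between a green- and a red-tagged species.

    All concentrations in nM.  Mass balance (free + complex == total, per
    channel) and the dissociation relation
    ``c_g_free * c_r_free / c_complex == kd_true`` hold by construction.
    """

    c_g_total: float
    c_r_total: float
    kd_true: float
    c_complex: float
    c_g_free: float
    c_r_free: float


def solve_equilibrium(c_g_total: float, c_r_total: float, kd: float) -> EquilibriumState:
    """Unique physical root of the 1:1 mass-action quadratic.

    With totals A, B and dissociation constant K the complex concentration is
    ``C = (A + B + K - sqrt((A + B + K)^2 - 4AB)) / 2``, evaluated in the
    cancellation-safe form ``2AB / (A + B + K + sqrt(...))``.
    """
    a, b, k = float(c_g_total), float(c_r_total), float(kd)
    if a < 0 or b < 0 or k < 0:
        raise ValueError("totals and kd must be non-negative")
    if a == 0 or b == 0:
        c = 0.0
    elif k == 0:
        c = min(a, b)
    else:
        s = a + b + k
        disc = math.sqrt(s * s - 4.0 * a * b)
        c = 2.0 * a * b / (s + disc)
    c = min(c, a, b)
    return EquilibriumState(
        c_g_total=a, c_r_total=b, kd_true=k,
        c_complex=c, c_g_free=a - c, c_r_free=b - c,
    )


@dataclass(frozen=True)
class FccsCurveModel:
    """Diffusion/photophysics parameters and lag grid used to render curves.

    The defaults describe a transcription-factor pair in the cytoplasm at an
    LSM-style confocal volume: a fast freely diffusing component around
    0.5 ms, a slow (complexed / transiently bound) component around 5 ms, a
    modest triplet fraction with a microsecond dark time.  The triplet term
    applies to the autocorrelations only.
    """

    f_fast: float = 0.7
    tau_d_fast: float = 5e-4
    tau_d_slow: float = 5e-3
    triplet_fraction: float = 0.15
    tau_triplet: float = 5e-6
    offset: float = 0.0
    lag_min: float = 1e-6
    lag_max: float = 1.0
    n_lags: int = 128

    def __post_init__(self) -> None:
        if self.tau_d_fast <= 0 or self.tau_d_slow <= 0:
            raise ValueError("diffusion times must be positive")
        if self.lag_min <= 0 or self.lag_max <= self.lag_min:
            raise ValueError("lag grid must satisfy 0 < lag_min < lag_max")

    @property
    def lags(self) -> np.ndarray:
        return np.geomspace(self.lag_min, self.lag_max, self.n_lags)

    @property
    def tau_d_mean(self) -> float:
        return self.f_fast * self.tau_d_fast + (1.0 - self.f_fast) * self.tau_d_slow

    def as_fit_params(self, n_particles: float, triplet: bool) -> DiffusionFitParams:
        return DiffusionFitParams(
            n_particles=n_particles,
            f_fast=self.f_fast,
            tau_d_fast=self.tau_d_fast,
            tau_d_slow=self.tau_d_slow,
            triplet_fraction=self.triplet_fraction if triplet else 0.0,
            tau_triplet=self.tau_triplet,
            offset=self.offset,
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a simulated single-cell FCCS experiment.

    Expression defaults give per-cell totals centred near 300 nM spanning
    roughly an order of magnitude across cells (log10 sd 0.5) — a realistic
    range for low-amount transient transfection, where expression varies
    widely between cells.  ``n_segments`` models the averaging of repeated
    short measurements per cell (5 x 2 s), which scales curve noise by
    1/sqrt(n_segments).
    """

    n_cells: int = 40
    expression_log10_mean_green: float = 2.5
    expression_log10_sd_green: float = 0.5
    expression_log10_mean_red: float = 2.5
    expression_log10_sd_red: float = 0.5
    kd_true: float = 1148.0
    volume: ConfocalVolume = field(default_factory=lambda: ConfocalVolume(v_eff_fL=0.35, s=5.0, w0_um=0.2))
    noise_sd_scale: float = 0.02
    n_segments: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.noise_sd_scale < 0:
            raise ValueError("noise_sd_scale must be >= 0")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")


def _render_curve(
    channel: str,
    amplitude: float,
    model: FccsCurveModel,
    volume: ConfocalVolume,
    noise_sd_scale: float,
    n_segments: int,
    rng: np.random.Generator,
) -> CorrelationCurve:
    lags = model.lags
    if amplitude <= 0:
        g = np.full_like(lags, model.offset)
        sem = np.zeros_like(lags)
        noise_sd = np.zeros_like(lags)
    else:
        params = model.as_fit_params(1.0 / amplitude, triplet=channel != "cross")
        evaluate = eval_crosscorr_model if channel == "cross" else eval_autocorr_model
        g = evaluate(lags, params, volume)
        noise_sd = noise_sd_scale * (amplitude / math.sqrt(n_segments)) / np.sqrt(
            1.0 + lags / model.tau_d_mean
        )
        sem = noise_sd.copy()
    if noise_sd_scale > 0:
        g = g + rng.normal(0.0, 1.0, size=lags.shape) * noise_sd
    return CorrelationCurve(
        channel=channel, lags=lags, g=g, sem=sem,
        meta={"v_eff_fL": volume.v_eff_fL, "s": volume.s, "cpm_kHz": 1.0},
    )


def simulate_fccs_curves(
    state: EquilibriumState,
    cfg: SimulationConfig,
    model_params: FccsCurveModel | Mapping[str, FccsCurveModel] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CorrelationCurve, CorrelationCurve, CorrelationCurve]:
    """Render the (green auto, red auto, cross) curve triple for one cell.

    Noise-free output (``noise_sd_scale=0``) is the analytic model evaluated
    exactly; otherwise zero-mean Gaussian noise with per-lag sd
    ``noise_sd_scale * (G(0)/sqrt(n_segments)) * (1 + tau/tau_D)^-1/2`` is
    added and recorded in the ``sem`` column.
    """
    if model_params is None:
        model_params = FccsCurveModel()
    if isinstance(model_params, FccsCurveModel):
        models = {ch: model_params for ch in ("green_auto", "red_auto", "cross")}
    else:
        models = dict(model_params)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    g0_green, g0_red, g0_cross = concentrations_to_amplitudes(
        state.c_g_total, state.c_r_total, state.c_complex, cfg.volume
    )
    out = []
    for channel, amp in (("green_auto", g0_green), ("red_auto", g0_red), ("cross", g0_cross)):
        out.append(
            _render_curve(channel, amp, models[channel], cfg.volume,
                          cfg.noise_sd_scale, cfg.n_segments, rng)
        )
    return tuple(out)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Brownian-dynamics photon traces (physics oracle)
# ---------------------------------------------------------------------------


def simulate_photon_traces(
    state: EquilibriumState,
    volume: ConfocalVolume,
    diffusion_um2_s: Mapping[str, float],
    dt: float,
    n_steps: int,
    seed: int,
    box_factor: float = 12.0,
    brightness_cpb: float = 2.0,
    max_particles: int = 200,
    chunk: int = 1 << 15,
) -> tuple[np.ndarray, np.ndarray]:
    """Brownian dynamics of point emitters in a periodic box around the focus.

    Species (free green, free red, complex) diffuse with the coefficients
    given under keys ``'green'``, ``'red'``, ``'complex'`` (um^2/s); particle
    numbers are drawn deterministically from the equilibrium concentrations
    and the box volume.  Each particle emits into its channel(s) with a
    Gaussian detection weight ``exp(-2(x^2+y^2)/w0^2 - 2 z^2/(s w0)^2)``;
    complexes emit into both.  Per-bin photon counts are Poisson with mean
    ``brightness_cpb * sum(weights)``.

    This is a desk-scale oracle for the correlator and the analytic models:
    it shares no code with either.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps > 1 << 20:
        raise ValueError("n_steps must be <= 2^20 (desk-scale oracle)")
    if volume.w0_um is None:
        raise ValueError("volume.w0_um is required for trace simulation")
    if box_factor < 10.0:
        raise ValueError("box must be at least 10 beam waists wide")
    w0 = volume.w0_um
    wz = volume.s * w0
    L = box_factor * w0
    box_volume_L = (L**3) * 1e-15  # um^3 -> litres
    from .fccs_quant import N_AVOGADRO

    def n_of(c_nM: float) -> int:
        return int(round(c_nM * 1e-9 * N_AVOGADRO * box_volume_L))

    species = [
        ("green", n_of(state.c_g_free), (True, False)),
        ("red", n_of(state.c_r_free), (False, True)),
        ("complex", n_of(state.c_complex), (True, True)),
    ]
    total = sum(n for _, n, _ in species)
    if total > max_particles:
        raise ValueError(
            f"{total} particles exceed the desk-scale limit of {max_particles}; "
            "reduce concentrations or the box size"
        )
    rng = np.random.default_rng(seed)
    trace_g = np.zeros(n_steps)
    trace_r = np.zeros(n_steps)
    if total == 0:
        return trace_g, trace_r

    positions = {}
    for name, n, _ in species:
        positions[name] = rng.uniform(0.0, L, size=(n, 3))

    for start in range(0, n_steps, chunk):
        stop = min(start + chunk, n_steps)
        m = stop - start
        intensity_g = np.zeros(m)
        intensity_r = np.zeros(m)
        for name, n, (emit_g, emit_r) in species:
            if n == 0:
                continue
            D = float(diffusion_um2_s.get(name, 0.0))
            pos = positions[name]
            if D > 0:
                steps = rng.normal(0.0, math.sqrt(2.0 * D * dt), size=(m, n, 3))
                path = np.cumsum(steps, axis=0) + pos  # (m, n, 3)
            else:
                path = np.broadcast_to(pos, (m, n, 3))
            frac = np.mod(path, L) - L / 2.0  # focus at box centre
            w = np.exp(
                -2.0 * (frac[..., 0] ** 2 + frac[..., 1] ** 2) / (w0 * w0)
                - 2.0 * frac[..., 2] ** 2 / (wz * wz)
            ).sum(axis=1)
            if emit_g:
                intensity_g += w
            if emit_r:
                intensity_r += w
            if D > 0:
                positions[name] = np.mod(path[-1], L)
        trace_g[start:stop] = rng.poisson(brightness_cpb * intensity_g)
        trace_r[start:stop] = rng.poisson(brightness_cpb * intensity_r)
    return trace_g, trace_r


# ---------------------------------------------------------------------------
# Cell populations
# ---------------------------------------------------------------------------


@dataclass
class CellSimulation:
    """One simulated cell: ground truth plus its three correlation curves."""

    cell_id: str
    compartment: str
    truth: EquilibriumState
    curves: tuple[CorrelationCurve, CorrelationCurve, CorrelationCurve]


def simulate_cell_population(
    cfg: SimulationConfig,
    model_params: FccsCurveModel | None = None,
    compartment: str = "cytoplasm",
) -> list[CellSimulation]:
    """Simulate ``cfg.n_cells`` cells with log-normal expression per channel.

    Per-cell totals are drawn log-normally (``10**N(mean, sd)`` per channel),
    the binding equilibrium is solved at ``cfg.kd_true``, and the curve triple
    is rendered per cell.  Ground truth is retained on each cell for recovery
    tests.
    """
    rng = np.random.default_rng(cfg.seed)
    cells: list[CellSimulation] = []
    for i in range(cfg.n_cells):
        cg = 10.0 ** rng.normal(cfg.expression_log10_mean_green, cfg.expression_log10_sd_green)
        cr = 10.0 ** rng.normal(cfg.expression_log10_mean_red, cfg.expression_log10_sd_red)
        state = solve_equilibrium(cg, cr, cfg.kd_true)
        curves = simulate_fccs_curves(state, cfg, model_params, rng=rng)
        cells.append(
            CellSimulation(cell_id=f"cell_{i:04d}", compartment=compartment,
                           truth=state, curves=curves)
        )
    return cells


def write_curve_files(cells: Sequence[CellSimulation], outdir: str | Path) -> Path:
    """Write one TSV (``lag_s  G  sem``) per channel per cell plus a JSON
    manifest carrying cell ids, compartments and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for cell in cells:
        entry = {
            "cell_id": cell.cell_id,
            "compartment": cell.compartment,
            "truth": {
                "c_g_total": cell.truth.c_g_total,
                "c_r_total": cell.truth.c_r_total,
                "kd_true": cell.truth.kd_true,
                "c_complex": cell.truth.c_complex,
            },
            "files": {},
        }
        for curve in cell.curves:
            fname = f"{cell.cell_id}_{curve.channel}.tsv"
            df = pd.DataFrame({"lag_s": curve.lags, "G": curve.g, "sem": curve.sem})
            df.to_csv(outdir / fname, sep="\t", index=False)
            entry["files"][curve.channel] = fname
        manifest.append(entry)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


# ---------------------------------------------------------------------------
# DULIP wells
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DulipGains:
    """Gain and noise parameters of the simulated luminescence assay.

    Defaults use unit gains and full bait capture so that the assay-unit K
    recovered by the estimator coincides numerically with the generating
    K_d in nM.  ``noise_cv`` is the log-normal coefficient of variation of
    per-well multiplicative noise.  Bait expression is narrow (fixed plasmid
    amount); prey expression spans the saturation range around K_d.
    """

    gain_fl_input: float = 1.0
    gain_rl_input: float = 1.0
    gain_fl_bound: float = 1.0
    gain_rl_bound: float = 1.0
    capture_efficiency: float = 1.0
    background_fl_bound: float = 0.0
    noise_cv: float = 0.1
    bait_log10_mean: float = 2.5
    bait_log10_sd: float = 0.1
    prey_log10_sd: float = 0.8


def simulate_dulip_assay(
    kd_true: float,
    gains: DulipGains | None = None,
    n_wells: int = 24,
    seed: int = 0,
    pair_id: str = "pair",
    cell_line: str = "WT",
    condition: str = "wt_bait",
    prey_log10_mean: float | None = None,
) -> list[DulipWell]:
    """Simulate a DULIP saturation series for one bait/prey pair.

    Input luminescences are proportional to total tagged protein; bound
    luminescences are proportional to captured bait and to the equilibrium
    complex, all with multiplicative log-normal well noise.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if kd_true < 0:
        raise ValueError("kd_true must be non-negative")
    g = gains or DulipGains()
    if prey_log10_mean is None:
        # centre the prey saturation series on K_d, but keep expression inside
        # the physically attainable range (~10 nM .. ~30 uM)
        prey_log10_mean = math.log10(kd_true) if kd_true > 0 else 2.0
        prey_log10_mean = min(max(prey_log10_mean, 1.0), 4.5)
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + g.noise_cv**2)) if g.noise_cv > 0 else 0.0

    def noise() -> float:
        return float(rng.lognormal(-0.5 * sigma * sigma, sigma)) if sigma > 0 else 1.0

    wells: list[DulipWell] = []
    for i in range(n_wells):
        bait = 10.0 ** rng.normal(g.bait_log10_mean, g.bait_log10_sd)
        prey = 10.0 ** rng.normal(prey_log10_mean, g.prey_log10_sd)
        eq = solve_equilibrium(bait, prey, kd_true)
        captured = g.capture_efficiency * bait
        captured_complex = g.capture_efficiency * eq.c_complex
        wells.append(
            DulipWell(
                pair_id=pair_id,
                fl_input=g.gain_fl_input * prey * noise(),
                rl_input=g.gain_rl_input * bait * noise(),
                fl_bound=g.gain_fl_bound * captured_complex * noise() + g.background_fl_bound,
                rl_bound=g.gain_rl_bound * captured * noise(),
                replicate_id=i % 3,
                experiment_id=i // 3,
                cell_line=cell_line,
                condition=condition,
            )
        )
    return wells


# ---------------------------------------------------------------------------
# Reporter screens
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReporterEffects:
    """Fixed-effect table of a simulated ARE-reporter screen on the log2
    scale: intercept (empty-vector baseline in the reference cell line),
    per-condition and per-cell-line main effects and optional
    condition x cell-line interactions."""

    intercept: float = 0.0
    condition: Mapping[str, float] = field(default_factory=dict)
    cell_line: Mapping[str, float] = field(default_factory=dict)
    interaction: Mapping[tuple[str, str], float] = field(default_factory=dict)


DEFAULT_CELL_LINES = (
    "WT", "NRF2_KO_1", "NRF2_KO_2", "NRF2_T80K_T80K", "NRF2_T80K_null", "KEAP1_KO",
)


def simulate_reporter_study(
    effects: ReporterEffects,
    sigma_plate: float,
    sigma_resid: float,
    n_plates: int = 6,
    replicates: int = 3,
    seed: int = 0,
    conditions: Sequence[str] = ("empty_vector", "partner"),
    cell_lines: Sequence[str] = ("WT", "KEAP1_KO"),
    rl_level: float = 1000.0,
) -> pd.DataFrame:
    """Simulate a plate-structured dual-luciferase screen.

    Every plate carries ``replicates`` wells of every condition x cell-line
    combination.  The latent value of a well is
    ``intercept + condition + cell_line + interaction + b_plate + e`` with
    ``b_plate ~ N(0, sigma_plate^2)`` and ``e ~ N(0, sigma_resid^2)``; raw
    luminescences are emitted as ``rl = rl_level`` and
    ``fl = rl * 2**value`` so the normalisation step can be exercised on the
    same data.  The latent value is returned in ``log2_ratio``.
    """
    if sigma_plate < 0 or sigma_resid < 0:
        raise ValueError("standard deviations must be non-negative")
    if "empty_vector" not in conditions:
        raise ValueError("conditions must include the empty_vector baseline")
    rng = np.random.default_rng(seed)
    rows = []
    for plate in range(n_plates):
        b_plate = rng.normal(0.0, sigma_plate) if sigma_plate > 0 else 0.0
        for line in cell_lines:
            for cond in conditions:
                fixed = (
                    effects.intercept
                    + effects.condition.get(cond, 0.0)
                    + effects.cell_line.get(line, 0.0)
                    + effects.interaction.get((cond, line), 0.0)
                )
                for rep in range(replicates):
                    e = rng.normal(0.0, sigma_resid) if sigma_resid > 0 else 0.0
                    value = fixed + b_plate + e
                    rows.append(
                        {
                            "plate": f"plate_{plate:02d}",
                            "cell_line": line,
                            "condition": cond,
                            "replicate": rep,
                            "fl": rl_level * 2.0**value,
                            "rl": rl_level,
                            "log2_ratio": value,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Y2H screens
# ---------------------------------------------------------------------------


def simulate_y2h_screen(
    true_edges: Iterable[tuple[str, str]],
    reproducibility: float,
    autoactivators: Iterable[str] = (),
    seed: int = 0,
    pairs: Sequence[tuple[str, str]] | None = None,
    false_positive_rate: float = 0.0,
    reporters: Sequence[str] = ("ADE2", "HIS3"),
    n_replicates: int = 2,
) -> pd.DataFrame:
    """Simulate growth calls of a matrix Y2H screen.

    Every tested ``(partner, nrf2_fragment)`` pair is assayed in
    ``n_replicates`` independent replicates; a true edge grows in a replicate
    with probability ``reproducibility`` (both reporters then score growth,
    modelling a shared activation event), a non-edge with
    ``false_positive_rate``.  Auto-activating partners are flagged on every
    call.
    """
    if not (0.0 <= reproducibility <= 1.0):
        raise ValueError("reproducibility must lie in [0, 1]")
    true_set = {tuple(e) for e in true_edges}
    if pairs is None:
        pairs = sorted(true_set)
    auto = set(autoactivators)
    rng = np.random.default_rng(seed)
    rows = []
    for partner, fragment in pairs:
        is_edge = (partner, fragment) in true_set
        p = reproducibility if is_edge else false_positive_rate
        for rep in range(n_replicates):
            grows = bool(rng.random() < p)
            for reporter in reporters:
                rows.append(
                    {
                        "bait": fragment,
                        "prey": partner,
                        "nrf2_fragment": fragment,
                        "assay_replicate": rep,
                        "reporter": reporter,
                        "growth": grows,
                        "autoactivator": partner in auto,
                    }
                )
    return pd.DataFrame(rows)
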