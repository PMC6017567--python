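"""Slow-binding enzyme inhibition kinetics.

This module implements the full analysis chain for reversible and
slow-binding (time-dependent) enzyme inhibition as practised in
small-molecule screening against tyrosinase and similar oxidases:

1.  closed-form kinetic models — Michaelis–Menten rate laws under the four
    classical inhibition modes, the slow-binding progress-curve equation
    ``[P](t) = vs·t + (vi − vs)/kobs · (1 − exp(−kobs·t))``, the hyperbolic
    dependence ``kobs = k4 + k3·[I]/(Kiapp + [I])`` that diagnoses a
    two-step (isomerisation) binding mechanism, percent-inhibition assay
    arithmetic and the four-parameter log-logistic dose–response model;
2.  a synthetic plate-reader data generator (closed-form and mass-action
    ODE variants) producing tidy CSV datasets with controlled noise;
3.  inference — per-curve progress fits, kobs-vs-[I] fits, one-step vs
    two-step mechanism discrimination, global inhibition-mode
    classification with Lineweaver–Burk diagnostics, Dixon-plot Ki
    estimation, IC50 fitting, and a per-compound orchestrator;
4.  reproducible parameter-recovery studies used by the test-suite and the
    acceptance script.

Units are fixed package-wide: time in s, concentrations in µM, signal in
absorbance units (AU), velocities in AU/s.  Absorbance is never converted
to molar product; the progress-curve model is fit in signal units, which
the linearity of the model permits.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    # kinetic models
    "InhibitionMode",
    "MichaelisMentenParams",
    "InhibitionModel",
    "SlowBindingCurveParams",
    "TwoStepBindingParams",
    "AssayDeltas",
    "DoseResponseParams",
    "velocity",
    "progress_value",
    "kobs_of_I",
    "percent_inhibition",
    "dose_response",
    "overall_ki_star",
    "ki_app_competitive",
    # synthetic data
    "AssayDesign",
    "MechanismSpec",
    "closed_form_params",
    "mechanism_from_kiapp",
    "simulate_progress_closed_form",
    "simulate_progress_mechanistic",
    "simulate_steady_state",
    "simulate_dose_response",
    "write_dataset",
    "read_dataset",
    "PROGRESS_COLUMNS",
    "VELOCITY_COLUMNS",
    "DOSE_COLUMNS",
    "KOBS_COLUMNS",
    # inference
    "FitResult",
    "fit_progress_curve",
    "extract_kobs_series",
    "fit_kobs_hyperbola",
    "classify_mechanism",
    "ModeCall",
    "classify_mode",
    "DixonResult",
    "dixon_ki",
    "fit_ic50",
    "InhibitionResult",
    "characterize_compound",
    # recovery studies
    "dixon_recovery_study",
    "ic50_recovery_study",
    "two_stage_recovery_study",
    "mechanism_discrimination_study",
    # run configuration
    "RunConfig",
    "DesignConfig",
    "MechanismConfig",
    "DoseConfig",
    "run_simulation",
]

logger = logging.getLogger("slowbind")

# ---------------------------------------------------------------------------
# Configuration constants (package-wide defaults)
# ---------------------------------------------------------------------------

#: Tidy CSV column contract for kinetic progress reads.
PROGRESS_COLUMNS = ["time_s", "signal_au", "inhibitor_um", "substrate_um", "replicate"]
#: Tidy CSV column contract for steady-state velocity tables.
VELOCITY_COLUMNS = ["substrate_um", "inhibitor_um", "v_au_per_s", "replicate"]
#: Tidy CSV column contract for dose–response tables.
DOSE_COLUMNS = ["inhibitor_um", "inhibition_pct", "replicate"]
#: Column contract for kobs-vs-[I] series.
KOBS_COLUMNS = ["inhibitor_um", "kobs_per_s", "kobs_se"]

#: Default kinetic read: 20 min sampled every 10 s (t = 0 included).
DEFAULT_T_GRID = tuple(float(t) for t in range(0, 1201, 10))
#: Default inhibitor series: two-fold dilutions 6.25–100 µM plus control.
DEFAULT_INHIBITOR_SERIES = (0.0, 6.25, 12.5, 25.0, 50.0, 100.0)
#: Default substrate concentration: 50 µL of 1.5 mM into 200 µL total.
DEFAULT_SUBSTRATE_UM = 375.0
#: Substrate series for mode-classification grids (two-fold around default).
DEFAULT_SUBSTRATE_SERIES = (93.75, 187.5, 375.0, 750.0)
#: Default maximal velocity, AU/s (full-scale ΔA475 ≈ 0.08 AU over 20 min).
DEFAULT_VMAX_AU_PER_S = 1.0e-4
#: Default Michaelis constant placeholder, µM (recorded in metadata).
DEFAULT_KM_UM = 200.0
#: Default association rate of the rapid E·I step, µM⁻¹ s⁻¹.
DEFAULT_KON_PER_UM_S = 10.0
#: Dopachrome-like signal conversion, AU per µM product (depletion check only).
DEFAULT_SIGNAL_PER_UM = 0.0021
#: Fraction of substrate that may be consumed before a depletion warning.
DEFAULT_DEPLETION_CAP = 0.10

#: AICc margin below which the simpler model is preferred (parsimony rule).
AICC_PARSIMONY_MARGIN = 2.0

_LSQ_TOL = dict(xtol=1e-14, ftol=1e-14, gtol=1e-14, x_scale="jac", max_nfev=5000)


def _positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ValueError(f"{name} must be > 0, got {value!r}")


def _nonnegative(name: str, value: float) -> None:
    if not (value >= 0):
        raise ValueError(f"{name} must be >= 0, got {value!r}")


# ===========================================================================
# SECTION 1 — kinetic models (pure closed forms)
# ===========================================================================


class InhibitionMode(str, Enum):
    """Classical reversible inhibition modes of the Michaelis–Menten law."""

    COMPETITIVE = "competitive"
    UNCOMPETITIVE = "uncompetitive"
    NONCOMPETITIVE = "noncompetitive"
    MIXED = "mixed"


@dataclass(frozen=True)
class MichaelisMentenParams:
    """Michaelis–Menten parameters.

    Attributes
    ----------
    Vmax : float
        Maximal velocity, signal units per second (AU/s).
    Km : float
        Michaelis constant, µM.
    """

    Vmax: float
    Km: float

    def __post_init__(self) -> None:
        _positive("Vmax", self.Vmax)
        _positive("Km", self.Km)


@dataclass(frozen=True)
class InhibitionModel:
    """Reversible inhibition mode and constant.

    ``alpha`` is the mixed-mode factor scaling Ki for the ESI branch; it is
    ignored unless ``mode`` is :attr:`InhibitionMode.MIXED`.
    """

    mode: InhibitionMode
    Ki: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        _positive("Ki", self.Ki)
        _positive("alpha", self.alpha)
        object.__setattr__(self, "mode", InhibitionMode(self.mode))


@dataclass(frozen=True)
class SlowBindingCurveParams:
    """Parameters of one slow-binding progress curve.

    ``vi`` is the initial velocity before the slow transition, ``vs`` the
    final steady-state velocity, and ``kobs`` the first-order rate constant
    of the approach from ``vi`` to ``vs``.  For an inhibitor ``vs <= vi``.
    """

    vi: float
    vs: float
    kobs: float

    def __post_init__(self) -> None:
        _nonnegative("vi", self.vi)
        _nonnegative("vs", self.vs)
        _positive("kobs", self.kobs)


@dataclass(frozen=True)
class TwoStepBindingParams:
    """Rate constants of the two-step (isomerisation) binding mechanism.

    The inhibitor first forms a rapid-equilibrium complex E·I with apparent
    dissociation constant ``Kiapp`` (µM, under assay conditions), which then
    isomerises slowly to a tighter complex E*·I with forward rate ``k3`` and
    reverse rate ``k4`` (both s⁻¹).
    """

    k3: float
    k4: float
    Kiapp: float

    def __post_init__(self) -> None:
        _positive("k3", self.k3)
        _nonnegative("k4", self.k4)
        _positive("Kiapp", self.Kiapp)


@dataclass(frozen=True)
class AssayDeltas:
    """Signal changes of the uninhibited and inhibited reactions (AU)."""

    delta_control: float
    delta_inhibitor: float

    def __post_init__(self) -> None:
        _positive("delta_control", self.delta_control)


@dataclass(frozen=True)
class DoseResponseParams:
    """Four-parameter log-logistic dose–response curve (percent inhibition)."""

    ic50: float
    hill: float = 1.0
    top: float = 100.0
    bottom: float = 0.0

    def __post_init__(self) -> None:
        _positive("ic50", self.ic50)
        if not (self.top > self.bottom):
            raise ValueError(f"top must exceed bottom, got {self.top!r} <= {self.bottom!r}")


def velocity(
    S: float | np.ndarray,
    I: float | np.ndarray,
    mm: MichaelisMentenParams,
    inh: InhibitionModel,
) -> float | np.ndarray:
    """Steady-state velocity under a classical inhibition mode.

    Parameters
    ----------
    S, I : float or array
        Substrate and inhibitor concentrations, µM (both >= 0).
    mm, inh
        Rate-law parameters.

    Returns
    -------
    float or array
        Velocity in AU/s.  With ``I = 0`` every mode reduces to the plain
        Michaelis–Menten form ``Vmax·S/(Km + S)``.
    """
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(S < 0) or np.any(I < 0):
        raise ValueError("S and I must be >= 0")
    a = 1.0 + I / inh.Ki  # competitive factor on Km
    mode = inh.mode
    if mode is InhibitionMode.COMPETITIVE:
        v = mm.Vmax * S / (mm.Km * a + S)
    elif mode is InhibitionMode.UNCOMPETITIVE:
        v = mm.Vmax * S / (mm.Km + S * a)
    elif mode is InhibitionMode.NONCOMPETITIVE:
        v = mm.Vmax * S / ((mm.Km + S) * a)
    elif mode is InhibitionMode.MIXED:
        b = 1.0 + I / (inh.alpha * inh.Ki)
        v = mm.Vmax * S / (mm.Km * a + S * b)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown mode {mode!r}")
    return float(v) if v.ndim == 0 else v


def progress_value(t: float | np.ndarray, p: SlowBindingCurveParams) -> float | np.ndarray:
    """Product signal of a slow-binding progress curve at time ``t`` (s).

    Evaluates ``vs·t + (vi − vs)/kobs · (1 − exp(−kobs·t))``; at ``t = 0``
    the signal is exactly 0, and for ``vi = vs`` the curve is the straight
    line ``vi·t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = p.vs * t + (p.vi - p.vs) / p.kobs * (-np.expm1(-p.kobs * t))
    return float(out) if out.ndim == 0 else out


def kobs_of_I(I: float | np.ndarray, p: TwoStepBindingParams) -> float | np.ndarray:
    """Observed rate constant of the slow transition vs inhibitor (s⁻¹).

    ``kobs = k4 + k3·[I]/(Kiapp + [I])`` — a hyperbola rising from ``k4``
    at ``[I] = 0`` toward the asymptote ``k3 + k4``; this saturating shape
    is the signature of two-step (isomerisation) binding, whereas a
    one-step binding mechanism gives kobs linear in ``[I]``.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("I must be >= 0")
    out = p.k4 + p.k3 * I / (p.Kiapp + I)
    return float(out) if out.ndim == 0 else out


def percent_inhibition(d: AssayDeltas) -> float:
    """Percent inhibition from endpoint signal changes.

    ``100 · (Δcontrol − Δinhibitor) / Δcontrol``.
    """
    return 100.0 * (d.delta_control - d.delta_inhibitor) / d.delta_control


def dose_response(I: float | np.ndarray, p: DoseResponseParams) -> float | np.ndarray:
    """Log-logistic percent inhibition at inhibitor concentration ``I`` (µM).

    ``bottom + (top − bottom)/(1 + (ic50/I)^hill)``; by convention the
    curve returns ``bottom`` at ``I = 0``.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("I must be >= 0")
    with np.errstate(divide="ignore"):
        ratio = np.where(I > 0, p.ic50 / np.where(I > 0, I, 1.0), np.inf)
        out = p.bottom + (p.top - p.bottom) / (1.0 + ratio**p.hill)
    return float(out) if out.ndim == 0 else out


def overall_ki_star(p: TwoStepBindingParams) -> float:
    """Overall steady-state inhibition constant Ki* of the two-step scheme.

    At equilibrium across both steps the apparent constant tightens from
    ``Kiapp`` to ``Kiapp · k4/(k3 + k4)``: the slow isomerisation pulls
    enzyme into the E*·I state, lowering the free-inhibitor concentration
    needed for half-maximal binding.
    """
    denom = p.k3 + p.k4
    if denom <= 0:
        raise ValueError("k3 + k4 must be > 0")
    return p.Kiapp * p.k4 / denom


def ki_app_competitive(Ki: float, S: float, Km: float) -> float:
    """Apparent Ki of a competitive inhibitor at substrate concentration S.

    ``Kiapp = Ki·(1 + S/Km)``.  Exposed as a helper for relating the
    fast-step constant of the two-step scheme to the substrate-free Ki;
    the fitters never assume it.
    """
    _positive("Ki", Ki)
    _positive("Km", Km)
    _nonnegative("S", S)
    return Ki * (1.0 + S / Km)


# ===========================================================================
# SECTION 2 — synthetic assay data
# ===========================================================================


@dataclass(frozen=True)
class AssayDesign:
    """Design of a simulated plate-reader assay.

    Attributes
    ----------
    inhibitor_concs : sequence of float
        Inhibitor concentrations, µM (>= 0).
    substrate_concs : sequence of float
        Substrate concentrations, µM; progress-curve simulators use the
        first entry, steady-state grids use all of them.
    t_grid : sequence of float
        Sampling times, s; strictly increasing starting at 0.
    replicates : int
        Technical replicates per condition (>= 1).
    noise_sd : float
        Gaussian noise σ.  For progress curves: fraction of that curve's
        maximal noiseless signal (additive).  For velocity grids:
        multiplicative fraction of each velocity.
    seed : int
        RNG seed; generation is bit-reproducible given the seed.
    """

    inhibitor_concs: Sequence[float] = DEFAULT_INHIBITOR_SERIES
    substrate_concs: Sequence[float] = (DEFAULT_SUBSTRATE_UM,)
    t_grid: Sequence[float] = DEFAULT_T_GRID
    replicates: int = 3
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        inh = tuple(float(x) for x in self.inhibitor_concs)
        sub = tuple(float(x) for x in self.substrate_concs)
        t = np.asarray(self.t_grid, dtype=float)
        if len(inh) == 0 or any(x < 0 for x in inh):
            raise ValueError("inhibitor_concs must be nonempty and >= 0")
        if len(sub) == 0 or any(x <= 0 for x in sub):
            raise ValueError("substrate_concs must be nonempty and > 0")
        if t.size < 2 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
            raise ValueError("t_grid must be strictly increasing from 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        _nonnegative("noise_sd", self.noise_sd)
        object.__setattr__(self, "inhibitor_concs", inh)
        object.__setattr__(self, "substrate_concs", sub)
        object.__setattr__(self, "t_grid", tuple(float(x) for x in t))

    def as_dict(self) -> dict[str, Any]:
        return {
            "inhibitor_um": list(self.inhibitor_concs),
            "substrate_um": list(self.substrate_concs),
            "t_grid_s": list(self.t_grid),
            "replicates": self.replicates,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class MechanismSpec:
    """Generating mechanism for simulated assays.

    ``two_step`` enables slow-binding behaviour; when absent the inhibitor
    equilibrates instantly and progress curves are straight lines.  The
    mechanistic simulator uses ``inh.Ki`` for the rapid first step with
    association rate ``fast_step_kon`` (µM⁻¹s⁻¹) and dissociation rate
    ``kon·Ki``; ``two_step.Kiapp`` is informational (the apparent constant
    at the design substrate) and is not read by the integrator.
    ``signal_per_um`` converts product signal to µM only for the
    substrate-depletion warning.
    """

    mm: MichaelisMentenParams = MichaelisMentenParams(DEFAULT_VMAX_AU_PER_S, DEFAULT_KM_UM)
    inh: InhibitionModel = InhibitionModel(InhibitionMode.COMPETITIVE, 12.452)
    two_step: Optional[TwoStepBindingParams] = None
    fast_step_kon: float = DEFAULT_KON_PER_UM_S
    signal_per_um: float = DEFAULT_SIGNAL_PER_UM
    depletion_cap: float = DEFAULT_DEPLETION_CAP

    def __post_init__(self) -> None:
        _positive("fast_step_kon", self.fast_step_kon)
        _positive("signal_per_um", self.signal_per_um)
        _positive("depletion_cap", self.depletion_cap)

    def as_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "vmax_au_per_s": self.mm.Vmax,
            "km_um": self.mm.Km,
            "mode": self.inh.mode.value,
            "ki_um": self.inh.Ki,
            "alpha": self.inh.alpha,
            "fast_step_kon_per_um_s": self.fast_step_kon,
            "signal_per_um": self.signal_per_um,
        }
        if self.two_step is not None:
            d["two_step"] = {
                "k3_per_s": self.two_step.k3,
                "k4_per_s": self.two_step.k4,
                "kiapp_um": self.two_step.Kiapp,
            }
        return d


def mechanism_from_kiapp(
    two_step: TwoStepBindingParams,
    mm: MichaelisMentenParams | None = None,
    S: float = DEFAULT_SUBSTRATE_UM,
    **kwargs: Any,
) -> MechanismSpec:
    """Build a competitive slow-binding mechanism whose apparent fast-step
    constant at substrate ``S`` equals ``two_step.Kiapp``.

    Inverts ``Kiapp = Ki·(1 + S/Km)`` to set the substrate-free Ki of the
    rapid step, so that simulated progress curves obey
    ``kobs = k4 + k3·[I]/(Kiapp + [I])`` with the given ``Kiapp``.
    """
    mm = mm or MichaelisMentenParams(DEFAULT_VMAX_AU_PER_S, DEFAULT_KM_UM)
    ki = two_step.Kiapp / (1.0 + S / mm.Km)
    return MechanismSpec(
        mm=mm,
        inh=InhibitionModel(InhibitionMode.COMPETITIVE, ki),
        two_step=two_step,
        **kwargs,
    )


def closed_form_params(mech: MechanismSpec, S: float, I: float) -> SlowBindingCurveParams:
    """Slow-binding curve parameters implied by a competitive two-step
    mechanism at one (substrate, inhibitor) condition.

    Under rapid equilibration of E, ES and E·I the progress curve is exactly
    the closed form with ``vi = velocity(S, I)``,
    ``kobs = k4 + k3·[I]/(Kiapp + [I])`` where ``Kiapp = Ki·(1 + S/Km)``,
    and ``vs = vi·k4/kobs``.
    """
    if mech.inh.mode is not InhibitionMode.COMPETITIVE:
        raise ValueError("closed-form slow-binding reduction assumes competitive inhibition")
    vi = velocity(S, I, mech.mm, mech.inh)
    if mech.two_step is None:
        return SlowBindingCurveParams(vi=vi, vs=vi, kobs=1.0)  # linear curve
    kiapp = ki_app_competitive(mech.inh.Ki, S, mech.mm.Km)
    eff = TwoStepBindingParams(mech.two_step.k3, mech.two_step.k4, kiapp)
    kobs = kobs_of_I(I, eff)
    vs = vi * (mech.two_step.k4 / kobs) if I > 0 else vi
    return SlowBindingCurveParams(vi=vi, vs=vs, kobs=kobs)


def _progress_frame(records: list[dict[str, Any]], meta: dict[str, Any]) -> pd.DataFrame:
    df = pd.DataFrame.from_records(records, columns=PROGRESS_COLUMNS)
    df.attrs["meta"] = meta
    return df


def simulate_progress_closed_form(
    design: AssayDesign,
    params_by_I: Mapping[float, SlowBindingCurveParams],
) -> pd.DataFrame:
    """Simulate progress curves from explicit per-concentration closed-form
    parameters.

    ``params_by_I`` maps every inhibitor concentration of the design to its
    :class:`SlowBindingCurveParams`.  Additive Gaussian noise with
    σ = ``noise_sd`` × (per-curve maximal noiseless signal) is applied;
    generation is deterministic given ``design.seed``.
    """
    missing = [I for I in design.inhibitor_concs if float(I) not in {float(k) for k in params_by_I}]
    if missing:
        raise ValueError(f"params_by_I missing inhibitor concentrations: {missing}")
    rng = np.random.default_rng(design.seed)
    S = design.substrate_concs[0]
    t = np.asarray(design.t_grid)
    records: list[dict[str, Any]] = []
    for I in design.inhibitor_concs:
        p = params_by_I[float(I)]
        clean = np.asarray(progress_value(t, p))
        sd = design.noise_sd * float(np.max(np.abs(clean))) if design.noise_sd > 0 else 0.0
        for rep in range(1, design.replicates + 1):
            sig = clean + rng.normal(0.0, sd, size=t.size) if sd > 0 else clean.copy()
            records.extend(
                {
                    "time_s": float(tt),
                    "signal_au": float(ss),
                    "inhibitor_um": float(I),
                    "substrate_um": float(S),
                    "replicate": rep,
                }
                for tt, ss in zip(t, sig)
            )
    meta = {
        "kind": "progress_closed_form",
        "design": design.as_dict(),
        "params_by_inhibitor_um": {
            str(float(I)): dataclasses.asdict(params_by_I[float(I)]) for I in design.inhibitor_concs
        },
        "warnings": [],
    }
    return _progress_frame(records, meta)


def _integrate_two_step(
    t: np.ndarray, S: float, I: float, mech: MechanismSpec
) -> np.ndarray:
    """Mass-action integration of the two-step competitive scheme.

    State (fractions of total enzyme + product signal): y = [EI, Q, P] with
    Q = E*·I.  Within the non-isomerised pool, substrate binding is treated
    as rapid equilibrium, so the free-enzyme fraction available to the
    inhibitor is (1 − EI − Q)·Km/(Km + S) and the catalytically productive
    fraction is (1 − EI − Q)·S-saturation.
    """
    mm, kon, ki = mech.mm, mech.fast_step_kon, mech.inh.Ki
    koff = kon * ki
    k3 = mech.two_step.k3 if mech.two_step else 0.0
    k4 = mech.two_step.k4 if mech.two_step else 0.0
    sat = S / (mm.Km + S)
    free_frac = mm.Km / (mm.Km + S)

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        ei, q, _p = y
        pool = 1.0 - ei - q
        d_ei = kon * I * pool * free_frac - koff * ei - k3 * ei + k4 * q
        d_q = k3 * ei - k4 * q
        d_p = mm.Vmax * sat * pool
        return [d_ei, d_q, d_p]

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [0.0, 0.0, 0.0],
        t_eval=t,
        method="LSODA",
        rtol=1e-8,
        atol=1e-12,
    )
    if not sol.success:  # pragma: no cover - LSODA handles this stiff system
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[2]


def simulate_progress_mechanistic(design: AssayDesign, mech: MechanismSpec) -> pd.DataFrame:
    """Simulate progress curves by mass-action integration of the two-step
    competitive binding scheme.

    The rapid first step must equilibrate faster than the first sampling
    interval (checked at generation time from ``fast_step_kon``); substrate
    depletion beyond ``mech.depletion_cap`` is recorded as a warning in the
    output metadata, not an error — the model itself assumes constant
    substrate (trace enzyme).
    """
    if mech.two_step is None:
        raise ValueError("mechanistic simulation requires two_step parameters")
    if mech.inh.mode is not InhibitionMode.COMPETITIVE:
        raise ValueError("mechanistic simulator implements the competitive scheme only")
    dt_first = design.t_grid[1] - design.t_grid[0]
    t_half = math.log(2.0) / (mech.fast_step_kon * mech.inh.Ki)
    if t_half >= dt_first:
        raise ValueError(
            f"fast step too slow: E·I equilibration half-time {t_half:.3g} s exceeds "
            f"first sampling interval {dt_first:.3g} s; increase fast_step_kon"
        )
    rng = np.random.default_rng(design.seed)
    S = design.substrate_concs[0]
    t = np.asarray(design.t_grid)
    warnings: list[str] = []
    records: list[dict[str, Any]] = []
    for I in design.inhibitor_concs:
        clean = _integrate_two_step(t, S, float(I), mech)
        depletion = clean[-1] / mech.signal_per_um / S
        if depletion > mech.depletion_cap:
            warnings.append(
                f"substrate depletion {100 * depletion:.1f}% at I={I} µM exceeds "
                f"cap {100 * mech.depletion_cap:.0f}%"
            )
        sd = design.noise_sd * float(np.max(np.abs(clean))) if design.noise_sd > 0 else 0.0
        for rep in range(1, design.replicates + 1):
            sig = clean + rng.normal(0.0, sd, size=t.size) if sd > 0 else clean.copy()
            records.extend(
                {
                    "time_s": float(tt),
                    "signal_au": float(ss),
                    "inhibitor_um": float(I),
                    "substrate_um": float(S),
                    "replicate": rep,
                }
                for tt, ss in zip(t, sig)
            )
    for w in warnings:
        logger.warning(w)
    meta = {
        "kind": "progress_mechanistic",
        "design": design.as_dict(),
        "mechanism": mech.as_dict(),
        "warnings": warnings,
    }
    return _progress_frame(records, meta)


def simulate_steady_state(design: AssayDesign, mech: MechanismSpec) -> pd.DataFrame:
    """Simulate a steady-state velocity grid over the design's [S]×[I] span.

    ``v = velocity(S, I) · (1 + ε)`` with multiplicative Gaussian ε of
    σ = ``design.noise_sd``; deterministic given the seed.
    """
    if len(set(design.substrate_concs)) < 2 or len(set(design.inhibitor_concs)) < 2:
        raise ValueError("steady-state design needs >= 2 distinct S and >= 2 distinct I")
    rng = np.random.default_rng(design.seed)
    records = []
    for S in design.substrate_concs:
        for I in design.inhibitor_concs:
            v0 = velocity(S, I, mech.mm, mech.inh)
            for rep in range(1, design.replicates + 1):
                eps = rng.normal(0.0, design.noise_sd) if design.noise_sd > 0 else 0.0
                records.append(
                    {
                        "substrate_um": float(S),
                        "inhibitor_um": float(I),
                        "v_au_per_s": float(v0 * (1.0 + eps)),
                        "replicate": rep,
                    }
                )
    df = pd.DataFrame.from_records(records, columns=VELOCITY_COLUMNS)
    df.attrs["meta"] = {
        "kind": "steady_state",
        "design": design.as_dict(),
        "mechanism": mech.as_dict(),
        "warnings": [],
    }
    return df


def simulate_dose_response(
    design: AssayDesign,
    p: DoseResponseParams,
    noise_pct_sd: float = 2.0,
) -> pd.DataFrame:
    """Simulate a percent-inhibition dose–response table.

    Additive Gaussian noise of σ = ``noise_pct_sd`` percentage points;
    deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    records = []
    for I in design.inhibitor_concs:
        y0 = dose_response(I, p)
        for rep in range(1, design.replicates + 1):
            eps = rng.normal(0.0, noise_pct_sd) if noise_pct_sd > 0 else 0.0
            records.append(
                {"inhibitor_um": float(I), "inhibition_pct": float(y0 + eps), "replicate": rep}
            )
    df = pd.DataFrame.from_records(records, columns=DOSE_COLUMNS)
    df.attrs["meta"] = {
        "kind": "dose_response",
        "design": design.as_dict(),
        "dose_response": dataclasses.asdict(p),
        "noise_pct_sd": noise_pct_sd,
        "warnings": [],
    }
    return df


def write_dataset(df: pd.DataFrame, csv_path: str | Path) -> Path:
    """Write a tidy dataset to CSV with a JSON metadata sidecar.

    The sidecar (``<stem>.meta.json``) holds the generating parameters,
    design and warnings from ``df.attrs['meta']``.
    """
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(csv_path, index=False)
    meta = df.attrs.get("meta", {})
    sidecar = csv_path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return csv_path


def read_dataset(csv_path: str | Path, kind: str | None = None) -> pd.DataFrame:
    """Read a tidy CSV dataset, validating its column contract.

    ``kind`` may be one of ``progress``, ``velocity``, ``dose`` or ``kobs``
    to enforce the corresponding column set; metadata is restored from the
    sidecar when present.
    """
    csv_path = Path(csv_path)
    try:
        df = pd.read_csv(csv_path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise ValueError(f"malformed CSV {csv_path}: {exc}") from exc
    contracts = {
        "progress": PROGRESS_COLUMNS,
        "velocity": VELOCITY_COLUMNS,
        "dose": DOSE_COLUMNS,
        "kobs": KOBS_COLUMNS[:2],
    }
    if kind is not None:
        require_columns(df, contracts[kind], str(csv_path))
    sidecar = csv_path.with_suffix(".meta.json")
    if sidecar.exists():
        df.attrs["meta"] = json.loads(sidecar.read_text())
    return df


def require_columns(df: pd.DataFrame, cols: Sequence[str], context: str = "dataset") -> None:
    """Raise ``ValueError`` naming the first missing required column."""
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{context}: missing required column '{c}'")
        if df[c].isna().any():
            bad = int(df.index[df[c].isna()][0])
            raise ValueError(f"{context}: column '{c}' has missing value at row {bad}")


# ===========================================================================
# SECTION 3 — inference
# ===========================================================================


@dataclass
class FitResult:
    """Outcome of one nonlinear (or linear) least-squares fit.

    ``flags`` carries data-driven caveats ("kobs_unidentifiable",
    "activation", "poorly_constrained", "ic50_above_max_tested", ...);
    a flagged result is still returned, never raised.  ``extra`` holds
    model-comparison diagnostics such as the straight-line AICc.
    """

    model_label: str
    params: dict[str, float]
    se: Optional[dict[str, float]]
    rss: float
    n: int
    nparams: int
    converged: bool
    aicc: float
    flags: list[str] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": self.model_label,
            "params": self.params,
            "se": self.se,
            "rss": self.rss,
            "n": self.n,
            "nparams": self.nparams,
            "converged": self.converged,
            "aicc": self.aicc,
            "flags": list(self.flags),
            "extra": {k: v for k, v in self.extra.items() if _json_safe(v)},
        }


def _json_safe(v: Any) -> bool:
    return isinstance(v, (int, float, str, bool, type(None), list, dict))


def _aicc(rss: float, n: int, k: int, yscale: float = 1.0) -> float:
    """Small-sample corrected Akaike criterion from a least-squares RSS.

    The RSS is floored at machine-noise level relative to the data scale so
    that nested models fitting noiseless data exactly tie (and the simpler
    one then wins on the parameter penalty) instead of being ranked by
    round-off.
    """
    floor = n * (1e-10 * max(yscale, 1e-300)) ** 2
    rss = max(rss, floor)
    if n - k - 1 <= 0:
        return math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS line y = a + b·x; returns (a, b, rss)."""
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


@dataclass
class _NLS:
    """Raw nonlinear least-squares outcome (internal)."""

    params: np.ndarray
    se: Optional[np.ndarray]
    rss: float
    converged: bool


def _nls(
    residual,
    p0: Sequence[float],
    bounds: tuple[Sequence[float], Sequence[float]],
    n_obs: int,
) -> _NLS:
    """Trust-region least squares with Gauss–Newton standard errors.

    SEs come from the linearised covariance ``(JᵀJ)⁻¹ · rss/(n−k)``; they
    are omitted when the Jacobian is singular or there are no residual
    degrees of freedom.
    """
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    p0 = np.clip(np.asarray(p0, dtype=float), lo + 1e-300, hi)
    res = least_squares(residual, p0, bounds=(lo, hi), method="trf", **_LSQ_TOL)
    rss = 2.0 * float(res.cost)
    se: Optional[np.ndarray] = None
    dof = n_obs - p0.size
    if res.status > 0 and dof > 0:
        try:
            cov = np.linalg.inv(res.jac.T @ res.jac) * (rss / dof)
            diag = np.diag(cov)
            if np.all(np.isfinite(diag)) and np.all(diag >= 0):
                se = np.sqrt(diag)
        except np.linalg.LinAlgError:
            se = None
    return _NLS(params=res.x, se=se, rss=rss, converged=res.status > 0)


def _multistart_nls(
    residual,
    p0: np.ndarray,
    bounds: tuple[Sequence[float], Sequence[float]],
    n_obs: int,
    n_starts: int = 5,
    jitter_sd: float = 0.5,
    rng_seed: int = 20180232,
) -> Optional[_NLS]:
    """Run the fit from ``p0`` and log-jittered restarts, keep the best.

    The RNG is fixed so repeated fits are bit-identical; jitter is
    multiplicative (lognormal) so positivity constraints survive it.
    """
    rng = np.random.default_rng(rng_seed)
    best: Optional[_NLS] = None
    for i in range(n_starts):
        start = p0 if i == 0 else p0 * np.exp(rng.normal(0.0, jitter_sd, size=p0.size))
        try:
            fit = _nls(residual, start, bounds, n_obs)
        except Exception:  # pragma: no cover - trf is robust
            continue
        if fit.converged and (best is None or fit.rss < best.rss):
            best = fit
    return best


def fit_progress_curve(
    times: np.ndarray | Sequence[float],
    signal: np.ndarray | Sequence[float],
    weights: np.ndarray | None = None,
) -> FitResult:
    """Fit one progress curve to the slow-binding closed form.

    Initial guesses are data-driven: kobs is profiled on a log grid (the
    model is linear in vi, vs given kobs), then all three parameters are
    refined by Levenberg–Marquardt.  A straight-line fit is always computed
    for comparison; if the curved model does not beat it by the AICc
    parsimony margin the result is flagged ``kobs_unidentifiable``.
    ``vs > vi`` is flagged ``activation``.  Non-convergence yields a
    flagged result, not an exception.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size != y.size:
        raise ValueError("times and signal must have equal length")
    if t.size < 8:
        raise ValueError(f"need >= 8 time points, got {t.size}")
    order = np.argsort(t)
    t, y = t[order], y[order]
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)[order]
    yscale = float(np.max(np.abs(y))) or 1.0
    t_max = float(t[-1])

    # Straight-line reference (2 params).
    a_lin, b_lin, rss_lin = _line_fit(t, y)
    aicc_line = _aicc(rss_lin, t.size, 2, yscale)

    # Profile kobs: Eq is linear in (vi, vs) at fixed kobs.
    best = None
    for k in np.logspace(math.log10(0.2 / t_max), math.log10(200.0 / t_max), 40):
        g = -np.expm1(-k * t) / k  # coefficient of vi
        A = np.column_stack([g, t - g]) * w[:, None]
        coef, *_ = np.linalg.lstsq(A, y * w, rcond=None)
        resid = y * w - A @ coef
        rss = float(resid @ resid)
        if best is None or rss < best[3]:
            best = (k, max(coef[0], 0.0), max(coef[1], 0.0), rss)
    k0, vi0, vs0, _ = best

    def model_y(p: np.ndarray) -> np.ndarray:
        vi, vs, kobs = p
        return vs * t + (vi - vs) / kobs * (-np.expm1(-kobs * t))

    fit = _nls(
        lambda p: w * (model_y(p) - y),
        [max(vi0, 1e-12 * yscale), max(vs0, 0.0), k0],
        ([0.0, 0.0, 1e-4 / t_max], [np.inf, np.inf, 1e4 / t_max]),
        t.size,
    )
    converged = fit.converged

    flags: list[str] = []
    if converged:
        p = dict(zip(("vi", "vs", "kobs"), (float(x) for x in fit.params)))
        se = dict(zip(("vi", "vs", "kobs"), (float(x) for x in fit.se))) if fit.se is not None else None
        rss = float(np.sum((y - model_y(fit.params)) ** 2))
    else:
        p = {"vi": vi0, "vs": vs0, "kobs": k0}
        se, rss = None, math.inf
        flags.append("not_converged")
    aicc_eq = _aicc(rss, t.size, 3, yscale)
    if not (aicc_eq < aicc_line - AICC_PARSIMONY_MARGIN):
        flags.append("kobs_unidentifiable")
    if p["vs"] > p["vi"] * (1.0 + 1e-6):
        flags.append("activation")
    return FitResult(
        model_label="slow_binding_progress",
        params=p,
        se=se if converged else None,
        rss=rss,
        n=t.size,
        nparams=3,
        converged=converged,
        aicc=aicc_eq,
        flags=flags,
        extra={"aicc_line": aicc_line, "line_slope": b_lin, "line_intercept": a_lin},
    )


def extract_kobs_series(progress: pd.DataFrame, include_zero: bool = False) -> pd.DataFrame:
    """Fit every progress curve of a tidy dataset and tabulate kobs vs [I].

    Replicates at one inhibitor concentration are pooled into a single fit
    (all time points enter one least-squares problem): kobs estimates from
    individual noisy curves are strongly right-skewed near the low end of
    the transient, and averaging per-replicate estimates propagates that
    skew into the downstream k4 extrapolation, whereas the pooled fit does
    not.  The kobs SE is the pooled fit's standard error.  The
    inhibitor-free control is excluded by default: without inhibitor there
    is no slow transition to time.  Per-concentration fits are kept in
    ``df.attrs['curve_fits']``.
    """
    require_columns(progress, PROGRESS_COLUMNS, "progress dataset")
    curve_fits: list[dict[str, Any]] = []
    rows = []
    for I, sub in progress.groupby("inhibitor_um"):
        f = fit_progress_curve(sub["time_s"].to_numpy(), sub["signal_au"].to_numpy())
        curve_fits.append(
            {"inhibitor_um": float(I), "n_replicates": int(sub["replicate"].nunique()), "fit": f}
        )
        if I == 0 and not include_zero:
            continue
        if not f.converged or "kobs_unidentifiable" in f.flags:
            continue
        rows.append(
            {
                "inhibitor_um": float(I),
                "kobs_per_s": f.params["kobs"],
                "kobs_se": (f.se or {}).get("kobs", math.nan),
                "n_curves": int(sub["replicate"].nunique()),
            }
        )
    out = pd.DataFrame(rows, columns=KOBS_COLUMNS + ["n_curves"])
    out.attrs["curve_fits"] = curve_fits
    return out


def fit_kobs_hyperbola(series: pd.DataFrame, weighted: bool = True) -> FitResult:
    """Fit the kobs-vs-[I] hyperbola of the two-step binding mechanism.

    Requires >= 4 distinct inhibitor concentrations.  Weighted least
    squares (1/se²) is used when the series carries finite ``kobs_se`` and
    ``weighted`` is True.  The fit is multi-start (5 jittered starts, fixed
    RNG) because the reverse rate k4 is weakly identified when it is much
    smaller than k3.  Kiapp beyond 10× the largest tested concentration, or
    non-convergence, flags the result ``poorly_constrained``.
    """
    require_columns(series, KOBS_COLUMNS[:2], "kobs series")
    I = series["inhibitor_um"].to_numpy(dtype=float)
    y = series["kobs_per_s"].to_numpy(dtype=float)
    if np.unique(I).size < 4:
        raise ValueError(f"need >= 4 distinct inhibitor concentrations, got {np.unique(I).size}")
    if np.any(y <= 0):
        raise ValueError("kobs values must be > 0")
    w = None
    if weighted and "kobs_se" in series.columns:
        se = series["kobs_se"].to_numpy(dtype=float)
        if np.all(np.isfinite(se)) and np.all(se > 0):
            w = 1.0 / se

    a_lin, b_lin, _ = _line_fit(I, y)
    k4_0 = max(a_lin, 1e-2 * float(np.min(y)))
    k3_0 = max(float(np.max(y) - np.min(y)), 1e-3 * float(np.max(y)))
    kiapp_0 = float(np.median(I[I > 0])) if np.any(I > 0) else 1.0
    ww = w if w is not None else np.ones_like(y)

    def resid(p: np.ndarray) -> np.ndarray:
        k3, k4, kiapp = p
        return ww * (k4 + k3 * I / (kiapp + I) - y)

    res = _multistart_nls(
        resid,
        np.array([k3_0, k4_0, kiapp_0]),
        ([1e-12, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        I.size,
    )
    flags: list[str] = []
    if res is None:
        return FitResult(
            model_label="kobs_two_step_hyperbola",
            params={"k3": k3_0, "k4": k4_0, "Kiapp": kiapp_0},
            se=None,
            rss=math.inf,
            n=I.size,
            nparams=3,
            converged=False,
            aicc=math.inf,
            flags=["not_converged", "poorly_constrained"],
        )
    p = dict(zip(("k3", "k4", "Kiapp"), (float(x) for x in res.params)))
    se = dict(zip(("k3", "k4", "Kiapp"), (float(x) for x in res.se))) if res.se is not None else None
    rss = float(np.sum((y - (p["k4"] + p["k3"] * I / (p["Kiapp"] + I))) ** 2))
    # flat series: k3 collapses to its bound and Kiapp loses all leverage
    if p["Kiapp"] > 10.0 * float(np.max(I)) or p["k3"] <= 2e-12 or se is None:
        flags.append("poorly_constrained")
    if p["k3"] + p["k4"] > 0:
        ki_star = p["Kiapp"] * p["k4"] / (p["k3"] + p["k4"])
    else:  # pragma: no cover
        ki_star = math.nan
    return FitResult(
        model_label="kobs_two_step_hyperbola",
        params=p,
        se=se,
        rss=rss,
        n=I.size,
        nparams=3,
        converged=True,
        aicc=_aicc(rss, I.size, 3, float(np.max(y))),
        flags=flags,
        extra={"overall_ki_star_um": ki_star, "line_intercept": a_lin, "line_slope": b_lin},
    )


def classify_mechanism(series: pd.DataFrame) -> str:
    """Discriminate one-step from two-step binding from a kobs-vs-[I] series.

    Compares the straight line ``kobs = a + b·[I]`` (one-step binding)
    against the saturating hyperbola (two-step) by AICc; ties within the
    parsimony margin go to ``one_step``.  Returns ``"one_step"`` or
    ``"two_step"``.
    """
    require_columns(series, KOBS_COLUMNS[:2], "kobs series")
    I = series["inhibitor_um"].to_numpy(dtype=float)
    y = series["kobs_per_s"].to_numpy(dtype=float)
    if np.unique(I).size < 4:
        raise ValueError(f"need >= 4 distinct inhibitor concentrations, got {np.unique(I).size}")
    _, _, rss_lin = _line_fit(I, y)
    aicc_lin = _aicc(rss_lin, I.size, 2, float(np.max(y)))
    hyp = fit_kobs_hyperbola(series, weighted=False)
    if not hyp.converged:
        return "one_step"
    return "two_step" if aicc_lin - hyp.aicc >= AICC_PARSIMONY_MARGIN else "one_step"


# --- inhibition-mode classification ----------------------------------------

_MODE_MODELS: dict[str, tuple[tuple[str, ...], Any]] = {
    "competitive": (
        ("Vmax", "Km", "Ki"),
        lambda S, I, Vmax, Km, Ki: Vmax * S / (Km * (1 + I / Ki) + S),
    ),
    "uncompetitive": (
        ("Vmax", "Km", "Ki"),
        lambda S, I, Vmax, Km, Ki: Vmax * S / (Km + S * (1 + I / Ki)),
    ),
    "noncompetitive": (
        ("Vmax", "Km", "Ki"),
        lambda S, I, Vmax, Km, Ki: Vmax * S / ((Km + S) * (1 + I / Ki)),
    ),
    "mixed": (
        ("Vmax", "Km", "Ki", "alpha"),
        lambda S, I, Vmax, Km, Ki, alpha: Vmax * S / (Km * (1 + I / Ki) + S * (1 + I / (alpha * Ki))),
    ),
}


@dataclass
class DixonResult:
    """Dixon-plot Ki estimate with its supporting geometry."""

    ki_um: float
    ki_se: Optional[float]
    intersections_um: list[float]
    lines: dict[float, tuple[float, float]]  # S -> (intercept, slope) of 1/v vs I

    def to_dict(self) -> dict[str, Any]:
        return {
            "ki_um": self.ki_um,
            "ki_se_um": self.ki_se,
            "intersections_um": self.intersections_um,
            "lines_1_over_v_vs_I": {str(s): list(ab) for s, ab in self.lines.items()},
        }


@dataclass
class ModeCall:
    """Inhibition-mode classification with its evidence.

    ``aicc_table`` ranks the four candidate rate laws; the chosen mode
    minimises AICc (ties broken toward fewer parameters).  The
    Lineweaver–Burk intercept-equality statistic tests the competitive
    signature of a common 1/Vmax intercept across inhibitor concentrations;
    the Dixon estimate is carried as the classical plot-based diagnostic.
    """

    mode: str
    ki_um: float
    ki_se: Optional[float]
    alpha: Optional[float]
    aicc_table: dict[str, float]
    fits: dict[str, FitResult]
    lb_intercepts: dict[float, tuple[float, float]]  # I -> (intercept, se)
    lb_intercept_stat: float
    lb_intercept_p: float
    dixon: Optional[DixonResult]

    def to_dict(self) -> dict[str, Any]:
        return {
            "mode": self.mode,
            "ki_um": self.ki_um,
            "ki_se_um": self.ki_se,
            "alpha": self.alpha,
            "aicc_table": self.aicc_table,
            "fits": {k: f.to_dict() for k, f in self.fits.items()},
            "lineweaver_burk": {
                "intercepts_by_inhibitor_um": {
                    str(i): {"intercept": a, "se": s} for i, (a, s) in self.lb_intercepts.items()
                },
                "common_intercept_chi2": self.lb_intercept_stat,
                "common_intercept_p": self.lb_intercept_p,
            },
            "dixon": self.dixon.to_dict() if self.dixon else None,
        }


def _fit_rate_law(label: str, S: np.ndarray, I: np.ndarray, v: np.ndarray) -> FitResult:
    names, fn = _MODE_MODELS[label]
    p0 = {
        "Vmax": 1.5 * float(np.max(v)),
        "Km": float(np.median(S)),
        "Ki": float(np.median(I[I > 0])) if np.any(I > 0) else 1.0,
        "alpha": 2.0,
    }
    lo = {"Vmax": 1e-300, "Km": 1e-9, "Ki": 1e-9, "alpha": 1e-3}
    hi = {"Vmax": np.inf, "Km": np.inf, "Ki": np.inf, "alpha": 1e3}

    def resid(p: np.ndarray) -> np.ndarray:
        return fn(S, I, **dict(zip(names, p))) - v

    res = _multistart_nls(
        resid,
        np.array([p0[n] for n in names]),
        ([lo[n] for n in names], [hi[n] for n in names]),
        v.size,
    )
    if res is None:
        return FitResult(label, {}, None, math.inf, v.size, len(names), False, math.inf,
                         flags=["not_converged"])
    p = {name: float(x) for name, x in zip(names, res.params)}
    se = {name: float(x) for name, x in zip(names, res.se)} if res.se is not None else None
    rss = float(np.sum((v - fn(S, I, **p)) ** 2))
    return FitResult(
        model_label=label,
        params=p,
        se=se,
        rss=rss,
        n=v.size,
        nparams=len(names),
        converged=True,
        aicc=_aicc(rss, v.size, len(names), float(np.max(v))),
    )


def classify_mode(grid: pd.DataFrame) -> ModeCall:
    """Classify the inhibition mode from a steady-state velocity grid.

    Fits the competitive, uncompetitive, noncompetitive and mixed global
    rate laws and selects by AICc (ties within the parsimony margin and
    exact ties go to the model with fewer parameters).  Also reports per-
    inhibitor Lineweaver–Burk regressions with a χ² test of a common
    1/Vmax intercept — the classical visual signature of competitive
    inhibition — and, when the Dixon construction is defined, the Dixon Ki.
    """
    require_columns(grid, VELOCITY_COLUMNS, "velocity grid")
    S = grid["substrate_um"].to_numpy(dtype=float)
    I = grid["inhibitor_um"].to_numpy(dtype=float)
    v = grid["v_au_per_s"].to_numpy(dtype=float)
    if np.unique(S).size < 2:
        raise ValueError("singular design: need >= 2 distinct substrate concentrations")
    if np.unique(I).size < 2:
        raise ValueError("need >= 2 distinct inhibitor concentrations")
    if np.any(v <= 0):
        raise ValueError("velocities must be > 0")

    fits = {label: _fit_rate_law(label, S, I, v) for label in _MODE_MODELS}
    ranked = sorted(fits.values(), key=lambda f: (round(f.aicc, 6), f.nparams))
    best = ranked[0]
    # parsimony: if a simpler model is within the margin of the top, take it
    for f in ranked[1:]:
        if f.nparams < best.nparams and f.aicc - ranked[0].aicc < AICC_PARSIMONY_MARGIN:
            best = f
            break

    # Lineweaver–Burk diagnostic: 1/v on 1/S per inhibitor concentration.
    intercepts: dict[float, tuple[float, float]] = {}
    for i_val, sub in grid.groupby("inhibitor_um"):
        if sub["substrate_um"].nunique() < 3:
            continue
        reg = stats.linregress(1.0 / sub["substrate_um"], 1.0 / sub["v_au_per_s"])
        intercepts[float(i_val)] = (float(reg.intercept), float(reg.intercept_stderr))
    if len(intercepts) >= 2 and all(s > 0 for _, s in intercepts.values()):
        b = np.array([a for a, _ in intercepts.values()])
        se_b = np.array([s for _, s in intercepts.values()])
        wmean = float(np.sum(b / se_b**2) / np.sum(1.0 / se_b**2))
        chi2 = float(np.sum(((b - wmean) / se_b) ** 2))
        pval = float(stats.chi2.sf(chi2, len(b) - 1))
    else:
        chi2, pval = math.nan, math.nan

    try:
        dixon = dixon_ki(grid)
    except ValueError:
        dixon = None

    return ModeCall(
        mode=best.model_label,
        ki_um=best.params.get("Ki", math.nan),
        ki_se=(best.se or {}).get("Ki"),
        alpha=best.params.get("alpha"),
        aicc_table={k: f.aicc for k, f in fits.items()},
        fits=fits,
        lb_intercepts=intercepts,
        lb_intercept_stat=chi2,
        lb_intercept_p=pval,
        dixon=dixon,
    )


def dixon_ki(grid: pd.DataFrame) -> DixonResult:
    """Estimate Ki from the Dixon construction (1/v vs [I] at fixed [S]).

    For a competitive inhibitor the Dixon lines at different substrate
    concentrations intersect at ``[I] = −Ki``; the estimate is the negated
    mean abscissa of all pairwise line intersections, with the SEM over
    pairs as its uncertainty.  Near-parallel pairs (the uncompetitive
    pattern, whose Dixon lines share the slope ``1/(Vmax·Ki)``) are
    excluded; if no pair intersects, the construction is undefined and a
    ``ValueError`` is raised.
    """
    require_columns(grid, VELOCITY_COLUMNS, "velocity grid")
    if grid["substrate_um"].nunique() < 2:
        raise ValueError("Dixon analysis needs >= 2 distinct substrate concentrations")
    lines: dict[float, tuple[float, float]] = {}
    for s_val, sub in grid.groupby("substrate_um"):
        if sub["inhibitor_um"].nunique() < 3:
            raise ValueError(
                f"Dixon analysis needs >= 3 distinct inhibitor concentrations per substrate, "
                f"got {sub['inhibitor_um'].nunique()} at S={s_val} µM"
            )
        reg = stats.linregress(sub["inhibitor_um"], 1.0 / sub["v_au_per_s"])
        lines[float(s_val)] = (float(reg.intercept), float(reg.slope))
    s_vals = sorted(lines)
    slopes = np.array([lines[s][1] for s in s_vals])
    slope_scale = float(np.max(np.abs(slopes))) or 1.0
    xs = []
    for idx, s1 in enumerate(s_vals):
        for s2 in s_vals[idx + 1 :]:
            a1, b1 = lines[s1]
            a2, b2 = lines[s2]
            if abs(b1 - b2) < 1e-6 * slope_scale:
                continue  # parallel pair: no intersection
            xs.append((a2 - a1) / (b1 - b2))
    if not xs:
        raise ValueError("Dixon intersection undefined: lines are parallel (uncompetitive pattern?)")
    xs_arr = np.asarray(xs)
    ki = float(-np.mean(xs_arr))
    se = float(np.std(xs_arr, ddof=1) / math.sqrt(xs_arr.size)) if xs_arr.size > 1 else None
    return DixonResult(ki_um=ki, ki_se=se, intersections_um=[float(x) for x in xs], lines=lines)


def fit_ic50(
    table: pd.DataFrame,
    fix_top: Optional[float] = 100.0,
    fix_bottom: Optional[float] = 0.0,
) -> FitResult:
    """Fit the log-logistic dose–response model to percent-inhibition data.

    Plateaus are fixed at (0, 100) by default — appropriate when the data
    are normalised to an uninhibited control — and may be freed by passing
    ``None``.  IC50 is fit on a log scale for positivity and stability.
    If the observed inhibition never reaches 50% the point estimate is
    withheld and the result flagged ``ic50_above_max_tested``.
    """
    require_columns(table, DOSE_COLUMNS[:2], "dose-response table")
    tab = table[table["inhibitor_um"] > 0]
    I = tab["inhibitor_um"].to_numpy(dtype=float)
    y = tab["inhibition_pct"].to_numpy(dtype=float)
    if np.unique(I).size < 4:
        raise ValueError(f"need >= 4 distinct inhibitor concentrations, got {np.unique(I).size}")
    mean_by_conc = tab.groupby("inhibitor_um")["inhibition_pct"].mean()
    if mean_by_conc.max() < 50.0:
        return FitResult(
            model_label="log_logistic_ic50",
            params={"ic50_lower_bound_um": float(np.max(I))},
            se=None,
            rss=math.nan,
            n=I.size,
            nparams=0,
            converged=False,
            aicc=math.inf,
            flags=["ic50_above_max_tested"],
            extra={"max_mean_inhibition_pct": float(mean_by_conc.max())},
        )

    lo_l, hi_l = math.log10(float(np.min(I))), math.log10(float(np.max(I)))
    names = ["log10_ic50", "hill"]
    p0 = [0.5 * (lo_l + hi_l), 1.0]
    lo_b = [lo_l - 3.0, 0.05]
    hi_b = [hi_l + 3.0, 20.0]
    if fix_top is None:
        names.append("top"); p0.append(100.0); lo_b.append(0.0); hi_b.append(200.0)
    if fix_bottom is None:
        names.append("bottom"); p0.append(0.0); lo_b.append(-100.0); hi_b.append(100.0)

    def model_y(p: np.ndarray) -> np.ndarray:
        d = dict(zip(names, p))
        top = d.get("top", fix_top)
        bottom = d.get("bottom", fix_bottom)
        return bottom + (top - bottom) / (1.0 + (10.0 ** d["log10_ic50"] / I) ** d["hill"])

    res = _multistart_nls(
        lambda p: model_y(p) - y, np.array(p0), (lo_b, hi_b), I.size, jitter_sd=0.25
    )
    if res is None:
        return FitResult("log_logistic_ic50", {}, None, math.inf, I.size, 2, False, math.inf,
                         flags=["not_converged"])
    d = dict(zip(names, (float(x) for x in res.params)))
    ic50 = 10.0 ** d["log10_ic50"]
    p = {
        "ic50": ic50,
        "hill": d["hill"],
        "top": d.get("top", fix_top),
        "bottom": d.get("bottom", fix_bottom),
    }
    se = None
    if res.se is not None:
        d_se = dict(zip(names, (float(x) for x in res.se)))
        se = {"ic50": math.log(10.0) * ic50 * d_se["log10_ic50"], "hill": d_se["hill"]}
    nvary = len(names)
    rss = float(np.sum((y - model_y(res.params)) ** 2))
    return FitResult(
        model_label="log_logistic_ic50",
        params=p,
        se=se,
        rss=rss,
        n=I.size,
        nparams=nvary,
        converged=True,
        aicc=_aicc(rss, I.size, nvary, 100.0),
    )


# --- per-compound orchestration --------------------------------------------


@dataclass
class InhibitionResult:
    """Per-compound inhibition report.

    ``mechanism_class`` is one of ``no_time_dependence``, ``one_step`` or
    ``two_step`` (None when no progress curves were supplied); two-step
    rate parameters are present exactly when the class is ``two_step``.
    """

    compound_id: str
    mode: Optional[ModeCall] = None
    ic50: Optional[FitResult] = None
    ic50_preincubated: Optional[FitResult] = None
    mechanism_class: Optional[str] = None
    two_step: Optional[FitResult] = None
    kobs_series: Optional[pd.DataFrame] = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"compound_id": self.compound_id, "flags": list(self.flags)}
        if self.mode is not None:
            d["mode"] = self.mode.to_dict()
        if self.ic50 is not None:
            d["ic50_um"] = self.ic50.params.get("ic50")
            d["ic50_fit"] = self.ic50.to_dict()
        if self.ic50_preincubated is not None:
            d["ic50_preincubated_um"] = self.ic50_preincubated.params.get("ic50")
            d["ic50_preincubated_fit"] = self.ic50_preincubated.to_dict()
        d["mechanism_class"] = self.mechanism_class
        if self.two_step is not None:
            d["two_step"] = {
                "k3_per_s": self.two_step.params["k3"],
                "k4_per_s": self.two_step.params["k4"],
                "kiapp_um": self.two_step.params["Kiapp"],
                "overall_ki_star_um": self.two_step.extra.get("overall_ki_star_um"),
                "fit": self.two_step.to_dict(),
            }
        if self.kobs_series is not None:
            d["kobs_series"] = self.kobs_series.to_dict(orient="records")
        return d

    def summary(self) -> str:
        """Human-readable one-compound summary table."""
        lines = [f"compound: {self.compound_id}"]
        if self.mode is not None:
            ki = f"{self.mode.ki_um:.3g}"
            if self.mode.ki_se is not None:
                ki += f" ± {self.mode.ki_se:.2g}"
            lines.append(f"  inhibition mode : {self.mode.mode} (Ki = {ki} µM)")
            if self.mode.dixon is not None:
                lines.append(f"  Dixon Ki        : {self.mode.dixon.ki_um:.3g} µM")
        for label, fit in (("IC50", self.ic50), ("IC50 (preincubated)", self.ic50_preincubated)):
            if fit is None:
                continue
            if fit.converged:
                lines.append(f"  {label:<16}: {fit.params['ic50']:.3g} µM")
            else:
                lines.append(f"  {label:<16}: {', '.join(fit.flags)}")
        if self.mechanism_class is not None:
            lines.append(f"  binding kinetics: {self.mechanism_class}")
        if self.two_step is not None:
            p = self.two_step.params
            lines.append(
                f"    k3 = {p['k3']:.3g} s⁻¹, k4 = {p['k4']:.3g} s⁻¹, "
                f"Kiapp = {p['Kiapp']:.3g} µM"
            )
        if self.flags:
            lines.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(lines)


def characterize_compound(
    compound_id: str,
    progress: Optional[pd.DataFrame] = None,
    steady_state: Optional[pd.DataFrame] = None,
    dose: Optional[pd.DataFrame] = None,
    dose_preincubated: Optional[pd.DataFrame] = None,
) -> InhibitionResult:
    """Run every applicable analysis stage for one compound.

    Mode classification needs the steady-state grid; IC50s need the
    dose–response tables; the binding-kinetics class needs progress curves.
    The class is ``no_time_dependence`` when no inhibited curve beats a
    straight line by the AICc parsimony margin, otherwise the kobs-vs-[I]
    series is classified as one-step or two-step, and the two-step rate
    parameters are fit when that mechanism wins.
    """
    if progress is None and steady_state is None and dose is None and dose_preincubated is None:
        raise ValueError("at least one input dataset is required")
    result = InhibitionResult(compound_id=compound_id)

    if steady_state is not None:
        result.mode = classify_mode(steady_state)

    if dose is not None:
        result.ic50 = fit_ic50(dose)
        if not result.ic50.converged:
            result.flags.extend(result.ic50.flags)
    if dose_preincubated is not None:
        result.ic50_preincubated = fit_ic50(dose_preincubated)
        if not result.ic50_preincubated.converged:
            result.flags.extend(f"preincubated:{f}" for f in result.ic50_preincubated.flags)

    if progress is not None:
        series = extract_kobs_series(progress)
        result.kobs_series = series
        curve_fits = series.attrs.get("curve_fits", [])
        time_dependent = any(
            rec["inhibitor_um"] > 0
            and rec["fit"].converged
            and "kobs_unidentifiable" not in rec["fit"].flags
            for rec in curve_fits
        )
        if not time_dependent:
            result.mechanism_class = "no_time_dependence"
        elif series["inhibitor_um"].nunique() < 4:
            result.mechanism_class = "one_step"
            result.flags.append("kobs_series_too_short")
        else:
            result.mechanism_class = classify_mechanism(series)
            if result.mechanism_class == "two_step":
                result.two_step = fit_kobs_hyperbola(series)
                if result.two_step.flags:
                    result.flags.extend(f"two_step:{f}" for f in result.two_step.flags)
    return result


# ===========================================================================
# SECTION 4 — parameter-recovery studies
# ===========================================================================
# Reproducible Monte-Carlo studies over many seeds; these back the
# acceptance checks and double as examples of full-pipeline use.


def _spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive n child seeds (< 2^31) deterministically from a master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31)


def dixon_recovery_study(
    true_ki_um: float,
    n_seeds: int = 100,
    master_seed: int = 0,
    noise_sd: float = 0.02,
    substrate_concs: Sequence[float] = DEFAULT_SUBSTRATE_SERIES,
    inhibitor_concs: Sequence[float] = (0.0, 12.5, 25.0, 50.0),
) -> pd.DataFrame:
    """Dixon-plot Ki recovery from noisy competitive velocity grids.

    For each seed, simulates a 4×4 [S]×[I] grid under the competitive rate
    law with the given true Ki and multiplicative noise, then estimates Ki
    from the pairwise Dixon-line intersections.  Returns one row per seed
    (columns ``seed``, ``ki_um``).
    """
    mech = MechanismSpec(
        mm=MichaelisMentenParams(DEFAULT_VMAX_AU_PER_S, DEFAULT_KM_UM),
        inh=InhibitionModel(InhibitionMode.COMPETITIVE, true_ki_um),
    )
    rows = []
    for seed in _spawn_seeds(master_seed, n_seeds):
        design = AssayDesign(
            inhibitor_concs=inhibitor_concs,
            substrate_concs=substrate_concs,
            replicates=3,
            noise_sd=noise_sd,
            seed=int(seed),
        )
        grid = simulate_steady_state(design, mech)
        rows.append({"seed": int(seed), "ki_um": dixon_ki(grid).ki_um})
    return pd.DataFrame(rows)


def ic50_recovery_study(
    true_ic50_um: float,
    n_seeds: int = 100,
    master_seed: int = 0,
    noise_pct_sd: float = 2.0,
    inhibitor_concs: Sequence[float] = (6.25, 12.5, 25.0, 50.0, 100.0),
    hill: float = 1.0,
) -> pd.DataFrame:
    """IC50 recovery from noisy log-logistic dose–response tables.

    Simulates triplicate percent-inhibition data on the two-fold series
    with plateaus (0, 100) and additive noise in percentage points, fits
    the log-logistic model, and returns one row per seed (``seed``,
    ``ic50_um``; non-converged fits yield NaN).
    """
    truth = DoseResponseParams(ic50=true_ic50_um, hill=hill)
    rows = []
    for seed in _spawn_seeds(master_seed, n_seeds):
        design = AssayDesign(
            inhibitor_concs=inhibitor_concs, replicates=3, noise_sd=0.0, seed=int(seed)
        )
        table = simulate_dose_response(design, truth, noise_pct_sd=noise_pct_sd)
        fit = fit_ic50(table)
        rows.append(
            {"seed": int(seed), "ic50_um": fit.params.get("ic50", math.nan) if fit.converged else math.nan}
        )
    return pd.DataFrame(rows)


def two_stage_recovery_study(
    truth: TwoStepBindingParams,
    n_seeds: int = 50,
    master_seed: int = 0,
    noise_sd: float = 0.01,
    inhibitor_concs: Sequence[float] = (0.0, 6.25, 12.5, 25.0, 50.0, 100.0),
    mechanistic: bool = True,
) -> pd.DataFrame:
    """Full two-stage slow-binding analysis on simulated progress curves.

    Per seed: simulate progress curves under the two-step competitive
    mechanism (mass-action ODE by default, closed form otherwise) with the
    given true (k3, k4, Kiapp); fit every curve to the slow-binding closed
    form; fit the resulting kobs series to the hyperbola.  Returns one row
    per seed with the recovered ``k3``, ``k4`` and ``kiapp_um``.
    """
    mech = mechanism_from_kiapp(truth)
    rows = []
    for seed in _spawn_seeds(master_seed, n_seeds):
        design = AssayDesign(
            inhibitor_concs=inhibitor_concs, replicates=3, noise_sd=noise_sd, seed=int(seed)
        )
        if mechanistic:
            curves = simulate_progress_mechanistic(design, mech)
        else:
            params = {
                float(I): closed_form_params(mech, design.substrate_concs[0], float(I))
                for I in design.inhibitor_concs
            }
            curves = simulate_progress_closed_form(design, params)
        series = extract_kobs_series(curves)
        fit = fit_kobs_hyperbola(series)
        rows.append(
            {
                "seed": int(seed),
                "k3": fit.params["k3"],
                "k4": fit.params["k4"],
                "kiapp_um": fit.params["Kiapp"],
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)


def mechanism_discrimination_study(
    truth: TwoStepBindingParams,
    n_seeds: int = 100,
    master_seed: int = 0,
    noise_sd: float = 0.01,
    inhibitor_concs: Sequence[float] = (0.0, 3.125, 6.25, 12.5, 25.0, 37.5, 50.0, 75.0, 100.0),
    replicates: int = 3,
) -> pd.DataFrame:
    """One-step vs two-step discrimination accuracy at matched noise.

    Runs the full pipeline (closed-form curves → per-curve fits → kobs
    series → AICc model comparison) on two generating mechanisms: the
    saturating two-step scheme with the given truth, and a one-step scheme
    whose kobs rises linearly with the same initial slope (k4 + k3/Kiapp·[I],
    with vi independent of [I] as direct slow binding implies).  Returns one
    row per (seed, truth_label) with the classifier's call.

    The default design samples eight inhibitor concentrations in triplicate:
    curvature of the hyperbola must be resolved against the small-sample
    AICc penalty, which is punishing for short series — at five
    concentrations even noiseless data barely favour the richer model.
    """
    mech2 = mechanism_from_kiapp(truth)
    S = DEFAULT_SUBSTRATE_UM
    v0 = velocity(S, 0.0, mech2.mm, mech2.inh)
    slope = truth.k3 / truth.Kiapp
    rows = []
    for seed in _spawn_seeds(master_seed, n_seeds):
        design = AssayDesign(
            inhibitor_concs=inhibitor_concs,
            replicates=replicates,
            noise_sd=noise_sd,
            seed=int(seed),
        )
        # two-step arm
        p2 = {float(I): closed_form_params(mech2, S, float(I)) for I in design.inhibitor_concs}
        series2 = extract_kobs_series(simulate_progress_closed_form(design, p2))
        rows.append(
            {"seed": int(seed), "truth": "two_step", "call": classify_mechanism(series2)}
        )
        # one-step arm: kobs linear in [I], vi unaffected by the inhibitor
        p1 = {}
        for I in design.inhibitor_concs:
            kobs = truth.k4 + slope * float(I)
            vs = v0 * truth.k4 / kobs if I > 0 else v0
            p1[float(I)] = SlowBindingCurveParams(vi=v0, vs=vs, kobs=kobs)
        series1 = extract_kobs_series(simulate_progress_closed_form(design, p1))
        rows.append(
            {"seed": int(seed), "truth": "one_step", "call": classify_mechanism(series1)}
        )
    return pd.DataFrame(rows)


# ===========================================================================
# SECTION 5 — run configuration (CLI glue)
# ===========================================================================

from pydantic import BaseModel, ConfigDict, Field, model_validator  # noqa: E402


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DesignConfig(_StrictModel):
    """Schema-validated assay design block (unknown keys rejected)."""

    inhibitor_um: list[float] = Field(default=list(DEFAULT_INHIBITOR_SERIES))
    substrate_um: list[float] = Field(default=[DEFAULT_SUBSTRATE_UM])
    t_end_s: float = 1200.0
    t_step_s: float = 10.0
    replicates: int = 3
    noise_sd: float = 0.01
    seed: int = 0

    def to_design(self) -> AssayDesign:
        n = int(round(self.t_end_s / self.t_step_s))
        return AssayDesign(
            inhibitor_concs=self.inhibitor_um,
            substrate_concs=self.substrate_um,
            t_grid=[i * self.t_step_s for i in range(n + 1)],
            replicates=self.replicates,
            noise_sd=self.noise_sd,
            seed=self.seed,
        )


class TwoStepConfig(_StrictModel):
    k3_per_s: float = 0.0041
    k4_per_s: float = 0.0004
    kiapp_um: float = 35.8

    def to_params(self) -> TwoStepBindingParams:
        return TwoStepBindingParams(self.k3_per_s, self.k4_per_s, self.kiapp_um)


class MechanismConfig(_StrictModel):
    """Generating-mechanism block for simulations."""

    vmax_au_per_s: float = DEFAULT_VMAX_AU_PER_S
    km_um: float = DEFAULT_KM_UM
    mode: Literal["competitive", "uncompetitive", "noncompetitive", "mixed"] = "competitive"
    ki_um: Optional[float] = None  # derived from kiapp when two_step is set
    alpha: float = 1.0
    two_step: Optional[TwoStepConfig] = None
    fast_step_kon_per_um_s: float = DEFAULT_KON_PER_UM_S

    def to_mechanism(self, substrate_um: float) -> MechanismSpec:
        mm = MichaelisMentenParams(self.vmax_au_per_s, self.km_um)
        if self.two_step is not None and self.ki_um is None:
            return mechanism_from_kiapp(
                self.two_step.to_params(), mm, S=substrate_um,
                fast_step_kon=self.fast_step_kon_per_um_s,
            )
        ki = self.ki_um if self.ki_um is not None else 12.452
        return MechanismSpec(
            mm=mm,
            inh=InhibitionModel(InhibitionMode(self.mode), ki, self.alpha),
            two_step=self.two_step.to_params() if self.two_step else None,
            fast_step_kon=self.fast_step_kon_per_um_s,
        )


class DoseConfig(_StrictModel):
    ic50_um: float = 39.7
    hill: float = 1.0
    top_pct: float = 100.0
    bottom_pct: float = 0.0
    noise_pct_sd: float = 2.0

    def to_params(self) -> DoseResponseParams:
        return DoseResponseParams(self.ic50_um, self.hill, self.top_pct, self.bottom_pct)


class RunConfig(_StrictModel):
    """Top-level simulation run configuration.

    ``kind`` selects the generator: mechanistic progress curves,
    steady-state velocity grid, or dose–response table.  Every run records
    this config (with its seed) next to its outputs.
    """

    kind: Literal["progress", "steady_state", "dose_response"] = "progress"
    design: DesignConfig = Field(default_factory=DesignConfig)
    mechanism: MechanismConfig = Field(default_factory=lambda: MechanismConfig(two_step=TwoStepConfig()))
    dose: DoseConfig = Field(default_factory=DoseConfig)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.kind == "steady_state" and len(self.design.substrate_um) < 2:
            # default progress design has one substrate level; widen for grids
            if self.design.substrate_um == [DEFAULT_SUBSTRATE_UM]:
                self.design.substrate_um = list(DEFAULT_SUBSTRATE_SERIES)
        return self


def run_simulation(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute a simulation run: generate the dataset, write ``data.csv``
    with its metadata sidecar, and record the resolved config (including
    the seed) as ``run_config.json``.  Returns the CSV path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = config.design.to_design()
    if config.kind == "progress":
        mech = config.mechanism.to_mechanism(design.substrate_concs[0])
        df = simulate_progress_mechanistic(design, mech)
    elif config.kind == "steady_state":
        mech = config.mechanism.to_mechanism(design.substrate_concs[0])
        df = simulate_steady_state(design, mech)
    else:
        df = simulate_dose_response(design, config.dose.to_params(), config.dose.noise_pct_sd)
    csv_path = write_dataset(df, out / "data.csv")
    (out / "run_config.json").write_text(config.model_dump_json(indent=2) + "\n")
    for w in df.attrs["meta"].get("warnings", []):
        logger.warning("%s", w)
    logger.info("wrote %s (%d rows)", csv_path, len(df))
    return csv_path
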