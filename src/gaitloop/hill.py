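"""Hill-type virtual muscle: the in-silico testbed for protocol evaluation.

The model composes four phenomenological elements on a normalized scale:

    F(t) = Fmax * ( a(t) * fl(L/Lo) * fv(v) + fp(L/Lo) )

* ``a`` — activation, a first-order lag of excitation with separate rise
  (``tau_act``) and fall (``tau_deact``) time constants;
* ``fl`` — active force–length, a Gaussian bell centered at the optimal
  length, fl(1 ± fl_width) = exp(-1);
* ``fv`` — force–velocity, the hyperbolic Hill relation for shortening
  (zero force at ``-vmax``) and a saturating eccentric branch capped at
  1.4x isometric during lengthening;
* ``fp`` — passive elasticity, zero at or below the optimal length and
  exponential above it, reaching Fmax at strain ``passive_strain_ref``.

The constants shipped as defaults are testbed choices for a generic fast
mouse muscle, not measurements; real protocol work supplies its own set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .protocol import CommandWaveform

__all__ = [
    "HillParameters",
    "VoltageExcitationMap",
    "SimResult",
    "activation_from_excitation",
    "active_force_length",
    "force_velocity",
    "passive_force",
    "simulate_force",
]

#: Eccentric force plateau relative to isometric.
ECCENTRIC_CAP = 1.4


@dataclass(frozen=True)
class HillParameters:
    """Constants of the Hill-type model (units: mN, mm, Lo/s, s)."""

    fmax_mn: float = 400.0
    lo_mm: float = 12.0
    vmax_lo_per_s: float = 10.0
    fl_width: float = 0.45
    fv_curvature: float = 0.25
    passive_strain_ref: float = 0.6
    passive_exponent: float = 4.0
    tau_act_s: float = 0.015
    tau_deact_s: float = 0.050

    def __post_init__(self) -> None:
        for name in ("fmax_mn", "lo_mm", "vmax_lo_per_s", "tau_act_s", "tau_deact_s"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.fl_width <= 1:
            raise ValueError("fl_width must lie in (0, 1]")
        if self.fv_curvature <= 0:
            raise ValueError("fv_curvature must be > 0")
        if self.passive_strain_ref < 0 or self.passive_exponent < 0:
            raise ValueError("passive parameters must be >= 0")


@dataclass(frozen=True)
class VoltageExcitationMap:
    """Saturating sigmoid from stimulator voltage to excitation in [0, 1].

    Rebased so zero voltage maps to exactly zero excitation; ``v_half`` is the
    half-activation voltage and ``slope_v`` the sigmoid width.  The default
    saturates near 30 V, where twitch and tetanus responses are maximal.
    """

    v_half: float = 12.0
    slope_v: float = 3.0

    def __post_init__(self) -> None:
        if self.v_half <= 0 or self.slope_v <= 0:
            raise ValueError("v_half and slope_v must be > 0")

    def __call__(self, voltage: np.ndarray) -> np.ndarray:
        v = np.asarray(voltage, dtype=float)
        sig = 1.0 / (1.0 + np.exp(-(v - self.v_half) / self.slope_v))
        sig0 = 1.0 / (1.0 + np.exp(self.v_half / self.slope_v))
        out = (sig - sig0) / (1.0 - sig0)
        return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class SimResult:
    time_s: np.ndarray
    activation: np.ndarray
    norm_length: np.ndarray
    norm_velocity: np.ndarray
    force_mn: np.ndarray
    params: HillParameters = field(repr=False, default=HillParameters())


def activation_from_excitation(excitation: np.ndarray, tau_act_s: float,
                               tau_deact_s: float, dt_s: float,
                               a0: float = 0.0) -> np.ndarray:
    """First-order excitation -> activation dynamics.

    Exact exponential update per step with the rise constant when excitation
    exceeds activation and the fall constant otherwise; for a constant input
    this reproduces the closed-form first-order response at every sample.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    u = np.clip(np.asarray(excitation, dtype=float), 0.0, 1.0)
    a = np.empty_like(u)
    prev = float(np.clip(a0, 0.0, 1.0))
    k_act = 1.0 - np.exp(-dt_s / tau_act_s)
    k_deact = 1.0 - np.exp(-dt_s / tau_deact_s)
    for i, ui in enumerate(u):
        k = k_act if ui > prev else k_deact
        prev = prev + (ui - prev) * k
        a[i] = prev
    return np.clip(a, 0.0, 1.0)


def active_force_length(norm_length: np.ndarray, fl_width: float = 0.45) -> np.ndarray:
    """Gaussian active force-length bell: 1 at Lo, exp(-1) at 1 +/- fl_width."""
    l = np.asarray(norm_length, dtype=float)
    return np.exp(-(((l - 1.0) / fl_width) ** 2))


def force_velocity(norm_velocity: np.ndarray, vmax_lo_per_s: float = 10.0,
                   curvature: float = 0.25) -> np.ndarray:
    """Hill force-velocity relation; velocity in Lo/s, lengthening positive.

    Shortening (v < 0):  fv = (vmax + v) / (vmax - v / curvature), zero at
    -vmax and 1 at rest.  Lengthening (v > 0): a saturating branch
    fv = 1 + (cap - 1) * v / (v + curvature * vmax) rising from 1 toward the
    eccentric plateau ``ECCENTRIC_CAP``.
    """
    v = np.asarray(norm_velocity, dtype=float)
    out = np.empty_like(v)
    short = v < 0
    vs = np.clip(v[short], -vmax_lo_per_s, 0.0)
    out[short] = (vmax_lo_per_s + vs) / (vmax_lo_per_s - vs / curvature)
    vl = v[~short]
    out[~short] = 1.0 + (ECCENTRIC_CAP - 1.0) * vl / (vl + curvature * vmax_lo_per_s)
    return np.maximum(out, 0.0)


def passive_force(norm_length: np.ndarray, strain_ref: float = 0.6,
                  exponent: float = 4.0) -> np.ndarray:
    """Passive elastic force: 0 at or below Lo, exponential above.

    fp = (exp(k * (L/Lo - 1) / e_ref) - 1) / (exp(k) - 1), so fp = 1 (one
    Fmax) at strain ``e_ref``.
    """
    l = np.asarray(norm_length, dtype=float)
    strain = np.maximum(l - 1.0, 0.0)
    if strain_ref == 0 or exponent == 0:
        return np.zeros_like(l)
    return (np.exp(exponent * strain / strain_ref) - 1.0) / (np.exp(exponent) - 1.0)


def simulate_force(params: HillParameters, command: CommandWaveform,
                   voltage_to_excitation: Callable[[np.ndarray], np.ndarray]
                   | None = None) -> SimResult:
    """Simulate the virtual muscle's force response to a command waveform.

    Length follows the command exactly (stiff position servo assumption),
    velocity by central differences, activation by explicit stepping on the
    command grid with sub-stepping when the time constants approach the step.
    """
    if voltage_to_excitation is None:
        voltage_to_excitation = VoltageExcitationMap()
    dt = 1.0 / command.sample_rate_hz
    norm_length = 1.0 + command.delta_length_mm / params.lo_mm
    norm_velocity = np.gradient(norm_length, dt)  # Lo/s; central differences
    exc = voltage_to_excitation(command.voltage_v)
    tau_min = min(params.tau_act_s, params.tau_deact_s)
    n_sub = max(1, int(np.ceil(2.0 * dt / tau_min))) if tau_min < 2.0 * dt else 1
    if n_sub > 1:
        u = np.repeat(exc, n_sub)
        a = activation_from_excitation(u, params.tau_act_s, params.tau_deact_s,
                                       dt / n_sub)[n_sub - 1 :: n_sub]
    else:
        a = activation_from_excitation(exc, params.tau_act_s, params.tau_deact_s, dt)
    fl = active_force_length(norm_length, params.fl_width)
    fv = force_velocity(norm_velocity, params.vmax_lo_per_s, params.fv_curvature)
    fp = passive_force(norm_length, params.passive_strain_ref, params.passive_exponent)
    force = params.fmax_mn * (a * fl * fv + fp)
    force = np.maximum(force, 0.0)
    return SimResult(command.time_s, a, norm_length, norm_velocity, force, params)
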