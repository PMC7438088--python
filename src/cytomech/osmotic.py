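"""Mixture-theory Kedem–Katchalsky model of passive cell volume response.

A round cell in a bath of nonpermeating solute (NaCl at room temperature)
exchanges water across its membrane at a rate set by the osmotic pressure
difference:

    dV/dt = A · L_p · R·θ · (c_i − c_e)

where ``A`` is the volume-dependent surface area of the (assumed spherical)
cell, ``L_p`` the hydraulic permeability in m³/(N·s), ``R·θ`` the thermal
factor converting osmolarity to osmotic pressure, and ``c_i``, ``c_e`` the
intra-/extracellular osmolarities.  Solute is conserved (``dn_i/dt = 0``)
and only a fraction ``φ_i`` of the cell volume is osmotically active water;
the inactive remainder ``(1 − φ_ir)·V_r`` is carried along unchanged, so

    c_i = n_i / (φ_i V),        φ_i = 1 − (1 − φ_ir) V_r / V,

with the subscript ``r`` denoting the reference state at the start of each
osmotic loading step.  At equilibrium the volume ratio has the closed form

    V_∞/V_r = 1 − φ_ir + φ_ir · c_er/c_e.

This module provides the forward simulation of that model under a stepwise
osmotic-loading protocol and the inverse problem: nonlinear least-squares
estimation of ``(L_p, φ_ir)`` per cell per step from a measured volume
trace.

Units: volumes m³, times s, osmolarities mOsm/liter (numerically equal to
mol/m³), ``L_p`` m³/(N·s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "ModelConstants",
    "OsmoticStep",
    "OsmoticProtocol",
    "CellState",
    "CellParams",
    "CellVolumeTrace",
    "MixtureFitResult",
    "QCConfig",
    "surface_area",
    "intracellular_osmolarity",
    "equilibrium_volume_ratio",
    "estimate_phir_from_equilibrium",
    "simulate_volume_response",
    "fit_mixture_model",
    "fit_two_step_sequence",
    "DegenerateStateError",
    "UnidentifiableError",
    "ProtocolMismatchError",
    "QCError",
]


class DegenerateStateError(ValueError):
    """Cell volume at or below its osmotically inactive (solid) fraction."""


class UnidentifiableError(ValueError):
    """The requested parameter carries no signal in the data."""


class ProtocolMismatchError(ValueError):
    """Trace does not cover the osmotic step it is being fitted against."""


class QCError(ValueError):
    """Trace fails a quality-control precondition (e.g. no plateau)."""


class IntegrationError(RuntimeError):
    """ODE integration failed; the message carries the last valid state."""


@dataclass(frozen=True)
class ModelConstants:
    """Physical constants of the transport model.

    ``osmolarity_scale`` converts mOsm/liter to mol/m³; the two units are
    numerically identical so the default is 1.0.  Default temperature is
    room temperature, at which the solute is nonpermeating and the cell
    shows no active volume recovery.
    """

    gas_constant: float = 8.314  # J/(mol K)
    temperature: float = 295.15  # K
    osmolarity_scale: float = 1.0  # (mol/m^3) per (mOsm/liter)

    def __post_init__(self) -> None:
        if self.gas_constant <= 0 or self.temperature <= 0:
            raise ValueError("gas constant and temperature must be positive")

    @property
    def rt(self) -> float:
        """R·θ in J/mol — osmotic pressure per unit osmolarity (mol/m³)."""
        return self.gas_constant * self.temperature


@dataclass(frozen=True)
class OsmoticStep:
    """One osmotic loading step: bath osmolarity held for a duration."""

    osmolarity: float  # mOsm/liter
    duration: float  # s

    def __post_init__(self) -> None:
        if self.osmolarity <= 0:
            raise ValueError(f"osmolarity must be positive, got {self.osmolarity}")
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")


@dataclass(frozen=True)
class OsmoticProtocol:
    """Stepwise osmotic loading protocol.

    The cell is assumed fully equilibrated at ``equilibration_osmolarity``
    when the first step is applied.  The default protocol is the standard
    hyper-then-hypo-osmotic pair: equilibrate at 333 mOsm/liter, step to
    466, step back to 333, 5 min per step.
    """

    steps: tuple[OsmoticStep, ...]
    equilibration_osmolarity: float = 333.0

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("protocol needs at least one step")
        if self.equilibration_osmolarity <= 0:
            raise ValueError("equilibration osmolarity must be positive")

    @classmethod
    def default(cls) -> "OsmoticProtocol":
        return cls(
            steps=(OsmoticStep(466.0, 300.0), OsmoticStep(333.0, 300.0)),
            equilibration_osmolarity=333.0,
        )

    def reference_osmolarity(self, step_index: int) -> float:
        """Bath osmolarity the cell was equilibrated in before a step."""
        if step_index == 0:
            return self.equilibration_osmolarity
        return self.steps[step_index - 1].osmolarity

    def step_direction(self, step_index: int) -> str:
        """'hyper' if the step raises bath osmolarity, 'hypo' if it lowers it."""
        c_er = self.reference_osmolarity(step_index)
        c_e = self.steps[step_index].osmolarity
        if c_e > c_er:
            return "hyper"
        if c_e < c_er:
            return "hypo"
        return "iso"

    def step_start_time(self, step_index: int) -> float:
        return float(sum(s.duration for s in self.steps[:step_index]))

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.steps))


@dataclass(frozen=True)
class CellState:
    """Instantaneous state of the cell."""

    volume: float  # m^3
    solute_moles: float  # mol
    active_water_fraction: float  # dimensionless, in [0, 1]

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.solute_moles <= 0:
            raise ValueError("solute amount must be positive")
        if not 0.0 <= self.active_water_fraction <= 1.0:
            raise ValueError("active water fraction must lie in [0, 1]")


@dataclass(frozen=True)
class CellParams:
    """Per-cell transport parameters and reference geometry.

    ``lp`` may be a single value or one value per protocol step (the
    membrane may present different effective permeabilities to shrinking
    and swelling).  ``c_ir`` is the intracellular osmolarity in the
    reference state, normally equal to the equilibration bath.
    """

    lp: float | tuple[float, ...]  # m^3/(N s)
    phi_ir: float  # dimensionless
    radius_ref: float  # m
    c_ir: float = 333.0  # mOsm/liter

    def __post_init__(self) -> None:
        for lp in self.lp_values:
            if lp <= 0:
                raise ValueError("hydraulic permeability must be positive")
        if not 0.0 <= self.phi_ir <= 1.0:
            raise ValueError("phi_ir must lie in [0, 1]")
        if self.radius_ref <= 0:
            raise ValueError("reference radius must be positive")
        if self.c_ir <= 0:
            raise ValueError("reference osmolarity must be positive")

    @property
    def lp_values(self) -> tuple[float, ...]:
        return self.lp if isinstance(self.lp, tuple) else (self.lp,)

    def lp_for_step(self, step_index: int) -> float:
        vals = self.lp_values
        return vals[step_index] if step_index < len(vals) else vals[-1]

    @property
    def volume_ref(self) -> float:
        """Reference volume of the spherical cell, (4/3)π a_r³."""
        return 4.0 / 3.0 * math.pi * self.radius_ref**3


@dataclass
class CellVolumeTrace:
    """Per-cell time series of volume under an osmotic protocol.

    ``time`` is seconds from the start of the first step; ``step_index``
    assigns each sample to a protocol step.
    """

    cell_id: str
    time: np.ndarray  # s
    volume: np.ndarray  # m^3
    step_index: np.ndarray  # int, per sample
    sampling_interval: float = 2.0  # s (0.5 Hz default)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        self.step_index = np.asarray(self.step_index, dtype=int)
        if not (len(self.time) == len(self.volume) == len(self.step_index)):
            raise ValueError("time, volume and step_index must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.volume <= 0):
            raise ValueError("volumes must be positive")

    def step_slice(self, step_index: int) -> slice:
        idx = np.flatnonzero(self.step_index == step_index)
        if idx.size == 0:
            raise ProtocolMismatchError(
                f"trace '{self.cell_id}' has no samples in step {step_index}"
            )
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class QCConfig:
    """Quality-control thresholds for trace/fit acceptance."""

    plateau_window: float = 30.0  # s over which the trace must be flat
    plateau_tolerance: float = 0.05  # max relative volume change in window
    min_r_squared: float = 0.8
    burst_jump: float = 0.15  # max relative single-frame volume jump
    min_samples: int = 10


@dataclass
class MixtureFitResult:
    """Estimates of (L_p, φ_ir) for one cell on one osmotic step."""

    cell_id: str
    step_index: int
    step_label: str  # 'hyper' | 'hypo' | 'iso'
    lp: float | None  # m^3/(N s)
    phi_ir: float | None
    rss: float
    r_squared: float
    converged: bool
    qc_flags: tuple[str, ...] = ()

    @property
    def passed_qc(self) -> bool:
        return self.converged and not self.qc_flags


# ---------------------------------------------------------------------------
# forward model


def surface_area(volume: float | np.ndarray) -> float | np.ndarray:
    """Surface area A = 3V/a = 4πa² of a sphere of volume V."""
    v = np.asarray(volume, dtype=float)
    if np.any(v <= 0):
        raise ValueError("volume must be positive")
    area = (36.0 * math.pi) ** (1.0 / 3.0) * v ** (2.0 / 3.0)
    return float(area) if np.isscalar(volume) else area


def intracellular_osmolarity(state: CellState, params: CellParams) -> float:
    """Osmolarity of the active water compartment, c_i = n_i/(φ_i V)."""
    v_ref = params.volume_ref
    phi_i = 1.0 - (1.0 - params.phi_ir) * v_ref / state.volume
    if phi_i <= 0.0:
        raise DegenerateStateError(
            "cell volume does not exceed its osmotically inactive fraction"
        )
    return state.solute_moles / (phi_i * state.volume)


def equilibrium_volume_ratio(phi_ir: float, c_er: float, c_e: float) -> float:
    """Closed-form equilibrium ratio V_∞/V_r = 1 − φ_ir + φ_ir·c_er/c_e."""
    if not 0.0 <= phi_ir <= 1.0:
        raise ValueError("phi_ir must lie in [0, 1]")
    if c_er <= 0 or c_e <= 0:
        raise ValueError("osmolarities must be positive")
    return 1.0 - phi_ir + phi_ir * c_er / c_e


def _rate_constant(lp: float, radius_ref: float, constants: ModelConstants) -> float:
    """Prefactor 3·L_p·R·θ/a_r of the normalized volume ODE, in m³/(mol·s)."""
    return 3.0 * lp * constants.rt / radius_ref


def _dvdt_normalized(
    v: float, lp_k: float, phi_ir: float, c_er: float, c_e: float
) -> float:
    # v = V/V_r; c_i = c_er·φ_ir/(v − 1 + φ_ir) by solute conservation.
    # The floor keeps the water compartment positive if the solver
    # momentarily overshoots the physical barrier v = 1 − φ_ir.
    v = max(v, 1.0 - phi_ir + 1e-6)
    c_i = c_er * phi_ir / (v - 1.0 + phi_ir)
    return lp_k * v ** (2.0 / 3.0) * (c_i - c_e)


def _integrate_step(
    t_eval: np.ndarray,
    v0: float,
    lp_k: float,
    phi_ir: float,
    c_er: float,
    c_e: float,
    rtol: float = 1e-8,
) -> np.ndarray:
    """Integrate the normalized volume ODE over one step at given times."""
    if phi_ir <= 1e-12 or c_er == c_e:
        # no osmotically active water, or no gradient: volume is constant
        return np.full_like(t_eval, v0)
    sol = solve_ivp(
        lambda _t, y: _dvdt_normalized(y[0], lp_k, phi_ir, c_er, c_e),
        (float(t_eval[0]), float(t_eval[-1])),
        [v0],
        t_eval=t_eval,
        method="LSODA",
        rtol=rtol,
        atol=1e-12,
    )
    if not sol.success:
        raise IntegrationError(
            f"volume ODE integration failed at t={sol.t[-1] if len(sol.t) else t_eval[0]}: "
            f"{sol.message}; last state v={sol.y[0, -1] if sol.y.size else v0}"
        )
    return sol.y[0]


def simulate_volume_response(
    params: CellParams,
    protocol: OsmoticProtocol,
    constants: ModelConstants = ModelConstants(),
    sampling_interval: float = 2.0,
    cell_id: str = "sim",
    rtol: float = 1e-8,
) -> CellVolumeTrace:
    """Forward-simulate the cell volume trace over a stepwise protocol.

    Solute amount and the osmotically inactive volume are conserved across
    the whole protocol; each step simply changes the bath osmolarity.
    The trace is sampled on a uniform grid (default 2 s, i.e. 0.5 Hz).
    ``params.lp`` may supply one permeability per step.
    """
    if sampling_interval <= 0:
        raise ValueError("sampling interval must be positive")

    v_solid = (1.0 - params.phi_ir) * params.volume_ref  # conserved, m^3
    # conserved solute (scaled): n_i = c_ir·φ_ir·V_r with c in mol/m^3
    n_i = params.c_ir * constants.osmolarity_scale * params.phi_ir * params.volume_ref

    times, volumes, step_ids = [], [], []
    v_abs = params.volume_ref  # equilibrated at c_ir before step 1
    for i, step in enumerate(protocol.steps):
        t0 = protocol.step_start_time(i)
        n_samp = max(int(math.floor(step.duration / sampling_interval)), 2)
        t_local = np.arange(n_samp) * sampling_interval
        # normalized coordinates relative to the state at step start
        v_ref_step = v_abs
        phi_ir_step = 1.0 - v_solid / v_ref_step
        if phi_ir_step > 1e-12:
            c_ir_step = n_i / (v_ref_step - v_solid) / constants.osmolarity_scale
        else:
            c_ir_step = params.c_ir
        lp_k = _rate_constant(
            params.lp_for_step(i),
            (3.0 * v_ref_step / (4.0 * math.pi)) ** (1.0 / 3.0),
            constants,
        )
        v_norm = _integrate_step(
            t_local,
            1.0,
            lp_k,
            phi_ir_step,
            c_ir_step * constants.osmolarity_scale,
            step.osmolarity * constants.osmolarity_scale,
            rtol=rtol,
        )
        times.append(t0 + t_local)
        volumes.append(v_norm * v_ref_step)
        step_ids.append(np.full(n_samp, i, dtype=int))
        # state at the end of the step (continue integration to the boundary)
        v_end = _integrate_step(
            np.array([0.0, step.duration]),
            1.0,
            lp_k,
            phi_ir_step,
            c_ir_step * constants.osmolarity_scale,
            step.osmolarity * constants.osmolarity_scale,
            rtol=rtol,
        )[-1]
        v_abs = v_end * v_ref_step

    return CellVolumeTrace(
        cell_id=cell_id,
        time=np.concatenate(times),
        volume=np.concatenate(volumes),
        step_index=np.concatenate(step_ids),
        sampling_interval=sampling_interval,
    )


# ---------------------------------------------------------------------------
# inverse problem


def _plateau_value(
    time: np.ndarray, volume: np.ndarray, qc: QCConfig
) -> tuple[float, bool]:
    """Mean volume over the final plateau window and whether it is flat."""
    t_end = time[-1]
    in_window = time >= t_end - qc.plateau_window
    window = volume[in_window]
    if window.size < 2:
        return float(volume[-1]), False
    rel_change = abs(window[-1] - window[0]) / window.mean()
    return float(window.mean()), rel_change <= qc.plateau_tolerance


def estimate_phir_from_equilibrium(
    trace: CellVolumeTrace,
    step_index: int,
    protocol: OsmoticProtocol,
    qc: QCConfig | None = None,
) -> tuple[float, bool]:
    """Invert the equilibrium relation for φ_ir from the step plateau.

    Returns ``(phi_ir, clamped)`` where ``clamped`` records whether the raw
    estimate fell outside [0, 1] and was clipped.  Raises
    :class:`UnidentifiableError` when the step has no osmotic gradient and
    :class:`QCError` when the trace never plateaus.
    """
    qc = qc or QCConfig()
    c_er = protocol.reference_osmolarity(step_index)
    c_e = protocol.steps[step_index].osmolarity
    if c_er == c_e:
        raise UnidentifiableError("phi_ir is unidentifiable without an osmotic step")
    sl = trace.step_slice(step_index)
    t, v = trace.time[sl], trace.volume[sl]
    v_inf, flat = _plateau_value(t, v, qc)
    if not flat:
        raise QCError(f"trace '{trace.cell_id}' step {step_index} has no plateau")
    ratio = v_inf / v[0]
    phi_raw = (ratio - 1.0) / (c_er / c_e - 1.0)
    phi = min(max(phi_raw, 0.0), 1.0)
    return phi, phi != phi_raw


def fit_mixture_model(
    trace: CellVolumeTrace,
    step_index: int,
    protocol: OsmoticProtocol,
    constants: ModelConstants = ModelConstants(),
    init: tuple[float, float] | None = None,
    bounds: tuple[tuple[float, float], tuple[float, float]] = (
        (1e-16, 1e-11),
        (0.0, 1.0),
    ),
    qc: QCConfig | None = None,
) -> MixtureFitResult:
    """Estimate (L_p, φ_ir) for one osmotic step by nonlinear least squares.

    The measured volumes are normalized to the first sample of the step
    (the reference state) and fitted against the integrated model.  L_p is
    optimized on a log10 scale; φ_ir is initialized from the equilibrium
    plateau when available.  QC flags mark traces with no plateau, poor
    fits (R² below threshold), or burst-like jumps, mirroring the exclusion
    of cells that lyse during loading.
    """
    qc = qc or QCConfig()
    sl = trace.step_slice(step_index)
    t = trace.time[sl]
    v = trace.volume[sl]
    if len(t) < qc.min_samples:
        raise ValueError(
            f"need at least {qc.min_samples} samples in step, got {len(t)}"
        )
    label = protocol.step_direction(step_index)
    c_er = protocol.reference_osmolarity(step_index)
    c_e = protocol.steps[step_index].osmolarity
    scale = constants.osmolarity_scale
    radius_ref = (3.0 * v[0] / (4.0 * math.pi)) ** (1.0 / 3.0)

    flags: list[str] = []
    jumps = np.abs(np.diff(v)) / v[:-1]
    if jumps.size and jumps.max() > qc.burst_jump:
        flags.append("burst")

    if c_er == c_e:
        return MixtureFitResult(
            trace.cell_id, step_index, label, None, None,
            rss=float("nan"), r_squared=float("nan"), converged=False,
            qc_flags=tuple(flags + ["unidentifiable"]),
        )

    t_local = t - t[0]
    v_obs = v / v[0]
    _, flat = _plateau_value(t_local, v_obs, qc)
    if not flat:
        flags.append("no_plateau")

    # flat trace despite a nonzero osmotic step: no signal for L_p
    if abs(v_obs[-1] - 1.0) < 5e-3 and np.ptp(v_obs) < 5e-3:
        return MixtureFitResult(
            trace.cell_id, step_index, label, None, None,
            rss=float("nan"), r_squared=float("nan"), converged=False,
            qc_flags=tuple(flags + ["unidentifiable"]),
        )

    (lp_lo, lp_hi), (phi_lo, phi_hi) = bounds
    if init is None:
        try:
            phi0, _ = estimate_phir_from_equilibrium(trace, step_index, protocol, qc)
        except (QCError, UnidentifiableError):
            phi0 = 0.5
        lp0 = 1e-13
    else:
        lp0, phi0 = init
    phi0 = min(max(phi0, phi_lo + 1e-6), phi_hi - 1e-6)
    lp0 = min(max(lp0, lp_lo), lp_hi)

    def residuals(x: np.ndarray) -> np.ndarray:
        lp, phi = 10.0 ** x[0], x[1]
        lp_k = _rate_constant(lp, radius_ref, constants)
        try:
            v_model = _integrate_step(
                t_local, 1.0, lp_k, phi, c_er * scale, c_e * scale, rtol=1e-8
            )
        except IntegrationError:
            # steer the optimizer away from numerically infeasible corners
            return np.full_like(v_obs, 1e3)
        return v_model - v_obs

    if init is None:
        # coarse 1-D sweep over L_p at the plateau-derived φ_ir picks the
        # right basin before the joint refinement
        candidates = np.linspace(math.log10(lp_lo) + 1.0, math.log10(lp_hi) - 1.0, 13)
        costs = [float(np.sum(residuals([lg, phi0]) ** 2)) for lg in candidates]
        lg0 = float(candidates[int(np.argmin(costs))])
    else:
        lg0 = math.log10(lp0)

    result = least_squares(
        residuals,
        x0=[lg0, phi0],
        bounds=(
            [math.log10(lp_lo), phi_lo],
            [math.log10(lp_hi), phi_hi],
        ),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    lp_hat = 10.0 ** result.x[0]
    phi_hat = float(result.x[1])
    rss = float(np.sum(result.fun**2))
    tss = float(np.sum((v_obs - v_obs.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("-inf")
    if r2 < qc.min_r_squared:
        flags.append("poor_fit")
    # an estimate pinned to the box edge carries no information about L_p
    if result.x[0] - math.log10(lp_lo) < 0.01 or math.log10(lp_hi) - result.x[0] < 0.01:
        flags.append("lp_at_bound")
    converged = bool(result.success)
    return MixtureFitResult(
        trace.cell_id,
        step_index,
        label,
        lp_hat if converged else None,
        phi_hat if converged else None,
        rss=rss,
        r_squared=r2,
        converged=converged,
        qc_flags=tuple(flags),
    )


def fit_two_step_sequence(
    trace: CellVolumeTrace,
    protocol: OsmoticProtocol,
    constants: ModelConstants = ModelConstants(),
    qc: QCConfig | None = None,
) -> list[MixtureFitResult]:
    """Fit every step of a multi-step protocol independently.

    The reference state (V_r, c_ir) is re-taken from the first sample of
    each step, assuming the cell equilibrated with the previous bath during
    the preceding 5-min hold.
    """
    if len(protocol.steps) < 2:
        raise ValueError("protocol must have at least two steps")
    present = set(np.unique(trace.step_index).tolist())
    missing = [i for i in range(len(protocol.steps)) if i not in present]
    if missing:
        raise ProtocolMismatchError(
            f"trace '{trace.cell_id}' is missing protocol steps {missing}"
        )
    return [
        fit_mixture_model(trace, i, protocol, constants, qc=qc)
        for i in range(len(protocol.steps))
    ]
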