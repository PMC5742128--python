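"""Per-fiber activation decision and threshold search.

Each myelinated fiber is reduced to its nodes of Ranvier: internodes are
perfectly insulating, so node n obeys

    C_m A dV_n/dt = G_a (V_{n-1} - 2V_n + V_{n+1} + V_{e,n-1} - 2V_{e,n}
                    + V_{e,n+1}) - A·i_ion(V_n, gates),

with sealed ends, nodal membrane area A, internodal axial conductance G_a,
and the extracellular drive V_{e,n}(t) = amplitude · w(t) · u_n, where u_n
is the unit-current potential interpolated at node n.  Because the
extracellular coupling is linear, scaling all u_n by k scales every
threshold by 1/k.

Two model variants:

* ``active_cable`` (default): CRRSS-style mammalian node kinetics (fast
  sodium m²h plus leak, 37 °C), semi-implicit Euler with exact exponential
  gate updates.  A spike is a node's absolute membrane potential crossing
  0 mV (full depolarization overshoot).
* ``linear_sdc``: passive activating-function oracle — a spike occurs when
  the peak positive second-difference drive reaches a fixed voltage; its
  threshold has the closed form  θ_sdc / max_t,n [w(t)·Δ²u]_n, which makes
  it the independent check for the bisection search.

The threshold amplification factor is found by doubling from a floor until
a spike occurs, then bisecting to a relative tolerance (default 1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .electrodes import StimulusWaveform
from .fibers import FiberSet
from .potential import UnitPotential, _PointLocator, interpolate_at_points

NON_EXCITABLE = np.inf


class SimulationError(RuntimeError):
    pass


@dataclass
class NeuronParams:
    """Electrical parameters of one fiber type."""

    model: str = "active_cable"            # or "linear_sdc"
    fiber_diameter: float = 3.0e-6         # m, outer fiber diameter D
    node_diameter_ratio: float = 0.7       # axon/node diameter = ratio · D
    node_length: float = 1.5e-6            # m
    internodal_distance: float = 300e-6    # m (overridden per fiber type)
    axoplasm_resistivity: float = 0.547    # Ω·m
    c_m: float = 0.025                     # F/m² nodal membrane capacitance
    g_na: float = 14450.0                  # S/m² peak sodium conductance
    g_leak: float = 1280.0                 # S/m²
    e_na: float = 0.115                    # V, sodium reversal relative to rest
    e_leak: float = 0.0                    # V relative to rest
    v_rest: float = -0.080                 # V absolute resting potential
    spike_potential: float = 0.0           # V absolute spike criterion
    dt: float = 2e-6                       # s, implicit-Euler step
    tail: float = 1e-3                     # s simulated after the stimulus
    sdc_threshold: float = 0.02            # V, linear_sdc spike criterion
    threshold_jitter_cv: float = 0.0       # optional per-fiber lognormal-free CV

    def __post_init__(self) -> None:
        for name in ("fiber_diameter", "node_diameter_ratio", "node_length",
                     "internodal_distance", "axoplasm_resistivity", "c_m",
                     "g_na", "g_leak", "dt", "tail", "sdc_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def node_area(self) -> float:
        d = self.node_diameter_ratio * self.fiber_diameter
        return np.pi * d * self.node_length

    @property
    def axial_conductance(self) -> float:
        d = self.node_diameter_ratio * self.fiber_diameter
        return np.pi * d**2 / (4.0 * self.axoplasm_resistivity * self.internodal_distance)


def default_params_by_type() -> dict[str, NeuronParams]:
    """Per-type defaults: internodal spacing and diameter co-vary (L ≈ 100·D)."""
    out = {}
    for ftype, delta in (("regular", 350e-6), ("irregular", 250e-6), ("dimorphic", 300e-6)):
        out[ftype] = NeuronParams(internodal_distance=delta, fiber_diameter=delta / 100.0)
    return out


@dataclass
class ThresholdResult:
    fiber_id: int
    threshold: float                  # A (amplification factor of the unit current)
    converged: bool
    bracket_history: list[tuple[float, float]] = dc_field(default_factory=list)
    branch: str = ""
    fiber_type: str = ""


# ----------------------------------------------------------------------
# rate functions (CRRSS mammalian node, 37 °C); v in volts relative to rest
# ----------------------------------------------------------------------

def _gate_rates(v: np.ndarray):
    vm = v * 1e3  # mV
    a_m = (97.0 + 0.363 * vm) / (1.0 + np.exp((31.0 - vm) / 5.3))
    b_m = a_m / np.exp((vm - 23.8) / 4.17)
    b_h = 15.6 / (1.0 + np.exp((24.0 - vm) / 10.0))
    a_h = b_h / np.exp((vm - 5.5) / 5.0)
    return a_m * 1e3, b_m * 1e3, a_h * 1e3, b_h * 1e3   # 1/ms -> 1/s


def _second_difference(u: np.ndarray) -> np.ndarray:
    """Sealed-end discrete cable operator applied to a node vector."""
    d = np.empty_like(u)
    d[1:-1] = u[:-2] - 2.0 * u[1:-1] + u[2:]
    d[0] = u[1] - u[0]
    d[-1] = u[-2] - u[-1]
    return d


def _active_cable_kernel(u, w_steps, amplitude, dt, A, Ga, C,
                         g_na_max, g_leak, e_na, e_leak, spike_level):
    """Semi-implicit time stepping; returns True on a spike.

    Gates advance by exact exponential update at the current voltage; the
    voltage update is implicit (tridiagonal Thomas solve).  After the
    stimulus, the loop exits early once the response has decayed to < 1 mV.
    """
    n = u.shape[0]
    v = np.zeros(n)
    m = np.zeros(n)
    h = np.zeros(n)
    # resting gate states at v = 0
    for i in range(n):
        am = 97.0 / (1.0 + np.exp(31.0 / 5.3))
        bm = am / np.exp(-23.8 / 4.17)
        bh = 15.6 / (1.0 + np.exp(2.4))
        ah = bh / np.exp(-1.1)
        m[i] = am / (am + bm)
        h[i] = ah / (ah + bh)

    lo = np.empty(n); di = np.empty(n); up = np.empty(n); rhs = np.empty(n)
    cp = np.empty(n); dp = np.empty(n)
    n_steps = w_steps.shape[0]
    stim_steps = 0
    for s in range(n_steps):
        if w_steps[s] != 0.0:
            stim_steps = s + 1
    for s in range(n_steps):
        w = w_steps[s]
        for i in range(n):
            vm = v[i] * 1e3
            am = (97.0 + 0.363 * vm) / (1.0 + np.exp((31.0 - vm) / 5.3)) * 1e3
            bm = am / np.exp((vm - 23.8) / 4.17)
            bh = 15.6 / (1.0 + np.exp((24.0 - vm) / 10.0)) * 1e3
            ah = bh / np.exp((vm - 5.5) / 5.0)
            tm = 1.0 / (am + bm)
            minf = am * tm
            m[i] = minf + (m[i] - minf) * np.exp(-dt / tm)
            th = 1.0 / (ah + bh)
            hinf = ah * th
            h[i] = hinf + (h[i] - hinf) * np.exp(-dt / th)

        for i in range(n):
            # extracellular second difference (sealed ends)
            if i == 0:
                d2 = u[1] - u[0]
            elif i == n - 1:
                d2 = u[n - 2] - u[n - 1]
            else:
                d2 = u[i - 1] - 2.0 * u[i] + u[i + 1]
            gna = g_na_max * m[i] * m[i] * h[i]
            gtot = gna + g_leak
            ndiag = 2.0 if 0 < i < n - 1 else 1.0
            lo[i] = -Ga
            up[i] = -Ga
            di[i] = C / dt + A * gtot + Ga * ndiag
            rhs[i] = (C / dt) * v[i] + A * (gna * e_na + g_leak * e_leak) \
                + Ga * amplitude * w * d2
        # Thomas solve
        cp[0] = up[0] / di[0]
        dp[0] = rhs[0] / di[0]
        for i in range(1, n):
            denom = di[i] - lo[i] * cp[i - 1]
            cp[i] = up[i] / denom
            dp[i] = (rhs[i] - lo[i] * dp[i - 1]) / denom
        v[n - 1] = dp[n - 1]
        for i in range(n - 2, -1, -1):
            v[i] = dp[i] - cp[i] * v[i + 1]

        vmax = 0.0
        vpos = -1.0
        for i in range(n):
            av = abs(v[i])
            if av > vmax:
                vmax = av
            if v[i] > vpos:
                vpos = v[i]
        if vmax > 1.0:
            return 2   # numerical blow-up
        if vpos >= spike_level:
            return 1
        if s >= stim_steps and vmax < 1e-3:
            return 0   # decayed subthreshold response
    return 0


try:  # pragma: no cover - exercised wherever numba is present
    import numba as _numba

    _active_cable_kernel = _numba.njit(cache=True, fastmath=False)(_active_cable_kernel)
except ImportError:  # pragma: no cover
    pass


def simulate_fiber(
    node_potentials: np.ndarray,
    waveform: StimulusWaveform,
    amplitude: float,
    params: NeuronParams,
) -> bool:
    """True if the stimulus elicits a spike on the fiber.

    ``node_potentials`` are the unit-current extracellular potentials u_n at
    the nodes of Ranvier (V per A).
    """
    u = np.asarray(node_potentials, dtype=float)
    if u.ndim != 1 or len(u) < 2:
        raise ValueError("need unit potentials at >= 2 nodes")
    if params.model == "linear_sdc":
        drive = _second_difference(u)
        peak = 0.0
        for _, w in waveform.phases:
            if w != 0.0:
                peak = max(peak, float((w * drive).max()))
        return amplitude * peak >= params.sdc_threshold

    if params.model != "active_cable":
        raise ValueError(f"unknown neuron model {params.model!r}")

    dt = params.dt
    n_steps = int(np.ceil((waveform.support + params.tail) / dt))
    # per-step waveform samples (evaluated at the end of each step)
    w_steps = np.asarray(waveform((np.arange(n_steps) + 1) * dt), dtype=float)
    A = params.node_area
    status = _active_cable_kernel(
        u, w_steps, float(amplitude), dt, A, params.axial_conductance,
        params.c_m * A, params.g_na, params.g_leak, params.e_na, params.e_leak,
        params.spike_potential - params.v_rest,
    )
    if status == 2:
        raise SimulationError(
            "membrane potential exceeded 1 V (numerical instability); reduce dt"
        )
    return bool(status)


def find_threshold(
    node_potentials: np.ndarray,
    waveform: StimulusWaveform,
    params: NeuronParams,
    rel_tol: float = 0.01,
    floor: float = 1e-6,
    ceiling_factor: float = 1e6,
) -> ThresholdResult:
    """Bracket by doubling from ``floor`` until a spike, then bisect.

    Returns threshold = +inf (non-excitable) if no spike occurs up to
    floor·ceiling_factor, e.g. for all-zero or spatially uniform potentials
    (a constant extracellular field exerts no second-difference drive).
    """
    if not 0 < rel_tol <= 0.1:
        raise ValueError("rel_tol must be in (0, 0.1]")
    history: list[tuple[float, float]] = []
    lo, hi = 0.0, floor
    ceiling = floor * ceiling_factor
    while hi <= ceiling:
        if simulate_fiber(node_potentials, waveform, hi, params):
            break
        lo, hi = hi, hi * 2.0
        history.append((lo, hi))
    else:
        return ThresholdResult(-1, NON_EXCITABLE, False, history)
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if simulate_fiber(node_potentials, waveform, mid, params):
            hi = mid
        else:
            lo = mid
        history.append((lo, hi))
    return ThresholdResult(-1, hi, True, history)


def branch_thresholds(
    fibers: FiberSet,
    unit: UnitPotential,
    waveform: StimulusWaveform,
    params_by_type: dict[str, NeuronParams] | None = None,
    rel_tol: float = 0.01,
    floor: float = 1e-6,
    ceiling_factor: float = 1e6,
    jitter_seed: int = 0,
    locator: _PointLocator | None = None,
) -> list[ThresholdResult]:
    """Thresholds for every fiber of a branch (order-independent results).

    Nodes of Ranvier are placed with the type's internodal distance if not
    already present.  Per-fiber errors are recorded as non-converged results
    rather than aborting the branch.  Optional Gaussian threshold jitter
    (params.threshold_jitter_cv > 0) approximates spontaneous-discharge
    variability; it is seeded per fiber and off by default.
    """
    from .fibers import place_nodes_of_ranvier

    params_by_type = params_by_type or default_params_by_type()
    locator = locator or _PointLocator(unit.mesh)
    results = []
    for i, fiber in enumerate(fibers.fibers):
        p = params_by_type.get(fiber.fiber_type)
        if p is None:
            p = params_by_type.get("dimorphic") or next(iter(params_by_type.values()))
        try:
            if len(fiber.node_arc_lengths) < 2:
                place_nodes_of_ranvier(fiber, p.internodal_distance)
            u = interpolate_at_points(unit, fiber.node_points(), locator=locator)
            res = find_threshold(u, waveform, p, rel_tol, floor, ceiling_factor)
        except (ValueError, SimulationError):
            res = ThresholdResult(i, NON_EXCITABLE, False)
        res.fiber_id = i
        res.branch = fibers.branch
        res.fiber_type = fiber.fiber_type
        if p.threshold_jitter_cv > 0 and np.isfinite(res.threshold):
            rng = np.random.default_rng((jitter_seed, i))
            res.threshold *= max(1.0 + p.threshold_jitter_cv * rng.standard_normal(), 0.05)
        results.append(res)
    return results


def thresholds_to_csv(results: list[ThresholdResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("fiber_id,branch,type,threshold_A,converged\n")
        for r in results:
            fh.write(f"{r.fiber_id},{r.branch},{r.fiber_type},{r.threshold:.6g},{r.converged}\n")
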