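"""Time integration of the coupled and reduced dynamics; regime labels.

The coupled mRNA/protein concentration dynamics in the polymerase- and
ribosome-limited regime are

    dc_mi/dt = k_m phi_i(c) c_n - c_mi (k_p c_r + 1/tau)
    dc_i/dt  = k_p c_r (c_mi / c_mT - c_i),

with c_n, c_r the RNA polymerase and ribosome concentrations and
c_mT = sum_i c_mi.  Summing the protein equations gives
d(sum c)/dt = k_p c_r (1 - sum c): the probability simplex is globally
attracting.  When mRNA turns over much faster than protein the mRNA
sector slaves to the proteins and the reduced N-dimensional system

    dc_i/dt = k_p c_r (phi_i(c) - c_i)

captures the protein dynamics.  Time is measured in units of 1/k_p.

Long-run behavior is labeled fixed_point / oscillatory / chaotic /
undetermined from the post-transient trajectory: amplitude of relative
fluctuations, concentration of spectral power at a dominant period (and
its harmonics), and the divergence rate of an initially 1e-8-separated
twin trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import linregress

from .regulation import CellParams, RegulatoryNetwork, allocation
from .steady_state import mrna_fixed_point, _simplex_point

__all__ = [
    "Trajectory",
    "rhs_phase1",
    "rhs_reduced",
    "integrate",
    "integrate_phase1",
    "integrate_reduced",
    "classify_trajectory",
    "classify_network_dynamics",
]


@dataclass
class Trajectory:
    """Solution samples on a user grid; ``c`` has shape (n_times, N)."""

    times: np.ndarray
    c: np.ndarray
    c_m: np.ndarray | None = None
    label: str | None = None
    diagnostics: dict = field(default_factory=dict)


def rhs_phase1(
    state: np.ndarray, net: RegulatoryNetwork, params: CellParams
) -> np.ndarray:
    """Time derivative of the stacked state (c_m, c) of the full system."""
    n = net.n_genes
    es = net.topology
    c_m, c = state[:n], state[n:]
    cmt = c_m.sum()
    if cmt <= 0:
        raise ValueError("total mRNA concentration must be positive")
    phi = allocation(net, c)
    kp_cr = params.k_p * c[es.ribosome_index]
    dc_m = params.k_m * phi * c[es.rnap_index] - c_m * (kp_cr + params.inv_tau)
    dc = kp_cr * (c_m / cmt - c)
    return np.concatenate([dc_m, dc])


def rhs_reduced(
    c: np.ndarray, net: RegulatoryNetwork, params: CellParams
) -> np.ndarray:
    """Time derivative of the protein-only reduced system."""
    kp_cr = params.k_p * c[net.topology.ribosome_index]
    return kp_cr * (allocation(net, c) - c)


def integrate(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    y0: np.ndarray,
    t_span: tuple[float, float],
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive stiff-capable integration; returns (times, states).

    ``states`` has one row per output time.  Integrator failures are
    surfaced with the solver's message and the time reached.
    """
    if t_span[1] <= t_span[0]:
        raise ValueError("t_span must be increasing")
    sol = solve_ivp(
        rhs, t_span, np.asarray(y0, dtype=float),
        t_eval=t_eval, rtol=rtol, atol=atol, method=method,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if sol.t.size else t_span[0]:g}: "
            f"{sol.message}"
        )
    return sol.t, sol.y.T


def integrate_phase1(
    net: RegulatoryNetwork,
    params: CellParams,
    c0: np.ndarray,
    c_m0: np.ndarray | None = None,
    t_end: float = 1000.0,
    n_points: int = 1024,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the full 2N system (mRNA levels default to quasi-steady)."""
    if c_m0 is None:
        c_m0 = mrna_fixed_point(net, params, c0)
    y0 = np.concatenate([c_m0, c0])
    t_eval = np.linspace(0.0, t_end, n_points)
    times, y = integrate(
        lambda t, y: rhs_phase1(y, net, params), y0, (0.0, t_end),
        t_eval=t_eval, rtol=rtol, atol=atol, method=method,
    )
    n = net.n_genes
    return Trajectory(times=times, c=y[:, n:], c_m=y[:, :n])


def integrate_reduced(
    net: RegulatoryNetwork,
    params: CellParams,
    c0: np.ndarray,
    t_end: float = 1000.0,
    n_points: int = 1024,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the reduced protein-only system."""
    t_eval = np.linspace(0.0, t_end, n_points)
    times, y = integrate(
        lambda t, y: rhs_reduced(y, net, params), np.asarray(c0, float),
        (0.0, t_end), t_eval=t_eval, rtol=rtol, atol=atol, method=method,
    )
    return Trajectory(times=times, c=y)


# --------------------------------------------------------------------------
# trajectory classification
# --------------------------------------------------------------------------

#: Relative fluctuation below which the post-transient state counts as a
#: fixed point.
FIXED_POINT_FLUCTUATION = 1e-6
#: Fraction of fluctuation power the dominant period (with harmonics)
#: must hold for an oscillatory label.
OSCILLATION_POWER_FRACTION = 0.5


def _relative_fluctuation(c: np.ndarray) -> np.ndarray:
    """(max - min) / mean per gene over the analysis window."""
    mean = np.maximum(c.mean(axis=0), 1e-300)
    return (c.max(axis=0) - c.min(axis=0)) / mean


def _dominant_peak_fraction(c: np.ndarray) -> tuple[float, float]:
    """(power fraction in the dominant period incl. harmonics, period index).

    Sums the detrended power spectra of the five most strongly
    fluctuating genes; harmonics are included because relaxation-type
    oscillations spread power over integer multiples of the fundamental.
    """
    fluct = _relative_fluctuation(c)
    top = np.argsort(fluct)[-5:]
    x = c[:, top] - c[:, top].mean(axis=0)
    spec = np.abs(np.fft.rfft(x, axis=0)) ** 2
    power = spec.sum(axis=1)
    power[0] = 0.0  # remove residual DC
    total = power.sum()
    if total <= 0:
        return 0.0, np.inf
    base = int(np.argmax(power[1:])) + 1
    keep = np.zeros(power.size, dtype=bool)
    k = 1
    while k * base < power.size:
        keep[max(k * base - 1, 1): k * base + 2] = True
        k += 1
    dominant = power[keep].sum()
    n_times = c.shape[0]
    period_index = n_times / base  # in samples
    return float(dominant / total), float(period_index)


def _divergence_rate(
    times: np.ndarray, c: np.ndarray, c_twin: np.ndarray
) -> tuple[float, float, float]:
    """(slope, stderr, total ln-growth) of the log twin separation.

    The slope is fitted over the middle third of the growth segment of
    ln ||c_twin - c|| (everything before 90% of the total growth is
    treated as growth segment, so saturation at the attractor size does
    not bias the fit).
    """
    sep = np.linalg.norm(c_twin - c, axis=1)
    sep = np.maximum(sep, 1e-300)
    ls = np.log(sep)
    growth = float(ls.max() - ls[0])
    if growth > np.log(100.0):
        cutoff = ls[0] + 0.9 * growth
        above = np.nonzero(ls >= cutoff)[0]
        i_end = int(above[0]) if above.size else ls.size
    else:
        i_end = ls.size
    lo, hi = i_end // 3, max(2 * i_end // 3, i_end // 3 + 2)
    hi = min(hi, ls.size)
    if hi - lo < 2:
        return 0.0, np.inf, growth
    fit = linregress(times[lo:hi], ls[lo:hi])
    stderr = float(fit.stderr) if np.isfinite(fit.stderr) else np.inf
    return float(fit.slope), stderr, growth


def classify_trajectory(
    traj: Trajectory,
    transient_fraction: float = 0.5,
    twin: Trajectory | None = None,
) -> str:
    """Label the long-run behavior of a trajectory.

    After discarding the leading ``transient_fraction`` of samples:
    ``fixed_point`` if the relative fluctuation is below 1e-6; otherwise
    ``oscillatory`` if a dominant spectral peak (with harmonics) holds at
    least half the fluctuation power and the twin trajectories do not
    diverge; otherwise ``chaotic`` if the twin separation grows at a
    positive rate (slope of the log-separation over its growth segment,
    guarded by twice its standard error and by at least one decade of
    total growth); otherwise ``undetermined``.

    Stores its diagnostics on ``traj.diagnostics`` and the label on
    ``traj.label``.
    """
    if not 0 <= transient_fraction < 1:
        raise ValueError("transient_fraction must lie in [0, 1)")
    start = int(transient_fraction * traj.times.size)
    c = traj.c[start:]
    amp = float(_relative_fluctuation(c).max())
    diags: dict = {"fluctuation_amplitude": amp}

    diverging = False
    if twin is not None:
        slope, stderr, growth = _divergence_rate(traj.times, traj.c, twin.c)
        diags.update(divergence_rate=slope, divergence_stderr=stderr,
                     divergence_growth=growth)
        # a positive fitted rate only counts as divergence when the
        # separation actually grew by at least two decades
        diverging = slope - 2.0 * stderr > 0 and growth > np.log(100.0)

    if amp < FIXED_POINT_FLUCTUATION:
        label = "fixed_point"
    else:
        frac, period_idx = _dominant_peak_fraction(c)
        dt = traj.times[1] - traj.times[0]
        window = (traj.times[-1] - traj.times[0]) * (1 - transient_fraction)
        period_resolved = period_idx * dt <= window / 3
        diags.update(dominant_power_fraction=frac,
                     dominant_period=period_idx * dt)
        if frac >= OSCILLATION_POWER_FRACTION and period_resolved and not diverging:
            label = "oscillatory"
        elif diverging:
            label = "chaotic"
        else:
            label = "undetermined"
    traj.label = label
    traj.diagnostics.update(diags)
    return label


def rhs_intrinsic(c: np.ndarray, net: RegulatoryNetwork) -> np.ndarray:
    """Reduced dynamics in intrinsic time, dc/ds = phi(c) - c.

    Rescaling time by the global clock rate, ds = k_p c_r dt, is an
    orbit-preserving reparameterization (c_r > 0 always): fixed points,
    periodic orbits and the sign of divergence rates are unchanged.  It
    removes the clock degeneracy of strongly repressed states, where
    c_r collapses by many orders of magnitude and the wall-clock
    dynamics freeze on any feasible horizon.
    """
    return allocation(net, c) - c


def classify_network_dynamics(
    net: RegulatoryNetwork,
    params: CellParams | None = None,
    seed: int = 0,
    clock: str = "intrinsic",
    t_transient: float | None = None,
    t_window: float | None = None,
    n_points: int = 8192,
    twin_separation: float = 1e-8,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> Trajectory:
    """Integrate the reduced system from a random state and label it.

    Two-stage protocol: a transient integration of length
    ``t_transient`` settles the system onto its attractor; the analysis
    window of length ``t_window`` then starts on the attractor, so the
    amplitude, spectral and divergence diagnostics are free of initial
    relaxation.  The twin trajectory is separated by
    ``twin_separation`` (relative, re-normalized to the simplex) *after*
    the transient, the standard protocol for divergence-rate estimates.

    With ``clock="intrinsic"`` (default) the orbit-equivalent system
    dc/ds = phi(c) - c is integrated (see :func:`rhs_intrinsic`);
    attractor timescales are then O(10-1000) regardless of how small
    the ribosome concentration gets.  With ``clock="wall"`` the reduced
    system is integrated in units of 1/k_p; out-of-equilibrium
    timescales are set by 1/(k_p c_r) and can grow without bound, so
    wall-clock horizons must be chosen accordingly.

    Returns the labeled analysis-window trajectory.
    """
    if params is None:
        params = CellParams()
    if clock == "intrinsic":
        rhs = lambda t, c: rhs_intrinsic(c, net)  # noqa: E731
        t_transient = 2000.0 if t_transient is None else t_transient
        t_window = 4000.0 if t_window is None else t_window
    elif clock == "wall":
        rhs = lambda t, c: rhs_reduced(c, net, params)  # noqa: E731
        t_transient = 5.0e6 if t_transient is None else t_transient
        t_window = 1.0e7 if t_window is None else t_window
    else:
        raise ValueError("clock must be 'intrinsic' or 'wall'")
    rng = np.random.default_rng(seed)
    c0 = _simplex_point(rng, net.n_genes)
    _, pre = integrate(
        rhs, c0, (0.0, t_transient),
        t_eval=np.array([t_transient]), rtol=rtol, atol=atol,
    )
    c_start = pre[-1]
    delta = rng.standard_normal(net.n_genes)
    c_twin = c_start * (1.0 + twin_separation * delta / np.linalg.norm(delta))
    c_twin = np.abs(c_twin)
    c_twin /= c_twin.sum()
    t_eval = np.linspace(0.0, t_window, n_points)
    t1, y1 = integrate(rhs, c_start, (0.0, t_window), t_eval=t_eval,
                       rtol=rtol, atol=atol)
    t2, y2 = integrate(rhs, c_twin, (0.0, t_window), t_eval=t_eval,
                       rtol=rtol, atol=atol)
    traj = Trajectory(times=t1, c=y1)
    twin = Trajectory(times=t2, c=y2)
    classify_trajectory(traj, transient_fraction=0.0, twin=twin)
    return traj
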