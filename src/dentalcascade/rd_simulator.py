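"""Activator-inhibitor (Turing) dynamics on growing 1-D dental laminae.

The model integrates

    du/dt = D_u u_xx + f(u, v)            (activator)
    dv/dt = D_v v_xx + h(u, v)            (inhibitor / substrate)

with zero-flux boundaries on a domain that elongates according to a
morphogroup-specific growth schedule.  Two growth modes are supported:

* ``apical`` -- new material is appended at the moving end at the
  homogeneous steady-state composition (the mechanism of jaw elongation:
  proliferation is localized at the growing front), with no dilution;
* ``uniform`` -- the whole domain stretches (Lagrangian formulation on the
  unit interval) and concentrations are diluted at rate L'/L.

Each tooth class is one independent cascade: a single activator peak is
seeded at the initiating bud locus (dP4 for premolars, M1 for molars) on a
short domain holding roughly one pattern wavelength, and as the domain grows
new peaks -- new tooth signaling centers -- insert sequentially toward the
moving end once the space from the nearest established peak exceeds its
inhibitory field.  Insertion events (time, position, ordinal) are the
simulator's primary output; the integrated activator mass of a peak a fixed
delay after insertion serves as a tooth-size proxy.

An optional exogenous spatial gradient modulates one named kinetic constant
along the jaw axis; a gradient that decays away from the bud weakens the
Turing band posteriorly, shrinking and eventually suppressing late peaks
(the reduced-or-absent M3 phenotype of short-jawed frugivores).

Numerics: operator splitting with an unconditionally stable implicit
(backward Euler) diffusion step and an explicit reaction step guarded by a
row-sum bound on the reaction Jacobian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.linalg import solve_banded
from scipy.optimize import minimize_scalar

from .errors import SimulationError
from .kinetics import Kinetics, get_kinetics

#: Ordinal -> locus label for each cascade (insertion order).
CASCADE_LOCI = {
    "premolar": ("dP4", "dP3", "P2"),
    "molar": ("M1", "M2", "M3"),
}


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthSchedule:
    """Piecewise-linear elongation-rate schedule g(t) >= 0.

    ``points`` are (time, rate) pairs in simulation units; the rate is
    interpolated linearly between points and held constant beyond the ends.
    ``direction`` is the anatomical direction of elongation (premolar
    cascades grow anteriorly, molar cascades posteriorly); ``growth_end``
    is the lab-frame end at which material is added in apical mode.
    """

    points: tuple = ((0.0, 0.0),)
    mode: str = "apical"
    direction: str = "anterior"
    growth_end: str = "right"

    def __post_init__(self):
        if self.mode not in ("apical", "uniform"):
            raise ValueError(f"unknown growth mode {self.mode!r}")
        if self.direction not in ("anterior", "posterior"):
            raise ValueError(f"unknown growth direction {self.direction!r}")
        if self.growth_end not in ("left", "right"):
            raise ValueError(f"unknown growth end {self.growth_end!r}")
        ts = [p[0] for p in self.points]
        if sorted(ts) != ts:
            raise ValueError("schedule times must be non-decreasing")

    def rate(self, t):
        ts = np.array([p[0] for p in self.points], dtype=float)
        rs = np.array([p[1] for p in self.points], dtype=float)
        return float(np.maximum(np.interp(t, ts, rs), 0.0))

    def integrated(self, t_end: float, n: int = 2001) -> float:
        """Total added length over [0, t_end] (trapezoidal quadrature)."""
        ts = np.linspace(0.0, t_end, n)
        gs = np.array([self.rate(t) for t in ts])
        return float(np.trapezoid(gs, ts))

    def scaled(self, factor: float) -> "GrowthSchedule":
        """Schedule with every rate multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise ValueError("scale factor must be >= 0")
        return replace(self, points=tuple((t, r * factor) for t, r in self.points))


@dataclass(frozen=True)
class GradientSpec:
    """Exogenous spatial modulation m(x) of one named kinetic constant.

    ``x`` is the cascade coordinate (distance from the initial bud locus in
    the growth direction).  Shapes: ``none`` (m = 1 everywhere), ``linear``
    (1 at the bud, reaching ``floor`` at ``scale`` and clamped there), and
    ``exponential`` (``floor + (1 - floor) * exp(-x / scale)``).  ``target``
    names the modulated kinetic constant; the special target ``"f"``
    multiplies the whole activator reaction term instead.
    """

    shape: str = "none"
    target: str = "b"
    floor: float = 1.0
    scale: float = 1.0

    def __post_init__(self):
        if self.shape not in ("none", "linear", "exponential"):
            raise ValueError(f"unknown gradient shape {self.shape!r}")
        if self.shape != "none":
            if not (0.0 < self.floor <= 1.0):
                raise ValueError("gradient floor must be in (0, 1]")
            if self.scale <= 0:
                raise ValueError("gradient scale must be > 0")

    def profile(self, x_cascade: np.ndarray) -> np.ndarray:
        d = np.maximum(np.asarray(x_cascade, dtype=float), 0.0)
        if self.shape == "none":
            return np.ones_like(d)
        if self.shape == "linear":
            return np.maximum(1.0 - (1.0 - self.floor) * d / self.scale, self.floor)
        return self.floor + (1.0 - self.floor) * np.exp(-d / self.scale)


@dataclass(frozen=True)
class Detection:
    """Signaling-center (peak) detection rule.

    A local maximum of u qualifies as a peak when its excess over the
    homogeneous steady state u* exceeds both ``threshold_frac`` times the
    largest excess any established peak has reached (relative threshold) and
    ``floor_frac * u*`` (absolute floor, which silences initial noise).  A
    qualifying maximum at distance >= ``min_separation`` from every
    established peak must persist for ``confirm_frames`` consecutive recorded
    frames before an insertion event is emitted (hysteresis against transient
    shoulder maxima).  ``min_separation`` defaults to 0.8 of the critical
    Turing wavelength.  ``size_delay`` is the lag after insertion at which
    the size proxy (integrated activator mass over the peak's inhibitory
    field) is measured.
    """

    threshold_frac: float = 0.5
    floor_frac: float = 0.2
    min_separation: float | None = None
    confirm_frames: int = 3
    size_delay: float = 12.0


@dataclass(frozen=True)
class Grid:
    """Spatial/temporal discretization: spacing dx, step dt, initial length L0."""

    dx: float = 0.25
    dt: float = 0.05
    L0: float = 12.0

    def __post_init__(self):
        if min(self.dx, self.dt, self.L0) <= 0:
            raise ValueError("dx, dt and L0 must all be > 0")


@dataclass(frozen=True)
class RDParameters:
    """Full parameterization of one cascade's reaction-diffusion run."""

    D_u: float = 1.0
    D_v: float = 40.0
    kinetics: Kinetics = field(default_factory=lambda: get_kinetics("schnakenberg"))
    growth: GrowthSchedule = field(default_factory=GrowthSchedule)
    gradient: GradientSpec = field(default_factory=GradientSpec)
    grid: Grid = field(default_factory=Grid)
    detection: Detection = field(default_factory=Detection)
    seed: int = 0
    noise_amplitude: float = 1e-3
    bud_amplitude: float = 0.5
    bud_width_cells: float = 5.0
    bud_offset: float = 0.0
    cascade: str = "premolar"

    def __post_init__(self):
        if self.D_u <= 0 or self.D_v <= 0:
            raise ValueError("diffusivities must be > 0")
        if self.D_v / self.D_u <= 1.0:
            raise ValueError("inhibitor must diffuse faster: D_v / D_u > 1")
        if self.cascade not in ("premolar", "molar", "generic"):
            raise ValueError(f"unknown cascade {self.cascade!r}")
        if self.bud_offset < 0:
            raise ValueError("bud_offset must be >= 0")


@dataclass
class RDState:
    """Discretized fields at one instant (lab coordinates)."""

    u: np.ndarray
    v: np.ndarray
    x: np.ndarray
    L: float
    t: float


@dataclass
class InsertionEvent:
    """Appearance of one new signaling center in a cascade.

    ``x_event`` is in cascade coordinates (distance from the initial bud
    locus along the growth direction at event time); ``x_lab`` is the
    lab-frame position on [0, L].
    """

    t_event: float
    x_event: float
    cascade: str
    ordinal: int
    x_lab: float = 0.0
    size_proxy: float | None = None

    @property
    def locus_label(self) -> str:
        loci = CASCADE_LOCI.get(self.cascade)
        if loci is None or self.ordinal > len(loci):
            return f"{self.cascade}_{self.ordinal}"
        return loci[self.ordinal - 1]


# --------------------------------------------------------------------------
# linear stability analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityResult:
    """Outcome of the dispersion-relation analysis of the homogeneous state."""

    homogeneous_stable: bool
    unstable: bool
    k_c: float | None
    lambda_c: float | None
    sigma_max: float | None
    band: tuple[float, float] | None
    steady_state: tuple[float, float]


def dispersion_growth_rate(kinetics: Kinetics, D_u: float, D_v: float, k):
    """Largest real part of the linearization's eigenvalues at wavenumber(s) k."""
    u0, v0 = kinetics.steady_state()
    fu, fv, hu, hv = kinetics.jacobian(u0, v0)
    k2 = np.asarray(k, dtype=float) ** 2
    tr = (fu + hv) - (D_u + D_v) * k2
    det = (fu - D_u * k2) * (hv - D_v * k2) - fv * hu
    disc = tr * tr - 4.0 * det
    sigma = np.where(disc >= 0.0, (tr + np.sqrt(np.maximum(disc, 0.0))) / 2.0, tr / 2.0)
    return float(sigma) if sigma.ndim == 0 else sigma


def linear_stability(kinetics: Kinetics, D_u: float, D_v: float) -> StabilityResult:
    """Turing (diffusion-driven) instability analysis; no D_v/D_u constraint.

    The homogeneous steady state must exist and be stable to spatially
    uniform perturbations; the instability band is located from the roots of
    the quartic ``q(k^2) = D_u D_v k^4 - (D_v f_u + D_u h_v) k^2 + det J``
    and the fastest-growing wavenumber ``k_c`` maximizes the dispersion
    relation inside the band.
    """
    u0, v0 = kinetics.steady_state()
    fu, fv, hu, hv = kinetics.jacobian(u0, v0)
    trJ, detJ = fu + hv, fu * hv - fv * hu
    homogeneous_stable = bool(trJ < 0 and detJ > 0)
    base = StabilityResult(homogeneous_stable, False, None, None, None, None,
                           (float(u0), float(v0)))
    if not homogeneous_stable:
        return base
    # q(s) < 0 for s = k^2 in the unstable band
    A, B, C = D_u * D_v, D_v * fu + D_u * hv, detJ
    disc = B * B - 4.0 * A * C
    if B <= 0.0 or disc <= 0.0:
        return base
    s1 = (B - math.sqrt(disc)) / (2.0 * A)
    s2 = (B + math.sqrt(disc)) / (2.0 * A)
    if s2 <= 0.0:
        return base
    s1 = max(s1, 0.0)
    k_lo, k_hi = math.sqrt(s1), math.sqrt(s2)
    res = minimize_scalar(
        lambda k: -dispersion_growth_rate(kinetics, D_u, D_v, k),
        bounds=(k_lo, k_hi), method="bounded",
        options={"xatol": 1e-12})
    k_c = float(res.x)
    sigma_max = float(-res.fun)
    if sigma_max <= 0.0:
        return base
    return StabilityResult(True, True, k_c, 2.0 * math.pi / k_c, sigma_max,
                           (k_lo, k_hi), (float(u0), float(v0)))


def turing_instability(params: RDParameters) -> StabilityResult:
    """Linear stability analysis of a full parameter set's kinetics."""
    return linear_stability(params.kinetics, params.D_u, params.D_v)


# --------------------------------------------------------------------------
# integrator internals
# --------------------------------------------------------------------------

def _diffusion_matrix(n: int, r: float) -> np.ndarray:
    """Banded (ab) form of I - r*Laplacian with zero-flux boundaries."""
    ab = np.zeros((3, n))
    ab[1, :] = 1.0 + 2.0 * r
    ab[0, 1:] = -r
    ab[2, :-1] = -r
    ab[0, 1] = -2.0 * r   # mirror condition at left boundary
    ab[2, -2] = -2.0 * r  # mirror condition at right boundary
    return ab


class _PeakTracker:
    """Frame-by-frame peak bookkeeping: tracking, hysteresis, size proxies."""

    def __init__(self, cascade: str, u_ss: float, det: Detection, min_sep: float):
        self.cascade = cascade
        self.u_ss = u_ss
        self.det = det
        self.min_sep = min_sep
        self.match_radius = min_sep / 2.0
        self.ref_excess = 0.0
        self.peaks: list[dict] = []        # established peaks
        self.candidates: list[dict] = []   # pending confirmation
        self.events: list[InsertionEvent] = []
        self.pending_proxy: list[tuple[InsertionEvent, int]] = []

    @staticmethod
    def _local_maxima(u: np.ndarray, x: np.ndarray) -> list[tuple[float, float]]:
        """(position, height) of local maxima, parabolic sub-grid refinement."""
        out = []
        n = len(u)
        if n < 3:
            return out
        if u[0] > u[1]:
            out.append((float(x[0]), float(u[0])))
        interior = np.nonzero((u[1:-1] >= u[:-2]) & (u[1:-1] > u[2:]))[0] + 1
        for i in interior:
            denom = u[i - 1] - 2.0 * u[i] + u[i + 1]
            off = 0.0 if denom >= 0 or abs(denom) < 1e-300 else \
                0.5 * (u[i - 1] - u[i + 1]) / denom
            off = float(np.clip(off, -0.5, 0.5))
            dx_loc = x[i + 1] - x[i]
            out.append((float(x[i] + off * dx_loc), float(u[i])))
        if u[-1] > u[-2]:
            out.append((float(x[-1]), float(u[-1])))
        return out

    def update(self, u: np.ndarray, x: np.ndarray, t: float,
               bud_lab: float, sign: float):
        maxima = self._local_maxima(u, x)
        threshold = max(self.det.threshold_frac * self.ref_excess,
                        self.det.floor_frac * self.u_ss)
        qualified = [(p, h) for p, h in maxima if (h - self.u_ss) >= threshold]

        # update established peaks to the nearest qualified maximum
        used = [False] * len(qualified)
        for peak in self.peaks:
            best, bestd = None, self.match_radius
            for j, (p, h) in enumerate(qualified):
                d = abs(p - peak["x"])
                if d < bestd and not used[j]:
                    best, bestd = j, d
            if best is not None:
                used[best] = True
                p, h = qualified[best]
                peak["x"], peak["h"] = p, h
                self.ref_excess = max(self.ref_excess, h - self.u_ss)

        # candidate handling for unmatched maxima
        new_candidates = []
        for j, (p, h) in enumerate(qualified):
            if used[j]:
                continue
            if any(abs(p - peak["x"]) < self.min_sep for peak in self.peaks):
                continue
            matched = None
            for cand in self.candidates:
                if abs(p - cand["x"]) < self.match_radius:
                    matched = cand
                    break
            if matched is not None:
                matched["x"], matched["frames"] = p, matched["frames"] + 1
                self.candidates.remove(matched)
                cand = matched
            else:
                cand = {"x": p, "frames": 1, "t_first": t}
            if cand["frames"] >= self.det.confirm_frames:
                self._emit(cand, t, bud_lab, sign)
            else:
                new_candidates.append(cand)
        self.candidates = new_candidates

    def _emit(self, cand: dict, t: float, bud_lab: float, sign: float):
        x_lab = cand["x"]
        event = InsertionEvent(
            t_event=cand["t_first"],
            x_event=max(sign * (x_lab - bud_lab), 0.0),
            cascade=self.cascade,
            ordinal=len(self.events) + 1,
            x_lab=x_lab,
        )
        self.events.append(event)
        self.peaks.append({"x": x_lab, "h": self.u_ss, "event": event})
        self.pending_proxy.append((event, len(self.peaks) - 1))

    def measure_proxies(self, u: np.ndarray, x: np.ndarray, t: float,
                        final: bool = False):
        remaining = []
        for event, idx in self.pending_proxy:
            if final or t >= event.t_event + self.det.size_delay:
                xp = self.peaks[idx]["x"]
                w = self.min_sep / 2.0
                event.size_proxy = self._window_mass(u, x, xp, w)
            else:
                remaining.append((event, idx))
        self.pending_proxy = remaining

    @staticmethod
    def _window_mass(u: np.ndarray, x: np.ndarray, xp: float, w: float) -> float:
        """Integrated activator mass over [xp - w, xp + w].

        Windows truncated by a zero-flux boundary are completed by mirror
        reflection (the Neumann condition makes the field locally symmetric),
        so boundary peaks are not undercounted relative to interior ones.
        """
        L = float(x[-1])
        lo, hi = xp - w, xp + w
        mask = (x >= max(lo, 0.0)) & (x <= min(hi, L))
        if mask.sum() < 2:
            return float(u[np.argmin(np.abs(x - xp))] * 2.0 * w)
        mass = float(np.trapezoid(u[mask], x[mask]))
        if lo < 0.0:  # reflect the part of the window beyond the left boundary
            m2 = (x >= 0.0) & (x <= -lo)
            if m2.sum() >= 2:
                mass += float(np.trapezoid(u[m2], x[m2]))
        if hi > L:  # reflect beyond the right boundary
            m2 = (x >= 2.0 * L - hi) & (x <= L)
            if m2.sum() >= 2:
                mass += float(np.trapezoid(u[m2], x[m2]))
        return mass


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

@dataclass
class SimulationResult:
    """Trajectory snapshots plus the detected insertion events of one run."""

    params: RDParameters
    t_end: float
    events: list[InsertionEvent]
    snapshots: list[RDState]
    lambda_c: float | None
    min_separation: float
    min_u: float
    min_v: float

    @property
    def final_state(self) -> RDState:
        return self.snapshots[-1]

    @property
    def n_events(self) -> int:
        return len(self.events)


def _constants_on_grid(params: RDParameters, x_cascade: np.ndarray):
    """Kinetic constants resolved per grid point under the gradient spec."""
    consts = dict(params.kinetics.constants)
    m_f = None
    if params.gradient.shape != "none":
        m = params.gradient.profile(x_cascade)
        if params.gradient.target == "f":
            m_f = m
        else:
            if params.gradient.target not in consts:
                raise ValueError(
                    f"gradient target {params.gradient.target!r} is not a "
                    f"constant of kinetics {params.kinetics.name!r}")
            consts[params.gradient.target] = consts[params.gradient.target] * m
    kin = get_kinetics(params.kinetics.name, **consts)
    return kin, m_f


def simulate(params: RDParameters, t_end: float, record_every: float = 0.5,
             store: str = "all") -> SimulationResult:
    """Integrate one cascade and extract its insertion events.

    ``record_every`` is the frame interval (simulation time) at which peaks
    are detected and snapshots stored; ``store="final"`` keeps only the last
    snapshot (useful in parameter sweeps).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    grid, growth, det = params.grid, params.growth, params.detection
    kin = params.kinetics
    u_ss, v_ss = kin.steady_state()
    u_ss, v_ss = float(u_ss), float(v_ss)

    stab = linear_stability(kin, params.D_u, params.D_v)
    lambda_c = stab.lambda_c
    min_sep = det.min_separation
    if min_sep is None:
        min_sep = 0.8 * lambda_c if lambda_c is not None else max(
            5.0 * grid.dx, grid.L0 / 4.0)

    # grid setup: apical mode keeps spacing == dx exactly; uniform mode keeps
    # the node count at round(L/dx)+1 and lets the spacing stretch
    n = int(round(grid.L0 / grid.dx)) + 1
    L = (n - 1) * grid.dx if growth.mode == "apical" else grid.L0
    x = np.linspace(0.0, L, n)
    bud_lab = (params.bud_offset if growth.growth_end == "right"
               else L - params.bud_offset)
    sign = 1.0 if growth.growth_end == "right" else -1.0

    rng = np.random.default_rng(params.seed)
    width = params.bud_width_cells * grid.dx
    u = u_ss + params.bud_amplitude * np.exp(-((x - bud_lab) ** 2) / (2.0 * width ** 2))
    u += params.noise_amplitude * rng.uniform(-1.0, 1.0, size=n)
    v = np.full(n, v_ss)

    def cascade_coords(x_arr):
        return np.maximum(sign * (x_arr - bud_lab), 0.0)

    kin_grid, m_f = _constants_on_grid(params, cascade_coords(x))
    ab_cache: dict = {}

    def diffusion_ab(npts: int, h: float):
        key = (npts, h)
        if key not in ab_cache:
            ru = params.D_u * grid.dt / (h * h)
            rv = params.D_v * grid.dt / (h * h)
            ab_cache[key] = (_diffusion_matrix(npts, ru), _diffusion_matrix(npts, rv))
        return ab_cache[key]

    tracker = _PeakTracker(params.cascade, u_ss, det, min_sep)
    snapshots: list[RDState] = []
    min_u = min_v = np.inf
    growth_buffer = 0.0
    t = 0.0
    next_record = 0.0
    n_steps = int(math.ceil(t_end / grid.dt))

    for step in range(n_steps + 1):
        # --- record / detect on frame boundaries
        if t >= next_record - 1e-12 or step == n_steps:
            tracker.update(u, x, t, bud_lab, sign)
            tracker.measure_proxies(u, x, t)
            if store == "all" or step == n_steps:
                snapshots.append(RDState(u.copy(), v.copy(), x.copy(), L, t))
            next_record += record_every
        if step == n_steps:
            break

        # --- reaction (explicit Euler) with stability guard
        fu, fv, hu, hv = kin_grid.jacobian(u, v)
        rho = max(np.max(np.abs(fu) + np.abs(fv)), np.max(np.abs(hu) + np.abs(hv)))
        if grid.dt * rho > 2.0:
            raise SimulationError(
                f"explicit reaction step unstable at t={t:.3f}: "
                f"dt * max row sum of Jacobian = {grid.dt * rho:.3f} > 2; "
                f"reduce dt below {2.0 / rho:.4g}")
        f_val = kin_grid.f(u, v)
        if m_f is not None:
            f_val = f_val * m_f
        h_val = kin_grid.h(u, v)
        g = growth.rate(t)
        if growth.mode == "uniform" and L > 0:
            dil = g / L
            u = u + grid.dt * (f_val - dil * u)
            v = v + grid.dt * (h_val - dil * v)
        else:
            u = u + grid.dt * f_val
            v = v + grid.dt * h_val

        # --- diffusion (implicit backward Euler)
        h_spacing = grid.dx if growth.mode == "apical" else L / (len(u) - 1)
        ab_u, ab_v = diffusion_ab(len(u), h_spacing)
        u = solve_banded((1, 1), ab_u, u)
        v = solve_banded((1, 1), ab_v, v)

        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise SimulationError(f"non-finite field encountered at t={t:.3f}")
        min_u = min(min_u, float(u.min()))
        min_v = min(min_v, float(v.min()))

        # --- growth
        if growth.mode == "apical" and g > 0.0:
            growth_buffer += g * grid.dt
            while growth_buffer >= grid.dx:
                growth_buffer -= grid.dx
                if growth.growth_end == "right":
                    u = np.append(u, u_ss)
                    v = np.append(v, v_ss)
                else:
                    u = np.insert(u, 0, u_ss)
                    v = np.insert(v, 0, v_ss)
                    bud_lab += grid.dx
                    for peak in tracker.peaks:
                        peak["x"] += grid.dx
                    for cand in tracker.candidates:
                        cand["x"] += grid.dx
                    for ev in tracker.events:
                        ev.x_lab += grid.dx
                L += grid.dx
                x = np.linspace(0.0, L, len(u))
                kin_grid, m_f = _constants_on_grid(params, cascade_coords(x))
        elif growth.mode == "uniform" and g > 0.0:
            L += g * grid.dt
            n_target = int(round(L / grid.dx)) + 1
            x = np.linspace(0.0, L, len(u))
            if n_target > len(u):
                x_new = np.linspace(0.0, L, n_target)
                u = np.interp(x_new, x, u)
                v = np.interp(x_new, x, v)
                x = x_new
            kin_grid, m_f = _constants_on_grid(params, cascade_coords(x))

        t += grid.dt

    tracker.measure_proxies(u, x, t, final=True)
    return SimulationResult(
        params=params, t_end=t_end, events=tracker.events, snapshots=snapshots,
        lambda_c=lambda_c, min_separation=min_sep,
        min_u=min_u, min_v=min_v,
    )


# --------------------------------------------------------------------------
# cascade-level drivers
# --------------------------------------------------------------------------

@dataclass
class TwoCascadeResult:
    """Paired premolar/molar runs and the merged appearance timeline."""

    premolar: SimulationResult
    molar: SimulationResult

    @property
    def merged_timeline(self) -> list[dict]:
        """Time-ordered appearance sequence across both cascades.

        ``x_jaw`` is a signed jaw coordinate with the initiating buds at the
        origin: premolar events extend anteriorly (negative), molar events
        posteriorly (positive).
        """
        rows = []
        for res, sgn in ((self.premolar, -1.0), (self.molar, +1.0)):
            for ev in res.events:
                rows.append({
                    "t_event": ev.t_event,
                    "cascade": ev.cascade,
                    "ordinal": ev.ordinal,
                    "locus_label": ev.locus_label,
                    "x_jaw": sgn * ev.x_event,
                    "size_proxy": ev.size_proxy,
                })
        rows.sort(key=lambda r: (r["t_event"], r["x_jaw"]))
        return rows


def two_cascade_run(premolar_params: RDParameters, molar_params: RDParameters,
                    t_end: float, record_every: float = 0.5,
                    enforce_directions: bool = True,
                    store: str = "all") -> TwoCascadeResult:
    """Run the two independent, oppositely directed cascades.

    The cascades share no state: each gets its own domain, fields and RNG
    stream.  By default the premolar cascade must be configured to grow
    anteriorly and the molar cascade posteriorly (the observed geometry of
    the dental lamina developing in both directions from the dP4 and M1
    buds); pass ``enforce_directions=False`` to override.
    """
    if enforce_directions:
        if premolar_params.growth.direction != "anterior":
            raise ValueError("premolar cascade must grow anteriorly "
                             "(pass enforce_directions=False to override)")
        if molar_params.growth.direction != "posterior":
            raise ValueError("molar cascade must grow posteriorly "
                             "(pass enforce_directions=False to override)")
    pre = simulate(premolar_params, t_end, record_every=record_every, store=store)
    mol = simulate(molar_params, t_end, record_every=record_every, store=store)
    return TwoCascadeResult(premolar=pre, molar=mol)


def gradient_run(params: RDParameters, t_end: float,
                 record_every: float = 0.5, store: str = "all") -> SimulationResult:
    """Run one cascade under an exogenous spatial gradient.

    Identical to :func:`simulate` but requires an active gradient spec; the
    events' size proxies are the quantity of interest (a gradient decaying
    away from the bud yields monotonically decreasing peak sizes).
    """
    if params.gradient.shape == "none":
        raise ValueError("gradient_run requires an active gradient spec")
    return simulate(params, t_end, record_every=record_every, store=store)


@dataclass(frozen=True)
class SequenceSummary:
    """Counts, locus labels and inter-insertion intervals of one cascade."""

    cascade: str
    n_events: int
    locus_labels: tuple
    absent: tuple
    t_events: tuple
    x_events: tuple
    intervals: tuple
    size_proxies: tuple


def insertion_sequence_summary(events: Sequence[InsertionEvent],
                               cascade: str | None = None) -> SequenceSummary:
    """Summarize one cascade's insertion events.

    Ordinals map deterministically to locus labels (premolar cascade:
    dP4, dP3, P2; molar: M1, M2, M3); loci beyond the number of events are
    reported absent.
    """
    evs = sorted(events, key=lambda e: e.ordinal)
    if cascade is None:
        cascade = evs[0].cascade if evs else "generic"
    if any(e.cascade != cascade for e in evs):
        raise ValueError("events from multiple cascades passed to summary")
    full = CASCADE_LOCI.get(cascade, ())
    labels = tuple(e.locus_label for e in evs)
    absent = tuple(full[len(evs):]) if full else ()
    ts = tuple(e.t_event for e in evs)
    return SequenceSummary(
        cascade=cascade,
        n_events=len(evs),
        locus_labels=labels,
        absent=absent,
        t_events=ts,
        x_events=tuple(e.x_event for e in evs),
        intervals=tuple(np.diff(ts).tolist()),
        size_proxies=tuple(e.size_proxy for e in evs),
    )
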