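"""Differential geometry of framed space curves.

Neurite centerlines are modelled as degree-4 B-splines carrying a Bishop
(rotation-minimizing) frame: an orthonormal triad (t, n1, n2) whose two
signed curvatures (k1, k2) encode bending without any torsion-induced spin
about the tangent.  The frame evolves along arc length s as

    dgamma/ds = t
    dt/ds     = k1 n1 + k2 n2  (= k, the curvature vector)
    dn1/ds    = -k1 t
    dn2/ds    = -k2 t

This module provides spline fitting, frame transport, the curvature-adaptive
step size, and the two single-step integrators used during recurrent
inference (forward Euler with re-orthonormalization, and exact advance along
the local parabola).  All lengths are in micrometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, interpolate, optimize

__all__ = [
    "FrameState",
    "Steering",
    "StepConfig",
    "CenterlineCurve",
    "FramedCurve",
    "fit_bspline",
    "complete_frame",
    "transport_bishop_frame",
    "adaptive_step",
    "integrate_euler",
    "integrate_parabola",
    "advance_parabola",
    "parabola_point",
    "rotate_flip_frame",
    "closest_point",
]

_ORTHO_TOL = 1e-9
_GAUSS5 = np.polynomial.legendre.leggauss(5)
_GAUSS10 = np.polynomial.legendre.leggauss(10)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize zero vector")
    return v / n


@dataclass(frozen=True)
class FrameState:
    """Agent pose: position plus orthonormal Bishop frame (t, n1, n2)."""

    position: np.ndarray
    t: np.ndarray
    n1: np.ndarray
    n2: np.ndarray

    def __post_init__(self):
        for name in ("position", "t", "n1", "n2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def validate(self, tol: float = _ORTHO_TOL, require_right_handed: bool = True) -> None:
        for v in (self.t, self.n1, self.n2):
            if abs(np.linalg.norm(v) - 1.0) > tol:
                raise ValueError("frame vectors must be unit length")
        for a, b in ((self.t, self.n1), (self.t, self.n2), (self.n1, self.n2)):
            if abs(float(a @ b)) > tol:
                raise ValueError("frame vectors must be pairwise orthogonal")
        if require_right_handed and float(self.t @ np.cross(self.n1, self.n2)) <= 0.0:
            raise ValueError("frame must be right-handed")

    def orthonormality_residual(self) -> float:
        M = np.stack([self.t, self.n1, self.n2])
        return float(np.abs(M @ M.T - np.eye(3)).max())

    def reversed(self) -> "FrameState":
        """Pose for flying the opposite way (t -> -t, handedness preserved)."""
        return FrameState(self.position, -self.t, self.n1, -self.n2)


@dataclass(frozen=True)
class Steering:
    """Bishop curvatures (1/um) plus optional predicted membrane distance (um)."""

    k1: float
    k2: float
    membrane_distance: float | None = None

    @property
    def kappa(self) -> float:
        return float(np.hypot(self.k1, self.k2))

    def curvature_vector(self, state: FrameState) -> np.ndarray:
        return self.k1 * state.n1 + self.k2 * state.n2


@dataclass(frozen=True)
class StepConfig:
    """Curvature-adaptive step size parameters.

    d : default step (um), typically the smallest voxel dimension.
    p : physical size of the projection plane (um).
    f : step-size factor; 1 during training, up to 5 during inference.
    """

    d: float = 11.24e-3
    p: float = 1.0
    f: float = 1.0

    def __post_init__(self):
        if not (self.d > 0 and self.p > 0):
            raise ValueError("d and p must be positive")
        if not (1.0 <= self.f <= 5.0):
            raise ValueError("step factor f must lie in [1, 5]")


def adaptive_step(kappa: float, cfg: StepConfig) -> float:
    """Step length f*d / (1 + (p/2)*kappa); shrinks in high-curvature stretches."""
    if kappa < 0:
        raise ValueError("curvature magnitude must be non-negative")
    return cfg.f * cfg.d / (1.0 + 0.5 * cfg.p * kappa)


def complete_frame(t: np.ndarray, n1_hint: np.ndarray | None = None) -> FrameState:
    """Deterministically complete a tangent into a right-handed frame at origin.

    Any rotation of (n1, n2) about t is a valid Bishop frame initialization;
    we pick the coordinate axis least aligned with t (or project the caller's
    hint) so that the choice is reproducible.
    """
    t = _unit(np.asarray(t, dtype=float))
    if n1_hint is None:
        axis = np.zeros(3)
        axis[int(np.argmin(np.abs(t)))] = 1.0
    else:
        axis = np.asarray(n1_hint, dtype=float)
    n1 = axis - (axis @ t) * t
    n1 = _unit(n1)
    n2 = np.cross(t, n1)
    return FrameState(np.zeros(3), t, n1, n2)


# ---------------------------------------------------------------------------
# Centerline curves
# ---------------------------------------------------------------------------


class CenterlineCurve:
    """A degree-k B-spline space curve reparametrized by arc length.

    Wraps a vector-valued ``scipy.interpolate.BSpline`` together with a
    monotone arc-length table so that all public evaluation is in terms of
    arc length s (um).
    """

    def __init__(self, spline: interpolate.BSpline, table_size: int = 512):
        self.spline = spline
        self._d1 = spline.derivative(1)
        self._d2 = spline.derivative(2)
        self.degree = spline.k
        lo, hi = spline.t[spline.k], spline.t[-spline.k - 1]
        self._u_range = (float(lo), float(hi))
        self._build_arc_table(table_size)

    # -- arc-length machinery ------------------------------------------------

    def _speed(self, u):
        return np.linalg.norm(np.atleast_2d(self._d1(u)), axis=-1)

    def _build_arc_table(self, n: int) -> None:
        lo, hi = self._u_range
        u = np.linspace(lo, hi, n)
        # Gauss-Legendre quadrature of |gamma'(u)| per sub-interval; the
        # integrand is smooth inside spline spans so order 10 per cell of a
        # fine grid reaches ~1e-10 relative error.
        x, w = _GAUSS10
        mid = 0.5 * (u[:-1] + u[1:])
        half = 0.5 * np.diff(u)
        pts = mid[:, None] + half[:, None] * x[None, :]
        sp = self._speed(pts.ravel()).reshape(pts.shape)
        seg = (sp * w[None, :]).sum(axis=1) * half
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if np.any(np.diff(s) <= 0):
            raise ValueError("degenerate curve: arc length not strictly increasing")
        self._table_u = u
        self._table_s = s
        self.length = float(s[-1])

    def s_to_u(self, s):
        s_arr = np.clip(np.atleast_1d(np.asarray(s, dtype=float)), 0.0, self.length)
        u = np.interp(s_arr, self._table_s, self._table_u)
        # Newton refinement on ds/du = |gamma'(u)| using the local table anchor.
        idx = np.clip(np.searchsorted(self._table_u, u) - 1, 0, len(self._table_u) - 2)
        x, w = _GAUSS5
        for _ in range(3):
            u0 = self._table_u[idx]
            s0 = self._table_s[idx]
            # local arc length from anchor via 5-point Gauss on [u0, u]
            mid = 0.5 * (u0 + u)
            half = 0.5 * (u - u0)
            sp = self._speed((mid[:, None] + half[:, None] * x[None, :]).ravel())
            sp = sp.reshape(len(u), -1)
            s_loc = s0 + (sp * w[None, :]).sum(axis=1) * half
            u = u - (s_loc - s_arr) / np.maximum(self._speed(u), 1e-30)
            u = np.clip(u, self._u_range[0], self._u_range[1])
        return u if np.ndim(s) else float(u[0])

    # -- evaluation in arc length -------------------------------------------

    def position(self, s):
        return np.asarray(self.spline(self.s_to_u(s)))

    def tangent(self, s):
        d1 = np.atleast_2d(self._d1(self.s_to_u(s)))
        t = d1 / np.linalg.norm(d1, axis=-1, keepdims=True)
        return t if np.ndim(s) else t[0]

    def curvature_vector(self, s):
        u = self.s_to_u(s)
        d1 = np.atleast_2d(self._d1(u))
        d2 = np.atleast_2d(self._d2(u))
        v2 = (d1 * d1).sum(axis=-1, keepdims=True)
        t = d1 / np.sqrt(v2)
        k = (d2 - t * (t * d2).sum(axis=-1, keepdims=True)) / v2
        return k if np.ndim(s) else k[0]

    def kappa(self, s):
        k = np.atleast_2d(self.curvature_vector(s))
        kk = np.linalg.norm(k, axis=-1)
        return kk if np.ndim(s) else float(kk[0])


def fit_bspline(
    nodes: Sequence[Sequence[float]] | np.ndarray,
    degree: int = 4,
    tol: float | None = None,
) -> CenterlineCurve:
    """Fit a degree-k B-spline centerline through ordered nodes.

    With ``tol=None`` the spline interpolates the nodes exactly.  With a
    positive ``tol`` a least-squares spline on clamped uniform knots is used
    and interior knots are refined until the maximum node distance drops
    below ``tol`` — appropriate when the nodes are jittery human annotations
    that should be smoothed rather than reproduced.
    """
    nodes = np.asarray(nodes, dtype=float)
    if nodes.ndim != 2 or nodes.shape[1] != 3:
        raise ValueError("nodes must be an (n, 3) array")
    if not np.all(np.isfinite(nodes)):
        raise ValueError("nodes must be finite")
    n = len(nodes)
    if n < degree + 1:
        raise ValueError(f"need at least degree+1={degree + 1} nodes, got {n}")
    chord = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
    if np.any(chord < 1e-12):
        raise ValueError("repeated coincident nodes are not allowed")
    u = np.concatenate([[0.0], np.cumsum(chord)])
    u /= u[-1]

    if tol is None:
        spline = interpolate.make_interp_spline(u, nodes, k=degree)
        return CenterlineCurve(spline)

    # least-squares with clamped uniform knots, refined until fit is tight
    n_interior = max(0, n - degree - 1) // 2
    while True:
        interior = np.linspace(0, 1, n_interior + 2)[1:-1]
        knots = np.concatenate([np.zeros(degree + 1), interior, np.ones(degree + 1)])
        try:
            spline = interpolate.make_lsq_spline(u, nodes, knots, k=degree)
        except Exception:
            spline = interpolate.make_interp_spline(u, nodes, k=degree)
            return CenterlineCurve(spline)
        err = np.linalg.norm(spline(u) - nodes, axis=1).max()
        if err < tol or n_interior >= n - degree - 1:
            return CenterlineCurve(spline)
        n_interior = min(2 * n_interior + 1, n - degree - 1)


# ---------------------------------------------------------------------------
# Frame transport
# ---------------------------------------------------------------------------


def _double_reflection(x0, t0, n0, x1, t1):
    """One rotation-minimizing transport step of normal n0 from (x0,t0) to (x1,t1)."""
    v1 = x1 - x0
    c1 = float(v1 @ v1)
    if c1 < 1e-30:
        n_l, t_l = n0, t0
    else:
        n_l = n0 - (2.0 / c1) * float(v1 @ n0) * v1
        t_l = t0 - (2.0 / c1) * float(v1 @ t0) * v1
    v2 = t1 - t_l
    c2 = float(v2 @ v2)
    if c2 < 1e-30:
        n_new = n_l
    else:
        n_new = n_l - (2.0 / c2) * float(v2 @ n_l) * v2
    # guard against drift
    n_new = n_new - float(n_new @ t1) * t1
    return _unit(n_new)


def transport_bishop_frame(
    curve: CenterlineCurve,
    initial: FrameState,
    s_samples: Sequence[float] | np.ndarray,
    ds_max: float | None = None,
) -> list[tuple[FrameState, Steering]]:
    """Transport a Bishop frame along a curve, reporting (frame, steering) pairs.

    The initial tangent must match the curve tangent at the first sample.
    Transport uses the double-reflection method on a dense internal grid, so
    the returned frame is rotation-minimizing (no spin about t); k1, k2 are
    the projections of the curve's curvature vector onto n1, n2.
    """
    s_samples = np.asarray(s_samples, dtype=float)
    if np.any(np.diff(s_samples) < 0):
        raise ValueError("s_samples must be non-decreasing")
    t_curve = curve.tangent(s_samples[0])
    angle = np.arccos(np.clip(float(initial.t @ t_curve), -1.0, 1.0))
    if angle > 1e-6:
        raise ValueError("initial tangent must align with curve tangent (angle < 1e-6 rad)")

    if ds_max is None:
        ds_max = max(curve.length / 2048.0, 1e-6)

    # dense internal grid: union of requested samples and a uniform march
    s0, s_end = float(s_samples[0]), float(s_samples[-1])
    n_int = max(int(np.ceil((s_end - s0) / ds_max)), 1)
    s_dense = np.union1d(np.linspace(s0, s_end, n_int + 1), s_samples)
    pos = np.atleast_2d(curve.position(s_dense))
    tan = np.atleast_2d(curve.tangent(s_dense))
    kvecs = np.atleast_2d(curve.curvature_vector(s_dense))
    sample_idx = np.searchsorted(s_dense, s_samples)

    out: list[tuple[FrameState, Steering]] = []
    n1 = initial.n1 - float(initial.n1 @ t_curve) * t_curve
    n1 = _unit(n1)
    emit_set = {int(i) for i in sample_idx}

    def emit(i, n1v):
        t = tan[i]
        n2v = np.cross(t, n1v)
        k = kvecs[i]
        out.append(
            (FrameState(pos[i], t, n1v, n2v), Steering(float(k @ n1v), float(k @ n2v)))
        )

    if 0 in emit_set:
        for _ in range(int(np.sum(sample_idx == 0))):
            emit(0, n1)
    for i in range(1, len(s_dense)):
        n1 = _double_reflection(pos[i - 1], tan[i - 1], n1, pos[i], tan[i])
        if i in emit_set:
            for _ in range(int(np.sum(sample_idx == i))):
                emit(i, n1)
    return out


# ---------------------------------------------------------------------------
# Single-step integrators
# ---------------------------------------------------------------------------


def integrate_euler(state: FrameState, steer: Steering, ds: float) -> FrameState:
    """One forward-Euler step of the Bishop ODEs + Gram-Schmidt (order t, n1, n2)."""
    if ds <= 0:
        raise ValueError("ds must be positive")
    if ds * steer.kappa > 1.0:
        warnings.warn("Euler step too coarse: ds * kappa > 1", stacklevel=2)
    k = steer.curvature_vector(state)
    pos = state.position + ds * state.t
    t = state.t + ds * k
    n1 = state.n1 - ds * steer.k1 * state.t
    n2 = state.n2 - ds * steer.k2 * state.t
    t = _unit(t)
    n1 = _unit(n1 - float(n1 @ t) * t)
    n2 = n2 - float(n2 @ t) * t - float(n2 @ n1) * n1
    n2 = _unit(n2)
    return FrameState(pos, t, n1, n2)


def _parabola_sigma(kappa: float, ds: float, tol: float = 1e-10) -> float:
    """Solve arc length L(sigma) = ds for x(sigma) = sigma t + sigma^2/2 k.

    L(sigma) = (sigma*sqrt(1+kappa^2 sigma^2) + asinh(kappa*sigma)/kappa) / 2,
    solved by Newton; L' = sqrt(1 + kappa^2 sigma^2).
    """
    if kappa == 0.0:
        return ds
    sigma = ds
    for _ in range(100):
        q = np.sqrt(1.0 + (kappa * sigma) ** 2)
        L = 0.5 * (sigma * q + np.arcsinh(kappa * sigma) / kappa)
        d = L - ds
        if abs(d) < tol:
            break
        sigma -= d / q
    return sigma


def parabola_point(state: FrameState, steer: Steering, sigma: float) -> np.ndarray:
    """Point on the steering parabola x(sigma) = pos + sigma t + sigma^2/2 k."""
    k = steer.curvature_vector(state)
    return state.position + sigma * state.t + 0.5 * sigma**2 * k


_GAUSS16 = np.polynomial.legendre.leggauss(16)


def advance_parabola(state: FrameState, kvec: np.ndarray, ds: float) -> FrameState:
    """Advance exactly along x(sigma) = pos + sigma t + sigma^2/2 kvec by arc length ds.

    ``kvec`` is a world-space curvature vector and may carry a tangential
    component (needed to continue a fixed parabola from a non-vertex point).
    The curve is planar, so rotation-minimizing transport of the normals is
    closed-form: the component of n1 along the plane normal b is conserved
    and the in-plane component co-rotates with the tangent.  The arc-length
    equation is solved by Newton to 1e-12.
    """
    if ds <= 0:
        raise ValueError("ds must be positive")
    kvec = np.asarray(kvec, dtype=float)
    t0 = state.t
    k_perp = kvec - float(kvec @ t0) * t0
    if float(np.linalg.norm(k_perp)) < 1e-14:
        # (near-)straight advance; speed |t + sigma k| may still vary if k || t
        a = float(kvec @ t0)
        if abs(a) < 1e-14:
            sigma = ds
        else:
            # |x'| = 1 + a*sigma  =>  ds = sigma + a sigma^2/2
            sigma = (np.sqrt(1.0 + 2.0 * a * ds) - 1.0) / a
        pos = state.position + sigma * t0 + 0.5 * sigma**2 * kvec
        t_new = _unit(t0 + sigma * kvec)
        return FrameState(pos, t_new, state.n1, np.cross(t_new, state.n1))

    def speed(sig):
        v = t0[None, :] + np.atleast_1d(sig)[:, None] * kvec[None, :]
        return np.linalg.norm(v, axis=1)

    def arclen(sig):
        x, w = _GAUSS16
        pts = 0.5 * sig * (x + 1.0)
        return 0.5 * sig * float(speed(pts) @ w)

    sigma = ds
    for _ in range(100):
        d = arclen(sigma) - ds
        if abs(d) < 1e-12:
            break
        sigma -= d / float(speed(np.array([sigma]))[0])

    b = _unit(np.cross(t0, kvec))
    pos = state.position + sigma * t0 + 0.5 * sigma**2 * kvec
    t_new = _unit(t0 + sigma * kvec)
    n_plane0 = np.cross(b, t0)
    n_plane1 = np.cross(b, t_new)
    a_in = float(state.n1 @ n_plane0)
    a_out = float(state.n1 @ b)
    n1_new = a_in * n_plane1 + a_out * b
    n1_new = _unit(n1_new - float(n1_new @ t_new) * t_new)
    n2_new = np.cross(t_new, n1_new)
    return FrameState(pos, t_new, n1_new, n2_new)


def integrate_parabola(state: FrameState, steer: Steering, ds: float) -> FrameState:
    """Advance exactly along the local steering parabola by arc length ds.

    The steering commands (k1, k2) define the parabola
    x(sigma) = pos + sigma t + sigma^2/2 (k1 n1 + k2 n2); the agent moves a
    true arc length ds along it and the frame is transported without spin.
    """
    return advance_parabola(state, steer.curvature_vector(state), ds)


def rotate_flip_frame(state: FrameState, theta: float, flip: bool = False) -> FrameState:
    """Rotate (n1, n2) by theta about t; optionally flip n2.

    Rotations about the tangent (applied jointly to the normals and the
    Bishop curvatures) are invariance transformations of the flight problem;
    the flip changes handedness, which is restored downstream by negating k2.
    """
    c, s = np.cos(theta), np.sin(theta)
    n1 = c * state.n1 + s * state.n2
    n2 = -s * state.n1 + c * state.n2
    if flip:
        n2 = -n2
    return FrameState(state.position, state.t, n1, n2)


def closest_point(
    curve: CenterlineCurve,
    x: Sequence[float] | np.ndarray,
    coarse_n: int = 512,
    bounds: tuple[float, float] | None = None,
) -> tuple[float, np.ndarray]:
    """Globally closest point on the curve to x; ties broken toward smaller s.

    ``bounds`` restricts the search to an arc-length window (used when the
    caller already knows the approximate location).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("query point must be finite")
    lo_b, hi_b = (0.0, curve.length) if bounds is None else (
        max(0.0, bounds[0]), min(curve.length, bounds[1])
    )
    s_grid = np.linspace(lo_b, hi_b, coarse_n)
    d2 = ((curve.position(s_grid) - x) ** 2).sum(axis=1)
    i = int(np.argmin(d2))
    lo = s_grid[max(i - 1, 0)]
    hi = s_grid[min(i + 1, coarse_n - 1)]

    def f(s):
        return float(((curve.position(float(s)) - x) ** 2).sum())

    res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    s_best, f_best = float(res.x), float(res.fun)
    for s_end in (lo_b, hi_b):
        fe = f(s_end)
        if fe < f_best - 1e-18 or (abs(fe - f_best) <= 1e-18 and s_end < s_best):
            s_best, f_best = s_end, fe
    return s_best, curve.position(s_best)


# ---------------------------------------------------------------------------
# Framed curves (ground truth for training / evaluation)
# ---------------------------------------------------------------------------


class FramedCurve:
    """A centerline curve with a transported Bishop frame cached on a grid.

    ``frame_at(s)`` reconstructs the rotation-minimizing frame at any arc
    length by one transport step from the nearest cached grid point, so
    repeated queries (flight-policy targets, oracle steering) stay cheap.
    """

    def __init__(self, curve: CenterlineCurve, initial: FrameState | None = None,
                 grid_n: int = 256, radius: float | Callable[[float], float] = 0.2):
        self.curve = curve
        t0 = curve.tangent(0.0)
        if initial is None:
            initial = complete_frame(t0)
        self.s_grid = np.linspace(0.0, curve.length, grid_n)
        pairs = transport_bishop_frame(curve, FrameState(curve.position(0.0), t0,
                                                         initial.n1, initial.n2),
                                       self.s_grid)
        self._frames = [p[0] for p in pairs]
        self._radius = radius

    @property
    def length(self) -> float:
        return self.curve.length

    def radius_at(self, s: float) -> float:
        if callable(self._radius):
            return float(self._radius(s))
        return float(self._radius)

    def frame_at(self, s: float) -> FrameState:
        s = float(np.clip(s, 0.0, self.curve.length))
        i = int(np.argmin(np.abs(self.s_grid - s)))
        ref = self._frames[i]
        x1 = self.curve.position(s)
        t1 = self.curve.tangent(s)
        n1 = _double_reflection(ref.position, ref.t, ref.n1, x1, t1)
        return FrameState(x1, t1, n1, np.cross(t1, n1))

    def steering_at(self, s: float, frame: FrameState | None = None) -> Steering:
        frame = frame or self.frame_at(s)
        k = self.curve.curvature_vector(s)
        return Steering(float(k @ frame.n1), float(k @ frame.n2))

    def state_and_steering(self, s: float) -> tuple[FrameState, Steering]:
        f = self.frame_at(s)
        return f, self.steering_at(s, f)
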