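"""Rod-shaped ("stadium") parametric active contour for cell segmentation.

The contour — called a *rodscule* in the spirit of surface snakes — is a pair
of concentric stadium shapes (a rectangle capped by two semicircles): an outer
rod ``Σ`` and an inner rod ``Σ'`` of exactly half the area.  Both derive from a
single ellipse ``Γ`` parametrized by three points ``P, Q, R`` on its border
whose triangle centroid is the ellipse center (the Steiner circumellipse of
the triangle, as in the Ovuscule construction).  The contrast energy

    E_R = (1/|Σ|) ( ∫_{Σ\\Σ'} f  −  ∫_{Σ'} f )

is minimal when the inner rod covers a bright cell and the surrounding annulus
covers dark background; because ``|Σ'| = |Σ|/2`` the energy is exactly zero on
a constant image.  At the optimum the *inner* rod outlines the cell, so all
cell measurements (length, width, orientation, extremities) are read from it.

Coordinates are 0-based pixels, ``x`` = column, ``y`` = row, pixel centers at
integer coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi


class DegenerateStateError(ValueError):
    """The three control points do not define a usable rod."""


# minimum allowed axis ratio b/a of the defining ellipse; beyond this the
# stadium collapses to a segment and the energy is no longer informative
_MIN_AXIS_RATIO = 0.02


@dataclass(frozen=True)
class RodsculeState:
    """The three control points on the border of the defining ellipse."""

    P: tuple[float, float]
    Q: tuple[float, float]
    R: tuple[float, float]

    def as_vector(self) -> np.ndarray:
        return np.array([*self.P, *self.Q, *self.R], dtype=float)

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "RodsculeState":
        v = np.asarray(v, dtype=float)
        return cls(P=(v[0], v[1]), Q=(v[2], v[3]), R=(v[4], v[5]))


@dataclass(frozen=True)
class Ellipse:
    center: np.ndarray
    semi_major: float
    semi_minor: float
    angle: float  # radians in (-pi/2, pi/2]

    @property
    def axis(self) -> np.ndarray:
        return np.array([np.cos(self.angle), np.sin(self.angle)])

    def extremal_points(self) -> np.ndarray:
        """The four axis-endpoints of the ellipse, shape (4, 2)."""
        u = self.axis
        n = np.array([-u[1], u[0]])
        c = self.center
        return np.array([c + self.semi_major * u, c - self.semi_major * u,
                         c + self.semi_minor * n, c - self.semi_minor * n])


@dataclass(frozen=True)
class Stadium:
    """A rectangle capped by two semicircles, given by its cap centers."""

    cap1: np.ndarray
    cap2: np.ndarray
    radius: float

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.cap1 + self.cap2)

    @property
    def half_length(self) -> float:
        """Half of the straight-segment length (0 for a disk)."""
        return 0.5 * float(np.linalg.norm(self.cap2 - self.cap1))

    @property
    def area(self) -> float:
        return 4.0 * self.half_length * self.radius + np.pi * self.radius ** 2

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed euclidean distance to the border (< 0 inside).

        ``points`` has shape (..., 2) in (x, y) order.
        """
        p = np.asarray(points, dtype=float)
        a, b = self.cap1, self.cap2
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d = np.linalg.norm(p - a, axis=-1)
        else:
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            d = np.linalg.norm(p - proj, axis=-1)
        return d - self.radius

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.signed_distance(points) <= 0.0

    def boundary_points(self, n: int = 200) -> np.ndarray:
        """~n points sampled along the border (straight sides + cap arcs)."""
        a, b = self.cap1, self.cap2
        L = float(np.linalg.norm(b - a))
        axis = (b - a) / L if L > 0 else np.array([1.0, 0.0])
        nrm = np.array([-axis[1], axis[0]])
        th0 = float(np.arctan2(axis[1], axis[0]))
        straight = 2 * L
        arcs = 2 * np.pi * self.radius
        n_side = max(int(round(n * straight / (straight + arcs) / 2)), 1) \
            if L > 0 else 0
        n_arc = max((n - 2 * n_side) // 2, 4)
        pts = []
        for t in np.linspace(0.0, 1.0, n_side, endpoint=False):
            pts.append(a + t * (b - a) + self.radius * nrm)
            pts.append(a + t * (b - a) - self.radius * nrm)
        for t in np.linspace(np.pi / 2, 3 * np.pi / 2, n_arc, endpoint=False):
            pts.append(a + self.radius
                       * np.array([np.cos(t + th0), np.sin(t + th0)]))
        for t in np.linspace(-np.pi / 2, np.pi / 2, n_arc, endpoint=False):
            pts.append(b + self.radius
                       * np.array([np.cos(t + th0), np.sin(t + th0)]))
        return np.asarray(pts)


@dataclass(frozen=True)
class RodGeometry:
    """All derived geometry of a rodscule state."""

    barycenter: np.ndarray
    outer_ellipse: Ellipse
    inner_ellipse: Ellipse
    outer_rod: Stadium
    inner_rod: Stadium
    area_outer: float
    area_inner: float

    @property
    def orientation(self) -> float:
        return self.outer_ellipse.angle

    def outer_extremal_points(self) -> np.ndarray:
        return self.outer_ellipse.extremal_points()

    def inner_extremal_points(self) -> np.ndarray:
        return self.inner_ellipse.extremal_points()


@dataclass
class CellMeasurements:
    """Per-cell quantities read off a converged rodscule (inner rod)."""

    length: float
    width: float
    orientation: float
    extremities: np.ndarray  # (2, 2) tip points along the axis
    barycenter: np.ndarray
    background_fluorescence: float
    energy: float


def _wrap_angle(theta: float) -> float:
    """Wrap to (-pi/2, pi/2] (axis orientation is defined modulo pi)."""
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2
    if theta == -np.pi / 2:
        theta = np.pi / 2
    return theta


def geometry_from_points(state: RodsculeState) -> RodGeometry:
    """Derive the full rod geometry from the three control points.

    The unique ellipse through ``P, Q, R`` centered at their centroid is built
    from the conjugate semi-diameters ``u = P - M`` and ``v = (Q - R)/sqrt(3)``
    (Steiner circumellipse).  The outer rod has the ellipse's semi-minor axis
    as cap radius and its cap centers placed so the major-axis endpoints lie on
    the cap arcs; the inner rod is the outer rod scaled by 1/sqrt(2) about the
    barycenter, which halves the area exactly and preserves orientation.
    """
    P = np.asarray(state.P, float)
    Q = np.asarray(state.Q, float)
    R = np.asarray(state.R, float)
    M = (P + Q + R) / 3.0
    u = P - M
    v = (Q - R) / np.sqrt(3.0)
    cross = u[0] * v[1] - u[1] * v[0]
    scale = max(np.linalg.norm(u), np.linalg.norm(v), 1e-12)
    if abs(cross) < 1e-9 * scale ** 2:
        raise DegenerateStateError("control points are (nearly) collinear")
    S = np.outer(u, u) + np.outer(v, v)
    w, V = np.linalg.eigh(S)
    b, a = float(np.sqrt(w[0])), float(np.sqrt(w[1]))
    if b / a < _MIN_AXIS_RATIO:
        raise DegenerateStateError(
            f"ellipse axis ratio {b / a:.3g} below {_MIN_AXIS_RATIO}")
    axis = V[:, 1]
    angle = _wrap_angle(float(np.arctan2(axis[1], axis[0])))
    axis = np.array([np.cos(angle), np.sin(angle)])

    outer_ell = Ellipse(center=M, semi_major=a, semi_minor=b, angle=angle)
    s = 1.0 / np.sqrt(2.0)
    inner_ell = Ellipse(center=M, semi_major=a * s, semi_minor=b * s,
                        angle=angle)
    ell_out = a - b  # half straight-segment length; 0 when the ellipse is a circle
    outer_rod = Stadium(cap1=M - ell_out * axis, cap2=M + ell_out * axis,
                        radius=b)
    inner_rod = Stadium(cap1=M - s * ell_out * axis, cap2=M + s * ell_out * axis,
                        radius=s * b)
    return RodGeometry(barycenter=M, outer_ellipse=outer_ell,
                       inner_ellipse=inner_ell, outer_rod=outer_rod,
                       inner_rod=inner_rod, area_outer=outer_rod.area,
                       area_inner=inner_rod.area)


def state_from_outer_rod(cap1, cap2, radius: float) -> RodsculeState:
    """Control points whose derived geometry has the given outer rod."""
    cap1 = np.asarray(cap1, float)
    cap2 = np.asarray(cap2, float)
    M = 0.5 * (cap1 + cap2)
    half = 0.5 * float(np.linalg.norm(cap2 - cap1))
    if half == 0.0:
        axis = np.array([1.0, 0.0])
    else:
        axis = (cap2 - cap1) / (2.0 * half)
    a = half + radius
    b = radius
    n = np.array([-axis[1], axis[0]])
    pts = []
    for t in (0.0, 2 * np.pi / 3, 4 * np.pi / 3):
        pts.append(M + a * np.cos(t) * axis + b * np.sin(t) * n)
    return RodsculeState(P=tuple(pts[0]), Q=tuple(pts[1]), R=tuple(pts[2]))


def initialize_from_spots(spot_a, spot_b, default_width: float,
                          margin: float) -> RodsculeState:
    """Initial state whose outer rod axis passes through two detected spots.

    The two spots (e.g. the SPB pair) approximately define the longitudinal
    axis of the cell; the rod's cap centers sit ``margin`` px beyond each spot
    and the rod radius is ``default_width / 2``.  The result is independent of
    the spot order.
    """
    a = np.asarray(spot_a, float)
    b = np.asarray(spot_b, float)
    if np.allclose(a, b):
        raise ValueError("spots coincide; cannot define an axis")
    # canonical order => swapped input gives the identical state
    if (a[0], a[1]) > (b[0], b[1]):
        a, b = b, a
    axis = (b - a) / np.linalg.norm(b - a)
    return state_from_outer_rod(a - margin * axis, b + margin * axis,
                                default_width / 2.0)


def contains(state: RodsculeState, point) -> bool:
    """True iff the point lies inside (or on) the outer rod."""
    geo = geometry_from_points(state)
    return bool(geo.outer_rod.contains(np.asarray(point, float)))


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

def _coverage(sd: np.ndarray) -> np.ndarray:
    # fractional pixel coverage from the signed distance: linear anti-aliasing
    # ramp over a 1-px band, piecewise-linear in the state
    return np.clip(0.5 - sd, 0.0, 1.0)


def _mirror_index(idx: np.ndarray, n: int) -> np.ndarray:
    # reflect-101 style mirroring of out-of-range indices
    if n == 1:
        return np.zeros_like(idx)
    period = 2 * (n - 1)
    idx = np.abs(idx) % period
    return np.where(idx >= n, period - idx, idx)


def rod_energy(image: np.ndarray, state: RodsculeState) -> float:
    """Contrast energy of the rod pair on an image.

    Discretization: each pixel enters the two region integrals with a coverage
    weight derived from the stadium signed distance; the weights of each rod
    are renormalized to the rod's analytic area, so that on a constant image
    the energy vanishes identically.  Pixels outside the image frame take
    mirrored boundary values.
    """
    geo = geometry_from_points(state)
    return _rod_energy_geo(np.asarray(image, float), geo)


def _rod_energy_geo(image: np.ndarray, geo: RodGeometry) -> float:
    h, w = image.shape
    rod = geo.outer_rod
    lo = np.floor(np.minimum(rod.cap1, rod.cap2) - rod.radius - 1.5).astype(int)
    hi = np.ceil(np.maximum(rod.cap1, rod.cap2) + rod.radius + 1.5).astype(int)
    if hi[0] < 0 or hi[1] < 0 or lo[0] >= w or lo[1] >= h:
        raise ValueError("rod lies fully outside the image")
    xs = np.arange(lo[0], hi[0] + 1)
    ys = np.arange(lo[1], hi[1] + 1)
    f = image[np.ix_(_mirror_index(ys, h), _mirror_index(xs, w))]
    gx, gy = np.meshgrid(xs.astype(float), ys.astype(float))
    pts = np.stack([gx, gy], axis=-1)
    w_out = _coverage(geo.outer_rod.signed_distance(pts))
    w_in = _coverage(geo.inner_rod.signed_distance(pts))
    s_out, s_in = w_out.sum(), w_in.sum()
    if s_out <= 0 or s_in <= 0:
        raise ValueError("rod covers no pixels")
    w_out *= geo.area_outer / s_out
    w_in *= geo.area_inner / s_in
    # ∫_{Σ\Σ'} f − ∫_{Σ'} f = ∫_Σ f − 2 ∫_{Σ'} f
    return float((np.sum(w_out * f) - 2.0 * np.sum(w_in * f)) / geo.area_outer)


def _energy_or_inf(image: np.ndarray, vec: np.ndarray) -> float:
    try:
        return rod_energy(image, RodsculeState.from_vector(vec))
    except (DegenerateStateError, ValueError):
        return np.inf


def energy_gradient(image: np.ndarray, state: RodsculeState,
                    step: float = 0.1) -> np.ndarray:
    """Gradient of the energy w.r.t. the six control-point coordinates.

    Central finite differences with a default step of 0.1 px, which is small
    against the 1-px coverage band yet large enough to average out the
    piecewise-linear kinks of the discretized energy.
    """
    image = np.asarray(image, float)
    x0 = state.as_vector()
    g = np.zeros(6)
    for k in range(6):
        xp, xm = x0.copy(), x0.copy()
        xp[k] += step
        xm[k] -= step
        ep = _energy_or_inf(image, xp)
        em = _energy_or_inf(image, xm)
        if not np.isfinite(ep) or not np.isfinite(em):
            raise DegenerateStateError("state too close to degeneracy for "
                                       "finite-difference gradient")
        g[k] = (ep - em) / (2.0 * step)
    return g


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

@dataclass
class OptimizeResult:
    state: RodsculeState
    energy: float
    n_iter: int
    converged: bool
    message: str
    energy_history: list = field(default_factory=list)


def optimize(image: np.ndarray, init: RodsculeState, *,
             grad_tol: float = 1e-4, max_iter: int = 500,
             fd_step: float = 0.1, max_step_px: float = 2.0) -> OptimizeResult:
    """Minimize the rod energy by nonlinear conjugate gradient.

    Polak–Ribière(+) directions with an Armijo backtracking line search; the
    first trial step along each direction moves the control points by at most
    ``max_step_px``.  Accepted iterates are strictly decreasing in energy.
    Non-convergence within ``max_iter`` returns the best state found with
    ``converged=False`` rather than raising.
    """
    image = np.asarray(image, float)
    x = init.as_vector()
    f = _energy_or_inf(image, x)
    if not np.isfinite(f):
        raise DegenerateStateError("initial state is degenerate")
    g = energy_gradient(image, RodsculeState.from_vector(x), fd_step)
    d = -g
    history = [f]
    message = "max iterations reached"
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gn = float(np.linalg.norm(g))
        if gn < grad_tol:
            converged, message = True, "gradient norm below tolerance"
            break
        if float(g @ d) >= 0.0:  # not a descent direction: restart
            d = -g
        dn = float(np.linalg.norm(d))
        t = max_step_px / dn
        accepted = False
        for _ in range(30):
            fn = _energy_or_inf(image, x + t * d)
            if fn < f + 1e-4 * t * float(g @ d):
                accepted = True
                break
            t *= 0.5
        if not accepted:
            if np.allclose(d, -g):
                converged, message = True, "step size below tolerance"
                break
            d = -g  # steepest-descent restart, retry next iteration
            continue
        x = x + t * d
        f = fn
        history.append(f)
        g_new = energy_gradient(image, RodsculeState.from_vector(x), fd_step)
        beta = max(0.0, float(g_new @ (g_new - g)) / max(float(g @ g), 1e-30))
        d = -g_new + beta * d
        g = g_new
    return OptimizeResult(state=RodsculeState.from_vector(x), energy=f,
                          n_iter=it, converged=converged, message=message,
                          energy_history=history)


# ---------------------------------------------------------------------------
# preprocessing, batch segmentation, measurements
# ---------------------------------------------------------------------------

def preprocess(stack: np.ndarray, *, low_pct: float = 0.3,
               high_pct: float = 99.7, out_max: float = 255.0) -> np.ndarray:
    """Average z-projection followed by linear contrast stretching.

    A stack of shape (z, y, x) is averaged along z (a 2D image passes
    through); intensities between the ``low_pct`` and ``high_pct`` percentiles
    are mapped linearly to [0, out_max] and clipped.
    """
    stack = np.asarray(stack, float)
    if stack.size == 0:
        raise ValueError("empty stack")
    if stack.ndim == 3:
        proj = stack.mean(axis=0)
    elif stack.ndim == 2:
        proj = stack
    else:
        raise ValueError(f"expected 2D image or 3D stack, got {stack.ndim}D")
    lo, hi = np.percentile(proj, [low_pct, high_pct])
    if hi <= lo:
        return np.full_like(proj, 0.0)
    return np.clip((proj - lo) / (hi - lo) * out_max, 0.0, out_max)


def estimate_noise_std(image: np.ndarray) -> float:
    """Robust noise std via the MAD of the horizontal pixel differences."""
    d = np.diff(np.asarray(image, float), axis=1).ravel()
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def segment_all(image: np.ndarray, initializations, **opt_kwargs):
    """Run the optimizer independently from each initialization.

    Returns a list of ``(OptimizeResult, CellMeasurements | None, status)``
    where status is "ok", "non_informative" (the converged energy is not
    distinguishable from the background-noise energy level) or
    "out_of_bounds".  Failures are flagged, never raised.
    """
    image = np.asarray(image, float)
    h, w = image.shape
    sigma = estimate_noise_std(image)
    out = []
    for init in initializations:
        try:
            res = optimize(image, init, **opt_kwargs)
            geo = geometry_from_points(res.state)
        except (DegenerateStateError, ValueError) as exc:
            out.append((None, None, f"failed: {exc}"))
            continue
        # pure-noise energy scale: std of a mean-difference of two half-areas
        noise_energy = sigma / np.sqrt(max(geo.area_outer, 1.0))
        m = geo.barycenter
        if not (0 <= m[0] < w and 0 <= m[1] < h):
            status = "out_of_bounds"
            meas = None
        elif abs(res.energy) < 3.0 * noise_energy:
            status = "non_informative"
            meas = None
        else:
            status = "ok"
            meas = measurements(res.state, image, energy=res.energy)
        out.append((res, meas, status))
    return out


def measurements(state: RodsculeState, image: np.ndarray, *,
                 spot_positions=None, spot_mask_radius: float = 4.0,
                 energy: float | None = None) -> CellMeasurements:
    """Cell quantities from a converged state: the inner rod is the outline.

    Background fluorescence is the median intensity over the inner rod with a
    disk of ``spot_mask_radius`` px around each given spot masked out; when no
    spots are given the two brightest interior pixels after light smoothing
    are masked as presumed spots.
    """
    image = np.asarray(image, float)
    geo = geometry_from_points(state)
    rod = geo.inner_rod
    a = rod.half_length + rod.radius
    length = 2.0 * a
    width = 2.0 * rod.radius
    axis = np.array([np.cos(geo.orientation), np.sin(geo.orientation)])
    tips = np.array([geo.barycenter - a * axis, geo.barycenter + a * axis])

    h, w = image.shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.stack([xs, ys], axis=-1).astype(float)
    inside = rod.contains(pts)
    if spot_positions is None:
        sm = ndi.gaussian_filter(image, 1.0)
        vals = np.where(inside, sm, -np.inf)
        spot_positions = []
        for _ in range(2):
            j = int(np.argmax(vals))
            py, px = divmod(j, w)
            if not np.isfinite(vals[py, px]):
                break
            spot_positions.append((px, py))
            yy0, yy1 = max(0, py - 3), min(h, py + 4)
            xx0, xx1 = max(0, px - 3), min(w, px + 4)
            vals[yy0:yy1, xx0:xx1] = -np.inf
    mask = inside.copy()
    for sp in spot_positions:
        d = np.linalg.norm(pts - np.asarray(sp, float), axis=-1)
        mask &= d > spot_mask_radius
    interior = image[mask] if mask.any() else image[inside]
    background = float(np.median(interior)) if interior.size else float("nan")

    if energy is None:
        energy = rod_energy(image, state)
    return CellMeasurements(length=length, width=width,
                            orientation=geo.orientation, extremities=tips,
                            barycenter=geo.barycenter,
                            background_fluorescence=background, energy=energy)
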