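"""Spot detection and PSF-model intensity estimation.

Diffraction-limited structures (e.g. spindle pole bodies) appear as bright
spots.  Candidates are enhanced with a Laplacian-of-Gaussian filter — a
band-pass whose single scale parameter σ matches the spot size — and picked
as local maxima with euclidean non-maximum suppression.  Each spot's
intensity is then estimated by least-squares fitting of a rotated 2D Gaussian
with constant offset,

    f(x, y) = A exp(-(a Δx² + 2 b Δx Δy + c Δy²)) + B,
    a =  cos²θ/(2σx²) + sin²θ/(2σy²)
    b = -sin(2θ)/(4σx²) + sin(2θ)/(4σy²)
    c =  sin²θ/(2σx²) + cos²θ/(2σy²)

which reduces to the axis-aligned Gaussian at θ = 0.  The amplitude A is the
reported spot intensity; B absorbs local background and noise floor, making
the estimate independent of the spot's surroundings.  Two simpler estimators
(neighborhood maximum, rolling-ball background subtraction) are provided for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import least_squares
from skimage.restoration import rolling_ball

MIN_SIGMA_PX = 0.3  # lower bound on fitted spreads, px


@dataclass(frozen=True)
class SpotCandidate:
    position: tuple[float, float]  # (x, y), px
    log_response: float
    frame: int = 0
    channel: int = 0


@dataclass
class SpotFit:
    amplitude: float          # A, gray levels
    offset: float             # B, gray levels
    center: tuple[float, float]   # subpixel (x, y)
    sigma_x: float
    sigma_y: float
    theta: float              # radians in (-pi/2, pi/2]
    residual_rms: float
    converged: bool
    at_bounds: bool = False


def log_kernel(sigma: float) -> np.ndarray:
    """Discrete LoG kernel truncated at 4σ, zero-sum, scale-normalized.

    Sign convention: positive center, so convolution gives positive peaks on
    bright spots.  The zero-sum correction removes the truncation's DC leak
    (constant images must give exactly zero response).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    r = int(np.ceil(4.0 * sigma))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1].astype(float)
    r2 = xx ** 2 + yy ** 2
    g = np.exp(-r2 / (2 * sigma ** 2)) / (2 * np.pi * sigma ** 2)
    k = -sigma ** 2 * (r2 - 2 * sigma ** 2) / sigma ** 4 * g
    return k - k.mean()


def log_filter(image: np.ndarray, sigma: float) -> np.ndarray:
    """Scale-normalized Laplacian-of-Gaussian response.

    Direct convolution with the single-parameter LoG kernel of
    :func:`log_kernel`; bright spots of size ~σ yield positive peaks of
    comparable height across scales.
    """
    img = np.asarray(image, float)
    return ndi.convolve(img, log_kernel(sigma), mode="nearest")


def detect_spots(filtered: np.ndarray, n_max: int, min_separation: float,
                 mask: np.ndarray | None = None,
                 threshold: float | None = None,
                 frame: int = 0, channel: int = 0) -> list[SpotCandidate]:
    """Local maxima of a filter response, greedily selected by height.

    Maxima are visited in descending response order; any maximum within
    ``min_separation`` px (euclidean) of an already accepted one is
    suppressed.  ``mask`` restricts candidates to a region (e.g. a segmented
    cell); ``threshold`` discards weak maxima.  At most ``n_max`` candidates
    are returned, possibly fewer.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    resp = np.asarray(filtered, float)
    is_max = resp == ndi.maximum_filter(resp, size=3, mode="nearest")
    # exclude flat plateaus (e.g. exactly-zero background response)
    is_max &= resp > ndi.minimum_filter(resp, size=3, mode="nearest")
    if mask is not None:
        is_max &= np.asarray(mask, bool)
    if threshold is not None:
        is_max &= resp > threshold
    ys, xs = np.nonzero(is_max)
    if xs.size == 0:
        return []
    order = np.lexsort((xs, ys, -resp[ys, xs]))  # deterministic tie order
    kept: list[SpotCandidate] = []
    kx, ky = [], []
    for idx in order:
        x, y = float(xs[idx]), float(ys[idx])
        if kept:
            d2 = (np.array(kx) - x) ** 2 + (np.array(ky) - y) ** 2
            if np.min(d2) < min_separation ** 2:
                continue
        kept.append(SpotCandidate(position=(x, y),
                                  log_response=float(resp[int(y), int(x)]),
                                  frame=frame, channel=channel))
        kx.append(x)
        ky.append(y)
        if len(kept) == n_max:
            break
    return kept


def gaussian2d(params, x, y):
    """Evaluate the rotated-Gaussian-plus-offset model at points (x, y)."""
    A, B, mx, my, sx, sy, th = params
    ct2, st2 = np.cos(th) ** 2, np.sin(th) ** 2
    s2t = np.sin(2 * th)
    a = ct2 / (2 * sx ** 2) + st2 / (2 * sy ** 2)
    b = -s2t / (4 * sx ** 2) + s2t / (4 * sy ** 2)
    c = st2 / (2 * sx ** 2) + ct2 / (2 * sy ** 2)
    dx, dy = x - mx, y - my
    return A * np.exp(-(a * dx ** 2 + 2 * b * dx * dy + c * dy ** 2)) + B


def fit_gaussian(image: np.ndarray, candidate, window: int = 9,
                 *, pixel_size: float | None = None,
                 diffraction_limit: float | None = None,
                 sigma0: float | None = None,
                 sigma_bounds: tuple[float, float] | None = None) -> SpotFit:
    """Fit the rotated 2D Gaussian + offset model around a candidate.

    The fit window (odd, default 9 px) is clipped to the image; at least a
    5x5 region must remain.  Initial spreads come from the optics — the
    diffraction limit divided by the pixel size — or ``sigma0``; initial
    amplitude/offset are the window max-minus-min and min; initial θ is 0.
    Bounds keep A ≥ 0 and σ within ``sigma_bounds`` (default
    [0.3, window/2]); when the optical PSF width is known, passing
    ``sigma_bounds=(sigma0, window / 2)`` prevents sub-diffraction widths —
    nothing images sharper than the PSF — which otherwise let the fit chase
    single noisy pixels on undersampled spots.  A fit that ends pinned at
    the upper σ bound is flagged.  Levenberg–Marquardt-type least squares
    (trust-region reflective, which accepts the bounds) refines all seven
    parameters to subpixel/subinteger precision.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    img = np.asarray(image, float)
    h, w = img.shape
    pos = candidate.position if hasattr(candidate, "position") else candidate
    cx, cy = int(round(pos[0])), int(round(pos[1]))
    half = window // 2
    x0, x1 = max(0, cx - half), min(w, cx + half + 1)
    y0, y1 = max(0, cy - half), min(h, cy + half + 1)
    if (x1 - x0) < 5 or (y1 - y0) < 5:
        raise ValueError("fewer than 5x5 valid pixels around the candidate")
    patch = img[y0:y1, x0:x1]
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)

    if sigma0 is None:
        if pixel_size and diffraction_limit:
            sigma0 = diffraction_limit / pixel_size
        else:
            sigma0 = 1.0
    vmin, vmax = float(patch.min()), float(patch.max())
    if sigma_bounds is None:
        smin, smax = MIN_SIGMA_PX, window / 2.0
    else:
        smin, smax = sigma_bounds
    p0 = np.array([max(vmax - vmin, 1e-3), vmin, float(cx), float(cy),
                   sigma0, sigma0, 0.0])
    p0[4] = np.clip(p0[4], smin, smax)
    p0[5] = np.clip(p0[5], smin, smax)
    lb = [0.0, -np.inf, x0 - 1.0, y0 - 1.0, smin, smin, -np.pi / 2 - 0.1]
    ub = [np.inf, np.inf, x1 + 0.0, y1 + 0.0, smax, smax, np.pi / 2 + 0.1]

    def resid(p):
        return (gaussian2d(p, xx, yy) - patch).ravel()

    sol = least_squares(resid, p0, bounds=(lb, ub), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    A, B, mx, my, sx, sy, th = sol.x
    # orientation is defined modulo pi; meaningless for isotropic spots
    th = (th + np.pi / 2) % np.pi - np.pi / 2
    if th == -np.pi / 2:
        th = np.pi / 2
    if abs(sx - sy) < 1e-6 * max(sx, sy):
        th = 0.0
    # landing on the lower sigma bound is valid when it encodes the optical
    # PSF width (an in-focus spot); only the upper bound signals a bad fit
    at_bounds = bool(np.isclose(sx, smax) or np.isclose(sy, smax))
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return SpotFit(amplitude=float(A), offset=float(B),
                   center=(float(mx), float(my)), sigma_x=float(sx),
                   sigma_y=float(sy), theta=float(th), residual_rms=rms,
                   converged=bool(sol.status > 0) and not at_bounds,
                   at_bounds=at_bounds)


def baseline_max_intensity(image: np.ndarray, candidate,
                           neighborhood: int = 5) -> float:
    """Maximum pixel value in an odd neighborhood around the candidate.

    The traditional estimate; it includes local background and the positive
    bias of the max statistic under noise.
    """
    if neighborhood % 2 == 0:
        raise ValueError("neighborhood must be odd")
    img = np.asarray(image, float)
    h, w = img.shape
    pos = candidate.position if hasattr(candidate, "position") else candidate
    cx, cy = int(round(pos[0])), int(round(pos[1]))
    half = neighborhood // 2
    return float(img[max(0, cy - half):min(h, cy + half + 1),
                     max(0, cx - half):min(w, cx + half + 1)].max())


def baseline_rolling_ball(image: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball background subtraction; returns the non-negative
    foreground image."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    img = np.asarray(image, float)
    bg = rolling_ball(img, radius=radius)
    return np.clip(img - bg, 0.0, None)


def project_stack(stack: np.ndarray):
    """Maximum-intensity z-projection plus per-pixel argmax slice.

    Detection on 3D stacks runs on this projection; the z position of a spot
    detected at (x, y) is the argmax slice there, and the 2D PSF fit is done
    on that slice.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3:
        raise ValueError("expected a (z, y, x) stack")
    return stack.max(axis=0), stack.argmax(axis=0)
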