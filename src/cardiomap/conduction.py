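"""Multi-vector conduction velocity from activation maps.

A polynomial surface T(x, y) is least-squares fitted to the activation
times inside a small window centred on each pixel (default 5x5); the
fitted gradient g = (dT/dx, dT/dy) in ms/pixel gives the local velocity

    v = g / |g|^2     (pixel/ms),  scaled by the pixel size to cm/s.

Velocity points from early to late activation (down the wavefront normal),
in image coordinates: x = column, y = row with y increasing downward.
Speeds outside configurable caps (default 1-200 cm/s) are treated as
artefactual — near-zero gradients from simultaneous epicardial
breakthrough would otherwise produce unbounded speeds.
"""

from __future__ import annotations

import numpy as np

from .containers import ScalarMap, TissueMask, VectorMap, as_mask


def _design_matrix(dx: np.ndarray, dy: np.ndarray, order: str) -> np.ndarray:
    cols = [np.ones_like(dx, dtype=float), dx.astype(float), dy.astype(float)]
    if order == "quadratic":
        cols += [dx.astype(float) ** 2, (dx * dy).astype(float),
                 dy.astype(float) ** 2]
    elif order != "plane":
        raise ValueError("order must be 'plane' or 'quadratic'")
    return np.column_stack(cols)


def local_gradient(
    activation: ScalarMap,
    window: int = 5,
    order: str = "plane",
    min_points: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel activation-time gradient (gx, gy) in ms/pixel.

    For each defined pixel, a first-order plane (default) or full
    second-order polynomial is least-squares fitted over the defined
    pixels of the centred ``window`` x ``window`` neighbourhood; the
    gradient at the centre is the fitted (dT/dx, dT/dy).  Pixels with
    fewer than ``min_points`` defined neighbours, or with a
    rank-deficient (collinear) fit, are NaN.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    half = window // 2
    defined = activation.defined
    T = activation.values
    rows, cols = T.shape
    gx = np.full_like(T, np.nan, dtype=float)
    gy = np.full_like(T, np.nan, dtype=float)

    oy, ox = np.mgrid[-half:half + 1, -half:half + 1]
    oy, ox = oy.ravel(), ox.ravel()
    n_par = 3 if order == "plane" else 6

    # pinv cache keyed by the boolean pattern of defined neighbours —
    # interior pixels of a well-masked map all share the full pattern,
    # so the expensive SVD runs only a handful of times per map.
    cache: dict[bytes, tuple[np.ndarray, int] | None] = {}

    for r, c in zip(*np.nonzero(defined)):
        rr, cc = r + oy, c + ox
        ok = (rr >= 0) & (rr < rows) & (cc >= 0) & (cc < cols)
        ok[ok] &= defined[rr[ok], cc[ok]]
        if ok.sum() < max(min_points, n_par):
            continue
        key = ok.tobytes()
        entry = cache.get(key, "miss")
        if entry == "miss":
            A = _design_matrix(ox[ok], oy[ok], order)
            u, s, vt = np.linalg.svd(A, full_matrices=False)
            rank = int(np.sum(s > s[0] * max(A.shape) * np.finfo(float).eps))
            entry = None if rank < n_par else (vt.T @ np.diag(1.0 / s) @ u.T, rank)
            cache[key] = entry
        if entry is None:   # collinear points
            continue
        pinv, _rank = entry
        coef = pinv @ T[rr[ok], cc[ok]]
        # d/dx and d/dy of the polynomial at the window centre are the
        # linear coefficients for both orders
        gx[r, c], gy[r, c] = coef[1], coef[2]
    return gx, gy


def velocity_from_gradient(
    gx: np.ndarray, gy: np.ndarray, pixel_size: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an activation-time gradient field to velocity in cm/s.

    v = g/|g|^2 in pixel/ms; speed in cm/s = (pixel_size um x 1e-4 cm) /
    (|g| ms/pixel x 1e-3 s) = 0.1 * pixel_size / |g|.  Zero gradients
    (simultaneous activation) yield NaN, not infinity.
    """
    gx = np.asarray(gx, dtype=float)
    gy = np.asarray(gy, dtype=float)
    g2 = gx ** 2 + gy ** 2
    scale = 0.1 * pixel_size  # (um/px -> cm) / (ms -> s)
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = np.where(g2 > 0, scale * gx / g2, np.nan)
        vy = np.where(g2 > 0, scale * gy / g2, np.nan)
        speed = np.where(g2 > 0, scale / np.sqrt(g2), np.nan)
    return vx, vy, speed


def cv_map(
    activation: ScalarMap,
    pixel_size: float,
    window: int = 5,
    order: str = "plane",
    speed_caps: tuple[float, float] = (1.0, 200.0),
    min_points: int = 12,
) -> VectorMap:
    """Conduction-velocity vector field from an activation map.

    Composes :func:`local_gradient` and :func:`velocity_from_gradient`;
    speeds outside ``speed_caps`` (cm/s) are excluded as artefactual.
    """
    gx, gy = local_gradient(activation, window=window, order=order,
                            min_points=min_points)
    vx, vy, speed = velocity_from_gradient(gx, gy, pixel_size)
    lo, hi = speed_caps
    bad = ~np.isfinite(speed) | (speed < lo) | (speed > hi)
    vx[bad] = np.nan
    vy[bad] = np.nan
    speed[bad] = np.nan
    return VectorMap(vx=vx, vy=vy, speed=speed, mask=activation.mask.copy())


def roi_mean_cv(vmap: VectorMap, roi: TissueMask | np.ndarray) -> float:
    """Arithmetic mean speed (cm/s) over defined pixels inside the ROI."""
    flags = as_mask(roi, vmap.speed.shape)
    sel = vmap.defined & flags
    if not sel.any():
        raise ValueError("ROI contains no defined velocity pixels")
    return float(vmap.speed[sel].mean())


def mean_direction_deg(vmap: VectorMap,
                       roi: TissueMask | np.ndarray | None = None) -> float:
    """Circular-mean propagation direction in degrees, image convention
    (0 deg = +x/columns, angles increase towards +y/down)."""
    flags = as_mask(roi, vmap.speed.shape) if roi is not None else \
        np.ones_like(vmap.defined)
    sel = vmap.defined & flags
    if not sel.any():
        raise ValueError("ROI contains no defined velocity pixels")
    ang = np.arctan2(vmap.vy[sel], vmap.vx[sel])
    return float(np.degrees(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())))
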