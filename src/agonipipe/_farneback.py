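"""Dense two-frame motion estimation via polynomial expansion.

Implements Farnebäck's algorithm: every neighbourhood of each frame is
approximated by a quadratic polynomial f(x) ~ x'Ax + b'x + c fitted under
Gaussian weighting, and the displacement field is recovered from how the
polynomial coefficients move between frames.  A coarse-to-fine image
pyramid handles displacements larger than the expansion neighbourhood.

The parameter surface mirrors the classic OpenCV ``calcOpticalFlowFarneback``
signature (pyr_scale, levels, winsize, iterations, poly_n, poly_sigma) so
that published parameterizations can be applied unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["farneback_flow"]


def _poly_exp(img: np.ndarray, n: int, sigma: float):
    """Per-pixel quadratic-polynomial expansion.

    Returns (A, b): A is (H, W, 2, 2) symmetric quadratic-term matrices,
    b is (H, W, 2) linear terms, for the basis {1, x, y, x^2, y^2, xy}
    fitted over a (2n+1)^2 Gaussian-weighted neighbourhood.
    """
    x = np.arange(-n, n + 1, dtype=float)
    w = np.exp(-(x**2) / (2.0 * sigma**2))  # separable applicability

    # Separable correlations of the weighted image with the 1-D basis
    # functions {1, x, x^2} along each axis.
    one, xw, x2w = w, w * x, w * x * x

    def corr(img, ky, kx):
        t = ndimage.correlate1d(img, ky, axis=0, mode="nearest")
        return ndimage.correlate1d(t, kx, axis=1, mode="nearest")

    # Moments <w f basis>; basis order: 1, y, x, y^2, x^2, xy
    m1 = corr(img, one, one)
    my = corr(img, xw, one)
    mx = corr(img, one, xw)
    my2 = corr(img, x2w, one)
    mx2 = corr(img, one, x2w)
    mxy = corr(img, xw, xw)

    # Gram matrix of the basis under w (constant over the image interior).
    s0 = one.sum()
    s2 = (x * x * w).sum()
    s4 = (x**4 * w).sum()
    # Nonzero entries: <1,1>=s0^2, <1,x^2>=<1,y^2>=s2*s0, <x,x>=<y,y>=s2*s0,
    # <x^2,x^2>=s4*s0, <x^2,y^2>=s2^2, <xy,xy>=s2^2.
    G = np.zeros((6, 6))
    G[0, 0] = s0 * s0
    G[0, 3] = G[3, 0] = G[0, 4] = G[4, 0] = s2 * s0
    G[1, 1] = G[2, 2] = s2 * s0
    G[3, 3] = G[4, 4] = s4 * s0
    G[3, 4] = G[4, 3] = s2 * s2
    G[5, 5] = s2 * s2
    Ginv = np.linalg.inv(G)

    m = np.stack([m1, my, mx, my2, mx2, mxy], axis=-1)
    r = m @ Ginv.T  # coefficients (c, by, bx, ayy, axx, axy/?) per pixel

    b = np.stack([r[..., 2], r[..., 1]], axis=-1)  # (bx, by)
    A = np.empty(img.shape + (2, 2))
    A[..., 0, 0] = r[..., 4]          # x^2
    A[..., 1, 1] = r[..., 3]          # y^2
    A[..., 0, 1] = A[..., 1, 0] = r[..., 5] / 2.0
    return A, b


def _update_flow(A1, b1, A2, b2, flow, winsize: int):
    """One fixed-point refinement of the displacement field."""
    h, wd = flow.shape[:2]
    yy, xx = np.mgrid[0:h, 0:wd]
    # Sample frame-2 expansion at the displaced (rounded) position.
    xs = np.clip(np.rint(xx + flow[..., 0]).astype(int), 0, wd - 1)
    ys = np.clip(np.rint(yy + flow[..., 1]).astype(int), 0, h - 1)
    A = 0.5 * (A1 + A2[ys, xs])
    db = -0.5 * (b2[ys, xs] - b1) + np.einsum("...ij,...j->...i", A, flow)

    # Normal equations G d = h, averaged over a winsize box neighbourhood.
    G11 = A[..., 0, 0] ** 2 + A[..., 1, 0] ** 2
    G12 = A[..., 0, 0] * A[..., 0, 1] + A[..., 1, 0] * A[..., 1, 1]
    G22 = A[..., 0, 1] ** 2 + A[..., 1, 1] ** 2
    h1 = A[..., 0, 0] * db[..., 0] + A[..., 1, 0] * db[..., 1]
    h2 = A[..., 0, 1] * db[..., 0] + A[..., 1, 1] * db[..., 1]

    size = winsize
    G11, G12, G22, h1, h2 = (
        ndimage.uniform_filter(a, size=size, mode="nearest")
        for a in (G11, G12, G22, h1, h2)
    )
    det = G11 * G22 - G12 * G12
    det = np.where(np.abs(det) < 1e-12, 1e-12, det)
    out = np.empty_like(flow)
    out[..., 0] = (G22 * h1 - G12 * h2) / det
    out[..., 1] = (G11 * h2 - G12 * h1) / det
    return out


def _resize(img: np.ndarray, shape) -> np.ndarray:
    zoom = (shape[0] / img.shape[0], shape[1] / img.shape[1])
    return ndimage.zoom(img, zoom, order=1, mode="nearest")


def farneback_flow(
    prev: np.ndarray,
    curr: np.ndarray,
    pyr_scale: float = 0.5,
    levels: int = 3,
    winsize: int = 15,
    iterations: int = 3,
    poly_n: int = 5,
    poly_sigma: float = 1.2,
) -> np.ndarray:
    """Dense displacement field mapping ``prev`` onto ``curr``.

    Returns an (H, W, 2) array of (dx, dy) in pixels.
    """
    prev = np.asarray(prev, dtype=float)
    curr = np.asarray(curr, dtype=float)
    if prev.shape != curr.shape or prev.ndim != 2:
        raise ValueError("frames must be 2-D grayscale arrays of equal shape")

    n = poly_n // 2
    shapes = []
    for lvl in range(levels):
        s = pyr_scale**lvl
        shapes.append((max(int(round(prev.shape[0] * s)), 2 * n + 1),
                       max(int(round(prev.shape[1] * s)), 2 * n + 1)))

    flow = None
    for lvl in reversed(range(levels)):
        shp = shapes[lvl]
        p = _resize(prev, shp) if shp != prev.shape else prev
        c = _resize(curr, shp) if shp != curr.shape else curr
        if flow is None:
            flow = np.zeros(shp + (2,))
        else:
            prev_shp = flow.shape[:2]
            flow = np.stack(
                [_resize(flow[..., 0], shp), _resize(flow[..., 1], shp)],
                axis=-1,
            )
            flow[..., 0] *= shp[1] / prev_shp[1]
            flow[..., 1] *= shp[0] / prev_shp[0]
        A1, b1 = _poly_exp(p, n, poly_sigma)
        A2, b2 = _poly_exp(c, n, poly_sigma)
        for _ in range(iterations):
            flow = _update_flow(A1, b1, A2, b2, flow, winsize)
    return flow
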