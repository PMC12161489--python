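"""Principal curves by the Hastie–Stuetzle alternating algorithm.

A principal curve is a smooth one-dimensional curve through the middle of
a point cloud, self-consistent under projection; it generalizes the first
principal component and is the geometric core of pathway-deregulation
scoring.  The fit alternates (a) projecting every point onto the current
polyline and (b) smoothing each coordinate against arc length with a
running-mean smoother, starting from the first principal component.

The stage is deliberately free of randomness: SVD initialization plus a
deterministic smoother make repeated fits bitwise identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class PrincipalCurve:
    """Fitted curve: ordered nodes, their cumulative arc length, and the
    arc-length coordinate of every input point.

    ``projections`` may extend beyond [0, arclen[-1]]: points past the
    terminal nodes are projected onto the extension of the end segments,
    so a straight-line cloud reproduces its PC1 coordinates exactly.
    """

    nodes: np.ndarray        # (m, d), ordered along the curve
    arclen: np.ndarray       # (m,), nondecreasing, arclen[0] == 0
    projections: np.ndarray  # (n,) signed arc-length coordinate per point
    mse: float
    n_iter: int
    converged: bool

    def project(self, points: np.ndarray) -> np.ndarray:
        """Arc-length coordinates of new points (terminal extrapolation)."""
        return _project_to_polyline(np.asarray(points, float),
                                    self.nodes, self.arclen)[0]


def _running_mean(y: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean along axis 0 with edge-shrunk windows."""
    n = y.shape[0]
    half = max(window // 2, 1)
    cs = np.vstack([np.zeros((1, y.shape[1])), np.cumsum(y, axis=0)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)[:, None]


def _dedupe_nodes(nodes: np.ndarray) -> np.ndarray:
    """Drop consecutive duplicate nodes (zero-length segments)."""
    if len(nodes) < 2:
        return nodes
    keep = np.ones(len(nodes), bool)
    keep[1:] = np.any(np.diff(nodes, axis=0) != 0, axis=1)
    out = nodes[keep]
    return out if len(out) >= 2 else nodes[:2]


def _project_to_polyline(
    points: np.ndarray, nodes: np.ndarray, arclen: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact orthogonal projection of points onto a polyline.

    Interior segments clamp the projection parameter to [0, 1]; the first
    and last segments extrapolate, giving signed coordinates below 0 or
    above the total arc length.  Returns (t, squared distances).
    """
    a, b = nodes[:-1], nodes[1:]
    seg = b - a                                   # (m-1, d)
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    seg_len2 = np.where(seg_len2 == 0, 1.0, seg_len2)
    # parameter of the foot of the perpendicular on each segment
    diff = points[:, None, :] - a[None, :, :]      # (n, m-1, d)
    t_par = np.einsum("nkd,kd->nk", diff, seg) / seg_len2
    t_clip = np.clip(t_par, 0.0, 1.0)
    t_clip[:, 0] = np.minimum(t_par[:, 0], 1.0) if seg.shape[0] > 1 \
        else t_par[:, 0]
    if seg.shape[0] > 1:
        t_clip[:, -1] = np.maximum(t_par[:, -1], 0.0)
    foot = a[None, :, :] + t_clip[..., None] * seg[None, :, :]
    d2 = np.einsum("nkd,nkd->nk", points[:, None, :] - foot,
                   points[:, None, :] - foot)
    best = np.argmin(d2, axis=1)
    idx = np.arange(len(points))
    seg_len = np.sqrt(seg_len2)
    t = arclen[best] + t_clip[idx, best] * seg_len[best]
    return t, d2[idx, best]


def _polyline(ordered: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    nodes = _dedupe_nodes(_running_mean(ordered, window))
    arclen = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(nodes, axis=0), axis=1))]
    )
    return nodes, arclen


def fit_principal_curve(
    points: np.ndarray,
    max_iter: int = 10,
    tol: float = 1e-4,
    smoother_span: float = 0.3,
    min_samples: int = 10,
) -> PrincipalCurve:
    """Fit a principal curve to an (n, d) point cloud.

    Parameters
    ----------
    points
        Samples in rows.  A 1-D array is treated as n points on the line.
    max_iter, tol
        Iteration stops when the mean squared projection distance changes
        by less than ``tol`` (relative), or after ``max_iter`` rounds.
    smoother_span
        Running-mean window as a fraction of n.
    min_samples
        Fewer points than this raises "too few samples".
    """
    x = np.asarray(points, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if n < min_samples:
        raise ValueError(f"too few samples: {n} < {min_samples}")
    if not np.isfinite(x).all():
        raise ValueError("points contain non-finite values")
    center = x.mean(axis=0)
    xc = x - center
    if np.allclose(xc, 0):
        raise ValueError("zero-variance input")

    # initialize on the first principal component line
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    t = xc @ vt[0]
    window = max(int(round(smoother_span * n)), 2)

    if n == 2:  # the segment joining the two points
        order = np.argsort(t, kind="stable")
        nodes = x[order]
        arclen = np.concatenate(
            [[0.0], [float(np.linalg.norm(nodes[1] - nodes[0]))]]
        )
        proj, d2 = _project_to_polyline(x, nodes, arclen)
        return PrincipalCurve(nodes, arclen, proj, float(d2.mean()), 0, True)

    mse_prev = np.inf
    converged = False
    nodes = arclen = None
    it = 0
    for it in range(1, max_iter + 1):
        order = np.argsort(t, kind="stable")
        nodes, arclen = _polyline(x[order], window)
        # fast node-level projection drives the iteration
        d2 = cdist(x, nodes, "sqeuclidean")
        nearest = np.argmin(d2, axis=1)
        t = arclen[nearest]
        mse = float(d2[np.arange(n), nearest].mean())
        if abs(mse_prev - mse) <= tol * max(mse_prev, np.finfo(float).tiny):
            converged = True
            break
        mse_prev = mse

    # one exact segment-level projection for the final coordinates
    proj, d2 = _project_to_polyline(x, nodes, arclen)
    return PrincipalCurve(nodes, arclen, proj, float(d2.mean()), it, converged)
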