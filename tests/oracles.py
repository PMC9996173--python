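"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's polar/slope-matching code path:
the chord oracle enumerates every contour point pair directly, and the
width oracle scans a rendered mask along rotated directions.
"""

from __future__ import annotations

import itertools

import numpy as np


def min_centroid_chord(contour_xy: np.ndarray, centroid: tuple[float, float], max_dist: float = 0.75) -> float:
    """Minimum length over all contour point pairs whose segment passes
    within ``max_dist`` pixels of the centroid."""
    pts = np.asarray(contour_xy, dtype=float)
    c = np.asarray(centroid, dtype=float)
    n = len(pts)
    a = pts[:, None, :]  # (n,1,2)
    b = pts[None, :, :]  # (1,n,2)
    ab = b - a
    ac = c[None, None, :] - a
    denom = np.einsum("ijk,ijk->ij", ab, ab)
    denom_safe = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.einsum("ijk,ijk->ij", ac, ab) / denom_safe, 0.0, 1.0)
    closest = a + t[..., None] * ab
    dist = np.linalg.norm(c[None, None, :] - closest, axis=-1)
    lengths = np.sqrt(denom)
    iu = np.triu_indices(n, k=1)
    ok = dist[iu] <= max_dist
    if not ok.any():
        raise ValueError("no chord passes near the centroid")
    return float(lengths[iu][ok].min())


def min_center_width_of_mask(mask: np.ndarray, n_angles: int = 360) -> float:
    """Minimum width of the mask along lines through its pixel-mean centre.

    Walks outward from the centre along each direction until leaving the
    foreground; width = forward + backward extent.
    """
    fg = np.asarray(mask) != 0
    ys, xs = np.nonzero(fg)
    cx, cy = xs.mean(), ys.mean()
    h, w = fg.shape
    best = np.inf
    for theta in np.linspace(0, np.pi, n_angles, endpoint=False):
        dx, dy = np.cos(theta), np.sin(theta)
        total = 0.0
        for sgn in (1.0, -1.0):
            r = 0.0
            while True:
                x = int(round(cx + sgn * r * dx))
                y = int(round(cy + sgn * r * dy))
                if not (0 <= x < w and 0 <= y < h) or not fg[y, x]:
                    break
                r += 0.25
            total += max(r - 0.25, 0.0)
        best = min(best, total)
    return float(best)


def wilcoxon_p_by_enumeration(diffs) -> float:
    """Exact two-sided signed-rank p-value by enumerating all 2^n sign vectors."""
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([0, 1], repeat=n)]
    )
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def kappa_direct(tp: int, fp: int, fn: int, tn: int) -> float:
    n = tp + fp + fn + tn
    obs = np.array([[tp, fn], [fp, tn]], dtype=float)
    p_o = np.trace(obs) / n
    p_e = (obs.sum(1) * obs.sum(0)).sum() / n**2  # note: symmetric layout
    return (p_o - p_e) / (1 - p_e)
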