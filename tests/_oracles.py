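"""Independent dense-grid oracles for the fuzzy closed forms under test.

Membership is evaluated directly from the breakpoint geometry (numpy,
vectorised) and the sup of pointwise minima is taken over a uniform grid, so
these share no code path with the closed-form implementations they check.
"""

import numpy as np

GRID_STEP = 1e-5


def grid_membership(points, x):
    """Vectorised piecewise-linear membership over array ``x``."""
    pts = tuple(points)
    if len(pts) == 3:
        a, b, c = pts
        b2 = b
    else:
        a, b, b2, c = pts
    x = np.asarray(x, dtype=float)
    mu = np.zeros_like(x)
    inside = (x >= a) & (x <= c)
    kernel = (x >= b) & (x <= b2)
    mu[kernel] = 1.0
    rising = inside & (x < b)
    if b > a:
        mu[rising] = (x[rising] - a) / (b - a)
    falling = inside & (x > b2)
    if c > b2:
        mu[falling] = (c - x[falling]) / (c - b2)
    return mu


def grid_defuzz(points, step=GRID_STEP):
    """Right/left/total Chen-Hwang scores by grid search over [0, 1]."""
    x = np.arange(0.0, 1.0 + step / 2, step)
    mu = grid_membership(points, x)
    right = float(np.minimum(mu, x).max())
    left = float(np.minimum(mu, 1.0 - x).max())
    return right, left, (right + 1.0 - left) / 2.0


def grid_possibility(p1, p2, step=GRID_STEP):
    """V(M1 >= M2) as sup_{x>=y} min(mu1(x), mu2(y)) on a grid.

    Equals 1 when the first mode dominates; otherwise the intersection
    height, found as the sup over a common abscissa.
    """
    if p1[1] >= p2[1]:
        return 1.0
    lo = max(p1[0], p2[0])
    hi = min(p1[2], p2[2])
    if lo >= hi:
        return 0.0
    x = np.arange(lo, hi + step / 2, step)
    return float(
        np.minimum(grid_membership(p1, x), grid_membership(p2, x)).max()
    )
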