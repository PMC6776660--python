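"""Independent reference implementations used only as test oracles.

Each function re-derives a pipeline quantity by the most literal route
available (explicit formulas, brute-force loops, naive agglomeration) and
is kept free of any code path shared with the package.
"""

import numpy as np


def tetrachromatic_ds(delta_f, e):
    """Literal transcription of the four-receptor receptor-noise distance."""
    f1, f2, f3, f4 = delta_f
    e1, e2, e3, e4 = e
    num = (
        (e1 * e2) ** 2 * (f4 - f3) ** 2
        + (e1 * e3) ** 2 * (f4 - f2) ** 2
        + (e1 * e4) ** 2 * (f3 - f2) ** 2
        + (e2 * e3) ** 2 * (f4 - f1) ** 2
        + (e2 * e4) ** 2 * (f3 - f1) ** 2
        + (e3 * e4) ** 2 * (f2 - f1) ** 2
    )
    den = (
        (e1 * e2 * e3) ** 2
        + (e1 * e2 * e4) ** 2
        + (e1 * e3 * e4) ** 2
        + (e2 * e3 * e4) ** 2
    )
    return np.sqrt(num / den)


def trichromatic_ds(delta_f, e):
    """Literal three-receptor receptor-noise distance."""
    f1, f2, f3 = delta_f
    e1, e2, e3 = e
    num = (
        e1**2 * (f3 - f2) ** 2
        + e2**2 * (f3 - f1) ** 2
        + e3**2 * (f2 - f1) ** 2
    )
    den = (e1 * e2) ** 2 + (e1 * e3) ** 2 + (e2 * e3) ** 2
    return np.sqrt(num / den)


def govardovskii_a1(lambda_max, wl):
    """Literal A1 pigment template (alpha + beta band), unnormalised."""
    x = lambda_max / np.asarray(wl, float)
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x))
        + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x))
        + 0.674
    )
    lmb = 189.0 + 0.315 * lambda_max
    b = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((np.asarray(wl, float) - lmb) / b) ** 2))
    return alpha + beta


def loess_local_linear(y, x, frac):
    """Independent LOESS: tricube weights, locally linear, span by points."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    k = int(np.ceil(frac * n))
    out = np.empty(n)
    for i, xi in enumerate(x):
        d = np.abs(x - xi)
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        w = (1 - (d[idx] / h) ** 3) ** 3 if h > 0 else np.ones(k)
        xw, yw = x[idx], y[idx]
        sw = w.sum()
        xm = (w * xw).sum() / sw
        ym = (w * yw).sum() / sw
        sxx = (w * (xw - xm) ** 2).sum()
        slope = (w * (xw - xm) * (yw - ym)).sum() / sxx if sxx > 0 else 0.0
        out[i] = ym + slope * (xi - xm)
    return out


def upgma_naive(d):
    """O(n^3) average-linkage agglomeration, scipy linkage format.

    Clusters are merged at the smallest average pairwise distance; new
    clusters get ids n, n+1, ... in merge order.
    """
    d = np.asarray(d, float)
    n = d.shape[0]
    members = {i: [i] for i in range(n)}
    active = list(range(n))
    next_id = n
    Z = []
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                pts_a, pts_b = members[a], members[b]
                avg = np.mean([d[p, q] for p in pts_a for q in pts_b])
                if best is None or avg < best[0]:
                    best = (avg, a, b)
        avg, a, b = best
        members[next_id] = members[a] + members[b]
        Z.append([min(a, b), max(a, b), avg, len(members[next_id])])
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return np.asarray(Z, float)


def hull_volume_delaunay(points):
    """Convex-hull volume as a sum of Delaunay simplex determinants."""
    from scipy.spatial import Delaunay

    points = np.asarray(points, float)
    tri = Delaunay(points)
    vol = 0.0
    for simplex in tri.simplices:
        a, b, c, d = points[simplex]
        vol += abs(np.linalg.det(np.stack([a - d, b - d, c - d]))) / 6.0
    return vol
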