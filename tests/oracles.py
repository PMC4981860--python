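"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately written with plain Python loops, sorted
lists, explicit pair enumeration and direct DFT sums — no shared code
with the package's vectorised implementations.
"""

from __future__ import annotations

import cmath
import math


# ---------------------------------------------------------------------------
# point-in-polygon (even-odd rule, boundary included)

def _on_segment(p, a, b, eps=1e-12):
    (pr, pc), (ar, ac), (br, bc) = p, a, b
    if (ar, ac) == (br, bc):  # zero-length edge carries no boundary
        return False
    cross = (br - ar) * (pc - ac) - (bc - ac) * (pr - ar)
    if abs(cross) > eps * max(1.0, abs(br - ar) + abs(bc - ac)):
        return False
    dot = (pr - ar) * (br - ar) + (pc - ac) * (bc - ac)
    return -eps <= dot <= (br - ar) ** 2 + (bc - ac) ** 2 + eps


def point_in_polygon(point, vertices) -> bool:
    """Even-odd ray casting with explicit boundary inclusion."""
    n = len(vertices)
    pr, pc = point
    inside = False
    for i in range(n):
        a, b = vertices[i], vertices[(i + 1) % n]
        if _on_segment(point, a, b):
            return True
        (ar, ac), (br, bc) = a, b
        if (ar > pr) != (br > pr):
            c_cross = (bc - ac) * (pr - ar) / (br - ar) + ac
            if pc < c_cross:
                inside = not inside
    return inside


def rasterize_bruteforce(vertices, rows, cols):
    return [[point_in_polygon((r, c), vertices) for c in range(cols)]
            for r in range(rows)]


# ---------------------------------------------------------------------------
# AUROC by explicit pair counting

def auc_pair_counting(scores, labels) -> float:
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# shared helpers for the estimator oracles

def _flat(pix):
    return [float(v) for row in pix for v in row]


def _mean(xs):
    return sum(xs) / len(xs)


def _sd(xs):
    m = _mean(xs)
    return math.sqrt(sum((v - m) ** 2 for v in xs) / len(xs))


def _percentile(xs, q):
    """Linear interpolation between order statistics."""
    s = sorted(xs)
    h = q / 100.0 * (len(s) - 1)
    lo = int(math.floor(h))
    if lo + 1 >= len(s):
        return s[-1]
    return s[lo] + (s[lo + 1] - s[lo]) * (h - lo)


def _median(xs):
    return _percentile(xs, 50)


def quantize(pix, vmin, vmax, n_levels):
    out = []
    rng = vmax - vmin
    for row in pix:
        orow = []
        for v in row:
            if rng == 0:
                lvl = 0
            else:
                lvl = int(math.floor((v - vmin) / rng * n_levels))
                lvl = min(max(lvl, 0), n_levels - 1)
            orow.append(lvl)
        out.append(orow)
    return out


def _level_counts(pix, ctx):
    lv = quantize(pix, ctx.value_min, ctx.value_max, ctx.n_levels)
    counts = [0] * ctx.n_levels
    for row in lv:
        for v in row:
            counts[v] += 1
    return counts


# co-occurrence: explicit pair enumeration, symmetric accumulation
_OFFSETS = [(0, 1), (1, 1), (1, 0), (1, -1)]


def glcm_oracle(pix, ctx, orientation):
    lv = quantize(pix, ctx.value_min, ctx.value_max, ctx.n_levels)
    rows, cols = len(lv), len(lv[0])
    dr, dc = _OFFSETS[orientation]
    dr, dc = dr * ctx.distance, dc * ctx.distance
    L = ctx.n_levels
    P = [[0.0] * L for _ in range(L)]
    n = 0
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                P[lv[r][c]][lv[r2][c2]] += 1.0
                P[lv[r2][c2]][lv[r][c]] += 1.0
                n += 2
    if n:
        for i in range(L):
            for j in range(L):
                P[i][j] /= n
    return P


def glcm_pooled_oracle(pix, ctx):
    mats = [glcm_oracle(pix, ctx, o) for o in range(4)]
    L = ctx.n_levels
    return [[sum(m[i][j] for m in mats) / 4.0 for j in range(L)]
            for i in range(L)]


def _g_marginals(P):
    L = len(P)
    pr = [sum(P[i][j] for j in range(L)) for i in range(L)]
    pc = [sum(P[i][j] for i in range(L)) for j in range(L)]
    mu_r = sum(i * pr[i] for i in range(L))
    mu_c = sum(j * pc[j] for j in range(L))
    return pr, pc, mu_r, mu_c


def g_contrast(P):
    return sum((i - j) ** 2 * P[i][j]
               for i in range(len(P)) for j in range(len(P)))


def g_energy(P):
    return sum(v * v for row in P for v in row)


def g_entropy(P):
    return -sum(v * math.log(v) for row in P for v in row if v > 0)


def g_correlation(P):
    pr, pc, mu_r, mu_c = _g_marginals(P)
    var_r = sum((i - mu_r) ** 2 * pr[i] for i in range(len(P)))
    var_c = sum((j - mu_c) ** 2 * pc[j] for j in range(len(P)))
    if var_r == 0 or var_c == 0:
        return 1.0
    cov = sum((i - mu_r) * (j - mu_c) * P[i][j]
              for i in range(len(P)) for j in range(len(P)))
    return cov / math.sqrt(var_r * var_c)


def g_homogeneity(P):
    return sum(P[i][j] / (1.0 + (i - j) ** 2)
               for i in range(len(P)) for j in range(len(P)))


def g_dissimilarity(P):
    return sum(abs(i - j) * P[i][j]
               for i in range(len(P)) for j in range(len(P)))


def g_cluster(P, power):
    _, _, mu_r, mu_c = _g_marginals(P)
    return sum((i + j - mu_r - mu_c) ** power * P[i][j]
               for i in range(len(P)) for j in range(len(P)))


def g_sum_dist(P):
    L = len(P)
    p = [0.0] * (2 * L - 1)
    for i in range(L):
        for j in range(L):
            p[i + j] += P[i][j]
    return p


def g_diff_dist(P):
    L = len(P)
    p = [0.0] * L
    for i in range(L):
        for j in range(L):
            p[abs(i - j)] += P[i][j]
    return p


def dist_mean(p):
    return sum(k * v for k, v in enumerate(p))


def dist_var(p):
    m = dist_mean(p)
    return sum((k - m) ** 2 * v for k, v in enumerate(p))


def dist_entropy(p):
    return -sum(v * math.log(v) for v in p if v > 0)


# curvature: explicit stencils on an edge-replicated grid

def _pad_edge(grid):
    rows = [list(r) for r in grid]
    rows = [rows[0]] + rows + [rows[-1]]
    return [[r[0]] + r + [r[-1]] for r in rows]


def _cdiff(grid, axis):
    g = _pad_edge(grid)
    rows, cols = len(grid), len(grid[0])
    out = [[0.0] * cols for _ in range(rows)]
    for r in range(rows):
        for c in range(cols):
            if axis == 0:
                out[r][c] = (g[r + 2][c + 1] - g[r][c + 1]) / 2.0
            else:
                out[r][c] = (g[r + 1][c + 2] - g[r + 1][c]) / 2.0
    return out


def curvature_oracle(pix, scale):
    f = [[scale * float(v) for v in row] for row in pix]
    fy = _cdiff(f, 0)
    fx = _cdiff(f, 1)
    fxx = _cdiff(fx, 1)
    fyy = _cdiff(fy, 0)
    fxy = _cdiff(fx, 0)
    rows, cols = len(f), len(f[0])
    H = [[0.0] * cols for _ in range(rows)]
    K = [[0.0] * cols for _ in range(rows)]
    k1 = [[0.0] * cols for _ in range(rows)]
    k2 = [[0.0] * cols for _ in range(rows)]
    for r in range(rows):
        for c in range(cols):
            gx, gy = fx[r][c], fy[r][c]
            g = 1.0 + gx * gx + gy * gy
            h = ((1.0 + gx * gx) * fyy[r][c] - 2.0 * gx * gy * fxy[r][c]
                 + (1.0 + gy * gy) * fxx[r][c]) / (2.0 * g ** 1.5)
            kk = (fxx[r][c] * fyy[r][c] - fxy[r][c] ** 2) / (g * g)
            d = math.sqrt(max(h * h - kk, 0.0))
            H[r][c], K[r][c] = h, kk
            k1[r][c], k2[r][c] = h + d, h - d
    return {"fx": fx, "fy": fy, "fxx": fxx, "fyy": fyy, "fxy": fxy,
            "H": H, "K": K, "k1": k1, "k2": k2}


def _interior(grid):
    return [grid[r][c] for r in range(1, len(grid) - 1)
            for c in range(1, len(grid[0]) - 1)]


# spectral: direct 2-D DFT

def dft_power(pix):
    """Direct DFT from the definition, via explicitly built basis matrices."""
    import numpy as _np
    rows, cols = len(pix), len(pix[0])
    w_row = [[cmath.exp(-2j * math.pi * u * r / rows) for r in range(rows)]
             for u in range(rows)]
    w_col = [[cmath.exp(-2j * math.pi * v * c / cols) for c in range(cols)]
             for v in range(cols)]
    F = _np.array(w_row) @ _np.array(pix, dtype=complex) @ _np.array(w_col).T
    return {(u, v): abs(F[u, v]) ** 2
            for u in range(rows) for v in range(cols)}


def _fftfreq(n):
    return [(k if k < (n + 1) // 2 else k - n) / n for k in range(n)]


_SPECTRAL_CACHE: dict = {}


def spectral_oracle(pix):
    key = tuple(tuple(row) for row in pix)
    if key in _SPECTRAL_CACHE:
        return _SPECTRAL_CACHE[key]
    rows, cols = len(pix), len(pix[0])
    power = dft_power(pix)
    fr, fc = _fftfreq(rows), _fftfreq(cols)
    items = []
    for u in range(rows):
        for v in range(cols):
            if u == 0 and v == 0:
                continue
            rad = math.hypot(fr[u], fc[v])
            items.append((rad, power[(u, v)]))
    _SPECTRAL_CACHE[key] = items
    return items


def spectral_band_fraction(pix, band):
    items = spectral_oracle(pix)
    total = sum(p for _, p in items)
    if total == 0:
        return 0.0
    lo, hi = 1.0 / 6.0, 1.0 / 3.0
    if band == 0:
        sel = sum(p for r, p in items if r < lo)
    elif band == 1:
        sel = sum(p for r, p in items if lo <= r < hi)
    else:
        sel = sum(p for r, p in items if r >= hi)
    return sel / total


def spectral_entropy(pix):
    items = spectral_oracle(pix)
    total = sum(p for _, p in items)
    if total == 0:
        return 0.0
    return -sum((p / total) * math.log(p / total)
                for _, p in items if p > 0)


# ---------------------------------------------------------------------------
# the per-estimator oracle table

def _first_order_oracles():
    def harmonic(pix, ctx):
        xs = _flat(pix)
        if min(xs) <= 0:
            xs = [v + ctx.quant_step for v in xs]
        return len(xs) / sum(1.0 / v for v in xs)

    def geometric(pix, ctx):
        xs = _flat(pix)
        if min(xs) <= 0:
            xs = [v + ctx.quant_step for v in xs]
        return math.exp(sum(math.log(v) for v in xs) / len(xs))

    def mode(pix, ctx):
        counts = _level_counts(pix, ctx)
        best = 0
        for lvl in range(1, len(counts)):
            if counts[lvl] > counts[best]:
                best = lvl
        if ctx.value_range == 0:
            return ctx.value_min
        return ctx.value_min + best * ctx.value_range / ctx.n_levels

    def hist_entropy(pix, ctx):
        counts = _level_counts(pix, ctx)
        n = sum(counts)
        return -sum((c / n) * math.log(c / n) for c in counts if c > 0)

    def hist_energy(pix, ctx):
        counts = _level_counts(pix, ctx)
        n = sum(counts)
        return sum((c / n) ** 2 for c in counts)

    def trimmed(pix, ctx):
        xs = sorted(_flat(pix))
        k = int(math.floor(0.1 * len(xs)))
        core = xs[k:len(xs) - k]
        return sum(core) / len(core)

    def skewness(pix, ctx):
        xs = _flat(pix)
        m, s = _mean(xs), _sd(xs)
        if s == 0:
            return 0.0
        return sum((v - m) ** 3 for v in xs) / len(xs) / s ** 3

    def kurtosis(pix, ctx):
        xs = _flat(pix)
        m, s = _mean(xs), _sd(xs)
        if s == 0:
            return 0.0
        return sum((v - m) ** 4 for v in xs) / len(xs) / s ** 4 - 3.0

    def bowley(pix, ctx):
        xs = _flat(pix)
        q1, q2, q3 = _percentile(xs, 25), _median(xs), _percentile(xs, 75)
        if q3 == q1:
            return 0.0
        return (q3 + q1 - 2 * q2) / (q3 - q1)

    def pearson2(pix, ctx):
        xs = _flat(pix)
        s = _sd(xs)
        if s == 0:
            return 0.0
        return 3.0 * (_mean(xs) - _median(xs)) / s

    return {
        "E1": lambda p, c: _mean(_flat(p)),
        "E2": lambda p, c: _sd(_flat(p)),
        "E3": harmonic,
        "E4": geometric,
        "E5": lambda p, c: _median(_flat(p)),
        "E6": mode,
        "E7": lambda p, c: _sd(_flat(p)) ** 2,
        "E8": lambda p, c: min(_flat(p)),
        "E9": lambda p, c: max(_flat(p)),
        "E10": lambda p, c: max(_flat(p)) - min(_flat(p)),
        "E11": lambda p, c: _percentile(_flat(p), 5),
        "E12": lambda p, c: _percentile(_flat(p), 10),
        "E13": lambda p, c: _percentile(_flat(p), 25),
        "E14": lambda p, c: _percentile(_flat(p), 75),
        "E15": lambda p, c: _percentile(_flat(p), 90),
        "E16": lambda p, c: _percentile(_flat(p), 95),
        "E17": lambda p, c: _percentile(_flat(p), 75) - _percentile(_flat(p), 25),
        "E18": lambda p, c: _sd(_flat(p)) / _mean(_flat(p)),
        "E19": skewness,
        "E20": kurtosis,
        "E21": bowley,
        "E22": pearson2,
        "E23": hist_entropy,
        "E24": hist_energy,
        "E25": lambda p, c: math.sqrt(_mean([v * v for v in _flat(p)])),
        "E26": lambda p, c: _mean([abs(v - _mean(_flat(p))) for v in _flat(p)]),
        "E27": trimmed,
        "E28": lambda p, c: _median([abs(v - _median(_flat(p)))
                                     for v in _flat(p)]),
        "E29": lambda p, c: 0.5 * (_percentile(_flat(p), 25)
                                   + _percentile(_flat(p), 75)),
        "E30": lambda p, c: 0.5 * (min(_flat(p)) + max(_flat(p))),
    }


def _glcm_oracles():
    def pooled(fn):
        return lambda p, c: fn(glcm_pooled_oracle(p, c))

    def orient(fn, o):
        return lambda p, c: fn(glcm_oracle(p, c, o))

    def marg_mean(P, axis):
        pr, pc, mu_r, mu_c = _g_marginals(P)
        return mu_c if axis == 1 else mu_r

    def marg_var(P, axis):
        pr, pc, mu_r, mu_c = _g_marginals(P)
        p, mu = (pc, mu_c) if axis == 1 else (pr, mu_r)
        return sum((i - mu) ** 2 * p[i] for i in range(len(p)))

    def autocorr(P):
        return sum(i * j * P[i][j]
                   for i in range(len(P)) for j in range(len(P)))

    def inv_diff(P):
        return sum(P[i][j] / (1.0 + abs(i - j))
                   for i in range(len(P)) for j in range(len(P)))

    def diag(P):
        return sum(P[i][i] for i in range(len(P)))

    return {
        "E31": pooled(lambda P: marg_mean(P, 1)),
        "E32": pooled(lambda P: marg_mean(P, 0)),
        "E33": pooled(lambda P: marg_var(P, 1)),
        "E34": pooled(lambda P: marg_var(P, 0)),
        "E35": pooled(g_energy),
        "E36": pooled(g_entropy),
        "E37": pooled(g_correlation),
        "E38": pooled(g_homogeneity),
        "E39": pooled(g_dissimilarity),
        "E40": pooled(lambda P: g_cluster(P, 3)),
        "E41": pooled(lambda P: g_cluster(P, 4)),
        "E42": pooled(lambda P: max(max(row) for row in P)),
        "E43": pooled(lambda P: dist_mean(g_sum_dist(P))),
        "E44": pooled(lambda P: dist_var(g_sum_dist(P))),
        "E45": pooled(lambda P: dist_entropy(g_sum_dist(P))),
        "E46": pooled(lambda P: dist_mean(g_diff_dist(P))),
        "E47": pooled(lambda P: dist_var(g_diff_dist(P))),
        "E48": pooled(lambda P: dist_entropy(g_diff_dist(P))),
        "E49": pooled(autocorr),
        "E50": pooled(inv_diff),
        "E51": pooled(diag),
        "E52": orient(g_contrast, 0),
        "E53": orient(g_contrast, 1),
        "E54": orient(g_contrast, 2),
        "E55": orient(g_contrast, 3),
        "E56": orient(g_energy, 0),
        "E57": pooled(g_contrast),
        "E58": orient(g_entropy, 0),
        "E59": orient(g_homogeneity, 0),
        "E60": orient(g_dissimilarity, 0),
    }


def _geometric_oracles():
    def field(pix, ctx, key):
        return _interior(curvature_oracle(pix, ctx.scale)[key])

    def grad_mag(pix, ctx):
        c = curvature_oracle(pix, ctx.scale)
        return [math.hypot(a, b)
                for a, b in zip(_interior(c["fx"]), _interior(c["fy"]))]

    def laplacian(pix, ctx):
        c = curvature_oracle(pix, ctx.scale)
        return [a + b
                for a, b in zip(_interior(c["fxx"]), _interior(c["fyy"]))]

    return {
        "E61": lambda p, c: _mean(grad_mag(p, c)),
        "E62": lambda p, c: _sd(grad_mag(p, c)),
        "E63": lambda p, c: max(grad_mag(p, c)),
        "E64": lambda p, c: _median(grad_mag(p, c)),
        "E65": lambda p, c: _mean([abs(v) for v in laplacian(p, c)]),
        "E66": lambda p, c: _sd(laplacian(p, c)),
        "E67": lambda p, c: _mean(field(p, c, "K")),
        "E68": lambda p, c: _sd(field(p, c, "K")),
        "E69": lambda p, c: max(field(p, c, "K")),
        "E70": lambda p, c: min(field(p, c, "K")),
        "E71": lambda p, c: _sd(field(p, c, "H")),
        "E72": lambda p, c: _mean([abs(v) for v in field(p, c, "H")]),
        "E73": lambda p, c: _mean(field(p, c, "H")),
        "E74": lambda p, c: max(field(p, c, "H")),
        "E75": lambda p, c: max(field(p, c, "k1")),
        "E76": lambda p, c: min(field(p, c, "k2")),
        "E77": lambda p, c: _mean(field(p, c, "k1")),
        "E78": lambda p, c: _mean(field(p, c, "k2")),
        "E79": lambda p, c: _mean([math.sqrt(1.0 + v * v)
                                   for v in grad_mag(p, c)]),
        "E80": lambda p, c: _mean([1.0 if v > 0 else 0.0
                                   for v in field(p, c, "K")]),
    }


def _spectral_oracles():
    return {
        "E81": lambda p, c: spectral_band_fraction(p, 0),
        "E82": lambda p, c: spectral_band_fraction(p, 1),
        "E83": lambda p, c: spectral_band_fraction(p, 2),
        "E84": lambda p, c: spectral_entropy(p),
    }


ORACLES = {}
ORACLES.update(_first_order_oracles())
ORACLES.update(_glcm_oracles())
ORACLES.update(_geometric_oracles())
ORACLES.update(_spectral_oracles())
assert len(ORACLES) == 84
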