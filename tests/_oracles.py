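"""Independent brute-force reference implementations used only by tests.

Everything here is written with naive loops and explicit arithmetic,
deliberately sharing no code path with the package, so agreement is a
meaningful check rather than a tautology.
"""

from __future__ import annotations

import cmath
import math

import numpy as np


# ---------------------------------------------------------------- filter indexes

def fisher_bf(x, y):
    x0 = [xi for xi, yi in zip(x, y) if yi == 0]
    x1 = [xi for xi, yi in zip(x, y) if yi == 1]
    m0 = sum(x0) / len(x0)
    m1 = sum(x1) / len(x1)
    v0 = sum((v - m0) ** 2 for v in x0) / (len(x0) - 1)
    v1 = sum((v - m1) ** 2 for v in x1) / (len(x1) - 1)
    if v0 + v1 == 0:
        return 1e6 if m1 != m0 else 0.0
    return (m1 - m0) ** 2 / (v0 + v1)


def corr_bf(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def ttest_bf(x, y):
    x0 = [xi for xi, yi in zip(x, y) if yi == 0]
    x1 = [xi for xi, yi in zip(x, y) if yi == 1]
    m0 = sum(x0) / len(x0)
    m1 = sum(x1) / len(x1)
    v0 = sum((v - m0) ** 2 for v in x0) / (len(x0) - 1)
    v1 = sum((v - m1) ** 2 for v in x1) / (len(x1) - 1)
    den = math.sqrt(v1 / len(x1) + v0 / len(x0))
    if den == 0:
        return 1e6 if m1 != m0 else 0.0
    return abs(m1 - m0) / den


def mi_bf(x, y, n_bins=10):
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    width = (hi - lo) / n_bins
    joint = {}
    for xi, yi in zip(x, y):
        b = min(int((xi - lo) / width), n_bins - 1)
        joint[(b, yi)] = joint.get((b, yi), 0) + 1
    n = len(x)
    px = {}
    py = {}
    for (b, yi), c in joint.items():
        px[b] = px.get(b, 0) + c
        py[yi] = py.get(yi, 0) + c
    total = 0.0
    for (b, yi), c in joint.items():
        pxy = c / n
        total += pxy * math.log2(pxy / ((px[b] / n) * (py[yi] / n)))
    return total


# ---------------------------------------------------------------- fuzzy system

def importance_bf(h, c, s, alpha):
    """Naive 81-rule enumeration of the Takagi-Sugeno output."""
    h = [min(max(v, 0.0), 1.0) for v in h]
    num = 0.0
    den = 0.0
    rule = 0
    for a0 in range(3):
        for a1 in range(3):
            for a2 in range(3):
                for a3 in range(3):
                    w = 1.0
                    for j, lev in enumerate((a0, a1, a2, a3)):
                        w *= math.exp(-0.5 * ((h[j] - c[j][lev]) / s[j][lev]) ** 2)
                    num += w * alpha[rule]
                    den += w
                    rule += 1
    return num / den


# ---------------------------------------------------------------- spectra

def hann_bf(n):
    return [0.5 - 0.5 * math.cos(2.0 * math.pi * k / n) for k in range(n)]


def periodogram_bf(x, fs):
    """One-sided Hann-tapered periodogram via an explicit DFT double loop."""
    n = len(x)
    w = hann_bf(n)
    xw = [xi * wi for xi, wi in zip(x, w)]
    scale = 1.0 / (fs * sum(wi * wi for wi in w))
    n_freq = n // 2 + 1
    freqs = [k * fs / n for k in range(n_freq)]
    P = []
    for k in range(n_freq):
        X = sum(xw[m] * cmath.exp(-2j * math.pi * k * m / n) for m in range(n))
        p = abs(X) ** 2 * scale
        if 0 < k and not (n % 2 == 0 and k == n_freq - 1):
            p *= 2.0
        P.append(p)
    return freqs, P


def freq_features_bf(x, fs):
    """Spectral variance, entropy, centroid, dominant freq, mean PSD (no flux)."""
    f, P = periodogram_bf(x, fs)
    total = sum(P)
    p = [v / total for v in P]
    cgf = sum(fi * pi for fi, pi in zip(f, p))
    spec_var = sum(pi * (fi - cgf) ** 2 for fi, pi in zip(f, p))
    spec_ent = -sum(pi * math.log2(pi) for pi in p if pi > 0)
    dom = f[1:][max(range(len(P) - 1), key=lambda i: P[1:][i])]
    mean_psd = total / len(P)
    return {
        "spec_var": spec_var,
        "spec_entropy": spec_ent,
        "cgf": cgf,
        "dom_freq": dom,
        "mean_psd": mean_psd,
    }


# ---------------------------------------------------------------- AUC

def auc_mannwhitney(scores, labels):
    """AUC as the Mann-Whitney statistic: P(score+ > score-) with tie credit."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    u = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                u += 1.0
            elif sp == sn:
                u += 0.5
    return u / (len(pos) * len(neg))
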