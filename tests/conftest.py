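"""Shared fixtures and independent brute-force oracles.

The oracle implementations here are deliberately plain-Python, loop-based
re-derivations of the quantities the package computes with vectorised
numpy/pandas code; they share no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from hydroqual import synthetic_data


@pytest.fixture(scope="session")
def survey_df():
    """One paper-mode synthetic survey (27 wells x 2 seasons), fixed seed."""
    return synthetic_data.generate(seed=123)


@pytest.fixture(scope="session")
def toy_df():
    """The embedded 5-well unit-test fixture."""
    return synthetic_data.fixture_small()


def brute_force_ewqi(X, limits, ph_index=None, ph_values=None):
    """Loop-based entropy-weight pipeline: returns (e, w, scores).

    ``X`` is an m x n list-of-lists of raw values; ``limits`` the per-column
    permissible limits (ignored for the pH column, rated against the 6.5-8.5
    band around neutral 7).
    """
    m, n = len(X), len(X[0])
    Y = [[0.0] * n for _ in range(m)]
    for j in range(n):
        col = [X[i][j] for i in range(m)]
        lo, hi = min(col), max(col)
        if hi > lo:
            for i in range(m):
                Y[i][j] = (X[i][j] - lo) / (hi - lo)
    e = [1.0] * n
    for j in range(n):
        s = sum(Y[i][j] for i in range(m))
        if s == 0:
            continue
        acc = 0.0
        for i in range(m):
            p = Y[i][j] / s
            if p > 0:
                acc += p * math.log(p)
        e[j] = -acc / math.log(m)
    info = [1.0 - v for v in e]
    total = sum(info)
    w = [v / total for v in info]
    scores = []
    for i in range(m):
        s = 0.0
        for j in range(n):
            c = X[i][j]
            if ph_index is not None and j == ph_index:
                c = ph_values[i]
                if c == 7.0:
                    q = 0.0
                else:
                    sp = 8.5 if c > 7.0 else 6.5
                    q = 100.0 * (c - 7.0) / (sp - 7.0)
            else:
                q = 100.0 * c / limits[j]
            s += w[j] * q
        scores.append(s)
    return e, w, scores


def naive_idw_raster(points, bbox, cell, power):
    """Double-loop IDW raster oracle (row 0 = top), mirroring the grid layout."""
    xmin, ymin, xmax, ymax = bbox
    n_cols = max(1, int(math.ceil((xmax - xmin) / cell)))
    n_rows = max(1, int(math.ceil((ymax - ymin) / cell)))
    out = np.empty((n_rows, n_cols))
    for r in range(n_rows):
        for c in range(n_cols):
            qx = xmin + (c + 0.5) * cell
            qy = ymin + (n_rows - 1 - r + 0.5) * cell
            num = den = 0.0
            exact = None
            for (px, py, pz) in points:
                d = math.hypot(px - qx, py - qy)
                if d < 1e-9:
                    exact = pz
                    break
                wgt = d ** (-power)
                num += wgt * pz
                den += wgt
            out[r, c] = exact if exact is not None else num / den
    return out


def pearson_two_pass(a, b):
    """Textbook two-pass Pearson correlation."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)
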