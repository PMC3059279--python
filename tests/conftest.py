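"""Shared fixtures and independent oracles.

``grid_search_ir_fit`` is a brute-force reference for the magnitude
inversion-recovery fit: it scans T1* on a 1-msec grid, restores polarity
by negating the k earliest-TI samples for every candidate null index k,
and solves each candidate by textbook simple linear regression of the
signed signal on exp(-TI/T1*).  It shares no code path with the package's
fitter.
"""

import numpy as np
import pytest


def grid_search_ir_fit(ti, signal, t1_star_lo=50.0, t1_star_hi=1500.0):
    """Exhaustive (1-msec grid) polarity-restored IR fit.

    Returns dict with a, b, t1_star_msec, t1_msec, rss.
    """
    ti = np.asarray(ti, dtype=float)
    signal = np.asarray(signal, dtype=float)
    order = np.argsort(ti)
    ti, signal = ti[order], signal[order]
    n = ti.size
    grid = np.arange(t1_star_lo, t1_star_hi + 0.5, 1.0)
    e = np.exp(-np.outer(1.0 / grid, ti))  # (G, n)
    e_mean = e.mean(axis=1)
    e_var = e.var(axis=1)

    best = None
    for k in range(n + 1):
        y = signal.copy()
        y[:k] *= -1.0
        y_mean = y.mean()
        cov = (e * y).mean(axis=1) - e_mean * y_mean
        slope = np.where(e_var > 0, cov / np.where(e_var > 0, e_var, 1.0), 0.0)
        intercept = y_mean - slope * e_mean
        pred = intercept[:, None] + slope[:, None] * e
        rss = ((pred - y) ** 2).sum(axis=1)
        g = int(np.argmin(rss))
        if best is None or rss[g] < best["rss"]:
            a = float(intercept[g])
            b = float(-slope[g])
            t1s = float(grid[g])
            best = {
                "a": a,
                "b": b,
                "t1_star_msec": t1s,
                "t1_msec": t1s * (b / a - 1.0) if a > 0 else np.nan,
                "rss": float(rss[g]),
                "null_index": k,
            }
    return best


@pytest.fixture
def ir_oracle():
    return grid_search_ir_fit


@pytest.fixture
def rng():
    return np.random.default_rng(20110304)
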