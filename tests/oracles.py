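"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and shares no code with the package:
ray-casting point-in-polygon (via matplotlib), a summed-area-table
exhaustive window search, O(n²) concordance pair enumeration, a direct
product-over-risk-sets Cox partial likelihood, and a by-hand log-rank
statistic.
"""

from __future__ import annotations

import numpy as np


def points_in_polygons(points: np.ndarray, polygons: list[np.ndarray]) -> np.ndarray:
    """Boolean mask: point inside ANY polygon (matplotlib ray casting)."""
    from matplotlib.path import Path

    mask = np.zeros(len(points), dtype=bool)
    for verts in polygons:
        mask |= Path(verts).contains_points(points)
    return mask


def exhaustive_window_peak(
    epi: np.ndarray, iel: np.ndarray, window: int, min_epi: int
) -> float:
    """Max of 100*n_iel/n_epi over ALL integer-origin windows (1-px stride).

    Exact for integer coordinates: any real-origin window's point content
    equals that of some integer-origin window. Uses a summed-area table.
    """
    allc = np.vstack([epi, iel])
    sx = int(allc[:, 0].min()) - window
    sy = int(allc[:, 1].min()) - window
    W = int(allc[:, 0].max()) - sx + window + 2
    H = int(allc[:, 1].max()) - sy + window + 2

    def window_sums(pts: np.ndarray) -> np.ndarray:
        hist = np.zeros((H, W))
        np.add.at(hist, ((pts[:, 1] - sy).astype(int), (pts[:, 0] - sx).astype(int)), 1)
        P = np.zeros((H + 1, W + 1))
        P[1:, 1:] = hist.cumsum(0).cumsum(1)
        ys = np.arange(0, H - window + 1)
        xs = np.arange(0, W - window + 1)
        return (
            P[np.ix_(ys + window, xs + window)]
            - P[np.ix_(ys, xs + window)]
            - P[np.ix_(ys + window, xs)]
            + P[np.ix_(ys, xs)]
        )

    ne = window_sums(epi)
    ni = window_sums(iel)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ne >= min_epi, 100.0 * ni / ne, -np.inf)
    return float(ratio.max())


def pairwise_concordance(times, events, risks) -> float:
    """O(n²) loop enumeration of Harrell's C with 0.5 for score ties."""
    n = len(times)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i]:
                den += 1
                if risks[i] > risks[j]:
                    num += 1.0
                elif risks[i] == risks[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Breslow log partial likelihood by explicit product over risk sets.

    Valid oracle for distinct event times (no ties), where Breslow and
    Efron coincide.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.where(events)[0]:
        risk_set = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk_set])))
    return ll


def logrank_chi2(times, events, groups) -> float:
    """Two-group log-rank chi-square from the observed-vs-expected table."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert len(labels) == 2
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        d = np.sum(events & (times == t))
        n = at_risk.sum()
        n1 = np.sum(at_risk & (groups == labels[0]))
        d1 = np.sum(events & (times == t) & (groups == labels[0]))
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)
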