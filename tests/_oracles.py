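"""Independent brute-force oracles used by the test suite.

Everything here is written deliberately naively -- explicit loops, repeated
from-scratch regressor rebuilds -- and shares no code with the package
implementation beyond numpy.  Tie conventions mirror the package's stated
ones: neighbor ties break toward the lower sample index (stable sort, with a
tentatively added candidate ranked last) and score ties toward the earliest
pool position.
"""

from __future__ import annotations

import numpy as np


def brute_minkowski(xa, xb, p):
    return sum(abs(float(a) - float(b)) ** p for a, b in zip(xa, xb)) ** (1.0 / p)


def brute_knn(features, labels, query, k, p):
    """Exhaustive sort-and-average kNN prediction."""
    d = np.array([brute_minkowski(query, f, p) for f in features])
    idx = np.argsort(d, kind="stable")[:k]
    return float(np.mean(np.asarray(labels, dtype=float)[idx]))


def brute_delta(features, labels, candidate, pseudo_label, k, p):
    """Literal delta-score: rebuild the regressor before and after adding."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    d_cand = np.array([brute_minkowski(candidate, f, p) for f in features])
    a_idx = np.argsort(d_cand, kind="stable")[:k]
    aug_f = np.vstack([features, np.asarray(candidate, dtype=float)])
    aug_l = np.append(labels, pseudo_label)
    total = 0.0
    for i in a_idx:
        before = brute_knn(features, labels, features[i], k, p)
        after = brute_knn(aug_f, aug_l, features[i], k, p)
        total += (labels[i] - after) ** 2 - (labels[i] - before) ** 2
    return total / len(a_idx)


def coreg_reference(l_features, l_labels, l_origins, u_features, u_origins,
                    k, orders=(2.0, 5.0), max_iterations=10):
    """Literal two-player co-training regression reference.

    Both players start from copies of the labeled set; per iteration each in
    turn scans the shared pool, scores every candidate by the brute delta,
    takes the best strictly negative one and removes it from the pool; at
    iteration end each player's set gains the other's selection.  Returns
    (acceptance log, per-player (features, labels) sets).
    """
    n_players = len(orders)
    sets = [
        [np.asarray(l_features, dtype=float).copy(),
         np.asarray(l_labels, dtype=float).copy()]
        for _ in orders
    ]
    pool = [(np.asarray(f, dtype=float), tuple(o))
            for f, o in zip(u_features, u_origins)]
    log = []
    for iteration in range(max_iterations):
        if not pool:
            break
        picks: list[tuple | None] = []
        for j, p in enumerate(orders):
            feats, labs = sets[j]
            best = None
            for pos, (xu, orig) in enumerate(pool):
                yhat = brute_knn(feats, labs, xu, k, p)
                delta = brute_delta(feats, labs, xu, yhat, k, p)
                if best is None or delta < best[0]:
                    best = (delta, pos, yhat)
            if best is not None and best[0] < 0:
                delta, pos, yhat = best
                xu, orig = pool.pop(pos)
                picks.append((j, xu, orig, yhat, delta))
                log.append({"iteration": iteration, "player": j, "origin": orig,
                            "pseudo_label": yhat, "delta": delta})
            else:
                picks.append(None)
        changed = False
        for j in range(n_players):
            for pick in picks:
                if pick is None or pick[0] == j:
                    continue
                _, xu, _, yhat, _ = pick
                sets[j][0] = np.vstack([sets[j][0], xu])
                sets[j][1] = np.append(sets[j][1], yhat)
                changed = True
        if not changed:
            break
    return log, sets


def brute_windows(x, p, q):
    """Naive triple-loop 2D sliding window; returns (windows, anchors)."""
    i_n, j_n, k_n = x.shape
    windows, anchors = [], []
    for i in range(i_n - p + 1):
        for k in range(k_n - q + 1):
            rows = []
            for bi in range(i, i + p):
                for ti in range(k, k + q):
                    rows.append(x[bi, :, ti])
            windows.append(np.array(rows))
            anchors.append((i + p - 1, k + q - 1))
    return np.array(windows), np.array(anchors)
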