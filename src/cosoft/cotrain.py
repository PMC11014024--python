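"""Multi-player co-training with kNN regressors under distinct Minkowski orders.

Semi-supervised regression by co-training: ``n`` kNN regressors ("players"),
identical except for the order ``p`` of the Minkowski metric they use, are
all initialized on the same small labeled set.  Each iteration, each player
scans the shared unlabeled pool, tentatively pseudo-labels every candidate
with its own prediction, and scores the candidate by the change in squared
error it induces on the candidate's k nearest labeled neighbors (the
delta-score; negative means the regressor improved).  The best improving
candidate, with its pseudo-label, is handed to every *other* player's
labeled set and removed from the pool.  Differing metrics give the players
different neighborhoods and therefore genuinely different views of the data,
which is what makes the exchange informative.

After training, the ensemble prediction is the unweighted mean of the
players' kNN predictions, and the pool's remaining samples are imputed so a
downstream supervised model can train on a fully labeled grid.

Tie conventions (fixed so runs are exactly reproducible and oracle-testable):
nearest-neighbor ties break toward the lower sample index; a tentatively
inserted candidate sits at the highest index, so on a distance tie the
incumbent neighbor wins; delta-score ties break toward the earliest pool
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .batch_data import MEASURED, PSEUDO, BatchTensor, SampleSet, flatten

__all__ = [
    "PlayerConfig",
    "PlayerEnsemble",
    "AcceptanceRecord",
    "default_minkowski_orders",
    "minkowski_distance",
    "knn_predict",
    "delta_score",
    "select_candidate",
    "cotrain",
    "ensemble_predict",
    "impute_labels",
]


def default_minkowski_orders(n_players: int) -> list[float]:
    """Default distance orders per player count.

    (2, 5) for two players, following the classic two-regressor convention;
    p=1 joins at three players for a more outlier-robust metric; further
    players extend with 3, 4, 6, ...
    """
    if n_players < 1:
        raise ValueError("n_players must be >= 1")
    if n_players == 1:
        return [2.0]
    if n_players == 2:
        return [2.0, 5.0]
    orders = [1.0, 2.0, 5.0]
    extra = 3.0
    while len(orders) < n_players:
        if extra not in orders:
            orders.append(extra)
        extra += 1.0
    return orders[:n_players]


@dataclass
class PlayerConfig:
    """Hyperparameters of the player ensemble.

    ``minkowski_orders`` must be pairwise distinct and all >= 1 (the
    Minkowski distance is a metric only for p >= 1).  ``pool_size`` caps the
    number of pool candidates each player scans per iteration ("all" scans
    the whole pool).
    """

    n_players: int = 3
    minkowski_orders: list[float] | None = None
    n_neighbors: int = 10
    max_iterations: int = 100
    pool_size: int | str = "all"
    distance_weighted: bool = False

    def __post_init__(self) -> None:
        if self.n_players < 1:
            raise ValueError("n_players must be >= 1")
        if self.minkowski_orders is None:
            self.minkowski_orders = default_minkowski_orders(self.n_players)
        self.minkowski_orders = [float(p) for p in self.minkowski_orders]
        if len(self.minkowski_orders) != self.n_players:
            raise ValueError("need one Minkowski order per player")
        if len(set(self.minkowski_orders)) != self.n_players:
            raise ValueError("Minkowski orders must be pairwise distinct")
        if any(p < 1 for p in self.minkowski_orders):
            raise ValueError("Minkowski orders must be >= 1")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.pool_size != "all" and (not isinstance(self.pool_size, int)
                                        or self.pool_size < 1):
            raise ValueError("pool_size must be 'all' or a positive integer")


@dataclass
class AcceptanceRecord:
    """One pseudo-label acceptance in the co-training log."""

    iteration: int
    player: int
    origin: tuple[int, int]
    pseudo_label: float
    delta: float


@dataclass
class _Player:
    order: float
    features: np.ndarray   # (m, J) labeled features
    labels: np.ndarray     # (m,)
    origins: np.ndarray    # (m, 2)


@dataclass
class PlayerEnsemble:
    """Fitted ensemble state: per-player labeled sets and the remaining pool."""

    config: PlayerConfig
    players: list[_Player]
    pool_features: np.ndarray
    pool_origins: np.ndarray
    log: list[AcceptanceRecord] = field(default_factory=list)
    n_iterations: int = 0
    fitted: bool = False


# ---------------------------------------------------------------------------
# kNN primitives
# ---------------------------------------------------------------------------

def minkowski_distance(xa: np.ndarray, xb: np.ndarray, p: float) -> float:
    """Order-p Minkowski distance (sum_i |xa_i - xb_i|^p)^(1/p)."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if xa.shape != xb.shape:
        raise ValueError(f"dimension mismatch: {xa.shape} vs {xb.shape}")
    if p < 1:
        raise ValueError("Minkowski order p must be >= 1")
    return float(np.sum(np.abs(xa - xb) ** p) ** (1.0 / p))


def _neighbor_indices(distances: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest distances, ties toward the lower index."""
    return np.argsort(distances, kind="stable")[:k]


def knn_predict(
    labeled: SampleSet, query: np.ndarray, k: int, p: float,
    weighted: bool = False,
) -> float:
    """Mean label of the k nearest labeled samples under order p.

    Unweighted by default; with ``weighted`` the neighbors are averaged with
    1/(d + 1e-12) weights.  Candidate selection always uses the unweighted
    mean (the delta-score criterion is defined for it).
    """
    if k > len(labeled):
        raise ValueError(f"k={k} exceeds labeled set size {len(labeled)}")
    query = np.asarray(query, dtype=float)
    d = cdist(query[None, :], labeled.features, metric="minkowski", p=p)[0]
    idx = _neighbor_indices(d, k)
    if weighted:
        w = 1.0 / (d[idx] + 1e-12)
        return float(np.sum(w * labeled.labels[idx]) / np.sum(w))
    return float(np.mean(labeled.labels[idx]))


def delta_score(
    labeled: SampleSet,
    candidate: tuple[np.ndarray, float],
    k: int,
    p: float,
) -> float:
    """Mean squared-error change on the candidate's k nearest labeled neighbors.

    Let ``a`` be the k nearest labeled neighbors of the candidate, ``P`` the
    kNN regressor on the labeled set and ``P'`` the regressor after adding
    the candidate with its pseudo-label.  Returns

        delta = sum_{xi in a} [(yi - P'(xi))^2 - (yi - P(xi))^2] / |a|

    Negative values signal that the pseudo-labeled candidate improves the
    regressor locally.  This literal from-scratch form is the reference;
    :func:`select_candidate` uses an algebraically identical fast path.
    """
    x_cand, y_cand = candidate
    x_cand = np.asarray(x_cand, dtype=float)
    if x_cand.shape != (labeled.n_features,):
        raise ValueError("candidate feature dimension mismatch")
    if k > len(labeled):
        raise ValueError(f"k={k} exceeds labeled set size {len(labeled)}")

    d_cand = cdist(x_cand[None, :], labeled.features, metric="minkowski", p=p)[0]
    a_idx = _neighbor_indices(d_cand, k)

    aug_features = np.vstack([labeled.features, x_cand])
    aug_labels = np.append(labeled.labels, y_cand)

    d_ll = cdist(labeled.features[a_idx], labeled.features, metric="minkowski", p=p)
    d_aug = cdist(labeled.features[a_idx], aug_features, metric="minkowski", p=p)
    total = 0.0
    for row, i in enumerate(a_idx):
        yi = labeled.labels[i]
        before = np.mean(labeled.labels[_neighbor_indices(d_ll[row], k)])
        after = np.mean(aug_labels[_neighbor_indices(d_aug[row], k)])
        total += (yi - after) ** 2 - (yi - before) ** 2
    return float(total / len(a_idx))


# ---------------------------------------------------------------------------
# candidate selection (vectorized, exactly equivalent to delta_score)
# ---------------------------------------------------------------------------

def _scan_pool(
    player: _Player,
    pool_features: np.ndarray,
    k: int,
    candidate_idx: np.ndarray,
) -> tuple[int, float, float] | None:
    """Best improving candidate for one player, or None.

    Returns (pool index, pseudo-label, delta).  The incremental P' update
    exploits that adding one point either displaces a neighbor's current
    k-th nearest labeled sample (strictly closer; ties keep the incumbent,
    matching the append-last stable-sort convention) or changes nothing.
    """
    if candidate_idx.size == 0:
        return None
    feats, labels = player.features, player.labels
    cand = pool_features[candidate_idx]

    d_cl = cdist(cand, feats, metric="minkowski", p=player.order)
    order_cl = np.argsort(d_cl, axis=1, kind="stable")[:, :k]
    pseudo = labels[order_cl].mean(axis=1)

    # per labeled point: its k nearest labeled neighbors (self included)
    d_ll = cdist(feats, feats, metric="minkowski", p=player.order)
    order_ll = np.argsort(d_ll, axis=1, kind="stable")[:, :k]
    pred_before = labels[order_ll].mean(axis=1)            # P(xi)
    kth_idx = order_ll[:, k - 1]
    kth_dist = d_ll[np.arange(len(feats)), kth_idx]        # distance to k-th nn
    kth_label = labels[kth_idx]

    n_cand = cand.shape[0]
    rows = np.repeat(np.arange(n_cand), k)
    neigh = order_cl.reshape(-1)                           # a(u), flattened
    d_to_cand = d_cl[rows, neigh]
    displaces = d_to_cand < kth_dist[neigh]
    pred_after = np.where(
        displaces,
        pred_before[neigh] + (pseudo[rows] - kth_label[neigh]) / k,
        pred_before[neigh],
    )
    yi = labels[neigh]
    diff = (yi - pred_after) ** 2 - (yi - pred_before[neigh]) ** 2
    deltas = diff.reshape(n_cand, k).mean(axis=1)

    best = int(np.argmin(deltas))  # first occurrence = earliest pool order
    if deltas[best] >= 0:
        return None
    return int(candidate_idx[best]), float(pseudo[best]), float(deltas[best])


def select_candidate(
    player_index: int,
    ensemble: PlayerEnsemble,
    config: PlayerConfig,
    rng: np.random.Generator | None = None,
) -> tuple[int, float, float] | None:
    """One player's pick from the current pool: (pool index, pseudo-label, delta).

    Returns None when the pool is empty or no candidate has a negative
    delta-score ("no data can improve the performance of the regressor").
    """
    n_pool = ensemble.pool_features.shape[0]
    if n_pool == 0:
        return None
    candidate_idx = np.arange(n_pool)
    if config.pool_size != "all" and config.pool_size < n_pool:
        if rng is None:
            rng = np.random.default_rng(0)
        candidate_idx = np.sort(
            rng.choice(n_pool, size=config.pool_size, replace=False)
        )
    return _scan_pool(
        ensemble.players[player_index], ensemble.pool_features,
        config.n_neighbors, candidate_idx,
    )


# ---------------------------------------------------------------------------
# the co-training loop
# ---------------------------------------------------------------------------

def cotrain(
    labeled: SampleSet,
    unlabeled: SampleSet,
    config: PlayerConfig,
    rng: np.random.Generator | None = None,
) -> PlayerEnsemble:
    """Run collaborative multi-player co-training.

    Every player starts from a copy of the labeled set.  Per iteration,
    players act in turn: each scans the (shared, shrinking) pool and selects
    at most one improving candidate, which is immediately removed from the
    pool.  At the end of the iteration the union of selections is
    cross-fed: player j receives every selection except its own.  The loop
    exits early when no labeled set changed.
    """
    if len(labeled) < config.n_neighbors:
        raise ValueError("labeled set smaller than n_neighbors")
    if not np.all(labeled.is_labeled):
        raise ValueError("labeled SampleSet contains NaN labels")

    players = [
        _Player(
            order=p,
            features=labeled.features.copy(),
            labels=labeled.labels.copy(),
            origins=labeled.origins.copy(),
        )
        for p in config.minkowski_orders
    ]
    ensemble = PlayerEnsemble(
        config=config,
        players=players,
        pool_features=unlabeled.features.copy(),
        pool_origins=unlabeled.origins.copy(),
    )
    if rng is None:
        rng = np.random.default_rng(0)

    for iteration in range(config.max_iterations):
        if ensemble.pool_features.shape[0] == 0:
            break
        # selections[j] = (features, origin, pseudo_label, delta) or None
        selections: list[tuple[np.ndarray, np.ndarray, float, float] | None] = []
        for j in range(config.n_players):
            pick = select_candidate(j, ensemble, config, rng)
            if pick is None:
                selections.append(None)
                continue
            idx, pseudo, delta = pick
            selections.append((
                ensemble.pool_features[idx].copy(),
                ensemble.pool_origins[idx].copy(),
                pseudo, delta,
            ))
            ensemble.log.append(AcceptanceRecord(
                iteration=iteration, player=j,
                origin=(int(ensemble.pool_origins[idx, 0]),
                        int(ensemble.pool_origins[idx, 1])),
                pseudo_label=pseudo, delta=delta,
            ))
            keep = np.ones(ensemble.pool_features.shape[0], dtype=bool)
            keep[idx] = False
            ensemble.pool_features = ensemble.pool_features[keep]
            ensemble.pool_origins = ensemble.pool_origins[keep]

        ensemble.n_iterations = iteration + 1
        # cross-feed: player j gets the union of selections minus its own
        changed = False
        for j, player in enumerate(players):
            add = [sel for jj, sel in enumerate(selections)
                   if jj != j and sel is not None]
            if not add:
                continue
            changed = True
            player.features = np.vstack([player.features] + [s[0] for s in add])
            player.labels = np.append(player.labels, [s[2] for s in add])
            player.origins = np.vstack([player.origins] + [s[1] for s in add])
        if not changed:
            break

    ensemble.fitted = True
    return ensemble


def ensemble_predict(ensemble: PlayerEnsemble, query: np.ndarray) -> float | np.ndarray:
    """Unweighted mean of the players' kNN predictions at ``query``.

    Accepts a single J-vector (returns a float) or an (n, J) matrix
    (returns a length-n vector).
    """
    if not ensemble.fitted:
        raise RuntimeError("ensemble is not fitted; run cotrain first")
    query = np.asarray(query, dtype=float)
    single = query.ndim == 1
    q = query[None, :] if single else query
    k = ensemble.config.n_neighbors
    preds = np.zeros(q.shape[0])
    for player in ensemble.players:
        d = cdist(q, player.features, metric="minkowski", p=player.order)
        idx = np.argsort(d, axis=1, kind="stable")[:, :k]
        if ensemble.config.distance_weighted:
            w = 1.0 / (np.take_along_axis(d, idx, axis=1) + 1e-12)
            preds += np.sum(w * player.labels[idx], axis=1) / np.sum(w, axis=1)
        else:
            preds += player.labels[idx].mean(axis=1)
    preds /= len(ensemble.players)
    return float(preds[0]) if single else preds


def impute_labels(data: BatchTensor, ensemble: PlayerEnsemble) -> BatchTensor:
    """Fill every unlabeled (batch, time) cell with the ensemble prediction.

    Measured labels are never overwritten.  The returned tensor has an
    all-true mask and a ``label_source`` provenance channel distinguishing
    measured from pseudo labels.
    """
    out = data.copy()
    source = np.full(out.mask.shape, MEASURED, dtype=object)
    missing = ~out.mask
    if missing.any():
        samples = flatten(data)
        queries = samples.features[missing.reshape(-1)]
        preds = ensemble_predict(ensemble, queries)
        out.y[missing] = preds
        source[missing] = PSEUDO
    out.mask = np.ones_like(out.mask, dtype=bool)
    out.label_source = source
    return out
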