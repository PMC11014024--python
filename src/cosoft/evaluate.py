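"""Metrics, end-to-end pipeline orchestration, and sweep experiments.

The full soft-sensor pipeline on a (train, test) campaign split:

1. co-train the multi-player kNN ensemble on the sparsely labeled training
   samples and impute pseudo-labels for every unlabeled training point;
2. fit per-variable standardization on the training tensor only and apply it
   to both splits;
3. slide the 2D (batch x time) window over each split separately (windows
   never straddle the split) and build training rows;
4. train the gated stacked target-related autoencoder on the (measured +
   pseudo) labels and predict the test anchors, averaging the per-row scores
   of each test window;
5. map predictions back to original units and score RMSE and R-squared
   against the measured test anchors.

With ``n_players=1`` (or zero co-training iterations) no pseudo-labels are
produced and the network trains on measured anchors only -- the purely
supervised windowed baseline the co-training variants are compared against.

Sweeps repeat the pipeline over label ratios or player counts with several
seeds and report per-cell seed means, following the ten-seed averaging
protocol common in this literature.  One master seed fans out to independent
simulation / co-training / network-initialization streams so every sweep
cell is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .batch_data import BatchTensor, apply_label_sparsity, flatten
from .cotrain import PlayerConfig, cotrain, default_minkowski_orders, impute_labels
from .gstae import GSTAEModel, TrainingReport, gated_predict, train_gstae
from .preprocess import (
    fit_standardizer,
    inverse_standardize_y,
    slide_window,
    standardize,
    window_to_training_rows,
)
from .synthetic import CampaignConfig, simulate_campaign, train_test_split

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "SweepResult",
    "rmse",
    "r_squared",
    "default_widths",
    "run_pipeline",
    "sweep_label_ratio",
    "sweep_players",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error sqrt(sum (y - yhat)^2 / n)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if y.size < 1:
        raise ValueError("need at least one point")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y: np.ndarray, yhat: np.ndarray, formula: str = "standard") -> float:
    """Coefficient of determination, in either of two conventions.

    ``standard``: 1 - RSS/TSS, the usual definition.  ``ratio``: the
    regression-sum-of-squares form sum (yhat - ybar)^2 / sum (y - ybar)^2
    with ybar the mean of the *true* values; the two agree only when the
    predictions are the least-squares fit.  Outputs always label which form
    was used.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    if y.size < 2:
        raise ValueError("need at least two points")
    ybar = y.mean()
    tss = float(np.sum((y - ybar) ** 2))
    if tss == 0:
        raise ValueError("y is constant; R^2 undefined")
    if formula == "standard":
        return 1.0 - float(np.sum((y - yhat) ** 2)) / tss
    if formula == "ratio":
        return float(np.sum((yhat - ybar) ** 2)) / tss
    raise ValueError(f"unknown formula {formula!r}; use 'standard' or 'ratio'")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_widths(j: int) -> list[int]:
    """Network widths for a J-wide input: presets for the 11- and 7-variable
    layouts, otherwise a strictly decreasing 4-level taper."""
    if j == 11:
        return [11, 9, 7, 4]
    if j == 7:
        return [7, 6, 5, 3]
    widths = [j]
    for frac in (0.8, 0.6, 0.4):
        w = max(int(round(j * frac)), 1)
        if w >= widths[-1]:
            w = widths[-1] - 1
        if w < 1:
            break
        widths.append(w)
    return widths


@dataclass
class PipelineConfig:
    """Everything run_pipeline needs besides the data.

    ``n_players=1`` (or ``max_iterations=0``) selects the supervised
    windowed baseline: no co-training, no pseudo-labels.
    """

    n_players: int = 3
    minkowski_orders: list[float] | None = None
    n_neighbors: int = 10
    max_iterations: int = 100
    pool_size: int | str = "all"
    window_p: int = 3
    window_q: int = 3
    window_mode: str = "stacked_sample"
    widths: list[int] | None = None
    lam: float = 0.5
    lr: float = 0.01
    pretrain_epochs: int = 200
    finetune_epochs: int = 500
    seed: int = 0

    def player_config(self) -> PlayerConfig:
        return PlayerConfig(
            n_players=self.n_players,
            minkowski_orders=self.minkowski_orders,
            n_neighbors=self.n_neighbors,
            max_iterations=self.max_iterations,
            pool_size=self.pool_size,
        )


def _split_seed(master: int) -> tuple[int, int, int]:
    """Fan one master seed into (simulation, co-training, network) streams."""
    ss = np.random.SeedSequence(master)
    children = ss.spawn(3)
    return tuple(int(c.generate_state(1)[0] % (2**31)) for c in children)


@dataclass
class PipelineResult:
    predictions: np.ndarray
    anchors: np.ndarray
    truth: np.ndarray
    metrics: dict[str, float]
    report: TrainingReport
    model: GSTAEModel
    n_pseudo_labels: int


# ---------------------------------------------------------------------------
# the end-to-end pipeline
# ---------------------------------------------------------------------------

def run_pipeline(
    train: BatchTensor, test: BatchTensor, config: PipelineConfig
) -> PipelineResult:
    """Run the complete soft-sensor pipeline on a train/test split."""
    if train.n_variables != test.n_variables:
        raise ValueError("train and test must share the variable axis")
    _, cotrain_seed, net_seed = _split_seed(config.seed)

    # 1. co-training and pseudo-label imputation (training split only)
    use_cotrain = config.n_players > 1 and config.max_iterations > 0
    n_pseudo = 0
    if use_cotrain:
        try:
            samples = flatten(train)
            ensemble = cotrain(
                samples.labeled_subset(),
                samples.unlabeled_subset(),
                config.player_config(),
                rng=np.random.default_rng(cotrain_seed),
            )
            train_full = impute_labels(train, ensemble)
            n_pseudo = int(np.sum(train_full.label_source == "pseudo"))
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"co-training stage failed: {exc}") from exc
    else:
        train_full = train

    # 2. standardization fitted on the training split only
    try:
        scaler = fit_standardizer(train_full)
        train_std = standardize(train_full, scaler)
        test_std = standardize(test, scaler)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"standardization stage failed: {exc}") from exc

    # 3. windows per split; training rows keep labeled anchors only
    p, q = config.window_p, config.window_q
    try:
        wd_train = slide_window(train_std, p, q)
        wd_test = slide_window(test_std, p, q)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"windowing stage failed: {exc}") from exc
    rows = window_to_training_rows(wd_train, mode=config.window_mode)
    labeled_rows = rows.labeled_subset()
    if len(labeled_rows) == 0:
        raise RuntimeError("no labeled training windows; lower the ratio or window size")

    # 4. network training and test prediction
    widths = config.widths or default_widths(labeled_rows.n_features)
    try:
        model, report = train_gstae(
            labeled_rows, widths,
            lam=config.lam, lr=config.lr,
            epochs=(config.pretrain_epochs, config.finetune_epochs),
            seed=net_seed,
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"network training stage failed: {exc}") from exc

    n_w, rows_per, j_n = wd_test.windows.shape
    if config.window_mode == "stacked_sample":
        scores = gated_predict(model, wd_test.windows.reshape(n_w * rows_per, j_n))
        pred_std = scores.reshape(n_w, rows_per).mean(axis=1)
    else:
        scores = gated_predict(model, wd_test.windows.reshape(n_w, rows_per * j_n))
        pred_std = np.asarray(scores)

    # 5. inverse-standardize and score against measured test anchors
    predictions = inverse_standardize_y(pred_std, scaler)
    truth = np.array([
        test.y[a, k] if test.mask[a, k] else np.nan for a, k in wd_test.anchors
    ])
    scored = ~np.isnan(truth)
    metrics = {
        "rmse": rmse(truth[scored], predictions[scored]),
        "r2": r_squared(truth[scored], predictions[scored], "standard"),
        "r2_ratio": r_squared(truth[scored], predictions[scored], "ratio"),
    }
    return PipelineResult(
        predictions=predictions,
        anchors=wd_test.anchors,
        truth=truth,
        metrics=metrics,
        report=report,
        model=model,
        n_pseudo_labels=n_pseudo,
    )


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Per-cell, per-seed metrics of a sweep plus their seed means."""

    axis_name: str
    axis_values: list
    seeds: list[int]
    cells: pd.DataFrame  # columns: axis value, seed, rmse, r2, r2_ratio
    config: dict = field(default_factory=dict)

    def seed_means(self) -> pd.DataFrame:
        return (
            self.cells.groupby(self.axis_name)[["rmse", "r2", "r2_ratio"]]
            .mean()
            .reset_index()
        )


def _run_cell(
    campaign: CampaignConfig,
    n_train: int,
    ratio: int,
    pipeline: PipelineConfig,
    seed: int,
) -> dict[str, float]:
    sim_seed, _, _ = _split_seed(seed)
    camp = replace(campaign, seed=sim_seed)
    data = simulate_campaign(camp)
    train, test = train_test_split(data, n_train)
    if ratio > 1:
        train = apply_label_sparsity(train, ratio)
    cfg = replace(pipeline, seed=seed)
    result = run_pipeline(train, test, cfg)
    return result.metrics


def sweep_label_ratio(
    campaign: CampaignConfig,
    ratios: list[int],
    seeds: list[int],
    pipeline: PipelineConfig | None = None,
    n_train: int | None = None,
) -> SweepResult:
    """Pipeline metrics across label sampling ratios, seed-averaged per cell."""
    if any(r < 1 for r in ratios):
        raise ValueError("ratios must be >= 1")
    pipeline = pipeline or PipelineConfig()
    n_train = n_train or max(1, int(round(campaign.n_batches * 0.75)))
    records = []
    for ratio in ratios:
        for seed in seeds:
            metrics = _run_cell(campaign, n_train, ratio, pipeline, seed)
            records.append({"ratio": ratio, "seed": seed, **metrics})
    cells = pd.DataFrame.from_records(records)
    return SweepResult(
        axis_name="ratio", axis_values=list(ratios), seeds=list(seeds),
        cells=cells,
        config={"campaign": campaign, "pipeline": pipeline, "n_train": n_train},
    )


def sweep_players(
    campaign: CampaignConfig,
    player_counts: list[int],
    seeds: list[int],
    ratio: int = 40,
    pipeline: PipelineConfig | None = None,
    n_train: int | None = None,
) -> SweepResult:
    """Pipeline metrics across player counts at a fixed label ratio.

    Count 1 runs the supervised no-pseudo-label baseline; counts >= 2 use the
    default Minkowski-order sequence for that count.
    """
    if any(c < 1 for c in player_counts):
        raise ValueError("player counts must be >= 1")
    pipeline = pipeline or PipelineConfig()
    n_train = n_train or max(1, int(round(campaign.n_batches * 0.75)))
    records = []
    for count in player_counts:
        cfg = replace(
            pipeline,
            n_players=count,
            minkowski_orders=default_minkowski_orders(count) if count > 1 else None,
            max_iterations=0 if count == 1 else pipeline.max_iterations,
        )
        for seed in seeds:
            metrics = _run_cell(campaign, n_train, ratio, cfg, seed)
            records.append({"players": count, "seed": seed, **metrics})
    cells = pd.DataFrame.from_records(records)
    return SweepResult(
        axis_name="players", axis_values=list(player_counts), seeds=list(seeds),
        cells=cells,
        config={"campaign": campaign, "pipeline": pipeline,
                "ratio": ratio, "n_train": n_train},
    )
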