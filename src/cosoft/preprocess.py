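"""Per-variable z-score standardization and the 2D (batch x time) sliding window.

Batch-process data carry dynamics in two directions: along time within a
batch, and across consecutive batches of a campaign.  A p x q window (p
batches x q time points) slides time-first, then shifts one batch, so each
window aggregates the recent past in both directions.  The quality value a
window predicts is anchored at its latest (batch, time) corner, keeping the
features causal in time.

Standardization is per process variable over the pooled I*K training values,
using the population standard deviation (divide by N).  The quality variable
gets its own (mean, sd) fitted on measured labels only, kept in the model so
predictions can be mapped back to original units.  The model is fitted on
training data only and applied unchanged to test data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .batch_data import BatchTensor, SampleSet

__all__ = [
    "StandardizationModel",
    "WindowedDataset",
    "fit_standardizer",
    "standardize",
    "inverse_standardize_y",
    "slide_window",
    "window_to_training_rows",
]


@dataclass
class StandardizationModel:
    """Per-variable (mean, population sd) for X plus a (mean, sd) pair for y."""

    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    fitted_on: str = ""

    @property
    def n_variables(self) -> int:
        return self.x_mean.shape[0]


@dataclass
class WindowedDataset:
    """Windows of a p x q slide: (n_windows, p*q, J) with anchors and labels.

    ``anchors[w]`` is the (batch, time) of window w's last corner; ``labels``
    holds the y value at that anchor (NaN when unmeasured).  Row order within
    a window is batch-major, then time.
    """

    windows: np.ndarray
    anchors: np.ndarray
    labels: np.ndarray
    window_shape: tuple[int, int]

    def __len__(self) -> int:
        return self.windows.shape[0]


def fit_standardizer(data: BatchTensor) -> StandardizationModel:
    """Pool all I*K values per variable; mean and population sd (divide by N)."""
    i, j, k = data.x.shape
    if i * k < 2:
        raise ValueError("need at least two values per variable to standardize")
    flat = data.x.reshape(i, j, k).transpose(1, 0, 2).reshape(j, i * k)
    x_mean = flat.mean(axis=1)
    x_sd = flat.std(axis=1)  # ddof=0: population sd
    y_obs = data.y[data.mask]
    if y_obs.size >= 1:
        y_mean = float(y_obs.mean())
        y_sd = float(y_obs.std())
    else:
        y_mean, y_sd = 0.0, 1.0
    return StandardizationModel(
        x_mean=x_mean, x_sd=x_sd, y_mean=y_mean, y_sd=y_sd,
        fitted_on=f"I={i}, J={j}, K={k}, labeled={int(data.mask.sum())}",
    )


def standardize(data: BatchTensor, model: StandardizationModel) -> BatchTensor:
    """Apply (x - mean)/sd per variable; sd=0 variables map to 0 with a warning.

    The quality series is standardized with its own (mean, sd); unmeasured y
    cells pass through untouched (they are NaN anyway).
    """
    if model.n_variables != data.n_variables:
        raise ValueError(
            f"model fitted for J={model.n_variables}, data has J={data.n_variables}"
        )
    out = data.copy()
    sd = model.x_sd.copy()
    degenerate = sd == 0
    if degenerate.any():
        names = [data.variable_names[v] for v in np.flatnonzero(degenerate)]
        warnings.warn(
            f"constant variables mapped to zero (sd=0): {names}", stacklevel=2
        )
        sd[degenerate] = 1.0
    out.x = (data.x - model.x_mean[None, :, None]) / sd[None, :, None]
    out.x[:, degenerate, :] = 0.0
    y_sd = model.y_sd if model.y_sd > 0 else 1.0
    out.y = (data.y - model.y_mean) / y_sd
    return out


def inverse_standardize_y(values: np.ndarray, model: StandardizationModel) -> np.ndarray:
    """Map standardized quality predictions back to original units."""
    y_sd = model.y_sd if model.y_sd > 0 else 1.0
    return np.asarray(values, dtype=float) * y_sd + model.y_mean


def slide_window(data: BatchTensor, p: int, q: int) -> WindowedDataset:
    """Slide a p x q window over the tensor, time-inner then batch-outer.

    Window (i, k) covers batches [i, i+p-1] x times [k, k+q-1]; there are
    (I-p+1)*(K-q+1) windows.  Each window is a (p*q) x J matrix with rows
    batch-major, anchored (and labeled) at its last (batch, time) corner.
    """
    i_n, j_n, k_n = data.x.shape
    if not 1 <= p <= i_n:
        raise ValueError(f"window batch size p={p} must be in [1, I={i_n}]")
    if not 1 <= q <= k_n:
        raise ValueError(f"window time size q={q} must be in [1, K={k_n}]")
    n_i = i_n - p + 1
    n_k = k_n - q + 1
    # (I, K, J) view so one window slice is contiguous in (batch, time) order
    xt = np.ascontiguousarray(np.transpose(data.x, (0, 2, 1)))
    windows = np.empty((n_i * n_k, p * q, j_n))
    anchors = np.empty((n_i * n_k, 2), dtype=int)
    labels = np.empty(n_i * n_k)
    w = 0
    for i in range(n_i):            # batch-outer
        block = xt[i : i + p]
        for k in range(n_k):        # time-inner
            windows[w] = block[:, k : k + q, :].reshape(p * q, j_n)
            ai, ak = i + p - 1, k + q - 1
            anchors[w] = (ai, ak)
            labels[w] = data.y[ai, ak] if data.mask[ai, ak] else np.nan
            w += 1
    return WindowedDataset(
        windows=windows, anchors=anchors, labels=labels, window_shape=(p, q)
    )


def window_to_training_rows(wd: WindowedDataset, mode: str = "stacked_sample") -> SampleSet:
    """Turn windows into network training rows.

    ``stacked_sample``: each window contributes its p*q rows of width J, all
    carrying the window's anchor label -- this keeps the network input width
    equal to the variable count.  ``flatten``: each window becomes a single
    row of width p*q*J.  Origins record the anchor (shared by a window's
    rows in stacked mode).
    """
    n_w, rows_per, j_n = wd.windows.shape
    if mode == "stacked_sample":
        features = wd.windows.reshape(n_w * rows_per, j_n)
        labels = np.repeat(wd.labels, rows_per)
        origins = np.repeat(wd.anchors, rows_per, axis=0)
    elif mode == "flatten":
        features = wd.windows.reshape(n_w, rows_per * j_n)
        labels = wd.labels.copy()
        origins = wd.anchors.copy()
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'stacked_sample' or 'flatten'")
    return SampleSet(features=features, labels=labels, origins=origins)
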