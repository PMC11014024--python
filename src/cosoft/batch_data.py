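"""Three-way batch-process data with partially observed quality labels.

Batch processes (fermentations, crystallizations, polymerizations) yield
three-way data: ``I`` batches x ``J`` process variables x ``K`` time points.
The quality variable (product concentration, biomass, ...) is expensive to
assay, so it is observed only at a subset of the (batch, time) grid.  This
module holds the central containers -- :class:`BatchTensor` for the three-way
array with a label mask, :class:`SampleSet` for the flat per-time-point view
consumed by the co-training players -- plus long-format CSV readers/writers
and label-sparsification utilities.

Conventions
-----------
All indices are 0-based.  Flat samples are ordered batch-major, then time.
Label positions are placed at a deterministic time stride by default
(quality assays at fixed sampling intervals); a seeded random mask is
available for robustness experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BatchTensor",
    "SampleSet",
    "GridError",
    "read_long_csv",
    "write_long_csv",
    "flatten",
    "apply_label_sparsity",
]

#: provenance channel values
MEASURED = "measured"
PSEUDO = "pseudo"


class GridError(ValueError):
    """Raised when a long-format file does not cover a complete I x K grid."""


@dataclass
class BatchTensor:
    """Process tensor ``x`` (I, J, K) with quality series ``y`` (I, K).

    ``mask`` is True where the quality value was actually measured; ``y``
    may hold anything (typically NaN) where ``mask`` is False.
    ``label_source`` is an optional provenance channel distinguishing
    measured from pseudo labels after imputation.
    """

    x: np.ndarray
    y: np.ndarray
    mask: np.ndarray
    variable_names: list[str] = field(default_factory=list)
    time_step: float = 1.0
    label_source: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.x.ndim != 3:
            raise ValueError(f"x must be (I, J, K), got shape {self.x.shape}")
        i, j, k = self.x.shape
        if min(i, j, k) < 1:
            raise ValueError("I, J, K must all be >= 1")
        if self.y.shape != (i, k):
            raise ValueError(f"y must be (I, K)={(i, k)}, got {self.y.shape}")
        if self.mask.shape != (i, k):
            raise ValueError(f"mask must be (I, K)={(i, k)}, got {self.mask.shape}")
        if not self.variable_names:
            self.variable_names = [f"var{n}" for n in range(j)]
        if len(self.variable_names) != j:
            raise ValueError("variable_names length must equal J")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("x has missing or non-finite entries")
        if not np.all(np.isfinite(self.y[self.mask])):
            raise ValueError("y must be finite wherever mask is true")
        if self.time_step <= 0:
            raise ValueError("time_step must be positive")

    @property
    def n_batches(self) -> int:
        return self.x.shape[0]

    @property
    def n_variables(self) -> int:
        return self.x.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.x.shape[2]

    @property
    def n_labeled(self) -> int:
        """Count of measured quality points (the assay count L)."""
        return int(self.mask.sum())

    def copy(self) -> "BatchTensor":
        return BatchTensor(
            x=self.x.copy(),
            y=self.y.copy(),
            mask=self.mask.copy(),
            variable_names=list(self.variable_names),
            time_step=self.time_step,
            label_source=None if self.label_source is None else self.label_source.copy(),
        )


@dataclass
class SampleSet:
    """Flat (batch, time) samples in R^J, the unit handled by co-training.

    ``labels`` uses NaN for unlabeled samples.  ``origins`` records the
    (batch_index, time_index) each row came from; uniqueness is required
    for sets produced by :func:`flatten` but windowed training rows may
    legitimately share an anchor origin.
    """

    features: np.ndarray
    labels: np.ndarray
    origins: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=float)
        self.origins = np.asarray(self.origins, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D (n, J) array")
        n = self.features.shape[0]
        if self.labels.shape != (n,):
            raise ValueError("labels must be length n")
        if self.origins.shape != (n, 2):
            raise ValueError("origins must be (n, 2)")

    def __len__(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def is_labeled(self) -> np.ndarray:
        return ~np.isnan(self.labels)

    def labeled_subset(self) -> "SampleSet":
        m = self.is_labeled
        return SampleSet(self.features[m], self.labels[m], self.origins[m])

    def unlabeled_subset(self) -> "SampleSet":
        m = ~self.is_labeled
        return SampleSet(self.features[m], self.labels[m], self.origins[m])


# ---------------------------------------------------------------------------
# long-format CSV I/O
# ---------------------------------------------------------------------------

def read_long_csv(path) -> BatchTensor:
    """Read a long-format CSV (`batch,time,<vars...>[,quality]`) into a tensor.

    The rows must cover a complete I x K grid; an empty quality field marks
    an unlabeled (batch, time) point.
    """
    # round_trip parsing: values written as repr(float) come back bit-exact
    frame = pd.read_csv(path, float_precision="round_trip")
    cols = list(frame.columns)
    if cols[:2] != ["batch", "time"]:
        raise ValueError("first two columns must be 'batch' and 'time'")
    has_quality = "quality" in cols
    var_names = [c for c in cols[2:] if c != "quality"]
    if not var_names:
        raise ValueError("no process-variable columns found")

    for col in cols:
        if col == "quality":
            continue
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna()
        if bad.any() or frame[col].isna().any():
            row = int(np.flatnonzero(bad | frame[col].isna())[0])
            raise ValueError(f"non-numeric or missing value in column '{col}' at data row {row}")
        frame[col] = converted
    if has_quality:
        converted = pd.to_numeric(frame["quality"], errors="coerce")
        bad = converted.isna() & frame["quality"].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-numeric value in column 'quality' at data row {row}")
        frame["quality"] = converted

    batches = np.sort(frame["batch"].unique())
    times = np.sort(frame["time"].unique())
    n_i, n_k = len(batches), len(times)
    if len(frame) != n_i * n_k:
        # locate the first hole for the error message
        seen = set(zip(frame["batch"], frame["time"]))
        for b in batches:
            for t in times:
                if (b, t) not in seen:
                    raise GridError(f"missing grid cell (batch={b}, time={t})")
        raise GridError("duplicate (batch, time) rows present")

    b_index = {b: n for n, b in enumerate(batches)}
    t_index = {t: n for n, t in enumerate(times)}
    x = np.empty((n_i, len(var_names), n_k), dtype=float)
    y = np.full((n_i, n_k), np.nan)
    mask = np.zeros((n_i, n_k), dtype=bool)
    bi = frame["batch"].map(b_index).to_numpy()
    ki = frame["time"].map(t_index).to_numpy()
    for v, name in enumerate(var_names):
        x[bi, v, ki] = frame[name].to_numpy()
    if has_quality:
        q = frame["quality"].to_numpy()
        good = ~np.isnan(q)
        y[bi[good], ki[good]] = q[good]
        mask[bi[good], ki[good]] = True

    if n_k > 1:
        steps = np.diff(times.astype(float))
        time_step = float(np.median(steps))
    else:
        time_step = 1.0
    return BatchTensor(x=x, y=y, mask=mask, variable_names=var_names, time_step=time_step)


def write_long_csv(data: BatchTensor, path) -> None:
    """Write a tensor to long-format CSV; masked quality cells become empty."""
    i, j, k = data.x.shape
    bi = np.repeat(np.arange(i), k)
    ki = np.tile(np.arange(k), i)
    columns: dict[str, object] = {
        "batch": bi,
        "time": ki * data.time_step,
    }
    for v, name in enumerate(data.variable_names):
        columns[name] = data.x[bi, v, ki]
    quality = data.y[bi, ki].astype(object)
    quality[~data.mask[bi, ki]] = None
    columns["quality"] = quality
    frame = pd.DataFrame(columns)
    # str(float) round-trips exactly through pandas' float64 parser
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# flattening and label sparsification
# ---------------------------------------------------------------------------

def flatten(data: BatchTensor) -> SampleSet:
    """Flatten to I*K samples of dimension J, batch-major then time."""
    i, j, k = data.x.shape
    features = np.transpose(data.x, (0, 2, 1)).reshape(i * k, j)
    labels = np.where(data.mask, data.y, np.nan).reshape(i * k)
    origins = np.column_stack(
        [np.repeat(np.arange(i), k), np.tile(np.arange(k), i)]
    )
    return SampleSet(features=features, labels=labels, origins=origins)


def apply_label_sparsity(
    data: BatchTensor,
    ratio: int,
    offset: int = 0,
    random_seed: int | None = None,
) -> BatchTensor:
    """Keep one label per ``ratio`` time points (the r:1 sampling ratio).

    By default labels sit at time indices ``t`` with ``t % ratio == offset``
    in every batch, mimicking a fixed assay interval.  With ``random_seed``
    set, the same count of positions per batch is drawn uniformly instead.
    Values of ``x`` and ``y`` are unchanged; only the mask is rewritten.
    """
    if int(ratio) != ratio or ratio < 1:
        raise ValueError("ratio must be an integer >= 1")
    ratio = int(ratio)
    if not 0 <= offset < ratio:
        raise ValueError("offset must satisfy 0 <= offset < ratio")
    out = data.copy()
    n_i, n_k = out.mask.shape
    if random_seed is None:
        mask_row = (np.arange(n_k) % ratio) == offset
        out.mask = np.tile(mask_row, (n_i, 1))
    else:
        rng = np.random.default_rng(random_seed)
        count = math.ceil((n_k - offset) / ratio)
        out.mask = np.zeros((n_i, n_k), dtype=bool)
        for b in range(n_i):
            picks = rng.choice(n_k, size=count, replace=False)
            out.mask[b, picks] = True
    if not np.all(np.isfinite(out.y[out.mask])):
        raise ValueError("y is not finite at a requested label position")
    return out
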