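"""Standardization, target encoding and train/validation splitting.

Two feature scalings are exposed, as the tree and the networks want
different things:

* :class:`ZScoreScaler` — z = (x - mean) / sd per column (sample SD,
  n - 1 denominator), the standardization required before the factorial
  GLM fits.  Fitted statistics are kept so held-out data can be
  transformed with training statistics.
* :class:`UnitIntervalScaler` — min-max to [0, 1] on training ranges,
  the sigmoid-friendly scaling used for network inputs.

Categorical targets are encoded on a single neuron with equally spaced
codes k/(K-1) and decoded to the nearest code (ties to the lower index).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import reference as ref

_ID_COLS = ("sample_id", "cultivar", "practice", "harvest")


def parameter_columns(table: pd.DataFrame) -> list[str]:
    """The numeric parameter columns of a cohort table, in table order."""
    return [c for c in table.columns if c not in _ID_COLS]


class ZScoreScaler(BaseEstimator, TransformerMixin):
    """Column-wise standardization to zero mean and unit sample variance.

    Raises on constant columns, where the transform is undefined.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=1)
        bad = np.flatnonzero(self.sd_ == 0)
        if bad.size:
            raise ValueError(
                f"constant column(s) at position(s) {bad.tolist()}: "
                "standard deviation is zero, standardization undefined")
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.mean_) / self.sd_

    def inverse_transform(self, X):
        return np.asarray(X, dtype=float) * self.sd_ + self.mean_


class UnitIntervalScaler(BaseEstimator, TransformerMixin):
    """Min-max scaling to [0, 1] on the ranges seen at fit time.

    Held-out values outside the training range map outside [0, 1]; they
    are not clipped, the sigmoid network tolerates them.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        span = X.max(axis=0) - self.min_
        bad = np.flatnonzero(span == 0)
        if bad.size:
            raise ValueError(
                f"constant column(s) at position(s) {bad.tolist()}: "
                "range is zero, min-max scaling undefined")
        self.span_ = span
        return self

    def transform(self, X):
        return (np.asarray(X, dtype=float) - self.min_) / self.span_

    def inverse_transform(self, X):
        return np.asarray(X, dtype=float) * self.span_ + self.min_


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize the parameter columns of a cohort table.

    Returns the standardized table and a (mean, sd) frame indexed by
    column, so held-out data can be transformed with the same statistics.
    """
    cols = parameter_columns(table)
    scaler = ZScoreScaler().fit(table[cols].to_numpy())
    out = table.copy()
    out[cols] = scaler.transform(table[cols].to_numpy())
    stats = pd.DataFrame({"mean": scaler.mean_, "sd": scaler.sd_}, index=cols)
    return out, stats


def encode_target(labels, levels: list[str] | tuple[str, ...]) -> np.ndarray:
    """Map level k of K (0-based) to the code k/(K-1)."""
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need at least 2 levels")
    lookup = {lev: k / (len(levels) - 1) for k, lev in enumerate(levels)}
    try:
        return np.array([lookup[l] for l in labels], dtype=float)
    except KeyError as e:
        raise ValueError(f"label {e.args[0]!r} not in levels {levels}") from e


def decode_target(values, levels: list[str] | tuple[str, ...]) -> np.ndarray:
    """Decode predicted floats to the nearest code's level.

    Ties resolve to the lower index (argmin takes the first minimum).
    """
    levels = list(levels)
    codes = np.arange(len(levels)) / (len(levels) - 1)
    values = np.atleast_1d(np.asarray(values, dtype=float))
    idx = np.abs(values[:, None] - codes[None, :]).argmin(axis=1)
    return np.array(levels, dtype=object)[idx]


def split_train_validation(table: pd.DataFrame, n_validation: int = ref.VALIDATION_SAMPLES,
                           seed: int = 0, stratified: bool = True
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded split into training and validation cohorts.

    Stratified mode spreads the validation cases over harvest x practice
    cells as evenly as possible (each cell contributes floor or ceil of
    n_validation / n_cells cases).  The default sizes reproduce the
    151/16 protocol on a 167-sample cohort.
    """
    if n_validation > len(table):
        raise ValueError(
            f"requested validation size {n_validation} exceeds cohort size "
            f"{len(table)}")
    rng = np.random.default_rng(seed)
    if not stratified:
        val_pos = rng.choice(len(table), size=n_validation, replace=False)
    else:
        cells = [grp.index.to_numpy() for _, grp in
                 table.groupby(["harvest", "practice"], sort=True)]
        base, extra = divmod(n_validation, len(cells))
        take = np.full(len(cells), base, dtype=int)
        take[rng.choice(len(cells), size=extra, replace=False)] += 1
        picks = []
        for cell_idx, k in zip(cells, take):
            k = min(k, len(cell_idx))
            picks.append(rng.choice(cell_idx, size=k, replace=False))
        val_pos = np.concatenate(picks)
        # top up (without replacement) if some cells were too small
        short = n_validation - len(val_pos)
        if short > 0:
            rest = np.setdiff1d(table.index.to_numpy(), val_pos)
            val_pos = np.concatenate(
                [val_pos, rng.choice(rest, size=short, replace=False)])
    val_mask = table.index.isin(val_pos)
    return table.loc[~val_mask].copy(), table.loc[val_mask].copy()


def save_split(train: pd.DataFrame, validation: pd.DataFrame, path) -> None:
    rows = [(sid, "train") for sid in train["sample_id"]] + \
           [(sid, "validation") for sid in validation["sample_id"]]
    pd.DataFrame(rows, columns=["sample_id", "partition"]).to_csv(
        path, index=False)


def load_split(table: pd.DataFrame, path) -> tuple[pd.DataFrame, pd.DataFrame]:
    spec = pd.read_csv(path).set_index("sample_id")["partition"]
    part = table["sample_id"].map(spec)
    if part.isna().any():
        missing = table.loc[part.isna(), "sample_id"].tolist()
        raise ValueError(f"split file lacks samples: {missing[:5]} ...")
    return (table[part == "train"].copy(),
            table[part == "validation"].copy())
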