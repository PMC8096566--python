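"""Tabular breakthrough data: loading, validation, normalization, splitting.

A breakthrough dataset maps four operating variables of a packed adsorption
column — initial adsorbate concentration ``c0``, bed height ``h0``, flow
velocity ``u`` and run time ``t`` — to the outlet-to-inlet concentration
ratio ``C/C0`` in [0, 1].  Units are carried as opaque labels: every model
in this package operates on min–max normalized features, so computation is
unit-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed feature ordering used throughout the package.
FEATURE_ORDER: tuple[str, ...] = ("c0", "h0", "u", "t")
TARGET = "ratio"

#: Small experimental overshoot above C/C0 = 1 tolerated on input.
RATIO_MAX = 1.05


class DataValidationError(ValueError):
    """A row violates the physical constraints of a breakthrough record."""


class ConfigurationError(ValueError):
    """The input file or column mapping is unusable."""


@dataclass(frozen=True)
class BreakthroughRecord:
    """One observation (c0, h0, u, t) -> C/C0.

    Predictors must be positive (t = 0 allowed); the ratio must lie in
    [0, 1.05].
    """

    c0: float
    h0: float
    u: float
    t: float
    ratio: float

    def __post_init__(self) -> None:
        for name in ("c0", "h0", "u"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DataValidationError(f"{name} must be strictly positive, got {v!r}")
        if not np.isfinite(self.t) or self.t < 0:
            raise DataValidationError(f"t must be non-negative, got {self.t!r}")
        if not np.isfinite(self.ratio) or not (0.0 <= self.ratio <= RATIO_MAX):
            raise DataValidationError(
                f"ratio must lie in [0, {RATIO_MAX}], got {self.ratio!r}"
            )

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.c0, self.h0, self.u, self.t, self.ratio)


@dataclass
class Dataset:
    """Ordered collection of breakthrough records with a fixed feature order."""

    frame: pd.DataFrame
    feature_order: tuple[str, ...] = FEATURE_ORDER

    def __post_init__(self) -> None:
        if len(self.frame) == 0:
            raise DataValidationError("empty dataset")
        required = list(self.feature_order) + [TARGET]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ConfigurationError(f"dataset missing columns: {missing}")
        if self.frame[required].isna().any().any():
            bad = int(self.frame[required].isna().any(axis=1).idxmax())
            raise DataValidationError(f"missing field in row {bad}")
        self.frame = self.frame[required].reset_index(drop=True).astype(float)

    @classmethod
    def from_records(cls, records: list[BreakthroughRecord]) -> "Dataset":
        frame = pd.DataFrame(
            [r.as_tuple() for r in records], columns=list(FEATURE_ORDER) + [TARGET]
        )
        return cls(frame)

    @property
    def X(self) -> np.ndarray:
        """Feature matrix, shape (n, 4), columns in ``feature_order``."""
        return self.frame[list(self.feature_order)].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        """Target vector C/C0, shape (n,)."""
        return self.frame[TARGET].to_numpy(float)

    def __len__(self) -> int:
        return len(self.frame)

    def records(self) -> list[BreakthroughRecord]:
        return [
            BreakthroughRecord(*row)
            for row in self.frame.itertuples(index=False, name=None)
        ]

    def subset(self, indices: np.ndarray) -> "Dataset":
        return Dataset(self.frame.iloc[np.asarray(indices)].reset_index(drop=True))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def load_table(path, column_map: dict[str, str] | None = None, sep: str | None = None) -> Dataset:
    """Read a delimited text table of breakthrough data.

    Parameters
    ----------
    path:
        CSV/TSV file with a header row.
    column_map:
        Mapping from the canonical names ``c0, h0, u, t, ratio`` to the
        column names used in the file.  Identity by default.
    sep:
        Field separator; sniffed by pandas when ``None``.
    """
    column_map = column_map or {}
    try:
        frame = pd.read_csv(path, sep=sep, engine="python")
    except pd.errors.EmptyDataError as exc:
        raise DataValidationError("empty dataset") from exc

    rename = {}
    for canonical in list(FEATURE_ORDER) + [TARGET]:
        source = column_map.get(canonical, canonical)
        if source not in frame.columns:
            raise ConfigurationError(
                f"required column {canonical!r} (file column {source!r}) not found; "
                f"available: {list(frame.columns)}"
            )
        rename[source] = canonical
    frame = frame.rename(columns=rename)[list(FEATURE_ORDER) + [TARGET]]
    if len(frame) == 0:
        raise DataValidationError("empty dataset")

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~frame.isna()
    if bad.any().any():
        row = int(bad.any(axis=1).idxmax())
        raise DataValidationError(f"unparsable numeric cell in row {row}")
    frame = numeric

    # row-level physical validation with index reporting
    for idx, row in frame.iterrows():
        try:
            BreakthroughRecord(*row.tolist())
        except DataValidationError as exc:
            raise DataValidationError(f"row {idx}: {exc}") from exc

    logger.info("loaded %d breakthrough records from %s", len(frame), path)
    return Dataset(frame)


@dataclass
class NormalizationSpec:
    """Per-feature min–max ranges for the affine map onto [-1, 1].

    The forward map is ``D_N = 2 (D - D_min) / (D_max - D_min) - 1``; values
    outside the fitted range map outside [-1, 1] without clipping.
    """

    mins: dict[str, float]
    maxs: dict[str, float]
    columns: tuple[str, ...] = field(default=FEATURE_ORDER)

    def __post_init__(self) -> None:
        for c in self.columns:
            if not self.maxs[c] > self.mins[c]:
                raise DataValidationError(
                    f"feature {c!r} has zero range (min == max == {self.mins[c]})"
                )

    @classmethod
    def fit(cls, data: Dataset | pd.DataFrame, columns: tuple[str, ...] = FEATURE_ORDER) -> "NormalizationSpec":
        frame = data.frame if isinstance(data, Dataset) else data
        mins = {c: float(frame[c].min()) for c in columns}
        maxs = {c: float(frame[c].max()) for c in columns}
        return cls(mins=mins, maxs=maxs, columns=tuple(columns))

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.mins[c] for c in self.columns])
        hi = np.array([self.maxs[c] for c in self.columns])
        return lo, hi

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Map original-unit values onto [-1, 1] columnwise."""
        X = np.atleast_2d(np.asarray(X, float))
        lo, hi = self._bounds()
        out = 2.0 * (X - lo) / (hi - lo) - 1.0
        if np.any(out < -1.0 - 1e-12) or np.any(out > 1.0 + 1e-12):
            logger.warning("values outside the fitted range were normalized beyond [-1, 1]")
        return out

    def inverse(self, Xn: np.ndarray) -> np.ndarray:
        Xn = np.atleast_2d(np.asarray(Xn, float))
        lo, hi = self._bounds()
        return (Xn + 1.0) / 2.0 * (hi - lo) + lo

    # single-column convenience used by the target-normalization switch
    def transform_column(self, values: np.ndarray, column: str) -> np.ndarray:
        lo, hi = self.mins[column], self.maxs[column]
        return 2.0 * (np.asarray(values, float) - lo) / (hi - lo) - 1.0

    def inverse_column(self, values: np.ndarray, column: str) -> np.ndarray:
        lo, hi = self.mins[column], self.maxs[column]
        return (np.asarray(values, float) + 1.0) / 2.0 * (hi - lo) + lo

    def to_dict(self) -> dict:
        return {"columns": list(self.columns), "mins": self.mins, "maxs": self.maxs}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationSpec":
        return cls(mins=d["mins"], maxs=d["maxs"], columns=tuple(d["columns"]))


def fit_normalizer(data: Dataset, include_target: bool = False) -> NormalizationSpec:
    """Column-wise min/max of the supplied data; errors on constant columns."""
    columns = FEATURE_ORDER + ((TARGET,) if include_target else ())
    return NormalizationSpec.fit(data, columns=columns)


def split(
    data: Dataset,
    train_fraction: float = 0.75,
    seed: int = 42,
    method: str = "random",
) -> tuple[Dataset, Dataset]:
    """Partition into train/test of sizes round(N·f) and the remainder.

    ``method="random"`` draws a uniform partition without replacement from a
    seeded generator (the default; repeated curves are interleaved across the
    parts).  ``method="sequential"`` takes the first round(N·f) rows, for
    sensitivity checks.
    """
    n = len(data)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if n < 4:
        raise ValueError("dataset too small to split (need >= 4 records)")
    n_train = int(round(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError("train_fraction produces an empty partition")

    if method == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
    elif method == "sequential":
        perm = np.arange(n)
    else:
        raise ValueError(f"unknown split method {method!r}")
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    logger.info("split %d records into %d train / %d test (seed=%s, %s)",
                n, n_train, n - n_train, seed, method)
    return data.subset(train_idx), data.subset(test_idx)


def split_indices(n: int, train_fraction: float = 0.75, seed: int = 42) -> tuple[np.ndarray, np.ndarray]:
    """Index-level variant of :func:`split`, for exporting partitions."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])
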