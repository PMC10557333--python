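"""Variable specifications, validated study tables, splits and design matrices.

A study is a rectangular table of categorical/ordinal/binary variables with
exactly one designated binary outcome.  Every variable carries an explicit
level order; integer scores 0..K-1 are assigned in that order and are the only
numeric representation the rest of the package ever sees.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SCALES = ("binary", "ordinal", "nominal")
ROLES = ("predictor", "outcome")


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one study variable.

    Parameters
    ----------
    name : str
        Column name in the data table.
    role : {"predictor", "outcome"}
    scale : {"binary", "ordinal", "nominal"}
    levels : sequence of str
        Ordered category labels; integer scores 0..K-1 follow this order.
    """

    name: str
    role: str
    scale: str
    levels: tuple[str, ...]

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r} for {self.name}")
        levels = tuple(str(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) < 2:
            raise ValueError(f"{self.name}: needs at least 2 levels")
        if len(set(levels)) != len(levels):
            raise ValueError(f"{self.name}: duplicate level labels")
        if self.scale == "binary" and len(levels) != 2:
            raise ValueError(f"{self.name}: binary scale requires exactly 2 levels")
        if self.role == "outcome" and self.scale != "binary":
            raise ValueError(f"{self.name}: outcome must be binary")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def scores(self) -> dict[str, int]:
        return {lab: k for k, lab in enumerate(self.levels)}


def _check_specs(specs: Sequence[VariableSpec]) -> VariableSpec:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate variable names in specs")
    outcomes = [s for s in specs if s.role == "outcome"]
    if len(outcomes) != 1:
        raise ValueError(f"exactly one outcome required, got {len(outcomes)}")
    return outcomes[0]


@dataclass
class StudyTable:
    """Validated rectangular dataset (labels, not codes, in ``data``)."""

    data: pd.DataFrame
    specs: tuple[VariableSpec, ...]
    n_dropped: int = 0

    def __post_init__(self):
        self.specs = tuple(self.specs)
        self.outcome = _check_specs(self.specs)

    @property
    def n(self) -> int:
        return len(self.data)

    def spec(self, name: str) -> VariableSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def codes(self, name: str) -> np.ndarray:
        """Integer scores 0..K-1 for one variable."""
        s = self.spec(name)
        return self.data[name].map(s.scores()).to_numpy(dtype=np.int64)

    def codes_frame(self, names: Iterable[str] | None = None) -> pd.DataFrame:
        names = list(names) if names is not None else [s.name for s in self.specs]
        return pd.DataFrame({v: self.codes(v) for v in names}, index=self.data.index)

    def outcome_array(self) -> np.ndarray:
        return self.codes(self.outcome.name)

    def subset(self, rows: np.ndarray) -> "StudyTable":
        return StudyTable(self.data.iloc[np.asarray(rows)].reset_index(drop=True), self.specs)


def load_table(source, specs: Sequence[VariableSpec]) -> StudyTable:
    """Read a delimited-text table and validate it against ``specs``.

    Rows with missing cells are dropped (count logged and stored on the
    table); any value outside a variable's declared levels is an error.
    """
    outcome = _check_specs(specs)
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source, dtype=str)
    missing_cols = [s.name for s in specs if s.name not in df.columns]
    if missing_cols:
        raise ValueError(f"columns missing from data: {missing_cols}")
    unknown = [c for c in df.columns if c not in {s.name for s in specs}]
    if unknown:
        raise ValueError(f"unknown columns not in specs: {unknown}")
    df = df[[s.name for s in specs]].astype(str)
    df = df.mask(df.isin(["nan", "None", ""]))
    complete = df.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d incomplete rows", n_dropped)
    df = df[complete].reset_index(drop=True)
    for s in specs:
        bad = ~df[s.name].isin(s.levels)
        if bad.any():
            val = df.loc[bad, s.name].iloc[0]
            raise ValueError(
                f"value not in declared levels: {val!r} for variable {s.name!r}"
            )
    if df[outcome.name].nunique() > 2:
        raise ValueError("outcome not binary")
    return StudyTable(df, tuple(specs), n_dropped=n_dropped)


def write_table(table: StudyTable, path) -> None:
    table.data.to_csv(path, index=False)


def specs_from_config(config) -> tuple[VariableSpec, ...]:
    """Build variable specs from a YAML/JSON config mapping or stream."""
    if isinstance(config, (str, bytes)):
        config = yaml.safe_load(config)
    elif hasattr(config, "read"):
        config = yaml.safe_load(config.read())
    out = []
    for item in config["variables"]:
        out.append(
            VariableSpec(
                name=item["name"],
                role=item.get("role", "predictor"),
                scale=item["scale"],
                levels=tuple(item["levels"]),
            )
        )
    _check_specs(out)
    return tuple(out)


def specs_to_config(specs: Sequence[VariableSpec]) -> dict:
    return {
        "variables": [
            {"name": s.name, "role": s.role, "scale": s.scale, "levels": list(s.levels)}
            for s in specs
        ]
    }


# ---------------------------------------------------------------------------
# train/test split


@dataclass(frozen=True)
class SplitIndex:
    train_rows: np.ndarray
    test_rows: np.ndarray
    seed: int
    train_fraction: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "train_rows": self.train_rows.tolist(),
                "test_rows": self.test_rows.tolist(),
                "seed": self.seed,
                "train_fraction": self.train_fraction,
            }
        )


def _allocate(sizes: np.ndarray, total_train: int, fraction: float) -> np.ndarray:
    """Largest-remainder allocation of train counts across strata."""
    raw = sizes * fraction
    base = np.floor(raw).astype(int)
    short = total_train - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    for i in order[: max(short, 0)]:
        base[i] += 1
    # over-allocation can only happen through rounding of the global total
    i = 0
    while base.sum() > total_train:
        j = order[-1 - i]
        if base[j] > 0:
            base[j] -= 1
        i += 1
    return base


def split_train_test(
    table: StudyTable,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify_on: str | None = "__outcome__",
) -> SplitIndex:
    """Deterministic train/test split, stratified on the outcome by default.

    ``|train| = round(fraction * n)``; within each stratum the allocation is
    proportional to the largest remainder, so stratum prevalences in the two
    halves differ from proportionality by less than one observation.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = table.n
    total_train = int(round(train_fraction * n))
    rng = np.random.default_rng(seed)
    if stratify_on is None:
        perm = rng.permutation(n)
        train = np.sort(perm[:total_train])
        test = np.sort(perm[total_train:])
    else:
        name = table.outcome.name if stratify_on == "__outcome__" else stratify_on
        if name not in table.data.columns:
            raise ValueError(f"stratification variable {name!r} absent")
        codes = table.codes(name)
        strata = np.unique(codes)
        sizes = np.array([(codes == s).sum() for s in strata])
        takes = _allocate(sizes.astype(float), total_train, train_fraction)
        train_parts, test_parts = [], []
        for s, take in zip(strata, takes):
            idx = np.flatnonzero(codes == s)
            perm = rng.permutation(len(idx))
            train_parts.append(idx[perm[:take]])
            test_parts.append(idx[perm[take:]])
        train = np.sort(np.concatenate(train_parts))
        test = np.sort(np.concatenate(test_parts))
    return SplitIndex(train, test, seed=seed, train_fraction=train_fraction)


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignMatrix:
    """Numeric predictor matrix with a record of how each column was coded."""

    X: np.ndarray
    column_map: list[tuple[str, str]]  # (variable, "score" | "indicator:<level>")
    variables: list[str]

    @property
    def shape(self):
        return self.X.shape

    def columns_for(self, variable: str) -> list[int]:
        return [j for j, (v, _) in enumerate(self.column_map) if v == variable]

    def subset(self, rows) -> "DesignMatrix":
        return DesignMatrix(X=self.X[np.asarray(rows)], column_map=self.column_map,
                            variables=self.variables)


def encode_design(
    table: StudyTable,
    scheme: str = "mixed",
    variables: Sequence[str] | None = None,
) -> DesignMatrix:
    """Encode predictors numerically.

    scheme:
      * ``"ordinal-score"`` — every variable becomes one integer-score column;
      * ``"indicator"`` — every variable becomes K-1 dummies (reference =
        first listed level);
      * ``"mixed"`` (default) — scores for binary/ordinal variables,
        indicators for nominal ones.
    """
    if scheme not in ("ordinal-score", "indicator", "mixed"):
        raise ValueError(f"unknown coding scheme {scheme!r}")
    if variables is None:
        variables = [s.name for s in table.specs if s.role == "predictor"]
    cols, cmap = [], []
    for name in variables:
        s = table.spec(name)
        codes = table.codes(name)
        use_indicator = scheme == "indicator" or (scheme == "mixed" and s.scale == "nominal")
        if use_indicator:
            for k in range(1, s.n_levels):
                cols.append((codes == k).astype(float))
                cmap.append((name, f"indicator:{s.levels[k]}"))
        else:
            cols.append(codes.astype(float))
            cmap.append((name, "score"))
    X = np.column_stack(cols) if cols else np.empty((table.n, 0))
    return DesignMatrix(X=X, column_map=cmap, variables=list(variables))
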