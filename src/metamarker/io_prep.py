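"""Reading, preprocessing and scaling of sample-by-metabolite abundance matrices.

The pipeline consumes a two-group matrix of LC-MS/MS peak areas: rows are
samples, columns are metabolites, plus one column holding the group label
(case vs control).  Preprocessing follows the standard targeted-metabolomics
recipe: metabolites with at most a small fraction of missing values have the
missing cells filled with the per-metabolite median of the observed values
(the median is robust to outliers), metabolites missing more often are
dropped, and abundances are log-transformed.  A per-metabolite min-max
scaler, fitted on control samples only, maps values into [0, 1] for the
neural stage, whose rectified output layer cannot produce negative values.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from math import log
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


@dataclass
class MetabolomicMatrix:
    """Samples x metabolites abundance matrix with group labels.

    ``values`` holds abundances as floats with NaN marking missing cells
    (allowed only before imputation).  ``group`` contains the normalized
    labels ``"case"`` / ``"control"``.
    """

    sample_ids: list[str]
    group: np.ndarray
    metabolite_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.group = np.asarray(self.group, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            dupes = sorted(
                {m for m in self.metabolite_ids if self.metabolite_ids.count(m) > 1}
            )
            raise ValueError(f"duplicate metabolite ids: {dupes}")
        if self.values.shape != (len(self.sample_ids), len(self.metabolite_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.metabolite_ids)} metabolites"
            )
        bad = set(self.group) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"group labels must be 'case'/'control', got {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def case_mask(self) -> np.ndarray:
        return self.group == CASE

    @property
    def control_mask(self) -> np.ndarray:
        return self.group == CONTROL

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def subset_samples(self, mask: np.ndarray) -> "MetabolomicMatrix":
        mask = np.asarray(mask)
        return MetabolomicMatrix(
            sample_ids=[s for s, keep in zip(self.sample_ids, mask) if keep],
            group=self.group[mask],
            metabolite_ids=list(self.metabolite_ids),
            values=self.values[mask],
        )

    def controls(self) -> "MetabolomicMatrix":
        return self.subset_samples(self.control_mask)

    def cases(self) -> "MetabolomicMatrix":
        return self.subset_samples(self.case_mask)

    def select_metabolites(self, ids: list[str]) -> "MetabolomicMatrix":
        idx = [self.metabolite_ids.index(i) for i in ids]
        return MetabolomicMatrix(
            sample_ids=list(self.sample_ids),
            group=self.group.copy(),
            metabolite_ids=list(ids),
            values=self.values[:, idx],
        )

    def column(self, metabolite_id: str) -> np.ndarray:
        return self.values[:, self.metabolite_ids.index(metabolite_id)]

    def to_dataframe(self, group_column: str = "group") -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample"),
            columns=self.metabolite_ids,
        )
        df.insert(0, group_column, self.group)
        return df


@dataclass
class PreprocessConfig:
    """Missing-value and transform settings.

    ``missing_fraction_max``: a metabolite is imputable only while its missing
    fraction does not exceed this proportion of samples (default 5%);
    above it the metabolite is dropped.
    """

    missing_fraction_max: float = 0.05
    log_transform: bool = True
    log_base: float = np.e

    def __post_init__(self) -> None:
        if not 0 <= self.missing_fraction_max < 1:
            raise ValueError("missing_fraction_max must be in [0, 1)")
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")


def _separator(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "tsv" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else "csv"
    if fmt not in {"tsv", "csv"}:
        raise ValueError(f"format must be 'tsv' or 'csv', got {fmt!r}")
    return "\t" if fmt == "tsv" else ","


def read_matrix(
    path: str | Path,
    group_column: str = "group",
    case_label: str | None = None,
    fmt: str | None = None,
    transpose: bool = False,
) -> MetabolomicMatrix:
    """Read a TSV/CSV abundance matrix with a per-sample group column.

    The first column holds sample ids, one designated column holds the group
    label (exactly two distinct labels), remaining columns are metabolites.
    Empty cells and ``NA`` mark missing values.  ``case_label`` names the
    label to treat as the case group; it may be omitted when the labels are
    literally ``case`` / ``control``.  With ``transpose`` the file stores
    metabolites as rows and samples as columns (the group label is then a row).
    """
    path = Path(path)
    sep = _separator(path, fmt)
    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    dupes = sorted({h for h in header[1:] if header[1:].count(h) > 1})
    if dupes:
        raise ValueError(f"duplicate column names in {path.name}: {dupes}")

    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=["NA"], encoding="utf-8",
        float_precision="round_trip",
    )
    if transpose:
        df = df.T
    if group_column not in df.columns:
        raise ValueError(f"group column {group_column!r} not found in {path.name}")
    labels = df[group_column].astype(str)
    distinct = sorted(labels.unique())
    if len(distinct) != 2:
        raise ValueError(
            f"group column {group_column!r} must contain exactly 2 labels, "
            f"found {distinct}"
        )
    if case_label is None:
        if set(distinct) == {CASE, CONTROL}:
            case_label = CASE
        else:
            raise ValueError(
                f"labels {distinct} are not 'case'/'control'; pass case_label"
            )
    elif case_label not in distinct:
        raise ValueError(f"case_label {case_label!r} not among labels {distinct}")

    value_df = df.drop(columns=[group_column])
    try:
        values = value_df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric abundance value in {path.name}: {exc}") from exc
    sample_ids = [str(s) for s in df.index]
    group = np.where(labels.to_numpy() == case_label, CASE, CONTROL).astype(object)
    return MetabolomicMatrix(
        sample_ids=sample_ids,
        group=group,
        metabolite_ids=[str(c) for c in value_df.columns],
        values=values,
    )


def write_matrix(
    m: MetabolomicMatrix,
    path: str | Path,
    group_column: str = "group",
    fmt: str | None = None,
) -> None:
    """Write the matrix in the dialect implied by the suffix (or ``fmt``)."""
    path = Path(path)
    sep = _separator(path, fmt)
    m.to_dataframe(group_column).to_csv(
        path, sep=sep, na_rep="NA", encoding="utf-8", float_format="%.17g"
    )


def impute_and_filter(
    m: MetabolomicMatrix, cfg: PreprocessConfig | None = None
) -> MetabolomicMatrix:
    """Median-impute sparsely missing metabolites; drop the rest.

    A metabolite whose missing fraction is at most ``cfg.missing_fraction_max``
    has each missing cell replaced by the median of its observed values.
    Metabolites above the threshold — including all-missing ones — are
    dropped and logged.  Observed cells are never altered.
    """
    cfg = cfg or PreprocessConfig()
    observed = ~np.isnan(m.values)
    if np.any(m.values[observed] < 0):
        raise ValueError("abundances must be nonnegative before imputation")
    keep: list[int] = []
    dropped: list[str] = []
    values = m.values.copy()
    n_imputed = 0
    for j, mid in enumerate(m.metabolite_ids):
        n_miss = int((~observed[:, j]).sum())
        if n_miss == 0:
            keep.append(j)
            continue
        if n_miss == m.n_samples:
            dropped.append(mid)
            logger.warning("metabolite %s has no observed values; dropped", mid)
            continue
        if n_miss / m.n_samples > cfg.missing_fraction_max:
            dropped.append(mid)
            continue
        med = float(np.median(values[observed[:, j], j]))
        values[~observed[:, j], j] = med
        n_imputed += n_miss
        keep.append(j)
    if dropped:
        logger.info(
            "dropped %d metabolites over the %.0f%% missingness threshold: %s",
            len(dropped), 100 * cfg.missing_fraction_max, ", ".join(dropped),
        )
    logger.info("imputed %d missing cells by per-metabolite medians", n_imputed)
    return MetabolomicMatrix(
        sample_ids=list(m.sample_ids),
        group=m.group.copy(),
        metabolite_ids=[m.metabolite_ids[j] for j in keep],
        values=values[:, keep],
    )


def log_transform(
    m: MetabolomicMatrix, cfg: PreprocessConfig | None = None
) -> MetabolomicMatrix:
    """Elementwise logarithm in ``cfg.log_base`` (natural log by default)."""
    cfg = cfg or PreprocessConfig()
    bad = np.argwhere(~(m.values > 0))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"nonpositive value {m.values[i, j]!r} for sample "
            f"{m.sample_ids[i]!r}, metabolite {m.metabolite_ids[j]!r}"
        )
    return replace(m, values=np.log(m.values) / log(cfg.log_base))


def preprocess(
    m: MetabolomicMatrix, cfg: PreprocessConfig | None = None
) -> MetabolomicMatrix:
    """Impute/filter then (optionally) log-transform."""
    cfg = cfg or PreprocessConfig()
    out = impute_and_filter(m, cfg)
    if cfg.log_transform:
        out = log_transform(out, cfg)
    return out


def preprocess_with_report(
    m: MetabolomicMatrix, cfg: PreprocessConfig | None = None
) -> tuple[MetabolomicMatrix, dict]:
    """Preprocess and return a JSON-serializable report of what was done."""
    cfg = cfg or PreprocessConfig()
    out = preprocess(m, cfg)
    kept = set(out.metabolite_ids)
    kept_cols = [j for j, mid in enumerate(m.metabolite_ids) if mid in kept]
    report = {
        "n_samples": m.n_samples,
        "n_metabolites_in": m.n_metabolites,
        "n_metabolites_kept": out.n_metabolites,
        "dropped_metabolites": [i for i in m.metabolite_ids if i not in kept],
        "imputed_cells": int(np.isnan(m.values[:, kept_cols]).sum()),
        "missing_fraction_max": cfg.missing_fraction_max,
        "log_transform": cfg.log_transform,
        "log_base": cfg.log_base,
    }
    return out, report


@dataclass
class ColumnScaler:
    """Per-metabolite affine map onto [0, 1] via min-max of the training values."""

    metabolite_ids: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    clipped_cells: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)


def fit_scaler(train: MetabolomicMatrix) -> ColumnScaler:
    """Fit min-max ranges on the given (training, typically control) samples.

    Constant metabolites (max == min) get a degenerate range and every value
    maps to 0.5.
    """
    if np.isnan(train.values).any():
        raise ValueError("scaler requires an imputed matrix (no missing values)")
    mins = train.values.min(axis=0)
    maxs = train.values.max(axis=0)
    n_const = int((maxs == mins).sum())
    if n_const:
        logger.warning("%d constant metabolites map to 0.5 under scaling", n_const)
    return ColumnScaler(list(train.metabolite_ids), mins, maxs)


def apply_scaler(scaler: ColumnScaler, m: MetabolomicMatrix) -> MetabolomicMatrix:
    """Map each metabolite onto [0, 1]; out-of-range values are clipped."""
    if m.metabolite_ids != scaler.metabolite_ids:
        raise ValueError("matrix metabolites do not match the scaler's")
    span = scaler.maxs - scaler.mins
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (m.values - scaler.mins) / span
    scaled[:, span == 0] = 0.5
    clipped = int(((scaled < 0) | (scaled > 1)).sum())
    if clipped:
        scaler.clipped_cells += clipped
        logger.info("clipped %d cells outside the training range", clipped)
    return replace(m, values=np.clip(scaled, 0.0, 1.0))


def invert_scaler(scaler: ColumnScaler, m: MetabolomicMatrix) -> MetabolomicMatrix:
    """Undo :func:`apply_scaler` (exact on the training range)."""
    if m.metabolite_ids != scaler.metabolite_ids:
        raise ValueError("matrix metabolites do not match the scaler's")
    span = scaler.maxs - scaler.mins
    values = m.values * span + scaler.mins
    values[:, span == 0] = scaler.mins[span == 0]
    return replace(m, values=values)
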