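"""Preprocessing chain for quantified urinary metabolite tables.

The chain is fixed and order-enforced:

    filter_missing -> impute_lod -> creatinine_normalize -> log_transform -> pareto_scale

* metabolites with a missing fraction strictly greater than the threshold
  (default 20%) are removed;
* remaining missing entries (below-LOD) are imputed with 1/5 of the
  metabolite's minimum positive observed value;
* concentrations are divided by the sample's urinary creatinine (µM / mM
  -> µmol/mmol creatinine) to correct for urine dilution;
* natural log transform;
* Pareto scaling: mean-centering and division by the square root of the
  sample (n-1) standard deviation, damping high-variance metabolites without
  the full unit-variance flattening of autoscaling.

``PreprocessPipeline`` freezes every data-dependent parameter (retained
metabolites, imputation minima, per-metabolite mean and sd) at fit time so
that cross-validation folds can transform held-out samples without leakage
(``apply_frozen``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class PreprocessError(ValueError):
    pass


class ChainOrderError(PreprocessError):
    """A preprocessing step was called out of chain order."""


STEP_ORDER = (
    "filter_missing",
    "impute_lod",
    "creatinine_normalize",
    "log_transform",
    "pareto_scale",
)


@dataclass
class MetaboliteTable:
    """Samples × metabolites concentration matrix (µM) with missingness as
    NaN, per-metabolite LOD (µM) and per-sample creatinine (mM)."""

    values: pd.DataFrame
    lod: pd.Series
    creatinine: pd.Series
    steps_applied: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.columns.is_unique or not self.values.index.is_unique:
            raise PreprocessError("sample and metabolite identifiers must be unique")
        if not self.lod.index.equals(self.values.columns):
            self.lod = self.lod.reindex(self.values.columns)
        if not self.creatinine.index.equals(self.values.index):
            self.creatinine = self.creatinine.reindex(self.values.index)
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise PreprocessError("concentrations must be nonnegative")
        cr = self.creatinine.to_numpy(dtype=float)
        if np.any(~np.isfinite(cr)) or np.any(cr <= 0):
            bad = self.creatinine.index[(~np.isfinite(cr)) | (cr <= 0)][0]
            raise PreprocessError(f"nonpositive or missing creatinine for sample {bad!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns

    def missing_fraction(self) -> pd.Series:
        return self.values.isna().mean(axis=0)

    def copy(self) -> "MetaboliteTable":
        return MetaboliteTable(
            self.values.copy(), self.lod.copy(), self.creatinine.copy(),
            list(self.steps_applied),
        )


@dataclass
class ProcessedMatrix:
    """The model-input space: the table after (part of) the chain, with the
    ordered step record and the Pareto scaling parameters when reached."""

    values: pd.DataFrame
    steps_applied: list[str]
    scaling_params: pd.DataFrame | None = None  # columns: mean, sd

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class FilterReport:
    removed: list[str]
    missing_fraction: pd.Series
    threshold: float


@dataclass
class FrozenParams:
    """Everything learned from the training table, reapplicable to new data."""

    metabolite_ids: list[str]
    impute_values: pd.Series          # min-positive / 5, per metabolite
    use_creatinine: bool
    pareto_mean: pd.Series
    pareto_sd: pd.Series


def _require_step(steps: Sequence[str], op: str) -> None:
    """Enforce the chain: ``op`` needs every earlier step done and itself
    not already applied (filter_missing alone is idempotent)."""
    pos = STEP_ORDER.index(op)
    if op in steps and op != "filter_missing":
        raise ChainOrderError(f"{op} already applied")
    missing = [s for s in STEP_ORDER[:pos] if s not in steps]
    # creatinine normalization may be skipped deliberately (--no-creatinine)
    if op in ("log_transform", "pareto_scale"):
        missing = [s for s in missing if s != "creatinine_normalize"]
    if missing:
        raise ChainOrderError(
            f"{op} called before required step(s): {', '.join(missing)}"
        )


# ---------------------------------------------------------------------------
# chain steps


def filter_missing(
    table: MetaboliteTable, max_missing_frac: float = 0.20
) -> tuple[MetaboliteTable, FilterReport]:
    """Drop metabolites whose missing fraction exceeds ``max_missing_frac``.

    Strict inequality: a metabolite missing exactly the threshold fraction is
    retained. Returns the filtered table and a removal report.
    """
    if not 0.0 <= max_missing_frac < 1.0:
        raise PreprocessError("max_missing_frac must be in [0, 1)")
    if table.values.shape[0] == 0 or table.values.shape[1] == 0:
        raise PreprocessError("empty table")
    frac = table.missing_fraction()
    keep = frac.index[frac <= max_missing_frac]
    removed = [m for m in table.metabolite_ids if m not in set(keep)]
    if len(keep) == 0:
        raise PreprocessError(
            "all metabolites exceed the missingness threshold; "
            "review max_missing_frac"
        )
    out = MetaboliteTable(
        table.values[keep].copy(),
        table.lod.loc[keep].copy(),
        table.creatinine.copy(),
        steps_applied=list(dict.fromkeys(table.steps_applied + ["filter_missing"])),
    )
    return out, FilterReport(removed, frac, max_missing_frac)


def impute_minima(table: MetaboliteTable) -> pd.Series:
    """Per-metabolite imputation value: minimum positive observed value / 5."""
    vals = table.values.where(table.values > 0)
    mins = vals.min(axis=0)
    if mins.isna().any():
        bad = mins.index[mins.isna()][0]
        raise PreprocessError(
            f"metabolite {bad!r} has no positive observation; cannot impute"
        )
    return mins / 5.0


def impute_lod(table: MetaboliteTable) -> MetaboliteTable:
    """Replace each missing (below-LOD) entry with 1/5 of the metabolite's
    minimum positive observed value; observed entries are untouched."""
    _require_step(table.steps_applied, "impute_lod")
    fill = impute_minima(table)
    values = table.values.fillna(fill)
    return MetaboliteTable(
        values, table.lod.copy(), table.creatinine.copy(),
        steps_applied=table.steps_applied + ["impute_lod"],
    )


def creatinine_normalize(table: MetaboliteTable) -> MetaboliteTable:
    """Divide each sample's concentrations (µM) by its urinary creatinine
    (mM); the result is in µmol/mmol creatinine."""
    _require_step(table.steps_applied, "creatinine_normalize")
    if table.values.isna().any().any():
        raise PreprocessError("missing values remain; impute before normalizing")
    values = table.values.div(table.creatinine, axis=0)
    return MetaboliteTable(
        values, table.lod.copy(), table.creatinine.copy(),
        steps_applied=table.steps_applied + ["creatinine_normalize"],
    )


def _as_processed(x) -> ProcessedMatrix:
    if isinstance(x, ProcessedMatrix):
        return x
    if isinstance(x, MetaboliteTable):
        return ProcessedMatrix(x.values.copy(), list(x.steps_applied))
    raise TypeError(f"expected MetaboliteTable or ProcessedMatrix, got {type(x)!r}")


def log_transform(x) -> ProcessedMatrix:
    """Elementwise natural log; errors with coordinates on nonpositive input."""
    pm = _as_processed(x)
    _require_step(pm.steps_applied, "log_transform")
    arr = pm.values.to_numpy(dtype=float)
    bad = np.argwhere(~(arr > 0))
    if bad.size:
        i, j = bad[0]
        raise PreprocessError(
            f"nonpositive value at sample {pm.values.index[i]!r}, "
            f"metabolite {pm.values.columns[j]!r}"
        )
    return ProcessedMatrix(
        pd.DataFrame(np.log(arr), index=pm.values.index, columns=pm.values.columns),
        pm.steps_applied + ["log_transform"],
    )


def pareto_scale(x) -> ProcessedMatrix:
    """Column-wise (x - mean) / sqrt(sd) with sample (n-1) sd.

    Constant columns map to all zeros. The (mean, sd) pairs are stored in
    ``scaling_params`` for frozen reapplication.
    """
    pm = _as_processed(x)
    _require_step(pm.steps_applied, "pareto_scale")
    if pm.values.shape[0] < 2:
        raise PreprocessError("pareto scaling needs at least 2 samples")
    mean = pm.values.mean(axis=0)
    sd = pm.values.std(axis=0, ddof=1)
    scaled = _pareto_apply(pm.values, mean, sd)
    return ProcessedMatrix(
        scaled,
        pm.steps_applied + ["pareto_scale"],
        scaling_params=pd.DataFrame({"mean": mean, "sd": sd}),
    )


def _pareto_apply(values: pd.DataFrame, mean: pd.Series, sd: pd.Series) -> pd.DataFrame:
    denom = np.sqrt(sd.to_numpy(dtype=float))
    centered = values.to_numpy(dtype=float) - mean.to_numpy(dtype=float)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom[None, :] > 0, centered / denom[None, :], 0.0)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# fit / frozen-transform pipeline


class PreprocessPipeline:
    """Fit the full chain on a training table; reapply frozen parameters to
    new data (the no-leakage contract used inside every CV fold)."""

    def __init__(self, max_missing_frac: float = 0.20, use_creatinine: bool = True):
        self.max_missing_frac = max_missing_frac
        self.use_creatinine = use_creatinine
        self.frozen_: FrozenParams | None = None
        self.filter_report_: FilterReport | None = None

    def fit_transform(self, table: MetaboliteTable) -> ProcessedMatrix:
        filtered, report = filter_missing(table, self.max_missing_frac)
        self.filter_report_ = report
        fill = impute_minima(filtered)
        imputed = impute_lod(filtered)
        normed = creatinine_normalize(imputed) if self.use_creatinine else imputed
        logged = log_transform(normed)
        scaled = pareto_scale(logged)
        assert scaled.scaling_params is not None
        self.frozen_ = FrozenParams(
            metabolite_ids=list(filtered.metabolite_ids),
            impute_values=fill,
            use_creatinine=self.use_creatinine,
            pareto_mean=scaled.scaling_params["mean"],
            pareto_sd=scaled.scaling_params["sd"],
        )
        return scaled

    def transform(self, table: MetaboliteTable) -> ProcessedMatrix:
        if self.frozen_ is None:
            raise PreprocessError("pipeline not fitted")
        return apply_frozen(self.frozen_, table)


def apply_frozen(params: FrozenParams | ProcessedMatrix, table: MetaboliteTable,
                 pipeline: PreprocessPipeline | None = None) -> ProcessedMatrix:
    """Transform ``table`` with parameters learned elsewhere: the training
    metabolite subset, training imputation minima, creatinine division, log,
    and the training (mean, sd) Pareto parameters."""
    if isinstance(params, ProcessedMatrix):
        raise PreprocessError(
            "pass the FrozenParams of a fitted PreprocessPipeline"
        )
    missing = [m for m in params.metabolite_ids if m not in table.metabolite_ids]
    if missing:
        raise PreprocessError(
            f"new table lacks fitted metabolites: {missing[:5]}"
        )
    values = table.values[params.metabolite_ids].copy()
    values = values.fillna(params.impute_values)
    if params.use_creatinine:
        values = values.div(table.creatinine, axis=0)
    arr = values.to_numpy(dtype=float)
    if not np.all(arr > 0):
        raise PreprocessError("nonpositive value after frozen imputation")
    logged = pd.DataFrame(np.log(arr), index=values.index, columns=values.columns)
    scaled = _pareto_apply(logged, params.pareto_mean, params.pareto_sd)
    steps = ["filter_missing", "impute_lod"]
    if params.use_creatinine:
        steps.append("creatinine_normalize")
    steps += ["log_transform", "pareto_scale"]
    return ProcessedMatrix(
        scaled, steps,
        scaling_params=pd.DataFrame(
            {"mean": params.pareto_mean, "sd": params.pareto_sd}
        ),
    )
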