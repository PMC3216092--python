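"""Data model, tabular readers/writers and configuration.

The pipeline's tabular convention is plain TSV: the first column holds gene
or factor identifiers, the header row holds time points in minutes, and
``NA`` / empty cells mark missing values.  Relative expression values are
strictly positive wherever present (the model is multiplicative and is fit
in log space), and binding coefficients are strictly positive with a
configurable floor so that ``log b`` is always defined.
"""

from __future__ import annotations

import dataclasses
import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tfa_cycle")

MISSING = "NA"


class DataValidationError(ValueError):
    """Raised when an input table or configuration fails validation."""


# ---------------------------------------------------------------------------
# Time grid


@dataclass(frozen=True)
class TimeGrid:
    """Sampling grid of a time course, in minutes.

    ``period_samples`` is the integer lag (in samples) corresponding to one
    full cycle: ``round(period_minutes / sampling_interval)`` where the
    sampling interval is the median of successive time differences.  For a
    36-point grid spanning 3973-4837 min with a 300-min cycle this is 12,
    and the grid spans three full cycles.
    """

    times: tuple[float, ...]
    period_minutes: float = 300.0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        object.__setattr__(self, "times", times)
        arr = np.asarray(times, dtype=float)
        if arr.size < 2:
            raise DataValidationError("TimeGrid needs at least 2 time points")
        if not np.all(np.diff(arr) > 0):
            raise DataValidationError("TimeGrid times must be strictly increasing")
        if self.period_minutes <= 0:
            raise DataValidationError("period_minutes must be positive")
        if self.period_samples < 2:
            raise DataValidationError(
                f"period_samples = {self.period_samples} < 2; grid too coarse "
                "for the requested period"
            )

    @property
    def n_timepoints(self) -> int:
        return len(self.times)

    @property
    def sampling_interval(self) -> float:
        return float(np.median(np.diff(np.asarray(self.times))))

    @property
    def period_samples(self) -> int:
        ratio = self.period_minutes / self.sampling_interval
        lag = int(round(ratio))
        if abs(ratio - lag) > 1e-6:
            warnings.warn(
                f"period_minutes / sampling_interval = {ratio:.4f} is not an "
                f"integer; rounding lag to {lag}",
                stacklevel=2,
            )
        return lag

    @property
    def times_array(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)


# ---------------------------------------------------------------------------
# Matrices


def _check_unique(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if list(ids).count(i) > 1})
        raise DataValidationError(f"duplicate {what} ids: {dupes[:5]}")
    return ids


@dataclass
class ExpressionMatrix:
    """Genes x time points of relative expression R_i(t).

    Present values are strictly positive; missing values are stored as NaN
    and retained (they are excluded gene-wise per time point inside the
    regression, never dropped row-wise up front).
    """

    gene_ids: tuple[str, ...]
    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), self.grid.n_timepoints):
            raise DataValidationError(
                f"expression shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {self.grid.n_timepoints} times"
            )
        present = self.values[~np.isnan(self.values)]
        if present.size and present.min() <= 0:
            raise DataValidationError("expression values must be positive or missing")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def log_values(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.log(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.grid.times))


@dataclass
class BindingMatrix:
    """Genes x TFs of promoter-binding coefficients b_ij > 0.

    Non-targets sit at the neutral baseline 1 so that log b = 0 and the
    pair contributes nothing to the log-linear model.
    """

    gene_ids: tuple[str, ...]
    tf_ids: tuple[str, ...]
    values: np.ndarray
    floor: float = 1e-4

    def __post_init__(self) -> None:
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        self.tf_ids = _check_unique(self.tf_ids, "TF")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.tf_ids)):
            raise DataValidationError("binding shape inconsistent with ids")
        if self.floor <= 0:
            raise DataValidationError("binding floor must be > 0")
        if np.isnan(self.values).any():
            raise DataValidationError("binding matrix may not contain NaN")
        if self.values.min() < self.floor:
            raise DataValidationError("binding values below floor")

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    def log_values(self) -> np.ndarray:
        return np.log(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.tf_ids))


@dataclass
class ActivityEstimate:
    """Per-time-point regression result: one alpha per TF plus diagnostics."""

    time_index: int
    alpha: np.ndarray
    intercept: float
    se: np.ndarray
    pvalue: np.ndarray
    sigma_ols: float
    sigma_robust: float
    sigma_final: float
    n_genes_used: int
    converged: bool = True
    mean_residual: float = float("nan")
    mean_studentized_residual: float = float("nan")

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.pvalue = np.asarray(self.pvalue, dtype=float)
        ok = ~np.isnan(self.se)
        if np.any(self.se[ok] < 0):
            raise DataValidationError("standard errors must be non-negative")
        okp = ~np.isnan(self.pvalue)
        if np.any((self.pvalue[okp] < 0) | (self.pvalue[okp] > 1)):
            raise DataValidationError("p-values must lie in [0, 1]")


@dataclass
class ActivityMatrix:
    """TFs x time points of activity coefficients with SEs and p-values.

    May carry one designated non-TF row (the normalized dissolved-oxygen
    trace, treated as an extra factor in the dynamical model); that row has
    no standard errors or p-values (flagged missing).
    """

    tf_ids: tuple[str, ...]
    grid: TimeGrid
    alpha: np.ndarray
    se: np.ndarray | None = None
    pvalue: np.ndarray | None = None
    non_tf_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.tf_ids = _check_unique(self.tf_ids, "factor")
        self.alpha = np.asarray(self.alpha, dtype=float)
        shape = (len(self.tf_ids), self.grid.n_timepoints)
        if self.alpha.shape != shape:
            raise DataValidationError(
                f"alpha shape {self.alpha.shape} != {shape}")
        for name in ("se", "pvalue"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != shape:
                    raise DataValidationError(f"{name} shape {arr.shape} != {shape}")
                setattr(self, name, arr)
        unknown = set(self.non_tf_ids) - set(self.tf_ids)
        if unknown:
            raise DataValidationError(f"non-TF ids not present: {sorted(unknown)}")
        for oid in self.non_tf_ids:
            i = self.tf_ids.index(oid)
            for arr in (self.se, self.pvalue):
                if arr is not None and not np.all(np.isnan(arr[i])):
                    raise DataValidationError(
                        f"designated non-TF row {oid!r} must have missing se/p-values")

    @property
    def n_factors(self) -> int:
        return len(self.tf_ids)

    def row(self, tf_id: str) -> np.ndarray:
        return self.alpha[self.tf_ids.index(tf_id)]

    def subset(self, keep_ids: Sequence[str]) -> "ActivityMatrix":
        keep = [str(k) for k in keep_ids]
        idx = [self.tf_ids.index(k) for k in keep]
        return ActivityMatrix(
            tf_ids=tuple(keep), grid=self.grid, alpha=self.alpha[idx],
            se=None if self.se is None else self.se[idx],
            pvalue=None if self.pvalue is None else self.pvalue[idx],
            non_tf_ids=tuple(i for i in self.non_tf_ids if i in keep),
        )

    def with_extra_row(self, row_id: str, values: np.ndarray,
                       non_tf: bool = True) -> "ActivityMatrix":
        values = np.asarray(values, dtype=float)
        if values.shape != (self.grid.n_timepoints,):
            raise DataValidationError("extra row length mismatch")
        nan_row = np.full((1, self.grid.n_timepoints), np.nan)
        return ActivityMatrix(
            tf_ids=self.tf_ids + (str(row_id),),
            grid=self.grid,
            alpha=np.vstack([self.alpha, values[None, :]]),
            se=None if self.se is None else np.vstack([self.se, nan_row]),
            pvalue=None if self.pvalue is None else np.vstack([self.pvalue, nan_row]),
            non_tf_ids=self.non_tf_ids + ((str(row_id),) if non_tf else ()),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.alpha, index=list(self.tf_ids),
                            columns=list(self.grid.times))


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """Tunable thresholds of the analysis funnel.

    Defaults follow the study procedure: per-time-point significance at
    p < 0.1 on at least 9 of the time points, periodicity threshold 0.44 at
    the one-cycle lag, 1000 permutations, 300-min period and a network
    threshold of 0.5 on time-translation matrix entries.
    """

    p_threshold: float = 0.1
    min_significant_timepoints: int = 9
    periodicity_threshold: float = 0.44
    n_permutations: int = 1000
    rng_seed: int = 0
    period_minutes: float = 300.0
    network_threshold: float = 0.5
    phase_grid_step_degrees: float = 1.0
    binding_floor: float = 1e-4
    center_autocorrelation: bool = False
    n_clusters: int = 2
    sigma_weight: float = 0.5
    include_oxygen: bool = True

    def __post_init__(self) -> None:
        for name in ("p_threshold", "periodicity_threshold", "period_minutes",
                     "network_threshold", "phase_grid_step_degrees",
                     "binding_floor"):
            if getattr(self, name) <= 0:
                raise DataValidationError(f"config {name} must be positive")
        if self.min_significant_timepoints < 1:
            raise DataValidationError("min_significant_timepoints must be >= 1")
        if self.n_permutations < 1:
            raise DataValidationError("n_permutations must be >= 1")
        if not 0.0 <= self.sigma_weight <= 1.0:
            raise DataValidationError("sigma_weight must lie in [0, 1]")
        if self.n_clusters < 1:
            raise DataValidationError("n_clusters must be >= 1")


def read_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config, filling defaults; unknown keys are rejected."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise DataValidationError("config file must hold a YAML mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise DataValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def write_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


# ---------------------------------------------------------------------------
# Readers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING, ""],
                     keep_default_na=True)
    return df


def read_expression(path: str | Path, period_minutes: float = 300.0
                    ) -> ExpressionMatrix:
    """Read a genes x times TSV of relative expression.

    The header row holds time points in minutes.  Cells that are empty,
    ``NA`` or <= 0 are marked missing (the log transform downstream is
    undefined for them); rows with missing values are retained.
    """
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise DataValidationError("expression file needs at least 2 time points")
    try:
        times = [float(c) for c in df.columns]
    except ValueError as exc:
        raise DataValidationError(f"non-numeric time header: {exc}") from exc
    values = df.to_numpy(dtype=float)
    values[values <= 0] = np.nan
    grid = TimeGrid(times=tuple(times), period_minutes=period_minutes)
    return ExpressionMatrix(gene_ids=tuple(df.index.astype(str)), grid=grid,
                            values=values)


def read_binding(path: str | Path, transform: str = "identity",
                 floor: float = 1e-4) -> BindingMatrix:
    """Read a genes x TFs TSV of binding coefficients.

    ``transform='identity'`` takes the stored numbers as coefficients b_ij
    directly (negative values are an error); ``'pvalue_to_strength'``
    converts binding p-values to strengths via b = 1 / clip(p, floor, 1),
    so weak/absent binding (p near 1) maps to the neutral baseline 1.
    Missing cells are set to baseline 1; all values are clipped below at
    ``floor``.
    """
    df = _read_tsv(path)
    values = df.to_numpy(dtype=float)
    if transform == "identity":
        if np.nanmin(values) < 0:
            raise DataValidationError("negative binding values under identity transform")
    elif transform == "pvalue_to_strength":
        with np.errstate(invalid="ignore"):
            values = 1.0 / np.clip(values, floor, 1.0)
    else:
        raise DataValidationError(f"unknown binding transform {transform!r}")
    values = np.where(np.isnan(values), 1.0, values)
    values = np.maximum(values, floor)
    return BindingMatrix(gene_ids=tuple(df.index.astype(str)),
                         tf_ids=tuple(df.columns.astype(str)),
                         values=values, floor=floor)


def read_oxygen(path: str | Path, grid: TimeGrid) -> np.ndarray:
    """Read a two-column (time, value) TSV and interpolate onto ``grid``.

    The trace's own sampling need not match the expression grid; linear
    interpolation aligns it.  Values outside the trace's span are held at
    the boundary values.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    # tolerate a header line
    try:
        float(raw.iloc[0, 0])
    except (TypeError, ValueError):
        raw = raw.iloc[1:]
    t = raw.iloc[:, 0].astype(float).to_numpy()
    v = raw.iloc[:, 1].astype(float).to_numpy()
    if t.size < 2:
        raise DataValidationError("oxygen trace needs at least 2 samples")
    if not np.all(np.diff(t) > 0):
        raise DataValidationError("oxygen trace times must be strictly increasing")
    return np.interp(grid.times_array, t, v)


# ---------------------------------------------------------------------------
# Writers (lossless TSV round trip)


def _format_frame(df: pd.DataFrame) -> str:
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", na_rep=MISSING, float_format="%.17g")
    return buf.getvalue()


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    Path(path).write_text(_format_frame(expr.to_frame()))


def write_binding(binding: BindingMatrix, path: str | Path) -> None:
    Path(path).write_text(_format_frame(binding.to_frame()))


def write_oxygen(times: np.ndarray, values: np.ndarray, path: str | Path) -> None:
    df = pd.DataFrame({"time": times, "oxygen": values})
    Path(path).write_text(df.to_csv(sep="\t", index=False, header=False,
                                    float_format="%.17g"))


def write_activity(activity: ActivityMatrix, path_prefix: str | Path,
                   what: tuple[str, ...] = ("alpha", "se", "pvalue")) -> list[Path]:
    """Write `<prefix>.tsv` (alpha) plus optional `<prefix>_se/_pvalues.tsv`."""
    prefix = Path(path_prefix)
    written: list[Path] = []
    mapping = {"alpha": ("", activity.alpha),
               "se": ("_se", activity.se),
               "pvalue": ("_pvalues", activity.pvalue)}
    for key in what:
        suffix, arr = mapping[key]
        if arr is None:
            continue
        df = pd.DataFrame(arr, index=list(activity.tf_ids),
                          columns=list(activity.grid.times))
        out = prefix.parent / (prefix.name + suffix + ".tsv")
        out.write_text(_format_frame(df))
        written.append(out)
    return written


def read_activity(path: str | Path, period_minutes: float = 300.0,
                  se_path: str | Path | None = None,
                  pvalue_path: str | Path | None = None,
                  non_tf_ids: Sequence[str] = ()) -> ActivityMatrix:
    df = _read_tsv(path)
    times = tuple(float(c) for c in df.columns)
    grid = TimeGrid(times=times, period_minutes=period_minutes)
    se = _read_tsv(se_path).to_numpy(dtype=float) if se_path else None
    pv = _read_tsv(pvalue_path).to_numpy(dtype=float) if pvalue_path else None
    return ActivityMatrix(tf_ids=tuple(df.index.astype(str)), grid=grid,
                          alpha=df.to_numpy(dtype=float), se=se, pvalue=pv,
                          non_tf_ids=tuple(str(i) for i in non_tf_ids))


def write_matrix(values: np.ndarray, row_ids: Sequence[str],
                 col_ids: Sequence[str], path: str | Path) -> None:
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=list(row_ids), columns=list(col_ids))
    Path(path).write_text(_format_frame(df))


def read_matrix(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


def setup_logging(level: int = logging.INFO) -> None:
    """Timestamped log lines to stderr (idempotent)."""
    root = logging.getLogger("tfa_cycle")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
    root.setLevel(level)
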