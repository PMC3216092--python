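"""Per-time-point TF activity estimation by robust log-linear regression.

The generative model is multiplicative: the relative expression of gene i
is R_i = c * prod_j b_ij^alpha_j, where b_ij measures how strongly TF j
binds gene i's promoter and alpha_j is TF j's activity.  Taking logs,

    log R_i = c' + sum_j alpha_j * log b_ij

which is an ordinary multiple linear regression of the per-time-point
log-expression vector on the log-binding matrix.  The fit is made robust
with iteratively reweighted least squares (IRLS) using Tukey bisquare
weights (tuning constant 4.685, the 95%-Gaussian-efficiency default) so
that a minority of badly-modelled genes does not dominate the alphas.

The residual scale combines an ordinary-least-squares estimate with a
median-absolute-deviation estimate: sigma_robust = MAD/0.6745 of the
residuals about their median, and the final scale is
max(sigma_robust, w*sigma_OLS + (1-w)*sigma_robust) with w = 0.5 by
default.  Standard errors come from sigma_final^2 * (X'WX)^-1 and
p-values from a two-sided t test with df = n_genes_used - n_TFs - 1.

TFs are then iteratively reduced: a TF is retained only if its activity
is significant (p below a threshold) at a minimum number of time points;
all failures are dropped simultaneously and the survivors refit, until a
fixed point is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    ActivityEstimate,
    ActivityMatrix,
    BindingMatrix,
    DataValidationError,
    ExpressionMatrix,
    PipelineConfig,
)

logger = logging.getLogger("tfa_cycle.activity")

BISQUARE_TUNING = 4.685


@dataclass
class RobustFitOptions:
    """Knobs of the IRLS fit; the intercept is always included."""

    tuning_constant: float = BISQUARE_TUNING
    max_iterations: int = 300
    convergence_tol: float = 1e-7
    sigma_weight: float = 0.5  # weight on sigma_OLS in the final-scale blend
    leverage_adjust: bool = False

    def __post_init__(self) -> None:
        if self.tuning_constant <= 0:
            raise DataValidationError("tuning_constant must be > 0")


@dataclass
class SelectionResult:
    """Outcome of iterative significance-based TF elimination."""

    retained_tf_ids: tuple[str, ...]
    n_iterations: int
    history: list[tuple[tuple[str, ...], dict[str, int]]]
    activity: ActivityMatrix
    diagnostics: pd.DataFrame | None = None


def mad_sigma(residuals: np.ndarray) -> float:
    """Robust residual scale: MAD about the median, scaled by 1/0.6745."""
    r = np.asarray(residuals, dtype=float)
    return float(np.median(np.abs(r - np.median(r))) / 0.6745)


def _bisquare_weights(u: np.ndarray) -> np.ndarray:
    w = np.zeros_like(u)
    inside = np.abs(u) < 1
    w[inside] = (1 - u[inside] ** 2) ** 2
    return w


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray | None) -> np.ndarray:
    if w is None:
        return np.linalg.lstsq(X, y, rcond=None)[0]
    sw = np.sqrt(w)
    return np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)[0]


def robust_linear_fit(X: np.ndarray, y: np.ndarray,
                      options: RobustFitOptions | None = None) -> dict:
    """Bisquare IRLS fit of y on X (an intercept column is appended).

    Returns a dict with coefficients (intercept last), standard errors,
    two-sided t p-values, the three residual-scale estimates, final
    weights, and convergence information.  On effectively noiseless data
    the robust fit coincides with ordinary least squares (all weights 1).
    """
    options = options or RobustFitOptions()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xd = np.hstack([X, np.ones((n, 1))])
    k = p + 1
    if n <= k:
        raise DataValidationError(
            f"underdetermined system: {n} observations for {k} parameters")

    beta = _wls(Xd, y, None)
    resid = y - Xd @ beta
    dof = n - k
    sigma_ols = float(np.sqrt(resid @ resid / dof))

    # residual magnitude at which IRLS is pointless (noiseless data)
    tiny = 1e-10 * max(1.0, float(np.abs(y).max()))

    h = None
    if options.leverage_adjust:
        Q, _ = np.linalg.qr(Xd)
        h = np.clip((Q ** 2).sum(axis=1), 0, 1 - 1e-12)

    weights = np.ones(n)
    converged = True
    n_iter = 0
    if mad_sigma(resid) > tiny:
        converged = False
        for n_iter in range(1, options.max_iterations + 1):
            radj = resid / np.sqrt(1 - h) if h is not None else resid
            s = mad_sigma(radj)
            if s <= tiny:
                converged = True
                break
            weights = _bisquare_weights(radj / (options.tuning_constant * s))
            if weights.sum() <= k:  # all points rejected; fall back
                weights = np.ones(n)
            new_beta = _wls(Xd, y, weights)
            delta = np.max(np.abs(new_beta - beta))
            scale = max(np.max(np.abs(new_beta)), 1.0)
            beta = new_beta
            resid = y - Xd @ beta
            if delta <= options.convergence_tol * scale:
                converged = True
                break

    sigma_robust = mad_sigma(resid)
    w = options.sigma_weight
    sigma_final = max(sigma_robust, w * sigma_ols + (1 - w) * sigma_robust)

    XtWX = Xd.T @ (Xd * weights[:, None])
    cov = sigma_final ** 2 * np.linalg.pinv(XtWX)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvalue = 2 * stats.t.sf(np.abs(tstat), dof)
    pvalue = np.where(se > 0, pvalue, 0.0)
    # an exactly-zero coefficient with zero SE is indistinguishable from noise
    pvalue = np.where((se == 0) & (beta == 0), 1.0, pvalue)

    stud = resid / sigma_final if sigma_final > 0 else np.zeros_like(resid)
    return {
        "coef": beta[:p],
        "intercept": float(beta[p]),
        "se": se[:p],
        "pvalue": pvalue[:p],
        "sigma_ols": sigma_ols,
        "sigma_robust": sigma_robust,
        "sigma_final": float(sigma_final),
        "weights": weights,
        "n_iterations": n_iter,
        "converged": converged,
        "mean_residual": float(resid.mean()),
        "mean_studentized_residual": float(stud.mean()),
        "df": dof,
    }


def estimate_activities_at_timepoint(
        log_expr_col: np.ndarray, log_binding: np.ndarray,
        options: RobustFitOptions | None = None,
        time_index: int = 0) -> ActivityEstimate:
    """Fit one time point's alphas; genes missing at this time are excluded."""
    log_expr_col = np.asarray(log_expr_col, dtype=float)
    log_binding = np.asarray(log_binding, dtype=float)
    usable = ~np.isnan(log_expr_col)
    n_tfs = log_binding.shape[1]
    if usable.sum() <= n_tfs + 1:
        raise DataValidationError(
            f"time point {time_index}: only {int(usable.sum())} usable genes "
            f"for {n_tfs} TFs")
    fit = robust_linear_fit(log_binding[usable], log_expr_col[usable], options)
    if not fit["converged"]:
        logger.warning("time point %d: IRLS did not converge in %d iterations",
                       time_index, fit["n_iterations"])
    return ActivityEstimate(
        time_index=time_index, alpha=fit["coef"], intercept=fit["intercept"],
        se=fit["se"], pvalue=fit["pvalue"], sigma_ols=fit["sigma_ols"],
        sigma_robust=fit["sigma_robust"], sigma_final=fit["sigma_final"],
        n_genes_used=int(usable.sum()), converged=fit["converged"],
        mean_residual=fit["mean_residual"],
        mean_studentized_residual=fit["mean_studentized_residual"],
    )


def _align(expr: ExpressionMatrix, binding: BindingMatrix
           ) -> tuple[np.ndarray, np.ndarray]:
    """Intersect the gene universes by id; order follows the binding ids."""
    expr_index = {g: i for i, g in enumerate(expr.gene_ids)}
    shared = [g for g in binding.gene_ids if g in expr_index]
    if len(shared) == 0:
        raise DataValidationError("no shared genes between expression and binding")
    e_rows = [expr_index[g] for g in shared]
    b_rows = [binding.gene_ids.index(g) for g in shared] \
        if shared != list(binding.gene_ids) else slice(None)
    log_expr = expr.log_values()[e_rows]
    log_bind = binding.log_values()[b_rows]
    return log_expr, log_bind


def estimate_activity_timecourse(
        expr: ExpressionMatrix, binding: BindingMatrix,
        options: RobustFitOptions | None = None
        ) -> tuple[ActivityMatrix, pd.DataFrame]:
    """Fit every time point and assemble the TF x time activity matrix.

    Returns the ActivityMatrix plus a per-time-point diagnostics table
    (sigma_OLS, sigma_robust, sigma_final, mean residual, mean studentized
    residual, genes used).  A time point with too few usable genes yields a
    flagged all-missing column rather than aborting the whole time course.
    """
    log_expr, log_bind = _align(expr, binding)
    n_tfs = binding.n_tfs
    n_t = expr.grid.n_timepoints
    alpha = np.full((n_tfs, n_t), np.nan)
    se = np.full((n_tfs, n_t), np.nan)
    pvalue = np.full((n_tfs, n_t), np.nan)
    rows = []
    for t in range(n_t):
        try:
            est = estimate_activities_at_timepoint(
                log_expr[:, t], log_bind, options, time_index=t)
        except DataValidationError as exc:
            logger.warning("skipping %s", exc)
            rows.append({"time": expr.grid.times[t], "sigma_ols": np.nan,
                         "sigma_robust": np.nan, "sigma_final": np.nan,
                         "mean_residual": np.nan,
                         "mean_studentized_residual": np.nan,
                         "n_genes_used": 0, "intercept": np.nan})
            continue
        alpha[:, t] = est.alpha
        se[:, t] = est.se
        pvalue[:, t] = est.pvalue
        rows.append({"time": expr.grid.times[t], "sigma_ols": est.sigma_ols,
                     "sigma_robust": est.sigma_robust,
                     "sigma_final": est.sigma_final,
                     "mean_residual": est.mean_residual,
                     "mean_studentized_residual": est.mean_studentized_residual,
                     "n_genes_used": est.n_genes_used,
                     "intercept": est.intercept})
    activity = ActivityMatrix(tf_ids=binding.tf_ids, grid=expr.grid,
                              alpha=alpha, se=se, pvalue=pvalue)
    return activity, pd.DataFrame(rows)


def significant_timepoint_counts(activity: ActivityMatrix,
                                 p_threshold: float) -> dict[str, int]:
    if activity.pvalue is None:
        raise DataValidationError("activity matrix has no p-values")
    counts = np.nansum(activity.pvalue < p_threshold, axis=1)
    return {tf: int(c) for tf, c in zip(activity.tf_ids, counts)}


def iterative_tf_selection(expr: ExpressionMatrix, binding: BindingMatrix,
                           config: PipelineConfig | None = None,
                           options: RobustFitOptions | None = None
                           ) -> SelectionResult:
    """Iteratively drop TFs with too few significant time points and refit.

    At each round every TF failing the criterion (at least
    ``min_significant_timepoints`` time points with p below ``p_threshold``)
    is dropped simultaneously, the survivors' alphas are recomputed, and
    the process repeats until no TF can be eliminated.  Retained sets are
    nested across iterations; a TF never re-enters.
    """
    config = config or PipelineConfig()
    if options is None:
        options = RobustFitOptions(sigma_weight=config.sigma_weight)
    if config.min_significant_timepoints > expr.grid.n_timepoints:
        raise DataValidationError(
            "min_significant_timepoints exceeds the number of time points; "
            "no TF can ever be retained")

    current = binding
    history: list[tuple[tuple[str, ...], dict[str, int]]] = []
    activity, diagnostics = estimate_activity_timecourse(expr, current, options)
    n_iterations = 0
    while True:
        n_iterations += 1
        counts = significant_timepoint_counts(activity, config.p_threshold)
        history.append((current.tf_ids, counts))
        keep = [tf for tf in current.tf_ids
                if counts[tf] >= config.min_significant_timepoints]
        logger.info("selection iteration %d: %d -> %d TFs",
                    n_iterations, current.n_tfs, len(keep))
        if len(keep) == 0:
            raise DataValidationError(
                "iterative selection eliminated every TF")
        if len(keep) == current.n_tfs:
            break
        cols = [current.tf_ids.index(tf) for tf in keep]
        current = BindingMatrix(gene_ids=current.gene_ids,
                                tf_ids=tuple(keep),
                                values=current.values[:, cols],
                                floor=current.floor)
        activity, diagnostics = estimate_activity_timecourse(expr, current, options)
    return SelectionResult(retained_tf_ids=current.tf_ids,
                           n_iterations=n_iterations, history=history,
                           activity=activity, diagnostics=diagnostics)


def selection_history_frame(result: SelectionResult) -> pd.DataFrame:
    rows = []
    for it, (ids, counts) in enumerate(result.history, start=1):
        for tf in ids:
            rows.append({"iteration": it, "tf_id": tf,
                         "n_significant_timepoints": counts[tf]})
    return pd.DataFrame(rows)
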