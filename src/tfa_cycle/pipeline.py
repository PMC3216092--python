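"""End-to-end orchestration of the analysis funnel.

Stage order follows the method: per-time-point activity regression on the
full TF set, iterative significance-based TF selection, periodicity
scoring and filtering, sine fits / peak phases / cycle-phase labels,
clustering on absolute activities, time-translation matrix estimation
(with the normalized oxygen trace as an extra factor), and network
extraction.  All intermediate tables are written under the run directory
together with a JSON manifest (config echo, seed, per-stage output file
hashes, package version, timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activity_inference import (
    RobustFitOptions,
    estimate_activity_timecourse,
    iterative_tf_selection,
    selection_history_frame,
)
from .clustering import cluster_profiles
from .core_io import (
    ActivityMatrix,
    BindingMatrix,
    DataValidationError,
    ExpressionMatrix,
    PipelineConfig,
    write_activity,
    write_matrix,
)
from .dynamics import (
    asymptotic_modes,
    estimate_transition_nonneg,
    estimate_transition_unconstrained,
    export_network,
    extract_network,
    model_residuals,
    normalize_oxygen,
)
from .periodicity import filter_periodic, score_activity_matrix
from .phase_analysis import (
    classify_cycle_phases_from_oxygen,
    classify_phase,
    fit_sine,
    peak_phase,
)

logger = logging.getLogger("tfa_cycle.pipeline")

STAGES = ("activities", "select", "periodicity", "phases", "cluster",
          "dynamics", "network")

OXYGEN_ID = "OXYGEN"


class PipelineStageError(RuntimeError):
    """A stage failed; partial outputs up to that stage are preserved."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, expression: ExpressionMatrix,
                 binding: BindingMatrix, oxygen: np.ndarray | None,
                 out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute all stages in order; returns the run manifest.

    ``seed`` overrides ``config.rng_seed`` for every stochastic component
    (here: the periodicity permutations).  Identical config + seed +
    inputs give identical output hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed if seed is None else seed
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "seed": seed,
        "version": __version__,
        "started": datetime.now(timezone.utc).isoformat(),
        "stages": [],
    }
    summary: dict = {"n_tfs_input": binding.n_tfs}
    options = RobustFitOptions(sigma_weight=config.sigma_weight)

    def record(stage: str, outputs: list[Path]) -> None:
        manifest["stages"].append({
            "stage": stage,
            "outputs": {p.name: _sha256(p) for p in outputs},
        })
        _write_manifest(out, manifest, summary)

    # -- stage 1: activities on the full TF set -----------------------------
    logger.info("stage activities: fitting %d TFs at %d time points",
                binding.n_tfs, expression.grid.n_timepoints)
    full_activity, diagnostics = estimate_activity_timecourse(
        expression, binding, options)
    outs = write_activity(full_activity, out / "activities_full")
    diag_path = out / "regression_diagnostics.tsv"
    diag_path.write_text(diagnostics.to_csv(sep="\t", index=False,
                                            float_format="%.17g"))
    record("activities", outs + [diag_path])

    # -- stage 2: iterative TF selection -------------------------------------
    selection = iterative_tf_selection(expression, binding, config, options)
    summary["n_tfs_after_selection"] = len(selection.retained_tf_ids)
    summary["n_selection_iterations"] = selection.n_iterations
    logger.info("stage select: %d -> %d TFs in %d iterations",
                binding.n_tfs, len(selection.retained_tf_ids),
                selection.n_iterations)
    activity = selection.activity
    outs = write_activity(activity, out / "activities")
    hist_path = out / "selection_history.tsv"
    hist_path.write_text(selection_history_frame(selection).to_csv(
        sep="\t", index=False))
    record("select", outs + [hist_path])

    # -- stage 3: periodicity -------------------------------------------------
    results = score_activity_matrix(
        activity, threshold=config.periodicity_threshold,
        n_permutations=config.n_permutations, seed=seed,
        center=config.center_autocorrelation)
    periodic_ids = filter_periodic(results, config.periodicity_threshold)
    summary["n_tfs_after_periodicity"] = len(periodic_ids)
    summary["top_periodicity_scores"] = {
        r.tf_id: round(r.score, 4)
        for r in sorted(results, key=lambda r: -r.score)[:5]}
    logger.info("stage periodicity: %d -> %d TFs at threshold %.2f",
                activity.n_factors, len(periodic_ids),
                config.periodicity_threshold)
    per_path = out / "periodicity.tsv"
    per_path.write_text(pd.DataFrame(
        [{"tf_id": r.tf_id, "score": repr(r.score),
          "lag_samples": r.lag_samples, "p_value": r.permutation_pvalue,
          "n_permutations": r.n_permutations, "seed": r.rng_seed}
         for r in results]).to_csv(sep="\t", index=False))
    record("periodicity", [per_path])

    if not periodic_ids:
        raise PipelineStageError(
            "phases", "no TFs passed the periodicity filter; nothing to fit")
    periodic = activity.subset(periodic_ids)

    # -- stage 4: phases ------------------------------------------------------
    sine_rows, peak_rows = [], []
    for tf in periodic.tf_ids:
        x = periodic.row(tf)
        sf = fit_sine(x, periodic.grid,
                      phase_grid_step=config.phase_grid_step_degrees, tf_id=tf)
        pk = peak_phase(x, periodic.grid, tf_id=tf)
        sine_rows.append({"tf_id": tf, "phase_deg": sf.phase_degrees,
                          "amplitude": repr(sf.amplitude),
                          "offset": repr(sf.offset), "rss": repr(sf.rss),
                          "indeterminate": sf.indeterminate})
        peak_rows.append({"tf_id": tf, "peak_deg": pk.angle_degrees,
                          "phase_label": classify_phase(pk.angle_degrees),
                          "tie": pk.tie, "indeterminate": pk.indeterminate})
    sine_path = out / "sine_fits.tsv"
    sine_path.write_text(pd.DataFrame(sine_rows).to_csv(sep="\t", index=False))
    peak_path = out / "peak_phases.tsv"
    peak_path.write_text(pd.DataFrame(peak_rows).to_csv(sep="\t", index=False))
    phase_outs = [sine_path, peak_path]
    if oxygen is not None:
        labels = classify_cycle_phases_from_oxygen(oxygen, periodic.grid)
        lab_path = out / "cycle_labels.tsv"
        lab_path.write_text(pd.DataFrame(
            {"time": list(periodic.grid.times), "label": labels}
        ).to_csv(sep="\t", index=False))
        phase_outs.append(lab_path)
    record("phases", phase_outs)

    # -- stage 5: clustering --------------------------------------------------
    n_clusters = min(config.n_clusters, periodic.n_factors)
    clustering = cluster_profiles(periodic, n_clusters=n_clusters)
    clus_path = out / "clusters.tsv"
    clus_path.write_text(pd.DataFrame(
        {"tf_id": list(clustering.tf_ids), "label": clustering.labels}
    ).to_csv(sep="\t", index=False))
    link_path = out / "linkage.tsv"
    link_path.write_text(pd.DataFrame(
        clustering.linkage_matrix,
        columns=["left", "right", "height", "size"]).to_csv(
            sep="\t", index=False, float_format="%.17g"))
    record("cluster", [clus_path, link_path])

    # -- stage 6: dynamics ----------------------------------------------------
    model_input = periodic
    if oxygen is not None and config.include_oxygen:
        model_input = periodic.with_extra_row(
            OXYGEN_ID, normalize_oxygen(oxygen, periodic))
    unconstrained = estimate_transition_unconstrained(model_input)
    constrained = estimate_transition_nonneg(model_input)
    ids = model_input.tf_ids
    tu_path = out / "transition_unconstrained.tsv"
    write_matrix(unconstrained.T, ids, ids, tu_path)
    tn_path = out / "transition_nonneg.tsv"
    write_matrix(constrained.T, ids, ids, tn_path)
    res_u = model_residuals(unconstrained, model_input).assign(model="unconstrained")
    res_c = model_residuals(constrained, model_input).assign(model="nonneg")
    res_path = out / "model_residuals.tsv"
    res_path.write_text(pd.concat([res_u, res_c]).to_csv(
        sep="\t", index=False, float_format="%.17g"))
    modes_path = out / "asymptotic_modes.tsv"
    modes_path.write_text(asymptotic_modes(unconstrained).to_csv(
        sep="\t", index=False, float_format="%.17g"))
    summary["rmse_unconstrained"] = float(np.mean(res_u["rmse"]))
    summary["rmse_nonneg"] = float(np.mean(res_c["rmse"]))
    summary["fit_residual_unconstrained"] = unconstrained.frobenius_fit_residual
    summary["fit_residual_nonneg"] = constrained.frobenius_fit_residual
    record("dynamics", [tu_path, tn_path, res_path, modes_path])

    # -- stage 7: network -----------------------------------------------------
    network = extract_network(unconstrained, config.network_threshold)
    summary["n_network_edges"] = len(network.edges)
    logger.info("stage network: %d edges at threshold %.2f",
                len(network.edges), config.network_threshold)
    net_outs = []
    for fmt, name in (("edgelist", "edges.tsv"), ("dot", "network.dot"),
                      ("graphml", "network.graphml")):
        export_network(network, out / name, fmt=fmt)
        net_outs.append(out / name)
    record("network", net_outs)

    manifest["finished"] = datetime.now(timezone.utc).isoformat()
    manifest["summary"] = summary
    _write_manifest(out, manifest, summary)
    return manifest


def _write_manifest(out: Path, manifest: dict, summary: dict) -> None:
    manifest["summary"] = summary
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
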