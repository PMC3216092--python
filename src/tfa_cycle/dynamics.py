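"""Linear time-translation model of factor activities and network extraction.

The activity vector evolves as a first-order linear system,

    alpha_{t+1} = T * alpha_t,

estimated from the observed activity matrix by least squares: with A the
activities excluding the last time point and B those excluding the first
(columns = time points), T minimizes ||B - T A||_F.  The solution uses the
pseudoinverse (identical to the normal-equations formula at full rank,
robust when A is rank-deficient).  A variant constrains every entry of T
to be non-negative via row-wise non-negative least squares; because the
constrained feasible set is smaller, its fit residual can never beat the
unconstrained one.

Entry T[k, j] couples factor j at time t to factor k at time t+1; entries
large in absolute value define directed regulatory edges.  The normalized
dissolved-oxygen trace may be appended as an extra factor so the model
captures coupling between activities and the respiration cycle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_io import ActivityMatrix, DataValidationError

logger = logging.getLogger("tfa_cycle.dynamics")


@dataclass
class TransitionModel:
    factor_ids: tuple[str, ...]
    T: np.ndarray
    constrained: bool
    A: np.ndarray  # factors x (n_t - 1), lagged (last time point dropped)
    B: np.ndarray  # factors x (n_t - 1), led (first time point dropped)
    residual_by_timepoint: np.ndarray | None = None
    rmse_by_timepoint: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.factor_ids)
        if self.T.shape != (k, k):
            raise DataValidationError("T must be square over the factor ids")
        if self.A.shape != self.B.shape:
            raise DataValidationError("A and B must have identical shape")
        if self.constrained and self.T.min() < -1e-12:
            raise DataValidationError("constrained model has negative entries")

    @property
    def frobenius_fit_residual(self) -> float:
        return float(np.linalg.norm(self.B - self.T @ self.A))


@dataclass
class Edge:
    source: str
    target: str
    weight: float
    tie: bool = False

    @property
    def sign(self) -> int:
        return int(np.sign(self.weight))


@dataclass
class RegulatoryNetwork:
    edges: list[Edge]
    threshold: float
    self_loops: list[Edge] = field(default_factory=list)
    self_loops_included: bool = False
    factor_ids: tuple[str, ...] = ()


def normalize_oxygen(trace: np.ndarray, activity: ActivityMatrix) -> np.ndarray:
    """Scale an oxygen trace to sit side-by-side with activity rows.

    The trace is z-scored and rescaled to the median per-factor standard
    deviation of the activity rows, making it affine-invariant and
    comparable in magnitude to the alphas.
    """
    v = np.asarray(trace, dtype=float)
    sd = float(np.std(v))
    if sd == 0:
        raise DataValidationError("zero-variance oxygen trace cannot be normalized")
    z = (v - v.mean()) / sd
    target_sd = float(np.median(np.std(activity.alpha, axis=1)))
    return z * target_sd


def _lag_lead(activity: ActivityMatrix) -> tuple[np.ndarray, np.ndarray]:
    alpha = activity.alpha
    if np.isnan(alpha).any():
        raise DataValidationError("activity matrix contains missing values")
    return alpha[:, :-1], alpha[:, 1:]


def _check_identifiable(activity: ActivityMatrix) -> None:
    n_f = activity.n_factors
    n_t = activity.grid.n_timepoints
    if n_t - 1 < n_f:
        raise DataValidationError(
            f"{n_t} time points cannot identify a {n_f}x{n_f} transition matrix")


def estimate_transition_unconstrained(activity: ActivityMatrix
                                      ) -> TransitionModel:
    """Least-squares T with min ||B - T A||_F via the pseudoinverse."""
    _check_identifiable(activity)
    A, B = _lag_lead(activity)
    if np.linalg.matrix_rank(A) < A.shape[0]:
        logger.warning("rank-deficient activity matrix; returning the "
                       "minimum-norm transition matrix")
    T = B @ np.linalg.pinv(A)
    model = TransitionModel(factor_ids=activity.tf_ids, T=T,
                            constrained=False, A=A, B=B)
    _attach_residuals(model, activity)
    return model


def estimate_transition_nonneg(activity: ActivityMatrix) -> TransitionModel:
    """Row-wise non-negative least squares for an entrywise T >= 0."""
    _check_identifiable(activity)
    A, B = _lag_lead(activity)
    k = A.shape[0]
    T = np.zeros((k, k))
    for row in range(k):
        T[row], _ = nnls(A.T, B[row])
    model = TransitionModel(factor_ids=activity.tf_ids, T=T,
                            constrained=True, A=A, B=B)
    _attach_residuals(model, activity)
    return model


def simulate(model: TransitionModel, alpha_0: np.ndarray,
             n_steps: int) -> np.ndarray:
    """Iterate the model: column s of the output is T^s applied to alpha_0."""
    a = np.asarray(alpha_0, dtype=float)
    k = len(model.factor_ids)
    if a.shape != (k,):
        raise DataValidationError(
            f"alpha_0 length {a.shape} does not match {k} factors")
    out = np.empty((k, n_steps + 1))
    out[:, 0] = a
    for s in range(1, n_steps + 1):
        out[:, s] = model.T @ out[:, s - 1]
    return out


def model_residuals(model: TransitionModel,
                    activity: ActivityMatrix) -> pd.DataFrame:
    """Observed-vs-simulated residuals per time point, two conventions.

    The trajectory is simulated from the first observed activity column.
    ``mean_residual`` is the difference between the factor-mean of the
    observed and the factor-mean of the simulated activities at each time
    point; ``rmse`` is the per-time-point root-mean-square difference, a
    stricter diagnostic that cannot cancel across factors.
    """
    n_t = activity.grid.n_timepoints
    sim = simulate(model, activity.alpha[:, 0], n_t - 1)
    diff = activity.alpha - sim
    return pd.DataFrame({
        "time": list(activity.grid.times),
        "mean_residual": activity.alpha.mean(axis=0) - sim.mean(axis=0),
        "rmse": np.sqrt((diff ** 2).mean(axis=0)),
    })


def _attach_residuals(model: TransitionModel, activity: ActivityMatrix) -> None:
    res = model_residuals(model, activity)
    model.residual_by_timepoint = res["mean_residual"].to_numpy()
    model.rmse_by_timepoint = res["rmse"].to_numpy()


def asymptotic_modes(model: TransitionModel) -> pd.DataFrame:
    """Eigenmodes of T: modulus, oscillation period and factor loadings.

    Complex-conjugate pairs correspond to oscillatory modes with period
    2*pi/|arg(lambda)| samples; |lambda| gives per-step decay (<1) or
    growth (>1).  Modes are reported dominant (largest modulus) first,
    with one row per conjugate pair.
    """
    vals, vecs = np.linalg.eig(model.T)
    order = np.argsort(-np.abs(vals))
    seen_conj: set[int] = set()
    rows = []
    for idx in order:
        if idx in seen_conj:
            continue
        lam = vals[idx]
        if abs(lam.imag) > 1e-12:
            # mark the conjugate partner as reported
            for j in np.flatnonzero(np.isclose(vals, lam.conjugate())):
                if j != idx:
                    seen_conj.add(int(j))
                    break
            period = 2 * np.pi / abs(np.angle(lam))
            oscillatory = True
        else:
            period = np.inf if lam.real >= 0 else 2.0
            oscillatory = abs(lam.imag) > 1e-12
        loadings = np.abs(vecs[:, idx])
        rows.append({"modulus": float(abs(lam)),
                     "period_samples": float(period),
                     "oscillatory": bool(abs(lam.imag) > 1e-12),
                     "eigenvalue_real": float(lam.real),
                     "eigenvalue_imag": float(lam.imag),
                     "top_factor": model.factor_ids[int(np.argmax(loadings))],
                     **{f"loading_{f}": float(l)
                        for f, l in zip(model.factor_ids, loadings)}})
    return pd.DataFrame(rows)


def extract_network(model: TransitionModel, threshold: float = 0.5,
                    include_self_loops: bool = False) -> RegulatoryNetwork:
    """Directed edges from transition-matrix entries exceeding a threshold.

    Entry T[k, j] (factor j driving factor k) yields edge j -> k when
    |T[k, j]| >= threshold.  When both directions of a factor pair pass,
    only the larger-magnitude direction is kept (exact ties keep both,
    flagged).  Self-loops are recorded separately and excluded from the
    edge list unless requested.
    """
    if threshold <= 0:
        raise DataValidationError("network threshold must be > 0")
    ids = model.factor_ids
    k = len(ids)
    candidates: dict[tuple[int, int], float] = {}
    self_loops: list[Edge] = []
    for tgt in range(k):
        for src in range(k):
            w = float(model.T[tgt, src])
            if abs(w) < threshold:
                continue
            if src == tgt:
                self_loops.append(Edge(ids[src], ids[tgt], w))
            else:
                candidates[(src, tgt)] = w
    edges: list[Edge] = []
    for (src, tgt), w in candidates.items():
        rev = candidates.get((tgt, src))
        if rev is not None:
            if abs(w) < abs(rev):
                continue  # the reverse direction wins
            if abs(w) == abs(rev) and src > tgt:
                edges.append(Edge(ids[src], ids[tgt], w, tie=True))
                continue
            tie = abs(w) == abs(rev)
            edges.append(Edge(ids[src], ids[tgt], w, tie=tie))
        else:
            edges.append(Edge(ids[src], ids[tgt], w))
    if include_self_loops:
        edges = edges + self_loops
    return RegulatoryNetwork(edges=edges, threshold=threshold,
                             self_loops=self_loops,
                             self_loops_included=include_self_loops,
                             factor_ids=ids)


def network_to_graph(network: RegulatoryNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for f in sorted(network.factor_ids):
        g.add_node(f)
    for e in sorted(network.edges, key=lambda e: (e.source, e.target)):
        g.add_edge(e.source, e.target, weight=e.weight, sign=e.sign)
    return g


def export_network(network: RegulatoryNetwork, path: str | Path,
                   fmt: str = "edgelist") -> None:
    """Write the network as GraphML, DOT or a tab-delimited edge list."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network_to_graph(network), path)
    elif fmt == "dot":
        lines = ["digraph regulatory_network {"]
        for f in sorted(network.factor_ids):
            lines.append(f'    "{f}";')
        for e in sorted(network.edges, key=lambda e: (e.source, e.target)):
            lines.append(f'    "{e.source}" -> "{e.target}" '
                         f'[weight={e.weight:.6g}, sign={e.sign}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "edgelist":
        df = pd.DataFrame(
            [{"source": e.source, "target": e.target,
              "weight": repr(e.weight), "sign": e.sign} for e in
             sorted(network.edges, key=lambda e: (e.source, e.target))],
            columns=["source", "target", "weight", "sign"])
        path.write_text(df.to_csv(sep="\t", index=False))
    else:
        raise DataValidationError(f"unknown network format {fmt!r}")


def read_network_edgelist(path: str | Path, threshold: float
                          ) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t")
    edges = [Edge(str(r.source), str(r.target), float(r.weight))
             for r in df.itertuples()]
    ids = tuple(sorted({e.source for e in edges} | {e.target for e in edges}))
    return RegulatoryNetwork(edges=edges, threshold=threshold, factor_ids=ids)
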