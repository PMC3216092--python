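"""Synthetic datasets with the statistical structure the analysis assumes.

The generator produces the three inputs of the pipeline — a genes x times
relative-expression matrix, a sparse positive genes x TFs binding matrix
and a dissolved-oxygen trace — together with full ground truth, so every
stage can be tested closed-loop without external data.

Activity profiles come in two families mirroring the shapes seen over the
yeast metabolic cycle: smooth sinusoids, and "spike" profiles (a
low-amplitude sinusoid plus a sharp Gaussian pulse recurring once per
cycle at a common cycle position, with positive-going and negative-going
members forming sign-flipped pairs).  Decoy TFs have identically zero
activity.  Expression follows the multiplicative model
R_i(t) = c * prod_j b_ij^{alpha_j(t)} with Gaussian noise added on the log
scale and an injectable fraction of missing cells.  The oxygen trace is a
sawtooth: a sharp drop (oxidative phase), a rise (reductive/building) and
a plateau (reductive/charging) in each cycle.

All generators are deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    ActivityMatrix,
    BindingMatrix,
    DataValidationError,
    ExpressionMatrix,
    TimeGrid,
    write_binding,
    write_expression,
    write_matrix,
    write_oxygen,
)


@dataclass(frozen=True)
class SineProfile:
    phase_degrees: float
    amplitude: float

    family = "sine"


@dataclass(frozen=True)
class SpikeProfile:
    """Low-amplitude sinusoidal baseline plus one sharp pulse per cycle."""

    center: float  # cycle position of the pulse, in samples
    width: float = 0.8  # Gaussian sd of the pulse, in samples
    sign: int = 1
    baseline_amplitude: float = 0.15
    pulse_amplitude: float = 0.9
    baseline_phase_degrees: float = 0.0

    family = "spike"


@dataclass(frozen=True)
class FlatProfile:
    family = "flat"


Profile = SineProfile | SpikeProfile | FlatProfile


@dataclass
class SyntheticSpec:
    """Generative settings; defaults give the standard closed-loop fixture.

    36 time points at 25-min spacing (three 300-min cycles, 12 samples per
    cycle), 200 genes, 13 active TFs (5 sinusoidal + 8 spike-shaped in
    sign-flipped pairs) among 37 zero-activity decoys, 25 promoter targets
    per TF with log-strengths ~ N(1.0, 0.3) truncated positive, log-scale
    expression noise sd 0.15 and 2% missing cells.
    """

    n_genes: int = 200
    n_timepoints: int = 36
    period_samples: int = 12
    period_minutes: float = 300.0
    start_minutes: float = 3973.0
    profiles: dict[str, Profile] = field(default_factory=dict)
    n_decoy_tfs: int = 37
    targets_per_tf: int = 25
    binding_log_mean: float = 1.0
    binding_log_sd: float = 0.3
    binding_floor: float = 1e-4
    noise_sd: float = 0.15
    missing_fraction: float = 0.02
    intercept: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints % self.period_samples:
            raise DataValidationError(
                "n_timepoints must be an integer multiple of period_samples")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise DataValidationError("missing_fraction must lie in [0, 1)")
        if self.targets_per_tf > self.n_genes:
            raise DataValidationError("targets_per_tf exceeds n_genes")
        if not self.profiles:
            self.profiles = default_profiles()

    @property
    def tf_ids(self) -> tuple[str, ...]:
        return tuple(self.profiles) + tuple(
            f"DECOY{i:02d}" for i in range(self.n_decoy_tfs))

    @property
    def grid(self) -> TimeGrid:
        dt = self.period_minutes / self.period_samples
        times = self.start_minutes + dt * np.arange(self.n_timepoints)
        return TimeGrid(times=tuple(times), period_minutes=self.period_minutes)


def default_profiles() -> dict[str, Profile]:
    """13 active TFs: a smooth-sine cluster and a spike cluster.

    The spike cluster shares a single pulse position early in the cycle
    (the oxidative burst) with four positive-going and four negative-going
    members; the sine cluster's phases are concentrated with one
    mirror-image pair 180 degrees apart, echoing the activator/repressor
    structure of the real cycle.
    """
    profiles: dict[str, Profile] = {}
    spike_up_phases = (290.0, 300.0, 310.0, 280.0)
    spike_dn_phases = (110.0, 120.0, 130.0, 100.0)
    for i, ph in enumerate(spike_up_phases):
        profiles[f"SPIKE_UP{i}"] = SpikeProfile(
            center=2.0, sign=1, baseline_phase_degrees=ph)
    for i, ph in enumerate(spike_dn_phases):
        profiles[f"SPIKE_DN{i}"] = SpikeProfile(
            center=2.0, sign=-1, baseline_phase_degrees=ph)
    sine_specs = ((200.0, 0.35), (215.0, 0.30), (225.0, 0.45),
                  (255.0, 0.30), (45.0, 0.40))
    for i, (ph, amp) in enumerate(sine_specs):
        profiles[f"SINE{i}"] = SineProfile(phase_degrees=ph, amplitude=amp)
    return profiles


def _profile_values(profile: Profile, n_t: int, period: int) -> np.ndarray:
    t = np.arange(n_t)
    omega = 2 * np.pi / period
    if isinstance(profile, SineProfile):
        return profile.amplitude * np.sin(
            omega * t + np.deg2rad(profile.phase_degrees))
    if isinstance(profile, SpikeProfile):
        base = profile.baseline_amplitude * np.sin(
            omega * t + np.deg2rad(profile.baseline_phase_degrees))
        # pulse repeated every cycle; wrap distance on the cycle circle
        pos = t % period
        d = np.minimum(np.abs(pos - profile.center),
                       period - np.abs(pos - profile.center))
        pulse = profile.pulse_amplitude * np.exp(-0.5 * (d / profile.width) ** 2)
        return base + profile.sign * pulse
    return np.zeros(n_t)


def generate_activities(spec: SyntheticSpec) -> ActivityMatrix:
    """True TF x time activity matrix (decoy rows identically zero)."""
    n_t = spec.n_timepoints
    rows = [_profile_values(spec.profiles.get(tf, FlatProfile()),
                            n_t, spec.period_samples)
            for tf in spec.tf_ids]
    return ActivityMatrix(tf_ids=spec.tf_ids, grid=spec.grid,
                          alpha=np.vstack(rows))


def generate_binding(spec: SyntheticSpec,
                     rng: np.random.Generator | None = None) -> BindingMatrix:
    """Sparse positive binding matrix: each TF binds a random target set.

    Targets receive b = exp(w) with w ~ N(mean, sd) truncated positive;
    non-targets sit at the neutral baseline 1.
    """
    rng = rng or np.random.default_rng(spec.rng_seed)
    gene_ids = tuple(f"GENE{i:04d}" for i in range(spec.n_genes))
    values = np.ones((spec.n_genes, len(spec.tf_ids)))
    for j in range(len(spec.tf_ids)):
        targets = rng.choice(spec.n_genes, size=spec.targets_per_tf,
                             replace=False)
        w = rng.normal(spec.binding_log_mean, spec.binding_log_sd,
                       size=spec.targets_per_tf)
        while np.any(w <= 0):  # truncate at zero by redrawing
            bad = w <= 0
            w[bad] = rng.normal(spec.binding_log_mean, spec.binding_log_sd,
                                size=int(bad.sum()))
        values[targets, j] = np.exp(w)
    return BindingMatrix(gene_ids=gene_ids, tf_ids=spec.tf_ids,
                         values=values, floor=spec.binding_floor)


def generate_expression(binding: BindingMatrix, activities: ActivityMatrix,
                        spec: SyntheticSpec,
                        rng: np.random.Generator | None = None
                        ) -> ExpressionMatrix:
    """Expression from the multiplicative model plus log-scale noise.

    log R = log c + (log B) alpha + eps, eps ~ N(0, noise_sd); a seeded
    random ``missing_fraction`` of cells is then masked.
    """
    rng = rng or np.random.default_rng(spec.rng_seed + 1)
    log_r = np.log(spec.intercept) + binding.log_values() @ activities.alpha
    if spec.noise_sd > 0:
        log_r = log_r + rng.normal(0.0, spec.noise_sd, size=log_r.shape)
    values = np.exp(log_r)
    if spec.missing_fraction > 0:
        mask = rng.random(values.shape) < spec.missing_fraction
        values[mask] = np.nan
    return ExpressionMatrix(gene_ids=binding.gene_ids, grid=activities.grid,
                            values=values)


# one cycle of the sawtooth, high plateau = 1, trough = 0, and the
# slope-segment label of each sample (forward-difference convention)
_OXYGEN_CYCLE = np.array([1.0, 0.5, 0.0, 0.25, 0.5, 0.75,
                          1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
_OXYGEN_LABELS = ["Ox"] * 2 + ["R/B"] * 4 + ["R/C"] * 6


def generate_oxygen(spec: SyntheticSpec, amplitude: float = 1.0,
                    noise_sd: float = 0.0,
                    rng: np.random.Generator | None = None
                    ) -> tuple[np.ndarray, list[str]]:
    """Sawtooth-like dissolved-oxygen trace plus its construction labels.

    Each cycle: a steep linear drop over ~2 samples (Ox), a rise over ~4
    (R/B) and a plateau over the remainder (R/C).
    """
    if spec.period_samples < 6:
        raise DataValidationError("oxygen sawtooth needs period_samples >= 6")
    P = spec.period_samples
    n_drop, n_rise = 2, 4
    cycle = np.ones(P)
    cycle[:n_drop + 1] = np.linspace(1.0, 0.0, n_drop + 1)
    cycle[n_drop:n_drop + n_rise + 1] = np.linspace(0.0, 1.0, n_rise + 1)
    labels_cycle = ["Ox"] * n_drop + ["R/B"] * n_rise + ["R/C"] * (P - n_drop - n_rise)
    n_cycles = spec.n_timepoints // P
    trace = amplitude * np.tile(cycle, n_cycles)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(spec.rng_seed + 2)
        trace = trace + rng.normal(0.0, noise_sd, size=trace.shape)
    return trace, labels_cycle * n_cycles


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    activities: ActivityMatrix  # ground truth
    binding: BindingMatrix
    expression: ExpressionMatrix
    oxygen: np.ndarray
    oxygen_labels: list[str]
    labels: pd.DataFrame  # tf_id, role, family, true phase/amplitude

    @property
    def active_tf_ids(self) -> tuple[str, ...]:
        return tuple(self.labels.loc[self.labels.role == "active", "tf_id"])


def generate_dataset(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Generate the full input triple plus ground-truth labels."""
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.rng_seed)
    activities = generate_activities(spec)
    binding = generate_binding(spec, rng)
    expression = generate_expression(binding, activities, spec, rng)
    oxygen, oxygen_labels = generate_oxygen(spec)
    rows = []
    for tf in spec.tf_ids:
        prof = spec.profiles.get(tf, FlatProfile())
        row = {"tf_id": tf,
               "role": "decoy" if prof.family == "flat" else "active",
               "family": prof.family,
               "true_phase_degrees": np.nan, "true_amplitude": np.nan}
        if isinstance(prof, SineProfile):
            row["true_phase_degrees"] = prof.phase_degrees
            row["true_amplitude"] = prof.amplitude
        rows.append(row)
    return SyntheticDataset(spec=spec, activities=activities, binding=binding,
                            expression=expression, oxygen=oxygen,
                            oxygen_labels=oxygen_labels,
                            labels=pd.DataFrame(rows))


def generate_linear_system(n_factors: int, spectral_radius: float = 0.95,
                           n_steps: int = 35, noise_sd: float = 0.0,
                           seed: int = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Random stable linear system and a trajectory from a random start.

    Returns (T_true, trajectory) where the trajectory has n_steps + 1
    columns; optional Gaussian process noise perturbs each step.
    """
    if not 0 < spectral_radius <= 1:
        raise DataValidationError("spectral_radius must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    T = rng.normal(size=(n_factors, n_factors))
    T *= spectral_radius / max(abs(np.linalg.eigvals(T)))
    traj = np.empty((n_factors, n_steps + 1))
    traj[:, 0] = rng.normal(size=n_factors)
    for s in range(1, n_steps + 1):
        traj[:, s] = T @ traj[:, s - 1]
        if noise_sd > 0:
            traj[:, s] += rng.normal(0.0, noise_sd, size=n_factors)
    return T, traj


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write expression.tsv, binding.tsv, oxygen.tsv and a truth/ directory."""
    out = Path(out_dir)
    truth = out / "truth"
    truth.mkdir(parents=True, exist_ok=True)
    write_expression(dataset.expression, out / "expression.tsv")
    write_binding(dataset.binding, out / "binding.tsv")
    write_oxygen(dataset.expression.grid.times_array, dataset.oxygen,
                 out / "oxygen.tsv")
    write_matrix(dataset.activities.alpha, dataset.activities.tf_ids,
                 [str(t) for t in dataset.activities.grid.times],
                 truth / "true_activities.tsv")
    (truth / "labels.tsv").write_text(
        dataset.labels.to_csv(sep="\t", index=False))
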