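"""Trial-structured synthetic parcel time series with planted network structure.

The generator emulates the statistical structure the downstream analysis
assumes in task fMRI parcel data:

* a modular community structure (positively correlated parcels within a
  module),
* anticorrelation between two large "systems" of modules, mirroring the
  task-positive / task-negative organisation of cortical activity
  (mutual anticorrelation among many modules at once is not
  positive-definite-feasible below -1/(K-1), so the planted negative
  coupling lives between two supersystems),
* designated *connector parcels*, one or more per module, whose
  correlation profile spreads across the other modules of their system
  and who carry the (weakly negative) bridge correlations across
  systems -- the structure connector-hub classification is designed to
  detect,
* slowly time-varying coupling: a smooth periodic attenuation of all
  off-diagonal correlations with a per-condition phase, and
* GARCH(1,1) conditional heteroskedasticity in every parcel's
  innovations.

Trials are contiguous segments of one long stationary-parameter process
that is later epoched; the dynamic-correlation stage needs runs much
longer than a single 9-sample trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "ParcelTimeSeriesSet",
    "GroundTruth",
    "generate_parcel_timeseries",
    "save_timeseries_tsv",
    "load_timeseries_tsv",
]

_CONDITION_NAMES = ("positive", "negative", "neutral")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic multi-subject, multi-condition design.

    Defaults follow the standard task design this pipeline targets
    (3 picture conditions, 9 trials per condition, 9 samples of 2 s per
    trial) at a reduced network size of 30 parcels in 6 modules.
    """

    n_parcels: int = 30
    n_modules: int = 6
    n_subjects: int = 24
    n_conditions: int = 3
    n_trials_per_condition: int = 9
    samples_per_trial: int = 9
    sampling_interval_s: float = 2.0
    intra_module_corr: float = 0.75
    inter_module_corr: float = -0.20
    corr_modulation_amplitude: float = 0.2
    garch_omega: float = 0.05
    garch_alpha: float = 0.10
    garch_beta: float = 0.85
    seed: int = 0
    # planted-structure refinements
    n_systems: int = 2
    allied_module_corr: float = 0.18
    connectors_per_module: int = 1
    connector_intra_corr: float = 0.40
    connector_cross_corr: float = 0.40
    connector_bridge_corr: float = -0.13
    connector_out_corr: float = -0.17
    connector_pair_corr: float = 0.20
    modulation_period_s: float = 18.0

    def validate(self) -> None:
        if self.n_modules > self.n_parcels:
            raise ValueError("n_modules must not exceed n_parcels")
        if not 0 < self.intra_module_corr < 1:
            raise ValueError("intra_module_corr must lie in (0, 1)")
        if not -1 < self.inter_module_corr <= 0:
            raise ValueError("inter_module_corr must lie in (-1, 0]")
        if not 0 <= self.corr_modulation_amplitude < 1:
            raise ValueError("corr_modulation_amplitude must lie in [0, 1)")
        if self.garch_alpha + self.garch_beta >= 1:
            raise ValueError("garch_alpha + garch_beta must be < 1 (stationarity)")
        if min(self.garch_omega, self.garch_alpha, self.garch_beta) < 0:
            raise ValueError("GARCH parameters must be nonnegative")
        if self.n_systems < 1 or self.n_modules % self.n_systems:
            raise ValueError("n_modules must be divisible by n_systems")
        # positive-definiteness of the planted target, checked explicitly
        R = self.target_correlation()
        lam = float(np.linalg.eigvalsh(R)[0])
        if lam <= 1e-10:
            raise ValueError(
                "planted correlation matrix is not positive definite "
                f"(min eigenvalue {lam:.4f}); offending block values: "
                f"intra={self.intra_module_corr}, "
                f"allied={self.allied_module_corr}, "
                f"inter={self.inter_module_corr}, "
                f"connector_cross={self.connector_cross_corr}"
            )

    # -- planted structure -------------------------------------------------

    def module_assignment(self) -> np.ndarray:
        """Module id per parcel (near-equal contiguous blocks)."""
        sizes = np.full(self.n_modules, self.n_parcels // self.n_modules)
        sizes[: self.n_parcels % self.n_modules] += 1
        return np.repeat(np.arange(self.n_modules), sizes)

    def system_assignment(self) -> np.ndarray:
        """System (supercluster) id per parcel."""
        mod_sys = np.arange(self.n_modules) // (self.n_modules // self.n_systems)
        return mod_sys[self.module_assignment()]

    def connector_mask(self) -> np.ndarray:
        """Boolean mask of designated connector parcels."""
        module = self.module_assignment()
        mask = np.zeros(self.n_parcels, dtype=bool)
        for m in range(self.n_modules):
            idx = np.where(module == m)[0]
            mask[idx[: min(self.connectors_per_module, len(idx))]] = True
        return mask

    def target_correlation(self) -> np.ndarray:
        """The planted (unmodulated) population correlation matrix."""
        module = self.module_assignment()
        system = self.system_assignment()
        hub = self.connector_mask()
        same_mod = module[:, None] == module[None, :]
        same_sys = system[:, None] == system[None, :]
        either_hub = hub[:, None] | hub[None, :]
        both_hub = hub[:, None] & hub[None, :]

        R = np.full((self.n_parcels, self.n_parcels), self.inter_module_corr)
        R[same_sys] = self.allied_module_corr
        R[same_sys & either_hub] = self.connector_cross_corr
        R[same_sys & both_hub] = self.connector_pair_corr
        R[same_mod] = self.intra_module_corr
        R[same_mod & either_hub] = self.connector_intra_corr
        # cross-system couplings of connectors are milder than the
        # member-member anticorrelation, and mildest between two
        # connectors (the designated crossing routes)
        R[~same_sys & either_hub] = self.connector_out_corr
        R[~same_sys & both_hub] = self.connector_bridge_corr
        np.fill_diagonal(R, 1.0)
        return R

    def modulation(self, t_seconds: np.ndarray, condition_index: int) -> np.ndarray:
        """Smooth periodic attenuation factor in [1 - A, 1].

        The factor multiplies all off-diagonal correlations; because it
        never exceeds 1 the modulated matrix shrinks toward the identity
        and remains positive definite whenever the base matrix is.
        """
        A = self.corr_modulation_amplitude
        phase = 2.0 * np.pi * condition_index / max(self.n_conditions, 1)
        osc = np.sin(2.0 * np.pi * t_seconds / self.modulation_period_s + phase)
        return 1.0 - A * (1.0 + osc) / 2.0

    def condition_names(self) -> list[str]:
        if self.n_conditions == 3:
            return list(_CONDITION_NAMES)
        return [f"cond-{i + 1}" for i in range(self.n_conditions)]


@dataclass
class ParcelTimeSeriesSet:
    """Trial-structured multivariate series: (subject, condition, trial, parcel, sample)."""

    values: np.ndarray
    sampling_interval_s: float
    labels: list[str]
    conditions: list[str]

    def __post_init__(self):
        if self.values.ndim != 5:
            raise ValueError("values must be 5-D (subject, condition, trial, parcel, sample)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contain non-finite values")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("parcel labels must be unique")
        if self.values.shape[3] != len(self.labels):
            raise ValueError("parcel axis does not match label count")

    def concatenated(self, subject: int, condition: int) -> np.ndarray:
        """(parcels, trials * samples) run for one subject/condition."""
        v = self.values[subject, condition]  # (trial, parcel, sample)
        return np.concatenate(list(v), axis=1)


@dataclass
class GroundTruth:
    """Planted generative structure, for parameter-recovery tests."""

    partition: dict[str, int]
    target_correlation_path: np.ndarray  # (condition, parcel, parcel, sample_in_trial)
    connector_parcels: list[str]
    system: dict[str, int]


def generate_parcel_timeseries(
    config: SyntheticConfig,
) -> tuple[ParcelTimeSeriesSet, GroundTruth]:
    """Generate the full synthetic data set plus its ground-truth record.

    Innovations at sample t are drawn with the planted instantaneous
    correlation matrix (base structure attenuated by the smooth
    modulation trajectory) and scaled by per-parcel GARCH(1,1)
    conditional standard deviations.  Identical config and seed yield
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_parcels
    spt = config.samples_per_trial
    n_run = config.n_trials_per_condition * spt
    labels = [f"P{i + 1:03d}" for i in range(p)]
    R = config.target_correlation()

    t_sec = np.arange(n_run) * config.sampling_interval_s
    eye = np.eye(p)

    # Pre-factor the modulated correlation matrices: the modulation repeats
    # every trial when the period equals the trial duration, but is computed
    # per run sample to stay general.
    chols: dict[int, list[np.ndarray]] = {}
    paths = np.empty((config.n_conditions, p, p, spt))
    for c in range(config.n_conditions):
        m = config.modulation(t_sec, c)
        chols[c] = [np.linalg.cholesky(eye + m[t] * (R - eye)) for t in range(n_run)]
        for k in range(spt):
            paths[c, :, :, k] = eye + m[k] * (R - eye)

    uncond_var = config.garch_omega / (1.0 - config.garch_alpha - config.garch_beta) \
        if config.garch_alpha + config.garch_beta < 1 else config.garch_omega

    values = np.empty(
        (config.n_subjects, config.n_conditions, config.n_trials_per_condition, p, spt)
    )
    for s in range(config.n_subjects):
        for c in range(config.n_conditions):
            h = np.full(p, uncond_var)
            run = np.empty((p, n_run))
            u = rng.standard_normal((n_run, p))
            for t in range(n_run):
                z = chols[c][t] @ u[t]
                x = np.sqrt(h) * z
                run[:, t] = x
                h = (config.garch_omega + config.garch_alpha * x**2
                     + config.garch_beta * h)
            values[s, c] = run.reshape(p, config.n_trials_per_condition, spt
                                       ).transpose(1, 0, 2)

    series = ParcelTimeSeriesSet(
        values=values,
        sampling_interval_s=config.sampling_interval_s,
        labels=labels,
        conditions=config.condition_names(),
    )
    module = config.module_assignment()
    system = config.system_assignment()
    hub = config.connector_mask()
    truth = GroundTruth(
        partition={labels[i]: int(module[i]) for i in range(p)},
        target_correlation_path=paths,
        connector_parcels=[labels[i] for i in np.where(hub)[0]],
        system={labels[i]: int(system[i]) for i in range(p)},
    )
    return series, truth


# -- on-disk layout: one TSV per subject/condition/trial ---------------------


def save_timeseries_tsv(series: ParcelTimeSeriesSet, root: str | Path) -> None:
    """Write ``sub-<k>/<condition>/trial-<j>.tsv`` files (rows = parcels)."""
    root = Path(root)
    n_subj, n_cond, n_trials = series.values.shape[:3]
    for s in range(n_subj):
        for c in range(n_cond):
            d = root / f"sub-{s + 1}" / series.conditions[c]
            d.mkdir(parents=True, exist_ok=True)
            for j in range(n_trials):
                df = pd.DataFrame(series.values[s, c, j], index=series.labels)
                df.to_csv(d / f"trial-{j + 1}.tsv", sep="\t", header=False,
                          float_format="%.10g")


def load_timeseries_tsv(root: str | Path,
                        sampling_interval_s: float = 2.0) -> ParcelTimeSeriesSet:
    """Load a directory tree written by :func:`save_timeseries_tsv`."""
    root = Path(root)
    sub_dirs = sorted(root.glob("sub-*"), key=lambda q: int(q.name.split("-")[1]))
    if not sub_dirs:
        raise FileNotFoundError(f"no sub-* directories under {root}")
    conditions = sorted(d.name for d in sub_dirs[0].iterdir() if d.is_dir())
    # keep the canonical condition order when present
    canon = [c for c in _CONDITION_NAMES if c in conditions]
    conditions = canon + [c for c in conditions if c not in canon]

    all_vals, labels = [], None
    for sd in sub_dirs:
        cond_vals = []
        for cond in conditions:
            trials = sorted((sd / cond).glob("trial-*.tsv"),
                            key=lambda q: int(q.stem.split("-")[1]))
            mats = []
            for tf in trials:
                df = pd.read_csv(tf, sep="\t", header=None, index_col=0)
                if labels is None:
                    labels = [str(i) for i in df.index]
                mats.append(df.to_numpy(dtype=float))
            cond_vals.append(np.stack(mats))
        all_vals.append(np.stack(cond_vals))
    return ParcelTimeSeriesSet(values=np.stack(all_vals),
                               sampling_interval_s=sampling_interval_s,
                               labels=labels, conditions=conditions)
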