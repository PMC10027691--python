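"""Synthetic multi-subject BOLD-like sessions with content-specific coupling.

The generator emulates the statistical structure the connectivity analysis
assumes: subROI x time matrices (TR = 1.47 s, 4 runs) in which working-
memory content is carried *between* regions.  Each ripple-velocity class
activates a latent factor shared by a class-specific subset of subROI pairs
across the ROIs of a designated "signal network" during the (lagged)
maintenance window of trials retro-cued to that class — a discretized
version of a "best-omega" connectivity topography.  On top of that sit
HRF-convolved evoked responses to the trial events, slow drifts below the
0.006 Hz high-pass cutoff, global confound channels (CSF/white-matter
analogs), and white (optionally AR(1)) noise.

With shared latent amplitude ``a = noise_sd * sqrt(rho / (1 - rho))`` the
correlation between two coupled subROIs during a co-activated window is
exactly ``rho`` (the configured ``coupling_strength``), which makes
parameter recovery well-posed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .roi_registry import ROIRegistry, ROINetwork
from .stimuli import TrialSchedule, generate_trial_schedule, N_CLASSES

__all__ = ["AcqConfig", "GroundTruth", "SessionData", "simulate_session", "simulate_cohort"]


@dataclass(frozen=True)
class AcqConfig:
    """Acquisition parameters of a synthetic session."""

    tr: float = 1.47  # s
    run_length: float = 620.0  # s; fits 24 trials at 25-s spacing plus tail
    n_runs: int = 4
    lag: float = 4.41  # hemodynamic analysis lag, s (= 3 TRs)

    def __post_init__(self) -> None:
        ratio = self.lag / self.tr
        if abs(ratio - round(ratio)) > 0.01:
            raise ValueError(
                f"lag {self.lag} s must be an integer multiple of TR {self.tr} s"
            )

    @property
    def n_scans(self) -> int:
        return int(self.run_length // self.tr)

    @property
    def lag_scans(self) -> int:
        return int(round(self.lag / self.tr))


@dataclass(frozen=True)
class GroundTruth:
    """Generator parameters for one cohort.

    ``signal_networks`` lists the ROI-name tuples that carry content;
    ``coupling_strength`` is the correlation increment a class-matched subROI
    pair attains during its class's maintenance windows.  Amplitudes are in
    units of the noise standard deviation.
    """

    signal_networks: tuple[tuple[str, ...], ...] = ()
    coupling_strength: float = 0.0
    noise_sd: float = 1.0
    evoked_amplitude: float = 1.0
    drift_amplitude: float = 2.0
    confound_amplitude: float = 0.5
    n_confounds: int = 2
    ar1: float = 0.0  # AR(1) noise coefficient; 0 = white
    coupling_jitter_sd: float = 0.0  # per-subject jitter of coupling_strength

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling_strength < 1.0):
            raise ValueError(
                "coupling_strength must lie in [0, 1) to keep the implied "
                "correlation matrices positive semi-definite"
            )
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("ar1 must lie in [0, 1)")

    def subroi_groups(self, registry: ROIRegistry) -> dict[str, np.ndarray]:
        """Class assignment of each signal ROI's subROIs (round-robin)."""
        names = {n for net in self.signal_networks for n in net}
        return {
            name: np.arange(registry[name].n_subrois) % N_CLASSES for name in names
        }

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class SessionData:
    """One synthetic subject: per-run subROI x time matrices plus metadata."""

    subject: str
    runs: list[np.ndarray]  # each n_subrois x n_scans
    confounds: list[np.ndarray]  # each n_scans x n_confounds
    schedule: TrialSchedule
    registry: ROIRegistry
    acq: AcqConfig
    truth: GroundTruth | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        n_units = self.registry.total_subrois
        for i, run in enumerate(self.runs):
            if run.shape != (n_units, self.acq.n_scans):
                raise ValueError(
                    f"run {i}: expected {(n_units, self.acq.n_scans)}, got {run.shape}"
                )

    def save(self, out_dir: str | Path) -> None:
        """Write one delimited matrix per run plus events.tsv and truth.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, (run, conf) in enumerate(zip(self.runs, self.confounds)):
            np.savetxt(out / f"{self.subject}_run-{i}_bold.tsv", run, delimiter="\t")
            np.savetxt(out / f"{self.subject}_run-{i}_confounds.tsv", conf, delimiter="\t")
        self.schedule.to_events_tsv(out / f"{self.subject}_events.tsv")
        if self.truth is not None:
            (out / f"{self.subject}_truth.json").write_text(self.truth.to_json())


def _noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, ar1: float) -> np.ndarray:
    eps = rng.normal(0.0, sd, size=shape)
    if ar1 == 0.0:
        return eps
    out = np.empty_like(eps)
    out[:, 0] = eps[:, 0]
    for t in range(1, shape[1]):
        out[:, t] = ar1 * out[:, t - 1] + eps[:, t]
    return out * math.sqrt(1.0 - ar1**2)  # keep marginal variance sd^2


def simulate_session(
    registry: ROIRegistry,
    schedule: TrialSchedule,
    acq: AcqConfig,
    truth: GroundTruth,
    seed: int = 0,
    subject: str = "sub-00",
) -> SessionData:
    """Generate one subject's session; fully reproducible from ``seed``."""
    from .glm import double_gamma_hrf, _convolve_boxcars  # deferred: circular import

    rng = np.random.default_rng(seed)
    n_units = registry.total_subrois
    n_scans = acq.n_scans
    slices = registry.subroi_slices()
    groups = truth.subroi_groups(registry)
    hrf = double_gamma_hrf(acq.tr)
    t_sec = np.arange(n_scans) * acq.tr

    rho = truth.coupling_strength
    if truth.coupling_jitter_sd > 0:
        rho = float(
            np.clip(rng.normal(rho, truth.coupling_jitter_sd), 0.0, 0.99)
        )
    a = truth.noise_sd * math.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0

    # per-unit amplitudes are stable across runs within a subject
    evoked_amp = rng.normal(truth.evoked_amplitude, 0.3 * abs(truth.evoked_amplitude), n_units)
    drift_load = rng.normal(0.0, truth.drift_amplitude, (n_units, 4))
    conf_load = rng.normal(0.0, truth.confound_amplitude, (n_units, truth.n_confounds))

    runs, confs = [], []
    for run in range(acq.n_runs):
        x = _noise(rng, (n_units, n_scans), truth.noise_sd, truth.ar1)

        # slow drifts: cosines below the 0.006 Hz high-pass cutoff
        for k in range(1, 5):
            basis = np.cos(np.pi * k * t_sec / acq.run_length)  # freq k/(2L) Hz
            x += drift_load[:, k - 1 : k] * basis[None, :]

        # global confound channels (CSF / white-matter analogs): smoothed noise
        conf = rng.normal(size=(n_scans, truth.n_confounds))
        kernel = np.ones(15) / 15.0
        for j in range(truth.n_confounds):
            conf[:, j] = np.convolve(conf[:, j], kernel, mode="same")
            conf[:, j] /= conf[:, j].std() or 1.0
        x += conf_load @ conf.T

        # evoked responses to the trial events
        events = schedule.events(run)
        for ttype in events["trial_type"].unique():
            sub = events[events["trial_type"] == ttype]
            reg = _convolve_boxcars(
                sub["onset"].to_numpy(), sub["duration"].to_numpy(), n_scans, acq.tr, hrf
            )
            x += evoked_amp[:, None] * reg[None, :]

        # content-specific coupling during lagged maintenance windows
        if a > 0 and truth.signal_networks:
            from .glm import maintenance_window_indices

            for _, trial in schedule.run_trials(run).iterrows():
                c = int(trial["cued_class"])
                i0, i1 = maintenance_window_indices(trial, acq, schedule.timing)
                i1 = min(i1, n_scans)
                if i1 <= i0:
                    continue
                z = rng.normal(size=i1 - i0)
                for net in truth.signal_networks:
                    for name in net:
                        rows = np.where(groups[name] == c)[0] + slices[name].start
                        x[rows, i0:i1] += a * z[None, :]

        runs.append(x)
        confs.append(conf)
    return SessionData(
        subject=subject, runs=runs, confounds=confs, schedule=schedule,
        registry=registry, acq=acq, truth=truth, seed=seed,
    )


def simulate_cohort(
    n_subjects: int,
    registry: ROIRegistry,
    acq: AcqConfig,
    truth: GroundTruth,
    seed: int = 0,
    schedule: TrialSchedule | None = None,
) -> list[SessionData]:
    """Generate a cohort with independent per-subject seeds and schedules.

    Subject seeds derive from the master seed via ``SeedSequence.spawn``, so
    the same master seed reproduces the cohort byte for byte.  If
    ``schedule`` is given it is shared; otherwise each subject gets their
    own seeded schedule (as in an individualized protocol).
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    sessions = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        sched = schedule or generate_trial_schedule(seed=sub_seed)
        sessions.append(
            simulate_session(
                registry, sched, acq, truth, seed=sub_seed, subject=f"sub-{i:02d}"
            )
        )
    return sessions
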