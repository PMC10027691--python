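"""Moving-ripple stimuli, staircase psychophysics, and retro-cue trial schedules.

A moving ripple is a broadband sound whose log-spectral envelope drifts in
time: the intensity of a carrier at octave position ``g = log2(f / f0)`` is

    s(g, t) = D0 + D * cos(2*pi*(omega*t + Omega*g) + psi)

with ripple velocity ``omega`` (cycles/s), spectral density ``Omega``
(cycles/octave), base offset ``D0``, modulation depth ``D``, and ripple phase
``psi``.  The waveform superimposes random-phase sinusoidal carriers (20 per
octave between 0.2 and 1.6 kHz by default), each amplitude-modulated by its
own ``s(g, t)``.

The working-memory task uses six ripple-velocity classes spaced 1.5 JND
apart in log2 velocity, drawn from an individualized pool of 17 stimuli at
0.5-JND spacing starting at omega = 4 cycles/s; the JND comes from an
adaptive staircase.  Each trial presents two items, retro-cues one of them,
imposes a 15-s maintenance period, and ends with a probe that matches the
relevant item in 50% of trials, matches neither item in 25%, and matches the
irrelevant item in 25%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "RippleSpec",
    "StimulusSet",
    "TrialTiming",
    "TrialSchedule",
    "StaircaseResult",
    "LogisticListener",
    "synthesize_ripple",
    "write_wav",
    "run_staircase",
    "staircase_target_proportion",
    "build_stimulus_set",
    "generate_trial_schedule",
]

VELOCITY_RANGE = (3.0, 48.0)  # admissible ripple velocities, cycles/s
N_CLASSES = 6
POOL_SIZE = 17


# ---------------------------------------------------------------------------
# Ripple synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RippleSpec:
    """Parameters of one moving ripple sound."""

    omega: float  # ripple velocity, cycles/s
    Omega: float = 1.0  # spectral density, cycles/octave
    duration: float = 1.0  # s
    f0: float = 200.0  # low spectral edge, Hz
    f_hi: float = 1600.0  # high spectral edge, Hz
    density: int = 20  # carrier sinusoids per octave
    depth: float = 0.9  # modulation depth D
    base: float = 1.0  # base offset D0
    phase: float = 0.0  # ripple phase psi, radians
    seed: int = 0  # seeds the random carrier phases

    def __post_init__(self) -> None:
        if not (self.f_hi > self.f0 > 0):
            raise ValueError("need f_hi > f0 > 0")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.density < 1:
            raise ValueError("density must be >= 1")
        if not (0 <= self.depth <= self.base):
            raise ValueError("need 0 <= depth D <= base D0")


def _carrier_octaves(spec: RippleSpec) -> np.ndarray:
    """Octave positions g of the carriers (log-spaced grid, cell centers)."""
    n_oct = math.log2(spec.f_hi / spec.f0)
    n = math.ceil(spec.density * n_oct)
    return (np.arange(n) + 0.5) * n_oct / n


def synthesize_ripple(
    spec: RippleSpec, sample_rate: float = 16000.0, peak_dbfs: float = -3.0
) -> np.ndarray:
    """Synthesize a moving ripple waveform.

    Carriers sit on a log-frequency grid (placement is not acoustically
    critical; a fixed grid keeps synthesis reproducible), carry independent
    seeded random phases, and are amplitude-modulated by s(g, t).  The output
    is peak-normalized to ``peak_dbfs``.
    """
    if sample_rate <= 2 * spec.f_hi:
        raise ValueError(
            f"sample_rate {sample_rate} violates Nyquist for f_hi {spec.f_hi}"
        )
    t = np.arange(round(spec.duration * sample_rate)) / sample_rate
    g = _carrier_octaves(spec)
    freqs = spec.f0 * 2.0**g
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(0, 2 * np.pi, size=len(g))
    env = spec.base + spec.depth * np.cos(
        2 * np.pi * (spec.omega * t[None, :] + spec.Omega * g[:, None]) + spec.phase
    )
    wave = np.sum(
        env * np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]), axis=0
    )
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = wave * (10.0 ** (peak_dbfs / 20.0) / peak)
    return wave


def write_wav(path, wave: np.ndarray, sample_rate: float = 16000.0) -> None:
    """Write a mono waveform (range [-1, 1]) as 16-bit PCM."""
    data = np.clip(wave, -1.0, 1.0)
    wavfile.write(path, int(sample_rate), (data * 32767).astype(np.int16))


# ---------------------------------------------------------------------------
# Adaptive staircase
# ---------------------------------------------------------------------------

# Transformed up-down rules: (consecutive correct to step down,
# consecutive incorrect to step up).  "1d2u" is the rule string as used for
# the discrimination-threshold procedure here; note that 1-down/2-up
# converges near 29.3% correct, which is unconventional for threshold
# tracking (2-down/1-up targets the usual 70.7% point) -- see
# ``staircase_target_proportion``.
_RULES = {"1d2u": (1, 2), "2d1u": (2, 1), "1d1u": (1, 1)}


def staircase_target_proportion(rule: str) -> float:
    """Asymptotic proportion correct tracked by a transformed up-down rule.

    At equilibrium the probability of a down step equals that of an up step:
    p^m = 1/2 for an m-down/1-up rule (p = 0.707 for 2d1u) and
    (1-p)^n = 1/2 for a 1-down/n-up rule (p = 0.293 for 1d2u).
    """
    m_down, n_up = _RULES[rule]
    if m_down > 1 and n_up > 1:
        raise ValueError("one of the step counts must be 1")
    if n_up == 1:
        return 0.5 ** (1.0 / m_down)
    return 1.0 - 0.5 ** (1.0 / n_up)


@dataclass
class LogisticListener:
    """Simulated listener with a logistic psychometric function.

    P(correct | interval x) = 1 / (1 + exp(-(x - threshold) / slope)).
    The p-correct point tracked by a rule is then
    threshold + slope * log(p / (1 - p)).
    """

    threshold: float = 0.2  # log2 ripple-velocity units
    slope: float = 0.05

    def p_correct(self, interval: float) -> float:
        return 1.0 / (1.0 + math.exp(-(interval - self.threshold) / self.slope))

    def interval_at(self, p: float) -> float:
        return self.threshold + self.slope * math.log(p / (1.0 - p))


@dataclass
class StaircaseResult:
    jnd: float
    converged: bool
    reversals: np.ndarray
    track: pd.DataFrame  # trial, interval, correct, reversal


def run_staircase(
    listener: Callable[[float], float] | LogisticListener,
    rule: str = "1d2u",
    start_interval: float = 1.0,
    initial_step: float = 0.2,
    final_step: float = 0.02,
    step_reversals: int = 4,
    stop_reversals: int = 12,
    averaged_reversals: int = 8,
    min_interval: float = 1e-4,
    max_interval: float = 4.0,
    max_trials: int = 2000,
    seed: int = 0,
) -> StaircaseResult:
    """Simulate a transformed up-down staircase and estimate the JND.

    ``listener`` maps an interval (log2 ripple-velocity units) to
    P(correct); steps are additive in log2 units, shrinking from
    ``initial_step`` to ``final_step`` after ``step_reversals`` reversals.
    The JND estimate is the mean interval over the last
    ``averaged_reversals`` reversals.  A track that fails to accumulate
    ``stop_reversals`` reversals within ``max_trials`` is flagged
    (``converged=False``) rather than raised.
    """
    if rule not in _RULES:
        raise ValueError(f"unknown staircase rule {rule!r}; expected {sorted(_RULES)}")
    m_down, n_up = _RULES[rule]
    p_of = listener.p_correct if hasattr(listener, "p_correct") else listener
    rng = np.random.default_rng(seed)

    interval = float(start_interval)
    step = float(initial_step)
    n_correct = n_wrong = 0
    direction = 0  # last step direction: -1 down, +1 up
    rows = []
    reversals: list[float] = []
    for trial in range(max_trials):
        correct = rng.random() < p_of(interval)
        move = 0
        if correct:
            n_correct += 1
            n_wrong = 0
            if n_correct >= m_down:
                move, n_correct = -1, 0
        else:
            n_wrong += 1
            n_correct = 0
            if n_wrong >= n_up:
                move, n_wrong = +1, 0
        is_reversal = move != 0 and direction != 0 and move != direction
        if is_reversal:
            reversals.append(interval)
            if len(reversals) == step_reversals:
                step = final_step
        rows.append((trial, interval, bool(correct), is_reversal))
        if move != 0:
            direction = move
            interval = float(np.clip(interval + move * step, min_interval, max_interval))
        if len(reversals) >= stop_reversals:
            break
    converged = len(reversals) >= stop_reversals
    tail = reversals[-averaged_reversals:] if reversals else [interval]
    track = pd.DataFrame(rows, columns=["trial", "interval", "correct", "reversal"])
    return StaircaseResult(
        jnd=float(np.mean(tail)), converged=converged,
        reversals=np.asarray(reversals), track=track,
    )


# ---------------------------------------------------------------------------
# Stimulus set
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSet:
    """Individualized stimulus pool and item classes.

    ``pool`` holds 17 ripple velocities at 0.5*JND spacing in log2 units
    starting at omega = 4 cycles/s; the 6 item classes sit at 1.5*JND
    spacing, i.e. pool indices 0, 3, 6, 9, 12, 15.  The irrelevant item of a
    class is offset by half a JND (one pool step).
    """

    jnd: float
    pool: tuple[RippleSpec, ...]
    class_pool_indices: tuple[int, ...]
    irrelevant_offset_steps: int = 1

    @property
    def pool_log2v(self) -> np.ndarray:
        return np.array([math.log2(s.omega) for s in self.pool])

    @property
    def class_log2v(self) -> np.ndarray:
        return self.pool_log2v[list(self.class_pool_indices)]

    def class_spec(self, klass: int) -> RippleSpec:
        return self.pool[self.class_pool_indices[klass]]

    def irrelevant_spec(self, klass: int) -> RippleSpec:
        return self.pool[self.class_pool_indices[klass] + self.irrelevant_offset_steps]


def build_stimulus_set(jnd: float, omega_start: float = 4.0, **spec_kwargs) -> StimulusSet:
    """Build the 17-stimulus pool and 6 item classes for a measured JND.

    Positioning of the class grid within the pool: classes anchor at the
    pool's low end (index 0 = the lowest velocity, 4 cycles/s) so the 1.5-JND
    class spacing lands exactly on every third 0.5-JND pool step.
    """
    if jnd <= 0:
        raise ValueError("jnd must be positive")
    lo, hi = VELOCITY_RANGE
    log2v = math.log2(omega_start) + 0.5 * jnd * np.arange(POOL_SIZE)
    velocities = 2.0**log2v
    if velocities[0] < lo or velocities[-1] > hi:
        raise ValueError(
            f"pool velocities {velocities[0]:.2f}-{velocities[-1]:.2f} c/s leave "
            f"the admissible range [{lo}, {hi}] (jnd={jnd})"
        )
    pool = tuple(RippleSpec(omega=float(v), **spec_kwargs) for v in velocities)
    class_idx = tuple(range(0, 3 * N_CLASSES, 3))  # 0,3,...,15
    return StimulusSet(jnd=float(jnd), pool=pool, class_pool_indices=class_idx)


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialTiming:
    """Within-trial event onsets (s, relative to trial start) and durations.

    The maintenance period is the 15 s between retro-cue offset and probe
    onset.  Inter-trial spacing and the lead-in are design choices of the
    synthetic protocol.
    """

    alert: float = 0.0
    alert_dur: float = 0.5
    item1: float = 1.0
    item2: float = 2.5
    item_dur: float = 1.0
    retrocue: float = 4.0
    retrocue_dur: float = 0.5
    maintenance_dur: float = 15.0
    probe_dur: float = 1.0
    response_cue_dur: float = 0.5
    trial_spacing: float = 25.0
    lead_in: float = 5.0

    @property
    def maintenance(self) -> float:
        return self.retrocue + self.retrocue_dur

    @property
    def probe(self) -> float:
        return self.maintenance + self.maintenance_dur

    @property
    def response_cue(self) -> float:
        return self.probe + self.probe_dur + 0.5

    def run_length(self, trials_per_run: int, tail: float = 15.0) -> float:
        last_start = self.lead_in + (trials_per_run - 1) * self.trial_spacing
        return last_start + self.response_cue + self.response_cue_dur + tail


PROBE_TYPES = ("match", "nonmatch_neither", "irrelevant_match")
_PROBE_COUNTS_PER_RUN = {"match": 12, "nonmatch_neither": 6, "irrelevant_match": 6}


@dataclass
class TrialSchedule:
    """Trial table plus the timing template used to place events."""

    trials: pd.DataFrame
    timing: TrialTiming
    stimset: StimulusSet
    seed: int

    @property
    def n_runs(self) -> int:
        return int(self.trials["run"].max()) + 1

    def run_trials(self, run: int) -> pd.DataFrame:
        return self.trials[self.trials["run"] == run].reset_index(drop=True)

    def events(self, run: int | None = None) -> pd.DataFrame:
        """BIDS-style long-format events (onset, duration, trial_type, ...)."""
        t = self.timing
        rows = []
        sub = self.trials if run is None else self.run_trials(run)
        for _, tr in sub.iterrows():
            t0 = tr["onset"]
            for ttype, on, dur in (
                ("alert", t.alert, t.alert_dur),
                ("item1", t.item1, t.item_dur),
                ("item2", t.item2, t.item_dur),
                ("retrocue", t.retrocue, t.retrocue_dur),
                ("probe", t.probe, t.probe_dur),
                ("response_cue", t.response_cue, t.response_cue_dur),
            ):
                rows.append(
                    {
                        "onset": t0 + on,
                        "duration": dur,
                        "trial_type": ttype,
                        "run": int(tr["run"]),
                        "trial": int(tr["trial"]),
                        "wm_class": int(tr["cued_class"]),
                        "irrelevant_class": int(tr["uncued_class"]),
                        "probe_type": tr["probe_type"],
                    }
                )
        return pd.DataFrame(rows).sort_values(["run", "onset"]).reset_index(drop=True)

    def to_events_tsv(self, path, run: int | None = None) -> None:
        self.events(run).to_csv(path, sep="\t", index=False)


def _balanced_uncued(cued: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A per-run uncued-class assignment: each class 4x, never equal to cued.

    Drawing uncued classes balanced (rather than uniformly at random) keeps
    the (run, class) exemplar grid complete when exemplars are re-labeled by
    the irrelevant item for the control analysis.
    """
    n = len(cued)
    base = np.repeat(np.arange(N_CLASSES), n // N_CLASSES)
    for _ in range(1000):
        cand = rng.permutation(base)
        bad = np.where(cand == cued)[0]
        # repair by pairwise swaps
        for i in bad:
            ok = np.where((cand != cued[i]) & (cued != cand[i]) & (cand != cand[i]))[0]
            if len(ok) == 0:
                break
            j = rng.choice(ok)
            cand[i], cand[j] = cand[j], cand[i]
        if not np.any(cand == cued):
            return cand
    raise RuntimeError("could not build a balanced uncued assignment")


def generate_trial_schedule(
    stimset: StimulusSet | None = None,
    n_runs: int = 4,
    trials_per_run: int = 24,
    timing: TrialTiming | None = None,
    seed: int = 0,
) -> TrialSchedule:
    """Generate a retro-cue trial schedule under the design constraints.

    Per run: each of the 6 classes is retro-cued exactly 4 times; retro-cue
    position (item 1 vs item 2) is balanced 12/12; probe types are
    match/nonmatch/irrelevant-match at 12/6/6 (i.e. 50%/25%/25% overall).
    Trial order is randomized by ``seed``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if trials_per_run % (2 * N_CLASSES) != 0 or trials_per_run % 4 != 0:
        raise ValueError(
            f"trials_per_run={trials_per_run} cannot satisfy class balance, "
            "retro-cue balance, and the 50/25/25 probe mix"
        )
    if stimset is None:
        stimset = build_stimulus_set(jnd=0.2)
    timing = timing or TrialTiming()
    rng = np.random.default_rng(seed)
    pool_v = stimset.pool_log2v
    per_class = trials_per_run // N_CLASSES
    probe_counts = {k: v * trials_per_run // 24 for k, v in _PROBE_COUNTS_PER_RUN.items()}

    rows = []
    for run in range(n_runs):
        cued = rng.permutation(np.repeat(np.arange(N_CLASSES), per_class))
        uncued = _balanced_uncued(cued, rng)
        pos = rng.permutation(
            np.repeat([1, 2], trials_per_run // 2)
        )  # retro-cued item position
        ptypes = rng.permutation(
            [pt for pt, k in probe_counts.items() for _ in range(k)]
        )
        for i in range(trials_per_run):
            c, u = int(cued[i]), int(uncued[i])
            cued_v = pool_v[stimset.class_pool_indices[c]]
            irr_v = pool_v[
                stimset.class_pool_indices[u] + stimset.irrelevant_offset_steps
            ]
            ptype = ptypes[i]
            if ptype == "match":
                probe_v = cued_v
            elif ptype == "irrelevant_match":
                probe_v = irr_v
            else:  # neither item: any pool stimulus distinct from both items
                cand = [v for v in pool_v if v not in (cued_v, irr_v)]
                probe_v = float(rng.choice(cand))
            item1_c, item2_c = (c, u) if pos[i] == 1 else (u, c)
            rows.append(
                {
                    "run": run,
                    "trial": i,
                    "onset": timing.lead_in + i * timing.trial_spacing,
                    "item1_class": item1_c,
                    "item2_class": item2_c,
                    "retrocue_pos": int(pos[i]),
                    "cued_class": c,
                    "uncued_class": u,
                    "cued_log2v": float(cued_v),
                    "irrelevant_log2v": float(irr_v),
                    "probe_log2v": float(probe_v),
                    "probe_type": ptype,
                }
            )
    trials = pd.DataFrame(rows)
    return TrialSchedule(trials=trials, timing=timing, stimset=stimset, seed=seed)
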