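"""Design matrices, nuisance residualization, and content-specific betas.

The connectivity analysis works on residuals of a task GLM: event regressors
(alert, the two items, retro-cue, probe, response cue) convolved with a
canonical double-gamma HRF, a per-run Legendre polynomial drift block acting
as a high-pass filter with 0.006 Hz cutoff, and optional confound channels
are regressed out of every subROI time series by ordinary least squares.
Content (class) boxcar regressors are *excluded* from that residualization —
they would remove the maintenance-period signal of interest — and are used
only on the activation path, where per-run per-class contrast effect sizes
("content betas") serve as decoding features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import legendre
from scipy import stats

from .synthetic_fmri import AcqConfig

__all__ = [
    "double_gamma_hrf",
    "drift_order",
    "build_design_matrix",
    "residualize",
    "extract_maintenance_segments",
    "content_betas",
    "CONTENT_DELAY_S",
]

HIGHPASS_HZ = 0.006
CONTENT_DELAY_S = 4.0  # content boxcars start this long after retro-cue onset
_OVERSAMPLE = 16  # HRF convolution grid, samples per TR


def double_gamma_hrf(
    tr: float,
    oversample: int = _OVERSAMPLE,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 6.0,
    length: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled on the oversampled grid.

    Gamma density peaking at ``peak`` s minus a 1/``ratio``-scaled gamma
    peaking at ``undershoot`` s, normalized to unit peak.
    """
    dt = tr / oversample
    t = np.arange(0, length, dt)
    h = stats.gamma.pdf(t, peak) - stats.gamma.pdf(t, undershoot) / ratio
    return h / h.max()


def drift_order(run_length: float, cutoff_hz: float = HIGHPASS_HZ) -> int:
    """Legendre drift order approximating a high-pass at ``cutoff_hz``.

    order = max(1, round(2 * cutoff * run_length)); e.g. 0.006 Hz over a
    600-s run gives round(7.2) = 7.
    """
    return max(1, round(2.0 * cutoff_hz * run_length))


def _convolve_boxcars(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_scans: int,
    tr: float,
    hrf: np.ndarray,
    oversample: int = _OVERSAMPLE,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at TR-grid frame times."""
    dt = tr / oversample
    n_hi = n_scans * oversample
    box = np.zeros(n_hi + len(hrf))
    for on, dur in zip(onsets, durations):
        i0 = int(round(on / dt))
        i1 = max(i0 + 1, int(round((on + dur) / dt)))
        if i0 >= n_hi:
            continue
        box[i0 : min(i1, n_hi)] = 1.0
    conv = np.convolve(box, hrf)[:n_hi]
    return conv[::oversample]


def build_design_matrix(
    events: pd.DataFrame,
    acq: AcqConfig,
    confounds: np.ndarray | pd.DataFrame | None = None,
    content_regressors: bool = False,
    n_classes: int = 6,
    cutoff_hz: float = HIGHPASS_HZ,
) -> pd.DataFrame:
    """Build one run's design matrix on the TR grid.

    ``events`` is a long-format table (onset, duration, trial_type) for a
    single run; each distinct trial_type becomes one HRF-convolved
    regressor.  The drift block holds Legendre polynomials (orders
    0..``drift_order``) over the run.  With ``content_regressors=True`` a
    boxcar per class spans [retro-cue onset + 4 s, probe onset), convolved
    with the HRF; this requires ``wm_class`` and per-trial retrocue/probe
    rows in ``events``.
    """
    n_scans = acq.n_scans
    if len(events) and (events["onset"] + events["duration"]).max() > acq.run_length:
        raise ValueError("events extend past the end of the run")
    hrf = double_gamma_hrf(acq.tr)
    cols: dict[str, np.ndarray] = {}
    for ttype in sorted(events["trial_type"].unique()) if len(events) else []:
        sub = events[events["trial_type"] == ttype]
        cols[ttype] = _convolve_boxcars(
            sub["onset"].to_numpy(), sub["duration"].to_numpy(), n_scans, acq.tr, hrf
        )
    if content_regressors:
        need = {"retrocue", "probe"}
        if not need <= set(events.get("trial_type", [])):
            raise ValueError("content regressors need retrocue and probe events")
        cues = events[events["trial_type"] == "retrocue"].sort_values("trial")
        probes = events[events["trial_type"] == "probe"].sort_values("trial")
        for c in range(n_classes):
            mask = cues["wm_class"].to_numpy() == c
            ons = cues["onset"].to_numpy()[mask] + CONTENT_DELAY_S
            offs = probes["onset"].to_numpy()[mask]
            cols[f"class_{c}"] = _convolve_boxcars(
                ons, np.maximum(offs - ons, 0.0), n_scans, acq.tr, hrf
            )
    if confounds is not None:
        arr = np.asarray(confounds, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.shape[0] != n_scans:
            raise ValueError("confounds length does not match run length")
        names = (
            list(confounds.columns)
            if isinstance(confounds, pd.DataFrame)
            else [f"confound_{i}" for i in range(arr.shape[1])]
        )
        for name, col in zip(names, arr.T):
            cols[str(name)] = col
    order = drift_order(acq.run_length, cutoff_hz)
    x = np.linspace(-1, 1, n_scans)
    for k in range(order + 1):
        cols[f"drift_{k}"] = legendre.legval(x, [0.0] * k + [1.0])
    dm = pd.DataFrame(cols, index=np.arange(n_scans) * acq.tr)
    return _prune_rank_deficient(dm)


def _prune_rank_deficient(dm: pd.DataFrame) -> pd.DataFrame:
    """Drop trailing columns that add no rank (degenerate regressors)."""
    X = dm.to_numpy()
    keep: list[int] = []
    rank = 0
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            warnings.warn(f"dropping rank-deficient regressor {dm.columns[j]!r}")
    return dm.iloc[:, keep]


def residualize(ts: np.ndarray, design: pd.DataFrame) -> np.ndarray:
    """OLS residuals of every subROI time series against the design.

    ``ts`` is units x time; returns the same shape with all design columns
    projected out (residuals orthogonal to every column).
    """
    X = design.to_numpy()
    if ts.shape[1] != X.shape[0]:
        raise ValueError(f"time axis mismatch: ts {ts.shape[1]} vs design {X.shape[0]}")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    return ts - (X @ beta).T


def _lag_samples(acq: AcqConfig) -> int:
    ratio = acq.lag / acq.tr
    if abs(ratio - round(ratio)) > 0.01:
        raise ValueError(
            f"hemodynamic lag {acq.lag} s is not an integer multiple of TR {acq.tr} s"
        )
    return int(round(ratio))


def maintenance_window_indices(
    trial: pd.Series, acq: AcqConfig, timing, anchor: str = "retrocue"
) -> tuple[int, int]:
    """TR-grid index window [start, stop) for one trial's lagged maintenance.

    The window runs from the anchor (retro-cue onset by default, or
    maintenance onset = retro-cue offset) plus the hemodynamic lag, to probe
    onset plus lag; onsets floor to the grid, offsets ceil (half-open).
    """
    lag = _lag_samples(acq) * acq.tr
    t0 = trial["onset"] + (timing.retrocue if anchor == "retrocue" else timing.maintenance)
    t1 = trial["onset"] + timing.probe
    return math.floor((t0 + lag) / acq.tr), math.ceil((t1 + lag) / acq.tr)


def extract_maintenance_segments(
    residuals: np.ndarray,
    run_trials: pd.DataFrame,
    acq: AcqConfig,
    timing,
    label_by: str = "cued",
    anchor: str = "retrocue",
    n_classes: int = 6,
) -> dict[int, np.ndarray]:
    """Per-class concatenated lagged maintenance segments for one run.

    Samples in [anchor + lag, probe + lag) of each trial are concatenated
    across the trials sharing a retro-cued class (``label_by="cued"``) or,
    for the irrelevant-item control, the non-cued class
    (``label_by="uncued"``).  Trials whose window leaves the run are dropped
    with a warning.
    """
    if label_by not in ("cued", "uncued"):
        raise ValueError("label_by must be 'cued' or 'uncued'")
    key = "cued_class" if label_by == "cued" else "uncued_class"
    n_t = residuals.shape[1]
    chunks: dict[int, list[np.ndarray]] = {c: [] for c in range(n_classes)}
    for _, trial in run_trials.iterrows():
        i0, i1 = maintenance_window_indices(trial, acq, timing, anchor)
        if i1 > n_t:
            warnings.warn(
                f"trial {int(trial['trial'])}: maintenance window exceeds run; dropped"
            )
            continue
        chunks[int(trial[key])].append(residuals[:, i0:i1])
    return {
        c: (np.concatenate(parts, axis=1) if parts else np.empty((residuals.shape[0], 0)))
        for c, parts in chunks.items()
    }


def content_betas(
    ts: np.ndarray,
    design: pd.DataFrame,
    n_classes: int = 6,
) -> dict[int, np.ndarray]:
    """Per-class OLS contrast effect sizes across units for one run.

    ``design`` must contain the ``class_c`` content columns; the contrast
    for class c picks out its content regressor, so the returned vector is
    simply that regressor's beta over units.
    """
    missing = [c for c in range(n_classes) if f"class_{c}" not in design.columns]
    if missing:
        raise ValueError(f"design lacks content columns for classes {missing}")
    X = design.to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, ts.T, rcond=None)
    col = {name: i for i, name in enumerate(design.columns)}
    return {c: beta[col[f"class_{c}"]].copy() for c in range(n_classes)}
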