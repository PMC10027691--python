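"""Group-level maximum-statistic permutation testing over unit families.

A "family" is the set of units tested together — e.g. all 2500 candidate
2-4-ROI connectivity networks, or the 86 activation ROIs.  For each of
``n_perm`` permutations, class labels are shuffled independently within
each run (the exchangeability block), *with the same shuffled labels
applied to every unit within a subject* — required for a valid family-wise
maximum.  Each unit's group-mean cross-validated accuracy is computed under
the shuffled labels and the family-wide maximum is recorded; the observed
group mean of a unit is then compared against this null with

    p = max(1, #{null >= observed}) / n_perm

(ties count against the observation; the floor makes the smallest
attainable p equal 1/n_perm, i.e. 0.002 at 500 permutations).

Labels are permuted on precomputed exemplars: the connectivity features
themselves do not depend on the class labels used by the classifier, so
shuffling labels of precomputed (run, class) exemplars is equivalent to
recomputing features under shuffled trial labels, at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import (
    correlation_stack,
    network_exemplars,
    within_roi_pattern,
)
from .decoding import (
    accuracy_from_fold_cache,
    gram_matrix,
    loro_cv_decode_gram,
    make_fold_cache,
)
from .glm import (
    build_design_matrix,
    content_betas,
    extract_maintenance_segments,
    residualize,
)
from .roi_registry import ROIDef, ROINetwork, build_registry, enumerate_networks, filter_networks
from .stimuli import N_CLASSES
from .synthetic_fmri import SessionData

__all__ = [
    "NullDistribution",
    "permute_labels_within_runs",
    "build_null",
    "assign_pvalue",
    "subject_unit_grams",
    "run_family_analysis",
    "FAMILY_MODES",
]

FAMILY_MODES = (
    "connectivity-2500",
    "activation-86",
    "irrelevant-item",
    "within-roi-control",
    "oc-control",
)


@dataclass
class NullDistribution:
    """Per-permutation family-wise maxima of group-mean accuracy."""

    max_stats: np.ndarray
    family: tuple[str, ...]
    seed: int
    unit_nulls: np.ndarray | None = None  # optional n_perm x n_units accuracies

    @property
    def n_perm(self) -> int:
        return len(self.max_stats)


def permute_labels_within_runs(
    labels: np.ndarray, runs: np.ndarray, rng: np.random.Generator | int
) -> np.ndarray:
    """Shuffle labels independently and uniformly within each run block."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    out = labels.copy()
    for r in np.unique(runs):
        idx = np.where(runs == r)[0]
        out[idx] = labels[idx][rng.permutation(len(idx))]
    return out


def _group_means(grams: np.ndarray, labels: np.ndarray, runs: np.ndarray,
                 subject_labels: list[np.ndarray] | None = None) -> np.ndarray:
    """Group-mean accuracy per unit; optional per-subject label vectors."""
    n_units, n_subjects = grams.shape[:2]
    means = np.empty(n_units)
    for u in range(n_units):
        accs = [
            loro_cv_decode_gram(
                grams[u, s],
                subject_labels[s] if subject_labels is not None else labels,
                runs,
                with_confusion=False,
            ).accuracy
            for s in range(n_subjects)
        ]
        means[u] = float(np.mean(accs))
    return means


def build_null(
    grams: np.ndarray,
    labels: np.ndarray,
    runs: np.ndarray,
    n_perm: int = 500,
    seed: int = 0,
    family: tuple[str, ...] | None = None,
    keep_unit_nulls: bool = False,
) -> NullDistribution:
    """Family-wise max-statistic null over precomputed exemplar Grams.

    ``grams`` has shape (n_units, n_subjects, n_exemplars, n_exemplars).
    Each permutation draws one within-run label shuffle per subject, shared
    across all units of that subject.  The identity permutation is not
    excluded from the draws (standard Monte-Carlo practice).
    """
    grams = np.asarray(grams)
    n_units, n_subjects = grams.shape[:2]
    # class labels are permuted; the Gram blocks are not, so slice them once
    caches = [
        [make_fold_cache(grams[u, s], runs) for s in range(n_subjects)]
        for u in range(n_units)
    ]
    _, label_idx = np.unique(labels, return_inverse=True)
    rng = np.random.default_rng(seed)
    max_stats = np.empty(n_perm)
    unit_nulls = np.empty((n_perm, n_units)) if keep_unit_nulls else None
    for p in range(n_perm):
        ys = [
            permute_labels_within_runs(label_idx, runs, rng).astype(np.float64)
            for _ in range(n_subjects)
        ]
        means = np.array(
            [
                np.mean([accuracy_from_fold_cache(caches[u][s], ys[s])
                         for s in range(n_subjects)])
                for u in range(n_units)
            ]
        )
        if unit_nulls is not None:
            unit_nulls[p] = means
        max_stats[p] = means.max()
    return NullDistribution(
        max_stats=max_stats,
        family=tuple(family) if family is not None else tuple(str(u) for u in range(n_units)),
        seed=seed,
        unit_nulls=unit_nulls,
    )


def assign_pvalue(observed: float, null: NullDistribution) -> float:
    """Permutation p-value with floor 1/n_perm; ties count against the observation."""
    if null.n_perm == 0:
        raise ValueError("empty null distribution")
    k = int(np.sum(null.max_stats >= observed))
    return max(1, k) / null.n_perm


# ---------------------------------------------------------------------------
# Cohort-level orchestration
# ---------------------------------------------------------------------------


def _session_correlation_stack(
    session: SessionData, label_by: str, anchor: str
) -> dict[tuple[int, int], np.ndarray]:
    """Residualize each run and correlate lagged per-class maintenance segments."""
    acq, sched = session.acq, session.schedule
    segments: dict[tuple[int, int], np.ndarray] = {}
    for run in range(acq.n_runs):
        design = build_design_matrix(
            sched.events(run), acq, confounds=session.confounds[run]
        )
        resid = residualize(session.runs[run], design)
        segs = extract_maintenance_segments(
            resid, sched.run_trials(run), acq, sched.timing,
            label_by=label_by, anchor=anchor,
        )
        for c, seg in segs.items():
            segments[(run, c)] = seg
    return correlation_stack(segments)


def subject_unit_grams(
    session: SessionData,
    units: list[ROINetwork | ROIDef],
    label_by: str = "cued",
    anchor: str = "retrocue",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exemplar Gram matrix per unit for one subject.

    Returns (grams, labels, runs): grams has shape (n_units, 24, 24) for the
    default 4 runs x 6 classes.  Networks yield inter-ROI connectivity
    features; bare ROIs yield the within-ROI upper-triangle control pattern.
    """
    slices = session.registry.subroi_slices()
    stack = _session_correlation_stack(session, label_by, anchor)
    grams, labels, runs = [], None, None
    for unit in units:
        if isinstance(unit, ROINetwork):
            feats = network_exemplars(stack, unit, slices)
        else:
            feats = within_roi_pattern(stack, unit, slices)
        grams.append(gram_matrix(feats.exemplars))
        labels, runs = feats.labels, feats.runs
    return np.asarray(grams), labels, runs


def _activation_grams(
    session: SessionData, rois: list[ROIDef]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-ROI content-beta exemplar Grams (activation-based MVPA path)."""
    acq, sched = session.acq, session.schedule
    slices = session.registry.subroi_slices()
    betas: dict[tuple[int, int], np.ndarray] = {}
    for run in range(acq.n_runs):
        design = build_design_matrix(
            sched.events(run), acq, confounds=session.confounds[run],
            content_regressors=True,
        )
        for c, vec in content_betas(session.runs[run], design).items():
            betas[(run, c)] = vec
    keys = sorted(betas)
    labels = np.asarray([c for _, c in keys])
    runs = np.asarray([r for r, _ in keys])
    grams = []
    for roi in rois:
        X = np.asarray([betas[key][slices[roi.name]] for key in keys])
        grams.append(gram_matrix(X))
    return np.asarray(grams), labels, runs


def run_family_analysis(
    mode: str,
    cohort: list[SessionData],
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    family: list | None = None,
    max_units: int | None = None,
    anchor: str = "retrocue",
) -> tuple[pd.DataFrame, NullDistribution]:
    """Observed accuracies, max-statistic null, and significance for a family.

    Modes: ``connectivity-2500`` (all 2-4-ROI networks), ``activation-86``
    (per-ROI content betas), ``irrelevant-item`` (connectivity networks
    relabeled by the non-cued item), ``within-roi-control`` (per-ROI
    upper-triangle patterns), ``oc-control`` (networks containing occipital
    cortex but no superior temporal cortex).  ``family`` overrides the
    default unit list; ``max_units`` deterministically subsamples large
    families for desk-scale runs (seeded, reported in the output).
    """
    if mode not in FAMILY_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {FAMILY_MODES}")
    registry = cohort[0].registry
    label_by = "uncued" if mode == "irrelevant-item" else "cued"

    if family is None:
        if mode in ("connectivity-2500", "irrelevant-item"):
            family = enumerate_networks(registry)
        elif mode == "oc-control":
            nets = enumerate_networks(registry)
            oc = [r.name for r in registry if r.area == "OC"]
            stc = [r.name for r in registry if r.area == "STC"]
            family = filter_networks(nets, must_include=oc, must_exclude=stc)
        elif mode == "within-roi-control":
            family = [r for r in registry if r.n_subrois >= 2]
        else:  # activation-86
            family = list(registry.rois)
    if max_units is not None and len(family) > max_units:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(family), size=max_units, replace=False))
        family = [family[i] for i in idx]

    unit_names = [u.label if isinstance(u, ROINetwork) else u.name for u in family]
    per_subject = []
    for session in cohort:
        if mode == "activation-86":
            grams, labels, runs = _activation_grams(session, family)
        else:
            grams, labels, runs = subject_unit_grams(
                session, family, label_by=label_by, anchor=anchor
            )
        per_subject.append(grams)
    # (n_units, n_subjects, n_ex, n_ex)
    grams = np.stack(per_subject, axis=1)

    observed = _group_means(grams, labels, runs)
    null = build_null(
        grams, labels, runs, n_perm=n_perm, seed=seed, family=tuple(unit_names)
    )
    pvals = np.asarray([assign_pvalue(obs, null) for obs in observed])
    report = pd.DataFrame(
        {
            "unit": unit_names,
            "observed": observed,
            "p": pvals,
            "significant": pvals <= alpha,
            "n_subjects": len(cohort),
            "mode": mode,
        }
    )
    return report, null
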