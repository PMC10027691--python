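"""Class-specific inter-ROI correlation matrices and pattern feature vectors.

For each run and maintained class, the Pearson correlation between every
subROI of ROI A and every subROI of ROI B is computed over the concatenated
(lagged) maintenance segments of that class — the concatenated series is
treated as a single sample, joins included.  A network's "connectivity
pattern" concatenates the flattened matrices of all its ROI pairs in
canonical order, yielding one feature vector per (run, class): a 24-exemplar
dataset over 4 runs x 6 classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .roi_registry import ROIDef, ROINetwork, ROIRegistry
from .stimuli import N_CLASSES

__all__ = [
    "ConnMatrix",
    "PatternFeatures",
    "pearson_cross_correlation",
    "class_connectivity_matrix",
    "correlation_stack",
    "assemble_pattern",
    "network_exemplars",
    "within_roi_pattern",
]


@dataclass(frozen=True)
class ConnMatrix:
    """SubROI-to-subROI correlation block between two ROIs for one (run, class)."""

    roi_a: str
    roi_b: str
    values: np.ndarray  # N_A x N_B, in [-1, 1]
    run: int
    klass: int


@dataclass
class PatternFeatures:
    """Exemplar matrix of one unit (network or within-ROI pattern)."""

    unit: str
    exemplars: np.ndarray  # (n_runs * n_classes) x T
    labels: np.ndarray  # class per exemplar
    runs: np.ndarray  # run tag per exemplar
    label_source: str = "wm_item"


def pearson_cross_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Product-moment correlation of every row of ``a`` with every row of ``b``.

    Rows with zero variance yield 0 (with a warning) instead of NaN so that
    degenerate synthetic inputs remain classifiable.
    """
    if a.shape[1] != b.shape[1]:
        raise ValueError("row length mismatch")
    if a.shape[1] < 3:
        raise ValueError("need at least 3 samples to correlate")
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt(np.sum(ac**2, axis=1))
    sb = np.sqrt(np.sum(bc**2, axis=1))
    dead_a, dead_b = sa == 0, sb == 0
    if dead_a.any() or dead_b.any():
        warnings.warn("zero-variance series: correlations set to 0")
        sa = np.where(dead_a, 1.0, sa)
        sb = np.where(dead_b, 1.0, sb)
    r = (ac @ bc.T) / np.outer(sa, sb)
    if dead_a.any():
        r[dead_a, :] = 0.0
    if dead_b.any():
        r[:, dead_b] = 0.0
    return np.clip(r, -1.0, 1.0)


def class_connectivity_matrix(
    segments: dict[str, np.ndarray] | np.ndarray,
    roi_a: str | ROIDef,
    roi_b: str | ROIDef,
    run: int = 0,
    klass: int = 0,
    slices: dict[str, slice] | None = None,
) -> ConnMatrix:
    """Correlation matrix between two ROIs over one (run, class) segment.

    ``segments`` is either a mapping of ROI name to subROI x samples arrays,
    or a stacked all-subROI matrix together with registry ``slices``.
    """
    name_a = roi_a.name if isinstance(roi_a, ROIDef) else roi_a
    name_b = roi_b.name if isinstance(roi_b, ROIDef) else roi_b
    if isinstance(segments, dict):
        seg_a, seg_b = segments[name_a], segments[name_b]
    else:
        if slices is None:
            raise ValueError("stacked segments require registry slices")
        seg_a, seg_b = segments[slices[name_a]], segments[slices[name_b]]
    return ConnMatrix(
        roi_a=name_a, roi_b=name_b,
        values=pearson_cross_correlation(seg_a, seg_b), run=run, klass=klass,
    )


def correlation_stack(
    segments_by_run_class: dict[tuple[int, int], np.ndarray],
    dtype=np.float32,
) -> dict[tuple[int, int], np.ndarray]:
    """Full subROI x subROI correlation matrix per (run, class).

    Input maps (run, class) to the stacked all-subROI segment matrix; the
    full correlation matrix is computed once and network feature vectors are
    sliced out of it, so the cost is shared across all candidate networks.
    """
    return {
        key: pearson_cross_correlation(seg, seg).astype(dtype)
        for key, seg in segments_by_run_class.items()
    }


def assemble_pattern(
    network: ROINetwork,
    matrices: dict[tuple[int, int], list[ConnMatrix]],
    label_source: str = "wm_item",
) -> PatternFeatures:
    """Concatenate pairwise matrices into the network's exemplar matrix.

    Feature order is deterministic: ROI pairs in canonical (name-sorted)
    network order, each N_A x N_B block flattened row-major with the
    first-named ROI's subROIs on rows.  Matrices arriving transposed (B, A)
    are reoriented, so input orientation and arrival order do not matter.
    """
    keys = sorted(matrices)
    rows, labels, runs = [], [], []
    for run, klass in keys:
        blocks = []
        have = {}
        for m in matrices[(run, klass)]:
            have[(m.roi_a, m.roi_b)] = m.values
            have[(m.roi_b, m.roi_a)] = m.values.T
        for a, b in network.pairs():
            if (a.name, b.name) not in have:
                raise ValueError(
                    f"missing connectivity matrix {a.name}-{b.name} for "
                    f"run {run}, class {klass}"
                )
            blocks.append(have[(a.name, b.name)].ravel())
        rows.append(np.concatenate(blocks))
        labels.append(klass)
        runs.append(run)
    exemplars = np.asarray(rows, dtype=float)
    if exemplars.shape[1] != network.feature_len:
        raise ValueError(
            f"assembled {exemplars.shape[1]} features, expected {network.feature_len}"
        )
    return PatternFeatures(
        unit=network.label, exemplars=exemplars,
        labels=np.asarray(labels), runs=np.asarray(runs), label_source=label_source,
    )


def network_exemplars(
    stack: dict[tuple[int, int], np.ndarray],
    network: ROINetwork,
    slices: dict[str, slice],
    label_source: str = "wm_item",
) -> PatternFeatures:
    """Slice a network's exemplar matrix out of full correlation matrices."""
    keys = sorted(stack)
    rows = []
    for key in keys:
        full = stack[key]
        rows.append(
            np.concatenate(
                [full[slices[a.name], slices[b.name]].ravel() for a, b in network.pairs()]
            )
        )
    return PatternFeatures(
        unit=network.label,
        exemplars=np.asarray(rows, dtype=float),
        labels=np.asarray([k for _, k in keys]),
        runs=np.asarray([r for r, _ in keys]),
        label_source=label_source,
    )


def within_roi_pattern(
    stack: dict[tuple[int, int], np.ndarray],
    roi: ROIDef,
    slices: dict[str, slice],
    label_source: str = "wm_item",
) -> PatternFeatures:
    """Within-ROI control: upper-triangle subROI correlations as features.

    An ROI with N subROIs yields N*(N-1)/2 features (diagonal excluded).
    """
    if roi.n_subrois < 2:
        raise ValueError("within-ROI pattern needs at least 2 subROIs")
    iu = np.triu_indices(roi.n_subrois, k=1)
    keys = sorted(stack)
    rows = [stack[key][slices[roi.name], slices[roi.name]][iu] for key in keys]
    return PatternFeatures(
        unit=roi.name,
        exemplars=np.asarray(rows, dtype=float),
        labels=np.asarray([k for _, k in keys]),
        runs=np.asarray([r for r, _ in keys]),
        label_source=label_source,
    )
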