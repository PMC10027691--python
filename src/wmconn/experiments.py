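"""Canned synthetic experiments exercising the full pipeline.

These presets wire generator, GLM, features, decoding, and inference
together under the study's task design (4 runs x 24 trials x 6 classes,
TR 1.47 s, 15-s maintenance, 4.41-s lag) at desk-scale problem sizes:
cohorts of ~8 subjects, 99-permutation nulls, and 50-unit families instead
of the full 2500-network x 500-permutation sweep, which the same functions
support by raising the arguments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .inference import run_family_analysis, subject_unit_grams, _group_means
from .roi_registry import ROIRegistry, ROINetwork, build_registry, enumerate_networks, registry_from_frame
from .synthetic_fmri import AcqConfig, GroundTruth, simulate_cohort

__all__ = [
    "uniform_registry",
    "planted_network_family",
    "detection_replicate",
    "chance_experiment",
    "fwe_replicate",
    "DEFAULT_PLANTED",
]

DEFAULT_PLANTED = ("LSMG", "LSTC", "RSTC")


def uniform_registry(n_rois: int = 8, n_subrois: int = 4) -> ROIRegistry:
    """Small registry of identically sized ROIs for fast simulations."""
    table = pd.DataFrame(
        {
            "name": [f"R{i:02d}" for i in range(n_rois)],
            "area": [f"A{i:02d}" for i in range(n_rois)],
            "hemisphere": ["left", "right"] * (n_rois // 2) + ["left"] * (n_rois % 2),
            "n_subrois": [n_subrois] * n_rois,
        }
    )
    return registry_from_frame(table, mode="custom")


def planted_network_family(
    registry: ROIRegistry,
    planted: tuple[str, ...] = DEFAULT_PLANTED,
    n_networks: int = 50,
    seed: int = 0,
) -> list[ROINetwork]:
    """The planted network plus a sample of networks it cannot leak into.

    Content-specific coupling lives on ROI *pairs*: any network containing
    two or more of the planted ROIs contains an informative pair and
    legitimately carries the signal.  A family suited to asking "is exactly
    the planted network flagged?" therefore samples its comparison networks
    from those sharing at most one ROI with the planted set.
    """
    nets = enumerate_networks(registry)
    planted_set = set(planted)
    planted_net = next(n for n in nets if set(n.names) == planted_set)
    eligible = [n for n in nets if len(set(n.names) & planted_set) <= 1]
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n_networks - 1, replace=False)
    return [planted_net] + [eligible[i] for i in sorted(idx)]


def detection_replicate(
    seed: int,
    coupling: float = 0.6,
    n_subjects: int = 8,
    n_perm: int = 99,
    n_networks: int = 50,
    alpha: float = 0.05,
    planted: tuple[str, ...] = DEFAULT_PLANTED,
) -> dict:
    """One planted-coupling cohort through the max-statistic analysis.

    Returns the planted network's observed group accuracy and p-value,
    whether the significant set is exactly the planted network, and whether
    any occipital-containing, STC-free control network was flagged.
    """
    registry = build_registry("connectivity-16")
    truth = GroundTruth(signal_networks=(planted,), coupling_strength=coupling)
    cohort = simulate_cohort(n_subjects, registry, AcqConfig(), truth, seed=seed)
    family = planted_network_family(registry, planted, n_networks, seed=seed)
    report, null = run_family_analysis(
        "connectivity-2500", cohort, n_perm=n_perm, alpha=alpha, seed=seed,
        family=family,
    )
    planted_label = "+".join(sorted(planted))
    row = report[report["unit"] == planted_label].iloc[0]
    sig = set(report[report["significant"]]["unit"])
    oc_no_stc = {
        n.label for n in family
        if ({"LOC", "ROC"} & set(n.names)) and not ({"LSTC", "RSTC"} & set(n.names))
    }
    return {
        "planted_observed": float(row["observed"]),
        "planted_p": float(row["p"]),
        "exact_detection": sig == {planted_label},
        "planted_detected": planted_label in sig,
        "oc_control_flagged": bool(sig & oc_no_stc),
        "n_significant": len(sig),
        "report": report,
        "null": null,
    }


def chance_experiment(
    seed: int,
    n_subjects: int = 8,
    n_networks: int = 10,
) -> dict:
    """Signal-free cohort: six-class decoding should sit at chance (1/6).

    Returns the grand mean accuracy over subjects and networks, the SEM of
    the per-subject means, and the per-subject accuracy matrix.
    """
    registry = build_registry("connectivity-16")
    cohort = simulate_cohort(
        n_subjects, registry, AcqConfig(), GroundTruth(), seed=seed
    )
    rng = np.random.default_rng(seed)
    nets = enumerate_networks(registry)
    family = [nets[i] for i in sorted(rng.choice(len(nets), n_networks, replace=False))]
    per_subject = []
    for session in cohort:
        grams, labels, runs = subject_unit_grams(session, family)
        accs = _group_means(grams[:, None], labels, runs)  # one subject per unit
        per_subject.append(accs)
    acc = np.asarray(per_subject)  # n_subjects x n_networks
    subject_means = acc.mean(axis=1)
    sem = subject_means.std(ddof=1) / np.sqrt(n_subjects)
    return {
        "mean_accuracy": float(acc.mean()),
        "sem": float(sem),
        "per_subject": acc,
        "chance": 1.0 / 6.0,
    }


def fwe_replicate(
    seed: int,
    n_subjects: int = 4,
    n_perm: int = 99,
    n_networks: int = 50,
    alpha: float = 0.05,
    n_rois: int = 8,
    n_subrois: int = 4,
) -> bool:
    """One signal-free cohort; True if *any* unit comes out significant.

    Uses a small uniform registry so that the family-wise error rate can be
    estimated over many replicate cohorts at desk scale.
    """
    registry = uniform_registry(n_rois, n_subrois)
    cohort = simulate_cohort(
        n_subjects, registry, AcqConfig(), GroundTruth(), seed=seed
    )
    report, _ = run_family_analysis(
        "connectivity-2500", cohort, n_perm=n_perm, alpha=alpha, seed=seed,
        max_units=n_networks,
    )
    return bool(report["significant"].any())
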