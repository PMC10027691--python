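"""ROI/subROI bookkeeping and enumeration of candidate connectivity networks.

The connectivity analysis operates on 16 cortical regions of interest
(8 bilateral areas: superior temporal cortex STC, middle frontal gyrus MFG,
inferior frontal gyrus IFG, precentral cortex PreC, supramarginal gyrus SMG,
angular gyrus AG, superior parietal lobule SPL, and occipital cortex OC as a
control area), each tiled into smaller "subROIs".  A *network* is an
unordered set of 2-4 ROIs; its feature vector concatenates the subROI-by-
subROI correlation matrices of every ROI pair, so a network over ROIs with
subROI counts ``N_A, N_B, ...`` yields ``T = sum over pairs of N_A * N_B``
features.

Registries are data-driven: the packaged TSV tables carry name, hemisphere,
subROI count, and an ``inferred`` flag marking entries whose counts are not
anatomically constrained (PreC, and all activation-mode voxel-count proxies).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ROIDef",
    "ROIRegistry",
    "ROINetwork",
    "build_registry",
    "enumerate_networks",
    "filter_networks",
    "pattern_feature_count",
    "ico_vertex_count",
]

_MODE_FILES = {
    "connectivity-16": "connectivity16.tsv",
    "activation-86": "activation86.tsv",
}


@dataclass(frozen=True)
class ROIDef:
    """One region of interest: a named cortical area in one hemisphere."""

    name: str
    hemisphere: str
    n_subrois: int
    area: str = ""
    role: str = "both"
    inferred: bool = False

    def __post_init__(self) -> None:
        if self.n_subrois < 1:
            raise ValueError(f"{self.name}: n_subrois must be >= 1")
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"{self.name}: unknown hemisphere {self.hemisphere!r}")


@dataclass(frozen=True)
class ROIRegistry:
    """Ordered collection of ROIDefs for one registry mode."""

    rois: tuple[ROIDef, ...]
    mode: str = "custom"

    def __post_init__(self) -> None:
        keys = [(r.name, r.hemisphere) for r in self.rois]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (name, hemisphere) in registry")
        names = [r.name for r in self.rois]
        if len(set(names)) != len(names):
            raise ValueError("ROI names must be unique within a registry")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]

    def __getitem__(self, name: str) -> ROIDef:
        for r in self.rois:
            if r.name == name:
                return r
        raise KeyError(f"unknown ROI {name!r}")

    @property
    def total_subrois(self) -> int:
        return sum(r.n_subrois for r in self.rois)

    def subroi_slices(self) -> dict[str, slice]:
        """Row ranges of each ROI in a stacked subROI x time matrix."""
        out, start = {}, 0
        for r in self.rois:
            out[r.name] = slice(start, start + r.n_subrois)
            start += r.n_subrois
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.rois],
                "area": [r.area for r in self.rois],
                "hemisphere": [r.hemisphere for r in self.rois],
                "n_subrois": [r.n_subrois for r in self.rois],
                "role": [r.role for r in self.rois],
                "inferred": [r.inferred for r in self.rois],
            }
        )


@dataclass(frozen=True)
class ROINetwork:
    """An unordered 2-4-ROI network, stored in canonical (name-sorted) order."""

    members: tuple[ROIDef, ...]

    def __post_init__(self) -> None:
        if not 2 <= len(self.members) <= 4:
            raise ValueError("network size must be 2, 3, or 4")
        ordered = tuple(sorted(self.members, key=lambda r: r.name))
        object.__setattr__(self, "members", ordered)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.members)

    @property
    def label(self) -> str:
        return "+".join(self.names)

    def pairs(self) -> list[tuple[ROIDef, ROIDef]]:
        """Unordered ROI pairs in canonical order."""
        return list(itertools.combinations(self.members, 2))

    @property
    def feature_len(self) -> int:
        return pattern_feature_count(self)


def build_registry(mode: str = "connectivity-16") -> ROIRegistry:
    """Load a packaged registry table.

    ``connectivity-16``: the 8 bilateral connectivity ROIs (16 entries) with
    their subROI counts.  ``activation-86``: 43 surface labels per hemisphere
    (86 entries) with voxel-count proxy units for the synthetic pipeline.
    """
    try:
        fname = _MODE_FILES[mode]
    except KeyError:
        raise ValueError(
            f"unknown registry mode {mode!r}; expected one of {sorted(_MODE_FILES)}"
        ) from None
    with resources.files("wmconn.data").joinpath(fname).open() as fh:
        table = pd.read_csv(fh, sep="\t")
    return registry_from_frame(table, mode=mode)


def registry_from_frame(table: pd.DataFrame, mode: str = "custom") -> ROIRegistry:
    """Build a registry from a table with columns name/hemisphere/n_subrois."""
    rois = tuple(
        ROIDef(
            name=str(row["name"]),
            hemisphere=str(row["hemisphere"]),
            n_subrois=int(row["n_subrois"]),
            area=str(row.get("area", "")),
            role=str(row.get("role", "both")),
            inferred=bool(row.get("inferred", False)),
        )
        for _, row in table.iterrows()
    )
    return ROIRegistry(rois=rois, mode=mode)


def enumerate_networks(
    registry: ROIRegistry, sizes: Iterable[int] = (2, 3, 4)
) -> list[ROINetwork]:
    """Every unordered ROI subset of the requested sizes, exactly once.

    Order is deterministic: ascending size, then lexicographic by member
    names, so permutation nulls and reports are reproducible across runs.
    For the 16-ROI registry and sizes {2,3,4} this yields
    C(16,2)+C(16,3)+C(16,4) = 2500 networks.
    """
    sizes = sorted(set(int(s) for s in sizes))
    if not sizes or any(s not in (2, 3, 4) for s in sizes):
        raise ValueError(f"sizes must be a non-empty subset of {{2,3,4}}, got {sizes}")
    ordered = sorted(registry.rois, key=lambda r: r.name)
    out: list[ROINetwork] = []
    for k in sizes:
        for combo in itertools.combinations(ordered, k):
            out.append(ROINetwork(members=combo))
    return out


def filter_networks(
    networks: Sequence[ROINetwork],
    must_include: Iterable[str] = (),
    must_exclude: Iterable[str] = (),
) -> list[ROINetwork]:
    """Keep networks containing >=1 ``must_include`` ROI and 0 ``must_exclude``.

    With an empty ``must_include`` no inclusion constraint applies.  Order of
    the input sequence is preserved.  Over the 2500-network space, including
    {LOC, ROC} keeps 1044 networks; additionally excluding {LSTC, RSTC}
    keeps 675.
    """
    include = set(must_include)
    exclude = set(must_exclude)
    known = {r.name for net in networks for r in net.members}
    for name in include | exclude:
        if networks and name not in known:
            raise KeyError(f"unknown ROI name {name!r}")
    out = []
    for net in networks:
        names = set(net.names)
        if include and not (names & include):
            continue
        if names & exclude:
            continue
        out.append(net)
    return out


def pattern_feature_count(network: ROINetwork) -> int:
    """Feature-vector length T = sum of N_A * N_B over unordered member pairs.

    E.g. for {LSTC:34, LSMG:34, RSTC:29}: 34*34 + 34*29 + 34*29 = 3128.
    """
    return sum(a.n_subrois * b.n_subrois for a, b in network.pairs())


def ico_vertex_count(order: int) -> int:
    """Vertex count of an icosahedron subdivided ``order`` times.

    Each subdivision adds one vertex per edge, giving V(n) = 10*4^n + 2:
    12, 42, 162, 642 (order 3 is the fsaverage3 mesh, 642 vertices per
    hemisphere, whose patches define the subROIs).
    """
    order = int(order)
    if order < 0:
        raise ValueError("subdivision order must be >= 0")
    return 10 * 4**order + 2
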