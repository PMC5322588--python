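"""PCI and boxplot-based barcode-gap classification.

Two instruments measure how well a marker separates species of a genus:

**PCI** (probability of correct identification): a species is *identified*
when the minimum interspecific p-distance involving it is strictly larger
than its maximum intraspecific distance; the genus PCI is the fraction of
scorable species identified.  Species with a single sequence have no
intraspecific distance and are excluded from scoring, but their sequences
still serve as interspecific partners for the others.

**Barcode gap**: pooled intraspecific and interspecific distances are
summarized as boxplots (quartiles by linear interpolation, whiskers at the
most extreme data within 1.5 IQR of the box) and classified:

* ``poor``   — the boxes overlap (intra Q3 >= inter Q1) or the intraspecific
  values sit above the interspecific ones (median(intra) >= median(inter));
* ``intermediate`` — boxes separate but the whiskers overlap
  (intra upper whisker >= inter lower whisker);
* ``good``   — whiskers separate (outlier overlap is allowed).

Checks run in that order, so ``poor`` takes precedence.  A genus is then
placed into one of four cross-marker groups: 1 = all three markers good,
4 = all three poor, 2 = at least one good (the good ones are the
recommended markers), 3 = the rest (no good marker, not all poor).
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import EvaluationError, InputError
from .records import MARKERS
from .distances import DistanceMatrix


class GapClass(enum.IntEnum):
    """Barcode-gap quality, totally ordered: good > intermediate > poor."""

    poor = 0
    intermediate = 1
    good = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class SpeciesDistanceSummary:
    species: str
    max_intra: float
    min_inter: float
    n_intra_pairs: int
    n_inter_pairs: int


@dataclass(frozen=True)
class BoxStats:
    q1: float
    median: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]


@dataclass(frozen=True)
class GenusMarkerResult:
    """Everything the evaluation knows about one genus x marker."""

    genus: str
    marker: str
    pci: float
    intra_pool: tuple[float, ...]
    inter_pool: tuple[float, ...]
    intra_box: BoxStats
    inter_box: BoxStats
    gap_class: GapClass


def _species_indices(matrix: DistanceMatrix) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for idx, (_, sp) in enumerate(matrix.labels):
        groups.setdefault(sp, []).append(idx)
    return groups


def species_summaries(matrix: DistanceMatrix) -> list[SpeciesDistanceSummary]:
    """Max-intra / min-inter summary per scorable species.

    Scorable = >= 2 sequences.  Singleton species are excluded from the
    output but their distances still contribute to other species' min_inter.
    """
    groups = _species_indices(matrix)
    v = matrix.values
    summaries: list[SpeciesDistanceSummary] = []
    for sp, idx in groups.items():
        if len(idx) < 2:
            continue
        others = [k for osp, oidx in groups.items() if osp != sp for k in oidx]
        if not others:
            continue
        intra = [v[i, j] for a, i in enumerate(idx) for j in idx[a + 1 :]]
        inter = [v[i, j] for i in idx for j in others]
        summaries.append(
            SpeciesDistanceSummary(
                species=sp,
                max_intra=float(max(intra)),
                min_inter=float(min(inter)),
                n_intra_pairs=len(intra),
                n_inter_pairs=len(inter),
            )
        )
    if not summaries:
        raise EvaluationError("no scorable species (every species is a singleton)")
    return summaries


def species_identified(s: SpeciesDistanceSummary) -> bool:
    """Strict inequality: ties between min-inter and max-intra fail."""
    return s.min_inter > s.max_intra


def genus_pci(matrix: DistanceMatrix) -> float:
    """Identified species / scorable species, in [0, 1]."""
    summaries = species_summaries(matrix)
    return sum(species_identified(s) for s in summaries) / len(summaries)


def box_stats(values: Sequence[float]) -> BoxStats:
    """Boxplot statistics: linear-interpolation quartiles, 1.5-IQR whiskers.

    Whiskers are attained data values (the most extreme points within
    1.5 IQR of the box); points beyond them are outliers.
    """
    if len(values) == 0:
        raise InputError("box_stats requires at least one value")
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    whisker_low, whisker_high = float(inside.min()), float(inside.max())
    outliers = tuple(float(x) for x in arr[(arr < whisker_low) | (arr > whisker_high)])
    return BoxStats(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
    )


def classify_gap(intra: BoxStats, inter: BoxStats) -> GapClass:
    """Classify the separation of intra vs inter distance boxplots.

    Precedence poor > intermediate > good; see the module docstring for the
    exact overlap rules.
    """
    if intra.q3 >= inter.q1 or intra.median >= inter.median:
        return GapClass.poor
    if intra.whisker_high >= inter.whisker_low:
        return GapClass.intermediate
    return GapClass.good


def distance_pools(matrix: DistanceMatrix) -> tuple[list[float], list[float]]:
    """All intraspecific and interspecific pairwise distances of a genus."""
    v = matrix.values
    species = matrix.species
    intra: list[float] = []
    inter: list[float] = []
    n = len(matrix)
    for i in range(n):
        for j in range(i + 1, n):
            (intra if species[i] == species[j] else inter).append(float(v[i, j]))
    return intra, inter


def evaluate_genus_marker(
    matrix: DistanceMatrix, genus: str, marker: str
) -> GenusMarkerResult:
    """Full per-genus, per-marker evaluation from one distance matrix."""
    intra, inter = distance_pools(matrix)
    if not intra or not inter:
        raise EvaluationError(
            f"{genus}/{marker}: need both intra- and interspecific distances"
        )
    intra_box = box_stats(intra)
    inter_box = box_stats(inter)
    return GenusMarkerResult(
        genus=genus,
        marker=marker.upper(),
        pci=genus_pci(matrix),
        intra_pool=tuple(intra),
        inter_pool=tuple(inter),
        intra_box=intra_box,
        inter_box=inter_box,
        gap_class=classify_gap(intra_box, inter_box),
    )


@dataclass(frozen=True)
class GroupAssignment:
    group: int
    recommended: tuple[str, ...]


def assign_group(classes: Mapping[str, GapClass]) -> GroupAssignment:
    """Cross-marker group 1-4 from the three per-marker gap classes.

    Requires exactly the markers ITS, ITS1, ITS2.  Group 2's recommended
    markers are the ones classified good.
    """
    keys = {k.upper() for k in classes}
    if keys != set(MARKERS):
        raise InputError(f"need exactly markers {MARKERS}, got {sorted(keys)}")
    by_marker = {k.upper(): v for k, v in classes.items()}
    values = [by_marker[m] for m in MARKERS]
    good = [m for m in MARKERS if by_marker[m] is GapClass.good]
    if all(v is GapClass.good for v in values):
        return GroupAssignment(1, tuple(MARKERS))
    if all(v is GapClass.poor for v in values):
        return GroupAssignment(4, ())
    if good:
        return GroupAssignment(2, tuple(good))
    return GroupAssignment(3, ())


def plot_genus_boxes(results: Sequence[GenusMarkerResult], path) -> None:
    """Side-by-side intra/inter boxplots per marker for one genus (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(results), figsize=(3.2 * len(results), 3.6))
    axes = np.atleast_1d(axes)
    for ax, res in zip(axes, results):
        ax.boxplot(
            [res.intra_pool, res.inter_pool],
            tick_labels=["intra", "inter"],
            whis=1.5,
        )
        ax.set_title(f"{res.genus} {res.marker}\n{res.gap_class} (PCI {res.pci:.0%})")
        ax.set_ylabel("uncorrected p-distance")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
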