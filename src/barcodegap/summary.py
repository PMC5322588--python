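"""Cross-genus, cross-marker summary statistics.

Works on a *PCI table*: one row per genus with PCI values (0-100 scale) for
the complete ITS and the ITS1/ITS2 sub-regions.  The packaged fixture
``table1_pci.tsv`` is the printed 113-genus table of the original
Basidiomycota survey, and ``table2_groups.tsv`` its barcode-gap group
assignments; :func:`reproduce_published_summaries` recomputes every
published summary statistic from those fixtures and reports deltas.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError
from .simulate import fixture_path

#: PCI-table column per marker.
MARKER_COLUMNS = {"ITS": "pci_its", "ITS1": "pci_its1", "ITS2": "pci_its2"}

MARKER_PAIRS = (("ITS", "ITS1"), ("ITS", "ITS2"), ("ITS1", "ITS2"))


def load_pci_table(path=None) -> pd.DataFrame:
    """Load a PCI table (default: the packaged printed-table fixture)."""
    path = fixture_path("table1_pci.tsv") if path is None else path
    table = pd.read_csv(path, sep="\t")
    missing = {"genus", *MARKER_COLUMNS.values()} - set(table.columns)
    if missing:
        raise InputError(f"PCI table missing column(s) {sorted(missing)}")
    if table["genus"].duplicated().any():
        raise InputError("PCI table has duplicate genus names")
    vals = table[list(MARKER_COLUMNS.values())]
    if ((vals < 0) | (vals > 100)).any().any():
        raise InputError("PCI values must lie in [0, 100]")
    return table


def load_group_table(path=None) -> pd.DataFrame:
    """Load a genus -> group (1-4) table (default: the packaged fixture)."""
    path = fixture_path("table2_groups.tsv") if path is None else path
    table = pd.read_csv(path, sep="\t", keep_default_na=False)
    if not {"genus", "group"} <= set(table.columns):
        raise InputError("group table needs 'genus' and 'group' columns")
    if not table["group"].isin([1, 2, 3, 4]).all():
        raise InputError("groups must be in {1, 2, 3, 4}")
    return table


def _column(table: pd.DataFrame, marker: str) -> pd.Series:
    try:
        col = MARKER_COLUMNS[marker.upper()]
    except KeyError:
        raise InputError(f"unknown marker {marker!r}") from None
    if len(table) == 0:
        raise InputError("PCI table is empty")
    return table[col]


def mean_pci(table: pd.DataFrame, marker: str) -> float:
    """Arithmetic mean of a marker's PCI column (0-100 scale)."""
    return float(_column(table, marker).mean())


def fraction_above_mean(table: pd.DataFrame, marker: str) -> float:
    """Fraction of genera strictly above the column mean."""
    col = _column(table, marker)
    return float((col > col.mean()).mean())


def spearman_rho(x, y) -> float:
    """Tie-corrected Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("x and y must have equal length")
    if x.size < 3:
        raise InputError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise InputError("zero rank variance: correlation undefined")
    return float(stats.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class MarkerSummary:
    """Means, above-mean fractions and pairwise rank correlations.

    A correlation is ``None`` when undefined (a constant PCI column has zero
    rank variance, which happens on small or perfectly separated datasets).
    """

    mean: dict[str, float]
    frac_above_mean: dict[str, float]
    spearman: dict[tuple[str, str], float | None]

    def to_dict(self) -> dict:
        return {
            "mean": dict(self.mean),
            "frac_above_mean": dict(self.frac_above_mean),
            "spearman": {f"{a}-{b}": v for (a, b), v in self.spearman.items()},
        }


def marker_summary(table: pd.DataFrame) -> MarkerSummary:
    """All cross-marker summary statistics of one PCI table."""
    markers = list(MARKER_COLUMNS)
    spearman: dict[tuple[str, str], float | None] = {}
    for a, b in MARKER_PAIRS:
        try:
            spearman[(a, b)] = spearman_rho(_column(table, a), _column(table, b))
        except InputError:
            spearman[(a, b)] = None
    return MarkerSummary(
        mean={m: mean_pci(table, m) for m in markers},
        frac_above_mean={m: fraction_above_mean(table, m) for m in markers},
        spearman=spearman,
    )


def group_dotplot_data(
    table: pd.DataFrame, groups: dict[str, int]
) -> dict[tuple[int, str], dict]:
    """Per-(group, marker) PCI values plus counts above/below the marker mean.

    The partition is exhaustive and disjoint: per marker, the value lists
    over groups 1-4 sum to the table's row count.
    """
    missing = [g for g in table["genus"] if g not in groups]
    if missing:
        raise InputError(f"genus without group assignment: {missing[:5]}")
    means = {m: mean_pci(table, m) for m in MARKER_COLUMNS}
    out: dict[tuple[int, str], dict] = {}
    for group in (1, 2, 3, 4):
        genera = [g for g in table["genus"] if groups[g] == group]
        sub = table[table["genus"].isin(genera)]
        for marker, col in MARKER_COLUMNS.items():
            vals = sub[col].tolist()
            out[(group, marker)] = {
                "genera": genera,
                "values": vals,
                "n_above_mean": int(sum(v > means[marker] for v in vals)),
                "n_below_or_equal_mean": int(sum(v <= means[marker] for v in vals)),
            }
    return out


#: Published summary values (printed in the original survey) that
#: :func:`reproduce_published_summaries` recomputes and compares against.
PUBLISHED = {
    "n_genera": 113,
    "mean": {"ITS": 63.0, "ITS1": 59.0, "ITS2": 58.0},
    "frac_above_mean_pct": {"ITS": 53.1, "ITS1": 46.0, "ITS2": 48.0},
    "spearman": {
        ("ITS", "ITS1"): 0.8825,
        ("ITS", "ITS2"): 0.9102,
        ("ITS1", "ITS2"): 0.8158,
    },
    "n_group4": 11,
}


def reproduce_published_summaries(
    pci_path=None, groups_path=None
) -> dict:
    """Recompute every published summary from the packaged fixtures.

    Returns a report dict with computed values, the published values, and
    their deltas, plus integrity flags (row counts, group-4 membership).
    Means are additionally rounded to the printed integer precision, since
    the fixture holds the printed (rounded) per-genus PCIs while the
    original means were computed from unrounded values.
    """
    try:
        table = load_pci_table(pci_path)
        groups = load_group_table(groups_path)
    except FileNotFoundError as exc:  # pragma: no cover - packaging guard
        raise ConfigurationError(f"missing fixture: {exc}") from exc
    summ = marker_summary(table)
    group_map = dict(zip(groups["genus"], groups["group"]))
    n_group4 = int((groups["group"] == 4).sum())

    report: dict = {
        "n_genera": {"computed": int(len(table)), "published": PUBLISHED["n_genera"]},
        "n_group4": {"computed": n_group4, "published": PUBLISHED["n_group4"]},
        "genus_sets_match": set(table["genus"]) == set(groups["genus"]),
        "markers": {},
        "spearman": {},
    }
    report["n_genera"]["delta"] = report["n_genera"]["computed"] - PUBLISHED["n_genera"]
    report["n_group4"]["delta"] = n_group4 - PUBLISHED["n_group4"]
    for m in MARKER_COLUMNS:
        mean = summ.mean[m]
        frac_pct = summ.frac_above_mean[m] * 100.0
        report["markers"][m] = {
            "mean_computed": mean,
            "mean_rounded": round(mean),
            "mean_published": PUBLISHED["mean"][m],
            "mean_delta": round(mean) - PUBLISHED["mean"][m],
            "frac_above_mean_pct_computed": frac_pct,
            "frac_above_mean_pct_published": PUBLISHED["frac_above_mean_pct"][m],
            "frac_above_mean_pct_delta": frac_pct
            - PUBLISHED["frac_above_mean_pct"][m],
        }
    for pair, rho_pub in PUBLISHED["spearman"].items():
        rho = summ.spearman[pair]
        report["spearman"]["-".join(pair)] = {
            "computed": rho,
            "published": rho_pub,
            "delta": rho - rho_pub,
        }
    report["dotplot"] = {
        f"group{g}_{m}": d["n_above_mean"]
        for (g, m), d in group_dotplot_data(table, group_map).items()
    }
    return report
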