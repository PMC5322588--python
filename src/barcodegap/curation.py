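"""Quality and logic filter cascade for barcode datasets.

Each filter is a pure records -> records function; :func:`run_curation`
chains them in a fixed order and keeps per-stage bookkeeping (a
:class:`CurationReport`).  The cascade mirrors standard DNA-barcoding
curation practice: voucher-backed sequences only, no ambiguous base calls,
species-level names only, complete ITS regions, plausible lengths, species
sampled from at least three localities, and at least two species per genus
(otherwise no interspecific distance exists to compare against).

Filter semantics worth stating:

* the name filter matches the inconclusive tokens ('sp.', 'aff.', 'cf.',
  'uncultured') as whole tokens after splitting on whitespace and stripping
  trailing periods, case-insensitively — 'crassifolia' does not match 'cf';
* the length filter keeps 400 <= len(ITS1+5.8S+ITS2) <= 800 (inclusive both
  ends) and requires ITS1 and ITS2 each >= 100 bp;
* the locality filter first drops records with no locality, then removes
  every record of species spanning fewer than the minimum number of
  distinct localities (exact string match after trimming and case-folding);
* group filters (locality, min-species) are the only stages where removing
  or adding one record can change the fate of others.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .errors import ConfigurationError, InputError
from .records import INCONCLUSIVE_TOKENS, UNAMBIGUOUS, SpecimenRecord
from .regions import DEFAULT_ANCHORS, AnchorConfig, split_its

Records = list[SpecimenRecord]


@dataclass(frozen=True)
class CurationStage:
    stage_name: str
    n_in: int
    n_out: int
    removed_accessions: tuple[str, ...]


@dataclass
class CurationReport:
    """Ordered per-stage in/out bookkeeping of one cascade run."""

    stages: list[CurationStage] = field(default_factory=list)

    def add(self, name: str, before: Records, after: Records) -> None:
        kept = {r.accession for r in after}
        removed = tuple(r.accession for r in before if r.accession not in kept)
        stage = CurationStage(name, len(before), len(after), removed)
        if self.stages and self.stages[-1].n_out != stage.n_in:
            raise InputError(
                f"stage {name!r}: n_in={stage.n_in} does not chain from "
                f"previous n_out={self.stages[-1].n_out}"
            )
        if stage.n_out > stage.n_in:
            raise InputError(f"stage {name!r}: n_out exceeds n_in")
        self.stages.append(stage)

    def removed_at(self, stage_name: str) -> tuple[str, ...]:
        for s in self.stages:
            if s.stage_name == stage_name:
                return s.removed_accessions
        raise KeyError(stage_name)

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage_name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "removed_accessions": list(s.removed_accessions),
                }
                for s in self.stages
            ]
        }


def filter_voucher(records: Records) -> Records:
    """Keep records with a non-empty voucher field (no format validation)."""
    return [r for r in records if r.voucher.strip()]


def filter_ambiguous(records: Records) -> Records:
    """Keep records whose sequence alphabet is exactly {A,C,G,T}.

    One or more IUPAC ambiguity characters disqualify a sequence.
    """
    return [r for r in records if set(r.sequence) <= UNAMBIGUOUS]


def _name_tokens(name: str) -> set[str]:
    return {tok.rstrip(".").lower() for tok in name.split()}


def filter_species_names(records: Records) -> Records:
    """Drop records whose organism name contains an inconclusive token."""
    return [
        r
        for r in records
        if not (_name_tokens(r.organism_name) & INCONCLUSIVE_TOKENS)
        and r.species_epithet
    ]


def filter_its_complete(
    records: Records,
    extractor: Callable = split_its,
    anchors: AnchorConfig = DEFAULT_ANCHORS,
) -> Records:
    """Keep records whose ITS splits into three non-empty regions.

    Successful records get their :class:`RegionSet` attached; failures are
    removals, not errors.  Records that already carry regions are kept as-is.
    """
    out: Records = []
    for r in records:
        if r.regions is not None:
            out.append(r)
            continue
        regions = extractor(r.sequence, anchors)
        if regions is not None:
            out.append(r.with_regions(regions))
    return out


def filter_lengths(
    records: Records,
    min_total: int = 400,
    max_total: int = 800,
    min_subregion: int = 100,
) -> Records:
    """Keep 400 <= full-ITS length <= 800 and ITS1, ITS2 each >= 100 bp.

    Requires regions attached; records without regions are removed (their
    completeness is unknown).
    """
    out: Records = []
    for r in records:
        if r.regions is None:
            continue
        total = len(r.regions)
        if (
            min_total <= total <= max_total
            and len(r.regions.its1) >= min_subregion
            and len(r.regions.its2) >= min_subregion
        ):
            out.append(r)
    return out


def _norm_locality(loc: str) -> str:
    return loc.strip().casefold()


def filter_localities(records: Records, min_localities: int = 3) -> Records:
    """Drop unlocated records, then species spanning < min distinct localities."""
    if min_localities < 1:
        raise ConfigurationError("min_localities must be >= 1")
    located = [r for r in records if _norm_locality(r.locality)]
    spans: dict[tuple[str, str], set[str]] = defaultdict(set)
    for r in located:
        spans[r.species_key].add(_norm_locality(r.locality))
    return [r for r in located if len(spans[r.species_key]) >= min_localities]


def filter_min_species_per_genus(records: Records, min_species: int = 2) -> Records:
    """Drop genera left with fewer than ``min_species`` distinct species."""
    if min_species < 1:
        raise ConfigurationError("min_species must be >= 1")
    species: dict[str, set[str]] = defaultdict(set)
    for r in records:
        species[r.genus].add(r.species_epithet)
    return [r for r in records if len(species[r.genus]) >= min_species]


@dataclass(frozen=True)
class CurationConfig:
    """Toggles and parameters of the cascade (defaults = the standard run)."""

    voucher: bool = True
    ambiguous: bool = True
    species_names: bool = True
    its_complete: bool = True
    lengths: bool = True
    localities: bool = True
    min_species_per_genus: bool = True
    min_localities: int = 3
    min_species: int = 2
    min_total: int = 400
    max_total: int = 800
    min_subregion: int = 100
    anchors: AnchorConfig = DEFAULT_ANCHORS


#: Fixed stage order of the cascade.
STAGE_ORDER = (
    "voucher",
    "ambiguous",
    "species_names",
    "its_complete",
    "lengths",
    "localities",
    "min_species_per_genus",
)


def run_curation(
    records: Sequence[SpecimenRecord],
    config: CurationConfig = CurationConfig(),
) -> tuple[Records, CurationReport]:
    """Apply the enabled filters in the fixed cascade order.

    Returns the surviving records (with regions attached from the
    ITS-completeness stage) and the per-stage report.
    """
    stages: dict[str, Callable[[Records], Records]] = {
        "voucher": filter_voucher,
        "ambiguous": filter_ambiguous,
        "species_names": filter_species_names,
        "its_complete": lambda rs: filter_its_complete(rs, anchors=config.anchors),
        "lengths": lambda rs: filter_lengths(
            rs, config.min_total, config.max_total, config.min_subregion
        ),
        "localities": lambda rs: filter_localities(rs, config.min_localities),
        "min_species_per_genus": lambda rs: filter_min_species_per_genus(
            rs, config.min_species
        ),
    }
    current = list(records)
    report = CurationReport()
    for name in STAGE_ORDER:
        if not getattr(config, name):
            continue
        nxt = stages[name](current)
        report.add(name, current, nxt)
        current = nxt
    return current, report
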