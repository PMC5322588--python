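"""Core record types: one voucher-backed sequence and its ITS partition.

A :class:`SpecimenRecord` is the unit that flows through the whole pipeline:
curation filters consume and return lists of records, region extraction
attaches a :class:`RegionSet`, and the distance stage slices marker
subsequences out of it.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .errors import InputError

#: IUPAC nucleotide one-letter codes accepted after canonicalization
#: (U is normalized to T on read, so it is absent here).
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

#: The four unambiguous bases.
UNAMBIGUOUS = frozenset("ACGT")

#: Name tokens that mark a record as not identified to species level.
INCONCLUSIVE_TOKENS = frozenset({"sp", "aff", "cf", "uncultured"})


def canonicalize_sequence(seq: str) -> str:
    """Uppercase a nucleotide string and normalize U -> T.

    Raises :class:`InputError` on characters outside the IUPAC alphabet.
    """
    s = seq.strip().upper().replace("U", "T")
    if not s:
        raise InputError("empty sequence")
    bad = set(s) - IUPAC_ALPHABET
    if bad:
        raise InputError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class RegionSet:
    """ITS1 / 5.8S / ITS2 partition of a complete ITS sequence.

    ``coords`` holds three 0-based half-open intervals on the parent
    sequence, ordered ITS1 < 5.8S < ITS2.  For a successful split all three
    parts are non-empty and the intervals tile ``[coords[0][0], coords[2][1])``
    contiguously.
    """

    its1: str
    s58: str
    its2: str
    coords: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        (a0, a1), (b0, b1), (c0, c1) = self.coords
        if not (a0 <= a1 <= b0 <= b1 <= c0 <= c1):
            raise InputError("region intervals must be ordered and disjoint")
        for part, (lo, hi) in zip((self.its1, self.s58, self.its2), self.coords):
            if len(part) != hi - lo:
                raise InputError("region length does not match its interval")
        if not (self.its1 and self.s58 and self.its2):
            raise InputError("all three regions must be non-empty")

    @property
    def full_its(self) -> str:
        """ITS1 + 5.8S + ITS2 concatenated (the 'complete ITS' marker)."""
        return self.its1 + self.s58 + self.its2

    def __len__(self) -> int:
        return len(self.its1) + len(self.s58) + len(self.its2)


@dataclass(frozen=True)
class SpecimenRecord:
    """One sequence with its taxonomy, voucher and locality metadata.

    ``species_epithet`` is the concrete epithet ("bisporus"); any remainder of
    the organism name — including inconclusive markers like 'sp.' or
    'uncultured' — lives in ``name_qualifiers``.  ``voucher`` and ``locality``
    may be empty strings, meaning "not provided" (they are what the voucher
    and locality filters test).
    """

    accession: str
    genus: str
    species_epithet: str
    sequence: str
    name_qualifiers: str = ""
    voucher: str = ""
    locality: str = ""
    regions: RegionSet | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.accession:
            raise InputError("accession must be non-empty")
        if not self.sequence:
            raise InputError(f"{self.accession}: sequence must be non-empty")

    @property
    def organism_name(self) -> str:
        """Full organism name: genus + epithet + qualifiers."""
        parts = [self.genus, self.species_epithet, self.name_qualifiers]
        return " ".join(p for p in parts if p)

    @property
    def species_key(self) -> tuple[str, str]:
        """(genus, epithet) pair used to group records into species."""
        return (self.genus, self.species_epithet)

    def with_regions(self, regions: RegionSet | None) -> "SpecimenRecord":
        return dataclasses.replace(self, regions=regions)

    def marker_sequence(self, marker: str) -> str:
        """Subsequence for a marker: 'ITS' (full), 'ITS1' or 'ITS2'.

        'ITS' falls back to the raw sequence when no regions are attached;
        the sub-regions require an attached :class:`RegionSet`.
        """
        m = marker.upper()
        if m == "ITS":
            return self.regions.full_its if self.regions is not None else self.sequence
        if self.regions is None:
            raise InputError(
                f"{self.accession}: marker {marker!r} requires extracted regions"
            )
        if m == "ITS1":
            return self.regions.its1
        if m == "ITS2":
            return self.regions.its2
        raise InputError(f"unknown marker {marker!r} (expected ITS, ITS1 or ITS2)")


MARKERS = ("ITS", "ITS1", "ITS2")
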