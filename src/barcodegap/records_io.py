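"""Read/write specimen records as FASTA + metadata TSV.

The on-disk contract keeps all metadata in a tab-separated table joined to
the FASTA by accession (FASTA headers carry the accession only): GenBank and
UNITE header dialects vary too much for headers to be a stable metadata
carrier.  An optional second TSV can *enrich* records by filling empty
fields, emulating how a curated secondary database supplements primary
records without overwriting them.
"""
from __future__ import annotations

import csv
import dataclasses
import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .records import SpecimenRecord, canonicalize_sequence

logger = logging.getLogger(__name__)

METADATA_COLUMNS = ("accession", "genus", "species", "voucher", "country")


def _read_metadata(path: str | Path) -> dict[str, dict[str, str]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        cols = reader.fieldnames or []
        missing = [c for c in METADATA_COLUMNS if c not in cols]
        if missing:
            raise FormatError(f"{path}: missing metadata column(s) {missing}")
        rows: dict[str, dict[str, str]] = {}
        for row in reader:
            acc = (row.get("accession") or "").strip()
            if not acc:
                raise FormatError(f"{path}: row with empty accession")
            if acc in rows:
                raise FormatError(f"{path}: duplicate accession {acc!r}")
            rows[acc] = {k: (v or "").strip() for k, v in row.items()}
    return rows


def _split_species(field: str) -> tuple[str, str]:
    """Split the TSV 'species' cell into (epithet, qualifiers).

    The first whitespace token is the epithet; the remainder (may contain
    'sp.', 'aff.', 'cf.', 'uncultured') is kept verbatim as qualifiers.
    """
    parts = field.split(None, 1)
    if not parts:
        return "", ""
    return parts[0], parts[1] if len(parts) > 1 else ""


def read_dataset(fasta: str | Path, metadata: str | Path) -> list[SpecimenRecord]:
    """One record per FASTA entry, outer-joined to the metadata TSV.

    FASTA entries without a metadata row get empty genus/voucher/locality
    (they survive only until the relevant curation filter).  Surplus
    metadata rows are ignored with a logged count.  Sequences are
    canonicalized (uppercase, U -> T).
    """
    meta = _read_metadata(metadata)
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(fasta), "fasta"):
        acc = entry.id.strip()
        if acc in seen:
            raise FormatError(f"{fasta}: duplicate FASTA accession {acc!r}")
        seen.add(acc)
        row = meta.pop(acc, None)
        epithet, qualifiers = _split_species(row["species"]) if row else ("", "")
        records.append(
            SpecimenRecord(
                accession=acc,
                genus=row["genus"] if row else "",
                species_epithet=epithet,
                name_qualifiers=qualifiers,
                voucher=row["voucher"] if row else "",
                locality=row["country"] if row else "",
                sequence=canonicalize_sequence(str(entry.seq)),
            )
        )
    if meta:
        logger.info("%d metadata row(s) without a FASTA entry ignored", len(meta))
    return records


def enrich_metadata(
    records: list[SpecimenRecord], enrichment: str | Path
) -> list[SpecimenRecord]:
    """Fill *empty* metadata fields from a second accession-keyed TSV.

    Only empty voucher/locality (and empty genus/species) cells are filled;
    populated fields are never overwritten.  Returns a new list.
    """
    extra = _read_metadata(enrichment)
    out: list[SpecimenRecord] = []
    for rec in records:
        row = extra.get(rec.accession)
        if row is None:
            out.append(rec)
            continue
        changes: dict[str, str] = {}
        if not rec.voucher and row["voucher"]:
            changes["voucher"] = row["voucher"]
        if not rec.locality and row["country"]:
            changes["locality"] = row["country"]
        if not rec.genus and row["genus"]:
            changes["genus"] = row["genus"]
        if not rec.species_epithet and row["species"]:
            epithet, qualifiers = _split_species(row["species"])
            changes["species_epithet"] = epithet
            if not rec.name_qualifiers and qualifiers:
                changes["name_qualifiers"] = qualifiers
        out.append(dataclasses.replace(rec, **changes) if changes else rec)
    return out


def read_prealigned(fasta: str | Path, metadata: str | Path) -> list[SpecimenRecord]:
    """Read rows of an existing multiple alignment (gapped FASTA) + TSV.

    Like :func:`read_dataset` but '-' gap characters are preserved (only
    uppercasing and U -> T applied), for the prealigned distance path.
    """
    meta = _read_metadata(metadata)
    records: list[SpecimenRecord] = []
    for entry in SeqIO.parse(str(fasta), "fasta"):
        acc = entry.id.strip()
        row = meta.get(acc)
        epithet, qualifiers = _split_species(row["species"]) if row else ("", "")
        records.append(
            SpecimenRecord(
                accession=acc,
                genus=row["genus"] if row else "",
                species_epithet=epithet,
                name_qualifiers=qualifiers,
                voucher=row["voucher"] if row else "",
                locality=row["country"] if row else "",
                sequence=str(entry.seq).upper().replace("U", "T"),
            )
        )
    return records


def write_dataset(
    records: list[SpecimenRecord], fasta: str | Path, metadata: str | Path
) -> None:
    """Inverse of :func:`read_dataset` (FASTA wrapped at 80 columns).

    Empty voucher/locality cells are emitted as empty strings, never
    omitted, so every TSV row has the full column count.
    """
    entries = [
        SeqRecord(Seq(r.sequence), id=r.accession, description="") for r in records
    ]
    with open(fasta, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(entries)
    with open(metadata, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(METADATA_COLUMNS)
        for r in records:
            species = " ".join(p for p in (r.species_epithet, r.name_qualifiers) if p)
            w.writerow([r.accession, r.genus, species, r.voucher, r.locality])
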