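"""End-to-end orchestration: simulate -> curate -> extract -> distances ->
evaluate -> summarize, with a reproducible run manifest.

The library functions in the other modules are the real interface; this
module wires them together for the command line and for batch runs.  A run
writes per-stage artifacts into an output directory plus ``manifest.json``
recording inputs, parameters, per-stage counts and SHA-256 hashes of every
output file — identical (config, seed, inputs) yield identical manifests.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import records_io
from .curation import CurationConfig, run_curation
from .distances import AlignParams, genus_distance_matrix, write_matrix_tsv
from .errors import ConfigurationError, EvaluationError
from .markers import GenusMarkerResult, assign_group, evaluate_genus_marker
from .records import MARKERS, SpecimenRecord
from .simulate import DefectConfig, GenusSimConfig, generate_genera, inject_defects
from .summary import MARKER_COLUMNS, group_dotplot_data, marker_summary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage toggles and parameters of one run (flat, serializable)."""

    outdir: str = "barcodegap_run"
    seed: int = 0
    # input: either simulate, or read fasta+metadata
    simulate: bool = True
    input_fasta: str = ""
    input_metadata: str = ""
    enrichment: str = ""
    # simulation
    n_genera: int = 10
    n_species: int = 5
    seqs_per_species: int = 4
    inter_div: float = 0.10
    intra_div: float = 0.01
    p_ambiguous: float = 0.0
    p_no_voucher: float = 0.0
    p_bad_name: float = 0.0
    p_bad_length: float = 0.0
    p_no_locality: float = 0.0
    # stage toggles
    curate: bool = True
    extract: bool = True
    distances: bool = True
    evaluate: bool = True
    summarize: bool = True
    # curation parameters
    min_localities: int = 3
    min_species: int = 2
    min_total: int = 400
    max_total: int = 800
    min_subregion: int = 100
    # alignment / distances
    align_match: int = 1
    align_mismatch: int = -1
    align_gap: int = -2
    gap_columns: str = "pairwise"

    def to_flat(self) -> str:
        """Flat ``key = value`` text serialization (round-trips)."""
        lines = []
        for f in dataclasses.fields(self):
            lines.append(f"{f.name} = {getattr(self, f.name)}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_flat(cls, text: str) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"bad config line: {line!r}")
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ConfigurationError(f"unknown config key {key!r}")
            t = types[key]
            if t == "bool":
                kwargs[key] = raw.lower() in ("1", "true", "yes", "on")
            elif t == "int":
                kwargs[key] = int(raw)
            elif t == "float":
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)


def evaluate_records(
    records: list[SpecimenRecord],
    markers: tuple[str, ...] = MARKERS,
    params: AlignParams = AlignParams(),
) -> tuple[dict[str, dict[str, GenusMarkerResult]], pd.DataFrame, dict[str, int]]:
    """Distance + PCI + gap evaluation for every evaluable genus.

    Returns (results[genus][marker], PCI table on the 0-100 scale, genus ->
    group map).  Genera that cannot be scored (fewer than two species, or no
    intraspecific pairs) are skipped with a log message.
    """
    by_genus: dict[str, list[SpecimenRecord]] = {}
    for r in records:
        by_genus.setdefault(r.genus, []).append(r)

    results: dict[str, dict[str, GenusMarkerResult]] = {}
    rows = []
    groups: dict[str, int] = {}
    for genus in sorted(by_genus):
        recs = by_genus[genus]
        if len({r.species_epithet for r in recs}) < 2:
            logger.info("skipping %s: fewer than two species", genus)
            continue
        try:
            per_marker = {
                m: evaluate_genus_marker(
                    genus_distance_matrix(recs, marker=m, params=params), genus, m
                )
                for m in markers
            }
        except EvaluationError as exc:
            logger.info("skipping %s: %s", genus, exc)
            continue
        results[genus] = per_marker
        if set(markers) == set(MARKERS):
            groups[genus] = assign_group(
                {m: res.gap_class for m, res in per_marker.items()}
            ).group
        rows.append(
            {
                "genus": genus,
                **{
                    MARKER_COLUMNS[m]: 100.0 * per_marker[m].pci
                    for m in markers
                    if m in MARKER_COLUMNS
                },
            }
        )
    table = pd.DataFrame(rows, columns=["genus", *MARKER_COLUMNS.values()])
    return results, table, groups


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            f.name: getattr(config, f.name) for f in dataclasses.fields(config)
        },
        "stages": {},
        "outputs": {},
    }

    # --- input ---------------------------------------------------------
    if config.simulate:
        records = generate_genera(
            n_genera=config.n_genera,
            seed=config.seed,
            n_species=config.n_species,
            seqs_per_species=config.seqs_per_species,
            inter_div=config.inter_div,
            intra_div=config.intra_div,
        )
        defects = DefectConfig(
            p_ambiguous=config.p_ambiguous,
            p_no_voucher=config.p_no_voucher,
            p_bad_name=config.p_bad_name,
            p_bad_length=config.p_bad_length,
            p_no_locality=config.p_no_locality,
            seed=config.seed,
        )
        records = inject_defects(records, defects)
        records_io.write_dataset(
            records, out / "simulated.fasta", out / "simulated.tsv"
        )
        manifest["stages"]["simulate"] = {"n_records": len(records)}
    else:
        if not (config.input_fasta and config.input_metadata):
            raise ConfigurationError(
                "simulate=False requires input_fasta and input_metadata"
            )
        records = records_io.read_dataset(config.input_fasta, config.input_metadata)
        manifest["stages"]["read"] = {"n_records": len(records)}
    if config.enrichment:
        records = records_io.enrich_metadata(records, config.enrichment)

    # --- curation ------------------------------------------------------
    if config.curate:
        cur_cfg = CurationConfig(
            min_localities=config.min_localities,
            min_species=config.min_species,
            min_total=config.min_total,
            max_total=config.max_total,
            min_subregion=config.min_subregion,
        )
        records, report = run_curation(records, cur_cfg)
        (out / "curation_report.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        records_io.write_dataset(records, out / "curated.fasta", out / "curated.tsv")
        manifest["stages"]["curate"] = {
            "counts": [(s.stage_name, s.n_in, s.n_out) for s in report.stages]
        }

    # --- region extraction outputs -------------------------------------
    if config.extract:
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        coords_rows = []
        for suffix, attr in (("ITS1", "its1"), ("5_8S", "s58"), ("ITS2", "its2")):
            entries = [
                SeqRecord(Seq(getattr(r.regions, attr)), id=r.accession, description="")
                for r in records
                if r.regions is not None
            ]
            with open(out / f"regions.{suffix}.fasta", "w") as fh:
                SeqIO.FastaIO.FastaWriter(fh, wrap=80).write_file(entries)
        for r in records:
            if r.regions is None:
                continue
            for name, (lo, hi) in zip(("ITS1", "5.8S", "ITS2"), r.regions.coords):
                coords_rows.append((r.accession, name, lo, hi))
        pd.DataFrame(
            coords_rows, columns=["accession", "region", "start", "end"]
        ).to_csv(out / "region_coords.tsv", sep="\t", index=False)
        manifest["stages"]["extract"] = {"n_with_regions": sum(
            r.regions is not None for r in records
        )}

    # --- distances / evaluate / summarize ------------------------------
    params = AlignParams(config.align_match, config.align_mismatch, config.align_gap)
    if config.evaluate or config.distances:
        results, pci_table, groups = evaluate_records(records, params=params)
        if config.distances:
            mat_dir = out / "matrices"
            mat_dir.mkdir(exist_ok=True)
            for genus, per_marker in results.items():
                for m in per_marker:
                    matrix = genus_distance_matrix(
                        [r for r in records if r.genus == genus],
                        marker=m,
                        params=params,
                    )
                    write_matrix_tsv(matrix, mat_dir / f"{genus}.{m}.tsv")
            manifest["stages"]["distances"] = {"n_genera": len(results)}
        if config.evaluate:
            pci_table.to_csv(out / "pci_table.tsv", sep="\t", index=False)
            pd.DataFrame(
                sorted(groups.items()), columns=["genus", "group"]
            ).to_csv(out / "groups.tsv", sep="\t", index=False)
            eval_rows = [
                {
                    "genus": g,
                    "marker": m,
                    "pci": res.pci,
                    "gap_class": res.gap_class.name,
                    "group": groups.get(g),
                }
                for g, per_marker in results.items()
                for m, res in per_marker.items()
            ]
            pd.DataFrame(eval_rows).to_csv(out / "evaluation.tsv", sep="\t", index=False)
            manifest["stages"]["evaluate"] = {"n_genera": len(results)}
            if config.summarize and len(pci_table) > 0:
                summ = marker_summary(pci_table)
                dot = {
                    f"group{g}_{m}": d["n_above_mean"]
                    for (g, m), d in group_dotplot_data(pci_table, groups).items()
                } if groups else {}
                (out / "summary.json").write_text(
                    json.dumps({**summ.to_dict(), "dotplot_above_mean": dot}, indent=2)
                )
                manifest["stages"]["summarize"] = {"n_genera": len(pci_table)}

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
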