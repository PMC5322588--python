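"""Seeded synthetic ITS datasets with known ground truth.

The generator builds per-genus sets of species under an i.i.d. per-site
substitution model with no indels, so that every downstream quantity
(p-distances, PCI, barcode-gap class) has an analytically known or
enumerable ground truth:

* a genus ancestor is drawn uniformly over {A,C,G,T} for ITS1 and ITS2 and
  carries the packaged 5.8S core (:data:`~barcodegap.regions.S58_CORE`);
* each species consensus mutates the ancestor independently on a species
  branch of per-site rate ``inter_div - intra_div`` (the 5.8S at
  ``s58_div``, default 0 so extraction anchors stay exact);
* each individual mutates its species consensus at ``intra_div``.

``inter_div`` is thus the *total* per-lineage (root-to-tip) divergence rate
governing between-species comparisons and ``intra_div`` the within-species
rate nested inside it.  Setting ``inter_div >> intra_div`` produces a clear
barcode gap; ``inter_div == intra_div`` collapses the species branch to
zero, so intraspecific and interspecific distances are drawn from the same
process and no gap exists (the boxplots overlap).

``inject_defects`` adds GenBank-style metadata and sequence defects, one
independent Bernoulli channel per curation filter.  Substreams are derived
from the master seed by stable hashing (CRC-32 of textual keys), so adding a
genus or a channel never perturbs the draws of another.

Seeded-stream contract (relied upon by the ground-truth bookkeeping):
channel ``name`` at probability ``p`` over ``n`` records hits record ``i``
iff ``rng_for(seed, "defect", name).random(n)[i] < p``.
"""
from __future__ import annotations

import dataclasses
import shutil
import zlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, InputError
from .records import SpecimenRecord
from .regions import S58_CORE

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AMBIGUITY_CODES = "NRYSWKMBDHV"

#: Country-level locality pool (the curation locality rule counts countries).
LOCALITY_POOL = (
    "Brazil", "Chile", "Peru", "Canada", "Norway", "Japan", "Kenya",
    "India", "Spain", "Mexico", "Australia", "Finland", "Portugal",
    "Germany", "Thailand", "Estonia", "Argentina", "Morocco", "Iceland",
    "New Zealand",
)

_SYLLABLES = (
    "al", "ba", "cu", "do", "er", "fi", "ga", "hi", "lo", "ma",
    "ni", "po", "ru", "si", "tu", "ve",
)
_SUFFIXES = ("ensis", "atus", "osa", "ella", "icola", "oides", "ianus", "ata")


def rng_for(seed: int, *keys: str | int) -> np.random.Generator:
    """Derive a named substream from a master seed.

    String keys are hashed with CRC-32 (stable across runs and platforms),
    so the stream for ("defect", "no_voucher") is a pure function of the
    master seed and the key path.
    """
    entropy = [int(seed) & 0xFFFFFFFF]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode()) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class GenusSimConfig:
    """Parameters of one simulated genus.

    ``inter_div`` / ``intra_div`` are per-site total divergence rates for
    between-species and within-species comparisons (species branch rate =
    ``max(inter_div - intra_div, 0)``); ``s58_div`` replaces both on the
    conserved 5.8S core (default 0 so anchors are exact).  ``seqs_per_species``
    must be >= 3 and ``n_localities_pool`` >= 3 so that round-robin locality
    assignment satisfies the >= 3 distinct-localities rule on clean data.
    """

    genus_name: str
    n_species: int = 5
    seqs_per_species: int = 4
    its1_len: int = 220
    s58_len: int = len(S58_CORE)
    its2_len: int = 240
    inter_div: float = 0.10
    intra_div: float = 0.01
    s58_div: float = 0.0
    n_localities_pool: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genus_name:
            raise ConfigurationError("genus_name must be non-empty")
        if self.n_species < 1:
            raise ConfigurationError("n_species must be >= 1")
        if self.seqs_per_species < 3:
            raise ConfigurationError("seqs_per_species must be >= 3")
        for name in ("its1_len", "its2_len"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if not (40 <= self.s58_len <= len(S58_CORE)):
            raise ConfigurationError(
                f"s58_len must be in [40, {len(S58_CORE)}] to keep both anchors"
            )
        for name in ("inter_div", "intra_div", "s58_div"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_localities_pool < 3:
            raise ConfigurationError("n_localities_pool must be >= 3")


@dataclass(frozen=True)
class DefectConfig:
    """Per-channel corruption probabilities, one channel per curation filter."""

    p_ambiguous: float = 0.0
    p_no_voucher: float = 0.0
    p_bad_name: float = 0.0
    p_bad_length: float = 0.0
    p_no_locality: float = 0.0
    seed: int = 0

    CHANNELS = ("ambiguous", "no_voucher", "bad_name", "bad_length", "no_locality")

    def __post_init__(self) -> None:
        for ch in self.CHANNELS:
            p = getattr(self, f"p_{ch}")
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"p_{ch} must be in [0, 1], got {p}")

    def probability(self, channel: str) -> float:
        return getattr(self, f"p_{channel}")


def _mutate(seq_arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """i.i.d. per-site substitution to a uniformly random *different* base."""
    if rate <= 0.0:
        return seq_arr.copy()
    mask = rng.random(seq_arr.size) < rate
    n = int(mask.sum())
    if n == 0:
        return seq_arr.copy()
    out = seq_arr.copy()
    # index into ACGT, shift by 1..3 mod 4 => always a different base
    idx = np.searchsorted(_BASES, out[mask])
    shift = rng.integers(1, 4, size=n)
    out[mask] = _BASES[(idx + shift) % 4]
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _epithet(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        k = int(rng.integers(2, 4))
        stem = "".join(_SYLLABLES[i] for i in rng.integers(0, len(_SYLLABLES), k))
        name = stem + _SUFFIXES[int(rng.integers(0, len(_SUFFIXES)))]
        if name not in used:
            used.add(name)
            return name


def _locality_pool(n: int) -> list[str]:
    pool = list(LOCALITY_POOL[:n])
    pool += [f"Country{i:02d}" for i in range(len(pool), n)]
    return pool


def generate_genus(config: GenusSimConfig) -> list[SpecimenRecord]:
    """Simulate one genus: ``n_species`` x ``seqs_per_species`` records.

    Records embed the packaged 5.8S core (at ``s58_div = 0``) so region
    extraction is exact on clean data, and localities are assigned
    round-robin within each species so every species spans >= 3 localities.
    Byte-identical output for identical (config, seed).
    """
    g = config.genus_name
    rng_anc = rng_for(config.seed, "genus", g, "ancestor")
    anc_its1 = rng_anc.choice(_BASES, config.its1_len)
    anc_its2 = rng_anc.choice(_BASES, config.its2_len)
    anc_s58 = np.frombuffer(S58_CORE[: config.s58_len].encode("ascii"), dtype=np.uint8)

    rng_names = rng_for(config.seed, "genus", g, "epithets")
    used: set[str] = set()
    pool = _locality_pool(config.n_localities_pool)

    records: list[SpecimenRecord] = []
    branch_rate = max(config.inter_div - config.intra_div, 0.0)
    for i in range(config.n_species):
        rng_sp = rng_for(config.seed, "genus", g, "species", i)
        sp_its1 = _mutate(anc_its1, branch_rate, rng_sp)
        sp_s58 = _mutate(anc_s58, config.s58_div, rng_sp)
        sp_its2 = _mutate(anc_its2, branch_rate, rng_sp)
        epithet = _epithet(rng_names, used)
        for j in range(config.seqs_per_species):
            rng_ind = rng_for(config.seed, "genus", g, "individual", i, j)
            its1 = _mutate(sp_its1, config.intra_div, rng_ind)
            s58 = _mutate(sp_s58, config.s58_div, rng_ind)
            its2 = _mutate(sp_its2, config.intra_div, rng_ind)
            records.append(
                SpecimenRecord(
                    accession=f"SIM-{g}-{i:03d}-{j:02d}",
                    genus=g,
                    species_epithet=epithet,
                    sequence=_to_str(its1) + _to_str(s58) + _to_str(its2),
                    voucher=f"FH-{g[:4].upper()}-{i:02d}{j:02d}",
                    locality=pool[j % len(pool)],
                )
            )
    return records


def generate_genera(
    configs: list[GenusSimConfig] | None = None,
    *,
    n_genera: int = 10,
    seed: int = 0,
    **overrides,
) -> list[SpecimenRecord]:
    """Simulate several genera; convenience over :func:`generate_genus`.

    Without explicit configs, genera are named GenusA, GenusB, ... and share
    the default parameters (plus ``overrides``); each still gets its own
    hashed substream from the master seed.
    """
    if configs is None:
        configs = [
            GenusSimConfig(genus_name=_genus_name(i), seed=seed, **overrides)
            for i in range(n_genera)
        ]
    out: list[SpecimenRecord] = []
    for cfg in configs:
        out.extend(generate_genus(cfg))
    return out


def _genus_name(i: int) -> str:
    name = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        name = chr(ord("A") + r) + name
    return f"Genus{name}"


# --- defect injection --------------------------------------------------------


def _truncate_target(record: SpecimenRecord, rng: np.random.Generator) -> int | None:
    """A truncation length that keeps both 5.8S anchors but goes below 400 bp.

    Uses attached regions if present, else locates the core end by exact
    search.  Returns None when no such length exists (caller pads instead).
    """
    seq = record.sequence
    if record.regions is not None:
        anchor_end = record.regions.coords[1][1]
    else:
        pos = seq.find(S58_CORE[-20:])
        if pos < 0:
            return None
        anchor_end = pos + 20
    lo = anchor_end + 5  # keep a non-empty ITS2 stub
    hi = min(399, len(seq) - 1)
    if lo > hi:
        return None
    return int(rng.integers(lo, hi + 1))


def inject_defects(
    records: list[SpecimenRecord],
    defects: DefectConfig,
    *,
    return_log: bool = False,
) -> list[SpecimenRecord] | tuple[list[SpecimenRecord], dict[str, set[str]]]:
    """Corrupt records, one independent seeded Bernoulli channel per filter.

    Channels: ``ambiguous`` (one base replaced by an IUPAC ambiguity code),
    ``no_voucher`` (voucher blanked), ``bad_name`` (organism name gains an
    inconclusive token), ``bad_length`` (sequence truncated below 400 bp or
    padded above 800 bp; the corruption preserves both 5.8S anchors so the
    record fails the *length* filter, not region extraction), and
    ``no_locality`` (locality blanked).  The input list is not modified.

    With ``return_log=True`` also returns {accession -> set of channels
    applied}, the ground truth for curation bookkeeping.
    """
    if not records:
        raise InputError("records must be non-empty")
    n = len(records)
    masks = {
        ch: rng_for(defects.seed, "defect", ch).random(n) < defects.probability(ch)
        for ch in DefectConfig.CHANNELS
    }
    rng_params = rng_for(defects.seed, "defect-params")

    out: list[SpecimenRecord] = []
    log: dict[str, set[str]] = {}
    for i, rec in enumerate(records):
        applied = {ch for ch in DefectConfig.CHANNELS if masks[ch][i]}
        changes: dict = {}
        seq = rec.sequence
        if "bad_length" in applied:
            if rng_params.random() < 0.5:
                t = _truncate_target(rec, rng_params)
            else:
                t = None
            if t is not None:
                seq = seq[:t]
            else:
                target = int(rng_params.integers(801, 901))
                pad = rng_params.choice(_BASES, max(target - len(seq), 1))
                seq = seq + _to_str(pad)
        if "ambiguous" in applied:
            pos = int(rng_params.integers(0, len(seq)))
            code = _AMBIGUITY_CODES[int(rng_params.integers(0, len(_AMBIGUITY_CODES)))]
            seq = seq[:pos] + code + seq[pos + 1 :]
        if seq != rec.sequence:
            changes["sequence"] = seq
            changes["regions"] = None
        if "no_voucher" in applied:
            changes["voucher"] = ""
        if "bad_name" in applied:
            token = ("sp.", "aff.", "cf.", "uncultured")[int(rng_params.integers(0, 4))]
            changes["name_qualifiers"] = (
                f"{token} {rec.name_qualifiers}".strip()
                if rec.name_qualifiers
                else token
            )
        if "no_locality" in applied:
            changes["locality"] = ""
        out.append(dataclasses.replace(rec, **changes) if changes else rec)
        if applied:
            log[rec.accession] = applied
    if return_log:
        return out, log
    return out


# --- packaged printed-table fixtures -----------------------------------------


def fixture_path(name: str) -> Path:
    """Path of a packaged fixture table (table1_pci.tsv, table2_groups.tsv)."""
    return Path(resources.files("barcodegap.data") / name)


def write_fixture_tables(outdir: str | Path) -> tuple[Path, Path]:
    """Copy the packaged printed-table fixtures into ``outdir``.

    ``table1_pci.tsv``: 113 genera x integer PCI values (%) for ITS, ITS1,
    ITS2.  ``table2_groups.tsv``: genus -> barcode-gap group 1-4, with the
    recommended marker(s) for group-2 genera.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in ("table1_pci.tsv", "table2_groups.tsv"):
        dst = outdir / name
        shutil.copyfile(fixture_path(name), dst)
        paths.append(dst)
    return tuple(paths)
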