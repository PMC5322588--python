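"""Filter cascade: per-filter semantics, idempotence, bookkeeping."""
from __future__ import annotations

import dataclasses

import pytest

from barcodegap.curation import (
    CurationConfig,
    filter_ambiguous,
    filter_its_complete,
    filter_lengths,
    filter_localities,
    filter_min_species_per_genus,
    filter_species_names,
    filter_voucher,
    run_curation,
)
from barcodegap.errors import ConfigurationError
from barcodegap.records import SpecimenRecord
from barcodegap.regions import S58_CORE
from barcodegap.simulate import DefectConfig, generate_genera, inject_defects


def rec(acc="R1", genus="Agaricus", epithet="bisporus", qualifiers="",
        voucher="V", locality="Brazil", seq="ACGT"):
    return SpecimenRecord(
        accession=acc, genus=genus, species_epithet=epithet,
        name_qualifiers=qualifiers, voucher=voucher, locality=locality,
        sequence=seq,
    )


def test_voucher_filter_keeps_only_vouchered():
    kept = filter_voucher([rec(acc="A", voucher="K(M)123"), rec(acc="B", voucher="")])
    assert [r.accession for r in kept] == ["A"]
    full = [rec(acc="A"), rec(acc="B")]
    assert filter_voucher(full) == full


def test_ambiguity_filter_is_strict_one_or_more():
    assert filter_ambiguous([rec(seq="ACGTN" + "ACGT" * 3)]) == []
    assert len(filter_ambiguous([rec(seq="ACGTACGT")])) == 1
    # single ambiguity code at the last position still disqualifies
    assert filter_ambiguous([rec(seq="ACGTACGR")]) == []


@pytest.mark.parametrize(
    "epithet,qualifiers,kept",
    [
        ("sp.", "", False),
        ("bisporus", "", True),
        ("edulis", "cf.", False),       # 'Boletus cf. edulis' style
        ("crassifolia", "", True),      # 'cf' inside a word is not a token
        ("affinis", "", True),          # 'aff' inside a word is not a token
        ("bisporus", "uncultured", False),
        ("", "", False),                # no concrete epithet
    ],
)
def test_name_filter_whole_token_semantics(epithet, qualifiers, kept):
    records = [rec(epithet=epithet, qualifiers=qualifiers)]
    assert (len(filter_species_names(records)) == 1) is kept


def test_name_filter_case_insensitive():
    assert filter_species_names([rec(epithet="SP.")]) == []
    assert filter_species_names([rec(epithet="bisporus", qualifiers="Uncultured")]) == []


def _its_seq(its1="A" * 150, its2="G" * 150):
    return its1 + S58_CORE + its2


def test_its_complete_attaches_regions(clean_genus):
    # clean_genus fixture already extracted; rebuild without regions
    bare = [r.with_regions(None) for r in clean_genus]
    out = filter_its_complete(bare)
    assert len(out) == len(bare)
    assert all(r.regions is not None for r in out)


def test_its_complete_removes_records_without_anchor():
    broken = rec(seq=_its_seq().replace(S58_CORE[:20], ""))
    assert filter_its_complete([broken]) == []


def test_its_complete_requires_nonempty_its1():
    # anchor at position 0 -> ITS1 empty -> not a complete ITS
    assert filter_its_complete([rec(seq=S58_CORE + "G" * 150)]) == []


@pytest.mark.parametrize(
    "its1_len,its2_len,kept",
    [
        (121, 121, True),    # total 400 inclusive
        (120, 121, False),   # total 399
        (321, 321, True),    # total 800 inclusive
        (321, 322, False),   # total 801
        (99, 251, False),    # ITS1 < 100 bp
        (251, 99, False),    # ITS2 < 100 bp
    ],
)
def test_length_filter_boundaries(its1_len, its2_len, kept):
    records = filter_its_complete(
        [rec(seq=_its_seq("A" * its1_len, "G" * its2_len))]
    )
    assert (len(filter_lengths(records)) == 1) is kept


def test_locality_filter_distinct_count_rule():
    species_a = [rec(acc=f"A{i}", epithet="alpha", locality=loc)
                 for i, loc in enumerate(["Brazil", "Brazil", "Chile"])]
    species_b = [rec(acc=f"B{i}", epithet="beta", locality=loc)
                 for i, loc in enumerate(["Brazil", "Chile", "Peru"])]
    kept = filter_localities(species_a + species_b)
    assert {r.species_epithet for r in kept} == {"beta"}


def test_locality_filter_drops_unlocated_then_counts():
    records = [rec(acc=f"C{i}", epithet="gamma", locality=loc)
               for i, loc in enumerate(["A", "B", "C", "", ""])]
    kept = filter_localities(records)
    assert len(kept) == 3 and all(r.locality for r in kept)


def test_locality_filter_validates_min():
    with pytest.raises(ConfigurationError):
        filter_localities([rec()], min_localities=0)


def test_min_species_filter():
    one_species = [rec(acc=f"D{i}", genus="Mono", epithet="unus") for i in range(5)]
    two_species = [rec(acc="E1", genus="Duo", epithet="unus"),
                   rec(acc="E2", genus="Duo", epithet="duo")]
    kept = filter_min_species_per_genus(one_species + two_species)
    assert {r.genus for r in kept} == {"Duo"}


@pytest.mark.parametrize(
    "filt",
    [filter_voucher, filter_ambiguous, filter_species_names,
     filter_its_complete, filter_localities, filter_min_species_per_genus],
)
def test_filters_idempotent_on_defect_dataset(filt):
    records = generate_genera(n_genera=6, seed=4)
    records = inject_defects(
        records,
        DefectConfig(p_ambiguous=0.2, p_no_voucher=0.2, p_bad_name=0.2,
                     p_no_locality=0.3, seed=4),
    )
    once = filt(records)
    assert filt(once) == once


def test_run_curation_clean_dataset_is_identity_cascade(clean_genus):
    kept, report = run_curation([r.with_regions(None) for r in clean_genus])
    assert len(kept) == len(clean_genus)
    for stage in report.stages:
        assert stage.n_in == stage.n_out == len(clean_genus)


def test_run_curation_absorbing_stage():
    records = generate_genera(n_genera=3, seed=8)
    records = inject_defects(records, DefectConfig(p_no_voucher=1.0, seed=8))
    kept, report = run_curation(records)
    assert kept == []
    assert report.stages[0].n_out == 0
    assert all(s.n_in == s.n_out == 0 for s in report.stages[1:])


def test_report_chains_and_respects_stage_order():
    records = generate_genera(n_genera=8, seed=15)
    records = inject_defects(
        records,
        DefectConfig(p_ambiguous=0.1, p_no_voucher=0.1, p_bad_name=0.1,
                     p_bad_length=0.1, p_no_locality=0.2, seed=15),
    )
    kept, report = run_curation(records)
    names = [s.stage_name for s in report.stages]
    assert names == ["voucher", "ambiguous", "species_names", "its_complete",
                     "lengths", "localities", "min_species_per_genus"]
    for prev, nxt in zip(report.stages, report.stages[1:]):
        assert prev.n_out == nxt.n_in
    assert report.stages[-1].n_out == len(kept)


def test_monotonicity_of_record_level_filters():
    """Adding a record never removes a survivor from record-level filters."""
    base = [rec(acc=f"M{i}", epithet=f"sp{i}x") for i in range(4)]
    extra = rec(acc="MX", voucher="", seq="ACGTN")
    for filt in (filter_voucher, filter_ambiguous, filter_species_names):
        kept_base = {r.accession for r in filt(base)}
        kept_more = {r.accession for r in filt(base + [extra])}
        assert kept_base <= kept_more


def test_group_filters_can_remove_previous_survivors():
    """Dropping one record can doom its whole species (locality rule)."""
    species = [rec(acc=f"G{i}", epithet="delta", locality=loc, voucher=v)
               for i, (loc, v) in enumerate(
                   [("A", "V"), ("B", "V"), ("C", "")])]
    kept, _ = run_curation(
        species, CurationConfig(its_complete=False, lengths=False,
                                min_species_per_genus=False)
    )
    # voucher filter removes G2, leaving 2 localities -> species removed
    assert kept == []


def test_config_toggles_disable_stages(clean_genus):
    records = inject_defects(
        [r.with_regions(None) for r in clean_genus],
        DefectConfig(p_no_voucher=1.0, seed=1),
    )
    kept, report = run_curation(records, CurationConfig(voucher=False))
    assert len(kept) == len(records)
    assert "voucher" not in [s.stage_name for s in report.stages]
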