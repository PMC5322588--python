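"""PCI, box statistics, gap classification and group assignment."""
from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodegap.distances import DistanceMatrix
from barcodegap.errors import EvaluationError, InputError
from barcodegap.markers import (
    BoxStats,
    GapClass,
    SpeciesDistanceSummary,
    assign_group,
    box_stats,
    classify_gap,
    distance_pools,
    evaluate_genus_marker,
    genus_pci,
    species_identified,
    species_summaries,
)


def matrix_from(species, values):
    labels = tuple((f"M{i}", sp) for i, sp in enumerate(species))
    return DistanceMatrix(labels=labels, values=np.asarray(values, dtype=float))


def random_matrix(rng, n_max=12, species_max=4):
    """A random valid small matrix (symmetric, zero diagonal, [0,1])."""
    n = int(rng.integers(3, n_max + 1))
    k = int(rng.integers(2, species_max + 1))
    # ensure at least one species with >= 2 members
    species = [f"sp{int(rng.integers(0, k))}" for _ in range(n)]
    species[0] = species[1] = "sp0"
    species[2] = "sp1"
    vals = rng.random((n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return matrix_from(species, vals)


def brute_force_summaries(matrix):
    """Oracle: literal double loop over all matrix pairs."""
    out = {}
    species = matrix.species
    n = len(matrix)
    for sp in dict.fromkeys(species):
        members = [i for i in range(n) if species[i] == sp]
        if len(members) < 2:
            continue
        intra, inter = [], []
        for i in members:
            for j in range(n):
                if j == i:
                    continue
                if species[j] == sp:
                    if j > i:
                        intra.append(matrix.values[i, j])
                else:
                    inter.append(matrix.values[i, j])
        if inter:
            out[sp] = (max(intra), min(inter), len(intra), len(inter))
    return out


def test_two_species_clean_separation():
    m = matrix_from(
        ["a", "a", "b", "b"],
        [[0, 0, 0.2, 0.2],
         [0, 0, 0.2, 0.2],
         [0.2, 0.2, 0, 0],
         [0.2, 0.2, 0, 0]],
    )
    summaries = {s.species: s for s in species_summaries(m)}
    assert summaries["a"].max_intra == 0.0 and summaries["a"].min_inter == 0.2
    assert summaries["b"].max_intra == 0.0 and summaries["b"].min_inter == 0.2
    assert genus_pci(m) == 1.0


def test_summaries_match_brute_force_on_random_matrices():
    rng = np.random.default_rng(31)
    for _ in range(25):
        m = random_matrix(rng)
        expected = brute_force_summaries(m)
        got = {s.species: (s.max_intra, s.min_inter, s.n_intra_pairs, s.n_inter_pairs)
               for s in species_summaries(m)}
        assert got.keys() == expected.keys()
        for sp in expected:
            assert got[sp][0] == pytest.approx(expected[sp][0])
            assert got[sp][1] == pytest.approx(expected[sp][1])
            assert got[sp][2:] == expected[sp][2:]


def test_singleton_species_excluded_but_contributes_inter():
    m = matrix_from(
        ["a", "a", "b"],
        [[0, 0.01, 0.005],
         [0.01, 0, 0.5],
         [0.005, 0.5, 0]],
    )
    summaries = species_summaries(m)
    assert [s.species for s in summaries] == ["a"]
    # singleton b's distances appear in a's min_inter
    assert summaries[0].min_inter == 0.005
    assert not species_identified(summaries[0])  # 0.005 < max_intra 0.01


def test_all_singletons_is_an_error():
    m = matrix_from(["a", "b", "c"], np.zeros((3, 3)))
    with pytest.raises(EvaluationError):
        species_summaries(m)


@pytest.mark.parametrize(
    "max_intra,min_inter,identified",
    [(0.02, 0.05, True), (0.05, 0.05, False), (0.05, 0.02, False)],
)
def test_identification_is_strict(max_intra, min_inter, identified):
    s = SpeciesDistanceSummary("x", max_intra, min_inter, 1, 1)
    assert species_identified(s) is identified


def test_pci_half_and_zero():
    # two species, one identified -> 0.5
    m = matrix_from(
        ["a", "a", "b", "b"],
        [[0, 0.01, 0.30, 0.30],
         [0.01, 0, 0.30, 0.30],
         [0.30, 0.30, 0, 0.40],
         [0.30, 0.30, 0.40, 0]],
    )
    assert genus_pci(m) == 0.5
    # every species overlapping -> 0.0
    m0 = matrix_from(
        ["a", "a", "b", "b"],
        [[0, 0.5, 0.1, 0.1],
         [0.5, 0, 0.1, 0.1],
         [0.1, 0.1, 0, 0.5],
         [0.1, 0.1, 0.5, 0]],
    )
    assert genus_pci(m0) == 0.0


# --- box statistics ----------------------------------------------------------


def test_box_stats_hand_computed_five_values():
    b = box_stats([1, 2, 3, 4, 5])
    assert (b.q1, b.median, b.q3) == (2, 3, 4)
    assert (b.whisker_low, b.whisker_high) == (1, 5)
    assert b.outliers == ()


def test_box_stats_constant_list():
    b = box_stats([0.3] * 6)
    assert b.q1 == b.median == b.q3 == b.whisker_low == b.whisker_high == 0.3
    assert b.iqr == 0 and b.outliers == ()


def test_box_stats_flags_outlier():
    # q1=q3=0, iqr=0 -> fences at 0 -> 10 is beyond the upper whisker
    b = box_stats([0, 0, 0, 0, 10])
    assert b.outliers == (10.0,)
    assert b.whisker_high == 0.0


def test_box_stats_whiskers_are_attained_values():
    vals = [1.0, 1.1, 1.2, 1.3, 9.9]
    b = box_stats(vals)
    assert b.whisker_low in vals and b.whisker_high in vals
    assert b.whisker_low >= b.q1 - 1.5 * b.iqr
    assert b.whisker_high <= b.q3 + 1.5 * b.iqr


def test_box_stats_empty_rejected():
    with pytest.raises(InputError):
        box_stats([])


# --- gap classification ------------------------------------------------------


def _box(vals):
    return box_stats(vals)


def test_classify_clear_gap_good():
    intra = _box([0.00, 0.01, 0.01, 0.02])
    inter = _box([0.20, 0.22, 0.25, 0.30])
    assert classify_gap(intra, inter) is GapClass.good


def test_classify_good_despite_overlapping_outliers():
    # outliers may overlap the other distribution without demoting the class
    intra = _box([0.01] * 20 + [0.25])
    inter = _box([0.20, 0.22, 0.25, 0.30])
    assert classify_gap(intra, inter) is GapClass.good


def test_classify_whisker_overlap_intermediate():
    intra = _box([0.00, 0.02, 0.04, 0.10])
    inter = _box([0.08, 0.20, 0.25, 0.30])
    b_intra, b_inter = intra, inter
    assert b_intra.q3 < b_inter.q1
    assert b_intra.whisker_high >= b_inter.whisker_low
    assert classify_gap(intra, inter) is GapClass.intermediate


def test_classify_box_overlap_poor():
    intra = _box([0.05, 0.10, 0.15, 0.22])
    inter = _box([0.12, 0.18, 0.25, 0.30])
    assert intra.q3 >= inter.q1
    assert classify_gap(intra, inter) is GapClass.poor


def test_classify_inverted_distances_poor():
    # intra above inter: poor regardless of box separation
    intra = _box([0.30, 0.35, 0.40])
    inter = _box([0.05, 0.10, 0.15])
    assert classify_gap(intra, inter) is GapClass.poor


def test_gap_class_total_order():
    assert GapClass.good > GapClass.intermediate > GapClass.poor


# --- invariance properties ---------------------------------------------------


@given(scale=st.floats(min_value=0.05, max_value=3.0))
@settings(max_examples=30, derandomize=True, deadline=None)
def test_scale_invariance_of_pci_and_class(scale):
    rng = np.random.default_rng(5)
    m = random_matrix(rng)
    vals = np.clip(m.values * scale, 0.0, 1.0)
    # avoid clipping distortion: only scales keeping everything in [0,1]
    if (m.values * scale).max() > 1.0:
        return
    scaled = DistanceMatrix(labels=m.labels, values=vals)
    assert genus_pci(scaled) == genus_pci(m)
    intra, inter = distance_pools(m)
    s_intra, s_inter = distance_pools(scaled)
    assert classify_gap(box_stats(s_intra), box_stats(s_inter)) is classify_gap(
        box_stats(intra), box_stats(inter)
    )


def test_inter_scaling_monotonicity():
    """Inflating interspecific distances (intra fixed) never lowers PCI and
    never degrades the gap class."""
    rng = np.random.default_rng(13)
    for _ in range(20):
        m = random_matrix(rng)
        species = np.array(m.species)
        inter_mask = species[:, None] != species[None, :]
        lam = 1.0 + rng.random()
        vals = m.values.copy()
        vals[inter_mask] = np.clip(vals[inter_mask] * lam, 0.0, 1.0)
        scaled = DistanceMatrix(labels=m.labels, values=vals)
        assert genus_pci(scaled) >= genus_pci(m)
        intra0, inter0 = distance_pools(m)
        intra1, inter1 = distance_pools(scaled)
        c0 = classify_gap(box_stats(intra0), box_stats(inter0))
        c1 = classify_gap(box_stats(intra1), box_stats(inter1))
        assert c1 >= c0


# --- group assignment --------------------------------------------------------


def test_group_assignment_examples():
    g = lambda a, b, c: assign_group({"ITS": a, "ITS1": b, "ITS2": c})
    assert g(GapClass.good, GapClass.good, GapClass.good).group == 1
    assert g(GapClass.poor, GapClass.poor, GapClass.poor).group == 4
    two = g(GapClass.good, GapClass.intermediate, GapClass.poor)
    assert two.group == 2 and two.recommended == ("ITS",)


def test_group_assignment_total_over_27_combinations():
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for combo in itertools.product(GapClass, repeat=3):
        res = assign_group(dict(zip(("ITS", "ITS1", "ITS2"), combo)))
        counts[res.group] += 1
        if res.group == 2:
            assert res.recommended and all(
                dict(zip(("ITS", "ITS1", "ITS2"), combo))[m] is GapClass.good
                for m in res.recommended
            )
    # all-good: 1 combo; any good but not all: 3 markers good-subsets
    assert counts[1] == 1 and counts[4] == 1
    assert counts[2] == 19 - 1  # combos with >= 1 good, minus the all-good
    assert sum(counts.values()) == 27


def test_group_assignment_requires_three_markers():
    with pytest.raises(InputError):
        assign_group({"ITS": GapClass.good, "ITS1": GapClass.good})


# --- full genus evaluation ---------------------------------------------------


def test_evaluate_genus_marker_pools_are_all_pairs(clean_genus):
    from barcodegap.distances import genus_distance_matrix

    m = genus_distance_matrix(clean_genus, "ITS")
    res = evaluate_genus_marker(m, "Testus", "ITS")
    n = len(m)
    assert len(res.intra_pool) + len(res.inter_pool) == n * (n - 1) // 2
    assert res.pci == genus_pci(m)
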