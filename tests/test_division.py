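"""Link severance, death modes and exact offspring-size asymmetry."""

import itertools

import numpy as np
import pytest

from snowflakesim import (
    SeveranceMode,
    build_unconstrained_tree,
    branch_partition,
    death_and_sever,
    expected_smaller_fraction,
    sever,
)
from snowflakesim.division import (
    asymptotic_biased_fraction,
    biased_fraction_oldest,
    uniform_fraction_oldest,
)

ALL_MODES = [
    SeveranceMode(v, l)
    for v, l in itertools.product(
        ("uniform_random_cell", "oldest_cell"),
        ("uniform_link", "branch_size_biased"),
    )
]


def brute_force_fraction(t, degree_cap, mode):
    """Independent oracle: explicit loop over every (victim, link)
    outcome using the object-level tree API."""
    cluster = build_unconstrained_tree(t, degree_cap)
    n = len(cluster)
    victims = [0] if mode.victim_rule == "oldest_cell" else list(range(n))
    total = 0.0
    for v in victims:
        parts = branch_partition(cluster, v)
        sizes = np.array([s for _, s in parts], dtype=float)
        if mode.link_rule == "branch_size_biased":
            link_p = sizes / sizes.sum()
        else:
            link_p = np.full(len(parts), 1.0 / len(parts))
        total += (link_p * np.minimum(sizes, n - sizes)).sum() / len(victims)
    return total / n


def test_sever_two_cell_cluster():
    c = build_unconstrained_tree(1)
    res = sever(c, (0, 1))
    assert len(res.fragment_a) == len(res.fragment_b) == 1
    assert res.smaller_fraction == 0.5


def test_sever_oldest_branch_halves_the_tree(uncapped_t3):
    res = sever(uncapped_t3, (0, 1))
    assert {len(res.fragment_a), len(res.fragment_b)} == {4}
    res.fragment_a.validate()
    res.fragment_b.validate()


def test_sever_leaf_link(uncapped_t3):
    leaf = next(c.id for c in uncapped_t3.cells() if not c.children)
    res = sever(uncapped_t3, (uncapped_t3.cell(leaf).parent, leaf))
    assert sorted([len(res.fragment_a), len(res.fragment_b)]) == [1, 7]
    assert res.smaller_fraction == pytest.approx(1 / 8)


def test_sever_rejects_missing_link(uncapped_t3):
    with pytest.raises(KeyError):
        sever(uncapped_t3, (5, 0))


def test_sever_frees_or_scars_attachment_sites(uncapped_t3):
    mother_links = uncapped_t3.cell(0).links_used
    freed = sever(uncapped_t3.copy(), (0, 1), free_link=True)
    assert freed.fragment_a.cell(0).links_used == mother_links - 1
    assert freed.fragment_b.cell(0).links_used == uncapped_t3.cell(1).links_used - 1
    scarred = sever(uncapped_t3.copy(), (0, 1), free_link=False)
    assert scarred.fragment_a.cell(0).links_used == mother_links
    assert scarred.fragment_b.cell(0).links_used == uncapped_t3.cell(1).links_used


def test_oldest_cell_rule_kills_the_root(rng):
    c = build_unconstrained_tree(3)
    mode = SeveranceMode("oldest_cell", "uniform_link")
    res = death_and_sever(c, mode, rng)
    dead_root = [f for f in (res.fragment_a, res.fragment_b) if not f.cell(0).alive or
                 any(not cell.alive for cell in f.cells())]
    assert res.severed_link[0] == 0 or res.severed_link[1] in (1, 2, 4)
    assert any(not cell.alive and cell.birth_gen == 0 for f in dead_root for cell in f.cells())


def test_single_cell_death_is_degenerate(rng):
    from snowflakesim import new_founder

    c = new_founder(0)
    res = death_and_sever(c, SeveranceMode(), rng)
    assert res.fragment_b is None and res.severed_link is None
    assert res.smaller_fraction == 0.0
    assert not res.fragment_a.cell(0).alive


def test_dead_cells_travel_with_their_fragment(rng):
    c = build_unconstrained_tree(4)
    res = death_and_sever(c, SeveranceMode("uniform_random_cell", "uniform_link"), rng)
    dead = sum(
        1 for f in (res.fragment_a, res.fragment_b) for cell in f.cells() if not cell.alive
    )
    assert dead == 1
    assert len(res.fragment_a) + len(res.fragment_b) == 16


@pytest.mark.parametrize(
    "t,cap,mode,expected",
    [
        (3, None, SeveranceMode("oldest_cell", "uniform_link"), 7 / 24),
        (3, None, SeveranceMode("oldest_cell", "branch_size_biased"), 21 / 56),
        (2, None, SeveranceMode("uniform_random_cell", "uniform_link"), 0.3125),
        (1, None, SeveranceMode("oldest_cell", "branch_size_biased"), 0.5),
    ],
)
def test_expected_fraction_worked_examples(t, cap, mode, expected):
    assert expected_smaller_fraction(t, cap, mode) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("mode", ALL_MODES, ids=lambda m: f"{m.victim_rule}-{m.link_rule}")
@pytest.mark.parametrize("cap", [None, 3, 4])
@pytest.mark.parametrize("t", [1, 2, 4, 6])
def test_vectorized_enumeration_matches_brute_force(t, cap, mode):
    assert expected_smaller_fraction(t, cap, mode) == pytest.approx(
        brute_force_fraction(t, cap, mode), abs=1e-12
    )


@pytest.mark.parametrize("t", range(1, 13))
def test_closed_forms_match_enumeration(t):
    assert expected_smaller_fraction(
        t, None, SeveranceMode("oldest_cell", "branch_size_biased")
    ) == pytest.approx(biased_fraction_oldest(t), abs=1e-12)
    assert expected_smaller_fraction(
        t, None, SeveranceMode("oldest_cell", "uniform_link")
    ) == pytest.approx(uniform_fraction_oldest(t), abs=1e-12)


def test_biased_fraction_approaches_one_third():
    esf = expected_smaller_fraction(
        20, None, SeveranceMode("oldest_cell", "branch_size_biased")
    )
    assert abs(esf - asymptotic_biased_fraction()) < 1e-5
    assert asymptotic_biased_fraction() == pytest.approx(1 / 3)


def test_uniform_fraction_decays_to_zero():
    vals = [uniform_fraction_oldest(t) for t in (5, 10, 15, 20)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < 0.06


@pytest.mark.parametrize("t", range(4, 9))
def test_mode_ordering_random_lt_oldest_lt_biased(t):
    """Weighting death toward older, central cells — and severance toward
    bigger branches — increases the smaller offspring's share."""
    random_uu = expected_smaller_fraction(
        t, None, SeveranceMode("uniform_random_cell", "uniform_link")
    )
    oldest_u = expected_smaller_fraction(
        t, None, SeveranceMode("oldest_cell", "uniform_link")
    )
    oldest_b = expected_smaller_fraction(
        t, None, SeveranceMode("oldest_cell", "branch_size_biased")
    )
    assert random_uu < oldest_u < oldest_b


@pytest.mark.parametrize("t", range(6, 11))
@pytest.mark.parametrize("cap", [3, 4])
def test_degree_caps_increase_offspring_symmetry(t, cap):
    mode = SeveranceMode("oldest_cell", "uniform_link")
    assert expected_smaller_fraction(t, cap, mode) > expected_smaller_fraction(
        t, None, mode
    )


@pytest.mark.parametrize("mode", ALL_MODES, ids=lambda m: f"{m.victim_rule}-{m.link_rule}")
@pytest.mark.parametrize("t", [1, 3, 5, 8])
def test_expected_fraction_never_exceeds_half(t, mode):
    assert expected_smaller_fraction(t, None, mode) <= 0.5 + 1e-12


def test_uniform_link_probabilities_on_root(rng):
    """Severing the root's links under the unbiased rule hits each of
    its three branches about equally often."""
    counts = {4: 0, 2: 0, 1: 0}
    for s in range(600):
        c = build_unconstrained_tree(3)
        res = death_and_sever(
            c, SeveranceMode("oldest_cell", "uniform_link"), np.random.default_rng(s)
        )
        counts[min(len(res.fragment_a), len(res.fragment_b))] += 1
    for k, v in counts.items():
        assert 130 <= v <= 270  # ~1/3 each; binomial 3-sigma bounds
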