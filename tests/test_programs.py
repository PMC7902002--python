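"""Pipeline mechanics: crossing schemes, selection, training windows, counts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from icbreed.designs import desk_designs
from icbreed.programs import (
    Cohort,
    build_grid_training_window,
    build_training_window,
    concat_cohorts,
    conventional_window_counts,
    grid_init_counts,
    grid_sample_and_select,
    grid_window_counts,
    initialize_state,
    make_crosses_max_avoidance,
    make_crosses_random,
    pair_universe_size,
    run_burnin,
    select_parents_truncation,
)
from icbreed.traits import sample_architecture

BURNIN_YEARS = 12


@pytest.fixture(scope="module")
def burned_state(founders_A, founders_B):
    """A desk-scale burn-in (shortened to 12 years) with grid initialization."""
    rng = np.random.default_rng(42)
    founders = {"A": founders_A, "B": founders_B}
    archs = {c: sample_architecture(founders[c], 0.9, np.random.default_rng(5 + i))
             for i, c in enumerate(("A", "B"))}
    designs = desk_designs()
    state = initialize_state(founders, archs, designs["Pheno"],
                             designs["Grid-GS"], BURNIN_YEARS, rng)
    return run_burnin(state, rng)


# ---------------------------------------------------------------------------
# structural counts


def test_pair_universe_size_oracle():
    # C(80, 2) = 80*79/2 = 3160
    assert pair_universe_size(80) == 3160
    assert pair_universe_size(2) == 1


def test_full_scale_window_counts(full_designs):
    # 5 PYT cohorts of 500 genotypes -> 2500 genotypes;
    # records: 5*500 PYT + 4*50 GIA1 + 3*13 GIA2 = 2500 + 200 + 39 = 2739
    assert conventional_window_counts(full_designs["Pheno"]) == (2500, 2739)
    # grid steady state: 5*500 genotypes per crop;
    # records: 5*(900 grid + 50 SIA1 + 8 SIA2) = 5*958 = 4790
    assert grid_window_counts(full_designs["Grid-GS"]) == (2500, 4790)
    # grid initialization: 5 years * 23 per-crop selections = 115 genotypes;
    # records: 5 * 23^2 = 2645 factorial pair records
    assert grid_init_counts(full_designs["Grid-GS"]) == (115, 2645)
    # the kept grid spans all 500 x 500 = 250,000 candidate pairs
    g = full_designs["Grid-GS"]
    assert g.grid_keep * g.grid_keep == 250_000


# ---------------------------------------------------------------------------
# crossing schemes


def test_random_crosses_distinct_pairs():
    rng = np.random.default_rng(1)
    crosses = make_crosses_random(20, 20, rng)
    assert crosses.shape == (20, 2)
    assert (crosses[:, 0] != crosses[:, 1]).all()
    seen = {tuple(sorted(c)) for c in crosses.tolist()}
    assert len(seen) == 20
    with pytest.raises(ValueError):
        make_crosses_random(3, 4, rng)  # only C(3,2)=3 pairs exist


@given(
    sizes=st.lists(st.integers(min_value=1, max_value=6), min_size=2, max_size=10),
    generation=st.integers(min_value=0, max_value=40),
)
def test_max_avoidance_equal_contribution_property(sizes, generation):
    # build a family-sorted parent list; pad to an even count
    families = np.repeat(np.arange(len(sizes)), sizes)
    if families.size % 2:
        families = np.append(families, len(sizes))
    families = np.sort(families)
    n_crosses = families.size // 2
    crosses = make_crosses_max_avoidance(families, generation, n_crosses)
    # every parent contributes to exactly one cross
    used = np.sort(crosses.ravel())
    assert np.array_equal(used, np.arange(families.size))
    # no self-cross
    assert (crosses[:, 0] != crosses[:, 1]).all()
    # when no family spans more than half the block, full sibs never meet
    counts = np.bincount(families)
    if counts.max() <= families.size // 2:
        assert (families[crosses[:, 0]] != families[crosses[:, 1]]).all()


def test_max_avoidance_rotates_with_generation():
    families = np.repeat(np.arange(4), 2)  # 8 parents, 4 families
    a = make_crosses_max_avoidance(families, 0, 4)
    b = make_crosses_max_avoidance(families, 1, 4)
    assert not np.array_equal(a, b)


def test_max_avoidance_geometry_validation():
    with pytest.raises(ValueError):
        make_crosses_max_avoidance(np.zeros(6, dtype=int), 0, 4)


# ---------------------------------------------------------------------------
# selection


def _toy_cohort(n, family, ids=None):
    ids = np.arange(n, dtype=np.int64) if ids is None else np.asarray(ids)
    return Cohort(
        ids=ids,
        haplo=np.zeros((n, 2, 3), dtype=np.uint8),
        family=np.asarray(family, dtype=np.int64),
        a_m=np.zeros(n), a_ic=np.zeros(n),
        birth_year=np.zeros(n, dtype=np.int32),
    )


def test_truncation_selects_best_and_orders_by_family():
    cohort = _toy_cohort(6, family=[0, 1, 0, 1, 2, 2])
    scores = np.array([5.0, 1.0, 4.0, 3.0, 2.0, 6.0])
    out = select_parents_truncation(cohort, scores, 4)
    # best four scores are 6, 5, 4, 3 -> ids 5, 0, 2, 3
    assert set(out.ids.tolist()) == {5, 0, 2, 3}
    # ordered by family for the pairing scheme
    assert (np.diff(out.family) >= 0).all()


def test_truncation_breaks_ties_by_id():
    cohort = _toy_cohort(4, family=[0, 0, 0, 0])
    scores = np.array([1.0, 1.0, 1.0, 1.0])
    out = select_parents_truncation(cohort, scores, 2)
    assert out.ids.tolist() == [0, 1]


def test_concat_cohorts_preserves_length():
    a = _toy_cohort(3, [0, 0, 1])
    b = _toy_cohort(2, [2, 2], ids=np.array([10, 11]))
    c = concat_cohorts(a, b)
    assert len(c) == 5
    assert c.ids.tolist() == [0, 1, 2, 10, 11]


# ---------------------------------------------------------------------------
# grid sampling


def test_grid_sample_and_select_oracle():
    rng = np.random.default_rng(7)
    ggia_A = np.array([0.0, 1.0, 2.0])
    ggia_B = np.array([0.0, 10.0])
    ids_A = np.array([100, 101, 102])
    ids_B = np.array([200, 201])
    field, adv = grid_sample_and_select(ggia_A, ggia_B, ids_A, ids_B,
                                        n_field=4, n_advance=2, rng=rng)
    assert field.shape == (4, 2)
    assert len({tuple(p) for p in field.tolist()}) == 4
    # best pair-gGIAs: (2+10)/2=6 then (1+10)/2=5.5
    assert adv.tolist() == [[2, 1], [1, 1]]
    with pytest.raises(ValueError):
        grid_sample_and_select(ggia_A, ggia_B, ids_A, ids_B, 7, 1, rng)


# ---------------------------------------------------------------------------
# pipeline integration (shortened desk burn-in)


def test_burnin_advances_to_final_year(burned_state):
    assert burned_state.year == BURNIN_YEARS
    assert len(burned_state.metrics) == BURNIN_YEARS


def test_pipeline_dh_cohorts_are_homozygous(burned_state):
    for crop in ("A", "B"):
        dh = burned_state.crops[crop].dh
        assert dh is not None and len(dh) > 0
        assert np.array_equal(dh.haplo[:, 0, :], dh.haplo[:, 1, :])


def test_conventional_training_window_respects_span(burned_state):
    desk = desk_designs()["Pheno"]
    ts = build_training_window(burned_state, "A", burned_state.year)
    years = ts.records["year"].to_numpy()
    assert years.max() - years.min() <= 4
    assert years.max() == burned_state.year - 1
    # steady state: 5 PYT cohorts of 100 genotypes
    assert ts.geno_ids.size == 5 * desk.pyt.entries
    assert set(ts.records["stage"]) <= {"PYT", "GIA1", "GIA2"}


def test_grid_training_window_after_initialization(burned_state):
    desk_grid = desk_designs()["Grid-GS"]
    # the window as seen by the first future-year model fit
    ts = build_grid_training_window(burned_state, burned_state.year + 1)
    for crop in ("A", "B"):
        # initialization keeps init_keep genotypes per crop per year
        assert ts.geno_ids[crop].size == 5 * desk_grid.init_keep
    # factorial pair records: init_keep^2 per initialization year, plus
    # the burn-in program's SIA pair records from the same span
    grid_records = ts.records[ts.records["stage"] == "GRID"]
    assert len(grid_records) == 5 * desk_grid.init_keep**2
    sia = desk_designs()["Pheno"]
    assert len(ts.records) == len(grid_records) + 5 * (
        sia.sia1.entries + sia.sia2.entries)
    years = ts.records["year"].to_numpy()
    assert years.max() - years.min() <= 4


def test_record_schema(burned_state):
    from icbreed.gsmodels import RECORD_COLUMNS

    assert set(burned_state.records[0]) == set(RECORD_COLUMNS)


def test_burnin_is_deterministic(founders_A, founders_B):
    founders = {"A": founders_A, "B": founders_B}
    archs = {c: sample_architecture(founders[c], 0.4, np.random.default_rng(9 + i))
             for i, c in enumerate(("A", "B"))}
    designs = desk_designs()
    runs = []
    for _ in range(2):
        rng = np.random.default_rng(77)
        state = initialize_state(founders, archs, designs["Pheno"], None, 6, rng)
        run_burnin(state, rng)
        runs.append(state)
    assert runs[0].metrics == runs[1].metrics
    a, b = runs[0].crops["A"].block, runs[1].crops["A"].block
    assert np.array_equal(a.ids, b.ids)
    assert np.array_equal(a.haplo, b.haplo)
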