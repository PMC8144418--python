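"""Tests for rate estimation, age grouping, and the uni likelihood fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryotx.estimation import (
    AgeGroupScheme,
    LbrCell,
    LbrTable,
    TransferRecord,
    bootstrap_lbr_ci,
    bootstrap_uni_ci,
    estimate_lbr,
    estimate_lbr_simplified,
    fit_lbr_table,
    fit_uni,
    uni_log_likelihood,
)
from embryotx.model import Cycle
from embryotx.simulate import ClinicSimConfig, simulate_clinic

from conftest import FRESH_BLAST, make_record

SCHEME = AgeGroupScheme()


class TestRecordValidation:
    def test_births_cannot_exceed_embryos(self):
        with pytest.raises(ValueError):
            make_record(2, 3)

    def test_age_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            make_record(1, 0, age=17)
        with pytest.raises(ValueError):
            make_record(1, 0, age=51)

    def test_heartbeats_bounded_by_embryos(self):
        with pytest.raises(ValueError):
            TransferRecord(30, FRESH_BLAST, 2, 1, n_fetal_heartbeats=3)


class TestAgeGroups:
    def test_window_membership_for_target_35(self):
        assert SCHEME.contains(33, 35)
        assert SCHEME.contains(37, 35)
        assert not SCHEME.contains(38, 35)
        assert not SCHEME.contains(32, 35)

    def test_pooled_group(self):
        assert SCHEME.contains(29, SCHEME.pooled_label)
        assert SCHEME.contains(25, SCHEME.pooled_label)
        assert not SCHEME.contains(35, SCHEME.pooled_label)
        # integer targets at or below the pooling boundary use the pooled group
        assert SCHEME.contains(20, 30)

    def test_target_above_range_errors(self):
        with pytest.raises(ValueError):
            SCHEME.contains(40, 44)

    def test_edge_windows_extend_symmetrically(self):
        assert SCHEME.contains(45, 43)
        assert SCHEME.contains(41, 43)
        assert not SCHEME.contains(46, 43)

    def test_label_for_age(self):
        assert SCHEME.label_for_age(30) == "<=34"
        assert SCHEME.label_for_age(40) == "40"
        assert SCHEME.label_for_age(44) is None


class TestLbrEstimators:
    def test_single_embryo_records_reduce_to_mean(self):
        records = [make_record(1, b) for b in (1, 0, 0, 0)]
        assert estimate_lbr(records) == pytest.approx(0.25)
        assert estimate_lbr_simplified(records) == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "data,expected",
        [([(2, 1), (1, 0)], 0.4), ([(2, 2), (2, 0)], 0.5)],
    )
    def test_least_squares_closed_form(self, data, expected):
        records = [make_record(n, b) for n, b in data]
        assert estimate_lbr(records) == pytest.approx(expected)

    def test_matches_generic_least_squares_solver(self):
        rng = np.random.default_rng(7)
        n = rng.integers(1, 4, size=40)
        b = rng.integers(0, n + 1)
        records = [make_record(int(ni), int(bi)) for ni, bi in zip(n, b)]
        oracle = np.linalg.lstsq(
            n.reshape(-1, 1).astype(float), b.astype(float), rcond=None
        )[0][0]
        assert estimate_lbr(records) == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize(
        "data,expected",
        [([(2, 1), (1, 0)], 1 / 3), ([(2, 2), (2, 0), (3, 1)], 3 / 7)],
    )
    def test_simplified_is_pooled_ratio(self, data, expected):
        records = [make_record(n, b) for n, b in data]
        assert estimate_lbr_simplified(records) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        n=st.integers(1, 4),
        births=st.lists(st.integers(0, 4), min_size=1, max_size=30),
    )
    def test_estimators_agree_when_embryo_counts_equal(self, n, births):
        records = [make_record(n, min(b, n)) for b in births]
        assert estimate_lbr(records) == pytest.approx(
            estimate_lbr_simplified(records), abs=1e-12
        )

    def test_duplicating_records_leaves_estimate_unchanged(self):
        records = [make_record(n, b) for n, b in [(2, 1), (3, 2), (1, 0)]]
        assert estimate_lbr(records) == pytest.approx(estimate_lbr(records * 2))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            estimate_lbr([])
        with pytest.raises(ValueError):
            estimate_lbr_simplified([])

    def test_ongoing_pregnancy_outcome(self):
        records = [
            TransferRecord(30, FRESH_BLAST, 2, 0, n_fetal_heartbeats=2),
            TransferRecord(30, FRESH_BLAST, 2, 0, n_fetal_heartbeats=0),
        ]
        assert estimate_lbr(records, outcome="ongoing_pregnancy") == pytest.approx(0.5)
        assert estimate_lbr(records) == pytest.approx(0.0)


class TestBootstrapCi:
    def test_degenerate_resampling_gives_point_interval(self):
        records = [make_record(1, 1) for _ in range(5)]
        assert bootstrap_lbr_ci(records, 200, seed=0) == (1.0, 1.0)

    def test_deterministic_under_seed(self):
        records = [make_record(n, b) for n, b in [(2, 1), (1, 1), (3, 0), (2, 2)] * 5]
        assert bootstrap_lbr_ci(records, 500, seed=42) == bootstrap_lbr_ci(
            records, 500, seed=42
        )

    def test_too_few_records_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            bootstrap_lbr_ci([make_record(1, 1)], 200, seed=0)

    def test_coverage_on_synthetic_cell(self):
        # true rate 0.3; CI from 500 single-embryo transfers should cover it
        # in most replicates (binomial bound: >=13/15 at the 95% level)
        rng = np.random.default_rng(11)
        covered = 0
        for rep in range(15):
            births = rng.random(500) < 0.3
            records = [make_record(1, int(b)) for b in births]
            lo, hi = bootstrap_lbr_ci(records, 400, seed=rep)
            covered += lo <= 0.3 <= hi
        assert covered >= 13


class TestFitLbrTable:
    def test_constant_rate_recovered_in_every_cell(self):
        config = ClinicSimConfig(
            n_transfers=3000,
            true_lbr_curve=lambda age, cat: 0.3,
            true_uni={Cycle.FRESH: 0.7, Cycle.FROZEN: 0.7},
            seed=5,
        )
        table = fit_lbr_table(simulate_clinic(config), SCHEME, n_bootstrap=300, seed=1)
        for (label, cat), cell in table.cells.items():
            if cell.n_transfers < 30 or cell.ci_low is None:
                continue
            se = max((cell.ci_high - cell.ci_low) / 3.92, 1e-3)
            assert abs(cell.lbr - 0.3) < 3 * se, (label, cat, cell)

    def test_empty_category_absent(self):
        records = [make_record(1, 0, age=30, category=FRESH_BLAST)] * 3
        table = fit_lbr_table(records, SCHEME, n_bootstrap=0)
        assert all(cat == FRESH_BLAST for (_, cat) in table.cells)

    def test_only_young_ages_gives_only_pooled_cells(self):
        # ages below 33 are outside every moving window, so only the
        # pooled young cell can be populated
        records = [make_record(2, 1, age=a) for a in (25, 28, 31, 32)]
        table = fit_lbr_table(records, SCHEME, n_bootstrap=0)
        assert set(table.cells) == {(SCHEME.pooled_label, FRESH_BLAST)}

    def test_ci_brackets_point_estimate(self):
        records = [make_record(n, b) for n, b in [(2, 1), (1, 1), (3, 0)] * 10]
        table = fit_lbr_table(records, SCHEME, n_bootstrap=400, seed=3)
        cell = table.cells[(SCHEME.pooled_label, FRESH_BLAST)]
        assert cell.ci_low <= cell.lbr <= cell.ci_high


def _one_cell_table(lbr, category=FRESH_BLAST, label=SCHEME.pooled_label):
    return LbrTable(
        cells={(label, category): LbrCell(lbr, None, None, 10, 20)},
        scheme=SCHEME,
    )


class TestUniLikelihood:
    def test_closed_form_singleton_term(self):
        table = _one_cell_table(0.3)
        transfer = make_record(2, 1)
        ll = uni_log_likelihood([transfer], table, 1.0)
        assert ll == pytest.approx(math.log(2 * 0.3 * 0.7), abs=1e-12)

    def test_zero_rate_cells_contribute_nothing(self):
        table = _one_cell_table(0.0)
        ll = uni_log_likelihood([make_record(2, 0), make_record(3, 0)], table, 0.9)
        assert ll == 0.0

    def test_uni_below_max_rate_rejected(self):
        table = _one_cell_table(0.5)
        with pytest.raises(ValueError, match="ill-formed"):
            uni_log_likelihood([make_record(2, 1)], table, 0.4)

    def test_singleton_probability_monotone_in_uni(self):
        # the grid argmax is unique because p(singleton) is increasing on [L, 1]
        table = _one_cell_table(0.3)
        grid = np.linspace(0.3, 1.0, 40)
        lls = [
            uni_log_likelihood([make_record(2, 1)], table, u) for u in grid[1:]
        ]
        assert all(np.diff(lls) > 0)


def _two_embryo_cohort(n, lbr, uni, seed):
    config = ClinicSimConfig(
        n_transfers=n,
        age_distribution={30: 1.0},
        category_mix={FRESH_BLAST: 1.0},
        embryos_per_transfer_distribution={2: 1.0},
        true_lbr_curve=lambda age, cat: lbr,
        true_uni={Cycle.FRESH: uni, Cycle.FROZEN: uni},
        seed=seed,
    )
    return simulate_clinic(config)


class TestFitUni:
    def test_recovers_true_uni(self):
        records = _two_embryo_cohort(2000, 0.3, 0.7, seed=2)
        table = fit_lbr_table(records, SCHEME, n_bootstrap=0)
        est = fit_uni(records, table)
        assert abs(est.value - 0.7) < 0.1
        assert not est.non_identifiable
        assert est.n_multiple_transfers == 2000

    def test_independence_data_fits_near_one_unflagged(self):
        records = _two_embryo_cohort(3000, 0.3, 1.0, seed=3)
        table = fit_lbr_table(records, SCHEME, n_bootstrap=0)
        est = fit_uni(records, table)
        assert est.value > 0.9
        assert not est.non_identifiable

    def test_excess_singletons_flagged_non_identifiable(self):
        # 60% singletons cannot happen under the model with rate 0.2:
        # p(singleton) <= 2 * 0.2 * (1 - 0.2) = 0.32 even at uni = 1
        transfers = [make_record(2, 1) for _ in range(60)] + [
            make_record(2, 0) for _ in range(40)
        ]
        est = fit_uni(transfers, _one_cell_table(0.2))
        assert est.value == 1.0
        assert est.non_identifiable

    def test_grid_argmax_is_grid_value(self):
        records = _two_embryo_cohort(500, 0.3, 0.7, seed=4)
        table = fit_lbr_table(records, SCHEME, n_bootstrap=0)
        est = fit_uni(records, table)
        grid_values = est.grid[:, 0]
        assert est.value in grid_values
        assert est.value == grid_values[np.argmax(est.grid[:, 1])] or est.non_identifiable

    def test_halving_grid_step_moves_estimate_at_most_one_step(self):
        records = _two_embryo_cohort(800, 0.3, 0.7, seed=6)
        table = fit_lbr_table(records, SCHEME, n_bootstrap=0)
        coarse = fit_uni(records, table, grid_step=0.01).value
        fine = fit_uni(records, table, grid_step=0.005).value
        assert abs(coarse - fine) <= 0.01 + 1e-12

    def test_no_multiples_errors(self):
        with pytest.raises(ValueError, match="multiple-embryo"):
            fit_uni([make_record(1, 0)], _one_cell_table(0.3))

    def test_all_zero_rate_cells_error(self):
        with pytest.raises(ValueError, match="zero-rate"):
            fit_uni([make_record(2, 0)], _one_cell_table(0.0))

    def test_multinomial_likelihood_agrees_roughly(self):
        records = _two_embryo_cohort(2000, 0.3, 0.7, seed=8)
        table = fit_lbr_table(records, SCHEME, n_bootstrap=0)
        singleton = fit_uni(records, table, likelihood="singleton").value
        multinomial = fit_uni(records, table, likelihood="multinomial").value
        assert abs(singleton - multinomial) < 0.1


class TestBootstrapUniCi:
    def test_deterministic_and_ordered(self):
        records = _two_embryo_cohort(400, 0.3, 0.7, seed=9)
        ci1 = bootstrap_uni_ci(records, SCHEME, n_bootstrap=100, seed=1)
        ci2 = bootstrap_uni_ci(records, SCHEME, n_bootstrap=100, seed=1)
        assert ci1 == ci2
        assert ci1[0] <= ci1[1]
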