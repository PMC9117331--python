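"""Signed KS activity scoring: oracle equivalence, screen scoring, threshold."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from signalome.scoring import (
    DEFAULT_THRESHOLD,
    active_drugs,
    derive_threshold,
    dmso_null_scores,
    per_cell_readout,
    score_screen,
    signed_ks,
)
from signalome.simulate import generate_screen
from signalome.simulate.screen import PATHWAYS, DrugSpec, ScreenDesign


def brute_force_signed_ks(treated, control):
    """Independent oracle: scan every sample point, count ECDF values."""
    t = np.asarray(treated, float)
    c = np.asarray(control, float)
    d = 0.0
    for x in np.concatenate([t, c]):
        ft = np.mean(t <= x)
        fc = np.mean(c <= x)
        d = max(d, abs(ft - fc))
    mt, mc = np.median(t), np.median(c)
    if mt > mc:
        sign = 1.0
    elif mt < mc:
        sign = -1.0
    else:
        sign = np.sign(t.mean() - c.mean())
    return sign * d


class TestSignedKS:
    def test_identical_samples_score_zero(self):
        assert signed_ks([1, 2, 3], [1, 2, 3]) == 0.0

    def test_fully_separated_lower_sample_scores_minus_one(self):
        assert signed_ks([1, 2, 3], [4, 5, 6]) == -1.0
        assert signed_ks([4, 5, 6], [1, 2, 3]) == 1.0

    def test_half_overlap_example(self):
        # ECDF gap peaks at 0.5 (at x=0); treated median 0.5 < control 1.0
        assert signed_ks([0, 1], [0.5, 1.5]) == -0.5

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            signed_ks([], [1.0])

    def test_oracle_equivalence_on_random_small_samples(self, rng):
        """|score| and sign match a brute-force ECDF scan to 1e-12."""
        for _ in range(1000):
            n, m = rng.integers(1, 51, size=2)
            t = rng.normal(rng.uniform(-1, 1), 1.0, size=n)
            c = rng.normal(0, 1.0, size=m)
            got = signed_ks(t, c)
            want = brute_force_signed_ks(t, c)
            assert abs(got - want) <= 1e-12
            # magnitude also matches the library KS statistic
            assert abs(abs(got) - stats.ks_2samp(t, c).statistic) <= 1e-12

    def test_antisymmetric_when_medians_differ(self, rng):
        for _ in range(200):
            t = rng.normal(0.3, 1, size=rng.integers(2, 40))
            c = rng.normal(0.0, 1, size=rng.integers(2, 40))
            if np.median(t) == np.median(c):
                continue
            assert signed_ks(t, c) == pytest.approx(-signed_ks(c, t), abs=1e-15)

    def test_invariant_under_monotone_transforms(self, rng):
        t = rng.lognormal(0.2, 0.5, size=40)
        c = rng.lognormal(0.0, 0.5, size=55)
        base = signed_ks(t, c)
        for f in (np.log, np.sqrt, lambda x: np.arctan(x) * 3 + 7):
            assert signed_ks(f(t), f(c)) == pytest.approx(base, abs=1e-15)

    @settings(derandomize=True, max_examples=200)
    @given(
        t=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
        c=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=30),
    )
    def test_score_bounded_and_matches_oracle(self, t, c):
        score = signed_ks(t, c)
        assert -1.0 <= score <= 1.0
        assert abs(score - brute_force_signed_ks(t, c)) <= 1e-12


class TestPerCellReadout:
    def test_translocation_reporter_uses_ratio(self):
        cell = {"cyto_mean": 4.0, "nuc_mean": 2.0, "bg_mean": 1.0}
        assert per_cell_readout(cell, "ratio") == 2.0

    def test_transcription_reporter_uses_background_subtracted_nucleus(self):
        cell = {"cyto_mean": 4.0, "nuc_mean": 5.0, "bg_mean": 2.0}
        assert per_cell_readout(cell, "nuclear_intensity") == 3.0

    def test_negative_background_subtraction_clips_to_zero(self):
        cell = {"cyto_mean": 0.0, "nuc_mean": 1.0, "bg_mean": 2.0}
        assert per_cell_readout(cell, "nuclear_intensity") == 0.0

    def test_zero_nucleus_in_ratio_mode_raises(self):
        with pytest.raises(ZeroDivisionError):
            per_cell_readout({"cyto_mean": 1.0, "nuc_mean": 0.0, "bg_mean": 0}, "ratio")

    def test_reporter_mode_assignment(self):
        from signalome.simulate.screen import READOUT_MODE

        assert READOUT_MODE["ERK"] == "ratio"
        assert READOUT_MODE["WNT"] == "nuclear_intensity"


def _tiny_cells(n_treated, n_control=40):
    rows = []
    for i in range(n_treated):
        rows.append(("W001", "drugX", 12.0, "ERK", 2.0 + 0.01 * i, 1.0, 0.1))
    for i in range(n_control):
        rows.append(("W002", "DMSO", 12.0, "ERK", 1.0 + 0.01 * i, 1.0, 0.1))
    return pd.DataFrame(
        rows,
        columns=["well", "drug", "time_h", "clone", "cyto_mean", "nuc_mean", "bg_mean"],
    )


class TestScoreScreen:
    def test_29_treated_cells_marks_score_invalid(self):
        m = score_screen(_tiny_cells(29), {"ERK": "ratio"})
        row = m.table.iloc[0]
        assert not row["valid"] and np.isnan(row["score"])

    def test_30_treated_cells_is_scored(self):
        m = score_screen(_tiny_cells(30), {"ERK": "ratio"})
        row = m.table.iloc[0]
        assert row["valid"] and row["score"] == 1.0  # fully shifted up

    def test_planted_activation_scores_increase_with_ramp(self, small_screen):
        design, cells, truth, matrix = small_screen
        drug = truth.drug_table[truth.drug_table["group"] == "A"].index[0]
        i = [d.name for d in design.drugs].index(drug)
        s = design.drugs[i].s
        p = int(np.argmax(truth.state_axis))  # most strongly activated pathway
        pathway = design.pathways[p]
        sub = matrix.table[
            (matrix.table["drug"] == drug) & (matrix.table["pathway"] == pathway)
        ].sort_values("time_h")
        scores = sub["score"].to_numpy()
        assert s > 0 and scores[-1] > 0.5
        assert scores[-1] > scores[1] > scores[0] - 0.2  # emerges over the ramp


class TestThreshold:
    def test_all_zero_null_scores_give_zero_threshold(self):
        assert derive_threshold(np.zeros(50)) == 0.0

    def test_uniform_grid_quantile_matches_documented_rule(self):
        grid = np.linspace(0.01, 0.30, 100)
        # frozen oracle: numpy linear-interpolation percentile of the grid
        assert derive_threshold(grid) == pytest.approx(
            np.percentile(grid, 99.5), abs=1e-15
        )
        assert derive_threshold(grid) == pytest.approx(0.29855, abs=1e-6)

    def test_too_few_scores_raise(self):
        with pytest.raises(ValueError, match="at least 20"):
            derive_threshold(np.zeros(19))

    def test_default_fallback_is_point_two(self):
        assert DEFAULT_THRESHOLD == 0.2


class TestNullScreen:
    def test_null_screen_stays_under_derived_threshold(self):
        """No effects, no jitter: treated wells behave like controls and at
        least 99% of scores fall below the control-derived threshold."""
        p = len(PATHWAYS)
        drugs = tuple(
            DrugSpec(f"null_{i}", 0.0, np.zeros(p)) for i in range(12)
        )
        design = ScreenDesign(
            drugs=drugs,
            n_dmso_wells=39,
            cells_per_well=150.0,
            well_jitter_sd=0.0,
            well_state_sd=0.0,
            seed=99,
        )
        cells, _ = generate_screen(design)
        matrix = score_screen(cells, design.modes)
        null = dmso_null_scores(cells, design.modes)
        threshold = derive_threshold(null)
        valid = matrix.table[matrix.table["valid"]]
        frac_below = (valid["score"].abs() <= threshold).mean()
        assert frac_below >= 0.99
        assert not active_drugs(matrix, max(threshold, DEFAULT_THRESHOLD))


class TestActiveDrugs:
    def test_infinite_threshold_selects_nothing(self, small_screen):
        *_, matrix = small_screen
        assert active_drugs(matrix, np.inf) == set()

    def test_planted_effects_are_detected(self, small_screen):
        design, _, truth, matrix = small_screen
        active = active_drugs(matrix, DEFAULT_THRESHOLD)
        conforming = set(
            truth.drug_table[truth.drug_table["group"] != "C"].index
        )
        assert conforming <= active

    def test_time_zero_scores_do_not_activate(self, small_screen):
        *_, matrix = small_screen
        t = matrix.table
        strong_at_zero = t[(t["time_h"] == 0) & (t["score"].abs() > 5)]
        assert strong_at_zero.empty  # sanity: column semantics


def test_score_matrix_array_round_trip(small_screen):
    *_, matrix = small_screen
    scores, mask = matrix.to_array()
    assert scores.shape == (
        len(matrix.drugs),
        len(matrix.pathways),
        len(matrix.timepoints),
    )
    assert np.isnan(scores[mask]).all()
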