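"""Zahnreihen segmentation, Z-spacing estimation and ratio summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracle import make_point, min_run_cover
from zahnreihen.analysis import (
    PairSpacing,
    WaveDirection,
    Zahnreihe,
    aggregate_mean_spacing,
    analyze_quadrant,
    classify_wave_direction,
    compute_z_spacing,
    ontogenetic_series,
    plotted_points,
    regional_z_spacing,
    replacement_ratio,
    segment_zahnreihen,
)
from zahnreihen.model import JawElement, JawQuadrant, Side, ValidationError


def scores_of(run):
    return [p.score for p in run.points]


class TestSegmentation:
    def test_single_descending_row_is_one_zahnreihe(self):
        pts = [make_point(i + 1, s) for i, s in enumerate([7, 6, 5, 4])]
        runs, exceptions = segment_zahnreihen(pts)
        assert len(runs) == 1 and not exceptions
        assert scores_of(runs[0]) == [7, 6, 5, 4]

    def test_pure_alternation_gives_two_point_runs(self):
        pts = [make_point(i + 1, s) for i, s in enumerate([5, 4, 5, 4, 5, 4])]
        runs, exceptions = segment_zahnreihen(pts)
        assert [scores_of(r) for r in runs] == [[5, 4]] * 3
        assert not exceptions

    def test_v18638_right_maxilla_reproduces_published_runs(self, v18638_quadrant):
        """The smallest Yinlong's right maxilla yields the four published
        Zahnreihen (M1-M3, M5-M6, M8-rM10, M10-M11) with rM1, rM2 and M13
        left over as exceptions."""
        runs, exceptions = segment_zahnreihen(plotted_points(v18638_quadrant))
        memberships = [[p.label for p in r.points] for r in runs]
        assert memberships == [
            ["M1", "M2", "M3"],
            ["M5", "M6"],
            ["M8", "M9", "rM10"],
            ["M10", "M11"],
        ]
        assert sorted(p.label for p in exceptions) == ["M13", "rM1", "rM2"]

    def test_unsorted_input_rejected(self):
        pts = [make_point(2, 5), make_point(1, 6)]
        with pytest.raises(ValidationError, match="sorted"):
            segment_zahnreihen(pts)

    def test_empty_input_gives_empty_result(self):
        assert segment_zahnreihen([]) == ([], [])

    def test_gap_tolerance_skips_empty_positions_only(self):
        # position 2 empty: tolerated; position 2 occupied by an
        # ineligible point: blocks the run.
        over_gap = [make_point(1, 6), make_point(3, 5)]
        runs, _ = segment_zahnreihen(over_gap)
        assert len(runs) == 1
        blocked = [make_point(1, 6), make_point(2, 7), make_point(3, 5)]
        runs, exceptions = segment_zahnreihen(blocked)
        assert [scores_of(r) for r in runs] == [[7, 5]]
        assert [p.score for p in exceptions] == [6]

    @given(
        st.lists(
            st.tuples(
                st.booleans(),  # position recorded at all
                st.one_of(st.none(), st.integers(4, 7)),  # functional score
                st.one_of(st.none(), st.integers(1, 3)),  # replacement score
            ),
            min_size=2,
            max_size=8,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_partition_and_descent_invariants(self, layout):
        """Every point lands in exactly one run or in exceptions, and every
        run descends strictly caudally."""
        pts = []
        for pos0, (present, f, r) in enumerate(layout):
            if not present:
                continue
            if f is not None:
                pts.append(make_point(pos0 + 1, f))
            if r is not None:
                pts.append(make_point(pos0 + 1, r))
        runs, exceptions = segment_zahnreihen(pts)
        covered = [id(p) for r in runs for p in r.points] + [id(p) for p in exceptions]
        assert sorted(covered) == sorted(id(p) for p in pts)
        for run in runs:
            assert all(
                b.position > a.position and b.score < a.score
                for a, b in zip(run.points, run.points[1:])
            )
        # rostral->caudal indexing
        assert [r.index for r in runs] == list(range(len(runs)))

    def test_greedy_matches_exhaustive_minimum_cover(self):
        """On random small rows the greedy partition uses exactly as many
        parts as the exhaustive minimum run cover."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 120:
            pts = []
            for pos in range(1, int(rng.integers(3, 9)) + 1):
                if rng.random() < 0.15:
                    continue
                if rng.random() < 0.85:
                    pts.append(make_point(pos, int(rng.integers(4, 8))))
                if rng.random() < 0.4:
                    pts.append(make_point(pos, int(rng.integers(1, 4))))
            if len(pts) < 2:
                continue
            runs, exceptions = segment_zahnreihen(pts)
            assert len(runs) + len(exceptions) == min_run_cover(pts)
            checked += 1


class TestZSpacing:
    def test_parallel_two_point_runs(self):
        runs, _ = segment_zahnreihen(
            [make_point(1, 5), make_point(2, 4), make_point(3, 5), make_point(4, 4)]
        )
        pairs, mean, skipped = compute_z_spacing(runs)
        assert mean == pytest.approx(2.0)
        assert not skipped

    def test_single_run_has_no_spacing(self):
        runs, _ = segment_zahnreihen([make_point(1, 7), make_point(2, 6)])
        pairs, mean, skipped = compute_z_spacing(runs)
        assert pairs == [] and mean is None

    def test_interpolation_at_unshared_levels(self):
        # run A: (1,7),(2,4); run B: (3,6),(4,5),(5,4): shared levels 4..6
        runs, _ = segment_zahnreihen(
            [make_point(1, 7), make_point(2, 4), make_point(3, 6),
             make_point(4, 5), make_point(5, 4)]
        )
        pairs, mean, _ = compute_z_spacing(runs)
        # A at 6 -> 1.333, 5 -> 1.667, 4 -> 2; B at 6 -> 3, 5 -> 4, 4 -> 5
        assert mean == pytest.approx(np.mean([3 - 4 / 3, 4 - 5 / 3, 5 - 2]))

    def test_disjoint_score_ranges_are_skipped_and_flagged(self):
        runs = [
            Zahnreihe([make_point(1, 7), make_point(2, 6)], 0),
            Zahnreihe([make_point(3, 2), make_point(4, 1)], 1),
        ]
        pairs, mean, skipped = compute_z_spacing(runs)
        assert skipped == [0] and mean is None

    def test_alternation_of_any_even_length_is_exactly_two(self):
        for n in (4, 8, 12):
            pts = [make_point(i + 1, 5 if i % 2 == 0 else 4) for i in range(n)]
            runs, _ = segment_zahnreihen(pts)
            _, mean, _ = compute_z_spacing(runs)
            assert mean == pytest.approx(2.0)
            assert classify_wave_direction(mean) is WaveDirection.ALTERNATING

    def test_published_chaoyangsaurus_aggregation(self):
        """Pooling the two published quadrant spacings 2.0 and 3.33 gives
        a taxon mean of 2.67 after half-up 2-decimal rounding."""
        assert aggregate_mean_spacing([2.0, 3.33]) == 2.67


class TestWaveDirection:
    @pytest.mark.parametrize(
        "spacing,expected",
        [
            (2.54, WaveDirection.ROSTRAL_TO_CAUDAL),
            (2.0, WaveDirection.ALTERNATING),
            (1.8, WaveDirection.CAUDAL_TO_ROSTRAL),
            (None, WaveDirection.UNDETERMINED),
        ],
    )
    def test_direction_rule(self, spacing, expected):
        assert classify_wave_direction(spacing) is expected

    def test_step_function_has_exactly_two_thresholds(self):
        eps = 0.05
        grid = np.arange(0.5, 4.0, 0.001)
        calls = [classify_wave_direction(float(z), eps=eps) for z in grid]
        changes = [
            (round(float(a_z), 3), a, b)
            for a_z, a, b in zip(grid[1:], calls, calls[1:])
            if a is not b
        ]
        assert len(changes) == 2
        assert changes[0][0] == pytest.approx(2.0 - eps, abs=0.002)
        assert changes[1][0] == pytest.approx(2.0 + eps + 0.001, abs=0.002)

    def test_non_positive_spacing_rejected(self):
        with pytest.raises(ValidationError):
            classify_wave_direction(0.0)


class TestRegionalSpacing:
    def test_one_pair_per_region(self):
        pairs = [PairSpacing(0, 3.0, 3.0), PairSpacing(1, 1.5, 10.0)]
        rostral, caudal = regional_z_spacing(pairs, row_length=13)
        assert rostral == 3.0 and caudal == 1.5

    def test_all_rostral_leaves_caudal_absent(self):
        pairs = [PairSpacing(0, 2.5, 2.0)]
        rostral, caudal = regional_z_spacing(pairs, row_length=13)
        assert rostral == 2.5 and caudal is None

    def test_v18638_rostral_spacing_exceeds_caudal(self, v18638_quadrant):
        """Z-spacing is higher rostrally in Yinlong's maxilla, i.e. the
        caudal tooth-row region replaces faster."""
        report = analyze_quadrant(v18638_quadrant)
        assert report.rostral_mean is not None and report.caudal_mean is not None
        assert report.rostral_mean > report.caudal_mean


class TestReplacementRatio:
    def test_v18638_right_maxilla(self, v18638_quadrant):
        n_f, n_r, ratio = replacement_ratio(v18638_quadrant)
        assert (n_f, n_r) == (10, 3)
        assert ratio == pytest.approx(0.30)

    def test_v14530_left_maxilla(self, yinlong_specimens):
        holotype = next(s for s in yinlong_specimens if s.specimen_id == "IVPP V14530")
        n_f, n_r, ratio = replacement_ratio(holotype.quadrant("maxilla", "left"))
        assert (n_f, n_r) == (13, 1)
        assert ratio == pytest.approx(1 / 13)

    def test_zero_replacement_is_ratio_zero(self):
        q = JawQuadrant(
            "X", "t", JawElement.DENTARY, Side.LEFT, [make_point(1, 5).source]
        )
        assert replacement_ratio(q)[2] == 0.0

    def test_zero_functional_is_undefined(self):
        q = JawQuadrant(
            "X", "t", JawElement.DENTARY, Side.LEFT, [make_point(1, 2).source]
        )
        with pytest.raises(ValidationError, match="undefined"):
            replacement_ratio(q)

    def test_ratio_at_most_one_on_all_fixtures(
        self, yinlong_specimens, ceratopsia_specimens
    ):
        """At most one replacement tooth per alveolus caps RT/FT at 1."""
        for sp in list(yinlong_specimens) + list(ceratopsia_specimens):
            for q in sp.quadrants:
                if q.n_functional:
                    assert 0.0 <= replacement_ratio(q)[2] <= 1.0


class TestOntogeneticSeries:
    def test_yinlong_maxilla_ratio_declines_with_size(self, yinlong_specimens):
        """Smaller Yinlong individuals replace proportionally more teeth:
        the RT/FT ratio never rises along the skull-length ordering."""
        table = ontogenetic_series(yinlong_specimens, element="maxilla")
        assert list(table["specimen_id"]) == [
            "IVPP V18638",
            "IVPP V18636",
            "IVPP V14530",
            "IVPP V18637",
        ]
        assert table.attrs["ratio_non_increasing"] is True
        assert table["ratio"].iloc[0] == pytest.approx(0.30)

    def test_single_specimen_trend_undetermined(self, yinlong_specimens):
        table = ontogenetic_series(yinlong_specimens[:1], element="maxilla")
        assert table.attrs["ratio_non_increasing"] is None

    def test_tied_ratios_count_as_non_increasing(self, yinlong_specimens):
        holotype = next(s for s in yinlong_specimens if s.specimen_id == "IVPP V14530")
        table = ontogenetic_series([holotype, holotype], element="maxilla")
        assert table.attrs["ratio_non_increasing"] is True

    def test_per_side_policy_yields_one_row_per_quadrant(self, yinlong_specimens):
        pooled = ontogenetic_series(yinlong_specimens, element="maxilla")
        per_side = ontogenetic_series(
            yinlong_specimens, element="maxilla", side_policy="per_side"
        )
        assert len(per_side) > len(pooled)
        assert set(per_side["side"]) <= {"left", "right"}
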