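"""Penalty factors: accuracy bins, geometric overlap, references, normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import monte_carlo_overlap
from qpass.errors import (
    AnnotationError,
    GeometryError,
    InputError,
    ReferenceGroupError,
)
from qpass.factors import (
    BallImpact,
    CohortReference,
    accuracy_penalty,
    fraction_to_penalty,
    impact_penalty,
    normalize_penalties,
    overlap_fraction,
    round_natural,
    time_penalty_raw,
    time_reference,
    touches_boundary,
    variability_penalty_raw,
    variability_reference,
)
from qpass.segmentation import PASS_TYPES, PassType

SQUARE = (0.0, 0.0, 0.61)  # the 0.61 m wall target


class TestAccuracyPenalty:
    @pytest.mark.parametrize("value", [0, 25, 50, 75, 100])
    def test_passthrough_of_recorded_values(self, value):
        assert accuracy_penalty(value) == value

    @pytest.mark.parametrize(
        "name, expected",
        [("perfect", 0), ("mostly_inside", 25), ("half", 50),
         ("mostly_outside", 75), ("outside", 100)],
    )
    def test_verbal_categories(self, name, expected):
        assert accuracy_penalty(name) == expected

    @pytest.mark.parametrize("bad", [30, "wide", -25])
    def test_unknown_category_rejected(self, bad):
        with pytest.raises(AnnotationError):
            accuracy_penalty(bad)


class TestOverlapFraction:
    def test_circle_strictly_inside(self):
        imp = BallImpact(center=(0.305, 0.305), radius=0.1, square=SQUARE)
        assert overlap_fraction(imp) == pytest.approx(1.0, abs=1e-6)
        assert not touches_boundary(imp)

    def test_circle_centred_on_edge(self):
        imp = BallImpact(center=(0.0, 0.305), radius=0.05, square=SQUARE)
        assert overlap_fraction(imp) == pytest.approx(0.5, abs=1e-3)
        assert touches_boundary(imp)

    def test_circle_fully_outside(self):
        imp = BallImpact(center=(-1.0, -1.0), radius=0.1, square=SQUARE)
        assert overlap_fraction(imp) == 0.0

    def test_matches_monte_carlo_oracle(self):
        mc_rng = np.random.default_rng(99)
        cfg_rng = np.random.default_rng(4)
        for _ in range(8):
            imp = BallImpact(
                center=tuple(cfg_rng.uniform(-0.3, 0.9, size=2)),
                radius=float(cfg_rng.uniform(0.05, 0.25)),
                square=SQUARE,
            )
            oracle = monte_carlo_overlap(imp, 10**6, mc_rng)
            assert overlap_fraction(imp) == pytest.approx(oracle, abs=1e-3)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(GeometryError):
            BallImpact(center=(0, 0), radius=0.0, square=SQUARE)
        with pytest.raises(GeometryError):
            BallImpact(center=(0, 0), radius=0.1, square=(0, 0, -1))


class TestFractionToPenalty:
    @pytest.mark.parametrize(
        "frac, touches, expected",
        [
            (1.0, False, 0),
            (1.0, True, 25),   # full cover but contacting a boundary line
            (0.0, False, 100),
            (0.0, True, 100),
            (0.8, False, 25),
            (0.5, False, 50),
            (0.2, False, 75),
            (1.0 / 3.0, False, 75),
            (2.0 / 3.0, False, 25),
        ],
    )
    def test_bins(self, frac, touches, expected):
        assert fraction_to_penalty(frac, touches) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            fraction_to_penalty(1.2, False)

    def test_monotone_quality_in_fraction(self):
        fracs = np.linspace(0, 1, 101)
        penalties = [fraction_to_penalty(f, True) for f in fracs]
        assert all(a >= b for a, b in zip(penalties, penalties[1:]))

    def test_geometric_scorer_monotone_as_ball_slides_out(self):
        # moving the impact centre away from the square never lowers the penalty
        xs = np.linspace(0.305, 1.2, 40)
        penalties = [
            impact_penalty(BallImpact(center=(x, 0.305), radius=0.12, square=SQUARE))
            for x in xs
        ]
        assert all(a <= b for a, b in zip(penalties, penalties[1:]))


class TestTimeFactor:
    def test_reference_is_quickest_type_mean(self):
        windows = {
            "chest": [40, 40], "bounce": [90, 90], "crossover": [100, 100],
            "between_the_leg": [110, 110], "behind_the_back": [120, 120],
        }
        assert time_reference(windows) == 40

    def test_single_type_degenerate(self):
        assert time_reference({"chest": [64, 66]}) == 65

    def test_matches_min_of_means_oracle(self, rng):
        for _ in range(20):
            windows = {
                pt: list(rng.integers(40, 200, size=rng.integers(2, 10)))
                for pt in PASS_TYPES
            }
            oracle = round_natural(min(np.mean(v) for v in windows.values()))
            assert time_reference(windows) == oracle

    def test_empty_reference_rejected(self):
        with pytest.raises(ReferenceGroupError):
            time_reference({})

    @pytest.mark.parametrize("n, ex_tr, expected", [(70, 70, 0), (83, 70, 13), (57, 70, 13)])
    def test_penalty_absolute_difference(self, n, ex_tr, expected):
        assert time_penalty_raw(n, ex_tr) == expected

    @given(n=st.integers(0, 500), m=st.integers(0, 500), ref=st.integers(0, 500))
    def test_penalty_triangle_inequality(self, n, m, ref):
        assert time_penalty_raw(n, ref) <= time_penalty_raw(n, m) + time_penalty_raw(m, ref) + 1


class TestVariabilityFactor:
    def test_reference_mean_of_constant(self):
        assert variability_reference({"chest": [50.0, 50.0, 50.0]})[PassType.CHEST] == 50.0

    def test_reference_two_point_mean(self):
        assert variability_reference({"bounce": [40.0, 60.0]})[PassType.BOUNCE] == 50.0

    def test_reference_matches_groupby_mean_oracle(self, rng):
        windows = {pt: list(rng.uniform(100, 600, size=12)) for pt in PASS_TYPES}
        ref = variability_reference(windows)
        for pt in PASS_TYPES:
            assert ref[pt] == pytest.approx(np.mean(windows[pt]))

    @pytest.mark.parametrize(
        "integral, ref, expected",
        [(300.0, 300.0, 0), (307.4, 300.0, 7), (292.6, 300.0, 7), (307.5, 300.0, 8)],
    )
    def test_penalty_rounding(self, integral, ref, expected):
        assert variability_penalty_raw(integral, ref) == expected

    def test_mean_reference_minimises_cohort_penalty(self, rng):
        # for symmetric integrals the group's own mean beats clearly-off references
        integrals = rng.normal(400.0, 30.0, size=200)
        mean_ref = float(integrals.mean())
        at_mean = np.mean([variability_penalty_raw(i, mean_ref) for i in integrals])
        sd = integrals.std()
        for offset in np.linspace(-3, 3, 13):
            if abs(offset) < 0.5:
                continue
            alt = mean_ref + offset * sd
            at_alt = np.mean([variability_penalty_raw(i, alt) for i in integrals])
            assert at_mean <= at_alt


class TestNormalizePenalties:
    def test_linear_scaling(self):
        np.testing.assert_allclose(normalize_penalties([0, 5, 10]), [0.0, 50.0, 100.0])

    def test_all_zero_pool(self):
        np.testing.assert_allclose(normalize_penalties([0, 0, 0]), [0.0, 0.0, 0.0])

    def test_empty_pool_rejected(self):
        with pytest.raises(InputError):
            normalize_penalties([])

    @given(
        raw=st.lists(st.integers(0, 10_000), min_size=1, max_size=50).filter(
            lambda v: max(v) > 0
        )
    )
    def test_max_maps_to_100_and_ratios_preserved(self, raw):
        out = normalize_penalties(raw)
        assert out.max() == pytest.approx(100.0)
        top = max(raw)
        for r, o in zip(raw, out):
            assert o == pytest.approx(r / top * 100.0, rel=1e-12)

    @given(
        raw=st.lists(st.integers(0, 1000), min_size=2, max_size=30).filter(
            lambda v: max(v) > 0
        ),
        c=st.floats(0.01, 1000.0),
    )
    def test_scale_invariance(self, raw, c):
        base = normalize_penalties(raw)
        scaled = normalize_penalties(np.asarray(raw, dtype=float) * c)
        np.testing.assert_allclose(scaled, base, rtol=1e-9, atol=1e-9)


class TestCohortReference:
    def _ref(self):
        return CohortReference(
            ex_tr=70,
            expt_ir={pt: 100.0 + 10 * i for i, pt in enumerate(PASS_TYPES)},
            source_group="A",
            fs=128.0,
        )

    def test_json_round_trip(self, tmp_path):
        ref = self._ref()
        path = tmp_path / "ref.json"
        ref.to_json(path)
        loaded = CohortReference.from_json(path)
        assert loaded.ex_tr == ref.ex_tr
        assert loaded.expt_ir == ref.expt_ir
        assert loaded.source_group == "A"
        assert loaded.filter == ref.filter

    def test_missing_pass_type_rejected(self):
        with pytest.raises(ReferenceGroupError):
            CohortReference(
                ex_tr=70, expt_ir={PassType.CHEST: 100.0}, source_group="A", fs=128.0
            )


class TestRounding:
    @pytest.mark.parametrize(
        "value, expected", [(7.4, 7), (7.5, 8), (7.6, 8), (0.0, 0), (0.5, 1)]
    )
    def test_round_half_away_from_zero(self, value, expected):
        assert round_natural(value) == expected

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            round_natural(-0.1)
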