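"""Charge-product statistic alpha, curve geometry and repeat ranking."""

import numpy as np
import pytest

from endocharge import (
    CompositionSpec,
    TitrationOptions,
    alpha_curve,
    build_profile,
    charge_curve,
    classify_segments,
    negativity_interval,
    net_charge,
    random_peptide,
    rank_repeats,
    sign_crossings,
)
from endocharge.interaction import AlignmentError, classify_value
from endocharge.protonation import ChargeCurve, get_table

TAB = get_table("protcalc_like")


def flat_curve(value, grid, sid="flat"):
    return ChargeCurve(sid, grid, np.full(len(grid), float(value)),
                       TitrationOptions(pka_table=TAB))


class TestAlphaCurve:
    def test_zero_curve_annihilates(self, fixture_curves, grid):
        e3, _, _ = fixture_curves
        assert np.all(alpha_curve(e3, flat_curve(0.0, grid)) == 0.0)

    def test_commutative(self, fixture_curves):
        e3, _, reps = fixture_curves
        np.testing.assert_array_equal(alpha_curve(e3, reps[2]),
                                      alpha_curve(reps[2], e3))

    def test_grid_mismatch_names_both_curves(self, fixture_curves, opts):
        e3, _, _ = fixture_curves
        other = ChargeCurve("short", np.array([5.0, 6.0]),
                            np.array([1.0, 0.5]), opts)
        with pytest.raises(AlignmentError, match="R112C_E3.*short"):
            alpha_curve(e3, other)

    def test_e3_rp1_negative_only_in_low_ph_window(self, fixture_curves, grid):
        """The E3 x RP1 product dips below zero only around pH 4.25-4.75."""
        e3, _, reps = fixture_curves
        a = alpha_curve(e3, reps[0])
        inside = (grid >= 4.3) & (grid <= 4.7)
        outside = (grid < 4.2) | (grid > 4.8)
        assert np.all(a[inside] < 0)
        assert np.all(a[outside] >= 0)


class TestBuildProfile:
    def test_single_repeat_mean_is_that_alpha(self, fixture_curves):
        e3, _, reps = fixture_curves
        prof = build_profile(e3, [reps[0]])
        np.testing.assert_array_equal(prof.mean_alpha, alpha_curve(e3, reps[0]))

    def test_empty_repeat_list_rejected(self, fixture_curves):
        e3, _, _ = fixture_curves
        with pytest.raises(AlignmentError):
            build_profile(e3, [])

    def test_mean_is_arithmetic_mean(self, fixture_curves):
        e3, _, reps = fixture_curves
        prof = build_profile(e3, reps)
        manual = sum(prof.per_repeat_alpha.values()) / len(reps)
        np.testing.assert_allclose(prof.mean_alpha, manual, rtol=0, atol=1e-12)

    def test_factorization_identity_on_random_inputs(self, grid, rng):
        """mean alpha == Z_ligand * mean(Z_repeats), an algebraic identity."""
        opts = TitrationOptions(pka_table=TAB)
        for _ in range(5):
            seeds = rng.integers(0, 2**31 - 1, size=4)
            peps = [
                random_peptide(
                    CompositionSpec(25, {"acidic": 0.3, "basic": 0.3}, int(s))
                )
                for s in seeds
            ]
            ligand, *reps = [charge_curve(p, grid, opts) for p in peps]
            prof = build_profile(ligand, reps)
            mean_z = np.mean([r.values for r in reps], axis=0)
            np.testing.assert_allclose(
                prof.mean_alpha, ligand.values * mean_z, rtol=0, atol=1e-12
            )

    def test_e4_mean_attractive_in_late_endosomal_ph(self, fixture_curves, grid):
        _, e4, reps = fixture_curves
        prof = build_profile(e4, reps)
        assert prof.mean_alpha[np.argmin(np.abs(grid - 5.5))] < 0

    def test_scaling_by_constant(self, fixture_curves):
        """Scaling one charge curve scales every alpha and the mean by c."""
        e3, _, reps = fixture_curves
        prof = build_profile(e3, reps)
        scaled = ChargeCurve(e3.sequence_id, e3.ph_grid, 2.5 * e3.values,
                             e3.options)
        prof2 = build_profile(scaled, reps)
        np.testing.assert_allclose(prof2.mean_alpha, 2.5 * prof.mean_alpha,
                                   rtol=1e-12)


class TestSignCrossings:
    def test_strictly_positive_has_none(self, grid):
        assert sign_crossings(grid, np.ones(len(grid))) == []

    def test_linear_root(self):
        grid = np.array([4.0, 8.0])
        assert sign_crossings(grid, np.array([-1.0, 1.0])) == [6.0]

    def test_exact_grid_zero_reported_once(self):
        grid = np.array([4.0, 5.0, 6.0])
        assert sign_crossings(grid, np.array([-1.0, 0.0, 1.0])) == [5.0]

    def test_matches_dense_grid_scan(self, fixture_curves, grid, opts):
        """Refined crossings agree with a step-1e-4 sign-change scan."""
        from endocharge import get_builtin

        e4, reps = fixture_curves[1], fixture_curves[2]
        seq_e4 = get_builtin("R112C_E4")
        seq_rp1 = get_builtin("RP1")

        def f(ph):
            return net_charge(seq_e4, ph, opts) * net_charge(seq_rp1, ph, opts)

        vals = alpha_curve(e4, reps[0])
        found = sign_crossings(grid, vals, f)
        dense = np.arange(4.0, 8.0, 1e-4)
        fd = np.array([f(p) for p in dense])
        flips = dense[np.where(np.sign(fd[:-1]) != np.sign(fd[1:]))[0]]
        assert len(found) == len(flips)
        for a, b in zip(found, flips):
            assert abs(a - b) < 2e-4


class TestNegativityInterval:
    def test_all_positive_is_none(self, grid):
        assert negativity_interval(grid, np.ones(len(grid))) is None

    def test_widest_of_multiple_intervals(self, caplog):
        grid = np.linspace(4.0, 8.0, 81)
        vals = np.sin(2 * np.pi * (grid - 4.0) / 4.0)  # neg on (6,8)
        vals[(grid > 4.4) & (grid < 4.6)] = -0.1  # narrow extra dip
        import logging

        with caplog.at_level(logging.WARNING, logger="endocharge.interaction"):
            iv = negativity_interval(grid, vals)
        assert iv is not None and iv[0] > 5.5
        assert "multiple" in caplog.text

    def test_endpoints_match_dense_scan(self, fixture_curves, grid):
        _, e4, reps = fixture_curves
        prof = build_profile(e4, reps)
        iv = negativity_interval(grid, prof.mean_alpha)
        dense = np.arange(4.0, 8.0, 1e-3)
        vals = np.interp(dense, grid, prof.mean_alpha)
        neg = dense[vals < 0]
        assert iv == pytest.approx((neg[0], neg[-1]), abs=2e-3)


class TestClassifySegments:
    def test_all_zero_is_single_neutral_segment(self, grid):
        segs = classify_segments(grid, np.zeros(len(grid)), eps=0.5)
        assert len(segs) == 1
        assert segs[0].label == "neutral"
        assert (segs[0].lo, segs[0].hi) == (grid[0], grid[-1])

    def test_segments_tile_grid_without_overlap(self, fixture_curves, grid):
        _, e4, reps = fixture_curves
        prof = build_profile(e4, reps)
        segs = classify_segments(grid, prof.mean_alpha, eps=0.5)
        assert segs[0].lo == grid[0] and segs[-1].hi == pytest.approx(grid[-1])
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.hi == pytest.approx(b.lo)
            assert a.label != b.label

    def test_e4_mean_segment_labels_along_pathway(self, fixture_curves, grid):
        """E4: attraction around pH 5.5, minimal near 6.5, repulsion near 7.5."""
        _, e4, reps = fixture_curves
        prof = build_profile(e4, reps)
        segs = classify_segments(grid, prof.mean_alpha, eps=0.5)

        def label_at(ph):
            return next(s.label for s in segs if s.lo <= ph <= s.hi)

        assert label_at(5.5) == "attractive"
        assert label_at(6.5) == "neutral"
        assert label_at(7.5) == "repulsive"

    def test_labels_agree_with_dense_probes(self, fixture_curves, grid):
        _, e4, reps = fixture_curves
        prof = build_profile(e4, reps)
        segs = classify_segments(grid, prof.mean_alpha, eps=0.5)
        for ph in np.arange(4.05, 8.0, 0.1):
            expected = classify_value(
                float(np.interp(ph, grid, prof.mean_alpha)), 0.5
            )
            seg_label = next(s.label for s in segs if s.lo <= ph <= s.hi)
            # boundary-adjacent probes may fall on either side
            if min(abs(ph - s.lo) for s in segs) > 0.05:
                assert seg_label == expected

    def test_sign_coherence_with_crossings(self, fixture_curves, grid):
        """Every sign crossing lies inside a label change as eps -> 0."""
        _, e4, reps = fixture_curves
        prof = build_profile(e4, reps)
        crossings = sign_crossings(grid, prof.mean_alpha)
        segs = classify_segments(grid, prof.mean_alpha, eps=1e-9)
        boundaries = [s.hi for s in segs[:-1]]
        for c in crossings:
            assert min(abs(c - b) for b in boundaries) < 1e-3


class TestRankRepeats:
    def test_single_curve_is_both_extremes(self, fixture_curves):
        _, _, reps = fixture_curves
        r = rank_repeats([reps[0]], 6.0)
        assert r.most_positive == r.most_negative == "RP1"

    def test_extremes_at_ph6(self, fixture_curves):
        _, _, reps = fixture_curves
        r = rank_repeats(reps, 6.0)
        assert r.most_positive == "RP7"
        assert r.most_negative == "RP1"

    def test_rp4_most_negative_at_low_ph(self, fixture_curves):
        """Below the crossover (~pH 4.6) RP4 overtakes RP1 as most negative."""
        _, _, reps = fixture_curves
        assert rank_repeats(reps, 4.4).most_negative == "RP4"

    def test_out_of_range_ph_rejected(self, fixture_curves):
        from endocharge import TitrationError

        _, _, reps = fixture_curves
        with pytest.raises(TitrationError):
            rank_repeats(reps, 9.0)

    def test_ties_break_by_input_order(self, grid):
        a = flat_curve(1.0, grid, "A")
        b = flat_curve(1.0, grid, "B")
        assert rank_repeats([a, b], 6.0).order == ("A", "B")


class TestIsoformAsymmetry:
    def test_e3_repulsion_dominates_at_neutral_ph(self, fixture_curves, grid):
        """E3's mean product exceeds E4's wherever both are repulsive (pH >= 6.5)."""
        e3, e4, reps = fixture_curves
        p3 = build_profile(e3, reps)
        p4 = build_profile(e4, reps)
        sel = grid >= 6.5
        assert np.all(p3.mean_alpha[sel] >= p4.mean_alpha[sel])
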