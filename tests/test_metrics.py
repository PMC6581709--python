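"""Outcome measures: centers, offset/spread/distance, confusion matrix,
CLR, summaries, and the clinical NSA cross-walk."""

import math

import numpy as np
import pytest
from shapely.geometry import Point

import handloc as hl
from handloc.hand_template import HandTemplate
from handloc.metrics import (
    UndefinedMetricError,
    discretize_response,
    round_report,
)

PALM_CENTER = (0.0, 50.0)  # deep inside the convex palm region


class TestResponseCenter:
    def test_single_point_is_its_own_center(self, right_template):
        assert hl.response_center([(5.0, 50.0)], right_template) == (5.0, 50.0)

    def test_centroid_in_convex_region(self, right_template):
        c = hl.response_center([(10.0, 40.0), (10.0, 60.0)], right_template)
        assert c == pytest.approx((10.0, 50.0))

    def test_centroid_in_web_notch_is_clamped_onto_outline(self, right_template):
        # responses on the index and middle fingertips: midpoint x=20, y=150
        # falls in the gap between the fingers (x in (18, 22), y > 95)
        a = right_template.site(5).position
        b = right_template.site(9).position
        mid = ((a[0] + b[0]) / 2, (a[1] + b[1]) / 2)
        assert not right_template.polygon.covers(Point(mid))
        c = hl.response_center([a, b], right_template)
        assert hl.contains(right_template, c)

    def test_empty_input_is_undefined(self, right_template):
        with pytest.raises(UndefinedMetricError):
            hl.response_center([], right_template)


class TestLocationMetrics:
    def test_responses_at_site_give_zero_offset_and_distance(self, right_template):
        site = right_template.site(21)
        rs = [site.position] * 5
        assert hl.location_offset(rs, site.position, right_template) == 0.0
        assert hl.location_distance(rs, site.position, right_template) == 0.0
        assert hl.location_spread(rs, right_template) == 0.0

    def test_symmetric_responses_offset_equals_center_error(self, right_template):
        site = right_template.site(23)  # (12, 32), deep palm
        rs = [(0.0, 40.0), (0.0, 60.0)]  # center (0, 50)
        expected_cm = math.dist(site.position, PALM_CENTER) / 10.0
        assert hl.location_offset(rs, site.position, right_template) == pytest.approx(
            expected_cm
        )

    def test_two_points_2cm_apart_spread_1cm(self, right_template):
        rs = [(0.0, 40.0), (0.0, 60.0)]  # 20 units = 2 cm apart
        assert hl.location_spread(rs, right_template) == pytest.approx(1.0)

    def test_distance_is_mean_of_individual_errors(self, right_template):
        site = right_template.site(23)
        sx, sy = site.position
        rs = [(sx, sy + 10.0), (sx, sy + 30.0)]  # 1 cm and 3 cm straight up
        assert hl.location_distance(rs, site.position, right_template) == pytest.approx(
            2.0
        )

    def test_spread_matches_rayleigh_closed_form(self, right_template):
        # mean distance of isotropic Gaussian samples to their mean is
        # sigma * sqrt(pi/2); convex palm neighborhood keeps geodesics straight
        sigma_cm = 0.5
        rng = np.random.default_rng(2024)
        pts = rng.normal(PALM_CENTER, sigma_cm * 10.0, size=(5000, 2))
        spread = hl.location_spread(pts, right_template)
        assert spread == pytest.approx(sigma_cm * math.sqrt(math.pi / 2), rel=0.02)

    def test_distance_at_least_offset_in_convex_region(self, right_template):
        # Jensen: mean error of points >= error of their mean when the
        # neighborhood is convex (geodesics are straight lines)
        rng = np.random.default_rng(5)
        site = right_template.site(21)
        for _ in range(20):
            rs = rng.uniform((-25.0, 20.0), (25.0, 80.0), size=(8, 2))
            d = hl.location_distance(rs, site.position, right_template)
            o = hl.location_offset(rs, site.position, right_template)
            assert d >= o - 1e-9


class TestConfusionMatrix:
    def test_identity_responses_give_identity_matrix(self, identity_session, right_template):
        cm = hl.confusion_matrix(identity_session, right_template)
        assert np.allclose(cm.matrix, 100.0 * np.eye(24))
        assert all(cm.row_n == 5)

    def test_rows_sum_to_100(self, right_template):
        subject = hl.VirtualSubject(
            field=hl.DistortionField(kind="identity", noise_sd_cm=1.5)
        )
        session = hl.simulate_session(subject, right_template, hl.ProtocolConfig(seed=8))
        cm = hl.confusion_matrix(session, right_template)
        assert np.allclose(cm.matrix.sum(axis=1), 100.0, atol=1e-9)

    def test_response_at_another_site_lands_in_that_column(self, right_template):
        trials = [
            hl.TrialRecord(1, site_id=1, response=right_template.site(9).position)
        ]
        session = hl.Session("x", hl.Side.RIGHT, 17.0, tuple(trials))
        cm = hl.confusion_matrix(session, right_template)
        assert cm.matrix[0, 8] == 100.0
        assert cm.row_n[0] == 1

    def test_missing_trials_excluded_from_percentages(self, right_template):
        trials = (
            hl.TrialRecord(1, site_id=1, response=right_template.site(1).position),
            hl.TrialRecord(2, site_id=1, attempts=3, response=None),
        )
        session = hl.Session("x", hl.Side.RIGHT, 17.0, trials)
        cm = hl.confusion_matrix(session, right_template)
        assert cm.matrix[0, 0] == 100.0
        assert cm.row_n[0] == 1
        assert cm.row_missing[0] == 1

    def test_discretization_matches_exhaustive_argmin(
        self, right_template, interior_points
    ):
        # independent route: full path queries per site, ties to lowest id
        for p in interior_points[:25]:
            exhaustive = {
                s.site_id: hl.geodesic_distance(right_template, p, s.position)
                for s in right_template.sites
            }
            best = min(exhaustive, key=lambda sid: (round(exhaustive[sid], 9), sid))
            assert discretize_response(p, right_template) == best

    def test_euclidean_option_matches_euclidean_argmin(
        self, right_template, interior_points
    ):
        for p in interior_points[:10]:
            best = min(
                right_template.sites,
                key=lambda s: (math.dist(p, s.position), s.site_id),
            ).site_id
            assert discretize_response(p, right_template, metric="euclidean") == best


class TestCorrectLocalizationRate:
    def test_identity_matrix_is_100_pct_sd_0(self, identity_session, right_template):
        cm = hl.confusion_matrix(identity_session, right_template)
        mean, sd = hl.correct_localization_rate(cm)
        assert (mean, sd) == (100.0, 0.0)

    def test_half_correct_sites_give_mean_50(self, right_template):
        trials = []
        for k, sid in enumerate(range(1, 25), start=1):
            target = sid if sid <= 12 else (sid - 12 if sid > 12 else sid)
            # sites 13..24 respond at a different site -> zero diagonal
            trials.append(
                hl.TrialRecord(k, sid, response=right_template.site(target).position)
            )
        session = hl.Session("x", hl.Side.RIGHT, 17.0, tuple(trials))
        cm = hl.confusion_matrix(session, right_template)
        mean, _ = hl.correct_localization_rate(cm)
        assert mean == pytest.approx(50.0)

    def test_fingertip_subset_uses_exactly_those_sites(self, right_template):
        # correct on fingertips only -> fingertip CLR 100, full CLR 5/24*100
        trials = []
        for k, sid in enumerate(range(1, 25), start=1):
            target = sid if sid in hl.FINGERTIP_SITES else (sid % 24) + 1
            trials.append(
                hl.TrialRecord(k, sid, response=right_template.site(target).position)
            )
        cm = hl.confusion_matrix(
            hl.Session("x", hl.Side.RIGHT, 17.0, tuple(trials)), right_template
        )
        tip_mean, tip_sd = hl.correct_localization_rate(cm, subset=hl.FINGERTIP_SITES)
        assert (tip_mean, tip_sd) == (100.0, 0.0)
        full_mean, _ = hl.correct_localization_rate(cm)
        assert full_mean == pytest.approx(100.0 * 5 / 24)

    def test_empty_subset_rejected(self, identity_session, right_template):
        cm = hl.confusion_matrix(identity_session, right_template)
        with pytest.raises(ValueError):
            hl.correct_localization_rate(cm, subset=[])


class TestSummarize:
    def test_zero_noise_identity_summary(self, identity_session, right_template):
        s = hl.summarize(identity_session, right_template)
        assert s.mean_offset_cm == 0.0
        assert s.mean_spread_cm == 0.0
        assert s.mean_distance_cm == 0.0
        assert s.mean_clr_pct == 100.0
        assert s.n_trials == 120
        assert s.n_missing == 0

    def test_trial_order_invariance(self, right_template):
        subject = hl.VirtualSubject(
            field=hl.DistortionField(kind="identity", noise_sd_cm=0.8)
        )
        session = hl.simulate_session(subject, right_template, hl.ProtocolConfig(seed=21))
        perm = np.random.default_rng(0).permutation(len(session.trials))
        shuffled = tuple(
            hl.TrialRecord(
                k, t.site_id, t.attempts, t.response, t.response_time
            )
            for k, t in enumerate((session.trials[i] for i in perm), start=1)
        )
        reordered = hl.Session("x", session.side, 17.0, shuffled)
        a = hl.summarize(session, right_template)
        b = hl.summarize(reordered, right_template)
        for oa, ob in zip(a.per_site, b.per_site):
            assert ob.offset_cm == pytest.approx(oa.offset_cm, abs=1e-9)
            assert ob.spread_cm == pytest.approx(oa.spread_cm, abs=1e-9)
            assert ob.distance_cm == pytest.approx(oa.distance_cm, abs=1e-9)

    def test_normalization_rescales_by_17_over_measured(self, right_template):
        subject = hl.VirtualSubject(
            field=hl.DistortionField(kind="identity", noise_sd_cm=0.8),
            hand_length_cm=21.25,
        )
        session = hl.simulate_session(subject, right_template, hl.ProtocolConfig(seed=4))
        raw = hl.summarize(session, right_template, normalize=False)
        norm = hl.summarize(session, right_template, normalize=True)
        assert norm.mean_offset_cm == pytest.approx(
            raw.mean_offset_cm * 17.0 / 21.25
        )
        assert norm.mean_clr_pct == raw.mean_clr_pct  # percentages scale-free

    def test_rigid_motion_invariance_and_scale_linearity(self, right_template):
        # rotate + translate template and responses jointly: cm metrics
        # unchanged; uniform scaling with fixed units_per_cm scales linearly
        theta = 0.3
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        shift = np.array([12.0, -7.0])

        def transformed(k=1.0, rotate=True):
            M = (R if rotate else np.eye(2)) * k
            from dataclasses import replace

            outline = tuple(tuple(M @ v + shift) for v in right_template.outline)
            sites = tuple(
                replace(s, position=tuple(M @ s.position + shift))
                for s in right_template.sites
            )
            return HandTemplate(
                outline=outline,
                sites=sites,
                hand_length=right_template.hand_length * k,
                units_per_cm=right_template.units_per_cm,
                side=right_template.side,
            ), M

        site = right_template.site(9)
        rs = np.array([(12.0, 150.0), (8.0, 140.0), (14.0, 120.0)])
        base_off = hl.location_offset(rs, site.position, right_template)
        base_spr = hl.location_spread(rs, right_template)
        for k in (1.0, 2.5):
            t2, M = transformed(k)
            rs2 = rs @ M.T + shift
            off2 = hl.location_offset(rs2, t2.site(9).position, t2)
            spr2 = hl.location_spread(rs2, t2)
            assert off2 == pytest.approx(base_off * k, rel=1e-9)
            assert spr2 == pytest.approx(base_spr * k, rel=1e-9)


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(1.6625, 1.7), (0.9417, 0.9), (4.9875, 5.0), (1.5625, 1.6), (0.05, 0.1)],
    )
    def test_half_up_report_rounding(self, value, expected):
        assert round_report(value) == expected


class TestNsaScoring:
    @pytest.mark.parametrize(
        "correct,score", [((True,) * 3, 2), ((True, True, False), 1),
                          ((False, True, False), 1), ((False,) * 3, 0)]
    )
    def test_per_location_rule(self, correct, score):
        from handloc.metrics import score_repetitions

        assert score_repetitions(correct) == score

    def test_total_is_sum_of_locations(self):
        obs = [
            hl.ClinicalObservation(f"loc{i}", reps)
            for i, reps in enumerate(
                [(True, False, False), (False,) * 3, (False,) * 3,
                 (True, True, False), (False, True, False), (False,) * 3]
            )
        ]
        score = hl.nsa_localization_score(obs)
        assert score.per_location == (1, 0, 0, 1, 1, 0)
        assert score.total == 3

    def test_wrong_location_count_rejected(self):
        with pytest.raises(ValueError):
            hl.nsa_localization_score(
                [hl.ClinicalObservation("a", (True, True, True))] * 5
            )


class TestNsaFromSession:
    def _session(self, right_template, field):
        subject = hl.VirtualSubject(field=field)
        return hl.simulate_session(subject, right_template, hl.ProtocolConfig(seed=2))

    def test_identity_zero_noise_scores_12(self, identity_session, right_template):
        assert hl.nsa_from_session(identity_session, right_template).total == 12

    def test_3cm_shift_everywhere_scores_0(self, right_template):
        session = self._session(
            right_template, hl.DistortionField(kind="distoproximal_shift", shift_cm=3.0)
        )
        assert hl.nsa_from_session(session, right_template).total == 0

    def test_1cm_shift_within_tolerance_scores_12(self, right_template):
        session = self._session(
            right_template, hl.DistortionField(kind="distoproximal_shift", shift_cm=1.0)
        )
        assert hl.nsa_from_session(session, right_template).total == 12

    def test_insufficient_responses_error_names_locations(
        self, identity_session, right_template
    ):
        trials = tuple(t for t in identity_session.trials if t.site_id != 9)
        renum = tuple(
            hl.TrialRecord(k, t.site_id, t.attempts, t.response)
            for k, t in enumerate(trials, start=1)
        )
        session = hl.Session("x", hl.Side.RIGHT, 17.0, renum)
        with pytest.raises(ValueError, match="digit_III_distal_phalanx"):
            hl.nsa_from_session(session, right_template)
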