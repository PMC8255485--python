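"""The synthetic cohort generator: trajectory statistics, call emission,
amplitude model, determinism, and ground-truth bookkeeping."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pytest

from usvscore.sync import ZoneTimeline
from usvscore.synthetic import (
    EmissionModel,
    MicArrayModel,
    OccupancyModel,
    SimConfig,
    generate_calls,
    generate_cohort,
    generate_trajectory,
    ground_truth_counts,
    rates_from_cvs,
    simulate_cohort,
)
from usvscore.vocabulary import KHZ22


def occupancy(tp, **kw):
    return OccupancyModel(focal_zone="N_reward", other_zone="E_reward",
                          target_preference=tp, **kw)


class TestTrajectory:
    def test_one_record_per_frame(self, zone_map):
        rng = np.random.default_rng(0)
        tracks, tl = generate_trajectory(occupancy(0.5), zone_map,
                                         600.0, 25.0, rng)
        assert len(tracks) == 15000
        assert tl.n_frames == 15000

    def test_degenerate_preference_never_visits_other(self, zone_map):
        rng = np.random.default_rng(1)
        _, tl = generate_trajectory(occupancy(1.0), zone_map, 600.0, 25.0, rng)
        assert tl.occupancy_frames("E_reward") == 0
        assert tl.occupancy_frames("N_reward") > 0

    def test_preference_converges_by_law_of_large_numbers(self, zone_map):
        rng = np.random.default_rng(2)
        _, tl = generate_trajectory(occupancy(0.5), zone_map,
                                    10_000.0, 25.0, rng)
        focal = tl.occupancy_frames("N_reward")
        other = tl.occupancy_frames("E_reward")
        assert abs(focal / (focal + other) - 0.5) < 0.05

    def test_positions_lie_inside_their_zone(self, zone_map):
        rng = np.random.default_rng(3)
        tracks, tl = generate_trajectory(occupancy(0.6), zone_map,
                                         60.0, 25.0, rng)
        for rec, zone in zip(tracks[::50], tl.zones[::50]):
            assert zone_map.zone_of(rec.x, rec.y) == str(zone)

    def test_unequal_dwell_means_still_hit_target(self, zone_map):
        model = occupancy(0.3, mean_dwell_focal=10.0, mean_dwell_other=40.0)
        rng = np.random.default_rng(4)
        _, tl = generate_trajectory(model, zone_map, 10_000.0, 25.0, rng)
        focal = tl.occupancy_frames("N_reward")
        other = tl.occupancy_frames("E_reward")
        assert abs(focal / (focal + other) - 0.3) < 0.05

    def test_transition_rows_sum_to_one(self):
        tm = occupancy(0.7).transition_matrix()
        assert np.allclose(tm.sum(axis=1), 1.0)

    def test_non_positive_duration_rejected(self, zone_map):
        with pytest.raises(ValueError):
            generate_trajectory(occupancy(0.5), zone_map, 0.0, 25.0,
                                np.random.default_rng(0))


def single_zone_timeline(seconds, zone="N_reward", frame_rate=25.0):
    n = int(seconds * frame_rate)
    return ZoneTimeline(zones=np.full(n, zone, dtype=object),
                        frame_rate=frame_rate)


class TestCalls:
    def test_all_zero_rates_yield_no_calls(self):
        model = EmissionModel(rates={"N_reward": {"Trill": 0.0}})
        calls = generate_calls(model, single_zone_timeline(1000),
                               MicArrayModel(), np.random.default_rng(0))
        assert calls == []

    def test_poisson_count_within_three_sigma(self):
        model = EmissionModel(rates={"N_reward": {"Trill": 0.5}})
        calls = generate_calls(model, single_zone_timeline(1000),
                               MicArrayModel(), np.random.default_rng(7))
        # thinning removes ~rate*duration ~ 2% of candidates
        assert abs(len(calls) - 500) < 3 * math.sqrt(500) + 0.02 * 500

    def test_calls_never_overlap(self):
        model = EmissionModel(rates={"N_reward": {"Trill": 1.0, "Flat": 1.0,
                                                  KHZ22: 0.05}})
        calls = generate_calls(model, single_zone_timeline(500),
                               MicArrayModel(), np.random.default_rng(8))
        ordered = sorted(calls, key=lambda c: c.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end <= b.start

    def test_source_at_microphone_gets_loudest_channel(self):
        mics = MicArrayModel(noise_sd_db=0.0)
        model = EmissionModel(rates={"N_reward": {"Trill": 0.2}})
        positions = np.tile(np.array(mics.positions[0]), (25 * 100, 1))
        calls = generate_calls(model, single_zone_timeline(100), mics,
                               np.random.default_rng(9), positions)
        assert calls
        for c in calls:
            assert int(np.argmax(c.amplitudes)) == 0

    def test_rate_calibration_recovers_cvs(self):
        """Realized frames/s converge to the calibration target."""
        target = 0.4
        rates = rates_from_cvs(target, {"Trill": 0.6, "Flat": 0.4})
        model = EmissionModel(rates={"N_reward": rates})
        tl = single_zone_timeline(20_000)
        calls = generate_calls(model, tl, MicArrayModel(),
                               np.random.default_rng(10))
        counts = ground_truth_counts(calls, tl)["N_reward"]
        realized = sum(counts.values()) / 20_000
        # thinning (uncompensated here) costs ~1%; allow 5% relative
        assert realized == pytest.approx(target, rel=0.05)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            EmissionModel(rates={"z": {"Trill": -0.1}})


class TestCohort:
    def test_same_seed_byte_identical(self, tmp_path):
        cfg = SimConfig(n_animals=1, seed=21)
        d1 = generate_cohort(cfg, tmp_path / "c1")
        d2 = generate_cohort(cfg, tmp_path / "c2")

        def digest(root):
            out = {}
            for p in sorted(Path(root).rglob("*")):
                if p.is_file():
                    rel = p.relative_to(root)
                    out[str(rel)] = hashlib.sha256(p.read_bytes()).hexdigest()
            return out

        assert digest(d1.root) == digest(d2.root)

    def test_trial_file_count(self, tmp_path):
        # 8 animals x (2 SDT conditions x 1 day + 3 SSPT conditions)
        cfg = SimConfig(n_animals=8, sdt_days=(2,), seed=1)
        ds = generate_cohort(cfg, tmp_path / "c")
        assert len(ds.manifest["trials"]) == 40
        labels = list((ds.root / "trials").glob("*_labels.csv"))
        assert len(labels) == 40

    def test_duplicate_trial_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SimConfig(n_animals=1, sdt_days=(2, 2), seed=0).trial_metas()

    def test_one_hot_holds_on_generated_labels(self):
        cfg = SimConfig(n_animals=2, seed=13)
        for sim in simulate_cohort(cfg):
            ordered = sorted(sim.calls, key=lambda c: c.start)
            for a, b in zip(ordered, ordered[1:]):
                assert a.end <= b.start

    def test_ground_truth_counts_conserve_frames(self):
        cfg = SimConfig(n_animals=1, seed=14)
        (sim, *_) = simulate_cohort(cfg)
        total = sum(sum(z.values()) for z in sim.true_counts.values())
        # every counted frame lies within some call's span
        span_frames = sum(
            math.ceil(c.end * 25) - math.floor(c.start * 25)
            for c in sim.calls)
        assert 0 < total <= span_frames

    def test_planted_trill_asymmetry_sign_recovered(self, zone_map):
        """With Trill emitted asymmetrically across zones and Flat
        symmetrically, the cohort-mean delta-SVS sign matches the
        planted asymmetry in >= 95% of replicate cohorts (600 s trials,
        8 animals), while Flat's delta stays centered on zero."""
        from usvscore.synthetic import (_dwell_segments,
                                        timeline_from_segments)

        model = occupancy(0.5)
        emission = EmissionModel(rates={
            "N_reward": {"Trill": 0.10, "Flat": 0.05},
            "E_reward": {"Trill": 0.03, "Flat": 0.05},
        })
        mics = MicArrayModel()
        trill_signs, flat_means = [], []
        for rep in range(20):
            dsvs_tr, dsvs_fl = [], []
            for animal in range(8):
                rng = np.random.default_rng(1000 + 97 * rep + animal)
                segs = _dwell_segments(model, 600.0, rng)
                tl = timeline_from_segments(segs, 600.0, 25.0)
                calls = generate_calls(emission, tl, mics, rng)
                counts = ground_truth_counts(calls, tl)
                svs = {}
                for zone in ("N_reward", "E_reward"):
                    occ = tl.occupancy_frames(zone) / 25.0
                    zc = counts.get(zone, {})
                    svs[zone] = {s: zc.get(s, 0) / occ
                                 for s in ("Trill", "Flat")}
                dsvs_tr.append(svs["N_reward"]["Trill"]
                               - svs["E_reward"]["Trill"])
                dsvs_fl.append(svs["N_reward"]["Flat"]
                               - svs["E_reward"]["Flat"])
            trill_signs.append(np.mean(dsvs_tr) > 0)
            flat_means.append(np.mean(dsvs_fl))
        assert sum(trill_signs) >= 19  # >= 95% of 20 cohorts
        assert abs(np.mean(flat_means)) < 0.02

    def test_emission_recovery_on_long_trial(self, zone_map):
        """Realized zone CVS converges to its planted calibration target."""
        from usvscore.io_formats import TrialMeta
        from usvscore.synthetic import (SSPT_CVS_OTHER, SSPT_DELTA_BASE,
                                        SSPT_DELTA_SLOPE, animal_effects,
                                        simulate_trial)

        cfg = SimConfig(n_animals=1, trial_duration=10_000.0, seed=15)
        meta = TrialMeta("rat01", "SSPT", "Jv5", 2, "A")
        sim = simulate_trial(cfg, meta, zone_map, with_positions=False)
        occ_s = sim.occupancy_frames(sim.focal_zone) / 25.0
        frames = sum(v for s, v in sim.true_counts[sim.focal_zone].items()
                     if s != KHZ22)
        eff = animal_effects(cfg, "rat01")
        target = (SSPT_CVS_OTHER * eff.propensity + SSPT_DELTA_BASE
                  + SSPT_DELTA_SLOPE * 5.0 + eff.delta_intercept)
        assert frames / occ_s == pytest.approx(target, rel=0.05)
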