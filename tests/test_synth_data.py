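"""Properties of the synthetic procedure generator."""

import numpy as np
import pytest

from endovlm.synth import (DatasetManifest, GeneratorConfig, LandmarkVector,
                           build_dataset, build_state_catalogue,
                           label_frequencies, oracle_decode_frame,
                           render_frame, sample_procedure)
from endovlm.synth.config import default_transition_matrix
from endovlm.synth.dataset import FrameRecord


def small_config(**kw):
    defaults = dict(seed=9, n_procedures=2, activities_per_procedure=(6, 8),
                    activity_duration=(1.0, 2.0), missing_channel_rate=0.0)
    defaults.update(kw)
    return GeneratorConfig(**defaults)


class TestConfig:
    def test_long_tail_invariant_enforced(self):
        with pytest.raises(ValueError):
            GeneratorConfig(class_frequencies=(0.15,) * 16)

    def test_transition_rows_must_normalise(self):
        bad = np.full((20, 20), 1.0 / 20)
        bad[0, 0] += 1e-3
        with pytest.raises(ValueError):
            GeneratorConfig(transition_matrix=bad)

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        cfg.save(tmp_path / "cfg.yaml")
        back = GeneratorConfig.load(tmp_path / "cfg.yaml")
        assert back.to_dict() == cfg.to_dict()


class TestProcedureSampling:
    def test_absorbing_chain_keeps_one_state(self):
        cfg = small_config(n_states=2, transition_matrix=np.eye(2),
                           activities_per_procedure=(3, 3))
        acts = sample_procedure(cfg, procedure_seed=1)
        assert len({a.state_id for a in acts}) == 1

    def test_seeded_determinism(self):
        cfg = small_config()
        a1 = sample_procedure(cfg, procedure_seed=4)
        a2 = sample_procedure(cfg, procedure_seed=4)
        assert [(x.state_id, x.start_time, x.keyword, x.report_sentence)
                for x in a1] == \
               [(x.state_id, x.start_time, x.keyword, x.report_sentence)
                for x in a2]
        a3 = sample_procedure(cfg, procedure_seed=5)
        assert [x.state_id for x in a1] != [x.state_id for x in a3]

    def test_two_state_switch_rate_matches_binomial(self):
        # oracle: 10,000 Bernoulli(0.9) transitions, 3-sigma band
        tm = np.array([[0.1, 0.9], [0.9, 0.1]])
        cfg = small_config(n_states=2, transition_matrix=tm,
                           activities_per_procedure=(10001, 10001))
        states = np.array([a.state_id for a in sample_procedure(cfg, 0)])
        switch_rate = float(np.mean(states[1:] != states[:-1]))
        sigma = np.sqrt(0.9 * 0.1 / 10000)
        assert abs(switch_rate - 0.9) <= max(3 * sigma, 0.01)

    def test_durations_within_configured_range(self):
        cfg = small_config()
        for a in sample_procedure(cfg, 0):
            assert cfg.activity_duration[0] <= a.duration <= cfg.activity_duration[1]

    def test_movement_direction_deterministic_in_transition(self):
        from endovlm.synth.procedures import movement_direction
        assert movement_direction(3, 3) == "hold"
        assert movement_direction(2, 5) == movement_direction(6, 9)

    def test_consecutive_states_share_information(self):
        """Non-uniform rows make the next state predictable above chance
        (positive empirical mutual information between consecutive states)."""
        cfg = small_config(activities_per_procedure=(2000, 2000))
        states = np.array([a.state_id for a in sample_procedure(cfg, 0)])
        S = cfg.n_states
        joint = np.zeros((S, S))
        for a, b in zip(states[:-1], states[1:]):
            joint[a, b] += 1
        joint /= joint.sum()
        px = joint.sum(1, keepdims=True)
        py = joint.sum(0, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            mi = np.nansum(joint * np.log(joint / (px * py)))
        assert mi > 0.1


class TestCatalogue:
    def test_membership_counts_match_frequencies(self):
        cfg = GeneratorConfig(seed=2)
        cat = build_state_catalogue(cfg)
        expected = np.round(np.asarray(cfg.class_frequencies) * cfg.n_states)
        assert np.array_equal(cat.sum(axis=0), expected)
        assert np.all(cat.sum(axis=1) > 0)

    def test_landmark_vector_constant_within_activity(self):
        cfg = small_config()
        cat = build_state_catalogue(cfg)
        for a in sample_procedure(cfg, 3):
            assert np.array_equal(a.landmark_vector.bits, cat[a.state_id])


class TestRendering:
    def test_all_zeros_round_trip(self):
        cfg = small_config()
        lv = LandmarkVector(np.zeros(16, dtype=np.int8))
        img = render_frame(lv, cfg, frame_seed=0)
        assert np.array_equal(oracle_decode_frame(img, cfg).bits, lv.bits)

    def test_all_ones_round_trip(self):
        cfg = small_config()
        lv = LandmarkVector(np.ones(16, dtype=np.int8))
        img = render_frame(lv, cfg, frame_seed=1)
        assert np.array_equal(oracle_decode_frame(img, cfg).bits, lv.bits)

    def test_seeded_determinism(self):
        cfg = small_config()
        lv = LandmarkVector((np.arange(16) % 3 == 0).astype(np.int8))
        assert np.array_equal(render_frame(lv, cfg, 7), render_frame(lv, cfg, 7))
        assert not np.array_equal(render_frame(lv, cfg, 7), render_frame(lv, cfg, 8))

    def test_pure_noise_decodes_to_all_zeros(self):
        cfg = small_config()
        rng = np.random.default_rng(0)
        noise = rng.integers(0, 80, size=(64, 64, 3), dtype=np.uint8)
        assert oracle_decode_frame(noise, cfg).bits.sum() == 0

    def test_wrong_image_size_raises(self):
        cfg = small_config()
        with pytest.raises(ValueError):
            oracle_decode_frame(np.zeros((32, 32, 3), dtype=np.uint8), cfg)

    def test_oracle_accuracy_on_random_vectors(self):
        cfg = small_config()
        rng = np.random.default_rng(1)
        hits = 0
        n = 200
        for i in range(n):
            bits = (rng.uniform(size=16) < 0.3).astype(np.int8)
            img = render_frame(LandmarkVector(bits), cfg, frame_seed=i)
            hits += np.array_equal(oracle_decode_frame(img, cfg).bits, bits)
        assert hits / n >= 0.99


class TestDataset:
    def test_no_missing_rate_no_discards(self, tmp_path):
        cfg = small_config(missing_channel_rate=0.0)
        m = build_dataset(cfg, tmp_path / "ds")
        assert m.n_discarded == 0
        assert all(all(r.channel_mask) for r in m.records)

    def test_candidate_count_is_rate_times_duration(self, tmp_path):
        cfg = small_config(activities_per_procedure=(1, 1),
                           activity_duration=(10.0, 10.0), n_procedures=1)
        m = build_dataset(cfg, tmp_path / "ds")
        assert m.n_kept == 50  # 10 s at 5 fps

    def test_manifest_round_trip_and_image_files(self, tmp_path, tiny_manifest):
        back = DatasetManifest.load(tiny_manifest.root)
        assert back.n_kept == tiny_manifest.n_kept
        assert [r.to_json() for r in back.records[:20]] == \
               [r.to_json() for r in tiny_manifest.records[:20]]
        for r in back.records[::50]:
            assert (back.root / r.image_path).exists()

    def test_byte_identical_regeneration(self, tmp_path):
        cfg = small_config(missing_channel_rate=0.1)
        m1 = build_dataset(cfg, tmp_path / "a")
        m2 = build_dataset(cfg, tmp_path / "b")
        assert [r.to_json() for r in m1.records] == [r.to_json() for r in m2.records]
        img1 = (tmp_path / "a" / m1.records[0].image_path).read_bytes()
        img2 = (tmp_path / "b" / m2.records[0].image_path).read_bytes()
        assert img1 == img2
        assert m1.n_discarded == m2.n_discarded > 0


class TestLabelFrequencies:
    def test_single_frame_single_class(self, tiny_manifest):
        rec = tiny_manifest.records[0]
        bits = np.zeros(16, dtype=np.int8)
        bits[4] = 1
        solo = FrameRecord(**{**rec.__dict__,
                              "landmark_vector": LandmarkVector(bits)})
        m = DatasetManifest(records=[solo],
                            generator_config=tiny_manifest.generator_config,
                            n_kept=1, n_discarded=0)
        freq = label_frequencies(m)
        assert freq[4] == 1.0 and freq.sum() == 1.0

    def test_sum_at_least_max_frequency(self, tiny_manifest):
        freq = label_frequencies(tiny_manifest)
        assert freq.sum() >= freq.max()

    def test_empty_manifest_raises(self, tiny_manifest):
        empty = DatasetManifest(records=[],
                                generator_config=tiny_manifest.generator_config,
                                n_kept=0, n_discarded=0)
        with pytest.raises(ValueError):
            label_frequencies(empty)
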