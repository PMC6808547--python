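"""Synthetic call generator: structure, dynamics, determinism, waveforms."""

import dataclasses

import numpy as np
import pytest

import vocalaccom as va
from vocalaccom.synth import (
    N_PARAMS,
    ScenarioConfig,
    SynthCallSpec,
    param_columns,
    scenario_from_yaml,
    scenario_to_yaml,
)


class TestDefaultScenario:
    def test_four_translocated_plus_four_baseline(self):
        cfg = va.default_scenario()
        inds = cfg.individuals
        assert len(inds) == 8
        assert sum(1 for _, c in inds if c == "MA") == 4
        assert sum(1 for _, c in inds if c == "ZH") == 4
        # 2F/2M per colony
        sexes = [cfg.sex_of(i) for i, c in inds if c == "MA"]
        assert sorted(sexes) == ["F", "F", "M", "M"]

    def test_trill_vectors_have_17_parameters(self):
        cfg = va.default_scenario()
        assert cfg.dialect_offset["MA"]["trill"].shape == (17,)
        assert cfg.dialect_offset["MA"]["phee"].shape == (15,)
        table, _ = va.simulate_features(
            dataclasses.replace(cfg, schedule=[("Before", 0.0, 5)]), seed=0
        )
        trill = table[table.call_type == "trill"]
        phee = table[table.call_type == "phee"]
        assert trill[param_columns("trill")].notna().all().all()
        assert phee["p16"].isna().all() and phee["p17"].isna().all()

    def test_week_coding_and_convergence_signs(self):
        cfg = va.default_scenario()
        weeks = sorted({w for _, w, _ in cfg.schedule})
        assert weeks == [0.0, 0.5] + [float(w) for w in range(1, 17)]
        assert cfg.convergence_rate["trill"]["F"] > 0  # convergence
        assert cfg.convergence_rate["phee"]["M"] > 0
        assert cfg.convergence_rate["food"]["F"] < 0  # divergence


class TestSimulateFeatures:
    def test_determinism_byte_identical(self, small_scenario):
        t1, _ = va.simulate_features(small_scenario, seed=42)
        t2, _ = va.simulate_features(small_scenario, seed=42)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)

    def test_schedule_counts(self, small_table, small_scenario):
        counts = small_table.groupby(["caller_id", "call_type", "week"]).size()
        assert (counts == 8).all()
        n_weeks = len(small_scenario.schedule)
        assert len(small_table) == 8 * 3 * n_weeks * 8

    def test_truth_week0_offset_exact(self):
        cfg = va.default_scenario()
        _, truth = va.simulate_features(
            dataclasses.replace(cfg, schedule=[("Before", 0.0, 5)]), seed=0
        )
        np.testing.assert_array_equal(
            truth.colony_centroids[("MA", "trill", 0.0)],
            cfg.dialect_offset["MA"]["trill"],
        )

    def test_zero_rate_constant_offset(self):
        cfg = va.default_scenario()
        cfg = dataclasses.replace(cfg, call_types=("trill",))
        cfg.convergence_rate["trill"] = {"F": 0.0, "M": 0.0}
        table, _ = va.simulate_features(cfg, seed=3)
        ma = table[table.colony == "MA"]
        zh = table[table.colony == "ZH"]
        cols = param_columns("trill")
        u = cfg.dialect_offset["MA"]["trill"]
        u = u / np.linalg.norm(u)
        proj = lambda df: df[cols].to_numpy() @ u  # noqa: E731
        early = proj(ma[ma.week == 0.0]).mean() - proj(zh[zh.week == 0.0]).mean()
        late = proj(ma[ma.week == 16.0]).mean() - proj(zh[zh.week == 16.0]).mean()
        # 80 calls/group: SE of the projected mean difference ~ 0.24
        assert abs(early - late) < 1.0
        assert early > 5.0  # offset norm is sqrt(17)*3 ~ 12.4

    def test_decay_moves_translocated_mean(self):
        cfg = dataclasses.replace(va.default_scenario(), call_types=("trill",))
        _, truth = va.simulate_features(cfg, seed=0)
        c1 = truth.colony_centroids[("MA", "trill", 1.0)]
        c16 = truth.colony_centroids[("MA", "trill", 16.0)]
        assert np.linalg.norm(c16) < np.linalg.norm(c1)
        rate = cfg.convergence_rate["trill"]["F"]
        np.testing.assert_allclose(
            c16, cfg.dialect_offset["MA"]["trill"] * np.exp(-rate * 16), rtol=1e-12
        )

    def test_rejects_bad_schedule_and_dimensions(self):
        cfg = va.default_scenario()
        bad = dataclasses.replace(cfg, schedule=[("Before", 0.0, 0)])
        with pytest.raises(ValueError, match="non-positive"):
            va.simulate_features(bad, seed=0)
        with pytest.raises(ValueError, match="length"):
            ScenarioConfig(dialect_offset={"MA": {"trill": np.zeros(5)}})
        with pytest.raises(ValueError, match=">= 0"):
            ScenarioConfig(individual_sd=-1.0)


class TestWaveformSynthesis:
    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            SynthCallSpec(duration=0.0)

    def test_aliasing_guard(self):
        spec = SynthCallSpec(f0_start=13000, f0_end=13000, f0_mean=13000)
        with pytest.raises(ValueError, match="sample_rate"):
            va.synthesize_waveform(spec, sample_rate=44100)

    def test_trill_waveform_is_fm(self):
        spec = SynthCallSpec(
            call_type="trill", duration=0.4, f0_mean=7000, fm_rate=25, fm_extent=800
        )
        x = va.synthesize_waveform(spec, 48000, seed=0)
        assert x.shape == (int(0.4 * 48000),)
        assert np.max(np.abs(x)) <= 0.9 + 1e-9

    def test_noise_snr(self):
        clean = va.synthesize_waveform(
            SynthCallSpec(duration=0.5, envelope="flat"), 48000
        )
        noisy = va.synthesize_waveform(
            SynthCallSpec(duration=0.5, envelope="flat", noise_snr=20.0), 48000, seed=1
        )
        # both peak-normalized to 0.9; noisy must differ but not drastically
        assert not np.allclose(clean, noisy)
        assert np.corrcoef(clean, noisy)[0, 1] > 0.9


def test_scenario_yaml_round_trip(tmp_path, small_scenario):
    path = tmp_path / "scenario.yaml"
    scenario_to_yaml(small_scenario, path)
    back = scenario_from_yaml(path)
    assert back.schedule == small_scenario.schedule
    assert back.convergence_rate == small_scenario.convergence_rate
    for colony in small_scenario.dialect_offset:
        for ct in small_scenario.dialect_offset[colony]:
            np.testing.assert_array_equal(
                back.dialect_offset[colony][ct],
                small_scenario.dialect_offset[colony][ct],
            )
    t1, _ = va.simulate_features(small_scenario, seed=9)
    t2, _ = va.simulate_features(back, seed=9)
    assert t1.equals(t2)


def test_monotone_effect_of_condition_offset():
    """A larger condition shift never decreases median pDFA observed-correct.

    The shift is applied as a transient perturbation between the Before and
    After1 conditions of the environmental scenario (the crossed design needs
    every individual in both test-factor levels, so a colony-level offset
    cannot be tested directly).
    """
    from vocalaccom.pdfa import CrossedPDFA
    from vocalaccom.synth import param_columns

    medians = []
    for magnitude in (0.0, 1.0, 2.5):
        stats = []
        for seed in range(5):
            cfg = va.perturbation_scenario()
            cfg = dataclasses.replace(
                cfg,
                call_types=("food",),
                schedule=[("Before", 0.0, 10), ("After1", 1.0, 10)],
            )
            cfg.perturbation["food"] = np.r_[np.full(6, magnitude), np.zeros(9)]
            table, _ = va.simulate_features(cfg, seed=100 + seed)
            food = table[table.call_type == "food"]
            est = CrossedPDFA(
                n_permutations=100, n_selection_rounds=10, random_state=seed
            ).fit(
                food[param_columns("food")].to_numpy(),
                food["condition"].to_numpy(),
                food["caller_id"].to_numpy(),
            )
            stats.append(est.pct_actual_correct_)
        medians.append(np.median(stats))
    assert medians[0] <= medians[1] <= medians[2]
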