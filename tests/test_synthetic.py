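"""Generators: determinism, study-condition structure, ground-truth export."""

import numpy as np
import pytest

from troopcall.social import compute_dai, davids_score, eigenvector_centrality
from troopcall.stats import spearman
from troopcall.synthetic import (
    CallSynthesisError,
    TroopConfig,
    TroopConfigError,
    make_roster,
    paper_tally_events,
    simulate_agonistic,
    simulate_movements,
    simulate_proximity,
    synthesize_call,
    write_dataset,
)


class TestRoster:
    def test_default_roster_composition(self, roster):
        assert len(roster) == 27
        assert sum(i.sex == "male" for i in roster) == 12
        assert sum(i.sex == "female" for i in roster) == 15

    def test_same_seed_identical(self, default_config):
        assert make_roster(default_config) == make_roster(TroopConfig(seed=1))

    def test_different_seed_differs(self, roster):
        other = make_roster(TroopConfig(seed=2))
        assert other != roster

    def test_migrants_have_zero_relatives(self, roster):
        assert any(i.n_relatives == 0 for i in roster)

    def test_invalid_config_names_field(self):
        with pytest.raises(TroopConfigError, match="session_length"):
            TroopConfig(session_length=0)
        with pytest.raises(TroopConfigError, match="zero_inflation"):
            TroopConfig(zero_inflation=1.5)
        with pytest.raises(TroopConfigError, match="n_males"):
            TroopConfig(n_males=1, n_females=1)


class TestProximity:
    def test_zero_fraction_means_no_proximity(self, roster):
        config = TroopConfig(seed=1, mean_proximity_fraction=0.0)
        records = simulate_proximity(roster, config)
        assert all(r.overlap_duration == 0 for r in records)

    def test_durations_bounded_by_session(self, roster, default_config):
        records = simulate_proximity(roster, default_config)
        assert all(0 <= r.overlap_duration <= r.session_duration for r in records)

    def test_default_troop_association_positive(self, dai_matrix):
        # direct-summation oracle: mean off-diagonal DAI strictly positive
        off = dai_matrix.values[np.triu_indices(len(dai_matrix.individuals), 1)]
        assert off.mean() > 0

    def test_gregarious_dyads_associate_more(self, roster, default_config, dai_matrix):
        g = np.array([i.true_gregariousness for i in roster])
        prod = np.outer(g, g)[np.triu_indices(len(roster), 1)]
        dai = dai_matrix.values[np.triu_indices(len(roster), 1)]
        assert spearman(prod, dai).rho > 0.5

    def test_determinism(self, roster, default_config):
        a = simulate_proximity(roster, default_config)
        b = simulate_proximity(roster, default_config)
        assert a == b


class TestAgonism:
    def test_every_dyad_interacts(self, roster, default_config):
        bouts = simulate_agonistic(roster, default_config)
        seen = {frozenset((b.actor_id, b.receiver_id)) for b in bouts}
        n = len(roster)
        assert len(seen) == n * (n - 1) // 2

    def test_flat_ladder_scores_near_zero(self):
        # with a flat ladder every dyad is a coin flip; at many bouts per
        # dyad the win proportions pin to 1/2 and every DS approaches 0
        config = TroopConfig(
            seed=3, n_males=4, n_females=4, dominance_steepness=0.0,
            mean_bouts_per_dyad=400.0,
        )
        troop = make_roster(config)
        res = davids_score(simulate_agonistic(troop, config), troop)
        assert np.abs(res.ds).max() < 1.5

    def test_steep_ladder_reproduces_latent_order(self):
        config = TroopConfig(seed=5, dominance_steepness=60.0)
        troop = make_roster(config)
        res = davids_score(simulate_agonistic(troop, config), troop)
        strengths = {i.id: i.latent_strength for i in troop}
        ranked = sorted(zip(res.ds, res.individuals), reverse=True)
        values = [strengths[i] for _, i in ranked]
        assert values == sorted(values, reverse=True)


class TestMovements:
    def test_degenerate_config_silences_every_event(self, roster, centrality):
        config = TroopConfig(
            seed=1,
            vocal_intercept=0.0,
            vocal_sex_effect=0.0,
            vocal_centrality_effect=0.0,
            order_effect=0.0,
            zero_inflation=1.0,
        )
        events, _ = simulate_movements(roster, centrality, config)
        assert all(not e.vocal for e in events)

    def test_positive_order_effect_yields_positive_correlation(self, roster, centrality):
        config = TroopConfig(seed=2, movement_count=500, order_effect=1.0)
        _, truth = simulate_movements(roster, centrality, config)
        obs = truth["observations"]
        res = spearman(obs["order_index"], obs["calls"])
        assert res.rho > 0 and res.p_value < 0.001

    def test_ground_truth_exported(self, roster, centrality, default_config):
        _, truth = simulate_movements(roster, centrality, default_config)
        assert truth["female"] == default_config.vocal_sex_effect
        assert truth["centrality"] == default_config.vocal_centrality_effect
        assert {"calls", "female", "centrality", "order_index", "exposure"}.issubset(
            truth["observations"].columns
        )

    def test_events_are_successful_and_ordered(self, roster, centrality, default_config):
        events, _ = simulate_movements(roster, centrality, default_config)
        assert len(events) == default_config.movement_count
        for e in events:
            times = [t for _, t in e.joins]
            assert times == sorted(times)
            assert e.n_participants >= 3 and e.successful

    def test_determinism(self, roster, centrality, default_config):
        a, _ = simulate_movements(roster, centrality, default_config)
        b, _ = simulate_movements(roster, centrality, default_config)
        assert a == b


class TestPaperTallyPreset:
    def test_exact_published_tallies(self):
        events = paper_tally_events(seed=0)
        assert len(events) == 132
        assert sum(e.vocal for e in events) == 52
        assert sum(e.initiator_vocal for e in events) == 34

    def test_vocal_events_recruit_more_participants(self):
        events = paper_tally_events(seed=0)
        vocal = np.mean([e.n_participants for e in events if e.vocal])
        silent = np.mean([e.n_participants for e in events if not e.vocal])
        assert vocal > silent


class TestCallSynthesis:
    def test_unknown_type_rejected(self):
        with pytest.raises(CallSynthesisError):
            synthesize_call("whistle")

    def test_jitter_zero_is_seed_invariant_and_bit_identical(self):
        a = synthesize_call("coo", jitter=0.0, seed=1)
        b = synthesize_call("coo", jitter=0.0, seed=99)
        assert np.array_equal(a.samples, b.samples)

    def test_jittered_calls_deterministic_per_seed(self):
        a = synthesize_call("coo", jitter=0.05, seed=7)
        b = synthesize_call("coo", jitter=0.05, seed=7)
        c = synthesize_call("coo", jitter=0.05, seed=8)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_bark_duration_and_rate(self):
        wave = synthesize_call("bark")
        assert wave.sample_rate == 44100.0
        assert wave.duration == pytest.approx(0.06, abs=1e-6)

    def test_samples_within_unit_range(self):
        for name in ("coo", "leap_coo", "bark"):
            wave = synthesize_call(name)
            assert np.max(np.abs(wave.samples)) < 1.0


class TestDatasetSerialization:
    def test_write_dataset_outputs(self, tmp_path):
        config = TroopConfig(seed=3, n_sessions_per_individual=2, movement_count=10)
        out = write_dataset(
            tmp_path, config, n_calls_per_type={"coo": 1, "bark": 1}
        )
        for name in ("roster.csv", "proximity.csv", "agonistic.csv", "movements.csv"):
            assert (tmp_path / name).exists()
        assert len(list((tmp_path / "calls").glob("*.wav"))) == 2
        assert out["truth"] is not None
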