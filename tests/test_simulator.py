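"""Scheduler tests: oracle equivalence, conservation, limits, determinism."""

import numpy as np
import pytest

from refutesim import InitSpec, Role, SimulationConfig, TopologyParams, TransitionParams
from refutesim.model_core import PairUpdateVariant
from refutesim.population import PopulationState
from refutesim.simulator import run, step

from _oracle import reference_step
from conftest import small_config, structure_from_pairs


def make_state(roles, emotions, d=None, w=None, b=None, days=None):
    n = len(roles)
    return PopulationState(
        roles=np.array(roles, dtype=np.int8),
        emotions=np.array(emotions, dtype=np.float64),
        d=np.array(d if d is not None else [1.0] * n),
        w=np.array(w if w is not None else [1.0] * n),
        b=np.array(b if b is not None else [1.0] * n),
        days_active=np.array(days if days is not None else [0] * n, dtype=np.int32),
        t=0,
    )


S, R, M = int(Role.S), int(Role.R), int(Role.M)


class TestOracleEquivalence:
    """One scheduled day must equal the brute-force scene-by-scene reference."""

    @pytest.mark.parametrize("variant", ["as_printed", "convergent"])
    def test_ten_agent_fixture_exact(self, variant):
        # every contact scene occurs: S-S, S-R, S-M, R-R, R-M, M-M,
        # plus one multi-contact agent (id 4) exercising the event order
        roles = [S, S, R, R, M, M, M, M, R, M]
        emotions = [0.90, 0.75, 0.40, 0.55, 0.50, 0.64, 0.35, 0.20, 0.70, 0.60]
        d = [1.0, 0.95, 1.0, 0.9, 1.0, 1.0, 0.85, 1.0, 1.0, 1.0]
        w = [0.9, 0.8, 0.7, 0.6, 0.9, 0.95, 0.4, 0.3, 0.8, 0.5]
        b = [0.8, 0.9, 0.6, 0.7, 0.9, 0.95, 0.5, 0.4, 0.7, 0.6]
        days = [2, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        contacts = [(0, 1), (0, 2), (1, 4), (2, 3), (8, 4), (5, 8), (6, 7), (3, 9)]

        config = SimulationConfig(
            n=10,
            days=1,
            seed=0,
            transition=TransitionParams(f_s=0.1, f_r=0.2, lambda_gate=0.1,
                                        spreader_active_days=3),
            init=InitSpec(frac_s=0.1),
            pair_update_variant=PairUpdateVariant(variant),
        )
        state = make_state(roles, emotions, d, w, b, days)
        act_seed = 123
        new = step(
            state,
            config,
            structure=None,
            rng_contacts=np.random.default_rng(0),
            rng_activation=np.random.default_rng(act_seed),
            contacts=np.array(contacts),
        )
        u = np.random.default_rng(act_seed).random(10)
        ref_roles, ref_emotions, ref_days = reference_step(
            roles, emotions, d, w, b, days, contacts,
            a=config.ctx.a, v=config.ctx.v, f_s=0.1, f_r=0.2,
            lambda_gate=0.1, spreader_active_days=3, variant=variant, u=u,
        )
        np.testing.assert_array_equal(new.roles, ref_roles)
        np.testing.assert_array_equal(new.emotions, ref_emotions)
        np.testing.assert_array_equal(new.days_active, ref_days)

    def test_override_and_gate_interact_like_reference(self):
        roles = [S, M, M, R]
        emotions = [0.9, 0.5, 0.4, 0.7]
        contacts = [(0, 1), (2, 3)]
        config = SimulationConfig(
            n=4, days=1, seed=0,
            transition=TransitionParams(f_s=0.0, f_r=0.0, lambda_gate=0.3),
            init=InitSpec(frac_s=0.25),
            r_sr_override=0.2,  # below the gate: nothing transmits
        )
        state = make_state(roles, emotions)
        new = step(state, config, None, np.random.default_rng(0),
                   np.random.default_rng(1), contacts=np.array(contacts))
        np.testing.assert_array_equal(new.emotions, emotions)
        np.testing.assert_array_equal(new.roles, roles)


class TestLimits:
    def test_null_dynamics_constant(self):
        config = small_config(
            transition=TransitionParams(f_s=0.0, f_r=0.0, lambda_gate=0.0,
                                        spreader_active_days=30),
            topology=TopologyParams(mode="spatial", radius=1e-4,
                                    contacts_per_agent_per_day=1),
            days=6,
            init=InitSpec(frac_s=0.1, d_range=(1.0, 1.0)),
        )
        traj = run(config)
        rec = traj.records
        assert rec["n_s"].nunique() == 1 and rec["n_r"].nunique() == 1
        np.testing.assert_array_equal(traj.initial_emotions, traj.final_emotions)

    def test_geometric_decay_closed_form(self):
        # no contacts, d = 0.9: every emotion is exactly 0.9^t * E(0)
        config = small_config(
            n=50,
            days=20,
            transition=TransitionParams(f_s=0.0, f_r=0.0),
            topology=TopologyParams(mode="spatial", radius=1e-4,
                                    contacts_per_agent_per_day=1),
            init=InitSpec(frac_s=0.1, d_range=(0.9, 0.9)),
        )
        traj = run(config)
        expected = traj.initial_emotions * 0.9**20
        np.testing.assert_allclose(traj.final_emotions, expected, rtol=1e-12)

    def test_zero_override_freezes_bands(self):
        config = small_config(r_sr_override=0.0, days=8)
        traj = run(config)
        rec = traj.records
        # no contagion channel: band counts can only move via activations,
        # which never change emotions
        assert rec["n_negative"].nunique() == 1
        assert rec["n_immune"].nunique() == 1
        assert rec["n_positive"].nunique() == 1


class TestRunContract:
    def test_zero_days_single_record(self):
        traj = run(small_config(days=0))
        assert len(traj.records) == 1 and traj.records["t"].iloc[0] == 0

    def test_same_seed_identical_different_seed_not(self):
        a = run(small_config(seed=5))
        b = run(small_config(seed=5))
        c = run(small_config(seed=6))
        assert a.records.equals(b.records)
        np.testing.assert_array_equal(a.final_emotions, b.final_emotions)
        assert not a.records.equals(c.records)

    def test_conservation_over_random_configs(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            n = int(rng.integers(20, 80))
            f_s, f_r = rng.random(2) * 0.3
            config = SimulationConfig(
                n=n,
                days=10,
                seed=int(rng.integers(2**31 - 1)),
                transition=TransitionParams(f_s=f_s, f_r=f_r,
                                            lambda_gate=float(rng.random() * 0.3)),
                init=InitSpec(frac_s=0.1,
                              m_emotion=(0.0, 1.0) if rng.random() < 0.5 else "immune"),
                topology=TopologyParams(mode="graph", graph_kind="erdos_renyi",
                                        p=0.2, contacts_per_agent_per_day=2),
                pair_update_variant=("as_printed" if rng.random() < 0.5 else "convergent"),
            )
            traj = run(config)
            rec = traj.records
            assert (rec[["n_s", "n_r", "n_m"]].sum(axis=1) == n).all()
            assert (rec[["n_negative", "n_immune", "n_positive"]].sum(axis=1) == n).all()

    def test_trajectory_metadata_embedded(self):
        traj = run(small_config(seed=11))
        assert traj.meta["seed"] == 11
        assert traj.meta["n"] == 40
        assert "refutesim_version" in traj.meta


class TestStepExample:
    def test_spreader_pulls_receiver_into_immune_band(self):
        # S(0.9) contacts R(0.3) with forced R_sr = 0.5: receiver moves to
        # 0.6 and, now inside the immune band, converts to M
        config = SimulationConfig(
            n=2, days=1, seed=0,
            transition=TransitionParams(f_s=0.0, f_r=0.0, lambda_gate=0.0),
            init=InitSpec(frac_s=0.5),
            r_sr_override=0.5,
        )
        state = make_state([S, R], [0.9, 0.3])
        new = step(state, config, None, np.random.default_rng(0),
                   np.random.default_rng(0), contacts=np.array([[0, 1]]))
        assert new.emotions[1] == pytest.approx(0.6)
        assert new.roles[1] == M
        assert new.emotions[0] == pytest.approx(0.9)
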