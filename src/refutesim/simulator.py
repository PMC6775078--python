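"""Synchronous day-by-day contagion loop.

Each day: (1) sample the contact pairs; (2) execute every contact as a full
pairwise event in a random order — same-role pairs (S-S, R-R) use the pair
rule under the configured variant, cross-role contacts (S->R, S->M, R->M)
move the receiver toward the source; roles are frozen at their day-start
values for the whole day while emotions evolve event by event (the
random-order event schedule of NetLogo-style agent models); (3) each event
clamps to [0, 1]; (4) apply emotion-band role transitions to contacted
agents; (5) apply spontaneous f_s/f_r activations to the remaining immunized
agents; (6) age spreaders and retire the expired ones to R; (7) recount and
advance the clock.

For execution speed the shuffled event list is partitioned into maximal
vertex-disjoint rounds; within a round no agent appears twice, so the
vectorized round update is exactly the sequential event semantics.  An agent
in exactly one contact receives precisely the printed receiver equation
``E' = d*E + (E_src - E)*R``; uncontacted agents apply the self-weighting
``E <- d*E`` once per day, so with the default d = 1 they are exactly
invariant and with d < 1 their emotion decays geometrically (closed-form
``d^t * E(0)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import SimulationConfig
from .model_core import EmotionBand, PairUpdateVariant, Role, classify_emotions
from .population import (
    ContactStructure,
    PopulationState,
    build_contact_structure,
    generate_population,
    sample_daily_contacts,
)

__all__ = ["Trajectory", "step", "run", "record_day"]

TRAJECTORY_COLUMNS = [
    "t",
    "n_s",
    "n_r",
    "n_m",
    "n_negative",
    "n_immune",
    "n_positive",
    "mean_emotion",
    "mean_emotion_r",
]


@dataclass
class Trajectory:
    """Per-day record of one run plus initial/final per-agent snapshots."""

    records: pd.DataFrame
    initial_emotions: np.ndarray
    final_emotions: np.ndarray
    initial_roles: np.ndarray
    final_roles: np.ndarray
    config: SimulationConfig
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.initial_emotions.shape[0]


def record_day(state: PopulationState) -> dict:
    n_s, n_r, n_m = state.counts()
    n_neg, n_imm, n_pos = state.band_counts()
    r_mask = state.roles == int(Role.R)
    return {
        "t": state.t,
        "n_s": n_s,
        "n_r": n_r,
        "n_m": n_m,
        "n_negative": n_neg,
        "n_immune": n_imm,
        "n_positive": n_pos,
        "mean_emotion": float(state.emotions.mean()),
        "mean_emotion_r": float(state.emotions[r_mask].mean()) if r_mask.any() else float("nan"),
    }


def _disjoint_rounds(pairs: np.ndarray, n: int):
    """Partition an ordered pair list into greedy vertex-disjoint rounds.

    Each yielded block contains pairs whose endpoints are all distinct and
    which precede, in list order, any other remaining pair sharing one of
    their endpoints — so executing the blocks in turn reproduces the
    sequential order exactly.
    """
    remaining = pairs
    while remaining.shape[0]:
        k = remaining.shape[0]
        flat = remaining.reshape(-1)  # positions 2i, 2i+1 belong to pair i
        first_pos = np.full(n, 2 * k, dtype=np.int64)
        first_pos[flat[::-1]] = np.arange(2 * k - 1, -1, -1)
        pair_idx = np.arange(k)
        admit = (first_pos[remaining[:, 0]] // 2 == pair_idx) & (
            first_pos[remaining[:, 1]] // 2 == pair_idx
        )
        yield remaining[admit]
        remaining = remaining[~admit]


def step(
    state: PopulationState,
    config: SimulationConfig,
    structure: ContactStructure,
    rng_contacts: np.random.Generator,
    rng_activation: np.random.Generator,
    contacts: np.ndarray | None = None,
) -> PopulationState:
    """Advance the population by one day (synchronous update).

    ``contacts`` may be supplied explicitly (shape (k, 2)) to bypass the
    sampler, e.g. for oracle tests; otherwise one day of contacts is drawn
    from ``structure``.
    """
    n = state.n
    if contacts is None:
        contacts = sample_daily_contacts(structure, rng_contacts)
        if contacts.shape[0]:
            contacts = contacts[rng_contacts.permutation(contacts.shape[0])]
    contacts = np.asarray(contacts, dtype=np.int64).reshape(-1, 2)

    roles_t = state.roles  # roles frozen at day start for the whole day
    new_emotions = state.emotions.copy()
    contacted = np.zeros(n, dtype=bool)

    for round_pairs in _disjoint_rounds(contacts, n):
        # both directed orientations of every undirected pair; within a
        # round all pairs are vertex-disjoint, so this vectorized update is
        # exactly the sequential per-event semantics
        recv = np.concatenate([round_pairs[:, 0], round_pairs[:, 1]])
        src = np.concatenate([round_pairs[:, 1], round_pairs[:, 0]])
        r_role = roles_t[recv]
        s_role = roles_t[src]
        src_active = (s_role == int(Role.S)) | (s_role == int(Role.R))
        receives = (
            ((r_role == int(Role.M)) & src_active)
            | ((r_role == int(Role.R)) & src_active)
            | ((r_role == int(Role.S)) & (s_role == int(Role.S)))
        )
        if config.r_sr_override is not None:
            prob = np.full(recv.shape, float(config.r_sr_override))
        else:
            prob = state.w[recv] * state.b[recv] * config.ctx.a * config.ctx.v
        receives &= prob >= config.transition.lambda_gate
        same_pair = (r_role == s_role) & (
            (r_role == int(Role.S)) | (r_role == int(Role.R))
        )
        if config.pair_update_variant is PairUpdateVariant.AS_PRINTED:
            sign = np.where(same_pair, -1.0, 1.0)
        else:
            sign = np.ones(recv.shape)
        idx = recv[receives]
        updated = (
            state.d[idx] * new_emotions[idx]
            + (new_emotions[src[receives]] - new_emotions[idx])
            * prob[receives]
            * sign[receives]
        )
        new_emotions[idx] = np.clip(updated, 0.0, 1.0)
        contacted[idx] = True

    # agents not updated by any contact apply the daily self-weighting once
    new_emotions[~contacted] = np.clip(
        state.d[~contacted] * new_emotions[~contacted], 0.0, 1.0
    )

    roles = roles_t.copy()
    days_active = state.days_active.copy()
    bands = classify_emotions(new_emotions)
    is_immune = bands == int(EmotionBand.IMMUNE)
    m_leaves = contacted & (roles == int(Role.M)) & ~is_immune
    sr_enters = (
        contacted
        & ((roles == int(Role.R)) | (roles == int(Role.S)))
        & is_immune
    )
    roles[m_leaves] = int(Role.R)
    roles[sr_enters] = int(Role.M)
    days_active[sr_enters] = 0

    # spontaneous activation of the remaining immunized agents; one uniform
    # per agent keeps the activation stream independent of compartment sizes
    u = rng_activation.random(n)
    f_s = config.transition.f_s
    f_r = config.transition.f_r
    m_mask = roles == int(Role.M)
    to_s = m_mask & (u < f_s)
    to_r = m_mask & (u >= f_s) & (u < f_s + f_r)
    roles[to_s] = int(Role.S)
    days_active[to_s] = 0
    roles[to_r] = int(Role.R)

    # spreaders that actually spread today age by one day and retire to R
    # once they have been active for spreader_active_days
    aged = (roles_t == int(Role.S)) & (roles == int(Role.S))
    days_active[aged] += 1
    retire = aged & (days_active >= config.transition.spreader_active_days)
    roles[retire] = int(Role.R)

    new_state = PopulationState(
        roles=roles,
        emotions=new_emotions,
        d=state.d,
        w=state.w,
        b=state.b,
        days_active=days_active,
        t=state.t + 1,
    )
    n_s, n_r, n_m = new_state.counts()
    if n_s + n_r + n_m != n:
        raise RuntimeError(
            f"internal consistency error: compartment counts {n_s}+{n_r}+{n_m} != {n}"
        )
    return new_state


def run(
    config: SimulationConfig,
    initial_state: PopulationState | None = None,
    structure: ContactStructure | None = None,
) -> Trajectory:
    """Run one simulation for ``config.days`` days and record every day.

    All randomness flows from ``config.seed`` through named child streams
    (population initialization, contact structure, daily contact sampling,
    spontaneous activations), so an identical config yields an identical
    trajectory, and toggling one mechanism does not perturb the others'
    draws.
    """
    ss = np.random.SeedSequence(config.seed)
    ss_init, ss_struct, ss_contacts, ss_act = ss.spawn(4)
    if initial_state is None:
        initial_state = generate_population(
            config.n, config.init, np.random.default_rng(ss_init)
        )
    if structure is None:
        structure = build_contact_structure(
            config.n, config.topology, np.random.default_rng(ss_struct)
        )
    rng_contacts = np.random.default_rng(ss_contacts)
    rng_act = np.random.default_rng(ss_act)

    state = initial_state.copy()
    records = [record_day(state)]
    initial_emotions = state.emotions.copy()
    initial_roles = state.roles.copy()
    for _ in range(config.days):
        state = step(state, config, structure, rng_contacts, rng_act)
        records.append(record_day(state))
    frame = pd.DataFrame.from_records(records, columns=TRAJECTORY_COLUMNS)
    meta = {
        "seed": config.seed,
        "days": config.days,
        "n": config.n,
        "refutesim_version": __version__,
        "numpy_version": np.__version__,
    }
    return Trajectory(
        records=frame,
        initial_emotions=initial_emotions,
        final_emotions=state.emotions.copy(),
        initial_roles=initial_roles,
        final_roles=state.roles.copy(),
        config=config,
        meta=meta,
    )
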