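"""Contact-level rules of the spreader/infected/immunized (SRM) emotion model.

The model tracks, for each networked individual, a continuous emotion value
``E`` in [0, 1] partitioned into three bands — negative [0, 0.33], immune
(0.33, 0.66] and positive (0.66, 1.00] — plus a compartment role:

* ``S`` (spreader): knows the refutation information and transmits its own
  emotion; its emotion is not changed by the agents it infects.
* ``R`` (infected): has had its emotion altered by contact and can pass the
  emotion on.
* ``M`` (immunized): currently disengaged (emotion in the middle band) but
  re-activatable with per-day probabilities ``f_s`` (to S) and ``f_r`` (to R).

Everything in this module is a pure, scalar, contact-level operation; the
synchronous population scheduler lives in :mod:`refutesim.simulator`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Role",
    "EmotionBand",
    "AgentTraits",
    "RefutationContext",
    "TransitionParams",
    "PairUpdateVariant",
    "clamp01",
    "compute_transmission_probability",
    "classify_emotion",
    "classify_emotions",
    "update_infected_by_spreader",
    "update_same_state_pair",
    "apply_band_transition",
    "spontaneous_activation",
    "expected_population_counts",
    "NEGATIVE_UPPER",
    "POSITIVE_LOWER",
]

#: Band boundaries: negative = [0, 0.33], immune = (0.33, 0.66], positive = (0.66, 1].
NEGATIVE_UPPER = 0.33
POSITIVE_LOWER = 0.66


class Role(enum.IntEnum):
    """Compartment role of an agent."""

    S = 0  # spreader
    R = 1  # infected
    M = 2  # immunized


class EmotionBand(enum.IntEnum):
    """Emotion band; integer codes are used in vectorized paths."""

    NEGATIVE = 0
    IMMUNE = 1
    POSITIVE = 2


class PairUpdateVariant(str, enum.Enum):
    """Direction of the difference term in same-role (S-S, R-R) updates.

    ``AS_PRINTED`` uses ``(self - other) * R`` for each member, which weakly
    pushes the pair apart; ``CONVERGENT`` uses ``(other - self) * R``, the
    same direction as the spreader-to-infected update, and pulls the pair
    together.  Both are exposed because the model's same-role rule is
    internally inconsistent with its cross-role rule; neither is asserted
    as canonical.
    """

    AS_PRINTED = "as_printed"
    CONVERGENT = "convergent"


def _check_unit(name: str, *values: float) -> None:
    for v in values:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class AgentTraits:
    """Subjective per-agent traits, each in [0, 1].

    d: subjective-judgment ability (1 = fully firm in own emotion),
    w: expression ability, b: willingness to spread.
    """

    d: float
    w: float
    b: float

    def __post_init__(self) -> None:
        _check_unit("d", self.d)
        _check_unit("w", self.w)
        _check_unit("b", self.b)


@dataclass(frozen=True)
class RefutationContext:
    """The refuting authority: credibility ``a`` and refutation speed ``v``."""

    a: float
    v: float

    def __post_init__(self) -> None:
        _check_unit("a", self.a)
        _check_unit("v", self.v)


@dataclass(frozen=True)
class TransitionParams:
    """Spontaneous-transition parameters of the immunized compartment.

    f_s, f_r: per-day probabilities of an M agent re-activating to S or R.
    lambda_gate: minimum transmission probability for a contact to transmit
        (0 disables the gate).
    spreader_active_days: days an S agent stays active before retiring to R.
    """

    f_s: float
    f_r: float
    lambda_gate: float = 0.0
    spreader_active_days: int = 3

    def __post_init__(self) -> None:
        _check_unit("f_s", self.f_s)
        _check_unit("f_r", self.f_r)
        _check_unit("lambda_gate", self.lambda_gate)
        if self.f_s + self.f_r > 1.0 + 1e-12:
            raise ValueError(
                "f_s + f_r must not exceed 1 (the expected number of activated "
                f"M agents cannot exceed the compartment), got {self.f_s} + {self.f_r}"
            )
        if self.spreader_active_days < 1:
            raise ValueError("spreader_active_days must be a positive integer")


def clamp01(x):
    """Clamp a value (or array) to [0, 1]."""
    return np.clip(x, 0.0, 1.0)


def compute_transmission_probability(
    traits: AgentTraits, ctx: RefutationContext
) -> float:
    """Pairwise transmission probability R_sr = w * b * a * v.

    The receiver contributes its expression ability ``w`` and spreading
    willingness ``b``; the refutation context contributes credibility ``a``
    and speed ``v``.  A product of four unit-interval factors, hence itself
    in [0, 1] and zero as soon as any factor is zero.
    """
    return traits.w * traits.b * ctx.a * ctx.v


def classify_emotion(e: float) -> EmotionBand:
    """Band of an emotion value: [0, 0.33] -> negative, (0.33, 0.66] -> immune,
    (0.66, 1] -> positive.  Boundary values belong to the lower band."""
    _check_unit("emotion", e)
    if e <= NEGATIVE_UPPER:
        return EmotionBand.NEGATIVE
    if e <= POSITIVE_LOWER:
        return EmotionBand.IMMUNE
    return EmotionBand.POSITIVE


def classify_emotions(e: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_emotion`; returns integer band codes."""
    e = np.asarray(e)
    out = np.full(e.shape, int(EmotionBand.IMMUNE), dtype=np.int8)
    out[e <= NEGATIVE_UPPER] = int(EmotionBand.NEGATIVE)
    out[e > POSITIVE_LOWER] = int(EmotionBand.POSITIVE)
    return out


def update_infected_by_spreader(
    e_r: float, e_s: float, d_r: float, r_sr: float
) -> tuple[float, float]:
    """Cross-role contact: the receiver moves toward the source.

    Returns ``(new_receiver_emotion, new_source_emotion)`` where the receiver
    becomes ``clamp(d_r * e_r + (e_s - e_r) * r_sr)`` and the source is
    unchanged.  Used for S->R, S->M and R->M contacts.
    """
    _check_unit("e_r", e_r)
    _check_unit("e_s", e_s)
    _check_unit("d_r", d_r)
    _check_unit("r_sr", r_sr)
    new_r = float(clamp01(d_r * e_r + (e_s - e_r) * r_sr))
    return new_r, e_s


def update_same_state_pair(
    e_1: float,
    e_2: float,
    d_1: float,
    d_2: float,
    r_12: float,
    r_21: float,
    variant: PairUpdateVariant | str = PairUpdateVariant.AS_PRINTED,
) -> tuple[float, float]:
    """Same-role contact (S-S or R-R): both members updated synchronously.

    ``r_12`` weights member 1's update, ``r_21`` member 2's.  The
    ``variant`` selects the sign of the difference term (see
    :class:`PairUpdateVariant`); both new values are computed from the
    time-t inputs and clamped to [0, 1].
    """
    _check_unit("e_1", e_1)
    _check_unit("e_2", e_2)
    _check_unit("d_1", d_1)
    _check_unit("d_2", d_2)
    _check_unit("r_12", r_12)
    _check_unit("r_21", r_21)
    try:
        variant = PairUpdateVariant(variant)
    except ValueError as exc:
        raise ValueError(f"unknown pair-update variant: {variant!r}") from exc
    if variant is PairUpdateVariant.AS_PRINTED:
        new_1 = d_1 * e_1 + (e_1 - e_2) * r_12
        new_2 = d_2 * e_2 + (e_2 - e_1) * r_21
    else:
        new_1 = d_1 * e_1 + (e_2 - e_1) * r_12
        new_2 = d_2 * e_2 + (e_1 - e_2) * r_21
    return float(clamp01(new_1)), float(clamp01(new_2))


def apply_band_transition(role: Role, new_emotion: float, was_contacted: bool) -> Role:
    """Role change induced by an emotion-band crossing after a contact update.

    An M agent whose contact-updated emotion leaves the immune band becomes R
    (infected to a positive or negative state); an S or R agent whose updated
    emotion enters the immune band loses its active role and becomes M.
    Agents that were not contacted keep their role.
    """
    _check_unit("new_emotion", new_emotion)
    if not was_contacted:
        return role
    band = classify_emotion(new_emotion)
    if role is Role.M and band is not EmotionBand.IMMUNE:
        return Role.R
    if role in (Role.S, Role.R) and band is EmotionBand.IMMUNE:
        return Role.M
    return role


def spontaneous_activation(role: Role, u: float, params: TransitionParams) -> Role:
    """Spontaneous re-activation of an immunized agent.

    Given a uniform draw ``u`` in [0, 1): returns S if ``u < f_s``, R if
    ``f_s <= u < f_s + f_r``, otherwise M.  Non-M roles pass through
    unchanged.
    """
    if role is not Role.M:
        return role
    if not (0.0 <= u < 1.0):
        raise ValueError(f"u must lie in [0, 1), got {u!r}")
    if u < params.f_s:
        return Role.S
    if u < params.f_s + params.f_r:
        return Role.R
    return Role.M


def expected_population_counts(
    s: float, r: float, m: float, params: TransitionParams, n: float
) -> tuple[float, float, float]:
    """Deterministic expectation of one day of spontaneous activations.

    s' = s + f_s*m, r' = r + f_r*m, m' = N - s' - r'.  Conserves N exactly
    and never drives m below zero while f_s + f_r <= 1.  This is the
    mean-field counterpart of the per-agent activation draws, used as an
    expectation-level invariant check, not as the simulation engine.
    """
    if abs((s + r + m) - n) > 1e-9:
        raise ValueError(f"compartments must sum to N: {s}+{r}+{m} != {n}")
    s2 = s + params.f_s * m
    r2 = r + params.f_r * m
    m2 = n - s2 - r2
    return s2, r2, m2
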