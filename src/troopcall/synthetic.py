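"""Synthetic troop data with known ground truth.

Every downstream stage of the package (acoustics, social metrics,
movement analytics, count regression) can be exercised without field
data: this module generates a roster with sexes, matrilines and a latent
dominance ladder, focal proximity sessions, decided agonistic bouts,
collective-movement events with per-individual call counts drawn from a
zero-inflated Poisson whose log-rate depends on sex, centrality and
joining order, and synthesized harmonic call waveforms whose extracted
features land on the published per-type centroids.

All generators are pure functions of (config, seed); each one draws from
a named sub-seed of the global seed so adding a generator never perturbs
the draws of another.  Latent quantities (gregariousness, strength
ladder, true regression coefficients) are exported so recovery tests can
compare estimates against the truth.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from .acoustics import (
    DB_FULL_SCALE_SINE,
    FRAME_LENGTH,
    HOP,
    Waveform,
    extract_features,
    write_wav,
)
from .acoustics import _frame_db as _acoustic_frame_db
from .movement import MIN_PARTICIPANTS, MovementEvent, event_order_indices
from .social import AgonisticBout, ProximityRecord

__all__ = [
    "TroopConfig",
    "Individual",
    "TroopConfigError",
    "CallSynthesisError",
    "make_roster",
    "simulate_proximity",
    "simulate_agonistic",
    "simulate_movements",
    "synthesize_call",
    "paper_tally_events",
    "write_dataset",
    "stable_subseed",
]

#: Number of harmonics in the synthetic stack; partials above the fifth
#: fall outside the 0-5 kHz band that carries the calls' energy.
N_HARMONICS = 5
_HARMONIC_AMPS = np.array([1.0 / k for k in range(1, N_HARMONICS + 1)])
#: RMS of the unit-envelope harmonic stack.
_STACK_RMS = math.sqrt(float(np.sum(_HARMONIC_AMPS**2)) / 2.0)


class TroopConfigError(ValueError):
    """A configuration field is invalid; the message names the field."""


class CallSynthesisError(ValueError):
    """Call synthesis cannot meet the requested feature targets."""


@dataclass(frozen=True)
class TroopConfig:
    """Study conditions for the synthetic troop.

    Defaults mirror the observed group: 27 focal animals (12 males, 15
    females), 10-minute focal sessions, 132 successful collective
    movements, and count-model effect sizes equal to the fitted
    vocal-frequency coefficients (positive for females and for social
    centrality, on the log-rate scale).
    """

    n_males: int = 12
    n_females: int = 15
    n_matrilines: int = 3
    matriline_coverage: float = 17 / 27  # fraction of the group in matrilines
    session_length: float = 600.0
    n_sessions_per_individual: int = 10
    mean_proximity_fraction: float = 0.15
    dominance_steepness: float = 2.0
    mean_bouts_per_dyad: float = 3.0
    movement_count: int = 132
    vocal_intercept: float = -1.5
    vocal_sex_effect: float = 0.771
    vocal_centrality_effect: float = 3.361
    order_effect: float = 1.0
    zero_inflation: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males < 0 or self.n_females < 0:
            raise TroopConfigError("n_males/n_females must be nonnegative")
        if self.n_males + self.n_females < 3:
            raise TroopConfigError("n_males + n_females must be at least 3")
        if self.n_matrilines < 0:
            raise TroopConfigError("n_matrilines must be nonnegative")
        for name in ("matriline_coverage", "mean_proximity_fraction", "zero_inflation"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise TroopConfigError(f"{name} must lie in [0, 1]")
        if not self.session_length > 0:
            raise TroopConfigError("session_length must be positive")
        if self.n_sessions_per_individual < 1:
            raise TroopConfigError("n_sessions_per_individual must be >= 1")
        if self.dominance_steepness < 0:
            raise TroopConfigError("dominance_steepness must be nonnegative")
        if self.mean_bouts_per_dyad < 1:
            raise TroopConfigError("mean_bouts_per_dyad must be >= 1")
        if self.movement_count < 0:
            raise TroopConfigError("movement_count must be nonnegative")

    @property
    def n_individuals(self) -> int:
        return self.n_males + self.n_females


@dataclass(frozen=True)
class Individual:
    """Roster entry; gregariousness and strength are generator latents."""

    id: str
    sex: str  # "male" | "female"
    matriline: str | None
    n_relatives: int
    true_gregariousness: float
    latent_strength: float


def stable_subseed(seed: int, name: str) -> np.random.SeedSequence:
    """Named sub-seed: a stable function of (seed, generator name)."""
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _rng(config: TroopConfig, name: str) -> np.random.Generator:
    return np.random.default_rng(stable_subseed(config.seed, name))


# -- roster ------------------------------------------------------------------

def make_roster(config: TroopConfig) -> list[Individual]:
    """Generate the focal roster.

    Matrilines are filled female-first (female philopatry); males left
    without a matriline stand for immigrants, whose in-group relative
    count is 0.  A latent gregariousness (lognormal) drives proximity;
    a latent strength ladder drives agonistic outcomes.
    """
    rng = _rng(config, "roster")
    n = config.n_individuals
    sexes = ["male"] * config.n_males + ["female"] * config.n_females
    ids = [f"{'M' if s == 'male' else 'F'}{k + 1:02d}" for k, s in enumerate(sexes)]

    matriline_of: dict[str, str | None] = {i: None for i in ids}
    if config.n_matrilines > 0 and config.matriline_coverage > 0:
        affiliated = int(round(config.matriline_coverage * n))
        affiliated = min(affiliated, n)
        # random composition with every matriline nonempty where possible
        sizes = np.zeros(config.n_matrilines, dtype=int)
        base = min(affiliated, config.n_matrilines)
        sizes[:base] = 1
        extra = affiliated - base
        if extra > 0:
            sizes += rng.multinomial(extra, np.full(config.n_matrilines, 1 / config.n_matrilines))
        # female-biased membership, not female-exclusive: matrilineal
        # societies keep a few natal males in their lines, and the odd
        # female can lack resident kin, so sex and kin count must not be
        # interchangeable covariates downstream
        weights = np.array([4.0 if s == "female" else 1.0 for s in sexes])
        pool = list(
            rng.choice(ids, size=len(ids), replace=False, p=weights / weights.sum())
        )
        cursor = 0
        for m, size in enumerate(sizes):
            for _ in range(int(size)):
                if cursor >= len(pool):
                    break
                matriline_of[pool[cursor]] = f"mat{m + 1}"
                cursor += 1

    sizes_by_line: dict[str, int] = {}
    for line in matriline_of.values():
        if line is not None:
            sizes_by_line[line] = sizes_by_line.get(line, 0) + 1

    gregariousness = rng.lognormal(mean=0.0, sigma=0.4, size=n)
    strength = np.linspace(1.0, -1.0, n)[rng.permutation(n)]

    return [
        Individual(
            id=ids[k],
            sex=sexes[k],
            matriline=matriline_of[ids[k]],
            n_relatives=(
                sizes_by_line[matriline_of[ids[k]]] - 1
                if matriline_of[ids[k]] is not None
                else 0
            ),
            true_gregariousness=float(gregariousness[k]),
            latent_strength=float(strength[k]),
        )
        for k in range(n)
    ]


# -- proximity ---------------------------------------------------------------

def simulate_proximity(
    roster: Sequence[Individual], config: TroopConfig
) -> list[ProximityRecord]:
    """Focal-session 1 m-proximity durations.

    The expected dyadic proximity fraction is proportional to the product
    of the two gregariousness latents, scaled so the troop-average dyad
    spends ``mean_proximity_fraction`` of a session within 1 m.  Each
    focal session logs one record per partner; durations are beta-jittered
    and capped at the session length.
    """
    if not roster:
        raise TroopConfigError("roster must be nonempty")
    rng = _rng(config, "proximity")
    n = len(roster)
    g = np.array([ind.true_gregariousness for ind in roster])
    g_norm = g / g.mean() if g.mean() > 0 else g
    length = config.session_length
    records: list[ProximityRecord] = []
    for i, focal in enumerate(roster):
        for s in range(config.n_sessions_per_individual):
            session_id = f"{focal.id}-s{s + 1:02d}"
            for j, partner in enumerate(roster):
                if j == i:
                    continue
                frac = config.mean_proximity_fraction * g_norm[i] * g_norm[j]
                frac = min(frac, 1.0)
                if frac <= 0:
                    duration = 0.0
                elif frac >= 1.0:
                    duration = length
                else:
                    # beta draw with mean `frac`, concentration 8
                    duration = length * rng.beta(8.0 * frac, 8.0 * (1.0 - frac))
                records.append(
                    ProximityRecord(
                        focal_id=focal.id,
                        partner_id=partner.id,
                        overlap_duration=float(duration),
                        session_id=session_id,
                        session_duration=length,
                    )
                )
    return records


# -- agonism -----------------------------------------------------------------

def simulate_agonistic(
    roster: Sequence[Individual], config: TroopConfig
) -> list[AgonisticBout]:
    """Decided aggression-submission bouts for every dyad.

    Win probabilities follow a logistic ladder on the latent strengths
    with slope ``dominance_steepness``; every dyad interacts at least
    once so David's Score is defined for all individuals.
    """
    if not roster:
        raise TroopConfigError("roster must be nonempty")
    rng = _rng(config, "agonistic")
    bouts: list[AgonisticBout] = []
    for i in range(len(roster)):
        for j in range(i + 1, len(roster)):
            a, b = roster[i], roster[j]
            n_bouts = 1 + rng.poisson(config.mean_bouts_per_dyad - 1.0)
            p_a = special.expit(
                config.dominance_steepness * (a.latent_strength - b.latent_strength)
            )
            wins_a = rng.binomial(n_bouts, p_a)
            bouts.extend(
                AgonisticBout(actor_id=a.id, receiver_id=b.id) for _ in range(wins_a)
            )
            bouts.extend(
                AgonisticBout(actor_id=b.id, receiver_id=a.id)
                for _ in range(n_bouts - wins_a)
            )
    return bouts


# -- movements ---------------------------------------------------------------

#: Spacing between synthetic events; far beyond the 5-minute close gap so
#: re-segmenting a serialized stream reproduces the events exactly.
_EVENT_SPACING = 4000.0


def _zip_counts(rng: np.random.Generator, lam: np.ndarray, pi: float) -> np.ndarray:
    structural = rng.random(lam.size) < pi
    return np.where(structural, 0, rng.poisson(lam))


def simulate_movements(
    roster: Sequence[Individual],
    centrality: Mapping[str, float] | pd.Series,
    config: TroopConfig,
) -> tuple[list[MovementEvent], dict]:
    """Collective movements with ZIP-distributed per-individual calls.

    Per participant, the call count is zero with probability
    ``zero_inflation`` and otherwise Poisson with log-rate

        intercept + sex_effect * female + centrality_effect * centrality
        + order_effect * order_index.

    Early joining weakly tracks gregariousness, so joining order carries
    social signal as it does in the field.  Returns the events plus a
    ground-truth dict (coefficients and the per-observation design) for
    recovery tests.
    """
    if not roster:
        raise TroopConfigError("roster must be nonempty")
    rng = _rng(config, "movements")
    n = len(roster)
    ids = [ind.id for ind in roster]
    female = np.array([1.0 if ind.sex == "female" else 0.0 for ind in roster])
    cent = np.array([float(centrality[i]) for i in ids])
    greg = np.array([ind.true_gregariousness for ind in roster])
    join_weight = np.exp(0.7 * (greg - greg.mean()) / (greg.std() + 1e-12))

    events: list[MovementEvent] = []
    rows = []
    for e in range(config.movement_count):
        size = MIN_PARTICIPANTS + rng.binomial(n - MIN_PARTICIPANTS, 0.3)
        members = rng.choice(n, size=size, replace=False, p=join_weight / join_weight.sum())
        start = e * _EVENT_SPACING
        gaps = rng.uniform(5.0, 200.0, size=size - 1)
        times = start + np.concatenate([[0.0], np.cumsum(gaps)])
        order = 1.0 - np.arange(size) / (size - 1)
        lam = np.exp(
            config.vocal_intercept
            + config.vocal_sex_effect * female[members]
            + config.vocal_centrality_effect * cent[members]
            + config.order_effect * order
        )
        counts = _zip_counts(rng, lam, config.zero_inflation)
        joins = tuple((ids[m], float(t)) for m, t in zip(members, times))
        calls = {ids[m]: int(c) for m, c in zip(members, counts)}
        events.append(
            MovementEvent(
                event_id=f"m{e + 1:03d}", joins=joins, calls=calls, successful=True
            )
        )
        for k, m in enumerate(members):
            rows.append(
                {
                    "event_id": f"m{e + 1:03d}",
                    "id": ids[m],
                    "calls": int(counts[k]),
                    "female": female[m],
                    "centrality": cent[m],
                    "order_index": order[k],
                    "exposure": 1.0,
                }
            )
    truth = {
        "intercept": config.vocal_intercept,
        "female": config.vocal_sex_effect,
        "centrality": config.vocal_centrality_effect,
        "order_index": config.order_effect,
        "zero_inflation": config.zero_inflation,
        "observations": pd.DataFrame(rows),
    }
    return events, truth


def paper_tally_events(
    roster: Sequence[Individual] | None = None,
    seed: int = 0,
) -> list[MovementEvent]:
    """Fixture reproducing the published movement tallies exactly.

    132 successful movements, 52 of them vocal, 34 with a vocalizing
    initiator.  Vocal events recruit more participants than silent ones,
    and calls concentrate on early joiners, so the participant-count test
    and the order/rate correlation behave as in the study.
    """
    if roster is None:
        roster = make_roster(TroopConfig(seed=seed))
    rng = np.random.default_rng(stable_subseed(seed, "paper_tally"))
    n = len(roster)
    ids = [ind.id for ind in roster]
    greg = np.array([ind.true_gregariousness for ind in roster])
    weight = np.exp(0.7 * (greg - greg.mean()) / (greg.std() + 1e-12))
    weight /= weight.sum()

    flags = np.array([True] * 52 + [False] * 80)
    rng.shuffle(flags)
    vocal_ids = np.flatnonzero(flags)
    initiator_vocal = set(rng.choice(vocal_ids, size=34, replace=False).tolist())

    events: list[MovementEvent] = []
    for e in range(132):
        vocal = bool(flags[e])
        p_extra = 0.45 if vocal else 0.2
        size = MIN_PARTICIPANTS + int(rng.binomial(n - MIN_PARTICIPANTS, p_extra))
        members = rng.choice(n, size=size, replace=False, p=weight)
        start = e * _EVENT_SPACING
        times = start + np.concatenate(
            [[0.0], np.cumsum(rng.uniform(5.0, 200.0, size=size - 1))]
        )
        order = 1.0 - np.arange(size) / (size - 1)
        counts = np.zeros(size, dtype=int)
        if vocal:
            # calls concentrate on early joiners, so the joining-order /
            # vocal-rate correlation seen in the field emerges here too
            if e in initiator_vocal:
                counts[0] = 1 + rng.poisson(1.0)
                counts[1:] = np.where(
                    rng.random(size - 1) < 0.6 * order[1:] ** 2,
                    1 + rng.poisson(order[1:]),
                    0,
                )
            else:
                counts[1:] = np.where(
                    rng.random(size - 1) < 0.6 * order[1:] ** 2,
                    1 + rng.poisson(order[1:]),
                    0,
                )
                if not np.any(counts[1:] > 0):
                    counts[1] = 1
        joins = tuple((ids[m], float(t)) for m, t in zip(members, times))
        calls = {ids[m]: int(c) for m, c in zip(members, counts)}
        events.append(
            MovementEvent(event_id=f"m{e + 1:03d}", joins=joins, calls=calls, successful=True)
        )
    return events


# -- call synthesis ----------------------------------------------------------

#: Published per-type feature targets, FEATURE order:
#: (duration, mean_f0, min_f0, max_f0, mean_amp, min_amp, max_amp)
CALL_TARGETS: dict[str, tuple[float, ...]] = {
    "coo": (0.23, 282.0, 244.0, 303.0, 53.0, 43.0, 56.0),
    "leap_coo": (0.26, 361.0, 260.0, 490.0, 58.0, 45.0, 63.0),
    "bark": (0.06, 378.0, 360.0, 398.0, 73.0, 68.0, 75.0),
}


def _plateau_ramp(t: np.ndarray, duration: float, plateau: float, q: float) -> np.ndarray:
    """0 on the leading plateau, 1 on the trailing one, t^q ramp between."""
    ramp_len = duration - 2.0 * plateau
    u = np.clip((t - plateau) / ramp_len, 0.0, 1.0)
    return u**q


def _frame_grid(n_samples: int, fs: float) -> tuple[np.ndarray, int]:
    win = int(round(FRAME_LENGTH * fs))
    hop = int(round(HOP * fs))
    starts = np.arange(0, n_samples - win + 1, hop)
    return starts, win


def _gaussian_weights(win: int) -> np.ndarray:
    from scipy.signal.windows import gaussian

    w = gaussian(win, std=win / 6.0)
    return w / w.sum()


def _frame_weighted_mean(values: np.ndarray, starts: np.ndarray, weights: np.ndarray) -> np.ndarray:
    win = weights.size
    return np.array([float(values[s : s + win] @ weights) for s in starts])


def _db_to_envelope(db: np.ndarray) -> np.ndarray:
    rms = np.power(10.0, (db - DB_FULL_SCALE_SINE) / 20.0) / math.sqrt(2.0)
    return rms / _STACK_RMS


def _frame_rms_db(envelope_sq: np.ndarray, starts: np.ndarray, win: int) -> np.ndarray:
    csum = np.concatenate(([0.0], np.cumsum(envelope_sq)))
    rms = np.sqrt((csum[starts + win] - csum[starts]) / win) * _STACK_RMS
    return 20.0 * np.log10(np.maximum(rms, 1e-12) * math.sqrt(2.0)) + DB_FULL_SCALE_SINE


def _solve_ramp_exponent(eval_mean, target: float) -> float:
    """Find q in [0.02, 60] with eval_mean(q) == target (monotone in q)."""
    lo, hi = 0.02, 60.0
    m_lo, m_hi = eval_mean(lo), eval_mean(hi)
    lo_val, hi_val = max(m_lo, m_hi), min(m_lo, m_hi)
    if not (hi_val <= target <= lo_val):
        # clamp: jittered targets can fall outside the achievable band
        return lo if abs(target - m_lo) < abs(target - m_hi) else hi
    return float(optimize.brentq(lambda q: eval_mean(q) - target, lo, hi, xtol=1e-6))


def _f0_contour_samples(
    duration: float,
    f0_min: float,
    f0_mean: float,
    f0_max: float,
    fs: float,
    flat: bool,
) -> np.ndarray:
    """Instantaneous f0, sampled at the audio rate.

    The sweep holds the published min/max on end plateaus at least one
    analysis frame long (where the call allows), so the measured contour
    never leaves the published band; the ramp exponent is tuned so the
    Gaussian-windowed frame mean lands on the mean target.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    starts, win = _frame_grid(n, fs)
    if starts.size < 1:
        raise CallSynthesisError("call too short for one analysis frame")
    if flat or f0_max - f0_min < 1e-9:
        return np.full(n, f0_mean)
    plateau = min(FRAME_LENGTH, duration / 4.0)
    gweights = _gaussian_weights(win)
    span = f0_max - f0_min

    def frame_mean(q: float) -> float:
        contour = f0_min + span * _plateau_ramp(t, duration, plateau, q)
        return float(np.mean(_frame_weighted_mean(contour, starts, gweights)))

    q = _solve_ramp_exponent(frame_mean, f0_mean)
    return f0_min + span * _plateau_ramp(t, duration, plateau, q)


def _amp_db_contour(
    duration: float,
    amp_min_db: float,
    amp_mean_db: float,
    amp_max_db: float,
    fs: float,
) -> np.ndarray:
    """Frame-dB envelope contour (same plateau-ramp family as f0)."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    starts, win = _frame_grid(n, fs)
    plateau = min(FRAME_LENGTH, duration / 4.0)
    if amp_max_db - amp_min_db < 1e-9:
        return np.full(n, amp_mean_db)
    db_span = amp_max_db - amp_min_db

    def frame_mean(q: float) -> float:
        contour = amp_min_db + db_span * _plateau_ramp(t, duration, plateau, q)
        env = _db_to_envelope(contour)
        return float(np.mean(_frame_rms_db(env**2, starts, win)))

    q = _solve_ramp_exponent(frame_mean, amp_mean_db)
    return amp_min_db + db_span * _plateau_ramp(t, duration, plateau, q)


def _calibrated_amp_contour(
    duration: float,
    amp_min_db: float,
    amp_mean_db: float,
    amp_max_db: float,
    fs: float,
) -> np.ndarray:
    """Solve for internal end levels so the *measured* frame-dB statistics
    hit the target triple.

    Near the call edges the analysis window straddles the plateau and the
    ramp, so the measured extremes sit inside the envelope's end levels;
    a short root solve on (min, mean, max) pre-compensates for that.
    """
    n = int(round(duration * fs))
    starts, win = _frame_grid(n, fs)
    target = np.array([amp_min_db, amp_mean_db, amp_max_db])

    def measured(v: np.ndarray) -> np.ndarray:
        lo = float(np.clip(v[0], 10.0, 94.0))
        hi = float(np.clip(v[2], lo + 0.1, 95.0))
        mid = float(np.clip(v[1], lo + 0.05, hi - 0.05))
        contour = _amp_db_contour(duration, lo, mid, hi, fs)
        db = _frame_rms_db(_db_to_envelope(contour) ** 2, starts, win)
        return np.array([db.min(), db.mean(), db.max()])

    sol = optimize.root(lambda v: measured(v) - target, target, method="hybr", tol=1e-6)
    v = sol.x
    lo = float(np.clip(v[0], 10.0, 94.0))
    hi = float(np.clip(v[2], lo + 0.1, 95.0))
    mid = float(np.clip(v[1], lo + 0.05, hi - 0.05))
    return _amp_db_contour(duration, lo, mid, hi, fs)


def _build_waveform(
    duration: float,
    f0: np.ndarray,
    db_contour: np.ndarray,
    fs: float,
) -> Waveform:
    envelope = _db_to_envelope(db_contour)
    phase = np.cumsum(f0) / fs
    stack = np.zeros(f0.size)
    for k in range(1, N_HARMONICS + 1):
        stack += (1.0 / k) * np.sin(2.0 * math.pi * k * phase)
    return Waveform(envelope * stack, fs)


def synthesize_call(
    call_type: str,
    jitter: float = 0.0,
    seed: int = 0,
    contour: str = "sweep",
    sample_rate: float = 44100.0,
    calibrate: bool = True,
) -> Waveform:
    """Synthesize one harmonic call of the given type.

    The waveform is a 5-harmonic stack (1/k amplitude rolloff) whose f0
    contour holds the type's minimum and maximum on short end plateaus
    with a monotone ramp between them, tuned so the extracted frame-mean
    lands on the type's mean f0; ``contour='flat'`` instead holds f0
    constant at the mean.  The amplitude envelope is calibrated (in the
    package's own frame-RMS dB convention, full-scale sine = 96 dB) so
    the computed dB statistics hit the type's amplitude triple.

    ``jitter > 0`` perturbs every feature target multiplicatively by
    ``1 + jitter * N(0, 1)`` before synthesis (seeded, deterministic);
    ``jitter = 0`` reproduces the published centroid for any seed.
    """
    if call_type not in CALL_TARGETS:
        raise CallSynthesisError(
            f"unknown call type: {call_type!r} (expected one of {sorted(CALL_TARGETS)})"
        )
    if contour not in ("sweep", "flat"):
        raise CallSynthesisError(f"unknown contour mode: {contour!r}")
    targets = np.array(CALL_TARGETS[call_type])
    if jitter > 0:
        rng = np.random.default_rng(stable_subseed(seed, f"call-{call_type}"))
        targets = targets * (1.0 + jitter * rng.standard_normal(targets.size))
        targets[0] = max(targets[0], 0.06)  # keep at least a few frames
        targets[1:4] = np.sort(np.clip(targets[1:4], 80.0, 590.0))
        targets[4:7] = np.sort(np.clip(targets[4:7], 20.0, 90.0))

    duration, f0_mean, f0_min, f0_max = targets[0], targets[1], targets[2], targets[3]
    amp_mean, amp_min, amp_max = targets[4], targets[5], targets[6]
    flat = contour == "flat"

    # Amplitude: pre-compensate the envelope's internal end levels so the
    # measured frame-dB triple lands on the target (edge frames straddle
    # plateau and ramp, biasing the raw extremes inward).
    if calibrate:
        db_contour = _calibrated_amp_contour(duration, amp_min, amp_mean, amp_max, sample_rate)
    else:
        db_contour = _amp_db_contour(duration, amp_min, amp_mean, amp_max, sample_rate)

    # f0: the plateaus stay pinned to the published min/max (the contour
    # must not leave the band); a short fixed-point run aligns the
    # extractor's measured mean with the mean target.
    internal_mean = f0_mean
    wave = None
    for _ in range(4 if calibrate else 1):
        if not flat:
            internal_mean = float(np.clip(internal_mean, f0_min + 0.5, f0_max - 0.5))
        f0 = _f0_contour_samples(duration, f0_min, internal_mean, f0_max, sample_rate, flat)
        wave = _build_waveform(duration, f0, db_contour, sample_rate)
        if not calibrate or flat:
            break
        err = extract_features(wave).mean_f0 - f0_mean
        if abs(err) < 0.02:
            break
        internal_mean -= err

    if calibrate:
        # one-shot refinement against the real waveform (the analytic
        # envelope model ignores the harmonic stack's intra-frame ripple);
        # kept only if it actually reduces the worst error, because for
        # very short calls the target triple is not exactly reachable and
        # shifting targets around the compromise point can overshoot
        n = wave.samples.size
        starts, win = _frame_grid(n, sample_rate)

        def amp_err(candidate: Waveform) -> np.ndarray:
            db = _acoustic_frame_db(candidate.samples, starts, win)
            return np.array(
                [db.min() - amp_min, db.mean() - amp_mean, db.max() - amp_max]
            )

        err3 = amp_err(wave)
        if np.max(np.abs(err3)) > 0.05:
            db_refined = _calibrated_amp_contour(
                duration, amp_min - err3[0], amp_mean - err3[1], amp_max - err3[2], sample_rate
            )
            refined = _build_waveform(duration, f0, db_refined, sample_rate)
            if np.max(np.abs(amp_err(refined))) < np.max(np.abs(err3)):
                wave = refined
    return wave


# -- dataset serialization ---------------------------------------------------

def roster_to_frame(roster: Sequence[Individual]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [i.id for i in roster],
            "sex": [i.sex for i in roster],
            "matriline": [i.matriline if i.matriline is not None else "" for i in roster],
            "n_relatives": [i.n_relatives for i in roster],
            "true_gregariousness": [i.true_gregariousness for i in roster],
            "latent_strength": [i.latent_strength for i in roster],
        }
    )


def roster_from_frame(df: pd.DataFrame) -> list[Individual]:
    return [
        Individual(
            id=str(r.id),
            sex=str(r.sex),
            matriline=str(r.matriline) if str(r.matriline) else None,
            n_relatives=int(r.n_relatives),
            true_gregariousness=float(r.true_gregariousness),
            latent_strength=float(r.latent_strength),
        )
        for r in df.itertuples()
    ]


#: Session start times anchor to the observation schedule's morning block.
_SESSION_EPOCH = pd.Timestamp("2021-08-18T08:30:00")


def write_dataset(
    out_dir: str | Path,
    config: TroopConfig,
    preset: str | None = None,
    n_calls_per_type: Mapping[str, int] | None = None,
    call_jitter: float = 0.0,
) -> dict:
    """Generate and serialize a full synthetic dataset.

    Writes roster.csv, proximity.csv, agonistic.csv, movements.csv and a
    calls/ directory of 16-bit WAV files.  ``preset='paper_tally'``
    replaces the stochastic movement log with the fixture matching the
    published event tallies.  Returns the in-memory objects.
    """
    from .social import compute_dai, eigenvector_centrality

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roster = make_roster(config)
    proximity = simulate_proximity(roster, config)
    agonistic = simulate_agonistic(roster, config)
    dai = compute_dai(proximity, roster)
    centrality = eigenvector_centrality(dai).to_series()
    if preset == "paper_tally":
        events = paper_tally_events(roster, seed=config.seed)
        truth = None
    elif preset is None:
        events, truth = simulate_movements(roster, centrality, config)
    else:
        raise TroopConfigError(f"unknown preset: {preset!r}")

    roster_to_frame(roster).to_csv(out / "roster.csv", index=False)

    prox_rows = []
    for k, rec in enumerate(proximity):
        session_index = int(rec.session_id.rsplit("s", 1)[-1]) - 1
        start = _SESSION_EPOCH + pd.Timedelta(days=session_index)
        prox_rows.append(
            {
                "focal_id": rec.focal_id,
                "partner_id": rec.partner_id,
                "overlap_duration_s": rec.overlap_duration,
                "session_id": rec.session_id,
                "session_start": start.isoformat(),
                "session_duration_s": rec.session_duration,
            }
        )
    pd.DataFrame(prox_rows).to_csv(out / "proximity.csv", index=False)

    pd.DataFrame(
        {
            "actor_id": [b.actor_id for b in agonistic],
            "receiver_id": [b.receiver_id for b in agonistic],
            "outcome": ["actor_wins"] * len(agonistic),
        }
    ).to_csv(out / "agonistic.csv", index=False)

    from .movement import events_to_frame

    events_to_frame(events).to_csv(out / "movements.csv", index=False)

    calls_dir = out / "calls"
    calls_dir.mkdir(exist_ok=True)
    if n_calls_per_type is None:
        n_calls_per_type = {"coo": 22, "leap_coo": 7, "bark": 1}
    for name, count in n_calls_per_type.items():
        for k in range(count):
            wave = synthesize_call(name, jitter=call_jitter, seed=config.seed + k)
            write_wav(calls_dir / f"{name}_{k + 1:02d}.wav", wave)

    return {
        "roster": roster,
        "proximity": proximity,
        "agonistic": agonistic,
        "events": events,
        "centrality": centrality,
        "truth": truth if preset is None else None,
    }
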