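"""Seeded synthetic moth cohorts and flight records.

The real training corpus for this kind of model is a laboratory collection
of per-moth stimulus/response time series; none is publicly deposited, so
this module generates cohorts with the statistical structure the learners
assume and that real data would plausibly exhibit:

* a latent group structure — each moth belongs to one of ``c_true`` groups
  with a group-specific stimulus->response mapping;
* individual-specific additive offsets on the seven flight parameters;
* observation noise;
* ambient conditions with the wind capped at 1.5 m/s;
* all features normalisable to [0, 1].

The ground-truth dynamics are a per-group linear map on centred features
passed through a logistic squashing, with the horizontal-deflection channel
driven purely by the left/right lamp asymmetry (so symmetric stimulation
yields zero expected deflection, i.e. 0.5 on the normalised scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema
from .behavior import accumulate_history

__all__ = ["SyntheticMoth", "GroundTruthDynamics", "Cohort",
           "generate_cohort", "simulate_flight", "generate_dataset",
           "probe_settings", "probe_responses", "make_instructions",
           "group_contrast"]

RESTING = 0.5   # normalised resting value of every flight parameter


@dataclass
class SyntheticMoth:
    id: int
    group: int
    shape: np.ndarray          # (3,) wing span, body length, mass in [0,1]
    offset: np.ndarray         # (7,) individual offset, Normal(0, sigma_ind)


@dataclass
class GroundTruthDynamics:
    """Per-group response matrices ``A_g`` (7 x 80) acting on centred
    normalised features, squashed by a logistic of slope ``squash_slope``.

    Row 0 (horizontal deflection) carries only the antisymmetric
    left-minus-right lamp terms, scaled by a per-group asymmetry
    coefficient, so left/right-symmetric stimulation maps to 0.5 exactly.
    """

    A: np.ndarray              # (c_true, 7, 80)
    squash_slope: float
    sigma_obs: float

    def respond(self, moth: SyntheticMoth, x: np.ndarray,
                rng: np.random.Generator | None = None,
                noise: bool = True) -> np.ndarray:
        """Flight parameters for a normalised 80-dim input vector."""
        x = np.asarray(x, dtype=float)
        z = self.A[moth.group] @ (x - 0.5)
        y = 1.0 / (1.0 + np.exp(-self.squash_slope * z))
        y = y + moth.offset
        if noise and self.sigma_obs > 0:
            if rng is None:
                raise ValueError("rng required for noisy responses")
            y = y + rng.normal(0.0, self.sigma_obs, 7)
        return np.clip(y, 0.0, 1.0)


@dataclass
class Cohort:
    moths: list[SyntheticMoth]
    dynamics: GroundTruthDynamics
    c_true: int
    seed: int | None = None

    @property
    def shapes(self) -> np.ndarray:
        return np.array([m.shape for m in self.moths])

    @property
    def labels(self) -> np.ndarray:
        return np.array([m.group for m in self.moths])

    def moth(self, moth_id: int) -> SyntheticMoth:
        for m in self.moths:
            if m.id == moth_id:
                return m
        raise KeyError(f"unknown moth id {moth_id}")


def _asym_row(coef: float) -> np.ndarray:
    """theta_h row: +coef on the left lamps' intensities, -coef on the
    right lamps' (exactly antisymmetric in the lamp pair swap)."""
    row = np.zeros(schema.N_FEATURES)
    blk = len(schema.LAMP_BLOCK)
    for li, lamp in enumerate(schema.LAMP_NAMES):
        sgn = 1.0 if lamp.startswith("left") else -1.0
        row[li * blk + 0] = sgn * coef            # intensity
        row[li * blk + 2] = 0.4 * sgn * coef      # x moving velocity
    return row


def generate_cohort(n_moths: int = 36, c_true: int = 3,
                    seed: int | None = None, sigma_ind: float = 0.05,
                    sigma_obs: float = 0.05, separation: float = 1.0,
                    squash_slope: float = 2.0) -> Cohort:
    """Build a cohort with balanced group assignment and per-group response
    matrices ``A_g = A0 + separation * B_g``.

    ``separation`` is the identifiability knob: at the default the mean
    between-group response contrast exceeds three observation-noise sigmas;
    at 0 all groups share one mapping and grouping becomes unrecoverable.
    """
    if n_moths < c_true:
        raise ValueError("need at least one moth per group")
    rng = np.random.default_rng(seed)
    D = schema.N_FEATURES
    scale = 1.6 / np.sqrt(D)
    A0 = rng.normal(0.0, scale, (7, D))
    A = np.empty((c_true, 7, D))
    for g in range(c_true):
        B = rng.normal(0.0, scale, (7, D))
        A[g] = A0 + separation * B
        A[g, 0] = _asym_row(1.2 * (1.0 + 0.3 * separation * (g - (c_true - 1) / 2)))
    dyn = GroundTruthDynamics(A=A, squash_slope=squash_slope,
                              sigma_obs=sigma_obs)
    # balanced assignment: groups cycle 0..c-1
    moths = []
    for j in range(n_moths):
        moths.append(SyntheticMoth(
            id=j, group=j % c_true,
            shape=rng.random(3),
            offset=rng.normal(0.0, sigma_ind, 7)))
    return Cohort(moths=moths, dynamics=dyn, c_true=c_true, seed=seed)


def _build_x(stimulus01, ambient01, prev, accum) -> np.ndarray:
    return np.concatenate([stimulus01, ambient01, prev, accum])


def simulate_flight(cohort: Cohort, moth: SyntheticMoth, stimulus01, ambient,
                    prev, accum, rng: np.random.Generator,
                    noise: bool = True) -> np.ndarray:
    """One response step.  ``ambient`` is raw (winds in m/s, cap enforced);
    everything else is already normalised."""
    amb01 = schema.normalize_ambient(ambient)
    x = _build_x(stimulus01, amb01, prev, accum)
    return cohort.dynamics.respond(moth, x, rng, noise=noise)


def _draw_ambient(rng: np.random.Generator) -> np.ndarray:
    amb01 = np.clip(rng.normal(0.5, 0.15, schema.N_AMBIENT), 0.0, 1.0)
    return schema.denormalize_ambient(amb01)


def generate_dataset(cohort: Cohort, records_per_moth: int = 304,
                     seed: int | None = None,
                     session_length: int = 50) -> pd.DataFrame:
    """Time-ordered flight records for every moth in the cohort.

    Records are organised in recording sessions of ``session_length``
    steps: ambient conditions are redrawn at each session start and drift
    slowly within a session; the stimulus is drawn freshly each step (an
    exploring controller); the previous-parameter and accumulated-history
    fields are rolled from the emitted trajectory.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for moth in cohort.moths:
        amb = _draw_ambient(rng)
        history: list[np.ndarray] = []
        prev = np.full(7, RESTING)
        for t in range(records_per_moth):
            if t % session_length == 0:
                amb = _draw_ambient(rng)
                history, prev = [], np.full(7, RESTING)
            drift = rng.normal(0.0, 0.01, schema.N_AMBIENT) \
                * (schema.AMBIENT_RANGES[:, 1] - schema.AMBIENT_RANGES[:, 0])
            amb = np.clip(amb + drift, schema.AMBIENT_RANGES[:, 0],
                          schema.AMBIENT_RANGES[:, 1])
            stim = rng.random(schema.N_STIMULUS)
            accum = accumulate_history(history)
            target = simulate_flight(cohort, moth, stim, amb, prev, accum, rng)
            rows.append(np.concatenate([[moth.id, t], stim, amb, prev,
                                        accum, target]))
            history.insert(0, target)
            del history[3:]
            prev = target
    df = pd.DataFrame(rows, columns=schema.RECORD_COLUMNS)
    df["id"] = df["id"].astype(int)
    df["t"] = df["t"].astype(int)
    return df


def probe_settings() -> tuple[np.ndarray, np.ndarray]:
    """The fixed grouping probe grid: 3 ambient presets x 12 stimulus
    presets (36 combinations).

    Ambient presets: cool/dim, warm/bright, and windy (1.2 m/s).  Stimulus
    presets cover the laterality, intensity, duration and pattern-motion
    extremes, including a left-only and a right-only intensity preset.
    """
    amb = np.full((3, schema.N_AMBIENT), 0.5)
    amb[0, :5] = (0.2, 0.3, 0.5, 0.5, 0.5)          # cool, dim
    amb[0, 7:] = 0.25
    amb[1, :5] = (0.8, 0.6, 0.5, 0.5, 0.5)          # warm, bright
    amb[1, 7:] = 0.75
    amb[2, :5] = 0.5
    amb[2, list(schema.WIND_IDX)] = 0.8              # windy (0.8 * 1.5 m/s)
    amb[0, list(schema.WIND_IDX)] = 0.1
    amb[1, list(schema.WIND_IDX)] = 0.1

    blk = len(schema.LAMP_BLOCK)
    n_lamp = len(schema.LAMP_NAMES)

    def preset(settings):
        s = np.full(schema.N_STIMULUS, 0.1)
        for (lamp, var), v in settings.items():
            li = schema.LAMP_NAMES.index(lamp)
            s[li * blk + schema.LAMP_BLOCK.index(var)] = v
        return s

    full = {(l, "intensity"): 0.9 for l in schema.LAMP_NAMES}
    stim = np.stack([
        preset({("left_uva", "intensity"): 0.9, ("left_uvb", "intensity"): 0.9}),
        preset({("right_uva", "intensity"): 0.9, ("right_uvb", "intensity"): 0.9}),
        preset(full),
        np.full(schema.N_STIMULUS, 0.1),
        preset({("left_uva", "intensity"): 0.9}),
        preset({("right_uvb", "intensity"): 0.9}),
        preset({**full, **{(l, "duration"): 0.9 for l in schema.LAMP_NAMES}}),
        preset({**full, **{(l, "vx"): 0.9 for l in schema.LAMP_NAMES}}),
        preset({**full, **{(l, "vy"): 0.9 for l in schema.LAMP_NAMES}}),
        preset({**full, **{(l, "vz"): 0.9 for l in schema.LAMP_NAMES}}),
        preset({**full, **{(l, "dx"): 0.9 for l in schema.LAMP_NAMES}}),
        np.full(schema.N_STIMULUS, 0.5),
    ])
    return amb, stim


def probe_responses(cohort: Cohort, seed: int | None = None,
                    n_reps: int = 3) -> np.ndarray:
    """Mean flight-parameter response of each moth to each of the 36 probe
    settings, starting from rest; shape ``(n_moths, 36, 7)``."""
    rng = np.random.default_rng(seed)
    amb01, stim = probe_settings()
    rest = np.full(7, RESTING)
    out = np.empty((len(cohort.moths), amb01.shape[0] * stim.shape[0], 7))
    for mi, moth in enumerate(cohort.moths):
        k = 0
        for a in amb01:
            for s in stim:
                x = _build_x(s, a, rest, rest)
                reps = [cohort.dynamics.respond(moth, x, rng) for _ in range(n_reps)]
                out[mi, k] = np.mean(reps, axis=0)
                k += 1
    return out


def make_instructions(cohort: Cohort, n: int, seed: int | None = None,
                      stim_band: tuple[float, float] = (0.3, 0.7)) -> pd.DataFrame:
    """Achievable control instructions: random stimuli applied in random
    contexts, with the resulting (noise-free) flight parameters recorded as
    the required behavior.

    Stimuli are drawn from ``stim_band``, the controllable mid-range of the
    dynamics where the stimulus->behavior map is smooth and injective on
    the instruction set (flight parameters away from the squashing
    saturation).

    Each instruction is a maneuver command and marks as *relevant* only the
    flight parameters it explicitly sets: a horizontal maneuver the
    horizontal deflection angle and angular velocity, a vertical maneuver
    the vertical pair, an acceleration maneuver the three accelerations,
    and a full-pose instruction all seven.  Success is judged on the
    relevant parameters only.

    Columns: moth id, the 7 required parameters, relevance flags, raw
    ambient, previous/accumulated parameters, and the stimulus that
    generated the requirement (ground truth, for diagnostics only)."""
    rng = np.random.default_rng(seed)
    lo, hi = stim_band
    maneuvers = ((0, 1), (2, 3), (4, 5, 6), tuple(range(7)))
    rows = []
    for _ in range(n):
        moth = cohort.moths[rng.integers(len(cohort.moths))]
        amb = _draw_ambient(rng)
        # instructions arrive mid-flight: the moth's current state is its
        # (noisy, offset-bearing) trajectory under random preceding stimuli
        history: list[np.ndarray] = []
        prev = np.full(7, RESTING)
        for _step in range(3):
            prev = simulate_flight(
                cohort, moth, lo + (hi - lo) * rng.random(schema.N_STIMULUS),
                amb, prev, accumulate_history(history), rng)
            history.insert(0, prev)
        accum = accumulate_history(history)
        stim = lo + (hi - lo) * rng.random(schema.N_STIMULUS)
        req = simulate_flight(cohort, moth, stim, amb, prev, accum, rng,
                              noise=False)
        rel = np.zeros(7)
        rel[list(maneuvers[rng.integers(len(maneuvers))])] = 1.0
        rows.append(np.concatenate([[moth.id], req, rel, amb, prev, accum,
                                    stim]))
    cols = (["id"] + [f"req{i+1}" for i in range(7)]
            + [f"rel{i+1}" for i in range(7)] + schema.AMB_COLS
            + schema.PREV_COLS + schema.ACCUM_COLS
            + [f"true_{c}" for c in schema.STIM_COLS])
    df = pd.DataFrame(rows, columns=cols)
    df["id"] = df["id"].astype(int)
    return df


def group_contrast(cohort: Cohort, seed: int | None = None,
                   n_probe: int = 200) -> float:
    """Mean absolute between-group difference of the noise-free group-mean
    response over random inputs — the identifiability margin, to be read
    against ``3 * sigma_obs``."""
    rng = np.random.default_rng(seed)
    X = rng.random((n_probe, schema.N_FEATURES))
    dyn = cohort.dynamics
    resp = []
    for g in range(cohort.c_true):
        z = (X - 0.5) @ dyn.A[g].T
        resp.append(1.0 / (1.0 + np.exp(-dyn.squash_slope * z)))
    diffs = []
    for g in range(cohort.c_true):
        for h in range(g + 1, cohort.c_true):
            diffs.append(np.mean(np.abs(resp[g] - resp[h])))
    return float(np.mean(diffs))
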