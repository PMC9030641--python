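"""Control Learner: the inverse model mapping required flight behavior to
recommended UV stimulation.

The input of the controller is the required flight-parameter vector, the
ambient conditions, the moth's previous/accumulated flight parameters and
its fuzzy group-membership vector (55 + c values in [0, 1]).  A PFDDAE
learns a high-order representation of this control context and a
multivariable linear head on the topmost code outputs the 32 stimulus
variables.

Training closes the loop: recommended stimuli are sent to a responder —
the *physical* responder (here, the synthetic ground-truth dynamics; in a
deployment, real cyborg moths) for a small fraction of instructions, and
the Behavior Learner for the rest, because physical trials are expensive.
The mixed regression loss weighs the model-feedback term by
``w_m = 1 - sum_j J_R(j) / |T_m|``: the better the Behavior Learner (small
per-moth regression errors ``J_R``), the more its feedback counts.

The head is warm-started by a distal-inverse least squares (regressing
applied stimuli on the codes of the contexts labelled with the behavior
they produced) and then fine-tuned by WWO on the closed-loop loss.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import schema
from . import wwo
from .behavior import HierarchicalBehaviorLearner, _MinMax01
from .pfdae import PFDDAE

__all__ = ["ControlLearner", "compute_wm", "control_loss",
           "evaluate_success_rate", "behavior_responder", "synthetic_responder",
           "CONTROL_WIDTHS"]

#: published layer sizes for the control stack; the input width adapts to
#: 55 + n_groups when fitting
CONTROL_WIDTHS = (75, 49, 35, 32)

REQ_COLS = [f"req{i+1}" for i in range(7)]


def compute_wm(individual_errors, n_m: int) -> float:
    """Model-feedback weight ``w_m = 1 - sum_j J_R(j) / |T_m|`` (clipped
    into [0, 1] with a warning if the raw value is negative)."""
    if n_m <= 0:
        raise ValueError("empty model-feedback subset")
    w = 1.0 - float(np.sum(individual_errors)) / n_m
    if w < 0:
        warnings.warn("behavior-learner errors exceed |T_m|; w_m clipped to 0",
                      RuntimeWarning, stacklevel=2)
    return float(np.clip(w, 0.0, 1.0))


def _rms7(required: np.ndarray, produced: np.ndarray) -> np.ndarray:
    """Per-instruction RMS deviation across the 7 normalised parameters."""
    required = np.atleast_2d(required)
    produced = np.atleast_2d(produced)
    return np.sqrt(np.mean((required - produced) ** 2, axis=1))


def control_loss(required: np.ndarray, produced: np.ndarray,
                 is_physical: np.ndarray, w_m: float) -> float:
    """Mixed closed-loop regression error: physical-feedback deviations
    count fully, model-feedback deviations are weighted by ``w_m``; the sum
    is normalised by the total instruction count."""
    required = np.atleast_2d(required)
    if required.shape[0] == 0:
        raise ValueError("empty instruction batch")
    dev = _rms7(required, produced)
    is_physical = np.asarray(is_physical, dtype=bool)
    return float((dev[is_physical].sum() + w_m * dev[~is_physical].sum())
                 / dev.shape[0])


def evaluate_success_rate(required: np.ndarray, produced: np.ndarray,
                          relevant: np.ndarray | None = None,
                          tol: float = 0.15, mode: str = "range"):
    """Fraction of instructions whose produced flight parameters deviate
    from the required values by less than ``tol`` on every relevant
    parameter.

    ``mode='range'`` (default) measures the deviation relative to the
    parameter's normalised full scale (1.0); ``mode='expected'`` measures
    it relative to the required value itself.
    Returns ``(success_rate, per-instruction deviation matrix)``.
    """
    required = np.atleast_2d(np.asarray(required, dtype=float))
    produced = np.atleast_2d(np.asarray(produced, dtype=float))
    if required.shape[0] == 0:
        raise ValueError("empty instruction set")
    if relevant is None:
        relevant = np.ones_like(required, dtype=bool)
    dev = np.abs(produced - required)
    if mode == "expected":
        dev = dev / np.maximum(np.abs(required), 1e-12)
    elif mode != "range":
        raise ValueError(f"unknown deviation mode {mode!r}")
    ok = np.where(relevant, dev < tol, True).all(axis=1)
    return float(ok.mean()), dev


# ---------------------------------------------------------------------------
# responders
# ---------------------------------------------------------------------------

def _instructions_to_records(instructions: pd.DataFrame,
                             stimuli: np.ndarray) -> pd.DataFrame:
    data = {"id": instructions["id"].to_numpy(), "t": np.arange(len(instructions))}
    for k, c in enumerate(schema.STIM_COLS):
        data[c] = stimuli[:, k]
    for c in schema.AMB_COLS + schema.PREV_COLS + schema.ACCUM_COLS:
        data[c] = instructions[c].to_numpy()
    for c in schema.TARGET_COLS:
        data[c] = 0.0
    return pd.DataFrame(data)


def behavior_responder(model: HierarchicalBehaviorLearner):
    """Responder closure: the Behavior Learner predicts the flight
    parameters a stimulus would produce in each instruction's context."""
    def respond(stimuli: np.ndarray, instructions: pd.DataFrame) -> np.ndarray:
        return model.predict(_instructions_to_records(instructions, stimuli))
    return respond


def synthetic_responder(cohort, rng: np.random.Generator | None = None,
                        noise: bool = True):
    """Responder closure over the synthetic ground-truth dynamics (stands
    for the physical moths in this repository)."""
    from .synth import simulate_flight
    rng = rng or np.random.default_rng(0)

    def respond(stimuli: np.ndarray, instructions: pd.DataFrame) -> np.ndarray:
        out = np.empty((len(instructions), 7))
        amb = instructions[schema.AMB_COLS].to_numpy(dtype=float)
        prev = instructions[schema.PREV_COLS].to_numpy(dtype=float)
        accum = instructions[schema.ACCUM_COLS].to_numpy(dtype=float)
        ids = instructions["id"].to_numpy()
        for k in range(len(instructions)):
            out[k] = simulate_flight(cohort, cohort.moth(int(ids[k])),
                                     stimuli[k], amb[k], prev[k], accum[k],
                                     rng, noise=noise)
        return out
    return respond


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class ControlLearner(BaseEstimator):
    """PFDDAE + linear-head inverse controller.

    ``fit`` needs an instruction table (required parameters + context), a
    trained :class:`HierarchicalBehaviorLearner` (model feedback and group
    memberships) and optionally a physical responder for a fraction
    ``t_p_fraction`` of the instructions.  ``recommend`` returns the
    32-dim stimulus vector in [0, 1] for new instructions.
    """

    def __init__(self, hidden_widths=CONTROL_WIDTHS[1:], noise_level=0.2,
                 budget_pretrain=300, budget_finetune=1500,
                 t_p_fraction=0.1, w_m=None, max_train_samples=256,
                 probe_band=(0.3, 0.7), random_state=None):
        self.hidden_widths = hidden_widths
        self.noise_level = noise_level
        self.budget_pretrain = budget_pretrain
        self.budget_finetune = budget_finetune
        self.t_p_fraction = t_p_fraction
        self.w_m = w_m
        self.max_train_samples = max_train_samples
        self.probe_band = probe_band
        self.random_state = random_state

    # -- input construction ------------------------------------------------

    def _control_inputs(self, instructions: pd.DataFrame,
                        required: np.ndarray | None = None) -> np.ndarray:
        req = required if required is not None else \
            instructions[REQ_COLS].to_numpy(dtype=float)
        amb = schema.normalize_ambient(
            instructions[schema.AMB_COLS].to_numpy(dtype=float))
        prev = instructions[schema.PREV_COLS].to_numpy(dtype=float)
        accum = instructions[schema.ACCUM_COLS].to_numpy(dtype=float)
        bm = self.behavior_model_
        U = np.stack([bm.memberships_[:, bm._moth_col[i]]
                      for i in instructions["id"].to_numpy()])
        return np.clip(np.hstack([req, amb, prev, accum, U]), 0.0, 1.0)

    def _codes(self, Xc: np.ndarray) -> np.ndarray:
        return self.code_scaler_.transform(self.stack_.transform(Xc))

    # -- estimator API -----------------------------------------------------

    def fit(self, instructions: pd.DataFrame,
            behavior_model: HierarchicalBehaviorLearner,
            physical_responder=None):
        if not hasattr(behavior_model, "individual_"):
            raise ValueError("behavior model must be trained first")
        rng = np.random.default_rng(self.random_state)
        self.behavior_model_ = behavior_model
        n = len(instructions)
        Xc = self._control_inputs(instructions)
        d_in = Xc.shape[1]

        # unsupervised pretraining of the control representation
        self.stack_ = PFDDAE(
            layer_widths=(d_in,) + tuple(self.hidden_widths),
            noise_level=self.noise_level, budget=self.budget_pretrain,
            max_train_samples=self.max_train_samples,
            random_state=int(rng.integers(2**31))).fit(Xc)
        raw_codes = self.stack_.transform(Xc)
        self.code_scaler_ = _MinMax01().fit(raw_codes)

        # physical/model feedback partition
        n_p = int(round(self.t_p_fraction * n)) if physical_responder else 0
        perm = rng.permutation(n)
        is_phys = np.zeros(n, dtype=bool)
        is_phys[perm[:n_p]] = True
        self.is_physical_ = is_phys
        if self.w_m is not None:
            self.w_m_ = float(self.w_m)
        elif n - n_p == 0:
            self.w_m_ = 1.0          # no model-feedback subset at all
        else:
            self.w_m_ = compute_wm(
                list(behavior_model.training_errors_.values()),
                int(n - n_p))

        model_resp = behavior_responder(behavior_model)

        def respond_all(stimuli: np.ndarray) -> np.ndarray:
            out = np.empty((n, 7))
            if n_p:
                sub = instructions.iloc[is_phys]
                out[is_phys] = physical_responder(stimuli[is_phys], sub)
            sub = instructions.iloc[~is_phys]
            out[~is_phys] = model_resp(stimuli[~is_phys], sub)
            return out

        # distal-inverse warm start: label random stimuli (drawn from the
        # controllable band) with the behavior they produce, then regress
        # stimulus on the control code
        lo, hi = self.probe_band
        s_probe = lo + (hi - lo) * rng.random((n, schema.N_STIMULUS))
        p_probe = respond_all(s_probe)
        Z_probe = self._codes(self._control_inputs(instructions,
                                                   required=p_probe))
        A = np.hstack([Z_probe, np.ones((n, 1))])
        W0, _, _, _ = np.linalg.lstsq(A, s_probe, rcond=None)

        # WWO fine-tuning of the head on the closed-loop mixed loss
        req = instructions[REQ_COLS].to_numpy(dtype=float)
        Z = self._codes(Xc)
        Az = np.hstack([Z, np.ones((n, 1))])

        def objective(genome: np.ndarray) -> float:
            W = genome.reshape(W0.shape)
            stim = np.clip(Az @ W, 0.0, 1.0)
            produced = respond_all(stim)
            return control_loss(req, produced, is_phys, self.w_m_)

        space = wwo.SearchSpace((W0 - 2.0).ravel(), (W0 + 2.0).ravel())
        res = wwo.optimize(objective, space,
                           wwo.OptimizerConfig(budget=self.budget_finetune),
                           rng, x0=W0.ravel())
        self.head_ = res.x.reshape(W0.shape)
        self.loss_trace_ = res.trace
        self.final_loss_ = res.fun
        return self

    def recommend(self, instructions: pd.DataFrame) -> np.ndarray:
        """Recommended stimulus vectors (n, 32), clipped to [0, 1]."""
        check_is_fitted(self, "head_")
        Z = self._codes(self._control_inputs(instructions))
        A = np.hstack([Z, np.ones((Z.shape[0], 1))])
        return np.clip(A @ self.head_, 0.0, 1.0)

    # sklearn-style alias
    predict = recommend

    def evaluate(self, instructions: pd.DataFrame, responder,
                 tol: float = 0.15, mode: str = "range"):
        """Closed-loop evaluation against a responder: returns the success
        rate at tolerance ``tol`` and the per-instruction deviations.
        Per-instruction relevance flags (``rel1..rel7`` columns) restrict
        the success check to the parameters the instruction sets."""
        stim = self.recommend(instructions)
        produced = responder(stim, instructions)
        req = instructions[REQ_COLS].to_numpy(dtype=float)
        rel_cols = [f"rel{i+1}" for i in range(7)]
        relevant = None
        if all(c in instructions.columns for c in rel_cols):
            relevant = instructions[rel_cols].to_numpy(dtype=float) > 0.5
        return evaluate_success_rate(req, produced, relevant, tol=tol,
                                     mode=mode)
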