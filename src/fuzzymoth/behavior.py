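"""Three-hierarchy Behavior Learner: stimulus -> flight-parameter prediction.

The forward model maps an 80-dimensional input (32 UV-stimulus variables,
34 ambient variables, 7 previous flight parameters, 7 parameters
accumulated over the previous three 200 ms steps) to the seven flight
parameters (horizontal/vertical deflection angle and angular velocity and
the x/y/z accelerations), all normalised to [0, 1].

Learning is divided into three hierarchies, all built from WWO-pretrained
Pythagorean fuzzy denoising autoencoders:

1. a *common* stack (80/46/26) pretrained unsupervised on every moth's
   records — the species-level representation;
2. per-group stacks (26/15/9) pretrained on the common codes of the moths
   in each fuzzy group, with reconstruction errors weighted by the PFCM
   membership degrees (and restricted to memberships above a floor);
3. per-moth stacks (9/6/7) whose input is the membership-weighted mixture
   of the group-stack outputs, topped by a multivariable linear regression
   fitted by least squares.

The regression error is a weighted sum over the seven outputs with fixed
importance weights (0.24, 0.2, 0.2, 0.15, 0.07, 0.07, 0.07) reflecting how
much each parameter matters to the flight path.  The per-dimension linear
fits themselves are weight-independent (the loss decouples per output
dimension); the weights matter for reporting and model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import schema
from .pfcm import PythagoreanFuzzyCMeans
from .pfdae import PFDDAE

__all__ = ["HierarchicalBehaviorLearner", "MonolithicBehaviorLearner",
           "accumulate_history", "build_input_vector", "build_input_matrix",
           "weighted_regression_error", "mix_group_outputs",
           "compute_group_profiles", "OUTPUT_WEIGHTS", "count_fuzzy_params",
           "monolithic_widths_matching"]

#: importance of each flight parameter in the regression loss
OUTPUT_WEIGHTS = np.array([0.24, 0.2, 0.2, 0.15, 0.07, 0.07, 0.07])

HISTORY_DECAY = 0.5
HISTORY_STEPS = 3


def accumulate_history(past_params, decay: float = HISTORY_DECAY) -> np.ndarray:
    """Exponentially weighted accumulation of up to three past steps
    (most recent first), normalised over the steps available; an empty
    history yields the zero vector."""
    past = [np.asarray(p, dtype=float) for p in past_params[:HISTORY_STEPS]]
    if not past:
        return np.zeros(schema.N_FLIGHT)
    w = np.array([decay**i for i in range(len(past))])
    return np.tensordot(w / w.sum(), np.stack(past), axes=1)


def build_input_vector(record: pd.Series | dict) -> np.ndarray:
    """Normalised 80-dim model input from one record row: stimulus, ambient
    (wind re-scaled by its 1.5 m/s cap, over-cap rejected), previous and
    accumulated flight parameters."""
    get = record.__getitem__
    stim = np.array([get(c) for c in schema.STIM_COLS], dtype=float)
    amb = np.array([get(c) for c in schema.AMB_COLS], dtype=float)
    prev = np.array([get(c) for c in schema.PREV_COLS], dtype=float)
    accum = np.array([get(c) for c in schema.ACCUM_COLS], dtype=float)
    x = np.concatenate([stim, schema.normalize_ambient(amb), prev, accum])
    if x.shape[0] != schema.N_FEATURES:
        raise ValueError("malformed record")
    if np.any((x < -1e-9) | (x > 1 + 1e-9)):
        raise ValueError("record feature outside [0, 1] after normalization")
    return np.clip(x, 0.0, 1.0)


def build_input_matrix(records: pd.DataFrame) -> np.ndarray:
    """Vectorised :func:`build_input_vector` over a record table."""
    stim = records[schema.STIM_COLS].to_numpy(dtype=float)
    amb = schema.normalize_ambient(records[schema.AMB_COLS].to_numpy(dtype=float))
    prev = records[schema.PREV_COLS].to_numpy(dtype=float)
    accum = records[schema.ACCUM_COLS].to_numpy(dtype=float)
    X = np.hstack([stim, amb, prev, accum])
    if np.any((X < -1e-9) | (X > 1 + 1e-9)):
        raise ValueError("record feature outside [0, 1] after normalization")
    return np.clip(X, 0.0, 1.0)


def weighted_regression_error(pred: np.ndarray, actual: np.ndarray,
                              w: np.ndarray | None = None) -> float:
    """Importance-weighted squared regression error
    ``sum_d w_d (y_d - yhat_d)^2``, averaged over rows when given a batch."""
    w = OUTPUT_WEIGHTS if w is None else np.asarray(w, dtype=float)
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    actual = np.atleast_2d(np.asarray(actual, dtype=float))
    if pred.shape != actual.shape or pred.shape[1] != w.shape[0]:
        raise ValueError("prediction/target length mismatch")
    return float(np.mean((pred - actual) ** 2 @ w))


def mix_group_outputs(u_col: np.ndarray, group_outputs: np.ndarray,
                      u_floor: float = 0.1, renormalize: bool = False) -> np.ndarray:
    """Membership-weighted mixture of group-stack outputs feeding an
    individual learner: ``x_d = sum_i u_i y'_d(i)`` over the groups whose
    membership clears the floor."""
    u = np.asarray(u_col, dtype=float)
    Y = np.asarray(group_outputs, dtype=float)   # (c, ..., D'')
    keep = u > u_floor
    if not keep.any():
        raise ValueError("no group membership above the floor")
    u_eff = np.where(keep, u, 0.0)
    if renormalize:
        u_eff = u_eff / u_eff.sum()
    return np.tensordot(u_eff, Y, axes=(0, 0))


def compute_group_profiles(common: PFDDAE, shapes: np.ndarray,
                           probe_resp: np.ndarray,
                           probe_amb: np.ndarray,
                           probe_stim: np.ndarray) -> np.ndarray:
    """Per-moth grouping profile: shape descriptors concatenated with the
    topmost-common representations of the moth's responses to the 3 x 12
    probe settings.

    Shape descriptors are min-max normalised per column (they live on their
    own scales).  Probe-code columns are range-normalised with the divisor
    floored at a quarter of the largest column range: columns carrying real
    between-moth signal are equalised, while noise-only columns (tiny
    range) are not blown up to full scale — either extreme (pure per-column
    or one shared factor) lets noise or an unlucky code projection swamp a
    group separation.
    """
    n_moths = probe_resp.shape[0]
    n_probe = probe_amb.shape[0] * probe_stim.shape[0]
    if probe_resp.shape[1] != n_probe:
        raise ValueError("probe responses do not match the probe grid")
    ctx = np.array([np.concatenate([s, a]) for a in probe_amb
                    for s in probe_stim])          # (36, 66)
    profs = []
    for mi in range(n_moths):
        resp = probe_resp[mi]                      # (36, 7)
        X = np.hstack([ctx, resp, resp])           # stim | amb | prev | accum
        codes = common.transform(X)                # (36, top)
        profs.append(np.concatenate([np.asarray(shapes[mi], dtype=float),
                                     codes.ravel()]))
    P = np.array(profs)
    n_shape = np.asarray(shapes).shape[1]
    S, C = P[:, :n_shape], P[:, n_shape:]
    lo, hi = S.min(axis=0), S.max(axis=0)
    span = np.where(hi - lo > 1e-12, hi - lo, 1.0)
    S = (S - lo) / span
    crange = np.ptp(C, axis=0)
    span_c = np.maximum(crange, 0.25 * crange.max()) if crange.max() > 1e-12 \
        else np.ones_like(crange)
    C = (C - C.min(axis=0)) / span_c
    return np.hstack([S, C])


class _MinMax01:
    """Per-column min-max rescaling to [0, 1] (fitted on training data,
    clipped at transform time).  Each sub-learner's affine map assumes
    inputs spanning [0, 1]; topmost representations concentrate in a narrow
    band, so they are rescaled at every hierarchy boundary."""

    def fit(self, X: np.ndarray) -> "_MinMax01":
        self.lo_ = X.min(axis=0)
        span = X.max(axis=0) - self.lo_
        self.span_ = np.where(span > 1e-12, span, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.clip((X - self.lo_) / self.span_, 0.0, 1.0)


def _fit_mlr(Z: np.ndarray, Y: np.ndarray, ridge: float = 1e-6):
    """Per-dimension least squares with intercept; ridge fallback when the
    design is rank deficient."""
    A = np.hstack([Z, np.ones((Z.shape[0], 1))])
    coef, _, rank, _ = np.linalg.lstsq(A, Y, rcond=None)
    if rank < A.shape[1]:
        G = A.T @ A + ridge * np.eye(A.shape[1])
        coef = np.linalg.solve(G, A.T @ Y)
    return coef[:-1], coef[-1]


class HierarchicalBehaviorLearner(RegressorMixin, BaseEstimator):
    """Common / group-specific / individual-specific behavior model.

    ``fit`` expects a record table (see :mod:`fuzzymoth.schema`) plus the
    cohort's per-moth shape descriptors and probe responses (used to build
    the grouping profiles).  ``predict`` returns the seven flight
    parameters for each record row, clipped to [0, 1].

    Notable fitted attributes: ``common_`` (species stack), ``grouper_``
    (PFCM model over moth profiles), ``memberships_`` (c x n_moths),
    ``group_stacks_``, ``individual_`` (per-moth stack + regression head)
    and ``training_errors_`` (per-moth weighted regression error).
    """

    def __init__(self, n_groups=3, common_widths=(80, 46, 26),
                 group_widths=(26, 15, 9), individual_widths=(9, 6, 7),
                 u_floor=0.1, noise_level=0.2, budget_common=600,
                 budget_group=300, budget_individual=200,
                 cluster_init="wwo", cluster_budget=150,
                 max_train_samples=256, renormalize_mix=False,
                 output_weights=None, random_state=None):
        self.n_groups = n_groups
        self.common_widths = common_widths
        self.group_widths = group_widths
        self.individual_widths = individual_widths
        self.u_floor = u_floor
        self.noise_level = noise_level
        self.budget_common = budget_common
        self.budget_group = budget_group
        self.budget_individual = budget_individual
        self.cluster_init = cluster_init
        self.cluster_budget = cluster_budget
        self.max_train_samples = max_train_samples
        self.renormalize_mix = renormalize_mix
        self.output_weights = output_weights
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------

    def _weights(self) -> np.ndarray:
        return OUTPUT_WEIGHTS if self.output_weights is None \
            else np.asarray(self.output_weights, dtype=float)

    def _mix_inputs(self, codes_s: np.ndarray, u_col: np.ndarray) -> np.ndarray:
        outs = np.stack([gs.transform(codes_s) for gs in self.group_stacks_])
        return mix_group_outputs(u_col, outs, self.u_floor,
                                 self.renormalize_mix)

    # -- estimator API -----------------------------------------------------

    def fit(self, records: pd.DataFrame, y=None, shapes=None,
            probe_resp=None, probe_amb=None, probe_stim=None):
        rng = np.random.default_rng(self.random_state)
        X = build_input_matrix(records)
        Y = records[schema.TARGET_COLS].to_numpy(dtype=float)
        ids = records["id"].to_numpy()
        self.moth_ids_ = np.unique(ids)
        n_moths = self.moth_ids_.size

        # 1. species-common stack
        self.common_ = PFDDAE(
            layer_widths=self.common_widths, noise_level=self.noise_level,
            budget=self.budget_common, max_train_samples=self.max_train_samples,
            random_state=int(rng.integers(2**31))).fit(X)
        codes = self.common_.transform(X)
        self.code_scaler_ = _MinMax01().fit(codes)
        codes = self.code_scaler_.transform(codes)

        # 2. grouping on probe profiles
        if shapes is None:
            shapes = np.zeros((n_moths, 3))
        if probe_resp is None:
            raise ValueError("probe responses are required to group moths")
        profiles = compute_group_profiles(self.common_, shapes, probe_resp,
                                          probe_amb, probe_stim)
        self.profiles_ = profiles
        self.grouper_ = PythagoreanFuzzyCMeans(
            n_clusters=self.n_groups, init=self.cluster_init,
            wwo_budget=self.cluster_budget,
            random_state=int(rng.integers(2**31))).fit(profiles)
        self.memberships_ = self.grouper_.membership_matrix_   # (c, n_moths)
        col = {mid: j for j, mid in enumerate(self.moth_ids_)}
        u_rec = self.memberships_[:, [col[i] for i in ids]]    # (c, n_rec)

        # 3. group-specific stacks (membership-weighted, floored)
        self.group_stacks_ = []
        for i in range(self.n_groups):
            sel = u_rec[i] > self.u_floor
            if not sel.any():
                raise ValueError(f"group {i} has no training records above "
                                 f"u_floor={self.u_floor}")
            gs = PFDDAE(
                layer_widths=self.group_widths, noise_level=self.noise_level,
                budget=self.budget_group,
                max_train_samples=self.max_train_samples,
                random_state=int(rng.integers(2**31)))
            gs.fit(codes[sel], sample_weight=u_rec[i][sel])
            self.group_stacks_.append(gs)

        # 4. individual stacks + MLR heads
        mixed_all = np.empty((X.shape[0], self.group_widths[-1]))
        for mid in self.moth_ids_:
            sel = ids == mid
            mixed_all[sel] = self._mix_inputs(codes[sel],
                                              self.memberships_[:, col[mid]])
        self.mix_scaler_ = _MinMax01().fit(mixed_all)
        mixed_all = self.mix_scaler_.transform(mixed_all)
        self.individual_ = {}
        self.training_errors_ = {}
        w = self._weights()
        for mid in self.moth_ids_:
            sel = ids == mid
            mixed = mixed_all[sel]
            st = PFDDAE(
                layer_widths=self.individual_widths,
                noise_level=self.noise_level, budget=self.budget_individual,
                max_train_samples=self.max_train_samples,
                random_state=int(rng.integers(2**31))).fit(mixed)
            Z = st.transform(mixed)
            coef, intercept = _fit_mlr(Z, Y[sel])
            pred = np.clip(Z @ coef + intercept, 0.0, 1.0)
            self.individual_[mid] = (st, coef, intercept)
            self.training_errors_[mid] = weighted_regression_error(
                pred, Y[sel], w)
        self._moth_col = col
        return self

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "individual_")
        X = build_input_matrix(records)
        ids = records["id"].to_numpy()
        unknown = set(ids) - set(self.moth_ids_.tolist())
        if unknown:
            raise ValueError(f"unknown moth id(s): {sorted(unknown)}")
        codes = self.code_scaler_.transform(self.common_.transform(X))
        out = np.empty((X.shape[0], schema.N_FLIGHT))
        for mid in np.unique(ids):
            sel = ids == mid
            mixed = self.mix_scaler_.transform(self._mix_inputs(
                codes[sel], self.memberships_[:, self._moth_col[mid]]))
            st, coef, intercept = self.individual_[mid]
            Z = st.transform(mixed)
            out[sel] = np.clip(Z @ coef + intercept, 0.0, 1.0)
        return out

    def score_records(self, records: pd.DataFrame) -> float:
        """Importance-weighted regression error on a record table."""
        Y = records[schema.TARGET_COLS].to_numpy(dtype=float)
        return weighted_regression_error(self.predict(records), Y,
                                         self._weights())


class MonolithicBehaviorLearner(RegressorMixin, BaseEstimator):
    """Non-hierarchical comparator: a single PFDDAE over all moths' records
    with one shared regression head (no grouping, no per-moth models)."""

    def __init__(self, widths=(80, 55, 30, 12), noise_level=0.2, budget=1100,
                 max_train_samples=256, output_weights=None, random_state=None):
        self.widths = widths
        self.noise_level = noise_level
        self.budget = budget
        self.max_train_samples = max_train_samples
        self.output_weights = output_weights
        self.random_state = random_state

    def fit(self, records: pd.DataFrame, y=None):
        X = build_input_matrix(records)
        Y = records[schema.TARGET_COLS].to_numpy(dtype=float)
        self.stack_ = PFDDAE(
            layer_widths=self.widths, noise_level=self.noise_level,
            budget=self.budget, max_train_samples=self.max_train_samples,
            random_state=self.random_state).fit(X)
        Z = self.stack_.transform(X)
        self.coef_, self.intercept_ = _fit_mlr(Z, Y)
        return self

    def predict(self, records: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "stack_")
        Z = self.stack_.transform(build_input_matrix(records))
        return np.clip(Z @ self.coef_ + self.intercept_, 0.0, 1.0)

    def score_records(self, records: pd.DataFrame) -> float:
        Y = records[schema.TARGET_COLS].to_numpy(dtype=float)
        w = OUTPUT_WEIGHTS if self.output_weights is None \
            else np.asarray(self.output_weights, dtype=float)
        return weighted_regression_error(self.predict(records), Y, w)


def count_fuzzy_params(widths) -> int:
    """Number of PFN parameters (W, b, b') in a stack of the given widths."""
    return sum(o * i + o + i for i, o in zip(widths[:-1], widths[1:]))


def monolithic_widths_matching(n_groups: int, n_moths: int,
                               common=(80, 46, 26), group=(26, 15, 9),
                               individual=(9, 6, 7)) -> tuple[int, ...]:
    """Widths ``(80, h, ~0.57h, 12)`` for a monolithic stack whose total PFN
    parameter count is closest to the full hierarchy's."""
    target = (count_fuzzy_params(common) + n_groups * count_fuzzy_params(group)
              + n_moths * count_fuzzy_params(individual))
    best, best_gap = None, None
    for h in range(12, 80):
        widths = (80, h, max(8, int(0.57 * h)), 12)
        gap = abs(count_fuzzy_params(widths) - target)
        if best_gap is None or gap < best_gap:
            best, best_gap = widths, gap
    return best
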