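"""Pythagorean fuzzy denoising autoencoder (PFDAE) layers and the stacked
deep model (PFDDAE) with WWO layer-wise unsupervised pretraining.

A fuzzy layer is the classic DAE affine map ``s(Wx + b)`` with every weight
and bias an interval-valued PFN.  Multiplication of a crisp input by a fuzzy
weight uses the Pythagorean scalar law and the sum over inputs uses the
algebraic sum, so an encoder unit computes::

    y_i = activate( (+)_d  x_d (*) W_id  (+)  b_i )

Both laws are products in ``log(1 - mu^2)`` / ``log(nu)`` space, so a whole
layer forward pass reduces to four matrix multiplications (one per interval
bound of each degree channel).  The decoder reuses the transposed weights on
the defuzzified (centroid-membership) hidden vector and the reconstruction
error is the crisp-vs-fuzzy RMS distance.

Training is derivative-free: a layer's parameters are encoded as a genome in
the unit box (valid PFNs by construction) and searched by WWO to minimise
the mean squared reconstruction error of corrupted inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import pfn as pf
from . import wwo

__all__ = ["FuzzyLayer", "PFDDAE", "corrupt", "encode", "decode",
           "layer_loss", "pretrain_stack", "encode_topmost",
           "genome_length", "genome_to_params", "train_layer"]

_LOG_FLOOR = 1e-300


@dataclass
class FuzzyLayer:
    """One fuzzy DAE layer: ``W`` is ``(d_out, d_in, 4)``, ``b`` is
    ``(d_out, 4)``, ``b_prime`` (decoder bias) is ``(d_in, 4)``; all PFNs."""

    W: np.ndarray
    b: np.ndarray
    b_prime: np.ndarray

    @property
    def d_in(self) -> int:
        return self.W.shape[1]

    @property
    def d_out(self) -> int:
        return self.W.shape[0]


def corrupt(X: np.ndarray, noise_level: float, rng: np.random.Generator) -> np.ndarray:
    """Masking corruption: each coordinate is independently zeroed with
    probability ``noise_level``."""
    X = np.asarray(X, dtype=float)
    if not 0.0 <= noise_level <= 1.0:
        raise ValueError("noise_level must be in [0, 1]")
    if noise_level == 0.0:
        return X.copy()
    mask = rng.random(X.shape) >= noise_level
    return X * mask


def _affine(X: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Fuzzy affine map ``(+)_d x_d (*) W[:, d] (+) b`` for a crisp batch
    ``X`` of shape ``(n, d_in)``; returns activated PFNs ``(n, d_out, 4)``."""
    log_one_m_mu2 = np.log(np.maximum(1.0 - W[..., 0:2] ** 2, _LOG_FLOOR))
    log_nu = np.log(np.maximum(W[..., 2:4], _LOG_FLOOR))
    b_mu = np.log(np.maximum(1.0 - b[..., 0:2] ** 2, _LOG_FLOOR))
    b_nu = np.log(np.maximum(b[..., 2:4], _LOG_FLOOR))
    out = np.empty((X.shape[0], W.shape[0], 4))
    for ch in range(2):  # interval bounds lo, hi
        s_mu = X @ log_one_m_mu2[..., ch].T + b_mu[:, ch]
        s_nu = X @ log_nu[..., ch].T + b_nu[:, ch]
        out[..., ch] = np.sqrt(np.clip(1.0 - np.exp(s_mu), 0.0, 1.0))
        out[..., 2 + ch] = np.exp(s_nu)
    return pf.arr_activate(out)


def encode(layer: FuzzyLayer, X: np.ndarray) -> np.ndarray:
    """Encode a crisp batch ``(n, d_in)`` into PFN codes ``(n, d_out, 4)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != layer.d_in:
        raise ValueError(f"expected {layer.d_in} inputs, got {X.shape[1]}")
    return _affine(X, layer.W, layer.b)


def defuzz_mu(Y: np.ndarray) -> np.ndarray:
    """Centroid membership channel of a PFN batch — the crisp hidden code."""
    return 0.5 * (Y[..., 0] + Y[..., 1])


def decode(layer: FuzzyLayer, Y: np.ndarray) -> np.ndarray:
    """Decode PFN codes back to fuzzy reconstructions ``(n, d_in, 4)`` using
    the transposed weights on the defuzzified hidden activations."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[-2] != layer.d_out:
        raise ValueError(f"expected {layer.d_out} hidden units, got {Y.shape[-2]}")
    H = np.atleast_2d(defuzz_mu(Y))
    return _affine(H, np.swapaxes(layer.W, 0, 1), layer.b_prime)


def layer_loss(layer: FuzzyLayer, X: np.ndarray, noise_level: float = 0.0,
               rng: np.random.Generator | None = None,
               variant: str = "half_mu") -> float:
    """Mean squared fuzzy reconstruction error of ``X`` (corrupted at
    ``noise_level``) through one encode/decode pass."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("empty training data")
    Xc = corrupt(X, noise_level, rng or np.random.default_rng(0))
    recon = decode(layer, encode(layer, Xc))
    d2 = pf.arr_crisp_distance_sq(X, recon, variant)   # (n, d_in)
    return float(np.mean(np.mean(d2, axis=1)))


# ---------------------------------------------------------------------------
# genome <-> parameters
# ---------------------------------------------------------------------------

def genome_length(d_in: int, d_out: int) -> int:
    return 4 * (d_out * d_in + d_out + d_in)


def _genes_to_pfn(G: np.ndarray, fan_in: float = 1.0) -> np.ndarray:
    """Map genes ``(..., 4)`` in the unit box to valid PFNs.

    The base map is ``mu_hi = g2``, ``mu_lo = g1*mu_hi``,
    ``nu_hi = g3*sqrt(1-mu_hi^2)``, ``nu_lo = g4*nu_hi``.  For weight
    matrices the membership magnitude is tempered by the layer fan-in —
    ``log(1-mu^2)`` scales as ``1/fan_in`` and ``log(nu)`` likewise — so
    that the algebraic-sum products over ``fan_in`` inputs stay in the
    responsive range instead of saturating at ``mu -> 1``, ``nu -> 0``.
    """
    out = np.empty_like(G)
    g2 = np.clip(G[..., 1], 0.0, 1.0 - 1e-12)
    if fan_in > 1:
        mu_hi = np.sqrt(1.0 - (1.0 - g2**2) ** (1.0 / fan_in))
        nu_cap = np.sqrt(np.clip(1.0 - mu_hi**2, 0.0, 1.0))
        nu_hi = np.clip(G[..., 2], 1e-12, 1.0) ** (1.0 / fan_in) * nu_cap
    else:
        mu_hi = g2
        nu_hi = G[..., 2] * np.sqrt(np.clip(1.0 - g2**2, 0.0, 1.0))
    out[..., 1] = mu_hi
    out[..., 0] = G[..., 0] * mu_hi
    out[..., 3] = nu_hi
    out[..., 2] = G[..., 3] * nu_hi
    return out


def genome_to_params(genome: np.ndarray, d_in: int, d_out: int) -> FuzzyLayer:
    """Decode a flat genome in ``[0,1]^(4P)`` into a valid fuzzy layer.
    Weight genes are tempered by the fan-in (see :func:`_genes_to_pfn`);
    bias genes are not (each bias enters one product once)."""
    P = d_out * d_in + d_out + d_in
    G = np.asarray(genome, dtype=float).reshape(P, 4)
    W = _genes_to_pfn(G[: d_out * d_in], fan_in=d_in).reshape(d_out, d_in, 4)
    b = _genes_to_pfn(G[d_out * d_in: d_out * d_in + d_out])
    b_prime = _genes_to_pfn(G[d_out * d_in + d_out:])
    return FuzzyLayer(W, b, b_prime)


def train_layer(X: np.ndarray, d_out: int, budget: int,
                noise_level: float, rng: np.random.Generator,
                population: int = 8, patience: int | None = None,
                variant: str = "half_mu", n_corruptions: int = 3,
                sample_weight: np.ndarray | None = None) -> tuple[FuzzyLayer, list]:
    """WWO-pretrain one fuzzy layer on ``X``; returns the layer and the
    best-so-far loss trace.  ``n_corruptions`` independently corrupted
    copies of ``X`` are drawn once up front (so the objective stays
    deterministic within the run) and reconstructed against the clean data,
    approximating the expectation over the corruption distribution."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d_in = X.shape[1]
    w = None
    if sample_weight is not None:
        w = np.asarray(sample_weight, dtype=float)[:, None]
    if noise_level > 0.0 and n_corruptions > 1:
        Xc = np.vstack([corrupt(X, noise_level, rng)
                        for _ in range(n_corruptions)])
        X = np.tile(X, (n_corruptions, 1))
        if w is not None:
            w = np.tile(w, (n_corruptions, 1))
    else:
        Xc = corrupt(X, noise_level, rng)

    def objective(genome: np.ndarray) -> float:
        layer = genome_to_params(genome, d_in, d_out)
        recon = decode(layer, encode(layer, Xc))
        d2 = pf.arr_crisp_distance_sq(X, recon, variant)
        if w is not None:
            return float(np.mean(w * d2))
        return float(np.mean(d2))

    space = wwo.SearchSpace.unit(genome_length(d_in, d_out))
    cfg = wwo.OptimizerConfig(budget=budget, population=population,
                              patience=patience)
    res = wwo.optimize(objective, space, cfg, rng)
    return genome_to_params(res.x, d_in, d_out), res.trace


# ---------------------------------------------------------------------------
# stacked model
# ---------------------------------------------------------------------------

class PFDDAE(TransformerMixin, BaseEstimator):
    """Stacked Pythagorean fuzzy denoising autoencoder.

    ``fit`` performs greedy layer-wise unsupervised pretraining: each layer
    is trained by WWO to reconstruct (a corrupted copy of) its input, then
    its defuzzified hidden codes become the next layer's crisp training
    data.  ``transform`` returns the defuzzified topmost representation.

    Parameters
    ----------
    layer_widths : sequence of int
        Unit counts from the input layer upward, e.g. ``(80, 46, 26)``.
    noise_level : float
        Masking-corruption probability used during pretraining.
    budget : int
        Total WWO objective-evaluation budget, split equally across layers.
    max_train_samples : int or None
        If set, each layer's WWO objective is evaluated on a fixed seeded
        subsample of at most this many rows (the greedy forward pass still
        uses all rows).
    """

    def __init__(self, layer_widths=(80, 46, 26), noise_level=0.2,
                 budget=2000, population=8, max_train_samples=512,
                 patience=None, distance_variant="half_mu", random_state=None):
        self.layer_widths = layer_widths
        self.noise_level = noise_level
        self.budget = budget
        self.population = population
        self.max_train_samples = max_train_samples
        self.patience = patience
        self.distance_variant = distance_variant
        self.random_state = random_state

    def _validate(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.layer_widths[0]:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.layer_widths[0]}")
        if np.any((X < -1e-9) | (X > 1 + 1e-9)):
            raise ValueError("inputs must lie in [0, 1]")
        return np.clip(X, 0.0, 1.0)

    def fit(self, X, y=None, sample_weight=None):
        X = self._validate(X)
        rng = np.random.default_rng(self.random_state)
        n_layers = len(self.layer_widths) - 1
        if n_layers < 1:
            raise ValueError("need at least two widths (input and one hidden)")
        per_layer = self.budget // n_layers
        if per_layer < self.population:
            raise ValueError("budget too small for the number of layers")
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=float)
        self.layers_, self.loss_traces_ = [], []
        data = X
        for d_out in self.layer_widths[1:]:
            if self.max_train_samples and data.shape[0] > self.max_train_samples:
                idx = rng.choice(data.shape[0], self.max_train_samples,
                                 replace=False)
                train = data[idx]
                sw = None if sample_weight is None else sample_weight[idx]
            else:
                train = data
                sw = sample_weight
            layer, trace = train_layer(
                train, d_out, per_layer, self.noise_level, rng,
                population=self.population, patience=self.patience,
                variant=self.distance_variant, sample_weight=sw)
            self.layers_.append(layer)
            self.loss_traces_.append(trace)
            data = defuzz_mu(encode(layer, data))
        self.final_losses_ = [t[-1][1] for t in self.loss_traces_]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        """Defuzzified topmost hidden representation, in ``[0,1]^top``."""
        check_is_fitted(self, "layers_")
        data = self._validate(X)
        for layer in self.layers_:
            data = defuzz_mu(encode(layer, data))
        return data

    def reconstruction_error(self, X, noise_level: float = 0.0,
                             rng: np.random.Generator | None = None,
                             n_draws: int = 1) -> float:
        """Mean squared fuzzy reconstruction error of the whole stack:
        encode to the top (optionally corrupting the input first), then
        decode back down; the final fuzzy output is compared with the clean
        input.  With ``noise_level > 0`` the error is averaged over
        ``n_draws`` independent corruption draws."""
        check_is_fitted(self, "layers_")
        X = self._validate(X)
        rng = rng or np.random.default_rng(0)
        total = 0.0
        for _ in range(n_draws if noise_level > 0 else 1):
            data = corrupt(X, noise_level, rng)
            for layer in self.layers_:
                data = defuzz_mu(encode(layer, data))
            for layer in reversed(self.layers_):
                fuzzy = decode(layer, pf.arr_fuzzify(data))
                data = defuzz_mu(fuzzy)
            d2 = pf.arr_crisp_distance_sq(X, fuzzy, self.distance_variant)
            total += float(np.mean(d2))
        return total / (n_draws if noise_level > 0 else 1)

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        check_is_fitted(self, "layers_")
        payload = {
            "layer_widths": list(self.layer_widths),
            "noise_level": self.noise_level,
            "distance_variant": self.distance_variant,
            "layers": [{"W": l.W.tolist(), "b": l.b.tolist(),
                        "b_prime": l.b_prime.tolist()} for l in self.layers_],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "PFDDAE":
        payload = json.loads(text)
        model = cls(layer_widths=tuple(payload["layer_widths"]),
                    noise_level=payload["noise_level"],
                    distance_variant=payload["distance_variant"])
        model.layers_ = [FuzzyLayer(np.array(l["W"]), np.array(l["b"]),
                                    np.array(l["b_prime"]))
                         for l in payload["layers"]]
        model.loss_traces_ = []
        model.n_features_in_ = model.layer_widths[0]
        return model


def pretrain_stack(X, layer_widths, budget, noise_level=0.2,
                   random_state=None, **kwargs) -> PFDDAE:
    """Functional wrapper: pretrain and return a :class:`PFDDAE`."""
    return PFDDAE(layer_widths=layer_widths, budget=budget,
                  noise_level=noise_level, random_state=random_state,
                  **kwargs).fit(X)


def encode_topmost(stack: PFDDAE, X) -> np.ndarray:
    """Defuzzified topmost representation (wrapper over ``transform``)."""
    return stack.transform(X)
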