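"""Interval-valued Pythagorean fuzzy numbers (PFNs): algebra, defuzzification
and distance measures.

A Pythagorean fuzzy number carries a membership degree ``mu`` and a
non-membership degree ``nu`` constrained by ``mu**2 + nu**2 <= 1``; the
residual ``pi = sqrt(1 - mu**2 - nu**2)`` is the hesitancy.  The
interval-valued variant replaces each degree by an interval, and the
Pythagorean constraint is enforced at the upper bounds (which makes it hold
over the whole interval box).

Every operation is available in two forms: a scalar API built on the
:class:`PFN` dataclass, and a vectorised API acting on ``(..., 4)`` float
arrays whose last axis is ``(mu_lo, mu_hi, nu_lo, nu_hi)``.  The vectorised
form is what the fuzzy network layers use; the scalar form delegates to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PFN",
    "Centroid",
    "make_pfn",
    "project_valid",
    "fuzzify",
    "centroid",
    "crisp_distance",
    "crisp_fuzzy_vector_distance",
    "pfn_distance",
    "pfn_vector_distance",
    "pfn_add",
    "pfn_scale",
    "activate",
    "arr_centroid",
    "arr_fuzzify",
    "arr_project_valid",
    "arr_add",
    "arr_scale",
    "arr_activate",
    "arr_pfn_distance",
    "arr_crisp_distance_sq",
    "is_valid_arr",
]

#: absolute slack for floating-point constraint checks
_TOL = 1e-12

#: smallest positive value fed to ``log`` (log-space layer arithmetic)
_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class PFN:
    """An interval-valued Pythagorean fuzzy number.

    Parameters are the interval bounds of the membership degree
    (``mu_lo <= mu_hi``) and of the non-membership degree
    (``nu_lo <= nu_hi``), all in ``[0, 1]``, with
    ``mu_hi**2 + nu_hi**2 <= 1``.
    """

    mu_lo: float
    mu_hi: float
    nu_lo: float
    nu_hi: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mu_lo, self.mu_hi, self.nu_lo, self.nu_hi])

    @property
    def pi_lo(self) -> float:
        """Hesitancy at the upper corner of the interval box (smallest pi)."""
        return float(np.sqrt(max(0.0, 1.0 - self.mu_hi**2 - self.nu_hi**2)))

    @property
    def pi_hi(self) -> float:
        """Hesitancy at the lower corner of the interval box (largest pi)."""
        return float(np.sqrt(max(0.0, 1.0 - self.mu_lo**2 - self.nu_lo**2)))


@dataclass(frozen=True)
class Centroid:
    """Crisp centroid ``(c_mu, c_nu)`` of a PFN."""

    c_mu: float
    c_nu: float


def make_pfn(mu_lo: float, mu_hi: float, nu_lo: float, nu_hi: float) -> PFN:
    """Construct a validated PFN, raising ``ValueError`` naming the violated
    invariant (bound range, ordering, or the Pythagorean squared-sum)."""
    for name, v in (("mu_lo", mu_lo), ("mu_hi", mu_hi),
                    ("nu_lo", nu_lo), ("nu_hi", nu_hi)):
        if not (-_TOL <= v <= 1.0 + _TOL):
            raise ValueError(f"{name}={v} outside [0, 1]")
    if mu_lo > mu_hi + _TOL:
        raise ValueError(f"ordering violated: mu_lo={mu_lo} > mu_hi={mu_hi}")
    if nu_lo > nu_hi + _TOL:
        raise ValueError(f"ordering violated: nu_lo={nu_lo} > nu_hi={nu_hi}")
    ss = mu_hi**2 + nu_hi**2
    if ss > 1.0 + _TOL:
        raise ValueError(
            f"Pythagorean constraint violated: mu_hi^2 + nu_hi^2 = {ss} > 1")
    return PFN(float(mu_lo), float(mu_hi), float(nu_lo), float(nu_hi))


def _pfn(a: np.ndarray) -> PFN:
    return PFN(*(float(v) for v in a))


# ---------------------------------------------------------------------------
# vectorised core
# ---------------------------------------------------------------------------

def is_valid_arr(p: np.ndarray, tol: float = _TOL) -> np.ndarray:
    """Boolean mask of PFN-invariant satisfaction over the leading axes."""
    p = np.asarray(p, dtype=float)
    in_range = ((p >= -tol) & (p <= 1.0 + tol)).all(axis=-1)
    ordered = (p[..., 0] <= p[..., 1] + tol) & (p[..., 2] <= p[..., 3] + tol)
    pyth = p[..., 1] ** 2 + p[..., 3] ** 2 <= 1.0 + tol
    return in_range & ordered & pyth


def arr_project_valid(p: np.ndarray) -> np.ndarray:
    """Restore PFN invariants: clip to [0,1], sort each interval, then
    radially rescale ``(mu_hi, nu_hi)`` onto the unit circle where the
    squared sum exceeds 1 (lower bounds clipped to stay below the upper
    bounds).  Idempotent."""
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0).copy()
    mu = np.sort(p[..., 0:2], axis=-1)
    nu = np.sort(p[..., 2:4], axis=-1)
    ss = mu[..., 1] ** 2 + nu[..., 1] ** 2
    scale = np.where(ss > 1.0, 1.0 / np.sqrt(np.maximum(ss, _LOG_FLOOR)), 1.0)
    mu = np.minimum(mu, (mu[..., 1] * scale)[..., None])
    nu = np.minimum(nu, (nu[..., 1] * scale)[..., None])
    return np.concatenate([mu, nu], axis=-1)


def arr_fuzzify(x: np.ndarray) -> np.ndarray:
    """Map crisp values in [0,1] to degenerate-interval PFNs with
    ``mu = x``, ``nu = 1 - x`` (always Pythagorean-valid)."""
    x = np.asarray(x, dtype=float)
    if np.any((x < -_TOL) | (x > 1.0 + _TOL)):
        raise ValueError("fuzzify input outside [0, 1]")
    x = np.clip(x, 0.0, 1.0)
    return np.stack([x, x, 1.0 - x, 1.0 - x], axis=-1)


def arr_centroid(p: np.ndarray) -> np.ndarray:
    """Centroid ``(c_mu, c_nu)``: midpoint of each interval under the
    uniform-density reading of the ratio-of-integrals centroid."""
    p = np.asarray(p, dtype=float)
    c_mu = 0.5 * (p[..., 0] + p[..., 1])
    c_nu = 0.5 * (p[..., 2] + p[..., 3])
    return np.stack([c_mu, c_nu], axis=-1)


def _pi_sq(mu: np.ndarray, nu: np.ndarray) -> np.ndarray:
    return np.maximum(0.0, 1.0 - mu**2 - nu**2)


def arr_pfn_distance(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Pythagorean distance between PFNs evaluated at their centroids:
    Euclidean distance in ``(mu^2, nu^2, pi^2)`` space scaled by 1/sqrt(2);
    always in [0, 1]."""
    c1, c2 = arr_centroid(p1), arr_centroid(p2)
    m1, n1 = c1[..., 0], c1[..., 1]
    m2, n2 = c2[..., 0], c2[..., 1]
    d2 = ((m1**2 - m2**2) ** 2 + (n1**2 - n2**2) ** 2
          + (_pi_sq(m1, n1) - _pi_sq(m2, n2)) ** 2) / 2.0
    return np.sqrt(d2)


def arr_crisp_distance_sq(alpha: np.ndarray, p: np.ndarray,
                          variant: str = "half_mu") -> np.ndarray:
    """Squared distance between a crisp value and a PFN via its centroid.

    ``variant="half_mu"`` (default): ``(c_mu - alpha)^2 / 2 + c_nu^2``.
    ``variant="half_both"``: ``((c_mu - alpha)^2 + c_nu^2) / 2``.
    """
    c = arr_centroid(p)
    dmu2 = (c[..., 0] - np.asarray(alpha, dtype=float)) ** 2
    if variant == "half_mu":
        return dmu2 / 2.0 + c[..., 1] ** 2
    if variant == "half_both":
        return (dmu2 + c[..., 1] ** 2) / 2.0
    raise ValueError(f"unknown crisp-distance variant {variant!r}")


def arr_add(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Pythagorean algebraic sum, applied bound-wise to the intervals:
    ``mu = sqrt(mu1^2 + mu2^2 - mu1^2 mu2^2)``, ``nu = nu1 * nu2``."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    out = np.empty(np.broadcast_shapes(p1.shape, p2.shape))
    m1s, m2s = p1[..., 0:2] ** 2, p2[..., 0:2] ** 2
    out[..., 0:2] = np.sqrt(np.clip(m1s + m2s - m1s * m2s, 0.0, 1.0))
    out[..., 2:4] = p1[..., 2:4] * p2[..., 2:4]
    return out


def arr_scale(lam: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Scalar multiplication law ``mu = sqrt(1 - (1 - mu^2)**lam)``,
    ``nu = nu**lam`` for ``lam >= 0``, applied bound-wise."""
    lam = np.asarray(lam, dtype=float)[..., None]
    if np.any(lam < 0):
        raise ValueError("scale factor must be non-negative")
    p = np.asarray(p, dtype=float)
    out = np.empty(np.broadcast_shapes(lam.shape[:-1], p.shape[:-1]) + (4,))
    one_m = np.clip(1.0 - p[..., 0:2] ** 2, 0.0, 1.0)
    out[..., 0:2] = np.sqrt(np.clip(1.0 - one_m ** lam, 0.0, 1.0))
    out[..., 2:4] = p[..., 2:4] ** lam
    return out


def arr_activate(p: np.ndarray) -> np.ndarray:
    """Exponential squashing used as the layer activation.

    Applies ``s(t) = exp(t - 1)`` endpoint-wise to the membership bounds
    (fixed point at t = 1, monotone, image in [1/e, 1]) and the dual map
    ``t -> 1 - exp(-t)`` to the non-membership bounds, then projects back
    onto the Pythagorean constraint.
    """
    p = np.asarray(p, dtype=float)
    out = np.empty_like(p)
    out[..., 0:2] = np.exp(p[..., 0:2] - 1.0)
    out[..., 2:4] = 1.0 - np.exp(-p[..., 2:4])
    return arr_project_valid(out)


# ---------------------------------------------------------------------------
# scalar API
# ---------------------------------------------------------------------------

def project_valid(mu_lo: float, mu_hi: float, nu_lo: float, nu_hi: float) -> PFN:
    """Project four arbitrary reals onto the nearest-by-construction valid
    PFN (clip, order, radially rescale the upper corner)."""
    return _pfn(arr_project_valid(np.array([mu_lo, mu_hi, nu_lo, nu_hi])))


def fuzzify(x: float) -> PFN:
    """Degenerate-interval PFN with ``mu = x`` and ``nu = 1 - x``."""
    return _pfn(arr_fuzzify(float(x)))


def centroid(p: PFN) -> Centroid:
    c = arr_centroid(p.as_array())
    return Centroid(float(c[0]), float(c[1]))


def crisp_distance(alpha: float, p: PFN, variant: str = "half_mu") -> float:
    """Distance between a crisp number in [0,1] and a PFN (via centroid)."""
    return float(np.sqrt(arr_crisp_distance_sq(alpha, p.as_array(), variant)))


def crisp_fuzzy_vector_distance(x: np.ndarray, xf: np.ndarray,
                                variant: str = "half_mu") -> float:
    """Root-mean-square crisp-vs-fuzzy reconstruction error of a PFN vector
    ``xf`` (shape ``(D, 4)``) against a crisp vector ``x`` (shape ``(D,)``)."""
    x = np.asarray(x, dtype=float)
    xf = np.asarray(xf, dtype=float)
    if x.shape[0] != xf.shape[0]:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {xf.shape[0]}")
    return float(np.sqrt(np.mean(arr_crisp_distance_sq(x, xf, variant))))


def pfn_distance(p1: PFN, p2: PFN) -> float:
    return float(arr_pfn_distance(p1.as_array(), p2.as_array()))


def pfn_vector_distance(x: np.ndarray, v: np.ndarray) -> float:
    """RMS aggregation of per-coordinate PFN distances between two PFN
    vectors of equal length (shape ``(D, 4)``)."""
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    if x.shape[0] != v.shape[0]:
        raise ValueError(f"length mismatch: {x.shape[0]} vs {v.shape[0]}")
    return float(np.sqrt(np.mean(arr_pfn_distance(x, v) ** 2)))


def pfn_add(p1: PFN, p2: PFN) -> PFN:
    return _pfn(arr_add(p1.as_array(), p2.as_array()))


def pfn_scale(lam: float, p: PFN) -> PFN:
    return _pfn(arr_scale(float(lam), p.as_array()))


def activate(p: PFN) -> PFN:
    return _pfn(arr_activate(p.as_array()))
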