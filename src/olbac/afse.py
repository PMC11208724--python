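"""Adversarial feature-subspace perturbations and the stabilization loss.

A molecular embedding ``f`` is probed with a random Gaussian vector ``r`` of
norm ``ε``; the gradient ``g = ∇_r D(N(f,f), N(f,f+r))`` of the prediction
discrepancy with respect to the probe is rescaled to norm ``η`` to give the
adversarial perturbation ``d = η·g/‖g‖``. The divergence ``D`` is the
squared difference of predictor outputs (logits for classification).

``d`` is a derived optimization clue: it is treated as a constant with
respect to model parameters wherever it is consumed (stabilization loss,
decoder), which is what makes the min–max training stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .encoder import Predictor

__all__ = ["Perturbation", "sample_probe", "adversarial_perturbation",
           "adversarial_perturbation_batch", "afse_loss", "divergence"]

_FLAT_TOL = 1e-12


@dataclass
class Perturbation:
    d: np.ndarray          # (D,) or (M, D); ‖d‖₂ = η per row unless flat
    eta: float
    epsilon: float
    flat: bool             # True when the probe gradient vanished


def divergence(x: Tensor, y: Tensor) -> Tensor:
    """D(x, y) = (x − y)²: symmetric, nonnegative, zero iff equal."""
    return (x - y) ** 2


def sample_probe(dim: int, epsilon: float, rng: np.random.Generator,
                 n: int = 1) -> np.ndarray:
    """Gaussian probe(s) rescaled to exact norm ``ε`` (rows of an (n, dim)
    array)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    r = rng.standard_normal((n, dim))
    norms = np.linalg.norm(r, axis=1, keepdims=True)
    # a zero draw has probability zero; resample defensively
    while np.any(norms < _FLAT_TOL):
        bad = norms[:, 0] < _FLAT_TOL
        r[bad] = rng.standard_normal((bad.sum(), dim))
        norms = np.linalg.norm(r, axis=1, keepdims=True)
    return epsilon * r / norms


def adversarial_perturbation_batch(
    f: np.ndarray,
    predictor: Predictor,
    eta: float,
    epsilon: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Row-wise adversarial perturbations for an (M, D) block of embeddings.

    Each row's gradient is taken at its own probe; rows with a flat probe
    gradient get a zero perturbation. The predictor's parameter gradients
    are cleared afterwards — this pass informs only ``d``.
    """
    f = np.atleast_2d(f)
    r = Tensor(sample_probe(f.shape[1], epsilon, rng, n=f.shape[0]),
               requires_grad=True)
    f_const = Tensor(f)
    loss = divergence(predictor(f_const, f_const), predictor(f_const, f_const + r)).sum()
    if not np.isfinite(loss.data):
        raise FloatingPointError("gradient overflow in adversarial probe")
    loss.backward()
    g = r.grad
    predictor.zero_grad()
    if g is None or not np.all(np.isfinite(g)):
        raise FloatingPointError("gradient overflow in adversarial probe")
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    d = np.zeros_like(g)
    ok = norms[:, 0] >= _FLAT_TOL
    d[ok] = eta * g[ok] / norms[ok]
    return d


def adversarial_perturbation(
    f: np.ndarray,
    predictor: Predictor,
    eta: float,
    epsilon: float,
    rng: np.random.Generator,
) -> Perturbation:
    """Single-embedding adversarial perturbation (see module docstring)."""
    d = adversarial_perturbation_batch(np.atleast_2d(f), predictor, eta, epsilon, rng)[0]
    return Perturbation(d=d, eta=eta, epsilon=epsilon,
                        flat=bool(np.linalg.norm(d) < _FLAT_TOL))


def afse_loss(f: Tensor, d: np.ndarray, predictor: Predictor) -> Tensor:
    """Stabilization loss D(N(f,f), N(f,f+d)), averaged over the batch.

    ``f`` carries model gradients; ``d`` enters as a constant.
    """
    d_const = Tensor(np.atleast_2d(d))
    return divergence(predictor(f, f), predictor(f, f + d_const)).mean()
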