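"""Multi-kernel soft-margin SVM with simplex-constrained kernel weights.

The classifier combines one linear base kernel per feature channel,

    K(x_i, x) = sum_f  beta_f * k_f(x_i^(f), x^(f)),     beta_f >= 0,
                                                          sum_f beta_f = 1,

and learns ``beta`` jointly with the SVM by alternating (i) a standard
soft-margin SVM solve on the combined Gram matrix and (ii) a reduced-
gradient descent step on ``beta`` over the probability simplex with an
Armijo backtracking line search, the scheme popularized as SimpleMKL.
The prediction for a test point is

    F(x) = sign( sum_i  y_i alpha_i K(x_i, x) + b ),

with a score of exactly 0 mapped to the +1 (control) class.

Each base Gram matrix is rescaled to unit mean diagonal before
combination so that the learned weights are comparable across channels
of different dimensionality; the same constants are applied to test
cross-kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

_SVM_TOL = 1e-7


class KernelValidityError(ValueError):
    """Raised when a Gram matrix is not positive semidefinite."""


@dataclass(frozen=True)
class KernelBundle:
    """Per-channel training Gram matrices and their normalization constants."""

    grams: tuple[np.ndarray, ...]
    channel_names: tuple[str, ...]
    norm_constants: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.grams:
            raise ValueError("need at least one base kernel")
        n = self.grams[0].shape[0]
        for g in self.grams:
            if g.shape != (n, n):
                raise ValueError("all Gram matrices must be square and same size")
            validate_psd(g)
        if len(self.channel_names) != len(self.grams):
            raise ValueError("channel_names and grams lengths differ")

    @property
    def n_kernels(self) -> int:
        return len(self.grams)

    @property
    def n_samples(self) -> int:
        return self.grams[0].shape[0]


@dataclass
class MKLModel:
    """Fitted multi-kernel SVM.

    ``alpha_signed[i]`` stores y_i * alpha_i, so the decision score for a
    combined cross-kernel row k is ``k @ alpha_signed + b``.
    """

    beta: np.ndarray
    alpha_signed: np.ndarray
    bias: float
    support: np.ndarray
    y: np.ndarray
    C: float
    channel_names: tuple[str, ...]
    norm_constants: tuple[float, ...]
    objective: float
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float)
        if np.any(beta < -1e-9) or abs(beta.sum() - 1.0) > 1e-9:
            raise ValueError("beta must lie on the probability simplex")
        alpha = np.abs(self.alpha_signed)
        if np.any(alpha > self.C * (1 + 1e-6)):
            raise ValueError("dual coefficients exceed the box constraint")
        if abs(self.alpha_signed.sum()) > 1e-5 * max(1.0, alpha.sum()):
            raise ValueError("equality constraint sum(alpha_i y_i) = 0 violated")


def linear_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gram matrix of inner products between rows of ``a`` and ``b``."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"feature dimensions differ: {a.shape[1]} vs {b.shape[1]}")
    return a @ b.T


def validate_psd(gram: np.ndarray, tol: float = 1e-8) -> None:
    g = np.asarray(gram, dtype=float)
    if not np.allclose(g, g.T, atol=1e-8):
        raise KernelValidityError("Gram matrix is not symmetric")
    w = np.linalg.eigvalsh(g)
    scale = max(1.0, float(np.abs(w).max()))
    if w.min() < -tol * scale:
        raise KernelValidityError(f"Gram matrix has negative eigenvalue {w.min():.3e}")


def normalize_gram(gram: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale a training Gram to unit mean diagonal; return (gram, constant)."""
    c = float(np.mean(np.diag(gram)))
    if c <= 0:
        # all-zero features: leave the Gram untouched rather than divide by 0
        return np.asarray(gram, dtype=float), 1.0
    return np.asarray(gram, dtype=float) / c, c


def make_bundle(channel_matrices: dict[str, np.ndarray]) -> KernelBundle:
    """Build normalized linear base kernels from per-channel training rows."""
    names, grams, consts = [], [], []
    for ch, X in channel_matrices.items():
        g, c = normalize_gram(linear_kernel(X, X))
        names.append(ch)
        grams.append(g)
        consts.append(c)
    return KernelBundle(grams=tuple(grams), channel_names=tuple(names),
                        norm_constants=tuple(consts))


def combine_kernels(grams: tuple[np.ndarray, ...] | list[np.ndarray],
                    beta: np.ndarray) -> np.ndarray:
    """Elementwise convex combination sum_f beta_f K_f."""
    beta = np.asarray(beta, dtype=float)
    if len(beta) != len(grams):
        raise ValueError("beta length must equal the number of kernels")
    if np.any(beta < -1e-12) or abs(beta.sum() - 1.0) > 1e-9:
        raise ValueError("beta must be nonnegative and sum to 1")
    out = np.zeros_like(np.asarray(grams[0], dtype=float))
    for b, g in zip(beta, grams):
        out += b * np.asarray(g, dtype=float)
    return out


def fit_svm_fixed_kernel(gram: np.ndarray, y: np.ndarray, C: float = 1.0,
                         check_psd: bool = True
                         ) -> tuple[np.ndarray, float, float]:
    """Solve the soft-margin SVM dual on a precomputed kernel.

    Returns ``(alpha_signed, bias, objective)`` where ``alpha_signed[i]``
    is y_i * alpha_i over all training samples and ``objective`` is the
    dual value sum_i alpha_i - 1/2 * s^T K s with s = alpha_signed.
    """
    gram = np.asarray(gram, dtype=float)
    y = np.asarray(y)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("labels must contain both classes, coded -1/+1")
    if check_psd:
        validate_psd(gram)
    clf = SVC(kernel="precomputed", C=C, tol=_SVM_TOL)
    clf.fit(gram, y)
    signed = np.zeros(len(y))
    signed[clf.support_] = clf.dual_coef_[0]
    # sklearn orients dual_coef_ as y_i * alpha_i for classes_ = [-1, +1]
    bias = float(clf.intercept_[0])
    objective = float(np.abs(signed).sum() - 0.5 * signed @ gram @ signed)
    return signed, bias, objective


def _mkl_gradient(grams, signed) -> np.ndarray:
    # dJ/dbeta_f = -1/2 s^T K_f s  (Danskin; s fixed at the dual optimum)
    return np.array([-0.5 * signed @ g @ signed for g in grams])


def fit_mkl(bundle: KernelBundle, y: np.ndarray, C: float = 1.0,
            tol: float = 1e-4, max_iter: int = 100, gap_tol: float = 1e-3,
            armijo_c: float = 1e-4, backtrack: float = 0.5,
            max_backtracks: int = 20) -> MKLModel:
    """Learn simplex kernel weights and the SVM jointly (reduced gradient).

    Starting from uniform weights, alternate an SVM solve on the combined
    kernel with a reduced-gradient step on ``beta`` accepted under
    Armijo's sufficient-decrease rule.  Stops when the relative objective
    decrease falls below ``tol``, the duality-gap criterion falls below
    ``gap_tol``, or ``max_iter`` is reached (the model is then returned
    with ``converged=False``).
    """
    y = np.asarray(y)
    F = bundle.n_kernels
    grams = bundle.grams
    beta = np.full(F, 1.0 / F)

    def solve(b):
        return fit_svm_fixed_kernel(combine_kernels(grams, b), y, C=C, check_psd=False)

    signed, bias, J = solve(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if F == 1:
            converged = True
            break
        grad = _mkl_gradient(grams, signed)
        # duality-gap criterion: best single-kernel quadratic term vs current
        quad = -2.0 * grad  # s^T K_f s per kernel
        gap = (quad.max() - float(beta @ quad)) / max(1.0, abs(J))
        if gap < gap_tol:
            converged = True
            break
        mu = int(np.argmax(beta))
        reduced = grad - grad[mu]
        d = -reduced
        d[(beta <= 1e-12) & (d < 0)] = 0.0
        d[mu] = -(np.sum(d) - d[mu])
        if np.abs(d).max() < 1e-12:
            converged = True
            break
        neg = d < 0
        gamma_max = float(np.min(-beta[neg] / d[neg])) if neg.any() else 1.0
        if gamma_max <= 0:
            converged = True
            break
        slope = float(grad @ d)
        gamma = gamma_max
        accepted = False
        for _ in range(max_backtracks):
            cand = np.clip(beta + gamma * d, 0.0, None)
            cand /= cand.sum()
            s_c, b_c, J_c = solve(cand)
            if J_c <= J + armijo_c * gamma * slope:
                accepted = True
                break
            gamma *= backtrack
        if not accepted:
            converged = True
            break
        beta, signed, bias, J_new = cand, s_c, b_c, J_c
        if abs(J - J_new) <= tol * max(1.0, abs(J)):
            J = J_new
            converged = True
            break
        J = J_new
    support = np.flatnonzero(np.abs(signed) > 1e-12)
    return MKLModel(beta=beta, alpha_signed=signed, bias=bias, support=support,
                    y=y, C=C, channel_names=bundle.channel_names,
                    norm_constants=bundle.norm_constants, objective=J,
                    converged=converged, n_iter=it)


def cross_kernels(model: MKLModel, test_channels: dict[str, np.ndarray],
                  train_channels: dict[str, np.ndarray]) -> list[np.ndarray]:
    """Normalized test-vs-train Gram rows per channel, in model order."""
    if set(test_channels) != set(model.channel_names):
        raise ValueError("test channels do not match the trained channels")
    out = []
    for ch, c in zip(model.channel_names, model.norm_constants):
        out.append(linear_kernel(test_channels[ch], train_channels[ch]) / c)
    return out


def decision_score(model: MKLModel, test_grams: list[np.ndarray]) -> np.ndarray:
    """Decision scores sum_i y_i alpha_i K(x_i, x) + b for test rows."""
    if len(test_grams) != len(model.beta):
        raise ValueError("number of test cross-kernels does not match beta")
    k = np.zeros_like(np.atleast_2d(test_grams[0]), dtype=float)
    for b, g in zip(model.beta, test_grams):
        k += b * np.atleast_2d(g)
    return k @ model.alpha_signed + model.bias


def predict_label(scores: np.ndarray) -> np.ndarray:
    """Sign decision; a score of exactly 0 predicts the control (+1) class."""
    return np.where(np.asarray(scores) < 0, -1, 1)
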