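"""Eigenvalue-Enhanced Global Covariance Pooling (EGCP).

Second-order pooling for noise-robust fine-grained recognition. Given a
feature map ``x`` with ``D`` channels over ``H x W`` spatial positions, the
operator:

1. normalizes each channel to zero mean / unit variance (with an ``eps``
   guard) and records per-channel precision weights ``w_d = 1/(sigma_d^2 + eps)``,
   so high-variance (noise-prone) channels are down-weighted;
2. forms the weighted channel covariance
   ``P = (1/N) (W^{1/2} X) (W^{1/2} X)^T`` with ``W = diag(w_d)`` and ``X`` the
   centered ``D x N`` feature matrix (``N = H*W``);
3. regularizes ``P_reg = P + eps*I``, eigendecomposes ``P_reg = U Lam U^T``
   and floors the eigenvalues at ``eps``;
4. enhances the spectrum with ``lam_en = log(1 + lam)`` — a concave map whose
   relative gain ``log(1+lam)/lam`` is largest for small eigenvalues, which
   carry the subtle texture statistics that separate visually similar
   classes;
5. rescales by a dynamic factor ``S_F = ||P_en^{1/2} exp(-P_en)||_F``
   (equivalently ``sqrt(sum_i lam_en,i * exp(-2*lam_en,i))``), producing the
   final symmetric feature matrix ``A = (S_F + 1) * P_en^{1/2}``, flattened
   row-major to a length-``D^2`` descriptor.

All steps are differentiable; functions accept a single feature map
``(D, H, W)`` or a batch ``(B, D, H, W)`` and operate batched over leading
axes. Matrix functions are evaluated in the eigenbasis (``U f(Lam) U^T``) —
valid because all spectra involved are nonnegative — and every downstream
quantity is a spectral function of ``P_reg``, hence independent of the
eigenbasis chosen for repeated eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tensor import Tensor, as_tensor, eigh

__all__ = [
    "EGCPConfig",
    "NormalizedFeatureMap",
    "CovarianceMatrix",
    "EigenState",
    "EGCPResult",
    "normalize_features",
    "weighted_covariance",
    "regularize_and_decompose",
    "enhance_eigenvalues",
    "dynamic_scaling",
    "scaling_factor_closed_form",
    "egcp_transform",
]


@dataclass(frozen=True)
class EGCPConfig:
    """Configuration of the pooling operator.

    epsilon: the numerical guard used for channel normalization, covariance
        regularization and the eigenvalue floor; must lie in (0, 1).
    """

    epsilon: float = 1e-5

    def __post_init__(self):
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError(f"epsilon must be in (0, 1), got {self.epsilon}")


@dataclass
class NormalizedFeatureMap:
    """Channel-standardized features plus the statistics that produced them."""

    values: Tensor          # (..., D, H, W), per-channel mean ~ 0
    mu: Tensor              # (..., D) per-channel means
    sigma2: Tensor          # (..., D) per-channel variances
    weights: Tensor         # (..., D) precision weights 1/(sigma2 + eps)
    epsilon: float


@dataclass
class CovarianceMatrix:
    entries: Tensor         # (..., D, D), symmetric
    regularized: bool = False


@dataclass
class EigenState:
    """Spectral state of a (regularized) covariance matrix."""

    U: Tensor               # (..., D, D) orthonormal columns
    lambdas: Tensor         # (..., D) eigenvalues, descending
    lambdas_reg: Tensor     # (..., D) floored at eps
    lambdas_en: Tensor | None = None  # (..., D) log(1 + lambdas_reg)


@dataclass
class EGCPResult:
    P_en: Tensor            # (..., D, D) enhanced covariance
    S_mat: Tensor           # (..., D, D) dynamic scaling matrix exp(-P_en)
    Q_cross: Tensor         # (..., D, D) P_en^{1/2} @ S_mat
    S_F: Tensor             # (...,) Frobenius norm of Q_cross
    A: Tensor               # (..., D, D) final feature matrix
    a_flat: Tensor          # (..., D^2) row-major flattening of A
    state: EigenState = field(repr=False, default=None)


def _tT(m: Tensor) -> Tensor:
    """Transpose the two trailing axes."""
    axes = list(range(m.data.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return m.transpose(tuple(axes))


def _spectral(U: Tensor, diag: Tensor) -> Tensor:
    """Assemble U @ diag(d) @ U^T for batched U (..., D, D), d (..., D)."""
    d = diag.reshape(diag.shape[:-1] + (1,) + diag.shape[-1:])  # (..., 1, D)
    return (U * d) @ _tT(U)


def normalize_features(x, cfg: EGCPConfig = EGCPConfig()) -> NormalizedFeatureMap:
    """Standardize each channel over its spatial positions.

    Raises ``ValueError`` naming the first offending channel if the input
    contains non-finite values.
    """
    x = as_tensor(x)
    if x.data.ndim < 3:
        raise ValueError("expected (..., D, H, W) feature map")
    if not np.isfinite(x.data).all():
        bad = ~np.isfinite(x.data).all(axis=(-1, -2))
        ch = int(np.argwhere(bad.reshape(-1, bad.shape[-1]).any(axis=0))[0][0])
        raise ValueError(f"non-finite values in feature channel {ch}")
    mu = x.mean(axis=(-1, -2), keepdims=True)                   # (..., D, 1, 1)
    sigma2 = ((x - mu) ** 2).mean(axis=(-1, -2), keepdims=True)
    inv_std = (sigma2 + cfg.epsilon) ** -0.5
    values = (x - mu) * inv_std
    squeeze = lambda t: t.reshape(t.shape[:-2])
    return NormalizedFeatureMap(
        values=values,
        mu=squeeze(mu),
        sigma2=squeeze(sigma2),
        weights=squeeze((sigma2 + cfg.epsilon) ** -1.0),
        epsilon=cfg.epsilon,
    )


def weighted_covariance(xn: NormalizedFeatureMap) -> CovarianceMatrix:
    """Precision-weighted channel covariance ``P`` of the normalized features.

    ``P_ij = sqrt(w_i w_j) * (1/N) sum_n Xt_{i,n} Xt_{j,n}`` with ``Xt`` the
    centered normalized feature matrix (D x N); equivalently
    ``P = (1/N)(W^{1/2} Xt)(W^{1/2} Xt)^T``. Higher-variance channels carry
    smaller weight.
    """
    v = xn.values
    *lead, D, H, W = v.shape
    N = H * W
    if N == 0:
        raise ValueError("feature map has no spatial positions")
    X = v.reshape(tuple(lead) + (D, N))
    X = X - X.mean(axis=-1, keepdims=True)      # exact centering
    sw = (xn.weights ** 0.5).reshape(tuple(lead) + (D, 1))
    Xs = X * sw
    P = (Xs @ _tT(Xs)) * (1.0 / N)
    return CovarianceMatrix(entries=P, regularized=False)


def _check_symmetric(P: np.ndarray, rtol: float = 1e-6) -> None:
    scale = max(1.0, float(np.max(np.abs(P))))
    if float(np.max(np.abs(P - np.swapaxes(P, -1, -2)))) > rtol * scale:
        raise ValueError("covariance matrix is not symmetric "
                         "(asymmetry beyond tolerance; upstream bug?)")


def regularize_and_decompose(P: CovarianceMatrix | Tensor | np.ndarray,
                             cfg: EGCPConfig = EGCPConfig()) -> EigenState:
    """``P_reg = P + eps*I``, eigendecompose, floor eigenvalues at ``eps``."""
    entries = P.entries if isinstance(P, CovarianceMatrix) else as_tensor(P)
    _check_symmetric(entries.data)
    D = entries.shape[-1]
    P_reg = entries + Tensor(cfg.epsilon * np.eye(D))
    lam, U = eigh(P_reg)
    # max(lam, eps) written with relu so the floor stays differentiable
    lam_reg = (lam - cfg.epsilon).relu() + cfg.epsilon
    return EigenState(U=U, lambdas=lam, lambdas_reg=lam_reg)


def enhance_eigenvalues(lambdas_reg) -> Tensor:
    """Concave spectral enhancement ``lam_en = log(1 + lam)`` (order-preserving)."""
    lam = as_tensor(lambdas_reg)
    if float(lam.data.min()) < 0.0:
        raise ValueError("eigenvalues must be nonnegative before enhancement")
    from .tensor import log1p
    return log1p(lam)


def scaling_factor_closed_form(lambdas_en: np.ndarray) -> np.ndarray:
    """Closed form for the dynamic scaling factor: sqrt(sum lam * exp(-2 lam))."""
    lam = np.asarray(lambdas_en, dtype=np.float64)
    return np.sqrt(np.sum(lam * np.exp(-2.0 * lam), axis=-1))


def dynamic_scaling(U, lambdas_en) -> tuple[Tensor, Tensor, Tensor]:
    """Dynamic scaling matrix, cross matrix and scalar factor.

    ``S_mat = U exp(-Lam_en) U^T`` balances the enhanced spectrum;
    ``Q_cross = P_en^{1/2} S_mat = U Lam_en^{1/2} exp(-Lam_en) U^T``; the
    factor ``S_F = ||Q_cross||_F`` is computed from the assembled matrix and
    verified against its eigenvalue closed form.
    """
    U, lam = as_tensor(U), as_tensor(lambdas_en)
    if float(lam.data.min()) < 0.0:
        raise ValueError("enhanced eigenvalues must be nonnegative")
    from .tensor import exp
    S_mat = _spectral(U, exp(-lam))
    Q_cross = _spectral(U, (lam ** 0.5) * exp(-lam))
    S_F = ((Q_cross ** 2).sum(axis=(-1, -2))) ** 0.5
    closed = scaling_factor_closed_form(lam.data)
    if not np.all(np.abs(S_F.data - closed) < 1e-8):
        raise AssertionError("dynamic scaling factor disagrees with closed form")
    return S_mat, Q_cross, S_F


def egcp_transform(x, cfg: EGCPConfig = EGCPConfig()) -> EGCPResult:
    """Full pooling pipeline from a feature map to the flattened descriptor.

    Accepts ``(D, H, W)`` or ``(B, D, H, W)``; fully differentiable w.r.t. x.
    """
    xn = normalize_features(x, cfg)
    P = weighted_covariance(xn)
    state = regularize_and_decompose(P, cfg)
    lam_en = enhance_eigenvalues(state.lambdas_reg)
    state.lambdas_en = lam_en
    S_mat, Q_cross, S_F = dynamic_scaling(state.U, lam_en)
    P_en = _spectral(state.U, lam_en)
    P_sqrt = _spectral(state.U, lam_en ** 0.5)
    scale = (S_F + 1.0).reshape(S_F.shape + (1, 1))
    A = scale * P_sqrt
    D = A.shape[-1]
    a_flat = A.reshape(A.shape[:-2] + (D * D,))
    return EGCPResult(P_en=P_en, S_mat=S_mat, Q_cross=Q_cross, S_F=S_F,
                      A=A, a_flat=a_flat, state=state)
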