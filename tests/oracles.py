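"""Independent reference implementations used as test oracles.

Everything here is written with explicit loops and generic dense linear
algebra (scipy matrix functions), deliberately sharing no code with the
package's differentiable implementations.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def egcp_reference(x: np.ndarray, eps: float) -> dict:
    """Loop-based covariance pooling pipeline on one (D, H, W) feature map."""
    D, H, W = x.shape
    N = H * W
    mu = np.zeros(D)
    sig2 = np.zeros(D)
    for d in range(D):
        acc = 0.0
        for h in range(H):
            for w in range(W):
                acc += x[d, h, w]
        mu[d] = acc / N
        acc = 0.0
        for h in range(H):
            for w in range(W):
                acc += (x[d, h, w] - mu[d]) ** 2
        sig2[d] = acc / N
    xn = np.zeros_like(x)
    wgt = np.zeros(D)
    for d in range(D):
        wgt[d] = 1.0 / (sig2[d] + eps)
        for h in range(H):
            for w in range(W):
                xn[d, h, w] = (x[d, h, w] - mu[d]) / np.sqrt(sig2[d] + eps)
    # center the normalized features and form the weighted covariance
    X = xn.reshape(D, N)
    Xc = X - X.mean(axis=1, keepdims=True)
    P = np.zeros((D, D))
    for i in range(D):
        for j in range(D):
            acc = 0.0
            for n in range(N):
                acc += Xc[i, n] * Xc[j, n]
            P[i, j] = np.sqrt(wgt[i] * wgt[j]) * acc / N
    P_reg = P + eps * np.eye(D)
    lam, U = np.linalg.eigh(P_reg)
    lam, U = lam[::-1].copy(), U[:, ::-1].copy()
    lam_reg = np.maximum(lam, eps)
    lam_en = np.log1p(lam_reg)
    P_en = U @ np.diag(lam_en) @ U.T
    S_mat = scipy.linalg.expm(-P_en)
    P_sqrt = scipy.linalg.sqrtm(P_en).real
    Q = P_sqrt @ S_mat
    S_F = np.linalg.norm(Q, "fro")
    A = (S_F + 1.0) * P_sqrt
    return {"mu": mu, "sigma2": sig2, "weights": wgt, "xn": xn, "P": P,
            "P_reg": P_reg, "lam": lam, "lam_reg": lam_reg, "lam_en": lam_en,
            "P_en": P_en, "S_mat": S_mat, "Q_cross": Q, "S_F": S_F,
            "A": A, "a_flat": A.reshape(-1)}


def topk_accuracy_reference(true_labels, rankings, k) -> float:
    """Brute-force membership count."""
    hits = 0
    for y, ranking in zip(true_labels, rankings):
        if y in list(ranking[:k]):
            hits += 1
    return hits / len(true_labels)


def per_class_reference(true_labels, top1) -> dict:
    """Independent confusion tally."""
    classes = sorted(set(int(c) for c in true_labels) | set(int(c) for c in top1))
    table = {}
    f1s = []
    for c in classes:
        tp = sum(1 for y, p in zip(true_labels, top1) if y == c and p == c)
        fp = sum(1 for y, p in zip(true_labels, top1) if y != c and p == c)
        fn = sum(1 for y, p in zip(true_labels, top1) if y == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        table[c] = {"TP": tp, "FP": fp, "FN": fn,
                    "precision": prec, "recall": rec, "f1": f1}
        f1s.append(f1)
    return {"table": table, "macro_f1": sum(f1s) / len(f1s)}


def distillation_reference(teacher_logits, student_logits, T) -> float:
    """Direct softened cross-entropy summation, mean over the batch."""
    t = np.atleast_2d(np.asarray(teacher_logits, dtype=float))
    s = np.atleast_2d(np.asarray(student_logits, dtype=float))
    total = 0.0
    for ti, si in zip(t, s):
        pt = np.exp(ti / T - np.max(ti / T))
        pt /= pt.sum()
        ps = np.exp(si / T - np.max(si / T))
        ps /= ps.sum()
        total += -sum(pt[i] * np.log(ps[i]) for i in range(len(pt)))
    return total / t.shape[0]


def finite_difference_grad(f, x0: np.ndarray, eps: float = 1e-6,
                           indices=None) -> np.ndarray:
    """Central finite differences of scalar-valued f at x0 (selected indices)."""
    g = np.zeros_like(x0, dtype=float)
    if indices is None:
        it = np.nditer(x0, flags=["multi_index"])
        indices = []
        for _ in it:
            indices.append(it.multi_index)
    for idx in indices:
        xp = x0.copy()
        xp[idx] += eps
        xm = x0.copy()
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
    return g
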