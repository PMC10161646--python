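"""Profile-REML machinery for the single-GRM linear mixed model.

Model: y = X b + g + e with g ~ N(0, sg2 * G), e ~ N(0, se2 * I).

All fits work in the eigenbasis of the GRM restricted to the orthogonal
complement of the fixed effects: with Q an orthonormal basis of null(X'),
K = Q' G Q = E diag(theta) E', and omega = (Q E)' y, the restricted
log-likelihood profiled over se2 at variance ratio lam = sg2 / se2 is

    llf(lam) = -1/2 [ (n-p) (log(2 pi se2_hat) + 1) + sum_i log(lam theta_i + 1) ]
    se2_hat  = mean_i omega_i^2 / (lam theta_i + 1)

a one-dimensional problem solved by Brent search on log(lam) with explicit
boundary handling at lam = 0. The same rotation is shared across traits and
across permutations, which is what makes matrix-wide scans cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, qr
from scipy.optimize import minimize_scalar

LOG_LAM_LO = -14.0
LOG_LAM_HI = 14.0


@dataclass
class ProjectedKernel:
    """Eigen-structure of the GRM in the complement of the fixed effects."""

    basis: np.ndarray   # n x (n - p), orthonormal columns
    theta: np.ndarray   # eigenvalues, length n - p
    n: int
    p: int

    @classmethod
    def build(cls, G: np.ndarray, X: np.ndarray) -> "ProjectedKernel":
        n, p = X.shape
        if np.linalg.matrix_rank(X) < p:
            raise ValueError("fixed-effect design is rank deficient")
        Qfull, _ = qr(X, mode="full")
        Q2 = Qfull[:, p:]
        K = Q2.T @ G @ Q2
        theta, E = eigh((K + K.T) / 2.0)
        return cls(basis=Q2 @ E, theta=np.clip(theta, 0.0, None), n=n, p=p)

    def rotate(self, y: np.ndarray) -> np.ndarray:
        return self.basis.T @ y

    @property
    def identifiable(self) -> bool:
        """False when the eigenvalue spectrum is (near) constant, i.e. G ~ c I
        in the projected space and sg2/se2 cannot be separated."""
        t = self.theta
        spread = t.max() - t.min()
        return bool(spread > 1e-8 * max(1.0, t.mean()))


def reml_loglik(omega_sq: np.ndarray, theta: np.ndarray, lam: float) -> float:
    """Restricted log-likelihood at ratio lam, profiled over se2."""
    w = lam * theta + 1.0
    k = omega_sq.shape[0]
    se2 = float(np.sum(omega_sq / w) / k)
    return -0.5 * (k * (np.log(2 * np.pi * se2) + 1.0) + float(np.sum(np.log(w))))


def reml_profile(omega: np.ndarray, theta: np.ndarray):
    """Maximize the profiled REML over lam >= 0.

    Returns (lam_hat, llf_hat, se2_hat, converged).
    """
    osq = omega**2
    res = minimize_scalar(
        lambda t: -reml_loglik(osq, theta, np.exp(t)),
        bounds=(LOG_LAM_LO, LOG_LAM_HI),
        method="bounded",
        options={"xatol": 1e-10},
    )
    lam = float(np.exp(res.x))
    llf = -float(res.fun)
    converged = bool(res.success)
    # explicit boundary check: lam = 0 and the box edges
    llf0 = reml_loglik(osq, theta, 0.0)
    if llf0 >= llf:
        lam, llf = 0.0, llf0
    k = omega.shape[0]
    se2 = float(np.sum(osq / (lam * theta + 1.0)) / k)
    return lam, llf, se2, converged


def reml_profile_grid(
    Omega: np.ndarray, theta: np.ndarray, n_grid: int = 64
) -> np.ndarray:
    """Vectorized grid REML for many traits at once.

    ``Omega`` is (n - p) x T (rotated traits). Evaluates the profiled
    restricted likelihood on a fixed log-spaced lam grid (plus lam = 0) and
    returns the per-trait argmax ratio. Used inside permutation scans where
    thousands of fits are needed and grid resolution is ample.
    """
    grid = np.concatenate([[0.0], np.exp(np.linspace(LOG_LAM_LO, LOG_LAM_HI, n_grid))])
    osq = Omega**2  # k x T
    k = osq.shape[0]
    best_llf = np.full(osq.shape[1], -np.inf)
    best_lam = np.zeros(osq.shape[1])
    for lam in grid:
        w = lam * theta + 1.0
        se2 = (osq / w[:, None]).sum(axis=0) / k
        llf = -0.5 * (k * (np.log(2 * np.pi * se2) + 1.0) + np.sum(np.log(w)))
        better = llf > best_llf
        best_llf[better] = llf[better]
        best_lam[better] = lam
    return best_lam
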