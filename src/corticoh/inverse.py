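"""Forward projection and regularized inverse source estimation.

Scalp potentials are modeled as the projection of oriented cortical patch
sources through a lead field, Phi = K J + eps. Source estimation solves
the penalized least-squares problem

    J_hat = argmin_J ||Phi - K J||^2 + alpha ||W J||^2

where W is either the identity (minimum-norm) or the discrete cortical
surface Laplacian (CSL smoothing). The closed-form minimizer is

    J_hat = (K'K + alpha W'W + ridge I)^{-1} K' Phi,

with a small ridge stabilizer because W'W annihilates constants and is
therefore singular. In the underdetermined regime (sensors << patches)
the equivalent representer form

    J_hat = M^{-1} K' (K M^{-1} K' + I)^{-1} Phi,   M = alpha W'W + ridge I

is used, which only ever factorizes a sensors x sensors matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import LaplacianOperator

logger = logging.getLogger("corticoh.inverse")

__all__ = [
    "LeadField",
    "SourceEstimate",
    "forward_project",
    "solve_inverse",
    "residual",
    "choose_alpha",
    "average_reference",
    "default_alpha_grid",
]

#: relative scale of the ridge stabilizer added to the normal matrix
RIDGE_SCALE = 1e-10


@dataclass
class LeadField:
    """Linear map from oriented patch dipole moments to sensor potentials.

    ``K`` has shape (n_sensors, n_patches) in microvolts per unit dipole
    moment; orientation is folded into the columns, so each patch carries
    a single signed amplitude.
    """

    K: np.ndarray
    sensor_names: list[str] | None = None
    patch_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        if self.K.ndim != 2:
            raise ValueError("K must be 2-D (sensors x patches)")
        if not np.all(np.isfinite(self.K)):
            raise ValueError("lead field contains non-finite entries")

    @property
    def n_sensors(self) -> int:
        return self.K.shape[0]

    @property
    def n_patches(self) -> int:
        return self.K.shape[1]


@dataclass
class SourceEstimate:
    """Estimated patch source waveforms (patches x samples)."""

    J_hat: np.ndarray
    method: str          # {"minimum_norm", "csl"}
    alpha: float


def _as_matrix(K) -> np.ndarray:
    return K.K if isinstance(K, LeadField) else np.asarray(K, dtype=float)


def _as_W(W, n_patches: int):
    """Normalize the penalty operator argument; None means identity."""
    if W is None:
        return None
    if isinstance(W, LaplacianOperator):
        W = W.W
    if sp.issparse(W):
        if W.shape != (n_patches, n_patches):
            raise ValueError("W shape does not match patch count")
        return W.tocsr()
    W = np.asarray(W, dtype=float)
    if W.shape != (n_patches, n_patches):
        raise ValueError("W shape does not match patch count")
    if np.allclose(W, np.eye(n_patches)):
        return None
    return W


def average_reference(X: np.ndarray) -> np.ndarray:
    """Subtract the mean across sensors (rows) from each column."""
    X = np.asarray(X, dtype=float)
    return X - X.mean(axis=0, keepdims=True)


def forward_project(K, J: np.ndarray, noise_sd: float = 0.0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Project sources to sensors: Phi = K J + eps.

    ``eps`` is i.i.d. Gaussian sensor noise with standard deviation
    ``noise_sd`` (microvolts); 0 disables it.
    """
    Km = _as_matrix(K)
    J = np.atleast_2d(np.asarray(J, dtype=float))
    if J.shape[0] != Km.shape[1]:
        raise ValueError(
            f"dimension mismatch: K has {Km.shape[1]} patches, "
            f"J has {J.shape[0]} rows")
    Phi = Km @ J
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        Phi = Phi + rng.normal(0.0, noise_sd, size=Phi.shape)
    return Phi


def _ridge(Km: np.ndarray, WtW, alpha: float) -> float:
    n = Km.shape[1]
    tr = float(np.einsum("ij,ij->", Km, Km))
    if WtW is not None and alpha > 0:
        trW = WtW.diagonal().sum() if sp.issparse(WtW) else np.trace(WtW)
        tr += alpha * float(trW)
    return RIDGE_SCALE * tr / n


def solve_inverse(K, Phi: np.ndarray, W=None, alpha: float = 0.0) -> SourceEstimate:
    """Solve the regularized inverse problem for source amplitudes.

    Parameters
    ----------
    K : LeadField or (n_sensors, n_patches) array
    Phi : (n_sensors,) or (n_sensors, n_samples) array
        Scalp potentials (microvolts).
    W : LaplacianOperator, sparse/dense matrix, or None
        Penalty operator; None (or the identity) selects the minimum-norm
        method, anything else the CSL method.
    alpha : float >= 0
        Regularization weight. ``alpha = 0`` requires a full-column-rank
        lead field and returns the plain least-squares solution.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    Km = _as_matrix(K)
    Phi = np.asarray(Phi, dtype=float)
    squeeze = Phi.ndim == 1
    Phi2 = Phi[:, None] if squeeze else Phi
    if Phi2.shape[0] != Km.shape[0]:
        raise ValueError(
            f"dimension mismatch: K has {Km.shape[0]} sensors, "
            f"Phi has {Phi2.shape[0]} rows")
    n_s, n_p = Km.shape
    Wop = _as_W(W, n_p)
    method = "minimum_norm" if Wop is None else "csl"

    if alpha == 0:
        J, _, rank, _ = np.linalg.lstsq(Km, Phi2, rcond=None)
        if rank < n_p:
            raise np.linalg.LinAlgError(
                f"alpha=0 requires full column rank: rank(K)={rank} < "
                f"{n_p} patches")
    else:
        if Wop is None:
            WtW = None
        else:
            WtW = (Wop.T @ Wop)
        rid = _ridge(Km, WtW, alpha)
        if n_s >= n_p:
            A = Km.T @ Km
            if WtW is not None:
                A = A + alpha * (WtW.toarray() if sp.issparse(WtW) else WtW)
            else:
                A = A + alpha * np.eye(n_p)
            A[np.diag_indices_from(A)] += rid
            try:
                c = sla.cho_factor(A)
                J = sla.cho_solve(c, Km.T @ Phi2)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    "regularized normal matrix is singular (rank-deficient "
                    "system)") from exc
        else:
            J = _solve_representer(Km, Phi2, WtW, alpha, rid)
    J = np.ascontiguousarray(J)
    return SourceEstimate(J_hat=J[:, 0] if squeeze else J,
                          method=method, alpha=float(alpha))


def _solve_representer(Km, Phi2, WtW, alpha, rid, refine: int = 2):
    """Underdetermined solve via M^{-1} K' (K M^{-1} K' + I)^{-1} Phi.

    M = alpha W'W + ridge I is nearly singular along W's null space
    (condition ~ 1/ridge), so the plain representer solution loses digits;
    a couple of iterative-refinement steps on the normal equations
    (K'K + M) J = K'Phi, each using a Woodbury application of the inverse,
    bring it back to the accuracy of the dense normal-equation solve.
    """
    n_p = Km.shape[1]
    if WtW is None:
        def M_inv(X):
            return X / (alpha + rid)

        def M_apply(X):
            return (alpha + rid) * X
    elif sp.issparse(WtW):
        Ms = (alpha * WtW + rid * sp.eye(n_p)).tocsc()
        lu = spla.splu(Ms)

        def M_inv(X):
            return lu.solve(X)

        def M_apply(X):
            return Ms @ X
    else:
        Md = alpha * WtW + rid * np.eye(n_p)
        lu_d = sla.lu_factor(Md)

        def M_inv(X):
            return sla.lu_solve(lu_d, X)

        def M_apply(X):
            return Md @ X

    M_inv_Kt = M_inv(Km.T)
    G = Km @ M_inv_Kt
    G[np.diag_indices_from(G)] += 1.0
    try:
        c = sla.cho_factor(G)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "regularized sensor-space matrix is singular") from exc

    def A_inv(R):
        # Woodbury: (K'K + M)^{-1} R
        MR = M_inv(R)
        return MR - M_inv_Kt @ sla.cho_solve(c, Km @ MR)

    rhs = Km.T @ Phi2
    J = M_inv_Kt @ sla.cho_solve(c, Phi2)
    for _ in range(refine):
        r = rhs - Km.T @ (Km @ J) - M_apply(J)
        J = J + A_inv(r)
    return J


def residual(K, Phi: np.ndarray, J_hat: np.ndarray) -> tuple[np.ndarray, float]:
    """Sensor-space residual Phi - K J_hat and the relative misfit.

    Returns ``(residual, ||residual|| / ||Phi||)``; a zero-signal input
    gives relative misfit 0 by convention.
    """
    Km = _as_matrix(K)
    J_hat = np.asarray(J_hat, dtype=float)
    r = np.asarray(Phi, dtype=float) - Km @ J_hat
    denom = np.linalg.norm(Phi)
    rel = 0.0 if denom == 0 else float(np.linalg.norm(r) / denom)
    return r, rel


def default_alpha_grid(K, W=None, n: int = 9) -> np.ndarray:
    """Log-spaced alpha candidates 1e-6..1e2 scaled by tr(K'K)/tr(W'W)."""
    Km = _as_matrix(K)
    n_p = Km.shape[1]
    Wop = _as_W(W, n_p)
    trK = float(np.einsum("ij,ij->", Km, Km))
    if Wop is None:
        trW = float(n_p)
    elif sp.issparse(Wop):
        trW = float((Wop.multiply(Wop)).sum())
    else:
        trW = float(np.einsum("ij,ij->", Wop, Wop))
    return np.logspace(-6, 2, n) * trK / trW


def choose_alpha(K, Phi: np.ndarray, W=None,
                 grid: np.ndarray | None = None) -> float:
    """Pick alpha from a grid by generalized cross-validation.

    GCV(alpha) = n ||Phi - K J_alpha||^2 / tr(I - H_alpha)^2 with
    H = K (K'K + alpha W'W + ridge I)^{-1} K'. The grid value with the
    smallest score wins; ties go to the larger alpha (more smoothing),
    except that scores at the round-off floor (residuals indistinguishable
    from an exact fit) count as perfect, and among perfect fits the
    *smallest* alpha wins — when the data are exactly consistent, the
    least-regularized solution is the right one.
    """
    Km = _as_matrix(K)
    Phi = np.asarray(Phi, dtype=float)
    Phi2 = Phi[:, None] if Phi.ndim == 1 else Phi
    if grid is None:
        grid = default_alpha_grid(Km, W)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("alpha grid must be non-empty and positive")
    n_s, n_p = Km.shape
    Wop = _as_W(W, n_p)
    WtW = None if Wop is None else (Wop.T @ Wop)

    scores = np.full(grid.size, np.inf)
    for i, a in enumerate(np.sort(grid)):
        rid = _ridge(Km, WtW, a)
        if WtW is None:
            M_inv_Kt = Km.T / (a + rid)
        else:
            M = a * WtW + rid * sp.eye(n_p, format="csr")
            M = M.tocsc() if sp.issparse(M) else M
            M_inv_Kt = (spla.splu(M).solve(Km.T) if sp.issparse(M)
                        else np.linalg.solve(M, Km.T))
        B = Km @ M_inv_Kt                      # sensors x sensors
        Gi = np.linalg.inv(B + np.eye(n_s))    # (B+I)^{-1} = I - H
        J = M_inv_Kt @ (Gi @ Phi2)
        rss = float(np.sum((Phi2 - Km @ J) ** 2))
        tr_ImH = float(np.trace(Gi))
        scores[i] = np.inf if tr_ImH <= 0 else n_s * rss / tr_ImH ** 2
    if not np.any(np.isfinite(scores)):
        raise ValueError("GCV score non-finite for every grid value")
    order = np.sort(grid)
    if n_s > n_p:
        # exact fit is informative only when the system is overdetermined
        # (an underdetermined system reproduces any data at small alpha)
        floor = 1e-10 * float(np.sum(Phi2 ** 2)) / n_s
        perfect = np.flatnonzero(scores <= floor)
        if perfect.size:
            return float(order[perfect[0]])
    # ties at numerical resolution resolve to the larger (smoother) alpha
    best = np.flatnonzero(scores <= scores.min() * (1 + 1e-12))[-1]
    return float(order[best])
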