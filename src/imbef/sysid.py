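"""Output-only subspace identification of innovation-form state-space models.

The model for a scalar series y_k is

    u_{k+1} = A u_k + K e_k
    y_k     = B u_k + e_k

with state u_k in R^n, dynamics A (n x n), output map B (1 x n), steady-state
Kalman gain K (n x 1) and white innovations e_k.  Estimation follows the
classical stochastic subspace route: mean removal, block-Hankel matrices of
past/future outputs, orthogonal projection of the future row space onto the
past, CVA-weighted SVD truncated at the requested order, A from the shift
invariance of the extended observability matrix, B from its first row, and K
from the joint least-squares regression of the state/output residuals.

The (A, B, K) parameterization is unique only up to a similarity transform,
so the decomposition is canonicalized deterministically (states ordered by
descending singular value, each left singular vector signed so its
largest-magnitude entry is positive): the same series always yields the same
matrix entries, which matters because those entries are used directly as
classification features downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: estimation needs at least this many samples per Hankel block row
MIN_SAMPLES_PER_HORIZON = 10


@dataclass(frozen=True)
class SSModel:
    """Estimated innovation-form model for one scalar series."""

    A: np.ndarray  # (n, n) dynamics
    B: np.ndarray  # (1, n) output map
    K: np.ndarray  # (n, 1) steady-state Kalman gain
    order: int
    residual_variance: float = float("nan")

    def __post_init__(self):
        n = self.order
        A = np.asarray(self.A, dtype=float).reshape(n, n)
        B = np.asarray(self.B, dtype=float).reshape(1, n)
        K = np.asarray(self.K, dtype=float).reshape(n, 1)
        for name, M in (("A", A), ("B", B), ("K", K)):
            if not np.all(np.isfinite(M)):
                raise ValueError(f"non-finite entries in {name}")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        object.__setattr__(self, "K", K)

    @property
    def n_params(self) -> int:
        return self.order ** 2 + 2 * self.order

    @property
    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)

    def parameter_vector(self) -> np.ndarray:
        """[vec(A) row-major, B, K] — the feature layout used downstream."""
        return np.concatenate([self.A.ravel(), self.B.ravel(), self.K.ravel()])


def default_horizon(order: int) -> int:
    return 2 * order + 1


def estimate_ssm(y: np.ndarray, order: int, horizon: int | None = None) -> SSModel:
    """Fit an order-n innovation model to a scalar series.

    Deterministic: repeated calls on the same input return identical
    matrices.  Raises on constant input, on series shorter than
    ``MIN_SAMPLES_PER_HORIZON * horizon`` samples, and when the requested
    order exceeds the numerically observable rank of the projection.
    """
    y = np.asarray(y, dtype=float).ravel()
    if order < 1:
        raise ValueError("order must be >= 1")
    i = default_horizon(order) if horizon is None else int(horizon)
    if i <= order:
        raise ValueError(f"horizon {i} must exceed the order {order}")
    if y.size < MIN_SAMPLES_PER_HORIZON * i:
        raise ValueError(
            f"series of length {y.size} too short for horizon {i}; "
            f"need at least {MIN_SAMPLES_PER_HORIZON * i} samples"
        )
    y = y - y.mean()
    if np.max(np.abs(y)) == 0.0 or np.var(y) < 1e-300:
        raise ValueError("series has zero variance; model is unidentifiable")

    n_cols = y.size - 2 * i + 1
    hank = np.lib.stride_tricks.sliding_window_view(y, n_cols)[: 2 * i]
    scale = 1.0 / np.sqrt(n_cols)
    past, future = hank[:i] * scale, hank[i:] * scale

    # orthogonal projection of the future row space onto the past
    gains, *_ = np.linalg.lstsq(past.T, future.T, rcond=None)
    proj = gains.T @ past

    # CVA weighting: whiten by the future output covariance
    r_ff = future @ future.T
    try:
        chol = np.linalg.cholesky(r_ff)
        weighted = np.linalg.solve(chol, proj)
    except np.linalg.LinAlgError:
        chol = np.eye(i)
        weighted = proj
    U, s, Vt = np.linalg.svd(weighted, full_matrices=False)

    if s[0] <= 0 or s[order - 1] <= 1e-10 * s[0]:
        eff = int(np.sum(s > 1e-10 * s[0]))
        raise ValueError(
            f"requested order {order} exceeds the effective rank {eff} of the "
            "projection"
        )

    # canonical sign: largest-magnitude entry of each left singular vector > 0
    for k in range(order):
        pivot = np.argmax(np.abs(U[:, k]))
        if U[pivot, k] < 0:
            U[:, k] = -U[:, k]
            Vt[k] = -Vt[k]

    gamma = chol @ (U[:, :order] * np.sqrt(s[:order]))  # extended observability
    A, *_ = np.linalg.lstsq(gamma[:-1], gamma[1:], rcond=None)
    B = gamma[0].copy()

    # state sequence (times i .. i+N-1) for the innovation regression
    states, *_ = np.linalg.lstsq(gamma, proj, rcond=None)
    x_now, x_next = states[:, :-1], states[:, 1:]
    y_now = y[i : i + n_cols - 1] * scale
    e = y_now - B @ x_now
    ete = float(e @ e)
    if ete <= 0:
        raise ValueError("innovation variance vanished; cannot estimate K")
    K = ((x_next - A @ x_now) @ e) / ete
    residual_variance = float(np.var(e)) * n_cols

    return SSModel(A=A, B=B.reshape(1, -1), K=K.reshape(-1, 1), order=order,
                   residual_variance=residual_variance)


def simulate_ssm(model: SSModel, T: int, noise_sd: float, seed: int,
                 u0: np.ndarray | None = None) -> np.ndarray:
    """Forward recursion of the innovation model with Gaussian e_k.

    Reproducible under ``seed``; with ``noise_sd=0`` and zero initial state
    the output is identically zero.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if model.spectral_radius >= 1.0:
        import warnings

        warnings.warn("simulating an unstable model; output may diverge",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, noise_sd, size=T)
    n = model.order
    u = np.zeros(n) if u0 is None else np.asarray(u0, dtype=float).reshape(n)
    A, B, K = model.A, model.B.ravel(), model.K.ravel()
    y = np.empty(T)
    for k in range(T):
        y[k] = B @ u + e[k]
        u = A @ u + K * e[k]
    return y


def one_step_residuals(model: SSModel, y: np.ndarray) -> np.ndarray:
    """Innovations of ``y`` (mean removed) under the fitted predictor."""
    y = np.asarray(y, dtype=float).ravel()
    y = y - y.mean()
    A, B, K = model.A, model.B.ravel(), model.K.ravel()
    u = np.zeros(model.order)
    e = np.empty(y.size)
    for k in range(y.size):
        e[k] = y[k] - B @ u
        u = A @ u + K * e[k]
    return e
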