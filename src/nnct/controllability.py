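"""Average and modal controllability of a structural connectome.

The connectome is treated as the system matrix of a noise-free linear
time-invariant model of regional activity,

    x(t+1) = A x(t) + B_K u_K(t)          (discrete time)

where x is the regional activity state and B_K selects the control nodes.
Because the raw adjacency matrix generally has spectral radius >= 1, it is
first scaled to A / (c + sigma_max(A)) with c = 1 by default, the standard
stabilization in the network-control literature; the continuous-time variant
subtracts the identity so that all eigenvalue real parts are negative.

Two complementary node-level diagnostics are computed:

* **average controllability** — Trace(W_k) of the single-node controllability
  Gramian W_k = sum_t A^t e_k e_k^T A^t, the energy of the impulse response
  from node k; large values mean node k can steer the system to many nearby,
  low-energy states.
* **modal controllability** — phi_i = sum_j (1 - lambda_j^2) v_ij^2 over the
  eigenmodes (lambda_j, v_j) of A; large values mean node i couples to the
  fast-decaying, hard-to-reach modes and can push the system to distant
  states.

Whole-brain values are the arithmetic means of the regional vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    ValidationError,
)
from .io import Connectome


@dataclass(frozen=True)
class NormalizedSystem:
    """A stabilized system matrix plus the scaling that produced it.

    ``mode`` is ``"discrete"`` (spectral radius < 1) or ``"continuous"``
    (all eigenvalue real parts < 0); ``scale`` is the divisor applied to the
    raw adjacency matrix.
    """

    A_norm: np.ndarray
    scale: float
    mode: str


@dataclass(frozen=True)
class ControllabilityProfile:
    """Per-node average/modal controllability and their whole-brain means."""

    node_ids: tuple
    avg: np.ndarray
    modal: np.ndarray
    whole_brain_avg: float
    whole_brain_modal: float


def normalize_adjacency(
    C: Connectome | np.ndarray,
    mode: str = "discrete",
    offset: float = 1.0,
) -> NormalizedSystem:
    """Scale an adjacency matrix for Gramian convergence.

    discrete:   A_norm = A / (offset + sigma_max(A))
    continuous: A_norm = A / (offset + sigma_max(A)) - I

    ``offset`` must be > 0 so that the scaled spectral radius is < 1 even for
    matrices whose largest eigenvalue equals sigma_max.  The all-zero matrix
    is allowed (scale = offset).
    """
    A = C.A if isinstance(C, Connectome) else np.asarray(C, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValidationError("adjacency contains NaN or Inf")
    if offset <= 0:
        raise ValidationError("normalization offset must be positive")
    if A.size == 0:
        raise DegenerateInputError("empty adjacency matrix")
    smax = float(np.linalg.norm(A, 2)) if np.any(A) else 0.0
    scale = offset + smax
    A_norm = A / scale
    if mode == "continuous":
        A_norm = A_norm - np.eye(A.shape[0])
    elif mode != "discrete":
        raise ValidationError(f"unknown mode {mode!r}")
    return NormalizedSystem(A_norm=A_norm, scale=scale, mode=mode)


def average_controllability(S: NormalizedSystem) -> np.ndarray:
    """Trace of the single-node controllability Gramian for every node.

    With B = e_k, Trace(W_k) = sum_t ||A^t e_k||^2, which is the k-th
    diagonal entry of the solution X of the discrete Lyapunov equation
    X = A^T X A + I.  One Lyapunov solve therefore yields all nodes at once;
    the geometric series converges iff the spectral radius of A is < 1.
    """
    _require_mode(S, "discrete")
    A = S.A_norm
    rho = float(np.max(np.abs(np.linalg.eigvals(A)))) if np.any(A) else 0.0
    if rho >= 1.0:
        raise ConvergenceError(
            f"spectral radius {rho:.6g} >= 1: controllability Gramian diverges"
        )
    if not np.any(A):
        return np.ones(A.shape[0])
    X = linalg.solve_discrete_lyapunov(A.T, np.eye(A.shape[0]))
    return np.diag(X).copy()


def modal_controllability(S: NormalizedSystem) -> np.ndarray:
    """phi_i = sum_j (1 - lambda_j^2) v_ij^2 over the eigenmodes of A_norm.

    Requires a symmetric A_norm (real eigensystem, orthonormal eigenvectors),
    which also guarantees 0 < phi_i <= 1 whenever the spectral radius is < 1.
    """
    _require_mode(S, "discrete")
    A = S.A_norm
    if np.max(np.abs(A - A.T), initial=0.0) > 1e-10:
        raise ValidationError("modal controllability requires a symmetric matrix")
    lam, V = np.linalg.eigh(A)
    return ((1.0 - lam**2) * V**2).sum(axis=1)


def profile(C: Connectome, offset: float = 1.0) -> ControllabilityProfile:
    """Normalize (discrete) and compute the full controllability profile."""
    S = normalize_adjacency(C, mode="discrete", offset=offset)
    avg = average_controllability(S)
    modal = modal_controllability(S)
    return ControllabilityProfile(
        node_ids=tuple(C.node_ids),
        avg=avg,
        modal=modal,
        whole_brain_avg=float(avg.mean()),
        whole_brain_modal=float(modal.mean()),
    )


def normalize_regional(values: np.ndarray) -> np.ndarray:
    """Z-score a regional vector across nodes (sample standard deviation)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise DegenerateInputError("need a 1-D vector with at least 2 nodes")
    sd = values.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance across nodes")
    return (values - values.mean()) / sd


def _require_mode(S: NormalizedSystem, mode: str) -> None:
    if S.mode != mode:
        raise ValidationError(f"operation requires a {mode}-mode system, got {S.mode}")
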