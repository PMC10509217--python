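"""Optimal-control energy for transitions to network activation states.

A state transition is modelled in continuous time on the stabilized
connectome, dx/dt = A x + B u, starting from the resting baseline x(0) = 0
and ending at a target activation state x(T) in which every node of one
canonical functional network is at magnitude 1 and all others at 0.  The
control cost is the Hamiltonian

    H(p, x, u, t) = x^T x + u^T u + p^T (A x + B u)

whose stationarity condition gives the optimal input u* = -1/2 B^T p, with
state and costate evolving as the linear Hamiltonian system

    d/dt [x; p] = [[A, -1/2 B B^T], [-2 I, -A^T]] [x; p]

(the -2I block vanishes when the state-cost term is disabled, which reduces
the problem to the classical minimum-energy transition).  The two-point
boundary conditions x(0) = x0, x(T) = xT are imposed through the block
matrix exponential over [0, T]: p(0) is obtained from one linear solve, and
the trajectory follows deterministically — no shooting iteration.

The per-node energy is E_k = integral_0^T u*_k(t)^2 dt (trapezoidal rule on
a uniform grid), and a network's activation cost is the sum over nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    SolvabilityError,
    ValidationError,
)
from .controllability import NormalizedSystem, normalize_adjacency
from .io import Atlas, Connectome, check_atlas_matches


@dataclass(frozen=True)
class ControlTask:
    """A baseline -> target transition over horizon ``T``.

    ``control_set`` lists controlled node indices (``None`` = all nodes:
    every region can receive input, matching per-node energy maps).
    ``state_cost_on`` keeps the x^T x term of the Hamiltonian; switching it
    off yields the pure minimum-energy problem, useful for validation
    against the closed-form Gramian solution.
    """

    x0: np.ndarray
    xT: np.ndarray
    T: float = 1.0
    control_set: tuple | None = None
    state_cost_on: bool = True

    def __post_init__(self):
        x0 = np.asarray(self.x0, dtype=float)
        xT = np.asarray(self.xT, dtype=float)
        object.__setattr__(self, "x0", x0)
        object.__setattr__(self, "xT", xT)
        if x0.shape != xT.shape or x0.ndim != 1:
            raise ValidationError("x0 and xT must be 1-D vectors of equal length")
        if not self.T > 0:
            raise ValidationError("horizon T must be positive")


@dataclass(frozen=True)
class OptimalTrajectory:
    """Solution of the two-point boundary-value problem on a uniform grid.

    ``u`` has one row per *controlled* node, in ``control_set`` order.
    """

    times: np.ndarray
    x: np.ndarray  # (n, n_grid)
    p: np.ndarray  # (n, n_grid)
    u: np.ndarray  # (m, n_grid)
    control_set: tuple
    endpoint_error: float


@dataclass(frozen=True)
class EnergyProfile:
    """Per-node control energy for one target network."""

    node_ids: tuple
    per_node: np.ndarray
    total: float
    target_network: str = ""


def build_target_state(atlas: Atlas, network: str) -> np.ndarray:
    """Activation state: 1 on every node of ``network``, 0 elsewhere."""
    mask = atlas.network_members(network)
    if not mask.any():
        raise DegenerateInputError(f"network {network!r} has no member nodes")
    return mask.astype(float)


def solve_optimal_control(
    S: NormalizedSystem,
    task: ControlTask,
    n_grid: int = 1001,
    endpoint_tol: float = 1e-6,
) -> OptimalTrajectory:
    """Solve the optimal-control two-point boundary-value problem."""
    if S.mode != "continuous":
        raise ValidationError("energy computations require a continuous-mode system")
    A = S.A_norm
    n = A.shape[0]
    if task.x0.size != n:
        raise ValidationError(f"state dimension {task.x0.size} != system dimension {n}")
    if n_grid < 2:
        raise ValidationError("n_grid must be >= 2")

    control_set = (
        tuple(range(n)) if task.control_set is None else tuple(task.control_set)
    )
    if len(set(control_set)) != len(control_set):
        raise ValidationError("duplicate nodes in control_set")
    B = np.eye(n)[:, list(control_set)]

    BBt = B @ B.T
    Z = np.zeros((2 * n, 2 * n))
    Z[:n, :n] = A
    Z[:n, n:] = -0.5 * BBt
    if task.state_cost_on:
        Z[n:, :n] = -2.0 * np.eye(n)
    Z[n:, n:] = -A.T

    M = linalg.expm(Z * task.T)
    M11, M12 = M[:n, :n], M[:n, n:]
    try:
        p0 = linalg.solve(M12, task.xT - M11 @ task.x0)
    except linalg.LinAlgError:
        raise SolvabilityError(
            "singular boundary map: target unreachable with this control set"
        )
    if not np.all(np.isfinite(p0)):
        raise SolvabilityError("boundary solve produced non-finite costate")

    times = np.linspace(0.0, task.T, n_grid)
    step = linalg.expm(Z * (times[1] - times[0]))
    y = np.concatenate([task.x0, p0])
    traj = np.empty((2 * n, n_grid))
    traj[:, 0] = y
    for i in range(1, n_grid):
        y = step @ y
        traj[:, i] = y
    x = traj[:n]
    p = traj[n:]
    u = -0.5 * (B.T @ p)

    endpoint_error = float(np.linalg.norm(x[:, -1] - task.xT))
    if endpoint_error > endpoint_tol:
        raise ConvergenceError(
            f"endpoint error {endpoint_error:.3g} exceeds tolerance {endpoint_tol:.3g}"
        )
    return OptimalTrajectory(
        times=times,
        x=x,
        p=p,
        u=u,
        control_set=control_set,
        endpoint_error=endpoint_error,
    )


def nodal_energy(
    traj: OptimalTrajectory,
    node_ids: tuple | None = None,
    target_network: str = "",
) -> EnergyProfile:
    """Integrate per-node input energy E_k = int u_k(t)^2 dt (trapezoid).

    Uncontrolled nodes receive energy 0.
    """
    n = traj.x.shape[0]
    per_node = np.zeros(n)
    energies = np.trapezoid(traj.u**2, traj.times, axis=1)
    for k, e in zip(traj.control_set, energies):
        per_node[k] = e
    ids = tuple(node_ids) if node_ids is not None else tuple(f"n{i+1:03d}" for i in range(n))
    return EnergyProfile(
        node_ids=ids,
        per_node=per_node,
        total=float(per_node.sum()),
        target_network=target_network,
    )


def network_energy_table(
    C: Connectome,
    atlas: Atlas,
    T: float = 1.0,
    n_grid: int = 1001,
    state_cost_on: bool = True,
    control_set: tuple | None = None,
    offset: float = 1.0,
) -> dict:
    """Energy profiles for transitions to every functional network present.

    Returns an ordered mapping ``network -> EnergyProfile`` covering each
    canonical network with at least one member node in ``atlas``.  The block
    Hamiltonian matrix depends only on the connectome, so its exponentials
    are shared across the eight targets.
    """
    check_atlas_matches(C, atlas)
    S = normalize_adjacency(C, mode="continuous", offset=offset)
    x0 = np.zeros(C.n_nodes)
    out: dict = {}
    for network in atlas.networks_present():
        xT = build_target_state(atlas, network)
        task = ControlTask(
            x0=x0, xT=xT, T=T, control_set=control_set, state_cost_on=state_cost_on
        )
        traj = solve_optimal_control(S, task, n_grid=n_grid)
        out[network] = nodal_energy(traj, node_ids=C.node_ids, target_network=network)
    return out
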