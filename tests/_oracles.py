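"""Independent brute-force oracles used to cross-check the implementation.

These deliberately take different computational routes than the package:
truncated geometric series instead of a Lyapunov solve, a discretized
quadratic program instead of the boundary-value matrix exponential, and the
Van Loan integral formula for the finite-horizon reachability Gramian.
"""

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spl
from scipy import linalg


def ac_series(A: np.ndarray, n_terms: int = 400) -> np.ndarray:
    """Average controllability by direct summation of sum_t ||A^t e_k||^2."""
    n = A.shape[0]
    out = np.zeros(n)
    P = np.eye(n)
    for _ in range(n_terms + 1):
        out += (P**2).sum(axis=0)
        P = A @ P
    return out


def collocation_energy(A, B, x0, xT, T, state_cost_on=True, n_steps=2000):
    """Direct-collocation QP: piecewise-constant control, Euler dynamics.

    Minimizes dt * (sum_k x_k^T x_k + sum_k u_k^T u_k) subject to
    x_{k+1} = (I + dt A) x_k + dt B u_k and x_N = xT, by solving the sparse
    KKT system.  Returns (input_energy, controls).
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    n, m = B.shape
    N = n_steps
    dt = T / N
    Ad = np.eye(n) + dt * A
    Bd = dt * B
    nz = N * n + N * m  # x_1..x_N then u_0..u_{N-1}

    def xi(k):  # x_k, k = 1..N
        return (k - 1) * n

    def ui(k):  # u_k, k = 0..N-1
        return N * n + k * m

    H = np.zeros(nz)
    if state_cost_on:
        for k in range(1, N + 1):
            w = 0.5 if k == N else 1.0  # trapezoid weight (x_0 = x0 is fixed)
            H[xi(k) : xi(k) + n] = 2 * dt * w
    for k in range(N):
        H[ui(k) : ui(k) + m] = 2 * dt

    rows, cols, vals, rhs = [], [], [], []
    r = 0
    for k in range(N):
        for i in range(n):
            rows.append(r); cols.append(xi(k + 1) + i); vals.append(1.0)
            if k > 0:
                for j in range(n):
                    rows.append(r); cols.append(xi(k) + j); vals.append(-Ad[i, j])
            for j in range(m):
                rows.append(r); cols.append(ui(k) + j); vals.append(-Bd[i, j])
            rhs.append((Ad @ x0)[i] if k == 0 else 0.0)
            r += 1
    for i in range(n):
        rows.append(r); cols.append(xi(N) + i); vals.append(1.0)
        rhs.append(xT[i])
        r += 1
    C = sp.csr_matrix((vals, (rows, cols)), shape=(r, nz))
    K = sp.bmat([[sp.diags(H), C.T], [C, None]], format="csc")
    sol = spl.spsolve(K, np.concatenate([np.zeros(nz), rhs]))
    U = sol[N * n : nz].reshape(N, m)
    return float(dt * np.sum(U**2)), U


def minimum_energy_closed_form(A, B, x0, xT, T):
    """Closed-form minimum input energy via the finite-horizon reachability
    Gramian W_c(T) = int_0^T e^{As} B B^T e^{A^T s} ds (Van Loan blocks)."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    n = A.shape[0]
    Z = np.zeros((2 * n, 2 * n))
    Z[:n, :n] = -A
    Z[:n, n:] = B @ B.T
    Z[n:, n:] = A.T
    F = linalg.expm(Z * T)
    Wc = F[n:, n:].T @ F[:n, n:]
    nu = xT - linalg.expm(A * T) @ x0
    return float(nu @ np.linalg.solve(Wc, nu))


def bh_reject_bruteforce(p_values, q):
    """Benjamini-Hochberg step-up by literal evaluation of the definition:
    find the largest k with p_(k) <= k q / m and reject all p <= p_(k)."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.sort(p)
    k_star = 0
    for k in range(1, m + 1):
        if order[k - 1] <= k * q / m:
            k_star = k
    if k_star == 0:
        return np.zeros(m, dtype=bool)
    return p <= order[k_star - 1]
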