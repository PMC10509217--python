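"""Degree- and strength-preserving null networks and energy comparisons.

Surrogates are built in two stages.  First the binary topology is randomized
with Maslov–Sneppen double-edge swaps, which preserves every node's binary
degree exactly.  Second, the original multiset of edge weights is reassigned
to the rewired edges by a greedy rank-matching rule: weights are placed in
descending order on the free edge whose endpoints have the largest residual
target strength (the node strengths of the original network).  The weight
multiset is therefore preserved bit-exactly and the strength sequence is
approximated; with the default swap intensity the surrogate strength
sequence rank-correlates with the original well above 0.9 on sparse modular
networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, ParameterError
from .io import Atlas, Connectome
from .energy import network_energy_table


@dataclass
class NullEnsemble:
    """An original connectome with its randomized surrogates."""

    original: Connectome
    surrogates: list
    seed: int
    n_swaps_per_edge: int


def rewire_null(
    C: Connectome,
    seed: int,
    n_swaps_per_edge: int = 10,
) -> Connectome:
    """One degree-preserving, strength-matching surrogate of ``C``."""
    if n_swaps_per_edge < 1:
        raise ParameterError("n_swaps_per_edge must be >= 1")
    n = C.n_nodes
    iu = np.triu_indices(n, 1)
    present = C.A[iu] > 0
    edges = list(zip(iu[0][present], iu[1][present]))
    weights = C.A[iu][present]
    m = len(edges)
    if m < 2:
        raise DegenerateInputError("need at least 2 edges to rewire")

    G = nx.Graph()
    G.add_nodes_from(range(n))
    G.add_edges_from(edges)
    try:
        nx.double_edge_swap(
            G,
            nswap=n_swaps_per_edge * m,
            max_tries=100 * n_swaps_per_edge * m,
            seed=int(seed),
        )
    except nx.NetworkXError as exc:
        raise DegenerateInputError(f"graph cannot be rewired: {exc}")

    new_edges = np.array(sorted(tuple(sorted(e)) for e in G.edges()), dtype=int)
    # greedy rank-matching: heaviest weight to the free edge whose endpoints
    # have the highest residual target strength
    target = C.strengths().astype(float)
    residual = target.copy()
    A_new = np.zeros_like(C.A)
    free = np.ones(m, dtype=bool)
    u, v = new_edges[:, 0], new_edges[:, 1]
    for w in np.sort(weights)[::-1]:
        scores = residual[u] + residual[v]
        scores[~free] = -np.inf
        j = int(np.argmax(scores))
        free[j] = False
        A_new[u[j], v[j]] = A_new[v[j], u[j]] = w
        residual[u[j]] -= w
        residual[v[j]] -= w
    return Connectome(node_ids=C.node_ids, A=A_new)


def null_ensemble(
    C: Connectome,
    n_null: int,
    seed: int,
    n_swaps_per_edge: int = 10,
) -> NullEnsemble:
    """Generate ``n_null`` seeded surrogates (seed + i for surrogate i)."""
    if n_null < 1:
        raise ParameterError("n_null must be >= 1")
    surrogates = [
        rewire_null(C, seed=seed + i, n_swaps_per_edge=n_swaps_per_edge)
        for i in range(n_null)
    ]
    return NullEnsemble(
        original=C, surrogates=surrogates, seed=seed, n_swaps_per_edge=n_swaps_per_edge
    )


def strength_rank_correlation(C: Connectome, surrogate: Connectome) -> float:
    """Spearman rank correlation between original and surrogate strengths."""
    rho = stats.spearmanr(C.strengths(), surrogate.strengths()).statistic
    return float(rho)


def energy_vs_null(
    C: Connectome,
    atlas: Atlas,
    n_null: int,
    seed: int,
    n_swaps_per_edge: int = 10,
    T: float = 1.0,
    n_grid: int = 1001,
    state_cost_on: bool = True,
) -> pd.DataFrame:
    """Compare per-network activation energy of ``C`` with its surrogates.

    For each functional network the real total energy is tested against the
    surrogate distribution both parametrically (paired two-sided t-test of
    the surrogate-minus-real differences) and nonparametrically (percentile
    of the real value among the surrogates).  Small ensembles make the
    t-test fragile, which is why both are reported.

    Returns a DataFrame with one row per network: ``network, real_total,
    null_mean, null_sd, t, p, percentile, degenerate``.
    """
    if n_null < 2:
        raise ParameterError("n_null must be >= 2 for a paired comparison")
    ens = null_ensemble(C, n_null=n_null, seed=seed, n_swaps_per_edge=n_swaps_per_edge)
    kwargs = dict(T=T, n_grid=n_grid, state_cost_on=state_cost_on)
    real = {nw: ep.total for nw, ep in network_energy_table(C, atlas, **kwargs).items()}
    null_totals = {nw: [] for nw in real}
    for surr in ens.surrogates:
        table = network_energy_table(surr, atlas, **kwargs)
        for nw in real:
            null_totals[nw].append(table[nw].total)

    rows = []
    for nw, totals in null_totals.items():
        totals = np.asarray(totals)
        diffs = totals - real[nw]
        degenerate = bool(np.allclose(diffs, 0.0))
        if degenerate:
            t = p = np.nan
        else:
            res = stats.ttest_1samp(diffs, 0.0)
            t, p = float(res.statistic), float(res.pvalue)
        percentile = float(100.0 * np.mean(totals < real[nw]))
        rows.append(
            {
                "network": nw,
                "real_total": real[nw],
                "null_mean": float(totals.mean()),
                "null_sd": float(totals.std(ddof=1)),
                "t": t,
                "p": p,
                "percentile": percentile,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
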