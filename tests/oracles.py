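"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own algorithms: attribution by
explicit path enumeration with proportional splitting (valid on acyclic
networks), attribution by direct linear solve, and plain double loops for
zonal and impact sums.
"""

import numpy as np


def path_enumeration_attribution(T: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Origin attribution on an acyclic flow network by DFS over paths.

    A tonne produced at ``o`` entering country ``m``'s supply is consumed
    there in proportion consumption/supply and forwarded along each
    outgoing edge in proportion flow/supply. Returns [consumer, origin]
    attributed tonnes. Recursion only terminates on DAGs.
    """
    n = len(P)
    supply = P + T.sum(axis=0)
    exports = T.sum(axis=1)
    consumption = supply - exports
    with np.errstate(divide="ignore", invalid="ignore"):
        retain = np.where(supply > 0, consumption / supply, 0.0)
        fwd = np.where(supply[:, None] > 0, T / supply[:, None], 0.0)
    A = np.zeros((n, n))

    def dfs(origin: int, node: int, mass: float) -> None:
        if mass <= 0:
            return
        A[node, origin] += mass * retain[node]
        for nxt in range(n):
            if T[node, nxt] > 0:
                dfs(origin, nxt, mass * fwd[node, nxt])

    for o in range(n):
        dfs(o, o, P[o])
    return A


def linear_solve_attribution(T: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Origin attribution by solving the supply-mix balance directly.

    X = diag(P) (I - F)^{-1} with F the supply-normalised flow matrix;
    attribution scales each country's supply mix by its consumption.
    """
    n = len(P)
    supply = P + T.sum(axis=0)
    exports = T.sum(axis=1)
    consumption = supply - exports
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(supply[:, None] > 0, T / supply[:, None], 0.0)
    X = np.diag(P) @ np.linalg.inv(np.eye(n) - F)
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(supply[None, :] > 0, X / supply[None, :], 0.0)
    return (M * consumption[None, :]).T


def random_acyclic_network(rng: np.random.Generator, n: int):
    """Random DAG trade network with exports strictly within supply."""
    P = rng.uniform(10.0, 200.0, size=n)
    T = np.zeros((n, n))
    supply = P.copy()
    for i in range(n - 1):
        targets = [j for j in range(i + 1, n) if rng.random() < 0.6]
        if not targets:
            continue
        export_frac = rng.uniform(0.0, 0.9)
        shares = rng.dirichlet(np.ones(len(targets)))
        for j, sh in zip(targets, shares):
            T[i, j] = supply[i] * export_frac * sh
            supply[j] += T[i, j]
    return T, P


def loop_zonal_sum(values, valid, codes, code) -> float:
    total = 0.0
    nr, nc = values.shape
    for r in range(nr):
        for c in range(nc):
            if valid[r, c] and codes[r, c] == code:
                total += values[r, c]
    return total


def loop_total_impact(intensity, production, int_valid, prod_valid, fraction) -> float:
    """Sum of dry-weight impact over jointly valid, nonzero-product cells."""
    total = 0.0
    nr, nc = intensity.shape
    for r in range(nr):
        for c in range(nc):
            if int_valid[r, c] and prod_valid[r, c]:
                v = intensity[r, c] * fraction * production[r, c]
                if v != 0.0:
                    total += v
    return total
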