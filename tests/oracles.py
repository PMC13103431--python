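"""Independent brute-force oracles used to validate the implementation."""

from itertools import combinations, product

import numpy as np


def lasso_objective(D, y, x, lam):
    r = y - D @ x
    return 0.5 * float(r @ r) + lam * float(np.sum(np.abs(x)))


def lasso_bruteforce(D, y, lam, tol=1e-10):
    """Exact lasso solution by enumerating active sets and sign patterns.

    Solves min_x ½‖y − Dx‖² + λ‖x‖₁ for small atom counts by solving the
    KKT system on every support/sign combination and keeping the best
    KKT-consistent candidate.  Feasible only for N_D ≲ 8.
    """
    n_atoms = D.shape[1]
    best_x = np.zeros(n_atoms)
    best_obj = lasso_objective(D, y, best_x, lam)
    # the zero vector is optimal iff max |D^T y| <= lam; still enumerate
    for k in range(1, n_atoms + 1):
        for support in combinations(range(n_atoms), k):
            A = D[:, support]
            G = A.T @ A
            for signs in product((-1.0, 1.0), repeat=k):
                s = np.asarray(signs)
                try:
                    xa = np.linalg.solve(G, A.T @ y - lam * s)
                except np.linalg.LinAlgError:
                    continue
                if np.any(np.sign(xa) != s):
                    continue
                x = np.zeros(n_atoms)
                x[list(support)] = xa
                grad = D.T @ (D @ x - y)
                if np.max(np.abs(grad)) > lam + 1e-7:
                    continue
                obj = lasso_objective(D, y, x, lam)
                if obj < best_obj - tol:
                    best_obj = obj
                    best_x = x
    return best_x, best_obj


def brute_isolation(traces, d):
    """Row indices whose nearest neighbour is strictly further than d."""
    traces = np.asarray(traces, dtype=float)
    n = traces.shape[0]
    removed = []
    for i in range(n):
        dists = np.linalg.norm(traces - traces[i], axis=1)
        dists[i] = np.inf
        if dists.min() > d:
            removed.append(i)
    return removed


def brute_distance_matrix(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = a.shape[0], b.shape[0]
    D = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            D[i, j] = np.sqrt(np.sum((a[i] - b[j]) ** 2))
    return D


def dense_component_curve(protocol, component, kinetics, dt=1.0):
    """Dense-grid closed-form evaluation of a component basis.

    Re-implements the piecewise kinetics independently (scalar loop over
    a dt-spaced grid, carrying the phase-start value explicitly).
    """
    import math

    times = np.arange(0.0, protocol.total_duration + dt / 2, dt)
    out = np.empty_like(times)
    for idx, t in enumerate(times):
        v0 = 0.0
        for ph in protocol.phases:
            end = ph.start + ph.duration
            t_in = min(t, end) - ph.start
            if t_in < 0:
                break
            is_light = ph.intensity > 0
            if is_light:
                raw = 1.0 - math.exp(-t_in / kinetics.tau_rise)
                if kinetics.transitory_fraction < 1.0:
                    f = kinetics.transitory_fraction
                    raw *= f + (1 - f) * math.exp(
                        -t_in / kinetics.tau_transitory)
                val = v0 + (1 - v0) * raw
            else:
                if kinetics.frozen_in_dark:
                    val = v0
                else:
                    val = v0 * math.exp(-t_in / kinetics.tau_relax)
            if t <= end:
                out[idx] = val
                break
            v0 = val
        else:
            out[idx] = val
    return times, out
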