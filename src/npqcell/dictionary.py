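"""Sparse dictionary learning of elementary F_m′ waveforms.

Traces (sum-normalized, length T) are modelled as sparse linear
combinations of N_D learned unit-norm atoms by minimizing

    min_{D,X}  ½‖Y − DX‖²_F + λ‖X‖₁

with Y the T×n data matrix, D the T×N_D dictionary and X the N_D×n
coefficient (code) matrix.  The optimization alternates a per-column
lasso solved by least-angle regression with a block atom update under
the unit-norm constraint; both steps decrease the objective, so the
recorded fit history is non-increasing.  The N_D-dimensional codes are
the feature vectors passed to the discriminant projection.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoLars

__all__ = [
    "SparseDictionary",
    "Codes",
    "fit_dictionary",
    "encode",
    "reconstruction_error",
    "select_n_atoms",
]


@dataclass
class SparseDictionary:
    """Learned dictionary: T×N_D matrix of unit-Euclidean-norm atoms."""

    atoms: np.ndarray
    lam: float
    seed: int
    fit_history: list[float] = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[1]

    @property
    def trace_length(self) -> int:
        return self.atoms.shape[0]

    def to_dict(self) -> dict:
        return {"T": self.trace_length, "N_D": self.n_atoms,
                "lambda": self.lam, "seed": self.seed,
                "atoms": self.atoms.ravel().tolist(),
                "fit_history": list(self.fit_history)}

    @classmethod
    def from_dict(cls, d: dict) -> "SparseDictionary":
        atoms = np.asarray(d["atoms"], dtype=float).reshape(d["T"], d["N_D"])
        return cls(atoms=atoms, lam=d["lambda"], seed=d["seed"],
                   fit_history=list(d.get("fit_history", [])))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "SparseDictionary":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Codes:
    """Sparse codes: N_D×n coefficient matrix with source ids."""

    X: np.ndarray
    source_ids: list | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("codes must be finite")


def _lasso_columns(Y: np.ndarray, D: np.ndarray, lam: float) -> np.ndarray:
    """Per-column solution of min_x ½‖y − Dx‖² + λ‖x‖₁ via LARS.

    LassoLars optimizes (1/(2T))‖y − Dx‖² + α‖x‖₁, so α = λ/T recovers
    the unscaled objective.  λ = 0 falls back to least squares.
    """
    T, n = Y.shape
    if lam == 0:
        return np.linalg.lstsq(D, Y, rcond=None)[0]
    alpha = lam / T
    X = np.empty((D.shape[1], n))
    model = LassoLars(alpha=alpha, fit_intercept=False)
    with warnings.catch_warnings():
        # collinear atoms legitimately trigger LARS regressor drops
        warnings.filterwarnings("ignore", category=ConvergenceWarning)
        for j in range(n):
            model.fit(D, Y[:, j])
            X[:, j] = model.coef_
    return X


def _objective(Y, D, X, lam) -> float:
    resid = Y - D @ X
    return 0.5 * float(np.sum(resid * resid)) + lam * float(np.sum(np.abs(X)))


def _update_atoms(Y: np.ndarray, D: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Block coordinate atom update under the unit-norm constraint.

    For each atom j, d_j ← E_j x_j / ‖E_j x_j‖ with E_j the residual
    excluding atom j — the exact minimizer of the reconstruction term
    over unit-norm d_j, hence monotone.  Atoms with (near-)zero usage are
    re-seeded with the worst-reconstructed data column, which leaves the
    objective unchanged (their code row is zero).
    """
    D = D.copy()
    R = Y - D @ X
    for j in range(D.shape[1]):
        x_j = X[j]
        Rj = R + np.outer(D[:, j], x_j)
        v = Rj @ x_j
        norm = np.linalg.norm(v)
        if norm > 1e-12:
            D[:, j] = v / norm
        else:
            col_err = np.sum((Y - D @ X) ** 2, axis=0)
            worst = Y[:, int(np.argmax(col_err))]
            D[:, j] = worst / np.linalg.norm(worst)
        R = Rj - np.outer(D[:, j], x_j)
    return D


def fit_dictionary(Y: np.ndarray, n_atoms: int = 10, lam: float = 1e-6,
                   seed: int = 0, max_iter: int = 200, tol: float = 1e-8,
                   ) -> SparseDictionary:
    """Alternating minimization of the sparse-coding objective.

    ``Y`` is T×n with sum-normalized traces as columns; atoms are
    initialized from ``n_atoms`` randomly chosen (seeded) data columns,
    unit-normalized.  Stops at ``max_iter`` or when the relative
    objective decrease falls below ``tol``.  Deterministic given seed.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be a 2D matrix with traces as columns")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y must be finite")
    T, n = Y.shape
    if n < n_atoms:
        raise ValueError(f"need at least n_atoms={n_atoms} traces, got {n}")
    rng = np.random.default_rng(seed)
    # farthest-point column init: a seeded first pick, then greedily the
    # column furthest from those already chosen — avoids duplicate-atom
    # local minima when the data contain repeated waveforms
    chosen = [int(rng.integers(n))]
    d2 = np.sum((Y - Y[:, chosen[0]][:, None]) ** 2, axis=0)
    while len(chosen) < n_atoms:
        nxt = int(np.argmax(d2))
        if d2[nxt] <= 0:        # all remaining columns duplicate chosen ones
            remaining = np.setdiff1d(np.arange(n), chosen)
            nxt = int(rng.choice(remaining))
        chosen.append(nxt)
        d2 = np.minimum(d2, np.sum((Y - Y[:, nxt][:, None]) ** 2, axis=0))
    D = Y[:, chosen].copy()
    D /= np.linalg.norm(D, axis=0, keepdims=True)
    history: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        X = _lasso_columns(Y, D, lam)
        D = _update_atoms(Y, D, X)
        obj = _objective(Y, D, X, lam)
        history.append(obj)
        if prev - obj <= tol * max(abs(prev), 1e-30):
            break
        prev = obj
    return SparseDictionary(atoms=D, lam=lam, seed=seed, fit_history=history)


def encode(Y: np.ndarray, dictionary: SparseDictionary,
           lam: float | None = None) -> Codes:
    """Sparse-code traces against a fixed dictionary.

    ``Y`` is T×n (or a single length-T vector).  Returns the N_D×n lasso
    codes at ``lam`` (the dictionary's λ by default).
    """
    Y = np.asarray(Y, dtype=float)
    single = Y.ndim == 1
    if single:
        Y = Y[:, None]
    if Y.shape[0] != dictionary.trace_length:
        raise ValueError(
            f"trace length {Y.shape[0]} does not match atom length "
            f"{dictionary.trace_length}")
    if lam is None:
        lam = dictionary.lam
    X = _lasso_columns(Y, dictionary.atoms, lam)
    return Codes(X=X)


def reconstruction_error(Y: np.ndarray, dictionary: SparseDictionary,
                         codes: Codes) -> tuple[np.ndarray, float]:
    """Squared Euclidean residual ‖y − Dx‖² per trace, and its mean."""
    Y = np.asarray(Y, dtype=float)
    resid = Y - dictionary.atoms @ codes.X
    per_trace = np.sum(resid * resid, axis=0)
    return per_trace, float(per_trace.mean())


def select_n_atoms(Y: np.ndarray, candidates: list[int],
                   threshold: float = 2e-4, lam: float = 1e-6,
                   n_seeds: int = 3, base_seed: int = 0) -> int:
    """Smallest dictionary size meeting the reconstruction threshold.

    Fits each candidate size with ``n_seeds`` seeds and returns the
    smallest whose mean per-trace reconstruction error, averaged over
    seeds, is ≤ ``threshold``; if none qualifies, returns the largest
    candidate with a warning.
    """
    if not candidates:
        raise ValueError("candidates must be non-empty")
    candidates = sorted(candidates)
    for n_atoms in candidates:
        errs = []
        for s in range(n_seeds):
            d = fit_dictionary(Y, n_atoms=n_atoms, lam=lam,
                               seed=base_seed + s)
            _, mean_err = reconstruction_error(Y, d, encode(Y, d))
            errs.append(mean_err)
        if float(np.mean(errs)) <= threshold:
            return n_atoms
    warnings.warn("no candidate dictionary size met the reconstruction "
                  "threshold; returning the largest")
    return candidates[-1]
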