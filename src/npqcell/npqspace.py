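"""Projection of sparse codes into the 3D NPQ score space.

A multiclass linear discriminant analysis (LDA) on the dictionary codes
of the four labeled reference populations yields a projection
T ∈ N_D×3 (c − 1 = 3 directions for c = 4 classes).  The LDA axes are
then aligned with biologically named axes: the principal direction of
each single-component population (Pop-qT, Pop-qE, Pop-qI) in LDA space
becomes one column of an oblique transfer matrix R, and per-axis origins
are anchored by the populations known to lack each component:

* q̃T origin — mean of pooled {Pop-qE, Pop-qI, Pop-0} cells (all carry
  the kinase knockout, hence no state transitions);
* q̃E origin — mean of Pop-qI cells (never exposed to high light, so no
  LHCSR expression);
* q̃I origin — mean of pooled {Pop-qE, Pop-qT, Pop-0} cells (late
  protocol repeats, photoinhibition-free).

A cell's score is  (q̃T, q̃E, q̃I) = R⁻¹ · (Tᵗ · x) − origins  with x its
sparse code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg

from . import dictionary as dict_mod
from .preprocess import balanced_subsample, normalize_sum, remove_isolated
from .simulate import LabeledTraceSet

__all__ = [
    "LdaProjection",
    "AxisAlignment",
    "NpqModel",
    "ScoreSet",
    "TrainConfig",
    "fit_lda",
    "class_principal_direction",
    "build_alignment",
    "score_traces",
    "train_pipeline",
]

AXES = ("qT", "qE", "qI")
#: Expressing population per axis, and the populations anchoring each
#: axis origin (those biologically lacking the component).
_EXPRESSING = {"qT": "PopQT", "qE": "PopQE", "qI": "PopQI"}
_ORIGIN_POOL = {
    "qT": ("PopQE", "PopQI", "Pop0"),
    "qE": ("PopQI",),
    "qI": ("PopQE", "PopQT", "Pop0"),
}


@dataclass
class LdaProjection:
    """LDA projection with its scatter matrices."""

    T_matrix: np.ndarray          # (N_D, 3)
    class_means: np.ndarray       # (c, N_D)
    class_labels: list[str]
    S_B: np.ndarray
    S_W: np.ndarray
    eigenvalues: np.ndarray


@dataclass
class AxisAlignment:
    """Oblique change of basis and per-axis origins in LDA space."""

    R: np.ndarray                 # (3, 3), columns = class directions
    origins: np.ndarray           # (3,)
    sign_flipped: tuple[bool, bool, bool] = (False, False, False)


def fit_lda(codes: np.ndarray, labels: list[str], ridge: float = 1e-4,
            n_components: int = 3) -> LdaProjection:
    """Multiclass LDA via the generalized eigenproblem S_B v = μ S_W v.

    S_B is the class-size-weighted between-class scatter, S_W the pooled
    within-class scatter, regularized as S_W + ridge·(tr S_W / p)·I — a
    scale-aware shrinkage that stops near-degenerate code directions
    (almost-collinear atoms) from dominating the projection.  Eigenvector
    signs are fixed deterministically (largest-magnitude entry positive).
    """
    codes = np.asarray(codes, dtype=float)
    labels = list(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("LDA requires at least 2 classes")
    p = codes.shape[1]
    mu = codes.mean(axis=0)
    S_B = np.zeros((p, p))
    S_W = np.zeros((p, p))
    means = []
    lab_arr = np.asarray(labels)
    for c in classes:
        xc = codes[lab_arr == c]
        if xc.shape[0] < 2:
            raise ValueError(f"class {c!r} needs at least 2 samples")
        mc = xc.mean(axis=0)
        means.append(mc)
        d = mc - mu
        S_B += xc.shape[0] * np.outer(d, d)
        xc0 = xc - mc
        S_W += xc0.T @ xc0
    n_components = min(n_components, len(classes) - 1)
    scale = max(np.trace(S_W) / p, np.finfo(float).tiny)
    evals, evecs = linalg.eigh(S_B, S_W + ridge * scale * np.eye(p))
    order = np.argsort(evals)[::-1][:n_components]
    T = evecs[:, order]
    for j in range(T.shape[1]):
        k = int(np.argmax(np.abs(T[:, j])))
        if T[k, j] < 0:
            T[:, j] = -T[:, j]
    return LdaProjection(T_matrix=T, class_means=np.vstack(means),
                         class_labels=classes, S_B=S_B, S_W=S_W,
                         eigenvalues=evals[order])


def class_principal_direction(points: np.ndarray,
                              other_centroid: np.ndarray | None = None,
                              eigengap_tol: float = 1e-3) -> np.ndarray:
    """First principal direction of a point cloud, as a unit vector.

    The sign is fixed so that (class centroid − ``other_centroid``) has a
    positive projection; with no reference centroid the largest-magnitude
    entry is made positive.  Degenerate clouds (zero covariance, or
    relative eigengap below ``eigengap_tol``) raise.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 2:
        raise ValueError("need at least 2 points")
    cov = np.cov(points, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0:
        raise ValueError("degenerate class: zero covariance")
    if len(evals) > 1 and (evals[-1] - evals[-2]) / evals[-1] < eigengap_tol:
        raise ValueError("degenerate class: principal direction is not "
                         "unique (eigengap below tolerance)")
    v = evecs[:, -1]
    v = v / np.linalg.norm(v)
    if other_centroid is not None:
        ref = points.mean(axis=0) - np.asarray(other_centroid, dtype=float)
        if ref @ v < 0:
            v = -v
    else:
        k = int(np.argmax(np.abs(v)))
        if v[k] < 0:
            v = -v
    return v


def build_alignment(projected: np.ndarray, labels: list[str],
                    cond_bound: float = 1e3) -> AxisAlignment:
    """Assemble the transfer matrix R and the per-axis origins.

    ``projected`` holds LDA-space coordinates (n×3) of the four training
    populations.  R's columns are the principal directions of the
    Pop-qT, Pop-qE and Pop-qI clouds (in axis order q̃T, q̃E, q̃I); after
    the R⁻¹ change of basis, each axis origin is the mean over the cells
    biologically lacking that component.  Axis signs are flipped if
    needed so the expressing class scores positive.
    """
    projected = np.asarray(projected, dtype=float)
    lab_arr = np.asarray(list(labels))
    for pop in ("Pop0", "PopQE", "PopQT", "PopQI"):
        if not np.any(lab_arr == pop):
            raise ValueError(f"population {pop!r} missing from training set")
    cols = []
    for axis in AXES:
        pop = _EXPRESSING[axis]
        pts = projected[lab_arr == pop]
        other = projected[lab_arr != pop].mean(axis=0)
        cols.append(class_principal_direction(pts, other_centroid=other))
    R = np.column_stack(cols)
    cond = np.linalg.cond(R)
    if cond > cond_bound:
        raise ValueError(
            f"transfer matrix is ill-conditioned (cond={cond:.3g} > "
            f"{cond_bound:.3g}); class clouds are nearly degenerate")
    flips = [False, False, False]
    for _ in range(2):  # second pass after sign flips converges
        coords = np.linalg.solve(R, projected.T).T
        origins = np.array([
            coords[np.isin(lab_arr, _ORIGIN_POOL[axis]), a].mean()
            for a, axis in enumerate(AXES)
        ])
        aligned = coords - origins
        changed = False
        for a, axis in enumerate(AXES):
            m = aligned[lab_arr == _EXPRESSING[axis], a].mean()
            if m < 0:
                R[:, a] = -R[:, a]
                flips[a] = not flips[a]
                changed = True
        if not changed:
            break
    return AxisAlignment(R=R, origins=origins, sign_flipped=tuple(flips))


@dataclass
class ScoreSet:
    """Per-cell (q̃T, q̃E, q̃I) scores."""

    scores: np.ndarray            # (n, 3) in AXES order
    cell_ids: list[int]
    labels: list[str]
    repeat: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def axis(self, name: str) -> np.ndarray:
        return self.scores[:, AXES.index(name)]

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "cell_id": self.cell_ids,
            "population": self.labels,
            "repeat": self.repeat,
            "qT_score": self.scores[:, 0],
            "qE_score": self.scores[:, 1],
            "qI_score": self.scores[:, 2],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScoreSet":
        df = pd.read_csv(path)
        return cls(
            scores=df[["qT_score", "qE_score", "qI_score"]].to_numpy(float),
            cell_ids=list(df["cell_id"]),
            labels=list(df["population"].astype(str)),
            repeat=int(df["repeat"].iloc[0]) if len(df) else 0,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; all randomness flows from ``seed``."""

    n_atoms: int = 10
    lam: float = 1e-6
    n_samples: int = 300
    isolation_d: float = 0.01
    min_area: int = 5
    ridge: float = 1e-4
    cond_bound: float = 1e3
    max_iter: int = 200
    tol: float = 1e-8
    seed: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_atoms", "lam", "n_samples", "isolation_d", "min_area",
            "ridge", "cond_bound", "max_iter", "tol", "seed")}


@dataclass
class NpqModel:
    """Trained end-to-end scoring model (dictionary → LDA → alignment)."""

    dictionary: dict_mod.SparseDictionary
    projection: LdaProjection
    alignment: AxisAlignment
    config: TrainConfig = field(default_factory=TrainConfig)
    training_report: dict = field(default_factory=dict)
    # transient training artifacts (not serialized): aligned scores and
    # sum-normalized traces of the post-filter training cells
    training_scores: "ScoreSet | None" = None
    training_traces: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "dictionary": self.dictionary.to_dict(),
            "T_matrix": self.projection.T_matrix.tolist(),
            "class_means": self.projection.class_means.tolist(),
            "class_labels": self.projection.class_labels,
            "eigenvalues": self.projection.eigenvalues.tolist(),
            "R": self.alignment.R.tolist(),
            "origins": self.alignment.origins.tolist(),
            "sign_flipped": list(self.alignment.sign_flipped),
            "config": self.config.to_dict(),
            "training_report": self.training_report,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NpqModel":
        proj = LdaProjection(
            T_matrix=np.asarray(d["T_matrix"], dtype=float),
            class_means=np.asarray(d["class_means"], dtype=float),
            class_labels=list(d["class_labels"]),
            S_B=np.empty((0, 0)), S_W=np.empty((0, 0)),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
        )
        align = AxisAlignment(
            R=np.asarray(d["R"], dtype=float),
            origins=np.asarray(d["origins"], dtype=float),
            sign_flipped=tuple(bool(b) for b in d["sign_flipped"]),
        )
        return cls(
            dictionary=dict_mod.SparseDictionary.from_dict(d["dictionary"]),
            projection=proj, alignment=align,
            config=TrainConfig(**d["config"]),
            training_report=d.get("training_report", {}),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "NpqModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def score_traces(traces: np.ndarray, model: NpqModel,
                 cell_ids: list[int] | None = None,
                 labels: list[str] | None = None,
                 repeat: int = 0) -> ScoreSet:
    """Score F_m′ traces in the 3D NPQ space.

    Traces (n×T, raw or already sum-normalized — normalization is
    idempotent) are sparse-coded, projected by Tᵗ, obliquely re-based by
    R⁻¹ and shifted by the frozen training origins.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if traces.shape[1] != model.dictionary.trace_length:
        raise ValueError(
            f"trace length {traces.shape[1]} does not match model "
            f"(expected {model.dictionary.trace_length})")
    Y = normalize_sum(traces).T
    codes = dict_mod.encode(Y, model.dictionary)
    lda_coords = (model.projection.T_matrix.T @ codes.X).T        # n×3
    coords = np.linalg.solve(model.alignment.R, lda_coords.T).T
    scores = coords - model.alignment.origins
    n = scores.shape[0]
    return ScoreSet(scores=scores,
                    cell_ids=cell_ids if cell_ids is not None
                    else list(range(n)),
                    labels=labels if labels is not None else ["?"] * n,
                    repeat=repeat)


def train_pipeline(trace_sets: dict[str, LabeledTraceSet],
                   config: TrainConfig | None = None) -> NpqModel:
    """Train the full scoring model from the four reference populations.

    ``trace_sets`` maps population labels Pop0/PopQE/PopQT/PopQI to their
    trace sets.  Stages: sum-normalize → pooled KD-tree isolation filter
    → balanced subsample for dictionary learning → encode all survivors
    → LDA → axis alignment.  Deterministic given ``config.seed``.
    """
    config = config or TrainConfig()
    required = {"Pop0", "PopQE", "PopQT", "PopQI"}
    missing = required - set(trace_sets)
    if missing:
        raise ValueError(f"missing training populations: {sorted(missing)}")
    ss = np.random.SeedSequence(config.seed)
    sub_seed, dict_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                           for s in ss.spawn(2))

    norm = {lab: normalize_sum(ts.traces) for lab, ts in trace_sets.items()}
    pooled = np.vstack([norm[lab] for lab in sorted(norm)])
    pooled_labels = np.concatenate([
        np.repeat(lab, norm[lab].shape[0]) for lab in sorted(norm)])
    kept_traces, iso_report = remove_isolated(pooled, d=config.isolation_d)
    keep_mask = np.ones(pooled.shape[0], dtype=bool)
    keep_mask[iso_report.removed_ids] = False
    kept_labels = pooled_labels[keep_mask]

    by_class = {lab: kept_traces[kept_labels == lab] for lab in sorted(norm)}
    train_Y, _ = balanced_subsample(by_class, n_samples=config.n_samples,
                                    rng=sub_seed)
    dct = dict_mod.fit_dictionary(train_Y.T, n_atoms=config.n_atoms,
                                  lam=config.lam, seed=dict_seed,
                                  max_iter=config.max_iter, tol=config.tol)
    _, train_err = dict_mod.reconstruction_error(
        train_Y.T, dct, dict_mod.encode(train_Y.T, dct))

    codes = dict_mod.encode(kept_traces.T, dct)
    proj = fit_lda(codes.X.T, list(kept_labels), ridge=config.ridge)
    lda_coords = codes.X.T @ proj.T_matrix
    align = build_alignment(lda_coords, list(kept_labels),
                            cond_bound=config.cond_bound)
    aligned = np.linalg.solve(align.R, lda_coords.T).T - align.origins
    report = {
        "n_input": int(pooled.shape[0]),
        "n_removed_isolation": iso_report.n_removed_isolation,
        "n_training_subsample": int(train_Y.shape[0]),
        "mean_reconstruction_error": train_err,
        "lda_eigenvalues": proj.eigenvalues.tolist(),
        "class_counts": {lab: int((kept_labels == lab).sum())
                         for lab in sorted(norm)},
        "seeds": {"master": config.seed, "subsample": sub_seed,
                  "dictionary": dict_seed},
    }
    return NpqModel(dictionary=dct, projection=proj, alignment=align,
                    config=config, training_report=report,
                    training_scores=ScoreSet(
                        scores=aligned,
                        cell_ids=list(range(aligned.shape[0])),
                        labels=list(kept_labels)),
                    training_traces=kept_traces)
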