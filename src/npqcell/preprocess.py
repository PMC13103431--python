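"""Trace filtering and normalization ahead of model training.

The training pipeline applies, in order: an area filter (segmented cells
smaller than 5 pixels are artefacts), sum-normalization of each trace to
a probability distribution, a KD-tree isolation filter (traces whose
nearest neighbour is further than D = 0.01 are outliers), and a balanced
class subsample for dictionary training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .imaging import CellRecord

__all__ = [
    "FilterReport",
    "filter_by_area",
    "remove_isolated",
    "normalize_sum",
    "normalize_to_initial",
    "balanced_subsample",
]


@dataclass
class FilterReport:
    """Bookkeeping for a filtering stage."""

    n_input: int
    n_removed_area: int = 0
    n_removed_isolation: int = 0
    removed_ids: list = field(default_factory=list)

    @property
    def n_survivors(self) -> int:
        return self.n_input - self.n_removed_area - self.n_removed_isolation

    def to_dict(self) -> dict:
        return {"n_input": self.n_input,
                "n_removed_area": self.n_removed_area,
                "n_removed_isolation": self.n_removed_isolation,
                "n_survivors": self.n_survivors,
                "removed_ids": list(self.removed_ids)}


def filter_by_area(cells: list[CellRecord], min_area: int = 5,
                   ) -> tuple[list[CellRecord], FilterReport]:
    """Discard cells whose segmented surface is smaller than ``min_area``
    pixels (strictly smaller; a 5-pixel cell survives the default)."""
    survivors = [c for c in cells if c.area >= min_area]
    removed = [c.cell_id for c in cells if c.area < min_area]
    report = FilterReport(n_input=len(cells), n_removed_area=len(removed),
                          removed_ids=removed)
    return survivors, report


def remove_isolated(traces: np.ndarray, d: float = 0.01,
                    ) -> tuple[np.ndarray, FilterReport]:
    """Remove traces whose nearest neighbour is further than ``d``.

    Operates on sum-normalized traces (rows).  A trace is removed iff its
    nearest-neighbour Euclidean distance, excluding itself, strictly
    exceeds ``d`` — i.e. all neighbours are further than ``d``.  Uses a
    KD-tree; the removal set is identical to brute-force pairwise
    distances.  Returns surviving rows and a report whose
    ``removed_ids`` are input row indices.
    """
    traces = np.asarray(traces, dtype=float)
    n = traces.shape[0]
    if n < 2:
        raise ValueError("isolation is undefined for fewer than 2 traces")
    tree = cKDTree(traces)
    # k=2: first neighbour is the point itself (distance 0)
    dist, _ = tree.query(traces, k=2)
    nn = dist[:, 1]
    keep = nn <= d
    report = FilterReport(n_input=n,
                          n_removed_isolation=int((~keep).sum()),
                          removed_ids=list(np.flatnonzero(~keep)))
    return traces[keep], report


def normalize_sum(trace: np.ndarray) -> np.ndarray:
    """Scale a trace (or rows of a matrix) to sum to 1."""
    trace = np.asarray(trace, dtype=float)
    s = trace.sum(axis=-1, keepdims=True)
    if np.any(s <= 0):
        raise ValueError("cannot sum-normalize a trace with non-positive sum")
    return trace / s


def normalize_to_initial(trace: np.ndarray) -> np.ndarray:
    """Scale a trace (or rows) so the first value is 1 (display form)."""
    trace = np.asarray(trace, dtype=float)
    first = trace[..., :1]
    if np.any(first <= 0):
        raise ValueError("cannot normalize a trace whose first value is <= 0")
    return trace / first


def balanced_subsample(class_traces: dict[str, np.ndarray],
                       n_samples: int = 300,
                       rng: np.random.Generator | int | None = 0,
                       ) -> tuple[np.ndarray, list[str]]:
    """Class-balanced random subsample without replacement.

    ``class_traces`` maps a class label to an (n_c, T) matrix.  Returns
    ``n_samples`` traces in total, ``n_samples // n_classes`` from each
    class (n_samples must divide evenly), with their labels.
    Deterministic given the rng seed.
    """
    labels = sorted(class_traces)
    n_classes = len(labels)
    if n_samples % n_classes:
        raise ValueError(
            f"n_samples={n_samples} not divisible by {n_classes} classes")
    per_class = n_samples // n_classes
    rng = np.random.default_rng(rng)
    rows, out_labels = [], []
    for lab in labels:
        mat = np.asarray(class_traces[lab])
        if mat.shape[0] < per_class:
            raise ValueError(
                f"class {lab!r} has {mat.shape[0]} traces, "
                f"needs >= {per_class}")
        idx = rng.choice(mat.shape[0], size=per_class, replace=False)
        rows.append(mat[np.sort(idx)])
        out_labels += [lab] * per_class
    return np.vstack(rows), out_labels
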