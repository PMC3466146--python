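"""Correspondence analysis (CA) of a genes x 9-signal count matrix.

CA decomposes the chi-square residuals of a contingency-style table: with
``P`` the matrix of proportions, row masses ``r`` and column masses ``c``,
the standardised residuals ``S_ij = (P_ij - r_i c_j) / sqrt(r_i c_j)`` are
factored by SVD, and row/column principal coordinates are the mass-rescaled
singular vectors.  Total inertia equals the Pearson chi-square statistic of
the table divided by its grand total.  Running CA on per-gene raw stop
signal counts is equivalent to analysing the per-gene TSSR vectors, since
CA normalises rows to profiles internally while keeping count-proportional
masses.

Gene clouds are summarised per genome by a mass-weighted centroid on the
first two axes and a covariance ellipse scaled by the chi-square(2)
quantile — at the 0.95 level the region that would hold ~95% of a
bivariate normal cloud.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CAResult:
    row_coords: np.ndarray       # (n_rows, k) principal coordinates
    col_coords: np.ndarray       # (n_cols, k)
    singular_values: np.ndarray  # (k,), non-increasing
    inertia_share: np.ndarray    # (k,), sums to 1 when total inertia > 0
    row_masses: np.ndarray
    col_masses: np.ndarray
    row_index: tuple[int, ...]   # positions of retained (non-zero) input rows

    @property
    def total_inertia(self) -> float:
        return float(np.sum(self.singular_values**2))

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    angle: float  # radians, orientation of the major axis

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of 2-D points inside the ellipse."""
        pts = np.atleast_2d(points) - np.asarray(self.center)
        c, s = np.cos(self.angle), np.sin(self.angle)
        rot = pts @ np.array([[c, -s], [s, c]])
        a, b = self.semi_axes
        if a == 0 or b == 0:
            return np.zeros(len(pts), dtype=bool)
        return (rot[:, 0] / a) ** 2 + (rot[:, 1] / b) ** 2 <= 1.0


@dataclass(frozen=True)
class GroupSummary:
    group: str
    centroid: tuple[float, float]
    ellipse: Ellipse | None
    n_members: int


def correspondence_analysis(counts: np.ndarray, atol: float = 1e-12) -> CAResult:
    """Correspondence analysis of a non-negative count matrix.

    All-zero rows are dropped with a log message (their profile is
    undefined); `row_index` records which input rows survive.  Axis signs
    are fixed so each axis's largest-magnitude column coordinate is
    positive, making results reproducible across SVD implementations.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2:
        raise ValueError("counts must be a 2-D matrix")
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    row_tot = X.sum(axis=1)
    keep = np.flatnonzero(row_tot > 0)
    if len(keep) < X.shape[0]:
        logger.info("dropping %d all-zero row(s)", X.shape[0] - len(keep))
    X = X[keep]
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 non-zero rows and 2 columns")
    total = X.sum()
    if total <= 0:
        raise ValueError("grand total must be positive")
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    col_keep = c > 0
    S = (P[:, col_keep] - np.outer(r, c[col_keep])) / np.sqrt(
        np.outer(r, c[col_keep])
    )
    U, sing, Vt = np.linalg.svd(S, full_matrices=False)
    rank = int(np.sum(sing > atol * max(1.0, sing[0] if len(sing) else 0.0)))
    max_axes = min(X.shape[0], int(col_keep.sum())) - 1
    k = min(rank, max_axes)
    U, sing, Vt = U[:, :k], sing[:k], Vt[:k]
    row_coords = (U * sing) / np.sqrt(r)[:, None]
    col_full = np.zeros((X.shape[1], k))
    col_full[col_keep] = (Vt.T * sing) / np.sqrt(c[col_keep])[:, None]
    # deterministic sign convention per axis
    for a in range(k):
        j = int(np.argmax(np.abs(col_full[:, a])))
        if col_full[j, a] < 0:
            col_full[:, a] *= -1
            row_coords[:, a] *= -1
    inertia = sing**2
    share = inertia / inertia.sum() if inertia.sum() > 0 else inertia
    c_out = np.zeros(X.shape[1])
    c_out[col_keep] = c[col_keep]
    return CAResult(
        row_coords=row_coords,
        col_coords=col_full,
        singular_values=sing,
        inertia_share=share,
        row_masses=r,
        col_masses=c_out,
        row_index=tuple(int(i) for i in keep),
    )


def sample_genes(genes: Sequence, n: int, seed: int) -> list:
    """Uniform sample of ``n`` genes without replacement, reproducible."""
    if n > len(genes):
        raise ValueError(f"cannot sample {n} of {len(genes)} genes")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(genes), size=n, replace=False)
    return [genes[i] for i in idx]


def group_summary(
    result: CAResult,
    labels: Sequence[str] | Mapping[int, str],
    level: float = 0.95,
) -> list[GroupSummary]:
    """Per-group centroids and confidence ellipses on CA axes 1-2.

    ``labels`` gives one group label per *retained* row (or a mapping from
    retained-row position to label).  The centroid is the mass-weighted mean
    of member row coordinates; the ellipse comes from the 2x2 covariance of
    member coordinates scaled by the chi-square quantile with 2 df (5.991 at
    the 0.95 level).  Groups with fewer than 3 members get a centroid but no
    ellipse.
    """
    n = result.row_coords.shape[0]
    if isinstance(labels, Mapping):
        lab = [labels[i] for i in range(n)]
    else:
        lab = list(labels)
    if len(lab) != n:
        raise ValueError(f"need {n} labels, got {len(lab)}")
    coords = result.row_coords[:, :2]
    masses = result.row_masses
    quantile = chi2.ppf(level, df=2)
    out = []
    for group in sorted(set(lab)):
        member = np.array([l == group for l in lab])
        xy = coords[member]
        w = masses[member]
        centroid = tuple((xy * w[:, None]).sum(axis=0) / w.sum())
        if member.sum() < 3:
            out.append(GroupSummary(group, centroid, None, int(member.sum())))
            continue
        cov = np.cov(xy, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        evals = np.clip(evals, 0.0, None)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        semi = tuple(np.sqrt(quantile * evals))
        angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
        mean = xy.mean(axis=0)  # ellipse centred on the data mean
        out.append(
            GroupSummary(
                group,
                centroid,
                Ellipse(tuple(mean), semi, angle),
                int(member.sum()),
            )
        )
    return out


def ellipses_disjoint(a: Ellipse, b: Ellipse) -> bool:
    """Conservative disjointness: centre gap exceeds the two major semi-axes."""
    gap = float(np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1]))
    return gap > a.semi_axes[0] + b.semi_axes[0]
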