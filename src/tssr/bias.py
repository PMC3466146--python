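"""Positional TSSR bias on a circular bacterial chromosome.

Genes are categorised three ways: by replichore (the two oppositely
replicated chromosome halves between the replication origin Ori and
terminus Ter), by strand orientation, and by proximity to Ori or Ter (the
``window_n`` genes nearest each side of the coordinate).  Group mean TSSR
profiles are compared with a two-sided Kolmogorov-Smirnov statistic over
the nine ordered signal categories,

    D = max_k | CDF_A(k) - CDF_B(k) |,

whose null distribution is calibrated by M random re-partitions of the
pooled genes into two groups of the original sizes:
p = (1/M) * sum_m I(D_m >= D_obs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import TSSRVector
from .io import GeneLocation


@dataclass(frozen=True)
class ChromosomeConfig:
    """Circular chromosome geometry and the Ori/Ter window size."""

    length: int
    ori: int
    ter: int
    window_n: int = 100

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        for name, coord in (("ori", self.ori), ("ter", self.ter)):
            if not 1 <= coord <= self.length:
                raise ValueError(f"{name} outside 1..{self.length}")
        if self.ori == self.ter:
            raise ValueError("ori and ter must differ")
        if self.window_n < 1:
            raise ValueError("window_n must be positive")


@dataclass(frozen=True)
class GeneCategoryAssignment:
    gene_id: str
    replichore: Literal["Left", "Right"]
    orientation: Literal["Forward", "Reverse"]
    proximity: Literal["Ori", "Ter", "none"]


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    M: int
    seed: int
    group_means: tuple[tuple[float, ...], tuple[float, ...]]
    sd_of_means: tuple[float, float]


def _circular_sides(mids: np.ndarray, coord: int, length: int):
    """Signed circular offset from ``coord``: positive = higher-coordinate side."""
    off = (mids - coord) % length
    right = off <= length / 2  # higher-coordinate ("right") side
    distance = np.where(right, off, length - off)
    return right, distance


def assign_categories(
    locations: Sequence[GeneLocation], cfg: ChromosomeConfig
) -> list[GeneCategoryAssignment]:
    """Replichore, orientation and Ori/Ter-window labels for every gene.

    The Right replichore is the arc from Ori moving in increasing coordinate
    (mod length) to Ter; Left is the complement.  The Ori window holds the
    ``window_n`` genes with midpoints nearest Ori on each side (2*window_n
    genes), likewise for Ter; a gene falling in both windows is an error
    (the windows would overlap on a short chromosome).
    """
    if not locations:
        raise ValueError("no gene locations supplied")
    L = cfg.length
    for loc in locations:
        if loc.chromosome_length != L:
            raise ValueError(
                f"gene {loc.gene_id} is on a chromosome of length "
                f"{loc.chromosome_length}, expected {L}"
            )
    mids = np.array([loc.midpoint() for loc in locations])
    arc_ori_ter = (cfg.ter - cfg.ori) % L
    on_right = ((mids - cfg.ori) % L) <= arc_ori_ter

    def window(coord: int) -> set[int]:
        side, distance = _circular_sides(mids, coord, L)
        chosen: set[int] = set()
        for side_mask in (side, ~side):
            idx = np.flatnonzero(side_mask)
            if len(idx) < cfg.window_n:
                raise ValueError(
                    f"only {len(idx)} genes on one side of coordinate {coord}, "
                    f"need {cfg.window_n}"
                )
            order = idx[np.argsort(distance[idx], kind="stable")]
            chosen.update(int(i) for i in order[: cfg.window_n])
        return chosen

    ori_set = window(cfg.ori)
    ter_set = window(cfg.ter)
    overlap = ori_set & ter_set
    if overlap:
        raise ValueError(
            f"Ori and Ter windows overlap on {len(overlap)} gene(s); "
            "window_n too large for this chromosome"
        )
    out = []
    for i, loc in enumerate(locations):
        proximity = "Ori" if i in ori_set else ("Ter" if i in ter_set else "none")
        out.append(
            GeneCategoryAssignment(
                gene_id=loc.gene_id,
                replichore="Right" if on_right[i] else "Left",
                orientation="Forward" if loc.strand == "+" else "Reverse",
                proximity=proximity,
            )
        )
    return out


def mean_profile(genes: Sequence[TSSRVector] | np.ndarray) -> np.ndarray:
    """Arithmetic mean of per-gene TSSR vectors, one value per signal."""
    mat = _as_matrix(genes)
    if mat.shape[0] == 0:
        raise ValueError("empty group")
    return mat.mean(axis=0)


def ks_statistic(mean_a: np.ndarray, mean_b: np.ndarray) -> float:
    """Max CDF gap between two 9-bin discrete distributions (canonical order)."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    a = a / a.sum()
    b = b / b.sum()
    return float(np.max(np.abs(np.cumsum(a) - np.cumsum(b))))


def _as_matrix(genes) -> np.ndarray:
    if isinstance(genes, np.ndarray):
        return np.asarray(genes, dtype=float)
    return np.array([g.as_array() if isinstance(g, TSSRVector) else g for g in genes])


def permutation_pvalue(
    genes_a: Sequence[TSSRVector] | np.ndarray,
    genes_b: Sequence[TSSRVector] | np.ndarray,
    M: int = 1000,
    seed: int = 0,
    statistic: Literal["cdf_of_means", "mean_of_cdfs"] = "cdf_of_means",
    replace: bool = False,
) -> KSResult:
    """Permutation-calibrated KS comparison of two equal-sized gene groups.

    The observed D compares the two group mean profiles (``cdf_of_means``,
    the default) or the group averages of per-gene cumulative profiles
    (``mean_of_cdfs``).  Each of the M resamplings re-partitions the pooled
    genes uniformly at random into disjoint halves of the original sizes
    (``replace=True`` draws each half with replacement instead) and
    recomputes D; the p-value is the fraction of resampled statistics at or
    above the observed one.
    """
    A = _as_matrix(genes_a)
    B = _as_matrix(genes_b)
    if A.shape[0] != B.shape[0]:
        raise ValueError(
            f"group sizes must be equal (got {A.shape[0]} and {B.shape[0]}); "
            "subsample the larger group first"
        )
    if M < 1:
        raise ValueError("M must be >= 1")
    nA = A.shape[0]
    pooled = np.vstack([A, B])
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 genes in total")

    if statistic == "mean_of_cdfs":
        # average of per-gene cumulative profiles instead of CDF of the mean
        prof = np.cumsum(pooled / pooled.sum(axis=1, keepdims=True), axis=1)

        def stat(ia: np.ndarray, ib: np.ndarray) -> float:
            return float(np.max(np.abs(prof[ia].mean(0) - prof[ib].mean(0))))

    elif statistic == "cdf_of_means":

        def stat(ia: np.ndarray, ib: np.ndarray) -> float:
            return ks_statistic(pooled[ia].mean(0), pooled[ib].mean(0))

    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    idx_a = np.arange(nA)
    idx_b = np.arange(nA, 2 * nA)
    d_obs = stat(idx_a, idx_b)

    rng = np.random.default_rng(seed)
    n = pooled.shape[0]
    exceed = 0
    for _ in range(M):
        if replace:
            ia = rng.integers(0, n, size=nA)
            ib = rng.integers(0, n, size=nA)
        else:
            perm = rng.permutation(n)
            ia, ib = perm[:nA], perm[nA:]
        if stat(ia, ib) >= d_obs - 1e-15:
            exceed += 1
    mean_a_obs = A.mean(axis=0)
    mean_b_obs = B.mean(axis=0)
    return KSResult(
        D=d_obs,
        p=exceed / M,
        M=M,
        seed=seed,
        group_means=(tuple(mean_a_obs), tuple(mean_b_obs)),
        sd_of_means=(
            float(np.std(mean_a_obs, ddof=1)),
            float(np.std(mean_b_obs, ddof=1)),
        ),
    )
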