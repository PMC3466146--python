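"""Frame-resolved translation stop signal (TSS) counting and TSSR arithmetic.

A translation stop signal is any TAA, TAG or TGA trimer read on one of the
three reading frames of a protein-coding gene.  On frame 1 these are the
stop codons; on frames 2 and 3 they are the off-frame "hidden" (premature)
stop codons formed across codon junctions.  A gene is summarised by nine
non-negative counts, ordered

    (TAA, TAG, TGA) x (frame 1, frame 2, frame 3)

and a TSSR (translation stop signal ratio) is the same nine numbers
normalised to proportions.  The genome-level profile pools or averages the
per-gene vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical order of the nine stop-signal classes.
SIGNALS = (
    "TAA@f1", "TAG@f1", "TGA@f1",
    "TAA@f2", "TAG@f2", "TGA@f2",
    "TAA@f3", "TAG@f3", "TGA@f3",
)

STOP_TRIMERS = ("TAA", "TAG", "TGA")

Frame = Literal[1, 2, 3]
Mode = Literal["pooled", "mean"]


class UndefinedSignalError(ValueError):
    """Raised when a ratio is requested for an all-zero count vector."""


@dataclass(frozen=True)
class GeneSeq:
    """A single CDS on its coding strand, 5'->3', stop codon included."""

    gene_id: str
    sequence: str
    genome_id: str | None = None

    def __post_init__(self) -> None:
        canon = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", canon)
        if len(canon) % 3 != 0:
            logger.warning(
                "gene %s has length %d, not a multiple of 3", self.gene_id, len(canon)
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TSSCounts:
    """Nine stop-signal counts for one gene, in canonical signal order."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        c = tuple(int(x) for x in self.counts)
        if len(c) != 9:
            raise ValueError(f"expected 9 counts, got {len(c)}")
        if any(x < 0 for x in c):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return sum(self.counts)

    def frame(self, frame: Frame) -> tuple[int, int, int]:
        """The (TAA, TAG, TGA) counts of one reading frame."""
        if frame not in (1, 2, 3):
            raise ValueError("frame must be 1, 2 or 3")
        i = 3 * (frame - 1)
        return self.counts[i : i + 3]

    def __add__(self, other: "TSSCounts") -> "TSSCounts":
        return TSSCounts(tuple(a + b for a, b in zip(self.counts, other.counts)))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class TSSRVector:
    """Nine proportions over the stop-signal classes; sums to one."""

    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        r = tuple(float(x) for x in self.ratios)
        if len(r) != 9:
            raise ValueError(f"expected 9 ratios, got {len(r)}")
        if any(x < -1e-12 or x > 1 + 1e-12 for x in r):
            raise ValueError("ratios must lie in [0, 1]")
        if abs(sum(r) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {sum(r)!r}")
        object.__setattr__(self, "ratios", r)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.ratios, dtype=float)


@dataclass(frozen=True)
class FrameRatio:
    """(TAA, TAG, TGA) proportions on a single reading frame."""

    frame: Frame
    ratios: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.frame not in (1, 2, 3):
            raise ValueError("frame must be 1, 2 or 3")
        r = tuple(float(x) for x in self.ratios)
        if len(r) != 3:
            raise ValueError("expected 3 ratios")
        if abs(sum(r) - 1.0) > 1e-9:
            raise ValueError("frame ratios must sum to 1")
        object.__setattr__(self, "ratios", r)


# ---------------------------------------------------------------------------
# counting

_BYTE_T = ord("T")
_BYTE_A = ord("A")
_BYTE_G = ord("G")


def count_tss(gene: GeneSeq | str) -> TSSCounts:
    """Count TAA/TAG/TGA trimers on each of the three reading frames.

    Frame ``f`` scans trimers starting at 0-based offsets ``p ≡ f-1 (mod 3)``
    from the first nucleotide of the CDS; the terminal stop codon therefore
    lands on frame 1.  Windows containing any character other than A, C, G
    or T never match.  Short or empty sequences yield all-zero counts.
    """
    seq = gene.sequence if isinstance(gene, GeneSeq) else GeneSeq("_", gene).sequence
    L = len(seq)
    counts = [0] * 9
    if L < 3:
        return TSSCounts(tuple(counts))
    b = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    # match positions for each stop trimer, vectorised over all offsets
    is_t = b == _BYTE_T
    is_a = b == _BYTE_A
    is_g = b == _BYTE_G
    n = L - 2  # number of trimer windows
    t0 = is_t[:n]
    taa = t0 & is_a[1 : n + 1] & is_a[2 : n + 2]
    tag = t0 & is_a[1 : n + 1] & is_g[2 : n + 2]
    tga = t0 & is_g[1 : n + 1] & is_a[2 : n + 2]
    pos = np.arange(n)
    frame_of = pos % 3  # frame index = offset mod 3
    for si, hits in enumerate((taa, tag, tga)):
        per_frame = np.bincount(frame_of[hits], minlength=3)
        for f in range(3):
            counts[3 * f + si] = int(per_frame[f])
    return TSSCounts(tuple(counts))


# ---------------------------------------------------------------------------
# ratios


def genic_tssr(counts: TSSCounts) -> TSSRVector:
    """Normalise a gene's nine counts to its Genic-TSSR (proportions)."""
    total = counts.total
    if total == 0:
        raise UndefinedSignalError("gene has no translation stop signals")
    return TSSRVector(tuple(c / total for c in counts.counts))


def frame_tssr(counts: TSSCounts, frame: Frame) -> FrameRatio:
    """TSSR of one reading frame: that frame's counts normalised to sum 1."""
    trip = counts.frame(frame)
    total = sum(trip)
    if total == 0:
        raise UndefinedSignalError(f"frame {frame} has no translation stop signals")
    return FrameRatio(frame, tuple(c / total for c in trip))


def genomic_tssr(
    gene_counts: Iterable[TSSCounts], mode: Mode = "pooled"
) -> TSSRVector:
    """Genome-level TSSR over a set of genes.

    ``pooled`` sums the nine counters over all genes and divides by the grand
    total (the arithmetic behind the published per-genome profiles);
    ``mean`` averages the per-gene Genic-TSSR vectors, skipping genes with
    no signal at all.
    """
    mat = np.array([c.counts for c in gene_counts], dtype=float)
    if mat.size == 0:
        raise UndefinedSignalError("no genes supplied")
    if mode == "pooled":
        pooled = mat.sum(axis=0)
        total = pooled.sum()
        if total == 0:
            raise UndefinedSignalError("all genes have zero signals")
        return TSSRVector(tuple(pooled / total))
    if mode == "mean":
        totals = mat.sum(axis=1)
        keep = mat[totals > 0]
        if keep.shape[0] == 0:
            raise UndefinedSignalError("all genes have zero signals")
        ratios = keep / keep.sum(axis=1, keepdims=True)
        out = ratios.mean(axis=0)
        return TSSRVector(tuple(out / out.sum()))
    raise ValueError(f"unknown mode {mode!r}")


def genomic_frame_tssr(
    gene_counts: Iterable[TSSCounts], frame: Frame, mode: Mode = "pooled"
) -> FrameRatio:
    """Genome-level per-frame TSSR (TSSR-1/2/3), pooled or averaged."""
    mat = np.array([c.frame(frame) for c in gene_counts], dtype=float)
    if mat.size == 0:
        raise UndefinedSignalError("no genes supplied")
    if mode == "pooled":
        pooled = mat.sum(axis=0)
        total = pooled.sum()
        if total == 0:
            raise UndefinedSignalError(f"frame {frame} has no signals in any gene")
        return FrameRatio(frame, tuple(pooled / total))
    if mode == "mean":
        totals = mat.sum(axis=1)
        keep = mat[totals > 0]
        if keep.shape[0] == 0:
            raise UndefinedSignalError(f"frame {frame} has no signals in any gene")
        ratios = keep / keep.sum(axis=1, keepdims=True)
        out = ratios.mean(axis=0)
        return FrameRatio(frame, tuple(out / out.sum()))
    raise ValueError(f"unknown mode {mode!r}")


def profile_genome(
    genes: Sequence[GeneSeq], mode: Mode = "pooled"
) -> tuple[TSSRVector, list[TSSCounts]]:
    """Count every gene and return the genome TSSR plus per-gene counts."""
    counts = [count_tss(g) for g in genes]
    return genomic_tssr(counts, mode=mode), counts
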