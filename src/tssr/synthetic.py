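"""Synthetic genes and genomes from explicit codon-usage models.

The baseline model draws body codons i.i.d. from a probability table over
the 61 sense codons and one terminal stop from a table over {TAA, TAG,
TGA}.  Off-frame stop signals then arise exactly as they do in real genes:
a frame-2 signal when the last two nucleotides of one codon plus the first
of the next spell TAA/TAG/TGA, a frame-3 signal from the last nucleotide
plus the next codon's first two.  Because draws are independent, the
expected nine-signal count vector has a closed form by enumerating all
codon pairs — an exact oracle for the counting and profiling machinery.

A junction-biasing option multiplies the probability of codon pairs that
form selected off-frame signals (renormalising at each draw), which injects
frame-specific effects for power studies of the positional-bias test; the
closed-form expectation applies only to the unbiased model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .core import STOP_TRIMERS, GeneSeq
from .io import GeneLocation

ALL_CODONS = tuple("".join(p) for p in product("TCAG", repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_TRIMERS)

#: Gap between consecutive genes when laying out a synthetic chromosome.
INTERGENIC_GAP = 50


def _frame2_trimer(c1: str, c2: str) -> str:
    return c1[1:] + c2[0]


def _frame3_trimer(c1: str, c2: str) -> str:
    return c1[2] + c2[:2]


@dataclass(frozen=True)
class CodonUsageModel:
    """An i.i.d. codon model for one synthetic genome.

    ``sense_usage`` maps the 61 sense codons to probabilities (missing
    codons get probability 0); ``stop_usage`` maps TAA/TAG/TGA likewise.
    ``n_codons`` is the body length in codons — a fixed count or an
    inclusive (low, high) range sampled uniformly.  ``junction_bias`` maps
    (frame, stop trimer) to a multiplicative weight applied to codon pairs
    forming that off-frame signal.
    """

    sense_usage: Mapping[str, float]
    stop_usage: Mapping[str, float]
    n_codons: int | tuple[int, int] = 300
    seed: int = 0
    junction_bias: Mapping[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table, support in (
            ("sense_usage", self.sense_usage, SENSE_CODONS),
            ("stop_usage", self.stop_usage, STOP_TRIMERS),
        ):
            bad = set(table) - set(support)
            if bad:
                raise ValueError(f"{name} has invalid codons: {sorted(bad)}")
            vals = np.array([table.get(c, 0.0) for c in support])
            if np.any(vals < 0):
                raise ValueError(f"{name} has negative probabilities")
            if abs(vals.sum() - 1.0) > 1e-12:
                raise ValueError(f"{name} must sum to 1, got {vals.sum()!r}")
        for (frame, stop), mult in self.junction_bias.items():
            if frame not in (2, 3) or stop not in STOP_TRIMERS or mult < 0:
                raise ValueError(f"invalid junction bias {(frame, stop, mult)}")
        lo, hi = self._length_range()
        if lo < 1 or hi < lo:
            raise ValueError("n_codons must be >= 1 (or a valid range)")

    def _length_range(self) -> tuple[int, int]:
        if isinstance(self.n_codons, int):
            return self.n_codons, self.n_codons
        lo, hi = self.n_codons
        return int(lo), int(hi)

    @classmethod
    def uniform(
        cls,
        stop_usage: Mapping[str, float] | None = None,
        n_codons: int | tuple[int, int] = 300,
        seed: int = 0,
        junction_bias: Mapping[tuple[int, str], float] | None = None,
    ) -> "CodonUsageModel":
        """Uniform sense-codon usage; stops default to an AT-rich 0.6/0.1/0.3."""
        sense = {c: 1.0 / len(SENSE_CODONS) for c in SENSE_CODONS}
        stops = dict(stop_usage or {"TAA": 0.6, "TAG": 0.1, "TGA": 0.3})
        return cls(sense, stops, n_codons, seed, dict(junction_bias or {}))

    def _sense_probs(self) -> np.ndarray:
        return np.array([self.sense_usage.get(c, 0.0) for c in SENSE_CODONS])

    def _stop_probs(self) -> np.ndarray:
        return np.array([self.stop_usage.get(c, 0.0) for c in STOP_TRIMERS])


def _pair_weights(model: CodonUsageModel) -> np.ndarray | None:
    """(61, 61) multiplicative weights for body codon transitions, or None."""
    if not model.junction_bias:
        return None
    W = np.ones((len(SENSE_CODONS), len(SENSE_CODONS)))
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            t2 = _frame2_trimer(c1, c2)
            t3 = _frame3_trimer(c1, c2)
            if t2 in STOP_TRIMERS:
                W[i, j] *= model.junction_bias.get((2, t2), 1.0)
            if t3 in STOP_TRIMERS:
                W[i, j] *= model.junction_bias.get((3, t3), 1.0)
    return W


def simulate_gene(
    model: CodonUsageModel, rng: np.random.Generator | None = None
) -> GeneSeq:
    """Draw one synthetic CDS: body codons then a terminal stop."""
    if rng is None:
        rng = np.random.default_rng(model.seed)
    lo, hi = model._length_range()
    n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
    p_sense = model._sense_probs()
    W = _pair_weights(model)
    idx = np.empty(n, dtype=int)
    idx[0] = rng.choice(len(SENSE_CODONS), p=p_sense)
    if W is None:
        if n > 1:
            idx[1:] = rng.choice(len(SENSE_CODONS), size=n - 1, p=p_sense)
    else:
        for k in range(1, n):
            w = p_sense * W[idx[k - 1]]
            idx[k] = rng.choice(len(SENSE_CODONS), p=w / w.sum())
    stop = STOP_TRIMERS[rng.choice(3, p=model._stop_probs())]
    seq = "".join(SENSE_CODONS[i] for i in idx) + stop
    return GeneSeq(gene_id=f"synth_{rng.integers(0, 2**31):08x}", sequence=seq)


def expected_tss_counts(model: CodonUsageModel, n: int | None = None) -> np.ndarray:
    """Exact expected nine-signal counts of a gene with ``n`` body codons.

    Enumerates every ordered codon pair at the n-1 body junctions and the
    body-to-stop junction; the frame-1 expectation is just the stop-usage
    table.  Only defined for the unbiased i.i.d. model.
    """
    if model.junction_bias:
        raise ValueError("closed-form expectation requires an unbiased model")
    if n is None:
        lo, hi = model._length_range()
        if lo != hi:
            raise ValueError("specify n for a variable-length model")
        n = lo
    p_sense = model._sense_probs()
    p_stop = model._stop_probs()
    expected = np.zeros(9)
    expected[0:3] = p_stop  # terminal stop is the only frame-1 signal
    stop_index = {s: k for k, s in enumerate(STOP_TRIMERS)}
    for i, c1 in enumerate(SENSE_CODONS):
        if p_sense[i] == 0:
            continue
        # body-body junctions (n-1 of them) and the body->stop junction
        for j, c2 in enumerate(SENSE_CODONS):
            w = (n - 1) * p_sense[i] * p_sense[j]
            if w == 0:
                continue
            t2 = _frame2_trimer(c1, c2)
            if t2 in stop_index:
                expected[3 + stop_index[t2]] += w
            t3 = _frame3_trimer(c1, c2)
            if t3 in stop_index:
                expected[6 + stop_index[t3]] += w
        for k, c2 in enumerate(STOP_TRIMERS):
            w = p_sense[i] * p_stop[k]
            if w == 0:
                continue
            t2 = _frame2_trimer(c1, c2)
            if t2 in stop_index:
                expected[3 + stop_index[t2]] += w
            t3 = _frame3_trimer(c1, c2)
            if t3 in stop_index:
                expected[6 + stop_index[t3]] += w
    return expected


def simulate_genome(
    model: CodonUsageModel,
    n_genes: int,
    rng: np.random.Generator | None = None,
    genome_id: str | None = None,
) -> tuple[list[GeneSeq], list[GeneLocation]]:
    """Simulate a gene set laid head-to-tail on a circular chromosome.

    Genes are separated by 50-nt gaps; the chromosome is sized to fit
    exactly.  Strands are independent Bernoulli(0.5) draws (the sequence is
    always reported on its coding strand; the strand label only matters for
    positional analyses).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    genes = []
    for k in range(n_genes):
        g = simulate_gene(model, rng)
        gid = f"{genome_id or 'synth'}_g{k:05d}"
        genes.append(GeneSeq(gene_id=gid, sequence=g.sequence, genome_id=genome_id))
    length = sum(len(g) for g in genes) + n_genes * INTERGENIC_GAP
    locations = []
    pos = 1
    for g in genes:
        start = pos
        end = pos + len(g) - 1
        strand = "+" if rng.random() < 0.5 else "-"
        locations.append(GeneLocation(g.gene_id, start, end, strand, length))
        pos = end + INTERGENIC_GAP + 1
    return genes, locations
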