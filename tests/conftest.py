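import numpy as np
import pytest

from tssr import GeneSeq, TSSCounts, packaged_profile_table

# The 12-codon worked example gene: ATG GTA AGG GTG AGT ATA ATG GTA GCC GGT GGT TAA
WORKED_GENE = "ATGGTAAGGGTGAGTATAATGGTAGCCGGTGGTTAA"

# Pooled nine-signal counts of the 4289 E. coli K-12 genes.
K12_COUNTS = TSSCounts((2707, 326, 1256, 13755, 9780, 42155, 31463, 6048, 44610))

STOPS = ("TAA", "TAG", "TGA")


def naive_count_tss(seq: str) -> tuple[int, ...]:
    """Independent oracle: scan every start position, classify by p mod 3."""
    seq = seq.upper().replace("U", "T")
    counts = [0] * 9
    for p in range(len(seq) - 2):
        window = seq[p : p + 3]
        if any(ch not in "ACGT" for ch in window):
            continue
        if window in STOPS:
            counts[3 * (p % 3) + STOPS.index(window)] += 1
    return tuple(counts)


@pytest.fixture(scope="session")
def table61():
    return packaged_profile_table()


@pytest.fixture
def worked_gene():
    return GeneSeq("worked", WORKED_GENE)


@pytest.fixture
def rng():
    return np.random.default_rng(20120531)


def divergent_usage_models(n_codons: int = 80):
    """Two codon-usage models with opposite off-frame stop signatures:
    one rich in frame-3 TAA (thymine-ending lead codons before AA-starting
    codons), one rich in frame-2 TGA (NTG leads before A-starting codons)."""
    from tssr import SENSE_CODONS, CodonUsageModel

    def boosted(codons, factor, stops):
        sense = {c: 1.0 for c in SENSE_CODONS}
        for c in codons:
            sense[c] *= factor
        tot = sum(sense.values())
        return CodonUsageModel(
            {c: p / tot for c, p in sense.items()}, stops, n_codons=n_codons
        )

    taa3_rich = boosted(
        ["TTA", "ATA", "GGT", "AAT", "AAA", "AAC", "AAG"], 10,
        {"TAA": 0.8, "TAG": 0.1, "TGA": 0.1},
    )
    tga2_rich = boosted(
        ["ATG", "CTG", "GTG", "TTG", "ACA", "AGA", "ACC"], 10,
        {"TAA": 0.1, "TAG": 0.1, "TGA": 0.8},
    )
    return taa3_rich, tga2_rich
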