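"""Correspondence analysis of per-gene stop-signal counts.

Genes from two synthetic genomes with different codon usages are pooled
into a genes x 9 count matrix; CA projects them onto the plane of maximum
chi-square variation.  Each genome's gene cloud gets a centroid and a 95%
covariance ellipse — well-separated usages give disjoint ellipses.
"""

import numpy as np

from tssr import (
    CodonUsageModel,
    correspondence_analysis,
    count_tss,
    group_summary,
    sample_genes,
    simulate_gene,
)

rng = np.random.default_rng(17)


def boosted_usage(codons, stops):
    """Uniform sense usage with a 10x boost on selected codons."""
    from tssr import SENSE_CODONS

    w = {c: (10.0 if c in codons else 1.0) for c in SENSE_CODONS}
    tot = sum(w.values())
    return CodonUsageModel({c: x / tot for c, x in w.items()}, stops)


models = {
    # thymine-ending leads + AA-starting codons -> many frame-3 TAA signals
    "taa3_rich": boosted_usage(
        {"TTA", "ATA", "GGT", "AAT", "AAA", "AAC", "AAG"},
        {"TAA": 0.8, "TAG": 0.1, "TGA": 0.1},
    ),
    # NTG leads + A-starting codons -> many frame-2 TGA signals
    "tga2_rich": boosted_usage(
        {"ATG", "CTG", "GTG", "TTG", "ACA", "AGA", "ACC"},
        {"TAA": 0.1, "TAG": 0.1, "TGA": 0.8},
    ),
}

rows, labels = [], []
for name, model in models.items():
    genes = [simulate_gene(model, rng) for _ in range(800)]
    for g in sample_genes(genes, 500, seed=17):  # 500 random genes per genome
        rows.append(count_tss(g).counts)
        labels.append(name)

result = correspondence_analysis(np.array(rows, dtype=float))
print(f"{result.row_coords.shape[0]} genes, {result.n_axes} axes")
print("axis inertia shares:", np.round(result.inertia_share[:3], 3))

for s in group_summary(result, [labels[i] for i in result.row_index]):
    print(
        f"{s.group}: centroid=({s.centroid[0]:+.3f}, {s.centroid[1]:+.3f}) "
        f"ellipse semi-axes=({s.ellipse.semi_axes[0]:.3f}, "
        f"{s.ellipse.semi_axes[1]:.3f})"
    )
# axis 1 separates the genomes; the centroid is each genome's average gene
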