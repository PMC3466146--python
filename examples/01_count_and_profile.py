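"""Count stop signals on a single gene and pool a genome profile.

The gene below is a 12-codon CDS.  Each reading frame is scanned for
TAA/TAG/TGA trimers: frame 1 holds the real stop codon, frames 2 and 3 the
hidden (premature) stops formed across codon junctions.  The genome-level
profile divides nine pooled counters by their grand total.
"""

from tssr import TSSCounts, count_tss, frame_tssr, genic_tssr, genomic_tssr

gene = "ATG" "GTA" "AGG" "GTG" "AGT" "ATA" "ATG" "GTA" "GCC" "GGT" "GGT" "TAA"
counts = count_tss(gene)
print("gene:", gene)
print("nine-signal counts (TAA,TAG,TGA x frames 1-3):", counts.counts)
print("frame-2 ratio (hidden stops):", frame_tssr(counts, 2).ratios)
# one TAA stop codon; two TAA, one TAG, one TGA hidden on frame 2

# Genome profile from pooled counters — here the nine genome-wide totals of
# the 4289 E. coli K-12 genes.
k12 = TSSCounts((2707, 326, 1256, 13755, 9780, 42155, 31463, 6048, 44610))
profile = genomic_tssr([k12], mode="pooled")
print("\nE. coli K-12 pooled total:", k12.total)
print("Genomic-TSSR:", tuple(round(x, 3) for x in profile.ratios))
# each entry is that signal's share of all 152100 stop signals in the genome
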