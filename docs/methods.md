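# Methods

## The translation stop signal model

A protein-coding gene, taken on its coding strand 5'→3' with the stop codon
included, is scanned for the trimers TAA, TAG and TGA on each of its three
reading frames. Frame *f* ∈ {1,2,3} consists of the trimer windows starting
at 0-based offsets *p* ≡ *f*−1 (mod 3); the terminal stop codon is counted
on frame 1. Frame-2 signals arise from codon pairs in which the lead codon
contributes its last two nucleotides (leads are codons for L, I, V, M);
frame-3 signals from thymine-ending lead codons contributing one
nucleotide. The gene is summarised by the nine counts

    (TAA, TAG, TGA) × (frame 1, frame 2, frame 3)

in that fixed order. Derived quantities:

- **Genic-TSSR** — the nine counts divided by their sum (undefined, and
  signalled as such, when the gene has no signal at all; a well-formed CDS
  always has at least its stop codon).
- **TSSR-1/2/3** — one frame's three counts normalised to sum 1.
- **Genomic-TSSR** — the genome-level nine-vector. Two estimators are
  provided. `pooled` (default) sums the nine counters over all genes and
  divides by the grand total; it is the arithmetic that reproduces the
  published per-genome tables and equals the total-count-weighted mean of
  the Genic-TSSRs. `mean` is the unweighted average of per-gene Genic-TSSRs
  (zero-signal genes skipped). The two differ when gene totals vary; both
  are exposed because genome-level descriptions in the literature use the
  word "average" loosely.

Counting conventions: sequences are uppercased and U→T on ingest; a window
containing any non-ACGT letter never matches; sequences whose length is not
a multiple of 3 are accepted (a warning is logged) since real annotations
contain imperfect CDSs. Records whose FASTA header contains the
case-insensitive substring "authentic frameshift" — genes annotated as
translated across multiple frames — can be excluded on ingest, and are by
default in the CLI.

The worked 12-codon example gene used in the tests has frame-3 counts
(0,0,0) by direct scan; the nine-scalar series (1,0,0,2,1,1,1,1,1) used in
the ratio examples is taken as a given input where downstream arithmetic
needs it.

## Genome profile clustering

Distances between genomes are city-block (L1) sums over the raw nine
ratios — no standardisation or centering, since the profiles are already
commensurate proportions. Agglomeration is complete linkage
(inter-cluster distance = maximum member-pair distance), written out
explicitly so that exact ties merge the pair whose sorted cluster creation
indices (leaves 0..n−1 in input order, then one index per merge) are
lexicographically smallest. This makes the topology fully deterministic and
invariant, up to relabelling, under input row permutations; SciPy's
implementation is used as an independent cross-check in the tests. Single
and average linkage are available as exploratory toggles.

Tree queries operationalise branch-membership claims: the *smallest
containing cluster* of a label set is the lowest node whose leaf set
contains it, and a group is *monophyletic* when that node's leaves equal
the group exactly. Newick export writes an ultrametric tree by the midpoint
convention (leaf depth = root merge height / 2); `scale="unit"` divides all
heights by the root height so the display spans 0–1. Labels are sanitised
(spaces, colons, parentheses → underscores) to keep the Newick parseable.

The bundled table `tssr/data/table2_genomic_tssr.tsv` holds 61
proteobacterial Genomic-TSSR profiles (14 α, 6 β, 41 γ) at 3-decimal
precision. Read-time validation renormalises each row to sum exactly 1 and
rejects rows whose sum is farther than 0.01 from 1 (3-dp rounding moves
sums by a few thousandths at most).

## Correspondence analysis

CA is computed from the standard definition: with `P` the matrix of
proportions, row masses `r` and column masses `c`, the standardised
residuals `S = D_r^{-1/2} (P − r cᵀ) D_c^{-1/2}` are factored by SVD;
row/column principal coordinates are the mass-rescaled singular vectors
times the singular values, total inertia is the sum of squared singular
values and equals the Pearson chi-square statistic over the grand total
(asserted to 1e-9 against an independent chi-square computation in tests).
CA runs on per-gene raw counts rather than ratios: row-profile
normalisation inside CA makes this equivalent to analysing Genic-TSSRs
while keeping count-proportional masses. Axis signs are fixed by requiring
each axis's largest-magnitude column coordinate to be positive; all-zero
rows are dropped with a log message; the number of axes is at most
min(rows, 9) − 1.

Gene groups are summarised on the first plane by a mass-weighted centroid
and a covariance ellipse scaled by the χ²₂ quantile (5.991 at the 0.95
level) — a *data* ellipse covering ~95 % of a normal cloud, not a
confidence region for the centroid; the data-ellipse reading matches
figures that draw gene clouds. Groups with fewer than three members get a
centroid but no ellipse.

## Positional bias test

On a circular chromosome with replication origin *ori* and terminus *ter*
(1-based coordinates), the Right replichore is the arc from *ori* in
increasing coordinate (mod length) to *ter*; Left is the complement. Gene
position is its circular midpoint. Orientation is Forward for '+' strand.
The Ori window takes the `window_n` genes with midpoints nearest *ori* on
each circular side (2·`window_n` genes; default 100 per side, i.e. 400
windowed genes for the Ori/Ter contrast), likewise for Ter; overlapping
windows are an error rather than silently double-labelling genes.

Two groups are compared by the two-sided Kolmogorov–Smirnov statistic over
the nine ordered signal categories: D = max_k |CDF_A(k) − CDF_B(k)|, where
each CDF accumulates the group's *mean* Genic-TSSR in canonical signal
order. An alternative statistic that averages per-gene cumulative profiles
(`statistic="mean_of_cdfs"`) is exposed but not the default. Significance
comes from M random re-partitions (default 1000) of the pooled genes into
two disjoint halves of the original sizes — drawing with replacement is an
option — with p = (1/M)·Σ I(D_m ≥ D_obs). Groups must be equal-sized; the
caller subsamples the larger group. All randomness flows through one seeded
generator, so results are bit-reproducible. The reported summary also
includes each group's mean profile and the standard deviation over the nine
entries of each mean.

## Synthetic data generator

The generator emulates the statistical structure that produces off-frame
stop signals in real genes: body codons drawn i.i.d. from a sense-codon
usage table, one terminal stop from a stop-usage table. Defaults, chosen
once as field-typical values: 300 body codons (~900 nt, a typical bacterial
CDS length), uniform sense usage, stop usage TAA 0.6 / TAG 0.1 / TGA 0.3
(an AT-rich stop preference in the range real genome tables show). Under
i.i.d. draws the expected nine-signal vector is exactly enumerable over all
64² codon pairs at the n−1 body junctions plus the body→stop junction, and
the frame-1 expectation is the stop-usage table itself; tests require
empirical means over thousands of simulated genes to sit within 3 standard
errors of this closed form.

A junction-biasing option multiplies the probability of codon pairs forming
selected off-frame signals (the next codon is drawn from the reweighted,
renormalised table given the previous one), injecting frame-specific
effects for power studies of the KS test; the closed-form expectation does
not apply to biased models and is refused for them. `simulate_genome` lays
genes head-to-tail with 50-nt gaps on a circular chromosome sized to fit,
with Bernoulli(0.5) strands.

What the generator does *not* emulate: realistic gene-length distributions,
amino-acid constraints, dicodon correlations beyond the injected bias,
GC-skew, intergenic sequence, or horizontal transfer. Tests passing on
synthetic data therefore validate the arithmetic and the statistical
machinery — counting, profiling, clustering recovery, test calibration and
power — not biological claims about real genomes.

## Numerical choices and edge cases

- Ratio vectors must sum to 1 within 1e-9; profile-table rows are
  renormalised within a 0.01 tolerance as described above.
- All-zero count vectors raise a dedicated `UndefinedSignalError`; callers
  decide whether to exclude (mean mode and CA do; pooled mode simply adds
  zeros).
- Distance matrices are validated for symmetry (1e-12) and zero diagonal.
- Permutation p-values use a ≥ comparison with a 1e-15 slack so that ties
  at D_obs count as exceedances (conservative, and it makes identical
  groups give p = 1 exactly).
- Comparisons against 3-decimal published table rows use ±0.0005
  (half-ulp of the printed precision).

## Problem sizes used in the test suite

Simulation-backed tests run at sizes that make their statistical tolerances
sharp but keep the default suite fast: 4 000–20 000 genes for
expectation-convergence checks, 100 replicates × 400 genes for KS null
calibration, 200 genes per group at M = 1000 for the power check, and
nine 150–200-gene genomes for end-to-end clustering recovery. These sizes
are the package's own choices for a crisp signal-to-noise ratio at
desk scale.

## Known limitations

- The genome profile is insensitive to gene order and gene length
  distribution by construction; genomes with very few genes give noisy
  profiles and no warning is raised below any particular gene count.
- Complete linkage on 3-dp rounded published profiles can in principle tie;
  the deterministic tie-break resolves this reproducibly but a different
  tie-break could yield a different (equally valid) topology.
- The KS statistic on nine ordered categories depends on the canonical
  signal order; reordering categories changes D (but not the identity
  D = 0 ⇔ equal means).
- CA group ellipses assume an approximately elliptical gene cloud; heavily
  skewed clouds are summarised poorly.
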