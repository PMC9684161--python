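# Methods

## Model and procedure

A species-level genome bin (SGB) is an equivalence class of genomes at
≥ 95% average nucleotide identity (ANI) with ≥ 30% aligned overlap. Because
all-versus-all ANI is too expensive at catalog scale, clustering is
two-step: a cheap MinHash (Mash) distance drives an average-linkage
preclustering at distance 0.05, and a precise fragment ANI recomputed only
between precluster representatives drives a complete-linkage merge at
ANI > 95%. The second step exists because MinHash Jaccard shrinks with
genome incompleteness — a 60%-complete MAG of an otherwise identical genome
has Jaccard ≈ 0.6/1.4 ≈ 0.43 against its parent, i.e. Mash distance ≈ 0.024
even at zero divergence, and incompleteness stacks with true divergence —
so Mash alone splits species whose members are incomplete and moderately
diverged, while fragment ANI (which measures identity only over the
alignable fraction and reports the missing fraction as coverage, not
divergence) puts them back together.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 21 | k-mer length for sketching (odd so canonicalization is unambiguous) |
| `sketch_size` | 10,000 | bottom-s sketch capacity |
| `precluster_cutoff` | 0.05 | average-linkage cut on Mash distance (≈ 95% identity) |
| `candidate_cutoff` | 0.10 | max Mash distance for ANI recomputation between representatives |
| `ani_cutoff` | 95 (%) | complete-linkage species boundary, strict (> 95) |
| `coverage_cutoff` | 0.3 | min-direction aligned-coverage gate, strict (> 0.3) |
| `fragment_length` | 1020 bp | ANIb fragment size |
| `min_contig` | 1500 bp | minimum contig length emitted by the MAG degrader |

Quality tiers follow MIMAG with strict inequalities (high: > 90%
complete, < 5% contaminated; medium: > 50%, < 10%); boundary values
(exactly 90/5 or 50/10) resolve to the lower tier. The fragment-acceptance
filters (≥ 70% of fragment length aligned, ≥ 30% identity) are the ANIb
convention; fragment length and filters are configuration, not claims
about any particular dataset.

The candidate cutoff of 0.10 is a deliberate design choice: a literal
Mash-distance threshold of 0.95 would pair nearly everything, so the
refinement set is restricted to representative pairs whose Mash distance
is at most twice the preclustering cutoff — wide enough to catch species
split by incompleteness (the rescue scenario peaks around distance
0.05–0.08) and narrow enough to keep the quadratic ANI stage small.

## Sketching and hashing

K-mers are 2-bit packed (A=0, C=1, G=2, T=3 — numeric order equals
lexicographic order), canonicalized as min(k-mer, reverse complement), and
finalized with splitmix64; windows containing non-ACGT characters are
skipped. Bit compatibility with the Mash binary is not a goal — all
downstream decisions depend only on the distance structure, and the
estimator (bottom-s of the merged union M, estimate = |M ∩ A ∩ B| / |M|)
and the distance formula are the standard ones. For substitution-only
strain pairs the expected distance has a closed form: k-mer survival is
(1−p)^k, giving Jaccard j = q/(2−q) with q = (1−p)^k, and the Mash formula
collapses to D = −ln(1−p) ≈ p, which is why calibration against planted
rates is a meaningful test.

## Fragment alignment

edlib provides semi-global (query vs contig infix) edit-distance alignment
with a full path. A true local alignment is recovered from that path by a
maximum-scoring-segment scan over the cigar with +1 per match and −2 per
mismatch/indel column. The penalty is load-bearing: optimal edit-distance
alignments of *unrelated* DNA still have ≈ 55% matching columns, so at
1:1 scoring random alignments drift upward and would pass a 30%-identity
filter; at 1:2 they drift negative (0.55 − 2·0.45 < 0) and the best
segment stays far below the 70%-length filter, while genuinely homologous
regions at ≥ 70% identity keep extending. Fragments overlapping a subject
contig only partially are thereby trimmed to their true overlapping core,
which is what makes directional coverage track completeness.

Directional results are symmetrized as the arithmetic mean of the two
ANIs and the minimum of the two coverages — the conservative reading of
"at least 30% overlap of the aligned genomes". An undefined direction
(zero accepted fragments) fails the pair.

## Representative selection

kSGB: the member with the largest genome, over all members including MAGs
(ties break lexicographically by id). uSGB: competition ranking (equal
values share the smallest rank) per criterion — completeness descending,
contamination ascending, mean sequencing depth descending, strain
heterogeneity ascending, N50 descending — and the member minimizing the
rank sum wins, ties again lexicographic. "Coverage" in this ranking is
read as the MAG's mean sequencing depth from binning, not ANI coverage:
the ranking is computed before any ANI exists in the workflow. After an
ANI merge the representative is re-selected on the merged membership,
using the kSGB rule if any member is a reference genome.

## Synthetic communities

The generator emulates exactly the features the clustering math is
sensitive to, and nothing else: ancestral genomes are iid base sequences
at a specified GC (no repeats — repeats affect assembly, which is out of
scope, not k-mer Jaccard at these divergences); strains are
substitution-only mutants so the planted ANI is analytically
100·(1−p); MAGs are made by retaining uniformly placed non-overlapping
segments totaling the requested completeness (split into ≈ retained/20 kb
pieces, each ≥ 1500 bp, emulating assembly contiguity) and appending whole
foreign contigs as contamination; per-contig depths are
depth_scale·weight·(1+ε) with ε zero-mean Gaussian of standard deviation
`noise_cv`.

The default community is 20 species × 100 kb with 2–6 strains each at
substitution rates cycled from {0.005, 0.01, 0.02, 0.03} (smallest first,
so a 2-strain species is tight), references for every second species,
MAG completeness 85–100% and contamination ≤ 2%. Two strains at rates
0.02 and 0.03 from the ancestor sit at ≈ 95.1% pairwise ANI — deliberately
straddling the species boundary from above — while inter-species pairs are
unrelated (Mash distance 1). What passing tests on this fixture show is
that the clustering, gating, selection and profiling *logic* is correct
under known truth; they do not show robustness to real-data phenomena the
generator omits: indels and rearrangements, horizontal transfer, repeat-
and mobile-element-driven chimeric contigs, conserved inter-species
regions, or assembly error.

## Numerical choices and degenerate inputs

Dendrogram cut semantics: a cluster is a maximal set whose merge heights
are all ≤ cutoff for the Mash step (distance exactly 0.05 merges), and
strictly < 5 on the 100−ANI scale for the ANI step (ANI exactly 95 does
not merge), implementing the strict "> 95%" boundary. Pairs missing from
the ANI map, or failing the coverage gate, are assigned the maximal
distance. Pre-cluster unions merge entire memberships, not just
representatives, and re-running the merge on its own output is a no-op.
All-zero depth samples yield a flagged empty profile; Bray-Curtis of two
all-zero profiles is an error, not a number. Every stochastic operation
takes an explicit seed and is bit-reproducible.

## Problem sizes

Tests and the acceptance script run the default 90-genome community
(sketching and the full two-step clustering in ~15 s), single 100-kb
genome pairs for ANI properties, and 50-contig toy genomes for profiling.
These sizes were chosen because every property under test — calibration,
boundary behavior, rescue, recovery — is scale-free at ≥ 100 kb; catalog-
scale inputs change runtime, not the logic.

## Known limitations

Fragment ANI is edit-distance based and substitution-calibrated; for
genomes with heavy indel content the identity denominator (alignment
columns) differs slightly from BLAST conventions. Mash distance is clamped
to [0,1] with D(j=0) = 1 by convention. The profiling stage assumes depths
are already normalized (jgi-style) and profiles only representative-genome
contigs; member-genome aggregation is out of scope. Taxonomy assignment,
phylogenetics and read-level simulation are out of scope.
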