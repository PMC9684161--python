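# sgbforge

Construction and profiling of **species-level genome bins (SGBs)** — the
genome-dereplication step at the heart of large metagenome-assembled-genome
(MAG) catalogs, such as those built for the human oral microbiome. Thousands
of MAGs and reference genomes are grouped into species clusters defined by
**≥ 95% average nucleotide identity (ANI) with ≥ 30% aligned overlap**, each
cluster gets a representative genome, and per-sample contig depths are
converted into SGB relative-abundance profiles.

The package is aimed at method developers and bioinformaticians who want the
clustering logic itself — the part usually buried inside ad-hoc pipeline
scripts — as a tested, deterministic library with a synthetic-community
generator that plants known ground truth (species labels, pairwise ANIs,
mixture weights) so every stage can be verified end to end.

## The method

1. **Quality gate (MIMAG).** MAGs are tiered by CheckM-style completeness
   *c* and contamination *x*: high quality iff *c* > 90 and *x* < 5; medium
   iff *c* > 50 and *x* < 10 (strict inequalities); only medium-or-better
   MAGs enter clustering. Reference genomes bypass the gate. tRNA
   (≥ 18 of the 20 standard amino-acid isotypes) and rRNA (5S + 16S + 23S)
   audits are reported as flags.
2. **MinHash preclustering.** Each genome is sketched as the bottom-10,000
   64-bit hashes over its canonical 21-mers. The Mash distance
   `D = −(1/k)·ln(2j/(1+j))` of the estimated Jaccard index *j* feeds
   average-linkage hierarchical clustering cut at distance 0.05.
3. **Fragment-ANI refinement.** MinHash distances are inflated for
   incomplete genomes, which can split one species across preclusters. For
   representative pairs within Mash distance 0.10, an ANIb-style fragment
   ANI is computed (1020-bp fragments, local alignment on both strands,
   70%-length / 30%-identity acceptance); pairs must have min-direction
   aligned coverage > 0.3, and preclusters merge under complete linkage at
   ANI > 95%.
4. **Catalog.** Clusters containing a reference genome are **kSGBs** (known),
   MAG-only clusters **uSGBs** (unknown); clusters containing an oral
   reference genome or an oral MAG are flagged oral. The kSGB representative
   is the largest genome; the uSGB representative minimizes the sum of five
   competition ranks (completeness ↓, contamination ↑, depth ↓, strain
   heterogeneity ↑, N50 ↓).
5. **Profiling.** Normalized per-contig depths are collapsed to a
   length-weighted mean depth per representative genome and normalized into
   per-sample SGB relative abundances; richness (> 0.1% abundance), uSGB
   richness/abundance shares and Bray-Curtis dissimilarities summarize the
   profiles.

## Worked example

```python
from sgbforge.config import PipelineConfig
from sgbforge.pipeline import cluster_genomes
from sgbforge.records import QualityMetrics
from sgbforge.synthetic import build_community

genomes, metrics, truth = build_community(seed=11)   # 20 species, 90 genomes
qm = {g: QualityMetrics(genome_id=g, **m) for g, m in metrics.items()}
res = cluster_genomes(genomes, qm, PipelineConfig())
print(res.stage_counts)
```

prints

```
{'input_genomes': 90, 'retained_genomes': 90, 'preclusters': 20,
 'candidate_pairs': 0, 'sgbs': 20}
```

i.e. the 90 genomes (10 references + 80 MAGs at planted strain divergences
of 0.5–3%) collapse into exactly the 20 planted species: 10 kSGBs and 10
uSGBs, with an Adjusted Rand Index of 1.0 against the planted labels.

The same run is available from the shell:

```bash
sgbforge simulate --out fixture --seed 11
sgbforge run --fixture fixture --seed 11 --out run
# run/catalog.tsv, run/profiles.tsv, run/run.log
```

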