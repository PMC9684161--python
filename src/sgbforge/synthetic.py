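"""Synthetic genome communities with planted ground truth.

Generates ancestral genomes per species, strain variants at controlled
substitution rates (hence analytically known pairwise ANI), degraded MAGs
(incompleteness by segment dropout, contamination by foreign-contig
injection, contigs >= 1500 bp), and per-contig depth tables drawn from known
mixture weights. Every operation is deterministic under a fixed seed, so the
whole downstream pipeline — quality gating, sketching, clustering, ANI
refinement, profiling — is testable without external data.

Design notes: mutation is substitution-only so the target ANI of a
parent/strain pair is exactly 100·(1−p); contamination is injected as whole
foreign contigs, matching the bin-level way CheckM conceptualizes
contamination; ancestral sequences are iid bases at a specified GC content —
repeat structure is irrelevant to the clustering math under test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import GenomeRecord, SpeciesSpec, SyntheticTruth

_BASES = np.frombuffer(b"ACGT", dtype="S1")

DEFAULT_MIN_CONTIG = 1500

#: Strain substitution-rate menu for the default community; assigned
#: cyclically from the smallest so few-strain species stay tight.
DEFAULT_STRAIN_RATES = (0.005, 0.01, 0.02, 0.03)


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def generate_species(spec: SpeciesSpec, seed: int) -> GenomeRecord:
    """Draw the ancestral genome of a species as one contig of iid bases.

    Base probabilities are (1-gc)/2 for A/T and gc/2 for C/G, so realized GC
    concentrates at ``spec.gc_content`` (within ±2 points for >= 100 kb).
    """
    if spec.genome_length <= 0:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(seed)
    at = (1.0 - spec.gc_content) / 2.0
    gc = spec.gc_content / 2.0
    codes = rng.choice(4, size=spec.genome_length, p=[at, gc, gc, at])
    seq = _codes_to_str(codes.astype(np.uint8))
    return GenomeRecord(
        genome_id=spec.species_id,
        contigs={f"{spec.species_id}|0": seq},
        species_id=spec.species_id,
    )


def mutate_strain(parent: GenomeRecord, subst_rate: float, seed: int) -> GenomeRecord:
    """Substitute each site independently with probability ``subst_rate``.

    Substitutions always change the base (uniform over the other three), so
    the expected ANI to the parent is exactly 100·(1−subst_rate).
    """
    if not 0.0 <= subst_rate <= 0.3:
        raise ValueError(f"substitution rate out of [0,0.3]: {subst_rate}")
    rng = np.random.default_rng(seed)
    new_contigs: dict[str, str] = {}
    child_id = f"{parent.genome_id}~m{seed}"
    for idx, (_, seq) in enumerate(parent.contigs.items()):
        codes = np.frombuffer(seq.encode("ascii"), dtype="S1")
        codes = np.searchsorted(_BASES, codes).astype(np.uint8)
        hit = rng.random(len(codes)) < subst_rate
        # shift by 1..3 mod 4: uniform over the three other bases
        shifts = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
        codes[hit] = (codes[hit] + shifts) % 4
        new_contigs[f"{child_id}|{idx}"] = _codes_to_str(codes)
    return GenomeRecord(
        genome_id=child_id,
        contigs=new_contigs,
        species_id=parent.species_id,
    )


def degrade_to_mag(
    genome: GenomeRecord,
    completeness: float,
    contamination_sources: list[GenomeRecord] | None = None,
    contamination: float = 0.0,
    min_contig: int = DEFAULT_MIN_CONTIG,
    seed: int = 0,
    genome_id: str | None = None,
    mean_contig: int = 20_000,
) -> tuple[GenomeRecord, dict]:
    """Degrade a genome into a MAG with known completeness/contamination.

    Retains a uniformly placed set of non-overlapping segments of the parent
    totaling ``completeness`` percent of its length, each emitted as a contig
    of at least ``min_contig`` bp (the retained budget is split into roughly
    ``retained/mean_contig`` pieces, emulating assembly contiguity), then
    appends whole foreign contigs drawn from ``contamination_sources``
    totaling ``contamination`` percent of the retained length.

    Returns the MAG plus a dict of the true quality metrics
    (completeness, contamination, per the construction).
    """
    if not 0.0 < completeness <= 100.0:
        raise ValueError("completeness must be in (0,100]")
    if not 0.0 <= contamination < 100.0:
        raise ValueError("contamination must be in [0,100)")
    rng = np.random.default_rng(seed)
    parent_len = genome.length
    target = int(round(parent_len * completeness / 100.0))
    if target < min_contig:
        raise ValueError(
            f"completeness {completeness}% of {parent_len} bp leaves {target} bp, "
            f"below the {min_contig} bp contig minimum"
        )
    mag_id = genome_id or f"{genome.genome_id}~mag{seed}"

    seq = genome.sequence
    if completeness >= 100.0:
        kept_segments = [(0, parent_len)]
    else:
        # split the retained budget into pieces each >= min_contig, then
        # drop them at uniform non-overlapping positions (stars and bars
        # over the discarded slack)
        max_pieces = target // min_contig
        n_pieces = max(1, min(max_pieces, round(target / mean_contig)))
        # piece lengths: min_contig each + random split of the remainder
        extra = target - n_pieces * min_contig
        cuts = np.sort(rng.integers(0, extra + 1, size=n_pieces - 1)) if n_pieces > 1 else np.array([], dtype=int)
        extras = np.diff(np.concatenate(([0], cuts, [extra])))
        lengths = (min_contig + extras).astype(int)
        slack = parent_len - target
        gap_cuts = np.sort(rng.integers(0, slack + 1, size=n_pieces))
        gaps = np.diff(np.concatenate(([0], gap_cuts)))
        kept_segments = []
        pos = 0
        for gap, ln in zip(gaps, lengths):
            pos += int(gap)
            kept_segments.append((pos, pos + int(ln)))
            pos += int(ln)

    contigs: dict[str, str] = {}
    for i, (a, b) in enumerate(kept_segments):
        contigs[f"{mag_id}|{i}"] = seq[a:b]
    retained = sum(b - a for a, b in kept_segments)

    # foreign contamination: whole contigs cut from other genomes
    contam_target = retained * contamination / 100.0
    contam_added = 0
    if contamination > 0.0:
        if not contamination_sources:
            raise ValueError("contamination requested but no sources given")
        j = len(kept_segments)
        while contam_added < contam_target:
            src = contamination_sources[int(rng.integers(len(contamination_sources)))]
            src_seq = src.sequence
            want = int(min(max(min_contig, contam_target - contam_added), len(src_seq)))
            start = int(rng.integers(0, len(src_seq) - want + 1))
            contigs[f"{mag_id}|{j}"] = src_seq[start : start + want]
            contam_added += want
            j += 1

    true_completeness = 100.0 * retained / parent_len
    true_contamination = 100.0 * contam_added / retained if retained else 0.0
    mag = GenomeRecord(
        genome_id=mag_id,
        contigs=contigs,
        species_id=genome.species_id,
        oral=genome.oral,
    )
    metrics = {
        "completeness": true_completeness,
        "contamination": true_contamination,
    }
    return mag, metrics


def simulate_depths(
    mags: list[GenomeRecord],
    weights: dict[str, dict[str, float]],
    depth_scale: float = 30.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-contig depth table from known per-sample species mixture weights.

    Each contig of a genome of species *i* in sample *s* gets depth
    ``depth_scale · weight[s][i] · (1 + ε)`` with ε zero-mean Gaussian of
    standard deviation ``noise_cv`` (clipped at −1 so depths stay >= 0).
    """
    if depth_scale <= 0:
        raise ValueError("depth_scale must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    for sample_id, w in weights.items():
        for sp, v in w.items():
            if v < 0:
                raise ValueError(f"negative weight for {sp} in {sample_id}")
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights for sample {sample_id} sum to {total}")

    rng = np.random.default_rng(seed)
    rows = []
    truth = SyntheticTruth()
    for sample_id in sorted(weights):
        w = weights[sample_id]
        truth.sample_weights[sample_id] = dict(w)
        for g in mags:
            if g.species_id is None or g.species_id not in w:
                continue
            base = depth_scale * w[g.species_id]
            for contig_id, seq in g.contigs.items():
                eps = rng.normal(0.0, noise_cv) if noise_cv > 0 else 0.0
                depth = base * max(0.0, 1.0 + eps)
                rows.append((sample_id, contig_id, len(seq), depth))
    for g in mags:
        if g.species_id is not None:
            truth.genome_to_species[g.genome_id] = g.species_id
    table = pd.DataFrame(rows, columns=["sample_id", "contig_id", "length", "depth"])
    return table, truth


def default_community_specs(
    n_species: int = 20,
    genome_length: int = 100_000,
    rates: tuple[float, ...] = DEFAULT_STRAIN_RATES,
) -> list[SpeciesSpec]:
    """The default 20-species fixture: 100 kb genomes, 2-6 strains each.

    Strain counts cycle 2..6 across species; substitution rates are taken
    cyclically from ``rates`` starting at the smallest, so the community
    spans the 95% ANI species boundary from both sides (worst intra-species
    pair ≈ 95.1% ANI, inter-species unrelated).
    """
    specs = []
    for i in range(n_species):
        n_strains = 2 + (i % 5)
        strain_rates = [rates[j % len(rates)] for j in range(n_strains)]
        gc = 0.35 + 0.02 * (i % 11)
        specs.append(
            SpeciesSpec(
                species_id=f"sp{i:02d}",
                genome_length=genome_length,
                gc_content=gc,
                strain_subst_rates=strain_rates,
            )
        )
    return specs


def build_community(
    specs: list[SpeciesSpec] | None = None,
    seed: int = 0,
    reference_every: int = 2,
    oral_every: int = 2,
    mag_completeness_range: tuple[float, float] = (85.0, 100.0),
    mag_contamination_max: float = 2.0,
    min_contig: int = DEFAULT_MIN_CONTIG,
) -> tuple[list[GenomeRecord], dict[str, dict], SyntheticTruth]:
    """Generate the full synthetic community with planted truth.

    Every ``reference_every``-th species contributes its ancestor as a
    reference genome (making its SGB a kSGB); every ``oral_every``-th
    reference is flagged oral, and all MAGs are oral (the study's MAGs all
    come from oral samples). Strains are degraded into MAGs with
    completeness drawn uniformly from ``mag_completeness_range`` and
    contamination from [0, ``mag_contamination_max``].

    Returns (genomes, quality metrics by genome id, truth).
    """
    if specs is None:
        specs = default_community_specs()
    rng = np.random.default_rng(seed)
    genomes: list[GenomeRecord] = []
    metrics: dict[str, dict] = {}
    truth = SyntheticTruth()

    for i, spec in enumerate(specs):
        anc_seed = int(rng.integers(2**31))
        ancestor = generate_species(spec, seed=anc_seed)
        if i % reference_every == 0:
            ref = GenomeRecord(
                genome_id=f"ref_{spec.species_id}",
                contigs={f"ref_{spec.species_id}|0": ancestor.sequence},
                is_reference=True,
                oral=(i % (reference_every * oral_every) == 0),
                species_id=spec.species_id,
            )
            genomes.append(ref)
            truth.genome_to_species[ref.genome_id] = spec.species_id
        for j, rate in enumerate(spec.strain_subst_rates):
            strain = mutate_strain(ancestor, rate, seed=int(rng.integers(2**31)))
            comp = float(rng.uniform(*mag_completeness_range))
            contam = float(rng.uniform(0.0, mag_contamination_max))
            sources = [g for g in genomes if g.species_id != spec.species_id] or None
            if sources is None:
                contam = 0.0
            mag, true_q = degrade_to_mag(
                strain,
                completeness=comp,
                contamination_sources=sources,
                contamination=contam,
                min_contig=min_contig,
                seed=int(rng.integers(2**31)),
                genome_id=f"mag_{spec.species_id}_{j}",
            )
            mag.oral = True
            genomes.append(mag)
            truth.genome_to_species[mag.genome_id] = spec.species_id
            truth.target_ani[frozenset((ancestor.genome_id, mag.genome_id))] = 100.0 * (
                1.0 - rate
            )
            metrics[mag.genome_id] = {
                "completeness": true_q["completeness"],
                "contamination": true_q["contamination"],
                "strain_heterogeneity": float(rng.uniform(0.0, 20.0)),
                "mean_depth": float(rng.uniform(5.0, 80.0)),
            }
    return genomes, metrics, truth
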