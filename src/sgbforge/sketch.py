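"""Bottom-s MinHash sketching of canonical k-mers and Mash distance.

Stage-1 distance of the two-step SGB clustering: each genome is reduced to
the s smallest 64-bit hash values over its canonical k-mers (k = 21,
s = 10,000 by default, the Mash sketching parameters); the Jaccard index of
two genomes is estimated from the bottom-s union of the merged sketches and
converted to an evolutionary distance by the Mash formula

    D = -(1/k) · ln( 2j / (1+j) ),   D = 1 for j = 0,  clamped to [0,1].

Hashing is a fixed, documented pipeline — k-mers are 2-bit packed (A=0,
C=1, G=2, T=3, so numeric order equals lexicographic order), canonicalized
as min(kmer, reverse complement), and finalized with splitmix64. Bit
compatibility with the Mash binary is not a goal; the analysis depends only
on the distance structure. Windows containing non-ACGT characters are
skipped.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .records import GenomeRecord

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 10_000

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
for i, b in enumerate(b"acgt"):
    _CODE[b] = i


@dataclass
class Sketch:
    genome_id: str
    k: int
    s: int
    hashes: np.ndarray  # sorted ascending uint64, <= s values

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "k": self.k,
            "s": self.s,
            "hashes": [int(h) for h in self.hashes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Sketch":
        return cls(
            genome_id=d["genome_id"],
            k=int(d["k"]),
            s=int(d["s"]),
            hashes=np.asarray(d["hashes"], dtype=np.uint64),
        )


def _splitmix64(x: np.ndarray) -> np.ndarray:
    """Vectorized splitmix64 finalizer (uint64 arithmetic wraps)."""
    z = x + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def _canonical_kmer_hashes(seq: str, k: int) -> np.ndarray:
    """Hashes of all canonical k-mers of one contig (invalid windows skipped)."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    valid = codes != 255
    windows_valid = (
        np.convolve(valid.astype(np.int32), np.ones(k, dtype=np.int32), "valid") == k
    )
    if not windows_valid.any():
        return np.empty(0, dtype=np.uint64)
    c = np.where(valid, codes, 0).astype(np.uint64)
    view = np.lib.stride_tricks.sliding_window_view(c, k)
    pow_fwd = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = view @ pow_fwd
    # reverse complement: complement code is 3 - code; positions reversed
    rc = (np.uint64(3) - view) @ pow_fwd[::-1]
    canon = np.minimum(fwd, rc)
    return _splitmix64(canon[windows_valid])


def sketch_genome(
    genome: GenomeRecord, k: int = DEFAULT_K, s: int = DEFAULT_SKETCH_SIZE
) -> Sketch:
    """Bottom-s sketch over all contigs. Requires at least one k-mer."""
    if k % 2 == 0:
        raise ValueError("k must be odd so canonicalization is well-defined")
    parts = [
        _canonical_kmer_hashes(seq, k)
        for seq in genome.contigs.values()
        if len(seq) >= k
    ]
    parts = [p for p in parts if p.size]
    if not parts:
        raise ValueError(f"no k-mers: all contigs of {genome.genome_id} shorter than k={k}")
    hashes = np.unique(np.concatenate(parts))  # sorted distinct
    return Sketch(genome_id=genome.genome_id, k=k, s=s, hashes=hashes[:s])


def jaccard_estimate(a: Sketch, b: Sketch) -> float:
    """Mash's bottom-s Jaccard estimator from the merged sketch union."""
    if a.k != b.k or a.s != b.s:
        raise ValueError("sketches have mismatched k or s")
    union = np.union1d(a.hashes, b.hashes)
    m = union[: min(a.s, union.size)]
    shared = np.intersect1d(a.hashes, b.hashes, assume_unique=True)
    hits = np.intersect1d(m, shared, assume_unique=True).size
    return hits / m.size if m.size else 0.0


def mash_distance(j: float, k: int = DEFAULT_K) -> float:
    """Mash distance from a Jaccard estimate; j=0 maps to 1 by convention."""
    if not 0.0 <= j <= 1.0:
        raise ValueError(f"jaccard estimate out of [0,1]: {j}")
    if k < 1:
        raise ValueError("k must be >= 1")
    if j == 0.0:
        return 1.0
    d = -math.log(2.0 * j / (1.0 + j)) / k
    return min(max(d, 0.0), 1.0)


def pairwise_mash(sketches: list[Sketch]) -> tuple[list[str], np.ndarray]:
    """All-versus-all Mash distance matrix (symmetric, zero diagonal)."""
    ids = [sk.genome_id for sk in sketches]
    n = len(sketches)
    d = np.zeros((n, n))
    for i in range(n):
        for jx in range(i + 1, n):
            dist = mash_distance(jaccard_estimate(sketches[i], sketches[jx]), sketches[i].k)
            d[i, jx] = d[jx, i] = dist
    return ids, d


def save_sketches(sketches: list[Sketch], path) -> None:
    with open(path, "w") as fh:
        json.dump([sk.to_dict() for sk in sketches], fh)


def load_sketches(path) -> list[Sketch]:
    with open(path) as fh:
        return [Sketch.from_dict(d) for d in json.load(fh)]
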