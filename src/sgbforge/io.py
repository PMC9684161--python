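"""Plain-text readers and writers for the pipeline's stage files.

FASTA via Biopython; tables as TSV via pandas; sketches and truth as JSON.
All stage outputs are ordinary files so any stage can be re-entered.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GenomeRecord, QualityMetrics, SGBRecord, SyntheticTruth

QUALITY_COLUMNS = [
    "genome_id",
    "completeness",
    "contamination",
    "strain_heterogeneity",
    "mean_depth",
]
DEPTH_COLUMNS = ["sample_id", "contig_id", "length", "depth"]


def write_genome_fasta(genome: GenomeRecord, path: Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in genome.contigs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genome_fasta(path: Path, genome_id: str | None = None) -> GenomeRecord:
    path = Path(path)
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not contigs:
        raise ValueError(f"no sequences in {path}")
    return GenomeRecord(genome_id=genome_id or path.stem, contigs=contigs)


def write_quality_tsv(metrics: dict[str, dict], path: Path) -> None:
    rows = [
        {
            "genome_id": gid,
            "completeness": m["completeness"],
            "contamination": m["contamination"],
            "strain_heterogeneity": m.get("strain_heterogeneity", 0.0),
            "mean_depth": m.get("mean_depth", 0.0),
        }
        for gid, m in sorted(metrics.items())
    ]
    pd.DataFrame(rows, columns=QUALITY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_quality_tsv(path: Path) -> dict[str, QualityMetrics]:
    df = pd.read_csv(path, sep="\t")
    missing = set(QUALITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"quality report missing columns: {sorted(missing)}")
    out = {}
    for _, row in df.iterrows():
        out[row["genome_id"]] = QualityMetrics(
            genome_id=row["genome_id"],
            completeness=float(row["completeness"]),
            contamination=float(row["contamination"]),
            strain_heterogeneity=float(row["strain_heterogeneity"]),
            mean_depth=float(row["mean_depth"]),
        )
    return out


def write_depth_tsv(table: pd.DataFrame, path: Path) -> None:
    table[DEPTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_depth_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")
    return df


def write_truth_json(truth: SyntheticTruth, path: Path) -> None:
    payload = {
        "genome_to_species": truth.genome_to_species,
        "target_ani": {"|".join(sorted(k)): v for k, v in truth.target_ani.items()},
        "sample_weights": truth.sample_weights,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path: Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    truth = SyntheticTruth(
        genome_to_species=payload["genome_to_species"],
        target_ani={
            frozenset(k.split("|")): v for k, v in payload["target_ani"].items()
        },
        sample_weights=payload["sample_weights"],
    )
    truth.validate()
    return truth


def write_catalog_tsv(catalog: list[SGBRecord], path: Path) -> None:
    rows = [
        {
            "sgb_id": r.sgb_id,
            "kind": r.kind,
            "oral": r.oral,
            "representative_id": r.representative_id,
            "n_members": len(r.member_ids),
            "member_ids": ";".join(sorted(r.member_ids)),
        }
        for r in catalog
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: Path) -> list[SGBRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SGBRecord(
            sgb_id=row["sgb_id"],
            member_ids=frozenset(row["member_ids"].split(";")),
            representative_id=row["representative_id"],
            kind=row["kind"],
            oral=bool(row["oral"]),
        )
        for _, row in df.iterrows()
    ]


def write_ani_pairs_tsv(pairs: list[dict], path: Path) -> None:
    cols = ["query_id", "subject_id", "ani", "coverage", "n_fragments_aligned"]
    pd.DataFrame(pairs, columns=cols).to_csv(path, sep="\t", index=False)
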