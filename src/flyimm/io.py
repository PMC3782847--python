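"""Readers and writers for the pipeline's plain-text formats.

FASTA goes through Biopython; tables are TSV/CSV via pandas.  Headers are
parsed up to the first whitespace, matching common aligner behaviour.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """id (up to first whitespace) → uppercase sequence."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_reads_fasta(reads: Iterable, path) -> None:
    """Write a synthetic ReadSet; truth source and condition go in the description."""
    records = [
        SeqRecord(
            Seq(r.sequence),
            id=r.read_id,
            description=f"truth={r.truth_source} condition={r.condition}",
        )
        for r in reads
    ]
    SeqIO.write(records, str(path), "fasta")


def write_tsv(frame: pd.DataFrame, path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def read_survival_csv(path) -> dict[str, "pd.DataFrame"]:
    """CSV with columns (replicate, day, alive, n_start) → per-replicate frames."""
    frame = pd.read_csv(path)
    required = {"replicate", "day", "alive", "n_start"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"survival CSV missing columns {sorted(missing)}")
    return {str(rep): grp.sort_values("day") for rep, grp in frame.groupby("replicate")}


def write_gff3(putatives, path, source: str = "flyimm") -> None:
    """Putative gene loci as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for pg in putatives:
        strand = "+" if pg.frame > 0 else "-"
        attrs = f"ID={pg.putative_id};hit={pg.hit_id};evalue={pg.e_value:.3g}"
        lines.append(
            "\t".join(
                [
                    "genome",
                    source,
                    "gene",
                    str(pg.query_start + 1),
                    str(pg.query_end),
                    ".",
                    strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
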