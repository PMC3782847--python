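"""Novel-gene discovery from unidentified reads.

Reads that survived the triage cascade without hitting any annotated gene are
mapped back to the genome; overlapping placements are merged into contigs
(consensus by per-column majority).  Because most contigs are short —
comparable to a 3'-UTR — each is extended by 250 bp of flanking genome on
both sides before a translated homology screen (six-frame translation, local
Smith–Waterman against a protein set, Karlin–Altschul e-values).  Putative
genes passing the e-value threshold are then tested for induction exactly
like annotated genes, except that the induction coefficient uses
depth-normalised read counts only (no transcript length is known for an
unannotated unit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq, reverse_complement

from flyimm.quantify import IC_INFINITY, IC_UNDEFINED
from flyimm.stats import ControlSet, gene_induction_test
from flyimm.synthetic import SyntheticGenome

# Karlin–Altschul parameters for gapped BLOSUM62 scoring (open 11 / extend 1)
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass
class ReadPlacement:
    read_id: str
    start: int
    end: int
    matches: int
    condition: str
    sequence: str


@dataclass
class Contig:
    contig_id: str
    start: int  # genome coordinates, 0-based half-open
    end: int
    consensus: str
    n_reads_infected: int
    n_reads_naive: int
    mean_depth: float

    def __post_init__(self) -> None:
        if len(self.consensus) != self.end - self.start:
            raise ValueError("consensus length must equal interval length")
        if self.n_reads_infected + self.n_reads_naive < 1:
            raise ValueError("a contig needs at least one read")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PutativeGene:
    putative_id: str
    contig: Contig
    query_start: int
    query_end: int
    hit_id: str
    e_value: float
    frame: int
    reads_infected: int
    reads_naive: int
    ic: float = IC_UNDEFINED
    p_value: float | None = None
    test_used: str | None = None


class GenomeMapper:
    """Place reads on the genome by exact k-mer seeding + ungapped extension.

    Same matching contract as read triage (identity >= ``min_identity`` over
    >= ``min_coverage`` of the read); placement reported as a genome interval.
    """

    def __init__(self, genome: str, k: int = 16,
                 min_identity: float = 0.95, min_coverage: float = 0.90):
        self.genome = genome
        self.k = k
        self.min_identity = min_identity
        self.min_coverage = min_coverage
        index: dict[str, list[int]] = {}
        for pos in range(len(genome) - k + 1):
            index.setdefault(genome[pos : pos + k], []).append(pos)
        self._index = index

    def place(self, read_id: str, sequence: str, condition: str) -> ReadPlacement | None:
        if len(sequence) < self.k:
            return None
        seeds = sorted({0, (len(sequence) - self.k) // 2, len(sequence) - self.k})
        offsets: set[int] = set()
        for sp in seeds:
            for pos in self._index.get(sequence[sp : sp + self.k], ()):
                offsets.add(pos - sp)
        best: tuple[int, int, int, int, int] | None = None  # (-matches, -span, start, lo, hi)
        for offset in offsets:
            lo = max(0, -offset)
            hi = min(len(sequence), len(self.genome) - offset)
            span = hi - lo
            if span < self.min_coverage * len(sequence):
                continue
            matches = sum(
                1 for i in range(lo, hi) if sequence[i] == self.genome[offset + i]
            )
            if matches < self.min_identity * span:
                continue
            key = (-matches, -span, offset + lo, lo, hi)
            if best is None or key[:3] < best[:3]:
                best = key
        if best is None:
            return None
        matches, span, start, lo, hi = -best[0], -best[1], best[2], best[3], best[4]
        return ReadPlacement(read_id, start, start + span, matches, condition, sequence[lo:hi])


def build_contigs(
    reads: Iterable,
    genome: SyntheticGenome | str,
    mapper: GenomeMapper | None = None,
) -> tuple[list[Contig], list[str]]:
    """Map unidentified reads to the genome and merge them into contigs.

    Overlapping placements (>= 1 bp) merge into maximal intervals; consensus
    is per-column majority over covering reads, ties broken toward the
    reference base.  Returns ``(contigs, unmapped_read_ids)``.
    """
    genome_seq = genome.sequence if isinstance(genome, SyntheticGenome) else genome
    if not genome_seq:
        raise ValueError("genome is empty")
    if mapper is None:
        mapper = GenomeMapper(genome_seq)

    placements: list[ReadPlacement] = []
    unmapped: list[str] = []
    for read in reads:
        p = mapper.place(read.read_id, read.sequence, getattr(read, "condition", "infected"))
        if p is None:
            unmapped.append(read.read_id)
        else:
            placements.append(p)

    placements.sort(key=lambda p: (p.start, p.end))
    contigs: list[Contig] = []
    cluster: list[ReadPlacement] = []

    def _flush() -> None:
        if not cluster:
            return
        start = min(p.start for p in cluster)
        end = max(p.end for p in cluster)
        # per-column base tally
        votes = [dict() for _ in range(end - start)]
        for p in cluster:
            for i, base in enumerate(p.sequence):
                col = p.start - start + i
                votes[col][base] = votes[col].get(base, 0) + 1
        consensus = []
        for col, tally in enumerate(votes):
            ref_base = genome_seq[start + col]
            if not tally:
                consensus.append(ref_base)
                continue
            top = max(tally.values())
            winners = sorted(b for b, c in tally.items() if c == top)
            consensus.append(ref_base if ref_base in winners else winners[0])
        n_inf = sum(1 for p in cluster if p.condition == "infected")
        n_nv = len(cluster) - n_inf
        depth = sum(p.end - p.start for p in cluster) / (end - start)
        contigs.append(
            Contig(f"CT{len(contigs):05d}", start, end, "".join(consensus), n_inf, n_nv, depth)
        )

    current_end = -1
    for p in placements:
        if cluster and p.start >= current_end:
            _flush()
            cluster = []
        cluster.append(p)
        current_end = max(current_end, p.end)
    _flush()
    return contigs, unmapped


def extend_contig(
    contig: Contig,
    genome: SyntheticGenome | str,
    flank: int = 250,
) -> tuple[str, tuple[int, int]]:
    """Extract the contig's genome interval plus ``flank`` bp on each side.

    The interval is clipped to the genome bounds; with ``flank=0`` the genome
    sequence of the contig interval itself is returned.
    """
    genome_seq = genome.sequence if isinstance(genome, SyntheticGenome) else genome
    if contig.start < 0 or contig.end > len(genome_seq):
        raise ValueError("contig interval outside genome bounds")
    start = max(0, contig.start - flank)
    end = min(len(genome_seq), contig.end + flank)
    return genome_seq[start:end], (start, end)


def six_frame_translations(query: str) -> list[tuple[int, str]]:
    """(frame, protein) for frames +1..+3 and -1..-3; stops rendered as '*'."""
    frames: list[tuple[int, str]] = []
    rc = reverse_complement(query)
    for offset in range(3):
        for strand, seq in ((1, query), (-1, rc)):
            sub = seq[offset:]
            usable = len(sub) - len(sub) % 3
            if usable >= 3:
                frames.append((strand * (offset + 1), str(Seq(sub[:usable]).translate())))
    return frames


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def screen_homology(
    query: str,
    proteins: Mapping[str, str],
    e_threshold: float = 1e-5,
    aligner: Align.PairwiseAligner | None = None,
) -> tuple[str, float, int] | None:
    """Translated homology screen of a nucleotide query against a protein set.

    The query is translated in all six frames; each frame is locally aligned
    (Smith–Waterman, BLOSUM62, affine gaps 11/1) against every protein.  The
    e-value of a raw score S is the Karlin–Altschul form K·m·n·e^(−λS) with
    m the frame's translated length and n the total residue count of the
    database.  Returns ``(protein_id, e_value, frame)`` for the best hit with
    e <= ``e_threshold``, else None.
    """
    if len(query) < 3:
        return None
    if not proteins:
        raise ValueError("protein set is empty")
    if aligner is None:
        aligner = _protein_aligner()
    n_db = sum(len(p) for p in proteins.values())
    best: tuple[float, float, str, int] | None = None  # (e, -score, id, frame)
    for frame, prot in six_frame_translations(query):
        if not prot:
            continue
        for pid in sorted(proteins):
            score = float(aligner.score(prot, proteins[pid]))
            e = KA_K * len(prot) * n_db * math.exp(-KA_LAMBDA * score)
            key = (e, -score, pid, frame)
            if best is None or key < best:
                best = key
    if best is None or best[0] > e_threshold:
        return None
    return best[2], best[0], best[3]


def depth_normalized_ic(
    reads_infected: int,
    reads_naive: int,
    total_infected: int,
    total_naive: int,
) -> float:
    """IC from depth-normalised read counts (no transcript length known)."""
    if total_infected <= 0 or total_naive <= 0:
        raise ValueError("library totals must be positive")
    if reads_naive == 0:
        return IC_UNDEFINED if reads_infected == 0 else IC_INFINITY
    return (reads_infected / total_infected) / (reads_naive / total_naive)


def test_putative_genes(
    putatives: Sequence[PutativeGene],
    control_set: ControlSet,
    total_infected: int,
    total_naive: int,
) -> list[PutativeGene]:
    """Test putative-gene induction exactly like annotated genes.

    Reuses the control-anchored 2x2 test; the IC is the ratio of
    depth-normalised read counts because unannotated units have no known
    transcript length.  Mutates and returns the input records.
    """
    for pg in putatives:
        pg.p_value, pg.test_used = gene_induction_test(
            (pg.reads_infected, pg.reads_naive),
            (control_set.pooled_infected, control_set.pooled_naive),
        )
        pg.ic = depth_normalized_ic(
            pg.reads_infected, pg.reads_naive, total_infected, total_naive
        )
    return putatives


def discover_genes(
    unidentified_reads: Iterable,
    genome: SyntheticGenome | str,
    proteins: Mapping[str, str],
    control_set: ControlSet | None = None,
    total_infected: int = 1,
    total_naive: int = 1,
    flank: int = 250,
    e_threshold: float = 1e-5,
    mapper: GenomeMapper | None = None,
) -> tuple[list[PutativeGene], list[Contig], list[str]]:
    """End-to-end discovery: map → contigs → extend → translated screen → test.

    Returns ``(putative_genes, all_contigs, unmapped_read_ids)``; putative ids
    are assigned PGxxxxx in contig order.
    """
    contigs, unmapped = build_contigs(unidentified_reads, genome, mapper=mapper)
    aligner = _protein_aligner()
    putatives: list[PutativeGene] = []
    for contig in contigs:
        query, (qs, qe) = extend_contig(contig, genome, flank=flank)
        hit = screen_homology(query, proteins, e_threshold=e_threshold, aligner=aligner)
        if hit is None:
            continue
        pid, e, frame = hit
        putatives.append(
            PutativeGene(
                putative_id=f"PG{len(putatives):05d}",
                contig=contig,
                query_start=qs,
                query_end=qe,
                hit_id=pid,
                e_value=e,
                frame=frame,
                reads_infected=contig.n_reads_infected,
                reads_naive=contig.n_reads_naive,
            )
        )
    if control_set is not None and putatives:
        test_putative_genes(putatives, control_set, total_infected, total_naive)
    return putatives, contigs, unmapped


def putative_gene_table(putatives: Sequence[PutativeGene]) -> pd.DataFrame:
    """Tabular view mirroring the published putative-gene table."""
    from flyimm.quantify import format_ic

    return pd.DataFrame(
        {
            "putative_id": [p.putative_id for p in putatives],
            "contig_start": [p.contig.start for p in putatives],
            "contig_end": [p.contig.end for p in putatives],
            "hit_id": [p.hit_id for p in putatives],
            "e_value": [p.e_value for p in putatives],
            "frame": [p.frame for p in putatives],
            "reads_infected": [p.reads_infected for p in putatives],
            "reads_naive": [p.reads_naive for p in putatives],
            "ic": [format_ic(p.ic) for p in putatives],
            "p_value": [p.p_value for p in putatives],
        }
    ).set_index("putative_id")
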