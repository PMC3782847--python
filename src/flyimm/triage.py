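"""Hierarchical read triage and per-gene counting.

Pyrosequencing reads are classified by querying reference sets in a fixed
cascade — mitochondrial genome, then rRNA, then CDS, gene and transcript
databases — with the first hit terminating the search; reads that hit nothing
are "unidentified" and feed the novel-gene workflow.  The matcher is a
pluggable contract (an external aligner can stand in); the built-in is exact
k-mer seeding with ungapped extension, which classifies error-free reads
perfectly and degrades gracefully under substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd

CASCADE_STAGES = ("mito", "rrna", "cds", "gene", "transcript")
TARGETED_STAGES = frozenset({"cds", "gene", "transcript"})


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    stage: str  # mito | rrna | cds | gene | transcript | unidentified
    target_id: str | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if (self.stage in TARGETED_STAGES) != (self.target_id is not None):
            raise ValueError(
                f"{self.read_id}: target_id must be present iff stage is one "
                f"of {sorted(TARGETED_STAGES)} (got stage={self.stage!r})"
            )


@dataclass
class TriageSummary:
    """Per-library read accounting (the published summary-table layout)."""

    total_reads: int
    mito_reads: int
    rrna_reads: int
    other_reads: int
    assigned_reads: int
    genes_hit: int
    unidentified_reads: int
    min_length: int
    max_length: int
    mean_length: float

    def __post_init__(self) -> None:
        if self.mito_reads + self.rrna_reads + self.other_reads != self.total_reads:
            raise ValueError("mito + rrna + other must equal total")
        if self.assigned_reads + self.unidentified_reads != self.other_reads:
            raise ValueError("assigned + unidentified must equal other")
        if self.genes_hit > self.assigned_reads:
            raise ValueError("genes_hit cannot exceed assigned reads")

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "total_reads": self.total_reads,
                "max_length": self.max_length,
                "min_length": self.min_length,
                "mean_length": self.mean_length,
                "mito_reads": self.mito_reads,
                "rrna_reads": self.rrna_reads,
                "other_reads": self.other_reads,
                "assigned_reads": self.assigned_reads,
                "genes_hit": self.genes_hit,
                "unidentified_reads": self.unidentified_reads,
            }
        )


class HomologyMatcher(Protocol):
    """Contract for read-to-reference matching.

    ``query`` returns the best hit ``(target_id, score)`` in the reference
    set, or ``None``.  Implementations must be deterministic for fixed inputs
    and break ties by highest score, then longest aligned span, then
    lexicographically smallest target id.
    """

    def query(self, sequence: str, references: Mapping[str, str]) -> tuple[str, float] | None:
        ...


class KmerMatcher:
    """Exact k-mer seeding with ungapped extension.

    A read seeds at up to three positions (start, middle, end); each seed hit
    implies a diagonal on which the full read is compared ungapped to the
    reference.  A hit requires identity >= ``min_identity`` over a span
    covering >= ``min_coverage`` of the read.  Score = number of matching
    bases.  Indexes are cached per reference-set identity.
    """

    def __init__(self, k: int = 16, min_identity: float = 0.95, min_coverage: float = 0.90):
        self.k = k
        self.min_identity = min_identity
        self.min_coverage = min_coverage
        self._index_cache: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def _index(self, references: Mapping[str, str]) -> dict[str, list[tuple[str, int]]]:
        key = id(references)
        if key not in self._index_cache:
            index: dict[str, list[tuple[str, int]]] = {}
            for target_id, seq in references.items():
                for pos in range(len(seq) - self.k + 1):
                    index.setdefault(seq[pos : pos + self.k], []).append((target_id, pos))
            self._index_cache[key] = index
        return self._index_cache[key]

    def query(self, sequence: str, references: Mapping[str, str]) -> tuple[str, float] | None:
        if len(sequence) < self.k:
            return None
        index = self._index(references)
        seed_positions = sorted({0, (len(sequence) - self.k) // 2, len(sequence) - self.k})
        # candidate diagonals: (target, read offset in target)
        candidates: set[tuple[str, int]] = set()
        for sp in seed_positions:
            for target_id, pos in index.get(sequence[sp : sp + self.k], ()):
                candidates.add((target_id, pos - sp))
        best: tuple[float, int, str] | None = None  # (-score, -span, target)
        for target_id, offset in candidates:
            ref = references[target_id]
            lo = max(0, -offset)
            hi = min(len(sequence), len(ref) - offset)
            span = hi - lo
            if span < self.min_coverage * len(sequence):
                continue
            matches = sum(
                1 for i in range(lo, hi) if sequence[i] == ref[offset + i]
            )
            if matches < self.min_identity * span:
                continue
            key = (-float(matches), -span, target_id)
            if best is None or key < best:
                best = key
        if best is None:
            return None
        return best[2], -best[0]


@dataclass
class ReferenceSets:
    """The five reference databases of the triage cascade.

    ``mito`` and ``rrna`` hits discard the read (no target recorded); hits in
    ``cds``, ``gene`` or ``transcript`` assign it to a gene-level target.
    """

    mito: Mapping[str, str]
    rrna: Mapping[str, str]
    cds: Mapping[str, str]
    gene: Mapping[str, str] = field(default_factory=dict)
    transcript: Mapping[str, str] = field(default_factory=dict)

    def for_stage(self, stage: str) -> Mapping[str, str]:
        return getattr(self, stage)

    def validate(self) -> None:
        for stage in ("mito", "rrna", "cds"):
            if not self.for_stage(stage):
                raise ValueError(f"reference set {stage!r} is empty")


def classify_reads(
    reads: Iterable,
    references: ReferenceSets,
    matcher: HomologyMatcher | None = None,
) -> list[ReadAssignment]:
    """Run the triage cascade over a read set.

    Stages are tried in the fixed order mito → rrna → cds → gene →
    transcript; the first stage with a hit stops the cascade.  Reads hitting
    nothing are assigned stage ``unidentified``.
    """
    references.validate()
    reads = list(reads)
    if not reads:
        raise ValueError("read set is empty")
    if matcher is None:
        matcher = KmerMatcher()
    assignments: list[ReadAssignment] = []
    for read in reads:
        assignment = None
        for stage in CASCADE_STAGES:
            refs = references.for_stage(stage)
            if not refs:
                continue
            hit = matcher.query(read.sequence, refs)
            if hit is not None:
                target, score = hit
                if stage in TARGETED_STAGES:
                    assignment = ReadAssignment(read.read_id, stage, target, score)
                else:
                    assignment = ReadAssignment(read.read_id, stage, None, score)
                break
        if assignment is None:
            assignment = ReadAssignment(read.read_id, "unidentified")
        assignments.append(assignment)
    return assignments


def count_reads_per_gene(
    assignments: Sequence[ReadAssignment],
    gene_ids: Iterable[str] | None = None,
) -> pd.Series:
    """Per-gene read counts: each read counts toward exactly one target.

    ``gene_ids`` optionally fixes the count-table universe so genes with zero
    reads are retained with count 0.
    """
    counts: dict[str, int] = {}
    if gene_ids is not None:
        counts = {g: 0 for g in gene_ids}
    for a in assignments:
        if a.target_id is not None:
            counts[a.target_id] = counts.get(a.target_id, 0) + 1
    return pd.Series(counts, name="reads", dtype=int).sort_index()


def summarize_library(
    assignments: Sequence[ReadAssignment],
    reads: Iterable,
) -> TriageSummary:
    """Build the per-library accounting summary from assignments."""
    reads = list(reads)
    stages = pd.Series([a.stage for a in assignments])
    mito = int((stages == "mito").sum())
    rrna = int((stages == "rrna").sum())
    assigned = int(stages.isin(list(TARGETED_STAGES)).sum())
    unidentified = int((stages == "unidentified").sum())
    lengths = np.array([len(r.sequence) for r in reads])
    genes_hit = len({a.target_id for a in assignments if a.target_id is not None})
    return TriageSummary(
        total_reads=len(assignments),
        mito_reads=mito,
        rrna_reads=rrna,
        other_reads=assigned + unidentified,
        assigned_reads=assigned,
        genes_hit=genes_hit,
        unidentified_reads=unidentified,
        min_length=int(lengths.min()),
        max_length=int(lengths.max()),
        mean_length=float(lengths.mean()),
    )


def summary_from_totals(
    total_reads: int,
    mito_reads: int,
    rrna_reads: int,
    assigned_reads: int | None = None,
    genes_hit: int = 0,
    min_length: int = 0,
    max_length: int = 0,
    mean_length: float = 0.0,
) -> TriageSummary:
    """Derive the remaining accounting identities from printed totals.

    other = total − mito − rRNA; unidentified = other − assigned.  Useful for
    reconstructing a published summary table from its marginal totals.
    """
    other = total_reads - mito_reads - rrna_reads
    if assigned_reads is None:
        assigned_reads = other
    return TriageSummary(
        total_reads=total_reads,
        mito_reads=mito_reads,
        rrna_reads=rrna_reads,
        other_reads=other,
        assigned_reads=assigned_reads,
        genes_hit=genes_hit,
        unidentified_reads=other - assigned_reads,
        min_length=min_length,
        max_length=max_length,
        mean_length=mean_length,
    )
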