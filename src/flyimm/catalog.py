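"""Cross-species homologue mapping and immune-gene class summaries.

Gene ids differ between the two species' genomes, so comparisons run through
a one-to-one homologue map.  Many-to-many id tables (multi-copy families) are
resolved by translated-alignment score; immune classes (recognition /
signaling / effector) come from a reference list of known immune genes; the
module also produces the paired effector summary (genes piled by normalised
expression with regulation categories) and Venn counts of expressed
immune-related genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from flyimm.stats import significance_stars
from flyimm.synthetic import GeneCatalog

VALID_CLASSES = {"recognition", "signaling", "effector"}


class TranslatedMatcher(Protocol):
    """Contract: score a candidate homologue pair, higher is better."""

    def score(self, cds_a: str, cds_b: str) -> tuple[float, int]:
        """Return (alignment score, aligned length)."""
        ...


class ProteinAlignMatcher:
    """Local protein alignment of translated CDS (BLOSUM62, affine gaps)."""

    def __init__(self, open_gap: float = -11.0, extend_gap: float = -1.0):
        self.aligner = Align.PairwiseAligner()
        self.aligner.mode = "local"
        self.aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        self.aligner.open_gap_score = open_gap
        self.aligner.extend_gap_score = extend_gap

    @staticmethod
    def _translate(cds: str) -> str:
        usable = len(cds) - len(cds) % 3
        return str(Seq(cds[:usable]).translate()).replace("*", "X")

    def score(self, cds_a: str, cds_b: str) -> tuple[float, int]:
        pa, pb = self._translate(cds_a), self._translate(cds_b)
        if not pa or not pb:
            return 0.0, 0
        aln = self.aligner.align(pa, pb)
        best = aln[0]
        span = int(best.aligned[0][-1][1] - best.aligned[0][0][0]) if len(best.aligned[0]) else 0
        return float(best.score), span


@dataclass
class HomologyMap:
    """Resolved one-to-one homologue pairs between species A and B."""

    pairs: list[tuple[str, str]]
    provenance: str = "table"
    rejects: list[str] = field(default_factory=list)
    #: ids that appeared in multi-copy families, per species
    duplicates_a: set[str] = field(default_factory=set)
    duplicates_b: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("homology map is not one-to-one")

    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}


def resolve_homologues(
    multi_map: pd.DataFrame,
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
    matcher: TranslatedMatcher | None = None,
) -> HomologyMap:
    """Resolve a many-to-many homologue table to one-to-one pairs.

    ``multi_map`` needs columns ``gene_a`` and ``gene_b``.  Rows whose ids are
    absent from their catalog go to the rejects report (not fatal).  For
    ambiguous families, candidate pairs are ranked by translated-alignment
    score, then aligned length, then lexicographic ids, and picked greedily
    under the one-to-one constraint.
    """
    if multi_map.empty:
        return HomologyMap([], provenance="table")
    if matcher is None:
        matcher = ProteinAlignMatcher()

    ids_a = set(catalog_a.gene_ids)
    ids_b = set(catalog_b.gene_ids)
    rejects: list[str] = []
    rows: list[tuple[str, str]] = []
    for a, b in multi_map[["gene_a", "gene_b"]].itertuples(index=False):
        if a not in ids_a:
            rejects.append(a)
        elif b not in ids_b:
            rejects.append(b)
        else:
            rows.append((a, b))

    count_a = pd.Series([a for a, _ in rows]).value_counts() if rows else pd.Series(dtype=int)
    count_b = pd.Series([b for _, b in rows]).value_counts() if rows else pd.Series(dtype=int)
    dup_a = {a for a, _ in rows if count_a[a] > 1}
    dup_b = {b for _, b in rows if count_b[b] > 1}

    unambiguous = [(a, b) for a, b in rows if a not in dup_a and b not in dup_b]
    ambiguous = [(a, b) for a, b in rows if a in dup_a or b in dup_b]

    scored = []
    for a, b in ambiguous:
        s, span = matcher.score(catalog_a[a].cds_sequence, catalog_b[b].cds_sequence)
        scored.append((-s, -span, a, b))
    scored.sort()

    taken_a = {a for a, _ in unambiguous}
    taken_b = {b for _, b in unambiguous}
    resolved = list(unambiguous)
    provenance = "table"
    for _, _, a, b in scored:
        if a in taken_a or b in taken_b:
            continue
        resolved.append((a, b))
        taken_a.add(a)
        taken_b.add(b)
        provenance = "best_translated_hit"
    resolved.sort()
    return HomologyMap(resolved, provenance, rejects, dup_a, dup_b)


def assign_immune_class(
    catalog: GeneCatalog,
    reference_list: pd.DataFrame,
) -> pd.DataFrame:
    """Annotate a catalog with immune classes from a reference gene list.

    ``reference_list`` needs columns ``gene_id, immune_class`` and optionally
    ``effector_subtype``.  Genes absent from the list get class ``none``.
    Returns the annotated catalog frame.
    """
    frame = catalog.to_frame().copy()
    frame["immune_class"] = "none"
    frame["effector_subtype"] = None
    if not reference_list.empty:
        bad = set(reference_list["immune_class"]) - VALID_CLASSES
        if bad:
            raise ValueError(f"unknown immune class tokens: {sorted(bad)}")
        ref = reference_list.set_index("gene_id")
        known = frame.index.intersection(ref.index)
        frame.loc[known, "immune_class"] = ref.loc[known, "immune_class"]
        if "effector_subtype" in ref.columns:
            frame.loc[known, "effector_subtype"] = ref.loc[known, "effector_subtype"]
    return frame


def class_counts(annotated: pd.DataFrame) -> pd.Series:
    """Number of genes per immune class (recognition / signaling / effector)."""
    counts = annotated["immune_class"].value_counts()
    return counts.reindex(["recognition", "signaling", "effector"], fill_value=0)


def effector_summary(
    records: pd.DataFrame,
    annotated: pd.DataFrame,
    homology: HomologyMap | None = None,
    expressed_min_reads: int = 1,
) -> pd.DataFrame:
    """Effector-gene panel: expressed effectors piled by normalised expression.

    ``records`` is a per-gene frame with at least ``reads_infected,
    tmm_infected, ic, p_value, category`` (the output of the quantification +
    testing steps).  Effector-class genes with at least ``expressed_min_reads``
    reads in the infected library are kept, sorted stably by descending
    infected TMM; each row carries its regulation category, significance
    stars, and the homologous partner id where one is mapped.
    """
    effectors = annotated.index[annotated["immune_class"] == "effector"]
    sub = records.loc[records.index.intersection(effectors)].copy()
    sub = sub[sub["reads_infected"] >= expressed_min_reads]
    sub = sub.sort_values("tmm_infected", ascending=False, kind="stable")
    sub["stars"] = [significance_stars(p) for p in sub["p_value"]]
    sub["subtype"] = annotated.loc[sub.index, "effector_subtype"]
    if homology is not None:
        partner = homology.a_to_b()
        sub["homologue"] = [partner.get(g) for g in sub.index]
    return sub


@dataclass
class VennCounts:
    only_a: int
    shared: int
    only_b: int
    duplicates_a: int = 0
    duplicates_b: int = 0

    def as_tuple(self) -> tuple[int, int, int]:
        return self.only_a, self.shared, self.only_b


def venn_counts(
    expressed_a: Iterable[str],
    expressed_b: Iterable[str],
    homology: HomologyMap,
) -> VennCounts:
    """Venn counts of expressed genes, shared membership via homologue pairs.

    A gene of species A is "shared" when its resolved partner is expressed in
    species B.  Genes whose ids sat in multi-copy families are additionally
    tallied as duplicates (the parenthetical counts of the published Venn
    panels).
    """
    set_a = set(expressed_a)
    set_b = set(expressed_b)
    a2b = homology.a_to_b()
    shared = sum(1 for a in set_a if a2b.get(a) in set_b)
    return VennCounts(
        only_a=len(set_a) - shared,
        shared=shared,
        only_b=len(set_b) - shared,
        duplicates_a=len(set_a & homology.duplicates_a),
        duplicates_b=len(set_b & homology.duplicates_b),
    )
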