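"""Novel-gene discovery: mapping, contigs, flank extension, translated screen."""

import math
from dataclasses import dataclass

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from flyimm import synthetic as syn
from flyimm.discovery import (
    Contig,
    GenomeMapper,
    build_contigs,
    depth_normalized_ic,
    discover_genes,
    extend_contig,
    screen_homology,
    test_putative_genes as evaluate_putative_genes,
    PutativeGene,
)
from flyimm.quantify import IC_INFINITY
from flyimm.stats import ControlSet
from flyimm.synthetic import back_translate


@dataclass
class Read:
    read_id: str
    sequence: str
    condition: str = "infected"


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(100)
    return "".join(rng.choice(list("ACGT"), size=5000))


class TestBuildContigs:
    def test_overlapping_reads_merge_into_one_contig(self, toy_genome):
        reads = [
            Read("r1", toy_genome[1000:1100]),
            Read("r2", toy_genome[1050:1150]),
        ]
        contigs, unmapped = build_contigs(reads, toy_genome)
        assert unmapped == []
        assert len(contigs) == 1
        assert (contigs[0].start, contigs[0].end) == (1000, 1150)
        assert contigs[0].consensus == toy_genome[1000:1150]

    def test_non_overlapping_reads_stay_separate_and_disjoint(self, toy_genome):
        reads = [Read(f"r{i}", toy_genome[s : s + 80]) for i, s in enumerate([100, 400, 900])]
        contigs, _ = build_contigs(reads, toy_genome)
        assert len(contigs) == 3
        intervals = sorted((c.start, c.end) for c in contigs)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 <= s2  # pairwise disjoint after merging

    def test_reads_from_one_segment_give_contig_inside_truth_interval(self, catalog, genome):
        """Error-free reads from a planted hidden gene assemble within it."""
        hg = genome.hidden_genes[0]
        rng = np.random.default_rng(7)
        reads = []
        for i in range(30):
            start = int(rng.integers(hg.start, hg.end - 90))
            reads.append(Read(f"r{i}", genome.sequence[start : start + 90]))
        contigs, unmapped = build_contigs(reads, genome)
        assert unmapped == []
        assert len(contigs) == 1
        assert contigs[0].start >= hg.start
        assert contigs[0].end <= hg.end

    def test_mapped_fraction_reportable(self, toy_genome):
        reads = [Read("r1", toy_genome[10:110]), Read("r2", "A" * 100)]
        contigs, unmapped = build_contigs(reads, toy_genome)
        mapped_fraction = (2 - len(unmapped)) / 2
        assert mapped_fraction == 0.5


class TestExtendContig:
    def make_contig(self, start, end, genome):
        return Contig("CT0", start, end, genome[start:end], 1, 0, 1.0)

    def test_flank_arithmetic(self, toy_genome):
        contig = self.make_contig(1000, 1200, toy_genome)
        seq, (s, e) = extend_contig(contig, toy_genome, flank=250)
        assert (s, e) == (750, 1450)
        assert len(seq) == 700
        assert seq == toy_genome[750:1450]

    def test_left_flank_clipped_at_origin(self, toy_genome):
        contig = self.make_contig(0, 100, toy_genome)
        _, (s, e) = extend_contig(contig, toy_genome, flank=250)
        assert s == 0

    def test_median_length_contig_bounded_query(self, toy_genome):
        contig = self.make_contig(2000, 2192, toy_genome)
        seq, _ = extend_contig(contig, toy_genome, flank=250)
        assert len(seq) <= 692

    def test_zero_flank_is_identity(self, toy_genome):
        contig = self.make_contig(1000, 1200, toy_genome)
        seq, (s, e) = extend_contig(contig, toy_genome, flank=0)
        assert (s, e) == (1000, 1200)
        assert seq == contig.consensus


@pytest.fixture(scope="module")
def protein_db():
    rng = np.random.default_rng(5)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    db = {f"decoy{i:02d}": "".join(rng.choice(aas, size=130)) for i in range(15)}
    db["target"] = "MKWVKTLASQRGYHNDCFEPILVSTAQKGNWFRDHYECMLIPAVSTGKQN" + "RLEWDKAHYS"
    return db


class TestScreenHomology:
    def test_exact_orf_is_best_hit_below_threshold(self, protein_db, toy_genome):
        query = toy_genome[:200] + back_translate(protein_db["target"]) + toy_genome[300:500]
        hit = screen_homology(query, protein_db)
        assert hit is not None
        pid, e, frame = hit
        assert pid == "target"
        assert e <= 1e-5
        assert frame > 0

    def test_reverse_complement_orf_found_in_negative_frame(self, protein_db, toy_genome):
        insert = back_translate(protein_db["target"])
        query = toy_genome[:200] + reverse_complement(insert) + toy_genome[300:500]
        hit = screen_homology(query, protein_db)
        assert hit is not None
        assert hit[0] == "target"
        assert hit[2] < 0

    def test_random_queries_produce_no_hits_at_threshold(self, protein_db):
        rng = np.random.default_rng(11)
        false_hits = 0
        for _ in range(100):
            query = "".join(rng.choice(list("ACGT"), size=300))
            if screen_homology(query, protein_db) is not None:
                false_hits += 1
        assert false_hits == 0

    def test_threshold_is_pure_postcondition(self, protein_db, toy_genome):
        query = toy_genome[:100] + back_translate(protein_db["target"]) + toy_genome[200:300]
        strict = screen_homology(query, protein_db, e_threshold=1e-5)
        loose = screen_homology(query, protein_db, e_threshold=math.inf)
        assert strict is not None
        assert loose[:2] == strict[:2]

    def test_too_short_query_has_no_hit(self, protein_db):
        assert screen_homology("AC", protein_db) is None


class TestPutativeGeneTesting:
    def make_pg(self, reads_inf, reads_nv):
        contig = Contig("CT0", 0, 100, "A" * 100, reads_inf, reads_nv, 1.0)
        return PutativeGene("PG00000", contig, 0, 100, "hit", 1e-10, 1,
                            reads_inf, reads_nv)

    def test_infected_only_putative(self):
        cs = ControlSet(("c1", "c2"), 500, 500, 1.0)
        [pg] = evaluate_putative_genes([self.make_pg(7, 0)], cs, 1000, 1000)
        assert pg.ic is IC_INFINITY
        assert pg.p_value < 0.05

    def test_suppressed_putative_down_call(self):
        cs = ControlSet(("c1", "c2"), 500, 500, 1.0)
        [pg] = evaluate_putative_genes([self.make_pg(2, 10)], cs, 1000, 1000)
        assert pg.ic == pytest.approx(0.2)
        assert pg.test_used == "fisher"

    def test_depth_normalisation_uses_library_totals(self):
        assert depth_normalized_ic(10, 10, 2000, 1000) == pytest.approx(0.5)

    def test_null_putatives_type_one_error_near_alpha(self):
        rng = np.random.default_rng(21)
        cs = ControlSet(("c1", "c2"), 4000, 4000, 1.0)
        n_sig = 0
        n = 400
        for _ in range(n):
            mu = rng.uniform(20, 80)
            pg = self.make_pg(int(rng.poisson(mu)), int(rng.poisson(mu)))
            evaluate_putative_genes([pg], cs, 100_000, 100_000)
            if pg.p_value < 0.05:
                n_sig += 1
        from scipy import stats as sps

        lo, hi = sps.binom.ppf([0.005, 0.995], n, 0.05)
        assert lo <= n_sig <= hi


def test_end_to_end_recovery_of_planted_genes(catalog, genome):
    """Hidden genes with >= 20 reads are recovered by the full discovery path."""
    rng = np.random.default_rng(33)
    reads = []
    per_gene = {}
    for hg in genome.hidden_genes:
        k = int(rng.integers(20, 40))
        per_gene[hg.name] = k
        for i in range(k):
            start = int(rng.integers(hg.start, hg.end - 90))
            reads.append(Read(f"{hg.name}_r{i}", genome.sequence[start : start + 90]))
    proteins = {f"{hg.name}_prot": hg.protein for hg in genome.hidden_genes}
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for i in range(10):
        proteins[f"decoy{i}"] = "".join(rng.choice(aas, size=120))
    cs = ControlSet(("c1", "c2"), 1000, 1000, 1.0)
    putatives, contigs, unmapped = discover_genes(
        reads, genome, proteins, cs, 50_000, 50_000
    )
    assert unmapped == []
    recovered = {p.hit_id for p in putatives}
    eligible = [hg for hg in genome.hidden_genes if per_gene[hg.name] >= 20]
    frac = sum(1 for hg in eligible if f"{hg.name}_prot" in recovered) / len(eligible)
    assert frac >= 0.9
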