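"""Synthetic data generation for the immune-transcriptome pipeline.

The study this package models sequenced pooled larval fat-body/salivary-gland
cDNA of two Drosophila species (fungus-infected vs naïve) on a 454 GS Junior;
the raw libraries were never deposited.  This module generates stand-ins with
the statistical structure the downstream analysis assumes:

* a gene catalog with transcript lengths, immune classes and endogenous
  control genes,
* paired two-condition read-count tables from a negative-binomial model with
  known per-gene fold changes (truth labels returned for recovery tests),
* read libraries drawn verbatim from mitochondrial / rRNA / nuclear-gene /
  unannotated genome segments,
* secreted-peptide precursors with signal–propeptide–mature architecture,
* daily survival counts from a logistic time-to-death model.

All randomness flows through one ``numpy.random.default_rng(seed)`` per call,
so a fixed seed gives byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = np.array(list("ACGT"))
IMMUNE_CLASSES = ("recognition", "signaling", "effector", "none")
EFFECTOR_SUBTYPES = ("AMP", "IM", "other")

#: Reserved fold-change token for genes expressed only after infection.
INFECTED_ONLY = "infected_only"

# Residue pools for precursor construction.  The propeptide pool avoids
# K/R (so the terminal dibasic motif is the first one) and A/G/S/C (so the
# signal-cleavage context is unambiguous).
_HYDROPHOBIC = list("LIVF")
_PROPEPTIDE_POOL = list("NQEDTPH")
_MATURE_NEUTRAL = list("GASTNQ")


# ---------------------------------------------------------------------------
# Gene catalog
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    gene_id: str
    transcript_length: int
    cds_sequence: str
    immune_class: str = "none"
    effector_subtype: str | None = None
    is_control: bool = False
    homologue_id: str | None = None

    def __post_init__(self) -> None:
        if self.immune_class not in IMMUNE_CLASSES:
            raise ValueError(f"unknown immune class {self.immune_class!r}")
        if self.transcript_length < len(self.cds_sequence):
            raise ValueError(
                f"{self.gene_id}: transcript length {self.transcript_length} "
                f"shorter than CDS ({len(self.cds_sequence)} bp)"
            )


@dataclass
class GeneCatalog:
    entries: list[GeneModel]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids are not unique")
        if len(self.control_ids) < 2:
            raise ValueError("a catalog needs at least two endogenous controls")

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.entries]

    @property
    def control_ids(self) -> list[str]:
        return [g.gene_id for g in self.entries if g.is_control]

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, gene_id: str) -> GeneModel:
        for g in self.entries:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.entries],
                "transcript_length": [g.transcript_length for g in self.entries],
                "immune_class": [g.immune_class for g in self.entries],
                "effector_subtype": [g.effector_subtype for g in self.entries],
                "is_control": [g.is_control for g in self.entries],
                "homologue_id": [g.homologue_id for g in self.entries],
            }
        ).set_index("gene_id")


DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    # roughly the proportions seen in a whole-transcriptome immune catalog
    # (a few percent of detected genes are immune-related)
    "recognition": 0.02,
    "signaling": 0.05,
    "effector": 0.03,
}


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def generate_gene_catalog(
    n_genes: int,
    class_fractions: Mapping[str, float] | None = None,
    mean_length: int = 900,
    min_cds_length: int = 150,
    seed: int = 0,
) -> GeneCatalog:
    """Generate a deterministic gene catalog with endogenous controls.

    CDS lengths are drawn from a gamma distribution (shape 4) around
    ``mean_length``, floored at ``min_cds_length`` and rounded to a codon
    multiple; transcript length adds a uniform 100–500 bp of UTR.  The first
    two genes are the endogenous controls (ribosomal-protein / GAPDH
    analogues), immune class ``none`` and true fold change pinned at 1 by
    :func:`generate_count_experiment` callers.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    fractions = dict(DEFAULT_CLASS_FRACTIONS if class_fractions is None else class_fractions)
    unknown = set(fractions) - set(IMMUNE_CLASSES[:3])
    if unknown:
        raise ValueError(f"unknown immune classes in fractions: {sorted(unknown)}")
    if any(f < 0 for f in fractions.values()) or sum(fractions.values()) > 1:
        raise ValueError("class fractions must be non-negative and sum to <= 1")

    rng = np.random.default_rng(seed)
    lengths = rng.gamma(shape=4.0, scale=mean_length / 4.0, size=n_genes)
    cds_lengths = np.maximum(min_cds_length, (lengths // 3).astype(int) * 3)
    utr = rng.integers(100, 501, size=n_genes)

    class_draws = rng.random(n_genes)
    subtype_draws = rng.random(n_genes)

    entries: list[GeneModel] = []
    for i in range(n_genes):
        if i == 0:
            gene_id, is_control = "RpL32", True
        elif i == 1:
            gene_id, is_control = "GAPDH", True
        else:
            gene_id, is_control = f"G{i:05d}", False
        immune_class = "none"
        if not is_control:
            cum = 0.0
            for cls in ("recognition", "signaling", "effector"):
                cum += fractions.get(cls, 0.0)
                if class_draws[i] < cum:
                    immune_class = cls
                    break
        subtype = None
        if immune_class == "effector":
            subtype = ("AMP", "IM", "other")[int(subtype_draws[i] * 3) % 3]
        entries.append(
            GeneModel(
                gene_id=gene_id,
                transcript_length=int(cds_lengths[i] + utr[i]),
                cds_sequence=_random_dna(rng, int(cds_lengths[i])),
                immune_class=immune_class,
                effector_subtype=subtype,
                is_control=is_control,
            )
        )
    return GeneCatalog(entries)


# ---------------------------------------------------------------------------
# Count experiment
# ---------------------------------------------------------------------------

@dataclass
class InductionSpec:
    """Ground-truth description of a two-condition count experiment.

    ``fold_changes`` maps gene id to the true infected/naïve expression ratio
    (1.0 = unchanged) or the :data:`INFECTED_ONLY` token for genes silent in
    the naïve larvae.  ``dispersion`` is the negative-binomial dispersion
    (variance = mean + dispersion * mean^2); 0 degenerates to Poisson.
    ``depth_*`` are expected library sizes (reads) for an unchanged
    transcriptome.  ``control_boost`` multiplies the expression weight of the
    endogenous control genes: housekeeping controls (ribosomal protein,
    GAPDH) are among the most highly expressed genes in a real library, and
    the pooled control counts anchor every downstream contingency test.
    """

    fold_changes: Mapping[str, float | str]
    dispersion: float = 0.1
    depth_infected: int = 60_000
    depth_naive: int = 60_000
    infected_only_rate: float = 4.0  # expression multiplier for INFECTED_ONLY genes
    control_boost: float = 50.0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.depth_infected <= 0 or self.depth_naive <= 0:
            raise ValueError("library depths must be positive")
        for gid, fc in self.fold_changes.items():
            if fc == INFECTED_ONLY:
                continue
            if not (isinstance(fc, (int, float)) and fc > 0):
                raise ValueError(f"{gid}: fold change must be positive or {INFECTED_ONLY!r}")

    @classmethod
    def null(cls, catalog: GeneCatalog, **kwargs) -> "InductionSpec":
        return cls({g: 1.0 for g in catalog.gene_ids}, **kwargs)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if dispersion < 1e-12:
        out[pos] = rng.poisson(mean[pos])
    else:
        n = 1.0 / dispersion
        p = n / (n + mean[pos])
        out[pos] = rng.negative_binomial(n, p)
    return out


def generate_count_experiment(
    catalog: GeneCatalog,
    spec: InductionSpec,
    seed: int = 0,
) -> tuple["pd.DataFrame", pd.DataFrame]:
    """Draw a paired infected/naïve count table plus truth labels.

    Relative expression weights are lognormal per gene (transcript-length
    weighted, since longer transcripts attract more shotgun reads); the naïve
    mean for gene *g* is ``depth_naive * w_g`` and the infected mean
    ``depth_infected * w_g * fc_g``.  Returns ``(counts, truth)`` where
    ``counts`` has columns ``reads_infected, reads_naive, transcript_length``
    indexed by gene and ``truth`` carries the true fold changes and means.
    """
    missing = set(catalog.gene_ids) - set(spec.fold_changes)
    if missing:
        raise ValueError(f"fold changes missing for {len(missing)} genes")

    rng = np.random.default_rng(seed)
    ids = catalog.gene_ids
    lengths = np.array([g.transcript_length for g in catalog.entries], dtype=float)
    expr = rng.lognormal(mean=0.0, sigma=1.0, size=len(ids)) * lengths
    is_control = np.array([g.is_control for g in catalog.entries])
    expr[is_control] *= spec.control_boost
    weights = expr / expr.sum()

    fc = np.ones(len(ids))
    infected_only = np.zeros(len(ids), dtype=bool)
    for i, gid in enumerate(ids):
        val = spec.fold_changes[gid]
        if val == INFECTED_ONLY:
            infected_only[i] = True
            fc[i] = spec.infected_only_rate
        else:
            fc[i] = float(val)

    mean_naive = spec.depth_naive * weights
    mean_naive[infected_only] = 0.0
    mean_infected = spec.depth_infected * weights * fc

    counts = pd.DataFrame(
        {
            "reads_infected": _nb_draw(rng, mean_infected, spec.dispersion),
            "reads_naive": _nb_draw(rng, mean_naive, spec.dispersion),
            "transcript_length": lengths.astype(int),
        },
        index=pd.Index(ids, name="gene_id"),
    )
    truth = pd.DataFrame(
        {
            "true_fc": [spec.fold_changes[g] for g in ids],
            "mean_infected": mean_infected,
            "mean_naive": mean_naive,
            "is_control": [g.is_control for g in catalog.entries],
        },
        index=counts.index,
    )
    return counts, truth


# ---------------------------------------------------------------------------
# Genome and read libraries
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    kind: str  # mito | rrna | gene | unannotated | spacer
    name: str
    start: int  # 0-based, half-open
    end: int


@dataclass
class HiddenGene:
    name: str
    start: int
    end: int
    protein: str


@dataclass
class SyntheticGenome:
    sequence: str
    segments: list[Segment]
    hidden_genes: list[HiddenGene] = field(default_factory=list)

    def segments_of(self, kind: str) -> list[Segment]:
        return [s for s in self.segments if s.kind == kind]

    def segment_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.kind, s.name, s.start, s.end) for s in self.segments],
            columns=["kind", "name", "start", "end"],
        )

    def __len__(self) -> int:
        return len(self.sequence)


_CODONS = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}


def back_translate(protein: str) -> str:
    """One fixed codon per residue — deterministic reverse translation."""
    return "".join(_CODONS[aa] for aa in protein)


def generate_genome(
    catalog: GeneCatalog,
    mito_length: int = 2_000,
    rrna_length: int = 2_000,
    n_unannotated: int = 3,
    unannotated_length: int = 2_000,
    n_hidden_genes: int = 0,
    hidden_gene_length: int = 100,  # amino acids
    spacer_length: int = 100,
    seed: int = 0,
) -> SyntheticGenome:
    """Assemble a single genome string with annotated segment intervals.

    Layout: mito segment, rRNA segment, each catalog gene's CDS (separated by
    spacers), then unannotated segments.  Up to one hidden protein-coding
    gene is planted per unannotated segment (round-robin) until
    ``n_hidden_genes`` are placed; these emulate unannotated transcription
    units discoverable from unidentified reads.
    """
    if n_hidden_genes > n_unannotated:
        raise ValueError("at most one hidden gene per unannotated segment")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    segments: list[Segment] = []
    hidden: list[HiddenGene] = []
    pos = 0

    def _push(kind: str, name: str, seq: str) -> None:
        nonlocal pos
        segments.append(Segment(kind, name, pos, pos + len(seq)))
        parts.append(seq)
        pos += len(seq)

    _push("mito", "mito", _random_dna(rng, mito_length))
    _push("spacer", "sp_mito", _random_dna(rng, spacer_length))
    _push("rrna", "rrna", _random_dna(rng, rrna_length))
    for gene in catalog.entries:
        _push("spacer", f"sp_{gene.gene_id}", _random_dna(rng, spacer_length))
        _push("gene", gene.gene_id, gene.cds_sequence)
    aa_alphabet = np.array(list(_CODONS))
    for i in range(n_unannotated):
        _push("spacer", f"sp_u{i}", _random_dna(rng, spacer_length))
        if i < n_hidden_genes:
            protein = "".join(rng.choice(aa_alphabet, size=hidden_gene_length))
            coding = back_translate(protein)
            pad_total = max(0, unannotated_length - len(coding))
            pad_left = int(rng.integers(0, pad_total + 1))
            seq = _random_dna(rng, pad_left) + coding + _random_dna(rng, pad_total - pad_left)
            start = pos + pad_left
            hidden.append(HiddenGene(f"HG{i:03d}", start, start + len(coding), protein))
            _push("unannotated", f"U{i:03d}", seq)
        else:
            _push("unannotated", f"U{i:03d}", _random_dna(rng, unannotated_length))

    return SyntheticGenome("".join(parts), segments, hidden)


@dataclass
class ReadRecord:
    read_id: str
    sequence: str
    truth_source: str  # mito | rrna | gene:<id> | unannotated
    condition: str  # infected | naive


@dataclass
class ReadSet:
    records: list[ReadRecord]

    def __post_init__(self) -> None:
        ids = [r.read_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("read ids not unique")
        for r in self.records:
            if not r.sequence or set(r.sequence) - set("ACGT"):
                raise ValueError(f"{r.read_id}: invalid sequence")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


DEFAULT_MIX = {"mito": 0.05, "rrna": 0.25, "gene": 0.5, "unannotated": 0.2}


def _substring_read(rng: np.random.Generator, source: str, read_length: int) -> str:
    if read_length > len(source):
        raise ValueError(
            f"read length {read_length} exceeds source length {len(source)}"
        )
    start = int(rng.integers(0, len(source) - read_length + 1))
    return source[start : start + read_length]


def generate_read_library(
    catalog: GeneCatalog,
    genome: SyntheticGenome,
    mix: Mapping[str, float] | None = None,
    n_reads: int = 10_000,
    read_length: int = 100,
    condition: str = "infected",
    gene_counts: Mapping[str, int] | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSet:
    """Draw reads as exact substrings of their truth sources.

    ``mix`` gives category fractions for mito / rrna / gene / unannotated.
    Gene reads come from CDS sequences (uniformly over genes whose CDS is
    long enough, or proportional to ``gene_counts`` when given).  Unannotated
    reads come from hidden-gene transcripts when the genome has planted any,
    otherwise uniformly from unannotated segments.  ``error_rate`` optionally
    applies uniform substitutions (off by default so triage can be tested
    exactly).
    """
    mix = dict(DEFAULT_MIX if mix is None else mix)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("mix fractions must sum to 1")
    rng = np.random.default_rng(seed)

    mito_seq = genome.sequence[genome.segments_of("mito")[0].start : genome.segments_of("mito")[0].end]
    rrna_seq = genome.sequence[genome.segments_of("rrna")[0].start : genome.segments_of("rrna")[0].end]
    unann = genome.segments_of("unannotated")
    if not unann and mix.get("unannotated", 0) > 0:
        raise ValueError("genome has no unannotated segments")

    if gene_counts is None:
        eligible = [g for g in catalog.entries if len(g.cds_sequence) >= read_length]
        gene_pool = [g.gene_id for g in eligible]
        gene_probs = None
    else:
        gene_pool = [g for g, c in gene_counts.items() if c > 0
                     and len(catalog[g].cds_sequence) >= read_length]
        totals = np.array([gene_counts[g] for g in gene_pool], dtype=float)
        gene_probs = totals / totals.sum()
    if mix.get("gene", 0) > 0 and not gene_pool:
        raise ValueError("no gene CDS long enough for the requested read length")

    categories = list(mix)
    cat_idx = rng.choice(len(categories), size=n_reads, p=[mix[c] for c in categories])
    records: list[ReadRecord] = []
    for i in range(n_reads):
        cat = categories[int(cat_idx[i])]
        if cat == "mito":
            seq, truth = _substring_read(rng, mito_seq, read_length), "mito"
        elif cat == "rrna":
            seq, truth = _substring_read(rng, rrna_seq, read_length), "rrna"
        elif cat == "gene":
            if gene_probs is None:
                gid = gene_pool[int(rng.integers(0, len(gene_pool)))]
            else:
                gid = gene_pool[int(rng.choice(len(gene_pool), p=gene_probs))]
            seq, truth = _substring_read(rng, catalog[gid].cds_sequence, read_length), f"gene:{gid}"
        elif cat == "unannotated":
            if genome.hidden_genes:
                hg = genome.hidden_genes[int(rng.integers(0, len(genome.hidden_genes)))]
                source = genome.sequence[hg.start : hg.end]
            else:
                seg = unann[int(rng.integers(0, len(unann)))]
                source = genome.sequence[seg.start : seg.end]
            seq, truth = _substring_read(rng, source, read_length), "unannotated"
        else:
            raise ValueError(f"unknown mix category {cat!r}")
        if error_rate > 0:
            chars = np.array(list(seq))
            hit = rng.random(len(chars)) < error_rate
            if hit.any():
                chars[hit] = rng.choice(NUCLEOTIDES, size=int(hit.sum()))
                seq = "".join(chars)
        records.append(ReadRecord(f"{condition[:3]}_{i:06d}", seq, truth, condition))
    return ReadSet(records)


# ---------------------------------------------------------------------------
# Peptide precursors
# ---------------------------------------------------------------------------

@dataclass
class PrecursorTruth:
    sequence: str
    is_amp: bool
    signal_end: int  # mature region of the precursor starts here if no propeptide
    mature_start: int  # index into the precursor
    violation: str | None = None  # which criterion a non-AMP breaks


def _net_charge(seq: str) -> int:
    return seq.count("K") + seq.count("R") - seq.count("D") - seq.count("E")


def generate_precursor_peptides(
    n: int,
    amp_fraction: float = 0.3,
    seed: int = 0,
) -> list[PrecursorTruth]:
    """Generate secreted-peptide precursors with known segmentation.

    AMP-truth precursors carry (i) an N-terminal signal peptide — a short
    positively charged n-region, a hydrophobic core of 8 Leu/Ile/Val/Phe,
    and a small-residue cleavage context ending in Ala; (ii) a propeptide
    ending in a dibasic Lys-Arg motif; and (iii) a cationic mature segment of
    net charge >= +2 and 15–60 residues.  Non-AMP precursors violate exactly
    one criterion (no signal peptide, or an anionic mature segment).
    """
    if not 0 <= amp_fraction <= 1:
        raise ValueError("amp_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[PrecursorTruth] = []
    is_amp = rng.random(n) < amp_fraction
    for i in range(n):
        # signal peptide: M + K + 8 hydrophobics + "SAA" cleavage context
        n_region = "M" + "K" * int(rng.integers(1, 3))
        core = "".join(rng.choice(_HYDROPHOBIC, size=8))
        c_region = "S" + "A" * int(rng.integers(1, 3)) + "A"
        signal = n_region + core + c_region
        # propeptide: 6-14 residues avoiding K/R and A/G/S/C, ending in KR
        pro_len = int(rng.integers(6, 15))
        propep = "".join(rng.choice(_PROPEPTIDE_POOL, size=pro_len)) + "KR"
        mat_len = int(rng.integers(15, 61))
        if is_amp[i]:
            n_basic = int(rng.integers(4, 9))
            residues = ["K" if rng.random() < 0.5 else "R" for _ in range(n_basic)]
            residues += list(rng.choice(_MATURE_NEUTRAL, size=mat_len - n_basic))
            mature = "".join(rng.permutation(residues))
            # permutation may create internal dibasic motifs; that is fine —
            # only the first dibasic after the signal defines the cleavage,
            # and it is the planted propeptide terminus.
            seq = signal + propep + mature
            out.append(PrecursorTruth(seq, True, len(signal),
                                      len(signal) + len(propep)))
        else:
            which = int(rng.integers(0, 2))
            if which == 0:
                # no signal peptide: acidic N-terminus, no hydrophobic core
                head = "M" + "".join(rng.choice(list("DENQST"), size=len(signal) - 1))
                mature = "".join(rng.choice(_MATURE_NEUTRAL, size=mat_len))
                seq = head + propep + mature
                out.append(PrecursorTruth(seq, False, len(head),
                                          len(head) + len(propep), "no_signal"))
            else:
                # signal present but mature segment anionic
                n_acid = int(rng.integers(3, 7))
                residues = ["D" if rng.random() < 0.5 else "E" for _ in range(n_acid)]
                residues += list(rng.choice(_MATURE_NEUTRAL, size=mat_len - n_acid))
                mature = "".join(rng.permutation(residues))
                seq = signal + propep + mature
                out.append(PrecursorTruth(seq, False, len(signal),
                                          len(signal) + len(propep), "anionic_mature"))
    return out


# ---------------------------------------------------------------------------
# Survival counts
# ---------------------------------------------------------------------------

def generate_survival_counts(
    n_flies: int,
    lt50_true: float,
    slope: float = 1.5,
    horizon: int = 14,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily alive counts from a logistic time-to-death model.

    Each fly's death time is logistic with location ``lt50_true`` and scale
    ``1/slope``; a fly counted alive on day *t* has death time > *t*.
    ``slope = inf`` gives the deterministic step curve (all deaths at the
    LT50 boundary).  Returns a frame with columns ``day`` (0..horizon) and
    ``alive``.
    """
    if n_flies < 10:
        raise ValueError("n_flies must be >= 10")
    if slope <= 0:
        raise ValueError("slope must be positive")
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    rng = np.random.default_rng(seed)
    if math.isinf(slope):
        death = np.full(n_flies, float(lt50_true))
    else:
        death = rng.logistic(loc=lt50_true, scale=1.0 / slope, size=n_flies)
    days = np.arange(0, horizon + 1)
    alive = (death[None, :] > days[:, None]).sum(axis=1)
    return pd.DataFrame({"day": days, "alive": alive, "n_start": n_flies})
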