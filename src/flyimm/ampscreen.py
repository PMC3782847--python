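"""Physicochemical screening of peptide precursors for AMP candidacy.

Antimicrobial peptides of insects are small cationic secreted peptides,
typically synthesised as a precursor: an N-terminal signal peptide, often a
propeptide released at a dibasic site, and the mature cationic peptide.  The
screen segments a precursor with transparent heuristics (a pluggable
predictor interface admits external signal-peptide/propeptide tools), computes
mature-peptide properties — length, molecular weight (average residue masses),
net charge at neutral pH by integer side-chain counting, the most enriched
residue pair — and calls a candidate an AMP when it is secreted, its mature
peptide is cationic (net charge >= +2) and of typical AMP length (10–100 aa).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

# Kyte–Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Average masses of the free amino acids (Da); peptide-bond formation
# releases one water (18.02 Da) per bond.
FREE_AA_MASS = {
    "G": 75.07, "A": 89.09, "S": 105.09, "P": 115.13, "V": 117.15,
    "T": 119.12, "C": 121.16, "L": 131.17, "I": 131.17, "N": 132.12,
    "D": 133.10, "Q": 146.15, "K": 146.19, "E": 147.13, "M": 149.21,
    "H": 155.16, "F": 165.19, "R": 174.20, "Y": 181.19, "W": 204.23,
}

WATER_MASS = 18.02
DIBASIC_MOTIFS = ("KR", "RR", "KK", "RK")
CLEAVAGE_CONTEXT = set("AGSC")


@dataclass
class PeptideCandidate:
    precursor: str
    signal_end: int | None  # [0, signal_end) is the signal peptide
    mature_start: int  # mature segment start in the precursor
    mature: str
    mature_length: int
    molecular_weight_kda: float
    net_charge: int
    enriched_residues: tuple[str, float]  # (two-letter residue pair, combined fraction)
    is_secreted: bool
    has_propeptide: bool
    amp_call: bool = False


def net_charge(sequence: str) -> int:
    """Net charge at neutral pH: #K + #R − #D − #E (His excluded, termini ignored)."""
    return (
        sequence.count("K") + sequence.count("R")
        - sequence.count("D") - sequence.count("E")
    )


def predict_signal_peptide(
    precursor: str,
    max_core_start: int = 30,
    core_length: int = 6,
    min_hydropathy: float = 1.6,
    cleavage_window: int = 8,
) -> int | None:
    """Heuristic signal-peptide detection; returns the cleavage boundary.

    Looks within the first ``max_core_start`` residues for a hydrophobic core
    (a run of >= ``core_length`` consecutive residues, each of Kyte–Doolittle
    hydropathy >= ``min_hydropathy``, so the run mean also clears the
    threshold), requires at least one Lys/Arg in the n-region before the
    core, and a small residue (Ala/Gly/Ser/Cys) at the −1 position within
    ``cleavage_window`` residues after the core.  The returned index is the
    first residue of the post-signal region; None means no signal peptide (a
    valid outcome, not an error).
    """
    if len(precursor) < 15:
        raise ValueError("precursor shorter than 15 residues")
    kd = [KYTE_DOOLITTLE.get(a) for a in precursor]
    if any(v is None for v in kd):
        raise ValueError("non-standard residue in precursor")

    # first maximal hydrophobic run of sufficient length starting in-range
    core_start = core_end = None
    i = 1
    while i <= min(max_core_start, len(precursor) - core_length):
        if kd[i] >= min_hydropathy:
            j = i
            while j < len(precursor) and kd[j] >= min_hydropathy:
                j += 1
            if j - i >= core_length:
                core_start, core_end = i, j
                break
            i = j
        i += 1
    if core_start is None:
        return None
    if not any(a in "KR" for a in precursor[:core_start]):
        return None

    # latest qualifying small-residue −1 position within the window
    cleavage = None
    for pos in range(core_end + 1, min(core_end + cleavage_window, len(precursor) - 1) + 1):
        if precursor[pos - 1] in CLEAVAGE_CONTEXT:
            cleavage = pos
    return cleavage


def predict_propeptide_cleavage(post_signal: str) -> int | None:
    """Mature-peptide start after the first dibasic motif (KR/RR/KK/RK).

    The motif must start at position >= 2 of the post-signal sequence; the
    mature peptide begins immediately after it.  None when no motif is found
    (the whole post-signal sequence is then the mature peptide).
    """
    if not post_signal:
        raise ValueError("post-signal sequence is empty")
    for i in range(2, len(post_signal) - 1):
        if post_signal[i : i + 2] in DIBASIC_MOTIFS:
            return i + 2
    return None


def peptide_properties(mature: str) -> tuple[int, float, int, tuple[str, float]]:
    """(length, molecular weight in kDa, net charge, enriched residue pair).

    MW sums average free-amino-acid masses minus one water per peptide bond.
    The enriched pair is the two residues of highest combined fraction
    (alphabetical within ties), reported with that fraction.
    """
    if not mature:
        raise ValueError("empty mature sequence")
    bad = set(mature) - set(FREE_AA_MASS)
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)}")
    mw_da = sum(FREE_AA_MASS[a] for a in mature) - (len(mature) - 1) * WATER_MASS
    counts = {a: mature.count(a) for a in set(mature)}
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) == 1:
        pair, combined = ranked[0][0] * 2, ranked[0][1]
    else:
        pair = "".join(sorted((ranked[0][0], ranked[1][0])))
        combined = ranked[0][1] + ranked[1][1]
    return len(mature), mw_da / 1000.0, net_charge(mature), (pair, combined / len(mature))


def screen_precursor(
    precursor: str,
    signal_predictor: Callable[[str], int | None] | None = None,
    propeptide_predictor: Callable[[str], int | None] | None = None,
) -> PeptideCandidate:
    """Segment a precursor and compute mature-peptide properties.

    External predictors (e.g. wrappers around dedicated signal-peptide or
    propeptide tools) can replace the built-in heuristics; they must return a
    cleavage index or None.
    """
    signal_predictor = signal_predictor or predict_signal_peptide
    propeptide_predictor = propeptide_predictor or predict_propeptide_cleavage

    signal_end = signal_predictor(precursor)
    is_secreted = signal_end is not None
    post_signal = precursor[signal_end:] if is_secreted else precursor
    pro_end = propeptide_predictor(post_signal) if post_signal else None
    has_propeptide = pro_end is not None
    mature_start = (signal_end or 0) + (pro_end or 0)
    mature = precursor[mature_start:]
    if not mature:  # degenerate segmentation: treat the post-signal part as mature
        mature_start = signal_end or 0
        mature = precursor[mature_start:]
        has_propeptide = False
    length, mw, charge, enriched = peptide_properties(mature)
    return PeptideCandidate(
        precursor=precursor,
        signal_end=signal_end,
        mature_start=mature_start,
        mature=mature,
        mature_length=length,
        molecular_weight_kda=mw,
        net_charge=charge,
        enriched_residues=enriched,
        is_secreted=is_secreted,
        has_propeptide=has_propeptide,
    )


def amp_verdict(
    candidate: PeptideCandidate,
    min_charge: int = 2,
    min_length: int = 10,
    max_length: int = 100,
    require_propeptide: bool = False,
) -> bool:
    """AMP call: secreted, cationic mature peptide of typical AMP length.

    Propeptide presence is reported on the candidate but not required by
    default (set ``require_propeptide`` to demand it).
    """
    ok = (
        candidate.is_secreted
        and candidate.net_charge >= min_charge
        and min_length <= candidate.mature_length <= max_length
    )
    if require_propeptide:
        ok = ok and candidate.has_propeptide
    return bool(ok)


def screen_peptides(
    precursors: Sequence[str],
    **verdict_kwargs,
) -> list[PeptideCandidate]:
    """Screen a batch of precursors; sets ``amp_call`` on each candidate."""
    out = []
    for seq in precursors:
        cand = screen_precursor(seq)
        cand.amp_call = amp_verdict(cand, **verdict_kwargs)
        out.append(cand)
    return out
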