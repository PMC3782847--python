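"""Control-anchored significance testing of per-gene induction.

With a single pooled library per condition there are no replicates, so each
gene's infected/naïve read counts are compared against the pooled counts of
endogenous control genes (a ribosomal protein gene and GAPDH) on a 2x2
contingency table:

    [[gene_infected,    gene_naive   ],
     [control_infected, control_naive]]

Pearson's chi-square (1 df, no continuity correction) is used when every cell
holds at least five reads, otherwise the two-sided Fisher exact test
(probability-mass rule).  Genes are then categorised by their induction
coefficient: infected-only, >2-fold up, weakly up, weakly down, <2-fold down.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from flyimm.quantify import CountTable, IC_INFINITY, ic_is_undefined

CATEGORIES = (
    "infected_only",
    "up_strong",
    "up_weak",
    "unchanged",
    "down_weak",
    "down_strong",
    "undefined",
)


@dataclass
class ControlSet:
    """Pooled endogenous-control counts anchoring every per-gene test."""

    control_ids: tuple[str, ...]
    pooled_infected: int
    pooled_naive: int
    homogeneity_p: float

    def __post_init__(self) -> None:
        if self.pooled_infected <= 0 or self.pooled_naive <= 0:
            raise ValueError("pooled control counts must be positive in both conditions")


@dataclass
class RegulationCall:
    gene_id: str
    ic: float
    p_value: float
    significant: bool
    category: str


def pool_controls(table: CountTable, control_ids: Sequence[str]) -> ControlSet:
    """Pool control-gene counts and test their between-condition homogeneity.

    Pooling the controls is only defensible if their infected/naïve read
    proportions agree; with two controls this is Fisher's exact test on the
    2x2 control table (a chi-square is used for >2 controls, where scipy has
    no exact r x 2 test).  A single control pools trivially (p = 1 by
    convention).
    """
    present = [g for g in control_ids if g in table.gene_ids]
    if not present:
        raise ValueError(f"no control gene of {list(control_ids)} found in the table")
    counts = np.array([table.counts(g) for g in present], dtype=int)
    pooled_inf, pooled_nv = counts.sum(axis=0)
    if len(present) == 1:
        p = 1.0
    elif len(present) == 2:
        p = float(sps.fisher_exact(counts, alternative="two-sided")[1])
    else:
        p = float(sps.chi2_contingency(counts, correction=False)[1])
    return ControlSet(tuple(present), int(pooled_inf), int(pooled_nv), p)


def gene_induction_test(
    gene_counts: tuple[int, int],
    control_counts: tuple[int, int],
) -> tuple[float, str]:
    """Test one gene's counts against the pooled controls.

    Builds the 2x2 table [gene_inf, gene_naive; ctrl_inf, ctrl_naive].  If
    the minimum over the four cells is >= 5, Pearson's chi-square (1 df, no
    continuity correction) is applied; otherwise the two-sided Fisher exact
    test.  Returns ``(p_value, test_used)`` where ``test_used`` is one of
    ``chi2``, ``fisher`` or ``no-signal`` (both gene counts zero; p = 1).
    """
    gi, gn = gene_counts
    ci, cn = control_counts
    if min(gi, gn, ci, cn) < 0:
        raise ValueError("counts must be non-negative")
    if ci <= 0 or cn <= 0:
        raise ValueError("control counts must be positive in both conditions")
    if gi == 0 and gn == 0:
        return 1.0, "no-signal"
    table = np.array([[gi, gn], [ci, cn]], dtype=int)
    if table.min() >= 5:
        _, p, _, _ = sps.chi2_contingency(table, correction=False)
        return float(p), "chi2"
    p = sps.fisher_exact(table, alternative="two-sided")[1]
    return float(p), "fisher"


def classify_regulation(
    gene_id: str,
    ic: float,
    p_value: float,
    alpha: float = 0.05,
) -> RegulationCall:
    """Categorise a gene by its induction coefficient.

    Boundary conventions: IC exactly 2 is weakly up, exactly 0.5 weakly down,
    exactly 1 unchanged.  ``infected_only`` is reserved for IC = INFINITY.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if ic_is_undefined(ic):
        category = "undefined"
    elif math.isinf(ic):
        category = "infected_only"
    elif ic > 2.0:
        category = "up_strong"
    elif ic > 1.0 or ic == 2.0:
        category = "up_weak"
    elif ic == 1.0:
        category = "unchanged"
    elif ic >= 0.5:
        category = "down_weak"
    else:
        category = "down_strong"
    return RegulationCall(gene_id, ic, p_value, bool(p_value < alpha), category)


def significance_stars(p_value: float) -> str:
    """The published tables' asterisk convention (*P<0.05, **P<0.01)."""
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Optional BH adjustment (off by default in the pipeline — the analysis
    reports raw p-values)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(p_values), method="fdr_bh")[1]


def test_gene_table(
    table: CountTable,
    control_ids: Sequence[str],
    ic_values: Mapping[str, float],
    alpha: float = 0.05,
    adjust: bool = False,
) -> "pd.DataFrame":
    """Run the control-anchored test over every gene of a count table.

    Control genes themselves are excluded from testing.  Returns a frame with
    columns ``p_value, test_used, significant, category, stars`` indexed by
    gene id.
    """
    import pandas as pd

    controls = pool_controls(table, control_ids)
    rows = []
    genes = [g for g in table.gene_ids if g not in controls.control_ids]
    for gid in genes:
        p, used = gene_induction_test(
            table.counts(gid), (controls.pooled_infected, controls.pooled_naive)
        )
        rows.append((gid, p, used))
    frame = pd.DataFrame(rows, columns=["gene_id", "p_value", "test_used"]).set_index("gene_id")
    if adjust:
        frame["p_value"] = benjamini_hochberg(frame["p_value"])
    calls = [
        classify_regulation(gid, ic_values.get(gid, IC_INFINITY), frame.loc[gid, "p_value"], alpha)
        for gid in frame.index
    ]
    frame["ic"] = [c.ic for c in calls]
    frame["significant"] = [c.significant for c in calls]
    frame["category"] = [c.category for c in calls]
    frame["stars"] = [significance_stars(p) for p in frame["p_value"]]
    return frame
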