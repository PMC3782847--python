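"""Expression quantification: RPSM, TMM normalisation, induction coefficients.

Expression is first standardised to reads per site per million reads,

    RPSM = (reads / total_reads / transcript_length) * 1e6,

which calibrates both sequencing depth and transcript length.  A between-
library trimmed-mean-of-M-values (TMM) factor then corrects for composition
differences between the infected and naïve libraries; the normalised value is
RPSM divided by the library's factor.  The induction coefficient is

    IC = TMM_infected / TMM_naive,

with the distinguished value INFINITY when a gene is observed only in the
infected library and UNDEFINED when it is observed in neither.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: IC of a gene expressed only in the infected library.
IC_INFINITY = math.inf
#: IC of a gene expressed in neither library.
IC_UNDEFINED = math.nan


def ic_is_undefined(ic: float) -> bool:
    return isinstance(ic, float) and math.isnan(ic)


@dataclass
class CountTable:
    """Per-gene read counts for one species' paired infected/naïve libraries.

    ``data`` is indexed by gene id with integer columns ``reads_infected``
    and ``reads_naive`` plus ``transcript_length`` (bp).  ``total_infected``
    and ``total_naive`` are the library totals used for per-million scaling;
    they default to the column sums but may be larger (reads assigned to
    genes outside the table still count toward depth).
    """

    data: pd.DataFrame
    total_infected: int | None = None
    total_naive: int | None = None

    def __post_init__(self) -> None:
        required = {"reads_infected", "reads_naive", "transcript_length"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"count table missing columns {sorted(missing)}")
        if (self.data[list(required)] < 0).any().any():
            raise ValueError("counts and lengths must be non-negative")
        col_inf = int(self.data["reads_infected"].sum())
        col_nv = int(self.data["reads_naive"].sum())
        if self.total_infected is None:
            self.total_infected = col_inf
        if self.total_naive is None:
            self.total_naive = col_nv
        if self.total_infected < col_inf or self.total_naive < col_nv:
            raise ValueError("library totals cannot be below the column sums")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    def counts(self, gene_id: str) -> tuple[int, int]:
        row = self.data.loc[gene_id]
        return int(row["reads_infected"]), int(row["reads_naive"])


@dataclass
class ExpressionRecord:
    gene_id: str
    reads_infected: int
    reads_naive: int
    rpsm_infected: float
    rpsm_naive: float
    tmm_infected: float
    tmm_naive: float
    ic: float
    p_value: float | None = None
    category: str | None = None


def rpsm(reads: int, total_reads: int, transcript_length: int) -> float:
    """Reads per site per million reads."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if transcript_length <= 0:
        raise ValueError("transcript_length must be positive")
    if reads < 0:
        raise ValueError("reads must be non-negative")
    return reads / total_reads / transcript_length * 1e6


def tmm_factors(
    table: CountTable,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> tuple[float, float]:
    """Trimmed-mean-of-M-values scaling factors for the two libraries.

    For each gene expressed in both libraries, M = log2 of the ratio of
    depth-normalised counts (infected over naïve, using the table's stated
    library totals) and A = the mean log2 abundance.  Genes in the extreme
    ``trim_m`` tails of M and ``trim_a`` tails of A are discarded; the factor
    is the weighted mean of the remaining M values with inverse
    asymptotic-binomial-variance weights, exponentiated.  The pair is scaled
    so the factors multiply to 1; normalised expression is RPSM divided by
    the library's factor.
    """
    x_inf = table.data["reads_infected"].to_numpy(dtype=float)
    x_nv = table.data["reads_naive"].to_numpy(dtype=float)
    n_inf = float(table.total_infected)
    n_nv = float(table.total_naive)

    both = (x_inf > 0) & (x_nv > 0)
    if both.sum() < 2:
        raise ValueError("need at least 2 genes with nonzero counts in both libraries")
    xi, xn = x_inf[both], x_nv[both]

    m = np.log2((xi / n_inf) / (xn / n_nv))
    a = 0.5 * np.log2((xi / n_inf) * (xn / n_nv))
    # asymptotic variance of M under binomial sampling (delta method)
    w = (n_inf - xi) / (n_inf * xi) + (n_nv - xn) / (n_nv * xn)

    keep = np.ones(len(m), dtype=bool)
    if len(m) > 2:
        m_lo, m_hi = np.quantile(m, [trim_m, 1.0 - trim_m])
        a_lo, a_hi = np.quantile(a, [trim_a, 1.0 - trim_a])
        keep = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
        if not keep.any():
            keep = np.ones(len(m), dtype=bool)

    with np.errstate(divide="ignore"):
        inv_var = np.where(w[keep] > 0, 1.0 / w[keep], 0.0)
    if inv_var.sum() == 0:  # all weights degenerate (e.g. x == N)
        log_f = float(np.mean(m[keep]))
    else:
        log_f = float(np.sum(m[keep] * inv_var) / np.sum(inv_var))
    f = 2.0 ** log_f  # infected relative to naïve
    factor_infected = math.sqrt(f)
    factor_naive = 1.0 / math.sqrt(f)
    return factor_infected, factor_naive


def normalized_expression(
    table: CountTable,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.DataFrame:
    """Per-gene RPSM and TMM-normalised expression for both conditions.

    Returns a frame indexed like the count table with columns
    ``rpsm_infected, rpsm_naive, tmm_infected, tmm_naive, ic``.
    """
    f_inf, f_nv = tmm_factors(table, trim_m=trim_m, trim_a=trim_a)
    lengths = table.data["transcript_length"].to_numpy(dtype=float)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    rpsm_inf = table.data["reads_infected"].to_numpy(float) / table.total_infected / lengths * 1e6
    rpsm_nv = table.data["reads_naive"].to_numpy(float) / table.total_naive / lengths * 1e6
    tmm_inf = rpsm_inf / f_inf
    tmm_nv = rpsm_nv / f_nv
    ic = np.array([induction_coefficient(i, n) for i, n in zip(tmm_inf, tmm_nv)])
    return pd.DataFrame(
        {
            "reads_infected": table.data["reads_infected"],
            "reads_naive": table.data["reads_naive"],
            "rpsm_infected": rpsm_inf,
            "rpsm_naive": rpsm_nv,
            "tmm_infected": tmm_inf,
            "tmm_naive": tmm_nv,
            "ic": ic,
        },
        index=table.data.index,
    )


def induction_coefficient(tmm_infected: float, tmm_naive: float) -> float:
    """Infected/naïve expression ratio with the distinguished edge values.

    Returns :data:`IC_INFINITY` when the gene is expressed only in the
    infected library and :data:`IC_UNDEFINED` when expressed in neither.
    """
    if tmm_infected < 0 or tmm_naive < 0:
        raise ValueError("expression values must be non-negative")
    if tmm_naive == 0:
        return IC_UNDEFINED if tmm_infected == 0 else IC_INFINITY
    return tmm_infected / tmm_naive


def format_ic(ic: float, decimals: int = 3) -> str:
    """Render an IC the way the published tables do (3 decimals, 'Infinity')."""
    if ic_is_undefined(ic):
        return "Undefined"
    if math.isinf(ic):
        return "Infinity"
    return f"{ic:.{decimals}f}"
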