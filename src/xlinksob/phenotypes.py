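"""Count-based phenotype quantifications.

Small statistics layer for the organismal read-outs: percentages from
event/total count pairs (embryo hatching, Ftz stripe counts, pole-cell
presence, mRNA/protein localization), hatching tables, and the
one-sample t-test used for RIP fold enrichments against a null mean of 1
(no enrichment over control).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CountPair:
    events: int
    total: int
    label: str = ""

    def __post_init__(self):
        if self.events < 0 or self.total < 0:
            raise ValueError("counts must be non-negative")
        if self.events > self.total:
            raise ValueError(f"{self.label or 'pair'}: events exceed total")


def percent(pair: CountPair, decimals: int = 1) -> float:
    """100 * events / total, rounded half-up to ``decimals`` places.

    Half-up rounding matches how tabulated percentages are printed
    (banker's rounding would turn e.g. 62.05 into 62.0, not 62.1).
    """
    if pair.total == 0:
        raise ValueError(f"{pair.label or 'pair'}: zero total")
    raw = Decimal(100 * pair.events) / Decimal(pair.total)
    q = Decimal(1).scaleb(-decimals)
    return float(raw.quantize(q, rounding=ROUND_HALF_UP))


def hatching_table(rows: list[tuple[str, int, int]]) -> pd.DataFrame:
    """Build a hatching summary from (genotype, eggs laid, hatched) rows.

    Adds ``unhatched = laid - hatched`` and the hatching percentage at
    one decimal.  Rows with zero eggs laid report 0.0% and are flagged in
    ``zero_total`` rather than erroring, matching how such rows are
    tabulated.
    """
    out = []
    for genotype, laid, hatched in rows:
        if hatched > laid:
            raise ValueError(f"{genotype}: hatched ({hatched}) > laid ({laid})")
        if laid == 0:
            pct, flag = 0.0, True
        else:
            pct, flag = percent(CountPair(hatched, laid, genotype)), False
        out.append({"genotype": genotype, "eggs_laid": laid,
                    "hatched": hatched, "unhatched": laid - hatched,
                    "hatching_pct": pct, "zero_total": flag})
    return pd.DataFrame(out)


def one_sample_t(values, null_mean: float = 1.0) -> tuple[float, float]:
    """One-sample t-test of replicate fold enrichments against a null mean.

    Returns ``(t, two-sided p)``; ``t = (mean - null) / (sd / sqrt(n))``
    on ``n - 1`` degrees of freedom.  Raises on fewer than two values and
    flags a zero-variance sample as undefined.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two replicate values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite fold enrichment value")
    if np.allclose(x.std(ddof=1), 0.0):
        if np.allclose(x.mean(), null_mean):
            return 0.0, 1.0  # degenerate but unambiguous: no deviation at all
        raise ZeroDivisionError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(x, popmean=null_mean)
    return float(res.statistic), float(res.pvalue)


def multiple_one_sample_t(sets: dict[str, list[float]], null_mean: float = 1.0,
                          correction: str | None = None) -> pd.DataFrame:
    """Per-transcript one-sample t-tests (optionally BH-corrected).

    No multiple-testing correction is applied unless ``correction='bh'``.
    """
    rows = []
    for label, values in sets.items():
        t, p = one_sample_t(values, null_mean)
        rows.append({"label": label, "n": len(values),
                     "mean": float(np.mean(values)), "t": t, "pvalue": p})
    df = pd.DataFrame(rows)
    if correction == "bh":
        from statsmodels.stats.multitest import multipletests
        df["fdr"] = multipletests(df["pvalue"], method="fdr_bh")[1]
    return df
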