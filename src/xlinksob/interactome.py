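"""Label-free proteomics differential abundance.

Pipeline on a MaxQuant-style protein-groups table: remove contaminant /
reverse / only-identified-by-site groups and groups with insufficient
peptide evidence; log2-transform; impute missing (left-censored) values
with small beta-distributed numbers between 0.1% and 1.5% of the lowest
measured log value; keep groups measured in at least two replicates of
at least one condition; then test each group with an empirical-Bayes
moderated t-statistic (per-group variances shrunk toward a prior fitted
across groups, in the style of limma) and call groups with BH-adjusted
FDR <= 0.05 and log2 fold change >= 2 significantly enriched.

The moderation prior (d0, s0^2) is estimated by moment matching on the
log residual variances: if s^2 ~ s0^2 * F(d, d0), then
E[log s^2] and Var[log s^2] involve digamma/trigamma terms in d and d0;
the trigamma equation is inverted numerically (Newton on the scaled
inverse) exactly as in the standard implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

FLAG_COLUMNS = ("contaminant", "reverse", "only_identified_by_site")


@dataclass
class ModerationParams:
    d0: float           # prior degrees of freedom (may be inf)
    s0_sq: float        # prior variance
    df_residual: float  # residual df per group


def lfq_columns(table: pd.DataFrame, condition: str) -> list[str]:
    return [c for c in table.columns if c.startswith(f"lfq_{condition}_")]


def filter_groups(table: pd.DataFrame, min_peptides: int = 2,
                  min_unique: int = 1,
                  literal_peptide_rule: bool = False) -> pd.DataFrame:
    """Drop flagged rows and rows with insufficient peptide evidence.

    The default requires peptides >= 2 AND unique peptides >= 1 (the
    conventional protein-groups filter).  ``literal_peptide_rule`` keeps
    any row that satisfies either threshold, removing only rows failing
    both.
    """
    keep = ~table[list(FLAG_COLUMNS)].any(axis=1)
    enough_pep = table["peptides"] >= min_peptides
    enough_unique = table["unique_peptides"] >= min_unique
    if literal_peptide_rule:
        keep &= enough_pep | enough_unique
    else:
        keep &= enough_pep & enough_unique
    return table.loc[keep].reset_index(drop=True)


def impute_missing(values: pd.DataFrame, seed: int,
                   beta_shape: tuple[float, float] = (1.0, 1.0),
                   low: float = 0.001, high: float = 0.015,
                   per_column: bool = False) -> pd.DataFrame:
    """Left-censored imputation on log-transformed abundances.

    Each missing cell is replaced by ``m * u`` where ``m`` is the lowest
    measured log value (global by default, per column optionally) and
    ``u`` is beta-distributed, rescaled to [``low``, ``high``] — i.e.
    between 0.1% and 1.5% of the lowest measured value.  Measured cells
    are never altered.
    """
    if values.isna().all().all():
        raise ValueError("cannot impute an all-missing matrix")
    rng = np.random.default_rng(seed)
    out = values.copy()
    a, b = beta_shape
    for col in out.columns:
        m = out[col].min() if per_column else np.nanmin(values.to_numpy())
        if np.isnan(m):
            raise ValueError(f"column {col} has no measured values")
        mask = out[col].isna()
        u = rng.beta(a, b, size=int(mask.sum()))
        scaled = m * (low + u * (high - low))
        out.loc[mask, col] = scaled
    return out


def presence_filter(table: pd.DataFrame, mask: pd.DataFrame,
                    conditions: tuple[str, str] = ("ctrl", "bait"),
                    min_measured: int = 2) -> pd.Series:
    """Rows with >= ``min_measured`` originally-measured values in >= 1
    condition.  ``mask`` is the measured-value indicator taken before
    imputation, so imputed cells never count as measured."""
    keep = pd.Series(False, index=table.index)
    for cond in conditions:
        cols = lfq_columns(table, cond)
        keep |= mask[cols].sum(axis=1) >= min_measured
    return keep


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def fit_variance_prior(variances: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log variances (empirical-Bayes prior).

    Returns ``(d0, s0_sq)``; ``d0 = inf`` when the observed spread of log
    variances is no wider than expected from chi-square sampling alone.
    """
    variances = np.asarray(variances, dtype=float)
    ok = variances > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(variances[ok])) if ok.any() else 0.0
    z = np.log(variances[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    e_mean = e.mean()
    e_var = e.var(ddof=1)
    excess = e_var - special.polygamma(1, df / 2)
    if excess <= 0:
        s0_sq = float(np.exp(e_mean))
        return np.inf, s0_sq
    d0 = 2 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return float(d0), s0_sq


def moderated_test(table: pd.DataFrame,
                   conditions: tuple[str, str] = ("ctrl", "bait"),
                   d0_override: float | None = None,
                   ) -> tuple[pd.DataFrame, ModerationParams]:
    """Moderated two-sample comparison of ``conditions[1]`` over ``[0]``.

    Per-group pooled variances are shrunk toward the fitted prior:
    ``s_post^2 = (d0*s0^2 + df*s^2) / (d0 + df)``; the moderated t is
    ``(mean_bait - mean_ctrl) / (s_post * sqrt(1/n1 + 1/n2))`` on
    ``d0 + df`` degrees of freedom, with two-sided p-values and BH
    adjustment across groups.  ``d0_override`` forces the prior df
    (0 recovers the ordinary pooled t; inf uses s0 for every group).
    """
    ctrl_cols = lfq_columns(table, conditions[0])
    bait_cols = lfq_columns(table, conditions[1])
    n1, n2 = len(ctrl_cols), len(bait_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per condition")
    x = table[ctrl_cols].to_numpy(float)
    y = table[bait_cols].to_numpy(float)
    df_res = n1 + n2 - 2
    mean_diff = y.mean(axis=1) - x.mean(axis=1)
    ss = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s_sq = ss / df_res

    d0, s0_sq = fit_variance_prior(s_sq, df_res)
    if d0_override is not None:
        d0 = d0_override
    if np.isinf(d0):
        s_post_sq = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    else:
        s_post_sq = (d0 * s0_sq + df_res * s_sq) / (d0 + df_res)
        # cap at the pooled residual df: with more prior df than the data
        # carry in total, the t reference degenerates to the pooled-variance
        # case rather than gaining further certainty
        df_total = min(d0 + df_res, len(s_sq) * df_res)

    se = np.sqrt(s_post_sq * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_diff / se
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    fdr = multipletests(p, method="fdr_bh")[1]
    result = pd.DataFrame({
        "protein_id": table["protein_id"].to_numpy()
        if "protein_id" in table else np.arange(len(table)),
        "log2fc": mean_diff, "t": t, "pvalue": p, "fdr": fdr,
    })
    return result, ModerationParams(d0=d0, s0_sq=s0_sq, df_residual=df_res)


def classify(result: pd.DataFrame, fdr_max: float = 0.05,
             lfc_min: float = 2.0) -> pd.DataFrame:
    """Flag significantly enriched groups: FDR <= 0.05 and log2FC >= 2."""
    out = result.copy()
    out["significant"] = (out["fdr"] <= fdr_max) & (out["log2fc"] >= lfc_min)
    return out


def run_interactome(table: pd.DataFrame, seed: int,
                    conditions: tuple[str, str] = ("ctrl", "bait"),
                    fdr_max: float = 0.05, lfc_min: float = 2.0,
                    log2_transform: bool = False,
                    ) -> tuple[pd.DataFrame, ModerationParams]:
    """Full filtering/imputation/testing pipeline on a protein-groups table.

    Abundance columns are expected on the log2 scale; pass
    ``log2_transform=True`` for raw intensities (zeros become missing).
    """
    filtered = filter_groups(table)
    if log2_transform:
        cols = [c for cond in conditions for c in lfq_columns(filtered, cond)]
        vals = filtered[cols].where(filtered[cols] > 0)
        filtered[cols] = np.log2(vals)
    value_cols = [c for cond in conditions for c in lfq_columns(filtered, cond)]
    mask = filtered[value_cols].notna()
    keep = presence_filter(filtered, mask, conditions)
    filtered = filtered.loc[keep].reset_index(drop=True)
    mask = filtered[value_cols].notna()
    imputed = filtered.copy()
    imputed[value_cols] = impute_missing(filtered[value_cols], seed=seed)
    result, params = moderated_test(imputed, conditions)
    return classify(result, fdr_max, lfc_min), params
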