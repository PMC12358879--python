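"""Peak-area normalization and genotype group comparisons.

Mass-spectrometry peak areas carry sample-level scale effects
(injection amount, extraction efficiency). Upper-quartile normalization
removes them: each sample's areas are divided by that sample's 75th
percentile of positive areas, then rescaled by the geometric mean of
all samples' upper quartiles so values stay in peak-area units.

Group comparisons are classical pooled-variance (Student) two-sample
t-tests per metabolite within each tissue x sex stratum, with 95%
confidence intervals of each group mean and the fold change of
arithmetic means (hAdsl / WT). A Benjamini-Hochberg column is included
as supplementary output; the primary p-values are unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .behavior import HADSL, WT

__all__ = [
    "MetaboliteTable",
    "CorrelationResult",
    "upper_quartile_normalize",
    "group_compare",
    "expression_metabolite_correlation",
]

SAMPLE_COLUMNS = ("tissue", "sex", "genotype")


@dataclass
class MetaboliteTable:
    """Peak areas (samples x metabolites) plus per-sample metadata.

    ``values``: DataFrame indexed by sample id, one column per
    metabolite, all entries >= 0. ``samples``: DataFrame with the same
    index carrying at least tissue, sex and genotype.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.samples.index):
            raise ValueError("values and samples must share the same sample index")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata lacks columns: {missing}")
        arr = self.values.to_numpy(dtype=np.float64)
        if (arr < 0).any():
            raise ValueError("peak areas must be nonnegative")
        if not self.normalized and not (arr > 0).any(axis=1).all():
            bad = self.values.index[~(arr > 0).any(axis=1)].tolist()
            raise ValueError(f"samples with no positive area: {bad}")


@dataclass
class CorrelationResult:
    """Pearson correlation between expression and metabolite fold change."""

    r: float
    n: int
    p: float
    log_transform: bool
    undefined: bool = False


def _upper_quartile(row: np.ndarray) -> float:
    """75th percentile of the positive areas (linear interpolation)."""
    pos = row[row > 0]
    if pos.size == 0:
        return 0.0
    return float(np.percentile(pos, 75, method="linear"))


def upper_quartile_normalize(
    table: MetaboliteTable, per_tissue: bool = False
) -> MetaboliteTable:
    """Divide each sample by its upper quartile, rescale to peak-area units.

    The rescale factor is the geometric mean of the per-sample upper
    quartiles (computed within tissue when ``per_tissue``), so after
    normalization every sample's 75th percentile of positive areas
    equals that geometric mean. Idempotent: normalizing twice equals
    normalizing once.
    """
    vals = table.values.to_numpy(dtype=np.float64)
    uq = np.array([_upper_quartile(r) for r in vals])
    zero = np.flatnonzero(uq == 0.0)
    if zero.size:
        raise ValueError(
            f"upper quartile is 0 for sample(s) {table.values.index[zero].tolist()}"
        )
    if per_tissue:
        scale = np.empty_like(uq)
        tissues = table.samples["tissue"].to_numpy()
        for t in np.unique(tissues):
            m = tissues == t
            scale[m] = np.exp(np.mean(np.log(uq[m])))
    else:
        scale = np.full_like(uq, np.exp(np.mean(np.log(uq))))
    out = vals / uq[:, None] * scale[:, None]
    return MetaboliteTable(
        values=pd.DataFrame(out, index=table.values.index, columns=table.values.columns),
        samples=table.samples.copy(),
        normalized=True,
    )


def _mean_ci(x: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Group mean and its t-based confidence interval (n-1 df)."""
    n = x.size
    mean = float(x.mean())
    if n < 2:
        return mean, np.nan, np.nan
    half = stats.t.ppf(0.5 + level / 2, n - 1) * x.std(ddof=1) / np.sqrt(n)
    return mean, mean - half, mean + half


def group_compare(
    table: MetaboliteTable,
    metabolites: Sequence[str] | None = None,
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sample genotype comparison per metabolite per tissue x sex stratum.

    Uses the pooled-variance Student t-test by default (``welch=True``
    switches to the unequal-variance form). Strata with fewer than 2
    samples in either group are flagged (``insufficient``), with NaN
    statistics, rather than silently dropped. When both groups are
    constant and equal, p = 1 by convention.

    Columns: tissue, sex, metabolite, n1, n2, mean1, mean2, ci1_lo,
    ci1_hi, ci2_lo, ci2_hi, fold, t, df, p, p_bh, insufficient
    (group 1 = hAdsl, group 2 = WT; fold = mean1/mean2).
    """
    cols = list(table.values.columns if metabolites is None else metabolites)
    rows = []
    for (tissue, sex), idx in table.samples.groupby(["tissue", "sex"]).groups.items():
        meta = table.samples.loc[idx]
        v = table.values.loc[idx]
        g1 = v[meta["genotype"] == HADSL]
        g2 = v[meta["genotype"] == WT]
        for metab in cols:
            x1 = g1[metab].to_numpy(dtype=np.float64)
            x2 = g2[metab].to_numpy(dtype=np.float64)
            row = {"tissue": tissue, "sex": sex, "metabolite": metab,
                   "n1": x1.size, "n2": x2.size}
            if x1.size < 2 or x2.size < 2:
                row.update(
                    mean1=np.nan, mean2=np.nan, ci1_lo=np.nan, ci1_hi=np.nan,
                    ci2_lo=np.nan, ci2_hi=np.nan, fold=np.nan, t=np.nan,
                    df=np.nan, p=np.nan, insufficient=True,
                )
                rows.append(row)
                continue
            m1, lo1, hi1 = _mean_ci(x1)
            m2, lo2, hi2 = _mean_ci(x2)
            if np.ptp(x1) == 0 and np.ptp(x2) == 0 and m1 == m2:
                t_stat, p, df = 0.0, 1.0, float(x1.size + x2.size - 2)
            else:
                res = stats.ttest_ind(x1, x2, equal_var=not welch)
                t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
            row.update(
                mean1=m1, mean2=m2, ci1_lo=lo1, ci1_hi=hi1, ci2_lo=lo2, ci2_hi=hi2,
                fold=(m1 / m2) if m2 != 0 else np.inf, t=t_stat, df=df, p=p,
                insufficient=False,
            )
            rows.append(row)
    out = pd.DataFrame(rows)
    out["p_bh"] = np.nan
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def expression_metabolite_correlation(
    expression: Sequence[float],
    fold_changes: Sequence[float],
    log_transform: bool = False,
) -> CorrelationResult:
    """Pearson correlation of per-tissue expression with metabolite fold change.

    Tests the hypothesis that the metabolic consequence of reduced
    enzyme activity is largest where the enzyme's expression is lowest
    (a negative R). ``log_transform`` applies log to the fold changes
    first. Constant input yields an undefined result (flagged), since
    Pearson R is then ill-defined.
    """
    x = np.asarray(expression, dtype=np.float64)
    y = np.asarray(fold_changes, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("expression and fold_changes must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("need at least 3 matched units")
    if log_transform:
        if (y <= 0).any():
            raise ValueError("log transform requires positive fold changes")
        y = np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(
            r=np.nan, n=x.size, p=np.nan, log_transform=log_transform, undefined=True
        )
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(r), n=x.size, p=float(p), log_transform=log_transform
    )
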