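"""ASV count-table statistics and negative-binomial covariate association.

Takes a 16S amplicon sequence variant (ASV) count table (ASVs x samples,
genus-level taxonomy) together with a per-sample metabolic covariate (the
log2 fold change in bacterial production or growth efficiency after
leachate addition) and computes:

* Shannon diversity per sample (nats, unrarefied counts);
* low-abundance filtering (total reads across samples below a cutoff);
* median-of-ratios size factors for library-depth normalisation;
* a per-ASV negative-binomial GLM (log link, size-factor offset,
  intercept + covariate) with method-of-moments dispersion and Wald
  tests, slopes reported in log2 units; and
* Benjamini-Hochberg step-up adjustment of the Wald p-values.

This is a deliberately plain NB GLM: no dispersion shrinkage across ASVs,
no outlier or independent filtering — the association machinery is fully
transparent at the cost of some power relative to shrinkage estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AsvCountTable",
    "shannon_index",
    "shannon_per_sample",
    "filter_low_abundance",
    "size_factors",
    "nb_association",
    "bh_adjust",
]


@dataclass(frozen=True)
class AsvCountTable:
    """ASV x sample integer counts with genus-level taxonomy.

    ``counts`` rows are ASV ids, columns sample ids; ``taxonomy`` maps ASV
    id to a genus label and must cover every row.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.integer) or arr.min() < 0):
            raise ValueError("counts must be non-negative integers")
        missing = self.counts.index.difference(self.taxonomy.index)
        if len(missing):
            raise ValueError(f"taxonomy missing for ASVs: {list(missing)[:5]}")

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_tsv(self, counts_path, taxonomy_path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="asv_id")
        self.taxonomy.rename("genus").to_csv(taxonomy_path, sep="\t", index_label="asv_id")

    @classmethod
    def from_tsv(cls, counts_path, taxonomy_path) -> "AsvCountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="asv_id")
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col="asv_id")["genus"]
        return cls(counts=counts.astype(np.int64), taxonomy=taxonomy)


def shannon_index(counts: Sequence[float] | np.ndarray) -> float:
    """Shannon diversity H = -sum p ln p (nats) over taxa with positive counts.

    Returns NaN for an all-zero sample.
    """
    arr = np.asarray(counts, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total == 0:
        return float("nan")
    p = arr[arr > 0] / total
    return float(-(p * np.log(p)).sum())


def shannon_per_sample(table: AsvCountTable) -> pd.Series:
    return pd.Series(
        {col: shannon_index(table.counts[col].to_numpy()) for col in table.counts.columns},
        name="shannon",
    )


def filter_low_abundance(table: AsvCountTable, min_reads: int = 100) -> AsvCountTable:
    """Remove ASVs whose total reads across samples fall below ``min_reads``.

    An ASV at exactly the cutoff is retained (the rule is "< min_reads
    removed").
    """
    keep = table.counts.sum(axis=1) >= min_reads
    counts = table.counts.loc[keep]
    return AsvCountTable(counts=counts, taxonomy=table.taxonomy.loc[counts.index])


def size_factors(table: AsvCountTable, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios library-size factors, one per sample.

    Each sample's factor is the median over reference ASVs (those with
    positive counts in every sample) of count / geometric-mean ratios.
    ``pseudocount`` can rescue sparse tables with no ubiquitous ASV.
    """
    counts = table.counts.to_numpy(dtype=float) + pseudocount
    ubiquitous = (counts > 0).all(axis=1)
    if not ubiquitous.any():
        raise ValueError(
            "no ASV has positive counts in all samples; pass pseudocount > 0 to proceed"
        )
    ref = counts[ubiquitous]
    log_geo_mean = np.mean(np.log(ref), axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geo_mean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=table.counts.columns, name="size_factor")


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to the
    input order.  Missing (NaN) p-values pass through as NaN and do not
    count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = np.isfinite(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    scaled = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(q, 1.0)
    out[valid] = adjusted
    return out


def _moment_dispersion(y: np.ndarray, mu: np.ndarray, floor: float = 1e-8) -> float:
    # NB2 method of moments: Var = mu + alpha mu^2 -> alpha from residuals
    num = np.sum((y - mu) ** 2 - mu)
    den = np.sum(mu**2)
    return max(floor, num / den) if den > 0 else floor


def nb_association(
    table: AsvCountTable,
    covariate: pd.Series | Sequence[float],
    factors: pd.Series | None = None,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Per-ASV negative-binomial association with a per-sample covariate.

    For each ASV fits counts ~ NB(mu, alpha) with log mu = log(size factor)
    + b0 + b1 * covariate; dispersion alpha is estimated per ASV by the
    method of moments around an initial Poisson fit (floored at
    ``dispersion_floor``).  Slopes are reported in log2 units with Wald
    standard errors and p-values.  A constant covariate, or an ASV whose
    fit fails to converge, yields NaN slope/p for that ASV rather than an
    error.  Returns a DataFrame indexed by ASV id with columns
    log2_fold_change, se, pvalue, padj, base_mean and converged.
    """
    cov = np.asarray(covariate, dtype=float)
    if cov.shape[0] != table.n_samples:
        raise ValueError("covariate length must equal the number of samples")
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariate must be finite for all samples")
    if factors is None:
        factors = size_factors(table)
    sf = np.asarray(factors, dtype=float)
    offset = np.log(sf)
    exog = np.column_stack([np.ones_like(cov), cov])
    degenerate = np.ptp(cov) == 0.0

    counts = table.counts.to_numpy(dtype=float)
    norm_mean = (counts / sf).mean(axis=1)

    rows = []
    ln2 = np.log(2.0)
    for i, asv in enumerate(table.counts.index):
        y = counts[i]
        record = {"asv_id": asv, "log2_fold_change": np.nan, "se": np.nan,
                  "pvalue": np.nan, "base_mean": norm_mean[i], "converged": False}
        if not degenerate:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    pois = sm.GLM(y, exog, family=sm.families.Poisson(), offset=offset).fit()
                    alpha = _moment_dispersion(y, pois.mu, floor=dispersion_floor)
                    nb = sm.GLM(
                        y, exog, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
                    ).fit()
                slope_ln, se_ln = float(nb.params[1]), float(nb.bse[1])
                if np.isfinite(slope_ln) and np.isfinite(se_ln) and se_ln > 0:
                    z = slope_ln / se_ln
                    record.update(
                        log2_fold_change=slope_ln / ln2,
                        se=se_ln / ln2,
                        pvalue=float(2.0 * sps.norm.sf(abs(z))),
                        converged=bool(nb.converged),
                    )
            except Exception:
                pass  # flagged non-converged with NaN statistics
        rows.append(record)
    result = pd.DataFrame(rows).set_index("asv_id")
    result["padj"] = bh_adjust(result["pvalue"].to_numpy())
    result["genus"] = table.taxonomy.loc[result.index].to_numpy()
    return result
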