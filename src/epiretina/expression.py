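"""RNA-seq normalization, expressed-gene and deregulation classification.

Counts are normalized with median-of-ratios size factors; RPK divides the
normalized count by the median transcript length in kb.  A gene is
*expressed* when RPK >= 1 in every WT sample.  Deregulation classes use
strict thresholds: down when FC < 0.7 and adjusted p < 0.05, up when
FC > 1.3 and adjusted p < 0.05.

The negative-binomial Wald test of a full DE framework is out of scope:
adjusted p-values are either supplied alongside the counts, or produced by
a documented stand-in.  The default stand-in mirrors an NB Wald test with
trended dispersion: the per-gene log2-scale variance is predicted from the
mean-dispersion trend (var_log2 ~ (1/mu + alpha)/ln(2)^2 with alpha fitted
across genes), the group difference is referred to a normal distribution,
and p-values are Benjamini-Hochberg adjusted.  A per-gene two-sample
t-test on log2(normalized count + 1) is available as ``mode='ttest'``; it
is markedly conservative at 3-4 replicates because of its few degrees of
freedom.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .density import mann_whitney_p


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one per sample/column).

    The reference is the per-gene geometric mean across samples over genes
    with all-positive counts; each sample's factor is the median ratio of
    its counts to the reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene with positive counts in all samples")
    log_ref = np.log(positive).mean(axis=1)
    factors = np.exp(np.log(positive).sub(log_ref, axis=0).median(axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    if factors is None:
        factors = size_factors(counts)
    return counts.div(factors, axis=1)


def rpk_table(
    counts: pd.DataFrame,
    factors: pd.Series,
    lengths_kb: pd.Series,
) -> pd.DataFrame:
    """RPK = (count / size factor) / median transcript length in kb.

    Genes without a length are dropped with a warning.
    """
    missing = counts.index.difference(lengths_kb.index)
    if len(missing):
        import warnings

        warnings.warn(f"{len(missing)} genes lack a length; dropped from RPK")
    kept = counts.loc[counts.index.intersection(lengths_kb.index)]
    norm = kept.div(factors, axis=1)
    return norm.div(lengths_kb.loc[kept.index], axis=0)


def expressed_genes(rpk: pd.DataFrame, wt_samples: Sequence[str], threshold: float = 1.0) -> set[str]:
    """Genes with RPK >= threshold in ALL WT samples (boundary inclusive)."""
    wt = [s for s in wt_samples]
    if not wt:
        raise ValueError("need at least one WT sample")
    mask = (rpk[wt] >= threshold).all(axis=1)
    return set(rpk.index[mask])


def classify_deregulated(
    fc: float,
    adj_p: float | None,
    down_fc: float = 0.7,
    up_fc: float = 1.3,
    alpha: float = 0.05,
) -> str:
    """'down' | 'up' | 'none' with strict inequalities; missing adjusted p
    yields 'none'."""
    if adj_p is None or (isinstance(adj_p, float) and np.isnan(adj_p)):
        return "none"
    if not 0 <= adj_p <= 1:
        raise ValueError("adjusted p must be in [0, 1]")
    if fc < down_fc and adj_p < alpha:
        return "down"
    if fc > up_fc and adj_p < alpha:
        return "up"
    return "none"


_LN2_SQ = float(np.log(2.0) ** 2)


def _trended_wald_p(
    logn: pd.DataFrame,
    norm: pd.DataFrame,
    wt_samples: Sequence[str],
    mut_samples: Sequence[str],
) -> pd.Series:
    """Wald p-values with variance predicted from the mean-dispersion trend.

    On the log2 scale an NB count with mean mu and dispersion alpha has
    variance ~ (1/mu + alpha) / ln(2)^2; alpha is fitted by a robust
    (median) method of moments from the pooled within-group variances, so
    the per-gene standard error carries no per-gene estimation noise and a
    normal reference is appropriate.
    """
    a = logn[list(mut_samples)].to_numpy()
    b = logn[list(wt_samples)].to_numpy()
    n1, n2 = a.shape[1], b.shape[1]
    dof = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / dof
    mu = norm.mean(axis=1).to_numpy()
    use = mu > 0
    if not use.any():
        return pd.Series(np.nan, index=norm.index)
    alpha = float(np.median(s2[use] * _LN2_SQ - 1.0 / mu[use]))
    alpha = max(alpha, 1e-4)
    s2_pred = (1.0 / np.maximum(mu, 1e-9) + alpha) / _LN2_SQ
    se = np.sqrt(s2_pred * (1.0 / n1 + 1.0 / n2))
    z = (a.mean(axis=1) - b.mean(axis=1)) / se
    return pd.Series(
        np.where(use, 2.0 * stats.norm.sf(np.abs(z)), np.nan), index=norm.index
    )


def differential_expression(
    counts: pd.DataFrame,
    wt_samples: Sequence[str],
    mut_samples: Sequence[str],
    factors: pd.Series | None = None,
    adj_p: pd.Series | None = None,
    mode: str = "trended",
) -> pd.DataFrame:
    """Per-gene mutant/WT fold change of mean normalized counts plus an
    adjusted p column.

    When ``adj_p`` is not supplied the stand-in test runs: ``mode='trended'``
    (default, see :func:`_trended_wald_p`) or ``mode='ttest'`` (per-gene
    two-sample t on log2(normalized+1)).  Either way p-values are
    BH-adjusted and the mode lands in ``df.attrs['p_value_mode']``.
    """
    norm = normalized_counts(counts, factors)
    mean_wt = norm[list(wt_samples)].mean(axis=1)
    mean_mut = norm[list(mut_samples)].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (mean_mut / mean_wt).replace([np.inf, -np.inf], np.nan)
    if adj_p is not None:
        padj = adj_p.reindex(counts.index)
        mode = "supplied"
    else:
        logn = np.log2(norm + 1.0)
        if mode == "trended":
            pvals = _trended_wald_p(logn, norm, wt_samples, mut_samples)
        elif mode == "ttest":
            res = stats.ttest_ind(
                logn[list(mut_samples)], logn[list(wt_samples)], axis=1
            )
            pvals = pd.Series(res.pvalue, index=counts.index)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        ok = pvals.notna()
        padj = pd.Series(np.nan, index=counts.index)
        if ok.any():
            padj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
        mode = f"standin_{mode}_bh"
    out = pd.DataFrame(
        {
            "mean_wt": mean_wt,
            "mean_mut": mean_mut,
            "fc": fc,
            "log2fc": np.log2(fc.where(fc > 0)),
            "adj_p": padj,
        }
    )
    out["class"] = [
        classify_deregulated(f, p if pd.notna(p) else None)
        if pd.notna(f)
        else "none"
        for f, p in zip(out["fc"], out["adj_p"])
    ]
    out.attrs["p_value_mode"] = mode
    return out


def median_rpk_ratio(
    set_a: Iterable[str],
    set_b: Iterable[str],
    rpk: pd.DataFrame | pd.Series,
    round_mode: str = "none",
) -> dict:
    """Ratio of median RPKs of two gene sets (median over genes of the
    per-gene mean RPK when a table is given), with a Mann-Whitney p."""
    values = rpk.mean(axis=1) if isinstance(rpk, pd.DataFrame) else rpk
    a = values.reindex(list(set_a)).dropna().to_numpy()
    b = values.reindex(list(set_b)).dropna().to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both gene sets must be represented in the RPK table")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_b == 0:
        raise ValueError("median RPK of set_b is zero")
    ratio = med_a / med_b
    if round_mode == "nearest_int":
        reported: float = float(round(ratio))
    elif round_mode == "one_decimal":
        reported = round(ratio, 1)
    else:
        reported = ratio
    return {
        "median_a": med_a,
        "median_b": med_b,
        "ratio": ratio,
        "reported_ratio": reported,
        "mannwhitney_p": mann_whitney_p(a, b),
    }


def read_count_table(path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Counts TSV with a '#genotype' header row mapping sample -> genotype."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
        second_pos = fh.tell()
        second = fh.readline().rstrip("\n").split("\t")
    genotypes: dict[str, str] = {}
    skip = [0]
    if second and second[0] == "#genotype":
        genotypes = dict(zip(first[1:], second[1:]))
        skip = [1]
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    return df, genotypes


def write_count_table(counts: pd.DataFrame, genotypes: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(counts.columns) + "\n")
        fh.write(
            "#genotype\t" + "\t".join(genotypes[c] for c in counts.columns) + "\n"
        )
        counts.to_csv(fh, sep="\t", header=False)
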