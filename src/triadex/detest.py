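"""Normalization and the per-gene negative-binomial pairwise Wald test.

The pipeline calls one internal NB test for all three contrasts of a
(female, male, hybrid) triad so that the downstream pattern classification is
internally consistent:

* library scaling by median-of-ratios size factors (geometric mean rescaled
  to 1), with an upper-quartile fallback when no gene is detected in every
  library;
* per-gene NB dispersion by method-of-moments pooled within groups, shrunk
  toward a fitted ``alpha(mu) = a0 + a1/mu`` mean trend and floored;
* a Wald z-test on the log ratio of group means of size-factor-normalized
  counts (delta-method standard error), two-sided p, Benjamini-Hochberg q.

Differential calls follow strict thresholds: ``|log2FC| > fc_threshold`` and
``p < alpha`` (raw p by default; BH q with ``use_adjusted``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, GeneLengths

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-4
PSEUDOCOUNT = 0.5


@dataclass
class NormalizedMatrix:
    """Normalized expression values (CPM or FPKM) with their size factors."""

    values: pd.DataFrame
    size_factors: pd.Series
    unit: str  # "CPM" or "FPKM"

    def __post_init__(self) -> None:
        sf = self.size_factors.to_numpy(float)
        if not np.all(np.isfinite(sf)) or (sf <= 0).any():
            raise ValueError("size factors must be finite and positive")


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else counts


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Each sample's factor is the median across genes of the ratio of its count
    to the gene's geometric mean, using only genes with a nonzero count in
    every sample. When no such gene exists, falls back to upper-quartile
    scaling of nonzero counts.
    """
    df = _as_frame(counts)
    arr = df.to_numpy(float)
    if arr.sum() == 0:
        raise ValueError("all-zero count matrix: size factors undefined")
    allpos = (arr > 0).all(axis=1)
    if allpos.any():
        loggeo = np.log(arr[allpos]).mean(axis=1, keepdims=True)
        ratios = np.log(arr[allpos]) - loggeo
        logsf = np.median(ratios, axis=0)
    else:
        logger.warning(
            "no gene detected in all %d samples; using upper-quartile scaling",
            arr.shape[1],
        )
        uq = np.array(
            [np.percentile(col[col > 0], 75) if (col > 0).any() else np.nan
             for col in arr.T]
        )
        if np.isnan(uq).any():
            raise ValueError("a sample has no nonzero counts")
        logsf = np.log(uq)
    logsf = logsf - logsf.mean()  # geometric mean 1
    return pd.Series(np.exp(logsf), index=df.columns, name="size_factor")


def to_cpm(
    counts: CountMatrix | pd.DataFrame, factors: pd.Series | None = None
) -> NormalizedMatrix:
    """Counts per million of normalized library size.

    Each sample's normalized library size is its size factor times the
    geometric-mean raw library size, so the factors carry all between-sample
    depth differences exactly once: rescaling one library leaves its CPM
    column unchanged after factor recomputation.
    """
    df = _as_frame(counts)
    if factors is None:
        factors = size_factors(df)
    libsize = df.sum(axis=0).to_numpy(float)
    common = np.exp(np.mean(np.log(libsize)))
    denom = factors.loc[df.columns].to_numpy(float) * common
    values = df.to_numpy(float) / denom * 1e6
    return NormalizedMatrix(
        pd.DataFrame(values, index=df.index, columns=df.columns), factors, "CPM"
    )


def to_fpkm(
    counts: CountMatrix | pd.DataFrame,
    lengths: GeneLengths,
    factors: pd.Series | None = None,
) -> NormalizedMatrix:
    """Fragments per kilobase per million: CPM scaled by gene length in kb."""
    df = _as_frame(counts)
    missing = df.index.difference(lengths.index)
    if len(missing):
        raise KeyError(f"no gene length for: {list(missing[:5])}")
    cpm = to_cpm(df, factors)
    lens = lengths.loc[df.index].to_numpy(float)
    values = cpm.values.to_numpy() * 1e3 / lens[:, None]
    return NormalizedMatrix(
        pd.DataFrame(values, index=df.index, columns=df.columns),
        cpm.size_factors,
        "FPKM",
    )


def count_expressed(
    norm: NormalizedMatrix, samples: list[str], threshold: float = 0.0
) -> int:
    """Number of genes whose mean normalized value across ``samples`` exceeds
    ``threshold`` (strict)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    missing = [s for s in samples if s not in norm.values.columns]
    if missing:
        raise KeyError(f"unknown samples: {missing}")
    means = norm.values[samples].mean(axis=1)
    return int((means > threshold).sum())


# ---------------------------------------------------------------------------
# NB Wald test


def _fit_dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha = a0 + a1/mu on usable moment estimates."""
    use = (mu > 0) & np.isfinite(alpha_mom) & (alpha_mom > 0)
    if use.sum() < 10:
        return max(np.nanmedian(alpha_mom[use]) if use.any() else 0.1, DISPERSION_FLOOR), 0.0
    x = 1.0 / mu[use]
    y = alpha_mom[use]
    A = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a0 = max(float(coef[0]), DISPERSION_FLOOR)
    a1 = max(float(coef[1]), 0.0)
    return a0, a1


def nb_pairwise_test(
    counts: CountMatrix | pd.DataFrame,
    group1: list[str],
    group2: list[str],
    *,
    factors: pd.Series | None = None,
    contrast: str = "g1vsg2",
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
    min_total: int = 10,
    shrink_weight: float = 0.0,
) -> pd.DataFrame:
    """Per-gene NB Wald test of ``group2`` over ``group1``.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (group2 over
    group1), ``se``, ``pvalue``, ``qvalue``, ``state`` and ``tested``. Genes
    with fewer than ``min_total`` total counts across both groups are excluded
    from testing (``tested = False``, state ``ns``); BH adjustment runs over
    tested genes only.
    """
    if len(group1) < 2 or len(group2) < 2:
        raise ValueError("each group needs >= 2 replicates for the NB test")
    df = _as_frame(counts)
    missing = [s for s in group1 + group2 if s not in df.columns]
    if missing:
        raise KeyError(f"unknown samples: {missing}")
    if factors is None:
        factors = size_factors(df[group1 + group2])

    sf1 = factors.loc[group1].to_numpy(float)
    sf2 = factors.loc[group2].to_numpy(float)
    n1, n2 = len(group1), len(group2)
    x1 = df[group1].to_numpy(float) / sf1
    x2 = df[group2].to_numpy(float) / sf2

    total = df[group1 + group2].sum(axis=1).to_numpy()
    tested = total >= min_total
    n_filtered = int((~tested).sum())
    if n_filtered:
        logger.info(
            "contrast %s: %d genes below %d total counts filtered before testing",
            contrast, n_filtered, min_total,
        )

    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    log2fc = np.log2((m2 + PSEUDOCOUNT) / (m1 + PSEUDOCOUNT))

    # method-of-moments dispersion pooled within groups:
    # var(count/sf) = mu/sf + alpha*mu^2  =>  alpha = (v - mu*mean(1/sf)) / mu^2
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    c1 = np.mean(1.0 / sf1)
    c2 = np.mean(1.0 / sf2)
    with np.errstate(divide="ignore", invalid="ignore"):
        a1_mom = (v1 - m1 * c1) / np.square(m1)
        a2_mom = (v2 - m2 * c2) / np.square(m2)
    w1, w2 = (n1 - 1), (n2 - 1)
    alpha_mom = (np.nan_to_num(a1_mom) * w1 + np.nan_to_num(a2_mom) * w2) / (w1 + w2)
    mu_pool = (m1 * n1 + m2 * n2) / (n1 + n2)
    a0, a1c = _fit_dispersion_trend(mu_pool[tested], alpha_mom[tested])
    with np.errstate(divide="ignore"):
        trend = a0 + a1c / np.maximum(mu_pool, 1e-8)
    alpha_gene = np.maximum(alpha_mom, DISPERSION_FLOOR)
    # geometric shrinkage toward the trend stabilises the few-replicate MoM
    disp = np.exp(
        shrink_weight * np.log(alpha_gene) + (1 - shrink_weight) * np.log(trend)
    )
    disp = np.maximum(disp, DISPERSION_FLOOR)

    # delta-method variance of log group means of normalized counts
    var_mean1 = (m1 * np.sum(1.0 / sf1) / n1**2) + disp * np.square(m1) / n1
    var_mean2 = (m2 * np.sum(1.0 / sf2) / n2**2) + disp * np.square(m2) / n2
    varln = var_mean1 / np.square(m1 + PSEUDOCOUNT) + var_mean2 / np.square(
        m2 + PSEUDOCOUNT
    )
    se = np.sqrt(np.maximum(varln, 0.0)) / np.log(2)
    se = np.maximum(se, 1e-8)
    z = log2fc / se
    pvalue = 2.0 * stats.norm.sf(np.abs(z))
    pvalue[log2fc == 0.0] = 1.0

    out = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se,
            "pvalue": np.where(tested, pvalue, np.nan),
            "qvalue": np.nan,
            "tested": tested,
        },
        index=df.index,
    )
    if tested.any():
        out.loc[tested, "qvalue"] = multipletests(
            out.loc[tested, "pvalue"].to_numpy(), method="fdr_bh"
        )[1]
    out.attrs["contrast"] = contrast
    out.attrs["n_filtered"] = n_filtered
    return apply_de_thresholds(
        out, fc_threshold=fc_threshold, alpha=alpha, use_adjusted=use_adjusted
    )


def apply_de_thresholds(
    results: pd.DataFrame,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Recompute the up/down/ns state under the given thresholds.

    ``up`` requires ``log2fc > fc_threshold`` (strict) and significance
    ``< alpha`` (strict); ``down`` is symmetric; everything else, including
    untested genes, is ``ns``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1); got {alpha}")
    out = results.copy()
    if "tested" not in out.columns:
        out["tested"] = True
    crit = out["qvalue"] if use_adjusted else out["pvalue"]
    sig = (crit < alpha) & out["tested"]
    state = np.full(len(out), "ns", dtype=object)
    state[(out["log2fc"] > fc_threshold) & sig] = "up"
    state[(out["log2fc"] < -fc_threshold) & sig] = "down"
    out["state"] = state
    out.attrs.update(results.attrs)
    out.attrs["n_up"] = int((state == "up").sum())
    out.attrs["n_down"] = int((state == "down").sum())
    out.attrs["n_total_de"] = out.attrs["n_up"] + out.attrs["n_down"]
    return out
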