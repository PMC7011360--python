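"""Relative quantification of qPCR Ct tables by the 2^−ΔΔCt method.

Per replicate, ΔCt = Ct(target) − Ct(reference gene); per genotype the mean
ΔCt is referenced to a calibrator genotype, ΔΔCt = mean ΔCt(genotype) −
mean ΔCt(calibrator), and the relative expression fold is 2^−ΔΔCt. The
replicate SD of ΔCt propagates to a fold range [2^−(ΔΔCt+sd), 2^−(ΔΔCt−sd)].
Plate-wide Ct shifts cancel in ΔCt; changing the calibrator rescales all
folds by one common factor, leaving between-genotype ratios invariant.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import CtTable


def ddct(
    ct: CtTable,
    target_gene: str,
    reference_gene: str,
    calibrator: str,
) -> pd.DataFrame:
    """Per-genotype relative expression of ``target_gene``.

    Returns a DataFrame indexed by genotype with columns ``dct_mean``,
    ``dct_sd``, ``ddct``, ``fold``, ``fold_lo``, ``fold_hi``,
    ``n_replicates``. The calibrator's fold is 1 by construction.
    """
    df = ct.table
    tgt = df[(df["gene"] == target_gene) & (~df["is_reference"])]
    ref = df[(df["gene"] == reference_gene) & (df["is_reference"])]
    if tgt.empty:
        raise KeyError(f"no Ct records for target gene '{target_gene}'")
    if ref.empty:
        raise KeyError(f"no Ct records for reference gene '{reference_gene}'")

    merged = tgt.merge(
        ref[["genotype", "replicate", "ct"]],
        on=["genotype", "replicate"],
        suffixes=("_target", "_ref"),
    )
    missing = set(zip(tgt["genotype"], tgt["replicate"])) - set(
        zip(merged["genotype"], merged["replicate"])
    )
    if missing:
        g, r = sorted(missing)[0]
        raise KeyError(
            f"missing reference Ct for genotype '{g}' replicate {r}"
        )
    merged["dct"] = merged["ct_target"] - merged["ct_ref"]

    per_geno = merged.groupby("genotype")["dct"].agg(
        dct_mean="mean", dct_sd=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
        n_replicates="size",
    )
    if calibrator not in per_geno.index:
        raise KeyError(f"calibrator genotype '{calibrator}' absent from Ct table")
    cal = per_geno.loc[calibrator, "dct_mean"]
    per_geno["ddct"] = per_geno["dct_mean"] - cal
    per_geno["fold"] = np.power(2.0, -per_geno["ddct"])
    per_geno["fold_lo"] = np.power(2.0, -(per_geno["ddct"] + per_geno["dct_sd"]))
    per_geno["fold_hi"] = np.power(2.0, -(per_geno["ddct"] - per_geno["dct_sd"]))
    per_geno.attrs["target_gene"] = target_gene
    per_geno.attrs["calibrator"] = calibrator
    return per_geno[
        ["dct_mean", "dct_sd", "ddct", "fold", "fold_lo", "fold_hi", "n_replicates"]
    ]


def concordance(
    rnaseq_folds: pd.Series,
    qpcr_folds: pd.Series,
    baseline: str | None = None,
) -> tuple[float, float]:
    """Agreement between RNA-seq and qPCR fold estimates.

    Both inputs are fold values indexed by (gene, genotype). Returns the
    Spearman rank correlation over shared points and the fraction of shared
    points whose up/down direction relative to the baseline genotype (fold
    >= 1 vs < 1; default baseline is the fold scale's calibrator, i.e. the
    comparison is to fold = 1) agrees between platforms.
    """
    shared = rnaseq_folds.index.intersection(qpcr_folds.index)
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared (gene, genotype) points, got {len(shared)}"
        )
    a = rnaseq_folds.loc[shared].to_numpy(float)
    b = qpcr_folds.loc[shared].to_numpy(float)
    rho = float(stats.spearmanr(a, b).statistic)
    if baseline is not None:
        keep = [i for i in shared if i[1] != baseline]
        a = rnaseq_folds.loc[keep].to_numpy(float)
        b = qpcr_folds.loc[keep].to_numpy(float)
    agreement = float(np.mean((a >= 1.0) == (b >= 1.0)))
    return rho, agreement
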