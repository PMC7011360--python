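"""Mid-parent biomass heterosis statistics.

For a triad and trait the module computes the mid-parent value
``MPV = (mean(P1) + mean(P2)) / 2``, mid-parent heterosis
``MPH% = 100 (H − MPV) / MPV``, better-parent heterosis
``BPH% = 100 (H − best parent) / best parent`` and a significance test of the
hybrid against the mid-parent level. The default test is a Welch two-sample
t-test of the hybrid replicates against replicate-wise mid-parent composites
``(P1_i + P2_i) / 2`` (parents paired by replicate order); when the parents
have unequal replicate counts it falls back to a one-sample t-test against
the scalar MPV. Significance marks follow the two-star convention:
``**`` for p < 0.01, ``*`` for 0.01 ≤ p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PhenotypeTable

logger = logging.getLogger(__name__)


@dataclass
class HeterosisResult:
    triad_id: str
    timepoint: int
    trait: str
    mpv: float
    hybrid_mean: float
    mph_percent: float
    bph_percent: float
    statistic: float
    pvalue: float
    mark: str


def significance_mark(p: float) -> str:
    """`**` below 0.01, `*` below 0.05, empty otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def mid_parent_value(parent1: np.ndarray, parent2: np.ndarray) -> float:
    p1 = np.asarray(parent1, float)
    p2 = np.asarray(parent2, float)
    if p1.size == 0 or p2.size == 0:
        raise ValueError("each parent needs >= 1 replicate for the MPV")
    return float((p1.mean() + p2.mean()) / 2.0)


def mph_percent(hybrid_mean: float, mpv: float) -> float:
    return 100.0 * (hybrid_mean - mpv) / mpv


def bph_percent(hybrid_mean: float, parent1: np.ndarray, parent2: np.ndarray) -> float:
    best = max(np.asarray(parent1, float).mean(), np.asarray(parent2, float).mean())
    return 100.0 * (hybrid_mean - best) / best


def test_vs_mpv(
    hybrid: np.ndarray,
    parent1: np.ndarray,
    parent2: np.ndarray,
    *,
    triad_id: str = "",
    timepoint: int = 0,
    trait: str = "fresh",
) -> HeterosisResult:
    """Test whether the hybrid deviates from its mid-parent level."""
    h = np.asarray(hybrid, float)
    p1 = np.asarray(parent1, float)
    p2 = np.asarray(parent2, float)
    if h.size < 2:
        raise ValueError("need >= 2 hybrid replicates to test against the MPV")
    mpv = mid_parent_value(p1, p2)
    if p1.size == p2.size:
        composites = (p1 + p2) / 2.0
        stat, p = stats.ttest_ind(h, composites, equal_var=False)
    else:
        logger.info(
            "triad %s: unequal parent replicate counts (%d vs %d); "
            "one-sample t against scalar MPV", triad_id, p1.size, p2.size,
        )
        stat, p = stats.ttest_1samp(h, mpv)
    if np.isnan(p):  # zero variance everywhere: no evidence of deviation
        stat, p = 0.0, 1.0
    hm = float(h.mean())
    return HeterosisResult(
        triad_id=triad_id,
        timepoint=timepoint,
        trait=trait,
        mpv=mpv,
        hybrid_mean=hm,
        mph_percent=mph_percent(hm, mpv),
        bph_percent=bph_percent(hm, p1, p2),
        statistic=float(stat),
        pvalue=float(p),
        mark=significance_mark(float(p)),
    )


def heterosis_table(
    pheno: PhenotypeTable,
    triads: dict[str, tuple[str, str, str]],
    traits: tuple[str, ...] = ("fresh", "dry"),
) -> pd.DataFrame:
    """Heterosis statistics for every (triad, timepoint, trait).

    ``triads`` maps triad id -> (female genotype, male genotype, hybrid
    genotype).
    """
    rows = []
    timepoints = sorted(pheno.table["timepoint"].unique())
    for triad_id, (female, male, hybrid) in triads.items():
        for tp in timepoints:
            for trait in traits:
                res = test_vs_mpv(
                    pheno.biomass(hybrid, tp, trait),
                    pheno.biomass(female, tp, trait),
                    pheno.biomass(male, tp, trait),
                    triad_id=triad_id,
                    timepoint=tp,
                    trait=trait,
                )
                rows.append(res.__dict__)
    return pd.DataFrame(rows)
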