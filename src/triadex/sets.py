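"""Gene-set algebra over DEG lists and pattern calls.

Covers the cross-contrast and cross-hybrid comparisons of the analysis:
unique/common partitions of two or three DEG lists, the overdominant genes
shared by all hybrids in a tissue, and a per-gene z-scored expression matrix
for exporting shared-gene expression profiles.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd

from .detest import NormalizedMatrix

logger = logging.getLogger(__name__)

OD_ROLLUPS = {"OD-up", "OD-down"}


def venn_partition(named_sets: dict[str, set[str]]) -> dict[str, set[str]]:
    """Disjoint Venn regions of 2 or 3 named sets.

    Region keys are ``&``-joined sorted name combinations (e.g. ``"A"``,
    ``"A&B"``, ``"A&B&C"``); a gene lands in the region of exactly the sets
    that contain it. The 2^k − 1 regions are disjoint and their union is the
    union of the inputs.
    """
    names = list(named_sets)
    if not 2 <= len(names) <= 3:
        raise ValueError(
            f"venn_partition takes 2 or 3 sets, got {len(names)}; "
            "use upset_table for more"
        )
    regions: dict[str, set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(named_sets[n] for n in combo))
            outside = set.union(
                set(), *(named_sets[n] for n in names if n not in combo)
            )
            regions["&".join(combo)] = inside - outside
    return regions


def upset_table(named_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Membership-pattern counts for any number of sets (boolean columns +
    ``n_genes``), for when a Venn layout no longer applies."""
    universe = sorted(set().union(*named_sets.values()))
    member = pd.DataFrame(
        {name: [g in s for g in universe] for name, s in named_sets.items()},
        index=universe,
    )
    out = member.groupby(list(named_sets)).size().rename("n_genes").reset_index()
    return out.sort_values("n_genes", ascending=False).reset_index(drop=True)


def overdominant_genes(
    pattern_calls: pd.DataFrame, direction: str | None = None
) -> set[str]:
    """Genes with an overdominant rollup in one pattern table.

    ``direction`` restricts to ``"up"`` (OD-up) or ``"down"`` (OD-down);
    default pools both directions.
    """
    if direction is None:
        mask = pattern_calls["rollup"].isin(OD_ROLLUPS)
    elif direction in ("up", "down"):
        mask = pattern_calls["rollup"] == f"OD-{direction}"
    else:
        raise ValueError(f"direction must be 'up', 'down' or None; got {direction!r}")
    return set(pattern_calls.index[mask])


def common_overdominant(
    calls_per_hybrid: dict[str, pd.DataFrame],
    direction_match: bool = False,
) -> set[str]:
    """Genes overdominant in every hybrid's pattern table.

    By default OD-up and OD-down are pooled (a gene only needs *some*
    overdominant call in each hybrid); ``direction_match`` additionally
    requires the same direction in all hybrids.
    """
    if not calls_per_hybrid:
        raise ValueError("no pattern tables given")
    universes = [set(df.index) for df in calls_per_hybrid.values()]
    shared = set.intersection(*universes)
    if any(u != shared for u in universes):
        logger.warning(
            "pattern tables have mismatched gene universes; "
            "restricting to the %d shared genes", len(shared),
        )
    if direction_match:
        per_dir = [
            set.intersection(
                *(overdominant_genes(df, d) for df in calls_per_hybrid.values())
            )
            for d in ("up", "down")
        ]
        common = per_dir[0] | per_dir[1]
    else:
        common = set.intersection(
            *(overdominant_genes(df) for df in calls_per_hybrid.values())
        )
    return common & shared


def zscore_matrix(
    norm: NormalizedMatrix | pd.DataFrame,
    genes: list[str],
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-scores (population-sd convention) across selected samples.

    Constant rows are set to all zeros and returned in the flagged list.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise KeyError(f"unknown genes: {missing[:5]}")
    sub = values.loc[genes, samples] if samples is not None else values.loc[genes]
    arr = sub.to_numpy(float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)  # population (n) denominator
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (arr - mean) / sd
    z[flat] = 0.0
    flagged = [g for g, f in zip(sub.index, flat) if f]
    return pd.DataFrame(z, index=sub.index, columns=sub.columns), flagged
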