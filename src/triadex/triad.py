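"""Twelve-group expression-pattern classification for parent/parent/F1 triads.

Each gene of a triad is summarized by three differential-expression states:

* ``state_FH`` — hybrid vs female parent (sign of hybrid − female),
* ``state_MH`` — hybrid vs male parent (sign of hybrid − male),
* ``state_FM`` — male vs female parent (sign of male − female),

each ``up``, ``down`` or ``ns`` under one shared threshold configuration.
The 27 possible state combinations map deterministically onto the classical
inheritance-mode groups:

====== ===================== ========================================
group  rollup                geometry (F = female, M = male, H = hybrid)
====== ===================== ========================================
0      conserved             F ≈ M ≈ H (all three contrasts ns)
1, 2   additive              parents differ, H strictly between them
3, 4   M-ELD                 H ≈ M, both differ from F (M high / low)
5, 6   F-ELD                 H ≈ F, both differ from M (F high / low)
7–9    OD-down               H below both parents (F>M / F≈M / F<M)
10–12  OD-up                 H above both parents (F>M / F≈M / F<M)
13     ambiguous             every remaining combination
====== ===================== ========================================

Each informative group (1–12) corresponds to exactly one state combination;
the 14 combinations that fit none of the geometries above (e.g. the hybrid
differing from only one parent while the parents are equivalent, or
direction-inconsistent triples arising from non-transitive test calls) land
in the ambiguous bin. "H matches a parent" is the accepted-null convention:
the corresponding contrast is ns, which is evidence of absence only in the
power-limited sense.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .detest import nb_pairwise_test, size_factors
from .io import CountMatrix, DesignError, SampleSheet

STATES = ("up", "down", "ns")

ROLLUP_OF_GROUP = {
    0: "conserved",
    1: "additive", 2: "additive",
    3: "M-ELD", 4: "M-ELD",
    5: "F-ELD", 6: "F-ELD",
    7: "OD-down", 8: "OD-down", 9: "OD-down",
    10: "OD-up", 11: "OD-up", 12: "OD-up",
    13: "ambiguous",
}

# canonical (state_FH, state_MH, state_FM) -> group for the informative groups
_CANONICAL: dict[tuple[str, str, str], int] = {
    ("ns", "ns", "ns"): 0,
    ("down", "up", "down"): 1,   # F high parent, H between
    ("up", "down", "up"): 2,     # M high parent, H between
    ("up", "ns", "up"): 3,       # H ≈ M, M high
    ("down", "ns", "down"): 4,   # H ≈ M, M low
    ("ns", "up", "down"): 5,     # H ≈ F, F high
    ("ns", "down", "up"): 6,     # H ≈ F, F low
    ("down", "down", "down"): 7,
    ("down", "down", "ns"): 8,
    ("down", "down", "up"): 9,
    ("up", "up", "down"): 10,
    ("up", "up", "ns"): 11,
    ("up", "up", "up"): 12,
}


@dataclass(frozen=True)
class PatternCall:
    """Classification of one gene: group 0–13 plus its rollup category."""

    gene: str
    group: int
    rollup: str


def classify_gene(
    state_fh: str, state_mh: str, state_fm: str, gene: str = ""
) -> PatternCall:
    """Map one gene's three pairwise DE states to its pattern group."""
    key = (state_fh, state_mh, state_fm)
    for s in key:
        if s not in STATES:
            raise ValueError(f"invalid DE state token: {s!r}")
    group = _CANONICAL.get(key, 13)
    return PatternCall(gene=gene, group=group, rollup=ROLLUP_OF_GROUP[group])


def enumerate_groups() -> dict[tuple[str, str, str], int]:
    """Exhaustive map of all 27 state combinations to their group."""
    return {
        combo: classify_gene(*combo).group
        for combo in itertools.product(STATES, repeat=3)
    }


def swap_roles(combo: tuple[str, str, str]) -> tuple[str, str, str]:
    """State triple after exchanging the female and male labels.

    FH and MH swap; FM (male − female) flips sign.
    """
    flip = {"up": "down", "down": "up", "ns": "ns"}
    fh, mh, fm = combo
    return (mh, fh, flip[fm])


def classify_states(states: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification of a table with columns state_FH/MH/FM."""
    table = enumerate_groups()
    groups = [
        table[(fh, mh, fm)]
        for fh, mh, fm in zip(
            states["state_FH"], states["state_MH"], states["state_FM"]
        )
    ]
    out = states.copy()
    out["group"] = groups
    out["rollup"] = out["group"].map(ROLLUP_OF_GROUP)
    return out


def classify_triad(
    counts: CountMatrix,
    design: SampleSheet,
    triad_id: str,
    tissue: str,
    *,
    fc_threshold: float = 1.0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
    min_total: int = 10,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every gene of one triad in one tissue.

    Runs the NB Wald test for the three contrasts (female vs hybrid, male vs
    hybrid, female vs male) with size factors shared across the triad's nine
    libraries, then maps each gene's state triple to its group. Genes below
    the count filter in any contrast are reported as group 0 with a
    ``low_expression`` flag rather than dropped.

    Returns ``(per-gene table, group histogram over 0–13)``.
    """
    roles = {}
    for role in ("female", "male", "hybrid"):
        ids = design.samples_for(triad_id, tissue, role=role)
        if not ids:
            raise DesignError(
                f"triad '{triad_id}' tissue '{tissue}' lacks {role} samples"
            )
        roles[role] = ids
    all_samples = roles["female"] + roles["male"] + roles["hybrid"]
    factors = size_factors(counts.counts[all_samples])

    kw = dict(
        factors=factors,
        fc_threshold=fc_threshold,
        alpha=alpha,
        use_adjusted=use_adjusted,
        min_total=min_total,
    )
    de_fh = nb_pairwise_test(counts, roles["female"], roles["hybrid"],
                             contrast="FvsH", **kw)
    de_mh = nb_pairwise_test(counts, roles["male"], roles["hybrid"],
                             contrast="MvsH", **kw)
    de_fm = nb_pairwise_test(counts, roles["female"], roles["male"],
                             contrast="FvsM", **kw)

    low = ~(de_fh["tested"] & de_mh["tested"] & de_fm["tested"])
    states = pd.DataFrame(
        {
            "state_FH": de_fh["state"].where(~low, "ns"),
            "state_MH": de_mh["state"].where(~low, "ns"),
            "state_FM": de_fm["state"].where(~low, "ns"),
        },
        index=counts.counts.index,
    )
    out = classify_states(states)
    out["low_expression"] = low
    for label, de in (("FH", de_fh), ("MH", de_mh), ("FM", de_fm)):
        out[f"log2fc_{label}"] = de["log2fc"]
        out[f"p_{label}"] = de["pvalue"]
    out.index.name = "gene"

    summary = out["group"].value_counts().reindex(range(14), fill_value=0)
    summary.index.name = "group"
    summary.name = "n_genes"
    return out, summary
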