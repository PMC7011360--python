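"""Synthetic data with planted inheritance classes, the pipeline's test bed.

The generator emulates the study design every stage assumes: one female
parent (A) crossed to three male parents (B, C, D) giving three hybrids
(H, M, L), two tissues (root, leaf) and three biological replicates — 42
libraries. Each gene is planted, per tissue, into one inheritance class
(conserved / additive / M-ELD / F-ELD / OD-up / OD-down); genotype means are
built from the class geometry and counts drawn from a negative binomial with
a ``a0 + a1/mu`` dispersion trend and log-normal library-size factors. The
emitted :class:`TruthTable` is the ground truth that parameter-recovery
tests score against.

Companion generators produce a phenotype table with configurable mid-parent
heterosis per hybrid and timepoint, a flat annotation with one term enriched
in planted overdominant genes, and a qPCR Ct table consistent with the
planted expression ratios (exact in the noiseless limit).

All randomness flows from a single seed; each generator draws from a
sub-stream derived by a fixed label, so adding a generator never perturbs
the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnnotationMap, CountMatrix, CtTable, PhenotypeTable, SampleSheet

CLASSES = ("conserved", "additive", "M-ELD", "F-ELD", "OD-up", "OD-down")

DEFAULT_PROPORTIONS = {
    "conserved": 0.70,
    "additive": 0.06,
    "M-ELD": 0.06,
    "F-ELD": 0.06,
    "OD-up": 0.06,
    "OD-down": 0.06,
}

# hybrid biomass targets relative to MPV: the high hybrid gains vigor by
# 30 DAE, the medium hybrid tracks its mid-parent, the low hybrid lags
DEFAULT_MPH_TARGETS = {
    "H": {10: 0.05, 20: 0.08, 30: 0.20},
    "M": {10: 0.0, 20: 0.0, 30: 0.0},
    "L": {10: -0.15, 20: -0.15, 30: -0.15},
}


@dataclass
class SimConfig:
    """Study-design parameters of the generator (defaults = the emulated design)."""

    seed: int
    n_genes: int = 2000
    replicates: int = 3
    tissues: tuple[str, ...] = ("root", "leaf")
    female: str = "A"
    males: tuple[str, ...] = ("B", "C", "D")
    hybrids: tuple[str, ...] = ("H", "M", "L")
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    effect_lfc: float = 2.0            # |log2FC| of planted parental / hybrid effects
    base_mean: float = 150.0           # median of the log-normal baseline mean
    base_log_sd: float = 1.0
    dispersion_a0: float = 0.05        # NB dispersion = a0 + a1/mu
    dispersion_a1: float = 1.0
    libsize_log_sd: float = 0.1
    # phenotypes
    pheno_replicates: int = 5
    timepoints: tuple[int, ...] = (10, 20, 30)
    biomass_cv: float = 0.10
    mph_targets: dict[str, dict[int, float]] = field(
        default_factory=lambda: {h: dict(t) for h, t in DEFAULT_MPH_TARGETS.items()}
    )
    dry_ratio: float = 0.15
    # annotation
    n_terms: int = 20
    term_size: int = 50
    planted_term_odds: float = 10.0
    # qPCR
    ct_genes: int = 12
    ct_replicates: int = 3
    ct_sd: float = 0.25
    ct_reference_gene: str = "actin"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.biomass_cv < 0 or self.ct_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if len(self.males) != len(self.hybrids):
            raise ValueError("need one hybrid per male parent")

    @property
    def genotypes(self) -> list[str]:
        return [self.female, *self.males, *self.hybrids]

    @property
    def triads(self) -> dict[str, tuple[str, str, str]]:
        """triad id -> (female, male, hybrid); triads named after their hybrid."""
        return {
            h: (self.female, m, h) for m, h in zip(self.males, self.hybrids)
        }

    def rng(self, label: str) -> np.random.Generator:
        """Sub-stream keyed by a fixed label, independent of other streams."""
        return np.random.default_rng([self.seed, zlib.crc32(label.encode())])


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, n + 1)]


def _class_means(
    cls: str, mu: float, lfc: float, male_high: bool
) -> tuple[float, float, float]:
    """(female, male, hybrid) mean from the class geometry."""
    e = 2.0 ** lfc
    if cls == "conserved":
        return mu, mu, mu
    f, m = (mu, mu * e) if male_high else (mu * e, mu)
    if cls == "additive":
        # log-scale mid-parent: symmetric +-lfc/2 margins to both parents
        return f, m, float(np.sqrt(f * m))
    if cls == "M-ELD":
        return f, m, m
    if cls == "F-ELD":
        return f, m, f
    if cls == "OD-up":
        return mu, mu, mu * e
    if cls == "OD-down":
        return mu, mu, mu / e
    raise ValueError(f"unknown class {cls!r}")


def simulate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, SampleSheet, pd.DataFrame]:
    """Generate the count matrix, sample sheet and truth table.

    The truth table has one row per (gene, tissue): planted ``class``, the
    signed male-over-female ``parental_log2fc`` and the hybrid's deviation
    from the arithmetic mid-parent, ``hybrid_deviation`` (log2). The same
    class geometry is applied to every triad (the three male parents share a
    gene's planted parental mean).
    """
    genes = _gene_ids(config.n_genes)
    rng_cls = config.rng("classes")
    rng_mu = config.rng("base-means")
    rng_lib = config.rng("library-sizes")
    rng_nb = config.rng("nb-counts")

    mu = config.base_mean * np.exp(
        rng_mu.normal(0.0, config.base_log_sd, config.n_genes)
    )

    labels = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in labels])

    # sample sheet: 1 row per library; the shared female parent lists all triads
    triad_of = {m: h for m, h in zip(config.males, config.hybrids)}
    rows = []
    for genotype in config.genotypes:
        if genotype == config.female:
            role, triad = "female", ";".join(config.hybrids)
        elif genotype in config.males:
            role, triad = "male", triad_of[genotype]
        else:
            role, triad = "hybrid", genotype
        for tissue in config.tissues:
            for rep in range(1, config.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{genotype}_{tissue}_{rep}",
                        "genotype": genotype,
                        "role": role,
                        "triad_id": triad,
                        "tissue": tissue,
                        "replicate": rep,
                    }
                )
    sheet = SampleSheet(pd.DataFrame(rows))
    sample_ids = sheet.table["sample_id"].tolist()

    sf = np.exp(rng_lib.normal(0.0, config.libsize_log_sd, len(sample_ids)))
    sf /= np.exp(np.mean(np.log(sf)))

    truth_rows = []
    counts = np.zeros((config.n_genes, len(sample_ids)), dtype=np.int64)
    col_of = {s: j for j, s in enumerate(sample_ids)}
    geno_of = dict(zip(sheet.table["sample_id"], sheet.table["genotype"]))
    tissue_of = dict(zip(sheet.table["sample_id"], sheet.table["tissue"]))

    for tissue in config.tissues:
        cls = rng_cls.choice(labels, size=config.n_genes, p=probs)
        male_high = rng_cls.random(config.n_genes) < 0.5
        means = {g: np.empty(config.n_genes) for g in config.genotypes}
        for i in range(config.n_genes):
            f, m, h = _class_means(
                cls[i], mu[i], config.effect_lfc, bool(male_high[i])
            )
            means[config.female][i] = f
            for male in config.males:
                means[male][i] = m
            for hyb in config.hybrids:
                means[hyb][i] = h
            truth_rows.append(
                {
                    "gene": genes[i],
                    "tissue": tissue,
                    "class": cls[i],
                    "parental_log2fc": 0.0
                    if cls[i] == "conserved" or cls[i].startswith("OD")
                    else np.log2(m / f),
                    "hybrid_deviation": float(np.log2(h / ((f + m) / 2.0))),
                }
            )
        for s in sample_ids:
            if tissue_of[s] != tissue:
                continue
            mean_vec = means[geno_of[s]] * sf[col_of[s]]
            alpha = config.dispersion_a0 + config.dispersion_a1 / mean_vec
            size = 1.0 / alpha
            p = size / (size + mean_vec)
            counts[:, col_of[s]] = rng_nb.negative_binomial(size, p)

    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=sample_ids))
    truth = pd.DataFrame(truth_rows)
    return cm, sheet, truth


def truth_means(truth: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """Relative planted means (female = 1) reconstructed from a truth table."""
    sub = truth[truth["tissue"] == tissue].set_index("gene")
    m_rel = np.power(2.0, sub["parental_log2fc"])
    mid = (1.0 + m_rel) / 2.0
    h_rel = mid * np.power(2.0, sub["hybrid_deviation"])
    return pd.DataFrame(
        {"female": 1.0, "male": m_rel, "hybrid": h_rel, "class": sub["class"]}
    )


def simulate_phenotypes(config: SimConfig) -> PhenotypeTable:
    """Biomass table with hybrid means planted at MPV × (1 + MPH target)."""
    rng = config.rng("phenotypes")
    base = {10: 2.0, 20: 8.0, 30: 20.0}
    mult = {config.female: 1.05}
    for j, male in enumerate(config.males):
        mult[male] = 1.0 - 0.05 * j
    rows = []
    for tp in config.timepoints:
        tp_base = base.get(tp, 2.0 * tp / 10.0)
        means = {g: tp_base * mult[g] for g in (config.female, *config.males)}
        for male, hyb in zip(config.males, config.hybrids):
            mpv = (means[config.female] + means[male]) / 2.0
            target = config.mph_targets.get(hyb, {}).get(tp, 0.0)
            means[hyb] = mpv * (1.0 + target)
        for genotype in config.genotypes:
            m = means[genotype]
            fresh = rng.normal(m, config.biomass_cv * m, config.pheno_replicates)
            fresh = np.maximum(fresh, 0.05 * m)
            ratio = np.clip(
                rng.normal(config.dry_ratio, 0.1 * config.dry_ratio,
                           config.pheno_replicates),
                0.01, 0.9,
            )
            for rep in range(config.pheno_replicates):
                rows.append(
                    {
                        "genotype": genotype,
                        "replicate": rep + 1,
                        "timepoint": tp,
                        "fresh": fresh[rep],
                        "dry": fresh[rep] * ratio[rep],
                    }
                )
    return PhenotypeTable(pd.DataFrame(rows))


def simulate_annotation(
    config: SimConfig, truth: pd.DataFrame, tissue: str | None = None
) -> AnnotationMap:
    """Flat annotation with one term ("TERM_OD") enriched in planted
    overdominant genes at the configured odds; background terms are uniform
    random gene sets."""
    rng = config.rng("annotation")
    tissue = tissue or config.tissues[0]
    sub = truth[truth["tissue"] == tissue]
    genes = sub["gene"].to_numpy()
    is_od = sub["class"].str.startswith("OD").to_numpy()

    weights = np.where(is_od, config.planted_term_odds, 1.0).astype(float)
    weights /= weights.sum()
    planted = rng.choice(
        genes, size=min(config.term_size, len(genes)), replace=False, p=weights
    )
    mapping: dict[str, set[str]] = {"TERM_OD": set(planted)}
    for t in range(1, config.n_terms):
        members = rng.choice(
            genes, size=min(config.term_size, len(genes)), replace=False
        )
        mapping[f"T{t:03d}"] = set(members)
    return AnnotationMap(mapping)


def simulate_ct(
    config: SimConfig, truth: pd.DataFrame, tissue: str | None = None
) -> tuple[CtTable, pd.DataFrame]:
    """Ct table consistent with the planted expression ratios.

    Target-gene Ct = gene offset − log2(relative expression) + N(0, ct_sd);
    the reference gene sits at a fixed Ct for every genotype. With
    ``ct_sd = 0`` the 2^−ΔΔCt folds recover the planted ratios exactly.
    Returns the table plus the per-(gene, genotype) planted fold relative to
    the female parent.
    """
    rng = config.rng("qpcr")
    tissue = tissue or config.tissues[0]
    rel = truth_means(truth, tissue)
    od = rel.index[rel["class"].str.startswith("OD")]
    pool = od if len(od) >= config.ct_genes else rel.index
    chosen = list(rng.choice(pool, size=min(config.ct_genes, len(pool)),
                             replace=False))

    geno_rel = {}
    for g in chosen:
        geno_rel[g] = {config.female: rel.loc[g, "female"]}
        for male in config.males:
            geno_rel[g][male] = rel.loc[g, "male"]
        for hyb in config.hybrids:
            geno_rel[g][hyb] = rel.loc[g, "hybrid"]

    offsets = {g: o for g, o in zip(chosen, rng.uniform(20.0, 26.0, len(chosen)))}
    rows, planted = [], []
    for genotype in config.genotypes:
        for rep in range(1, config.ct_replicates + 1):
            rows.append(
                {
                    "genotype": genotype,
                    "gene": config.ct_reference_gene,
                    "is_reference": True,
                    "replicate": rep,
                    "ct": 18.0 + rng.normal(0.0, config.ct_sd),
                }
            )
            for g in chosen:
                rows.append(
                    {
                        "genotype": genotype,
                        "gene": g,
                        "is_reference": False,
                        "replicate": rep,
                        "ct": offsets[g]
                        - np.log2(geno_rel[g][genotype])
                        + rng.normal(0.0, config.ct_sd),
                    }
                )
    for g in chosen:
        for genotype in config.genotypes:
            planted.append(
                {
                    "gene": g,
                    "genotype": genotype,
                    "fold": geno_rel[g][genotype] / geno_rel[g][config.female],
                }
            )
    return CtTable(pd.DataFrame(rows)), pd.DataFrame(planted)
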