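"""Readers, writers and typed containers for the pipeline's external formats.

Every downstream module consumes only the objects defined here: an integer
gene x sample :class:`CountMatrix`, a :class:`SampleSheet` binding libraries
to (genotype, role, triad, tissue, replicate), a gene-length table for FPKM,
a flat gene-to-term :class:`AnnotationMap`, a biomass :class:`PhenotypeTable`
and a qPCR :class:`CtTable`.

The canonical on-disk dialect is TSV (tab-delimited, UTF-8, ``#`` comment
lines ignored). Count matrices may alternatively be MatrixMarket ``.mtx``
(1-based, integer) with ``.rownames``/``.colnames`` sidecar files. Gene and
sample identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

logger = logging.getLogger(__name__)

VALID_ROLES = {"female", "male", "hybrid", "other"}


class FormatError(ValueError):
    """A file does not conform to its expected format."""


class DesignError(ValueError):
    """A sample sheet violates the triad design constraints."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class CountMatrix:
    """Integer read counts, genes as rows, libraries as columns."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dups[:5]}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # accept float input only if exactly integral
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                bad = np.argwhere(~np.isfinite(arr) | (arr != np.floor(arr)))[0]
                raise FormatError(
                    "non-integer count at gene "
                    f"'{df.index[bad[0]]}', sample '{df.columns[bad[1]]}'"
                )
            self.counts = df.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise FormatError(
                f"negative count at gene '{df.index[bad[0]]}', "
                f"sample '{df.columns[bad[1]]}'"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class SampleSheet:
    """Per-library design table.

    Columns: sample_id, genotype, role (female/male/hybrid/other), triad_id,
    tissue, replicate. A library shared between triads (the common female
    parent of several hybrids) lists all its triads separated by ``;`` in
    triad_id.
    """

    table: pd.DataFrame

    REQUIRED = ["sample_id", "genotype", "role", "triad_id", "tissue", "replicate"]

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"sample sheet missing columns: {missing}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample_id: {dups[:5]}")
        df = df.copy()
        df["role"] = df["role"].str.lower()
        bad_roles = set(df["role"]) - VALID_ROLES
        if bad_roles:
            raise FormatError(f"unknown roles: {sorted(bad_roles)}")
        df["replicate"] = df["replicate"].astype(int)
        if (df["replicate"] < 1).any():
            raise FormatError("replicate indices must be >= 1")
        self.table = df.reset_index(drop=True)
        self._validate_triads()

    def _validate_triads(self) -> None:
        long = self.expanded()
        for (triad, tissue), grp in long[long["role"] != "other"].groupby(
            ["triad_id", "tissue"]
        ):
            for role in ("female", "male", "hybrid"):
                sub = grp[grp["role"] == role]
                genos = sub["genotype"].unique()
                if len(genos) == 0:
                    raise DesignError(
                        f"triad '{triad}' tissue '{tissue}' has no {role} samples"
                    )
                if len(genos) > 1:
                    raise DesignError(
                        f"triad '{triad}' tissue '{tissue}' has multiple {role} "
                        f"genotypes: {sorted(genos)}"
                    )
                if len(sub) < 2:
                    raise DesignError(
                        f"triad '{triad}' tissue '{tissue}' role {role} has "
                        f"{len(sub)} replicate(s); >= 2 required for testing"
                    )

    def expanded(self) -> pd.DataFrame:
        """One row per (sample, triad): splits multi-triad memberships."""
        df = self.table.copy()
        df["triad_id"] = df["triad_id"].astype(str).str.split(";")
        return df.explode("triad_id").reset_index(drop=True)

    @property
    def triads(self) -> list[str]:
        return sorted(self.expanded()["triad_id"].unique())

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def samples_for(
        self, triad_id: str, tissue: str, role: str | None = None,
        genotype: str | None = None,
    ) -> list[str]:
        long = self.expanded()
        m = (long["triad_id"] == triad_id) & (long["tissue"] == tissue)
        if role is not None:
            m &= long["role"] == role
        if genotype is not None:
            m &= long["genotype"] == genotype
        return long.loc[m, "sample_id"].tolist()

    def genotype_samples(self, genotype: str, tissue: str | None = None) -> list[str]:
        m = self.table["genotype"] == genotype
        if tissue is not None:
            m &= self.table["tissue"] == tissue
        ids = self.table.loc[m, "sample_id"].tolist()
        if not ids:
            raise KeyError(f"unknown genotype/tissue: {genotype}/{tissue}")
        return ids


@dataclass
class AnnotationMap:
    """Flat term -> gene-set annotation with an explicit background universe."""

    term_to_genes: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, genes in self.term_to_genes.items():
            if not term:
                raise FormatError("empty term identifier")
            if not genes:
                raise FormatError(f"term '{term}' maps to an empty gene set")

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.term_to_genes.values():
            out |= genes
        return out

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_to_genes)


@dataclass
class PhenotypeTable:
    """Per-plant biomass records: genotype, replicate, timepoint (DAE), fresh/dry g."""

    table: pd.DataFrame

    REQUIRED = ["genotype", "replicate", "timepoint", "fresh", "dry"]

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"phenotype table missing columns: {missing}")
        df = df.copy()
        n0 = len(df)
        df = df.dropna(subset=["fresh", "dry"])
        if len(df) < n0:
            logger.info("dropped %d phenotype rows with missing biomass", n0 - len(df))
        if (df["fresh"] < 0).any() or (df["dry"] < 0).any():
            raise FormatError("negative biomass value")
        bad = df["dry"] > df["fresh"]
        if bad.any():
            row = df[bad].iloc[0]
            raise FormatError(
                f"dry biomass exceeds fresh for genotype '{row['genotype']}' "
                f"replicate {row['replicate']}"
            )
        self.table = df.reset_index(drop=True)

    def biomass(self, genotype: str, timepoint: int, trait: str = "fresh") -> np.ndarray:
        df = self.table
        m = (df["genotype"] == genotype) & (df["timepoint"] == timepoint)
        vals = df.loc[m, trait].to_numpy(float)
        if vals.size == 0:
            raise KeyError(f"no {trait} biomass for genotype '{genotype}' at {timepoint} DAE")
        return vals


@dataclass
class CtTable:
    """qPCR cycle-threshold records: genotype, gene, is_reference, replicate, ct."""

    table: pd.DataFrame

    REQUIRED = ["genotype", "gene", "is_reference", "replicate", "ct"]

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise FormatError(f"Ct table missing columns: {missing}")
        df = df.copy()
        if df["is_reference"].dtype != bool:
            df["is_reference"] = (
                df["is_reference"].astype(str).str.lower().isin(["1", "true", "yes"])
            )
        if (df["ct"] <= 0).any():
            raise FormatError("Ct values must be > 0")
        for genotype, grp in df.groupby("genotype"):
            reps_with_ref = set(grp.loc[grp["is_reference"], "replicate"])
            reps = set(grp["replicate"])
            if not reps_with_ref:
                raise FormatError(
                    f"genotype '{genotype}' has no reference-gene Ct records"
                )
            if reps - reps_with_ref:
                raise FormatError(
                    f"genotype '{genotype}' replicates {sorted(reps - reps_with_ref)} "
                    "lack a reference-gene Ct"
                )
        self.table = df.reset_index(drop=True)


GeneLengths = pd.Series  # gene id -> effective length in bp


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def read_counts(path: str | Path, format: str = "tsv") -> CountMatrix:
    """Read a count matrix from TSV (gene rows, sample header) or MTX.

    MTX input expects ``<path>`` plus sidecars ``<stem>.rownames`` and
    ``<stem>.colnames`` (one identifier per line, file order preserved).
    """
    path = Path(path)
    if format == "tsv":
        df = _read_tsv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        for col in df.columns:
            if not np.issubdtype(df[col].dtype, np.number):
                bad = df[~df[col].astype(str).str.fullmatch(r"-?\d+")]
                gene = bad.index[0] if len(bad) else "?"
                raise FormatError(
                    f"non-integer count at gene '{gene}', sample '{col}' in {path}"
                )
        return CountMatrix(df)
    if format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        stem = path.with_suffix("")
        genes = Path(f"{stem}.rownames").read_text().split()
        samples = Path(f"{stem}.colnames").read_text().split()
        if len(genes) != mat.shape[0] or len(samples) != mat.shape[1]:
            raise FormatError(
                f"MTX dimensions {mat.shape} do not match sidecar name files "
                f"({len(genes)} rows, {len(samples)} cols)"
            )
        return CountMatrix(pd.DataFrame(mat, index=genes, columns=samples))
    raise ValueError(f"unknown count-matrix format: {format!r}")


def write_counts(cm: CountMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        cm.counts.to_csv(path, sep="\t", index_label="gene")
    elif format == "mtx":
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.counts.to_numpy()))
        stem = path.with_suffix("")
        Path(f"{stem}.rownames").write_text("\n".join(cm.genes) + "\n")
        Path(f"{stem}.colnames").write_text("\n".join(cm.samples) + "\n")
    else:
        raise ValueError(f"unknown count-matrix format: {format!r}")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = _read_tsv(path, dtype=str)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_gene_lengths(path: str | Path) -> GeneLengths:
    df = _read_tsv(path, header=None, names=["gene", "length"], dtype={0: str})
    lengths = pd.Series(df["length"].to_numpy(float), index=df["gene"], name="length")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise FormatError(f"non-positive gene length for '{bad}'")
    return lengths


def read_annotation(path: str | Path) -> AnnotationMap:
    """Two-column TSV: gene <TAB> term (one pair per line)."""
    df = _read_tsv(path, header=None, names=["gene", "term"], dtype=str)
    if df.isna().any().any():
        raise FormatError(f"annotation file {path} has incomplete rows")
    mapping: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        mapping.setdefault(term, set()).add(gene)
    return AnnotationMap(mapping)


def write_annotation(annot: AnnotationMap, path: str | Path) -> None:
    rows = [
        (gene, term)
        for term in annot.terms
        for gene in sorted(annot.term_to_genes[term])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = _read_tsv(path)
    df["timepoint"] = df["timepoint"].astype(int)
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.table.to_csv(path, sep="\t", index=False)


def read_ct(path: str | Path) -> CtTable:
    df = _read_tsv(path)
    return CtTable(df)


def write_ct(ct: CtTable, path: str | Path) -> None:
    ct.table.to_csv(path, sep="\t", index=False)


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"run config {path} must be a YAML mapping")
    return cfg
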