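"""Reading, validation and writing of the tabular inputs.

All inputs are plain TSV (tab-separated, UTF-8, header row, ``NA`` for
missing), the dialect used by GDC / cBioPortal exports:

* count matrix       -- genes x samples, non-negative integers
* copy-number matrix -- genes x samples, GISTIC-style integer calls in
  {-2, -1, 0, 1, 2} (2 = high-level amplification, -2 = deep deletion)
* clinical table     -- one row per sample (stage, receptor status,
  morphology, intrinsic-subtype label, survival)
* gene annotation    -- gene id, symbol, transcript length (bp), family tag
* mutation table     -- gene id -> mutation count

Sample role (tumor vs. normal reference) is supplied through an explicit
role map rather than a column-name convention, because the reference panel
is a separate population from the cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAMILY_TAGS = ("OR", "oncotypedx", "pam50", "other")
CNA_CALLS = (-2, -1, 0, 1, 2)
STAGES = ("i", "ii", "iii", "iv")
RECEPTOR = ("pos", "neg")
MORPHOLOGY = ("IDC", "ILC", "mixed", "other")
SUBTYPES = ("LumA", "LumB", "Her2", "Basal", "Normal")

CLINICAL_COLUMNS = (
    "stage",
    "er_status",
    "her2_status",
    "tnbc",
    "morphology",
    "subtype_label",
    "survival_months",
    "event",
)


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


@dataclass
class CountMatrix:
    """Raw read counts, genes x samples, plus per-sample roles."""

    counts: pd.DataFrame
    roles: pd.Series  # sample -> "tumor" | "reference"

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.roles.index[self.roles == "tumor"])

    @property
    def reference_samples(self) -> list[str]:
        return list(self.roles.index[self.roles == "reference"])


@dataclass
class CohortBundle:
    """The validated inputs of one screening run."""

    counts: CountMatrix
    cna: pd.DataFrame
    clinical: pd.DataFrame
    annotation: pd.DataFrame
    mutations: pd.Series
    dropped_genes: list[str] = field(default_factory=list)


def _read_tsv_matrix(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pandas raises several parser errors
        raise ValidationError(f"malformed TSV for {what} at {path}: {exc}") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids in {what}: {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids in {what}: {dups}")
    return df


def _to_numeric(df: pd.DataFrame, what: str, integer: bool) -> pd.DataFrame:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        line = int(np.flatnonzero(bad.any(axis=1))[0]) + 2  # header is line 1
        raise ValidationError(
            f"non-numeric entry in {what} at gene {gene!r} (line {line})"
        )
    if numeric.isna().any().any():
        gene = numeric.isna().any(axis=1).idxmax()
        raise ValidationError(f"missing value in {what} at gene {gene!r}")
    if integer:
        arr = numeric.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError(f"non-integer entry in {what}")
        numeric = numeric.round().astype(np.int64)
    return numeric


def read_count_matrix(
    path: str | Path, role_map: Mapping[str, str] | pd.Series
) -> CountMatrix:
    """Read a genes x samples raw-count TSV and attach sample roles.

    ``role_map`` maps every sample id to ``"tumor"`` or ``"reference"``.
    Negative counts, duplicate ids and unknown samples are rejected.
    """
    df = _to_numeric(_read_tsv_matrix(path, "count matrix"), "count matrix", True)
    if (df.to_numpy() < 0).any():
        gene = df.index[(df < 0).any(axis=1)][0]
        raise ValidationError(f"negative count at gene {gene!r}")
    roles = pd.Series(dict(role_map), dtype=object)
    unknown = set(roles.index) - set(df.columns)
    if unknown:
        raise ValidationError(f"role map names unknown samples: {sorted(unknown)}")
    missing = set(df.columns) - set(roles.index)
    if missing:
        raise ValidationError(f"samples without a role: {sorted(missing)}")
    bad_roles = set(roles.unique()) - {"tumor", "reference"}
    if bad_roles:
        raise ValidationError(f"unknown roles {sorted(bad_roles)}")
    roles = roles.reindex(df.columns)
    return CountMatrix(counts=df, roles=roles)


def read_cna_matrix(path: str | Path) -> pd.DataFrame:
    """Read a GISTIC-style integer call matrix; every entry must be in -2..2."""
    df = _to_numeric(_read_tsv_matrix(path, "CNA matrix"), "CNA matrix", True)
    bad = ~df.isin(CNA_CALLS)
    if bad.any().any():
        gene = df.index[bad.any(axis=1)][0]
        value = df.loc[gene][bad.loc[gene]].iloc[0]
        raise ValidationError(
            f"CNA call {value} at gene {gene!r} outside {{-2,-1,0,1,2}}"
        )
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation table (gene_id, symbol, length_bp, family)."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    required = {"gene_id", "symbol", "length_bp", "family"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"annotation missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in annotation")
    df = df.set_index("gene_id")
    df["length_bp"] = pd.to_numeric(df["length_bp"], errors="raise").astype(np.int64)
    if (df["length_bp"] < 1).any():
        bad = df.index[df["length_bp"] < 1][0]
        raise ValidationError(f"length_bp < 1 for gene {bad!r}")
    unknown = ~df["family"].isin(FAMILY_TAGS)
    if unknown.any():
        logger.warning(
            "annotation: %d unknown family tags mapped to 'other'", unknown.sum()
        )
        df.loc[unknown, "family"] = "other"
    return df


def _normalize_enum(series: pd.Series, allowed: tuple, name: str) -> pd.Series:
    out = series.where(series.isin(allowed))
    n_bad = (series.notna() & out.isna()).sum()
    if n_bad:
        logger.warning("clinical: %d unknown %s tokens mapped to NA", n_bad, name)
    return out


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical table.

    Unknown enum tokens are mapped to NA with a logged warning; a survival
    time requires an event flag.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise ValidationError("clinical table missing 'sample_id' column")
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"clinical table missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in clinical table")
    df = df.set_index("sample_id")
    df["stage"] = _normalize_enum(df["stage"], STAGES, "stage")
    df["er_status"] = _normalize_enum(df["er_status"], RECEPTOR, "er_status")
    df["her2_status"] = _normalize_enum(df["her2_status"], RECEPTOR, "her2_status")
    df["morphology"] = _normalize_enum(df["morphology"], MORPHOLOGY, "morphology")
    df["subtype_label"] = _normalize_enum(df["subtype_label"], SUBTYPES, "subtype")
    df["tnbc"] = df["tnbc"].map({"1": True, "0": False, "True": True, "False": False})
    df["survival_months"] = pd.to_numeric(df["survival_months"], errors="coerce")
    if (df["survival_months"].dropna() < 0).any():
        raise ValidationError("negative survival_months")
    df["event"] = pd.to_numeric(df["event"], errors="coerce")
    has_time = df["survival_months"].notna()
    if (has_time & df["event"].isna()).any():
        raise ValidationError("survival_months present without event flag")
    return df


def read_mutations(path: str | Path) -> pd.Series:
    """Read the gene -> mutation-count table."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    if not {"gene_id", "n_mutations"} <= set(df.columns):
        raise ValidationError("mutation table needs columns gene_id, n_mutations")
    if df["gene_id"].duplicated().any():
        raise ValidationError("duplicate gene_id in mutation table")
    counts = pd.to_numeric(df.set_index("gene_id")["n_mutations"], errors="raise")
    if (counts < 0).any():
        raise ValidationError("negative mutation count")
    return counts.astype(np.int64)


def align_genes(
    counts: CountMatrix, annotation: pd.DataFrame
) -> tuple[CountMatrix, list[str]]:
    """Restrict the count matrix to annotated genes.

    Genes present in counts but absent from annotation have no transcript
    length, so FPKM is undefined for them; they are dropped with a warning
    and reported for querying.
    """
    keep = counts.counts.index.intersection(annotation.index)
    dropped = sorted(set(counts.counts.index) - set(keep))
    if dropped:
        logger.warning("dropping %d genes without annotation", len(dropped))
    return CountMatrix(counts.counts.loc[keep], counts.roles), dropped


# ---------------------------------------------------------------------------
# Writers (canonical dialect; write(read(f)) is byte-identical)
# ---------------------------------------------------------------------------


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(Path(path), sep="\t", index_label="gene_id")


def write_roles(cm: CountMatrix, path: str | Path) -> None:
    cm.roles.rename("role").to_csv(Path(path), sep="\t", index_label="sample_id")


def write_cna_matrix(cna: pd.DataFrame, path: str | Path) -> None:
    cna.to_csv(Path(path), sep="\t", index_label="gene_id")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(Path(path), sep="\t", index_label="gene_id", na_rep="NA")


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    out = clinical.copy()
    out["tnbc"] = out["tnbc"].map({True: "1", False: "0"})
    out["event"] = out["event"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(Path(path), sep="\t", index_label="sample_id", na_rep="NA")


def write_mutations(mutations: pd.Series, path: str | Path) -> None:
    mutations.rename("n_mutations").to_csv(
        Path(path), sep="\t", index_label="gene_id"
    )


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> None:
    """Write a validated bundle as the canonical TSV file set."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_matrix(bundle.counts, out / "counts.tsv")
    write_roles(bundle.counts, out / "roles.tsv")
    write_cna_matrix(bundle.cna, out / "cna.tsv")
    write_clinical(bundle.clinical, out / "clinical.tsv")
    write_annotation(bundle.annotation, out / "annotation.tsv")
    write_mutations(bundle.mutations, out / "mutations.tsv")


def read_bundle(in_dir: str | Path) -> CohortBundle:
    """Read a bundle directory written by :func:`write_bundle`."""
    d = Path(in_dir)
    roles = pd.read_csv(d / "roles.tsv", sep="\t", index_col=0)["role"]
    counts = read_count_matrix(d / "counts.tsv", roles)
    return CohortBundle(
        counts=counts,
        cna=read_cna_matrix(d / "cna.tsv"),
        clinical=read_clinical(d / "clinical.tsv"),
        annotation=read_annotation(d / "annotation.tsv"),
        mutations=read_mutations(d / "mutations.tsv"),
    )
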