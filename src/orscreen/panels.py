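"""Breast-cancer panel-gene comparisons across sub-populations.

Ships the canonical 21-gene Oncotype DX and 50-gene PAM50 symbol lists
(overridable).  Panel genes are compared across sub-populations by one-way
ANOVA, by default on z-scores so genes are on a common scale.  No
recurrence-score or intrinsic-subtype calling is performed — panels are
used purely as gene lists.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .stratify import SubpopulationAssignment, _anova_guarded

logger = logging.getLogger(__name__)

# 16 cancer-related + 5 reference genes of the Oncotype DX assay
ONCOTYPE_DX_GENES = (
    "MKI67", "AURKA", "BIRC5", "CCNB1", "MYBL2",          # proliferation
    "MMP11", "CTSV",                                       # invasion
    "GRB7", "ERBB2",                                       # HER2 group
    "ESR1", "PGR", "BCL2", "SCUBE2",                       # estrogen group
    "GSTM1", "BAG1", "CD68",                               # other
    "ACTB", "GAPDH", "RPLP0", "GUSB", "TFRC",              # reference
)

PAM50_GENES = (
    "ACTR3B", "ANLN", "BAG1", "BCL2", "BIRC5", "BLVRA", "CCNB1", "CCNE1",
    "CDC20", "CDC6", "CDH3", "CENPF", "CEP55", "CXXC5", "EGFR", "ERBB2",
    "ESR1", "EXO1", "FGFR4", "FOXA1", "FOXC1", "GPR160", "GRB7", "KIF2C",
    "KRT14", "KRT17", "KRT5", "MAPT", "MDM2", "MELK", "MIA", "MKI67",
    "MLPH", "MMP11", "MYBL2", "MYC", "NAT1", "NDC80", "NUF2", "ORC6",
    "PGR", "PHGDH", "PTTG1", "RRM2", "SFRP1", "SLC39A6", "TMEM45B", "TYMS",
    "UBE2C", "UBE2T",
)

PANELS = {"oncotypedx": ONCOTYPE_DX_GENES, "pam50": PAM50_GENES}


class PanelError(ValueError):
    pass


def panel_genes(
    annotation: pd.DataFrame, panel: str, symbols: tuple[str, ...] | None = None
) -> list[str]:
    """Gene ids of a panel: family-tag matches plus packaged symbol list.

    The annotation's single family tag cannot represent genes shared
    between panels (11 genes sit in both), so membership is the union of
    the tag and the symbol list.
    """
    if symbols is None:
        if panel not in PANELS:
            raise PanelError(f"unknown panel {panel!r}; choose from {sorted(PANELS)}")
        symbols = PANELS[panel]
    tagged = annotation.index[annotation["family"] == panel]
    by_symbol = annotation.index[annotation["symbol"].isin(symbols)]
    return sorted(set(tagged) | set(by_symbol))


def panel_compare(
    values: pd.DataFrame,
    subpops: SubpopulationAssignment,
    genes: list[str],
    alpha: float = 0.05,
    correction: str | None = None,
) -> pd.DataFrame:
    """One-way ANOVA per panel gene across sub-populations.

    ``values`` is genes x samples (z-scores or log2 FPKM).  A
    sub-population with fewer than 2 samples skips the test with a
    warning (F and p are NaN).  ``correction="bh"`` applies
    Benjamini-Hochberg across panel genes (off by default, matching
    per-gene reporting).
    """
    labels = subpops.labels
    sp_names = sorted(labels.unique())
    if len(sp_names) < 2:
        raise PanelError("need >= 2 sub-populations")
    groups_idx = {sp: labels.index[labels == sp] for sp in sp_names}
    small = [sp for sp, idx in groups_idx.items() if len(idx) < 2]
    testable = not small
    if small:
        logger.warning("sub-populations %s have < 2 samples; tests skipped", small)
    rows = []
    present = [g for g in genes if g in values.index]
    for gene in present:
        row: dict = {"gene": gene}
        vecs = []
        for sp in sp_names:
            v = values.loc[gene, groups_idx[sp]].to_numpy(float)
            row[f"mean_{sp}"] = v.mean() if len(v) else np.nan
            vecs.append(v)
        if testable:
            f, p = _anova_guarded(vecs)
        else:
            f, p = np.nan, np.nan
        row["F"] = f
        row["p"] = p
        rows.append(row)
    out = pd.DataFrame(rows).set_index("gene")
    if correction == "bh" and out["p"].notna().any():
        mask = out["p"].notna()
        out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
        out["significant"] = out.get("p_adj", out["p"]) <= alpha
    else:
        out["significant"] = out["p"] <= alpha
    out["significant"] = out["significant"].fillna(False).astype(bool)
    return out


def phenotype_composition(
    labels: pd.Series, clinical: pd.DataFrame
) -> pd.DataFrame:
    """TNBC / HER2 / ER / NA percentages per group (each row sums to 100).

    Classification priority mirrors the clinical convention: TNBC first,
    then HER2-positive, then ER-positive, otherwise NA.
    """
    clin = clinical.reindex(labels.index)

    def classify(row) -> str:
        if row["tnbc"] is True:
            return "TNBC"
        if row["her2_status"] == "pos":
            return "HER2"
        if row["er_status"] == "pos":
            return "ER"
        return "NA"

    phen = clin.apply(classify, axis=1)
    tab = pd.crosstab(labels.rename("group"), phen.rename("phenotype"))
    for col in ("TNBC", "HER2", "ER", "NA"):
        if col not in tab.columns:
            tab[col] = 0
    tab = tab[["TNBC", "HER2", "ER", "NA"]]
    return tab.div(tab.sum(axis=1), axis=0) * 100.0
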