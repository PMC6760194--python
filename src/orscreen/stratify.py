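"""Hierarchical stratification of over-expressed genes and positive cases.

Clustering follows the analysis convention for this screen: Euclidean
distance, Ward linkage, tree cut at k clusters.  Input rows/columns are
sorted lexicographically before linkage so results are invariant to input
order; cluster labels are assigned deterministically.

`cluster_cases` also supports an ``argmax`` mode that assigns each case to
the over-expressed gene with its maximal z-score — the two readings of
"supervised clustering" differ only in how boundary cases are split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import f_oneway

logger = logging.getLogger(__name__)


class StratifyError(ValueError):
    pass


@dataclass
class GeneGroupAssignment:
    labels: pd.Series  # gene -> "Group1".."Groupk"
    k: int
    linkage: np.ndarray
    order: list[str]  # dendrogram leaf order


@dataclass
class SubpopulationAssignment:
    labels: pd.Series  # case -> "I".."k" (roman)
    k: int
    defining_gene: dict[str, str]  # sub-population -> gene id
    defining_stats: pd.DataFrame  # per defining gene: F statistic, p value
    linkage: np.ndarray | None
    order: list[str]


_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


def _ward_cut(mat: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    link = hierarchy.linkage(mat, method="ward", metric="euclidean")
    flat = hierarchy.fcluster(link, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(link)
    return link, flat, order


def cluster_genes(values: pd.DataFrame, k: int = 3) -> GeneGroupAssignment:
    """Cluster genes by their abundance profiles across tumors.

    ``values`` is genes x samples (z-scores by default upstream, so gene
    scales are comparable).  Genes are sorted lexicographically first;
    groups are numbered by their lexicographically smallest member.
    """
    if k < 1:
        raise StratifyError("k must be >= 1")
    if k > len(values):
        raise StratifyError(f"k={k} exceeds number of genes ({len(values)})")
    values = values.sort_index()
    if k == 1:
        labels = pd.Series("Group1", index=values.index)
        return GeneGroupAssignment(labels, 1, np.empty((0, 4)), list(values.index))
    link, flat, order = _ward_cut(values.to_numpy(float), k)
    labels = _canonical_labels(values.index, flat, prefix="Group")
    return GeneGroupAssignment(labels, k, link, list(values.index[order]))


def _canonical_labels(index: pd.Index, flat: np.ndarray, prefix: str) -> pd.Series:
    """Relabel clusters by their lexicographically smallest member."""
    firsts = {}
    for cid in np.unique(flat):
        firsts[cid] = index[flat == cid].min()
    ordered = sorted(firsts, key=lambda c: firsts[c])
    if prefix == "roman":
        names = {cid: _ROMAN[i] for i, cid in enumerate(ordered)}
    else:
        names = {cid: f"{prefix}{i + 1}" for i, cid in enumerate(ordered)}
    return pd.Series([names[c] for c in flat], index=index)


def cluster_cases(
    z: pd.DataFrame,
    cases: list[str] | None = None,
    k: int = 3,
    mode: str = "tree",
) -> SubpopulationAssignment:
    """Stratify positive cases into sub-populations over the gene panel.

    ``z`` is genes x samples (restricted upstream to the over-expressed
    panel); ``cases`` restricts the columns (typically the cases flagged
    positive by the screen).  Each sub-population's defining gene maximizes
    the within-cluster minus out-of-cluster mean z contrast; defining genes
    are tested across sub-populations by one-way ANOVA.  Sub-populations
    are numbered I..k by their defining gene (lexicographic), mirroring the
    convention that each sub-population is named for one dominant gene.
    """
    if mode not in ("tree", "argmax"):
        raise StratifyError("mode must be 'tree' or 'argmax'")
    sub = z[cases] if cases is not None else z
    sub = sub.sort_index().sort_index(axis=1)
    n_cases = sub.shape[1]
    if k < 1:
        raise StratifyError("k must be >= 1")
    if k > n_cases:
        raise StratifyError(f"k={k} exceeds number of cases ({n_cases})")
    mat = sub.to_numpy(float).T  # cases x genes
    link = None
    order = list(sub.columns)
    if k == 1:
        flat = np.ones(n_cases, dtype=int)
    elif mode == "tree":
        if np.allclose(mat, mat[0]):
            logger.warning("all case vectors identical; split is arbitrary")
        link, flat, leaf = _ward_cut(mat, k)
        order = list(sub.columns[leaf])
    else:
        top = np.argsort(-mat, axis=1)[:, 0]
        top_genes = sub.index.to_numpy()[top]
        uniq = pd.unique(np.sort(top_genes))
        if len(uniq) < k:
            raise StratifyError(
                f"argmax mode yields {len(uniq)} groups, fewer than k={k}"
            )
        keep = list(uniq[:k])
        flat = np.array(
            [keep.index(g) + 1 if g in keep else 1 for g in top_genes], dtype=int
        )

    # defining gene per cluster: greatest in-cluster vs out-of-cluster contrast
    defining: dict[int, str] = {}
    for cid in np.unique(flat):
        inside = mat[flat == cid].mean(axis=0)
        if (flat != cid).any():
            outside = mat[flat != cid].mean(axis=0)
        else:
            outside = np.zeros_like(inside)
        contrast = inside - outside
        defining[cid] = sub.index[int(np.argmax(contrast))]

    ordered = sorted(np.unique(flat), key=lambda c: defining[c])
    names = {cid: _ROMAN[i] for i, cid in enumerate(ordered)}
    labels = pd.Series([names[c] for c in flat], index=sub.columns)

    def_gene = {names[c]: defining[c] for c in ordered}
    rows = []
    for sp, gene in def_gene.items():
        groups = [
            sub.loc[gene, labels.index[labels == name]].to_numpy()
            for name in names.values()
        ]
        if len(groups) > 1 and all(len(g) > 1 for g in groups):
            f, p = _anova_guarded(groups)
        else:
            f, p = np.nan, np.nan
        rows.append({"subpopulation": sp, "gene": gene, "F": f, "p": p})
    stats = pd.DataFrame(rows).set_index("subpopulation")
    return SubpopulationAssignment(labels, k, def_gene, stats, link, order)


def _anova_guarded(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA with a zero-within-variance guard (F -> inf, p -> 0)."""
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    means = np.array([g.mean() for g in groups])
    if within == 0:
        if np.allclose(means, means[0]):
            return 0.0, 1.0
        return np.inf, 0.0
    with np.errstate(invalid="ignore"):
        f, p = f_oneway(*groups)
    return float(f), float(p)


def group_summaries(
    assignment: GeneGroupAssignment, burden: pd.DataFrame
) -> pd.DataFrame:
    """Per-group mean n_upreg / sum_upreg with one-way ANOVA across groups."""
    labels = assignment.labels
    if labels.empty:
        raise StratifyError("empty group assignment")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise StratifyError("need >= 2 groups for a between-group comparison")
    rows = []
    for stat in ("n_upreg", "sum_upreg"):
        vals = [burden.loc[labels.index[labels == g], stat].to_numpy(float) for g in groups]
        if any(len(v) < 1 for v in vals):
            raise StratifyError("every group needs >= 1 member")
        f, p = _anova_guarded(vals)
        row = {"statistic": stat, "F": f, "p": p}
        row.update({g: v.mean() for g, v in zip(groups, vals)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("statistic")


def composition_tables(
    subpops: SubpopulationAssignment,
    clinical: pd.DataFrame,
    variables: tuple[str, ...] = ("stage", "er_status", "her2_status", "tnbc", "morphology", "subtype_label"),
) -> dict[str, pd.DataFrame]:
    """Counts and within-sub-population percentages per clinical variable.

    The NA category is retained; each table's row sums equal the
    sub-population sizes.
    """
    labels = subpops.labels
    clin = clinical.reindex(labels.index)
    out = {}
    for var in variables:
        col = clin[var]
        if col.dtype == object or col.dtype == bool:
            col = col.astype(object)
        col = col.where(col.notna(), "NA")
        tab = pd.crosstab(labels, col)
        tab.index.name = "subpopulation"
        pct = tab.div(tab.sum(axis=1), axis=0) * 100.0
        out[var] = pd.concat({"count": tab, "percent": pct}, axis=1)
    return out


def ordered_matrix(
    values: pd.DataFrame,
    genes: GeneGroupAssignment | None = None,
    subpops: SubpopulationAssignment | None = None,
) -> pd.DataFrame:
    """Heatmap-ready matrix: genes in dendrogram order, cases by sub-population."""
    rows = genes.order if genes is not None else list(values.index)
    cols = subpops.order if subpops is not None else list(values.columns)
    cols = [c for c in cols if c in values.columns]
    return values.loc[rows, cols]
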