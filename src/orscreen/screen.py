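"""The over-expression screen: z-scores, burden statistics, thresholds, funnel.

For gene *i* and tumor *j*, the z-score anchors log2 expression to a small
normal-tissue reference panel:

    Z_ij = (X_ij - Xbar_i) / sigma_i

with Xbar_i and sigma_i the mean and (n-1)-denominator SD over the
reference samples.  Over the cohort of m patients showing any family-gene
upregulation (Z >= z_cut for at least one screened family gene), each gene
accumulates three burden statistics:

    sum_upreg_i      = sum_j Z_ij                 (all cohort z-scores)
    n_upreg_i        = #{ j : Z_ij >= z_cut }     (indicator, boundary counts)
    weighted_upreg_i = n_upreg_i * sum_upreg_i

A statistic's significance threshold is the one-sided upper 95% point of
its distribution across the whole gene family, mean + z_{1-alpha} * SD.
The two-part selection keeps genes whose (sum, weighted) and
(count, weighted) statistics both exceed their thresholds; the final
over-expressed set additionally requires a high-level amplification call
(GISTIC 2) in at least one tumor.

Genes whose reference SD falls below ``min_ref_sd`` are unscreenable: with
a 4-sample panel, library-normalization jitter on genes with identical
reference counts would otherwise masquerade as variance and blow up the
z-scores.  Unscreenable family genes still enter the threshold
distribution, as zero-burden rows (no detected upregulation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import ExpressionMatrix

logger = logging.getLogger(__name__)

SUM_MODES = ("all", "positive", "above_cut")


class ScreenError(ValueError):
    pass


@dataclass
class ReferenceStats:
    """Per-gene mean/SD over the normal reference panel."""

    mean: pd.Series
    sd: pd.Series
    n_ref: int
    min_ref_sd: float

    @property
    def screenable(self) -> pd.Series:
        return self.sd > self.min_ref_sd

    @property
    def unscreenable_genes(self) -> list[str]:
        return list(self.sd.index[~self.screenable])


@dataclass
class ZScoreMatrix:
    """Genes x tumor samples deviation from the reference mean in SD units."""

    values: pd.DataFrame
    z_cut: float = 2.0


@dataclass
class SignificanceThresholds:
    sum_threshold: float
    count_threshold: float
    weighted_threshold: float
    alpha: float
    method: str = "one-sided normal upper tail, mean + z(1-alpha)*SD over family"


@dataclass
class ScreenResult:
    """The nested gene sets of the selection funnel, plus per-case flags."""

    part1_genes: set[str]
    part2_genes: set[str]
    shared_genes: set[str]
    amplified_genes: set[str]
    overexpressed_genes: set[str]
    direction: str
    burden: pd.DataFrame
    thresholds: SignificanceThresholds
    zscores: ZScoreMatrix
    cohort_samples: list[str]
    has_overexpressed_upreg: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    unscreenable_genes: list[str] = field(default_factory=list)

    @property
    def positive_cases(self) -> list[str]:
        return list(self.has_overexpressed_upreg.index[self.has_overexpressed_upreg])


def reference_stats(
    expr: ExpressionMatrix,
    reference_ids: list[str] | None = None,
    min_ref_sd: float = 0.01,
) -> ReferenceStats:
    """Mean and sample SD per gene over the reference columns only."""
    if expr.stage != "log2fpkm":
        raise ScreenError(f"reference_stats expects log2fpkm, got {expr.stage!r}")
    ref_ids = reference_ids if reference_ids is not None else expr.reference_samples
    if len(ref_ids) < 2:
        raise ScreenError(f"need >= 2 reference samples, got {len(ref_ids)}")
    ref = expr.values[list(ref_ids)]
    stats = ReferenceStats(
        mean=ref.mean(axis=1),
        sd=ref.std(axis=1, ddof=1),
        n_ref=len(ref_ids),
        min_ref_sd=min_ref_sd,
    )
    n_unscr = (~stats.screenable).sum()
    if n_unscr:
        logger.info("%d genes unscreenable (reference SD <= %g)", n_unscr, min_ref_sd)
    return stats


def zscores(
    expr: ExpressionMatrix,
    ref: ReferenceStats,
    genes: list[str] | None = None,
    z_cut: float = 2.0,
) -> ZScoreMatrix:
    """Z_ij = (X_ij - Xbar_i) / sigma_i over tumor samples.

    Requesting a gene whose reference SD is degenerate is an error; by
    default all screenable genes of ``expr`` are scored.
    """
    tumors = expr.tumor_samples
    if genes is None:
        genes = list(expr.values.index[ref.screenable.reindex(expr.values.index, fill_value=False)])
    else:
        bad = [g for g in genes if not bool(ref.screenable.get(g, False))]
        if bad:
            raise ScreenError(f"unscreenable genes requested: {bad[:5]}")
    x = expr.values.loc[genes, tumors]
    z = x.sub(ref.mean.loc[genes], axis=0).div(ref.sd.loc[genes], axis=0)
    return ZScoreMatrix(values=z, z_cut=z_cut)


def burden_stats(
    z: ZScoreMatrix,
    z_cut: float | None = None,
    sum_mode: str = "all",
    population_size: int | None = None,
) -> pd.DataFrame:
    """Per-gene burden statistics over the upregulated cohort.

    The cohort comprises the m tumors with Z >= z_cut for at least one
    screened gene; ``sum_mode`` controls which z-scores enter the sum
    ('all' by default — the literal reading of the defining sum; 'positive'
    and 'above_cut' restrict it).  ``prevalence`` divides the upregulated
    case count by the full study population (defaults to all tumors).
    """
    if sum_mode not in SUM_MODES:
        raise ScreenError(f"sum_mode must be one of {SUM_MODES}")
    cut = z.z_cut if z_cut is None else z_cut
    zv = z.values
    up = zv >= cut
    cohort = zv.columns[up.any(axis=0)]
    if len(cohort) == 0:
        raise ScreenError("empty cohort: no tumor has any gene above z_cut")
    zc = zv[cohort]
    if sum_mode == "all":
        s = zc.sum(axis=1)
    elif sum_mode == "positive":
        s = zc.clip(lower=0).sum(axis=1)
    else:  # above_cut
        s = zc.where(zc >= cut, 0.0).sum(axis=1)
    n = (zc >= cut).sum(axis=1)
    pop = population_size if population_size is not None else zv.shape[1]
    out = pd.DataFrame(
        {
            "sum_upreg": s,
            "n_upreg": n.astype(np.int64),
            "weighted_upreg": n * s,
            "prevalence": n / pop,
        }
    )
    out.attrs["m"] = len(cohort)
    out.attrs["cohort"] = list(cohort)
    out.attrs["population_size"] = pop
    out.attrs["z_cut"] = cut
    out.attrs["sum_mode"] = sum_mode
    return out


def _upper_tail_threshold(values: np.ndarray, alpha: float) -> float:
    zmult = sps.norm.ppf(1.0 - alpha)
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    if sd == 0.0:
        logger.warning("degenerate statistic distribution; threshold equals its value")
        return float(values.mean())
    return float(values.mean() + zmult * sd)


def significance_thresholds(
    burden: pd.DataFrame,
    alpha: float = 0.05,
    n_family: int | None = None,
) -> SignificanceThresholds:
    """Upper-tail thresholds over the family-wide statistic distributions.

    threshold = mean + z_(1-alpha) * SD across family genes (z_0.95 = 1.6449).
    ``n_family`` pads the distribution with zero-burden rows for family
    genes that were unscreenable, so the thresholds always refer to the
    whole gene family.
    """
    if len(burden) < 3:
        raise ScreenError("need >= 3 genes with finite statistics")
    if not 0.0 < alpha < 1.0:
        raise ScreenError("alpha must be in (0, 1)")
    pad = 0 if n_family is None else max(0, n_family - len(burden))

    def padded(col: str) -> np.ndarray:
        v = burden[col].to_numpy(dtype=float)
        return np.concatenate([v, np.zeros(pad)]) if pad else v

    return SignificanceThresholds(
        sum_threshold=_upper_tail_threshold(padded("sum_upreg"), alpha),
        count_threshold=_upper_tail_threshold(padded("n_upreg"), alpha),
        weighted_threshold=_upper_tail_threshold(padded("weighted_upreg"), alpha),
        alpha=alpha,
    )


def select_two_part(
    burden: pd.DataFrame, thr: SignificanceThresholds
) -> tuple[set[str], set[str], set[str]]:
    """Part 1: sum AND weighted exceed; part 2: count AND weighted exceed."""
    w_ok = burden["weighted_upreg"] > thr.weighted_threshold
    part1 = set(burden.index[(burden["sum_upreg"] > thr.sum_threshold) & w_ok])
    part2 = set(burden.index[(burden["n_upreg"] > thr.count_threshold) & w_ok])
    return part1, part2, part1 & part2


def high_amplification_genes(
    cna: pd.DataFrame, samples: list[str] | None = None
) -> set[str]:
    """Genes carrying a GISTIC call of 2 in at least one (tumor) sample."""
    sub = cna[samples] if samples is not None else cna
    return set(sub.index[(sub == 2).any(axis=1)])


def overexpressed_set(shared: set[str], amplified: set[str]) -> set[str]:
    return shared & amplified


def mutation_overlap(result: ScreenResult, mutations: pd.Series) -> set[str]:
    """Over-expressed genes that also carry somatic mutations."""
    mutated = set(mutations.index[mutations > 0])
    return result.overexpressed_genes & mutated


def prevalence_summary(
    burden: pd.DataFrame, bins: tuple[float, ...] = (0.05, 0.10, 0.12)
) -> pd.Series:
    """Histogram of genes per prevalence bin (default edges 5%, 10%, 12%)."""
    edges = [0.0, *bins, 1.0000001]
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    cat = pd.cut(burden["prevalence"], bins=edges, right=False, labels=labels)
    return cat.value_counts().reindex(labels, fill_value=0)


def run_screen(
    expr: ExpressionMatrix,
    cna: pd.DataFrame,
    family_genes: list[str],
    reference_ids: list[str] | None = None,
    z_cut: float = 2.0,
    alpha: float = 0.05,
    sum_mode: str = "all",
    direction: str = "up",
    min_ref_sd: float = 0.01,
    population_size: int | None = None,
) -> ScreenResult:
    """Run the full selection funnel over one gene family.

    ``direction="down"`` mirrors the screen on negated z-scores (indicator
    Z <= -z_cut, magnitudes of the down-sums thresholded), reusing the same
    machinery.
    """
    if direction not in ("up", "down"):
        raise ScreenError("direction must be 'up' or 'down'")
    family = [g for g in family_genes if g in expr.values.index]
    ref = reference_stats(expr, reference_ids, min_ref_sd=min_ref_sd)
    screenable = [g for g in family if bool(ref.screenable.get(g, False))]
    unscreenable = sorted(set(family) - set(screenable))
    if len(screenable) < 3:
        raise ScreenError("fewer than 3 screenable family genes")
    z = zscores(expr, ref, genes=screenable, z_cut=z_cut)
    if direction == "down":
        z = ZScoreMatrix(values=-z.values, z_cut=z_cut)
    try:
        burden = burden_stats(z, sum_mode=sum_mode, population_size=population_size)
    except ScreenError:
        # no tumor above the cutoff anywhere: an entirely negative screen
        logger.info("no tumor exceeds z_cut for any gene; empty screen result")
        pop = population_size if population_size is not None else z.values.shape[1]
        burden = pd.DataFrame(
            {
                "sum_upreg": 0.0,
                "n_upreg": np.zeros(len(screenable), dtype=np.int64),
                "weighted_upreg": 0.0,
                "prevalence": 0.0,
            },
            index=pd.Index(screenable),
        )
        burden.attrs.update(
            m=0, cohort=[], population_size=pop, z_cut=z.z_cut, sum_mode=sum_mode
        )
    thr = significance_thresholds(burden, alpha=alpha, n_family=len(family))
    part1, part2, shared = select_two_part(burden, thr)
    amplified = high_amplification_genes(cna) & set(family)
    over = overexpressed_set(shared, amplified)
    flag = (z.values.loc[sorted(over)] >= z.z_cut).any(axis=0) if over else pd.Series(
        False, index=z.values.columns
    )
    return ScreenResult(
        part1_genes=part1,
        part2_genes=part2,
        shared_genes=shared,
        amplified_genes=amplified,
        overexpressed_genes=over,
        direction=direction,
        burden=burden,
        thresholds=thr,
        zscores=z,
        cohort_samples=burden.attrs["cohort"],
        has_overexpressed_upreg=flag,
        unscreenable_genes=unscreenable,
    )


def screen_diagnostics(
    expr: ExpressionMatrix,
    cna: pd.DataFrame,
    family_genes: list[str],
    **kwargs,
) -> pd.DataFrame:
    """Funnel set sizes under every sum_mode (near-miss diagnostics).

    The defining sum is ambiguous about whether negative z-scores
    participate, so reported set sizes under each reading make the
    sensitivity of the funnel to that choice explicit.
    """
    rows = []
    for mode in SUM_MODES:
        res = run_screen(expr, cna, family_genes, sum_mode=mode, **kwargs)
        rows.append(
            {
                "sum_mode": mode,
                "part1": len(res.part1_genes),
                "part2": len(res.part2_genes),
                "shared": len(res.shared_genes),
                "amplified": len(res.amplified_genes),
                "overexpressed": len(res.overexpressed_genes),
                "sum_threshold": res.thresholds.sum_threshold,
                "count_threshold": res.thresholds.count_threshold,
                "weighted_threshold": res.thresholds.weighted_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("sum_mode")
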