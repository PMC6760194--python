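"""Kaplan-Meier estimation and log-rank stratification by gene upregulation.

Cases are dichotomized by a gene's (or gene group's) z-score at the
screen's cutoff and the two strata compared with the standard two-group
log-rank test (hypergeometric variance, 1 df, no continuity correction).
Tied event and censoring times follow the usual product-limit convention:
events precede censorings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .screen import ZScoreMatrix


class SurvivalError(ValueError):
    pass


@dataclass
class SurvivalCurve:
    """Product-limit step function with at-risk counts."""

    table: pd.DataFrame  # columns: time, survival, at_risk
    n: int
    n_events: int

    def probability_at(self, t: float) -> float:
        tab = self.table[self.table["time"] <= t]
        return float(tab["survival"].iloc[-1]) if len(tab) else 1.0


@dataclass
class StratifiedComparison:
    gene: str | list[str]
    groups: pd.Series  # case -> "upregulated" | "not_upregulated"
    curves: dict[str, SurvivalCurve]
    chi_square: float
    p_value: float


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations shrink the risk set without a step; with no
    censoring the curve equals the empirical survival function.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise SurvivalError("empty survival input")
    if (times < 0).any():
        raise SurvivalError("negative survival times")
    if times.shape != events.shape:
        raise SurvivalError("times and events differ in length")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index)
    table = pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(),
            "at_risk": at_risk.to_numpy(),
        }
    ).reset_index(drop=True)
    return SurvivalCurve(table=table, n=int(times.size), n_events=int(events.sum()))


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) on 1 df."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    if ta.size == 0 or tb.size == 0:
        raise SurvivalError("both groups need at least one observation")
    res = logrank_test(
        ta, tb, event_observed_A=np.asarray(events_a, bool),
        event_observed_B=np.asarray(events_b, bool),
    )
    return float(res.test_statistic), float(res.p_value)


def stratify_by_gene(
    z: ZScoreMatrix,
    gene: str | list[str],
    clinical: pd.DataFrame,
    z_cut: float | None = None,
) -> StratifiedComparison:
    """Compare survival between cases with and without gene upregulation.

    For a gene group, a case is "upregulated" when any member gene reaches
    the cutoff.  Both strata must be non-empty among cases with survival
    data.
    """
    cut = z.z_cut if z_cut is None else z_cut
    genes = [gene] if isinstance(gene, str) else list(gene)
    missing = [g for g in genes if g not in z.values.index]
    if missing:
        raise SurvivalError(f"gene(s) not screened: {missing}")
    up = (z.values.loc[genes] >= cut).any(axis=0)

    clin = clinical.reindex(up.index)
    ok = clin["survival_months"].notna() & clin["event"].notna()
    up = up[ok]
    if up.sum() == 0:
        raise SurvivalError(f"no upregulated cases with survival data for {gene}")
    if (~up).sum() == 0:
        raise SurvivalError(f"no non-upregulated cases with survival data for {gene}")
    groups = up.map({True: "upregulated", False: "not_upregulated"})
    curves = {}
    by = {}
    for name in ("upregulated", "not_upregulated"):
        idx = groups.index[groups == name]
        t = clin.loc[idx, "survival_months"].to_numpy(float)
        e = clin.loc[idx, "event"].astype(bool).to_numpy()
        curves[name] = km_estimate(t, e)
        by[name] = (t, e)
    chi2, p = logrank(*by["upregulated"], *by["not_upregulated"])
    return StratifiedComparison(gene, groups, curves, chi2, p)


def stratify_by_subpopulation(
    labels: pd.Series, target: str, clinical: pd.DataFrame
) -> StratifiedComparison:
    """Compare one sub-population's survival against all other cases."""
    clin = clinical.reindex(labels.index)
    ok = clin["survival_months"].notna() & clin["event"].notna()
    lab = labels[ok]
    if (lab == target).sum() == 0 or (lab != target).sum() == 0:
        raise SurvivalError(f"degenerate stratification on {target!r}")
    groups = (lab == target).map({True: "upregulated", False: "not_upregulated"})
    curves, by = {}, {}
    for name in ("upregulated", "not_upregulated"):
        idx = groups.index[groups == name]
        t = clin.loc[idx, "survival_months"].to_numpy(float)
        e = clin.loc[idx, "event"].astype(bool).to_numpy()
        curves[name] = km_estimate(t, e)
        by[name] = (t, e)
    chi2, p = logrank(*by["upregulated"], *by["not_upregulated"])
    return StratifiedComparison(f"subpopulation {target}", groups, curves, chi2, p)
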