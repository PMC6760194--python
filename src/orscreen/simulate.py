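"""Synthetic tumor-cohort generator with recorded ground truth.

The generator emulates the statistical structure the screen assumes, at the
count level: per-gene log-normal baseline expression (log2-FPKM mean/SD),
converted to integer read counts through the FPKM inverse with per-gene
transcript lengths and per-sample sequencing depths.

The stated world, chosen once (see docs/methods.md for rationale):

* Non-planted family genes sit at the *detection limit* — expected
  reference-depth counts log-uniform in [0.02, 0.5].  This mirrors an
  ectopically expressed family that is silent in normal tissue and in most
  tumors (the screen's own prevalence histogram shape), and it is the
  regime in which count quantization keeps null z-scores bounded.
* Planted genes have detectable baselines (expected counts in [20, 50]):
  a reference-anchored effect in SD units presupposes a measurable
  reference SD.
* Expressed genes (expected counts >= 3) share a per-sample
  tissue-composition factor carrying 95% of their biological variance —
  bulk expression of a co-regulated family co-varies through cell-type
  composition.  Detection-limit genes are shot-noise dominated and
  independent.
* Carriers of planted gene g are shifted by +delta * sigma_g in log2
  space, and (optionally) receive the gene's high-level amplification
  call; decoy amplification calls are placed on transcriptionally silent
  family members — amplification without expression, which the funnel must
  reject.
* Survival is exponential (median 120 months) with a hazard ratio applied
  to carriers of a designated gene; censoring is uniform over each
  subject's event time for a configurable fraction of cases.

A single pseudo-random stream ordered (genes, samples, clinical, survival)
makes every bundle a deterministic function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CohortBundle, CountMatrix
from .panels import ONCOTYPE_DX_GENES, PAM50_GENES


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedGene:
    """A family gene carrying a planted over-expression effect."""

    index: int                 # position within the family gene list
    delta: float = 6.0         # effect size in units of the gene's log2 SD
    carrier_fraction: float = 0.2


@dataclass
class SyntheticCohortConfig:
    n_tumors: int = 960
    n_reference: int = 4
    n_family_genes: int = 408
    n_filler_genes: int = 200  # non-panel background carrying library mass
    planted: tuple[PlantedGene, ...] = ()
    decoy_amplified_fraction: float = 0.04
    amplified_carrier_link: bool = True
    # baseline expected counts at reference depth
    null_count_range: tuple[float, float] = (0.02, 0.5)
    planted_count_range: tuple[float, float] = (20.0, 50.0)
    background_count_range: tuple[float, float] = (2e3, 2e4)
    panel_count_range: tuple[float, float] = (50.0, 500.0)
    # per-gene log2 SD; the filler stands in for the stable bulk of the
    # transcriptome, so its per-gene noise is small (library-size jitter
    # from the aggregate stays ~0.5%, as in a real ~20k-gene library)
    null_log2_sd: tuple[float, float] = (0.08, 0.2)
    planted_log2_sd: tuple[float, float] = (0.25, 0.4)
    background_log2_sd: tuple[float, float] = (0.05, 0.15)
    panel_log2_sd: tuple[float, float] = (0.2, 0.4)
    # shared tissue-composition factor
    composition_loading: float = 0.975
    expressed_count_threshold: float = 3.0
    # FPKM plumbing
    length_range_bp: tuple[float, float] = (500.0, 4000.0)
    tumor_depth_range: tuple[float, float] = (2.2e7, 2.8e7)
    reference_depth: float = 2.5e7
    # clinical / survival
    subtype_link: dict = field(default_factory=dict)   # planted idx -> subtype
    subtype_link_prob: float = 0.6
    panel_link: dict = field(default_factory=dict)     # planted idx -> (symbols, shift_sd)
    hazard_gene: int | None = None                     # planted index
    hazard_ratio: float = 1.0
    median_survival_months: float = 120.0
    censoring_fraction: float = 0.2
    with_survival: bool = True
    mutation_spec: tuple[tuple[int, int], ...] | None = None  # (family idx, count)

    def validate(self) -> None:
        if self.n_reference < 2:
            raise ConfigError("need >= 2 reference samples")
        for p in self.planted:
            if not 0 <= p.index < self.n_family_genes:
                raise ConfigError(f"planted index {p.index} out of range")
            if not 0.0 < p.carrier_fraction <= 1.0:
                raise ConfigError("carrier fraction must be in (0, 1]")
            if p.delta < 0:
                raise ConfigError("delta must be >= 0")
        if self.hazard_gene is not None and self.hazard_gene >= len(self.planted):
            raise ConfigError("hazard_gene must index a planted gene")
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ConfigError("censoring fraction must be in [0, 1)")


@dataclass
class SyntheticTruth:
    planted_genes: list[str]
    carriers: dict[str, list[str]]
    overexpressed: list[str]     # planted genes expected to pass the funnel
    decoy_amplified: list[str]
    hazard_gene: str | None
    hazard_carriers: list[str]
    config: SyntheticCohortConfig


_SUBTYPE_BASE = (("LumA", 0.44), ("LumB", 0.20), ("Her2", 0.10),
                 ("Basal", 0.18), ("Normal", 0.05), (None, 0.03))
_STAGE_BASE = (("i", 0.18), ("ii", 0.55), ("iii", 0.22), ("iv", 0.04), (None, 0.01))
_MORPH_BASE = (("IDC", 0.72), ("ILC", 0.18), ("mixed", 0.05), ("other", 0.04), (None, 0.01))

_DEFAULT_MUTATION_COUNTS = (8, 8, 7, 7, 6, 6, 6, 6, 6, 6, 6, 6, 6, 6, 6)


def _choice(rng: np.random.Generator, table, n: int) -> np.ndarray:
    labels = np.array([t[0] for t in table], dtype=object)
    probs = np.array([t[1] for t in table], dtype=float)
    return rng.choice(labels, size=n, p=probs / probs.sum())


def generate_cohort(
    config: SyntheticCohortConfig, seed: int
) -> tuple[CohortBundle, SyntheticTruth]:
    """Generate one cohort bundle plus its ground truth, deterministically."""
    config.validate()
    rng = np.random.default_rng(seed)
    cfg = config

    panel_symbols = sorted(set(ONCOTYPE_DX_GENES) | set(PAM50_GENES))
    n_fam, n_panel, n_fill = cfg.n_family_genes, len(panel_symbols), cfg.n_filler_genes
    ng = n_fam + n_panel + n_fill
    n_tum, n_ref = cfg.n_tumors, cfg.n_reference
    nsamp = n_tum + n_ref

    fam_ids = [f"ORS{i + 1:03d}" for i in range(n_fam)]
    fill_ids = [f"BG{i + 1:03d}" for i in range(n_fill)]
    gene_ids = fam_ids + panel_symbols + fill_ids
    tumor_ids = [f"T{i + 1:04d}" for i in range(n_tum)]
    ref_ids = [f"N{i + 1}" for i in range(n_ref)]
    sample_ids = tumor_ids + ref_ids

    # --- genes: baselines, SDs, lengths ---------------------------------
    lam = np.empty(ng)
    lo, hi = cfg.null_count_range
    lam[:n_fam] = 2.0 ** rng.uniform(np.log2(lo), np.log2(hi), n_fam)
    lo, hi = cfg.panel_count_range
    lam[n_fam:n_fam + n_panel] = 2.0 ** rng.uniform(np.log2(lo), np.log2(hi), n_panel)
    lo, hi = cfg.background_count_range
    lam[n_fam + n_panel:] = 2.0 ** rng.uniform(np.log2(lo), np.log2(hi), n_fill)

    sig = np.empty(ng)
    sig[:n_fam] = rng.uniform(*cfg.null_log2_sd, n_fam)
    sig[n_fam:n_fam + n_panel] = rng.uniform(*cfg.panel_log2_sd, n_panel)
    sig[n_fam + n_panel:] = rng.uniform(*cfg.background_log2_sd, n_fill)

    planted_idx = [p.index for p in cfg.planted]
    if cfg.planted:
        lam[planted_idx] = rng.uniform(*cfg.planted_count_range, len(cfg.planted))
        sig[planted_idx] = rng.uniform(*cfg.planted_log2_sd, len(cfg.planted))

    length = rng.uniform(*cfg.length_range_bp, ng)

    # --- samples: depths, carriers, shared factor -----------------------
    depth = np.concatenate(
        [rng.uniform(*cfg.tumor_depth_range, n_tum), np.full(n_ref, cfg.reference_depth)]
    )
    perm = rng.permutation(n_tum)
    carriers: dict[int, np.ndarray] = {}
    start = 0
    for p in cfg.planted:
        n_car = int(round(p.carrier_fraction * n_tum))
        carriers[p.index] = perm[start:start + n_car]
        start += n_car
        if start > n_tum:
            raise ConfigError("carrier fractions exceed the cohort")

    f_comp = rng.normal(0.0, 1.0, nsamp)
    eps = rng.normal(0.0, 1.0, (ng, nsamp))
    # family-specific composition factor: only expressed *family* genes load
    # on it (receptor-cell content), so it is not a library-size effect and
    # survives FPKM normalization
    is_family = np.arange(ng) < n_fam
    rho = np.where(
        is_family & (lam >= cfg.expressed_count_threshold),
        cfg.composition_loading,
        0.0,
    )
    noise = rho[:, None] * f_comp[None, :] + np.sqrt(1.0 - rho**2)[:, None] * eps

    mu = np.log2(lam * 1e9 / (length * cfg.reference_depth))  # log2 FPKM baseline
    log2_fpkm = mu[:, None] + sig[:, None] * noise
    for p in cfg.planted:
        log2_fpkm[p.index, carriers[p.index]] += p.delta * sig[p.index]
    # panel-gene shifts in carriers of linked planted genes
    sym_to_row = {s: n_fam + i for i, s in enumerate(panel_symbols)}
    for pi, (symbols, shift) in cfg.panel_link.items():
        rows = [sym_to_row[s] for s in symbols if s in sym_to_row]
        cars = carriers[cfg.planted[pi].index]
        for r in rows:
            log2_fpkm[r, cars] += shift * sig[r]

    counts = np.rint(2.0 ** log2_fpkm * length[:, None] * depth[None, :] / 1e9)
    counts = counts.astype(np.int64)

    # --- copy number ----------------------------------------------------
    cna = np.zeros((ng, n_tum), dtype=np.int64)
    sprinkle = rng.random((ng, n_tum))
    cna[sprinkle < 0.05] = 1
    cna[(sprinkle >= 0.05) & (sprinkle < 0.10)] = -1
    cna[(sprinkle >= 0.10) & (sprinkle < 0.102)] = -2
    silent = np.flatnonzero(
        (lam[:n_fam] < cfg.null_count_range[1] * 0.4)
        & ~np.isin(np.arange(n_fam), planted_idx)
    )
    n_decoys = int(round(cfg.decoy_amplified_fraction * n_fam))
    decoy_rows = rng.choice(silent, size=min(n_decoys, len(silent)), replace=False)
    for r in decoy_rows:
        hits = rng.choice(n_tum, size=1 + rng.poisson(2.0), replace=False)
        cna[r, hits] = 2
    for p in cfg.planted:
        if cfg.amplified_carrier_link and len(carriers[p.index]):
            cna[p.index, carriers[p.index]] = 2
        else:
            cna[p.index, rng.integers(0, n_tum)] = 2

    # --- clinical -------------------------------------------------------
    subtype = _choice(rng, _SUBTYPE_BASE, n_tum)
    link_draw = rng.random(n_tum)
    for pi, label in cfg.subtype_link.items():
        cars = carriers[cfg.planted[pi].index]
        take = cars[link_draw[cars] < cfg.subtype_link_prob]
        subtype[take] = label
    u = rng.random((n_tum, 4))
    er = np.where(
        pd.Series(subtype).isin(["LumA", "LumB"]), np.where(u[:, 0] < 0.9, "pos", "neg"),
        np.where(u[:, 0] < 0.15, "pos", "neg"),
    ).astype(object)
    her2 = np.where(
        subtype == "Her2", np.where(u[:, 1] < 0.9, "pos", "neg"),
        np.where(u[:, 1] < 0.1, "pos", "neg"),
    ).astype(object)
    tnbc = (er == "neg") & (her2 == "neg") & (
        (subtype == "Basal") | (u[:, 2] < 0.3)
    )
    none_mask = pd.isna(pd.Series(subtype)).to_numpy()
    er[none_mask & (u[:, 3] < 0.3)] = None
    her2[none_mask & (u[:, 3] < 0.3)] = None
    stage = _choice(rng, _STAGE_BASE, n_tum)
    morph = _choice(rng, _MORPH_BASE, n_tum)

    # --- survival -------------------------------------------------------
    if cfg.with_survival:
        rate = np.full(n_tum, np.log(2.0) / cfg.median_survival_months)
        hazard_carriers: list[int] = []
        if cfg.hazard_gene is not None:
            hz_idx = cfg.planted[cfg.hazard_gene].index
            hazard_carriers = list(carriers[hz_idx])
            rate[carriers[hz_idx]] *= cfg.hazard_ratio
        t_event = rng.exponential(1.0 / rate)
        censor = rng.random(n_tum) < cfg.censoring_fraction
        t_cens = rng.uniform(0.0, t_event)
        months = np.round(np.where(censor, t_cens, t_event), 2)
        event = ~censor
    else:
        hazard_carriers = []
        months = np.full(n_tum, np.nan)
        event = np.full(n_tum, np.nan)

    # --- assemble bundle ------------------------------------------------
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    roles = pd.Series(
        ["tumor"] * n_tum + ["reference"] * n_ref, index=sample_ids, dtype=object
    )
    cna_df = pd.DataFrame(cna, index=gene_ids, columns=tumor_ids)

    family_tag = np.array(["other"] * ng, dtype=object)
    family_tag[:n_fam] = "OR"
    for i, s in enumerate(panel_symbols):
        family_tag[n_fam + i] = "oncotypedx" if s in ONCOTYPE_DX_GENES else "pam50"
    annotation = pd.DataFrame(
        {
            "symbol": gene_ids,
            "length_bp": np.round(length).astype(np.int64),
            "family": family_tag,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    clinical = pd.DataFrame(
        {
            "stage": stage,
            "er_status": er,
            "her2_status": her2,
            "tnbc": tnbc,
            "morphology": morph,
            "subtype_label": subtype,
            "survival_months": months,
            "event": event,
        },
        index=pd.Index(tumor_ids, name="sample_id"),
    )
    if cfg.with_survival:
        clinical["event"] = clinical["event"].astype(float)

    if cfg.mutation_spec is not None:
        mut_items = list(cfg.mutation_spec)
    else:
        candidates = [i for i in silent if i not in set(decoy_rows)]
        mut_items = list(zip(candidates[: len(_DEFAULT_MUTATION_COUNTS)],
                             _DEFAULT_MUTATION_COUNTS))
    mutations = pd.Series(
        {fam_ids[i]: int(c) for i, c in mut_items}, dtype=np.int64
    ).rename_axis("gene_id")

    bundle = CohortBundle(
        counts=CountMatrix(counts_df, roles),
        cna=cna_df,
        clinical=clinical,
        annotation=annotation,
        mutations=mutations,
    )
    truth = SyntheticTruth(
        planted_genes=[fam_ids[i] for i in planted_idx],
        carriers={
            fam_ids[i]: [tumor_ids[j] for j in sorted(carriers[i])] for i in planted_idx
        },
        overexpressed=[fam_ids[p.index] for p in cfg.planted if p.delta > 0],
        decoy_amplified=[fam_ids[i] for i in sorted(decoy_rows)],
        hazard_gene=(
            fam_ids[cfg.planted[cfg.hazard_gene].index]
            if cfg.hazard_gene is not None else None
        ),
        hazard_carriers=[tumor_ids[j] for j in sorted(hazard_carriers)],
        config=cfg,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------

PROLIFERATION_GENES = ("MKI67", "AURKA", "BIRC5", "CCNB1", "MYBL2")
INVASION_GENES = ("CTSV", "MMP11")
LUMA_MARKERS = ("MLPH", "GPR160")
BASAL_MARKERS = ("CEP55", "CDH3")


def three_subpop_config(n_tumors: int = 240) -> SyntheticCohortConfig:
    """Three planted genes with disjoint carrier groups.

    Sub-population I carriers (gene ORS001) up-shift proliferation and
    luminal-A marker genes and are enriched for the LumA label;
    sub-population III carriers (gene ORS003) up-shift invasion and basal
    markers, carry the Basal label and a 3x death hazard.
    """
    return SyntheticCohortConfig(
        n_tumors=n_tumors,
        planted=(PlantedGene(0), PlantedGene(1), PlantedGene(2)),
        subtype_link={0: "LumA", 2: "Basal"},
        panel_link={
            0: (PROLIFERATION_GENES + LUMA_MARKERS, 3.0),
            2: (INVASION_GENES + BASAL_MARKERS, 3.0),
        },
        hazard_gene=2,
        hazard_ratio=3.0,
    )


def null_config(n_tumors: int = 240) -> SyntheticCohortConfig:
    """No planted signal; decoy amplifications only."""
    return SyntheticCohortConfig(n_tumors=n_tumors, planted=())


def hazard_config(n_tumors: int = 200, hazard_ratio: float = 3.0) -> SyntheticCohortConfig:
    """One planted gene whose carriers have an elevated death hazard."""
    return SyntheticCohortConfig(
        n_tumors=n_tumors,
        planted=(PlantedGene(0, carrier_fraction=0.3),),
        hazard_gene=0,
        hazard_ratio=hazard_ratio,
    )


def cellline_config(n_lines: int = 54) -> SyntheticCohortConfig:
    """A small cell-line panel: no survival, three planted genes."""
    return SyntheticCohortConfig(
        n_tumors=n_lines,
        planted=(
            PlantedGene(0, carrier_fraction=0.35),
            PlantedGene(1, carrier_fraction=0.3),
            PlantedGene(2, carrier_fraction=0.3),
        ),
        subtype_link={2: "Basal"},
        with_survival=False,
    )


FIXTURES = {
    "null": null_config,
    "three-subpop": three_subpop_config,
    "hazard": hazard_config,
    "cellline": cellline_config,
}


def make_fixture_suite(
    out_dir=None, seed: int = 7
) -> dict[str, tuple[CohortBundle, SyntheticTruth]]:
    """Generate the canonical named fixtures (optionally writing TSV bundles)."""
    from .io import write_bundle
    from pathlib import Path

    suite = {}
    for name, maker in FIXTURES.items():
        bundle, truth = generate_cohort(maker(), seed)
        suite[name] = (bundle, truth)
        if out_dir is not None:
            write_bundle(bundle, Path(out_dir) / name)
    return suite


def scaled(config: SyntheticCohortConfig, n_tumors: int) -> SyntheticCohortConfig:
    """A copy of ``config`` with a different cohort size."""
    return replace(config, n_tumors=n_tumors)
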