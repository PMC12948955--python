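"""Synthetic cohort generator emulating low-input epidermal methylation arrays.

The generator produces probe × sample β and detection-p matrices with the
statistical structure the downstream analysis assumes:

* a bimodal baseline β distribution (two-component Beta mixture with modes
  near 0.1 and 0.9, the canonical shape of high-quality array data);
* age-drift CpGs whose β changes linearly with donor age;
* mitotic-drift CpGs that start near the unmethylated mode and gain
  methylation with age at a per-probe rate (cell-division tracking);
* tumor-suppressor-gene promoter probes with a planted age-dependent
  methylation gain for a configurable fraction of genes;
* cell-type marker probes that are unmethylated in the owning cell type and
  methylated elsewhere (tissue-identity signal);
* non-variable (nv) probes that are flat except for a few planted outlier
  cells emulating somatic mutations;
* a replicate cohort (default 4 donors × 3 samples) with shared donor-level
  effects plus technical noise, used by the replicate-variance probe filter;
* per-sample quality scalars driving both detection-p failure rates (logistic
  failure model) and inflated β noise, emulating low-input degradation.

Everything is drawn from numpy Generators seeded from a single integer with
fixed stream ids (annotation = 0, cohort = 1, reference panels = 2), so the
same seed reproduces identical tables bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy.special import expit

from .datasets import (
    MethylationDataset,
    ProbeAnnotation,
    ValidationError,
)

__all__ = ["SynthConfig", "DegradationModel", "GroundTruth",
           "generate_annotation", "generate_cohort", "generate_reference_panels"]

# keratinocyte-plausible chromatin-state frequencies (Quies dominates genome-wide)
_STATE_WEIGHTS = {
    "TssA": 0.08, "TssFlnk": 0.04, "TssFlnkU": 0.02, "TssFlnkD": 0.02,
    "Tx": 0.05, "TxWk": 0.12, "EnhG": 0.03, "EnhA": 0.06, "EnhWk": 0.09,
    "ZNF/Rpts": 0.01, "Het": 0.05, "TssBiv": 0.02, "EnhBiv": 0.03,
    "ReprPC": 0.04, "ReprPCWk": 0.04, "Quies": 0.30,
}


@dataclass
class DegradationModel:
    """Per-sample quality scalar model for low-input degradation.

    Quality q ∈ [0, 1] is drawn per donor from Beta(quality_a, quality_b);
    a probe-sample cell fails detection with probability
    ``expit(failure_steepness * (failure_midpoint - q))``, detected cells get
    p ~ U(0, 0.05) and failed cells p ~ U(0.05, 1).  β noise is multiplied by
    ``1 + beta_noise_inflation * (1 - q)``.
    """

    quality_a: float = 3.8
    quality_b: float = 1.3
    failure_midpoint: float = 0.24
    failure_steepness: float = 20.0
    beta_noise_inflation: float = 1.0

    def failure_probability(self, quality: np.ndarray) -> np.ndarray:
        return expit(self.failure_steepness * (self.failure_midpoint - np.asarray(quality)))


@dataclass
class SynthConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the emulated study regime: 89 donors aged 18–85 with a
    ~60% female cohort, a 4-donor × 3-replicate technical cohort, age-drift
    slopes of 0.002–0.004 β-units/year and β noise of 0.03.
    """

    seed: int = 0
    n_donors: int = 89
    age_range: tuple[float, float] = (18.0, 85.0)
    sex_ratio: float = 0.6  # fraction female
    n_probes: int = 6000
    n_age_probes: int = 400
    age_slope_range: tuple[float, float] = (0.002, 0.004)
    n_mitotic_probes: int = 150
    mitotic_rate_range: tuple[float, float] = (0.001, 0.003)
    n_tsg_genes: int = 100
    probes_per_promoter: tuple[int, int] = (2, 5)
    tsg_gain_range: tuple[float, float] = (0.1, 0.3)
    frac_tsg_hyper: float = 0.6
    n_nv_probes: int = 40
    n_nv_outliers: int = 5
    cell_types: tuple[str, ...] = ("keratinocyte", "leukocyte", "myocyte", "hepatocyte")
    markers_per_type: int = 25
    frac_snp: float = 0.05
    frac_crossreactive: float = 0.03
    frac_sex_chrom: float = 0.03
    noise_sd: float = 0.03
    donor_effect_sd: float = 0.01
    degradation: DegradationModel = field(default_factory=DegradationModel)
    replicate_design: tuple[int, int] = (4, 3)  # (n_replicate_donors, n_replicates)
    reference_tissues: tuple[str, ...] = ("epidermis", "blood", "muscle")
    samples_per_tissue: int = 6
    frac_missing: float = 0.0

    def validate(self) -> None:
        for name in ("sex_ratio", "frac_snp", "frac_crossreactive",
                     "frac_sex_chrom", "frac_tsg_hyper", "frac_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.n_age_probes + self.n_mitotic_probes > self.n_probes:
            raise ValidationError("n_age_probes + n_mitotic_probes exceeds n_probes")
        if self._n_special() > self.n_probes:
            raise ValidationError(
                f"special probes ({self._n_special()}) exceed n_probes ({self.n_probes})"
            )
        if self.age_range[0] >= self.age_range[1]:
            raise ValidationError("age_range must be increasing")
        if self.replicate_design[1] < 2:
            raise ValidationError("replicate design needs >= 2 replicates per donor")

    def _max_tsg_probes(self) -> int:
        return self.n_tsg_genes * self.probes_per_promoter[1]

    def _n_special(self) -> int:
        return (
            self.n_age_probes
            + self.n_mitotic_probes
            + self._max_tsg_probes()
            + self.n_nv_probes
            + len(self.cell_types) * self.markers_per_type
        )


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    age_probes: pd.DataFrame        # probe_id, slope (β/yr), base
    mitotic_probes: pd.DataFrame    # probe_id, rate (β/yr), base
    tsg_genes: pd.DataFrame         # gene_id, gain_per_year, total_gain
    sample_quality: pd.Series       # sample_id -> quality scalar in [0,1]
    nv_outliers: pd.DataFrame       # sample_id, probe_id, shift

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.age_probes.to_csv(out / "truth_age_probes.tsv", sep="\t", index=False)
        self.mitotic_probes.to_csv(out / "truth_mitotic_probes.tsv", sep="\t", index=False)
        self.tsg_genes.to_csv(out / "truth_tsg_genes.tsv", sep="\t", index=False)
        self.sample_quality.rename("quality").rename_axis("sample_id").to_csv(
            out / "truth_sample_quality.tsv", sep="\t"
        )
        self.nv_outliers.to_csv(out / "truth_nv_outliers.tsv", sep="\t", index=False)


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def generate_annotation(cfg: SynthConfig) -> ProbeAnnotation:
    """Build a deterministic probe annotation table for the configuration.

    Probe roles (age, mitotic, TSG-promoter, marker, nv) occupy disjoint
    blocks at the start of the id space; QC flags (SNP overlap, sex
    chromosome, cross-reactive) are assigned only to the remaining background
    probes so planted signal is not removed by the annotation filters.  Flag
    counts are ``round(frac * n_probes)``.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    n = cfg.n_probes

    probe_ids = np.array([f"cg{i:07d}" for i in range(n)], dtype=object)
    roles = np.full(n, "background", dtype=object)
    cursor = 0

    def take(count: int, role: str) -> np.ndarray:
        nonlocal cursor
        idx = np.arange(cursor, cursor + count)
        roles[idx] = role
        cursor += count
        return idx

    age_idx = take(cfg.n_age_probes, "age")
    mito_idx = take(cfg.n_mitotic_probes, "mitotic")

    # TSG promoters: per gene 2..max probes split between TSS200/TSS1500
    links: list[tuple[str, str, str]] = []
    tsg_idx_all: list[int] = []
    lo, hi = cfg.probes_per_promoter
    for g in range(cfg.n_tsg_genes):
        gene = f"TSG{g:04d}"
        k = int(rng.integers(lo, hi + 1))
        idx = take(k, "tsg")
        tsg_idx_all.extend(idx.tolist())
        for j, i in enumerate(idx):
            region = "TSS200" if j % 2 == 0 else "TSS1500"
            links.append((probe_ids[i], gene, region))

    markers: list[tuple[str, str, int]] = []
    marker_idx: dict[str, np.ndarray] = {}
    for ct in cfg.cell_types:
        idx = take(cfg.markers_per_type, f"marker:{ct}")
        marker_idx[ct] = idx
        for r, i in enumerate(idx, start=1):
            markers.append((probe_ids[i], ct, r))

    nv_idx = take(cfg.n_nv_probes, "nv")
    probe_ids[nv_idx] = [f"nv{i:07d}" for i in nv_idx]

    background = np.flatnonzero(roles == "background")

    snp = np.zeros(n, dtype=bool)
    crossreactive = np.zeros(n, dtype=bool)
    sex_chrom = np.zeros(n, dtype=bool)
    n_snp = int(round(cfg.frac_snp * n))
    n_cross = int(round(cfg.frac_crossreactive * n))
    n_sex = int(round(cfg.frac_sex_chrom * n))
    if n_snp + n_cross + n_sex > len(background):
        raise ValidationError("not enough background probes to carry the QC flags")
    flagged = rng.choice(background, size=n_snp + n_cross + n_sex, replace=False)
    snp[flagged[:n_snp]] = True
    crossreactive[flagged[n_snp:n_snp + n_cross]] = True
    sex_chrom[flagged[n_snp + n_cross:]] = True

    chrom = np.array(
        [f"chr{c}" for c in rng.integers(1, 23, size=n)], dtype=object
    )
    chrom[sex_chrom] = rng.choice(["chrX", "chrY"], size=int(sex_chrom.sum()))

    states = np.array(list(_STATE_WEIGHTS), dtype=object)
    weights = np.array(list(_STATE_WEIGHTS.values()))
    weights = weights / weights.sum()
    chromatin = rng.choice(states, size=n, p=weights)
    # promoter probes look like TSS states
    chromatin[np.asarray(tsg_idx_all, dtype=int)] = rng.choice(
        ["TssA", "TssBiv", "TssFlnk"], size=len(tsg_idx_all), p=[0.6, 0.25, 0.15]
    )

    probe_class = np.full(n, "cg", dtype=object)
    probe_class[nv_idx] = "nv"
    tsg_flag = np.zeros(n, dtype=bool)
    tsg_flag[np.asarray(tsg_idx_all, dtype=int)] = True

    table = pd.DataFrame(
        {
            "chromosome": chrom,
            "snp_overlap": snp,
            "cross_reactive": crossreactive,
            "probe_class": probe_class,
            "chromatin_state": chromatin,
            "tsg_flag": tsg_flag,
            "role": roles,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeAnnotation(
        table=table,
        promoter_links=pd.DataFrame(links, columns=["probe_id", "gene_id", "region"]),
        marker_sets=pd.DataFrame(markers, columns=["probe_id", "cell_type", "rank"]),
    )


def _baseline_betas(
    cfg: SynthConfig, ann: ProbeAnnotation, rng: np.random.Generator
) -> np.ndarray:
    """Per-probe ground-state β (before age/mitotic/noise effects)."""
    roles = ann.table["role"].to_numpy()
    n = len(roles)
    # bimodal background: Beta(2,18) mode ~0.06 / Beta(18,2) mode ~0.94, mix 0.5
    low = rng.beta(2.0, 18.0, size=n)
    high = rng.beta(18.0, 2.0, size=n)
    pick_high = rng.random(n) < 0.5
    base = np.where(pick_high, high, low)

    age_mask = roles == "age"
    base[age_mask] = rng.uniform(0.3, 0.5, size=age_mask.sum())
    mito_mask = roles == "mitotic"
    base[mito_mask] = rng.uniform(0.03, 0.08, size=mito_mask.sum())
    tsg_mask = roles == "tsg"
    base[tsg_mask] = rng.uniform(0.05, 0.15, size=tsg_mask.sum())
    nv_mask = roles == "nv"
    base[nv_mask] = rng.uniform(0.01, 0.03, size=nv_mask.sum())
    for ct in cfg.cell_types:
        m = roles == f"marker:{ct}"
        # main cohort is keratinocyte tissue: own markers unmethylated
        base[m] = 0.05 if ct == cfg.cell_types[0] else 0.9
    return base


def generate_cohort(
    cfg: SynthConfig, annotation: ProbeAnnotation
) -> tuple[MethylationDataset, GroundTruth]:
    """Generate the main + replicate cohorts as one dataset.

    The ``cohort`` metadata column distinguishes ``main`` donors (one sample
    each) from the ``replicate`` cohort (``replicate_design`` donors ×
    replicates sharing donor-level effects).  See the module docstring for
    the planted signal structure.
    """
    cfg.validate()
    if "role" not in annotation.table.columns:
        raise ValidationError("annotation must come from generate_annotation (role column)")
    rng = _rng(cfg, 1)
    ann = annotation
    roles = ann.table["role"].to_numpy()
    probe_ids = ann.table.index.to_numpy()
    n_probes = len(probe_ids)
    age_min, age_max = cfg.age_range

    base = _baseline_betas(cfg, ann, rng)

    # planted effect parameters ------------------------------------------------
    age_mask = roles == "age"
    slopes = np.zeros(n_probes)
    mag = rng.uniform(*cfg.age_slope_range, size=int(age_mask.sum()))
    sign = rng.choice([-1.0, 1.0], size=int(age_mask.sum()))
    slopes[age_mask] = mag * sign
    # negative-slope probes start higher so the drift stays inside [0,1]
    base[age_mask] = np.where(
        slopes[age_mask] < 0,
        base[age_mask] + 0.2,
        base[age_mask],
    )

    mito_mask = roles == "mitotic"
    rates = np.zeros(n_probes)
    rates[mito_mask] = rng.uniform(*cfg.mitotic_rate_range, size=int(mito_mask.sum()))

    tsg_gain_per_year = np.zeros(n_probes)
    gene_rows = []
    span = age_max - age_min
    links = ann.promoter_links
    genes = sorted(links["gene_id"].unique())
    n_hyper = int(round(cfg.frac_tsg_hyper * len(genes)))
    hyper_genes = set(rng.choice(np.array(genes, dtype=object), size=n_hyper, replace=False))
    pos_of = {p: i for i, p in enumerate(probe_ids)}
    for gene in genes:
        gain = float(rng.uniform(*cfg.tsg_gain_range)) if gene in hyper_genes else 0.0
        gene_rows.append((gene, gain / span, gain))
        for p in links.loc[links["gene_id"] == gene, "probe_id"]:
            tsg_gain_per_year[pos_of[p]] = gain / span

    # samples ------------------------------------------------------------------
    deg = cfg.degradation
    n_rep_donors, n_reps = cfg.replicate_design

    sample_rows = []
    columns = []
    quality_list = []

    donor_ages = rng.uniform(age_min, age_max, size=cfg.n_donors)
    donor_sex = np.where(rng.random(cfg.n_donors) < cfg.sex_ratio, "F", "M")
    donor_quality = rng.beta(deg.quality_a, deg.quality_b, size=cfg.n_donors)

    cols: list[str] = []

    def expected_beta(age: float) -> np.ndarray:
        mu = base + slopes * (age - age_min) + rates * age + tsg_gain_per_year * (age - age_min)
        return mu

    col_arrays = []
    for d in range(cfg.n_donors):
        sid = f"S{d + 1:03d}"
        age = float(donor_ages[d])
        q = float(donor_quality[d])
        noise_sd = cfg.noise_sd * (1.0 + deg.beta_noise_inflation * (1.0 - q))
        vals = expected_beta(age)
        if cfg.noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=n_probes)
        col_arrays.append(vals)
        cols.append(sid)
        delta_ct = max(0.0, 0.2 + 3.6 * (1.0 - q) + float(rng.normal(0.0, 0.3)))
        sample_rows.append(
            (sid, f"D{d + 1:03d}", age, donor_sex[d], delta_ct, "none", "main", "epidermis")
        )
        quality_list.append((sid, q))

    # replicate cohort: donor effects shared across the donor's replicates
    rep_ages = rng.uniform(age_min, age_max, size=n_rep_donors)
    rep_sex = np.where(rng.random(n_rep_donors) < cfg.sex_ratio, "F", "M")
    rep_quality = rng.beta(deg.quality_a, deg.quality_b, size=n_rep_donors)
    rep_groups = ["same-site-different-day", "near-site-same-day"]
    for d in range(n_rep_donors):
        donor = f"RD{d + 1:02d}"
        age = float(rep_ages[d])
        q = float(rep_quality[d])
        donor_effect = rng.normal(0.0, cfg.donor_effect_sd, size=n_probes) if cfg.donor_effect_sd > 0 else 0.0
        noise_sd = cfg.noise_sd * (1.0 + deg.beta_noise_inflation * (1.0 - q))
        for r in range(n_reps):
            sid = f"R{d + 1:02d}-{r + 1}"
            vals = expected_beta(age) + donor_effect
            if cfg.noise_sd > 0:
                vals = vals + rng.normal(0.0, noise_sd, size=n_probes)
            col_arrays.append(vals)
            cols.append(sid)
            group = rep_groups[r % len(rep_groups)]
            delta_ct = max(0.0, 0.2 + 3.6 * (1.0 - q) + float(rng.normal(0.0, 0.3)))
            sample_rows.append((sid, donor, age, rep_sex[d], delta_ct, group, "replicate", "epidermis"))
            quality_list.append((sid, q))

    betas = np.column_stack(col_arrays)
    n_samples = betas.shape[1]

    # nv outliers: planted mutation-like shifts on nv probes
    nv_positions = np.flatnonzero(roles == "nv")
    outlier_rows = []
    if cfg.n_nv_outliers > 0 and len(nv_positions) > 0 and n_samples > 0:
        chosen_p = rng.choice(nv_positions, size=cfg.n_nv_outliers, replace=True)
        chosen_s = rng.integers(0, n_samples, size=cfg.n_nv_outliers)
        shifts = rng.uniform(0.4, 0.7, size=cfg.n_nv_outliers)
        for p, s, sh in zip(chosen_p, chosen_s, shifts):
            betas[p, s] += sh
            outlier_rows.append((cols[s], probe_ids[p], float(sh)))

    betas = np.clip(betas, 0.0, 1.0)

    # detection p: logistic failure model of per-sample quality
    quality_arr = np.array([q for _, q in quality_list])
    p_fail = deg.failure_probability(quality_arr)  # per sample
    fail = rng.random((n_probes, n_samples)) < p_fail[None, :]
    detp = np.where(
        fail,
        rng.uniform(0.05, 1.0, size=(n_probes, n_samples)),
        rng.uniform(0.0, 0.05, size=(n_probes, n_samples)),
    )

    if cfg.frac_missing > 0:
        miss = rng.random((n_probes, n_samples)) < cfg.frac_missing
        betas = betas.astype(float)
        betas[miss] = np.nan

    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "donor_id", "age", "sex", "delta_ct",
                 "replicate_group", "cohort", "tissue_label"],
    ).set_index("sample_id")

    ds = MethylationDataset(
        betas=pd.DataFrame(betas, index=pd.Index(probe_ids, name="probe_id"), columns=cols),
        detection_p=pd.DataFrame(detp, index=pd.Index(probe_ids, name="probe_id"), columns=cols),
        samples=samples,
    )
    truth = GroundTruth(
        age_probes=pd.DataFrame(
            {"probe_id": probe_ids[age_mask], "slope": slopes[age_mask], "base": base[age_mask]}
        ),
        mitotic_probes=pd.DataFrame(
            {"probe_id": probe_ids[mito_mask], "rate": rates[mito_mask], "base": base[mito_mask]}
        ),
        tsg_genes=pd.DataFrame(gene_rows, columns=["gene_id", "gain_per_year", "total_gain"]),
        sample_quality=pd.Series(dict(quality_list), name="quality"),
        nv_outliers=pd.DataFrame(outlier_rows, columns=["sample_id", "probe_id", "shift"]),
    )
    return ds, truth


def generate_reference_panels(
    cfg: SynthConfig, annotation: ProbeAnnotation
) -> list[MethylationDataset]:
    """One small panel per reference tissue, with marker-probe identity signal.

    Each tissue owns one cell type (``reference_tissues[i]`` ↔
    ``cell_types[i]``): its marker probes are unmethylated (~0.05) in the
    owning tissue and methylated (~0.9) elsewhere.  Background probes get a
    tissue-specific baseline so whole-methylome embeddings also separate the
    tissues.
    """
    cfg.validate()
    if len(cfg.reference_tissues) > len(cfg.cell_types):
        raise ValidationError("more reference tissues than cell types")
    if cfg.markers_per_type == 0:
        warnings.warn("zero marker probes per cell type: identity checks degrade to chance")
    rng = _rng(cfg, 2)
    roles = annotation.table["role"].to_numpy()
    probe_ids = annotation.table.index.to_numpy()
    n = len(probe_ids)
    panels = []
    for t, tissue in enumerate(cfg.reference_tissues):
        own_ct = cfg.cell_types[t]
        low = rng.beta(2.0, 18.0, size=n)
        high = rng.beta(18.0, 2.0, size=n)
        base = np.where(rng.random(n) < 0.5, high, low)
        for ct in cfg.cell_types:
            m = roles == f"marker:{ct}"
            base[m] = 0.05 if ct == own_ct else 0.9
        cols, arrays, rows = [], [], []
        ages = rng.uniform(*cfg.age_range, size=cfg.samples_per_tissue)
        for s in range(cfg.samples_per_tissue):
            sid = f"{tissue[:3].upper()}{s + 1:02d}"
            vals = np.clip(base + rng.normal(0.0, 0.02, size=n), 0.0, 1.0)
            cols.append(sid)
            arrays.append(vals)
            rows.append((sid, f"{tissue}-donor{s + 1}", float(ages[s]), "F" if s % 2 else "M",
                         np.nan, "none", "reference", tissue))
        betas = np.column_stack(arrays)
        detp = rng.uniform(0.0, 0.05, size=betas.shape)
        samples = pd.DataFrame(
            rows, columns=["sample_id", "donor_id", "age", "sex", "delta_ct",
                           "replicate_group", "cohort", "tissue_label"],
        ).set_index("sample_id")
        panels.append(
            MethylationDataset(
                betas=pd.DataFrame(betas, index=pd.Index(probe_ids, name="probe_id"), columns=cols),
                detection_p=pd.DataFrame(detp, index=pd.Index(probe_ids, name="probe_id"), columns=cols),
                samples=samples,
            )
        )
    return panels
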