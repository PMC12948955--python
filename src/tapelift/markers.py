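"""Skin-cancer marker analyses on methylation datasets.

Three marker families are covered:

* **Mitotic age** — per-sample scores from a parameterized mitotic-clock
  definition restricted to the high-confidence probe set.  Two aggregation
  families are supported: ``rate_normalized_mean`` (mean over clock probes of
  (β − β₀) / (δ·(1 − β₀)), a cumulative-cell-division estimate given each
  probe's ground-state methylation β₀ and per-year drift rate δ; negative
  scores clamp to 0) and ``upper_quantile`` (the empirical q-quantile of the
  clock probes' β, linear interpolation between order statistics).

* **TSG promoter hypermethylation** — per-gene mean promoter methylation
  (TSS200/TSS1500 probes within the high-confidence set, minimum two probes
  per gene), Welch-tested between a young (18–29 y) and an old (≥ 60 y)
  donor group, ranked by the old − young difference; only hypermethylated
  genes (old > young, p below threshold) qualify.  No multiple-testing
  correction is applied to this ranking (raw p-values, a fidelity choice).

* **nv-probe outliers** — robust per-probe z-scores across samples
  (0.6745·(β − median)/MAD with a MAD floor); cells whose |z| strictly
  exceeds a cutoff are flagged as potential somatic-mutation signals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import MethylationDataset, ProbeAnnotation, ValidationError

__all__ = [
    "MitoticClockDefinition",
    "estimate_mitotic_age",
    "mean_promoter_methylation",
    "tsg_sample_correlation",
    "rank_tsg_hypermethylation",
    "gene_age_correlation",
    "detect_nv_outliers",
]

AGGREGATIONS = ("rate_normalized_mean", "upper_quantile")


@dataclass
class MitoticClockDefinition:
    """Parameterized mitotic-age estimator.

    ``rate_normalized_mean`` requires per-probe ``ground_state`` β₀ ∈ [0, 1)
    and drift ``rate`` δ > 0 (β-units per year); ``upper_quantile`` requires
    ``quantile`` ∈ (0, 1).
    """

    name: str
    probe_ids: list[str]
    aggregation: str
    ground_state: np.ndarray | None = None
    rate: np.ndarray | None = None
    quantile: float | None = None

    def __post_init__(self) -> None:
        if self.aggregation not in AGGREGATIONS:
            raise ValidationError(f"unknown aggregation {self.aggregation!r}")
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValidationError("duplicate probe ids in mitotic clock definition")
        if self.aggregation == "rate_normalized_mean":
            if self.ground_state is None or self.rate is None:
                raise ValidationError("rate_normalized_mean needs ground_state and rate")
            self.ground_state = np.asarray(self.ground_state, dtype=float)
            self.rate = np.asarray(self.rate, dtype=float)
            if len(self.ground_state) != len(self.probe_ids) or len(self.rate) != len(self.probe_ids):
                raise ValidationError("parameter vectors must match probe_ids length")
            if np.any(self.rate <= 0):
                raise ValidationError("rates must be > 0")
            if np.any((self.ground_state < 0) | (self.ground_state >= 1)):
                raise ValidationError("ground_state must lie in [0, 1)")
        else:
            if self.quantile is None or not 0.0 < self.quantile < 1.0:
                raise ValidationError("upper_quantile needs quantile in (0, 1)")

    # -- file format: JSON header + TSV parameter table --------------------
    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = pd.DataFrame({"probe_id": self.probe_ids})
        if self.aggregation == "rate_normalized_mean":
            table["ground_state"] = self.ground_state
            table["rate"] = self.rate
        params_path = out / f"{self.name}_params.tsv"
        table.to_csv(params_path, sep="\t", index=False)
        header_path = out / f"{self.name}.json"
        header_path.write_text(json.dumps({
            "name": self.name,
            "aggregation": self.aggregation,
            "quantile": self.quantile,
            "params_file": params_path.name,
        }, indent=2))
        return {"header": header_path, "params": params_path}

    @classmethod
    def read(cls, header_path: str | Path) -> "MitoticClockDefinition":
        header_path = Path(header_path)
        header = json.loads(header_path.read_text())
        table = pd.read_csv(header_path.parent / header["params_file"], sep="\t",
                            dtype={"probe_id": str})
        return cls(
            name=header["name"],
            probe_ids=table["probe_id"].tolist(),
            aggregation=header["aggregation"],
            ground_state=table["ground_state"].to_numpy() if "ground_state" in table else None,
            rate=table["rate"].to_numpy() if "rate" in table else None,
            quantile=header.get("quantile"),
        )


def estimate_mitotic_age(
    ds: MethylationDataset,
    definition: MitoticClockDefinition,
    high_conf_probes: Sequence[str] | None = None,
) -> tuple[pd.Series, dict]:
    """Per-sample mitotic-age score with a probe-coverage report.

    Clock probes are intersected with the dataset's probes and, when given,
    the high-confidence set; coverage = usable / defined.  Missing β cells
    are ignored per sample.
    """
    usable = pd.Index(definition.probe_ids)
    if high_conf_probes is not None:
        usable = usable.intersection(pd.Index(high_conf_probes))
    usable = usable.intersection(ds.probe_ids)
    if len(usable) == 0:
        raise ValidationError("no usable clock probes in the dataset")
    pos = {p: i for i, p in enumerate(definition.probe_ids)}
    sel = [pos[p] for p in usable]
    B = ds.betas.loc[usable].to_numpy(dtype=float)

    if definition.aggregation == "rate_normalized_mean":
        b0 = definition.ground_state[sel][:, None]
        rate = definition.rate[sel][:, None]
        terms = (B - b0) / (rate * (1.0 - b0))
        score = np.nanmean(terms, axis=0)
        score = np.maximum(score, 0.0)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            score = np.nanquantile(B, definition.quantile, axis=0)
    report = {
        "n_defined": len(definition.probe_ids),
        "n_usable": len(usable),
        "coverage": len(usable) / len(definition.probe_ids),
        "aggregation": definition.aggregation,
    }
    return pd.Series(score, index=ds.sample_ids, name=definition.name), report


def mean_promoter_methylation(
    ds: MethylationDataset,
    ann: ProbeAnnotation,
    high_conf_probes: Sequence[str] | None = None,
    min_probes: int = 2,
) -> pd.DataFrame:
    """Gene × sample mean promoter β over qualifying TSS200/TSS1500 probes.

    A probe linked to several genes contributes to each of them; genes with
    fewer than ``min_probes`` qualifying probes are excluded.  Missing β
    cells are averaged over the available probes of the gene.
    """
    links = ann.promoter_links
    probes_ok = set(ds.probe_ids)
    if high_conf_probes is not None:
        probes_ok &= set(str(p) for p in high_conf_probes)
    links = links[links["probe_id"].isin(probes_ok)]
    counts = links.groupby("gene_id")["probe_id"].nunique()
    genes = counts.index[counts >= min_probes]
    links = links[links["gene_id"].isin(genes)]
    rows = []
    for gene, grp in links.groupby("gene_id"):
        probes = grp["probe_id"].unique().tolist()
        rows.append(pd.Series(ds.betas.loc[probes].mean(axis=0, skipna=True), name=gene))
    if not rows:
        return pd.DataFrame(columns=ds.sample_ids)
    return pd.DataFrame(rows).rename_axis("gene_id")


def tsg_sample_correlation(promoter_betas: pd.DataFrame) -> pd.DataFrame:
    """Sample × sample Pearson correlation on promoter methylation rows."""
    if promoter_betas.shape[0] < 2:
        raise ValidationError("need at least 2 promoter probes/genes")
    arr = promoter_betas.astype(float)
    constant = arr.nunique(dropna=True) <= 1
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant sample vectors: NaN correlations")
    corr = arr.corr(method="pearson")  # pairwise-complete
    np.fill_diagonal(corr.values, 1.0)
    return corr


def rank_tsg_hypermethylation(
    gene_matrix: pd.DataFrame,
    meta: pd.DataFrame,
    young: tuple[float, float] = (18.0, 29.0),
    old_min: float = 60.0,
    p_max: float = 0.05,
    top_k: int = 50,
) -> pd.DataFrame:
    """Rank genes by old-vs-young promoter hypermethylation.

    Per gene, mean promoter β is Welch-tested (two-sided, unequal variances)
    between samples aged within ``young`` (inclusive) and samples aged at
    least ``old_min``.  Genes hypermethylated with age (old mean > young
    mean) at raw p < ``p_max`` are ranked by the difference of group means
    descending (ties broken by gene id) and the top ``top_k`` returned.
    """
    ages = pd.to_numeric(meta.loc[gene_matrix.columns, "age"], errors="coerce")
    young_ids = ages.index[(ages >= young[0]) & (ages <= young[1])]
    old_ids = ages.index[ages >= old_min]
    if len(young_ids) < 2 or len(old_ids) < 2:
        raise ValidationError(
            f"need >= 2 samples per age group (young={len(young_ids)}, old={len(old_ids)})"
        )
    ym = gene_matrix[young_ids].mean(axis=1)
    om = gene_matrix[old_ids].mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tt = stats.ttest_ind(
            gene_matrix[old_ids], gene_matrix[young_ids], axis=1, equal_var=False,
            nan_policy="omit",
        )
    out = pd.DataFrame(
        {
            "young_mean": ym,
            "old_mean": om,
            "difference": om - ym,
            "p_value": tt.pvalue,
        },
        index=gene_matrix.index,
    )
    out = out[(out["difference"] > 0) & (out["p_value"] < p_max)]
    out = out.assign(gene=out.index).sort_values(
        ["difference", "gene"], ascending=[False, True]
    ).drop(columns="gene").head(top_k)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def gene_age_correlation(gene_matrix: pd.DataFrame, ages) -> pd.DataFrame:
    """Per-gene Pearson r between promoter methylation and age, with the
    least-squares line."""
    ages = np.asarray(ages, dtype=float)
    if gene_matrix.shape[1] != len(ages):
        raise ValidationError("ages length does not match sample axis")
    if len(ages) < 3:
        raise ValidationError("need at least 3 samples")
    rows = []
    for gene, vals in gene_matrix.iterrows():
        v = vals.to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() < 3 or np.std(v[ok]) == 0 or np.std(ages[ok]) == 0:
            warnings.warn(f"gene {gene}: correlation undefined")
            rows.append((gene, np.nan, np.nan, np.nan, int(ok.sum())))
            continue
        r = float(stats.pearsonr(ages[ok], v[ok])[0])
        slope, intercept = np.polyfit(ages[ok], v[ok], 1)
        rows.append((gene, r, float(slope), float(intercept), int(ok.sum())))
    return pd.DataFrame(
        rows, columns=["gene_id", "pearson_r", "slope", "intercept", "n_used"]
    ).set_index("gene_id")


def detect_nv_outliers(
    ds: MethylationDataset,
    ann: ProbeAnnotation,
    high_conf_probes: Sequence[str] | None = None,
    z_max: float = 3.5,
    mad_floor: float = 0.01,
) -> pd.DataFrame:
    """Flag (sample, nv-probe) cells with extreme robust z-scores.

    For each non-variable probe the across-sample median and MAD are
    computed; a cell is flagged when |0.6745·(β − median)/MAD| strictly
    exceeds ``z_max``.  Probes with MAD below ``mad_floor`` use the floor so
    near-constant probes still yield finite scores.
    """
    nv = pd.Index(ann.nv_probe_ids())
    if high_conf_probes is not None:
        nv = nv.intersection(pd.Index(high_conf_probes))
    nv = nv.intersection(ds.probe_ids)
    if ds.n_samples < 5:
        raise ValidationError("need at least 5 samples for robust nv statistics")
    rows = []
    for probe in nv:
        v = ds.betas.loc[probe].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if ok.sum() < 5:
            continue
        med = float(np.median(v[ok]))
        mad = float(np.median(np.abs(v[ok] - med)))
        mad = max(mad, mad_floor)
        z = 0.6745 * (v - med) / mad
        hits = np.flatnonzero(np.abs(z) > z_max)
        for j in hits:
            rows.append((ds.sample_ids[j], probe, float(v[j]), med, mad, float(z[j])))
    return pd.DataFrame(
        rows, columns=["sample_id", "probe_id", "beta", "median", "mad", "robust_z"]
    )
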