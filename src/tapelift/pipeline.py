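"""Configuration-driven orchestration of the full analysis workflow.

``run_pipeline`` executes, in fixed order: cohort generation (or loading),
sample integrity and detection gates, serial probe subsetting, per-CpG age
association, clock training/evaluation (direct and PC variants), marker
analyses (mitotic age, TSG hypermethylation, nv outliers) and tissue-identity
checks.  Every stage logs its inputs, outputs and thresholds into a JSON run
report, and all randomness derives from the single mandatory config seed, so
re-running an identical configuration reproduces all numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import agestats as ag
from . import clocks as ck
from . import identity as idm
from . import markers as mk
from . import qc as qcm
from .datasets import ValidationError, write_dataset, write_annotation
from .simulate import DegradationModel, SynthConfig, generate_annotation, generate_cohort, generate_reference_panels

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


@dataclass
class ClockSettings:
    split_fraction: float = 0.8
    direct_alpha: float = 0.1
    pc_alpha: float = 0.5
    n_folds: int = 10
    n_lambdas: int = 50


@dataclass
class AgeStatsSettings:
    q_threshold: float = 0.01
    top_k: int = 1000


@dataclass
class MarkerSettings:
    young: tuple[float, float] = (18.0, 29.0)
    old_min: float = 60.0
    top_k: int = 50
    min_probes: int = 2
    z_max: float = 3.5
    quantile: float = 0.95


@dataclass
class IdentitySettings:
    top_n: int = 25
    n_components: int = 2


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str = "tapelift_run"
    synth: SynthConfig = field(default_factory=SynthConfig)
    thresholds: qcm.QcThresholds = field(default_factory=qcm.QcThresholds)
    agestats: AgeStatsSettings = field(default_factory=AgeStatsSettings)
    clocks: ClockSettings = field(default_factory=ClockSettings)
    markers: MarkerSettings = field(default_factory=MarkerSettings)
    identity: IdentitySettings = field(default_factory=IdentitySettings)
    write_matrices: bool = False


def _build(section_cls, data: dict, errors: list[str], path: str):
    known = {f.name for f in dataclasses.fields(section_cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            errors.append(f"{path}.{key}: unknown field")
            continue
        kwargs[key] = value
    try:
        return section_cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{path}: {exc}")
        return None


def config_from_dict(data: dict) -> tuple[PipelineConfig | None, list[str]]:
    errors: list[str] = []
    if "seed" not in data:
        errors.append("seed: required field is missing")
    synth_data = dict(data.get("synth", {}))
    synth_data.setdefault("seed", data.get("seed", 0))
    if "degradation" in synth_data and isinstance(synth_data["degradation"], dict):
        synth_data["degradation"] = DegradationModel(**synth_data["degradation"])
    for tup_key in ("age_range", "age_slope_range", "mitotic_rate_range",
                    "probes_per_promoter", "tsg_gain_range", "replicate_design",
                    "cell_types", "reference_tissues"):
        if tup_key in synth_data and isinstance(synth_data[tup_key], list):
            synth_data[tup_key] = tuple(synth_data[tup_key])
    synth = _build(SynthConfig, synth_data, errors, "synth")
    if synth is not None:
        try:
            synth.validate()
        except ValidationError as exc:
            errors.append(f"synth: {exc}")
    thresholds = _build(qcm.QcThresholds, dict(data.get("thresholds", {})), errors, "thresholds")
    agestats_s = _build(AgeStatsSettings, dict(data.get("agestats", {})), errors, "agestats")
    clocks_data = dict(data.get("clocks", {}))
    clocks_s = _build(ClockSettings, clocks_data, errors, "clocks")
    if clocks_s is not None:
        if not 0.0 < clocks_s.split_fraction < 1.0:
            errors.append("clocks.split_fraction: must be in (0, 1)")
        for name in ("direct_alpha", "pc_alpha"):
            v = getattr(clocks_s, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"clocks.{name}: must be in [0, 1], got {v}")
    markers_data = dict(data.get("markers", {}))
    if "young" in markers_data and isinstance(markers_data["young"], list):
        markers_data["young"] = tuple(markers_data["young"])
    markers_s = _build(MarkerSettings, markers_data, errors, "markers")
    identity_s = _build(IdentitySettings, dict(data.get("identity", {})), errors, "identity")
    if errors:
        return None, errors
    return (
        PipelineConfig(
            seed=int(data["seed"]),
            out_dir=str(data.get("out_dir", "tapelift_run")),
            synth=synth,
            thresholds=thresholds,
            agestats=agestats_s,
            clocks=clocks_s,
            markers=markers_s,
            identity=identity_s,
            write_matrices=bool(data.get("write_matrices", False)),
        ),
        [],
    )


def validate_config(path: str | Path) -> tuple[PipelineConfig | None, list[str]]:
    """Parse and validate a YAML pipeline config; returns (config, errors)."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except Exception as exc:
        return None, [f"config file: {exc}"]
    if not isinstance(data, dict):
        return None, ["config file: top level must be a mapping"]
    return config_from_dict(data)


def _child_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the workflow and return (and write) the run report."""
    t0 = time.time()
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "seed": cfg.seed,
        "thresholds": dataclasses.asdict(cfg.thresholds),
        "settings": {
            "agestats": dataclasses.asdict(cfg.agestats),
            "clocks": dataclasses.asdict(cfg.clocks),
            "markers": dataclasses.asdict(cfg.markers),
            "identity": dataclasses.asdict(cfg.identity),
        },
        "stages": {},
    }

    def stage(name: str, **info) -> None:
        report["stages"][name] = {"status": "ok", **info}

    def skip(name: str, reason: str) -> None:
        report["stages"][name] = {"status": "skipped", "reason": reason}

    # 1. data ---------------------------------------------------------------
    ann = generate_annotation(cfg.synth)
    ds, truth = generate_cohort(cfg.synth, ann)
    panels = generate_reference_panels(cfg.synth, ann)
    stage("simulate", n_probes=ds.n_probes, n_samples=ds.n_samples,
          n_reference_panels=len(panels))
    if cfg.write_matrices:
        write_dataset(ds, out / "dataset")
        write_annotation(ann, out / "annotation")
        truth.write(out / "truth")

    main_ids = ds.samples.index[ds.samples["cohort"] == "main"].tolist()
    rep_ids = ds.samples.index[ds.samples["cohort"] == "replicate"].tolist()
    thr = cfg.thresholds
    thr_relaxed = thr.relaxed()

    # 2. sample gates -------------------------------------------------------
    main_meta = ds.samples.loc[main_ids]
    rep_meta = ds.samples.loc[rep_ids]
    main_int, _ = qcm.gate_samples_by_integrity(main_meta, thr)
    rep_int, _ = qcm.gate_samples_by_integrity(rep_meta, thr_relaxed)
    stage("integrity_gate",
          main_in=len(main_ids), main_retained=len(main_int),
          replicate_in=len(rep_ids), replicate_retained=len(rep_int))

    main_det, main_frac = (
        qcm.qc_samples_by_detection(ds.subset(sample_ids=main_int), thr)
        if main_int else ([], pd.Series(dtype=float))
    )
    rep_det, _ = (
        qcm.qc_samples_by_detection(ds.subset(sample_ids=rep_int), thr_relaxed)
        if rep_int else ([], pd.Series(dtype=float))
    )
    stage("detection_gate",
          main_in=len(main_int), main_retained=len(main_det),
          replicate_in=len(rep_int), replicate_retained=len(rep_det))

    if len(main_det) < 3:
        reason = (
            "no main-cohort samples passed the sample gates"
            if not main_det
            else f"only {len(main_det)} main-cohort samples passed the sample gates"
        )
        for name in ("probe_subsetting", "age_association", "clocks", "markers", "identity"):
            skip(name, reason)
        report["runtime_seconds"] = round(time.time() - t0, 3)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        return report

    main_ds = ds.subset(sample_ids=main_det)

    # 3. probe subsetting ---------------------------------------------------
    note = None
    if len(rep_det) >= 2:
        rep_ds = ds.subset(sample_ids=rep_det)
        design = {d: g.index.tolist() for d, g in rep_ds.samples.groupby("donor_id")
                  if len(g) >= 2}
        rep_ds = rep_ds.subset(sample_ids=[s for ids in design.values() for s in ids])
        filt = qcm.subset_pipeline(main_ds, rep_ds, ann, thr, design=design)
    else:
        note = "replicate cohort unavailable; annotation + detection filters only"
        retained, stages = qcm.filter_annotation_probes(ann, probe_ids=main_ds.probe_ids.tolist())
        from .datasets import FilterReport
        filt = FilterReport()
        for name, criterion, n_in, n_out in stages:
            filt.add_stage(name, criterion, n_in, n_out)
        n_in = len(retained)
        retained = qcm.filter_detection_all([main_ds.subset(probe_ids=retained)], thr)
        filt.add_stage("detection_all",
                       f"retain probes with detection p < {thr.detp_threshold} in all cells",
                       n_in, len(retained))
        filt.final_probe_ids = retained
    filt.write(out / "filter")
    high_conf = filt.final_probe_ids
    stage("probe_subsetting",
          stages=[dataclasses.asdict(s) for s in filt.stages],
          n_high_confidence=len(high_conf), note=note)

    if not high_conf:
        for name in ("age_association", "clocks", "markers", "identity"):
            skip(name, "no probes survived subsetting")
        report["runtime_seconds"] = round(time.time() - t0, 3)
        (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
        return report

    hc_ds = main_ds.subset(probe_ids=high_conf)
    ages = pd.to_numeric(hc_ds.samples["age"]).to_numpy()

    # 4. age association ----------------------------------------------------
    assoc = ag.age_association(hc_ds.betas, ages)
    assoc.to_csv(out / "age_association.tsv", sep="\t")
    top = ag.select_age_probes(assoc, hc_ds.betas,
                               q_threshold=cfg.agestats.q_threshold,
                               top_k=cfg.agestats.top_k)
    n_sig = int((assoc["q_value"] < cfg.agestats.q_threshold).sum())
    if top:
        z = ag.zscore_rows(hc_ds.betas.loc[top])
        order = np.argsort(ages, kind="stable")
        z.iloc[:, order].to_csv(out / "top_age_probes_zscores.tsv", sep="\t")
    stage("age_association", n_probes=len(assoc), n_significant=n_sig,
          n_selected=len(top), d0=float(assoc["d0"].iloc[0]))

    # 5. clocks -------------------------------------------------------------
    clock_metrics: dict[str, Any] = {}
    if hc_ds.n_samples >= max(5, cfg.clocks.n_folds + 1) and len(high_conf) >= 2:
        split = ck.split_train_test(hc_ds.sample_ids, cfg.clocks.split_fraction,
                                    seed=_child_seed(cfg.seed, 10))
        train_b = hc_ds.betas[list(split.train)]
        test_b = hc_ds.betas[list(split.test)]
        ages_s = pd.to_numeric(hc_ds.samples["age"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            direct = ck.train_direct_clock(
                train_b, ages_s[list(split.train)], alpha=cfg.clocks.direct_alpha,
                n_folds=cfg.clocks.n_folds, seed=_child_seed(cfg.seed, 11),
                n_lambdas=cfg.clocks.n_lambdas)
            pc = ck.train_pc_clock(
                train_b, ages_s[list(split.train)], alpha=cfg.clocks.pc_alpha,
                n_folds=cfg.clocks.n_folds, seed=_child_seed(cfg.seed, 12),
                n_lambdas=cfg.clocks.n_lambdas)
        for name, model in (("direct", direct), ("pc", pc)):
            pred_test, _ = ck.predict_age(model, hc_ds.subset(sample_ids=list(split.test)))
            ev = ck.evaluate_clock(pred_test, ages_s[list(split.test)])
            clock_metrics[name] = {
                "train_rmse": model.training_metrics.get("rmse"),
                "train_pearson_r": model.training_metrics.get("pearson_r"),
                "test_rmse": ev.rmse,
                "test_pearson_r": ev.pearson_r,
                "n_active_cpgs": model.n_active_cpgs,
                "penalty_lambda": model.penalty_lambda,
            }
            ck.save_clock(model, out / f"clock_{name}")
        stage("clocks", n_train=len(split.train), n_test=len(split.test),
              **clock_metrics)
    else:
        skip("clocks", "too few samples or probes after QC")

    # 6. markers ------------------------------------------------------------
    marker_info: dict[str, Any] = {}
    tmp = truth.mitotic_probes
    usable_mito = [p for p in tmp["probe_id"] if p in set(high_conf)]
    if usable_mito:
        sub = tmp.set_index("probe_id").loc[usable_mito]
        rn_def = mk.MitoticClockDefinition(
            name="synthetic-rate-clock", probe_ids=usable_mito,
            aggregation="rate_normalized_mean",
            ground_state=sub["base"].to_numpy(), rate=sub["rate"].to_numpy())
        uq_def = mk.MitoticClockDefinition(
            name="synthetic-quantile-clock", probe_ids=usable_mito,
            aggregation="upper_quantile", quantile=cfg.markers.quantile)
        for deff in (rn_def, uq_def):
            score, cov = mk.estimate_mitotic_age(hc_ds, deff, high_conf)
            marker_info[deff.aggregation] = {
                "coverage": cov["coverage"],
                "pearson_r_vs_age": (
                    float(np.corrcoef(score.to_numpy(), ages)[0, 1])
                    if score.std() > 0 else None),
            }
            score.rename_axis("sample_id").to_csv(
                out / f"mitotic_{deff.aggregation}.tsv", sep="\t")
    gene_mat = mk.mean_promoter_methylation(hc_ds, ann, high_conf,
                                            min_probes=cfg.markers.min_probes)
    tsg_table = pd.DataFrame()
    if not gene_mat.empty:
        try:
            tsg_table = mk.rank_tsg_hypermethylation(
                gene_mat, hc_ds.samples, young=cfg.markers.young,
                old_min=cfg.markers.old_min, top_k=cfg.markers.top_k)
            tsg_table.to_csv(out / "tsg_hypermethylation.tsv", sep="\t")
        except ValidationError as exc:
            marker_info["tsg_error"] = str(exc)
    nv_flags = mk.detect_nv_outliers(hc_ds, ann, high_conf, z_max=cfg.markers.z_max)
    nv_flags.to_csv(out / "nv_outliers.tsv", sep="\t", index=False)
    marker_info.update(n_tsg_genes=int(gene_mat.shape[0]),
                       n_tsg_ranked=int(len(tsg_table)),
                       n_nv_flags=int(len(nv_flags)))
    stage("markers", **marker_info)

    # 7. identity -----------------------------------------------------------
    try:
        emb = idm.pca_embed([hc_ds] + panels, probe_set=high_conf,
                            n_components=cfg.identity.n_components)
        emb.coordinates.assign(tissue=emb.tissue_labels).to_csv(
            out / "pca_embedding.tsv", sep="\t")
        clus = idm.marker_correlation_cluster([hc_ds] + panels, ann,
                                              top_n=cfg.identity.top_n)
        (out / "dendrogram.nwk").write_text(clus.newick + "\n")
        comp = idm.compartment_distribution(high_conf, ann)
        comp.to_csv(out / "compartments.tsv", sep="\t")
        stage("identity",
              explained_variance=[float(v) for v in emb.explained_variance_ratio],
              n_marker_samples=len(clus.sample_ids),
              n_states=int(len(comp)))
    except ValidationError as exc:
        skip("identity", str(exc))

    report["runtime_seconds"] = round(time.time() - t0, 3)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
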