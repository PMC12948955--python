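"""Sample quality gates and serial high-confidence probe subsetting.

Two sample-level gates run before any probe work:

* a gDNA-integrity gate on the qPCR ΔCt value (strictly below 3 cycles for
  the main cohort; inclusively ≤ 3.5 for the relaxed replicate cohorts), and
* a post-array detection gate retaining samples in which at least 75% (70%
  relaxed) of probes have a detection p-value strictly below 0.05.

Probe subsetting then proceeds serially: SNP-overlapping probes, sex-
chromosome probes and cross-reactive probes are removed in that order; probes
with high intra-individual replicate variance (sample variance > 0.1 in the
replicate sets of at least two donors) are dropped; finally only probes
detected (p < 0.05, non-missing) in every cell of every dataset are retained.
Each stage is recorded in a :class:`~tapelift.datasets.FilterReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    AxisMismatchError,
    FilterReport,
    MethylationDataset,
    ProbeAnnotation,
    ValidationError,
)

__all__ = [
    "QcThresholds",
    "gate_samples_by_integrity",
    "qc_samples_by_detection",
    "filter_annotation_probes",
    "filter_replicate_variance",
    "filter_detection_all",
    "subset_pipeline",
]


@dataclass(frozen=True)
class QcThresholds:
    """Numeric gates of the QC workflow.

    ``delta_ct_comparator`` is ``"lt"`` (strict, main cohort) or ``"le"``
    (inclusive, relaxed cohorts).  The detection boundary is always strict:
    a cell with p exactly 0.05 counts as *not* detected.
    """

    delta_ct_max: float = 3.0
    delta_ct_comparator: str = "lt"
    detp_threshold: float = 0.05
    min_detected_fraction: float = 0.75
    variance_threshold: float = 0.1
    min_flagged_donors: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.min_detected_fraction <= 1.0:
            raise ValidationError("min_detected_fraction must be in (0, 1]")
        if self.delta_ct_comparator not in ("lt", "le"):
            raise ValidationError("delta_ct_comparator must be 'lt' or 'le'")
        if self.delta_ct_max < 0 or self.detp_threshold < 0 or self.variance_threshold < 0:
            raise ValidationError("thresholds must be non-negative")

    def relaxed(self) -> "QcThresholds":
        """The relaxed variant used for the replicate cohorts."""
        return replace(
            self,
            delta_ct_max=3.5,
            delta_ct_comparator="le",
            min_detected_fraction=0.70,
        )


def gate_samples_by_integrity(
    samples: pd.DataFrame,
    thr: QcThresholds,
    pregated_cohorts: Sequence[str] = ("reference", "independent"),
) -> tuple[list[str], pd.DataFrame]:
    """Retain samples whose gDNA ΔCt passes the integrity gate.

    Samples with a missing ΔCt are retained only when their ``cohort`` label
    is in ``pregated_cohorts`` (data already QC'd upstream).  Negative ΔCt is
    a validation error.

    Returns ``(retained_sample_ids, report)`` where the report has one row
    per sample with its ΔCt and retention decision.
    """
    dct = pd.to_numeric(samples.get("delta_ct", pd.Series(np.nan, index=samples.index)),
                        errors="coerce")
    if (dct.dropna() < 0).any():
        bad = dct.index[dct < 0].tolist()
        raise ValidationError(f"negative delta_ct for samples {bad[:5]}")
    cohort = samples.get("cohort", pd.Series("main", index=samples.index)).astype(str)
    if thr.delta_ct_comparator == "lt":
        passes = dct < thr.delta_ct_max
    else:
        passes = dct <= thr.delta_ct_max
    pregated = dct.isna() & cohort.isin(list(pregated_cohorts))
    retained = passes.fillna(False) | pregated
    report = pd.DataFrame(
        {
            "delta_ct": dct,
            "cohort": cohort,
            "pregated": pregated,
            "retained": retained,
        }
    )
    return samples.index[retained].tolist(), report


def qc_samples_by_detection(
    ds: MethylationDataset, thr: QcThresholds
) -> tuple[list[str], pd.Series]:
    """Retain samples with at least ``min_detected_fraction`` detected probes.

    A probe-sample cell is detected iff its detection p-value is non-missing
    and strictly below ``detp_threshold``; the fraction is taken over all
    probes.  The boundary is inclusive on the fraction (exactly 75% passes).
    """
    detected = (ds.detection_p < thr.detp_threshold).fillna(False)
    fraction = detected.sum(axis=0) / ds.n_probes
    retained = fraction >= thr.min_detected_fraction
    return ds.sample_ids[retained].tolist(), fraction.rename("detected_fraction")


_ANNOTATION_STAGES = (
    ("snp_overlap", "remove probes overlapping known SNPs"),
    ("sex_chromosomes", "remove probes on chromosomes X/Y"),
    ("cross_reactive", "remove cross-reactive probes"),
)


def filter_annotation_probes(
    ann: ProbeAnnotation, probe_ids: Sequence[str] | None = None
) -> tuple[list[str], list[tuple[str, str, int, int]]]:
    """Serially drop SNP-overlap, sex-chromosome and cross-reactive probes.

    Returns the retained probe ids (annotation order) and per-stage counts
    ``(stage, criterion, n_in, n_out)``.  The result is order-independent (the
    three criteria intersect) but counts reflect the serial order above.
    """
    ann.validate_chromosomes()
    table = ann.table if probe_ids is None else ann.table.loc[list(probe_ids)]
    masks = {
        "snp_overlap": table["snp_overlap"].astype(bool),
        "sex_chromosomes": table["chromosome"].astype(str).isin(["X", "Y", "chrX", "chrY"]),
        "cross_reactive": table["cross_reactive"].astype(bool),
    }
    keep = pd.Series(True, index=table.index)
    stages = []
    for name, criterion in _ANNOTATION_STAGES:
        n_in = int(keep.sum())
        keep &= ~masks[name]
        stages.append((name, criterion, n_in, int(keep.sum())))
    return table.index[keep].tolist(), stages


def filter_replicate_variance(
    ds: MethylationDataset,
    design: Mapping[str, Sequence[str]],
    thr: QcThresholds,
) -> tuple[list[str], pd.Series]:
    """Drop probes with high intra-donor replicate variance.

    For each probe and donor the unbiased (n−1) sample variance of the
    donor's replicate β values is computed; the (probe, donor) pair is
    flagged when the variance strictly exceeds ``variance_threshold``.  A
    probe is dropped when flagged in at least ``min_flagged_donors`` donors.
    A donor whose replicate values contain a missing β contributes no flag
    for that probe.

    Returns the retained probe ids and the per-probe flagged-donor count.
    """
    flags = pd.Series(0, index=ds.probe_ids)
    for donor, sample_ids in design.items():
        sample_ids = list(sample_ids)
        if len(sample_ids) < 2:
            raise ValidationError(f"donor {donor!r} has fewer than 2 replicates")
        vals = ds.betas[sample_ids]
        has_missing = vals.isna().any(axis=1)
        var = vals.var(axis=1, ddof=1)
        flags += ((var > thr.variance_threshold) & ~has_missing).astype(int)
    keep = flags < thr.min_flagged_donors
    return ds.probe_ids[keep].tolist(), flags.rename("n_flagged_donors")


def filter_detection_all(
    ds_list: Sequence[MethylationDataset], thr: QcThresholds
) -> list[str]:
    """Retain probes detected (p < threshold, non-missing) in every cell of
    every dataset."""
    if not ds_list:
        raise ValidationError("filter_detection_all needs at least one dataset")
    probes = ds_list[0].probe_ids
    keep = pd.Series(True, index=probes)
    for ds in ds_list:
        if set(ds.probe_ids) != set(probes):
            raise AxisMismatchError("datasets do not share a probe axis")
        detected = (ds.detection_p < thr.detp_threshold).fillna(False)
        keep &= detected.all(axis=1).reindex(probes)
    return probes[keep].tolist()


def subset_pipeline(
    main_ds: MethylationDataset,
    replicate_ds: MethylationDataset,
    ann: ProbeAnnotation,
    thr: QcThresholds,
    design: Mapping[str, Sequence[str]] | None = None,
) -> FilterReport:
    """Serial high-confidence probe subsetting.

    Order: annotation filters (SNP → sex chromosomes → cross-reactive) →
    replicate-variance filter on ``replicate_ds`` → detection filter across
    both datasets.  ``design`` maps replicate donors to their sample ids; by
    default it is derived from ``replicate_ds.samples["donor_id"]``.
    """
    if set(main_ds.probe_ids) != set(replicate_ds.probe_ids):
        raise AxisMismatchError("main and replicate datasets do not share probes")
    missing_ann = main_ds.probe_ids.difference(ann.probe_ids).tolist()
    if missing_ann:
        raise ValidationError(f"probes without annotation: {missing_ann[:5]}")
    if design is None:
        design = {
            donor: grp.index.tolist()
            for donor, grp in replicate_ds.samples.groupby("donor_id")
        }

    report = FilterReport()
    retained, ann_stages = filter_annotation_probes(
        ann, probe_ids=main_ds.probe_ids.tolist()
    )
    for name, criterion, n_in, n_out in ann_stages:
        report.add_stage(name, criterion, n_in, n_out)

    rep_sub = replicate_ds.subset(probe_ids=retained)
    n_in = len(retained)
    retained, _ = filter_replicate_variance(rep_sub, design, thr)
    report.add_stage(
        "replicate_variance",
        f"drop probes with replicate beta variance > {thr.variance_threshold} "
        f"in >= {thr.min_flagged_donors} donors",
        n_in,
        len(retained),
    )

    n_in = len(retained)
    retained = filter_detection_all(
        [main_ds.subset(probe_ids=retained), replicate_ds.subset(probe_ids=retained)],
        thr,
    )
    report.add_stage(
        "detection_all",
        f"retain probes with detection p < {thr.detp_threshold} in all cells of all datasets",
        n_in,
        len(retained),
    )
    report.final_probe_ids = retained
    return report
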