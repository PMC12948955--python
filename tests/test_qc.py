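"""Sample gates, serial probe filters, and oracle equivalence checks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tapelift.datasets import MethylationDataset, ProbeAnnotation, ValidationError
from tapelift.qc import (
    QcThresholds,
    filter_annotation_probes,
    filter_detection_all,
    filter_replicate_variance,
    gate_samples_by_integrity,
    qc_samples_by_detection,
    subset_pipeline,
)


def _meta(delta_cts, cohort="main"):
    return pd.DataFrame(
        {"delta_ct": delta_cts, "cohort": cohort},
        index=pd.Index([f"s{i}" for i in range(len(delta_cts))], name="sample_id"),
    )


class TestIntegrityGate:
    def test_strict_boundary_excludes_equal(self):
        ids, _ = gate_samples_by_integrity(_meta([1.3, 2.9, 3.0, 4.0]), QcThresholds())
        assert ids == ["s0", "s1"]

    def test_relaxed_inclusive_boundary(self):
        thr = QcThresholds().relaxed()
        assert thr.delta_ct_max == 3.5 and thr.delta_ct_comparator == "le"
        ids, _ = gate_samples_by_integrity(_meta([3.2, 3.5, 3.6]), thr)
        assert ids == ["s0", "s1"]

    def test_empty_cohort(self):
        ids, report = gate_samples_by_integrity(_meta([]), QcThresholds())
        assert ids == [] and len(report) == 0

    def test_negative_delta_ct_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            gate_samples_by_integrity(_meta([-0.1]), QcThresholds())

    def test_missing_delta_ct_only_kept_if_pregated(self):
        meta = _meta([np.nan, np.nan])
        meta["cohort"] = ["main", "reference"]
        ids, _ = gate_samples_by_integrity(meta, QcThresholds())
        assert ids == ["s1"]


def _detection_ds(p_matrix):
    p = pd.DataFrame(p_matrix)
    p.index = [f"p{i}" for i in range(p.shape[0])]
    p.columns = [f"s{i}" for i in range(p.shape[1])]
    betas = pd.DataFrame(0.5, index=p.index, columns=p.columns)
    meta = pd.DataFrame({"cohort": "main"}, index=p.columns)
    return MethylationDataset(betas, p, meta)


class TestDetectionGate:
    @pytest.mark.parametrize("n_detected,expect_kept", [(75, True), (74, False)])
    def test_75_percent_boundary(self, n_detected, expect_kept):
        col = [0.01] * n_detected + [0.5] * (100 - n_detected)
        ds = _detection_ds(np.array(col).reshape(-1, 1))
        ids, frac = qc_samples_by_detection(ds, QcThresholds())
        assert frac.iloc[0] == pytest.approx(n_detected / 100)
        assert (ids == ["s0"]) is expect_kept

    def test_p_exactly_005_not_detected(self):
        ds = _detection_ds(np.array([[0.05], [0.01]]))
        _, frac = qc_samples_by_detection(ds, QcThresholds())
        assert frac.iloc[0] == 0.5

    def test_missing_p_counts_as_not_detected(self):
        ds = _detection_ds(np.array([[np.nan], [0.01]]))
        _, frac = qc_samples_by_detection(ds, QcThresholds())
        assert frac.iloc[0] == 0.5


class TestAnnotationFilter:
    def test_serial_counts(self):
        table = pd.DataFrame(
            {
                "chromosome": ["chr1", "chrX", "chr2", "chr3", "chr5"],
                "snp_overlap": [True, False, False, False, False],
                "cross_reactive": [False, False, True, False, False],
            },
            index=[f"p{i}" for i in range(5)],
        )
        ann = ProbeAnnotation(table=table)
        kept, stages = filter_annotation_probes(ann)
        assert kept == ["p3", "p4"]
        assert [(s[2], s[3]) for s in stages] == [(5, 4), (4, 3), (3, 2)]

    def test_no_flags_identity(self, toy_annotation):
        clean = toy_annotation.table.copy()
        clean["snp_overlap"] = False
        clean["cross_reactive"] = False
        clean["chromosome"] = "chr1"
        kept, _ = filter_annotation_probes(ProbeAnnotation(table=clean))
        assert kept == list(clean.index)

    def test_double_flagged_probe_removed_at_snp_stage(self):
        table = pd.DataFrame(
            {
                "chromosome": ["chr1", "chr2"],
                "snp_overlap": [True, False],
                "cross_reactive": [True, False],
            },
            index=["p0", "p1"],
        )
        kept, stages = filter_annotation_probes(ProbeAnnotation(table=table))
        assert kept == ["p1"]
        # cross-reactive stage sees no additional removal
        assert stages[2][2] == stages[2][3] == 1

    def test_order_invariance_of_final_set(self, small_cohort):
        """The retained set is an intersection, so criterion order cannot
        change it (only the per-stage counts)."""
        _, _, ann = small_cohort
        kept, _ = filter_annotation_probes(ann)
        table = ann.table
        masks = [
            table["snp_overlap"].astype(bool),
            table["chromosome"].isin(["chrX", "chrY", "X", "Y"]),
            table["cross_reactive"].astype(bool),
        ]
        for perm in itertools.permutations(masks):
            keep = pd.Series(True, index=table.index)
            for m in perm:
                keep &= ~m
            assert set(table.index[keep]) == set(kept)

    def test_unknown_chromosome_rejected(self):
        table = pd.DataFrame(
            {"chromosome": ["chrx7"], "snp_overlap": [False], "cross_reactive": [False]},
            index=["p0"],
        )
        with pytest.raises(ValidationError, match="chromosome"):
            filter_annotation_probes(ProbeAnnotation(table=table))


def _replicate_ds(values, donors):
    """values: probe × sample array; donors: list mapping samples to donors."""
    arr = np.asarray(values, dtype=float)
    cols = [f"s{i}" for i in range(arr.shape[1])]
    betas = pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])], columns=cols)
    detp = pd.DataFrame(0.01, index=betas.index, columns=cols)
    meta = pd.DataFrame({"donor_id": donors, "cohort": "replicate"}, index=cols)
    ds = MethylationDataset(betas, detp, meta)
    design = {d: [c for c, dd in zip(cols, donors) if dd == d] for d in set(donors)}
    return ds, design


class TestReplicateVariance:
    def test_hand_computed_variance_flags(self):
        # var([0.1, 0.9, 0.1], ddof=1) = 0.2133... > 0.1 → flagged
        ds, design = _replicate_ds([[0.1, 0.9, 0.1]], ["d1", "d1", "d1"])
        kept, flags = filter_replicate_variance(ds, design, QcThresholds(min_flagged_donors=1))
        assert kept == []
        assert np.var([0.1, 0.9, 0.1], ddof=1) == pytest.approx(0.21333333, abs=1e-6)

    def test_single_flagged_donor_retained(self):
        vals = [[0.1, 0.9, 0.1, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]]
        donors = ["d1"] * 3 + ["d2"] * 3 + ["d3"] * 3 + ["d4"] * 3
        ds, design = _replicate_ds(vals, donors)
        kept, flags = filter_replicate_variance(ds, design, QcThresholds())
        assert kept == ["p0"] and flags.iloc[0] == 1

    def test_two_flagged_donors_dropped(self):
        vals = [[0.1, 0.9, 0.1, 0.9, 0.1, 0.9, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5]]
        donors = ["d1"] * 3 + ["d2"] * 3 + ["d3"] * 3 + ["d4"] * 3
        ds, design = _replicate_ds(vals, donors)
        kept, _ = filter_replicate_variance(ds, design, QcThresholds())
        assert kept == []

    def test_identical_values_never_flagged(self):
        ds, design = _replicate_ds([[0.4, 0.4, 0.4]], ["d1"] * 3)
        kept, flags = filter_replicate_variance(ds, design, QcThresholds(min_flagged_donors=1))
        assert kept == ["p0"] and flags.iloc[0] == 0

    def test_missing_beta_suppresses_donor_flag(self):
        ds, design = _replicate_ds([[0.1, np.nan, 0.9]], ["d1"] * 3)
        kept, flags = filter_replicate_variance(ds, design, QcThresholds(min_flagged_donors=1))
        assert kept == ["p0"] and flags.iloc[0] == 0

    def test_single_replicate_donor_rejected(self):
        ds, design = _replicate_ds([[0.1, 0.2]], ["d1", "d2"])
        with pytest.raises(ValidationError, match="fewer than 2"):
            filter_replicate_variance(ds, design, QcThresholds())


class TestDetectionAll:
    def test_all_below_threshold_retained(self):
        ds = _detection_ds(np.array([[0.01, 0.04]]))
        assert filter_detection_all([ds], QcThresholds()) == ["p0"]

    def test_single_failing_cell_drops_probe(self):
        p = np.full((1, 100), 0.01)
        p[0, 57] = 0.06
        ds = _detection_ds(p)
        assert filter_detection_all([ds], QcThresholds()) == []

    def test_missing_p_drops_probe(self):
        p = np.array([[0.01, np.nan]])
        ds = _detection_ds(p)
        assert filter_detection_all([ds], QcThresholds()) == []


def _random_fixture(rng, n_probes, n_samples):
    """Random main + replicate datasets and annotation for oracle testing."""
    probes = [f"p{i}" for i in range(n_probes)]
    main_cols = [f"m{i}" for i in range(n_samples)]
    rep_cols = [f"r{d}-{k}" for d in range(4) for k in range(3)]
    betas = pd.DataFrame(rng.random((n_probes, n_samples)), index=probes, columns=main_cols)
    detp = pd.DataFrame(
        rng.choice([0.01, 0.03, 0.2], p=[0.8, 0.15, 0.05], size=(n_probes, n_samples)),
        index=probes, columns=main_cols,
    )
    main_meta = pd.DataFrame({"donor_id": main_cols, "cohort": "main"}, index=main_cols)
    main = MethylationDataset(betas, detp, main_meta)

    rep_betas = pd.DataFrame(
        np.clip(rng.random((n_probes, 1)) + rng.normal(0, 0.2, (n_probes, 12)), 0, 1),
        index=probes, columns=rep_cols,
    )
    rep_detp = pd.DataFrame(
        rng.choice([0.01, 0.2], p=[0.93, 0.07], size=(n_probes, 12)),
        index=probes, columns=rep_cols,
    )
    donors = [c.split("-")[0] for c in rep_cols]
    rep_meta = pd.DataFrame({"donor_id": donors, "cohort": "replicate"}, index=rep_cols)
    rep = MethylationDataset(rep_betas, rep_detp, rep_meta)

    table = pd.DataFrame(
        {
            "chromosome": rng.choice(["chr1", "chr2", "chrX", "chrY"],
                                     p=[0.45, 0.45, 0.05, 0.05], size=n_probes),
            "snp_overlap": rng.random(n_probes) < 0.06,
            "cross_reactive": rng.random(n_probes) < 0.04,
        },
        index=probes,
    )
    return main, rep, ProbeAnnotation(table=table)


def brute_force_subset(main, rep, ann, thr):
    """Independent boolean-mask re-implementation of the serial subsetting."""
    t = ann.table
    keep = (
        ~t["snp_overlap"].astype(bool)
        & ~t["chromosome"].isin(["chrX", "chrY", "X", "Y"])
        & ~t["cross_reactive"].astype(bool)
    )
    donors = rep.samples["donor_id"]
    flags = pd.Series(0, index=rep.probe_ids)
    for d in donors.unique():
        cols = donors.index[donors == d]
        sub = rep.betas[cols]
        v = sub.var(axis=1, ddof=1)
        flags += ((v > thr.variance_threshold) & sub.notna().all(axis=1)).astype(int)
    keep &= (flags < thr.min_flagged_donors).reindex(keep.index)
    for ds in (main, rep):
        det_ok = ((ds.detection_p < thr.detp_threshold).fillna(False)).all(axis=1)
        keep &= det_ok.reindex(keep.index)
    return [p for p in main.probe_ids if keep[p]]


def test_subset_pipeline_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    thr = QcThresholds()
    for trial in range(12):
        n_probes = int(rng.integers(20, 400))
        n_samples = int(rng.integers(3, 25))
        main, rep, ann = _random_fixture(rng, n_probes, n_samples)
        report = subset_pipeline(main, rep, ann, thr)
        assert report.final_probe_ids == brute_force_subset(main, rep, ann, thr)
        # serial monotonicity: retained sets nested
        outs = [s.n_out for s in report.stages]
        ins = [s.n_in for s in report.stages]
        assert all(o <= i for o, i in zip(outs, ins))
        assert ins[1:] == outs[:-1]


def test_permissive_thresholds_retain_everything():
    rng = np.random.default_rng(7)
    main, rep, ann = _random_fixture(rng, 60, 5)
    ann.table["snp_overlap"] = False
    ann.table["cross_reactive"] = False
    ann.table["chromosome"] = "chr1"
    # fixture detection p values are all < 1.0, so threshold 1.0 passes all
    thr = QcThresholds(detp_threshold=1.0, variance_threshold=1.0, min_flagged_donors=99)
    report = subset_pipeline(main, rep, ann, thr)
    assert report.final_probe_ids == list(main.probe_ids)


def test_planted_fixture_counts(small_cohort):
    """On the synthetic cohort the annotation-stage counts equal the planted
    flag counts exactly."""
    ds, _, ann = small_cohort
    main = ds.subset(sample_ids=ds.samples.index[ds.samples["cohort"] == "main"].tolist())
    rep = ds.subset(sample_ids=ds.samples.index[ds.samples["cohort"] == "replicate"].tolist())
    report = subset_pipeline(main, rep, ann, QcThresholds())
    n = len(ann.probe_ids)
    n_snp = int(ann.table["snp_overlap"].sum())
    n_sex = int(ann.sex_chromosome_mask().sum())
    n_cross = int(ann.table["cross_reactive"].sum())
    assert report.stages[0].n_out == n - n_snp
    assert report.stages[1].n_out == n - n_snp - n_sex
    assert report.stages[2].n_out == n - n_snp - n_sex - n_cross
    assert set(report.final_probe_ids) <= set(main.probe_ids)
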