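"""Mitotic-age scoring, TSG promoter hypermethylation, nv-probe outliers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tapelift.datasets import MethylationDataset, ProbeAnnotation, ValidationError
from tapelift.markers import (
    MitoticClockDefinition,
    detect_nv_outliers,
    estimate_mitotic_age,
    gene_age_correlation,
    mean_promoter_methylation,
    rank_tsg_hypermethylation,
    tsg_sample_correlation,
)


def _ds(betas: pd.DataFrame, meta: pd.DataFrame | None = None) -> MethylationDataset:
    detp = pd.DataFrame(0.01, index=betas.index, columns=betas.columns)
    if meta is None:
        meta = pd.DataFrame({"cohort": "main"}, index=betas.columns)
    return MethylationDataset(betas, detp, meta)


class TestMitotic:
    def test_upper_quantile_hand_computed(self):
        """19 probes at 0.1 and one at 0.9: the 0.95 linear-interpolation
        quantile is 0.1 + 0.05·(0.9 − 0.1) = 0.14."""
        probes = [f"p{i}" for i in range(20)]
        vals = [0.1] * 19 + [0.9]
        betas = pd.DataFrame({"s1": vals}, index=probes)
        deff = MitoticClockDefinition("toy", probes, "upper_quantile", quantile=0.95)
        score, report = estimate_mitotic_age(_ds(betas), deff)
        assert score["s1"] == pytest.approx(0.14, abs=1e-12)
        assert report["coverage"] == 1.0

    def test_ground_state_scores_zero(self):
        probes = ["p1", "p2"]
        b0 = np.array([0.1, 0.2])
        betas = pd.DataFrame({"s1": b0}, index=probes)
        deff = MitoticClockDefinition("toy", probes, "rate_normalized_mean",
                                      ground_state=b0, rate=np.array([0.01, 0.02]))
        score, _ = estimate_mitotic_age(_ds(betas), deff)
        assert score["s1"] == 0.0

    def test_rate_normalized_closed_form(self):
        """β = β0 + rate·t·(1−β0) for every probe gives score exactly t."""
        t = 37.5
        probes = ["p1", "p2", "p3"]
        b0 = np.array([0.05, 0.1, 0.2])
        rate = np.array([0.002, 0.004, 0.001])
        beta = b0 + rate * t * (1 - b0)
        betas = pd.DataFrame({"s1": beta}, index=probes)
        deff = MitoticClockDefinition("toy", probes, "rate_normalized_mean",
                                      ground_state=b0, rate=rate)
        score, _ = estimate_mitotic_age(_ds(betas), deff)
        assert score["s1"] == pytest.approx(t, rel=1e-12)

    def test_coverage_restricted_to_high_confidence(self):
        probes = [f"p{i}" for i in range(4)]
        betas = pd.DataFrame({"s1": [0.2] * 4}, index=probes)
        deff = MitoticClockDefinition("toy", probes, "upper_quantile", quantile=0.5)
        _, report = estimate_mitotic_age(_ds(betas), deff, high_conf_probes=probes[:3])
        assert report["coverage"] == 0.75

    def test_empty_intersection_rejected(self):
        betas = pd.DataFrame({"s1": [0.2]}, index=["pX"])
        deff = MitoticClockDefinition("toy", ["p1"], "upper_quantile", quantile=0.5)
        with pytest.raises(ValidationError):
            estimate_mitotic_age(_ds(betas), deff)

    @pytest.mark.parametrize("aggregation", ["rate_normalized_mean", "upper_quantile"])
    def test_monotone_under_uniform_beta_increase(self, aggregation):
        rng = np.random.default_rng(0)
        probes = [f"p{i}" for i in range(30)]
        base = rng.uniform(0.05, 0.3, 30)
        betas = pd.DataFrame({"lo": base, "hi": np.clip(base + 0.1, 0, 1)}, index=probes)
        if aggregation == "rate_normalized_mean":
            deff = MitoticClockDefinition("toy", probes, aggregation,
                                          ground_state=np.full(30, 0.05),
                                          rate=np.full(30, 0.002))
        else:
            deff = MitoticClockDefinition("toy", probes, aggregation, quantile=0.95)
        score, _ = estimate_mitotic_age(_ds(betas), deff)
        assert score["hi"] > score["lo"]

    def test_definition_file_roundtrip(self, tmp_path):
        deff = MitoticClockDefinition("rt", ["p1", "p2"], "rate_normalized_mean",
                                      ground_state=np.array([0.1, 0.2]),
                                      rate=np.array([0.01, 0.02]))
        paths = deff.write(tmp_path)
        back = MitoticClockDefinition.read(paths["header"])
        assert back.probe_ids == deff.probe_ids
        np.testing.assert_allclose(back.rate, deff.rate)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValidationError):
            MitoticClockDefinition("bad", ["p1"], "rate_normalized_mean")
        with pytest.raises(ValidationError):
            MitoticClockDefinition("bad", ["p1"], "upper_quantile", quantile=1.5)
        with pytest.raises(ValidationError):
            MitoticClockDefinition("bad", ["p1"], "rate_normalized_mean",
                                   ground_state=np.array([0.1]), rate=np.array([-0.1]))


class TestPromoterMeans:
    def test_simple_mean(self, toy_annotation):
        betas = pd.DataFrame(
            {"s1": [0.0, 0.0, 0.0, 0.2, 0.4], "s2": [0.0, 0.0, 0.0, 0.3, 0.5]},
            index=[f"p{i}" for i in range(1, 6)],
        )
        gm = mean_promoter_methylation(_ds(betas), toy_annotation, min_probes=2)
        assert gm.loc["G1", "s1"] == pytest.approx(0.3)
        assert gm.loc["G1", "s2"] == pytest.approx(0.4)

    def test_gene_below_min_probes_excluded(self, toy_annotation):
        betas = pd.DataFrame({"s1": [0.1] * 5}, index=[f"p{i}" for i in range(1, 6)])
        gm = mean_promoter_methylation(_ds(betas), toy_annotation,
                                       high_conf_probes=["p4"], min_probes=2)
        assert gm.empty

    def test_shared_probe_contributes_to_both_genes(self):
        table = pd.DataFrame(
            {"chromosome": ["chr1"] * 3, "snp_overlap": False, "cross_reactive": False},
            index=["p1", "p2", "p3"],
        )
        links = pd.DataFrame({
            "probe_id": ["p1", "p2", "p2", "p3"],
            "gene_id": ["GA", "GA", "GB", "GB"],
            "region": ["TSS200", "TSS1500", "TSS200", "TSS200"],
        })
        ann = ProbeAnnotation(table=table, promoter_links=links)
        betas = pd.DataFrame({"s1": [0.2, 0.4, 0.6]}, index=["p1", "p2", "p3"])
        gm = mean_promoter_methylation(_ds(betas), ann)
        assert gm.loc["GA", "s1"] == pytest.approx(0.3)
        assert gm.loc["GB", "s1"] == pytest.approx(0.5)

    def test_missing_beta_averages_available(self, toy_annotation):
        betas = pd.DataFrame({"s1": [0.1, 0.1, 0.1, np.nan, 0.4]},
                             index=[f"p{i}" for i in range(1, 6)])
        gm = mean_promoter_methylation(_ds(betas), toy_annotation)
        assert gm.loc["G1", "s1"] == pytest.approx(0.4)


class TestSampleCorrelation:
    def test_duplicated_sample_correlates_perfectly(self):
        rng = np.random.default_rng(1)
        v = rng.random(10)
        m = pd.DataFrame({"a": v, "b": v, "c": rng.random(10)})
        corr = tsg_sample_correlation(m)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_anticorrelated_vectors(self):
        m = pd.DataFrame({"a": [0.1, 0.2, 0.3], "b": [0.3, 0.2, 0.1]})
        corr = tsg_sample_correlation(m)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_brute_force_pairwise(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.random((15, 6)), columns=list("abcdef"))
        corr = tsg_sample_correlation(m)
        for i in "abc":
            for j in "def":
                expected = stats.pearsonr(m[i], m[j])[0]
                assert corr.loc[i, j] == pytest.approx(expected, abs=1e-12)


def _age_meta(ages):
    return pd.DataFrame({"age": ages, "cohort": "main"},
                        index=[f"s{i}" for i in range(len(ages))])


def brute_force_tsg_rank(gene_matrix, meta, young, old_min, p_max, top_k):
    ages = meta["age"]
    yids = ages.index[(ages >= young[0]) & (ages <= young[1])]
    oids = ages.index[ages >= old_min]
    rows = []
    for gene in gene_matrix.index:
        o = gene_matrix.loc[gene, oids]
        yv = gene_matrix.loc[gene, yids]
        t, p = stats.ttest_ind(o, yv, equal_var=False)
        diff = o.mean() - yv.mean()
        if diff > 0 and p < p_max:
            rows.append((gene, diff))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return [g for g, _ in rows[:top_k]]


class TestTsgRanking:
    def test_planted_strongest_gene_ranked_first(self):
        rng = np.random.default_rng(3)
        ages = [20, 22, 25, 28, 61, 65, 70, 80]
        meta = _age_meta(ages)
        old = np.array(ages) >= 60
        genes = {}
        genes["BIG"] = 0.1 + 0.2 * old + rng.normal(0, 0.01, 8)
        genes["SMALL"] = 0.1 + 0.05 * old + rng.normal(0, 0.01, 8)
        genes["FLAT"] = 0.1 + rng.normal(0, 0.01, 8)
        gm = pd.DataFrame(genes, index=meta.index).T
        table = rank_tsg_hypermethylation(gm, meta)
        assert table.index[0] == "BIG"
        assert "FLAT" not in table.index

    def test_hypomethylated_gene_excluded(self):
        ages = [20, 25, 28, 61, 65, 80]
        meta = _age_meta(ages)
        gm = pd.DataFrame([[0.5, 0.5, 0.5, 0.2, 0.21, 0.19]],
                          index=["DOWN"], columns=meta.index)
        table = rank_tsg_hypermethylation(gm, meta)
        assert table.empty

    def test_fewer_than_top_k_returned(self):
        ages = [20, 25, 28, 61, 65, 80]
        meta = _age_meta(ages)
        gm = pd.DataFrame([[0.1, 0.11, 0.09, 0.4, 0.41, 0.39]],
                          index=["UP"], columns=meta.index)
        table = rank_tsg_hypermethylation(gm, meta, top_k=50)
        assert list(table.index) == ["UP"]

    def test_small_group_rejected(self):
        meta = _age_meta([20, 61, 65, 80])
        gm = pd.DataFrame([[0.1, 0.2, 0.2, 0.2]], index=["G"], columns=meta.index)
        with pytest.raises(ValidationError, match="2 samples"):
            rank_tsg_hypermethylation(gm, meta)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        n_young, n_old, n_other = 6, 6, 4
        ages = ([rng.uniform(18, 29) for _ in range(n_young)]
                + [rng.uniform(60, 85) for _ in range(n_old)]
                + [rng.uniform(35, 55) for _ in range(n_other)])
        meta = _age_meta(ages)
        gm = pd.DataFrame(
            rng.random((100, len(ages))) * 0.5
            + np.outer(rng.uniform(-0.1, 0.25, 100), np.array(ages) >= 60),
            index=[f"G{i:03d}" for i in range(100)], columns=meta.index,
        ).clip(0, 1)
        ours = rank_tsg_hypermethylation(gm, meta, top_k=50)
        expected = brute_force_tsg_rank(gm, meta, (18, 29), 60, 0.05, 50)
        assert list(ours.index) == expected


class TestGeneAgeCorrelation:
    def test_perfectly_linear(self):
        ages = np.array([20.0, 40.0, 60.0, 80.0])
        gm = pd.DataFrame([0.1 + 0.002 * ages], index=["G"])
        res = gene_age_correlation(gm, ages)
        assert res.loc["G", "pearson_r"] == pytest.approx(1.0)
        assert res.loc["G", "slope"] == pytest.approx(0.002)

    def test_constant_gene_warns(self):
        ages = np.array([20.0, 40.0, 60.0])
        gm = pd.DataFrame([[0.3, 0.3, 0.3]], index=["G"])
        with pytest.warns(UserWarning, match="undefined"):
            res = gene_age_correlation(gm, ages)
        assert np.isnan(res.loc["G", "pearson_r"])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(18, 85, 12)
        gm = pd.DataFrame(rng.random((6, 12)), index=[f"G{i}" for i in range(6)])
        res = gene_age_correlation(gm, ages)
        for g in gm.index:
            assert res.loc[g, "pearson_r"] == pytest.approx(
                stats.pearsonr(ages, gm.loc[g])[0], abs=1e-12)


class TestNvOutliers:
    def _nv_ann(self, probes):
        table = pd.DataFrame(
            {"chromosome": "chr1", "snp_overlap": False, "cross_reactive": False,
             "probe_class": "nv"},
            index=probes,
        )
        return ProbeAnnotation(table=table)

    def test_single_shifted_sample_flagged(self):
        cols = [f"s{i}" for i in range(21)]
        vals = [0.02] * 20 + [0.60]
        betas = pd.DataFrame([vals], index=["nv1"], columns=cols)
        flags = detect_nv_outliers(_ds(betas), self._nv_ann(["nv1"]))
        assert len(flags) == 1
        assert flags.iloc[0]["sample_id"] == "s20"
        assert abs(flags.iloc[0]["robust_z"]) > 3.5

    def test_identical_samples_unflagged(self):
        betas = pd.DataFrame([[0.02] * 10], index=["nv1"],
                             columns=[f"s{i}" for i in range(10)])
        flags = detect_nv_outliers(_ds(betas), self._nv_ann(["nv1"]))
        assert flags.empty

    def test_exactly_at_threshold_not_flagged(self):
        # z_max set to the cell's own modified z: strict > means no flag
        mad_floor = 0.01
        cols = [f"s{i}" for i in range(9)]
        vals = np.array([0.1] * 8 + [0.15])
        med = float(np.median(vals))
        z_cell = 0.6745 * (vals[-1] - med) / mad_floor
        betas = pd.DataFrame([vals], index=["nv1"], columns=cols)
        at = detect_nv_outliers(_ds(betas), self._nv_ann(["nv1"]),
                                z_max=z_cell, mad_floor=mad_floor)
        assert at.empty
        below = detect_nv_outliers(_ds(betas), self._nv_ann(["nv1"]),
                                   z_max=z_cell * (1 - 1e-9), mad_floor=mad_floor)
        assert len(below) == 1

    def test_too_few_samples_rejected(self):
        betas = pd.DataFrame([[0.1] * 4], index=["nv1"],
                             columns=[f"s{i}" for i in range(4)])
        with pytest.raises(ValidationError, match="5 samples"):
            detect_nv_outliers(_ds(betas), self._nv_ann(["nv1"]))

    def test_planted_outliers_found_in_synth_cohort(self, small_cohort):
        ds, truth, ann = small_cohort
        flags = detect_nv_outliers(ds, ann)
        found = set(zip(flags["sample_id"], flags["probe_id"]))
        planted = set(zip(truth.nv_outliers["sample_id"], truth.nv_outliers["probe_id"]))
        assert planted <= found


def test_planted_tsg_gain_recovered_within_20_percent(small_cohort):
    """Mean top-k old−young difference matches the planted expectation."""
    ds, truth, ann = small_cohort
    main = ds.samples[ds.samples["cohort"] == "main"]
    hc = list(ds.probe_ids)
    gm = mean_promoter_methylation(ds.subset(sample_ids=main.index.tolist()), ann, hc)
    table = rank_tsg_hypermethylation(gm, main, top_k=10)
    ages = main["age"].astype(float)
    young_frac = (ages[(ages >= 18) & (ages <= 29)] - 18).mean() / (85 - 18)
    old_frac = (ages[ages >= 60] - 18).mean() / (85 - 18)
    gains = truth.tsg_genes.set_index("gene_id").loc[table.index, "total_gain"]
    expected = (gains * (old_frac - young_frac)).mean()
    got = table["difference"].mean()
    assert got == pytest.approx(expected, rel=0.2)
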