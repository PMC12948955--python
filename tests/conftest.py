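import numpy as np
import pandas as pd
import pytest

from tapelift import (
    MethylationDataset,
    ProbeAnnotation,
    SynthConfig,
    generate_annotation,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A fast cohort: 40 donors, 1200 probes, full planted structure."""
    return SynthConfig(
        seed=101,
        n_donors=40,
        n_probes=1200,
        n_age_probes=60,
        n_mitotic_probes=40,
        n_tsg_genes=20,
        n_nv_probes=20,
        n_nv_outliers=3,
        markers_per_type=10,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    ann = generate_annotation(small_cfg)
    ds, truth = generate_cohort(small_cfg, ann)
    return ds, truth, ann


@pytest.fixture
def toy_dataset() -> MethylationDataset:
    betas = pd.DataFrame(
        [[0.1, 0.9], [0.5, 0.4], [np.nan, 0.2]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2"],
    )
    detp = pd.DataFrame(
        [[0.01, 0.02], [0.03, 0.2], [0.6, 0.001]],
        index=["p1", "p2", "p3"],
        columns=["s1", "s2"],
    )
    samples = pd.DataFrame(
        {
            "donor_id": ["d1", "d2"],
            "age": [25.0, 61.0],
            "sex": ["F", "M"],
            "delta_ct": [1.0, 2.5],
            "cohort": ["main", "main"],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    return MethylationDataset(betas=betas, detection_p=detp, samples=samples)


@pytest.fixture
def toy_annotation() -> ProbeAnnotation:
    table = pd.DataFrame(
        {
            "chromosome": ["chr1", "chrX", "chr2", "chr3", "chr4"],
            "snp_overlap": [True, False, False, False, False],
            "cross_reactive": [False, False, True, False, False],
            "probe_class": ["cg", "cg", "cg", "nv", "cg"],
            "chromatin_state": ["TssA", "Quies", "EnhA", "Quies", "TssA"],
            "tsg_flag": [False, False, False, False, True],
        },
        index=pd.Index([f"p{i}" for i in range(1, 6)], name="probe_id"),
    )
    links = pd.DataFrame(
        {
            "probe_id": ["p4", "p5"],
            "gene_id": ["G1", "G1"],
            "region": ["TSS200", "TSS1500"],
        }
    )
    return ProbeAnnotation(table=table, promoter_links=links)
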