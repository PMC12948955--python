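"""Core containers and delimited-text I/O for methylation array data.

The central object is :class:`MethylationDataset`: a probe × sample matrix of
methylation β-values (fraction methylated, in [0, 1]) paired with a matrix of
detection p-values of identical shape, plus per-sample metadata.  Probe-level
metadata (flags, promoter links, chromatin states, marker-set memberships)
lives in :class:`ProbeAnnotation`.

All axis alignment is by identifier, never by position: the β and detection-p
files of a dataset must name the same probes and samples, and any reordering
needed is performed during loading.  Matrices are read and written as
tab-separated text with probe ids in the first column, a header row of sample
ids, and missing values encoded as ``NA``.  Values are written at full
precision so a write → read round trip is numerically exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "AxisMismatchError",
    "MethylationDataset",
    "ProbeAnnotation",
    "FilterReport",
    "FilterStage",
    "read_dataset",
    "write_dataset",
    "read_annotation",
    "write_annotation",
    "read_manifest",
    "load_dataset_from_manifest",
]

PROMOTER_REGIONS = frozenset({"TSS200", "TSS1500"})
PROBE_CLASSES = frozenset({"cg", "nv", "other"})

#: Keratinocyte chromatin-state labels (EpiMap-style 18-state segmentation).
CHROMATIN_STATES = (
    "TssA", "TssFlnk", "TssFlnkU", "TssFlnkD", "Tx", "TxWk",
    "EnhG", "EnhA", "EnhWk", "ZNF/Rpts", "Het", "TssBiv", "EnhBiv",
    "ReprPC", "ReprPCWk", "Quies",
)

NA_REP = "NA"


class ValidationError(ValueError):
    """A container or file violated a structural or range constraint."""


class AxisMismatchError(ValidationError):
    """Two matrices that must share axes do not; the message names the ids."""


def _require_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dups = ids[ids.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} ids: {dups[:10]}")


def _check_axis_equal(a: pd.Index, b: pd.Index, what: str) -> None:
    """Raise AxisMismatchError naming ids present on one side only."""
    if a.equals(b):
        return
    only_a = a.difference(b).tolist()
    only_b = b.difference(a).tolist()
    if only_a or only_b:
        raise AxisMismatchError(
            f"{what} axes differ: {len(only_a)} only in first "
            f"(e.g. {only_a[:5]}), {len(only_b)} only in second (e.g. {only_b[:5]})"
        )


def _check_unit_interval(df: pd.DataFrame, what: str) -> None:
    vals = df.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    if np.any(bad & ~np.isnan(vals)):
        i, j = np.argwhere(bad & ~np.isnan(vals))[0]
        raise ValidationError(
            f"{what} value out of [0, 1]: {vals[i, j]!r} at probe "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )


@dataclass
class MethylationDataset:
    """Probe × sample β-value and detection-p matrices plus sample metadata.

    Parameters
    ----------
    betas : DataFrame
        Probe × sample methylation fractions in [0, 1]; NaN = missing.
    detection_p : DataFrame
        Probe × sample detection p-values in [0, 1]; NaN = missing.  Shares
        both axes with ``betas`` (reordered to match on construction).
    samples : DataFrame
        Indexed by sample id; typical columns are ``donor_id``, ``age``,
        ``sex``, ``delta_ct``, ``replicate_group``, ``cohort``,
        ``tissue_label``.
    """

    betas: pd.DataFrame
    detection_p: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.betas.index = self.betas.index.astype(str)
        self.betas.columns = self.betas.columns.astype(str)
        self.detection_p.index = self.detection_p.index.astype(str)
        self.detection_p.columns = self.detection_p.columns.astype(str)
        self.samples.index = self.samples.index.astype(str)
        _require_unique(self.betas.index, "probe")
        _require_unique(self.betas.columns, "sample")
        _require_unique(self.samples.index, "sample-metadata")
        # align by id, never by position
        if not self.detection_p.index.equals(self.betas.index) or not (
            self.detection_p.columns.equals(self.betas.columns)
        ):
            _check_axis_equal(
                self.betas.index.sort_values(),
                self.detection_p.index.sort_values(),
                "probe",
            )
            _check_axis_equal(
                self.betas.columns.sort_values(),
                self.detection_p.columns.sort_values(),
                "sample",
            )
            self.detection_p = self.detection_p.loc[self.betas.index, self.betas.columns]
        _check_axis_equal(
            self.betas.columns.sort_values(),
            self.samples.index.sort_values(),
            "sample (betas vs metadata)",
        )
        self.samples = self.samples.loc[self.betas.columns]
        _check_unit_interval(self.betas, "beta")
        _check_unit_interval(self.detection_p, "detection p")
        if "age" in self.samples.columns:
            ages = pd.to_numeric(self.samples["age"], errors="coerce")
            if (ages.dropna() < 0).any():
                raise ValidationError("negative age in sample metadata")
        if "delta_ct" in self.samples.columns:
            dct = pd.to_numeric(self.samples["delta_ct"], errors="coerce")
            if (dct.dropna() < 0).any():
                raise ValidationError("negative delta_ct in sample metadata")

    # -- basic accessors ---------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.betas.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.betas.columns

    @property
    def n_probes(self) -> int:
        return len(self.betas.index)

    @property
    def n_samples(self) -> int:
        return len(self.betas.columns)

    def subset(
        self,
        probe_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "MethylationDataset":
        """Restrict to the requested probes/samples, preserving request order.

        Unknown or duplicated requested ids raise :class:`ValidationError`.
        """
        probes = self.betas.index if probe_ids is None else pd.Index([str(p) for p in probe_ids])
        samples = self.betas.columns if sample_ids is None else pd.Index([str(s) for s in sample_ids])
        for req, have, what in (
            (probes, self.betas.index, "probe"),
            (samples, self.betas.columns, "sample"),
        ):
            _require_unique(req, f"requested {what}")
            unknown = req.difference(have).tolist()
            if unknown:
                raise ValidationError(f"unknown {what} ids requested: {unknown[:10]}")
        return MethylationDataset(
            betas=self.betas.loc[probes, samples].copy(),
            detection_p=self.detection_p.loc[probes, samples].copy(),
            samples=self.samples.loc[samples].copy(),
        )


@dataclass
class ProbeAnnotation:
    """Per-probe flags and mappings.

    ``table`` is indexed by probe id with columns ``chromosome``,
    ``snp_overlap``, ``cross_reactive``, ``probe_class`` (cg | nv | other),
    ``chromatin_state`` and ``tsg_flag``.  ``promoter_links`` is a long table
    (probe_id, gene_id, region) restricted to TSS200/TSS1500; a probe may link
    to several genes and a gene to several probes.  ``marker_sets`` is a long
    table (probe_id, cell_type, rank) of cell-type-specific unmethylated
    marker probes, rank 1 = most specific.
    """

    table: pd.DataFrame
    promoter_links: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["probe_id", "gene_id", "region"])
    )
    marker_sets: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["probe_id", "cell_type", "rank"])
    )

    def __post_init__(self) -> None:
        self.table.index = self.table.index.astype(str)
        _require_unique(self.table.index, "annotation probe")
        required = {"chromosome", "snp_overlap", "cross_reactive"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"annotation table missing columns: {sorted(missing)}")
        bad_regions = set(self.promoter_links["region"]) - PROMOTER_REGIONS
        if bad_regions:
            raise ValidationError(f"invalid promoter regions: {sorted(bad_regions)}")
        if "probe_class" in self.table.columns:
            bad = set(self.table["probe_class"].dropna()) - PROBE_CLASSES
            if bad:
                raise ValidationError(f"invalid probe_class labels: {sorted(bad)}")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def validate_chromosomes(self) -> None:
        """Check chromosome labels are autosome names or X/Y."""
        labels = set(self.table["chromosome"].dropna().astype(str))
        ok = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)} | {"X", "Y", "chrX", "chrY"}
        bad = labels - ok
        if bad:
            raise ValidationError(f"unknown chromosome labels: {sorted(bad)[:10]}")

    def sex_chromosome_mask(self) -> pd.Series:
        chrom = self.table["chromosome"].astype(str)
        return chrom.isin(["X", "Y", "chrX", "chrY"])

    def nv_probe_ids(self) -> pd.Index:
        if "probe_class" not in self.table.columns:
            return pd.Index([])
        return self.table.index[self.table["probe_class"] == "nv"]

    def subset(self, probe_ids: Sequence[str]) -> "ProbeAnnotation":
        ids = pd.Index([str(p) for p in probe_ids])
        unknown = ids.difference(self.table.index).tolist()
        if unknown:
            raise ValidationError(f"unknown probe ids requested: {unknown[:10]}")
        keep = set(ids)
        return ProbeAnnotation(
            table=self.table.loc[ids].copy(),
            promoter_links=self.promoter_links[self.promoter_links["probe_id"].isin(keep)].copy(),
            marker_sets=self.marker_sets[self.marker_sets["probe_id"].isin(keep)].copy(),
        )


@dataclass
class FilterStage:
    name: str
    criterion: str
    n_in: int
    n_out: int


@dataclass
class FilterReport:
    """Ordered record of a serial probe-subsetting run.

    Each stage records how many probes entered and left; stages chain
    (``n_in`` of stage k+1 equals ``n_out`` of stage k) and the final set is a
    subset of the input universe.
    """

    stages: list[FilterStage] = field(default_factory=list)
    final_probe_ids: list[str] = field(default_factory=list)

    def add_stage(self, name: str, criterion: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValidationError(f"stage {name!r}: n_out {n_out} > n_in {n_in}")
        if self.stages and n_in != self.stages[-1].n_out:
            raise ValidationError(
                f"stage {name!r}: n_in {n_in} != previous n_out {self.stages[-1].n_out}"
            )
        self.stages.append(FilterStage(name, criterion, n_in, n_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.criterion, s.n_in, s.n_out) for s in self.stages],
            columns=["stage", "criterion", "n_in", "n_out"],
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stages_path = out / "filter_stages.tsv"
        self.to_frame().to_csv(stages_path, sep="\t", index=False)
        ids_path = out / "retained_probes.txt"
        ids_path.write_text("\n".join(self.final_probe_ids) + "\n")
        json_path = out / "filter_report.json"
        json_path.write_text(
            json.dumps(
                {
                    "stages": [vars(s) for s in self.stages],
                    "n_final": len(self.final_probe_ids),
                },
                indent=2,
            )
        )
        return {"stages": stages_path, "probes": ids_path, "json": json_path}


# ---------------------------------------------------------------------------
# I/O


def _read_matrix(path: str | Path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA_REP],
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        raise ValidationError(f"{what} file {path} contains non-numeric values")
    return df.astype(float)


def read_dataset(
    beta_path: str | Path,
    detp_path: str | Path,
    meta_path: str | Path,
) -> MethylationDataset:
    """Load a dataset from three TSV files, aligning all axes by id."""
    betas = _read_matrix(beta_path, "beta")
    detp = _read_matrix(detp_path, "detection p")
    meta = pd.read_csv(meta_path, sep="\t", na_values=[NA_REP])
    if "sample_id" not in meta.columns:
        raise ValidationError(f"metadata file {meta_path} lacks a sample_id column")
    meta = meta.set_index("sample_id")
    meta.index = meta.index.astype(str)
    return MethylationDataset(betas=betas, detection_p=detp, samples=meta)


def write_dataset(ds: MethylationDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the three TSV files plus a manifest; full-precision values."""
    if ds.n_samples == 0:
        raise ValidationError("refusing to write a dataset with zero samples")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": out / "betas.tsv",
        "detection_p": out / "detection_p.tsv",
        "samples": out / "samples.tsv",
    }
    ds.betas.rename_axis("probe_id").to_csv(paths["betas"], sep="\t", na_rep=NA_REP, float_format="%.17g")
    ds.detection_p.rename_axis("probe_id").to_csv(paths["detection_p"], sep="\t", na_rep=NA_REP, float_format="%.17g")
    ds.samples.rename_axis("sample_id").to_csv(paths["samples"], sep="\t", na_rep=NA_REP)
    manifest = out / "manifest.yaml"
    manifest.write_text(
        yaml.safe_dump({k: p.name for k, p in paths.items()}, sort_keys=True)
    )
    paths["manifest"] = manifest
    return paths


def write_annotation(ann: ProbeAnnotation, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "annotation.tsv",
        "promoter_links": out / "promoter_links.tsv",
        "marker_sets": out / "marker_sets.tsv",
    }
    ann.table.rename_axis("probe_id").to_csv(paths["annotation"], sep="\t", na_rep=NA_REP)
    ann.promoter_links.to_csv(paths["promoter_links"], sep="\t", index=False)
    ann.marker_sets.to_csv(paths["marker_sets"], sep="\t", index=False)
    return paths


def read_annotation(out_dir: str | Path) -> ProbeAnnotation:
    out = Path(out_dir)
    table = pd.read_csv(out / "annotation.tsv", sep="\t", index_col=0, na_values=[NA_REP])
    table.index = table.index.astype(str)
    for col in ("snp_overlap", "cross_reactive", "tsg_flag"):
        if col in table.columns:
            table[col] = table[col].astype(bool)
    links_path = out / "promoter_links.tsv"
    markers_path = out / "marker_sets.tsv"
    links = (
        pd.read_csv(links_path, sep="\t", dtype={"probe_id": str, "gene_id": str})
        if links_path.exists() and links_path.stat().st_size > 0
        else pd.DataFrame(columns=["probe_id", "gene_id", "region"])
    )
    if links.empty and list(links.columns) != ["probe_id", "gene_id", "region"]:
        links = pd.DataFrame(columns=["probe_id", "gene_id", "region"])
    markers = (
        pd.read_csv(markers_path, sep="\t", dtype={"probe_id": str, "cell_type": str})
        if markers_path.exists() and markers_path.stat().st_size > 0
        else pd.DataFrame(columns=["probe_id", "cell_type", "rank"])
    )
    if markers.empty and list(markers.columns) != ["probe_id", "cell_type", "rank"]:
        markers = pd.DataFrame(columns=["probe_id", "cell_type", "rank"])
    return ProbeAnnotation(table=table, promoter_links=links, marker_sets=markers)


def read_manifest(path: str | Path) -> dict:
    """Read a YAML/JSON manifest naming the matrix, metadata and annotation files."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValidationError(f"manifest {path} is not a mapping")
    return dict(data)


def load_dataset_from_manifest(path: str | Path) -> MethylationDataset:
    path = Path(path)
    man = read_manifest(path)
    base = path.parent
    try:
        return read_dataset(
            base / man["betas"], base / man["detection_p"], base / man["samples"]
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValidationError(f"manifest {path} missing key {exc}") from exc
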