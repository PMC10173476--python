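"""Domain types, TSV readers/writers, configuration and logging.

The central container is :class:`CountTable`, a feature x sample matrix of
non-negative expression values with attached feature and sample metadata.
Raw tables carry integer read counts; tables that went through the
subgenome-mismatch correction may be fractional, because the correction adds
replicate-averaged quantities.

All tabular I/O is tab-separated UTF-8 with ``NA`` for missing values.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("plureval")

FEATURE_CLASSES = ("hc_gene", "lc_gene", "te_family")
SUBGENOMES = ("A", "B", "D", "un")
GENE_SUBGENOMES = ("A", "B", "D")
TISSUES = ("leaf", "grain")
ROLES = ("diploid_parent", "tetraploid_parent", "synthetic", "natural_hexaploid")

#: subgenomes on which a sample of a given ploidy role carries native chromosomes
NATIVE_SUBGENOMES = {
    "diploid_parent": frozenset({"D"}),
    "tetraploid_parent": frozenset({"A", "B"}),
    "synthetic": frozenset({"A", "B", "D"}),
    "natural_hexaploid": frozenset({"A", "B", "D"}),
}

FEATURE_COLUMNS = ("feature_class", "subgenome", "chromosome", "order_index", "length_bp")
SAMPLE_COLUMNS = ("genotype_id", "tissue", "generation_label", "role", "replicate_of")
TRIAD_COLUMNS = ("gene_A", "gene_B", "gene_D")

UNITS = ("counts", "rpm", "tpm")


class ValidationError(ValueError):
    """A table or configuration violates a structural invariant."""


def configure_logging(level: int = logging.INFO) -> None:
    """Structured logging to stderr with stage names."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Feature x sample expression matrix with metadata.

    Parameters
    ----------
    values
        DataFrame indexed by ``feature_id`` with one column per ``sample_id``.
    features
        DataFrame indexed by ``feature_id`` with columns ``feature_class``,
        ``subgenome``, ``chromosome``, ``order_index``, ``length_bp``
        (``length_bp`` may be NA for TE families).
    samples
        DataFrame indexed by ``sample_id`` with columns ``genotype_id``,
        ``tissue``, ``generation_label``, ``role``, ``replicate_of``.
    unit
        ``counts``, ``rpm`` or ``tpm``.
    mismatch_corrected
        Provenance flag set by the subgenome-mismatch correction; guards
        against applying the correction twice.
    """

    values: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "counts"
    mismatch_corrected: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        v, f, s = self.values, self.features, self.samples
        if self.unit not in UNITS:
            raise ValidationError(f"unknown unit {self.unit!r}")
        if f.index.has_duplicates:
            dup = f.index[f.index.duplicated()][0]
            raise ValidationError(f"duplicate feature_id {dup!r}")
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id {dup!r}")
        if not v.index.equals(f.index):
            raise ValidationError("matrix rows do not match the feature annotation")
        if not v.columns.equals(s.index):
            raise ValidationError("matrix columns do not match the sample sheet")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("negative or missing count: matrix contains NA")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count {arr[i, j]} at feature {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        bad = ~f["feature_class"].isin(FEATURE_CLASSES)
        if bad.any():
            row = f.index[bad][0]
            raise ValidationError(
                f"unknown feature_class {f.loc[row, 'feature_class']!r} for feature {row!r}"
            )
        bad = ~f["subgenome"].isin(SUBGENOMES)
        if bad.any():
            row = f.index[bad][0]
            raise ValidationError(
                f"unknown subgenome {f.loc[row, 'subgenome']!r} for feature {row!r}"
            )
        if (pd.to_numeric(f["order_index"]) < 0).any():
            raise ValidationError("order_index must be non-negative")
        lengths = pd.to_numeric(f["length_bp"], errors="coerce")
        if ((lengths <= 0) & lengths.notna()).any():
            raise ValidationError("length_bp must be positive where present")
        bad = ~s["role"].isin(ROLES)
        if bad.any():
            row = s.index[bad][0]
            raise ValidationError(f"unknown role {s.loc[row, 'role']!r} for sample {row!r}")
        bad = ~s["tissue"].isin(TISSUES)
        if bad.any():
            row = s.index[bad][0]
            raise ValidationError(f"unknown tissue {s.loc[row, 'tissue']!r} for sample {row!r}")

    # -- convenience --------------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def column_totals(self) -> pd.Series:
        return self.values.sum(axis=0)

    def subset_features(self, feature_ids) -> "CountTable":
        feature_ids = pd.Index(feature_ids)
        return CountTable(
            self.values.loc[feature_ids],
            self.features.loc[feature_ids],
            self.samples,
            unit=self.unit,
            mismatch_corrected=self.mismatch_corrected,
        )

    def subset_samples(self, sample_ids) -> "CountTable":
        sample_ids = pd.Index(sample_ids)
        return CountTable(
            self.values[sample_ids],
            self.features,
            self.samples.loc[sample_ids],
            unit=self.unit,
            mismatch_corrected=self.mismatch_corrected,
        )

    def copy(self) -> "CountTable":
        return CountTable(
            self.values.copy(),
            self.features.copy(),
            self.samples.copy(),
            unit=self.unit,
            mismatch_corrected=self.mismatch_corrected,
        )


@dataclass
class TriadTable:
    """Homoeologous gene triads: one gene per A/B/D subgenome."""

    records: pd.DataFrame  # indexed by triad_id, columns gene_A, gene_B, gene_D

    def __post_init__(self) -> None:
        r = self.records
        missing = [c for c in TRIAD_COLUMNS if c not in r.columns]
        if missing:
            raise ValidationError(f"triad table lacks columns {missing}")
        if r.index.has_duplicates:
            raise ValidationError("duplicate triad_id")
        genes = r[list(TRIAD_COLUMNS)].to_numpy()
        if any(len(set(row)) != 3 for row in genes):
            raise ValidationError("triad members must be distinct")

    def validate_against(self, features: pd.DataFrame) -> None:
        for col, sub in zip(TRIAD_COLUMNS, GENE_SUBGENOMES):
            ids = self.records[col]
            unknown = ids[~ids.isin(features.index)]
            if len(unknown):
                raise ValidationError(f"triad gene {unknown.iloc[0]!r} absent from annotation")
            wrong = ids[features.loc[ids, "subgenome"].to_numpy() != sub]
            if len(wrong):
                raise ValidationError(
                    f"triad gene {wrong.iloc[0]!r} is not on subgenome {sub}"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PipelineConfig:
    """Tunable constants of the analysis.

    The defaults are the published operating points of the method: parental
    RPM scaling of 1/3 (diploid) and 2/3 (tetraploid), in-silico parent
    weights 0.33/0.67, DE thresholds FDR < 0.01 with fold change > 3
    (|log2FC| > 1.585), a 5 RPM floor on triad totals, biased-homoeolog
    contribution cut-offs 1/6 and 2/3, a 0.3 eigen-distance movement cut-off,
    karyotype windows of 200 position-ordered genes and a TPM presence floor
    of 0.01 in at least two samples.
    """

    diploid_scale: float = 1.0 / 3.0
    tetraploid_scale: float = 2.0 / 3.0
    insilico_diploid_weight: float = 0.33
    insilico_tetraploid_weight: float = 0.67
    fdr_max: float = 0.01
    min_fold_change: float = 3.0
    min_abs_log2fc: float = 1.585
    min_triad_rpm: float = 5.0
    biased_low: float = 1.0 / 6.0
    biased_high: float = 2.0 / 3.0
    movement_cutoff: float = 0.3
    window_size: int = 200
    tpm_floor: float = 0.01
    min_samples_expressed: int = 2
    mono_band: tuple = (0.35, 0.65)
    tri_band: tuple = (1.35, 1.65)
    exclude_flagged: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.biased_low < self.biased_high < 1.0):
            raise ValidationError("need 0 < biased_low < biased_high < 1")
        if self.window_size < 1:
            raise ValidationError("window_size must be >= 1")
        for name in ("diploid_scale", "tetraploid_scale",
                     "insilico_diploid_weight", "insilico_tetraploid_weight"):
            w = getattr(self, name)
            if not (0.0 < w <= 1.0):
                raise ValidationError(f"{name} must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("mono_band", "tri_band"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if index_col not in df.columns:
        raise ValidationError(f"{path}: missing column {index_col!r}")
    if df[index_col].duplicated().any():
        dup = df[index_col][df[index_col].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate {index_col} {dup!r}")
    return df.set_index(index_col)


def load_dataset(counts_path, annotation_path, samples_path) -> CountTable:
    """Load a raw count matrix with its feature annotation and sample sheet.

    The matrix TSV has a ``feature_id`` column plus one column per sample;
    the annotation and sample sheet are cross-validated against it.
    """
    values = _read_tsv(counts_path, "feature_id")
    features = _read_tsv(annotation_path, "feature_id")
    samples = _read_tsv(samples_path, "sample_id")

    missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
    if missing:
        raise ValidationError(f"{annotation_path}: missing columns {missing}")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"{samples_path}: missing columns {missing}")

    unknown_feat = values.index.difference(features.index)
    if len(unknown_feat):
        raise ValidationError(f"matrix feature {unknown_feat[0]!r} absent from annotation")
    unknown_samp = values.columns.difference(samples.index)
    if len(unknown_samp):
        raise ValidationError(f"matrix sample {unknown_samp[0]!r} absent from sample sheet")

    features = features.loc[values.index]
    samples = samples.loc[values.columns]
    values = values.astype(float)
    return CountTable(values, features, samples, unit="counts")


def load_triads(path, features: pd.DataFrame | None = None) -> TriadTable:
    records = _read_tsv(path, "triad_id")
    table = TriadTable(records)
    if features is not None:
        table.validate_against(features)
    return table


def write_table(table, path) -> None:
    """Write a result table as TSV (``NA`` for missing, 12 significant digits).

    Accepts a DataFrame (the index is written as the first column) or a
    :class:`CountTable` (its values are written with a ``feature_id`` column).
    """
    if isinstance(table, CountTable):
        df = table.values.copy()
        df.index.name = "feature_id"
    else:
        df = table
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.12g")


def write_count_table(table: CountTable, prefix) -> None:
    """Write matrix + annotation + sample sheet under ``<prefix>.*.tsv``.

    A ``<prefix>.meta.json`` sidecar records the unit and whether the
    subgenome-mismatch correction has been applied (the provenance flag that
    guards against applying it twice).
    """
    import json

    prefix = Path(prefix)
    values = table.values.copy()
    values.index.name = "feature_id"
    write_table(values, prefix.with_suffix(".counts.tsv"))
    feats = table.features.copy()
    feats.index.name = "feature_id"
    write_table(feats, prefix.with_suffix(".features.tsv"))
    samps = table.samples.copy()
    samps.index.name = "sample_id"
    write_table(samps, prefix.with_suffix(".samples.tsv"))
    with open(prefix.with_suffix(".meta.json"), "w") as fh:
        json.dump({"unit": table.unit, "mismatch_corrected": table.mismatch_corrected}, fh)


def load_count_table(prefix) -> CountTable:
    """Load a table written by :func:`write_count_table`, with provenance."""
    import json

    prefix = Path(prefix)
    table = load_dataset(
        prefix.with_suffix(".counts.tsv"),
        prefix.with_suffix(".features.tsv"),
        prefix.with_suffix(".samples.tsv"),
    )
    meta_path = prefix.with_suffix(".meta.json")
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
        table.unit = meta.get("unit", "counts")
        table.mismatch_corrected = bool(meta.get("mismatch_corrected", False))
    return table
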