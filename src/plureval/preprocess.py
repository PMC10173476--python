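"""Expression-unit conversion and cross-ploidy pre-processing.

This stage makes parental (diploid DD / tetraploid AABB) and hexaploid
libraries comparable before any normalization or testing:

* ``normalize_expression`` converts raw counts to RPM or TPM;
* ``correct_subgenome_mismatch`` transfers each parent's cross-mapped
  ("wrong-subgenome") signal to the other parent's libraries, so both parents
  carry the same contamination the hexaploid inevitably carries;
* ``redistribute_parent_te_counts`` undoes the random multimapper smearing of
  TE-family counts in the parents, whose reads can only originate from their
  native subgenomes;
* ``split_by_subgenome`` partitions hexaploid tables into AB- and D-parts so
  each part can be normalized together with the matching parent;
* ``combine_parents_in_silico`` builds the weighted in-silico hexaploid
  (0.33 * diploid RPM + 0.67 * tetraploid RPM) used as a parental baseline
  for homoeolog-bias comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import (
    CountTable,
    PipelineConfig,
    ValidationError,
    log,
)


def normalize_expression(
    table: CountTable, kind: str, totals: pd.Series | None = None
) -> CountTable:
    """Convert a raw count table to RPM or TPM.

    RPM: value * 1e6 / library total. TPM: counts are first divided by the
    feature length in kb, then each column is scaled to sum to 1e6.

    ``totals`` overrides the per-library denominator (RPM only); this is how
    a table holding a subset of features -- e.g. TE families quantified
    separately from genes -- is expressed per million reads of the *whole*
    library rather than per million of the subset.
    """
    if table.unit != "counts":
        raise ValidationError(f"expected unit='counts', got {table.unit!r}")
    if kind not in ("rpm", "tpm"):
        raise ValidationError(f"unknown expression unit {kind!r}")
    values = table.values.astype(float)
    if kind == "tpm":
        if totals is not None:
            raise ValidationError("explicit totals only apply to RPM")
        lengths = pd.to_numeric(table.features["length_bp"], errors="coerce")
        if lengths.isna().any():
            missing = lengths.index[lengths.isna()][0]
            raise ValidationError(f"length_bp required for TPM: missing for {missing!r}")
        values = values.div(lengths / 1e3, axis=0)
    if totals is None:
        totals = values.sum(axis=0)
    else:
        totals = totals.loc[values.columns].astype(float)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValidationError(f"zero column total for sample {zero[0]!r}")
    values = values.mul(1e6 / totals, axis=1)
    out = table.copy()
    out.values = values
    out.unit = kind
    return out


def correct_subgenome_mismatch(
    diploid: CountTable, tetraploid: CountTable, params: PipelineConfig | None = None
) -> tuple[CountTable, CountTable]:
    """Transfer each parent's subgenome-mismatch signal to the other parent.

    Mismatch features are AB-located genes in the diploid table and D-located
    genes in the tetraploid table. Their per-library RPMs are scaled by 1/3
    (diploid) or 2/3 (tetraploid) -- the share of the hexaploid transcriptome
    the donor genome represents -- and averaged across the donor's replicates.
    The averaged RPM is then added to every library of the other parent on
    that library's hexaploid-equivalent count scale,
    ``RPM * (column_total / native_share) / 1e6``, where ``native_share`` is
    1/3 for a diploid recipient and 2/3 for a tetraploid one. Dividing by the
    recipient's native share expresses its depth as the depth of the full
    hexaploid transcriptome it stands in for, which is the scale on which the
    synthetic libraries accumulate the same cross-mapped signal. Native
    counts are untouched; outputs keep unit='counts' but may be fractional.
    """
    params = params or PipelineConfig()
    if diploid.mismatch_corrected or tetraploid.mismatch_corrected:
        raise ValidationError("subgenome-mismatch correction already applied")
    if not (diploid.samples["role"] == "diploid_parent").all():
        raise ValidationError("diploid table must contain only diploid_parent samples")
    if not (tetraploid.samples["role"] == "tetraploid_parent").all():
        raise ValidationError("tetraploid table must contain only tetraploid_parent samples")
    if not diploid.values.index.equals(tetraploid.values.index):
        raise ValidationError("parent tables must share the same feature set")
    for t in (diploid, tetraploid):
        if t.n_samples < 1:
            raise ValidationError("each parent needs at least one replicate")

    genes = diploid.features["feature_class"].isin(("hc_gene", "lc_gene"))
    sub = diploid.features["subgenome"]
    dip_mismatch = genes & sub.isin(("A", "B"))
    tet_mismatch = genes & (sub == "D")

    dip_tot = diploid.column_totals()
    tet_tot = tetraploid.column_totals()

    dip_rpm = diploid.values.mul(1e6 / dip_tot, axis=1)
    tet_rpm = tetraploid.values.mul(1e6 / tet_tot, axis=1)

    # donor-scaled, replicate-averaged mismatch RPM
    dip_avg = (dip_rpm.loc[dip_mismatch] * params.diploid_scale).mean(axis=1)
    tet_avg = (tet_rpm.loc[tet_mismatch] * params.tetraploid_scale).mean(axis=1)

    dip_out = diploid.copy()
    tet_out = tetraploid.copy()
    # recipient hexaploid-equivalent depth = column total / native share
    for col in tet_out.values.columns:
        depth = tet_tot[col] / params.tetraploid_scale
        tet_out.values.loc[dip_mismatch.index[dip_mismatch], col] += dip_avg * depth / 1e6
    for col in dip_out.values.columns:
        depth = dip_tot[col] / params.diploid_scale
        dip_out.values.loc[tet_mismatch.index[tet_mismatch], col] += tet_avg * depth / 1e6

    dip_out.mismatch_corrected = True
    tet_out.mismatch_corrected = True
    dip_out.validate()
    tet_out.validate()
    return dip_out, tet_out


def _te_family_of(feature_ids: pd.Index) -> pd.Series:
    return pd.Series(
        [fid.rsplit("_", 1)[0] for fid in feature_ids], index=feature_ids, dtype=object
    )


def redistribute_parent_te_counts(table: CountTable) -> CountTable:
    """Reassign a parent's smeared TE-family counts to its native subgenomes.

    TE reads in the parents can only originate from the parent's own genome,
    so per family: in the diploid all A/B/un bucket counts are added to the D
    bucket; in the tetraploid the D and un bucket counts are split equally
    between A and B. Family totals are conserved per library. Synthetic and
    natural-hexaploid samples keep their per-bucket counts.
    """
    roles = set(table.samples["role"])
    if roles == {"diploid_parent"}:
        native = "D"
    elif roles == {"tetraploid_parent"}:
        native = "AB"
    else:
        raise ValidationError(
            "TE redistribution applies only to single-role parent tables, got roles "
            f"{sorted(roles)}"
        )
    te = table.features["feature_class"] == "te_family"
    out = table.copy()
    if not te.any():
        return out
    fam = _te_family_of(table.features.index[te])
    sub = table.features.loc[te, "subgenome"]
    vals = out.values
    for family, ids in fam.groupby(fam).groups.items():
        ids = pd.Index(ids)
        bucket = {s: ids[sub.loc[ids] == s] for s in ("A", "B", "D", "un")}
        total = vals.loc[ids].sum(axis=0)
        if native == "D":
            vals.loc[ids] = 0.0
            if len(bucket["D"]) != 1:
                raise ValidationError(f"TE family {family!r} lacks a unique D bucket")
            vals.loc[bucket["D"][0]] = total
        else:
            a_and_b = vals.loc[bucket["A"]].sum(axis=0) + vals.loc[bucket["B"]].sum(axis=0)
            rest = (total - a_and_b) / 2.0
            if len(bucket["A"]) != 1 or len(bucket["B"]) != 1:
                raise ValidationError(f"TE family {family!r} lacks unique A/B buckets")
            a_id, b_id = bucket["A"][0], bucket["B"][0]
            new_a = vals.loc[a_id] + rest
            new_b = vals.loc[b_id] + rest
            vals.loc[ids] = 0.0
            vals.loc[a_id] = new_a
            vals.loc[b_id] = new_b
    out.validate()
    return out


def split_by_subgenome(table: CountTable) -> tuple[CountTable, CountTable]:
    """Partition a table into its AB-part and D-part.

    Features with subgenome 'un' belong to neither part; they are dropped
    with a log message. Column totals of each part are recomputed implicitly
    (each part is a standalone CountTable) and become the library sizes used
    by downstream normalization.
    """
    sub = table.features["subgenome"]
    un = sub == "un"
    if un.any():
        log.info("split_by_subgenome: dropping %d 'un' features", int(un.sum()))
    ab = table.subset_features(table.features.index[sub.isin(("A", "B"))])
    d = table.subset_features(table.features.index[sub == "D"])
    return ab, d


def combine_parents_in_silico(
    diploid_rpm: CountTable,
    tetraploid_rpm: CountTable,
    weights: tuple[float, float] = (0.33, 0.67),
) -> CountTable:
    """Weighted in-silico hexaploid parent: w_d * diploid + w_t * tetraploid RPM.

    Replicate-averaged per parent, producing a single pseudo-sample.
    """
    if diploid_rpm.unit != "rpm" or tetraploid_rpm.unit != "rpm":
        raise ValidationError("combine_parents_in_silico expects RPM tables")
    if not diploid_rpm.values.index.equals(tetraploid_rpm.values.index):
        raise ValidationError("parent tables must share the same feature set")
    w_d, w_t = weights
    combined = (
        w_d * diploid_rpm.values.mean(axis=1) + w_t * tetraploid_rpm.values.mean(axis=1)
    )
    dip_geno = diploid_rpm.samples["genotype_id"].iloc[0]
    tet_geno = tetraploid_rpm.samples["genotype_id"].iloc[0]
    sid = f"insilico_{tet_geno}x{dip_geno}"
    values = combined.to_frame(sid)
    samples = pd.DataFrame(
        {
            "genotype_id": [f"{tet_geno}x{dip_geno}"],
            "tissue": [diploid_rpm.samples["tissue"].iloc[0]],
            "generation_label": ["insilico"],
            "role": ["synthetic"],
            "replicate_of": [f"{tet_geno}x{dip_geno}"],
        },
        index=pd.Index([sid], name="sample_id"),
    )
    return CountTable(values, diploid_rpm.features.copy(), samples, unit="rpm")


def te_family_totals(rpm_table: CountTable) -> pd.DataFrame:
    """Per-family RPM totals (A + B + D + un buckets) by library."""
    te = rpm_table.features["feature_class"] == "te_family"
    if not te.any():
        raise ValidationError("table contains no te_family features")
    fam = _te_family_of(rpm_table.features.index[te])
    return rpm_table.values.loc[te].groupby(fam).sum()
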