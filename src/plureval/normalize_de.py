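"""TMM normalization in genotype-consistent groups, NB differential expression
and the midparent-value TE-family test.

Normalization never crosses ploidy levels on whole libraries: the D-parts of
hexaploid samples are normalized together with the diploid (DD) parent and
the AB-parts with the tetraploid (AABB) parent, so library-size differences
caused by transcriptome size never masquerade as differential expression.

The DE test is a negative-binomial likelihood-ratio test of equal means with
log effective library sizes as offsets, per-feature dispersions estimated by
a moment estimator shrunk toward a trimmed common value, and
Benjamini-Hochberg adjustment. A gene is called differentially expressed at
FDR < 0.01 and fold change > 3 (|log2FC| > 1.585).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core_io import CountTable, PipelineConfig, ValidationError, log

DISPERSION_FLOOR = 1e-6
_FALLBACK_DISPERSION = 0.1


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> float:
    """Trimmed mean of M-values of one library against the reference.

    Uses genes positive in both libraries; double-trims by log-ratio (30%
    each side) and absolute intensity (5% each side); weights each gene by
    the inverse of its asymptotic (binomial) variance.
    """
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValidationError("library shares no expressed features with the reference")
    o = obs[pos] / n_obs
    r = ref[pos] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    w = (n_obs - obs[pos]) / (n_obs * obs[pos]) + (n_ref - ref[pos]) / (n_ref * ref[pos])

    fin = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
    m, a, w = m[fin], a[fin], w[fin]
    if len(m) == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0

    n = len(m)
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if not keep.any():
        return 1.0
    f = np.nansum(m[keep] / w[keep]) / np.nansum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    values: pd.DataFrame | CountTable,
    lib_sizes: pd.Series | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Per-library TMM scaling factors, rescaled to geometric mean 1.

    The reference library is the one whose upper-quartile count fraction is
    closest to the mean upper quartile across libraries.
    """
    if isinstance(values, CountTable):
        values = values.values
    if values.shape[1] < 2:
        raise ValidationError("TMM needs at least two libraries")
    arr = values.to_numpy(dtype=float)
    if lib_sizes is None:
        lib_sizes = values.sum(axis=0)
    sizes = lib_sizes.loc[values.columns].to_numpy(dtype=float)
    if (sizes <= 0).any():
        raise ValidationError("zero library size")

    f75 = np.array([np.quantile(arr[:, j] / sizes[j], 0.75) for j in range(arr.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.array(
        [
            _tmm_pair(arr[:, j], arr[:, ref], sizes[j], sizes[ref], logratio_trim, sum_trim)
            for j in range(arr.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=values.columns, name="tmm_factor")


# ---------------------------------------------------------------------------
# normalization groups
# ---------------------------------------------------------------------------


@dataclass
class NormalizationGroup:
    """One genotype-consistent normalization unit (one parent, one partition)."""

    partition: str  # "AB" or "D"
    parent_genotype: str
    table: CountTable
    factors: pd.Series
    effective_sizes: pd.Series
    synthetic_genotypes: tuple = ()


def _combine(parts: list[CountTable]) -> CountTable:
    values = pd.concat([p.values for p in parts], axis=1)
    samples = pd.concat([p.samples for p in parts], axis=0)
    return CountTable(
        values,
        parts[0].features,
        samples,
        unit="counts",
        mismatch_corrected=any(p.mismatch_corrected for p in parts),
    )


def build_normalization_groups(
    synthetic_ab: CountTable,
    synthetic_d: CountTable,
    diploid: CountTable,
    tetraploid: CountTable,
    parentage: dict | None = None,
) -> list[NormalizationGroup]:
    """Group split hexaploid parts with the matching parent and TMM-normalize.

    ``parentage`` maps each synthetic genotype to
    ``{"diploid": genotype_id, "tetraploid": genotype_id}``; by default every
    synthetic is assigned the (single) parent genotype present in each parent
    table. One group is built per (parent genotype, partition); after
    normalization, features with zero counts across all group members are
    removed.
    """
    dip_geno = sorted(set(diploid.samples["genotype_id"]))
    tet_geno = sorted(set(tetraploid.samples["genotype_id"]))
    syn_genos = sorted(set(synthetic_d.samples["genotype_id"]))
    if parentage is None:
        if len(dip_geno) != 1 or len(tet_geno) != 1:
            raise ValidationError("parentage required when parents have several genotypes")
        parentage = {g: {"diploid": dip_geno[0], "tetraploid": tet_geno[0]} for g in syn_genos}
    for g in syn_genos:
        if g not in parentage:
            raise ValidationError(f"synthetic genotype {g!r} has no parent assignment")
        if parentage[g]["diploid"] not in dip_geno or parentage[g]["tetraploid"] not in tet_geno:
            raise ValidationError(f"parent genotype of synthetic {g!r} is absent")

    groups: list[NormalizationGroup] = []
    specs = [
        ("D", synthetic_d, diploid, "diploid"),
        ("AB", synthetic_ab, tetraploid, "tetraploid"),
    ]
    for partition, syn_part, parent, key in specs:
        part_features = syn_part.features.index
        parent_part = parent.subset_features(part_features)
        for pg in sorted(set(parent.samples["genotype_id"])):
            members = [g for g in syn_genos if parentage[g][key] == pg]
            if not members:
                continue
            syn_cols = syn_part.samples.index[syn_part.samples["genotype_id"].isin(members)]
            par_cols = parent_part.samples.index[parent_part.samples["genotype_id"] == pg]
            combined = _combine(
                [syn_part.subset_samples(syn_cols), parent_part.subset_samples(par_cols)]
            )
            factors = tmm_factors(combined.values)
            sizes = combined.column_totals() * factors
            nonzero = combined.values.sum(axis=1) > 0
            if (~nonzero).any():
                combined = combined.subset_features(combined.values.index[nonzero])
            groups.append(
                NormalizationGroup(
                    partition=partition,
                    parent_genotype=pg,
                    table=combined,
                    factors=factors,
                    effective_sizes=sizes,
                    synthetic_genotypes=tuple(members),
                )
            )
    return groups


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


def estimate_dispersion(
    values: pd.DataFrame,
    effective_sizes: pd.Series,
    condition: pd.Series,
    prior_df: float = 10.0,
) -> pd.Series:
    """Per-feature NB dispersion (variance = mu + phi mu^2).

    Method-of-moments on depth-normalized counts, pooled across conditions
    with >= 2 replicates, then shrunk toward the trimmed common dispersion
    with ``prior_df`` prior degrees of freedom; floored at 1e-6. Returns a
    Series whose ``attrs['common']`` holds the common dispersion.
    """
    sizes = effective_sizes.loc[values.columns].to_numpy(dtype=float)
    scale = np.exp(np.mean(np.log(sizes)))
    z = values.to_numpy(dtype=float) / sizes * scale

    cond = condition.loc[values.columns]
    phi_num = np.zeros(values.shape[0])
    df_tot = np.zeros(values.shape[0])
    for level in cond.unique():
        cols = np.flatnonzero((cond == level).to_numpy())
        if len(cols) < 2:
            continue
        zc = z[:, cols]
        m = zc.mean(axis=1)
        s2 = zc.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_c = (s2 - m) / m**2
        ok = m > 0
        dfc = len(cols) - 1
        phi_num[ok] += dfc * phi_c[ok]
        df_tot[ok] += dfc

    if not (df_tot > 0).any():
        log.warning("estimate_dispersion: no replicated condition; using fallback common dispersion")
        out = pd.Series(_FALLBACK_DISPERSION, index=values.index)
        out.attrs["common"] = _FALLBACK_DISPERSION
        out.attrs["prior_df"] = prior_df
        return out

    with np.errstate(invalid="ignore"):
        phi_feat = np.where(df_tot > 0, phi_num / np.maximum(df_tot, 1), np.nan)

    informative = np.isfinite(phi_feat) & (z.mean(axis=1) >= 1.0)
    if informative.any():
        common = float(stats.trim_mean(np.clip(phi_feat[informative], 0, None), 0.1))
    else:
        common = _FALLBACK_DISPERSION
    common = max(common, DISPERSION_FLOOR)

    shrunk = (prior_df * common + df_tot * np.nan_to_num(phi_feat, nan=0.0)) / (prior_df + df_tot)
    shrunk = np.clip(shrunk, DISPERSION_FLOOR, None)
    out = pd.Series(shrunk, index=values.index, name="dispersion")
    out.attrs["common"] = common
    out.attrs["prior_df"] = prior_df
    return out


# ---------------------------------------------------------------------------
# NB likelihood-ratio test
# ---------------------------------------------------------------------------


def _fit_nb_mean(
    y: np.ndarray, offsets: np.ndarray, phi: np.ndarray, n_iter: int = 30
) -> np.ndarray:
    """Vectorized Newton fit of log-mean beta with mu_ij = exp(beta_i + o_j)."""
    tot = y.sum(axis=1)
    denom = np.exp(offsets).sum()
    with np.errstate(divide="ignore"):
        beta = np.where(tot > 0, np.log(tot / denom), -30.0)
    phi = phi[:, None]
    for _ in range(n_iter):
        mu = np.exp(beta[:, None] + offsets[None, :])
        wden = 1.0 + phi * mu
        score = ((y - mu) / wden).sum(axis=1)
        info = (mu / wden).sum(axis=1)
        step = np.where(info > 0, score / np.maximum(info, 1e-12), 0.0)
        step = np.clip(step, -3.0, 3.0)
        beta = np.clip(beta + step, -30.0, 30.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return beta


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    r = 1.0 / phi[:, None]
    mu = np.clip(mu, 1e-12, None)
    ll = (
        gammaln(y + r)
        - gammaln(r)
        - gammaln(y + 1.0)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=1)


def de_test(
    values: pd.DataFrame,
    effective_sizes: pd.Series,
    condition: pd.Series,
    dispersion: pd.Series,
    config: PipelineConfig | None = None,
    contrast: tuple[str, str] = ("synthetic", "parent"),
) -> pd.DataFrame:
    """NB likelihood-ratio test of equal means between two conditions.

    ``condition`` labels each library; ``contrast`` is (numerator,
    denominator), so positive log2FC means higher in the numerator
    (synthetic). Returns one record per feature with ``log2fc``, ``pvalue``,
    ``fdr``, ``significant`` and ``direction``.
    """
    config = config or PipelineConfig()
    cond = condition.loc[values.columns]
    num, den = contrast
    mask_num = (cond == num).to_numpy()
    mask_den = (cond == den).to_numpy()
    if not mask_num.any() or not mask_den.any():
        raise ValidationError(f"empty contrast side in {contrast}")

    y = values.to_numpy(dtype=float)
    offsets = np.log(effective_sizes.loc[values.columns].to_numpy(dtype=float))
    phi = dispersion.loc[values.index].to_numpy(dtype=float)

    both = mask_num | mask_den
    y2, o2 = y[:, both], offsets[both]
    beta_null = _fit_nb_mean(y2, o2, phi)
    beta_num = _fit_nb_mean(y[:, mask_num], offsets[mask_num], phi)
    beta_den = _fit_nb_mean(y[:, mask_den], offsets[mask_den], phi)

    mu_null = np.exp(beta_null[:, None] + o2[None, :])
    mu_alt = np.empty_like(y2)
    nn = mask_num[both]
    mu_alt[:, nn] = np.exp(beta_num[:, None] + o2[None, nn])
    mu_alt[:, ~nn] = np.exp(beta_den[:, None] + o2[None, ~nn])

    lrt = 2.0 * (_nb_loglik(y2, mu_alt, phi) - _nb_loglik(y2, mu_null, phi))
    lrt = np.clip(lrt, 0.0, None)
    # Moderated small-sample reference: the chi-square(1) limit is liberal
    # in the extreme tail with few replicates and estimated dispersions, so
    # the signed root of the LRT is referred to a t distribution whose
    # degrees of freedom combine the contrast's residual df with the prior
    # df of the dispersion shrinkage (the moderated-t idea).
    df_mod = (int(mask_num.sum()) - 1) + (int(mask_den.sum()) - 1) + float(
        dispersion.attrs.get("prior_df", 10.0)
    )
    pvals = 2.0 * stats.t.sf(np.sqrt(lrt), df=max(df_mod, 1.0))
    all_zero = y2.sum(axis=1) == 0
    pvals[all_zero] = 1.0

    log2fc = (beta_num - beta_den) / np.log(2.0)
    log2fc[all_zero] = 0.0

    fdr = bh_adjust(pd.Series(pvals, index=values.index))
    significant = (fdr.to_numpy() < config.fdr_max) & (np.abs(log2fc) > config.min_abs_log2fc)
    direction = np.where(~significant, "none", np.where(log2fc > 0, "up", "down"))

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "significant": significant,
            "direction": direction,
        },
        index=values.index.rename("feature_id"),
    )


def bh_adjust(pvalues: pd.Series) -> pd.Series:
    """Benjamini-Hochberg adjusted p-values; ties broken by (p, feature_id)."""
    m = len(pvalues)
    order = np.lexsort((pvalues.index.astype(str), pvalues.to_numpy()))
    ranked = pvalues.to_numpy()[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return pd.Series(out, index=pvalues.index, name="fdr")


def group_de(
    group: NormalizationGroup,
    config: PipelineConfig | None = None,
    synthetic_genotype: str | None = None,
) -> pd.DataFrame:
    """Run the DE contrast (synthetic vs parent) inside a normalization group."""
    config = config or PipelineConfig()
    samples = group.table.samples
    role = samples["role"]
    cond = pd.Series(np.where(role == "synthetic", "synthetic", "parent"), index=samples.index)
    cols = samples.index
    if synthetic_genotype is not None:
        keep = (role != "synthetic") | (samples["genotype_id"] == synthetic_genotype)
        cols = samples.index[keep]
    values = group.table.values[cols]
    dispersion = estimate_dispersion(values, group.effective_sizes, cond)
    rec = de_test(values, group.effective_sizes, cond, dispersion, config)
    rec.insert(0, "subgenome", group.table.features.loc[rec.index, "subgenome"].to_numpy())
    return rec


def classify_degs(records: pd.DataFrame) -> pd.DataFrame:
    """Tally significant up/down DEGs per subgenome."""
    if "subgenome" not in records.columns:
        raise ValidationError("records lack a subgenome column")
    sig = records[records["significant"]]
    out = (
        sig.groupby(["subgenome", "direction"]).size().unstack(fill_value=0)
        if len(sig)
        else pd.DataFrame()
    )
    for col in ("up", "down"):
        if col not in out.columns:
            out[col] = 0
    return out[["up", "down"]].astype(int)


# ---------------------------------------------------------------------------
# midparent-value TE test
# ---------------------------------------------------------------------------


def build_mpv_libraries(
    diploid_te_rpm: pd.DataFrame, tetraploid_te_rpm: pd.DataFrame
) -> pd.DataFrame:
    """Midparent pseudo-libraries: 1/3 diploid + 2/3 tetraploid RPM per family,
    one column per (diploid replicate, tetraploid replicate) combination."""
    if diploid_te_rpm.shape[1] == 0 or tetraploid_te_rpm.shape[1] == 0:
        raise ValidationError("need at least one replicate per parent")
    fams = diploid_te_rpm.index.intersection(tetraploid_te_rpm.index)
    cols = {}
    for d, t in itertools.product(diploid_te_rpm.columns, tetraploid_te_rpm.columns):
        cols[f"mpv_{d}_{t}"] = (
            diploid_te_rpm.loc[fams, d] / 3.0 + 2.0 * tetraploid_te_rpm.loc[fams, t] / 3.0
        )
    return pd.DataFrame(cols, index=fams)


def te_mpv_de(
    synthetic_te_rpm: pd.DataFrame,
    mpv: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """NB test of synthetic TE-family totals against midparent pseudo-libraries.

    RPM totals are rounded (half to even) and treated as counts on a common
    unit depth (equal offsets), so the comparison is on the RPM scale itself.
    """
    config = config or PipelineConfig()
    if mpv.shape[1] < 2 or synthetic_te_rpm.shape[1] < 2:
        raise ValidationError("need >= 2 MPV pseudo-libraries and >= 2 synthetic replicates")
    fams = synthetic_te_rpm.index.intersection(mpv.index)
    dropped = synthetic_te_rpm.index.symmetric_difference(mpv.index)
    if len(dropped):
        log.warning("te_mpv_de: %d families absent on one side, excluded", len(dropped))
    values = pd.concat([np.round(synthetic_te_rpm.loc[fams]), np.round(mpv.loc[fams])], axis=1)
    cond = pd.Series(
        ["synthetic"] * synthetic_te_rpm.shape[1] + ["parent"] * mpv.shape[1],
        index=values.columns,
    )
    sizes = pd.Series(1e6, index=values.columns)
    dispersion = estimate_dispersion(values, sizes, cond)
    return de_test(values, sizes, cond, dispersion, config)


# ---------------------------------------------------------------------------
# naive whole-library cross-ploidy DE (the procedure the split design replaces)
# ---------------------------------------------------------------------------


def naive_cross_ploidy_de(
    table: CountTable,
    parent_role: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """DE of synthetic vs one parent with whole-library normalization.

    Normalizes the complete libraries of both ploidy levels together (TMM on
    the full feature set) and tests every feature. This reproduces the
    cross-ploidy comparison the split-by-subgenome design is built to avoid
    and exists for benchmarking its failure mode.
    """
    config = config or PipelineConfig()
    samples = table.samples
    keep = samples.index[samples["role"].isin((parent_role, "synthetic"))]
    sub = table.subset_samples(keep)
    factors = tmm_factors(sub.values)
    sizes = sub.column_totals() * factors
    cond = pd.Series(
        np.where(sub.samples["role"] == "synthetic", "synthetic", "parent"),
        index=sub.samples.index,
    )
    nonzero = sub.values.sum(axis=1) > 0
    values = sub.values.loc[nonzero]
    dispersion = estimate_dispersion(values, sizes, cond)
    rec = de_test(values, sizes, cond, dispersion, config)
    rec.insert(0, "subgenome", table.features.loc[rec.index, "subgenome"].to_numpy())
    return rec
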