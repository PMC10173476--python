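"""In-silico karyotype screening and sample-consistency diagnostics.

Aneuploidy is screened from expression alone: median TPM over windows of 200
position-ordered genes in a polyploid sample is compared to the same windows
in a replicate-averaged parental reference (AB genes against the tetraploid
parent, D genes against the diploid parent). Because the parents and the
hexaploid have different transcriptome sizes, the raw window ratios are
rescaled by the median ratio within the sample's subgenome partition, so a
euploid chromosome sits near 1, a monosomy near 0.5 and a trisomy near 1.5.

Consistency diagnostics are a Pearson-correlation heatmap of
log(RPM + 0.001) with UPGMA clustering, and a PCA of the RPM profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_io import CountTable, PipelineConfig, ValidationError, log

_GENE_CLASSES = ("hc_gene", "lc_gene")


@dataclass
class KaryotypeProfile:
    sample_id: str
    windows: pd.DataFrame  # chromosome, window_index, n_genes, ratio_raw, ratio
    flags: dict = field(default_factory=dict)  # chromosome -> flag


def filter_expressed_genes(tpm: CountTable, config: PipelineConfig | None = None) -> pd.Index:
    """Genes retained for karyotyping: TPM above the floor in enough samples."""
    config = config or PipelineConfig()
    genes = tpm.features["feature_class"].isin(_GENE_CLASSES)
    expressed = (tpm.values > config.tpm_floor).sum(axis=1) >= config.min_samples_expressed
    return tpm.values.index[genes & expressed]


def parental_reference(tpm: CountTable) -> pd.Series:
    """Replicate-averaged parental TPM: AB genes from the tetraploid parent,
    D genes from the diploid parent."""
    roles = tpm.samples["role"]
    dip = tpm.samples.index[roles == "diploid_parent"]
    tet = tpm.samples.index[roles == "tetraploid_parent"]
    if len(dip) == 0 or len(tet) == 0:
        raise ValidationError("parental reference needs both parent roles")
    sub = tpm.features["subgenome"]
    ref = pd.Series(np.nan, index=tpm.values.index)
    ref[sub == "D"] = tpm.values.loc[sub == "D", dip].mean(axis=1)
    ab = sub.isin(("A", "B"))
    ref[ab] = tpm.values.loc[ab, tet].mean(axis=1)
    return ref


def karyotype_ratios(
    sample_tpm: pd.Series,
    reference_tpm: pd.Series,
    features: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Windowed median TPM ratios (sample / reference), partition-rescaled.

    Genes are sorted by (chromosome, order_index) and cut into consecutive
    non-overlapping windows of ``window_size``; a final partial window is
    kept when it holds at least half a window. Windows whose reference
    median is zero are dropped with a warning. Raw ratios are rescaled by
    the median raw ratio within the sample's AB or D partition so the
    typical euploid window sits at 1.
    """
    config = config or PipelineConfig()
    genes = sample_tpm.index.intersection(reference_tpm.index)
    feat = features.loc[genes]
    keep = feat["subgenome"].isin(("A", "B", "D"))
    feat = feat[keep].sort_values(["chromosome", "order_index"], kind="stable")

    rows = []
    w = config.window_size
    for chrom, block in feat.groupby("chromosome", sort=True):
        ids = block.index
        n = len(ids)
        starts = range(0, n, w)
        for k, s in enumerate(starts):
            window_ids = ids[s : s + w]
            if len(window_ids) < w and len(window_ids) < w / 2:
                break
            ref_med = float(np.median(reference_tpm.loc[window_ids]))
            if ref_med <= 0:
                log.warning("karyotype: zero reference median in %s window %d", chrom, k)
                continue
            samp_med = float(np.median(sample_tpm.loc[window_ids]))
            rows.append(
                (
                    chrom,
                    k,
                    len(window_ids),
                    block.loc[window_ids[0], "subgenome"],
                    samp_med / ref_med,
                )
            )
    windows = pd.DataFrame(
        rows, columns=["chromosome", "window_index", "n_genes", "subgenome", "ratio_raw"]
    )
    if windows.empty:
        raise ValidationError("no karyotype windows could be formed")
    partition = np.where(windows["subgenome"] == "D", "D", "AB")
    windows["partition"] = partition
    med = windows.groupby("partition")["ratio_raw"].transform("median")
    windows["ratio"] = windows["ratio_raw"] / med
    return windows


def flag_aneuploidy(windows: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Flag each chromosome from its median rescaled window ratio."""
    config = config or PipelineConfig()
    flags = {}
    for chrom, block in windows.groupby("chromosome"):
        med = float(block["ratio"].median())
        if config.mono_band[0] <= med <= config.mono_band[1]:
            flags[chrom] = "monosomy_candidate"
        elif config.tri_band[0] <= med <= config.tri_band[1]:
            flags[chrom] = "trisomy_candidate"
        else:
            flags[chrom] = "euploid"
    return flags


def karyotype_profile(
    tpm: CountTable,
    sample_id: str,
    config: PipelineConfig | None = None,
    retained: pd.Index | None = None,
    reference: pd.Series | None = None,
) -> KaryotypeProfile:
    """Full karyotype screen of one polyploid sample against the parents."""
    config = config or PipelineConfig()
    if retained is None:
        retained = filter_expressed_genes(tpm, config)
    if reference is None:
        reference = parental_reference(tpm)
    sample = tpm.values.loc[retained, sample_id]
    windows = karyotype_ratios(sample, reference.loc[retained], tpm.features, config)
    flags = flag_aneuploidy(windows, config)
    return KaryotypeProfile(sample_id=sample_id, windows=windows, flags=flags)


def screen_polyploids(tpm: CountTable, config: PipelineConfig | None = None) -> list[KaryotypeProfile]:
    """Karyotype-screen every synthetic / natural-hexaploid sample."""
    config = config or PipelineConfig()
    retained = filter_expressed_genes(tpm, config)
    reference = parental_reference(tpm)
    poly = tpm.samples.index[tpm.samples["role"].isin(("synthetic", "natural_hexaploid"))]
    return [
        karyotype_profile(tpm, sid, config, retained=retained, reference=reference)
        for sid in poly
    ]


# ---------------------------------------------------------------------------
# consistency diagnostics
# ---------------------------------------------------------------------------


def sample_correlation_heatmap(rpm: CountTable) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation of log(RPM + 0.001) with UPGMA leaf order."""
    if rpm.n_samples < 2:
        raise ValidationError("correlation heatmap needs at least two samples")
    x = np.log(rpm.values.to_numpy(dtype=float) + 0.001)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = rpm.values.columns[np.flatnonzero(sd == 0)[0]]
        raise ValidationError(f"sample {bad!r} is constant after log transform")
    corr = np.corrcoef(x, rowvar=False)
    corr_df = pd.DataFrame(corr, index=rpm.values.columns, columns=rpm.values.columns)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [rpm.values.columns[i] for i in hierarchy.leaves_list(linkage)]
    return corr_df, order


def pca_overview(rpm: CountTable, n_components: int = 2) -> pd.DataFrame:
    """Sample scores on the top principal components of the RPM profiles.

    Components are ordered by explained variance; each component's sign is
    fixed by making its largest-magnitude loading positive. Explained
    variance fractions are exposed via ``result.attrs['explained']``.
    """
    if rpm.n_samples < 3:
        raise ValidationError("PCA needs at least three samples")
    x = rpm.values.to_numpy(dtype=float).T  # samples x features
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] *= -1.0
            scores[:, j] *= -1.0
    total = float((s**2).sum())
    out = pd.DataFrame(
        scores,
        index=rpm.values.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    out.attrs["explained"] = (s[:k] ** 2 / total if total > 0 else np.zeros(k)).tolist()
    return out
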