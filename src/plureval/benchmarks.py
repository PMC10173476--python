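"""Self-contained benchmark experiments on simulated data with known truth.

These functions wire the generator to the analysis stages to measure the
pipeline's operating characteristics: karyotype copy-number recovery, DE
calibration (type-I error and power), the efficacy of the subgenome-mismatch
correction, the false-positive cost of naive whole-library cross-ploidy
normalization relative to the split-by-subgenome design, and recovery of
TE-family deviations from the midparent value.

Every experiment is deterministic for a fixed seed and sized to run on a
single CPU in seconds to a few minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import CountTable, PipelineConfig
from .karyotype import screen_polyploids
from .normalize_de import (
    build_mpv_libraries,
    build_normalization_groups,
    group_de,
    naive_cross_ploidy_de,
    te_mpv_de,
)
from .preprocess import (
    correct_subgenome_mismatch,
    normalize_expression,
    redistribute_parent_te_counts,
    split_by_subgenome,
    te_family_totals,
)
from .simulate import SimulationConfig, simulate_experiment, simulate_te_families


def _roles(table: CountTable):
    roles = table.samples["role"]
    by = {
        r: table.subset_samples(table.samples.index[roles == r])
        for r in ("diploid_parent", "tetraploid_parent", "synthetic")
    }
    return by["diploid_parent"], by["tetraploid_parent"], by["synthetic"]


def _split_de(
    table: CountTable,
    config: PipelineConfig,
    corrected: bool = True,
) -> pd.DataFrame:
    """The full split-by-subgenome DE route on one simulated experiment."""
    dip, tet, syn = _roles(table)
    if corrected:
        dip, tet = correct_subgenome_mismatch(dip, tet, config)
    ab, d = split_by_subgenome(syn)
    groups = build_normalization_groups(ab, d, dip, tet)
    return pd.concat([group_de(g, config) for g in groups])


# ---------------------------------------------------------------------------
# karyotype copy-number recovery
# ---------------------------------------------------------------------------


def karyotype_copy_ratio_experiment(
    copy_ratio: float,
    seed: int,
    n_triads: int = 5600,  # 800 genes per chromosome -> 4 windows of 200 each
    baseline_mean: float = 100.0,
    dispersion: float = 0.1,
    replicates: int = 3,
    chromosome: str = "chr2D",
) -> dict:
    """Plant one aneuploid chromosome in a synthetic hexaploid and screen it.

    All synthetic replicates carry the aneuploidy (one plant, one karyotype).
    Returns the affected chromosome's median rescaled window ratio pooled
    over replicates, the per-chromosome flags and the problem size.
    """
    sample_ids = [f"Lx109_r{i}" for i in range(1, replicates + 1)]
    cfg = SimulationConfig(
        n_triads=n_triads,
        baseline_mean=baseline_mean,
        dispersion=dispersion,
        mismatch_rate=0.0,  # pure copy-number signal, no cross-mapping overlay
        replicates={
            "diploid_parent": replicates,
            "tetraploid_parent": replicates,
            "synthetic": replicates,
        },
        aneuploidy_spec=[
            {"sample_id": s, "chromosome": chromosome, "copy_ratio": copy_ratio}
            for s in sample_ids
        ],
        rng_seed=seed,
    )
    table, _, _ = simulate_experiment(cfg)
    tpm = normalize_expression(table, "tpm")
    profiles = [p for p in screen_polyploids(tpm) if p.sample_id in sample_ids]
    affected = pd.concat(
        [p.windows.loc[p.windows["chromosome"] == chromosome, "ratio"] for p in profiles]
    )
    flags = {p.sample_id: p.flags for p in profiles}
    n_genes = int((table.features["chromosome"] == chromosome).sum())
    return {
        "median_ratio": float(affected.median()),
        "flags": flags,
        "chromosome": chromosome,
        "n_genes_on_chromosome": n_genes,
    }


# ---------------------------------------------------------------------------
# DE calibration
# ---------------------------------------------------------------------------


def _calibration_config(seed: int, de_spec=None) -> SimulationConfig:
    # ~2000 gene features, n = 3 + 3 per contrast side, phi = 0.1
    return SimulationConfig(
        n_triads=667,
        baseline_mean=100.0,
        dispersion=0.1,
        mismatch_rate=0.0,
        de_spec=de_spec or [],
        rng_seed=seed,
    )


def de_null_calibration(seed: int, n_runs: int = 20) -> dict:
    """Type-I control: split-pipeline DEG counts under the generator's NB null."""
    counts = []
    raw_p_fractions = []
    for i in range(n_runs):
        table, _, _ = simulate_experiment(_calibration_config(seed + i))
        rec = _split_de(table, PipelineConfig(), corrected=False)
        counts.append(int(rec["significant"].sum()))
        raw_p_fractions.append(float((rec["pvalue"] < 0.05).mean()))
    return {
        "deg_counts": counts,
        "runs_with_zero_degs": int(sum(c == 0 for c in counts)),
        "n_runs": n_runs,
        "mean_raw_p_lt_05": float(np.mean(raw_p_fractions)),
    }


def de_power(seed: int, n_runs: int = 3, n_de: int = 100) -> dict:
    """Recovery of genes simulated at |log2FC| = 3 (half up, half down)."""
    recovered = total = 0
    for i in range(n_runs):
        spec = [
            {"n_features": n_de // 2, "log2fc": 3.0},
            {"n_features": n_de - n_de // 2, "log2fc": -3.0},
        ]
        table, _, truth = simulate_experiment(_calibration_config(seed + 100 + i, spec))
        rec = _split_de(table, PipelineConfig(), corrected=False)
        true_ids = truth.de_truth.index
        hits = rec.loc[rec.index.intersection(true_ids), "significant"].sum()
        recovered += int(hits)
        total += len(true_ids)
    return {"recovered": recovered, "total": total, "power": recovered / total}


# ---------------------------------------------------------------------------
# mismatch-correction efficacy
# ---------------------------------------------------------------------------


def mismatch_correction_experiment(seed: int, mismatch_rate: float = 0.05) -> dict:
    """Spurious DEGs on mismatch-receiving features, corrected vs uncorrected.

    No true DE is simulated; singleton genes give their decoy homoeologs a
    purely cross-mapped signal, and spread homoeolog bias makes weakly
    expressed triad members sensitive to contamination.
    """
    cfg = SimulationConfig(
        n_triads=800,
        n_singletons_per_subgenome=100,
        baseline_mean=300.0,
        dispersion=0.1,
        mismatch_rate=mismatch_rate,
        bias_spec={"alpha": (2.0, 2.0, 2.0)},
        rng_seed=seed,
    )
    table, _, truth = simulate_experiment(cfg)
    receivers = truth.mismatch_receivers
    config = PipelineConfig()
    out = {}
    for label, corrected in (("corrected", True), ("uncorrected", False)):
        rec = _split_de(table, config, corrected=corrected)
        affected = rec.index.intersection(pd.Index(sorted(receivers)))
        out[label] = int(rec.loc[affected, "significant"].sum())
        out[f"{label}_tested"] = int(len(affected))
    return out


# ---------------------------------------------------------------------------
# split vs whole-library normalization
# ---------------------------------------------------------------------------


def split_normalization_experiment(seed: int) -> dict:
    """False DEGs from whole-library cross-ploidy normalization vs the split
    design, on a simulation whose only real difference is ploidy."""
    cfg = SimulationConfig(
        n_triads=700,
        baseline_mean=100.0,
        dispersion=0.1,
        rng_seed=seed,  # default mismatch_rate: realistic contamination
    )
    table, _, _ = simulate_experiment(cfg)
    config = PipelineConfig()

    rec_split = _split_de(table, config, corrected=True)
    n_split = int(rec_split["significant"].sum())

    n_naive = 0
    for parent_role, subgenomes in (
        ("diploid_parent", ("D",)),
        ("tetraploid_parent", ("A", "B")),
    ):
        rec = naive_cross_ploidy_de(table, parent_role, config)
        on_native = rec["subgenome"].isin(subgenomes)
        n_naive += int(rec.loc[on_native, "significant"].sum())
    return {"split_degs": n_split, "whole_library_degs": n_naive}


# ---------------------------------------------------------------------------
# TE midparent-value recovery
# ---------------------------------------------------------------------------


def te_mpv_recovery(seed: int, n_runs: int = 20) -> dict:
    """Flagging of TE families at 8x the midparent value vs families at MPV."""
    rpm_levels = [100.0, 200.0, 300.0, 500.0, 800.0]
    te_spec = []
    for i, level in enumerate(rpm_levels * 4):
        te_spec.append(
            {"family": f"null_fam{i}", "diploid_rpm": level, "tetraploid_rpm": level * 1.5,
             "log2_mpv_effect": 0.0}
        )
    for i, level in enumerate(rpm_levels):
        te_spec.append(
            {"family": f"up_fam{i}", "diploid_rpm": level, "tetraploid_rpm": level * 1.5,
             "log2_mpv_effect": 3.0}
        )
    config = PipelineConfig()
    ok_runs = 0
    details = []
    for i in range(n_runs):
        cfg = SimulationConfig(te_spec=te_spec, rng_seed=seed + i)
        table, truth = simulate_te_families(cfg)
        dip, tet, syn = _roles(table)
        # TE families are quantified against whole-library depth, not the
        # TE-only column sums
        depth = table.samples["library_depth"]
        dip_tot = te_family_totals(
            normalize_expression(redistribute_parent_te_counts(dip), "rpm", totals=depth)
        )
        tet_tot = te_family_totals(
            normalize_expression(redistribute_parent_te_counts(tet), "rpm", totals=depth)
        )
        syn_tot = te_family_totals(normalize_expression(syn, "rpm", totals=depth))
        mpv = build_mpv_libraries(dip_tot, tet_tot)
        rec = te_mpv_de(syn_tot, mpv, config)
        up = rec.index.str.startswith("up_")
        hit = bool(rec.loc[up, "significant"].all())
        clean = bool(~rec.loc[~up, "significant"].any())
        details.append({"all_effects_flagged": hit, "no_null_flagged": clean})
        ok_runs += int(hit and clean)
    return {"ok_runs": ok_runs, "n_runs": n_runs, "details": details}
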