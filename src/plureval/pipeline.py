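"""End-to-end orchestration: simulate -> preprocess -> QC -> DE -> TE MPV ->
triads -> overlaps, from a single YAML configuration.

The stage order follows the analysis logic: karyotype/consistency QC runs
before differential expression so aneuploid libraries can be flagged (they
are kept with a warning by default and excluded when the pipeline config
sets ``exclude_flagged: true``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core_io import (
    CountTable,
    PipelineConfig,
    ValidationError,
    load_dataset,
    load_triads,
    log,
    write_count_table,
    write_table,
)
from .karyotype import pca_overview, sample_correlation_heatmap, screen_polyploids
from .normalize_de import (
    build_mpv_libraries,
    build_normalization_groups,
    classify_degs,
    group_de,
    te_mpv_de,
)
from .overlaps import overlap_test
from .preprocess import (
    combine_parents_in_silico,
    correct_subgenome_mismatch,
    normalize_expression,
    redistribute_parent_te_counts,
    split_by_subgenome,
    te_family_totals,
)
from .simulate import SimulationConfig, simulate_experiment, simulate_te_families
from .triads import bias_correlation, bias_de_association, triad_movement, triad_states


@dataclass
class RunManifest:
    config_hash: str
    rng_seed: int
    version: str
    stages: list = field(default_factory=list)

    def add(self, name: str, outputs: dict) -> None:
        self.stages.append({"stage": name, "outputs": outputs})

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _by_role(table: CountTable, role: str) -> CountTable:
    ids = table.samples.index[table.samples["role"] == role]
    return table.subset_samples(ids)


def _rows(obj) -> int:
    return int(len(obj))


def load_run_config(config_path) -> dict:
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError("run config must be a mapping")
    if "simulate" in cfg and "data" in cfg:
        raise ValidationError("ambiguous input: both 'simulate' and 'data' blocks present")
    if "simulate" not in cfg and "data" not in cfg:
        raise ValidationError("run config needs a 'simulate' or 'data' block")
    known = {"simulate", "data", "pipeline"}
    unknown = set(cfg) - known
    if unknown:
        raise ValidationError(f"unknown config blocks: {sorted(unknown)}")
    return cfg


def run_pipeline(config_path, out_dir, seed: int | None = None) -> RunManifest:
    """Execute all stages and write result TSVs plus a run manifest."""
    cfg = load_run_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pconf = PipelineConfig.from_dict(cfg.get("pipeline", {}))

    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    manifest = RunManifest(
        config_hash=hashlib.sha256(blob).hexdigest()[:16],
        rng_seed=seed if seed is not None else cfg.get("simulate", {}).get("rng_seed", 0),
        version=__version__,
    )

    # -- stage: input --------------------------------------------------------
    te_table = None
    truth = None
    if "simulate" in cfg:
        sim_kwargs = dict(cfg["simulate"])
        if seed is not None:
            sim_kwargs["rng_seed"] = seed
        for key in ("synthetic_genotypes", "te_smear_weights"):
            if key in sim_kwargs:
                sim_kwargs[key] = tuple(sim_kwargs[key])
        sconf = SimulationConfig(**sim_kwargs)
        genes, triad_table, truth = simulate_experiment(sconf)
        te_table, te_truth = simulate_te_families(sconf)
        truth.te_truth = te_truth.te_truth
        write_count_table(genes, out / "genes")
        write_count_table(te_table, out / "te")
        write_table(triad_table.records, out / "triads.tsv")
        write_table(truth.de_truth, out / "truth_de.tsv")
        write_table(truth.bias_truth, out / "truth_bias.tsv")
        manifest.add(
            "simulate",
            {"genes": _rows(genes.values), "te": _rows(te_table.values), "triads": _rows(triad_table)},
        )
    else:
        data = cfg["data"]
        genes = load_dataset(data["counts"], data["features"], data["samples"])
        triad_table = load_triads(data["triads"], genes.features)
        gene_mask = genes.features["feature_class"].isin(("hc_gene", "lc_gene"))
        if (~gene_mask).any():
            te_table = genes.subset_features(genes.features.index[~gene_mask])
            genes = genes.subset_features(genes.features.index[gene_mask])
        manifest.add("load", {"genes": _rows(genes.values), "triads": _rows(triad_table)})

    # -- stage: preprocess ---------------------------------------------------
    diploid = _by_role(genes, "diploid_parent")
    tetraploid = _by_role(genes, "tetraploid_parent")
    synthetic = _by_role(genes, "synthetic")
    dip_corr, tet_corr = correct_subgenome_mismatch(diploid, tetraploid, pconf)
    syn_ab, syn_d = split_by_subgenome(synthetic)
    write_count_table(dip_corr, out / "diploid_corrected")
    write_count_table(tet_corr, out / "tetraploid_corrected")
    manifest.add(
        "preprocess",
        {"diploid_corrected": _rows(dip_corr.values), "synthetic_ab": _rows(syn_ab.values),
         "synthetic_d": _rows(syn_d.values)},
    )

    # -- stage: qc -----------------------------------------------------------
    tpm = normalize_expression(genes, "tpm")
    profiles = screen_polyploids(tpm, pconf)
    kary_rows = []
    flagged_samples = set()
    for prof in profiles:
        for chrom, flag in prof.flags.items():
            med = prof.windows.loc[prof.windows["chromosome"] == chrom, "ratio"].median()
            kary_rows.append((prof.sample_id, chrom, float(med), flag))
            if flag != "euploid":
                flagged_samples.add(prof.sample_id)
                log.warning("karyotype: sample %s chromosome %s flagged %s",
                            prof.sample_id, chrom, flag)
    kary = pd.DataFrame(
        kary_rows, columns=["sample_id", "chromosome", "median_ratio", "flag"]
    ).set_index("sample_id")
    write_table(kary, out / "karyotype.tsv")

    rpm = normalize_expression(genes, "rpm")
    corr, order = sample_correlation_heatmap(rpm)
    write_table(corr, out / "sample_correlation.tsv")
    pca = pca_overview(rpm)
    write_table(pca, out / "pca.tsv")
    manifest.add("qc", {"karyotype": _rows(kary), "flagged": len(flagged_samples)})

    if pconf.exclude_flagged and flagged_samples:
        keep = [s for s in synthetic.samples.index if s not in flagged_samples]
        synthetic = synthetic.subset_samples(keep)
        syn_ab, syn_d = split_by_subgenome(synthetic)
        log.warning("excluding flagged samples: %s", sorted(flagged_samples))

    # -- stage: de -----------------------------------------------------------
    groups = build_normalization_groups(syn_ab, syn_d, dip_corr, tet_corr)
    genotypes = sorted(set(synthetic.samples["genotype_id"]))
    de_by_genotype: dict[str, pd.DataFrame] = {}
    for geno in genotypes:
        parts = [
            group_de(g, pconf, synthetic_genotype=geno)
            for g in groups
            if geno in g.synthetic_genotypes
        ]
        rec = pd.concat(parts)
        de_by_genotype[geno] = rec
        write_table(rec, out / f"de_{geno}.tsv")
        write_table(classify_degs(rec), out / f"de_{geno}_summary.tsv")
    manifest.add(
        "de", {f"de_{g}": _rows(r) for g, r in de_by_genotype.items()}
    )

    # -- stage: te_mpv -------------------------------------------------------
    if te_table is not None and (te_table.features["feature_class"] == "te_family").any():
        # TE RPMs use whole-library depth: gene-assigned + TE-assigned reads
        te_depth = genes.column_totals().add(te_table.column_totals(), fill_value=0.0)
        te_rpm_parents = {}
        for role in ("diploid_parent", "tetraploid_parent"):
            part = redistribute_parent_te_counts(_by_role(te_table, role))
            te_rpm_parents[role] = te_family_totals(
                normalize_expression(part, "rpm", totals=te_depth)
            )
        syn_te = te_family_totals(
            normalize_expression(_by_role(te_table, "synthetic"), "rpm", totals=te_depth)
        )
        mpv = build_mpv_libraries(
            te_rpm_parents["diploid_parent"], te_rpm_parents["tetraploid_parent"]
        )
        te_rec = te_mpv_de(syn_te, mpv, pconf)
        write_table(te_rec, out / "te_mpv_de.tsv")
        manifest.add("te_mpv", {"te_mpv_de": _rows(te_rec)})

    # -- stage: triads -------------------------------------------------------
    dip_rpm = normalize_expression(diploid, "rpm")
    tet_rpm = normalize_expression(tetraploid, "rpm")
    insilico = combine_parents_in_silico(
        dip_rpm, tet_rpm, (pconf.insilico_diploid_weight, pconf.insilico_tetraploid_weight)
    )
    parent_states = triad_states(insilico, triad_table, pconf)
    write_table(parent_states, out / "triads_insilico_parents.tsv")
    syn_rpm = normalize_expression(synthetic, "rpm")
    triad_outputs = {"insilico": _rows(parent_states)}
    for geno in genotypes:
        cols = syn_rpm.samples.index[syn_rpm.samples["genotype_id"] == geno]
        states = triad_states(syn_rpm, triad_table, pconf, sample_ids=cols)
        write_table(states, out / f"triads_{geno}.tsv")
        moves = triad_movement(parent_states, states, pconf)
        write_table(moves, out / f"triad_movement_{geno}.tsv")
        r, _ = bias_correlation(parent_states, states)
        assoc = bias_de_association(states, triad_table, de_by_genotype[geno], pconf)
        assoc["parent_bias_correlation"] = r
        with open(out / f"bias_de_association_{geno}.json", "w") as fh:
            json.dump(assoc, fh, indent=2)
        triad_outputs[geno] = _rows(states)
    manifest.add("triads", triad_outputs)

    # -- stage: overlaps -----------------------------------------------------
    if len(genotypes) >= 2:
        rows = []
        for i in range(len(genotypes)):
            for j in range(i + 1, len(genotypes)):
                g1, g2 = genotypes[i], genotypes[j]
                r1, r2 = de_by_genotype[g1], de_by_genotype[g2]
                background = set(r1.index[r1["pvalue"].notna()]) & set(r2.index)
                s1 = {f: d for f, d in r1.loc[r1["significant"], "direction"].items()}
                s2 = {f: d for f, d in r2.loc[r2["significant"], "direction"].items()}
                s1 = {f: d for f, d in s1.items() if f in background}
                s2 = {f: d for f, d in s2.items() if f in background}
                res = overlap_test(s1, s2, background)
                rows.append({"set1": g1, "set2": g2, **res.as_dict()})
        ov = pd.DataFrame(rows).set_index("set1")
        write_table(ov, out / "overlaps.tsv")
        manifest.add("overlaps", {"overlaps": _rows(ov)})

    manifest.write(out / "manifest.json")
    return manifest
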