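"""Seeded generator of parent / synthetic-hexaploid count tables with known truth.

The generator emulates post-mapping RNA-seq count tables for a wheat-style
polyploidization experiment: a diploid (DD) parent, a tetraploid (AABB)
parent and synthetic hexaploid (AABBDD) replicates sequenced to comparable
depth. Counts are negative-binomial (variance = mu + phi * mu^2) around
per-gene expected values that reflect

* a per-triad baseline expression level (lognormal around ``baseline_mean``),
* a per-triad homoeolog-bias vector on the 2-simplex (parental legacy: the
  same vector drives parents and synthetics),
* optional true differential expression in the synthetics (``de_spec``),
* chromosome dosage (monosomy/trisomy via ``aneuploidy_spec``),
* library depth: every library is sequenced to a similar total, so a gene
  native to a lower-ploidy parent takes a proportionally larger share of
  that parent's library.

Cross-mapping contamination ("subgenome mismatches") is injected by moving a
Binomial(count, mismatch_rate) portion of each gene's reads to its homoeolog
partner features, so library totals are conserved. TE-family tables are
simulated separately with per-family totals smeared multinomially across
A/B/D/un subgenome buckets, emulating random placement of multi-mapping reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    CountTable,
    TriadTable,
    ValidationError,
    GENE_SUBGENOMES,
)

_DECOY_SUBGENOME = {"A": "D", "B": "D", "D": "A"}


@dataclass
class SimulationConfig:
    """Study-design and statistical parameters of the generator."""

    n_triads: int = 2000
    n_singletons_per_subgenome: int = 0
    n_chromosomes_per_subgenome: int = 7  # as in each wheat subgenome
    replicates: dict = field(
        default_factory=lambda: {"diploid_parent": 3, "tetraploid_parent": 3, "synthetic": 3}
    )
    synthetic_genotypes: tuple = ("Lx109",)
    diploid_genotype: str = "tauschii109"
    tetraploid_genotype: str = "langdon"
    tissue: str = "grain"
    baseline_mean: float = 100.0
    expression_sigma: float = 0.5
    dispersion: float = 0.1
    library_size: int = 0  # 0 -> n_hexaploid_genes * baseline_mean
    library_size_jitter: float = 0.1
    de_spec: list = field(default_factory=list)
    bias_spec: dict = field(default_factory=lambda: {"alpha": (8.0, 8.0, 8.0)})
    mismatch_rate: float = 0.02
    aneuploidy_spec: list = field(default_factory=list)
    # TE-family block
    n_te_families: int = 30
    te_spec: list = field(default_factory=list)
    te_dispersion: float = 0.05
    te_rpm_log_mean: float = 5.5  # lognormal location of per-family RPM levels
    te_rpm_log_sigma: float = 1.0
    te_smear_weights: tuple = (0.25, 0.25, 0.25, 0.25)  # A, B, D, un
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_triads < 1:
            raise ValidationError("n_triads must be positive")
        if not (0.0 <= self.mismatch_rate < 1.0):
            raise ValidationError("mismatch_rate must be in [0, 1)")
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise ValidationError("baseline_mean must be > 0 and dispersion >= 0")
        for entry in self.aneuploidy_spec:
            if entry["copy_ratio"] not in (0.5, 1.5):
                raise ValidationError("copy_ratio must be 0.5 (monosomy) or 1.5 (trisomy)")


@dataclass
class SimTruth:
    """Ground-truth tables of one simulated experiment."""

    de_truth: pd.DataFrame  # feature_id -> log2fc (true DE features only)
    bias_truth: pd.DataFrame  # triad_id -> A, B, D parental contributions
    mismatch_truth: pd.DataFrame  # feature_id -> rate, partners
    aneuploidy_truth: pd.DataFrame  # sample_id, chromosome, copy_ratio
    te_truth: pd.DataFrame | None = None  # family -> parental RPMs, MPV effect

    @property
    def mismatch_receivers(self) -> set:
        """Features that receive cross-assigned reads from an expressed partner."""
        out: set = set()
        rate = self.mismatch_truth["rate"]
        for fid, row in self.mismatch_truth.iterrows():
            if rate.loc[fid] > 0:
                for p in (row["partner_1"], row["partner_2"]):
                    if isinstance(p, str) and p:
                        out.add(p)
        return out


# ---------------------------------------------------------------------------
# feature universe
# ---------------------------------------------------------------------------


def _build_features(config: SimulationConfig) -> tuple[pd.DataFrame, TriadTable, pd.DataFrame]:
    """Annotation, triad table and the homoeolog partner map."""
    rows = []
    triad_rows = []
    partners: dict[str, tuple[str, str]] = {}
    n_chrom = config.n_chromosomes_per_subgenome

    for t in range(config.n_triads):
        tid = f"triad{t:05d}"
        ids = {s: f"g{t:05d}{s}" for s in GENE_SUBGENOMES}
        chrom_no = t % n_chrom + 1
        for s in GENE_SUBGENOMES:
            rows.append((ids[s], "hc_gene", s, f"chr{chrom_no}{s}", t // n_chrom))
        triad_rows.append((tid, ids["A"], ids["B"], ids["D"]))
        partners[ids["A"]] = (ids["B"], ids["D"])
        partners[ids["B"]] = (ids["A"], ids["D"])
        partners[ids["D"]] = (ids["A"], ids["B"])

    base = config.n_triads // n_chrom
    for s in GENE_SUBGENOMES:
        for i in range(config.n_singletons_per_subgenome):
            sid = f"s{s}{i:04d}"
            did = f"{sid}dec"
            ds = _DECOY_SUBGENOME[s]
            chrom_no = i % n_chrom + 1
            rows.append((sid, "hc_gene", s, f"chr{chrom_no}{s}", base + i // n_chrom))
            rows.append((did, "lc_gene", ds, f"chr{chrom_no}{ds}", base + i // n_chrom))
            partners[sid] = (did, "")
            partners[did] = (sid, "")

    features = pd.DataFrame(
        rows, columns=["feature_id", "feature_class", "subgenome", "chromosome", "order_index"]
    ).set_index("feature_id")
    # re-rank order_index within each chromosome so it is strictly increasing
    features = features.sort_values(["chromosome", "order_index"], kind="stable")
    features["order_index"] = features.groupby("chromosome").cumcount()
    triads = TriadTable(
        pd.DataFrame(triad_rows, columns=["triad_id", "gene_A", "gene_B", "gene_D"]).set_index(
            "triad_id"
        )
    )
    pmap = pd.DataFrame(
        {
            "partner_1": {k: v[0] for k, v in partners.items()},
            "partner_2": {k: v[1] for k, v in partners.items()},
        }
    ).loc[features.index]
    return features, triads, pmap


def _build_samples(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    reps = config.replicates
    for role, geno, gen in (
        ("diploid_parent", config.diploid_genotype, "P0"),
        ("tetraploid_parent", config.tetraploid_genotype, "P0"),
    ):
        n = int(reps.get(role, 0))
        if n < 1:
            raise ValidationError(f"role {role!r} needs at least one replicate")
        for i in range(1, n + 1):
            rows.append((f"{geno}_r{i}", geno, config.tissue, gen, role, geno))
    n = int(reps.get("synthetic", 0))
    if n < 1:
        raise ValidationError("role 'synthetic' needs at least one replicate")
    for geno in config.synthetic_genotypes:
        for i in range(1, n + 1):
            rows.append((f"{geno}_r{i}", geno, config.tissue, "C2", "synthetic", geno))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "genotype_id", "tissue", "generation_label", "role", "replicate_of"],
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB(mu, phi) with variance mu + phi*mu^2; Poisson when phi == 0."""
    mu = np.asarray(mu, dtype=float)
    if phi <= 0:
        return rng.poisson(mu).astype(float)
    shape = 1.0 / phi
    lam = rng.gamma(shape, scale=mu * phi)
    return rng.poisson(lam).astype(float)


def _resolve_de(config: SimulationConfig, features: pd.DataFrame, rng) -> pd.Series:
    """Per-feature true log2FC (synthetic vs parent) from ``de_spec``."""
    gene_pool = features.index[
        (features["feature_class"].isin(("hc_gene", "lc_gene")))
        & ~features.index.str.endswith("dec")
    ]
    taken: list[str] = []
    lfc = {}
    for entry in config.de_spec:
        if "features" in entry:
            ids = list(entry["features"])
            unknown = [f for f in ids if f not in features.index]
            if unknown:
                raise ValidationError(f"de_spec references unknown feature {unknown[0]!r}")
        else:
            pool = gene_pool.difference(pd.Index(taken))
            if entry.get("subgenome"):
                pool = pool[features.loc[pool, "subgenome"] == entry["subgenome"]]
            n = int(entry["n_features"])
            if n > len(pool):
                raise ValidationError("de_spec asks for more features than available")
            ids = list(rng.choice(pool.to_numpy(), size=n, replace=False))
        taken.extend(ids)
        for f in ids:
            lfc[f] = float(entry["log2fc"])
    return pd.Series(lfc, dtype=float)


def simulate_experiment(config: SimulationConfig) -> tuple[CountTable, TriadTable, SimTruth]:
    """Generate the gene-level experiment: counts, triads and ground truth."""
    rng = np.random.default_rng(config.rng_seed)
    features, triads, pmap = _build_features(config)
    samples = _build_samples(config)

    # gene lengths (for TPM): lognormal around ~2 kb
    features["length_bp"] = np.round(
        np.exp(rng.normal(np.log(2000.0), 0.4, size=len(features)))
    ).astype(int)

    # per-triad baseline and bias
    log_base = rng.normal(
        np.log(config.baseline_mean) - 0.5 * config.expression_sigma**2,
        config.expression_sigma,
        size=config.n_triads,
    )
    triad_base = np.exp(log_base)
    if "vectors" in config.bias_spec:
        bias = np.asarray(config.bias_spec["vectors"], dtype=float)
        if bias.shape != (config.n_triads, 3):
            raise ValidationError("bias_spec vectors must have shape (n_triads, 3)")
    else:
        alpha = np.asarray(config.bias_spec.get("alpha", (8.0, 8.0, 8.0)), dtype=float)
        bias = rng.dirichlet(alpha, size=config.n_triads)
    bias = bias / bias.sum(axis=1, keepdims=True)

    # base expression weight per feature (hexaploid scale)
    w = pd.Series(0.0, index=features.index)
    for j, s in enumerate(GENE_SUBGENOMES):
        ids = triads.records[f"gene_{s}"].to_numpy()
        w.loc[ids] = 3.0 * triad_base * bias[:, j]
    singleton_mask = features.index.str.startswith("s") & ~features.index.str.endswith("dec")
    n_single = int(singleton_mask.sum())
    if n_single:
        w.loc[singleton_mask] = np.exp(
            rng.normal(
                np.log(config.baseline_mean) - 0.5 * config.expression_sigma**2,
                config.expression_sigma,
                size=n_single,
            )
        )

    de_lfc = _resolve_de(config, features, rng)

    lib_size = config.library_size or int(round(len(features) * config.baseline_mean))
    n_hex_genes = len(features)

    aneu = {(e["sample_id"], e["chromosome"]): float(e["copy_ratio"]) for e in config.aneuploidy_spec}
    known_samples = set(samples.index)
    for sid, _ in aneu:
        if sid not in known_samples:
            raise ValidationError(f"aneuploidy_spec references unknown sample {sid!r}")

    native = {
        "diploid_parent": features["subgenome"] == "D",
        "tetraploid_parent": features["subgenome"].isin(("A", "B")),
        "synthetic": features["subgenome"].isin(GENE_SUBGENOMES),
    }

    counts = np.zeros((len(features), len(samples)))
    depths = np.zeros(len(samples))
    feat_chrom = features["chromosome"].to_numpy()
    w_arr = w.to_numpy()
    de_mult = pd.Series(1.0, index=features.index)
    if len(de_lfc):
        de_mult.loc[de_lfc.index] = 2.0 ** de_lfc
    de_arr = de_mult.to_numpy()

    for j, (sid, srow) in enumerate(samples.iterrows()):
        role = srow["role"]
        ws = w_arr * native[role].to_numpy()
        if role == "synthetic":
            ws = ws * de_arr
        for (a_sid, chrom), ratio in aneu.items():
            if a_sid == sid:
                ws = np.where(feat_chrom == chrom, ws * ratio, ws)
        total_w = ws.sum()
        if total_w <= 0:
            raise ValidationError(f"sample {sid!r} has no expressed native features")
        depth = lib_size * np.exp(rng.normal(0.0, config.library_size_jitter))
        depths[j] = depth
        mu = depth * ws / total_w
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)

    # mismatch injection: move Binomial(count, rate) to homoeolog partners
    if config.mismatch_rate > 0:
        idx = {f: i for i, f in enumerate(features.index)}
        p1 = pmap["partner_1"].to_numpy()
        p2 = pmap["partner_2"].to_numpy()
        for j in range(len(samples)):
            y = counts[:, j]
            moved = rng.binomial(y.astype(int), config.mismatch_rate)
            counts[:, j] = y - moved
            both = p2 != ""
            to_first = np.where(both, rng.binomial(moved, 0.5), moved)
            to_second = moved - to_first
            np.add.at(counts[:, j], [idx[p] for p in p1], to_first)
            sel = both & (to_second > 0)
            if sel.any():
                np.add.at(counts[:, j], [idx[p] for p in p2[sel]], to_second[sel])

    samples = samples.assign(library_depth=depths)
    values = pd.DataFrame(counts, index=features.index, columns=samples.index)
    table = CountTable(values, features, samples, unit="counts")

    expressed = w > 0
    mismatch_truth = pmap.copy()
    mismatch_truth["rate"] = np.where(expressed, config.mismatch_rate, 0.0)
    truth = SimTruth(
        de_truth=pd.DataFrame({"log2fc": de_lfc}),
        bias_truth=pd.DataFrame(bias, index=triads.records.index, columns=list(GENE_SUBGENOMES)),
        mismatch_truth=mismatch_truth,
        aneuploidy_truth=pd.DataFrame(
            [
                (e["sample_id"], e["chromosome"], float(e["copy_ratio"]))
                for e in config.aneuploidy_spec
            ],
            columns=["sample_id", "chromosome", "copy_ratio"],
        ),
    )
    return table, triads, truth


# ---------------------------------------------------------------------------
# TE families
# ---------------------------------------------------------------------------


def _resolve_te_spec(config: SimulationConfig, rng) -> pd.DataFrame:
    if config.te_spec:
        spec = pd.DataFrame(config.te_spec).set_index("family")
        if (spec[["diploid_rpm", "tetraploid_rpm"]] < 0).to_numpy().any():
            raise ValidationError("TE RPM levels must be non-negative")
        if "log2_mpv_effect" not in spec.columns:
            spec["log2_mpv_effect"] = 0.0
        return spec
    n = config.n_te_families
    if n < 1:
        raise ValidationError("te_spec is empty and n_te_families < 1")
    levels_d = np.exp(rng.normal(config.te_rpm_log_mean, config.te_rpm_log_sigma, size=n))
    levels_t = np.exp(rng.normal(config.te_rpm_log_mean, config.te_rpm_log_sigma, size=n))
    return pd.DataFrame(
        {
            "diploid_rpm": levels_d,
            "tetraploid_rpm": levels_t,
            "log2_mpv_effect": np.zeros(n),
        },
        index=[f"RLX_famc{i}" for i in range(n)],
    )


def simulate_te_families(config: SimulationConfig) -> tuple[CountTable, SimTruth]:
    """Generate per-family TE counts smeared across subgenome buckets.

    Each family's library-level total is NB around its role-specific expected
    RPM x library depth; the synthetic expectation is the midparent value
    (1/3 diploid + 2/3 tetraploid RPM) times ``2 ** log2_mpv_effect``. The
    total is then smeared multinomially across per-subgenome buckets
    (A/B/D/un) regardless of ploidy role, emulating random reporting of
    multi-mapping reads.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    spec = _resolve_te_spec(config, rng)
    samples = _build_samples(config)
    lib_size = config.library_size or int(
        round((3 * config.n_triads + 6 * config.n_singletons_per_subgenome) * config.baseline_mean)
    )

    buckets = ["A", "B", "D", "un"]
    rows = []
    for fam in spec.index:
        for b in buckets:
            rows.append((f"{fam}_{b}", "te_family", b, "chrUn", 0, np.nan))
    features = pd.DataFrame(
        rows,
        columns=["feature_id", "feature_class", "subgenome", "chromosome", "order_index", "length_bp"],
    ).set_index("feature_id")
    features["order_index"] = features.groupby("chromosome").cumcount()

    mpv = spec["diploid_rpm"] / 3.0 + 2.0 * spec["tetraploid_rpm"] / 3.0
    level = {
        "diploid_parent": spec["diploid_rpm"],
        "tetraploid_parent": spec["tetraploid_rpm"],
        "synthetic": mpv * 2.0 ** spec["log2_mpv_effect"],
    }
    weights = np.asarray(config.te_smear_weights, dtype=float)
    weights = weights / weights.sum()

    counts = np.zeros((len(features), len(samples)))
    depths = np.zeros(len(samples))
    for j, (sid, srow) in enumerate(samples.iterrows()):
        depth = lib_size * np.exp(rng.normal(0.0, config.library_size_jitter))
        depths[j] = depth
        mu = level[srow["role"]].to_numpy() * depth / 1e6
        totals = _nb_draw(rng, mu, config.te_dispersion).astype(int)
        smear = np.vstack([rng.multinomial(t, weights) for t in totals])
        counts[:, j] = smear.reshape(-1)

    samples = samples.assign(library_depth=depths)
    values = pd.DataFrame(counts, index=features.index, columns=samples.index)
    table = CountTable(values, features, samples, unit="counts")
    truth = SimTruth(
        de_truth=pd.DataFrame(columns=["log2fc"]),
        bias_truth=pd.DataFrame(columns=list(GENE_SUBGENOMES)),
        mismatch_truth=pd.DataFrame(columns=["partner_1", "partner_2", "rate"]),
        aneuploidy_truth=pd.DataFrame(columns=["sample_id", "chromosome", "copy_ratio"]),
        te_truth=spec,
    )
    return table, truth
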