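"""Homoeolog expression bias over triads.

Each triad's A/B/D homoeolog contributions form a point on the 2-simplex.
A triad is classified by its nearest of seven reference points (Euclidean
"eigen" distance): the centre (1/3, 1/3, 1/3) for Balanced, a vertex for
Dominant A/B/D and an edge midpoint for Suppressed A/B/D. Movement between
two states (e.g. in-silico parents vs synthetic) is the Euclidean distance
between contribution vectors; a movement is reported when the category
changed and the distance exceeds the 0.3 cut-off.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CountTable, PipelineConfig, TriadTable, ValidationError, log

#: fixed order breaks nearest-centroid ties deterministically
CENTROIDS: list[tuple[str, tuple[float, float, float]]] = [
    ("Balanced", (1 / 3, 1 / 3, 1 / 3)),
    ("Dominant A", (1.0, 0.0, 0.0)),
    ("Dominant B", (0.0, 1.0, 0.0)),
    ("Dominant D", (0.0, 0.0, 1.0)),
    ("Suppressed A", (0.0, 0.5, 0.5)),
    ("Suppressed B", (0.5, 0.0, 0.5)),
    ("Suppressed D", (0.5, 0.5, 0.0)),
]

CATEGORY_NAMES = [name for name, _ in CENTROIDS]
_CENTROID_ARR = np.array([c for _, c in CENTROIDS])


def eigen_distance(p, q) -> float:
    """Euclidean distance between two contribution vectors on the simplex."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.sqrt(((p - q) ** 2).sum()))


def triad_contributions(
    rpm: CountTable,
    triad_table: TriadTable,
    config: PipelineConfig | None = None,
    sample_ids=None,
) -> pd.DataFrame:
    """Replicate-mean triad contributions with the 5 RPM total filter.

    Expression per homoeolog is the replicate-mean RPM over ``sample_ids``
    (default: all columns). Triads whose total mean RPM falls below
    ``min_triad_rpm`` are removed (a total of exactly 5 is kept). Returns a
    frame indexed by triad_id with columns A, B, D (contributions summing to
    1) and total_rpm.
    """
    config = config or PipelineConfig()
    if rpm.unit != "rpm":
        raise ValidationError("triad contributions expect an RPM table")
    cols = rpm.values.columns if sample_ids is None else pd.Index(sample_ids)
    mean = rpm.values[cols].mean(axis=1)
    rec = triad_table.records
    missing = (
        set(rec["gene_A"]) | set(rec["gene_B"]) | set(rec["gene_D"])
    ) - set(mean.index)
    if missing:
        raise ValidationError(f"triad gene {sorted(missing)[0]!r} missing from table")
    a = mean.loc[rec["gene_A"]].to_numpy()
    b = mean.loc[rec["gene_B"]].to_numpy()
    d = mean.loc[rec["gene_D"]].to_numpy()
    total = a + b + d
    keep = total >= config.min_triad_rpm
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = np.column_stack([a, b, d]) / total[:, None]
    out = pd.DataFrame(contrib, index=rec.index, columns=["A", "B", "D"])
    out["total_rpm"] = total
    return out[keep]


def classify_triads(states: pd.DataFrame) -> pd.DataFrame:
    """Assign the nearest-centroid category to each triad state.

    Adds a ``category`` column and one distance column per centroid. Ties
    are broken by the fixed centroid order (Balanced first, then Dominant
    A/B/D, then Suppressed A/B/D).
    """
    pts = states[["A", "B", "D"]].to_numpy(dtype=float)
    dists = np.sqrt(((pts[:, None, :] - _CENTROID_ARR[None, :, :]) ** 2).sum(axis=2))
    out = states.copy()
    # np.argmin returns the first minimum, i.e. the fixed-order tie-break
    out["category"] = [CATEGORY_NAMES[i] for i in np.argmin(dists, axis=1)]
    for j, name in enumerate(CATEGORY_NAMES):
        out[f"dist_{name.replace(' ', '_')}"] = dists[:, j]
    return out


def triad_states(
    rpm: CountTable,
    triad_table: TriadTable,
    config: PipelineConfig | None = None,
    sample_ids=None,
) -> pd.DataFrame:
    """Contributions + categories in one step."""
    return classify_triads(triad_contributions(rpm, triad_table, config, sample_ids))


def bias_correlation(
    states_x: pd.DataFrame, states_y: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of A/B/D contributions over shared retained triads.

    Returns the coefficient and the paired long-format points
    (triad_id, subgenome, x, y) for scatter plotting.
    """
    shared = states_x.index.intersection(states_y.index)
    if len(shared) < 2:
        raise ValidationError("need at least two shared retained triads")
    frames = []
    for s in ("A", "B", "D"):
        frames.append(
            pd.DataFrame(
                {
                    "triad_id": shared,
                    "subgenome": s,
                    "x": states_x.loc[shared, s].to_numpy(),
                    "y": states_y.loc[shared, s].to_numpy(),
                }
            )
        )
    paired = pd.concat(frames, ignore_index=True)
    r = float(np.corrcoef(paired["x"], paired["y"])[0, 1])
    return r, paired


def triad_movement(
    states_from: pd.DataFrame,
    states_to: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-triad movement between two categorized state sets.

    Triads retained in only one sample are excluded (not expressed in both).
    A movement is ``reported`` when the category changed and the distance
    exceeds ``movement_cutoff``. Summary counts of unbalanced->balanced and
    balanced->unbalanced reported transitions are exposed in ``attrs``.
    """
    config = config or PipelineConfig()
    for df in (states_from, states_to):
        if "category" not in df.columns:
            raise ValidationError("states must be categorized (see classify_triads)")
    shared = states_from.index.intersection(states_to.index)
    p = states_from.loc[shared, ["A", "B", "D"]].to_numpy(dtype=float)
    q = states_to.loc[shared, ["A", "B", "D"]].to_numpy(dtype=float)
    dist = np.sqrt(((p - q) ** 2).sum(axis=1))
    cat_from = states_from.loc[shared, "category"]
    cat_to = states_to.loc[shared, "category"]
    changed = (cat_from != cat_to).to_numpy()
    reported = changed & (dist > config.movement_cutoff)
    out = pd.DataFrame(
        {
            "from_category": cat_from,
            "to_category": cat_to,
            "distance": dist,
            "category_changed": changed,
            "reported": reported,
        },
        index=shared,
    )
    rep = out[out["reported"]]
    out.attrs["unbalanced_to_balanced"] = int(
        ((rep["from_category"] != "Balanced") & (rep["to_category"] == "Balanced")).sum()
    )
    out.attrs["balanced_to_unbalanced"] = int(
        ((rep["from_category"] == "Balanced") & (rep["to_category"] != "Balanced")).sum()
    )
    return out


def bias_de_association(
    states: pd.DataFrame,
    triad_table: TriadTable,
    de_records: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> dict:
    """Association of homoeolog bias with differential expression.

    (i) Welch two-sample T-test comparing the log2 fold changes of dominant
    homoeolog genes (contribution > biased_high) against suppressed ones
    (contribution < biased_low). (ii) Chi-square independence test of the
    2x2 table (triad contains a significant DEG) x (triad unbalanced).
    """
    config = config or PipelineConfig()
    rec = triad_table.records.loc[triad_table.records.index.intersection(states.index)]
    gene_cols = {"A": "gene_A", "B": "gene_B", "D": "gene_D"}

    dominant_genes, suppressed_genes = [], []
    for s, col in gene_cols.items():
        contrib = states.loc[rec.index, s]
        dominant_genes.extend(rec.loc[contrib > config.biased_high, col])
        suppressed_genes.extend(rec.loc[contrib < config.biased_low, col])

    report: dict = {}
    lfc = de_records["log2fc"]
    dom = lfc.loc[lfc.index.intersection(pd.Index(dominant_genes))]
    sup = lfc.loc[lfc.index.intersection(pd.Index(suppressed_genes))]
    report["n_dominant"] = int(len(dom))
    report["n_suppressed"] = int(len(sup))
    if len(dom) >= 2 and len(sup) >= 2:
        if np.allclose(dom.var(ddof=1) + sup.var(ddof=1), 0.0) and np.isclose(
            dom.mean(), sup.mean()
        ):
            t_stat, t_p = 0.0, 1.0
        else:
            t_stat, t_p = stats.ttest_ind(dom, sup, equal_var=False)
        report["t_statistic"] = float(t_stat)
        report["t_pvalue"] = float(t_p)
    else:
        log.warning("bias_de_association: a homoeolog class has < 2 members; T-test skipped")
        report["t_statistic"] = np.nan
        report["t_pvalue"] = np.nan

    sig_genes = set(de_records.index[de_records["significant"]])
    has_deg = rec[list(gene_cols.values())].isin(sig_genes).any(axis=1)
    unbalanced = states.loc[rec.index, "category"] != "Balanced"
    table = pd.crosstab(has_deg, unbalanced)
    table = table.reindex(index=[False, True], columns=[False, True], fill_value=0)
    report["contingency"] = table.to_numpy().tolist()
    if (table.to_numpy().sum(axis=0) > 0).all() and (table.to_numpy().sum(axis=1) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        report["chi2_statistic"] = float(chi2)
        report["chi2_pvalue"] = float(p)
    else:
        log.warning("bias_de_association: degenerate contingency table; chi-square skipped")
        report["chi2_statistic"] = np.nan
        report["chi2_pvalue"] = np.nan
    return report


def ternary_coordinates(states: pd.DataFrame) -> pd.DataFrame:
    """Barycentric -> Cartesian coordinates for external ternary plotting."""
    a = states["A"].to_numpy()
    b = states["B"].to_numpy()
    d = states["D"].to_numpy()
    x = 0.5 * (2 * b + d) / (a + b + d)
    y = (np.sqrt(3) / 2) * d / (a + b + d)
    return pd.DataFrame({"x": x, "y": y}, index=states.index)
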