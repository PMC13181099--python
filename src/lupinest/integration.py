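"""Cross-experiment synthesis: standardization, ordination, clustering,
correlation screening, the Integrated Selection Index, and soil-matched
accession recommendations.

The Integrated Selection Index (ISI) is computed at 14 days after sowing
from the substrate-pH experiment only, over the non-limiting pH levels 5.5
and 7.0 (alkaline 8.5 is excluded to avoid bias from inhibitory
conditions):

* establishment component: mean establishment proportion over pH 5.5/7.0;
* growth component: mean total seedling length (mm) over pH 5.5/7.0;
* stability component: 1 / (|est(7.0) - est(5.5)| + 1), which lies in
  (0.5, 1] when establishment is a proportion.

Each component is min-max rescaled to [0, 1] across accessions (a constant
component maps to a neutral 0.5) and the ISI is their unweighted mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame  # trait x component
    scores: pd.DataFrame  # accession x component
    var_explained: np.ndarray  # percent per component, sums to 100


@dataclass(frozen=True)
class ClusteringResult:
    linkage: np.ndarray  # scipy linkage matrix (Ward.D2 on Euclidean distances)
    labels: pd.Series  # cluster id per accession at the chosen k
    mean_silhouette: float
    node_support: pd.DataFrame  # one row per internal node: leaf set, support


def zscore_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (population SD, ddof=0).

    Constant and all-missing columns are dropped with a warning; rows with
    any remaining missing value are rejected (impute upstream).
    """
    if len(table) < 2:
        raise ValueError("need >= 2 accessions to standardize")
    out = {}
    for col in table.columns:
        x = table[col].astype(float)
        if x.isna().all():
            warnings.warn(f"dropping all-missing column {col!r}", stacklevel=2)
            continue
        sd = float(x.std(ddof=0))
        if sd == 0:
            warnings.warn(f"dropping constant column {col!r}", stacklevel=2)
            continue
        out[col] = (x - x.mean()) / sd
    z = pd.DataFrame(out, index=table.index)
    if z.isna().any().any():
        raise ValueError("missing values remain after column screening")
    return z


def pca(z: pd.DataFrame) -> PCAResult:
    """PCA of a standardized matrix via SVD.

    Components are ordered by decreasing variance; each loading column's
    sign is fixed so its largest-magnitude entry is positive. On z-scored
    input this equals the eigendecomposition of the correlation matrix.
    """
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("PCA needs >= 2 rows and >= 2 columns")
    x = z.to_numpy(float)
    x = x - x.mean(axis=0)
    if not np.any(x):
        raise ValueError("matrix has rank 0")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for j in range(vt.shape[0]):
        i_max = np.argmax(np.abs(vt[j]))
        if vt[j, i_max] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    var = s**2
    var_pct = 100.0 * var / var.sum()
    comp_names = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        loadings=pd.DataFrame(vt.T, index=z.columns, columns=comp_names),
        scores=pd.DataFrame(u * s, index=z.index, columns=comp_names),
        var_explained=var_pct,
    )


def _node_leafsets(link: np.ndarray, n: int) -> list[frozenset[int]]:
    """Leaf-index sets for every internal node of a linkage tree."""
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    sets = []
    for i, (a, b, _, _) in enumerate(link[:, :4]):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        sets.append(merged)
    return sets


def ward_cluster(
    z: pd.DataFrame, k: int, bootstrap_reps: int = 100, rng_seed: int = 0
) -> ClusteringResult:
    """Ward.D2 agglomeration on Euclidean distances with bootstrap support.

    Node support is the fraction of row-bootstrap resamples in which the
    node's (unique, resampled) leaf set reappears intact as a node of the
    resampled tree — ordinary resampling support, not a multiscale
    'approximately unbiased' p-value.
    """
    n = len(z)
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must be in [2, {n - 1}], got {k}")
    x = z.to_numpy(float)
    link = linkage(x, method="ward")
    labels = fcluster(link, t=k, criterion="maxclust")
    if len(set(labels)) > 1 and np.ptp(x) > 0:
        sil = float(silhouette_score(x, labels))
    else:
        sil = float("nan")
    node_sets = _node_leafsets(link, n)
    hits = np.zeros(len(node_sets))
    trials = np.zeros(len(node_sets))
    rng = np.random.default_rng(rng_seed)
    for _ in range(bootstrap_reps):
        idx = rng.integers(0, n, size=n)
        uniq = np.unique(idx)
        if len(uniq) < 3:
            continue
        boot_link = linkage(x[uniq], method="ward")
        boot_sets = {frozenset(uniq[list(s)]) for s in _node_leafsets(boot_link, len(uniq))}
        uniq_set = set(uniq.tolist())
        for j, node in enumerate(node_sets):
            restricted = frozenset(i for i in node if i in uniq_set)
            if len(restricted) < 2 or len(restricted) == len(uniq):
                continue
            trials[j] += 1
            if restricted in boot_sets:
                hits[j] += 1
    with np.errstate(invalid="ignore"):
        support = np.where(trials > 0, hits / np.maximum(trials, 1), np.nan)
    node_df = pd.DataFrame(
        {
            "node": range(len(node_sets)),
            "leaves": [tuple(sorted(z.index[i] for i in s)) for s in node_sets],
            "support": support,
            "n_resamples": trials.astype(int),
        }
    )
    return ClusteringResult(
        linkage=link,
        labels=pd.Series(labels, index=z.index, name="cluster"),
        mean_silhouette=sil,
        node_support=node_df,
    )


def spearman_screen(
    table: pd.DataFrame, bootstrap_reps: int = 500, rng_seed: int = 0
) -> pd.DataFrame:
    """Pairwise Spearman rho with percentile-bootstrap 95% CIs and BH q-values.

    Constant traits yield NaN rho/CI and are excluded from the BH family.
    Requires >= 4 complete observation pairs per tested pair.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for a, b in combinations(table.columns, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 4:
            raise ValueError(f"pair ({a}, {b}): need >= 4 complete pairs")
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append({"trait_a": a, "trait_b": b, "rho": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan})
            continue
        rho, p = sps.spearmanr(x, y)
        boots = np.empty(bootstrap_reps)
        for i in range(bootstrap_reps):
            idx = rng.integers(0, len(x), size=len(x))
            if np.std(x[idx]) == 0 or np.std(y[idx]) == 0:
                boots[i] = np.nan
            else:
                boots[i] = sps.spearmanr(x[idx], y[idx]).statistic
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        rows.append({"trait_a": a, "trait_b": b, "rho": float(rho), "ci_low": float(lo), "ci_high": float(hi), "p_value": float(p)})
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    q = np.full(len(out), np.nan)
    if tested.any():
        q[tested.to_numpy()] = multipletests(out.loc[tested, "p_value"], method="fdr_bh")[1]
    out["q_value"] = q
    return out


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = np.min(values), np.max(values)
    if hi == lo:
        return np.full_like(values, 0.5, dtype=float)  # neutral when constant
    return (values - lo) / (hi - lo)


def compute_isi(ph_summary: pd.DataFrame) -> pd.DataFrame:
    """Integrated Selection Index from a DAS-14 per-accession pH summary.

    ``ph_summary`` needs columns accession_id, ph_level, establishment
    (proportion in [0,1]) and total_mm; only pH 5.5 and 7.0 rows are used.
    Accessions missing either pH level are excluded with a warning. Ranks
    are dense (1 = best), ties broken lexicographically by accession id.
    """
    need = {"accession_id", "ph_level", "establishment", "total_mm"}
    if not need.issubset(ph_summary.columns):
        raise ValueError(f"ph_summary must have columns {sorted(need)}")
    sub = ph_summary[ph_summary["ph_level"].isin([5.5, 7.0])]
    wide_est = sub.pivot_table(index="accession_id", columns="ph_level", values="establishment")
    wide_len = sub.pivot_table(index="accession_id", columns="ph_level", values="total_mm")
    complete = wide_est.dropna().index.intersection(wide_len.dropna().index)
    dropped = sorted(set(wide_est.index) - set(complete))
    if dropped:
        warnings.warn(f"excluding accessions missing a pH level: {dropped}", stacklevel=2)
    if len(complete) == 0:
        raise ValueError("no accession has both pH 5.5 and 7.0 summaries")
    est = wide_est.loc[complete]
    length = wide_len.loc[complete]
    est_mean = est.mean(axis=1)
    length_mean = length.mean(axis=1)
    stability = 1.0 / ((est[7.0] - est[5.5]).abs() + 1.0)
    out = pd.DataFrame(
        {
            "accession_id": complete,
            "est_mean": est_mean.to_numpy(),
            "length_mean": length_mean.to_numpy(),
            "stability": stability.to_numpy(),
        }
    ).sort_values("accession_id", kind="stable")
    for comp in ("est", "length", "stability"):
        col = {"est": "est_mean", "length": "length_mean", "stability": "stability"}[comp]
        out[f"norm_{comp}"] = _minmax(out[col].to_numpy())
    out["isi"] = out[["norm_est", "norm_length", "norm_stability"]].mean(axis=1)
    order = out.sort_values(["isi", "accession_id"], ascending=[False, True], kind="stable")
    out["rank"] = pd.Series(range(1, len(out) + 1), index=order.index)
    return out.reset_index(drop=True)


def recommend_accessions(
    soil_matrix: pd.DataFrame,
    performance: Mapping[str, float] | pd.Series,
    soil_code: str,
    top_n: int = 5,
) -> pd.DataFrame:
    """Soil-matched recommendation list combining two rankings.

    Accessions in the top-``top_n`` of *both* the soil establishment ranking
    (the matrix column) and the pH-performance ranking (e.g. ISI) come
    first, ordered by soil rank and flagged ``overlap``; if fewer than
    ``top_n`` overlap, the list is completed with the next best accessions
    from the soil ranking, flagged ``fill``.
    """
    if soil_code not in soil_matrix.columns:
        raise ValueError(f"soil {soil_code!r} not in matrix columns {list(soil_matrix.columns)}")
    perf = pd.Series(performance, dtype=float).dropna()
    soil_rank = soil_matrix[soil_code].dropna()
    if soil_rank.empty or perf.empty:
        raise ValueError("empty performance table")
    soil_order = soil_rank.sort_values(ascending=False, kind="stable")
    soil_order = soil_order.loc[sorted(soil_order.index)].sort_values(ascending=False, kind="stable")
    perf_top = set(perf.sort_values(ascending=False, kind="stable").index[:top_n])
    soil_top = list(soil_order.index[:top_n])
    chosen: list[tuple[str, str]] = [(acc, "overlap") for acc in soil_top if acc in perf_top]
    for acc in soil_order.index:
        if len(chosen) >= top_n:
            break
        if acc not in {c[0] for c in chosen}:
            chosen.append((acc, "fill"))
    return pd.DataFrame(
        {
            "accession_id": [c[0] for c in chosen],
            "source": [c[1] for c in chosen],
            "soil_establishment_pct": [float(soil_rank[c[0]]) for c in chosen],
        }
    )
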