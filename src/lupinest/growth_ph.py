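"""Substrate-pH seedling growth analytics.

Traits per seedling: total length (hypocotyl + epicotyl, mm), the
stabilized hypocotyl-to-epicotyl ratio H/(E+1) (1 mm added so seedlings
with measured but non-elongated epicotyls stay finite), hypocotyl
allocation H/total, and binary establishment (total >= 30 mm, inclusive).
Seedlings lacking either organ measurement are retained but flagged
invalid and excluded from growth/allocation analyses.

Family-wise pairwise comparisons use a seeded permutation null of the
maximum |t| statistic rather than the studentized-range distribution; this
controls the family-wise error rate without the studentized-range CDF and
is a documented divergence from textbook Tukey HSD.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .io_soil import SeedlingGrowthRecord, records_to_frame

ESTABLISHMENT_MM = 30.0
LOGIT_EPS = 0.005


@dataclass(frozen=True)
class GrowthTraits:
    accession_id: str
    species: str
    ph_level: float
    das: int
    replicate: int
    hypocotyl_mm: float | None
    epicotyl_mm: float | None
    valid: bool
    total_mm: float | None = None
    ratio: float | None = None
    allocation: float | None = None
    established: bool | None = None


def derive_growth_traits(record: SeedlingGrowthRecord) -> GrowthTraits:
    """Trait derivation for one seedling; invalid (missing-organ) records
    keep their context but carry no traits."""
    h, e = record.hypocotyl_mm, record.epicotyl_mm
    base = dict(
        accession_id=record.accession_id,
        species=record.species,
        ph_level=record.ph_level,
        das=record.das,
        replicate=record.replicate,
        hypocotyl_mm=h,
        epicotyl_mm=e,
    )
    if h is None or e is None:
        return GrowthTraits(valid=False, **base)
    if h < 0 or e < 0:
        raise ValueError("organ lengths must be non-negative")
    total = h + e
    return GrowthTraits(
        valid=True,
        total_mm=total,
        ratio=h / (e + 1.0),
        allocation=(h / total) if total > 0 else 0.0,
        established=total >= ESTABLISHMENT_MM,
        **base,
    )


def traits_table(records: Iterable[SeedlingGrowthRecord]) -> pd.DataFrame:
    rows = [derive_growth_traits(r) for r in records]
    return records_to_frame(rows) if rows else pd.DataFrame()


def filter_valid(records: Iterable[SeedlingGrowthRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split into (valid-trait table, per-stratum exclusion counts).

    The exclusion table reports, per pH x DAS stratum, how many seedlings
    lacked either organ measurement.
    """
    df = traits_table(list(records))
    if df.empty:
        return df, pd.DataFrame(columns=["ph_level", "das", "n_excluded"])
    excl = (
        df[~df["valid"]]
        .groupby(["ph_level", "das"], sort=True)
        .size()
        .rename("n_excluded")
        .reset_index()
    )
    return df[df["valid"]].reset_index(drop=True), excl


SOURCE_LABELS = {"C(ph_level)": "pH", "C(das)": "DAS", "C(ph_level):C(das)": "pH x DAS", "Residual": "residual"}


def anova_two_way(traits: pd.DataFrame, response: str) -> pd.DataFrame:
    """Two-factor (pH, DAS) ANOVA with interaction, type-II sums of squares.

    Balanced designs make type I/II/III coincide; empty design cells raise
    naming the cell. Returns a table with sources pH, DAS, pH x DAS,
    residual and columns sum_sq, df, F, p_value.
    """
    df = traits.dropna(subset=[response])
    for factor in ("ph_level", "das"):
        if df[factor].nunique() < 2:
            raise ValueError(f"factor {factor} needs >= 2 levels")
    counts = df.groupby(["ph_level", "das"]).size()
    full = pd.MultiIndex.from_product([sorted(df["ph_level"].unique()), sorted(df["das"].unique())])
    empty = [c for c in full if c not in counts.index]
    if empty:
        raise ValueError(f"empty design cell(s): {empty}")
    model = smf.ols(f"{response} ~ C(ph_level) * C(das)", data=df).fit()
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    table = anova_lm(model, typ=2)
    out = table.rename(index=SOURCE_LABELS).reset_index().rename(
        columns={"index": "source", "sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p_value"}
    )
    return out[["source", "sum_sq", "df", "F", "p_value"]]


def _group_arrays(df: pd.DataFrame, response: str, factor: str | Sequence[str]) -> dict:
    factors = [factor] if isinstance(factor, str) else list(factor)
    groups = {}
    for keys, grp in df.dropna(subset=[response]).groupby(factors, sort=True):
        label = keys if isinstance(keys, tuple) else (keys,)
        groups["/".join(str(k) for k in label)] = grp[response].to_numpy(float)
    return groups


def _pairwise_t(groups: dict) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    """Pairwise t statistics with pooled within-group variance over all groups."""
    labels = sorted(groups)
    ns = np.array([len(groups[g]) for g in labels])
    means = np.array([groups[g].mean() for g in labels])
    ss_within = sum(((groups[g] - groups[g].mean()) ** 2).sum() for g in labels)
    df_within = int(ns.sum() - len(labels))
    s2 = ss_within / df_within if df_within > 0 else 0.0
    pairs, diffs, ts = [], [], []
    for i, j in combinations(range(len(labels)), 2):
        d = means[i] - means[j]
        se = np.sqrt(s2 * (1 / ns[i] + 1 / ns[j]))
        pairs.append((labels[i], labels[j]))
        diffs.append(d)
        ts.append(d / se if se > 0 else 0.0)
    return pairs, np.array(diffs), np.array(ts)


def pairwise_contrasts(
    traits: pd.DataFrame,
    response: str,
    factor: str | Sequence[str],
    n_perm: int = 999,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """All pairwise mean comparisons with max-|t| permutation adjustment.

    The family-wise adjusted p for a pair is the fraction of label
    permutations whose maximum |t| over all pairs reaches that pair's
    observed |t| (add-one permutation p). With exactly two groups this
    reduces to the plain permutation p.
    """
    groups = _group_arrays(traits, response, factor)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, arr in groups.items():
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has < 2 observations")
    pairs, diffs, ts = _pairwise_t(groups)
    labels = sorted(groups)
    sizes = [len(groups[g]) for g in labels]
    pooled = np.concatenate([groups[g] for g in labels])
    rng = np.random.default_rng(rng_seed)
    bounds = np.cumsum([0] + sizes)
    max_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(pooled)
        perm_groups = {labels[i]: perm[bounds[i]: bounds[i + 1]] for i in range(len(labels))}
        _, _, t_null = _pairwise_t(perm_groups)
        max_null[b] = np.max(np.abs(t_null))
    adj_p = np.array([(1 + np.sum(max_null >= abs(t))) / (n_perm + 1) for t in ts])
    return pd.DataFrame(
        {
            "group_a": [p[0] for p in pairs],
            "group_b": [p[1] for p in pairs],
            "mean_diff": diffs,
            "t": ts,
            "p_adj": adj_p,
        }
    )


def polynomial_ph_response(traits: pd.DataFrame, response: str, degree: int = 2) -> dict:
    """Least-squares polynomial in centered pH; returns coefficients and R^2.

    With three design pH levels a quadratic is saturated on the level means;
    the result carries ``saturated=True`` in that case (an interpolating,
    not a predictive, fit).
    """
    df = traits.dropna(subset=[response])
    x = df["ph_level"].to_numpy(float)
    y = df[response].to_numpy(float)
    levels = np.unique(x)
    if degree + 1 > len(levels):
        raise ValueError(f"degree {degree} needs > {degree} distinct pH levels, have {len(levels)}")
    xc = x - x.mean()
    design = np.vander(xc, degree + 1, increasing=True)
    coefs, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coefs
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return {
        "coefficients": coefs,  # increasing powers of centered pH
        "center": float(x.mean()),
        "r_squared": 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0,
        "saturated": degree + 1 == len(levels),
    }


def ph_summary(traits: pd.DataFrame, das: int = 14) -> pd.DataFrame:
    """Per-accession x pH summary at one time point: establishment proportion
    (total >= 30 mm among valid seedlings) and mean total length. This is the
    input the Integrated Selection Index consumes."""
    df = traits[traits["valid"] & (traits["das"] == das)]
    if df.empty:
        raise ValueError(f"no valid seedlings at DAS {das}")
    grp = df.groupby(["accession_id", "ph_level"], sort=True)
    out = grp.agg(establishment=("established", "mean"), total_mm=("total_mm", "mean"))
    return out.reset_index()


def logit_allocation_regression(
    traits: pd.DataFrame, predictors: str = "C(ph_level) * C(das)"
) -> pd.DataFrame:
    """OLS on logit-transformed hypocotyl allocation.

    Allocation is clamped to [0.005, 0.995] before the logit (boundary
    seedlings with allocation exactly 0 or 1 stay in the fit). Emits a
    degenerate-response warning column note when every value sits at one
    clamped bound.
    """
    df = traits.dropna(subset=["allocation"]).copy()
    if df.empty:
        raise ValueError("no valid allocation values")
    clamped = df["allocation"].clip(LOGIT_EPS, 1 - LOGIT_EPS)
    df["allocation_logit"] = np.log(clamped / (1 - clamped))
    if clamped.nunique() == 1 and clamped.iloc[0] in (LOGIT_EPS, 1 - LOGIT_EPS):
        import warnings

        warnings.warn("degenerate response: all allocations at a clamped bound", stacklevel=2)
    model = smf.ols(f"allocation_logit ~ {predictors}", data=df).fit()
    return pd.DataFrame(
        {
            "term": model.params.index,
            "coef": model.params.to_numpy(),
            "se": model.bse.to_numpy(),
            "ci_low": model.conf_int()[0].to_numpy(),
            "ci_high": model.conf_int()[1].to_numpy(),
            "p_value": model.pvalues.to_numpy(),
        }
    )
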