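"""Multi-soil ordinal establishment analytics.

The 0-5 score collapses to three nested binary outcomes: germination
(score >= 1), cotyledon emergence (score >= 3), and successful
establishment (score = 5). Score 4 (arrested growth or fungal damage)
counts toward germination and cotyledon emergence but never establishment.

The accession-level random intercept of a full GLMM is not estimated here;
species/soil/treatment effects are fitted as fixed-effects logistic
regression (IRLS via statsmodels GLM) with per-accession aggregation used
for accession-level summaries. Outputs carry that approximation note.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .io_soil import OrdinalOutcomeRecord, records_to_frame

OUTCOME_THRESHOLDS = {"germinated": 1, "cotyledon": 3, "established": 5}

MODEL_NOTE = (
    "fixed-effects logistic approximation: accession-level random intercepts "
    "are not estimated; accession summaries use direct per-accession aggregation"
)


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: MLE diverges."""


def derive_outcomes(score: int) -> tuple[bool, bool, bool]:
    """(germinated, cotyledon, established) flags from a 0-5 score."""
    if score not in range(6):
        raise ValueError(f"score must be in 0..5, got {score}")
    return (score >= 1, score >= 3, score == 5)


def outcomes_frame(records: Iterable[OrdinalOutcomeRecord]) -> pd.DataFrame:
    df = records_to_frame(list(records))
    for name, thr in OUTCOME_THRESHOLDS.items():
        df[name] = (df["score"] >= thr) if thr < 5 else (df["score"] == 5)
    return df


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def aggregate_rates(records: Iterable[OrdinalOutcomeRecord], group_by: Sequence[str]) -> pd.DataFrame:
    """Per-group outcome proportions with Wilson 95% intervals.

    One row per group; for each of the three nested outcomes the event
    count / n rate plus ci_low/ci_high columns. Groups emptied by filtering
    upstream simply do not appear.
    """
    df = outcomes_frame(records)
    if df.empty:
        raise ValueError("no records to aggregate")
    rows = []
    grouped = df.groupby(list(group_by), sort=True) if group_by else [((), df)]
    for keys, grp in grouped:
        if not isinstance(keys, tuple):
            keys = (keys,)
        row = dict(zip(group_by, keys))
        row["n"] = len(grp)
        for name in OUTCOME_THRESHOLDS:
            k = int(grp[name].sum())
            row[f"{name}_rate"] = k / len(grp)
            lo, hi = wilson_interval(k, len(grp))
            row[f"{name}_ci_low"] = lo
            row[f"{name}_ci_high"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def establishment_matrix(records: Iterable[OrdinalOutcomeRecord]) -> pd.DataFrame:
    """Accession x soil matrix of percent established, averaged over the two
    scarification treatments (NS and S weighted equally). Missing cells are
    NaN, never zero-filled."""
    df = outcomes_frame(records)
    per_trt = (
        df.groupby(["accession_id", "soil_code", "treatment"])["established"].mean().reset_index()
    )
    cell = per_trt.groupby(["accession_id", "soil_code"])["established"].mean() * 100.0
    return cell.unstack("soil_code")


def fit_logistic(
    records: Iterable[OrdinalOutcomeRecord],
    outcome: str = "established",
    design: str = "species * soil_code + treatment",
) -> pd.DataFrame:
    """Fixed-effects logistic fit (IRLS ML); returns a coefficient table.

    Columns: coef (log-odds), se, odds_ratio, or_ci_low/high (Wald 95%),
    p_value. Raises :class:`SeparationError` on (quasi-)complete separation
    and ValueError naming aliased terms on rank deficiency.
    """
    if outcome not in OUTCOME_THRESHOLDS:
        raise ValueError(f"outcome must be one of {sorted(OUTCOME_THRESHOLDS)}")
    df = outcomes_frame(records)
    y = df[outcome].astype(int)
    if y.nunique() < 2:
        raise SeparationError(f"outcome {outcome!r} is constant; model degenerate")
    formula = f"{outcome}_int ~ {design}"
    df[f"{outcome}_int"] = y
    model = smf.glm(formula, data=df, family=sm.families.Binomial())
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        _, r = np.linalg.qr(exog)
        aliased = [model.exog_names[i] for i in range(exog.shape[1]) if abs(r[i, i]) < 1e-8]
        raise ValueError(f"design matrix rank deficient; aliased terms: {aliased}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    if not res.converged or np.max(np.abs(res.params)) > 15:
        raise SeparationError("logistic fit diverged: likely complete separation in the design")
    out = pd.DataFrame(
        {
            "term": res.params.index,
            "coef": res.params.to_numpy(),
            "se": res.bse.to_numpy(),
            "odds_ratio": np.exp(res.params.to_numpy()),
            "or_ci_low": np.exp(res.params.to_numpy() - 1.96 * res.bse.to_numpy()),
            "or_ci_high": np.exp(res.params.to_numpy() + 1.96 * res.bse.to_numpy()),
            "p_value": res.pvalues.to_numpy(),
        }
    )
    out.attrs["model_note"] = MODEL_NOTE
    return out


def correlate_dormancy_establishment(
    dds50: Mapping[str, tuple[float, bool]] | pd.DataFrame,
    establishment: pd.DataFrame,
) -> pd.DataFrame:
    """Per-soil Pearson correlation between dormancy (DDS50) and establishment.

    ``dds50`` maps accession -> (days, censored); censored accessions are
    excluded (and counted in ``n_censored_excluded``), never imputed.
    ``establishment`` is the accession x soil percent matrix. Soils with a
    zero-variance side get NaN r with reason 'zero variance'. Requires >= 4
    complete accessions per soil.
    """
    if isinstance(dds50, pd.DataFrame):
        dds50 = {r.accession_id: (r.dds50, bool(r.dds50_censored)) for r in dds50.itertuples()}
    usable = {a: v for a, (v, cens) in dds50.items() if not cens}
    n_censored = len(dds50) - len(usable)
    rows = []
    for soil in establishment.columns:
        col = establishment[soil].dropna()
        common = sorted(set(col.index) & set(usable))
        x = np.array([usable[a] for a in common], float)
        y = col.loc[common].to_numpy(float)
        row = {"soil_code": soil, "n": len(common), "n_censored_excluded": n_censored}
        if len(common) < 4:
            raise ValueError(f"soil {soil}: need >= 4 accessions with both values, have {len(common)}")
        if np.std(x) == 0 or np.std(y) == 0:
            row.update({"r": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan, "note": "zero variance"})
        else:
            r, p = sps.pearsonr(x, y)
            lo, hi = _fisher_z_ci(r, len(common))
            row.update({"r": float(r), "ci_low": lo, "ci_high": hi, "p_value": float(p), "note": ""})
        rows.append(row)
    return pd.DataFrame(rows)


def _fisher_z_ci(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    if n <= 3 or abs(r) >= 1:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    crit = sps.norm.ppf(1 - alpha / 2)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))
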