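"""Germination indices, physical-dormancy estimation, and survival analysis.

All indices are computed per accession x treatment trial from the weekly
census curve. Event time is the census day on which a germination is first
observed (no midpoint correction). Percentages use viable seeds as the
denominator throughout, so physical dormancy PD = 100 - FGP_NS is the
fraction of *viable* non-scarified seeds that failed to germinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .io_soil import GerminationTrial

DORMANCY_CLASSES = ("low", "intermediate", "high")
HORIZON_DAYS = 365


class Dds50(NamedTuple):
    """Days to 50% cumulative germination; censored at the horizon when the
    curve never crosses 50% of viable seeds."""

    value: float
    censored: bool


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate of remaining-ungerminated probability."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    at_risk: tuple[int, ...]
    n_events: tuple[int, ...]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float


class UndefinedMetricError(ValueError):
    pass


def compute_fgp(trial: GerminationTrial) -> float:
    """Final germination percentage relative to viable seeds."""
    if trial.n_viable == 0:
        raise UndefinedMetricError(f"{trial.accession_id}/{trial.treatment}: no viable seeds, FGP undefined")
    return 100.0 * trial.cumulative_germinated[-1] / trial.n_viable


def compute_pd(ns_trial: GerminationTrial) -> float:
    """Physical dormancy: 100 - FGP of the non-scarified trial."""
    if ns_trial.treatment != "NS":
        raise ValueError("physical dormancy is defined from the non-scarified (NS) trial only")
    return 100.0 - compute_fgp(ns_trial)


def event_days(trial: GerminationTrial) -> list[int]:
    """Observed germination days, one entry per germinated seed."""
    out: list[int] = []
    for day, new in zip(trial.census_days, trial.newly_germinated):
        out.extend([day] * new)
    return out


def censored_days(trial: GerminationTrial) -> list[int]:
    """Censoring day (last census) for each seed still ungerminated."""
    n_cens = trial.n_viable - trial.cumulative_germinated[-1]
    return [trial.census_days[-1]] * n_cens


def compute_mgt(trial: GerminationTrial) -> float | None:
    """Mean germination time (days) over germinated seeds; None if none germinated."""
    days = event_days(trial)
    if not days:
        return None
    return float(np.mean(days))


def compute_ivg(trial: GerminationTrial) -> float:
    """Maguire germination velocity index: sum of newly germinated counts
    divided by their census day. Higher = faster, more synchronous."""
    return float(sum(new / day for day, new in zip(trial.census_days, trial.newly_germinated)))


def compute_dds50(trial: GerminationTrial) -> Dds50:
    """Days to 50% cumulative germination of viable seeds.

    The crossing day is linearly interpolated between the bracketing
    censuses (from day 0, count 0 if the first census already exceeds 50%).
    Trials whose final cumulative fraction stays below 50% are returned as
    right-censored at the 365-day horizon.
    """
    target = 0.5 * trial.n_viable
    prev_day, prev_cum = 0, 0
    for day, cum in zip(trial.census_days, trial.cumulative_germinated):
        if cum >= target:
            if cum == prev_cum:  # flat segment cannot cross
                return Dds50(float(day), False)
            frac = (target - prev_cum) / (cum - prev_cum)
            return Dds50(prev_day + (day - prev_day) * frac, False)
        prev_day, prev_cum = day, cum
    return Dds50(float(HORIZON_DAYS), True)


def metrics_table(trials: Iterable[GerminationTrial]) -> pd.DataFrame:
    """Per-trial germination metrics; PD is reported on NS rows only."""
    rows = []
    for t in trials:
        dds = compute_dds50(t)
        rows.append(
            {
                "accession_id": t.accession_id,
                "treatment": t.treatment,
                "n_viable": t.n_viable,
                "fgp": compute_fgp(t),
                "mgt": compute_mgt(t),
                "ivg": compute_ivg(t),
                "dds50": dds.value,
                "dds50_censored": dds.censored,
                "pd": compute_pd(t) if t.treatment == "NS" else np.nan,
            }
        )
    return pd.DataFrame(rows)


def km_estimate(event_days: Sequence[float], censored_days: Sequence[float] = ()) -> SurvivalCurve:
    """Kaplan-Meier estimate of the probability of remaining ungerminated.

    ``at_risk`` and ``n_events`` are reported per distinct event time
    (censored-only times do not appear as curve points).
    """
    if len(event_days) + len(censored_days) == 0:
        raise ValueError("km_estimate requires at least one subject")
    if any(d < 1 for d in list(event_days) + list(censored_days)):
        raise ValueError("all days must be >= 1")
    durations = np.concatenate([np.asarray(event_days, float), np.asarray(censored_days, float)])
    observed = np.concatenate([np.ones(len(event_days)), np.zeros(len(censored_days))])
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    times = ev.index.to_numpy(float)
    surv = kmf.survival_function_at_times(times).to_numpy(float)
    return SurvivalCurve(
        times=tuple(times),
        survival=tuple(surv),
        at_risk=tuple(int(x) for x in ev["at_risk"]),
        n_events=tuple(int(x) for x in ev["observed"]),
    )


def logrank_test(groups: Mapping[str, tuple[Sequence[float], Sequence[float]]]) -> TestResult:
    """Log-rank chi-square test across >= 2 labelled (events, censored) groups."""
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    durations, observed, labels = [], [], []
    for label, (events, censored) in groups.items():
        if len(events) + len(censored) == 0:
            raise ValueError(f"group {label!r} has no subjects")
        durations.extend(list(events) + list(censored))
        observed.extend([1] * len(events) + [0] * len(censored))
        labels.extend([label] * (len(events) + len(censored)))
    res = multivariate_logrank_test(np.asarray(durations, float), np.asarray(labels), np.asarray(observed))
    return TestResult(statistic=float(res.test_statistic), df=len(groups) - 1, p_value=float(res.p_value))


def trial_groups_for_logrank(trials: Iterable[GerminationTrial], by: str = "treatment") -> dict[str, tuple[list[int], list[int]]]:
    """Pool trials into labelled event/censor collections for the log-rank test."""
    groups: dict[str, tuple[list[int], list[int]]] = {}
    for t in trials:
        label = getattr(t, by) if by != "treatment" else t.treatment
        ev, cens = groups.setdefault(str(label), ([], []))
        ev.extend(event_days(t))
        cens.extend(censored_days(t))
    return groups


def dormancy_scores(metrics_ns: pd.DataFrame) -> pd.Series:
    """Continuous dormancy score from NS metrics (higher = more dormant).

    The four indices are oriented so larger means more dormant (MGT and
    DDS50 as-is; FGP and IVG sign-flipped), z-scored (population SD), and
    projected on the first principal axis. Censored DDS50 and undefined MGT
    enter at the 365-day horizon. The axis sign is fixed so the score
    correlates positively with the oriented-index mean.
    """
    df = metrics_ns.set_index("accession_id")
    mgt = df["mgt"].astype(float).fillna(float(HORIZON_DAYS))
    mat = np.column_stack(
        [
            mgt.to_numpy(),
            df["dds50"].astype(float).to_numpy(),
            -df["fgp"].astype(float).to_numpy(),
            -df["ivg"].astype(float).to_numpy(),
        ]
    )
    sd = mat.std(axis=0)
    mean = mat.mean(axis=0)
    keep = sd > 0
    if not keep.any():
        return pd.Series(np.zeros(len(df)), index=df.index, name="dormancy_score")
    z = (mat[:, keep] - mean[keep]) / sd[keep]
    # first principal axis of the z-scored matrix
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    score = z @ vt[0]
    composite = z.mean(axis=1)
    if np.dot(score, composite) < 0:
        score = -score
    return pd.Series(score, index=df.index, name="dormancy_score")


def classify_dormancy(metrics_ns: pd.DataFrame) -> pd.Series:
    """Tertile classification of accessions into low/intermediate/high dormancy.

    Requires >= 3 accessions with NS metrics. Identical metrics across all
    accessions degenerate to everyone classified ``low`` (documented tie
    rule: no evidence of dormancy differences).
    """
    ns = metrics_ns[metrics_ns["treatment"] == "NS"] if "treatment" in metrics_ns else metrics_ns
    if ns["accession_id"].nunique() < 3:
        raise ValueError("dormancy classification needs at least 3 accessions")
    score = dormancy_scores(ns)
    if np.allclose(score.to_numpy(), score.iloc[0]):
        return pd.Series(["low"] * len(score), index=score.index, name="dormancy_class")
    q1, q2 = np.quantile(score.to_numpy(), [1 / 3, 2 / 3])
    labels = np.where(score <= q1, "low", np.where(score <= q2, "intermediate", "high"))
    return pd.Series(labels, index=score.index, name="dormancy_class")
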