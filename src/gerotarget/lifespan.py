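"""Organismal lifespan-assay analysis: Kaplan-Meier curves, logrank test,
medians, and percent median change.

A survival dataset is a plain records table (one row per animal) with
columns ``animal_id, arm, repeat_id, day, event`` where ``arm`` is
``control`` or ``treatment`` and ``event`` is 1 for an observed death and 0
for censoring.  Biological repeats are pooled into a single analysis (the
repeat label is preserved; a repeat-stratified logrank is available as an
option).  The median convention is the step-function one: the smallest
observed day at which the survival estimate drops to 0.5 or below.

Kaplan-Meier fitting and the logrank test are delegated to ``lifelines``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "SURVIVAL_COLUMNS",
    "SurvivalSummary",
    "LogrankResult",
    "pool_repeats",
    "km_curve",
    "logrank_test",
    "median_change_percent",
    "summarize_assay",
    "read_lifespan_tsv",
    "write_lifespan_tsv",
]

SURVIVAL_COLUMNS = ("animal_id", "arm", "repeat_id", "day", "event")


class LifespanError(ValueError):
    pass


@dataclass
class SurvivalSummary:
    arm: str
    km_curve: pd.DataFrame  # columns day, survival
    median_day: float | None
    n: int


@dataclass
class LogrankResult:
    chi2: float
    df: int
    p_value: float


def _check(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(SURVIVAL_COLUMNS) - set(records.columns)
    if missing:
        raise LifespanError(f"records missing columns {sorted(missing)}")
    if (records["day"] <= 0).any():
        raise LifespanError("death/censor days must be positive")
    return records


def pool_repeats(datasets: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate biological repeats into one records table.

    Animal ids clashing across repeats are re-keyed with a repeat prefix.
    """
    frames = [_check(d).copy() for d in datasets]
    pooled = pd.concat(frames, ignore_index=True)
    if pooled.duplicated(subset=["animal_id"]).any():
        pooled["animal_id"] = (
            pooled["repeat_id"].astype(str) + ":" + pooled["animal_id"].astype(str)
        )
    return pooled


def km_curve(records: pd.DataFrame, arm: str) -> SurvivalSummary:
    """Product-limit survival curve and step-function median for one arm."""
    sub = _check(records)[lambda d: d["arm"] == arm]
    if len(sub) == 0:
        raise LifespanError(f"arm {arm!r} is empty")
    if (sub["event"] == 1).sum() == 0:
        raise LifespanError(f"arm {arm!r} has no observed deaths")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["day"], event_observed=sub["event"])
    sf = kmf.survival_function_
    curve = pd.DataFrame(
        {"day": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )
    curve = curve[curve["day"] > 0].reset_index(drop=True)
    below = curve[curve["survival"] <= 0.5]
    median = float(below["day"].iloc[0]) if len(below) else None
    return SurvivalSummary(arm=arm, km_curve=curve, median_day=median, n=len(sub))


def logrank_test(records: pd.DataFrame, stratify_repeats: bool = False) -> LogrankResult:
    """Two-sample logrank test between the control and treatment arms."""
    records = _check(records)
    arms = set(records["arm"])
    if len(arms) != 2:
        raise LifespanError(f"need exactly two arms, got {sorted(arms)}")
    for arm in arms:
        sub = records[records["arm"] == arm]
        if len(sub) == 0 or (sub["event"] == 1).sum() == 0:
            raise LifespanError(f"arm {arm!r} is empty or has no deaths")
    strata = records["repeat_id"] if stratify_repeats else None
    res = multivariate_logrank_test(
        records["day"], records["arm"], records["event"], strata=strata
    )
    return LogrankResult(
        chi2=float(res.test_statistic), df=1, p_value=float(res.p_value)
    )


def median_change_percent(treated_median: float, control_median: float) -> float:
    """Percent change of the treated median over control, one decimal."""
    if control_median <= 0:
        raise LifespanError("control median must be positive")
    return round(100.0 * (treated_median - control_median) / control_median, 1)


def summarize_assay(
    records: pd.DataFrame,
    *,
    n_bootstrap: int = 0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Medians per arm, percent median change, and the logrank test.

    With ``n_bootstrap > 0`` adds 95% bootstrap percentile intervals for the
    per-arm medians (resampling animals within arm).
    """
    control = km_curve(records, "control")
    treated = km_curve(records, "treatment")
    if control.median_day is None or treated.median_day is None:
        raise LifespanError("median undefined in one arm (survival never reaches 0.5)")
    lr = logrank_test(records)
    out = {
        "control_median": control.median_day,
        "treatment_median": treated.median_day,
        "median_change_percent": median_change_percent(
            treated.median_day, control.median_day
        ),
        "logrank_chi2": lr.chi2,
        "logrank_p": lr.p_value,
        "n_control": control.n,
        "n_treatment": treated.n,
    }
    if n_bootstrap > 0:
        rng = rng or np.random.default_rng()
        for arm in ("control", "treatment"):
            sub = records[records["arm"] == arm].reset_index(drop=True)
            meds = []
            for _ in range(n_bootstrap):
                idx = rng.integers(0, len(sub), len(sub))
                boot = sub.iloc[idx]
                if (boot["event"] == 1).sum() == 0:
                    continue
                meds.append(km_curve(boot.assign(arm=arm), arm).median_day)
            meds = [m for m in meds if m is not None]
            lo, hi = np.percentile(meds, [2.5, 97.5]) if meds else (np.nan, np.nan)
            out[f"{arm}_median_ci95"] = (float(lo), float(hi))
    return out


def write_lifespan_tsv(records: pd.DataFrame, path) -> None:
    _check(records)[list(SURVIVAL_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_lifespan_tsv(path) -> pd.DataFrame:
    return _check(pd.read_csv(path, sep="\t"))
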