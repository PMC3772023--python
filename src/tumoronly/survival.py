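"""Kaplan-Meier estimation and log-rank screening of mutation carriers.

Survival tables are pandas DataFrames with columns ``patient_id``,
``time`` (non-negative) and ``event`` (1 = death observed, 0 =
censored), one row per patient.  The screen compares carriers of SNVs
in each sufficiently mutated gene against non-carriers with the
standard one-degree-of-freedom log-rank test (two-sided p from the
chi-square upper tail, simultaneous events handled in a single
risk-set update).
"""

from __future__ import annotations

import dataclasses
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import CohortCallMatrix

__all__ = [
    "validate_survival_table",
    "km_curve",
    "km_median",
    "LogRankResult",
    "logrank_test",
    "mutation_survival_screen",
]


def validate_survival_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = {"patient_id", "time", "event"} - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("survival table is empty")
    t = df["time"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)) or np.any(t < 0):
        raise ValueError("times must be finite and non-negative")
    e = df["event"].to_numpy()
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")
    if df["patient_id"].duplicated().any():
        raise ValueError("one record per patient required")
    return df


def km_curve(table: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct observed time with the at-risk count,
    event and censoring counts, and the survival probability just after
    that time.  Survival starts at 1 and is non-increasing; censored
    times reduce the risk set without a step.
    """
    validate_survival_table(table)
    t = table["time"].to_numpy(dtype=float)
    e = table["event"].to_numpy(dtype=int)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    times = np.unique(t)
    n = len(t)
    rows = []
    s = 1.0
    for tt in times:
        at_risk = int((t >= tt).sum())
        d = int(e[t == tt].sum())
        c = int((t == tt).sum()) - d
        if d > 0:
            s *= 1.0 - d / at_risk
        rows.append((tt, at_risk, d, c, s))
    return pd.DataFrame(
        rows, columns=["time", "n_at_risk", "n_events", "n_censored", "survival"]
    )


def km_median(table: pd.DataFrame) -> float:
    """Median survival: earliest time at which S(t) <= 0.5 (NaN if never reached)."""
    curve = km_curve(table)
    hit = curve[curve["survival"] <= 0.5]
    return float(hit["time"].iloc[0]) if len(hit) else float("nan")


@dataclasses.dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def _logrank_arrays(time: np.ndarray, event: np.ndarray, in_a: np.ndarray) -> LogRankResult:
    """One-df log-rank over pooled risk sets (ties in a single update)."""
    etimes = np.unique(time[event == 1])
    if len(etimes) == 0:
        oa = ob = 0.0
        return LogRankResult(0.0, 1.0, (oa, ob), (0.0, 0.0))
    ta = np.sort(time[in_a])
    tb = np.sort(time[~in_a])
    na = len(ta) - np.searchsorted(ta, etimes, side="left")
    nb = len(tb) - np.searchsorted(tb, etimes, side="left")
    nn = na + nb

    def events_at(mask):
        tt = time[mask & (event == 1)]
        idx = np.searchsorted(etimes, tt)
        return np.bincount(idx, minlength=len(etimes))

    da = events_at(in_a)
    db = events_at(~in_a)
    d = da + db
    ea = d * na / nn
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(
            nn > 1,
            d * (na / nn) * (nb / nn) * (nn - d) / np.maximum(nn - 1, 1),
            0.0,
        )
    oa, eaS, vS = float(da.sum()), float(ea.sum()), float(v.sum())
    ob, ebS = float(db.sum()), float(d.sum() - ea.sum())
    if vS <= 0:
        return LogRankResult(0.0, 1.0, (oa, ob), (eaS, ebS))
    chi2 = (oa - eaS) ** 2 / vS
    p = float(stats.chi2.sf(chi2, 1))
    return LogRankResult(float(chi2), p, (oa, ob), (eaS, ebS))


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> LogRankResult:
    """Log-rank comparison of two survival tables.

    With no events in either group the convention (statistic 0, p = 1)
    is returned.  The statistic is invariant to swapping the groups.
    """
    validate_survival_table(group_a)
    validate_survival_table(group_b)
    time = np.concatenate([group_a["time"].to_numpy(float), group_b["time"].to_numpy(float)])
    event = np.concatenate([group_a["event"].to_numpy(int), group_b["event"].to_numpy(int)])
    in_a = np.zeros(len(time), dtype=bool)
    in_a[: len(group_a)] = True
    return _logrank_arrays(time, event, in_a)


def mutation_survival_screen(
    cohort: CohortCallMatrix,
    survival: pd.DataFrame,
    min_carriers: int = 3,
) -> pd.DataFrame:
    """Log-rank screen of every gene with enough mutation carriers.

    For each gene mutated in at least ``min_carriers`` patients (and at
    least one non-carrier), carriers are compared against non-carriers;
    the direction column reports "worse" when carriers die faster than
    expected (O > E) and "better" otherwise.  Returns a table sorted by
    p-value: gene, n_carriers, chi_square, p_value, direction,
    median_carrier, median_other.
    """
    validate_survival_table(survival)
    surv = survival.set_index("patient_id")
    missing = [p for p in cohort.patients if p not in surv.index]
    if missing:
        raise ValueError(f"survival table does not cover patients: {missing[:5]}")
    surv = surv.loc[cohort.patients]
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    pat_index = {p: i for i, p in enumerate(cohort.patients)}
    carriers_by_gene = (
        cohort.records.groupby("gene", observed=True)["patient"].agg(set).to_dict()
    )
    rows = []
    for gene in sorted(carriers_by_gene):
        carriers = carriers_by_gene[gene]
        nc = len(carriers)
        if nc < min_carriers or nc >= len(cohort.patients):
            continue
        mask = np.zeros(len(cohort.patients), dtype=bool)
        mask[[pat_index[p] for p in carriers]] = True
        res = _logrank_arrays(time, event, mask)
        direction = "worse" if res.observed[0] > res.expected[0] else "better"
        med_c = _median_of(time, event, mask)
        med_o = _median_of(time, event, ~mask)
        rows.append((gene, nc, res.statistic, res.p_value, direction, med_c, med_o))
    out = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "n_carriers",
            "chi_square",
            "p_value",
            "direction",
            "median_carrier",
            "median_other",
        ],
    )
    return out.sort_values(["p_value", "gene"], kind="stable").reset_index(drop=True)


def _median_of(time: np.ndarray, event: np.ndarray, mask: np.ndarray) -> float:
    df = pd.DataFrame(
        {"patient_id": np.arange(mask.sum()), "time": time[mask], "event": event[mask]}
    )
    return km_median(df) if len(df) else float("nan")
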