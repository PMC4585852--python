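"""Survival analysis: Kaplan-Meier, log-rank, RESTORE concordance scoring.

The concordance question: does each RESTORE gene associate with worse
outcome in the expression state that would trigger the translational
compensation seen in the cell-line panel?  Concretely, patients are
dichotomized at the cohort median of each gene; a RESTORE_DOWN gene is
concordant when the high-expression group has significantly worse
survival, a RESTORE_UP gene when the low-expression group does.

The product-limit estimator and the two-group log-rank test are
implemented here because the concordance call needs the signed
observed-minus-expected term (the direction of risk); the implementations
are cross-checked against lifelines in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def km_estimate(times: np.ndarray, events: np.ndarray) -> pd.DataFrame:
    """Product-limit survival estimate S(t) over distinct event times.

    Returns a frame (time, n_at_risk, n_events, survival); with no events
    S is identically 1.  Negative times are an error.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("at least one subject is required")
    if (times < 0).any():
        raise ValueError("negative survival time")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    rows = []
    s = 1.0
    n = len(times)
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events",
                                       "survival"])


@dataclass
class LogrankResult:
    statistic: float
    p: float
    observed_minus_expected_a: float  # > 0: group A has excess events (worse)
    n_events: int


def logrank_test(
    times_a: np.ndarray, events_a: np.ndarray,
    times_b: np.ndarray, events_b: np.ndarray,
) -> LogrankResult:
    """Two-group log-rank test (chi-square, 1 df).

    Sums observed minus expected events for group A over the distinct
    event times, with the hypergeometric variance term.  With no events at
    all the statistic is undefined (NaN, p NaN).
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if len(ta) == 0 or len(tb) == 0:
        raise ValueError("both groups must be non-empty")
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    group_a = np.concatenate([np.ones(len(ta), bool), np.zeros(len(tb), bool)])
    event_times = np.unique(all_t[all_e == 1])
    if len(event_times) == 0:
        warnings.warn("no events in either group; log-rank undefined")
        return LogrankResult(float("nan"), float("nan"), 0.0, 0)
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        at_risk = all_t >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & group_a).sum())
        d = int(((all_t == t) & (all_e == 1)).sum())
        d_a = int(((all_t == t) & (all_e == 1) & group_a).sum())
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var == 0:
        return LogrankResult(0.0, 1.0, o_minus_e, int(all_e.sum()))
    chi2 = o_minus_e ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return LogrankResult(float(chi2), p, float(o_minus_e), int(all_e.sum()))


def restore_prognosis_concordance(
    restore_calls: pd.DataFrame, cohort: pd.DataFrame, alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Score each RESTORE gene's prognostic concordance on a cohort.

    ``restore_calls`` carries a ``class`` column; only RESTORE_UP/_DOWN
    rows are scored.  ``cohort`` has columns time, event and one column
    per gene.  Each gene is dichotomized at the cohort median; the high
    group is worse when its observed events exceed expectation.  A gene is
    concordant when the risk direction matches its class (high worse for
    RESTORE_DOWN, low worse for RESTORE_UP) at p < alpha.  Genes with
    constant expression are skipped with a warning.

    Returns (per-gene table, summary) where summary carries the concordant
    counts per subclass and the global concordant fraction.
    """
    restore = restore_calls[restore_calls["class"].str.startswith("RESTORE")]
    t = cohort["time"].to_numpy(float)
    e = cohort["event"].to_numpy(int)
    rows = []
    for g, row in restore.iterrows():
        if g not in cohort.columns:
            warnings.warn(f"gene {g!r} absent from the cohort; skipped")
            continue
        expr = cohort[g].to_numpy(float)
        cutoff = float(np.median(expr))
        high = expr > cutoff
        if high.sum() == 0 or (~high).sum() == 0:
            warnings.warn(f"gene {g!r}: constant or one-sided expression; skipped")
            continue
        res = logrank_test(t[high], e[high], t[~high], e[~high])
        if np.isnan(res.p):
            continue
        risk = "high" if res.observed_minus_expected_a > 0 else "low"
        concordant = bool(
            res.p < alpha
            and ((row["class"] == "RESTORE_DOWN" and risk == "high")
                 or (row["class"] == "RESTORE_UP" and risk == "low"))
        )
        rows.append((g, row["class"], risk, res.p, concordant))
    table = pd.DataFrame(rows, columns=["gene_id", "class", "risk_group",
                                        "p", "concordant"]).set_index("gene_id")
    summary = {}
    for cls in ("RESTORE_DOWN", "RESTORE_UP"):
        sub = table[table["class"] == cls]
        summary[f"n_{cls.lower()}"] = int(len(sub))
        summary[f"n_{cls.lower()}_concordant"] = int(sub["concordant"].sum())
    n_total = len(table)
    summary["n_restore_scored"] = n_total
    summary["n_concordant"] = int(table["concordant"].sum())
    summary["concordant_fraction"] = (summary["n_concordant"] / n_total
                                      if n_total else float("nan"))
    return table, summary
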