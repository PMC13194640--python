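"""Survival statistics behind the gene-family outcome screen.

A cohort is (time, event, expression) per subject. Each gene is screened
by splitting the cohort into high and low expressors (median split by
default; an exploratory minimal-p cutoff scan is also available),
estimating the high-vs-low hazard ratio from a single-binary-covariate
proportional-hazards partial likelihood (Efron tie handling, Newton
iteration, observed-information CI), and testing the split with the
one-degree-of-freedom log-rank statistic. Genes are ranked by HR
descending, and the screen summary counts HR > 1 and HR > 1 with
raw p < 0.05 — no multiplicity adjustment drives the significance
count, though a BH-adjusted column is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .gsea import benjamini_hochberg


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimator.

    Returns one row per distinct event time with the number at risk,
    number of events, and the survival estimate just after that time.
    Survival starts at 1 and is non-increasing; with no events the
    frame is empty and S stays 1 throughout.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ConfigError("empty cohort")
    if (times <= 0).any():
        raise ConfigError("times must be positive")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = []
    s = 1.0
    n = len(times)
    i = 0
    while i < n:
        t = times[i]
        j = i
        d = 0
        while j < n and times[j] == t:
            d += events[j]
            j += 1
        at_risk = n - i
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append((t, at_risk, d, s))
        i = j
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def _risk_table(t1, e1, t0, e0):
    """Per distinct event time: d1, d, n1, n over the pooled cohort."""
    t1, e1 = np.asarray(t1, float), np.asarray(e1, int)
    t0, e0 = np.asarray(t0, float), np.asarray(e0, int)
    all_t = np.concatenate([t1, t0])
    all_e = np.concatenate([e1, e0])
    grp = np.concatenate([np.ones(len(t1), int), np.zeros(len(t0), int)])
    event_times = np.unique(all_t[all_e == 1])
    rows = []
    for t in event_times:
        at_risk = all_t >= t
        d_mask = (all_t == t) & (all_e == 1)
        rows.append((t, int((d_mask & (grp == 1)).sum()), int(d_mask.sum()),
                     int((at_risk & (grp == 1)).sum()), int(at_risk.sum())))
    return rows


def logrank_test(times_high, events_high, times_low, events_low):
    """Two-group log-rank test; returns (chi2, p).

    Observed-minus-expected events in the high group over pooled risk
    sets, hypergeometric variance, one degree of freedom. Invariant to
    which group is called high.
    """
    table = _risk_table(times_high, events_high, times_low, events_low)
    if not table:
        raise ConfigError("log-rank test needs at least one event")
    o_minus_e = 0.0
    var = 0.0
    for _, d1, d, n1, n in table:
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    log_hr: float
    se_log_hr: float
    converged: bool
    flag: str = ""  # "", "no_events_high", "no_events_low", "nonconverged"


def hazard_ratio(times_high, events_high, times_low, events_low,
                 max_iter: int = 50, tol: float = 1e-10) -> HazardRatioResult:
    """High-vs-low hazard ratio from a binary-covariate Cox fit.

    Partial likelihood with Efron handling of tied event times,
    maximized by Newton iteration on the scalar log HR; the 95% CI uses
    the observed information. A group with zero events has an infinite
    or zero HR and is flagged instead of iterated.
    """
    e_high = int(np.sum(events_high))
    e_low = int(np.sum(events_low))
    if e_high + e_low == 0:
        raise ConfigError("hazard ratio needs at least one event")
    if e_high == 0:
        return HazardRatioResult(0.0, 0.0, np.nan, -np.inf, np.inf, False, "no_events_high")
    if e_low == 0:
        return HazardRatioResult(np.inf, np.nan, np.inf, np.inf, np.inf, False, "no_events_low")

    table = _risk_table(times_high, events_high, times_low, events_low)
    beta = 0.0
    converged = False
    for _ in range(max_iter):
        score, info = _efron_score_info(table, beta)
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(step) < tol:
            converged = True
            break
        if abs(beta) > 50:  # monotone likelihood guard
            break
    score, info = _efron_score_info(table, beta)
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    hr = float(np.exp(beta))
    z = stats.norm.ppf(0.975)
    return HazardRatioResult(
        hr=hr,
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        log_hr=float(beta),
        se_log_hr=float(se),
        converged=converged,
        flag="" if converged else "nonconverged",
    )


def _efron_score_info(table, beta: float):
    """Score and observed information of the Efron partial likelihood."""
    eb = np.exp(beta)
    score = 0.0
    info = 0.0
    for _, d1, d, n1, n in table:
        n0 = n - n1
        d0 = d - d1
        R = n0 + n1 * eb       # sum of risks over the risk set
        Rp = n1 * eb           # d/dbeta
        E = d0 + d1 * eb       # sum of risks over tied events
        Ep = d1 * eb
        score += d1
        for l in range(d):
            f = l / d
            phi = R - f * E
            phip = Rp - f * Ep
            score -= phip / phi
            info += (phip * phi - phip ** 2) / phi ** 2
    return score, info


@dataclass
class Dichotomy:
    """A high/low split of a cohort by one gene's expression."""

    high: np.ndarray  # boolean per subject
    cutoff: float
    method: str
    scan: pd.DataFrame | None = None  # cutoff scan (exploratory), best_cutoff only


def dichotomize(values, method: str = "median", times=None, events=None,
                quantiles=None) -> Dichotomy:
    """Split expression values into high/low groups.

    ``median``: high iff value > median (ties go low). ``best_cutoff``:
    scan the 0.2-0.8 quantiles in steps of 0.05, pick the cutoff with
    minimal log-rank p; requires times and events and is exploratory by
    construction (the minimal p is optimistically biased).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        raise ConfigError("dichotomization needs at least 4 subjects")
    if np.ptp(values) == 0:
        raise ConfigError("all expression values equal; no split possible")
    if method == "median":
        cutoff = float(np.median(values))
        high = values > cutoff
        if not high.any() or high.all():
            raise ConfigError("median split produced an empty group")
        return Dichotomy(high, cutoff, "median")
    if method == "best_cutoff":
        if times is None or events is None:
            raise ConfigError("best_cutoff needs times and events")
        times = np.asarray(times, float)
        events = np.asarray(events, int)
        if quantiles is None:
            quantiles = np.arange(0.20, 0.80 + 1e-9, 0.05)
        rows = []
        for q in quantiles:
            cut = float(np.quantile(values, q))
            high = values > cut
            if not high.any() or high.all():
                continue
            _, p = logrank_test(times[high], events[high], times[~high], events[~high])
            rows.append((q, cut, p))
        if not rows:
            raise ConfigError("no quantile cutoff produces two nonempty groups")
        scan = pd.DataFrame(rows, columns=["quantile", "cutoff", "logrank_p"])
        best = scan.loc[scan["logrank_p"].idxmin()]
        high = values > best["cutoff"]
        return Dichotomy(high, float(best["cutoff"]), "best_cutoff", scan)
    raise ConfigError(f"unknown dichotomization method {method!r}")


def screen_genes(cohort: pd.DataFrame, genes, method: str = "median") -> pd.DataFrame:
    """Per-gene HR + log-rank p screen, ranked by HR descending.

    ``cohort`` needs time and event columns plus one expression column
    per screened gene. Emits raw log-rank p (which drives the HR > 1,
    p < 0.05 significance count) and a BH-adjusted column.
    """
    genes = list(genes)
    missing = [g for g in genes if g not in cohort.columns]
    if missing:
        raise ConfigError("cohort lacks expression for: " + ", ".join(missing))
    times = cohort["time"].to_numpy(float)
    events = cohort["event"].to_numpy(int)
    rows = []
    for gene in genes:
        split = dichotomize(cohort[gene].to_numpy(), method, times=times, events=events)
        h = split.high
        chi2, p = logrank_test(times[h], events[h], times[~h], events[~h])
        hr = hazard_ratio(times[h], events[h], times[~h], events[~h])
        rows.append((gene, hr.hr, hr.ci_low, hr.ci_high, p,
                     int(h.sum()), int((~h).sum()), split.cutoff, hr.flag))
    out = pd.DataFrame(rows, columns=["gene", "hr", "ci_low", "ci_high", "logrank_p",
                                      "n_high", "n_low", "cutoff", "flag"])
    if len(out):
        out["logrank_p_bh"] = benjamini_hochberg(out["logrank_p"].to_numpy())
        out = out.sort_values("hr", ascending=False, kind="stable").reset_index(drop=True)
    else:
        out["logrank_p_bh"] = pd.Series(dtype=float)
    return out


def summarize_screen(screen: pd.DataFrame, p_threshold: float = 0.05) -> dict:
    """Counts the screen reports: HR > 1, and HR > 1 with raw p below threshold."""
    hr_gt_1 = screen["hr"] > 1
    return {
        "n_genes": int(len(screen)),
        "n_hr_gt_1": int(hr_gt_1.sum()),
        "n_hr_gt_1_significant": int((hr_gt_1 & (screen["logrank_p"] < p_threshold)).sum()),
    }
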