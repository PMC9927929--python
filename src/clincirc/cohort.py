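"""Cohort-level statistics over per-series rhythm calls.

Operates on plain pandas DataFrames: a *call table* has one row per
(subject, analyte) with a boolean ``circadian`` column, optionally
``acrophase_h`` (hours, only meaningful where circadian) and a per-subject
``group`` label. Subjects are classified "standard" when at least K analytes
(default K = 3 of the 9 clock genes) carry a detected circadian oscillation,
"reduced" otherwise.

Circular quantities (acrophases, event clock times) live on a 24-h circle;
the helpers here provide the circular mean with IQR band, the two-sample
Watson U-squared test, and acrophase-on-event-time regression with branch
unwrapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SubjectSummary",
    "summarize_subjects",
    "prevalence_test",
    "correlate_counts",
    "circular_mean_iqr",
    "watson_u2",
    "entrainment_regression",
    "PrevalenceResult",
    "CircularSummary",
    "EntrainmentFit",
]


@dataclass(frozen=True)
class SubjectSummary:
    subject_id: str
    n_rhythmic: int
    classification: str  # "standard" | "reduced"
    group: str | None = None
    acrophases: dict | None = None  # analyte -> hours, circadian analytes only


def summarize_subjects(calls: pd.DataFrame, K: int = 3) -> list[SubjectSummary]:
    """Count rhythmic analytes per subject and classify at threshold K.

    ``calls`` needs columns subject, analyte, circadian; one row per
    (subject, analyte).
    """
    if len(calls) == 0:
        raise ValueError("empty call table")
    required = {"subject", "analyte", "circadian"}
    if missing := required - set(calls.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    if calls.duplicated(subset=["subject", "analyte"]).any():
        raise ValueError("call table must have one row per (subject, analyte)")
    out = []
    for subject, g in calls.groupby("subject", sort=True):
        n = int(g["circadian"].sum())
        acro = None
        if "acrophase_h" in g.columns:
            rows = g[g["circadian"] & g["acrophase_h"].notna()]
            acro = dict(zip(rows["analyte"], rows["acrophase_h"].astype(float)))
        group = None
        if "group" in g.columns and g["group"].notna().any():
            group = str(g["group"].dropna().iloc[0])
        out.append(
            SubjectSummary(
                subject_id=str(subject),
                n_rhythmic=n,
                classification="standard" if n >= K else "reduced",
                group=group,
                acrophases=acro,
            )
        )
    return out


@dataclass(frozen=True)
class PrevalenceResult:
    chi2: float
    pvalue: float
    degenerate: bool  # True when a margin of the 2x2 table is zero


def prevalence_test(
    groupA: pd.DataFrame,
    groupB: pd.DataFrame,
    analyte: str,
    *,
    continuity_correction: bool = False,
) -> PrevalenceResult:
    """Chi-squared test of rhythm prevalence for one analyte between groups.

    2x2 table of (rhythmic yes/no) x (group), without Yates continuity
    correction by default.
    """
    cells = []
    for g in (groupA, groupB):
        sub = g[g["analyte"] == analyte]
        if len(sub) == 0:
            raise ValueError(f"no calls for analyte {analyte!r} in one group")
        yes = int(sub["circadian"].sum())
        cells.append([yes, len(sub) - yes])
    table = np.array(cells)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return PrevalenceResult(chi2=0.0, pvalue=1.0, degenerate=True)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity_correction)
    return PrevalenceResult(chi2=float(chi2), pvalue=float(p), degenerate=False)


def correlate_counts(
    summaries: list[SubjectSummary], covariate: dict
) -> tuple[float, float, float]:
    """Pearson correlation of per-subject rhythmic counts against a clinical
    covariate (e.g. CRP). Returns (r, r^2, p)."""
    pairs = [
        (s.n_rhythmic, float(covariate[s.subject_id]))
        for s in summaries
        if s.subject_id in covariate
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 subjects with both count and covariate")
    x, y = map(np.asarray, zip(*pairs))
    if np.ptp(y) == 0:
        raise ValueError("constant covariate")
    r, p = stats.pearsonr(x, y)
    return float(r), float(r**2), float(p)


@dataclass(frozen=True)
class CircularSummary:
    mean_h: float
    iqr_low_h: float
    iqr_high_h: float
    defined: bool  # False when the resultant vector is ~0 (uniform phases)


def circular_mean_iqr(
    acrophases, tau: float = 24.0, *, resultant_tol: float = 1e-8
) -> CircularSummary:
    """Circular mean (resultant vector) and IQR band of phases on a
    tau-circle. Quartiles are taken after cutting the circle opposite the
    mean, so the band never straddles the cut."""
    a = np.asarray(list(acrophases), float)
    if a.size < 2:
        raise ValueError("need at least 2 acrophases")
    ang = 2 * np.pi * a / tau
    z = np.exp(1j * ang).mean()
    if abs(z) < resultant_tol:
        return CircularSummary(float("nan"), float("nan"), float("nan"), False)
    mean = (np.angle(z) * tau / (2 * np.pi)) % tau
    if np.isclose(mean, tau):  # wrap 24.0 back to 0
        mean = 0.0
    # rotate mean to tau/2, quartiles on the line, rotate back
    rotated = (a - mean + tau / 2) % tau
    q1, q3 = np.percentile(rotated, [25, 75])
    return CircularSummary(
        mean_h=float(mean),
        iqr_low_h=float((q1 + mean - tau / 2) % tau),
        iqr_high_h=float((q3 + mean - tau / 2) % tau),
        defined=True,
    )


def _watson_u2_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Watson U^2 from the difference of empirical CDFs on the
    pooled circular sample."""
    n, m = a.size, b.size
    N = n + m
    pooled = np.concatenate([a, b])
    order = np.argsort(pooled, kind="stable")
    is_a = np.concatenate([np.ones(n, bool), np.zeros(m, bool)])[order]
    # d_k = F_a - F_b after each pooled observation
    da = np.cumsum(is_a) / n
    db = np.cumsum(~is_a) / m
    d = da - db
    return float(n * m / N**2 * (np.sum(d**2) - np.sum(d) ** 2 / N))


def _watson_asymptotic_p(u2: float, terms: int = 50) -> float:
    """Asymptotic tail probability P(U^2 > u2) = 2 sum (-1)^{k-1} exp(-2 k^2 pi^2 u2)."""
    k = np.arange(1, terms + 1)
    p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * np.pi**2 * u2))
    return float(min(max(p, 0.0), 1.0))


def watson_u2(
    samplesA,
    samplesB,
    tau: float = 24.0,
    *,
    method: str = "asymptotic",
    n_perm: int = 9999,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sample Watson U^2 test for a common circular distribution.

    Returns (U^2, p). ``method="permutation"`` shuffles group labels
    (recommended for small samples); ties across the pooled sample force the
    permutation path, whose statistic ranking is unaffected by how ties are
    broken in the sort.
    """
    a = np.mod(np.asarray(list(samplesA), float), tau)
    b = np.mod(np.asarray(list(samplesB), float), tau)
    if a.size < 4 or b.size < 4:
        raise ValueError("each sample needs at least 4 points")
    u2 = _watson_u2_stat(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if method == "asymptotic" and has_ties:
        method = "permutation"
    if method == "asymptotic":
        return u2, _watson_asymptotic_p(u2)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _watson_u2_stat(perm[: a.size], perm[a.size :]) >= u2:
            hits += 1
    return u2, (hits + 1) / (n_perm + 1)


@dataclass(frozen=True)
class EntrainmentFit:
    slope: float
    intercept: float
    r2: float
    identifiable: bool  # False when event times span < 4 h


def entrainment_regression(
    acrophases: dict, event_times: dict, tau: float = 24.0
) -> EntrainmentFit:
    """OLS of acrophase on event clock time after circular unwrapping.

    Acrophases live on a tau-circle, so each may be shifted by an integer
    number of periods. The line (slope, intercept) is found by minimizing the
    sum of squared *wrapped* residuals over a coarse slope/intercept grid,
    then each acrophase is unwrapped to the branch nearest the line and the
    final OLS is run on the unwrapped values — equivalent to the exhaustive
    branch search at these small n, without enumerating 3^n assignments.
    """
    subjects = sorted(set(acrophases) & set(event_times))
    if len(subjects) < 3:
        raise ValueError("need at least 3 paired subjects")
    x = np.array([float(event_times[s]) for s in subjects])
    y = np.array([float(acrophases[s]) % tau for s in subjects])
    identifiable = bool(np.ptp(x) >= 4.0)
    if not identifiable:
        import warnings

        warnings.warn("event times span under 4 h; slope poorly identified", stacklevel=2)

    def wrapped_sse(slope, intercept):
        r = (y - slope * x - intercept + tau / 2) % tau - tau / 2
        return np.sum(r**2)

    slopes = np.arange(-2.0, 3.0 + 1e-9, 0.01)
    best = (np.inf, 0.0, 0.0)
    for b in slopes:
        # best intercept on the circle for this slope: dense scan
        r0 = (y - b * x) % tau
        cands = np.r_[r0, np.arange(0, tau, 0.1)]
        sses = [wrapped_sse(b, c) for c in cands]
        j = int(np.argmin(sses))
        if sses[j] < best[0]:
            best = (sses[j], b, float(cands[j] % tau))
    _, b0, c0 = best
    # unwrap to the branch nearest the provisional line, then plain OLS
    y_un = y + tau * np.round((b0 * x + c0 - y) / tau)
    sxx = np.sum((x - x.mean()) ** 2)
    slope = float(np.sum((x - x.mean()) * (y_un - y_un.mean())) / sxx)
    intercept = float(y_un.mean() - slope * x.mean())
    yhat = slope * x + intercept
    sst = float(np.sum((y_un - y_un.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y_un - yhat) ** 2)) / sst if sst > 0 else 0.0
    return EntrainmentFit(slope=slope, intercept=intercept % tau, r2=r2, identifiable=identifiable)
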