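"""Seeded synthetic cohort fixtures.

These emulate the structure of the clinical cohorts the detector is aimed
at — they are synthetic stand-ins, not patient data:

(a) a 9-clock-gene x 20-subject cohort with a "standard" and a "reduced"
    subgroup plus an inflammation-like covariate anti-correlated with the
    number of rhythmic genes;
(b) an entrained cohort whose per-subject acrophases track a synthetic
    event time with slope 1;
(c) an event-time list with a 2:1 circular modulation peaking at 06:00.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CLOCK_GENES", "make_fixtures", "gen_cohort_frame", "gen_entrained_cohort", "gen_modulated_events"]

CLOCK_GENES = ["PER1", "PER2", "PER3", "NR1D1", "NR1D2", "BMAL1", "CLOCK", "CRY1", "CRY2"]


def gen_cohort_frame(
    seed: int,
    n_standard: int = 12,
    n_reduced: int = 8,
    window: float = 48.0,
    interval: float = 4.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic cohort of per-gene time series plus covariate table.

    Standard subjects carry 6-9 rhythmic clock genes, reduced subjects 0-2;
    rhythmic genes are low-noise cosines, the rest flat traces with noise.
    The covariate falls linearly with the subject's rhythmic-gene count.
    Returns (series_frame, covariate_frame).
    """
    rng = np.random.default_rng([seed, 101])
    t = np.arange(0.0, window + 1e-9, interval)
    rows, cov_rows = [], []
    subjects = [("standard", i) for i in range(n_standard)] + [
        ("reduced", i) for i in range(n_reduced)
    ]
    for group, i in subjects:
        sid = f"{group[:3].upper()}{i + 1:02d}"
        n_rhythmic = int(rng.integers(6, 10)) if group == "standard" else int(rng.integers(0, 3))
        rhythmic = set(rng.choice(CLOCK_GENES, size=n_rhythmic, replace=False))
        for gene in CLOCK_GENES:
            mesor = rng.uniform(8, 12)
            if gene in rhythmic:
                amp = rng.uniform(2, 4)
                phi = rng.uniform(0, 24)
                y = mesor + amp * np.cos(2 * np.pi * (t - phi) / 24.0)
                y = y + 0.15 * amp * rng.standard_normal(t.size)
            else:
                y = mesor + 0.4 * rng.standard_normal(t.size)
            for tt, vv in zip(t, y):
                rows.append(
                    {"subject": sid, "analyte": gene, "time_h": tt, "value": vv, "group": group}
                )
        cov_rows.append(
            {
                "subject": sid,
                "covariate": 120.0 - 10.0 * len(rhythmic) + 5.0 * rng.standard_normal(),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(cov_rows)


def gen_entrained_cohort(
    seed: int, n_subjects: int = 10, phase_offset: float = 5.0, noise_sd_h: float = 0.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Series whose acrophases equal event time + offset (mod 24) with
    wrapped noise; events spread over the day. Returns (series, events)."""
    rng = np.random.default_rng([seed, 202])
    t = np.arange(0.0, 48.0 + 1e-9, 4.0)
    rows, ev_rows = [], []
    event_times = np.sort(rng.uniform(0, 24, n_subjects))
    for i, ev in enumerate(event_times):
        sid = f"ENT{i + 1:02d}"
        phi = (ev + phase_offset + noise_sd_h * rng.standard_normal()) % 24.0
        y = 10.0 + 3.0 * np.cos(2 * np.pi * (t - phi) / 24.0)
        y = y + 0.3 * rng.standard_normal(t.size)
        for tt, vv in zip(t, y):
            rows.append({"subject": sid, "analyte": "PER3", "time_h": tt, "value": vv})
        ev_rows.append({"subject": sid, "event_time_h": ev})
    return pd.DataFrame(rows), pd.DataFrame(ev_rows)


def gen_modulated_events(
    seed: int, n_events: int = 400, peak_h: float = 6.0, depth: float = 1.0 / 3.0
) -> np.ndarray:
    """Event clock times from density proportional to
    1 + depth*cos(2*pi*(t - peak)/24); depth 1/3 gives a 2:1 peak-to-trough
    ratio. Rejection sampling, seeded."""
    rng = np.random.default_rng([seed, 303])
    out = np.empty(n_events)
    k = 0
    while k < n_events:
        t = rng.uniform(0, 24, 4 * (n_events - k))
        u = rng.uniform(0, 1 + depth, t.size)
        accept = t[u <= 1 + depth * np.cos(2 * np.pi * (t - peak_h) / 24.0)]
        take = accept[: n_events - k]
        out[k : k + take.size] = take
        k += take.size
    return np.sort(out)


def make_fixtures(seed: int, outdir: str | Path) -> dict[str, Path]:
    """Write the three fixture families as CSVs; byte-identical per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    series, cov = gen_cohort_frame(seed)
    paths["cohort_series"] = outdir / "cohort_series.csv"
    series.to_csv(paths["cohort_series"], index=False, float_format="%.6f")
    paths["cohort_covariate"] = outdir / "cohort_covariate.csv"
    cov.to_csv(paths["cohort_covariate"], index=False, float_format="%.6f")

    ent_series, ent_events = gen_entrained_cohort(seed)
    paths["entrained_series"] = outdir / "entrained_series.csv"
    ent_series.to_csv(paths["entrained_series"], index=False, float_format="%.6f")
    paths["entrained_events"] = outdir / "entrained_events.csv"
    ent_events.to_csv(paths["entrained_events"], index=False, float_format="%.6f")

    ev = gen_modulated_events(seed)
    paths["events"] = outdir / "events.csv"
    pd.DataFrame({"subject": [f"E{i + 1:03d}" for i in range(ev.size)], "event_time_h": ev}).to_csv(
        paths["events"], index=False, float_format="%.6f"
    )
    return paths
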