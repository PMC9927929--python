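"""The ClinCirc sequential detector.

Three stages, each able to reject a series:

1. **Lomb-Scargle gate** — the dominant periodogram harmonic must lie in the
   circadian band (default 18-30 h, closed interval).
2. **Loose period filter** — an unconstrained cosinor fit must not land on an
   excessively high or low period (default bounds 15-40 h, strictly
   containing the band). This is the stage that rejects monotone trends,
   whose best-fitting sinusoid has a far longer period than circadian.
3. **Constrained characterization** — a cosinor fit with the period
   constrained to the band and the amplitude capped at 2 sample SDs; the
   zero-amplitude F-test at level alpha decides presence.

An accepted series carries the constrained fit, from which mesor, amplitude,
relative amplitude, acrophase and period are read off.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .cosinor import CosinorFit, fit_free_period
from .lombscargle import CIRCADIAN_BAND, Periodogram, compute_periodogram
from .series import MIN_SPAN_H, SampledSeries, Timescale

__all__ = [
    "ClinCircConfig",
    "RejectionStage",
    "RhythmCall",
    "Characteristics",
    "clincirc_call",
    "characterize",
]


@dataclass(frozen=True)
class ClinCircConfig:
    """Tunable thresholds of the ClinCirc procedure."""

    circadian_band: tuple[float, float] = CIRCADIAN_BAND
    loose_period_bounds: tuple[float, float] = (15.0, 40.0)
    amplitude_cap_sd: float = 2.0  # cap = this many sample SDs
    alpha: float = 0.05
    require_significance: bool = True
    log_transform: bool = False  # log-transform values before fitting

    def __post_init__(self) -> None:
        lo, hi = self.circadian_band
        llo, lhi = self.loose_period_bounds
        if not (llo < lo and hi < lhi):
            raise ValueError("loose_period_bounds must strictly contain circadian_band")
        if self.amplitude_cap_sd <= 0:
            raise ValueError("amplitude_cap_sd must be positive")


class RejectionStage(enum.Enum):
    NONE = "none"
    LSP_GATE = "lsp_gate"
    LOOSE_PERIOD = "loose_period"
    AMPLITUDE_TEST = "amplitude_test"


@dataclass(frozen=True)
class RhythmCall:
    """Per-series ClinCirc verdict with the stage at which rejection occurred."""

    circadian: bool
    rejection_stage: RejectionStage
    periodogram: Periodogram
    fit: CosinorFit | None = None  # constrained fit; present when it was computed
    timescale: Timescale = Timescale.CLOCK_TIME

    def __post_init__(self) -> None:
        if self.circadian != (self.rejection_stage is RejectionStage.NONE):
            raise ValueError("circadian flag inconsistent with rejection stage")
        if self.circadian and self.fit is None:
            raise ValueError("accepted call must carry the constrained fit")


@dataclass(frozen=True)
class Characteristics:
    mesor: float
    amplitude: float
    relative_amplitude: float
    acrophase_h: float
    period_h: float
    timescale: Timescale


def clincirc_call(s: SampledSeries, cfg: ClinCircConfig | None = None) -> RhythmCall:
    """Run the three-stage ClinCirc procedure on one series.

    Raises on unusable input (fewer than 5 samples or span under 20 h)
    rather than returning a silent non-circadian call.
    """
    cfg = cfg or ClinCircConfig()
    s.require_usable()
    if s.span < MIN_SPAN_H:
        raise ValueError(
            f"observation span {s.span:.1f} h is below the {MIN_SPAN_H:.0f}-h design floor"
        )
    if cfg.log_transform:
        if np.any(s.values <= 0):
            raise ValueError("log transform requires strictly positive values")
        s = s.with_values(np.log(s.values))

    pg = compute_periodogram(s)
    lo, hi = cfg.circadian_band
    if not (lo <= pg.dominant_period <= hi):
        return RhythmCall(False, RejectionStage.LSP_GATE, pg, timescale=s.timescale)

    loose = fit_free_period(s)  # unconstrained period
    llo, lhi = cfg.loose_period_bounds
    if not (llo <= loose.period <= lhi):
        return RhythmCall(False, RejectionStage.LOOSE_PERIOD, pg, timescale=s.timescale)

    cap = cfg.amplitude_cap_sd * float(np.std(s.values, ddof=1))
    fit = fit_free_period(s, bounds=cfg.circadian_band, amplitude_cap=cap)
    if cfg.require_significance and not (fit.zero_amp_pvalue < cfg.alpha):
        return RhythmCall(
            False, RejectionStage.AMPLITUDE_TEST, pg, fit=fit, timescale=s.timescale
        )
    return RhythmCall(True, RejectionStage.NONE, pg, fit=fit, timescale=s.timescale)


def characterize(call: RhythmCall) -> Characteristics:
    """Extract rhythm characteristics from an accepted call.

    The acrophase is reported in hours on the series' declared timescale
    (clock time, or hours post-event).
    """
    if not call.circadian or call.fit is None:
        raise ValueError("characterize requires a circadian call")
    f = call.fit
    return Characteristics(
        mesor=f.mesor,
        amplitude=f.amplitude,
        relative_amplitude=f.relative_amplitude,
        acrophase_h=f.acrophase,
        period_h=f.period,
        timescale=call.timescale,
    )
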