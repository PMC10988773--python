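"""ROI aggregation, individual-level significance, correlations, behaviour.

Regions of interest follow the study layout: a left occipito-temporal ROI
around PO7 with its right-hemisphere mirror, and a medial-occipital ROI
(Oz, Iz, O1, O2) for the base-rate response.  The exact five LROI
electrodes are configurable and every report echoes the set actually used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import TaskEvent
from .errors import ConfigurationError, ValidationError
from .spectral import AmplitudeSpectrum
from .stats import Z_INDIVIDUAL


@dataclass(frozen=True)
class ROI:
    """A named set of electrodes averaged together."""

    name: str
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValidationError(f"duplicate channels in ROI {self.name!r}")


def default_rois() -> dict[str, ROI]:
    """LROI (around PO7), its right mirror RROI, and the medial-occipital MO."""
    return {
        "LROI": ROI("LROI", ("PO7", "P7", "P9", "PO9", "O1")),
        "RROI": ROI("RROI", ("PO8", "P8", "P10", "PO10", "O2")),
        "MO": ROI("MO", ("Oz", "Iz", "O1", "O2")),
    }


def roi_average(spectrum: AmplitudeSpectrum, roi: ROI) -> AmplitudeSpectrum:
    """Unweighted mean amplitude across the ROI channels, per bin."""
    missing = [c for c in roi.channels if c not in spectrum.channel_names]
    if missing:
        raise ConfigurationError(f"ROI {roi.name!r} channels missing: {missing}")
    rows = [spectrum.channel_names.index(c) for c in roi.channels]
    return AmplitudeSpectrum(
        amps=spectrum.amps[rows].mean(axis=0, keepdims=True),
        freqs=spectrum.freqs.copy(),
        df_hz=spectrum.df_hz,
        channel_names=[roi.name],
    )


def grand_average(spectra: list[AmplitudeSpectrum]) -> AmplitudeSpectrum:
    """Bin-wise mean across participants (grids must match exactly)."""
    if not spectra:
        raise ConfigurationError("no spectra to average")
    first = spectra[0]
    for s in spectra[1:]:
        if s.amps.shape != first.amps.shape or not np.allclose(s.freqs, first.freqs):
            raise ConfigurationError("spectra have mismatching grids")
    return AmplitudeSpectrum(
        amps=np.mean([s.amps for s in spectra], axis=0),
        freqs=first.freqs.copy(),
        df_hz=first.df_hz,
        channel_names=list(first.channel_names),
    )


def individual_significance(results: pd.DataFrame,
                            z_thresh: float = Z_INDIVIDUAL
                            ) -> tuple[pd.DataFrame, dict]:
    """Flag significant individual responses and tally them across the design.

    ``results`` must carry columns ``participant``, ``z`` and any design
    columns (task, discrimination, control_type, roi, ...).  Returns the
    table with a ``significant`` column plus summary counts: participants
    significant in at least one cell, in every cell (collapsing ROI:
    a design cell counts as significant if any ROI reaches threshold),
    and per-ROI / per-task tallies.
    """
    required = {"participant", "z"}
    if not required.issubset(results.columns):
        raise ValidationError(f"results table needs columns {sorted(required)}")
    table = results.copy()
    table["significant"] = table["z"] > z_thresh
    cell_cols = [c for c in ("task", "discrimination", "control_type")
                 if c in table.columns]
    summary: dict = {"z_thresh": z_thresh, "n_participants": table["participant"].nunique()}
    by_p = table.groupby("participant")["significant"]
    summary["n_significant_any"] = int(by_p.any().sum())
    if cell_cols:
        cells = table.groupby(["participant", *cell_cols])["significant"].any()
        summary["n_significant_all_cells"] = int(
            cells.groupby("participant").all().sum()
        )
    else:
        summary["n_significant_all_cells"] = int(by_p.all().sum())
    for col in ("roi", "task"):
        if col in table.columns:
            summary[f"n_significant_by_{col}"] = {
                k: int(g.groupby(table["participant"]).any().sum())
                for k, g in table.groupby(col)["significant"]
            }
    return table, summary


def spearman_correlation(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan"), float("nan")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class BehaviorScore:
    """Hit rate, false alarms and reaction times for one sequence's task."""

    n_go: int
    n_nogo: int
    n_presses: int
    hits: int
    false_alarms: int
    hit_rate: float
    fa_rate: float
    mean_rt_s: float  # NaN when there are no hits


def score_behavior(events: list[TaskEvent], keypresses: list[float],
                   window: tuple[float, float] = (0.15, 1.0)) -> BehaviorScore:
    """Match keypresses to go events and score hits, false alarms and RT.

    A press counts as a hit for the earliest unmatched go event whose
    response window ``[onset+window[0], onset+window[1]]`` contains it; each
    press matches at most one event and vice versa.  Unmatched presses are
    false alarms.  The false-alarm rate is per no-go trial when no-go
    trials exist (bars task), else per go trial.
    """
    go = sorted((e.onset_s for e in events if e.is_go))
    n_nogo = sum(1 for e in events if not e.is_go)
    presses = sorted(float(p) for p in keypresses)
    matched_events: set[int] = set()
    rts = []
    fa = 0
    for p in presses:
        hit_idx = None
        for i, onset in enumerate(go):
            if i in matched_events:
                continue
            if onset + window[0] <= p <= onset + window[1]:
                hit_idx = i
                break
        if hit_idx is None:
            fa += 1
        else:
            matched_events.add(hit_idx)
            rts.append(p - go[hit_idx])
    hits = len(matched_events)
    hit_rate = hits / len(go) if go else float("nan")
    denom = n_nogo if n_nogo > 0 else len(go)
    fa_rate = fa / denom if denom > 0 else float("nan")
    return BehaviorScore(
        n_go=len(go), n_nogo=n_nogo, n_presses=len(presses),
        hits=hits, false_alarms=fa, hit_rate=hit_rate, fa_rate=fa_rate,
        mean_rt_s=float(np.mean(rts)) if rts else float("nan"),
    )
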