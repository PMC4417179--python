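"""Raw intensity traces -> corrected FRET time series.

Photobleach change-point detection, background subtraction using the
post-bleach baseline, and the standard two-colour corrections: donor
leakage into the acceptor channel (default 0.12) and the gamma detection
imbalance factor (default 1.7).  The corrected efficiency is
E = A' / (A' + gamma * I_D) with A' = I_A - l * I_D, computed on
background-subtracted intensities; frames at or after the first bleach
are excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .synthetic_data import IntensityTrace

__all__ = [
    "CorrectionParams",
    "FretTrace",
    "TraceTooShortError",
    "detect_photobleach",
    "subtract_background",
    "compute_fret",
    "correct_trace",
]

E_CLIP = (-0.2, 1.2)


class TraceTooShortError(ValueError):
    """Trace has too few frames for change-point detection."""


@dataclass(frozen=True)
class CorrectionParams:
    """Leakage and gamma correction factors for the dye pair / setup."""

    leakage: float = 0.12
    gamma: float = 1.7

    def __post_init__(self) -> None:
        if not (0 <= self.leakage < 0.5):
            raise ValueError("leakage must be in [0, 0.5)")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass
class FretTrace:
    """Corrected per-frame FRET efficiency with bleach truncation.

    ``efficiency`` is clipped to [-0.2, 1.2] for storage; ``raw_efficiency``
    keeps the unclipped values used by kinetics.  Frames at index >=
    ``analysis_end`` (the first detected bleach, or trace length if none)
    are not valid FRET observations.
    """

    molecule_id: str
    frame_period: float
    efficiency: np.ndarray
    raw_efficiency: np.ndarray
    total: np.ndarray
    analysis_end: int
    background_donor: float = 0.0
    background_acceptor: float = 0.0
    condition: str = ""
    degenerate: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.analysis_end <= len(self.efficiency)):
            raise ValueError("analysis_end out of range")

    @property
    def n_frames(self) -> int:
        return len(self.efficiency)

    @property
    def pre_bleach(self) -> np.ndarray:
        """Unclipped efficiencies of the analysable (pre-bleach) frames."""
        return self.raw_efficiency[: self.analysis_end]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Split index minimising the SSE of a two-segment constant fit.

    Returns (k, drop): the post-segment starts at frame k and the level
    drops by `drop` (positive means a downward step).
    """
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    k = np.arange(1, n)
    n1, n2 = k.astype(float), (n - k).astype(float)
    s1, s2 = cs[k], cs[n] - cs[k]
    sse = (cs2[k] - s1 * s1 / n1) + (cs2[n] - cs2[k] - s2 * s2 / n2)
    best = int(k[np.argmin(sse)])
    drop = float(cs[best] / best - (cs[n] - cs[best]) / (n - best))
    return best, drop


def _noise_scale(x: np.ndarray) -> float:
    """Robust per-frame noise sd from first differences (MAD-based)."""
    d = np.diff(x)
    mad = np.median(np.abs(d - np.median(d)))
    return 1.4826 * mad / np.sqrt(2.0)


def _detect_step_down(x: np.ndarray, threshold_mads: float) -> int | None:
    if len(x) < 10:
        return None
    k, drop = _best_split(x)
    sigma = _noise_scale(x)
    if drop <= 0:
        return None
    if sigma == 0:
        return k  # noiseless step
    return k if drop > threshold_mads * sigma else None


def detect_photobleach(
    trace: IntensityTrace, threshold_mads: float = 4.0
) -> tuple[int | None, int | None]:
    """Locate single-step photobleaching of the acceptor and donor.

    Each channel is fit with a two-segment piecewise-constant model; the
    split with the largest sum-of-squares reduction is accepted as a
    bleach only if the downward step exceeds ``threshold_mads`` times the
    robust (MAD-derived) per-frame noise scale.  The donor bleach is
    searched on the donor channel *after* the acceptor bleach, where the
    donor intensity has risen (energy transfer lost) and then falls at its
    own bleaching.

    Returns ``(acceptor_bleach_frame, donor_bleach_frame)``; ``None``
    where no step was accepted.
    """
    if trace.n_frames < 10:
        raise TraceTooShortError(
            f"trace {trace.molecule_id!r} has {trace.n_frames} frames, need >= 10"
        )
    bleach_a = _detect_step_down(trace.acceptor, threshold_mads)
    bleach_d = None
    if bleach_a is not None and trace.n_frames - bleach_a >= 10:
        bleach_d = _detect_step_down(trace.donor[bleach_a:], threshold_mads)
        if bleach_d is not None:
            bleach_d += bleach_a
    if bleach_d is None:
        # the donor may have bleached first, taking the acceptor signal
        # down with it: its own down-step then coincides with (or
        # precedes) the acceptor-channel step
        bleach_d = _detect_step_down(trace.donor, threshold_mads)
    return bleach_a, bleach_d


def subtract_background(
    trace: IntensityTrace,
    bleach_frames: tuple[int | None, int | None],
    default_background: tuple[float, float] = (0.0, 0.0),
    min_frames: int = 5,
) -> tuple[IntensityTrace, tuple[float, float]]:
    """Subtract the post-bleach baseline from both channels.

    Both backgrounds are estimated from the region after the donor bleach:
    once the donor is dark there is no energy transfer and no leakage, so
    both channels sit at their camera baseline — the "after photobleaching
    of both fluorophores" region of the experimental protocol.  The region
    after an acceptor-only bleach is *not* used for the acceptor baseline,
    because donor leakage keeps feeding that channel until the donor
    itself goes dark.  When fewer than ``min_frames`` baseline frames are
    available, the configured default (instrument-calibration) background
    is used for that channel.
    """
    bleach_a, bleach_d = bleach_frames
    n = trace.n_frames

    def _median_after(x: np.ndarray, start: int | None) -> float | None:
        if start is None or n - start < min_frames:
            return None
        return float(np.median(x[start:]))

    start = None
    if bleach_d is not None:
        start = bleach_d if bleach_a is None else max(bleach_a, bleach_d)
    bg_d = _median_after(trace.donor, start)
    if bg_d is None:
        bg_d = float(default_background[0])
    bg_a = _median_after(trace.acceptor, start)
    if bg_a is None:
        bg_a = float(default_background[1])

    corrected = IntensityTrace(
        molecule_id=trace.molecule_id,
        frame_period=trace.frame_period,
        donor=trace.donor - bg_d,
        acceptor=trace.acceptor - bg_a,
        condition=trace.condition,
        metadata={**trace.metadata, "background_donor": bg_d, "background_acceptor": bg_a},
    )
    return corrected, (bg_d, bg_a)


def compute_fret(
    trace: IntensityTrace,
    params: CorrectionParams = CorrectionParams(),
    bleach_frames: tuple[int | None, int | None] = (None, None),
    backgrounds: tuple[float, float] = (0.0, 0.0),
    degenerate_fraction: float = 0.2,
) -> FretTrace:
    """Leakage/gamma-corrected FRET efficiency per frame.

    Expects a background-subtracted trace.  A' = I_A - l * I_D is the
    leakage-corrected acceptor signal; E = A' / (A' + gamma * I_D), and
    the corrected total A' + gamma * I_D is recorded per frame.  A trace
    whose corrected total is non-positive on more than
    ``degenerate_fraction`` of pre-bleach frames is flagged degenerate
    (excluded from kinetics, retained for logging).
    """
    a_prime = trace.acceptor - params.leakage * trace.donor
    total = a_prime + params.gamma * trace.donor
    with np.errstate(divide="ignore", invalid="ignore"):
        e_raw = np.where(total != 0, a_prime / total, np.nan)

    bleach_a, bleach_d = bleach_frames
    candidates = [b for b in (bleach_a, bleach_d) if b is not None]
    analysis_end = min(candidates) if candidates else trace.n_frames

    pre = total[:analysis_end]
    degenerate = False
    if analysis_end > 0:
        bad = np.count_nonzero(~(pre > 0))
        degenerate = bad > degenerate_fraction * analysis_end
    else:
        degenerate = True

    return FretTrace(
        molecule_id=trace.molecule_id,
        frame_period=trace.frame_period,
        efficiency=np.clip(e_raw, *E_CLIP),
        raw_efficiency=e_raw,
        total=total,
        analysis_end=analysis_end,
        background_donor=backgrounds[0],
        background_acceptor=backgrounds[1],
        condition=trace.condition,
        degenerate=degenerate,
        metadata=dict(trace.metadata),
    )


def correct_trace(
    trace: IntensityTrace,
    params: CorrectionParams = CorrectionParams(),
    threshold_mads: float = 4.0,
    default_background: tuple[float, float] = (0.0, 0.0),
) -> FretTrace:
    """Full correction pipeline: bleach detection -> background -> FRET."""
    bleach = detect_photobleach(trace, threshold_mads=threshold_mads)
    subtracted, backgrounds = subtract_background(
        trace, bleach, default_background=default_background
    )
    return compute_fret(subtracted, params, bleach_frames=bleach, backgrounds=backgrounds)
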