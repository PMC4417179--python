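"""FRET-efficiency histograms and peak finding.

Two protocols are implemented.  The *snapshot* histogram gives each
molecule one count: its mean efficiency over a 500-ms window (10 frames of
50 ms), normalised to total counts — the protocol used for salt-titration
histograms.  The *per-state* histograms give each (molecule, state) pair
one count — the molecule's mean efficiency over the frames assigned to
that state — and scale each state's histogram so its total mass equals the
state's relative population, so the three histograms together carry unit
mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .state_kinetics import DwellRecord, occupancy
from .trace_correction import FretTrace

__all__ = [
    "FretHistogram",
    "EmptyHistogramError",
    "snapshot_histogram",
    "per_state_histograms",
    "peak_positions",
]


class EmptyHistogramError(ValueError):
    """No eligible molecules contributed any counts."""


@dataclass(frozen=True)
class FretHistogram:
    """Normalised FRET histogram.

    ``fractions`` sum to 1 for the snapshot protocol; a per-state
    histogram's mass equals that state's relative population.
    """

    edges: np.ndarray
    fractions: np.ndarray
    protocol: str
    condition: str = ""
    state: str | None = None

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        fractions = np.asarray(self.fractions, dtype=float)
        if len(edges) != len(fractions) + 1:
            raise ValueError("need len(edges) == len(fractions) + 1")
        if np.any(fractions < 0):
            raise ValueError("fractions must be >= 0")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "fractions", fractions)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def mass(self) -> float:
        return float(self.fractions.sum())


def _make_edges(bin_width: float, e_range: tuple[float, float]) -> np.ndarray:
    lo, hi = e_range
    n = int(np.ceil((hi - lo) / bin_width))
    return lo + bin_width * np.arange(n + 1)


def snapshot_histogram(
    fret_traces: Sequence[FretTrace],
    window_frames: int = 10,
    bin_width: float = 0.02,
    selector: str = "random",
    seed: int = 0,
    e_range: tuple[float, float] = (-0.2, 1.2),
    condition: str = "",
) -> FretHistogram:
    """One count per molecule: mean E over a short window of frames.

    ``selector``: ``"random"`` draws a uniformly random pre-bleach window
    start per molecule (seeded, so reruns are identical), ``"first"``
    takes the first window.  Molecules with fewer than ``window_frames``
    pre-bleach frames, and degenerate traces, are skipped.
    """
    if selector not in ("random", "first"):
        raise ValueError(f"unknown selector {selector!r}")
    rng = np.random.default_rng(seed)
    values = []
    for tr in fret_traces:
        if tr.degenerate:
            continue
        pre = tr.pre_bleach
        if len(pre) < window_frames:
            continue
        start = int(rng.integers(0, len(pre) - window_frames + 1)) if selector == "random" else 0
        values.append(float(np.mean(pre[start : start + window_frames])))
    if not values:
        raise EmptyHistogramError("no molecule has enough pre-bleach frames")
    edges = _make_edges(bin_width, e_range)
    counts, _ = np.histogram(np.clip(values, edges[0], edges[-1] - 1e-12), bins=edges)
    return FretHistogram(
        edges=edges,
        fractions=counts / counts.sum(),
        protocol="snapshot",
        condition=condition,
    )


def per_state_histograms(
    fret_traces: Sequence[FretTrace],
    dwell_tables: Sequence[Sequence[DwellRecord]],
    bin_width: float = 0.02,
    e_range: tuple[float, float] = (-0.2, 1.2),
    condition: str = "",
    per_dwell: bool = False,
) -> dict[str, FretHistogram]:
    """Per-state FRET histograms scaled to each state's relative population.

    For every molecule and state, the mean efficiency over the frames the
    segmentation assigned to that state contributes one count to the
    state's histogram (``per_dwell=True`` switches the contribution unit
    to one count per dwell).  Each histogram is then scaled so its total
    mass equals that state's occupancy over the pooled cohort, hence the
    masses sum to 1.
    """
    if len(fret_traces) != len(dwell_tables):
        raise ValueError("need one dwell table per trace")
    all_dwells = [d for table in dwell_tables for d in table]
    if not all_dwells:
        raise EmptyHistogramError("no dwells in cohort")
    occ = occupancy(all_dwells)
    states = sorted(occ, key=occ.__getitem__, reverse=True)

    contributions: dict[str, list[float]] = {s: [] for s in states}
    for tr, table in zip(fret_traces, dwell_tables):
        pre = tr.pre_bleach
        dt = tr.frame_period
        per_state_frames: dict[str, list[np.ndarray]] = {}
        for d in table:
            start = int(round(d.start_s / dt))
            stop = start + int(round(d.duration_s / dt))
            frames = pre[start:stop]
            if len(frames) == 0:
                continue
            if per_dwell:
                contributions[d.state].append(float(np.mean(frames)))
            else:
                per_state_frames.setdefault(d.state, []).append(frames)
        if not per_dwell:
            for state, chunks in per_state_frames.items():
                contributions[state].append(float(np.mean(np.concatenate(chunks))))

    edges = _make_edges(bin_width, e_range)
    out: dict[str, FretHistogram] = {}
    for state in states:
        vals = contributions[state]
        if not vals:
            counts = np.zeros(len(edges) - 1)
        else:
            counts, _ = np.histogram(np.clip(vals, edges[0], edges[-1] - 1e-12), bins=edges)
            counts = counts / counts.sum() * occ[state]
        out[state] = FretHistogram(
            edges=edges,
            fractions=counts,
            protocol="per_state",
            condition=condition,
            state=state,
        )
    return out


def _weighted_gmm_1d(
    x: np.ndarray, w: np.ndarray, n_components: int, n_iter: int = 500, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """EM for a 1-D Gaussian mixture with per-point weights.

    Returns (means, sds, masses) sorted by mean ascending.  Written in
    place of an off-the-shelf mixture fit because the input is a binned
    histogram (weighted points), which standard fitters do not accept.
    """
    w = w / w.sum()
    # spread initial means over the weighted quantiles
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    qs = (np.arange(n_components) + 0.5) / n_components
    mu = np.interp(qs, cw, x[order])
    var_all = float(np.sum(w * (x - np.sum(w * x)) ** 2)) + 1e-12
    var = np.full(n_components, var_all / max(n_components, 1))
    pi = np.full(n_components, 1.0 / n_components)

    prev_ll = -np.inf
    for _ in range(n_iter):
        # E step
        log_p = (
            np.log(pi[None, :] + 1e-300)
            - 0.5 * np.log(2 * np.pi * var[None, :])
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        log_norm = np.logaddexp.reduce(log_p, axis=1)
        resp = np.exp(log_p - log_norm[:, None])
        ll = float(np.sum(w * log_norm))
        # M step (weighted)
        wk = resp * w[:, None]
        nk = wk.sum(axis=0) + 1e-300
        pi = nk / nk.sum()
        mu = (wk * x[:, None]).sum(axis=0) / nk
        var = (wk * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        var = np.maximum(var, 1e-10)
        if abs(ll - prev_ll) < tol * (1 + abs(ll)):
            break
        prev_ll = ll
    if not np.all(np.isfinite(mu)):
        raise RuntimeError("mixture fit diverged")
    order = np.argsort(mu)
    return mu[order], np.sqrt(var[order]), pi[order]


def peak_positions(hist: FretHistogram, n_peaks: int = 1) -> list[tuple[float, float]]:
    """Peak efficiencies and masses by Gaussian-mixture fitting.

    Fits ``n_peaks`` Gaussian components to the bin centers weighted by
    counts and returns (mean, mass) pairs sorted by mean ascending.  On
    fit failure, falls back to the top-n local maxima with a warning.
    """
    if hist.mass <= 0:
        raise EmptyHistogramError("cannot locate peaks of an empty histogram")
    occupied = hist.fractions > 0
    x = hist.centers[occupied]
    w = hist.fractions[occupied]
    try:
        mu, _, pi = _weighted_gmm_1d(x, w, n_peaks)
        return [(float(m), float(p * hist.mass)) for m, p in zip(mu, pi)]
    except (RuntimeError, FloatingPointError) as exc:
        warnings.warn(f"mixture fit failed ({exc}); falling back to local maxima",
                      stacklevel=2)
        f = hist.fractions
        is_max = np.r_[f[0] >= f[1], (f[1:-1] >= f[:-2]) & (f[1:-1] >= f[2:]), f[-1] >= f[-2]]
        idx = np.flatnonzero(is_max & (f > 0))
        top = idx[np.argsort(f[idx])[::-1][:n_peaks]]
        top = np.sort(top)
        return [(float(hist.centers[i]), float(f[i])) for i in top]
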