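"""Raw fluorescence -> transient-masked ΔF/F in baseline-s.d. units.

The pipeline follows the standard significant-transient procedure for
in vivo calcium imaging:

1. slow drift removal by subtracting the rolling 8th percentile of the
   fluorescence distribution in a 20-s window around each time point;
2. an initial baseline estimate from all points not exceeding 2.3
   total-s.d., giving a provisional ΔF/F in baseline-s.d. units;
3. selection, per cell, of the least-stringent (onset amplitude, minimum
   duration) pair for which the ratio of negative- to positive-oriented
   detected events — the false-positive rate, since calcium transients are
   strictly positive-going — stays below 5%;
4. definitive baseline statistics recomputed from non-transient frames,
   rescaling ΔF/F, and a final transient mask; everything outside the mask
   is set to zero for downstream analysis.

Analyses are restricted to frames with running speed >= 5 cm/s that are not
inside blank-screen teleport gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

log = logging.getLogger(__name__)

__all__ = [
    "ProcessedTrace", "TransientExtractor", "run_mask", "detrend_percentile",
    "estimate_baseline", "select_transient_thresholds", "extract_transients",
    "activity_rate", "is_active", "preprocess_session",
]

ONSET_GRID = (2.0, 2.5, 3.0, 3.5, 4.0)
DURATION_GRID = tuple(range(2, 13))
OFFSET_SIGMA = 0.5
FPR_LIMIT = 0.05
SPEED_THRESHOLD_CM_S = 5.0


@dataclass
class ProcessedTrace:
    """Per-cell preprocessed activity substrate."""

    dff: np.ndarray                # ΔF/F in baseline-s.d. units
    transient_mask: np.ndarray     # bool, True over significant transients
    masked_dff: np.ndarray         # dff * mask (zero outside transients)
    baseline_mean: float
    baseline_sd: float
    onset_sigma: float
    min_duration_frames: int
    fpr_estimate: float
    transient_count: int
    flagged: bool = False          # degenerate or FPR fallback
    flag_reason: str = ""


def run_mask(behavior, speed_threshold_cm_s=SPEED_THRESHOLD_CM_S):
    """Frames included in all spatial analyses: running, not in a gap."""
    return ((behavior.speed_cm_s >= speed_threshold_cm_s)
            & ~behavior.in_gap()
            & np.isfinite(behavior.position_cm))


try:  # optional acceleration; the numpy path is exact and always available
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _rolling_percentile_py(x, half, q):
    n = x.size
    out = np.empty(n)
    win = 2 * half + 1
    rank = q * (win - 1)
    lo, frac = int(rank), rank - int(rank)
    view = np.lib.stride_tricks.sliding_window_view(x, win)
    part = np.partition(view, (lo, lo + 1), axis=1)
    out[half:n - half] = part[:, lo] + frac * (part[:, lo + 1] - part[:, lo])
    for i in range(half):
        for j in (i, n - 1 - i):
            w = np.sort(x[max(0, j - half):j + half + 1])
            r = q * (w.size - 1)
            k, f = int(r), r - int(r)
            hi = min(k + 1, w.size - 1)
            out[j] = w[k] + f * (w[hi] - w[k])
    return out


if _njit is not None:
    @_njit(cache=False)
    def _rolling_percentile_nb(x, half, q):  # pragma: no cover - jitted
        n = x.size
        out = np.empty(n)
        buf = np.empty(min(n, 2 * half + 1))
        m = 0
        l = 0
        r = 0
        for i in range(n):
            nl = i - half if i - half > 0 else 0
            nr = i + half + 1 if i + half + 1 < n else n
            while r < nr:
                v = x[r]
                a, b = 0, m
                while a < b:
                    mid = (a + b) // 2
                    if buf[mid] < v:
                        a = mid + 1
                    else:
                        b = mid
                for k in range(m, a, -1):
                    buf[k] = buf[k - 1]
                buf[a] = v
                m += 1
                r += 1
            while l < nl:
                v = x[l]
                a, b = 0, m
                while a < b:
                    mid = (a + b) // 2
                    if buf[mid] < v:
                        a = mid + 1
                    else:
                        b = mid
                for k in range(a, m - 1):
                    buf[k] = buf[k + 1]
                m -= 1
                l += 1
            rank = q * (m - 1)
            k = int(rank)
            frac = rank - k
            if k + 1 < m:
                out[i] = buf[k] + frac * (buf[k + 1] - buf[k])
            else:
                out[i] = buf[k]
        return out


def detrend_percentile(raw, frame_rate_hz, window_s=20.0, percentile=8.0):
    """Subtract the rolling ``percentile`` of a centered ``window_s`` window.

    The window shrinks symmetrically at the trace edges rather than padding,
    so no frames are discarded. Percentiles use linear interpolation between
    order statistics (the numpy convention).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("empty trace")
    half = int(round(window_s * frame_rate_hz / 2))
    n = raw.size
    if n <= 2 * half + 1:
        return raw - np.percentile(raw, percentile)
    q = percentile / 100.0
    if _njit is not None:
        baseline = _rolling_percentile_nb(raw, half, q)
    else:
        baseline = _rolling_percentile_py(raw, half, q)
    return raw - baseline


def estimate_baseline(trace, clip_sigma=2.3, two_sided=False):
    """Baseline mean/s.d. from points not exceeding ``clip_sigma`` total-s.d.

    One-sided by default: only points above mean + clip_sigma * s.d. are
    excluded, because calcium transients are positive-going.
    """
    trace = np.asarray(trace, dtype=float)
    mu, sd = trace.mean(), trace.std()
    if sd == 0:
        raise ValueError("degenerate trace: zero variance")
    if two_sided:
        keep = np.abs(trace - mu) <= clip_sigma * sd
    else:
        keep = trace <= mu + clip_sigma * sd
    return float(trace[keep].mean()), float(trace[keep].std())


def _count_events(dff, onset_sigma, min_duration, offset_sigma=OFFSET_SIGMA):
    """Segments where dff >= onset for >= min_duration frames.

    An event's support starts at the onset crossing and extends forward
    until dff falls below ``offset_sigma``; overlapping supports merge.
    Returns (count, support mask).
    """
    n = dff.size
    above = dff >= onset_sigma
    if not above.any():
        return 0, np.zeros(n, dtype=bool)
    # run starts/ends of the supra-onset regions
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    run_ends = np.concatenate((idx[breaks], [idx[-1]]))  # inclusive
    keep = (run_ends - run_starts + 1) >= min_duration
    if not keep.any():
        return 0, np.zeros(n, dtype=bool)
    run_starts, run_ends = run_starts[keep], run_ends[keep]
    # forward extension of each event to the next sub-offset frame
    off_idx = np.flatnonzero(dff < offset_sigma)
    pos = np.searchsorted(off_idx, run_ends + 1)
    stops = np.where(pos < off_idx.size,
                     off_idx[np.minimum(pos, off_idx.size - 1)], n)
    mask = np.zeros(n, dtype=bool)
    count = 0
    last_stop = 0
    for s, stop in zip(run_starts, stops):
        mask[s:stop] = True
        if s >= last_stop:      # not merged with the previous event
            count += 1
        last_stop = max(last_stop, stop)
    return count, mask


def select_transient_thresholds(dff, onset_grid=ONSET_GRID,
                                duration_grid=DURATION_GRID,
                                fpr_limit=FPR_LIMIT):
    """Choose the least-stringent (onset, duration) pair with FPR < 5%.

    The FPR of a threshold pair is the ratio of negative-oriented events
    (detected on -dff) to positive-oriented events; zero positives give
    ratio 0. Pairs are scanned in order of increasing stringency (onset
    ascending, then duration ascending) and the first admissible pair is
    accepted. If none qualifies, the most stringent pair is used and the
    cell is flagged.
    """
    for onset in onset_grid:
        for dur in duration_grid:
            n_pos, _ = _count_events(dff, onset, dur)
            n_neg, _ = _count_events(-dff, onset, dur)
            ratio = 0.0 if n_pos == 0 else n_neg / n_pos
            if ratio < fpr_limit:
                return float(onset), int(dur), float(ratio), False
    onset, dur = onset_grid[-1], duration_grid[-1]
    n_pos, _ = _count_events(dff, onset, dur)
    n_neg, _ = _count_events(-dff, onset, dur)
    ratio = 0.0 if n_pos == 0 else n_neg / n_pos
    log.warning("no threshold pair reached FPR < %.2f; using most stringent",
                fpr_limit)
    return float(onset), int(dur), float(ratio), True


def extract_transients(dff, onset_sigma, min_duration_frames):
    """Transient mask, count and masked ΔF/F at the accepted thresholds."""
    count, mask = _count_events(dff, onset_sigma, min_duration_frames)
    masked = np.where(mask, dff, 0.0)
    return mask, count, masked


def activity_rate(masked_dff, included_frames, frame_rate_hz):
    """Time-averaged transient-masked ΔF/F over included frames (ΔF/F s^-1).

    Interpreted as the mean of the masked trace per second of included
    time; an alternative transient-integral rate gives the same number
    because masked frames outside transients are zero.
    """
    included = np.asarray(included_frames, dtype=bool)
    if included.sum() == 0:
        raise ValueError("no included frames")
    return float(np.mean(masked_dff[included]))


def is_active(transient_count, duration_min):
    """Active cell: strictly more than one transient per minute."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    return transient_count / duration_min > 1.0


class TransientExtractor(BaseEstimator, TransformerMixin):
    """Convert raw traces into transient-masked ΔF/F (baseline-s.d. units).

    Scikit-learn style transformer over an ``(n_frames, n_cells)`` matrix.
    ``fit`` runs drift correction, baseline estimation and per-cell
    threshold selection; ``transform`` returns the masked ΔF/F matrix.
    Fitted attributes follow sklearn conventions (trailing underscore).

    Parameters
    ----------
    frame_rate_hz : acquisition rate of the traces.
    window_s, percentile : rolling-percentile drift correction.
    clip_sigma : total-s.d. clip for the initial baseline estimate.
    onset_grid, duration_grid : detection-threshold search grids.
    fpr_limit : admissible negative/positive event ratio (< 0.05).
    """

    def __init__(self, frame_rate_hz=15.5, window_s=20.0, percentile=8.0,
                 clip_sigma=2.3, two_sided_clip=False,
                 onset_grid=ONSET_GRID, duration_grid=DURATION_GRID,
                 fpr_limit=FPR_LIMIT, offset_sigma=OFFSET_SIGMA):
        self.frame_rate_hz = frame_rate_hz
        self.window_s = window_s
        self.percentile = percentile
        self.clip_sigma = clip_sigma
        self.two_sided_clip = two_sided_clip
        self.onset_grid = onset_grid
        self.duration_grid = duration_grid
        self.fpr_limit = fpr_limit
        self.offset_sigma = offset_sigma

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_frames, n_cells)")
        n_frames, n_cells = X.shape
        self.traces_ = []
        for j in range(n_cells):
            self.traces_.append(self._process_one(X[:, j]))
        self.n_features_in_ = n_cells
        self.baseline_mean_ = np.array([t.baseline_mean for t in self.traces_])
        self.baseline_sd_ = np.array([t.baseline_sd for t in self.traces_])
        self.onset_sigma_ = np.array([t.onset_sigma for t in self.traces_])
        self.min_duration_ = np.array([t.min_duration_frames
                                       for t in self.traces_])
        self.fpr_ = np.array([t.fpr_estimate for t in self.traces_])
        self.flagged_ = np.array([t.flagged for t in self.traces_])
        self.transient_count_ = np.array([t.transient_count
                                          for t in self.traces_])
        self.masked_dff_ = np.column_stack([t.masked_dff
                                            for t in self.traces_])
        return self

    def transform(self, X):
        """Masked ΔF/F of ``X``, shape (n_frames, n_cells).

        Thresholds are selected per trace from the trace itself, so
        transforming new data reruns the full per-cell procedure.
        """
        if not hasattr(self, "traces_"):
            raise RuntimeError("TransientExtractor is not fitted")
        X = np.asarray(X, dtype=float)
        if X is not None and X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different number of cells than fitted")
        return np.column_stack([self._process_one(X[:, j]).masked_dff
                                for j in range(X.shape[1])])

    def fit_transform(self, X, y=None):
        return self.fit(X).masked_dff_

    def _process_one(self, raw):
        detrended = detrend_percentile(raw, self.frame_rate_hz,
                                       self.window_s, self.percentile)
        try:
            mu0, sd0 = estimate_baseline(detrended, self.clip_sigma,
                                         self.two_sided_clip)
        except ValueError as exc:
            z = np.zeros_like(detrended)
            return ProcessedTrace(z, z.astype(bool), z, 0.0, 0.0,
                                  self.onset_grid[-1], self.duration_grid[-1],
                                  0.0, 0, flagged=True, flag_reason=str(exc))
        if sd0 <= 0:
            z = np.zeros_like(detrended)
            return ProcessedTrace(z, z.astype(bool), z, mu0, 0.0,
                                  self.onset_grid[-1], self.duration_grid[-1],
                                  0.0, 0, flagged=True,
                                  flag_reason="zero baseline s.d.")
        dff0 = (detrended - mu0) / sd0
        onset, dur, fpr, fallback = select_transient_thresholds(
            dff0, self.onset_grid, self.duration_grid, self.fpr_limit)
        _, _, masked0 = extract_transients(dff0, onset, dur)
        # definitive baseline from non-transient frames, then re-extract
        mask0 = masked0 != 0.0
        quiet = detrended[~mask0]
        if quiet.size >= 2 and quiet.std() > 0:
            mu, sd = float(quiet.mean()), float(quiet.std())
        else:
            mu, sd = mu0, sd0
        dff = (detrended - mu) / sd
        mask, count, masked = extract_transients(dff, onset, dur)
        return ProcessedTrace(dff, mask, masked, mu, sd, onset, dur, fpr,
                              count, flagged=fallback,
                              flag_reason="fpr fallback" if fallback else "")


def preprocess_session(session, speed_threshold_cm_s=SPEED_THRESHOLD_CM_S,
                       active_on_running_time=True, **extractor_kwargs):
    """Run the full preprocessing stage on a :class:`SessionRecording`.

    Returns ``(extractor, included_frames, active)`` where ``active`` marks
    cells with more than one transient per minute of included time.
    """
    extractor_kwargs.setdefault("frame_rate_hz", session.frame_rate_hz)
    ext = TransientExtractor(**extractor_kwargs)
    ext.fit(session.fluorescence.T)
    included = run_mask(session.behavior, speed_threshold_cm_s)
    if active_on_running_time:
        minutes = included.sum() / session.frame_rate_hz / 60.0
        counts = np.array([_transients_in(t, included) for t in ext.traces_])
    else:
        minutes = session.fluorescence.shape[1] / session.frame_rate_hz / 60.0
        counts = ext.transient_count_
    active = np.array([is_active(c, minutes) if minutes > 0 else False
                       for c in counts])
    active &= ~ext.flagged_
    return ext, included, active


def _transients_in(trace, included):
    """Number of detected transients whose onset lies in included frames."""
    mask = trace.transient_mask
    onsets = np.flatnonzero(mask & ~np.concatenate(([False], mask[:-1])))
    return int(np.sum(included[onsets]))
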