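"""Spatial tuning: activity maps, spatial information, place fields.

Activity maps are per-cell mean transient-masked ΔF/F over the 80 5-cm
bins of the track, restricted to running frames. Spatial information is
the Skaggs-type statistic

    SI = sum_i p_i * lambda_i * log2(lambda_i / lambda_bar)

in bits s^-1, where lambda_i is the mean calcium activity and p_i the
occupancy fraction of bin i, and lambda_bar = sum_i p_i lambda_i. Its
significance comes from a position-shuffle null (default: circular time
shift of at least 10 s, preserving trace autocorrelation).

Place fields are contiguous bin spans of the 3-point-smoothed map in which
every bin exceeds 25% of the span between the map baseline (mean of the
lowest 20 bins) and the map peak, and which additionally satisfy: width of
at least 3 bins (15 cm); in-field mean at least seven times the out-field
mean; and significant transients present in at least 20% of the in-field
moving time. Accepted fields must also survive a bootstrap in which the
trace is cut into 50-frame segments and segment-shuffled 1000 times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActivityMap", "PlaceField", "SpatialTuningResult", "bin_activity",
    "smooth_map", "spatial_information", "si_shuffle_test",
    "detect_place_fields", "bootstrap_field_significance", "per_run_maps",
]

PRESENCE_MIN = 0.2
INOUT_RATIO_MIN = 7.0
WIDTH_MIN_BINS = 3
CONTIGUITY_FRACTION = 0.25
BASELINE_LOWEST_BINS = 20


@dataclass
class ActivityMap:
    """Mean masked ΔF/F per spatial bin with occupancy fractions."""

    lambda_i: np.ndarray        # NaN for unvisited bins
    p_i: np.ndarray             # occupancy fraction, sums to 1 over visited
    context_id: int | None = None
    smoothed: bool = False

    @property
    def lambda_bar(self):
        lam = np.where(np.isnan(self.lambda_i), 0.0, self.lambda_i)
        return float(np.sum(self.p_i * lam))

    @property
    def n_bins(self):
        return self.lambda_i.size


@dataclass
class SpatialTuningResult:
    si_bits_per_s: float
    shuffle_p: float
    is_significant: bool
    n_shuffles: int


@dataclass
class PlaceField:
    """An accepted (or candidate) place field of one cell in one context."""

    cell_id: int | None
    context_id: int | None
    bin_span: tuple               # inclusive (start, end)
    infield_mean: float
    outfield_mean: float
    presence_fraction: float
    bootstrap_p: float | None = None

    @property
    def width_bins(self):
        return self.bin_span[1] - self.bin_span[0] + 1

    def width_cm(self, bin_cm=5.0):
        return self.width_bins * bin_cm


def _bin_stats(values, bin_idx, n_bins):
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    sums = np.bincount(bin_idx, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    return means, counts


def bin_activity(masked_dff, position_cm, included_frames, track,
                 context_id=None):
    """Per-bin mean masked ΔF/F and occupancy over included frames."""
    included = np.asarray(included_frames, dtype=bool)
    if included.sum() == 0:
        raise ValueError("no included frames")
    pos = np.asarray(position_cm, dtype=float)[included]
    vals = np.asarray(masked_dff, dtype=float)[included]
    if np.any((pos < 0) | (pos >= track.length_cm + track.bin_cm)):
        raise ValueError("positions outside the track")
    bin_idx = track.bin_of(pos)
    means, counts = _bin_stats(vals, bin_idx, track.n_bins)
    p = counts / counts.sum()
    return ActivityMap(lambda_i=means, p_i=p, context_id=context_id)


def smooth_map(m):
    """3-point boxcar smoothing; edges average the available 2 neighbors.

    Unvisited (NaN) bins are ignored in each window; a window with no
    visited bin stays NaN. Accepts an :class:`ActivityMap` or array.
    """
    arr = m.lambda_i if isinstance(m, ActivityMap) else np.asarray(m, float)
    if arr.size < 3:
        raise ValueError("map must have at least 3 bins")
    out = _smooth3(arr)
    if isinstance(m, ActivityMap):
        return ActivityMap(lambda_i=out, p_i=m.p_i.copy(),
                           context_id=m.context_id, smoothed=True)
    return out


def _smooth3(arr):
    n = arr.size
    valid = np.isfinite(arr)
    vals = np.where(valid, arr, 0.0)
    ker = np.ones(3)
    sums = np.convolve(vals, ker, mode="same")
    cnts = np.convolve(valid.astype(float), ker, mode="same")
    with np.errstate(invalid="ignore"):
        out = sums / cnts
    out[cnts == 0] = np.nan
    return out


def spatial_information(m, p_i=None):
    """Skaggs SI in bits s^-1; zero-activity bins contribute 0 by the
    x*log(x) -> 0 limit convention, and an all-zero map has SI 0."""
    if isinstance(m, ActivityMap):
        lam, p = m.lambda_i, m.p_i
    else:
        lam, p = np.asarray(m, float), np.asarray(p_i, float)
    lam = np.where(np.isnan(lam), 0.0, lam)
    if np.any(lam < 0):
        raise ValueError("negative activity in map")
    lam_bar = float(np.sum(p * lam))
    if lam_bar == 0:
        return 0.0
    pos = lam > 0
    return float(np.sum(p[pos] * lam[pos] * np.log2(lam[pos] / lam_bar)))


def si_shuffle_test(masked_dff, position_cm, included_frames, track,
                    frame_rate_hz=15.5, n_shuffles=1000, min_shift_s=10.0,
                    style="circular", seed=0, rng=None):
    """Shuffle test for spatial information.

    Each shuffle displaces the activity relative to the position by a
    circular time shift of at least ``min_shift_s`` applied on the *full
    session timeline* (so that activity clumps keep their alignment with
    the run/pause structure), then recomputes SI over the included
    frames; ``style='permute'`` (and the fallback for traces shorter than
    two minimum shifts) instead permutes included frames, which destroys
    trace autocorrelation and is anticonservative for clumped activity.
    ``shuffle_p`` is the fraction of shuffles with SI strictly greater
    than observed; a cell whose observed SI is 0 (no measurable spatial
    modulation, e.g. constant position or silent trace) is assigned p = 1.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    included = np.asarray(included_frames, dtype=bool)
    full_vals = np.asarray(masked_dff, float)
    n_full = full_vals.size
    bin_idx = track.bin_of(np.asarray(position_cm, float)[included])
    counts = np.bincount(bin_idx, minlength=track.n_bins).astype(float)
    p = counts / counts.sum()

    def si_of(vals):
        sums = np.bincount(bin_idx, weights=vals, minlength=track.n_bins)
        with np.errstate(invalid="ignore"):
            lam = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        return spatial_information(lam, p)

    observed = si_of(full_vals[included])
    if observed <= 0:
        return SpatialTuningResult(observed, 1.0, False, n_shuffles)
    min_shift = int(round(min_shift_s * frame_rate_hz))
    if style == "circular" and n_full > 2 * min_shift:
        shifts = rng.integers(min_shift, n_full - min_shift, size=n_shuffles)
        shuffled = (si_of(np.roll(full_vals, int(k))[included])
                    for k in shifts)
    else:
        sel_vals = full_vals[included]
        shuffled = (si_of(rng.permutation(sel_vals))
                    for _ in range(n_shuffles))
    higher = sum(s > observed for s in shuffled)
    p_val = higher / n_shuffles
    return SpatialTuningResult(observed, p_val, p_val < 0.05, n_shuffles)


# ---------------------------------------------------------------------------
# place fields
# ---------------------------------------------------------------------------

def _candidate_spans(smoothed, lowest_bins=BASELINE_LOWEST_BINS,
                     fraction=CONTIGUITY_FRACTION):
    """Contiguous runs where every bin exceeds baseline + fraction*(max-baseline)."""
    vals = np.where(np.isfinite(smoothed), smoothed, -np.inf)
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        return [], 0.0
    k = min(lowest_bins, finite.size)
    baseline = np.sort(finite)[:k].mean()
    peak = finite.max()
    if peak <= baseline:
        return [], baseline
    thr = baseline + fraction * (peak - baseline)
    above = vals > thr
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return [], baseline
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist())), baseline


def detect_place_fields(smoothed_map, transient_mask, position_cm,
                        included_frames, track, cell_id=None,
                        context_id=None, presence_min=PRESENCE_MIN,
                        inout_ratio_min=INOUT_RATIO_MIN,
                        width_min_bins=WIDTH_MIN_BINS):
    """Apply the five place-field criteria to a smoothed activity map.

    Out-field mean excludes the bins of *all* candidate spans of the cell,
    so a second candidate does not inflate its neighbor's out-field level.
    Multiple fields per cell are permitted. Presence is the fraction of
    in-field moving time carrying significant transients.
    """
    smoothed = (smoothed_map.lambda_i if isinstance(smoothed_map, ActivityMap)
                else np.asarray(smoothed_map, float))
    spans, _ = _candidate_spans(smoothed)
    if not spans:
        return []
    in_any = np.zeros(smoothed.size, dtype=bool)
    for s, e in spans:
        in_any[s:e + 1] = True
    finite = np.isfinite(smoothed)
    out_vals = smoothed[~in_any & finite]
    outfield_mean = float(out_vals.mean()) if out_vals.size else 0.0

    included = np.asarray(included_frames, dtype=bool)
    pos = np.nan_to_num(np.asarray(position_cm, float))  # NaN frames excluded
    bin_idx = track.bin_of(pos)
    tmask = np.asarray(transient_mask, dtype=bool)

    fields = []
    for s, e in spans:
        width = e - s + 1
        if width < width_min_bins:
            continue
        infield_mean = float(np.nanmean(smoothed[s:e + 1]))
        if outfield_mean > 0 and infield_mean < inout_ratio_min * outfield_mean:
            continue
        if outfield_mean <= 0 and infield_mean <= 0:
            continue
        in_field_frames = included & (bin_idx >= s) & (bin_idx <= e)
        n_in = in_field_frames.sum()
        if n_in == 0:
            continue
        presence = float(tmask[in_field_frames].mean())
        if presence < presence_min:
            continue
        fields.append(PlaceField(cell_id=cell_id, context_id=context_id,
                                 bin_span=(int(s), int(e)),
                                 infield_mean=infield_mean,
                                 outfield_mean=outfield_mean,
                                 presence_fraction=presence))
    return fields


def _segment_permute(n_frames, segment_frames, rng):
    n_seg = int(np.ceil(n_frames / segment_frames))
    order = rng.permutation(n_seg)
    idx = np.arange(n_frames)
    segments = [idx[k * segment_frames:(k + 1) * segment_frames]
                for k in range(n_seg)]
    return np.concatenate([segments[k] for k in order])


def bootstrap_field_significance(masked_dff, transient_mask, position_cm,
                                 included_frames, track, n_shuffles=1000,
                                 segment_frames=50, seed=0, rng=None,
                                 **detect_kwargs):
    """Segment-shuffle bootstrap P for a cell's place field(s).

    The masked ΔF/F trace (and its transient mask) is broken into segments
    of ``segment_frames`` consecutive frames, segment-shuffled, and the
    full field-detection procedure is rerun; P is the fraction of shuffles
    yielding at least one accepted field. Fields are kept when P < 0.05.
    """
    masked_dff = np.asarray(masked_dff, float)
    n = masked_dff.size
    if n < 2 * segment_frames:
        raise ValueError("trace too short for segment bootstrap")
    rng = rng if rng is not None else np.random.default_rng(seed)
    included = np.asarray(included_frames, dtype=bool)
    tmask = np.asarray(transient_mask, dtype=bool)
    hits = 0
    for _ in range(n_shuffles):
        perm = _segment_permute(n, segment_frames, rng)
        shuf_vals = masked_dff[perm]
        shuf_mask = tmask[perm]
        m = bin_activity(shuf_vals, position_cm, included, track)
        sm = smooth_map(m)
        if detect_place_fields(sm, shuf_mask, position_cm, included, track,
                               **detect_kwargs):
            hits += 1
    return hits / n_shuffles


def per_run_maps(masked_dff, behavior, included_frames, context,
                 smoothing=False):
    """Per-run activity maps (n_runs, n_bins) for one cell and context.

    Bins a run never visited while running are NaN. Runs are returned in
    temporal order of their run ids.
    """
    track = behavior.track
    included = np.asarray(included_frames, dtype=bool)
    sel_ctx = behavior.context_id == context
    run_ids = np.unique(behavior.run_id[sel_ctx & (behavior.run_id >= 0)])
    maps = np.full((run_ids.size, track.n_bins), np.nan)
    vals = np.asarray(masked_dff, float)
    for r, rid in enumerate(run_ids):
        sel = included & (behavior.run_id == rid)
        if not sel.any():
            continue
        bin_idx = track.bin_of(behavior.position_cm[sel])
        means, counts = _bin_stats(vals[sel], bin_idx, track.n_bins)
        maps[r] = np.where(counts > 0, means, np.nan)
        if smoothing:
            maps[r] = _smooth3(maps[r])
    return maps, run_ids
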