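"""Context discrimination, stability, remapping and behavior metrics.

These quantify how a cell's (or population's) spatial code differs between
a familiar and a novel context and how stable it is within and across
days: run-to-run reliability (mean pairwise Pearson correlation of
per-run maps), session consistency (first vs last block of five runs),
cross-context map correlation with its three-way remapping classification
(low r <= 0.1 = global remapping, 0.1 < r < 0.6 = medium, r >= 0.6 = high
generalization), day-to-day map-correlation matrices conditioned on
place-cell status, and the behavioral controls (running speed excluding
rest, reward-zone lick-rate ratio).
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .track import FAMILIAR, NOVEL

__all__ = [
    "discrimination_score", "activity_difference", "run_reliability",
    "session_consistency", "map_correlation", "remap_classify",
    "remap_fraction_estimate", "cross_day_matrix", "field_statistics",
    "lick_ratio", "mean_running_speed", "REMAP_LOW_MAX", "REMAP_HIGH_MIN",
]

REMAP_LOW_MAX = 0.1     # r <= 0.1 -> low (global remapping)
REMAP_HIGH_MIN = 0.6    # r >= 0.6 -> high (generalization)


def activity_difference(act_fam, act_nov):
    """Dataset-level activity-difference score: activity(Fam) - activity(Nov)."""
    return act_fam - act_nov


def discrimination_score(act_fam, act_nov):
    """Place-cell context discrimination: |fam - nov| / (fam + nov) in [0, 1].

    1 means activity confined to one context, 0 means equal rates.
    """
    if act_fam < 0 or act_nov < 0:
        raise ValueError("activity rates must be non-negative")
    total = act_fam + act_nov
    if total == 0:
        raise ValueError("both activity rates are zero; score undefined")
    return abs(act_fam - act_nov) / total


def _pearson(a, b):
    """Pearson r of two equal-length maps, ignoring bins NaN in either.

    Returns NaN when fewer than 3 shared bins or either side is
    zero-variance (degenerate).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return math.nan
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


def map_correlation(map_a, map_b):
    """Pearson correlation between two per-bin activity maps."""
    return _pearson(map_a, map_b)


def run_reliability(run_maps):
    """Trial-to-trial reliability: mean pairwise Pearson r over all runs.

    ``run_maps`` is (n_runs, n_bins); degenerate (zero-variance or
    unvisited) runs are excluded pairwise. NaN when fewer than two valid
    runs or no valid pair.
    """
    run_maps = np.asarray(run_maps, float)
    if run_maps.ndim != 2 or run_maps.shape[0] < 2:
        return math.nan
    rs = [_pearson(run_maps[i], run_maps[j])
          for i, j in itertools.combinations(range(run_maps.shape[0]), 2)]
    rs = [r for r in rs if not math.isnan(r)]
    return float(np.mean(rs)) if rs else math.nan


def session_consistency(first_block_maps, last_block_maps):
    """Correlation of the mean map of the first and last block of 5 runs."""
    a = np.nanmean(np.asarray(first_block_maps, float), axis=0)
    b = np.nanmean(np.asarray(last_block_maps, float), axis=0)
    return _pearson(a, b)


def remap_classify(r):
    """Three-way remapping class from a cross-context map correlation."""
    if not (-1.0 - 1e-9 <= r <= 1.0 + 1e-9):
        raise ValueError("correlation must lie in [-1, 1]")
    if r <= REMAP_LOW_MAX:
        return "low"
    if r >= REMAP_HIGH_MIN:
        return "high"
    return "medium"


def remap_fraction_estimate(fam_maps, nov_maps, threshold=REMAP_LOW_MAX,
                            n_null_pairs=5, seed=0):
    """Chance-corrected estimate of the globally-remapping cell fraction.

    The naive fraction of cells with cross-context r <= ``threshold``
    understates the true remapping fraction, because an independently
    relocated field lands near its old position by chance in a sizeable
    fraction of cells (~20% on an 80-bin track with typical field widths),
    in which case the maps still correlate. This estimator calibrates
    that leakage from the data: pairing each cell's familiar map with
    novel maps of *other* cells realizes the independent-field null, and

        f_hat = P(r <= threshold, observed) / P(r <= threshold, null).

    Valid when well-expressed stable maps essentially never fall below
    the threshold (the regime for cells with detected fields in both
    contexts). Returns (f_hat, observed_low_fraction, null_low_fraction).
    """
    fam_maps = np.asarray(fam_maps, float)
    nov_maps = np.asarray(nov_maps, float)
    n = fam_maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cells to calibrate the null")
    rs = np.array([_pearson(fam_maps[i], nov_maps[i]) for i in range(n)])
    rs = rs[np.isfinite(rs)]
    if rs.size == 0:
        raise ValueError("no finite cross-context correlations")
    obs_low = float(np.mean(rs <= threshold))
    rng = np.random.default_rng(seed)
    null = []
    for i in range(n):
        others = np.delete(np.arange(n), i)
        for j in rng.choice(others, size=min(n_null_pairs, n - 1),
                            replace=False):
            r = _pearson(fam_maps[i], nov_maps[j])
            if not math.isnan(r):
                null.append(r)
    null_low = float(np.mean(np.asarray(null) <= threshold))
    if null_low == 0:
        raise ValueError("degenerate null: no low-correlation pairs")
    return min(obs_low / null_low, 1.0), obs_low, null_low


def cross_day_matrix(daily_maps, place_by_day):
    """Median cross-day map-correlation matrix conditioned on place cells.

    ``daily_maps`` is (n_days, n_cells, n_bins) for one context;
    ``place_by_day`` is (n_days, n_cells) bool. Entry (d, e) is the median,
    over cells with an accepted field on day d, of corr(map_d, map_e);
    the diagonal is reported as 1 and is excluded from summaries. A day
    without place cells yields a NaN row.
    """
    daily_maps = np.asarray(daily_maps, float)
    place_by_day = np.asarray(place_by_day, bool)
    n_days = daily_maps.shape[0]
    out = np.full((n_days, n_days), np.nan)
    for d in range(n_days):
        cells = np.nonzero(place_by_day[d])[0]
        for e in range(n_days):
            if d == e:
                out[d, e] = 1.0
                continue
            rs = [_pearson(daily_maps[d, c], daily_maps[e, c]) for c in cells]
            rs = [r for r in rs if not math.isnan(r)]
            if rs:
                out[d, e] = float(np.median(rs))
    return out


def field_statistics(fields_by_cell, bin_cm=5.0):
    """Per-cell field count and mean width (cm) from accepted fields."""
    stats = {}
    for cell_id, fields in fields_by_cell.items():
        widths = [f.width_cm(bin_cm) for f in fields]
        stats[cell_id] = {
            "n_fields": len(fields),
            "mean_width_cm": float(np.mean(widths)) if widths else math.nan,
        }
    return stats


def lick_ratio(lick_events, position_cm, behavior_context, context, track):
    """In-zone / out-zone lick-rate ratio for one context.

    Rates are occupancy-normalized (licks per second of time spent inside
    vs outside the reward zones, the 5 bins around each reward center).
    Returns ``inf`` when all licking is confined to the zones.
    """
    sel = (np.asarray(behavior_context) == context) \
        & np.isfinite(np.asarray(position_cm, float))
    if sel.sum() == 0:
        raise ValueError("no frames in requested context")
    pos = np.asarray(position_cm, float)[sel]
    licks = np.asarray(lick_events, bool)[sel]
    zone = track.reward_zone_mask(context)[track.bin_of(pos)]
    t_in, t_out = zone.sum(), (~zone).sum()
    if t_in == 0 or t_out == 0:
        raise ValueError("degenerate reward-zone occupancy")
    rate_in = licks[zone].sum() / t_in
    rate_out = licks[~zone].sum() / t_out
    if rate_out == 0:
        return math.inf
    return float(rate_in / rate_out)


def mean_running_speed(speed_cm_s, included_frames):
    """Mean speed over running (included) frames, excluding rest."""
    included = np.asarray(included_frames, bool)
    if included.sum() == 0:
        raise ValueError("no included frames")
    return float(np.asarray(speed_cm_s, float)[included].mean())
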