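"""Population-vector decoding of position and context.

Each session's runs are split into two interleaved halves: template runs,
from which a per-cell mean activity is computed for each 5-cm bin of the
familiar and novel tracks (a cells x 160 template matrix; or, in
``mean_rate`` mode, a cells x 2 matrix of whole-track mean rates), and
test runs, whose population activity is resampled into 100-ms bins. Each
test population vector is Pearson-correlated with every template column;
the decoded (context, position) is the column with the highest
correlation. Context error per time bin is 0/1; spatial error is the
absolute distance (cm) between decoded and true position, irrespective of
the decoded context.

Cumulative context accuracy aggregates the per-bin context decisions over
non-overlapping segments of growing length Δt (majority vote; ties count
as incorrect), averaged over 25 random 50-cell ensembles; the time to 90%
accuracy is the first Δt whose mean accuracy exceeds 0.9.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .preprocess import run_mask
from .track import FAMILIAR, NOVEL

log = logging.getLogger(__name__)

__all__ = [
    "PopulationVectorDecoder", "DecodingResult", "CumulativeAccuracy",
    "split_runs", "build_template", "decode_timebins", "decode_session",
    "error_vs_ensemble_size", "cumulative_context_accuracy",
    "template_mode_ratio", "per_context_errors", "timebin_population",
]

DEFAULT_DELTA_T_GRID = (0.1, 0.2, 0.5, 1, 2, 5, 10, 15, 20, 30, 45, 60, 90, 120)


class PopulationVectorDecoder(BaseEstimator, ClassifierMixin):
    """Correlation-template decoder (nearest centroid under Pearson r).

    ``fit(X, y)`` averages the population vectors of each label into a
    template column; ``predict(X)`` returns, for each row, the label of
    the template column with the highest Pearson correlation. Labels
    encode (context, spatial bin) in spatial mode or context alone in
    mean-rate mode. Ties are broken toward the lowest label; rows with
    zero variance are undecodable and predicted as -1 (callers skip them).
    """

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_cells) matching y")
        self.classes_ = np.unique(y)
        self.template_ = np.column_stack(
            [X[y == c].mean(axis=0) for c in self.classes_])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        """Pearson correlation of each row with each template column."""
        X = np.asarray(X, dtype=float)
        T = self.template_
        n = X.shape[1]
        Xc = X - X.mean(axis=1, keepdims=True)
        xs = Xc.std(axis=1)
        Tc = T - T.mean(axis=0, keepdims=True)
        ts = Tc.std(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (Xc @ Tc) / n / np.outer(xs, ts)
        corr[:, ts == 0] = -np.inf
        corr[xs == 0, :] = -np.inf
        return corr

    def predict(self, X):
        corr = self.decision_function(X)
        out = self.classes_[np.argmax(corr, axis=1)]
        out = np.asarray(out)
        undecodable = ~np.isfinite(corr).any(axis=1) \
            | np.all(corr == -np.inf, axis=1)
        out = out.astype(float)
        out[undecodable] = -1
        return out.astype(int)


@dataclass
class DecodingResult:
    """Per-100-ms-bin decode of one ensemble on the test runs."""

    times_s: np.ndarray
    true_context: np.ndarray
    true_position_cm: np.ndarray
    decoded_context: np.ndarray
    decoded_bin: np.ndarray
    context_error: np.ndarray       # 0/1 per bin
    spatial_error_cm: np.ndarray
    ensemble: np.ndarray
    n_skipped: int = 0

    @property
    def mean_context_error(self):
        return float(self.context_error.mean())

    @property
    def mean_spatial_error_cm(self):
        return float(self.spatial_error_cm.mean())


@dataclass
class CumulativeAccuracy:
    delta_t_s: np.ndarray
    accuracy: np.ndarray            # mean over ensembles, per delta_t
    per_ensemble: np.ndarray        # (n_ensembles, n_delta_t)
    time_to_90_s: float             # NaN when not reached

    @property
    def reached_90(self):
        return not math.isnan(self.time_to_90_s)


def split_runs(behavior, parity=0):
    """Interleaved template/test halves of the session's runs, per context.

    Within each context, runs in temporal order alternate template, test,
    template, ... (``parity=1`` swaps the two roles). 15 runs per context
    give 8 template and 7 test runs.
    """
    template, test = [], []
    for ctx in (FAMILIAR, NOVEL):
        sel = (behavior.context_id == ctx) & (behavior.run_id >= 0)
        runs = np.unique(behavior.run_id[sel])
        if runs.size < 2:
            raise ValueError("need at least two runs per context to split")
        for k, rid in enumerate(runs):
            (template if k % 2 == parity else test).append(int(rid))
    return sorted(template), sorted(test)


def build_template(masked_dff, behavior, included_frames, template_runs,
                   mode="spatial"):
    """Template matrix and its column labels from the template runs.

    Spatial mode: (n_cells, 2*n_bins) per-bin mean masked ΔF/F, familiar
    bins first; column label = context * n_bins + bin. Mean-rate mode:
    (n_cells, 2) whole-track mean rates, label = context.
    """
    X, y = _template_samples(masked_dff, behavior, included_frames,
                             template_runs, mode)
    dec = PopulationVectorDecoder().fit(X, y)
    n_bins = behavior.track.n_bins
    n_cols = 2 * n_bins if mode == "spatial" else 2
    template = np.zeros((masked_dff.shape[0], n_cols))
    template[:, dec.classes_] = dec.template_
    missing = np.setdiff1d(np.arange(n_cols), dec.classes_)
    if missing.size:
        log.info("%d template columns unvisited in template runs",
                 missing.size)
    return dec, template


def _template_samples(masked_dff, behavior, included_frames, run_ids, mode):
    included = np.asarray(included_frames, bool)
    sel = included & np.isin(behavior.run_id, run_ids)
    if not sel.any():
        raise ValueError("no included frames in template runs")
    X = masked_dff[:, sel].T
    ctx = behavior.context_id[sel]
    if mode == "spatial":
        bins = behavior.track.bin_of(behavior.position_cm[sel])
        y = ctx * behavior.track.n_bins + bins
    elif mode == "mean_rate":
        y = ctx
    else:
        raise ValueError(f"unknown template mode: {mode!r}")
    return X, y


def timebin_population(masked_dff, behavior, included_frames, run_ids,
                       bin_ms=100):
    """Resample test-run activity into 100-ms population vectors.

    Frames are assigned by timestamp to half-open ``bin_ms`` windows;
    frames of a window are averaged. Returns (X, true_context,
    true_position_cm, window_times_s).
    """
    included = np.asarray(included_frames, bool)
    sel = included & np.isin(behavior.run_id, run_ids)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise ValueError("no included frames in test runs")
    t = behavior.times_s[idx]
    win = np.floor(t / (bin_ms / 1000.0)).astype(np.int64)
    uniq, inverse, counts = np.unique(win, return_inverse=True,
                                      return_counts=True)
    n_cells = masked_dff.shape[0]
    X = np.zeros((uniq.size, n_cells))
    for j in range(n_cells):
        X[:, j] = np.bincount(inverse, weights=masked_dff[j, idx]) / counts
    pos = np.bincount(inverse, weights=behavior.position_cm[idx]) / counts
    # windows never straddle contexts (runs are separated by blank gaps)
    ctx = np.zeros(uniq.size, dtype=int)
    ctx[inverse] = behavior.context_id[idx]
    times = uniq * (bin_ms / 1000.0)
    return X, ctx, pos, times


def decode_timebins(masked_dff, behavior, included_frames, template_runs,
                    test_runs, ensemble, mode="spatial", bin_ms=100):
    """Decode every 100-ms test bin with one cell ensemble."""
    ensemble = np.asarray(ensemble, dtype=int)
    if ensemble.size == 0:
        raise ValueError("empty ensemble")
    track = behavior.track
    _, template = build_template(masked_dff, behavior, included_frames,
                                 template_runs, mode)
    X, true_ctx, true_pos, times = timebin_population(
        masked_dff, behavior, included_frames, test_runs, bin_ms)
    Xe = X[:, ensemble]
    Te = template[ensemble]

    dec = PopulationVectorDecoder()
    dec.classes_ = np.arange(Te.shape[1])
    dec.template_ = Te
    dec.n_features_in_ = ensemble.size
    labels = dec.predict(Xe)

    keep = labels >= 0
    n_skipped = int((~keep).sum())
    labels, true_ctx = labels[keep], true_ctx[keep]
    true_pos, times = true_pos[keep], times[keep]
    if mode == "spatial":
        dec_ctx = labels // track.n_bins
        dec_bin = labels % track.n_bins
        dec_pos = (dec_bin + 0.5) * track.bin_cm
        spatial_err = np.abs(dec_pos - true_pos)
    else:
        dec_ctx = labels
        dec_bin = np.full(labels.size, -1)
        spatial_err = np.full(labels.size, np.nan)
    ctx_err = (dec_ctx != true_ctx).astype(float)
    return DecodingResult(times_s=times, true_context=true_ctx,
                          true_position_cm=true_pos, decoded_context=dec_ctx,
                          decoded_bin=dec_bin, context_error=ctx_err,
                          spatial_error_cm=spatial_err, ensemble=ensemble,
                          n_skipped=n_skipped)


def decode_session(masked_dff, behavior, included_frames=None, ensemble=None,
                   mode="spatial", bin_ms=100, parity=0):
    """Split runs, build the template and decode the test half."""
    if included_frames is None:
        included_frames = run_mask(behavior)
    if ensemble is None:
        ensemble = np.arange(masked_dff.shape[0])
    template_runs, test_runs = split_runs(behavior, parity)
    return decode_timebins(masked_dff, behavior, included_frames,
                           template_runs, test_runs, ensemble, mode, bin_ms)


def error_vs_ensemble_size(masked_dff, behavior, included_frames,
                           candidate_cells, sizes=None, n_draws=25, seed=0,
                           mode="spatial", bin_ms=100, parity=0):
    """Mean context/spatial error per ensemble size (random subsamples)."""
    sizes = sizes if sizes is not None else (5, 10, 25, 50, 100)
    rng = np.random.default_rng(seed)
    candidates = np.asarray(candidate_cells, dtype=int)
    template_runs, test_runs = split_runs(behavior, parity)
    out = {}
    for size in sizes:
        if size > candidates.size:
            log.info("skipping ensemble size %d (> %d candidates)",
                     size, candidates.size)
            continue
        ctx_errs, sp_errs = [], []
        for _ in range(n_draws):
            ens = rng.choice(candidates, size=size, replace=False)
            res = decode_timebins(masked_dff, behavior, included_frames,
                                  template_runs, test_runs, ens, mode, bin_ms)
            ctx_errs.append(res.mean_context_error)
            sp_errs.append(res.mean_spatial_error_cm)
        out[size] = (float(np.mean(ctx_errs)), float(np.mean(sp_errs)))
    return out


def _segment_accuracy(context_error, seg_bins):
    """Fraction of non-overlapping segments decoded correctly by majority.

    A segment is correct when its mean per-bin context error is < 0.5;
    a tie (exactly 0.5) counts as incorrect.
    """
    n = context_error.size
    n_seg = n // seg_bins
    if n_seg == 0:
        return math.nan
    segs = context_error[:n_seg * seg_bins].reshape(n_seg, seg_bins)
    wrong = segs.mean(axis=1) >= 0.5
    return 1.0 - float(wrong.mean())


def cumulative_context_accuracy(masked_dff, behavior, included_frames,
                                candidate_cells, delta_t_grid=None,
                                n_ensembles=25, ensemble_size=50, seed=0,
                                bin_ms=100, mode="spatial", parity=0,
                                accuracy_threshold=0.9):
    """Context-decoding accuracy vs integration time Δt; time to 90%.

    For each of ``n_ensembles`` random ``ensemble_size``-cell ensembles the
    test bins are decoded once; for each Δt the per-bin context decisions
    are aggregated over non-overlapping Δt segments by majority. The time
    to 90% accuracy is the first grid Δt whose ensemble-mean accuracy
    exceeds the threshold.
    """
    grid = np.asarray(delta_t_grid if delta_t_grid is not None
                      else DEFAULT_DELTA_T_GRID, dtype=float)
    rng = np.random.default_rng(seed)
    candidates = np.asarray(candidate_cells, dtype=int)
    if candidates.size < ensemble_size:
        raise ValueError("not enough candidate cells for the ensemble size")
    template_runs, test_runs = split_runs(behavior, parity)
    bin_s = bin_ms / 1000.0
    per_ens = np.full((n_ensembles, grid.size), np.nan)
    for e in range(n_ensembles):
        ens = rng.choice(candidates, size=ensemble_size, replace=False)
        res = decode_timebins(masked_dff, behavior, included_frames,
                              template_runs, test_runs, ens, mode, bin_ms)
        for g, dt in enumerate(grid):
            seg_bins = max(1, int(round(dt / bin_s)))
            per_ens[e, g] = _segment_accuracy(res.context_error, seg_bins)
    # grid points longer than the test data leave all-NaN columns
    valid = np.isfinite(per_ens).any(axis=0)
    acc = np.full(grid.size, np.nan)
    acc[valid] = np.nanmean(per_ens[:, valid], axis=0)
    reached = np.flatnonzero(acc > accuracy_threshold)
    t90 = float(grid[reached[0]]) if reached.size else math.nan
    return CumulativeAccuracy(delta_t_s=grid, accuracy=acc,
                              per_ensemble=per_ens, time_to_90_s=t90)


def template_mode_ratio(masked_dff, behavior, included_frames, ensemble,
                        bin_ms=100, parity=0):
    """Spatial-template / mean-rate-template context-error ratio.

    A ratio below 1 indicates that context-specific spatial maps carry
    contextual information beyond mean-rate differences.
    """
    template_runs, test_runs = split_runs(behavior, parity)
    err = {}
    for mode in ("spatial", "mean_rate"):
        res = decode_timebins(masked_dff, behavior, included_frames,
                              template_runs, test_runs, ensemble, mode,
                              bin_ms)
        err[mode] = res.mean_context_error
    if err["mean_rate"] == 0:
        raise ValueError("mean-rate context error is zero; ratio undefined")
    return err["spatial"] / err["mean_rate"]


def per_context_errors(result):
    """Context/spatial error means stratified by the true context."""
    out = {}
    for ctx, name in ((FAMILIAR, "familiar"), (NOVEL, "novel")):
        sel = result.true_context == ctx
        if not sel.any():
            out[name] = {"context_error": math.nan,
                         "spatial_error_cm": math.nan, "n_bins": 0}
            continue
        out[name] = {
            "context_error": float(result.context_error[sel].mean()),
            "spatial_error_cm": float(np.nanmean(
                result.spatial_error_cm[sel])),
            "n_bins": int(sel.sum()),
        }
    return out
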