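"""Session- and cohort-level orchestration.

``analyze_session`` runs preprocessing, spatial tuning, place-field
detection and context metrics for one session and returns tidy per-cell
tables; ``run_pipeline`` drives simulate -> preprocess -> spatial ->
context -> decode over a multi-day, multi-profile cohort from a YAML
config, writing per-stage HDF5/CSV/JSON artifacts with full seed
provenance. Stages are cached: an existing output file short-circuits
recomputation of that stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decoding, io, metrics, preprocess, simulate, spatial
from .track import CONTEXT_NAMES, FAMILIAR, NOVEL, TrackSpec

log = logging.getLogger(__name__)

__all__ = ["default_config", "load_config", "analyze_session",
           "run_pipeline", "validate_session", "SessionAnalysis"]


def default_config():
    return {
        "seed": 0,
        "n_cells": 200,
        "n_days": 5,
        "n_runs_per_context": 15,
        "profiles": ["left_like", "right_like"],
        "n_si_shuffles": 1000,
        "n_bootstrap": 1000,
        "speed_threshold_cm_s": 5.0,
        "decode": {"ensemble_size": 50, "n_ensembles": 25, "bin_ms": 100},
    }


def load_config(path):
    cfg = default_config()
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    if "seed" not in user:
        raise ValueError("config must set an explicit seed")
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _profile_by_name(name):
    presets = {"left_like": simulate.LEFT_LIKE,
               "right_like": simulate.RIGHT_LIKE}
    if name not in presets:
        raise ValueError(f"unknown hemisphere profile: {name!r}")
    return presets[name]


@dataclass
class SessionAnalysis:
    """All single-session results needed by the context/decode stages."""

    extractor: preprocess.TransientExtractor
    included: np.ndarray
    active: np.ndarray                       # bool per cell
    masked: np.ndarray                       # (n_cells, n_frames)
    maps: dict                               # context -> (n_cells, n_bins) raw
    smoothed: dict                           # context -> smoothed maps
    cells: pd.DataFrame                      # per (cell, context) table
    fields: dict                             # (cell, context) -> [PlaceField]
    is_place: np.ndarray                     # (n_cells, 2) bool
    session: simulate.SessionRecording


def analyze_session(session, n_si_shuffles=1000, n_bootstrap=1000,
                    speed_threshold_cm_s=5.0, seed=0,
                    bootstrap_accept_above=False):
    """Preprocess one session and compute spatial tuning + place fields.

    Shuffle and bootstrap tests are run on active cells only (inactive
    cells cannot pass the >1 transient/min gate, and their SI is not
    reported in summaries). Setting ``n_si_shuffles=0`` or ``n_bootstrap=0``
    skips the corresponding test (used by stages that only need the
    preprocessed traces). ``bootstrap_accept_above`` switches to the
    literal accept-if-P>0.05 reading of the bootstrap rule.
    """
    rng = np.random.default_rng(seed)
    beh = session.behavior
    track = beh.track
    ext, included, active = preprocess.preprocess_session(
        session, speed_threshold_cm_s=speed_threshold_cm_s)
    masked = np.vstack([t.masked_dff for t in ext.traces_])
    tmasks = np.vstack([t.transient_mask for t in ext.traces_])
    n_cells = masked.shape[0]

    maps, smoothed, ctx_included = {}, {}, {}
    for ctx in (FAMILIAR, NOVEL):
        sel = included & (beh.context_id == ctx)
        ctx_included[ctx] = sel
        raw = np.full((n_cells, track.n_bins), np.nan)
        smo = np.full((n_cells, track.n_bins), np.nan)
        for i in range(n_cells):
            m = spatial.bin_activity(masked[i], beh.position_cm, sel, track,
                                     context_id=ctx)
            raw[i] = m.lambda_i
            smo[i] = spatial.smooth_map(m).lambda_i
        maps[ctx], smoothed[ctx] = raw, smo

    rows = []
    fields = {}
    is_place = np.zeros((n_cells, 2), dtype=bool)
    minutes_by_ctx = {c: ctx_included[c].sum() / beh.frame_rate_hz / 60.0
                      for c in (FAMILIAR, NOVEL)}
    for i in range(n_cells):
        for ctx in (FAMILIAR, NOVEL):
            sel = ctx_included[ctx]
            rate = preprocess.activity_rate(masked[i], sel, beh.frame_rate_hz)
            row = {"cell": i, "context": CONTEXT_NAMES[ctx],
                   "activity_rate": rate, "active": bool(active[i]),
                   "flagged": bool(ext.flagged_[i]),
                   "si": math.nan, "shuffle_p": math.nan,
                   "si_significant": False, "n_fields": 0,
                   "is_place": False, "bootstrap_p": math.nan}
            if active[i]:
                if n_si_shuffles > 0:
                    tuning = spatial.si_shuffle_test(
                        masked[i], beh.position_cm, sel, track,
                        frame_rate_hz=beh.frame_rate_hz,
                        n_shuffles=n_si_shuffles, rng=rng)
                    row.update(si=tuning.si_bits_per_s,
                               shuffle_p=tuning.shuffle_p,
                               si_significant=tuning.is_significant)
                cand = (spatial.detect_place_fields(
                    smoothed[ctx][i], tmasks[i], beh.position_cm, sel, track,
                    cell_id=i, context_id=ctx) if n_bootstrap > 0 else [])
                if cand:
                    p_boot = spatial.bootstrap_field_significance(
                        masked[i], tmasks[i], beh.position_cm, sel, track,
                        n_shuffles=n_bootstrap, rng=rng)
                    accept = (p_boot > 0.05 if bootstrap_accept_above
                              else p_boot < 0.05)
                    if accept:
                        for f in cand:
                            f.bootstrap_p = p_boot
                        fields[(i, ctx)] = cand
                        is_place[i, ctx] = True
                        row.update(n_fields=len(cand), is_place=True,
                                   bootstrap_p=p_boot)
            rows.append(row)
    cells = pd.DataFrame(rows)
    return SessionAnalysis(extractor=ext, included=included, active=active,
                           masked=masked, maps=maps, smoothed=smoothed,
                           cells=cells, fields=fields, is_place=is_place,
                           session=session)


def context_table(analysis):
    """Per-cell context metrics (discrimination, stability, remapping)."""
    beh = analysis.session.behavior
    rows = []
    cells = analysis.cells.set_index(["cell", "context"])
    for i in range(analysis.masked.shape[0]):
        if not analysis.active[i]:
            continue
        act = {c: cells.loc[(i, CONTEXT_NAMES[c]), "activity_rate"]
               for c in (FAMILIAR, NOVEL)}
        row = {"cell": i,
               "diff_score": metrics.activity_difference(act[FAMILIAR],
                                                         act[NOVEL])}
        total = act[FAMILIAR] + act[NOVEL]
        row["discrimination"] = (
            metrics.discrimination_score(act[FAMILIAR], act[NOVEL])
            if total > 0 else math.nan)
        r = metrics.map_correlation(analysis.maps[FAMILIAR][i],
                                    analysis.maps[NOVEL][i])
        row["cross_context_r"] = r
        row["remap_class"] = (metrics.remap_classify(r)
                              if not math.isnan(r) else "undefined")
        for ctx in (FAMILIAR, NOVEL):
            name = CONTEXT_NAMES[ctx]
            run_maps, _ = spatial.per_run_maps(analysis.masked[i], beh,
                                               analysis.included, ctx)
            row[f"reliability_{name}"] = metrics.run_reliability(run_maps)
            n_runs = run_maps.shape[0]
            if n_runs >= 10:
                row[f"consistency_{name}"] = metrics.session_consistency(
                    run_maps[:5], run_maps[-5:])
            else:
                row[f"consistency_{name}"] = math.nan
            row[f"is_place_{name}"] = bool(analysis.is_place[i, ctx])
        rows.append(row)
    return pd.DataFrame(rows)


def decode_summary(analysis, ensemble_size=50, n_ensembles=25, bin_ms=100,
                   seed=0, delta_t_grid=None):
    """Decoding-stage summary for one analyzed session."""
    beh = analysis.session.behavior
    candidates = np.flatnonzero(analysis.active)
    out = {"n_active": int(candidates.size)}
    if candidates.size == 0:
        return out
    size = min(ensemble_size, candidates.size)
    rng = np.random.default_rng(seed)
    ens = rng.choice(candidates, size=size, replace=False)
    res = decoding.decode_session(analysis.masked, beh, analysis.included,
                                  ensemble=ens, bin_ms=bin_ms)
    out["context_error"] = res.mean_context_error
    out["spatial_error_cm"] = res.mean_spatial_error_cm
    out["per_context"] = decoding.per_context_errors(res)
    if candidates.size >= ensemble_size:
        cum = decoding.cumulative_context_accuracy(
            analysis.masked, beh, analysis.included, candidates,
            delta_t_grid=delta_t_grid, n_ensembles=n_ensembles,
            ensemble_size=ensemble_size, seed=seed, bin_ms=bin_ms)
        out["time_to_90_s"] = cum.time_to_90_s
        out["accuracy_curve"] = {float(dt): float(a) for dt, a
                                 in zip(cum.delta_t_s, cum.accuracy)}
    return out


def run_pipeline(config, out_dir):
    """Run simulate -> preprocess/spatial -> context -> decode -> report.

    Writes, per profile and day: the session HDF5, per-cell CSV tables and
    a JSON decode summary; plus a cohort-level ``report.json``. Existing
    stage outputs are reused (delete a file to recompute that stage).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(config, sort_keys=True)
    (out / "config.yaml").write_text(cfg_text)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    log.info("pipeline config hash %s", cfg_hash)

    report = {"config_hash": cfg_hash, "profiles": {}}
    ss = np.random.SeedSequence(config["seed"])
    profile_seeds = {name: int(child.generate_state(1)[0] % (2 ** 31))
                     for name, child in zip(config["profiles"],
                                            ss.spawn(len(config["profiles"])))}
    for name in config["profiles"]:
        profile = _profile_by_name(name)
        pseed = profile_seeds[name]
        sessions = None
        day_summaries = []
        for day in range(1, config["n_days"] + 1):
            spath = out / f"{name}_day{day}.h5"
            if not spath.exists():
                if sessions is None:
                    sessions = simulate.simulate_cohort(
                        profile, n_cells=config["n_cells"],
                        n_days=config["n_days"], seed=pseed,
                        n_runs_per_context=config["n_runs_per_context"])
                io.save_session(sessions[day - 1], spath)
            session = io.load_session(spath)
            cells_path = out / f"{name}_day{day}_cells.csv"
            ctx_path = out / f"{name}_day{day}_context.csv"
            dec_path = out / f"{name}_day{day}_decode.json"
            if cells_path.exists() and ctx_path.exists() and dec_path.exists():
                # round_trip parsing keeps cached reruns bit-identical
                cells = pd.read_csv(cells_path,
                                    float_precision="round_trip")
                ctx_tab = pd.read_csv(ctx_path,
                                      float_precision="round_trip")
                dec = json.loads(dec_path.read_text())
            else:
                analysis = analyze_session(
                    session,
                    n_si_shuffles=config["n_si_shuffles"],
                    n_bootstrap=config["n_bootstrap"],
                    speed_threshold_cm_s=config["speed_threshold_cm_s"],
                    seed=pseed + day)
                cells = analysis.cells
                ctx_tab = context_table(analysis)
                dec = decode_summary(analysis,
                                     ensemble_size=config["decode"]
                                     ["ensemble_size"],
                                     n_ensembles=config["decode"]
                                     ["n_ensembles"],
                                     bin_ms=config["decode"]["bin_ms"],
                                     seed=pseed + day)
                # %.17g guarantees float round-trip through the CSV cache
                cells.to_csv(cells_path, index=False,
                             float_format="%.17g")
                ctx_tab.to_csv(ctx_path, index=False,
                               float_format="%.17g")
                dec_path.write_text(json.dumps(dec, indent=1))
            day_summaries.append(_summarize_day(cells, ctx_tab, dec, day))
        report["profiles"][name] = {"seed": pseed, "days": day_summaries}
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def _summarize_day(cells, ctx_tab, dec, day):
    active = cells[cells["active"]]
    summary = {
        "day": day,
        "frac_active": float(cells.groupby("cell")["active"].first().mean()),
        "mean_activity": float(cells["activity_rate"].mean()),
        "mean_si_active": float(active["si"].mean()) if len(active) else None,
        "frac_place_of_active": (
            float(active.groupby("cell")["is_place"].any().mean())
            if len(active) else None),
        "decode": dec,
    }
    if len(ctx_tab):
        valid = ctx_tab[ctx_tab["remap_class"] != "undefined"]
        summary["median_cross_context_r"] = (
            float(valid["cross_context_r"].median()) if len(valid) else None)
        place = ctx_tab[ctx_tab["is_place_familiar"]
                        | ctx_tab["is_place_novel"]]
        pv = place[place["remap_class"] != "undefined"]
        summary["remap_fractions"] = (
            {c: float((pv["remap_class"] == c).mean())
             for c in ("low", "medium", "high")} if len(pv) else None)
        summary["mean_reliability"] = float(np.nanmean(
            ctx_tab[["reliability_familiar", "reliability_novel"]]
            .to_numpy()))
    return summary


def validate_session(path):
    """Schema and consistency diagnostics for a session file.

    Returns (ok, list of messages); warnings do not fail validation.
    """
    msgs, ok = [], True
    try:
        session = io.load_session(path)
    except Exception as exc:  # noqa: BLE001 - report, don't crash
        return False, [f"unreadable session file: {exc}"]
    beh = session.behavior
    n = session.fluorescence.shape[1]
    for key in ("position_cm", "speed_cm_s", "context_id", "run_id",
                "lick_events", "reward_events"):
        if getattr(beh, key).shape[0] != n:
            ok = False
            msgs.append(f"behavior stream {key} length mismatch")
    if not np.isfinite(session.fluorescence).all():
        ok = False
        msgs.append("NaN/inf in fluorescence")
    valid = ~beh.in_gap()
    pos = beh.position_cm[valid]
    if pos.size and (np.nanmin(pos) < 0
                     or np.nanmax(pos) >= beh.track.length_cm
                     + beh.track.bin_cm):
        ok = False
        msgs.append("positions outside track range")
    if beh.frame_rate_hz <= 0:
        ok = False
        msgs.append("non-positive frame rate")
    run_ids = beh.run_id[beh.run_id >= 0]
    if run_ids.size and np.any(np.diff(run_ids) < 0):
        ok = False
        msgs.append("run ids not monotonically non-decreasing")
    if not ok:
        return ok, msgs
    if not msgs:
        msgs.append("session OK")
    return ok, msgs
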