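"""HDF5 session container.

Layout: /fluorescence (cells x frames), /behavior/{position_cm, speed_cm_s,
context_id, run_id, lick_events, reward_events}, /meta (frame_rate_hz, day,
hemisphere, track spec) and, for simulated sessions, /ground_truth.
Processed results are added by the pipeline under /processed and /maps.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .simulate import Behavior, GroundTruth, SessionRecording
from .track import TrackSpec

__all__ = ["save_session", "load_session", "behavior_to_frame"]

_BEHAVIOR_KEYS = ("position_cm", "speed_cm_s", "context_id", "run_id",
                  "lick_events", "reward_events")


def _track_meta(track):
    return json.dumps({
        "length_cm": track.length_cm, "n_bins": track.n_bins,
        "bin_cm": track.bin_cm,
        "reward_centers_cm": {str(k): list(v)
                              for k, v in track.reward_centers_cm.items()},
        "teleport_gap_s": list(track.teleport_gap_s),
    })


def _track_from_meta(s):
    d = json.loads(s)
    return TrackSpec(
        length_cm=d["length_cm"], n_bins=d["n_bins"], bin_cm=d["bin_cm"],
        reward_centers_cm={int(k): tuple(v)
                           for k, v in d["reward_centers_cm"].items()},
        teleport_gap_s=tuple(d["teleport_gap_s"]),
    )


def save_session(session, path):
    """Write a :class:`SessionRecording` (and ground truth, if any)."""
    beh = session.behavior
    with h5py.File(path, "w") as f:
        f.create_dataset("fluorescence", data=session.fluorescence,
                         dtype="f8")
        g = f.create_group("behavior")
        for key in _BEHAVIOR_KEYS:
            g.create_dataset(key, data=getattr(beh, key))
        meta = f.create_group("meta")
        meta.attrs["frame_rate_hz"] = beh.frame_rate_hz
        meta.attrs["day_index"] = session.day_index
        meta.attrs["hemisphere"] = session.hemisphere
        meta.attrs["track"] = _track_meta(beh.track)
        if session.ground_truth is not None:
            gt = session.ground_truth
            h = f.create_group("ground_truth")
            h.create_dataset("is_active", data=gt.is_active)
            h.create_dataset("is_place", data=gt.is_place)
            h.create_dataset("field_center_bins", data=gt.field_center_bins)
            h.create_dataset("field_width_bins", data=gt.field_width_bins)
            h.create_dataset(
                "remap_class",
                data=np.array([s.encode() for s in gt.remap_class]))
            flat = (np.concatenate(gt.event_frames)
                    if gt.event_frames else np.empty(0, int))
            offsets = np.cumsum([0] + [len(e) for e in gt.event_frames])
            h.create_dataset("event_frames_flat", data=flat.astype(np.int64))
            h.create_dataset("event_frames_offsets", data=offsets)
    return path


def load_session(path):
    with h5py.File(path, "r") as f:
        beh = Behavior(
            frame_rate_hz=float(f["meta"].attrs["frame_rate_hz"]),
            track=_track_from_meta(f["meta"].attrs["track"]),
            **{k: f["behavior"][k][()] for k in _BEHAVIOR_KEYS},
        )
        truth = None
        if "ground_truth" in f:
            h = f["ground_truth"]
            offsets = h["event_frames_offsets"][()]
            flat = h["event_frames_flat"][()]
            events = [flat[offsets[i]:offsets[i + 1]]
                      for i in range(offsets.size - 1)]
            truth = GroundTruth(
                is_active=h["is_active"][()].astype(bool),
                is_place=h["is_place"][()].astype(bool),
                field_center_bins=h["field_center_bins"][()],
                field_width_bins=h["field_width_bins"][()],
                remap_class=np.array([s.decode()
                                      for s in h["remap_class"][()]],
                                     dtype=object),
                event_frames=events,
            )
        return SessionRecording(
            fluorescence=f["fluorescence"][()],
            behavior=beh,
            day_index=int(f["meta"].attrs["day_index"]),
            hemisphere=str(f["meta"].attrs["hemisphere"]),
            ground_truth=truth,
        )


def behavior_to_frame(behavior):
    """Behavior streams as a tidy DataFrame (CSV-exportable)."""
    return pd.DataFrame({
        "time_s": behavior.times_s,
        **{k: getattr(behavior, k) for k in _BEHAVIOR_KEYS},
    })
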