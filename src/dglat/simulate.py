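"""Synthetic virtual-track sessions with known ground truth.

Generates multi-day, two-context linear-track sessions (behavior plus
GCaMP6s-like fluorescence) whose statistical structure mimics head-fixed
granule-cell recordings: sparse activity, place cells with context-specific
or generalized fields, run-to-run field jitter, and day-to-day drift.
Hemisphere presets encode the qualitative left/right contrasts (a larger
active and place-coding fraction, sharper and more reliable fields, and
more cross-context global remapping on the left).

Behavior model: each run is a forward traversal of the 4-m track at a
clipped Ornstein-Uhlenbeck speed around a target, with Bernoulli pause
episodes; runs alternate between contexts in blocks of five, starting
familiar, and are separated by 4-10 s blank-screen gaps whose frames carry
a sentinel (NaN) position and are excluded from all spatial analyses.

Fluorescence model: per cell, calcium events are drawn from an
inhomogeneous Poisson process whose rate is ``infield_event_rate_hz``
inside the cell's (run-jittered) field and ``outfield_event_rate_hz``
elsewhere; events are convolved with a double-exponential kernel and added
to a slowly drifting multiplicative baseline plus i.i.d. Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .track import FAMILIAR, NOVEL, TrackSpec

__all__ = [
    "HemisphereProfile", "LEFT_LIKE", "RIGHT_LIKE", "Behavior", "GroundTruth",
    "SessionRecording", "simulate_behavior", "simulate_fluorescence",
    "simulate_session", "simulate_cohort", "gcamp_kernel",
]


@dataclass(frozen=True)
class HemisphereProfile:
    """Cell-population parameters for one simulated hemisphere.

    ``frac_active`` is the probability that a cell fires more than one
    transient per minute; ``frac_place_of_active`` the probability that an
    active cell carries a place field (in both contexts).
    ``frac_global_remap`` is the probability that a place cell's novel-context
    field location is drawn independently of its familiar field (global
    remapping) rather than preserved (generalization).
    """

    name: str = "custom"
    frac_active: float = 0.20
    frac_place_of_active: float = 0.50
    field_width_bins_mean: float = 5.0
    field_width_bins_sd: float = 1.5
    # in-field rate chosen so a field is expressed on most traversals
    # (even a minimum-width ~0.75 s pass carries a transient with p ~ 0.5)
    infield_event_rate_hz: float = 0.7
    outfield_event_rate_hz: float = 0.01
    sustained_event_rate_hz: float = 0.08   # active non-place cells
    silent_event_rate_hz: float = 0.002     # inactive cells
    run_jitter_bins: float = 1.0
    frac_global_remap: float = 0.5
    day_drift_prob: float = 0.15
    # GCaMP6s-like kernel; rise/decay are simulator choices, not measured.
    kernel_rise_s: float = 0.18
    kernel_decay_s: float = 1.8
    amp_mean_sigma: float = 6.0     # mean event amplitude (a.u.; the default
                                    # noise s.d. is 1 a.u., so ~6 noise s.d.)
    amp_sigma_log: float = 0.3      # lognormal spread of amplitudes
    baseline_au: float = 50.0
    noise_sigma_au: float = 1.0
    drift_amp: float = 0.05         # multiplicative slow-drift amplitude
    drift_period_s: float = 300.0

    def __post_init__(self):
        for p in (self.frac_active, self.frac_place_of_active,
                  self.frac_global_remap, self.day_drift_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.infield_event_rate_hz <= self.outfield_event_rate_hz:
            raise ValueError("in-field event rate must exceed out-field rate")


#: Presets encoding the qualitative hemisphere contrasts: the left-like
#: population is larger (more active/place cells), sharper (less run-to-run
#: jitter) and discriminates contexts more (more global remapping).
LEFT_LIKE = HemisphereProfile(
    name="left_like", frac_active=0.25, frac_place_of_active=0.55,
    infield_event_rate_hz=0.70, run_jitter_bins=0.8, frac_global_remap=0.65,
)
RIGHT_LIKE = HemisphereProfile(
    name="right_like", frac_active=0.15, frac_place_of_active=0.40,
    infield_event_rate_hz=0.55, run_jitter_bins=1.8, frac_global_remap=0.30,
)


@dataclass
class Behavior:
    """Per-frame behavior streams for one session (both contexts)."""

    frame_rate_hz: float
    position_cm: np.ndarray     # NaN during blank gaps
    speed_cm_s: np.ndarray
    context_id: np.ndarray      # -1 during gaps
    run_id: np.ndarray          # -1 during gaps
    lick_events: np.ndarray     # bool
    reward_events: np.ndarray   # bool
    track: TrackSpec

    @property
    def n_frames(self):
        return self.position_cm.size

    @property
    def times_s(self):
        return np.arange(self.n_frames) / self.frame_rate_hz

    def in_gap(self):
        return self.context_id < 0


@dataclass
class GroundTruth:
    """Simulator ground truth serialized alongside each session."""

    is_active: np.ndarray                 # (n_cells,) bool
    is_place: np.ndarray                  # (n_cells,) bool; fields in both contexts
    field_center_bins: np.ndarray         # (n_cells, 2) float, NaN if no field
    field_width_bins: np.ndarray          # (n_cells,) float
    remap_class: np.ndarray               # (n_cells,) 'global'|'stable'|'none'
    event_frames: list                    # per cell, int array of event frames


@dataclass
class SessionRecording:
    """One animal/day/field-of-view recording: raw traces + behavior."""

    fluorescence: np.ndarray              # (n_cells, n_frames)
    behavior: Behavior
    day_index: int = 1
    hemisphere: str = "custom"
    ground_truth: GroundTruth | None = None

    @property
    def n_cells(self):
        return self.fluorescence.shape[0]

    @property
    def frame_rate_hz(self):
        return self.behavior.frame_rate_hz


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def _block_schedule(n_runs_per_context, block_size=5):
    """Alternating context blocks, starting familiar: F F F F F N N N N N ..."""
    schedule = []
    remaining = {FAMILIAR: n_runs_per_context, NOVEL: n_runs_per_context}
    ctx = FAMILIAR
    while remaining[FAMILIAR] or remaining[NOVEL]:
        take = min(block_size, remaining[ctx])
        schedule.extend([ctx] * take)
        remaining[ctx] -= take
        other = NOVEL if ctx == FAMILIAR else FAMILIAR
        ctx = other if remaining[other] else ctx
    return schedule


def simulate_behavior(track=None, n_runs_per_context=15, frame_rate_hz=15.5,
                      target_speed_cm_s=20.0, speed_sigma=6.0, speed_tau_s=2.0,
                      rest_fraction=0.10, mean_pause_s=2.0,
                      lick_rate_in_hz=4.0, lick_rate_out_hz=0.5, lick_bias=0.0,
                      seed=0, rng=None):
    """Simulate the behavior streams of one session.

    Runs alternate between familiar and novel context in blocks of five
    (default 15 runs per context, 30 total). Within a run, position advances
    by a clipped Ornstein-Uhlenbeck speed around ``target_speed_cm_s``;
    with ``rest_fraction`` of the moving time replaced by pause episodes
    (speed 0) of mean length ``mean_pause_s``. Licking is an inhomogeneous
    Bernoulli process with elevated rate inside reward zones;
    ``lick_bias=1`` suppresses all out-of-zone licking.
    """
    track = track or TrackSpec()
    if frame_rate_hz <= 0:
        raise ValueError("frame rate must be positive")
    if n_runs_per_context < 1:
        raise ValueError("need at least one run per context")
    rng = rng if rng is not None else np.random.default_rng(seed)
    dt = 1.0 / frame_rate_hz

    # per-frame pause-entry probability chosen so that pauses occupy
    # ~rest_fraction of run time given mean pause length
    mean_pause_frames = max(mean_pause_s * frame_rate_hz, 1.0)
    if rest_fraction > 0:
        p_pause = rest_fraction / ((1 - rest_fraction) * mean_pause_frames)
    else:
        p_pause = 0.0

    pos, spd, ctx, run, lick, rew = [], [], [], [], [], []
    schedule = _block_schedule(n_runs_per_context)
    for run_idx, context in enumerate(schedule):
        x = 0.0
        v = target_speed_cm_s
        pause_left = 0
        rewarded = [False] * len(track.reward_centers_cm[context])
        zone = track.reward_zone_mask(context)
        while x < track.length_cm:
            if pause_left > 0:
                v_eff = 0.0
                pause_left -= 1
            else:
                if rng.random() < p_pause:
                    pause_left = max(1, int(rng.exponential(mean_pause_frames)))
                    v_eff = 0.0
                else:
                    v_eff = v
            pos.append(x)
            spd.append(v_eff)
            ctx.append(context)
            run.append(run_idx)
            in_zone = bool(zone[track.bin_of(x)])
            rate = lick_rate_in_hz if in_zone else lick_rate_out_hz * (1.0 - lick_bias)
            lick.append(rng.random() < rate * dt)
            hit = False
            for k, c in enumerate(track.reward_centers_cm[context]):
                if not rewarded[k] and x <= c < x + v_eff * dt:
                    rewarded[k] = hit = True
            rew.append(hit)
            x += v_eff * dt
            # OU update of the underlying (moving) speed, clipped at 0
            v += (target_speed_cm_s - v) * dt / speed_tau_s \
                + speed_sigma * np.sqrt(dt) * rng.standard_normal()
            v = max(v, 0.0)
            if v < 1e-3:  # never let the OU trap the animal at 0 forever
                v = 1e-3
        # blank-screen teleport gap
        gap_frames = int(round(rng.uniform(*track.teleport_gap_s) * frame_rate_hz))
        pos.extend([np.nan] * gap_frames)
        spd.extend([0.0] * gap_frames)
        ctx.extend([-1] * gap_frames)
        run.extend([-1] * gap_frames)
        lick.extend([False] * gap_frames)
        rew.extend([False] * gap_frames)

    return Behavior(
        frame_rate_hz=frame_rate_hz,
        position_cm=np.array(pos, dtype=float),
        speed_cm_s=np.array(spd, dtype=float),
        context_id=np.array(ctx, dtype=np.int16),
        run_id=np.array(run, dtype=np.int32),
        lick_events=np.array(lick, dtype=bool),
        reward_events=np.array(rew, dtype=bool),
        track=track,
    )


# ---------------------------------------------------------------------------
# fluorescence
# ---------------------------------------------------------------------------

def gcamp_kernel(frame_rate_hz, rise_s=0.18, decay_s=1.8):
    """Double-exponential calcium-indicator impulse response, peak 1."""
    t = np.arange(0, rise_s + 6 * decay_s, 1.0 / frame_rate_hz)
    h = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return h / h.max()


@dataclass
class _CellPopulation:
    """Persistent cell identities reused across days of a cohort."""

    is_active: np.ndarray
    is_place: np.ndarray
    centers: np.ndarray         # (n_cells, 2) bins
    widths: np.ndarray          # (n_cells,)
    remap_class: np.ndarray


def _draw_population(profile, n_cells, track, rng):
    is_active = rng.random(n_cells) < profile.frac_active
    is_place = is_active & (rng.random(n_cells) < profile.frac_place_of_active)
    widths = np.clip(
        rng.normal(profile.field_width_bins_mean, profile.field_width_bins_sd,
                   n_cells),
        3.0, track.n_bins / 4)
    centers = np.full((n_cells, 2), np.nan)
    remap = np.array(["none"] * n_cells, dtype=object)
    for i in np.nonzero(is_place)[0]:
        half = widths[i] / 2
        fam = rng.uniform(half, track.n_bins - half)
        if rng.random() < profile.frac_global_remap:
            nov = rng.uniform(half, track.n_bins - half)
            remap[i] = "global"
        else:
            nov = fam
            remap[i] = "stable"
        centers[i] = (fam, nov)
    return _CellPopulation(is_active, is_place, centers, widths, remap)


def _drift_population(pop, profile, track, rng):
    """Apply one day of field relocation with probability day_drift_prob."""
    centers = pop.centers.copy()
    for i in np.nonzero(pop.is_place)[0]:
        half = pop.widths[i] / 2
        for c in (FAMILIAR, NOVEL):
            if rng.random() < profile.day_drift_prob:
                centers[i, c] = rng.uniform(half, track.n_bins - half)
    return replace(pop, centers=centers)


def _event_rates(behavior, pop, profile, rng):
    """Per-cell, per-frame Poisson event rate given true fields."""
    n_frames = behavior.n_frames
    track = behavior.track
    valid = ~behavior.in_gap() & np.isfinite(behavior.position_cm)
    bin_idx = np.where(valid, behavior.track.bin_of(
        np.nan_to_num(behavior.position_cm)), -1)
    pos_bins = behavior.position_cm / track.bin_cm  # float bins

    n_cells = pop.is_active.size
    rates = np.empty((n_cells, n_frames))
    run_ids = behavior.run_id
    unique_runs = np.unique(run_ids[run_ids >= 0])
    for i in range(n_cells):
        if not pop.is_active[i]:
            rates[i] = profile.silent_event_rate_hz
        elif not pop.is_place[i]:
            rates[i] = profile.sustained_event_rate_hz
        else:
            r = np.full(n_frames, profile.outfield_event_rate_hz)
            half = pop.widths[i] / 2
            for run_idx in unique_runs:
                sel = run_ids == run_idx
                ctx = behavior.context_id[sel][0]
                center = pop.centers[i, ctx] \
                    + rng.normal(0.0, profile.run_jitter_bins)
                infield = sel & valid \
                    & (np.abs(pos_bins - center) <= half)
                r[infield] = profile.infield_event_rate_hz
            rates[i] = r
    rates[:, ~valid] = np.minimum(rates[:, ~valid],
                                  profile.outfield_event_rate_hz)
    return rates


def simulate_fluorescence(behavior, profile=None, n_cells=200, seed=0,
                          rng=None, population=None, day_index=1):
    """Simulate raw fluorescence traces for ``n_cells`` cells.

    Returns a :class:`SessionRecording` whose ``ground_truth`` records the
    active/place status, true field centers and event times of every cell.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    profile = profile or HemisphereProfile()
    rng = rng if rng is not None else np.random.default_rng(seed)
    track = behavior.track
    pop = population or _draw_population(profile, n_cells, track, rng)

    dt = 1.0 / behavior.frame_rate_hz
    rates = _event_rates(behavior, pop, profile, rng)
    events = rng.random(rates.shape) < rates * dt

    kernel = gcamp_kernel(behavior.frame_rate_hz,
                          profile.kernel_rise_s, profile.kernel_decay_s)
    n_frames = behavior.n_frames
    t = behavior.times_s
    traces = np.empty((n_cells, n_frames))
    event_frames = []
    for i in range(n_cells):
        frames = np.nonzero(events[i])[0]
        event_frames.append(frames)
        amps = profile.amp_mean_sigma * np.exp(
            rng.normal(0.0, profile.amp_sigma_log, frames.size)
            - profile.amp_sigma_log ** 2 / 2)
        impulses = np.zeros(n_frames)
        np.add.at(impulses, frames, amps)
        signal = np.convolve(impulses, kernel)[:n_frames]
        phase = rng.uniform(0, 2 * np.pi)
        baseline = profile.baseline_au * (
            1.0 + profile.drift_amp
            * np.sin(2 * np.pi * t / profile.drift_period_s + phase))
        noise = profile.noise_sigma_au * rng.standard_normal(n_frames) \
            if profile.noise_sigma_au > 0 else 0.0
        traces[i] = baseline + signal + noise

    truth = GroundTruth(
        is_active=pop.is_active.copy(), is_place=pop.is_place.copy(),
        field_center_bins=pop.centers.copy(), field_width_bins=pop.widths.copy(),
        remap_class=pop.remap_class.copy(), event_frames=event_frames,
    )
    return SessionRecording(fluorescence=traces, behavior=behavior,
                            day_index=day_index, hemisphere=profile.name,
                            ground_truth=truth)


def simulate_session(profile=None, n_cells=200, seed=0, track=None,
                     n_runs_per_context=15, day_index=1, **behavior_kwargs):
    """Convenience wrapper: behavior + fluorescence for one session."""
    profile = profile or HemisphereProfile()
    rng = np.random.default_rng(seed)
    behavior = simulate_behavior(track=track,
                                 n_runs_per_context=n_runs_per_context,
                                 rng=rng, **behavior_kwargs)
    return simulate_fluorescence(behavior, profile, n_cells, rng=rng,
                                 day_index=day_index)


def simulate_cohort(profile=None, n_cells=200, n_days=5, seed=0, track=None,
                    n_runs_per_context=15, **behavior_kwargs):
    """Simulate ``n_days`` consecutive sessions with persistent cell identity.

    Field relocation between days is governed by ``profile.day_drift_prob``;
    behavior is drawn fresh each day.
    """
    profile = profile or HemisphereProfile()
    track = track or TrackSpec()
    ss = np.random.SeedSequence(seed)
    pop_rng = np.random.default_rng(ss.spawn(1)[0])
    pop = _draw_population(profile, n_cells, track, pop_rng)
    sessions = []
    for day, child in enumerate(ss.spawn(n_days), start=1):
        rng = np.random.default_rng(child)
        if day > 1:
            pop = _drift_population(pop, profile, track, pop_rng)
        behavior = simulate_behavior(track=track,
                                     n_runs_per_context=n_runs_per_context,
                                     rng=rng, **behavior_kwargs)
        sessions.append(simulate_fluorescence(
            behavior, profile, n_cells, rng=rng, population=pop,
            day_index=day))
    return sessions
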