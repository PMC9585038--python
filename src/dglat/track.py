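"""Virtual linear-track geometry.

The track is a 4-m virtual corridor discretized into 80 bins of 5 cm.
Bins are 0-based and half-open: bin k covers [k*bin_cm, (k+1)*bin_cm) cm.
After each traversal the screens blank for 4-10 s before the animal is
teleported back to the start; those gap frames carry no position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Per-frame position value used during inter-run blank gaps.
GAP_POSITION = np.nan

#: Context codes. Familiar tracks offer four reward sites, novel tracks two.
FAMILIAR, NOVEL = 0, 1
CONTEXT_NAMES = {FAMILIAR: "familiar", NOVEL: "novel"}


@dataclass(frozen=True)
class TrackSpec:
    """Geometry and reward layout of the virtual linear track."""

    length_cm: float = 400.0
    n_bins: int = 80
    bin_cm: float = 5.0
    #: Reward-site centers (cm) per context: familiar has 4 sites, novel 2.
    reward_centers_cm: dict = field(
        default_factory=lambda: {FAMILIAR: (50.0, 150.0, 250.0, 350.0),
                                 NOVEL: (100.0, 300.0)}
    )
    teleport_gap_s: tuple = (4.0, 10.0)

    def __post_init__(self):
        if self.length_cm <= 0:
            raise ValueError("track length must be positive")
        if abs(self.n_bins * self.bin_cm - self.length_cm) > 1e-9:
            raise ValueError("n_bins * bin_cm must equal length_cm")
        for centers in self.reward_centers_cm.values():
            for c in centers:
                if not (0 <= c < self.length_cm):
                    raise ValueError("reward centers must lie within the track")

    def bin_of(self, position_cm):
        """0-based spatial bin index; positions are clipped to the last bin."""
        pos = np.asarray(position_cm, dtype=float)
        idx = np.floor(pos / self.bin_cm).astype(int)
        return np.clip(idx, 0, self.n_bins - 1)

    def reward_zone_mask(self, context):
        """Boolean over bins: the 5 bins (25 cm) around each reward center."""
        mask = np.zeros(self.n_bins, dtype=bool)
        for c in self.reward_centers_cm[context]:
            center_bin = int(np.floor(c / self.bin_cm))
            lo = max(0, center_bin - 2)
            hi = min(self.n_bins, center_bin + 3)
            mask[lo:hi] = True
        return mask
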