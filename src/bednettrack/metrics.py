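"""Track-quality statistics: potential positions, gaps and detection rates.

A gap in a track is a run of frames where the mosquito went undetected but
tracking bridged across it.  With Δt the inter-frame time and Δt_k the time
difference between recorded positions k−1 and k, the total number of
*potential* positions in a track is

    N_t = Σ_{k=0}^{n−1} Int[Δt_k / Δt],

where Int[·] is the nearest integer and the first recorded position
contributes 1 (Δt_0 ≔ Δt by convention, so a gap-free track has N_t = n).
The total number of missed positions is

    N_Gaps = Σ_{k=0}^{n−1} Int[Δt_k / Δt − 1],

giving the conservation law n + N_Gaps = N_t.  The headline performance
figure is the detection percentage: recorded positions divided by N_t,
reported overall and stratified into the *across net* (bednet) and *outside
net* (background) regions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from bednettrack.tracking import Track

#: Region strata used in cohort summaries.
ACROSS, OUTSIDE = "across_net", "outside_net"

_STRATUM_OF = {
    "bednet": ACROSS,
    "front_net": ACROSS,
    "behind_net": ACROSS,
    "background": OUTSIDE,
}


def _nearest_int(x: float) -> int:
    """Nearest integer, ties rounded half away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _frame_times(track) -> np.ndarray:
    if isinstance(track, Track):
        return track.frames.astype(float)
    return np.asarray(track, dtype=float)


def potential_positions(track, dt: float = 1.0) -> int:
    """Total number of potential positions N_t along a track.

    ``track`` may be a :class:`~bednettrack.tracking.Track` or a sequence of
    frame times; ``dt`` is the inter-frame time in the same units (1.0 when
    frames are indexed by integer frame number).
    """
    t = _frame_times(track)
    if len(t) == 0:
        return 0
    if np.any(np.diff(t) <= 0):
        raise ValueError("track frames must be strictly increasing")
    total = 1  # the first recorded position
    for k in range(1, len(t)):
        total += _nearest_int((t[k] - t[k - 1]) / dt)
    return total


def gap_structure(track, dt: float = 1.0) -> tuple[int, list[int]]:
    """Total missed positions N_Gaps and the individual gap sizes (frames).

    A gap occurs at step k when Int[Δt_k/Δt − 1] > 0; its size is that value.
    """
    t = _frame_times(track)
    sizes = []
    for k in range(1, len(t)):
        g = _nearest_int((t[k] - t[k - 1]) / dt - 1.0)
        if g > 0:
            sizes.append(g)
    return sum(sizes), sizes


def uninterrupted_lengths(track, dt: float = 1.0) -> list[int]:
    """Lengths (positions) of maximal runs with a detection at every frame step."""
    t = _frame_times(track)
    if len(t) == 0:
        return []
    runs, cur = [], 1
    for k in range(1, len(t)):
        if _nearest_int((t[k] - t[k - 1]) / dt) == 1:
            cur += 1
        else:
            runs.append(cur)
            cur = 1
    runs.append(cur)
    return runs


@dataclass
class TrackMetrics:
    """Per-track gap accounting (satisfies n + N_Gaps = N_t)."""

    n_positions: int
    n_t: int
    n_gaps: int
    gap_sizes: list[int]
    uninterrupted: list[int]

    @classmethod
    def from_track(cls, track, dt: float = 1.0) -> "TrackMetrics":
        n_gaps, sizes = gap_structure(track, dt)
        return cls(
            n_positions=len(_frame_times(track)),
            n_t=potential_positions(track, dt),
            n_gaps=n_gaps,
            gap_sizes=sizes,
            uninterrupted=uninterrupted_lengths(track, dt),
        )


@dataclass
class CohortMetrics:
    """Cohort-level summary stratified by across-net / outside-net region."""

    detected_positions_in_tracks: int = 0
    n_tracks: int = 0
    gap_size_mean: dict = dc_field(default_factory=dict)
    gap_size_sd: dict = dc_field(default_factory=dict)
    gaps_positions_ratio: dict = dc_field(default_factory=dict)
    average_track_length: float = 0.0
    average_uninterrupted_track_length: float = 0.0
    detected_pct: dict = dc_field(default_factory=dict)
    detected_pct_overall: float = 0.0

    def to_dict(self) -> dict:
        """Flat mapping with row names mirroring the standard report table."""
        g = lambda d, k: d.get(k, 0.0)
        return {
            "detected positions in tracks": self.detected_positions_in_tracks,
            "number of tracks": self.n_tracks,
            "mean gap size (frames) across net": g(self.gap_size_mean, ACROSS),
            "sd gap size (frames) across net": g(self.gap_size_sd, ACROSS),
            "gaps/positions ratio across net": g(self.gaps_positions_ratio, ACROSS),
            "mean gap size (frames) outside net": g(self.gap_size_mean, OUTSIDE),
            "sd gap size (frames) outside net": g(self.gap_size_sd, OUTSIDE),
            "gaps/positions ratio outside net": g(self.gaps_positions_ratio, OUTSIDE),
            "average track length": self.average_track_length,
            "average uninterrupted track length": self.average_uninterrupted_track_length,
            "detected mosquitoes across net (%)": g(self.detected_pct, ACROSS),
            "detected mosquitoes outside net (%)": g(self.detected_pct, OUTSIDE),
            "detected mosquitoes overall (%)": self.detected_pct_overall,
        }


def _stratum(region: str) -> str:
    try:
        return _STRATUM_OF[region]
    except KeyError:
        raise ValueError(f"unknown region label {region!r}") from None


def cohort_summary(tracks: list[Track], dt: float = 1.0) -> CohortMetrics:
    """Aggregate track metrics over a recording, stratified by region.

    Every recorded position carries a region label; a gap is attributed to the
    region of its two flanking detections, split half and half when they
    differ.  Per-region detection percentage is detected positions over
    detected-plus-missed positions in that region; the overall percentage is
    Σn / ΣN_t over all tracks.
    """
    m = CohortMetrics()
    if not tracks:
        warnings.warn("cohort_summary: no tracks; returning all-zero summary",
                      stacklevel=2)
        return m

    detected = {ACROSS: 0.0, OUTSIDE: 0.0}
    missed = {ACROSS: 0.0, OUTSIDE: 0.0}
    # gap events as (size, weight) per stratum: weight 0.5 each side for
    # gaps spanning the net boundary
    gap_events = {ACROSS: [], OUTSIDE: []}
    lengths, uninterrupted = [], []

    for tr in tracks:
        pts = tr.points
        lengths.append(tr.n)
        uninterrupted.extend(uninterrupted_lengths(tr, dt))
        for i, (f, x, y, region, _) in enumerate(pts):
            detected[_stratum(region)] += 1.0
            if i == 0:
                continue
            g = _nearest_int((f - pts[i - 1][0]) / dt - 1.0)
            if g > 0:
                s_prev = _stratum(pts[i - 1][3])
                s_cur = _stratum(region)
                if s_prev == s_cur:
                    gap_events[s_cur].append((g, 1.0))
                    missed[s_cur] += g
                else:
                    gap_events[s_prev].append((g, 0.5))
                    gap_events[s_cur].append((g, 0.5))
                    missed[s_prev] += g / 2.0
                    missed[s_cur] += g / 2.0

    m.n_tracks = len(tracks)
    m.detected_positions_in_tracks = int(detected[ACROSS] + detected[OUTSIDE])
    m.average_track_length = float(np.mean(lengths))
    m.average_uninterrupted_track_length = float(np.mean(uninterrupted))
    for s in (ACROSS, OUTSIDE):
        sizes = np.array([g for g, _ in gap_events[s]], dtype=float)
        weights = np.array([w for _, w in gap_events[s]], dtype=float)
        if weights.sum() > 0:
            mean = float(np.average(sizes, weights=weights))
            var = float(np.average((sizes - mean) ** 2, weights=weights))
            m.gap_size_mean[s] = mean
            m.gap_size_sd[s] = math.sqrt(var)
        else:
            m.gap_size_mean[s] = 0.0
            m.gap_size_sd[s] = 0.0
        m.gaps_positions_ratio[s] = (
            float(weights.sum() / detected[s]) if detected[s] else 0.0
        )
        potential = detected[s] + missed[s]
        m.detected_pct[s] = 100.0 * detected[s] / potential if potential else 0.0
    total_detected = detected[ACROSS] + detected[OUTSIDE]
    total_potential = total_detected + missed[ACROSS] + missed[OUTSIDE]
    m.detected_pct_overall = (
        100.0 * total_detected / total_potential if total_potential else 0.0
    )
    return m


def power_density(total_source_w: float, scene_volume_m3: float) -> float:
    """Optical power density (W m⁻³) of a recording rig, to 2 significant figures.

    A planning aid: e.g. 0.88 W spread over a 4.8 m³ scene gives 0.18 W m⁻³.
    """
    if scene_volume_m3 <= 0:
        raise ValueError("scene volume must be positive")
    if total_source_w < 0:
        raise ValueError("source power must be >= 0")
    if total_source_w == 0:
        return 0.0
    q = total_source_w / scene_volume_m3
    ndigits = 1 - int(math.floor(math.log10(abs(q))))
    return round(q, ndigits)
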