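"""Two-pass linking of per-frame detections into flight tracks.

Pass 1 performs greedy mutual-nearest-neighbour association frame to frame,
tolerating at most a single missing position at a time; fragments with fewer
than five positions are discarded.  Pass 2 lengthens and combines the
surviving fragments by bridging gaps of up to 15 frames, ranking merge
candidates by straight-line extrapolation cost.  Both passes are
deterministic: ties are broken by smaller distance, then lower fragment /
detection index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class TrackingConfig:
    """Association gates and track acceptance rules.

    ``max_link_dist_px`` is the per-frame-step association gate: 40 px at
    0.5 mm/px and 50 fps corresponds to a ~1 m/s flight speed.  The pass-1
    rules (one missing position at a time, minimum five positions) and the
    pass-2 gap cap of 15 frames define which candidate tracks survive.
    """

    max_link_dist_px: float = 40.0
    pass1_max_missing: int = 1
    pass1_min_positions: int = 5
    pass2_max_gap: int = 15
    pass2_cost_per_frame_px: float = 12.0
    frame_rate_hz: float = 50.0

    def __post_init__(self) -> None:
        if self.max_link_dist_px <= 0:
            raise ValueError("max_link_dist_px must be > 0")
        if self.pass2_max_gap < self.pass1_max_missing:
            raise ValueError("pass2_max_gap must be >= pass1_max_missing")
        if self.pass1_min_positions < 1:
            raise ValueError("pass1_min_positions must be >= 1")


@dataclass
class Track:
    """A time-ordered sequence of detections attributed to one mosquito.

    ``points`` rows are ``(frame, x_px, y_px, region, detection_index)`` with
    strictly increasing frames; ``detection_index`` is the row index into the
    detection table each position originated from.
    """

    id: int
    points: list[tuple[int, float, float, str, int]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.points], dtype=int)

    @property
    def first_frame(self) -> int:
        return self.points[0][0]

    @property
    def last_frame(self) -> int:
        return self.points[-1][0]

    def end_velocity(self) -> tuple[float, float]:
        """Per-frame velocity over the final recorded step (0 for single points)."""
        if self.n < 2:
            return 0.0, 0.0
        f0, x0, y0, *_ = self.points[-2]
        f1, x1, y1, *_ = self.points[-1]
        dt = f1 - f0
        return (x1 - x0) / dt, (y1 - y0) / dt


def _detections_by_frame(detections: pd.DataFrame):
    cols = ["frame", "x_px", "y_px"]
    for c in cols:
        if c not in detections.columns:
            raise ValueError(f"detection table lacks required column {c!r}")
    det = detections.reset_index(drop=True)
    regions = det["region"] if "region" in det.columns else pd.Series(
        ["background"] * len(det)
    )
    order = np.argsort(det["frame"].to_numpy(), kind="stable")
    grouped: dict[int, list[tuple[int, float, float, str]]] = {}
    for i in order:
        f = int(det["frame"].iloc[i])
        grouped.setdefault(f, []).append(
            (i, float(det["x_px"].iloc[i]), float(det["y_px"].iloc[i]), str(regions.iloc[i]))
        )
    return grouped


def link_pass1(detections: pd.DataFrame, cfg: TrackingConfig | None = None) -> list[Track]:
    """Initial frame-to-frame association into track fragments.

    Detections in consecutive frames are linked greedily by centroid distance
    within ``max_link_dist_px``; a fragment may additionally bridge a single
    missing frame (distance budget doubled).  Two consecutive missing frames
    close the fragment.  Fragments with fewer than ``pass1_min_positions``
    recorded positions are discarded.
    """
    cfg = cfg or TrackingConfig()
    grouped = _detections_by_frame(detections)
    open_tracks: list[Track] = []
    done: list[Track] = []
    next_id = 0
    for f in sorted(grouped):
        dets = grouped[f]
        # retire fragments that can no longer be extended
        still_open = []
        for tr in open_tracks:
            if f - tr.last_frame > cfg.pass1_max_missing + 1:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        pairs = []
        for ti, tr in enumerate(open_tracks):
            gap = f - tr.last_frame
            if gap < 1:
                continue
            gate = cfg.max_link_dist_px * gap
            _, tx, ty, *_ = tr.points[-1]
            for di, (_, dx, dy, _) in enumerate(dets):
                dist = float(np.hypot(dx - tx, dy - ty))
                if dist <= gate:
                    pairs.append((dist, ti, di))
        pairs.sort()
        used_t: set[int] = set()
        used_d: set[int] = set()
        for dist, ti, di in pairs:
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            idx, dx, dy, region = dets[di]
            open_tracks[ti].points.append((f, dx, dy, region, idx))
        for di, (idx, dx, dy, region) in enumerate(dets):
            if di not in used_d:
                open_tracks.append(Track(next_id, [(f, dx, dy, region, idx)]))
                next_id += 1
    done.extend(open_tracks)
    kept = [t for t in done if t.n >= cfg.pass1_min_positions]
    kept.sort(key=lambda t: (t.first_frame, t.id))
    for new_id, t in enumerate(kept):
        t.id = new_id
    logger.info("pass 1: %d fragments kept of %d started", len(kept), next_id)
    return kept


def link_pass2(fragments: list[Track], cfg: TrackingConfig | None = None) -> list[Track]:
    """Merge track fragments across gaps of up to ``pass2_max_gap`` frames.

    A fragment pair (A, B) is a merge candidate when B starts 1–15 frames
    after A ends, the end→start distance is within ``max_link_dist_px × gap``
    and the extrapolation error stays below ``pass2_cost_per_frame_px`` per
    bridged frame (the bridge must be consistent with a plausible flight
    continuation).  Candidates are ranked by gap length first,
    then by straight-line extrapolation cost (distance between A's end
    extrapolated at its final velocity and B's start): the true continuation
    of a briefly lost track almost always resumes within a frame or two, so
    short bridges take precedence over speculative long ones.  Each fragment
    end and start is merged at most once, so chains form transitively in a
    single pass.  Remaining ties fall back to the earlier fragment id,
    deterministically.
    """
    cfg = cfg or TrackingConfig()
    frags = sorted(fragments, key=lambda t: (t.first_frame, t.id))
    candidates = []
    for a in frags:
        vx, vy = a.end_velocity()
        _, ax, ay, *_ = a.points[-1]
        for b in frags:
            if b.id == a.id:
                continue
            gap = b.first_frame - a.last_frame
            if not 1 <= gap <= cfg.pass2_max_gap:
                continue
            _, bx, by, *_ = b.points[0]
            if np.hypot(bx - ax, by - ay) > cfg.max_link_dist_px * gap:
                continue
            cost = float(np.hypot(bx - (ax + vx * gap), by - (ay + vy * gap)))
            if cost > cfg.pass2_cost_per_frame_px * gap:
                continue
            candidates.append((gap, cost, a.id, b.id))
    candidates.sort()
    succ: dict[int, int] = {}
    has_pred: set[int] = set()
    tied = {}
    for gap, cost, aid, bid in candidates:
        if aid in succ or bid in has_pred:
            if aid in succ and (gap, cost, aid) in tied and tied[(gap, cost, aid)] != bid:
                logger.debug(
                    "pass 2: ambiguous merge for fragment %d at cost %.3f; "
                    "kept earlier candidate", aid, cost,
                )
            continue
        succ[aid] = bid
        has_pred.add(bid)
        tied[(gap, cost, aid)] = bid

    by_id = {t.id: t for t in frags}
    merged: list[Track] = []
    for t in frags:
        if t.id in has_pred:
            continue
        chain = Track(t.id, list(t.points))
        cur = t.id
        while cur in succ:
            cur = succ[cur]
            chain.points.extend(by_id[cur].points)
        merged.append(chain)
    merged.sort(key=lambda t: (t.first_frame, t.id))
    for new_id, t in enumerate(merged):
        t.id = new_id
    logger.info("pass 2: %d tracks from %d fragments", len(merged), len(frags))
    return merged


def build_tracks(detections: pd.DataFrame, cfg: TrackingConfig | None = None) -> list[Track]:
    """Full two-pass tracking: :func:`link_pass1` then :func:`link_pass2`."""
    cfg = cfg or TrackingConfig()
    return link_pass2(link_pass1(detections, cfg), cfg)


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Tracks as a tidy table (columns track_id, frame, x_px, y_px, region)."""
    rows = [
        (t.id, f, x, y, region)
        for t in tracks
        for (f, x, y, region, _) in t.points
    ]
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px", "region"])


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    """Rebuild :class:`Track` objects from a table written by :func:`tracks_to_frame`."""
    tracks = []
    for tid, group in df.groupby("track_id"):
        group = group.sort_values("frame")
        points = [
            (int(r.frame), float(r.x_px), float(r.y_px), str(r.region), -1)
            for r in group.itertuples(index=False)
        ]
        tracks.append(Track(int(tid), points))
    tracks.sort(key=lambda t: (t.first_frame, t.id))
    return tracks
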