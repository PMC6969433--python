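"""Link localizations into per-molecule binding events.

Bound molecules are assumed stationary, so an event is a run of
localizations at (nearly) the same position in consecutive frames, with a
small tolerated number of missing frames (fluorophore blinking or missed
detections).  Linking is greedy nearest-neighbour: localizations in frame
``f`` join the closest open event within ``radius_px`` whose last
supporting frame is recent enough; the rest open new events.

Events touching the first or last frame of the stack are censored: their
total residence time cannot be determined, so they are excluded from
dwell-time fits (but counted and reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BindingEvent",
    "link_events",
    "censor_events",
    "event_table",
    "write_events",
    "read_events",
]

EVENT_COLUMNS = [
    "event_id",
    "mean_x_px",
    "mean_y_px",
    "start_frame",
    "end_frame",
    "n_frames",
    "duration_s",
    "n_locs",
    "n_gaps",
    "touches_start",
    "touches_end",
    "region",
]


@dataclass
class BindingEvent:
    """One molecule's contiguous presence at a location."""

    event_id: int
    mean_x_px: float
    mean_y_px: float
    start_frame: int
    end_frame: int
    duration_s: float
    n_locs: int
    n_gaps: int
    touches_start: bool = False
    touches_end: bool = False
    region: str = "unassigned"
    support_index: list[int] = field(default_factory=list, repr=False, compare=False)

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


class _OpenTrack:
    __slots__ = ("event_id", "last_x", "last_y", "last_frame", "sum_x", "sum_y",
                 "n", "start_frame", "support")

    def __init__(self, event_id: int, x: float, y: float, frame: int, index: int):
        self.event_id = event_id
        self.last_x = x
        self.last_y = y
        self.last_frame = frame
        self.sum_x = x
        self.sum_y = y
        self.n = 1
        self.start_frame = frame
        self.support = [index]

    def extend(self, x: float, y: float, frame: int, index: int) -> None:
        self.last_x = x
        self.last_y = y
        self.last_frame = frame
        self.sum_x += x
        self.sum_y += y
        self.n += 1
        self.support.append(index)


def link_events(
    localizations: pd.DataFrame,
    radius_px: float = 1.0,
    max_gap_frames: int = 1,
    frame_interval_s: float = 1.0,
    n_frames_total: int | None = None,
) -> list[BindingEvent]:
    """Greedy frame-to-frame nearest-neighbour linking.

    A localization in frame ``f`` joins the open event whose last position
    is within ``radius_px`` and whose last supporting frame is at least
    ``f - 1 - max_gap_frames``; candidate pairs are assigned in order of
    distance (ties to the lowest event id).  Unmatched localizations open
    new events; events unmatched for more than ``max_gap_frames`` frames
    close.  Every localization supports exactly one event.

    ``n_frames_total`` (if given) sets the censoring flags
    ``touches_start`` / ``touches_end``; :func:`censor_events` can also set
    them later.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    if len(localizations) == 0:
        return []

    locs = localizations.sort_values(["frame", "y_px", "x_px"], kind="mergesort")
    frames = locs["frame"].to_numpy().astype(int)
    xs = locs["x_px"].to_numpy()
    ys = locs["y_px"].to_numpy()
    order_index = locs.index.to_numpy()

    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    next_id = 0
    i = 0
    n = len(frames)
    while i < n:
        f = frames[i]
        j = i
        while j < n and frames[j] == f:
            j += 1
        # retire stale tracks
        still_open = []
        for tr in open_tracks:
            if tr.last_frame >= f - 1 - max_gap_frames:
                still_open.append(tr)
            else:
                closed.append(tr)
        open_tracks = still_open

        idx = np.arange(i, j)
        if open_tracks and len(idx):
            tx = np.array([t.last_x for t in open_tracks])
            ty = np.array([t.last_y for t in open_tracks])
            d = np.hypot(
                xs[idx][:, None] - tx[None, :], ys[idx][:, None] - ty[None, :]
            )
            pairs = []
            for a in range(len(idx)):
                for b in range(len(open_tracks)):
                    if d[a, b] <= radius_px:
                        pairs.append((d[a, b], open_tracks[b].event_id, a, b))
            pairs.sort()
            used_locs: set[int] = set()
            used_tracks: set[int] = set()
            for _, _, a, b in pairs:
                if a in used_locs or b in used_tracks:
                    continue
                used_locs.add(a)
                used_tracks.add(b)
                k = idx[a]
                open_tracks[b].extend(xs[k], ys[k], f, int(order_index[k]))
        else:
            used_locs = set()

        for a in range(len(idx)):
            if a in used_locs:
                continue
            k = idx[a]
            open_tracks.append(
                _OpenTrack(next_id, xs[k], ys[k], f, int(order_index[k]))
            )
            next_id += 1
        i = j

    closed.extend(open_tracks)
    events = []
    for tr in closed:
        n_frames = tr.last_frame - tr.start_frame + 1
        ev = BindingEvent(
            event_id=tr.event_id,
            mean_x_px=tr.sum_x / tr.n,
            mean_y_px=tr.sum_y / tr.n,
            start_frame=tr.start_frame,
            end_frame=tr.last_frame,
            duration_s=n_frames * frame_interval_s,
            n_locs=tr.n,
            n_gaps=n_frames - tr.n,
            support_index=tr.support,
        )
        if n_frames_total is not None:
            ev.touches_start = ev.start_frame == 0
            ev.touches_end = ev.end_frame == n_frames_total - 1
        events.append(ev)
    events.sort(key=lambda e: (e.start_frame, e.mean_y_px, e.mean_x_px))
    return events


def censor_events(
    events: list[BindingEvent], n_frames_total: int
) -> tuple[list[BindingEvent], int]:
    """Drop events whose total residence time is unobservable.

    An event present in the first or last frame of the stack may have
    started before the movie or outlasted it; such events are excluded
    from the kept list.  Returns ``(kept, n_excluded)``.
    """
    if n_frames_total < 2:
        raise ValueError("n_frames_total must be >= 2")
    kept: list[BindingEvent] = []
    excluded = 0
    for ev in events:
        ev.touches_start = ev.start_frame == 0
        ev.touches_end = ev.end_frame == n_frames_total - 1
        if ev.touches_start or ev.touches_end:
            excluded += 1
        else:
            kept.append(ev)
    return kept, excluded


def event_table(events: list[BindingEvent]) -> pd.DataFrame:
    """Events as a DataFrame sorted by start frame, then mean position."""
    rows = [
        {
            "event_id": e.event_id,
            "mean_x_px": e.mean_x_px,
            "mean_y_px": e.mean_y_px,
            "start_frame": e.start_frame,
            "end_frame": e.end_frame,
            "n_frames": e.n_frames,
            "duration_s": e.duration_s,
            "n_locs": e.n_locs,
            "n_gaps": e.n_gaps,
            "touches_start": e.touches_start,
            "touches_end": e.touches_end,
            "region": e.region,
        }
        for e in events
    ]
    table = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return table.sort_values(
        ["start_frame", "mean_y_px", "mean_x_px"], kind="mergesort"
    ).reset_index(drop=True)


def write_events(path, events: list[BindingEvent] | pd.DataFrame) -> None:
    table = events if isinstance(events, pd.DataFrame) else event_table(events)
    table.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)
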