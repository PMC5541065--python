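"""Seafloor topographic profiles from diver sensor tracks, and rugosity.

The instrument logs its own depth (pressure sensor, positive down) and its
altitude above the seafloor (single-beam acoustic altimeter) at 1 Hz; their
sum is the seafloor depth under the track. Along-track distance is assigned
by a constant-speed assumption over the transect length — the dominant
approximation, as the diver carries no positioning beyond heading and
acceleration. The arc-chord rugosity index is the contoured profile length
divided by the planar (chord) length: 1 for a flat bottom, larger for more
structurally complex terrain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SensorTrack", "TopoProfile", "fuse_bottom_profile", "rugosity", "read_track_csv"]


@dataclass
class SensorTrack:
    """1-Hz diver log: timestamps (s), depth (m, positive down), altitude (m),
    and optional PAR / O2 / pH channels. Missing values are NaN."""

    timestamps: np.ndarray
    depth: np.ndarray
    altitude: np.ndarray
    par: np.ndarray | None = None
    o2: np.ndarray | None = None
    ph: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.altitude = np.asarray(self.altitude, dtype=float)
        n = self.timestamps.size
        if self.depth.size != n or self.altitude.size != n:
            raise ValueError("timestamps, depth and altitude must have equal length")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.depth[np.isfinite(self.depth)] < 0):
            raise ValueError("depth must be >= 0 (positive-down convention)")
        if np.any(self.altitude[np.isfinite(self.altitude)] <= 0):
            raise ValueError("altitude must be > 0 where present")
        for name in ("par", "o2", "ph"):
            ch = getattr(self, name)
            if ch is not None:
                ch = np.asarray(ch, dtype=float)
                if ch.size != n:
                    raise ValueError(f"{name} channel length mismatch")
                setattr(self, name, ch)


@dataclass
class TopoProfile:
    """Along-transect seafloor profile: distance (m, increasing) vs bottom
    depth (m, positive down). ``segments`` lists contiguous index ranges;
    more than one segment means the source track had gaps too long to
    interpolate."""

    distance: np.ndarray
    bottom_depth: np.ndarray
    segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.bottom_depth = np.asarray(self.bottom_depth, dtype=float)
        if self.distance.size < 2:
            raise ValueError("profile needs at least 2 points")
        if self.distance.size != self.bottom_depth.size:
            raise ValueError("distance and depth length mismatch")
        if not np.all(np.diff(self.distance) > 0):
            raise ValueError("distance must be strictly increasing")
        if not np.all(np.isfinite(self.bottom_depth)):
            raise ValueError("bottom depths must be finite")
        if not self.segments:
            self.segments = ((0, self.distance.size),)


def read_track_csv(path) -> SensorTrack:
    """Read a sensor CSV with columns ``t_s, depth_m, altitude_m[, par, o2, ph]``."""
    df = pd.read_csv(path)
    for col in ("t_s", "depth_m", "altitude_m"):
        if col not in df.columns:
            raise ValueError(f"sensor CSV missing required column '{col}'")
    opt = {name: df[col].to_numpy(float) for name, col in
           (("par", "par"), ("o2", "o2"), ("ph", "ph")) if col in df.columns}
    return SensorTrack(
        df["t_s"].to_numpy(float), df["depth_m"].to_numpy(float),
        df["altitude_m"].to_numpy(float), **opt,
    )


def write_track_csv(track: SensorTrack, path) -> None:
    data = {"t_s": track.timestamps, "depth_m": track.depth, "altitude_m": track.altitude}
    for name in ("par", "o2", "ph"):
        ch = getattr(track, name)
        if ch is not None:
            data[name] = ch
    pd.DataFrame(data).to_csv(path, index=False)


def fuse_bottom_profile(
    track: SensorTrack,
    transect_length: float,
    max_gap: float = 5.0,
) -> TopoProfile:
    """Fuse depth + altitude into a seafloor profile with constant-speed distance.

    bottom_depth(t) = depth(t) + altitude(t); distance(t) maps linearly from
    elapsed time onto [0, transect_length]. Leading/trailing invalid samples
    are dropped; interior gaps up to ``max_gap`` seconds are linearly
    interpolated; longer gaps split the profile into segments (rugosity is
    then reported per segment).
    """
    if transect_length <= 0:
        raise ValueError("transect_length must be > 0")
    t = track.timestamps
    bottom = track.depth + track.altitude
    valid = np.isfinite(bottom)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid (depth, altitude) pairs")

    first, last = np.argmax(valid), len(valid) - 1 - np.argmax(valid[::-1])
    t = t[first : last + 1]
    bottom = bottom[first : last + 1]
    valid = valid[first : last + 1]

    # split where an invalid run spans more than max_gap seconds
    breaks: list[int] = []
    i = 0
    while i < len(valid):
        if not valid[i]:
            j = i
            while j < len(valid) and not valid[j]:
                j += 1
            if t[j] - t[i - 1] > max_gap:
                breaks.append(i)
                breaks.append(j)
            i = j
        else:
            i += 1

    if np.any(~valid):
        bottom = bottom.copy()
        bottom[~valid] = np.interp(t[~valid], t[valid], bottom[valid])

    t0, tN = track.timestamps[0], track.timestamps[-1]
    distance = transect_length * (t - t0) / (tN - t0)

    if not breaks:
        return TopoProfile(distance, bottom)

    # drop long-gap samples and record the surviving contiguous runs
    keep = np.ones(len(t), dtype=bool)
    segments: list[tuple[int, int]] = []
    bounds = [0] + breaks + [len(t)]
    out_start = 0
    for k in range(0, len(bounds) - 1):
        a, b = bounds[k], bounds[k + 1]
        if k % 2 == 1:  # inside a long gap
            keep[a:b] = False
        else:
            segments.append((out_start, out_start + (b - a)))
            out_start += b - a
    return TopoProfile(distance[keep], bottom[keep], tuple(s for s in segments if s[1] - s[0] >= 2))


def _arc_chord(distance: np.ndarray, depth: np.ndarray) -> float:
    chord = distance[-1] - distance[0]
    if chord <= 0:
        raise ValueError("zero planar span; rugosity undefined")
    contour = float(np.sum(np.hypot(np.diff(distance), np.diff(depth))))
    return contour / chord


def rugosity(profile: TopoProfile, window: float | str = "whole"):
    """Arc-chord rugosity: contoured length / planar length, always >= 1.

    ``window="whole"`` returns one scalar per contiguous segment (a plain
    float when the profile has a single segment). A numeric ``window`` (m)
    computes the index over non-overlapping windows within each segment;
    the last partial window is dropped. Returns an ndarray in windowed or
    multi-segment mode.
    """
    if window == "whole":
        out = [
            _arc_chord(profile.distance[a:b], profile.bottom_depth[a:b])
            for a, b in profile.segments
        ]
        return out[0] if len(out) == 1 else np.asarray(out)

    window = float(window)
    span = profile.distance[-1] - profile.distance[0]
    if window <= 0 or window > span:
        raise ValueError(f"window must be in (0, {span:.3f}] m")
    results: list[float] = []
    for a, b in profile.segments:
        d = profile.distance[a:b]
        z = profile.bottom_depth[a:b]
        start = d[0]
        while start + window <= d[-1] + 1e-12:
            sel = (d >= start - 1e-12) & (d <= start + window + 1e-12)
            if sel.sum() >= 2:
                results.append(_arc_chord(d[sel], z[sel]))
            start += window
    return np.asarray(results)
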