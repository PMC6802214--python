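"""Adhesion tracking over time and dynamics read-outs.

Adhesions segmented frame-by-frame are linked into tracks by maximal pixel
overlap (deterministic tie-breaks, no gap closing: a one-frame
disappearance ends a track).  The read-outs mirror live-imaging analyses
of adhesion turnover in stem-cell colonies: per-class lifetime and
maximal-size frequency distributions (lifetimes capped, by default at
105 min, to the shortest replicate movie) and the per-frame percentage of
the colony edge/centre covered by adhesions.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: default lifetime cap (minutes) — length of the shortest replicate movie
DEFAULT_LIFETIME_CAP_MIN = 105.0
#: default histogram bin widths
DEFAULT_LIFETIME_BIN_MIN = 15.0
DEFAULT_SIZE_BIN_UM2 = 0.5


@dataclass
class Track:
    track_id: int
    start_frame: int
    areas_um2: list[float]  # one entry per contiguous frame
    klass: str | None = None

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.areas_um2) - 1

    @property
    def n_frames(self) -> int:
        return len(self.areas_um2)

    @property
    def max_area_um2(self) -> float:
        return max(self.areas_um2)


@dataclass
class TrackSet:
    tracks: list[Track]
    frame_interval_min: float
    pixel_um: float

    def lifetimes_min(self, cap_min: float | None = None) -> np.ndarray:
        lt = np.array([t.n_frames * self.frame_interval_min for t in self.tracks])
        if cap_min is not None:
            lt = np.minimum(lt, cap_min)
        return lt

    def by_class(self, klass: str) -> "TrackSet":
        return TrackSet(
            [t for t in self.tracks if t.klass == klass],
            self.frame_interval_min, self.pixel_um,
        )


@dataclass
class ClassDistribution:
    bin_edges: np.ndarray
    frequencies: np.ndarray  # sums to 1 for non-empty input
    n: int


@dataclass
class DynamicsSummary:
    lifetime: dict[str, ClassDistribution]
    max_size: dict[str, ClassDistribution]
    coverage_pct: dict[str, np.ndarray]  # per-frame %, NaN where mask empty


def _overlap_pairs(prev: np.ndarray, cur: np.ndarray):
    """Pixel-overlap counts between labels of consecutive frames."""
    both = (prev > 0) & (cur > 0)
    if not both.any():
        return {}
    keys, counts = np.unique(
        prev[both].astype(np.int64) << 32 | cur[both].astype(np.int64),
        return_counts=True,
    )
    return {(int(k >> 32), int(k & 0xFFFFFFFF)): int(c) for k, c in zip(keys, counts)}


def track_adhesions(
    label_stack,
    pixel_um: float,
    frame_interval_min: float = 1.0,
    edge_mask: np.ndarray | None = None,
) -> TrackSet:
    """Link per-frame labeled adhesion images into tracks by maximal pixel
    overlap.

    A region with no overlap in the previous frame starts a new track; a
    track with no successor ends.  Ties are broken by larger overlap area
    then smaller label; when a track splits, the largest fragment keeps the
    identity.  If ``edge_mask`` is given, each track is classed 'edge' or
    'centre' by the majority of its first-frame pixels.
    """
    stack = [np.asarray(f) for f in label_stack]
    shape = stack[0].shape
    if any(f.shape != shape for f in stack):
        raise ValueError("all frames must share the same shape")
    px_area = pixel_um**2
    tracks: list[Track] = []
    next_id = 0

    def new_track(frame_idx: int, area_px: int, label_img, lab) -> Track:
        nonlocal next_id
        klass = None
        if edge_mask is not None:
            pix = label_img == lab
            n_edge = int((pix & edge_mask).sum())
            klass = "edge" if 2 * n_edge > int(pix.sum()) else "centre"
        t = Track(track_id=next_id, start_frame=frame_idx, areas_um2=[area_px * px_area], klass=klass)
        next_id += 1
        tracks.append(t)
        return t

    # label -> Track mapping for the current frame
    prev_map: dict[int, Track] = {}
    prev_frame = None
    for fi, frame in enumerate(stack):
        labels, counts = np.unique(frame[frame > 0], return_counts=True)
        areas = dict(zip(labels.tolist(), counts.tolist()))
        cur_map: dict[int, Track] = {}
        if prev_frame is not None and prev_map:
            overlaps = _overlap_pairs(prev_frame, frame)
            # each current region picks its best previous label
            choice: dict[int, tuple[int, int]] = {}  # cur -> (overlap, prev)
            for (p, c), n in overlaps.items():
                if p not in prev_map:
                    continue
                best = choice.get(c)
                if best is None or n > best[0] or (n == best[0] and p < best[1]):
                    choice[c] = (n, p)
            # each previous track continues into its largest claiming fragment
            claim: dict[int, tuple[int, int]] = {}  # prev -> (overlap, cur)
            for c, (n, p) in choice.items():
                best = claim.get(p)
                if best is None or n > best[0] or (n == best[0] and c < best[1]):
                    claim[p] = (n, c)
            for p, (_, c) in claim.items():
                t = prev_map[p]
                t.areas_um2.append(areas[c] * px_area)
                cur_map[c] = t
        for lab, area_px in areas.items():
            if lab not in cur_map:
                cur_map[lab] = new_track(fi, area_px, frame, lab)
        prev_map, prev_frame = cur_map, frame
    return TrackSet(tracks=tracks, frame_interval_min=frame_interval_min, pixel_um=pixel_um)


def _frequency(values: np.ndarray, bin_width: float, upper: float) -> ClassDistribution:
    edges = np.arange(0.0, upper + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    counts, edges = np.histogram(np.clip(values, edges[0], edges[-1] - 1e-9), bins=edges)
    freq = counts / counts.sum() if counts.sum() else counts.astype(float)
    return ClassDistribution(bin_edges=edges, frequencies=freq, n=len(values))


def lifetime_distribution(
    tracks: TrackSet,
    cap_min: float = DEFAULT_LIFETIME_CAP_MIN,
    bin_width_min: float = DEFAULT_LIFETIME_BIN_MIN,
) -> dict[str, ClassDistribution]:
    """Per-class frequency distribution of capped lifetimes.

    Lifetime = frames present x frame interval, capped at ``cap_min``;
    frequencies are normalized per class.  An empty track set yields an
    empty dict.
    """
    if cap_min <= 0:
        raise ValueError("cap must be positive")
    out = {}
    for klass in sorted({t.klass for t in tracks.tracks if t.klass is not None} or {None}):
        sub = tracks.by_class(klass) if klass is not None else tracks
        if not sub.tracks:
            continue
        out[klass if klass is not None else "all"] = _frequency(
            sub.lifetimes_min(cap_min=cap_min), bin_width_min, cap_min
        )
    return out


def max_size_distribution(
    tracks: TrackSet, bin_width_um2: float = DEFAULT_SIZE_BIN_UM2
) -> dict[str, ClassDistribution]:
    """Per-class frequency distribution of each track's maximal area."""
    out = {}
    classes = sorted({t.klass for t in tracks.tracks if t.klass is not None} or {None})
    for klass in classes:
        sub = tracks.by_class(klass) if klass is not None else tracks
        if not sub.tracks:
            continue
        sizes = np.array([t.max_area_um2 for t in sub.tracks])
        out[klass if klass is not None else "all"] = _frequency(
            sizes, bin_width_um2, float(sizes.max()) + bin_width_um2
        )
    return out


def coverage_fraction(
    label_stack, edge_mask: np.ndarray, centre_mask: np.ndarray
) -> dict[str, np.ndarray]:
    """Per-frame percentage of each class region covered by adhesions.

    Returns arrays of ``100 * |adhesion pixels in mask| / |mask|`` per
    frame; a class with an empty mask gets NaN and a warning.
    """
    edge_mask = np.asarray(edge_mask, dtype=bool)
    centre_mask = np.asarray(centre_mask, dtype=bool)
    if (edge_mask & centre_mask).any():
        raise ValueError("edge and centre masks must be disjoint")
    out = {}
    for name, mask in (("edge", edge_mask), ("centre", centre_mask)):
        denom = int(mask.sum())
        if denom == 0:
            warnings.warn(f"{name} mask is empty: coverage undefined")
            out[name] = np.full(len(label_stack), np.nan)
            continue
        out[name] = np.array(
            [100.0 * int(((np.asarray(f) > 0) & mask).sum()) / denom for f in label_stack]
        )
    return out


def summarize_dynamics(
    label_stack,
    edge_mask: np.ndarray,
    centre_mask: np.ndarray,
    pixel_um: float,
    frame_interval_min: float = 1.0,
    cap_min: float = DEFAULT_LIFETIME_CAP_MIN,
) -> tuple[TrackSet, DynamicsSummary]:
    """Track a labeled movie and compute all three dynamics read-outs."""
    tracks = track_adhesions(
        label_stack, pixel_um=pixel_um,
        frame_interval_min=frame_interval_min, edge_mask=edge_mask,
    )
    summary = DynamicsSummary(
        lifetime=lifetime_distribution(tracks, cap_min=cap_min),
        max_size=max_size_distribution(tracks),
        coverage_pct=coverage_fraction(label_stack, edge_mask, centre_mask),
    )
    return tracks, summary
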