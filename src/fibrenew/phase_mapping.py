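"""Phase-singularity and wavefront detection, tracking and scale transforms.

A phase singularity (PS) is a pixel-scale topological defect: the
discrete line integral of wrapped phase differences around it is ±2pi.
Two detectors are provided — a convolutional plaquette-kernel method
(:func:`detect_ps_kernel`) and a double-ring method
(:func:`detect_ps_double_ring`) requiring consistent winding on two
concentric integration rings. Wavefronts are zero-phase isolines with
free ends terminating at PS (:func:`extract_wavefronts`). Per-frame
detections are associated through time by bipartite matching into an
:class:`~fibrenew.types.EventTable` (:func:`track_entities`).

Field-of-view cropping and density decimation
(:func:`crop_field`, :func:`decimate_and_interpolate`) support the
mapping-scale analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage import measure

from .signal_processing import interpolate_phase
from .types import (
    EVENT_COLUMNS,
    EventTable,
    ParameterError,
    PhaseMovie,
    PSDetection,
    TrackConfig,
    WavefrontDetection,
)

__all__ = [
    "wrap_diff",
    "detect_ps_kernel",
    "detect_ps_double_ring",
    "detect_movie",
    "extract_wavefronts",
    "extract_wavefronts_movie",
    "track_entities",
    "detections_to_frame",
    "decimate_and_interpolate",
    "crop_field",
]


def wrap_diff(d: np.ndarray) -> np.ndarray:
    """Wrap phase differences into ``[-pi, pi)``."""
    return np.mod(d + np.pi, 2.0 * np.pi) - np.pi


def _plaquette_circulation(frame: np.ndarray) -> np.ndarray:
    """Circulation of wrapped phase differences around every 2x2 plaquette.

    Entry ``[i, j]`` is the loop integral over corners
    (i,j) -> (i,j+1) -> (i+1,j+1) -> (i+1,j); values are multiples of
    2pi (0 or ±2pi for physical fields).
    """
    dx = wrap_diff(np.diff(frame, axis=1))  # H x (W-1)
    dy = wrap_diff(np.diff(frame, axis=0))  # (H-1) x W
    return dx[:-1, :] + dy[:, 1:] - dx[1:, :] - dy[:, :-1]


def detect_ps_kernel(frame: np.ndarray, mask: np.ndarray | None = None,
                     frame_index: int = 0) -> list[PSDetection]:
    """Plaquette topological-charge detector.

    Reports one detection per 2x2 plaquette whose circulation is ±2pi,
    at the plaquette center (half-integer coordinates); chirality is the
    sign of the circulation. Plaquettes touching masked pixels are
    skipped (detector blind spots).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 2:
        raise ParameterError("frame must be a 2-D grid of at least 2x2")
    circ = _plaquette_circulation(frame)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        valid = m[:-1, :-1] & m[:-1, 1:] & m[1:, :-1] & m[1:, 1:]
        circ = np.where(valid, circ, 0.0)
    iy, ix = np.nonzero(np.abs(circ) > np.pi)
    return [
        PSDetection(frame=frame_index, x=j + 0.5, y=i + 0.5,
                    chirality=int(np.sign(circ[i, j])), method="kernel")
        for i, j in zip(iy, ix)
    ]


def _ring_offsets(radius: int) -> np.ndarray:
    """Pixel offsets (dy, dx) of the Chebyshev ring at ``radius``,
    ordered counterclockwise (closed integration loop)."""
    pts = [(dy, dx) for dy in range(-radius, radius + 1)
           for dx in range(-radius, radius + 1)
           if max(abs(dy), abs(dx)) == radius]
    pts.sort(key=lambda p: np.arctan2(p[0], p[1]))
    return np.array(pts)


_RINGS = {1: _ring_offsets(1), 2: _ring_offsets(2)}


def _ring_winding(frame: np.ndarray, radius: int) -> np.ndarray:
    """Integer winding number of the phase around every pixel, integrated
    on the Chebyshev ring at ``radius``. Border pixels (incomplete ring)
    get winding 0."""
    H, W = frame.shape
    offs = _RINGS[radius] if radius in _RINGS else _ring_offsets(radius)
    total = np.zeros((H - 2 * radius, W - 2 * radius))
    for k in range(len(offs)):
        dy0, dx0 = offs[k]
        dy1, dx1 = offs[(k + 1) % len(offs)]
        a = frame[radius + dy0:H - radius + dy0, radius + dx0:W - radius + dx0]
        b = frame[radius + dy1:H - radius + dy1, radius + dx1:W - radius + dx1]
        total += wrap_diff(b - a)
    w = np.zeros((H, W), dtype=int)
    w[radius:H - radius, radius:W - radius] = np.round(total / (2.0 * np.pi)).astype(int)
    return w


def detect_ps_double_ring(frame: np.ndarray, mask: np.ndarray | None = None,
                          frame_index: int = 0,
                          radii: tuple[int, int] = (1, 2)) -> list[PSDetection]:
    """Double-ring topological-charge detector.

    A pixel is a PS candidate when the winding number is the same
    nonzero ±1 on both concentric rings around it. Adjacent candidate
    pixels enclosing the same defect are merged into one detection at
    their centroid. Defects closer than the outer ring radius to the
    boundary are not reported (the outer ring is incomplete there).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or min(frame.shape) < 2 * max(radii) + 1:
        raise ParameterError("frame too small for the double-ring detector")
    w1 = _ring_winding(frame, radii[0])
    w2 = _ring_winding(frame, radii[1])
    agree = (w1 == w2) & (np.abs(w1) == 1)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        r = max(radii)
        full = ndimage.minimum_filter(m.astype(int), size=2 * r + 1,
                                      mode="constant", cval=0) > 0
        agree &= full
    detections: list[PSDetection] = []
    for sign in (+1, -1):
        lab, n = ndimage.label(agree & (w1 == sign),
                               structure=np.ones((3, 3), dtype=int))
        if n:
            for cy, cx in ndimage.center_of_mass(agree & (w1 == sign), lab,
                                                 range(1, n + 1)):
                detections.append(PSDetection(frame=frame_index, x=float(cx),
                                              y=float(cy), chirality=sign,
                                              method="double_ring"))
    return detections


def detect_movie(movie: PhaseMovie, method: str = "kernel") -> list[list[PSDetection]]:
    """Run a PS detector on every frame of a movie."""
    detect = {"kernel": detect_ps_kernel,
              "double_ring": detect_ps_double_ring}.get(method)
    if detect is None:
        raise ParameterError(f"unknown detection method {method!r}")
    mask = None if movie.mask.all() else movie.mask
    return [detect(movie.values[t], mask=mask, frame_index=t)
            for t in range(movie.n_frames)]


def extract_wavefronts(frame: np.ndarray, frame_index: int = 0,
                       min_vertices: int = 2) -> list[WavefrontDetection]:
    """Zero-phase isolines by marching squares on the phasor.

    Contours of ``sin(phi)`` at level 0 contain both the ``phi = 0`` and
    ``phi = ±pi`` lines; vertices are kept only where ``cos(phi) > 0``
    (the zero-phase branch). Contour ends in the grid interior are free
    ends — they terminate at phase singularities.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0 and frame.flat[0] == 0:
        raise ParameterError("degenerate isoline: frame is identically zero phase")
    s, c = np.sin(frame), np.cos(frame)
    H, W = frame.shape
    fronts: list[WavefrontDetection] = []
    for contour in measure.find_contours(s, 0.0):
        cos_vals = ndimage.map_coordinates(c, contour.T, order=1)
        keep = cos_vals > 0.0
        # split into consecutive runs of kept vertices
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            if len(run) < min_vertices:
                continue
            poly_rc = contour[run]  # (row, col)
            poly = poly_rc[:, ::-1].copy()  # (x, y)
            ends = []
            for v in (poly[0], poly[-1]):
                on_boundary = (v[0] < 1.0 or v[1] < 1.0
                               or v[0] > W - 2.0 or v[1] > H - 2.0)
                if not on_boundary:
                    ends.append((float(v[0]), float(v[1])))
            fronts.append(WavefrontDetection(frame=frame_index, polyline=poly,
                                             endpoints=tuple(ends)))
    return fronts


def extract_wavefronts_movie(movie: PhaseMovie) -> list[list[WavefrontDetection]]:
    return [extract_wavefronts(movie.values[t], frame_index=t)
            for t in range(movie.n_frames)]


# ---------------------------------------------------------------------------
# Tracking
# ---------------------------------------------------------------------------


class _Track:
    __slots__ = ("tid", "first_frame", "last_frame", "x", "y", "chirality", "x0", "y0")

    def __init__(self, tid, frame, x, y, chirality):
        self.tid = tid
        self.first_frame = frame
        self.last_frame = frame
        self.x = x
        self.y = y
        self.x0 = x
        self.y0 = y
        self.chirality = chirality


def _match_ps(tracks, dets, radius_px, match_chirality, assignment):
    """Pair active tracks with detections; returns (pairs, unmatched_dets)."""
    if not tracks or not dets:
        return [], list(range(len(dets)))
    tp = np.array([[t.x, t.y] for t in tracks])
    dp = np.array([[d.x, d.y] for d in dets])
    dist = np.linalg.norm(tp[:, None, :] - dp[None, :, :], axis=2)
    feasible = dist <= radius_px
    if match_chirality:
        tc = np.array([t.chirality for t in tracks])
        dc = np.array([d.chirality for d in dets])
        feasible &= tc[:, None] == dc[None, :]
    big = radius_px * 1e6 + 1.0
    cost = np.where(feasible, dist, big)
    pairs = []
    if assignment == "optimal":
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if feasible[i, j]:
                pairs.append((i, j))
    else:  # greedy nearest-neighbor
        order = np.dstack(np.unravel_index(np.argsort(cost, axis=None), cost.shape))[0]
        used_t, used_d = set(), set()
        for i, j in order:
            if not feasible[i, j]:
                break
            if i in used_t or j in used_d:
                continue
            used_t.add(i)
            used_d.add(j)
            pairs.append((int(i), int(j)))
    matched_d = {j for _, j in pairs}
    return pairs, [j for j in range(len(dets)) if j not in matched_d]


def _match_wavefronts(tracks, dets, min_overlap, assignment):
    """Pair wavefront tracks with detections by shared-pixel overlap."""
    if not tracks or not dets:
        return [], list(range(len(dets)))
    overlap = np.zeros((len(tracks), len(dets)))
    det_sets = [d.pixel_set() for d in dets]
    for i, t in enumerate(tracks):
        for j, ds in enumerate(det_sets):
            overlap[i, j] = len(t.pixels & ds)
    feasible = overlap >= min_overlap
    cost = -overlap
    rows, cols = linear_sum_assignment(cost)
    pairs = [(i, j) for i, j in zip(rows, cols) if feasible[i, j]]
    matched_d = {j for _, j in pairs}
    return pairs, [j for j in range(len(dets)) if j not in matched_d]


class _WfTrack(_Track):
    __slots__ = ("pixels",)


def track_entities(detections: list[list], config: TrackConfig, dt_ms: float,
                   pixel_mm: float = 1.0, kind: str = "PS") -> EventTable:
    """Associate per-frame detections into tracked entities.

    Frame-to-frame association is a minimal-total-distance bipartite
    matching within the association radius ``config.r`` (PS additionally
    matched by chirality when ``config.match_chirality``); wavefronts
    are matched by shared-pixel polyline overlap. Unmatched detections
    open new entities, unmatched entities close, and entities observed
    for less than ``config.tau_ms`` are discarded. Intervals are
    half-open: an entity seen in frames ``[f0, f1]`` has
    ``onset = f0 * dt`` and ``offset = (f1 + 1) * dt``.
    """
    n_frames = len(detections)
    radius_px = config.radius_px(pixel_mm)
    is_ps = kind == "PS"
    active: list = []
    closed: list = []
    next_id = 0
    for f in range(n_frames):
        dets = detections[f]
        if is_ps:
            pairs, new_idx = _match_ps(active, dets, radius_px,
                                       config.match_chirality, config.assignment)
        else:
            pairs, new_idx = _match_wavefronts(active, dets, config.min_overlap,
                                               config.assignment)
        matched_t = set()
        # deterministic tie-break: extend lowest entity id first
        for i, j in sorted(pairs, key=lambda p: active[p[0]].tid):
            t = active[i]
            d = dets[j]
            t.last_frame = f
            if is_ps:
                t.x, t.y = d.x, d.y
            else:
                t.x, t.y = d.centroid
                t.pixels = d.pixel_set()
            matched_t.add(i)
        survivors = []
        for i, t in enumerate(active):
            if i in matched_t:
                survivors.append(t)
            else:
                closed.append(t)
        for j in sorted(new_idx):
            d = dets[j]
            if is_ps:
                t = _Track(next_id, f, d.x, d.y, d.chirality)
            else:
                cx, cy = d.centroid
                t = _WfTrack(next_id, f, cx, cy, 0)
                t.pixels = d.pixel_set()
            next_id += 1
            survivors.append(t)
        active = survivors
    closed.extend(active)
    alive_ids = {t.tid for t in active}

    rows = []
    for t in sorted(closed, key=lambda t: t.tid):
        onset = t.first_frame * dt_ms
        offset = (t.last_frame + 1) * dt_ms
        if offset - onset < config.tau_ms:
            continue
        rows.append({
            "id": t.tid,
            "kind": kind,
            "onset_ms": onset,
            "offset_ms": offset,
            "x": t.x0,
            "y": t.y0,
            "chirality": t.chirality,
            "censored_left": t.first_frame == 0,
            "censored_right": t.tid in alive_ids,
        })
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if len(df):
        df["id"] = np.arange(len(df))
    meta = {"tracker": "bipartite", "r_px": radius_px, "tau_ms": config.tau_ms,
            "assignment": config.assignment, "dt_ms": dt_ms}
    return EventTable(df, epoch_ms=n_frames * dt_ms, metadata=meta)


def detections_to_frame(detections: list[list[PSDetection]]) -> pd.DataFrame:
    """Flatten per-frame detections into the detections CSV layout."""
    rows = [
        {"frame": d.frame, "x": d.x, "y": d.y, "chirality": d.chirality,
         "method": d.method}
        for frame_dets in detections for d in frame_dets
    ]
    return pd.DataFrame(rows, columns=["frame", "x", "y", "chirality", "method"])


# ---------------------------------------------------------------------------
# Scale transforms
# ---------------------------------------------------------------------------


def decimate_and_interpolate(movie: PhaseMovie, keep_shape: tuple[int, int],
                             analysis_shape: tuple[int, int] | None = None) -> PhaseMovie:
    """Coarse-grain to ``keep_shape`` uniformly spaced pixels, then
    phasor-interpolate back to ``analysis_shape`` (default: the original
    resolution) — emulating lower electrode density at a fixed field of
    view."""
    H, W = movie.shape
    kh, kw = keep_shape
    if kh < 2 or kw < 2:
        raise ParameterError("keep_shape must be at least 2 x 2")
    if kh > H or kw > W:
        raise ParameterError("keep_shape cannot exceed the movie shape")
    if analysis_shape is None:
        analysis_shape = (H, W)
    if (kh, kw) == (H, W) and analysis_shape == (H, W):
        return PhaseMovie(movie.values.copy(), movie.dt_ms, movie.pixel_mm,
                          movie.mask.copy(), dict(movie.metadata))
    rows = np.round(np.linspace(0, H - 1, kh)).astype(int)
    cols = np.round(np.linspace(0, W - 1, kw)).astype(int)
    sub = movie.values[:, rows][:, :, cols]
    sub_mask = movie.mask[rows][:, cols]
    T = movie.n_frames
    out = np.empty((T, analysis_shape[0], analysis_shape[1]))
    for t in range(T):
        out[t] = interpolate_phase(sub[t], analysis_shape, mask=sub_mask)
    zoom = (analysis_shape[0] / kh, analysis_shape[1] / kw)
    mask = ndimage.zoom(sub_mask.astype(float), zoom, order=0, grid_mode=True,
                        mode="nearest") > 0.5
    meta = dict(movie.metadata)
    meta.update({"decimated_from": (H, W), "keep_shape": (kh, kw)})
    pixel_mm = movie.pixel_mm * (H - 1) / max(analysis_shape[0] - 1, 1)
    return PhaseMovie(out, movie.dt_ms, pixel_mm, mask, meta)


def crop_field(movie: PhaseMovie, window: tuple[int, int, int, int]) -> PhaseMovie:
    """Restrict the field of view to ``window = (row0, row1, col0, col1)``
    (half-open). Entities drifting out of the window become boundary
    deaths downstream."""
    r0, r1, c0, c1 = window
    H, W = movie.shape
    if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
        raise ParameterError(f"window {window} not inside grid {movie.shape}")
    meta = dict(movie.metadata)
    meta["crop_window"] = window
    return PhaseMovie(movie.values[:, r0:r1, c0:c1], movie.dt_ms, movie.pixel_mm,
                      movie.mask[r0:r1, c0:c1], meta)
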