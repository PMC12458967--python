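"""Midline extraction and the mean-subtracted posture-angle representation.

Pipeline: binary mask -> skeleton -> ordered, pruned, smoothed polyline ->
arc-length resampling to ``n_points`` -> tangent angles at the N-1 segments,
unwrapped along the body and mean-subtracted.  The mean subtraction removes
global orientation; translation never enters.  Head identity is not
resolved — only frame-to-frame orientation consistency is enforced, which is
all the amplitude statistics need (they are invariant to a global flip).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import gaussian_filter1d
from skimage.measure import label
from skimage.morphology import skeletonize

from .containers import MidlineSeries, PostureAngleSeries
from .errors import CoiledFrameError, GeometryError, ParameterError, SegmentationError

logger = logging.getLogger(__name__)

__all__ = [
    "extract_midline_from_mask",
    "resample_arclength",
    "to_angle_vector",
    "to_curvature_vector",
    "flip_vector",
    "orient_frames",
    "midlines_to_posture",
    "masks_to_posture",
]

# 8-neighbourhood offsets and their step lengths
_OFFS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_SQRT2 = float(np.sqrt(2.0))


def _skeleton_graph(skel: np.ndarray) -> tuple[list[tuple[int, int]], dict, dict]:
    """Adjacency of skeleton pixels under 8-connectivity."""
    pix = list(map(tuple, np.argwhere(skel)))
    index = {p: i for i, p in enumerate(pix)}
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(len(pix))}
    for p, i in index.items():
        for dr, dc in _OFFS:
            q = (p[0] + dr, p[1] + dc)
            j = index.get(q)
            if j is not None:
                adj[i].append((j, _SQRT2 if dr and dc else 1.0))
    return pix, index, adj


def _geodesic(adj: dict, start: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Dijkstra over the (tiny, unit-ish weighted) skeleton graph."""
    import heapq

    dist = np.full(n, np.inf)
    prev = np.full(n, -1, dtype=int)
    dist[start] = 0.0
    heap = [(0.0, start)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v, w in adj[u]:
            nd = d + w
            if nd < dist[v]:
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, v))
    return dist, prev


def extract_midline_from_mask(
    mask: np.ndarray,
    prune_frac: float = 0.10,
    smooth_sigma_px: float = 2.0,
) -> np.ndarray:
    """Ordered midline polyline (x, y in pixel units) from a binary mask.

    The morphological skeleton is reduced to its longest endpoint-to-endpoint
    geodesic; side branches are tolerated (implicitly pruned) if shorter than
    ``prune_frac`` of that length, otherwise the posture is considered
    coiled/self-intersecting and the frame is rejected.

    Raises
    ------
    SegmentationError
        Zero or multiple foreground components.
    CoiledFrameError
        More than two endpoints survive pruning; callers should drop the
        frame and record the reason rather than abort.
    """
    mask = np.asarray(mask, bool)
    lab, n_comp = label(mask, connectivity=2, return_num=True)
    if n_comp == 0:
        raise SegmentationError("mask has no foreground component")
    if n_comp > 1:
        raise SegmentationError(f"mask has {n_comp} foreground components, expected 1")

    skel = skeletonize(mask)
    pix, _, adj = _skeleton_graph(skel)
    if len(pix) < 3:
        raise SegmentationError("skeleton degenerate (<3 pixels)")

    endpoints = [i for i in range(len(pix)) if len(adj[i]) == 1]
    if len(endpoints) < 2:
        raise CoiledFrameError("skeleton has no open ends (closed loop)")

    # main axis = longest geodesic between any endpoint pair
    d0, _ = _geodesic(adj, endpoints[0], len(pix))
    far = max(endpoints, key=lambda i: d0[i] if np.isfinite(d0[i]) else -1.0)
    d1, prev = _geodesic(adj, far, len(pix))
    end = max(endpoints, key=lambda i: d1[i] if np.isfinite(d1[i]) else -1.0)
    main_len = d1[end]
    if not np.isfinite(main_len) or main_len <= 0:
        raise SegmentationError("skeleton is disconnected")

    # any other endpoint hanging further than the prune length off the main
    # path marks a coiled or branched posture
    path: list[int] = []
    u = end
    while u != -1:
        path.append(u)
        u = prev[u]
    on_path = set(path)
    prune_len = prune_frac * main_len
    for e in endpoints:
        if e in (far, end) or e in on_path:
            continue
        # branch length = geodesic distance from e to the nearest main-path pixel
        de, _ = _geodesic(adj, e, len(pix))
        branch = min(de[i] for i in path)
        if branch > prune_len:
            raise CoiledFrameError(
                f"spur of length {branch:.1f} px exceeds prune length {prune_len:.1f} px"
            )

    rc = np.asarray([pix[i] for i in path], float)   # (row, col)
    # return math-convention coordinates: x = col, y up = (nrows-1) - row,
    # so mask-path angles match midline-path angles without a mirror flip
    xy = np.stack([rc[:, 1], (mask.shape[0] - 1) - rc[:, 0]], axis=1)
    if smooth_sigma_px > 0:
        xy = gaussian_filter1d(xy, sigma=smooth_sigma_px, axis=0, mode="nearest")
    return xy


def resample_arclength(polyline: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to ``n_points`` equally spaced arc-length points.

    Linear interpolation between vertices; the first and last points are
    preserved exactly.
    """
    if n_points < 8:
        raise ParameterError(f"n_points must be >= 8, got {n_points}")
    pts = np.asarray(polyline, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise GeometryError("polyline has zero arc length")
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, n_points)
    out = np.stack(
        [np.interp(targets, arc, pts[:, 0]), np.interp(targets, arc, pts[:, 1])],
        axis=1,
    )
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def to_angle_vector(points: np.ndarray) -> np.ndarray:
    """Mean-subtracted tangent angles of an equally-spaced polyline.

    Angles are unwrapped along the body before the mean is removed, so a
    shape crossing the ±pi seam does not tear.  The result is invariant to
    translation and (after mean subtraction) to global rotation.
    """
    pts = np.asarray(points, float)
    d = np.diff(pts, axis=0)
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    return theta - theta.mean()


def to_curvature_vector(points: np.ndarray) -> np.ndarray:
    """Signed curvature d(theta)/ds at interior segment joints.

    Alternative posture representation (one derivative up from tangent
    angles); length N-2 for N input points.
    """
    pts = np.asarray(points, float)
    d = np.diff(pts, axis=0)
    seg = np.linalg.norm(d, axis=1)
    theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    ds = 0.5 * (seg[1:] + seg[:-1])
    kappa = np.diff(theta) / ds
    return kappa - kappa.mean()


def flip_vector(v: np.ndarray, representation: str = "angles") -> np.ndarray:
    """Posture vector of the same shape traversed from the other end.

    For mean-subtracted tangent angles a head/tail swap reverses the vector
    (each segment angle gains pi, which the mean subtraction absorbs); for
    signed curvature it reverses *and* negates.
    """
    return v[::-1] if representation == "angles" else -v[::-1]


def orient_frames(
    angle_matrix: np.ndarray, representation: str = "angles"
) -> tuple[np.ndarray, np.ndarray]:
    """Enforce frame-to-frame head/tail orientation consistency.

    For each frame after the first, keep the original vector or its
    flipped twin (the vector of the polyline traversed from the other
    end), whichever is closer in Euclidean distance to the previously
    retained frame.  The first frame's orientation is arbitrary — the
    amplitude statistics are invariant to a global flip.  Returns
    (oriented matrix, flipped flags).
    """
    A = np.atleast_2d(np.asarray(angle_matrix, float)).copy()
    flipped = np.zeros(len(A), dtype=bool)
    for i in range(1, len(A)):
        alt = flip_vector(A[i], representation)
        if np.linalg.norm(alt - A[i - 1]) < np.linalg.norm(A[i] - A[i - 1]):
            A[i] = alt
            flipped[i] = True
    return A, flipped


def midlines_to_posture(
    series: MidlineSeries,
    n_points: int = 49,
    representation: str = "angles",
    orient: bool = False,
) -> PostureAngleSeries:
    """Direct midline path: resample each frame and convert.

    Midline tables are declared head-to-tail consistent, so no
    re-orientation is applied by default; pass ``orient=True`` for inputs
    with unknown per-frame point order.  (Re-orienting consistent data is
    not harmless: reversal-plus-negation is a near-symmetry of
    single-wavelength waves at some phases and greedy matching can then
    flip frames spuriously.)
    """
    conv = {"angles": to_angle_vector, "curvature": to_curvature_vector}
    if representation not in conv:
        raise ParameterError(f"unknown representation {representation!r}")
    rows, lengths = [], []
    for frame in series.coords:
        pts = resample_arclength(np.asarray(frame, float), n_points)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        lengths.append(seg.sum())
        rows.append(conv[representation](pts))
    angles = np.asarray(rows)
    if orient and len(angles) > 1:
        angles, _ = orient_frames(angles, representation)
    scale = series.px_per_cm or 1.0
    return PostureAngleSeries(
        angles=angles,
        times_s=np.asarray(series.times_s, float),
        body_length=np.asarray(lengths) / (scale if series.units == "px" else 1.0),
        worm_id=series.worm_id,
        representation=representation,
    )


def masks_to_posture(
    masks,
    times_s,
    n_points: int = 49,
    px_per_cm: float | None = None,
    prune_frac: float = 0.10,
    smooth_sigma_px: float = 2.0,
    representation: str = "angles",
    worm_id: str = "worm",
) -> PostureAngleSeries:
    """Mask path: skeletonize every frame, drop coiled frames, convert.

    Coiled/self-intersecting frames raise per-frame and are recorded in
    ``dropped`` with their reason; an empty result is an error upstream.
    """
    conv = {"angles": to_angle_vector, "curvature": to_curvature_vector}
    if representation not in conv:
        raise ParameterError(f"unknown representation {representation!r}")
    rows, lengths, kept_t, dropped = [], [], [], []
    for i, mask in enumerate(masks):
        try:
            poly = extract_midline_from_mask(
                mask, prune_frac=prune_frac, smooth_sigma_px=smooth_sigma_px
            )
            pts = resample_arclength(poly, n_points)
        except CoiledFrameError as exc:
            dropped.append((i, f"coiled: {exc}"))
            continue
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        lengths.append(seg.sum() / (px_per_cm or 1.0))
        rows.append(conv[representation](pts))
        kept_t.append(times_s[i])
    if dropped:
        logger.info("dropped %d/%d frames: %s", len(dropped), len(masks),
                    [r for _, r in dropped[:3]])
    angles = np.asarray(rows) if rows else np.zeros((0, n_points - 1))
    if len(angles) > 1:
        angles, _ = orient_frames(angles, representation)
    return PostureAngleSeries(
        angles=angles,
        times_s=np.asarray(kept_t, float),
        body_length=np.asarray(lengths),
        worm_id=worm_id,
        representation=representation,
        dropped=dropped,
    )
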