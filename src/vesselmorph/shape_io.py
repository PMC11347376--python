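"""Vessel outline I/O, contour canonicalization, and elementary polygon geometry.

A vessel cross-section outline is an ordered closed polygon in image
coordinates (x = column, y = row, y increasing downward). The polygon is
closed by convention: the segment from the last point back to the first is
implicit and the first point is never repeated. All downstream shape math
(elliptic Fourier analysis in particular) assumes the canonical form produced
here: consecutive duplicate vertices removed and positive shoelace area.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Contour",
    "ContourError",
    "read_polygons",
    "write_polygons",
    "extract_contours",
    "rasterize",
    "resample_contour",
    "polygon_geometry",
]


class ContourError(ValueError):
    """Raised for degenerate or malformed vessel outlines."""


def _shoelace(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Contour:
    """Ordered closed polygon of a vessel cross-section outline.

    Parameters
    ----------
    points
        (m, 2) array of (x, y) vertices in pixel units; the closing segment
        is implicit. Canonicalized on construction: consecutive duplicates
        (including a repeated closing point) are dropped and the orientation
        is flipped to positive shoelace area if necessary, keeping the
        original first vertex first.
    pixel_size
        Optional physical scale in micrometre per pixel.
    vessel_id, sample_id
        Identifiers carried through descriptor tables and classification.
    """

    points: np.ndarray
    pixel_size: float | None = None
    vessel_id: str = ""
    sample_id: str = ""
    _canonical: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ContourError("contour points must be an (m, 2) array")
        # drop consecutive duplicates, treating the polygon as cyclic
        keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
        if keep.any():
            pts = pts[keep]
        if len(pts) < 3:
            raise ContourError(
                f"contour needs at least 3 distinct points, got {len(pts)}"
            )
        signed_area = _shoelace(pts)
        if signed_area == 0.0:
            raise ContourError("degenerate contour: zero enclosed area")
        if signed_area < 0:
            # reverse traversal but keep the first vertex first
            pts = np.roll(pts[::-1], 1, axis=0)
        self.points = pts
        self._canonical = True

    @property
    def n_points(self) -> int:
        return len(self.points)

    def area(self) -> float:
        return _shoelace(self.points)

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def centroid(self) -> tuple[float, float]:
        """Area-weighted centroid of the enclosed polygon."""
        p, q = self.points, np.roll(self.points, -1, axis=0)
        cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        a = cross.sum() / 2.0
        cx = float(np.sum((p[:, 0] + q[:, 0]) * cross) / (6.0 * a))
        cy = float(np.sum((p[:, 1] + q[:, 1]) * cross) / (6.0 * a))
        return cx, cy

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(
            self.points + np.array([dx, dy]),
            pixel_size=self.pixel_size,
            vessel_id=self.vessel_id,
            sample_id=self.sample_id,
        )


def polygon_geometry(c: Contour) -> tuple[float, float, tuple[float, float]]:
    """Return (shoelace area, Euclidean perimeter, area-weighted centroid)."""
    return c.area(), c.perimeter(), c.centroid()


# ---------------------------------------------------------------------------
# polygon file I/O
#
# CSV dialect: header vessel_id,sample_id,x,y; one vertex per row, vertices of
# a vessel grouped together. JSON dialect: list of
# {"vessel_id": ..., "sample_id": ..., "points": [[x, y], ...]}.
# ---------------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValueError(f"cannot infer polygon format from {path.name!r}")


def read_polygons(path: str | Path, fmt: str | None = None) -> list[Contour]:
    """Read vessel outlines from a polygon CSV or JSON file.

    Records with fewer than 3 distinct vertices are skipped with a warning;
    malformed rows raise with the offending line number.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    groups: list[tuple[str, str, list[list[float]]]] = []
    if fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header[:4]] != [
                "vessel_id",
                "sample_id",
                "x",
                "y",
            ]:
                raise ValueError(
                    f"{path}: expected header 'vessel_id,sample_id,x,y'"
                )
            current_key: tuple[str, str] | None = None
            for lineno, row in enumerate(reader, start=2):
                if not row or not any(field.strip() for field in row):
                    continue
                if len(row) < 4:
                    raise ValueError(f"{path}: malformed row at line {lineno}")
                vid, sid = row[0].strip(), row[1].strip()
                try:
                    x, y = float(row[2]), float(row[3])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric coordinate at line {lineno}"
                    ) from exc
                if current_key != (vid, sid):
                    current_key = (vid, sid)
                    groups.append((vid, sid, []))
                groups[-1][2].append([x, y])
    elif fmt == "json":
        with open(path) as fh:
            records = json.load(fh)
        for i, rec in enumerate(records):
            try:
                groups.append(
                    (
                        str(rec["vessel_id"]),
                        str(rec.get("sample_id", "")),
                        [[float(x), float(y)] for x, y in rec["points"]],
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}: malformed record {i}") from exc
    else:
        raise ValueError(f"unknown polygon format {fmt!r}")

    contours: list[Contour] = []
    n_skipped = 0
    for vid, sid, pts in groups:
        try:
            contours.append(Contour(np.array(pts), vessel_id=vid, sample_id=sid))
        except ContourError:
            n_skipped += 1
            warnings.warn(
                f"{path}: skipped outline {vid!r} ({len(pts)} point(s), "
                "need >= 3 distinct)",
                stacklevel=2,
            )
    if n_skipped:
        warnings.warn(f"{path}: {n_skipped} outline(s) skipped", stacklevel=2)
    return contours


def write_polygons(
    contours: list[Contour], path: str | Path, fmt: str | None = None
) -> None:
    """Write vessel outlines in the polygon CSV or JSON dialect."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["vessel_id", "sample_id", "x", "y"])
            for c in contours:
                for x, y in c.points:
                    writer.writerow(
                        [c.vessel_id, c.sample_id, repr(float(x)), repr(float(y))]
                    )
    elif fmt == "json":
        records = [
            {
                "vessel_id": c.vessel_id,
                "sample_id": c.sample_id,
                "points": c.points.tolist(),
            }
            for c in contours
        ]
        with open(path, "w") as fh:
            json.dump(records, fh)
    else:
        raise ValueError(f"unknown polygon format {fmt!r}")


# ---------------------------------------------------------------------------
# label-mask boundary tracing
# ---------------------------------------------------------------------------

# outgoing crack edges of one foreground pixel (r, c), traversed with the
# object kept on the left in (x=c, y=r) coordinates; each entry is
# (neighbour offset, edge start corner, edge end corner) in (x, y)
_SIDES = (
    ((-1, 0), (0, 0), (1, 0)),  # background above -> top edge, left to right
    ((0, 1), (1, 0), (1, 1)),  # background right -> right edge, downward
    ((1, 0), (1, 1), (0, 1)),  # background below -> bottom edge, leftward
    ((0, -1), (0, 1), (0, 0)),  # background left -> left edge, upward
)


def _trace_loops(mask: np.ndarray, connectivity: int) -> list[np.ndarray]:
    """Chain the crack (pixel-edge) boundary of a binary mask into loops."""
    rr, cc = np.nonzero(mask)
    edges: dict[tuple[int, int], list[tuple[tuple[int, int], tuple[int, int]]]] = {}
    h, w = mask.shape
    for r, c in zip(rr.tolist(), cc.tolist()):
        for (dr, dc), (sx, sy), (ex, ey) in _SIDES:
            nr, nc = r + dr, c + dc
            if 0 <= nr < h and 0 <= nc < w and mask[nr, nc]:
                continue
            start = (c + sx, r + sy)
            end = (c + ex, r + ey)
            edges.setdefault(start, []).append((end, (ex - sx, ey - sy)))

    loops: list[np.ndarray] = []
    while edges:
        start = next(iter(edges))
        end, direction = edges[start][0]
        loop = [start]
        node, incoming = end, direction
        _pop_edge(edges, start, end)
        while node != start:
            loop.append(node)
            options = edges.get(node, [])
            if len(options) == 1:
                nxt, direction = options[0]
            else:
                # corner shared by two diagonal pixels: with 8-connectivity
                # keep the loop on the same object (turn across the corner),
                # with 4-connectivity split the objects apart
                want_negative = connectivity == 8
                nxt, direction = _pick_turn(options, incoming, want_negative)
            _pop_edge(edges, node, nxt)
            node, incoming = nxt, direction
        loops.append(np.array(loop, dtype=float))
    return loops


def _pick_turn(options, incoming, want_negative):
    for end, direction in options:
        cross = incoming[0] * direction[1] - incoming[1] * direction[0]
        if (cross < 0) == want_negative:
            return end, direction
    return options[0]


def _pop_edge(edges, start, end) -> None:
    lst = edges[start]
    for i, (e, _) in enumerate(lst):
        if e == end:
            del lst[i]
            break
    if not lst:
        del edges[start]


def extract_contours(mask: np.ndarray, connectivity: int = 8) -> list[Contour]:
    """Trace the outer boundary of every labelled object in an integer mask.

    The boundary runs along pixel edges (the "crack" between foreground and
    background), so a filled axis-aligned k-by-k block yields a contour of
    shoelace area exactly k**2. Holes inside an object are ignored; labels
    whose boundary degenerates to fewer than 3 points are dropped.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2 or not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("label mask must be a 2D integer array")
    if mask.min() < 0:
        raise ValueError("label mask must be non-negative")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    contours: list[Contour] = []
    for label in np.unique(mask):
        if label == 0:
            continue
        loops = _trace_loops(mask == label, connectivity)
        if not loops:
            continue
        outer = max(loops, key=lambda lp: abs(_shoelace(lp)))
        if len(outer) < 3:
            continue
        contours.append(Contour(outer, vessel_id=str(int(label))))
    return contours


def rasterize(
    contours: list[Contour], shape: tuple[int, int], labels: list[int] | None = None
) -> np.ndarray:
    """Fill polygons into an integer label mask of the given (rows, cols) shape.

    A pixel belongs to a polygon when its center lies inside; this is the
    inverse convention of :func:`extract_contours` up to the half-pixel
    boundary band.
    """
    from skimage.draw import polygon as draw_polygon

    out = np.zeros(shape, dtype=np.int32)
    for i, c in enumerate(contours):
        label = labels[i] if labels is not None else i + 1
        rr, cc = draw_polygon(c.points[:, 1], c.points[:, 0], shape=shape)
        out[rr, cc] = label
    return out


def resample_contour(c: Contour, m: int = 256) -> Contour:
    """Resample a closed polygon to m points equally spaced in arc length.

    The first resampled point coincides with the contour's first vertex;
    perimeter is preserved to floating-point accuracy.
    """
    if m < 8:
        raise ValueError("resampling needs m >= 8 points")
    pts = np.vstack([c.points, c.points[:1]])
    seg = np.hypot(*np.diff(pts, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    total = t[-1]
    if total <= 0:
        raise ContourError("cannot resample a zero-perimeter contour")
    ti = np.linspace(0.0, total, m, endpoint=False)
    new = np.column_stack(
        [np.interp(ti, t, pts[:, 0]), np.interp(ti, t, pts[:, 1])]
    )
    return Contour(
        new, pixel_size=c.pixel_size, vessel_id=c.vessel_id, sample_id=c.sample_id
    )
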