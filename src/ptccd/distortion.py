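"""Radial taper distortion mapping and per-pixel face quadrilaterals.

The fibre-optic taper demagnifies the detector-face image onto the CCD
and distorts it.  The simulation uses a radially symmetric third-order
polynomial mapping about the grid centres::

    r_ccd = (r_face / demag) * (1 + k2 * r_face**2)

(a pincushion for ``k2 > 0``).  The mapping is bijective whenever
``r_ccd`` is strictly increasing in ``r_face``, which is checked at
construction.  The inverse (CCD -> face) is evaluated from a dense
monotone lookup table.

Mapping the four vertices of each CCD pixel back to the face yields a
convex quadrilateral per raw pixel; the area of that quadrilateral,
relative to the nominal ``(demag * ccd_pixel)**2``, is the effective
collection-area factor used to flatten flood fields, and the overlap of
the quadrilaterals with the orthogonal 73 um face grid drives the
distortion-correction reapportioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .config import DetectorConfig

__all__ = ["RadialMap", "DistortionMap", "build_distortion_map",
           "clip_polygon_to_rect", "polygon_area"]


class DistortionError(ValueError):
    pass


class RadialMap:
    """Forward (face->CCD) and inverse (CCD->face) radial mapping."""

    def __init__(self, cfg: DetectorConfig):
        self.cfg = cfg
        t = cfg.taper
        self.demag = t.demag
        self.k2 = t.k2_per_um2
        self.face_c = cfg.face_center_um
        self.ccd_c = cfg.ccd_center_um
        if self.demag <= 1:
            raise DistortionError("demagnification ratio must exceed 1")
        # Bijectivity: r_ccd(r) monotone on the face (checked to the corner).
        r_max = cfg.face_center_um * np.sqrt(2.0) * 1.05
        r = np.linspace(0.0, r_max, 200_001)
        rc = self._r_fwd(r)
        if np.any(np.diff(rc) <= 0):
            raise DistortionError("distortion mapping is not bijective "
                                  "(r_ccd(r_face) not strictly increasing)")
        self._r_face_tab = r
        self._r_ccd_tab = rc

    def _r_fwd(self, r: np.ndarray) -> np.ndarray:
        return (r / self.demag) * (1.0 + self.k2 * r * r)

    def face_to_ccd(self, xy_face: np.ndarray) -> np.ndarray:
        """Map positions (um) on the detector face to CCD-plane positions."""
        v = np.asarray(xy_face, dtype=float) - self.face_c
        r = np.hypot(v[..., 0], v[..., 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(r > 0, self._r_fwd(r) / np.where(r > 0, r, 1.0),
                             1.0 / self.demag)
        return self.ccd_c + v * scale[..., None]

    def ccd_to_face(self, xy_ccd: np.ndarray) -> np.ndarray:
        """Inverse mapping, via the dense monotone lookup table."""
        v = np.asarray(xy_ccd, dtype=float) - self.ccd_c
        r = np.hypot(v[..., 0], v[..., 1])
        r_face = np.interp(r, self._r_ccd_tab, self._r_face_tab)
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(r > 0, r_face / np.where(r > 0, r, 1.0), self.demag)
        return self.face_c + v * scale[..., None]


# ---------------------------------------------------------------------------
# Convex polygon clipping (Sutherland-Hodgman against axis-aligned rectangles)

def polygon_area(poly: np.ndarray) -> float:
    """Signed shoelace area of a polygon given as an (n, 2) vertex array."""
    if len(poly) < 3:
        return 0.0
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _clip_half_plane(poly, axis, bound, keep_leq):
    out = []
    n = len(poly)
    for i in range(n):
        cur, nxt = poly[i], poly[(i + 1) % n]
        cin = (cur[axis] <= bound) if keep_leq else (cur[axis] >= bound)
        nin = (nxt[axis] <= bound) if keep_leq else (nxt[axis] >= bound)
        if cin:
            out.append(cur)
        if cin != nin:
            t = (bound - cur[axis]) / (nxt[axis] - cur[axis])
            out.append((cur[0] + t * (nxt[0] - cur[0]),
                        cur[1] + t * (nxt[1] - cur[1])))
    return out


def clip_polygon_to_rect(poly: np.ndarray, x0, x1, y0, y1) -> np.ndarray:
    """Clip a convex polygon against [x0,x1]x[y0,y1]; returns the clipped
    vertex array (possibly empty)."""
    p = [tuple(v) for v in np.asarray(poly, dtype=float)]
    for axis, bound, keep_leq in ((0, x1, True), (0, x0, False),
                                  (1, y1, True), (1, y0, False)):
        if not p:
            break
        p = _clip_half_plane(p, axis, bound, keep_leq)
    return np.asarray(p, dtype=float).reshape(-1, 2)


def polygon_overlap_redistribute(
    quads: np.ndarray,
    values: np.ndarray,
    grid_x0: float,
    grid_y0: float,
    nx: int,
    ny: int,
    pitch: float,
) -> tuple[np.ndarray, float]:
    """Reapportion per-quadrilateral values onto an orthogonal grid.

    Each value is split among target pixels in proportion to the clipped
    overlap area of its (simple, convex) quadrilateral with the pixel
    rectangles; the fraction of a quad falling outside the grid is
    dropped and accumulated in the returned loss total.

    Returns ``(raster, lost_value)`` with ``raster`` of shape (ny, nx).
    """
    quads = np.asarray(quads, dtype=float)
    values = np.asarray(values, dtype=float)
    out = np.zeros((ny, nx))
    lost = 0.0
    for quad, val in zip(quads, values):
        area = abs(polygon_area(quad))
        if area <= 0:
            raise DistortionError("degenerate (zero-area) quadrilateral")
        fx = (quad[:, 0] - grid_x0) / pitch
        fy = (quad[:, 1] - grid_y0) / pitch
        ix0, ix1 = int(np.floor(fx.min())), int(np.ceil(fx.max()))
        iy0, iy1 = int(np.floor(fy.min())), int(np.ceil(fy.max()))
        covered = 0.0
        for iy in range(max(iy0, 0), min(iy1, ny)):
            for ix in range(max(ix0, 0), min(ix1, nx)):
                clipped = clip_polygon_to_rect(
                    quad,
                    grid_x0 + ix * pitch, grid_x0 + (ix + 1) * pitch,
                    grid_y0 + iy * pitch, grid_y0 + (iy + 1) * pitch,
                )
                a = abs(polygon_area(clipped))
                if a > 0:
                    out[iy, ix] += val * a / area
                    covered += a / area
        lost += val * max(0.0, 1.0 - covered)
    return out, lost


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistortionMap:
    """Geometry of the taper mapping for a rectangular CCD-pixel window.

    ``quads`` holds, for each raw pixel in the window (row-major), the
    four face-plane vertices (um) of its back-projected quadrilateral.
    ``area_factor`` is the quad area relative to the nominal
    (demag * ccd_pixel)^2 collection area.  ``redistribution`` is the
    sparse operator taking raw window pixel values (flattened) to the
    corrected face-grid window (flattened), with matrix elements equal
    to overlap-area fractions of each quad; ``in_grid_fraction`` is its
    column sum (the kept fraction of each raw pixel).
    """

    radial: RadialMap
    ccd_x0: int
    ccd_y0: int
    ncx: int
    ncy: int
    face_x0: int
    face_y0: int
    nfx: int
    nfy: int
    quads: np.ndarray              # (ncy*ncx, 4, 2) um on the face
    area_factor: np.ndarray        # (ncy, ncx)
    redistribution: sparse.csr_matrix   # (nfy*nfx, ncy*ncx)
    in_grid_fraction: np.ndarray   # (ncy, ncx)

    def raw_pixel_weights_for_box(self, mask_flat: np.ndarray) -> np.ndarray:
        """For a corrected-window pixel mask (flattened, boolean), the
        fraction of each raw pixel's value that lands inside the masked
        region.  Summing gives the effective raw-pixel count N for the
        pixel-noise term."""
        w = np.asarray(
            self.redistribution[mask_flat.nonzero()[0], :].sum(axis=0)
        ).ravel()
        return w


def _pixel_vertices(x0: int, y0: int, ncx: int, ncy: int, pitch: float):
    """Vertex positions (um) of all pixels in a window: (ncy, ncx, 4, 2),
    corners ordered counter-clockwise."""
    xs = (np.arange(x0, x0 + ncx + 1)) * pitch
    ys = (np.arange(y0, y0 + ncy + 1)) * pitch
    gx, gy = np.meshgrid(xs, ys)
    corners = np.stack([gx, gy], axis=-1)      # (ncy+1, ncx+1, 2)
    v00 = corners[:-1, :-1]
    v10 = corners[:-1, 1:]
    v11 = corners[1:, 1:]
    v01 = corners[1:, :-1]
    return np.stack([v00, v10, v11, v01], axis=2)   # (ncy, ncx, 4, 2)


def build_distortion_map(
    cfg: DetectorConfig,
    ccd_x0: int, ccd_y0: int, ncx: int, ncy: int,
    face_x0: int, face_y0: int, nfx: int, nfy: int,
) -> DistortionMap:
    """Back-project a CCD-pixel window through the taper and build the
    polygon-overlap redistribution operator onto a face-grid window."""
    radial = RadialMap(cfg)
    t = cfg.taper
    pitch = cfg.face_pixel_um
    verts = _pixel_vertices(ccd_x0, ccd_y0, ncx, ncy, t.ccd_pixel_um)
    quads = radial.ccd_to_face(verts.reshape(-1, 2)).reshape(ncy * ncx, 4, 2)

    nominal_area = (t.demag * t.ccd_pixel_um) ** 2
    areas = np.abs([polygon_area(q) for q in quads])
    if np.any(areas <= 0):
        raise DistortionError("degenerate back-projected pixel quadrilateral")
    area_factor = (areas / nominal_area).reshape(ncy, ncx)

    gx0 = face_x0 * pitch
    gy0 = face_y0 * pitch
    rows, cols, vals = [], [], []
    kept = np.zeros(ncy * ncx)
    for j, quad in enumerate(quads):
        area = areas[j]
        fx = (quad[:, 0] - gx0) / pitch
        fy = (quad[:, 1] - gy0) / pitch
        ix0, ix1 = int(np.floor(fx.min())), int(np.ceil(fx.max()))
        iy0, iy1 = int(np.floor(fy.min())), int(np.ceil(fy.max()))
        for iy in range(max(iy0, 0), min(iy1, nfy)):
            for ix in range(max(ix0, 0), min(ix1, nfx)):
                clipped = clip_polygon_to_rect(
                    quad,
                    gx0 + ix * pitch, gx0 + (ix + 1) * pitch,
                    gy0 + iy * pitch, gy0 + (iy + 1) * pitch,
                )
                a = abs(polygon_area(clipped))
                if a > 0:
                    frac = a / area
                    rows.append(iy * nfx + ix)
                    cols.append(j)
                    vals.append(frac)
                    kept[j] += frac
    redis = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(nfy * nfx, ncy * ncx)
    )
    return DistortionMap(
        radial=radial,
        ccd_x0=ccd_x0, ccd_y0=ccd_y0, ncx=ncx, ncy=ncy,
        face_x0=face_x0, face_y0=face_y0, nfx=nfx, nfy=nfy,
        quads=quads, area_factor=area_factor,
        redistribution=redis,
        in_grid_fraction=kept.reshape(ncy, ncx),
    )
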