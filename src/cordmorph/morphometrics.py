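"""Per-slice morphometry of a binary spinal cord segmentation.

Six measures are computed on every axial slice of a canonically oriented
(RAS+) binary mask: cross-sectional area (CSA), anteroposterior (AP) and
transverse diameters, compression ratio, eccentricity and solidity. The
cord is generally not perpendicular to the axial plane, so areas and
diameters measured in-plane overestimate the true cross-section; they are
corrected to first order using the local angulation of the cord centerline:

* CSA is multiplied by ``cos(theta)``, where ``theta`` is the angle between
  the centerline tangent and the superior-inferior (SI) axis;
* the AP diameter is multiplied by ``cos(theta_sag)`` and the transverse
  diameter by ``cos(theta_cor)``, the tangent's tilt components in the
  sagittal and coronal planes.

Diameters and eccentricity come from the *equivalent ellipse* of the pixel
set — the ellipse with the same second-order central moments. Moments are
computed in millimetres (voxel anisotropy aware) and include the per-axis
``w^2/12`` pixel-extent term, so the equivalent ellipse of a rasterized
ellipse matches the continuous one to first order. The diameter along a
direction ``u`` is the support width of that ellipse, ``4 * sqrt(u' S u)``
with ``S`` the moment matrix; for an axis-aligned ellipse this reduces to
the familiar ``2a``/``2b``.

Solidity (area / convex-hull area, in percent) measures indentation of the
cord contour and is computed over *all* positive pixels of the slice, so
disconnected components are treated as a single object.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import convex_hull_image

from .definitions import METRICS, UNLABELED
from .errors import DegenerateInputError, UndefinedShapeError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationVolume",
    "Centerline",
    "SliceMorphometrics",
    "extract_centerline",
    "compute_slice_morphometrics",
    "cross_sectional_area",
    "ap_transverse_diameters",
    "compression_ratio",
    "eccentricity",
    "solidity",
]


@dataclass(frozen=True)
class SegmentationVolume:
    """A canonically oriented (RAS+) binary segmentation with voxel geometry.

    Parameters
    ----------
    voxels
        3D boolean array; axis order (RL, AP, SI), SI index increasing
        toward superior.
    voxel_size
        Voxel dimensions in mm, ordered (RL, AP, SI).
    source_orientation
        Orientation code of the file the volume was loaded from (kept for
        provenance / round-trips); canonical data is always 'RAS'.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    source_orientation: str = "RAS"

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValidationError(f"expected a 3D volume, got ndim={v.ndim}")
        if v.dtype != bool:
            uniq = np.unique(v)
            if not np.isin(uniq, (0, 1)).all():
                raise ValidationError("voxels must be binary (0/1)")
            v = v.astype(bool)
        object.__setattr__(self, "voxels", v)
        vs = tuple(float(s) for s in self.voxel_size)
        if len(vs) != 3 or any(s <= 0 for s in vs):
            raise ValidationError(f"voxel_size must be 3 positive mm values, got {self.voxel_size}")
        object.__setattr__(self, "voxel_size", vs)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[2]

    def nonempty_slices(self) -> np.ndarray:
        """Indices of axial slices containing at least one positive voxel."""
        return np.flatnonzero(self.voxels.any(axis=(0, 1)))

    def slice_mask(self, z: int) -> np.ndarray:
        return self.voxels[:, :, z]


@dataclass(frozen=True)
class Centerline:
    """Smoothed cord centerline sampled at the mask's nonempty slices.

    All arrays are aligned with ``slices``. Tangents are unit vectors in
    (RL, AP, SI) mm coordinates; ``angle_deg`` is the angle between the
    tangent and the SI axis, with its sagittal-plane (AP/SI) and
    coronal-plane (RL/SI) components stored separately for the per-axis
    diameter corrections.
    """

    slices: np.ndarray
    center_rl_mm: np.ndarray
    center_ap_mm: np.ndarray
    tangent: np.ndarray
    angle_deg: np.ndarray
    tilt_sag_deg: np.ndarray
    tilt_cor_deg: np.ndarray
    _index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_index", {int(z): i for i, z in enumerate(self.slices)})

    def has_slice(self, z: int) -> bool:
        return int(z) in self._index

    def at(self, z: int) -> dict:
        """Centerline sample at slice ``z`` as a plain dict."""
        i = self._index[int(z)]
        return {
            "center_rl_mm": float(self.center_rl_mm[i]),
            "center_ap_mm": float(self.center_ap_mm[i]),
            "tangent": self.tangent[i],
            "angle_deg": float(self.angle_deg[i]),
            "tilt_sag_deg": float(self.tilt_sag_deg[i]),
            "tilt_cor_deg": float(self.tilt_cor_deg[i]),
        }


@dataclass(frozen=True)
class SliceMorphometrics:
    """The six morphometric measures (plus angulation) for one axial slice."""

    slice_index: int
    csa_mm2: float
    ap_diameter_mm: float
    transverse_diameter_mm: float
    compression_ratio: float
    eccentricity: float
    solidity_pct: float
    angle_deg: float
    level: str = UNLABELED

    def as_dict(self) -> dict:
        d = {"slice_index": self.slice_index, "level": self.level}
        d.update({m: getattr(self, m) for m in METRICS})
        d["angle_deg"] = self.angle_deg
        return d


# ---------------------------------------------------------------------------
# centerline


def extract_centerline(seg: SegmentationVolume, smoothing_degree: int = 3) -> Centerline:
    """Fit a smooth centerline through the per-slice mask centroids.

    The per-slice intensity centroids (in mm) are fitted with a polynomial
    of ``smoothing_degree`` in the SI coordinate, independently for the RL
    and AP components; tangents come from the analytic derivative of the
    fit, which also provides one-sided tangents at the volume boundaries.

    Raises
    ------
    DegenerateInputError
        If the mask is empty or has fewer than ``smoothing_degree + 1``
        nonempty slices.
    """
    if not 1 <= int(smoothing_degree) <= 5:
        raise ValidationError("smoothing_degree must be in 1..5")
    zs = seg.nonempty_slices()
    if zs.size == 0:
        raise DegenerateInputError("empty segmentation volume")
    if zs.size < smoothing_degree + 1:
        raise DegenerateInputError(
            f"need at least {smoothing_degree + 1} nonempty slices for a "
            f"degree-{smoothing_degree} centerline fit, got {zs.size}"
        )
    if not np.all(np.diff(zs) == 1):
        logger.warning("segmentation has gaps along SI; centerline fitted across them")

    drl, dap, dsi = seg.voxel_size
    cx = np.empty(zs.size)
    cy = np.empty(zs.size)
    for i, z in enumerate(zs):
        ii, jj = np.nonzero(seg.slice_mask(z))
        cx[i] = ii.mean() * drl
        cy[i] = jj.mean() * dap
    z_mm = zs * dsi

    px = np.polynomial.Polynomial.fit(z_mm, cx, smoothing_degree)
    py = np.polynomial.Polynomial.fit(z_mm, cy, smoothing_degree)
    tx = px.deriv()(z_mm)  # d RL / d SI (dimensionless)
    ty = py.deriv()(z_mm)  # d AP / d SI

    tangent = np.stack([tx, ty, np.ones_like(tx)], axis=1)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    angle = np.degrees(np.arctan(np.hypot(tx, ty)))
    tilt_sag = np.degrees(np.arctan(np.abs(ty)))
    tilt_cor = np.degrees(np.arctan(np.abs(tx)))

    return Centerline(
        slices=zs,
        center_rl_mm=px(z_mm),
        center_ap_mm=py(z_mm),
        tangent=tangent,
        angle_deg=angle,
        tilt_sag_deg=tilt_sag,
        tilt_cor_deg=tilt_cor,
    )


# ---------------------------------------------------------------------------
# per-slice shape descriptors


def _central_moments_mm(mask: np.ndarray, pixel_size: tuple[float, float]) -> np.ndarray:
    """2x2 central second-moment matrix of the positive pixels, in mm^2.

    Includes the w^2/12 within-pixel term per axis so that the moments of a
    rasterized region approximate those of the continuous region.
    """
    ii, jj = np.nonzero(mask)
    if ii.size == 0:
        raise UndefinedShapeError("empty slice mask")
    drl, dap = pixel_size
    x = ii * drl
    y = jj * dap
    x = x - x.mean()
    y = y - y.mean()
    s = np.array(
        [
            [np.mean(x * x) + drl**2 / 12.0, np.mean(x * y)],
            [np.mean(x * y), np.mean(y * y) + dap**2 / 12.0],
        ]
    )
    return s


def _check_noncollinear(mask: np.ndarray) -> None:
    ii, jj = np.nonzero(mask)
    if ii.size < 3:
        raise UndefinedShapeError("shape descriptors need at least 3 pixels")
    # rank of the centered point cloud (pixel centers, grid units)
    pts = np.stack([ii - ii.mean(), jj - jj.mean()], axis=1).astype(float)
    if np.linalg.matrix_rank(pts, tol=1e-9) < 2:
        raise UndefinedShapeError("positive pixels are collinear")


def cross_sectional_area(
    mask: np.ndarray, pixel_size: tuple[float, float], angle_deg: float = 0.0
) -> float:
    """Angle-corrected cross-sectional area in mm^2.

    In-plane area (pixel count x pixel area) scaled by ``cos(angle_deg)``,
    the first-order correction for a cord crossing the axial plane at an
    oblique angle.
    """
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise UndefinedShapeError("empty slice mask")
    return n * pixel_size[0] * pixel_size[1] * math.cos(math.radians(angle_deg))


def ap_transverse_diameters(
    mask: np.ndarray,
    pixel_size: tuple[float, float],
    tilt_sag_deg: float = 0.0,
    tilt_cor_deg: float = 0.0,
) -> tuple[float, float]:
    """(AP, transverse) diameters in mm from the equivalent ellipse.

    The diameter along an axis is the support width of the moment-matched
    ellipse on that axis, ``4 * sqrt(S_uu)``. The AP extent is corrected by
    ``cos(tilt_sag_deg)`` and the RL (transverse) extent by
    ``cos(tilt_cor_deg)``.
    """
    _check_noncollinear(mask)
    s = _central_moments_mm(mask, pixel_size)
    transverse = 4.0 * math.sqrt(s[0, 0]) * math.cos(math.radians(tilt_cor_deg))
    ap = 4.0 * math.sqrt(s[1, 1]) * math.cos(math.radians(tilt_sag_deg))
    return ap, transverse


def compression_ratio(ap_mm: float, transverse_mm: float) -> float:
    """AP diameter over transverse diameter (dimensionless, no clipping)."""
    if transverse_mm <= 0:
        raise UndefinedShapeError("transverse diameter must be positive")
    return ap_mm / transverse_mm


def eccentricity(mask: np.ndarray, pixel_size: tuple[float, float]) -> float:
    """Eccentricity of the equivalent ellipse, in [0, 1).

    Focal distance over major-axis length: ``sqrt(1 - (b/a)^2)`` with
    ``a >= b`` the semi-axes of the moment-matched ellipse. 0 is a circle.
    """
    _check_noncollinear(mask)
    s = _central_moments_mm(mask, pixel_size)
    lmin, lmax = np.linalg.eigvalsh(s)
    if lmax <= 0:
        raise UndefinedShapeError("degenerate second moments")
    return math.sqrt(max(0.0, 1.0 - lmin / lmax))


def solidity(mask: np.ndarray) -> float:
    """Area over convex-hull area of all positive pixels, in percent.

    Pixel-count based: both areas scale with the pixel area, so the ratio is
    valid for anisotropic pixels. 100% for convex shapes; indentations (e.g.
    cord compression) lower it.
    """
    _check_noncollinear(mask)
    # hull of pixel centers: pixel-count ratio is 100 for convex rasters
    hull = convex_hull_image(mask, offset_coordinates=False)
    hull_n = int(hull.sum())
    if hull_n == 0:
        raise UndefinedShapeError("degenerate convex hull")
    return 100.0 * float(np.count_nonzero(mask)) / hull_n


# ---------------------------------------------------------------------------
# driver


def compute_slice_morphometrics(
    seg: SegmentationVolume,
    cl: Centerline | None = None,
    levels: dict[int, str] | None = None,
) -> list[SliceMorphometrics]:
    """All six measures for every usable axial slice of ``seg``.

    Slices whose shape descriptors are undefined (fewer than 3 pixels, or
    collinear pixels) are logged and excluded from the output. Disconnected
    in-plane components are kept and measured together.

    Parameters
    ----------
    seg
        Canonical binary segmentation.
    cl
        Centerline used for the angulation correction; computed with default
        settings when omitted.
    levels
        Optional map of slice index to vertebral level name used to fill the
        ``level`` field.
    """
    if cl is None:
        cl = extract_centerline(seg)
    drl, dap, _ = seg.voxel_size
    out: list[SliceMorphometrics] = []
    for z in seg.nonempty_slices():
        mask = seg.slice_mask(z)
        if mask.sum() > 1 and _n_components(mask) > 1:
            logger.warning("slice %d has disconnected components; measuring all pixels", z)
        if not cl.has_slice(int(z)):
            raise ValidationError(f"centerline not defined on nonempty slice {z}")
        c = cl.at(int(z))
        try:
            _check_noncollinear(mask)
        except UndefinedShapeError as exc:
            logger.warning("slice %d excluded: %s", z, exc)
            continue
        csa = cross_sectional_area(mask, (drl, dap), c["angle_deg"])
        ap, tr = ap_transverse_diameters(
            mask, (drl, dap), c["tilt_sag_deg"], c["tilt_cor_deg"]
        )
        out.append(
            SliceMorphometrics(
                slice_index=int(z),
                csa_mm2=csa,
                ap_diameter_mm=ap,
                transverse_diameter_mm=tr,
                compression_ratio=compression_ratio(ap, tr),
                eccentricity=eccentricity(mask, (drl, dap)),
                solidity_pct=solidity(mask),
                angle_deg=c["angle_deg"],
                level=(levels or {}).get(int(z), UNLABELED),
            )
        )
    return out


def _n_components(mask: np.ndarray) -> int:
    from scipy.ndimage import label

    _, n = label(mask)
    return n
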