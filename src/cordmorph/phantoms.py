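"""Synthetic inputs with analytic ground truth.

Two generators make every pipeline stage testable without any data
download:

* :func:`make_cord_phantom` rasterizes a tube of elliptical cross-section
  with per-level semi-axis profiles, optional tilt (shear of the tube axis
  in the sagittal or coronal plane) and optional per-slice boundary jitter.
  Because the *perpendicular* cross-section is the specified ellipse, the
  analytic per-slice ground truth is closed-form: CSA ``pi*a*b``, diameters
  ``2b`` (AP) and ``2a`` (RL), compression ratio ``b/a``, eccentricity
  ``sqrt(1-(min/maj)^2)``, solidity 100%, angle equal to the construction
  tilt. A tilted tube's axial sections are correspondingly stretched
  (AP semi-axis ``b/cos(theta)`` for sagittal tilt), which is exactly the
  effect the angulation correction must undo.

* :func:`make_synthetic_cohort` draws per-subject template-space metric
  profiles from per-slice normal distributions whose mean/SD default to the
  packaged normative landmark tables (male and female profiles separately),
  linearly interpolated across the covered PAM50 slices. Subjects carry a
  per-metric random intercept (ICC 0.8 by default: a subject's cord is
  uniformly large or small, so neighbouring slices are strongly correlated)
  while the marginal per-slice SD stays at the specified value. Demographic
  attributes (sex split 105:98, vendors Siemens/Philips/GE 139:36:28, age
  28.7 +/- 5.6 y) default to the composition of the source cohort, and an
  optional block of pathology-flagged subjects (default 64) emulates the
  excluded fraction of the source dataset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .definitions import METRICS, UNLABELED, vertebra_name
from .errors import ValidationError
from .morphometrics import SegmentationVolume
from .pam50 import LevelLabeling, NormalizedMetrics, PAM50LevelMap, load_pam50_level_map
from .normative import SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "make_cord_phantom",
    "make_synthetic_cohort",
    "load_normative_landmarks",
    "landmark_profiles",
]


# ---------------------------------------------------------------------------
# cord phantom


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic cord.

    ``level_semi_axes`` maps vertebra id to (RL, AP) semi-axes in mm
    (piecewise-constant per level); ``disc_slices`` maps disc id to native
    slice index (strictly decreasing with id). ``tilt_deg`` shears the tube
    axis in ``tilt_plane`` ('sagittal': centers drift along AP; 'coronal':
    along RL). ``rotation_deg`` rotates the cross-section in-plane and is
    only supported at zero tilt. ``jitter_sd`` is the SD of a per-slice
    multiplicative perturbation of both semi-axes; the ground truth tracks
    the jittered values, and ``seed`` fully determines the output.

    ``dither_voxels`` scales a deterministic sub-voxel displacement of the
    construction center per slice (low-discrepancy irrational strides).
    Binary rasterization of a fixed ellipse carries an alignment-dependent,
    zero-mean discretization error of a few percent at 0.8 mm voxels; the
    dither makes consecutive slices sample different alignments so the
    error averages out along a level. The ground-truth centerline tracks
    the dither. Set 0 for a perfectly grid-aligned tube.
    """

    level_semi_axes: dict[int, tuple[float, float]]
    disc_slices: dict[int, int]
    voxel_size: tuple[float, float, float] = (0.8, 0.8, 0.8)
    tilt_deg: float = 0.0
    tilt_plane: str = "sagittal"
    rotation_deg: float = 0.0
    jitter_sd: float = 0.0
    dither_voxels: float = 1.0
    pad_slices: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tilt_plane not in ("sagittal", "coronal"):
            raise ValidationError("tilt_plane must be 'sagittal' or 'coronal'")
        if not 0 <= self.tilt_deg < 60:
            raise ValidationError("tilt_deg must be in [0, 60)")
        if self.rotation_deg and self.tilt_deg:
            raise ValidationError("in-plane rotation is only supported at zero tilt")
        LevelLabeling(self.disc_slices)  # validates monotonicity
        for k, (a, b) in self.level_semi_axes.items():
            if min(a, b) < max(self.voxel_size[:2]):
                raise ValidationError(
                    f"level {vertebra_name(k)} semi-axes {(a, b)} below voxel size"
                )

    @classmethod
    def cervical(cls, voxel_size=(0.8, 0.8, 0.8), **kwargs) -> "PhantomSpec":
        """Cervical cord C1-T1 with level sizes from the normative tables.

        Per-level semi-axes are half the mid-level normative transverse (RL)
        and AP diameters of the whole-cohort table; disc positions follow
        the template's level heights converted to the requested slice
        thickness, producing the physiological bulge at C4-C5.
        """
        lm = load_normative_landmarks()
        lv = lm[(lm.cohort == "all") & (lm.landmark == "level")]
        ap = lv[lv.metric == "ap_diameter_mm"].set_index("name")["mean"]
        tr = lv[lv.metric == "transverse_diameter_mm"].set_index("name")["mean"]
        template = load_pam50_level_map()
        axes = {
            k: (tr[vertebra_name(k)] / 2.0, ap[vertebra_name(k)] / 2.0)
            for k in template.levels()
        }
        scale = template.slice_thickness_mm / voxel_size[2]
        base = min(template.boundaries.values())
        pad = kwargs.get("pad_slices", 3)
        discs = {
            d: int(round((s - base) * scale)) + pad
            for d, s in template.boundaries.items()
        }
        return cls(level_semi_axes=axes, disc_slices=discs, voxel_size=voxel_size, **kwargs)


def _slice_profile(spec: PhantomSpec) -> pd.DataFrame:
    """Per-slice level id and (possibly jittered) semi-axes."""
    lab = LevelLabeling(spec.disc_slices)
    zmin = min(spec.disc_slices.values())
    zmax = max(spec.disc_slices.values()) - 1
    z0 = zmin - spec.pad_slices
    z1 = zmax + spec.pad_slices
    if z0 < 0:
        raise ValidationError("disc slices leave no room for pad_slices at the bottom")
    levels = sorted(spec.level_semi_axes)
    rows = []
    for z in range(z0, z1 + 1):
        name = lab.level_of_slice(z)
        if name == UNLABELED:
            # pads continue the adjacent end level's profile
            k = levels[0] if z > zmax else levels[-1]
        else:
            k = next(i for i in levels if vertebra_name(i) == name)
        a, b = spec.level_semi_axes[k]
        rows.append({"slice": z, "level": lab.level_of_slice(z), "a_rl": a, "b_ap": b})
    prof = pd.DataFrame(rows).set_index("slice")
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(spec.seed)
        jit = rng.normal(1.0, spec.jitter_sd, size=(len(prof), 2))
        jit = np.clip(jit, 0.5, 1.5)
        prof["a_rl"] *= jit[:, 0]
        prof["b_ap"] *= jit[:, 1]
    return prof


def make_cord_phantom(
    spec: PhantomSpec,
) -> tuple[SegmentationVolume, LevelLabeling, pd.DataFrame]:
    """Rasterize a cord phantom and return it with labels and ground truth.

    Returns
    -------
    seg
        Binary volume in canonical orientation.
    labeling
        Disc labels re-indexed to the volume's slice coordinates.
    ground_truth
        Per-slice DataFrame (indexed by volume slice) with the analytic six
        measures, the construction angle and centerline position.
    """
    prof = _slice_profile(spec)
    drl, dap, dsi = spec.voxel_size
    theta = math.radians(spec.tilt_deg)
    shear = math.tan(theta)  # mm in-plane per mm SI

    z_arr = prof.index.to_numpy()
    z_mm = (z_arr - z_arr.min()) * dsi
    z_mid = z_mm.mean()

    a_ax = prof["a_rl"].to_numpy().copy()  # axial RL semi-axis
    b_ax = prof["b_ap"].to_numpy().copy()  # axial AP semi-axis
    off_rl = np.zeros_like(z_mm)
    off_ap = np.zeros_like(z_mm)
    if spec.tilt_plane == "sagittal":
        b_ax = b_ax / math.cos(theta)
        off_ap = shear * (z_mm - z_mid)
    else:
        a_ax = a_ax / math.cos(theta)
        off_rl = shear * (z_mm - z_mid)

    if spec.dither_voxels:
        # low-discrepancy sub-voxel dither, deterministic in the slice index
        k = np.arange(len(z_arr), dtype=float)
        off_rl = off_rl + spec.dither_voxels * (np.mod(k * 0.6180339887, 1.0) - 0.5) * drl
        off_ap = off_ap + spec.dither_voxels * (np.mod(k * 0.4142135624, 1.0) - 0.5) * dap

    # grid large enough for the widest axial section plus the shear excursion
    half_x = (np.abs(off_rl) + a_ax).max() + 2 * drl
    half_y = (np.abs(off_ap) + b_ax).max() + 2 * dap
    nx = 2 * int(math.ceil(half_x / drl)) + 3
    ny = 2 * int(math.ceil(half_y / dap)) + 3
    cx0 = (nx // 2) * drl + 0.237 * drl  # off-grid center avoids raster symmetry artifacts
    cy0 = (ny // 2) * dap + 0.173 * dap

    xs = np.arange(nx) * drl
    ys = np.arange(ny) * dap
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    phi = math.radians(spec.rotation_deg)
    cphi, sphi = math.cos(phi), math.sin(phi)

    vol = np.zeros((nx, ny, len(z_arr)), dtype=bool)
    for i in range(len(z_arr)):
        dx = X - (cx0 + off_rl[i])
        dy = Y - (cy0 + off_ap[i])
        if phi:
            dx, dy = cphi * dx + sphi * dy, -sphi * dx + cphi * dy
        vol[:, :, i] = (dx / a_ax[i]) ** 2 + (dy / b_ax[i]) ** 2 <= 1.0

    seg = SegmentationVolume(voxels=vol, voxel_size=spec.voxel_size)
    z_shift = int(z_arr.min())
    labeling = LevelLabeling({d: s - z_shift for d, s in spec.disc_slices.items()})

    a = prof["a_rl"].to_numpy()
    b = prof["b_ap"].to_numpy()
    maj = np.maximum(a, b)
    mnr = np.minimum(a, b)
    if phi:
        # projections of the rotated ellipse onto the anatomical axes
        ap_d = 2.0 * np.sqrt((a * sphi) ** 2 + (b * cphi) ** 2)
        tr_d = 2.0 * np.sqrt((a * cphi) ** 2 + (b * sphi) ** 2)
    else:
        ap_d = 2.0 * b
        tr_d = 2.0 * a
    gt = pd.DataFrame(
        {
            "level": prof["level"].to_numpy(),
            "csa_mm2": np.pi * a * b,
            "ap_diameter_mm": ap_d,
            "transverse_diameter_mm": tr_d,
            "compression_ratio": ap_d / tr_d,
            "eccentricity": np.sqrt(1.0 - (mnr / maj) ** 2),
            "solidity_pct": 100.0,
            "angle_deg": spec.tilt_deg,
            "center_rl_mm": cx0 + off_rl,
            "center_ap_mm": cy0 + off_ap,
        },
        index=pd.Index(z_arr - z_shift, name="slice_index"),
    )
    return seg, labeling, gt


# ---------------------------------------------------------------------------
# synthetic cohorts


def load_normative_landmarks() -> pd.DataFrame:
    """The packaged normative landmark table (whole cohort, males, females)."""
    with resources.files("cordmorph.data").joinpath("normative_landmarks.csv").open() as f:
        return pd.read_csv(f)


def landmark_profiles(cohort: str, template: PAM50LevelMap | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(mean, sd) per-slice profiles interpolated from the landmark table.

    Landmark means/SDs of ``cohort`` ('all', 'male' or 'female') are placed
    at their template slices and linearly interpolated over the template's
    full covered span (constant extension beyond the outermost landmarks).
    """
    template = template or load_pam50_level_map()
    lm = load_normative_landmarks()
    lm = lm[lm.cohort == cohort]
    if lm.empty:
        raise ValidationError(f"unknown landmark cohort {cohort!r}")
    slices = np.asarray(template.all_slices())
    mean = {}
    sd = {}
    for metric in METRICS:
        sub = lm[lm.metric == metric].sort_values("pam50_slice")
        mean[metric] = np.interp(slices, sub["pam50_slice"], sub["mean"])
        sd[metric] = np.interp(slices, sub["pam50_slice"], sub["sd"])
    idx = pd.Index(slices, name="pam50_slice")
    return pd.DataFrame(mean, index=idx), pd.DataFrame(sd, index=idx)


@dataclass(frozen=True)
class CohortSpec:
    """Composition and distributions of a synthetic cohort.

    ``mean_profiles``/``sd_profiles`` map sex ('M'/'F') to slice-by-metric
    DataFrames; defaults come from the packaged male/female normative
    tables. ``subject_icc`` is the share of the per-slice variance carried
    by a per-subject, per-metric random intercept. ``vendor_offsets``
    optionally shifts metric means per manufacturer. ``n_flagged`` appends
    pathology-flagged subjects (drawn from the same distributions) that any
    normative aggregate must exclude. The seed fully determines the cohort.
    """

    n: int = 203
    male_fraction: float = 105 / 203
    mean_profiles: dict = None
    sd_profiles: dict = None
    subject_icc: float = 0.8
    vendor_probs: dict = field(
        default_factory=lambda: {"Siemens": 139 / 203, "Philips": 36 / 203, "GE": 28 / 203}
    )
    vendor_offsets: dict | None = None
    age_mean: float = 28.7
    age_sd: float = 5.6
    age_range: tuple[float, float] = (19.0, 52.0)
    n_flagged: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("cohort needs n >= 2")
        if not 0.0 <= self.subject_icc <= 1.0:
            raise ValidationError("subject_icc must be in [0, 1]")
        if self.mean_profiles is None or self.sd_profiles is None:
            mu_m, sd_m = landmark_profiles("male")
            mu_f, sd_f = landmark_profiles("female")
            object.__setattr__(self, "mean_profiles", {"M": mu_m, "F": mu_f})
            object.__setattr__(self, "sd_profiles", {"M": sd_m, "F": sd_f})
        for sex in ("M", "F"):
            if (self.sd_profiles[sex][list(METRICS)] < 0).any().any():
                raise ValidationError("SD profiles must be nonnegative")

    @classmethod
    def pooled(cls, **kwargs) -> "CohortSpec":
        """Spec with no sex effect: both sexes use the whole-cohort profiles."""
        mu, sd = landmark_profiles("all")
        return cls(mean_profiles={"M": mu, "F": mu}, sd_profiles={"M": sd, "F": sd}, **kwargs)

    @classmethod
    def study(cls, **kwargs) -> "CohortSpec":
        """The source-study composition: 203 healthy + 64 flagged subjects."""
        kwargs.setdefault("n", 203)
        kwargs.setdefault("n_flagged", 64)
        return cls(**kwargs)


# Table-1 anthropometrics per sex: (height mean, sd), (weight mean, sd)
_HEIGHT = {"M": (179.3, 7.7), "F": (165.4, 6.1)}
_WEIGHT = {"M": (75.9, 10.8), "F": (58.9, 9.9)}


def _exact_counts(n: int, probs: dict[str, float]) -> list[str]:
    """Deterministic composition: largest-remainder rounding of n*probs."""
    items = list(probs.items())
    raw = [n * p for _, p in items]
    base = [int(math.floor(r)) for r in raw]
    rem = n - sum(base)
    order = np.argsort([b - r for r, b in zip(raw, base)])
    for i in order[:rem]:
        base[i] += 1
    out = []
    for (name, _), k in zip(items, base):
        out.extend([name] * k)
    return out


def make_synthetic_cohort(
    spec: CohortSpec, template: PAM50LevelMap | None = None
) -> list[SubjectRecord]:
    """Draw a reproducible synthetic cohort of template-space records.

    Metric value at slice ``s`` for subject ``j`` of sex ``g``:
    ``mu_g(s) + vendor_offset + sigma_g(s) * (sqrt(icc)*u_jm +
    sqrt(1-icc)*e_jms)`` with ``u_jm`` a per-subject per-metric intercept
    and ``e_jms`` independent noise, both standard normal — so the marginal
    per-slice SD equals ``sigma_g(s)``.
    """
    template = template or load_pam50_level_map()
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n + spec.n_flagged

    # exact composition within the healthy and flagged blocks separately
    sexes, vendors = [], []
    for block in (spec.n, spec.n_flagged):
        s = _exact_counts(block, {"M": spec.male_fraction, "F": 1 - spec.male_fraction})
        v = _exact_counts(block, spec.vendor_probs)
        rng.shuffle(s)
        rng.shuffle(v)
        sexes += s
        vendors += v

    slices = spec.mean_profiles["M"].index
    levels = pd.Series([template.level_of_slice(int(z)) for z in slices], index=slices)
    n_slices = len(slices)
    width = len(str(n_total))

    records: list[SubjectRecord] = []
    for j in range(n_total):
        sex = sexes[j]
        vendor = vendors[j]
        flagged = j >= spec.n
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), *spec.age_range))
        h_mu, h_sd = _HEIGHT[sex]
        w_mu, w_sd = _WEIGHT[sex]
        mu = spec.mean_profiles[sex]
        sd = spec.sd_profiles[sex]
        data = pd.DataFrame(index=slices, columns=["level", *METRICS], dtype=object)
        data["level"] = levels
        u = rng.standard_normal(len(METRICS))  # per-metric subject intercept
        eps = rng.standard_normal((n_slices, len(METRICS)))
        icc = spec.subject_icc
        noise = math.sqrt(icc) * u[None, :] + math.sqrt(1 - icc) * eps
        for mi, metric in enumerate(METRICS):
            shift = 0.0
            if spec.vendor_offsets:
                shift = spec.vendor_offsets.get(vendor, {}).get(metric, 0.0)
            data[metric] = (
                mu[metric].to_numpy() + shift + sd[metric].to_numpy() * noise[:, mi]
            )
        data[list(METRICS)] = data[list(METRICS)].astype(float)
        sid = f"sub-syn{j + 1:0{width}d}"
        records.append(
            SubjectRecord(
                subject_id=sid,
                sex=sex,
                age_years=age,
                manufacturer=vendor,
                height_cm=float(rng.normal(h_mu, h_sd)),
                weight_kg=float(rng.normal(w_mu, w_sd)),
                pathology_flag=flagged,
                metrics=NormalizedMetrics(subject_id=sid, data=data),
            )
        )
    return records


def cohort_participants_table(records: list[SubjectRecord]) -> pd.DataFrame:
    """BIDS-style participants table for a synthetic cohort."""
    return pd.DataFrame(
        {
            "participant_id": [r.subject_id for r in records],
            "sex": [r.sex for r in records],
            "age": [round(r.age_years, 1) for r in records],
            "height": [round(r.height_cm, 1) for r in records],
            "weight": [round(r.weight_kg, 1) for r in records],
            "manufacturer": [r.manufacturer for r in records],
            "pathology": ["compression" if r.pathology_flag else "HC" for r in records],
        }
    )
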