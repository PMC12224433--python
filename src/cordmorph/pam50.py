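"""Template-space normalization of per-slice morphometrics.

Instead of warping images into the PAM50 spinal cord template (and
distorting the very anatomy being measured), per-slice metric profiles are
resampled level by level: for each vertebral level, the ``n`` native-space
values are placed on the normalized coordinate ``u = i/(n-1)`` and read off
by linear interpolation at the ``m`` template slices of the same level,
``u = j/(m-1)``. Disc-adjacent values therefore land exactly on
disc-adjacent template slices, and values inside a level are convex
combinations of native values of that level — no information crosses a disc
boundary.

Level span convention (applied identically in native and template space,
with the SI index increasing toward superior): the level of vertebra ``k``
spans slices ``[disc_{k+1}, disc_k - 1]``, i.e. it includes its inferior
disc slice and stops just below its superior disc slice. Disc ``k`` is the
disc at the top of vertebra ``k``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .definitions import METRICS, UNLABELED, disc_name, vertebra_id, vertebra_name
from .errors import ValidationError
from .morphometrics import SliceMorphometrics

logger = logging.getLogger(__name__)

__all__ = [
    "LevelLabeling",
    "PAM50LevelMap",
    "NormalizedMetrics",
    "load_pam50_level_map",
    "slices_per_level",
    "normalize_to_pam50",
    "mid_vertebral_slice",
]


@dataclass(frozen=True)
class LevelLabeling:
    """Disc positions along SI and the vertebral levels they delimit.

    ``disc_slices`` maps disc id ``k`` (the disc between vertebrae ``k-1``
    and ``k``) to a native SI slice index. In canonical orientation the
    index increases toward superior, so slice indices must decrease
    strictly as the disc id increases.
    """

    disc_slices: dict[int, int]

    def __post_init__(self) -> None:
        discs = {int(k): int(v) for k, v in self.disc_slices.items()}
        if not discs:
            raise ValidationError("at least one disc label is required")
        ids = sorted(discs)
        slices = [discs[k] for k in ids]
        if any(b >= a for a, b in zip(slices, slices[1:])):
            raise ValidationError(
                "disc slice indices must decrease strictly with disc id "
                f"(superior to inferior); got {discs}"
            )
        object.__setattr__(self, "disc_slices", discs)

    def complete_levels(self) -> list[int]:
        """Vertebra ids bounded by two labeled discs (superior and inferior)."""
        return [k for k in sorted(self.disc_slices) if k + 1 in self.disc_slices]

    def level_slices(self, vertebra: int) -> list[int]:
        """Native slices of a complete level, ascending (inferior->superior)."""
        if vertebra not in self.complete_levels():
            raise ValidationError(f"level {vertebra_name(vertebra)} is not bounded by two discs")
        lo = self.disc_slices[vertebra + 1]
        hi = self.disc_slices[vertebra] - 1
        return list(range(lo, hi + 1))

    def level_of_slice(self, z: int) -> str:
        """Level name at native slice ``z``, or 'unlabeled'."""
        for k in self.complete_levels():
            if self.disc_slices[k + 1] <= z < self.disc_slices[k]:
                return vertebra_name(k)
        return UNLABELED


@dataclass(frozen=True)
class PAM50LevelMap:
    """Per-level slice ranges and landmark slices of the PAM50 template.

    Same boundary semantics as :class:`LevelLabeling`, but in template slice
    coordinates (one axial slice every ``slice_thickness_mm``).
    """

    boundaries: dict[int, int]
    slice_thickness_mm: float = 0.5
    _labeling: LevelLabeling = field(repr=False, default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_labeling", LevelLabeling(self.boundaries))
        object.__setattr__(self, "boundaries", self._labeling.disc_slices)

    def levels(self) -> list[int]:
        return self._labeling.complete_levels()

    def level_names(self) -> list[str]:
        return [vertebra_name(k) for k in self.levels()]

    def level_slices(self, level: int | str) -> list[int]:
        """Template slices of a level, ascending."""
        k = level if isinstance(level, int) else vertebra_id(level)
        return self._labeling.level_slices(k)

    def all_slices(self) -> list[int]:
        """All template slices covered by complete levels, ascending."""
        lo = min(self.disc_slice(k + 1) for k in self.levels())
        hi = max(self.disc_slice(k) for k in self.levels()) - 1
        return list(range(lo, hi + 1))

    def disc_slice(self, disc: int) -> int:
        return self._labeling.disc_slices[int(disc)]

    def level_of_slice(self, z: int) -> str:
        return self._labeling.level_of_slice(z)

    def landmarks(self) -> list[tuple[str, str, int]]:
        """(kind, name, slice) for mid-level and disc landmarks, superior first.

        Discs interior to the covered span only (the artificial top-of-C1
        and bottom boundaries are skipped).
        """
        out: list[tuple[str, str, int]] = []
        levels = self.levels()
        for k in levels:
            out.append(("level", vertebra_name(k), mid_vertebral_slice(self, k)))
            if k + 1 in levels:
                out.append(("disc", disc_name(k + 1), self.disc_slice(k + 1)))
        return out


def load_pam50_level_map(path=None) -> PAM50LevelMap:
    """Load the PAM50 level map from the packaged fixture or a JSON file."""
    if path is None:
        text = resources.files("cordmorph.data").joinpath("pam50_levels.json").read_text()
    else:
        with open(path) as f:
            text = f.read()
    doc = json.loads(text)
    return PAM50LevelMap(
        boundaries={int(k): int(v) for k, v in doc["boundaries"].items()},
        slice_thickness_mm=float(doc.get("slice_thickness_mm", 0.5)),
    )


def pam50_level_map_from_labeled_seg(path) -> PAM50LevelMap:
    """Rebuild a level map from a labeled template segmentation (NIfTI).

    Each voxel of the labeled segmentation carries its vertebra id; the
    boundary of vertebra ``k`` (disc ``k``) is taken as one above the
    topmost slice labeled ``k``.
    """
    from .io import _load_canonical

    data, _ = _load_canonical(path)
    vals = np.round(data).astype(int)
    boundaries: dict[int, int] = {}
    tops: dict[int, int] = {}
    bottoms: dict[int, int] = {}
    for k in np.unique(vals):
        if k <= 0:
            continue
        zs = np.flatnonzero((vals == k).any(axis=(0, 1)))
        tops[int(k)] = int(zs.max())
        bottoms[int(k)] = int(zs.min())
    for k, top in tops.items():
        boundaries[k] = top + 1
    if tops:
        kmax = max(tops)
        boundaries[kmax + 1] = bottoms[kmax]
    return PAM50LevelMap(boundaries=boundaries)


@dataclass(frozen=True)
class NormalizedMetrics:
    """Per-PAM50-slice metric values for one subject.

    ``data`` is indexed by template slice (ascending) over the template's
    full covered span, with a ``level`` column and one column per metric;
    template slices whose level is not fully covered in native space are NaN.
    """

    subject_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("level", *METRICS) if c not in self.data.columns]
        if missing:
            raise ValidationError(f"normalized metrics missing columns {missing}")


# ---------------------------------------------------------------------------


def slices_per_level(lab: LevelLabeling) -> dict[str, list[int]]:
    """Ordered native slices of each complete level, keyed by level name.

    Levels not bounded by two discs are excluded; with a single disc label
    the map is empty (logged).
    """
    if len(lab.disc_slices) < 2:
        logger.warning("fewer than two disc labels: no complete level")
        return {}
    return {vertebra_name(k): lab.level_slices(k) for k in lab.complete_levels()}


def mid_vertebral_slice(template: PAM50LevelMap, level: int | str) -> int:
    """Template slice at the middle of a level (ties rounded toward superior)."""
    slices = template.level_slices(level)
    return (slices[0] + slices[-1] + 1) // 2


def _interp_level(native_vals: pd.Series, m: int) -> np.ndarray:
    """Resample one level's native profile onto m template slices."""
    vals = native_vals.dropna()
    n = len(vals)
    if n == 0:
        return np.full(m, np.nan)
    if n == 1:
        logger.warning("level has a single defined native slice; constant extension")
        return np.full(m, float(vals.iloc[0]))
    # normalized coordinate of the *defined* native slices within the level
    pos = np.asarray(vals.index, dtype=float)
    lo, hi = native_vals.index[0], native_vals.index[-1]
    u_native = (pos - lo) / (hi - lo)
    u_template = np.linspace(0.0, 1.0, m)
    return np.interp(u_template, u_native, vals.to_numpy(dtype=float))


def normalize_to_pam50(
    metrics: list[SliceMorphometrics] | pd.DataFrame,
    native: LevelLabeling,
    template: PAM50LevelMap,
    subject_id: str = "subject",
) -> NormalizedMetrics:
    """Interpolate native per-slice metrics onto PAM50 template slices.

    Interpolation is independent per metric and per level. Native slices on
    which a metric is undefined are dropped from that metric's interpolation
    support; levels only partially covered in native space (field-of-view
    edge) are excluded rather than extrapolated.
    """
    if isinstance(metrics, pd.DataFrame):
        native_df = metrics.set_index("slice_index") if "slice_index" in metrics.columns else metrics
    else:
        native_df = pd.DataFrame([m.as_dict() for m in metrics]).set_index("slice_index")

    t_slices = template.all_slices()
    out = pd.DataFrame(index=pd.Index(t_slices, name="pam50_slice"), columns=["level", *METRICS], dtype=object)
    out["level"] = UNLABELED
    for m in METRICS:
        out[m] = np.nan

    covered = set(native_df.index)
    for k in native.complete_levels():
        name = vertebra_name(k)
        if k not in template.levels():
            logger.warning("native level %s absent from the template map; skipped", name)
            continue
        n_slices = native.level_slices(k)
        if not any(z in covered for z in n_slices):
            continue
        t_lvl = template.level_slices(k)
        out.loc[t_lvl, "level"] = name
        # full native span of the level; metrics undefined on a slice are NaN
        lvl = native_df.reindex(n_slices)
        for metric in METRICS:
            out.loc[t_lvl, metric] = _interp_level(lvl[metric], len(t_lvl))
    out[list(METRICS)] = out[list(METRICS)].astype(float)
    return NormalizedMetrics(subject_id=subject_id, data=out)
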