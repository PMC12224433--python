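"""File formats: NIfTI volumes and labels, CSV/TSV tables, run configs.

All volumes are reoriented to canonical RAS+ on load (axis 0 right-left,
axis 1 anterior-posterior, axis 2 superior-inferior with the index
increasing toward superior); slice indices in every output refer to this
canonical orientation. CSV outputs are comma-separated UTF-8 with a header
row and empty fields for missing values.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .definitions import METRICS
from .errors import ValidationError
from .morphometrics import SegmentationVolume, SliceMorphometrics
from .normative import NormativeStats, SubjectRecord
from .pam50 import LevelLabeling, NormalizedMetrics

logger = logging.getLogger(__name__)

__all__ = [
    "read_segmentation",
    "write_segmentation",
    "read_disc_labels",
    "write_disc_labels",
    "metrics_to_frame",
    "write_native_metrics",
    "write_normalized_metrics",
    "read_normalized_metrics",
    "write_normative_stats",
    "read_normative_stats",
    "read_participants",
    "write_participants",
    "read_subject_records",
    "RunConfig",
]


def _load_canonical(path) -> tuple[np.ndarray, nib.Nifti1Image]:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValidationError(f"expected a 3D volume, got {img.ndim}D in {path}")
    orig = "".join(nib.aff2axcodes(img.affine))
    can = nib.as_closest_canonical(img)
    data = np.asanyarray(can.dataobj)
    can.extra["source_orientation"] = orig
    return data, can


def read_segmentation(path) -> SegmentationVolume:
    """Load a binary cord mask from NIfTI, reorienting to canonical RAS+.

    Values are binarized at > 0.5; soft or multi-valued content triggers a
    warning before thresholding.
    """
    data, can = _load_canonical(path)
    uniq = np.unique(data)
    if uniq.size > 2:
        logger.warning(
            "%s has %d distinct values; binarizing at > 0.5", path, uniq.size
        )
    zooms = can.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValidationError(f"invalid voxel sizes {zooms} in {path}")
    return SegmentationVolume(
        voxels=data > 0.5,
        voxel_size=tuple(float(z) for z in zooms),
        source_orientation=can.extra["source_orientation"],
    )


def write_segmentation(seg: SegmentationVolume, path) -> None:
    """Write a canonical volume as NIfTI with an RAS+ affine."""
    affine = np.diag([*seg.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(seg.voxels.astype(np.uint8), affine), str(path))


def read_disc_labels(path) -> LevelLabeling:
    """Load single-voxel disc labels from NIfTI.

    Voxel value ``k`` marks the disc at the top of vertebra ``k`` (3 is the
    C2-C3 disc). Duplicate ids, no labels, or slice order inconsistent with
    the superior-inferior axis raise errors.
    """
    data, _ = _load_canonical(path)
    ii, jj, kk = np.nonzero(data)
    if ii.size == 0:
        raise ValidationError(f"no disc labels found in {path}")
    vals = np.round(data[ii, jj, kk]).astype(int)
    discs: dict[int, int] = {}
    for v, z in zip(vals, kk):
        if v in discs:
            raise ValidationError(f"duplicate disc label {v} in {path}")
        discs[int(v)] = int(z)
    return LevelLabeling(discs)


def write_disc_labels(
    labeling: LevelLabeling, seg: SegmentationVolume, path
) -> None:
    """Write disc labels as single voxels placed on the cord centroid."""
    vol = np.zeros(seg.voxels.shape, dtype=np.int16)
    for disc, z in labeling.disc_slices.items():
        zz = int(np.clip(z, 0, seg.n_slices - 1))
        mask = seg.slice_mask(zz)
        if mask.any():
            ii, jj = np.nonzero(mask)
            vol[int(ii.mean()), int(jj.mean()), zz] = disc
        else:
            vol[vol.shape[0] // 2, vol.shape[1] // 2, zz] = disc
    affine = np.diag([*seg.voxel_size, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))


# ---------------------------------------------------------------------------
# tabular formats


def metrics_to_frame(metrics: list[SliceMorphometrics]) -> pd.DataFrame:
    """Native per-slice metrics as a DataFrame (one row per slice)."""
    return pd.DataFrame([m.as_dict() for m in metrics])


def write_native_metrics(metrics: list[SliceMorphometrics], path) -> None:
    metrics_to_frame(metrics).to_csv(path, index=False)


def write_normalized_metrics(nm: NormalizedMetrics, path) -> None:
    """Per-subject template-space CSV: one row per PAM50 slice."""
    nm.data.reset_index().to_csv(path, index=False)


def read_normalized_metrics(path, subject_id: str | None = None) -> NormalizedMetrics:
    df = pd.read_csv(path)
    if "pam50_slice" not in df.columns:
        raise ValidationError(f"{path} is not a normalized-metrics CSV")
    df = df.set_index("pam50_slice")
    return NormalizedMetrics(subject_id=subject_id or Path(path).stem, data=df)


def write_normative_stats(stats: NormativeStats, path) -> None:
    stats.to_frame().to_csv(path, index=False)


def read_normative_stats(path) -> NormativeStats:
    return NormativeStats.from_frame(pd.read_csv(path))


def read_participants(path) -> pd.DataFrame:
    """Read a BIDS participants.tsv."""
    return pd.read_csv(path, sep="\t", dtype={"participant_id": str})


def write_participants(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_subject_records(metrics_dir, participants_path) -> list[SubjectRecord]:
    """Assemble SubjectRecords from per-subject CSVs plus a participants TSV.

    Each row of the participants table must have a ``<participant_id>.csv``
    in ``metrics_dir``; rows without one are skipped with a warning.
    """
    participants = read_participants(participants_path)
    metrics_dir = Path(metrics_dir)
    records = []
    for _, row in participants.iterrows():
        f = metrics_dir / f"{row['participant_id']}.csv"
        if not f.exists():
            logger.warning("no metrics CSV for %s; skipped", row["participant_id"])
            continue
        nm = read_normalized_metrics(f, subject_id=row["participant_id"])
        pathology = str(row.get("pathology", "")).strip().lower()
        records.append(
            SubjectRecord(
                subject_id=row["participant_id"],
                sex=str(row["sex"]),
                age_years=float(row["age"]),
                manufacturer=str(row.get("manufacturer", "unknown")),
                height_cm=_opt_float(row.get("height")),
                weight_kg=_opt_float(row.get("weight")),
                pathology_flag=pathology not in ("", "n/a", "na", "nan", "none", "hc", "healthy"),
                metrics=nm,
            )
        )
    return records


def _opt_float(v) -> float | None:
    try:
        f = float(v)
    except (TypeError, ValueError):
        return None
    return f if np.isfinite(f) else None


# ---------------------------------------------------------------------------
# run configuration


@dataclasses.dataclass
class RunConfig:
    """Validated settings of a pipeline run, serialized next to its outputs."""

    command: str
    inputs: dict
    output_dir: str
    seed: int | None = None
    filters: dict = dataclasses.field(default_factory=dict)
    options: dict = dataclasses.field(default_factory=dict)

    def dump(self, path=None) -> str:
        doc = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def load(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)
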