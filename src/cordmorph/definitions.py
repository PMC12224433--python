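"""Shared vocabulary: metric names, vertebra/disc naming, canonical axes.

Canonical array orientation throughout the package is RAS+: axis 0 runs
right-left (index increasing toward the subject's Right), axis 1
anterior-posterior (toward Anterior), axis 2 superior-inferior (toward
Superior). Axial slice ``z`` therefore means ``voxels[:, :, z]``.
"""

from __future__ import annotations

#: The six per-slice morphometric measures, in canonical column order.
METRICS: tuple[str, ...] = (
    "csa_mm2",
    "ap_diameter_mm",
    "transverse_diameter_mm",
    "compression_ratio",
    "eccentricity",
    "solidity_pct",
)

#: Vertebra numbering: 1-7 cervical, 8+ thoracic.
_VERTEBRAE = {i: f"C{i}" for i in range(1, 8)}
_VERTEBRAE.update({i: f"T{i - 7}" for i in range(8, 20)})
_VERTEBRA_IDS = {name: i for i, name in _VERTEBRAE.items()}

UNLABELED = "unlabeled"


def vertebra_name(vertebra_id: int) -> str:
    """Name of vertebra ``vertebra_id`` (1 -> 'C1', 8 -> 'T1')."""
    try:
        return _VERTEBRAE[int(vertebra_id)]
    except KeyError:
        raise ValueError(f"unknown vertebra id {vertebra_id!r}") from None


def vertebra_id(name: str) -> int:
    """Inverse of :func:`vertebra_name` ('T1' -> 8)."""
    try:
        return _VERTEBRA_IDS[str(name).upper()]
    except KeyError:
        raise ValueError(f"unknown vertebra name {name!r}") from None


def disc_name(disc_id: int) -> str:
    """Name of the disc at the top of vertebra ``disc_id``.

    Disc ``k`` separates vertebrae ``k-1`` and ``k``, so disc 3 is 'C2-C3'.
    Disc 1 (the superior boundary of C1) has no anatomical name and is
    rendered 'top-C1'.
    """
    disc_id = int(disc_id)
    if disc_id == 1:
        return "top-C1"
    return f"{vertebra_name(disc_id - 1)}-{vertebra_name(disc_id)}"
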