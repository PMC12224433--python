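import numpy as np
import pandas as pd
import pytest

import cordmorph as cm


def raster_ellipse(a_rl_mm, b_ap_mm, px=0.8, offset=(0.25, 0.25), n=40):
    """Pixel-center rasterization of an axis-aligned ellipse (RL x AP semi-axes)."""
    X, Y = np.meshgrid(
        np.arange(n) - n // 2 + offset[0],
        np.arange(n) - n // 2 + offset[1],
        indexing="ij",
    )
    return (X / (a_rl_mm / px)) ** 2 + (Y / (b_ap_mm / px)) ** 2 <= 1


def tube(radius_mm=3.0, n_slices=20, px=0.8, shear_ap=0.0, n=32):
    """Stack of circles whose centers advance shear_ap pixels per slice (AP)."""
    vol = np.zeros((n, n, n_slices), dtype=bool)
    for z in range(n_slices):
        vol[:, :, z] = raster_ellipse(
            radius_mm, radius_mm, px, offset=(0.25, 0.25 + shear_ap * z), n=n
        )
    return cm.SegmentationVolume(voxels=vol, voxel_size=(px, px, px))


def measure_phantom(spec):
    """Run the morphometrics pipeline on a phantom; join with its ground truth."""
    seg, lab, gt = cm.make_cord_phantom(spec)
    cl = cm.extract_centerline(seg)
    levels = {int(z): lab.level_of_slice(int(z)) for z in seg.nonempty_slices()}
    res = cm.compute_slice_morphometrics(seg, cl, levels)
    df = pd.DataFrame([m.as_dict() for m in res]).set_index("slice_index")
    return seg, lab, df.join(gt, rsuffix="_gt")


@pytest.fixture(scope="session")
def template():
    return cm.load_pam50_level_map()


@pytest.fixture(scope="session")
def cervical_measured():
    """Default cervical phantom (0.8 mm isotropic) measured end to end."""
    return measure_phantom(cm.PhantomSpec.cervical())


@pytest.fixture(scope="session")
def cervical_measured_tilt30():
    return measure_phantom(cm.PhantomSpec.cervical(tilt_deg=30.0))


@pytest.fixture(scope="session")
def cohort_203():
    """Table-seeded synthetic cohort matching the study composition."""
    return cm.make_synthetic_cohort(cm.CohortSpec(seed=1))


def native_frame(slices, csa):
    """Native metrics frame with csa as the probe metric (others constant)."""
    df = pd.DataFrame({"slice_index": list(slices), "level": "C3", "csa_mm2": csa})
    for m in cm.METRICS[1:]:
        df[m] = 1.0
    df["angle_deg"] = 0.0
    return df


def native_frame_builder():
    return native_frame


def toy_records(values_by_subject, slices=(100, 101, 102), **attrs):
    """Records whose csa equals the given per-subject constant (others = 1)."""
    recs = []
    for i, v in enumerate(values_by_subject):
        data = pd.DataFrame(index=pd.Index(slices, name="pam50_slice"))
        data["level"] = "C3"
        for m in cm.METRICS:
            data[m] = 1.0
        data["csa_mm2"] = v
        a = {"sex": "M" if i % 2 == 0 else "F", "age_years": 25.0, "manufacturer": "Siemens"}
        a.update(attrs)
        recs.append(
            cm.SubjectRecord(
                subject_id=f"sub-{i:02d}",
                metrics=cm.NormalizedMetrics(subject_id=f"sub-{i:02d}", data=data),
                **a,
            )
        )
    return recs


@pytest.fixture
def toy_cohort_builder():
    return toy_records


def per_level_mean_error_pct(joined, metric):
    """Max |level-mean measured - level-mean truth| / truth, in percent."""
    lv = joined[joined.level != "unlabeled"]
    g = lv.groupby("level").apply(
        lambda d: 100.0 * abs(d[metric].mean() - d[metric + "_gt"].mean()) / d[metric + "_gt"].mean(),
        include_groups=False,
    )
    return float(g.max())
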