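"""Normative database construction and subject-vs-database comparison.

Once every subject's morphometrics live on the same PAM50 slice grid, the
database is a per-slice, per-metric aggregate over a filtered healthy
cohort: subject count ``n``, mean, sample SD (``n-1`` denominator) and
coefficient of variation ``COV = 100 * SD / mean``. On top of this sit

* COV profiles (per slice, averaged per vertebral level, and overall
  across all slices as mean +/- SD),
* landmark tables — mean +/- SD rows at the disc and mid-vertebral
  template slices, the format normative values are conventionally
  reported in,
* Z-scoring of a new subject against the database,
* per-slice two-group comparisons with the Wilcoxon rank-sum test at
  alpha = 0.001 (no multiple-testing correction; the stringent alpha is
  the stated control),
* cohort selection and demographics from a BIDS participants table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .definitions import METRICS
from .errors import DegenerateInputError, ValidationError
from .pam50 import NormalizedMetrics, PAM50LevelMap

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectRecord",
    "CohortFilter",
    "NormativeStats",
    "CovProfile",
    "select_cohort",
    "aggregate",
    "cov_profile",
    "landmark_table",
    "format_landmark_table",
    "z_score",
    "compare_groups",
    "demographics",
    "AGE_DECADES",
]

#: Age decade bins, upper bound inclusive (age 30 belongs to '21-30').
AGE_DECADES: tuple[tuple[int, int], ...] = ((10, 20), (21, 30), (31, 40), (41, 50), (51, 60))

#: participants-table values treated as "no pathology".
_HEALTHY_TOKENS = {"", "n/a", "na", "nan", "none", "hc", "healthy"}

STATS_COLUMNS = ("n", "mean", "sd", "cov_pct")


def age_decade(age: float) -> str | None:
    """Decade label for an age, or None outside the binning range."""
    for lo, hi in AGE_DECADES:
        if lo <= age <= hi:
            return f"{lo}-{hi}"
    return None


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's demographics plus template-space metrics."""

    subject_id: str
    sex: str
    age_years: float
    manufacturer: str
    metrics: NormalizedMetrics
    height_cm: float | None = None
    weight_kg: float | None = None
    pathology_flag: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass(frozen=True)
class CohortFilter:
    """Demographic/scanner filter applied before aggregation.

    Each field is None (no restriction) or a collection of allowed values;
    age decades use the labels of :data:`AGE_DECADES` (e.g. '21-30').
    """

    sex: frozenset | None = None
    age_decades: frozenset | None = None
    manufacturers: frozenset | None = None

    @classmethod
    def make(cls, sex=None, age_decades=None, manufacturers=None) -> "CohortFilter":
        def norm(v):
            if v is None:
                return None
            if isinstance(v, str):
                v = [v]
            return frozenset(v)

        return cls(norm(sex), norm(age_decades), norm(manufacturers))

    def matches(self, rec: SubjectRecord) -> bool:
        if self.sex is not None and rec.sex not in self.sex:
            return False
        if self.age_decades is not None and age_decade(rec.age_years) not in self.age_decades:
            return False
        if self.manufacturers is not None and rec.manufacturer not in self.manufacturers:
            return False
        return True


@dataclass(frozen=True)
class NormativeStats:
    """Per-slice, per-metric normative aggregate.

    ``data`` has a MultiIndex column per (metric, stat) with stats
    ``n, mean, sd, cov_pct``, indexed by PAM50 slice; ``levels`` maps each
    slice to its level name.
    """

    data: pd.DataFrame
    levels: pd.Series
    n_subjects: int

    def get(self, metric: str, stat: str) -> pd.Series:
        return self.data[(metric, stat)]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: pam50_slice, level, metric, n, mean, sd, cov_pct."""
        rows = self.data.stack(level=0, future_stack=True).reset_index()
        rows.columns = ["pam50_slice", "metric", *STATS_COLUMNS]
        rows.insert(1, "level", rows["pam50_slice"].map(self.levels))
        return rows

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_subjects: int | None = None) -> "NormativeStats":
        wide = frame.pivot(index="pam50_slice", columns="metric", values=list(STATS_COLUMNS))
        wide = wide.swaplevel(axis=1).sort_index(axis=1)
        levels = frame.drop_duplicates("pam50_slice").set_index("pam50_slice")["level"]
        n = int(n_subjects if n_subjects is not None else np.nanmax(frame["n"]))
        return cls(data=wide, levels=levels, n_subjects=n)


# ---------------------------------------------------------------------------
# cohort selection and demographics


def select_cohort(participants: pd.DataFrame, exclusion_rule=None) -> list[str]:
    """Subject ids whose pathology column is empty/healthy.

    ``exclusion_rule`` optionally takes a row and returns True to exclude
    it on top of the pathology screen.
    """
    for col in ("participant_id", "pathology"):
        if col not in participants.columns:
            raise ValidationError(f"participants table lacks required column {col!r}")
    if participants.empty:
        logger.warning("empty participants table: empty cohort")
        return []

    def healthy(v) -> bool:
        if pd.isna(v):
            return True
        return str(v).strip().lower() in _HEALTHY_TOKENS

    keep = participants["pathology"].map(healthy)
    if exclusion_rule is not None:
        keep &= ~participants.apply(exclusion_rule, axis=1).astype(bool)
    included = participants.loc[keep, "participant_id"].tolist()
    logger.info(
        "cohort selection: %d included, %d excluded of %d",
        len(included), len(participants) - len(included), len(participants),
    )
    return included


def demographics(participants: pd.DataFrame, cohort: list[str] | None = None) -> pd.DataFrame:
    """Descriptive statistics of age/height/weight, whole cohort and per sex.

    Returns one row per variable with mean/SD overall and per sex, the
    Shapiro-Wilk normality p-value (whole cohort), and the male-vs-female
    Wilcoxon rank-sum p-value. Missing values are dropped pairwise (counts
    logged).
    """
    df = participants
    if cohort is not None:
        df = df[df["participant_id"].isin(set(cohort))]
    for col in ("age", "sex"):
        if col not in df.columns:
            raise ValidationError(f"participants table lacks required column {col!r}")
    rows = []
    for var in ("age", "height", "weight"):
        if var not in df.columns:
            continue
        x = pd.to_numeric(df[var], errors="coerce")
        n_missing = int(x.isna().sum())
        if n_missing:
            logger.info("demographics: %d missing values dropped for %s", n_missing, var)
        xm = x[(df["sex"] == "M") & x.notna()]
        xf = x[(df["sex"] == "F") & x.notna()]
        xall = x.dropna()
        row = {
            "variable": var,
            "n": len(xall),
            "mean": xall.mean(),
            "sd": xall.std(ddof=1),
            "mean_M": xm.mean(),
            "sd_M": xm.std(ddof=1),
            "mean_F": xf.mean(),
            "sd_F": xf.std(ddof=1),
        }
        row["shapiro_p"] = sps.shapiro(xall).pvalue if len(xall) >= 3 else np.nan
        row["p_M_vs_F"] = (
            sps.ranksums(xm, xf).pvalue if len(xm) >= 2 and len(xf) >= 2 else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# aggregation


def _metric_panel(records: list[SubjectRecord], metric: str) -> pd.DataFrame:
    """Slice x subject matrix of one metric."""
    return pd.DataFrame(
        {r.subject_id: r.metrics.data[metric] for r in records}
    )


def aggregate(
    records: list[SubjectRecord],
    cohort_filter: CohortFilter | None = None,
    min_n: int = 2,
) -> NormativeStats:
    """Per-slice per-metric n/mean/SD/COV over a filtered cohort.

    Pathology-flagged records never enter the aggregate. Slices with fewer
    than ``min_n`` contributing subjects are reported missing (NaN stats,
    true ``n``). Sample SD (``ddof=1``) throughout.
    """
    kept = [r for r in records if not r.pathology_flag]
    if len(kept) < len(records):
        logger.info("aggregate: %d pathology-flagged records excluded", len(records) - len(kept))
    if cohort_filter is not None:
        kept = [r for r in kept if cohort_filter.matches(r)]
    if len(kept) < 2:
        raise DegenerateInputError(f"need at least 2 records after filtering, got {len(kept)}")

    blocks = {}
    levels = kept[0].metrics.data["level"]
    for metric in METRICS:
        panel = _metric_panel(kept, metric)
        n = panel.notna().sum(axis=1)
        mean = panel.mean(axis=1)
        sd = panel.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = 100.0 * sd / mean.where(mean != 0)
        low = n < min_n
        mean[low] = np.nan
        sd[low] = np.nan
        cov[low] = np.nan
        blocks[metric] = pd.DataFrame(
            {"n": n, "mean": mean, "sd": sd, "cov_pct": cov}
        )
    data = pd.concat(blocks, axis=1)
    data.index.name = "pam50_slice"
    return NormativeStats(data=data, levels=levels, n_subjects=len(kept))


@dataclass(frozen=True)
class CovProfile:
    """COV summaries: per slice, averaged per level, and overall."""

    per_slice: pd.DataFrame  # slice x metric
    per_level: pd.DataFrame  # level x metric
    overall: pd.DataFrame  # metric x (mean, sd)


def cov_profile(stats: NormativeStats, template: PAM50LevelMap) -> CovProfile:
    """COV per slice, mean COV per vertebral level, and overall mean +/- SD.

    The overall figure is the mean and sample SD of the per-slice COV over
    all covered template slices.
    """
    per_slice = pd.DataFrame(
        {m: stats.get(m, "cov_pct") for m in METRICS}
    )
    level_of = pd.Series(
        {z: template.level_of_slice(z) for z in per_slice.index}, name="level"
    )
    per_level = per_slice.groupby(level_of).mean()
    per_level = per_level.reindex(template.level_names())
    overall = pd.DataFrame(
        {"mean": per_slice.mean(), "sd": per_slice.std(ddof=1)}
    )
    overall.index.name = "metric"
    return CovProfile(per_slice=per_slice, per_level=per_level, overall=overall)


# ---------------------------------------------------------------------------
# landmark tables


def landmark_table(stats: NormativeStats, template: PAM50LevelMap) -> pd.DataFrame:
    """Normative mean +/- SD at disc and mid-vertebral template slices.

    Rows alternate mid-level and disc landmarks from superior to inferior;
    columns carry ``<metric>_mean`` / ``<metric>_sd`` plus the landmark's
    template slice. Landmarks without data are rows of NaN.
    """
    rows = []
    for kind, name, sl in template.landmarks():
        row = {"landmark": f"{kind.capitalize()} {name}", "pam50_slice": sl}
        if sl in stats.data.index:
            for m in METRICS:
                row[f"{m}_mean"] = stats.get(m, "mean").get(sl, np.nan)
                row[f"{m}_sd"] = stats.get(m, "sd").get(sl, np.nan)
            row["n"] = int(stats.get(METRICS[0], "n").get(sl, 0))
        else:
            logger.warning("landmark %s %s at slice %d has no data", kind, name, sl)
            for m in METRICS:
                row[f"{m}_mean"] = np.nan
                row[f"{m}_sd"] = np.nan
            row["n"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


def format_landmark_table(table: pd.DataFrame, decimals: int = 2) -> pd.DataFrame:
    """Human-readable 'mean ± sd' rendering of :func:`landmark_table`."""
    out = table[["landmark", "pam50_slice"]].copy()
    for m in METRICS:
        out[m] = [
            "" if pd.isna(mu) else f"{round(mu, decimals)} ± {round(sd, decimals)}"
            for mu, sd in zip(table[f"{m}_mean"], table[f"{m}_sd"])
        ]
    return out


# ---------------------------------------------------------------------------
# subject comparison


def z_score(subject: NormalizedMetrics, stats: NormativeStats) -> pd.DataFrame:
    """Per-slice, per-metric Z-scores of one subject against the database.

    ``z = (x - mean) / sd``; NaN wherever the subject or the database lacks
    data, or the database SD is zero (flagged in the log).
    """
    out = {}
    for m in METRICS:
        x = subject.data[m]
        mu = stats.get(m, "mean").reindex(x.index)
        sd = stats.get(m, "sd").reindex(x.index)
        zero = sd == 0
        if zero.any():
            logger.warning("z_score: %s has %d slices with zero SD", m, int(zero.sum()))
        out[m] = (x - mu) / sd.where(~zero)
    z = pd.DataFrame(out)
    z.insert(0, "level", subject.data["level"])
    return z


def compare_groups(
    records: list[SubjectRecord],
    grouping: str,
    groups: tuple[str, str],
    metric: str,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Per-slice two-sided Wilcoxon rank-sum comparison of two groups.

    ``grouping`` is a SubjectRecord attribute ('sex' or 'manufacturer');
    ``groups`` the two values to compare. Returns per-slice n per group,
    p-value and a significance flag at ``alpha``. No multiple-testing
    correction is applied. Slices with fewer than 2 subjects in either
    group get NaN p-values.
    """
    attr = {"sex": "sex", "manufacturer": "manufacturer"}.get(grouping, grouping)
    ga = [r for r in records if getattr(r, attr) == groups[0]]
    gb = [r for r in records if getattr(r, attr) == groups[1]]
    if not ga or not gb:
        raise DegenerateInputError(f"empty group in {groups} for {grouping!r}")
    pa = _metric_panel(ga, metric)
    pb = _metric_panel(gb, metric)
    idx = pa.index
    pvals = np.full(len(idx), np.nan)
    na = pa.notna().sum(axis=1).to_numpy()
    nb = pb.notna().sum(axis=1).to_numpy()
    a_arr = pa.to_numpy(dtype=float)
    b_arr = pb.to_numpy(dtype=float)
    for i in range(len(idx)):
        if na[i] < 2 or nb[i] < 2:
            continue
        a = a_arr[i][~np.isnan(a_arr[i])]
        b = b_arr[i][~np.isnan(b_arr[i])]
        if np.array_equal(a, b):
            pvals[i] = 1.0
            continue
        pvals[i] = sps.ranksums(a, b).pvalue
    out = pd.DataFrame(
        {"n_a": na, "n_b": nb, "p_value": pvals}, index=idx
    )
    out["significant"] = out["p_value"] < alpha
    return out
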