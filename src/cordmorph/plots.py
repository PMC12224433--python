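"""Static profile figures for normative databases."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .definitions import METRICS
from .normative import CovProfile, NormativeStats
from .pam50 import PAM50LevelMap

_LABELS = {
    "csa_mm2": "CSA [mm$^2$]",
    "ap_diameter_mm": "AP diameter [mm]",
    "transverse_diameter_mm": "Transverse diameter [mm]",
    "compression_ratio": "Compression ratio [a.u.]",
    "eccentricity": "Eccentricity [a.u.]",
    "solidity_pct": "Solidity [%]",
}


def _annotate_levels(ax, template: PAM50LevelMap) -> None:
    for k in template.levels():
        slices = template.level_slices(k)
        ax.axvline(slices[0], color="0.85", lw=0.6, zorder=0)
        from .pam50 import mid_vertebral_slice

        ax.text(
            mid_vertebral_slice(template, k),
            0.02,
            template.level_names()[template.levels().index(k)],
            transform=ax.get_xaxis_transform(),
            ha="center",
            fontsize=7,
            color="0.4",
        )


def plot_metric_profiles(stats: NormativeStats, template: PAM50LevelMap, path, title=None) -> None:
    """Mean +/- SD band of each metric across PAM50 slices, level-annotated."""
    fig, axes = plt.subplots(2, 3, figsize=(13, 6), sharex=True)
    for ax, metric in zip(axes.ravel(), METRICS):
        mu = stats.get(metric, "mean")
        sd = stats.get(metric, "sd")
        ax.plot(mu.index, mu, lw=1.2)
        ax.fill_between(mu.index, mu - sd, mu + sd, alpha=0.3, lw=0)
        ax.set_ylabel(_LABELS[metric], fontsize=8)
        ax.invert_xaxis()  # superior on the left, matching radiological profiles
        _annotate_levels(ax, template)
    for ax in axes[1]:
        ax.set_xlabel("PAM50 axial slice")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cov_profile(cov: CovProfile, template: PAM50LevelMap, path, title=None) -> None:
    """Per-slice COV scatter with the overall mean +/- SD in the panel title."""
    fig, axes = plt.subplots(2, 3, figsize=(13, 6), sharex=True)
    for ax, metric in zip(axes.ravel(), METRICS):
        s = cov.per_slice[metric]
        ax.scatter(s.index, s, s=4)
        mu = cov.overall.loc[metric, "mean"]
        sd = cov.overall.loc[metric, "sd"]
        ax.set_title(f"{_LABELS[metric]}: COV {mu:.1f} ± {sd:.1f}%", fontsize=8)
        ax.set_ylabel("COV [%]", fontsize=8)
        ax.invert_xaxis()
        _annotate_levels(ax, template)
    for ax in axes[1]:
        ax.set_xlabel("PAM50 axial slice")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
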