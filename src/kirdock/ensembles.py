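"""Conformer-ensemble docking: ranked score profiles and their comparison."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .dockengine import DockConfig, PoseList, dock_rigid
from .errors import ParameterError
from .structio import StructureBundle

__all__ = [
    "ScoreProfile",
    "ProfileComparison",
    "BundleDockResult",
    "score_profile",
    "top_k_mean",
    "dock_bundle",
    "compare_profiles",
    "profiles_table",
    "plot_profiles",
]


@dataclass
class ScoreProfile:
    """Descending top-N pose scores for one channel/conformer pairing."""

    channel_label: str
    conformer_index: int
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ParameterError("profile scores must be a 1-D vector")

    def __len__(self) -> int:
        return len(self.scores)


def score_profile(poselist: PoseList, n: int = 2000,
                  channel_label: str | None = None,
                  conformer_index: int = 0) -> ScoreProfile:
    """Descending truncation of a pose list's scores to the top ``n``."""
    if n <= 0:
        raise ParameterError("profile length must be positive")
    if len(poselist) == 0:
        raise ParameterError("cannot profile an empty pose list")
    scores = np.sort(poselist.scores())[::-1][:n]
    return ScoreProfile(
        channel_label if channel_label is not None else poselist.receptor_id,
        conformer_index, scores,
    )


def top_k_mean(profile: ScoreProfile, k: int = 5) -> float:
    """Mean of the first min(k, len) profile scores."""
    if k <= 0:
        raise ParameterError("k must be positive")
    if len(profile) == 0:
        raise ParameterError("empty profile")
    if len(profile) < k:
        warnings.warn(
            f"profile has only {len(profile)} scores; top-{k} mean uses all "
            "of them", stacklevel=2,
        )
    return float(np.mean(profile.scores[:k]))


@dataclass
class ProfileComparison:
    """Rank-wise dominance plus a Mann-Whitney U comparison of two profiles."""

    label_a: str
    label_b: str
    dominance: float            # fraction of shared ranks where a > b (ties 0.5)
    u_statistic: float
    p_value: float
    top_k_mean_difference: float
    n_ranks: int


def compare_profiles(a: ScoreProfile, b: ScoreProfile,
                     top_k: int = 5) -> ProfileComparison:
    """Compare two ranked score profiles.

    ``comparison(a, b)`` mirrors ``comparison(b, a)``: dominance fractions
    sum to 1 and the two-sided p-value is identical.
    """
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("profiles must be non-empty")
    n = min(len(a), len(b))
    sa, sb = a.scores[:n], b.scores[:n]
    wins = np.sum(sa > sb) + 0.5 * np.sum(sa == sb)
    u_stat, p_value = mannwhitneyu(a.scores, b.scores, alternative="two-sided")
    return ProfileComparison(
        label_a=a.channel_label, label_b=b.channel_label,
        dominance=float(wins / n),
        u_statistic=float(u_stat), p_value=float(p_value),
        top_k_mean_difference=top_k_mean(a, min(top_k, n)) - top_k_mean(b, min(top_k, n)),
        n_ranks=int(n),
    )


@dataclass
class BundleDockResult:
    """Per-conformer profiles plus the best-conformer summary."""

    profiles: list[ScoreProfile]
    best_conformer_index: int
    best_top_k_mean: float
    top_k: int = 5
    pose_lists: list[PoseList] = field(default_factory=list)


def dock_bundle(
    receptor: StructureBundle,
    bundle: StructureBundle,
    config: DockConfig | None = None,
    profile_n: int = 2000,
    top_k: int = 5,
    keep_pose_lists: bool = False,
) -> BundleDockResult:
    """Dock every model of a conformer bundle against one receptor.

    Deterministic: each conformer is docked with the identical config and the
    argmax conformer by top-k mean is reported (ties -> lowest index).
    """
    if bundle.n_models == 0:
        raise ParameterError("empty conformer bundle")
    config = config or DockConfig()
    profiles: list[ScoreProfile] = []
    pose_lists: list[PoseList] = []
    for m in range(bundle.n_models):
        poselist = dock_rigid(receptor, bundle, config, ligand_model_index=m)
        profiles.append(score_profile(poselist, profile_n,
                                      channel_label=receptor.identifier,
                                      conformer_index=m))
        if keep_pose_lists:
            pose_lists.append(poselist)
    means = [top_k_mean(p, min(top_k, len(p))) for p in profiles]
    best = int(np.argmax(means))
    return BundleDockResult(profiles, best, float(means[best]), top_k, pose_lists)


def profiles_table(profiles: list[ScoreProfile]) -> pd.DataFrame:
    """Wide table: one rank column plus one score column per profile."""
    n = max(len(p) for p in profiles)
    data = {"rank": np.arange(1, n + 1)}
    for p in profiles:
        column = f"{p.channel_label}:{p.conformer_index}"
        padded = np.full(n, np.nan)
        padded[:len(p)] = p.scores
        data[column] = padded
    return pd.DataFrame(data)


def plot_profiles(profiles: list[ScoreProfile], path: str | Path,
                  title: str = "Docking score profiles") -> Path:
    """Rank-vs-score curves, one per profile (saved to ``path``)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for p in profiles:
        ax.plot(np.arange(1, len(p) + 1), p.scores,
                label=f"{p.channel_label}:{p.conformer_index}")
    ax.set_xlabel("rank")
    ax.set_ylabel("docking score")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
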