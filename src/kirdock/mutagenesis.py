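"""In silico site-directed mutagenesis screen: enumerate, rebuild, re-dock."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path
from typing import Sequence

from .dockengine import DockConfig, dock_rigid
from .ensembles import (
    ProfileComparison,
    ScoreProfile,
    compare_profiles,
    score_profile,
    top_k_mean,
)
from .grafting import ChimeraSpec, apply_mutations, mutation_label, thread_chimera
from .structio import StructureBundle
from .symmetry import OperatorSet, assemble_oligomer

__all__ = [
    "MutationSet",
    "ScanRow",
    "ScanResult",
    "ReceptorBuilder",
    "enumerate_variants",
    "mutation_scan",
    "hotspot_rank",
]


@dataclass(frozen=True)
class MutationSet:
    """One or more vestibule-position mutations applied together."""

    mutations: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _, _ in self.mutations]
        if len(positions) != len(set(positions)):
            raise ValueError(f"duplicate positions in mutation set: {positions}")

    @classmethod
    def single(cls, position: int, from_aa: str, to_aa: str) -> "MutationSet":
        return cls(((position, from_aa.upper(), to_aa.upper()),))

    @property
    def label(self) -> str:
        return mutation_label(self.mutations)

    @property
    def positions(self) -> set[int]:
        return {p for p, _, _ in self.mutations}


def enumerate_variants(
    base: ChimeraSpec,
    singles: Sequence[MutationSet],
    combine_up_to: int = 1,
) -> list[ChimeraSpec]:
    """All 1..k-subsets of the single mutation sets, as chimera specs.

    Combinations with conflicting positions are skipped with a warning;
    duplicates (by label) are removed; output order is deterministic
    (subset size, then submission order).
    """
    variants: list[ChimeraSpec] = []
    seen: set[str] = set()
    for size in range(1, max(0, combine_up_to) + 1):
        for combo in combinations(range(len(singles)), size):
            sets = [singles[i] for i in combo]
            positions: list[int] = []
            for s in sets:
                positions.extend(s.positions)
            if len(positions) != len(set(positions)):
                warnings.warn(
                    f"skipping conflicting combination "
                    f"{'+'.join(s.label for s in sets)}", stacklevel=2,
                )
                continue
            mutations = tuple(sorted(m for s in sets for m in s.mutations))
            label = mutation_label(mutations)
            if label in seen:
                continue
            seen.add(label)
            variants.append(replace(base, mutations=mutations, label=label))
    return variants


@dataclass
class ReceptorBuilder:
    """Thread a chimera spec and reassemble the homotetramer it encodes."""

    template: StructureBundle
    operators: OperatorSet
    length_tolerance: int = 0

    def build(self, spec: ChimeraSpec) -> StructureBundle:
        resolved = apply_mutations(spec)
        subunit, _report = thread_chimera(self.template, resolved,
                                          length_tolerance=self.length_tolerance)
        tetramer, _clashes = assemble_oligomer(subunit, self.operators)
        tetramer.identifier = spec.label or "variant"
        return tetramer


@dataclass
class ScanRow:
    label: str
    n_mutations: int
    top_k_mean: float
    gain: float                         # vs base, same metric
    profile: ScoreProfile
    comparisons: dict[str, ProfileComparison] = field(default_factory=dict)
    failed: bool = False
    error: str = ""


@dataclass
class ScanResult:
    base: ScanRow
    rows: dict[str, ScanRow]
    references: dict[str, ScoreProfile] = field(default_factory=dict)
    top_k: int = 5

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["label\tn_mutations\ttop_k_mean\tgain\tfailed"]
        for row in [self.base, *self.rows.values()]:
            lines.append(f"{row.label}\t{row.n_mutations}\t"
                         f"{row.top_k_mean:.6f}\t{row.gain:.6f}\t"
                         f"{int(row.failed)}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def mutation_scan(
    base: ChimeraSpec,
    variants: Sequence[ChimeraSpec],
    builder: ReceptorBuilder,
    ligand: StructureBundle,
    config: DockConfig | None = None,
    reference_profiles: dict[str, ScoreProfile] | None = None,
    top_k: int = 5,
    ligand_model_index: int = 0,
) -> ScanResult:
    """Dock the base chimera and every variant with an identical config.

    A variant whose build or docking fails is recorded as a failed row and
    the scan continues.  Results are keyed by variant label and fully
    deterministic.
    """
    config = config or DockConfig()

    def run(spec: ChimeraSpec) -> ScanRow:
        label = spec.label or mutation_label(spec.mutations)
        try:
            receptor = builder.build(spec)
            poselist = dock_rigid(receptor, ligand, config,
                                  ligand_model_index=ligand_model_index)
            profile = score_profile(poselist, config.top_n, channel_label=label,
                                    conformer_index=ligand_model_index)
            metric = top_k_mean(profile, min(top_k, len(profile)))
            row = ScanRow(label=label, n_mutations=len(spec.mutations),
                          top_k_mean=metric, gain=0.0, profile=profile)
            for ref_label, ref_profile in (reference_profiles or {}).items():
                row.comparisons[ref_label] = compare_profiles(profile, ref_profile)
            return row
        except Exception as exc:  # recorded, never aborts the sweep
            return ScanRow(label=label, n_mutations=len(spec.mutations),
                           top_k_mean=float("nan"), gain=float("nan"),
                           profile=ScoreProfile(label, ligand_model_index, [0.0]),
                           failed=True, error=str(exc))

    base_spec = base if base.label else replace(base, label="base")
    base_row = run(base_spec)
    rows: dict[str, ScanRow] = {}
    for spec in variants:
        row = run(spec)
        if not row.failed and not base_row.failed:
            row.gain = row.top_k_mean - base_row.top_k_mean
        rows[row.label] = row
    return ScanResult(base=base_row, rows=rows,
                      references=dict(reference_profiles or {}), top_k=top_k)


def hotspot_rank(
    scan: ScanResult, metric: str = "top_k_mean_gain"
) -> list[tuple[str, float]]:
    """Variants ordered by descending gain over base; ties by label."""
    if metric != "top_k_mean_gain":
        raise ValueError(f"unknown hotspot metric {metric!r}")
    usable = [(label, row.gain) for label, row in scan.rows.items()
              if not row.failed]
    usable.sort(key=lambda item: (-item[1], item[0]))
    return usable
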