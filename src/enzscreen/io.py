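"""Readers, writers, packaged fixtures and pipeline configuration.

All tabular IO is delimited text (CSV) via pandas; reports and manifests
are JSON.  The packaged fixtures transcribe, with one decimal as printed,
the benchmark activity table (``set_s``), the combinatorial substitution
library (``library``), the sterically forbidden pairs (``exclusions``) and
the top-20 screened candidates (``set_l_top20``).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .benchmark import ActivityRecord, ClassificationThresholds
from .mutants import ExclusionConstraint, MutationLibrary, parse_mutant
from .profiles import BarrierAnalysis, EnergyProfile, FilterConfig

FIXTURES = ("set_s", "library", "exclusions", "set_l_top20")


def _fixture_path(name: str):
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURES}")
    return resources.files("enzscreen.data").joinpath(f"{name}.csv")


def load_fixture(name: str):
    """Load a packaged table as its typed in-memory form.

    ``set_s`` -> list[ActivityRecord] (23 rows including the WT reference);
    ``library`` -> MutationLibrary; ``exclusions`` -> ExclusionConstraint;
    ``set_l_top20`` -> list[(mutant, barrier)].
    """
    with resources.as_file(_fixture_path(name)) as path:
        if name == "set_s":
            return read_activity_table(path)
        if name == "library":
            return read_library(path)
        if name == "exclusions":
            return read_exclusions(path)
        return read_ranked_table(path)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _numeric(df: pd.DataFrame, column: str, path) -> pd.Series:
    converted = pd.to_numeric(df[column], errors="coerce")
    bad = df.index[converted.isna() & df[column].notna()]
    if len(bad):
        row = int(bad[0]) + 2  # 1-based plus header line
        raise ValueError(
            f"{path}: non-numeric value {df[column][bad[0]]!r} in column "
            f"{column!r} at line {row}"
        )
    return converted


def read_activity_table(path) -> list[ActivityRecord]:
    """Activity table: columns mutant, activity_fold_wt, barrier_kcal_mol[, organism]."""
    df = pd.read_csv(path)
    _require_columns(df, ["mutant", "activity_fold_wt", "barrier_kcal_mol"], path)
    activities = _numeric(df, "activity_fold_wt", path)
    barriers = _numeric(df, "barrier_kcal_mol", path)
    records = []
    for idx, row in df.iterrows():
        organism = row.get("organism")
        records.append(
            ActivityRecord(
                mutant=str(row["mutant"]).strip(),
                activity=float(activities[idx]),
                barrier=float(barriers[idx]),
                organism=None if pd.isna(organism) else str(organism),
            )
        )
    return records


def read_library(path) -> MutationLibrary:
    df = pd.read_csv(path)
    _require_columns(df, ["position", "wt_residue", "allowed_substitutions"], path)
    positions = _numeric(df, "position", path)
    records = []
    for idx, row in df.iterrows():
        subs = [s.strip() for s in str(row["allowed_substitutions"]).split(",") if s.strip()]
        records.append((int(positions[idx]), str(row["wt_residue"]).strip(), subs))
    return MutationLibrary.from_records(records)


def read_exclusions(path) -> ExclusionConstraint:
    df = pd.read_csv(path)
    _require_columns(df, ["mutation_a", "mutation_b"], path)
    return ExclusionConstraint.from_pairs(
        [(str(a).strip(), str(b).strip()) for a, b in zip(df["mutation_a"], df["mutation_b"])]
    )


def read_ranked_table(path) -> list[tuple[str, float]]:
    df = pd.read_csv(path)
    _require_columns(df, ["mutant", "barrier_kcal_mol"], path)
    barriers = _numeric(df, "barrier_kcal_mol", path)
    return [
        (str(m).strip(), float(b)) for m, b in zip(df["mutant"], barriers)
    ]


def read_profiles(path) -> list[EnergyProfile]:
    """Profile file: columns mutant, frame, energy_kcal_mol; many mutants per file."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["mutant", "frame", "energy_kcal_mol"], path)
    _numeric(df, "frame", path)
    _numeric(df, "energy_kcal_mol", path)
    profiles = []
    for mutant, group in df.groupby("mutant", sort=True):
        group = group.sort_values("frame")
        profiles.append(
            EnergyProfile(
                mutant=str(mutant),
                points=tuple(
                    (int(f), float(e))
                    for f, e in zip(group["frame"], group["energy_kcal_mol"])
                ),
            )
        )
    return profiles


def write_profiles(profiles: Iterable[EnergyProfile], path) -> None:
    rows = [
        {"mutant": p.mutant, "frame": f, "energy_kcal_mol": e}
        for p in profiles
        for f, e in p.points
    ]
    # %.17g round-trips doubles exactly through the text format
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_analyses(analyses: Iterable[BarrierAnalysis], path) -> None:
    rows = [
        {
            "mutant": a.mutant,
            "barrier": a.barrier,
            "peak_frame": a.peak_frame,
            "regular": a.regular,
            "disposition": a.disposition.value,
        }
        for a in analyses
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json_report(obj, path) -> None:
    """Deterministic JSON: sorted keys, no timestamps."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative configuration with full defaulting; unknown keys rejected."""

    improve_min: float = 1.2
    degrade_max: float = 0.8
    barrier_cutoff: float = 12.5
    barrier_max: float = 19.0
    peak_similarity_window: float = 2.0
    n_segments: int = 10
    ranking_n: int = 20
    max_order: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def thresholds(self) -> ClassificationThresholds:
        return ClassificationThresholds(
            improve_min=self.improve_min,
            degrade_max=self.degrade_max,
            barrier_cutoff=self.barrier_cutoff,
        )

    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            barrier_max=self.barrier_max,
            peak_similarity_window=self.peak_similarity_window,
        )
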