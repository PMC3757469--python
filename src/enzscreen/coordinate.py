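"""Constrained interpolation schedule along the nucleophilic-attack coordinate.

The reaction coordinate is the distance between the catalytic serine
O-gamma and the substrate carbonyl carbon C20.  Frame i of an n-segment
schedule fixes that distance at

    d_i = d_ini - i * (d_ini - d_fin) / n,      i = 0 .. n,

so frame 0 is the enzyme-substrate (ES) complex and frame n the tetrahedral
intermediate (TI).  Each frame is geometry-optimized externally with the
distance constrained; this module only produces the schedule and
backend-agnostic job descriptions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .mutants import MutantID

DEFAULT_FIXED_RESIDUES = ("S50", "P133", "Q156", "L277", "P280")


@dataclass(frozen=True)
class InterpolationSchedule:
    """Linear distance schedule from the ES complex to the TI."""

    d_ini: float
    d_fin: float
    n_segments: int = 10

    def __post_init__(self) -> None:
        if self.d_ini <= 0 or self.d_fin <= 0:
            raise ValueError("distances must be positive")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")


@dataclass(frozen=True)
class ConstraintSet:
    """Optimization constraints carried to the external energy backend.

    ``fixed_residues`` are surface residues frozen to keep the hydrogen-bond
    network from rearranging along the path; ``gradient_criterion`` is in
    kcal/(mol*Angstrom) and ``locality_cutoff`` (the NDDO interaction
    cutoff) in Angstrom.
    """

    fixed_residues: tuple[str, ...] = DEFAULT_FIXED_RESIDUES
    coordinate_atoms: tuple[str, str] = ("S105:OG", "SUB:C20")
    gradient_criterion: float = 0.5
    locality_cutoff: float = 15.0

    def __post_init__(self) -> None:
        if self.coordinate_atoms[0] == self.coordinate_atoms[1]:
            raise ValueError("coordinate atoms must be distinct")
        if self.gradient_criterion <= 0:
            raise ValueError("gradient_criterion must be positive")


def frame_distance(schedule: InterpolationSchedule, i: int) -> float:
    """Constrained O-gamma..C20 distance (Angstrom) at frame ``i``."""
    if not 0 <= i <= schedule.n_segments:
        raise ValueError(
            f"frame index {i} outside 0..{schedule.n_segments}"
        )
    return schedule.d_ini - i * (schedule.d_ini - schedule.d_fin) / schedule.n_segments


def schedule_distances(schedule: InterpolationSchedule) -> list[tuple[int, float]]:
    """All (frame, distance) pairs, monotone from d_ini to d_fin."""
    return [(i, frame_distance(schedule, i)) for i in range(schedule.n_segments + 1)]


def render_job(
    schedule: InterpolationSchedule,
    constraints: ConstraintSet,
    i: int,
    mutant: MutantID | str,
) -> dict:
    """Serializable, backend-agnostic job record for one interpolation frame.

    Two renders of identical inputs are identical; serialize with
    :func:`job_to_json` for a byte-stable form.
    """
    return {
        "mutant": str(mutant),
        "frame": i,
        "distance_angstrom": frame_distance(schedule, i),
        "coordinate_atoms": list(constraints.coordinate_atoms),
        "fixed_residues": list(constraints.fixed_residues),
        "gradient_criterion_kcal_mol_angstrom": constraints.gradient_criterion,
        "locality_cutoff_angstrom": constraints.locality_cutoff,
    }


def job_to_json(job: dict) -> str:
    return json.dumps(job, sort_keys=True, separators=(",", ":"))
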