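"""Barrier extraction and quality filtering of reaction energy profiles.

The reaction barrier of a profile is the highest energy along the path
minus the energy of the enzyme-substrate complex (frame 0).  Profiles whose
shape is irregular — multiple interior peaks of similar height, which make
the barrier ill-defined — are discarded as inconclusive; of the regular
profiles, those with barriers above a configurable maximum (default
19.0 kcal/mol, the largest barrier retained in the benchmark set) are
discarded as unpromising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence


class Disposition(str, Enum):
    KEPT = "kept"
    DISCARDED_IRREGULAR = "discarded_irregular"
    DISCARDED_HIGH_BARRIER = "discarded_high_barrier"


@dataclass(frozen=True)
class EnergyProfile:
    """Ordered (frame, energy kcal/mol) series along the ES->TI coordinate."""

    mutant: str
    points: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("profile needs at least 3 points")
        frames = [f for f, _ in self.points]
        if frames[0] != 0:
            raise ValueError("profile must start at frame 0 (ES reference)")
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("frame indices must be strictly increasing")
        if not all(math.isfinite(e) for _, e in self.points):
            raise ValueError("energies must be finite")

    @property
    def energies(self) -> tuple[float, ...]:
        return tuple(e for _, e in self.points)

    @property
    def frames(self) -> tuple[int, ...]:
        return tuple(f for f, _ in self.points)


@dataclass(frozen=True)
class FilterConfig:
    """Screening filters: barrier ceiling and peak-similarity window (kcal/mol)."""

    barrier_max: float = 19.0
    peak_similarity_window: float = 2.0

    def __post_init__(self) -> None:
        if self.barrier_max <= 0:
            raise ValueError("barrier_max must be positive")
        if self.peak_similarity_window < 0:
            raise ValueError("peak_similarity_window must be >= 0")


@dataclass(frozen=True)
class BarrierAnalysis:
    mutant: str
    barrier: float
    peak_frame: int
    regular: bool
    interior_maxima: tuple[tuple[int, float], ...]
    disposition: Disposition


def barrier_height(profile: EnergyProfile) -> tuple[float, int]:
    """Barrier (kcal/mol) and peak frame: max energy minus the ES energy.

    Ties in the maximum resolve to the lowest frame index, so a profile whose
    maximum is the ES point itself reports a barrier of 0 at frame 0.
    """
    es = profile.energies[0]
    peak_frame, peak_e = max(
        profile.points, key=lambda p: (p[1], -p[0])
    )
    return peak_e - es, peak_frame


def interior_maxima(profile: EnergyProfile) -> list[tuple[int, float]]:
    """Interior local maxima: frames strictly above both neighbours.

    A plateau of equal energies that stands above its surroundings counts
    once, at its first frame.  Endpoints are never interior maxima.
    """
    frames, energies = profile.frames, profile.energies
    n = len(energies)
    maxima: list[tuple[int, float]] = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and energies[j + 1] == energies[i]:
            j += 1
        # run i..j of equal energies; a peak needs strict drops on both sides
        if j < n - 1 and energies[i - 1] < energies[i] and energies[j + 1] < energies[i]:
            maxima.append((frames[i], energies[i]))
        i = j + 1
    return maxima


def classify_regularity(
    profile: EnergyProfile, config: FilterConfig | None = None
) -> bool:
    """True for a regular (single-peak) profile.

    Irregular means at least two interior maxima lie within
    ``peak_similarity_window`` of the profile's global maximum energy —
    the automated counterpart of flagging "multiple peaks of similar
    height" by eye.
    """
    config = config or FilterConfig()
    global_max = max(profile.energies)
    near = [
        (f, e)
        for f, e in interior_maxima(profile)
        if global_max - e <= config.peak_similarity_window
    ]
    return len(near) < 2


def analyze_profile(
    profile: EnergyProfile, config: FilterConfig | None = None
) -> BarrierAnalysis:
    """Extract the barrier and assign a filter disposition.

    Irregularity takes precedence over the barrier ceiling so the two
    discard categories stay disjoint; a barrier exactly at ``barrier_max``
    is kept (only strictly larger barriers are discarded).
    """
    config = config or FilterConfig()
    barrier, peak_frame = barrier_height(profile)
    maxima = tuple(interior_maxima(profile))
    regular = classify_regularity(profile, config)
    if not regular:
        disposition = Disposition.DISCARDED_IRREGULAR
    elif barrier > config.barrier_max:
        disposition = Disposition.DISCARDED_HIGH_BARRIER
    else:
        disposition = Disposition.KEPT
    return BarrierAnalysis(
        mutant=profile.mutant,
        barrier=barrier,
        peak_frame=peak_frame,
        regular=regular,
        interior_maxima=maxima,
        disposition=disposition,
    )


def apply_filters(
    profiles: Iterable[EnergyProfile], config: FilterConfig | None = None
) -> dict[Disposition, list[BarrierAnalysis]]:
    """Partition profiles into kept / irregular / high-barrier, exhaustively."""
    config = config or FilterConfig()
    partition: dict[Disposition, list[BarrierAnalysis]] = {d: [] for d in Disposition}
    for profile in profiles:
        analysis = analyze_profile(profile, config)
        partition[analysis.disposition].append(analysis)
    return partition


def plot_profiles(
    profiles: Sequence[EnergyProfile], path: str, ncols: int = 4
) -> None:
    """Write a grid of per-mutant profile plots for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(profiles)
    nrows = max(1, -(-n // ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3 * ncols, 2.2 * nrows))
    axes = [axes] if n == 1 and nrows * ncols == 1 else list(axes.flat)
    for ax, profile in zip(axes, profiles):
        ax.plot(profile.frames, profile.energies, "o-", ms=3)
        ax.set_title(profile.mutant, fontsize=7)
    for ax in axes[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
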