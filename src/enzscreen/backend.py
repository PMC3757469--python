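"""Optional adapter for a semi-empirical quantum-chemistry backend.

Writes plain-text input decks for a constrained single-frame geometry
optimization and parses the final energy from the program's text output.
The adapter is deliberately isolated: nothing else in the package imports
it, and the core pipeline consumes energies from delimited profile files
regardless of how they were produced.
"""

from __future__ import annotations

import re

_ENERGY_RE = re.compile(
    r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*KCAL/MOL"
)


def write_input_deck(job: dict, method: str = "PM6") -> str:
    """Render a keyword-block input deck for one interpolation-frame job.

    The deck records the method, locality (NDDO) cutoff, gradient
    convergence criterion, frozen residues and the fixed reaction-coordinate
    distance.  How the distance constraint is realised (frozen atoms vs an
    internal-coordinate restraint) is left to the backend.
    """
    lines = [
        f"{method} MOZYME CUTOFF={job['locality_cutoff_angstrom']:.1f} "
        f"GNORM={job['gradient_criterion_kcal_mol_angstrom']:.2f}",
        f"mutant {job['mutant']} frame {job['frame']}",
        f"FIX_DISTANCE {job['coordinate_atoms'][0]} {job['coordinate_atoms'][1]} "
        f"{job['distance_angstrom']:.4f}",
    ]
    lines += [f"FREEZE {res}" for res in job["fixed_residues"]]
    return "\n".join(lines) + "\n"


def parse_final_energy(output_text: str) -> float:
    """Final energy (kcal/mol) from backend text output.

    Matches the last line of the form
    ``FINAL HEAT OF FORMATION = <value> KCAL/MOL``.
    """
    matches = _ENERGY_RE.findall(output_text)
    if not matches:
        raise ValueError("no final energy line found in backend output")
    return float(matches[-1])
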