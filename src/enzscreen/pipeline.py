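"""End-to-end screening pipeline: enumerate -> analyze -> filter -> report.

Mirrors the bookkeeping of a combinatorial screen: per-order possible
counts, exclusion-pair removals, filter dispositions and the final kept
set, logged stage by stage so the numbers can be diffed against a study's
accounting table.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

from . import io as eio
from .benchmark import benchmark, composition_summary, optimize_cutoff, rank_candidates
from .mutants import ExclusionConstraint, MutationLibrary, count_by_order, enumerate_mutants
from .profiles import Disposition, apply_filters

logger = logging.getLogger("enzscreen")


def enumeration_manifest(
    library: MutationLibrary,
    max_order: int,
    exclusions: ExclusionConstraint | None = None,
) -> dict:
    """Enumerate and account: per-order possible/excluded/remaining counts."""
    mutants = enumerate_mutants(library, max_order, exclusions)
    by_order = Counter(m.order for m in mutants)
    manifest = {
        "per_order": {
            str(o): {
                "possible": count_by_order(library, o),
                "remaining": by_order.get(o, 0),
                "excluded": count_by_order(library, o) - by_order.get(o, 0),
            }
            for o in range(1, max_order + 1)
        },
        "total_possible": sum(count_by_order(library, o) for o in range(1, max_order + 1)),
        "total_remaining": len(mutants),
    }
    manifest["total_excluded"] = manifest["total_possible"] - manifest["total_remaining"]
    return manifest


def run_pipeline(config: eio.PipelineConfig, inputs: dict, outdir) -> dict:
    """Run every stage for which inputs resolve; write reports under outdir.

    ``inputs`` maps stage names to file paths (or None to use the packaged
    fixture): ``library``, ``exclusions``, ``profiles``, ``activities``.
    Stages with missing inputs are skipped with a logged warning; the
    enumeration outputs are produced regardless.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    library = (
        eio.read_library(inputs["library"])
        if inputs.get("library")
        else eio.load_fixture("library")
    )
    exclusions = (
        eio.read_exclusions(inputs["exclusions"])
        if inputs.get("exclusions")
        else eio.load_fixture("exclusions")
    )
    mutants = enumerate_mutants(library, config.max_order, exclusions)
    manifest = enumeration_manifest(library, config.max_order, exclusions)
    for o, row in manifest["per_order"].items():
        logger.info(
            "order %s: possible %d / excluded-pair %d / remaining %d",
            o, row["possible"], row["excluded"], row["remaining"],
        )
    (outdir / "mutants.txt").write_text("".join(f"{m}\n" for m in mutants))
    eio.write_json_report(manifest, outdir / "enumeration.json")
    bundle["enumeration"] = manifest

    profiles_path = inputs.get("profiles")
    if profiles_path and Path(profiles_path).exists():
        profiles = eio.read_profiles(profiles_path)
    else:
        profiles = []
        if profiles_path:
            logger.warning("profile file %s not found; analysis stage skipped", profiles_path)
        else:
            logger.warning("no profile input; analysis stage skipped")
    if profiles:
        partition = apply_filters(profiles, config.filter_config())
        kept = partition[Disposition.KEPT]
        all_analyses = [a for group in partition.values() for a in group]
        eio.write_analyses(all_analyses, outdir / "analyses.csv")
        logger.info(
            "profiles: %d analyzed / %d inconclusive / %d high-barrier / %d kept",
            len(profiles),
            len(partition[Disposition.DISCARDED_IRREGULAR]),
            len(partition[Disposition.DISCARDED_HIGH_BARRIER]),
            len(kept),
        )
        ranked = rank_candidates(kept, config.ranking_n) if kept else []
        summary = composition_summary([m for m, _ in ranked]) if ranked else None
        bundle["screening"] = {
            "n_profiles": len(profiles),
            "n_kept": len(kept),
            "n_irregular": len(partition[Disposition.DISCARDED_IRREGULAR]),
            "n_high_barrier": len(partition[Disposition.DISCARDED_HIGH_BARRIER]),
            "top_candidates": [{"mutant": m, "barrier": b} for m, b in ranked],
            "top_by_order": summary.by_order if summary else {},
        }
        eio.write_json_report(bundle["screening"], outdir / "screening.json")

    activities_path = inputs.get("activities")
    records = None
    if activities_path:
        records = eio.read_activity_table(activities_path)
    elif inputs.get("use_fixture_activities"):
        records = eio.load_fixture("set_s")
    if records is not None:
        records = [r for r in records if r.mutant.upper() != "WT"]
        report = benchmark(records, config.thresholds())
        scan = optimize_cutoff(records, config.thresholds())
        bundle["benchmark"] = {
            "n_records": report.n_records,
            "n_agree": report.n_agree,
            "agreement_rate": report.agreement_rate,
            "agreement_percent": report.agreement_percent,
            "high_activity": {
                "threshold": report.high_activity.threshold,
                "size": report.high_activity.size,
                "n_correct": report.high_activity.n_correct,
            },
            "low_activity": {
                "threshold": report.low_activity.threshold,
                "size": report.low_activity.size,
                "n_correct": report.low_activity.n_correct,
            },
            "cutoff_scan": {
                "max_agreement": scan.max_agreement,
                "optimal_cutoffs": list(scan.optimal_cutoffs),
            },
            "per_mutant": [
                {
                    "mutant": c.mutant,
                    "exp_factor": c.exp_factor,
                    "comp_factor": c.comp_factor,
                    "agree": c.agree,
                }
                for c in report.comparisons
            ],
        }
        eio.write_json_report(bundle["benchmark"], outdir / "benchmark.json")
        logger.info(
            "benchmark: %d/%d agree (%d%%)",
            report.n_agree, report.n_records, report.agreement_percent,
        )
    else:
        logger.warning("no activity input; benchmark stage skipped")
    return bundle
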