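"""Benchmark barrier-based predictions against measured activities.

Loads the 22-mutant benchmark table (fold-wild-type amidase activity and
computed barrier per mutant), classifies each side qualitatively, counts
agreements at the 12.5 kcal/mol cutoff, and scans all cutoffs for the
maximum achievable agreement.
"""

import enzscreen as ez

records = [r for r in ez.load_fixture("set_s") if r.mutant != "WT"]
report = ez.benchmark(records)
scan = ez.optimize_cutoff(records)

print(f"agreement: {report.n_agree}/{report.n_records} "
      f"({report.agreement_percent}%)")
print(f"most active (>= {report.high_activity.threshold}-fold, "
      f"n={report.high_activity.size}): {report.high_activity.n_correct} correct")
print(f"least active (<= {report.low_activity.threshold}-fold, "
      f"n={report.low_activity.size}): {report.low_activity.n_correct} correct")
print(f"cutoff scan: max agreement {scan.max_agreement}, "
      f"optimal cutoffs include 12.5: {12.5 in scan.optimal_cutoffs}")
# An agreement means the sign predicted from the barrier (-1 if >= cutoff)
# matches the sign of the measured activity change (+1 if >= 1.2-fold WT,
# -1 if <= 0.8-fold).
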