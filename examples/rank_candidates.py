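"""Rank screened candidates by ascending barrier and summarize composition.

For prospective screening no cutoff is needed: one simply takes the N
mutants with the lowest barriers.  This example ranks the packaged top-20
candidate table and summarizes which positions the candidates mutate.
"""

import enzscreen as ez

top20 = ez.load_fixture("set_l_top20")
wt_barrier = next(r.barrier for r in ez.load_fixture("set_s") if r.mutant == "WT")

best = ez.rank_candidates(top20, 5)
print("five lowest-barrier candidates:")
for mutant, barrier in best:
    print(f"  {mutant:30s} {barrier:5.1f} kcal/mol")

below = [m for m, b in top20 if b < wt_barrier]
print(f"{len(below)} candidates beat the predicted wild-type barrier "
      f"({wt_barrier} kcal/mol): {', '.join(below)}")

summary = ez.composition_summary([m for m, _ in top20])
print("candidates by order:", summary.by_order)
print("occurrences by position:", summary.by_position)
# A lower barrier for forming the tetrahedral intermediate is taken to
# predict higher catalytic activity, so low-barrier multi-mutants are the
# ones worth making in the lab.
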