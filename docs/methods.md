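# Methods

## Model and scope

The package operationalizes a qualitative screen for enzyme activity built
on one mechanistic assumption: in serine hydrolases the formation of the
tetrahedral intermediate (TI) by nucleophilic attack of the catalytic
serine O-gamma on the substrate carbonyl carbon is rate determining, so a
lower potential-energy barrier for that step predicts higher overall
activity. Under first-order kinetics with enzyme saturation and fast
binding/release, the catalytic rate constant is proportional to specific
activity, which licenses comparing barrier heights with fold-wild-type
activity factors — but only qualitatively. The screen never attempts a
quantitative rate ranking; its output is a sign (+1 improving / −1
degrading) and an ordering of candidates by barrier.

The quantum-chemistry step itself — constrained geometry optimization and
energy evaluation of each interpolation frame — is deliberately outside
the package. The package produces the per-frame job descriptions and
consumes tabular (frame, energy) profiles, whatever produced them. An
optional text adapter (`backend.py`) writes keyword-block input decks and
parses a final-energy line; nothing else depends on it.

## Combinatorial enumeration

A mutant's identity is the unordered set of its point substitutions, at
most one per position, written canonically in ascending position order
(`G39A-T103G-…`). Order 0 is the wild-type reference and is never
enumerated. The number of order-o combinations from per-position
multiplicities g_i is the elementary symmetric polynomial e_o({g_i}),
computed by the standard descending-index recurrence (exact in integers);
enumeration expands the same products explicitly and is validated against
the closed form and against a brute-force oracle on random small
libraries. Steric exclusion is input data, not computed: a mutant is
discarded iff it contains a forbidden pair as a subset, which equals
removing the union of pair-containing combinations from the unconstrained
enumeration. The packaged library (six positions, g = 1,1,3,2,5,1) yields
13/64/154/193 combinations of order 1–4 (424 total), of which 38 contain a
forbidden pair, leaving 386.

## Reaction-coordinate schedule

Frame i of an n-segment schedule (default n = 10, i.e. 11 structures)
fixes the O-gamma..C20 distance at d_i = d_ini − i(d_ini − d_fin)/n.
Frame 0 is the enzyme–substrate (ES) complex — its energy anchors the
barrier — and frame n the TI. Indexing 0..n inclusive is the package's
standardization: the ES reference must itself be a frame for the barrier
definition to be evaluable from the profile alone. Units are fixed to
Angstrom and kcal/mol throughout; there is no unit-conversion layer.
Default constraints carried to the backend: frozen surface residues S50,
P133, Q156, L277, P280 (these otherwise rearrange their hydrogen bonds
along the path and corrupt the profile shape), gradient criterion
0.5 kcal/(mol·Å), locality (NDDO) cutoff 15 Å. How the distance constraint
is realised mechanically is left to the backend; the job record only
states it.

## Barrier extraction and filters

The barrier is max-over-frames energy minus the frame-0 energy; the peak
frame is the argmax, ties resolved to the lowest frame so a profile whose
maximum is the ES point reports barrier 0 at frame 0. Barrier extraction
is invariant under adding a constant to all energies.

Profile regularity was originally a visual judgement ("multiple peaks of
similar height are inconclusive"); the package formalizes it: a profile is
irregular iff at least two interior local maxima lie within
`peak_similarity_window` (default 2.0 kcal/mol) of the global maximum
energy. The window default is the package's own choice of what "similar
height" means — there is no published value — so counts of discarded
profiles under this rule are not comparable to any published bookkeeping;
the criterion is kept recoverable by plotting (`plot_profiles`). Interior
maxima require strict drops on both sides; an elevated plateau counts once
at its first frame; endpoints never count. Shrinking the window can only
reduce the number of irregular profiles (tested as a monotonicity
property).

Filter precedence: irregularity is tested first, then the barrier ceiling
(`barrier_max`, default 19.0 kcal/mol — the largest barrier retained in
the benchmark set), so the two discard categories are disjoint and the
partition {kept, discarded_irregular, discarded_high_barrier} is
exhaustive. A barrier exactly at the ceiling is kept: only strictly larger
barriers are discarded.

## Classification and benchmarking

Experimental factor: +1 at activity ≥ 1.2-fold WT, −1 at ≤ 0.8-fold, 0 in
the open band between (the defining rule only names the outer regions;
neutral records are excluded from agreement counts and listed — the
packaged benchmark table happens to contain none). Computational factor:
−1 at barrier ≥ cutoff, +1 below. Boundary semantics follow the rule's
"or higher/lower" and "≥ cutoff" phrasing exactly.

The cutoff scan evaluates every observed barrier value plus every midpoint
between adjacent distinct values — sufficient because agreement as a
function of the cutoff only changes at observed values — and reports the
full set of maximizing cutoffs rather than a single number, since the
optimum is a plateau. On the packaged 22-mutant table the maximum
agreement is 15 (68% rounded from 15/22 = 68.18%) and 12.5 kcal/mol is
among the optima. Subgroup defaults 3.0-fold (most active) and 0.5-fold
(least active) are configurable. Prospective ranking needs no cutoff: the
N lowest barriers are taken, ties broken by canonical mutant string for
reproducibility.

## Synthetic profiles

The generator is a statistical stand-in for the external energy backend,
not a physical model. The primary bump interpolates
(0, baseline) → (peak_frame, baseline + barrier) → (n, baseline + ΔE_TI)
with squared-sine arcs, strictly monotone on each side, so at zero noise
barrier and peak frame are recovered exactly; ΔE_TI defaults to half the
barrier. Irregular profiles superimpose a single-frame rival spike a
stated depth below the main peak; a spike that would not stand above the
underlying curve raises an error rather than silently mislabelling, and
the screening-set generator falls back to a placement near the far
endpoint with depth capped at 0.2× the barrier (which keeps it inside the
similarity window whenever the drawn depth was). Gaussian noise with
standard deviation `noise_sd` is added independently per frame, frame 0
included — extraction must tolerate a noisy reference. All generation is
seeded; there is no unseeded path.

Screening-set defaults: barriers N(13, 4²) kcal/mol truncated below at
1 kcal/mol, resembling the 5.7–19+ kcal/mol range of a real combinatorial
screen; irregular fraction 0.2; noise 0 by default because the
semi-empirical energies being emulated are deterministic. What passing
tests show: the analysis chain recovers constructed ground truth exactly
at zero noise and degrades gracefully with noise. What they do not show:
anything about the accuracy of real semi-empirical barriers, profile
shapes with correlated frame-to-frame error, or optimization failures.

## Numerical and design choices

- Integer combinatorics throughout counting; no floating point there.
- Profile CSVs are written with `%.17g` and read with round-trip float
  parsing, so write→read is bit-exact and re-running the pipeline is
  byte-identical (reports contain no timestamps).
- `optimize_cutoff` requires ≥2 distinct barrier values; degenerate inputs
  raise rather than return a vacuous scan.
- Configuration is a flat YAML mapping with full defaulting; unknown keys
  are rejected to catch typos.
- `max_order` defaults to 4 (the largest order in the packaged
  accounting) but is an ordinary parameter; nothing caps it.

## Known limitations

- The regularity window and the neutral-band handling are formalizations
  of judgements that were originally visual/unspecified; results are
  sensitive to the window for marginal profiles.
- Steric compatibility is input data; the package cannot decide it.
- No smoothing, transition-state refinement, or free-energy corrections;
  the barrier is read directly off the discrete profile.
- Organism/expression effects on measured activities are carried as an
  optional tag only, never modelled.
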