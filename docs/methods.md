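# Methods

This note documents the model, the constants, the numerical choices, and
the limits of what the shipped tests demonstrate.

## Hydrodynamic radius and the scaling exponent

The predictor treats a disordered chain's mean hydrodynamic radius as a
function of composition only:

    R_h(N, f_PPII, Q_net) = 2.16 Å · N^e + 0.26 Å·|Q_net| − 0.29 Å·√N
    e = 0.503 − 0.11·ln(1 − f_PPII)

`f_PPII` is the composition mean of an experimental per-residue
polyproline-II propensity scale; `Q_net` counts K and R as +1 and D and E
as −1 (histidine, cysteine, and termini are neutral by construction —
the descriptor is a formal count, not a titration model).  Inverting
`R_h = R_0·N^v` with `R_0 = 2.16 Å` gives the scaling exponent
`v_model`.  The parameterisation was developed against disordered
ensembles: applied to a folded protein's sequence it reports the
dimensions the chain would have *if disordered* (≈ 0.51–0.56), not the
collapsed-globule exponent (≈ 0.3).  `predict_rh` is strictly increasing
in `f_PPII` and in `|Q_net|` at fixed N; both properties are asserted in
the suite.

Degenerate inputs: `f_PPII = 1` (a pure-proline stretch — proline carries
PPII propensity 1.00, the scale's reference value) makes `ln(1 − f)`
undefined and raises immediately rather than clamping; `N < 2` has no
defined exponent (`log N = 0`).

## Scale tables

Six per-residue tables are embedded as versioned constants (never
fetched at runtime): the PPII propensity scale measured in unfolded
peptides (Hilser-lab host–guest series), Levitt's 1978 normalized β-turn
frequencies, the Chou–Fasman 1978 turn parameters, the Hutchinson–
Thornton 1994 four-position turn potentials, the Kapcha–Rossky atomistic
hydropathy rescaled to [0, 1] (the λ of the SHD descriptor), and the
formal-charge table.  Each table's source is noted beside its values and
all tables are exportable as TSV for audit.  Provenance caveat: the
four-position turn table was transcribed without access to a
machine-readable original; it feeds only the order-sensitive `turn_ht`
descriptor, which the classifier never consumes (classification uses the
Levitt scale exclusively), so region calls and sector assignments do not
depend on it.

## Windowed classification

Windows of 25 residues slide in 1-residue steps (possible for N > 25).
To make the window exponent comparable across window sizes, the window's
residue counts are multiplied by 4 and `v_model` is evaluated at the
effective length 4 × 25 = 100 with the net charge scaled accordingly.
The choice of 4 is where doubling increments become small: for windows
with zero net charge, |v(4×) − v(8×)| stays below 0.005 (measured
maximum 0.0040 over a seeded 500-residue average-composition chain).
For charged windows the |Q_net| term grows linearly in the multiplier
while the leading term grows only as N^~0.55, so strict convergence
cannot hold there; the suite asserts the zero-charge bound plus
shrinking increments overall.  This is an intrinsic property of the
R_h model, not an implementation artifact.

Each window's `(v_model, turn)` point is assigned a sector by
SD-normalised nearest-centroid distance,

    d² = ((v − v_c)/0.019)² + ((t − t_c)/0.082)²

with centroids PS (0.542, 1.152), ID (0.558, 1.062), Folded
(0.536, 0.969) — the three calibration-cohort means — and the
non-phase-separating IDP cohort's SDs as the normalisation.  The
published description of the sector boundaries fixes them only up to the
depicted figure, so the nearest-centroid rule is this package's concrete
geometry; it reproduces the documented point assignments (each centroid
is a fixed point; the Sup35 prion-domain point (0.531, 1.183) falls in
PS) and is injectable: any object with a `classify(v, t)` method can be
substituted without touching callers.  Distance ties — a measure-zero
event — break by the fixed priority PS > ID > Folded for determinism.

The window's central residue (start + 12 for the 25-mer; even window
sizes, if configured, center at start + size/2 − 1) takes the sector's
label P/D/F; residues before the first center copy window 1 and residues
after the last center copy the final window.  Window sums are maintained
by a rolling update (O(N) table lookups); values agree with direct
evaluation to ~1e-12, and identical inputs give bit-identical tracks.

## Region calling

A qualifying interval for label L has length ≥ 20 and ≥ 90 % of
positions labeled L.  Purity is non-monotone under extension, so maximal
qualifying intervals (those not contained in a strictly longer
qualifying interval for the same label) are computed globally: for each
start the farthest qualifying end is found with prefix sums, then a
left-to-right scan removes dominated intervals.  All purity comparisons
are done on integer counts (`10·count ≥ 9·length` for the default
threshold) so boundary purities of exactly 0.90 are decided exactly;
both the threshold and the length floor are inclusive.  The suite checks
equivalence against an exhaustive O(N²) interval oracle on hundreds of
random tracks.

Overlaps between adjacent regions of different labels (possible because
of the 10 % mixing allowance) are split evenly, the odd residue going to
the upstream region; overlap resolution proceeds pairwise left-to-right
when three or more regions chain.  Split regions are not re-filtered by
length or purity; their purity is recomputed and reported.  Same-label
overlapping maximal intervals cannot both survive maximality filtering
when their union qualifies (the union would contain them), so the
same-label merge branch is defensive only.  One consequence of the
purity rule worth knowing: a run of 19 identical labels inside a
different background *is* called (the 21-residue interval holding it has
purity 19/21 ≈ 0.905); the floor genuinely excludes runs only when no
≥ 20-residue interval reaches 90 %.

`longest_pure_region` (the proteome-scan statistic, intervals of any
length ≥ 1) uses the prefix-sum transform: an interval's purity is
≥ p/q iff the transformed integers `q·indicator − p` have nonnegative
sum there, so the answer is the longest nonnegative-sum subarray, found
in O(N log N).

## Cohort statistics

Set summaries are arithmetic means with sample SDs (n − 1).  The
two-sample z-test uses the set variances,
`z = (m1 − m2)/√(s1²/n1 + s2²/n2)`, reporting the upper-tail
standard-normal probability of |z| — a convention fixed by requiring the
self-comparison to give exactly 0.5; p therefore lies in (0, 0.5] and is
symmetric in the samples.  The Mann–Whitney U test (scipy) uses midranks
for ties, the exact null when both n ≤ 20 without ties, and the normal
approximation with continuity correction otherwise; the suite checks the
exact path against a brute-force rank enumeration.

The proteome scan skips records too short for windowing (N ≤ 25) or with
nonstandard residues, counting them rather than aborting — proteome
FASTA files routinely contain X.  Its cumulative curve (percent of
proteins whose longest ≥ 90 %-P region reaches each length threshold)
is non-increasing by construction.

## Synthetic data

`generate_sequence` draws residues i.i.d. from a named composition
profile with an explicit seed.  The three classifier-aligned profiles
follow the compositional biases that separate the cohorts — `ps_like`
enriches G, S, P, N, Q (a G/S-rich low-complexity composition),
`folded_like` enriches I, L, V, A, F, and `id_like` is a lysine/arginine-
rich polyelectrolyte — with exact fractions chosen once, by a numerical
calibration, so that every 25-residue window of a 200-mer lands in the
intended sector with margin against multinomial sampling noise (no
mislabeled window in 300 calibration draws per profile); the fractions
are frozen in `synthetic.py`.  `natural` uses the Swiss-Prot average
composition.  What i.i.d. draws deliberately do not emulate: residue
order correlations, repeats, charge blocks, real IDR length
distributions, or the mixture of regions within one protein.  Passing
fixture tests therefore demonstrates the pipeline's correctness and
determinism on compositionally realistic input, not classifier accuracy
on biological proteins — the latter is what the reference-data
acceptance checks measure when their inputs are supplied.

## Numerical conventions

* All descriptor arithmetic is double precision; rounding only at the
  presentation layer (TSVs print 6 decimals).
* SHD and SCD use 1-based consecutive sequence indices; |j − i| is the
  raw index gap.  SHD is computed by an O(N) gap-grouped cumulative-sum
  form, SCD pairwise over charged positions (switching to an FFT
  autocorrelation form, with integer rounding of the correlation, for
  chains with > 2048 charged residues); both are verified against the
  literal double-loop definition in the suite.
* Sequence validation is strict: only the 20 standard one-letter codes,
  case-normalised; ambiguity codes are rejected (or whole records
  skipped under the permissive policy), never imputed.

## Known limitations

* The sector geometry is a documented concrete choice, not a recovered
  copy of the original figure's boundary lines; swap in another
  `SectorGeometry` to recalibrate against a reference implementation.
* Pure-proline 25-mers (f_PPII = 1) are an error case of the R_h model
  and abort labeling of that sequence.
* The R_h model, and hence every v_model-derived quantity, is meaningful
  for disordered chains only; Folded-sector calls say "composition looks
  like a foldable region", not "this region is folded".
* `turn_ht` is exposed for set-level analysis; its table's transcription
  provenance is weaker than the other scales (see above).
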