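# Methods

## Hybridization model

The toolkit targets functional gene arrays of the multiple-probe-concept
type: a hierarchy of 18–28-mer probes in which narrow clades are covered by
specific probes and, wherever the alignment allows, by probes of broader
specificity, so that a genuine positive on a specific probe should be echoed
by its broader companions.

Probes and targets are both stored as sense-strand DNA; the labelled target
actually present in the hybridization is single-stranded antisense RNA
(run-off T7 transcription from a tagged reverse primer). A probe position
therefore *matches* when the probe base equals the target's sense base, and
the physical base opposition at a mismatch is (probe DNA base, RNA complement
of the sense base). This is the convention under which the two wobble
pairings carry their reduced weights: a probe G over sense A faces rU
(dG·rU, weight 0.7), and a probe T over sense C faces rG (dT·rG, 0.4).

The weighted-mismatch score of a probe–target window is

    wMM = Σ_mismatches  w_pos(i, L) · w_bp(probe_i, rna_i)

with position weights 0.3/0.6/1.0 at probe 5′ positions 1–3, 0.3/0.8/1.1 at
3′ positions 1–3 (counting inward from the 3′ terminus), 1.2 internally, and
basepair weights dA·rC 1.2, dT·rC 1.2, dG·rU 0.7, dT·rG 0.4, all other
mismatched pairs 1.0. Matching is strictly ungapped; every probe-length
window on the target sense strand is scored, windows with more than
`max_mismatches` (default 3) mismatches are not match sites at all, and the
lowest-wMM surviving window wins, ties broken by smallest offset.
Coordinates are 1-based inclusive.

Prediction classes use a closed lower and open upper boundary: wMM ≤ 1.5
POSITIVE, 1.5 < wMM ≤ 2.5 POTENTIAL, wMM > 2.5 NEGATIVE, and NO_MATCH when
no window survives the budget. Threshold comparisons tolerate 1e-9 of float
summation error; the smallest possible wMM increment is 0.3 × 0.4 = 0.12,
five orders of magnitude larger, so the tolerance can never change a class
a real mismatch pattern determines. An ambiguous N in a target is treated
conservatively as a default-weight (1.0) mismatch. The window scan is
vectorized (numpy sliding windows over byte-encoded sequences); the test
suite checks it against an independent pure-Python exhaustive enumeration.

## Thermodynamics

Probe melting temperature uses the unified DNA/DNA nearest-neighbour
parameter set (Allawi & SantaLucia), evaluated through Biopython's
`MeltingTemp.Tm_NN`, at a total oligo concentration of 250 nM — entered as
`dnac1 = dnac2 = 125` nM so the concentration term is ln(CT/4), the standard
form for non-self-complementary duplexes — and monovalent salt corrected to
50 mM Na⁺ with the entropy correction ΔS += 0.368·(N−1)·ln[Na⁺]
(Biopython `saltcorr=5`). The DNA/DNA table is an approximation for the
DNA/RNA duplexes actually formed on the array; Tm here characterizes and
ranks probes rather than predicting absolute duplex stability. The chosen
table and salt formula are recorded in `TmParams` and in every output
manifest so results remain reproducible if the defaults are overridden.
A hand-coded nearest-neighbour evaluator in the tests reproduces the values
to machine precision.

## Signal pipeline

Per spot, net = max(signal median − background median, 0); the clamp is a
toolkit decision so percentages and calls stay nonnegative. Within each of
the three replicate subarrays, probe nets are divided by the mean net of the
positive-control probes *of that subarray* (multi-copy spots averaged
first), cancelling subarray-scale intensity differences; the three
percentages are then aggregated into a per-probe mean and sample standard
deviation (ddof = 1). Control membership is data (the probe table's control
flag), not hard-coded names; rows for the external spike control `hyaBp`
are parsed and dropped. By construction the positive-control mean is 100%
on every array, normalization is idempotent, and all downstream calls are
invariant under any positive rescaling of the raw intensities.

Reference values — the maximum achievable normalized signal per probe — are
the strongest replicate-mean a probe reached on validation arrays where it
is a full match for the hybridized target (replicate means, not single-spot
maxima, for robustness to single-spot artifacts). Probes never full-matched,
or weaker than the group floor, fall back to 300% (AOA) or 200% (AOB) of the
control signal, flagged `floored`. A probe is called positive when its mean
reaches at least 5% of its reference value (boundary inclusive, with the
same 1e-9 float tolerance); scaled values above 100% are reported, not
capped. Exports print one decimal; calls always use unrounded values.

The multiple-probe consistency check reports, for every positive probe,
whether at least one probe targeting a proper ancestor clade is also
positive (SUPPORTED), whether all such broader probes are negative
(UNSUPPORTED — the pattern that identifies likely false positives), or
whether the hierarchy simply offers no broader probe (NO_BROADER_PROBE).

## Validation bookkeeping

A validation panel hybridizes pure reference targets one per array.
Expected calls derive from the prediction classes; POTENTIAL pairs are never
counted as errors in either direction, because such probes were re-curated
manually in practice and an automatable scorer should stay neutral about
them. Positive-control probes are excluded from the scored reactions. A
probe *behaves as predicted* when all of its reactions are correct and is
*validated with a perfect match* when it was observed positive on at least
one wMM = 0 target; the behaving percentage is quoted over validated probes.
Probes observed positive on an expected-negative target are flagged as false
positives; removal is reported, never silently applied.

Environmental comparisons take a call matrix, the clade forest, and a clone
library given as a list of clade assignments. A positive probe (positive in
≥ 1 sample) is *supported* when some clone's clade lies within its
specificity (its clade or a descendant). Clade sets on both sides aggregate
to the forest's *high-level* clades — an explicit marking in the forest
input (defaulting to the roots), because the mapping from probes to named
lineages is curation, not inference. Δ counts array-detected high-level
clades absent from the library; Δ% = 100·(positive − supported)/positive,
rounded half away from zero to one decimal (so 1/16 → 6.3%).

## Synthetic data

The simulator defines the toolkit's test conditions. `generate_panel` draws
random probes (18–28 nt, uniform) and builds, per probe, five engineered
targets: an exact embedding (wMM 0, POSITIVE), embeddings with 1, 2 and 3
internal complement-substituted mismatches (each worth 1.2 × 1.0, so wMM
1.2 / 2.4 / 3.6 — POSITIVE, POTENTIAL, NEGATIVE), and one unrelated sequence
with no window inside the mismatch budget (NO_MATCH). Flanks are random
20-mers, redrawn (up to 100 times) whenever they would create a better
window than the engineered site, so the analytic ground truth is verified,
not assumed; the tests additionally confirm it against the independent
enumeration oracle.

`simulate_scan` maps a probe's best wMM against the hybridized pool to a
relative signal by linear interpolation between the two anchors the model
fixes — full signal at wMM 0, none at or beyond 2.5:

    relative_signal(wMM) = clamp(1 − wMM/2.5, 0, 1)

The interpolation shape between the anchors is declared plumbing and
isolated in one function for substitution. Expected percentage = reference ×
relative signal + a uniform nonspecific term in [0, 3% of reference];
positive-control spots sit at `control_net` (default 10 000 raw units, a
mid-range scanner intensity); a constant background median (default 100) is
added to every spot and subtracted again by the pipeline. Per-spot noise is
multiplicative lognormal at CV 0.1 (mean 1), chosen over additive Gaussian
to keep raw intensities positive; one global seed governs all draws and is
written into every simulated file's header. Because the 3% nonspecific
ceiling sits strictly below the 5% call cutoff, a zero-noise simulation
recovers the predicted class of every non-POTENTIAL pair exactly — this is
the end-to-end invariant the tests and the acceptance script exercise.

What the simulator does *not* emulate: PCR amplification bias, *amoA*
copy-number variation, cross-group (AOA probe vs AOB target) hybridization,
spatial artifacts, or sequence-dependent binding capacity differences
between probes. Passing tests therefore demonstrate the correctness of the
scoring, normalization and bookkeeping chain under the stated signal model,
not the wet-lab behaviour of any particular probe set.

## Problem sizes

The test suite and acceptance script use panels of 4–10 probes (× 5
engineered targets each) for pipeline checks, 1000 random probes for the
scoring-equivalence check, and the published panel dimensions (184 × 49 plus
145 × 32, with 72 discordant reactions injected; 110 validated probes with
13 constructed violators; the five environmental count patterns) for the
bookkeeping arithmetic. All complete in a few seconds on one CPU.

## Known limitations

- The DNA/DNA nearest-neighbour approximation ignores the DNA/RNA chemistry
  of the actual duplexes, and the exact salt-correction variant of the
  original probe-design software is not documented; the configured choice is
  recorded in output metadata instead.
- Degenerate probe bases are rejected rather than expanded; only targets may
  carry N.
- Probe design itself (candidate enumeration against a sequence database)
  and clone phylogenetic placement are out of scope: clade assignments
  arrive as input.
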