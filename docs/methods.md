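# Methods

## The problem

A local-alignment database search reports, for a protein query, the
high-scoring alignments to a database of subject sequences. Classical
significance analysis (the E-value) converts an alignment score *s* into the
expected number of random alignments scoring at least *s*, via the
Karlin–Altschul Gumbel approximation with precomputed parameters *K* and *λ*
for the chosen substitution matrix and gap penalties. That calibration can
drift — per matrix, per penalty pair, per database — and E-values are then
conservative in some regimes and anti-conservative (liberal) in others.

This package implements an alternative that requires no precomputed
parameters: a shuffle-based, studentized P-value for the *database-wide*
optimal score, with family-wise error rate (FWER) control.

## The Studentized-Gumbel statistic

Let *S* be the optimal local alignment score of the query against the whole
database, and let *Y₁…Y_m* be the optimal scores of *m* independent random
shuffles of the query searched identically (we default to m = 50). The test
statistic is the studentized score

    T = (S − Ȳ) / σ_Y ,

with Ȳ the sample mean and σ_Y the sample standard deviation
((m−1)-denominator, matching the two-sample-t analogy: under a *normal*
null, T/√(1+1/m) is exactly t-distributed with m−1 degrees of freedom).

Under the extreme-value model the null law of *S* (a maximum of
approximately Gumbel scores with a shared rate) is again Gumbel, with
unknown location and rate. Studentization removes both parameters: if *S*
and the *Yⱼ* are iid Gumbel(μ, λ), the law of *T* depends on *m* only. We
call it the Studentized-Gumbel(m) distribution, SG_m. It has no standard
closed form, so its right tail G(t) is tabulated once per *m* by Monte-Carlo
and reused everywhere — any matrix, penalties, or database.

## Tabulating G(t) by importance sampling

Plain Monte-Carlo cannot reach tails like 10⁻¹⁴, so per draw the null sample
*Y* comes from Gumbel(μ=0, scale 3) while *S* comes from a shifted, widened
proposal Gumbel(μ=33, scale 15); each draw contributes the likelihood ratio
f_target(S)/f_proposal(S) (computed on the log scale) to the bin containing
its studentized value. Binning is half-open, [edge, edge+width), with width
0.001 on [0, 45); a value maps to bin ⌊(t − t_min)/width⌋ and tails are
reported at bin centers (the convention is ours; lookups are step functions
at bin resolution, so the induced error is below the Monte-Carlo error).
G(t) at a bin is the weight mass in that bin and above, divided by the total
draw count N. Negative *t* is not tabulated: a score below the null mean is
never interesting, and P = 1 there.

Pivotality means the generating (μ, λ) pair is arbitrary, but it fixes the
sensible proposal; re-expressing both laws through the same affine map
reproduces the table bin for bin (tested exactly via shared uniforms).

Draws are generated in fixed chunks of 250 000 with per-chunk child seeds
spawned from the master seed, so tables are reproducible at bounded memory
for any N. Replicates with σ_Y = 0 (probability zero under continuous
draws) would be dropped with a logged warning. The default N for a shipped
table is 10⁸; tests and the acceptance script use 10⁶–10⁷, which keeps the
tail trustworthy to roughly 10⁻⁶–10⁻⁹.

### Precision cutoff

The table is only trusted up to the largest bin whose coefficient of
variation is at most 0.01 (scanning downward from the top). Two CV
definitions are implemented:

* `standard_error` (default): the standard error of the importance-sampling
  estimator of G(t), divided by G(t). This shrinks like 1/√N, so larger
  runs extend the trusted range — consistent with a cutoff near the top of
  the grid being reachable only at very large N.
* `tail_weights`: the sample standard deviation of the raw weights in the
  bin and above, divided by G(t) — a literal per-weight reading. Because
  the weights themselves span orders of magnitude and their SD does not
  shrink with N, this CV essentially never reaches 0.01 and the cutoff
  degenerates to t_min; it is kept as a switchable sensitivity option, not
  the default.

Queries whose studentized score exceeds the cutoff receive G(cutoff), the
smallest trusted tail value. Per-bin standard errors are stored in the
table as accuracy metadata.

At N = 10⁶ the cutoff lands near t ≈ 12 (G ≈ 10⁻⁶); at 10⁷ near t ≈ 17.
Reproducing a cutoff in the mid-30s (G ≈ 10⁻¹⁴ scale) requires on the order
of 10¹⁰ draws — hours of compute — and is supported but not exercised in
the test suite.

## P-values and FWER control

For each query, one null sample is collected and shared by all of its
reported alignments. Each alignment score is studentized against it and
assigned P = G(T) (1 if T ≤ 0). Reporting every alignment with P ≤ α
controls the FWER at α: among the alignments of one query, some null
alignment is reported iff the maximal score's P-value is ≤ α, an event of
probability ≤ α whenever the P-values are valid. Studentization is
location-scale free, so raw scores and bit scores give identical P-values
(raw integer scores are used to avoid rounding differences).

Degenerate null samples (σ_Y = 0, e.g. a homopolymeric query whose shuffles
are all identical) take the limiting values: P = 1 when S ≤ Ȳ, otherwise
G(cutoff) with a warning.

For many-query screens, the Benjamini–Yekutieli step-up adjustment is
provided; its harmonic-sum inflation keeps FDR control under the arbitrary
dependence that overlapping alignments create.

## The score engines

The built-in engine is a score-only Smith–Waterman with affine gaps
(open + k·extend for a gap of length k, the NCBI convention, so (11, 1)
matches `blastp -gapopen 11 -gapextend 1`), compiled with numba to ~250M
cells/s, which makes 10⁴-replicate calibration experiments feasible on one
CPU. No traceback is produced — the significance layer needs only maxima.
Matrices use the NCBI 24-residue text layout (parsed with biopython);
unknown residues map to X and score per the matrix's X row; no
low-complexity filtering or compositional adjustment is applied.

The blastp adapter runs an external executable with a pinned tabular output
format (`qseqid sseqid score evalue`) and refuses to let callers override
it — silent column drift is the classic parsing bug. A query with no
reported alignments contributes the floor score 0 to the null sample.

## Validation harness

Null calibration simulates draws from the null by searching independent
shuffles of a query and recording the optimal score (and minimal E-value
where available). SG P-values for the simulated scores use auxiliary null
samples drawn with replacement from the pooled score sample — statistically
equivalent at null and m·times cheaper than fresh shuffles. Validity is
assessed by probability plots (log10 empirical frequency vs log10 value,
with the ≤ convention for ties at repeated integer scores) and, at each
canonical α ∈ {0.05, 0.01, 10⁻³, 10⁻⁴, 10⁻⁵, 10⁻⁶}, a one-sided binomial
test run only when the observed exceedance frequency is above α.

The "MLE P-value" — fit a Gumbel to the m null scores by maximum likelihood
and read its tail at S — is included purely as a diagnostic: with m = 50 it
is measurably anti-conservative at small α, which is exactly why the
studentized route is preferred. Gumbel MLE solves the profiled likelihood
equation for the scale by bracketed root finding (xtol 10⁻¹⁰), then the
location in closed form; a vectorized fixed-point variant handles bulk
diagnostics.

## Synthetic data

Sequence generators draw residues iid from a marginal amino-acid frequency
table; the default is the Robinson–Robinson (1991) composition, the
standard background used by protein search tools (any 20-entry table can be
supplied as a TSV). Databases are independent iid records with lengths
fixed, listed, or uniform on a range. These emulate the iid null model of
extreme-value alignment statistics, not real proteins: no compositional
bias, repeats, or domain structure. A green calibration test therefore
establishes validity under the iid null — the regime where E-value theory
itself is supposed to work — and says nothing about biased-composition
queries (where shuffling itself preserves composition, the method's main
robustness argument).

## Numerical and design notes

* Gumbel parameterization is (location μ, rate λ) everywhere; serialized
  tables record both to avoid scale/rate confusion.
* The classical HSP formulas use the plain n·l search-space term; no
  edge-effect correction or K estimation is provided (those belong to the
  tool whose E-values are being audited, and the SG method needs neither).
* Table files are plain TSV with a commented metadata header; loads verify
  the format version and (on request) m, with distinct errors for each
  failure mode.
* Tests scale simulations to desk size (10⁴ engine replicates, 10⁵–10⁷
  score-level replicates) and state tolerances as α + 3 standard errors or
  as Monte-Carlo error bands; seeds are fixed for reproducibility.

## Known limitations

* The table's bulk bins (t ≲ 1) are estimated by rare, huge importance
  weights and converge slowly; this does not affect P-values of interest
  (they live in the tail) but total-mass diagnostics must budget for it.
* Runtime is m+1 searches per query — a factor-51 premium over a single
  search at the default m.
* Validity rests on the Gumbel approximation to the null score law; for
  very short queries the approximation degrades and the P-values become
  conservative (never observed liberal in our calibration runs), matching
  the behaviour expected from theory.
* Nucleotide search, per-subject significance, and k-let
  composition-preserving shuffles are out of scope.
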