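# Methods

## The scanning model

The preinitiation complex (PIC) is a walker on the 1-based nucleotide
positions of a linear mRNA; the 5'-cap sits at position 0 and acts as a
permanent block.  The walker state is the position of the PIC's 5'
trailing edge.  Per step, in order:

1. **Pawl lottery.**  With probability `p_pawl` a pawl is deposited at the
   position immediately 5' of the trailing edge.  Pawl dissociation is
   assumed slow enough to ignore, so the pawl frontier (the most 3' pawl,
   with the cap as frontier 0) is non-decreasing along a trajectory.
2. **Direction.**  5'→3' or 3'→5' with probability ½ each, except that a
   3'→5' move that would put the trailing edge onto (or past) the pawl
   frontier is replaced by a forced 5'→3' move.
3. **Move** 1 nt.
4. **Inspection.**  The P-site occupies the 13th–15th nt of the bound
   fragment (offset +12 to +14 from the trailing edge).  If it now exactly
   covers a start site's AUG, recognition succeeds with probability
   `1 − leakage` (the site's override if set, else `p_leakage`).  AUGs are
   recognisable in both movement directions.  Because every step shifts
   the footprint by 1 nt, an aligned step is one "scan" and consecutive
   double-counting is impossible.

Recognition of a *functional* site (the annotated start, or an in-frame
downstream ATG) ends the trajectory with protein output and never
triggers decay.  Recognition of a *nonfunctional* (out-of-frame) site
ends the trajectory and triggers NMD with probability `p_nmd`.  When the
P-site's leading position passes the 3' end of the modelled window the
trajectory ends as runoff; the same NMD lottery applies (configurable via
`runoff_nmd`, on by default because the next ATGs downstream of the
reporter's variable region are all out-of-frame).

The default reporter window is 50 nt upstream and 50 nt downstream of the
annotated start.  Start positions are never inspected at the initial
state (trailing edge 1), only after a move; sites closer than 13 nt to
the cap can never enter the P-site and are recognised with probability 0
— the model deliberately excludes cap-proximal initiation (short-UTR
effects are outside its scope).  The exact 3' extent of the footprint
plays no role beyond the P-site offset: runoff is defined on the P-site's
leading position, and this convention is the one configurable place where
a different footprint assumption would enter.

**Ensemble quantities.**  For `n` trajectories: `fraction_init[s]` per
site, `fraction_runoff` (the outcome classes partition to 1 exactly),
`fraction_nmd`, predicted mRNA level `1 − fraction_nmd`, predicted
protein `expression = (Σ functional fraction_init) × (1 − fraction_nmd)`,
and `net_leakage = 1 − fraction_init[aATG]`.  Duo expression is reported
normalised by the Solo ensemble.  With `net = single^k`, the implied
inspections per triplet is `k = log(net)/log(single)`.

## Exact solver

The process is an absorbing Markov chain on states `(t, g)` where `t` is
the trailing edge and `g = t − frontier ≥ 1` the gap to the pawl
frontier: between pawl events `t` and `g` move in lockstep, a pawl resets
`g` to 1, and `g = 1` forces a forward move.  Absorbing states are each
recognition event and runoff; recognition removes probability
`(1 − leakage)` from every entry into an aligned state.  Absorption
probabilities from the start state `(1, 1)` come from one sparse linear
solve of size `T(T+1)/2` where `T = window length − 12` (≈ 4,200 states
for the default reporter; a configurable cap guards the quadratic
growth).  Expected inspections per site follow from the expected visits
of the aligned transient states divided by the leakage.  The solve is
independent of `p_nmd` (decay acts after absorption), so fits cache one
solve per `(layout, p_pawl, leakage vector)` and reuse it across `p_nmd`
values — this is what makes oracle-based fitting fast.

The simulator and the solver are developed as two independent routes and
cross-checked in the tests (recognition fractions within 3 binomial
standard deviations at 10,000 replicates across random geometries).

## Fitting

The observed side is the per-position mean of Solo-normalised GFP
intensities for Duo variants; by default only out-of-frame dATG positions
among +7..+31 enter the RSS (in-frame variants express protein from both
starts and carry almost no positional signal; the full 25-position set is
available via a switch).  The objective is the plain sum of squared
differences.

*Grid screen*: all combinations of
{0.001, 0.01, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8} for the three
probabilities (1,000 sets); the chains start from the per-parameter
median of the ten lowest-RSS sets.

*Chains*: 300 iterations by default; each iteration updates one parameter
in the fixed cyclic order (`p_pawl`, `p_leakage`, `p_nmd`) with a uniform
proposal in a window of full width 0.0004, 0.2 and 0.5 respectively,
clipped to [0, 1]; a proposal is accepted only when its RSS is strictly
lower than the incumbent's.  This is a greedy stochastic hill-climb — it
is implemented exactly as such, with no Metropolis acceptance of uphill
moves, no likelihood, and no posterior.  The incumbent RSS is cached, not
re-simulated each iteration (`reevaluate_incumbent` turns on
re-evaluation for robustness studies of the Monte-Carlo noise).  Thirty
independent chains give the parameter mean and standard error over the
per-chain best sets.

The RSS can be evaluated by stochastic simulation (100 trajectories per
variant per evaluation, the noisy regime) or by the exact solver
(`use_oracle=True`), which removes objective noise and is the default in
the test suite for speed and determinism.

*Context-specific leakage*: with `p_pawl` and `p_nmd` pinned to the
global fit, 100-iteration chains optimise only the leakage against Solo
reporters grouped by the −3 nucleotide; the simulated counterpart of each
observation is Solo expression under the candidate leakage divided by
Solo expression under the globally fitted (N-context) leakage.  This
normalisation convention is a package choice — the observed values must
be supplied on the same scale (per-context Solo mean over the overall
Solo mean).

## Library quantification

Read structure (dATG design): 12 random nt — 6-nt barcode — fixed 5'
flank — variable region (6 doped nt + ATG + 30 doped nt) — fixed 3'
flank — 6-nt barcode — 12 random nt.  Because the 135-nt insert is
shorter than a 150-nt read, the mate read runs into the opposite adapter
and the construct is located by searching for the 5' flank rather than at
a fixed offset.  A read pair is rejected when (1) either read fails the
flank structure, (2) any of the four barcodes is not one assigned to a
single sample, or (3) the two reads disagree anywhere in the variable
region.  Mismatching pairs are dropped, never corrected.

Coordinates: the A of the annotated start is +1; upstream positions are
negative with no zero (−1 abuts +1).  An ATG at signed offset `o` from
the annotated A (`o = position − 1` downstream, `o = position` upstream)
is in-frame iff `o % 3 == 0`; this reproduces in-frame upstream ATGs at
−3, −6, … and in-frame downstream ATGs at +4, +7, ….  The −3 context of
an ATG is read from the sequence itself, falling back to the fixed flank
when it lies outside the variable region.  Nomenclature strings name Solo
variants by the concrete −3 nucleotide (`Solo(1T)`) — the unit of the
context-strength analyses — while Duo names render the annotated start's
doped context as `N` (`Duo(1N, 4A)`), matching how variants are grouped
by the second ATG's position.

Filters, in order: presence in all three libraries (FACS-, RNA- and
DNA-seq), DNA-seq pairs > 8, summed FACS pairs > 64, no in-frame stop in
the downstream region, and no upstream ATG (dATG libraries) or no uORF
stop codon (uATG library).  An audit table records removals per rule;
the counts always sum to input minus kept.  `n_ij` fractions are computed
on the unfiltered count table (filtering is downstream of counting).
Variants shared by two replicates are averaged and a correlation report
emitted.  Group summaries use a t-interval on the mean by default
(bootstrap optional) — the interval method is a package choice.

## Genome scan

A CDS enters the scan if it starts with ATG and is at least 45 nt long.
The scanned window is the 45 nt downstream of the annotated start,
positions +4..+48; an ATG is counted at the position of its A (+4..+46),
so ATGs overlapping the annotated start (+2, +3) are excluded — they
cannot occur after an ATG anyway.  Per frame, counts at every scannable
position (zeros included) are rank-correlated with position; depletion of
proximal dATGs shows as a positive Spearman ρ.  No multiple-testing
correction is applied (raw P values are reported).  Expression strata
take the top and bottom 2,000 genes by the supplied expression column,
ties broken deterministically by gene id.  "Main transcript" selection is
the caller's responsibility — the scan uses the FASTA as given.

CAI is the geometric mean of relative-adaptiveness weights over the
10 codons downstream of the start; weights derive from a reference set as
count over the maximum synonymous count, with never-observed codons given
0.01.  The implementation is cross-checked against Biopython's
`CodonAdaptationIndex` in the tests.

## Synthetic data

The generators reproduce the study conditions wherever those are part of
the design: doped positions are i.i.d. 25% A/C/G/T; the reporter window
is 50 + 3 + 50 nt; designed extra-ATG oligos fix one ATG per position;
eight FACS bins; observation tables cover dATG positions +7..+31.
Quantities the experimental design does not dictate are package defaults,
chosen once as plausible for yeast reporter data and documented here:

- **GFP observation noise**: multiplicative lognormal (fluorescence
  ratios are positive and right-skewed), log-sd 0.05 by default.
- **Cell-to-cell intensity spread** within a clone: lognormal with log-sd
  0.25 (fluorescence CVs of ~25–30% are typical), centred so the clone
  *mean* equals its true GFP — the mean is what the bin-weighted
  estimator recovers, so truth and estimand coincide by construction.
- **Bin gates**: seven log-spaced edges from 0.25 to 4.0 around a unit
  median; bin metadata (median `G_i`, gate fraction `P_i`) is computed
  from the pooled simulated cells, as a cytometer would record it.
- **Read sampling**: one read pair per sorted cell for FACS bins;
  multinomial allocation for DNA-/RNA-seq-style libraries.
- **Corruption**: a configurable fraction of pairs receives exactly one
  of the three rejection-rule violations, chosen uniformly; barcodes are
  pairwise Hamming distance ≥ 3 so a single substitution cannot turn one
  valid barcode into another.
- **Synthetic CDS**: ATG + i.i.d. sense codons + stop.  The planted
  depletion models remove early out-of-frame ATGs with probability
  declining linearly from `depletion_strength` at +4 to 0 at the window
  end, optionally scaled by −3 context strength (A > G > C > T) or
  applied only to high-expression genes.

What the generators deliberately do **not** emulate: sequencing-error
profiles beyond uniform substitution, PCR amplification bias and
jackpotting, gating spillover between bins, codon-usage or
secondary-structure effects on expression, and real gene-length or GC
composition distributions.  Passing round-trip tests therefore
demonstrates that the pipeline's arithmetic and bookkeeping are correct
under clean conditions, not that it is robust to every artefact of real
sequencing data.

## Numerical and scale choices

- One root seed per entry point; independent work units (chains,
  replicate ensembles, generators) receive spawned child streams, so
  results are bit-reproducible at fixed seed and independent across
  units.
- The ensemble simulator advances all replicates in lock-step with
  vectorised updates; 10,000 Solo trajectories take well under a second.
- Default problem sizes in the tests: 10,000–20,000 replicates for
  net-leakage estimates; the parameter-recovery check runs the full grid
  screen plus 10 chains × 100 iterations on the exact-solver objective
  (a scaled-down version of the full 30 × 300 stochastic fit, which is a
  long-running job best launched via the CLI).
- Degenerate inputs fail loudly: probabilities outside [0, 1], net or
  single-scan rates of exactly 0 or 1 in the scans-per-triplet formula,
  zero Solo expression in normalisation, zero bin weight in the GFP
  formula, constant counts in the trend test (flagged, not NaN-propagated).

## Known limitations

- The model ignores eIF composition, ATP consumption, secondary-structure
  pausing, reinitiation after uORF termination, and multiple simultaneous
  PICs; `p_pawl`, `p_leakage` and `p_nmd` absorb all such effects.
- The greedy chains estimate a point minimum with spread across restarts;
  the reported SE is variability of a hill-climb, not a posterior width.
- Exact-solver state space grows quadratically with window length;
  windows beyond a few hundred nt need the stochastic engine.
- Net leakage values for single-scan leakages 0.68 and 0.77 are close
  (≈0.045 and ≈0.07 under the default geometry); analyses that depend on
  separating nearby leakage values need the exact solver or large
  replicate counts.
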