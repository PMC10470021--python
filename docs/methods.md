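# Methods

## Effector–target balance model

The model is deliberately static algebra, not a dynamical system. It assumes:

* **Heterozygosity.** Essentially all CALR-mutant patients are heterozygous,
  so a variant allele fraction `v` maps to a transformed-cell fraction `2v`;
  `v` is validated to lie in [0, 0.5]. The peripheral-blood VAF is taken as a
  proxy for the myeloid-cell VAF.
* **Target pool.** Only circulating neutrophils (`N`, default 6·10¹¹, lifetime
  6.6 d) and monocytes (`M`, default 1·10¹⁰, lifetime 3.5 d) count as targets;
  bone-marrow progenitors are excluded, so the burden is a lower bound. The
  monocyte lifetime is stored for completeness but plays no role in the
  eradication criterion, which uses only the dominant self-renewal time
  (the 6.6-day neutrophil lifetime).
* **Serial killing at constant rate.** Each of the `b·T` specific effectors
  kills one target per `τ` days, with no exhaustion, no proliferation, and no
  target regrowth during killing beyond the lifetime criterion itself.

Under these assumptions the kills per effector, total kill time and maximal
controllable VAF are the closed forms given in the README. Two numerical
choices matter:

* `τ` is stored internally in days; the parser accepts explicit unit tags
  (minutes, hours, days) and the unit conversions are exact rationals, so
  "90 min", "1.5 h" and 0.0625 d give bit-identical outputs.
* `max_controllable_vaf` is **not** clamped at the biological bound 0.5; a
  value above 0.5 means any possible VAF is controllable. `display_vaf`
  clamps and flags for presentation, keeping the pure formula testable (the
  identity `total_kill_time(vaf = VAF_max) = 6.6 d` is exercised to 1e-9
  relative tolerance in the tests).

Parameter sweeps (`sweep`) evaluate the scalar operations cell by cell over a
strictly increasing axis and a series of parameter values; every grid cell is
defined to equal its scalar re-evaluation, which is the invariant the tests
enforce.

## Clonotype tables

A clonotype is keyed, by default, on (locus, CDR3 amino-acid sequence, V
call); the recipe is configurable to (locus, CDR3aa) or (locus, CDR3nt, V, J)
and is recorded in every tracking result and run manifest, since coarser keys
merge counts and can only reduce the clonotype count. Duplicate keys merge on
ingest by summing reads. Reads are whatever count column the input provides
(AIRR `duplicate_count` is normally already UMI-collapsed).

Filtering follows the two standard rules: clonotypes with fewer than 2 reads
are dropped (noise floor), and culture clonotypes below 1% frequency are
dropped when defining the specific set (feeder/bystander carry-over); a
frequency of exactly 1% is retained. After the read filter, frequencies are
recomputed over the survivors by default so they sum to 1; because the
original denominator is not recoverable from published tables, a
`renormalize=False` mode preserves the pre-filter denominator instead, and
both modes are exposed. Absent clonotypes have frequency exactly 0 — no
pseudocounts. Alpha and beta chains are always processed as separate,
unpaired samples.

Tracking a key list across samples produces a keys × samples frequency
matrix. A row may be all-zero (e.g. a culture-only clonotype tracked into
bulk samples — precisely the "no enrichment" observation); this is logged as
a warning rather than rejected. Report percentages are formatted with 3
decimals and a dot separator.

## ELISPOT statistics

Normalised counts are mean(stimulated) − mean(unstimulated) − mean(target
alone, when target cells are plated); negative values are reported as 0 with
the raw value retained for audit.

Positivity uses the distribution-free resampling construction: under the
boundary null that stimulated wells behave like `multiplier ×` control wells,
the stimulated wells and the multiplier-scaled control wells are
exchangeable, so the one-sided p-value is the fraction of relabellings of the
pooled wells whose mean difference reaches the observed one. `multiplier=1`
is the ordinary DFR test, `multiplier=2` the conservative DFR2x variant. With
triplicates the 20 relabellings are enumerated exhaustively (the smallest
attainable p is 1/20 = 0.05, so a triplicate response is callable at α = 0.05
only when the observed labelling is strictly extremal); enumeration is used
whenever the relabelling space has at most 10⁶ elements, otherwise a seeded
Monte-Carlo sample with an add-one estimate `(1 + hits)/(1 + resamples)`
(default 10,000 resamples). Statistic comparisons use a 1e-9-scaled slack so
integer ties count as ties. DFR2x conservativeness (its p never undercutting
DFR1x's) holds empirically and is property-tested rather than asserted
algebraically. No multiple-testing correction is applied across conditions.

## Synthetic data

The generators emulate the study conditions, with known ground truth attached
to every sample's `metadata`:

* **Bulk repertoires**: 3,000 clonotypes at 10⁶ reads by default, multinomial
  sampling over deterministic rank weights. The power-law size law with
  exponent `a` uses weights `r^(−1/(a−1))`, making the rank-frequency log-log
  slope exactly `−1/(a−1)`; the cohort default `a = 2` (Zipf-like slope −1)
  keeps thousands of clonotypes above the 2-read floor at 10⁶ reads, matching
  the scale of real bulk bone-marrow samples. The default depth makes a
  0.02%-scale spike detectable (~220 expected reads).
* **Paired timepoints**: the end-of-trial sample reuses a retention fraction
  (default 0.9) of baseline clone templates at their rank weights, replaces
  the rest with novel clones, resamples reads, and receives the spike-ins;
  the baseline never contains spikes, so baseline recovery must be exactly 0.
* **Cultures**: a handful of dominant clones (default 5 at 90% total) over a
  low-frequency background, emulating near-monoclonal antigen-enriched
  cultures whose specific fraction runs 69–99%.
* **ELISPOT**: independent Poisson counts per well; stimulated rate =
  background + effect.
* CDR3s are uniform-length (8–20) random strings over the 20-letter
  amino-acid alphabet with V/J labels from a small fixed catalogue — only
  identity-key behaviour matters, not biological realism. No VDJ
  recombination model, no sequencing-error model, no generation
  probabilities.

What passing tests show, and don't: spike recovery within binomial tolerance
demonstrates that the bookkeeping (filters, keys, denominators) is unbiased
at realistic depths; it says nothing about wet-lab biases (expansion,
sorting, library preparation) that synthetic multinomial reads cannot
exhibit.

Problem sizes in the test suite are scaled to the check at hand: closed-form
identities use 1,000 random parameter sets; the null-calibration suite uses
2,000 simulated triplicate assays; spike recovery uses the full cohort
defaults (8 chain-samples at 10⁶ reads); structural pipeline tests use a
reduced cohort (hundreds of clonotypes at 2–3·10⁴ reads).

## Pipeline

One run = one immutable output directory (timestamp + config-hash name by
default, an explicit name on request; re-use of an existing directory is an
error). All file contents are derived solely from the configuration and seed,
so same-seed re-runs are byte-identical; seeds for each (patient, chain) and
assay are derived deterministically from the run seed and kept below 2³¹.
Filters log removed-row counts at INFO, and the manifest records package
version, seed, key recipe, thresholds and (for simulated cohorts) the full
ground truth, so every report number can be recomputed from the emitted
tables — a property the tests spot-check.

## Known limitations

* The balance model ignores bone-marrow HSCs and progenitors, effector
  proliferation and exhaustion, and any spatial structure; it is an
  order-of-magnitude argument, not a simulator.
* The DFR implementation follows the permutation construction described
  above; it is validated against exhaustive enumeration, not against the
  original R reference implementation.
* Repertoire operations assume clonotype tables as input; read-level
  processing (UMI consensus, V(D)J alignment) is out of scope.
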