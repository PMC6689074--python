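# Methods

## Binding-affinity model

Binding is described by mononucleotide free-energy models: a model of
footprint *L* assigns every (position, base) a penalty ΔΔG(i, b) ≥ 0 in
dimensionless RT units (RT = 1; only relative affinities carry meaning, so
no kcal/mol conversion is attempted). Models are *anchored*: at every
position the minimum penalty over the four bases is exactly 0, so the
optimal window has total penalty 0 and raw relative affinity 1. The
relative affinity of a window is `exp(−Σ penalties)/norm_max`. Because the
energies are additive, log affinity decomposes exactly by position; this
additivity is what makes flank optimisation exact by independent
per-position choice and penalty recovery a linear regression.

`norm_max` re-expresses affinities relative to a reference maximum (e.g.
the best window in a reference sequence set, scanned on both strands).
Each model's normalisation corresponds to a different and unknown
dissociation constant, so no operation in the package combines affinities
from two models arithmetically; cross-model results are reported
side-by-side only (per-factor site lists, per-factor concordance).

Two binding modes are used. Dimer (Hox–cofactor) models have a 12-bp
footprint laid out as one Exd-side flank base, the 8-bp class core, and
three Hox-side flank bases. Monomer models have a 6-bp footprint: one
flank base, the 4-bp core (TAAT generically; TTAT/TTAG for Abd-B, encoded
as two equally optimal bases at the discriminating core position), one
flank base.

Numerical choices: windows containing non-ACGT characters score 0, are
excluded from site lists and counted in a log line. Unanchored or negative
penalties are rejected at construction rather than silently re-anchored,
so JSON round trips are loss-free. Site ranking ties break by ascending
start, then + before −. Scan thresholds below 0 are clamped to 0; a
threshold above 1 is allowed and yields an empty site list. Sequences
shorter than the footprint yield an empty scan with a logged notice, not
an error. The default scan threshold is 0.05 relative affinity — low
enough to retain the weak sites that matter in this system.

## Site taxonomy and class calls

A site's class label is assigned only when its core positions *exactly*
match a registered class core (on the scored strand); near-cores keep
label `none` but full graded affinity. This separates core identity (which
class of complex the site recruits) from affinity (how well it recruits
it), and it is the level at which engineering guarantees are stated.

## Rational design operations

* `convert_class` substitutes only core positions; minimality is certified
  by the Hamming distance of the cores (1 for every conversion between the
  registered classes, which differ only at core index 5).
* `optimize_flanks` substitutes only flank positions and attains the exact
  model maximum with the core fixed (valid by additivity); ties between
  equally optimal bases break in A,C,G,T order.
* `knockout` has two modes. Core mode (default) finds the fewest
  substitutions after which no registered class core remains on either
  strand and none has been created — mirroring core-directed mutagenesis.
  Affinity mode drives every window of every supplied model below a
  ceiling. The search is exhaustive (certified minimal, lexicographically
  smallest plan by position then alternative base) for regions ≤ 60 bp
  needing ≤ 3 edits; beyond that an iterative greedy search is used and
  the plan records `certified: False`.
* `restore` splices original bases back over stated regions.
* `side_effect_audit` reports the complete per-model scan diff (gained,
  lost, affinity-changed sites) *and* exact-core gains/losses. The
  core-level channel exists because conversion side effects — e.g. a
  class 1 conversion creating a new class 3 core out of overlapping
  sequence — are core-identity events, and can fall in windows too close
  to a sequence end to carry a full 12-bp dimer window.

Every design operation can attach a predicted-effects audit, which by
construction equals an independently recomputed audit of its application.

## Expression logic

Activity is modelled per segment and per intra-segment position:

    score = w_hox·Hox + w_stat·STAT − w_wnt·WNT,  floored at 0,

with ternary calls (off/weak/strong) at two ordered thresholds. The Hox
term sums over the factors occupying the segment under the genotype
(removed factors excluded, ectopic factors added): the factor's best
composite-site affinity when cofactors are available (zero otherwise,
emulating hth/exd loss), plus monomer competence × the monomer-site
aggregate. The aggregate is the sum of monomer-site affinities ≥ 0.1,
capped at 1: many weak sites act cumulatively, the cap prevents unbounded
drive, and the 0.1 floor keeps incidental sub-threshold TAAT matches
(e.g. inside the composite cassette itself) from leaking into segment
scores.

Defaults, frozen as the package's named calibration: w_hox = w_stat = 1,
w_wnt = 2, thresholds (0.3, 0.7), STAT level 0.12 in every segment,
monomer competence 0.3 for all Hox factors except Abd-B at 1.0. The
biology constrains signs and orderings (additive Hox + STAT; WNT
repression; Abd-B the strongest monomer actor), not magnitudes; the
calibration was chosen once so that the qualitative genotype truth table
holds and is not tuned per analysis. STAT is a per-segment scalar
(site-level STAT scanning is out of scope), and WNT is a two-position
intra-segment mask (one position inside the repressed segment-polarity
stripe, one outside) — the minimal structure that distinguishes segmental
patches from a continuous lateral stripe.

Factor activation domains (registry defaults) follow the genetic removal
series rather than protein staining extents: Lab ic; Dfd md/mx; Scr lb/T1;
Antp T1–T3; Ubx T3–A1; Abd-A A2–A7; Abd-B A8–A9; Pb is registered but has
no expression domain in this system. This partition reproduces the
observed epistasis (removing Scr/Antp/Ubx silences T1–A1 but not A2–A9;
additionally removing Abd-A silences through A7, leaving Abd-B's A8–A9).

## Synthetic data

No real enhancer sequence is published for this system, so the generator
emulates its architecture. Backgrounds are grown base by base, excluding
any base that would complete a forbidden motif (class cores, monomer
cores, and their reverse complements) — exact, unlike whole-sequence
rejection. The dual-core cassette is 55 bp with the 15-bp geometry
`TGATTAATGATTTAT`: class 2 core at offset 0 and class 3 core at offset 7
share exactly one base pair, which admits a single-substitution dual
knockout. Fragment lengths are S1-like 300 bp (inert), S2-like 250 bp
(cassette + one planted generic monomer site at relative affinity 0.25 and
one optimal Abd-B monomer site), S3-like 130 bp (one of each again);
the concatenation is 680 bp and the reporter-style constructs span
200–680 bp. The seven variant constructs are produced by the design
operations themselves, so fixture geometry and designer behaviour cannot
drift apart. Suite generation validates itself against the scanner
(manifest coordinates must equal scan output; backgrounds must carry no
near-site above 0.017 for any composite model) and resamples on failure;
fixtures regenerate byte-identically from (suite version, seed).

Synthetic model calibration: core mismatches cost a 50-fold factor except
at the single class-discriminating core position, where cross-class
binding is graded — class 2 models bind class 3 cores at 0.25 and class 1
cores at 0.1 of their own core (promiscuity), class 3 models bind class 2
at 0.1 and class 1 at 0.05, class 1 models bind non-cognate cores at
0.02–0.05. Flank penalties are 2- to 4-fold per suboptimal base, shared
across the class models. These constants were chosen once so that (a) the
in vitro orderings are reproduced (class 2 promiscuous; Lab weak on
non-class-1 sites; the mutant site essentially unbound; optimal flanks
severalfold above native), (b) the seven variant windows have pairwise
distinct affinities spanning >100-fold per factor, and (c) the expression
truth table holds under the frozen logic defaults.

Pseudo-measurements apply multiplicative lognormal noise (mean-1 noise
factor with the requested coefficient of variation) to true window
affinities, standing in for quantified band intensities. Penalty recovery
regresses −log(noisy affinity) on per-position base indicators (anchored
base as reference, intercept absorbing the small lognormal bias) by
ordinary least squares; at n = 500 windows and cv = 0.1 all 15 free
parameters of a 6-bp model are recovered within 3 standard errors.

## What the synthetic fixtures do and do not show

Passing tests demonstrate internal correctness (scanner equals exhaustive
scoring; designs are minimal and audited; the logic model reproduces the
qualitative genotype table under its frozen calibration) on sequences with
idealised properties: backgrounds entirely free of near-sites, exactly
planted monomer content, and additive, mononucleotide energetics. Real
enhancers have correlated base composition, many graded near-sites,
dinucleotide and shape effects, chromatin context, and unmodelled
collaborator inputs; agreement on fixtures therefore validates the
machinery, not the biology of any particular locus. Model *fitting* from
binding data, cross-species conservation analysis, and spatially
continuous tissue simulation are out of scope.

## Known limitations

* Dfd's registered domain includes the mandible, where the real reporter
  is silent; the model consequently over-predicts md activity. Segment
  occupancy is binary and ignores protein levels.
* The class 2 variant's predicted head activity under class conversion is
  more all-or-none than observed (real class 2 complexes retain partial
  activity on converted sites).
* The two-position WNT mask cannot represent graded intra-segment
  patterns (e.g. paired patches within single segments).
* Monomer aggregation treats sites as independent and caps their sum;
  cooperative or competitive occupancy is not modelled.
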