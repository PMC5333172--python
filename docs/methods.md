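# Methods

`regevo` simulates the evolution of regulatory DNA whose fitness is the
fidelity of the gap-gene expression pattern it drives.  This note
documents the model, the synthetic data it runs on, the numerical
choices, and what the scaled-down simulations do and do not show.

## The genotype-phenotype map

A genotype is four named regulatory loci (one per gap gene: *hb*, *Kr*,
*gt*, *kni*) of plain nucleotide sequence plus three fixed interval
annotations per locus: accessibility intervals (the represented,
mutable sequence), CRM intervals, and footprint intervals.

**Site annotation.** Each of the eight factors (Bcd, Cad, Hb, Gt, Kr,
Kni, Tll, Hkb) has a log2-odds PWM against a uniform background.  Every
window on both strands scoring at least the PWM threshold is a
candidate site with binding energy E equal to its score.  A candidate
enters the model if it (1) scores at least a stricter high-score cutoff
and lies wholly inside an accessibility interval, or (2) overlaps a CRM
interval, or (3) overlaps a footprint interval.  Both thresholds are
calibrated to exact per-window tail probabilities computed by
convolving the per-column score distributions (defaults: 5e-3 for the
scan threshold, 1.5e-3 for the high-score cutoff; see "Choosing the
operating regime" below).

**Expression.** Site occupancy is thermodynamic,

    phi_s = q_s / (1 + q_s),    q_s = K_f * c_f(i) * exp(beta * (E_s - E_ref_f)),

with c_f(i) the factor concentration in nucleus i and E_ref_f the
factor's scan threshold, so the weakest callable site has q = K c.
Same-factor sites within 50 bp (edge to edge) boost each other in one
fixed-point pass, q' = q (1 + omega * sum of neighbour phi).  The
activation probability of gene a in nucleus i is

    P_on = logistic( sum_s T_{f(s)->a} phi'_s + theta_a ),

and gene products follow reaction-diffusion dynamics on a row of nuclei
with zero-flux boundaries:

    dm/dt = R P_on - lambda m + D lap(m)
    dp/dt = r m - rho p + D' lap(p)

Bcd, Cad, Tll and Hkb are time-constant external profiles; the four gap
factors read their concentrations from the simulated protein state, so
gap-gap feedback is live.  This structure is a deliberately small
surrogate for fitted thermodynamic gap-gene circuits: it preserves
affinity- and concentration-dependent occupancy, short-range
same-factor cooperativity, signed combinatorial regulation, gap-gap
feedback, and spatial coupling, while making no claim to quantitative
fit.  The module boundary is such that a fitted model could be swapped
in behind the same `simulate` interface.

**Fitness.** The rms-score of an individual is

    F = sqrt( (1/N) sum_{p,a,i,t} (u - U)^2 )

over the full observation grid (both products, all genes, nuclei and
observation times), where U is the wild-type solution computed once
from the founder genotype.  The founder therefore has F = 0 exactly.
The regulatory rms-score of a single site is F recomputed with that
site deleted from the wild-type annotation (sequence unchanged).

**Evolution.** Per generation: every individual's loci are mutated by
independent per-base substitution at rate mu within the accessible
sequence; individuals are annotated, simulated and sorted by F; the
breeding pool is everyone at least as fit as the rank-`elite_size`
individual (ties included); pairs of parents are drawn uniformly with
replacement and recombined by inheriting each locus whole from either
parent with probability 1/2 (no within-locus break points).
Generation 0 is the unmutated founder population.  Indels are excluded
so the coordinate system is fixed, which the tracker's
coordinate-identity test presupposes.

**Tracking.** One elite individual is re-drawn uniformly each
generation and its sites matched between consecutive generations:
identical (tf, start, length, strand) sites persist; remaining sites
match greedily, in coordinate order, to the nearest unmatched
same-factor site overlapping their vicinity (the window of three site
lengths containing the site), ties to the smaller coordinate; the rest
are deaths and births.  A birth overlapping the vicinity of the
wild-type coordinates of a same-factor site whose lineage is currently
dead is a rebirth; it starts a fresh trajectory carrying a link, and
does not extend the dead lineage's lifetime.  Core sites are initial
lineages alive in every generation (moves allowed; the never-moved
subset is reported separately).  Non-core lineages within 50 bp of a
same-factor core site are cooperative; those merely intersecting a core
site are overlapping (cooperative takes precedence).

## Synthetic data

The generators replace the external data inputs (genome regions,
empirical PWMs, DNase and curated-site data, fitted parameters) with
seeded stand-ins:

* **PWMs** realize a target per-column information content (jittered
  +-10%) with a random consensus; the Hb motif is a repetitive
  homopolymer-A consensus of lower per-column content, so polyA/polyT
  tracts produce dense self-overlapping hits -- the motif-redundancy
  property that drives Hb's fast site loss.
* **Loci** are i.i.d. uniform background (GC knob available) with ~15
  planted sites each: strong tier plants the exact consensus, weak tier
  1-2 mismatches; strands random.  Footprints are exactly the planted
  intervals, accessibility covers the planted sites (padded) plus
  random intervals up to the configured fraction (the desk default
  represents the whole locus), and two random CRM intervals cover
  ~15% of each locus.
* **External gradients**: Bcd anterior-exponential (decay length 8
  nuclei), Cad the posterior mirror (10), Tll and Hkb symmetric
  terminal peaks (widths 2.5 and 1.2), all bounded by c_max = 1.
* **Regulatory signs**: the full qualitative gap-network motif --
  maternal activators (Bcd everywhere; Cad posterior targets,
  repressing *hb*), gap autoactivation with mutual repression, and
  terminal repressors (Tll sparing *hb*).  Every factor regulates every
  target, as in fitted gap-gene circuits; magnitudes are a uniform
  `weight`.

What the generator does **not** emulate: real base composition, real
motif shapes, measured expression profiles, nuclear divisions, or 3D
genome organisation.  Passing tests therefore demonstrate properties of
the method and of the modelled evolutionary regime, not quantitative
agreement with *D. melanogaster* data.

## Choosing the operating regime

The target phenomenology -- quasi-steady positive fitness, continuous
site turnover, compensatory gains -- lives in the regime where the
per-genome mutational load on functional sequence exceeds one, so that
offspring with an unchanged annotation are rarer than the breeding
pool.  At full scale (4 x 18 kb, ~1,500 sites) this holds trivially.
At desk scale (4 x 2 kb) it constrains the annotation density: with the
default thresholds the founder carries ~360 included sites covering
~25% of the sequence, giving a functional load of ~2 substitutions per
genome per generation and an annotation-preserving offspring fraction
of ~0.1, safely below the 20% truncation fraction.  Lowering the
thresholds by an order of magnitude leaves the desk population frozen
at F = 0 with no functional turnover -- a regime in which the turnover
analyses are undefined.

## Numerical choices

* **Integrator**: exponential-Euler -- decay is integrated exactly
  (m <- a m + b (synthesis + diffusion), a = exp(-lambda dt),
  b = (1 - a)/lambda), synthesis and diffusion explicitly.  The scheme
  is unconditionally stable in the decay term, reproduces the D = 0
  constant-input closed form to machine precision at any dt, and
  conserves mass exactly under zero-flux diffusion with zero decay.
  Default dt = 0.04 time units on t in [0, 6] with observations at
  t = 1..6; at this dt the fitness ranking of mutants is identical to a
  10x finer grid and |dF| < 0.012.  A one-sided clip at zero guards the
  explicit diffusion step against round-off undershoot.
* **Threshold calibration**: exact DP over discretised scores
  (precision 1e-3 score units).
* **Ties**: stable sorts everywhere; greedy matching ties break to the
  smaller coordinate; rank ties at the elite boundary are included.
* **Degenerate inputs**: empty annotations are legal (P_on =
  logistic(theta)); individuals whose dynamics go non-finite receive
  F = +inf and are logged, never selected; statistics over empty site
  sets return NaN with an n = 0 flag.
* **Seeding**: one global seed spawns per-stage `SeedSequence` children
  (pwms, genotype, evolution, analysis) in a fixed order; the evolution
  generator drives parent choice, locus inheritance, mutation and the
  tracked-individual draw in a fixed per-generation order, so runs are
  bit-reproducible and the manifest checksums prove it.

## Analysis conventions

* Bin energies use fixed 180-bp bins tiling each locus (the bin count
  follows sequence length); a site straddling a bin edge belongs to the
  bin containing its start; the trailing partial bin is normalised by
  its own length.
* "New" sites in elite-averaged statistics are sites whose
  (tf, locus, start, strand) is absent from the founder annotation;
  tracked/core statistics use the tracked individual's trajectories
  only (only one individual is tracked per generation).
* Overlap statistics count unordered pairs of intersecting intervals
  (same factor for self-overlaps) as a fraction of the site count; a
  per-site counting mode is available.
* The bootstrapped KS test pools both samples, redraws samples of the
  original sizes with replacement, and applies the +1 p-value
  correction.  Its type-I error at alpha = 0.05 is calibrated in the
  test suite.
* Pearson correlation is used throughout; epoch boundaries for
  fitness-energy correlations default to thirds of the run.
* At desk scale the tracked-site energy trend is compositional: the
  mean E of surviving initial sites rises because weak sites die first,
  while an individual survivor's own E drifts down by ~1% -- an erosion
  below the selection resolution of a 50-individual population.  The
  bin-level dE meanwhile is negative, reproducing the opposite-trends
  contrast between the two annotation levels.

## Scaled-down study conditions

The `desk` preset -- used by the test suite and by
`scripts/acceptance.py` -- runs 4 loci x 2,000 bp, 30 nuclei, 50
individuals with top-10 truncation (the same 20% truncation fraction as
the full-scale configuration's 20 of 100), mu = 0.001 substitutions/bp/
generation, 300 generations.  A full-scale `paper` preset (18 kb loci,
100 individuals, 3,350 generations) is expressible but impractically
slow for routine testing; a `smoke` preset (2 loci x 800 bp, 20
individuals, 30 generations) exercises the pipeline end to end in
seconds.

## Known limitations

* The expression model is a structural surrogate, not a fitted model;
  absolute F values and knockout scores are in arbitrary units.
* Substitution-only mutation ignores indels and rearrangements.
* The tracked individual is re-drawn every generation by design, so
  trajectories splice across lineages; cross-individual
  genealogy is out of scope.
* Greedy vicinity matching can differ from a globally optimal
  assignment in adversarial many-site collisions; the suite checks
  agreement on small histories.
* Desk-scale runs lose proportionally fewer sites than full-scale
  runs would (roughly half the initial sites survive 300 generations),
  so core-site sets are comparatively large.
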