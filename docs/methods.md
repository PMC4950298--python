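# Methods

This note documents the models and procedures implemented in `wolbsweep`,
the assumptions behind them, and the design choices made where the problem
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The biological setting

A host population is fixed for a resident, maternally inherited *Wolbachia*
strain and for one mitochondrial haplotype (HT1). A second strain invades;
because *Wolbachia* and mitochondria share the cytoplasm, the haplotype of
the founding doubly infected lineage (HT2) hitchhikes with the invader.
The invader induces unidirectional cytoplasmic incompatibility (CI):
crosses between doubly infected males and singly infected females lose a
fraction *l*<sub>CI</sub> of eggs, while all other crosses are compatible.
Under strict maternal co-inheritance every doubly infected individual
should carry HT2; doubly infected individuals on HT1 ("mismatch") indicate
paternal or horizontal transmission of the invading strain.

## Four-cytotype recursion (`wolbsweep.model`)

The model tracks frequencies of four heritable cytotypes — A1, A2
(singly infected, haplotype HT1/HT2) and B1, B2 (doubly infected) — in a
panmictic population with discrete, non-overlapping generations. One
generation applies, in this order:

1. **Horizontal acquisition.** Each singly infected individual acquires
   the invading strain with probability β (default) or β·*p*<sub>B</sub>
   under the frequency-dependent option (below). A fraction α of
   acquisitions reaches the germline and moves the individual to the B
   class of the same haplotype; the remaining 1−α are *somatic*:
   PCR-detectable at census but neither CI-active nor transmitted. The
   somatic part appears only as an "observed" overlay
   β(1−α)·*x*<sub>A*h*</sub> on the heritable double class of haplotype
   *h*.
2. **Census.** Observed (PCR-visible) frequencies are recorded, including
   the somatic overlay.
3. **Random mating with CI, via the mating table.** For each
   (mother, father) cytotype pair the table holds a reproductive weight
   (mother's fecundity × CI survival) and an offspring distribution:
   haplotype is strictly maternal; B mothers transmit the invader with
   probability 1−µ; crosses of A mothers with B fathers carry weight
   *F*<sub>A</sub>(1−*l*<sub>CI</sub>) and surviving offspring gain the
   strain paternally with probability τ; offspring of B fathers that
   missed maternal transmission also gain it paternally with probability
   τ; all other crosses are fully compatible with weight
   *F*<sub>mother</sub>.
4. **Renormalisation** by mean reproductive output.

With τ = β = 0 the haplotypes are neutral labels and the model collapses
to the classical single-strain CI recursion

  *p*′ = *F p*(1−µ) / [*F p* + (1−*p*)(1 − *l*<sub>CI</sub>·*p*)],

with *F* the fecundity of infected relative to uninfected females. This
reduction is enforced as a correctness anchor: a property test checks
agreement to 10⁻¹² over 1000 random parameter draws, and total frequency
is conserved to 10⁻¹² after every step.

**Parameters.** *l*<sub>CI</sub> ∈ [0,1] (CI level; 0.98 throughout, from
crossing experiments in this system), µ ∈ [0,1] (maternal transmission
leakage; 0, since field data show near-perfect transmission),
*F*<sub>A</sub>, *F*<sub>B</sub> > 0 (relative fecundities; 1, no measured
fitness cost), τ ∈ [0,1] (paternal transmission), α ∈ [0,1] (germline
conversion of acquisitions), β ∈ [0,1] (per-generation horizontal
acquisition). The three named scenarios are presets: paternal
(τ = 0.3), heritable horizontal (α = 1, β = 0.015), somatic
(α = 0, β = 0.3).

**Initial conditions.** The default founder state is
*x*<sub>B2</sub> = 0.01, *x*<sub>A1</sub> = 0.99 — one rare HT2-linked
doubly infected lineage entering an HT1 population — configurable via
`CytotypeState.founder`. Convergence is declared when every component
moves less than 10⁻¹⁰ between generations (cap 10 000 generations);
"permanent" quantities are read at convergence, "transient" ones via the
trajectory peak (ties break to the earliest generation).

**Event-order and denominator choices.** The order
acquisition → census → mating is a fixed convention, recorded in run
provenance; at the parameter values used the alternative orders shift
outcomes negligibly. Mismatch is exposed under both denominators (all
individuals, or PCR-positive doubly infected individuals) because the
natural reporting choice differs between claims.

**Acquisition-model variants and what the scenarios show.** Under the
default constant-rate acquisition, the heritable-horizontal scenario from
the 1% founder converges to ≈92% mismatch among infected individuals:
conversions of the abundant resident background in the first generations
are amplified by the CI sweep exactly like the founding lineage, so the
captured-HT1 class overwhelms the original HT2 lineage. A
frequency-dependent (mass-action) variant, `acquisition="frequency"`,
scales the acquisition probability by the heritable double-infection
frequency — acquisition from infected carriers — which suppresses early
conversions; from a 5% founder it yields a permanent association near
20–22%, and ≈10% for the paternal scenario. The sensitivity sweep in
`analysis/01_scenarios.py` tabulates both variants over founder
frequencies {0.001, 0.01, 0.05}. The package default remains the
constant-rate model with the 1% founder; the qualitative contrast between
scenarios (permanent mismatch for paternal and heritable-horizontal
transmission, transient mismatch with extinction for somatic) holds under
every combination examined.

## Travelling-wave dispersal bound (`wolbsweep.wave`)

A CI invasion with bistable-type local dynamics spreads as a travelling
wave whose front width is set by the balance of dispersal and selection:

  Δ*x* = 3σ/√*l*<sub>CI</sub>,

with σ the standard deviation of per-generation dispersal and Δ*x* the
transition-zone width (frequency rising from 5% to 95%). Solving for σ
turns an observed lower bound on Δ*x* into a lower bound on σ; reporting
rounds to the nearest integer km. When the invasion advances from both
ends of a transect, each front's width is bounded by half the end-to-end
transitional span (`transitional_span` halves by default).

The square-root form is adopted deliberately: it reproduces both reported
bounds (σ > 43 km from Δ*x* = 130 km; σ > 28 km from Δ*x* = 85 km at
*l*<sub>CI</sub> = 0.98), whereas a non-radical variant Δ*x* = 3σ/*l*<sub>CI</sub>
gives 42 km for the first; the latter is kept behind `literal=True` for
comparison only.

"Latitudinal distance" is pure north–south separation, |Δlat|·111.2 km,
matching the north–south axis of spread; a haversine great-circle distance
is provided but is not the default.

**Width measurement.** `transition_zone_width` orients the transect so
the profile increases, monotonises it by isotonic regression
(pool-adjacent-violators, `scipy.optimize.isotonic_regression`) — without
which binomial sampling noise creates multiple threshold crossings — and
locates the 5% and 95% crossings by linear interpolation between adjacent
sites. NaN marks a profile that never crosses a threshold (e.g. an
everywhere-fixed transect). The estimator is invariant to sites added
outside the crossing interval and to transect orientation.

**Numerical check of the relation.** `simulate_invasion_wave` runs a
deterministic 1-D deme grid (Gaussian dispersal kernel truncated at 4σ,
deme spacing σ/10, front re-centred each generation) to the wave's
asymptotic shape. Its emergent 5–95% width is ≈1.4× the analytic value at
*l*<sub>CI</sub> = 0.98 (the analytic "3" descends from a gradient-based
width definition, ≈√8σ/√*s* for tension zones, not from the 5–95% range),
so σ bounds computed from observed 5–95% spans via the analytic relation
are conservative. `analysis/02_wave_bounds.py` prints this comparison.

## Survey association statistics (`wolbsweep.association`)

Individual records carry population, period (1998/1999, 2000/2001, 2008,
2014), zone (fixed/transition), host plant (Prunus/Lonicera/unknown),
infection (single/double) and haplotype (HT1/HT2/untyped). Summaries
count, per stratum, the mismatched classes (double∧HT1, single∧HT2) and
report percentages to one decimal with half-up rounding. Individuals with
untyped haplotype (the 1998/1999 collections were screened for infection
only) enter infection denominators but are excluded — and logged — from
haplotype denominators.

Fisher's exact test is the standard two-sided hypergeometric test (sum of
tables with probability not exceeding the observed table's), delegated to
`scipy.stats.fisher_exact`; an exact-rational full-enumeration oracle in
the test suite verifies agreement to 10⁻¹² over every 2×2 table with
total ≤ 30. The odds ratio is reported with Haldane's 0.5 continuity
value in every cell and plays no role in the p-value.

The bundled tables in `wolbsweep.synth.paper_fixtures` synthesise
individual records whose stratum margins equal the published survey
counts exactly (margins are sufficient statistics for every statistic
computed here). Where the published margins do not determine a joint
allocation — host plant × period among transition-zone doubly infected
flies, the per-period split of transition-zone singly infected flies —
one consistent allocation is fixed and documented in the source; no
statistic reported by the package depends on it.

## PCR-RFLP haplotyping (`wolbsweep.rflp`)

The diagnostic assay digests a 546-bp COI amplicon with HaeIII (GG^CC,
blunt cut at offset 2). Site search is an exact substring scan on the
given strand; fragment lengths always sum to the input length. Calls:
HT1 for a single fragment within ±5 bp of full length; HT2 for a fragment
multiset matching {342, 204} within ±5 bp per fragment; otherwise
`unknown` (the wet-lab analogue is re-sequencing). The ±5 bp tolerance
reflects agarose gel resolution; exact matching is available by setting
`Assay(tolerance=0)`. IUPAC ambiguity codes never match the motif — a
conservative no-cut rule that avoids false HT2 calls on poor-quality
sequence. Because GGCC is palindromic, digesting a reverse complement
reverses the fragment list (property-tested, and the cut-position scan is
cross-checked against Biopython's `Restriction.HaeIII`).

Inputs are assumed to be pre-trimmed amplicons; primer handling and
reading-frame validation are out of scope.

## Synthetic surveys (`wolbsweep.synth`)

`SurveyDesign`/`generate_survey` emulate a field survey along a
north–south transect: per-site double-infection frequency follows a
logistic cline whose 5–95% width defaults to 3σ/√*l*<sub>CI</sub>
(`SurveyDesign.transect`), or explicit per-site frequencies (e.g. from a
model trajectory); infection status is binomial per site; haplotype is
binomial conditional on infection, with an elevated mismatch probability
inside a declared transition interval (default 0.2, matching the order of
the observed transition-zone mismatch), a small one outside (0.015) and a
small single∧HT2 leakage probability (0.005). Transect positions map to
latitude at 111.2 km/degree so survey geometry and the wave module agree.
All draws come from one seeded `numpy` generator; identical seeds give
byte-identical outputs, and the seed lands in the output metadata and
provenance records.

`generate_fixture_amplicons` builds the haplotype pair as two 546-bp
sequences differing at exactly one C/T transition inside the single HaeIII
site (cut after base 342). They are constructed stand-ins for the real
GenBank amplicons (labelled `synthetic` in their ids); the true SNP
position within the real amplicons is only implied by the fragment sizes,
so the cut position is placed by construction.

**What the generator does not emulate:** spatial autocorrelation beyond
the smooth cline, overdispersion between years, host-plant-structured
sampling effort, prolonged pupal dormancy mixing cohorts, and
population-level pseudo-replication. Passing round-trip tests therefore
show estimator correctness under clean binomial sampling, not robustness
to every field artefact.

## Numerical conventions

Frequencies are unitless in [0,1]; percentages appear only at the
reporting layer (one decimal, half-up). Undefined ratios (empty
denominators) are NaN, never exceptions. Heritable frequencies are
renormalised by their exact sum each generation, keeping conservation at
the 10⁻¹² level over arbitrary horizons. Problem sizes used by the
checked examples — 10⁴-generation cap on recursions, 41 sites × 200
individuals for cline recovery, exhaustive 2×2 enumeration to total 30 —
were chosen so every routine check completes in seconds while leaving
sampling error well inside the stated tolerances.

## Known limitations

- Deterministic, infinite-population dynamics: no drift, no stochastic
  loss of rare lineages (relevant precisely at the 1% founder stage).
- Panmixia within the modelled population; the spatial wave enters only
  through the separate deme simulation and the width relation.
- No bistable threshold analysis: with *F* = 1 and µ = 0 the invasion has
  no unstable equilibrium, so founder frequency affects timing and lineage
  composition but not eventual fixation.
- The published per-period Fisher p-values (0.029; 0.001) and one printed
  percentage are not reconstructible from the published marginal counts
  alone; the package reports values computed from the counts it carries.
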