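# Methods

## Model structure

The cascade is a deterministic reaction network over two well-mixed
compartments, intracellular (1 pL) and extracellular (1 nL), approximating a
cultured cell monolayer and its medium.  State variables are the 49 metabolite
pools (24 species present in both compartments, plus the membrane-esterified
AA pool); enzymes and transporters are parameters, not states — their
concentrations stay at the sampled value for the whole run unless an
induction schedule reassigns them, reflecting the assumption that protein
turnover is slow relative to the 7 h simulated window.  Metabolite pools start
at 10⁻²⁸ mM, a numerical zero that keeps logarithmic quantities defined.

Four rate-law families cover the 113 reactions: reversible uni-uni
Michaelis–Menten kinetics with competitive binding for the 21 enzymatic steps,
reversible mass action for the 9 non-enzymatic conversions, saturable carrier
transport with competition for the 35 ABC/PGT reactions, and first-order decay
for the 47 degradation reactions.  Reaction 95 is the substrate-release step
(below); reactions 1 (enzymatic release) and 113 (non-enzymatic membrane
release) are present but disabled by default, so the release function is the
sole AA source in the shipped configuration.

The shipped catalogue is a synthetic reconstruction assembled from the
pathway's published topology: the full inventory satisfies every structural
constraint the original network states (reaction, metabolite and parameter
counts; compartment volumes; release-reaction switches) but individual
stoichiometric rows are this package's own transcription of standard
eicosanoid biochemistry, not a copy of a published table.  Tests that depend
on exact inventory therefore check the counts and invariants, not row-level
identity with any external source.

Two reconstruction choices deserve note.  The COX-2 side-oxygenation of AA to
15-HPETE (reaction 14) carries a turnover prior ~200-fold below the main
cyclooxygenase reaction: COX-2 is orders of magnitude more abundant than
15-LOX, and without the reduced turnover the "minor" route would dominate
15-HETE production.  PHGPx carries a high-abundance prior (median 3×10⁻⁴ mM)
so that intracellular reduction of hydroperoxides outcompetes their export —
otherwise the medium would accumulate HPETEs rather than the HETEs the assay
panel actually quantifies.

## Substrate release

Availability of free AA after the stimulus is an explicit function of time,
not a mechanistic phospholipase model.  The profile is piecewise: within each
segment the available concentration relaxes exponentially from its current
level toward a target, `A(t) = target + (A₀ − target)·2^(−(t−t₀)/τ)`, with τ
the doubling time (rise) or half-life (decay; the decay switch appends a
segment targeting zero at the configured peak time, so the available pool
halves every half-life thereafter).  Schedule entries reassign the target and
τ at set times, which is how the pulsed/constant/decaying/delayed programmes
are built; the "minimal + delayed" programme targets 10% of the total until
3 h and the full amount thereafter, delivering a 10%/90% split exactly.

Reaction 95's flux is the analytic time-derivative of `A`; during decay the
negative branch is damped by `AA/(AA + 10⁻⁹ mM)` so withdrawal can never push
the intracellular pool negative while remaining continuous in the state.
Cumulative release is computed segment-wise in closed form (each segment is
monotone), which is what the 3 h release-fraction quantity reports.

The default total release is 0.1 mM over 6 h.  For scale: an ionophore
stimulus mobilises a substantial share of the ~10 mM-equivalent esterified AA
pool of a keratinocyte, but only the free fraction transiting the cytosol is
"available" in the model's sense; 0.1 mM keeps free AA in the tens of
nanomolar quasi-steady range against the sampled COX consumption, consistent
with sub-micromolar free AA in stimulated cells.

## Parameter priors and sampling

Every independently sampled parameter has a log-normal prior
`ln x ~ N(μ, σ)`.  Priors fitted from weighted literature values use weighted
moments of the log-values with σ floored at 0.25 so a single source never
produces a point mass.  The default prior set covers all 184 independent
parameters of the fixture: per-kind location hyperparameters (turnovers
~10 s⁻¹, Michaelis constants ~5 µM, strongly exergonic oxygenation
equilibria, minutes-scale non-enzymatic conversions, ~10 h clearance
half-lives) and abundance priors per catalyst (COX isoforms ~10⁻³ mM, PHGPx
~3×10⁻⁴ mM, other enzymes ~3×10⁻⁶ mM, carriers ~10⁻⁵ mM).  Widths follow the
provenance structure of a literature-weighted parameterisation: rate constants
σ = 0.5, Michaelis constants σ = 1.0, protein abundances σ = 1.5 (roughly the
three-decade spans protein databases report across cell types).

Within each reaction, `K_mp` (enzymatic) and `k_r` (non-enzymatic) are
dependent: derived per draw from the Haldane relation `K_mp = K_eq·K_ms`
(the equal forward/reverse turnover convention of the implemented rate law)
and `k_r = k_f/K_eq`.  Sampling is otherwise independent across parameters —
no cross-reaction correlations are imposed — and is a pure function of the
seed (draws happen in sorted parameter-name order).  Transporter turnover and
every catalyst's starting concentration are shared across the reactions that
catalyst serves, which is what makes the independent-parameter census 184.

## Numerical integration

The ODE right-hand side is assembled once per variant into vectorised index
arrays plus a stoichiometry matrix; cross-compartment rows carry the
donor/acceptor volume ratio so transport conserves amount exactly, and
carrier fluxes on the donor basis additionally scale with the
transporter-home/donor volume ratio (the same carrier pool produces a
1000-fold smaller concentration change in the 1000-fold larger medium).
Integration uses LSODA with rtol 10⁻⁸ and atol 10⁻³⁰ mM by default (the atol
must resolve the 10⁻²⁸ mM floor); ensemble-throughput paths relax rtol to
10⁻⁶, which moves report-time concentrations by well under 0.1%.  Stimulus
onset, release re-assignments and induction steps stop and restart the
integrator rather than making the right-hand side discontinuous.  A variant
whose integration fails is returned with a status flag and excluded from
summaries and scoring with a logged count, so pathological draws cannot abort
an ensemble.

## Scoring and Ψ

The point score is `ln N(ln c_exp; ln c_sim, σ)` with σ = 1 (the published
width of the scoring density is not recoverable from the source text; σ is
configurable and, being a monotone transform of the squared log-error, does
not affect variant ranking).  Simulated values are floored at 10⁻³⁰ mM before
the log; below-LOQ experimental points are excluded from scoring rather than
imputed.  Cumulative scores are plain sums; Ψ percentages count variants
passing −10 (point), −40 (metabolite cumulative) and −500 (total) with all
three thresholds configurable.  Scores are invariant to the concentration
unit provided experiment and simulation share it.

## Adaptation

The best-fitting decile (ties broken by variant index) defines the empirical
distribution tested against each prior by a two-sided one-sample KS test in
ln space, at level α/n with α = 0.01 and n the number of independently
sampled parameters (184 for the full fixture, recomputed for reduced
networks).  On rejection the adjusted prior is the maximum-likelihood
log-normal refit of the selected values, floored at σ_min — the concrete
mechanism chosen here for "favouring enriched values"; the binned enrichment
profile (20 log-space bins over the prior's central 99.9% mass, pseudocount
0.5) is retained for inspection either way.  Dependent parameters are not
testable; only sampled ones enter the family.

## Synthetic data and what passing tests show

The pseudo-experiment generator samples the model at 0.5/1/3/6 h for a chosen
observable panel (defaults mirror a keratinocyte-like six-eicosanoid panel
and a fibroblast-like three-eicosanoid panel) and applies multiplicative
log-normal noise, σ = 0.3 by default (±35% at one σ, a plausible lipidomics
replicate spread).  It emulates the *statistical* structure scoring assumes —
sparse time points, positive concentrations, below-LOQ flags, cell-type
differences as shifted abundance distributions — and deliberately not the
measurement chain (extraction recovery, internal-standard normalisation,
matrix effects).  Green tests therefore demonstrate the pipeline's internal
correctness and its behaviour under known truths, not agreement with any real
cell line.

The recovery harness runs the whole loop at a scaled-down ensemble size of
300 variants (throughput on one CPU; a production run would use 1000).  Its
report answers two questions separately: where the top-decile refit of the
target prior landed, and whether the Bonferroni-corrected KS test flagged the
shift.  Recovery of an absolute enzyme concentration from product levels is
partial by construction: free AA is consumption-limited by the sampled COX
pool, so every LOX product carries the COX-abundance draw as a confounder the
observable panel cannot resolve, and the refit median typically lands
55–110% of the way to a +2 ln-unit truth depending on the draw.  At the
scaled-down top-30 selection the corrected KS threshold (D ≈ 0.42) exceeds
the distance such enrichment produces (D ≈ 0.25–0.40), so significance is
expected only at larger ensembles — the same test at the top-100 of a
1000-variant ensemble crosses the threshold comfortably.

## Known limitations

* The catalogue is a reconstruction: row-level stoichiometry and per-reaction
  prior locations are field-plausible defaults, not transcribed measurements.
* CYP450 metabolism, esterified-HETE hydrolysis, cysteinyl leukotrienes,
  feedback regulation and transcription/translation dynamics are out of scope.
* Unit conversion from assay output (pg per 10⁶ cells) to mM requires a
  user-supplied factor; the package refuses to guess one.
* Induction is piecewise-constant; smoothed induction would need an explicit
  time constant.
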