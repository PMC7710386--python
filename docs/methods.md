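# Methods

## Reaction–diffusion model

The simulator integrates a linear activator–inhibitor pair with saturating
synthesis. The core factor u is produced at `Au − Bv + C` (self-activation,
inhibition by v, basal offset C) and decays at `Du`; the inhibitor v is
produced at `Eu − F` and decays at `Gv`. Both synthesis terms are clamped to
`[0, synUmax]` and `[0, synVmax]` *before* the decay terms are subtracted; the
clamps are what keep an otherwise linear system bounded and let it hold
stable Turing patterns. With the default constants the interior steady state
has `tr J = −0.01 < 0` and `det J = 0.005 > 0`, so it is stable in a
well-mixed system and destabilized by diffusion once `Dᵥ ≫ Dᵤ` (the suite
checks both directions of this Turing property). Note the inhibition sign:
with `+Bv` in the u-kinetics the steady state would be a saddle and no
Turing regime would exist at these constants, so the cross term is
implemented as inhibition of u by v.

Integration is explicit Euler with `dt = 0.01` and 2000 steps by default; a
guard aborts with the step index on non-finite values. Initial conditions
are the stable rest state of the (mean) kinetics plus uniform noise of
amplitude 0.1 drawn from the run's seed. When several clipped fixed points
are stable the interior one is preferred for initialization, since that is
the state whose instability seeds the pattern; placement of the noise
around a fixed point (rather than around zero) was a free choice and is
configurable through the amplitude only.

### Meshes and Laplacians

Grids use the 5-point stencil (optionally periodic). Spheres are Fibonacci
lattices; fused blobs sample the implicit surface
`(r/d₁)² + (r/d₂)² = 1` of two overlapping balls (single connected surface
for separation `< 2√2·r`), with seeding on both spheres, Newton projection
onto the isosurface and a short local-repulsion relaxation. Point clouds are
rescaled to unit mean nearest-neighbour spacing so diffusion lengths match
grid runs, and carry a symmetrized k-nearest-neighbour (k = 6) graph
Laplacian with inverse-distance weights and zero row sums. A single scale
constant, calibrated once on a reference sphere against the analytic l = 1
Laplace–Beltrami eigenvalue `2/ρ²` (Rayleigh quotient on the coordinate
function z), transfers to all point-cloud meshes built the same way; the
suite checks agreement within 10% across sphere sizes. The blend axis of a
metaball is each cell's normalized projection onto the line joining the ball
centres; hybrid parameter fields interpolate two endpoint parameter sets
along that axis (linear by default, renormalized sigmoid optional), with the
extreme cells carrying the endpoints exactly.

### Calibrated endpoints

The coefficient distinguishing the two "pure species" is the basal synthesis
C — the only kinetic coefficient without a fixed default. A sweep on a
64×64 periodic grid classifies each C by the pigmented-area fraction of the
binarized steady state; the stored endpoints are `C = −0.04` (dark spots,
pigmented fraction ≈ 0.06) and `C = +0.32` (light spots, ≈ 0.88), with
labyrinths near the midpoint. `calibrate_c_endpoints` recomputes the sweep
and the selections for any other kinetics.

## Pattern quantification

Patterns are summarized by lightness (unpigmented fraction) and
`PCS = 1 − Σ wᵢQᵢ`, the area-weighted mean isoperimetric quotient over all
closed contours. Contours are traced at sub-pixel resolution (marching
squares) and measured as polygons — shoelace area, polygonal perimeter — so
the quotient of a rasterized disk stays near 1 (the suite bounds the
digitization bias at ±0.05 for radius 50 px). Binary rasters are lightly
Gaussian-smoothed (σ = 1 px, configurable) before tracing to remove
pixel-edge staircasing. Every closed contour — hole boundaries included — is
an independent element, which treats dark-on-light and light-on-dark
patterns symmetrically. A minimum-area filter (9 px² for rasters) suppresses
specks; simulated concentration fields are instead spline-upsampled 4× and
contoured at the binarization threshold directly with a 1 px² filter, since
a smooth field has no specks and its pattern wavelength spans only a few
cells. The area weighting makes the score track the dominant elements, so
one large simple element among many tiny complex ones scores close to the
large element's `1 − Q`.

## Collocation statistics

Species-level annotations (11 binary motifs) collapse to genus level by OR;
pairwise screens use genera with ≥ 2 species, triple screens (anchor pair
treated as a single compound motif) genera with ≥ 3 species. The six
measures follow the standard corpus-linguistics/ecology definitions; the t
and z scores use square-root denominators (`√O₁₁`, `√E₁₁`), with a
`radicals=False` switch for the plain-denominator variant. Log-likelihood
terms with `Oᵢⱼ = 0` contribute zero; natural logarithms throughout.

A property worth knowing: under a species-level null in which every motif is
iid across species, *genus-level* presence is `1 − (1 − p)ⁿ`, increasing in
genus size n — so when genus sizes vary, every motif pair is positively
associated at genus level with no mechanistic dependence (Z of roughly +4
at study-like scale). This size confounding is inherent to genus-level
collocation, not an artifact of the implementation; the synthetic generator
therefore offers `fixed_species_per_genus` for strict null calibrations
(where |Z| < 3 holds), and effect detection should always be read against
the heterogeneous-null baseline rather than zero.

## Introgression statistics

The ABBA–BABA test uses population allele frequencies
(`p_ABBA = (1−p₁)p₂p₃(1−p₄)`, `p_BABA = p₁(1−p₂)p₃(1−p₄)`) rather than
single sampled reads — deterministic and testable at desk scale. Standard
errors come from a delete-one-block jackknife over contiguous blocks
(blocks are an input column; a helper assigns them from positions, emulating
5-Mb windows). `D_min` evaluates the three trio topologies by column
permutation and reports the minimum |D|; its p-value is the two-sided normal
tail of the jackknife z belonging to the topology attaining the minimum —
one defensible rule among several, flagged in the output rather than
presented as canonical. Sites with missing frequencies are dropped and
counted. Holm–Bonferroni is the plain step-down procedure (cross-checked
against statsmodels in the suite). Interclass heterozygosity is the fraction
of callable panel-diagnostic sites with dosage exactly 1, optionally with a
block-jackknife standard error.

## Correlated motif evolution

The trait is the genus-level portfolio of (Sp-D, Sp-L, Maze), coded as
states 000–111 (bit order as listed). Only single-motif flips have nonzero
rates, matching the transition structure of correlated-evolution models.
Model classes differ in the context a rate sees: independent (6 rates),
dependent (3 motifs × gain/loss × 4 contexts = 24), and ind-X variants
(10 rates) in which one motif is context-free while the other two depend on
each other. Likelihoods use Felsenstein pruning with eigen-decomposed
propagators (numba-compiled; scipy `expm` as the fallback and as the
independent oracle in tests, which match to 1e-10 against brute-force
enumeration on small trees). Trees are rescaled to unit height before
fitting, so rates are per tree depth. Fitting maximizes the
replicate-averaged log-likelihood over log-rates (L-BFGS-B, bounds
1e-4–200, multi-start, optional warm start from a simpler model's fit
lifted into the richer parameterization). Replicate genus trees — one
random species kept per genus, renamed to the genus — contribute by
averaging log-likelihoods; per-replicate fitting is available by calling
`fit_model` per tree.

Model comparison defaults to the AIC difference expressed on the
2·Δlog-likelihood scale (so the 18 extra dependent-model parameters must
earn their keep), with evidence read at the 2/5/10 thresholds; an LRT route
and a stepping-stone marginal-likelihood route (short random-walk MH over
power posteriors, exponential rate priors) are provided. The stepping-stone
sampler is validated against brute-force prior Monte Carlo on small trees
and is intended for toy-scale checks, not production Bayes factors.

Parameter-recovery experiments in the suite condition the fits on the
generating root state: with a uniform root prior the gain/loss direction of
a trait is only weakly identified on a single tree, because an inverted
history (trait ancestral, never gained) can explain the same tips. The root
prior remains configurable (uniform default, stationary or fixed).

## Synthetic data

The generators define the study conditions for every test: annotation
tables with 2000 genera, geometric genus sizes of mean 4.5 species
(matching an 18k-species / 4k-genus survey), an ~5% labyrinthine-motif
prevalence and plausible prevalences for the other ten motifs; the blending
dependency multiplies the per-species Maze probability in genera carrying
both spot motifs (hazard multiplier at genus level — it controls exactly
what the collocation screen measures, without simulating hybrid speciation).
Genotypes use per-site ancestral frequencies U(0.05, 0.95) drifted per
population under Balding–Nichols (F = 0.1), an outgroup fixed ancestral,
and admixture as the frequency mixture `p₂' = (1−f)p₂ + f p₃`; diagnostic
sites are fixed panel differences with F1 dosage 1 everywhere and F2
dosages {0,1,2} at {¼,½,¼}. Trees are birth–death simulations conditioned
on the tip count. What the generators do *not* emulate: linkage and
coalescent noise (blocks are iid sites), annotation error, taxonomic
non-independence beyond the genus level, and image noise — so passing tests
demonstrate correctness of the statistics and the qualitative phenomena,
not robustness to every property of field data.

## Problem sizes and numerical choices

The default experiment sizes — 64×192 blending grids over 20 seeds, 2000
steps, 2000-genus tables, 5k–50k-site frequency matrices over 25–50 blocks,
200-tip recovery studies over 20 seeds — were chosen to give stable pass/fail
margins at desk scale. Degenerate inputs raise rather than guess: flat
fields under auto-thresholding, all-or-nothing patterns in PCS, empty
contingency margins, zero informative sites, single-block jackknives and
missing tip states are all explicit errors. Ties in the blending criterion
use ≥ for the complexity comparison (the centre may equal an endpoint's
score); the collocation t score reports 0 with a flag when `O₁₁ = 0`.

## Interfaces

The package is a library: the importable API plus the narrative scripts in
`examples/` are the intended interface, and file I/O (annotation TSV/CSV,
frequency TSV, newick trees, PNG export of grid runs) lives behind ordinary
functions rather than a command-line layer.

## Known limitations

Sphere and metaball runs are quantified only after unrolling/projection or
on grid surrogates; quantitative PCS comparisons are defined on 2D rasters.
The 8-state fitter targets desk-scale trees (hundreds of tips × hundreds of
replicates is feasible; whole-phylogeny screens are scripts, not test
surface). The stepping-stone sampler trades rigor for speed. D statistics
assume the frequency model; read-sampling noise and mapping bias of
sequence-based pipelines are out of scope.
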