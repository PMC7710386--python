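"""Correlated evolution of Sp-D, Sp-L and Maze on a phylogeny.

Simulates the 8-state motif chain on a 200-tip birth-death tree under a
dependent model in which the Maze gain rate is high only when both spot
motifs are present (rate d) and the Maze loss rate is low in that context
(rate h), then fits the independent and dependent models by maximum
likelihood, compares them, and reports the recovered Maze gain/loss rates
a-h by spot-motif context.
"""

from patternblend.synth import gen_trait_tree
from patternblend.traitevo import (
    RateModel,
    compare_models,
    fit_model,
    maze_rate_summary,
    scale_to_unit_height,
    simulate_ctmc,
)

base = RateModel.create("dependent")
rates = []
for name in base.names:
    motif, rest = name.split(":", 1)
    if motif == "Maze":
        both = "Sp-D=1" in rest and "Sp-L=1" in rest
        rates.append((8.0 if both else 0.1) if rest.startswith("gain") else (0.1 if both else 2.0))
    else:
        rates.append(3.0 if rest.startswith("gain") else 0.5)
truth = RateModel.create("dependent", rates)

tree, _ = gen_trait_tree(200, seed=1)
tree = scale_to_unit_height(tree)
tips = simulate_ctmc(tree, truth, root_state=0, seed=1)

fit_ind = fit_model(tree, tips, "independent", rescale=False, root=0, n_starts=1)
fit_dep = fit_model(
    tree, tips, "dependent", rescale=False, root=0, n_starts=1, warm_start=fit_ind.model
)
comparison = compare_models(fit_ind, fit_dep, method="aic")

print(f"log L (independent, 6 rates): {fit_ind.log_likelihood:.2f}")
print(f"log L (dependent, 24 rates) : {fit_dep.log_likelihood:.2f}")
print(f"penalized support for dependence: {comparison.value:.1f} "
      f"({comparison.evidence}; winner: {comparison.winner})")

summary = maze_rate_summary(fit_dep)
print("\nMaze gain rates by spot context (true a-c = 0.1, d = 8):")
print("  a (no spots) = {a:.2f}   b (Sp-D only) = {b:.2f}".format(**summary.gains))
print("  c (Sp-L only) = {c:.2f}  d (both)      = {d:.2f}".format(**summary.gains))
print("Maze loss rates (true e-g = 2, h = 0.1):")
print("  e = {e:.2f}  f = {f:.2f}  g = {g:.2f}  h = {h:.2f}".format(**summary.losses))

print(
    "\nRates are per unit tree height. Recovering d >> a, b, c (and a low h)"
    "\nis the phylogenetic signature of pattern blending: labyrinths arise"
    "\npreferentially in lineages where both spot motifs coexist."
)
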