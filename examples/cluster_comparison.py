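"""Recovering an injected verb-encyclopedic connectivity effect.

Injects a verb-encyclopedic pool-reuse effect into the generator
(tripling the reuse exponent, with the matched acquisition-order bias),
normalizes degree in the encyclopedic networks, and runs the
cluster-based permutation test comparing noun vs verb normalized degree
across 20-word vocabulary-size bins.
"""

from lexnets import (
    build_null_histograms,
    compare_pos_within_type,
    generate_lexicon,
    inject_effect,
    normalize_children,
)
from lexnets.clusters import direction_label
from lexnets.simulate import NormsConfig, PopulationConfig, generate_population

multipliers = {("verb", "encyclopedic"): 3.0}
lexicon = generate_lexicon(inject_effect(NormsConfig(), multipliers), seed=42)
children = generate_population(
    lexicon, PopulationConfig(n_children=500, effect_multipliers=multipliers),
    seed=43,
)
hists, _ = build_null_histograms(lexicon, children, ["encyclopedic"],
                                 reps=200, seed=44)
records = normalize_children(children, lexicon, hists)
for pos, group in records.groupby("pos"):
    print(f"mean encyclopedic normalized degree, {pos}s: "
          f"{group.normalized_degree.mean():5.1f}")

result = compare_pos_within_type(records, "encyclopedic", n_perm=1000, seed=45)
print(f"\nclusters (t threshold {result.threshold}, "
      f"{result.n_perm} permutations):")
for cluster in result.clusters:
    print(f"  {cluster.start}-{cluster.end} words  "
          f"{direction_label(result, cluster)}  "
          f"cluster t = {cluster.mass:7.1f}  p = {cluster.p:.4g}")
# A V > N cluster spanning most of the size range: verbs' encyclopedic
# connectivity exceeds the random-network baseline by more than nouns'
# does, and the permutation null says that is no binning accident.
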