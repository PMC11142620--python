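"""One child's semantic networks and weighted degree.

Simulates a child vocabulary, builds the shared-feature network under
each feature-type restriction, and reports the mean weighted degree of
the child's nouns and verbs in each network.
"""

from lexnets import build_network, generate_lexicon, mean_degree_by_pos
from lexnets.norms import FEATURE_TYPES
from lexnets.simulate import PopulationConfig, generate_population

lexicon = generate_lexicon(seed=1)
child = generate_population(lexicon, PopulationConfig(n_children=20), seed=2)[0]
print(f"child {child.child_id}: age {child.age} months, "
      f"{child.n_nouns} nouns + {child.n_verbs} verbs")

for restriction in FEATURE_TYPES + ("all",):
    graph = build_network(child, lexicon, restriction)
    summary = mean_degree_by_pos(graph, restriction, child.child_id)
    n_edges = graph.number_of_edges()
    print(f"  {restriction:<13} {n_edges:5d} edges   "
          f"mean weighted degree: nouns {summary.noun_mean:7.2f}  "
          f"verbs {summary.verb_mean:7.2f}")
# Weighted degree sums the shared-feature counts on a word's edges: high
# values mean the word is semantically close to many produced words.
# Raw values scale with vocabulary size and composition, which is why the
# normalization in examples/normalized_degree.py exists.
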