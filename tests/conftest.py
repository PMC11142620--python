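import numpy as np
import pytest

from lexnets.networks import ChildVocabulary
from lexnets.simulate import generate_lexicon


@pytest.fixture(scope="session")
def default_lexicon():
    """One default-configuration synthetic lexicon (359 nouns, 103 verbs)."""
    return generate_lexicon(seed=11)


def make_uniform_children(lexicon, n_children, rng, min_nouns=5, min_verbs=1):
    """Children whose vocabularies are uniform random draws from the lexicon.

    Under this generative model a child's observed mean weighted degree
    is itself one draw from the normalization null, so normalized degree
    should be calibrated (approximately Uniform(0, 100)).
    """
    nouns = sorted(lexicon.keys("noun"))
    verbs = sorted(lexicon.keys("verb"))
    children = []
    for i in range(n_children):
        nn = int(rng.integers(min_nouns, len(nouns) + 1))
        nv = int(rng.integers(min_verbs, len(verbs) + 1))
        words = [nouns[j] for j in rng.permutation(len(nouns))[:nn]]
        words += [verbs[j] for j in rng.permutation(len(verbs))[:nv]]
        children.append(
            ChildVocabulary(child_id=f"c{i:04d}", age=24, words=frozenset(words))
        )
    return children


@pytest.fixture(scope="session")
def null_calibration(default_lexicon):
    """Full normalization pipeline run on 500 uniform-draw children.

    Shared by the calibration and oracle-equivalence checks; returns the
    children, the fitted histograms, the sampled space, the seed used
    for the null simulations, and the normalized-degree records.
    """
    from lexnets.normalize import build_null_histograms, normalize_children

    rng = np.random.default_rng(123)
    children = make_uniform_children(default_lexicon, 500, rng)
    seed = 7
    hists, space = build_null_histograms(
        default_lexicon, children, restrictions=["all"],
        reps=200, n_bins=64, seed=seed,
    )
    records = normalize_children(children, default_lexicon, hists)
    return {
        "children": children,
        "hists": hists,
        "space": space,
        "seed": seed,
        "reps": 200,
        "records": records,
    }
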