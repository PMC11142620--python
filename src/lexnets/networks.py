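"""Per-child semantic networks and weighted degree.

A child's semantic network has the words the child produces as nodes and
an undirected edge between two words whenever they share at least one
semantic feature; the edge weight is the number of shared features.
Restricting the feature set to one type (perceptual, functional,
taxonomic or encyclopedic) yields four additional networks per child.
The statistic of interest is the *weighted degree* of a word — the sum
of the weights of its incident edges — averaged separately over the
nouns and the verbs in the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .norms import FEATURE_TYPES, POS_VALUES, Lexicon, LexiconFormatError

logger = logging.getLogger(__name__)

#: Valid network restrictions: one feature type, or all features.
RESTRICTIONS: tuple[str, ...] = FEATURE_TYPES + ("all",)

VOCAB_COLUMNS: tuple[str, ...] = ("child_id", "age", "word", "pos", "produced")


@dataclass(frozen=True)
class ChildVocabulary:
    """One checklist administration: the words a child produces."""

    child_id: str
    age: int
    words: frozenset[tuple[str, str]]
    percentile: float | None = None

    @property
    def n_nouns(self) -> int:
        return sum(1 for _, pos in self.words if pos == "noun")

    @property
    def n_verbs(self) -> int:
        return sum(1 for _, pos in self.words if pos == "verb")

    @property
    def vocab_size(self) -> int:
        return len(self.words)

    @property
    def size_point(self) -> tuple[int, int]:
        return (self.n_nouns, self.n_verbs)

    def restrict_to(self, lexicon: Lexicon) -> "ChildVocabulary":
        """Drop produced words absent from the lexicon (with a warning)."""
        kept = frozenset(w for w in self.words if w in lexicon)
        dropped = len(self.words) - len(kept)
        if dropped:
            logger.warning(
                "child %s: dropped %d word(s) missing from the lexicon",
                self.child_id, dropped,
            )
        return ChildVocabulary(self.child_id, self.age, kept, self.percentile)


def read_vocabulary(
    path: str | Path,
    lexicon: Lexicon | None = None,
    percentiles: Mapping[str, float] | None = None,
) -> list[ChildVocabulary]:
    """Read item-level checklist records.

    Expected columns: ``child_id, age, word, pos, produced`` with
    ``produced`` in {0, 1}; one row per child x word.  If a lexicon is
    given, produced words missing from it are dropped with a warning.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        sep = "\t" if "\t" in fh.readline() else ","
    table = pd.read_csv(path, sep=sep, dtype={"child_id": str, "word": str, "pos": str})
    missing = [c for c in VOCAB_COLUMNS if c not in table.columns]
    if missing:
        raise LexiconFormatError(f"{path}: missing column(s) {missing}")
    children = []
    for child_id, group in table.groupby("child_id", sort=True):
        produced = group[group["produced"].astype(int) == 1]
        words = frozenset(zip(produced["word"], produced["pos"]))
        vocab = ChildVocabulary(
            child_id=str(child_id),
            age=int(group["age"].iloc[0]),
            words=words,
            percentile=None if percentiles is None else percentiles.get(str(child_id)),
        )
        if lexicon is not None:
            vocab = vocab.restrict_to(lexicon)
        children.append(vocab)
    return children


def write_vocabulary(
    children: Sequence[ChildVocabulary],
    lexicon: Lexicon,
    path: str | Path,
    sep: str = "\t",
) -> None:
    """Write one row per child x lexicon word with a produced flag."""
    keys = sorted(lexicon.keys())
    rows = []
    for child in sorted(children, key=lambda c: c.child_id):
        for form, pos in keys:
            rows.append(
                (child.child_id, child.age, form, pos,
                 int((form, pos) in child.words))
            )
    pd.DataFrame(rows, columns=list(VOCAB_COLUMNS)).to_csv(path, sep=sep, index=False)


def write_percentiles(
    children: Sequence[ChildVocabulary], path: str | Path, sep: str = "\t"
) -> None:
    rows = [(c.child_id, c.percentile) for c in sorted(children, key=lambda c: c.child_id)]
    pd.DataFrame(rows, columns=["child_id", "percentile"]).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# Network construction and degree
# ---------------------------------------------------------------------------


def _check_restriction(restriction: str) -> None:
    if restriction not in RESTRICTIONS:
        raise ValueError(
            f"restriction must be one of {RESTRICTIONS}, got {restriction!r}"
        )


def build_network(
    vocab: ChildVocabulary | Iterable[tuple[str, str]],
    lexicon: Lexicon,
    restriction: str = "all",
) -> nx.Graph:
    """Build one feature-type-restricted semantic network.

    Nodes are ``(form, pos)`` keys; isolated words stay in the graph.
    Two words are joined iff they share >= 1 feature of the restricted
    type, with the edge weight equal to the number of such shared
    features ("all" counts shared features of every type).
    """
    _check_restriction(restriction)
    words = vocab.words if isinstance(vocab, ChildVocabulary) else frozenset(vocab)
    present = [w for w in words if w in lexicon]
    if len(present) < len(words):
        logger.warning("dropped %d word(s) missing from the lexicon",
                       len(words) - len(present))
    graph = nx.Graph()
    graph.add_nodes_from(sorted(present))
    feature_index: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for key in sorted(present):
        for label, ftype in lexicon[key].features:
            if restriction != "all" and ftype != restriction:
                continue
            feature_index.setdefault((label, ftype), []).append(key)
    for sharers in feature_index.values():
        for u, v in combinations(sharers, 2):
            if graph.has_edge(u, v):
                graph[u][v]["weight"] += 1
            else:
                graph.add_edge(u, v, weight=1)
    return graph


def weighted_degree(graph: nx.Graph, word) -> float:
    """Sum of incident edge weights; 0 for isolated nodes."""
    if word not in graph:
        raise KeyError(word)
    return float(graph.degree(word, weight="weight"))


@dataclass(frozen=True)
class DegreeSummary:
    """Mean weighted degree over noun and verb nodes of one network.

    A mean is None (and the matching flag True) when the network has no
    node of that part of speech.
    """

    child_id: str | None
    restriction: str
    noun_mean: float | None
    verb_mean: float | None
    n_nouns: int
    n_verbs: int

    @property
    def noun_undefined(self) -> bool:
        return self.noun_mean is None

    @property
    def verb_undefined(self) -> bool:
        return self.verb_mean is None


def mean_degree_by_pos(
    graph: nx.Graph,
    restriction: str = "all",
    child_id: str | None = None,
) -> DegreeSummary:
    """Arithmetic mean weighted degree per part of speech.

    Nodes must be ``(form, pos)`` keys (as produced by
    :func:`build_network`); isolates contribute degree 0.
    """
    by_pos: dict[str, list[float]] = {"noun": [], "verb": []}
    for node in graph.nodes:
        _, pos = node
        by_pos[pos].append(float(graph.degree(node, weight="weight")))
    means = {
        pos: (float(np.mean(vals)) if vals else None) for pos, vals in by_pos.items()
    }
    return DegreeSummary(
        child_id=child_id,
        restriction=restriction,
        noun_mean=means["noun"],
        verb_mean=means["verb"],
        n_nouns=len(by_pos["noun"]),
        n_verbs=len(by_pos["verb"]),
    )


def write_edge_list(graph: nx.Graph, path: str | Path, sep: str = "\t") -> None:
    rows = [
        ("|".join(u), "|".join(v), d["weight"])
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["word_a", "word_b", "weight"]).to_csv(
        path, sep=sep, index=False
    )


# ---------------------------------------------------------------------------
# Fast shared-feature arithmetic used by the null-model simulations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SharedFeatureMatrix:
    """Pairwise shared-feature counts for a whole lexicon.

    ``matrix[i, j]`` is the number of features of the restricted type
    shared by words i and j (diagonal zero).  ``keys`` maps row index to
    the (form, pos) key; ``noun_idx``/``verb_idx`` are index arrays.
    """

    restriction: str
    keys: tuple[tuple[str, str], ...]
    matrix: np.ndarray
    noun_idx: np.ndarray
    verb_idx: np.ndarray

    @property
    def index(self) -> dict[tuple[str, str], int]:
        return {k: i for i, k in enumerate(self.keys)}


def shared_feature_matrix(lexicon: Lexicon, restriction: str = "all") -> SharedFeatureMatrix:
    """Compute the full word x word shared-feature count matrix."""
    _check_restriction(restriction)
    keys = tuple(sorted(lexicon.keys()))
    feat_ids: dict[tuple[str, str], int] = {}
    rows, cols = [], []
    for i, key in enumerate(keys):
        for label, ftype in lexicon[key].features:
            if restriction != "all" and ftype != restriction:
                continue
            fid = feat_ids.setdefault((label, ftype), len(feat_ids))
            rows.append(i)
            cols.append(fid)
    n, m = len(keys), max(len(feat_ids), 1)
    incidence = np.zeros((n, m), dtype=np.float64)
    if rows:
        incidence[rows, cols] = 1.0
    matrix = incidence @ incidence.T
    np.fill_diagonal(matrix, 0.0)
    noun_idx = np.array([i for i, (_, pos) in enumerate(keys) if pos == "noun"])
    verb_idx = np.array([i for i, (_, pos) in enumerate(keys) if pos == "verb"])
    return SharedFeatureMatrix(
        restriction=restriction,
        keys=keys,
        matrix=matrix,
        noun_idx=noun_idx,
        verb_idx=verb_idx,
    )


def mean_degrees_from_matrix(
    sfm: SharedFeatureMatrix, words: Iterable[tuple[str, str]]
) -> tuple[float | None, float | None]:
    """Per-POS mean weighted degree of the subnetwork on ``words``.

    Equivalent to building the restricted network and averaging weighted
    degree per part of speech, but via matrix arithmetic.
    """
    index = sfm.index
    sel = np.array(sorted(index[w] for w in words if w in index), dtype=int)
    if sel.size == 0:
        return (None, None)
    sub = sfm.matrix[np.ix_(sel, sel)]
    degrees = sub.sum(axis=1)
    pos = np.array([sfm.keys[i][1] for i in sel])
    noun_deg = degrees[pos == "noun"]
    verb_deg = degrees[pos == "verb"]
    return (
        float(noun_deg.mean()) if noun_deg.size else None,
        float(verb_deg.mean()) if verb_deg.size else None,
    )
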