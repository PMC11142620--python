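"""Synthetic feature norms and child vocabulary populations.

The generator emulates the statistical structure the analyses assume:

* a lexicon of early-learned nouns and verbs whose per-word feature
  counts and feature-type proportions match the published composition of
  checklist words (nouns lean perceptual/functional, verbs lean
  encyclopedic), with features drawn from shared per-type pools under a
  Zipf-like reuse law so that words share features and networks have
  edges;
* a population of children whose produced-word sets follow a logistic
  acquisition model (older and higher-ability children know more words;
  verbs carry a difficulty offset so nouns are learned first), with
  vocabulary-size percentiles computed within age-month groups and a
  late-talker exclusion filter.

An *effect injection* mechanism scales the pool-reuse exponent of chosen
(part of speech, feature type) cells — concentrating those words'
features on the most popular pool items and thereby inflating their
shared-feature density — and, in the population model, advances the
acquisition of words that are well connected in the injected cells.
This creates vocabularies whose normalized degree departs from the
random-draw baseline in a controlled direction, enabling end-to-end
recovery tests of the verb-encyclopedic pattern.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from .networks import ChildVocabulary, shared_feature_matrix
from .norms import FEATURE_TYPES, POS_VALUES, Lexicon, LexiconEntry


class ConfigError(ValueError):
    """A generator configuration is internally inconsistent or infeasible."""


Cell = tuple[str, str]  # (pos, feature_type)

#: Feature-type proportion profiles for nouns and verbs (published cell means).
DEFAULT_PROFILES: dict[str, dict[str, float]] = {
    "noun": {"encyclopedic": 0.27, "functional": 0.20, "perceptual": 0.41,
             "taxonomic": 0.12},
    "verb": {"encyclopedic": 0.55, "functional": 0.03, "perceptual": 0.28,
             "taxonomic": 0.14},
}

#: Per-type shared feature pool sizes.  Chosen so that, with the default
#: Zipf reuse exponent of 1, typical word pairs share 0-2 features of a
#: type — dense enough for connected networks, sparse enough for isolates.
DEFAULT_POOL_SIZES: dict[str, int] = {
    "encyclopedic": 400,
    "functional": 200,
    "perceptual": 400,
    "taxonomic": 120,
}


@dataclass(frozen=True)
class NormsConfig:
    """Configuration for :func:`generate_lexicon`.

    ``reuse_exponents`` maps (pos, feature_type) to the Zipf exponent s
    used when that part of speech draws features of that type: selection
    probability of pool rank r is proportional to r**-s.  Larger s
    concentrates draws on top-ranked features and raises shared-feature
    density for that cell.
    """

    n_nouns: int = 359
    n_verbs: int = 103
    type_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {p: dict(v) for p, v in DEFAULT_PROFILES.items()}
    )
    total_mean: Mapping[str, float] = field(
        default_factory=lambda: {"noun": 13.15, "verb": 12.41}
    )
    total_sd: Mapping[str, float] = field(
        default_factory=lambda: {"noun": 3.42, "verb": 3.97}
    )
    total_min: int = 3
    pool_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_POOL_SIZES)
    )
    reuse_exponents: Mapping[Cell, float] = field(default_factory=dict)

    def exponent(self, pos: str, ftype: str) -> float:
        return float(self.reuse_exponents.get((pos, ftype), 1.0))

    def validate(self) -> None:
        if self.n_nouns < 0 or self.n_verbs < 0:
            raise ConfigError("word counts must be non-negative")
        if self.total_min < 1:
            raise ConfigError("total_min must be >= 1")
        for pos in POS_VALUES:
            profile = self.type_profiles[pos]
            total = sum(profile.get(t, 0.0) for t in FEATURE_TYPES)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{pos} profile must sum to 1, got {total}")
        for ftype in FEATURE_TYPES:
            if self.pool_sizes[ftype] < 1:
                raise ConfigError(f"{ftype} pool must have >= 1 feature")
        for cell, s in self.reuse_exponents.items():
            if s < 0:
                raise ConfigError(f"reuse exponent for {cell} must be >= 0")


def inject_effect(cfg: NormsConfig, multipliers: Mapping[Cell, float]) -> NormsConfig:
    """Scale the pool-reuse exponent of selected (pos, feature type) cells.

    A multiplier of 1 leaves the configuration unchanged; larger values
    concentrate that cell's feature draws on popular pool items, raising
    its expected shared-feature density; 0 makes draws uniform over the
    pool so sharing drops to chance pool collisions.
    """
    for cell, m in multipliers.items():
        if m < 0:
            raise ConfigError(f"multiplier for {cell} must be >= 0")
        pos, ftype = cell
        if pos not in POS_VALUES or ftype not in FEATURE_TYPES:
            raise ConfigError(f"unknown cell {cell!r}")
    exponents = dict(cfg.reuse_exponents)
    for cell, m in multipliers.items():
        base = cfg.exponent(*cell)
        exponents[cell] = base * float(m)
    return dataclasses.replace(cfg, reuse_exponents=exponents)


def _zipf_weights(pool_size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, pool_size + 1, dtype=np.float64)
    weights = ranks ** (-exponent)
    return weights / weights.sum()


def generate_lexicon(cfg: NormsConfig | None = None, seed: int = 0) -> Lexicon:
    """Draw a synthetic feature-norm lexicon.

    Per word: total feature count ~ rounded normal truncated at
    ``total_min``; type counts ~ multinomial over the POS profile;
    feature labels drawn without replacement from the type's shared pool
    with Zipf-like reuse.  Deterministic under ``seed``.
    """
    cfg = cfg or NormsConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    weights = {
        (pos, ftype): _zipf_weights(cfg.pool_sizes[ftype], cfg.exponent(pos, ftype))
        for pos in POS_VALUES
        for ftype in FEATURE_TYPES
    }
    entries = []
    for pos, n_words in (("noun", cfg.n_nouns), ("verb", cfg.n_verbs)):
        profile = np.array([cfg.type_profiles[pos][t] for t in FEATURE_TYPES])
        mean, sd = cfg.total_mean[pos], cfg.total_sd[pos]
        for i in range(n_words):
            total = int(round(rng.normal(mean, sd)))
            while total < cfg.total_min:
                total = int(round(rng.normal(mean, sd)))
            counts = rng.multinomial(total, profile)
            features = set()
            for ftype, count in zip(FEATURE_TYPES, counts):
                if count == 0:
                    continue
                pool = cfg.pool_sizes[ftype]
                if count > pool:
                    raise ConfigError(
                        f"word needs {count} distinct {ftype} features but the "
                        f"pool holds only {pool}"
                    )
                picks = rng.choice(pool, size=count, replace=False,
                                   p=weights[(pos, ftype)])
                features.update((f"{ftype[:3]}_{r:04d}", ftype) for r in picks)
            entries.append(
                LexiconEntry(form=f"{pos}{i + 1:03d}", pos=pos,
                             features=frozenset(features))
            )
    return Lexicon(entries)


# ---------------------------------------------------------------------------
# Child populations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration for :func:`generate_population`.

    The acquisition model produces word w for child c iff
    ``logistic(ability_c + age_slope * (age_c - age_center) -
    difficulty_w)`` exceeds a uniform draw.  Word difficulty is a normal
    score plus a verb offset (nouns earlier) minus a connectivity bonus
    for cells named in ``effect_multipliers`` (see module docstring).
    Percentiles are vocabulary-size ranks within age-month groups;
    children at or below ``percentile_threshold`` are removed.
    """

    n_children: int = 500
    age_min: int = 16
    age_max: int = 30
    age_center: float = 23.0
    age_slope: float = 0.35
    ability_sd: float = 1.0
    difficulty_sd: float = 2.0
    verb_offset: float = 1.25
    percentile_threshold: float = 20.0
    effect_multipliers: Mapping[Cell, float] = field(default_factory=dict)
    connectivity_bias: float = 0.75

    def validate(self) -> None:
        if self.n_children < 1:
            raise ConfigError("n_children must be >= 1")
        if not (0 <= self.percentile_threshold < 100):
            raise ConfigError("percentile_threshold must be in [0, 100)")
        if self.age_min > self.age_max:
            raise ConfigError("age_min must be <= age_max")
        for cell, m in self.effect_multipliers.items():
            if m <= 0:
                raise ConfigError(
                    f"population multiplier for {cell} must be > 0 "
                    "(acquisition bias uses log multiplier)"
                )


def _connectivity_bonus(lexicon: Lexicon, cfg: PopulationConfig,
                        keys: list[tuple[str, str]]) -> np.ndarray:
    """Acquisition-order bonus from injected-cell connectivity.

    For each (pos, type) cell with multiplier m != 1, words of that POS
    get ``connectivity_bias * log(m) * z`` added to their acquisition
    score, where z is the standardized within-POS weighted degree of the
    word in the type-restricted lexicon-wide network.  Multiplier 1 (or
    no multipliers) leaves the population model unchanged.
    """
    bonus = np.zeros(len(keys))
    active = {c: m for c, m in cfg.effect_multipliers.items() if m != 1.0}
    if not active or cfg.connectivity_bias == 0.0:
        return bonus
    key_pos = np.array([pos for _, pos in keys])
    for (pos, ftype), mult in sorted(active.items()):
        sfm = shared_feature_matrix(lexicon, ftype)
        same_pos = sfm.noun_idx if pos == "noun" else sfm.verb_idx
        if same_pos.size < 2:
            continue
        degree = sfm.matrix[np.ix_(same_pos, same_pos)].sum(axis=1)
        sd = degree.std()
        z = (degree - degree.mean()) / sd if sd > 0 else np.zeros_like(degree)
        zmap = {sfm.keys[i]: z[j] for j, i in enumerate(same_pos)}
        for w, key in enumerate(keys):
            if key_pos[w] == pos and key in zmap:
                bonus[w] += cfg.connectivity_bias * np.log(mult) * zmap[key]
    return bonus


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def age_group_percentiles(sizes: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Vocabulary-size percentile within each age-month group.

    Percentile = average rank within the child's age group x 100 / n,
    mirroring checklist norming practice.
    """
    percentiles = np.empty(len(sizes), dtype=float)
    for age in np.unique(ages):
        mask = ages == age
        ranks = rankdata(sizes[mask], method="average")
        percentiles[mask] = ranks * 100.0 / mask.sum()
    return percentiles


def generate_population(
    lexicon: Lexicon,
    cfg: PopulationConfig | None = None,
    seed: int = 0,
) -> list[ChildVocabulary]:
    """Draw a population of child vocabularies from the logistic model.

    Returns the children surviving the percentile filter (those with
    vocabulary-size percentile strictly above the threshold), each with
    the percentile attached.
    """
    cfg = cfg or PopulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    keys = sorted(lexicon.keys())
    n_words = len(keys)
    is_verb = np.array([pos == "verb" for _, pos in keys])

    difficulty = rng.normal(0.0, cfg.difficulty_sd, n_words)
    difficulty += cfg.verb_offset * is_verb
    difficulty -= _connectivity_bonus(lexicon, cfg, keys)

    ages = rng.integers(cfg.age_min, cfg.age_max + 1, cfg.n_children)
    ability = rng.normal(0.0, cfg.ability_sd, cfg.n_children)
    skill = ability + cfg.age_slope * (ages - cfg.age_center)

    prob = _sigmoid(skill[:, None] - difficulty[None, :])
    produced = rng.random((cfg.n_children, n_words)) < prob

    sizes = produced.sum(axis=1)
    percentiles = age_group_percentiles(sizes, ages)

    children = []
    for c in range(cfg.n_children):
        if percentiles[c] <= cfg.percentile_threshold:
            continue
        words = frozenset(keys[w] for w in np.flatnonzero(produced[c]))
        children.append(
            ChildVocabulary(
                child_id=f"child{c + 1:04d}",
                age=int(ages[c]),
                words=words,
                percentile=float(percentiles[c]),
            )
        )
    return children
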