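"""Feature norms: data model, I/O and composition analysis.

A *lexicon* is a set of early-learned words, each carrying semantic
features produced by adults and standardized into labels shared across
words.  Every feature belongs to one of four types:

- ``perceptual``: sensorimotor information (<is red>, <is greasy>)
- ``functional``: interaction/use information (<is eaten>)
- ``taxonomic``: category membership (<a food>, <a vehicle>)
- ``encyclopedic``: complex, social, affective or decontextualized
  knowledge that fits none of the above (<is fun>)

The composition analysis counts features of each type per word, converts
counts to within-word proportions (so words with many features do not
dominate), and compares the resulting profiles between nouns and verbs
with a two-way ANOVA (feature type x part of speech) plus
noun-minus-verb contrasts per feature type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FEATURE_TYPES: tuple[str, ...] = (
    "encyclopedic",
    "functional",
    "perceptual",
    "taxonomic",
)
POS_VALUES: tuple[str, ...] = ("noun", "verb")

#: Columns required in a feature-norm table.
NORM_COLUMNS: tuple[str, ...] = ("word", "pos", "feature", "feature_type")


class LexiconFormatError(ValueError):
    """The norms file is structurally malformed (e.g. missing columns)."""


class LexiconValidationError(ValueError):
    """The norms file has admissible structure but inadmissible content."""


class InsufficientDataError(ValueError):
    """A statistical routine was handed too few observations."""


def _normalize_label(label: str) -> str:
    return str(label).strip().casefold()


@dataclass(frozen=True)
class LexiconEntry:
    """One word with its typed feature set.

    ``features`` is a frozenset of ``(feature_label, feature_type)``
    pairs; labels are case-folded and whitespace-trimmed, and unique
    within the entry by construction.
    """

    form: str
    pos: str
    features: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.pos not in POS_VALUES:
            raise LexiconValidationError(
                f"{self.form!r}: pos must be one of {POS_VALUES}, got {self.pos!r}"
            )
        if not self.features:
            raise LexiconValidationError(f"{self.form!r} ({self.pos}) has no features")
        for label, ftype in self.features:
            if ftype not in FEATURE_TYPES:
                raise LexiconValidationError(
                    f"{self.form!r}: unknown feature_type {ftype!r}"
                )
        labels = [label for label, _ in self.features]
        if len(set(labels)) != len(labels):
            raise LexiconValidationError(
                f"{self.form!r}: a feature label appears under two types"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.form, self.pos)

    def type_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(FEATURE_TYPES, 0)
        for _, ftype in self.features:
            counts[ftype] += 1
        return counts

    @property
    def total_features(self) -> int:
        return len(self.features)


class Lexicon:
    """A collection of :class:`LexiconEntry`, unique by (form, pos)."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self._entries: dict[tuple[str, str], LexiconEntry] = {}
        for entry in entries:
            if entry.key in self._entries:
                raise LexiconValidationError(f"duplicate entry {entry.key!r}")
            self._entries[entry.key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self._entries.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return tuple(key) in self._entries

    def __getitem__(self, key: tuple[str, str]) -> LexiconEntry:
        return self._entries[tuple(key)]

    @property
    def n_nouns(self) -> int:
        return sum(1 for e in self if e.pos == "noun")

    @property
    def n_verbs(self) -> int:
        return sum(1 for e in self if e.pos == "verb")

    def keys(self, pos: str | None = None) -> list[tuple[str, str]]:
        """Word keys, optionally restricted to one part of speech."""
        if pos is None:
            return list(self._entries)
        if pos not in POS_VALUES:
            raise ValueError(f"pos must be one of {POS_VALUES}, got {pos!r}")
        return [k for k, e in self._entries.items() if e.pos == pos]

    def to_frame(self) -> pd.DataFrame:
        """Long table with one row per (word, feature)."""
        rows = [
            (e.form, e.pos, label, ftype)
            for e in self
            for label, ftype in sorted(e.features)
        ]
        return pd.DataFrame(rows, columns=list(NORM_COLUMNS))


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a feature-norm table (TSV default; comma-separated accepted).

    Required columns: ``word``, ``pos``, ``feature``, ``feature_type``.
    Feature labels are case-folded, trimmed and de-duplicated per word.
    Unknown feature types or words left with an empty feature set raise
    :class:`LexiconValidationError` naming the offending row/word.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    missing = [c for c in NORM_COLUMNS if c not in table.columns]
    if missing:
        raise LexiconFormatError(f"{path}: missing column(s) {missing}")
    for idx, row in enumerate(table.itertuples(index=False), start=2):
        if _normalize_label(row.feature_type) not in FEATURE_TYPES:
            raise LexiconValidationError(
                f"{path}:{idx}: unknown feature_type {row.feature_type!r} "
                f"for word {row.word!r}"
            )
        if row.pos.strip() not in POS_VALUES:
            raise LexiconValidationError(
                f"{path}:{idx}: pos must be one of {POS_VALUES}, got {row.pos!r}"
            )
        if not row.feature.strip():
            raise LexiconValidationError(
                f"{path}:{idx}: empty feature for word {row.word!r}"
            )
    entries = []
    for (form, pos), group in table.groupby(["word", "pos"], sort=True):
        feats = frozenset(
            (_normalize_label(f), _normalize_label(t))
            for f, t in zip(group["feature"], group["feature_type"])
        )
        entries.append(LexiconEntry(form=str(form), pos=str(pos).strip(), features=feats))
    return Lexicon(entries)


def write_lexicon(lexicon: Lexicon, path: str | Path, sep: str = "\t") -> None:
    lexicon.to_frame().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Composition analysis
# ---------------------------------------------------------------------------

_COUNT_COLS = {t: f"c_{t[:3]}" for t in FEATURE_TYPES}
_PROP_COLS = {t: f"p_{t[:3]}" for t in FEATURE_TYPES}


def composition_profiles(lexicon: Lexicon) -> pd.DataFrame:
    """Per-word feature-type counts and within-word proportions.

    Returns one row per word with columns ``word, pos, c_enc, c_fun,
    c_per, c_tax, total, p_enc, p_fun, p_per, p_tax``; proportions sum
    to 1 exactly for every word.
    """
    rows = []
    for entry in lexicon:
        counts = entry.type_counts()
        total = entry.total_features
        row: dict[str, object] = {"word": entry.form, "pos": entry.pos}
        for ftype in FEATURE_TYPES:
            row[_COUNT_COLS[ftype]] = counts[ftype]
        row["total"] = total
        for ftype in FEATURE_TYPES:
            row[_PROP_COLS[ftype]] = counts[ftype] / total
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class WelchResult:
    """Welch (unequal-variance) two-sample t test, noun - verb direction."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t: float
    df: float
    p: float


def compare_total_features(lexicon: Lexicon) -> WelchResult:
    """Welch t test on per-word total feature counts, nouns vs verbs."""
    nouns = np.array([e.total_features for e in lexicon if e.pos == "noun"], float)
    verbs = np.array([e.total_features for e in lexicon if e.pos == "verb"], float)
    if len(nouns) < 2 or len(verbs) < 2:
        raise InsufficientDataError(
            f"need >=2 words per part of speech, got {len(nouns)} nouns, "
            f"{len(verbs)} verbs"
        )
    sd_a = float(np.std(nouns, ddof=1))
    sd_b = float(np.std(verbs, ddof=1))
    mean_a = float(np.mean(nouns))
    mean_b = float(np.mean(verbs))
    if sd_a == 0.0 and sd_b == 0.0:
        # Both groups constant: Welch df is undefined.  Equal means are a
        # well-defined "no difference"; unequal constant means are not.
        if mean_a == mean_b:
            return WelchResult(mean_a, mean_b, sd_a, sd_b, 0.0,
                               float(len(nouns) + len(verbs) - 2), 1.0)
        raise InsufficientDataError(
            "both groups have zero variance but different means; "
            "Welch degrees of freedom are undefined"
        )
    res = stats.ttest_ind(nouns, verbs, equal_var=False)
    return WelchResult(mean_a, mean_b, sd_a, sd_b,
                       float(res.statistic), float(res.df), float(res.pvalue))


@dataclass(frozen=True)
class AnovaResult:
    """Two-way ANOVA of proportion ~ feature type * part of speech.

    ``table`` mirrors a standard sequential (type I) ANOVA table with
    rows FT, POS, FT x POS and Residuals.  ``cell_means`` holds the mean
    proportion per (pos, feature type) with model-based standard errors;
    ``contrasts`` holds the noun-minus-verb estimated marginal mean
    difference per feature type with unadjusted 95% t-intervals (None
    when only one part of speech is present).
    """

    table: pd.DataFrame
    cell_means: pd.DataFrame
    contrasts: pd.DataFrame | None
    mse: float
    df_resid: int


def anova_composition(profiles: pd.DataFrame | Lexicon) -> AnovaResult:
    """Two-way ANOVA on feature-type proportions.

    Each word contributes four observations (one proportion per feature
    type), so the residual df is ``4 * n_words - 8``.  Because every
    word's four proportions sum to one, the part-of-speech main effect
    is identically zero; the informative terms are the feature-type main
    effect and the FT x POS interaction.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if isinstance(profiles, Lexicon):
        profiles = composition_profiles(profiles)
    long = profiles.melt(
        id_vars=["word", "pos"],
        value_vars=[_PROP_COLS[t] for t in FEATURE_TYPES],
        var_name="ft",
        value_name="prop",
    )
    inv = {v: k for k, v in _PROP_COLS.items()}
    long["ft"] = long["ft"].map(inv)

    pos_levels = sorted(long["pos"].unique())
    two_pos = len(pos_levels) == 2
    formula = "prop ~ C(ft) * C(pos)" if two_pos else "prop ~ C(ft)"
    fit = ols(formula, data=long).fit()
    anova = sm.stats.anova_lm(fit, typ=1)

    rename = {"C(ft)": "FT", "C(pos)": "POS", "C(ft):C(pos)": "FT x POS",
              "Residual": "Residuals"}
    table = anova.rename(index=rename)
    table = table.rename(columns={"sum_sq": "SS", "PR(>F)": "p"})
    table["MS"] = table["SS"] / table["df"]
    table = table[["df", "SS", "MS", "F", "p"]]

    df_resid = int(fit.df_resid)
    mse = float(fit.mse_resid)

    grp = long.groupby(["pos", "ft"], sort=True)["prop"]
    counts = profiles.groupby("pos")["word"].count()
    cell = grp.mean().rename("mean").reset_index()
    cell["se"] = cell["pos"].map(lambda p: math.sqrt(mse / counts[p]))
    cell["n"] = cell["pos"].map(counts)

    contrasts = None
    if two_pos:
        n_n, n_v = int(counts["noun"]), int(counts["verb"])
        se = math.sqrt(mse * (1.0 / n_n + 1.0 / n_v))
        tcrit = float(stats.t.ppf(0.975, df_resid))
        wide = cell.pivot(index="ft", columns="pos", values="mean")
        est = wide["noun"] - wide["verb"]
        contrasts = pd.DataFrame(
            {
                "ft": est.index,
                "emm_n_minus_v": est.values,
                "se": se,
                "ci_low": est.values - tcrit * se,
                "ci_high": est.values + tcrit * se,
            }
        ).reset_index(drop=True)

    return AnovaResult(table=table, cell_means=cell, contrasts=contrasts,
                       mse=mse, df_resid=df_resid)
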