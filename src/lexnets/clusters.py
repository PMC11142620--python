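"""Cluster-based permutation comparison of normalized degree.

Children are assigned to vocabulary-size bins (20 words wide by
default); within each bin a paired t test compares two within-child
conditions (noun vs verb normalized degree within one network type, or
encyclopedic vs perceptual normalized degree within one part of speech).
Contiguous runs of same-sign bins whose |t| meets a threshold form
clusters; a cluster's mass is the sum of its member t statistics.
Significance comes from a permutation null in which each child's
condition labels are independently swapped with probability 1/2 and the
maximum |cluster mass| per permutation is collected; the empirical p for
an observed cluster is ``(1 + #{null >= |mass|}) / (1 + n_perm)``, so it
is never zero and controls the family-wise error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Default per-bin t threshold (two-tailed p ~ .001 at large df).
T_THRESHOLD: float = 3.29


@dataclass(frozen=True)
class BinSeries:
    """Paired per-child observations grouped into vocabulary-size bins.

    Bin ``labels[k]`` is the right edge of the half-open interval
    ``(label - width, label]``; ``a[k]`` and ``b[k]`` are aligned arrays
    of condition-A and condition-B values for the children in bin k.
    """

    bin_width: int
    labels: tuple[int, ...]
    a: tuple[np.ndarray, ...]
    b: tuple[np.ndarray, ...]
    child_ids: tuple[tuple[str, ...], ...]
    cond_a: str = "A"
    cond_b: str = "B"

    @property
    def n_children(self) -> int:
        return sum(len(ids) for ids in self.child_ids)

    def differences(self) -> list[np.ndarray]:
        return [ai - bi for ai, bi in zip(self.a, self.b)]


@dataclass(frozen=True)
class Cluster:
    """A maximal run of contiguous supra-threshold, same-sign bins."""

    start: int
    end: int
    mass: float
    direction: str
    p: float | None = None


@dataclass(frozen=True)
class PermutationResult:
    series: BinSeries
    t_table: pd.DataFrame
    clusters: tuple[Cluster, ...]
    null_max: np.ndarray
    n_perm: int
    threshold: float
    seed: int

    def table(self) -> pd.DataFrame:
        """Cluster report: one row per observed cluster."""
        rows = [
            (self.series.cond_a, self.series.cond_b, c.start, c.end,
             c.direction, c.mass, c.p)
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=["cond_a", "cond_b", "range_start", "range_end",
                     "direction", "cluster_t", "p"],
        )


def bin_children(
    records: pd.DataFrame,
    condition: tuple[str, str],
    by: str = "pos",
    value: str = "normalized_degree",
    bin_width: int = 20,
) -> BinSeries:
    """Pair two conditions within child and group into size bins.

    ``records`` must already be filtered so that, per child, exactly one
    row exists per condition level (e.g. one restriction's noun and verb
    records).  A child lands in the bin labeled ``k * bin_width`` when
    ``(k - 1) * bin_width < vocab_size <= k * bin_width`` with
    ``vocab_size = n_nouns + n_verbs``.  Children missing either
    condition (e.g. zero verbs) are excluded.
    """
    if bin_width < 1:
        raise ValueError(f"bin_width must be >= 1, got {bin_width}")
    cond_a, cond_b = condition
    sub = records[records[by].isin(condition)].copy()
    counts = sub.groupby(["child_id", by]).size()
    if (counts > 1).any():
        raise ValueError(
            f"multiple rows per child per {by!r} level; filter records first"
        )
    sub["vocab_size"] = sub["n_nouns"] + sub["n_verbs"]
    wide = sub.pivot_table(
        index=["child_id", "vocab_size"], columns=by, values=value,
        aggfunc="first",
    ).reset_index()
    wide = wide.dropna(subset=[cond_a, cond_b])
    sizes = wide["vocab_size"].to_numpy()
    bins = (np.ceil(sizes / bin_width) * bin_width).astype(int)

    labels, a_arrs, b_arrs, ids = [], [], [], []
    for label in np.unique(bins):
        mask = bins == label
        labels.append(int(label))
        a_arrs.append(wide.loc[mask, cond_a].to_numpy(dtype=float))
        b_arrs.append(wide.loc[mask, cond_b].to_numpy(dtype=float))
        ids.append(tuple(wide.loc[mask, "child_id"]))
    return BinSeries(
        bin_width=bin_width,
        labels=tuple(labels),
        a=tuple(a_arrs),
        b=tuple(b_arrs),
        child_ids=tuple(ids),
        cond_a=str(cond_a),
        cond_b=str(cond_b),
    )


def _paired_t(diffs: np.ndarray) -> float:
    """Paired t on differences; NaN when n < 2 or variance is zero."""
    n = diffs.size
    if n < 2:
        return float("nan")
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        # all-equal differences: t = 0 when the common difference is 0,
        # otherwise infinite t — guarded as a skipped (degenerate) bin.
        return 0.0 if diffs[0] == 0.0 else float("nan")
    return float(diffs.mean() / (sd / np.sqrt(n)))


def binwise_paired_t(series: BinSeries) -> pd.DataFrame:
    """Per-bin paired t statistics (positive when condition A > B).

    Bins with fewer than two pairs or zero-variance nonzero differences
    are recorded with ``t = NaN`` and ``skipped = True``.
    """
    rows = []
    for label, ai, bi in zip(series.labels, series.a, series.b):
        t = _paired_t(ai - bi)
        rows.append(
            (label, len(ai), float(ai.mean()), float(bi.mean()), t,
             not np.isfinite(t))
        )
    return pd.DataFrame(
        rows, columns=["bin", "n", "mean_a", "mean_b", "t", "skipped"]
    )


def find_clusters(
    t_table: pd.DataFrame | Sequence[float],
    threshold: float = T_THRESHOLD,
    labels: Sequence[int] | None = None,
) -> list[Cluster]:
    """Maximal runs of contiguous same-sign bins with |t| >= threshold.

    Skipped (NaN) bins break contiguity.  Cluster mass is the sum of the
    member t statistics.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if isinstance(t_table, pd.DataFrame):
        t_values = t_table["t"].to_numpy(dtype=float)
        labels = t_table["bin"].to_numpy()
    else:
        t_values = np.asarray(t_table, dtype=float)
        labels = np.asarray(labels if labels is not None
                            else np.arange(1, len(t_values) + 1))
    clusters: list[Cluster] = []
    start = mass = None
    sign = 0
    for i, t in enumerate(t_values):
        sig = np.isfinite(t) and abs(t) >= threshold
        s = int(np.sign(t)) if sig else 0
        if sig and s == sign:
            mass += t
            end = i
        else:
            if sign != 0:
                clusters.append(_make_cluster(labels, start, end, mass))
            if sig:
                start, end, mass, sign = i, i, float(t), s
            else:
                start = mass = None
                sign = 0
    if sign != 0:
        clusters.append(_make_cluster(labels, start, end, mass))
    return clusters


def _make_cluster(labels, start: int, end: int, mass: float) -> Cluster:
    return Cluster(
        start=int(labels[start]),
        end=int(labels[end]),
        mass=float(mass),
        direction="A>B" if mass > 0 else "B>A",
    )


def _null_max_masses(
    series: BinSeries,
    threshold: float,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 1000,
) -> np.ndarray:
    """Max |cluster mass| per permutation under within-child label swaps.

    Each child appears in exactly one bin, so independently flipping the
    sign of each child's difference realizes the within-child shuffle.
    Vectorized over permutations in chunks; a streaming scan over bins
    tracks the running same-sign supra-threshold cluster mass.
    """
    diffs = series.differences()
    ns = np.array([d.size for d in diffs])
    sqrt_ns = np.sqrt(ns)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        p = min(chunk, n_perm - done)
        t_mat = np.full((p, len(diffs)), np.nan)
        for j, d in enumerate(diffs):
            if d.size < 2:
                continue
            signs = rng.choice((-1.0, 1.0), size=(p, d.size))
            x = signs * d
            m = x.mean(axis=1)
            sd = x.std(axis=1, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = m / (sd / sqrt_ns[j])
            t[sd == 0.0] = np.where(m[sd == 0.0] == 0.0, 0.0, np.nan)
            t_mat[:, j] = t
        best = np.zeros(p)
        cur_mass = np.zeros(p)
        cur_sign = np.zeros(p)
        for j in range(len(diffs)):
            t = t_mat[:, j]
            finite = np.isfinite(t)
            sig = finite & (np.abs(t) >= threshold)
            s = np.where(sig, np.sign(t), 0.0)
            cont = sig & (s == cur_sign) & (cur_sign != 0)
            t_safe = np.where(finite, t, 0.0)
            cur_mass = np.where(cont, cur_mass + t_safe,
                                np.where(sig, t_safe, 0.0))
            cur_sign = s
            best = np.maximum(best, np.abs(cur_mass))
        out[done:done + p] = best
        done += p
    return out


def permutation_null(
    series: BinSeries,
    threshold: float = T_THRESHOLD,
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Full cluster-based permutation test on a paired bin series."""
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    if not any(d.size >= 2 for d in series.differences()):
        raise ValueError("need at least one bin with >= 2 paired children")
    t_table = binwise_paired_t(series)
    observed = find_clusters(t_table, threshold=threshold)
    rng = np.random.default_rng(seed)
    null_max = _null_max_masses(series, threshold, n_perm, rng)
    clusters = tuple(
        Cluster(
            start=c.start,
            end=c.end,
            mass=c.mass,
            direction=c.direction,
            p=float((1 + np.sum(null_max >= abs(c.mass))) / (1 + n_perm)),
        )
        for c in observed
    )
    return PermutationResult(
        series=series,
        t_table=t_table,
        clusters=clusters,
        null_max=null_max,
        n_perm=n_perm,
        threshold=threshold,
        seed=seed,
    )


def compare_pos_within_type(
    records: pd.DataFrame,
    restriction: str,
    bin_width: int = 20,
    threshold: float = T_THRESHOLD,
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Noun vs verb normalized degree within one network type.

    Condition A is nouns, so positive cluster masses read "N > V" and
    negative ones "V > N".
    """
    sub = records[records["restriction"] == restriction]
    if sub.empty:
        raise ValueError(f"no records for restriction {restriction!r}")
    series = bin_children(sub, ("noun", "verb"), by="pos", bin_width=bin_width)
    return permutation_null(series, threshold=threshold, n_perm=n_perm, seed=seed)


def compare_types_within_pos(
    records: pd.DataFrame,
    pos: str,
    type_a: str = "encyclopedic",
    type_b: str = "perceptual",
    bin_width: int = 20,
    threshold: float = T_THRESHOLD,
    n_perm: int = 10000,
    seed: int = 0,
) -> PermutationResult:
    """Two network types' normalized degree within one part of speech."""
    sub = records[records["pos"] == pos]
    if sub.empty:
        raise ValueError(f"no records for pos {pos!r}")
    series = bin_children(sub, (type_a, type_b), by="restriction",
                          bin_width=bin_width)
    return permutation_null(series, threshold=threshold, n_perm=n_perm, seed=seed)


def direction_label(result: PermutationResult, cluster: Cluster) -> str:
    """Human-readable direction, e.g. "N > V" or "perceptual > encyclopedic"."""
    short = {"noun": "N", "verb": "V"}
    a = short.get(result.series.cond_a, result.series.cond_a)
    b = short.get(result.series.cond_b, result.series.cond_b)
    return f"{a} > {b}" if cluster.direction == "A>B" else f"{b} > {a}"
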