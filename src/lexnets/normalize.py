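"""Random-network normalization of mean weighted degree.

Raw mean weighted degree confounds semantic structure with vocabulary
composition: larger vocabularies, and vocabularies with more of the
feature-rich part of speech, have mechanically higher degree.  The
normalization expresses each child's observed per-POS mean weighted
degree as a percentile rank against random networks built from uniform
random draws of the same number of nouns and verbs from the lexicon.

Pipeline (per feature-type restriction and part of speech):

1. enumerate the distinct (n_nouns, n_verbs) vocabulary-size points
   observed across children;
2. strategically sample that space: a fraction of the points inside the
   2-SD PCA region, all points outside it, and the points on the edges
   of the space;
3. at each sampled point, simulate random networks (uniform word draws)
   and record the per-replicate mean weighted degree per POS;
4. assemble the replicate means into a 3-D histogram (noun size x verb
   size x degree bin) with shared bin edges;
5. linearly interpolate histogram columns over the vocabulary-size plane
   to cover unsampled observed points (nearest-point fallback outside
   the convex hull), renormalizing columns;
6. optionally smooth each column along the degree axis with a Gaussian
   kernel of two bin widths, reflected at zero, and renormalize — the
   end-to-end builder applies this only when the kernel is genuinely
   slight relative to the columns' own spread (see
   :func:`build_null_histograms`), because a kernel comparable to the
   column standard deviation inflates the null spread and biases every
   percentile toward 50;
7. convert each child's raw mean degree to a percentile ("proportion of
   random networks at or below the observed value", x 100) by summing
   bin mass below the value plus a linear share of the containing bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .networks import (
    ChildVocabulary,
    SharedFeatureMatrix,
    mean_degrees_from_matrix,
    shared_feature_matrix,
)
from .norms import Lexicon

Point = tuple[int, int]


class NormalizationStateError(RuntimeError):
    """The pipeline was queried before the required stage was run."""


# ---------------------------------------------------------------------------
# Vocabulary-size space
# ---------------------------------------------------------------------------


def enumerate_space(children: Iterable[ChildVocabulary]) -> list[Point]:
    """Distinct (n_nouns, n_verbs) points over children, sorted."""
    return sorted({child.size_point for child in children})


@dataclass(frozen=True)
class SampledSpace:
    """The strategically sampled subset of the vocabulary-size space."""

    all_points: tuple[Point, ...]
    points: tuple[Point, ...]
    tags: tuple[str, ...]  # one of {"interior", "exterior", "edge", "all"}
    center: tuple[float, float] | None
    axes: np.ndarray | None  # principal axes as rows
    axis_sd: tuple[float, float] | None
    seed: int

    def tag_of(self, point: Point) -> str:
        return self.tags[self.points.index(point)]


def _edge_points(points: np.ndarray) -> set[Point]:
    """Boundary of the observed lattice: per noun size, min/max verb
    size; per verb size, min/max noun size."""
    edges: set[Point] = set()
    for x in np.unique(points[:, 0]):
        ys = points[points[:, 0] == x, 1]
        edges.add((int(x), int(ys.min())))
        edges.add((int(x), int(ys.max())))
    for y in np.unique(points[:, 1]):
        xs = points[points[:, 1] == y, 0]
        edges.add((int(xs.min()), int(y)))
        edges.add((int(xs.max()), int(y)))
    return edges


def sample_space(
    points: Sequence[Point],
    interior_frac: float = 0.15,
    sd_radius: float = 2.0,
    seed: int = 0,
    standardize: bool = False,
) -> SampledSpace:
    """Sample the vocabulary-size space for null-network simulation.

    PCA is run on the (centered, optionally standardized) observed
    points; a point is *interior* when its score on every principal axis
    is within ``sd_radius`` standard deviations of that axis's scores.
    The sample is the union of ``ceil(interior_frac * n_interior)``
    interior points drawn uniformly without replacement, all exterior
    points, and all edge points of the observed lattice.  Fewer than
    three points, or a degenerate (collinear) configuration, selects
    every point.
    """
    if not (0.0 < interior_frac <= 1.0):
        raise ValueError(f"interior_frac must be in (0, 1], got {interior_frac}")
    pts = np.asarray(sorted(set(map(tuple, points))), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n_nouns, n_verbs) pairs")
    unique_points = [
        (int(x), int(y)) for x, y in pts
    ]
    rng = np.random.default_rng(seed)

    degenerate = len(pts) < 3
    center = axes = sds = None
    if not degenerate:
        centered = pts - pts.mean(axis=0)
        if standardize:
            scale = centered.std(axis=0, ddof=1)
            scale[scale == 0] = 1.0
            centered = centered / scale
        cov = np.cov(centered.T)
        eigvals, eigvecs = np.linalg.eigh(cov)
        if eigvals.min() <= 1e-12:  # collinear
            degenerate = True
        else:
            axes = eigvecs.T[::-1]  # rows, major axis first
            scores = centered @ axes.T
            sds = scores.std(axis=0, ddof=1)
            center = tuple(pts.mean(axis=0))

    if degenerate:
        return SampledSpace(
            all_points=tuple(unique_points),
            points=tuple(unique_points),
            tags=tuple("all" for _ in unique_points),
            center=None,
            axes=None,
            axis_sd=None,
            seed=seed,
        )

    interior_mask = np.all(np.abs(scores) <= sd_radius * sds, axis=1)
    interior = [p for p, m in zip(unique_points, interior_mask) if m]
    exterior = [p for p, m in zip(unique_points, interior_mask) if not m]
    edges = _edge_points(pts.astype(int))

    n_take = int(np.ceil(interior_frac * len(interior)))
    taken = set()
    if interior and n_take:
        idx = rng.choice(len(interior), size=min(n_take, len(interior)),
                         replace=False)
        taken = {interior[i] for i in idx}

    sampled: dict[Point, str] = {}
    for p in exterior:
        sampled[p] = "exterior"
    for p in sorted(edges):
        sampled.setdefault(p, "edge")
    for p in sorted(taken):
        sampled.setdefault(p, "interior")

    ordered = sorted(sampled)
    return SampledSpace(
        all_points=tuple(unique_points),
        points=tuple(ordered),
        tags=tuple(sampled[p] for p in ordered),
        center=center,
        axes=axes,
        axis_sd=(float(sds[0]), float(sds[1])),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Random-network simulation
# ---------------------------------------------------------------------------


def point_rng(seed: int, point_index: int) -> np.random.Generator:
    """Reproducible per-point substream (stable under parallel fan-out)."""
    return np.random.default_rng([seed, point_index])


def simulate_random_networks(
    point: Point,
    lexicon: Lexicon | SharedFeatureMatrix,
    restriction: str = "all",
    reps: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Per-replicate mean weighted degree of random networks at one point.

    Each replicate draws ``n_nouns`` nouns and ``n_verbs`` verbs
    uniformly without replacement from the lexicon, forms the restricted
    network, and records the mean weighted degree per POS.  Returns
    ``(noun_means, verb_means)`` arrays of length ``reps``; a POS with
    zero words yields None.
    """
    sfm = (
        lexicon
        if isinstance(lexicon, SharedFeatureMatrix)
        else shared_feature_matrix(lexicon, restriction)
    )
    nn, nv = int(point[0]), int(point[1])
    if nn > sfm.noun_idx.size or nv > sfm.verb_idx.size:
        raise ValueError(
            f"point {point} exceeds lexicon capacity "
            f"({sfm.noun_idx.size} nouns, {sfm.verb_idx.size} verbs)"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    n = sfm.matrix.shape[0]
    sel = np.zeros((reps, n))
    sel_noun = np.zeros((reps, n))
    for r in range(reps):
        if nn:
            picks = sfm.noun_idx[rng.permutation(sfm.noun_idx.size)[:nn]]
            sel[r, picks] = 1.0
            sel_noun[r, picks] = 1.0
        if nv:
            picks = sfm.verb_idx[rng.permutation(sfm.verb_idx.size)[:nv]]
            sel[r, picks] = 1.0
    degrees = sel @ sfm.matrix  # (reps, n): degree of every word if selected
    noun_means = (degrees * sel_noun).sum(axis=1) / nn if nn else None
    verb_means = (degrees * (sel - sel_noun)).sum(axis=1) / nv if nv else None
    return noun_means, verb_means


def simulate_space(
    space: SampledSpace | Sequence[Point],
    lexicon: Lexicon | SharedFeatureMatrix,
    restriction: str = "all",
    reps: int = 200,
    seed: int = 0,
) -> dict[Point, tuple[np.ndarray | None, np.ndarray | None]]:
    """Run :func:`simulate_random_networks` at every sampled point."""
    points = space.points if isinstance(space, SampledSpace) else list(space)
    sfm = (
        lexicon
        if isinstance(lexicon, SharedFeatureMatrix)
        else shared_feature_matrix(lexicon, restriction)
    )
    return {
        tuple(p): simulate_random_networks(
            tuple(p), sfm, restriction, reps=reps, rng=point_rng(seed, i)
        )
        for i, p in enumerate(points)
    }


# ---------------------------------------------------------------------------
# 3-D histograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegreeHistogram3D:
    """Noun-size x verb-size x degree-bin null distributions.

    The vocabulary-size plane is sparse, so populated columns are stored
    as a mapping from (n_nouns, n_verbs) to a probability-mass vector
    over shared degree bins; unpopulated points are simply absent.
    """

    restriction: str
    pos: str
    bin_edges: np.ndarray
    columns: dict[Point, np.ndarray]
    reps: int
    seed: int

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def column(self, point: Point) -> np.ndarray:
        return self.columns[tuple(point)]

    def points(self) -> list[Point]:
        return sorted(self.columns)

    def save(self, path: str | Path) -> None:
        pts = np.array(self.points(), dtype=np.int64)
        mass = np.array([self.columns[tuple(p)] for p in pts])
        np.savez_compressed(
            path,
            restriction=np.array(self.restriction),
            pos=np.array(self.pos),
            bin_edges=self.bin_edges,
            points=pts,
            mass=mass,
            reps=np.array(self.reps),
            seed=np.array(self.seed),
        )

    @classmethod
    def load(cls, path: str | Path) -> "DegreeHistogram3D":
        with np.load(path, allow_pickle=False) as data:
            columns = {
                (int(x), int(y)): mass
                for (x, y), mass in zip(data["points"], data["mass"])
            }
            return cls(
                restriction=str(data["restriction"]),
                pos=str(data["pos"]),
                bin_edges=data["bin_edges"],
                columns=columns,
                reps=int(data["reps"]),
                seed=int(data["seed"]),
            )


def _shared_edges(samples: Mapping[Point, np.ndarray], n_bins: int) -> np.ndarray:
    pooled_max = max((float(v.max()) for v in samples.values() if v.size), default=0.0)
    hi = pooled_max * (1.0 + 1.0 / n_bins) if pooled_max > 0 else 1.0
    return np.linspace(0.0, hi, n_bins + 1)


def assemble_histograms(
    samples: Mapping[Point, tuple[np.ndarray | None, np.ndarray | None]],
    restriction: str,
    n_bins: int = 64,
    reps: int = 0,
    seed: int = 0,
) -> dict[str, DegreeHistogram3D]:
    """Histogram the simulated degree means, per part of speech.

    Bin edges are shared across the whole space per POS, spanning
    ``[0, max * (1 + 1/n_bins)]`` with ``n_bins`` equal-width bins.
    Returns ``{"noun": hist, "verb": hist}``; a point appears in a POS's
    histogram only when that POS was non-empty there.
    """
    if n_bins < 8:
        raise ValueError(f"n_bins must be >= 8, got {n_bins}")
    out: dict[str, DegreeHistogram3D] = {}
    for pos, slot in (("noun", 0), ("verb", 1)):
        per_point = {
            p: vals[slot] for p, vals in samples.items() if vals[slot] is not None
        }
        edges = _shared_edges(per_point, n_bins)
        columns = {}
        for p, values in per_point.items():
            clipped = np.clip(values, edges[0], edges[-1])
            counts, _ = np.histogram(clipped, bins=edges)
            columns[tuple(p)] = counts / counts.sum()
        out[pos] = DegreeHistogram3D(
            restriction=restriction,
            pos=pos,
            bin_edges=edges,
            columns=columns,
            reps=reps or (len(next(iter(per_point.values()))) if per_point else 0),
            seed=seed,
        )
    return out


def _renormalized(mass: np.ndarray) -> np.ndarray:
    mass = np.clip(mass, 0.0, None)
    total = mass.sum()
    if total <= 0:
        raise NormalizationStateError("histogram column has no mass")
    return mass / total


def interpolate_space(
    hist: DegreeHistogram3D, targets: Sequence[Point]
) -> DegreeHistogram3D:
    """Cover target points by piecewise-linear interpolation of columns.

    Each degree bin's mass is interpolated independently over the
    (n_nouns, n_verbs) plane (Delaunay-based, so a target coinciding
    with a sampled point reproduces its column exactly); targets outside
    the convex hull — or every target, when the sampled points are too
    few or collinear — fall back to the nearest sampled column.  Columns
    are renormalized to sum to one.
    """
    if not hist.columns:
        raise NormalizationStateError("no sampled histogram columns")
    src_pts = np.array(hist.points(), dtype=float)
    src_mass = np.array([hist.columns[tuple(p)] for p in hist.points()])
    targets = [(int(x), int(y)) for x, y in targets]
    result = np.full((len(targets), hist.n_bins), np.nan)
    tgt = np.array(targets, dtype=float)

    can_triangulate = len(src_pts) >= 3 and (
        np.linalg.matrix_rank(src_pts - src_pts.mean(axis=0)) == 2
    )
    if can_triangulate:
        interp = LinearNDInterpolator(src_pts, src_mass)
        result = interp(tgt)
    missing = np.isnan(result).any(axis=1)
    if missing.any():
        tree = cKDTree(src_pts)
        _, nearest = tree.query(tgt[missing])
        result[missing] = src_mass[nearest]

    columns = {
        p: _renormalized(result[i]) for i, p in enumerate(targets)
    }
    return DegreeHistogram3D(
        restriction=hist.restriction,
        pos=hist.pos,
        bin_edges=hist.bin_edges,
        columns=columns,
        reps=hist.reps,
        seed=hist.seed,
    )


def smooth_histograms(
    hist: DegreeHistogram3D, bandwidth_bins: float = 2.0
) -> DegreeHistogram3D:
    """Gaussian-smooth every column along the degree axis.

    Sigma equals ``bandwidth_bins`` bin widths; the kernel is reflected
    at the boundaries so mass is conserved, then columns are
    renormalized.
    """
    if bandwidth_bins <= 0:
        raise ValueError(f"bandwidth_bins must be > 0, got {bandwidth_bins}")
    columns = {
        p: _renormalized(gaussian_filter1d(mass, sigma=bandwidth_bins, mode="reflect"))
        for p, mass in hist.columns.items()
    }
    return DegreeHistogram3D(
        restriction=hist.restriction,
        pos=hist.pos,
        bin_edges=hist.bin_edges,
        columns=columns,
        reps=hist.reps,
        seed=hist.seed,
    )


def percentile_rank(raw_degree: float, column: np.ndarray,
                    bin_edges: np.ndarray) -> float:
    """Percentile of a raw degree against one histogram column.

    Mass of bins entirely at or below the value, plus a linear share of
    the containing bin, times 100.  Values below the first edge map to
    0; values at or above the last edge map to 100.
    """
    column = np.asarray(column, dtype=float)
    if column.size != len(bin_edges) - 1:
        raise ValueError("column length must match bin count")
    total = column.sum()
    if total <= 0:
        raise NormalizationStateError("empty histogram column")
    if raw_degree <= bin_edges[0]:
        return 0.0
    if raw_degree >= bin_edges[-1]:
        return 100.0
    i = int(np.searchsorted(bin_edges, raw_degree, side="right")) - 1
    width = bin_edges[i + 1] - bin_edges[i]
    frac = (raw_degree - bin_edges[i]) / width
    below = column[:i].sum() + column[i] * frac
    return float(100.0 * below / total)


# ---------------------------------------------------------------------------
# End-to-end normalization
# ---------------------------------------------------------------------------


def median_column_sd_bins(hist: DegreeHistogram3D) -> float:
    """Median per-column standard deviation, in bin-width units."""
    if not hist.columns:
        return 0.0
    centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
    width = hist.bin_edges[1] - hist.bin_edges[0]
    sds = []
    for mass in hist.columns.values():
        mean = float(mass @ centers)
        var = float(mass @ (centers - mean) ** 2)
        sds.append(np.sqrt(var) / width)
    return float(np.median(sds))


#: Smoothing is "slight" when the kernel sigma is at most this fraction of
#: the typical column sd: the smoothed sd is then inflated by < 6%.
_SLIGHT_SMOOTHING_RATIO = 1.0 / 3.0


def build_null_histograms(
    lexicon: Lexicon,
    children: Sequence[ChildVocabulary],
    restrictions: Sequence[str],
    reps: int = 200,
    n_bins: int = 64,
    interior_frac: float = 0.15,
    sd_radius: float = 2.0,
    bandwidth_bins: float = 2.0,
    seed: int = 0,
    smooth: bool | str = "auto",
) -> tuple[dict[tuple[str, str], DegreeHistogram3D], SampledSpace]:
    """Fit the full null model for every restriction and POS.

    Returns histograms keyed by (restriction, pos), interpolated to
    cover every observed vocabulary-size point, along with the sampled
    space.  ``smooth`` may be True, False or "auto" (default): "auto"
    applies the KDE pass only when the kernel sigma is at most one third
    of the median column standard deviation, i.e. when smoothing merely
    polishes binning artifacts.  A kernel wide relative to the columns
    themselves would inflate the null spread and pull every percentile
    toward 50, destroying the normalization's calibration — which is the
    one property a null-model percentile must keep.
    """
    observed = enumerate_space(children)
    space = sample_space(observed, interior_frac=interior_frac,
                         sd_radius=sd_radius, seed=seed)
    hists: dict[tuple[str, str], DegreeHistogram3D] = {}
    for restriction in restrictions:
        sfm = shared_feature_matrix(lexicon, restriction)
        samples = simulate_space(space, sfm, restriction, reps=reps, seed=seed)
        per_pos = assemble_histograms(samples, restriction, n_bins=n_bins,
                                      reps=reps, seed=seed)
        for pos, hist in per_pos.items():
            slot = 0 if pos == "noun" else 1
            targets = [p for p in observed if p[slot] > 0]
            if not targets:
                continue
            covered = interpolate_space(hist, targets)
            if smooth == "auto":
                typical_sd = median_column_sd_bins(hist)
                apply = bandwidth_bins <= _SLIGHT_SMOOTHING_RATIO * typical_sd
            else:
                apply = bool(smooth)
            if apply:
                covered = smooth_histograms(covered, bandwidth_bins=bandwidth_bins)
            hists[(restriction, pos)] = covered
    return hists, space


def normalize_children(
    children: Sequence[ChildVocabulary],
    lexicon: Lexicon,
    hists: Mapping[tuple[str, str], DegreeHistogram3D],
) -> pd.DataFrame:
    """Normalized-degree records for every child x restriction x POS.

    Returns a DataFrame with columns ``child_id, restriction, pos,
    raw_degree, normalized_degree, n_nouns, n_verbs``; a POS with zero
    produced words yields no record for that child.
    """
    restrictions = sorted({r for r, _ in hists})
    matrices = {r: shared_feature_matrix(lexicon, r) for r in restrictions}
    rows = []
    for child in children:
        point = child.size_point
        for restriction in restrictions:
            noun_raw, verb_raw = mean_degrees_from_matrix(
                matrices[restriction], child.words
            )
            for pos, raw in (("noun", noun_raw), ("verb", verb_raw)):
                if raw is None:
                    continue
                hist = hists.get((restriction, pos))
                if hist is None or tuple(point) not in hist.columns:
                    raise NormalizationStateError(
                        f"no histogram column for point {point} "
                        f"({restriction}, {pos})"
                    )
                pct = percentile_rank(raw, hist.column(point), hist.bin_edges)
                rows.append(
                    (child.child_id, restriction, pos, raw, pct,
                     point[0], point[1])
                )
    return pd.DataFrame(
        rows,
        columns=["child_id", "restriction", "pos", "raw_degree",
                 "normalized_degree", "n_nouns", "n_verbs"],
    )
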