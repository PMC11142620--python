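"""End-to-end orchestration of the two analyses.

``run_experiment1`` reads a feature-norm table and writes the
composition, ANOVA and contrast tables.  ``run_experiment2`` reads norms
plus item-level vocabulary records, normalizes per-child mean weighted
degree against random networks for each feature-type restriction, runs
the cluster-based permutation comparisons (noun vs verb within each
type; encyclopedic vs perceptual within each part of speech) and writes
the normalized-degree table, the cluster report and per-bin diagnostics.
All outputs are TSV plus a JSON run manifest; identical seeds and inputs
reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .clusters import (
    PermutationResult,
    compare_pos_within_type,
    compare_types_within_pos,
    direction_label,
)
from .networks import ChildVocabulary, read_vocabulary
from .normalize import build_null_histograms, normalize_children
from .norms import (
    FEATURE_TYPES,
    Lexicon,
    anova_composition,
    compare_total_features,
    composition_profiles,
    read_lexicon,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

#: Scaled-down settings for desk use vs full-scale analysis settings.
PRESETS: dict[str, dict[str, int]] = {
    "desk": {"reps": 200, "n_perm": 1000},
    "full": {"reps": 1000, "n_perm": 10000},
}


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters for a full run."""

    norms_path: str | Path
    out_dir: str | Path
    vocab_path: str | Path | None = None
    reps: int = 200
    n_bins: int = 64
    interior_frac: float = 0.15
    sd_radius: float = 2.0
    bandwidth_bins: float = 2.0
    bin_width: int = 20
    t_threshold: float = 3.29
    n_perm: int = 1000
    seed: int = 0
    preset: str | None = None

    def resolved(self) -> "RunConfig":
        if self.preset is None:
            return self
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")
        return dataclasses.replace(self, **PRESETS[self.preset], preset=None)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


def _write_manifest(out_dir: Path, stage: str, cfg: RunConfig,
                    extra: Mapping[str, object]) -> None:
    manifest = {
        "stage": stage,
        "lexnets_version": __version__,
        "seed": cfg.seed,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
        **extra,
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def _to_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def run_experiment1(cfg: RunConfig) -> dict[str, Path]:
    """Composition analysis: counts, proportions, Welch t, ANOVA, contrasts."""
    cfg = cfg.resolved()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    lexicon = read_lexicon(cfg.norms_path)
    logger.info("exp1: %d nouns, %d verbs", lexicon.n_nouns, lexicon.n_verbs)

    profiles = composition_profiles(lexicon)
    welch = compare_total_features(lexicon)
    result = anova_composition(profiles)

    paths = {
        "composition": out_dir / "composition.tsv",
        "anova": out_dir / "anova.tsv",
        "cell_means": out_dir / "cell_means.tsv",
        "contrasts": out_dir / "contrasts.tsv",
    }
    _to_tsv(profiles.sort_values(["pos", "word"]), paths["composition"])
    _to_tsv(result.table, paths["anova"], index=True)
    _to_tsv(result.cell_means, paths["cell_means"])
    if result.contrasts is not None:
        _to_tsv(result.contrasts, paths["contrasts"])
    _write_manifest(
        out_dir, "exp1", cfg,
        {
            "n_nouns": lexicon.n_nouns,
            "n_verbs": lexicon.n_verbs,
            "residual_df": result.df_resid,
            "welch": dataclasses.asdict(welch),
        },
    )
    logger.info("exp1 done in %.2fs (residual df = %d)",
                time.perf_counter() - t0, result.df_resid)
    return paths


def _cluster_report(
    results: Mapping[str, PermutationResult]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    report_rows, diag_rows = [], []
    for name in sorted(results):
        res = results[name]
        for c in res.clusters:
            report_rows.append(
                (name, c.start, c.end, direction_label(res, c), c.mass, c.p)
            )
        for row in res.t_table.itertuples(index=False):
            diag_rows.append((name, row.bin, row.n, row.mean_a, row.mean_b,
                              row.t, row.skipped))
    report = pd.DataFrame(
        report_rows,
        columns=["comparison", "range_start", "range_end", "direction",
                 "cluster_t", "p"],
    )
    diagnostics = pd.DataFrame(
        diag_rows,
        columns=["comparison", "bin", "n", "mean_a", "mean_b", "t", "skipped"],
    )
    return report, diagnostics


def run_experiment2(cfg: RunConfig) -> dict[str, Path]:
    """Network normalization and cluster-based permutation comparisons."""
    cfg = cfg.resolved()
    if cfg.vocab_path is None:
        raise ValueError("run_experiment2 requires vocab_path")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    lexicon = read_lexicon(cfg.norms_path)
    children = read_vocabulary(cfg.vocab_path, lexicon=lexicon)
    children = [c for c in children if c.vocab_size > 0]
    logger.info("exp2: %d children, %d lexicon words", len(children), len(lexicon))

    hists, space = build_null_histograms(
        lexicon, children, restrictions=list(FEATURE_TYPES),
        reps=cfg.reps, n_bins=cfg.n_bins, interior_frac=cfg.interior_frac,
        sd_radius=cfg.sd_radius, bandwidth_bins=cfg.bandwidth_bins,
        seed=cfg.seed,
    )
    logger.info("exp2: sampled %d of %d vocabulary-size points",
                len(space.points), len(space.all_points))
    records = normalize_children(children, lexicon, hists)

    results: dict[str, PermutationResult] = {}
    for restriction in FEATURE_TYPES:
        results[f"pos_within_{restriction}"] = compare_pos_within_type(
            records, restriction, bin_width=cfg.bin_width,
            threshold=cfg.t_threshold, n_perm=cfg.n_perm, seed=cfg.seed,
        )
    for pos in ("noun", "verb"):
        results[f"enc_vs_per_within_{pos}"] = compare_types_within_pos(
            records, pos, bin_width=cfg.bin_width,
            threshold=cfg.t_threshold, n_perm=cfg.n_perm, seed=cfg.seed,
        )
    report, diagnostics = _cluster_report(results)

    paths = {
        "normalized": out_dir / "normalized_degree.tsv",
        "clusters": out_dir / "clusters.tsv",
        "diagnostics": out_dir / "bin_diagnostics.tsv",
    }
    _to_tsv(records.sort_values(["child_id", "restriction", "pos"]),
            paths["normalized"])
    _to_tsv(report, paths["clusters"])
    _to_tsv(diagnostics, paths["diagnostics"])
    _write_manifest(
        out_dir, "exp2", cfg,
        {
            "n_children": len(children),
            "n_observed_points": len(space.all_points),
            "n_sampled_points": len(space.points),
        },
    )
    logger.info("exp2 done in %.2fs", time.perf_counter() - t0)
    return paths


def simulate_inputs(
    out_dir: str | Path,
    n_children: int = 500,
    seed: int = 0,
    norms_overrides: Mapping | None = None,
    population_overrides: Mapping | None = None,
) -> dict[str, Path]:
    """Generate norms + vocabulary files in the formats the pipeline reads."""
    import dataclasses as dc

    from .networks import write_percentiles, write_vocabulary
    from .norms import write_lexicon
    from .simulate import NormsConfig, PopulationConfig, generate_lexicon, \
        generate_population

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    norms_cfg = NormsConfig(**(norms_overrides or {}))
    pop_cfg = PopulationConfig(
        **{"n_children": n_children, **(population_overrides or {})}
    )
    lexicon = generate_lexicon(norms_cfg, seed=seed)
    children = generate_population(lexicon, pop_cfg, seed=seed + 1)
    paths = {
        "norms": out_dir / "norms.tsv",
        "vocab": out_dir / "vocabulary.tsv",
        "percentiles": out_dir / "percentiles.tsv",
    }
    write_lexicon(lexicon, paths["norms"])
    write_vocabulary(children, lexicon, paths["vocab"])
    write_percentiles(children, paths["percentiles"])
    return paths
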