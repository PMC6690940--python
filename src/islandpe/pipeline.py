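"""End-to-end orchestration: clean -> incidence -> metrics -> null -> categories.

`run_analysis` is the in-memory engine (what tests and the acceptance
script call); `run_pipeline` wraps it with file I/O, per-stage seeding and
TSV/JSON outputs; `sensitivity_sweep` reruns the analysis on island subsets
filtered by sampling coverage (ICEr) and reports category stability.

For the restricted variant, branch ranges and the null model always use
the *full* incidence matrix (occurrences are randomized among all islands,
and R_c counts every island), but only islands harboring at least one
island-restricted genus are tested and classified, so islands without
endemic genera can never be flagged as centers of restricted endemism.

Sampling-coverage correction (``icer_mode``): ``off`` leaves scores alone;
``divide_observed`` divides the observed PE/PEalt/RPE by the island's ICEr
before comparing with the raw null; ``divide_both`` divides observed and
null values alike — a per-island positive factor on both sides of a rank
comparison cancels, so ``divide_both`` changes reported scores but provably
not frequencies or categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .categorization import assign_categories, compare_variants, summarize_categories
from .endemism import EndemismScores, compute_scores, restrict_islands
from .io_formats import (
    ConfigurationError,
    DatedTree,
    GenusAnnotations,
    IncidenceMatrix,
    build_incidence,
    read_island_table,
    read_newick,
    read_occurrences,
    write_results,
    write_run_metadata,
)
from .null_model import TailFrequencies, null_metric_distribution, tail_frequencies
from .preprocessing import (
    exclude_undersampled,
    filter_bounding_box,
    filter_native_status,
    fit_richness_model,
)

logger = logging.getLogger("islandpe.pipeline")

__all__ = ["RunConfig", "VariantResult", "run_analysis", "run_pipeline", "sensitivity_sweep"]

ICER_MODES = ("off", "divide_observed", "divide_both")


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    tree_path: str
    occurrences_path: str
    island_table_path: str | None = None
    continental_path: str | None = None
    bbox_path: str | None = None
    native_status_path: str | None = None
    output_dir: str = "results"
    variants: tuple[str, ...] = ("expanded", "restricted")
    alpha: float = 0.05
    super_alpha: float = 0.01
    n_sims: int = 1000
    seed: int = 0
    undersampling_factor: float = 5.0
    icer_mode: str = "off"
    n_max: int | None = None
    burn_in: int | None = None
    thinning: int | None = None
    occurrence_dialect: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.alpha > self.super_alpha > 0):
            raise ConfigurationError("need alpha > super_alpha > 0")
        if self.icer_mode not in ICER_MODES:
            raise ConfigurationError(f"icer_mode must be one of {ICER_MODES}")


@dataclass
class VariantResult:
    variant: str
    scores: EndemismScores  # over tested islands, coverage-corrected if asked
    frequencies: TailFrequencies
    assignments: dict[str, str]
    summary: pd.DataFrame
    tested_islands: list[str]


def _subset_scores(s: EndemismScores, keep: Sequence[str]) -> EndemismScores:
    idx = [s.island_ids.index(i) for i in keep]
    return EndemismScores(
        s.variant, list(keep), s.pe[idx], s.pe_alt[idx], s.rpe[idx], s.l_uniform
    )


def _subset_freqs(f: TailFrequencies, keep: Sequence[str]) -> TailFrequencies:
    idx = [f.island_ids.index(i) for i in keep]
    return TailFrequencies(
        list(keep),
        f.n_sims,
        {m: v[idx] for m, v in f.freq_higher.items()},
        {m: v[idx] for m, v in f.freq_lower.items()},
    )


def _apply_icer(s: EndemismScores, icer: Mapping[str, float]) -> EndemismScores:
    f = np.array([icer[i] for i in s.island_ids], dtype=float)
    if (f <= 0).any() or not np.isfinite(f).all():
        raise ConfigurationError("ICEr factors must be finite and positive")
    return EndemismScores(s.variant, list(s.island_ids), s.pe / f, s.pe_alt / f, s.rpe / f, s.l_uniform)


def run_analysis(
    tree: DatedTree,
    incidence: IncidenceMatrix,
    annotations: GenusAnnotations | None = None,
    variants: Sequence[str] = ("expanded",),
    alpha: float = 0.05,
    super_alpha: float = 0.01,
    n_sims: int = 1000,
    seed: int = 0,
    n_max: int | None = None,
    burn_in: int | None = None,
    thinning: int | None = None,
    icer: Mapping[str, float] | None = None,
    icer_mode: str = "off",
) -> dict[str, VariantResult]:
    """Metrics + null test + categories for each requested variant."""
    if icer_mode not in ICER_MODES:
        raise ConfigurationError(f"icer_mode must be one of {ICER_MODES}")
    if icer_mode != "off" and icer is None:
        raise ConfigurationError(f"icer_mode={icer_mode!r} needs ICEr scores")
    results: dict[str, VariantResult] = {}
    variant_seeds = {v: s for v, s in zip(variants, _child_seeds(seed, len(variants)))}
    for variant in variants:
        observed = compute_scores(tree, incidence, annotations, variant, n_max)
        obs_for_test = observed
        if icer_mode == "divide_observed":
            obs_for_test = _apply_icer(observed, icer)
        ensemble = null_metric_distribution(
            tree,
            incidence,
            variant=variant,
            annotations=annotations,
            n_sims=n_sims,
            seed=variant_seeds[variant],
            observed=obs_for_test,
            burn_in=burn_in,
            thinning=thinning,
            n_max=n_max,
        )
        freqs = tail_frequencies(obs_for_test, ensemble)

        if variant == "restricted":
            if annotations is None:
                raise ConfigurationError("restricted variant requires annotations")
            tested = restrict_islands(incidence, annotations)
            if not tested:
                logger.warning("restricted variant: no eligible islands")
        else:
            tested = list(incidence.island_ids)

        report_scores = observed if icer_mode == "off" else _apply_icer(observed, icer)
        sub_scores = _subset_scores(report_scores, tested)
        sub_freqs = _subset_freqs(freqs, tested)
        assignments = assign_categories(sub_freqs, alpha=alpha, super_alpha=super_alpha)
        summary = summarize_categories(assignments, max(len(tested), 1))
        results[variant] = VariantResult(variant, sub_scores, sub_freqs, assignments, summary, tested)
    return results


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """File-to-file run; returns the in-memory bundle it also writes.

    Stages: read tree and occurrences; native-status and bounding-box
    filters (when annotation tables are present); incidence; optional
    under-sampling exclusion via the species-area model; per-variant
    metrics, null test and categories; TSV results + JSON metadata.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tree = read_newick(config.tree_path)
    occ = read_occurrences(config.occurrences_path, config.occurrence_dialect)
    records = list(occ)

    island_table = None
    if config.island_table_path:
        island_table = read_island_table(config.island_table_path)

    annotations = None
    if config.continental_path or config.bbox_path or config.native_status_path:
        annotations = GenusAnnotations.from_frames(
            pd.read_csv(config.continental_path) if config.continental_path else None,
            pd.read_csv(config.bbox_path) if config.bbox_path else None,
            pd.read_csv(config.native_status_path) if config.native_status_path else None,
        )
        reports = {}
        if annotations.native_status and island_table is not None and "region" in island_table.columns:
            region_map = island_table["region"].to_dict()
            records, rep = filter_native_status(records, annotations, region_map)
            reports[rep.rule] = rep
        if annotations.bounding_box:
            records, rep = filter_bounding_box(records, annotations)
            reports[rep.rule] = rep
        for rep in reports.values():
            logger.info("%s: removed %d / %d records", rep.rule, rep.n_removed, rep.n_input)

    incidence = build_incidence(records, tree)

    excluded: list[str] = []
    if island_table is not None and {"area", "richness"} <= set(island_table.columns):
        model = fit_richness_model(island_table)
        retained, report = exclude_undersampled(island_table, model, config.undersampling_factor)
        keep = [i for i in incidence.island_ids if i in set(retained)]
        excluded = [i for i in incidence.island_ids if i not in set(retained)]
        incidence = incidence.subset_islands(keep)
        report.to_csv(out / "undersampling_report.tsv", sep="\t", index=False)

    variants = tuple(
        v for v in config.variants
        if v == "expanded" or (annotations is not None and annotations.continental)
    )
    results = run_analysis(
        tree,
        incidence,
        annotations=annotations,
        variants=variants,
        alpha=config.alpha,
        super_alpha=config.super_alpha,
        n_sims=config.n_sims,
        seed=config.seed,
        n_max=config.n_max,
        burn_in=config.burn_in,
        thinning=config.thinning,
    )
    for variant, res in results.items():
        write_results(res.scores, res.frequencies, res.assignments, out / f"results_{variant}.tsv")
        res.summary.to_csv(out / f"summary_{variant}.tsv", sep="\t")
    if {"expanded", "restricted"} <= set(results):
        change = compare_variants(
            results["expanded"].assignments, results["restricted"].assignments
        )
        change.to_csv(out / "category_changes.tsv", sep="\t", index=False)
    write_run_metadata(
        out / "run_metadata.json",
        seed=config.seed,
        n_sims=config.n_sims,
        alpha=config.alpha,
        super_alpha=config.super_alpha,
        n_records=len(records),
        n_rejected=occ.n_rejected,
        n_islands=incidence.n_islands,
        n_genera=incidence.n_genera,
        excluded_undersampled=excluded,
        variants=list(results),
    )
    return {"incidence": incidence, "results": results, "excluded": excluded}


def sensitivity_sweep(
    tree: DatedTree,
    incidence: IncidenceMatrix,
    icer: Mapping[str, float],
    thresholds: Sequence[float],
    annotations: GenusAnnotations | None = None,
    variant: str = "expanded",
    **analysis_kwargs,
) -> pd.DataFrame:
    """Re-run the analysis on islands with ICEr >= t for each threshold t.

    Returns one row per island with its category at every threshold (NaN
    when excluded) and a ``stable`` flag: the category never changed while
    the island remained in the analysis.  Thresholds excluding every
    island are skipped with a warning.
    """
    cols: dict[float, dict[str, str]] = {}
    for t in thresholds:
        keep = [i for i in incidence.island_ids if icer.get(i, 1.0) >= t]
        if not keep:
            logger.warning("threshold %s excludes all islands; skipped", t)
            continue
        sub = incidence.subset_islands(keep)
        res = run_analysis(tree, sub, annotations, variants=(variant,), **analysis_kwargs)
        cols[t] = res[variant].assignments
    if not cols:
        raise ConfigurationError("no sweep point retained any island")
    df = pd.DataFrame({f"t_{t:g}": pd.Series(a) for t, a in sorted(cols.items())})
    df.index.name = "island_id"

    def _stable(row) -> bool:
        seen = [v for v in row if isinstance(v, str)]
        return len(set(seen)) <= 1

    df["stable"] = df.apply(_stable, axis=1)
    return df.sort_index()
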