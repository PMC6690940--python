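"""Occurrence cleaning and island-exclusion rules.

Natural-history occurrence data carry misidentifications, introductions and
georeferencing errors, and island floras are unevenly sampled.  Before any
endemism arithmetic, the pipeline therefore

* removes records whose genus is flagged non-native in the island's region
  (unknown status falls through to the next test),
* removes records falling outside the genus's native-range bounding box
  (boundary-inclusive; boxes crossing the antimeridian are handled as two
  longitude segments),
* excludes islands whose observed richness is more than ``factor`` (default
  5) times below the richness predicted by a species-area model — a sign of
  under-sampling rather than genuine poverty,
* scores each island's sampling completeness with the relative incidence
  coverage estimator ICEr = S_obs / S_ICE, used by the sensitivity sweep.

Every filter returns the retained records plus a per-rule exclusion report,
and each filter is idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import (
    ConfigurationError,
    GenusAnnotations,
    OccurrenceRecord,
    ValidationError,
)

logger = logging.getLogger("islandpe.preprocessing")

__all__ = [
    "FilterReport",
    "filter_native_status",
    "filter_bounding_box",
    "RichnessModel",
    "fit_richness_model",
    "exclude_undersampled",
    "CoverageScore",
    "ice_richness",
    "ice_coverage",
    "ICE_INFREQUENT_CUTOFF",
]


@dataclass
class FilterReport:
    """Bookkeeping for one cleaning rule (supports the bias audit trail)."""

    rule: str
    n_input: int = 0
    n_removed: int = 0
    n_untested: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


def filter_native_status(
    records: Iterable[OccurrenceRecord],
    annotations: GenusAnnotations,
    island_region: Mapping[str, str],
) -> tuple[list[OccurrenceRecord], FilterReport]:
    """Drop records whose genus is known non-native in the island's region.

    Unknown status (or an island with no region mapping) passes through and
    is counted as untested — the bounding-box filter still applies to it.
    """
    kept: list[OccurrenceRecord] = []
    rep = FilterReport("native_status")
    for rec in records:
        rep.n_input += 1
        region = island_region.get(rec.island_id)
        if region is None:
            logger.warning("island %s has no region mapping; record passes", rec.island_id)
            rep.n_untested += 1
            kept.append(rec)
            continue
        status = annotations.native_status.get((rec.genus, region))
        if status is None:
            rep.n_untested += 1
            kept.append(rec)
        elif status == "non_native":
            rep.n_removed += 1
        else:
            kept.append(rec)
    return kept, rep


def filter_bounding_box(
    records: Iterable[OccurrenceRecord],
    annotations: GenusAnnotations,
) -> tuple[list[OccurrenceRecord], FilterReport]:
    """Drop records strictly outside their genus's native bounding box.

    Points exactly on a box edge are retained.  Genera without a box pass
    with a warning (counted untested).
    """
    kept: list[OccurrenceRecord] = []
    rep = FilterReport("bounding_box")
    warned: set[str] = set()
    for rec in records:
        rep.n_input += 1
        box = annotations.bounding_box.get(rec.genus)
        if box is None:
            if rec.genus not in warned:
                logger.warning("genus %s has no bounding box; records pass", rec.genus)
                warned.add(rec.genus)
            rep.n_untested += 1
            kept.append(rec)
        elif box.contains(rec.latitude, rec.longitude):
            kept.append(rec)
        else:
            rep.n_removed += 1
    return kept, rep


# ---------------------------------------------------------------------------
# Species-area richness model and under-sampling exclusion
# ---------------------------------------------------------------------------


@dataclass
class RichnessModel:
    """log10(richness) ~ log10(area) [+ log10(1 + isolation)] OLS fit."""

    intercept: float
    slope_area: float
    slope_isolation: float | None
    n_islands: int
    reliable: bool
    _results: object = field(default=None, repr=False, compare=False)

    def predict(self, area, isolation=None) -> np.ndarray:
        area = np.asarray(area, dtype=float)
        if (area <= 0).any():
            raise ValidationError("areas must be positive")
        log_pred = self.intercept + self.slope_area * np.log10(area)
        if self.slope_isolation is not None:
            if isolation is None:
                raise ConfigurationError("model was fitted with isolation; pass it")
            log_pred = log_pred + self.slope_isolation * np.log10(1.0 + np.asarray(isolation, dtype=float))
        return 10.0 ** log_pred


def fit_richness_model(
    island_table: pd.DataFrame,
    use_isolation: bool = False,
) -> RichnessModel:
    """Fit the species-area power law S = c * A^z on the log10 scale.

    ``island_table`` needs ``richness`` and ``area`` columns (positive), and
    ``isolation`` (distance to continent, >= 0) when ``use_isolation``.
    Fits on fewer than 10 islands proceed but are flagged unreliable.
    """
    df = island_table
    for col in ("richness", "area"):
        if col not in df.columns:
            raise ConfigurationError(f"island table lacks column {col!r}")
    if (df["area"] <= 0).any() or (df["richness"] <= 0).any():
        raise ValidationError("richness and area must be positive for the log-log fit")
    if df["area"].nunique() == 1:
        raise ValidationError("degenerate design: all island areas equal")

    y = np.log10(df["richness"].to_numpy(float))
    X = np.log10(df["area"].to_numpy(float))[:, None]
    if use_isolation:
        if "isolation" not in df.columns:
            raise ConfigurationError("use_isolation=True needs an 'isolation' column")
        X = np.column_stack([X, np.log10(1.0 + df["isolation"].to_numpy(float))])
    Xc = sm.add_constant(X)
    res = sm.OLS(y, Xc).fit()
    n = len(df)
    reliable = n >= 10
    if not reliable:
        logger.warning("richness model fitted on only %d islands: unreliable", n)
    return RichnessModel(
        intercept=float(res.params[0]),
        slope_area=float(res.params[1]),
        slope_isolation=float(res.params[2]) if use_isolation else None,
        n_islands=n,
        reliable=reliable,
        _results=res,
    )


def exclude_undersampled(
    island_table: pd.DataFrame,
    model: RichnessModel,
    factor: float = 5.0,
) -> tuple[list[str], pd.DataFrame]:
    """Exclude islands with observed richness below predicted/factor.

    Returns (retained island ids, exclusion report with observed and
    predicted richness for every excluded island).
    """
    if factor <= 1:
        raise ConfigurationError("factor must exceed 1")
    iso = island_table["isolation"] if model.slope_isolation is not None else None
    predicted = model.predict(island_table["area"], iso)
    observed = island_table["richness"].to_numpy(float)
    excluded = observed < predicted / factor
    ids = island_table["island_id"].astype(str).tolist()
    report = pd.DataFrame(
        {
            "island_id": ids,
            "observed": observed,
            "predicted": predicted,
            "excluded": excluded,
        }
    )
    retained = [i for i, ex in zip(ids, excluded) if not ex]
    if excluded.any():
        logger.info("excluded %d under-sampled island(s)", int(excluded.sum()))
    return retained, report


# ---------------------------------------------------------------------------
# ICE sampling-coverage estimator
# ---------------------------------------------------------------------------

ICE_INFREQUENT_CUTOFF = 10


@dataclass
class CoverageScore:
    island_id: str
    s_obs: int
    s_ice: float
    icer: float  # S_obs / S_ICE, in (0, 1] when stable
    stable: bool = True

    def __post_init__(self):
        if self.stable and not (0.0 < self.icer <= 1.0 + 1e-12):
            raise ValidationError(f"ICEr out of (0,1]: {self.icer}")


def ice_richness(unit_by_taxon: np.ndarray, cutoff: int = ICE_INFREQUENT_CUTOFF) -> tuple[float, bool]:
    """Incidence-based coverage estimate of true richness (Lee-Chao ICE).

    ``unit_by_taxon`` is a binary sampling-units x taxa matrix.  Taxa found
    in <= ``cutoff`` units are "infrequent"; with Q_j the number of taxa in
    exactly j units, N_inf = sum j*Q_j, and sample coverage
    C_ICE = 1 - Q_1/N_inf,

        S_ICE = S_freq + S_inf/C_ICE + (Q_1/C_ICE) * gamma^2,

    where gamma^2 is the squared CV of infrequent-taxon incidences
    (truncated at 0).  When every infrequent taxon is a singleton C_ICE = 0
    and the estimator is undefined; a Chao2-style fallback is returned with
    ``stable=False``.  Returns (S_ICE, stable).
    """
    m = np.asarray(unit_by_taxon)
    if m.ndim != 2 or m.size == 0:
        raise ValidationError("need a non-empty units x taxa incidence matrix")
    if not np.isin(m, (0, 1)).all():
        raise ValidationError("unit incidence must be binary")
    freq = m.sum(axis=0)  # incidence frequency per taxon
    freq = freq[freq > 0]
    s_obs = freq.size
    if s_obs == 0:
        raise ValidationError("no taxa observed")
    infreq = freq[freq <= cutoff]
    s_freq = int((freq > cutoff).sum())
    s_inf = infreq.size
    if s_inf == 0:
        return float(s_obs), True  # all taxa frequent: coverage complete
    q1 = int((infreq == 1).sum())
    q2 = int((infreq == 2).sum())
    n_inf = int(infreq.sum())
    if n_inf == q1:  # all infrequent taxa are singletons -> C_ICE = 0
        if q2 > 0:
            s_ice = s_obs + q1 * q1 / (2.0 * q2)
        else:
            s_ice = s_obs + q1 * (q1 - 1) / 2.0
        return float(max(s_ice, s_obs)), False
    c_ice = 1.0 - q1 / n_inf
    # number of sampling units containing at least one infrequent taxon
    infreq_cols = np.flatnonzero((m.sum(axis=0) > 0) & (m.sum(axis=0) <= cutoff))
    m_inf = int((m[:, infreq_cols].sum(axis=1) > 0).sum())
    if m_inf > 1:
        j = np.arange(1, cutoff + 1)
        qj = np.array([(infreq == jj).sum() for jj in j], dtype=float)
        gamma2 = (s_inf / c_ice) * (m_inf / (m_inf - 1.0)) * (
            float((j * (j - 1) * qj).sum()) / (n_inf * n_inf)
        ) - 1.0
        gamma2 = max(gamma2, 0.0)
    else:
        gamma2 = 0.0
    s_ice = s_freq + s_inf / c_ice + (q1 / c_ice) * gamma2
    return float(max(s_ice, s_obs)), True


def ice_coverage(
    island_units: Mapping[str, np.ndarray],
    cutoff: int = ICE_INFREQUENT_CUTOFF,
) -> dict[str, CoverageScore]:
    """ICEr per island from each island's sampling-units x taxa matrix.

    Islands with zero sampling units are flagged (score undefined); when no
    infrequent taxa exist ICEr = 1 exactly.
    """
    out: dict[str, CoverageScore] = {}
    for isl, m in island_units.items():
        m = np.asarray(m)
        if m.size == 0 or m.sum() == 0:
            logger.warning("island %s has no sampling units: ICEr undefined", isl)
            out[isl] = CoverageScore(isl, 0, float("nan"), float("nan"), stable=False)
            continue
        s_ice, stable = ice_richness(m, cutoff)
        s_obs = int((m.sum(axis=0) > 0).sum())
        icer = min(s_obs / s_ice, 1.0)
        out[isl] = CoverageScore(isl, s_obs, s_ice, icer, stable=stable)
    return out
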