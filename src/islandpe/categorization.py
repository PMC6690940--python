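"""Categorical classification of islands by endemism type.

An island is a *significant* area of phylogenetic endemism when the RPE
numerator (PE), denominator (PEalt) or both are significantly high against
the null ensemble.  Significant islands are then split into non-overlapping
categories, evaluated in a fixed precedence order:

1. **paleo** — RPE significantly high: rare long (old) branches dominate.
2. **neo** — RPE significantly low: rare short (young) branches dominate.
3. **super** — both PE and PEalt in the highest 1% of the null
   distribution; an extreme case of mixed endemism.
4. **mixed** — both PE and PEalt significantly high, RPE in neither tail:
   rare long and rare short branches co-occur.

Significant islands matching none of the four (e.g. only PEalt high with a
middling ratio) are labeled ``significant_other`` so nothing is silently
dropped; they are excluded from four-category summaries.  Thresholds are
inclusive (freq >= 0.95, i.e. alpha = 0.05; super at 0.99).
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import round_sig
from .io_formats import ConfigurationError
from .null_model import TailFrequencies

logger = logging.getLogger("islandpe.categories")

__all__ = [
    "CATEGORIES",
    "FOUR_CATEGORIES",
    "assign_category",
    "assign_categories",
    "compare_variants",
    "summarize_categories",
]

CATEGORIES = (
    "not_significant",
    "significant_other",
    "neo",
    "paleo",
    "mixed",
    "super",
)
FOUR_CATEGORIES = ("paleo", "neo", "mixed", "super")


def assign_category(
    freq_pe_high: float,
    freq_pealt_high: float,
    freq_rpe_high: float,
    freq_rpe_low: float,
    alpha: float = 0.05,
    super_alpha: float = 0.01,
) -> str:
    """Classify one island from its four tail frequencies.

    Raises ValueError on NaN input (the island is unclassifiable and must
    be flagged by the caller).
    """
    vals = (freq_pe_high, freq_pealt_high, freq_rpe_high, freq_rpe_low)
    if any(not math.isfinite(v) for v in vals):
        raise ValueError("NaN/inf tail frequency: island unclassifiable")
    if not all(0.0 <= v <= 1.0 for v in vals):
        raise ValueError(f"tail frequencies outside [0, 1]: {vals}")
    if not (0 < super_alpha < alpha):
        raise ConfigurationError("need alpha > super_alpha > 0")

    hi, s_hi = 1.0 - alpha, 1.0 - super_alpha
    significant = freq_pe_high >= hi or freq_pealt_high >= hi
    if not significant:
        return "not_significant"
    if freq_rpe_high >= hi:
        return "paleo"
    if freq_rpe_low >= hi:
        return "neo"
    if freq_pe_high >= s_hi and freq_pealt_high >= s_hi:
        return "super"
    if freq_pe_high >= hi and freq_pealt_high >= hi:
        return "mixed"
    return "significant_other"


def assign_categories(
    freqs: TailFrequencies,
    alpha: float = 0.05,
    super_alpha: float = 0.01,
) -> dict[str, str]:
    """Per-island categories; NaN frequencies yield ``unclassifiable``."""
    out: dict[str, str] = {}
    fh, fl = freqs.freq_higher, freqs.freq_lower
    for k, isl in enumerate(freqs.island_ids):
        try:
            out[isl] = assign_category(
                float(fh["PE"][k]),
                float(fh["PEalt"][k]),
                float(fh["RPE"][k]),
                float(fl["RPE"][k]),
                alpha=alpha,
                super_alpha=super_alpha,
            )
        except ValueError:
            logger.warning("island %s unclassifiable (NaN frequency)", isl)
            out[isl] = "unclassifiable"
    return out


def compare_variants(
    assign_expanded: Mapping[str, str],
    assign_restricted: Mapping[str, str],
) -> pd.DataFrame:
    """Category-change table between the expanded and restricted runs.

    Islands missing from the restricted assignment (no island-restricted
    genus) are labeled ``excluded_R``; ``direction`` reads "expanded->restricted".
    """
    rows = []
    for isl in sorted(assign_expanded):
        cat_e = assign_expanded[isl]
        if isl in assign_restricted:
            cat_r = assign_restricted[isl]
            changed = cat_e != cat_r
        else:
            cat_r = "excluded_R"
            changed = True
        rows.append(
            {
                "island_id": isl,
                "category_expanded": cat_e,
                "category_restricted": cat_r,
                "changed": changed,
                "direction": f"{cat_e}->{cat_r}",
            }
        )
    return pd.DataFrame(rows, columns=[
        "island_id", "category_expanded", "category_restricted", "changed", "direction",
    ])


def summarize_categories(
    assignments: Mapping[str, str] | Sequence[str] | Mapping[str, int],
    total_islands: int,
    sig_figs: int = 2,
) -> pd.DataFrame:
    """Counts and percentages of the analyzed-island total per category.

    Accepts per-island labels or precomputed ``{category: count}``.
    Percentages are 100*count/total rounded to ``sig_figs`` significant
    figures (the reporting precision used throughout); ``significant``
    aggregates the four endemism categories.
    """
    if total_islands <= 0:
        raise ConfigurationError("total_islands must be positive")
    if isinstance(assignments, Mapping) and assignments and all(
        isinstance(v, (int, np.integer)) for v in assignments.values()
    ):
        counts = dict(assignments)
    else:
        labels = list(assignments.values()) if isinstance(assignments, Mapping) else list(assignments)
        counts = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
    n_assigned = sum(counts.values())
    if n_assigned > total_islands:
        raise ConfigurationError("more assigned islands than total_islands")

    rows = []
    for cat in CATEGORIES:
        c = int(counts.get(cat, 0))
        rows.append({"category": cat, "count": c, "percent": round_sig(100.0 * c / total_islands, sig_figs)})
    sig = sum(int(counts.get(c, 0)) for c in FOUR_CATEGORIES)
    rows.append(
        {"category": "significant", "count": sig, "percent": round_sig(100.0 * sig / total_islands, sig_figs)}
    )
    return pd.DataFrame(rows).set_index("category")
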