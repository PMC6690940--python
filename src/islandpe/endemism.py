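"""Phylogenetic endemism metrics on island presence-absence data.

Phylogenetic endemism (PE) weights every branch of a dated phylogeny by the
inverse of its geographic range and sums the weighted lengths over the
branches an assemblage touches.  Here the range of a branch is R_c, the
number of islands harboring at least one genus descended from it, so for
island i

    PE(i) = sum over branches c on i's tip-to-root paths of  l_c / R_c .

Two range variants are supported:

* ``expanded`` — R_c as counted from the incidence matrix; every genus
  native to an island contributes fully, whether or not it also occurs on
  a continent.
* ``restricted`` — any branch supporting at least one continent-occurring
  genus has its denominator replaced wholesale by N_max (by default the
  number of islands in the matrix), so island-restricted lineages dominate
  and continental genera have almost no influence.

PEalt is PE recomputed with every branch length replaced by a single
uniform length (by default the mean branch length of the tree), keeping the
topology; it isolates the contribution of branch *rarity* from branch
*length*.  RPE = PE / PEalt: islands dominated by rare long branches have
RPE above the null expectation, islands dominated by rare short branches
below it.

The heavy lifting is one boolean matrix product between the incidence
matrix and the tree's branch-by-tip descendant matrix, which makes the
null-model loop (recomputing everything on thousands of randomized
matrices) a batched tensor contraction; see :class:`MetricEngine`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import (
    ConfigurationError,
    DatedTree,
    GenusAnnotations,
    IncidenceMatrix,
    ValidationError,
)

logger = logging.getLogger("islandpe.endemism")

__all__ = [
    "BranchRangeTable",
    "EndemismScores",
    "MetricEngine",
    "branch_ranges",
    "pe",
    "pe_alt",
    "rpe",
    "compute_scores",
    "restrict_islands",
]

VARIANTS = ("expanded", "restricted")


@dataclass
class BranchRangeTable:
    """Per-branch island ranges under one weighting variant.

    ``presence[i, c]`` says island i carries branch c (some descendant genus
    of c is present on i); ``r`` is the island count per branch and
    ``r_effective`` the denominator actually used (``N_max`` for branches
    with continental support under the restricted variant).
    """

    variant: str
    presence: np.ndarray  # (n_islands, n_branches) bool
    r: np.ndarray  # (n_branches,) int
    continental_support: np.ndarray  # (n_branches,) bool
    r_effective: np.ndarray  # (n_branches,) float
    n_max: int

    def island_set(self, branch: int, island_ids: Sequence[str]) -> set[str]:
        return {island_ids[k] for k in np.flatnonzero(self.presence[:, branch])}


@dataclass
class EndemismScores:
    """Per-island PE, PEalt and RPE for one variant."""

    variant: str
    island_ids: list[str]
    pe: np.ndarray
    pe_alt: np.ndarray
    rpe: np.ndarray
    l_uniform: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "island_id": self.island_ids,
                "variant": self.variant,
                "PE": self.pe,
                "PEalt": self.pe_alt,
                "RPE": self.rpe,
            }
        ).set_index("island_id", drop=False)


def _align_genera(tree: DatedTree, incidence: IncidenceMatrix) -> np.ndarray:
    """Descendant matrix restricted to (and ordered as) the incidence columns."""
    idx = tree.tip_index
    missing = [g for g in incidence.genus_names if g not in idx]
    if missing:
        raise ValidationError(f"incidence genera absent from tree: {missing[:10]}")
    cols = np.array([idx[g] for g in incidence.genus_names], dtype=np.int64)
    return tree.desc[:, cols]


class MetricEngine:
    """Precomputed arrays for fast (batched) PE/PEalt/RPE evaluation.

    Built once per (tree, genus set, variant); ``scores`` evaluates one
    incidence matrix, ``scores_batch`` a stack of them (the null-model hot
    path).  Branches no descendant of which is in the genus set simply never
    appear on any island and drop out.
    """

    def __init__(
        self,
        tree: DatedTree,
        genus_names: Sequence[str],
        variant: str = "expanded",
        annotations: GenusAnnotations | None = None,
        n_max: int | None = None,
        l_uniform: float | None = None,
    ):
        if variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {variant!r}")
        if variant == "restricted" and annotations is None:
            raise ConfigurationError("restricted variant requires continental flags")
        self.variant = variant
        self.tree = tree
        self.genus_names = list(genus_names)
        idx = tree.tip_index
        missing = [g for g in self.genus_names if g not in idx]
        if missing:
            raise ValidationError(f"genera absent from tree: {missing[:10]}")
        cols = np.array([idx[g] for g in self.genus_names], dtype=np.int64)
        self.desc = tree.desc[:, cols]  # (n_br, n_gen) bool
        self.desc_f = self.desc.astype(np.float32)
        self.lengths = tree.branch_lengths.astype(np.float64)
        self.l_uniform = float(l_uniform) if l_uniform is not None else tree.mean_branch_length
        if self.l_uniform <= 0:
            raise ConfigurationError("l_uniform must be > 0")
        if annotations is not None:
            cont = annotations.continental_vector(self.genus_names)
            self.continental_branch = self.desc @ cont  # any continental descendant
        else:
            self.continental_branch = np.zeros(self.desc.shape[0], dtype=bool)
        self.n_max = n_max  # resolved per matrix when None

    def _resolve_nmax(self, n_islands: int) -> int:
        n = self.n_max if self.n_max is not None else n_islands
        if self.variant == "restricted" and n < n_islands:
            raise ConfigurationError(
                f"N_max={n} smaller than island count {n_islands}"
            )
        return int(n)

    def ranges(self, matrix: np.ndarray) -> BranchRangeTable:
        m = np.asarray(matrix, dtype=np.int64)
        presence = (m @ self.desc.T.astype(np.int64)) > 0  # (n_isl, n_br)
        r = presence.sum(axis=0).astype(np.int64)
        n_max = self._resolve_nmax(m.shape[0])
        r_eff = r.astype(float)
        if self.variant == "restricted":
            r_eff[self.continental_branch] = float(n_max)
        return BranchRangeTable(self.variant, presence, r, self.continental_branch.copy(), r_eff, n_max)

    def scores_from_ranges(self, ranges: BranchRangeTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        active = ranges.r > 0
        w_pe = np.zeros_like(ranges.r_effective)
        w_alt = np.zeros_like(ranges.r_effective)
        w_pe[active] = self.lengths[active] / ranges.r_effective[active]
        w_alt[active] = self.l_uniform / ranges.r_effective[active]
        pres = ranges.presence.astype(np.float64)
        pe_v = pres @ w_pe
        alt_v = pres @ w_alt
        with np.errstate(divide="ignore", invalid="ignore"):
            rpe_v = np.where(alt_v > 0, pe_v / alt_v, np.nan)
        return pe_v, alt_v, rpe_v

    def scores(self, matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(PE, PEalt, RPE) arrays for one islands x genera binary matrix."""
        return self.scores_from_ranges(self.ranges(matrix))

    def scores_batch(self, matrices: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized scores for a (n_sims, n_islands, n_genera) stack."""
        ms = np.ascontiguousarray(matrices, dtype=np.float32)
        pres = (ms @ self.desc_f.T) > 0  # (s, n_isl, n_br)
        r = pres.sum(axis=1).astype(np.float64)  # (s, n_br)
        n_max = self._resolve_nmax(ms.shape[1])
        r_eff = r.copy()
        if self.variant == "restricted":
            r_eff[:, self.continental_branch] = float(n_max)
        active = r > 0
        w_pe = np.zeros_like(r_eff)
        w_alt = np.zeros_like(r_eff)
        np.divide(self.lengths[None, :], r_eff, out=w_pe, where=active)
        np.divide(self.l_uniform, r_eff, out=w_alt, where=active)
        pres64 = pres.astype(np.float64)
        pe_v = np.einsum("sib,sb->si", pres64, w_pe)
        alt_v = np.einsum("sib,sb->si", pres64, w_alt)
        with np.errstate(divide="ignore", invalid="ignore"):
            rpe_v = np.where(alt_v > 0, pe_v / alt_v, np.nan)
        return pe_v, alt_v, rpe_v


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------


def branch_ranges(
    tree: DatedTree,
    incidence: IncidenceMatrix,
    annotations: GenusAnnotations | None = None,
    variant: str = "expanded",
    n_max: int | None = None,
) -> BranchRangeTable:
    """Island ranges R_c per branch (and restricted denominators).

    The island set of a branch is the union of the island sets of its
    descendant tips; under ``restricted`` any branch with at least one
    continental descendant genus gets denominator ``n_max`` (default: the
    number of islands in the matrix).
    """
    eng = MetricEngine(tree, incidence.genus_names, variant, annotations, n_max)
    return eng.ranges(incidence.matrix)


def pe(
    tree: DatedTree,
    ranges: BranchRangeTable,
    incidence: IncidenceMatrix,
) -> np.ndarray:
    """PE(i) = sum of l_c / R_c over branches present on island i."""
    if (ranges.presence.any(axis=0) & (ranges.r == 0)).any():
        raise ValidationError("branch present on an island but R_c == 0")
    lengths = _branch_lengths_for(tree, ranges)
    active = ranges.r > 0
    w = np.zeros_like(ranges.r_effective)
    w[active] = lengths[active] / ranges.r_effective[active]
    out = ranges.presence.astype(float) @ w
    empty = incidence.row_sums == 0
    if empty.any():
        logger.warning("%d island(s) with no genera get PE = 0", int(empty.sum()))
    return out


def pe_alt(
    tree: DatedTree,
    ranges: BranchRangeTable,
    incidence: IncidenceMatrix,
    l_uniform: float | None = None,
) -> np.ndarray:
    """PEalt(i): PE with every branch length replaced by ``l_uniform``."""
    l_u = float(l_uniform) if l_uniform is not None else tree.mean_branch_length
    if l_u <= 0:
        raise ConfigurationError("l_uniform must be > 0")
    active = ranges.r > 0
    w = np.zeros_like(ranges.r_effective)
    w[active] = l_u / ranges.r_effective[active]
    return ranges.presence.astype(float) @ w


def rpe(pe_scores: np.ndarray, pealt_scores: np.ndarray) -> np.ndarray:
    """RPE(i) = PE(i)/PEalt(i); NaN (flagged) where PEalt is zero."""
    pe_scores = np.asarray(pe_scores, dtype=float)
    pealt_scores = np.asarray(pealt_scores, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(pealt_scores > 0, pe_scores / pealt_scores, np.nan)
    if np.isnan(out).any():
        logger.warning("%d island(s) with PEalt=0: RPE undefined", int(np.isnan(out).sum()))
    return out


def _branch_lengths_for(tree: DatedTree, ranges: BranchRangeTable) -> np.ndarray:
    if len(tree.branch_lengths) != ranges.presence.shape[1]:
        raise ValidationError("branch range table does not match tree")
    return tree.branch_lengths


def compute_scores(
    tree: DatedTree,
    incidence: IncidenceMatrix,
    annotations: GenusAnnotations | None = None,
    variant: str = "expanded",
    n_max: int | None = None,
    l_uniform: float | None = None,
) -> EndemismScores:
    """One-call PE/PEalt/RPE for every island in the incidence matrix."""
    eng = MetricEngine(tree, incidence.genus_names, variant, annotations, n_max, l_uniform)
    pe_v, alt_v, rpe_v = eng.scores(incidence.matrix)
    return EndemismScores(variant, list(incidence.island_ids), pe_v, alt_v, rpe_v, eng.l_uniform)


def restrict_islands(
    incidence: IncidenceMatrix,
    annotations: GenusAnnotations,
) -> list[str]:
    """Islands eligible for restricted-variant testing.

    Only islands harboring at least one island-restricted genus (continental
    flag False) are kept, so islands whose flora is entirely shared with
    continents cannot be flagged as centers of restricted endemism.
    """
    cont = annotations.continental_vector(incidence.genus_names)
    has_insular = (incidence.matrix[:, ~cont].sum(axis=1) > 0)
    return [i for i, ok in zip(incidence.island_ids, has_insular) if ok]
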