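"""Fixed-fixed randomization null model and tail frequencies.

PE, PEalt and RPE all grow with island richness, so observed values are
compared with a null ensemble in which genus occurrences are shuffled among
islands while every island keeps its number of genera (row sums) and every
genus keeps its number of island occurrences (column sums).  Matrices with
both marginals fixed are sampled with the curveball algorithm: repeated
"trades" between random island pairs that exchange a random subset of the
genera not shared by the two islands.  Each trade preserves both marginals
exactly, and the chain converges to the uniform distribution on the set of
matrices with the observed marginals.

One long chain is run, started at the observed matrix: ``burn_in`` accepted
trades are discarded, then a sample is emitted every ``thinning`` accepted
trades.  Defaults scale with matrix fill (5x and 1x the number of
presences).  For every sample the three metrics are recomputed from
scratch, and per-island tail counters record how often the observed value
strictly exceeds (or falls below) the simulated one; ties count in neither
tail, which is conservative toward non-significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from ._utils import as_rng
from .endemism import MetricEngine, EndemismScores
from .io_formats import (
    ConfigurationError,
    DatedTree,
    GenusAnnotations,
    IncidenceMatrix,
    ValidationError,
)

logger = logging.getLogger("islandpe.null")

__all__ = [
    "CurveballChain",
    "randomize_fixed_fixed",
    "NullEnsemble",
    "TailFrequencies",
    "null_metric_distribution",
    "tail_frequencies",
]

METRICS = ("PE", "PEalt", "RPE")


class CurveballChain:
    """Markov chain over binary matrices with both marginals fixed.

    The state is kept as one presence set per row.  A trade picks two
    distinct rows, pools the genera exclusive to each, and deals them back
    at random keeping each row's count — a step that is its own inverse and
    uniform over outcomes, so the stationary distribution on the fiber is
    uniform.  A trade is *accepted* when both exclusive sets are non-empty
    (otherwise nothing can move).
    """

    def __init__(self, matrix: np.ndarray, rng: np.random.Generator):
        m = np.asarray(matrix)
        if not np.isin(m, (0, 1)).all():
            raise ValidationError("curveball needs a binary matrix")
        self.shape = m.shape
        self.rows: list[set[int]] = [set(np.flatnonzero(r)) for r in m]
        self.rng = rng
        self.n_presences = int(m.sum())

    def trade(self) -> bool:
        """Attempt one trade; returns True when the state could change."""
        n = len(self.rows)
        if n < 2:
            return False
        i, j = self.rng.choice(n, size=2, replace=False)
        a, b = self.rows[i], self.rows[j]
        only_a = list(a - b)
        only_b = list(b - a)
        if not only_a or not only_b:
            return False
        pool = only_a + only_b
        self.rng.shuffle(pool)
        k = len(only_a)
        new_a, new_b = pool[:k], pool[k:]
        shared = a & b
        self.rows[i] = shared | set(new_a)
        self.rows[j] = shared | set(new_b)
        return True

    def _any_tradeable_pair(self) -> bool:
        rows = self.rows
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                if rows[i] - rows[j] and rows[j] - rows[i]:
                    return True
        return False

    def advance(self, n_accepted: int) -> None:
        """Perform ``n_accepted`` accepted trades.

        Matrices whose fixed-marginal fiber is a single point (e.g. all
        ones, or any state where no row pair has exclusive presences) are
        their own randomization; detected and returned as-is.
        """
        done = 0
        failed_streak = 0
        check_after = max(1000, 20 * len(self.rows))
        while done < n_accepted:
            if self.trade():
                done += 1
                failed_streak = 0
            else:
                failed_streak += 1
                if failed_streak >= check_after:
                    if not self._any_tradeable_pair():
                        return  # frozen state: unique fiber
                    failed_streak = 0

    def state(self) -> np.ndarray:
        out = np.zeros(self.shape, dtype=np.int8)
        for k, row in enumerate(self.rows):
            out[k, list(row)] = 1
        return out


def randomize_fixed_fixed(
    matrix: np.ndarray,
    seed,
    burn_in: int | None = None,
    thinning: int | None = None,
    n_samples: int | None = None,
    restart: bool = False,
) -> Iterator[np.ndarray]:
    """Yield binary matrices with exactly the marginals of ``matrix``.

    ``burn_in`` / ``thinning`` default to 5x / 1x the number of presences.
    With ``burn_in=0, thinning=0`` the first sample is the observed matrix
    itself (degenerate chain start).  ``restart=True`` re-burns the chain
    from the observed matrix for every sample (auditing mode; slower).
    """
    m = np.asarray(matrix)
    rng = as_rng(seed)
    n_pres = int(m.sum())
    if burn_in is None:
        burn_in = 5 * n_pres
    if thinning is None:
        thinning = n_pres
    if burn_in < 0 or thinning < 0:
        raise ConfigurationError("burn_in and thinning must be >= 0")

    count = 0
    if restart:
        while n_samples is None or count < n_samples:
            chain = CurveballChain(m, rng)
            chain.advance(burn_in)
            yield chain.state()
            count += 1
        return
    chain = CurveballChain(m, rng)
    chain.advance(burn_in)
    while n_samples is None or count < n_samples:
        if count > 0 or thinning > 0:
            chain.advance(thinning)
        yield chain.state()
        count += 1


@dataclass
class TailFrequencies:
    """Per-island tail frequencies against the null ensemble.

    ``freq_higher[m][i]`` is the proportion of simulations in which the
    observed metric ``m`` on island ``i`` strictly exceeded the simulated
    value; ``freq_lower`` the strict-below proportion.  Ties fall in
    neither tail, so the two sum to at most 1.
    """

    island_ids: list[str]
    n_sims: int
    freq_higher: dict[str, np.ndarray]
    freq_lower: dict[str, np.ndarray]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "island_id": self.island_ids,
                "freq_PE": self.freq_higher["PE"],
                "freq_PEalt_high": self.freq_higher["PEalt"],
                "freq_RPE_high": self.freq_higher["RPE"],
                "freq_RPE_low": self.freq_lower["RPE"],
            }
        ).set_index("island_id", drop=False)

    def row(self, island_id: str) -> dict[str, float]:
        k = self.island_ids.index(island_id)
        return {
            "freq_PE_high": float(self.freq_higher["PE"][k]),
            "freq_PEalt_high": float(self.freq_higher["PEalt"][k]),
            "freq_RPE_high": float(self.freq_higher["RPE"][k]),
            "freq_RPE_low": float(self.freq_lower["RPE"][k]),
        }


@dataclass
class NullEnsemble:
    """Streamed null distribution summary (optionally with full samples)."""

    island_ids: list[str]
    n_sims: int
    seed: int | None
    variant: str
    counts_higher: dict[str, np.ndarray]
    counts_lower: dict[str, np.ndarray]
    sums: dict[str, np.ndarray]
    sumsq: dict[str, np.ndarray]
    samples: dict[str, np.ndarray] | None = None  # (n_sims, n_islands) each
    streamed_observed: bool = False

    def mean(self, metric: str) -> np.ndarray:
        return self.sums[metric] / self.n_sims

    def std(self, metric: str) -> np.ndarray:
        v = self.sumsq[metric] / self.n_sims - self.mean(metric) ** 2
        return np.sqrt(np.maximum(v, 0.0))


def null_metric_distribution(
    tree: DatedTree,
    incidence: IncidenceMatrix,
    variant: str = "expanded",
    annotations: GenusAnnotations | None = None,
    n_sims: int = 1000,
    seed=0,
    observed: EndemismScores | None = None,
    burn_in: int | None = None,
    thinning: int | None = None,
    n_max: int | None = None,
    l_uniform: float | None = None,
    keep_samples: bool = False,
    chunk: int = 128,
) -> NullEnsemble:
    """Recompute PE/PEalt/RPE on ``n_sims`` fixed-marginal randomizations.

    Continental flags travel with genera (columns are shuffled across
    islands, never relabeled) and N_max is held fixed, so the restricted
    weighting rule applies identically in every simulation.  RPE under the
    null is the ratio of the *simulated* PE and PEalt.  When ``observed``
    is given, strict-tail counters accumulate as the chain streams.
    """
    if n_sims < 1:
        raise ConfigurationError("n_sims must be >= 1")
    eng = MetricEngine(tree, incidence.genus_names, variant, annotations, n_max, l_uniform)
    n_isl = incidence.n_islands
    counts_h = {m: np.zeros(n_isl, dtype=np.int64) for m in METRICS}
    counts_l = {m: np.zeros(n_isl, dtype=np.int64) for m in METRICS}
    sums = {m: np.zeros(n_isl) for m in METRICS}
    sumsq = {m: np.zeros(n_isl) for m in METRICS}
    kept = {m: [] for m in METRICS} if keep_samples else None

    obs_vals = None
    if observed is not None:
        if list(observed.island_ids) != list(incidence.island_ids):
            raise ValidationError("observed scores not aligned with incidence islands")
        obs_vals = {"PE": observed.pe, "PEalt": observed.pe_alt, "RPE": observed.rpe}

    stream = randomize_fixed_fixed(
        incidence.matrix, seed, burn_in=burn_in, thinning=thinning, n_samples=n_sims
    )
    buffer: list[np.ndarray] = []

    def flush():
        if not buffer:
            return
        stack = np.stack(buffer)
        pe_v, alt_v, rpe_v = eng.scores_batch(stack)
        for name, vals in (("PE", pe_v), ("PEalt", alt_v), ("RPE", rpe_v)):
            sums[name] += np.nansum(vals, axis=0)
            sumsq[name] += np.nansum(vals**2, axis=0)
            if obs_vals is not None:
                obs = obs_vals[name][None, :]
                counts_h[name] += (obs > vals).sum(axis=0)
                counts_l[name] += (obs < vals).sum(axis=0)
            if kept is not None:
                kept[name].append(vals)
        buffer.clear()

    for sample in stream:
        buffer.append(sample)
        if len(buffer) >= chunk:
            flush()
    flush()

    samples = {m: np.concatenate(kept[m], axis=0) for m in METRICS} if kept else None
    return NullEnsemble(
        list(incidence.island_ids),
        n_sims,
        seed if isinstance(seed, int) else None,
        variant,
        counts_h,
        counts_l,
        sums,
        sumsq,
        samples,
        streamed_observed=obs_vals is not None,
    )


def tail_frequencies(observed: EndemismScores, ensemble: NullEnsemble) -> TailFrequencies:
    """Convert observed scores + ensemble into per-island tail frequencies.

    Uses the streamed counters when the ensemble was built against the same
    observed scores; otherwise recounts from stored samples.
    """
    if list(observed.island_ids) != list(ensemble.island_ids):
        raise ValidationError("observed scores and ensemble cover different islands")
    n = ensemble.n_sims
    if ensemble.streamed_observed:
        fh = {m: ensemble.counts_higher[m] / n for m in METRICS}
        fl = {m: ensemble.counts_lower[m] / n for m in METRICS}
    elif ensemble.samples is None:
        raise ValidationError(
            "ensemble has neither streamed counters nor stored samples"
        )
    else:
        obs = {"PE": observed.pe, "PEalt": observed.pe_alt, "RPE": observed.rpe}
        fh, fl = {}, {}
        for m in METRICS:
            sims = ensemble.samples[m]
            fh[m] = (obs[m][None, :] > sims).mean(axis=0)
            fl[m] = (obs[m][None, :] < sims).mean(axis=0)
    return TailFrequencies(list(ensemble.island_ids), n, fh, fl)
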