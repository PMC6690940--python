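"""Synthetic worlds for exercising and validating the endemism pipeline.

Real inputs for this kind of analysis are a dated genus-level phylogeny and
millions of occurrence records; neither is needed to validate the method.
This module generates worlds with the statistical structure the analysis
assumes — a Yule (pure-birth) tree with heterogeneous branch lengths, a
right-skewed islands-per-genus occupancy distribution, continental flags on
a fraction of widespread genera — plus *plantable* signal:

* a pool of rare genera on long terminal branches ("paleo pool", lengths
  multiplied by ``m_long``),
* a pool of rare genera on short terminal branches ("neo pool", multiplied
  by ``m_short``),
* designated islands whose floras are drawn preferentially from those
  pools, with concentration ``kappa`` (the probability that a pool genus
  is steered onto its designated islands rather than placed at random).

With ``kappa = 0`` planted islands are statistically indistinguishable
from background, so category recovery runs at chance; with ``kappa = 1``
and strong multipliers, planted islands should be recovered as paleo / neo
/ mixed centers.  Every output is byte-deterministic given (scenario,
seed), and occurrence records are emitted in the exact delimited formats
the real parsers read.

Genus names carry their pool ("Paleo###", "Neo###", "Bg###"): synthetic
data is self-documenting about where its signal was planted.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from ._utils import as_rng
from .categorization import FOUR_CATEGORIES
from .io_formats import (
    BoundingBox,
    DatedTree,
    GenusAnnotations,
    IncidenceMatrix,
    OccurrenceRecord,
    ValidationError,
)

logger = logging.getLogger("islandpe.synthetic")

__all__ = [
    "GenerationError",
    "SyntheticScenario",
    "SyntheticOccurrences",
    "generate_tree",
    "generate_incidence",
    "generate_occurrence_records",
    "generate_sampling_units",
    "RecoveryReport",
    "recovery_report",
    "null_scenario",
    "strong_planted_scenario",
]


class GenerationError(RuntimeError):
    """Raised when a scenario cannot be realized (e.g. pool too small)."""


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic world.

    Defaults describe a mid-sized archipelago system: 60 islands, 300
    genera, a zeta-distributed occupancy (exponent 2, strongly right-skewed
    as in natural-history occurrence data), 10% of genera in each rare
    pool, and 30% of background genera also occurring on continents.
    """

    n_genera: int = 300
    n_islands: int = 60
    seed: int = 0
    birth_rate: float = 0.1
    f_paleo: float = 0.1
    m_long: float = 10.0
    f_neo: float = 0.1
    m_short: float = 0.1
    occupancy_model: str = "zeta"  # "zeta" | "uniform"
    occupancy_exponent: float = 2.0
    uniform_max_occupancy: int = 5
    pool_max_occupancy: int = 2  # pool genera are rare by construction
    continental_fraction: float = 0.3
    planted_paleo: tuple[str, ...] = ()
    planted_neo: tuple[str, ...] = ()
    planted_mixed: tuple[str, ...] = ()
    kappa: float = 1.0
    max_records_per_presence: int = 3
    noise_out_of_box: float = 0.0
    noise_non_native: float = 0.0
    n_regions: int = 6

    def __post_init__(self):
        for name in ("f_paleo", "f_neo", "kappa", "continental_fraction",
                     "noise_out_of_box", "noise_non_native"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        planted = list(self.planted_paleo) + list(self.planted_neo) + list(self.planted_mixed)
        if len(planted) != len(set(planted)):
            raise ValidationError("planted island lists must be disjoint")
        if self.n_genera < 2:
            raise ValidationError("need at least 2 genera")

    # -- derived naming -----------------------------------------------------

    @property
    def island_ids(self) -> list[str]:
        return [f"I{k:04d}" for k in range(self.n_islands)]

    @property
    def n_paleo_pool(self) -> int:
        return int(round(self.f_paleo * self.n_genera))

    @property
    def n_neo_pool(self) -> int:
        return int(round(self.f_neo * self.n_genera))

    @property
    def paleo_pool(self) -> list[str]:
        return [f"Paleo{k:04d}" for k in range(self.n_paleo_pool)]

    @property
    def neo_pool(self) -> list[str]:
        return [f"Neo{k:04d}" for k in range(self.n_neo_pool)]

    @property
    def background(self) -> list[str]:
        n_bg = self.n_genera - self.n_paleo_pool - self.n_neo_pool
        return [f"Bg{k:04d}" for k in range(n_bg)]

    @property
    def genus_names(self) -> list[str]:
        return self.paleo_pool + self.neo_pool + self.background


def generate_tree(scenario: SyntheticScenario) -> DatedTree:
    """Pure-birth tree with scaled terminal branches for the rare pools.

    Tip labels are assigned to tree positions at random (seeded), then the
    terminal branch of every paleo-pool tip is multiplied by ``m_long`` and
    of every neo-pool tip by ``m_short``.  Internal branches are untouched,
    so pool tips are long/short *terminal* branches — the lever that makes
    an island's flora old or young.
    """
    pyrng = random.Random(scenario.seed)
    tree = treesim.birth_death_tree(
        birth_rate=scenario.birth_rate,
        death_rate=0.0,
        num_extant_tips=scenario.n_genera,
        rng=pyrng,
    )
    leaves = list(tree.leaf_node_iter())
    names = list(scenario.genus_names)
    pyrng.shuffle(names)
    tns = dendropy.TaxonNamespace()
    for leaf, name in zip(leaves, names):
        leaf.taxon = tns.new_taxon(label=name)
    tree.taxon_namespace = tns

    paleo = set(scenario.paleo_pool)
    neo = set(scenario.neo_pool)
    for leaf in leaves:
        if leaf.taxon.label in paleo:
            leaf.edge.length *= scenario.m_long
        elif leaf.taxon.label in neo:
            leaf.edge.length *= scenario.m_short
    out = DatedTree.from_dendropy(tree)
    logger.info(
        "synthetic tree: %d tips, mean branch length %.3f",
        out.n_tips, out.mean_branch_length,
    )
    return out


def _sample_occupancy(scenario: SyntheticScenario, rng: np.random.Generator, n: int) -> np.ndarray:
    """Islands-per-genus draws from the configured occupancy model."""
    kmax = scenario.n_islands
    if scenario.occupancy_model == "zeta":
        k = np.arange(1, kmax + 1, dtype=float)
        p = k ** (-scenario.occupancy_exponent)
        p /= p.sum()
        return rng.choice(np.arange(1, kmax + 1), size=n, p=p)
    if scenario.occupancy_model == "uniform":
        hi = min(scenario.uniform_max_occupancy, kmax)
        return rng.integers(1, hi + 1, size=n)
    raise ValidationError(f"unknown occupancy model {scenario.occupancy_model!r}")


def generate_incidence(
    scenario: SyntheticScenario,
    tree: DatedTree,
) -> tuple[IncidenceMatrix, GenusAnnotations]:
    """Incidence matrix with planted rare-pool concentrations.

    Background genera land on islands uniformly with skewed occupancy.
    Each pool genus is, with probability ``kappa``, steered onto the
    designated islands of its class (mixed islands are targets of both
    pools, dealt round-robin so every planted island receives a comparable
    share); otherwise it behaves like background.  Continental flags go to
    background genera only (pool genera are island endemics by design).
    """
    rng = as_rng(np.random.SeedSequence((scenario.seed, 1)))
    islands = scenario.island_ids
    isl_index = {i: k for k, i in enumerate(islands)}
    genera = [g for g in scenario.genus_names if g in set(tree.tip_labels)]
    if set(genera) != set(scenario.genus_names):
        raise GenerationError("tree does not carry the scenario's genus names")
    mat = np.zeros((len(islands), len(genera)), dtype=np.int8)
    gcol = {g: j for j, g in enumerate(genera)}

    paleo_targets = [isl_index[i] for i in scenario.planted_paleo + scenario.planted_mixed]
    neo_targets = [isl_index[i] for i in scenario.planted_neo + scenario.planted_mixed]
    for name, targets, pool in (
        ("paleo", paleo_targets, scenario.paleo_pool),
        ("neo", neo_targets, scenario.neo_pool),
    ):
        if targets and scenario.kappa > 0 and len(pool) < len(targets):
            raise GenerationError(
                f"{name} pool of {len(pool)} genera cannot cover "
                f"{len(targets)} planted islands"
            )
    bad = [i for i in scenario.planted_paleo + scenario.planted_neo + scenario.planted_mixed
           if i not in isl_index]
    if bad:
        raise GenerationError(f"planted islands not in this world: {bad}")

    occ = {g: int(k) for g, k in zip(genera, _sample_occupancy(scenario, rng, len(genera)))}
    pool_sets = {"paleo": set(scenario.paleo_pool), "neo": set(scenario.neo_pool)}
    for g in pool_sets["paleo"] | pool_sets["neo"]:
        occ[g] = int(rng.integers(1, scenario.pool_max_occupancy + 1))

    # round-robin cursors so planted islands share the pool evenly
    cursors = {"paleo": 0, "neo": 0}
    for g in genera:
        k = occ[g]
        pool = "paleo" if g in pool_sets["paleo"] else "neo" if g in pool_sets["neo"] else None
        targets = paleo_targets if pool == "paleo" else neo_targets if pool == "neo" else []
        if pool and targets and rng.random() < scenario.kappa:
            first = targets[cursors[pool] % len(targets)]
            cursors[pool] += 1
            chosen = {first}
            others = [t for t in targets if t != first]
            rng.shuffle(others)
            for t in others[: k - 1]:
                chosen.add(t)
            rows = list(chosen)
        else:
            rows = list(rng.choice(len(islands), size=min(k, len(islands)), replace=False))
        mat[rows, gcol[g]] = 1

    # no empty islands: seed each with one background genus
    empty = np.flatnonzero(mat.sum(axis=1) == 0)
    bg_cols = [gcol[g] for g in scenario.background] or list(range(len(genera)))
    for row in empty:
        mat[row, bg_cols[int(rng.integers(len(bg_cols)))]] = 1

    ann = GenusAnnotations()
    for g in genera:
        if g in pool_sets["paleo"] or g in pool_sets["neo"]:
            ann.continental[g] = False
        else:
            ann.continental[g] = bool(rng.random() < scenario.continental_fraction)

    inc = IncidenceMatrix(list(islands), genera, mat)
    return inc, ann


# ---------------------------------------------------------------------------
# Occurrence records with injected noise
# ---------------------------------------------------------------------------


@dataclass
class SyntheticOccurrences:
    """Occurrence records plus the bookkeeping that makes them an oracle."""

    records: list[OccurrenceRecord]
    island_table: pd.DataFrame  # island_id, latitude, longitude, area, region, richness
    island_region: dict[str, str]
    annotations: GenusAnnotations
    out_of_box_idx: frozenset[int]  # record indices planted outside their box
    non_native_idx: frozenset[int]  # record indices planted as non-native

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genus": [r.genus for r in self.records],
                "island_id": [r.island_id for r in self.records],
                "latitude": [r.latitude for r in self.records],
                "longitude": [r.longitude for r in self.records],
            }
        )


def generate_occurrence_records(
    scenario: SyntheticScenario,
    incidence: IncidenceMatrix,
    annotations: GenusAnnotations,
) -> SyntheticOccurrences:
    """Expand an incidence matrix into noisy occurrence records.

    Clean records (1..k per presence) sit at the island centroid with small
    jitter, inside their genus's bounding box and never flagged non-native.
    Noise records are *spurious presences* — (genus, island) pairs absent
    from the incidence — either placed outside the genus box or flagged
    non-native in the target island's region, so inverting the filters must
    recover the clean incidence exactly.
    """
    rng = as_rng(np.random.SeedSequence((scenario.seed, 2)))
    islands = list(incidence.island_ids)
    genera = list(incidence.genus_names)
    lat = rng.uniform(-60, 60, size=len(islands))
    lon = rng.uniform(-179, 179, size=len(islands))
    area = np.exp(rng.normal(2.0, 1.5, size=len(islands)))
    region = {isl: f"R{int(rng.integers(scenario.n_regions)):02d}" for isl in islands}

    jitter = 0.1
    margin = 2.0
    boxes: dict[str, BoundingBox] = {}
    for j, g in enumerate(genera):
        rows = np.flatnonzero(incidence.matrix[:, j])
        boxes[g] = BoundingBox(
            lat_min=max(float(lat[rows].min()) - margin, -90.0),
            lat_max=min(float(lat[rows].max()) + margin, 90.0),
            lon_min=max(float(lon[rows].min()) - margin, -180.0),
            lon_max=min(float(lon[rows].max()) + margin, 180.0),
        )
    annotations.bounding_box.update(boxes)

    records: list[OccurrenceRecord] = []
    for k, isl in enumerate(islands):
        for j in np.flatnonzero(incidence.matrix[k]):
            for _ in range(int(rng.integers(1, scenario.max_records_per_presence + 1))):
                records.append(
                    OccurrenceRecord(
                        genera[j],
                        isl,
                        float(np.clip(lat[k] + rng.normal(0, jitter), -90, 90)),
                        float(lon[k] + rng.normal(0, jitter)),
                    )
                )
    n_clean = len(records)

    present = {(islands[k], genera[j]) for k, j in zip(*np.nonzero(incidence.matrix))}
    genus_regions = {}
    for isl, g in present:
        genus_regions.setdefault(g, set()).add(region[isl])

    def spurious_pair(require_foreign_region: bool) -> tuple[str, str] | None:
        for _ in range(200):
            g = genera[int(rng.integers(len(genera)))]
            isl = islands[int(rng.integers(len(islands)))]
            if (isl, g) in present:
                continue
            if require_foreign_region and region[isl] in genus_regions.get(g, set()):
                continue
            return isl, g
        return None

    out_idx: set[int] = set()
    for _ in range(int(round(scenario.noise_out_of_box * n_clean))):
        pair = spurious_pair(require_foreign_region=False)
        if pair is None:
            break
        isl, g = pair
        box = boxes[g]
        bad_lat = box.lat_max + 5.0 if box.lat_max + 5.0 <= 90.0 else box.lat_min - 5.0
        out_idx.add(len(records))
        records.append(OccurrenceRecord(g, isl, float(bad_lat), float(lon[isl_idx(islands, isl)])))

    nn_idx: set[int] = set()
    for _ in range(int(round(scenario.noise_non_native * n_clean))):
        pair = spurious_pair(require_foreign_region=True)
        if pair is None:
            break
        isl, g = pair
        annotations.native_status[(g, region[isl])] = "non_native"
        box = boxes[g]
        inside_lat = float(np.clip((box.lat_min + box.lat_max) / 2.0, -90, 90))
        inside_lon = (box.lon_min + box.lon_max) / 2.0
        nn_idx.add(len(records))
        records.append(OccurrenceRecord(g, isl, inside_lat, float(inside_lon)))

    richness = incidence.row_sums
    table = pd.DataFrame(
        {
            "island_id": islands,
            "latitude": lat,
            "longitude": lon,
            "area": area,
            "region": [region[i] for i in islands],
            "richness": richness,
        }
    ).set_index("island_id", drop=False)

    return SyntheticOccurrences(
        records, table, region, annotations, frozenset(out_idx), frozenset(nn_idx)
    )


def isl_idx(islands: Sequence[str], isl: str) -> int:
    return islands.index(isl)


def generate_sampling_units(
    scenario: SyntheticScenario,
    incidence: IncidenceMatrix,
    n_units: int = 8,
    p_detect: float = 0.5,
) -> dict[str, np.ndarray]:
    """Per-island visit x genus detection matrices for the ICE coverage score.

    Each island gets ``n_units`` independent visits; every genus present on
    the island is detected on a visit with probability ``p_detect``.  A
    genus never detected across all visits is simply absent from that
    island's unit matrix (ICE works on what was seen).
    """
    rng = as_rng(np.random.SeedSequence((scenario.seed, 3)))
    out: dict[str, np.ndarray] = {}
    for k, isl in enumerate(incidence.island_ids):
        cols = np.flatnonzero(incidence.matrix[k])
        det = (rng.random((n_units, cols.size)) < p_detect).astype(np.int8)
        out[isl] = det
    return out


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    """Planted-class vs assigned-category confusion summary."""

    recall: dict[str, float]
    false_positive_rate: float
    confusion: pd.DataFrame
    n_planted: dict[str, int]
    n_unplanted: int


def recovery_report(
    assignments: Mapping[str, str],
    scenario: SyntheticScenario,
) -> RecoveryReport:
    """Score pipeline output against the planted truth.

    Recall of a planted class is the fraction of its islands assigned that
    category (mixed plants also count a ``super`` label as recovered,
    super being a subdivision of mixed).  The false-positive rate is the
    fraction of unplanted islands assigned any of the four endemism
    categories.
    """
    planted = {
        "paleo": list(scenario.planted_paleo),
        "neo": list(scenario.planted_neo),
        "mixed": list(scenario.planted_mixed),
    }
    accepted = {"paleo": {"paleo"}, "neo": {"neo"}, "mixed": {"mixed", "super"}}
    recall = {}
    rows = []
    for cls, ids in planted.items():
        hits = sum(1 for i in ids if assignments.get(i) in accepted[cls])
        recall[cls] = hits / len(ids) if ids else float("nan")
        counts = {}
        for i in ids:
            lab = assignments.get(i, "missing")
            counts[lab] = counts.get(lab, 0) + 1
        rows.append({"planted": cls, **counts})
    all_planted = {i for ids in planted.values() for i in ids}
    unplanted = [i for i in assignments if i not in all_planted]
    fp = sum(1 for i in unplanted if assignments[i] in FOUR_CATEGORIES)
    fpr = fp / len(unplanted) if unplanted else float("nan")
    confusion = pd.DataFrame(rows).fillna(0).set_index("planted")
    return RecoveryReport(
        recall, fpr, confusion,
        {c: len(v) for c, v in planted.items()}, len(unplanted),
    )


# ---------------------------------------------------------------------------
# Canonical study conditions
# ---------------------------------------------------------------------------


def null_scenario(seed: int = 0, n_islands: int = 40, n_genera: int = 300) -> SyntheticScenario:
    """No planted signal, uniform occupancy: the type-I-error world."""
    return SyntheticScenario(
        n_genera=n_genera,
        n_islands=n_islands,
        seed=seed,
        f_paleo=0.0,
        f_neo=0.0,
        occupancy_model="uniform",
        planted_paleo=(),
        planted_neo=(),
        planted_mixed=(),
    )


def strong_planted_scenario(seed: int = 0, kappa: float = 1.0) -> SyntheticScenario:
    """Strong planted signal: kappa=1, m_long=10, single-island pools, 60 islands.

    Two planted islands per class and 20% of genera in each rare pool, so
    each planted island's flora is dominated by its pool (about fifteen
    single-island pool genera against a background of common ones).
    """
    return SyntheticScenario(
        n_genera=300,
        n_islands=60,
        seed=seed,
        f_paleo=0.2,
        f_neo=0.2,
        m_long=10.0,
        m_short=0.1,
        pool_max_occupancy=1,
        kappa=kappa,
        planted_paleo=("I0000", "I0001"),
        planted_neo=("I0002", "I0003"),
        planted_mixed=("I0004", "I0005"),
    )
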