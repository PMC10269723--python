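"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure of a reference-anchored full-length 16S
survey plus a MAG/SGB genome set, with planted ground truth so that every
downstream stage can be checked for exact recovery:

* a backbone tree of reference type strains realising a nested taxonomy;
* query OTUs grafted sister to (known / new species) or basal to
  (uncultured lineages) their anchors, with percent identities to the
  nearest type strain drawn from per-category bands that keep a safety
  margin ``boundary_margin`` (ε) away from the 98.7 / 94.5 decision
  thresholds;
* a sample × OPU count table with planted core taxa of configurable
  prevalence;
* a genome set with planted species clusters (within-cluster ANI above,
  between-cluster below the 95% species boundary) and planted rank-novelty
  levels on the AAI scale.

Identity values are stored independently of branch lengths: in the real
procedure identities come from alignment, not from the tree, and the two
evidence streams are deliberately decoupled here as well.  Same seed and
config give byte-identical artifacts.  No sequences are emitted.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .community import AbundanceTable
from .errors import ConfigError
from .opu import RANKS, Lineage, OpuCategory, OtuRecord, ReferenceTaxon
from .sgb import GenomeRecord, RankCall

# identity thresholds the bands must keep clear of
_SPECIES_ID = 98.7
_GENUS_ID = 94.5
_ANI_SPECIES = 95.0
_AAI_EDGES = (50.0, 65.0, 95.0)

_CATEGORY_CYCLE = ("known", "new", "uncultured")
_RANK_CYCLE = ("novel_species", "novel_genus", "order_level")


def _default_lineage_shape() -> dict[str, int]:
    return {"phylum": 2, "class": 3, "order": 4, "family": 6, "genus": 12, "species": 24}


def _default_identity_bands() -> dict[str, tuple[float, float]]:
    return {"known": (98.9, 100.0), "new": (94.7, 98.5), "uncultured": (85.0, 94.3)}


def _default_aai_bands() -> dict[str, tuple[float, float]]:
    return {"novel_species": (70.0, 90.0), "novel_genus": (52.0, 63.0), "order_level": (40.0, 48.0)}


def _default_quality_ranges() -> dict[str, tuple[float, float]]:
    return {
        "completeness": (90.0, 100.0),
        "contamination": (0.0, 5.0),
        "strain_heterogeneity": (0.0, 100.0),
        "n50": (100_000, 5_000_000),
    }


@dataclass
class SimConfig:
    """All knobs of the generator; defaults are the package's reference
    study conditions (30 samples, 200 queries, 3 species clusters × 2
    strains) with ε = 0.2 percentage points around every decision boundary."""

    seed: int = 0
    lineage_shape: dict[str, int] = field(default_factory=_default_lineage_shape)
    n_queries: int = 200
    identity_bands: dict[str, tuple[float, float]] = field(default_factory=_default_identity_bands)
    boundary_margin: float = 0.2
    n_samples: int = 30
    n_core: int = 5
    core_prevalence: float = 0.95
    detection_threshold: float = 0.90
    abundance_dispersion: float = 1.0
    core_abundance_mean: float = 150.0
    background_abundance_mean: float = 10.0
    n_species_clusters: int = 3
    strains_per_cluster: int = 2
    ani_within: tuple[float, float] = (95.5, 99.9)
    ani_between: tuple[float, float] = (80.0, 90.0)
    aai_bands: dict[str, tuple[float, float]] = field(default_factory=_default_aai_bands)
    clade_override_clusters: tuple[int, ...] = ()
    quality_ranges: dict[str, tuple[float, float]] = field(default_factory=_default_quality_ranges)
    n_reads: int = 5000
    read_length_mean: float = 1445.0
    read_length_sd: float = 120.0

    @property
    def n_references(self) -> int:
        return self.lineage_shape["species"]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        eps = self.boundary_margin
        if eps <= 0:
            raise ConfigError("boundary_margin must be > 0")
        if set(self.lineage_shape) != set(RANKS):
            raise ConfigError(f"lineage_shape must have exactly the ranks {RANKS}")
        counts = [self.lineage_shape[r] for r in RANKS]
        if any(c < 1 for c in counts):
            raise ConfigError("all lineage_shape counts must be >= 1")
        if any(a > b for a, b in zip(counts, counts[1:])):
            raise ConfigError("lineage_shape counts must be nondecreasing phylum -> species")
        for n, name in [
            (self.n_queries, "n_queries"), (self.n_samples, "n_samples"),
            (self.n_species_clusters, "n_species_clusters"),
            (self.strains_per_cluster, "strains_per_cluster"), (self.n_reads, "n_reads"),
        ]:
            if n < 0 or (name not in ("n_queries",) and n < 1):
                raise ConfigError(f"{name} must be positive")
        if set(self.identity_bands) != set(_CATEGORY_CYCLE):
            raise ConfigError("identity_bands must have keys known/new/uncultured")
        for key, (lo, hi) in self.identity_bands.items():
            if not 0 <= lo < hi <= 100:
                raise ConfigError(f"identity band {key} not a valid percent range")
            for edge in (_SPECIES_ID, _GENUS_ID):
                if lo < edge + eps and hi > edge - eps:
                    raise ConfigError(
                        f"identity band {key}={lo, hi} comes within ε={eps} of threshold {edge}"
                    )
        if self.identity_bands["known"][0] < _SPECIES_ID:
            raise ConfigError("'known' band must lie above the species threshold")
        if not (_GENUS_ID < self.identity_bands["new"][0] and self.identity_bands["new"][1] < _SPECIES_ID):
            raise ConfigError("'new' band must lie between the genus and species thresholds")
        if self.identity_bands["uncultured"][1] > _GENUS_ID:
            raise ConfigError("'uncultured' band must lie below the genus threshold")
        if self.ani_within[0] <= self.ani_between[1]:
            raise ConfigError("ani_within and ani_between must be disjoint (within above)")
        if self.ani_within[0] < _ANI_SPECIES + eps or self.ani_between[1] > _ANI_SPECIES - eps:
            raise ConfigError(f"ANI bands must keep ε={eps} clear of the 95% species boundary")
        for key, (lo, hi) in self.aai_bands.items():
            if key not in _RANK_CYCLE:
                raise ConfigError(f"unknown AAI band {key!r}")
            if not 0 <= lo < hi <= 100:
                raise ConfigError(f"AAI band {key} not a valid percent range")
            for edge in _AAI_EDGES:
                if lo < edge + eps and hi > edge - eps:
                    raise ConfigError(f"AAI band {key} comes within ε={eps} of threshold {edge}")
        lo, hi = self.aai_bands["novel_species"]
        if not (65 < lo and hi < 95):
            raise ConfigError("novel_species AAI band must lie in (65, 95)")
        lo, hi = self.aai_bands["novel_genus"]
        if not (50 < lo and hi < 65):
            raise ConfigError("novel_genus AAI band must lie in (50, 65)")
        if self.aai_bands["order_level"][1] > 50:
            raise ConfigError("order_level AAI band must lie below 50")
        if not 0 < self.core_prevalence <= 1:
            raise ConfigError("core_prevalence must be in (0, 1]")
        if any(i < 0 or i >= self.n_species_clusters for i in self.clade_override_clusters):
            raise ConfigError("clade_override_clusters indices out of range")
        if self.core_prevalence <= self.detection_threshold:
            warnings.warn(
                "core_prevalence <= detection_threshold: planted core recovery "
                "is not guaranteed", stacklevel=2,
            )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted answers for every stage, keyed by generated labels."""

    opu_membership: dict[str, str] = field(default_factory=dict)  # query -> planted OPU
    opu_category: dict[str, str] = field(default_factory=dict)  # planted OPU -> category
    opu_anchor_taxon: dict[str, str] = field(default_factory=dict)  # planted OPU -> taxon
    core_set: list[str] = field(default_factory=list)
    species_clusters: dict[str, str] = field(default_factory=dict)  # genome -> cluster
    rank_labels: dict[str, str] = field(default_factory=dict)  # cluster -> expected call

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed % (2**31), stage])


# ---------------------------------------------------------------------------
# reference backbone
# ---------------------------------------------------------------------------


def _taxonomy_names(cfg: SimConfig) -> dict[str, list[str]]:
    prefix = {"phylum": "P", "class": "C", "order": "O", "family": "F", "genus": "G", "species": "S"}
    return {r: [f"{prefix[r]}{i + 1:02d}" for i in range(cfg.lineage_shape[r])] for r in RANKS}


def _parent_index(child_idx: int, n_parents: int) -> int:
    return child_idx % n_parents


def simulate_reference_set(cfg: SimConfig) -> tuple[list[ReferenceTaxon], dendropy.Tree]:
    """Reference type strains plus a rooted bifurcating backbone tree.

    Taxa at each rank are distributed round-robin over the rank above, so
    the tip lineages realise ``lineage_shape`` exactly; sibling subtrees are
    joined into ladders to keep the tree bifurcating.  Every species tip is
    a type strain, labelled ``R001``… in construction order.
    """
    names = _taxonomy_names(cfg)
    rng = _rng(cfg, 1)

    # children[rank][parent_idx] -> list of child indices at the rank below
    children: dict[str, dict[int, list[int]]] = {}
    for upper, lower in zip(RANKS, RANKS[1:]):
        n_par = cfg.lineage_shape[upper]
        groups: dict[int, list[int]] = {i: [] for i in range(n_par)}
        for ci in range(cfg.lineage_shape[lower]):
            groups[_parent_index(ci, n_par)].append(ci)
        children[upper] = groups

    refs: list[ReferenceTaxon] = []

    def lineage_of(species_idx: int) -> Lineage:
        idx = species_idx
        chain = {"species": idx}
        for upper in reversed(RANKS[:-1]):
            idx = _parent_index(idx, cfg.lineage_shape[upper])
            chain[upper] = idx
        return tuple(names[r][chain[r]] for r in RANKS)  # type: ignore[return-value]

    def blen() -> str:
        return f"{rng.uniform(0.01, 0.10):.4f}"

    def subtree(rank_idx: int, taxon_idx: int) -> str:
        rank = RANKS[rank_idx]
        if rank == "species":
            tip = f"R{taxon_idx + 1:03d}"
            refs.append(ReferenceTaxon(tip, lineage_of(taxon_idx), is_type_strain=True))
            return f"{tip}:{blen()}"
        kids = children[rank][taxon_idx]
        parts = [subtree(rank_idx + 1, k) for k in kids]
        out = parts[0]
        for p in parts[1:]:
            out = f"({out},{p}):{blen()}"
        return out

    tops = [subtree(0, i) for i in range(cfg.lineage_shape["phylum"])]
    newick = tops[0]
    for p in tops[1:]:
        newick = f"({newick},{p}):{blen()}"
    if ")" not in newick:  # single-species degenerate backbone
        newick = f"({newick})"
    tree = dendropy.Tree.get(data=newick + ";", schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return refs, tree


# ---------------------------------------------------------------------------
# query planting
# ---------------------------------------------------------------------------


def _shared_rank_of(refs: Sequence[ReferenceTaxon]) -> Optional[str]:
    for i in range(len(RANKS) - 1, -1, -1):
        if len({r.lineage[i] for r in refs}) == 1:
            return RANKS[i]
    return None


_UNCULT_CATEGORY = {
    "family": OpuCategory.UNCULTURED_GENUS,
    "order": OpuCategory.UNCULTURED_FAMILY,
    "class": OpuCategory.UNCULTURED_ORDER,
}


def plant_queries(
    tree: dendropy.Tree,
    refs: Sequence[ReferenceTaxon],
    cfg: SimConfig,
) -> tuple[dendropy.Tree, pd.DataFrame, list[OtuRecord], GroundTruth]:
    """Graft query OTUs onto a copy of the backbone and emit identities.

    Queries are grouped into planted OPUs of 1–3 members cycling through the
    known / new / uncultured categories.  Known and new-species OPUs are
    grafted sister to a random type-strain tip; uncultured OPUs basal to a
    clade whose references share exactly a family, order or class.  Pendant
    branches are short, so planted membership equals the minimal-anchored-
    clade answer by construction.  Per-query identities to the nearest type
    strain are drawn from the category's band; identities to all other
    references sit at least one point lower.

    Returns the augmented tree, the query × reference identity matrix,
    query OtuRecords (with read counts for representative picking) and the
    ground truth.
    """
    rng = _rng(cfg, 2)
    ref_by_id = {r.tip_id: r for r in refs}
    tree = dendropy.Tree.get(
        data=tree.as_string(schema="newick"), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    truth = GroundTruth()
    ref_ids = sorted(ref_by_id)
    ident = pd.DataFrame(
        np.zeros((cfg.n_queries, len(ref_ids))),
        index=[f"Q{i + 1:04d}" for i in range(cfg.n_queries)],
        columns=ref_ids,
    )
    if cfg.n_queries == 0:
        return tree, ident, [], truth

    tip_nodes = {
        lf.taxon.label: lf for lf in tree.leaf_node_iter() if lf.taxon.label in ref_by_id
    }
    # candidate anchors for uncultured OPUs: clades sharing family/order/class
    candidates: list[tuple[dendropy.Node, OpuCategory, str, list[str]]] = []
    for node in tree.preorder_internal_node_iter():
        below = [ref_by_id[lf.taxon.label] for lf in node.leaf_iter()]
        if len(below) < 2:
            continue
        rank = _shared_rank_of(below)
        if rank in _UNCULT_CATEGORY:
            name = below[0].lineage[RANKS.index(rank)]
            candidates.append(
                (node, _UNCULT_CATEGORY[rank], name, sorted(r.tip_id for r in below))
            )

    taxa = tree.taxon_namespace

    def graft(target: dendropy.Node, member_ids: list[str]) -> None:
        qroot = None
        for qid in member_ids:
            leaf = dendropy.Node(taxon=taxa.require_taxon(label=qid))
            leaf.edge.length = 0.001
            if qroot is None:
                qroot = leaf
            else:
                join = dendropy.Node()
                join.edge.length = 0.001
                join.add_child(qroot)
                join.add_child(leaf)
                qroot = join
        parent = target.parent_node
        knee = dendropy.Node()
        knee.edge.length = 0.001
        if parent is None:
            # target is the root: new root above it
            tree.seed_node = knee
            knee.add_child(target)
        else:
            parent.remove_child(target)
            parent.add_child(knee)
            knee.add_child(target)
        knee.add_child(qroot)

    qnames = list(ident.index)
    qi = 0
    opu_idx = 0
    otus: list[OtuRecord] = []
    while qi < cfg.n_queries:
        size = min(int(rng.integers(1, 4)), cfg.n_queries - qi)
        members = qnames[qi : qi + size]
        qi += size
        cat_key = _CATEGORY_CYCLE[opu_idx % 3]
        pid = f"P{opu_idx + 1:04d}"
        opu_idx += 1

        lo, hi = cfg.identity_bands[cat_key]
        if cat_key in ("known", "new"):
            anchor_id = ref_ids[int(rng.integers(0, len(ref_ids)))]
            graft(tip_nodes[anchor_id], members)
            category = OpuCategory.KNOWN_SPECIES if cat_key == "known" else OpuCategory.NEW_SPECIES
            ref = ref_by_id[anchor_id]
            taxon = ref.rank_name("species") if cat_key == "known" else ref.rank_name("genus")
            nearest = anchor_id
        else:
            if not candidates:
                raise ConfigError(
                    "lineage_shape offers no multi-genus clade to anchor uncultured queries"
                )
            node, category, taxon, below_ids = candidates[int(rng.integers(0, len(candidates)))]
            graft(node, members)
            nearest = below_ids[0]

        truth.opu_category[pid] = category.value
        truth.opu_anchor_taxon[pid] = taxon
        for qid in members:
            truth.opu_membership[qid] = pid
            row = rng.uniform(60.0, lo - 1.0, size=len(ref_ids))
            ident.loc[qid] = np.round(row, 2)
            ident.at[qid, nearest] = round(float(rng.uniform(lo, hi)), 2)
            otus.append(
                OtuRecord(qid, total_count=int(rng.integers(1, 1000)), identities={})
            )

    otus = [
        OtuRecord(o.tip_id, o.total_count, identities=ident.loc[o.tip_id].to_dict())
        for o in otus
    ]
    return tree, ident, otus, truth


# ---------------------------------------------------------------------------
# abundance table
# ---------------------------------------------------------------------------


def simulate_abundance(
    cfg: SimConfig, opu_ids: Sequence[str]
) -> tuple[AbundanceTable, list[str]]:
    """Sample × OPU count table with ``n_core`` planted core OPUs.

    Core OPUs are present in at least ``ceil(core_prevalence · n_samples)``
    samples; every other OPU is present in strictly fewer samples than the
    downstream detection threshold requires, so prevalence detection at
    ``detection_threshold`` recovers exactly the planted set.  Counts are
    rounded log-normal draws (sigma = ``abundance_dispersion``); core OPUs
    get a higher median so the core set carries most of the community, as
    it does in wild-mammal gut profiles.
    """
    if cfg.n_core > len(opu_ids):
        raise ConfigError("n_core exceeds the number of OPUs")
    rng = _rng(cfg, 3)
    opu_ids = list(opu_ids)
    n, m = cfg.n_samples, len(opu_ids)
    core = sorted(rng.choice(opu_ids, size=cfg.n_core, replace=False).tolist())
    core_set = set(core)

    worth = cfg.detection_threshold * n
    max_noncore = int(math.ceil(worth) - 1 if float(worth).is_integer() else math.floor(worth))
    max_noncore = max(1, max_noncore)
    n_core_present = int(math.ceil(cfg.core_prevalence * n))

    counts = np.zeros((n, m), dtype=int)
    for j, opu in enumerate(opu_ids):
        if opu in core_set:
            k, mu = n_core_present, math.log(cfg.core_abundance_mean)
        else:
            k, mu = int(rng.integers(1, max_noncore + 1)), math.log(cfg.background_abundance_mean)
        rows = rng.choice(n, size=k, replace=False)
        draws = rng.lognormal(mean=mu, sigma=cfg.abundance_dispersion, size=k)
        counts[rows, j] = np.maximum(1, np.rint(draws)).astype(int)
    # guarantee at least one positive count per sample
    for i in range(n):
        if counts[i].sum() == 0:
            counts[i, 0] = 1

    table = AbundanceTable(
        pd.DataFrame(counts, index=[f"sample{i + 1:03d}" for i in range(n)], columns=opu_ids)
    )
    return table, core


# ---------------------------------------------------------------------------
# genome set
# ---------------------------------------------------------------------------


@dataclass
class SimulatedGenomes:
    genomes: list[GenomeRecord]
    ani: pd.DataFrame  # square, symmetric, percent
    aai: pd.DataFrame  # genomes × named taxa, percent
    clade_map: dict[str, str]  # genome -> known genus clade (override evidence)
    truth: GroundTruth


def simulate_genome_set(cfg: SimConfig) -> SimulatedGenomes:
    """Planted species clusters with ANI, AAI and quality evidence.

    Cluster *i* (``strains_per_cluster`` genomes) draws within-cluster ANI
    from ``ani_within`` and between-cluster ANI from ``ani_between``; its
    planted novelty rank cycles through novel species / novel genus /
    order-level, realised as an AAI band of the cluster's nearest named
    taxon.  Clusters listed in ``clade_override_clusters`` additionally sit
    inside a known genus clade, so a sub-genus AAI is expected to be
    overridden to a novel-species call.
    """
    rng = _rng(cfg, 4)
    nc, k = cfg.n_species_clusters, cfg.strains_per_cluster
    ids = [f"G{i + 1:03d}" for i in range(nc * k)]
    cluster_of = {ids[i * k + j]: f"T{i + 1:03d}" for i in range(nc) for j in range(k)}

    ani = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids, columns=ids)
    for a_i, a in enumerate(ids):
        ani.at[a, a] = 100.0
        for b in ids[a_i + 1 :]:
            lo, hi = cfg.ani_within if cluster_of[a] == cluster_of[b] else cfg.ani_between
            v = round(float(rng.uniform(lo, hi)), 2)
            ani.at[a, b] = v
            ani.at[b, a] = v

    named = [f"N{i + 1:03d}" for i in range(max(3, nc))]
    aai = pd.DataFrame(np.zeros((len(ids), len(named))), index=ids, columns=named)
    truth = GroundTruth()
    clade_map: dict[str, str] = {}
    bg_hi = min(lo for lo, _ in cfg.aai_bands.values()) - 2.0
    for i in range(nc):
        cid = f"T{i + 1:03d}"
        band_key = _RANK_CYCLE[i % 3]
        lo, hi = cfg.aai_bands[band_key]
        nearest = named[i % len(named)]
        row = np.round(rng.uniform(25.0, bg_hi, size=len(named)), 2)
        row[named.index(nearest)] = round(float(rng.uniform(lo, hi)), 2)
        override = i in cfg.clade_override_clusters
        expected = {
            "novel_species": RankCall.NOVEL_SPECIES,
            "novel_genus": RankCall.NOVEL_GENUS,
            "order_level": RankCall.ORDER_LEVEL,
        }[band_key]
        if override and band_key != "novel_species":
            expected = RankCall.NOVEL_SPECIES  # clade evidence outranks AAI
        truth.rank_labels[cid] = expected.value
        members = [g for g in ids if cluster_of[g] == cid]
        for g in members:
            aai.loc[g] = row
            truth.species_clusters[g] = cid
            if override:
                clade_map[g] = f"Genus{i + 1:02d}"

    qr = cfg.quality_ranges
    genomes = [
        GenomeRecord(
            g,
            completeness=round(float(rng.uniform(*qr["completeness"])), 2),
            contamination=round(float(rng.uniform(*qr["contamination"])), 2),
            strain_heterogeneity=round(float(rng.uniform(*qr["strain_heterogeneity"])), 2),
            n50=int(rng.integers(int(qr["n50"][0]), int(qr["n50"][1]) + 1)),
        )
        for g in ids
    ]
    return SimulatedGenomes(genomes, ani, aai, clade_map, truth)


def simulate_read_lengths(cfg: SimConfig) -> np.ndarray:
    """Integer amplicon lengths, normal around ``read_length_mean``."""
    rng = _rng(cfg, 5)
    lengths = rng.normal(cfg.read_length_mean, cfg.read_length_sd, size=cfg.n_reads)
    return np.maximum(1, np.rint(lengths)).astype(int)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    config: SimConfig
    refs: list[ReferenceTaxon]
    backbone: dendropy.Tree
    tree: dendropy.Tree
    identity: pd.DataFrame
    otus: list[OtuRecord]
    abundance: AbundanceTable
    read_lengths: np.ndarray
    genomes: SimulatedGenomes
    truth: GroundTruth


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Generate every pipeline input in one deterministic pass."""
    refs, backbone = simulate_reference_set(cfg)
    tree, identity, otus, truth = plant_queries(backbone, refs, cfg)
    planted_opus = sorted(set(truth.opu_membership.values()))
    if not planted_opus:  # no queries: still exercise the abundance stage
        planted_opus = [f"P{i + 1:04d}" for i in range(max(cfg.n_core, 10))]
    table, core = simulate_abundance(cfg, planted_opus)
    truth.core_set = core
    gen = simulate_genome_set(cfg)
    truth.species_clusters = gen.truth.species_clusters
    truth.rank_labels = gen.truth.rank_labels
    gen.truth = truth
    return SimulatedDataset(
        cfg, refs, backbone, tree, identity, otus, table,
        simulate_read_lengths(cfg), gen, truth,
    )
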