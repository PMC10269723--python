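"""Operational phylogenetic unit (OPU) delineation and classification.

An OPU is the smallest monophyletic clade of a reference-anchored 16S rRNA
tree that contains query OTU representatives together with at least one
reference sequence.  Each OPU is then classified by the best percent identity
of its representative OTU to a type strain:

* identity >= ``species_identity`` (default 98.7)  -> known species;
* ``genus_identity`` <= identity < ``species_identity`` (94.5 <= I < 98.7)
  -> potential new species within the type strain's genus;
* identity < ``genus_identity`` -> uncultured lineage, placed one rank below
  the most specific rank shared by all reference tips of the anchor clade.

Only type strains can trigger a known-species call; non-type references
contribute clade evidence only.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import dendropy

from .errors import ClassificationError, ConfigError, DelineationError, InputError

#: Taxonomic ranks, most inclusive first.  Lineages are 6-tuples in this
#: order; unresolved ranks are empty strings (no gaps above the most
#: specific filled rank).
RANKS: tuple[str, ...] = ("phylum", "class", "order", "family", "genus", "species")

Lineage = tuple[str, str, str, str, str, str]


def make_lineage(
    phylum: str = "",
    class_: str = "",
    order: str = "",
    family: str = "",
    genus: str = "",
    species: str = "",
) -> Lineage:
    """Build a 6-rank lineage tuple, validating the no-gap invariant."""
    lin = (phylum, class_, order, family, genus, species)
    filled = [bool(x) for x in lin]
    if True in filled:
        deepest = max(i for i, f in enumerate(filled) if f)
        if not all(filled[: deepest + 1]):
            raise InputError(f"lineage has a gap above its most specific rank: {lin}")
    return lin


def parse_lineage(text: str) -> Lineage:
    """Parse a semicolon-separated ``phylum;class;order;family;genus;species`` string."""
    parts = [p.strip() for p in text.split(";")]
    if len(parts) > 6:
        raise InputError(f"lineage has more than 6 ranks: {text!r}")
    parts += [""] * (6 - len(parts))
    return make_lineage(*parts)


def format_lineage(lineage: Lineage) -> str:
    return ";".join(lineage)


@dataclass(frozen=True)
class ReferenceTaxon:
    """A reference (anchor) tip of the tree with its taxonomy."""

    tip_id: str
    lineage: Lineage
    is_type_strain: bool = False

    def rank_name(self, rank: str) -> str:
        return self.lineage[RANKS.index(rank)]


@dataclass(frozen=True)
class OtuRecord:
    """A query OTU representative: read count plus identities to references."""

    tip_id: str
    total_count: int = 0
    identities: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.total_count < 0:
            raise InputError(f"OTU {self.tip_id}: negative total_count")
        for ref, v in self.identities.items():
            if not 0.0 <= v <= 100.0:
                raise InputError(f"OTU {self.tip_id}: identity to {ref} outside [0,100]")


class OpuCategory(str, enum.Enum):
    KNOWN_SPECIES = "KNOWN_SPECIES"
    NEW_SPECIES = "NEW_SPECIES"
    UNCULTURED_GENUS = "UNCULTURED_GENUS"
    UNCULTURED_FAMILY = "UNCULTURED_FAMILY"
    UNCULTURED_ORDER = "UNCULTURED_ORDER"
    UNCULTURED_CLASS = "UNCULTURED_CLASS"


#: shared-rank -> category one level below it, for the uncultured branch
_UNCULTURED_BY_SHARED_RANK = {
    "family": OpuCategory.UNCULTURED_GENUS,
    "order": OpuCategory.UNCULTURED_FAMILY,
    "class": OpuCategory.UNCULTURED_ORDER,
    "phylum": OpuCategory.UNCULTURED_CLASS,
}


@dataclass
class Opu:
    """One delineated OPU: its member queries, anchor evidence and call."""

    opu_id: str
    members: list[str]
    anchor_refs: list[str]
    category: Optional[OpuCategory] = None
    assigned_taxon: str = ""
    representative: str = ""
    best_identity: Optional[float] = None


@dataclass(frozen=True)
class ThresholdConfig:
    """Identity thresholds for the classification cascade (percent)."""

    species_identity: float = 98.7
    genus_identity: float = 94.5

    def __post_init__(self):
        if not self.genus_identity < self.species_identity:
            raise ConfigError("genus_identity must be < species_identity")


# ---------------------------------------------------------------------------
# delineation
# ---------------------------------------------------------------------------


def _maybe_midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    # The clade ascent needs a root.  A basal polytomy is taken as an
    # unrooted tree and midpoint-rooted when branch lengths allow it.
    root = tree.seed_node
    if len(root.child_nodes()) <= 2:
        return tree
    if all(e.length is not None for e in tree.preorder_edge_iter() if e.head_node is not root):
        tree.is_rooted = True
        tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def delineate_opus(
    tree: dendropy.Tree,
    refs: Sequence[ReferenceTaxon],
    otus: Optional[Sequence[OtuRecord]] = None,
) -> list[Opu]:
    """Partition query tips into OPUs by the minimal-anchored-clade rule.

    For each query tip the anchor is its closest ancestor whose subtree
    contains at least one reference tip; queries sharing an anchor node form
    one OPU.  Tips not named in *refs* are queries; if *otus* is given, every
    query tip must appear in it.

    Returns OPUs in tree leaf order, labelled ``OPU0001`` onward, with
    ``members`` and ``anchor_refs`` filled; classification fields are left
    for :func:`classify_opu`.
    """
    ref_ids = {r.tip_id for r in refs}
    if len(ref_ids) != len(refs):
        raise InputError("duplicate reference tip ids")

    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label if lf.taxon else "" for lf in leaves]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise InputError(f"duplicate tip label in tree: {lab!r}")
        seen.add(lab)
    if not (seen & ref_ids):
        raise DelineationError("tree contains no reference tips")

    if otus is not None:
        otu_ids = {o.tip_id for o in otus}
        stray = seen - ref_ids - otu_ids
        if stray:
            raise InputError(f"tree tips neither reference nor OTU: {sorted(stray)[:5]}")

    tree = _maybe_midpoint_root(tree)

    has_ref: dict[int, bool] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            has_ref[id(node)] = (node.taxon.label in ref_ids) if node.taxon else False
        else:
            has_ref[id(node)] = any(has_ref[id(c)] for c in node.child_nodes())

    anchors: dict[int, dendropy.Node] = {}
    anchor_members: dict[int, list[str]] = {}
    order: list[int] = []
    for leaf in tree.leaf_node_iter():
        lab = leaf.taxon.label if leaf.taxon else ""
        if lab in ref_ids:
            continue
        node = leaf
        while node is not None and not has_ref[id(node)]:
            node = node.parent_node
        if node is None:  # pragma: no cover - guarded by the ref check above
            raise DelineationError(f"query {lab!r} has no anchored ancestor")
        key = id(node)
        if key not in anchor_members:
            anchor_members[key] = []
            anchors[key] = node
            order.append(key)
        anchor_members[key].append(lab)

    opus: list[Opu] = []
    for i, key in enumerate(order, start=1):
        node = anchors[key]
        anchor_refs = sorted(
            lf.taxon.label
            for lf in node.leaf_iter()
            if lf.taxon and lf.taxon.label in ref_ids
        )
        opus.append(
            Opu(
                opu_id=f"OPU{i:04d}",
                members=sorted(anchor_members[key]),
                anchor_refs=anchor_refs,
            )
        )
    return opus


# ---------------------------------------------------------------------------
# representative selection and classification
# ---------------------------------------------------------------------------


def pick_representative(opu: Opu, otus: Mapping[str, OtuRecord] | Sequence[OtuRecord]) -> str:
    """Most frequent member OTU; ties broken by smallest tip id."""
    by_id = _otu_map(otus)
    if not opu.members:
        raise InputError(f"{opu.opu_id}: no members")
    return min(opu.members, key=lambda m: (-(by_id[m].total_count if m in by_id else 0), m))


def _otu_map(otus) -> Mapping[str, OtuRecord]:
    if isinstance(otus, Mapping):
        return otus
    return {o.tip_id: o for o in otus}


def _shared_rank(anchor_refs: Iterable[ReferenceTaxon]) -> tuple[Optional[str], str]:
    """Most specific rank (and its name) shared by every anchor reference."""
    refs = list(anchor_refs)
    for i in range(len(RANKS) - 1, -1, -1):
        names = {r.lineage[i] for r in refs}
        if len(names) == 1 and next(iter(names)):
            return RANKS[i], next(iter(names))
    return None, ""


def classify_opu(
    opu: Opu,
    refs: Mapping[str, ReferenceTaxon] | Sequence[ReferenceTaxon],
    otus: Mapping[str, OtuRecord] | Sequence[OtuRecord],
    cfg: ThresholdConfig = ThresholdConfig(),
) -> Opu:
    """Fill category / assigned taxon / best identity of *opu* in place.

    The identity used is the representative OTU's best identity to a type
    strain.  Below the genus threshold the anchor clade's shared lineage
    decides the rank; a clade whose references share a genus outranks the
    identity signal and yields a new-species call in that genus.
    """
    ref_map = refs if isinstance(refs, Mapping) else {r.tip_id: r for r in refs}
    otu_map = _otu_map(otus)
    if not opu.representative:
        opu.representative = pick_representative(opu, otu_map)
    rep = otu_map.get(opu.representative)
    idents = rep.identities if rep is not None else {}

    type_idents = {
        rid: v
        for rid, v in idents.items()
        if rid in ref_map and ref_map[rid].is_type_strain
    }
    best_ref: Optional[str] = None
    if type_idents:
        best_ref = min(type_idents, key=lambda r: (-type_idents[r], r))
        opu.best_identity = type_idents[best_ref]

    anchor = [ref_map[r] for r in opu.anchor_refs if r in ref_map]
    if not type_idents and not anchor:
        raise ClassificationError(f"{opu.opu_id}: no identities and no anchor lineage")

    if best_ref is not None and type_idents[best_ref] >= cfg.species_identity:
        opu.category = OpuCategory.KNOWN_SPECIES
        t = ref_map[best_ref]
        opu.assigned_taxon = t.rank_name("species") or t.rank_name("genus")
        return opu
    if best_ref is not None and type_idents[best_ref] >= cfg.genus_identity:
        opu.category = OpuCategory.NEW_SPECIES
        opu.assigned_taxon = ref_map[best_ref].rank_name("genus")
        return opu

    rank, name = _shared_rank(anchor)
    if rank in ("species", "genus"):
        # Clade evidence places the OPU inside a known genus even though the
        # identity fell below the genus threshold: call a new species there.
        genus = anchor[0].rank_name("genus")
        opu.category = OpuCategory.NEW_SPECIES
        opu.assigned_taxon = genus
    elif rank is not None:
        opu.category = _UNCULTURED_BY_SHARED_RANK[rank]
        opu.assigned_taxon = name
    else:
        # Anchors share no named rank at all: deepest expressible novelty.
        opu.category = OpuCategory.UNCULTURED_CLASS
        opu.assigned_taxon = ""
    return opu


def call_opus(
    tree: dendropy.Tree,
    refs: Sequence[ReferenceTaxon],
    otus: Sequence[OtuRecord],
    cfg: ThresholdConfig = ThresholdConfig(),
) -> list[Opu]:
    """Delineate, pick representatives and classify in one pass."""
    ref_map = {r.tip_id: r for r in refs}
    otu_map = _otu_map(otus)
    opus = delineate_opus(tree, refs, otus)
    for opu in opus:
        opu.representative = pick_representative(opu, otu_map)
        classify_opu(opu, ref_map, otu_map, cfg)
    return opus


def category_counts(opus: Sequence[Opu]) -> dict[str, int]:
    """Number of OPUs per category (category value -> count)."""
    out: dict[str, int] = {}
    for opu in opus:
        if opu.category is None:
            raise InputError(f"{opu.opu_id} is unclassified")
        out[opu.category.value] = out.get(opu.category.value, 0) + 1
    return out
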