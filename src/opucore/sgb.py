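"""Species-level genome bin (SGB) quality, clustering and rank assignment.

Metagenome-assembled genomes (MAGs) are scored with the dRep-style quality
formula

    quality = completeness − 5·contamination
              + contamination·(strain_heterogeneity/100) + 0.5·log10(N50),

tiered by CheckM-style completeness/contamination bounds, filtered with the
stricter completeness − 5·contamination ≥ 50 rule, and clustered by ANI
(99% dereplication, 95% species boundary) as connected components of the
threshold graph.  Cluster ranks follow an ANI → AAI → phylogeny cascade:
ANI ≥ 95% or AAI ≥ 95% means a known species; AAI 65–95% a novel species in
the nearest named genus; AAI 45–65% a novel genus (family-level placement);
AAI < 50% order-level novelty; and a cluster embedded in a known genus clade
is demoted to a novel species even when its AAI falls below 65%.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from .errors import ConfigError, InputError, UnclassifiableError


@dataclass(frozen=True)
class GenomeRecord:
    genome_id: str
    completeness: float  # percent
    contamination: float  # percent
    strain_heterogeneity: float = 0.0  # percent
    n50: int = 1  # bp

    def __post_init__(self):
        for name in ("completeness", "contamination", "strain_heterogeneity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise InputError(f"{self.genome_id}: {name}={v} outside [0,100]")
        if self.n50 < 1:
            raise InputError(f"{self.genome_id}: N50 must be >= 1")


class QualityTier(str, enum.Enum):
    NEAR_COMPLETE = "near_complete"
    MEDIUM = "medium"
    PARTIAL = "partial"
    FAIL = "fail"


@dataclass(frozen=True)
class SgbCluster:
    cluster_id: str
    members: tuple[str, ...]
    representative: str


class RankCall(str, enum.Enum):
    KNOWN_SPECIES = "KNOWN_SPECIES"
    NOVEL_SPECIES = "NOVEL_SPECIES"
    NOVEL_GENUS = "NOVEL_GENUS"
    NOVEL_FAMILY_OR_ABOVE = "NOVEL_FAMILY_OR_ABOVE"
    ORDER_LEVEL = "ORDER_LEVEL"


@dataclass(frozen=True)
class RankConfig:
    """Percent thresholds of the rank cascade, strictly ordered."""

    ani_species: float = 95.0
    ani_dereplicate: float = 99.0
    aai_species: float = 95.0
    aai_genus_low: float = 65.0
    aai_family_low: float = 50.0

    def __post_init__(self):
        if not self.aai_family_low < self.aai_genus_low < self.aai_species:
            raise ConfigError("AAI thresholds must be strictly ordered")
        if not self.ani_species < self.ani_dereplicate:
            raise ConfigError("ani_species must be below ani_dereplicate")


@dataclass(frozen=True)
class RankAssignment:
    cluster_id: str
    call: RankCall
    nearest_named: str
    ani_best: Optional[float]
    aai_best: Optional[float]
    clade_override_applied: bool = False


def genome_quality_score(g: GenomeRecord) -> float:
    """dRep-style quality score (log base 10 of N50)."""
    return (
        g.completeness
        - 5.0 * g.contamination
        + g.contamination * (g.strain_heterogeneity / 100.0)
        + 0.5 * math.log10(g.n50)
    )


def quality_tier(g: GenomeRecord) -> QualityTier:
    """near_complete (≥90, ≤5) → medium (≥70, ≤10) → partial (≥50, ≤5) → fail."""
    if g.completeness >= 90 and g.contamination <= 5:
        return QualityTier.NEAR_COMPLETE
    if g.completeness >= 70 and g.contamination <= 10:
        return QualityTier.MEDIUM
    if g.completeness >= 50 and g.contamination <= 5:
        return QualityTier.PARTIAL
    return QualityTier.FAIL


def passes_quality_filter(g: GenomeRecord) -> bool:
    """Strict signal-to-noise control for downstream clustering."""
    return (
        g.completeness - 5.0 * g.contamination >= 50.0
        and g.completeness > 50.0
        and g.contamination < 10.0
    )


def cluster_genomes(
    genomes: Sequence[GenomeRecord],
    ani: pd.DataFrame,
    threshold: float,
    symmetry_tol: float = 0.1,
) -> list[SgbCluster]:
    """Single-linkage ANI clustering at *threshold* percent.

    Clusters are the connected components of the graph whose edges join
    genome pairs with ANI ≥ threshold; missing cells count as below
    threshold.  The representative is the member with the highest
    :func:`genome_quality_score` (ties to the smallest genome id).
    Cluster ids are assigned in order of each cluster's smallest member.
    """
    by_id = {g.genome_id: g for g in genomes}
    graph = nx.Graph()
    graph.add_nodes_from(by_id)
    ids = [g.genome_id for g in genomes]
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            vab = _cell(ani, a, b)
            vba = _cell(ani, b, a)
            if vab is not None and vba is not None and abs(vab - vba) > symmetry_tol:
                raise InputError(f"conflicting asymmetric ANI for ({a},{b}): {vab} vs {vba}")
            v = vab if vab is not None else vba
            if v is not None and v >= threshold:
                graph.add_edge(a, b)

    comps = sorted(nx.connected_components(graph), key=lambda c: min(c))
    clusters = []
    for i, comp in enumerate(comps, start=1):
        members = tuple(sorted(comp))
        rep = min(members, key=lambda m: (-genome_quality_score(by_id[m]), m))
        clusters.append(SgbCluster(f"SGB{i:03d}", members, rep))
    return clusters


def _cell(df: pd.DataFrame, a: str, b: str) -> Optional[float]:
    if a in df.index and b in df.columns:
        v = df.at[a, b]
        if pd.notna(v):
            return float(v)
    return None


def dereplicate_then_cluster(
    genomes: Sequence[GenomeRecord],
    ani: pd.DataFrame,
    cfg: RankConfig = RankConfig(),
) -> tuple[list[SgbCluster], list[SgbCluster]]:
    """Two-stage dRep-style workflow: 99% dereplication, then 95% species
    clustering of the dereplicated representatives.  Returns (derep, species)."""
    derep = cluster_genomes(genomes, ani, cfg.ani_dereplicate)
    by_id = {g.genome_id: g for g in genomes}
    reps = [by_id[c.representative] for c in derep]
    species = cluster_genomes(reps, ani, cfg.ani_species)
    return derep, species


def assign_rank(
    cluster_id: str,
    ani_to_named: Mapping[str, float],
    aai_to_named: Mapping[str, float],
    genus_clade_membership: Optional[str] = None,
    cfg: RankConfig = RankConfig(),
) -> RankAssignment:
    """Rank an SGB by the ANI → AAI → clade cascade.

    *ani_to_named* / *aai_to_named* map named-taxon labels to percent
    identities of the cluster representative; either may be empty.
    *genus_clade_membership* names the known genus whose phylogenomic clade
    embeds the SGB, if any; it overrides a sub-genus AAI signal.
    """
    ani_best = aai_best = None
    nearest = ""
    if ani_to_named:
        near_ani = min(ani_to_named, key=lambda t: (-ani_to_named[t], t))
        ani_best = float(ani_to_named[near_ani])
    if aai_to_named:
        near_aai = min(aai_to_named, key=lambda t: (-aai_to_named[t], t))
        aai_best = float(aai_to_named[near_aai])

    if ani_best is not None and ani_best >= cfg.ani_species:
        return RankAssignment(cluster_id, RankCall.KNOWN_SPECIES, near_ani, ani_best, aai_best)
    if aai_best is not None:
        nearest = near_aai
        if aai_best >= cfg.aai_species:
            return RankAssignment(cluster_id, RankCall.KNOWN_SPECIES, nearest, ani_best, aai_best)
        if aai_best >= cfg.aai_genus_low:
            return RankAssignment(cluster_id, RankCall.NOVEL_SPECIES, nearest, ani_best, aai_best)
        if genus_clade_membership:
            return RankAssignment(
                cluster_id, RankCall.NOVEL_SPECIES, genus_clade_membership,
                ani_best, aai_best, clade_override_applied=True,
            )
        if aai_best >= cfg.aai_family_low:
            return RankAssignment(cluster_id, RankCall.NOVEL_GENUS, nearest, ani_best, aai_best)
        return RankAssignment(cluster_id, RankCall.ORDER_LEVEL, nearest, ani_best, aai_best)
    if genus_clade_membership:
        return RankAssignment(
            cluster_id, RankCall.NOVEL_SPECIES, genus_clade_membership,
            ani_best, None, clade_override_applied=True,
        )
    raise UnclassifiableError(f"{cluster_id}: no ANI/AAI/clade evidence to rank")
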