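import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import opucore as oc
from opucore.errors import InputError, UnclassifiableError


def G(gid="G1", comp=90.0, cont=0.0, sh=0.0, n50=100_000):
    return oc.GenomeRecord(gid, comp, cont, sh, n50)


class TestQualityScore:
    @pytest.mark.parametrize(
        "comp, cont, sh, n50, score",
        [
            (0, 0, 0, 1, 0.0),
            (100, 0, 0, 1_000_000, 103.0),
            (90, 4, 50, 100_000, 74.5),
        ],
    )
    def test_formula(self, comp, cont, sh, n50, score):
        assert oc.genome_quality_score(G(comp=comp, cont=cont, sh=sh, n50=n50)) == pytest.approx(score)

    def test_invalid_inputs(self):
        with pytest.raises(InputError):
            G(n50=0)
        with pytest.raises(InputError):
            G(cont=101)

    def test_monotone_in_each_metric(self):
        base = oc.genome_quality_score(G(comp=80, cont=3, sh=40, n50=50_000))
        assert oc.genome_quality_score(G(comp=81, cont=3, sh=40, n50=50_000)) > base
        assert oc.genome_quality_score(G(comp=80, cont=4, sh=40, n50=50_000)) < base
        assert oc.genome_quality_score(G(comp=80, cont=3, sh=40, n50=60_000)) > base


class TestTiersAndFilter:
    @pytest.mark.parametrize(
        "comp, cont, tier",
        [
            (95, 2, oc.QualityTier.NEAR_COMPLETE),
            (90, 5, oc.QualityTier.NEAR_COMPLETE),
            (75, 8, oc.QualityTier.MEDIUM),
            (95, 8, oc.QualityTier.MEDIUM),  # contamination demotes from near-complete
            (55, 3, oc.QualityTier.PARTIAL),
            (55, 8, oc.QualityTier.FAIL),
            (45, 2, oc.QualityTier.FAIL),
        ],
    )
    def test_tier_ladder(self, comp, cont, tier):
        assert oc.quality_tier(G(comp=comp, cont=cont)) == tier

    @pytest.mark.parametrize(
        "comp, cont, ok",
        [
            (60, 2, True),  # 60 - 10 = 50 exactly
            (50.5, 0.2, False),  # 49.5 < 50
            (100, 0, True),
            (60, 1.9, True),
            (51, 10, False),  # contamination must be < 10
            (50, 0, False),  # completeness must be > 50
        ],
    )
    def test_strict_filter(self, comp, cont, ok):
        assert oc.passes_quality_filter(G(comp=comp, cont=cont)) is ok


def ani_frame(values):
    ids = sorted({a for a, _ in values} | {b for _, b in values})
    df = pd.DataFrame(100.0 * np.eye(len(ids)), index=ids, columns=ids)
    for (a, b), v in values.items():
        df.at[a, b] = v
        df.at[b, a] = v
    return df


class TestClustering:
    def setup_method(self):
        self.genomes = [G("A", comp=95), G("B", comp=90), G("C", comp=85)]
        self.ani = ani_frame({("A", "B"): 96, ("B", "C"): 96, ("A", "C"): 94})

    def test_single_linkage_chains(self):
        clusters = oc.cluster_genomes(self.genomes, self.ani, 95)
        assert len(clusters) == 1
        assert clusters[0].members == ("A", "B", "C")
        assert clusters[0].representative == "A"  # highest completeness

    def test_high_threshold_singletons(self):
        clusters = oc.cluster_genomes(self.genomes, self.ani, 99)
        assert [c.members for c in clusters] == [("A",), ("B",), ("C",)]

    def test_missing_cells_count_as_below_threshold(self):
        ani = self.ani.drop(columns=["C"]).drop(index=["C"])
        clusters = oc.cluster_genomes(self.genomes, ani, 95)
        assert {c.members for c in clusters} == {("A", "B"), ("C",)}

    def test_conflicting_asymmetry_rejected(self):
        ani = self.ani.copy()
        ani.at["A", "B"] = 99.0  # B,A still 96
        with pytest.raises(InputError):
            oc.cluster_genomes(self.genomes, ani, 95)

    def test_higher_threshold_refines(self):
        rng = np.random.default_rng(5)
        ids = [f"G{i}" for i in range(10)]
        vals = rng.uniform(80, 100, size=(10, 10))
        sym = (vals + vals.T) / 2
        np.fill_diagonal(sym, 100.0)
        ani = pd.DataFrame(sym, index=ids, columns=ids)
        genomes = [G(g) for g in ids]
        coarse = {frozenset(c.members) for c in oc.cluster_genomes(genomes, ani, 95)}
        fine = {frozenset(c.members) for c in oc.cluster_genomes(genomes, ani, 99)}
        for f in fine:
            assert any(f <= c for c in coarse)

    def test_recovers_planted_clusters_and_two_stage_equivalence(self, sim):
        g = sim.genomes
        truth_clusters = {}
        for gid, cid in sim.truth.species_clusters.items():
            truth_clusters.setdefault(cid, set()).add(gid)
        expected = {frozenset(v) for v in truth_clusters.values()}
        direct = oc.cluster_genomes(g.genomes, g.ani, 95)
        assert {frozenset(c.members) for c in direct} == expected
        derep, species = oc.dereplicate_then_cluster(g.genomes, g.ani)
        derep_members = {c.representative: set(c.members) for c in derep}
        expanded = {
            frozenset(m for r in c.members for m in derep_members[r]) for c in species
        }
        assert expanded == expected

    def test_single_strain_dereplication_is_identity(self):
        cfg = oc.SimConfig(seed=3, strains_per_cluster=1)
        g = oc.simulate_genome_set(cfg)
        derep = oc.cluster_genomes(g.genomes, g.ani, 99)
        assert all(len(c.members) == 1 for c in derep)
        assert len(derep) == cfg.n_species_clusters


class TestAssignRank:
    @pytest.mark.parametrize(
        "ani, aai, clade, call, override",
        [
            ({"N1": 97.0}, {}, None, oc.RankCall.KNOWN_SPECIES, False),
            ({"N1": 95.0}, {}, None, oc.RankCall.KNOWN_SPECIES, False),
            ({"N1": 82.0}, {"N1": 78.0}, None, oc.RankCall.NOVEL_SPECIES, False),
            ({}, {"N1": 95.0}, None, oc.RankCall.KNOWN_SPECIES, False),
            ({}, {"N1": 94.8}, None, oc.RankCall.NOVEL_SPECIES, False),
            ({}, {"N1": 65.0}, None, oc.RankCall.NOVEL_SPECIES, False),
            ({}, {"N1": 64.8}, None, oc.RankCall.NOVEL_GENUS, False),
            ({}, {"N1": 58.0}, None, oc.RankCall.NOVEL_GENUS, False),
            ({}, {"N1": 58.0}, "Treponema", oc.RankCall.NOVEL_SPECIES, True),
            ({}, {"N1": 50.0}, None, oc.RankCall.NOVEL_GENUS, False),
            ({}, {"N1": 49.8}, None, oc.RankCall.ORDER_LEVEL, False),
            ({}, {"N1": 47.0}, None, oc.RankCall.ORDER_LEVEL, False),
            ({}, {"N1": 47.0}, "Treponema", oc.RankCall.NOVEL_SPECIES, True),
            ({}, {}, "Treponema", oc.RankCall.NOVEL_SPECIES, True),
        ],
    )
    def test_cascade(self, ani, aai, clade, call, override):
        out = oc.assign_rank("SGB001", ani, aai, clade)
        assert out.call == call
        assert out.clade_override_applied is override

    def test_nearest_named_reported(self):
        out = oc.assign_rank("SGB001", {}, {"Na": 70.0, "Nb": 80.0}, None)
        assert out.nearest_named == "Nb"
        assert out.aai_best == 80.0

    def test_empty_evidence_raises(self):
        with pytest.raises(UnclassifiableError):
            oc.assign_rank("SGB001", {}, {}, None)

    @given(
        st.floats(min_value=0, max_value=100),
        st.floats(min_value=0, max_value=100),
        st.booleans(),
    )
    def test_cascade_total_on_nonempty_evidence(self, ani, aai, clade):
        out = oc.assign_rank("X", {"N": ani}, {"N": aai}, "G" if clade else None)
        assert isinstance(out.call, oc.RankCall)

    def test_recovers_planted_ranks(self, sim):
        g = sim.genomes
        clusters = oc.cluster_genomes(g.genomes, g.ani, 95)
        truth_by_members = {}
        for gid, cid in sim.truth.species_clusters.items():
            truth_by_members.setdefault(cid, set()).add(gid)
        for c in clusters:
            pid = next(k for k, v in truth_by_members.items() if frozenset(v) == frozenset(c.members))
            out = oc.assign_rank(
                c.cluster_id, {}, dict(g.aai.loc[c.representative]),
                g.clade_map.get(c.representative),
            )
            assert out.call.value == sim.truth.rank_labels[pid]

    def test_planted_clade_override_recovered(self):
        cfg = oc.SimConfig(seed=9, n_species_clusters=4, clade_override_clusters=(1,))
        g = oc.simulate_genome_set(cfg)
        assert g.truth.rank_labels["T002"] == "NOVEL_SPECIES"
        rep = next(gid for gid, cid in g.truth.species_clusters.items() if cid == "T002")
        out = oc.assign_rank("T002", {}, dict(g.aai.loc[rep]), g.clade_map.get(rep))
        assert out.call == oc.RankCall.NOVEL_SPECIES
        assert out.clade_override_applied
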