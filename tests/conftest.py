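import dendropy
import pytest
from hypothesis import settings

import opucore as oc

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim():
    """One simulated dataset at the default study conditions."""
    return oc.simulate_dataset(oc.SimConfig(seed=7))


@pytest.fixture()
def simple_refs():
    """Three type strains spanning two genera of one family."""
    mk = oc.make_lineage
    return [
        oc.ReferenceTaxon("R1", mk("P1", "C1", "O1", "F1", "G1", "S1"), True),
        oc.ReferenceTaxon("R2", mk("P1", "C1", "O1", "F1", "G1", "S2"), True),
        oc.ReferenceTaxon("R3", mk("P1", "C1", "O1", "F1", "G2", "S3"), True),
    ]


def parse_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    tree.is_rooted = True
    return tree


def truth_partition(truth: oc.GroundTruth) -> set[frozenset]:
    groups: dict[str, set[str]] = {}
    for q, pid in truth.opu_membership.items():
        groups.setdefault(pid, set()).add(q)
    return {frozenset(v) for v in groups.values()}


def truth_category_by_members(truth: oc.GroundTruth) -> dict[frozenset, str]:
    groups: dict[str, set[str]] = {}
    for q, pid in truth.opu_membership.items():
        groups.setdefault(pid, set()).add(q)
    return {frozenset(v): truth.opu_category[pid] for pid, v in groups.items()}
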