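"""Plain-text readers and writers for every artifact of the pipeline.

Trees are Newick; matrices and tables are TSV with labelled first column;
summaries are JSON.  Writers use fixed float formats so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import InputError
from .opu import Opu, OpuCategory, OtuRecord, ReferenceTaxon, format_lineage, parse_lineage
from .sgb import GenomeRecord, RankAssignment, SgbCluster


def read_newick(path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", unquoted_underscores=True, suppress_rooting=True)
    )


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix_tsv(df: pd.DataFrame, path, decimals: int = 2) -> None:
    df.to_csv(path, sep="\t", float_format=f"%.{decimals}f")


# --- references and OTUs ----------------------------------------------------


def write_reference_table(refs: Sequence[ReferenceTaxon], path) -> None:
    pd.DataFrame(
        {
            "tip_id": [r.tip_id for r in refs],
            "lineage": [format_lineage(r.lineage) for r in refs],
            "is_type_strain": [int(r.is_type_strain) for r in refs],
        }
    ).to_csv(path, sep="\t", index=False)


def read_reference_table(path) -> list[ReferenceTaxon]:
    df = pd.read_csv(path, sep="\t", dtype={"tip_id": str})
    for col in ("tip_id", "lineage", "is_type_strain"):
        if col not in df.columns:
            raise InputError(f"reference table missing column {col!r}")
    return [
        ReferenceTaxon(row.tip_id, parse_lineage(str(row.lineage)), bool(row.is_type_strain))
        for row in df.itertuples()
    ]


def write_otu_counts(otus: Sequence[OtuRecord], path) -> None:
    pd.DataFrame(
        {"tip_id": [o.tip_id for o in otus], "total_count": [o.total_count for o in otus]}
    ).to_csv(path, sep="\t", index=False)


def read_otu_records(counts_path, identities_path=None) -> list[OtuRecord]:
    """OTU records from a count TSV plus an optional identity matrix."""
    df = pd.read_csv(counts_path, sep="\t", dtype={"tip_id": str})
    ident = read_matrix_tsv(identities_path) if identities_path is not None else None
    out = []
    for row in df.itertuples():
        idents: Mapping[str, float] = {}
        if ident is not None and row.tip_id in ident.index:
            idents = ident.loc[row.tip_id].dropna().to_dict()
        out.append(OtuRecord(row.tip_id, int(row.total_count), idents))
    return out


# --- OPUs -------------------------------------------------------------------


def write_opu_table(opus: Sequence[Opu], path) -> None:
    pd.DataFrame(
        {
            "opu_id": [o.opu_id for o in opus],
            "members": [",".join(o.members) for o in opus],
            "anchor_refs": [",".join(o.anchor_refs) for o in opus],
            "category": [o.category.value if o.category else "" for o in opus],
            "assigned_taxon": [o.assigned_taxon for o in opus],
            "representative": [o.representative for o in opus],
            "best_identity": [
                f"{o.best_identity:.2f}" if o.best_identity is not None else "" for o in opus
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_opu_table(path) -> list[Opu]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for row in df.itertuples():
        out.append(
            Opu(
                opu_id=row.opu_id,
                members=row.members.split(",") if row.members else [],
                anchor_refs=row.anchor_refs.split(",") if row.anchor_refs else [],
                category=OpuCategory(row.category) if row.category else None,
                assigned_taxon=row.assigned_taxon,
                representative=row.representative,
                best_identity=float(row.best_identity) if row.best_identity else None,
            )
        )
    return out


# --- genomes ----------------------------------------------------------------


def write_genome_table(genomes: Sequence[GenomeRecord], path) -> None:
    pd.DataFrame(
        {
            "genome_id": [g.genome_id for g in genomes],
            "completeness": [f"{g.completeness:.2f}" for g in genomes],
            "contamination": [f"{g.contamination:.2f}" for g in genomes],
            "strain_heterogeneity": [f"{g.strain_heterogeneity:.2f}" for g in genomes],
            "n50": [g.n50 for g in genomes],
        }
    ).to_csv(path, sep="\t", index=False)


def read_genome_table(path) -> list[GenomeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str})
    return [
        GenomeRecord(
            row.genome_id,
            float(row.completeness),
            float(row.contamination),
            float(row.strain_heterogeneity),
            int(row.n50),
        )
        for row in df.itertuples()
    ]


def write_cluster_table(clusters: Sequence[SgbCluster], path) -> None:
    pd.DataFrame(
        {
            "cluster_id": [c.cluster_id for c in clusters],
            "members": [",".join(c.members) for c in clusters],
            "representative": [c.representative for c in clusters],
        }
    ).to_csv(path, sep="\t", index=False)


def write_rank_table(ranks: Sequence[RankAssignment], path) -> None:
    pd.DataFrame(
        {
            "cluster_id": [r.cluster_id for r in ranks],
            "call": [r.call.value for r in ranks],
            "nearest_named": [r.nearest_named for r in ranks],
            "ani_best": [f"{r.ani_best:.2f}" if r.ani_best is not None else "" for r in ranks],
            "aai_best": [f"{r.aai_best:.2f}" if r.aai_best is not None else "" for r in ranks],
            "clade_override_applied": [int(r.clade_override_applied) for r in ranks],
        }
    ).to_csv(path, sep="\t", index=False)


def read_clade_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"genome_id", "genus_clade"} <= set(df.columns):
        raise InputError("clade map needs columns genome_id, genus_clade")
    return {r.genome_id: r.genus_clade for r in df.itertuples() if r.genus_clade}


def write_clade_map(clade_map: Mapping[str, str], path) -> None:
    items = sorted(clade_map.items())
    pd.DataFrame(
        {"genome_id": [k for k, _ in items], "genus_clade": [v for _, v in items]}
    ).to_csv(path, sep="\t", index=False)


# --- misc -------------------------------------------------------------------


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_lengths_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    col = "length" if "length" in df.columns else df.columns[-1]
    return df[col].to_numpy(dtype=int)


def write_lengths_tsv(lengths, path) -> None:
    pd.DataFrame({"length": np.asarray(lengths, dtype=int)}).to_csv(path, sep="\t", index=False)
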