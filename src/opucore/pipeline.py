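"""End-to-end orchestration: simulate → qc → opu → core → sgb.

One JSON (or YAML) config document drives the whole run; every threshold
is a named key defaulting to the standard values (98.7 / 94.5 identity,
0.90 prevalence, 99 / 95 ANI, 65 / 50 AAI).  Outputs are plain-text files
under per-stage subdirectories plus a ``manifest.json`` that echoes the
config, hashes all inputs and lists all outputs; identical config and seed
reproduce identical outputs (the manifest carries no timestamps).
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

from . import io
from .community import AbundanceTable, CoreConfig, detect_core, richness_stats, summarize_categories
from .errors import ConfigError, OpucoreError, StageError
from .opu import ThresholdConfig, call_opus
from .qc import QcConfig, run_qc
from .sgb import (
    RankConfig,
    assign_rank,
    cluster_genomes,
    genome_quality_score,
    passes_quality_filter,
)
from .synthetic import SimConfig, simulate_dataset

__version__ = "0.1.0"

log = logging.getLogger("opucore")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {},
    "qc": {"min_len": 1200, "max_len": 1600, "lengths": None},
    "opu": {
        "species_identity": 98.7,
        "genus_identity": 94.5,
        "tree": None,
        "refs": None,
        "identities": None,
        "counts": None,
    },
    "core": {
        "prevalence_threshold": 0.90,
        "strict": True,
        "counts": None,
        "opu_members": None,
    },
    "sgb": {
        "ani_dereplicate": 99.0,
        "ani_species": 95.0,
        "aai_species": 95.0,
        "aai_genus_low": 65.0,
        "aai_family_low": 50.0,
        "quality": None,
        "ani": None,
        "aai": None,
        "clade_map": None,
    },
}


@dataclasses.dataclass
class RunManifest:
    version: str
    seed: int
    config: dict
    inputs: dict[str, str]  # path -> sha256
    outputs: dict[str, dict[str, str]]  # stage -> name -> path

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    return doc


def _merge_config(user: dict) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, val in user.items():
        if key == "seed":
            cfg["seed"] = int(val)
        elif key in ("simulate", "qc", "opu", "core", "sgb"):
            if val is None:
                cfg[key] = None
            elif isinstance(val, dict):
                if key == "simulate":
                    cfg[key] = dict(val)
                else:
                    unknown = set(val) - set(cfg[key])
                    if unknown:
                        raise ConfigError(f"unknown keys in [{key}]: {sorted(unknown)}")
                    cfg[key].update(val)
            else:
                raise ConfigError(f"section [{key}] must be a mapping or null")
        else:
            raise ConfigError(f"unknown config section {key!r}")
    return cfg


def _require_path(stage: str, name: str, value: Optional[str]) -> Path:
    if value is None:
        raise ConfigError(f"[{stage}] needs an input path for {name!r}")
    p = Path(value)
    if not p.exists():
        raise ConfigError(f"[{stage}] input file not found: {p}")
    return p


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config, outdir, seed: Optional[int] = None) -> RunManifest:
    """Run every configured stage in dependency order.

    *config* is a mapping or a path to a JSON/YAML document.  When the
    ``simulate`` section is present its outputs feed the later stages;
    otherwise each stage reads the file paths named in its section.
    Returns the manifest, which is also written to ``outdir/manifest.json``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = _merge_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(__version__, cfg["seed"], cfg, {}, {})

    sim = None
    if cfg["simulate"] is not None:
        stage_dir = outdir / "simulate"
        stage_dir.mkdir(exist_ok=True)
        try:
            sim_cfg = SimConfig(**{**cfg["simulate"], "seed": cfg["seed"]})
            sim = simulate_dataset(sim_cfg)
            paths = _write_simulated(sim, stage_dir)
        except OpucoreError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage context
            raise StageError("simulate", str(exc)) from exc
        manifest.outputs["simulate"] = {k: str(v) for k, v in paths.items()}
        log.info("simulate: %d refs, %d queries, %d genomes",
                 len(sim.refs), sim_cfg.n_queries, len(sim.genomes.genomes))

    # ---- qc ----------------------------------------------------------------
    if cfg["qc"] is not None:
        stage_dir = outdir / "qc"
        stage_dir.mkdir(exist_ok=True)
        try:
            qc_cfg = QcConfig(int(cfg["qc"]["min_len"]), int(cfg["qc"]["max_len"]))
            if cfg["qc"]["lengths"] is not None:
                path = _require_path("qc", "lengths", cfg["qc"]["lengths"])
                manifest.inputs[str(path)] = _sha256(path)
                lengths = io.read_lengths_tsv(path)
            elif sim is not None:
                lengths = sim.read_lengths
            else:
                raise ConfigError("[qc] needs 'lengths' when simulate is disabled")
            summary = run_qc(lengths, qc_cfg)
            out = stage_dir / "qc_summary.json"
            io.write_json(dataclasses.asdict(summary), out)
        except OpucoreError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("qc", str(exc)) from exc
        manifest.outputs["qc"] = {"summary": str(out)}
        log.info("qc: retained %d/%d (%.2f%%) with window [%d, %d]",
                 summary.retained_count, summary.raw_count, summary.retention_pct,
                 qc_cfg.min_len, qc_cfg.max_len)

    # ---- opu ---------------------------------------------------------------
    opus = None
    if cfg["opu"] is not None:
        stage_dir = outdir / "opu"
        stage_dir.mkdir(exist_ok=True)
        try:
            thr = ThresholdConfig(
                float(cfg["opu"]["species_identity"]), float(cfg["opu"]["genus_identity"])
            )
            if sim is not None and cfg["opu"]["tree"] is None:
                tree, refs, otus = sim.tree, sim.refs, sim.otus
            else:
                tree_p = _require_path("opu", "tree", cfg["opu"]["tree"])
                refs_p = _require_path("opu", "refs", cfg["opu"]["refs"])
                id_p = _require_path("opu", "identities", cfg["opu"]["identities"])
                cnt_p = _require_path("opu", "counts", cfg["opu"]["counts"])
                for p in (tree_p, refs_p, id_p, cnt_p):
                    manifest.inputs[str(p)] = _sha256(p)
                tree = io.read_newick(tree_p)
                refs = io.read_reference_table(refs_p)
                otus = io.read_otu_records(cnt_p, id_p)
            opus = call_opus(tree, refs, otus, thr)
            out = stage_dir / "opus.tsv"
            io.write_opu_table(opus, out)
        except OpucoreError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("opu", str(exc)) from exc
        manifest.outputs["opu"] = {"opus": str(out)}
        log.info("opu: %d OPUs at thresholds %.1f/%.1f",
                 len(opus), thr.species_identity, thr.genus_identity)

    # ---- core --------------------------------------------------------------
    if cfg["core"] is not None:
        stage_dir = outdir / "core"
        stage_dir.mkdir(exist_ok=True)
        try:
            core_cfg = CoreConfig(
                float(cfg["core"]["prevalence_threshold"]), bool(cfg["core"]["strict"])
            )
            if sim is not None and cfg["core"]["counts"] is None:
                table = sim.abundance
                members_of = {
                    pid: [q for q, p in sim.truth.opu_membership.items() if p == pid]
                    for pid in table.opus
                }
            else:
                cnt_p = _require_path("core", "counts", cfg["core"]["counts"])
                manifest.inputs[str(cnt_p)] = _sha256(cnt_p)
                table = AbundanceTable.from_tsv(cnt_p)
                members_of = None
                if cfg["core"]["opu_members"] is not None:
                    mem_p = _require_path("core", "opu_members", cfg["core"]["opu_members"])
                    manifest.inputs[str(mem_p)] = _sha256(mem_p)
                    members_of = _read_members(mem_p)
            core = detect_core(table, core_cfg)
            mean_rich, sd_rich = richness_stats(table)
            outputs = {}
            core_out = stage_dir / "core.tsv"
            with open(core_out, "w") as fh:
                fh.write("opu_id\n" + "".join(f"{c}\n" for c in core.core_opus))
            outputs["core"] = str(core_out)
            summary = {
                "n_core": len(core.core_opus),
                "core_mean_abundance_pct": round(core.mean_abundance_pct, 2),
                "core_sd_abundance_pct": round(core.sd_abundance_pct, 2),
                "richness_mean": round(mean_rich, 2),
                "richness_sd": round(sd_rich, 2),
            }
            if opus is not None:
                cat_map = _column_categories(table.opus, opus, members_of)
                cats = summarize_categories(cat_map, table)
                summary["categories"] = {
                    k: {"n_opus": v.n_opus, "mean_abundance_pct": round(v.mean_abundance_pct, 2)}
                    for k, v in cats.items()
                }
            sum_out = stage_dir / "core_summary.json"
            io.write_json(summary, sum_out)
            outputs["summary"] = str(sum_out)
        except OpucoreError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("core", str(exc)) from exc
        manifest.outputs["core"] = outputs
        log.info("core: %d core OPUs (mean %.2f%% of the community)",
                 len(core.core_opus), core.mean_abundance_pct)

    # ---- sgb ---------------------------------------------------------------
    if cfg["sgb"] is not None:
        stage_dir = outdir / "sgb"
        stage_dir.mkdir(exist_ok=True)
        try:
            rank_cfg = RankConfig(
                ani_species=float(cfg["sgb"]["ani_species"]),
                ani_dereplicate=float(cfg["sgb"]["ani_dereplicate"]),
                aai_species=float(cfg["sgb"]["aai_species"]),
                aai_genus_low=float(cfg["sgb"]["aai_genus_low"]),
                aai_family_low=float(cfg["sgb"]["aai_family_low"]),
            )
            if sim is not None and cfg["sgb"]["quality"] is None:
                genomes = sim.genomes.genomes
                ani, aai, clade_map = sim.genomes.ani, sim.genomes.aai, sim.genomes.clade_map
            else:
                q_p = _require_path("sgb", "quality", cfg["sgb"]["quality"])
                ani_p = _require_path("sgb", "ani", cfg["sgb"]["ani"])
                aai_p = _require_path("sgb", "aai", cfg["sgb"]["aai"])
                for p in (q_p, ani_p, aai_p):
                    manifest.inputs[str(p)] = _sha256(p)
                genomes = io.read_genome_table(q_p)
                ani = io.read_matrix_tsv(ani_p)
                aai = io.read_matrix_tsv(aai_p)
                clade_map = {}
                if cfg["sgb"]["clade_map"] is not None:
                    cm_p = _require_path("sgb", "clade_map", cfg["sgb"]["clade_map"])
                    manifest.inputs[str(cm_p)] = _sha256(cm_p)
                    clade_map = io.read_clade_map(cm_p)
            kept = [g for g in genomes if passes_quality_filter(g)]
            derep = cluster_genomes(kept, ani, rank_cfg.ani_dereplicate)
            by_id = {g.genome_id: g for g in kept}
            reps = [by_id[c.representative] for c in derep]
            species = cluster_genomes(reps, ani, rank_cfg.ani_species)
            # expand species clusters back over the dereplicated members
            derep_members = {c.representative: list(c.members) for c in derep}
            full_species = [
                dataclasses.replace(
                    c,
                    members=tuple(sorted(m for r in c.members for m in derep_members[r])),
                )
                for c in species
            ]
            ranks = []
            for c in full_species:
                row = aai.loc[c.representative].dropna() if c.representative in aai.index else {}
                ranks.append(
                    assign_rank(
                        c.cluster_id,
                        {},
                        dict(row) if len(row) else {},
                        clade_map.get(c.representative),
                        rank_cfg,
                    )
                )
            outputs = {}
            io.write_cluster_table(full_species, stage_dir / "clusters.tsv")
            io.write_rank_table(ranks, stage_dir / "ranks.tsv")
            with open(stage_dir / "quality_scores.tsv", "w") as fh:
                fh.write("genome_id\tquality_score\tpasses_filter\n")
                for g in genomes:
                    fh.write(
                        f"{g.genome_id}\t{genome_quality_score(g):.3f}"
                        f"\t{int(passes_quality_filter(g))}\n"
                    )
            for name in ("clusters", "ranks", "quality_scores"):
                outputs[name] = str(stage_dir / f"{name}.tsv")
        except OpucoreError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("sgb", str(exc)) from exc
        manifest.outputs["sgb"] = outputs
        log.info("sgb: %d genomes kept, %d species clusters", len(kept), len(full_species))

    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _read_members(path) -> dict[str, list[str]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {r.opu_id: r.members.split(",") if r.members else [] for r in df.itertuples()}


def _column_categories(columns, opus, members_of) -> dict[str, str]:
    """Category for each abundance-table column, via the OPU calls.

    Columns that are themselves OPU ids map directly; otherwise the column's
    member OTUs (from the grouping file) locate the called OPU containing
    them.
    """
    by_id = {o.opu_id: o for o in opus}
    if all(c in by_id for c in columns):
        return {c: by_id[c].category.value for c in columns}
    if members_of is None:
        raise ConfigError(
            "[core] abundance columns are not OPU ids and no opu_members grouping was given"
        )
    member_to_cat = {m: o.category.value for o in opus for m in o.members}
    out = {}
    for col in columns:
        cats = {member_to_cat[m] for m in members_of.get(col, []) if m in member_to_cat}
        if not cats:
            raise ConfigError(f"[core] column {col!r} has no members with a called category")
        out[col] = sorted(cats)[0] if len(cats) == 1 else _majority(
            [member_to_cat[m] for m in members_of[col] if m in member_to_cat]
        )
    return out


def _majority(cats: list[str]) -> str:
    best = max(set(cats), key=lambda c: (cats.count(c), c))
    return best


def _write_simulated(sim, stage_dir: Path) -> dict[str, Path]:
    paths = {
        "backbone": stage_dir / "backbone.nwk",
        "tree": stage_dir / "tree.nwk",
        "refs": stage_dir / "refs.tsv",
        "identities": stage_dir / "identities.tsv",
        "otus": stage_dir / "otus.tsv",
        "counts": stage_dir / "counts.tsv",
        "opu_members": stage_dir / "opu_members.tsv",
        "read_lengths": stage_dir / "read_lengths.tsv",
        "quality": stage_dir / "quality.tsv",
        "ani": stage_dir / "ani.tsv",
        "aai": stage_dir / "aai.tsv",
        "clade_map": stage_dir / "clade_map.tsv",
        "ground_truth": stage_dir / "ground_truth.json",
        "sim_config": stage_dir / "sim_config.json",
    }
    io.write_newick(sim.backbone, paths["backbone"])
    io.write_newick(sim.tree, paths["tree"])
    io.write_reference_table(sim.refs, paths["refs"])
    io.write_matrix_tsv(sim.identity, paths["identities"])
    io.write_otu_counts(sim.otus, paths["otus"])
    sim.abundance.to_tsv(paths["counts"])
    members: dict[str, list[str]] = {}
    for q, pid in sorted(sim.truth.opu_membership.items()):
        members.setdefault(pid, []).append(q)
    with open(paths["opu_members"], "w") as fh:
        fh.write("opu_id\tmembers\n")
        for pid in sorted(members):
            fh.write(f"{pid}\t{','.join(sorted(members[pid]))}\n")
    io.write_lengths_tsv(sim.read_lengths, paths["read_lengths"])
    io.write_genome_table(sim.genomes.genomes, paths["quality"])
    io.write_matrix_tsv(sim.genomes.ani, paths["ani"])
    io.write_matrix_tsv(sim.genomes.aai, paths["aai"])
    io.write_clade_map(sim.genomes.clade_map, paths["clade_map"])
    Path(paths["ground_truth"]).write_text(sim.truth.to_json() + "\n")
    Path(paths["sim_config"]).write_text(sim.config.to_json() + "\n")
    return paths
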