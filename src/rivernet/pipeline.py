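"""End-to-end orchestration: load -> preprocess -> per-group networks ->
topology -> roles/modules -> neutral-model fits -> HAILS -> correlations.

A single YAML config drives the run; every seed is derived from one master
seed per stage and recorded, together with all thresholds and input-file
hashes, in a machine-readable manifest. Reruns of the same config produce
byte-identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import envstats, hails, modules, ncm, preprocess, topology
from .inference import InferenceConfig, infer_network
from .io import (
    AbundanceMatrix,
    read_abundance,
    read_landuse,
    read_metadata,
    write_network,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    abundance: str
    output_dir: str
    taxonomy: str | None = None
    metadata: str | None = None
    landuse: str | None = None
    taxa_in_rows: bool = True
    group_columns: tuple[str, ...] = ("reach", "season")
    rarefaction_depth: int | None = None  # default: min sample total
    min_taxon_total: int = 30
    min_group_samples: int = 4
    master_seed: int = 0
    inference: dict = field(default_factory=dict)  # InferenceConfig overrides
    env_columns: list[str] | None = None  # numeric metadata columns; default: all numeric
    keystone_r_min: float = 0.8
    keystone_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "group_columns" in raw:
            raw["group_columns"] = tuple(raw["group_columns"])
        return cls(**raw)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (master_seed + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _group_key(values: tuple) -> str:
    return "_".join(str(v) for v in values)


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = read_abundance(
        config.abundance,
        taxa_in_rows=config.taxa_in_rows,
        taxonomy_path=config.taxonomy,
        metadata_path=config.metadata,
    )
    if config.metadata is not None and matrix.sample_data is None:
        raise ValueError("metadata file produced no table")

    group_col_missing = []
    if matrix.sample_data is not None:
        group_col_missing = [c for c in config.group_columns if c not in matrix.sample_data.columns]
    if config.metadata is not None and group_col_missing:
        raise ValueError(f"grouping columns missing from metadata: {group_col_missing}")

    depth = config.rarefaction_depth or int(matrix.counts.sum(axis=1).min())
    rarefied = preprocess.rarefy(matrix, depth, seed=stage_seed(config.master_seed, "rarefy"))

    diversity = preprocess.alpha_diversity(rarefied)
    diversity.to_csv(out / "diversity.tsv", sep="\t", index_label="sample", lineterminator="\n")

    # ------------------------------------------------------------- groups
    if matrix.sample_data is not None and not group_col_missing:
        keys = rarefied.sample_data[list(config.group_columns)].apply(tuple, axis=1)
        group_map = {g: list(idx) for g, idx in keys.groupby(keys).groups.items()}
    else:
        group_map = {("all",): rarefied.sample_ids}

    inf_cfg_base = dict(min_taxon_total=config.min_taxon_total, **config.inference)
    topo_rows = {}
    ncm_fits = {}
    census_rows = {}
    skipped = {}
    for gkey in sorted(group_map, key=_group_key):
        samples = group_map[gkey]
        name = _group_key(gkey)
        if len(samples) < config.min_group_samples:
            skipped[name] = f"only {len(samples)} samples (< {config.min_group_samples})"
            logger.warning("skipping group %s: %s", name, skipped[name])
            continue
        gmat = rarefied.subset_samples(samples)
        gmat_f = preprocess.filter_taxa(gmat, config.min_taxon_total)
        cfg = InferenceConfig(
            seed=stage_seed(config.master_seed, f"network/{name}"), **inf_cfg_base
        )
        net = infer_network(gmat_f, cfg)
        write_network(net, out / f"network_{name}.tsv", fmt="tsv")
        write_network(net, out / f"network_{name}.graphml", fmt="graphml")

        if net.n_nodes > 0:
            part = modules.detect_modules(net, seed=stage_seed(config.master_seed, f"modules/{name}"))
            summary = topology.summarize(net, part.assignment, part.modularity)
            roles = modules.classify_roles(net, part)
            roles.to_csv(out / f"roles_{name}.tsv", sep="\t", lineterminator="\n")
            census_rows[name] = modules.role_census(roles)
            profiles = modules.module_profiles(net, part)
            profiles.drop(columns=["composition"]).to_csv(
                out / f"module_profiles_{name}.tsv", sep="\t", lineterminator="\n"
            )
            topo_rows[name] = summary.as_dict()

            keystones = modules.keystone_nodes(roles)
            if matrix.sample_data is not None and keystones:
                env = _numeric_env(gmat, config.env_columns)
                if not env.empty:
                    knet = envstats.keystone_env_network(
                        keystones, gmat, env, config.keystone_r_min, config.keystone_alpha
                    )
                    write_network(knet, out / f"keystone_env_{name}.tsv", fmt="tsv")
        else:
            skipped[name] = "network empty after thresholding"

        ncm_fits[gkey] = ncm.fit(gmat)

    if topo_rows:
        topo_df = pd.DataFrame.from_dict(topo_rows, orient="index")
        topo_df.round(3).to_csv(out / "topology.tsv", sep="\t", index_label="group", lineterminator="\n")
    if census_rows:
        pd.DataFrame.from_dict(census_rows, orient="index").round(4).to_csv(
            out / "role_census.tsv", sep="\t", index_label="group", lineterminator="\n"
        )
    if ncm_fits:
        ncm.compare_groups(ncm_fits).to_csv(out / "ncm.tsv", sep="\t", index=False, lineterminator="\n")

    # ------------------------------------------------------------- HAILS
    if config.landuse is not None:
        lut = read_landuse(config.landuse)
        hres = hails.compute_hails(lut)
        hres = hails.classify_reaches(hres)
        hres.round(3).to_csv(out / "hails.tsv", sep="\t", index_label="sub_basin", lineterminator="\n")

    # -------------------------------------- network-index x environment
    # observation unit: one network (reach x season group) per row, paired
    # with the group-mean environmental values -- small n, flagged low power
    if topo_rows and matrix.sample_data is not None:
        env_all = _numeric_env(rarefied, config.env_columns)
        if not env_all.empty:
            group_env = {}
            for gkey, samples in group_map.items():
                name = _group_key(gkey)
                if name in topo_rows:
                    group_env[name] = env_all.loc[env_all.index.intersection(samples)].mean()
            env_df = pd.DataFrame.from_dict(group_env, orient="index")
            topo_df = pd.DataFrame.from_dict(topo_rows, orient="index")
            numeric = topo_df.select_dtypes("number")
            corr = envstats.correlate(numeric, env_df)
            corr.to_csv(out / "index_env_correlations.tsv", sep="\t", index=False, lineterminator="\n")

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "rarefaction_depth": depth,
        "stage_seeds": {
            s: stage_seed(config.master_seed, s)
            for s in ["rarefy"] + [f"network/{_group_key(g)}" for g in sorted(group_map, key=_group_key)]
        },
        "inputs": {
            k: _sha256(p)
            for k, p in {
                "abundance": config.abundance,
                "taxonomy": config.taxonomy,
                "metadata": config.metadata,
                "landuse": config.landuse,
            }.items()
            if p is not None
        },
        "groups": {_group_key(g): len(s) for g, s in group_map.items()},
        "skipped_groups": skipped,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def _numeric_env(matrix: AbundanceMatrix, columns: list[str] | None) -> pd.DataFrame:
    sd = matrix.sample_data
    if sd is None:
        return pd.DataFrame()
    env = sd.select_dtypes("number")
    if columns is not None:
        env = env[[c for c in columns if c in env.columns]]
    return env
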