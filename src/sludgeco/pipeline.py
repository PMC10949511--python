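"""End-to-end pipeline: table preparation -> diversity -> neutral model ->
per-plant networks + consensus -> guilds -> genome-sequenced proportions ->
RDA, driven by a single YAML-able config with seeded determinism.

Every output table gets a provenance sidecar (package version, config
hash, seeds) so identical configs reproduce byte-identical runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diversity as div
from . import guilds as guilds_mod
from . import mdm as mdm_mod
from . import network as net
from . import ncm as ncm_mod
from . import ordination as ord_mod
from .simulate import (
    GraphSimSpec,
    NeutralSimSpec,
    generate_reference_set,
    generate_taxonomy_and_guilds,
    random_sequences,
    simulate_graph_community,
)
from .tables import (
    OtuTable,
    read_fasta,
    read_metadata,
    read_operational,
    read_otu_table,
    read_taxonomy,
    remove_singletons,
    rarefy,
    relative_abundance,
    write_fasta,
    write_otu_table,
    write_taxonomy,
)

log = logging.getLogger("sludgeco")

DEFAULT_PARAMS: dict[str, Any] = {
    "depth": 25000,
    "spearman_alpha": 0.05,
    "intersect_alpha": 0.01,
    "mean_filter": 1e-4,
    "prevalence": 0.8,
    "core_min_rel": 1e-3,
    "n_boot": 1000,
    "min_plants": 2,
    "stars_B": 50,
    "stars_beta": 0.05,
    "lambda_path": 20,
    "lambda_min_ratio": 0.01,
    "subsample_ratio": 0.8,
    "rda_n_perm": 999,
    "wanted_min_rel": 1e-3,
}

DEFAULT_STAGES = ("table", "diversity", "ncm", "network", "guilds", "mdm", "rda")


def config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_df(df: pd.DataFrame, path: Path, sidecar: dict) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")
    with open(path.with_suffix(path.suffix + ".prov.yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def run_pipeline(config: Mapping, out_dir: str | Path) -> Path:
    """Run the configured stages in dependency order.

    ``config`` keys: ``inputs`` (otu_table, taxonomy, metadata,
    operational, sequences, references, wanted — all paths, most
    optional), ``stages`` (name -> bool), ``params`` (overrides of
    :data:`DEFAULT_PARAMS`) and ``seed``.  Returns the run directory.
    Stage failures abort with the stage named; outputs of completed
    stages are retained.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(config)
    params = {**DEFAULT_PARAMS, **cfg.get("params", {})}
    stages = {s: True for s in DEFAULT_STAGES}
    stages.update(cfg.get("stages", {}))
    seed = int(cfg.get("seed", 0))
    chash = config_hash(cfg)
    prov_base = {"version": __version__, "config_hash": chash, "seed": seed}

    inputs = cfg.get("inputs", {})
    if "otu_table" not in inputs:
        raise ValueError("config.inputs.otu_table is required")

    def _stage(name: str) -> bool:
        return bool(stages.get(name, True))

    try:
        table = read_otu_table(inputs["otu_table"])
        taxonomy = read_taxonomy(inputs["taxonomy"]) if inputs.get("taxonomy") else None
        metadata = read_metadata(inputs["metadata"]) if inputs.get("metadata") else None
    except Exception as exc:
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc
    log.info("loaded table: %d taxa x %d samples", table.n_taxa, table.n_samples)

    plant_of: dict[str, str] = {}
    as_samples: list[str] = list(table.sample_ids)
    if metadata is not None:
        plant_of = dict(zip(metadata["sample_id"], metadata["plant"]))
        as_set = set(metadata.loc[metadata["sample_type"] == "AS", "sample_id"])
        as_samples = [s for s in table.sample_ids if s in as_set] or as_samples

    # --- table preparation ------------------------------------------------
    if _stage("table"):
        try:
            table = remove_singletons(table)
            if params["depth"]:
                table = rarefy(table, int(params["depth"]), seed=seed)
            table = table.drop_empty_taxa()
        except Exception as exc:
            raise RuntimeError(f"stage 'table' failed: {exc}") from exc
        write_otu_table(table, out / "table.tsv")
        with open(out / "table.tsv.prov.yaml", "w") as fh:
            yaml.safe_dump({**prov_base, "stage": "table", "depth": params["depth"]}, fh)
        as_samples = [s for s in as_samples if s in set(table.sample_ids)]
        log.info("prepared table: %d taxa x %d samples", table.n_taxa, table.n_samples)

    plants = sorted({plant_of.get(s, "ALL") for s in as_samples})

    def plant_table(plant: str) -> OtuTable:
        cols = [s for s in as_samples if plant_of.get(s, "ALL") == plant]
        return table.subset_samples(cols).drop_empty_taxa()

    # --- diversity --------------------------------------------------------
    if _stage("diversity"):
        try:
            alpha = div.alpha_diversity(table)
            dm = div.bray_curtis(table)
            ordn = div.pcoa(dm)
        except Exception as exc:
            raise RuntimeError(f"stage 'diversity' failed: {exc}") from exc
        _write_df(alpha, out / "alpha_diversity.tsv", {**prov_base, "stage": "diversity"})
        _write_df(
            pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)),
            out / "bray_curtis.tsv",
            {**prov_base, "stage": "diversity"},
        )
        coords = ordn.coordinates.copy()
        _write_df(coords, out / "pcoa_coordinates.tsv",
                  {**prov_base, "stage": "diversity",
                   "proportion_explained": [float(x) for x in ordn.proportion_explained]})

    # --- neutral community model -----------------------------------------
    if _stage("ncm"):
        try:
            rows = []
            for plant in plants:
                pt = plant_table(plant)
                if pt.n_samples < 2:
                    log.warning("plant %s has <2 AS samples; NCM skipped", plant)
                    continue
                fit = ncm_mod.fit_ncm(
                    ncm_mod.build_ncm_input(pt), n_boot=int(params["n_boot"]), seed=seed
                )
                rows.append(
                    {
                        "plant": plant, "m": fit.m_hat, "Nm": fit.Nm, "r2": fit.r2,
                        "n_taxa": fit.n_taxa, "N": fit.N,
                        "m_ci_low": fit.ci.get("m", (np.nan, np.nan))[0],
                        "m_ci_high": fit.ci.get("m", (np.nan, np.nan))[1],
                        "r2_ci_low": fit.ci.get("r2", (np.nan, np.nan))[0],
                        "r2_ci_high": fit.ci.get("r2", (np.nan, np.nan))[1],
                    }
                )
                _write_df(fit.per_taxon, out / f"ncm_per_taxon_{plant}.tsv",
                          {**prov_base, "stage": "ncm", "plant": plant})
            summary = pd.DataFrame(rows).set_index("plant") if rows else pd.DataFrame()
            _write_df(summary, out / "ncm_summary.tsv", {**prov_base, "stage": "ncm"})
        except Exception as exc:
            raise RuntimeError(f"stage 'ncm' failed: {exc}") from exc

    # --- networks ---------------------------------------------------------
    consensus = None
    guild_sets: dict[str, set[str]] = {}
    if _stage("guilds") and taxonomy is not None:
        pass  # guild extraction happens below; network consensus reuses it

    if _stage("network"):
        try:
            per_plant: dict[str, list[net.EdgeRecord]] = {}
            core_sets: dict[str, set[str]] = {}
            for plant in plants:
                pt = plant_table(plant)
                if pt.n_samples < 6:
                    log.warning("plant %s has <6 AS samples; network skipped", plant)
                    continue
                from .tables import filter_by_mean_abundance

                ft = filter_by_mean_abundance(pt, params["mean_filter"])
                sp05 = net.spearman_network(ft, params["mean_filter"], params["spearman_alpha"])
                sp01 = [e for e in sp05 if e.p_value < params["intersect_alpha"]]
                mb = net.mb_network(
                    ft,
                    lambda_path=int(params["lambda_path"]),
                    lambda_min_ratio=params["lambda_min_ratio"],
                    stars_B=int(params["stars_B"]),
                    stars_beta=params["stars_beta"],
                    subsample_ratio=params["subsample_ratio"],
                    seed=seed,
                )
                inter = net.intersect_methods(sp01, mb)
                per_plant[plant] = [
                    net.EdgeRecord(e.taxon_a, e.taxon_b, e.rho, e.p_value,
                                   methods=e.methods, plants=frozenset({plant}))
                    for e in inter
                ]
                core_sets[plant] = net.core_taxa(pt, params["prevalence"], params["core_min_rel"])
                stats_ = net.network_stats(sp05)
                log.info("plant %s: %d spearman edges, %d mb, %d intersected, modularity %s",
                         plant, len(sp05), len(mb), len(inter), stats_.get("modularity"))
                net.export_graph(per_plant[plant], out / f"network_{plant}.graphml")
            if taxonomy is not None:
                gsum = guilds_mod.extract_guilds(table, taxonomy)
                guild_sets = {g: set(m) for g, m in gsum.members.items()}
            if len(per_plant) >= 2:
                consensus = net.cross_plant_consensus(
                    per_plant, core_sets, guild_sets, min_plants=int(params["min_plants"])
                )
                net.export_graph(consensus, out / "consensus.graphml")
                net.export_graph(consensus, out / "consensus.gexf", fmt="gexf")
                edge_df = pd.DataFrame(
                    [
                        {"taxon_a": e.taxon_a, "taxon_b": e.taxon_b, "rho": e.rho,
                         "sign": e.sign, "p_value": e.p_value,
                         "plants": ",".join(sorted(e.plants)),
                         "methods": ",".join(sorted(e.methods))}
                        for e in consensus.edges
                    ]
                )
                _write_df(edge_df, out / "consensus_edges.tsv",
                          {**prov_base, "stage": "network",
                           "provenance": consensus.provenance})
                stats_c = net.network_stats(consensus.edges)
                with open(out / "consensus_stats.json", "w") as fh:
                    json.dump({k: v for k, v in stats_c.items() if k != "modules"},
                              fh, indent=2, sort_keys=True)
        except Exception as exc:
            raise RuntimeError(f"stage 'network' failed: {exc}") from exc

    # --- guilds -----------------------------------------------------------
    guild_summary = None
    if _stage("guilds"):
        if taxonomy is None:
            log.warning("no taxonomy input; guild stage skipped")
        else:
            try:
                defs = (guilds_mod.load_guild_definitions(inputs.get("guild_definitions"))
                        if inputs.get("guild_definitions") else None)
                guild_summary = guilds_mod.extract_guilds(table, taxonomy, defs)
                _write_df(guild_summary.per_sample, out / "guild_abundance.tsv",
                          {**prov_base, "stage": "guilds"})
                ratio = guilds_mod.aob_nob_ratio(guild_summary, plant_of or None)
                _write_df(ratio, out / "aob_nob_ratio.tsv", {**prov_base, "stage": "guilds"})
            except Exception as exc:
                raise RuntimeError(f"stage 'guilds' failed: {exc}") from exc

    # --- genome-sequenced proportions ------------------------------------
    if _stage("mdm"):
        if not (inputs.get("sequences") and inputs.get("references")):
            log.warning("sequences/references not both given; mdm stage skipped")
        else:
            try:
                queries = read_fasta(inputs["sequences"])
                refs = read_fasta(inputs["references"])
                queries = {t: queries[t] for t in table.taxon_ids if t in queries}
                matches = mdm_mod.match_exact(queries, refs)
                sub = table.subset_samples(
                    [s for s in table.sample_ids if s in set(as_samples)]
                )
                covered = [t for t in sub.taxon_ids if t in queries]
                sub = OtuTable(sub.counts.loc[covered].copy(), sub.depth_note)
                report = mdm_mod.mdm_proportions(sub, matches, plant_of or None)
                _write_df(report.per_group, out / "mdm_proportions.tsv",
                          {**prov_base, "stage": "mdm"})
                if inputs.get("wanted"):
                    wanted = read_fasta(inputs["wanted"])
                    wl = mdm_mod.wanted_list_map(
                        queries, wanted, sub,
                        min_mean_rel=params["wanted_min_rel"],
                        sample_groups=plant_of or None,
                    )
                    _write_df(wl, out / "wanted_list.tsv", {**prov_base, "stage": "mdm"})
            except Exception as exc:
                raise RuntimeError(f"stage 'mdm' failed: {exc}") from exc

    # --- RDA --------------------------------------------------------------
    if _stage("rda"):
        if not inputs.get("operational") or metadata is None:
            log.warning("operational parameters or metadata missing; rda stage skipped")
        elif guild_summary is None or guild_summary.rel_abundance.empty:
            log.warning("no guild OTUs for RDA response matrix; rda stage skipped")
        else:
            try:
                ops = read_operational(inputs["operational"])
                meta = metadata.set_index("sample_id")
                param_cols = [c for c in ops.columns if c not in ("plant", "date")]
                ops_idx = ops.set_index(["plant", "date"])
                rows, keep = [], []
                for s in as_samples:
                    key = (meta.loc[s, "plant"], meta.loc[s, "date"])
                    if key in ops_idx.index:
                        rows.append(ops_idx.loc[key, param_cols])
                        keep.append(s)
                if len(keep) <= len(param_cols) + 1:
                    raise ValueError("too few samples with operational records for RDA")
                X = pd.DataFrame(rows, index=keep)[param_cols].astype(float)
                counts = table.subset_samples(keep).counts
                Y = counts.loc[[t for t in guild_summary.rel_abundance.index
                                if t in counts.index]].T
                res = ord_mod.rda(Y, X, n_perm=int(params["rda_n_perm"]), seed=seed)
                _write_df(res.marginal, out / "rda_parameter_ranking.tsv",
                          {**prov_base, "stage": "rda",
                           "constrained_proportion": float(res.constrained_proportion),
                           "global_p": float(res.global_p)})
                _write_df(res.sample_scores, out / "rda_sample_scores.tsv",
                          {**prov_base, "stage": "rda"})
                _write_df(res.biplot_scores, out / "rda_biplot_scores.tsv",
                          {**prov_base, "stage": "rda"})
            except Exception as exc:
                raise RuntimeError(f"stage 'rda' failed: {exc}") from exc

    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump({"config": _plain(cfg), "hash": chash, "version": __version__}, fh)
    return out


def _plain(obj):
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# demo dataset


def make_demo_inputs(
    out_dir: str | Path,
    seed: int = 0,
    n_taxa: int = 80,
    n_samples: int = 13,
    depth: int = 3000,
    plants: tuple[str, ...] = ("ST", "TP", "SWH", "YL", "SK", "STL"),
) -> dict[str, str]:
    """Write a small six-plant synthetic study to ``out_dir``.

    Per plant, a graph-structured community (shared chain graph, so
    cross-plant consensus edges exist) of ``n_taxa`` taxa over
    ``n_samples`` monthly AS samples; shared taxonomy with planted
    guilds; representative sequences and a half-covered reference set;
    seasonal operational parameters.  Returns a config ``inputs`` dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    months = [f"2018-{m:02d}" for m in range(1, 13)] + ["2019-01"]
    months = months[:n_samples]

    tables = []
    meta_rows = []
    for pi, plant in enumerate(plants):
        spec = GraphSimSpec(
            p=n_taxa, n_samples=n_samples, graph="chain", strength=0.45,
            N=depth, seed=seed * 1000 + pi,
        )
        t, _ = simulate_graph_community(spec)
        t.counts.columns = [f"{plant}_{m}_AS" for m in months]
        tables.append(t.counts)
        for m in months:
            meta_rows.append(
                {"sample_id": f"{plant}_{m}_AS", "plant": plant, "date": m, "sample_type": "AS"}
            )
    combined = OtuTable(pd.concat(tables, axis=1))
    combined.counts.index.name = "#OTU ID"
    write_otu_table(combined, out / "otu_table.tsv")
    pd.DataFrame(meta_rows).to_csv(out / "metadata.csv", index=False)

    tax = generate_taxonomy_and_guilds(
        combined.taxon_ids,
        {"AOB": 0.1, "NOB": 0.05, "PAO": 0.05, "BFB": 0.05, "anammox": 0.0125},
        seed=seed,
    )
    write_taxonomy(tax, out / "taxonomy.tsv")

    seqs = random_sequences(combined.taxon_ids, length=200, seed=seed + 1)
    queries, refs = generate_reference_set(seqs, include_fraction=0.5, seed=seed + 2)
    write_fasta(queries, out / "sequences.fasta")
    write_fasta(refs, out / "references.fasta")
    wanted_ids = list(queries)[: max(4, n_taxa // 10)]
    write_fasta({f"WANTED_{i}": queries[q] for i, q in enumerate(wanted_ids)},
                out / "wanted.fasta")

    ops_rows = []
    for pi, plant in enumerate(plants):
        for mi, m in enumerate(months):
            month_num = int(m.split("-")[1])
            temp = 22 + 6 * np.sin(2 * np.pi * (month_num - 4) / 12) + rng.normal(0, 0.5)
            ops_rows.append(
                {
                    "plant": plant, "date": m,
                    "temperature": round(float(temp), 2),
                    "mcrt": round(float(8 + pi + rng.normal(0, 0.5)), 2),
                    "hrt": round(float(10 + 0.5 * pi + rng.normal(0, 0.3)), 2),
                }
            )
    pd.DataFrame(ops_rows).to_csv(out / "operational.csv", index=False)

    return {
        "otu_table": str(out / "otu_table.tsv"),
        "taxonomy": str(out / "taxonomy.tsv"),
        "metadata": str(out / "metadata.csv"),
        "operational": str(out / "operational.csv"),
        "sequences": str(out / "sequences.fasta"),
        "references": str(out / "references.fasta"),
        "wanted": str(out / "wanted.fasta"),
    }


def demo_config(inputs: Mapping[str, str], seed: int = 0) -> dict:
    """Pipeline config sized for the synthetic six-plant demo."""
    return {
        "seed": seed,
        "inputs": dict(inputs),
        "stages": {s: True for s in DEFAULT_STAGES},
        "params": {
            "depth": 2000,
            "n_boot": 0,
            "stars_B": 20,
            "rda_n_perm": 199,
            "mean_filter": 1e-4,
        },
    }
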