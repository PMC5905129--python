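"""Multi-stage orchestration with an explicit, validated run configuration.

A run executes selected stages in dependency order on files under one
output directory and writes a manifest recording parameters, seeds, input
checksums and per-stage outputs.  All randomness flows from configured
seeds, so identical config + inputs reproduce identical result files.
"""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import pandas as pd

from . import __version__, gsea, io, labeling, mid, sources, synthetic

__all__ = ["validate_config", "run_pipeline", "demo_config"]

STAGE_ORDER = ["simulate", "gsea", "concordance", "mid", "labeling_stats",
               "nucleotide_sources"]

_KNOWN_KEYS = {
    "": {"seed", "stages", "simulate", "gsea", "concordance", "mid",
         "labeling_stats", "nucleotide_sources"},
    "simulate": {"expression", "mid", "dualtracer"},
    "simulate.expression": {"n_probes", "samples_per_group", "node_sets",
                            "planted_modules", "effect_size", "n_datasets"},
    "simulate.expression.node_sets": {"n_modules", "nodes_per_module",
                                      "n_extra_nodes", "disjoint"},
    "simulate.mid": {"metabolites", "tracer_enrichment", "noise_sd",
                     "natural_abundance", "n_replicates"},
    "simulate.dualtracer": {"groups", "n_samples", "noise_sd", "denovo_shift_dist"},
    "gsea": {"n_perm", "weight_exponent", "mode", "min_nodes", "max_nodes",
             "expr", "cls", "probe_map", "ec_map", "gmt"},
    "concordance": {"tau", "a", "b"},
    "mid": {"correct_na", "mode", "normalize_enrichment", "tracer_enrichment",
            "input", "samples"},
    "labeling_stats": {"alpha", "k", "method", "categories", "index", "labels"},
    "nucleotide_sources": {"denovo_min_shift", "input", "labels"},
}


def _check_keys(section: dict, path: str) -> None:
    known = _KNOWN_KEYS.get(path)
    if known is None:
        return
    for key in section:
        if key not in known:
            where = path or "top level"
            raise ValueError(f"unknown config key {key!r} in {where}")
        if isinstance(section[key], dict):
            _check_keys(section[key], f"{path}.{key}" if path else key)


def validate_config(config: dict) -> dict:
    """Reject unknown keys, require explicit seeding, fill stage defaults."""
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    _check_keys(config, "")
    if "seed" not in config:
        raise ValueError("config must set an explicit 'seed' (no wall-clock seeding)")
    stages = config.get("stages", [s for s in STAGE_ORDER if s in config])
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {STAGE_ORDER}")
    config = dict(config)
    config["stages"] = [s for s in STAGE_ORDER if s in stages]
    return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _require(path: Path, stage: str, what: str) -> Path:
    if not Path(path).exists():
        raise FileNotFoundError(
            f"stage {stage!r}: missing required artifact {what} at {path}"
        )
    return Path(path)


def _simulate(cfg: dict, seed: int, outdir: Path, manifest: dict) -> None:
    produced: dict[str, str] = {}
    indir = outdir / "inputs"
    indir.mkdir(parents=True, exist_ok=True)
    if "expression" in cfg:
        e = cfg["expression"]
        ns_cfg = e.get("node_sets", {})
        node_sets = synthetic.gen_node_sets(
            n_modules=ns_cfg.get("n_modules", 30),
            nodes_per_module=ns_cfg.get("nodes_per_module", 8),
            n_extra_nodes=ns_cfg.get("n_extra_nodes", 0),
            disjoint=ns_cfg.get("disjoint", True),
            seed=seed,
        )
        io.write_gmt(node_sets, indir / "modules.gmt")
        produced["gmt"] = str(indir / "modules.gmt")
        for d in range(e.get("n_datasets", 1)):
            truth = synthetic.ExpressionTruth(
                planted_modules={m: int(s) for m, s in e.get("planted_modules", {}).items()},
                effect_size=e.get("effect_size", 0.0),
                seed=seed + 1000 * d,
            )
            ds = synthetic.gen_expression_dataset(
                n_probes=e.get("n_probes", 300),
                samples_per_group=tuple(e.get("samples_per_group", [20, 20])),
                node_sets=node_sets,
                truth=truth,
            )
            tag = f"_{d}" if e.get("n_datasets", 1) > 1 else ""
            io.write_gct(ds.values, indir / f"expression{tag}.gct")
            io.write_cls(ds.labels, indir / f"phenotype{tag}.cls", classes=ds.classes)
            io.write_map_tsv(ds.probe_to_gene, indir / f"probe_map{tag}.tsv")
            io.write_map_tsv(ds.gene_to_ec, indir / f"ec_map{tag}.tsv")
            produced[f"expression{tag}"] = str(indir / f"expression{tag}.gct")
            produced[f"cls{tag}"] = str(indir / f"phenotype{tag}.cls")
            produced[f"probe_map{tag}"] = str(indir / f"probe_map{tag}.tsv")
            produced[f"ec_map{tag}"] = str(indir / f"ec_map{tag}.tsv")
        io.write_json(
            {"planted_modules": dict(e.get("planted_modules", {})),
             "effect_size": e.get("effect_size", 0.0), "seed": seed},
            indir / "expression_truth.json",
        )
    if "mid" in cfg:
        m = cfg["mid"]
        mets = m["metabolites"]
        truth = synthetic.FluxTruth(
            fc={k: dict(v["fc"]) for k, v in mets.items()},
            formulas={k: v["formula"] for k, v in mets.items()},
            tracer_enrichment=m.get("tracer_enrichment", 0.5),
            noise_sd=m.get("noise_sd", 0.05),
            natural_abundance=m.get("natural_abundance", True),
            seed=seed + 1,
        )
        panel = synthetic.gen_mid_panel(truth, n_replicates=m.get("n_replicates", 3))
        io.write_mid_panel(panel, indir / "mid.csv", indir / "mid_samples.csv")
        io.write_labels_csv(panel.samples["group"], indir / "mid_labels.csv")
        io.write_json(
            {"fc": {k: dict(v["fc"]) for k, v in mets.items()},
             "tracer_enrichment": truth.tracer_enrichment, "seed": truth.seed},
            indir / "mid_truth.json",
        )
        produced["mid"] = str(indir / "mid.csv")
        produced["mid_samples"] = str(indir / "mid_samples.csv")
        produced["mid_labels"] = str(indir / "mid_labels.csv")
    if "dualtracer" in cfg:
        d = cfg["dualtracer"]
        frames, labels = [], {}
        for g, (group, fr) in enumerate(sorted(d["groups"].items())):
            truth = synthetic.SourceTruth(
                f_preexisting=fr["f_preexisting"],
                f_denovo=fr["f_denovo"],
                f_salvage=fr["f_salvage"],
                noise_sd=d.get("noise_sd", 0.05),
                denovo_shift_dist={int(k): v for k, v in
                                   d.get("denovo_shift_dist", {5: 1.0}).items()},
                label=group,
                seed=seed + 2 + g,
            )
            panel = synthetic.gen_dual_tracer_panel(truth, n_samples=d.get("n_samples", 3))
            frame = panel.data.copy()
            frame["sample"] = group + "_" + frame["sample"]
            frames.append(frame)
            labels.update({s: group for s in frame["sample"].unique()})
        merged = sources.DualTracerPanel(
            data=pd.concat(frames, ignore_index=True),
            labels=pd.Series(labels),
        )
        io.write_dual_tracer(merged, indir / "dualtracer.csv", indir / "dualtracer_labels.csv")
        io.write_json({"groups": {k: dict(v) for k, v in d["groups"].items()},
                       "seed": seed}, indir / "dualtracer_truth.json")
        produced["dualtracer"] = str(indir / "dualtracer.csv")
        produced["dualtracer_labels"] = str(indir / "dualtracer_labels.csv")
    manifest["stages"]["simulate"] = {"outputs": produced}


def _load_dataset(cfg: dict, outdir: Path, stage: str, tag: str = "") -> gsea.ExpressionDataset:
    indir = outdir / "inputs"
    expr = Path(cfg.get("expr", indir / f"expression{tag}.gct"))
    cls = Path(cfg.get("cls", indir / f"phenotype{tag}.cls"))
    pmap = Path(cfg.get("probe_map", indir / f"probe_map{tag}.tsv"))
    emap = Path(cfg.get("ec_map", indir / f"ec_map{tag}.tsv"))
    for p, what in [(expr, "expression matrix"), (cls, "CLS phenotype"),
                    (pmap, "probe map"), (emap, "EC map")]:
        _require(p, stage, what)
    values = io.read_gct(expr) if expr.suffix == ".gct" else io.read_tsv_matrix(expr)
    labels = io.read_cls(cls)
    labels.index = values.columns
    return gsea.ExpressionDataset(
        values=values,
        labels=labels,
        probe_to_gene=io.read_map_tsv(pmap),
        gene_to_ec=io.read_map_tsv(emap, multi=True),
    )


def _run_gsea(cfg: dict, seed: int, outdir: Path, manifest: dict) -> None:
    gmt = Path(cfg.get("gmt", outdir / "inputs" / "modules.gmt"))
    _require(gmt, "gsea", "GMT module file")
    collection = io.read_gmt(gmt)
    sim = manifest["config"].get("simulate", {}).get("expression", {})
    n_datasets = sim.get("n_datasets", 1)
    outputs = {}
    for d in range(n_datasets):
        tag = f"_{d}" if n_datasets > 1 else ""
        ds = _load_dataset(cfg, outdir, "gsea", tag)
        results = gsea.score_collection(
            ds, collection,
            n_perm=cfg.get("n_perm", 1000),
            seed=seed + 10 + d,
            weight_exponent=cfg.get("weight_exponent", 1.0),
            mode=cfg.get("mode", "auto"),
            min_nodes=cfg.get("min_nodes", 3),
            max_nodes=cfg.get("max_nodes", 500),
        )
        out = outdir / f"enrichment{tag}.tsv"
        io.write_enrichment_tsv(results, out)
        outputs[f"enrichment{tag}"] = str(out)
    manifest["stages"]["gsea"] = {"outputs": outputs}


def _run_concordance(cfg: dict, outdir: Path, manifest: dict) -> None:
    a = Path(cfg.get("a", outdir / "enrichment_0.tsv"))
    b = Path(cfg.get("b", outdir / "enrichment_1.tsv"))
    _require(a, "concordance", "first enrichment table")
    _require(b, "concordance", "second enrichment table")
    result = gsea.cross_dataset_concordance(
        io.read_enrichment_tsv(a), io.read_enrichment_tsv(b), tau=cfg.get("tau", 1.2)
    )
    result.nes_pairs.rename_axis("module_id").to_csv(outdir / "nes_pairs.tsv", sep="\t")
    io.write_json(
        {"pearson": result.pearson, "spearman": result.spearman, "tau": result.tau,
         "shared_up": result.shared_up, "shared_down": result.shared_down},
        outdir / "concordance.json",
    )
    manifest["stages"]["concordance"] = {
        "outputs": {"nes_pairs": str(outdir / "nes_pairs.tsv"),
                    "concordance": str(outdir / "concordance.json")}
    }


def _run_mid(cfg: dict, outdir: Path, manifest: dict) -> None:
    indir = outdir / "inputs"
    data = _require(Path(cfg.get("input", indir / "mid.csv")), "mid", "MID long CSV")
    samp = _require(Path(cfg.get("samples", indir / "mid_samples.csv")), "mid",
                    "per-sample CSV")
    panel = io.read_mid_panel(
        data, samp, tracer_enrichment=cfg.get("tracer_enrichment", 1.0)
    )
    table = mid.labeling_index_table(
        panel,
        correct_na=cfg.get("correct_na", True),
        mode=cfg.get("mode", "fractional"),
        normalize_enrichment=cfg.get("normalize_enrichment", False),
    )
    io.write_labeling_index(table, outdir / "labeling_index.tsv")
    mid.relative_amounts(panel).rename_axis("metabolite").to_csv(
        outdir / "relative_amounts.tsv", sep="\t"
    )
    manifest["stages"]["mid"] = {
        "outputs": {"labeling_index": str(outdir / "labeling_index.tsv"),
                    "relative_amounts": str(outdir / "relative_amounts.tsv")}
    }


def _run_labeling_stats(cfg: dict, seed: int, outdir: Path, manifest: dict) -> None:
    index = _require(Path(cfg.get("index", outdir / "labeling_index.tsv")),
                     "labeling_stats", "labeling-index table")
    labels_path = _require(Path(cfg.get("labels", outdir / "inputs" / "mid_labels.csv")),
                           "labeling_stats", "sample labels")
    table = io.read_labeling_index(index)
    labels = io.read_labels_csv(labels_path)
    part = labeling.cluster_partition(
        table, k=cfg.get("k", 2), method=cfg.get("method", "hierarchical"),
        seed=seed + 20, true_labels=labels,
    )
    diff = labeling.differential_labeling(table, labels, alpha=cfg.get("alpha", 0.05))
    diff.table.rename_axis("metabolite").to_csv(outdir / "differential_labeling.tsv", sep="\t")
    payload = {
        "assignments": part.assignments.to_dict(),
        "k": part.k, "method": part.method, "ari": part.ari,
        "degenerate": part.degenerate,
    }
    if part.linkage_matrix is not None:
        payload["linkage"] = part.linkage_matrix.tolist()
    io.write_json(payload, outdir / "partition.json")
    outputs = {"partition": str(outdir / "partition.json"),
               "differential": str(outdir / "differential_labeling.tsv")}
    if "categories" in cfg:
        cat_path = _require(Path(cfg["categories"]), "labeling_stats", "category CSV")
        cats = io.read_labels_csv(cat_path)
        category = set(cats.index[cats.astype(bool)])
        universe = set(table.values.index)
        enr = labeling.category_overrepresentation(
            set(diff.significant), category & universe, universe
        )
        io.write_json(
            {"table": enr.table.tolist(), "chi2": enr.chi2, "p": enr.p,
             "fisher_p": enr.fisher_p},
            outdir / "category_enrichment.json",
        )
        outputs["category_enrichment"] = str(outdir / "category_enrichment.json")
    manifest["stages"]["labeling_stats"] = {"outputs": outputs}


def _run_sources(cfg: dict, outdir: Path, manifest: dict) -> None:
    indir = outdir / "inputs"
    data = _require(Path(cfg.get("input", indir / "dualtracer.csv")),
                    "nucleotide_sources", "dual-tracer CSV")
    labels = Path(cfg.get("labels", indir / "dualtracer_labels.csv"))
    panel = io.read_dual_tracer(data, labels if labels.exists() else None)
    part = sources.source_fractions(panel, denovo_min_shift=cfg.get("denovo_min_shift", 3))
    part.per_sample.to_csv(outdir / "source_fractions.tsv", sep="\t")
    outputs = {"source_fractions": str(outdir / "source_fractions.tsv")}
    if part.group_summary is not None:
        io.write_json(
            {"summary": part.group_summary.to_dict(orient="records")},
            outdir / "source_summary.json",
        )
        outputs["source_summary"] = str(outdir / "source_summary.json")
    manifest["stages"]["nucleotide_sources"] = {"outputs": outputs}


def run_pipeline(config: dict, outdir) -> dict:
    """Execute configured stages in dependency order; returns the manifest."""
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest: dict = {
        "version": __version__,
        "config": config,
        "seed": seed,
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for stage in config["stages"]:
        cfg = config.get(stage, {}) or {}
        if stage == "simulate":
            _simulate(cfg, seed, outdir, manifest)
        elif stage == "gsea":
            _run_gsea(cfg, seed, outdir, manifest)
        elif stage == "concordance":
            _run_concordance(cfg, outdir, manifest)
        elif stage == "mid":
            _run_mid(cfg, outdir, manifest)
        elif stage == "labeling_stats":
            _run_labeling_stats(cfg, seed, outdir, manifest)
        elif stage == "nucleotide_sources":
            _run_sources(cfg, outdir, manifest)
    # checksum every produced artifact for replayability
    for stage_info in manifest["stages"].values():
        stage_info["checksums"] = {
            name: _sha256(path) for name, path in stage_info["outputs"].items()
        }
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


def demo_config(seed: int = 0) -> dict:
    """Small end-to-end configuration exercising all stages in seconds."""
    return {
        "seed": seed,
        "stages": STAGE_ORDER,
        "simulate": {
            "expression": {
                "n_probes": 140,
                "samples_per_group": [10, 10],
                "node_sets": {"n_modules": 12, "nodes_per_module": 8},
                "planted_modules": {"M0000": 1, "M0001": -1},
                "effect_size": 2.0,
                "n_datasets": 2,
            },
            "mid": {
                "metabolites": {
                    "alanine": {"formula": "C3H7NO2",
                                "fc": {"groupA": 0.10, "groupB": 0.30}},
                    "glutamate": {"formula": "C5H9NO4",
                                  "fc": {"groupA": 0.25, "groupB": 0.25}},
                    "ribose_5_phosphate": {"formula": "C5H11O8P",
                                           "fc": {"groupA": 0.15, "groupB": 0.40}},
                },
                "tracer_enrichment": 0.5,
                "noise_sd": 0.02,
                "n_replicates": 3,
            },
            "dualtracer": {
                "groups": {
                    "wt": {"f_preexisting": 0.4, "f_denovo": 0.48, "f_salvage": 0.12},
                    "mut": {"f_preexisting": 0.4, "f_denovo": 0.3, "f_salvage": 0.3},
                },
                "n_samples": 3,
                "noise_sd": 0.05,
            },
        },
        "gsea": {"n_perm": 150, "mode": "phenotype"},
        "concordance": {"tau": 1.2},
        "mid": {"correct_na": True, "mode": "fractional", "tracer_enrichment": 0.5},
        "labeling_stats": {"alpha": 0.05, "k": 2, "method": "hierarchical"},
        "nucleotide_sources": {"denovo_min_shift": 3},
    }
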