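"""Run configuration: validation, dispatch and provenance.

A run file (YAML or JSON) names the inputs, the preprocessing choices and
exactly one analysis block (simulate | similarity | stats | network |
validate); :func:`run` executes it and writes the artifacts plus a
provenance JSON sufficient to re-run the analysis bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigError

log = logging.getLogger(__name__)

ANALYSIS_BLOCKS = ("simulate", "similarity", "stats", "network", "validate")

_TOP_KEYS = {
    "data", "catalog", "design", "preprocess", "outdir", "seed", "log_level",
    *ANALYSIS_BLOCKS,
}
_PREPROCESS_KEYS = {
    "log2", "flag_outliers", "drop_flagged", "filter_missing", "impute", "transform",
}


@dataclass
class RunConfig:
    analysis: str
    params: dict
    data: str | None = None
    catalog: str | None = None
    design: str | None = None
    preprocess: dict = field(default_factory=dict)
    outdir: str = "chronomet_out"
    seed: int = 0
    log_level: str = "info"

    def to_dict(self) -> dict:
        return {
            "analysis": self.analysis,
            "params": self.params,
            "data": self.data,
            "catalog": self.catalog,
            "design": self.design,
            "preprocess": self.preprocess,
            "outdir": self.outdir,
            "seed": self.seed,
            "log_level": self.log_level,
        }


def load_config(path) -> RunConfig:
    """Parse and validate a YAML/JSON run file; unknown keys are rejected."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("run file must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
    blocks = [b for b in ANALYSIS_BLOCKS if b in raw]
    if len(blocks) != 1:
        raise ConfigError(
            f"exactly one analysis block required, found {blocks or 'none'}"
        )
    pre = raw.get("preprocess", {}) or {}
    unknown_pre = set(pre) - _PREPROCESS_KEYS
    if unknown_pre:
        raise ConfigError(f"unknown preprocess key(s): {sorted(unknown_pre)}")
    if pre.get("impute", "none") not in ("linear", "knn", "none"):
        raise ConfigError(f"unknown impute choice {pre.get('impute')!r}")
    return RunConfig(
        analysis=blocks[0],
        params=raw[blocks[0]] or {},
        data=raw.get("data"),
        catalog=raw.get("catalog"),
        design=raw.get("design"),
        preprocess=pre,
        outdir=raw.get("outdir", "chronomet_out"),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "info")),
    )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(cfg: RunConfig, outdir: Path, extra: dict | None = None) -> None:
    payload = {
        "tool": "chronomet",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "input_checksums": {
            k: _sha256(v)
            for k, v in (("data", cfg.data), ("catalog", cfg.catalog), ("design", cfg.design))
            if v and Path(v).exists()
        },
    }
    payload.update(extra or {})
    (outdir / "provenance.json").write_text(json.dumps(payload, indent=1, default=str))


def _load_inputs(cfg: RunConfig):
    from .study import StudyDesign, read_catalog, read_long_table

    if not (cfg.data and cfg.catalog and cfg.design):
        raise ConfigError("this analysis block needs data, catalog and design paths")
    for p in (cfg.data, cfg.catalog, cfg.design):
        if not Path(p).exists():
            raise ConfigError(f"input file not found: {p}")
    catalog = read_catalog(cfg.catalog)
    design = StudyDesign.from_json(cfg.design)
    return read_long_table(cfg.data, catalog, design)


def _preprocess(ds, cfg: RunConfig):
    from . import preprocess as pp

    pre = cfg.preprocess
    if pre.get("log2", True) and ds.transform_tag == "raw":
        ds = pp.log2_values(ds)
    if pre.get("flag_outliers", False):
        report = pp.flag_outliers(ds)
        if pre.get("drop_flagged", False):
            ds = pp.drop_flagged(ds, report)
    if pre.get("filter_missing") is not None:
        ds = pp.filter_missingness(ds, float(pre["filter_missing"]))
    impute = pre.get("impute", "none")
    if impute == "linear":
        ds = pp.impute_linear(ds)
    elif impute == "knn":
        ds = pp.impute_knn(ds)
    mode = pre.get("transform", "none")
    if mode and mode != "none":
        ds = pp.transform(ds, mode)
    return ds


def run(cfg: RunConfig) -> int:
    """Execute one analysis block; returns a process exit status."""
    logging.basicConfig(level=cfg.log_level.upper())
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        extra = _dispatch(cfg, outdir)
    except Exception:
        log.exception("run failed")
        return 1
    write_provenance(cfg, outdir, extra)
    return 0


def _complete_only(ds):
    """Make the dataset complete for GGM estimation.

    Residual missing entries left by the chosen imputation (leading/trailing
    gaps under linear interpolation) are filled with the metabolite's overall
    mean; metabolites with no observations at all are dropped.
    """
    keep = [u for u in ds.uids if ds.values[u].notna().any()]
    if len(keep) < len(ds.uids):
        log.warning("dropping %d fully missing metabolite(s)", len(ds.uids) - len(keep))
    ds = ds.subset(uids=keep)
    n_resid = int(ds.values.isna().to_numpy().sum())
    if n_resid:
        log.warning("mean-filling %d residual missing value(s) for the GGM", n_resid)
        return ds.with_values(ds.values.fillna(ds.values.mean(axis=0)))
    return ds


def _dispatch(cfg: RunConfig, outdir: Path) -> dict:
    params = dict(cfg.params)
    if cfg.analysis == "simulate":
        from .simulate import KineticTemplate, ModuleSpec, SimConfig, simulate_dataset
        from .study import write_catalog, write_long_table

        modules = [
            ModuleSpec(m["id"], tuple(m["members"]), m.get("loading", 0.8))
            for m in params.pop("modules", [])
        ]
        templates = {
            uid: KineticTemplate(**t)
            for uid, t in params.pop("template_assignment", {}).items()
        }
        sim_cfg = SimConfig(
            modules=modules, template_assignment=templates, seed=cfg.seed, **params
        )
        ds, truth = simulate_dataset(sim_cfg)
        write_long_table(ds, outdir / "dataset.tsv")
        write_catalog(ds.catalog, outdir / "catalog.tsv")
        ds.design.to_json(outdir / "design.json")
        truth_payload = {
            "true_edges": [sorted(e) for e in sorted(truth.true_edges, key=sorted)],
            "true_responders": {k: sorted(v) for k, v in truth.true_responders.items()},
            "injected_outliers": truth.injected_outliers,
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth_payload, indent=1))
        return {"n_observations": ds.n_observations}

    ds = _preprocess(_load_inputs(cfg), cfg)

    if cfg.analysis == "similarity":
        from .preprocess import transform
        from .similarity import BandPolicy, rank_similar

        if ds.transform_tag == "log2":
            ds = transform(ds, "zscore")
        band = BandPolicy(
            params.get("window", 30.0), params.get("fasting_window", 120.0)
        )
        result = rank_similar(
            ds,
            params["ref"],
            measure=params.get("measure", "frechet"),
            mode=params.get("mode", "mean_trajectory"),
            tp_range=tuple(params["tp_range"]) if "tp_range" in params else None,
            band=band,
        )
        result.to_frame().to_csv(outdir / "similarity.tsv", sep="\t", index=False)
        return {"n_candidates": len(result.rows)}

    if cfg.analysis == "stats":
        from .stats import paired_t_scan, scan_to_frame, volcano_frame

        results = paired_t_scan(ds, params["challenge"], params.get("tps", "all"))
        scan_to_frame(results).to_csv(outdir / "scan.tsv", sep="\t", index=False)
        volcano_frame(results).to_csv(outdir / "volcano.tsv", sep="\t", index=False)
        return {"n_tests": len(results)}

    if cfg.analysis == "network":
        from .ggm import DynamicalGGM, annotate_and_export

        ds = _complete_only(ds)
        model = DynamicalGGM(ds, uids=params.get("uids"))
        results = model.fit()
        net = results.network(
            mode=params.get("mode", "cutoff"),
            cutoff=params.get("cutoff", 0.12),
            correction=params.get("correction", "bonferroni"),
            require_pearson=not params.get("no_pearson_gate", False),
        )
        net.edge_frame().to_csv(outdir / "edges.tsv", sep="\t", index=False)
        annotate_and_export(net, [], "OGTT", 0, outdir / "network.graphml", "graphml")
        (outdir / "summary.txt").write_text(results.summary() + "\n")
        return {"n_edges": net.n_edges, "lambda_star": results.lambda_star}

    if cfg.analysis == "validate":
        from .ggm import DynamicalGGM
        from .validation import CompoundGraph, bootstrap_relabel, pathway_distance_profile

        model = DynamicalGGM(_complete_only(ds))
        net = model.fit().network(
            mode=params.get("mode", "cutoff"), cutoff=params.get("cutoff", 0.12)
        )
        graph = CompoundGraph.from_edge_file(params["graph"])
        id_map = {}
        with open(params["map"]) as fh:
            header = fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2 and parts[1]:
                    id_map[parts[0]] = parts[1]
        summary = pathway_distance_profile(net, graph, id_map)
        boot = bootstrap_relabel(
            net, graph, id_map, n_iter=int(params.get("iters", 1000)), seed=cfg.seed
        )
        (outdir / "validation.json").write_text(
            json.dumps(
                {
                    "n_edges_total": summary.n_edges_total,
                    "n_mappable": summary.n_mappable,
                    "d1": summary.d1,
                    "d2": summary.d2,
                    "d3": summary.d3,
                    "gt3": summary.gt3,
                    "unreachable": summary.unreachable,
                    "observed_d1": boot.observed_count,
                    "max_null_d1": boot.max_null,
                    "empirical_p": boot.empirical_p,
                },
                indent=1,
            )
        )
        return {"empirical_p": boot.empirical_p}

    raise ConfigError(f"unknown analysis {cfg.analysis!r}")
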