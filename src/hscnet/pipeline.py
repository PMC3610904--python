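"""Configuration-driven orchestration of the full analysis.

A single YAML (or dict) config names the input files, the analyses to run and
the statistical options; ``run_pipeline`` executes the stages in a fixed order
(load -> normalize -> map -> restrict -> enrich -> phenotype correlation ->
subnetwork -> limiting dilution) and writes TSV/JSON/GraphML outputs plus a
run log. Identical config + inputs + seed give byte-identical data outputs;
the run log additionally records wall-clock stage timings and attrition
counts (symbols silently lost to mapping or universe restriction are
surfaced, not hidden).
"""

from __future__ import annotations

import importlib.metadata
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import core_sets, interactome, limiting_dilution, overlap_stats, phenotype_assoc

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

DATA_OUTPUTS = ["results.tsv", "phenocorr.tsv", "subnetwork.graphml",
                "nodes.tsv", "lda.json", "manifest.json"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: Path = Path("results")
    inputs: dict = field(default_factory=dict)
    analyses: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    base_dir: Path = Path(".")

    _KNOWN_OPTIONS = {
        "sd_model": ("hypergeometric", "binomial"),
        "or_method": ("cmle", "sample"),
        "bh": (True, False),
        "normalize": ("upper", "asis"),
        "map_policy": ("all_targets", "drop_ambiguous"),
        "lda_threshold": None,
        "lda_ci": ("wald", "profile"),
    }

    def __post_init__(self) -> None:
        for key, allowed in list(self.options.items()):
            if key not in self._KNOWN_OPTIONS:
                raise ValueError(f"unknown option {key!r}")
            spec = self._KNOWN_OPTIONS[key]
            if spec is not None and allowed not in spec:
                raise ValueError(f"option {key}={allowed!r} not in {spec}")

    def opt(self, key: str, default):
        return self.options.get(key, default)

    def path(self, key: str) -> Path:
        try:
            rel = self.inputs[key]
        except KeyError:
            raise PipelineError(f"config stage 'load': missing input {key!r}")
        p = Path(rel)
        if not p.is_absolute():
            p = self.base_dir / p
        if not p.exists():
            raise PipelineError(f"config stage 'load': input file {p} not found")
        return p

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(seed=int(raw.get("seed", 0)),
                   output_dir=Path(raw.get("output_dir", "results")),
                   inputs=raw.get("inputs", {}) or {},
                   analyses=raw.get("analyses", {}) or {},
                   options=raw.get("options", {}) or {},
                   base_dir=path.parent)


def _version() -> str:
    try:
        return importlib.metadata.version("hscnet")
    except importlib.metadata.PackageNotFoundError:
        return "unknown"


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every configured stage; returns the manifest dict.

    Any stage error aborts with a stage-labeled :class:`PipelineError` and
    removes partial outputs.
    """
    outdir = config.base_dir / config.output_dir \
        if not Path(config.output_dir).is_absolute() else Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage_log: list[dict] = []
    attrition: dict[str, int] = {}
    stage = "load"
    try:
        t0 = time.perf_counter()
        normalize = config.opt("normalize", "upper")
        sets: dict[str, core_sets.GeneSet] = {}
        universe = omap = ann = net = doses = None
        if "gene_sets" in config.inputs:
            for gs in core_sets.read_gmt(config.path("gene_sets"), policy=normalize):
                sets[gs.name] = gs
        if "universe" in config.inputs:
            universe = core_sets.read_universe(config.path("universe"),
                                              policy=normalize)
        if "ortholog_map" in config.inputs:
            omap = core_sets.read_ortholog_map(config.path("ortholog_map"),
                                              policy=normalize)
        if "annotations" in config.inputs:
            ann = phenotype_assoc.read_annotations(config.path("annotations"))
        if "interactome" in config.inputs:
            net = interactome.read_edges(config.path("interactome"),
                                         policy=normalize)
        if "dose_table" in config.inputs:
            doses = limiting_dilution.read_dose_table(
                config.path("dose_table"),
                threshold=float(config.opt("lda_threshold", 0.1)))
        stage_log.append({"stage": stage,
                          "seconds": time.perf_counter() - t0})

        def _get_set(name: str) -> core_sets.GeneSet:
            if name not in sets:
                raise PipelineError(f"stage '{stage}': unknown gene set {name!r}"
                                    f" (available: {sorted(sets)})")
            return sets[name]

        results: list[overlap_stats.OverlapResult] = []

        stage = "enrich"
        t0 = time.perf_counter()
        for spec_item in config.analyses.get("enrich", []) or []:
            if universe is None:
                raise PipelineError("stage 'enrich': no universe input configured")
            fixed = _get_set(spec_item["fixed"])
            comparator = _get_set(spec_item["comparator"])
            if spec_item.get("map_comparator") and omap is not None:
                before = len(comparator)
                comparator = core_sets.map_orthologs(
                    comparator, omap,
                    policy=config.opt("map_policy", "all_targets"))
                attrition[f"map:{spec_item['comparator']}"] = before - len(comparator)
            for nm, gs in (("fixed", fixed), ("comparator", comparator)):
                before = len(gs)
                gs = core_sets.restrict_universe(universe, gs)
                attrition[f"restrict:{gs.name}"] = before - len(gs)
                if nm == "fixed":
                    fixed = gs
                else:
                    comparator = gs
            results.append(overlap_stats.enrich(
                fixed, comparator, universe,
                sd_model=config.opt("sd_model", "hypergeometric"),
                or_method=config.opt("or_method", "cmle")))
        stage_log.append({"stage": stage, "seconds": time.perf_counter() - t0})

        stage = "phenotype_enrichment"
        t0 = time.perf_counter()
        pheno_cfg = config.analyses.get("phenotype_enrichment") or {}
        for set_name in pheno_cfg.get("sets", []) or []:
            if ann is None:
                raise PipelineError("stage 'phenotype_enrichment': no "
                                    "annotations input configured")
            results.extend(phenotype_assoc.set_phenotype_enrichment(
                _get_set(set_name), ann,
                phenotypes=pheno_cfg.get("phenotypes"),
                sd_model=config.opt("sd_model", "hypergeometric"),
                or_method=config.opt("or_method", "cmle")))
        stage_log.append({"stage": stage, "seconds": time.perf_counter() - t0})

        stage = "write_results"
        if results or config.analyses.get("enrich") is not None:
            frame = overlap_stats.results_to_frame(results)
            if config.opt("bh", False) and len(frame):
                frame["p_two_sided_bh"] = overlap_stats.bh_adjust(
                    list(frame["p_two_sided"]))
            p = outdir / "results.tsv"
            frame.to_csv(p, sep="\t", index=False)
            written.append(p)

        stage = "phenocorr"
        t0 = time.perf_counter()
        if config.analyses.get("phenotype_correlation"):
            if ann is None:
                raise PipelineError("stage 'phenocorr': no annotations input "
                                    "configured")
            corr = phenotype_assoc.phenotype_correlation(ann)
            p = outdir / "phenocorr.tsv"
            phenotype_assoc.write_correlation_tsv(corr, p)
            written.append(p)
        stage_log.append({"stage": stage, "seconds": time.perf_counter() - t0})

        stage = "subnet"
        t0 = time.perf_counter()
        sub_cfg = config.analyses.get("subnetwork")
        if sub_cfg:
            if net is None:
                raise PipelineError("stage 'subnet': no interactome input "
                                    "configured")
            expressed = _get_set(sub_cfg["expressed"])
            fingerprint = (_get_set(sub_cfg["fingerprint"])
                           if sub_cfg.get("fingerprint") else None)
            sub = interactome.project_subnetwork(net, expressed, fingerprint)
            p = outdir / "subnetwork.graphml"
            interactome.write_graph(sub, p, format="GraphML")
            written.append(p)
            p = outdir / "nodes.tsv"
            interactome.write_node_table(sub, p)
            written.append(p)
        stage_log.append({"stage": stage, "seconds": time.perf_counter() - t0})

        stage = "lda"
        t0 = time.perf_counter()
        if config.analyses.get("lda"):
            if doses is None:
                raise PipelineError("stage 'lda': no dose_table input configured")
            fit = limiting_dilution.fit_frequency(
                doses, ci_method=config.opt("lda_ci", "wald"))
            points = limiting_dilution.nonresponder_points(doses)
            payload = {
                "fit": fit.to_dict(),
                "groups": [{"dose": g.dose, "n_tested": g.n_tested,
                            "n_engrafted": g.n_engrafted} for g in doses],
                "nonresponder_curve": [
                    {"dose": pt.dose,
                     "log_fraction_negative": pt.log_fraction_negative,
                     "excluded": pt.excluded} for pt in points],
            }
            p = outdir / "lda.json"
            with open(p, "w", encoding="utf-8") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
                fh.write("\n")
            written.append(p)
        stage_log.append({"stage": stage, "seconds": time.perf_counter() - t0})

        stage = "manifest"
        manifest = {
            "outputs": sorted(p.name for p in written),
            "seed": config.seed,
            "options": {k: config.options.get(k) for k in sorted(config.options)},
            "inputs": {k: str(config.inputs[k]) for k in sorted(config.inputs)},
        }
        p = outdir / "manifest.json"
        with open(p, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(p)

        run_log = {
            "version": _version(),
            "seed": config.seed,
            "options": manifest["options"],
            "stages": stage_log,
            "attrition": attrition,
        }
        with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
            json.dump(run_log, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return manifest
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
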