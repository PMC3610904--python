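"""Seeded generators emulating every input of the cross-tissue analysis.

The defaults mirror the study conditions the package targets: an array-scale
universe of 20,000 genes, a 319-gene stem-cell fingerprint as the fixed set, a
1,013-gene differential-expression list as the comparator, an ortholog map
covering ~86% of symbols (319 fingerprint genes mapping to ~274 across
species), MGI-style block-structured phenotype annotations, random
interactomes, and limiting-dilution experiments simulated from a true
frequency of 1e-4 under the single-hit Poisson model (doses 2e3/1e4/5e4, 10
animals per dose).

Every generator draws from its own stream derived from the root seed by a
fixed offset, so adding a generator never perturbs the output of another.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .core_sets import GeneSet, OrthologMap, Universe, write_gmt
from .interactome import Interactome
from .limiting_dilution import DoseGroup
from .overlap_stats import nchg_pmf
from .phenotype_assoc import AnnotationMatrix

import pandas as pd

__all__ = [
    "SimSpec", "gen_universe", "gen_overlap_pair", "gen_overlap_counts",
    "gen_annotation_matrix", "gen_interactome", "gen_lda_experiment",
    "write_bundle",
]

# fixed per-generator stream offsets (never renumber)
_STREAM_UNIVERSE = 1
_STREAM_OVERLAP = 2
_STREAM_ANNOTATION = 3
_STREAM_GRAPH = 4
_STREAM_LDA = 5
_STREAM_BUNDLE = 6


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic study; equal specs give identical output."""

    seed: int = 0
    # universe / overlap pair
    N: int = 20000
    K: int = 319
    n: int = 1013
    odds: float = 1.0
    # ortholog map composition
    map_fraction: float = 0.86
    ambiguous_fraction: float = 0.05
    # annotation block design
    ann_genes: int = 400
    ann_phenotypes: int = 8
    ann_blocks: int = 2
    within_rate: float = 0.4
    between_rate: float = 0.05
    # interactome
    net_nodes: int = 250
    edge_prob: float = 0.02
    net_model: str = "gnp"          # gnp | ba (preferential attachment)
    ba_m: int = 3
    # limiting dilution truth
    lda_frequency: float = 1e-4
    lda_doses: tuple[float, ...] = (2_000.0, 10_000.0, 50_000.0)
    lda_animals: int = 10

    def __post_init__(self) -> None:
        if self.N < 1 or self.K < 0 or self.n < 0:
            raise ValueError("sizes must be non-negative with N >= 1")
        if self.K > self.N or self.n > self.N:
            raise ValueError("need K <= N and n <= N")
        if self.odds < 0:
            raise ValueError("odds parameter must be >= 0")
        for r in (self.map_fraction, self.ambiguous_fraction,
                  self.within_rate, self.between_rate, self.edge_prob):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"rates must lie in [0, 1], got {r}")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed])


def _symbols(prefix: str, count: int) -> list[str]:
    return [f"{prefix}{i:05d}" for i in range(1, count + 1)]


def gen_universe(spec: SimSpec) -> tuple[Universe, OrthologMap]:
    """Synthetic universe plus a partial ortholog map onto a target species.

    Each source symbol is mapped with probability ``map_fraction``; a mapped
    group gains a second target with probability ``ambiguous_fraction``
    (1:many homology). Unmapped symbols emulate cross-species attrition.
    """
    rng = spec.rng(_STREAM_UNIVERSE)
    src = _symbols("G", spec.N)
    mapped = rng.random(spec.N) < spec.map_fraction
    ambiguous = rng.random(spec.N) < spec.ambiguous_fraction
    groups = []
    for i, s in enumerate(src):
        if not mapped[i]:
            continue
        targets = {f"H{i + 1:05d}"}
        if ambiguous[i]:
            targets.add(f"H{i + 1:05d}B")
        groups.append((frozenset({s}), frozenset(targets)))
    universe = Universe(name="sim_universe", symbols=frozenset(src))
    return universe, OrthologMap(groups=tuple(groups), policy="upper")


def gen_overlap_counts(spec: SimSpec, size: int = 1,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Overlap counts under the Fisher noncentral hypergeometric at ``odds``.

    The pmf is normalized explicitly over the feasible overlap range and
    sampled directly — no rejection sampling; ``odds=1`` reduces exactly to the
    central hypergeometric, ``odds=0`` (``inf``) to the minimal (maximal)
    feasible overlap.
    """
    if rng is None:
        rng = spec.rng(_STREAM_OVERLAP)
    kmin = max(0, spec.n + spec.K - spec.N)
    kmax = min(spec.K, spec.n)
    if spec.odds == 0.0:
        return np.full(size, kmin, dtype=np.int64)
    if math.isinf(spec.odds):
        return np.full(size, kmax, dtype=np.int64)
    ks, pmf = nchg_pmf(spec.N, spec.K, spec.n, math.log(spec.odds))
    return rng.choice(ks, size=size, p=pmf)


def gen_overlap_pair(spec: SimSpec,
                     rng: np.random.Generator | None = None
                     ) -> tuple[GeneSet, GeneSet]:
    """A (fixed, comparator) set pair with overlap drawn at the given odds."""
    if rng is None:
        rng = spec.rng(_STREAM_OVERLAP)
    src = np.array(_symbols("G", spec.N))
    fixed_idx = rng.choice(spec.N, size=spec.K, replace=False)
    m = int(gen_overlap_counts(spec, size=1, rng=rng)[0])
    in_fixed = rng.choice(fixed_idx, size=m, replace=False)
    mask = np.ones(spec.N, dtype=bool)
    mask[fixed_idx] = False
    outside = np.flatnonzero(mask)
    out_fixed = rng.choice(outside, size=spec.n - m, replace=False)
    fixed = GeneSet(name="FIXED_SET", symbols=frozenset(src[fixed_idx]),
                    universe_name="sim_universe")
    comparator = GeneSet(name="COMPARATOR_SET",
                         symbols=frozenset(src[np.concatenate([in_fixed,
                                                               out_fixed])]),
                         universe_name="sim_universe")
    return fixed, comparator


def gen_annotation_matrix(spec: SimSpec) -> AnnotationMatrix:
    """Block-structured binary annotations.

    Phenotypes are split into ``ann_blocks`` blocks and each gene is assigned
    a latent block; a gene is annotated to a phenotype of its own block with
    probability ``within_rate`` and to other blocks' phenotypes with
    ``between_rate``, so within-block columns co-occur more than between-block
    ones by construction.
    """
    if spec.within_rate < spec.between_rate:
        raise ValueError("within_rate must be >= between_rate")
    rng = spec.rng(_STREAM_ANNOTATION)
    genes = [f"g{i:04d}" for i in range(1, spec.ann_genes + 1)]
    pheno_block = np.arange(spec.ann_phenotypes) % spec.ann_blocks
    phenotypes = [f"MP_b{pheno_block[j]}_{j:02d}"
                  for j in range(spec.ann_phenotypes)]
    gene_block = rng.integers(spec.ann_blocks, size=spec.ann_genes)
    same = gene_block[:, None] == pheno_block[None, :]
    rates = np.where(same, spec.within_rate, spec.between_rate)
    incidence = (rng.random((spec.ann_genes, spec.ann_phenotypes)) < rates)
    df = pd.DataFrame(incidence.astype(np.int8), index=genes,
                      columns=phenotypes)
    return AnnotationMatrix(incidence=df)


def gen_interactome(spec: SimSpec) -> Interactome:
    """Random interactome: Erdős–Rényi G(n, p) or preferential attachment."""
    if spec.net_nodes < 2:
        raise ValueError("interactome needs at least 2 nodes")
    seed = int(spec.rng(_STREAM_GRAPH).integers(2 ** 31))
    if spec.net_model == "gnp":
        g = nx.gnp_random_graph(spec.net_nodes, spec.edge_prob, seed=seed)
    elif spec.net_model == "ba":
        g = nx.barabasi_albert_graph(spec.net_nodes, spec.ba_m, seed=seed)
    else:
        raise ValueError(f"unknown net_model {spec.net_model!r}")
    g = nx.relabel_nodes(g, {i: f"P{i:04d}" for i in g.nodes})
    return Interactome(graph=g, name="sim_interactome")


def gen_lda_experiment(spec: SimSpec,
                       rng: np.random.Generator | None = None
                       ) -> list[DoseGroup]:
    """Simulated dilution experiment: engraftment ~ Bernoulli(1 - exp(-f d))."""
    if spec.lda_frequency < 0:
        raise ValueError("true frequency must be >= 0")
    if rng is None:
        rng = spec.rng(_STREAM_LDA)
    groups = []
    for d in spec.lda_doses:
        if d <= 0:
            raise ValueError("doses must be > 0")
        p = -math.expm1(-spec.lda_frequency * d)
        engrafted = int(rng.binomial(spec.lda_animals, p))
        groups.append(DoseGroup(dose=float(d), n_tested=spec.lda_animals,
                                n_engrafted=engrafted))
    return groups


def write_bundle(spec: SimSpec, outdir) -> dict[str, str]:
    """Write a complete synthetic input bundle plus a manifest.

    Emits sets.gmt (fixed/comparator plus expressed/fingerprint sets over the
    interactome), universe.tsv, orthologs.tsv, annotations.tsv, network.sif,
    doses.tsv, a pipeline config.yaml wired to those files, and manifest.json
    recording the SimSpec.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    universe, omap = gen_universe(spec)
    fixed, comparator = gen_overlap_pair(spec)
    ann = gen_annotation_matrix(spec)
    net = gen_interactome(spec)
    lda = gen_lda_experiment(spec)

    rng = spec.rng(_STREAM_BUNDLE)
    nodes = sorted(net.graph.nodes)
    n_expr = max(1, len(nodes) // 3)
    expressed = sorted(rng.choice(nodes, size=n_expr, replace=False))
    fingerprint = sorted(rng.choice(expressed, size=max(1, n_expr // 3),
                                    replace=False))

    files: dict[str, str] = {}

    def _reg(key, name):
        files[key] = name
        return outdir / name

    write_gmt([
        fixed, comparator,
        GeneSet(name="HSC_EXPRESSED", symbols=frozenset(expressed)),
        GeneSet(name="HSC_FINGERPRINT", symbols=frozenset(fingerprint)),
    ], _reg("gene_sets", "sets.gmt"))

    with open(_reg("universe", "universe.tsv"), "w", encoding="utf-8") as fh:
        for s in sorted(universe.symbols):
            fh.write(s + "\n")
    with open(_reg("ortholog_map", "orthologs.tsv"), "w", encoding="utf-8") as fh:
        for src, tgt in omap.groups:
            for s in sorted(src):
                for t in sorted(tgt):
                    fh.write(f"{s}\t{t}\n")
    with open(_reg("annotations", "annotations.tsv"), "w", encoding="utf-8") as fh:
        for gene in ann.genes:
            row = ann.incidence.loc[gene]
            for term in ann.phenotypes:
                if row[term]:
                    fh.write(f"{gene}\t{term}\n")
    with open(_reg("interactome", "network.sif"), "w", encoding="utf-8") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{u} pp {v}\n")
    with open(_reg("dose_table", "doses.tsv"), "w", encoding="utf-8") as fh:
        fh.write("dose\tn_tested\tn_engrafted\n")
        for g in lda:
            fh.write(f"{g.dose:g}\t{g.n_tested}\t{g.n_engrafted}\n")

    config = {
        "seed": spec.seed,
        "output_dir": "results",
        "inputs": {k: files[k] for k in sorted(files)},
        "analyses": {
            "enrich": [{"fixed": "FIXED_SET", "comparator": "COMPARATOR_SET"}],
            "phenotype_enrichment": {"sets": []},
            "phenotype_correlation": True,
            "subnetwork": {"expressed": "HSC_EXPRESSED",
                           "fingerprint": "HSC_FINGERPRINT"},
            "lda": True,
        },
        "options": {"sd_model": "hypergeometric", "or_method": "cmle",
                    "bh": False, "normalize": "upper"},
    }
    import yaml
    with open(outdir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    files["config"] = "config.yaml"

    manifest = {"simspec": dataclasses.asdict(spec), "files": files}
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["manifest"] = "manifest.json"
    return files
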