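"""End-to-end pipeline: calls -> recurrence/regions -> association -> network
-> connectedness null -> modules -> annotation -> survival.

One invocation consumes a config (all stage parameters plus input paths),
executes the eight stages in order into a run directory, and writes a
manifest recording the package version, config hash, seed and per-stage row
counts.  All randomness flows from the single config seed through named
per-stage substreams, so an identical config and seed reproduce every
tabular output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .annotate import enrich_modules, enrichment_table
from .association import association_table, permutation_pvalues
from .modules import detect_modules, edge_swap_null, find_hubs
from .network import build_network, connectedness_null
from .segments import (
    gene_level_calls,
    genes_in_regions,
    mask_segments,
    read_gistic_lesions,
    recurrence_filter,
    score_regions,
)
from .survival import gene_survival_screen, ploidy_survival
from .synthetic import (
    SyntheticConfig,
    generate_genome_map,
    generate_interactome,
    simulate_cn_profiles,
    simulate_expression,
    simulate_survival,
)

__all__ = ["PipelineConfig", "InputError", "StageError", "run_pipeline", "make_fixture"]

logger = logging.getLogger(__name__)

STAGES = [
    "calls",
    "recurrence_regions",
    "association",
    "network",
    "connectedness",
    "modules",
    "annotation",
    "survival",
]


class InputError(Exception):
    """A referenced input file is missing or unreadable (CLI exit code 2)."""


class StageError(Exception):
    """A pipeline stage failed; carries the stage name (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All stage parameters (defaults mirror the emulated analysis) and inputs."""

    # input paths
    seg: str = ""
    ploidy: str = ""
    genome_map: str = ""
    expression: str = ""
    interactome: str = ""
    masks: str = ""  # optional BED
    gene_sets: str = ""  # optional GMT
    survival: str = ""  # optional TSV
    gistic_lesions: str = ""  # optional: replaces the internal region scorer

    # stage parameters
    call_delta: float = 0.9
    min_markers: int = 10
    mask_max_overlap: float = 0.5
    recurrence_min_freq: float = 0.20
    region_perms: int = 200
    region_q: float = 0.25
    association_perms: int = 1000
    association_fdr: float = 0.1
    linker_fdr: float = 0.05
    connectedness_perms: int = 1000
    null_networks: int = 1000
    swaps_per_edge: int = 10
    hub_fraction: float = 0.05
    ploidy_cut: float = 3.0
    min_group: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            ("call_delta", self.call_delta > 0),
            ("min_markers", self.min_markers >= 1),
            ("mask_max_overlap", 0 <= self.mask_max_overlap <= 1),
            ("recurrence_min_freq", 0 <= self.recurrence_min_freq <= 1),
            ("region_perms", self.region_perms >= 100),
            ("region_q", 0 < self.region_q <= 1),
            ("association_perms", self.association_perms >= 1),
            ("association_fdr", 0 < self.association_fdr <= 1),
            ("linker_fdr", 0 < self.linker_fdr <= 1),
            ("connectedness_perms", self.connectedness_perms >= 1),
            ("null_networks", self.null_networks >= 2),
            ("swaps_per_edge", self.swaps_per_edge >= 1),
            ("hub_fraction", 0 < self.hub_fraction <= 1),
            ("min_group", self.min_group >= 1),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"parameter {name} outside its domain: {getattr(self, name)}")

    def scale_perms(self, factor: float) -> "PipelineConfig":
        """Uniformly scale all null-replicate counts (floored at their minima)."""
        return dataclasses.replace(
            self,
            region_perms=max(100, int(self.region_perms * factor)),
            association_perms=max(1, int(self.association_perms * factor)),
            connectedness_perms=max(1, int(self.connectedness_perms * factor)),
            null_networks=max(2, int(self.null_networks * factor)),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    ss = np.random.SeedSequence(cfg.seed, spawn_key=(STAGES.index(stage),))
    return int(ss.generate_state(1)[0] % (2**31))


def _check_inputs(cfg: PipelineConfig) -> None:
    required = ["seg", "ploidy", "genome_map", "expression", "interactome"]
    optional = ["masks", "gene_sets", "survival", "gistic_lesions"]
    for name in required:
        path = getattr(cfg, name)
        if not path:
            raise InputError(f"required input {name!r} not configured")
        if not Path(path).exists():
            raise InputError(f"input file not found: {path} (config key {name!r})")
    for name in optional:
        path = getattr(cfg, name)
        if path and not Path(path).exists():
            raise InputError(f"input file not found: {path} (config key {name!r})")


def _write(df: pd.DataFrame, path: Path, **kwargs) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=cio.FLOAT_FORMAT, **kwargs)
    return len(df)


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute all stages into ``outdir`` and return the manifest dict."""
    _check_inputs(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    manifest: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stages": {},
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        logger.info("stage %s: %s", stage, counts)

    # ------------------------------------------------------------ stage 1
    stage = "calls"
    try:
        profiles = cio.read_profiles(cfg.seg, cfg.ploidy)
        genome_map = cio.read_genome_map(cfg.genome_map)
        expression = cio.read_matrix(cfg.expression)
        interactome = cio.read_interactome(cfg.interactome)
        if cfg.masks:
            masks = cio.read_bed(cfg.masks)
            profiles = [
                mask_segments(p, masks, max_overlap=cfg.mask_max_overlap)
                for p in profiles
            ]
        cm = gene_level_calls(
            profiles, genome_map, delta=cfg.call_delta, min_markers=cfg.min_markers
        )
        cio.write_matrix(cm.calls, outdir / "call_matrix.tsv")
        cio.write_matrix(cm.cn, outdir / "cn_matrix.tsv")
        record(stage, genes=cm.shape[0], samples=cm.shape[1])
    except (InputError, FileNotFoundError):
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------ stage 2
    stage = "recurrence_regions"
    try:
        recurrence = recurrence_filter(cm, min_freq=cfg.recurrence_min_freq)
        freq = recurrence.frequencies.reset_index(names="gene")
        _write(freq, outdir / "frequencies.tsv")
        if cfg.gistic_lesions:
            regions = [r for r in read_gistic_lesions(cfg.gistic_lesions) if r.q < cfg.region_q]
        else:
            scan = score_regions(
                cm, profiles, genome_map,
                n_perm=cfg.region_perms, seed=_stage_seed(cfg, stage),
                q_threshold=cfg.region_q,
            )
            _write(scan.gene_table, outdir / "region_gene_scores.tsv")
            regions = scan.regions
        region_df = pd.DataFrame(
            [
                {"chrom": r.interval.chrom, "start": r.interval.start,
                 "end": r.interval.end, "direction": r.direction,
                 "score": r.score, "q": r.q}
                for r in regions
            ],
            columns=["chrom", "start", "end", "direction", "score", "q"],
        )
        _write(region_df, outdir / "regions.tsv")
        record(stage, gain_recurrent=len(recurrence.gain_genes),
               loss_recurrent=len(recurrence.loss_genes), regions=len(regions))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------ stage 3
    stage = "association"
    try:
        candidates = sorted(genes_in_regions(regions, genome_map) & set(expression.index))
        if not candidates:
            raise ValueError("no genes inside significant regions have expression data")
        results = permutation_pvalues(
            cm.cn.loc[candidates],
            expression.loc[candidates],
            n_perm=cfg.association_perms,
            seed=_stage_seed(cfg, stage),
            fdr_threshold=cfg.association_fdr,
        )
        assoc = association_table(results)
        _write(assoc, outdir / "association.tsv")
        altered = set(assoc.loc[assoc["selected"], "gene"])
        record(stage, tested=len(candidates), selected=len(altered))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------ stage 4
    stage = "network"
    try:
        net, linkers = build_network(
            interactome, altered,
            frequencies=recurrence.frequencies, linker_fdr=cfg.linker_fdr,
        )
        linker_df = pd.DataFrame(
            [
                {"gene": t.gene, "global_degree": t.global_degree,
                 "altered_neighbors": t.altered_neighbors, "p": t.p_hyper,
                 "q": t.q, "accepted": t.accepted}
                for t in linkers
            ],
            columns=["gene", "global_degree", "altered_neighbors", "p", "q", "accepted"],
        )
        _write(linker_df, outdir / "linker_tests.tsv")
        (outdir / "dropped_genes.txt").write_text("".join(f"{g}\n" for g in net.dropped))
        record(stage, nodes=net.n_nodes, edges=net.n_edges,
               drivers=len(net.nodes_by_role("driver")),
               linkers=len(net.nodes_by_role("linker")), dropped=len(net.dropped))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------ stage 5
    stage = "connectedness"
    try:
        n_altered_in_graph = len({g for g in altered if g in interactome})
        null = connectedness_null(
            interactome, n_altered_in_graph, net.n_nodes, net.n_edges,
            n_perm=cfg.connectedness_perms, seed=_stage_seed(cfg, stage),
            linker_fdr=cfg.linker_fdr,
        )
        _write(
            pd.DataFrame(
                {"null_nodes": null.null_nodes, "null_edges": null.null_edges}
            ),
            outdir / "connectedness_null.tsv",
        )
        summary = pd.DataFrame(
            [{"observed_nodes": null.observed_nodes, "observed_edges": null.observed_edges,
              "p_nodes": null.p_nodes, "p_edges": null.p_edges,
              "n_perm": cfg.connectedness_perms}]
        )
        _write(summary, outdir / "connectedness_summary.tsv")
        record(stage, p_nodes=null.p_nodes, p_edges=null.p_edges)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------ stage 6
    stage = "modules"
    try:
        partition = detect_modules(net)
        mod_null = edge_swap_null(
            net, n_networks=cfg.null_networks,
            swaps_per_edge=cfg.swaps_per_edge, seed=_stage_seed(cfg, stage),
        )
        roles = {n: net.graph.nodes[n]["role"] for n in net.graph.nodes}
        assign_df = pd.DataFrame(
            [
                {"gene": g, "module": c, "role": roles[g], "degree": net.graph.degree(g)}
                for g, c in sorted(partition.assignment.items())
            ]
        )
        _write(assign_df, outdir / "module_assignment.tsv")
        _write(partition.modules, outdir / "module_summary.tsv")
        hubs = find_hubs(net, top_fraction=cfg.hub_fraction)
        _write(hubs, outdir / "hubs.tsv")
        _write(
            pd.DataFrame(
                [{"q_obs": mod_null.q_obs, "q_null_mean": float(mod_null.q_null.mean()),
                  "q_null_sd": float(mod_null.q_null.std(ddof=1)),
                  "scaled_score": mod_null.scaled_score, "p_emp": mod_null.p_emp,
                  "n_networks": cfg.null_networks}]
            ),
            outdir / "modularity_null.tsv",
        )
        cio.export_cytoscape(net, partition, outdir / "cytoscape")
        record(stage, modules=len(partition.modules), q=partition.q,
               scaled_score=mod_null.scaled_score, hubs=len(hubs))
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------ stage 7
    stage = "annotation"
    try:
        if cfg.gene_sets:
            gene_sets = cio.read_gmt(cfg.gene_sets)
            background = set(interactome.nodes)
            enr = enrich_modules(partition, gene_sets, background)
            n = _write(enrichment_table(enr), outdir / "enrichment.tsv")
            record(stage, tests=n)
        else:
            record(stage, skipped="no gene_sets configured")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # ------------------------------------------------------------ stage 8
    stage = "survival"
    try:
        if cfg.survival:
            surv = cio.read_survival(cfg.survival)
            loss_drivers = {
                n for n, d in net.graph.nodes(data=True)
                if d["role"] == "driver" and d["alteration"] == "loss"
            }
            screen = gene_survival_screen(cm, surv, loss_drivers, min_group=cfg.min_group)
            _write(screen, outdir / "survival_screen.tsv")
            try:
                plo = ploidy_survival(profiles, surv, ploidy_cut=cfg.ploidy_cut)
                _write(plo.curves, outdir / "ploidy_km_curves.tsv")
                _write(
                    pd.DataFrame([{"statistic": plo.statistic, "p": plo.p,
                                   **{f"n_{k}": v for k, v in plo.group_sizes.items()}}]),
                    outdir / "ploidy_logrank.tsv",
                )
                ploidy_p = plo.p
            except ValueError as exc:
                logger.warning("ploidy survival skipped: %s", exc)
                ploidy_p = float("nan")
            record(stage, screened=len(screen), ploidy_logrank_p=ploidy_p)
        else:
            record(stage, skipped="no survival table configured")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


# --------------------------------------------------------------------------
# fixture bundles

FIXTURE_SCALES = {
    "tiny": dict(n_genes=100, n_samples=12, n_modules=5, module_size=8,
                 n_chromosomes=4),
    "paper-like": dict(n_genes=5000, n_samples=41, n_modules=5, module_size=12,
                       n_chromosomes=22),
}
# desk-scale null-replicate counts written into the fixture configs; the
# edge-swap null re-runs module detection per network, so it gets fewer
# replicates at the larger scale
FIXTURE_PERMS = {
    "tiny": {"perms": 100, "null_networks": 100},
    "paper-like": {"perms": 200, "null_networks": 50},
}


def make_fixture(outdir, scale: str = "tiny", seed: int = 0) -> PipelineConfig:
    """Write a complete synthetic input bundle (plus ground truth) to ``outdir``.

    ``tiny`` (100 genes / 12 samples) runs in seconds; ``paper-like``
    (5,000 genes / 41 samples at mean ploidy 2.8) in minutes.  Returns the
    pipeline config pointing at the written files; the same config is saved
    as ``config.yaml``.
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"unknown scale {scale!r}; choose from {sorted(FIXTURE_SCALES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = SyntheticConfig(seed=seed, **FIXTURE_SCALES[scale])

    interactome, truth = generate_interactome(scfg)
    genome_map = generate_genome_map(scfg)
    profiles = simulate_cn_profiles(scfg, genome_map, truth)
    cm = gene_level_calls(profiles, genome_map)
    expression = simulate_expression(cm, truth, scfg)
    survival = simulate_survival(cm, truth, scfg)

    cio.write_profiles(profiles, outdir / "segments.seg", outdir / "ploidy.tsv")
    cio.write_genome_map(genome_map, outdir / "genome_map.tsv")
    cio.write_interactome(interactome, outdir / "interactome.tsv")
    cio.write_matrix(expression, outdir / "expression.tsv")
    cio.write_survival(survival, outdir / "survival.tsv")
    cio.write_ground_truth(truth, outdir / "ground_truth.json")

    # masks: one interval per chromosome over a gene-free head region
    from .segments import GenomicInterval

    masks = [
        GenomicInterval(chrom, 0, 1000)
        for chrom in sorted(genome_map["chrom"].unique())
    ]
    cio.write_bed(masks, outdir / "masks.bed")

    # gene sets: the planted modules plus random distractor sets
    rng = scfg.rng(9)
    genes = sorted(interactome.nodes)
    gene_sets: dict[str, set[str]] = {}
    for m in sorted(set(truth.planted_module_membership.values())):
        gene_sets[f"PLANTED_MODULE_{m}"] = {
            g for g, mm in truth.planted_module_membership.items() if mm == m
        }
    for i in range(5):
        gene_sets[f"RANDOM_SET_{i}"] = set(
            rng.choice(genes, size=min(15, len(genes)), replace=False)
        )
    cio.write_gmt(gene_sets, outdir / "gene_sets.gmt")

    n = FIXTURE_PERMS[scale]["perms"]
    cfg = PipelineConfig(
        seg=str(outdir / "segments.seg"),
        ploidy=str(outdir / "ploidy.tsv"),
        genome_map=str(outdir / "genome_map.tsv"),
        expression=str(outdir / "expression.tsv"),
        interactome=str(outdir / "interactome.tsv"),
        masks=str(outdir / "masks.bed"),
        gene_sets=str(outdir / "gene_sets.gmt"),
        survival=str(outdir / "survival.tsv"),
        region_perms=max(100, n),
        connectedness_perms=n,
        null_networks=FIXTURE_PERMS[scale]["null_networks"],
        seed=seed,
    )
    cfg.to_yaml(outdir / "config.yaml")
    return cfg
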