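"""End-to-end orchestration: series -> band -> DCC -> graphs -> backbone.

Stage order: load or generate parcel series; band-limit each run;
estimate dynamic correlations for all pairs; epoch and group-average
into per-(condition, time) Fisher-z matrices; soft-threshold;
community detection and node/edge metrics; connector-hub
classification; edge-betweenness sparsification; backbone extraction;
small-worldness of each connector network.  All stochastic stages are
seeded, so a config (including its seed) reproduces identical outputs
byte for byte; the manifest records a digest of every written file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .band import modwt_band_reconstruct
from .connector import (
    TimePointMetrics,
    classify_connector_hubs,
    extract_backbone,
    intermodular_sign_summary,
    sparsify_by_edge_betweenness,
)
from .dcc import dcc_all_pairs, epoch_and_group_average
from .graph import (
    DEFAULT_BETA,
    NodeGraphMetrics,
    edge_betweenness,
    louvain_partition,
    nodal_betweenness,
    participation_coefficient,
    small_worldness,
    soft_threshold,
)
from .registry import HubRegistry
from .synthetic import SyntheticConfig, generate_parcel_timeseries, load_timeseries_tsv

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "run_pipeline",
           "validate_fixture_tables"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration of one pipeline run; defaults are materialized."""

    input_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    f_lo: float = 0.03
    f_hi: float = 0.07
    wavelet: str = "sym8"
    beta_exponent: int = DEFAULT_BETA
    pc_threshold: float = 0.5
    hub_rule_mode: str = "all"
    average_on_z: bool = False
    louvain_runs: int = 20
    louvain_seed: int = 7
    small_world_nulls: int = 50
    small_world_seed: int = 11
    sampling_interval_s: float = 2.0
    output_dir: str = "chronnect_out"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def validate(self) -> None:
        if self.input_dir is None and self.synthetic is None:
            raise ValueError(
                "config must provide either input_dir or a synthetic spec"
            )
        if self.hub_rule_mode not in ("all", "any"):
            raise ValueError("hub_rule_mode must be 'all' or 'any'")


@dataclass
class PipelineResult:
    """In-memory artifacts of one run (what the output tree serializes)."""

    group_matrices: dict
    time_metrics: dict
    hub_sets: dict
    networks: dict
    backbone: object
    small_world: dict
    sign_summaries: dict
    labels: list[str]
    conditions: list[str]
    dcc_fallbacks: dict


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list = field(default_factory=list)
    digests: dict = field(default_factory=dict)
    fallback_counts: dict = field(default_factory=dict)
    result: PipelineResult | None = None  # in-memory only, not serialized

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items() if k != "result"}
        d.pop("result", None)
        return json.dumps(d, indent=2, sort_keys=True)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_matrix_tsv(path: Path, matrix: np.ndarray, labels: list[str]) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def _write_pajek(path: Path, net) -> None:
    lines = [f"*Vertices {len(net.nodes)}"]
    index = {v: k + 1 for k, v in enumerate(net.nodes)}
    for v in net.nodes:
        lines.append(f'{index[v]} "{v}"')
    lines.append("*Edges")
    for i, j, value in net.signed_edges:
        lines.append(f"{index[i]} {index[j]} {value:.10g}")
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage and write the declared output tree.

    Returns the manifest; the in-memory artifacts remain available on
    its ``result`` attribute.  Failures abort with the stage name and
    the offending unit in the message.
    """
    config.validate()
    manifest = RunManifest(config=config.to_dict(), version=__version__)
    out = Path(config.output_dir)

    def stage(name: str, detail: str = "") -> None:
        logger.info("stage %s %s", name, detail)
        manifest.stages.append({"name": name, "status": "completed",
                                "detail": detail})

    # 1. input
    if config.synthetic is not None:
        series, _truth = generate_parcel_timeseries(config.synthetic)
        stage("input", f"synthetic ({config.synthetic.n_parcels} parcels)")
    else:
        series = load_timeseries_tsv(config.input_dir, config.sampling_interval_s)
        stage("input", f"loaded {config.input_dir}")

    # 2. band filtering
    band = modwt_band_reconstruct(series, config.f_lo, config.f_hi, config.wavelet)
    stage("band_filter", f"levels {band.levels_used} wavelet {band.wavelet_name}")

    # 3. dynamic correlations per subject x condition
    n_subj, n_cond, n_trials, p, spt = band.values.shape
    tensors, fallbacks = {}, {}
    for s in range(n_subj):
        for c, cond in enumerate(band.conditions):
            try:
                t = dcc_all_pairs(band.concatenated(s, c), band.labels)
            except ValueError as exc:
                raise RuntimeError(
                    f"stage dcc failed for subject {s + 1}, condition {cond}: {exc}"
                ) from exc
            tensors[(s, cond)] = t
            fallbacks[f"sub-{s + 1}/{cond}"] = t.n_fallback_pairs
    manifest.fallback_counts = fallbacks
    stage("dcc", f"{len(tensors)} runs, fallbacks={sum(fallbacks.values())}")

    # 4. group averaging -> one Fisher-z matrix per (condition, time index)
    matrices = epoch_and_group_average(tensors, spt, config.average_on_z)
    stage("group_average", f"{len(matrices)} matrices")

    # 5. full-graph metrics per (condition, time index)
    time_metrics: dict[tuple[str, int], TimePointMetrics] = {}
    for n_idx, ((cond, k), gm) in enumerate(sorted(matrices.items())):
        graph = soft_threshold(gm.r_values(), config.beta_exponent)
        part = louvain_partition(graph, config.louvain_runs,
                                 seed=config.louvain_seed + 1000 * n_idx)
        pc = participation_coefficient(graph, part)
        nbc = nodal_betweenness(graph)
        ebc = edge_betweenness(graph)
        time_metrics[(cond, k)] = TimePointMetrics(
            partition=part,
            metrics=NodeGraphMetrics(participation=pc, nodal_betweenness=nbc),
            edge_bc=ebc,
        )
    stage("graph_metrics", f"{len(time_metrics)} time points")

    # 6. connector hubs per condition
    hub_sets = {}
    for cond in band.conditions:
        by_time = {k: m for (c2, k), m in time_metrics.items() if c2 == cond}
        hub_sets[cond] = classify_connector_hubs(
            cond, by_time, config.pc_threshold, config.hub_rule_mode
        )
    stage("connector_hubs",
          " ".join(f"{c}:{len(h.hubs)}" for c, h in hub_sets.items()))

    # 7. sparsification -> signed connector networks
    networks = {
        (cond, k): sparsify_by_edge_betweenness(
            time_metrics[(cond, k)].edge_bc, matrices[(cond, k)],
            hub_sets[cond], k,
        )
        for (cond, k) in matrices
    }
    stage("sparsify", f"{len(networks)} connector networks")

    # 8. backbone
    backbone = extract_backbone(networks)
    stage("backbone", f"shared hubs: {len(backbone.shared_hubs)}")

    # 9. small-worldness + sign summaries
    small_world, signs = {}, {}
    for n_idx, ((cond, k), net) in enumerate(sorted(networks.items())):
        signs[(cond, k)] = intermodular_sign_summary(net)
        if len(net.nodes) >= 4:
            small_world[(cond, k)] = small_worldness(
                net.adjacency(), config.small_world_nulls,
                seed=config.small_world_seed + 1000 * n_idx,
            )
    stage("small_world", f"{len(small_world)} networks evaluated")

    result = PipelineResult(
        group_matrices=matrices, time_metrics=time_metrics, hub_sets=hub_sets,
        networks=networks, backbone=backbone, small_world=small_world,
        sign_summaries=signs, labels=list(band.labels),
        conditions=list(band.conditions), dcc_fallbacks=fallbacks,
    )
    manifest.result = result
    _write_outputs(out, config, manifest, result)
    return manifest


def _write_outputs(out: Path, config: PipelineConfig, manifest: RunManifest,
                   result: PipelineResult) -> None:
    (out / "matrices").mkdir(parents=True, exist_ok=True)
    (out / "graphs").mkdir(exist_ok=True)
    (out / "metrics").mkdir(exist_ok=True)
    labels = result.labels
    written: list[Path] = []

    for (cond, k), gm in sorted(result.group_matrices.items()):
        path = out / "matrices" / f"{cond}_t{k}.tsv"
        _write_matrix_tsv(path, gm.z_values, labels)
        written.append(path)

    for (cond, k), net in sorted(result.networks.items()):
        pj = out / "graphs" / f"{cond}_t{k}.net"
        _write_pajek(pj, net)
        written.append(pj)
        rows = [
            {"source": labels[i], "target": labels[j], "value": v,
             "community_source": net.communities.get(i),
             "community_target": net.communities.get(j)}
            for i, j, v in net.signed_edges
        ]
        csvp = out / "graphs" / f"{cond}_t{k}.csv"
        pd.DataFrame(rows, columns=["source", "target", "value",
                                    "community_source", "community_target"]
                     ).to_csv(csvp, index=False, float_format="%.10g")
        written.append(csvp)

    for (cond, k), tm in sorted(result.time_metrics.items()):
        path = out / "metrics" / f"{cond}_t{k}.csv"
        pd.DataFrame({
            "node": labels,
            "community": tm.partition.assignment,
            "participation": tm.metrics.participation,
            "betweenness": tm.metrics.nodal_betweenness,
        }).to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    summary = {
        f"{cond}_t{k}": {
            "n_hub_nodes": len(result.networks[(cond, k)].nodes),
            "n_edges": len(result.networks[(cond, k)].signed_edges),
            "modularity_q": result.time_metrics[(cond, k)].partition.modularity_q,
            "n_communities": result.time_metrics[(cond, k)].partition.n_communities,
            "intermodular_edges": result.sign_summaries[(cond, k)].n_intermodular,
            "intermodular_negative": result.sign_summaries[(cond, k)].n_negative,
            "small_world": (
                {"gamma": result.small_world[(cond, k)].gamma,
                 "lambda": result.small_world[(cond, k)].lam,
                 "sigma": result.small_world[(cond, k)].sigma}
                if (cond, k) in result.small_world else None
            ),
        }
        for (cond, k) in sorted(result.networks)
    }
    spath = out / "metrics" / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(spath)

    bb = result.backbone
    bpath = out / "backbone.json"
    bpath.write_text(json.dumps({
        "shared_hubs": [labels[i] for i in bb.shared_hubs],
        "stable_edges": {
            cond: sorted([labels[i], labels[j]] for i, j in edges)
            for cond, edges in bb.stable_edges.items()
        },
    }, indent=2, sort_keys=True))
    written.append(bpath)

    for path in written:
        manifest.digests[str(path.relative_to(out))] = _digest(path)
    (out / "manifest.json").write_text(manifest.to_json())


def validate_fixture_tables(registry: HubRegistry) -> dict:
    """Summarize a hub registry: counts, set algebra, hemisphere split."""
    counts = registry.counts()
    shared = registry.shared()
    report = {
        "per_condition_counts": counts,
        "union_size": len(registry.union()),
        "shared_size": len(shared),
        "shared_subunits": sorted(shared),
        "shared_hemisphere": registry.hemisphere_split(shared),
    }
    conds = registry.conditions
    report["pairwise_intersections"] = {
        f"{a}&{b}": len(registry.subunits(a) & registry.subunits(b))
        for i, a in enumerate(conds) for b in conds[i + 1:]
    }
    return report
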