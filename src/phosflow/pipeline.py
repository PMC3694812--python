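"""End-to-end orchestration: ingest -> meta-analysis -> clustering ->
networks -> causal screen, driven by one config, with a JSON run manifest.

Every stochastic stage draws from the single configured seed; two runs
with identical config and seed write identical outputs and the same run
hash (the hash covers the effective config and the stage output file
digests, not wall-clock timings).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .causal_bn import (
    causal_screen, discretize, screen_to_frame, write_causal_graphml,
    write_causal_sif,
)
from .clustering import TightClusterParams, filter_min_observed, knn_impute, tight_cluster
from .core_model import (
    KINASES, RatioMatrix, collapse_replicates, map_peptides_to_proteins,
    read_quant_table,
)
from .correlation_network import (
    build_peptide_network, lift_to_proteins, mutant_similarity, write_graphml,
    write_sif,
)
from .errors import StageError, ValidationError
from .meta_analysis import (
    aw_screen, build_regulation_pairs, meta_analyze, select_differential_per_mutant,
)

logger = logging.getLogger(__name__)

STAGES = ("ingest", "meta", "cluster", "network", "causal", "report")


@dataclass
class PipelineConfig:
    table: str | None = None          # input long-table TSV; None -> simulate
    out_dir: str = "phosflow_out"
    seed: int = 0
    # thresholds
    alpha: float = 0.05
    min_sig_conditions: int = 4
    sig_b_threshold: float = 0.05
    fold_threshold: float = 2.0
    r_min: float = 0.9
    p_max: float = 0.05
    posterior_min: float = 0.5
    prior_ess: float = 1.0
    min_conditions: int = 4
    # tight clustering
    k0: int = 10
    n_subsamples: int = 50
    subsample_fraction: float = 0.7
    alpha_comembership: float = 0.8
    beta_stability: float = 0.7
    n_clusters_target: int = 8
    min_cluster_size: int = 5
    # adaptively weighted cross-check
    run_aw: bool = True
    n_null: int = 10_000
    # synthetic fallback when no table is given
    n_peptides: int = 1000
    n_replicates: int = 2
    noise_sd: float = 0.25
    format_options: dict = field(default_factory=dict)

    def validate(self) -> None:
        in_unit = {
            "alpha": self.alpha, "sig_b_threshold": self.sig_b_threshold,
            "r_min": self.r_min, "p_max": self.p_max,
            "posterior_min": self.posterior_min,
            "subsample_fraction": self.subsample_fraction,
            "alpha_comembership": self.alpha_comembership,
            "beta_stability": self.beta_stability,
        }
        for name, value in in_unit.items():
            if not 0.0 < value <= 1.0:
                raise ValidationError(f"{name}={value} outside (0, 1]")
        if self.fold_threshold <= 1:
            raise ValidationError("fold_threshold must exceed 1")
        if self.prior_ess <= 0:
            raise ValidationError("prior_ess must be positive")
        if not 0 <= self.min_sig_conditions <= len(KINASES):
            raise ValidationError("min_sig_conditions must lie in [0, 8]")
        if not 0 <= self.min_conditions <= len(KINASES):
            raise ValidationError("min_conditions must lie in [0, 8]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def cluster_params(self) -> TightClusterParams:
        return TightClusterParams(
            k0=self.k0,
            n_subsamples=self.n_subsamples,
            subsample_fraction=self.subsample_fraction,
            alpha_comembership=self.alpha_comembership,
            beta_stability=self.beta_stability,
            n_clusters_target=self.n_clusters_target,
            min_cluster_size=self.min_cluster_size,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in workflow order and write a run manifest.

    Stage outputs land under ``config.out_dir``; failures raise StageError
    carrying the stage name (partial outputs are retained on disk).
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "phosflow", "version": __version__},
        "seed": config.seed,
        "config": asdict(config),
        "stages": [],
    }
    counts: dict[str, int] = {}
    t_total = time.monotonic()

    def record(stage: str, params: dict, outputs: dict[str, Path], t0: float) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "params": params,
                "outputs": {name: _sha256(p) for name, p in sorted(outputs.items())},
                "files": {name: p.name for name, p in sorted(outputs.items())},
                "elapsed_s": round(time.monotonic() - t0, 3),
            }
        )

    # ---- ingest ---------------------------------------------------------
    t0 = time.monotonic()
    try:
        if config.table is not None:
            records = read_quant_table(config.table, config.format_options)
        else:
            from .synthetic_data import simulate_study

            records, _ = simulate_study(
                config.seed,
                n_peptides=config.n_peptides,
                n_replicates=config.n_replicates,
                noise_sd=config.noise_sd,
            )
        matrix = collapse_replicates(records)
        matrix_dir = out / "matrix"
        layer_paths = matrix.to_dir(matrix_dir)
        counts["identified_peptides"] = len(matrix.peptides)
        counts["identified_proteins"] = len(
            {p for pep in matrix.peptides for p in pep.protein_ids}
        )
        n_obs = matrix.n_observed
        counts["common_all_8"] = int((n_obs == 8).sum())
        counts["common_4_to_8"] = int((n_obs >= 4).sum())
        record(
            "ingest",
            {"table": config.table or f"synthetic(seed={config.seed})"},
            {f"matrix/{k}": p for k, p in layer_paths.items()},
            t0,
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("ingest", str(exc)) from exc

    # ---- meta-analysis --------------------------------------------------
    t0 = time.monotonic()
    try:
        meta = meta_analyze(
            matrix, alpha=config.alpha,
            min_sig_conditions=config.min_sig_conditions,
            sig_b_threshold=config.sig_b_threshold,
        )
        outputs = {}
        meta_path = out / "meta.tsv"
        meta.to_csv(meta_path, sep="\t", float_format="%.8g")
        outputs["meta"] = meta_path
        differential = select_differential_per_mutant(matrix, config.sig_b_threshold)
        pairs = build_regulation_pairs(differential)
        for name, frame in (("differential", differential), ("regulation_pairs", pairs)):
            p = out / f"{name}.tsv"
            frame.to_csv(p, sep="\t", index=False, float_format="%.8g")
            outputs[name] = p
        if config.run_aw:
            pcond = np.minimum(1.0, 2.0 * matrix.significance_b)
            complete = pcond.dropna()
            if not complete.empty:
                aw = aw_screen(complete, n_null=config.n_null, seed=config.seed)
                p = out / "aw.tsv"
                aw.to_csv(p, sep="\t", float_format="%.8g")
                outputs["aw"] = p
        counts["significant_in_ge1"] = int((meta["n_significant_conditions"] >= 1).sum())
        counts["regulation_pairs"] = len(differential)
        counts["globally_significant"] = int(meta["globally_significant"].sum())
        counts["high_confidence"] = int(meta["high_confidence"].sum())
        record(
            "meta",
            {"alpha": config.alpha, "min_sig_conditions": config.min_sig_conditions},
            outputs, t0,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("meta", str(exc)) from exc

    # ---- clustering -----------------------------------------------------
    t0 = time.monotonic()
    try:
        eligible, n_excluded = filter_min_observed(matrix.log2, config.min_conditions)
        imputed = knn_impute(eligible, k=5)
        tight = tight_cluster(imputed, config.cluster_params())
        outputs = {}
        membership = pd.DataFrame(
            [
                {"cluster": c + 1, "modified_sequence": key,
                 "proteins": ";".join(sorted(map_peptides_to_proteins(
                     [matrix.peptide(key)])[key]))}
                for c, members in enumerate(tight.clusters)
                for key in members
            ],
            columns=["cluster", "modified_sequence", "proteins"],
        )
        p = out / "clusters.tsv"
        membership.to_csv(p, sep="\t", index=False)
        outputs["clusters"] = p
        p = out / "co_membership.tsv"
        tight.co_membership.to_csv(p, sep="\t", float_format="%.6g")
        outputs["co_membership"] = p
        counts["tight_clusters"] = len(tight.clusters)
        counts["clustered_peptides"] = int(sum(len(c) for c in tight.clusters))
        counts["scattered_peptides"] = len(tight.scattered)
        record(
            "cluster",
            {"min_conditions": config.min_conditions, "n_excluded": n_excluded,
             "params": asdict(config.cluster_params())},
            outputs, t0,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("cluster", str(exc)) from exc

    # ---- networks -------------------------------------------------------
    t0 = time.monotonic()
    try:
        outputs = {}
        similarity = mutant_similarity(matrix, fold_threshold=config.fold_threshold)
        p = out / "mutant_similarity.tsv"
        similarity.rho.to_csv(p, sep="\t", float_format="%.6g")
        outputs["mutant_similarity"] = p

        complete = matrix.log2.dropna()
        edges = build_peptide_network(
            complete, r_threshold=config.r_min, p_threshold=config.p_max
        )
        p = out / "peptide_edges.tsv"
        edges.to_csv(p, sep="\t", index=False, float_format="%.8g")
        outputs["peptide_edges"] = p

        mapping = map_peptides_to_proteins(matrix.peptides)
        network = lift_to_proteins(edges, mapping)
        write_sif(network, out / "protein_network.sif")
        outputs["protein_network_sif"] = out / "protein_network.sif"
        write_graphml(network, out / "protein_network.graphml")
        outputs["protein_network_graphml"] = out / "protein_network.graphml"
        hubs = pd.DataFrame(
            sorted(
                ({"protein": n, "degree": network.degree[n],
                  "hub": n in network.hubs,
                  "self_connected": n in network.self_connected}
                 for n in network.graph.nodes),
                key=lambda r: (-r["degree"], r["protein"]),
            ),
            columns=["protein", "degree", "hub", "self_connected"],
        )
        p = out / "protein_degrees.tsv"
        hubs.to_csv(p, sep="\t", index=False)
        outputs["protein_degrees"] = p
        counts["complete_peptides"] = len(complete)
        counts["correlated_pairs"] = len(edges)
        counts["network_proteins"] = len(network.graph.nodes)
        counts["hub_proteins"] = len(network.hubs)
        record(
            "network",
            {"fold_threshold": config.fold_threshold, "r_min": config.r_min,
             "p_max": config.p_max},
            outputs, t0,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("network", str(exc)) from exc

    # ---- causal screen --------------------------------------------------
    t0 = time.monotonic()
    try:
        states = discretize(matrix)
        # focus: peptides of the mutated kinases, the high-confidence
        # globally significant peptides, and peptides of hub proteins
        focus_proteins = set(KINASES) | network.hubs
        focus_keys = [
            key for key in states.index
            if (mapping[key] & focus_proteins) or meta.at[key, "high_confidence"]
        ]
        outputs = {}
        reported: list = []
        if len(focus_keys) >= 2:
            results, reported = causal_screen(
                states.loc[focus_keys], mapping,
                prior_ess=config.prior_ess,
                report_threshold=config.posterior_min,
            )
            frame = screen_to_frame(results)
            p = out / "causal_pairs.tsv"
            frame.to_csv(p, sep="\t", index=False, float_format="%.8g")
            outputs["causal_pairs"] = p
            write_causal_sif(reported, out / "causal_network.sif")
            outputs["causal_network_sif"] = out / "causal_network.sif"
            write_causal_graphml(reported, out / "causal_network.graphml")
            outputs["causal_network_graphml"] = out / "causal_network.graphml"
        counts["causal_focus_peptides"] = len(focus_keys)
        counts["causal_edges"] = len(reported)
        record(
            "causal",
            {"prior_ess": config.prior_ess, "posterior_min": config.posterior_min},
            outputs, t0,
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("causal", str(exc)) from exc

    # ---- report ---------------------------------------------------------
    t0 = time.monotonic()
    manifest["counts"] = counts
    report_text = summarize_counts(counts)
    report_path = out / "report.txt"
    report_path.write_text(report_text)
    record("report", {}, {"report": report_path}, t0)

    # the hash identifies the analysis, not where it was written
    hashed_config = {k: v for k, v in manifest["config"].items() if k != "out_dir"}
    hash_payload = json.dumps(
        {
            "config": hashed_config,
            "outputs": [s["outputs"] for s in manifest["stages"]],
            "counts": counts,
        },
        sort_keys=True,
    )
    manifest["run_hash"] = hashlib.sha256(hash_payload.encode()).hexdigest()
    manifest["elapsed_s"] = round(time.monotonic() - t_total, 3)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete in %.1fs; run hash %s",
                manifest["elapsed_s"], manifest["run_hash"][:12])
    return manifest


def summarize_counts(counts: dict[str, int]) -> str:
    """Human-readable per-stage summary (dataset/analysis count table)."""
    lines = [
        "phosflow run summary",
        "====================",
        f"Identified phosphopeptides            {counts.get('identified_peptides', 0)}",
        f"Identified proteins                   {counts.get('identified_proteins', 0)}",
        f"Common among all 8 KDs                {counts.get('common_all_8', 0)}",
        f"Common among 4-8 KDs                  {counts.get('common_4_to_8', 0)}",
        f"Significant in >= 1 KD                {counts.get('significant_in_ge1', 0)}",
        f"Kinase-peptide regulation pairs       {counts.get('regulation_pairs', 0)}",
        f"Globally significant peptides         {counts.get('globally_significant', 0)}"
        f" ({counts.get('high_confidence', 0)} high-confidence)",
        f"Tight clusters                        {counts.get('tight_clusters', 0)}"
        f" ({counts.get('clustered_peptides', 0)} peptides;"
        f" {counts.get('scattered_peptides', 0)} scattered)",
        f"Complete-measurement peptides         {counts.get('complete_peptides', 0)}",
        f"Strongly correlated peptide pairs     {counts.get('correlated_pairs', 0)}",
        f"Correlation-network proteins          {counts.get('network_proteins', 0)}"
        f" ({counts.get('hub_proteins', 0)} hubs)",
        f"Causal edges (posterior > threshold)  {counts.get('causal_edges', 0)}",
    ]
    return "\n".join(lines) + "\n"


def summarize_run(manifest: dict | str | Path) -> str:
    """Render the summary report from a manifest (idempotent)."""
    if not isinstance(manifest, dict):
        with open(manifest) as fh:
            manifest = json.load(fh)
    if "counts" not in manifest:
        raise ValidationError("manifest carries no counts; was the run complete?")
    return summarize_counts(manifest["counts"])
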