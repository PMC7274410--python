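"""End-to-end orchestration: generate → select → cluster → infer → quantify.

A run writes every stage artifact into one output directory as plain-text
TSV/CSV/SIF/JSON, echoes the effective configuration as YAML, and logs
per-stage timings. Given the same configuration (including the seed), a
rerun reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ctio
from .network import FitOptions, fit_all_pairs, filter_candidates, summarize_network
from .qpcr import concordance, ddct_fold_change, qpcr_table_to_records, ttest_two_sample
from .srp import CONTROL, STRESSES, hierarchical_cluster, ratio_matrix, select_srp
from .simulate import (
    QPCR_GENES,
    generate_network,
    generate_qpcr,
    generate_spot_table,
    simulate_timecourse,
)

__all__ = ["PipelineConfig", "run_pipeline", "render_report", "GENE_SPOT_MAP"]

logger = logging.getLogger(__name__)

#: qPCR transcripts matched to their protein spot in the packaged catalog.
GENE_SPOT_MAP = {
    "heat_shock_protein_70": "spot1",
    "catalase": "spot5",
    "calreticulin": "spot11",
    "serine_hydroxymethyltransferase_5": "spot12",
    "ascorbate_peroxidase": "spot19",
    "chalcone_flavone_isomerase": "spot21",
    "peroxidase": "spot22",
    "superoxide_dismutase": "spot26",
    "peroxiredoxin": "spot29",
}


@dataclass
class PipelineConfig:
    """Effective settings of one pipeline run (fully YAML-serializable)."""

    out_dir: str = "crosstol_run"
    seed: int = 1
    # selection thresholds
    fc_threshold: float = 1.5
    alpha: float = 0.05
    r2_threshold: float = 0.9
    # fit options
    fix_h: bool = True
    threads: int = 1
    # generator settings
    n_spots: int = 39
    n_planted: int = 10
    n_proteins: int = 6
    n_edges: int = 5
    n_timepoints: int = 8
    noise_cv: float = 0.02
    qpcr_noise_sd: float = 0.15
    cultivar: str = "PI-471938"
    extra: dict = field(default_factory=dict)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-12s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage on freshly generated data and write artifacts.

    Stages: spot-table generation → SRP selection → expression clustering →
    time-course simulation → network inference → qPCR/enzyme
    quantification → concordance → report. Returns the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    t0 = time.perf_counter()

    # --- spot table and SRP selection
    spot_table, spot_truth = generate_spot_table(
        seed=config.seed,
        n_spots=config.n_spots,
        n_planted=config.n_planted,
        cultivar=config.cultivar,
        use_catalog_ids=config.n_spots <= 39,
    )
    spot_table.to_csv(out / "spot_table.tsv", sep="\t", index=False,
                      float_format="%.10g")
    (out / "spot_truth.json").write_text(spot_truth.to_json())
    srps = select_srp(
        spot_table, fc_threshold=config.fc_threshold, alpha=config.alpha
    )
    ctio.write_srp_tsv(srps, out / "srp.tsv")
    t0 = _stage("select-srp", t0)

    # --- clustering of the fold-change matrix
    ratios = ratio_matrix(spot_table, cultivar=config.cultivar)
    ratios.to_csv(out / "ratio_matrix.tsv", sep="\t", float_format="%.10g")
    _, leaf_order = hierarchical_cluster(ratios.to_numpy())
    ordered = ratios.index.to_numpy()[leaf_order]
    pd.Series(ordered, name="spot_id").to_csv(
        out / "leaf_order.tsv", sep="\t", index=False
    )
    t0 = _stage("cluster", t0)

    # --- interaction network from a simulated time course
    network = generate_network(
        config.n_proteins, config.n_edges, seed=config.seed
    )
    trajectories = simulate_timecourse(
        network,
        times=np.linspace(0.0, 21.0, config.n_timepoints),
        noise_cv=config.noise_cv,
        seed=config.seed,
    )
    ctio.write_trajectories(trajectories, out / "timecourse.tsv")
    from .simulate import GroundTruth

    (out / "network_truth.json").write_text(
        GroundTruth(seed=config.seed, network=network).to_json()
    )
    options = FitOptions(fix_h=config.fix_h, seed=config.seed)
    all_cands = fit_all_pairs(trajectories, options, n_jobs=config.threads)
    retained = filter_candidates(all_cands, config.r2_threshold)
    ctio.write_candidates_tsv(retained, out / "edges.tsv")
    ctio.write_sif(retained, out / "edges.sif")
    summary = summarize_network(retained, network.categories)
    ctio.write_summary_tsv(summary, out / "network_summary.tsv")
    t0 = _stage("infer-net", t0)

    # --- transcript quantification and concordance with protein folds
    qpcr_table, qpcr_truth = generate_qpcr(
        seed=config.seed, ct_noise_sd=config.qpcr_noise_sd
    )
    qpcr_table.to_csv(out / "qpcr.tsv", sep="\t", index=False,
                      float_format="%.10g")
    (out / "qpcr_truth.json").write_text(qpcr_truth.to_json())
    groups = qpcr_table_to_records(qpcr_table)
    protein_folds = {
        rec.spot_id: rec.fold_changes for rec in srps
    }
    rows = []
    for gene in QPCR_GENES:
        calibrator = groups[(gene, CONTROL)]
        cal_dct = [r.ct_target - r.ct_reference for r in calibrator]
        for stress in STRESSES:
            sample = groups[(gene, stress)]
            fold = ddct_fold_change(sample, calibrator)
            t_stat, p = ttest_two_sample(
                [r.ct_target - r.ct_reference for r in sample], cal_dct
            )
            spot = GENE_SPOT_MAP.get(gene)
            row = {
                "gene": gene,
                "stress": stress,
                "transcript_fold": fold,
                "t": t_stat,
                "p": p,
            }
            if spot in protein_folds:
                call = concordance(
                    fold,
                    protein_folds[spot][stress],
                    gene=gene,
                    stress=stress,
                )
                row["protein_fold"] = call.protein_fold
                row["call"] = call.call
            else:
                row["protein_fold"] = float("nan")
                row["call"] = "no-protein-data"
            rows.append(row)
    pd.DataFrame(
        rows,
        columns=[
            "gene", "stress", "transcript_fold", "t", "p",
            "protein_fold", "call",
        ],
    ).to_csv(out / "qpcr_folds.tsv", sep="\t", index=False,
             float_format="%.10g")
    t0 = _stage("qpcr", t0)

    render_report(out)
    _stage("report", t0)
    return out


def render_report(run_dir: str | Path) -> Path:
    """Summarize a finished run's artifacts into plain-text tables.

    Emits cluster membership, promotive/inhibitive counts per category, and
    a run summary, all re-derived from the stage outputs in ``run_dir``.
    """
    run_dir = Path(run_dir)
    needed = ["srp.tsv", "edges.tsv", "network_summary.tsv", "qpcr_folds.tsv"]
    for name in needed:
        if not (run_dir / name).exists():
            raise FileNotFoundError(f"missing run artifact: {run_dir / name}")

    srp = pd.read_csv(run_dir / "srp.tsv", sep="\t")
    cluster_rows = []
    if len(srp):
        for (cultivar, cluster), sub in srp.groupby(
            ["cultivar", "cluster"], sort=True
        ):
            cluster_rows.append(
                {
                    "cultivar": cultivar,
                    "cluster": cluster,
                    "n_spots": len(sub),
                    "spots": ",".join(sorted(sub["spot_id"].astype(str))),
                }
            )
    pd.DataFrame(
        cluster_rows, columns=["cultivar", "cluster", "n_spots", "spots"]
    ).to_csv(run_dir / "report_clusters.tsv", sep="\t", index=False)

    edges = pd.read_csv(run_dir / "edges.tsv", sep="\t")
    summary = pd.read_csv(run_dir / "network_summary.tsv", sep="\t")
    qpcr = pd.read_csv(run_dir / "qpcr_folds.tsv", sep="\t")

    n_pro = int((edges["sign"] == "promotive").sum()) if len(edges) else 0
    n_inh = int((edges["sign"] == "inhibitive").sum()) if len(edges) else 0
    nodes = (
        set(edges["regulator"]).union(edges["target"]) if len(edges) else set()
    )
    lines = [
        "crosstol run summary",
        "====================",
        f"stress-responsive spots selected: {len(srp)}",
        f"expression clusters: "
        + ", ".join(
            f"{r['cluster']}={r['n_spots']}" for r in cluster_rows
        )
        if cluster_rows
        else "expression clusters: none",
        f"retained interactions: {len(edges)} "
        f"({n_pro} promotive, {n_inh} inhibitive)",
        f"interacting proteins: {len(nodes)}",
        f"transcript measurements: {len(qpcr)}",
        f"concordant transcript/protein calls: "
        f"{int((qpcr['call'] == 'concordant').sum())}",
    ]
    (run_dir / "report_summary.txt").write_text("\n".join(lines) + "\n")
    summary.to_csv(run_dir / "report_network.tsv", sep="\t", index=False)
    return run_dir
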