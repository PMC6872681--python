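"""End-to-end analysis pipeline.

Runs the full stack — input (PLINK files or simulation) → QC → diversity →
LD decay → ROH → pairwise F_ST → d_i selection scan → structure (PCA, NJ
tree) → optional D-statistics — from one YAML config, writing per-stage TSV
outputs and a JSON reproducibility manifest with stage-wise SNP/individual
counts and realized thresholds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .differentiation import allele_frequencies, d_statistic, pairwise_fst_matrix
from .diversity import diversity_table, ibs_distance_matrix
from .linkage import (
    accumulative_roh,
    decay_curve,
    detect_roh,
    ld_prune,
    pairwise_r2,
    r2_threshold_distance,
    roh_table,
)
from .panel import GenotypePanel, filter_individuals, filter_snps
from .plink_io import read_plink_bed, read_plink_text
from .selection import breed_scan, group_contrast_scan
from .simulate import AdmixEvent, SelectionTarget, SimConfig, simulate_panel
from .structure import neighbor_joining, pca, write_newick

logger = logging.getLogger(__name__)

DEFAULT_STAGES = (
    "qc",
    "diversity",
    "ld_decay",
    "roh",
    "fst",
    "scan",
    "structure",
)


@dataclass
class RunConfig:
    """One auditable home for every pipeline threshold.

    Defaults: SNP MAF 0.01 and call rate 0.90, individual call rate 0.95;
    LD-decay subset MAF 0.05, 500-kb pair cap, r²₀.₃ summary; ROH on an
    r² ≥ 0.8-pruned subset with the 50-SNP window vote and 200-kb minimum;
    selection scan in 200-kb windows, ≥6 SNPs, 99.5th percentile.
    """

    out_dir: str = "popdog_out"
    seed: int = 0
    plink_prefix: str | None = None
    plink_binary: bool = False
    population_map: str | None = None
    simulate: dict[str, Any] | None = None
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    qc: dict[str, float] = field(
        default_factory=lambda: {
            "maf_min": 0.01,
            "snp_call_rate_min": 0.90,
            "ind_call_rate_min": 0.95,
        }
    )
    ld: dict[str, float] = field(
        default_factory=lambda: {
            "maf_min": 0.05,
            "max_dist_kb": 500,
            "bin_width_kb": 10,
            "r2_threshold": 0.3,
        }
    )
    roh: dict[str, float] = field(
        default_factory=lambda: {
            "prune_r2": 0.8,
            "window_snps": 50,
            "max_het_per_window": 1,
            "max_missing_per_window": 5,
            "min_length_kb": 200,
            "min_snps": 25,
            "hit_fraction": 0.05,
        }
    )
    scan: dict[str, Any] = field(
        default_factory=lambda: {
            "window_kb": 200,
            "min_snps": 6,
            "percentile": 99.5,
            "contrast": None,  # {"focal": [...], "background": [...]}
        }
    )
    structure: dict[str, Any] = field(
        default_factory=lambda: {"prune_r2": 0.5, "n_components": 10}
    )
    dstat: dict[str, Any] | None = None  # {"quartet": [...], "block_snps": 300}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg


def _sim_config(block: dict[str, Any], seed: int) -> SimConfig:
    block = dict(block)
    targets = [SelectionTarget(**t) for t in block.pop("selection_targets", [])]
    admix = [AdmixEvent(**e) for e in block.pop("admix_events", [])]
    block.setdefault("seed", seed)
    return SimConfig(selection_targets=targets, admix_events=admix, **block)


def load_input(config: RunConfig) -> GenotypePanel:
    if config.simulate is not None:
        panel, _ = simulate_panel(_sim_config(config.simulate, config.seed))
        return panel
    if config.plink_prefix is None:
        raise ValueError("config must provide plink_prefix or simulate block")
    prefix = config.plink_prefix
    pop_map = config.population_map
    if pop_map is not None and not Path(pop_map).exists():
        raise FileNotFoundError(f"population map not found: {pop_map}")
    if config.plink_binary:
        return read_plink_bed(
            f"{prefix}.bed", f"{prefix}.bim", f"{prefix}.fam", pop_map
        )
    return read_plink_text(f"{prefix}.ped", f"{prefix}.map", pop_map)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "package_version": __version__,
        "config": {
            k: v for k, v in config.__dict__.items() if not k.startswith("_")
        },
        "stages": {},
    }

    panel = load_input(config)
    manifest["input"] = {
        "n_individuals": panel.n_individuals,
        "n_snps": panel.n_snps,
        "populations": panel.populations,
    }

    def record(stage: str, t0: float, **info: Any) -> None:
        info["seconds"] = round(time.time() - t0, 3)
        manifest["stages"][stage] = info
        logger.info("stage %s: %s", stage, info)

    for stage in config.stages:
        t0 = time.time()
        try:
            if stage == "qc":
                panel, snp_rep = filter_snps(
                    panel,
                    maf_min=config.qc["maf_min"],
                    call_rate_min=config.qc["snp_call_rate_min"],
                )
                panel, ind_rep = filter_individuals(
                    panel, call_rate_min=config.qc["ind_call_rate_min"]
                )
                record(
                    stage,
                    t0,
                    snps_in=snp_rep.n_snps_in,
                    snps_out=snp_rep.n_snps_out,
                    individuals_in=ind_rep.n_individuals_in,
                    individuals_out=ind_rep.n_individuals_out,
                )
            elif stage == "diversity":
                table = diversity_table(panel)
                table.to_csv(out / "diversity.tsv", sep="\t", index=False)
                record(stage, t0, n_populations=len(table))
            elif stage == "ld_decay":
                auto = panel.autosomal()
                sub, _ = filter_snps(auto, maf_min=config.ld["maf_min"],
                                     call_rate_min=0.9)
                curves = {}
                for pop in sub.populations:
                    pairs = pairwise_r2(
                        sub.subset(populations=[pop]),
                        max_dist_kb=config.ld["max_dist_kb"],
                    )
                    curve = decay_curve(pairs, bin_width_kb=config.ld["bin_width_kb"])
                    curve.insert(0, "population", pop)
                    curves[pop] = r2_threshold_distance(
                        curve, threshold=config.ld["r2_threshold"]
                    )
                    curve.to_csv(
                        out / f"ld_decay_{pop}.tsv", sep="\t", index=False
                    )
                record(stage, t0, r2_threshold_distance_kb=curves)
            elif stage == "roh":
                auto = panel.autosomal()
                kept = ld_prune(auto, r2_max=config.roh["prune_r2"])
                pruned = auto.take_snps(
                    np.isin(np.array(auto.snp_ids, dtype=object), kept)
                )
                segs = detect_roh(
                    pruned,
                    window_snps=int(config.roh["window_snps"]),
                    max_het_per_window=int(config.roh["max_het_per_window"]),
                    max_missing_per_window=int(config.roh["max_missing_per_window"]),
                    min_length_kb=config.roh["min_length_kb"],
                    min_snps=int(config.roh["min_snps"]),
                    hit_fraction=config.roh["hit_fraction"],
                )
                roh_table(segs).to_csv(out / "roh_segments.tsv", sep="\t", index=False)
                accumulative_roh(segs, panel.individual_ids).to_csv(
                    out / "roh_per_individual.tsv", sep="\t", header=["total_bp"]
                )
                record(stage, t0, n_segments=len(segs), snps_after_prune=len(kept))
            elif stage == "fst":
                matrix = pairwise_fst_matrix(panel.autosomal())
                matrix.to_csv(out / "pairwise_fst.tsv", sep="\t")
                record(stage, t0, n_populations=len(matrix))
            elif stage == "scan":
                contrast = config.scan.get("contrast")
                kwargs = dict(
                    window_bp=int(config.scan["window_kb"] * 1000),
                    min_snps=int(config.scan["min_snps"]),
                    percentile=config.scan["percentile"],
                )
                if contrast:
                    result = group_contrast_scan(
                        panel,
                        focal=contrast["focal"],
                        background=contrast["background"],
                        **kwargs,
                    )
                    results = {"contrast": result}
                else:
                    results = breed_scan(panel, **kwargs)
                thresholds = {}
                for name, res in results.items():
                    res.window_table().to_csv(
                        out / f"scan_windows_{name}.tsv", sep="\t", index=False
                    )
                    res.region_table().to_csv(
                        out / f"scan_regions_{name}.tsv", sep="\t", index=False
                    )
                    thresholds[name] = res.threshold
                record(
                    stage,
                    t0,
                    thresholds=thresholds,
                    n_windows={k: len(v.windows) for k, v in results.items()},
                    n_called={k: len(v.called) for k, v in results.items()},
                )
            elif stage == "structure":
                kept = ld_prune(panel, r2_max=config.structure["prune_r2"])
                pruned = panel.take_snps(
                    np.isin(np.array(panel.snp_ids, dtype=object), kept)
                )
                n_comp = min(
                    int(config.structure["n_components"]),
                    pruned.n_individuals - 1,
                )
                res = pca(pruned, n_components=n_comp)
                import pandas as pd

                coords = pd.DataFrame(
                    res.coordinates,
                    columns=[f"PC{i + 1}" for i in range(n_comp)],
                )
                coords.insert(0, "population", res.populations)
                coords.insert(0, "individual", res.individual_ids)
                coords.to_csv(out / "pca.tsv", sep="\t", index=False)
                dist = ibs_distance_matrix(pruned)
                dist.to_phylip(out / "ibs_distance.phylip")
                tree = neighbor_joining(dist)
                write_newick(tree, out / "nj_tree.nwk")
                record(
                    stage,
                    t0,
                    snps_after_prune=len(kept),
                    pc1_variance_fraction=float(res.variance_fraction[0]),
                )
            elif stage == "dstat":
                if not config.dstat:
                    raise ValueError("dstat stage requires a dstat config block")
                table = allele_frequencies(
                    panel.autosomal(), list(config.dstat["quartet"])
                )
                res = d_statistic(
                    table, block_snps=int(config.dstat.get("block_snps", 300))
                )
                (out / "dstat.tsv").write_text(
                    "P1\tP2\tP3\tOutgroup\tD\tZ\tn_blocks\tn_snps\n"
                    + "\t".join(map(str, res.quartet))
                    + f"\t{res.d:.6f}\t{res.z:.3f}\t{res.n_blocks}\t{res.n_snps}\n"
                )
                record(stage, t0, d=res.d, z=res.z, n_blocks=res.n_blocks)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
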