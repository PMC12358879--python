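"""End-to-end pipeline stages writing tabular reports.

Each stage reads its inputs, runs the corresponding analysis module
and writes delimited-text reports plus a ``run_log.yaml`` recording
seed, package version and every parameter, so a run is reproducible
from its output directory alone.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, behavior, io, metabolomics, popgen, simulate
from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _write_log(cfg: PipelineConfig, out: Path) -> None:
    from dataclasses import fields

    data = {
        "version": __version__,
        **{
            f.name: (list(v) if isinstance(v := getattr(cfg, f.name), tuple) else v)
            for f in fields(cfg)
        },
    }
    (out / "run_log.yaml").write_text(yaml.safe_dump(data, sort_keys=False))


def _stage_behavior(cfg: PipelineConfig, out: Path) -> None:
    events = io.read_visit_events(cfg.events_path)
    roster = io.read_roster(cfg.roster_path)
    stats_frames, perm_frames = [], []
    for sex in sorted(roster["sex"].unique()):  # sexes analyzed separately
        ros = roster[roster["sex"] == sex]
        ev = events[events["animal"].isin(ros["animal"])]
        if ev.empty:
            continue
        st = behavior.first_n_proportion(
            ev, ros, cfg.K, cfg.onset, cfg.rewarded_corners
        )
        st.insert(0, "sex", sex)
        stats_frames.append(st)
        pm = behavior.shuffle_null_test(
            ev,
            ros,
            cfg.K,
            cfg.onset,
            cfg.rewarded_corners,
            B=cfg.B,
            seed=cfg.seed,
            family_m=cfg.bonferroni_family or None,
        )
        pm.insert(0, "sex", sex)
        pm["seed"] = cfg.seed
        perm_frames.append(pm)
    pd.concat(stats_frames).to_csv(out / "competition_stats.csv", index=False)
    pd.concat(perm_frames).to_csv(out / "permutation_tests.csv", index=False)


def _stage_metabolomics(cfg: PipelineConfig, out: Path) -> None:
    table = io.read_metabolite_table(cfg.metabolite_path)
    norm = metabolomics.upper_quartile_normalize(table)
    io.write_metabolite_table(norm, out / "normalized_table.csv")
    report = metabolomics.group_compare(norm)
    report.to_csv(out / "group_comparisons.csv", index=False)


def _stage_popgen(cfg: PipelineConfig, out: Path) -> None:
    region = cfg.region
    hap = io.read_haplotypes_vcf(cfg.vcf_path, region)
    windows = popgen.sliding_window_scan(hap, cfg.window_bp, cfg.step_bp)
    popgen.window_stats_frame(windows, hap.contig).to_csv(
        out / "window_stats.csv", index=False
    )
    if cfg.s:
        alpha, above = popgen.scaled_selection_coefficient(cfg.s, cfg.Ne)
        pd.DataFrame(
            [
                {
                    "s": cfg.s,
                    "Ne": cfg.Ne,
                    "alpha_2Nes": alpha,
                    "above_nearly_neutral_threshold": above,
                }
            ]
        ).to_csv(out / "selection_summary.csv", index=False)


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    roster = simulate.make_roster(n_cages=5)
    events = simulate.simulate_visit_stream(
        simulate.VisitSimParams(
            roster=roster, n_days=cfg.n_days, theta=cfg.theta, seed=cfg.seed
        )
    )
    io.write_roster(roster, out / "roster.csv")
    io.write_visit_events(events, out / "visit_events.csv")
    table = simulate.simulate_metabolite_table(
        simulate.MetaboliteSimParams(seed=cfg.seed)
    )
    io.write_metabolite_table(table, out / "metabolite_table.csv")
    hap = simulate.simulate_haplotypes_wf(
        N=100, n_sample=50, L=20_000, mu=5e-6, T=1_200, seed=cfg.seed
    )
    io.write_haplotypes_vcf(hap, out / "haplotypes.vcf")


_STAGES = {
    "behavior": _stage_behavior,
    "metabolomics": _stage_metabolomics,
    "popgen": _stage_popgen,
    "simulate": _stage_simulate,
}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run one stage end-to-end; returns the output directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _write_log(cfg, out)
    logger.info("running stage %s (seed=%d) -> %s", cfg.stage, cfg.seed, out)
    try:
        _STAGES[cfg.stage](cfg, out)
    except Exception:
        logger.exception("stage %s failed", cfg.stage)
        raise
    return out
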