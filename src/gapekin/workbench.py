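"""End-to-end pipeline orchestration.

Runs simulate -> correct -> segment -> kinetics -> histograms -> structure
from a single nested configuration, writes every intermediate as a
plain-text file, and records a run manifest (config hash, seeds, per-stage
outputs and record counts) so a rerun with the same config and seed is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as gio
from .histograms import peak_positions, per_state_histograms, snapshot_histogram
from .state_kinetics import (
    SegmentationModel,
    segment_states,
    summarize_kinetics,
)
from .structural_interpretation import FoersterModel, fret_to_distance, gaping_amplitude
from .synthetic_data import (
    CohortConfig,
    EmissionModel,
    SaltRule,
    calibrate_rate_matrix,
    ed28_mean_dwells,
    ed28_occupancies,
    simulate_cohort,
)
from .trace_correction import CorrectionParams, correct_trace

logger = logging.getLogger("gapekin")

__all__ = ["RunManifest", "run_pipeline", "build_cohort_config"]

STAGES = ("simulate", "correct", "segment", "kinetics", "histograms", "structure")


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_sha256: str
    seed: int
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, outputs: list[str], n_records: int) -> None:
        self.stages.append({"stage": name, "outputs": outputs, "n_records": n_records})

    def to_dict(self) -> dict:
        return {"config_sha256": self.config_sha256, "seed": self.seed, "stages": self.stages}


def _config_hash(config: dict) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def build_cohort_config(config: dict, seed: int | None = None) -> CohortConfig:
    """Translate the nested run configuration into a CohortConfig."""
    rates_cfg = config.get("rates", {})
    rm = calibrate_rate_matrix(
        rates_cfg.get("mean_dwells", ed28_mean_dwells()),
        rates_cfg.get("occupancies", ed28_occupancies()),
        rates_cfg.get("connectivity", "mid_centered"),
    )
    cohort_cfg = dict(config.get("cohort", {}))
    emission = EmissionModel(**config.get("emission", {}))
    salt_rule = None
    if "salt_rule" in config:
        sr = config["salt_rule"]
        salt_rule = SaltRule(
            reference_mM=sr.get("reference_mM", 50.0),
            exit_exponents=sr.get("exit_exponents", {}),
        )
    return CohortConfig(
        rate_matrix=rm,
        emission=emission,
        n_molecules=int(cohort_cfg.get("n_molecules", 1000)),
        duration=float(cohort_cfg.get("duration_s", 3000.0)),
        frame_period=float(cohort_cfg.get("frame_period_s", 0.5)),
        free_dna_fraction=float(cohort_cfg.get("free_dna_fraction", 0.0)),
        free_dna_fret=float(cohort_cfg.get("free_dna_fret", 0.10)),
        salt_mM=float(cohort_cfg.get("salt_mM", 50.0)),
        salt_rule=salt_rule,
        seed=int(cohort_cfg.get("seed", 0) if seed is None else seed),
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> RunManifest:
    """Execute the full simulate-to-structure pipeline.

    ``config`` is either a nested dict or the path of a YAML file with
    sections ``cohort``, ``rates``, ``emission``, ``correction``,
    ``segmentation``, ``histograms`` and ``structure`` (all optional —
    defaults reproduce the calibrated ED2.8 cohort).  Outputs land under
    ``out_dir``; the manifest is written as ``manifest.json``.
    """
    if not isinstance(config, dict):
        config = gio.load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort_config = build_cohort_config(config, seed=seed)
    manifest = RunManifest(config_sha256=_config_hash(config), seed=cohort_config.seed)

    # --- simulate -----------------------------------------------------
    logger.info("stage simulate: %d molecules", cohort_config.n_molecules)
    cohort = simulate_cohort(cohort_config)
    traces_dir = out / "traces"
    traces_dir.mkdir(exist_ok=True)
    trace_files = []
    for tr in cohort.traces:
        p = traces_dir / f"{tr.molecule_id}.tsv"
        gio.write_trace(tr, p)
        trace_files.append(str(p.relative_to(out)))
    manifest.add_stage("simulate", trace_files[:3] + ["..."], len(cohort))

    # --- correct ------------------------------------------------------
    corr_cfg = dict(config.get("correction", {}))
    default_bg = tuple(
        corr_cfg.pop(
            "default_background",
            (cohort_config.emission.background_donor,
             cohort_config.emission.background_acceptor),
        )
    )
    params = CorrectionParams(**corr_cfg)
    fret_dir = out / "fret"
    fret_dir.mkdir(exist_ok=True)
    fret_traces = []
    n_degenerate = 0
    for tr in cohort.traces:
        try:
            ft = correct_trace(tr, params, default_background=default_bg)
        except Exception as exc:  # stage context for the failing molecule
            raise RuntimeError(f"stage correct failed on {tr.molecule_id}: {exc}") from exc
        if ft.degenerate:
            n_degenerate += 1
            continue
        fret_traces.append(ft)
        gio.write_fret_trace(ft, fret_dir / f"{ft.molecule_id}.tsv")
    if n_degenerate:
        logger.warning("stage correct: %d degenerate traces excluded", n_degenerate)
    manifest.add_stage("correct", [str(fret_dir.relative_to(out))], len(fret_traces))

    # --- segment ------------------------------------------------------
    seg_cfg = dict(config.get("segmentation", {}))
    if "state_means" not in seg_cfg:
        seg_cfg["state_means"] = dict(cohort_config.emission.state_fret) \
            if "free_dna" not in cohort_config.emission.state_fret else None
        if seg_cfg["state_means"] is None:
            seg_cfg.pop("state_means")
    model = SegmentationModel(**seg_cfg)
    dwell_tables = []
    for ft in fret_traces:
        try:
            dwell_tables.append(segment_states(ft, model))
        except Exception as exc:
            raise RuntimeError(f"stage segment failed on {ft.molecule_id}: {exc}") from exc
    all_dwells = [d for t in dwell_tables for d in t]
    dwell_path = out / "dwells.tsv"
    gio.write_dwells(all_dwells, dwell_path)
    manifest.add_stage("segment", [dwell_path.name], len(all_dwells))

    # --- kinetics -----------------------------------------------------
    kin_cfg = config.get("kinetics", {})
    summary = summarize_kinetics(
        all_dwells,
        condition=f"{cohort_config.salt_mM:g}mM",
        fit_states=tuple(kin_cfg.get("fit_states", ["high"])),
        n_boot=int(kin_cfg.get("n_boot", 1000)),
        seed=cohort_config.seed,
    )
    kin_path = out / "kinetics.json"
    kin_path.write_text(json.dumps(_summary_dict(summary), indent=2) + "\n")
    manifest.add_stage("kinetics", [kin_path.name], len(summary.states))

    # --- histograms ---------------------------------------------------
    hist_cfg = config.get("histograms", {})
    bin_width = float(hist_cfg.get("bin_width", 0.02))
    state_hists = per_state_histograms(fret_traces, dwell_tables, bin_width=bin_width)
    hist_files = []
    for state, h in state_hists.items():
        p = out / f"hist_{state}.tsv"
        _write_histogram(h, p)
        hist_files.append(p.name)
    snap = snapshot_histogram(
        fret_traces,
        window_frames=int(hist_cfg.get("window_frames", 10)),
        bin_width=bin_width,
        seed=cohort_config.seed,
    )
    snap_path = out / "hist_snapshot.tsv"
    _write_histogram(snap, snap_path)
    hist_files.append(snap_path.name)
    manifest.add_stage("histograms", hist_files, len(hist_files))

    # --- structure ----------------------------------------------------
    foerster = FoersterModel(**config.get("structure", {}))
    state_e = {
        state: peak_positions(h, 1)[0][0]
        for state, h in state_hists.items()
        if h.mass > 0
    }
    distances = {s: fret_to_distance(e, foerster) for s, e in state_e.items()}
    adjacent, extreme = gaping_amplitude(state_e, foerster) if len(state_e) >= 2 else ({}, 0.0)
    struct_path = out / "structure.json"
    struct_path.write_text(
        json.dumps(
            {
                "r0_nm": foerster.r0_nm,
                "state_fret": state_e,
                "distance_nm": distances,
                "adjacent_dr_nm": {f"{a}->{b}": v for (a, b), v in adjacent.items()},
                "extreme_dr_nm": extreme,
            },
            indent=2,
        )
        + "\n"
    )
    manifest.add_stage("structure", [struct_path.name], len(distances))

    gio.write_manifest(manifest.to_dict(), out / "manifest.json")
    return manifest


def _summary_dict(summary) -> dict:
    out: dict[str, Any] = {"condition": summary.condition, "states": {}}
    for state, k in summary.states.items():
        entry = {
            "mean_dwell_s": k.mean_dwell_s,
            "occupancy": k.occupancy,
            "n_dwells": k.n_dwells,
            "n_exits": k.n_exits,
        }
        if k.lifetime is not None:
            entry["lifetime_cdf_fit_s"] = k.lifetime.tau_s
            entry["lifetime_cdf_fit_se_s"] = k.lifetime.se_s
            entry["lifetime_mle_s"] = k.lifetime.tau_mle_s
            entry["lifetime_mle_se_s"] = k.lifetime.se_mle_s
        out["states"][state] = entry
    return out


def _write_histogram(hist, path: Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "bin_left": hist.edges[:-1],
            "bin_right": hist.edges[1:],
            "fraction": hist.fractions,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
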