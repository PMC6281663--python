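"""End-to-end orchestration: simulate → preprocess → decompose → assign → correlate.

A :class:`PipelineConfig` carries one input mode (synthetic generator
configuration, a spike-table path, or a response-matrix path) plus every
stage parameter with its standard default.  :func:`run_pipeline` executes
the stages in order, writes each artifact (CSV/JSON) before the final
report, and returns the report as a dict.  When a response matrix is
supplied directly, the screening/filtering and the trial-level correlation
stages are skipped and noted in the report.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assignment as asg
from . import correlations as corr
from . import nnmf
from . import preprocessing as prep
from . import synthetic as syn


@dataclass
class PipelineConfig:
    """Input mode plus all stage parameters (defaults are the standard ones)."""

    # exactly one input mode
    synthetic: syn.SyntheticConfig | None = None
    spike_table: str | None = None
    response_matrix: str | None = None

    sigma_ms: float = 40.0
    grid_step_ms: float = 8.0
    activity_threshold: float = 1.26
    k_min: int = 2
    k_max: int = 10
    runs: int = 100
    bootstrap_iters: int = 50
    history_len: int = 15
    cosine_threshold: float = 0.5
    variability_cutoff: float = 0.05
    alpha: float = 0.05
    inner_max_iter: int = 200
    n_jobs: int = 1
    out_dir: str = "taskphase_run"
    seed: int = 0
    verbose: bool = True


def validate_config(config: PipelineConfig) -> list[str]:
    """Check every config invariant; return the list of violations (empty = ok)."""
    v = []
    modes = [m for m in (config.synthetic, config.spike_table, config.response_matrix)
             if m is not None]
    if len(modes) != 1:
        v.append("exactly one input mode (synthetic | spike_table | response_matrix) required")
    if config.sigma_ms <= 0:
        v.append("sigma_ms must be > 0")
    if config.grid_step_ms != 8.0:
        v.append("grid_step_ms must be 8 (251 samples per condition)")
    if config.k_min < 2:
        v.append("k_min must be >= 2")
    if config.k_max < config.k_min:
        v.append("k_max must be >= k_min")
    if config.runs < 1:
        v.append("runs must be >= 1")
    if config.bootstrap_iters < config.history_len:
        v.append("bootstrap_iters must be >= history_len")
    if not 0 < config.cosine_threshold < 1:
        v.append("cosine_threshold must be in (0, 1)")
    if not 0 < config.variability_cutoff:
        v.append("variability_cutoff must be > 0")
    if not 0 < config.alpha < 1:
        v.append("alpha must be in (0, 1)")
    if config.activity_threshold < 0:
        v.append("activity_threshold must be >= 0")
    if config.synthetic is not None:
        try:
            config.synthetic.validate()
        except syn.ConfigurationError as exc:
            v.append(str(exc))
    return v


def _log(config: PipelineConfig, stage: str, msg: str) -> None:
    if config.verbose:
        stamp = time.strftime("%H:%M:%S")
        print(f"[{stamp}] [{stage}] {msg}", file=sys.stderr, flush=True)


def _config_echo(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write artifacts under ``config.out_dir``.

    Returns the run report (also written as ``report.json``).
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid pipeline config: " + "; ".join(violations))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": _config_echo(config), "stages": [], "notices": []}

    # --- input stage -------------------------------------------------------
    spikes = None
    truth = None
    if config.response_matrix is not None:
        _log(config, "input", f"reading response matrix {config.response_matrix}")
        matrix = prep.read_response_matrix(config.response_matrix)
        report["notices"].append(
            "response-matrix input: screening/filtering skipped; correlation "
            "stages skipped (no trial-level data)")
        pre = None
    else:
        if config.synthetic is not None:
            _log(config, "simulate", "sampling synthetic population")
            spikes, truth = syn.sample_population(config.synthetic)
            syn.write_spike_table(spikes, out / "spikes.csv")
            syn.write_ground_truth(truth, out / "ground_truth_units.csv",
                                   out / "ground_truth_config.yaml")
            report["stages"].append("simulate")
        else:
            _log(config, "input", f"reading spike table {config.spike_table}")
            spikes = syn.read_spike_table(config.spike_table)
        _log(config, "preprocess", "screening, filtering, building response matrix")
        pre = prep.preprocess(spikes, sigma_ms=config.sigma_ms,
                              threshold=config.activity_threshold, alpha=config.alpha)
        matrix = pre["response_matrix"]
        pre["screen"].to_csv(out / "selectivity_screen.csv", index=False)
        prep.write_response_matrix(matrix, out / "response_matrix.csv")
        pd.DataFrame(pre["retained_units"],
                     columns=["session_id", "unit_id"]).to_csv(
            out / "unit_map.csv", index=False)
        report["stages"].append("preprocess")
        report["n_units_total"] = int(
            spikes[["session_id", "unit_id"]].drop_duplicates().shape[0])
        report["n_selective"] = int(pre["screen"]["selective"].sum())
        report["n_retained"] = matrix.n_units

    # --- decomposition -----------------------------------------------------
    _log(config, "decompose",
         f"K selection over [{config.k_min}, {config.k_max}], {config.runs} runs each")
    selection = nnmf.select_k(
        matrix.R,
        k_range=range(config.k_min, config.k_max + 1),
        runs=config.runs,
        variability_cutoff=config.variability_cutoff,
        seed=config.seed,
        n_jobs=config.n_jobs,
        n_bootstrap=config.bootstrap_iters,
        history_len=config.history_len,
        cosine_threshold=config.cosine_threshold,
        inner_max_iter=config.inner_max_iter,
    )
    fact = selection.factorization
    explained, residual = nnmf.energy_decomposition(matrix.R, fact)
    np.savetxt(out / "W.csv", fact.W, delimiter=",")
    np.savetxt(out / "H.csv", fact.H, delimiter=",")
    nnmf_report = {
        "selected_k": selection.selected_k,
        "explained_energy": explained,
        "residual_energy": residual,
        "median_variability_by_k": {str(k): v for k, v in selection.median_by_k.items()},
        "min_residual_by_k": {str(k): v for k, v in selection.residual_by_k.items()},
        "seed": config.seed,
    }
    (out / "nnmf_report.json").write_text(json.dumps(nnmf_report, indent=2))
    report["stages"].append("decompose")
    report["selected_k"] = selection.selected_k
    report["explained_energy"] = explained
    report["residual_energy"] = residual

    # --- assignment --------------------------------------------------------
    _log(config, "assign", "assigning units to CRPs")
    assignments, excluded = asg.assign_units(matrix, fact.W)
    chron = asg.chronological_ranks(fact.W)
    assignments["chron_rank"] = [chron.rank_of(k) for k in assignments["crp_index"]]
    if pre is not None:
        pafs = asg.pa_fs_table(assignments, pre["second_half_counts"],
                               alpha=config.alpha)
        summary = asg.per_crp_summary(assignments, pafs, chron)
        assignments = assignments.merge(pafs, on=["session_id", "unit_id"])
        summary.to_csv(out / "per_crp_summary.csv", index=False)
        report["per_crp_unit_counts"] = dict(
            zip(summary["chron_rank"].astype(str), summary["n_units"]))
        report["per_crp_same_fraction"] = dict(
            zip(summary["chron_rank"].astype(str), summary["same_fraction"]))
    assignments.to_csv(out / "assignments.csv", index=False)
    order, images = asg.sort_units_by_peak(matrix)
    for cond, img in images.items():
        np.savetxt(out / f"peak_sorted_{cond}.csv", img, delimiter=",")
    report["stages"].append("assign")
    report["n_unassignable"] = len(excluded)

    # --- correlations ------------------------------------------------------
    if pre is not None:
        _log(config, "correlate", "computing pair records and group statistics")
        labels = _unit_labels(assignments, pre["screen"])
        group_report: dict = {}
        pair_frames = []
        for scope in ("all", "PA", "FS"):
            pairs = corr.build_pair_records(pre["full_counts"], labels, scope=scope)
            pairs = corr.attach_crp_ranks(pairs, labels)
            pair_frames.append(pairs)
            td_groups, td_matrix = corr.temporal_distance_groups(
                pairs, n_crps=fact.K)
            if scope == "all" and td_matrix.size:
                np.savetxt(out / "mean_rsc_by_rank.csv", td_matrix, delimiter=",")
            group_report[scope] = {
                "temporal_distance": {k: g.to_dict() for k, g in td_groups.items()},
                "sign_split": {
                    sign: {k: g.to_dict() for k, g in groups.items()}
                    for sign, groups in corr.sign_split_stats(pairs).items()
                },
                "segregation": {
                    k: g.to_dict() for k, g in corr.segregation_stats(pairs).items()
                },
            }
        pd.concat(pair_frames, ignore_index=True).to_csv(
            out / "pair_records.csv", index=False)
        (out / "group_stats.json").write_text(json.dumps(group_report, indent=2))
        report["stages"].append("correlate")
        report["group_stats"] = group_report

    report["software_version"] = _version()
    (out / "report.json").write_text(json.dumps(report, indent=2))
    _log(config, "done", f"artifacts in {out}")
    return report


def _unit_labels(assignments: pd.DataFrame, screen: pd.DataFrame) -> pd.DataFrame:
    """Label table for the correlation stage: CRP units + selective units."""
    crp = assignments[["session_id", "unit_id", "chron_rank"]].copy()
    crp["population"] = "crp"
    crp["pref_stimulus"] = ""
    stim = screen[screen["selective"]][
        ["session_id", "unit_id", "pref_stimulus"]].copy()
    stim["population"] = "stim"
    stim["chron_rank"] = -1
    return pd.concat([crp, stim], ignore_index=True)


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("taskphase")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"
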