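"""End-to-end pipeline: simulate (or load) a cohort, preprocess, epoch,
compute ITC/TLI and learning curves, and run the group statistics.

The configuration is a nested mapping (usually loaded from YAML) with
one section per stage; unknown sections or keys are rejected and every
run report embeds the fully resolved configuration and all seeds, so a
rerun with the same config reproduces the same numbers.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .design import SequenceSpec, TONE_RATE, TRIPLET_RATE
from .epochs import standard_epochs
from .learning import group_mean_fit, sliding_tli
from .preprocess import PreprocConfig, preprocess
from .simulate import EffectSpec, Recording, simulate_cohort
from .spectral import compute_itc, exact_bin, peak_vs_neighbors, subject_tli
from .stats import (brain_behavior_correlation, cluster_permutation,
                    group_ttest)

DEFAULT_CONFIG: dict = {
    "sequence": {
        "n_blocks": 6, "triplets_per_block": 400,
        "p_statistical": 0.08, "p_acoustic": 0.18, "p_double": 0.02,
        "targets_per_block": 8, "counterbalance_id": 0,
    },
    "simulation": {
        "n_control": 19, "n_dyslexia": 17,
        "d": 0.64, "rho": 0.35, "rho_reading": 0.0, "tone_gap": 0.3,
        "srate": 500.0, "seed": 0,
    },
    "preprocessing": {
        "bad_channel_z": 3.0, "hp_cutoff": 0.2, "hp_transition": 0.4,
        "lp_cutoff": 30.0, "lp_transition": 5.0,
        "max_passband_deviation": 0.001,
    },
    "epoching": {"p2p_threshold": 300.0, "triplets_per_epoch": 6},
    "spectral": {"itc_mode": "standard"},
    "learning_curve": {"window_epochs": 30, "x_convention": "retained"},
    "stats": {"n_perm": 1000, "alpha_pointwise": 0.05,
              "min_cluster_len": 2, "seed": 0},
    "output": {"dir": None},
}


def default_config(mini: bool = False) -> dict:
    """The full-scale default configuration (the study design); ``mini=True`` scales
    the run down to a desk-sized smoke configuration (2 short blocks,
    8+8 subjects, 100 Hz, 3-epoch windows)."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if mini:
        cfg["sequence"].update({"n_blocks": 2, "triplets_per_block": 90})
        cfg["simulation"].update({"n_control": 8, "n_dyslexia": 8,
                                  "srate": 100.0})
        cfg["learning_curve"]["window_epochs"] = 3
        cfg["stats"]["n_perm"] = 500
    return cfg


def validate_config(config: dict) -> list[str]:
    """Exhaustive validation; returns a list of error messages (empty
    when the config is acceptable)."""
    errors: list[str] = []
    if not isinstance(config, dict):
        return ["config must be a mapping"]
    for section in DEFAULT_CONFIG:
        if section not in config:
            errors.append(f"missing section: {section}")
    for section, content in config.items():
        if section not in DEFAULT_CONFIG:
            errors.append(f"unknown section: {section}")
            continue
        if not isinstance(content, dict):
            errors.append(f"section {section} must be a mapping")
            continue
        for key in content:
            if key not in DEFAULT_CONFIG[section]:
                errors.append(f"unknown key {section}.{key}")
    if errors:
        return errors

    seq, sim = config["sequence"], config["simulation"]
    pre, st = config["preprocessing"], config["stats"]
    try:
        SequenceSpec(
            n_blocks=seq["n_blocks"],
            triplets_per_block=seq["triplets_per_block"],
            p_statistical=seq["p_statistical"], p_acoustic=seq["p_acoustic"],
            p_double=seq["p_double"], targets_per_block=seq["targets_per_block"],
            counterbalance_id=seq["counterbalance_id"],
        ).validate()
    except ValueError as e:
        errors.append(f"sequence: {e}")
    if sim["n_control"] < 2 or sim["n_dyslexia"] < 2:
        errors.append("simulation: need >= 2 subjects per group")
    try:
        PreprocConfig(
            bad_channel_z=pre["bad_channel_z"], hp_cutoff=pre["hp_cutoff"],
            hp_transition=pre["hp_transition"], lp_cutoff=pre["lp_cutoff"],
            lp_transition=pre["lp_transition"],
            max_passband_deviation=pre["max_passband_deviation"],
        ).validate(sim["srate"])
    except ValueError as e:
        errors.append(f"preprocessing: {e}")
    if config["epoching"]["p2p_threshold"] <= 0:
        errors.append("epoching: p2p_threshold must be > 0")
    if config["spectral"]["itc_mode"] not in ("standard", "complex-average"):
        errors.append("spectral: itc_mode must be standard or complex-average")
    if config["learning_curve"]["window_epochs"] < 1:
        errors.append("learning_curve: window_epochs must be >= 1")
    if config["learning_curve"]["x_convention"] not in ("retained",
                                                        "presented"):
        errors.append("learning_curve: unknown x_convention")
    if st["n_perm"] < 1:
        errors.append("stats: n_perm must be >= 1")
    if not 0 < st["alpha_pointwise"] < 1:
        errors.append("stats: alpha_pointwise must be in (0, 1)")
    if st["min_cluster_len"] < 1:
        errors.append("stats: min_cluster_len must be >= 1")
    return errors


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def analyze_subject(recording: Recording, config: dict) -> dict:
    """Run one subject from continuous data to TLI and learning curve."""
    pre_cfg = PreprocConfig(**config["preprocessing"])
    rec, pre_log = preprocess(recording, pre_cfg)
    eps, epoch_log = standard_epochs(
        rec, cluster=True,
        threshold=config["epoching"]["p2p_threshold"],
        triplets_per_epoch=config["epoching"]["triplets_per_epoch"])
    spectrum = compute_itc(eps, mode=config["spectral"]["itc_mode"])
    tli = subject_tli(spectrum, subject_id=recording.subject_id)

    first = int(np.min(eps.blocks))
    first_eps = eps.select(eps.blocks == first)
    curve = None
    w = config["learning_curve"]["window_epochs"]
    if first_eps.n_epochs >= w:
        curve = sliding_tli(first_eps, window_epochs=w,
                            x_convention=config["learning_curve"]
                            ["x_convention"],
                            subject_id=recording.subject_id)
    return {"subject_id": recording.subject_id, "tli": tli,
            "spectrum": spectrum, "curve": curve,
            "preproc_log": pre_log, "epoch_log": epoch_log}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def run_pipeline(config: dict, write: bool = True) -> dict:
    """Simulate a cohort under ``config`` and produce the full report:
    per-subject TLI, peak-vs-control-bin tests per group and rate, group
    comparisons of ITC and TLI, the cluster-based permutation test on
    the TLI time courses, group log-fits, and the three brain-behavior
    correlations."""
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    seq, sim = config["sequence"], config["simulation"]
    spec = SequenceSpec(
        n_blocks=seq["n_blocks"], triplets_per_block=seq["triplets_per_block"],
        p_statistical=seq["p_statistical"], p_acoustic=seq["p_acoustic"],
        p_double=seq["p_double"], targets_per_block=seq["targets_per_block"],
        counterbalance_id=seq["counterbalance_id"])
    effect = EffectSpec(d=sim["d"], rho=sim["rho"],
                        rho_reading=sim["rho_reading"],
                        tone_gap=sim["tone_gap"])
    cohort = simulate_cohort(sim["n_control"], sim["n_dyslexia"],
                             effect=effect, seed=sim["seed"],
                             sequence_spec=spec, srate=sim["srate"])

    results = [analyze_subject(rec, config) for rec in cohort.recordings]
    groups = np.array([p.group for p in cohort.profiles])
    report = cohort_statistics(results, groups, cohort.behavior, config)

    report = _jsonable(report)
    out_dir = config["output"]["dir"]
    if write and out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
    return report


def cohort_statistics(results: list[dict], groups, behavior,
                      config: dict) -> dict:
    """Cohort-level statistics from per-subject :func:`analyze_subject`
    results plus the behavioral table (needs z-scored score columns)."""
    groups = np.asarray(groups)
    tli = np.array([r["tli"].tli for r in results])
    itc_tone = np.array([r["tli"].itc_tone for r in results])
    itc_tri = np.array([r["tli"].itc_triplet for r in results])
    spectra = np.stack([r["spectrum"].itc[0] for r in results])
    ep_len = results[0]["spectrum"].epoch_length
    ctrl, dys = groups == "control", groups == "dyslexia"

    report: dict = {
        "software": {"package": "tripletlearn", "version": __version__},
        "config": copy.deepcopy(config),
        "rates": {"tone_hz": TONE_RATE, "triplet_hz": TRIPLET_RATE,
                  "bin_tone": exact_bin(ep_len, TONE_RATE),
                  "bin_triplet": exact_bin(ep_len, TRIPLET_RATE)},
        "subjects": [{
            "subject_id": r["subject_id"],
            "group": g,
            "tli": r["tli"].tli,
            "itc_tone": r["tli"].itc_tone,
            "itc_triplet": r["tli"].itc_triplet,
            "n_epochs_by_block": r["tli"].n_epochs_by_block,
            "epochs_rejected": r["epoch_log"]["n_epochs_rejected"],
            "log_fit": asdict(r["curve"].fit)
            if r["curve"] is not None and r["curve"].fit else None,
        } for r, g in zip(results, groups)],
    }

    peak = {}
    for gname, gmask in (("control", ctrl), ("dyslexia", dys)):
        peak[gname] = {}
        for rname, rate in (("tone", TONE_RATE), ("triplet", TRIPLET_RATE)):
            pt = peak_vs_neighbors(spectra[gmask], ep_len, rate)
            peak[gname][rname] = {
                "t": pt.t, "df": pt.df, "p": pt.p, "d": pt.d,
                "peak_freq": pt.peak_freq,
                "control_freqs": list(pt.control_freqs)}
    report["peak_vs_control_bins"] = peak

    report["group_tests"] = {
        "itc_tone_two_sided": asdict(group_ttest(
            itc_tone[ctrl], itc_tone[dys], alternative="two-sided")),
        "itc_triplet_two_sided": asdict(group_ttest(
            itc_tri[ctrl], itc_tri[dys], alternative="two-sided")),
        "tli_one_sided_control_gt_dyslexia": asdict(group_ttest(
            tli[ctrl], tli[dys], alternative="greater")),
    }

    curves = [r["curve"] for r in results]
    if all(c is not None for c in curves):
        n_common = min(len(c.tli) for c in curves)
        if n_common >= max(2, config["stats"]["min_cluster_len"]):
            X = np.stack([c.tli[:n_common] for c in curves])
            ct = cluster_permutation(
                X, groups, n_perm=config["stats"]["n_perm"],
                alpha=config["stats"]["alpha_pointwise"],
                min_len=config["stats"]["min_cluster_len"],
                seed=config["stats"]["seed"])
            report["cluster_test"] = {
                "n_timepoints": n_common,
                "clusters": [asdict(c) for c in ct.clusters],
                "n_permutations": ct.n_permutations,
            }
        else:
            report["cluster_test"] = {"skipped":
                                      "common time course too short"}
        try:
            report["group_log_fits"] = {
                "control": asdict(group_mean_fit(
                    [c for c, m in zip(curves, ctrl) if m])),
                "dyslexia": asdict(group_mean_fit(
                    [c for c, m in zip(curves, dys) if m])),
            }
        except ValueError as e:
            report["group_log_fits"] = {"skipped": str(e)}
    else:
        report["cluster_test"] = {
            "skipped": "some subjects lack enough epochs for one window"}
        report["group_log_fits"] = {"skipped": "missing learning curves"}

    report["brain_behavior"] = {
        name: asdict(brain_behavior_correlation(
            tli, behavior[name + "_z"].to_numpy()))
        for name in ("spelling", "reading_speed", "reading_comprehension")
    }
    report["behavior_table"] = behavior.drop(
        columns=["latent_trait"], errors="ignore").to_dict(orient="list")
    return report
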