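"""End-to-end orchestration: simulate/ingest -> preprocess -> connectivity
-> NBS -> classify -> report.

A single nested config (YAML on disk, plain dict in memory) drives every
stage. The master seed fans out to per-stage seeds through a stable hash,
so adding or reordering stages never shifts another stage's random
stream, and a full run is bit-reproducible: re-running with the same
config yields identical artifact checksums.

NBS edge selection and SVM tuning see discovery-cohort epochs only; the
testing cohort is scored once with the frozen model.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from vnsnet import classifier as clf_mod
from vnsnet import connectivity, nbs, preprocessing, synthetic
from vnsnet.montage import CHANNELS, N_EDGES, edge_labels

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "input": {"mode": "synthetic", "edf_dir": None, "manifest": None},
    "synthetic": {
        "n_responders": 15,
        "n_nonresponders": 8,
        "epochs_per_patient": [4, 20],
        "sampling_rate": 1000,
        "epoch_seconds": 60,
        "within_second_noise_sd": 1.0,
        "effect_size": 0.4,
    },
    "preprocessing": {
        "epoch_seconds": 60,
        "target_epochs": 56,
        "n_discovery_responders": 10,
        "n_discovery_nonresponders": 6,
    },
    "connectivity": {
        "bandwidth": None,  # null -> n^(1/3)
        "lambda": 0.1,
        "centering": "epoch_mean",
    },
    "nbs": {
        "thresholds": [0.05, 0.01, 0.005, 0.001],
        "n_permutations": 5000,
        "unit": "epoch",
        "alpha": 0.05,
    },
    "classifier": {
        # coarse default grid keeps a full run tractable; widen per study
        "costs": [0.125, 1.0, 8.0, 64.0],
        "gammas": [2.0**-9, 2.0**-5, 2.0**-1],
        "n_folds": 5,
        "fold_unit": "epoch",
        "standardize": True,
    },
}


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _merge_strict(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, value in (override or {}).items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown config key: {where}")
        if isinstance(defaults[key], dict) and not isinstance(value, dict) and value is not None:
            raise ValueError(f"config key {where} must be a mapping")
        if isinstance(defaults[key], dict):
            out[key] = _merge_strict(defaults[key], value or {}, where)
        else:
            out[key] = value
    return out


def _validate(config: dict) -> dict:
    for t in config["nbs"]["thresholds"]:
        if not 0 < t < 1:
            raise ValueError(f"nbs.thresholds entry {t} outside (0, 1)")
    if config["connectivity"]["centering"] not in connectivity.CENTERINGS:
        raise ValueError("connectivity.centering invalid")
    if config["connectivity"]["lambda"] < 0:
        raise ValueError("connectivity.lambda must be nonnegative")
    if config["input"]["mode"] not in ("synthetic", "edf"):
        raise ValueError("input.mode must be 'synthetic' or 'edf'")
    if config["input"]["mode"] == "edf":
        for key in ("edf_dir", "manifest"):
            path = config["input"][key]
            if path is None or not Path(path).exists():
                raise ValueError(f"input.{key} must exist in edf mode")
    return config


def make_config(override: dict | None = None) -> dict:
    """Defaults merged with ``override``; unknown keys are errors."""
    return _validate(_merge_strict(DEFAULT_CONFIG, override or {}))


def load_config(path) -> dict:
    """Load, default-fill and validate a YAML pipeline config."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return make_config(data)


def dump_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# stages


def _gather_epochs(config: dict):
    """Input stage: per-patient epoch matrices + manifest (memory-lean)."""
    seed = config["seed"]
    mode = config["input"]["mode"]
    epoch_seconds = config["preprocessing"]["epoch_seconds"]
    epochs_by_patient: dict[str, list] = {}
    ground_truth = None
    if mode == "synthetic":
        syn = config["synthetic"]
        cohort_spec = synthetic.CohortSpec(
            n_responders=syn["n_responders"],
            n_nonresponders=syn["n_nonresponders"],
            epochs_per_patient=tuple(syn["epochs_per_patient"]),
            sampling_rate=syn["sampling_rate"],
            epoch_seconds=syn["epoch_seconds"],
            within_second_noise_sd=syn["within_second_noise_sd"],
            seed=stage_seed(seed, "simulate"),
        )
        network_spec = synthetic.default_network_spec(effect_size=syn["effect_size"])
        manifest, plans, ground_truth = synthetic.plan_cohort(cohort_spec, network_spec)
        labels = dict(zip(manifest["patient_id"], manifest["label"]))
        for rec in synthetic.iter_recordings(cohort_spec, plans):
            epochs_by_patient[rec.patient_id] = preprocessing.epochs_from_recording(
                rec, labels[rec.patient_id], epoch_seconds
            )
    else:
        manifest = pd.read_csv(config["input"]["manifest"])
        edf_dir = Path(config["input"]["edf_dir"])
        for _, row in manifest.iterrows():
            fname = row.get("edf", f"{row['patient_id']}.edf")
            rec = preprocessing.load_recording(edf_dir / fname, row["patient_id"])
            epochs_by_patient[row["patient_id"]] = preprocessing.epochs_from_recording(
                rec, row["label"], epoch_seconds
            )
    return manifest, epochs_by_patient, ground_truth


def _preprocess(config: dict, manifest, epochs_by_patient):
    pre = config["preprocessing"]
    seed = config["seed"]
    assignment = preprocessing.assign_cohorts(
        manifest,
        pre["n_discovery_responders"],
        pre["n_discovery_nonresponders"],
        seed=stage_seed(seed, "cohorts"),
    )
    n_raw = sum(len(v) for v in epochs_by_patient.values())
    augmented = {
        pid: preprocessing.bootstrap_augment(
            eps, pre["target_epochs"], seed=stage_seed(seed, f"bootstrap:{pid}")
        )
        for pid, eps in epochs_by_patient.items()
    }
    return assignment, augmented, n_raw


def run_pipeline(config: dict, outdir) -> dict:
    """Execute every stage and write all artifacts; returns the RunRecord."""
    config = _validate(_merge_strict(DEFAULT_CONFIG, config)) if config else make_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    record: dict = {"config": copy.deepcopy(config), "timings": {}, "counts": {}}
    t0 = time.time()

    def _stage_done(name):
        record["timings"][name] = round(time.time() - t0, 3)

    manifest, epochs_by_patient, ground_truth = _gather_epochs(config)
    _stage_done("input")
    assignment, augmented, n_raw = _preprocess(config, manifest, epochs_by_patient)
    _stage_done("preprocess")

    all_epochs = [e for pid in sorted(augmented) for e in augmented[pid]]
    conn = config["connectivity"]
    features = connectivity.connectivity_pipeline(
        all_epochs, h=conn["bandwidth"], lam=conn["lambda"], centering=conn["centering"]
    )
    features["cohort"] = [assignment.cohort_of(p) for p in features["patient_id"]]
    _stage_done("connectivity")

    edge_cols = [c for c in features.columns if "-" in c]
    disc = features[features["cohort"] == "discovery"]
    test = features[features["cohort"] == "testing"]
    record["counts"] = {
        "n_patients": int(len(manifest)),
        "n_raw_epochs": int(n_raw),
        "n_epochs_total": int(len(features)),
        "n_discovery_epochs": int(len(disc)),
        "n_testing_epochs": int(len(test)),
        "n_discovery_responder_epochs": int((disc["label"] == "responder").sum()),
        "n_discovery_nonresponder_epochs": int((disc["label"] == "nonresponder").sum()),
        "n_testing_responder_epochs": int((test["label"] == "responder").sum()),
        "n_testing_nonresponder_epochs": int((test["label"] == "nonresponder").sum()),
        "n_edges": len(edge_cols),
    }

    nbs_cfg = config["nbs"]
    disc_X = disc[edge_cols].to_numpy(float)
    nbs_results = {}
    for thr in nbs_cfg["thresholds"]:
        nbs_results[thr] = nbs.nbs_fwe_test(
            disc_X,
            disc["label"].to_numpy(),
            threshold=thr,
            n_perm=nbs_cfg["n_permutations"],
            unit=nbs_cfg["unit"],
            patient_ids=disc["patient_id"].to_numpy(),
            seed=stage_seed(config["seed"], f"nbs:{thr}"),
            alpha=nbs_cfg["alpha"],
        )
    primary = nbs_results[nbs_cfg["thresholds"][0]]
    selected = primary.selected_edges
    fallback = False
    if not selected:
        fallback = True
        stats_ = nbs.edgewise_glm_stats(disc_X, disc["label"].to_numpy())
        selected = nbs.suprathreshold_graph(stats_, nbs_cfg["thresholds"][0]).edges
        logger.warning(
            "no FWE-significant component; falling back to %d suprathreshold edges",
            len(selected),
        )
    if not selected:
        raise RuntimeError("NBS stage selected no edges at all; nothing to classify")
    labels_all = edge_labels()
    from vnsnet.montage import edge_index

    selected_cols = [labels_all[edge_index(i, j)] for i, j in selected]
    _stage_done("nbs")

    cls_cfg = config["classifier"]
    grid = clf_mod.GridSpec(
        costs=tuple(cls_cfg["costs"]),
        gammas=tuple(cls_cfg["gammas"]),
        n_folds=cls_cfg["n_folds"],
        fold_unit=cls_cfg["fold_unit"],
        seed=stage_seed(config["seed"], "folds"),
    )
    Xd = disc[selected_cols].to_numpy(float)
    yd = disc["label"].to_numpy()
    cost, gamma, grid_table = clf_mod.grid_search_svm(
        Xd, yd, grid, patient_ids=disc["patient_id"].to_numpy()
    )
    model = clf_mod.train_svm(
        Xd, yd, cost, gamma, feature_names=selected_cols,
        standardize=cls_cfg["standardize"],
    )
    # calibrate the operating cutoff on out-of-fold discovery scores
    folds = clf_mod.cv_folds(
        yd, disc["patient_id"].to_numpy(), grid.n_folds, grid.fold_unit, grid.seed
    )
    oof_scores = clf_mod.cross_val_scores(
        Xd, yd, cost, gamma, folds, standardize=cls_cfg["standardize"]
    )
    _, cv_auc, cutoff = clf_mod.roc_curve_auc(oof_scores, yd)
    _, train_auc, _ = clf_mod.roc_curve_auc(clf_mod.decision_scores(model, Xd), yd)
    model.cutoff = cutoff
    Xt = test[selected_cols].to_numpy(float)
    yt = test["label"].to_numpy()
    report = clf_mod.evaluate_epochs(model, Xt, yt)
    pred = (clf_mod.decision_scores(model, Xt) >= cutoff).astype(int)
    patient_eval = clf_mod.evaluate_patients(pred, test["patient_id"].to_numpy(), yt)
    _stage_done("classifier")

    # ------------------------------------------------------------------ outputs
    artifacts = {}

    def _write_json(name, obj):
        path = outdir / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
        artifacts[name] = path

    manifest_out = manifest.copy()
    manifest_out["cohort"] = [assignment.cohort_of(p) for p in manifest_out["patient_id"]]
    manifest_out.to_csv(outdir / "manifest.csv", index=False)
    artifacts["manifest.csv"] = outdir / "manifest.csv"

    nbs_json = {}
    for thr, res in nbs_results.items():
        nbs_json[str(thr)] = {
            "threshold": res.threshold,
            "n_permutations": res.n_permutations,
            "unit": res.unit,
            "component_sizes": [len(c) for c in res.components],
            "fwe_p": res.fwe_p,
            "n_selected_edges": len(res.selected_edges),
            "selected_edges": [
                [CHANNELS[i], CHANNELS[j]] for i, j in res.selected_edges
            ],
            "hubs": nbs.rank_hubs(res),
        }
    _write_json("nbs_result.json", nbs_json)

    stats_primary = nbs.edgewise_glm_stats(disc_X, disc["label"].to_numpy())
    edge_rows = []
    for i, j in selected:
        k = edge_index(i, j)
        edge_rows.append((CHANNELS[i], CHANNELS[j], stats_primary.t[k]))
    pd.DataFrame(edge_rows, columns=["node1", "node2", "t_stat"]).to_csv(
        outdir / "selected_edges.tsv", sep="\t", index=False, float_format="%.6f"
    )
    artifacts["selected_edges.tsv"] = outdir / "selected_edges.tsv"

    report.roc.to_csv(
        outdir / "roc_test.tsv", sep="\t", index=False, float_format="%.6f"
    )
    artifacts["roc_test.tsv"] = outdir / "roc_test.tsv"

    evaluation = {
        "grid": {"cost": cost, "gamma": gamma,
                 "mean_cv_auc": float(grid_table["mean_auc"].max())},
        "train_auc": train_auc,
        "cutoff": cutoff,
        "edge_selection_fallback": fallback,
        "n_selected_edges": len(selected),
        "test_epoch": {
            "auc": report.auc,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "accuracy": report.accuracy,
            "confusion": report.confusion,
        },
        "test_patient": {
            k: patient_eval[k] for k in ("TP", "FN", "TN", "FP", "accuracy", "votes")
        },
    }
    _write_json("evaluation.json", evaluation)

    record["counts"]["n_selected_edges"] = len(selected)
    record["artifacts"] = {
        name: hashlib.sha256(path.read_bytes()).hexdigest()
        for name, path in sorted(artifacts.items())
    }
    record["version"] = __import__("vnsnet").__version__
    _stage_done("total")
    (outdir / "run_record.json").write_text(
        json.dumps(record, indent=2, sort_keys=True, default=str) + "\n"
    )
    write_report(outdir)
    return record


def write_report(run_dir) -> Path:
    """Render the human-readable summary from the machine artifacts."""
    run_dir = Path(run_dir)
    nbs_json = json.loads((run_dir / "nbs_result.json").read_text())
    evaluation = json.loads((run_dir / "evaluation.json").read_text())
    record = json.loads((run_dir / "run_record.json").read_text())
    lines = ["VNS response prediction - run summary", "=" * 40, ""]
    counts = record["counts"]
    lines.append(
        f"Patients: {counts['n_patients']}  raw epochs: {counts['n_raw_epochs']}  "
        f"augmented: {counts['n_epochs_total']} "
        f"(discovery {counts['n_discovery_epochs']}, testing {counts['n_testing_epochs']})"
    )
    lines.append(f"Edges per epoch: {counts['n_edges']}")
    lines.append("")
    lines.append("Differential network (NBS)")
    lines.append("-" * 30)
    for thr, res in nbs_json.items():
        sizes = res["component_sizes"] or [0]
        pvals = ", ".join(f"{p:.4f}" for p in res["fwe_p"]) or "-"
        lines.append(
            f"p < {thr}: {res['n_selected_edges']} selected edges "
            f"(largest component {max(sizes)}, FWE p: {pvals})"
        )
        for rank, hub in enumerate(res["hubs"][:3], 1):
            lines.append(f"    hub {rank}: {hub['node']} ({hub['ratio']})")
    if not any(res["n_selected_edges"] for res in nbs_json.values()):
        lines.append("No significant differential network at any threshold.")
    lines.append("")
    lines.append("Classifier")
    lines.append("-" * 30)
    if evaluation.get("edge_selection_fallback"):
        lines.append("NOTE: fallback to suprathreshold edges (no significant component).")
    grid = evaluation["grid"]
    lines.append(
        f"best cost={grid['cost']:g} gamma={grid['gamma']:g} "
        f"mean CV AUC={grid['mean_cv_auc']:.3f}"
    )
    te = evaluation["test_epoch"]
    lines.append(
        f"test epochs: AUC={te['auc']:.3f} sens={te['sensitivity']:.3f} "
        f"spec={te['specificity']:.3f} acc={te['accuracy']:.3f}"
    )
    tp = evaluation["test_patient"]
    lines.append(
        f"test patients: TP={tp['TP']} FN={tp['FN']} TN={tp['TN']} FP={tp['FP']} "
        f"accuracy={tp['accuracy']:.3f}"
    )
    path = run_dir / "report.txt"
    path.write_text("\n".join(lines) + "\n")
    return path
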