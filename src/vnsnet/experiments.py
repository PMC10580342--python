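"""Study-scale validation experiments.

Each function runs one self-contained experiment on synthetic cohorts:
design arithmetic of the epoch bookkeeping, estimator-vs-oracle error
measurements, NBS type-I calibration and planted-network recovery, and the
end-to-end classification study. They are what the acceptance script and
the acceptance test suite execute; problem sizes are chosen so a full
sweep completes in minutes on one core (documented in the methods note).
"""

from __future__ import annotations

import numpy as np

from vnsnet import connectivity, nbs, pipeline, synthetic
from vnsnet.montage import N_EDGES, edge_pairs


def _seed(master: int, name: str) -> int:
    return pipeline.stage_seed(master, f"experiment:{name}")


def cohort_arithmetic(seed: int = 0) -> dict:
    """Simulate the reference study design (23 patients, 15R/8NR, 10+6
    discovery, 56 epochs per child after bootstrap) and count epochs at
    every stage of preprocessing."""
    config = pipeline.make_config({"seed": _seed(seed, "cohort")})
    manifest, epochs_by_patient, _ = pipeline._gather_epochs(config)
    assignment, augmented, n_raw = pipeline._preprocess(
        config, manifest, epochs_by_patient
    )
    counts = {
        "n_patients": len(manifest),
        "n_responders": int((manifest["label"] == "responder").sum()),
        "n_raw_epochs": n_raw,
        "n_epochs_total": sum(len(v) for v in augmented.values()),
    }
    for cohort in ("discovery", "testing"):
        members = getattr(assignment, cohort)
        labels = dict(zip(manifest["patient_id"], manifest["label"]))
        counts[f"n_{cohort}_epochs"] = sum(len(augmented[p]) for p in members)
        counts[f"n_{cohort}_responder_epochs"] = sum(
            len(augmented[p]) for p in members if labels[p] == "responder"
        )
        counts[f"n_{cohort}_nonresponder_epochs"] = sum(
            len(augmented[p]) for p in members if labels[p] == "nonresponder"
        )
    return counts


def partial_correlation_oracle_error(seed: int = 0, trials: int = 100) -> float:
    """Max |rho_hat - rho_oracle| over random 4-8 channel Gaussian draws.

    The oracle regresses each channel pair on all remaining channels with
    plain least squares and correlates the residuals (uncentered), fully
    independent of the precision-scaling path under test.
    """
    rng = np.random.default_rng(_seed(seed, "pcorr"))
    worst = 0.0
    for _ in range(trials):
        p = int(rng.integers(4, 9))
        # random SPD precision with moderate conditioning
        a = rng.standard_normal((p, p)) / np.sqrt(p)
        prec = a @ a.T + np.eye(p)
        x = synthetic.simulate_epoch_series(prec, 400, seed=int(rng.integers(2**31)))
        S = x.T @ x / len(x)
        rho = connectivity.partial_correlations(connectivity.glasso_precision(S, 0.0))
        for k, (i, j) in enumerate(edge_pairs(p)):
            others = [c for c in range(p) if c not in (i, j)]
            Z = x[:, others]
            ri = x[:, i] - Z @ np.linalg.lstsq(Z, x[:, i], rcond=None)[0]
            rj = x[:, j] - Z @ np.linalg.lstsq(Z, x[:, j], rcond=None)[0]
            oracle = ri @ rj / np.sqrt((ri @ ri) * (rj @ rj))
            worst = max(worst, abs(rho[k] - oracle))
    return worst


def kernel_covariance_oracle_errors(seed: int = 0) -> tuple[float, float]:
    """(brute-force formula error, infinite-bandwidth static-limit error).

    First term: max |vectorized - loop| over random epochs for the
    kernel-weighted covariance at every second. Second: at h = 1e6 the
    estimate must equal the unweighted second-moment matrix.
    """
    rng = np.random.default_rng(_seed(seed, "kernel"))
    brute_err = 0.0
    for _ in range(5):
        x = rng.standard_normal((60, 19))
        h = float(rng.uniform(1.0, 10.0))
        tvc = connectivity.time_varying_covariance(x, h=h, centering="none")
        for t in range(1, 61):
            raw = np.array([np.exp(-0.5 * ((i - t) / h) ** 2) for i in range(1, 61)])
            num = np.zeros((19, 19))
            for i in range(60):
                num += raw[i] * np.outer(x[i], x[i])
            brute_err = max(brute_err, np.abs(tvc.matrices[t - 1] - num / raw.sum()).max())
    x = rng.standard_normal((60, 19))
    tvc = connectivity.time_varying_covariance(x, h=1e6, centering="none")
    static = x.T @ x / 60
    static_err = float(max(np.abs(tvc.matrices[t] - static).max() for t in range(60)))
    return float(brute_err), static_err


def _group_features(precision, n_epochs, lam, rng):
    rows = np.empty((n_epochs, N_EDGES))
    for k in range(n_epochs):
        epoch = synthetic.simulate_epoch_series(
            precision, 60, seed=int(rng.integers(2**31))
        )
        rows[k] = connectivity.epoch_features(epoch, lam=lam)
    return rows


def nbs_null_calibration(
    seed: int = 0,
    n_replicates: int = 200,
    n_perm: int = 500,
    epochs_per_group: int = 30,
    lam: float = 0.0,
) -> float:
    """Family-wise false-positive rate of the NBS under the null.

    Both groups draw epochs from the same (base-network) precision, so any
    FWE-significant component is a false positive; the rate over
    replicates estimates the achieved FWE level at alpha = 0.05.
    """
    spec = synthetic.default_network_spec(effect_size=0.0)
    _, prec = synthetic.make_group_precisions(spec)
    rng = np.random.default_rng(_seed(seed, "null"))
    labels = np.array([1] * epochs_per_group + [0] * epochs_per_group)
    hits = 0
    for _ in range(n_replicates):
        features = _group_features(prec, 2 * epochs_per_group, lam, rng)
        res = nbs.nbs_fwe_test(
            features,
            labels,
            threshold=0.05,
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        if any(p < 0.05 for p in res.fwe_p):
            hits += 1
    return hits / n_replicates


def nbs_recovery(
    seed: int = 0,
    n_replicates: int = 20,
    epochs_per_group: int = 100,
    n_perm: int = 1000,
    lam: float = connectivity.DEFAULT_LAMBDA,
) -> dict:
    """Planted differential-network recovery at the default strong effect.

    Returns the mean fraction of planted edges inside the FWE-significant
    component and the largest component FWE p-value across replicates.
    """
    spec = synthetic.default_network_spec()
    prec_a, prec_b = synthetic.make_group_precisions(spec)
    planted = set(spec.differential_edges)
    rng = np.random.default_rng(_seed(seed, "recovery"))
    labels = np.array([1] * epochs_per_group + [0] * epochs_per_group)
    fractions, worst_p = [], 0.0
    for _ in range(n_replicates):
        features = np.vstack(
            [
                _group_features(prec_a, epochs_per_group, lam, rng),
                _group_features(prec_b, epochs_per_group, lam, rng),
            ]
        )
        res = nbs.nbs_fwe_test(
            features, labels, threshold=0.05, n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        recovered = planted & set(res.selected_edges)
        fractions.append(len(recovered) / len(planted))
        worst_p = max(worst_p, min(res.fwe_p) if res.fwe_p else 1.0)
    return {
        "mean_recovery_fraction": float(np.mean(fractions)),
        "min_recovery_fraction": float(np.min(fractions)),
        "max_fwe_p": worst_p,
        "n_replicates": n_replicates,
    }


def end_to_end_config(seed: int, effect_size: float) -> dict:
    """Scaled study config for the full-pipeline experiments: the reference
    patient design, with a 200 Hz raw rate and a single NBS threshold to
    keep a complete run to a couple of minutes."""
    return pipeline.make_config(
        {
            "seed": _seed(seed, f"e2e:{effect_size}"),
            "synthetic": {"sampling_rate": 200, "effect_size": effect_size},
            "nbs": {"thresholds": [0.05], "n_permutations": 2000},
        }
    )


def end_to_end(seed: int, effect_size: float, outdir) -> dict:
    """Run the full pipeline at the given planted effect size."""
    import json
    from pathlib import Path

    record = pipeline.run_pipeline(end_to_end_config(seed, effect_size), outdir)
    evaluation = json.loads((Path(outdir) / "evaluation.json").read_text())
    return {"record": record, "evaluation": evaluation}


def determinism_check(seed: int, outdir_a, outdir_b) -> bool:
    """Two small full runs under one master seed: identical checksums?"""
    override = {
        "seed": _seed(seed, "determinism"),
        "synthetic": {
            "n_responders": 6,
            "n_nonresponders": 4,
            "epochs_per_patient": [2, 4],
            "sampling_rate": 100,
        },
        "preprocessing": {
            "target_epochs": 8,
            "n_discovery_responders": 4,
            "n_discovery_nonresponders": 2,
        },
        "nbs": {"n_permutations": 200, "thresholds": [0.05]},
        "classifier": {"costs": [1.0, 8.0], "gammas": [0.01, 0.1]},
    }
    a = pipeline.run_pipeline(pipeline.make_config(override), outdir_a)
    b = pipeline.run_pipeline(pipeline.make_config(override), outdir_b)
    return a["artifacts"] == b["artifacts"]
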