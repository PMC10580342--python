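"""Synthetic EEG cohorts with a planted group-differential network.

Two patient groups (responder / nonresponder analogues) draw their
per-second 19-channel values from zero-mean multivariate Gaussians whose
sparse precision matrices share a base edge support and differ exactly on
a planted differential edge set, by default two stars hubbed at C3 and C4.
Raw 1000 Hz traces are synthesized as the per-second latent value plus
white within-second noise, so 1-s block averaging recovers the latent
series exactly at zero noise. The latent seconds are i.i.d. (no temporal
autocorrelation); an optional covariance-interpolation mode blends two
precisions linearly across the epoch to exercise the time-varying
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from vnsnet import edf
from vnsnet.montage import CHANNELS, N_CHANNELS, channel_index
from vnsnet.preprocessing import NONRESPONDER, RESPONDER, RawRecording

_MIN_EIG = 1e-3
_GAP_SECONDS = 5  # silence before / between / after seizure windows

Edge = tuple[int, int]


def _normalize_edges(edges, n_channels: int) -> set[Edge]:
    out: set[Edge] = set()
    for i, j in edges:
        if not (0 <= i < n_channels and 0 <= j < n_channels) or i == j:
            raise ValueError(f"invalid edge ({i}, {j}) for {n_channels} channels")
        out.add((min(i, j), max(i, j)))
    return out


@dataclass
class GroupNetworkSpec:
    """Shared-plus-differential sparse precision structure for two groups."""

    n_channels: int = N_CHANNELS
    base_edges: frozenset = frozenset()
    differential_edges: frozenset = frozenset()
    effect_size: float = 0.4
    base_strength: float = 0.25
    diagonal: float = 1.5

    def __post_init__(self):
        self.base_edges = frozenset(_normalize_edges(self.base_edges, self.n_channels))
        self.differential_edges = frozenset(
            _normalize_edges(self.differential_edges, self.n_channels)
        )
        if self.effect_size < 0 or self.base_strength < 0 or self.diagonal <= 0:
            raise ValueError("strengths must be nonnegative, diagonal positive")


@dataclass
class CohortSpec:
    """Study-design parameters of one simulated cohort."""

    n_responders: int = 15
    n_nonresponders: int = 8
    epochs_per_patient: tuple[int, int] = (4, 20)
    sampling_rate: int = 1000
    epoch_seconds: int = 60
    within_second_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.epochs_per_patient
        if min(self.n_responders, self.n_nonresponders, lo) < 1 or lo > hi:
            raise ValueError("counts must be >= 1 and epoch range ordered")
        if self.within_second_noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


@dataclass
class SimulatedCohort:
    recordings: list[RawRecording]
    manifest: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)


def default_network_spec(
    effect_size: float = 0.4, n_base_edges: int = 20, base_seed: int = 20230511
) -> GroupNetworkSpec:
    """Default planted structure: C3/C4 hub stars over a random sparse base.

    The differential edges connect C3 to {P3, Pz, Cz, T3, O1} and C4 to
    {P4, Pz, Cz, T4, O2}, mirroring the centro-parietal hubs the method is
    meant to recover; base edges are a fixed pseudo-random sparse support
    disjoint from the planted stars.
    """
    c3, c4 = channel_index("C3"), channel_index("C4")
    diff = {(c3, channel_index(ch)) for ch in ("P3", "Pz", "Cz", "T3", "O1")}
    diff |= {(c4, channel_index(ch)) for ch in ("P4", "Pz", "Cz", "T4", "O2")}
    diff = _normalize_edges(diff, N_CHANNELS)
    rng = np.random.default_rng(base_seed)
    all_pairs = [
        (i, j)
        for i in range(N_CHANNELS)
        for j in range(i + 1, N_CHANNELS)
        if (i, j) not in diff
    ]
    picks = rng.choice(len(all_pairs), size=n_base_edges, replace=False)
    base = {all_pairs[k] for k in picks}
    return GroupNetworkSpec(
        base_edges=frozenset(base),
        differential_edges=frozenset(diff),
        effect_size=effect_size,
    )


def make_group_precisions(spec: GroupNetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Build the two group precision matrices.

    Both share ``-base_strength`` off-diagonals on the base support; group
    A (responder analogue) additionally gets ``-effect_size`` on every
    differential edge (a strength delta where the edge is also a base
    edge). Diagonals start at ``spec.diagonal`` and are boosted equally on
    both matrices until the smaller of the two smallest eigenvalues
    reaches a positive floor, preserving A - B exactly.
    """
    p = spec.n_channels
    base = np.zeros((p, p))
    for i, j in spec.base_edges:
        base[i, j] = base[j, i] = -spec.base_strength
    delta = np.zeros((p, p))
    for i, j in spec.differential_edges:
        delta[i, j] = delta[j, i] = -spec.effect_size
    a = base + delta + spec.diagonal * np.eye(p)
    b = base + spec.diagonal * np.eye(p)
    for _ in range(200):
        min_eig = min(np.linalg.eigvalsh(a)[0], np.linalg.eigvalsh(b)[0])
        if min_eig >= _MIN_EIG:
            return a, b
        boost = (_MIN_EIG - min_eig) * np.eye(p)
        a = a + boost
        b = b + boost
    raise ValueError("could not reach positive definiteness; infeasible spec")


def _covariance_factor(precision: np.ndarray) -> np.ndarray:
    """Cholesky factor L with L L^T = inv(precision); errors if not SPD."""
    try:
        c = np.linalg.cholesky(precision)
    except np.linalg.LinAlgError:
        raise ValueError("precision matrix is not positive definite") from None
    # inv(precision) = inv(C)^T inv(C); a triangular solve gives the factor
    return np.linalg.inv(c).T


def simulate_epoch_series(
    precision: np.ndarray, epoch_seconds: int = 60, seed=None
) -> np.ndarray:
    """Draw ``epoch_seconds`` i.i.d. rows from N(0, inv(precision))."""
    factor = _covariance_factor(np.asarray(precision, dtype=float))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((int(epoch_seconds), precision.shape[0]))
    return z @ factor.T


def simulate_epoch_series_tv(
    precision_start: np.ndarray,
    precision_end: np.ndarray,
    epoch_seconds: int = 60,
    seed=None,
) -> np.ndarray:
    """Smoothly nonstationary epoch: covariance blends linearly in time.

    Second j draws from N(0, (1-w) Sigma_start + w Sigma_end) with
    w = j/(epoch_seconds-1). Exists to exercise the kernel-weighted
    time-varying covariance estimator.
    """
    cov0 = np.linalg.inv(np.asarray(precision_start, dtype=float))
    cov1 = np.linalg.inv(np.asarray(precision_end, dtype=float))
    rng = np.random.default_rng(seed)
    n = int(epoch_seconds)
    out = np.empty((n, cov0.shape[0]))
    for j in range(n):
        w = j / max(n - 1, 1)
        chol = np.linalg.cholesky((1 - w) * cov0 + w * cov1)
        out[j] = chol @ rng.standard_normal(cov0.shape[0])
    return out


def simulate_raw_recording(
    patient_id: str,
    n_seizures: int,
    precision: np.ndarray,
    cohort_spec: CohortSpec,
    seed=None,
) -> RawRecording:
    """Synthesize one annotated continuous recording.

    Each seizure window holds a fresh latent 60 x 19 draw; every raw
    sample of second j is the latent value plus N(0, noise_sd^2) white
    noise, and inter-seizure gaps are unit white noise. Onsets are spaced
    a fixed gap apart, so windows never overlap or run off the end.
    """
    if n_seizures < 1:
        raise ValueError("need at least one seizure")
    rate, secs = cohort_spec.sampling_rate, cohort_spec.epoch_seconds
    gap = _GAP_SECONDS * rate
    window = secs * rate
    total = gap + n_seizures * (window + gap)
    rng = np.random.default_rng(seed)
    p = precision.shape[0]
    signal = rng.standard_normal((total, p))  # background + within-second noise
    onsets = []
    for k in range(n_seizures):
        onset = gap + k * (window + gap)
        latent = simulate_epoch_series(precision, secs, seed=rng.integers(2**31))
        block = np.repeat(latent, rate, axis=0)
        signal[onset : onset + window] *= cohort_spec.within_second_noise_sd
        signal[onset : onset + window] += block
        onsets.append(onset)
    return RawRecording(
        signal=signal,
        sampling_rate=rate,
        channel_labels=CHANNELS[:p] if p == N_CHANNELS else tuple(map(str, range(p))),
        onsets=onsets,
        patient_id=patient_id,
    )


def plan_cohort(
    cohort_spec: CohortSpec, network_spec: GroupNetworkSpec | None = None
):
    """Draw the per-patient design (manifest + seeds) without any signal.

    Returns ``(manifest, patient_plans, ground_truth)`` where each plan is
    ``(patient_id, label, n_seizures, seed, precision)``. Separating the
    plan from signal synthesis lets large cohorts be generated one patient
    at a time under the same master seed.
    """
    if network_spec is None:
        network_spec = default_network_spec()
    prec_a, prec_b = make_group_precisions(network_spec)
    rng = np.random.default_rng(cohort_spec.seed)
    lo, hi = cohort_spec.epochs_per_patient
    rows, plans = [], []
    groups = [(RESPONDER, "R", cohort_spec.n_responders, prec_a)] + [
        (NONRESPONDER, "N", cohort_spec.n_nonresponders, prec_b)
    ]
    for label, prefix, count, precision in groups:
        for k in range(count):
            pid = f"{prefix}{k + 1:02d}"
            n_seiz = int(rng.integers(lo, hi + 1))
            seed = int(rng.integers(2**31))
            plans.append((pid, label, n_seiz, seed, precision))
            rows.append({"patient_id": pid, "label": label, "n_seizures": n_seiz})
    ground_truth = {
        "precision_responder": prec_a,
        "precision_nonresponder": prec_b,
        "differential_edges": sorted(network_spec.differential_edges),
        "network_spec": network_spec,
    }
    return pd.DataFrame(rows), plans, ground_truth


def iter_recordings(cohort_spec: CohortSpec, plans):
    """Lazily synthesize one RawRecording per patient plan."""
    for pid, _label, n_seiz, seed, precision in plans:
        yield simulate_raw_recording(pid, n_seiz, precision, cohort_spec, seed=seed)


def simulate_cohort(
    cohort_spec: CohortSpec, network_spec: GroupNetworkSpec | None = None
) -> SimulatedCohort:
    """Generate the full two-group cohort with ground truth attached."""
    manifest, plans, ground_truth = plan_cohort(cohort_spec, network_spec)
    return SimulatedCohort(
        recordings=list(iter_recordings(cohort_spec, plans)),
        manifest=manifest,
        ground_truth=ground_truth,
    )


def ground_truth_partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Partial correlation matrix implied by a generating precision."""
    d = np.sqrt(np.diag(precision))
    rho = -precision / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def write_fixtures(cohort: SimulatedCohort, directory, assignment=None) -> dict:
    """Write one EDF+ file per patient plus a CSV manifest.

    Returns a mapping patient_id -> EDF path. The manifest gains a
    ``cohort`` column (from ``assignment`` when given, else
    ``'unassigned'``) and an ``edf`` column with relative file names.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for rec in cohort.recordings:
        path = directory / f"{rec.patient_id}.edf"
        annotations = [
            (onset / rec.sampling_rate, 60.0, "seizure") for onset in rec.onsets
        ]
        edf.write_edf(
            path,
            rec.signal,
            rec.sampling_rate,
            rec.channel_labels,
            annotations,
            patient_id=rec.patient_id,
        )
        paths[rec.patient_id] = path
    manifest = cohort.manifest.copy()
    manifest["cohort"] = [
        assignment.cohort_of(pid) if assignment is not None else "unassigned"
        for pid in manifest["patient_id"]
    ]
    manifest["edf"] = [f"{pid}.edf" for pid in manifest["patient_id"]]
    manifest.to_csv(directory / "manifest.csv", index=False)
    return paths
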