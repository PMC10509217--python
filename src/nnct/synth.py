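"""Synthetic infant-like connectome cohorts with known injected structure.

Real neonatal connectomes are access-controlled, so every downstream stage
is exercised on generated 90-node cohorts that emulate their gross
features: positive right-skewed edge weights on a 0-1 scale (log-normal),
modular block structure aligned with the eight canonical functional
networks, a minority of hub nodes with amplified strength, a developmental
trend (hub strength grows with postmenstrual age), and a preterm deficit
(edge weights incident to a designated node subset are attenuated).

Both effects are injected through *generative* parameters, never by editing
computed metrics, so recovery tests validate the whole pipeline: the
age-related amplification of hub edges raises average controllability with
age, and the preterm attenuation depresses it at the affected nodes.  The
generator draws all random numbers before applying the deterministic age
and group scalings, so two calls with the same seed but different ages
share every draw and differ only through the scaling — which makes the
injected age trend monotone per seed.

The defaults are not calibrated to any real dataset (no edge-level
summaries of neonatal connectomes were available to calibrate against);
they are chosen to give plausible densities (~0.2-0.3) and weight scales.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .io import (
    Atlas,
    CANONICAL_NETWORKS,
    Cohort,
    Connectome,
    SubjectRecord,
    apply_threshold,
    validate_connectome,
    write_atlas,
    write_cohort,
    write_connectome,
)

#: PMA sampling windows (weeks): preterm birth scans and TEA-era scans.
DEFAULT_AGE_RANGES = {"birth": (28.0, 36.0), "TEA": (37.0, 44.0)}

#: Lobe assigned to each canonical network in the default synthetic atlas.
_NETWORK_LOBE = {
    "visual": "occipital",
    "somatomotor": "frontal",
    "dorsal_attention": "parietal",
    "ventral_attention": "temporal",
    "limbic": "limbic",
    "frontoparietal": "frontal",
    "default_mode": "parietal",
    "subcortical": "subcortical",
}

# Motion summaries per scan era (mean, sd): intra-volume translation (mm),
# rotation (a.u.) and outlier ratio (%), as typically reported for neonatal
# diffusion acquisitions.
_MOTION = {
    "birth": ((0.12, 0.051), (0.18, 0.10), (0.22, 0.088)),
    "TEA": ((0.13, 0.052), (0.19, 0.092), (0.25, 0.083)),
}

# Developmental-outcome scaled scores at ~18 months (mean, sd) by group.
_BSID = {
    "term": {"cognition": (10.10, 2.12), "language": (19.28, 5.09), "motor": (20.62, 3.15)},
    "preterm": {"cognition": (9.31, 2.95), "language": (17.91, 6.22), "motor": (19.26, 4.03)},
}


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic connectome generator.

    ``age_effect`` is a per-week multiplicative gain on the hub amplification
    relative to 28 weeks PMA; ``group_effect`` is the multiplier (< 1 for a
    deficit) applied to edges incident to ``affected_nodes`` for preterm
    subjects.  All weights live on a dimensionless 0-1 scale.
    """

    n_nodes: int = 90
    n_modules: int = 8
    p_within: float = 0.7
    p_between: float = 0.15
    weight_logmean: float = -2.3
    weight_logsd: float = 0.5
    hub_fraction: float = 0.15
    hub_gain: float = 2.0
    age_effect: float = 0.05
    group_effect: float = 0.7
    n_affected: int = 10
    noise_sd: float = 0.2

    def __post_init__(self):
        for name in ("p_within", "p_between"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        for name in ("weight_logsd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not 0.0 <= self.hub_fraction <= 1.0:
            raise ParameterError("hub_fraction outside [0, 1]")
        if self.hub_gain <= 0 or self.group_effect <= 0:
            raise ParameterError("hub_gain and group_effect must be positive")
        if self.n_modules < 1 or self.n_nodes < self.n_modules:
            raise ParameterError("need n_nodes >= n_modules >= 1")
        if not 0 <= self.n_affected <= self.n_nodes:
            raise ParameterError("n_affected outside [0, n_nodes]")


@dataclass
class SyntheticCohort:
    """A generated cohort: records, matrices, and the injected ground truth."""

    cohort: Cohort
    connectomes: dict  # (subject_id, scan) -> Connectome
    truth: dict


def module_assignment(params: GeneratorParams) -> np.ndarray:
    """Deterministic contiguous-block node -> module map."""
    return (np.arange(params.n_nodes) * params.n_modules) // params.n_nodes


def hub_nodes(params: GeneratorParams) -> np.ndarray:
    """Deterministic hub set: evenly spaced node indices, spreading hubs
    across modules."""
    n_hubs = int(round(params.hub_fraction * params.n_nodes))
    if n_hubs == 0:
        return np.array([], dtype=int)
    return np.unique(np.linspace(0, params.n_nodes - 1, n_hubs).round().astype(int))


def affected_nodes(params: GeneratorParams) -> np.ndarray:
    """Deterministic preterm-deficit node set: the first ``n_affected``
    non-hub nodes."""
    hubs = set(hub_nodes(params).tolist())
    pool = [i for i in range(params.n_nodes) if i not in hubs]
    return np.array(pool[: params.n_affected], dtype=int)


def default_atlas(params: GeneratorParams) -> Atlas:
    """Atlas matching the generator's module structure, one canonical
    network per module (cycled if n_modules != 8)."""
    modules = module_assignment(params)
    networks = [CANONICAL_NETWORKS[m % len(CANONICAL_NETWORKS)] for m in modules]
    return Atlas(
        node_ids=tuple(f"n{i+1:03d}" for i in range(params.n_nodes)),
        labels=tuple(f"Region_{i+1:03d}" for i in range(params.n_nodes)),
        lobes=tuple(_NETWORK_LOBE[nw] for nw in networks),
        networks=tuple(networks),
    )


def generate_connectome(
    params: GeneratorParams,
    pma_weeks: float,
    group: str,
    seed: int,
) -> Connectome:
    """One synthetic connectome for a subject of the given age and group."""
    if group not in ("term", "preterm"):
        raise ParameterError(f"unknown group {group!r}")
    if pma_weeks <= 0:
        raise ParameterError("pma_weeks must be positive")
    n = params.n_nodes
    rng = np.random.default_rng(seed)
    modules = module_assignment(params)
    same_module = modules[:, None] == modules[None, :]
    P = np.where(same_module, params.p_within, params.p_between)

    # all random draws happen before any age/group scaling (see module docs)
    iu = np.triu_indices(n, 1)
    present = rng.random(len(iu[0])) < P[iu]
    W = rng.lognormal(params.weight_logmean, params.weight_logsd, len(iu[0]))
    jitter = (
        rng.lognormal(0.0, params.noise_sd, len(iu[0]))
        if params.noise_sd > 0
        else np.ones(len(iu[0]))
    )

    gain = params.hub_gain * (1.0 + params.age_effect * (pma_weeks - 28.0))
    node_factor = np.ones(n)
    node_factor[hub_nodes(params)] = max(gain, 1e-6)
    if group == "preterm":
        node_factor[affected_nodes(params)] *= params.group_effect
    edge_factor = np.sqrt(node_factor[iu[0]] * node_factor[iu[1]])

    w = np.where(present, W * jitter * edge_factor, 0.0)
    w = np.minimum(w, 1.0)  # QA-like weights live on (0, 1]
    A = np.zeros((n, n))
    A[iu] = w
    A = A + A.T
    A = apply_threshold(A)
    ids = [f"n{i+1:03d}" for i in range(n)]
    return validate_connectome(ids, A)


def generate_cohort(
    params: GeneratorParams,
    n_term: int = 448,
    n_preterm: int = 73,
    age_ranges: dict | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a full cohort: term subjects scanned once in the TEA-era
    window, preterm subjects scanned at birth and again at TEA.

    Same ``seed`` and parameters reproduce the cohort bit-identically.
    """
    if n_term < 0 or n_preterm < 0:
        raise ParameterError("subject counts must be >= 0")
    ranges = dict(DEFAULT_AGE_RANGES)
    if age_ranges:
        ranges.update(age_ranges)
    for key, (lo, hi) in ranges.items():
        if not lo < hi:
            raise ParameterError(f"empty age range for {key!r}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    records: list = []
    connectomes: dict = {}
    record_seeds: dict = {}

    def scan_record(subject_id, group, scan, ga, pma):
        sex = "female" if rng.random() < 0.47 else "male"
        volume = max(50.0, -600.0 + 25.0 * pma + rng.normal(0.0, 30.0))
        (mt, mr, mo) = (
            max(0.01, rng.normal(m, s)) for (m, s) in _MOTION[scan]
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        record_seeds[(subject_id, scan)] = sub_seed
        connectomes[(subject_id, scan)] = generate_connectome(
            params, pma_weeks=pma, group=group, seed=sub_seed
        )
        return SubjectRecord(
            subject_id=subject_id,
            group=group,
            scan=scan,
            ga_weeks=round(ga, 2),
            pma_weeks=round(pma, 2),
            sex=sex,
            brain_volume=round(volume, 1),
            motion_translation=round(mt, 3),
            motion_rotation=round(mr, 3),
            outlier_ratio=round(mo, 3),
            connectome_path=f"{subject_id}_{scan}.tsv",
        )

    def bsid(group):
        if rng.random() >= (0.79 if group == "term" else 0.77):
            return {}
        return {
            f"bsid_{k}": round(float(rng.normal(m, s)), 2)
            for k, (m, s) in _BSID[group].items()
        }

    for i in range(n_term):
        sid = f"term{i+1:04d}"
        pma = rng.uniform(*ranges["TEA"])
        ga = min(rng.uniform(37.0, 42.0), pma - 0.2)
        rec = scan_record(sid, "term", "TEA", ga, pma)
        for k, v in bsid("term").items():
            setattr(rec, k, v)
        records.append(rec)

    for i in range(n_preterm):
        sid = f"pret{i+1:04d}"
        pma_birth = rng.uniform(*ranges["birth"])
        ga = pma_birth - 3.0  # first scan ~3 weeks after birth
        pma_tea = rng.uniform(*ranges["TEA"])
        scores = bsid("preterm")
        for scan, pma in (("birth", pma_birth), ("TEA", pma_tea)):
            rec = scan_record(sid, "preterm", scan, ga, pma)
            for k, v in scores.items():
                setattr(rec, k, v)
            records.append(rec)

    truth = {
        "params": asdict(params),
        "seed": int(seed),
        "hub_nodes": hub_nodes(params).tolist(),
        "affected_nodes": affected_nodes(params).tolist(),
        "module_assignment": module_assignment(params).tolist(),
        "record_seeds": {f"{s}:{sc}": v for (s, sc), v in record_seeds.items()},
    }
    return SyntheticCohort(cohort=Cohort(records=records), connectomes=connectomes, truth=truth)


def write_cohort_dir(sc: SyntheticCohort, out_dir, params: GeneratorParams | None = None) -> None:
    """Write cohort.tsv, atlas.tsv, per-record matrices and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort(sc.cohort, out / "cohort.tsv")
    p = params or GeneratorParams(**sc.truth["params"])
    write_atlas(default_atlas(p), out / "atlas.tsv")
    for (sid, scan), C in sc.connectomes.items():
        write_connectome(C, out / f"{sid}_{scan}.tsv")
    (out / "truth.json").write_text(json.dumps(sc.truth, indent=2, sort_keys=True))
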