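"""One-command orchestration of the full analysis.

Stage order mirrors the scientific narrative: per-subject controllability
profiles, developmental rates and their comparison, term-vs-preterm group
tests with FDR, network activation energies and their group tests,
real-vs-null energy comparisons, and outcome-score correlations.  Every
stage writes plain TSV/JSON so any stage can be re-run or inspected on its
own, and all stochastic stages are seeded, so identical config + inputs
reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .controllability import profile
from .energy import network_energy_table
from .errors import DegenerateInputError, NnctError, ValidationError
from .io import (
    Atlas,
    Cohort,
    check_atlas_matches,
    read_atlas,
    read_cohort,
    read_connectome,
)
from .nulls import energy_vs_null
from .stats import (
    compare_correlations,
    pearson,
    region_results_frame,
    regionwise_group_test,
    residualize,
    two_sample_t,
)

log = logging.getLogger("nnct")

_FLOAT_FMT = "%.12g"


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    inputs: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)
    notices: list = field(default_factory=list)

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "version": self.version,
                    "inputs": self.inputs,
                    "outputs": self.outputs,
                    "timestamps": self.timestamps,
                    "notices": self.notices,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages


def load_inputs(cfg: RunConfig):
    cohort = read_cohort(cfg.paths.cohort)
    atlas = read_atlas(cfg.paths.atlas)
    cdir = Path(cfg.paths.connectome_dir)
    connectomes = {}
    for rec in cohort.records:
        if not rec.connectome_path:
            raise ValidationError(f"{rec.subject_id}: record lacks connectome_path")
        C = read_connectome(
            cdir / rec.connectome_path, threshold=cfg.normalization.threshold
        )
        check_atlas_matches(C, atlas)
        connectomes[(rec.subject_id, rec.scan)] = C
    return cohort, atlas, connectomes


def compute_profiles(cohort: Cohort, connectomes: dict, offset: float = 1.0):
    """Per-node controllability profiles (long format) and the per-subject
    whole-brain table, which also carries covariates for later stages."""
    prof_rows, wb_rows = [], []
    for rec in cohort.records:
        C = connectomes[(rec.subject_id, rec.scan)]
        pr = profile(C, offset=offset)
        for j, node in enumerate(pr.node_ids):
            prof_rows.append(
                {
                    "subject_id": rec.subject_id,
                    "scan": rec.scan,
                    "node_id": node,
                    "avg": pr.avg[j],
                    "modal": pr.modal[j],
                }
            )
        wb = {
            "subject_id": rec.subject_id,
            "scan": rec.scan,
            "group": rec.group,
            "pma_weeks": rec.pma_weeks,
            "sex": rec.sex,
            "brain_volume": rec.brain_volume,
            "motion_translation": rec.motion_translation,
            "motion_rotation": rec.motion_rotation,
            "outlier_ratio": rec.outlier_ratio,
            "network_strength": float(C.strengths().mean()),
            "network_density": C.density(),
            "wb_avg": pr.whole_brain_avg,
            "wb_modal": pr.whole_brain_modal,
        }
        for k in ("bsid_cognition", "bsid_language", "bsid_motor"):
            wb[k] = getattr(rec, k, None)
        wb_rows.append(wb)
    return pd.DataFrame(prof_rows), pd.DataFrame(wb_rows)


_WINDOWS = (("preterm", "birth"), ("preterm", "TEA"), ("term", "TEA"))


def stage_development(wb: pd.DataFrame):
    """Whole-brain development rates per (group, scan) window, their
    pairwise Fisher-z comparisons, plus avg-modal coupling per window."""
    rates, couplings = [], []
    for group, scan in _WINDOWS:
        sub = wb[(wb["group"] == group) & (wb["scan"] == scan)]
        if len(sub) < 3:
            continue
        for metric in ("wb_avg", "wb_modal"):
            try:
                r, p = pearson(sub[metric], sub["pma_weeks"])
            except DegenerateInputError:
                r, p = np.nan, np.nan
            rates.append(
                {"group": group, "scan": scan, "metric": metric,
                 "r": r, "p": p, "n": len(sub)}
            )
        try:
            r, p = pearson(sub["wb_avg"], sub["wb_modal"])
            couplings.append(
                {"group": group, "scan": scan, "r_avg_modal": r, "p": p, "n": len(sub)}
            )
        except DegenerateInputError:
            pass
    rates = pd.DataFrame(rates)

    comparisons = []

    def compare(metric, g1, s1, g2, s2):
        a = rates[(rates["group"] == g1) & (rates["scan"] == s1) & (rates["metric"] == metric)]
        b = rates[(rates["group"] == g2) & (rates["scan"] == s2) & (rates["metric"] == metric)]
        if len(a) != 1 or len(b) != 1:
            return
        a, b = a.iloc[0], b.iloc[0]
        if not (np.isfinite(a["r"]) and np.isfinite(b["r"])):
            return
        if a["n"] <= 3 or b["n"] <= 3:  # Fisher z needs n > 3 per window
            return
        cc = compare_correlations(a["r"], int(a["n"]), b["r"], int(b["n"]))
        comparisons.append(
            {
                "metric": metric,
                "window1": f"{g1}:{s1}",
                "window2": f"{g2}:{s2}",
                "r1": cc.r1, "n1": cc.n1, "r2": cc.r2, "n2": cc.n2,
                "z": cc.z, "p_one_sided": cc.p_one_sided,
                "p_two_sided": cc.p_two_sided,
            }
        )

    for metric in ("wb_avg", "wb_modal"):
        compare(metric, "preterm", "birth", "preterm", "TEA")
        compare(metric, "preterm", "TEA", "term", "TEA")
    return rates, pd.DataFrame(comparisons), pd.DataFrame(couplings)


def _covariate_matrix(wb: pd.DataFrame, names) -> pd.DataFrame | None:
    if not names:
        return None
    cols = {}
    for name in names:
        if name == "sex":
            cols["sex"] = (wb["sex"].astype(str) == "female").astype(float)
        else:
            cols[name] = wb[name].astype(float)
    return pd.DataFrame(cols, index=wb.index)


def stage_group_tests(profiles: pd.DataFrame, wb: pd.DataFrame, covariates, q: float):
    """Term vs preterm-at-TEA tests: whole-brain t and regional FDR maps."""
    tea = wb[wb["scan"] == "TEA"].reset_index(drop=True)
    groups = tea["group"].to_numpy()
    if len(set(groups)) < 2:
        raise DegenerateInputError("need both term and preterm TEA records")
    X = _covariate_matrix(tea, covariates)

    wb_tests = {}
    for metric in ("wb_avg", "wb_modal"):
        resid = residualize(tea[metric].to_numpy(), X)
        t, df, p = two_sample_t(resid[groups == "term"], resid[groups == "preterm"])
        wb_tests[metric] = {"t": t, "df": df, "p": p,
                            "n_term": int((groups == "term").sum()),
                            "n_preterm": int((groups == "preterm").sum())}

    keys = tea[["subject_id", "scan"]]
    prof_tea = profiles.merge(keys, on=["subject_id", "scan"])
    node_ids = list(dict.fromkeys(prof_tea["node_id"]))
    regional = {}
    for metric in ("avg", "modal"):
        wide = prof_tea.pivot(index="subject_id", columns="node_id", values=metric)
        wide = wide.loc[tea["subject_id"], node_ids]
        results = regionwise_group_test(
            wide.to_numpy(), groups, node_ids, covariates=X, q=q,
            group_order=("term", "preterm"),
        )
        regional[metric] = region_results_frame(results)
    return wb_tests, regional["avg"], regional["modal"]


def stage_regional_rates(profiles: pd.DataFrame, wb: pd.DataFrame):
    """Per-node development rates per window and the preterm-TEA vs term
    comparison of regional rates."""
    rows = []
    merged = profiles.merge(
        wb[["subject_id", "scan", "group", "pma_weeks"]], on=["subject_id", "scan"]
    )
    for group, scan in _WINDOWS:
        sub = merged[(merged["group"] == group) & (merged["scan"] == scan)]
        if sub.empty:
            continue
        n = sub["subject_id"].nunique()
        if n < 4:
            continue
        for node, g in sub.groupby("node_id", sort=False):
            try:
                r, p = pearson(g["avg"], g["pma_weeks"])
            except DegenerateInputError:
                r, p = np.nan, np.nan
            rows.append({"group": group, "scan": scan, "node_id": node,
                         "r": r, "p": p, "n": n})
    rates = pd.DataFrame(rows)
    comps = []
    if not rates.empty:
        a = rates[(rates["group"] == "preterm") & (rates["scan"] == "TEA")]
        b = rates[(rates["group"] == "term") & (rates["scan"] == "TEA")]
        bi = b.set_index("node_id")
        for _, row in a.iterrows():
            if row["node_id"] not in bi.index:
                continue
            other = bi.loc[row["node_id"]]
            if not (np.isfinite(row["r"]) and np.isfinite(other["r"])):
                continue
            cc = compare_correlations(row["r"], int(row["n"]), other["r"], int(other["n"]))
            comps.append({"node_id": row["node_id"], "r_preterm": cc.r1,
                          "r_term": cc.r2, "z": cc.z,
                          "p_one_sided": cc.p_one_sided,
                          "p_two_sided": cc.p_two_sided})
    return rates, pd.DataFrame(comps)


def compute_energy(cohort: Cohort, atlas: Atlas, connectomes: dict, cfg: RunConfig):
    totals_rows, node_rows = [], []
    for rec in cohort.records:
        C = connectomes[(rec.subject_id, rec.scan)]
        table = network_energy_table(
            C,
            atlas,
            T=cfg.energy.T,
            n_grid=cfg.energy.n_grid,
            state_cost_on=cfg.energy.state_cost_on,
            offset=cfg.normalization.offset,
        )
        for nw, ep in table.items():
            totals_rows.append(
                {"subject_id": rec.subject_id, "scan": rec.scan,
                 "group": rec.group, "network": nw, "total": ep.total}
            )
            for node, e in zip(ep.node_ids, ep.per_node):
                node_rows.append(
                    {"subject_id": rec.subject_id, "scan": rec.scan,
                     "network": nw, "node_id": node, "energy": e}
                )
    return pd.DataFrame(totals_rows), pd.DataFrame(node_rows)


def stage_energy_group_tests(totals: pd.DataFrame, wb: pd.DataFrame, covariates, q: float):
    """Term vs preterm-at-TEA t-test of total activation energy per network."""
    tea = wb[wb["scan"] == "TEA"].reset_index(drop=True)
    groups = tea["group"].to_numpy()
    X = _covariate_matrix(tea, covariates)
    tot_tea = totals[totals["scan"] == "TEA"]
    networks = list(dict.fromkeys(tot_tea["network"]))
    wide = tot_tea.pivot(index="subject_id", columns="network", values="total")
    wide = wide.loc[tea["subject_id"], networks]
    results = regionwise_group_test(
        wide.to_numpy(), groups, networks, covariates=X, q=q,
        group_order=("term", "preterm"),
    )
    df = region_results_frame(results).rename(columns={"node_id": "network"})
    return df


def stage_nulls(cohort: Cohort, atlas: Atlas, connectomes: dict, cfg: RunConfig):
    rows = []
    records = cohort.records[: cfg.nulls.n_subjects]
    for i, rec in enumerate(records):
        C = connectomes[(rec.subject_id, rec.scan)]
        df = energy_vs_null(
            C,
            atlas,
            n_null=cfg.nulls.n_null,
            seed=cfg.seed + 1000 * (i + 1),
            n_swaps_per_edge=cfg.nulls.n_swaps_per_edge,
            T=cfg.energy.T,
            n_grid=cfg.energy.n_grid,
            state_cost_on=cfg.energy.state_cost_on,
        )
        df.insert(0, "subject_id", rec.subject_id)
        df.insert(1, "scan", rec.scan)
        rows.append(df)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()


def stage_outcomes(wb: pd.DataFrame):
    """Whole-brain controllability vs developmental outcome scores (TEA)."""
    out = {}
    tea = wb[wb["scan"] == "TEA"]
    for score in ("bsid_cognition", "bsid_language", "bsid_motor"):
        sub = tea.dropna(subset=[score])
        if len(sub) < 3:
            continue
        entry = {}
        for metric in ("wb_avg", "wb_modal"):
            try:
                r, p = pearson(sub[metric], sub[score])
            except DegenerateInputError:
                continue
            entry[metric] = {"r": r, "p": p, "n": len(sub)}
        if entry:
            out[score] = entry
    return out


# ---------------------------------------------------------------------------
# orchestration


def run_all(cfg: RunConfig) -> RunManifest:
    out = Path(cfg.paths.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg, out)
    manifest = RunManifest(config=cfg.to_dict())
    t0 = time.time()

    def record(name: str, path: Path):
        manifest.outputs[name] = _sha256(path)
        manifest.timestamps[name] = round(time.time() - t0, 3)

    log.info("stage: load inputs")
    cohort, atlas, connectomes = load_inputs(cfg)
    for name in ("cohort", "atlas"):
        manifest.inputs[name] = _sha256(getattr(cfg.paths, name))

    log.info("stage: controllability profiles (%d records)", len(cohort))
    profiles, wb = compute_profiles(cohort, connectomes, offset=cfg.normalization.offset)
    _write_tsv(profiles, out / "profiles.tsv")
    _write_tsv(wb, out / "whole_brain.tsv")
    record("profiles.tsv", out / "profiles.tsv")
    record("whole_brain.tsv", out / "whole_brain.tsv")

    log.info("stage: development rates")
    rates, comparisons, couplings = stage_development(wb)
    _write_tsv(rates, out / "development_rates.tsv")
    _write_tsv(comparisons, out / "rate_comparisons.tsv")
    _write_tsv(couplings, out / "avg_modal_coupling.tsv")
    record("development_rates.tsv", out / "development_rates.tsv")
    record("rate_comparisons.tsv", out / "rate_comparisons.tsv")
    record("avg_modal_coupling.tsv", out / "avg_modal_coupling.tsv")

    reg_rates, reg_comps = stage_regional_rates(profiles, wb)
    _write_tsv(reg_rates, out / "regional_rates.tsv")
    _write_tsv(reg_comps, out / "regional_rate_comparisons.tsv")
    record("regional_rates.tsv", out / "regional_rates.tsv")
    record("regional_rate_comparisons.tsv", out / "regional_rate_comparisons.tsv")

    has_both = bool(cohort.by_group("term", "TEA")) and bool(cohort.by_group("preterm", "TEA"))
    if has_both:
        log.info("stage: group tests")
        wb_tests, reg_avg, reg_modal = stage_group_tests(
            profiles, wb, cfg.stats.covariates, cfg.stats.q
        )
        (out / "whole_brain_tests.json").write_text(
            json.dumps(wb_tests, indent=2, sort_keys=True)
        )
        _write_tsv(reg_avg, out / "group_tests_avg.tsv")
        _write_tsv(reg_modal, out / "group_tests_modal.tsv")
        record("whole_brain_tests.json", out / "whole_brain_tests.json")
        record("group_tests_avg.tsv", out / "group_tests_avg.tsv")
        record("group_tests_modal.tsv", out / "group_tests_modal.tsv")
    else:
        msg = "group-difference stages skipped: need both term and preterm TEA records"
        log.info(msg)
        manifest.notices.append(msg)

    log.info("stage: control energy (%d records)", len(cohort))
    totals, node_energy = compute_energy(cohort, atlas, connectomes, cfg)
    _write_tsv(totals, out / "energy_totals.tsv")
    _write_tsv(node_energy, out / "energy_nodes.tsv")
    record("energy_totals.tsv", out / "energy_totals.tsv")
    record("energy_nodes.tsv", out / "energy_nodes.tsv")

    if has_both:
        energy_tests = stage_energy_group_tests(totals, wb, cfg.stats.covariates, cfg.stats.q)
        _write_tsv(energy_tests, out / "energy_group_tests.tsv")
        record("energy_group_tests.tsv", out / "energy_group_tests.tsv")

    if cfg.nulls.n_null >= 2 and cfg.nulls.n_subjects > 0:
        log.info("stage: null-model comparisons")
        nulls_df = stage_nulls(cohort, atlas, connectomes, cfg)
        _write_tsv(nulls_df, out / "null_comparison.tsv")
        record("null_comparison.tsv", out / "null_comparison.tsv")

    outcomes = stage_outcomes(wb)
    if outcomes:
        log.info("stage: outcome correlations")
        (out / "outcome_correlations.json").write_text(
            json.dumps(outcomes, indent=2, sort_keys=True)
        )
        record("outcome_correlations.json", out / "outcome_correlations.json")
    else:
        manifest.notices.append("outcome correlations skipped: no outcome scores")

    manifest.write(out / "manifest.json")
    log.info("done in %.1f s", time.time() - t0)
    return manifest


def _setup_logging(cfg: RunConfig, out: Path) -> None:
    level = getattr(logging, str(cfg.log_level).upper(), logging.INFO)
    log.setLevel(level)
    # one run.log per output directory: replace any handler from a prior run
    for h in [h for h in log.handlers if isinstance(h, logging.FileHandler)]:
        h.close()
        log.removeHandler(h)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(type(h) is logging.StreamHandler for h in log.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(sh)
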