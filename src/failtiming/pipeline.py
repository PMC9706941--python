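"""End-to-end failure-timing analysis: cohort -> endpoints -> cut-points ->
early/late survival contrasts -> multivariable Cox tables -> adjusted
forest curves, behind a single reproducible configuration.

Every stage receives its own seed derived from the master seed by a fixed
offset, so stages can be re-run in isolation and the whole report is
byte-reproducible under an identical configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (COHORT_COLUMNS, COVARIATE_LEVELS, CohortParams,
                     default_params, generate_cohort, read_cohort)
from .cutpoint import CutpointScanner, split_failures
from .forest import HazardCurveForest, adjusted_group_curves
from .survival import (BackwardEliminatedCox, contingency_test,
                       derive_endpoints, km_estimate, logrank_test,
                       survival_at)

log = logging.getLogger("failtiming")

#: multivariable candidate covariates (baseline-table variable set)
DEFAULT_COX_CANDIDATES = [
    "sex", "histology", "age_group", "family_history", "t_stage", "n_stage",
    "overall_stage", "ebv_dna", "ic_cycles", "ccd_group",
]
DEFAULT_RSF_ADJUST = [
    "sex", "age_group", "smoking", "family_history", "t_stage", "n_stage",
    "ccd_group",
]

SEED_OFFSETS = {"simulate": 0, "cutpoint_lrf": 101, "cutpoint_df": 102,
                "rsf": 103, "rsf_profiles": 104}


@dataclass
class AnalysisConfig:
    """Pipeline configuration; loadable from YAML via :meth:`from_yaml`."""

    cohort_csv: str | None = None
    n_patients: int = 3000
    master_seed: int = 0
    cohort_params: dict | None = None  # full CohortParams override
    cutpoint_resamples: int = 1000
    cutpoint_method: str = "permutation"
    cutpoint_min_fraction: float = 0.10
    cutpoint_min_events: int = 5
    cutpoint_grid_min: int | None = None
    cutpoint_grid_max: int | None = None
    cox_candidates: list[str] = field(
        default_factory=lambda: list(DEFAULT_COX_CANDIDATES))
    cox_screen_alpha: float = 0.10
    cox_stay_alpha: float = 0.05
    cox_ties: str = "efron"
    rsf_trees: int = 1000
    rsf_mtry: int | None = None
    rsf_min_terminal_events: int = 15
    rsf_smoothing_window: int = 3
    rsf_horizon: int = 60
    rsf_group: str = "ccd_group"
    rsf_adjust: list[str] = field(
        default_factory=lambda: list(DEFAULT_RSF_ADJUST))
    rsf_max_profiles: int | None = 500
    output_dir: str | None = None

    def seed_for(self, stage: str) -> int:
        return int(self.master_seed) + SEED_OFFSETS[stage]

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sig10(x: float) -> float:
    """Stable 10-significant-digit representation for probabilities."""
    return float(f"{float(x):.10g}")


def validate_cohort(table: pd.DataFrame) -> list[dict]:
    """Schema and invariant checks; returns findings, never raises."""
    findings: list[dict] = []
    expected = list(COHORT_COLUMNS)
    missing = [c for c in expected if c not in table.columns]
    extra = [c for c in table.columns if c not in expected]
    for c in missing:
        findings.append({"row": None, "column": c, "message": "missing column"})
    for c in extra:
        findings.append({"row": None, "column": c, "message": "unexpected column"})
    if missing:
        return findings

    time_cols = ["t_locoregional", "t_distant", "t_death_or_lastcontact"]
    flag_cols = ["locoregional_event", "distant_event", "death"]
    numeric = {}
    for c in time_cols + flag_cols:
        col = pd.to_numeric(table[c], errors="coerce")
        numeric[c] = col
        for i in table.index[col.isna()]:
            findings.append({"row": int(i), "column": c,
                             "message": f"non-numeric value {table.at[i, c]!r}"})
    for c in time_cols:
        for i in table.index[numeric[c] < 0]:
            findings.append({"row": int(i), "column": c,
                             "message": "negative time"})
    for c in flag_cols:
        bad = ~numeric[c].isin([0, 1]) & numeric[c].notna()
        for i in table.index[bad]:
            findings.append({"row": int(i), "column": c,
                             "message": "event flag must be 0 or 1"})
    final = numeric["t_death_or_lastcontact"]
    for c, flag in (("t_locoregional", "locoregional_event"),
                    ("t_distant", "distant_event")):
        mask = (numeric[flag] == 1) & (numeric[c] > final + 1e-9)
        for i in table.index[mask.fillna(False)]:
            findings.append({"row": int(i), "column": c,
                             "message": "failure time after death/last contact"})
    for cov, levels in COVARIATE_LEVELS.items():
        bad = ~table[cov].astype(str).isin(levels)
        for i in table.index[bad]:
            findings.append({"row": int(i), "column": cov,
                             "message": f"unknown level {table.at[i, cov]!r}"})
    return findings


def _encode_candidates(df: pd.DataFrame, candidates: list[str]) -> pd.DataFrame:
    """Indicator contrasts against each covariate's reference (first) level."""
    cols = {}
    for cov in candidates:
        levels = COVARIATE_LEVELS.get(cov)
        if levels is None:
            raise ValueError(f"unknown candidate covariate {cov!r}")
        vals = df[cov].astype(str)
        for lv in levels[1:]:
            cols[f"{cov}={lv}"] = (vals == lv).astype(float)
    return pd.DataFrame(cols, index=df.index)


def _km_summary(times, events, horizons=(12, 36, 60)) -> dict:
    curve = km_estimate(times, events)
    return {
        "n": int(np.size(times)),
        "n_events": int(np.sum(events)),
        **{f"survival_{h}m": _sig10(survival_at(curve, h))
           for h in horizons},
    }


def _cox_table(fit) -> dict:
    return {
        "retained": [
            {
                "covariate": name,
                "coef": _sig10(c),
                "HR": _sig10(hr),
                "ci_lower": _sig10(lo),
                "ci_upper": _sig10(hi),
                "p": _sig10(p),
            }
            for name, c, hr, lo, hi, p in zip(
                fit.names, fit.coef, fit.hazard_ratio, fit.ci_lower,
                fit.ci_upper, fit.p_value)
        ],
        "eliminated": [
            {"covariate": name, "p_at_removal": _sig10(p)}
            for name, p in fit.elimination_trace
        ],
        "n": fit.n,
        "n_events": fit.n_events,
        "ties_method": fit.ties_method,
        "converged": bool(fit.converged),
    }


def _failure_cohort(cohort: pd.DataFrame, endpoints: pd.DataFrame,
                    kind: str) -> pd.DataFrame:
    """Failure patients for one endpoint: interval, post-failure time, death."""
    col = {"lrf": ("lrffs_time", "lrffs_event", "pf_lrf_time", "pf_lrf_event"),
           "df": ("dffs_time", "dffs_event", "pf_df_time", "pf_df_event")}[kind]
    t_col, e_col, pf_t, pf_e = col
    mask = endpoints[e_col] == 1
    return pd.DataFrame({
        "interval": endpoints.loc[mask, t_col].to_numpy(dtype=float),
        "post_time": endpoints.loc[mask, pf_t].to_numpy(dtype=float),
        "death": endpoints.loc[mask, pf_e].to_numpy(dtype=int),
    }, index=endpoints.index[mask])


def _composite_failure(cohort: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """First-failure endpoint (locoregional or distant; death censors)."""
    tl = cohort["t_locoregional"].to_numpy(dtype=float)
    td = cohort["t_distant"].to_numpy(dtype=float)
    to = cohort["t_death_or_lastcontact"].to_numpy(dtype=float)
    el = cohort["locoregional_event"].astype(bool).to_numpy()
    ed = cohort["distant_event"].astype(bool).to_numpy()
    t_fail = np.where(el, tl, np.inf)
    t_fail = np.minimum(t_fail, np.where(ed, td, np.inf))
    event = np.isfinite(t_fail)
    return np.where(event, t_fail, to), event


def run_pipeline(config: AnalysisConfig) -> dict:
    """Execute the full analysis; returns the report dict (and writes the
    report plus tidy CSV artifacts when ``config.output_dir`` is set)."""
    t_start = time.time()
    report: dict = {}
    warnings_acc: list[str] = []

    # --- stage: cohort -----------------------------------------------------
    if config.cohort_csv:
        cohort = read_cohort(config.cohort_csv)
        params = None
        source = {"type": "csv", "path": str(config.cohort_csv)}
    else:
        if config.cohort_params is not None:
            params = CohortParams.from_dict(config.cohort_params)
            params = dataclasses.replace(params, seed=config.seed_for("simulate"))
        else:
            params = default_params(n_patients=config.n_patients,
                                    seed=config.seed_for("simulate"))
        cohort = generate_cohort(params)
        source = {"type": "simulated", "n_patients": params.n_patients,
                  "seed": params.seed}
    findings = validate_cohort(cohort)
    hard = [f for f in findings if f["message"].startswith("missing")]
    if hard:
        raise ValueError(f"cohort schema mismatch: {hard}")
    if findings:
        raise ValueError(f"cohort failed validation with {len(findings)} "
                         f"finding(s); first: {findings[0]}")
    log.info("stage=cohort n=%d elapsed=%.2fs", len(cohort), time.time() - t_start)

    # --- stage: endpoints --------------------------------------------------
    endpoints = derive_endpoints(cohort)
    frac = {
        "locoregional": float(endpoints["lrffs_event"].mean()),
        "distant": float(endpoints["dffs_event"].mean()),
        "death": float(endpoints["os_event"].mean()),
        "any_failure_or_death": float(endpoints["ffs_event"].mean()),
    }
    report["event_summary"] = {
        "n_patients": int(len(cohort)),
        "event_fractions": {k: _sig10(v) for k, v in frac.items()},
        "median_followup_months": round(
            float(np.median(cohort["t_death_or_lastcontact"])), 6),
        "five_year": {
            name: round(100.0 * float(survival_at(
                km_estimate(endpoints[f"{name}_time"],
                            endpoints[f"{name}_event"]), 60.0)), 6)
            for name in ("os", "ffs", "lrffs", "dffs")
        },
    }

    # --- stage: baseline table --------------------------------------------
    group_col = config.rsf_group
    baseline = {}
    glevels = list(COVARIATE_LEVELS[group_col])
    for cov in COVARIATE_LEVELS:
        if cov == group_col:
            continue
        tab = pd.crosstab(cohort[cov].astype(str),
                          cohort[group_col].astype(str))
        tab = tab.reindex(columns=glevels, fill_value=0)
        try:
            res = contingency_test(tab.to_numpy())
            test = {"statistic": _sig10(res.statistic),
                    "p": _sig10(res.p_value), "method": res.method}
        except ValueError as exc:
            test = {"skipped": str(exc)}
        baseline[cov] = {
            "counts": {str(lv): [int(x) for x in row]
                       for lv, row in tab.iterrows()},
            "test": test,
        }
    report["baseline_table"] = {"group": group_col, "columns": glevels,
                                "covariates": baseline}

    # --- stage: cut-point scans -------------------------------------------
    cutoffs = {}
    report["cutpoint"] = {}
    report["postfailure_km"] = {}
    for kind, stage in (("lrf", "cutpoint_lrf"), ("df", "cutpoint_df")):
        fc = _failure_cohort(cohort, endpoints, kind)
        grid = None
        if config.cutpoint_grid_min is not None and config.cutpoint_grid_max is not None:
            grid = np.arange(config.cutpoint_grid_min,
                             config.cutpoint_grid_max + 1)
        scanner = CutpointScanner(
            grid=grid, min_fraction=config.cutpoint_min_fraction,
            min_events=config.cutpoint_min_events,
            n_resamples=config.cutpoint_resamples,
            method=config.cutpoint_method,
            random_state=config.seed_for(stage))
        scanner.fit(fc["interval"], fc["post_time"], fc["death"])
        warnings_acc.extend(scanner.scan_.warnings)
        cutoffs[kind] = scanner.selected_cutoff_
        report["cutpoint"][kind] = {
            "n_failures": int(len(fc)),
            "candidates": [int(c) for c in scanner.candidate_months_],
            "p_values": [_sig10(p) if np.isfinite(p) else None
                         for p in scanner.p_values_],
            "early_n": [int(a) for a in scanner.group_sizes_[:, 0]],
            "late_n": [int(b) for b in scanner.group_sizes_[:, 1]],
            "selected_cutoff": round(scanner.selected_cutoff_, 6),
            "min_p": _sig10(scanner.min_p_),
            "corrected_p": _sig10(scanner.corrected_p_),
            "n_resamples": config.cutpoint_resamples,
            "method": config.cutpoint_method,
        }
        labels = split_failures(fc["interval"], scanner.selected_cutoff_)
        early = labels == "early"
        lr = logrank_test((fc["post_time"][early], fc["death"][early]),
                          (fc["post_time"][~early], fc["death"][~early]))
        report["postfailure_km"][kind] = {
            "early": _km_summary(fc["post_time"][early], fc["death"][early]),
            "late": _km_summary(fc["post_time"][~early], fc["death"][~early]),
            "logrank_p": _sig10(lr.p_value),
        }
        log.info("stage=cutpoint_%s cutoff=%s elapsed=%.2fs", kind,
                 scanner.selected_cutoff_, time.time() - t_start)

    # --- stage: treatment-group KM ----------------------------------------
    gvals = cohort[group_col].astype(str)
    report["group_km"] = {}
    for name in ("os", "ffs", "lrffs", "dffs"):
        t = endpoints[f"{name}_time"]
        e = endpoints[f"{name}_event"]
        lr = logrank_test(*[(t[gvals == g], e[gvals == g]) for g in glevels])
        report["group_km"][name] = {
            "groups": {g: _km_summary(t[gvals == g], e[gvals == g])
                       for g in glevels},
            "logrank_p": _sig10(lr.p_value),
        }

    # --- stage: Cox tables -------------------------------------------------
    X = _encode_candidates(cohort, config.cox_candidates)
    cox_inputs: dict[str, tuple] = {
        name: (endpoints[f"{name}_time"].to_numpy(dtype=float),
               endpoints[f"{name}_event"].to_numpy(dtype=int))
        for name in ("os", "ffs", "lrffs", "dffs")
    }
    for kind, short in (("lrf", "lrffs"), ("df", "dffs")):
        cut = cutoffs[kind]
        t = endpoints[f"{short}_time"].to_numpy(dtype=float)
        e = endpoints[f"{short}_event"].to_numpy(dtype=int)
        # early endpoint: administrative censoring at the cut-off
        cox_inputs[f"e{short}"] = (np.minimum(t, cut),
                                   ((e == 1) & (t <= cut)).astype(int))
        # late endpoint: landmark cohort of patients event-free at the cut-off
        at_risk = t > cut
        cox_inputs[f"l{short}"] = (t[at_risk], e[at_risk], at_risk)
    report["cox_tables"] = {}
    for name, data in cox_inputs.items():
        if len(data) == 3:
            t, e, mask = data
            Xsub = X[mask]
        else:
            t, e = data
            Xsub = X
        if e.sum() == 0:
            report["cox_tables"][name] = {"skipped": "no events"}
            continue
        est = BackwardEliminatedCox(
            screen_alpha=config.cox_screen_alpha,
            stay_alpha=config.cox_stay_alpha, ties=config.cox_ties)
        est.fit(Xsub, t, e)
        report["cox_tables"][name] = _cox_table(est.result_)
    log.info("stage=cox tables=%d elapsed=%.2fs", len(report["cox_tables"]),
             time.time() - t_start)

    # --- stage: RSF adjusted curves ---------------------------------------
    t_fail, e_fail = _composite_failure(cohort)
    forest = HazardCurveForest(
        n_trees=config.rsf_trees, mtry=config.rsf_mtry,
        min_terminal_events=config.rsf_min_terminal_events,
        random_state=config.seed_for("rsf"))
    forest.fit(cohort[config.rsf_adjust], t_fail, e_fail)
    grid = np.arange(0, config.rsf_horizon + 1)
    curves = adjusted_group_curves(
        forest, cohort[config.rsf_adjust], group_col, grid,
        smoothing_window=config.rsf_smoothing_window,
        max_profiles=config.rsf_max_profiles,
        random_state=config.seed_for("rsf_profiles"))
    report["rsf_curves"] = {
        "endpoint": "first treatment failure (death censors)",
        "time_grid": [int(m) for m in grid],
        "adjustment_covariates": curves.adjustment_covariates,
        "smoothing_window": config.rsf_smoothing_window,
        "n_trees": config.rsf_trees,
        "cumulative": {g: [_sig10(v) for v in F]
                       for g, F in curves.cumulative.items()},
        "monthly": {g: [_sig10(v) for v in f]
                    for g, f in curves.monthly.items()},
    }
    log.info("stage=rsf trees=%d elapsed=%.2fs", config.rsf_trees,
             time.time() - t_start)

    # --- provenance --------------------------------------------------------
    cfg = config.to_dict()
    cfg_json = json.dumps(cfg, sort_keys=True)
    report["provenance"] = {
        "package": "failtiming",
        "version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stage_seeds": {s: config.seed_for(s) for s in SEED_OFFSETS},
        "cohort_source": source,
        "warnings": warnings_acc,
    }

    if config.output_dir:
        _write_artifacts(Path(config.output_dir), report, cohort, params)
    return report


def _write_artifacts(outdir: Path, report: dict, cohort: pd.DataFrame,
                     params: CohortParams | None) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    cohort.to_csv(outdir / "cohort.csv", index=False, float_format="%.6f")
    if params is not None:
        with open(outdir / "cohort.params.json", "w") as fh:
            json.dump(params.to_dict(), fh, indent=2, sort_keys=True)
    for kind in ("lrf", "df"):
        cp = report["cutpoint"][kind]
        pd.DataFrame({
            "candidate_month": cp["candidates"],
            "p_value": cp["p_values"],
            "early_n": cp["early_n"],
            "late_n": cp["late_n"],
        }).to_csv(outdir / f"cutpoint_scan_{kind}.csv", index=False)
    rc = report["rsf_curves"]
    rows = []
    for g in rc["cumulative"]:
        for m, F, f in zip(rc["time_grid"], rc["cumulative"][g],
                           rc["monthly"][g]):
            rows.append((g, m, F, f))
    pd.DataFrame(rows, columns=["group", "month", "cumulative", "monthly"]) \
        .to_csv(outdir / "rsf_curves.csv", index=False)
    rows = []
    for name, tab in report["cox_tables"].items():
        for entry in tab.get("retained", []):
            rows.append({"endpoint": name, **entry})
    pd.DataFrame(rows).to_csv(outdir / "cox_tables.csv", index=False)
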