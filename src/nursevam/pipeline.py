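"""End-to-end orchestration: simulate/ingest -> assemble -> split -> fit ->
margins -> diagnostics -> validation -> power, with every stage artifact
written to an output directory and recorded in a run manifest.

A single global seed fans out to per-stage seeds through the documented rule
``stage_seed(k) = (seed * 1000003 + k) mod 2^31`` so that stages can be
re-run in isolation and two runs with the same seed produce byte-identical
CSV artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import AssembledCohort, apply_exclusions, build_design_matrix, label_outcomes, split_sample
from .exceptions import NurseVamError, SchemaError
from .power import PowerSpec, achieved_power, min_encounters_per_nurse
from .rates import (
    assign_quartiles,
    event_rate_percent,
    plot_rate_distribution,
    project_avoidable_cases,
    summarize_distribution,
)
from .simulate import RawEhrExtract, SimulationConfig, draw_nurse_effects, simulate_cohort
from .validation import (
    assignment_balance_tests,
    cluster_nurses,
    plot_cross_validation,
    transition_matrix,
    weighted_rate_correlation,
)
from .vam import CaabuVam, auc_comparison


def stage_seed(seed: int, k: int) -> int:
    return (int(seed) * 1000003 + k) % (2**31)


@dataclass
class PipelineConfig:
    """Exactly one of ``simulation`` / ``input_dir`` selects the data source."""

    simulation: SimulationConfig | None = None
    input_dir: str | None = None
    cutoff: str | None = None  # split date; default = midpoint of the span
    window_min_h: float = 24.0
    window_max_h: float = 48.0
    min_encounters_per_nurse: int = 45
    penalty: float | None = None
    cluster_level: str = "patient"
    margin_mode: str = "zero"
    k_clusters: int = 4
    cluster_max_iter: int = 10000
    bootstrap_reps: int = 999
    output_dir: str = "nursevam_out"
    seed: int = 0

    def __post_init__(self):
        if (self.simulation is None) == (self.input_dir is None):
            raise NurseVamError(
                "config must set exactly one of {simulation, input_dir}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return d


REQUIRED_COLUMNS = {
    "patients.csv": [
        "patient_id", "age", "sex", "mdc", "insurance", "admission_type",
        "prior_admission_30d", "unit", "icu_admit_time", "icu_discharge_time",
    ],
    "assignments.csv": ["patient_id", "nurse_id", "shift_date", "shift_kind"],
    "events.csv": ["patient_id", "event_time", "event_kind", "confirmed"],
}
_TS_COLS = {
    "patients.csv": ["icu_admit_time", "icu_discharge_time"],
    "assignments.csv": ["shift_date"],
    "events.csv": ["event_time"],
}


def validate_schema(input_dir: str | Path) -> list[dict]:
    """Column/type/referential checks on the three raw tables.

    Returns diagnostics dicts with keys level ("error"/"warning"), table,
    message, and rows (offending row indices, truncated).
    """
    input_dir = Path(input_dir)
    diags: list[dict] = []
    tables: dict[str, pd.DataFrame] = {}
    for fname, cols in REQUIRED_COLUMNS.items():
        fp = input_dir / fname
        if not fp.exists():
            diags.append({"level": "error", "table": fname, "message": "file missing", "rows": []})
            continue
        df = pd.read_csv(fp)
        tables[fname] = df
        for c in cols:
            if c not in df.columns:
                diags.append(
                    {"level": "error", "table": fname, "message": f"missing required column {c!r}", "rows": []}
                )
        for c in _TS_COLS[fname]:
            if c in df.columns:
                parsed = pd.to_datetime(df[c], errors="coerce", format="ISO8601")
                bad = df.index[parsed.isna() & df[c].notna()].tolist()
                if bad:
                    diags.append(
                        {
                            "level": "error",
                            "table": fname,
                            "message": f"column {c!r} has non-ISO-8601 timestamps",
                            "rows": bad[:20],
                        }
                    )
    if "patients.csv" in tables:
        known = set(tables["patients.csv"].get("patient_id", []))
        for fname in ("assignments.csv", "events.csv"):
            df = tables.get(fname)
            if df is not None and "patient_id" in df.columns:
                bad = df.index[~df["patient_id"].isin(known)].tolist()
                if bad:
                    diags.append(
                        {
                            "level": "error",
                            "table": fname,
                            "message": "patient_id not present in patients.csv (referential integrity)",
                            "rows": bad[:20],
                        }
                    )
        if "prior_admission_30d" in tables["patients.csv"].columns:
            vals = set(tables["patients.csv"]["prior_admission_30d"].unique())
            if not vals <= {0, 1}:
                diags.append(
                    {"level": "warning", "table": "patients.csv",
                     "message": "prior_admission_30d has values outside {0, 1}", "rows": []}
                )
    return diags


def _fit_half(cohort: AssembledCohort, cfg: PipelineConfig, ref_seed: int):
    design = build_design_matrix(cohort, ref_seed=ref_seed)
    res = CaabuVam(design).fit(penalty=cfg.penalty, cluster_level=cfg.cluster_level)
    margins = res.nurse_margins(mode=cfg.margin_mode)
    return design, res, margins


class _Stage:
    """Context wrapper tagging any failure with its pipeline stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None and isinstance(exc, Exception):
            raise NurseVamError(f"[stage: {self.name}] {exc}") from exc
        return False


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, writing artifacts under ``config.output_dir``.

    Returns a dict of in-memory results keyed by stage; the ``manifest.json``
    in the output directory lists every artifact path, the fanned-out seeds,
    and the package version.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seed)
    artifacts: dict[str, str] = {}
    results: dict = {}

    with _Stage("simulate"):
        if config.simulation is not None:
            sim_cfg = dataclasses.replace(config.simulation, seed=stage_seed(seed, 0))
            effects = draw_nurse_effects(sim_cfg)
            extract = simulate_cohort(sim_cfg, effects)
            extract.to_dir(out / "extract")
            effects.to_csv(out / "extract" / "nurse_effects.csv", index=False)
            artifacts["extract"] = str(out / "extract")
            results["effects"] = effects
        else:
            diags = validate_schema(config.input_dir)
            errors = [d for d in diags if d["level"] == "error"]
            if errors:
                raise SchemaError(f"input schema invalid: {errors[:3]}")
            extract = RawEhrExtract.from_dir(config.input_dir)
        results["extract"] = extract

    with _Stage("assemble"):
        encounters = label_outcomes(extract, config.window_min_h, config.window_max_h)
        cohort = apply_exclusions(
            encounters,
            extract.event_table,
            min_encounters_per_nurse=config.min_encounters_per_nurse,
            float_nurses=extract.float_nurses,
        )
        cohort.to_csv(out / "cohort.csv")
        cohort.write_exclusion_log(out / "exclusion_log.json")
        artifacts["cohort"] = str(out / "cohort.csv")
        results["cohort"] = cohort

    with _Stage("split"):
        if config.cutoff is not None:
            cutoff = pd.Timestamp(config.cutoff)
        else:
            d = pd.to_datetime(cohort.encounters["icu_discharge_time"])
            cutoff = (d.min() + (d.max() - d.min()) / 2).normalize()
        est, val = split_sample(cohort, cutoff)
        est.to_csv(out / "cohort_estimation.csv")
        val.to_csv(out / "cohort_validation.csv")
        results["est"], results["val"], results["cutoff"] = est, val, cutoff

    with _Stage("fit"):
        design_e, fit_e, margins_e = _fit_half(est, config, stage_seed(seed, 1))
        design_v, fit_v, margins_v = _fit_half(val, config, stage_seed(seed, 2))
        margins_e.to_csv(out / "nurse_rates_estimation.csv", index=False)
        margins_v.to_csv(out / "nurse_rates_validation.csv", index=False)
        fit_e.coefficient_table().to_csv(out / "vam_coefficients_estimation.csv", index=False)
        fit_v.coefficient_table().to_csv(out / "vam_coefficients_validation.csv", index=False)
        (out / "vam_summary_estimation.txt").write_text(fit_e.summary())
        results.update(
            fit_estimation=fit_e, fit_validation=fit_v,
            rates_estimation=margins_e, rates_validation=margins_v,
        )

    with _Stage("tests"):
        joint = fit_e.joint_nurse_test()
        auc = auc_comparison(
            design_e, cluster_level=config.cluster_level,
            n_boot=config.bootstrap_reps, seed=stage_seed(seed, 3),
        )
        results["joint_test"], results["auc"] = joint, auc

    with _Stage("distribution"):
        summary = summarize_distribution(margins_e)
        quart_e = assign_quartiles(margins_e)
        quart_v = assign_quartiles(margins_v)
        plot_rate_distribution(margins_e, out / "fig1_rate_distribution.png")
        results.update(distribution=summary, quartiles_estimation=quart_e, quartiles_validation=quart_v)

        est_patients = set(est.encounters["patient_id"])
        caabu = extract.event_table
        caabu = caabu[(caabu["event_kind"] == "caabu") & (caabu["confirmed"] == 1)]
        observed = len(est_patients & set(caabu["patient_id"]))
        link_counts = est.nurse_link_counts()
        projection = None
        if observed > 0:
            projection = project_avoidable_cases(
                margins_e, quart_e,
                shifts_per_nurse=float(link_counts.mean()),
                observed_cases=observed,
            )
        results["avoidable"] = projection
        results["observed_cases_estimation"] = observed
        results["event_rate_pct_estimation"] = event_rate_percent(observed, est.n_patients)

    with _Stage("validation"):
        balance = assignment_balance_tests(margins_e, val)
        corr = weighted_rate_correlation(margins_e, margins_v)
        clusters = cluster_nurses(
            margins_e, margins_v, k=config.k_clusters, init=quart_e,
            max_iter=config.cluster_max_iter, seed=stage_seed(seed, 4),
        )
        weights = (
            margins_e.set_index("nurse_id")["n_encounters"]
            .add(margins_v.set_index("nurse_id")["n_encounters"], fill_value=0)
        )
        tm = transition_matrix(quart_e, quart_v, weights)
        tm.to_frame().to_csv(out / "transition_matrix.csv")
        clusters.assignments.to_csv(out / "clusters.csv", index=False)
        plot_cross_validation(margins_e, margins_v, clusters, out / "fig2_cross_validation.png")
        (out / "balance_report.json").write_text(json.dumps(balance.to_dict(), indent=2))
        results.update(balance=balance, correlation=corr, clusters=clusters, transitions=tm)

    with _Stage("power"):
        obs_rate = results["event_rate_pct_estimation"] / 100.0
        p_null = obs_rate / 2.0 if 0 < obs_rate < 1 else 0.05705
        spec = PowerSpec(p_null=p_null)
        n_min = min_encounters_per_nurse(spec)
        power_block = {
            "p_null": p_null,
            "p_alt": spec.p_alt,
            "alpha": spec.alpha,
            "target_power": spec.power,
            "min_encounters_per_nurse": n_min,
            "achieved_power_at_min": achieved_power(spec, n_min),
        }
        results["power"] = power_block

    with _Stage("report"):
        report = {
            "version": __version__,
            "seed": seed,
            "stage_seeds": {f"stage_{k}": stage_seed(seed, k) for k in range(5)},
            "cutoff": str(results["cutoff"].date()),
            "n_encounters": {"estimation": est.n_encounters, "validation": val.n_encounters},
            "n_patients": {"estimation": est.n_patients, "validation": val.n_patients},
            "n_nurses": {"estimation": len(est.nurse_roster), "validation": len(val.nurse_roster)},
            "event_rate_pct_estimation": results["event_rate_pct_estimation"],
            "joint_nurse_test": results["joint_test"].to_dict(),
            "auc": {
                "restricted": results["auc"].auc_restricted,
                "full": results["auc"].auc_full,
                "p_one_sided": results["auc"].test.p_value,
            },
            "rate_distribution": results["distribution"].to_dict(),
            "weighted_correlation": results["correlation"].to_dict(),
            "avoidable_cases": results["avoidable"].to_dict() if results["avoidable"] else None,
            "power": results["power"],
            "artifacts": artifacts,
        }
        (out / "manifest.json").write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
        results["report"] = report

    return results
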