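"""Seeded synthetic shift-level EHR extracts for two ICUs.

The generator emulates the data-generating process the downstream analysis
assumes: patients arrive at a medical and a neurological ICU, stay for a
geometric number of 12-hour shifts (07:00-19:00 day, 19:00-07:00 night), and
are cared for by roughly one nurse per two patients.  Each patient carries a
latent per-encounter hazard of a confirmed catheter-associated asymptomatic
bacteriuria (CAABU) event, driven by patient covariates plus the mean latent
prevention effect of the nurses assigned to the encounter.  A patient's first
event is the only one; the laboratory report is time-stamped uniformly 24-48
hours after the end of the triggering shift, which is exactly the attribution
window the cohort module uses for outcome labeling.

Everything is deterministic given ``SimulationConfig.seed``: identical configs
produce byte-identical extracts.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigurationError, SimulationError

UNITS = ("medical", "neurological")

#: Marginal distributions matched to the study population: 55% male, age 60
#: (SD 16.6), ~52% surgical admissions, and the published insurance and Major
#: Diagnostic Category (MDC) mixes.  "Missing" is a real 22nd MDC level
#: (ungroupable MS-DRG codes), not absent data.
MDC_CATEGORIES: tuple[str, ...] = (
    "DDs of Nervous System",
    "DDs of Eye",
    "DDs of Ear, Nose, Mouth And Throat",
    "DDs of Respiratory System",
    "DDs of Circulatory System",
    "DDs of Digestive System",
    "DDs of Hepatobiliary System And Pancreas",
    "DDs of Musculoskeletal System And Connective Tissue",
    "DDs of Skin, Subcutaneous Tissue And Breast",
    "DDs of Endocrine, Nutritional And Metabolic System",
    "DDs of Kidney And Urinary Tract",
    "Pregnancy, Childbirth And Puerperium",
    "DDs of Blood and Blood Forming Organs and Immunological Disorders",
    "Myeloproliferative DDs",
    "Infectious and Parasitic DDs",
    "Mental DDs",
    "Alcohol/Drug Use or Induced Mental DDs",
    "Injuries, Poison And Toxic Effect of Drugs",
    "Factors Influencing Health Status",
    "Multiple Significant Trauma",
    "Human Immunodeficiency Virus Infection",
    "Missing",
)

_MDC_COUNTS = np.array(
    [314, 1, 20, 102, 86, 36, 36, 93, 2, 24, 16, 3, 10, 27, 97, 1, 5, 27, 2, 3, 8, 174],
    dtype=float,
)
MDC_PROBS = _MDC_COUNTS / _MDC_COUNTS.sum()

INSURANCE_CATEGORIES = ("private", "medicaid", "medicare", "other", "uninsured")
INSURANCE_PROBS = np.array([0.3163, 0.4940, 0.1564, 0.0230, 0.0103])
INSURANCE_PROBS = INSURANCE_PROBS / INSURANCE_PROBS.sum()

#: Default covariate effects on the EVENT log-odds; continuous covariates enter
#: centered (age at 60 years, ICU dwell time at 60 hours) so the baseline
#: log-odds is interpretable as the hazard of an average encounter.
DEFAULT_COVARIATE_EFFECTS: Mapping[str, float] = {
    "age_per_year": 0.015,
    "male": 0.10,
    "surgical": -0.10,
    "prior_admission_30d": 0.25,
    "micu": 0.15,
    "day_shift": 0.0,
    "hours_in_icu_per_hour": 0.002,
    "mdc:DDs of Kidney And Urinary Tract": 0.30,
}

AGE_MEAN, AGE_SD = 60.0, 16.6
SHIFT_HOURS = 12
DAY_SHIFT_START_HOUR = 7  # 07:00; the night shift starts at 19:00


def _per_unit(value, unit: str, name: str):
    """Resolve a scalar-or-mapping config field for one unit."""
    if isinstance(value, Mapping):
        try:
            return value[unit]
        except KeyError as exc:
            raise ConfigurationError(f"{name} missing entry for unit {unit!r}") from exc
    return value


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic extract.

    Defaults are sized to the source study: two ICUs (19 + 16 beds,
    57 + 53 nurses), 365 days in two consecutive ~6-month halves, mean ICU
    length of stay 5.5 (medical) / 4.6 (neurological) days, a 1:2
    nurse-to-patient ratio, and a baseline hazard calibrated so that ~11-12%
    of patients develop a confirmed CAABU event.
    """

    n_nurses_per_unit: int | Mapping[str, int] = field(
        default_factory=lambda: {"medical": 57, "neurological": 53}
    )
    n_beds_per_unit: int | Mapping[str, int] = field(
        default_factory=lambda: {"medical": 19, "neurological": 16}
    )
    n_days: int = 365
    shift_hours: int = SHIFT_HOURS
    nurse_effect_sd: float = 0.3
    baseline_event_logodds: float = -4.55
    covariate_effect_map: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    patients_per_nurse: float = 2.0
    mean_icu_los_days: float | Mapping[str, float] = field(
        default_factory=lambda: {"medical": 5.5, "neurological": 4.6}
    )
    assignment_bias: float = 0.0
    target_occupancy: float = 0.85
    two_nurse_frac: float = 0.05
    n_float_nurses: int = 3
    float_shift_frac: float = 0.05
    prior_event_frac: float = 0.016
    cauti_frac: float = 0.012
    unconfirmed_event_frac: float = 0.01
    start_date: str = "2015-07-01"
    seed: int = 0

    def __post_init__(self):
        for unit in UNITS:
            for name in ("n_nurses_per_unit", "n_beds_per_unit"):
                v = _per_unit(getattr(self, name), unit, name)
                if not (isinstance(v, (int, np.integer)) and v > 0):
                    raise ConfigurationError(f"{name}[{unit}] must be a positive count, got {v!r}")
            los = _per_unit(self.mean_icu_los_days, unit, "mean_icu_los_days")
            if not los > 0:
                raise ConfigurationError(f"mean_icu_los_days[{unit}] must be positive")
        if self.n_days <= 0:
            raise ConfigurationError("n_days must be positive")
        if self.shift_hours != SHIFT_HOURS:
            raise ConfigurationError("shift_hours is fixed at 12")
        if self.nurse_effect_sd < 0:
            raise ConfigurationError("nurse_effect_sd must be >= 0")
        if abs(self.assignment_bias) > 1:
            raise ConfigurationError("assignment_bias must lie in [-1, 1]")
        if self.patients_per_nurse <= 0:
            raise ConfigurationError("patients_per_nurse must be positive")
        if not 0 < self.target_occupancy <= 1:
            raise ConfigurationError("target_occupancy must lie in (0, 1]")
        for name in ("two_nurse_frac", "float_shift_frac", "prior_event_frac",
                     "cauti_frac", "unconfirmed_event_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_float_nurses < 0:
            raise ConfigurationError("n_float_nurses must be >= 0")

    @property
    def n_shifts(self) -> int:
        return 2 * self.n_days

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariate_effect_map"] = dict(self.covariate_effect_map)
        for key in ("n_nurses_per_unit", "n_beds_per_unit", "mean_icu_los_days"):
            if isinstance(d[key], Mapping):
                d[key] = dict(d[key])
        return d


@dataclass
class RawEhrExtract:
    """The three canonical tables plus provenance.

    patient_table:    patient_id, age, sex, mdc, insurance, admission_type,
                      prior_admission_30d, unit, icu_admit_time, icu_discharge_time
    assignment_table: patient_id, nurse_id, shift_date, shift_kind
    event_table:      patient_id, event_time, event_kind, confirmed
    """

    patient_table: pd.DataFrame
    assignment_table: pd.DataFrame
    event_table: pd.DataFrame
    float_nurses: tuple[str, ...] = ()
    manifest: dict = field(default_factory=dict)

    def to_dir(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        ts = "%Y-%m-%dT%H:%M:%S"
        self.patient_table.to_csv(path / "patients.csv", index=False, date_format=ts)
        self.assignment_table.to_csv(path / "assignments.csv", index=False, date_format=ts)
        self.event_table.to_csv(path / "events.csv", index=False, date_format=ts)
        manifest = dict(self.manifest)
        manifest["float_nurses"] = list(self.float_nurses)
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "RawEhrExtract":
        path = Path(path)
        patients = pd.read_csv(
            path / "patients.csv", parse_dates=["icu_admit_time", "icu_discharge_time"]
        )
        assignments = pd.read_csv(path / "assignments.csv", parse_dates=["shift_date"])
        events = pd.read_csv(path / "events.csv", parse_dates=["event_time"])
        manifest = {}
        float_nurses: tuple[str, ...] = ()
        mf = path / "manifest.json"
        if mf.exists():
            manifest = json.loads(mf.read_text())
            float_nurses = tuple(manifest.get("float_nurses", ()))
        return cls(patients, assignments, events, float_nurses, manifest)


def draw_nurse_effects(config: SimulationConfig) -> pd.DataFrame:
    """Draw latent per-nurse prevention effects.

    Returns one row per nurse (plus any float nurses, unit ``"float"``) with
    ``true_effect`` ~ i.i.d. Normal(0, nurse_effect_sd^2) on the log-odds scale
    of the CAABU-FREE outcome: positive values mean fewer events.  This is the
    latent quantity the VAM nurse coefficients estimate.
    """
    rng = np.random.default_rng([int(config.seed), 0])
    rows = []
    for unit, prefix in (("medical", "M"), ("neurological", "N")):
        n = _per_unit(config.n_nurses_per_unit, unit, "n_nurses_per_unit")
        for i in range(n):
            rows.append((f"{prefix}{i + 1:03d}", unit))
    for i in range(config.n_float_nurses):
        rows.append((f"F{i + 1:03d}", "float"))
    effects = rng.normal(0.0, config.nurse_effect_sd, size=len(rows))
    return pd.DataFrame(
        {
            "nurse_id": [r[0] for r in rows],
            "unit": [r[1] for r in rows],
            "true_effect": effects,
        }
    )


def _shift_start(t0: pd.Timestamp, idx: np.ndarray | int) -> pd.Timestamp | pd.Series:
    return t0 + pd.to_timedelta(np.asarray(idx) * 12 + DAY_SHIFT_START_HOUR, unit="h")


def simulate_cohort(config: SimulationConfig, effects: pd.DataFrame) -> RawEhrExtract:
    """Simulate a full extract under ``config`` with the given latent effects.

    Patients arrive as a Poisson process per unit (rate set so expected
    occupancy matches ``target_occupancy``), stay a geometric number of whole
    shifts, and are blocked if no bed is free for the stay.  Each patient-shift
    gets one on-duty nurse (occasionally two); nurse-patient matching is random
    when ``assignment_bias`` is 0 and acuity-ranked otherwise.  Events are
    per-encounter Bernoulli draws on the hazard

        logit p = baseline + covariate effects - mean(assigned nurses' effects)

    taking each patient's first success; the confirmed report is stamped
    uniformly 24-48 h after the triggering shift's end.
    """
    eff_map = effects.set_index("nurse_id")["true_effect"]
    rng = np.random.default_rng([int(config.seed), 1])
    t0 = pd.Timestamp(config.start_date)
    n_shifts = config.n_shifts
    cov = dict(DEFAULT_COVARIATE_EFFECTS)
    cov.update(config.covariate_effect_map)

    unit_rosters = {
        u: effects.loc[effects["unit"] == u, "nurse_id"].to_numpy() for u in UNITS
    }
    float_roster = effects.loc[effects["unit"] == "float", "nurse_id"].to_numpy()
    for u in UNITS:
        if len(unit_rosters[u]) == 0:
            raise ConfigurationError(f"effects table has no nurses for unit {u!r}")

    # ------------------------------------------------------------------ patients
    patients: dict[str, list] = {k: [] for k in (
        "patient_id", "age", "sex", "mdc", "insurance", "admission_type",
        "prior_admission_30d", "unit", "admit_shift", "n_stay_shifts",
    )}
    n_blocked = 0
    pid = 0
    for unit in UNITS:
        beds = _per_unit(config.n_beds_per_unit, unit, "n_beds_per_unit")
        los_days = _per_unit(config.mean_icu_los_days, unit, "mean_icu_los_days")
        # arrivals per day; the 1.12 factor compensates admission-gate
        # blocking and end-of-horizon truncation so the REALIZED census
        # matches target_occupancy
        lam = 1.12 * config.target_occupancy * beds / los_days
        occupancy = np.zeros(n_shifts, dtype=int)
        for day in range(config.n_days):
            for _ in range(rng.poisson(lam)):
                admit_minute = rng.integers(0, 1440)
                admit_time_h = day * 24 + admit_minute / 60.0
                # shift index containing the admission instant (may be -1 for
                # arrivals before 07:00 on day 0); assignments start next shift
                s_adm = math.floor((admit_time_h - DAY_SHIFT_START_HOUR) / 12.0)
                los_shifts = int(rng.geometric(1.0 / (2.0 * los_days)))
                first = s_adm + 1
                last = min(first + los_shifts - 1, n_shifts - 1)
                if first < 0 or first > n_shifts - 1 or last < first:
                    continue
                # bed gate at admission only; mid-stay census may flex above
                # the licensed bed count (boarding), as real units do
                if occupancy[first] >= beds:
                    n_blocked += 1
                    continue
                occupancy[first : last + 1] += 1
                pid += 1
                patients["patient_id"].append(f"P{pid:05d}")
                patients["age"].append(float(np.clip(rng.normal(AGE_MEAN, AGE_SD), 18, 100)))
                patients["sex"].append("male" if rng.random() < 0.55 else "female")
                patients["mdc"].append(MDC_CATEGORIES[rng.choice(len(MDC_CATEGORIES), p=MDC_PROBS)])
                patients["insurance"].append(
                    INSURANCE_CATEGORIES[rng.choice(len(INSURANCE_CATEGORIES), p=INSURANCE_PROBS)]
                )
                patients["admission_type"].append("surgical" if rng.random() < 0.52 else "medical")
                patients["prior_admission_30d"].append(int(rng.random() < 0.15))
                patients["unit"].append(unit)
                patients["admit_shift"].append(s_adm)
                patients["n_stay_shifts"].append(last - first + 1)

    pt = pd.DataFrame(patients)
    if pt.empty:
        raise SimulationError("no patients admitted; check arrival rates and horizon")
    # admission instant uniformly inside the admission shift, minutes resolution,
    # so every assigned (subsequent) shift lies fully inside the stay
    admit_offset_min = rng.integers(0, 12 * 60, size=len(pt))
    pt["icu_admit_time"] = _shift_start(t0, pt["admit_shift"].to_numpy()) + pd.to_timedelta(
        admit_offset_min, unit="m"
    )
    pt["first_shift"] = pt["admit_shift"] + 1
    pt["last_shift"] = pt["first_shift"] + pt["n_stay_shifts"] - 1
    pt["icu_discharge_time"] = _shift_start(t0, pt["last_shift"].to_numpy() + 1)

    # --------------------------------------------------------------- assignments
    # per-shift membership lists per unit
    pt_by_unit = {u: pt.index[pt["unit"] == u].to_numpy() for u in UNITS}
    true_eff = {u: eff_map.loc[unit_rosters[u]].to_numpy() for u in UNITS}

    enc_pat_idx: list[int] = []
    enc_shift: list[int] = []
    enc_nurses: list[tuple[str, ...]] = []
    bias = config.assignment_bias
    for unit in UNITS:
        roster = unit_rosters[unit]
        beds_u = _per_unit(config.n_beds_per_unit, unit, "n_beds_per_unit")
        if math.ceil(beds_u / config.patients_per_nurse) > len(roster):
            raise SimulationError(
                f"staffing infeasible in unit {unit!r}: {beds_u} beds need "
                f"{math.ceil(beds_u / config.patients_per_nurse)} nurses per shift, "
                f"roster has {len(roster)}"
            )
        roster_eff = true_eff[unit]
        idx = pt_by_unit[unit]
        firsts = pt.loc[idx, "first_shift"].to_numpy()
        lasts = pt.loc[idx, "last_shift"].to_numpy()
        ages = pt.loc[idx, "age"].to_numpy()
        members: list[list[int]] = [[] for _ in range(n_shifts)]
        for j, (f, l) in enumerate(zip(firsts, lasts)):
            for s in range(f, l + 1):
                members[s].append(j)
        for s in range(n_shifts):
            present = members[s]
            if not present:
                continue
            # transient boarding spikes above the bed count are absorbed by
            # overloading the on-duty nurses rather than failing the run
            n_duty = min(math.ceil(len(present) / config.patients_per_nurse), len(roster))
            duty_idx = rng.choice(len(roster), size=n_duty, replace=False)
            duty = list(roster[duty_idx])
            duty_eff = list(roster_eff[duty_idx])
            if len(float_roster) and rng.random() < config.float_shift_frac:
                f_id = str(rng.choice(float_roster))
                duty[0] = f_id
                duty_eff[0] = float(eff_map.loc[f_id])
            # acuity-ranked matching: with bias b, better (more protective)
            # nurses tend to get higher-acuity (older) patients when b > 0
            noise = rng.normal(size=n_duty)
            if bias != 0.0:
                e = np.asarray(duty_eff)
                es = (e - e.mean()) / (e.std() + 1e-12) if n_duty > 1 else np.zeros(n_duty)
                key = bias * es + math.sqrt(max(0.0, 1 - bias * bias)) * noise
            else:
                key = noise
            nurse_order = np.argsort(-key, kind="stable")
            acuity_noise = rng.normal(size=len(present))
            pat_order = np.argsort(
                -(np.array([ages[j] for j in present]) + 1e-6 * acuity_noise), kind="stable"
            )
            cap = math.ceil(len(present) / n_duty)
            slots = [nurse_order[t // cap] for t in range(len(present))]
            second_draw = rng.random(len(present))
            for t, p_ord in enumerate(pat_order):
                j = present[p_ord]
                d = slots[t]
                nurses = [duty[d]]
                if n_duty > 1 and second_draw[t] < config.two_nurse_frac:
                    d2 = (d + 1) % n_duty
                    nurses.append(duty[d2])
                enc_pat_idx.append(int(idx[j]))
                enc_shift.append(s)
                enc_nurses.append(tuple(sorted(set(nurses))))

    enc = pd.DataFrame(
        {
            "pat_idx": enc_pat_idx,
            "shift": enc_shift,
            "nurses": enc_nurses,
        }
    )
    eff_dict = eff_map.to_dict()
    enc["mean_effect"] = [
        sum(eff_dict[n] for n in tup) / len(tup) for tup in enc["nurses"]
    ]

    # -------------------------------------------------------------------- events
    base = pt.loc[enc["pat_idx"]].reset_index(drop=True)
    lp = np.full(len(enc), config.baseline_event_logodds)
    lp += cov.get("age_per_year", 0.0) * (base["age"].to_numpy() - AGE_MEAN)
    lp += cov.get("male", 0.0) * (base["sex"] == "male").to_numpy()
    lp += cov.get("surgical", 0.0) * (base["admission_type"] == "surgical").to_numpy()
    lp += cov.get("prior_admission_30d", 0.0) * base["prior_admission_30d"].to_numpy()
    lp += cov.get("micu", 0.0) * (base["unit"] == "medical").to_numpy()
    day_shift = (enc["shift"].to_numpy() % 2 == 0).astype(float)
    lp += cov.get("day_shift", 0.0) * day_shift
    shift_start_h = enc["shift"].to_numpy() * 12.0 + DAY_SHIFT_START_HOUR
    admit_h = (base["icu_admit_time"] - t0).dt.total_seconds().to_numpy() / 3600.0
    hours_before = np.maximum(shift_start_h - admit_h, 0.0)
    lp += cov.get("hours_in_icu_per_hour", 0.0) * (hours_before - 60.0)
    for key, val in cov.items():
        if key.startswith("mdc:"):
            lp += val * (base["mdc"] == key[4:]).to_numpy()
        elif key.startswith("insurance:"):
            lp += val * (base["insurance"] == key[10:]).to_numpy()
    lp -= enc["mean_effect"].to_numpy()
    p_event = expit(lp) if np.isfinite(config.baseline_event_logodds) else np.zeros(len(enc))

    # patients with a pre-admission event never accrue an in-stay event: their
    # encounters are excluded downstream anyway
    prior_flag = rng.random(len(pt)) < config.prior_event_frac
    u_event = rng.random(len(enc))
    success = (u_event < p_event) & ~prior_flag[enc["pat_idx"].to_numpy()]

    ev_rows: list[tuple[str, pd.Timestamp, str, int]] = []
    if success.any():
        hits = enc.loc[success, ["pat_idx", "shift"]].copy()
        first_hit = hits.groupby("pat_idx")["shift"].idxmin()
        offsets_h = 24.0 + 24.0 * (1.0 - rng.random(len(first_hit)))
        cauti_draw = rng.random(len(first_hit))
        cauti_off = rng.uniform(12.0, 48.0, size=len(first_hit))
        for k, ix in enumerate(first_hit.to_numpy()):
            p_i = int(enc.at[ix, "pat_idx"])
            s_i = int(enc.at[ix, "shift"])
            shift_end = t0 + pd.Timedelta(hours=(s_i + 1) * 12 + DAY_SHIFT_START_HOUR)
            t_ev = (shift_end + pd.Timedelta(hours=offsets_h[k])).floor("min")
            pid_str = pt.at[p_i, "patient_id"]
            ev_rows.append((pid_str, t_ev, "caabu", 1))
            if cauti_draw[k] < config.cauti_frac:
                ev_rows.append(
                    (pid_str, (t_ev + pd.Timedelta(hours=cauti_off[k])).floor("min"), "cauti", 1)
                )

    for i in np.flatnonzero(prior_flag):
        t_ev = (pt.at[i, "icu_admit_time"] - pd.Timedelta(hours=rng.uniform(1, 72))).floor("min")
        ev_rows.append((pt.at[i, "patient_id"], t_ev, "caabu", 1))

    # unconfirmed cultures: schema noise the assembly must ignore
    for i in np.flatnonzero(rng.random(len(pt)) < config.unconfirmed_event_frac):
        stay_h = rng.uniform(0, 12.0 * pt.at[i, "n_stay_shifts"])
        t_ev = (pt.at[i, "icu_admit_time"] + pd.Timedelta(hours=stay_h)).floor("min")
        ev_rows.append((pt.at[i, "patient_id"], t_ev, "caabu", 0))

    event_table = pd.DataFrame(ev_rows, columns=["patient_id", "event_time", "event_kind", "confirmed"])
    event_table = event_table.sort_values(["patient_id", "event_time"], kind="stable").reset_index(drop=True)

    shift_arr = enc["shift"].to_numpy()
    assignment_rows = {
        "patient_id": np.repeat(
            pt.loc[enc["pat_idx"], "patient_id"].to_numpy(), [len(t) for t in enc["nurses"]]
        ),
        "nurse_id": np.concatenate([list(t) for t in enc["nurses"]]),
        "shift_date": np.repeat(
            (t0 + pd.to_timedelta(shift_arr // 2, unit="D")).normalize().to_numpy(),
            [len(t) for t in enc["nurses"]],
        ),
        "shift_kind": np.repeat(
            np.where(shift_arr % 2 == 0, "day", "night"), [len(t) for t in enc["nurses"]]
        ),
    }
    assignment_table = pd.DataFrame(assignment_rows)

    patient_table = pt[
        [
            "patient_id", "age", "sex", "mdc", "insurance", "admission_type",
            "prior_admission_30d", "unit", "icu_admit_time", "icu_discharge_time",
        ]
    ].copy()
    patient_table["age"] = patient_table["age"].round(1)

    manifest = {
        "config": config.to_dict(),
        "seed": int(config.seed),
        "n_patients": int(len(patient_table)),
        "n_patient_shifts": int(len(enc)),
        "n_blocked_arrivals": int(n_blocked),
        "n_confirmed_caabu": int(
            ((event_table["event_kind"] == "caabu") & (event_table["confirmed"] == 1)).sum()
        ),
    }
    return RawEhrExtract(
        patient_table,
        assignment_table,
        event_table,
        tuple(float_roster.tolist()),
        manifest,
    )


def simulate_extract(config: SimulationConfig) -> tuple[RawEhrExtract, pd.DataFrame]:
    """Convenience wrapper: draw effects, simulate, return both."""
    effects = draw_nurse_effects(config)
    return simulate_cohort(config, effects), effects
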