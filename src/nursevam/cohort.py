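"""From raw extract to analysis cohort.

Turns the three raw tables into patient-shift encounter records with the
CAABU-free outcome, applies the study's exclusion rules, splits the sample
into estimation/validation halves by discharge date, and builds the design
matrix for the value-added model.

Outcome convention: an encounter is labeled CAABU-positive (caabu_free = 0)
when a confirmed CAABU culture is time-stamped in the half-open,
upper-inclusive window (shift_end + 24 h, shift_end + 48 h] — the CDC
infection-location attribution rule with its "48 hour maximum limit" read as
inclusive.  Both endpoints are configurable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import AssemblyError, ConfigurationError, IntegrityError
from .simulate import RawEhrExtract

MDC_REFERENCE = "DDs of Nervous System"
INSURANCE_REFERENCE = "uninsured"
DOW_ORDER = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday")  # ref Sunday

ENCOUNTER_COLUMNS = [
    "patient_id", "shift_date", "shift_kind", "shift_start", "shift_end",
    "nurse_ids", "caabu_free", "age", "male", "mdc", "insurance", "surgical",
    "prior_admission_30d", "hours_in_icu_before_shift", "day_of_week",
    "day_shift", "micu", "icu_admit_time", "icu_discharge_time",
]


def label_outcomes(
    extract: RawEhrExtract,
    window_min_h: float = 24.0,
    window_max_h: float = 48.0,
) -> pd.DataFrame:
    """Build one encounter record per (patient, shift) with the 0/1 outcome.

    caabu_free is 0 iff a confirmed CAABU culture time t satisfies
    window_min_h < t - shift_end <= window_max_h (hours); otherwise 1.
    Covariates and shift controls are attached from the patient table.
    """
    if window_min_h < 0 or window_max_h <= window_min_h:
        raise ConfigurationError("need 0 <= window_min_h < window_max_h")
    patients = extract.patient_table
    assignments = extract.assignment_table
    events = extract.event_table

    known = set(patients["patient_id"])
    unknown = set(events["patient_id"]) - known
    if unknown:
        raise IntegrityError(f"events reference unknown patients: {sorted(unknown)[:5]}")
    unknown_a = set(assignments["patient_id"]) - known
    if unknown_a:
        raise IntegrityError(f"assignments reference unknown patients: {sorted(unknown_a)[:5]}")

    enc = (
        assignments.groupby(["patient_id", "shift_date", "shift_kind"], sort=True)["nurse_id"]
        .apply(lambda s: tuple(sorted(set(s))))
        .reset_index()
        .rename(columns={"nurse_id": "nurse_ids"})
    )
    start_hour = np.where(enc["shift_kind"] == "day", 7, 19)
    enc["shift_start"] = pd.to_datetime(enc["shift_date"]) + pd.to_timedelta(start_hour, unit="h")
    enc["shift_end"] = enc["shift_start"] + pd.Timedelta(hours=12)

    caabu = events[(events["event_kind"] == "caabu") & (events["confirmed"] == 1)]
    ev_by_patient = caabu.groupby("patient_id")["event_time"].apply(list)
    lo = pd.Timedelta(hours=window_min_h)
    hi = pd.Timedelta(hours=window_max_h)

    def _label(row) -> int:
        times = ev_by_patient.get(row.patient_id)
        if not times:
            return 1
        end = row.shift_end
        for t in times:
            if end + lo < t <= end + hi:
                return 0
        return 1

    enc["caabu_free"] = [_label(r) for r in enc.itertuples()]

    pt = patients.set_index("patient_id")
    enc = enc.join(pt, on="patient_id")
    enc["male"] = (enc["sex"] == "male").astype(int)
    enc["surgical"] = (enc["admission_type"] == "surgical").astype(int)
    enc["micu"] = (enc["unit"] == "medical").astype(int)
    enc["day_shift"] = (enc["shift_kind"] == "day").astype(int)
    enc["day_of_week"] = pd.to_datetime(enc["shift_start"]).dt.day_name()
    hours = (enc["shift_start"] - enc["icu_admit_time"]).dt.total_seconds() / 3600.0
    enc["hours_in_icu_before_shift"] = hours.clip(lower=0.0)
    enc = enc[ENCOUNTER_COLUMNS].sort_values(
        ["patient_id", "shift_start"], kind="stable"
    ).reset_index(drop=True)
    return enc


@dataclass
class AssembledCohort:
    """Labeled, exclusion-filtered encounters plus the modeled-nurse roster."""

    encounters: pd.DataFrame
    nurse_roster: tuple[str, ...]
    exclusion_log: dict = field(default_factory=dict)

    @property
    def n_encounters(self) -> int:
        return len(self.encounters)

    @property
    def n_patients(self) -> int:
        return self.encounters["patient_id"].nunique()

    def nurse_link_counts(self) -> pd.Series:
        """Encounters linked to each roster nurse (an encounter with two
        nurses counts once for each)."""
        counts: dict[str, int] = {n: 0 for n in self.nurse_roster}
        for tup in self.encounters["nurse_ids"]:
            for n in tup:
                if n in counts:
                    counts[n] += 1
        return pd.Series(counts, dtype=int).sort_index()

    def nurse_units(self) -> pd.Series:
        """Majority care unit per roster nurse."""
        rows: dict[str, list[int]] = {n: [0, 0] for n in self.nurse_roster}
        for tup, micu in zip(self.encounters["nurse_ids"], self.encounters["micu"]):
            for n in tup:
                if n in rows:
                    rows[n][int(micu)] += 1
        return pd.Series(
            {n: ("medical" if c[1] >= c[0] else "neurological") for n, c in rows.items()}
        ).sort_index()

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.encounters.copy()
        out["nurse_ids"] = ["|".join(t) for t in out["nurse_ids"]]
        out.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")
        return path

    @classmethod
    def from_csv(cls, path: str | Path, nurse_roster=None, exclusion_log=None) -> "AssembledCohort":
        enc = pd.read_csv(
            path,
            parse_dates=["shift_date", "shift_start", "shift_end",
                         "icu_admit_time", "icu_discharge_time"],
        )
        enc["nurse_ids"] = [tuple(s.split("|")) for s in enc["nurse_ids"]]
        if nurse_roster is None:
            nurse_roster = tuple(sorted({n for t in enc["nurse_ids"] for n in t}))
        return cls(enc, tuple(nurse_roster), exclusion_log or {})

    def write_exclusion_log(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.exclusion_log, indent=2, sort_keys=True))
        return path


def _apply_roster_threshold(enc: pd.DataFrame, min_encounters: int) -> tuple[pd.DataFrame, tuple[str, ...], dict]:
    """Drop sub-threshold nurses from the roster; keep their encounters only
    when a roster nurse co-attended."""
    counts: dict[str, int] = {}
    for tup in enc["nurse_ids"]:
        for n in tup:
            counts[n] = counts.get(n, 0) + 1
    roster = {n for n, c in counts.items() if c >= min_encounters}
    below = sorted(set(counts) - roster)
    stripped = [tuple(n for n in tup if n in roster) for tup in enc["nurse_ids"]]
    keep = [len(t) > 0 for t in stripped]
    out = enc.loc[keep].copy()
    out["nurse_ids"] = [t for t, k in zip(stripped, keep) if k]
    log = {
        "nurses_below_min": len(below),
        "encounters_dropped_unmodeled_nurse": int(len(enc) - len(out)),
    }
    return out.reset_index(drop=True), tuple(sorted(roster)), log


def apply_exclusions(
    encounters: pd.DataFrame,
    events: pd.DataFrame,
    min_encounters_per_nurse: int = 45,
    float_nurses: tuple[str, ...] = (),
) -> AssembledCohort:
    """Apply the study's four exclusion rules, logging a count for each.

    1. drop all encounters of patients with a confirmed CAABU/CAUTI report at
       or before ICU admission;
    2. drop encounters ending at/after the patient's first confirmed report
       (first-event censoring);
    3. remove float nurses from encounter nurse sets (drop the encounter only
       if nobody remains);
    4. drop nurses linked to fewer than ``min_encounters_per_nurse`` encounters
       from the roster (their encounters survive only with a roster co-nurse).
    """
    enc = encounters.copy()
    log: dict = {"min_encounters_per_nurse": int(min_encounters_per_nurse)}

    confirmed = events[events["confirmed"] == 1]
    first_event = confirmed.groupby("patient_id")["event_time"].min()

    admit = enc.groupby("patient_id")["icu_admit_time"].first()
    both = first_event.reindex(admit.index)
    prior_patients = set(both.index[(both.notna()) & (both <= admit)])
    n0 = len(enc)
    enc = enc[~enc["patient_id"].isin(prior_patients)]
    log["patients_prior_event"] = len(prior_patients)
    log["encounters_prior_event_patients"] = int(n0 - len(enc))

    ev = pd.to_datetime(first_event.reindex(enc["patient_id"])).to_numpy()
    ev_na = pd.isna(ev)
    ev_filled = np.where(ev_na, np.datetime64("2262-01-01"), ev)
    keep = ev_na | (enc["shift_end"].to_numpy() < ev_filled)
    log["encounters_after_event"] = int(len(enc) - keep.sum())
    enc = enc.loc[keep]

    float_set = set(float_nurses)
    stripped = [tuple(n for n in tup if n not in float_set) for tup in enc["nurse_ids"]]
    log["float_links_removed"] = int(
        sum(len(a) - len(b) for a, b in zip(enc["nurse_ids"], stripped))
    )
    keep2 = [len(t) > 0 for t in stripped]
    enc = enc.loc[keep2].copy()
    enc["nurse_ids"] = [t for t, k in zip(stripped, keep2) if k]
    log["encounters_dropped_float_only"] = int(len(keep2) - sum(keep2))

    enc, roster, tlog = _apply_roster_threshold(enc.reset_index(drop=True), min_encounters_per_nurse)
    log.update(tlog)
    if enc.empty or not roster:
        raise AssemblyError("cohort empty after exclusions", )
    log["n_encounters_final"] = int(len(enc))
    log["n_patients_final"] = int(enc["patient_id"].nunique())
    log["n_nurses_final"] = len(roster)
    return AssembledCohort(enc, roster, log)


def split_sample(
    cohort: AssembledCohort, cutoff
) -> tuple[AssembledCohort, AssembledCohort]:
    """Split by hospitalization discharge DATE: strictly before the cutoff
    date goes to estimation, on/after to validation.  The nurse roster (and
    the minimum-encounters rule) is recomputed within each half.
    """
    cutoff = pd.Timestamp(cutoff).normalize()
    enc = cohort.encounters
    discharge_date = pd.to_datetime(enc["icu_discharge_time"]).dt.normalize()
    span_lo = pd.to_datetime(enc["icu_admit_time"]).min().normalize()
    span_hi = discharge_date.max()
    if not (span_lo <= cutoff <= span_hi + pd.Timedelta(days=1)):
        raise ConfigurationError(
            f"cutoff {cutoff.date()} outside data span [{span_lo.date()}, {span_hi.date()}]"
        )
    min_enc = int(cohort.exclusion_log.get("min_encounters_per_nurse", 45))
    halves = []
    for name, mask in (
        ("estimation", discharge_date < cutoff),
        ("validation", discharge_date >= cutoff),
    ):
        sub = enc.loc[mask].reset_index(drop=True)
        if sub.empty:
            warnings.warn(f"{name} half is empty for cutoff {cutoff.date()}")
            halves.append(AssembledCohort(sub, (), {"half": name, "empty": True}))
            continue
        sub, roster, tlog = _apply_roster_threshold(sub, min_enc)
        log = {"half": name, "min_encounters_per_nurse": min_enc, **tlog,
               "n_encounters_final": int(len(sub)),
               "n_patients_final": int(sub["patient_id"].nunique()) if len(sub) else 0,
               "n_nurses_final": len(roster)}
        halves.append(AssembledCohort(sub, roster, log))
    return halves[0], halves[1]


@dataclass
class VamDesign:
    """Design matrix bundle for the value-added logistic model."""

    X: pd.DataFrame
    y: np.ndarray
    nurse_cols: list[str]
    ref_nurse: str
    cluster_patient: np.ndarray
    nurse_link_counts: pd.Series
    nurse_units: pd.Series
    dropped_columns: list[str]
    cohort: AssembledCohort | None = None
    reference_levels: dict | None = None
    #: membership indicator of the reference nurse (not a column of X); lets
    #: penalized fits restore the full nurse block
    ref_nurse_indicator: np.ndarray | None = None

    @property
    def nobs(self) -> int:
        return len(self.y)

    @property
    def covariate_cols(self) -> list[str]:
        nurse = set(self.nurse_cols)
        return [c for c in self.X.columns if c not in nurse]


def build_design_matrix(cohort: AssembledCohort, ref_seed: int = 0) -> VamDesign:
    """Assemble Y, the multi-hot nurse block, and the covariate block.

    One roster nurse is removed as the (seeded-random) reference category;
    encounters with several roster nurses set every attending nurse's
    indicator to 1.  Reference categories: MDC "DDs of Nervous System",
    insurance "uninsured", Sunday, night shift, female, medical admission,
    neurological ICU.  Constant columns are dropped with a logged warning.
    """
    if not cohort.nurse_roster:
        raise AssemblyError("cohort has an empty nurse roster")
    enc = cohort.encounters
    roster = sorted(cohort.nurse_roster)
    rng = np.random.default_rng([int(ref_seed), 97])
    ref_nurse = roster[int(rng.integers(len(roster)))]
    y_arr = enc["caabu_free"].to_numpy(dtype=int)

    def _family_reference(series: pd.Series, preferred: str) -> str:
        """Reference level for a categorical family.

        The preferred (study-defined) level is kept unless it is absent or
        its rows all share one outcome — an outcome-constant reference makes
        the intercept diverge (reference-side separation).  Fallback is the
        largest level with both outcomes, logged as a warning.
        """

        def usable(cat) -> bool:
            m = (series == cat).to_numpy()
            return bool(m.any()) and y_arr[m].min() != y_arr[m].max()

        if usable(preferred):
            return preferred
        for cat in series.value_counts().index:
            if usable(cat):
                warnings.warn(
                    f"reference level {preferred!r} absent or outcome-constant; "
                    f"using {cat!r} as the reference instead"
                )
                return str(cat)
        return preferred  # fully degenerate family; downstream drop rules apply

    mdc_ref = _family_reference(enc["mdc"], MDC_REFERENCE)
    ins_ref = _family_reference(enc["insurance"], INSURANCE_REFERENCE)
    dow_ref = _family_reference(enc["day_of_week"], "Sunday")

    cols: dict[str, np.ndarray] = {"const": np.ones(len(enc))}
    cols["age"] = enc["age"].to_numpy(float)
    for c in ("male", "surgical", "prior_admission_30d", "day_shift", "micu"):
        cols[c] = enc[c].to_numpy(float)
    cols["hours_in_icu_before_shift"] = enc["hours_in_icu_before_shift"].to_numpy(float)
    for cat in sorted(enc["mdc"].unique()):
        if cat != mdc_ref:
            cols[f"mdc:{cat}"] = (enc["mdc"] == cat).to_numpy(float)
    for cat in sorted(enc["insurance"].unique()):
        if cat != ins_ref:
            cols[f"insurance:{cat}"] = (enc["insurance"] == cat).to_numpy(float)
    for d in ("Sunday", *DOW_ORDER):
        if d != dow_ref:
            cols[f"dow:{d}"] = (enc["day_of_week"] == d).to_numpy(float)

    nurse_cols = []
    member = {n: np.zeros(len(enc)) for n in roster}
    for i, tup in enumerate(enc["nurse_ids"]):
        for n in tup:
            member[n][i] = 1.0
    for n in roster:
        if n == ref_nurse:
            continue
        col = f"nurse:{n}"
        cols[col] = member[n]
        nurse_cols.append(col)

    dropped = []
    for c in list(cols):
        if c != "const" and len(np.unique(cols[c])) <= 1:
            dropped.append(c)
            del cols[c]
            if c in nurse_cols:
                nurse_cols.remove(c)
    X = pd.DataFrame(cols, index=enc.index)
    if dropped:
        warnings.warn(f"dropped constant design columns: {dropped}")

    return VamDesign(
        X=X.astype(float),
        y=enc["caabu_free"].to_numpy(dtype=int),
        nurse_cols=nurse_cols,
        ref_nurse=ref_nurse,
        cluster_patient=enc["patient_id"].to_numpy(),
        nurse_link_counts=cohort.nurse_link_counts(),
        nurse_units=cohort.nurse_units(),
        dropped_columns=dropped,
        cohort=cohort,
        reference_levels={"mdc": mdc_ref, "insurance": ins_ref, "day_of_week": dow_ref},
        ref_nurse_indicator=member[ref_nurse],
    )
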