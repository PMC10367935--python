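"""Patients, therapy lines, real-world endpoints, and analysis cohorts.

The clinical substrate is a longitudinal record of systemic therapy lines
per patient, on an integer day clock. From it we derive:

* rwPFS (real-world progression-free survival): time from a line's start to
  the start of the next systemic line or death, whichever comes first;
  censored at last follow-up when neither is observed. This
  time-to-next-treatment operationalization is a validated real-world proxy
  for progression.
* OS: time from line start to death, censored at last follow-up.

Durations are converted with months = days / 30.4375. Zero-length intervals
(next line starting the same day) are set to 0.5 day so survival fitters
see strictly positive times.

``select_cohort`` applies the eligibility rules of the validation analyses
(molecular data present, specimen collected before line start, no prior
checkpoint blockade, eligible therapy class, study-specific exclusions) and
returns an analysis table plus a per-criterion exclusion audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .scoring import IRSResult, MolecularCovariates, ScoringModel, classify_irs, compute_irs
from .tmb import TumorSample

__all__ = [
    "DAYS_PER_MONTH",
    "TherapyLine",
    "Patient",
    "SurvivalRecord",
    "CohortSpec",
    "AnalysisCohort",
    "DrugDictionary",
    "classify_therapy_line",
    "derive_rwpfs",
    "derive_os",
    "select_cohort",
    "assign_tumor_type_covariate",
    "group_race",
    "load_patients",
]

DAYS_PER_MONTH = 30.4375
MIN_DURATION_DAYS = 0.5  # floor for zero-length intervals

MONO = "PD-(L)1 mono"
CHEMO = "chemo"
COMBO = "PD-(L)1+chemo"
OTHER = "other"


# ---------------------------------------------------------------------------
# drug dictionary and line classification


@dataclass(frozen=True)
class DrugDictionary:
    """Configurable agent-name sets driving therapy-line classification.

    ``partners`` are the targeted agents (ramucirumab, bevacizumab,
    cetuximab) that are chemo-compatible: they classify like cytotoxics and
    do not push a line to "other".
    """

    pd1_agents: frozenset[str] = frozenset(
        {
            "pembrolizumab",
            "nivolumab",
            "atezolizumab",
            "durvalumab",
            "avelumab",
            "cemiplimab",
            "dostarlimab",
        }
    )
    ctla4_agents: frozenset[str] = frozenset({"ipilimumab", "tremelimumab"})
    cytotoxics: frozenset[str] = frozenset(
        {
            "carboplatin",
            "cisplatin",
            "oxaliplatin",
            "paclitaxel",
            "nab-paclitaxel",
            "docetaxel",
            "pemetrexed",
            "gemcitabine",
            "fluorouracil",
            "capecitabine",
            "etoposide",
            "irinotecan",
            "topotecan",
            "vinorelbine",
            "doxorubicin",
            "cyclophosphamide",
        }
    )
    partners: frozenset[str] = frozenset({"ramucirumab", "bevacizumab", "cetuximab"})

    def is_io(self, agent: str) -> bool:
        return agent in self.pd1_agents or agent in self.ctla4_agents


DEFAULT_DRUGS = DrugDictionary()


def classify_therapy_line(
    agents: Iterable[str], drugs: DrugDictionary = DEFAULT_DRUGS
) -> tuple[str, bool]:
    """Map an agent set to (therapy_class, pembrolizumab flag).

    Unknown agents or CTLA4-containing regimens classify as "other".
    """
    agent_set = {a.strip().lower() for a in agents if a and a.strip()}
    if not agent_set:
        raise ValueError("therapy line has an empty agent set")
    pembro = "pembrolizumab" in agent_set
    has_pd1 = bool(agent_set & drugs.pd1_agents)
    has_ctla4 = bool(agent_set & drugs.ctla4_agents)
    chemo_like = drugs.cytotoxics | drugs.partners
    has_chemo = bool(agent_set & chemo_like)
    unknown = agent_set - drugs.pd1_agents - drugs.ctla4_agents - chemo_like
    if unknown or has_ctla4:
        return OTHER, pembro
    if has_pd1 and has_chemo:
        return COMBO, pembro
    if has_pd1:
        return MONO, pembro
    if has_chemo:
        return CHEMO, pembro
    return OTHER, pembro


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class TherapyLine:
    patient_id: str
    line_number: int
    start_day: int
    stop_day: int | None = None
    agents: frozenset[str] = frozenset()
    therapy_class: str | None = None
    pembrolizumab: bool = False

    def __post_init__(self) -> None:
        if self.stop_day is not None and not self.start_day < self.stop_day:
            raise ValueError(
                f"line {self.patient_id}/{self.line_number}: start_day must precede stop_day"
            )

    def classified(self, drugs: DrugDictionary = DEFAULT_DRUGS) -> "TherapyLine":
        cls, pembro = classify_therapy_line(self.agents, drugs)
        return replace(self, therapy_class=cls, pembrolizumab=pembro)


@dataclass
class Patient:
    patient_id: str
    age_at_collection: float
    sex: str
    tumor_type: str
    race: str = "unknown"
    collection_day: int = 0
    death_day: int | None = None
    last_followup_day: int = 0
    covariates: MolecularCovariates | None = None
    sample: TumorSample | None = None
    irs: IRSResult | None = None
    in_discovery: bool = False
    in_prior_validation: bool = False
    lines: list[TherapyLine] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lines = sorted(self.lines, key=lambda ln: ln.line_number)
        starts = [ln.start_day for ln in self.lines]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError(
                f"patient {self.patient_id}: line start days must strictly increase "
                "with line number"
            )
        if starts and self.last_followup_day < max(starts):
            raise ValueError(
                f"patient {self.patient_id}: last follow-up precedes a line start"
            )
        if self.death_day is not None and self.death_day > self.last_followup_day:
            raise ValueError(
                f"patient {self.patient_id}: death_day after last_followup_day"
            )
        if self.irs is None and self.covariates is not None:
            self.irs = classify_irs(compute_irs(self.covariates))

    # line navigation -------------------------------------------------
    def next_line(self, line: TherapyLine) -> TherapyLine | None:
        later = [ln for ln in self.lines if ln.start_day > line.start_day]
        return min(later, key=lambda ln: ln.start_day) if later else None

    def preceding_line(self, line: TherapyLine) -> TherapyLine | None:
        earlier = [ln for ln in self.lines if ln.start_day < line.start_day]
        return max(earlier, key=lambda ln: ln.start_day) if earlier else None

    def prior_io(self, line: TherapyLine, drugs: DrugDictionary = DEFAULT_DRUGS) -> bool:
        """Any anti-PD-(L)1 or CTLA4 exposure starting before this line."""
        return any(
            any(drugs.is_io(a) for a in ln.agents)
            for ln in self.lines
            if ln.start_day < line.start_day
        )


@dataclass(frozen=True)
class SurvivalRecord:
    duration_months: float
    event: bool
    endpoint: str  # "rwPFS" or "OS"

    def __post_init__(self) -> None:
        if self.duration_months < 0:
            raise ValueError("duration_months must be >= 0")


def _to_months(days: float) -> float:
    return max(days, MIN_DURATION_DAYS) / DAYS_PER_MONTH


def derive_rwpfs(patient: Patient, line: TherapyLine) -> SurvivalRecord:
    """rwPFS: next-line start or death = event; otherwise censor at follow-up."""
    if line not in patient.lines:
        raise ValueError("line does not belong to patient")
    nxt = patient.next_line(line)
    event_days: list[int] = []
    if nxt is not None:
        event_days.append(nxt.start_day - line.start_day)
    if patient.death_day is not None:
        event_days.append(patient.death_day - line.start_day)
    if event_days:
        d = min(event_days)
        if d < 0:
            raise ValueError(
                f"patient {patient.patient_id}: event precedes line start"
            )
        return SurvivalRecord(_to_months(d), True, "rwPFS")
    return SurvivalRecord(
        _to_months(patient.last_followup_day - line.start_day), False, "rwPFS"
    )


def derive_os(patient: Patient, line: TherapyLine) -> SurvivalRecord:
    if line not in patient.lines:
        raise ValueError("line does not belong to patient")
    if patient.death_day is not None:
        d = patient.death_day - line.start_day
        if d < 0:
            raise ValueError(f"patient {patient.patient_id}: death precedes line start")
        return SurvivalRecord(_to_months(d), True, "OS")
    return SurvivalRecord(
        _to_months(patient.last_followup_day - line.start_day), False, "OS"
    )


# ---------------------------------------------------------------------------
# cohort selection


@dataclass(frozen=True)
class CohortSpec:
    """Declarative eligibility rules for one analysis cohort."""

    name: str
    endpoints: tuple[str, ...] = ("rwPFS", "OS")
    eligible_classes: tuple[str, ...] = (MONO,)
    require_no_prior_io: bool = True
    exclude_msi_high: bool = False
    exclude_discovery: bool = True
    exclude_prior_validation: bool = True
    tumor_whitelist: tuple[str, ...] | None = None
    one_line_per_patient: bool = True

    def __post_init__(self) -> None:
        if self.tumor_whitelist is not None and not self.tumor_whitelist:
            raise ValueError("tumor_whitelist must be nonempty when given")


MONOTHERAPY_SPEC = CohortSpec(name="monotherapy-validation")
RACE_SPEC = CohortSpec(
    name="race-validation",
    endpoints=("rwPFS",),
    exclude_msi_high=True,
    exclude_prior_validation=False,
)
COMBO_SPEC = CohortSpec(
    name="treatment-comparison",
    endpoints=("rwPFS",),
    eligible_classes=(MONO, CHEMO, COMBO),
    tumor_whitelist=("NSCLC", "H&N", "EGC", "SCLC", "TNBC"),
    one_line_per_patient=False,
)


@dataclass
class AnalysisCohort:
    spec: CohortSpec
    table: pd.DataFrame
    audit: dict[str, int]
    patients: dict[str, Patient]

    @property
    def n_lines(self) -> int:
        return len(self.table)


#: criterion evaluation order; audit counts first failing criterion, so the
#: counts sum to the total number excluded.
_CRITERIA = (
    "molecular_data",
    "eligible_class",
    "specimen_before_start",
    "no_prior_io",
    "msi_high_excluded",
    "discovery_excluded",
    "prior_validation_excluded",
    "tumor_type",
)


def _first_failure(
    patient: Patient, line: TherapyLine, spec: CohortSpec, drugs: DrugDictionary
) -> str | None:
    if patient.covariates is None or patient.sample is None:
        return "molecular_data"
    if (line.therapy_class or line.classified(drugs).therapy_class) not in spec.eligible_classes:
        return "eligible_class"
    if not patient.collection_day < line.start_day:
        return "specimen_before_start"
    if spec.require_no_prior_io and patient.prior_io(line, drugs):
        return "no_prior_io"
    if spec.exclude_msi_high and patient.sample.msi_high:
        return "msi_high_excluded"
    if spec.exclude_discovery and patient.in_discovery:
        return "discovery_excluded"
    if spec.exclude_prior_validation and patient.in_prior_validation:
        return "prior_validation_excluded"
    if spec.tumor_whitelist is not None and patient.tumor_type not in spec.tumor_whitelist:
        return "tumor_type"
    return None


def select_cohort(
    patients: Sequence[Patient],
    spec: CohortSpec,
    drugs: DrugDictionary = DEFAULT_DRUGS,
    model: ScoringModel | None = None,
) -> AnalysisCohort:
    """Select eligible (patient, line) rows and build the analysis table.

    Order-independent in the input patient sequence: rows are sorted by
    (patient_id, line start). The audit maps each criterion to the number of
    candidate lines excluded by it (first failing criterion in a fixed
    order), plus ``selected``.
    """
    model = model or ScoringModel()
    audit = {c: 0 for c in _CRITERIA}
    rows = []
    for patient in sorted(patients, key=lambda p: p.patient_id):
        selected_for_patient = 0
        for line in patient.lines:
            line = line if line.therapy_class is not None else line.classified(drugs)
            fail = _first_failure(patient, line, spec, drugs)
            if fail is not None:
                audit[fail] += 1
                continue
            if spec.one_line_per_patient and selected_for_patient:
                continue
            selected_for_patient += 1
            irs = patient.irs or classify_irs(compute_irs(patient.covariates, model), model)
            rec_pfs = derive_rwpfs(patient, line)
            rec_os = derive_os(patient, line)
            rows.append(
                {
                    "patient_id": patient.patient_id,
                    "line_number": line.line_number,
                    "start_day": line.start_day,
                    "therapy_class": line.therapy_class,
                    "pembrolizumab": line.pembrolizumab,
                    "age": patient.age_at_collection,
                    "sex": patient.sex,
                    "tumor_type": patient.tumor_type,
                    "race_group": group_race(patient.race),
                    "score": irs.score,
                    "irs_group2": irs.group2,
                    "irs_group3": irs.group3,
                    "msi_high": patient.sample.msi_high,
                    "combined_msi_tmb": (
                        "MSI/TMB-H"
                        if (patient.sample.msi_high or irs_tmb_high(patient))
                        else "MSS/TMB-L"
                    ),
                    "has_preceding_line": patient.preceding_line(line) is not None,
                    "rwpfs_months": rec_pfs.duration_months,
                    "rwpfs_event": rec_pfs.event,
                    "os_months": rec_os.duration_months,
                    "os_event": rec_os.event,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(["patient_id", "start_day"]).reset_index(drop=True)
    audit["selected"] = len(table)
    return AnalysisCohort(spec=spec, table=table, audit=audit, patients={p.patient_id: p for p in patients})


def irs_tmb_high(patient: Patient) -> bool:
    """TMB-H call from the model-scale TMB covariate (>= 10 Muts/Mb)."""
    return patient.covariates is not None and patient.covariates.tmb >= 10.0


def assign_tumor_type_covariate(
    tumor_types: pd.Series, min_count: int = 15
) -> tuple[pd.Series, str]:
    """Recode tumor types: keep labels with count > min_count, pool the rest.

    Returns the recoded series and the reference level (most frequent kept
    label, or "other" if nothing clears the threshold).
    """
    if tumor_types.empty:
        raise ValueError("empty tumor-type series")
    counts = tumor_types.value_counts()
    keep = set(counts[counts > min_count].index)
    recoded = tumor_types.where(tumor_types.isin(keep), "other")
    ref = counts[counts > min_count].index[0] if keep else "other"
    return recoded, str(ref)


_RACE_OTHER = {
    "american indian or alaskan native",
    "native hawaiian or other pacific islander",
    "other",
}
_RACE_NON_EUROPEAN = {"asian", "black or african american"} | _RACE_OTHER


def group_race(raw: str | None) -> str:
    """Collapse self-reported race labels to European / non-European / unknown."""
    if raw is None or not str(raw).strip():
        return "unknown"
    r = str(raw).strip().lower()
    if r in {"white or caucasian", "white", "caucasian", "european"}:
        return "European"
    if r in _RACE_NON_EUROPEAN or r == "non-european":
        return "non-European"
    return "unknown"


# ---------------------------------------------------------------------------
# flat-file loading


def load_patients(
    patients_csv: str | Path,
    lines_csv: str | Path,
    covariates_tsv: str | Path | None = None,
    column_map: Mapping[str, str] | None = None,
    drugs: DrugDictionary = DEFAULT_DRUGS,
) -> list[Patient]:
    """Load patients from flat files (supplementary-data style).

    ``patients_csv`` columns: patient_id, age, sex, tumor_type, race,
    collection_day, death_day (blank if alive), last_followup_day, msi_high,
    mtc, panel_mb, in_discovery, in_prior_validation.
    ``lines_csv`` columns: patient_id, line_number, start_day, stop_day
    (blank ok), agents (semicolon-separated).
    ``covariates_tsv`` columns: sample_id, tmb, pd1, pdl1, top2a, adam12;
    joined on patient_id == sample_id.
    ``column_map`` renames input columns to this schema.
    """
    pats = pd.read_csv(patients_csv)
    lins = pd.read_csv(lines_csv)
    if column_map:
        pats = pats.rename(columns=dict(column_map))
        lins = lins.rename(columns=dict(column_map))
    cov = None
    if covariates_tsv is not None:
        cov = pd.read_csv(covariates_tsv, sep="\t").set_index("sample_id")

    lines_by_pid: dict[str, list[TherapyLine]] = {}
    for r in lins.itertuples():
        agents = frozenset(a.strip().lower() for a in str(r.agents).split(";") if a.strip())
        stop = None if pd.isna(getattr(r, "stop_day", None)) else int(r.stop_day)
        ln = TherapyLine(
            patient_id=str(r.patient_id),
            line_number=int(r.line_number),
            start_day=int(r.start_day),
            stop_day=stop,
            agents=agents,
        ).classified(drugs)
        lines_by_pid.setdefault(str(r.patient_id), []).append(ln)

    patients = []
    for r in pats.itertuples():
        pid = str(r.patient_id)
        covariates = sample = None
        if cov is not None and pid in cov.index:
            c = cov.loc[pid]
            covariates = MolecularCovariates(
                tmb=float(c.tmb), pd1=float(c.pd1), pdl1=float(c.pdl1),
                top2a=float(c.top2a), adam12=float(c.adam12),
            )
            sample = TumorSample(
                sample_id=pid,
                mtc=float(getattr(r, "mtc", 0.5)),
                panel_mb=float(getattr(r, "panel_mb", 1.0)),
                msi_high=bool(getattr(r, "msi_high", False)),
            )
        death = getattr(r, "death_day", None)
        patients.append(
            Patient(
                patient_id=pid,
                age_at_collection=float(r.age),
                sex=str(r.sex),
                tumor_type=str(r.tumor_type),
                race=str(getattr(r, "race", "unknown")),
                collection_day=int(r.collection_day),
                death_day=None if pd.isna(death) else int(death),
                last_followup_day=int(r.last_followup_day),
                covariates=covariates,
                sample=sample,
                in_discovery=bool(getattr(r, "in_discovery", False)),
                in_prior_validation=bool(getattr(r, "in_prior_validation", False)),
                lines=lines_by_pid.get(pid, []),
            )
        )
    return patients
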