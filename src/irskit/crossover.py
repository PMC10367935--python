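"""Case cross-over comparison: index anti-PD-(L)1 line vs the immediately
preceding systemic line within the same patient.

Each eligible patient contributes a pair (rwPFS1 on the preceding line,
rwPFS2 on the index line). The treatment-by-IRS interaction is tested by
stacking both records per patient and fitting a Cox model with treatment,
IRS group and their interaction; the interaction is assessed by a
likelihood-ratio test against the no-interaction model, with
cluster-robust (by patient) variance on the reported coefficients.

The rwPFS2/rwPFS1 >= 1.3 rule classifies pairs as showing clinical benefit
of the index therapy. Evaluability (the denominator of the rate) requires:
pfs1 ended in an event (a completed PFS), and pfs2 is either an event or
censored beyond 1.3 * pfs1 (so the classification is determinate either
way). This rule is an explicit modelling assumption — see the package
methods documentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import AnalysisCohort, Patient, SurvivalRecord, derive_rwpfs
from .survival import CoxFit, fit_cox, lrt_nested

__all__ = [
    "CrossoverPair",
    "build_crossover_pairs",
    "interaction_lrt",
    "pfs_ratio_classify",
    "RATIO_CUTOFF",
]

RATIO_CUTOFF = 1.3


@dataclass(frozen=True)
class CrossoverPair:
    patient_id: str
    pfs1: SurvivalRecord  # immediately preceding line
    pfs2: SurvivalRecord  # index PD-(L)1 line
    irs_group: str  # two-group status at index
    evaluable: bool
    ratio: float | None  # defined only when evaluable

    def __post_init__(self) -> None:
        if self.evaluable and self.ratio is None:
            raise ValueError("evaluable pair must carry a ratio")


def _evaluable(pfs1: SurvivalRecord, pfs2: SurvivalRecord, cutoff: float) -> bool:
    if pfs1.duration_months <= 0 or not pfs1.event:
        return False
    if pfs2.event:
        return True
    # censored pfs2: determinate only if already beyond the cutoff
    return pfs2.duration_months >= cutoff * pfs1.duration_months


def build_crossover_pairs(
    cohort: AnalysisCohort, cutoff: float = RATIO_CUTOFF
) -> list[CrossoverPair]:
    """One pair per cohort patient whose index line has a preceding systemic
    line (first-line index patients contribute nothing). The preceding line
    is the one with the latest start strictly before the index start."""
    pairs: list[CrossoverPair] = []
    for row in cohort.table.itertuples():
        patient: Patient = cohort.patients[row.patient_id]
        index_line = next(
            ln for ln in patient.lines if ln.start_day == row.start_day
        )
        prev = patient.preceding_line(index_line)
        if prev is None:
            continue
        pfs1 = derive_rwpfs(patient, prev)
        pfs2 = SurvivalRecord(row.rwpfs_months, bool(row.rwpfs_event), "rwPFS")
        ok = _evaluable(pfs1, pfs2, cutoff)
        ratio = pfs2.duration_months / pfs1.duration_months if ok else None
        pairs.append(
            CrossoverPair(row.patient_id, pfs1, pfs2, row.irs_group2, ok, ratio)
        )
    return pairs


def _stack(pairs: list[CrossoverPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        for rec, is_index in ((p.pfs1, 0), (p.pfs2, 1)):
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "duration": rec.duration_months,
                    "event": rec.event,
                    "index_line": is_index,
                    "irs_h": 1 if p.irs_group == "H" else 0,
                }
            )
    return pd.DataFrame(rows)


def interaction_lrt(pairs: list[CrossoverPair]) -> dict:
    """Treatment-by-IRS interaction test on the stacked paired records.

    Returns the LRT statistic/df/p for the interaction, cluster-robust
    coefficient summaries from the full model, and per-IRS-group log-rank
    comparisons of index vs preceding line.
    """
    counts = pd.Series([p.irs_group for p in pairs]).value_counts()
    if counts.get("H", 0) < 2 or counts.get("L", 0) < 2:
        raise ValueError("need >= 2 pairs in each IRS group")
    df = _stack(pairs)
    df["interaction"] = df["index_line"] * df["irs_h"]
    full = fit_cox(
        df, "duration", "event", ["index_line", "irs_h", "interaction"],
        term="interaction", cluster_col="patient_id", robust=True,
    )
    reduced = fit_cox(
        df, "duration", "event", ["index_line", "irs_h"],
        term="index_line", cluster_col="patient_id", robust=True,
    )
    stat, dof, p = lrt_nested(full, reduced)

    from lifelines.statistics import logrank_test

    logrank = {}
    for g, flag in (("H", 1), ("L", 0)):
        sub = df[df["irs_h"] == flag]
        a = sub[sub["index_line"] == 1]
        b = sub[sub["index_line"] == 0]
        res = logrank_test(a["duration"], b["duration"], a["event"], b["event"])
        logrank[g] = float(res.p_value)
    return {
        "lrt_stat": stat,
        "lrt_df": dof,
        "lrt_p": p,
        "full_fit": full,
        "reduced_fit": reduced,
        "interaction_coef": float(full.term_estimates["interaction"]),
        "logrank_p_by_group": logrank,
    }


def pfs_ratio_classify(
    pairs: list[CrossoverPair], cutoff: float = RATIO_CUTOFF
) -> dict:
    """Classify evaluable pairs by rwPFS2/rwPFS1 >= cutoff per IRS group.

    Returns per-group counts/rates and the 2x2 table
    [[H_above, H_below], [L_above, L_below]] ready for the
    Mantel–Haenszel odds-ratio test.
    """
    counts = {g: {"above": 0, "below": 0} for g in ("H", "L")}
    for p in pairs:
        if not p.evaluable:
            continue
        key = "above" if p.ratio >= cutoff else "below"
        counts[p.irs_group][key] += 1
    table = np.array(
        [
            [counts["H"]["above"], counts["H"]["below"]],
            [counts["L"]["above"], counts["L"]["below"]],
        ]
    )
    out = {"table": table, "cutoff": cutoff, "n_evaluable": int(table.sum())}
    for g in ("H", "L"):
        tot = counts[g]["above"] + counts[g]["below"]
        out[g] = {
            "above": counts[g]["above"],
            "total": tot,
            "rate": counts[g]["above"] / tot if tot else float("nan"),
        }
    return out
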