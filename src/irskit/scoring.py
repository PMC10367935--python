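"""Immunotherapy Response Score (IRS) computation and classification.

IRS is a locked linear combination of tumor mutation burden (TMB) and four
gene-expression covariates (PD-1/PDCD1, PD-L1/CD274, TOP2A, ADAM12, each in
log2 normalized-reads-per-million units):

    IRS = 0.273758*TMB + 0.112641*PD1 + 0.061904*PDL1
          - 0.077011*TOP2A - 0.057991*ADAM12

Samples are classified two ways with published, locked thresholds:

* two-group:   IRS-H if score >= 0.873569, else IRS-L
* three-group: IRS-UL if score < 0.41, IRS-IL if 0.41 <= score < 0.873569,
               IRS-H otherwise

Both boundaries are inclusive on the upper group (>= for H, >= for IL at
0.41). Scores are never rounded before classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import pandas as pd

__all__ = [
    "ScoringModel",
    "MolecularCovariates",
    "IRSResult",
    "compute_irs",
    "classify_irs",
    "score_table",
]


@dataclass(frozen=True)
class ScoringModel:
    """Locked IRS coefficients and classification thresholds."""

    coef_tmb: float = 0.273758
    coef_pd1: float = 0.112641
    coef_pdl1: float = 0.061904
    coef_top2a: float = -0.077011
    coef_adam12: float = -0.057991
    threshold_high: float = 0.873569
    threshold_ul: float = 0.41

    def __post_init__(self) -> None:
        if not self.threshold_ul < self.threshold_high:
            raise ValueError(
                "threshold_ul must be below threshold_high "
                f"({self.threshold_ul} vs {self.threshold_high})"
            )


@dataclass(frozen=True)
class MolecularCovariates:
    """Model-scale covariates for one sample.

    ``tmb`` is the TMB covariate on the scale the linear model expects
    (default convention: mutations per megabase as reported by the assay);
    the four expression values are log2 nRPM and may be negative.
    """

    tmb: float
    pd1: float
    pdl1: float
    top2a: float
    adam12: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"covariate {f.name!r} is not finite: {v!r}")


@dataclass(frozen=True)
class IRSResult:
    score: float
    group2: str  # "L" or "H"
    group3: str  # "UL", "IL" or "H"


def compute_irs(cov: MolecularCovariates, model: ScoringModel | None = None) -> float:
    """Return the IRS linear score for one sample (no clipping, no rounding)."""
    model = model or ScoringModel()
    return (
        model.coef_tmb * cov.tmb
        + model.coef_pd1 * cov.pd1
        + model.coef_pdl1 * cov.pdl1
        + model.coef_top2a * cov.top2a
        + model.coef_adam12 * cov.adam12
    )


def classify_irs(score: float, model: ScoringModel | None = None) -> IRSResult:
    """Classify an IRS score into the two-group and three-group schemes.

    The High boundary is inclusive (score >= threshold_high is H) and the
    IL lower boundary is inclusive (score == threshold_ul is IL, not UL).
    """
    model = model or ScoringModel()
    if not math.isfinite(score):
        raise ValueError(f"score is not finite: {score!r}")
    if score >= model.threshold_high:
        return IRSResult(score, "H", "H")
    if score < model.threshold_ul:
        return IRSResult(score, "L", "UL")
    return IRSResult(score, "L", "IL")


#: expected covariate column names in tabular input
COVARIATE_COLUMNS = ("tmb", "pd1", "pdl1", "top2a", "adam12")


def score_table(table: pd.DataFrame, model: ScoringModel | None = None) -> pd.DataFrame:
    """Score a per-sample covariate table.

    Parameters
    ----------
    table
        Must contain ``sample_id`` plus the five covariate columns
        ``tmb, pd1, pdl1, top2a, adam12``.

    Returns
    -------
    A copy of the table with ``score``, ``irs_group2`` and ``irs_group3``
    columns appended.
    """
    model = model or ScoringModel()
    missing = [c for c in ("sample_id", *COVARIATE_COLUMNS) if c not in table.columns]
    if missing:
        raise ValueError(f"covariate table is missing columns: {missing}")
    bad = table[list(COVARIATE_COLUMNS)].apply(
        lambda s: ~pd.to_numeric(s, errors="coerce").apply(math.isfinite)
    )
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        raise ValueError(f"non-finite covariate values in column {col!r}")

    out = table.copy()
    out["score"] = (
        model.coef_tmb * out["tmb"]
        + model.coef_pd1 * out["pd1"]
        + model.coef_pdl1 * out["pdl1"]
        + model.coef_top2a * out["top2a"]
        + model.coef_adam12 * out["adam12"]
    )
    out["irs_group2"] = pd.Series(
        ["H" if s >= model.threshold_high else "L" for s in out["score"]],
        index=out.index,
    )
    out["irs_group3"] = pd.Series(
        [classify_irs(s, model).group3 for s in out["score"]], index=out.index
    )
    return out
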