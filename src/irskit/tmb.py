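"""Tumor-only TMB candidate-mutation filtering and TMB status.

Tumor-only panels cannot subtract germline variants with a matched normal,
so the point-estimate filter removes likely germline calls by three rules:

1. population-database rule: any variant reported in gnomAD is excluded;
2. heterozygous-VAF window: variants with VAF in [0.45, 0.55] are excluded
   when the molecularly informed tumor content (MTC) is below 80% — at low
   tumor content a ~50% VAF is far likelier to be germline than somatic.
   These variants are retained for the *upper bound* of the TMB estimate;
3. clonality rule: only variants with VAF strictly greater than MTC/4 are
   counted (subclonal calls and germline-on-lost-allele artifacts drop out).

TMB-H is called at >= 10 mutations per megabase (inclusive); combined
MSI/TMB status is MSI/TMB-H when either MSI-H or TMB-H.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "VariantCall",
    "TumorSample",
    "TMBResult",
    "filter_candidate_mutations",
    "compute_tmb",
    "tmb_from_variants",
    "read_variant_table",
    "read_variant_vcf",
]

VAF_WINDOW = (0.45, 0.55)  # closed interval
MTC_WINDOW_LIMIT = 0.80  # window applies only when MTC < 80%
TMB_HIGH_THRESHOLD = 10.0  # Muts/Mb, inclusive


@dataclass(frozen=True)
class VariantCall:
    variant_id: str
    vaf: float
    in_gnomad: bool
    eligible: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(
                f"variant {self.variant_id!r}: VAF must be in [0, 1], got {self.vaf}"
            )


@dataclass(frozen=True)
class TumorSample:
    sample_id: str
    mtc: float
    panel_mb: float
    msi_high: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.mtc <= 1.0:
            raise ValueError(f"sample {self.sample_id!r}: MTC must be in (0, 1]")
        if self.panel_mb <= 0:
            raise ValueError(f"sample {self.sample_id!r}: panel_mb must be > 0")


@dataclass(frozen=True)
class TMBResult:
    sample_id: str
    point_estimate: float
    upper_bound: float
    tmb_high: bool
    combined_status: str  # "MSI/TMB-H" or "MSS/TMB-L"


def filter_candidate_mutations(
    variants: Sequence[VariantCall], sample: TumorSample
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Apply the tumor-only germline filters; returns (point_set, upper_set).

    ``point_set`` feeds the TMB point estimate; ``upper_set`` additionally
    keeps variants excluded only by the heterozygous-VAF window and feeds
    the upper bound. Input order is preserved and point_set is a subset of
    upper_set.
    """
    point: list[VariantCall] = []
    upper: list[VariantCall] = []
    window_active = sample.mtc < MTC_WINDOW_LIMIT
    for v in variants:
        if not v.eligible or v.in_gnomad:
            continue
        if not v.vaf > sample.mtc / 4.0:
            continue
        in_window = VAF_WINDOW[0] <= v.vaf <= VAF_WINDOW[1]
        upper.append(v)
        if not (window_active and in_window):
            point.append(v)
    return point, upper


def compute_tmb(point_count: int, upper_count: int, sample: TumorSample) -> TMBResult:
    """Convert filtered mutation counts to Muts/Mb and status calls."""
    if point_count < 0 or upper_count < point_count:
        raise ValueError("require 0 <= point_count <= upper_count")
    point = point_count / sample.panel_mb
    upper = upper_count / sample.panel_mb
    tmb_high = point >= TMB_HIGH_THRESHOLD
    combined = "MSI/TMB-H" if (tmb_high or sample.msi_high) else "MSS/TMB-L"
    return TMBResult(sample.sample_id, point, upper, tmb_high, combined)


def tmb_from_variants(variants: Sequence[VariantCall], sample: TumorSample) -> TMBResult:
    """Filter and count in one step."""
    point, upper = filter_candidate_mutations(variants, sample)
    return compute_tmb(len(point), len(upper), sample)


def read_variant_table(path: str | Path) -> list[VariantCall]:
    """Read variants from a TSV with columns variant_id, vaf, in_gnomad[, eligible]."""
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "vaf", "in_gnomad"}
    if missing := required - set(df.columns):
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if "eligible" not in df.columns:
        df["eligible"] = True
    return [
        VariantCall(str(r.variant_id), float(r.vaf), bool(r.in_gnomad), bool(r.eligible))
        for r in df.itertuples()
    ]


def read_variant_vcf(
    path: str | Path,
    vaf_field: str = "VAF",
    gnomad_field: str = "GNOMAD",
) -> list[VariantCall]:
    """Read variants from a VCF.

    VAF is taken from the named INFO field; gnomAD membership from a flag or
    0/1 INFO field. Records failing FILTER (other than PASS/'.') are marked
    ineligible rather than dropped, so the audit trail keeps them.
    """
    import pysam

    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}>{','.join(rec.alts or ('.',))}"
            info = dict(rec.info)
            if vaf_field not in info:
                raise ValueError(f"record {vid}: INFO field {vaf_field!r} missing")
            raw = info[vaf_field]
            vaf = float(raw[0] if isinstance(raw, tuple) else raw)
            gno = bool(info.get(gnomad_field, False))
            filters = set(rec.filter.keys())
            eligible = filters <= {"PASS"}
            calls.append(VariantCall(vid, vaf, gno, eligible))
    return calls


def tmb_table(
    variant_sets: Iterable[tuple[TumorSample, Sequence[VariantCall]]]
) -> pd.DataFrame:
    """Per-sample TMB results as a tidy frame."""
    rows = []
    for sample, variants in variant_sets:
        res = tmb_from_variants(variants, sample)
        rows.append(
            {
                "sample_id": res.sample_id,
                "tmb": res.point_estimate,
                "tmb_upper": res.upper_bound,
                "tmb_high": res.tmb_high,
                "combined_status": res.combined_status,
            }
        )
    return pd.DataFrame(rows)
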