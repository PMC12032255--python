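"""Per-sample metabarcoding quality scores and control-derived removal
thresholds.

MTQ (technical quality) is the fraction of a sample's demultiplexed reads that
could be assigned to any reference taxon before filtering; MAQ (analytical
quality) is the fraction belonging to variants that survive the full filter
cascade.  Negative controls — dominated by unassignable or filtered-out
reads — score low on both, so removal thresholds are set just above the
control maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .tables import (
    ReplicateReadTable,
    ValidationError,
    eligible_control_ids,
)

SCORE_COLUMNS = ["sample_id", "mtq", "maq"]


@dataclass(frozen=True)
class QualityThresholds:
    mtq_min: float
    maq_min: float

    def __post_init__(self) -> None:
        for name, v in (("mtq_min", self.mtq_min), ("maq_min", self.maq_min)):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


def compute_quality_scores(
    raw_table: ReplicateReadTable,
    assignments: pd.DataFrame,
    filtered_table: ReplicateReadTable,
) -> pd.DataFrame:
    """MTQ/MAQ per sample from three snapshots of one pipeline run.

    ``raw_table`` is the demultiplexed table, ``assignments`` the pre-filter
    variant → taxon calls, and ``filtered_table`` the post-cascade table.
    MTQ(s) = assigned reads of s / total reads of s; MAQ(s) = reads of s on
    variants retained in ``filtered_table`` / total reads of s.  Read-free
    samples score 0 on both.
    """
    raw_samples = set(raw_table.counts["sample_id"])
    extra = set(filtered_table.counts["sample_id"]) - raw_samples
    if extra:
        raise ValidationError(
            f"samples present in filtered but not raw table: {sorted(extra)[:3]} "
            "(snapshots are not from the same pipeline run)"
        )

    totals = raw_table.sample_totals()
    assigned_variants = set(assignments["variant_id"])
    retained_variants = set(filtered_table.counts["variant_id"])

    c = raw_table.counts
    assigned = (
        c[c["variant_id"].isin(assigned_variants)].groupby("sample_id")["reads"].sum()
    )
    retained = (
        c[c["variant_id"].isin(retained_variants)].groupby("sample_id")["reads"].sum()
    )

    rows = []
    for sample in sorted(raw_samples):
        total = int(totals.get(sample, 0))
        if total == 0:
            mtq = maq = 0.0
        else:
            mtq = float(assigned.get(sample, 0)) / total
            maq = float(retained.get(sample, 0)) / total
        rows.append({"sample_id": sample, "mtq": mtq, "maq": maq})
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def derive_thresholds(
    control_scores: pd.DataFrame,
    margin_mtq: float = 0.01,
    margin_maq: float = 0.01,
) -> QualityThresholds:
    """Thresholds = per-score maximum over eligible controls plus a margin.

    ``control_scores`` must contain only the eligible (C1–C6) controls; use
    :func:`control_quality_scores` to subset.
    """
    if control_scores.empty:
        raise ValidationError(
            "no eligible controls to derive quality thresholds from; "
            "pass explicit mtq_min/maq_min instead"
        )
    return QualityThresholds(
        mtq_min=float(control_scores["mtq"].max()) + margin_mtq,
        maq_min=float(control_scores["maq"].max()) + margin_maq,
    )


def control_quality_scores(
    scores: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    eligible = set(eligible_control_ids(meta))
    return scores[scores["sample_id"].isin(eligible)].reset_index(drop=True)


def filter_low_quality_samples(
    scores: pd.DataFrame,
    thresholds: QualityThresholds,
    meta: pd.DataFrame,
) -> tuple[list[str], list[str]]:
    """Split sediment samples into (kept, removed).

    A sediment sample is removed iff MTQ < mtq_min OR MAQ < maq_min (strict,
    matching the "and/or" rule); controls are never in either list — they are
    excluded from downstream analysis regardless of score.
    """
    sediment = set(meta.loc[meta["sample_type"] == "sediment", "sample_id"])
    kept, removed = [], []
    for row in scores.itertuples():
        if row.sample_id not in sediment:
            continue
        if row.mtq < thresholds.mtq_min or row.maq < thresholds.maq_min:
            removed.append(row.sample_id)
        else:
            kept.append(row.sample_id)
    return sorted(kept), sorted(removed)
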