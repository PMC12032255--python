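"""Mammal detection records: contamination rates from negative controls,
the sporadic pre-8-ka exclusion rule for domesticates, and first appearances.

Domesticated taxa (cattle, sheep, goat, deer) occur sporadically in negative
controls, so single, isolated PCR-replicate detections of domesticates in
samples older than the regional domestication horizon are flagged and excluded
rather than read as genuine presences.
"""

from __future__ import annotations

import pandas as pd

from .tables import (
    ReplicateReadTable,
    ValidationError,
    negative_control_ids,
    sediment_ids,
)

DEFAULT_EXCLUSION_TAXA = ("Bos taurus", "Ovis aries", "Capra hircus")
DEFAULT_AGE_CUTOFF_KA = 8.0

RECORD_COLUMNS = [
    "taxon",
    "sample_id",
    "age_ka",
    "lake_id",
    "region",
    "n_pos_replicates",
    "reads",
    "sporadic",
    "excluded",
]


def build_detection_records(
    taxon_table: ReplicateReadTable, meta: pd.DataFrame
) -> pd.DataFrame:
    """One row per (taxon, sediment sample) with any retained reads.

    ``sporadic`` marks single-replicate detections; ``excluded`` starts False
    and is set by :func:`apply_exclusion_rule`.
    """
    sed = set(sediment_ids(meta))
    c = taxon_table.counts
    c = c[c["sample_id"].isin(sed)]
    if c.empty:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    g = (
        c.groupby(["variant_id", "sample_id"])
        .agg(n_pos_replicates=("reads", "size"), reads=("reads", "sum"))
        .reset_index()
        .rename(columns={"variant_id": "taxon"})
    )
    info = meta.set_index("sample_id")[["age_ka", "lake_id", "region"]]
    g = g.join(info, on="sample_id")
    g["sporadic"] = g["n_pos_replicates"] == 1
    g["excluded"] = False
    return g[RECORD_COLUMNS].sort_values(["taxon", "age_ka"]).reset_index(drop=True)


def contamination_rates(
    taxon_table: ReplicateReadTable, meta: pd.DataFrame, taxa
) -> dict[str, float]:
    """Fraction of negative controls (C1–C7) with >= 1 retained read per taxon."""
    controls = negative_control_ids(meta)
    if not controls:
        raise ValidationError("no negative controls available")
    c = taxon_table.counts
    c = c[c["sample_id"].isin(set(controls))]
    hit_controls = c.groupby("variant_id")["sample_id"].nunique()
    return {t: float(hit_controls.get(t, 0)) / len(controls) for t in taxa}


def apply_exclusion_rule(
    records: pd.DataFrame,
    taxa=DEFAULT_EXCLUSION_TAXA,
    age_cutoff_ka: float = DEFAULT_AGE_CUTOFF_KA,
) -> pd.DataFrame:
    """Flag single-replicate detections of the listed domesticates strictly
    older than ``age_cutoff_ka`` as excluded.  Multi-replicate and post-cutoff
    detections are never touched."""
    if records.empty:
        return records.copy()
    if records["age_ka"].isna().any():
        s = records.loc[records["age_ka"].isna(), "sample_id"].iloc[0]
        raise ValidationError(f"record for sample {s!r} lacks an age")
    out = records.copy()
    out["excluded"] = (
        out["taxon"].isin(set(taxa))
        & (out["age_ka"] > age_cutoff_ka)
        & (out["n_pos_replicates"] == 1)
    )
    return out


def first_appearance(
    records: pd.DataFrame, taxon: str, scope: str = "all"
) -> float | dict[str, float] | None:
    """Oldest non-excluded detection age for a taxon.

    scope="all" returns a single age (or None), scope="region"/"lake" a dict
    keyed by region or lake (empty scopes absent).
    """
    hits = records[(records["taxon"] == taxon) & ~records["excluded"]]
    if scope == "all":
        return float(hits["age_ka"].max()) if len(hits) else None
    if scope == "region":
        key = "region"
    elif scope == "lake":
        key = "lake_id"
    else:
        raise ValidationError(f"unknown scope {scope!r}; use all|region|lake")
    return {k: float(v) for k, v in hits.groupby(key)["age_ka"].max().items()}
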