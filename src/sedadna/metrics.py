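"""Replicate-weighted abundance (wtRep, RAI) and Hill-N0 diversity.

All metrics are computed from the fully filtered taxon-level table.  For a
taxon t in sample s with R performed PCR replicates:

* ``wtrep(t, s)`` — sum over the sample's replicates of t's within-replicate
  read proportion; a relative detectability measure in [0, R].
* ``wtrep_prop = wtrep / R`` in [0, 1].
* ``RAI(t, s)`` — (t's read proportion within s) x wtrep_prop; a proportional
  abundance index in [0, 1].
* scaled RAI — RAI divided by the summed RAI of all taxa in a plotted group,
  so group shares sum to 1 per sample.
* Hill N0 — order-0 diversity, the count of taxa detected (wtrep_prop > 0).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import ReplicateReadTable, ValidationError

MATRIX_COLUMNS = [
    "taxon",
    "sample_id",
    "reads",
    "n_pos_replicates",
    "wtrep",
    "wtrep_prop",
    "rai",
]

GROWTH_FORMS = ("forb", "graminoid", "shrub", "tree")
ELEVATION_BELTS = ("montane", "subalpine", "alpine", "nival")


def compute_wtrep(table: ReplicateReadTable) -> pd.DataFrame:
    """Per-(taxon, sample) reads, positive replicates, wtRep and wtRep_prop.

    ``table`` must be taxon-collapsed and fully filtered; empty replicates
    contribute 0 to the wtRep sum, and the denominator of ``wtrep_prop`` is
    the number of replicates *performed* (``table.n_replicates``), not the
    number with surviving reads.
    """
    c = table.counts
    if c.empty:
        return pd.DataFrame(columns=MATRIX_COLUMNS)
    cell_totals = c.groupby(["sample_id", "replicate"])["reads"].transform("sum")
    prop = c["reads"] / cell_totals
    f = c.assign(prop=prop)
    g = f.groupby(["variant_id", "sample_id"])
    out = g.agg(
        reads=("reads", "sum"),
        n_pos_replicates=("reads", "size"),
        wtrep=("prop", "sum"),
    ).reset_index()
    out = out.rename(columns={"variant_id": "taxon"})
    out["wtrep_prop"] = out["wtrep"] / table.n_replicates
    return out


def compute_rai(matrix: pd.DataFrame) -> pd.DataFrame:
    """Add the RAI column: read proportion within the sample x wtRep_prop."""
    sample_totals = matrix.groupby("sample_id")["reads"].transform("sum")
    read_prop = np.where(sample_totals > 0, matrix["reads"] / sample_totals, 0.0)
    out = matrix.copy()
    out["rai"] = read_prop * out["wtrep_prop"]
    return out


def build_taxon_sample_matrix(table: ReplicateReadTable) -> pd.DataFrame:
    """Convenience: wtRep fields plus RAI in one call."""
    return compute_rai(compute_wtrep(table))[MATRIX_COLUMNS]


def scale_rai(matrix: pd.DataFrame, group) -> pd.DataFrame:
    """Scaled RAI within a plotted taxon group.

    Rows for taxa outside ``group`` get ``rai_scaled`` NaN; within the group,
    scaled values sum to 1 per sample unless the group has no signal there
    (then all 0).
    """
    group = set(group)
    if not group:
        raise ValidationError("scale_rai requires a non-empty taxon group")
    out = matrix.copy()
    member = out["taxon"].isin(group)
    sums = out[member].groupby("sample_id")["rai"].transform("sum")
    scaled = pd.Series(np.nan, index=out.index, dtype=float)
    scaled.loc[member[member].index] = np.where(
        sums > 0, out.loc[member, "rai"] / sums, 0.0
    )
    out["rai_scaled"] = scaled
    return out


def hill_n0(matrix: pd.DataFrame, taxa=None, sample_id: str | None = None):
    """Order-0 Hill number: taxa with wtrep_prop > 0.

    With ``sample_id`` given, returns that sample's count; otherwise a Series
    indexed by sample (samples with no detections are simply absent).
    """
    m = matrix
    if taxa is not None:
        m = m[m["taxon"].isin(set(taxa))]
    m = m[m["wtrep_prop"] > 0]
    per_sample = m.groupby("sample_id")["taxon"].nunique()
    if sample_id is not None:
        return int(per_sample.get(sample_id, 0))
    return per_sample


def validate_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    forms = annotations["growth_form"].dropna()
    bad = set(forms) - set(GROWTH_FORMS)
    if bad:
        raise ValidationError(f"unknown growth_form labels: {sorted(bad)}")
    belts = annotations["elevation_belt"].dropna()
    bad = set(belts) - set(ELEVATION_BELTS)
    if bad:
        raise ValidationError(f"unknown elevation_belt labels: {sorted(bad)}")
    return annotations


def aggregate_groups(
    matrix: pd.DataFrame, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample diversity and abundance summaries by ecological group.

    Returns one row per sample with Hill N0 for all taxa and per growth form,
    plus summed scaled-RAI shares per growth form, for light-indicator taxa,
    grazing-indicator taxa, and per elevation belt.  For each categorical
    aggregation the scaling group is the set of taxa annotated for *that*
    category; unannotated taxa are excluded from that aggregation only.
    """
    validate_annotations(annotations)
    ann = annotations.set_index("taxon")
    samples = sorted(matrix["sample_id"].unique())
    out = pd.DataFrame({"sample_id": samples}).set_index("sample_id")

    out["n0_total"] = hill_n0(matrix).reindex(samples, fill_value=0)
    form_of = ann["growth_form"].dropna()
    for form in GROWTH_FORMS:
        taxa = set(form_of.index[form_of == form])
        out[f"n0_{form}"] = hill_n0(matrix, taxa=taxa).reindex(samples, fill_value=0)

    def _shares(classes: pd.Series, prefix: str, values) -> None:
        members = set(classes.index)
        if not members:
            for v in values:
                out[f"{prefix}_{v}"] = 0.0
            return
        scaled = scale_rai(matrix, members)
        scaled = scaled[scaled["taxon"].isin(members)].copy()
        scaled["cls"] = scaled["taxon"].map(classes)
        pivot = (
            scaled.groupby(["sample_id", "cls"], observed=True)["rai_scaled"]
            .sum()
            .unstack(fill_value=0.0)
        )
        for v in values:
            col = pivot[v] if v in pivot.columns else pd.Series(0.0, index=pivot.index)
            out[f"{prefix}_{v}"] = col.reindex(samples, fill_value=0.0)

    _shares(form_of, "rai", GROWTH_FORMS)

    light = ann["light"].dropna().astype(bool)
    _shares(light.map({True: "light", False: "other"}), "rai_share", ["light"])
    grazing = ann["grazing"].dropna().astype(bool)
    _shares(grazing.map({True: "grazing", False: "other"}), "rai_share", ["grazing"])
    belts = ann["elevation_belt"].dropna()
    _shares(belts, "rai_belt", ELEVATION_BELTS)

    return out.reset_index()
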