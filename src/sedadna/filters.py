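"""Variant-level retention filtering, homopolymer error merging, and
negative-control-based decontamination.

Stages run in a fixed order (order changes results, so it is part of the
contract):

1. :class:`HomopolymerMerger` — merge run-length-equivalent variants into the
   most abundant source sequence.
2. :class:`RetentionFilter` — zero weak cells (< 3 reads per PCR replicate),
   then drop variants with < 10 total reads or < 3 positive replicates across
   the whole dataset.
3. :class:`ControlEnrichmentScreen` — drop variants whose mean per-replicate
   relative frequency in eligible negative controls exceeds that in sediment
   samples.
4. :class:`KnownContaminantFilter` — drop variants assigned to a user-supplied
   list of common laboratory contaminants.

Each stage is an sklearn-style transformer over :class:`ReplicateReadTable`;
module-level functions wrap them for one-shot use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from sklearn.base import BaseEstimator

from .tables import (
    ReplicateReadTable,
    ValidationError,
    eligible_control_ids,
    sediment_ids,
)


@dataclass
class FilterThresholds:
    """Retention thresholds (defaults are the workflow's printed values)."""

    min_reads_per_replicate: int = 3
    min_total_reads: int = 10
    min_replicates_dataset: int = 3
    known_contaminants: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in (
            "min_reads_per_replicate",
            "min_total_reads",
            "min_replicates_dataset",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        self.known_contaminants = frozenset(self.known_contaminants)


def run_length_compress(seq: str) -> str:
    """Collapse homopolymer runs: ``AAATG`` → ``ATG``."""
    out = []
    prev = None
    for ch in seq:
        if ch != prev:
            out.append(ch)
            prev = ch
    return "".join(out)


class HomopolymerMerger(BaseEstimator):
    """Merge sequence variants that differ only in homopolymer run lengths.

    Variants with identical run-length-compressed sequences are pooled into a
    single source variant: the one with the highest dataset-wide read total
    (ties broken by lexicographically smaller sequence).  Counts are summed
    per (sample, replicate).  Idempotent by construction: the surviving
    variants all have distinct compressed forms.
    """

    def fit(self, table: ReplicateReadTable, y=None):
        return self

    def transform(self, table: ReplicateReadTable) -> ReplicateReadTable:
        merged, self.merge_log_ = merge_error_variants(table)
        return merged


def merge_error_variants(
    table: ReplicateReadTable, assignments: pd.DataFrame | None = None
) -> tuple[ReplicateReadTable, pd.DataFrame]:
    """Functional form of :class:`HomopolymerMerger`.

    Returns the merged table and a log with one row per absorbed variant
    (columns: merged_variant, source_variant, merged_reads; plus merged_taxon
    when ``assignments`` are supplied, for audit only).
    """
    groups: dict[str, list[str]] = {}
    for vid in table.counts["variant_id"].unique():
        seq = table.sequences.get(vid)
        key = run_length_compress(seq) if seq is not None else f"\x00{vid}"
        groups.setdefault(key, []).append(vid)

    totals = table.variant_totals()
    rename: dict[str, str] = {}
    log_rows = []
    taxon_of = (
        dict(zip(assignments["variant_id"], assignments["taxon"]))
        if assignments is not None
        else {}
    )
    for members in groups.values():
        if len(members) == 1:
            continue
        source = min(
            members,
            key=lambda v: (-int(totals.get(v, 0)), table.sequences.get(v, "")),
        )
        for v in members:
            if v == source:
                continue
            rename[v] = source
            log_rows.append(
                {
                    "merged_variant": v,
                    "source_variant": source,
                    "merged_reads": int(totals.get(v, 0)),
                    "merged_taxon": taxon_of.get(v, ""),
                }
            )

    log = pd.DataFrame(
        log_rows,
        columns=["merged_variant", "source_variant", "merged_reads", "merged_taxon"],
    )
    if not rename:
        return table.copy(), log
    c = table.counts
    new_counts = (
        c.assign(variant_id=c["variant_id"].map(lambda v: rename.get(v, v)))
        .groupby(["sample_id", "replicate", "variant_id"], as_index=False)["reads"]
        .sum()
    )
    return table.with_counts(new_counts), log


class RetentionFilter(BaseEstimator):
    """Per-cell and dataset-wide read/replicate retention thresholds.

    (a) cells with fewer than ``min_reads_per_replicate`` reads are zeroed;
    (b) after (a), variants with dataset-wide totals below ``min_total_reads``
    or positive replicates below ``min_replicates_dataset`` are removed.
    Zeroed cells do not count as representation in (b).
    """

    def __init__(
        self,
        min_reads_per_replicate: int = 3,
        min_total_reads: int = 10,
        min_replicates_dataset: int = 3,
    ):
        self.min_reads_per_replicate = min_reads_per_replicate
        self.min_total_reads = min_total_reads
        self.min_replicates_dataset = min_replicates_dataset

    def fit(self, table: ReplicateReadTable, y=None):
        return self

    def transform(self, table: ReplicateReadTable) -> ReplicateReadTable:
        c = table.counts
        c = c[c["reads"] >= self.min_reads_per_replicate]
        if c.empty:
            return table.with_counts(c)
        totals = c.groupby("variant_id")["reads"].sum()
        n_reps = c.groupby("variant_id").size()
        keep = totals.index[
            (totals >= self.min_total_reads) & (n_reps >= self.min_replicates_dataset)
        ]
        return table.with_counts(c[c["variant_id"].isin(set(keep))])


def apply_retention_filters(
    table: ReplicateReadTable, thresholds: FilterThresholds | None = None
) -> ReplicateReadTable:
    t = thresholds or FilterThresholds()
    return RetentionFilter(
        t.min_reads_per_replicate, t.min_total_reads, t.min_replicates_dataset
    ).transform(table)


class ControlEnrichmentScreen(BaseEstimator):
    """Remove variants more frequent (on average) in negative-control PCR
    replicates than in sediment-sample replicates.

    A variant's frequency in a replicate is its reads divided by the
    replicate's total retained reads; replicates without reads contribute
    frequency 0, and every performed replicate (R per sample) enters the mean.
    Only controls of types C1–C6 are eligible; removal requires a *strictly*
    greater control mean.

    Removing a variant changes the per-replicate denominators of the rest, so
    the rule is re-applied until no further variant qualifies; the fixpoint
    makes the screen (and the cascade) idempotent.
    """

    def fit(self, table: ReplicateReadTable, meta: pd.DataFrame):
        controls = eligible_control_ids(meta)
        sediments = sediment_ids(meta)
        n_control_cells = len(controls) * table.n_replicates
        n_sediment_cells = len(sediments) * table.n_replicates
        self.skipped_ = False
        if n_control_cells == 0:
            warnings.warn(
                "no eligible control replicates; control-enrichment screen skipped",
                stacklevel=2,
            )
            self.skipped_ = True
            self.removed_variants_ = []
            return self

        ctrl = set(controls)
        sed = set(sediments)
        removed: set[str] = set()
        c = table.counts
        while True:
            if c.empty:
                break
            cell_totals = c.groupby(["sample_id", "replicate"])["reads"].transform("sum")
            f = c.assign(freq=c["reads"] / cell_totals)
            ctrl_sum = (
                f[f["sample_id"].isin(ctrl)].groupby("variant_id")["freq"].sum()
            )
            sed_sum = f[f["sample_id"].isin(sed)].groupby("variant_id")["freq"].sum()
            variants = pd.Index(c["variant_id"].unique())
            ctrl_mean = ctrl_sum.reindex(variants, fill_value=0.0) / n_control_cells
            if n_sediment_cells:
                sed_mean = sed_sum.reindex(variants, fill_value=0.0) / n_sediment_cells
            else:
                sed_mean = pd.Series(0.0, index=variants)
            hits = set(variants[ctrl_mean > sed_mean])
            if not hits:
                break
            removed |= hits
            c = c[~c["variant_id"].isin(hits)]
        self.removed_variants_ = sorted(removed)
        return self

    def transform(self, table: ReplicateReadTable) -> ReplicateReadTable:
        if self.skipped_:
            return table.copy()
        return table.drop_variants(self.removed_variants_)


def remove_control_enriched(
    table: ReplicateReadTable, meta: pd.DataFrame
) -> tuple[ReplicateReadTable, list[str]]:
    screen = ControlEnrichmentScreen().fit(table, meta)
    return screen.transform(table), list(screen.removed_variants_)


class KnownContaminantFilter(BaseEstimator):
    """Drop variants assigned to listed contaminant taxa (unassigned variants
    are never touched by this screen)."""

    def __init__(self, contaminants=()):
        self.contaminants = frozenset(contaminants)

    def fit(self, table: ReplicateReadTable, assignments: pd.DataFrame):
        hits = assignments[assignments["taxon"].isin(self.contaminants)]
        self.removed_variants_ = sorted(set(hits["variant_id"]))
        return self

    def transform(self, table: ReplicateReadTable) -> ReplicateReadTable:
        return table.drop_variants(self.removed_variants_)


def remove_known_contaminants(
    table: ReplicateReadTable,
    assignments: pd.DataFrame,
    contaminants,
) -> ReplicateReadTable:
    return KnownContaminantFilter(contaminants).fit(table, assignments).transform(table)


class FilterCascade(BaseEstimator):
    """The full four-stage cascade in its fixed order.

    ``fit_transform(table, meta=..., assignments=...)`` returns the filtered
    table; per-stage outputs are kept on the fitted object for audit
    (``merge_log_``, ``control_removed_``, ``contaminant_removed_``).
    """

    def __init__(self, thresholds: FilterThresholds | None = None):
        self.thresholds = thresholds

    def fit_transform(
        self,
        table: ReplicateReadTable,
        meta: pd.DataFrame,
        assignments: pd.DataFrame | None = None,
    ) -> ReplicateReadTable:
        t = self.thresholds or FilterThresholds()
        table, self.merge_log_ = merge_error_variants(table, assignments)
        table = apply_retention_filters(table, t)
        screen = ControlEnrichmentScreen().fit(table, meta)
        table = screen.transform(table)
        self.control_removed_ = list(screen.removed_variants_)
        if assignments is not None and t.known_contaminants:
            contam = KnownContaminantFilter(t.known_contaminants).fit(
                table, assignments
            )
            table = contam.transform(table)
            self.contaminant_removed_ = list(contam.removed_variants_)
        else:
            self.contaminant_removed_ = []
        return table
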