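"""End-to-end orchestration: demultiplexed tables in, filtered taxon-level
matrices, quality calls and mammal records out.

Stage order (plants, trnL P6-loop):

1. short/singleton removal
2. exact-match taxonomic assignment; unassigned variants drop out
3. filter cascade (homopolymer merge → retention thresholds → control screen →
   known-contaminant list)
4. MTQ/MAQ quality scoring, control-derived thresholds, sample removal
5. taxon collapse and wtRep/RAI/Hill-N0 matrices

The mammal (16S) arm differs in assignment (>= 95% identity) and skips sample
quality, feeding detection records and the sporadic pre-8-ka exclusion instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import mammals as mammal_mod
from .assign import ReferenceLibrary, Taxonomy, assign_mammals, assign_plants, collapse_by_taxon
from .filters import FilterCascade, FilterThresholds
from .metrics import build_taxon_sample_matrix
from .quality import (
    QualityThresholds,
    compute_quality_scores,
    control_quality_scores,
    derive_thresholds,
    filter_low_quality_samples,
)
from .seq_io import remove_short_and_singletons
from .tables import ReplicateReadTable, sediment_ids


@dataclass
class PlantPipelineResult:
    raw_table: ReplicateReadTable
    assignments: pd.DataFrame
    filtered_table: ReplicateReadTable
    taxon_table: ReplicateReadTable
    matrix: pd.DataFrame
    quality_scores: pd.DataFrame
    quality_thresholds: QualityThresholds | None
    kept_samples: list[str]
    removed_samples: list[str]
    cascade: FilterCascade

    @property
    def taxa(self) -> list[str]:
        return sorted(self.taxon_table.counts["variant_id"].unique())


@dataclass
class MammalPipelineResult:
    raw_table: ReplicateReadTable
    assignments: pd.DataFrame
    filtered_table: ReplicateReadTable
    taxon_table: ReplicateReadTable
    matrix: pd.DataFrame
    records: pd.DataFrame
    contamination_rates: dict[str, float]
    cascade: FilterCascade


def run_plant_pipeline(
    table: ReplicateReadTable,
    meta: pd.DataFrame,
    libraries: list[ReferenceLibrary],
    taxonomy: Taxonomy | None = None,
    thresholds: FilterThresholds | None = None,
    quality_thresholds: QualityThresholds | None = None,
    margin_mtq: float = 0.02,
    margin_maq: float = 0.01,
) -> PlantPipelineResult:
    """Run the full plant arm.  ``quality_thresholds`` overrides the
    control-derived thresholds when given."""
    raw = table
    work = remove_short_and_singletons(table)
    assignments = assign_plants(work.sequences, libraries, taxonomy)
    work = work.keep_variants(set(assignments["variant_id"]))

    cascade = FilterCascade(thresholds)
    filtered = cascade.fit_transform(work, meta, assignments)

    scores = compute_quality_scores(raw, assignments, filtered)
    if quality_thresholds is None:
        qt = derive_thresholds(
            control_quality_scores(scores, meta), margin_mtq, margin_maq
        )
    else:
        qt = quality_thresholds
    kept, removed = filter_low_quality_samples(scores, qt, meta)

    analysis_table = filtered.restrict_samples(kept)
    taxon_table = collapse_by_taxon(analysis_table, assignments)
    matrix = build_taxon_sample_matrix(taxon_table)
    return PlantPipelineResult(
        raw_table=raw,
        assignments=assignments,
        filtered_table=filtered,
        taxon_table=taxon_table,
        matrix=matrix,
        quality_scores=scores,
        quality_thresholds=qt,
        kept_samples=kept,
        removed_samples=removed,
        cascade=cascade,
    )


def run_mammal_pipeline(
    table: ReplicateReadTable,
    meta: pd.DataFrame,
    library: ReferenceLibrary,
    taxonomy: Taxonomy | None = None,
    thresholds: FilterThresholds | None = None,
    min_identity: float = 95.0,
    exclusion_taxa=mammal_mod.DEFAULT_EXCLUSION_TAXA,
    age_cutoff_ka: float = mammal_mod.DEFAULT_AGE_CUTOFF_KA,
    rate_taxa=None,
) -> MammalPipelineResult:
    """Run the full mammal arm, ending in exclusion-flagged detection records
    and per-taxon control contamination rates."""
    raw = table
    work = remove_short_and_singletons(table)
    assignments = assign_mammals(
        work.sequences, library, taxonomy, min_identity=min_identity
    )
    work = work.keep_variants(set(assignments["variant_id"]))

    cascade = FilterCascade(thresholds)
    filtered = cascade.fit_transform(work, meta, assignments)

    taxon_table = collapse_by_taxon(filtered, assignments)
    if rate_taxa is None:
        rate_taxa = sorted(assignments["taxon"].unique())
    rates = mammal_mod.contamination_rates(taxon_table, meta, rate_taxa)

    sediment_table = taxon_table.restrict_samples(sediment_ids(meta))
    matrix = build_taxon_sample_matrix(sediment_table)
    records = mammal_mod.build_detection_records(taxon_table, meta)
    records = mammal_mod.apply_exclusion_rule(records, exclusion_taxa, age_cutoff_ka)
    return MammalPipelineResult(
        raw_table=raw,
        assignments=assignments,
        filtered_table=filtered,
        taxon_table=taxon_table,
        matrix=matrix,
        records=records,
        contamination_rates=rates,
        cascade=cascade,
    )
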