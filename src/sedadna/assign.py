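"""Taxonomic assignment of sequence variants against prioritized reference
libraries.

Plants (trnL P6-loop) are assigned only on an exact (100%) sequence match, with
library priority deciding conflicts between libraries and a lowest-common-label
rule deciding multi-taxon matches within one library.  Mammals (16S) are
assigned by global alignment identity with a 95% floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

from .tables import ReplicateReadTable, ValidationError

ASSIGNMENT_COLUMNS = ["variant_id", "taxon", "percent_identity", "library"]


@dataclass
class ReferenceLibrary:
    """A named reference library with a priority rank (1 = consulted first)."""

    name: str
    priority_rank: int
    records: list[tuple[str, str]] = field(default_factory=list)
    """(taxon_label, sequence) pairs; one taxon may have several sequences."""

    def __post_init__(self) -> None:
        for taxon, seq in self.records:
            if not seq:
                raise ValidationError(
                    f"library {self.name!r}: empty sequence for {taxon!r}"
                )

    def sequence_index(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {}
        for taxon, seq in self.records:
            idx.setdefault(seq.upper(), set()).add(taxon)
        return idx


class Taxonomy:
    """A label → parent-label tree used for lowest-common-label resolution."""

    def __init__(self, parents: dict[str, str]):
        self.parents = dict(parents)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Taxonomy":
        return cls(dict(zip(df["taxon"], df["parent"])))

    def lineage(self, label: str) -> list[str]:
        out = [label]
        seen = {label}
        while label in self.parents:
            label = self.parents[label]
            if label in seen:  # defensive: cyclic input
                raise ValidationError(f"cycle in taxonomy at {label!r}")
            seen.add(label)
            out.append(label)
        return out

    def lowest_common_label(self, labels) -> str | None:
        """Deepest label shared by every lineage, or None if the labels share
        no ancestor in the table."""
        labels = sorted(set(labels))
        if len(labels) == 1:
            return labels[0]
        lineages = [self.lineage(lb) for lb in labels]
        common = set(lineages[0])
        for lin in lineages[1:]:
            common &= set(lin)
        if not common:
            return None
        # lineage order is species -> root, so the first common entry is deepest
        for label in lineages[0]:
            if label in common:
                return label
        return None


def _validate_libraries(libraries: list[ReferenceLibrary]) -> list[ReferenceLibrary]:
    if not libraries:
        raise ValidationError("at least one reference library is required")
    ranks = [lib.priority_rank for lib in libraries]
    if len(set(ranks)) != len(ranks):
        raise ValidationError("library priority ranks must be unique")
    return sorted(libraries, key=lambda lib: lib.priority_rank)


def _resolve_multi(taxa: set[str], taxonomy: Taxonomy | None) -> str | None:
    if len(taxa) == 1:
        return next(iter(taxa))
    if taxonomy is None:
        raise ValidationError(
            f"sequence matches multiple taxa {sorted(taxa)} but no taxonomy "
            "table was provided for lowest-common-label resolution"
        )
    return taxonomy.lowest_common_label(taxa)


def assign_plants(
    variants: dict[str, str],
    libraries: list[ReferenceLibrary],
    taxonomy: Taxonomy | None = None,
) -> pd.DataFrame:
    """Exact-match assignment of plant variants.

    Parameters
    ----------
    variants
        Mapping variant_id → sequence.
    libraries
        Reference libraries; consulted in increasing ``priority_rank`` order,
        and the first library containing an exact match supplies the label.
    taxonomy
        Needed only when one library maps the same sequence to several taxa;
        the assignment then falls to their lowest common label.

    Returns a DataFrame with columns variant_id, taxon, percent_identity
    (always 100.0), library.  Variants without an exact match are absent.
    """
    libraries = _validate_libraries(libraries)
    indexes = [(lib.name, lib.sequence_index()) for lib in libraries]
    rows = []
    for vid in sorted(variants):
        seq = variants[vid].upper()
        for lib_name, idx in indexes:
            taxa = idx.get(seq)
            if taxa:
                label = _resolve_multi(taxa, taxonomy)
                if label is not None:
                    rows.append(
                        {
                            "variant_id": vid,
                            "taxon": label,
                            "percent_identity": 100.0,
                            "library": lib_name,
                        }
                    )
                break
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def _aligner() -> Align.PairwiseAligner:
    # fixed global scheme: match 1, mismatch -1, gap -1
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def global_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Percent identity = matches / alignment columns x 100 under the best
    global alignment (match 1, mismatch -1, gap -1).

    Computed on the lexicographically ordered pair: co-optimal alignments can
    differ in identity count, and fixing the orientation makes the function
    exactly symmetric.
    """
    a, b = a.upper(), b.upper()
    if a == b:
        return 100.0
    if b < a:
        a, b = b, a
    if aligner is None:
        aligner = _aligner()
    alignment = aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return 100.0 * identities / alignment.length


def assign_mammals(
    variants: dict[str, str],
    library: ReferenceLibrary,
    taxonomy: Taxonomy | None = None,
    min_identity: float = 95.0,
    target_taxa: set[str] | None = None,
) -> pd.DataFrame:
    """Identity-threshold assignment of mammal 16S variants.

    The best-identity reference wins; references tied at the best identity are
    resolved to their lowest common label.  Identities below ``min_identity``
    are discarded, as are assignments outside ``target_taxa`` when given (the
    workflow only keeps mammals; bird/fish/invertebrate hits are off-target).
    """
    aligner = _aligner()
    rows = []
    for vid in sorted(variants):
        seq = variants[vid].upper()
        best = -1.0
        best_taxa: set[str] = set()
        for taxon, ref in library.records:
            ident = global_identity(seq, ref, aligner)
            if ident > best + 1e-12:
                best, best_taxa = ident, {taxon}
            elif abs(ident - best) <= 1e-12:
                best_taxa.add(taxon)
        if best < min_identity or not best_taxa:
            continue
        label = _resolve_multi(best_taxa, taxonomy)
        if label is None:
            continue
        if target_taxa is not None and label not in target_taxa:
            continue
        rows.append(
            {
                "variant_id": vid,
                "taxon": label,
                "percent_identity": best,
                "library": library.name,
            }
        )
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def collapse_by_taxon(
    table: ReplicateReadTable, assignments: pd.DataFrame
) -> ReplicateReadTable:
    """Sum counts of all variants sharing a taxon label within each
    (sample, replicate).  Unassigned variants contribute nothing.

    The returned table is keyed by taxon label in place of variant id and
    carries no sequences.
    """
    label = dict(zip(assignments["variant_id"], assignments["taxon"]))
    c = table.counts
    assigned = c[c["variant_id"].isin(label)]
    if assigned.empty:
        return ReplicateReadTable(n_replicates=table.n_replicates)
    collapsed = (
        assigned.assign(variant_id=assigned["variant_id"].map(label))
        .groupby(["sample_id", "replicate", "variant_id"], as_index=False)["reads"]
        .sum()
    )
    return ReplicateReadTable(
        counts=collapsed, sequences={}, n_replicates=table.n_replicates
    )
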