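"""Reading, writing, demultiplexing and dereplication of tagged amplicons.

File formats
------------
* tagged reads / reference libraries: FASTA (via Biopython)
* tag lookup, count tables, metadata, annotations, climate: TSV

A tagged read is ``<8 bp forward tag><amplicon><8 bp reverse tag>``; both tags
must match a lookup row exactly (no mismatch tolerance) for the read to be
assigned to its (sample, PCR replicate).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tables import (
    COUNT_COLUMNS,
    META_COLUMNS,
    ReplicateReadTable,
    ValidationError,
    validate_meta,
)

TAG_LENGTH = 8

LOOKUP_COLUMNS = ["forward_tag", "reverse_tag", "sample_id", "replicate", "marker"]

_BASES = set("ACGT")


def normalize_sequence(seq: str) -> str:
    s = str(seq).strip().upper()
    if not s:
        raise ValidationError("empty sequence")
    bad = set(s) - _BASES
    if bad:
        raise ValidationError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return s


# ---------------------------------------------------------------------------
# tag lookup
# ---------------------------------------------------------------------------


def validate_lookup(lookup: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in LOOKUP_COLUMNS if c not in lookup.columns]
    if missing:
        raise ValidationError(f"tag lookup missing columns: {missing}")
    for col in ("forward_tag", "reverse_tag"):
        tags = lookup[col].astype(str)
        if (tags.str.len() != TAG_LENGTH).any():
            bad = tags[tags.str.len() != TAG_LENGTH].iloc[0]
            raise ValidationError(f"{col} {bad!r} is not {TAG_LENGTH} bp")
    key = ["forward_tag", "reverse_tag", "marker"]
    if lookup.duplicated(subset=key).any():
        row = lookup[lookup.duplicated(subset=key)].iloc[0]
        raise ValidationError(
            "duplicate tag pair in lookup: "
            f"({row.forward_tag}, {row.reverse_tag}) for marker {row.marker}"
        )
    if (lookup["replicate"].astype(int) < 1).any():
        raise ValidationError("replicate indices in lookup must be >= 1")
    return lookup


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------


@dataclass
class DemuxResult:
    """Output of :func:`demultiplex`: the count table plus assignment bookkeeping."""

    table: ReplicateReadTable
    n_assigned: int
    n_unassigned: int

    @property
    def n_input(self) -> int:
        return self.n_assigned + self.n_unassigned


def demultiplex(
    records,
    lookup: pd.DataFrame,
    marker: str | None = None,
    n_replicates: int = 8,
) -> DemuxResult:
    """Assign tagged reads to (sample, replicate) cells and collapse identical
    amplicon sequences within each cell.

    Reads whose tag pair is absent from the lookup are counted as unassigned
    and do not enter the table.  Variant ids are assigned deterministically
    (``<marker>_v<k>`` in lexicographic sequence order).
    """
    lookup = validate_lookup(lookup)
    if marker is not None:
        lookup = lookup[lookup["marker"] == marker]
    tag_map: dict[tuple[str, str], tuple[str, int]] = {
        (row.forward_tag, row.reverse_tag): (row.sample_id, int(row.replicate))
        for row in lookup.itertuples()
    }

    cell_counts: dict[tuple[str, int, str], int] = {}
    n_assigned = 0
    n_unassigned = 0
    for rec in records:
        seq = normalize_sequence(str(rec.seq))
        if len(seq) < 2 * TAG_LENGTH:
            n_unassigned += 1
            continue
        fwd, insert, rev = (
            seq[:TAG_LENGTH],
            seq[TAG_LENGTH:-TAG_LENGTH],
            seq[-TAG_LENGTH:],
        )
        dest = tag_map.get((fwd, rev))
        if dest is None or not insert:
            n_unassigned += 1
            continue
        sample, rep = dest
        key = (sample, rep, insert)
        cell_counts[key] = cell_counts.get(key, 0) + 1
        n_assigned += 1

    prefix = marker if marker is not None else "amplicon"
    unique_seqs = sorted({seq for (_, _, seq) in cell_counts})
    ids = {seq: f"{prefix}_v{i:06d}" for i, seq in enumerate(unique_seqs, start=1)}
    counts = {
        (s, r, ids[seq]): n for (s, r, seq), n in cell_counts.items()
    }
    sequences = {vid: seq for seq, vid in ids.items()}
    table = ReplicateReadTable.from_dict(
        counts, sequences=sequences, n_replicates=n_replicates
    )
    return DemuxResult(table=table, n_assigned=n_assigned, n_unassigned=n_unassigned)


def write_tagged_fasta(
    table: ReplicateReadTable,
    lookup: pd.DataFrame,
    handle,
    marker: str | None = None,
) -> int:
    """Expand a count table back into tagged single reads (inverse of demux).

    Used by the simulator and for round-trip testing.  Returns the number of
    reads written.
    """
    lookup = validate_lookup(lookup)
    if marker is not None:
        lookup = lookup[lookup["marker"] == marker]
    cell_tags = {
        (row.sample_id, int(row.replicate)): (row.forward_tag, row.reverse_tag)
        for row in lookup.itertuples()
    }
    records = []
    i = 0
    for row in table.counts.itertuples():
        try:
            fwd, rev = cell_tags[(row.sample_id, int(row.replicate))]
        except KeyError:
            raise ValidationError(
                f"no tag pair for (sample={row.sample_id!r}, replicate={row.replicate})"
            ) from None
        seq = table.sequences[row.variant_id]
        for _ in range(int(row.reads)):
            i += 1
            records.append(
                SeqRecord(Seq(fwd + seq + rev), id=f"read_{i:08d}", description="")
            )
    SeqIO.write(records, handle, "fasta")
    return i


# ---------------------------------------------------------------------------
# early variant filters
# ---------------------------------------------------------------------------


def remove_short_and_singletons(
    table: ReplicateReadTable, min_length: int = 10
) -> ReplicateReadTable:
    """Drop variants shorter than ``min_length`` bp and dataset-wide singletons.

    A singleton is a variant with exactly one read summed over every sample and
    replicate.  Idempotent: surviving variants keep their counts, so no new
    singletons can be created.
    """
    totals = table.variant_totals()
    drop = set(totals.index[totals == 1])
    for vid in table.counts["variant_id"].unique():
        seq = table.sequences.get(vid)
        if seq is not None and len(seq) < min_length:
            drop.add(vid)
    return table.drop_variants(drop)


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------


def _read_tsv(path_or_handle, columns: list[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(path_or_handle, sep="\t", dtype={"sample_id": str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} TSV missing columns: {missing}")
    return df


def write_table_tsv(table: ReplicateReadTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index=False)


def read_table_tsv(path, sequences: dict[str, str] | None = None,
                   n_replicates: int = 8) -> ReplicateReadTable:
    df = _read_tsv(path, COUNT_COLUMNS, "count table")
    neg = df.index[df["reads"] < 0]
    if len(neg):
        row = df.loc[neg[0]]
        raise ValidationError(
            f"negative read count at line {neg[0] + 2}: "
            f"(sample={row.sample_id!r}, replicate={row.replicate}, "
            f"variant={row.variant_id!r})"
        )
    return ReplicateReadTable(
        counts=df[COUNT_COLUMNS], sequences=dict(sequences or {}),
        n_replicates=n_replicates,
    )


def write_meta_tsv(meta: pd.DataFrame, path) -> None:
    meta[META_COLUMNS].to_csv(path, sep="\t", index=False)


def read_meta_tsv(path) -> pd.DataFrame:
    return validate_meta(_read_tsv(path, META_COLUMNS, "metadata"))


def write_sequences_tsv(sequences: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(sequences.items()), columns=["variant_id", "sequence"]
    ).to_csv(path, sep="\t", index=False)


def read_sequences_tsv(path) -> dict[str, str]:
    df = _read_tsv(path, ["variant_id", "sequence"], "sequences")
    return {
        row.variant_id: normalize_sequence(row.sequence) for row in df.itertuples()
    }


def write_lookup_tsv(lookup: pd.DataFrame, path) -> None:
    lookup[LOOKUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_lookup_tsv(path) -> pd.DataFrame:
    return validate_lookup(_read_tsv(path, LOOKUP_COLUMNS, "tag lookup"))


def write_climate_tsv(climate: pd.DataFrame, path) -> None:
    climate.to_csv(path, sep="\t", index=False)


def read_climate_tsv(path) -> pd.DataFrame:
    return _read_tsv(
        path, ["lake_id", "time_ka", "tjul_C", "pann_mm"], "climate"
    )


def write_annotations_tsv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, sep="\t", index=False)


def read_annotations_tsv(path) -> pd.DataFrame:
    return _read_tsv(
        path,
        ["taxon", "growth_form", "light", "grazing", "elevation_belt"],
        "annotations",
    )


# ---------------------------------------------------------------------------
# reference FASTA
# ---------------------------------------------------------------------------


def _parse_header_fields(description: str) -> dict[str, str]:
    fields = {}
    for token in description.split():
        if "=" in token:
            k, v = token.split("=", 1)
            fields[k] = v.replace("_", " ")
    return fields


def read_reference_fasta(path):
    """Parse a reference FASTA whose headers carry ``taxon=`` and ``library=``
    fields (underscores in values stand for spaces).

    Returns a list of dicts with keys taxon, library, sequence, record_id.
    """
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        fields = _parse_header_fields(rec.description)
        if "taxon" not in fields or "library" not in fields:
            raise ValidationError(
                f"reference record {rec.id!r} lacks taxon=/library= header fields"
            )
        out.append(
            {
                "record_id": rec.id,
                "taxon": fields["taxon"],
                "library": fields["library"],
                "sequence": normalize_sequence(str(rec.seq)),
            }
        )
    return out


def write_reference_fasta(records, handle) -> None:
    """Inverse of :func:`read_reference_fasta`."""
    seq_records = []
    for rec in records:
        desc = (
            f"taxon={rec['taxon'].replace(' ', '_')} "
            f"library={rec['library'].replace(' ', '_')}"
        )
        seq_records.append(
            SeqRecord(Seq(rec["sequence"]), id=rec["record_id"], description=desc)
        )
    SeqIO.write(seq_records, handle, "fasta")


def fasta_from_string(text: str):
    return list(SeqIO.parse(io.StringIO(text), "fasta"))
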