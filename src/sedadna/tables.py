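"""Core in-memory containers for replicate-level metabarcoding count data.

The central object of the pipeline is the :class:`ReplicateReadTable`, a sparse
long-format table of read counts indexed by (sample, PCR replicate, sequence
variant).  Sample metadata travels alongside it as a plain :class:`pandas.DataFrame`
with a fixed column contract (see :data:`META_COLUMNS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Long-format count table columns.
COUNT_COLUMNS = ["sample_id", "replicate", "variant_id", "reads"]

#: Sample metadata columns.  ``depth_cm`` and ``age_ka`` may be NaN for controls.
META_COLUMNS = ["sample_id", "lake_id", "depth_cm", "age_ka", "sample_type", "region"]

#: Negative-control types used for contaminant screening and quality thresholds.
ELIGIBLE_CONTROL_TYPES = frozenset({"C1", "C2", "C3", "C4", "C5", "C6"})

#: Control types produced in the post-PCR lab; excluded from all screening.
EXCLUDED_CONTROL_TYPES = frozenset({"C7", "C8"})

CONTROL_TYPES = ELIGIBLE_CONTROL_TYPES | EXCLUDED_CONTROL_TYPES

VALID_SAMPLE_TYPES = frozenset({"sediment"}) | CONTROL_TYPES

VALID_REGIONS = frozenset({"West", "Central", "East"})


class ValidationError(ValueError):
    """Raised when an input table violates its documented invariants."""


def _empty_counts() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": pd.Series(dtype=object),
            "replicate": pd.Series(dtype=np.int64),
            "variant_id": pd.Series(dtype=object),
            "reads": pd.Series(dtype=np.int64),
        }
    )


@dataclass
class ReplicateReadTable:
    """Sparse read counts per (sample, PCR replicate, sequence variant).

    Parameters
    ----------
    counts
        Long-format DataFrame with columns ``sample_id`` (str), ``replicate``
        (int, 1-based), ``variant_id`` (str) and ``reads`` (positive int).
        Zero-count entries are never stored.
    sequences
        Mapping from variant id to its uppercase nucleotide sequence.  Variants
        collapsed to the taxon level carry no sequences.
    n_replicates
        Number of PCR replicates performed per sample (the study design uses 8).
    """

    counts: pd.DataFrame = field(default_factory=_empty_counts)
    sequences: dict[str, str] = field(default_factory=dict)
    n_replicates: int = 8

    def __post_init__(self) -> None:
        if list(self.counts.columns) != COUNT_COLUMNS:
            self.counts = self.counts.reindex(columns=COUNT_COLUMNS)
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        c = self.counts
        if c["reads"].isna().any():
            raise ValidationError("read counts contain missing values")
        if not np.issubdtype(c["reads"].dtype, np.integer):
            as_int = c["reads"].astype(np.int64)
            if not np.array_equal(as_int.to_numpy(), c["reads"].to_numpy()):
                raise ValidationError("read counts must be integers")
            self.counts = c = c.assign(reads=as_int)
        bad = c.index[c["reads"] < 0]
        if len(bad):
            row = c.loc[bad[0]]
            raise ValidationError(
                f"negative read count at (sample={row.sample_id!r}, "
                f"replicate={row.replicate}, variant={row.variant_id!r})"
            )
        if (c["reads"] == 0).any():
            # zero rows are dropped silently: absence of a row encodes zero
            self.counts = c = c[c["reads"] > 0].reset_index(drop=True)
        if len(c) and (c["replicate"] < 1).any():
            raise ValidationError("replicate indices are 1-based")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if len(c) and int(c["replicate"].max()) > self.n_replicates:
            raise ValidationError(
                f"replicate index {int(c['replicate'].max())} exceeds "
                f"n_replicates={self.n_replicates}"
            )

    # -- derived summaries -------------------------------------------------

    @property
    def variant_ids(self) -> list[str]:
        return sorted(self.counts["variant_id"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.counts["sample_id"].unique())

    @property
    def total_reads(self) -> int:
        return int(self.counts["reads"].sum())

    def variant_totals(self) -> pd.Series:
        """Dataset-wide read total per variant."""
        return self.counts.groupby("variant_id")["reads"].sum()

    def variant_replicate_counts(self) -> pd.Series:
        """Dataset-wide number of positive (sample, replicate) cells per variant."""
        return self.counts.groupby("variant_id").size()

    def replicate_totals(self) -> pd.Series:
        """Total reads per (sample, replicate) cell, positive cells only."""
        return self.counts.groupby(["sample_id", "replicate"])["reads"].sum()

    def sample_totals(self) -> pd.Series:
        return self.counts.groupby("sample_id")["reads"].sum()

    # -- functional updates -------------------------------------------------

    def with_counts(self, counts: pd.DataFrame) -> "ReplicateReadTable":
        keep = set(counts["variant_id"].unique())
        seqs = {v: s for v, s in self.sequences.items() if v in keep}
        return ReplicateReadTable(
            counts=counts.reset_index(drop=True),
            sequences=seqs,
            n_replicates=self.n_replicates,
        )

    def drop_variants(self, variant_ids) -> "ReplicateReadTable":
        drop = set(variant_ids)
        kept = self.counts[~self.counts["variant_id"].isin(drop)]
        return self.with_counts(kept)

    def keep_variants(self, variant_ids) -> "ReplicateReadTable":
        keep = set(variant_ids)
        kept = self.counts[self.counts["variant_id"].isin(keep)]
        return self.with_counts(kept)

    def restrict_samples(self, sample_ids) -> "ReplicateReadTable":
        keep = set(sample_ids)
        kept = self.counts[self.counts["sample_id"].isin(keep)]
        return self.with_counts(kept)

    def copy(self) -> "ReplicateReadTable":
        return replace(
            self, counts=self.counts.copy(), sequences=dict(self.sequences)
        )

    def equals(self, other: "ReplicateReadTable") -> bool:
        key = ["sample_id", "replicate", "variant_id"]
        a = self.counts.sort_values(key).reset_index(drop=True)
        b = other.counts.sort_values(key).reset_index(drop=True)
        return a.equals(b) and self.sequences == other.sequences

    def to_dict(self) -> dict[tuple[str, int, str], int]:
        """Counts as a plain ``{(sample, replicate, variant): reads}`` mapping."""
        c = self.counts
        return dict(
            zip(
                zip(c["sample_id"], c["replicate"].astype(int), c["variant_id"]),
                c["reads"].astype(int),
            )
        )

    @classmethod
    def from_dict(
        cls,
        counts: dict[tuple[str, int, str], int],
        sequences: dict[str, str] | None = None,
        n_replicates: int = 8,
    ) -> "ReplicateReadTable":
        rows = [
            {"sample_id": s, "replicate": r, "variant_id": v, "reads": n}
            for (s, r, v), n in counts.items()
            if n
        ]
        df = pd.DataFrame(rows, columns=COUNT_COLUMNS) if rows else _empty_counts()
        return cls(counts=df, sequences=dict(sequences or {}), n_replicates=n_replicates)


# -- sample metadata helpers ------------------------------------------------


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-metadata contract and return the validated frame."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id in metadata: {dup!r}")
    bad = set(meta["sample_type"]) - VALID_SAMPLE_TYPES
    if bad:
        raise ValidationError(f"unknown sample_type values: {sorted(bad)}")
    sed = meta[meta["sample_type"] == "sediment"]
    if sed["age_ka"].isna().any():
        s = sed.loc[sed["age_ka"].isna(), "sample_id"].iloc[0]
        raise ValidationError(f"sediment sample {s!r} lacks an age")
    if (sed["age_ka"] < 0).any():
        s = sed.loc[sed["age_ka"] < 0, "sample_id"].iloc[0]
        raise ValidationError(f"sediment sample {s!r} has negative age")
    return meta


def sediment_ids(meta: pd.DataFrame) -> list[str]:
    return meta.loc[meta["sample_type"] == "sediment", "sample_id"].tolist()


def eligible_control_ids(meta: pd.DataFrame) -> list[str]:
    """Controls usable for screening/thresholds (post-PCR-lab C7/C8 excluded)."""
    mask = meta["sample_type"].isin(ELIGIBLE_CONTROL_TYPES)
    return meta.loc[mask, "sample_id"].tolist()


def control_ids(meta: pd.DataFrame) -> list[str]:
    mask = meta["sample_type"].isin(CONTROL_TYPES)
    return meta.loc[mask, "sample_id"].tolist()


def negative_control_ids(meta: pd.DataFrame) -> list[str]:
    """All negative controls (C1–C7); C8 is a positive control."""
    mask = meta["sample_type"].isin(CONTROL_TYPES - {"C8"})
    return meta.loc[mask, "sample_id"].tolist()
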