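"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sedadna.tables import META_COLUMNS, ReplicateReadTable

ALPHABET = "ACGT"


def make_table(counts: dict, sequences: dict | None = None, n_replicates: int = 8):
    """Build a ReplicateReadTable from {(sample, replicate, variant): reads}."""
    return ReplicateReadTable.from_dict(
        counts, sequences=sequences or {}, n_replicates=n_replicates
    )


def make_meta(rows: list[dict]) -> pd.DataFrame:
    """Build metadata; unspecified columns get benign defaults."""
    defaults = {
        "lake_id": "L1",
        "depth_cm": np.nan,
        "age_ka": np.nan,
        "sample_type": "sediment",
        "region": "West",
    }
    full = []
    for row in rows:
        rec = dict(defaults, **row)
        if rec["sample_type"] == "sediment" and np.isnan(rec["age_ka"]):
            rec["age_ka"] = 1.0
        full.append(rec)
    return pd.DataFrame(full)[META_COLUMNS]


def random_sequence(rng: np.random.Generator, lo: int = 10, hi: int = 40) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(list(ALPHABET), size=n))


def random_study_table(rng: np.random.Generator):
    """A random small table + metadata for oracle comparison.

    <= 10 samples x 8 replicates x <= 50 variants; includes homopolymer
    near-duplicates, sparse counts spanning the retention boundaries, and a
    mix of sediment samples and control types.
    """
    n_samples = int(rng.integers(2, 11))
    n_variants = int(rng.integers(2, 51))
    n_replicates = 8
    types = ["sediment"] * max(1, n_samples - 3) + list(
        rng.choice(["C1", "C3", "C5", "C6", "C7", "C8", "sediment"], size=3)
    )
    types = types[:n_samples]
    samples = [f"S{i}" for i in range(n_samples)]
    sample_types = dict(zip(samples, types))

    sequences: dict[str, str] = {}
    variants = []
    for i in range(n_variants):
        vid = f"v{i:03d}"
        if variants and rng.random() < 0.3:
            # homopolymer variant of an earlier sequence
            base = sequences[str(rng.choice(variants))]
            j = int(rng.integers(0, len(base)))
            seq = base[: j + 1] + base[j] + base[j + 1 :]
        else:
            seq = random_sequence(rng)
        sequences[vid] = seq
        variants.append(vid)
    # a few variants without sequences (already taxon-collapsed)
    for vid in rng.choice(variants, size=min(3, n_variants), replace=False):
        del sequences[str(vid)]

    counts: dict[tuple[str, int, str], int] = {}
    for s in samples:
        for rep in range(1, n_replicates + 1):
            if rng.random() < 0.2:
                continue  # dropped replicate
            for vid in variants:
                if rng.random() < 0.25:
                    counts[(s, rep, vid)] = int(rng.integers(1, 30))

    meta = make_meta(
        [{"sample_id": s, "sample_type": t} for s, t in sample_types.items()]
    )
    table = make_table(counts, sequences, n_replicates)
    return table, meta, counts, sequences, sample_types


@pytest.fixture(scope="session")
def small_config():
    from sedadna.simulate import StudyConfig

    return StudyConfig(
        n_lakes=4,
        samples_per_lake=10,
        n_plant_taxa=20,
        n_mammal_taxa=8,
        reads_per_replicate_mean=300.0,
        mammal_reads_per_replicate_mean=150.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    from sedadna.simulate import simulate_study

    return simulate_study(small_config)
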