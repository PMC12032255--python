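"""Independent brute-force re-evaluation of the filter cascade.

Deliberately written against plain dicts with explicit loops — no pandas, no
imports from the package under test — so that agreement with the vectorized
implementation is meaningful evidence of correctness.
"""

from __future__ import annotations

Counts = dict[tuple[str, int, str], int]


def rle(seq: str) -> str:
    out = []
    for ch in seq:
        if not out or out[-1] != ch:
            out.append(ch)
    return "".join(out)


def oracle_merge(counts: Counts, sequences: dict[str, str]) -> Counts:
    """Pool variants with equal run-length-compressed sequences into the
    variant with the largest dataset total (tie: lexicographically smaller
    sequence)."""
    totals: dict[str, int] = {}
    for (_, _, v), n in counts.items():
        totals[v] = totals.get(v, 0) + n
    groups: dict[str, list[str]] = {}
    for v in totals:
        if v in sequences:
            key = rle(sequences[v])
        else:
            key = "\x00" + v  # sequence-less variants never merge
        groups.setdefault(key, []).append(v)
    rename: dict[str, str] = {}
    for members in groups.values():
        if len(members) < 2:
            continue
        source = members[0]
        for v in members[1:]:
            better = totals[v] > totals[source] or (
                totals[v] == totals[source]
                and sequences.get(v, "") < sequences.get(source, "")
            )
            if better:
                source = v
        for v in members:
            if v != source:
                rename[v] = source
    out: Counts = {}
    for (s, r, v), n in counts.items():
        key = (s, r, rename.get(v, v))
        out[key] = out.get(key, 0) + n
    return out


def oracle_retention(
    counts: Counts, min_reads: int, min_total: int, min_reps: int
) -> Counts:
    kept = {k: n for k, n in counts.items() if n >= min_reads}
    totals: dict[str, int] = {}
    reps: dict[str, int] = {}
    for (_, _, v), n in kept.items():
        totals[v] = totals.get(v, 0) + n
        reps[v] = reps.get(v, 0) + 1
    good = {v for v in totals if totals[v] >= min_total and reps[v] >= min_reps}
    return {k: n for k, n in kept.items() if k[2] in good}


def oracle_control_screen(
    counts: Counts,
    sample_types: dict[str, str],
    n_replicates: int,
) -> tuple[Counts, list[str]]:
    """Strictly-greater mean per-replicate frequency in C1-C6 controls than in
    sediment samples; means over every performed replicate, zeros included.
    Re-applied until no variant qualifies (fixpoint), since each removal
    changes the remaining variants' denominators."""
    eligible = {"C1", "C2", "C3", "C4", "C5", "C6"}
    controls = [s for s, t in sample_types.items() if t in eligible]
    sediments = [s for s, t in sample_types.items() if t == "sediment"]
    if not controls:
        return dict(counts), []

    ctrl_set, sed_set = set(controls), set(sediments)
    removed_all: list[str] = []
    current = dict(counts)
    while True:
        cell_totals: dict[tuple[str, int], int] = {}
        for (s, r, _), n in current.items():
            cell_totals[(s, r)] = cell_totals.get((s, r), 0) + n

        variants = sorted({v for (_, _, v) in current})
        removed = []
        for v in variants:
            ctrl_sum = 0.0
            sed_sum = 0.0
            for (s, r, w), n in current.items():
                if w != v:
                    continue
                freq = n / cell_totals[(s, r)]
                if s in ctrl_set:
                    ctrl_sum += freq
                elif s in sed_set:
                    sed_sum += freq
            ctrl_mean = ctrl_sum / (len(controls) * n_replicates)
            sed_mean = (
                sed_sum / (len(sediments) * n_replicates) if sediments else 0.0
            )
            if ctrl_mean > sed_mean:
                removed.append(v)
        if not removed:
            break
        removed_all.extend(removed)
        removed_set = set(removed)
        current = {k: n for k, n in current.items() if k[2] not in removed_set}
    return current, sorted(removed_all)


def oracle_known_contaminants(
    counts: Counts, taxon_of: dict[str, str], contaminants: set[str]
) -> Counts:
    bad = {v for v, t in taxon_of.items() if t in contaminants}
    return {k: n for k, n in counts.items() if k[2] not in bad}


def oracle_cascade(
    counts: Counts,
    sequences: dict[str, str],
    sample_types: dict[str, str],
    n_replicates: int,
    min_reads: int = 3,
    min_total: int = 10,
    min_reps: int = 3,
    taxon_of: dict[str, str] | None = None,
    contaminants: set[str] | None = None,
) -> Counts:
    counts = oracle_merge(counts, sequences)
    counts = oracle_retention(counts, min_reads, min_total, min_reps)
    counts, _ = oracle_control_screen(counts, sample_types, n_replicates)
    if taxon_of is not None and contaminants:
        counts = oracle_known_contaminants(counts, taxon_of, contaminants)
    return counts
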