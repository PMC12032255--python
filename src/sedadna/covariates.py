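"""Sample chronologies and climate covariates.

Provides a simple monotone age–depth interpolator (full Bayesian age modelling
is done upstream with dedicated tools), nearest-neighbour matching of
100-yr-step climate series to sample ages, and the within/between-lake
decomposition used by the attribution model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import ValidationError

CLIMATE_COLUMNS = ["lake_id", "time_ka", "tjul_C", "pann_mm"]
CLIMATE_VARS = ["tjul_C", "pann_mm"]


def assign_ages(depths_cm, age_depth_table: pd.DataFrame) -> np.ndarray:
    """Linear interpolation of ages (ka) at the given depths (cm).

    ``age_depth_table`` needs columns ``depth_cm`` and ``age_ka``, strictly
    monotone in depth.  Extrapolation beyond the tabulated range is refused.
    """
    t = age_depth_table.sort_values("depth_cm")
    d = t["depth_cm"].to_numpy(dtype=float)
    a = t["age_ka"].to_numpy(dtype=float)
    if len(d) < 2:
        raise ValidationError("age-depth table needs at least two knots")
    if not (np.all(np.diff(d) > 0)):
        raise ValidationError("age-depth table depths must be strictly increasing")
    if not (np.all(np.diff(a) >= 0)):
        raise ValidationError("age-depth table ages must be monotone in depth")
    depths = np.asarray(depths_cm, dtype=float)
    if depths.ndim == 0:
        depths = depths[None]
    out_of_range = (depths < d[0]) | (depths > d[-1])
    if out_of_range.any():
        bad = depths[out_of_range][0]
        raise ValidationError(
            f"depth {bad} cm outside the age-depth table range "
            f"[{d[0]}, {d[-1]}]; extrapolation is refused"
        )
    return np.interp(depths, d, a)


def match_climate(
    samples: pd.DataFrame, climate: pd.DataFrame
) -> pd.DataFrame:
    """Nearest-neighbour climate values at each sample's age.

    ``samples`` needs columns ``sample_id``, ``lake_id``, ``age_ka``; ``climate``
    follows :data:`CLIMATE_COLUMNS` with one series per lake on a regular grid
    covering the sample ages.  Exact midpoint ties go to the younger (smaller
    ka) grid point.
    """
    out_rows = []
    by_lake = {k: g.sort_values("time_ka") for k, g in climate.groupby("lake_id")}
    for row in samples.itertuples():
        try:
            series = by_lake[row.lake_id]
        except KeyError:
            raise ValidationError(f"no climate series for lake {row.lake_id!r}") from None
        t = series["time_ka"].to_numpy(dtype=float)
        age = float(row.age_ka)
        if age < t[0] - 1e-12 or age > t[-1] + 1e-12:
            raise ValidationError(
                f"sample {row.sample_id!r} age {age} ka outside climate grid "
                f"[{t[0]}, {t[-1]}] for lake {row.lake_id!r}"
            )
        dist = np.abs(t - age)
        # ties resolve to the smaller time (younger); argmin takes the first
        idx = int(np.argmin(dist))
        rec = series.iloc[idx]
        out_rows.append(
            {
                "sample_id": row.sample_id,
                "lake_id": row.lake_id,
                "age_ka": age,
                "matched_time_ka": float(rec["time_ka"]),
                "tjul_C": float(rec["tjul_C"]),
                "pann_mm": float(rec["pann_mm"]),
            }
        )
    return pd.DataFrame(out_rows)


def decompose_within_between(
    values, lake_ids, center: bool = False
) -> pd.DataFrame:
    """Split a per-sample covariate into between-lake and within-lake parts.

    ``lake_mean`` is the unweighted mean over the lake's samples (optionally
    centred on the grand mean of lake means when ``center=True``); ``anomaly``
    is the sample value minus its lake mean.  value == lake_mean_raw + anomaly
    exactly, and anomalies average to 0 within each lake.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "lake_id": lake_ids})
    lake_means = df.groupby("lake_id")["value"].transform("mean")
    anomaly = df["value"] - lake_means
    between = lake_means.copy()
    if center:
        grand = df.groupby("lake_id")["value"].mean().mean()
        between = between - grand
    return pd.DataFrame(
        {
            "value": df["value"],
            "lake_id": df["lake_id"],
            "lake_mean": between,
            "anomaly": anomaly,
        }
    )
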