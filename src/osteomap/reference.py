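"""Published reference measurements from a one-year CBCT growth study of
minipig mandibles (n = 8 subjects, 12 monthly instances, 653-vertex models).

Shipped as plain CSV fixtures: per-landmark position RMSE of the
mesh-propagated landmarks against a manually identified gold standard (mm),
per-pair inter-landmark growth-rate RMSE (%/month), and per-region monthly
growth rates decomposed along the anatomical axes (%/month).  The summary
helpers below recompute the study's headline numbers (ensemble means,
initial-period means, error bounds) from the per-interval values.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

#: vertex counts of the six study regions (condyle, posterior ramus, anterior
#: ramus, posterior corpus, middle corpus, anterior corpus) on the 653-vertex
#: study meshes
STUDY_REGION_VERTEX_COUNTS = {
    "condyle": 171, "posterior_ramus": 49, "anterior_ramus": 42,
    "posterior_corpus": 131, "middle_corpus": 130, "anterior_corpus": 130,
}

INTERVALS = [f"T{i}-T{i + 1}" for i in range(1, 12)]
INSTANCES = [f"T{i}" for i in range(1, 13)]


def _load(name: str) -> pd.DataFrame:
    with resources.files("osteomap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_landmark_position_rmse() -> pd.DataFrame:
    """17 landmarks x 12 instances position RMSE (mm) with printed margins.

    The trailing ``Mean``/``SD`` rows and columns are the study's printed
    summary values; the data block is rows 0..16, columns T1..T12.
    """
    return _load("minipig_landmark_position_rmse.csv")


def load_interlandmark_rate_rmse() -> pd.DataFrame:
    """22 landmark pairs x 11 intervals rate RMSE (%/month) with printed margins."""
    return _load("minipig_interlandmark_rate_rmse.csv")


def load_region_growth_rates() -> pd.DataFrame:
    """Six regions x three directions x 11 intervals mean rates (%/month)."""
    return _load("minipig_region_growth_rates.csv")


# -- summary recomputations -------------------------------------------------

def region_interval_values(region: str, direction: str) -> np.ndarray:
    df = load_region_growth_rates()
    row = df[(df.region == region) & (df.direction == direction)]
    if len(row) != 1:
        raise KeyError(f"no reference row for {region}/{direction}")
    return row[INTERVALS].to_numpy(float).ravel()


def region_ensemble_mean(region: str, direction: str) -> float:
    """Unweighted mean of the 11 per-interval region rates."""
    return float(region_interval_values(region, direction).mean())


def region_ensemble_sd(region: str, direction: str) -> float:
    """Sample SD of the 11 per-interval region rates."""
    return float(region_interval_values(region, direction).std(ddof=1))


def region_initial_period_mean(region: str, direction: str,
                               n_intervals: int = 4) -> float:
    """Mean rate over the initial growth period (the first four intervals)."""
    return float(region_interval_values(region, direction)[:n_intervals].mean())


def landmark_rmse_summary() -> dict:
    """Recomputed instance means of the landmark position RMSE table.

    Returns the per-instance means over the 17 landmarks, their range, and
    the overall maximum entry.
    """
    df = load_landmark_position_rmse()
    data = df[~df.landmark.isin(["Mean", "SD"])][INSTANCES].to_numpy(float)
    col_means = data.mean(axis=0)
    return {
        "instance_means": col_means,
        "min_instance_mean": float(col_means.min()),
        "max_instance_mean": float(col_means.max()),
        "max_rmse": float(data.max()),
        "max_rmse_first8": float(data[:, :8].max()),
        "max_instance_mean_first8": float(col_means[:8].max()),
    }


def rate_rmse_summary() -> dict:
    """Recomputed interval means of the inter-landmark rate RMSE table.

    ``max_interval_mean_first8`` covers the intervals within the first eight
    months (T1-T2 .. T7-T8); ``max_interval_mean_late`` the months-9-12
    intervals (T8-T9 .. T11-T12).
    """
    df = load_interlandmark_rate_rmse()
    data = df[~df.pair.isin(["Mean", "SD"])][INTERVALS].to_numpy(float)
    col_means = data.mean(axis=0)
    return {
        "interval_means": col_means,
        "max_interval_mean_first8": float(col_means[:7].max()),
        "max_interval_mean_late": float(col_means[7:].max()),
    }
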