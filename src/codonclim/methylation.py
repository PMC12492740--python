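"""5mC site filtering, 1-Mb window summaries, and within-species zone tests.

Sites with coverage below 10 or caller modification score below 50 are
removed; the survivors are tiled into non-overlapping windows (1 Mb by
default, from coordinate 0 on each contig) and summarized as the percentage
of methylated sites per window.  Windows without passing sites are undefined
rather than 0% - absence of data is not absence of methylation - and are
excluded from tests.  Within each species sampled in more than one climate
zone, window percentages are compared across samples with a Kruskal-Wallis
test, reporting which zone's median is higher.

All samples of one species must share a coordinate system (the study maps
samples to a single reference assembly); this module assumes rather than
performs that alignment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .data_io import ZONE_COLDNESS

DEFAULT_WINDOW_SIZE = 1_000_000
DEFAULT_MIN_COVERAGE = 10
DEFAULT_MIN_SCORE = 50.0


def filter_sites(
    sites: pd.DataFrame,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    min_score: float = DEFAULT_MIN_SCORE,
) -> pd.DataFrame:
    """Keep sites with coverage >= min_coverage and mod_score >= min_score.

    Boundary inclusive: the filter removes sites with coverage *less than*
    10 or score *less than* 50, so a (10, 50) site survives.
    """
    keep = (sites["coverage"] >= min_coverage) & (sites["mod_score"] >= min_score)
    return sites[keep].copy()


def window_methylation(
    sites: pd.DataFrame,
    window_size: int = DEFAULT_WINDOW_SIZE,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Percent methylated sites per non-overlapping window of one sample.

    Windows tile each contig from coordinate 0 in steps of ``window_size``;
    position ``window_size`` itself belongs to the second window (0-based
    half-open convention).  Only windows containing at least one passing site
    are emitted, so the sum of ``n_sites`` equals the number of input sites.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    df = sites.copy()
    if len(df) == 0:
        out = pd.DataFrame(
            columns=["contig", "window_start", "n_sites", "n_methylated", "pct_methylated"]
        )
    else:
        df["window_start"] = (df["start"] // window_size) * window_size
        grouped = (
            df.groupby(["contig", "window_start"], sort=True)
            .agg(n_sites=("methylated", "size"), n_methylated=("methylated", "sum"))
            .reset_index()
        )
        grouped["pct_methylated"] = 100.0 * grouped["n_methylated"] / grouped["n_sites"]
        out = grouped
    if sample_id is not None:
        out.insert(0, "sample_id", sample_id)
    return out


def compare_within_species(
    windows: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis on window methylation percentages, per species.

    ``windows`` holds window records of all samples (columns sample_id,
    contig, window_start, n_sites, n_methylated, pct_methylated);
    ``metadata`` maps sample_id to species and climate_zone.  Species with
    samples from fewer than two zones are skipped with a warning.  Each
    result row reports the zone with the higher median window percentage and
    whether that zone is the colder one.
    """
    meta = metadata.set_index("sample_id")
    unknown = sorted(set(windows["sample_id"]) - set(meta.index))
    if unknown:
        raise ValueError(f"window records with sample ids missing from metadata: {unknown}")
    df = windows.merge(
        meta[["species", "climate_zone"]], left_on="sample_id", right_index=True
    )
    rows = []
    for species, sub in df.groupby("species", sort=True):
        zones = sub.groupby("climate_zone")["pct_methylated"]
        if len(zones) < 2:
            warnings.warn(f"species {species!r} sampled in a single climate zone; skipped")
            continue
        groups = {z: v.to_numpy() for z, v in zones}
        stat, p = _stats.kruskal(*groups.values())
        medians = {z: float(np.median(v)) for z, v in groups.items()}
        higher = max(medians, key=medians.get)
        coldest = max(groups, key=lambda z: ZONE_COLDNESS[z])
        rows.append(
            {
                "species": species,
                "zones": "|".join(sorted(groups)),
                "n_windows": int(sum(len(v) for v in groups.values())),
                "statistic": float(stat),
                "p": float(p),
                "significant": bool(p < alpha),
                "higher_zone": higher,
                "colder_zone_higher": bool(higher == coldest),
            }
        )
    return pd.DataFrame(rows)
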