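"""Group comparisons between climate zones, and their dN/dS application.

The generic machinery is normality-gated: Shapiro-Wilk on each group decides
between one-way ANOVA with Tukey HSD post-hoc tests and Kruskal-Wallis with
pairwise Mann-Whitney rank-sum tests (BH-adjusted).  The dN/dS application
discards ratios above 10, stratifies genes into positive ([1, 10)) and
negative ((0, 1)) selection classes, and compares zones within each gene
group (CAFE families vs other genes) as well as the two gene groups within
each zone.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

#: dN/dS strata, half-open exactly as printed: positive selection [1, 10),
#: negative (purifying) selection (0, 1).
DNDS_STRATA = {
    "positive": (1.0, 10.0),
    "negative": (0.0, 1.0),
}


@dataclass
class ZoneComparisonResult:
    variable: str
    groups: Mapping[str, int]  # group label -> size
    omnibus_test: str  # 'anova' | 'kruskal_wallis'
    statistic: float
    p: float
    posthoc: list[tuple[str, float, float]] = field(default_factory=list)
    # posthoc rows: ("groupA|groupB", statistic, p_adjusted)


def compare_groups(
    values: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    variable: str = "value",
) -> ZoneComparisonResult:
    """Omnibus + post-hoc comparison of two or more numeric groups.

    If every group passes Shapiro-Wilk normality at 0.05, a one-way ANOVA is
    used with Tukey HSD post-hoc pairs; otherwise Kruskal-Wallis with
    pairwise Mann-Whitney tests, BH-adjusted.  Post-hoc tests run only when
    the omnibus p-value is below ``alpha``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in groups.items():
        if len(arr) < 3:
            raise ValueError(f"group {name!r} has fewer than 3 observations")
    labels = list(groups)
    arrays = [groups[k] for k in labels]

    normal = True
    for arr in arrays:
        if np.ptp(arr) == 0:
            normal = False  # degenerate group: fall through to rank tests
            break
        if _stats.shapiro(arr).pvalue < 0.05:
            normal = False
            break

    posthoc: list[tuple[str, float, float]] = []
    if normal:
        stat, p = _stats.f_oneway(*arrays)
        test = "anova"
        if p < alpha:
            tk = _stats.tukey_hsd(*arrays)
            for i, j in itertools.combinations(range(len(labels)), 2):
                posthoc.append(
                    (
                        f"{labels[i]}|{labels[j]}",
                        float(tk.statistic[i, j]),
                        float(tk.pvalue[i, j]),
                    )
                )
    else:
        stat, p = _stats.kruskal(*arrays)
        test = "kruskal_wallis"
        if p < alpha:
            raw = []
            for i, j in itertools.combinations(range(len(labels)), 2):
                mw = _stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
                raw.append((f"{labels[i]}|{labels[j]}", float(mw.statistic), float(mw.pvalue)))
            adj = multipletests([r[2] for r in raw], method="fdr_bh")[1]
            posthoc = [(pair, s, float(pa)) for (pair, s, _), pa in zip(raw, adj)]

    return ZoneComparisonResult(
        variable=variable,
        groups={k: len(v) for k, v in groups.items()},
        omnibus_test=test,
        statistic=float(stat),
        p=float(p),
        posthoc=posthoc,
    )


def filter_dnds(records: pd.DataFrame, max_dnds: float = 10.0) -> pd.DataFrame:
    """Discard records with dN/dS strictly above ``max_dnds`` (idempotent)."""
    return records[records["dnds"] <= max_dnds].copy()


def stratify_dnds(records: pd.DataFrame, stratum: str | None) -> pd.DataFrame:
    """Subset records to a selection stratum: 'positive' [1, 10), 'negative' (0, 1)."""
    if stratum is None:
        return records
    if stratum not in DNDS_STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {list(DNDS_STRATA)}")
    lo, hi = DNDS_STRATA[stratum]
    if stratum == "positive":
        keep = (records["dnds"] >= lo) & (records["dnds"] < hi)
    else:
        keep = (records["dnds"] > lo) & (records["dnds"] < hi)
    return records[keep].copy()


def compare_dnds(
    records: pd.DataFrame,
    max_dnds: float = 10.0,
    stratum: str | None = None,
    paired: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Zone-wise and gene-group-wise rank tests on per-gene dN/dS records.

    ``records`` needs columns gene_id, climate_zone, gene_group, dnds.
    Ratios above ``max_dnds`` are discarded first, then the optional
    selection ``stratum`` applied.  Within each gene group every zone pair is
    compared, and within each zone the two gene groups are compared, all with
    Mann-Whitney rank-sum tests (or Wilcoxon signed-rank when ``paired``,
    which requires equal-size matched vectors).  p-values are BH-adjusted
    across the whole comparison set.
    """
    df = stratify_dnds(filter_dnds(records, max_dnds), stratum)
    if df["climate_zone"].nunique() < 2:
        raise ValueError("records must span at least 2 climate zones after filtering")

    rows = []

    def rank_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        if paired:
            if len(a) != len(b):
                raise ValueError("paired mode requires matched, equal-size vectors")
            res = _stats.wilcoxon(a, b)
        else:
            res = _stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)

    for group, sub in df.groupby("gene_group"):
        zones = sorted(sub["climate_zone"].unique())
        for za, zb in itertools.combinations(zones, 2):
            a = sub.loc[sub["climate_zone"] == za, "dnds"].to_numpy()
            b = sub.loc[sub["climate_zone"] == zb, "dnds"].to_numpy()
            if len(a) == 0 or len(b) == 0:
                warnings.warn(f"no surviving records for {za} vs {zb} in {group}; skipped")
                continue
            stat, p = rank_test(a, b)
            rows.append(
                {
                    "comparison": "zone_pair",
                    "gene_group": group,
                    "group_a": za,
                    "group_b": zb,
                    "n_a": len(a),
                    "n_b": len(b),
                    "median_a": float(np.median(a)),
                    "median_b": float(np.median(b)),
                    "statistic": stat,
                    "p": p,
                }
            )
    for zone, sub in df.groupby("climate_zone"):
        groups = sorted(sub["gene_group"].unique())
        if len(groups) < 2:
            continue
        a = sub.loc[sub["gene_group"] == groups[0], "dnds"].to_numpy()
        b = sub.loc[sub["gene_group"] == groups[1], "dnds"].to_numpy()
        stat, p = rank_test(a, b)
        rows.append(
            {
                "comparison": "gene_group_within_zone",
                "gene_group": zone,
                "group_a": groups[0],
                "group_b": groups[1],
                "n_a": len(a),
                "n_b": len(b),
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "statistic": stat,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adjusted"] < alpha
    return out
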