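"""Amino-acid enrichment/depletion between two sequence sets.

Given pooled amino-acid counts of a query set and a background set (typically
two samples of the same species from different climate zones), each residue's
relative enrichment is fold = (Cq - Cb) / Cb where Cq and Cb are the residue's
fractional compositions.  Significance follows the bootstrap z-test scheme of
composition-profiling tools: both sets are resampled with replacement (at
their own totals) from the pooled composition, the fold recomputed per
replicate, and the observed fold standardized against the bootstrap null's
centre and spread; the two-sided p-value is normal-theory on that z-value.
p-values are Benjamini-Hochberg adjusted across the 20 residues.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm
from statsmodels.stats.multitest import multipletests

from .codon_stats import AMINO_ACIDS


def _as_vector(counts) -> np.ndarray:
    if isinstance(counts, Mapping):
        return np.array([float(counts.get(a, 0)) for a in AMINO_ACIDS])
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (20,):
        raise ValueError("amino-acid counts must map the 20 residues or be a 20-vector")
    return arr


def aa_enrichment(
    query: Mapping[str, float] | Sequence[float],
    background: Mapping[str, float] | Sequence[float],
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test each amino acid for enrichment/depletion of query vs background.

    Returns one row per amino acid: fraction_query, fraction_background,
    fold, p_value, p_adjusted, direction in {enriched, depleted, none}.
    Residues absent from the background have an undefined fold and are
    flagged with direction 'undefined'.  Deterministic given ``seed``.
    """
    q = _as_vector(query)
    b = _as_vector(background)
    if q.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both residue sets must have a positive total")
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000")
    nq, nb = q.sum(), b.sum()
    fq, fb = q / nq, b / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(fb > 0, (fq - fb) / fb, np.nan)

    rng = np.random.default_rng(seed)
    pooled = (q + b) / (nq + nb)
    bq = rng.multinomial(int(round(nq)), pooled, size=n_boot) / nq
    bb = rng.multinomial(int(round(nb)), pooled, size=n_boot) / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        fold_star = np.where(bb > 0, (bq - bb) / bb, np.nan)

    p = np.full(20, np.nan)
    with np.errstate(invalid="ignore"):
        centre = np.nanmean(fold_star, axis=0)
        spread = np.nanstd(fold_star, axis=0, ddof=1)
    for i in range(20):
        if np.isnan(fold[i]) or np.isnan(spread[i]) or spread[i] == 0:
            continue
        z = (fold[i] - centre[i]) / spread[i]
        p[i] = float(2.0 * _norm.sf(abs(z)))

    p_adj = np.full(20, np.nan)
    defined = ~np.isnan(p)
    if defined.any():
        p_adj[defined] = multipletests(p[defined], method="fdr_bh")[1]

    direction = np.where(
        np.isnan(fold),
        "undefined",
        np.where(
            (p_adj < alpha) & (fold > 0),
            "enriched",
            np.where((p_adj < alpha) & (fold < 0), "depleted", "none"),
        ),
    )
    return pd.DataFrame(
        {
            "amino_acid": list(AMINO_ACIDS),
            "fraction_query": fq,
            "fraction_background": fb,
            "fold": fold,
            "p_value": p,
            "p_adjusted": p_adj,
            "direction": direction,
        }
    )
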