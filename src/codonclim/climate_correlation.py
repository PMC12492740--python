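"""PCA of temperature bioclim variables and the feature-vs-PC correlation screen.

The 11 WorldClim temperature variables (BIO1-BIO11) are strongly
inter-correlated, so they are first grouped by a PCA on the correlation
matrix.  Components explaining at least 5% of variance are retained, and
variables contributing more than 10% to a retained component are its
"important" variables.  Genomic features (GC12, GC3, ENC, amino-acid usage,
codon usage, optional scalar columns) are then screened against the retained
PC scores with Pearson correlation; p-values are Benjamini-Hochberg adjusted
within the amino-acid family and within the codon family separately, while
scalar features keep their raw p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests

FEATURE_FAMILIES = ("scalar", "amino_acid", "codon")


@dataclass
class PCAResult:
    """PCA of standardized variables (eigen-decomposition of the correlation matrix).

    ``loadings`` are variable-PC correlations (eigenvector * sqrt(eigenvalue));
    ``rotation`` holds the raw unit eigenvectors; ``contributions`` are
    100 * squared eigenvector entries, summing to 100 per PC.  Each PC is
    oriented so its largest-magnitude loading is positive.
    """

    variance_explained: pd.Series  # fraction per PC
    loadings: pd.DataFrame  # variable x PC
    rotation: pd.DataFrame  # variable x PC (unit eigenvectors)
    scores: pd.DataFrame  # sample x PC
    contributions: pd.DataFrame  # variable x PC, percent


def pca_bioclim(table: pd.DataFrame) -> PCAResult:
    """PCA of a samples x variables table (e.g. the BIO1-BIO11 bioclim table).

    ``table`` must be indexed by sample id with one numeric column per
    variable; a ``sample_id`` column is accepted and used as the index.
    """
    df = table.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    if df.isna().any().any():
        raise ValueError("bioclim table contains missing values")
    if len(df) < 3:
        raise ValueError("PCA needs at least 3 samples")
    sd = df.std(ddof=1)
    constant = sd.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant variable(s) cannot be standardized: {constant}")
    Z = (df - df.mean()) / sd
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # orient each PC so its largest-|loading| variable loads positively
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] *= -1
    pcs = [f"PC{i + 1}" for i in range(len(eigval))]
    rotation = pd.DataFrame(eigvec, index=df.columns, columns=pcs)
    loadings = rotation * np.sqrt(eigval)
    scores = pd.DataFrame(Z.to_numpy() @ eigvec, index=df.index, columns=pcs)
    contributions = rotation**2 * 100.0
    return PCAResult(
        variance_explained=pd.Series(eigval / eigval.sum(), index=pcs),
        loadings=loadings,
        rotation=rotation,
        scores=scores,
        contributions=contributions,
    )


def retain_pcs(pca: PCAResult, min_var: float = 0.05) -> list[str]:
    """PCs explaining at least ``min_var`` of total variance (boundary inclusive)."""
    kept = [pc for pc, v in pca.variance_explained.items() if v >= min_var]
    return kept


def important_variables(pca: PCAResult, pc: str, min_contrib: float = 10.0) -> list[str]:
    """Variables contributing strictly more than ``min_contrib`` percent to ``pc``."""
    if pc not in pca.contributions.columns:
        raise KeyError(f"unknown principal component {pc!r}")
    col = pca.contributions[pc]
    return col.index[col > min_contrib].tolist()


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation via the t transformation.

    t = r * sqrt(n - 2) / sqrt(1 - r^2) with n - 2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * _stats.t.sf(abs(t), df=n - 2))


def pearson_test(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate (constant) input vector")
    r = float(np.corrcoef(x, y)[0, 1])
    return PearsonResult(r=r, p=pearson_pvalue(r, len(x)), n=len(x))


def correlation_screen(
    features: pd.DataFrame,
    families: Mapping[str, str],
    scores: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "pearson",
    per_pc_adjust: bool = False,
    pool_scalars: bool = False,
) -> pd.DataFrame:
    """Screen every feature against every retained PC score.

    ``features``: samples x features (indexed by sample id, or with a
    ``sample_id`` column); ``families`` maps each feature column to
    'scalar' | 'amino_acid' | 'codon'; ``scores``: samples x retained PCs.

    BH adjustment is applied within the amino-acid and codon families
    separately (across all retained PCs by default; per PC when
    ``per_pc_adjust``).  Scalar features keep raw p-values unless
    ``pool_scalars`` groups them into a third adjusted family.  A record is
    significant when its relevant (adjusted or raw) p-value is below
    ``alpha``.  Output is sorted by raw p.
    """
    feats = features.copy()
    if "sample_id" in feats.columns:
        feats = feats.set_index("sample_id")
    unknown = [c for c in feats.columns if c not in families]
    if unknown:
        raise ValueError(f"feature(s) without a family assignment: {unknown[:5]}")
    bad_family = {f: fam for f, fam in families.items() if fam not in FEATURE_FAMILIES}
    if bad_family:
        raise ValueError(f"unknown feature family: {bad_family}")
    missing = sorted(set(feats.index).symmetric_difference(scores.index))
    if missing:
        raise ValueError(f"sample ids differ between features and scores: {missing}")
    feats = feats.loc[scores.index]

    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    X = feats.to_numpy(dtype=float)
    S = scores.to_numpy(dtype=float)
    if method == "spearman":
        X = _stats.rankdata(X, axis=0)
        S = _stats.rankdata(S, axis=0)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Sc = S - S.mean(axis=0)
    xs = np.sqrt((Xc**2).sum(axis=0))
    ss = np.sqrt((Sc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = (Xc.T @ Sc) / np.outer(xs, ss)  # features x PCs
    R = np.clip(R, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt(n - 2) / np.sqrt(1.0 - R**2)
    P = 2.0 * _stats.t.sf(np.abs(t), df=n - 2)
    P = np.where(np.abs(R) >= 1.0, 0.0, P)

    rows = []
    for i, feat in enumerate(feats.columns):
        for j, pc in enumerate(scores.columns):
            rows.append(
                {
                    "feature_name": feat,
                    "feature_family": families[feat],
                    "pc": pc,
                    "r": R[i, j],
                    "p": P[i, j],
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = out["p"]
    adjusted_families = ["amino_acid", "codon"] + (["scalar"] if pool_scalars else [])
    group_cols = ["feature_family"] + (["pc"] if per_pc_adjust else [])
    for _, idx in out.groupby(group_cols).groups.items():
        sub = out.loc[idx]
        fam = sub["feature_family"].iloc[0]
        if fam in adjusted_families:
            ok = sub["p"].notna()
            if ok.any():
                out.loc[sub.index[ok], "p_adjusted"] = multipletests(
                    sub.loc[ok, "p"], method="fdr_bh"
                )[1]
    out["significant"] = out["p_adjusted"] < alpha
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)
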