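"""Per-gene and per-sample codon-level statistics.

This module carries the study's core codon machinery: codon counting in frame
0, GC content by codon position (GC1/GC2/GC3 and their mean GC12), relative
synonymous codon usage (RSCU), Wright's effective number of codons (ENC) with
its expected-value curve under pure GC3 drift, amino-acid usage, the strong
codon-bias filter (ENC <= 35), the GC12-on-GC3 neutrality regression, and
correspondence analysis of RSCU tables.

All statistics use the standard genetic code (translation table 1); stop
codons are counted but excluded from every downstream statistic, following the
convention of classic codon-usage software.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats as _stats

BASES = "ACGT"
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
CODON_INDEX: Mapping[str, int] = {c: i for i, c in enumerate(CODONS)}

#: Alphabetical one-letter codes of the 20 proteinogenic amino acids.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))
AA_INDEX: Mapping[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: codon-to-amino-acid map plus synonymous family structure.

    ``families`` partitions the sense codons into synonymous families keyed by
    amino acid; degeneracy is the family size (1, 2, 3, 4 or 6 under the
    standard code).
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]
    families: Mapping[str, tuple[str, ...]]

    @classmethod
    def from_table_id(cls, table_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa = {c: table.forward_table[c] for c in CODONS if c in table.forward_table}
        families: dict[str, list[str]] = {}
        for codon, aa in codon_to_aa.items():
            families.setdefault(aa, []).append(codon)
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            stop_codons=frozenset(table.stop_codons),
            families={aa: tuple(sorted(cs)) for aa, cs in sorted(families.items())},
        )

    def degeneracy(self, aa: str) -> int:
        return len(self.families[aa])


STANDARD_CODE = GeneticCode.from_table_id(1)

# --- precomputed index structures for the standard code -------------------
_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _BASE_LUT[ord(_b)] = _i

_SENSE_MASK = np.array([c not in STANDARD_CODE.stop_codons for c in CODONS])
_STOP_MASK = ~_SENSE_MASK
_GC_AT_POS = np.array([[b in "GC" for b in codon] for codon in CODONS])  # (64, 3)

#: codon index arrays per synonymous family, keyed by amino acid
_FAMILY_IDX: Mapping[str, np.ndarray] = {
    aa: np.array([CODON_INDEX[c] for c in codons])
    for aa, codons in STANDARD_CODE.families.items()
}
#: amino acids grouped by family degeneracy; class weights of Wright's formula
_DEGENERACY_CLASSES: Mapping[int, tuple[str, ...]] = {
    k: tuple(aa for aa in AMINO_ACIDS if STANDARD_CODE.degeneracy(aa) == k)
    for k in (1, 2, 3, 4, 6)
}


# ---------------------------------------------------------------------------
# Codon counting

class CodonCounts(NamedTuple):
    counts: np.ndarray  # length 64, stop codons included
    n_skipped: int  # ambiguous triplets + a trailing partial triplet


def count_codons(sequence: str, code: GeneticCode = STANDARD_CODE) -> CodonCounts:
    """Count codons of ``sequence`` read in frame 0 as non-overlapping triplets.

    Triplets containing characters outside {A, C, G, T} are skipped, as is a
    trailing partial triplet; both are tallied in ``n_skipped``.  Stop codons
    are counted in the 64-vector but every downstream statistic ignores them.
    """
    seq = sequence.upper().replace("U", "T")
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    n_triplets = len(arr) // 3
    trailing = len(arr) - 3 * n_triplets
    counts = np.zeros(64, dtype=np.int64)
    skipped = 1 if trailing else 0
    if n_triplets:
        trip = _BASE_LUT[arr[: 3 * n_triplets]].reshape(n_triplets, 3)
        valid = (trip >= 0).all(axis=1)
        idx = trip[valid, 0] * 16 + trip[valid, 1] * 4 + trip[valid, 2]
        counts = np.bincount(idx, minlength=64).astype(np.int64)
        skipped += int((~valid).sum())
    return CodonCounts(counts, skipped)


def n_sense_codons(counts: np.ndarray) -> int:
    return int(counts[_SENSE_MASK].sum())


# ---------------------------------------------------------------------------
# GC content by codon position

class GCByPosition(NamedTuple):
    gc1: float
    gc2: float
    gc3: float
    gc12: float


def gc_by_position(counts: np.ndarray) -> GCByPosition:
    """GC fraction at each codon position over counted sense codons.

    GC12 is defined as the mean of GC1 and GC2.  Undefined (NaN) when no
    sense codon was counted.
    """
    sense = counts * _SENSE_MASK
    total = sense.sum()
    if total == 0:
        return GCByPosition(math.nan, math.nan, math.nan, math.nan)
    gc = (sense @ _GC_AT_POS) / total
    return GCByPosition(float(gc[0]), float(gc[1]), float(gc[2]), float((gc[0] + gc[1]) / 2))


# ---------------------------------------------------------------------------
# RSCU

def rscu(counts: np.ndarray, code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Relative synonymous codon usage per codon (length-64 vector).

    RSCU(c) = count(c) * degeneracy / family total.  Families with zero total
    are undefined (NaN), not zero: absence of data is not absence of usage.
    Single-codon families (Met, Trp) are 1 when observed, NaN when absent.
    Stop codons are always NaN.
    """
    out = np.full(64, np.nan)
    for aa, idx in _FAMILY_IDX.items():
        fam = counts[idx]
        n_fam = fam.sum()
        if n_fam > 0:
            out[idx] = fam * len(idx) / n_fam
    return out


# ---------------------------------------------------------------------------
# ENC (Wright's effective number of codons)

def family_homozygosity(family_counts: Sequence[int] | np.ndarray) -> float:
    """Wright's codon homozygosity F-hat for one synonymous family.

    With n codons observed and p_i the within-family frequencies:
    F = (n * sum(p_i^2) - 1) / (n - 1).  Undefined (NaN) for n < 2.  A
    non-positive estimate (possible at tiny n) is clamped to 1/degeneracy,
    the uniform-usage floor, to keep ENC finite.
    """
    fam = np.asarray(family_counts, dtype=float)
    n = fam.sum()
    if n < 2:
        return math.nan
    p = fam / n
    f = (n * float(p @ p) - 1.0) / (n - 1.0)
    if f <= 0:
        return 1.0 / len(fam)
    return f


def enc(counts: np.ndarray, code: GeneticCode = STANDARD_CODE) -> float:
    """Effective number of codons of one gene, by Wright's class formula.

    ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 where Fk is the mean homozygosity of
    the degeneracy-k families with defined F-hat.  When the single
    degeneracy-3 family (Ile) is undefined, 1/F3 is interpolated from the
    mean of F2 and F4 (Wright's rule); if any other class has no defined
    family the statistic is undefined (NaN).  Values are clamped to [20, 61].
    """
    class_means: dict[int, float] = {}
    for k, aas in _DEGENERACY_CLASSES.items():
        if k == 1:
            continue
        fs = [family_homozygosity(counts[_FAMILY_IDX[aa]]) for aa in aas]
        fs = [f for f in fs if not math.isnan(f)]
        class_means[k] = float(np.mean(fs)) if fs else math.nan
    f2, f3, f4, f6 = class_means[2], class_means[3], class_means[4], class_means[6]
    if math.isnan(f2) or math.isnan(f4) or math.isnan(f6):
        return math.nan
    if math.isnan(f3):
        f3 = (f2 + f4) / 2.0
    value = 2.0 + 9.0 / f2 + 1.0 / f3 + 5.0 / f4 + 3.0 / f6
    return float(min(61.0, max(20.0, value)))


def expected_enc(gc3: float) -> float:
    """Expected ENC under pure GC3 compositional drift (no selection):

    ENC = 2 + GC3 + 29 / (GC3^2 + (1 - GC3)^2)

    Symmetric about GC3 = 0.5 where it peaks at 60.5.
    """
    if not 0.0 <= gc3 <= 1.0:
        raise ValueError(f"GC3 must lie in [0, 1], got {gc3}")
    return 2.0 + gc3 + 29.0 / (gc3**2 + (1.0 - gc3) ** 2)


# ---------------------------------------------------------------------------
# Amino-acid usage

def amino_acid_fractions(counts: np.ndarray, code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Fraction of each amino acid (alphabetical order) among sense codons."""
    total = n_sense_codons(counts)
    if total == 0:
        return np.full(20, np.nan)
    out = np.empty(20)
    for aa, idx in _FAMILY_IDX.items():
        out[AA_INDEX[aa]] = counts[idx].sum() / total
    return out


def amino_acid_counts(counts: np.ndarray, code: GeneticCode = STANDARD_CODE) -> pd.Series:
    """Absolute amino-acid counts (alphabetical order) from a codon count vector."""
    return pd.Series(
        {aa: int(counts[idx].sum()) for aa, idx in _FAMILY_IDX.items()}
    ).reindex(list(AMINO_ACIDS))


# ---------------------------------------------------------------------------
# Per-gene statistics

@dataclass
class GeneCodonStats:
    gene_id: str
    n_codons: int  # sense codons counted
    n_stop: int
    n_skipped: int
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    enc: float
    aa_fractions: np.ndarray = field(repr=False)


def gene_stats(gene_id: str, sequence: str, code: GeneticCode = STANDARD_CODE
               ) -> tuple[GeneCodonStats, np.ndarray]:
    """Compute all per-gene codon statistics; returns (stats, 64-codon counts)."""
    counts, skipped = count_codons(sequence, code)
    gc = gc_by_position(counts)
    stats = GeneCodonStats(
        gene_id=gene_id,
        n_codons=n_sense_codons(counts),
        n_stop=int(counts[_STOP_MASK].sum()),
        n_skipped=skipped,
        gc1=gc.gc1,
        gc2=gc.gc2,
        gc3=gc.gc3,
        gc12=gc.gc12,
        enc=enc(counts, code),
        aa_fractions=amino_acid_fractions(counts, code),
    )
    return stats, counts


def per_gene_table(records: Mapping[str, str], code: GeneticCode = STANDARD_CODE
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene statistics for a whole CDS set.

    Returns ``(stats, counts)``: ``stats`` has one row per gene with columns
    gene_id, n_codons, n_stop, n_skipped, gc1, gc2, gc3, gc12, enc and one
    ``aa_<X>`` fraction column per amino acid; ``counts`` is the gene x 64
    codon count matrix.
    """
    rows = []
    count_rows = []
    for gene_id, seq in records.items():
        st, counts = gene_stats(gene_id, seq, code)
        row = {
            "gene_id": st.gene_id,
            "n_codons": st.n_codons,
            "n_stop": st.n_stop,
            "n_skipped": st.n_skipped,
            "gc1": st.gc1,
            "gc2": st.gc2,
            "gc3": st.gc3,
            "gc12": st.gc12,
            "enc": st.enc,
        }
        for aa, frac in zip(AMINO_ACIDS, st.aa_fractions):
            row[f"aa_{aa}"] = frac
        rows.append(row)
        count_rows.append(counts)
    stats = pd.DataFrame(rows)
    counts_df = pd.DataFrame(
        np.array(count_rows, dtype=np.int64) if count_rows else np.empty((0, 64), dtype=np.int64),
        index=list(records.keys()),
        columns=list(CODONS),
    )
    return stats, counts_df


def strong_bias_genes(stats: pd.DataFrame, threshold: float = 35.0) -> list[str]:
    """Gene ids with defined ENC <= threshold (strong codon-usage bias)."""
    ok = stats["enc"].notna() & (stats["enc"] <= threshold)
    return stats.loc[ok, "gene_id"].tolist()


# ---------------------------------------------------------------------------
# Sample-level aggregation

@dataclass
class SampleFeatures:
    """Per-sample, per-gene-set averaged genomic features.

    GC12/GC3/ENC are unweighted means over genes with defined values; amino
    acid and codon usage are percentage abundances from counts pooled across
    the gene set (pooling is what makes percentages sum to exactly 100);
    RSCU likewise comes from pooled counts.
    """

    sample_id: str
    gene_set: str
    n_genes: int
    mean_gc12: float
    mean_gc3: float
    mean_enc: float
    aa_usage: pd.Series  # % per amino acid, sums to 100
    codon_usage: pd.Series  # % per sense codon
    rscu: pd.Series  # per-codon RSCU from pooled counts (NaN where undefined)

    def to_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "gene_set": self.gene_set,
            "n_genes": self.n_genes,
            "mean_gc12": self.mean_gc12,
            "mean_gc3": self.mean_gc3,
            "mean_enc": self.mean_enc,
        }
        row.update({f"aa_{a}": v for a, v in self.aa_usage.items()})
        row.update({f"codon_{c}": v for c, v in self.codon_usage.items()})
        return row


def aggregate_sample_features(
    sample_id: str,
    gene_set: str,
    stats: pd.DataFrame,
    counts: pd.DataFrame,
    gene_ids: Iterable[str] | None = None,
    include_single_codon_families: bool = True,
    code: GeneticCode = STANDARD_CODE,
) -> SampleFeatures:
    """Aggregate per-gene statistics into one sample-level feature vector."""
    if gene_ids is not None:
        gene_ids = [g for g in gene_ids if g in counts.index]
        stats = stats[stats["gene_id"].isin(gene_ids)]
        counts = counts.loc[gene_ids]
    if len(stats) == 0:
        raise ValueError(f"sample {sample_id}: gene set {gene_set!r} is empty")
    pooled = counts.to_numpy().sum(axis=0)
    if n_sense_codons(pooled) == 0:
        raise ValueError(f"sample {sample_id}: gene set {gene_set!r} has no sense codons")

    aa_frac = amino_acid_fractions(pooled, code)
    aa_usage = pd.Series(aa_frac * 100.0, index=list(AMINO_ACIDS))

    sense_codons = [c for c in CODONS if c not in code.stop_codons]
    if not include_single_codon_families:
        sense_codons = [c for c in sense_codons if code.degeneracy(code.codon_to_aa[c]) > 1]
    sense_idx = [CODON_INDEX[c] for c in sense_codons]
    codon_total = pooled[sense_idx].sum()
    codon_usage = pd.Series(pooled[sense_idx] / codon_total * 100.0, index=sense_codons)

    rscu_vec = rscu(pooled, code)
    rscu_series = pd.Series(
        [rscu_vec[CODON_INDEX[c]] for c in CODONS if c not in code.stop_codons],
        index=[c for c in CODONS if c not in code.stop_codons],
    )
    return SampleFeatures(
        sample_id=sample_id,
        gene_set=gene_set,
        n_genes=len(stats),
        mean_gc12=float(stats["gc12"].mean()),
        mean_gc3=float(stats["gc3"].mean()),
        mean_enc=float(stats["enc"].mean()),
        aa_usage=aa_usage,
        codon_usage=codon_usage,
        rscu=rscu_series,
    )


def features_table(features: Sequence[SampleFeatures]) -> pd.DataFrame:
    return pd.DataFrame([f.to_row() for f in features])


def build_rscu_matrix(features: Sequence[SampleFeatures]) -> pd.DataFrame:
    """Samples x codons RSCU matrix for correspondence analysis.

    Single-codon families (constant RSCU 1) and codons whose RSCU is
    undefined in any sample are dropped: an undefined RSCU marks an unused
    family, not zero usage.
    """
    code = STANDARD_CODE
    mat = pd.DataFrame(
        {f.sample_id: f.rscu for f in features}
    ).T
    multi = [c for c in mat.columns if code.degeneracy(code.codon_to_aa[c]) > 1]
    mat = mat[multi]
    return mat.dropna(axis=1, how="any")


# ---------------------------------------------------------------------------
# Neutrality regression

class NeutralityFit(NamedTuple):
    slope: float
    intercept: float
    r: float
    p: float
    n: int


def neutrality_regression(gc3: Sequence[float], gc12: Sequence[float]) -> NeutralityFit:
    """OLS of GC12 on GC3 with Pearson r and its two-sided t-test p-value.

    A significant positive relationship indicates that mutational (GC)
    pressure, which acts on all codon positions, dominates over selection,
    which constrains the first two positions more strongly.
    """
    x = np.asarray(gc3, dtype=float)
    y = np.asarray(gc12, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("neutrality regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("GC3 values are constant; regression undefined")
    fit = _stats.linregress(x, y)
    return NeutralityFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=len(x),
    )


# ---------------------------------------------------------------------------
# Correspondence analysis

@dataclass
class CAResult:
    """Correspondence analysis of a non-negative samples x codons table.

    ``row_coords``/``col_coords`` are principal coordinates; inertia per
    dimension is the squared singular value of the standardized residual
    matrix, and total inertia equals the table's chi-square statistic divided
    by its grand total.
    """

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    inertia: np.ndarray
    total_inertia: float


def correspondence_analysis(table: pd.DataFrame) -> CAResult:
    X = table.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("correspondence analysis requires a non-negative table")
    if np.isnan(X).any():
        raise ValueError("correspondence analysis input contains NaN")
    row_sums = X.sum(axis=1)
    col_sums = X.sum(axis=0)
    if (row_sums == 0).any():
        bad = table.index[np.flatnonzero(row_sums == 0)[0]]
        raise ValueError(f"all-zero row in CA input: {bad!r}")
    if (col_sums == 0).any():
        bad = table.columns[np.flatnonzero(col_sums == 0)[0]]
        raise ValueError(f"all-zero column in CA input: {bad!r}")
    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    k = min(X.shape) - 1  # drop the trivial dimension
    U, sv, Vt = U[:, :k], sv[:k], Vt[:k]
    dims = [f"Dim{i + 1}" for i in range(k)]
    row_coords = pd.DataFrame(
        (U * sv) / np.sqrt(r)[:, None], index=table.index, columns=dims
    )
    col_coords = pd.DataFrame(
        (Vt.T * sv) / np.sqrt(c)[:, None], index=table.columns, columns=dims
    )
    inertia = sv**2
    return CAResult(
        row_coords=row_coords,
        col_coords=col_coords,
        inertia=inertia,
        total_inertia=float(inertia.sum()),
    )
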