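"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pytest

from codonclim.codon_stats import CODONS, STANDARD_CODE


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


# ---------------------------------------------------------------------------
# Independent oracles, coded with plain dict/loop arithmetic so they share no
# code path with the package implementations they check.

def wright_enc_reference(counts_by_codon: dict[str, int]) -> float:
    """Brute-force ENC: class-averaged homozygosity, straight from the formula."""
    families: dict[str, list[str]] = {}
    for codon, aa in STANDARD_CODE.codon_to_aa.items():
        families.setdefault(aa, []).append(codon)

    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in families.items():
        k = len(codons)
        if k == 1:
            continue
        n = sum(counts_by_codon.get(c, 0) for c in codons)
        if n < 2:
            continue
        sum_p2 = sum((counts_by_codon.get(c, 0) / n) ** 2 for c in codons)
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        if f <= 0:
            f = 1.0 / k
        f_by_class[k].append(f)

    means = {}
    for k, fs in f_by_class.items():
        means[k] = sum(fs) / len(fs) if fs else None
    if means[2] is None or means[4] is None or means[6] is None:
        return float("nan")
    if means[3] is None:
        means[3] = (means[2] + means[4]) / 2.0
    value = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(61.0, max(20.0, value))


def chi_square_over_n_reference(table: np.ndarray) -> float:
    """Direct chi-square statistic of a contingency table, divided by its total."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    chi2 = 0.0
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            expected = row[i] * col[j] / n
            chi2 += (table[i, j] - expected) ** 2 / expected
    return chi2 / n


def random_codon_counts(rng: np.random.Generator, max_count: int = 10) -> np.ndarray:
    """A random small 64-codon count table with every family populated."""
    counts = rng.integers(0, max_count + 1, size=64)
    return counts.astype(np.int64)


def counts_to_dict(counts: np.ndarray) -> dict[str, int]:
    return {codon: int(c) for codon, c in zip(CODONS, counts) if c > 0}
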