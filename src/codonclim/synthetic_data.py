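"""Synthetic inputs with planted statistical structure.

This generator stands in for a multi-genome climate study: a panel of fungal
samples spanning eleven species and three climate zones (the default sample
plan mirrors the published panel's species/zone/elevation layout), each with
an annotated CDS set, an 11-variable temperature bioclim table, per-gene
dN/dS records and a per-site 5mC call table.  Every statistical structure
the pipeline is meant to detect is planted explicitly and recorded in a
truth table:

* CDS sets have controllable GC3 and codon-bias strength.  Amino-acid
  sequences are drawn from a fungal-like composition; the synonymous codon
  is chosen per family from a Boltzmann weighting (inverse temperature =
  ``bias_strength`` toward one preferred codon per family) combined with a
  GC3 pressure toward ``gc3_target``.  With zero bias this reproduces
  Wright's expected ENC-GC3 curve.
* The bioclim table is generated from two latent axes - a "means/extrema"
  axis driving BIO1/BIO5/BIO10/BIO11 and a "variability" axis driving
  BIO2/BIO4/BIO7 positively and BIO6 negatively - plus noise, so a PCA
  recovers the axes and their important variables.
* Feature-climate links are planted by shifting each sample's composition
  parameters along the variability axis (by default: GC12, arginine and the
  GTG codon increase with it, valine decreases - the sign pattern the
  pipeline should recover).
* Methylomes have a climate-zone effect: colder-zone samples get an elevated
  per-site methylation probability.

Codon choice is a family-wise multinomial without dinucleotide context -
sufficient for ENC/RSCU/GC targets, and a documented simplification.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import data_io
from .codon_stats import (
    AMINO_ACIDS,
    CODON_INDEX,
    CODONS,
    STANDARD_CODE,
    GeneticCode,
)
from .data_io import ZONE_COLDNESS

#: Fungal-like baseline amino-acid composition (fractions, alphabetical order).
BASE_AA_COMPOSITION: Mapping[str, float] = {
    "A": 0.088, "C": 0.013, "D": 0.055, "E": 0.062, "F": 0.040,
    "G": 0.072, "H": 0.022, "I": 0.052, "K": 0.058, "L": 0.090,
    "M": 0.022, "N": 0.041, "P": 0.050, "Q": 0.040, "R": 0.052,
    "S": 0.081, "T": 0.056, "V": 0.061, "W": 0.013, "Y": 0.032,
}

#: Default sample plan: (species, climate_zone, elevation masl, region) for a
#: 27-sample panel across 11 species, mirroring the study panel's layout.
DEFAULT_SAMPLE_PLAN: tuple[tuple[str, str, float, str], ...] = (
    ("sp01", "mediterranean", 553, "europe"),
    ("sp01", "cold_temperate", 1250, "europe"),
    ("sp01", "alpine", 2450, "europe"),
    ("sp02", "cold_temperate", 1360, "europe"),
    ("sp02", "alpine", 2350, "europe"),
    ("sp03", "mediterranean", 425, "europe"),
    ("sp03", "cold_temperate", 1250, "europe"),
    ("sp04", "mediterranean", 425, "europe"),
    ("sp04", "cold_temperate", 80, "europe"),
    ("sp05", "cold_temperate", 1504, "europe"),
    ("sp05", "alpine", 2154, "europe"),
    ("sp06", "cold_temperate", 1359, "europe"),
    ("sp06", "alpine", 2350, "europe"),
    ("sp07", "mediterranean", 631, "california"),
    ("sp07", "cold_temperate", 2036, "california"),
    ("sp08", "mediterranean", 330, "europe"),
    ("sp08", "cold_temperate", 1250, "europe"),
    ("sp08", "cold_temperate", 1688, "europe"),
    ("sp08", "alpine", 2350, "europe"),
    ("sp09", "mediterranean", 659, "europe"),
    ("sp09", "cold_temperate", 1504, "europe"),
    ("sp10", "mediterranean", 659, "europe"),
    ("sp10", "mediterranean", 659, "europe"),
    ("sp10", "cold_temperate", 1504, "europe"),
    ("sp11", "mediterranean", 330, "europe"),
    ("sp11", "mediterranean", 700, "europe"),
    ("sp11", "cold_temperate", 1350, "europe"),
)


@dataclass(frozen=True)
class PlantedEffect:
    """A feature planted to correlate with a latent bioclim axis.

    ``feature`` is 'gc12', 'aa:<X>' (one-letter amino acid) or
    'codon:<XYZ>'; ``r`` is the signed target correlation with the axis.
    """

    feature: str
    axis: int = 2  # 1 = means/extrema, 2 = variability
    r: float = 0.8


DEFAULT_PLANTED_EFFECTS: tuple[PlantedEffect, ...] = (
    PlantedEffect("gc12", 2, 0.8),
    PlantedEffect("aa:R", 2, 0.8),
    PlantedEffect("codon:GTG", 2, 0.8),
    PlantedEffect("aa:V", 2, -0.8),
)


@dataclass(frozen=True)
class MethylationConfig:
    n_contigs: int = 5
    contig_length: int = 2_000_000
    sites_per_contig: int = 1000
    base_prob: float = 0.25
    zone_effect: float = 0.5  # colder zone: base_prob * (1 + effect) per coldness rank
    mean_coverage: float = 20.0


@dataclass(frozen=True)
class DnDsConfig:
    n_genes_per_zone: int = 400
    cafe_fraction: float = 0.15
    zone_medians: Mapping[str, float] = field(
        default_factory=lambda: {
            "alpine": 0.10,
            "mediterranean": 0.12,
            "cold_temperate": 0.15,
        }
    )
    cafe_shift: float = 0.8  # multiplicative median shift of CAFE-family genes
    sigma: float = 1.0  # log-normal spread


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    sample_plan: tuple[tuple[str, str, float, str], ...] = DEFAULT_SAMPLE_PLAN
    genes_per_sample: int = 120
    codons_per_gene: int = 300
    single_copy_fraction: float = 0.4
    gc3_target: float = 0.55
    gc3_jitter: float = 0.04
    bias_strength: float = 0.4
    bioclim_noise: float = 1.0
    planted_effects: tuple[PlantedEffect, ...] = DEFAULT_PLANTED_EFFECTS
    methylation: MethylationConfig = field(default_factory=MethylationConfig)
    dnds: DnDsConfig = field(default_factory=DnDsConfig)

    def __post_init__(self):
        if self.genes_per_sample <= 0 or self.codons_per_gene <= 0:
            raise ValueError("gene and codon counts must be positive")
        if not 0.0 < self.gc3_target < 1.0:
            raise ValueError(
                "gc3_target must lie strictly inside (0, 1): Met, Trp and the "
                "fixed third positions make the boundaries unattainable"
            )
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be >= 0")
        for eff in self.planted_effects:
            if not abs(eff.r) < 1:
                raise ValueError(f"planted |r| must be < 1: {eff}")

    def sample_ids(self) -> list[str]:
        return [f"s{i + 1:02d}" for i in range(len(self.sample_plan))]


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# Metadata and membership

def simulate_metadata(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        {
            "sample_id": sid,
            "species": species,
            "climate_zone": zone,
            "elevation": elevation,
            "region": region,
        }
        for sid, (species, zone, elevation, region) in zip(
            config.sample_ids(), config.sample_plan
        )
    ]
    return pd.DataFrame(rows)


def simulate_membership(config: SimulationConfig) -> pd.DataFrame:
    n_single = int(round(config.genes_per_sample * config.single_copy_fraction))
    rows = [
        {
            "gene_id": f"g{i + 1:04d}",
            "gene_set": "single_copy_orthologue" if i < n_single else "other",
        }
        for i in range(config.genes_per_sample)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bioclim

def simulate_bioclim(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the BIO1-BIO11 table plus its latent truth axes.

    Axis 1 ("means/extrema") tracks how warm a site is overall and is tied
    to the sample's climate zone; axis 2 ("variability") is independent.
    Returns ``(bioclim, truth)`` where truth holds the standardized axis
    values per sample.
    """
    rng = _rng(config, 1)
    meta = simulate_metadata(config)
    n = len(meta)
    coldness = meta["climate_zone"].map(ZONE_COLDNESS).to_numpy(dtype=float)
    z1 = -(coldness - coldness.mean()) + 0.7 * rng.standard_normal(n)
    z1 = (z1 - z1.mean()) / z1.std(ddof=0)
    z2 = rng.standard_normal(n)
    # orthogonalize in-sample so the two axes are exactly uncorrelated and
    # the PCA can attribute each variable block to a single component
    z2 = z2 - z1 * float(z1 @ z2) / float(z1 @ z1)
    z2 = (z2 - z2.mean()) / z2.std(ddof=0)
    s = config.bioclim_noise
    basis = np.column_stack([z1, z2])

    def e() -> np.ndarray:
        # noise residualized against both axes in-sample, so each variable's
        # axis loadings are exact and the PCA block structure is clean
        x = rng.standard_normal(n)
        x = x - basis @ np.linalg.lstsq(basis, x, rcond=None)[0]
        sd = x.std(ddof=0)
        return x / sd if sd > 0 else x

    bio = {
        "BIO1": 10.0 + 6.0 * z1 + 0.8 * s * e(),
        "BIO2": 10.0 + 3.0 * z2 + 0.5 * s * e(),
        "BIO3": 40.0 + 2.0 * z1 - 1.5 * z2 + 3.0 * s * e(),
        "BIO4": 600.0 + 150.0 * z2 + 25.0 * s * e(),
        "BIO5": 26.0 + 5.0 * z1 + 0.8 * s * e(),
        "BIO6": -4.0 - 4.0 * z2 + 0.7 * s * e(),
        "BIO7": 30.0 + 5.0 * z2 + 0.8 * s * e(),
        "BIO8": 12.0 + 1.5 * z1 + 0.5 * z2 + 4.0 * s * e(),
        "BIO9": 8.0 + 1.2 * z1 - 0.5 * z2 + 4.0 * s * e(),
        "BIO10": 18.0 + 5.5 * z1 + 0.8 * s * e(),
        "BIO11": 2.0 + 6.0 * z1 + 0.8 * s * e(),
    }
    df = pd.DataFrame(bio)
    df["BIO7"] = np.clip(df["BIO7"], 0.1, None)
    df["BIO6"] = np.minimum(df["BIO6"], df["BIO5"] - 0.5)  # min month below max month
    df.insert(0, "sample_id", meta["sample_id"])
    df = df[["sample_id"] + [f"BIO{i}" for i in range(1, 12)]]
    truth = pd.DataFrame(
        {"sample_id": meta["sample_id"], "axis_means": z1, "axis_variability": z2}
    )
    return df, truth


# ---------------------------------------------------------------------------
# CDS generation

#: mean GC fraction of codon positions 1+2, per amino acid (uniform over family)
_GC12_SCORE = {
    aa: float(
        np.mean([(c[0] in "GC") + (c[1] in "GC") for c in STANDARD_CODE.families[aa]]) / 2.0
    )
    for aa in AMINO_ACIDS
}

# planted-effect tilt coefficients (per unit of latent signal):
# _GC12_TILT gives a ~1.5 percentage-point GC12 swing per unit signal,
# _AA_TILT a ~25% relative swing of the target residue, _CODON_TILT a
# within-family swing of the target codon strong enough to dominate any
# opposing family-level effect (the planted GTG rise must survive the
# planted valine decline).
_GC12_TILT = 0.14
_AA_TILT = 0.25
_CODON_TILT = 1.0


def _sample_codon_distributions(
    config: SimulationConfig,
    gc3: float,
    codon_boosts: Mapping[str, float],
    code: GeneticCode = STANDARD_CODE,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-amino-acid codon sampling tables.

    Returns (cumprob, codon_idx): both (20, 6) arrays, cumprob padded with 1s
    and codon_idx padded with the family's last codon.
    """
    cum = np.ones((20, 6))
    idx = np.zeros((20, 6), dtype=np.int64)
    for ai, aa in enumerate(AMINO_ACIDS):
        codons = code.families[aa]
        w = np.empty(len(codons))
        for ci, codon in enumerate(codons):
            base = gc3 if codon[2] in "GC" else 1.0 - gc3
            pref = config.bias_strength if ci == 0 else 0.0
            boost = codon_boosts.get(codon, 0.0)
            with np.errstate(over="ignore"):
                w[ci] = base * np.exp(min(pref + boost, 700.0))
        w = w / w.sum()
        cum[ai, : len(codons)] = np.cumsum(w)
        cum[ai, len(codons):] = 1.0
        idx[ai, : len(codons)] = [CODON_INDEX[c] for c in codons]
        idx[ai, len(codons):] = CODON_INDEX[codons[-1]]
    return cum, idx


_CODON_ARR = np.array(CODONS)


def _tilted_composition(signals: Mapping[str, float]) -> np.ndarray:
    """Apply planted exponential tilts to the baseline amino-acid composition."""
    comp = np.array([BASE_AA_COMPOSITION[a] for a in AMINO_ACIDS])
    log_w = np.zeros(20)
    if "gc12" in signals:
        score = np.array([_GC12_SCORE[a] for a in AMINO_ACIDS])
        log_w += _GC12_TILT * signals["gc12"] * (score - score.mean()) / 0.11
        # 0.11 ~ composition-weighted variance of the GC12 score, so the
        # realized GC12 responds by about _GC12_TILT per unit signal / 10
    for key, x in signals.items():
        if key.startswith("aa:"):
            log_w[AMINO_ACIDS.index(key.split(":", 1)[1])] += _AA_TILT * x
    comp = comp * np.exp(log_w)
    return comp / comp.sum()


def simulate_cds(
    config: SimulationConfig,
    axes: pd.DataFrame | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> tuple[dict[str, dict[str, str]], dict]:
    """Generate per-sample CDS sets; returns ``(cds, truth)``.

    ``cds`` maps sample_id -> {gene_id: sequence}; every gene starts with ATG
    and ends with a TAA stop.  When ``axes`` (from :func:`simulate_bioclim`)
    is given, the configured planted effects shift each sample's composition
    parameters along the chosen latent axis.  Deterministic given the seed.
    """
    rng = _rng(config, 2)
    sample_ids = config.sample_ids()
    gene_ids = [f"g{i + 1:04d}" for i in range(config.genes_per_sample)]
    axis_lookup: dict[str, dict[int, float]] = {}
    if axes is not None:
        ax = axes.set_index("sample_id")
        axis_lookup = {
            sid: {1: float(ax.loc[sid, "axis_means"]), 2: float(ax.loc[sid, "axis_variability"])}
            for sid in sample_ids
        }

    cds: dict[str, dict[str, str]] = {}
    truth_samples = []
    for sid in sample_ids:
        # per-feature latent signals: r * axis + sqrt(1-r^2) * noise
        signals: dict[str, float] = {}
        intended = {}
        if axes is not None:
            for eff in config.planted_effects:
                z = axis_lookup[sid][eff.axis]
                x = eff.r * z + np.sqrt(1.0 - eff.r**2) * rng.standard_normal()
                signals[eff.feature] = x
                intended[eff.feature] = eff.r
        comp_signals = {k: v for k, v in signals.items() if not k.startswith("codon:")}
        comp = _tilted_composition(comp_signals)
        codon_boosts = {
            k.split(":", 1)[1]: _CODON_TILT * v
            for k, v in signals.items()
            if k.startswith("codon:")
        }
        gc3 = float(np.clip(config.gc3_target + config.gc3_jitter * rng.standard_normal(),
                            0.05, 0.95))
        cum, idx = _sample_codon_distributions(config, gc3, codon_boosts, code)

        genes: dict[str, str] = {}
        n = config.codons_per_gene
        for gid in gene_ids:
            aa_idx = rng.choice(20, size=n, p=comp)
            u = rng.random(n)
            pick = (u[:, None] > cum[aa_idx]).sum(axis=1)
            codon_idx = idx[aa_idx, pick]
            genes[gid] = "ATG" + "".join(_CODON_ARR[codon_idx]) + "TAA"
        cds[sid] = genes
        truth_samples.append(
            {"sample_id": sid, "gc3_pressure": gc3, "signals": signals}
        )
    truth = {
        "samples": truth_samples,
        "planted_effects": [dataclasses.asdict(e) for e in config.planted_effects],
        "bias_strength": config.bias_strength,
        "gc3_target": config.gc3_target,
    }
    return cds, truth


def simulate_feature_links(
    config: SimulationConfig, bioclim_truth: pd.DataFrame
) -> tuple[dict[str, dict[str, str]], dict]:
    """Regenerate CDS sets with composition shifted along the latent axes.

    Thin wrapper over :func:`simulate_cds` passing the bioclim truth axes, so
    realized features carry the configured planted correlations.
    """
    return simulate_cds(config, axes=bioclim_truth)


# ---------------------------------------------------------------------------
# Methylomes

def simulate_methylome(config: SimulationConfig) -> tuple[dict[str, pd.DataFrame], dict]:
    """Per-sample bedMethyl-like site tables with a climate-zone effect.

    CpG sites are placed uniformly per contig, coverage is negative-binomial,
    the modification score is correlated with the true state, and the
    per-site methylation probability is ``base_prob * (1 + zone_effect)``
    per step of zone coldness (mediterranean < cold_temperate < alpine).
    """
    mc = config.methylation
    rng = _rng(config, 3)
    meta = simulate_metadata(config)
    tables: dict[str, pd.DataFrame] = {}
    probs: dict[str, float] = {}
    for _, row in meta.iterrows():
        sid = row["sample_id"]
        p_meth = mc.base_prob * (1.0 + mc.zone_effect) ** ZONE_COLDNESS[row["climate_zone"]]
        p_meth = min(p_meth, 0.99)
        probs[sid] = p_meth
        frames = []
        for ci in range(mc.n_contigs):
            pos = np.unique(rng.integers(0, mc.contig_length, size=mc.sites_per_contig))
            m = len(pos)
            p_nb = 10.0 / (10.0 + mc.mean_coverage)
            coverage = rng.negative_binomial(10, p_nb, size=m)
            state = rng.random(m) < p_meth
            score = np.where(
                state,
                rng.normal(80.0, 12.0, size=m),
                rng.normal(68.0, 12.0, size=m),
            )
            frames.append(
                pd.DataFrame(
                    {
                        "contig": f"ctg{ci + 1}",
                        "start": pos,
                        "end": pos + 1,
                        "coverage": coverage,
                        "mod_score": np.clip(score, 0.0, 100.0).round(2),
                        "methylated": state.astype(int),
                    }
                )
            )
        tables[sid] = pd.concat(frames, ignore_index=True)
    truth = {"per_sample_probability": probs, "config": dataclasses.asdict(mc)}
    return tables, truth


# ---------------------------------------------------------------------------
# dN/dS records

def simulate_dnds(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Log-normal per-gene dN/dS records with zone-specific medians."""
    dc = config.dnds
    rng = _rng(config, 4)
    rows = []
    for zone in sorted(dc.zone_medians):
        median = dc.zone_medians[zone]
        n_cafe = int(round(dc.n_genes_per_zone * dc.cafe_fraction))
        for i in range(dc.n_genes_per_zone):
            cafe = i < n_cafe
            med = median * (dc.cafe_shift if cafe else 1.0)
            rows.append(
                {
                    "gene_id": f"{zone[:3]}_{i + 1:05d}",
                    "climate_zone": zone,
                    "gene_group": "cafe_family" if cafe else "other",
                    "dnds": float(rng.lognormal(np.log(med), dc.sigma)),
                }
            )
    truth = {"zone_medians": dict(dc.zone_medians), "cafe_shift": dc.cafe_shift}
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Feature-level simulation (used for screen calibration at scale)

def simulate_feature_matrix(
    n_samples: int,
    seed: int | Sequence[int] = 0,
    planted: Sequence[tuple[str, str, float]] = (),
    n_pcs: int = 3,
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Direct feature-level simulation for correlation-screen studies.

    Generates independent standard-normal PC scores and a null feature matrix
    with the screen's standard layout (3 scalars, 20 amino acids, 61 codons).
    ``planted`` entries ``(feature_name, pc, r)`` overwrite a feature with
    ``r * score + sqrt(1 - r^2) * noise``.  Returns
    ``(features, families, scores)`` ready for ``correlation_screen``.
    """
    rng = np.random.default_rng(seed)
    sample_ids = [f"s{i + 1:03d}" for i in range(n_samples)]
    pcs = [f"PC{i + 1}" for i in range(n_pcs)]
    scores = pd.DataFrame(
        rng.standard_normal((n_samples, n_pcs)), index=sample_ids, columns=pcs
    )
    families: dict[str, str] = {}
    cols: dict[str, np.ndarray] = {}
    for name in ("mean_gc12", "mean_gc3", "mean_enc"):
        cols[name] = rng.standard_normal(n_samples)
        families[name] = "scalar"
    for aa in AMINO_ACIDS:
        cols[f"aa_{aa}"] = rng.standard_normal(n_samples)
        families[f"aa_{aa}"] = "amino_acid"
    for codon in CODONS:
        if codon in STANDARD_CODE.stop_codons:
            continue
        cols[f"codon_{codon}"] = rng.standard_normal(n_samples)
        families[f"codon_{codon}"] = "codon"
    for name, pc, r in planted:
        if name not in cols:
            raise KeyError(f"unknown feature {name!r}")
        z = scores[pc].to_numpy()
        cols[name] = r * z + np.sqrt(1.0 - r**2) * rng.standard_normal(n_samples)
    features = pd.DataFrame(cols, index=sample_ids)
    return features, families, scores


# ---------------------------------------------------------------------------
# Full dataset

def simulate_dataset(config: SimulationConfig, outdir: str | Path) -> dict:
    """Write a complete ready-to-run input directory; returns the truth dict.

    Layout: metadata.tsv, bioclim.tsv, membership.tsv, dnds.tsv,
    cds/<sample>.fasta, methylation/<sample>.tsv, truth.json.
    """
    outdir = Path(outdir)
    (outdir / "cds").mkdir(parents=True, exist_ok=True)
    (outdir / "methylation").mkdir(parents=True, exist_ok=True)

    meta = simulate_metadata(config)
    data_io.write_table(meta, outdir / "metadata.tsv")
    data_io.write_table(simulate_membership(config), outdir / "membership.tsv")

    bioclim, bio_truth = simulate_bioclim(config)
    data_io.write_table(bioclim, outdir / "bioclim.tsv")

    cds, cds_truth = simulate_cds(config, axes=bio_truth)
    for sid, genes in cds.items():
        data_io.write_cds_fasta(genes, outdir / "cds" / f"{sid}.fasta")

    meth_tables, meth_truth = simulate_methylome(config)
    for sid, table in meth_tables.items():
        table.to_csv(outdir / "methylation" / f"{sid}.tsv", sep="\t",
                     index=False, header=False)

    dnds, dnds_truth = simulate_dnds(config)
    data_io.write_table(dnds, outdir / "dnds.tsv")

    truth = {
        "seed": config.seed,
        "bioclim_axes": bio_truth.to_dict(orient="list"),
        "cds": cds_truth,
        "methylation": meth_truth,
        "dnds": dnds_truth,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
    return truth
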