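"""Synthetic dairy-cattle-like data: genotypes, feature maps, DRP phenotypes.

The generator emulates the statistical structure the downstream analyses
assume, at desk scale:

* two populations ("breeds") diverged by drift from shared ancestral allele
  frequencies (Balding-Nichols model, divergence parameter ``fst``), with
  population-specific block LD;
* non-overlapping genes grouped into GO-like feature terms, one of which (the
  focal term) is enriched for causal variants;
* de-regressed-proof (DRP) phenotypes: true genetic value plus noise whose
  variance is inflated by ``(1 - r^2)/r^2`` for an individual of reliability
  ``r^2``.

Block LD is produced by ranking the 2N haplotypes of a block by a random
pool assignment (default 8 pools) and filling each variant's carriers from
the top of that ranking; the per-variant allele count itself is drawn
Binomial(2N, p_pop), so between-population divergence is governed solely by
the drift parameter while variants within a block share carrier sets and are
therefore correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import FeatureMap, GenotypePanel, concat_panels

POPULATION_LABELS = ("popA", "popB", "popC", "popD")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Defaults mirror the study conditions at desk scale: a dairy-trait
    heritability of 0.39, DRP reliabilities in the high range observed for
    production traits, ~79% of each population born before the split year,
    and moderate between-breed divergence.
    """

    n_individuals: int = 1000          # per population
    n_variants: int = 5000
    n_chromosomes: int = 5
    ld_block_length: int = 25          # variants per haplotype block
    pool_size: int = 8                 # haplotype pools per block
    ancestral_maf_range: tuple = (0.05, 0.5)
    fst: float = 0.1
    n_populations: int = 2
    n_genes: int = 300
    genes_per_term: int = 15
    n_terms: int = 30
    gene_coverage: float = 0.5         # fraction of variants covered by genes
    h2: float = 0.39
    feature_share: float = 0.3         # target share of genetic variance in the focal term
    n_causal: int = 200
    reliability_range: tuple = (0.80, 0.98)
    train_fraction: float = 0.79       # probability of a pre-cutoff birth year
    birth_year_cutoff: int = 2006
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_individuals": self.n_individuals,
            "n_variants": self.n_variants,
            "n_chromosomes": self.n_chromosomes,
            "ld_block_length": self.ld_block_length,
            "pool_size": self.pool_size,
            "n_populations": self.n_populations,
            "n_genes": self.n_genes,
            "genes_per_term": self.genes_per_term,
            "n_terms": self.n_terms,
            "n_causal": self.n_causal,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if not (0 < self.h2 <= 1):
            raise ValueError("h2 must be in (0, 1]")
        if not (0 <= self.feature_share <= 1):
            raise ValueError("feature_share must be in [0, 1]")
        lo, hi = self.ancestral_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        lo, hi = self.reliability_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("reliability_range must lie in (0, 1]")
        if self.gene_coverage <= 0:
            raise ValueError("gene_coverage must be positive")
        if self.n_populations > len(POPULATION_LABELS):
            raise ValueError("too many populations requested")


@dataclass
class TrueValues:
    """Ground truth recorded by :func:`simulate_phenotypes`."""

    ids: np.ndarray
    g: np.ndarray                # total genetic value
    g_feature: np.ndarray
    g_rest: np.ndarray
    causal_index: np.ndarray     # variant columns with nonzero effect
    beta: np.ndarray             # effect per causal variant (same order)
    sigma_e2: float              # base residual variance (reliability 1)
    focal_term: str
    realized_feature_share: float
    realized_h2: float


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _chromosome_sizes(n_variants: int, n_chromosomes: int) -> np.ndarray:
    """Split variants across chromosomes as evenly as possible (never fails)."""
    base = n_variants // n_chromosomes
    sizes = np.full(n_chromosomes, base, dtype=int)
    sizes[: n_variants - base * n_chromosomes] += 1
    return sizes[sizes > 0]


def _block_haplotypes(rng, n_hap: int, freqs: np.ndarray, pool_size: int) -> np.ndarray:
    """Alleles (n_hap x block_len) with block LD and exact Binomial counts."""
    pool = rng.integers(0, pool_size, size=n_hap)
    pool_rank = rng.permutation(pool_size)
    # haplotype ordering: grouped by (shuffled) pool, random within pool
    score = pool_rank[pool] + rng.random(n_hap)
    order = np.argsort(score)
    out = np.zeros((n_hap, freqs.size), dtype=np.int8)
    counts = rng.binomial(n_hap, freqs)
    for j, c in enumerate(counts):
        out[order[:c], j] = 1
    return out


def simulate_genotypes(config: SimulationConfig) -> dict:
    """Simulate per-population genotype panels sharing one variant list.

    Returns a dict ``{population label: GenotypePanel}``.  Population allele
    frequencies follow a Balding-Nichols drift model around shared ancestral
    frequencies; dosages are haplotype sums in {0, 1, 2}.
    """
    root = np.random.SeedSequence(config.seed)
    ss_anc, ss_pos, *ss_pops = root.spawn(2 + config.n_populations)
    rng = np.random.default_rng(ss_anc)

    sizes = _chromosome_sizes(config.n_variants, config.n_chromosomes)
    m = int(sizes.sum())
    lo, hi = config.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)

    pos_rng = np.random.default_rng(ss_pos)
    chroms, positions = [], []
    for c, size in enumerate(sizes, start=1):
        gaps = pos_rng.integers(200, 2000, size=size)
        positions.append(np.cumsum(gaps))
        chroms.append(np.full(size, c))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)
    variants = pd.DataFrame(
        {
            "id": [f"snp{c}_{p}" for c, p in zip(chrom, pos)],
            "chrom": chrom.astype(int),
            "pos": pos.astype(int),
            "a1": "A",
            "a2": "B",
        }
    )

    f = config.fst
    panels = {}
    for k in range(config.n_populations):
        label = POPULATION_LABELS[k]
        prng = np.random.default_rng(ss_pops[k])
        if f == 0:
            p_pop = p_anc.copy()
        else:
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            p_pop = prng.beta(a, b)
        p_pop = np.clip(p_pop, 1e-6, 1 - 1e-6)

        n_hap = 2 * config.n_individuals
        hap = np.empty((n_hap, m), dtype=np.int8)
        start = 0
        while start < m:
            stop = min(start + config.ld_block_length, m)
            # blocks never straddle a chromosome boundary
            stop_chrom = chrom[start]
            same = np.flatnonzero(chrom[start:stop] != stop_chrom)
            if same.size:
                stop = start + same[0]
            hap[:, start:stop] = _block_haplotypes(
                prng, n_hap, p_pop[start:stop], config.pool_size
            )
            start = stop
        dos = hap[0::2] + hap[1::2]
        ids = np.array([f"{label}_{i:05d}" for i in range(config.n_individuals)], dtype=object)
        panels[label] = GenotypePanel(
            ids=ids,
            populations=np.full(config.n_individuals, label, dtype=object),
            variants=variants,
            dosages=dos.astype(np.float64),
        )
    return panels


# ---------------------------------------------------------------------------
# feature map
# ---------------------------------------------------------------------------

FAMILY_LABELS = (
    "metabolic process",
    "response to stimulus",
    "biological regulation",
    "cellular process",
    "immune system process",
)


def simulate_feature_map(panel: GenotypePanel, config: SimulationConfig):
    """Lay non-overlapping genes over the panel and group them into terms.

    Returns ``(FeatureMap, gene_table)`` where ``gene_table`` has columns
    ``gene_id, chrom, start, end`` (1-based inclusive).  Every term has
    ``genes_per_term`` member genes (at least 10, matching the convention of
    only analysing terms with >= 10 annotated genes) and a non-empty variant
    set.
    """
    if config.genes_per_term < 10:
        raise ValueError("terms must contain at least 10 genes (genes_per_term >= 10)")
    if config.genes_per_term > config.n_genes:
        raise ValueError("genes_per_term exceeds n_genes")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[6])

    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    chrom_labels = panel.chromosomes
    m = panel.n_variants
    vpg = max(1, int(m * config.gene_coverage / config.n_genes))  # variants per gene

    # allocate gene counts per chromosome proportional to variant counts
    chrom_sizes = np.array([(chrom == c).sum() for c in chrom_labels])
    counts = np.floor(config.n_genes * chrom_sizes / m).astype(int)
    while counts.sum() < config.n_genes:
        counts[int(np.argmax(chrom_sizes / (counts + 1)))] += 1

    genes, records = {}, []
    g_id = 0
    for c, n_g in zip(chrom_labels, counts):
        cols = np.flatnonzero(chrom == c)
        if n_g * vpg > cols.size:
            raise ValueError(
                f"cannot place {n_g} genes of {vpg} variants on chromosome {c} "
                f"({cols.size} variants)"
            )
        slack = cols.size - n_g * vpg
        # random non-negative gaps before/between genes
        cuts = np.sort(rng.integers(0, slack + 1, size=n_g))
        starts = cuts + vpg * np.arange(n_g)
        for s in starts:
            idx = cols[s : s + vpg]
            gene = f"gene{g_id:04d}"
            genes[gene] = idx
            records.append(
                {"gene_id": gene, "chrom": c, "start": int(pos[idx[0]]), "end": int(pos[idx[-1]])}
            )
            g_id += 1

    gene_ids = np.array(list(genes), dtype=object)
    terms, families = {}, {}
    for t in range(config.n_terms):
        tid = f"term{t + 1:03d}"
        terms[tid] = list(rng.choice(gene_ids, size=config.genes_per_term, replace=False))
        families[tid] = FAMILY_LABELS[t % len(FAMILY_LABELS)]
    fmap = FeatureMap(terms=terms, genes=genes, families=families, n_panel_variants=m)
    for tid in fmap.term_ids:
        if fmap.m_f(tid) < 1:
            raise RuntimeError(f"term {tid} has no variants")  # unreachable by construction
    return fmap, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(panel, feature_map: FeatureMap, config: SimulationConfig,
                        focal_term: str | None = None):
    """Simulate DRP phenotypes with a focal feature enriched for causal variants.

    ``panel`` may be a single (possibly multi-population) panel or the dict
    returned by :func:`simulate_genotypes`.  Effects are drawn i.i.d. normal
    per causal variant and rescaled so that, in the first population, the
    focal term's share of genetic variance equals ``feature_share`` and the
    heritability equals ``h2``.  Observed values are ``y = g + e`` with
    ``Var(e_i) = sigma_e^2 (1 - r_i^2)/r_i^2``.

    Returns ``(phenotypes, truth)``: a DataFrame with columns
    ``id, trait, drp, reliability, birth_year, population`` and a
    :class:`TrueValues` record.
    """
    if isinstance(panel, dict):
        panel = concat_panels(panel)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[7])
    if focal_term is None:
        focal_term = feature_map.term_ids[0]
    feat_idx = feature_map.variant_indices(focal_term)
    if config.feature_share > 0 and feat_idx.size == 0:
        raise ValueError("feature_share > 0 but the focal feature contains no variants")

    ref = panel.populations == panel.populations[0]  # scale in the first population
    m = panel.n_variants
    rest_idx = np.setdiff1d(np.arange(m), feat_idx)

    n_cf = 0 if config.feature_share == 0 else min(feat_idx.size, max(1, config.n_causal // 10))
    n_co = min(rest_idx.size, max(0, config.n_causal - n_cf))
    causal_f = rng.choice(feat_idx, size=n_cf, replace=False) if n_cf else np.array([], dtype=int)
    causal_o = rng.choice(rest_idx, size=n_co, replace=False) if n_co else np.array([], dtype=int)

    def _component(idx, target_var):
        """Genetic component with realized variance target_var in the ref pop."""
        if idx.size == 0 or target_var == 0:
            return np.zeros(panel.n_individuals), np.zeros(idx.size)
        beta = rng.standard_normal(idx.size)
        g = panel.dosages[:, idx] @ beta
        sd = g[ref].std()
        scale = 0.0 if sd == 0 else np.sqrt(target_var) / sd
        return g * scale, beta * scale

    g_f, beta_f = _component(causal_f, config.feature_share)
    g_r, beta_r = _component(causal_o, 1.0 - config.feature_share)
    g = g_f + g_r

    var_g = float(g[ref].var())
    sigma_e2 = var_g * (1 - config.h2) / config.h2

    lo, hi = config.reliability_range
    rel = rng.uniform(lo, hi, size=panel.n_individuals)
    e = rng.standard_normal(panel.n_individuals) * np.sqrt(sigma_e2 * (1 - rel) / rel)
    y = g + e

    pre = rng.random(panel.n_individuals) < config.train_fraction
    year = np.where(
        pre,
        rng.integers(config.birth_year_cutoff - 5, config.birth_year_cutoff, panel.n_individuals),
        rng.integers(config.birth_year_cutoff, config.birth_year_cutoff + 3, panel.n_individuals),
    )

    phen = pd.DataFrame(
        {
            "id": panel.ids,
            "trait": "sim_trait",
            "drp": y,
            "reliability": rel,
            "birth_year": year.astype(int),
            "population": panel.populations,
        }
    )
    vf, vr = float(g_f[ref].var()), float(g_r[ref].var())
    truth = TrueValues(
        ids=panel.ids,
        g=g,
        g_feature=g_f,
        g_rest=g_r,
        causal_index=np.concatenate([causal_f, causal_o]),
        beta=np.concatenate([beta_f, beta_r]),
        sigma_e2=sigma_e2,
        focal_term=focal_term,
        realized_feature_share=vf / (vf + vr) if (vf + vr) > 0 else np.nan,
        realized_h2=var_g / (var_g + sigma_e2) if (var_g + sigma_e2) > 0 else np.nan,
    )
    return phen, truth
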