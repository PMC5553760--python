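"""Marker quality control and variant-to-feature mapping.

Filters follow the standard sequence-data editing rules: exclude markers
with minor allele frequency < 0.01 or a Hardy-Weinberg goodness-of-fit
p-value < 1e-6.  Variants are assigned to a gene when their 1-based position
falls inside the gene's [start, end] interval (inclusive on both ends); a
term's variant set is the union over its member genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import FeatureMap, GenotypePanel


def compute_maf(panel: GenotypePanel) -> np.ndarray:
    """Per-variant minor allele frequency from mean dosage, folded to [0, 0.5]."""
    if panel.n_individuals == 0:
        raise ValueError("cannot compute MAF with zero individuals")
    p = panel.dosages.mean(axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def hwe_test(counts) -> float:
    """One-d.f. chi-square Hardy-Weinberg goodness-of-fit p-value.

    ``counts`` is ``(n_AA, n_Aa, n_aa)``.  Monomorphic markers return p = 1
    by convention.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    chi2 = float((((np.array([n_aa, n_ab, n_bb]) - exp) ** 2) / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test_panel(panel: GenotypePanel) -> np.ndarray:
    """Vectorized HWE p-values; imputed dosages are rounded to hard calls."""
    hard = np.rint(panel.dosages).astype(int)
    n = hard.shape[0]
    n_bb = (hard == 0).sum(axis=0)
    n_ab = (hard == 1).sum(axis=0)
    n_aa = (hard == 2).sum(axis=0)
    p = (2 * n_aa + n_ab) / (2.0 * n)
    pvals = np.ones(panel.n_variants)
    poly = (p > 0) & (p < 1)
    e_aa = n * p[poly] ** 2
    e_ab = 2 * n * p[poly] * (1 - p[poly])
    e_bb = n * (1 - p[poly]) ** 2
    chi2 = (
        (n_aa[poly] - e_aa) ** 2 / e_aa
        + (n_ab[poly] - e_ab) ** 2 / e_ab
        + (n_bb[poly] - e_bb) ** 2 / e_bb
    )
    pvals[poly] = stats.chi2.sf(chi2, df=1)
    return pvals


@dataclass
class QcReport:
    table: pd.DataFrame          # id, maf, hwe_p, removed, reason
    n_input: int
    n_removed_maf: int
    n_removed_hwe: int

    @property
    def n_kept(self) -> int:
        return self.n_input - int(self.table["removed"].sum())


def apply_qc(panel: GenotypePanel, maf_min: float = 0.01, hwe_min: float = 1e-6):
    """Remove variants failing MAF or HWE filters.

    Returns ``(filtered panel, QcReport)``.  The two filters are applied to
    the original panel, so their order is irrelevant.  Raises if every
    variant would be removed.
    """
    if not (0 <= maf_min < 1) or not (0 <= hwe_min < 1):
        raise ValueError("thresholds must lie in [0, 1)")
    maf = compute_maf(panel)
    hwe_p = hwe_test_panel(panel)
    fail_maf = maf < maf_min
    fail_hwe = hwe_p < hwe_min
    removed = fail_maf | fail_hwe
    reason = np.where(
        fail_maf & fail_hwe, "maf+hwe", np.where(fail_maf, "maf", np.where(fail_hwe, "hwe", ""))
    )
    report = QcReport(
        table=pd.DataFrame(
            {
                "id": panel.variants["id"],
                "maf": maf,
                "hwe_p": hwe_p,
                "removed": removed,
                "reason": reason,
            }
        ),
        n_input=panel.n_variants,
        n_removed_maf=int(fail_maf.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
    )
    if removed.all():
        raise ValueError(
            f"QC removed all {panel.n_variants} variants "
            f"(maf<{maf_min}: {report.n_removed_maf}, hwe<{hwe_min}: {report.n_removed_hwe})"
        )
    return panel.subset_variants(~removed), report


def map_variants_to_features(panel: GenotypePanel, gene_table: pd.DataFrame,
                             gene_sets: dict, families: dict | None = None) -> FeatureMap:
    """Build a :class:`FeatureMap` against ``panel``.

    ``gene_table`` must have columns ``gene_id, chrom, start, end`` with
    1-based inclusive coordinates.  A variant at position p belongs to a gene
    when ``start <= p <= end``; genes on chromosomes absent from the panel
    are skipped with a warning.  Must be re-run after any variant filtering.
    """
    chrom = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    by_chrom = {}
    for c in panel.chromosomes:
        cols = np.flatnonzero(chrom == c)
        by_chrom[c] = (cols, pos[cols])

    genes = {}
    for row in gene_table.itertuples(index=False):
        if row.chrom not in by_chrom:
            warnings.warn(f"gene {row.gene_id} on unknown chromosome {row.chrom!r}; skipped")
            continue
        cols, cpos = by_chrom[row.chrom]
        lo = np.searchsorted(cpos, row.start, side="left")
        hi = np.searchsorted(cpos, row.end, side="right")
        genes[row.gene_id] = cols[lo:hi]

    terms = {t: [g for g in members if g in genes] for t, members in gene_sets.items()}
    return FeatureMap(
        terms=terms,
        genes=genes,
        families=dict(families or {}),
        n_panel_variants=panel.n_variants,
    )


def combine_features(feature_map: FeatureMap, term_ids, new_id: str = None) -> FeatureMap:
    """Merge terms into a single feature (union of genes/variants).

    Returns a new map containing all original terms plus the combined one.
    """
    term_ids = list(term_ids)
    if not term_ids:
        raise ValueError("no terms to combine")
    for t in term_ids:
        if t not in feature_map.terms:
            raise KeyError(f"unknown term {t!r}")
    if new_id is None:
        new_id = "combined:" + "+".join(term_ids)
    genes = sorted({g for t in term_ids for g in feature_map.terms[t]})
    terms = dict(feature_map.terms)
    terms[new_id] = genes
    families = dict(feature_map.families)
    families[new_id] = "combined"
    return FeatureMap(
        terms=terms,
        genes=feature_map.genes,
        families=families,
        n_panel_variants=feature_map.n_panel_variants,
    )
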