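"""VanRaden method-2 genomic relationship matrices.

``G_ij = (1/m) sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k))``

i.e. every marker is centred at twice its allele frequency and scaled by its
own expected heterozygosity before averaging.  The module builds whole-genome
matrices, feature/remainder partitions (which satisfy the exact identity
``m G = m_f G_f + m_R G_R`` when one frequency set is used), and
leave-one-chromosome-out matrices for association scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .panel import GenotypePanel

DEFAULT_RIDGE = 1e-6


@dataclass
class RelationshipMatrix:
    """Dense symmetric relationship matrix over a set of individuals."""

    values: np.ndarray
    ids: np.ndarray
    variant_index: np.ndarray | None   # panel columns used
    freqs_source: str
    m_used: int
    ridge: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix dimension does not match number of ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, ids) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([lookup[i] for i in ids], dtype=int)
        return self.values[np.ix_(idx, idx)]


def _usable(freqs: np.ndarray) -> np.ndarray:
    return (freqs > 0.0) & (freqs < 1.0)


def compute_grm(panel: GenotypePanel, variant_subset=None, allele_freqs=None,
                ridge: float = DEFAULT_RIDGE, freqs_source: str = "observed") -> RelationshipMatrix:
    """VanRaden method-2 GRM over ``variant_subset`` (default: all variants).

    ``allele_freqs``, when given, must cover all panel columns; by default
    the frequencies observed in the panel's individuals are used.  Variants
    with frequency outside (0, 1) are excluded with a warning; a small ridge
    is added to the diagonal so that feature matrices built from few markers
    remain positive definite.
    """
    if variant_subset is None:
        subset = np.arange(panel.n_variants)
    else:
        subset = np.asarray(variant_subset)
        if subset.dtype == bool:
            subset = np.flatnonzero(subset)
    if subset.size == 0:
        raise ValueError("empty variant subset")
    if allele_freqs is None:
        allele_freqs = panel.dosages.mean(axis=0) / 2.0
    else:
        allele_freqs = np.asarray(allele_freqs, dtype=float)

    ok = _usable(allele_freqs[subset])
    if not ok.any():
        raise ValueError("all variants in the subset are monomorphic")
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} variants with allele frequency outside (0, 1)"
        )
    used = subset[ok]
    p = allele_freqs[used]
    w = (panel.dosages[:, used] - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    g = (w @ w.T) / used.size
    if ridge:
        g[np.diag_indices_from(g)] += ridge
    return RelationshipMatrix(
        values=g,
        ids=panel.ids,
        variant_index=used,
        freqs_source=freqs_source,
        m_used=int(used.size),
        ridge=ridge,
    )


def partition_grms(panel: GenotypePanel, feature_index, allele_freqs=None,
                   ridge: float = DEFAULT_RIDGE, g_all: RelationshipMatrix | None = None):
    """Feature and remainder GRMs ``(G_f, G_R)`` for a variant partition.

    Both matrices use the same allele frequencies, so the weighted-sum
    identity ``m_f G_f + m_R G_R = m G`` holds exactly (up to the common
    ridge).  When a precomputed whole-panel ``g_all`` built from the same
    frequencies/ridge is supplied, G_R is recovered from the identity
    instead of a second full matrix product.
    """
    feature_index = np.asarray(feature_index)
    if feature_index.dtype == bool:
        feature_index = np.flatnonzero(feature_index)
    feature_index = np.unique(feature_index)
    if allele_freqs is None:
        allele_freqs = panel.dosages.mean(axis=0) / 2.0
    usable = np.flatnonzero(_usable(np.asarray(allele_freqs, dtype=float)))
    feat = np.intersect1d(feature_index, usable)
    rest = np.setdiff1d(usable, feature_index)
    if feat.size == 0:
        raise ValueError("feature contains no usable variants")
    if rest.size == 0:
        raise ValueError("remainder-genome variant set is empty")

    g_f = compute_grm(panel, feat, allele_freqs, ridge=ridge)
    if g_all is not None:
        if g_all.m_used != usable.size:
            raise ValueError("g_all was not built from the same usable variant set")
        m, m_f, m_r = g_all.m_used, g_f.m_used, rest.size
        raw_all = g_all.values.copy()
        raw_all[np.diag_indices_from(raw_all)] -= g_all.ridge
        raw_f = g_f.values.copy()
        raw_f[np.diag_indices_from(raw_f)] -= ridge
        vals = (m * raw_all - m_f * raw_f) / m_r
        if ridge:
            vals[np.diag_indices_from(vals)] += ridge
        g_r = RelationshipMatrix(
            values=vals,
            ids=panel.ids,
            variant_index=rest,
            freqs_source=g_f.freqs_source,
            m_used=int(m_r),
            ridge=ridge,
        )
    else:
        g_r = compute_grm(panel, rest, allele_freqs, ridge=ridge)
    return g_f, g_r


def loco_grm(panel: GenotypePanel, chrom, allele_freqs=None,
             ridge: float = DEFAULT_RIDGE) -> RelationshipMatrix:
    """GRM from all variants NOT on ``chrom`` (leave one chromosome out)."""
    chroms = panel.chromosomes
    if len(chroms) < 2:
        raise ValueError("LOCO requires at least two chromosomes")
    if chrom not in chroms:
        raise KeyError(f"chromosome {chrom!r} not in panel")
    keep = panel.variants["chrom"].to_numpy() != chrom
    return compute_grm(panel, keep, allele_freqs, ridge=ridge,
                       freqs_source=f"observed (minus chr {chrom})")
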