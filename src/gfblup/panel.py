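"""Core in-memory containers: genotype panels and genomic-feature maps.

A :class:`GenotypePanel` holds allele dosages (individuals x variants, values
in [0, 2] counting the A1 allele) together with variant metadata and a
population label per individual.  A :class:`FeatureMap` links named feature
terms (GO-like gene sets) to genes and genes to variant column indices of the
panel it was built against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ("id", "chrom", "pos", "a1", "a2")


@dataclass
class GenotypePanel:
    """Dosage matrix plus variant and individual metadata.

    Parameters
    ----------
    ids
        Individual identifiers, unique.
    populations
        Population/breed label per individual (same length as ``ids``).
    variants
        DataFrame with columns ``id, chrom, pos, a1, a2``; ``pos`` is 1-based
        and strictly increasing within each chromosome.
    dosages
        ``(n_individuals, n_variants)`` array with values in [0, 2].
    """

    ids: np.ndarray
    populations: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.variants = self.variants.reset_index(drop=True)
        self.validate()

    # -- basic properties -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chromosomes(self) -> list:
        """Chromosome labels in panel (genome) order."""
        return list(dict.fromkeys(self.variants["chrom"]))

    def validate(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.ids) or m != len(self.variants):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.variants)} variants"
            )
        if len(self.ids) != len(self.populations):
            raise ValueError("ids and populations differ in length")
        if len(np.unique(self.ids.astype(str))) != n:
            raise ValueError("duplicate individual ids")
        if self.dosages.size and (
            self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9
        ):
            raise ValueError("dosages outside [0, 2]")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}"
                )

    # -- subsetting -------------------------------------------------------
    def subset_variants(self, index: np.ndarray) -> "GenotypePanel":
        """Return a panel restricted to variant column ``index`` (kept in
        genome order regardless of the order given)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        index = np.unique(index)
        return GenotypePanel(
            ids=self.ids,
            populations=self.populations,
            variants=self.variants.iloc[index],
            dosages=self.dosages[:, index],
        )

    def subset_individuals(self, mask_or_ids) -> "GenotypePanel":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            lookup = {i: k for k, i in enumerate(self.ids)}
            idx = np.array([lookup[i] for i in arr], dtype=int)
        return GenotypePanel(
            ids=self.ids[idx],
            populations=self.populations[idx],
            variants=self.variants,
            dosages=self.dosages[idx],
        )

    def for_population(self, label: str) -> "GenotypePanel":
        mask = self.populations == label
        if not mask.any():
            raise KeyError(f"no individuals with population label {label!r}")
        return self.subset_individuals(mask)

    def variant_indexer(self) -> dict:
        """Map variant id -> column index."""
        return {v: k for k, v in enumerate(self.variants["id"])}


def concat_panels(panels) -> GenotypePanel:
    """Stack panels that share an identical variant list (e.g. the two
    populations of one simulation) into one multi-population panel."""
    panels = list(panels.values()) if isinstance(panels, dict) else list(panels)
    if not panels:
        raise ValueError("no panels to concatenate")
    ref = panels[0].variants
    for p in panels[1:]:
        if not ref[["id", "chrom", "pos"]].equals(p.variants[["id", "chrom", "pos"]]):
            raise ValueError("panels do not share a variant list")
    return GenotypePanel(
        ids=np.concatenate([p.ids for p in panels]),
        populations=np.concatenate([p.populations for p in panels]),
        variants=ref,
        dosages=np.vstack([p.dosages for p in panels]),
    )


@dataclass
class FeatureMap:
    """Feature terms -> genes -> variant indices of a specific panel.

    ``terms`` maps a term id to its member gene ids, ``genes`` maps a gene id
    to a sorted array of variant column indices.  A term's variant set is the
    union over its member genes; ``m_f`` is the size of that union.
    """

    terms: dict
    genes: dict
    families: dict = field(default_factory=dict)
    n_panel_variants: int | None = None

    def __post_init__(self) -> None:
        self.genes = {g: np.unique(np.asarray(v, dtype=int)) for g, v in self.genes.items()}
        if self.n_panel_variants is not None:
            for g, idx in self.genes.items():
                if idx.size and (idx.min() < 0 or idx.max() >= self.n_panel_variants):
                    raise ValueError(f"gene {g!r} has variant indices outside the panel")

    @property
    def term_ids(self) -> list:
        return list(self.terms)

    def variant_indices(self, term_id: str) -> np.ndarray:
        """Sorted union of member genes' variant indices."""
        if term_id not in self.terms:
            raise KeyError(f"unknown term {term_id!r}")
        parts = [self.genes[g] for g in self.terms[term_id] if g in self.genes]
        if not parts:
            return np.array([], dtype=int)
        return np.unique(np.concatenate(parts))

    def m_f(self, term_id: str) -> int:
        return int(self.variant_indices(term_id).size)
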