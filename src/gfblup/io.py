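"""Readers and writers for the formats the pipeline exchanges.

* PLINK ``.bed/.bim/.fam`` (SNP-major 2-bit bed; dosages are counts of the
  A1 allele, so a 00 code = 2 copies of A1).
* A TSV dosage dialect: ``<prefix>.variants.tsv`` (id, chrom, pos, a1, a2)
  plus ``<prefix>.dosages.tsv`` (one row per individual: id, population,
  then one column per variant id).
* Phenotypes as TSV (id, trait, drp, reliability, birth_year, population).
* Gene coordinates as BED (0-based half-open on disk, 1-based inclusive in
  memory) and gene sets as GMT.
* Dense relationship matrices cached in HDF5.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenotypePanel

PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, SNP-major: 00 hom A1 (dosage 2), 10 het, 11 hom A2, 01 missing
_CODE_FOR_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11}
_DOSAGE_FOR_CODE = np.array([2.0, np.nan, 1.0, 0.0])


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def write_plink(panel: GenotypePanel, prefix) -> None:
    """Write a panel as PLINK .bed/.bim/.fam (dosages rounded to hard calls)."""
    prefix = Path(prefix)
    v = panel.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "id": v["id"],
            "cm": 0,
            "pos": v["pos"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": panel.populations,
            "iid": panel.ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phen": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)

    hard = np.rint(panel.dosages).astype(int)
    codes = np.full(hard.shape, 0b01, dtype=np.uint8)
    for d, c in _CODE_FOR_DOSAGE.items():
        codes[hard == d] = c
    n, m = codes.shape
    n_pad = (-n) % 4
    if n_pad:
        codes = np.vstack([codes, np.zeros((n_pad, m), dtype=np.uint8)])
    c = codes.T.reshape(m, -1, 4)  # SNP-major, 4 samples per byte
    packed = c[:, :, 0] | (c[:, :, 1] << 2) | (c[:, :, 2] << 4) | (c[:, :, 3] << 6)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def read_plink(prefix) -> GenotypePanel:
    """Read PLINK .bed/.bim/.fam into a :class:`GenotypePanel`."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phen"],
    )
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    n, m = len(fam), len(bim)
    bpv = (n + 3) // 4
    body = raw[3:].reshape(m, bpv)
    shifts = np.arange(4) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    dosages = _DOSAGE_FOR_CODE[codes.reshape(m, -1)[:, :n]].T
    variants = bim[["id", "chrom", "pos", "a1", "a2"]]
    return GenotypePanel(
        ids=fam["iid"].astype(str).to_numpy(dtype=object),
        populations=fam["fid"].astype(str).to_numpy(dtype=object),
        variants=variants,
        dosages=dosages,
    )


# ---------------------------------------------------------------------------
# TSV dosage dialect
# ---------------------------------------------------------------------------

def write_dosage_tsv(panel: GenotypePanel, prefix) -> None:
    prefix = Path(prefix)
    panel.variants.to_csv(f"{prefix}.variants.tsv", sep="\t", index=False)
    dos = pd.DataFrame(panel.dosages, columns=panel.variants["id"])
    dos.insert(0, "population", panel.populations)
    dos.insert(0, "id", panel.ids)
    dos.to_csv(f"{prefix}.dosages.tsv", sep="\t", index=False, float_format="%.6g")


def read_dosage_tsv(prefix) -> GenotypePanel:
    prefix = Path(prefix)
    variants = pd.read_csv(f"{prefix}.variants.tsv", sep="\t")
    dos = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t")
    return GenotypePanel(
        ids=dos["id"].astype(str).to_numpy(dtype=object),
        populations=dos["population"].astype(str).to_numpy(dtype=object),
        variants=variants,
        dosages=dos[variants["id"]].to_numpy(dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# phenotypes, genes, gene sets
# ---------------------------------------------------------------------------

PHENOTYPE_COLUMNS = ["id", "trait", "drp", "reliability", "birth_year", "population"]


def write_phenotypes(phen: pd.DataFrame, path) -> None:
    phen[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_phenotypes(path) -> pd.DataFrame:
    phen = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = set(PHENOTYPE_COLUMNS) - set(phen.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns {sorted(missing)}")
    return phen


def write_genes_bed(gene_table: pd.DataFrame, path) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    bed = pd.DataFrame(
        {
            "chrom": gene_table["chrom"],
            "start": gene_table["start"] - 1,
            "end": gene_table["end"],
            "name": gene_table["gene_id"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_genes_bed(path) -> pd.DataFrame:
    """Read BED gene coordinates, converting to 1-based inclusive."""
    bed = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2, 3],
                      names=["chrom", "start", "end", "name"])
    return pd.DataFrame(
        {
            "gene_id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"] + 1,
            "end": bed["end"],
        }
    )


def write_gmt(terms: dict, path, descriptions: dict | None = None) -> None:
    with open(path, "w") as fh:
        for term, genes in terms.items():
            desc = (descriptions or {}).get(term, "na")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_gmt(path):
    """Read a GMT file -> (term -> gene list, term -> description)."""
    terms, desc = {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = parts[2:]
            desc[parts[0]] = parts[1]
    return terms, desc


# ---------------------------------------------------------------------------
# GRM cache
# ---------------------------------------------------------------------------

def save_grm_hdf5(grm, path) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("matrix", data=grm.values)
        fh.create_dataset("ids", data=np.asarray(grm.ids, dtype="S"))
        fh.attrs["freqs_source"] = grm.freqs_source
        fh.attrs["m_used"] = grm.m_used
        fh.attrs["ridge"] = grm.ridge


def load_grm_hdf5(path):
    import h5py

    from .grm import RelationshipMatrix

    with h5py.File(path, "r") as fh:
        return RelationshipMatrix(
            values=fh["matrix"][...],
            ids=np.array([s.decode() for s in fh["ids"][...]], dtype=object),
            variant_index=None,
            freqs_source=str(fh.attrs["freqs_source"]),
            m_used=int(fh.attrs["m_used"]),
            ridge=float(fh.attrs["ridge"]),
        )
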