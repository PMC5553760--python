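"""Two-step mixed-model association scan (EMMAX-style) with LOCO GRMs.

Step 1 fits ``y = 1 mu + a + e`` with ``a ~ N(0, G sigma_a^2)`` per
chromosome, where G excludes the chromosome being scanned (leave one
chromosome out, avoiding double-fitting the tested variant).  Step 2 holds
the step-1 variances fixed and tests each variant by generalized least
squares under ``V = G sigma_a^2 + I sigma_e^2``:

``y = 1 mu + x b + eta``, ``t = b / se(b)``.

Residual structure in the scan is I as in the canonical two-step model; an
option substitutes the DRP reliability weights D.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .grm import compute_grm, loco_grm
from .mixedmodel import reliability_weights, reml_fit
from .panel import GenotypePanel

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.4549364...


def single_variant_gls(x, y, v) -> tuple:
    """GLS fit of ``y = 1 mu + x b`` under known covariance V.

    Returns ``(b, se, t)``; the standard error comes from the inverse of the
    weighted normal equations (V treated as known, no residual rescaling).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant genotype vector")
    v = np.asarray(v, dtype=float)
    c, low = linalg.cho_factor(v, lower=True, check_finite=False)
    design = np.column_stack([np.ones_like(x), x])
    td = linalg.solve_triangular(c, design, lower=True, check_finite=False)
    ty = linalg.solve_triangular(c, y, lower=True, check_finite=False)
    xtx = td.T @ td
    coef = np.linalg.solve(xtx, td.T @ ty)
    cov = np.linalg.inv(xtx)
    b = float(coef[1])
    se = float(np.sqrt(cov[1, 1]))
    return b, se, b / se


def gwas_scan(panel: GenotypePanel, phenotypes: pd.DataFrame, loco: bool = True,
              use_reliability: bool = False, reml_kwargs: dict | None = None) -> pd.DataFrame:
    """Genome-ordered association table: id, chrom, pos, b, se, t2, p.

    ``phenotypes`` must carry ``id`` and ``drp`` (and ``reliability`` when
    ``use_reliability``); individuals are matched to the panel by id and the
    scan runs on the intersection.  Zero-variance variants yield rows with
    missing statistics.
    """
    phen = phenotypes.set_index("id")
    keep = np.array([i in phen.index for i in panel.ids])
    if not keep.all():
        panel = panel.subset_individuals(keep)
    phen = phen.loc[panel.ids]
    y = phen["drp"].to_numpy(dtype=float)
    d = reliability_weights(phen["reliability"].to_numpy()) if use_reliability else None
    d_vec = d if d is not None else np.ones(y.size)
    reml_kwargs = reml_kwargs or {}

    chrom_arr = panel.variants["chrom"].to_numpy()
    chroms = panel.chromosomes
    full_g = None if (loco and len(chroms) > 1) else compute_grm(panel)

    rows = []
    for chrom in chroms:
        g = loco_grm(panel, chrom) if (loco and len(chroms) > 1) else full_g
        vc = reml_fit(y, [g.values], d, names=["a", "e"], **reml_kwargs)
        v = vc["a"] * g.values
        v[np.diag_indices_from(v)] += vc["e"] * d_vec
        c, _ = linalg.cho_factor(v, lower=True, check_finite=False)

        cols = np.flatnonzero(chrom_arr == chrom)
        x = panel.dosages[:, cols]
        block = linalg.solve_triangular(
            c, np.column_stack([y, np.ones(y.size), x]), lower=True, check_finite=False
        )
        ty, tone, tx = block[:, 0], block[:, 1], block[:, 2:]
        one_ss = tone @ tone
        # project out the transformed intercept
        xc = tx - np.outer(tone, (tone @ tx) / one_ss)
        yc = ty - tone * ((tone @ ty) / one_ss)
        sxx = np.einsum("ij,ij->j", xc, xc)
        sxy = yc @ xc
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.where(sxx > 1e-12, sxy / sxx, np.nan)
            se = np.where(sxx > 1e-12, np.sqrt(1.0 / sxx), np.nan)
        t = b / se
        sub = panel.variants.iloc[cols]
        rows.append(
            pd.DataFrame(
                {
                    "id": sub["id"].to_numpy(),
                    "chrom": sub["chrom"].to_numpy(),
                    "pos": sub["pos"].to_numpy(),
                    "b": b,
                    "se": se,
                    "t2": t**2,
                    "p": 2.0 * stats.norm.sf(np.abs(t)),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def genomic_inflation(t2_values) -> float:
    """Inflation factor lambda = median(t^2) / median of chi-square(1)."""
    t2 = np.asarray(t2_values, dtype=float)
    t2 = t2[np.isfinite(t2)]
    if t2.size == 0:
        raise ValueError("no test statistics")
    return float(np.median(t2) / CHI2_1_MEDIAN)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_tests


def gwas_diagnostics(assoc: pd.DataFrame, alpha: float = 0.05) -> dict:
    t2 = assoc["t2"].to_numpy()
    n_tested = int(np.isfinite(t2).sum())
    return {
        "lambda": genomic_inflation(t2),
        "n_tested": n_tested,
        "threshold": bonferroni_threshold(alpha, n_tested),
    }


def manhattan(assoc: pd.DataFrame, path, threshold: float | None = None) -> None:
    """Minimal Manhattan plot (log10 p by genome position)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    x0 = 0
    for k, (chrom, grp) in enumerate(assoc.groupby("chrom", sort=False)):
        ax.scatter(x0 + np.arange(len(grp)), -np.log10(grp["p"]), s=4,
                   color="C0" if k % 2 == 0 else "C1")
        x0 += len(grp)
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=0.8, ls="--")
    ax.set_xlabel("genome position (variant rank)")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
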