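"""Orchestration of the within- and between-population experiments.

A run chains: marker QC -> variant-to-feature mapping -> birth-year split ->
LOCO mixed-model GWAS on the training animals -> cyclical-permutation set
test per feature term -> GBLUP baseline -> GFBLUP per term (optionally plus
a combined top-k feature) -> accuracy/bias metrics on validation DRP.  The
between-population variant trains every model on one population and
validates on the other, on the intersection of the per-population post-QC
variant sets.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import io as gio
from .evaluation import accuracy, bias, delta_r, split_by_birth_year
from .grm import compute_grm, partition_grms
from .gwas import gwas_diagnostics, gwas_scan
from .mixedmodel import (
    blup_solve,
    predict_gebv,
    reliability_weights,
    reml_fit,
    summarize_partition,
)
from .panel import concat_panels
from .qc import apply_qc, combine_features, map_variants_to_features
from .settest import set_test_table
from .sim import SimulationConfig, simulate_feature_map, simulate_genotypes, simulate_phenotypes

REPORT_COLUMNS = [
    "term", "family", "model", "m_f", "snp_f", "t_sum", "p_set",
    "sigma2_f", "sigma2_r", "sigma2_g", "sigma2_e", "h2_feature", "h2",
    "r", "bias", "delta_r", "predictive", "converged",
]


@dataclass
class RunConfig:
    """Configuration of one experiment.

    Either ``sim`` (synthetic cohort) or the four input paths must be set.
    ``mode`` is ``"within"`` (split one population by birth year) or
    ``"between"`` (train on the first population, validate on the second).
    """

    sim: SimulationConfig | None = None
    genotypes_prefix: str | None = None     # TSV dosage dialect prefix
    plink_prefix: str | None = None
    phenotypes_path: str | None = None
    genes_bed: str | None = None
    gene_sets_gmt: str | None = None
    trait: str = "sim_trait"
    mode: str = "within"
    maf_min: float = 0.01
    hwe_min: float = 1e-6
    n_permutations: int = 1000
    reml_tol: float = 1e-6
    reml_max_iter: int = 100
    birth_year_cutoff: int = 2006
    top_k_combined: int = 0                 # 0 = no combined feature
    max_terms: int | None = None            # cap on fitted terms (None = all)
    use_reliability_in_gwas: bool = False
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("within", "between"):
            raise ValueError("mode must be 'within' or 'between'")
        if self.sim is None and not (
            (self.genotypes_prefix or self.plink_prefix)
            and self.phenotypes_path and self.genes_bed and self.gene_sets_gmt
        ):
            raise ValueError("need either a simulation config or all four input paths")
        for name in ("maf_min", "hwe_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimulationConfig(**raw["sim"])
        return cls(**raw)


def load_inputs(config: RunConfig):
    """Assemble (panels dict, gene_table, gene_sets, families, phenotypes)."""
    if config.sim is not None:
        panels = simulate_genotypes(config.sim)
        first = next(iter(panels.values()))
        fmap, gene_table = simulate_feature_map(first, config.sim)
        phen, _ = simulate_phenotypes(panels, fmap, config.sim)
        return panels, gene_table, dict(fmap.terms), dict(fmap.families), phen
    if config.genotypes_prefix:
        panel = gio.read_dosage_tsv(config.genotypes_prefix)
    else:
        panel = gio.read_plink(config.plink_prefix)
    panels = {label: panel.for_population(label) for label in dict.fromkeys(panel.populations)}
    gene_table = gio.read_genes_bed(config.genes_bed)
    gene_sets, desc = gio.read_gmt(config.gene_sets_gmt)
    phen = gio.read_phenotypes(config.phenotypes_path)
    phen = phen[phen["trait"] == config.trait].reset_index(drop=True)
    return panels, gene_table, gene_sets, desc, phen


def _fit_and_predict(y_train, d_train, grms, train_ids, valid_ids, drp_valid,
                     names, config, init=None):
    """REML fit on training, predict validation, return (vc, r, bias)."""
    sub = [g.submatrix(train_ids) for g in grms]
    vc = reml_fit(y_train, sub, d_train, init=init, names=names,
                  tol=config.reml_tol, max_iter=config.reml_max_iter)
    fit = blup_solve(vc, y_train, sub, d_train, training_ids=train_ids)
    pred = predict_gebv(fit, grms, train_ids, valid_ids)
    return vc, accuracy(pred["gebv"], drp_valid), bias(pred["gebv"], drp_valid), pred


def _experiment(config: RunConfig):
    """Shared core of the within/between runs."""
    panels, gene_table, gene_sets, families, phen = load_inputs(config)
    labels = list(panels)
    log = {"mode": config.mode, "seed": config.seed, "populations": labels}

    if config.mode == "within":
        label = labels[0]
        panel, report_qc = apply_qc(panels[label], config.maf_min, config.hwe_min)
        pop_phen = phen[phen["population"] == label].reset_index(drop=True)
        train_ids, valid_ids = split_by_birth_year(pop_phen, config.birth_year_cutoff)
        log["qc"] = {label: {"n_input": report_qc.n_input, "n_kept": report_qc.n_kept}}
    else:
        if len(labels) < 2:
            raise ValueError("between-population mode needs two populations")
        qc_panels, qc_log = {}, {}
        for label in labels[:2]:
            qp, rep = apply_qc(panels[label], config.maf_min, config.hwe_min)
            qc_panels[label] = qp
            qc_log[label] = {"n_input": rep.n_input, "n_kept": rep.n_kept}
        a, b = labels[:2]
        shared = np.intersect1d(
            qc_panels[a].variants["id"].to_numpy(), qc_panels[b].variants["id"].to_numpy()
        )
        if shared.size == 0:
            raise ValueError("no shared variants after per-population QC")
        keep = {
            lab: np.flatnonzero(qc_panels[lab].variants["id"].isin(shared).to_numpy())
            for lab in (a, b)
        }
        panel = concat_panels([qc_panels[a].subset_variants(keep[a]),
                               qc_panels[b].subset_variants(keep[b])])
        train_ids = panel.ids[panel.populations == a]
        valid_ids = panel.ids[panel.populations == b]
        log["qc"] = qc_log
        log["n_shared_variants"] = int(shared.size)

    fmap = map_variants_to_features(panel, gene_table, gene_sets, families)
    phen_idx = phen.set_index("id")
    y_train = phen_idx.loc[train_ids, "drp"].to_numpy(dtype=float)
    d_train = reliability_weights(phen_idx.loc[train_ids, "reliability"].to_numpy())
    drp_valid = phen_idx.loc[valid_ids, "drp"].to_numpy(dtype=float)
    has_drp = np.isfinite(drp_valid)   # metrics use non-missing validation DRP only
    valid_ids, drp_valid = valid_ids[has_drp], drp_valid[has_drp]
    log["n_train"], log["n_valid"] = int(train_ids.size), int(valid_ids.size)
    log["n_variants"] = int(panel.n_variants)

    # --- GWAS on the training animals + set test ------------------------
    train_panel = panel.subset_individuals(train_ids)
    assoc = gwas_scan(train_panel, phen, loco=True,
                      use_reliability=config.use_reliability_in_gwas,
                      reml_kwargs={"tol": config.reml_tol, "max_iter": config.reml_max_iter})
    log["gwas"] = gwas_diagnostics(assoc)
    terms = fmap.term_ids
    if config.max_terms is not None:
        terms = terms[: config.max_terms]
    fit_map = fmap
    if terms:
        sets = set_test_table(assoc, fmap, n_perm=config.n_permutations, seed=config.seed)
        sets = sets[sets["term"].isin(terms)].reset_index(drop=True)
        if config.top_k_combined and len(sets):
            top = sets.nsmallest(config.top_k_combined, "p_set")["term"].tolist()
            fit_map = combine_features(fmap, top, new_id="combined_top")
            comb = set_test_table(
                assoc,
                FeatureMapView(fit_map, ["combined_top"]),
                n_perm=config.n_permutations,
                seed=config.seed + 1,
            )
            sets = pd.concat([sets, comb], ignore_index=True)
            terms = terms + ["combined_top"]
    else:
        sets = pd.DataFrame(columns=["term", "family", "m_f", "t_sum", "p_set"])

    # --- GBLUP baseline -------------------------------------------------
    g_all = compute_grm(panel)
    vc0, r0, b0, pred0 = _fit_and_predict(
        y_train, d_train, [g_all], train_ids, valid_ids, drp_valid,
        names=["g", "e"], config=config,
    )
    m_total = g_all.m_used
    gebv_frames = [pd.DataFrame({
        "term": "GBLUP", "id": valid_ids, "g_f": np.nan, "g_r": np.nan,
        "g_total": pred0["gebv"],
    })]
    rows = [{
        "term": "GBLUP", "family": "", "model": "GBLUP",
        "m_f": m_total, "snp_f": 1.0, "t_sum": np.nan, "p_set": np.nan,
        "sigma2_f": np.nan, "sigma2_r": np.nan, "sigma2_g": vc0["g"],
        "sigma2_e": vc0["e"],
        "h2_feature": np.nan, "h2": summarize_partition(vc0, m_total, 0).h2
        if m_total else np.nan,
        "r": r0, "bias": b0, "delta_r": 0.0, "predictive": False,
        "converged": vc0.converged,
    }]

    # --- GFBLUP per term ------------------------------------------------
    set_lookup = sets.set_index("term") if len(sets) else None
    for term in terms:
        idx = fit_map.variant_indices(term)
        if idx.size == 0 or idx.size >= m_total:
            continue
        g_f, g_r = partition_grms(panel, idx, g_all=g_all)
        vc, r_f, b_f, pred_t = _fit_and_predict(
            y_train, d_train, [g_f, g_r], train_ids, valid_ids, drp_valid,
            names=["f", "r", "e"], config=config,
        )
        summ = summarize_partition(vc, g_f.m_used, g_r.m_used)
        gebv_frames.append(pd.DataFrame({
            "term": term, "id": valid_ids, "g_f": pred_t["f"],
            "g_r": pred_t["r"], "g_total": pred_t["gebv"],
        }))
        d_r, pred_flag = delta_r(r_f, r0)
        srow = set_lookup.loc[term] if set_lookup is not None else None
        rows.append({
            "term": term, "family": fit_map.families.get(term, ""), "model": "GFBLUP",
            "m_f": g_f.m_used, "snp_f": summ.snp_f,
            "t_sum": float(srow["t_sum"]) if srow is not None else np.nan,
            "p_set": float(srow["p_set"]) if srow is not None else np.nan,
            "sigma2_f": vc["f"], "sigma2_r": vc["r"], "sigma2_g": np.nan,
            "sigma2_e": vc["e"],
            "h2_feature": summ.h2_feature, "h2": summ.h2,
            "r": r_f, "bias": b_f, "delta_r": d_r, "predictive": pred_flag,
            "converged": vc.converged,
        })

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    gebv = pd.concat(gebv_frames, ignore_index=True)
    return report, log, gebv


class FeatureMapView:
    """Restrict a FeatureMap to a subset of terms (for set_test_table)."""

    def __init__(self, fmap, term_ids):
        self._fmap = fmap
        self.term_ids = list(term_ids)
        self.families = fmap.families

    def variant_indices(self, term):
        return self._fmap.variant_indices(term)


def run_within_population(config: RunConfig):
    """Within-population experiment (birth-year training/validation split)."""
    if config.mode != "within":
        config = replace(config, mode="within")
    report, log, gebv = _experiment(config)
    if config.outdir:
        write_outputs(report, log, config.outdir, gebv)
    return report, log


def run_between_population(config: RunConfig):
    """Train on the first population, validate on the second."""
    if config.mode != "between":
        config = replace(config, mode="between")
    report, log, gebv = _experiment(config)
    if config.outdir:
        write_outputs(report, log, config.outdir, gebv)
    return report, log


def write_outputs(report: pd.DataFrame, log: dict, outdir, gebv: pd.DataFrame = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(outdir / "report.tsv", sep="\t", index=False, float_format="%.6g")
    if gebv is not None:
        gebv.to_csv(outdir / "gebv.tsv", sep="\t", index=False, float_format="%.6g")
    with open(outdir / "diagnostics.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True, default=str)


def enrichment_prediction_correlation(report: pd.DataFrame):
    """Correlation across terms of set-test -log10 p with the accuracy gain.

    Returns ``(r, p)``; this is the scatter-plot statistic relating
    post-GWAS enrichment to the GFBLUP improvement.
    """
    sub = report[(report["model"] == "GFBLUP") & np.isfinite(report["p_set"])]
    if len(sub) < 3:
        raise ValueError("need at least 3 feature terms")
    return tuple(
        float(v) for v in stats.pearsonr(-np.log10(sub["p_set"]), sub["delta_r"])
    )


def family_comparison(report_a: pd.DataFrame, report_b: pd.DataFrame) -> pd.DataFrame:
    """Paired per-family comparison of set-test signal between two traits.

    For every feature family, the -log10 set-test p-values of the terms
    shared by the two reports are compared with a paired Student's t-test.
    """
    a = report_a[report_a["model"] == "GFBLUP"].set_index("term")
    b = report_b[report_b["model"] == "GFBLUP"].set_index("term")
    shared = a.index.intersection(b.index)
    rows = []
    for family, grp in a.loc[shared].groupby("family"):
        terms = grp.index
        xa = -np.log10(a.loc[terms, "p_set"].to_numpy(dtype=float))
        xb = -np.log10(b.loc[terms, "p_set"].to_numpy(dtype=float))
        ok = np.isfinite(xa) & np.isfinite(xb)
        if ok.sum() < 2 or np.allclose(xa[ok] - xb[ok], (xa[ok] - xb[ok])[0]):
            t_stat, p = np.nan, np.nan
        else:
            t_stat, p = stats.ttest_rel(xa[ok], xb[ok])
        rows.append({
            "family": family, "n_terms": int(ok.sum()),
            "mean_neglog10p_a": float(np.mean(xa[ok])) if ok.any() else np.nan,
            "mean_neglog10p_b": float(np.mean(xb[ok])) if ok.any() else np.nan,
            "t": float(t_stat) if np.isfinite(t_stat) else np.nan,
            "p": float(p) if np.isfinite(p) else np.nan,
        })
    return pd.DataFrame(rows)
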