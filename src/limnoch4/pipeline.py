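"""End-to-end orchestration: synthetic or file-driven runs with one report.

``run_all`` executes the four analysis stages in order — flux thermal
sensitivity, isotope partitioning, community statistics, CH4 prediction — and
returns a JSON-serialisable report; with an output directory it also writes
the CSV artifacts.  ``validate_inputs`` checks file schemas and cross-file
sample-key consistency without running the analyses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community as comm
from . import flux as fx
from . import io as io_
from . import isotopes as iso
from . import multivariate as mv
from . import regression as reg
from . import synthetic as syn
from .config import SyntheticConfig

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Exactly one of ``synthetic`` or ``paths`` drives the run."""

    synthetic: SyntheticConfig | None = None
    paths: dict | None = None
    seed: int = 0
    rarefaction_depth: int | None = None
    permutations: int = 999
    outdir: Path | None = None
    guilds: dict = field(default_factory=lambda: dict(comm.DEFAULT_GUILDS))

    def __post_init__(self):
        if (self.synthetic is None) == (self.paths is None):
            raise ValueError("set exactly one of 'synthetic' or 'paths'")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        c = cfg.synthetic
        records = syn.generate_flux_records(c)
        chem = syn.generate_core_chemistry(c)
        table = syn.generate_otu_table(c)
        standards, qpcr_samples = syn.generate_qpcr_plate(c)
        depth = cfg.rarefaction_depth or c.rarefaction_depth
        return records, chem, table, standards, qpcr_samples, depth
    p = cfg.paths
    records = io_.read_flux_csv(p["flux"]) if "flux" in p else None
    chem = io_.read_chem_csv(p["chem"]) if "chem" in p else None
    table = None
    if "otu" in p and "meta" in p:
        table = io_.read_otu_tsv(p["otu"], io_.read_meta_csv(p["meta"]))
    standards = qpcr_samples = None
    if "qpcr_standards" in p and "qpcr_samples" in p:
        standards, qpcr_samples = io_.read_qpcr_csv(
            p["qpcr_standards"], p["qpcr_samples"]
        )
    return records, chem, table, standards, qpcr_samples, cfg.rarefaction_depth or 3000


def run_all(cfg: RunConfig) -> dict:
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": cfg.seed,
        "stages": {},
        "errors": {},
    }
    records, chem, table, standards, qpcr_samples, rare_depth = _load_inputs(cfg)
    if cfg.synthetic is not None:
        report["config_hash"] = cfg.synthetic.config_hash()

    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        h = report.get("config_hash")
        if records is not None:
            io_.write_flux_csv(records, outdir / "flux.csv", h)
        if chem is not None:
            io_.write_chem_csv(chem, outdir / "chem.csv", h)
        if table is not None:
            io_.write_otu_tsv(table, outdir / "otu.tsv", h)
            io_.write_meta_csv(table.sample_meta, outdir / "meta.csv", h)
        if standards is not None:
            io_.write_qpcr_csv(
                standards, qpcr_samples, outdir / "qpcr_standards.csv",
                outdir / "qpcr_samples.csv", h,
            )

    # ----- stage 1: flux thermal sensitivity ---------------------------
    if records is not None:
        try:
            report["stages"]["flux"] = _stage_flux(records, cfg)
        except Exception as e:  # keep partial outputs, summarise the error
            report["errors"]["flux"] = str(e)

    # ----- stage 2: isotope partitioning -------------------------------
    fugitive = None
    if chem is not None:
        try:
            stage, fugitive = _stage_isotopes(chem, outdir)
            report["stages"]["isotopes"] = stage
        except Exception as e:
            report["errors"]["isotopes"] = str(e)

    # ----- stage 3: community ------------------------------------------
    rare = None
    if table is not None:
        try:
            stage, rare = _stage_community(
                table, rare_depth, cfg, fugitive, standards, qpcr_samples
            )
            report["stages"]["community"] = stage
        except Exception as e:
            report["errors"]["community"] = str(e)

    # ----- stage 4: CH4 prediction -------------------------------------
    if rare is not None and chem is not None:
        try:
            report["stages"]["prediction"] = _stage_prediction(rare, chem, cfg)
        except Exception as e:
            report["errors"]["prediction"] = str(e)

    if outdir:
        with open(outdir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
    return _jsonable(report)


def _stage_flux(records: pd.DataFrame, cfg: RunConfig) -> dict:
    bins = fx.bin_flux(records)
    groups = {
        key: grp.reset_index(drop=True)
        for key, grp in bins.groupby(["lake", "zone"], sort=True)
    }
    fits = {}
    polys = {}
    for key, b in groups.items():
        fit = fx.fit_arrhenius(b, group=key)
        fits["/".join(key)] = {
            "slope_K": fit.slope,
            "intercept": fit.intercept,
            "se_slope": fit.se_slope,
            "r2": fit.r2,
            "apparent_Ea_kJ_mol": fit.apparent_Ea_kJ_mol,
            "n_bins": fit.n_bins,
        }
        if len(b) >= 3:
            poly = fx.fit_polynomial(b, degree=2)
            polys["/".join(key)] = {
                "coefficients": list(poly.coefficients),
                "r2": poly.r2,
            }
    comparisons = []
    for subset in fx.SUBSETS:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for c in fx.compare_slopes(groups, subset=subset):
                comparisons.append(
                    {
                        "pair": ["/".join(g) for g in c.pair],
                        "subset": c.subset,
                        "interaction_p": c.interaction_p,
                        "significant": c.significant,
                        "slopes": {"/".join(g): s for g, s in c.slopes.items()},
                    }
                )
    return {
        "n_records": int(len(records)),
        "n_bins": int(len(bins)),
        "arrhenius": fits,
        "polynomial": polys,
        "slope_comparisons": comparisons,
    }


def _stage_isotopes(chem: pd.DataFrame, outdir):
    fug = iso.fugitive_profile(chem)
    if outdir:
        fug.to_csv(Path(outdir) / "fugitive.csv", index_label="sample")
    pathway_counts = fug["pathway"].value_counts().to_dict()
    stage = {
        "n_samples": int(len(fug)),
        "mean_alpha": float(fug["alpha"].mean()),
        "mean_alphaC": float(fug["alphaC"].mean()),
        "mean_f_meth": float(fug["f_meth"].mean()),
        "pathway_counts": pathway_counts,
        "dominant_pathway": max(pathway_counts, key=pathway_counts.get),
        "n_negative_fugitive": int(
            fug["flags"].str.contains("negative_fugitive").sum()
        ),
    }
    return stage, fug


def _stage_community(table, rare_depth, cfg: RunConfig, fugitive, standards, qpcr):
    rare = comm.rarefy(table, depth=rare_depth, seed=cfg.seed)
    dm = comm.braycurtis(rare)
    ord_ = mv.pcoa(dm)
    stage: dict = {
        "n_samples": int(len(rare.samples)),
        "rarefaction_depth": int(rare_depth),
        "pcoa_pct_axis1": float(ord_.proportion_explained[0] * 100),
        "pcoa_pct_axis2": float(ord_.proportion_explained[1] * 100),
    }
    for factor in ("zone", "lake"):
        res = mv.permanova(
            dm, rare.sample_meta[factor], n_perm=cfg.permutations, seed=cfg.seed
        )
        stage[f"permanova_{factor}"] = {"pseudo_F": res.pseudo_F, "p": res.p_value}
    depth_vals = rare.sample_meta["depth_cm"].to_numpy(dtype=float)
    dm_depth = pd.DataFrame(
        np.abs(depth_vals[:, None] - depth_vals[None, :]),
        index=rare.samples, columns=rare.samples,
    )
    mres = mv.mantel(dm, dm_depth, n_perm=cfg.permutations, seed=cfg.seed)
    stage["mantel_depth"] = {"rho": mres.rho, "p": mres.p_value}

    abund, tests = comm.guild_abundance(rare, cfg.guilds)
    stage["guilds"] = {
        g: {
            "mean_pct": float(abund[g].mean()),
            "mean_pct_edge": float(abund.loc[rare.sample_meta.zone == "edge", g].mean()),
            "mean_pct_middle": float(
                abund.loc[rare.sample_meta.zone == "middle", g].mean()
            ),
        }
        for g in abund.columns
    }
    stage["guild_tests"] = {
        t.guild: {"t_p": t.t_p, "anova_p": t.anova_p} for t in tests
    }

    if fugitive is not None:
        fug_series = fugitive["fugitive_CH4_uM"]
        try:
            mfug, _ = iso.correlate_fugitive_with_microbes(
                fug_series, dm, n_perm=cfg.permutations, seed=cfg.seed
            )
            stage["mantel_fugitive"] = {"rho": mfug.rho, "p": mfug.p_value}
        except iso.IsotopeError as e:
            stage["mantel_fugitive"] = {"error": str(e)}

    if standards is not None and qpcr is not None:
        qres = comm.quantify_qpcr(qpcr, standard_table=standards)
        stage["qpcr"] = {
            "curve_r2": qres.curve_r2,
            "curve_slope": qres.curve_slope,
            "mean_log10_copies_per_g": float(np.log10(qres.copies_per_g).mean()),
        }
        proxy, ptests = comm.absolute_guild_proxy(
            abund, qres.copies_per_g, rare.sample_meta["zone"]
        )
        stage["absolute_proxy_tests"] = {
            t.guild: {"t_p": t.t_p, "anova_p": t.anova_p} for t in ptests
        }
    return stage, rare


def _stage_prediction(rare, chem: pd.DataFrame, cfg: RunConfig) -> dict:
    vm = reg.assemble_variables(rare, chem, guilds=cfg.guilds)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = reg.compare_models(vm)
    best = table["plsr_r2"].idxmax()
    model = table.loc[best, "model"]
    stage = {
        "n_variables_total": int(vm.X.shape[1]),
        "suites": {
            s: {
                "n_variables": int(row["n_variables"]),
                "plsr_r2": float(row["plsr_r2"]),
                "plsr_components": int(row["plsr_components"]),
                "mlr_adj_r2": float(row["mlr_adj_r2"]),
                "mlr_p": float(row["mlr_p"]),
            }
            for s, row in table.iterrows()
        },
        "best_suite": best,
        "n_vip_significant": int(len(model.significant_vars_)),
        "top_vip": model.vip_.sort_values(ascending=False).head(10).to_dict(),
    }
    return stage


# ----------------------------------------------------------------------
# input validation
# ----------------------------------------------------------------------

def validate_inputs(paths: dict) -> dict:
    """Schema-check input files and cross-file sample-key consistency."""
    report = {"files": {}, "cross": {}, "ok": True}
    loaded = {}
    readers = {
        "flux": io_.read_flux_csv,
        "chem": io_.read_chem_csv,
        "meta": io_.read_meta_csv,
    }
    for key, reader in readers.items():
        if key not in paths:
            continue
        try:
            loaded[key] = reader(paths[key])
            report["files"][key] = "ok"
        except Exception as e:
            report["files"][key] = str(e)
            report["ok"] = False
    if "otu" in paths:
        if "meta" in loaded:
            try:
                loaded["otu"] = io_.read_otu_tsv(paths["otu"], loaded["meta"])
                report["files"]["otu"] = "ok"
            except Exception as e:
                report["files"]["otu"] = str(e)
                report["ok"] = False
        else:
            report["files"]["otu"] = "skipped: metadata unavailable"
    if "qpcr_standards" in paths and "qpcr_samples" in paths:
        try:
            loaded["qpcr"] = io_.read_qpcr_csv(
                paths["qpcr_standards"], paths["qpcr_samples"]
            )
            report["files"]["qpcr"] = "ok"
        except Exception as e:
            report["files"]["qpcr"] = str(e)
            report["ok"] = False

    if "otu" in loaded and "chem" in loaded:
        otu_samples = set(loaded["otu"].samples)
        chem_samples = set(loaded["chem"].index)
        orphans = sorted(otu_samples - chem_samples)
        report["cross"]["otu_samples_missing_chem"] = orphans
        if orphans:
            report["ok"] = False
    return report
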