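"""Forward generators for every pipeline input.

Emulates the field design: bubble-trap flux records per lake zone following a
zone-specific Arrhenius law with lognormal noise, four sediment cores with
porewater chemistry produced by the forward isotope mass-balance model,
a 16S OTU table with zone-enriched CH4-cycling guilds on a depth gradient,
and a qPCR plate (standard dilution series + sample Cts) for absolute
abundances.

A per-(core, depth) latent "methanogenic activity" factor — its own random
stream — scales both the methanogen/syntroph guild means in the community and
the methanogenic DIC fraction in the chemistry, so microbial abundances carry
information about porewater CH4 beyond what the abiotic depth profiles hold,
as the field data suggest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import OtuTable
from .config import ConfigError, SyntheticConfig

__all__ = [
    "generate_flux_records",
    "generate_core_chemistry",
    "generate_otu_table",
    "generate_qpcr_plate",
    "methanogenic_activity",
    "sample_id",
]


def sample_id(lake: str, zone: str, depth_cm) -> str:
    """Sample naming convention: lake code + E/M + depth, e.g. ``MHE4``."""
    return f"{lake}{'E' if zone == 'edge' else 'M'}{int(depth_cm)}"


# ----------------------------------------------------------------------
# flux records
# ----------------------------------------------------------------------

def generate_flux_records(cfg: SyntheticConfig) -> pd.DataFrame:
    """Bubble-trap flux records: columns trap_id, lake, zone, date, temp_C, flux.

    Temperatures are uniform on the zone's range; flux follows the zone's
    Arrhenius law, ``exp(lnA + slope / T_K)``, times multiplicative lognormal
    noise (ebullition is strongly right-skewed).
    """
    rng = cfg.rng("flux")
    start = pd.Timestamp("2009-06-01")
    rows = []
    for lake in cfg.lakes:
        for zone in cfg.zones:
            lo, hi = cfg.temp_range_C[zone]
            slope = cfg.arrhenius_slope_K[zone]
            lnA = cfg.arrhenius_lnA[zone]
            for trap in range(cfg.traps_per_zone):
                trap_id = f"{lake}-{zone}-T{trap + 1}"
                temps = rng.uniform(lo, hi, size=cfg.n_flux_obs)
                noise = (
                    rng.normal(0.0, cfg.flux_noise_sdlog, size=cfg.n_flux_obs)
                    if cfg.flux_noise_sdlog > 0
                    else np.zeros(cfg.n_flux_obs)
                )
                flux = np.exp(lnA + slope / (temps + 273.15) + noise)
                dates = start + pd.to_timedelta(
                    rng.integers(0, 6 * 120, size=cfg.n_flux_obs), unit="D"
                )
                for d, t, f in zip(dates, temps, flux):
                    rows.append((trap_id, lake, zone, d, t, f))
    return pd.DataFrame(
        rows, columns=["trap_id", "lake", "zone", "date", "temp_C", "flux"]
    )


# ----------------------------------------------------------------------
# shared latent activity
# ----------------------------------------------------------------------

def methanogenic_activity(cfg: SyntheticConfig) -> pd.Series:
    """Latent lognormal activity factor per (lake, zone, depth) on the grid."""
    rng = cfg.rng("activity")
    idx = []
    for lake in cfg.lakes:
        for zone in cfg.zones:
            for d in cfg.depth_grid_cm:
                idx.append(sample_id(lake, zone, d))
    if cfg.activity_sdlog > 0:
        vals = np.exp(rng.normal(0.0, cfg.activity_sdlog, size=len(idx)))
    else:
        vals = np.ones(len(idx))
    return pd.Series(vals, index=idx, name="activity")


# ----------------------------------------------------------------------
# core chemistry
# ----------------------------------------------------------------------

def generate_core_chemistry(cfg: SyntheticConfig) -> pd.DataFrame:
    """Depth-resolved porewater/solid-phase chemistry for the four cores.

    The isotope triplet is produced by the forward mass-balance model:
    d13C_CH4 from the configured fractionation factor, the methanogenic CO2
    endmember by 1:1 mass balance, and d13C_DIC as the f-weighted mix of that
    endmember with unfractionated substrate carbon.  Measured porewater CH4 is
    the retained fraction of generated CH4 (f * DIC).  Gaussian noise with sd
    ``isotope_noise_sd`` is added to d13C_CH4 and d13C_DIC after the forward
    computation; the true per-row methanogenic fraction is kept in
    ``f_meth_true`` for validation.
    """
    rng = cfg.rng("chemistry")
    activity = methanogenic_activity(cfg)
    depths = np.asarray(cfg.depth_grid_cm, dtype=float)
    dic = cfg.DIC_uM_profile()
    rows = []
    for lake in cfg.lakes:
        for zone in cfg.zones:
            core = f"{lake}-{zone}"
            f_prof = cfg.f_meth_profile(zone)
            toc_base = 8.0 if zone == "edge" else 12.0
            for i, depth in enumerate(depths):
                sid = sample_id(lake, zone, depth)
                f = float(np.clip(f_prof[i] * activity[sid], 0.0, 1.0))
                d_toc = cfg.d13C_TOC_permil + rng.normal(0.0, 0.3)
                d_ch4 = (d_toc + 1000.0) / cfg.alpha_true - 1000.0
                d_co2meth = 2.0 * d_toc - d_ch4
                d_dic = f * d_co2meth + (1.0 - f) * d_toc
                if cfg.isotope_noise_sd > 0:
                    d_ch4 += rng.normal(0.0, cfg.isotope_noise_sd)
                    d_dic += rng.normal(0.0, cfg.isotope_noise_sd)
                else:
                    rng.normal(size=2)  # keep stream alignment across noise settings
                dic_i = dic[i] * (
                    np.exp(rng.normal(0.0, cfg.DIC_noise_sdlog))
                    if cfg.DIC_noise_sdlog > 0
                    else 1.0
                )
                ch4 = cfg.measured_CH4_fraction * f * dic_i
                toc = max(toc_base - 0.05 * depth + rng.normal(0.0, 0.5), 0.5)
                s_pct = max(0.4 + rng.normal(0.0, 0.05), 0.05)
                rows.append(
                    (
                        sid, core, lake, zone, depth, toc, d_toc, ch4, dic_i,
                        d_ch4, d_dic, s_pct, toc / s_pct, f,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "sample", "core", "lake", "zone", "depth_cm", "TOC_pct", "d13C_TOC",
            "CH4_uM", "DIC_uM", "d13C_CH4", "d13C_DIC", "S_pct", "TOC_TS",
            "f_meth_true",
        ],
    ).set_index("sample")
    return df


# ----------------------------------------------------------------------
# OTU table
# ----------------------------------------------------------------------

_METHANOGEN_LINEAGES = [
    "Archaea;Euryarchaeota;Methanomicrobia;Methanomicrobiales;Methanoregulaceae;Methanoregula",
    "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;Methanosaetaceae;Methanosaeta",
    "Archaea;Euryarchaeota;Methanobacteria;Methanobacteriales;Methanobacteriaceae;Methanobacterium",
    "Archaea;Euryarchaeota;Methanomicrobia;Methanocellales;Methanocellaceae;Methanocella",
]
_ANME_LINEAGE = "Archaea;Euryarchaeota;Methanomicrobia;ANME-1;ANME-1a;unclassified"
_METHANOTROPH_LINEAGE = (
    "Bacteria;Proteobacteria;Gammaproteobacteria;Methylococcales;Methylococcaceae;Methylobacter"
)
_SYNTROPH_LINEAGE = (
    "Bacteria;Proteobacteria;Deltaproteobacteria;Syntrophobacterales;Syntrophaceae;Syntrophus"
)
_BACKGROUND_LINEAGES = [
    "Bacteria;Chloroflexi;Anaerolineae;Anaerolineales;Anaerolineaceae",
    "Bacteria;Bacteroidetes;Bacteroidia;Bacteroidales;Porphyromonadaceae",
    "Bacteria;Acidobacteria;Holophagae;Holophagales;Holophagaceae",
    "Bacteria;Planctomycetes;Phycisphaerae;Phycisphaerales;Phycisphaeraceae",
    "Bacteria;Aminicenantes;Aminicenantia;Aminicenantales;unclassified",
    "Archaea;Euryarchaeota;Thermoplasmata;Thermoplasmatales;unclassified",
    "Bacteria;Verrucomicrobia;Verrucomicrobiae;Verrucomicrobiales;Verrucomicrobiaceae",
    "Bacteria;Actinobacteria;Actinobacteria;Actinomycetales;unclassified",
    "Bacteria;Firmicutes;Clostridia;Clostridiales;Ruminococcaceae",
    "Bacteria;Nitrospirae;Nitrospira;Nitrospirales;Nitrospiraceae",
    "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales;Desulfobacteraceae",
    "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Comamonadaceae",
]

_GUILD_SIZES = {
    "methanogen": 8,
    "ANME": 3,
    "aerobic_methanotroph": 4,
    "syntrophaceae": 5,
}


def _otu_taxonomy(cfg: SyntheticConfig) -> tuple[pd.Series, dict]:
    """Deterministic OTU id -> lineage assignment plus guild membership."""
    n_guild = sum(_GUILD_SIZES.values())
    if cfg.n_otus < n_guild + 1:
        raise ConfigError(f"n_otus must exceed {n_guild} (guild OTUs)")
    tax, members, k = {}, {g: [] for g in _GUILD_SIZES}, 0
    for g, size in _GUILD_SIZES.items():
        for j in range(size):
            otu = f"OTU{k + 1}"
            if g == "methanogen":
                tax[otu] = _METHANOGEN_LINEAGES[j % len(_METHANOGEN_LINEAGES)]
            elif g == "ANME":
                tax[otu] = _ANME_LINEAGE
            elif g == "aerobic_methanotroph":
                tax[otu] = _METHANOTROPH_LINEAGE
            else:
                tax[otu] = _SYNTROPH_LINEAGE
            members[g].append(otu)
            k += 1
    for j in range(cfg.n_otus - n_guild):
        otu = f"OTU{k + 1}"
        base = _BACKGROUND_LINEAGES[j % len(_BACKGROUND_LINEAGES)]
        tax[otu] = f"{base};genus{j + 1}"
        k += 1
    return pd.Series(tax, name="taxonomy"), members


def generate_otu_table(cfg: SyntheticConfig) -> OtuTable:
    """Dirichlet-multinomial OTU counts with guild, zone, and depth structure.

    Mean composition per sample: guild blocks hit their per-zone target
    fractions (methanogens and syntrophs scaled by the shared latent activity;
    aerobic methanotrophs present only above ``methanotroph_max_depth_cm``),
    and background OTUs carry lognormal zone effects plus log-linear depth
    gradients.  Counts sum to ``library_size`` in every sample.
    """
    taxonomy, members = _otu_taxonomy(cfg)
    rng = cfg.rng("otu")
    activity = methanogenic_activity(cfg)
    otus = list(taxonomy.index)
    n = len(otus)
    guild_otus = {o for mm in members.values() for o in mm}
    background = [o for o in otus if o not in guild_otus]

    base = rng.normal(0.0, 1.5, size=len(background))
    zone_eff = rng.normal(0.0, cfg.zone_effect_sdlog, size=len(background))
    depth_eff = rng.normal(0.0, cfg.depth_effect_sdlog, size=len(background))
    within = {
        g: np.exp(rng.normal(0.0, 1.0, size=len(mm))) for g, mm in members.items()
    }
    within = {g: w / w.sum() for g, w in within.items()}

    meta_rows, count_rows, ids = [], [], []
    for (lake, zone), depths in cfg.core_depths_cm.items():
        if lake not in cfg.lakes:
            continue
        for depth in depths:
            sid = sample_id(lake, zone, depth)
            act = activity[sid]
            targets = {}
            for g, per_zone in cfg.guild_fractions.items():
                q = per_zone[zone]
                if g in ("methanogen", "syntrophaceae"):
                    q *= act
                if g == "aerobic_methanotroph" and depth > cfg.methanotroph_max_depth_cm:
                    q = 0.0
                targets[g] = q
            total_guild = sum(targets.values())
            if total_guild >= 0.5:  # keep background dominant
                targets = {g: q * 0.5 / total_guild for g, q in targets.items()}
                total_guild = 0.5
            w = np.exp(
                base
                + (zone_eff if zone == "middle" else 0.0)
                + depth_eff * depth
            )
            mean = pd.Series(0.0, index=otus)
            mean[background] = w / w.sum() * (1.0 - total_guild)
            for g, mm in members.items():
                mean[mm] = targets[g] * within[g]
            p = mean.to_numpy()
            p = p / p.sum()
            if cfg.overdispersion > 0:
                # alpha_i = p_i / theta, so 1/theta is the total concentration
                p = rng.dirichlet(p / cfg.overdispersion)
            counts = rng.multinomial(cfg.library_size, p)
            ids.append(sid)
            count_rows.append(counts)
            meta_rows.append((f"{lake}-{zone}", lake, zone, float(depth)))
    counts = pd.DataFrame(count_rows, index=ids, columns=otus)
    meta = pd.DataFrame(
        meta_rows, index=ids, columns=["core", "lake", "zone", "depth_cm"]
    )
    return OtuTable(counts, taxonomy, meta)


# ----------------------------------------------------------------------
# qPCR plate
# ----------------------------------------------------------------------

def generate_qpcr_plate(cfg: SyntheticConfig):
    """Standard dilution series and sample Cts for total 16S quantification.

    Returns ``(standards, samples)``.  Standards follow a log-linear Ct vs
    log10(copies/uL) curve at the configured amplification efficiency
    (slope = -1/log10(1+E); 3.32 cycles per decade at 100%).  Sample Cts are
    back-computed from true copies/g declining log-linearly with depth
    (``qpcr_decay`` log10 units per cm), recorded in ``true_copies_per_g``.
    """
    from .community import QpcrStandard

    if cfg.qpcr_efficiency <= 0:
        raise ConfigError("qPCR efficiency must be positive")
    rng = cfg.rng("qpcr")
    std = QpcrStandard()
    slope = -1.0 / np.log10(1.0 + cfg.qpcr_efficiency)

    srows = []
    for dil in std.dilutions:
        copies = std.copies_per_uL(dil)
        for rep in range(3):
            ct = cfg.qpcr_intercept_ct + slope * np.log10(copies)
            if cfg.qpcr_noise_sd_ct > 0:
                ct += rng.normal(0.0, cfg.qpcr_noise_sd_ct)
            srows.append((dil, rep + 1, copies, ct))
    standards = pd.DataFrame(
        srows, columns=["dilution", "replicate", "copies_per_uL", "ct"]
    )

    sediment_g, elution_uL, template_dilution = 0.25, 100.0, 100.0
    qrows = []
    for (lake, zone), depths in cfg.core_depths_cm.items():
        if lake not in cfg.lakes:
            continue
        for depth in depths:
            sid = sample_id(lake, zone, depth)
            true = 10.0 ** (
                np.log10(cfg.qpcr_surface_copies_per_g) - cfg.qpcr_decay * depth
            )
            per_uL = true * sediment_g / elution_uL / template_dilution
            ct = cfg.qpcr_intercept_ct + slope * np.log10(per_uL)
            if cfg.qpcr_noise_sd_ct > 0:
                ct += rng.normal(0.0, cfg.qpcr_noise_sd_ct)
            qrows.append(
                (
                    sid, f"{lake}-{zone}", lake, zone, float(depth), ct,
                    template_dilution, sediment_g, elution_uL, true,
                )
            )
    samples = pd.DataFrame(
        qrows,
        columns=[
            "sample", "core", "lake", "zone", "depth_cm", "ct",
            "template_dilution", "sediment_g", "elution_uL", "true_copies_per_g",
        ],
    )
    return standards, samples
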