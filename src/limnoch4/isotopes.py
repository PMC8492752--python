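"""Stable carbon isotope mass balance for depth-resolved "fugitive" methane.

The model: fermentation and respiration generate CO2 without fractionating
carbon, while methanogenesis converts substrate carbon into CH4 and CO2 (1:1)
with a strong fractionation.  CO2/DIC stays dissolved in porewater whereas
most CH4 escapes (dominantly by ebullition).  Starting from the measured
delta13C of sedimentary organic carbon (the substrate), porewater CH4 and DIC:

* alpha   = (d13C_substrate + 1000) / (d13C_CH4 + 1000) — the fractionation
  factor of methanogenesis;
* by 1:1 mass balance the methanogenic CO2 endmember sits at
  d13C_CO2meth = 2*d13C_TOC - d13C_CH4;
* the fraction of DIC derived from methanogenesis is the two-endmember mixing
  coordinate f = (d13C_DIC - d13C_TOC) / (d13C_CO2meth - d13C_TOC);
* generated CH4 = f * DIC (one CH4 per methanogenic CO2), and the excess of
  generated over measured porewater CH4 is the fugitive CH4 lost from that
  depth.  The system is assumed to be at steady state.

The apparent fractionation alphaC between DIC and CH4 classifies the dominant
methanogenic pathway: hydrogenotrophic methanogenesis fractionates more
strongly (larger alphaC) than acetoclastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

R_GAS = 8.314  # J mol-1 K-1

# classical genetic-zonation convention; configurable in apparent_alpha_c
ALPHA_C_HYDROGENOTROPHIC = 1.065
ALPHA_C_ACETOCLASTIC = 1.055


class IsotopeError(ValueError):
    pass


def fractionation_factor(d13C_substrate, d13C_CH4):
    """alpha = (d_substrate + 1000) / (d_CH4 + 1000).

    Accepts scalars or arrays (permil VPDB).  Raises on non-physical input
    that would make alpha non-positive.
    """
    num = np.asarray(d13C_substrate, dtype=float) + 1000.0
    den = np.asarray(d13C_CH4, dtype=float) + 1000.0
    if np.any(den == 0):
        raise IsotopeError("d13C_CH4 = -1000 permil is undefined")
    alpha = num / den
    if np.any(alpha <= 0):
        raise IsotopeError("non-positive fractionation factor (bad delta values)")
    return alpha if alpha.ndim else float(alpha)


def apparent_alpha_c(
    d13C_DIC,
    d13C_CH4,
    hydrogenotrophic_min: float = ALPHA_C_HYDROGENOTROPHIC,
    acetoclastic_max: float = ALPHA_C_ACETOCLASTIC,
):
    """Apparent fractionation alphaC between DIC and CH4, with pathway call.

    Returns ``(alphaC, pathway)`` where pathway is ``"hydrogenotrophic"`` for
    alphaC >= ``hydrogenotrophic_min``, ``"acetoclastic"`` for
    alphaC <= ``acetoclastic_max``, else ``"intermediate"``.
    """
    alpha_c = fractionation_factor(d13C_DIC, d13C_CH4)
    a = np.atleast_1d(np.asarray(alpha_c, dtype=float))
    pathway = np.where(
        a >= hydrogenotrophic_min,
        "hydrogenotrophic",
        np.where(a <= acetoclastic_max, "acetoclastic", "intermediate"),
    )
    if np.isscalar(alpha_c) or np.ndim(alpha_c) == 0:
        return float(a[0]), str(pathway[0])
    return a, pathway


@dataclass
class FugitiveResult:
    depth_cm: float
    alpha: float
    alphaC: float
    f_meth: float            # clipped to [0, 1]
    f_meth_raw: float        # unclipped mixing coordinate
    generated_CH4_uM: float
    fugitive_CH4_uM: float
    pathway: str
    flags: set = field(default_factory=set)


REQUIRED_CHEM = ("depth_cm", "d13C_TOC", "d13C_CH4", "d13C_DIC", "CH4_uM", "DIC_uM")


def fugitive_ch4(sample) -> FugitiveResult:
    """Fugitive-CH4 mass balance for one core depth.

    ``sample`` is any mapping (dict, pandas Series, dataclass with the same
    attribute names) carrying the fields in :data:`REQUIRED_CHEM`.
    """
    get = (lambda k: sample[k]) if hasattr(sample, "__getitem__") else (
        lambda k: getattr(sample, k)
    )
    vals = {k: float(get(k)) for k in REQUIRED_CHEM}
    flags: set = set()

    d_toc, d_ch4, d_dic = vals["d13C_TOC"], vals["d13C_CH4"], vals["d13C_DIC"]
    alpha = fractionation_factor(d_toc, d_ch4)
    alpha_c, pathway = apparent_alpha_c(d_dic, d_ch4)

    d_co2meth = 2.0 * d_toc - d_ch4
    denom = d_co2meth - d_toc  # = d_toc - d_ch4
    if denom == 0:
        flags.add("undefined_f")
        return FugitiveResult(
            vals["depth_cm"], alpha, alpha_c, float("nan"), float("nan"),
            float("nan"), float("nan"), pathway, flags,
        )
    f_raw = (d_dic - d_toc) / denom
    f = float(np.clip(f_raw, 0.0, 1.0))
    if f != f_raw:
        flags.add("f_clipped")
    generated = f * vals["DIC_uM"]
    fugitive = generated - vals["CH4_uM"]
    if fugitive < 0:
        flags.add("negative_fugitive")
    return FugitiveResult(
        vals["depth_cm"], float(alpha), float(alpha_c), f, float(f_raw),
        float(generated), float(fugitive), pathway, flags,
    )


def fugitive_profile(chem: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`fugitive_ch4` over a chemistry table (one row/depth)."""
    results = [fugitive_ch4(row) for _, row in chem.iterrows()]
    out = pd.DataFrame(
        {
            "depth_cm": [r.depth_cm for r in results],
            "alpha": [r.alpha for r in results],
            "alphaC": [r.alphaC for r in results],
            "f_meth": [r.f_meth for r in results],
            "f_meth_raw": [r.f_meth_raw for r in results],
            "generated_CH4_uM": [r.generated_CH4_uM for r in results],
            "fugitive_CH4_uM": [r.fugitive_CH4_uM for r in results],
            "pathway": [r.pathway for r in results],
            "flags": [";".join(sorted(r.flags)) for r in results],
        },
        index=chem.index,
    )
    for col in ("core", "lake", "zone"):
        if col in chem.columns:
            out[col] = chem[col]
    return out


def headspace_to_concentration(
    ppm: float,
    headspace_mL: float,
    temp_C: float,
    pressure_kPa: float = 101.325,
    water_mass_g: float = 1.0,
) -> float:
    """Headspace CH4 mixing ratio (ppm) to porewater concentration (uM).

    Ideal-gas moles in the headspace divided by the water volume of the
    sediment plug; the NaOH-trap protocol drives essentially all CH4 into the
    headspace, so no Henry's-law partitioning is applied.
    """
    if headspace_mL <= 0 or water_mass_g <= 0 or pressure_kPa <= 0:
        raise IsotopeError("volumes, mass, and pressure must be positive")
    if ppm < 0:
        raise IsotopeError("negative mixing ratio")
    t_K = temp_C + 273.15
    moles = ppm * 1e-6 * pressure_kPa * 1e3 * headspace_mL * 1e-6 / (R_GAS * t_K)
    water_L = water_mass_g / 1000.0
    return moles / water_L * 1e6  # umol per litre


def correlate_fugitive_with_microbes(
    fugitive: pd.Series,
    community_dm: pd.DataFrame,
    lineage_abundances: pd.DataFrame | None = None,
    n_perm: int = 999,
    seed: int | None = 0,
):
    """Relate fugitive CH4 to community structure and individual lineages.

    ``fugitive`` is a per-sample Series; ``community_dm`` a Bray-Curtis matrix
    over (at least) the same samples.  Runs a Mantel test against the Euclidean
    distance matrix of fugitive CH4, plus per-lineage OLS regressions of
    relative abundance on fugitive CH4 when ``lineage_abundances`` is given.
    Returns ``(MantelResult, DataFrame | None)``.
    """
    from scipy import stats as _st

    from .multivariate import mantel

    shared = [s for s in community_dm.index if s in fugitive.index]
    if len(shared) < 4:
        raise IsotopeError("need at least four matched samples")
    f = fugitive.loc[shared].to_numpy(dtype=float)
    dmA = community_dm.loc[shared, shared]
    dmB = pd.DataFrame(
        np.abs(f[:, None] - f[None, :]), index=shared, columns=shared
    )
    mres = mantel(dmA, dmB, method="spearman", n_perm=n_perm, seed=seed)

    lin = None
    if lineage_abundances is not None:
        rows = []
        la = lineage_abundances.loc[shared]
        for col in la.columns:
            y = la[col].to_numpy(dtype=float)
            if np.ptp(y) == 0 or np.ptp(f) == 0:
                rows.append((col, float("nan"), float("nan"), float("nan")))
                continue
            res = _st.linregress(f, y)
            rows.append((col, res.slope, res.rvalue**2, res.pvalue))
        lin = pd.DataFrame(rows, columns=["lineage", "slope", "r2", "p"]).set_index(
            "lineage"
        )
    return mres, lin
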