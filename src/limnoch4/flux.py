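"""Temperature sensitivity of ebullitive CH4 flux, and incubation rates.

Bubble-trap flux records are binned in fixed-width surface-sediment
temperature intervals per (lake, zone) group; binned means feed a 2nd-degree
polynomial fit (flux vs temperature) and an Arrhenius regression
(ln flux vs 1/T_K).  Homogeneity of regression between groups is tested with
a pairwise interaction model, optionally on robustness subsets of the binned
points.  Incubation rates come from the OLS slope of headspace CH4 against
time, normalised by sediment dry mass.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

R_GAS = 8.314  # J mol-1 K-1

SUBSETS = ("full", "edge_trimmed", "drop_top_middle_bin", "drop_bottom_middle_bin")


class FluxError(ValueError):
    pass


# ----------------------------------------------------------------------
# binning
# ----------------------------------------------------------------------

def bin_flux(
    records: pd.DataFrame, width_C: float = 1.0, group_cols=("lake", "zone")
) -> pd.DataFrame:
    """Bin flux records into half-open temperature intervals per group.

    Bins are integer-anchored, ``[k*width, (k+1)*width)``, with centers at
    ``(k + 0.5) * width``.  Returns one row per non-empty (group, bin) with
    the record count, mean flux, and a Student-t 95% confidence interval on
    the mean; single-record bins get a degenerate (NaN) interval and a flag.
    """
    if width_C <= 0:
        raise FluxError("bin width must be positive")
    if len(records) == 0:
        raise FluxError("no flux records")
    df = records.copy()
    idx = np.floor(df["temp_C"].to_numpy(dtype=float) / width_C).astype(int)
    df["bin_center_C"] = (idx + 0.5) * width_C
    rows = []
    for key, grp in df.groupby(list(group_cols) + ["bin_center_C"], sort=True):
        *gvals, center = key
        flux = grp["flux"].to_numpy(dtype=float)
        n = len(flux)
        mean = flux.mean()
        if n > 1:
            se = flux.std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.975, n - 1)
            lo, hi = mean - tcrit * se, mean + tcrit * se
            degenerate = False
        else:
            lo = hi = float("nan")
            degenerate = True
        rows.append((*gvals, center, n, mean, lo, hi, degenerate))
    return pd.DataFrame(
        rows,
        columns=list(group_cols)
        + ["bin_center_C", "n", "mean_flux", "ci_low", "ci_high", "degenerate"],
    )


# ----------------------------------------------------------------------
# polynomial and Arrhenius fits on binned means
# ----------------------------------------------------------------------

@dataclass
class PolynomialFit:
    coefficients: np.ndarray  # highest degree first (numpy.polyfit order)
    r2: float
    degree: int


def fit_polynomial(bins: pd.DataFrame, degree: int = 2) -> PolynomialFit:
    """Unweighted OLS of binned mean flux on powers of bin-center temperature."""
    x = bins["bin_center_C"].to_numpy(dtype=float)
    y = bins["mean_flux"].to_numpy(dtype=float)
    if len(x) < degree + 1:
        raise FluxError(f"need at least {degree + 1} bins for degree {degree}")
    coef = np.polyfit(x, y, degree)
    fitted = np.polyval(coef, x)
    ss_res = ((y - fitted) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PolynomialFit(coef, float(r2), degree)


@dataclass
class ArrheniusFit:
    group: tuple
    slope: float             # K, coefficient on 1/T_K
    intercept: float         # ln(mg m-2 d-1)
    se_slope: float
    r2: float
    n_bins: int

    @property
    def apparent_Ea_kJ_mol(self) -> float:
        """Apparent activation energy, -slope * R, in kJ/mol."""
        return -self.slope * R_GAS / 1000.0


def _arrhenius_xy(bins: pd.DataFrame, weighted: bool):
    ok = bins["mean_flux"] > 0
    if (~ok).any():
        warnings.warn(f"dropping {(~ok).sum()} bin(s) with non-positive mean flux")
    b = bins[ok]
    inv_T = 1.0 / (b["bin_center_C"].to_numpy(dtype=float) + 273.15)
    ln_f = np.log(b["mean_flux"].to_numpy(dtype=float))
    w = b["n"].to_numpy(dtype=float) if weighted else None
    return inv_T, ln_f, w


def fit_arrhenius(
    bins: pd.DataFrame, group: tuple = (), weighted: bool = False
) -> ArrheniusFit:
    """OLS of ln(binned mean flux) on inverse absolute temperature.

    Bins with non-positive mean flux are dropped with a warning; fewer than
    three usable bins is an error.  ``weighted=True`` weights by the record
    count per bin (the default follows the binned-means convention).
    """
    inv_T, ln_f, w = _arrhenius_xy(bins, weighted)
    if len(inv_T) < 3:
        raise FluxError("need at least three bins with positive mean flux")
    W = np.ones_like(inv_T) if w is None else w
    X = np.column_stack([np.ones_like(inv_T), inv_T])
    WX = X * W[:, None]
    beta = np.linalg.solve(X.T @ WX, WX.T @ ln_f)
    fitted = X @ beta
    resid = ln_f - fitted
    dof = len(inv_T) - 2
    s2 = (W * resid**2).sum() / dof
    cov = s2 * np.linalg.inv(X.T @ WX)
    ybar = (W * ln_f).sum() / W.sum()
    ss_tot = (W * (ln_f - ybar) ** 2).sum()
    ss_res = (W * resid**2).sum()
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ArrheniusFit(
        tuple(group), float(beta[1]), float(beta[0]),
        float(np.sqrt(cov[1, 1])), float(r2), int(len(inv_T)),
    )


# ----------------------------------------------------------------------
# homogeneity of regression (pairwise interaction tests)
# ----------------------------------------------------------------------

@dataclass
class SlopeComparison:
    pair: tuple
    subset: str
    interaction_p: float
    interaction_F: float
    significant: bool
    slopes: dict
    n_points: int


def _apply_subset(bins_a, bins_b, zone_a, zone_b, subset):
    """Robustness subsets defined on the binned points of an edge/middle pair."""
    if subset == "full":
        return bins_a, bins_b
    pair = {zone_a: bins_a, zone_b: bins_b}
    if "middle" not in pair or "edge" not in pair:
        return bins_a, bins_b  # subsets are defined for edge-vs-middle pairs
    edge, middle = pair["edge"].copy(), pair["middle"].copy()
    if subset == "edge_trimmed":
        edge = edge[edge["bin_center_C"] <= middle["bin_center_C"].max()]
    elif subset == "drop_top_middle_bin":
        middle = middle[middle["bin_center_C"] < middle["bin_center_C"].max()]
    elif subset == "drop_bottom_middle_bin":
        middle = middle[middle["bin_center_C"] > middle["bin_center_C"].min()]
    else:
        raise FluxError(f"unknown subset {subset!r}")
    out = {"edge": edge, "middle": middle}
    return out[zone_a], out[zone_b]


def compare_slopes(
    bins_by_group: dict,
    subset: str = "full",
    alpha: float = 0.05,
) -> list[SlopeComparison]:
    """Pairwise homogeneity-of-regression tests between Arrhenius lines.

    ``bins_by_group`` maps (lake, zone) -> binned DataFrame.  For every pair,
    ln(mean flux) is regressed on group, 1/T_K, and their interaction over the
    pooled binned points; the reported p-value is the F-test of the
    interaction term (equivalently the squared-t test, as each comparison is
    pairwise).  Robustness subsets drop bins as named; a pair whose group
    falls below three bins is skipped with a warning.
    """
    comparisons: list[SlopeComparison] = []
    for (ga, bins_a), (gb, bins_b) in itertools.combinations(
        sorted(bins_by_group.items()), 2
    ):
        sa, sb = _apply_subset(bins_a, bins_b, ga[-1], gb[-1], subset)
        if len(sa) < 3 or len(sb) < 3:
            warnings.warn(f"skipping {ga} vs {gb} ({subset}): <3 bins after subset")
            continue
        frames = []
        for g, b in ((ga, sa), (gb, sb)):
            ok = b["mean_flux"] > 0
            inv_T = 1.0 / (b.loc[ok, "bin_center_C"].to_numpy(dtype=float) + 273.15)
            ln_f = np.log(b.loc[ok, "mean_flux"].to_numpy(dtype=float))
            frames.append(pd.DataFrame({"inv_T": inv_T, "ln_f": ln_f, "grp": [g] * len(inv_T)}))
        pooled = pd.concat(frames, ignore_index=True)
        g_ind = (pooled["grp"] == gb).to_numpy(dtype=float)
        x = pooled["inv_T"].to_numpy()
        X = np.column_stack([np.ones(len(pooled)), g_ind, x, g_ind * x])
        y = pooled["ln_f"].to_numpy()
        n, p = X.shape
        if n <= p:
            warnings.warn(f"skipping {ga} vs {gb} ({subset}): underdetermined")
            continue
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        s2 = (resid**2).sum() / (n - p)
        cov = s2 * np.linalg.inv(X.T @ X)
        t_int = beta[3] / np.sqrt(cov[3, 3])
        F = t_int**2
        p_int = float(stats.f.sf(F, 1, n - p))
        slopes = {ga: float(beta[2]), gb: float(beta[2] + beta[3])}
        comparisons.append(
            SlopeComparison(
                (ga, gb), subset, p_int, float(F), p_int < alpha, slopes, n
            )
        )
    return comparisons


# ----------------------------------------------------------------------
# incubations
# ----------------------------------------------------------------------

@dataclass
class IncubationRate:
    rate: float              # amount CH4 per g dry sediment per day
    r2: float
    negative: bool


def incubation_rate(times_d, headspace_CH4, dry_mass_g: float) -> IncubationRate:
    """OLS slope of headspace CH4 amount vs time, per gram dry sediment.

    Negative slopes (net consumption or leakage) are returned as-is, flagged.
    """
    t = np.asarray(times_d, dtype=float)
    y = np.asarray(headspace_CH4, dtype=float)
    if dry_mass_g <= 0:
        raise FluxError("dry mass must be positive")
    if len(t) < 2 or np.any(np.diff(t) <= 0):
        raise FluxError("need >=2 strictly increasing timepoints")
    res = stats.linregress(t, y)
    rate = res.slope / dry_mass_g
    r2 = float(res.rvalue**2) if np.ptp(y) > 0 else 1.0
    return IncubationRate(float(rate), r2, rate < 0)


def incubation_anova(rates, groups) -> tuple[float, float]:
    """One-way ANOVA on incubation rates across groups (e.g. edge vs middle)."""
    rates = pd.Series(list(rates))
    groups = pd.Series(list(groups))
    samples = [rates[groups == g].to_numpy() for g in groups.unique()]
    F, p = stats.f_oneway(*samples)
    return float(F), float(p)
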