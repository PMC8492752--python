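"""Predicting porewater CH4 from abiotic variables and microbial abundances.

The estimator of record is :class:`PLSRegressionVIP`, a NIPALS partial least
squares regression (single response) with variance-in-projection (VIP)
importance scores, written as a scikit-learn estimator (``fit``/``predict``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so it
composes with sklearn model selection.  A multiple-linear-regression
counterpart wraps statsmodels OLS behind the same surface.  Module-level
functions assemble the explanatory-variable matrix (abiotic block + OTUs above
1% relative abundance + lineage sums + guild sums + MAG-lineage proxies) and
compare variable suites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

ABIOTIC_VARS = ("depth", "TOC", "d13C_TOC", "DIC", "S", "TOC_TS")


class ModelError(ValueError):
    pass


# ----------------------------------------------------------------------
# PLSR with VIP
# ----------------------------------------------------------------------

class PLSRegressionVIP(BaseEstimator, RegressorMixin):
    """NIPALS partial least squares regression with VIP scores.

    Parameters
    ----------
    n_components : int or "auto"
        Number of latent components.  ``"auto"`` selects the leave-one-out
        minimum-PRESS model (ties broken toward fewer components).
    scale : bool
        Autoscale columns to unit variance (columns are always centered).
    max_components : int or None
        Upper bound for the "auto" search (default: min(n-1, p, 10)).

    Fitted attributes
    -----------------
    ``x_weights_`` (p x A), ``x_scores_`` (n x A), ``x_loadings_`` (p x A),
    ``y_loadings_`` (A,), ``coef_`` (p,) on the original variable scale,
    ``vip_`` per-variable VIP scores (mean squared VIP = 1),
    ``r2_`` squared Pearson correlation of fitted vs observed response,
    ``press_`` the LOO PRESS per candidate component count (auto mode).
    """

    def __init__(self, n_components="auto", scale: bool = True, max_components=None):
        self.n_components = n_components
        self.scale = scale
        self.max_components = max_components

    # -- internals ------------------------------------------------------
    @staticmethod
    def _nipals(X: np.ndarray, y: np.ndarray, A: int):
        n, p = X.shape
        W = np.zeros((p, A))
        T = np.zeros((n, A))
        P = np.zeros((p, A))
        q = np.zeros(A)
        Xa, ya = X.copy(), y.copy()
        used = 0
        for a in range(A):
            w = Xa.T @ ya
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                break
            w /= norm
            t = Xa @ w
            tt = t @ t
            if tt < 1e-12:
                break
            pvec = Xa.T @ t / tt
            qa = ya @ t / tt
            Xa = Xa - np.outer(t, pvec)
            ya = ya - t * qa
            W[:, a], T[:, a], P[:, a], q[a] = w, t, pvec, qa
            used += 1
        return W[:, :used], T[:, :used], P[:, :used], q[:used]

    @staticmethod
    def _coef(W, P, q):
        # beta for scaled X, centered y:  B = W (P'W)^{-1} q
        A = W.shape[1]
        if A == 0:
            return np.zeros(W.shape[0])
        return W @ np.linalg.solve(P.T @ W, q)

    def _prepare(self, X):
        X = pd.DataFrame(X)
        var = X.var(axis=0, ddof=0)
        drop = var[var == 0].index
        if len(drop):
            warnings.warn(f"dropping zero-variance columns: {list(drop)}")
            X = X.drop(columns=drop)
        if X.shape[1] == 0:
            raise ModelError("no variables left after dropping constants")
        return X

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y):
        Xdf = self._prepare(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = Xdf.shape
        if n != len(y):
            raise ModelError("X and y lengths differ")
        if n < 5:
            raise ModelError("need at least five samples")
        self.feature_names_in_ = np.asarray(Xdf.columns, dtype=object)
        Xm = Xdf.to_numpy(dtype=float)
        self.x_mean_ = Xm.mean(axis=0)
        self.x_std_ = Xm.std(axis=0, ddof=1) if self.scale else np.ones(p)
        Z = (Xm - self.x_mean_) / self.x_std_
        self.y_mean_ = y.mean()
        yc = y - self.y_mean_

        a_max = self.max_components or min(n - 1, p, 10)
        a_max = int(min(a_max, n - 1, p))
        if self.n_components == "auto":
            press = np.full(a_max, np.inf)
            for A in range(1, a_max + 1):
                sq = 0.0
                for i in range(n):
                    mask = np.ones(n, dtype=bool)
                    mask[i] = False
                    Zi, yi = Z[mask], yc[mask]
                    mu, sd = Zi.mean(axis=0), 1.0
                    W, T, P, q = self._nipals(Zi - mu, yi - yi.mean(), A)
                    beta = self._coef(W, P, q)
                    pred = (Z[i] - mu) @ beta + yi.mean()
                    sq += (pred - yc[i]) ** 2
                press[A - 1] = sq
            A_opt = int(np.argmin(press)) + 1
            self.press_ = press
        else:
            A_opt = int(self.n_components)
            if not 1 <= A_opt <= a_max:
                raise ModelError(f"n_components must be in [1, {a_max}]")
            self.press_ = None

        W, T, P, q = self._nipals(Z, yc, A_opt)
        self.n_components_ = W.shape[1]
        self.x_weights_, self.x_scores_, self.x_loadings_ = W, T, P
        self.y_loadings_ = q
        beta_scaled = self._coef(W, P, q)
        self.coef_ = beta_scaled / self.x_std_
        self.intercept_ = self.y_mean_ - self.x_mean_ @ self.coef_

        fitted = Z @ beta_scaled + self.y_mean_
        self.fitted_ = fitted
        if np.ptp(fitted) > 0 and np.ptp(y) > 0:
            self.r2_ = float(np.corrcoef(fitted, y)[0, 1] ** 2)
        else:
            self.r2_ = 0.0
        self.vip_ = pd.Series(
            self._vip(W, T, q), index=self.feature_names_in_, name="VIP"
        )
        return self

    @staticmethod
    def _vip(W, T, q):
        """VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a), w_a unit norm."""
        p, A = W.shape
        if A == 0:
            return np.full(p, np.nan)
        ssy = q**2 * np.einsum("ia,ia->a", T, T)  # response SS per component
        wnorm2 = W**2  # columns already unit norm
        return np.sqrt(p * (wnorm2 @ ssy) / ssy.sum())

    def predict(self, X):
        check_is_fitted(self, "coef_")
        Xdf = pd.DataFrame(X)
        missing = [c for c in self.feature_names_in_ if c not in Xdf.columns]
        if missing and Xdf.shape[1] == len(self.feature_names_in_):
            Xdf.columns = self.feature_names_in_  # positional, unnamed input
        elif missing:
            raise ModelError(f"missing variables: {missing}")
        Xm = Xdf[list(self.feature_names_in_)].to_numpy(dtype=float)
        return Xm @ self.coef_ + self.intercept_

    @property
    def significant_vars_(self) -> pd.Index:
        """Variables with VIP strictly above 1."""
        check_is_fitted(self, "vip_")
        return self.vip_.index[self.vip_ > 1.0]


def fit_plsr(X, y, n_components="auto", scale: bool = True) -> PLSRegressionVIP:
    """Thin functional wrapper over :class:`PLSRegressionVIP`."""
    return PLSRegressionVIP(n_components=n_components, scale=scale).fit(X, y)


def vip_scores(model: PLSRegressionVIP) -> pd.Series:
    check_is_fitted(model, "vip_")
    return model.vip_


# ----------------------------------------------------------------------
# MLR
# ----------------------------------------------------------------------

class MultipleLinearRegression(BaseEstimator, RegressorMixin):
    """Ordinary least squares with r2, adjusted r2, and overall F-test p.

    Raises on rank-deficient design matrices, naming the collinear columns.
    """

    def fit(self, X, y):
        Xdf = pd.DataFrame(X)
        y = np.asarray(y, dtype=float).ravel()
        n, p = Xdf.shape
        if n <= p + 1:
            raise ModelError(f"need n > p + 1 (n={n}, p={p})")
        Xm = Xdf.to_numpy(dtype=float)
        design = np.column_stack([np.ones(n), Xm])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            from scipy.linalg import qr

            _, R, piv = qr(design, pivoting=True)
            tol = abs(R[0, 0]) * max(design.shape) * np.finfo(float).eps
            bad = [piv[i] for i in range(design.shape[1]) if abs(R[i, i]) <= tol]
            names = [
                "intercept" if j == 0 else str(Xdf.columns[j - 1]) for j in bad
            ]
            raise ModelError(f"rank-deficient design; collinear columns: {names}")
        res = sm.OLS(y, design).fit()
        self.feature_names_in_ = np.asarray(Xdf.columns, dtype=object)
        self.result_ = res
        self.intercept_ = float(res.params[0])
        self.coef_ = pd.Series(res.params[1:], index=Xdf.columns)
        self.r2_ = float(res.rsquared)
        self.adj_r2_ = float(res.rsquared_adj)
        self.f_pvalue_ = float(res.f_pvalue)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        Xm = pd.DataFrame(X)[list(self.feature_names_in_)].to_numpy(dtype=float)
        return Xm @ self.coef_.to_numpy() + self.intercept_


def fit_mlr(X, y) -> MultipleLinearRegression:
    return MultipleLinearRegression().fit(X, y)


# ----------------------------------------------------------------------
# variable assembly
# ----------------------------------------------------------------------

@dataclass
class VariableMatrix:
    X: pd.DataFrame
    provenance: pd.Series  # column -> tag
    y: pd.Series           # porewater CH4 (uM)

    def suite(self, tags: Sequence[str]) -> pd.DataFrame:
        cols = self.provenance.index[self.provenance.isin(tags)]
        return self.X[cols]


def assemble_variables(
    otu_table,
    chem: pd.DataFrame,
    guilds: Mapping[str, Sequence[str]] | None = None,
    mag_lineages: Mapping[str, Mapping[str, str]] | None = None,
    otu_threshold_pct: float = 1.0,
    lineage_level: str = "phylum",
    class_override: Sequence[str] = ("Proteobacteria",),
) -> VariableMatrix:
    """Build the explanatory-variable matrix for CH4 prediction.

    Blocks, with provenance tags:

    * ``abiotic`` — depth, TOC, d13C_TOC, DIC, S, TOC:TS (CH4-related
      measurements are deliberately excluded as confounders);
    * ``otu_gt1pct`` — every OTU whose relative abundance exceeds
      ``otu_threshold_pct`` (strictly) in at least one sample;
    * ``lineage_sum`` — relative abundances summed per phylum, with listed
      phyla resolved at class level instead;
    * ``guild_sum`` — summed relative abundance per functional guild;
    * ``mag_lineage_sum`` — configured MAG proxies: either one OTU mapped
      directly to a MAG, or a lineage-pattern sum.

    Missing chemistry cells are imputed by within-core linear interpolation
    over depth (with a warning).  Duplicate (identical) columns are collapsed.
    The response is porewater CH4 in uM.
    """
    from .community import DEFAULT_GUILDS, _match_guilds

    samples = list(otu_table.samples)
    missing = [s for s in samples if s not in chem.index]
    if missing:
        raise ModelError(f"samples missing from chemistry table: {missing}")
    ch = chem.loc[samples].copy()

    abiotic = pd.DataFrame(
        {
            "depth": ch["depth_cm"],
            "TOC": ch["TOC_pct"],
            "d13C_TOC": ch["d13C_TOC"],
            "DIC": ch["DIC_uM"],
            "S": ch["S_pct"],
            "TOC_TS": ch["TOC_TS"],
        }
    )
    if abiotic.isna().any().any():
        warnings.warn("imputing missing chemistry by within-core depth interpolation")
        abiotic = abiotic.assign(_core=ch["core"]).groupby("_core", group_keys=False)[
            list(abiotic.columns)
        ].apply(lambda g: g.interpolate(limit_direction="both"))

    rel = otu_table.relative_abundance() * 100.0

    keep = rel.columns[(rel > otu_threshold_pct).any(axis=0)]
    otu_block = rel[keep].copy()
    otu_block.columns = [str(c) for c in keep]

    levels = rel.columns.to_series().map(
        lambda o: _lineage_label(otu_table.taxonomy[o], lineage_level, class_override)
    )
    lineage_block = rel.T.groupby(levels).sum().T
    lineage_block.columns = [f"lineage:{c}" for c in lineage_block.columns]

    guilds = dict(guilds or DEFAULT_GUILDS)
    members = _match_guilds(otu_table.taxonomy, guilds)
    guild_block = pd.DataFrame(
        {
            f"guild:{g}": rel[mm].sum(axis=1) if len(mm) else 0.0
            for g, mm in members.items()
        },
        index=rel.index,
    )

    mag_block = pd.DataFrame(index=rel.index)
    for name, spec_ in (mag_lineages or {}).items():
        if "otu" in spec_:
            otu = spec_["otu"]
            if otu not in rel.columns:
                raise ModelError(f"MAG proxy OTU {otu!r} not in table")
            mag_block[f"mag:{name}"] = rel[otu]
        elif "pattern" in spec_:
            pat = spec_["pattern"].lower()
            hit = [o for o in rel.columns if pat in otu_table.taxonomy[o].lower()]
            mag_block[f"mag:{name}"] = rel[hit].sum(axis=1) if hit else 0.0
        else:
            raise ModelError(f"MAG proxy {name!r} needs 'otu' or 'pattern'")

    blocks = [
        (abiotic, "abiotic"),
        (otu_block, "otu_gt1pct"),
        (lineage_block, "lineage_sum"),
        (mag_block, "mag_lineage_sum"),
        (guild_block, "guild_sum"),
    ]
    X = pd.concat([b for b, _ in blocks], axis=1)
    prov = pd.Series(
        {c: tag for b, tag in blocks for c in b.columns}, name="provenance"
    )

    # collapse duplicate (identical-vector) columns, keeping the first
    dup = X.T.duplicated()
    if dup.any():
        dropped = X.columns[dup.to_numpy()]
        warnings.warn(f"collapsing {dup.sum()} duplicate column(s): {list(dropped)}")
        X = X.loc[:, ~dup.to_numpy()]
        prov = prov[X.columns]

    y = ch["CH4_uM"].rename("CH4_uM")
    return VariableMatrix(X, prov[X.columns], y)


def _lineage_label(lineage: str, level: str, class_override: Sequence[str]) -> str:
    parts = [p.strip() for p in lineage.split(";")]
    phylum = parts[1] if len(parts) > 1 else parts[0]
    if phylum in class_override and len(parts) > 2:
        return parts[2]
    if level == "class" and len(parts) > 2:
        return parts[2]
    return phylum


# ----------------------------------------------------------------------
# model comparison
# ----------------------------------------------------------------------

DEFAULT_SUITES: dict[str, tuple[str, ...]] = {
    "abiotic": ("abiotic",),
    "abiotic+guilds": ("abiotic", "guild_sum"),
    "abiotic+lineages": ("abiotic", "lineage_sum"),
    "abiotic+all": (
        "abiotic", "otu_gt1pct", "lineage_sum", "mag_lineage_sum", "guild_sum"
    ),
}


@dataclass
class SuiteResult:
    suite: str
    n_variables: int
    plsr_r2: float
    plsr_components: int
    mlr_adj_r2: float = float("nan")
    mlr_p: float = float("nan")
    plsr_model: PLSRegressionVIP = field(repr=False, default=None)


def compare_models(
    vm: VariableMatrix,
    suites: Mapping[str, Sequence[str]] | None = None,
    n_components="auto",
    scale: bool = True,
) -> pd.DataFrame:
    """Fit PLSR (and MLR where determined) per variable suite.

    Suites are named tag collections resolved against the matrix provenance.
    MLR is only attempted when n > p + 1.  Returns a tidy DataFrame (one row
    per suite) also carrying the fitted PLSR model per row.
    """
    suites = dict(suites or DEFAULT_SUITES)
    rows = []
    for name, tags in suites.items():
        Xs = vm.suite(tags)
        if Xs.shape[1] == 0:
            warnings.warn(f"suite {name!r} selects no variables; skipped")
            continue
        pls = PLSRegressionVIP(n_components=n_components, scale=scale).fit(Xs, vm.y)
        res = SuiteResult(name, Xs.shape[1], pls.r2_, pls.n_components_, plsr_model=pls)
        if len(vm.y) > Xs.shape[1] + 1:
            try:
                mlr = fit_mlr(Xs, vm.y)
                res.mlr_adj_r2, res.mlr_p = mlr.adj_r2_, mlr.f_pvalue_
            except ModelError as e:
                warnings.warn(f"MLR skipped for suite {name!r}: {e}")
        rows.append(res)
    if not rows:
        raise ModelError("no non-empty suites")
    df = pd.DataFrame(
        {
            "suite": [r.suite for r in rows],
            "n_variables": [r.n_variables for r in rows],
            "plsr_r2": [r.plsr_r2 for r in rows],
            "plsr_components": [r.plsr_components for r in rows],
            "mlr_adj_r2": [r.mlr_adj_r2 for r in rows],
            "mlr_p": [r.mlr_p for r in rows],
            "model": [r.plsr_model for r in rows],
        }
    ).set_index("suite")
    return df
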