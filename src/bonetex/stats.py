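"""Coefficient inference and T2D-vs-normal comparison tables.

For a fitted linear model the classical OLS machinery gives each of the
46 weights (bias + 45 features) a standard error from the unbiased
residual variance and the inverted normal matrix, a t statistic, and a
two-sided p value on n − 46 residual degrees of freedom.  Per group and
per DXA target the features with p < α are tabulated, and features
significant in exactly one group are listed as discordant — the
between-group contrast of interest.

By default p values are reported raw at α = 0.05 across all 45 features
(no multiplicity correction), matching common radiomics practice; a
Benjamini–Hochberg option is provided and its use is flagged in the
report, since ~45 × α features are expected significant by chance alone
under the global null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import InsufficientSampleError
from .models import DesignMatrix, FitResult, LinearModel, N_COLUMNS

__all__ = [
    "CoefficientReport",
    "GroupComparison",
    "coefficient_pvalues",
    "compare_groups",
    "correlation_report",
]

TERM_NAMES_BIAS_FIRST = ("Constant",)


@dataclass
class CoefficientReport:
    """Per-term inference for one (group, target) linear fit.

    ``table`` has one row per design column — "Constant" (the bias w₀)
    first, then the 45 features — with columns
    ``term, weight, se, t, p`` (plus ``p_adj`` when Benjamini–Hochberg
    adjustment was requested).  Rank-deficient columns carry NaN
    se/t/p.
    """

    table: pd.DataFrame
    target_name: str
    group: str
    df_resid: int
    adjusted: bool = False
    univariate: bool = False


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment (monotone adjusted p values)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def _dependent_columns(X: np.ndarray, rank: int) -> np.ndarray:
    """Boolean flags of columns involved in a linear dependency.

    A column is involved iff removing it leaves the rank unchanged
    (it lies in the span of the others).
    """
    p = X.shape[1]
    flags = np.zeros(p, dtype=bool)
    for j in range(p):
        sub = np.delete(X, j, axis=1)
        flags[j] = np.linalg.matrix_rank(sub) == rank
    return flags


def coefficient_pvalues(
    model: LinearModel,
    design: DesignMatrix,
    alpha: float = 0.05,
    adjust: bool = False,
    group: str = "",
    univariate: bool = False,
) -> CoefficientReport:
    """Two-sided t-test of each weight against zero.

    Standard errors come from the unbiased residual variance times the
    diagonal of (XᵀX)⁻¹; t = w/se; p from Student's t with n − 46 degrees
    of freedom.  With ``univariate`` each feature is instead tested in
    its own bias-plus-one-feature regression (df = n − 2).  Collinear
    columns of a rank-deficient design are reported with NaN p.
    """
    X, y = design.X, design.y
    n, p_cols = X.shape
    df = n - p_cols
    if df < 1:
        raise InsufficientSampleError(
            f"residual degrees of freedom {df} < 1 (n={n}, columns={p_cols})"
        )

    terms = ["Constant", *design.feature_names]

    if univariate:
        rows = []
        for j in range(p_cols):
            if j == 0:
                Xj = X[:, [0]]
            else:
                Xj = X[:, [0, j]]
            wj, *_ = np.linalg.lstsq(Xj, y, rcond=None)
            resid = y - Xj @ wj
            dfj = n - Xj.shape[1]
            s2 = float(resid @ resid) / dfj
            cov = s2 * np.linalg.inv(Xj.T @ Xj)
            k = 0 if j == 0 else 1
            se = float(np.sqrt(cov[k, k]))
            t = wj[k] / se if se > 0 else np.nan
            pv = 2.0 * sps.t.sf(abs(t), dfj) if np.isfinite(t) else np.nan
            rows.append((terms[j], float(wj[k]), se, float(t), float(pv)))
        table = pd.DataFrame(rows, columns=["term", "weight", "se", "t", "p"])
    else:
        w = model.weights
        rank = int(np.linalg.matrix_rank(X))
        if rank == p_cols:
            resid = y - X @ w
            s2 = float(resid @ resid) / df
            se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
            t = w / se
            pv = 2.0 * sps.t.sf(np.abs(t), df)
        else:
            dep = _dependent_columns(X, rank)
            se = np.full(p_cols, np.nan)
            t = np.full(p_cols, np.nan)
            pv = np.full(p_cols, np.nan)
            keep = ~dep
            if keep.any():
                # inference on the restricted full-rank submodel
                Xr = X[:, keep]
                wr, *_ = np.linalg.lstsq(Xr, y, rcond=None)
                dfr = n - Xr.shape[1]
                if dfr >= 1:
                    resid = y - Xr @ wr
                    s2 = float(resid @ resid) / dfr
                    ser = np.sqrt(s2 * np.diag(np.linalg.inv(Xr.T @ Xr)))
                    tr = wr / ser
                    se[keep] = ser
                    t[keep] = tr
                    pv[keep] = 2.0 * sps.t.sf(np.abs(tr), dfr)
        table = pd.DataFrame(
            {"term": terms, "weight": w, "se": se, "t": t, "p": pv}
        )

    if adjust:
        feat = table["term"] != "Constant"
        padj = np.full(len(table), np.nan)
        pvals = table.loc[feat, "p"].to_numpy()
        ok = np.isfinite(pvals)
        adj = np.full(pvals.size, np.nan)
        if ok.any():
            adj[ok] = _benjamini_hochberg(pvals[ok])
        padj[feat.to_numpy()] = adj
        table["p_adj"] = padj

    return CoefficientReport(
        table=table,
        target_name=model.target_name,
        group=group,
        df_resid=df,
        adjusted=adjust,
        univariate=univariate,
    )


@dataclass
class GroupComparison:
    """Significance flags per feature × target × group, plus discordances.

    ``table`` has columns ``target, term, sig_t2d, sig_normal,
    discordant``; flags are pandas nullable booleans, with <NA> marking a
    report that was absent for that (group, target).  ``significant``
    maps (target, group) to the list of significant feature names, and
    ``discordant`` maps target to the cross-group discordance list.
    """

    table: pd.DataFrame
    significant: dict
    discordant: dict
    alpha: float
    adjusted: bool


def compare_groups(
    reports: dict,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> GroupComparison:
    """Build the eight-table comparison from coefficient reports.

    ``reports`` maps ``(target, group)`` — group in {"t2d", "normal"} —
    to a :class:`CoefficientReport`.  Missing entries yield explicit
    <NA> flags, never silent omission.  Output is a pure function of the
    reports and α.
    """
    targets = sorted({t for t, _ in reports})
    pcol = "p_adj" if use_adjusted else "p"

    significant: dict = {}
    discordant: dict = {}
    rows = []
    for target in targets:
        flags = {}
        terms = None
        for grp in ("t2d", "normal"):
            rep = reports.get((target, grp))
            if rep is None:
                flags[grp] = None
                continue
            tab = rep.table
            feat = tab[tab["term"] != "Constant"]
            terms = list(feat["term"])
            sig = feat[pcol].to_numpy() < alpha
            flags[grp] = dict(zip(terms, sig))
            significant[(target, grp)] = [
                name for name, s in zip(terms, sig) if s
            ]
        if terms is None:
            continue
        disc = []
        for name in terms:
            s_t = flags["t2d"][name] if flags["t2d"] is not None else pd.NA
            s_n = flags["normal"][name] if flags["normal"] is not None else pd.NA
            is_disc = (
                bool(s_t) != bool(s_n)
                if (s_t is not pd.NA and s_n is not pd.NA)
                else pd.NA
            )
            if is_disc is True:
                disc.append(name)
            rows.append(
                {
                    "target": target,
                    "term": name,
                    "sig_t2d": s_t,
                    "sig_normal": s_n,
                    "discordant": is_disc,
                }
            )
        discordant[target] = disc

    table = pd.DataFrame(
        rows, columns=["target", "term", "sig_t2d", "sig_normal", "discordant"]
    )
    for col in ("sig_t2d", "sig_normal", "discordant"):
        table[col] = table[col].astype("boolean")
    return GroupComparison(
        table=table,
        significant=significant,
        discordant=discordant,
        alpha=alpha,
        adjusted=use_adjusted,
    )


def correlation_report(fits: dict) -> pd.DataFrame:
    """Summary of Pearson r and error metrics per group × target.

    ``fits`` maps ``(target, group)`` to a :class:`FitResult`.  Values
    are formatted to 3 decimals; missing combinations appear as "absent".
    """
    targets = sorted({t for t, _ in fits})
    groups = ("t2d", "normal")
    rows = []
    for target in targets:
        for grp in groups:
            fit = fits.get((target, grp))
            if fit is None:
                rows.append(
                    {"target": target, "group": grp, "pearson_r": "absent",
                     "sse": "absent", "mse": "absent", "n": "absent"}
                )
            else:
                rows.append(
                    {
                        "target": target,
                        "group": grp,
                        "pearson_r": f"{fit.pearson_r:.3f}",
                        "sse": f"{fit.sse:.3f}",
                        "mse": f"{fit.mse:.3f}",
                        "n": len(fit.predictions),
                    }
                )
    return pd.DataFrame(rows, columns=["target", "group", "pearson_r", "sse", "mse", "n"])


def plot_significance(report: CoefficientReport, path, alpha: float = 0.05) -> None:
    """Bar plot of per-feature −log10 p for one (group, target) fit.

    Optional QC figure; requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = report.table
    with np.errstate(divide="ignore"):
        neglog = -np.log10(tab["p"].to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.bar(np.arange(len(tab)), neglog, color="steelblue")
    ax.axhline(-np.log10(alpha), color="firebrick", ls="--", lw=1,
               label=f"p = {alpha}")
    ax.set_xticks(np.arange(len(tab)))
    ax.set_xticklabels(tab["term"], rotation=90, fontsize=6)
    ax.set_ylabel("-log10 p")
    ax.set_title(f"{report.target_name} — {report.group or 'all'}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(str(path), dpi=150)
    plt.close(fig)
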