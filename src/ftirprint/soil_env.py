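"""Soil-trait multivariate analysis and spectra-vs-environment correlation.

Soil tables are autoscaled before PCA; Hotelling-T2 flags outliers.
Group comparisons use the Kruskal-Wallis test with a rank-based least
significant difference post hoc, summarized as a compact letter display.
PLS1 regressions of the pre-processed spectra against each covariate
quantify (the lack of) environmental correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ftirprint.chemometrics_core import (
    PcaModel,
    cv_r2,
    fit_pca,
    select_n_lv,
)
from ftirprint.spectra_io import SpectralDataset
from ftirprint.validation import venetian_blinds

SOIL_COLUMNS = ("pH", "pct_LOI", "pct_water", "olsen_P", "C_to_N")


def validate_soil_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the physical ranges of a soil table (columns as in SOIL_COLUMNS)."""
    missing = [c for c in SOIL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"soil table missing columns {missing}")
    if ((table["pH"] <= 0) | (table["pH"] >= 14)).any():
        raise ValueError("pH out of (0, 14)")
    for col in ("pct_LOI", "pct_water"):
        if ((table[col] < 0) | (table[col] > 100)).any():
            raise ValueError(f"{col} out of [0, 100]")
    if (table["C_to_N"] <= 0).any() or (table["olsen_P"] < 0).any():
        raise ValueError("non-positive ratio or negative phosphorus")
    return table


def autoscale(table: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Center each column to mean 0 and scale to SD 1 (n-1 denominator).

    Returns the scaled matrix and a scaling record (mean, sd per column).
    """
    num = table.select_dtypes(include=[np.number])
    if num.shape[0] < 2:
        raise ValueError("need at least 2 rows to autoscale")
    mean = num.mean(axis=0)
    sd = num.std(axis=0, ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant column(s) cannot be autoscaled: {constant}")
    scaled = ((num - mean) / sd).to_numpy(dtype=float)
    record = pd.DataFrame({"mean": mean, "sd": sd})
    return scaled, record


def hotelling_t2_limit(n: int, k: int, alpha: float) -> float:
    """F-based upper control limit for Hotelling T2 on k PCA scores."""
    f_crit = stats.f.ppf(1 - alpha, k, n - k)
    return k * (n - 1) / (n - k) * f_crit


def soil_pca_with_outliers(
    table: pd.DataFrame, k: int = 2, t2_alpha: float = 0.05
) -> tuple[PcaModel, np.ndarray, PcaModel | None]:
    """Autoscaled PCA with Hotelling-T2 outlier flags.

    Returns (model on all rows, boolean flags, refit excluding flagged rows
    or None when nothing was flagged). Flagging is report-only; exclusion is
    the caller's decision.
    """
    num = table.select_dtypes(include=[np.number])
    n = num.shape[0]
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} rows for k={k}")
    X, _ = autoscale(table)
    model = fit_pca(X, k, center=True)
    var = model.scores.var(axis=0, ddof=1)
    t2 = np.sum(model.scores**2 / var, axis=1)
    limit = hotelling_t2_limit(n, model.k, t2_alpha)
    flags = t2 > limit
    refit = None
    if flags.any() and (~flags).sum() >= k + 2:
        refit = fit_pca(X[~flags], k, center=True)
    return model, flags, refit


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-squared p value.

    H is defined as 0 (p = 1) when every observation is tied.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    for g in uniq:
        if (groups == g).sum() == 0:
            raise ValueError(f"empty group {g!r}")
    n = values.size
    ranks = stats.rankdata(values)
    h = 12.0 / (n * (n + 1)) * sum(
        (ranks[groups == g].sum()) ** 2 / (groups == g).sum() for g in uniq
    ) - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    ties = np.sum(counts**3 - counts)
    denom = 1.0 - ties / (n**3 - n)
    if denom == 0:
        return 0.0, 1.0
    h /= denom
    p = float(stats.chi2.sf(h, uniq.size - 1))
    return float(h), p


def lsd_rank_posthoc(
    values: np.ndarray, groups: np.ndarray, alpha: float = 0.05
) -> tuple[pd.DataFrame, np.ndarray]:
    """Rank-based Fisher-LSD pairwise comparisons (Conover convention).

    Mean ranks are compared with a t criterion on N - g degrees of freedom
    using the Kruskal-Wallis rank variance. Returns the pairwise boolean
    significance matrix (as a labeled DataFrame) and the group order.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    g = uniq.size
    if g < 2:
        raise ValueError("need at least 2 groups")
    n = values.size
    ranks = stats.rankdata(values)
    h, _ = kruskal_wallis(values, groups)
    mean_ranks = np.array([ranks[groups == u].mean() for u in uniq])
    sizes = np.array([(groups == u).sum() for u in uniq])
    # Conover: S^2 = (sum R_i^2 - n (n+1)^2 / 4) / (n - 1)
    s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    if n - g <= 0:
        raise ValueError("not enough observations for the post hoc test")
    factor = s2 * (n - 1 - h) / (n - g)
    factor = max(factor, 0.0)
    t_crit = stats.t.ppf(1 - alpha / 2, n - g)
    sig = np.zeros((g, g), dtype=bool)
    for i in range(g):
        for j in range(i + 1, g):
            se = np.sqrt(factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
            diff = abs(mean_ranks[i] - mean_ranks[j])
            if se == 0:
                significant = diff > 0
            else:
                significant = diff / se > t_crit
            sig[i, j] = sig[j, i] = significant
    return pd.DataFrame(sig, index=uniq, columns=uniq), uniq


def compact_letter_display(
    pairwise: pd.DataFrame | np.ndarray, group_order: np.ndarray | list | None = None
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Two groups share a letter iff their pairwise comparison is
    non-significant. Letters are lowercase a, b, c, ...
    """
    if isinstance(pairwise, pd.DataFrame):
        order = list(pairwise.index) if group_order is None else list(group_order)
        sig = pairwise.loc[order, order].to_numpy(dtype=bool)
    else:
        sig = np.asarray(pairwise, dtype=bool)
        order = (
            list(range(sig.shape[0])) if group_order is None else list(group_order)
        )
    g = sig.shape[0]
    if not np.array_equal(sig, sig.T):
        raise ValueError("pairwise matrix must be symmetric")
    # columns of a boolean membership matrix: start with one all-inclusive letter
    columns: list[set[int]] = [set(range(g))]
    for i in range(g):
        for j in range(i + 1, g):
            if not sig[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                ci, cj = col - {j}, col - {i}
                # insert both halves, absorbing duplicates/subsets
                for new in (ci, cj):
                    if not any(new <= other for other in columns):
                        columns = [c for c in columns if not c <= new] + [new]
    # drop columns that distinguish nothing (can appear for isolated groups)
    columns = [c for c in columns if c]
    # stable letter order: by smallest member index
    columns.sort(key=lambda c: min(c))
    letters = {order[i]: "" for i in range(g)}
    for letter_idx, col in enumerate(columns):
        ch = chr(ord("a") + letter_idx)
        for i in sorted(col):
            letters[order[i]] += ch
    # groups not in any column (fully significant against everything after
    # absorption) need their own letter
    for i in range(g):
        if not letters[order[i]]:
            columns.append({i})
            letters[order[i]] = chr(ord("a") + len(columns) - 1)
    return letters


@dataclass
class EnvCorrelationResult:
    covariate: str
    n_lv: int
    cv_r2: float
    cv_rmse: float
    verdict: str


def env_correlation_report(
    spectra: SpectralDataset,
    covariates: pd.DataFrame,
    join_on: str = "site",
    max_lv: int = 10,
    cv_folds: int = 10,
    r2_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-covariate PLS1 of spectra against an environmental variable.

    ``covariates`` must carry a ``join_on`` column (site or region); each
    spectrum receives the covariate value of its site/region. Reports the
    venetian-blinds-selected LV count, cross-validated R2 and RMSE, and a
    'minimal correlation' verdict when cv R2 falls below the threshold.
    """
    if join_on not in covariates.columns:
        raise ValueError(f"covariate table lacks a {join_on!r} column")
    keys = spectra.labels(join_on)
    cov = covariates.drop(columns=["replicate"], errors="ignore").groupby(
        join_on
    ).mean(numeric_only=True)
    unmatched = sorted(set(keys) - set(cov.index))
    if unmatched:
        raise ValueError(f"no covariate rows for keys {unmatched}")
    X = spectra.absorbance
    folds = venetian_blinds(X.shape[0], cv_folds).fold_index
    rows = []
    for name in cov.columns:
        y = cov.loc[keys, name].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            rows.append(
                EnvCorrelationResult(name, 0, 0.0, float("nan"), "degenerate")
            )
            continue
        n_lv = select_n_lv(X, y, max_lv, folds)
        from ftirprint.chemometrics_core import cv_rmse_curve

        rmse = cv_rmse_curve(X, y, n_lv, folds)[n_lv - 1]
        r2 = cv_r2(X, y, n_lv, folds)
        verdict = "minimal correlation" if r2 < r2_threshold else "correlated"
        rows.append(EnvCorrelationResult(name, n_lv, float(r2), float(rmse), verdict))
    return pd.DataFrame([r.__dict__ for r in rows])


def join_covariate(
    spectra: SpectralDataset, covariates: pd.DataFrame, column: str, join_on: str = "site"
) -> np.ndarray:
    """Per-spectrum covariate vector by site/region join (mean over replicates)."""
    cov = covariates.groupby(join_on)[column].mean()
    keys = spectra.labels(join_on)
    unmatched = sorted(set(keys) - set(cov.index))
    if unmatched:
        raise ValueError(f"no covariate rows for keys {unmatched}")
    return cov.loc[keys].to_numpy(dtype=float)
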