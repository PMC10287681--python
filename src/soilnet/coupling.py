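"""Prokaryote-fungal coupling statistics and mixed-model correlations.

The coupling of the two domains within one community is the standardized
slope (beta) between the summed relative reads of the most prevalent
prokaryote and fungal network clusters, rank-matched by cluster index
(cluster assignment is prevalence-ordered, so pairing cluster k with cluster
k compares like with like).  Beta equals the Pearson correlation of the
(optionally ln- or sqrt-transformed) standardized vectors: +1 means reads
are distributed identically over the top clusters (coupled), 0 decoupled.

Cluster-cluster correlation tables use linear mixed models with a random
intercept (sowing density in the field design) and Bonferroni correction;
the stability-coupling test regresses ln temporal stability on beta with
soil as the random factor, reporting a type-III Wald chi-square.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateSeriesError

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingScore",
    "StabilityCouplingTest",
    "choose_transform",
    "apply_transform",
    "coupling_beta",
    "coupling_scores",
    "bonferroni_threshold",
    "cluster_correlations",
    "count_significant_cross_correlations",
    "stability_coupling_test",
]

DEFAULT_N_PAIRS = 9
SHAPIRO_ALPHA = 0.05


@dataclass
class CouplingScore:
    mesocosm_id: str
    beta: float
    n_cluster_pairs: int
    transform_prok: str
    transform_fungal: str


@dataclass
class StabilityCouplingTest:
    slope: float
    se: float
    wald_chi2: float
    p: float
    n: int
    grouping: str
    warning: str | None = None


def apply_transform(x: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return x
    if how == "ln":
        if np.any(x <= 0):
            raise DataError("ln transform requires positive values")
        return np.log(x)
    if how == "sqrt":
        if np.any(x < 0):
            raise DataError("sqrt transform requires non-negative values")
        return np.sqrt(x)
    raise DataError(f"unknown transform {how!r}")


def _residual_normal(resid: np.ndarray, alpha: float = SHAPIRO_ALPHA) -> bool:
    if len(resid) < 4 or np.allclose(resid, resid[0]):
        return True
    return stats.shapiro(resid).pvalue > alpha


def choose_transform(y: np.ndarray, x: np.ndarray) -> str:
    """First of none / ln / sqrt whose simple-regression residuals pass a
    Shapiro-Wilk normality check; ln needs positive, sqrt non-negative
    responses.  Falls back to 'none' when nothing passes."""
    for how in ("none", "ln", "sqrt"):
        try:
            yt = apply_transform(y, how)
        except DataError:
            continue
        slope, intercept = np.polyfit(x, yt, 1)
        if _residual_normal(yt - (slope * x + intercept)):
            return how
    return "none"


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateSeriesError("zero variance")
    return (v - v.mean()) / sd


def coupling_beta(
    prok: np.ndarray,
    fungal: np.ndarray,
    transform: str = "auto",
    mesocosm_id: str = "",
) -> CouplingScore:
    """Standardized slope of fungal on prokaryote cluster abundances.

    Both vectors are rank-matched by cluster index (1..k).  After the
    transform policy both are standardized, so beta equals their Pearson
    correlation and direction of regression is immaterial.
    """
    p = np.asarray(prok, dtype=float)
    f = np.asarray(fungal, dtype=float)
    if p.shape != f.shape:
        raise DataError("cluster vectors must be rank-matched and equal length")
    if len(p) < 3:
        raise DataError("need >= 3 cluster pairs")
    if transform == "auto":
        t_f = choose_transform(f, p)
        t_p = choose_transform(p, f)
    else:
        t_p = t_f = transform
    zp = _standardize(apply_transform(p, t_p))
    zf = _standardize(apply_transform(f, t_f))
    beta = float((zp * zf).sum() / (len(zp) - 1))
    return CouplingScore(
        mesocosm_id=mesocosm_id,
        beta=beta,
        n_cluster_pairs=len(p),
        transform_prok=t_p,
        transform_fungal=t_f,
    )


def coupling_scores(
    prok_abund: pd.DataFrame,
    fungal_abund: pd.DataFrame,
    n_pairs: int = DEFAULT_N_PAIRS,
    transform: str = "auto",
) -> pd.DataFrame:
    """Per-sample coupling beta from cluster-abundance matrices (samples x
    clusters, prevalence-ordered columns); uses the top ``n_pairs`` clusters
    of each domain (fewer when a domain has fewer clusters)."""
    k = min(n_pairs, prok_abund.shape[1], fungal_abund.shape[1])
    if k < 3:
        raise DataError(f"only {k} rank-matched cluster pairs available")
    common = prok_abund.index.intersection(fungal_abund.index)
    rows = []
    for sid in common:
        score = coupling_beta(
            prok_abund.loc[sid].to_numpy()[:k],
            fungal_abund.loc[sid].to_numpy()[:k],
            transform=transform,
            mesocosm_id=str(sid),
        )
        rows.append(
            {"mesocosm_id": sid, "beta": score.beta,
             "n_cluster_pairs": score.n_cluster_pairs,
             "transform_prok": score.transform_prok,
             "transform_fungal": score.transform_fungal}
        )
    return pd.DataFrame(rows).set_index("mesocosm_id")


def bonferroni_threshold(family_alpha: float, n_tests: int) -> tuple[float, float]:
    """Per-test alpha = family alpha / n_tests; returned full precision and
    rounded to 4 decimals."""
    if n_tests < 1:
        raise DataError("n_tests must be >= 1")
    per_test = family_alpha / n_tests
    return per_test, round(per_test, 4)


def _mixed_or_ols(y: np.ndarray, x: np.ndarray, groups) -> tuple[float, float, float]:
    """Standardized slope, SE and p for y ~ x, random intercept on groups
    when they have >= 2 levels.  Inputs already transformed; standardization
    happens here."""
    import statsmodels.api as sm

    from .lmm import fit_random_intercept

    zy, zx = _standardize(y), _standardize(x)
    exog = sm.add_constant(zx)
    use_mixed = groups is not None and pd.Series(groups).nunique() >= 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if use_mixed:
            try:
                fit = fit_random_intercept(zy, exog, np.asarray(groups))
                return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
            except Exception as exc:  # singular random effect etc.
                logger.debug("mixed fit failed (%s); falling back to OLS", exc)
        fit = sm.OLS(zy, exog).fit()
        return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])


def cluster_correlations(
    abund_a: pd.DataFrame,
    abund_b: pd.DataFrame | None = None,
    grouping=None,
    family_alpha: float = 0.05,
    denominator: str = "clusters",
    transform: str = "auto",
) -> pd.DataFrame:
    """Pairwise cluster correlation table with Bonferroni control.

    With one matrix, all unordered within-matrix pairs; with two, all
    cross-matrix pairs (the prokaryote-fungal case).  Each pair is fit as a
    mixed/plain linear model on standardized (transform-policy) variables.
    ``denominator``: "clusters" divides the family alpha by the total number
    of clusters involved, "pairs" by the number of tests.
    """
    cross = abund_b is not None
    if cross:
        common = abund_a.index.intersection(abund_b.index)
        A, B = abund_a.loc[common], abund_b.loc[common]
        pairs = [(ca, cb) for ca in A.columns for cb in B.columns]
        n_clusters = A.shape[1] + B.shape[1]
    else:
        A = B = abund_a
        cols = list(A.columns)
        pairs = [(cols[i], cols[j]) for i in range(len(cols))
                 for j in range(i + 1, len(cols))]
        n_clusters = A.shape[1]
    if len(A) < 5:
        raise DataError("need >= 5 observations per pair")
    if denominator == "clusters":
        per_test, _ = bonferroni_threshold(family_alpha, n_clusters)
    elif denominator == "pairs":
        per_test, _ = bonferroni_threshold(family_alpha, max(1, len(pairs)))
    else:
        raise DataError(f"unknown denominator rule {denominator!r}")

    groups = None
    if grouping is not None:
        groups = pd.Series(grouping).reindex(A.index).to_numpy()

    rows = []
    for ca, cb in pairs:
        x = A[ca].to_numpy(dtype=float)
        y = B[cb].to_numpy(dtype=float)
        try:
            if transform == "auto":
                t = choose_transform(y, x)
            else:
                t = transform
            coef, se, p = _mixed_or_ols(apply_transform(y, t), x, groups)
        except (DegenerateSeriesError, DataError) as exc:
            logger.warning("skipping pair (%s, %s): %s", ca, cb, exc)
            continue
        rows.append(
            {"cluster_a": ca, "cluster_b": cb, "coefficient": coef, "se": se,
             "p": p, "transform": t, "significant": bool(p < per_test)}
        )
    table = pd.DataFrame(
        rows,
        columns=["cluster_a", "cluster_b", "coefficient", "se", "p",
                 "transform", "significant"],
    )
    table.attrs["per_test_alpha"] = per_test
    table.attrs["family_alpha"] = family_alpha
    table.attrs["denominator"] = denominator
    table.attrs["n_tests"] = len(pairs)
    return table


def count_significant_cross_correlations(
    prok_abund: pd.DataFrame,
    fungal_abund: pd.DataFrame,
    grouping=None,
    family_alpha: float = 0.05,
    denominator: str = "clusters",
) -> int:
    table = cluster_correlations(
        prok_abund, fungal_abund, grouping=grouping,
        family_alpha=family_alpha, denominator=denominator,
    )
    return int(table["significant"].sum())


def stability_coupling_test(
    stability: pd.Series,
    betas: pd.Series,
    soil: pd.Series,
    ln_stability: bool = True,
) -> StabilityCouplingTest:
    """ln(stability) ~ coupling beta with soil as random intercept.

    Wald chi-square = (slope/SE)^2 (the type-III statistic for a single
    fixed effect), p from chi-square(1).  With a single soil the model falls
    back to plain regression with a warning.
    """
    import statsmodels.api as sm

    from .lmm import fit_random_intercept

    idx = stability.index.intersection(betas.index)
    y = stability.loc[idx].to_numpy(dtype=float)
    x = betas.loc[idx].to_numpy(dtype=float)
    g = pd.Series(soil).loc[idx]
    if ln_stability:
        y = np.log(y)
    if np.std(x, ddof=1) == 0:
        raise DegenerateSeriesError("coupling beta constant across mesocosms")
    exog = sm.add_constant(x)
    warning = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if g.nunique() >= 2:
            try:
                fit = fit_random_intercept(y, exog, g.to_numpy())
            except Exception as exc:
                warning = f"mixed model failed ({exc}); plain regression used"
                fit = sm.OLS(y, exog).fit()
        else:
            warning = "single soil: plain regression used"
            fit = sm.OLS(y, exog).fit()
    slope, se = float(fit.params[1]), float(fit.bse[1])
    chi2 = (slope / se) ** 2
    p = float(stats.chi2.sf(chi2, df=1))
    return StabilityCouplingTest(
        slope=slope, se=se, wald_chi2=float(chi2), p=p, n=len(y),
        grouping="soil", warning=warning,
    )
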