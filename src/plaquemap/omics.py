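"""Differential-abundance and gene-set statistics for sorted-microglia omics.

The statistical layer mirrors the moderated linear-model workflow standard
in the field: per-feature ordinary least squares against a design of
condition plus nuisance covariates (sex, batch/take-down day, optional
surrogate variables), empirical-Bayes shrinkage of residual variances
toward an inverse-chi-square prior, t-tests either ordinary or relative to
a fold-change threshold (the TREAT formulation, default threshold 1.2-fold
for gene expression), Benjamini-Hochberg FDR, and the study-specific
significance rules:

* analytes (lipids/metabolites): absolute fold difference > 20 % AND
  FDR q < 0.10;
* genes (TREAT path): FDR q <= 0.10.

Gene-set utilities implement eigen-weighted single-sample activity scores
(first-principal-component gene loadings as weights), the weighted
running-sum enrichment statistic with leading-edge extraction, mean
leading-edge t-statistic scores over a cross-comparison union, and the
exact hypergeometric overlap test.

All strict/inclusive boundary conventions are part of the contract and are
pinned by tests: detection in < 75 % of samples removes an analyte;
"more than ten reads" means > 10; "more than 20 %" excludes exactly 20 %;
the gene rule includes q = 0.10 exactly; signature extraction includes
log2FC = 1 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization and filtering
# ---------------------------------------------------------------------------


def normalize_internal_standard(
    peak_areas: pd.DataFrame,
    standard_areas: pd.DataFrame,
    standard_map: Mapping[str, str],
) -> pd.DataFrame:
    """log2 ratio of each analyte's peak area to its internal standard.

    ``peak_areas`` is analytes x samples; ``standard_areas`` is internal
    standards x samples (same sample columns); ``standard_map`` assigns each
    analyte its pre-assigned standard. Missing analyte areas propagate as
    missing; a missing, zero or negative standard area is an error.
    """
    missing = [a for a in peak_areas.index if a not in standard_map]
    if missing:
        raise KeyError(f"analytes without an internal standard: {missing[:5]}")
    std = pd.DataFrame(
        {a: standard_areas.loc[standard_map[a]] for a in peak_areas.index}
    ).T
    std = std[peak_areas.columns]
    if not (std.to_numpy() > 0).all():
        raise ValueError("internal standard areas must all be positive")
    return np.log2(peak_areas / std)


def filter_detection(values: pd.DataFrame, min_frac: float = 0.75) -> pd.DataFrame:
    """Drop features detected in less than ``min_frac`` of samples.

    Detection means a non-missing value. The removal rule is strict: a
    feature detected in exactly 75 % of samples is kept.
    """
    frac = values.notna().mean(axis=1)
    return values.loc[frac >= min_frac]


def median_scale(values: pd.DataFrame) -> pd.DataFrame:
    """Subtract each sample's median (over observed values).

    After scaling every sample's median is 0; adding a constant to one
    sample before scaling leaves its scaled values unchanged.
    """
    return values - values.median(axis=0, skipna=True)


def filter_low_expression(
    counts: pd.DataFrame, min_samples: int, min_reads: int = 10
) -> pd.DataFrame:
    """Drop genes without more than ``min_reads`` reads in >= ``min_samples`` samples.

    A gene is kept iff strictly more than ``min_reads`` reads (default:
    > 10) are assigned to it in at least ``min_samples`` samples —
    conventionally the minimum replicate-group size of the experiment.
    """
    keep = (counts > min_reads).sum(axis=1) >= min_samples
    return counts.loc[keep]


def sum_technical_replicates(counts: pd.DataFrame, sample_ids: Sequence[str]) -> pd.DataFrame:
    """Sum count columns that share a biological sample id."""
    return counts.T.groupby(list(sample_ids)).sum().T


# ---------------------------------------------------------------------------
# linear models
# ---------------------------------------------------------------------------


@dataclass
class LinearFit:
    """Per-feature OLS results for one contrast.

    ``stdev_unscaled`` is sqrt(c' (X'X)^-1 c) so that the coefficient's
    standard error is ``stdev_unscaled * sigma``.
    """

    features: pd.Index
    coef: np.ndarray
    stdev_unscaled: np.ndarray
    sigma2: np.ndarray
    df_resid: np.ndarray
    design_columns: list[str] = field(default_factory=list)


@dataclass
class ModeratedFit(LinearFit):
    """LinearFit with empirical-Bayes moderated variances."""

    s2_prior: float = np.nan
    df_prior: float = np.nan
    s2_post: np.ndarray = None  # type: ignore[assignment]
    df_total: np.ndarray = None  # type: ignore[assignment]


def build_design(
    metadata: pd.DataFrame,
    covariates: Sequence[str],
    categorical: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Design matrix with intercept from a sample-metadata table.

    Columns listed in ``covariates`` are included; object/category columns
    (or those named in ``categorical``) are dummy-coded dropping the first
    level, numeric columns pass through. Raises on a rank-deficient design,
    naming the collinear columns.
    """
    pieces = [pd.Series(1.0, index=metadata.index, name="Intercept")]
    categorical = set(categorical or [])
    for cov in covariates:
        col = metadata[cov]
        if cov in categorical or col.dtype == object or isinstance(
            col.dtype, pd.CategoricalDtype
        ):
            # reference level = first level observed in the data
            levels = list(dict.fromkeys(col))
            dummies = pd.DataFrame(
                {f"{cov}_{lvl}": (col == lvl).astype(float) for lvl in levels[1:]},
                index=metadata.index,
            )
            pieces.append(dummies)
        else:
            pieces.append(col.astype(float))
    design = pd.concat(pieces, axis=1)
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [
            c
            for i, c in enumerate(design.columns)
            if np.linalg.matrix_rank(np.delete(X, i, axis=1)) == rank
        ]
        raise ValueError(f"design is rank-deficient; collinear columns: {collinear}")
    return design


def _contrast_vector(design: pd.DataFrame, contrast: str | Sequence[float]) -> np.ndarray:
    if isinstance(contrast, str):
        if contrast not in design.columns:
            raise KeyError(
                f"contrast {contrast!r} is not a design column; available: {list(design.columns)}"
            )
        c = np.zeros(design.shape[1])
        c[design.columns.get_loc(contrast)] = 1.0
        return c
    c = np.asarray(contrast, dtype=float)
    if c.shape != (design.shape[1],):
        raise ValueError("contrast vector length must equal the number of design columns")
    return c


def fit_linear_model(
    values: pd.DataFrame,
    design: pd.DataFrame,
    contrast: str | Sequence[float],
    min_df: int = 1,
) -> LinearFit:
    """Per-feature ordinary least squares with a contrast extraction.

    ``values`` is features x samples (log2 scale, missing allowed) and
    ``design`` rows must align with the sample columns. Features are fit on
    their complete cases; features with residual df < ``min_df`` come back
    with NaN statistics and a logged reason. The contrast (a design column
    name, or a vector) defines the reported effect (log2 fold change).
    """
    if list(design.index) != list(values.columns):
        design = design.loc[values.columns]
    X_full = design.to_numpy(dtype=float)
    cvec = _contrast_vector(design, contrast)
    Y = values.to_numpy(dtype=float)
    n_feat, n_samp = Y.shape
    p = X_full.shape[1]

    coef = np.full(n_feat, np.nan)
    su = np.full(n_feat, np.nan)
    sigma2 = np.full(n_feat, np.nan)
    df_resid = np.zeros(n_feat)

    complete = ~np.isnan(Y)
    all_complete = complete.all()

    def solve(X: np.ndarray, y: np.ndarray):
        # y may be 1D (one feature) or 2D (features x samples, transposed)
        XtX_inv = linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        return beta, XtX_inv, resid

    if all_complete:
        beta, XtX_inv, resid = solve(X_full, Y.T)
        dof = n_samp - p
        coef = cvec @ beta
        su[:] = np.sqrt(cvec @ XtX_inv @ cvec)
        rss = (resid**2).sum(axis=0)
        sigma2 = rss / dof if dof > 0 else np.full(n_feat, np.nan)
        df_resid[:] = dof
    else:
        for i in range(n_feat):
            obs = complete[i]
            X = X_full[obs]
            dof = int(obs.sum()) - p
            if dof < min_df or np.linalg.matrix_rank(X) < p:
                logger.info(
                    "feature %s skipped: %d complete observations leave df=%d",
                    values.index[i],
                    int(obs.sum()),
                    dof,
                )
                continue
            beta, XtX_inv, resid = solve(X, Y[i, obs])
            coef[i] = cvec @ beta
            su[i] = np.sqrt(cvec @ XtX_inv @ cvec)
            sigma2[i] = (resid**2).sum() / dof
            df_resid[i] = dof

    return LinearFit(
        features=values.index,
        coef=coef,
        stdev_unscaled=su,
        sigma2=sigma2,
        df_resid=df_resid,
        design_columns=list(design.columns),
    )


# ---------------------------------------------------------------------------
# empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def _trigamma(x):
    return polygamma(1, x)


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = _trigamma(x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(sigma2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match a scaled F distribution to observed variances.

    Returns (scale s0^2, prior df d0); d0 may be inf when the observed
    variances show no excess dispersion beyond sampling noise.
    """
    ok = np.isfinite(sigma2) & (sigma2 > 0) & (df > 0)
    s2, d = sigma2[ok], df[ok]
    if s2.size < 2:
        return float(np.nanmedian(s2)) if s2.size else np.nan, np.inf
    z = np.log(s2)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - _trigamma(d / 2.0).mean()
    if evar > 0:
        df_prior = 2.0 * trigamma_inverse(evar)
        s2_prior = float(np.exp(emean + digamma(df_prior / 2.0) - np.log(df_prior / 2.0)))
    else:
        # no dispersion beyond sampling noise: pool completely
        df_prior = np.inf
        s2_prior = float(s2.mean())
    return s2_prior, df_prior


def moderate_variance(fit: LinearFit) -> ModeratedFit:
    """Shrink per-feature residual variances toward the empirical prior.

    The posterior variance is the df-weighted average
    ``(d0*s0^2 + d_g*s_g^2) / (d0 + d_g)``; the moderated t uses
    ``df_total = d_g + d0`` (capped at the summed residual df).
    """
    s2_prior, df_prior = fit_f_dist(fit.sigma2, fit.df_resid)
    if np.isinf(df_prior):
        s2_post = np.where(np.isfinite(fit.sigma2), s2_prior, np.nan)
        df_total = np.full_like(fit.df_resid, np.inf, dtype=float)
    else:
        s2_post = (df_prior * s2_prior + fit.df_resid * fit.sigma2) / (df_prior + fit.df_resid)
        total_df = np.nansum(fit.df_resid)
        df_total = np.minimum(fit.df_resid + df_prior, total_df)
    return ModeratedFit(
        features=fit.features,
        coef=fit.coef,
        stdev_unscaled=fit.stdev_unscaled,
        sigma2=fit.sigma2,
        df_resid=fit.df_resid,
        design_columns=fit.design_columns,
        s2_prior=s2_prior,
        df_prior=df_prior,
        s2_post=s2_post,
        df_total=df_total,
    )


def moderated_t_test(fit: ModeratedFit) -> pd.DataFrame:
    """Ordinary moderated t-test (two-sided) on the contrast coefficient."""
    se = fit.stdev_unscaled * np.sqrt(fit.s2_post)
    t = fit.coef / se
    df = fit.df_total
    p = 2.0 * _t_sf(np.abs(t), df)
    return pd.DataFrame({"log2fc": fit.coef, "t": t, "p": p}, index=fit.features)


def _t_sf(x: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Student-t survival function tolerating df = inf (normal limit)."""
    x = np.asarray(x, dtype=float)
    df = np.asarray(df, dtype=float)
    out = np.full(np.broadcast(x, df).shape, np.nan)
    inf = np.isinf(df)
    with np.errstate(invalid="ignore"):
        out = np.where(inf, stats.norm.sf(x), stats.t.sf(x, np.where(inf, 1.0, df)))
    return out


def treat_test(fit: ModeratedFit, lfc: float = np.log2(1.2)) -> pd.DataFrame:
    """Moderated t-test relative to a fold-change threshold.

    Tests H0: |true log2FC| <= ``lfc`` via the threshold-offset moderated
    t statistics: with a = |coef| and se the moderated standard error,
    ``p = P(T > (a - lfc)/se) + P(T > (a + lfc)/se)``. At ``lfc = 0`` this
    reduces exactly to the ordinary two-sided moderated t-test. The
    reported t is the threshold-offset statistic carrying the sign of the
    coefficient.
    """
    if lfc < 0:
        raise ValueError("fold-change threshold must be >= 0")
    se = fit.stdev_unscaled * np.sqrt(fit.s2_post)
    acoef = np.abs(fit.coef)
    t_right = (acoef - lfc) / se
    t_left = (acoef + lfc) / se
    p = _t_sf(t_right, fit.df_total) + _t_sf(t_left, fit.df_total)
    p = np.clip(p, 0.0, 1.0)
    t = np.sign(fit.coef) * t_right
    return pd.DataFrame({"log2fc": fit.coef, "t": t, "p": p}, index=fit.features)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# significance rules
# ---------------------------------------------------------------------------

RULES = {
    # lipids/metabolites: |fold difference| > 20 % AND q < 10 %
    "analyte": {"fc_gt": 0.20, "q_lt": 0.10},
    # TREAT-tested genes: q <= 10 % (the fold threshold lives in the test)
    "gene": {"q_le": 0.10},
}


def classify_differential(
    results: pd.DataFrame, rule: Literal["analyte", "gene"] = "analyte"
) -> pd.DataFrame:
    """Apply a named significance preset to a results table.

    ``results`` must have ``log2fc`` and ``p`` columns; a ``q`` column is
    added (BH over finite p) along with ``significant`` and a ``rule``
    record of the thresholds applied.

    * ``"analyte"``: significant iff |2^log2fc - 1| > 0.20 (equivalently
      |log2fc| > log2(1.2); strictly more than a 20 % fold difference,
      symmetric on the log scale) and q < 0.10 (strict).
    * ``"gene"``: significant iff q <= 0.10 (inclusive).
    """
    out = results.copy()
    out["q"] = bh_fdr(out["p"].to_numpy())
    thr = RULES[rule]
    if rule == "analyte":
        fc_ok = np.abs(out["log2fc"]) > np.log2(1.0 + thr["fc_gt"])
        out["significant"] = fc_ok & (out["q"] < thr["q_lt"])
        out["rule"] = f"|fold-1|>{thr['fc_gt']:.2f} & q<{thr['q_lt']:.2f}"
    else:
        out["significant"] = out["q"] <= thr["q_le"]
        out["rule"] = f"q<={thr['q_le']:.2f}"
    out["significant"] &= out["q"].notna()
    return out


def differential_analysis(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: Sequence[str],
    contrast: str,
    rule: Literal["analyte", "gene"] = "analyte",
    lfc: float | None = None,
) -> pd.DataFrame:
    """Fit, moderate, test and classify in one call.

    The gene rule tests relative to a 1.2-fold change (TREAT) by default;
    the analyte rule uses the ordinary moderated t-test and applies the
    fold-change cut at classification. ``lfc`` overrides the TREAT
    threshold.
    """
    design = build_design(metadata, covariates)
    fit = moderate_variance(fit_linear_model(values, design, contrast))
    if rule == "gene":
        res = treat_test(fit, lfc=np.log2(1.2) if lfc is None else lfc)
    else:
        res = moderated_t_test(fit)
    return classify_differential(res, rule)


# ---------------------------------------------------------------------------
# surrogate variables and repeated measures
# ---------------------------------------------------------------------------


def estimate_surrogates(
    values: pd.DataFrame, design: pd.DataFrame, n_sv: int = 2
) -> pd.DataFrame:
    """Residual-SVD surrogate variables.

    Fits the known design per feature (complete data required), then takes
    the top ``n_sv`` right singular vectors of the residual matrix as
    surrogate covariates capturing unmodeled structure. A deliberately
    simple estimator; it does not iterate feature weights.
    """
    Y = values.to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("surrogate estimation requires a complete matrix")
    X = design.loc[values.columns].to_numpy(dtype=float)
    hat = X @ linalg.inv(X.T @ X) @ X.T
    resid = Y - Y @ hat.T
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    sv = vt[:n_sv].T
    return pd.DataFrame(sv, index=values.columns, columns=[f"SV{i+1}" for i in range(n_sv)])


def paired_differences(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    subject: str,
    condition: str,
    levels: tuple[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-subject differences for a balanced repeated-measures design.

    For each subject with exactly one sample at each condition level, the
    difference ``levels[1] - levels[0]`` is computed per feature; testing
    the intercept of the resulting one-sample model is the paired analogue
    of fitting the subject as a random effect. Returns (differences,
    per-subject metadata of the first level's covariates).
    """
    a_lvl, b_lvl = levels
    diffs = {}
    meta_rows = {}
    for subj, grp in metadata.groupby(subject):
        a = grp.index[grp[condition] == a_lvl]
        b = grp.index[grp[condition] == b_lvl]
        if len(a) != 1 or len(b) != 1:
            logger.info("subject %s skipped: needs exactly one sample per level", subj)
            continue
        diffs[subj] = values[b[0]] - values[a[0]]
        meta_rows[subj] = metadata.loc[a[0]]
    if not diffs:
        raise ValueError("no subject has a complete pair of condition levels")
    return pd.DataFrame(diffs), pd.DataFrame(meta_rows).T


# ---------------------------------------------------------------------------
# gene-set scores
# ---------------------------------------------------------------------------


@dataclass
class GeneSetScore:
    """Eigen-weighted single-sample activity of one gene set."""

    name: str
    scores: pd.Series  # per sample
    weights: pd.Series  # per set gene present in the matrix
    orientation_sign: int


def eigen_weighted_score(
    expr: pd.DataFrame, genes: Sequence[str], name: str = "", allow_single: bool = False
) -> GeneSetScore:
    """Single-sample gene-set activity via first-principal-component weights.

    Restricts the expression matrix (genes x samples) to the set's genes,
    mean-centers each gene, and weights genes by their loadings on the
    first principal component of the centered submatrix; a sample's score
    is the weighted average of its centered expression. The PC sign is
    oriented so the score correlates positively with the set's mean
    centered expression profile, and recorded.
    """
    present = [g for g in genes if g in expr.index]
    if len(present) < 2:
        if allow_single and len(present) == 1:
            g = present[0]
            centered = expr.loc[g] - expr.loc[g].mean()
            return GeneSetScore(name, centered, pd.Series({g: 1.0}), 1)
        raise ValueError(
            f"gene set {name!r}: {len(present)} genes present in the matrix; "
            "need >= 2 (pass allow_single=True for the single-gene fallback)"
        )
    sub = expr.loc[present].astype(float)
    centered = sub.sub(sub.mean(axis=1), axis=0)
    u, s, vt = np.linalg.svd(centered.to_numpy(), full_matrices=False)
    loadings = u[:, 0]
    pc_scores = s[0] * vt[0]
    mean_profile = centered.mean(axis=0).to_numpy()
    sign = 1
    if mean_profile.std() > 0 and np.corrcoef(pc_scores, mean_profile)[0, 1] < 0:
        sign = -1
    loadings = sign * loadings
    weights = pd.Series(loadings, index=present)
    scores = weights @ centered / np.abs(loadings).sum()
    return GeneSetScore(name, pd.Series(scores, index=expr.columns), weights, sign)


@dataclass
class EnrichmentResult:
    """Running-sum enrichment of one gene set in one ranking."""

    name: str
    es: float
    leading_edge: list[str]
    leading_edge_mean_t: float


def running_sum_enrichment(
    ranked: pd.Series, genes: Sequence[str], name: str = ""
) -> EnrichmentResult:
    """Weighted running-sum enrichment score with leading-edge extraction.

    ``ranked`` maps genes to the ranking statistic, sorted descending
    (sorted here if not). Walking down the ranking, set members increment
    the running sum by |stat| / sum of set |stat| and non-members decrement
    by 1/(N-K); the enrichment score is the extremum of largest magnitude.
    The leading edge is the set members at or before a positive extremum
    (at or after a negative one). The mean ranking statistic over the
    leading edge is reported alongside.
    """
    ranked = ranked.sort_values(ascending=False, kind="stable")
    in_set = ranked.index.isin(set(genes))
    N, K = len(ranked), int(in_set.sum())
    if K == 0 or K == N:
        raise ValueError(f"gene set {name!r} has {K} of {N} ranked genes; ES is undefined")
    absstat = np.abs(ranked.to_numpy())
    hit_sum = absstat[in_set].sum()
    if hit_sum == 0:
        raise ValueError("all set members have zero statistic; ES is undefined")
    steps = np.where(in_set, absstat / hit_sum, -1.0 / (N - K))
    running = np.cumsum(steps)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    es = running[i_max] if running[i_max] >= -running[i_min] else running[i_min]
    if es >= 0:
        le_mask = in_set & (np.arange(N) <= i_max)
    else:
        le_mask = in_set & (np.arange(N) >= i_min)
    leading = list(ranked.index[le_mask])
    mean_t = float(ranked[le_mask].mean()) if leading else np.nan
    return EnrichmentResult(name, float(es), leading, mean_t)


def leading_edge_union(results: Sequence[EnrichmentResult]) -> list[str]:
    """Union of leading-edge genes across comparisons (first-seen order)."""
    seen: dict[str, None] = {}
    for r in results:
        for g in r.leading_edge:
            seen.setdefault(g)
    return list(seen)


def leading_edge_score(t_by_gene: pd.Series, union: Sequence[str]) -> float:
    """Mean moderated t over a fixed leading-edge gene universe.

    Using one cross-comparison union makes scores comparable between
    comparisons; genes absent from ``t_by_gene`` are an error.
    """
    missing = [g for g in union if g not in t_by_gene.index]
    if missing:
        raise KeyError(f"genes missing t statistics: {missing[:5]}")
    if not len(union):
        raise ValueError("leading-edge universe is empty")
    return float(t_by_gene.loc[list(union)].mean())


def hypergeometric_overlap(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail overlap p-value, P[X >= k].

    ``k`` observed overlap between a set of size ``K`` and a set of size
    ``n`` drawn from a universe of ``N`` genes.
    """
    if not (0 <= k <= min(K, n) <= N):
        raise ValueError("need 0 <= k <= min(K, n) <= N")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def extract_signature(diff: pd.DataFrame, min_log2fc: float = 1.0) -> list[str]:
    """Genes with log2 fold change >= ``min_log2fc`` (inclusive)."""
    return list(diff.index[diff["log2fc"] >= min_log2fc])
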