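"""Negative-binomial GLM differential expression for the factorial design.

The engine mirrors the classic count-based DE workflow: median-of-ratios
size factors, per-gene dispersion by Cox-Reid-adjusted profile likelihood,
a one-factor four-level NB GLM with log link and size-factor offsets fitted
by iteratively reweighted least squares, Wald contrasts of the condition
coefficients, and Benjamini-Hochberg FDR adjustment within each contrast.

Wald statistics are referred to a t distribution with residual degrees of
freedom (samples minus conditions) rather than a standard normal: the
per-gene dispersion is itself estimated with those few degrees of freedom,
and at triplicate scale the normal reference is measurably anticonservative
in the far tail while the t reference keeps both the 5% level and the BH
step-up calibrated (see docs/methods.md).

Deliberate simplifications relative to full empirical-Bayes pipelines: no
dispersion shrinkage toward a fitted mean-dispersion trend, no outlier
refitting, no independent filtering and no fold-change shrinkage. The goal
is a calibrated Wald test on a known model, not bit-compatibility with any
particular external tool.

The model/results pair follows the statsmodels convention::

    model = NBFactorialModel(counts, design, min_total_count=10)
    res = model.fit()
    table = res.contrast("TRT_A", "VEHICLE")   # per-gene ContrastResult frame
    print(res.summary())
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm, t as t_dist

from .io import CONDITIONS, CountMatrix, ValidationError, check_design_matches

LN2 = math.log(2.0)

ALPHA_MIN = 1e-8
ALPHA_MAX = 10.0
IRLS_MAX_ITER = 50
IRLS_TOL = 1e-8
BETA_CAP = 30.0  # natural-log scale; |log2fc| cap ~ 43


class EstimationError(ValueError):
    """A model quantity cannot be estimated from the given data."""


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with no zero count in any sample. For each
    sample the factor is the median over reference genes of
    ``count / geometric mean of that gene across samples``; with an even
    reference set the midpoint convention applies.

    Raises
    ------
    EstimationError
        If no gene has all-positive counts. A pseudo-reference fallback is
        deliberately not applied silently; supply factors explicitly instead.
    """
    k = counts.counts.astype(float)
    ref = np.all(k > 0, axis=1)
    if not ref.any():
        raise EstimationError(
            "median-of-ratios is undefined: no gene has positive counts in every "
            "sample; pass size factors explicitly (no pseudo-reference fallback is applied)"
        )
    logk = np.log(k[ref])
    log_geo = logk.mean(axis=1)
    factors = np.exp(np.median(logk - log_geo[:, None], axis=0))
    return pd.Series(factors, index=list(counts.sample_ids), name="size_factor")


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def _group_indices(design: pd.DataFrame, sample_ids: Sequence[str]):
    order = {s: i for i, s in enumerate(sample_ids)}
    cond_by_sample = dict(zip(design["sample_id"], design["condition"]))
    cond = np.array([cond_by_sample[s] for s in sample_ids])
    levels = [c for c in CONDITIONS if c in set(cond)]
    groups = {c: np.flatnonzero(cond == c) for c in levels}
    del order
    return cond, levels, groups


def _profile_nll(t, y, s, mu_c_cols, group_of_col):
    """Cox-Reid-adjusted profile negative log-likelihood at log-dispersion t.

    Condition means are profiled out by plugging in the normalized group
    means; the CR term 0.5*logdet(X'WX) is, for a saturated one-factor
    design, 0.5 * sum_c log(sum_{j in c} w_j) up to an alpha-free constant.
    """
    alpha = np.exp(t)[:, None]
    mu = np.clip(mu_c_cols * s[None, :], 1e-10, None)
    r = 1.0 / alpha
    ll = (
        gammaln(y + r)
        - gammaln(r)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu))
    ).sum(axis=1)
    w = mu / (1.0 + alpha * mu)
    cr = 0.0
    for cols in group_of_col:
        cr = cr + 0.5 * np.log(np.clip(w[:, cols].sum(axis=1), 1e-300, None))
    return -ll + cr


def estimate_dispersion(
    counts: CountMatrix,
    size_factors: pd.Series,
    design: pd.DataFrame,
    *,
    alpha_min: float = ALPHA_MIN,
    alpha_max: float = ALPHA_MAX,
) -> pd.DataFrame:
    """Per-gene NB dispersion (variance = mu + alpha*mu^2).

    A method-of-moments start from the within-condition residual variance of
    normalized counts is refined by maximizing the Cox-Reid-adjusted NB
    likelihood with condition means profiled out (vectorized golden-section
    search on log alpha). Estimates are clamped to [alpha_min, alpha_max];
    ``method_flag`` records the path: MLE for the adjusted-likelihood
    optimum, FLOOR when clamped at alpha_min (including all-zero genes,
    which downstream testing excludes), MOM when the likelihood search
    failed and the moment estimate was kept.
    """
    cond, levels, groups = _group_indices(design, counts.sample_ids)
    if not any(len(ix) >= 2 for ix in groups.values()):
        raise EstimationError("dispersion estimation needs >= 2 replicates in >= 1 condition")
    y = counts.counts.astype(float)
    s = size_factors.reindex(list(counts.sample_ids)).to_numpy(float)
    q = y / s[None, :]

    n_genes, n_samples = y.shape
    mu_c = np.empty((n_genes, len(levels)))
    col_level = np.empty(n_samples, dtype=int)
    for li, c in enumerate(levels):
        ix = groups[c]
        mu_c[:, li] = q[:, ix].mean(axis=1)
        col_level[ix] = li
    mu_c_cols = mu_c[:, col_level]

    # method-of-moments start (recorded, and kept if the search fails)
    resid_df = n_samples - len(levels)
    if resid_df > 0:
        var_pool = ((q - mu_c_cols) ** 2).sum(axis=1) / resid_df
    else:
        var_pool = np.zeros(n_genes)
    mu_bar = q.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(mu_bar > 0, (var_pool - mu_bar) / mu_bar**2, 0.0)
    alpha_mom = np.clip(alpha_mom, alpha_min, alpha_max)

    all_zero = y.sum(axis=1) == 0
    group_of_col = [groups[c] for c in levels]

    lo = math.log(alpha_min)
    hi = math.log(alpha_max)
    a = np.full(n_genes, lo)
    b = np.full(n_genes, hi)
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    invphi2 = 1.0 - invphi
    c_pt = a + invphi2 * (b - a)
    d_pt = a + invphi * (b - a)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        fc = _profile_nll(c_pt, y, s, mu_c_cols, group_of_col)
        fd = _profile_nll(d_pt, y, s, mu_c_cols, group_of_col)
        for _ in range(50):
            take = fc < fd
            b = np.where(take, d_pt, b)
            a = np.where(take, a, c_pt)
            c_pt = a + invphi2 * (b - a)
            d_pt = a + invphi * (b - a)
            fc = _profile_nll(c_pt, y, s, mu_c_cols, group_of_col)
            fd = _profile_nll(d_pt, y, s, mu_c_cols, group_of_col)
    alpha_hat = np.exp((a + b) / 2.0)
    bad = ~np.isfinite(alpha_hat) | ~np.isfinite(fc) | ~np.isfinite(fd)

    alpha_hat = np.where(bad, alpha_mom, alpha_hat)
    alpha_hat = np.clip(alpha_hat, alpha_min, alpha_max)
    # the likelihood is numerically flat near the boundary; snap to the floor
    floored = (alpha_hat <= 10.0 * alpha_min) | all_zero
    alpha_hat[floored] = alpha_min

    flag = np.where(bad, "MOM", "MLE").astype(object)
    flag[floored] = "FLOOR"

    return pd.DataFrame(
        {"gene_id": list(counts.gene_ids), "alpha_hat": alpha_hat, "method_flag": flag}
    )


# ---------------------------------------------------------------------------
# BH adjustment and DE selection
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``padj_(i) = min_{j >= i} (m * p_(j) / j)`` on the sorted scale, capped at
    one and mapped back to input order. Missing entries (NaN) pass through
    and are excluded from ``m``; values outside [0, 1] raise.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    m = int(finite.sum())
    if m == 0:
        return out
    ps = p[finite]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    restored = np.empty(m)
    restored[order] = adj
    out[finite] = restored
    return out


@dataclass(frozen=True)
class DEGeneSet:
    """Genes called differentially expressed in one contrast (padj < alpha)."""

    contrast_name: str
    alpha: float
    genes: frozenset

    def __len__(self) -> int:
        return len(self.genes)


def select_de(result: pd.DataFrame, alpha: float, name: Optional[str] = None) -> DEGeneSet:
    """Strict ``padj < alpha`` selection; genes with missing padj are excluded."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    padj = result["padj"].to_numpy(float)
    keep = np.isfinite(padj) & (padj < alpha)
    genes = frozenset(result.loc[keep, "gene_id"].astype(str))
    return DEGeneSet(name or result.attrs.get("contrast", "contrast"), alpha, genes)


# ---------------------------------------------------------------------------
# the model / results pair
# ---------------------------------------------------------------------------

class NBFactorialModel:
    """One-factor negative-binomial GLM over the four-condition design.

    Parameters
    ----------
    counts : CountMatrix
        Raw integer counts, genes x samples.
    design : DataFrame
        Columns ``sample_id``, ``condition``, ``replicate``; samples must
        coincide with the count matrix columns, and every condition present
        needs at least two replicates.
    min_total_count : int
        Expression filter: genes with total raw count below this are fitted
        and reported but receive missing ``padj`` (they do not enter the
        BH adjustment).

    Notes
    -----
    The GLM uses the natural-log link internally with ``log(size factor)``
    offsets and the vehicle condition as reference level; fold-changes are
    converted to base 2 only at reporting. Every contrast is a linear
    combination of coefficients from this single fit, which keeps the
    A-vs-vehicle, B-vs-vehicle, combo-vs-vehicle and combo-vs-B results
    internally consistent.
    """

    def __init__(self, counts: CountMatrix, design: pd.DataFrame, *, min_total_count: int = 10):
        check_design_matches(counts, design)
        cond, levels, groups = _group_indices(design, counts.sample_ids)
        low = [c for c in levels if len(groups[c]) < 2]
        if low:
            raise ValidationError(
                f"differential expression needs >= 2 replicates per condition; offending: {low}"
            )
        self.counts = counts
        self.design = design.reset_index(drop=True)
        self.min_total_count = int(min_total_count)
        self._cond = cond
        self.levels = levels            # present conditions, canonical order
        self.reference = levels[0]      # VEHICLE whenever present
        self._groups = groups
        # dummy design matrix: intercept + one indicator per non-reference level
        n = counts.n_samples
        X = np.zeros((n, len(levels)))
        X[:, 0] = 1.0
        for k, c in enumerate(levels[1:], start=1):
            X[groups[c], k] = 1.0
        self.exog = X

    @classmethod
    def from_dataframes(
        cls, counts: pd.DataFrame, design: pd.DataFrame, *, min_total_count: int = 10
    ) -> "NBFactorialModel":
        """Build from a genes x samples DataFrame and a design DataFrame."""
        return cls(CountMatrix.from_frame(counts), design, min_total_count=min_total_count)

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        size_factors: Optional[pd.Series] = None,
        dispersions: Optional[pd.DataFrame] = None,
    ) -> "NBFactorialResults":
        """Estimate size factors and dispersions (unless given) and run IRLS."""
        if size_factors is None:
            size_factors = estimate_size_factors(self.counts)
        size_factors = size_factors.reindex(list(self.counts.sample_ids))
        if size_factors.isna().any() or (size_factors <= 0).any():
            raise ValidationError("size factors must be positive and cover every sample")
        if dispersions is None:
            dispersions = estimate_dispersion(self.counts, size_factors, self.design)
        disp = (
            dispersions.set_index("gene_id")["alpha_hat"]
            .reindex(list(self.counts.gene_ids))
            .to_numpy(float)
        )
        if np.any(~np.isfinite(disp)) or np.any(disp < 0):
            raise ValidationError("dispersions must be finite, >= 0, and cover every gene")

        beta, cov, converged, n_iter = self._irls(size_factors.to_numpy(float), disp)
        return NBFactorialResults(self, size_factors, dispersions, disp, beta, cov, converged, n_iter)

    def _irls(self, s: np.ndarray, alpha: np.ndarray):
        y = self.counts.counts.astype(float)
        X = self.exog
        offset = np.log(s)[None, :]
        n_genes, n_samples = y.shape
        p = X.shape[1]

        # start from group means of normalized counts
        q = y / s[None, :]
        mu_c = np.column_stack(
            [np.clip(q[:, self._groups[c]].mean(axis=1), 1e-8, None) for c in self.levels]
        )
        beta = np.empty((n_genes, p))
        beta[:, 0] = np.log(mu_c[:, 0])
        for k in range(1, p):
            beta[:, k] = np.log(mu_c[:, k]) - beta[:, 0]
        beta = np.clip(beta, -BETA_CAP, BETA_CAP)

        a = alpha[:, None]
        converged = np.zeros(n_genes, dtype=bool)
        n_iter = np.zeros(n_genes, dtype=int)
        active = np.ones(n_genes, dtype=bool)
        ridge = 1e-10 * np.eye(p)

        for it in range(IRLS_MAX_ITER):
            if not active.any():
                break
            idx = np.flatnonzero(active)
            eta = beta[idx] @ X.T + offset
            eta = np.clip(eta, -BETA_CAP - 10, BETA_CAP + 10)
            mu = np.clip(np.exp(eta), 1e-10, None)
            w = mu / (1.0 + a[idx] * mu)
            z = (eta - offset) + (y[idx] - mu) / mu
            XtWX = np.einsum("gj,ji,jk->gik", w, X, X) + ridge
            XtWz = np.einsum("gj,ji->gi", w * z, X)
            new = np.linalg.solve(XtWX, XtWz[..., None])[..., 0]
            new = np.clip(new, -BETA_CAP, BETA_CAP)
            delta = np.max(np.abs(new - beta[idx]), axis=1)
            beta[idx] = new
            n_iter[idx] = it + 1
            done = delta < IRLS_TOL
            converged[idx[done]] = True
            active[idx[done]] = False

        # observed-information covariance at the final fit
        eta = np.clip(beta @ X.T + offset, -BETA_CAP - 10, BETA_CAP + 10)
        mu = np.clip(np.exp(eta), 1e-10, None)
        w = mu / (1.0 + a * mu)
        XtWX = np.einsum("gj,ji,jk->gik", w, X, X) + 1e-12 * np.eye(p)
        cov = np.linalg.inv(XtWX)
        return beta, cov, converged, n_iter


class NBFactorialResults:
    """Fit of :class:`NBFactorialModel`: coefficients, covariances, contrasts."""

    def __init__(self, model, size_factors, dispersions, disp_vec, beta, cov, converged, n_iter):
        self.model = model
        self.size_factors = size_factors
        self.dispersions = dispersions
        self._alpha = disp_vec
        self.params = beta          # genes x levels, natural-log scale
        self.cov_params = cov
        self.converged = converged
        self.n_iter = n_iter
        s = size_factors.to_numpy(float)
        self._q = model.counts.counts.astype(float) / s[None, :]
        self.base_mean = pd.Series(
            self._q.mean(axis=1), index=list(model.counts.gene_ids), name="base_mean"
        )
        total = model.counts.counts.sum(axis=1)
        self.tested = (total >= model.min_total_count) & (total > 0)

    # -- helpers ------------------------------------------------------------

    def _level_index(self, condition: str) -> int:
        condition = str(condition).strip().upper()
        if condition not in self.model.levels:
            raise ValidationError(
                f"condition {condition!r} not present in the design; have {self.model.levels}"
            )
        return self.model.levels.index(condition)

    def _contrast_vector(self, cond: str, ref: str) -> np.ndarray:
        c = np.zeros(len(self.model.levels))
        i, j = self._level_index(cond), self._level_index(ref)
        if i == j:
            raise ValidationError("contrast conditions must differ")
        if i > 0:
            c[i] = 1.0
        if j > 0:
            c[j] = -1.0
        return c

    def _fallback_estimates(self, cond: str, ref: str):
        """Pseudo-mean group-ratio estimate with a delta-method standard error.

        Used for genes where the GLM is unreliable: complete separation (one
        group all zeros) or IRLS non-convergence. Means get +0.5 pseudocounts
        on the normalized scale; the variance of each group-mean log uses the
        NB mean-variance relation at the pseudo mean.
        """
        gi = self.model._groups[cond]
        gj = self.model._groups[ref]
        s = self.size_factors.to_numpy(float)
        m1 = self._q[:, gi].mean(axis=1) + 0.5
        m0 = self._q[:, gj].mean(axis=1) + 0.5
        lfc = np.log2(m1 / m0)

        def var_log2_mean(m, cols):
            var_q = m[:, None] / s[cols][None, :] + self._alpha[:, None] * m[:, None] ** 2
            return var_q.sum(axis=1) / (len(cols) ** 2 * m**2) / LN2**2

        se = np.sqrt(var_log2_mean(m1, gi) + var_log2_mean(m0, gj))
        return lfc, se

    # -- public surface -----------------------------------------------------

    def contrast(self, cond: str, ref: str, *, alpha_bh: Optional[float] = None) -> pd.DataFrame:
        """Wald test of ``cond`` vs ``ref`` for every gene.

        Returns a frame with columns gene_id, base_mean, log2fc, se,
        wald_stat, pvalue, padj, flag. ``padj`` is BH-adjusted within this
        contrast over genes passing the expression filter; filtered genes
        keep their log2fc but have missing padj. Genes with an all-zero
        group or a non-converged IRLS fit fall back to a flagged pseudo-mean
        group-ratio estimate rather than raising.
        """
        cvec = self._contrast_vector(cond, ref)
        lfc = (self.params @ cvec) / LN2
        var_nat = np.einsum("i,gij,j->g", cvec, self.cov_params, cvec)
        se = np.sqrt(np.clip(var_nat, 0.0, None)) / LN2

        gi = self.model._groups[str(cond).strip().upper()]
        gj = self.model._groups[str(ref).strip().upper()]
        y = self.model.counts.counts
        zero_group = (y[:, gi].sum(axis=1) == 0) | (y[:, gj].sum(axis=1) == 0)
        all_zero = y.sum(axis=1) == 0
        needs_fallback = (zero_group | ~self.converged) & ~all_zero

        flag = np.where(self.converged, "ok", "fallback_nonconv").astype(object)
        if needs_fallback.any():
            fb_lfc, fb_se = self._fallback_estimates(
                str(cond).strip().upper(), str(ref).strip().upper()
            )
            lfc = np.where(needs_fallback, fb_lfc, lfc)
            se = np.where(needs_fallback, fb_se, se)
            flag[needs_fallback & zero_group] = "fallback_zero_group"
        flag[all_zero] = "all_zero"

        with np.errstate(divide="ignore", invalid="ignore"):
            wald = np.where(se > 0, lfc / se, 0.0)
        df_resid = self.model.counts.n_samples - len(self.model.levels)
        if df_resid >= 1:
            pvalue = 2.0 * t_dist.sf(np.abs(wald), df=df_resid)
        else:  # saturated design; fall back to the asymptotic reference
            pvalue = 2.0 * norm.sf(np.abs(wald))
        lfc = np.where(all_zero, 0.0, lfc)
        se = np.where(all_zero, np.nan, se)
        wald = np.where(all_zero, np.nan, wald)
        pvalue = np.where(all_zero, np.nan, pvalue)

        p_for_bh = np.where(self.tested, pvalue, np.nan)
        padj = bh_adjust(p_for_bh)

        out = pd.DataFrame(
            {
                "gene_id": list(self.model.counts.gene_ids),
                "base_mean": self.base_mean.to_numpy(),
                "log2fc": lfc,
                "se": se,
                "wald_stat": wald,
                "pvalue": pvalue,
                "padj": padj,
                "flag": flag,
            }
        )
        out.attrs["contrast"] = f"{str(cond).strip().upper()}_vs_{str(ref).strip().upper()}"
        return out

    def de_genes(self, cond: str, ref: str, alpha: float = 0.05) -> DEGeneSet:
        table = self.contrast(cond, ref)
        return select_de(table, alpha, name=table.attrs["contrast"])

    def summary(self, alpha: float = 0.05) -> str:
        """Human-readable overview of the fit."""
        lines = [
            "NB factorial GLM fit",
            "====================",
            f"genes: {self.model.counts.n_genes}   samples: {self.model.counts.n_samples}",
            f"conditions: {', '.join(self.model.levels)} (reference {self.model.reference})",
            f"tested genes (total count >= {self.model.min_total_count}): {int(self.tested.sum())}",
            "size factors: "
            + ", ".join(f"{s}={v:.3f}" for s, v in self.size_factors.items()),
            f"dispersion median: {float(np.median(self._alpha)):.4g}",
            f"IRLS converged: {int(self.converged.sum())}/{len(self.converged)}",
        ]
        for c in self.model.levels[1:]:
            n_de = len(self.de_genes(c, self.model.reference, alpha))
            lines.append(f"DE genes {c} vs {self.model.reference} (padj < {alpha}): {n_de}")
        return "\n".join(lines)


def wald_contrast(
    counts: CountMatrix,
    size_factors: pd.Series,
    dispersions: pd.DataFrame,
    design: pd.DataFrame,
    contrast,
    *,
    min_total_count: int = 10,
) -> pd.DataFrame:
    """Functional wrapper: fit the factorial GLM and return one Wald contrast.

    ``contrast`` is an ordered pair ``(condition, reference)``.
    """
    cond, ref = contrast
    model = NBFactorialModel(counts, design, min_total_count=min_total_count)
    res = model.fit(size_factors=size_factors, dispersions=dispersions)
    return res.contrast(cond, ref)
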