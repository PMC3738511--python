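"""Two-stage mixed-model analysis of loop-design two-color arrays.

Stage 1 (normalization) fits, over all spots jointly,

    Y = mu + dye + block + array + array:dye + array:block + e

with dye and block fixed and the three array terms as independent random
components, then carries the conditional residuals
(observed - fixed prediction - BLUPs) forward.

Stage 2 fits, per transcript, on those residuals,

    r = mu + treatment + spot + dye + array + e

with treatment/spot/dye fixed and array random, and tests the treatment
term with an F statistic.  Denominator degrees of freedom use the
containment rule n - rank([X Z]) familiar from classical mixed-model
ANOVA software (it reduces to the usual residual df when the random effect
is dropped, and equals the classical df in balanced designs).

P-values are adjusted per family (overall test; each pairwise contrast
separately) with the Benjamini-Hochberg step-up, and the differential-
expression call set is thresholded on the adjusted values.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .io_design import ArrayDesign, DesignError, ExpressionMatrix
from .reml import (RemlError, conditional_residuals, dummy_matrix,
                   fit_reml, indicator_matrix)

logger = logging.getLogger(__name__)


@dataclass
class NormalizationFit:
    """Fitted global normalization model."""

    fixed_effects: pd.Series           # intercept, dye and block coefficients
    variance_components: dict          # array, array_dye, array_block, residual
    residuals: ExpressionMatrix        # same cells as the input, normalized
    dye_contrast: float                # estimated Cy3 - Cy5 difference
    converged: bool
    loglik: float

    def __post_init__(self) -> None:
        assert all(v >= 0 for v in self.variance_components.values())


@dataclass
class GeneFit:
    transcript_id: str
    f_statistic: float
    df_num: int
    df_den: float
    p_value: float
    group_means: dict                  # adjusted (least-squares) group means
    contrasts: pd.DataFrame            # pair, estimate, se, t, p
    variance_components: dict
    converged: bool
    fallback_fixed: bool = False       # random effect dropped after failure


@dataclass
class DEResult:
    table: pd.DataFrame                # transcript, F, df, p, q + contrast cols
    contrast_tables: dict              # pair label -> DataFrame(p, q)
    significant: set                   # headline DE set (overall test)
    significant_pairwise: dict         # pair label -> set
    q_threshold: float
    n_tested: int
    skipped: dict = field(default_factory=dict)  # transcript -> reason code


# --------------------------------------------------------------------------
# model-frame construction
# --------------------------------------------------------------------------

def _long_frame(expr: ExpressionMatrix, design: ArrayDesign) -> pd.DataFrame:
    df = expr.values.dropna(subset=["intensity"]).copy()
    spot_meta = design.spots.set_index("spot")
    df = df.join(spot_meta[["transcript", "duplicate_index", "block"]], on="spot")
    ch = design.channels.set_index(["array", "dye"])
    df = df.join(ch[["sample", "group"]], on=["array", "dye"])
    if df["group"].isna().any():
        raise DesignError("intensity cells reference channels not in the design")
    return df


def fit_normalization(expr: ExpressionMatrix, design: ArrayDesign) -> NormalizationFit:
    """REML fit of the global dye/block/array model; returns residuals."""
    df = _long_frame(expr, design)
    if df.empty:
        raise DesignError("no non-missing expression values to normalize")
    if df["dye"].nunique() < 2:
        raise DesignError("normalization requires both dye channels")
    if design.n_arrays < 2:
        raise DesignError("normalization requires at least two arrays")

    y = df["intensity"].to_numpy()
    dye_d, dye_levels = dummy_matrix(df["dye"].to_numpy())
    blk_d, blk_levels = dummy_matrix(df["block"].to_numpy())
    X = np.column_stack([np.ones(len(df)), dye_d, blk_d])
    names = (["intercept"]
             + [f"dye[{lv}]" for lv in dye_levels]
             + [f"block[{lv}]" for lv in blk_levels])

    Z_array, _ = indicator_matrix(df["array"].to_numpy())
    Z_ad, _ = indicator_matrix(list(zip(df["array"], df["dye"])))
    Z_ab, _ = indicator_matrix(list(zip(df["array"], df["block"])))
    Z_blocks = [Z_array, Z_ad, Z_ab]

    fit = fit_reml(y, X, Z_blocks)
    if not fit.converged:
        logger.warning("normalization REML did not report convergence")
    resid = conditional_residuals(fit, y, X, Z_blocks)
    resid_df = df[["spot", "array", "dye"]].copy()
    resid_df["intensity"] = resid

    fixed = pd.Series(fit.beta, index=names)
    # dye contrast on the Cy3 - Cy5 scale regardless of reference level
    dye_name = names[1]
    coef = float(fixed[dye_name])
    dye_contrast = coef if dye_name == "dye[Cy3]" else -coef
    return NormalizationFit(
        fixed_effects=fixed,
        variance_components={
            "array": float(fit.sigma2[0]),
            "array_dye": float(fit.sigma2[1]),
            "array_block": float(fit.sigma2[2]),
            "residual": float(fit.sigma2_resid),
        },
        residuals=ExpressionMatrix(resid_df),
        dye_contrast=dye_contrast,
        converged=fit.converged,
        loglik=fit.loglik,
    )


# --------------------------------------------------------------------------
# per-gene ANOVA
# --------------------------------------------------------------------------

class GeneSkip(Exception):
    """Raised internally when a transcript cannot support the gene model."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


def _fit_gene_core(y, groups, dups, dyes, arrays, group_order=None,
                   force_zero_array_var=False) -> dict:
    """Pure-numpy treatment/spot/dye ANOVA for one transcript.

    All inputs are 1-D arrays over the transcript's non-missing cells.
    Returns plain scalars/lists (no p-values computed here, so callers can
    vectorize the tail probabilities); raises :class:`GeneSkip` for
    degenerate transcripts.
    """
    if len(y) == 0:
        raise GeneSkip("all_missing")
    present = list(dict.fromkeys(groups))
    if group_order is not None:
        present = [g for g in group_order if g in set(present)]
    counts = {lv: int(np.sum(groups == lv)) for lv in present}
    levels = [lv for lv in present if counts[lv] >= 2]
    if len(levels) < 2:
        raise GeneSkip("fewer_than_two_groups_with_two_observations")
    if len(levels) < len(present):  # drop underpopulated groups, keep the gene
        keep = np.isin(groups, levels)
        y, groups, dups, dyes, arrays = (a[keep] for a in
                                         (y, groups, dups, dyes, arrays))

    n = len(y)
    cols = [np.ones(n)]
    for lv in levels[1:]:
        cols.append((groups == lv).astype(float))
    n_treat = len(levels) - 1
    ti = list(range(1, 1 + n_treat))
    for lv in sorted(set(dups))[1:]:
        cols.append((dups == lv).astype(float))
    for lv in sorted(set(dyes))[1:]:
        cols.append((dyes == lv).astype(float))
    X = np.column_stack(cols)
    Z_array, _ = indicator_matrix(arrays)

    fallback = False
    try:
        if force_zero_array_var:
            fit = fit_reml(y, X, [Z_array], force_gamma=[0.0])
        else:
            fit = fit_reml(y, X, [Z_array])
        if not fit.converged:
            raise RemlError("not converged")
    except RemlError:
        try:
            fit = fit_reml(y, X, [])
        except RemlError as exc:
            raise GeneSkip(f"singular_design:{exc}") from exc
        fallback = True

    p = X.shape[1]
    if fallback or force_zero_array_var:
        df_den = n - p
    else:
        df_den = n - np.linalg.matrix_rank(np.column_stack([X, Z_array]))
    df_den = max(df_den, 1)

    # overall treatment F-test: joint null on the treatment dummies
    beta_t = fit.beta[ti]
    cov_t = fit.cov_beta[np.ix_(ti, ti)]
    try:
        F = float(beta_t @ np.linalg.solve(cov_t, beta_t)) / n_treat
    except np.linalg.LinAlgError:
        raise GeneSkip("singular_treatment_covariance")

    # adjusted (least-squares) group means: effects added to the average
    # fixed prediction of the non-treatment columns
    other = [0] + list(range(1 + n_treat, p))
    base = float(np.mean(X[:, other] @ fit.beta[other]))
    group_means = {levels[0]: base}
    for j, lv in enumerate(levels[1:]):
        group_means[lv] = base + float(beta_t[j])

    # all pairwise contrasts as (pair, estimate, se, t)
    full_idx = {levels[0]: None}
    for j, lv in enumerate(levels[1:]):
        full_idx[lv] = ti[j]
    contrasts = []
    for a, b in itertools.combinations(levels, 2):
        L = np.zeros(p)
        if full_idx[a] is not None:
            L[full_idx[a]] = 1.0
        if full_idx[b] is not None:
            L[full_idx[b]] -= 1.0
        est = float(L @ fit.beta)
        se = float(np.sqrt(L @ fit.cov_beta @ L))
        t = est / se if se > 0 else np.inf * np.sign(est)
        contrasts.append((f"{a}-{b}", est, se, t))

    return {
        "F": F, "df_num": n_treat, "df_den": float(df_den),
        "group_means": group_means, "contrasts": contrasts,
        "vc_array": float(fit.sigma2[0]) if len(fit.sigma2) else 0.0,
        "vc_resid": float(fit.sigma2_resid),
        "converged": fit.converged or fallback, "fallback": fallback,
    }


def fit_gene(
    gene_residuals: pd.DataFrame,
    design: ArrayDesign,
    transcript_id: Optional[str] = None,
    force_zero_array_var: bool = False,
) -> GeneFit:
    """Treatment/spot/dye ANOVA with a random array effect for one transcript.

    *gene_residuals* is the long frame restricted to one transcript (columns
    intensity, group, duplicate_index, dye, array), typically a slice of the
    normalization residuals.  Raises :class:`GeneSkip` for degenerate
    transcripts so callers can record a reason code instead of failing.
    """
    sub = gene_residuals.dropna(subset=["intensity"])
    tid = transcript_id if transcript_id is not None else (
        str(sub["transcript"].iloc[0]) if "transcript" in sub and len(sub) else "?")
    core = _fit_gene_core(
        sub["intensity"].to_numpy(),
        sub["group"].to_numpy(),
        sub["duplicate_index"].to_numpy(),
        sub["dye"].to_numpy(),
        sub["array"].to_numpy(),
        group_order=list(dict.fromkeys(design.channels["group"])),
        force_zero_array_var=force_zero_array_var,
    )
    p_value = float(stats.f.sf(core["F"], core["df_num"], core["df_den"]))
    rows = [{"pair": pair, "estimate": est, "se": se, "t": t,
             "p": float(2 * stats.t.sf(abs(t), core["df_den"]))}
            for pair, est, se, t in core["contrasts"]]
    return GeneFit(
        transcript_id=tid, f_statistic=core["F"], df_num=core["df_num"],
        df_den=core["df_den"], p_value=p_value,
        group_means=core["group_means"], contrasts=pd.DataFrame(rows),
        variance_components={"array": core["vc_array"],
                             "residual": core["vc_resid"]},
        converged=core["converged"], fallback_fixed=core["fallback"],
    )


# --------------------------------------------------------------------------
# multiple testing
# --------------------------------------------------------------------------

def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def run_de(
    expr: ExpressionMatrix,
    design: ArrayDesign,
    q_threshold: float = 0.001,
    de_set: str = "overall",
    normalization: Optional[NormalizationFit] = None,
) -> DEResult:
    """Normalize, fit every transcript, adjust per family, and call DE genes.

    de_set="overall" declares transcripts by the overall treatment test;
    "union-pairwise" declares the union of the pairwise-contrast calls.
    """
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must be in (0, 1)")
    if de_set not in ("overall", "union-pairwise"):
        raise ValueError(f"unknown de_set {de_set!r}")
    norm = normalization if normalization is not None else fit_normalization(
        expr, design)
    frame = _long_frame(norm.residuals, design)
    group_order = list(dict.fromkeys(design.channels["group"]))

    # iterate transcripts over plain numpy arrays (the per-gene fit is the
    # hot loop: one REML optimization per transcript)
    y_all = frame["intensity"].to_numpy()
    groups_all = frame["group"].to_numpy()
    dups_all = frame["duplicate_index"].to_numpy()
    dyes_all = frame["dye"].to_numpy()
    arrays_all = frame["array"].to_numpy()
    t_codes, t_levels = pd.factorize(frame["transcript"])
    order = np.argsort(t_codes, kind="stable")
    boundaries = np.searchsorted(t_codes[order], np.arange(len(t_levels) + 1))

    results: list[tuple] = []   # (tid, core dict)
    skipped: dict = {}
    for j, tid in enumerate(t_levels):
        idx = order[boundaries[j]:boundaries[j + 1]]
        try:
            core = _fit_gene_core(
                y_all[idx], groups_all[idx], dups_all[idx], dyes_all[idx],
                arrays_all[idx], group_order=group_order)
            results.append((str(tid), core))
        except GeneSkip as exc:
            skipped[str(tid)] = exc.reason
    if not results:
        raise DesignError("no transcript could be fit")

    F = np.array([c["F"] for _, c in results])
    df_num = np.array([c["df_num"] for _, c in results])
    df_den = np.array([c["df_den"] for _, c in results])
    table = pd.DataFrame({
        "transcript": [tid for tid, _ in results],
        "F": F, "df_num": df_num, "df_den": df_den,
        "p": stats.f.sf(F, df_num, df_den),
    })
    table["q"] = bh_adjust(table["p"])

    c_rows = [(tid, pair, est, se, t, c["df_den"])
              for tid, c in results for pair, est, se, t in c["contrasts"]]
    all_contrasts = pd.DataFrame(
        c_rows, columns=["transcript", "pair", "estimate", "se", "t", "df"])
    all_contrasts["p"] = 2 * stats.t.sf(
        np.abs(all_contrasts["t"]), all_contrasts["df"])
    contrast_tables: dict = {}
    significant_pairwise: dict = {}
    for pair, ct in all_contrasts.groupby("pair", sort=True):
        ct = ct[["transcript", "estimate", "p"]].reset_index(drop=True)
        ct["q"] = bh_adjust(ct["p"])
        contrast_tables[pair] = ct
        significant_pairwise[pair] = set(
            ct.loc[ct["q"] < q_threshold, "transcript"])

    overall_set = set(table.loc[table["q"] < q_threshold, "transcript"])
    if de_set == "overall":
        significant = overall_set
    else:
        significant = set().union(*significant_pairwise.values()) \
            if significant_pairwise else set()

    logger.info("DE analysis: %d tested, %d skipped, %d significant at q<%g",
                len(results), len(skipped), len(significant), q_threshold)
    return DEResult(
        table=table, contrast_tables=contrast_tables,
        significant=significant, significant_pairwise=significant_pairwise,
        q_threshold=q_threshold, n_tested=len(results), skipped=skipped,
    )
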