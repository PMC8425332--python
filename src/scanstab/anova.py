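"""Mixed-factorial (split-plot) ANOVA for time x scanner designs.

The design has one within-subject factor (visit, k levels) and one
between-subject factor (scanner type, g groups), with possibly unbalanced
group sizes.  The implementation follows the repeated-measures GLM
formulation:

* the between effect is a one-way ANOVA on per-subject visit means (scaled
  by k, which cancels in the F ratio);
* within effects are averaged univariate tests on orthonormal contrast
  scores over visits, with Type-III (unweighted-means) hypotheses so that
  unbalanced group sizes are handled the way repeated-measures GLM software
  does;
* Mauchly's W tests sphericity of the pooled contrast covariance, and the
  Greenhouse-Geisser epsilon deflates within-subject degrees of freedom
  when sphericity is rejected.

Fisher's-LSD pairwise site comparisons within a scanner type collapse each
subject to their across-visit mean and run an unprotected pooled-variance
two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import (
    CompleteCaseMatrix,
    ConfigurationError,
    DegenerateDataError,
    MeasurementTable,
    filter_complete_cases,
)

_ZERO_TOL = 1e-12


@dataclass(frozen=True)
class EffectResult:
    """One F-test in the mixed model (possibly GG-adjusted dfs)."""

    name: str
    ss: float
    df1: float
    df2: float
    f: float
    p: float
    infinite_f: bool = False


@dataclass(frozen=True)
class MixedAnovaResult:
    """F/df/p for time, scanner and time x scanner, plus sphericity
    diagnostics.  ``scanner`` and ``interaction`` are ``None`` when the
    design has a single group."""

    time: EffectResult
    scanner: EffectResult | None
    interaction: EffectResult | None
    epsilon_gg: float
    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    gg_applied: bool
    n_complete: int
    group_sizes: dict[str, int]

    @property
    def k(self) -> int:
        return int(round(self.time.df1 / (self.epsilon_gg if self.gg_applied else 1.0))) + 1


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows, each orthogonal to the constant vector.

    Helmert-style; the within-subject sums of squares are invariant to the
    particular orthonormal basis chosen.
    """
    c = np.zeros((k - 1, k))
    for i in range(1, k):
        c[i - 1, :i] = 1.0
        c[i - 1, i] = -float(i)
        c[i - 1] /= np.linalg.norm(c[i - 1])
    return c


def _groups(matrix: CompleteCaseMatrix) -> tuple[list[str], list[np.ndarray]]:
    labels = list(dict.fromkeys(matrix.group_labels))  # first-appearance order
    idx = [np.array([g == lab for g in matrix.group_labels]) for lab in labels]
    return labels, idx


def _f_p(ss: float, df1: float, ss_err: float, df2: float) -> tuple[float, float, bool]:
    """F ratio and p; flags the infinite-F degenerate case (zero error SS)."""
    if df1 <= 0:
        return math.nan, math.nan, False
    ms = ss / df1
    if ss_err <= _ZERO_TOL:
        # zero within-subject error: the F ratio degenerates
        if ms <= _ZERO_TOL:
            return math.nan, math.nan, True
        return math.inf, 0.0, True
    ms_err = ss_err / df2
    f = ms / ms_err
    return f, float(stats.f.sf(f, df1, df2)), False


def pooled_contrast_covariance(matrix) -> tuple[np.ndarray, int]:
    """Pooled within-group covariance of orthonormal contrast scores.

    Returns ``(S, df)`` where ``df = N - g`` (``N - 1`` for a plain array
    treated as a single group).
    """
    if isinstance(matrix, CompleteCaseMatrix):
        y = matrix.values
        labels, idx = _groups(matrix)
    else:
        y = np.asarray(matrix, dtype=float)
        labels, idx = ["all"], [np.ones(y.shape[0], dtype=bool)]
    n, k = y.shape
    z = y @ _orthonormal_contrasts(k).T  # N x (k-1)
    s = np.zeros((k - 1, k - 1))
    for mask in idx:
        zg = z[mask]
        dev = zg - zg.mean(axis=0)
        s += dev.T @ dev
    df = n - len(labels)
    if df < 1:
        raise DegenerateDataError("no residual degrees of freedom for the covariance")
    return s / df, df


def mauchly_test(matrix) -> tuple[float, float, int, float]:
    """Mauchly's sphericity test on the pooled contrast covariance.

    Returns ``(W, chi2, df, p)``.  For k = 2 sphericity holds trivially and
    ``(1, 0, 0, 1)`` is returned.  The chi-square approximation uses the
    pooled-covariance degrees of freedom (N - g).
    """
    y = matrix.values if isinstance(matrix, CompleteCaseMatrix) else np.asarray(matrix, float)
    k = y.shape[1]
    if k < 2:
        raise DegenerateDataError("need k >= 2 visits")
    if k == 2:
        return 1.0, 0.0, 0, 1.0
    s, n_eff = pooled_contrast_covariance(matrix)
    d = k - 1
    sign, logdet = np.linalg.slogdet(s)
    trace = float(np.trace(s))
    if sign <= 0 or trace <= 0:
        raise DegenerateDataError("singular contrast covariance; Mauchly W undefined")
    log_w = logdet - d * math.log(trace / d)
    w = float(np.exp(log_w))
    mult = n_eff - (2 * d * d + d + 2) / (6.0 * d)
    chi2 = float(-mult * log_w)
    df = d * (d + 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, df))
    return w, chi2, df, p


def gg_epsilon(matrix) -> float:
    """Greenhouse-Geisser epsilon from the pooled contrast covariance.

    epsilon = (sum lambda)^2 / ((k-1) * sum lambda^2) over the eigenvalues
    of the pooled covariance of orthonormal contrast scores, clipped to
    [1/(k-1), 1].  Equals 1 under compound symmetry.
    """
    y = matrix.values if isinstance(matrix, CompleteCaseMatrix) else np.asarray(matrix, float)
    k = y.shape[1]
    if k < 2:
        raise DegenerateDataError("need k >= 2 visits")
    if k == 2:
        return 1.0
    s, _ = pooled_contrast_covariance(matrix)
    lam = np.linalg.eigvalsh(s)
    sum_lam = float(lam.sum())
    sum_sq = float((lam**2).sum())
    if sum_sq <= 0:
        raise DegenerateDataError("zero contrast covariance; epsilon undefined")
    eps = sum_lam**2 / ((k - 1) * sum_sq)
    return float(min(1.0, max(1.0 / (k - 1), eps)))


def mixed_anova(matrix: CompleteCaseMatrix) -> MixedAnovaResult:
    """Fit the k x g mixed model and test time, scanner and their interaction.

    Unadjusted degrees of freedom are ``(k-1, (k-1)(N-g))`` for the within
    effects and ``(g-1, N-g)`` for the between effect.  Sphericity
    diagnostics are computed here; use :func:`apply_gg_if_violated` to gate
    the Greenhouse-Geisser correction on Mauchly's p.
    """
    y = matrix.values
    n, k = y.shape
    labels, idx = _groups(matrix)
    g = len(labels)
    sizes = {lab: int(mask.sum()) for lab, mask in zip(labels, idx)}
    if any(sz < 2 for sz in sizes.values()):
        raise DegenerateDataError(f"every group needs >= 2 subjects, got {sizes}")

    # ---- between-subjects stratum: one-way ANOVA on subject means --------
    m = y.mean(axis=1)
    grand = m.mean()
    group_means = np.array([m[mask].mean() for mask in idx])
    nj = np.array([sizes[lab] for lab in labels], dtype=float)
    ss_scanner = k * float((nj * (group_means - grand) ** 2).sum())
    ss_subj_err = k * sum(float(((m[mask] - m[mask].mean()) ** 2).sum()) for mask in idx)
    scanner: EffectResult | None = None
    if g > 1:
        f, p, inf_f = _f_p(ss_scanner, g - 1, ss_subj_err, n - g)
        scanner = EffectResult("scanner", ss_scanner, float(g - 1), float(n - g), f, p, inf_f)

    # ---- within-subjects stratum: Type-III tests on contrast scores ------
    z = y @ _orthonormal_contrasts(k).T  # n x (k-1)
    zbar = np.vstack([z[mask].mean(axis=0) for mask in idx])  # g x (k-1)
    resid = z - zbar[[labels.index(lab) for lab in matrix.group_labels], :]
    ss_err = float((resid**2).sum())
    df_err = (n - g) * (k - 1)

    # time: unweighted mean of group means (Type-III intercept hypothesis)
    u = zbar.mean(axis=0)
    w_time = g * g / float((1.0 / nj).sum())
    ss_time = w_time * float((u**2).sum())
    f_t, p_t, inf_t = _f_p(ss_time, k - 1, ss_err, df_err)
    time = EffectResult("time", ss_time, float(k - 1), float(df_err), f_t, p_t, inf_t)

    interaction: EffectResult | None = None
    if g > 1:
        lmat = np.hstack([np.eye(g - 1), -np.ones((g - 1, 1))])  # group contrasts
        mid = np.linalg.inv(lmat @ np.diag(1.0 / nj) @ lmat.T)
        lz = lmat @ zbar  # (g-1) x (k-1)
        ss_int = float(np.einsum("ic,ij,jc->", lz, mid, lz))
        f_i, p_i, inf_i = _f_p(ss_int, (g - 1) * (k - 1), ss_err, df_err)
        interaction = EffectResult(
            "time x scanner", ss_int, float((g - 1) * (k - 1)), float(df_err), f_i, p_i, inf_i
        )

    try:
        w, chi2, mdf, mp = mauchly_test(matrix)
        eps = gg_epsilon(matrix)
    except DegenerateDataError:
        # zero within-subject variance: sphericity trivially satisfied
        w, chi2, mdf, mp, eps = 1.0, 0.0, max(k * (k - 1) // 2 - 1, 0), 1.0, 1.0

    return MixedAnovaResult(
        time=time,
        scanner=scanner,
        interaction=interaction,
        epsilon_gg=eps,
        mauchly_w=w,
        mauchly_chi2=chi2,
        mauchly_df=mdf,
        mauchly_p=mp,
        gg_applied=False,
        n_complete=n,
        group_sizes=sizes,
    )


def _adjust(effect: EffectResult, eps: float) -> EffectResult:
    df1, df2 = effect.df1 * eps, effect.df2 * eps
    if effect.infinite_f:
        return replace(effect, df1=df1, df2=df2)
    p = float(stats.f.sf(effect.f, df1, df2)) if np.isfinite(effect.f) else effect.p
    return replace(effect, df1=df1, df2=df2, p=p)


def apply_gg_if_violated(
    result: MixedAnovaResult,
    mauchly_p: float | None = None,
    alpha_sphericity: float = 0.05,
) -> MixedAnovaResult:
    """Apply the Greenhouse-Geisser df correction when sphericity is rejected.

    When ``mauchly_p`` (default: the result's own) falls below
    ``alpha_sphericity``, the within-subject effects' dfs are multiplied by
    epsilon and their p-values recomputed (F is unchanged).  Otherwise the
    result is returned as-is with ``gg_applied`` false.
    """
    p = result.mauchly_p if mauchly_p is None else mauchly_p
    if p >= alpha_sphericity:
        return result
    eps = result.epsilon_gg
    return replace(
        result,
        time=_adjust(result.time, eps),
        interaction=_adjust(result.interaction, eps) if result.interaction else None,
        gg_applied=True,
    )


def bonferroni_family(
    p_values: Sequence[float], c: int, alpha: float = 0.05
) -> tuple[float, list[bool]]:
    """Family-wise Bonferroni as an adjusted alpha (not adjusted p-values).

    ``c`` is the family size (the number of measures tested per effect);
    returns ``(alpha/c, [p < alpha/c ...])``.
    """
    if c < 1:
        raise ConfigurationError("family size c must be >= 1")
    if c < len(p_values):
        raise ConfigurationError(
            f"family size c={c} smaller than the number of p-values ({len(p_values)})"
        )
    adjusted = alpha / c
    return adjusted, [bool(p < adjusted) for p in p_values]


@dataclass(frozen=True)
class PairwiseComparison:
    """Fisher's-LSD site comparison within one scanner type."""

    group_a: str
    group_b: str
    mean_diff: float
    t: float
    p: float
    df: int


def lsd_site_comparison(
    table: MeasurementTable, measure: str, scanner: str, k: int | None = None
) -> PairwiseComparison:
    """Compare the two sites of one scanner type on a measure.

    Subjects with all ``k`` visits are collapsed to their across-visit mean
    and the two sites compared by an unprotected pooled-variance two-sample
    t-test (Fisher's LSD with exactly two groups), df = n1 + n2 - 2.
    """
    scanner_of = table.scanner_of_site()
    sites = sorted(s for s, sc in scanner_of.items() if sc == scanner)
    if len(sites) != 2:
        raise ConfigurationError(
            f"scanner {scanner!r} maps to {len(sites)} site(s); exactly 2 supported"
        )
    ccm = filter_complete_cases(table, measure, k=k)
    means = ccm.values.mean(axis=1)
    site_arr = np.array(ccm.site_labels)
    a, b = sites
    xa, xb = means[site_arr == a], means[site_arr == b]
    if len(xa) < 2 or len(xb) < 2:
        raise DegenerateDataError(
            f"need >= 2 complete subjects per site, got {len(xa)} at {a!r}, {len(xb)} at {b!r}"
        )
    res = stats.ttest_ind(xa, xb, equal_var=True)
    return PairwiseComparison(
        group_a=a,
        group_b=b,
        mean_diff=float(xa.mean() - xb.mean()),
        t=float(res.statistic),
        p=float(res.pvalue),
        df=len(xa) + len(xb) - 2,
    )
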