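"""Two-way random-effects intraclass correlations for absolute agreement.

The subjects x visits matrix is decomposed by a two-way ANOVA (rows =
subjects, columns = visits) into between-subject, between-visit and
residual mean squares, from which the Shrout-Fleiss absolute-agreement
forms follow:

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))
    ICC(2,k) = (MSR - MSE) / (MSR + (MSC - MSE)/n)

Both treat subjects *and* visits as random samples from larger populations,
and both penalise systematic visit effects (absolute agreement rather than
consistency).  ICC(2,k) equals the Spearman-Brown step-up of ICC(2,1) at k,
an algebraic identity of the two formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import CompleteCaseMatrix, DegenerateDataError

#: Default average-measure reliability cutpoint for calling a measure stable.
DEFAULT_CUTOFF = 0.80

_DEGENERACY_TOL = 1e-12


def _as_matrix(matrix) -> np.ndarray:
    if isinstance(matrix, CompleteCaseMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


@dataclass(frozen=True)
class MeanSquares:
    """Two-way ANOVA decomposition of a subjects x visits matrix."""

    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int

    @property
    def df_rows(self) -> int:
        return self.n - 1

    @property
    def df_cols(self) -> int:
        return self.k - 1

    @property
    def df_error(self) -> int:
        return (self.n - 1) * (self.k - 1)

    @property
    def total_ss(self) -> float:
        return (
            self.df_rows * self.ms_rows
            + self.df_cols * self.ms_cols
            + self.df_error * self.ms_error
        )

    @property
    def degenerate(self) -> bool:
        """True for a constant matrix (zero total sum of squares)."""
        return self.total_ss <= _DEGENERACY_TOL


@dataclass(frozen=True)
class IccResult:
    """Point estimates of ICC(2,1) and ICC(2,k) for one measure."""

    icc_single: float
    icc_average: float
    n: int
    k: int
    reliable_flag: bool
    negative_estimate: bool = False


def mean_squares(matrix) -> MeanSquares:
    """Decompose a complete n x k matrix into MSR, MSC and MSE.

    Accepts a :class:`~scanstab.data_model.CompleteCaseMatrix` or any 2-D
    array-like with no missing entries.  A constant matrix yields all-zero
    mean squares and is flagged via :attr:`MeanSquares.degenerate`.
    """
    y = _as_matrix(matrix)
    if y.ndim != 2:
        raise DegenerateDataError("expected a 2-D subjects x visits matrix")
    n, k = y.shape
    if n < 2 or k < 2:
        raise DegenerateDataError(f"need n >= 2 and k >= 2, got {n}x{k}")
    if np.isnan(y).any():
        raise DegenerateDataError("matrix contains missing entries")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = ss_total - ss_rows - ss_cols
    ss_error = max(ss_error, 0.0)  # guard tiny negative round-off
    return MeanSquares(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=ss_error / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def icc_absolute_single(ms: MeanSquares) -> float:
    """Single-measure two-way random-effects ICC for absolute agreement.

    The reliability of any one visit's measurement; insensitive to the
    number of visits actually made, hence the relevant quantity for designs
    with a single assessment per occasion.
    """
    n, k = ms.n, ms.k
    denom = ms.ms_rows + (k - 1) * ms.ms_error + (k / n) * (ms.ms_cols - ms.ms_error)
    if ms.degenerate:
        raise DegenerateDataError("constant matrix: ICC undefined (zero total variance)")
    if denom <= 0:
        raise DegenerateDataError("non-positive ICC denominator")
    return (ms.ms_rows - ms.ms_error) / denom


def icc_absolute_average(ms: MeanSquares) -> float:
    """Average-measure two-way random-effects ICC for absolute agreement.

    The reliability of the mean of the k visits; interpretable as the ratio
    of true-score variance to total variance for k measures.
    """
    denom = ms.ms_rows + (ms.ms_cols - ms.ms_error) / ms.n
    if ms.degenerate:
        raise DegenerateDataError("constant matrix: ICC undefined (zero total variance)")
    if denom <= 0:
        raise DegenerateDataError("non-positive ICC denominator")
    return (ms.ms_rows - ms.ms_error) / denom


def spearman_brown_stepup(icc_single: float, k: int) -> float:
    """Reliability of the average of k parallel measurements: k r / (1 + (k-1) r)."""
    if not (0.0 <= icc_single <= 1.0):
        raise ValueError("icc_single must lie in [0, 1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    return k * icc_single / (1.0 + (k - 1) * icc_single)


def classify_reliability(icc_average: float, cutoff: float = DEFAULT_CUTOFF) -> bool:
    """True when the average-measure ICC meets the stability cutpoint
    (boundary inclusive)."""
    return bool(icc_average >= cutoff)


def icc_from_matrix(matrix, cutoff: float = DEFAULT_CUTOFF) -> IccResult:
    """Compute ICC(2,1) and ICC(2,k) for a complete-case matrix.

    Negative estimates (possible when between-subject variance is below the
    residual) are reported as computed, not clipped, and flagged via
    ``negative_estimate``.
    """
    ms = mean_squares(matrix)
    single = icc_absolute_single(ms)
    average = icc_absolute_average(ms)
    return IccResult(
        icc_single=single,
        icc_average=average,
        n=ms.n,
        k=ms.k,
        reliable_flag=classify_reliability(average, cutoff),
        negative_estimate=bool(single < 0 or average < 0),
    )
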