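"""Scalar statistics for tract-profile cohort analysis.

Three families of tests live here:

* **Partial correlation** between a behavioral score and FA, controlling
  a set of covariates, computed by the residual method: both variables
  are regressed (with intercept) on the covariates and the Pearson
  correlation of the residuals is taken, with a t reference distribution
  on n - 2 - k degrees of freedom. :func:`nodewise_map` applies this at
  every node of a tract with a single listwise-deleted subject set.

* **Partially overlapping samples t-tests** (Derrick, Russ, Toher &
  White, 2017) for comparing means of two cohorts that share a subset of
  paired subjects, in equal-variance and Welch-type variants. With no
  paired subjects these reduce exactly to the ordinary independent
  t-tests, and with only paired subjects to the paired t-test.

* A **Wilcoxon rank-sum / Mann-Whitney test** with mid-ranks for ties,
  tie-corrected normal variance and a 0.5 continuity correction, as
  used for ordinal demographic comparisons (maternal education).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    CollinearityError,
    DegenerateInputError,
    SampleSizeError,
    SchemaError,
    ValidationError,
)
from .profiles import TractProfileDataset


# ---------------------------------------------------------------------------
# Partial correlation
# ---------------------------------------------------------------------------

@dataclass
class PartialCorrelationResult:
    r: float
    t_stat: float
    df: int
    p: float
    n: int
    k: int


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Intercept-augmented design matrix; raises on rank deficiency."""
    if covariates is None or covariates.size == 0:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    if C.shape[0] != n:
        raise ValidationError("covariates must have one row per observation")
    X = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("covariate matrix is rank-deficient with intercept")
    return X


def residualize(v: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Least-squares residual of v (vector or matrix of columns) on X."""
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlation(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | None = None,
) -> PartialCorrelationResult:
    """Partial Pearson correlation of x and y given covariates.

    Residualizes x and y on (intercept, covariates) and correlates the
    residuals; with no covariates this is the plain Pearson correlation.
    The two-tailed p-value uses t = r * sqrt((n-2-k) / (1-r^2)) on
    n - 2 - k degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D vectors of equal length")
    n = len(x)
    X = _design(covariates, n)
    k = X.shape[1] - 1
    if n <= k + 2:
        raise SampleSizeError(f"need n > k + 2 (n={n}, k={k})")
    rx = residualize(x, X)
    ry = residualize(y, X)
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    # relative threshold: residuals of a variable on a design containing it
    # are pure rounding noise, many orders below any real residual variance
    if sx <= 1e-12 * max(1.0, float(x @ x)) or sy <= 1e-12 * max(1.0, float(y @ y)):
        raise DegenerateInputError("zero residual variance in x or y")
    r = float(rx @ ry / np.sqrt(sx * sy))
    r = min(1.0, max(-1.0, r))
    df = n - 2 - k
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * sps.t.sf(abs(t), df)
    return PartialCorrelationResult(r=r, t_stat=float(t), df=df, p=float(p), n=n, k=k)


def partial_correlation_map(
    x: np.ndarray, Y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized node-wise partial correlation.

    Parameters
    ----------
    x : (n,) score vector (not yet residualized)
    Y : (n, m) matrix of FA columns, already residualized on X
    X : (n, 1 + k) intercept-augmented design

    Returns (r, p) arrays of length m. This is the inner loop of both the
    observed node-wise map and the permutation null, so it avoids any
    per-node Python work: one least-squares solve for x, then a single
    matrix product against the pre-residualized FA columns.
    """
    n = len(x)
    rx = residualize(x, X)
    sx = float(rx @ rx)
    sy = np.einsum("ij,ij->j", Y, Y)
    # numerically-constant columns leave only rounding noise as residual
    if sx <= 1e-12 * max(1.0, float(x @ x)) or np.any(sy <= n * 1e-24):
        raise DegenerateInputError("zero residual variance in score or FA column")
    r = (rx @ Y) / np.sqrt(sx * sy)
    r = np.clip(r, -1.0, 1.0)
    df = len(x) - 2 - (X.shape[1] - 1)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * sps.t.sf(np.abs(t), df)
    return r, p


@dataclass
class NodewiseMap:
    """Per-node partial-correlation results for one (tract, measure) pair."""

    tract: str
    measure: str
    controls: tuple[str, ...]
    r: np.ndarray          # (n_nodes,)
    p: np.ndarray          # (n_nodes,)
    n: int
    k: int
    subjects: tuple[str, ...] = field(default=(), repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.r)

    @property
    def df(self) -> int:
        return self.n - 2 - self.k

    def result_at(self, node: int) -> PartialCorrelationResult:
        """Result for a 1-based node index."""
        r = float(self.r[node - 1])
        df = self.df
        t = np.inf * np.sign(r) if abs(r) >= 1 else r * np.sqrt(df / (1 - r * r))
        return PartialCorrelationResult(
            r=r, t_stat=float(t), df=df, p=float(self.p[node - 1]), n=self.n, k=self.k
        )


def usable_subjects(
    dataset: TractProfileDataset,
    subjects: pd.DataFrame,
    tracts: Sequence[str],
    measure: str,
    controls: Sequence[str],
) -> pd.DataFrame:
    """Rows of the subject table usable for a comparison, listwise.

    Keeps subjects with a complete profile on every tract in ``tracts``
    and non-missing measure and controls; the same set is then used at
    every node so clusters are comparable along the tract.
    """
    for col in ("subjectID", measure, *controls):
        if col not in subjects.columns:
            raise SchemaError(f"subject table lacks required column {col!r}")
    in_data = set(dataset.subjects)
    sub = subjects[subjects["subjectID"].isin(in_data)].copy()
    cols = [measure, *controls]
    sub = sub[~sub[cols].isna().any(axis=1)]
    for tract in tracts:
        fa = dataset.tract_matrix(tract, list(sub["subjectID"]))
        sub = sub[~np.isnan(fa[:, 0])]
    return sub.reset_index(drop=True)


def nodewise_map(
    dataset: TractProfileDataset,
    subjects: pd.DataFrame,
    tract: str,
    measure: str,
    controls: Sequence[str] = (),
) -> NodewiseMap:
    """Node-wise partial correlation between a score and a tract's FA.

    Subjects with any missing value among the measure, the controls or
    the tract profile are dropped once, listwise, so every node uses the
    identical subject set.
    """
    controls = tuple(controls)
    sub = usable_subjects(dataset, subjects, [tract], measure, controls)
    k = len(controls)
    if len(sub) < k + 3:
        raise SampleSizeError(
            f"only {len(sub)} usable subjects for {tract}/{measure} (need >= {k + 3})"
        )
    ids = list(sub["subjectID"])
    Y = dataset.tract_matrix(tract, ids)
    x = sub[measure].to_numpy(dtype=float)
    X = _design(sub[list(controls)].to_numpy(dtype=float) if controls else None, len(sub))
    Yres = residualize(Y, X)
    r, p = partial_correlation_map(x, Yres, X)
    return NodewiseMap(
        tract=tract, measure=measure, controls=controls,
        r=r, p=p, n=len(sub), k=k, subjects=tuple(ids),
    )


# ---------------------------------------------------------------------------
# Partially overlapping samples t-tests
# ---------------------------------------------------------------------------

@dataclass
class PartoverResult:
    t_stat: float
    df: float
    p: float
    variant: str
    n1: int
    n2: int
    nc: int
    na: int
    nb: int
    r_paired: float


def partover_t(
    group1: Sequence[float],
    group2: Sequence[float],
    keys1: Sequence | None = None,
    keys2: Sequence | None = None,
    variant: str = "equal_variance",
) -> PartoverResult:
    """Partially overlapping samples t-test (Derrick et al., 2017).

    ``keys1``/``keys2`` identify subjects; observations sharing a key
    across the two groups form the paired subset (nc pairs), the rest
    are independent (na, nb). ``variant`` is ``"equal_variance"`` (pooled
    SD) or ``"welch"``.

    Equal-variance statistic::

        t = (m1 - m2) / (sp * sqrt(1/n1 + 1/n2 - 2 r nc / (n1 n2)))

    with sp the pooled SD and r the Pearson correlation of the paired
    observations; degrees of freedom

        nu1 = (nc - 1) + ((na + nb + nc - 1) / (na + nb + 2 nc)) (na + nb).

    The Welch-type variant replaces the pooled denominator with
    sqrt(s1^2/n1 + s2^2/n2 - 2 r nc s1 s2 / (n1 n2)) and interpolates the
    Welch-Satterthwaite df the same way. Both reduce exactly to the
    pooled/Welch independent tests when nc = 0 and to the paired t-test
    when na = nb = 0.
    """
    if variant not in ("equal_variance", "welch"):
        raise ValidationError(f"unknown variant {variant!r}")
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise SampleSizeError("each group needs at least 2 observations")
    if keys1 is None or keys2 is None:
        pairs1 = np.array([], dtype=int)
        pairs2 = np.array([], dtype=int)
    else:
        if len(keys1) != n1 or len(keys2) != n2:
            raise ValidationError("keys must align with group values")
        pos2 = {k: i for i, k in enumerate(keys2)}
        pairs1 = np.array([i for i, k in enumerate(keys1) if k in pos2], dtype=int)
        pairs2 = np.array([pos2[keys1[i]] for i in pairs1], dtype=int)
    nc = len(pairs1)
    na, nb = n1 - nc, n2 - nc

    if nc == 0:
        r = 0.0
    elif nc == 1:
        raise DegenerateInputError("exactly one paired observation: r undefined")
    else:
        d1, d2 = x1[pairs1], x2[pairs2]
        if np.std(d1) == 0.0 or np.std(d2) == 0.0:
            if na == 0 and nb == 0 and np.std(d1 - d2) == 0.0:
                raise DegenerateInputError("zero difference variance in fully paired data")
            r = 0.0
        else:
            r = float(np.corrcoef(d1, d2)[0, 1])

    m1, m2 = x1.mean(), x2.mean()
    v1 = float(np.var(x1, ddof=1))
    v2 = float(np.var(x2, ddof=1))
    s1, s2 = np.sqrt(v1), np.sqrt(v2)

    if variant == "equal_variance":
        sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
        denom = sp * np.sqrt(1.0 / n1 + 1.0 / n2 - 2.0 * r * nc / (n1 * n2))
        df = (nc - 1) + ((na + nb + nc - 1) / (na + nb + 2 * nc)) * (na + nb)
    else:
        denom = np.sqrt(v1 / n1 + v2 / n2 - 2.0 * r * nc * s1 * s2 / (n1 * n2))
        gamma = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
        df = (nc - 1) + (gamma - nc + 1) * (na + nb) / (na + nb + 2 * nc)
    if denom == 0.0:
        raise DegenerateInputError("zero variance: t statistic undefined")
    t = float((m1 - m2) / denom)
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PartoverResult(
        t_stat=t, df=float(df), p=p, variant=variant,
        n1=n1, n2=n2, nc=nc, na=na, nb=nb, r_paired=r,
    )


# ---------------------------------------------------------------------------
# Rank-sum test
# ---------------------------------------------------------------------------

@dataclass
class RankSumResult:
    w_stat: float
    z: float
    p: float
    n1: int
    n2: int


def ranksum_test(group1: Sequence[float], group2: Sequence[float]) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, normal approximation.

    Ties receive mid-ranks; W is the Mann-Whitney statistic (rank sum of
    group 1 minus n1(n1+1)/2); the normal deviate uses the tie-corrected
    variance

        Var = (n1 n2 / 12) * ((N + 1) - sum(t^3 - t) / (N (N - 1)))

    and a 0.5 continuity correction, two-tailed.
    """
    x1 = np.asarray(group1, dtype=float)
    x2 = np.asarray(group2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x1, x2])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    N = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var == 0.0:
        raise DegenerateInputError("all observations tied: variance is zero")
    mu = n1 * n2 / 2.0
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * sps.norm.sf(z)))
    return RankSumResult(w_stat=w, z=float(np.sign(w - mu) * z), p=p, n1=n1, n2=n2)
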