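"""Contiguous-cluster detection and permutation-based FWE correction.

Node-wise p-maps along a tract are reduced to *clusters*: maximal runs
of adjacent nodes that are suprathreshold (p < alpha_node, two-tailed)
with a consistent correlation sign. Family-wise error over all nodes,
tracts and comparisons in a family is controlled by the max-statistic
permutation method: the behavioral score is shuffled across subjects,
the node-wise maps recomputed, and the size of the largest cluster
anywhere in the family recorded per permutation. The upper alpha
quantile of that null distribution gives a critical cluster size; an
observed cluster at least that large is FWE-significant without further
p-value adjustment. A more lenient, uncorrected decision rule (>= 9
adjacent nodes at 100-node resolution, >= 3 at 30) is also provided for
exploratory reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SampleSizeError, ValidationError
from .stats import (
    NodewiseMap,
    _design,
    partial_correlation_map,
    residualize,
    usable_subjects,
)
from .profiles import TractProfileDataset

#: default lenient adjacent-node rules per profile resolution
LENIENT_MIN_SIZE: dict[int, int] = {100: 9, 30: 3}


@dataclass
class Cluster:
    tract: str
    node_start: int      # 1-based inclusive
    node_end: int        # 1-based inclusive
    size: int
    sign: str            # "positive" | "negative"
    min_p: float
    mean_r: float
    measure: str = ""
    controls: tuple[str, ...] = ()


@dataclass
class PermutationNull:
    max_sizes: np.ndarray       # (n_perm,) int
    n_perm: int
    alpha_node: float
    seed: int
    family: tuple[tuple[str, str, tuple[str, ...]], ...]
    scheme: str = "labels"


@dataclass
class ClusterDecision:
    cluster: Cluster
    fwe_significant: bool
    lenient_significant: bool
    critical_size: int


# ---------------------------------------------------------------------------
# Cluster detection
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Start/stop (0-based, half-open) of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def find_clusters(map: NodewiseMap, alpha_node: float) -> list[Cluster]:
    """Maximal sign-consistent suprathreshold runs, ordered by start node.

    A run of nodes with p < alpha_node is split wherever the correlation
    sign changes, so every reported cluster has a single sign.
    """
    if not (0.0 < alpha_node < 1.0) and alpha_node != 0.0:
        raise ValidationError("alpha_node must lie in [0, 1)")
    supra = map.p < alpha_node
    clusters: list[Cluster] = []
    for start, stop in _runs(supra):
        signs = np.sign(map.r[start:stop])
        # split the run at sign changes
        cut = start
        for j in range(start + 1, stop + 1):
            if j == stop or signs[j - start] != signs[cut - start]:
                clusters.append(Cluster(
                    tract=map.tract,
                    node_start=cut + 1,
                    node_end=j,
                    size=j - cut,
                    sign="positive" if map.r[cut] >= 0 else "negative",
                    min_p=float(map.p[cut:j].min()),
                    mean_r=float(map.r[cut:j].mean()),
                    measure=map.measure,
                    controls=map.controls,
                ))
                cut = j
    return clusters


def max_cluster_size(p: np.ndarray, r: np.ndarray, alpha_node: float) -> int:
    """Largest sign-consistent suprathreshold run length in one map."""
    supra = p < alpha_node
    best = 0
    for start, stop in _runs(supra):
        signs = np.sign(r[start:stop])
        changes = np.flatnonzero(np.diff(signs) != 0)
        bounds = np.concatenate([[0], changes + 1, [stop - start]])
        best = max(best, int(np.diff(bounds).max()))
    return best


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def build_max_cluster_null(
    dataset: TractProfileDataset,
    subjects: pd.DataFrame,
    family: Sequence[tuple[str, str, Sequence[str]]],
    alpha_node: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    scheme: str = "labels",
) -> PermutationNull:
    """Null distribution of the family-wise maximum cluster size.

    ``family`` lists (tract, measure, controls) comparisons searched
    jointly. Per permutation one subject shuffle is drawn and applied to
    the measure column of every comparison, the node-wise partial
    correlations are recomputed, and the maximum sign-consistent
    suprathreshold cluster size over all comparisons is recorded (0 when
    nothing is suprathreshold).

    All comparisons in a family must share the same listwise-deleted
    subject set (the planned families differ only in tract, so this
    holds by construction); otherwise the joint shuffle would not be
    well defined.

    ``scheme`` selects what is shuffled: ``"labels"`` permutes the raw
    measure across subjects, holding FA and covariates fixed;
    ``"freedman_lane"`` permutes the residuals of the measure on the
    covariates and adds back the fitted values, preserving the
    measure-covariate relation under the null.

    Permutation i draws its shuffle from an independent substream of the
    master seed, so results do not depend on execution order.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not family:
        raise ValidationError("family must be non-empty")
    if scheme not in ("labels", "freedman_lane"):
        raise ValidationError(f"unknown permutation scheme {scheme!r}")

    family = tuple((t, m, tuple(c)) for t, m, c in family)

    # one shared subject set across the family
    sets = []
    for tract, measure, controls in family:
        sub = usable_subjects(dataset, subjects, [tract], measure, controls)
        sets.append(tuple(sub["subjectID"]))
    ids = sets[0]
    if any(s != ids for s in sets[1:]):
        raise ValidationError(
            "comparisons in a permutation family must share a subject set"
        )
    sub = subjects.set_index("subjectID").loc[list(ids)].reset_index()
    n = len(ids)

    # precompute fixed pieces per comparison
    prepared = []
    for tract, measure, controls in family:
        k = len(controls)
        if n < k + 3:
            raise SampleSizeError(
                f"only {n} usable subjects for {tract}/{measure} (need >= {k + 3})"
            )
        X = _design(
            sub[list(controls)].to_numpy(dtype=float) if controls else None, n
        )
        Y = dataset.tract_matrix(tract, list(ids))
        Yres = residualize(Y, X)
        x = sub[measure].to_numpy(dtype=float)
        if scheme == "freedman_lane":
            xres = residualize(x, X)
            xfit = x - xres
        else:
            xres = xfit = None
        prepared.append((x, xres, xfit, X, Yres))

    max_sizes = np.zeros(n_perm, dtype=int)
    for i in range(n_perm):
        rng = np.random.default_rng([seed, i])
        perm = rng.permutation(n)
        best = 0
        for x, xres, xfit, X, Yres in prepared:
            xp = xfit + xres[perm] if scheme == "freedman_lane" else x[perm]
            r, p = partial_correlation_map(xp, Yres, X)
            best = max(best, max_cluster_size(p, r, alpha_node))
        max_sizes[i] = best
    return PermutationNull(
        max_sizes=max_sizes, n_perm=n_perm, alpha_node=alpha_node,
        seed=seed, family=family, scheme=scheme,
    )


def fwe_critical_size(null: PermutationNull, alpha_fwe: float = 0.05) -> int:
    """Smallest cluster size c with P_null(max size >= c) <= alpha_fwe.

    The threshold is the smallest *observed* null maximum whose
    exceedance proportion (ties included) is at most alpha_fwe — a
    conservative tie-handling choice, with no percentile interpolation.
    When no observed value qualifies (e.g. every permutation yields 0),
    the critical size is one more than the largest null maximum: any
    observed cluster larger than everything in the null is significant.
    """
    if not (0.0 < alpha_fwe < 1.0):
        raise ValidationError("alpha_fwe must lie in (0, 1)")
    sizes = np.sort(null.max_sizes)
    n = len(sizes)
    for c in np.unique(sizes):
        if c == 0:
            continue
        exceed = n - np.searchsorted(sizes, c, side="left")
        if exceed / n <= alpha_fwe:
            return int(c)
    return int(sizes[-1]) + 1


def classify_clusters(
    clusters: Sequence[Cluster],
    critical_size: int,
    n_nodes_resolution: int,
    lenient_min_size: Mapping[int, int] = LENIENT_MIN_SIZE,
) -> list[ClusterDecision]:
    """Apply the stringent (FWE) and lenient (adjacent-node) rules."""
    if n_nodes_resolution not in lenient_min_size:
        raise ConfigurationError(
            f"no lenient adjacent-node rule configured for resolution "
            f"{n_nodes_resolution}"
        )
    lenient = lenient_min_size[n_nodes_resolution]
    return [
        ClusterDecision(
            cluster=c,
            fwe_significant=c.size >= critical_size,
            lenient_significant=c.size >= lenient,
            critical_size=critical_size,
        )
        for c in clusters
    ]


def decisions_frame(decisions: Sequence[ClusterDecision]) -> pd.DataFrame:
    """Tabular cluster report (one row per cluster decision)."""
    rows = []
    for d in decisions:
        c = d.cluster
        rows.append({
            "comparison": f"{c.tract}~{c.measure}",
            "tract": c.tract,
            "node_start": c.node_start,
            "node_end": c.node_end,
            "size": c.size,
            "sign": c.sign,
            "mean_r": c.mean_r,
            "min_p": c.min_p,
            "critical_size": d.critical_size,
            "fwe_significant": d.fwe_significant,
            "lenient_significant": d.lenient_significant,
        })
    return pd.DataFrame(rows, columns=[
        "comparison", "tract", "node_start", "node_end", "size", "sign",
        "mean_r", "min_p", "critical_size", "fwe_significant",
        "lenient_significant",
    ])
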