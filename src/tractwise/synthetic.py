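"""Synthetic cohorts of tract profiles, scores and streamline bundles.

The generator emulates the statistical structure the node-wise analysis
assumes: two partially overlapping age cohorts, smooth FA profiles over
equidistant nodes, behavioral scores on their standardized scales with
covariates (age, nonverbal IQ), and — optionally — an embedded partial
correlation between one score and FA inside a chosen node window.

The embedded effect is calibrated analytically, not by tuning: FA in
the window receives an additive term b * z, where z is the standardized
residual of the score on the effect's control covariates and

    b = rho / sqrt(1 - rho^2) * sigma_win,

with sigma_win the exact standard deviation of the window-mean FA noise
(subject offset plus Gaussian-smoothed node noise, whose window-mean
variance follows from the smoothing kernel's autocorrelation). The
population partial correlation of the window-mean FA with the score,
given those controls, is then exactly rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .profiles import StreamlineBundle, TractProfileDataset, resample_streamline

COHORTS = ("young", "old")

#: default per-measure (mean, sd) per cohort, on each test's reporting scale
DEFAULT_SCORE_MEANS: dict[str, tuple[float, float]] = {
    "elision_raw": (11.5, 11.0),
    "wordclasses_raw": (12.8, 12.0),
    "wid_raw": (122.5, 115.5),
    "core_language": (114.7, 103.7),
}
DEFAULT_SCORE_SDS: dict[str, tuple[float, float]] = {
    "elision_raw": (2.1, 2.8),
    "wordclasses_raw": (3.3, 3.3),
    "wid_raw": (16.0, 12.3),
    "core_language": (12.1, 14.0),
}

#: maternal-education level probabilities (levels 1..5 plus missing)
MATERNAL_ED_PROBS = (0.08, 0.14, 0.045, 0.43, 0.265, 0.04)

DEFAULT_TRACTS = ("Left Arcuate", "Left SLF", "Left IFOF", "Left ILF")


@dataclass
class EffectSpec:
    """An embedded score-FA partial correlation in one node window.

    ``controls`` names the covariate columns the correlation is partial
    to; the analysis recovering the effect should control the same set.
    """

    tract: str
    measure: str
    node_window: tuple[int, int]     # 1-based inclusive
    rho: float
    controls: tuple[str, ...] = ("age", "nviq")
    cohorts: tuple[str, ...] = COHORTS


@dataclass
class BundleSpec:
    """Generator settings for a jittered streamline bundle."""

    n_streamlines: int
    n_points: int
    centerline: np.ndarray                         # (k, 3) control points, mm
    spread_sd: float                               # mm lateral dispersion
    fa_field: Callable[[np.ndarray], np.ndarray] | float = 0.45
    fa_noise_sd: float = 0.02
    jitter_smoothness: float = 5.0                 # points; smooth offsets

    def validate(self) -> None:
        if self.n_streamlines < 2:
            raise ValidationError("n_streamlines must be >= 2")
        if self.n_points < 2:
            raise ValidationError("n_points must be >= 2")
        if self.spread_sd < 0:
            raise ValidationError("spread_sd must be >= 0")
        pts = np.asarray(self.centerline, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValidationError("centerline needs >= 2 control points in 3-D")
        if np.linalg.norm(np.diff(pts, axis=0), axis=1).sum() == 0.0:
            raise ValidationError("centerline has zero length")


@dataclass
class CohortSpec:
    """Study-level generator settings.

    Defaults mirror the cohort structure of the motivating study: 81
    five-year-olds and 164 seven-year-olds with 45 children observed at
    both ages, scores on the scaled/standard scales of the behavioral
    battery, and FA profiles over 100 nodes in the 0.3-0.6 range. The
    profile correlation length of 3 nodes is chosen so that the
    max-cluster-size permutation null at 100-node resolution yields FWE
    critical sizes around 15 nodes, the regime the along-tract FWE
    procedure operates in on real AFQ profiles.
    """

    n_young: int = 81
    n_old: int = 164
    n_overlap: int = 45
    score_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_MEANS))
    score_sds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_SDS))
    age_range_young: tuple[float, float] = (5.0, 6.3)
    age_range_old: tuple[float, float] = (7.0, 8.3)
    nviq_mean: float = 107.0
    nviq_sd: float = 16.0
    profile_mean_level: float = 0.45
    profile_smoothness: float = 3.0       # correlation length, nodes
    subject_sd: float = 0.03              # FA units, per-subject offset
    node_noise_sd: float = 0.04           # FA units, smooth along-tract noise
    effects: tuple[EffectSpec, ...] = ()
    n_nodes: int = 100
    tracts: tuple[str, ...] = DEFAULT_TRACTS
    measure_correlation: float = 0.3      # shared-factor correlation of scores
    pairing_correlation: float = 0.6      # same measure across cohorts, paired
    round_scores: bool = True

    def validate(self) -> None:
        if self.n_overlap > min(self.n_young, self.n_old):
            raise ValidationError("n_overlap exceeds a cohort size")
        if self.n_overlap < 0 or self.n_young < 1 or self.n_old < 1:
            raise ValidationError("cohort sizes must be positive")
        if self.n_nodes < 2:
            raise ValidationError("n_nodes must be >= 2")
        if not (0.0 < self.profile_mean_level < 1.0):
            raise ValidationError("profile_mean_level must lie in (0, 1)")
        for name, sds in self.score_sds.items():
            if min(sds) <= 0:
                raise ValidationError(f"score_sds[{name!r}] must be > 0")
        if self.nviq_sd <= 0 or self.subject_sd <= 0 or self.node_noise_sd <= 0:
            raise ValidationError("all SDs must be > 0")
        if not (0 <= self.measure_correlation < self.pairing_correlation < 1):
            raise ValidationError(
                "need 0 <= measure_correlation < pairing_correlation < 1")
        for eff in self.effects:
            if eff.tract not in self.tracts:
                raise ValidationError(
                    f"effect tract {eff.tract!r} not in tracts")
            if eff.measure not in self.score_means:
                raise ValidationError(
                    f"effect measure {eff.measure!r} not in score_means")
            lo, hi = eff.node_window
            if not (1 <= lo <= hi <= self.n_nodes):
                raise ValidationError(
                    f"effect node_window {eff.node_window} outside "
                    f"[1, {self.n_nodes}]")
            if not abs(eff.rho) < 1:
                raise ValidationError("effect rho must satisfy |rho| < 1")
            for c in eff.controls:
                if c not in ("age", "nviq") and c not in self.score_means:
                    raise ValidationError(
                        f"effect control {c!r} is not a generated column")


# ---------------------------------------------------------------------------
# Smooth noise machinery
# ---------------------------------------------------------------------------

def _gauss_kernel(smoothness: float) -> np.ndarray:
    """Gaussian kernel with unit L2 norm, so filtered white noise keeps
    its marginal variance."""
    half = max(1, int(np.ceil(4 * smoothness)))
    t = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (t / smoothness) ** 2)
    return w / np.linalg.norm(w)


def _smooth_noise(rng: np.random.Generator, n_rows: int, n_nodes: int,
                  smoothness: float, sd: float) -> np.ndarray:
    """Stationary Gaussian-smoothed white noise, per-node SD exactly ``sd``."""
    w = _gauss_kernel(smoothness)
    pad = len(w) - 1
    white = rng.standard_normal((n_rows, n_nodes + pad))
    out = np.empty((n_rows, n_nodes))
    for i in range(n_rows):
        out[i] = np.convolve(white[i], w, mode="valid")
    return sd * out


def _window_mean_noise_sd(spec: CohortSpec, window: tuple[int, int]) -> float:
    """Exact SD of the window-mean of the FA noise field.

    The smoothed noise has autocorrelation rho(d) = sum_m w_m w_{m+d}
    for the unit-norm kernel w; the window mean of the node noise plus
    the per-subject offset has variance

        subject_sd^2 + node_noise_sd^2 * mean_{j,k in W} rho(|j - k|).
    """
    w = _gauss_kernel(spec.profile_smoothness)
    width = window[1] - window[0] + 1
    acf = np.correlate(w, w, mode="full")[len(w) - 1:]  # rho(0..len-1)
    total = 0.0
    for d in range(width):
        r = acf[d] if d < len(acf) else 0.0
        count = width if d == 0 else 2 * (width - d)
        total += count * r
    var_nodes = spec.node_noise_sd**2 * total / width**2
    return float(np.sqrt(spec.subject_sd**2 + var_nodes))


def _mean_profile(spec: CohortSpec, tract_idx: int) -> np.ndarray:
    """Smooth deterministic mean FA profile, distinct per tract."""
    t = np.linspace(0.0, 1.0, spec.n_nodes)
    phase = 0.9 * tract_idx
    shape = 0.06 * np.sin(2 * np.pi * (t + 0.1 * phase)) \
        + 0.04 * np.cos(np.pi * t + phase)
    return np.clip(spec.profile_mean_level + shape, 0.05, 0.95)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _residualize_scores(sub: pd.DataFrame, measure: str,
                        controls: Sequence[str]) -> np.ndarray:
    """Standardized residual of a score on (intercept, controls)."""
    y = sub[measure].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in controls])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    res = y - X @ beta
    sd = res.std(ddof=1)
    if sd == 0.0:
        raise ValidationError(f"score {measure!r} has zero residual variance")
    return res / sd


def generate_cohort(
    spec: CohortSpec, seed: int
) -> tuple[TractProfileDataset, pd.DataFrame]:
    """Generate a synthetic two-cohort dataset.

    Returns the profile dataset (one row per subject-cohort observation,
    ``subjectID = "<key>_<cohort>"``) and the subject table with columns
    subjectKey, subjectID, cohort, age, nviq, the score columns of
    ``spec.score_means``, maternal_ed (1-5, NaN for missing),
    right_handed, mainstream_english and diagnosis.

    Deterministic given (spec, seed): identical inputs give bitwise
    identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    n_total_keys = spec.n_young + spec.n_old - spec.n_overlap
    keys = [f"s{i:04d}" for i in range(n_total_keys)]
    # first n_overlap keys are in both cohorts
    young_keys = keys[:spec.n_young]
    old_keys = keys[:spec.n_overlap] + keys[spec.n_young:]
    assert len(old_keys) == spec.n_old

    measures = list(spec.score_means)
    m_rho = spec.measure_correlation
    extra = spec.pairing_correlation - m_rho

    # latent structure shared across cohorts for paired subjects:
    # common ability factor (per key) + per-(key, measure) stable factor
    common = {k: rng.standard_normal() for k in keys}
    stable = {(k, m): rng.standard_normal() for k in keys for m in measures + ["nviq"]}

    rows = []
    for cohort, cohort_keys in (("young", young_keys), ("old", old_keys)):
        ci = 0 if cohort == "young" else 1
        lo, hi = spec.age_range_young if cohort == "young" else spec.age_range_old
        for k in cohort_keys:
            z_common = common[k]
            row = {
                "subjectKey": k,
                "subjectID": f"{k}_{cohort}",
                "cohort": cohort,
                "age": round(float(rng.uniform(lo, hi)), 2),
            }
            z = (np.sqrt(m_rho) * z_common
                 + np.sqrt(extra) * stable[(k, "nviq")]
                 + np.sqrt(1 - m_rho - extra) * rng.standard_normal())
            row["nviq"] = float(np.round(spec.nviq_mean + spec.nviq_sd * z))
            for m in measures:
                z = (np.sqrt(m_rho) * z_common
                     + np.sqrt(extra) * stable[(k, m)]
                     + np.sqrt(1 - m_rho - extra) * rng.standard_normal())
                val = spec.score_means[m][ci] + spec.score_sds[m][ci] * z
                row[m] = float(np.round(val)) if spec.round_scores else float(val)
            rows.append(row)
    sub = pd.DataFrame(rows)

    # maternal education per key, constant across cohorts; last slot missing
    levels = np.array([1, 2, 3, 4, 5, np.nan])
    ed = {k: levels[rng.choice(6, p=MATERNAL_ED_PROBS)] for k in keys}
    sub["maternal_ed"] = sub["subjectKey"].map(ed)
    sub["right_handed"] = True
    sub["mainstream_english"] = True
    sub["diagnosis"] = ""

    # FA profiles: tract mean shape + subject offset + smooth node noise
    n_rows = len(sub)
    values = np.empty((n_rows, len(spec.tracts), spec.n_nodes))
    for ti, tract in enumerate(spec.tracts):
        base = _mean_profile(spec, ti)
        offsets = rng.standard_normal(n_rows)[:, None] * spec.subject_sd
        noise = _smooth_noise(rng, n_rows, spec.n_nodes,
                              spec.profile_smoothness, spec.node_noise_sd)
        values[:, ti, :] = base[None, :] + offsets + noise

    # embed effects: additive b * z inside the window, per cohort
    for eff in spec.effects:
        ti = spec.tracts.index(eff.tract)
        lo, hi = eff.node_window
        sigma_win = _window_mean_noise_sd(spec, eff.node_window)
        b = eff.rho / np.sqrt(1.0 - eff.rho**2) * sigma_win
        for cohort in eff.cohorts:
            mask = (sub["cohort"] == cohort).to_numpy()
            z = _residualize_scores(sub[mask], eff.measure, eff.controls)
            values[np.flatnonzero(mask), ti, lo - 1:hi] += b * z[:, None]

    values = np.clip(values, 0.01, 0.99)
    dataset = TractProfileDataset(
        subjects=list(sub["subjectID"]),
        tracts=list(spec.tracts),
        values=values,
    )
    return dataset, sub


# ---------------------------------------------------------------------------
# Bundle generation
# ---------------------------------------------------------------------------

def generate_bundle(spec: BundleSpec, seed: int) -> StreamlineBundle:
    """Generate streamlines jittered around a centerline.

    Each streamline is the centerline resampled to ``n_points`` plus a
    smooth random lateral offset (Gaussian-smoothed along the
    streamline, per-point SD ``spread_sd`` in each coordinate). FA at
    each point follows ``fa_field`` (a constant or a callable of the
    fractional arc position in [0, 1]) plus independent noise.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    center = resample_streamline(np.asarray(spec.centerline, dtype=float),
                                 spec.n_points)
    t = np.linspace(0.0, 1.0, spec.n_points)
    if callable(spec.fa_field):
        fa_mean = np.asarray(spec.fa_field(t), dtype=float)
    else:
        fa_mean = np.full(spec.n_points, float(spec.fa_field))

    streamlines, values = [], []
    for _ in range(spec.n_streamlines):
        if spec.spread_sd > 0:
            offset = _smooth_noise(rng, 3, spec.n_points,
                                   spec.jitter_smoothness, spec.spread_sd).T
        else:
            offset = np.zeros((spec.n_points, 3))
        streamlines.append(center + offset)
        fa = fa_mean + rng.standard_normal(spec.n_points) * spec.fa_noise_sd
        values.append(np.clip(fa, 0.0, 1.0))
    return StreamlineBundle(streamlines=streamlines, point_values=values)
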