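"""Config-driven orchestration of the full tract-profile analysis.

The study plan is: filter subjects by inclusion criteria, run the
demographic tests (rank-sum on maternal education, partially
overlapping t-tests on the behavioral battery), then for every planned
comparison compute node-wise partial-correlation maps, build the
max-cluster-size permutation null over the comparison's tract family,
and classify the observed clusters under the stringent (FWE) and
lenient (adjacent-node) rules. Everything is reproducible from the
configuration plus one master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clusters as cl
from . import stats as st
from . import synthetic as syn
from .errors import ConfigurationError, SchemaError, ValidationError
from .profiles import (
    TractProfileDataset,
    read_nodes_csv,
    resample_profiles,
    write_nodes_csv,
)

logger = logging.getLogger("tractwise")

SCORE_COLUMNS = ("elision_raw", "wordclasses_raw", "wid_raw")

#: scores whose planned comparisons must control the complementary process
COMPLEMENT_CONTROL = {
    "elision_raw": "wordclasses_raw",
    "wordclasses_raw": "elision_raw",
}


# ---------------------------------------------------------------------------
# Inclusion criteria
# ---------------------------------------------------------------------------

@dataclass
class InclusionRules:
    """Cohort inclusion thresholds.

    Subjects must reach a nonverbal-IQ standard score of ``min_nviq``
    and a core-language standard score of ``min_core_language`` (both
    inclusive), be mainstream-English speakers and right-handed if
    required, carry no diagnosis, and score within ``outlier_sd``
    within-cohort standard deviations of the mean on each ability
    measure.
    """

    min_nviq: float = 70.0
    min_core_language: float = 80.0
    outlier_sd: float = 3.0
    require_right_handed: bool = True
    require_mainstream_english: bool = True

    def __post_init__(self) -> None:
        if self.min_nviq <= 0 or self.min_core_language <= 0 or self.outlier_sd <= 0:
            raise ValidationError("inclusion thresholds must be positive")


#: fixed precedence of exclusion reasons (first failing rule is logged)
EXCLUSION_ORDER = (
    "min_nviq", "min_core_language", "language_variety",
    "outlier", "handedness", "diagnosis",
)


def apply_inclusion_criteria(
    subjects: pd.DataFrame, rules: InclusionRules
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a subject table; returns (retained, exclusion log).

    The log has one row per excluded subject-cohort observation with
    the first failing rule in the documented precedence order. The
    outlier rule (scores beyond ``outlier_sd`` SDs of the within-cohort
    mean on Elision, Word Classes or Letter-Word ID) is evaluated on
    the subjects that survive the earlier rules, so its means and SDs
    are not distorted by subjects already excluded.
    """
    required = ["subjectID", "cohort", "nviq"]
    missing = [c for c in required if c not in subjects.columns]
    if missing:
        raise SchemaError(f"subject table lacks column(s) {', '.join(missing)}")

    sub = subjects.copy()
    reasons: dict[str, str] = {}

    def exclude(mask: pd.Series, reason: str) -> None:
        for sid in sub.loc[mask, "subjectID"]:
            reasons.setdefault(sid, reason)

    exclude(sub["nviq"] < rules.min_nviq, "min_nviq")
    if "core_language" in sub.columns:
        exclude(sub["core_language"] < rules.min_core_language, "min_core_language")
    if rules.require_mainstream_english and "mainstream_english" in sub.columns:
        exclude(~sub["mainstream_english"].astype(bool), "language_variety")

    # outlier rule on survivors of the threshold rules, within cohort
    alive = sub[~sub["subjectID"].isin(reasons)]
    for col in SCORE_COLUMNS:
        if col not in sub.columns:
            continue
        for _, grp in alive.groupby("cohort"):
            vals = grp[col].astype(float)
            mu, sd = vals.mean(), vals.std(ddof=1)
            if sd == 0 or np.isnan(sd):
                continue
            out = grp.loc[(vals - mu).abs() > rules.outlier_sd * sd, "subjectID"]
            for sid in out:
                reasons.setdefault(sid, "outlier")

    if rules.require_right_handed and "right_handed" in sub.columns:
        exclude(~sub["right_handed"].astype(bool), "handedness")
    if "diagnosis" in sub.columns:
        has_dx = sub["diagnosis"].fillna("").astype(str).str.strip() != ""
        exclude(has_dx, "diagnosis")

    log = pd.DataFrame(
        [{"subjectID": sid, "reason": reason} for sid, reason in reasons.items()],
        columns=["subjectID", "reason"],
    ).sort_values("subjectID").reset_index(drop=True)
    kept = sub[~sub["subjectID"].isin(reasons)].reset_index(drop=True)
    return kept, log


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------

@dataclass
class PermutationConfig:
    n_perm: int = 1000
    alpha_node: float = 0.05
    alpha_fwe: float = 0.05
    scheme: str = "labels"
    seed: int = 0


@dataclass
class ComparisonSpec:
    """One pre-registered comparison family: a set of tracts tested
    against one measure with shared controls, in one cohort."""

    name: str
    cohort: str
    tracts: tuple[str, ...]
    measure: str
    controls: tuple[str, ...]
    resolution: int = 100

    def __post_init__(self) -> None:
        self.tracts = tuple(self.tracts)
        self.controls = tuple(self.controls)
        if not self.tracts:
            raise ValidationError(f"comparison {self.name!r}: tracts empty")
        if self.cohort not in syn.COHORTS:
            raise ValidationError(
                f"comparison {self.name!r}: unknown cohort {self.cohort!r}")
        if self.measure in self.controls:
            raise ValidationError(
                f"comparison {self.name!r}: measure cannot be a control")
        if self.resolution not in cl.LENIENT_MIN_SIZE:
            raise ValidationError(
                f"comparison {self.name!r}: unsupported resolution "
                f"{self.resolution}")
        needed = COMPLEMENT_CONTROL.get(self.measure)
        if needed and needed not in self.controls:
            raise ValidationError(
                f"comparison {self.name!r}: the pre-registered design requires "
                f"controlling {needed!r} when testing {self.measure!r}")


@dataclass
class ComparisonResult:
    spec: ComparisonSpec
    maps: dict[str, st.NodewiseMap]
    decisions: list[cl.ClusterDecision]
    critical_size: int
    null: cl.PermutationNull


def run_comparison(
    dataset: TractProfileDataset,
    subjects: pd.DataFrame,
    spec: ComparisonSpec,
    perm: PermutationConfig,
) -> ComparisonResult:
    """Run one comparison family end-to-end.

    At 30-node resolution the profiles are resampled before any
    statistic is computed, so the observed maps and the permutation
    null see the same data.
    """
    sub = subjects[subjects["cohort"] == spec.cohort]
    data = dataset
    if spec.resolution != dataset.n_nodes:
        data = resample_profiles(dataset, spec.resolution)
    family = [(t, spec.measure, spec.controls) for t in spec.tracts]

    maps: dict[str, st.NodewiseMap] = {}
    found: list[cl.Cluster] = []
    for tract in spec.tracts:
        m = st.nodewise_map(data, sub, tract, spec.measure, spec.controls)
        maps[tract] = m
        found.extend(cl.find_clusters(m, perm.alpha_node))

    null = cl.build_max_cluster_null(
        data, sub, family,
        alpha_node=perm.alpha_node, n_perm=perm.n_perm,
        seed=perm.seed, scheme=perm.scheme,
    )
    critical = cl.fwe_critical_size(null, perm.alpha_fwe)
    decisions = cl.classify_clusters(found, critical, spec.resolution)
    return ComparisonResult(
        spec=spec, maps=maps, decisions=decisions,
        critical_size=critical, null=null,
    )


# ---------------------------------------------------------------------------
# Study configuration and report
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    config_hash: str
    seed: int
    n_after_filtering: dict[str, int]
    exclusions: pd.DataFrame
    demographics: dict
    comparisons: dict[str, ComparisonResult]

    def cluster_table(self) -> pd.DataFrame:
        frames = []
        for name, res in self.comparisons.items():
            df = cl.decisions_frame(res.decisions)
            df.insert(0, "family", name)
            if len(df):
                frames.append(df)
        if not frames:
            return pd.DataFrame()
        return pd.concat(frames, ignore_index=True)


def _build_comparisons(raw: Sequence[Mapping]) -> list[ComparisonSpec]:
    specs = []
    for i, item in enumerate(raw):
        try:
            specs.append(ComparisonSpec(
                name=item.get("name", f"comparison_{i}"),
                cohort=item["cohort"],
                tracts=tuple(item["tracts"]),
                measure=item["measure"],
                controls=tuple(item.get("controls", ())),
                resolution=int(item.get("resolution", 100)),
            ))
        except KeyError as exc:
            raise ConfigurationError(
                f"comparison {i}: missing key {exc.args[0]!r}") from None
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from None
    return specs


def _cohort_spec_from_config(raw: Mapping) -> syn.CohortSpec:
    kwargs = dict(raw)
    effects = kwargs.pop("effects", [])
    kwargs["effects"] = tuple(
        syn.EffectSpec(
            tract=e["tract"], measure=e["measure"],
            node_window=tuple(e["node_window"]), rho=float(e["rho"]),
            controls=tuple(e.get("controls", ("age", "nviq"))),
            cohorts=tuple(e.get("cohorts", syn.COHORTS)),
        )
        for e in effects
    )
    for key in ("tracts",):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    for key in ("score_means", "score_sds"):
        if key in kwargs:
            kwargs[key] = {k: tuple(v) for k, v in kwargs[key].items()}
    for key in ("age_range_young", "age_range_old"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    try:
        return syn.CohortSpec(**kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"bad simulate block: {exc}") from None


def _demographics(subjects: pd.DataFrame) -> dict:
    """Rank-sum on maternal education plus partially overlapping t-tests
    on every available score column, young vs old."""
    young = subjects[subjects["cohort"] == "young"]
    old = subjects[subjects["cohort"] == "old"]
    out: dict = {}

    if "maternal_ed" in subjects.columns:
        g1 = young["maternal_ed"].dropna().to_numpy(dtype=float)
        g2 = old["maternal_ed"].dropna().to_numpy(dtype=float)
        rs = st.ranksum_test(g1, g2)
        out["maternal_ed_ranksum"] = {
            "W": rs.w_stat, "p": rs.p, "n1": rs.n1, "n2": rs.n2,
        }

    # Welch-type for the score with unequal spread across cohorts in the
    # motivating battery; equal-variance elsewhere
    variant_map = {"elision_raw": "welch"}
    tests = {}
    for col in ("nviq", "core_language", *SCORE_COLUMNS):
        if col not in subjects.columns:
            continue
        y = young.dropna(subset=[col])
        o = old.dropna(subset=[col])
        res = st.partover_t(
            y[col].to_numpy(dtype=float), o[col].to_numpy(dtype=float),
            keys1=list(y["subjectKey"]), keys2=list(o["subjectKey"]),
            variant=variant_map.get(col, "equal_variance"),
        )
        tests[col] = {
            "t": res.t_stat, "df": res.df, "p": res.p,
            "variant": res.variant, "nc": res.nc,
        }
    out["partover_tests"] = tests
    return out


def run_study(
    config: str | Path | Mapping,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    n_perm: int | None = None,
) -> StudyReport:
    """Execute a full study from a YAML configuration.

    The configuration names either on-disk CSV inputs
    (``data: {nodes_csv, subjects_csv}``) or a synthetic-cohort block
    (``data: {simulate: {...}}``), the inclusion rules, the permutation
    settings and the planned comparisons. ``seed`` and ``n_perm``
    override the config when given. When ``out_dir`` is set, the
    cluster table, exclusion log and a JSON summary are written there.
    """
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        cfg = yaml.safe_load(text)
    else:
        cfg = dict(config)
        text = yaml.safe_dump(cfg, sort_keys=True)
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a mapping")
    cfg_hash = hashlib.sha256(text.encode()).hexdigest()[:16]

    perm_cfg = dict(cfg.get("permutation", {}))
    if seed is not None:
        perm_cfg["seed"] = seed
    if n_perm is not None:
        perm_cfg["n_perm"] = n_perm
    perm = PermutationConfig(**perm_cfg)
    master_seed = perm.seed

    data_cfg = cfg.get("data", {})
    stage = "load data"
    try:
        if "simulate" in data_cfg:
            spec = _cohort_spec_from_config(data_cfg["simulate"])
            dataset, subjects = syn.generate_cohort(spec, seed=master_seed)
        elif "nodes_csv" in data_cfg and "subjects_csv" in data_cfg:
            dataset = read_nodes_csv(data_cfg["nodes_csv"])
            subjects = pd.read_csv(data_cfg["subjects_csv"])
        else:
            raise ConfigurationError(
                "data block must provide either 'simulate' or both "
                "'nodes_csv' and 'subjects_csv'")

        stage = "inclusion criteria"
        rules = InclusionRules(**cfg.get("inclusion", {}))
        subjects, exclusions = apply_inclusion_criteria(subjects, rules)

        if cfg.get("overlap_only", False):
            counts = subjects.groupby("subjectKey")["cohort"].nunique()
            paired = set(counts[counts == 2].index)
            subjects = subjects[subjects["subjectKey"].isin(paired)]
            logger.info("overlap_only: restricted to %d paired keys", len(paired))

        stage = "demographics"
        demographics = _demographics(subjects)

        stage = "comparisons"
        specs = _build_comparisons(cfg.get("comparisons", []))
        comparisons: dict[str, ComparisonResult] = {}
        for i, cspec in enumerate(specs):
            stage = f"comparison {cspec.name!r}"
            cperm = PermutationConfig(
                n_perm=perm.n_perm, alpha_node=perm.alpha_node,
                alpha_fwe=perm.alpha_fwe, scheme=perm.scheme,
                # distinct substream per family, derived from the master seed
                seed=int(np.random.SeedSequence([master_seed, i]).generate_state(1)[0]
                         % (2**31)),
            )
            comparisons[cspec.name] = run_comparison(dataset, subjects, cspec, cperm)
            logger.info("family %s: critical size %d, %d cluster(s)",
                        cspec.name, comparisons[cspec.name].critical_size,
                        len(comparisons[cspec.name].decisions))
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    n_after = subjects.groupby("cohort")["subjectID"].count().to_dict()
    report = StudyReport(
        config_hash=cfg_hash, seed=master_seed,
        n_after_filtering={k: int(v) for k, v in n_after.items()},
        exclusions=exclusions, demographics=demographics,
        comparisons=comparisons,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.cluster_table().to_csv(out / "clusters.csv", index=False)
    report.exclusions.to_csv(out / "exclusions.csv", index=False)
    summary = {
        "config_hash": report.config_hash,
        "seed": report.seed,
        "n_after_filtering": report.n_after_filtering,
        "demographics": report.demographics,
        "critical_sizes": {
            name: res.critical_size for name, res in report.comparisons.items()
        },
        "n_fwe_significant": int(sum(
            d.fwe_significant for res in report.comparisons.values()
            for d in res.decisions
        )),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    for name, res in report.comparisons.items():
        rows = []
        for tract, m in res.maps.items():
            for j in range(m.n_nodes):
                rows.append({"tract": tract, "nodeID": j + 1,
                             "r": m.r[j], "p": m.p[j], "n": m.n})
        pd.DataFrame(rows).to_csv(out / f"map_{name}.csv", index=False)
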