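"""Cohort readers/writers, run configuration, and the staged pipeline.

The on-disk cohort layout is four UTF-8 comma-separated files sharing a
``subject_id`` key column:

* ``volumes_baseline.csv`` / ``volumes_followup.csv`` — 38 subfield columns
  in canonical roster order (mm^3);
* ``covariates.csv`` — age, sex (1 = female), education (band 0-3),
  apoe_e4_count (0/1/2);
* ``cognition.csv`` — mmse_baseline, mmse_followup (points).

``run_pipeline`` chains every analysis stage — change scores, paired tests
and asymmetry, cognition associations, pairwise partial correlations,
significance thresholding, centralities, consensus hubs — writing one
artifact per stage plus a manifest; identical config + seed reproduces
byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import associate_cognition, association_frame
from .centrality import BINARY, WEIGHTED, compute_centrality_profile, consensus_hubs
from .cohort import CohortConfig, LongitudinalCohort, default_config, generate_cohort
from .labels import CANONICAL_NAMES, N_SUBFIELDS
from .network import (
    edge_list_frame,
    matrix_frame,
    pairwise_partial_correlations,
    threshold_network,
    write_graphml,
)
from .volumetrics import (
    atrophy_report_frame,
    compute_change_table,
    hemispheric_asymmetry,
    subfield_atrophy_report,
)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"

COHORT_FILES = (
    "volumes_baseline.csv",
    "volumes_followup.csv",
    "covariates.csv",
    "cognition.csv",
)


class CohortIOError(ValueError):
    """Malformed on-disk cohort."""


def write_cohort(cohort: LongitudinalCohort, outdir) -> list[Path]:
    """Emit the four-CSV cohort layout; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {
        "volumes_baseline.csv": pd.DataFrame(
            cohort.volumes_baseline, columns=list(CANONICAL_NAMES)
        ),
        "volumes_followup.csv": pd.DataFrame(
            cohort.volumes_followup, columns=list(CANONICAL_NAMES)
        ),
        "covariates.csv": pd.DataFrame(
            {
                "age": cohort.age,
                "sex": cohort.sex,
                "education": cohort.education,
                "apoe_e4_count": cohort.apoe_e4_count,
            }
        ),
        "cognition.csv": pd.DataFrame(
            {
                "mmse_baseline": cohort.mmse_baseline,
                "mmse_followup": cohort.mmse_followup,
            }
        ),
    }
    paths = []
    for name, frame in frames.items():
        frame.insert(0, "subject_id", cohort.subject_ids)
        path = outdir / name
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
        paths.append(path)
    return paths


def _read_csv(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise CohortIOError(f"missing cohort file {path}")
    frame = pd.read_csv(path)
    if "subject_id" not in frame.columns:
        raise CohortIOError(f"{path.name}: missing subject_id column")
    if frame["subject_id"].duplicated().any():
        dup = frame["subject_id"][frame["subject_id"].duplicated()].iloc[0]
        raise CohortIOError(f"{path.name}: duplicate subject_id {dup!r}")
    return frame.set_index("subject_id")


def _numeric(frame: pd.DataFrame, fname: str, columns) -> pd.DataFrame:
    out = frame[list(columns)].apply(pd.to_numeric, errors="coerce")
    if out.isna().any().any():
        col = out.columns[out.isna().any()][0]
        subj = out.index[out[col].isna()][0]
        raise CohortIOError(
            f"{fname}: non-numeric or missing value for subject {subj!r}, "
            f"column {col!r}"
        )
    return out


def _volume_frame(frame: pd.DataFrame, fname: str, strict: bool) -> pd.DataFrame:
    got = set(frame.columns)
    want = set(CANONICAL_NAMES)
    missing = want - got
    if missing:
        raise CohortIOError(f"{fname}: missing subfield column {sorted(missing)[0]!r}")
    extra = got - want
    if extra and strict:
        raise CohortIOError(f"{fname}: unknown column {sorted(extra)[0]!r}")
    frame = _numeric(frame, fname, CANONICAL_NAMES)  # canonical column order
    bad = frame.le(0)
    if bad.any().any():
        col = frame.columns[bad.any()][0]
        subj = frame.index[bad[col]][0]
        raise CohortIOError(
            f"{fname}: non-positive volume for subject {subj!r}, column {col!r}"
        )
    return frame


def read_cohort(directory, strict: bool = True) -> LongitudinalCohort:
    """Load and validate the four-CSV cohort layout.

    Subfield columns are reordered to the canonical roster automatically;
    unknown extra columns are rejected unless ``strict=False``.  Subject
    sets must coincide across files; row order follows
    ``volumes_baseline.csv``.
    """
    directory = Path(directory)
    base = _read_csv(directory / "volumes_baseline.csv")
    follow = _read_csv(directory / "volumes_followup.csv")
    cov = _read_csv(directory / "covariates.csv")
    cog = _read_csv(directory / "cognition.csv")

    subjects = list(base.index)
    for fname, frame in (
        ("volumes_followup.csv", follow),
        ("covariates.csv", cov),
        ("cognition.csv", cog),
    ):
        if set(frame.index) != set(subjects):
            odd = set(frame.index).symmetric_difference(subjects)
            raise CohortIOError(
                f"{fname}: subject set differs from volumes_baseline.csv "
                f"(e.g. {sorted(odd)[0]!r})"
            )

    base = _volume_frame(base, "volumes_baseline.csv", strict)
    follow = _volume_frame(follow.loc[subjects], "volumes_followup.csv", strict)
    cov = _numeric(cov.loc[subjects], "covariates.csv",
                   ("age", "sex", "education", "apoe_e4_count"))
    cog = _numeric(cog.loc[subjects], "cognition.csv",
                   ("mmse_baseline", "mmse_followup"))

    cohort = LongitudinalCohort(
        subject_ids=[str(s) for s in subjects],
        age=cov["age"].to_numpy(float),
        sex=cov["sex"].to_numpy(int),
        education=cov["education"].to_numpy(int),
        apoe_e4_count=cov["apoe_e4_count"].to_numpy(int),
        mmse_baseline=cog["mmse_baseline"].to_numpy(int),
        mmse_followup=cog["mmse_followup"].to_numpy(int),
        volumes_baseline=base.to_numpy(float),
        volumes_followup=follow.to_numpy(float),
    )
    cohort.validate()
    return cohort


def save_config(config: CohortConfig, path) -> None:
    """Cohort config as a flat YAML mapping with per-subfield arrays."""
    data = dataclasses.asdict(config)
    for key in ("baseline_volume_means", "atrophy_means"):
        data[key] = [float(v) for v in data[key]]
    for key in ("apoe_probs", "education_probs"):
        data[key] = [float(v) for v in data[key]]
    data["factor_loadings"] = [
        [float(v) for v in row] for row in config.factor_loadings
    ]
    data["subfield_labels"] = list(CANONICAL_NAMES)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")


def load_config(path) -> CohortConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    labels = data.pop("subfield_labels", None)
    if labels is not None and list(labels) != list(CANONICAL_NAMES):
        raise CohortIOError(f"{path}: subfield_labels differ from the canonical roster")
    fields = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(data) - fields
    if unknown:
        raise CohortIOError(f"{path}: unknown config key {sorted(unknown)[0]!r}")
    config = CohortConfig(**data)
    config.validate()
    return config


@dataclass
class RunConfig:
    """End-to-end pipeline settings."""

    outdir: Path
    seed: int = 0
    cohort_dir: Path | None = None  # read an existing cohort ...
    cohort_config: CohortConfig | None = None  # ... or simulate one
    alpha: float = 0.05
    mode: str = BINARY  # path metrics: binary | weighted
    top_k: int = 5
    fdr: bool = False
    graphml: bool = False

    def validate(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if not 1 <= self.top_k <= N_SUBFIELDS:
            raise ValueError(f"top_k must lie in [1, {N_SUBFIELDS}]")
        if self.mode not in (BINARY, WEIGHTED):
            raise ValueError("mode must be 'binary' or 'weighted'")
        if self.cohort_dir is None and self.cohort_config is None:
            self.cohort_config = default_config(seed=self.seed)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, write per-stage artifacts, return the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def _save(frame: pd.DataFrame, name: str, sep: str = ",", index=False) -> None:
        path = outdir / name
        frame.to_csv(path, sep=sep, index=index, float_format=_FLOAT_FMT)
        artifacts[name] = name

    current = {"stage": "setup"}

    def _stage(name):
        current["stage"] = name
        logger.info("stage: %s", name)

    try:
        _stage("cohort")
        if config.cohort_dir is not None:
            cohort = read_cohort(config.cohort_dir)
            cohort_cfg = None
        else:
            cohort_cfg = config.cohort_config.replace(seed=config.seed)
            cohort = generate_cohort(cohort_cfg)
            write_cohort(cohort, outdir / "cohort")
            save_config(cohort_cfg, outdir / "cohort" / "config.yaml")
            artifacts["cohort"] = "cohort"
        logger.info("cohort: %d subjects, %d subfields", cohort.n_subjects, N_SUBFIELDS)

        _stage("changes")
        changes = compute_change_table(cohort)
        change_frame = pd.DataFrame(
            changes.volume_change_pct, columns=list(CANONICAL_NAMES)
        )
        change_frame.insert(0, "subject_id", changes.subject_ids)
        change_frame["cognitive_decline_pct"] = changes.cognitive_decline_pct
        _save(change_frame, "changes.csv")

        _stage("paired tests")
        report = subfield_atrophy_report(changes, cohort)
        _save(atrophy_report_frame(report, cohort, fdr=config.fdr),
              "atrophy_tests.tsv", sep="\t")
        asym = hemispheric_asymmetry(changes)
        left, right = changes.left_right_means()
        _save(
            pd.DataFrame(
                {
                    "left_mean_change_pct": [float(left.mean())],
                    "right_mean_change_pct": [float(right.mean())],
                    "left_minus_right": [asym.mean_change_pct],
                    "t": [asym.t_stat],
                    "p": [asym.p_value],
                    "n": [asym.n],
                }
            ),
            "asymmetry.tsv",
            sep="\t",
        )

        _stage("cognition associations")
        assoc = associate_cognition(
            changes, cohort.covariates(), cohort=cohort, include_aggregates=True
        )
        _save(association_frame(assoc), "associations.tsv", sep="\t")

        _stage("pairwise partial correlations")
        corr = pairwise_partial_correlations(changes, cohort.covariates())
        _save(matrix_frame(corr.r, corr.labels), "correlation_r.csv", index=True)
        _save(matrix_frame(corr.p, corr.labels), "correlation_p.csv", index=True)

        _stage("threshold network")
        adj = threshold_network(corr, alpha=config.alpha, fdr=config.fdr)
        logger.info("network: %d edges at alpha=%g", adj.n_edges, config.alpha)
        _save(matrix_frame(adj.weights, adj.labels), "adjacency.csv", index=True)
        _save(edge_list_frame(adj), "edges.tsv", sep="\t")
        if config.graphml:
            write_graphml(adj, outdir / "network.graphml")
            artifacts["network.graphml"] = "network.graphml"

        _stage("centrality")
        eigen_mode = BINARY if config.mode == BINARY else "weighted_abs"
        profile = compute_centrality_profile(
            adj, path_mode=config.mode, eigen_mode=eigen_mode
        )
        _save(profile.frame(), "centrality.csv")

        _stage("consensus hubs")
        hubs = consensus_hubs(profile, k=config.top_k)
        (outdir / "hubs.json").write_text(
            json.dumps(hubs.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )
        artifacts["hubs.json"] = "hubs.json"
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        logger.error("pipeline failed at stage %r: %s", current["stage"], exc)
        raise RuntimeError(f"pipeline stage {current['stage']!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "mode": config.mode,
        "top_k": config.top_k,
        "fdr": config.fdr,
        "n_subjects": cohort.n_subjects,
        "n_subfields": N_SUBFIELDS,
        "n_edges": adj.n_edges,
        "lambda_max": profile.lam,
        "consensus_hubs": hubs.consensus,
        "cohort_source": (
            str(config.cohort_dir) if config.cohort_dir is not None else "simulated"
        ),
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
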