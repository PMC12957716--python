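"""Percentage-change scores, paired baseline/follow-up tests, asymmetry.

Change scores are percentage differences relative to baseline::

    change (%) = 100 * (follow-up - baseline) / baseline

applied per subject both to subfield volumes and to the MMSE score
(cognitive decline).  Longitudinal volume loss is assessed with the paired
t-test on raw baseline vs. follow-up volumes per subfield, and hemispheric
asymmetry with a paired t-test of per-subject left vs. right mean
percentage change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import LongitudinalCohort
from .labels import (
    CANONICAL_NAMES,
    CANONICAL_ROSTER,
    LEFT_INDICES,
    N_SUBFIELDS,
    RIGHT_INDICES,
    Structure,
)


class DegenerateInputError(ValueError):
    """Raised when a test statistic is undefined (n < 2 or zero variance)."""


@dataclass
class ChangeTable:
    """Per-subject percentage changes: subfield volumes and cognition."""

    subject_ids: list[str]
    volume_change_pct: np.ndarray  # (n, 38), percent
    cognitive_decline_pct: np.ndarray  # (n,), percent
    labels: tuple = CANONICAL_ROSTER

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def left_right_means(self, weights: np.ndarray | None = None):
        """Per-subject mean change over left and over right subfields.

        ``weights`` (length 38, e.g. mean baseline volumes) switches from the
        default unweighted average to a weighted one within each hemisphere.
        """
        left = np.asarray(LEFT_INDICES)
        right = np.asarray(RIGHT_INDICES)
        if weights is None:
            return (
                self.volume_change_pct[:, left].mean(axis=1),
                self.volume_change_pct[:, right].mean(axis=1),
            )
        weights = np.asarray(weights, dtype=float)
        return (
            self.volume_change_pct[:, left] @ (weights[left] / weights[left].sum()),
            self.volume_change_pct[:, right] @ (weights[right] / weights[right].sum()),
        )


@dataclass
class PairedTestResult:
    """Paired t-test outcome for one subfield or aggregate."""

    label: str
    mean_change_pct: float
    t_stat: float
    p_value: float
    n: int

    @property
    def df(self) -> int:
        return self.n - 1


def percent_change(baseline, followup, context: str = "value"):
    """100 * (followup - baseline) / baseline; baseline must be positive.

    Works element-wise on arrays; ``context`` names the offending subject or
    column in error messages.
    """
    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    if np.any(baseline <= 0):
        raise ValueError(f"non-positive baseline in {context}")
    result = 100.0 * (followup - baseline) / baseline
    if result.ndim == 0:
        return float(result)
    return result


def compute_change_table(cohort: LongitudinalCohort) -> ChangeTable:
    """Percentage volume change per subject x subfield plus MMSE decline."""
    volume_change = np.empty_like(cohort.volumes_baseline)
    for j, name in enumerate(CANONICAL_NAMES):
        volume_change[:, j] = percent_change(
            cohort.volumes_baseline[:, j],
            cohort.volumes_followup[:, j],
            context=f"subfield column {name!r}",
        )
    bad = np.flatnonzero(cohort.mmse_baseline <= 0)
    if bad.size:
        raise ValueError(
            f"non-positive baseline MMSE for subject {cohort.subject_ids[bad[0]]!r}"
        )
    decline = percent_change(
        cohort.mmse_baseline.astype(float), cohort.mmse_followup.astype(float)
    )
    return ChangeTable(
        subject_ids=list(cohort.subject_ids),
        volume_change_pct=volume_change,
        cognitive_decline_pct=decline,
    )


def paired_t_test(before, after, label: str = "") -> PairedTestResult:
    """Two-sided paired t-test: t = mean(d) / (sd(d)/sqrt(n)), d = after - before."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1:
        raise ValueError("before and after must be 1-D vectors of equal length")
    n = before.size
    if n < 2:
        raise DegenerateInputError("paired t-test requires n >= 2")
    d = after - before
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError(
            f"zero-variance differences for {label or 'paired test'}"
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    mean_change = float(d.mean())
    return PairedTestResult(label=label, mean_change_pct=mean_change,
                            t_stat=float(t), p_value=float(p), n=n)


def subfield_atrophy_report(
    changes: ChangeTable, cohort: LongitudinalCohort
) -> list[PairedTestResult]:
    """Paired baseline vs. follow-up test per subfield.

    The t statistic is computed on raw volumes; ``mean_change_pct`` reports
    the mean of per-subject percentage changes (the per-subject ratio
    convention, matching the change-score definition).
    """
    if changes.subject_ids != list(cohort.subject_ids):
        raise ValueError("change table and cohort subject order differ")
    results = []
    for j, name in enumerate(CANONICAL_NAMES):
        res = paired_t_test(
            cohort.volumes_baseline[:, j], cohort.volumes_followup[:, j], label=name
        )
        res.mean_change_pct = float(changes.volume_change_pct[:, j].mean())
        results.append(res)
    return results


def hemispheric_asymmetry(
    changes: ChangeTable, weights: np.ndarray | None = None
) -> PairedTestResult:
    """Paired test of per-subject left vs. right mean percentage change.

    ``mean_change_pct`` reports the left-minus-right mean difference; a
    negative value means greater atrophy on the left.
    """
    left, right = changes.left_right_means(weights)
    res = paired_t_test(right, left, label="left minus right hemisphere mean")
    return res


_AGGREGATE_EXCLUDE = {Structure.HIPPOCAMPAL_FISSURE}  # CSF space, not tissue


def aggregate_volumes(cohort: LongitudinalCohort) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Summed-volume aggregates (baseline, follow-up) per named region group.

    Whole-hippocampus and whole-head/body aggregates are sums of constituent
    tissue subfield volumes (the hippocampal fissure is excluded); changes
    for aggregates are computed from the summed volumes, not by averaging
    subfield changes.
    """
    groups: dict[str, list[int]] = {}
    for i, lbl in enumerate(CANONICAL_ROSTER):
        if lbl.structure in _AGGREGATE_EXCLUDE:
            continue
        h = lbl.hemisphere.value
        groups.setdefault(f"Whole hippocampus {h}", []).append(i)
        if lbl.part.value in ("head", "body"):
            groups.setdefault(f"Whole hippocampal {lbl.part.value} {h}", []).append(i)
    return {
        name: (
            cohort.volumes_baseline[:, idx].sum(axis=1),
            cohort.volumes_followup[:, idx].sum(axis=1),
        )
        for name, idx in groups.items()
    }


def atrophy_report_frame(
    results: list[PairedTestResult],
    cohort: LongitudinalCohort | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Tabular atrophy report; optional Benjamini-Hochberg q-values."""
    frame = pd.DataFrame(
        {
            "label": [r.label for r in results],
            "mean_change_pct": [r.mean_change_pct for r in results],
            "t": [r.t_stat for r in results],
            "p": [r.p_value for r in results],
            "n": [r.n for r in results],
        }
    )
    if cohort is not None and len(results) == N_SUBFIELDS:
        frame.insert(1, "mean_baseline", cohort.volumes_baseline.mean(axis=0))
        frame.insert(2, "mean_followup", cohort.volumes_followup.mean(axis=0))
    if fdr:
        frame["q_fdr"] = benjamini_hochberg(frame["p"].to_numpy())
    return frame


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (delegates to statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]
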