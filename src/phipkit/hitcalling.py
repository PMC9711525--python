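"""Shared-hit calling, control-cohort downsampling, cross-cohort overlap.

A gene is a disease-specific *shared hit* when, on the chosen metric
(Z-score by default), all of the following hold:

1. it is positive (metric ≥ threshold, 10 by default) in at least
   ``case_min_frac`` of case samples (10% by default);
2. positive controls stay under the configured limit — either fewer than
   ``control_max_frac`` of controls (2% by default, pass condition
   ``n_pos < ceil(frac × n_controls)``) or strictly fewer than an absolute
   ``control_max_count``;
3. at least one positive case reaches a fold change of ``strong_fc_min``
   (50 by default) over mock-IP;
4. (dominance) no control's signal exceeds the highest case signal.

``downsample_controls`` repeats hit calling against randomly drawn control
subsets of increasing size, *recomputing* the Z-scores against each subset —
slicing the full-cohort Z-scores would leak the held-out controls into the
reference.  Growing the control cohort filters out background reactivities
that a handful of controls happens to miss, which is why apparent-hit
counts shrink as control sets grow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts_io import SampleSheet, ValidationError
from .enrichment import FoldChangeMatrix, ZScoreMatrix, zscore

logger = logging.getLogger(__name__)

CRITERION_NAMES = ("case_frac", "control_limit", "strong_case", "dominance")
DEFAULT_DOWNSAMPLE_SIZES = (5, 10, 25, 50, 100, 150)


@dataclass(frozen=True)
class HitCriteria:
    """Thresholds of the shared-hit definition (defaults as documented above).

    Exactly one control-limit mode is active: fractional
    (``control_max_frac``, default) or absolute (``control_max_count``);
    setting ``control_max_count`` switches to the absolute mode.
    ``strict_inequality`` switches positivity from ``≥`` to ``>``.
    """

    metric: str = "zscore"  # or "fold_change"
    positive_threshold: float = 10.0
    case_min_frac: float = 0.10
    control_max_frac: float | None = 0.02
    control_max_count: int | None = None
    strong_fc_min: float = 50.0
    dominance_rule: bool = True
    strict_inequality: bool = False

    def __post_init__(self) -> None:
        if self.metric not in ("zscore", "fold_change"):
            raise ValidationError(f"unknown metric {self.metric!r}")
        if self.positive_threshold <= 0 or self.strong_fc_min <= 0:
            raise ValidationError("thresholds must be positive")
        if not (0 < self.case_min_frac <= 1):
            raise ValidationError("case_min_frac must lie in (0, 1]")
        if (self.control_max_frac is None) == (self.control_max_count is None):
            raise ValidationError(
                "exactly one of control_max_frac / control_max_count must be set"
            )

    def control_limit(self, n_controls: int) -> int:
        """Pass condition is ``n_controls_positive < limit``."""
        if self.control_max_count is not None:
            return int(self.control_max_count)
        return max(1, math.ceil(self.control_max_frac * n_controls))


#: Fold-change variant of the criteria (>10-fold over mock-IP as positivity).
CAPTION_FC10 = HitCriteria(metric="fold_change", positive_threshold=10.0,
                           strict_inequality=True)


@dataclass
class HitTable:
    """Per-gene hit diagnostics plus the pass/fail verdict."""

    table: pd.DataFrame  # index gene; diagnostics + passed + failed_criteria
    criteria: HitCriteria
    n_cases: int
    n_controls: int

    @property
    def passed_genes(self) -> list[str]:
        return list(self.table.index[self.table["passed"]])

    @property
    def n_passed(self) -> int:
        return int(self.table["passed"].sum())


def call_hits(
    z: ZScoreMatrix,
    fc: FoldChangeMatrix,
    sheet: SampleSheet,
    crit: HitCriteria = HitCriteria(),
) -> HitTable:
    """Apply the shared-hit criteria gene by gene."""
    cases = sheet.case_ids
    controls = sheet.control_ids
    metric_df = z.z if crit.metric == "zscore" else fc.fc
    missing = [s for s in cases + controls if s not in metric_df.columns]
    if missing:
        raise ValidationError(f"metric matrix lacks required samples: {missing[:10]}")
    if not fc.fc.index.equals(metric_df.index):
        raise ValidationError("z and fc matrices must share the gene index")

    m_case = metric_df[cases].to_numpy(dtype=float)
    m_ctrl = metric_df[controls].to_numpy(dtype=float)
    thr = crit.positive_threshold
    pos_case = (m_case > thr) if crit.strict_inequality else (m_case >= thr)
    pos_ctrl = (m_ctrl > thr) if crit.strict_inequality else (m_ctrl >= thr)

    n_cases_pos = pos_case.sum(axis=1)
    n_ctrl_pos = pos_ctrl.sum(axis=1)
    max_case = m_case.max(axis=1)
    max_ctrl = (m_ctrl.max(axis=1) if controls
                else np.full(len(metric_df), -np.inf))
    fc_case = fc.fc[cases].to_numpy(dtype=float)
    strong = (pos_case & (fc_case >= crit.strong_fc_min)).any(axis=1)

    need_cases = math.ceil(crit.case_min_frac * len(cases))
    ok_case = n_cases_pos >= need_cases
    ok_ctrl = n_ctrl_pos < crit.control_limit(len(controls))
    ok_dom = (max_ctrl <= max_case) if crit.dominance_rule else np.ones(len(metric_df), bool)
    passed = ok_case & ok_ctrl & strong & ok_dom

    fails = [
        [name for name, ok in zip(CRITERION_NAMES, flags) if not ok]
        for flags in zip(ok_case, ok_ctrl, strong, ok_dom)
    ]
    table = pd.DataFrame(
        {
            "n_cases_positive": n_cases_pos,
            "n_controls_positive": n_ctrl_pos,
            "max_case_signal": max_case,
            "max_control_signal": max_ctrl,
            "strong_case_present": strong,
            "passed": passed,
            "failed_criteria": [";".join(f) for f in fails],
        },
        index=metric_df.index,
    )
    return HitTable(table=table, criteria=crit, n_cases=len(cases),
                    n_controls=len(controls))


# ---------------------------------------------------------------------------
# Control downsampling
# ---------------------------------------------------------------------------

@dataclass
class DownsamplingCurve:
    """Apparent-hit counts vs control-cohort size (mean, SD, per-rep detail)."""

    per_rep: pd.DataFrame  # columns: size, rep, n_hits
    seed: int
    reps: int

    @property
    def summary(self) -> pd.DataFrame:
        g = self.per_rep.groupby("size")["n_hits"]
        return pd.DataFrame({"mean_hits": g.mean(), "sd_hits": g.std(ddof=1)})


def downsample_controls(
    fc: FoldChangeMatrix,
    sheet: SampleSheet,
    crit: HitCriteria = HitCriteria(),
    sizes: tuple[int, ...] = DEFAULT_DOWNSAMPLE_SIZES,
    reps: int = 10,
    seed: int = 0,
) -> DownsamplingCurve:
    """Re-call hits against random control subsets of each requested size.

    For every subset the Z-scores are recomputed with only the sampled
    controls as the reference cohort; the held-out controls are removed from
    the analysis entirely (as if never collected).
    """
    controls = sheet.control_ids
    if reps < 1:
        raise ValidationError("reps must be ≥ 1")
    bad = [k for k in sizes if k > len(controls)]
    if bad:
        raise ValidationError(
            f"downsample sizes {bad} exceed available controls ({len(controls)})"
        )
    rng = np.random.default_rng(seed)
    cases = sheet.case_ids
    rows = []
    for size in sizes:
        for rep in range(reps):
            subset = list(rng.choice(controls, size=size, replace=False))
            sub_sheet = sheet.subset(cases + subset + sheet.mock_ids)
            sub_fc = FoldChangeMatrix(fc=fc.fc[cases + subset], mock_ids=fc.mock_ids)
            sub_z = zscore(sub_fc, sub_sheet)
            hits = call_hits(sub_z, sub_fc, sub_sheet, crit)
            rows.append((size, rep, hits.n_passed))
    return DownsamplingCurve(
        per_rep=pd.DataFrame(rows, columns=["size", "rep", "n_hits"]),
        seed=seed, reps=reps,
    )


# ---------------------------------------------------------------------------
# Cross-cohort overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapReport:
    """Which of cohort A's hits recur in cohort B (and vice versa)."""

    shared: list[str]  # passed in A, ≥1 positive sample in B
    a_only: list[str]
    b_only: list[str]  # passed in B but not in A
    table: pd.DataFrame  # per A-passed gene: positives in B


def cross_cohort_overlap(hits_a: HitTable, hits_b: HitTable) -> OverlapReport:
    """For each gene passing in cohort A, count positive samples in cohort B.

    Positivity in B uses B's own metric/threshold diagnostics
    (``n_cases_positive``), so the two HitTables should be built with
    comparable criteria.
    """
    genes_a = set(hits_a.table.index)
    genes_b = set(hits_b.table.index)
    if not genes_a & genes_b:
        logger.warning("cohorts share no genes; overlap is empty")
    passed_a = hits_a.passed_genes
    pos_in_b = {
        g: int(hits_b.table.at[g, "n_cases_positive"]) if g in genes_b else 0
        for g in passed_a
    }
    shared = [g for g in passed_a if pos_in_b[g] > 0]
    a_only = [g for g in passed_a if pos_in_b[g] == 0]
    b_only = [g for g in hits_b.passed_genes if g not in set(passed_a)]
    table = pd.DataFrame(
        {"n_positive_in_b": [pos_in_b[g] for g in passed_a],
         "shared": [g in set(shared) for g in passed_a]},
        index=pd.Index(passed_a, name="gene"),
    )
    return OverlapReport(shared=shared, a_only=a_only, b_only=b_only, table=table)
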