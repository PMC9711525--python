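"""Normalization, mock-IP fold change, and control-referenced Z-scores.

The enrichment statistics proceed in three steps on gene-level counts:

1. **normalize** — add a 0.5-read pseudocount to every gene and convert each
   sample column to percentage of total reads (columns sum to exactly 100;
   the pseudocount is included in the denominator so the composition stays
   closed and every entry is strictly positive).
2. **fold_change** — divide each serum sample's gene read-percentage by the
   mean read-percentage of that gene across the mock-IP (protein A/G
   bead-only, no serum) samples.  Mock-IP columns are dropped from the
   result.
3. **zscore** — standardize each fold change against the healthy-control
   cohort: a case sample is referenced to all controls; a control sample is
   referenced to all *other* controls (leave-one-out), so its own value
   never contaminates its reference.  The sample standard deviation (n−1
   denominator) is used throughout.

Zero-spread references are resolved deterministically: if the reference SD
is 0 and the value equals the reference mean the Z-score is 0; otherwise it
is ±inf, which compares as exceeding any finite positivity threshold
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts_io import CountMatrix, SampleSheet, ValidationError

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_PROFILE_THRESHOLDS = (5.0, 10.0, 25.0, 50.0, 100.0)


@dataclass
class FrequencyMatrix:
    """Pseudocounted read percentages, genes × samples (columns sum to 100)."""

    percent: pd.DataFrame
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def gene_ids(self) -> list[str]:
        return list(self.percent.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.percent.columns)


@dataclass
class FoldChangeMatrix:
    """Fold change over the mean mock-IP percentage; mock columns excluded."""

    fc: pd.DataFrame
    mock_ids: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fc.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fc.columns)


@dataclass
class ZScoreMatrix:
    """Control-referenced Z-scores for cases and controls.

    ``reference`` records, per scored sample, which control set was used.
    Entries are ±inf where the reference SD was exactly 0 and the value
    differed from the reference mean.
    """

    z: pd.DataFrame
    reference: dict[str, str] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.z.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.z.columns)

    @property
    def flagged(self) -> pd.DataFrame:
        """Boolean mask of entries where the reference SD was zero (±inf)."""
        return ~np.isfinite(self.z)


def normalize(gene_counts: CountMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> FrequencyMatrix:
    """Convert gene counts to pseudocounted percentage of total reads per sample."""
    if gene_counts.counts.size == 0:
        raise ValidationError("cannot normalize an empty count matrix")
    if gene_counts.level != "gene":
        raise ValidationError("normalize expects gene-level counts (aggregate first)")
    c = gene_counts.counts.to_numpy(dtype=float) + pseudocount
    percent = 100.0 * c / c.sum(axis=0, keepdims=True)
    return FrequencyMatrix(
        percent=pd.DataFrame(percent, index=gene_counts.counts.index,
                             columns=gene_counts.counts.columns),
        pseudocount=pseudocount,
    )


def fold_change(freq: FrequencyMatrix, sheet: SampleSheet) -> FoldChangeMatrix:
    """Fold change of each non-mock sample over the mean mock-IP percentage."""
    mock = [s for s in sheet.mock_ids if s in freq.percent.columns]
    if not mock:
        raise ValidationError("fold_change requires at least one mock_ip sample")
    serum = [s for s in freq.sample_ids if s not in set(mock)]
    mock_mean = freq.percent[mock].mean(axis=1)
    fc = freq.percent[serum].div(mock_mean, axis=0)
    return FoldChangeMatrix(fc=fc, mock_ids=mock)


def _loo_mean_sd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out mean and sample SD for each column of ``x`` (genes × n).

    Uses centered sufficient statistics: with d_j = x_j − mean(x),

        mean_loo_j = mean + (mean − x_j) / (n − 1)
        SS_loo_j   = Σ d² − d_j² · n/(n−1)
        var_loo_j  = SS_loo_j / (n − 2)

    Exact (0, not epsilon) when the held-out reference values are identical.
    With n = 2 the reference is a single value, so the SD is taken as 0.
    """
    n = x.shape[1]
    mean = x.mean(axis=1, keepdims=True)
    d = x - mean
    ss = (d * d).sum(axis=1, keepdims=True)
    mean_loo = mean + (mean - x) / (n - 1)
    ss_loo = ss - d * d * (n / (n - 1))
    if n > 2:
        var_loo = np.maximum(ss_loo, 0.0) / (n - 2)
    else:
        var_loo = np.zeros_like(ss_loo)
    return mean_loo, np.sqrt(var_loo)


def _z_from(values: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Standardize with the zero-SD rule (0 if centered, ±inf otherwise)."""
    diff = values - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / sd
    zero_sd = np.broadcast_to(sd == 0, z.shape)
    z = np.where(zero_sd & (diff == 0), 0.0, z)
    z = np.where(zero_sd & (diff > 0), np.inf, z)
    z = np.where(zero_sd & (diff < 0), -np.inf, z)
    return z


def zscore(fc: FoldChangeMatrix, sheet: SampleSheet,
           control_ids: list[str] | None = None) -> ZScoreMatrix:
    """Z-scores of fold changes against the healthy-control cohort.

    Cases are standardized against all controls; each control against all
    other controls (leave-one-out).  ``control_ids`` overrides the reference
    cohort (e.g. scoring one disease cohort against another study's
    controls); mock-IP samples never receive a Z-score.
    """
    controls = control_ids if control_ids is not None else sheet.control_ids
    controls = [c for c in controls if c in fc.fc.columns]
    if len(controls) < 2:
        raise ValidationError("zscore requires at least 2 control samples")
    control_set = set(controls)
    scored = [s for s in fc.sample_ids if s not in set(fc.mock_ids)]
    non_controls = [s for s in scored if s not in control_set]

    xc = fc.fc[controls].to_numpy(dtype=float)
    mu = xc.mean(axis=1, keepdims=True)
    sd = xc.std(axis=1, ddof=1, keepdims=True)

    z = pd.DataFrame(index=fc.fc.index, columns=scored, dtype=float)
    reference: dict[str, str] = {}
    if non_controls:
        vals = fc.fc[non_controls].to_numpy(dtype=float)
        z.loc[:, non_controls] = _z_from(vals, mu, sd)
        for s in non_controls:
            reference[s] = f"all controls (n={len(controls)})"
    mean_loo, sd_loo = _loo_mean_sd(xc)
    z.loc[:, controls] = _z_from(xc, mean_loo, sd_loo)
    for c in controls:
        reference[c] = f"controls excluding self (n={len(controls) - 1})"
    return ZScoreMatrix(z=z, reference=reference)


def enrichment_profile(
    fc: FoldChangeMatrix,
    thresholds: tuple[float, ...] = DEFAULT_PROFILE_THRESHOLDS,
) -> pd.DataFrame:
    """Per-sample count of genes reaching each fold-change threshold.

    Returns a samples × thresholds table of hit counts (column labels
    ``fc_ge_<t>``); counts are non-increasing along increasing thresholds.
    """
    if any(t <= 0 for t in thresholds):
        raise ValidationError("profile thresholds must be positive")
    out = {f"fc_ge_{t:g}": (fc.fc >= t).sum(axis=0) for t in thresholds}
    table = pd.DataFrame(out)
    table.index.name = "sample_id"
    return table
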