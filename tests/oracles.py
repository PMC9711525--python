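"""Independent brute-force reference implementations.

Plain Python loops over genes/samples, written without reference to the
vectorized library code so they can serve as oracles in equivalence tests.
"""

from __future__ import annotations

import math

import pandas as pd


def aggregate_oracle(counts: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    genes: list[str] = []
    for p in counts.index:
        g = mapping[p]
        if g not in genes:
            genes.append(g)
    out = pd.DataFrame(0, index=genes, columns=counts.columns, dtype=int)
    for p in counts.index:
        for s in counts.columns:
            out.at[mapping[p], s] += int(counts.at[p, s])
    return out


def normalize_oracle(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    out = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    for s in counts.columns:
        total = sum(counts.at[g, s] + pseudocount for g in counts.index)
        for g in counts.index:
            out.at[g, s] = 100.0 * (counts.at[g, s] + pseudocount) / total
    return out


def fold_change_oracle(percent: pd.DataFrame, mock_ids: list[str]) -> pd.DataFrame:
    serum = [s for s in percent.columns if s not in set(mock_ids)]
    out = pd.DataFrame(index=percent.index, columns=serum, dtype=float)
    for g in percent.index:
        mock_mean = sum(percent.at[g, m] for m in mock_ids) / len(mock_ids)
        for s in serum:
            out.at[g, s] = percent.at[g, s] / mock_mean
    return out


def _mean_sd(vals: list[float]) -> tuple[float, float]:
    n = len(vals)
    m = sum(vals) / n
    if n < 2:
        return m, 0.0
    var = sum((v - m) ** 2 for v in vals) / (n - 1)
    return m, math.sqrt(var)


def zscore_oracle(fc: pd.DataFrame, cases: list[str], controls: list[str]) -> pd.DataFrame:
    out = pd.DataFrame(index=fc.index, columns=cases + controls, dtype=float)
    for s in cases + controls:
        ref = [c for c in controls if c != s]
        for g in fc.index:
            m, sd = _mean_sd([float(fc.at[g, c]) for c in ref])
            v = float(fc.at[g, s])
            if sd == 0.0:
                out.at[g, s] = 0.0 if v == m else math.copysign(math.inf, v - m)
            else:
                out.at[g, s] = (v - m) / sd
    return out


def profile_oracle(fc: pd.DataFrame, thresholds: list[float]) -> dict[str, dict[float, int]]:
    out: dict[str, dict[float, int]] = {}
    for s in fc.columns:
        out[s] = {}
        for t in thresholds:
            out[s][t] = sum(1 for g in fc.index if fc.at[g, s] >= t)
    return out


def call_hits_oracle(
    z: pd.DataFrame,
    fc: pd.DataFrame,
    cases: list[str],
    controls: list[str],
    metric: str = "zscore",
    positive_threshold: float = 10.0,
    case_min_frac: float = 0.10,
    control_max_frac: float | None = 0.02,
    control_max_count: int | None = None,
    strong_fc_min: float = 50.0,
    dominance_rule: bool = True,
    strict: bool = False,
) -> pd.DataFrame:
    metric_df = z if metric == "zscore" else fc
    if control_max_count is not None:
        limit = control_max_count
    else:
        limit = max(1, math.ceil(control_max_frac * len(controls)))
    rows = {}
    for g in metric_df.index:

        def positive(v: float) -> bool:
            return v > positive_threshold if strict else v >= positive_threshold

        n_case = sum(1 for s in cases if positive(float(metric_df.at[g, s])))
        n_ctrl = sum(1 for s in controls if positive(float(metric_df.at[g, s])))
        max_case = max(float(metric_df.at[g, s]) for s in cases)
        max_ctrl = max(float(metric_df.at[g, s]) for s in controls)
        strong = any(
            positive(float(metric_df.at[g, s])) and float(fc.at[g, s]) >= strong_fc_min
            for s in cases
        )
        ok = (
            n_case >= math.ceil(case_min_frac * len(cases))
            and n_ctrl < limit
            and strong
            and (not dominance_rule or max_ctrl <= max_case)
        )
        rows[g] = dict(n_cases_positive=n_case, n_controls_positive=n_ctrl,
                       max_case_signal=max_case, max_control_signal=max_ctrl,
                       strong_case_present=strong, passed=ok)
    return pd.DataFrame.from_dict(rows, orient="index")
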