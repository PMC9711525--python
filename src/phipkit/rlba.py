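"""Radioligand binding assay (RLBA) antibody-index statistics.

The RLBA is the orthogonal whole-protein validation assay: in-vitro
transcribed/translated radiolabeled protein is immunoprecipitated with
patient serum and counted on a scintillation reader.  Per sample, the
antibody index normalizes the signal between the plate blanks and the
positive-control antibody:

    index = (sample − mean blank) / (positive control − mean blank)

A sample is called positive when its index strictly exceeds the cutoff
mean(healthy-control indices) + 3 × SD (sample SD, n−1); a sample exactly
at the cutoff is negative.  The index is a ratio of differences, so it is
invariant under a common rescaling of every cpm on the plate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import ValidationError, _detect_sep

WELL_ROLES = ("sample", "blank", "positive_control", "healthy_control")


@dataclass
class RlbaPlate:
    """One plate of scintillation readings (well, role, sample_id, cpm)."""

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        w = self.wells
        missing = {"role", "cpm"} - set(w.columns)
        if missing:
            raise ValidationError(f"plate table missing columns: {sorted(missing)}")
        bad = sorted(set(w["role"]) - set(WELL_ROLES))
        if bad:
            raise ValidationError(f"unknown well roles {bad}; allowed: {WELL_ROLES}")
        if (w["cpm"].astype(float) < 0).any():
            raise ValidationError("cpm values must be nonnegative")
        if not (w["role"] == "blank").any() or not (w["role"] == "positive_control").any():
            raise ValidationError("plate needs ≥1 blank and ≥1 positive_control well")

    def cpms(self, role: str) -> np.ndarray:
        return self.wells.loc[self.wells["role"] == role, "cpm"].to_numpy(dtype=float)


def read_plate(path: str | Path) -> RlbaPlate:
    """Read a well table (columns well, role, sample_id, cpm; CSV or TSV)."""
    df = pd.read_csv(path, sep=_detect_sep(Path(path)))
    return RlbaPlate(df)


def antibody_index(
    sample_cpm: float, blank_cpms: Sequence[float], positive_cpm: float | Sequence[float]
) -> float:
    """(sample − mean blank) / (positive control − mean blank).

    Multiple positive-control wells are averaged before use.  May be
    negative when the sample reads below the blanks.
    """
    blank = float(np.mean(np.asarray(blank_cpms, dtype=float)))
    pos = float(np.mean(np.asarray(positive_cpm, dtype=float)))
    if pos <= blank:
        raise ValidationError(
            f"positive control ({pos}) does not exceed mean blank ({blank}): assay failure"
        )
    return (float(sample_cpm) - blank) / (pos - blank)


@dataclass
class AntibodyIndexTable:
    """Per-sample antibody indices with the positivity call and its cutoff."""

    table: pd.DataFrame  # index sample_id; columns: index, positive
    cutoff: float
    healthy_ids: list[str]

    @property
    def positives(self) -> list[str]:
        return list(self.table.index[self.table["positive"]])


def compute_indices(plate: RlbaPlate) -> pd.Series:
    """Antibody index for every sample / healthy-control well on a plate."""
    blanks = plate.cpms("blank")
    pos = plate.cpms("positive_control")
    rows = plate.wells[plate.wells["role"].isin(["sample", "healthy_control"])]
    idx = {
        str(r["sample_id"]): antibody_index(float(r["cpm"]), blanks, pos)
        for _, r in rows.iterrows()
    }
    return pd.Series(idx, name="antibody_index")


def call_positives(
    indices: Mapping[str, float] | pd.Series, healthy_ids: Iterable[str]
) -> AntibodyIndexTable:
    """Positive ⇔ index > mean(healthy) + 3 × SD(healthy) (strict)."""
    s = pd.Series(dict(indices) if not isinstance(indices, pd.Series) else indices,
                  dtype=float)
    healthy = [h for h in healthy_ids]
    missing = [h for h in healthy if h not in s.index]
    if missing:
        raise ValidationError(f"healthy ids absent from indices: {missing}")
    if len(healthy) < 2:
        raise ValidationError("need ≥2 healthy controls for an SD-based cutoff")
    hvals = s[healthy].to_numpy(dtype=float)
    cutoff = float(hvals.mean() + 3.0 * hvals.std(ddof=1))
    table = pd.DataFrame({"index": s, "positive": s > cutoff})
    table.index.name = "sample_id"
    return AntibodyIndexTable(table=table, cutoff=cutoff, healthy_ids=list(healthy))
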