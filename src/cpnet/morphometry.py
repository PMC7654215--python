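"""Nuclear morphometric analysis and cumulative population doubling.

The nuclear irregularity index combines four shape descriptors measured on
a segmented nucleus:

    NII = Asp - Arbx + Rr + Rou

(aspect ratio minus area/bounding-box ratio plus radius ratio plus
roundness); it grows with irregularity. Nuclei are classified against an
untreated control population: size is small/normal/large by the area
z-score against the control mean +- k_area SD, shape is regular/irregular
by the NII exceeding the control mean + k_nii SD (one-sided, since NII
increases with irregularity). Small nuclei are SR/SI, large nuclei LR/LIr,
everything of normal size is N. SR typically marks apoptosis, LR/LIr
senescence.

Population doubling of one passage is PD = [log N(t) - log N(t0)] / log 2,
and the cumulative population doubling (CPD) is the running sum of PDs
across passages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DegenerateError, InputError

CLASSES = ("N", "SR", "SI", "LR", "LIr")


@dataclass
class NucleusRecord:
    area: float
    aspect: float
    areabox: float
    radius_ratio: float
    roundness: float
    nii: Optional[float] = None
    label: Optional[str] = None  # assigned class
    true_class: Optional[str] = None  # generator ground truth, if any


def nii(record: NucleusRecord) -> float:
    """Nuclear irregularity index: Asp - Arbx + Rr + Rou."""
    for name in ("aspect", "areabox", "radius_ratio", "roundness"):
        value = getattr(record, name)
        if value is None or not math.isfinite(value):
            raise InputError(f"missing metric {name!r}")
    return record.aspect - record.areabox + record.radius_ratio + record.roundness


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "area": r.area,
                "aspect": r.aspect,
                "areabox": r.areabox,
                "radius_ratio": r.radius_ratio,
                "roundness": r.roundness,
                "nii": r.nii if r.nii is not None else nii(r),
                "class": r.label or "",
                "true_class": r.true_class or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["area", "aspect", "areabox", "radius_ratio", "roundness", "nii", "class", "true_class"],
    )


def frame_to_records(df: pd.DataFrame):
    records = []
    for row in df.itertuples(index=False):
        rec = NucleusRecord(
            area=float(row.area),
            aspect=float(row.aspect),
            areabox=float(row.areabox),
            radius_ratio=float(row.radius_ratio),
            roundness=float(row.roundness),
            true_class=getattr(row, "true_class", None) or None,
        )
        rec.nii = nii(rec)
        records.append(rec)
    return records


def classify_nuclei(records, control, k_area: float = 2.5, k_nii: float = 2.5):
    """Classify nuclei against a control population (returns new records).

    Size and NII are standardized against the control mean and SD; k_area
    and k_nii set the width of the "normal" band in control SD units.
    """
    if not control:
        raise InputError("control population must be nonempty")
    ctrl_area = np.array([r.area for r in control], float)
    ctrl_nii = np.array([nii(r) for r in control], float)
    area_mean, area_sd = ctrl_area.mean(), ctrl_area.std(ddof=1)
    nii_mean, nii_sd = ctrl_nii.mean(), ctrl_nii.std(ddof=1)
    if area_sd == 0 or nii_sd == 0:
        raise DegenerateError("control SD is zero")

    out = []
    for r in records:
        value = nii(r)
        small = r.area < area_mean - k_area * area_sd
        large = r.area > area_mean + k_area * area_sd
        irregular = value > nii_mean + k_nii * nii_sd
        if small:
            label = "SI" if irregular else "SR"
        elif large:
            label = "LIr" if irregular else "LR"
        else:
            label = "N"
        out.append(
            NucleusRecord(
                area=r.area,
                aspect=r.aspect,
                areabox=r.areabox,
                radius_ratio=r.radius_ratio,
                roundness=r.roundness,
                nii=value,
                label=label,
                true_class=r.true_class,
            )
        )
    return out


def population_doubling(n_start: float, n_end: float) -> float:
    """PD = [log N(t) - log N(t0)] / log 2."""
    if n_start <= 0 or n_end <= 0:
        raise InputError("cell counts must be positive")
    return (math.log(n_end) - math.log(n_start)) / math.log(2)


@dataclass
class GrowthSeries:
    """Ordered passages of (day, n_start, n_end)."""

    passages: list  # of (day, n_start, n_end)

    def __post_init__(self):
        if not self.passages:
            raise InputError("growth series is empty")
        days = [p[0] for p in self.passages]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise InputError("days must be strictly increasing")
        for _, n0, n1 in self.passages:
            if n0 <= 0 or n1 <= 0:
                raise InputError("cell counts must be positive")

    @classmethod
    def read_tsv(cls, path) -> "GrowthSeries":
        df = pd.read_csv(path, sep="\t")
        return cls([(int(d), float(a), float(b)) for d, a, b in df.itertuples(index=False)])


def cumulative_pd(series: GrowthSeries) -> list:
    """Running sum of per-passage PDs, indexed by day."""
    out = []
    total = 0.0
    for day, n0, n1 in series.passages:
        total += population_doubling(n0, n1)
        out.append((day, total))
    return out
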