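"""Screening dimer frames for fibrillation-capable nucleation seeds.

A dimer frame is a seed candidate when the appended aromatic rings of the
two monomers are aligned and tightly associated.  The screen is a nested
sequence of three filters:

1. marker distances D1 < 0.6 nm and D2 < 0.6 nm with aromatic covered area
   CA_T,a > 2.5 nm^2 (aromatic regions aligned);
2. additionally D3 < 0.8 nm, a more relaxed contact criterion bringing the
   Phe rings of both monomers into proximity;
3. additionally both intra-monomer ring angles inside a window centred on
   120 deg — the conformation whose propagation preserves the binding site
   and can nucleate a fiber.

Occupancies are reported as percent of ALL frames by default (the "of total
simulation time" bookkeeping); a contact-only denominator is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import AssociationRecord
from .model import ModelError


@dataclass
class SeedCriteria:
    """Thresholds for the nested seed filters (lengths nm, areas nm^2, deg)."""

    d1_max: float = 0.6
    d2_max: float = 0.6
    cata_min: float = 2.5
    d3_max: float = 0.8
    angle_center: float = 120.0
    angle_halfwidth: float = 20.0
    #: boundary separating the low/high ring-angle modes, degrees
    angle_boundary: float = 90.0

    def validate(self) -> None:
        for name in ("d1_max", "d2_max", "cata_min", "d3_max"):
            if not getattr(self, name) > 0:
                raise ModelError(f"{name} must be > 0")
        lo = self.angle_center - self.angle_halfwidth
        hi = self.angle_center + self.angle_halfwidth
        if lo < 0 or hi > 180:
            raise ModelError("angle window must lie within [0, 180] degrees")


@dataclass
class SeedReport:
    """Stage-wise occupancies (percent) and per-frame classification."""

    fraction_d1d2: float
    fraction_d3: float
    fraction_seed: float
    angle_region_occupancy: dict[int, float]
    labels: list[str] = field(repr=False)   # per frame: none|d1d2|d3|seed
    n_frames: int = 0
    denominator: str = "total"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": range(self.n_frames), "classification": self.labels}
        )


def angle_region_partition(theta1: float, theta2: float, boundary: float = 90.0) -> int:
    """Quadrant id (1..4) of a ring-angle pair around ``boundary``.

    The four observed ring-angle modes are separated by one boundary per
    axis; region 4 (both angles above the boundary) contains the (120, 120)
    seed mode.  Angles exactly on a boundary join the lower-indexed region.
    """
    for t in (theta1, theta2):
        if not (0.0 <= t <= 180.0):
            raise ModelError(f"angle {t} outside [0, 180]")
    hi1 = theta1 > boundary
    hi2 = theta2 > boundary
    return 1 + int(hi1) + 2 * int(hi2)


SEED_ANGLE_REGION = 4  # region containing the (120 deg, 120 deg) mode


def classify_frames(
    records: list[AssociationRecord],
    criteria: SeedCriteria | None = None,
    denominator: str = "total",
) -> SeedReport:
    """Apply the nested seed filters to per-frame association records.

    ``denominator`` is ``"total"`` (all frames, including dissociated
    CA_T = 0 frames — the default) or ``"contact"`` (frames with CA_T > 0).
    """
    criteria = criteria or SeedCriteria()
    criteria.validate()
    if not records:
        raise ModelError("no records to classify")
    if denominator not in ("total", "contact"):
        raise ModelError("denominator must be 'total' or 'contact'")

    required = ("D1", "D2", "D3", "theta1", "theta2")
    labels: list[str] = []
    n_stage1 = n_stage2 = n_stage3 = 0
    region_counts: dict[int, int] = {1: 0, 2: 0, 3: 0, 4: 0}
    n_classified = 0
    lo = criteria.angle_center - criteria.angle_halfwidth
    hi = criteria.angle_center + criteria.angle_halfwidth

    for rec in records:
        vals = {f: getattr(rec, f) for f in required}
        if any(np.isnan(v) for v in vals.values()):
            raise ModelError(
                f"frame {rec.frame_index}: records lack required fields "
                f"{[f for f, v in vals.items() if np.isnan(v)]}"
            )
        stage1 = (
            vals["D1"] < criteria.d1_max
            and vals["D2"] < criteria.d2_max
            and rec.CATa > criteria.cata_min
        )
        stage2 = stage1 and vals["D3"] < criteria.d3_max
        in_window = lo <= vals["theta1"] <= hi and lo <= vals["theta2"] <= hi
        stage3 = stage2 and in_window
        if stage2:
            region_counts[
                angle_region_partition(vals["theta1"], vals["theta2"], criteria.angle_boundary)
            ] += 1
            n_classified += 1
        n_stage1 += stage1
        n_stage2 += stage2
        n_stage3 += stage3
        labels.append("seed" if stage3 else "d3" if stage2 else "d1d2" if stage1 else "none")

    if denominator == "total":
        denom = len(records)
    else:
        denom = sum(1 for r in records if r.CAT > 0)
        if denom == 0:
            raise ModelError("contact denominator requested but no frames have CAT > 0")

    occupancy = {
        k: (100.0 * v / n_classified if n_classified else 0.0)
        for k, v in region_counts.items()
    }
    return SeedReport(
        fraction_d1d2=100.0 * n_stage1 / denom,
        fraction_d3=100.0 * n_stage2 / denom,
        fraction_seed=100.0 * n_stage3 / denom,
        angle_region_occupancy=occupancy,
        labels=labels,
        n_frames=len(records),
        denominator=denominator,
    )
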