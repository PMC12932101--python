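"""Normalization of raw luminescence to transduction efficiency.

Raw RLU values are converted to transduction efficiency as a percentage of
the antibody-free (virus-only) control matched on plate, serotype and assay
format; percent inhibition is the complement (100 - transduction %).  This
ratiometric step cancels baseline differences in transduction efficiency
between serotypes and plates, so curves are comparable across runs.
Replicates are aggregated to mean and SD per dilution on the normalized
scale.  Values above 100% are legitimate (VSC baseline inflation) and are
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np

from .plates import PlateSet, PlateValidationError


@dataclass(frozen=True)
class CurvePoint:
    """Replicate-aggregated normalized transduction at one dilution."""

    dilution: Fraction
    mean_pct: float
    sd_pct: float
    n: int


@dataclass
class TransductionCurve:
    """Per-sample normalized transduction (%) along the dilution series.

    Points are sorted by increasing serum content, i.e. from the most
    dilute (1/128) to the least dilute (1/4) test serum.
    """

    sample_id: str
    serotype: str
    format: str
    points: list
    control_mean_rlu: float
    sample_type: str = "serum"
    #: relative standard error of the control mean the points were divided
    #: by — a scale uncertainty shared by every point of the curve
    control_rse: float = 0.0

    def point_at(self, dilution) -> Optional[CurvePoint]:
        target = Fraction(dilution)
        for p in self.points:
            if p.dilution == target:
                return p
        return None

    @property
    def dilutions(self) -> list:
        return [p.dilution for p in self.points]


def percent_inhibition(transduction_pct: float) -> float:
    """Percent inhibition = 100 - transduction %."""
    return 100.0 - transduction_pct


def normalize_plate(plates: PlateSet, subtract_blank: bool = False) -> list:
    """Normalize every test well to its matched antibody-free control.

    Controls are matched per (plate, serotype, format) group and aggregated
    by arithmetic mean; normalization never crosses plates.  A sample run on
    several plates of the same (serotype, format) contributes points
    normalized to each plate's own control, pooled into one curve.

    Parameters
    ----------
    plates : PlateSet
        Validated well set.
    subtract_blank : bool
        If True, subtract the group's blank-well mean RLU from every test
        and control well before normalizing (clipped at zero).  Off by
        default.

    Returns
    -------
    list of TransductionCurve, one per (sample, serotype, format).
    """
    groups: dict = {}
    for w in plates.wells:
        groups.setdefault((w.plate_id, w.serotype, w.format), []).append(w)

    # per-(sample, serotype, format) -> dilution -> list of normalized pcts
    values: dict = {}
    control_means: dict = {}
    control_rses: dict = {}
    sample_types: dict = {}
    for (plate_id, serotype, fmt), wells in groups.items():
        controls = [w.rlu for w in wells if w.role == "antibody_free_control"]
        tests = [w for w in wells if w.role == "test"]
        if not tests:
            continue
        if not controls:
            raise PlateValidationError(
                f"no antibody-free control for group {plate_id}/{serotype}/{fmt}"
            )
        blank = 0.0
        if subtract_blank:
            blanks = [w.rlu for w in wells if w.role == "blank"]
            blank = float(np.mean(blanks)) if blanks else 0.0
        corrected = [max(c - blank, 0.0) for c in controls]
        control_mean = float(np.mean(corrected))
        if control_mean == 0:
            raise PlateValidationError(
                f"control mean RLU is zero for group {plate_id}/{serotype}/{fmt}"
            )
        rse = 0.0
        if len(corrected) > 1:
            rse = float(
                np.std(corrected, ddof=1) / (control_mean * np.sqrt(len(corrected)))
            )
        for w in tests:
            key = (w.sample_id, serotype, fmt)
            pct = 100.0 * max(w.rlu - blank, 0.0) / control_mean
            values.setdefault(key, {}).setdefault(w.dilution, []).append(pct)
            control_means.setdefault(key, []).append(control_mean)
            control_rses.setdefault(key, []).append(rse)
            sample_types[key] = w.sample_type

    curves = []
    for (sample_id, serotype, fmt), by_dil in values.items():
        points = []
        for dilution in sorted(by_dil, key=float):
            vals = np.asarray(by_dil[dilution], dtype=float)
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            points.append(
                CurvePoint(
                    dilution=dilution,
                    mean_pct=float(vals.mean()),
                    sd_pct=sd,
                    n=int(vals.size),
                )
            )
        curves.append(
            TransductionCurve(
                sample_id=sample_id,
                serotype=serotype,
                format=fmt,
                points=points,
                control_mean_rlu=float(np.mean(control_means[(sample_id, serotype, fmt)])),
                sample_type=sample_types[(sample_id, serotype, fmt)],
                control_rse=float(np.mean(control_rses[(sample_id, serotype, fmt)])),
            )
        )
    curves.sort(key=lambda c: (c.serotype, c.format, c.sample_id))
    return curves
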