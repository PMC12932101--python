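"""Plate-level data containers and tabular I/O.

Raw data arrive as long-format CSV tables of 96-well plate-reader
luminescence (relative light units, RLU), one row per well, carrying the
experimental metadata needed downstream: which serum sample the well holds,
its role (test well, antibody-free control, blank), the AAV serotype, the
assay format (CSC = constant serum concentration, VSC = variable serum
concentration), the serum dilution and the replicate index.  A wide 8x12
grid export plus a plate-map config is also accepted.

Dilutions are kept as exact :class:`fractions.Fraction` values throughout
(titers are 2-fold series such as 1/4 ... 1/128; exact fractions avoid float
drift across the series).  In result tables a dilution is serialized as its
decimal value plus a ``"1/8"``-style display string.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from fractions import Fraction
from typing import Iterable, Optional

import pandas as pd
import yaml

FORMATS = ("CSC", "VSC")
ROLES = ("test", "antibody_free_control", "blank")

#: column order of the long-format wells CSV
WELL_COLUMNS = [
    "plate_id",
    "well",
    "sample_id",
    "role",
    "serotype",
    "format",
    "dilution",
    "replicate",
    "rlu",
    "sample_type",
]

_WELL_RE = re.compile(r"^([A-Ha-h])0?([1-9]|1[0-2])$")


class PlateValidationError(ValueError):
    """Raised when a plate table violates the schema or layout contract."""


def normalize_well_label(label: str) -> str:
    """Normalize a well position to letter-row, 1-based column ("a01" -> "A1")."""
    m = _WELL_RE.match(str(label).strip())
    if m is None:
        raise PlateValidationError(f"invalid well position {label!r}")
    return m.group(1).upper() + m.group(2)


def parse_dilution(value) -> Optional[Fraction]:
    """Parse a dilution cell: '1/8', '0.125' or none/NA -> Fraction or None."""
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"none", "na", "nan"}:
        return None
    try:
        frac = Fraction(s)
    except (ValueError, ZeroDivisionError) as exc:
        raise PlateValidationError(f"invalid dilution {value!r}") from exc
    if not 0 < frac <= 1:
        raise PlateValidationError(f"dilution {value!r} outside (0, 1]")
    return frac


def format_dilution(frac) -> str:
    """Display string for a dilution ('1/8'); empty string for None."""
    if frac is None:
        return ""
    f = Fraction(frac).limit_denominator(10**6)
    return f"{f.numerator}/{f.denominator}"


@dataclass(frozen=True)
class WellRecord:
    """One well's raw luminescence with its full experimental metadata."""

    plate_id: str
    well: str
    sample_id: str
    role: str
    serotype: str
    format: str
    dilution: Optional[Fraction]
    replicate: int
    rlu: float
    sample_type: str = "serum"  # serum | mab, drives the auto model policy

    def __post_init__(self):
        if self.role not in ROLES:
            raise PlateValidationError(f"unknown role {self.role!r}")
        if self.format not in FORMATS:
            raise PlateValidationError(f"unknown format {self.format!r}")
        if self.role == "test" and self.dilution is None:
            raise PlateValidationError(
                f"test well {self.plate_id}/{self.well} lacks a dilution"
            )
        if self.role == "antibody_free_control" and self.dilution is not None:
            raise PlateValidationError(
                f"control well {self.plate_id}/{self.well} must have dilution 'none'"
            )
        if self.rlu < 0:
            raise PlateValidationError(
                f"negative RLU in well {self.plate_id}/{self.well}"
            )
        if self.replicate < 1:
            raise PlateValidationError(
                f"replicate index must be >= 1 in {self.plate_id}/{self.well}"
            )


@dataclass
class PlateSet:
    """A validated collection of wells, possibly spanning several plates."""

    wells: list[WellRecord]
    provenance: str = ""

    def validate(self) -> "PlateSet":
        seen = set()
        for w in self.wells:
            key = (w.plate_id, w.well)
            if key in seen:
                raise PlateValidationError(f"duplicate well {key}")
            seen.add(key)
        # every group with test wells needs an antibody-free control
        groups_with_tests = {}
        groups_with_controls = set()
        for w in self.wells:
            g = (w.serotype, w.format, w.plate_id)
            if w.role == "test":
                groups_with_tests[g] = True
            elif w.role == "antibody_free_control":
                groups_with_controls.add(g)
        missing = [g for g in groups_with_tests if g not in groups_with_controls]
        if missing:
            raise PlateValidationError(
                "test group(s) lacking an antibody-free control well: "
                + ", ".join("/".join(g) for g in sorted(missing))
            )
        return self

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            rows.append(
                {
                    "plate_id": w.plate_id,
                    "well": w.well,
                    "sample_id": w.sample_id,
                    "role": w.role,
                    "serotype": w.serotype,
                    "format": w.format,
                    "dilution": format_dilution(w.dilution) or "none",
                    "replicate": w.replicate,
                    "rlu": w.rlu,
                    "sample_type": w.sample_type,
                }
            )
        return pd.DataFrame(rows, columns=WELL_COLUMNS)


def read_wells(path, plate_map=None) -> PlateSet:
    """Read a wells table into a validated :class:`PlateSet`.

    Parameters
    ----------
    path : str or Path
        Long-format CSV with the :data:`WELL_COLUMNS` schema, or — when
        ``plate_map`` is given — a wide 8x12 grid CSV whose first column is
        the row letter (A–H) and whose remaining columns are plate columns
        1–12, holding raw RLU values.
    plate_map : str, Path or dict, optional
        YAML file (or pre-parsed mapping) assigning metadata by well for the
        wide-grid layout: top-level ``plate_id``, ``serotype``, ``format``
        and a ``wells`` mapping of well position to
        ``{sample_id, role, dilution, replicate}``.  Grid wells absent from
        the map are ignored.
    """
    if plate_map is not None:
        return _read_wide_grid(path, plate_map)
    df = pd.read_csv(path, dtype=str)
    required = [c for c in WELL_COLUMNS if c != "sample_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PlateValidationError(
            "missing required column(s): " + ", ".join(missing)
        )
    wells = []
    for _, row in df.iterrows():
        wells.append(
            WellRecord(
                plate_id=str(row["plate_id"]),
                well=normalize_well_label(row["well"]),
                sample_id=str(row["sample_id"]),
                role=str(row["role"]),
                serotype=str(row["serotype"]),
                format=str(row["format"]),
                dilution=parse_dilution(row["dilution"]),
                replicate=int(row["replicate"]),
                rlu=float(row["rlu"]),
                sample_type=str(row.get("sample_type", "serum") or "serum"),
            )
        )
    return PlateSet(wells=wells, provenance=str(path)).validate()


def _read_wide_grid(path, plate_map) -> PlateSet:
    if not isinstance(plate_map, dict):
        with open(plate_map) as fh:
            plate_map = yaml.safe_load(fh)
    for key in ("plate_id", "serotype", "format", "wells"):
        if key not in plate_map:
            raise PlateValidationError(f"plate map missing key {key!r}")
    grid = pd.read_csv(path, index_col=0)
    rlu_by_well = {}
    for row_letter, row in grid.iterrows():
        for col, value in row.items():
            if pd.isna(value):
                continue
            rlu_by_well[normalize_well_label(f"{row_letter}{int(col)}")] = float(value)
    wells = []
    for pos, meta in plate_map["wells"].items():
        pos = normalize_well_label(pos)
        if pos not in rlu_by_well:
            raise PlateValidationError(f"plate map well {pos} absent from grid")
        wells.append(
            WellRecord(
                plate_id=str(plate_map["plate_id"]),
                well=pos,
                sample_id=str(meta.get("sample_id", "control")),
                role=str(meta["role"]),
                serotype=str(plate_map["serotype"]),
                format=str(plate_map["format"]),
                dilution=parse_dilution(meta.get("dilution")),
                replicate=int(meta.get("replicate", 1)),
                rlu=rlu_by_well[pos],
                sample_type=str(meta.get("sample_type", "serum")),
            )
        )
    return PlateSet(wells=wells, provenance=str(path)).validate()


def write_wells(plates: PlateSet, path) -> None:
    """Write a :class:`PlateSet` back to the long-format wells CSV."""
    plates.to_dataframe().to_csv(path, index=False)


def write_results(results, path) -> None:
    """Write any results table as CSV with a stable column order.

    ``results`` may be a DataFrame or an iterable of dataclass instances
    (column order then follows the dataclass field order).  An empty input
    still produces a header-only file when the columns are known.
    """
    if isinstance(results, pd.DataFrame):
        results.to_csv(path, index=False)
        return
    results = list(results)
    if not results:
        pd.DataFrame().to_csv(path, index=False)
        return
    cols = [f.name for f in fields(results[0])]
    rows = []
    for r in results:
        rows.append({c: getattr(r, c) for c in cols})
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# result-table converters (duck-typed; concrete types live in their modules)
# ---------------------------------------------------------------------------

CURVE_COLUMNS = [
    "sample_id",
    "serotype",
    "format",
    "sample_type",
    "dilution",
    "dilution_display",
    "mean_pct",
    "sd_pct",
    "n",
    "control_mean_rlu",
]

ND50_COLUMNS = [
    "sample_id",
    "serotype",
    "format",
    "nd50",
    "nd50_display",
    "ci_low",
    "ci_high",
    "model",
    "censored",
    "display_titer",
]


def curves_table(curves) -> pd.DataFrame:
    """Flatten TransductionCurve objects into a long table (one row per point)."""
    rows = []
    for c in curves:
        for p in c.points:
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "serotype": c.serotype,
                    "format": c.format,
                    "sample_type": c.sample_type,
                    "dilution": float(p.dilution),
                    "dilution_display": format_dilution(p.dilution),
                    "mean_pct": p.mean_pct,
                    "sd_pct": p.sd_pct,
                    "n": p.n,
                    "control_mean_rlu": c.control_mean_rlu,
                }
            )
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def nd50_table(results) -> pd.DataFrame:
    """ND50 results as a table; titers serialized as decimal + display string."""
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "serotype": r.serotype,
                "format": r.format,
                "nd50": "" if r.nd50 is None else repr(float(r.nd50)),
                "nd50_display": "" if r.nd50 is None else format_dilution(
                    Fraction(1, max(1, round(1.0 / r.nd50)))
                ),
                "ci_low": "" if r.ci_low is None else repr(float(r.ci_low)),
                "ci_high": "" if r.ci_high is None else repr(float(r.ci_high)),
                "model": r.model,
                "censored": r.censored,
                "display_titer": format_dilution(r.display_titer),
            }
        )
    return pd.DataFrame(rows, columns=ND50_COLUMNS)


def read_nd50_table(path):
    """Read an ND50 results CSV back into ND50Result objects.

    Verifies the fixed serialization rule: the decimal ``nd50`` column and
    the ``nd50_display`` fraction string must agree.
    """
    from .doseresponse import ND50Result  # deferred: avoids an import cycle

    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        nd50 = None if row["nd50"] == "" else float(row["nd50"])
        if nd50 is not None and row["nd50_display"]:
            # the display is the rounded-reciprocal convention (e.g. 1/8);
            # verify it is consistent with the authoritative decimal
            shown = Fraction(row["nd50_display"])
            if shown != Fraction(1, max(1, round(1.0 / nd50))):
                raise PlateValidationError(
                    f"nd50 decimal {nd50} disagrees with display "
                    f"{row['nd50_display']} for sample {row['sample_id']}"
                )
        out.append(
            ND50Result(
                sample_id=row["sample_id"],
                serotype=row["serotype"],
                format=row["format"],
                nd50=nd50,
                ci_low=None if row["ci_low"] == "" else float(row["ci_low"]),
                ci_high=None if row["ci_high"] == "" else float(row["ci_high"]),
                model=row["model"],
                censored=str(row["censored"]).lower() == "true",
                display_titer=Fraction(row["display_titer"]),
            )
        )
    return out
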