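"""Synthetic plate-data generator with serum matrix effects.

Cell-based AAV neutralization assays read out reporter luminescence after
transducing cells in the presence of serially diluted test serum.  Two
serum-driven artifacts, unrelated to antibodies, shape the raw signal:

* **enhancement** — serum pre-incubated with the vector increases
  transduction, saturating near 5% serum volume fraction;
* **inhibition** — serum present in the cell-culture medium decreases
  transduction.

In the *variable serum concentration* (VSC) format the total serum per well
rises as the test serum is less dilute, so the enhancement grows along the
dilution series and inflates the baseline above 100% of the antibody-free
control, masking partial neutralization.  The *constant serum concentration*
(CSC) format holds total serum fixed (default 10%) by diluting test serum in
an antibody-free serum matrix, so the matrix factor cancels exactly against
the format-matched control.

The generator draws per-well RLU as

    RLU = baseline * E(s_aav) * I(s_medium) * H(d) * eps

where ``E`` is the enhancement factor for the serum fraction pre-incubated
with the vector, ``I`` the inhibition factor for the serum fraction in the
cell medium, ``H`` the Hill neutralization survival of the test serum at
dilution ``d`` (identically 1 for seronegative samples, 0.5 at the true
ND50), and ``eps`` multiplicative lognormal noise.  Ground truth is recorded
so every downstream stage can be tested against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .plates import FORMATS, PlateSet, WellRecord, format_dilution, parse_dilution

#: default 2-fold dilution series 1/4 ... 1/128 (strongest serum first)
DEFAULT_DILUTIONS = tuple(Fraction(1, 2**k) for k in range(2, 8))

_ROWS = "ABCDEFGH"
_PLATE_CAPACITY = 96


@dataclass(frozen=True)
class MatrixEffectModel:
    """Antibody-independent serum effects on transduction.

    ``enhancement(s) = 1 + enhance_amplitude * s / (s + enhance_halfsat)``
    is a saturating hyperbola (half-maximal at ``enhance_halfsat``, default
    5% serum), and ``inhibition(s) = 1 / (1 + inhibit_strength * s**inhibit_shape)``
    is a Hill-type decay.  Both equal 1 at zero serum.
    """

    enhance_amplitude: float = 2.0
    enhance_halfsat: float = 0.05
    inhibit_strength: float = 8.0
    inhibit_shape: float = 1.0

    def __post_init__(self):
        if self.enhance_amplitude < 0:
            raise ValueError("enhance_amplitude must be >= 0")
        if not 0 < self.enhance_halfsat <= 1:
            raise ValueError("enhance_halfsat must be in (0, 1]")
        if self.inhibit_strength < 0:
            raise ValueError("inhibit_strength must be >= 0")
        if self.inhibit_shape <= 0:
            raise ValueError("inhibit_shape must be > 0")

    def enhancement(self, s):
        """Fold-change from serum pre-incubated with the vector."""
        s = np.asarray(s, dtype=float)
        out = 1.0 + self.enhance_amplitude * s / (s + self.enhance_halfsat)
        return float(out) if out.ndim == 0 else out

    def inhibition(self, s):
        """Fold-change from serum present in the cell medium."""
        s = np.asarray(s, dtype=float)
        out = 1.0 / (1.0 + self.inhibit_strength * s**self.inhibit_shape)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SampleProfile:
    """Ground-truth neutralization behaviour of one serum sample.

    ``true_nd50`` is the dilution fraction at which Hill survival is 0.5;
    ``None`` marks a seronegative sample (no drop anywhere in the series).
    """

    sample_id: str
    true_nd50: Optional[Fraction] = None
    hill_slope: float = 2.0
    sample_type: str = "serum"

    def __post_init__(self):
        if self.true_nd50 is not None:
            frac = Fraction(self.true_nd50)
            object.__setattr__(self, "true_nd50", frac)
            if not 0 < frac <= 1:
                raise ValueError("true_nd50 must be in (0, 1] or None")
        if self.hill_slope <= 0:
            raise ValueError("hill_slope must be > 0")

    @property
    def serostatus_truth(self) -> str:
        return "seronegative" if self.true_nd50 is None else "seropositive"

    def survival(self, dilution) -> float:
        """Hill neutralization survival H(d) with bottom 0 and top 1."""
        if self.true_nd50 is None:
            return 1.0
        ratio = float(dilution) / float(self.true_nd50)
        return 1.0 / (1.0 + ratio**self.hill_slope)


@dataclass(frozen=True)
class AssayDesign:
    """Plate layout and serum-composition rule for one assay format."""

    format: str = "CSC"
    serotype: str = "AAV9"
    dilutions: tuple = DEFAULT_DILUTIONS
    csc_total_serum: float = 0.10
    vsc_medium_serum: float = 0.0125
    vsc_test_serum_scale: float = 0.25  # final test-serum fraction = dilution * scale
    replicates: int = 3
    control_replicates: int = 6
    noise_sigma: float = 0.05
    baseline_rlu: float = 1.0e6
    seed: int = 0

    def __post_init__(self):
        if self.format not in FORMATS:
            raise ValueError(f"format must be one of {FORMATS}")
        dils = tuple(Fraction(d) for d in self.dilutions)
        object.__setattr__(self, "dilutions", dils)
        if not dils:
            raise ValueError("empty dilution list")
        for d in dils:
            if not 0 < d < 1:
                raise ValueError(f"dilution {d} outside (0, 1)")
        for a, b in zip(dils, dils[1:]):
            if b * 2 != a:
                raise ValueError("dilutions must decrease strictly by factor 2")
        if self.replicates < 1 or self.control_replicates < 1:
            raise ValueError("replicates and control_replicates must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.baseline_rlu <= 0:
            raise ValueError("non-positive baseline_rlu")

    @property
    def medium_serum(self) -> float:
        """Serum volume fraction in the cell-culture medium (drives inhibition)."""
        return 0.0 if self.format == "CSC" else self.vsc_medium_serum

    @property
    def control_serum(self) -> float:
        """Total serum seen by the vector in the antibody-free control well."""
        if self.format == "CSC":
            return self.csc_total_serum
        return self.vsc_medium_serum  # DMEM control: only the medium's serum


def serum_composition(format: str, dilution, design: AssayDesign) -> float:
    """Total serum volume fraction in a test well at a given dilution.

    CSC holds total serum fixed at ``csc_total_serum`` for every dilution;
    VSC adds the test serum (``dilution * vsc_test_serum_scale``) on top of
    the fixed medium serum, so total serum strictly increases as the test
    serum is less dilute.
    """
    d = float(dilution)
    if not 0 < d < 1:
        raise ValueError(f"dilution {dilution} outside (0, 1)")
    if format not in FORMATS:
        raise ValueError(f"format must be one of {FORMATS}")
    if format == "CSC":
        return design.csc_total_serum
    return design.vsc_medium_serum + design.vsc_test_serum_scale * d


@dataclass(frozen=True)
class SimulationTruth:
    """Generator ground truth: sample profiles + matrix model + design."""

    profiles: tuple
    matrix: MatrixEffectModel = MatrixEffectModel()
    design: AssayDesign = AssayDesign()

    def __post_init__(self):
        object.__setattr__(self, "profiles", tuple(self.profiles))
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in profiles")

    # -- serialization (ground-truth sidecar) -------------------------------

    def to_dict(self) -> dict:
        return {
            "profiles": [
                {
                    "sample_id": p.sample_id,
                    "true_nd50": format_dilution(p.true_nd50) or "none",
                    "hill_slope": p.hill_slope,
                    "sample_type": p.sample_type,
                }
                for p in self.profiles
            ],
            "matrix": {
                "enhance_amplitude": self.matrix.enhance_amplitude,
                "enhance_halfsat": self.matrix.enhance_halfsat,
                "inhibit_strength": self.matrix.inhibit_strength,
                "inhibit_shape": self.matrix.inhibit_shape,
            },
            "design": {
                "format": self.design.format,
                "serotype": self.design.serotype,
                "dilutions": [format_dilution(d) for d in self.design.dilutions],
                "csc_total_serum": self.design.csc_total_serum,
                "vsc_medium_serum": self.design.vsc_medium_serum,
                "vsc_test_serum_scale": self.design.vsc_test_serum_scale,
                "replicates": self.design.replicates,
                "control_replicates": self.design.control_replicates,
                "noise_sigma": self.design.noise_sigma,
                "baseline_rlu": self.design.baseline_rlu,
                "seed": self.design.seed,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationTruth":
        profiles = tuple(
            SampleProfile(
                sample_id=p["sample_id"],
                true_nd50=parse_dilution(p.get("true_nd50")),
                hill_slope=float(p.get("hill_slope", 2.0)),
                sample_type=p.get("sample_type", "serum"),
            )
            for p in data["profiles"]
        )
        d = dict(data["design"])
        d["dilutions"] = tuple(Fraction(x) for x in d["dilutions"])
        return cls(
            profiles=profiles,
            matrix=MatrixEffectModel(**data["matrix"]),
            design=AssayDesign(**d),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def expected_rlu(profile: Optional[SampleProfile], dilution, truth: SimulationTruth) -> float:
    """Noise-free expected RLU of one well (``profile=None`` -> control well)."""
    design, matrix = truth.design, truth.matrix
    inhib = matrix.inhibition(design.medium_serum)
    if profile is None:
        return design.baseline_rlu * matrix.enhancement(design.control_serum) * inhib
    s_total = serum_composition(design.format, dilution, design)
    return (
        design.baseline_rlu
        * matrix.enhancement(s_total)
        * inhib
        * profile.survival(dilution)
    )


def simulate_plate(truth: SimulationTruth, seed: Optional[int] = None) -> PlateSet:
    """Generate the full well set for one assay format.

    Test wells (one per profile x dilution x replicate) and antibody-free
    control wells (``control_replicates`` per plate) are laid out row-major
    across as many 96-well plates as needed; every plate carries its own
    controls so normalization stays within-plate.  Deterministic given the
    seed (``design.seed`` unless overridden).
    """
    design = truth.design
    rng = np.random.default_rng(design.seed if seed is None else seed)

    # (profile | None, dilution | None, replicate) specs, controls per plate
    test_specs = [
        (p, d, r)
        for p in truth.profiles
        for d in design.dilutions
        for r in range(1, design.replicates + 1)
    ]
    per_plate = _PLATE_CAPACITY - design.control_replicates
    if per_plate < 1:
        raise ValueError("control_replicates leaves no room for test wells")

    wells: list[WellRecord] = []
    plate_idx = 0
    for start in range(0, len(test_specs), per_plate):
        plate_idx += 1
        plate_id = f"{design.serotype}-{design.format}-P{plate_idx}"
        chunk = test_specs[start : start + per_plate]
        specs = [(None, None, r) for r in range(1, design.control_replicates + 1)]
        specs += chunk
        for i, (profile, dilution, rep) in enumerate(specs):
            pos = f"{_ROWS[i // 12]}{i % 12 + 1}"
            mean = expected_rlu(profile, dilution, truth)
            eps = (
                math.exp(rng.normal(0.0, design.noise_sigma))
                if design.noise_sigma > 0
                else 1.0
            )
            wells.append(
                WellRecord(
                    plate_id=plate_id,
                    well=pos,
                    sample_id="control" if profile is None else profile.sample_id,
                    role="antibody_free_control" if profile is None else "test",
                    serotype=design.serotype,
                    format=design.format,
                    dilution=dilution,
                    replicate=rep,
                    rlu=mean * eps,
                    sample_type="serum" if profile is None else profile.sample_type,
                )
            )
    return PlateSet(wells=wells, provenance="nabtiter.simulate").validate()


def simulate_serum_titration(
    mode: str,
    serum_levels: Sequence[float],
    matrix: MatrixEffectModel = MatrixEffectModel(),
    noise_sigma: float = 0.0,
    seed: int = 0,
    replicates: int = 3,
    baseline_rlu: float = 1.0e6,
) -> pd.DataFrame:
    """Antibody-free serum titration ("serum on cells" vs "serum on AAV").

    Emulates the matrix-effect characterization experiment: serum at each
    level is applied either to the cell medium (``on_cells``, inhibition
    only) or pre-incubated with the vector (``on_aav``, enhancement only),
    and luminescence is normalized to the 0%-serum condition.

    Returns a DataFrame with columns ``serum_level``, ``replicate``,
    ``transduction_pct``.
    """
    if mode not in ("on_cells", "on_aav"):
        raise ValueError("mode must be 'on_cells' or 'on_aav'")
    levels = [float(s) for s in serum_levels]
    if 0.0 not in levels:
        raise ValueError("serum_levels must include the 0% reference condition")
    rng = np.random.default_rng(seed)
    factor = matrix.enhancement if mode == "on_aav" else matrix.inhibition
    rows = []
    for s in levels:
        for rep in range(1, replicates + 1):
            eps = math.exp(rng.normal(0.0, noise_sigma)) if noise_sigma > 0 else 1.0
            rows.append((s, rep, baseline_rlu * factor(s) * eps))
    df = pd.DataFrame(rows, columns=["serum_level", "replicate", "rlu"])
    ref = df.loc[df["serum_level"] == 0.0, "rlu"].mean()
    df["transduction_pct"] = 100.0 * df["rlu"] / ref
    return df[["serum_level", "replicate", "transduction_pct"]]


# ---------------------------------------------------------------------------
# documented masking parameter set
# ---------------------------------------------------------------------------

#: Matrix-effect parameters under which VSC baseline inflation masks a
#: low-titer neutralizer: max 3-fold enhancement, half-saturating at 5% serum.
MASKING_MATRIX = MatrixEffectModel(
    enhance_amplitude=2.0, enhance_halfsat=0.05, inhibit_strength=8.0, inhibit_shape=1.0
)

#: The masked sample: true ND50 = 1/5 (inside the tested 1/4..1/128 range).
#: Noise-free, its CSC curve crosses 50% between 1/8 and 1/4 while its VSC
#: curve stays above 50% at every tested dilution.
MASKING_SAMPLE = SampleProfile("masked", true_nd50=Fraction(1, 5), hill_slope=2.0)

#: Panel around the masked sample: two seronegatives, one very weak
#: neutralizer (below the tested range), one mid and one strong titer.
MASKING_PANEL = (
    SampleProfile("neg1"),
    SampleProfile("neg2"),
    SampleProfile("weak", true_nd50=Fraction(1, 3), hill_slope=2.0),
    MASKING_SAMPLE,
    SampleProfile("mid", true_nd50=Fraction(1, 12), hill_slope=2.0),
    SampleProfile("strong", true_nd50=Fraction(1, 48), hill_slope=2.0),
)


def masking_demo_truth(format: str = "CSC", noise_sigma: float = 0.0) -> SimulationTruth:
    """The documented masking scenario for a given assay format.

    Simulating this truth under both formats (noise-free) demonstrates the
    masking effect: the ``masked`` sample classifies as neutralizing under
    CSC but non-neutralizing under VSC, and VSC flags strictly fewer samples
    as ineligible / neutralizing than CSC.
    """
    return SimulationTruth(
        profiles=MASKING_PANEL,
        matrix=MASKING_MATRIX,
        design=AssayDesign(format=format, noise_sigma=noise_sigma),
    )
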