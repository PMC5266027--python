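"""Patient-specific circulatory physiology.

Maps a patient's sex, height and weight onto the global and regional
haemodynamic quantities that scale the compartment model:

* total blood volume from the classical sex-specific anthropometric
  regression ``BV [L] = a * height[m]^3 + b * weight[kg] + c`` (Nadler's
  coefficients by default, stored in the config so they can be swapped);
* cardiac output by allometric scaling from a 70 kg reference adult,
  ``CO = CO_ref * (W / W_ref)^0.75``;
* regional blood flows and regional blood volumes as fixed reference
  fractions of those totals, one fraction per compartment of the circulation
  topology;
* organ extracellular (interstitial) volumes as mL per kg body weight.

All quantities are SI-adjacent CT conventions: mL, mL/s, seconds.  Minutes
appear only in the config (reference cardiac output) and are converted on
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .config import load_default_config
from .errors import ConfigurationError, ValidationError

_SEXES = ("male", "female")

HEIGHT_RANGE_CM = (100.0, 230.0)
WEIGHT_RANGE_KG = (25.0, 250.0)

_FLOW_TOL = 1e-9
_VOLUME_TOL = 1e-6


@dataclass(frozen=True)
class PatientProfile:
    """Demographic parameters driving all physiological scaling.

    ``age`` is carried as metadata only; the model uses sex, height and
    weight.
    """

    sex: str
    height_cm: float
    weight_kg: float
    age: float | None = None
    id: str = ""

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValidationError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        lo, hi = HEIGHT_RANGE_CM
        if not (lo <= self.height_cm <= hi):
            raise ValidationError(
                f"height_cm={self.height_cm} outside valid range [{lo}, {hi}]"
            )
        lo, hi = WEIGHT_RANGE_KG
        if not (lo <= self.weight_kg <= hi):
            raise ValidationError(
                f"weight_kg={self.weight_kg} outside valid range [{lo}, {hi}]"
            )


@dataclass
class BodyParameters:
    """Patient-scaled global and regional circulatory parameters.

    ``regional_flow`` holds each compartment's throughput blood flow in mL/s;
    ``regional_blood_volume`` its share of total blood volume in mL;
    ``extracellular_volume`` the interstitial volume (mL) of each exchange
    organ.  ``systemic_branches`` lists the parallel branches leaving the
    aortic network, whose flows must sum to cardiac output.
    """

    total_blood_volume: float
    cardiac_output: float
    regional_flow: dict[str, float]
    regional_blood_volume: dict[str, float]
    extracellular_volume: dict[str, float] = field(default_factory=dict)
    systemic_branches: tuple[str, ...] = ()

    def validate(self) -> None:
        for name, value in {
            "total_blood_volume": self.total_blood_volume,
            "cardiac_output": self.cardiac_output,
        }.items():
            if not value > 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        for table_name, table in (
            ("regional_flow", self.regional_flow),
            ("regional_blood_volume", self.regional_blood_volume),
            ("extracellular_volume", self.extracellular_volume),
        ):
            for comp, value in table.items():
                if not value > 0:
                    raise ValidationError(
                        f"{table_name}[{comp!r}] must be positive, got {value}"
                    )
        branch_flow = sum(self.regional_flow[b] for b in self.systemic_branches)
        if abs(branch_flow - self.cardiac_output) > _FLOW_TOL * self.cardiac_output:
            raise ValidationError(
                "systemic branch flows sum to "
                f"{branch_flow} mL/s, cardiac output is {self.cardiac_output} mL/s"
            )
        volume = sum(self.regional_blood_volume.values())
        if abs(volume - self.total_blood_volume) > _VOLUME_TOL * self.total_blood_volume:
            raise ValidationError(
                "regional blood volumes sum to "
                f"{volume} mL, total blood volume is {self.total_blood_volume} mL"
            )


def compute_blood_volume(profile: PatientProfile, config: Mapping | None = None) -> float:
    """Total blood volume in mL for a patient.

    Evaluates the sex-specific regression on height (m, cubed) and weight
    (kg).  Strictly increasing in both height and weight because the
    coefficients are positive.
    """
    cfg = config if config is not None else load_default_config()
    coeffs = cfg["physiology"]["blood_volume"][profile.sex]
    height_m = profile.height_cm / 100.0
    litres = (
        coeffs["h3_coeff"] * height_m**3
        + coeffs["w_coeff"] * profile.weight_kg
        + coeffs["intercept_L"]
    )
    return litres * 1000.0


def compute_cardiac_output(profile: PatientProfile, config: Mapping | None = None) -> float:
    """Cardiac output in mL/s via allometric scaling from the reference adult."""
    cfg = config if config is not None else load_default_config()
    co = cfg["physiology"]["cardiac_output"]
    ref_ml_s = co["reference_ml_per_min"] / 60.0
    return ref_ml_s * (profile.weight_kg / co["reference_weight_kg"]) ** co[
        "allometric_exponent"
    ]


def compute_body_parameters(
    profile: PatientProfile, physiology_table: Mapping | None = None
) -> BodyParameters:
    """Scale the reference fraction table to one patient.

    Regional flow = cardiac output x flow fraction; regional blood volume =
    total blood volume x volume fraction; organ extracellular volume =
    mL-per-kg reference x body weight.  The returned object satisfies the
    flow- and volume-conservation invariants by construction and is
    validated before return.
    """
    cfg = physiology_table if physiology_table is not None else load_default_config()
    comps = cfg["compartments"]
    if not comps:
        raise ConfigurationError("physiology table lists no compartments")

    bv = compute_blood_volume(profile, cfg)
    co = compute_cardiac_output(profile, cfg)

    regional_flow: dict[str, float] = {}
    regional_volume: dict[str, float] = {}
    ecv: dict[str, float] = {}
    branches: list[str] = []
    for comp in comps:
        name = comp["name"]
        regional_flow[name] = co * comp["flow_fraction"]
        regional_volume[name] = bv * comp["blood_volume_fraction"]
        if comp.get("kind") == "organ":
            ecv[name] = comp["extracellular_ml_per_kg"] * profile.weight_kg
        if comp.get("systemic_branch", False):
            branches.append(name)

    params = BodyParameters(
        total_blood_volume=bv,
        cardiac_output=co,
        regional_flow=regional_flow,
        regional_blood_volume=regional_volume,
        extracellular_volume=ecv,
        systemic_branches=tuple(branches),
    )
    params.validate()
    return params
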