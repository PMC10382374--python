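"""Map patient covariates to the full per-patient twin parameter set.

Physiology-dependent parameters (skin-layer thicknesses, PK compartment
volumes, inter-compartment clearances, hepatic clearance, and the pain
EC50) are computed from age, gender, weight and height, each multiplied by
an independent lognormal inter-individual variability factor exp(theta),
theta ~ Normal(0, sd_theta).  Physiology-independent constants
(diffusivities, capacities, the unbound fraction, and the PD endpoint
constants other than the pain EC50) come straight from the configuration.

Two scalars of the skin equations are not fixed by the printed formulas
(the viable-epidermis base thickness and the dermis age-scaling ratio);
they are shipped as configuration constants calibrated once so that the
reference-population means equal 29.7 um and 242.6 um, and
``calibrate_skin_constants`` re-derives them from any population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import BMI_BOUNDS, PatientProfile

REFERENCE_WEIGHT_KG = 70.0

#: Reference-table entries every PK derivation needs, per gender.
_PK_VOLUME_KEYS = ("V_central_L", "V_rapid_L", "V_slow_L", "V_gut_L", "V_liver_L")
_PK_FLOW_KEYS = (
    "Q_central_rapid_L_min",
    "Q_central_slow_L_min",
    "Q_central_gut_L_min",
    "Q_central_liver_L_min",
    "Q_gut_liver_L_min",
    "Q_liver_central_L_min",
)


@dataclass(frozen=True)
class VariabilitySpec:
    """Lognormal inter-individual variability: multiplier exp(theta) with
    theta ~ Normal(0, sd_theta).  sd_theta = 0.1 puts ~95% of parameter
    values within +-20% of the deterministic formula."""

    sd_theta: float = 0.1

    def draw(self, rng: np.random.Generator) -> float:
        if self.sd_theta == 0.0:
            return 0.0
        return float(rng.normal(0.0, self.sd_theta))

    def mean_multiplier(self) -> float:
        """E[exp(theta)] for the lognormal perturbation."""
        return math.exp(0.5 * self.sd_theta**2)


@dataclass(frozen=True)
class SkinGeometry:
    """Per-patient skin and patch geometry, in meters / m2 / ng."""

    d_sc: float
    d_vep: float
    d_edm: float
    d_patch: float
    patch_area: float
    patch_load: float  # ng of fentanyl in a fresh patch
    age_scaling_ratio: float

    def __post_init__(self) -> None:
        for name in ("d_sc", "d_vep", "d_edm", "d_patch", "patch_area"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class TransportParameters:
    """Layer diffusivities [m2/s] and capacities (dimensionless).

    Capacity ratios realize the interface partition coefficients:
    K_patch/K_sc = 0.29 (patch/epidermis) and K_vep/K_dermis = 1.
    """

    D_patch: float
    D_sc: float
    D_vep: float
    D_dermis: float
    K_patch: float
    K_sc: float
    K_vep: float
    K_dermis: float

    @property
    def K_pt_ep(self) -> float:
        return self.K_patch / self.K_sc

    @property
    def K_ep_dm(self) -> float:
        return self.K_vep / self.K_dermis


@dataclass(frozen=True)
class PKParameters:
    """Five-compartment PK parameter set (volumes [L], clearances [L/s]).

    Rate constants for the balance equations are derived on demand as
    flow / volume of the compartment whose equation they appear in.
    """

    V: Mapping[str, float]
    Q: Mapping[str, float]
    CL_hepatic: float
    CL_renal: float
    f_u: float
    literal_eq4_sign: bool = False
    literal_fu_central_only: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.f_u <= 1:
            raise ValueError("f_u must be in (0, 1]")
        for name, v in {**dict(self.V), **dict(self.Q)}.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.CL_hepatic < 0 or self.CL_renal < 0:
            raise ValueError("clearances must be non-negative")

    @property
    def k_re(self) -> float:
        """Renal elimination rate constant [1/s] on the central compartment."""
        return self.CL_renal / self.V["central"]

    @property
    def k_met(self) -> float:
        """Hepatic metabolic rate constant [1/s] on the liver compartment."""
        return self.CL_hepatic / self.V["liver"]


@dataclass(frozen=True)
class EndpointPD:
    """Sigmoid-Emax endpoint with an effect-compartment lag (decreasing
    branch: E = E0 - Emax * c^gamma / (EC50^gamma + c^gamma))."""

    k_e: float  # 1/s
    E0: float
    Emax: float
    ec50: float  # ng/ml
    gamma: float

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")


@dataclass(frozen=True)
class PDParameters:
    vas: EndpointPD
    ventilation: EndpointPD


@dataclass(frozen=True)
class TwinParameters:
    """The complete parameter bundle for one patient's digital twin."""

    patient: PatientProfile
    skin: SkinGeometry
    transport: TransportParameters
    pk: PKParameters
    pd: PDParameters
    theta: Mapping[str, float] = field(default_factory=dict)


def _gender_branch(gender: int, male: float, female: float) -> float:
    return gender * male + (1 - gender) * female


def sc_thickness_um(age: float, gender: int, cfg: Mapping) -> float:
    """Deterministic stratum-corneum thickness formula [um] (theta = 0)."""
    base = cfg["sc_slope_um_per_year"] * age + cfg["sc_base_um"] * _gender_branch(
        gender, 1.0, cfg["sc_female_factor"]
    )
    return cfg.get("sc_calibration_factor", 1.0) * base


def vep_thickness_um(gender: int, cfg: Mapping) -> float:
    """Deterministic viable-epidermis thickness formula [um] (theta = 0)."""
    return cfg["vep_base_um"] * _gender_branch(gender, 1.0, 1.0 / cfg["vep_female_divisor"])


def edm_thickness_um(bmi: float, gender: int, cfg: Mapping) -> float:
    """Deterministic equivalent-dermis thickness formula [um] (theta = 0).

    The BMI-linear branch evaluates in millimeters; the calibrated
    age-scaling ratio brings it to the equivalent (capillary-absorbing)
    thickness.
    """
    base_mm = _gender_branch(
        gender,
        cfg["edm_male_slope"] * bmi + cfg["edm_male_intercept"],
        cfg["edm_female_slope"] * bmi + cfg["edm_female_intercept"],
    )
    return base_mm * 1000.0 * cfg["edm_age_scaling_ratio"]


def derive_skin_geometry(
    patient: PatientProfile,
    skin_cfg: Mapping,
    patch_cfg: Mapping,
    thetas: Mapping[str, float],
) -> SkinGeometry:
    """Skin-layer thicknesses from the covariate formulas, each multiplied
    by its own exp(theta); output in meters."""
    lo, hi = skin_cfg.get("bmi_valid_range", BMI_BOUNDS)
    if not lo <= patient.bmi <= hi:
        raise ValueError(
            f"BMI {patient.bmi:.1f} outside the validated range [{lo}, {hi}] "
            "of the dermis-thickness equation"
        )
    um = 1e-6
    d_sc = sc_thickness_um(patient.age, patient.gender, skin_cfg) * math.exp(thetas["d_sc"]) * um
    d_vep = vep_thickness_um(patient.gender, skin_cfg) * math.exp(thetas["d_vep"]) * um
    d_edm = edm_thickness_um(patient.bmi, patient.gender, skin_cfg) * math.exp(thetas["d_edm"]) * um
    return SkinGeometry(
        d_sc=d_sc,
        d_vep=d_vep,
        d_edm=d_edm,
        d_patch=patch_cfg["thickness_um"] * um,
        patch_area=patch_cfg["area_cm2"] * 1e-4,
        patch_load=patch_cfg["load_mg"] * 1e6,
        age_scaling_ratio=skin_cfg["edm_age_scaling_ratio"],
    )


def derive_transport(transport_cfg: Mapping) -> TransportParameters:
    """Physiology-independent transport constants (no variability)."""
    return TransportParameters(
        D_patch=transport_cfg["D_patch"],
        D_sc=transport_cfg["D_epidermis"],
        D_vep=transport_cfg["D_epidermis"],
        D_dermis=transport_cfg["D_dermis"],
        K_patch=transport_cfg["K_patch"],
        K_sc=transport_cfg["K_sc"],
        K_vep=transport_cfg["K_vep"],
        K_dermis=transport_cfg["K_dermis"],
    )


def derive_pk_parameters(
    patient: PatientProfile,
    pk_ref: Mapping,
    thetas: Mapping[str, float],
) -> PKParameters:
    """Per-gender reference volumes and clearances scaled linearly by
    weight/70, each with an independent exp(theta) multiplier."""
    gender_key = "male" if patient.gender == 1 else "female"
    try:
        table = pk_ref[gender_key]
    except KeyError as exc:
        raise KeyError(f"pk_reference table missing gender entry {gender_key!r}") from exc
    scale = patient.weight / REFERENCE_WEIGHT_KG
    per_min = 1.0 / 60.0

    def entry(key: str) -> float:
        if key not in table:
            raise KeyError(f"pk_reference[{gender_key}] missing entry {key!r}")
        return float(table[key])

    V = {}
    for key in _PK_VOLUME_KEYS:
        name = key[2:-2]  # V_central_L -> central
        V[name] = entry(key) * scale * math.exp(thetas[f"V_{name}"])
    Q = {}
    for key in _PK_FLOW_KEYS:
        name = key[2:-6]  # Q_central_rapid_L_min -> central_rapid
        Q[name] = entry(key) * per_min * scale * math.exp(thetas[f"Q_{name}"])
    cl_h = entry("CL_hepatic_L_min") * per_min * scale * math.exp(thetas["CL_hepatic"])
    cl_re = entry("CL_renal_L_min") * per_min * scale * math.exp(thetas["CL_renal"])
    return PKParameters(
        V=V,
        Q=Q,
        CL_hepatic=cl_h,
        CL_renal=cl_re,
        f_u=pk_ref["f_u"],
        literal_eq4_sign=bool(pk_ref.get("literal_eq4_sign", False)),
        literal_fu_central_only=bool(pk_ref.get("literal_fu_central_only", False)),
    )


def derive_ec50_vas(age: float, theta: float, pd_vas_cfg: Mapping) -> float:
    """Age-linear pain EC50 [ng/ml], lognormally perturbed."""
    ec50 = (
        pd_vas_cfg["ec50_age_slope_per_year"] * age + pd_vas_cfg["ec50_intercept_ng_ml"]
    ) * math.exp(theta)
    if ec50 <= 0:
        raise ValueError(f"EC50 for age {age} is non-positive ({ec50:.3g} ng/ml)")
    return ec50


def derive_pd_parameters(
    patient: PatientProfile, pd_cfg: Mapping, thetas: Mapping[str, float]
) -> PDParameters:
    vas_cfg = pd_cfg["vas"]
    vent_cfg = pd_cfg["ventilation"]
    vas = EndpointPD(
        k_e=vas_cfg["k_e_per_s"],
        E0=vas_cfg["E0"],
        Emax=vas_cfg["Emax"],
        ec50=derive_ec50_vas(patient.age, thetas["EC50_vas"], vas_cfg),
        gamma=vas_cfg["gamma"],
    )
    ventilation = EndpointPD(
        k_e=vent_cfg["k_e_per_s"],
        E0=vent_cfg["E0_L_min"],
        Emax=vent_cfg["E0_L_min"] * vent_cfg["Emax_fraction"],
        ec50=vent_cfg["ec50_ng_ml"],
        gamma=vent_cfg["gamma"],
    )
    return PDParameters(vas=vas, ventilation=ventilation)


#: Names of every theta draw, in draw order (fixed so that a given seed
#: always yields the same multipliers).
THETA_NAMES = (
    "d_sc",
    "d_vep",
    "d_edm",
    "V_central",
    "V_rapid",
    "V_slow",
    "V_gut",
    "V_liver",
    "Q_central_rapid",
    "Q_central_slow",
    "Q_central_gut",
    "Q_central_liver",
    "Q_gut_liver",
    "Q_liver_central",
    "CL_hepatic",
    "CL_renal",
    "EC50_vas",
)


def draw_thetas(
    rng: np.random.Generator, variability: VariabilitySpec
) -> dict[str, float]:
    """One independent theta per physiology-dependent parameter."""
    return {name: variability.draw(rng) for name in THETA_NAMES}


def assemble_twin(
    patient: PatientProfile,
    config: Mapping,
    seed: int | np.random.Generator,
) -> TwinParameters:
    """Bundle the full parameter set for one patient, recording every theta
    draw for reproducibility.  Same patient + same seed -> identical twin."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    variability = VariabilitySpec(sd_theta=config["variability"]["sd_theta"])
    thetas = draw_thetas(rng, variability)
    return TwinParameters(
        patient=patient,
        skin=derive_skin_geometry(patient, config["skin"], config["patch"], thetas),
        transport=derive_transport(config["transport"]),
        pk=derive_pk_parameters(patient, config["pk_reference"], thetas),
        pd=derive_pd_parameters(patient, config["pd"], thetas),
        theta=thetas,
    )


def twin_parameter_table(twins: Sequence[TwinParameters]) -> pd.DataFrame:
    """Flat per-patient parameter table (for audit CSV output)."""
    rows = []
    for i, tw in enumerate(twins):
        row = {
            "id": i,
            "age_years": tw.patient.age,
            "gender": tw.patient.gender,
            "weight_kg": tw.patient.weight,
            "height_m": tw.patient.height,
            "d_sc_um": tw.skin.d_sc * 1e6,
            "d_vep_um": tw.skin.d_vep * 1e6,
            "d_edm_um": tw.skin.d_edm * 1e6,
            "ec50_vas_ng_ml": tw.pd.vas.ec50,
            "CL_hepatic_L_min": tw.pk.CL_hepatic * 60.0,
            "CL_renal_L_min": tw.pk.CL_renal * 60.0,
        }
        row.update({f"V_{k}_L": v for k, v in tw.pk.V.items()})
        row.update({f"Q_{k}_L_min": v * 60.0 for k, v in tw.pk.Q.items()})
        row.update({f"theta_{k}": v for k, v in tw.theta.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def calibrate_skin_constants(
    population: Sequence[PatientProfile],
    skin_cfg: Mapping,
    variability: VariabilitySpec,
    target_vep_um: float = 29.7,
    target_edm_um: float = 242.6,
) -> dict[str, float]:
    """Re-derive the two unprinted skin scalars from a reference population.

    Solves for the viable-epidermis base value and the dermis age-scaling
    ratio such that the *expected* population means (expectation over the
    lognormal variability taken analytically) equal the printed 29.7 um and
    242.6 um.  Deterministic given the population, hence idempotent.
    """
    mult = variability.mean_multiplier()
    vep_shape = np.mean(
        [_gender_branch(p.gender, 1.0, 1.0 / skin_cfg["vep_female_divisor"]) for p in population]
    )
    edm_cfg = dict(skin_cfg)
    edm_cfg["edm_age_scaling_ratio"] = 1.0
    edm_base = np.mean([edm_thickness_um(p.bmi, p.gender, edm_cfg) for p in population])
    return {
        "vep_base_um": float(target_vep_um / (vep_shape * mult)),
        "edm_age_scaling_ratio": float(target_edm_um / (edm_base * mult)),
    }
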