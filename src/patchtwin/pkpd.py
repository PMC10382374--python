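"""Five-compartment PBPK balance equations and sigmoid-Emax effects.

Compartments: central (blood + lungs), rapidly equilibrating (brain,
heart, skin, kidneys), slowly equilibrating (muscle, fat, carcass),
gastrointestinal (gut, spleen, pancreas) and hepatic (liver, where
metabolism happens).  Transdermal input enters the central compartment as
bottom-boundary flux x area / V_central.  Rate constants are derived per
balance equation as flow / volume of the compartment the equation
describes; the shared flows live in :class:`~patchtwin.parameters.PKParameters`.

The unbound fraction f_u gates every flux leaving the central compartment
and the same (gated) flux is what the receiving compartment collects, so
with elimination switched off the total drug amount is conserved exactly.
A ``literal_fu_central_only`` flag reproduces the variant in which the
receiving compartments collect the full ungated flux; that variant
creates mass in every central-to-tissue transfer and is dynamically
unstable, and is provided for inspection only.  Renal clearance is
elimination by default; ``literal_eq4_sign`` flips it to the
(non-physical) source sign.

Each clinical endpoint lags plasma through its own first-order effect
compartment, dc_e/dt = k_e (c_p - c_e), and maps concentration to effect
through a decreasing sigmoid: E = E0 - Emax * c_e^g / (EC50^g + c_e^g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import PDParameters, PKParameters

PK_COMPARTMENTS = ("central", "rapid", "slow", "gut", "liver")


@dataclass
class PKState:
    """Concentrations [ng/ml] in the five PK compartments."""

    c_p: float = 0.0
    c_r: float = 0.0
    c_s: float = 0.0
    c_g: float = 0.0
    c_l: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.c_p, self.c_r, self.c_s, self.c_g, self.c_l])


@dataclass
class EffectState:
    """Effect-compartment concentrations [ng/ml] for pain and ventilation."""

    c_e_vas: float = 0.0
    c_e_rd: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.c_e_vas, self.c_e_rd])


@dataclass(frozen=True)
class ClinicalEffects:
    vas: float  # 0..E0 pain score
    ventilation: float  # L/min


def pk_rhs(
    state: np.ndarray,
    pk: PKParameters,
    flux_density: float,
    patch_area: float,
) -> np.ndarray:
    """Time derivatives [ng/ml/s] of the five compartment concentrations.

    ``flux_density`` [ng m-2 s-1] and ``patch_area`` [m2] give the
    transdermal input; for several active sites pass the summed mass rate
    through any (flux_density, area) pair with the right product.
    """
    state = np.asarray(state, dtype=float)
    c_p, c_r, c_s, c_g, c_l = state
    V = pk.V
    Q = pk.Q
    f_u = pk.f_u
    v_c_ml = V["central"] * 1000.0
    input_rate = flux_density * patch_area / v_c_ml  # ng/ml/s

    renal_sign = -1.0 if pk.literal_eq4_sign else 1.0
    out_flows = (
        Q["central_rapid"]
        + Q["central_slow"]
        + Q["central_gut"]
        + Q["central_liver"]
        + renal_sign * pk.CL_renal
    )
    # Forward fluxes leaving central, as collected by the receiving
    # compartments [L/s * ng/ml = ug/s... consistently flow*conc/volume].
    arrival_gate = 1.0 if pk.literal_fu_central_only else f_u
    dc_p = (
        input_rate
        - f_u * out_flows * c_p / V["central"]
        + (Q["central_rapid"] * c_r + Q["central_slow"] * c_s + Q["liver_central"] * c_l)
        / V["central"]
    )
    dc_r = (arrival_gate * Q["central_rapid"] * c_p - Q["central_rapid"] * c_r) / V["rapid"]
    dc_s = (arrival_gate * Q["central_slow"] * c_p - Q["central_slow"] * c_s) / V["slow"]
    dc_g = (arrival_gate * Q["central_gut"] * c_p - Q["gut_liver"] * c_g) / V["gut"]
    dc_l = (
        arrival_gate * Q["central_liver"] * c_p
        + Q["gut_liver"] * c_g
        - Q["liver_central"] * c_l
        - pk.CL_hepatic * c_l
    ) / V["liver"]
    return np.array([dc_p, dc_r, dc_s, dc_g, dc_l])


def total_amount(state: np.ndarray, pk: PKParameters) -> float:
    """Total drug amount [ng] across the five compartments."""
    state = np.asarray(state, dtype=float)
    volumes_ml = np.array([pk.V[c] for c in PK_COMPARTMENTS]) * 1000.0
    return float(np.dot(state, volumes_ml))


def effect_rhs(effect: np.ndarray, c_p: float, pd_params: PDParameters) -> np.ndarray:
    """First-order effect-compartment lag, one k_e per endpoint."""
    effect = np.asarray(effect, dtype=float)
    k = np.array([pd_params.vas.k_e, pd_params.ventilation.k_e])
    return k * (c_p - effect)


def hill(c: float | np.ndarray, ec50: float, gamma: float) -> float | np.ndarray:
    """Sigmoid occupancy c^g / (EC50^g + c^g); exactly 0 at c = 0."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ec50) ** gamma, 0.0)
    out = ratio / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


def clinical_effects(effect: np.ndarray, pd_params: PDParameters) -> ClinicalEffects:
    """Map effect-site concentrations to the two endpoints (both use the
    decreasing branch: opioid lowers pain and ventilation)."""
    c_vas, c_rd = np.asarray(effect, dtype=float)
    vas = pd_params.vas.E0 - pd_params.vas.Emax * hill(
        c_vas, pd_params.vas.ec50, pd_params.vas.gamma
    )
    vent = pd_params.ventilation.E0 - pd_params.ventilation.Emax * hill(
        c_rd, pd_params.ventilation.ec50, pd_params.ventilation.gamma
    )
    return ClinicalEffects(vas=float(vas), ventilation=float(vent))
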