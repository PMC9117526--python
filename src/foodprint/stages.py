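"""Post-farm-gate GHGE stage models, including home cooking energy.

Processing, storage, transportation and packaging additions are fixed
per-group parameters (kg CO2-eq per kg as produced).  The preparation-at-home
stage is modelled from cooking energy: a food is cooked for a stated time per
batch on either a natural-gas burner (m3/h) or an electric appliance (kW),
and the energy intensity is multiplied by the matching emission factor.

Emission factors (kg CO2-eq per m3 gas, per kWh electricity) are required
configuration; ``calibrate_emission_factors`` back-solves the factor implied
by each published per-group preparation value and its cooking spec.
"""

from __future__ import annotations

from dataclasses import dataclass

from .registry import StageParameters

__all__ = [
    "CookingSpec",
    "EmissionFactors",
    "energy_per_kg",
    "preparation_ghge",
    "stage_total",
    "default_cooking_specs",
    "calibrate_emission_factors",
]


@dataclass(frozen=True)
class CookingSpec:
    """Home-cooking specification for one food group.

    Exactly one energy carrier is set: ``gas_rate_m3_per_h`` for natural gas
    or ``appliance_power_kw`` for electricity.
    """

    group: str
    minutes_per_batch: float
    batch_kg: float
    energy_carrier: str  # natural_gas | electricity
    appliance_power_kw: float | None = None
    gas_rate_m3_per_h: float | None = None

    def __post_init__(self) -> None:
        if self.minutes_per_batch < 0:
            raise ValueError("minutes_per_batch must be >= 0")
        if self.batch_kg <= 0:
            raise ValueError("batch_kg must be > 0")
        if self.energy_carrier == "natural_gas":
            if self.gas_rate_m3_per_h is None or self.appliance_power_kw is not None:
                raise ValueError("natural_gas spec needs gas_rate_m3_per_h only")
        elif self.energy_carrier == "electricity":
            if self.appliance_power_kw is None or self.gas_rate_m3_per_h is not None:
                raise ValueError("electricity spec needs appliance_power_kw only")
        else:
            raise ValueError(f"unknown energy carrier {self.energy_carrier!r}")


@dataclass(frozen=True)
class EmissionFactors:
    """Fuel-cycle emission factors: kg CO2-eq per m3 natural gas / per kWh."""

    ef_gas: float
    ef_electricity: float

    def __post_init__(self) -> None:
        if self.ef_gas <= 0 or self.ef_electricity <= 0:
            raise ValueError("emission factors must be > 0")


#: Typical household burner draws 0.4 m3/h of natural gas; rice is cooked
#: electrically (0.9 kW cooker, 35 min per 0.5 kg batch).
GAS_RATE_M3_PER_H = 0.4


def default_cooking_specs() -> dict[str, CookingSpec]:
    """Cooking times per batch for the groups that are cooked at home.

    Vegetables and legumes: 2 min per 500 g; meat: 40 min per 500 g; aquatic
    products and poultry: 20 min per kg; eggs: 10 min per 200 g; cereals
    (rice): 35 min per 500 g on a 0.9 kW electric cooker.  Groups eaten
    without cooking carry no spec and contribute zero preparation energy.
    """
    gas = lambda group, minutes, kg: CookingSpec(
        group, minutes, kg, "natural_gas", gas_rate_m3_per_h=GAS_RATE_M3_PER_H
    )
    return {
        "Vegetables": gas("Vegetables", 2.0, 0.5),
        "Legumes": gas("Legumes", 2.0, 0.5),
        "Meat": gas("Meat", 40.0, 0.5),
        "Aquatic products": gas("Aquatic products", 20.0, 1.0),
        "Poultry": gas("Poultry", 20.0, 1.0),
        "Eggs": gas("Eggs", 10.0, 0.2),
        "Cereals": CookingSpec("Cereals", 35.0, 0.5, "electricity", appliance_power_kw=0.9),
    }


def energy_per_kg(spec: CookingSpec) -> float:
    """Cooking energy intensity: m3 gas per kg, or kWh per kg."""
    hours = spec.minutes_per_batch / 60.0
    rate = spec.gas_rate_m3_per_h if spec.energy_carrier == "natural_gas" else spec.appliance_power_kw
    return hours * rate / spec.batch_kg


def preparation_ghge(spec: CookingSpec, factors: EmissionFactors) -> float:
    """Preparation-at-home GHGE (kg CO2-eq per kg cooked)."""
    ef = factors.ef_gas if spec.energy_carrier == "natural_gas" else factors.ef_electricity
    return energy_per_kg(spec) * ef


def stage_total(params: StageParameters, totals: str = "computed") -> float:
    """Total post-farm-gate GHGE addition for one food type.

    ``totals="computed"`` (default) sums the present stage values;
    ``totals="printed"`` returns the source table's total column verbatim.
    The two differ for rows whose printed total is inconsistent with its
    stage sum — the validation report identifies those rows.
    """
    if totals == "printed":
        if params.printed_total is None:
            raise ValueError(f"{params.key}: no printed total available")
        return params.printed_total
    if totals != "computed":
        raise ValueError("totals must be 'computed' or 'printed'")
    ct = params.computed_total
    if ct is None:
        raise ValueError(f"{params.key}: no stage values present")
    return ct


def calibrate_emission_factors(
    specs: dict[str, CookingSpec],
    published_preparation: dict[str, float],
) -> dict[str, dict[str, object]]:
    """Back-solve the emission factor implied by each published preparation cell.

    For every group present in both mappings, divides the published
    preparation GHGE (kg CO2-eq/kg) by the spec's energy intensity, yielding
    the implied kg CO2-eq per m3 (gas) or per kWh (electricity).  Implied gas
    factors are not identical across groups in the source parameters, so the
    result is reported per group rather than collapsed to one number.
    """
    out: dict[str, dict[str, object]] = {}
    for group, spec in specs.items():
        if group not in published_preparation:
            continue
        intensity = energy_per_kg(spec)
        if intensity == 0:
            continue
        out[group] = {
            "carrier": spec.energy_carrier,
            "implied_factor": published_preparation[group] / intensity,
        }
    return out
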