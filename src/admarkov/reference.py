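"""Packaged UK reference inputs.

``uk_reference_parameters()`` loads the shipped parameter set: published
prevalence / incidence / severity / cost values in 2019 GBP, a synthetic
population projection standing in for the external national projection, and
**placeholder** inter-state transition probabilities (no published numbers
exist to cite; see the provenance log).

``REPORTED_AD_COUNTS`` carries the published projected AD dementia counts for
the no-DMT baseline and the four core DMT scenarios at five-year marks
2020-2040, for use as reporting-layer inputs (e.g. change-vs-baseline
arithmetic); they are outputs of the original analysis, not of this package.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .params import ModelParameters, parameters_from_config

__all__ = [
    "uk_reference_parameters",
    "uk_reference_config",
    "REPORTED_AD_COUNTS",
    "REPORTED_TREATED_2040",
    "REPORTED_DRUG_PRICES",
]


def uk_reference_config() -> dict:
    """The raw packaged reference config as a mapping."""
    ref = resources.files("admarkov").joinpath("data/uk_reference.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def uk_reference_parameters(seed: int | None = None) -> ModelParameters:
    """Load the packaged UK reference ModelParameters.

    ``seed`` overrides the synthetic-population seed (the stand-in for the
    external national projection); all published values are unaffected.
    """
    cfg = uk_reference_config()
    if seed is not None:
        cfg["population"]["synthetic"]["seed"] = int(seed)
    return parameters_from_config(cfg)


#: Published projected AD dementia counts (persons) at five-year marks,
#: no-DMT baseline and the four core majority-primary scenarios.
REPORTED_AD_COUNTS: dict[str, dict[int, int]] = {
    "no_dmt": {2020: 570_212, 2025: 634_067, 2030: 770_603, 2035: 909_007, 2040: 1_038_405},
    "high_uptake_high_efficacy": {
        2020: 570_212, 2025: 634_067, 2030: 746_417, 2035: 836_875, 2040: 940_819,
    },
    "high_uptake_medium_efficacy": {
        2020: 570_212, 2025: 634_067, 2030: 750_468, 2035: 849_168, 2040: 957_862,
    },
    "high_uptake_low_efficacy": {
        2020: 570_212, 2025: 634_067, 2030: 754_511, 2035: 861_351, 2040: 974_585,
    },
    "low_uptake_medium_efficacy": {
        2020: 570_212, 2025: 634_067, 2030: 761_873, 2035: 883_319, 2040: 1_004_319,
    },
}

#: Published treated count in 2040 under high uptake, and the secondary-analysis
#: annual DMT prices (GBP/person-year) explored against it.
REPORTED_TREATED_2040: int = 2_018_749
REPORTED_DRUG_PRICES: tuple[float, float, float] = (1_200.0, 11_100.0, 21_000.0)
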