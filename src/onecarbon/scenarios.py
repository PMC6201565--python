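"""Parameterization builders: sex scaling, polymorphisms, nutrient
scaling, regulation ablations and virtual cohorts.

All operations are purely functional: they return new
:class:`~onecarbon.model.KineticParameters` (or
:class:`~onecarbon.model.RegulationSwitches`) objects and never mutate
their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import KineticParameters, RegulationSwitches, male_parameters

__all__ = [
    "FEMALE_FACTORS",
    "MTHFR_VARIANTS",
    "ScenarioSpec",
    "apply_sex_scaling",
    "apply_single_adaptation",
    "apply_polymorphism",
    "set_total_folate",
    "set_met_input",
    "toggle_regulation",
    "sample_expression_cohort",
    "build_scenario",
]

#: Female/male multiplicative adaptation factors.  The first five scale
#: the Vmax of differentially expressed enzymes; the sixth scales the
#: clamped sphingomyelin concentration.
FEMALE_FACTORS: dict[str, float] = {
    "PEMT": 2.3,
    "BHMT": 0.6,
    "SHMT": 2.2,
    "MS": 1.35,
    "MTHFR": 0.8,
    "SphMy": 1.3,
}

#: Parameter fields touched by each adaptation.
_ADAPTATION_FIELDS: dict[str, tuple[str, ...]] = {
    "PEMT": ("pemt_vmax",),
    "BHMT": ("bhmt_vmax",),
    # an SHMT expression change scales the enzyme, hence both directions
    "SHMT": ("shmt_vmax_f", "shmt_vmax_r"),
    "MS": ("ms_vmax",),
    "MTHFR": ("mthfr_vmax",),
    "SphMy": ("sphmy",),
}

#: MTHFR polymorphisms as Vmax multipliers.  The second variant is
#: named A1289C here, as printed in the source tables (the canonical
#: rs identifier is A1298C); the 0.68 factor is kept as printed.
MTHFR_VARIANTS: dict[str, float] = {
    "C677T": 0.3,
    "A1289C": 0.68,
}

#: Vmax fields perturbed when emulating inter-individual variation in
#: enzyme expression.
_EXPRESSION_VMAX_FIELDS = (
    "pemt_vmax", "sms_vmax", "phld_vmax", "chox_vmax", "bah_vmax",
    "bhmt_vmax", "cbs_vmax",
    "mat1_vmax", "mat3_vmax", "gnmt_vmax", "dnmt_vmax", "gamt_vmax",
    "as3mt_vmax", "sahh_vmax_f", "sahh_vmax_r", "ms_vmax",
    "mthfr_vmax", "shmt_vmax_f", "shmt_vmax_r", "ts_vmax", "dhfr_vmax",
    "aicart_vmax", "pgt_vmax", "mtd_vmax_f", "mtd_vmax_r",
    "mtch_vmax_f", "mtch_vmax_r", "fts_vmax", "ftd_vmax",
)


def apply_sex_scaling(p_male: KineticParameters, lam: float) -> KineticParameters:
    """Interpolate the six female adaptations.

    Each factor f is applied as 1 + lam*(f-1): lam=0 returns the male
    parameter set, lam=1 the full female set, intermediate lam a linear
    blend of the multiplicative factors.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"sex fraction must lie in [0, 1], got {lam}")
    changes: dict[str, float] = {}
    for name, factor in FEMALE_FACTORS.items():
        eff = 1.0 + lam * (factor - 1.0)
        for fld in _ADAPTATION_FIELDS[name]:
            changes[fld] = getattr(p_male, fld) * eff
    return replace(p_male, **changes)


def apply_single_adaptation(p_male: KineticParameters, which: str) -> KineticParameters:
    """Apply exactly one female adaptation, keeping the rest male."""
    if which not in FEMALE_FACTORS:
        raise KeyError(
            f"unknown adaptation {which!r}; expected one of {sorted(FEMALE_FACTORS)}"
        )
    factor = FEMALE_FACTORS[which]
    changes = {fld: getattr(p_male, fld) * factor
               for fld in _ADAPTATION_FIELDS[which]}
    return replace(p_male, **changes)


def apply_polymorphism(p: KineticParameters, variant: str) -> KineticParameters:
    """Scale the MTHFR Vmax by the variant's activity multiplier."""
    if variant not in MTHFR_VARIANTS:
        raise KeyError(
            f"unknown MTHFR variant {variant!r}; expected one of {sorted(MTHFR_VARIANTS)}"
        )
    return replace(p, mthfr_vmax=p.mthfr_vmax * MTHFR_VARIANTS[variant])


def set_total_folate(p: KineticParameters, scale: float) -> KineticParameters:
    """Multiply the conserved total-folate parameter (1 = normal)."""
    if scale <= 0:
        raise ValueError(f"folate scale must be > 0, got {scale}")
    return replace(p, folate_total=p.folate_total * scale)


def set_met_input(p: KineticParameters, scale: float) -> KineticParameters:
    """Multiply the methionine input flux (1 = normal)."""
    if scale <= 0:
        raise ValueError(f"methionine input scale must be > 0, got {scale}")
    return replace(p, met_input=p.met_input * scale)


def toggle_regulation(sw: RegulationSwitches, flag: str, on: bool) -> RegulationSwitches:
    """Return switches with exactly one flag changed."""
    return sw.with_flag(flag, on)


def sample_expression_cohort(
    p: KineticParameters, n: int, cv: float, seed: int
) -> list[KineticParameters]:
    """Virtual cohort: every Vmax independently perturbed by a uniform
    multiplicative factor in [1-cv, 1+cv].

    Enzyme expression (hence Vmax) varies by up to 25% between
    individuals, so ``cv`` must lie in [0, 0.25].
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if not 0.0 <= cv <= 0.25:
        raise ValueError(f"cv must lie in [0, 0.25], got {cv}")
    rng = np.random.default_rng(seed)
    cohort = []
    for _ in range(n):
        factors = rng.uniform(1.0 - cv, 1.0 + cv, size=len(_EXPRESSION_VMAX_FIELDS))
        changes = {fld: getattr(p, fld) * float(f)
                   for fld, f in zip(_EXPRESSION_VMAX_FIELDS, factors)}
        cohort.append(replace(p, **changes))
    return cohort


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative description of one perturbation experiment.

    ``sex_fraction`` interpolates the six female adaptations (0 = male,
    1 = female); ``single_adaptation`` applies exactly one of them
    instead (the two modes are mutually exclusive).  ``folate_scale``
    and ``met_input_scale`` multiply the respective boundary parameters,
    ``mthfr_variant`` applies a polymorphism, ``switch_overrides`` turns
    individual long-range regulations on or off, and ``cohort_seed``
    (with ``cohort_n``/``cohort_cv``) requests a virtual cohort.
    """

    sex_fraction: float = 0.0
    single_adaptation: str | None = None
    mthfr_variant: str | None = None
    folate_scale: float = 1.0
    met_input_scale: float = 1.0
    switch_overrides: dict = field(default_factory=dict)
    cohort_seed: int | None = None
    cohort_n: int = 1
    cohort_cv: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sex_fraction <= 1.0:
            raise ValueError("sex_fraction must lie in [0, 1]")
        if self.single_adaptation is not None and self.sex_fraction != 0.0:
            raise ValueError(
                "single_adaptation and sex_fraction are mutually exclusive"
            )
        if self.single_adaptation is not None \
                and self.single_adaptation not in FEMALE_FACTORS:
            raise KeyError(f"unknown adaptation {self.single_adaptation!r}")
        if self.mthfr_variant is not None and self.mthfr_variant not in MTHFR_VARIANTS:
            raise KeyError(f"unknown MTHFR variant {self.mthfr_variant!r}")
        if self.folate_scale <= 0 or self.met_input_scale <= 0:
            raise ValueError("folate_scale and met_input_scale must be > 0")
        known = {f.name for f in
                 RegulationSwitches.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        for k in self.switch_overrides:
            if k not in known:
                raise KeyError(f"unknown regulation flag {k!r}")

    def to_dict(self) -> dict:
        return {
            "sex_fraction": self.sex_fraction,
            "single_adaptation": self.single_adaptation,
            "mthfr_variant": self.mthfr_variant,
            "folate_scale": self.folate_scale,
            "met_input_scale": self.met_input_scale,
            "switch_overrides": dict(self.switch_overrides),
            "cohort_seed": self.cohort_seed,
            "cohort_n": self.cohort_n,
            "cohort_cv": self.cohort_cv,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        allowed = {f for f in cls.__dataclass_fields__}  # type: ignore[attr-defined]
        unknown = set(d) - allowed
        if unknown:
            raise KeyError(f"unknown ScenarioSpec keys: {sorted(unknown)}")
        return cls(**d)


def build_scenario(
    spec: ScenarioSpec, p_base: KineticParameters | None = None
) -> tuple[KineticParameters, RegulationSwitches]:
    """Materialize a scenario into a parameter set and switch set."""
    p = p_base if p_base is not None else male_parameters()
    if spec.single_adaptation is not None:
        p = apply_single_adaptation(p, spec.single_adaptation)
    elif spec.sex_fraction > 0.0:
        p = apply_sex_scaling(p, spec.sex_fraction)
    if spec.mthfr_variant is not None:
        p = apply_polymorphism(p, spec.mthfr_variant)
    if spec.folate_scale != 1.0:
        p = set_total_folate(p, spec.folate_scale)
    if spec.met_input_scale != 1.0:
        p = set_met_input(p, spec.met_input_scale)
    sw = RegulationSwitches()
    for flag, on in spec.switch_overrides.items():
        sw = toggle_regulation(sw, flag, on)
    return p, sw
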