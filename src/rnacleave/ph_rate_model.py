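"""Four-term pH-rate law for phosphodiester cleavage with a catalytic term.

The observed first-order rate constant for transesterification cleavage of
the dinucleoside monophosphate pool (the 3',5' dimer and its 2',5' isomer)
is modeled as

    k_cl = kH*[H+] + kH2O + kcat*[cat] * f([H+]) + kOH*KW/[H+]

where ``f`` is the diprotic speciation fraction

    f([H+]) = Ka1*Ka2 / ([H+]^2 + Ka1*[H+] + Ka1*Ka2)

with the two kinetic acid-dissociation constants constrained equal
(Ka1 = Ka2 = Ka): the apparent second-order dependence of the catalyzed
reaction on [OH-] between pH 5 and 6 means they cannot be resolved
independently, only their shared value is identifiable.  [H+] is taken as
10^(-pH) on the concentration scale; KW is the ionic product of water at
the experimental conditions (90 deg C, I = 0.1 M) and is configurable, not
fitted.  Temperature, ionic strength and buffer concentration are carried
as metadata only — buffer catalysis is assumed absent.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Union

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "RateParams",
    "Conditions",
    "TABLE1_BACKGROUND",
    "TABLE1_CATALYST",
    "hydronium_conc",
    "speciation_fraction",
    "eq1_rate",
    "rate_terms",
    "acceleration_ratio",
    "loglog_slope",
]

#: Default ionic product of water at the experimental conditions (M^2).
KW_DEFAULT = 6.2e-13


class RateParams(BaseModel):
    """Parameter vector of the pH-rate law (SI units).

    Attributes
    ----------
    kH : float
        Second-order rate constant for hydronium-ion-catalyzed cleavage
        (M^-1 s^-1).
    kH2O : float
        First-order rate constant for the pH-independent cleavage (s^-1).
    kOH : float
        Second-order rate constant for hydroxide-ion-catalyzed cleavage
        (M^-1 s^-1).
    kcat : float
        Second-order rate constant for the organomercury-catalyzed
        cleavage (M^-1 s^-1).
    Ka : float
        Shared kinetic acid-dissociation constant, Ka1 = Ka2 (M).  A purely
        kinetic constant inferred from the shape of the rate law; no
        microscopic protolytic site is assigned to it.
    KW : float
        Ionic product of water at the experimental conditions (M^2).
    """

    model_config = {"frozen": True}

    kH: float = Field(0.0, ge=0.0)
    kH2O: float = Field(0.0, ge=0.0)
    kOH: float = Field(0.0, ge=0.0)
    kcat: float = Field(0.0, ge=0.0)
    Ka: float = Field(0.0, ge=0.0)
    KW: float = Field(KW_DEFAULT, gt=0.0)

    @model_validator(mode="after")
    def _ka_required_with_kcat(self) -> "RateParams":
        if self.kcat > 0.0 and self.Ka <= 0.0:
            raise ValueError("Ka must be positive when kcat > 0")
        return self

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        """Serialize to a JSON string (and optionally write to *path*)."""
        text = json.dumps(self.model_dump(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "RateParams":
        """Load from a JSON string or file path."""
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        text = p.read_text() if p is not None else str(source)
        return cls(**json.loads(text))


class Conditions(BaseModel):
    """Reaction conditions: pH and catalyst concentration, plus metadata."""

    model_config = {"frozen": True}

    pH: float = Field(..., ge=0.0, le=14.0)
    cat_conc: float = Field(0.0, ge=0.0, description="catalyst conc (M)")
    temperature_C: float = 90.0
    ionic_strength_M: float = 0.1
    buffer_mM: float = 30.0


#: Table of fitted constants, no-catalyst column: hydronium-, water- and
#: hydroxide-catalyzed background cleavage at 90 deg C, I = 0.1 M.
TABLE1_BACKGROUND = RateParams(kH=2.4e-3, kH2O=1.3e-7, kOH=0.10)

#: Same, 1 mM organomercury-catalyst column, including the catalytic
#: second-order constant and the shared kinetic acid-dissociation constant.
TABLE1_CATALYST = RateParams(
    kH=3e-3, kH2O=1e-7, kOH=0.07, kcat=1.6e-3, Ka=3e-6
)


def hydronium_conc(pH: float) -> float:
    """Hydronium-ion concentration (M) from pH, on the concentration scale.

    Raises
    ------
    ValueError
        If pH is outside [0, 14].
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH out of range [0, 14]: {pH}")
    return 10.0 ** (-pH)


def speciation_fraction(params: RateParams, hconc: float) -> float:
    """Fraction of the catalyst-substrate ensemble in the reactive form.

    With Ka1 = Ka2 = Ka the diprotic fraction is
    Ka^2 / ([H+]^2 + Ka*[H+] + Ka^2): bounded in (0, 1), monotonically
    decreasing in [H+], equal to 1/3 at [H+] = Ka, tending to 1 in base
    and to 0 in acid.

    Raises
    ------
    ValueError
        If ``hconc`` is not positive or ``params.Ka`` is zero.
    """
    if hconc <= 0.0:
        raise ValueError(f"hydronium concentration must be positive: {hconc}")
    if params.Ka <= 0.0:
        raise ValueError("speciation fraction undefined for Ka = 0")
    # divide through by Ka^2 for numerical range safety
    r = hconc / params.Ka
    return 1.0 / (r * r + r + 1.0)


def rate_terms(params: RateParams, cond: Conditions) -> dict[str, float]:
    """The four additive contributions to the observed cleavage rate (s^-1).

    Keys: ``hydronium``, ``water``, ``catalytic``, ``hydroxide``.
    """
    h = hydronium_conc(cond.pH)
    catalytic = 0.0
    if params.kcat > 0.0 and cond.cat_conc > 0.0:
        catalytic = params.kcat * cond.cat_conc * speciation_fraction(params, h)
    return {
        "hydronium": params.kH * h,
        "water": params.kH2O,
        "catalytic": catalytic,
        "hydroxide": params.kOH * params.KW / h,
    }


def eq1_rate(params: RateParams, cond: Conditions) -> float:
    """Observed cleavage rate constant k_cl (s^-1) under *cond*.

    Sum of the hydronium, water, catalytic and hydroxide terms.  Reduces
    exactly to the three-term background law when ``cond.cat_conc == 0``
    (the result is then independent of ``kcat`` and ``Ka``).
    """
    return math.fsum(rate_terms(params, cond).values())


def acceleration_ratio(
    params_bg: RateParams, params_cat: RateParams, cond: Conditions
) -> float:
    """Fold-acceleration of the catalyzed over the background reaction.

    Evaluates the full law with *params_cat* at ``cond`` and divides by the
    background-only law with *params_bg* at the same pH with no catalyst.

    Raises
    ------
    ValueError
        If the background rate is zero (degenerate input).
    """
    bg_cond = cond.model_copy(update={"cat_conc": 0.0})
    k_bg = eq1_rate(params_bg, bg_cond)
    if k_bg <= 0.0:
        raise ValueError("background rate is zero; acceleration undefined")
    return eq1_rate(params_cat, cond) / k_bg


def loglog_slope(params: RateParams, cond: Conditions, dpH: float = 0.001) -> float:
    """Local slope of log10(k_cl) versus pH by central difference.

    For the isolated hydroxide term the slope is +1, for the isolated
    hydronium term -1, and for the isolated catalytic term in the
    [H+] >> Ka regime it approaches +2 (the apparent second-order
    dependence on [OH-]).  For any nonnegative parameter set the slope of
    the full law lies in [-1, +2].
    """
    if dpH <= 0.0:
        raise ValueError(f"dpH must be positive: {dpH}")
    lo = cond.model_copy(update={"pH": cond.pH - dpH})
    hi = cond.model_copy(update={"pH": cond.pH + dpH})
    return (
        math.log10(eq1_rate(params, hi)) - math.log10(eq1_rate(params, lo))
    ) / (2.0 * dpH)
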