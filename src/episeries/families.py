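"""The nested family of epistasis mean structures.

For fruit-level y = ln(locule count) in background b with focal-mutation
indicator m, every family specifies

    mu(b, 0) = beta_b          mu(b, 1) = beta_b + E(b)

and differs only in how the focal effect E varies across backgrounds:

========================  =====================================================
ADDITIVE (no epistasis)   E(b) = delta, one shift everywhere
CONSTANT                  E(WT) = delta_wt; E(b != WT) = delta_mut
PROPORTIONAL              E(b) = delta0 * (1 + eps * (beta_b - beta_WT))
                          (the multilinear model: effect scales linearly with
                          background strength)
SIGMOID                   E(b) = A / (1 + exp(-(beta_b - x0) / r)), r > 0
                          (dose-dependent: negligible below a threshold x0,
                          saturating at A above it)
IDIOSYNCRATIC             E(b) = delta_b, free per background (saturated)
========================  =====================================================

Observations are modelled as y ~ Normal(mu(b, m), sigma^2) with a single
residual sigma shared across genotypes and profiled out of the likelihood.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Mapping

from .exceptions import NotNestedError


class ModelFamily(str, enum.Enum):
    ADDITIVE = "additive"
    CONSTANT = "constant"
    PROPORTIONAL = "proportional"
    SIGMOID = "sigmoid"
    IDIOSYNCRATIC = "idiosyncratic"

    @classmethod
    def coerce(cls, value: "ModelFamily | str") -> "ModelFamily":
        return value if isinstance(value, cls) else cls(str(value).lower())


F = ModelFamily

#: strictly nested (small, big) pairs: the small family's mean structures are
#: an exact subset of the big family's.
STRICT_NESTING: frozenset[tuple[F, F]] = frozenset(
    {
        (F.ADDITIVE, F.CONSTANT),
        (F.ADDITIVE, F.PROPORTIONAL),
        (F.ADDITIVE, F.IDIOSYNCRATIC),
        (F.CONSTANT, F.IDIOSYNCRATIC),
        (F.PROPORTIONAL, F.IDIOSYNCRATIC),
        (F.SIGMOID, F.IDIOSYNCRATIC),
    }
)

#: approximately nested pairs: the small family is only a boundary/limit case
#: of the big one (e.g. a constant effect is the r -> infinity limit of the
#: sigmoid), so the chi-square reference for the LRT is approximate.
APPROX_NESTING: frozenset[tuple[F, F]] = frozenset(
    {
        (F.ADDITIVE, F.SIGMOID),
        (F.CONSTANT, F.SIGMOID),
        (F.PROPORTIONAL, F.SIGMOID),
    }
)

#: focal-parameter names per family (idiosyncratic keys are background labels)
FOCAL_PARAM_NAMES: dict[F, tuple[str, ...]] = {
    F.ADDITIVE: ("delta",),
    F.CONSTANT: ("delta_wt", "delta_mut"),
    F.PROPORTIONAL: ("delta0", "eps"),
    F.SIGMOID: ("A", "x0", "r"),
}


def nesting_of(small: F, big: F) -> str:
    """``"strict"`` or ``"approximate"``; raises for non-nested pairs."""
    small, big = F.coerce(small), F.coerce(big)
    if small is big:
        return "strict"  # reflexive: a family trivially nests in itself
    if (small, big) in STRICT_NESTING:
        return "strict"
    if (small, big) in APPROX_NESTING:
        return "approximate"
    raise NotNestedError(f"{small.value} is not nested within {big.value}")


@dataclass
class ModelParams:
    """Parameters of one family's mean structure.

    ``beta`` maps background label -> mean log phenotype without the focal
    mutation; ``focal`` holds the family-specific effect parameters (for
    IDIOSYNCRATIC the keys are background labels, value delta_b).  ``sigma``
    is the shared residual SD on the log scale (profiled at fit time).
    """

    family: ModelFamily
    beta: dict[str, float]
    focal: dict[str, float] = field(default_factory=dict)
    reference: str = "WT"
    sigma: float | None = None

    def __post_init__(self) -> None:
        self.family = ModelFamily.coerce(self.family)
        if self.reference not in self.beta:
            raise ValueError(f"reference background {self.reference!r} missing from beta")
        if self.family is F.SIGMOID and self.focal.get("r", 1.0) <= 0:
            raise ValueError("sigmoid rate parameter r must be > 0")

    def effect(self, background: str) -> float:
        return effect_function(self.family, self, background)

    def mu(self, background: str, m: int) -> float:
        return self.beta[background] + (self.effect(background) if m else 0.0)

    def to_dict(self) -> dict:
        return {
            "family": self.family.value,
            "beta": dict(self.beta),
            "focal": dict(self.focal),
            "reference": self.reference,
            "sigma": self.sigma,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParams":
        return cls(
            family=ModelFamily.coerce(d["family"]),
            beta=dict(d["beta"]),
            focal=dict(d["focal"]),
            reference=d.get("reference", "WT"),
            sigma=d.get("sigma"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def effect_function(family: ModelFamily | str, params: ModelParams, background: str) -> float:
    """Focal-mutation effect E(b) on mean log phenotype in ``background``."""
    family = ModelFamily.coerce(family)
    if background not in params.beta:
        raise KeyError(f"unknown background {background!r}")
    f = params.focal
    if family is F.ADDITIVE:
        return f["delta"]
    if family is F.CONSTANT:
        return f["delta_wt"] if background == params.reference else f["delta_mut"]
    if family is F.PROPORTIONAL:
        return f["delta0"] * (1.0 + f["eps"] * (params.beta[background] - params.beta[params.reference]))
    if family is F.SIGMOID:
        z = (params.beta[background] - f["x0"]) / f["r"]
        # numerically safe logistic
        if z >= 0:
            return f["A"] / (1.0 + math.exp(-z))
        ez = math.exp(z)
        return f["A"] * ez / (1.0 + ez)
    if family is F.IDIOSYNCRATIC:
        return f[background]
    raise AssertionError(family)


def n_mean_params(family: ModelFamily | str, design_or_k) -> int:
    """Number of mean-structure parameters for ``family``.

    ``design_or_k``: an :class:`~episeries.design.ExperimentDesign` or the
    total number of backgrounds K + 1 (reference included).  The count is the
    K + 1 background means plus the family's focal parameters (K + 1 again for
    the saturated idiosyncratic family).
    """
    family = ModelFamily.coerce(family)
    nb = design_or_k if isinstance(design_or_k, int) else design_or_k.n_backgrounds
    if nb < 1:
        raise ValueError("need at least the reference background")
    extra = {
        F.ADDITIVE: 1,
        F.CONSTANT: 2,
        F.PROPORTIONAL: 2,
        F.SIGMOID: 3,
        F.IDIOSYNCRATIC: nb,
    }[family]
    if family is F.CONSTANT and nb == 1:
        extra = 1  # only the reference cell exists: delta_mut is vacuous
    return nb + extra
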