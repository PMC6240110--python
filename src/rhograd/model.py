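"""Steady-state GEF/GAP reaction model of Rho GTPase activity gradients.

The model is purely local: active GTPase levels equilibrate fast, the total
pool is not limiting, and neither diffusion nor flow transport the active
form.  At steady state the active fraction at each position is the ratio of
the summed activation (GEF) rates to the summed deactivation (GAP) rates,

    R*(x) / R_tot = Σ_i α_i [GEF]_i(x) / Σ_i β_i [GAP]_i(x).

Two concrete gradients follow:

* Cdc42 — an exponentially distributed GEF (decay length λ ≈ 10 µm) over a
  uniform GAP gives a monotone exponential gradient,
  ``Cdc42*(x) ∝ α_C e^(−x/λ) / β_C``.
* Rac1 — the same exponential GEF, but deactivated by a uniform GAP plus a
  tip-localized GAP (β2-chimaerin, decay length γ = 5 µm),
  ``Rac1*(x) ∝ α_R e^(−x/λ) / (β_R + β_b e^(−x/γ))``.
  The localized GAP "chops off" the gradient at the edge, producing an
  interior maximum (the bump) at ``x_bump = γ ln((λ−γ)/(r γ))`` with
  ``r = β_R / β_b``; a bump exists iff ``r < (λ−γ)/γ``.

A refinement makes the localized GAP activity a linear function of the
Cdc42 and Rac1 levels themselves (positive crosstalk from Cdc42, Rac1
self-inhibition), which is solved per position in closed form; in-silico
knockdowns of Cdc42 or of the localized GAP reproduce the siRNA phenotypes.

Rates are in arbitrary units throughout — only ratios matter.  Profiles are
not normalized here; normalization is a quantification-stage concern.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import DegenerateModelError, InvalidParameterError
from .grid import SpatialGrid

__all__ = [
    "RegulatorProfile",
    "GTPaseParams",
    "TransportParams",
    "ActivityProfile",
    "steady_state_ratio",
    "cdc42_profile",
    "rac1_profile",
    "bump_position",
    "bump_exists",
    "crosstalk_rac1_profile",
    "diffusion_length",
]


@dataclass(frozen=True)
class RegulatorProfile:
    """Spatial concentration × rate profile of a GEF or GAP.

    ``form`` selects uniform (constant ``amplitude``), exponential
    (``amplitude · e^(−x/decay_length)``) or tabulated (explicit ``values``
    on a grid) shapes.
    """

    role: Literal["gef", "gap"]
    form: Literal["uniform", "exponential", "tabulated"] = "uniform"
    amplitude: float = 1.0
    decay_length: float | None = None
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.role not in ("gef", "gap"):
            raise InvalidParameterError(f"unknown regulator role {self.role!r}")
        if self.amplitude < 0:
            raise InvalidParameterError("regulator amplitude must be >= 0")
        if self.form == "exponential":
            if self.decay_length is None or self.decay_length <= 0:
                raise InvalidParameterError("exponential form needs decay_length > 0")
        if self.form == "tabulated":
            if self.values is None:
                raise InvalidParameterError("tabulated form needs values")
            v = np.asarray(self.values, dtype=float)
            if np.any(v < 0):
                raise InvalidParameterError("tabulated rates must be >= 0")
            object.__setattr__(self, "values", v)

    def evaluate(self, grid: SpatialGrid) -> np.ndarray:
        x = grid.positions
        if self.form == "uniform":
            return np.full_like(x, self.amplitude)
        if self.form == "exponential":
            return self.amplitude * np.exp(-x / self.decay_length)
        v = np.asarray(self.values, dtype=float)
        if v.size != x.size:
            raise InvalidParameterError(
                f"tabulated profile has {v.size} samples, grid has {x.size}"
            )
        return v.copy()


@dataclass(frozen=True)
class GTPaseParams:
    """Effective rates and length scales of the minimal gradient model.

    Defaults follow the worked parameter set used throughout: activation
    rates 1, uniform deactivation 0.5, localized GAP strength 1, GEF decay
    λ = 10 µm, localized-GAP decay γ = 5 µm.  ``beta_cb``/``beta_rb`` are the
    crosstalk coefficients coupling the localized GAP to the Cdc42 and Rac1
    levels; ``alpha_opto``/``lambda_opto`` parametrize an optogenetic GEF
    term ``α_opto e^(−x/λ_o)``.
    """

    alpha_c: float = 1.0
    beta_c: float = 0.5
    alpha_r: float = 1.0
    beta_r: float = 0.5
    beta_b: float = 1.0
    lam: float = 10.0
    gamma: float = 5.0
    beta_cb: float = 0.4
    beta_rb: float = 0.3
    alpha_opto: float = 0.0
    lambda_opto: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "alpha_c", "beta_c", "alpha_r", "beta_r", "beta_b",
            "beta_cb", "beta_rb", "alpha_opto",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.lam <= 0 or self.gamma <= 0 or self.lambda_opto <= 0:
            raise InvalidParameterError("length scales must be > 0")

    def to_json(self, path) -> None:
        import json
        from dataclasses import asdict
        from pathlib import Path

        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "GTPaseParams":
        import json
        from pathlib import Path

        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class TransportParams:
    """Active-state lifetime τ (s), lateral diffusion D (µm²/s) and the
    derived length scale ℓ_diff = √(τD) of the rejected transport model."""

    tau: float
    D: float
    ell_diff: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "ell_diff", diffusion_length(self.tau, self.D))


@dataclass
class ActivityProfile:
    """Active GTPase level (arbitrary units) on a spatial grid."""

    species: str
    grid: SpatialGrid
    values: np.ndarray
    condition: str = "wild-type"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.grid.positions.shape:
            raise InvalidParameterError("values do not match the grid")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise InvalidParameterError("activity must be finite and >= 0")
        self.values = v

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x_um": self.grid.positions,
                "value": self.values,
                "species": self.species,
                "condition": self.condition,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def steady_state_ratio(
    gefs: Sequence[RegulatorProfile],
    gaps: Sequence[RegulatorProfile],
    grid: SpatialGrid | None = None,
    species: str = "reporter",
    condition: str = "wild-type",
) -> ActivityProfile:
    """Active fraction as the ratio of summed GEF to summed GAP rates.

    Raises :class:`DegenerateModelError` if the total GAP rate vanishes
    anywhere; an empty GEF list yields an all-zero profile with a warning.
    """
    grid = grid or SpatialGrid()
    if not gaps:
        raise DegenerateModelError("at least one GAP profile is required")
    gap_total = np.zeros(grid.n)
    for g in gaps:
        if g.role != "gap":
            raise InvalidParameterError("GAP list contains a non-GAP profile")
        gap_total += g.evaluate(grid)
    if np.any(gap_total <= 0):
        raise DegenerateModelError("total GAP rate is zero at some position")
    gef_total = np.zeros(grid.n)
    if not gefs:
        warnings.warn("empty GEF list: activity is identically zero", stacklevel=2)
    for g in gefs:
        if g.role != "gef":
            raise InvalidParameterError("GEF list contains a non-GEF profile")
        gef_total += g.evaluate(grid)
    return ActivityProfile(species, grid, gef_total / gap_total, condition)


def cdc42_profile(
    params: GTPaseParams | None = None,
    grid: SpatialGrid | None = None,
    condition: str = "wild-type",
) -> ActivityProfile:
    """Monotone Cdc42 gradient: exponential GEF over a uniform GAP."""
    p = params or GTPaseParams()
    grid = grid or SpatialGrid()
    if p.beta_c <= 0:
        raise DegenerateModelError("beta_c must be > 0")
    values = p.alpha_c * np.exp(-grid.positions / p.lam) / p.beta_c
    return ActivityProfile("Cdc42", grid, values, condition)


def rac1_profile(
    params: GTPaseParams | None = None,
    grid: SpatialGrid | None = None,
    condition: str = "wild-type",
) -> ActivityProfile:
    """Rac1 gradient: exponential GEF over uniform plus tip-localized GAP."""
    p = params or GTPaseParams()
    grid = grid or SpatialGrid()
    if p.beta_r <= 0 and p.beta_b <= 0:
        raise DegenerateModelError("beta_r and beta_b cannot both be zero")
    x = grid.positions
    values = p.alpha_r * np.exp(-x / p.lam) / (p.beta_r + p.beta_b * np.exp(-x / p.gamma))
    return ActivityProfile("Rac1", grid, values, condition)


def bump_position(lam: float, gamma: float, r: float) -> float | None:
    """Closed-form position of the Rac1 interior maximum, or ``None``.

    ``x_bump = γ ln((λ−γ)/(r γ))`` for GEF decay λ, localized-GAP decay γ
    and GAP strength ratio ``r = β_R/β_b``.  Returns ``None`` when the
    expression is negative (the profile peaks at the edge); 0.0 marks the
    boundary case of a maximum exactly at the edge.
    """
    if gamma <= 0 or lam <= gamma:
        raise InvalidParameterError("need lam > gamma > 0 for a finite bump position")
    if r <= 0:
        raise InvalidParameterError("r must be > 0")
    x = gamma * math.log((lam - gamma) / (r * gamma))
    return x if x >= 0 else None


def bump_exists(lam: float, gamma: float, r: float) -> bool:
    """Whether the Rac1 profile has a strictly interior maximum:
    true iff ``r < (λ−γ)/γ``."""
    if gamma <= 0 or lam <= gamma:
        raise InvalidParameterError("need lam > gamma > 0")
    if r <= 0:
        raise InvalidParameterError("r must be > 0")
    return r < (lam - gamma) / gamma


def crosstalk_gamma_a(params: GTPaseParams) -> float:
    """Decay length of the tip-localization factor in the crosstalk model.

    Chosen as (1/γ − 1/λ)⁻¹ so that the Cdc42-driven component of the
    localized GAP, ∝ e^(−x/λ) · e^(−x/γ_a), decays with the measured
    β2-chimaerin length γ.
    """
    if params.lam <= params.gamma:
        raise InvalidParameterError("need lam > gamma for the localization factor")
    return 1.0 / (1.0 / params.gamma - 1.0 / params.lam)


def crosstalk_rac1_profile(
    params: GTPaseParams | None = None,
    grid: SpatialGrid | None = None,
    knockdowns: Iterable[str] = (),
    knockdown_efficiency: float = 1.0,
) -> tuple[ActivityProfile, ActivityProfile, RegulatorProfile]:
    """Rac1 profile when the localized GAP depends on Cdc42 and Rac1 levels.

    The localized GAP rate is ``β_b(x) = (β_Cb·Cdc42(x) + β_Rb·Rac1(x)) ·
    e^(−x/γ_a)`` with the tip-localization length ``γ_a`` from
    :func:`crosstalk_gamma_a`; the exponential factor stands for the
    actin/tip machinery required for β2-chimaerin recruitment.  Because
    Rac1 inhibits itself, the steady state solves a per-position quadratic

        β_Rb·g(x)·R² + (β_R + β_Cb·C(x)·g(x))·R − α_R e^(−x/λ) = 0,

    whose unique non-negative root is taken in closed form.

    ``knockdowns`` may contain ``"cdc42"`` (scales α_C by
    ``1 − knockdown_efficiency``) and/or ``"chimaerin"`` (scales β_Cb and
    β_Rb likewise); efficiency 1 is a complete knockdown.

    Returns the Rac1 profile, the Cdc42 profile it was computed with, and
    the resulting localized-GAP rate as a tabulated :class:`RegulatorProfile`.
    """
    p = params or GTPaseParams()
    grid = grid or SpatialGrid()
    kd = set(knockdowns)
    unknown = kd - {"cdc42", "chimaerin"}
    if unknown:
        raise InvalidParameterError(f"unknown knockdowns: {sorted(unknown)}")
    if not 0.0 <= knockdown_efficiency <= 1.0:
        raise InvalidParameterError("knockdown_efficiency must be in [0, 1]")
    keep = 1.0 - knockdown_efficiency
    if "cdc42" in kd:
        p = replace(p, alpha_c=p.alpha_c * keep)
    if "chimaerin" in kd:
        p = replace(p, beta_cb=p.beta_cb * keep, beta_rb=p.beta_rb * keep)

    condition = "+".join(sorted(f"si{k.capitalize()}" for k in kd)) or "wild-type"
    cdc42 = cdc42_profile(p, grid, condition=condition)
    x = grid.positions
    g = np.exp(-x / crosstalk_gamma_a(p))
    A = p.alpha_r * np.exp(-x / p.lam)
    a = p.beta_rb * g
    b = p.beta_r + p.beta_cb * cdc42.values * g
    if np.all(a == 0) and np.all(b <= 0):
        raise DegenerateModelError("total Rac1 deactivation is zero")
    disc = b * b + 4.0 * a * A
    assert np.all(disc >= 0), "quadratic discriminant must be non-negative"
    with np.errstate(divide="ignore", invalid="ignore"):
        quad = (-b + np.sqrt(disc)) / (2.0 * a)
        lin = A / b
    rac1_values = np.where(a > 0, quad, lin)
    if not np.all(np.isfinite(rac1_values)):
        raise DegenerateModelError("Rac1 steady state undefined at some position")
    beta_b_values = (p.beta_cb * cdc42.values + p.beta_rb * rac1_values) * g
    rac1 = ActivityProfile("Rac1", grid, rac1_values, condition)
    beta_b = RegulatorProfile(role="gap", form="tabulated", values=beta_b_values)
    return rac1, cdc42, beta_b


def crosstalk_fixed_point(
    params: GTPaseParams,
    grid: SpatialGrid,
    knockdowns: Iterable[str] = (),
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Damped fixed-point solution of the crosstalk steady state.

    Kept as an independent numerical cross-check of the closed-form
    quadratic root in :func:`crosstalk_rac1_profile`; not used in the
    analysis path.
    """
    p = params
    kd = set(knockdowns)
    if "cdc42" in kd:
        p = replace(p, alpha_c=0.0)
    if "chimaerin" in kd:
        p = replace(p, beta_cb=0.0, beta_rb=0.0)
    x = grid.positions
    g = np.exp(-x / crosstalk_gamma_a(p))
    A = p.alpha_r * np.exp(-x / p.lam)
    C = p.alpha_c * np.exp(-x / p.lam) / p.beta_c
    R = A / max(p.beta_r, 1e-12)
    for _ in range(max_iter):
        denom = p.beta_r + (p.beta_cb * C + p.beta_rb * R) * g
        R_new = (1.0 - damping) * R + damping * A / denom
        if np.max(np.abs(R_new - R)) < tol:
            return R_new
        R = R_new
    raise RuntimeError("fixed-point iteration did not converge")


def diffusion_length(tau: float, D: float) -> float:
    """Length scale ℓ_diff = √(τD) a transport mechanism would add."""
    if tau < 0 or D < 0:
        raise InvalidParameterError("tau and D must be >= 0")
    return math.sqrt(tau * D)
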