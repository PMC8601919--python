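"""Appendage surface areas, whole-body allometry, and relative-size indices.

Bills and tarsi act as "thermal windows": poorly insulated, vascularized
surfaces through which a bird can dump body heat by radiation and
convection.  Following Allen's rule, individuals with relatively large
appendages for their body size are expected to dissipate dry heat more
effectively.  This module turns caliper measurements into surface-area
estimates and into size-corrected indices suitable for regression
analysis:

* bill area from length/width/depth, treating the bill as an elliptical
  cone;
* tarsi area (both legs) from tarsus length and mid-shaft width/depth,
  treating each tarsus as an elliptical cylinder;
* whole-body surface area from body mass via a Meeh-type allometry;
* relative-size indices as sex-stratified residuals of log area on log
  wing length (wing length being the standard body-size proxy in small
  passerines);
* mass-independent physiological rates as residuals of log rate on log
  body mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "IndividualRecord",
    "bill_surface_area",
    "tarsi_surface_area",
    "whole_body_surface_area",
    "size_index",
    "mass_independent",
    "add_surface_areas",
    "add_size_indices",
]

#: Meeh-type whole-body surface-area allometry A = k * Mb**b with A in cm^2
#: and Mb in g.  The classic passerine fit uses k near 8-10; the default
#: follows the convention used throughout this package.
MEEH_COEFFICIENT = 10.0
MEEH_EXPONENT = 0.667


@dataclass
class IndividualRecord:
    """One bird: sex, mass, caliper measurements, and derived quantities.

    Linear measurements are in mm, mass in g, areas in mm^2.  ``Mb`` is
    the mean of pre- and post-trial body masses.  The ``true_*`` fields
    hold latent generator parameters when the record was synthesized and
    are ``None`` for real data.
    """

    id: str
    sex: str  # "M" or "F"
    mb: float
    bl: float  # bill length
    bw: float  # bill width
    bd: float  # bill depth
    tl: float  # tarsus length
    tw: float  # tarsus width (mid-shaft)
    td: float  # tarsus depth (mid-shaft)
    wing: float
    bill_area: float | None = None
    tarsi_area: float | None = None
    bill_index: float | None = None
    tarsi_index: float | None = None
    true_tlc: float | None = None
    true_tuc: float | None = None
    true_bmr: float | None = None
    true_ewl_inflection: float | None = None
    true_ewl_baseline: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        for name in ("mb", "bl", "bw", "bd", "tl", "tw", "td", "wing"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def bill_surface_area(bw: float, bd: float, bl: float) -> float:
    """Lateral surface area of the bill modeled as an elliptical cone.

    The basal cross-section is an ellipse with semi-axes ``bw/2`` and
    ``bd/2``; the mean semi-axis ``(bw + bd)/4`` times pi times the slant
    length ``bl`` gives the lateral area:

        A = pi * bl * (bw + bd) / 4     [mm^2]

    For a circular base (``bw == bd == 2 r``) this reduces to the exact
    cone formula ``pi * r * bl``.
    """
    bw, bd, bl = float(bw), float(bd), float(bl)
    if bw <= 0 or bd <= 0 or bl < 0:
        raise ValueError("bill measurements must be positive (bl may be 0)")
    return np.pi * bl * (bw + bd) / 4.0


def tarsi_surface_area(tw: float, td: float, tl: float) -> float:
    """Surface area of both tarsi modeled as elliptical cylinders.

    The cross-section is an ellipse with semi-axes ``a = tw/2`` and
    ``b = td/2``.  Its perimeter is approximated by

        P = pi * sqrt(2 (a^2 + b^2) - (a - b)^2 / 2)

    (the standard "root-mean-square" elliptic-perimeter approximation,
    exact for a circle), and the area is ``P * tl * 2`` for the two legs.
    """
    tw, td, tl = float(tw), float(td), float(tl)
    if tw <= 0 or td <= 0 or tl < 0:
        raise ValueError("tarsus measurements must be positive (tl may be 0)")
    a = tw / 2.0
    b = td / 2.0
    perimeter = np.pi * np.sqrt(2.0 * (a * a + b * b) - 0.5 * (a - b) ** 2)
    return perimeter * tl * 2.0


def whole_body_surface_area(mb: float, k: float = MEEH_COEFFICIENT,
                            b: float = MEEH_EXPONENT) -> float:
    """Meeh-type whole-body surface area, cm^2, from body mass in g.

    ``A = k * mb**b``.  Used only for order-of-magnitude context (what
    fraction of the integument the bill and legs represent).
    """
    if mb <= 0:
        raise ValueError("body mass must be positive")
    return k * float(mb) ** b


def size_index(areas: Sequence[float], wing: Sequence[float],
               sex: Sequence[str]) -> np.ndarray:
    """Sex-stratified relative-size index for an appendage.

    Within each sex, ordinary least squares of ``log(area)`` on
    ``log(wing)`` (natural logs) is fitted and the residuals returned in
    input order.  Residuals within each sex sum to zero by construction.
    Sexual size dimorphism (males larger) is the reason for
    stratification: a pooled fit would confound sex with size.

    Raises ``ValueError`` naming the sex if fewer than 3 individuals of
    either present sex are available.
    """
    areas = np.asarray(areas, dtype=float)
    wing = np.asarray(wing, dtype=float)
    sex = np.asarray(sex, dtype=object)
    if areas.shape != wing.shape or areas.shape != sex.shape:
        raise ValueError("areas, wing and sex must have equal length")
    if np.any(areas <= 0) or np.any(wing <= 0):
        raise ValueError("areas and wing lengths must be positive")
    index = np.empty_like(areas)
    for s in np.unique(sex):
        mask = sex == s
        if mask.sum() < 3:
            raise ValueError(
                f"need at least 3 individuals of sex {s!r} for the index "
                f"regression, got {int(mask.sum())}"
            )
        index[mask] = _ols_residuals(np.log(wing[mask]), np.log(areas[mask]))
    return index


def mass_independent(values: Sequence[float], mb: Sequence[float]) -> np.ndarray:
    """Mass-independent residuals of a physiological rate.

    Residuals of ``log(value)`` on ``log(mb)`` across all individuals
    pooled (the allometric correction is shared between the sexes, unlike
    the morphometric indices).  Typically applied to VO2 or EWL at a
    single test temperature.
    """
    values = np.asarray(values, dtype=float)
    mb = np.asarray(mb, dtype=float)
    if values.shape != mb.shape:
        raise ValueError("values and mb must have equal length")
    if values.size < 3:
        raise ValueError("need at least 3 individuals")
    if np.any(values <= 0) or np.any(mb <= 0):
        raise ValueError("rates and masses must be positive")
    return _ols_residuals(np.log(mb), np.log(values))


def _ols_residuals(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def add_surface_areas(population: Sequence[IndividualRecord]) -> None:
    """Fill ``bill_area`` and ``tarsi_area`` on every record, in place."""
    for ind in population:
        ind.bill_area = bill_surface_area(ind.bw, ind.bd, ind.bl)
        ind.tarsi_area = tarsi_surface_area(ind.tw, ind.td, ind.tl)


def add_size_indices(population: Sequence[IndividualRecord]) -> None:
    """Fill ``bill_index`` and ``tarsi_index`` on every record, in place.

    Requires surface areas to be present (call :func:`add_surface_areas`
    first) and at least 3 individuals per sex.
    """
    if any(ind.bill_area is None or ind.tarsi_area is None
           for ind in population):
        raise ValueError("surface areas must be computed before indices")
    wing = [ind.wing for ind in population]
    sex = [ind.sex for ind in population]
    bill_idx = size_index([ind.bill_area for ind in population], wing, sex)
    tarsi_idx = size_index([ind.tarsi_area for ind in population], wing, sex)
    for ind, b, t in zip(population, bill_idx, tarsi_idx):
        ind.bill_index = float(b)
        ind.tarsi_index = float(t)
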