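"""Endpoint volume -> calcium amount and content.

EDTA chelates Ca2+ 1:1, so the amount of calcium in the titrated aliquot is
``molarity x (V_endpoint - V_blank)`` (mol/L x mL -> µmol).  Two routes are
exposed: direct stoichiometry with an explicit blank, or inversion of a
fitted endpoint-volume-vs-amount calibration line whose intercept absorbs
the matrix + indicator consumption.  The two are mutually exclusive — the
blank is never subtracted twice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import CalibrationError

__all__ = [
    "CA_MOLAR_MASS",
    "TitrantSpec",
    "SampleSpec",
    "CalibrationModel",
    "QuantResult",
    "endpoint_to_amount",
    "amount_to_content",
    "fit_calibration",
    "invert_calibration",
    "quantify",
]

#: Molar mass of calcium, g/mol.
CA_MOLAR_MASS = 40.078


@dataclass(frozen=True)
class TitrantSpec:
    """Titrant solution: molarity in mol/L (0.025 M EDTA is the standard)."""

    molarity: float
    name: str = "EDTA"

    def __post_init__(self) -> None:
        if self.molarity <= 0:
            raise ValueError("titrant molarity must be positive")


@dataclass(frozen=True)
class SampleSpec:
    """Sample aliquot: 1 mL of milk or ~1 g of other products per 100 mL water."""

    basis: str = "volume"  # "volume" (mg/100 mL) or "mass" (mg/100 g)
    aliquot: float = 1.0
    total_dispersion: float = 100.0
    matrix_blank_volume: float = 0.0

    def __post_init__(self) -> None:
        if self.basis not in ("volume", "mass"):
            raise ValueError("basis must be 'volume' or 'mass'")
        if self.aliquot <= 0 or self.total_dispersion <= 0:
            raise ValueError("aliquot and dispersion volumes must be positive")


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line V_endpoint = slope * amount + intercept (mL vs µmol)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class QuantResult:
    v_endpoint: float
    ca_amount: float  # µmol in the titrated aliquot
    ca_content: float  # mg per 100 mL (volume basis) or mg per 100 g (mass basis)
    basis: str
    route: str  # "stoichiometric" or "calibrated"
    model: Optional[CalibrationModel] = None


def endpoint_to_amount(v_endpoint: float, titrant: TitrantSpec, blank: float = 0.0) -> float:
    """Calcium amount in µmol from the endpoint volume by 1:1 stoichiometry."""
    if v_endpoint < blank:
        raise ValueError(
            f"endpoint volume {v_endpoint} mL below blank {blank} mL: negative amount"
        )
    return titrant.molarity * (v_endpoint - blank) * 1000.0


def amount_to_content(amount: float, sample: SampleSpec) -> float:
    """Convert µmol in the aliquot to mg per 100 mL (or 100 g) of product."""
    if amount < 0:
        raise ValueError("calcium amount must be non-negative")
    return amount * CA_MOLAR_MASS / 1000.0 * (100.0 / sample.aliquot)


def fit_calibration(points: Sequence[Tuple[float, float]]) -> CalibrationModel:
    """OLS of endpoint volume (mL) on calcium amount (µmol).

    ``points`` are ``(amount_umol, v_endpoint_mL)`` pairs.  R² is the squared
    Pearson correlation; it is exactly 1 for two points or any exact line.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 (amount, volume) pairs")
    amounts, vols = pts[:, 0], pts[:, 1]
    if np.ptp(amounts) == 0:
        raise CalibrationError("all calcium amounts identical: rank-deficient fit")
    fit = stats.linregress(amounts, vols)
    r2 = 1.0 if np.allclose(vols, fit.slope * amounts + fit.intercept) else float(fit.rvalue**2)
    return CalibrationModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(r2, 1.0),
        n_points=int(pts.shape[0]),
    )


def invert_calibration(model: CalibrationModel, v_endpoint: float) -> float:
    """Amount (µmol) from an endpoint volume through the fitted line."""
    if model.slope == 0:
        raise CalibrationError("zero calibration slope cannot be inverted")
    return (v_endpoint - model.intercept) / model.slope


def quantify(
    v_endpoint: float,
    titrant: TitrantSpec,
    sample: SampleSpec,
    *,
    model: Optional[CalibrationModel] = None,
) -> QuantResult:
    """Full endpoint -> content conversion by either route.

    With a calibration model the intercept already accounts for matrix and
    indicator consumption, so the blank is ignored; otherwise the sample's
    ``matrix_blank_volume`` is subtracted stoichiometrically.
    """
    if model is not None:
        amount = invert_calibration(model, v_endpoint)
        if amount < 0:
            raise ValueError(
                f"calibrated amount {amount:.4g} µmol is negative "
                f"(endpoint below calibration intercept)"
            )
        route = "calibrated"
    else:
        amount = endpoint_to_amount(v_endpoint, titrant, sample.matrix_blank_volume)
        route = "stoichiometric"
    content = amount_to_content(amount, sample)
    return QuantResult(
        v_endpoint=float(v_endpoint),
        ca_amount=float(amount),
        ca_content=float(content),
        basis=sample.basis,
        route=route,
        model=model,
    )
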