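"""Michaelis-Menten uptake kinetics for the phosphate/arsenate analog pathway.

Arsenate (AsO4^3-) enters macroalgal tissue through the phosphate transport
system because of its chemical similarity to PO4^3-.  Writing uptake of each
ion in the standard Michaelis-Menten form,

    rho = mu * C / (k + C),

with maximal rate ``mu`` and half-saturation constant ``k``, the As:P uptake
ratio at the very low dissolved concentrations of oligotrophic surface water
(C << k, uptake approximately linear in concentration) collapses to

    rho_As / rho_P  =  (mu_As * k_P) / (mu_P * k_As) * [AsO4] / [PO4].

Surface arsenate in the tropical/subtropical Atlantic is nearly uniform and
uncorrelated with phosphate, so the uptake ratio — and, if tissue content
mirrors proportionate uptake, the tissue As:P ratio — is predicted to vary
as 1/[PO4], i.e. hyperbolically in phosphorus: slope exactly −1 in
log10-log10 space.  The functions here evaluate that theory; comparing its
−1 slope with the slope fitted to real tissue data is the point of
:func:`gulfweed.powerlaw.fit_power_law`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, UndefinedRatioError

__all__ = [
    "UptakeParams",
    "ConcentrationPair",
    "mm_uptake",
    "uptake_ratio",
    "predicted_asp_curve",
]

#: Default guard for the linear (first-order) uptake regime: concentrations
#: at or below k/10 keep the linearization error under ~10%.
LINEAR_REGIME_FRACTION = 0.1


@dataclass(frozen=True)
class UptakeParams:
    """Michaelis-Menten constants for the P and As uptake pathways.

    Rates share an arbitrary unit; the half-saturation constants share the
    concentration unit of the dissolved pools they are compared against.
    """

    mu_P: float
    mu_As: float
    k_P: float
    k_As: float

    def __post_init__(self):
        for name in ("mu_P", "mu_As", "k_P", "k_As"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ConcentrationPair:
    """Dissolved phosphate and arsenate concentrations (same units as the k's)."""

    PO4: float
    AsO4: float

    def __post_init__(self):
        if self.PO4 < 0 or self.AsO4 < 0:
            raise DomainError("concentrations must be non-negative")


def mm_uptake(conc, mu: float, k: float):
    """Michaelis-Menten uptake rate ``mu * conc / (k + conc)``.

    Monotone increasing in ``conc``, bounded above by ``mu``, equal to
    ``mu/2`` exactly at ``conc == k``.  Accepts scalars or arrays.
    """
    conc = np.asarray(conc, dtype=float)
    if mu <= 0 or k <= 0:
        raise DomainError("mu and k must be strictly positive")
    if np.any(conc < 0):
        raise DomainError("concentration must be non-negative")
    out = mu * conc / (k + conc)
    return float(out) if out.ndim == 0 else out


def uptake_ratio(
    params: UptakeParams, conc: ConcentrationPair, regime: str = "linearized"
) -> float:
    """As:P uptake ratio ``rho_As / rho_P``.

    ``regime="linearized"`` returns the first-order expression
    ``(mu_As*k_P)/(mu_P*k_As) * [AsO4]/[PO4]`` exactly; ``regime="full"``
    evaluates the ratio of the two saturating Michaelis-Menten rates.  The
    two agree to first order as both concentrations tend to zero.
    """
    if conc.PO4 <= 0:
        raise UndefinedRatioError("uptake ratio undefined for [PO4] = 0")
    if regime == "linearized":
        return (params.mu_As * params.k_P) / (params.mu_P * params.k_As) * (
            conc.AsO4 / conc.PO4
        )
    if regime == "full":
        return mm_uptake(conc.AsO4, params.mu_As, params.k_As) / mm_uptake(
            conc.PO4, params.mu_P, params.k_P
        )
    raise ValueError(f"unknown regime {regime!r}")


def predicted_asp_curve(
    P_grid,
    params: UptakeParams,
    AsO4_fixed: float,
    regime: str = "linearized",
) -> pd.DataFrame:
    """Theoretical As:P uptake ratio over a grid of phosphate concentrations.

    With arsenate held fixed (its surface concentration is nearly uniform in
    the region of interest), the linearized ratio is proportional to
    ``1/[PO4]``: log10(ratio) vs log10(P) is affine with slope exactly −1.
    The full regime bends shallower than −1 as P approaches saturation.

    Returns a DataFrame with columns ``P`` and ``ratio``; if the grid
    extends beyond the linear-regime guard (``max(P) > k_P/10``) a warning
    string is recorded in ``DataFrame.attrs["regime_warning"]``.
    """
    P = np.asarray(P_grid, dtype=float)
    if np.any(P <= 0):
        raise DomainError("P_grid must be strictly positive")
    if AsO4_fixed < 0:
        raise DomainError("AsO4_fixed must be non-negative")
    ratios = np.array(
        [
            uptake_ratio(params, ConcentrationPair(PO4=p, AsO4=AsO4_fixed), regime)
            for p in P
        ]
    )
    table = pd.DataFrame({"P": P, "ratio": ratios})
    guard = params.k_P * LINEAR_REGIME_FRACTION
    if regime == "linearized" and (P.max() > guard or AsO4_fixed > params.k_As * LINEAR_REGIME_FRACTION):
        table.attrs["regime_warning"] = (
            f"grid extends beyond the linear regime guard (P <= k_P/10 = {guard:g}); "
            "the linearized ratio is a poor approximation near saturation"
        )
    return table
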