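"""Two end-member nitrogen-isotope dilution for a growing population.

A standing stock with tissue d15N = ``d15N_initial`` grows using a nitrogen
source whose new growth carries ``d15N_new_growth``.  After the biomass has
grown by a factor F, mass balance gives

    d15N_final = (1/F) * d15N_initial + (1 - 1/F) * d15N_new_growth,

so the growth factor needed to dilute the signature to an observed
``d15N_target`` is F = (d_init - d_new) / (d_target - d_new), and the number
of population doublings is log2(F).  Typical end members: riverine-influenced
Gulf of Mexico tissue at +6 to +8 permil, new growth on N2 fixation at about
-2 permil (the fixation fractionation), observed at +2 permil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

__all__ = ["IsotopeMixingParams", "MixingResult", "isotope_mixing"]


@dataclass(frozen=True)
class IsotopeMixingParams:
    """End members (permil) for the dilution calculation."""

    d15N_initial: float
    d15N_new_growth: float
    d15N_target: float


@dataclass(frozen=True)
class MixingResult:
    growth_factor: float
    doublings: float


def isotope_mixing(params: IsotopeMixingParams) -> MixingResult:
    """Solve the two end-member mass balance for the growth factor.

    Raises :class:`~gulfweed.errors.DomainError` when the target does not lie
    strictly between the new-growth and initial values (no finite amount of
    growth can produce it), or when the end members coincide (degenerate:
    mixing leaves the signature pinned at the initial value).
    """
    d_init, d_new, d_final = (
        params.d15N_initial,
        params.d15N_new_growth,
        params.d15N_target,
    )
    if d_new == d_init:
        raise DomainError("end members coincide; dilution cannot change d15N")
    lo, hi = sorted((d_new, d_init))
    if d_final == d_init:
        return MixingResult(growth_factor=1.0, doublings=0.0)
    if not (lo < d_final < hi):
        raise DomainError(
            f"target {d_final} permil is not between the end members ({d_new}, {d_init})"
        )
    F = (d_init - d_new) / (d_final - d_new)
    return MixingResult(growth_factor=F, doublings=math.log2(F))


def forward_mixing(d15N_initial: float, d15N_new_growth: float, F: float) -> float:
    """Forward mass balance: signature after growth by factor F (F >= 1)."""
    if F < 1:
        raise DomainError("growth factor must be >= 1")
    return d15N_initial / F + (1.0 - 1.0 / F) * d15N_new_growth
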