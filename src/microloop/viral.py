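"""Viral production from dilution assays and virus-induced mortality.

In the dilution technique, hosts are diluted into virus-free water so
that newly produced viruses accumulate against a low background. Viral
production is the first-order regression slope of viral counts vs time,
corrected for host dilution:

    VP = m × (b / B)

with m the slope (virus ml⁻¹ h⁻¹), b the bacterial concentration after
dilution and B before. Lysed cells follow from an assumed burst size
(27 viruses per lysed cell for these lakes):

    lysed (cell ml⁻¹ d⁻¹) = VP × 24 / burst_size

and per-capita lysis mortality (d⁻¹) divides lysed cells by the standing
bacterial abundance.
"""

from __future__ import annotations

import warnings

from scipy import stats

from .datatypes import DEFAULT_BURST_SIZE, DilutionAssay, LysisResult
from .errors import InputError, ParameterError

#: Host-dilution correction conventions. ``b_over_B`` is the published
#: form (shrinks VP when hosts are diluted); ``B_over_b`` is the inverted
#: scale-up variant offered for sensitivity analysis.
CORRECTIONS = ("b_over_B", "B_over_b")


def fit_viral_production(assay: DilutionAssay,
                         correction: str = "b_over_B") -> LysisResult:
    """Least-squares slope of viral counts vs time, dilution-corrected.

    Negative slopes are floored to VP = 0 with a warning (production is
    physically non-negative); the raw slope is retained in the result.
    """
    if correction not in CORRECTIONS:
        raise ParameterError(f"unknown correction {correction!r}")
    times = assay.times
    if times.size < 3:
        raise InputError("dilution assay needs at least 3 time points")
    if times.std() == 0:
        raise InputError("zero time variance in dilution assay")
    m = float(stats.linregress(times, assay.viral_counts).slope)
    factor = assay.b / assay.B if correction == "b_over_B" \
        else assay.B / assay.b
    negative = m < 0
    if negative:
        warnings.warn(
            f"negative viral-count slope ({m:.3g}) in assay "
            f"{assay.experiment}/{assay.treatment}; flooring VP at 0",
            stacklevel=2,
        )
    vp = 0.0 if negative else m * factor
    return LysisResult(slope=m, vp=vp, negative_slope=negative)


def lysed_cells(vp: float, burst_size: float = DEFAULT_BURST_SIZE) -> float:
    """Bacteria lysed per ml per day implied by a viral production rate."""
    if burst_size <= 0:
        raise ParameterError("burst_size must be > 0")
    if vp < 0:
        raise InputError("viral production must be >= 0")
    return vp * 24.0 / burst_size


def lysis_mortality(lysed: float, bacterial_abundance: float) -> float:
    """Per-capita virus-induced mortality rate (d⁻¹)."""
    if bacterial_abundance <= 0:
        raise InputError("bacterial abundance must be > 0")
    if lysed < 0:
        raise InputError("lysed cells must be >= 0")
    return lysed / bacterial_abundance


def analyse_assay(assay: DilutionAssay, bacterial_abundance: float,
                  burst_size: float = DEFAULT_BURST_SIZE,
                  correction: str = "b_over_B") -> LysisResult:
    """Full chain: slope → VP → lysed cells → lysis mortality."""
    base = fit_viral_production(assay, correction)
    lysed = lysed_cells(base.vp, burst_size)
    mort = lysis_mortality(lysed, bacterial_abundance)
    return LysisResult(slope=base.slope, vp=base.vp, lysed=lysed,
                       mortality=mort, burst_size=burst_size,
                       negative_slope=base.negative_slope)
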