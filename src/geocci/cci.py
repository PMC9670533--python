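"""The Composite Coverage Index (CCI).

The CCI is a weighted average of coverage with eight essential RMNCH
interventions spanning the four stages of the continuum of care:

    CCI = 1/4 * ( DFPSm + (ANC4 + SBA)/2 + (BCG + 2*DPT3 + MSL)/4
                  + (ORS + CAREP)/2 )

Expanding the nested means gives fixed weights that sum to one exactly:
DFPSm 1/4; ANC4, SBA, DPT3, ORS, CAREP 1/8 each; BCG, MSL 1/16 each.
Because the weights sum to one the index is scale-equivariant: it can be
evaluated on proportions in [0, 1] or percentages in [0, 100] alike, and is
always bracketed by the smallest and largest component.

All operations are pure functions applicable to scalars, arrays, raster
stacks and posterior sample stacks.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Mapping

import numpy as np

from .grid import PosteriorSampleStack
from .survey import INDICATORS

__all__ = ["CCI_WEIGHTS", "MissingIndicatorError", "compute_cci", "combine_posterior_stacks"]


#: Exact weights from expanding the nested means of the index formula.
CCI_WEIGHTS: dict[str, Fraction] = {
    "DFPSm": Fraction(1, 4),
    "ANC4": Fraction(1, 8),
    "SBA": Fraction(1, 8),
    "BCG": Fraction(1, 16),
    "DPT3": Fraction(1, 8),
    "MSL": Fraction(1, 16),
    "ORS": Fraction(1, 8),
    "CAREP": Fraction(1, 8),
}

assert sum(CCI_WEIGHTS.values()) == 1


class MissingIndicatorError(KeyError):
    """Raised when a CCI input lacks one of the eight components.

    There is no silent reweighting: a partial vector would redefine the
    index, so it is always an error.
    """


def _check_components(values: Mapping[str, object]) -> None:
    missing = [k for k in INDICATORS if k not in values]
    if missing:
        raise MissingIndicatorError(
            f"CCI requires all eight indicators; missing: {missing}"
        )


def compute_cci(values: Mapping[str, object]):
    """Evaluate the CCI on a full eight-indicator vector.

    Parameters
    ----------
    values : mapping of indicator name -> scalar or ndarray
        All eight indicators on a common scale (all proportions or all
        percentages).  Arrays are combined elementwise and must broadcast.

    Returns
    -------
    The weighted average, on the same scale and shape as the inputs.
    """
    _check_components(values)
    out = None
    for name in INDICATORS:
        term = np.asarray(values[name], dtype=float) * float(CCI_WEIGHTS[name])
        out = term if out is None else out + term
    if out.ndim == 0:
        return float(out)
    return out


def combine_posterior_stacks(
    stacks: Mapping[str, PosteriorSampleStack],
) -> PosteriorSampleStack:
    """Combine eight per-indicator posterior stacks into a CCI stack.

    Sample s of the output at cell g is the CCI of the eight indicator
    samples (s, g) — the samplewise combination that propagates joint
    uncertainty into the index.  All stacks must share the sample count and
    grid geometry.
    """
    _check_components(stacks)
    ref = stacks[INDICATORS[0]]
    for name in INDICATORS[1:]:
        st = stacks[name]
        if st.n_samples != ref.n_samples:
            raise ValueError(
                f"stack {name!r} has {st.n_samples} samples, expected {ref.n_samples}"
            )
        if not st.template.same_geometry(ref.template):
            raise ValueError(f"stack {name!r} grid geometry differs from {ref.label!r}")
    combined = compute_cci({k: stacks[k].samples for k in INDICATORS})
    return PosteriorSampleStack(combined, ref.template.like(ref.template.values), label="CCI")
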