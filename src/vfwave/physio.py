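"""Derived coronary hemodynamic and metabolic quantities.

All operations are elementwise over per-(subject, timepoint) panels and are
deliberately unit-agnostic about flow: when LAD flow is expressed as percent
of baseline (the study's reporting convention), the Fick products MDO2/MVO2
are meaningful only relative to their own baseline -- use
:func:`percent_of_baseline` on the products, not on flow alone.

Sign conventions, stated explicitly because they are easy to flip:

* lactate flux = flow * (arterial - venous); positive = consumption,
  negative = production by the myocardium.
* PCO2 gradient = great-cardiac-vein PCO2 - arterial PCO2 (veno-arterial);
  it rises with anaerobic myocardial metabolism.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FickO2",
    "coronary_perfusion_pressure",
    "fick_o2",
    "lactate_flux",
    "pco2_gradient",
    "percent_of_baseline",
    "derive_panel",
    "SIGN_CONVENTIONS",
]

SIGN_CONVENTIONS = {
    "lactate_flux": "positive = myocardial consumption, negative = production",
    "pco2_gradient": "veno-arterial: great cardiac vein PCO2 minus arterial PCO2",
}


class FickO2(NamedTuple):
    mdo2: float
    mvo2: float
    extraction: float


def coronary_perfusion_pressure(map_mmHg, rap_mmHg):
    """CPP = mean aortic pressure - mean right atrial pressure (mmHg).

    May be negative; reported as-is.
    """
    return np.asarray(map_mmHg, dtype=float) - np.asarray(rap_mmHg, dtype=float)


def fick_o2(lad_flow, cao2_mldl, cvo2_mldl) -> FickO2:
    """Fick-principle myocardial oxygen delivery, consumption and extraction.

    mdo2 = flow * CaO2; mvo2 = flow * (CaO2 - CvO2);
    extraction = (CaO2 - CvO2) / CaO2.
    """
    flow = np.asarray(lad_flow, dtype=float)
    cao2 = np.asarray(cao2_mldl, dtype=float)
    cvo2 = np.asarray(cvo2_mldl, dtype=float)
    if np.any(flow < 0):
        raise ValueError("LAD flow must be non-negative")
    if np.any(cao2 == 0):
        raise ValueError("arterial O2 content is zero; extraction undefined")
    avdo2 = cao2 - cvo2
    return FickO2(mdo2=flow * cao2, mvo2=flow * avdo2, extraction=avdo2 / cao2)


def lactate_flux(lad_flow, lac_a_mM, lac_v_mM):
    """Myocardial lactate flux = flow * (arterial - venous).

    Positive = consumption, negative = production.
    """
    return (
        np.asarray(lad_flow, dtype=float)
        * (np.asarray(lac_a_mM, dtype=float) - np.asarray(lac_v_mM, dtype=float))
    )


def pco2_gradient(pvco2_mmHg, paco2_mmHg):
    """Veno-arterial coronary PCO2 gradient = GCV PCO2 - arterial PCO2 (mmHg)."""
    return np.asarray(pvco2_mmHg, dtype=float) - np.asarray(paco2_mmHg, dtype=float)


def percent_of_baseline(value, baseline):
    """100 * value / baseline; raises on a zero baseline."""
    baseline = np.asarray(baseline, dtype=float)
    if np.any(baseline == 0):
        raise ValueError("baseline is zero; percent of baseline undefined")
    return 100.0 * np.asarray(value, dtype=float) / baseline


def derive_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Append all derived quantities to a tidy physiological panel.

    Expects columns (any subset): map_mmHg, rap_mmHg, lad_flow, cao2_mldl,
    cvo2_mldl, lac_a_mM, lac_v_mM, paco2_mmHg, pvco2_mmHg.  Derivations are
    added only where their inputs are present; rows are independent.
    """
    out = panel.copy()
    cols = set(panel.columns)
    if {"map_mmHg", "rap_mmHg"} <= cols:
        out["cpp_mmHg"] = coronary_perfusion_pressure(panel["map_mmHg"], panel["rap_mmHg"])
    if {"lad_flow", "cao2_mldl", "cvo2_mldl"} <= cols:
        f = fick_o2(panel["lad_flow"], panel["cao2_mldl"], panel["cvo2_mldl"])
        out["mdo2"], out["mvo2"], out["o2_extraction"] = f.mdo2, f.mvo2, f.extraction
    if {"lad_flow", "lac_a_mM", "lac_v_mM"} <= cols:
        out["lactate_flux"] = lactate_flux(
            panel["lad_flow"], panel["lac_a_mM"], panel["lac_v_mM"]
        )
    if {"pvco2_mmHg", "paco2_mmHg"} <= cols:
        out["pco2_gradient_mmHg"] = pco2_gradient(panel["pvco2_mmHg"], panel["paco2_mmHg"])
    out.attrs["sign_conventions"] = dict(SIGN_CONVENTIONS)
    return out
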