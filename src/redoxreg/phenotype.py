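"""Growth and pigmentation analytics.

PMP (photomembrane production index) is OD880/OD660 — pigment absorbance
normalized per unit biomass. ΔPMP is the PMP of a condition minus the
PMP of the unpigmented aerobic control, so the control's own ΔPMP is 0
and a pigmented culture scores positive. Optical densities may be
corrected to a 1 cm path-length equivalent first; the correction cancels
in the PMP ratio.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .models import GrowthSeries


def correct_pathlength(od_raw, pathlength_factor: float):
    """Normalize absorbance to a 1 cm equivalent: od_raw / factor.

    The factor is the effective path length in cm of the plate/cuvette
    geometry used; it must be supplied for the instrument at hand (there
    is no universal default).
    """
    if pathlength_factor <= 0:
        raise ValueError("path-length factor must be positive")
    return np.asarray(od_raw, dtype=float) / pathlength_factor if np.ndim(od_raw) else float(od_raw) / pathlength_factor


def compute_pmp(od880, od660):
    """PMP = OD880 / OD660; undefined at zero biomass."""
    od880 = np.asarray(od880, dtype=float)
    od660 = np.asarray(od660, dtype=float)
    if (od660 <= 0).any() if od660.ndim else od660 <= 0:
        raise ValueError("PMP undefined: OD660 must be > 0")
    out = od880 / od660
    return float(out) if out.ndim == 0 else out


def compute_delta_pmp(pmp_i, pmp_c):
    """ΔPMP = PMP of the sample minus PMP of the unpigmented control."""
    out = np.asarray(pmp_i, dtype=float) - np.asarray(pmp_c, dtype=float)
    return float(out) if out.ndim == 0 else out


def growth_endpoints(series: GrowthSeries, pathlength_factor: float = 1.0) -> dict:
    """Endpoint metrics of one growth curve.

    Maximal biomass is the max of corrected OD660 over time; the
    endpoint PMP is taken at the final time point (end-of-culture
    measurement, not the max over time).
    """
    if len(series.time_h) == 0:
        raise ValueError("empty growth series")
    od660 = correct_pathlength(series.od660, pathlength_factor)
    od880 = correct_pathlength(series.od880, pathlength_factor)
    i_max = int(np.argmax(od660))
    return {
        "condition": series.condition,
        "strain": series.strain,
        "replicate": series.replicate,
        "max_od660": float(od660[i_max]),
        "time_of_max_h": float(series.time_h[i_max]),
        "endpoint_pmp": compute_pmp(od880[-1], od660[-1]),
    }


def endpoint_table(series: list[GrowthSeries], pathlength_factor: float = 1.0) -> list[dict]:
    """Per-replicate endpoints for a collection of growth curves."""
    return [growth_endpoints(s, pathlength_factor) for s in series]


def endpoint_delta_pmp(
    series: list[GrowthSeries],
    control_condition: str,
    pathlength_factor: float = 1.0,
) -> dict[tuple[str, str], float]:
    """Mean endpoint ΔPMP per (strain, condition) against the control.

    The control PMP is the mean endpoint PMP of the same strain grown in
    ``control_condition``.
    """
    table = endpoint_table(series, pathlength_factor)
    groups: dict[tuple[str, str], list[float]] = {}
    for row in table:
        groups.setdefault((row["strain"], row["condition"]), []).append(row["endpoint_pmp"])
    out = {}
    for (strain, condition), pmps in groups.items():
        control = groups.get((strain, control_condition))
        if control is None:
            raise ValueError(f"no series for control condition {control_condition!r}, strain {strain!r}")
        out[(strain, condition)] = float(np.mean(pmps) - np.mean(control))
    return out


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Unpaired two-tailed Student's t test (equal-variance).

    Degenerate case — both groups constant with equal means — returns
    (0.0, 1.0) by convention rather than NaN.
    """
    import warnings

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    with warnings.catch_warnings():
        # near-constant groups trip scipy's precision-loss warning; the
        # degenerate outcome is handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):
        return 0.0, 1.0
    return float(t), float(p)
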