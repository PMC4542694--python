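"""Concentration–response analysis of cell-based receptor assays.

Responses are fractions of responding cells normalised to a reference
agonist condition, so the curve bottom is structurally zero and the model is

    R(c) = top · c^h / (EC50^h + c^h)

with free plateau ``top``, Hill slope ``h`` and midpoint ``EC50`` (μM).
Weighted least squares uses 1/SE² weights when per-point standard errors are
available.  The pH dependency of a variant is summarised as the ratio of the
predicted responses at a reference concentration under acidic vs neutral
conditions; antagonism is quantified as the fractional suppression of a
co-applied agonist's response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ResponseTable",
    "DoseResponseFit",
    "FitError",
    "fit_hill",
    "ph_dependency",
    "antagonism_index",
    "read_response_tables",
]


class FitError(ValueError):
    """Dose-response input unusable for the requested fit."""


@dataclass
class ResponseTable:
    """Normalized responses of one variant at one pH across concentrations."""

    variant: str
    ph: float
    concentration_um: np.ndarray  # μM, > 0
    response: np.ndarray  # normalized fraction, >= 0
    se: Optional[np.ndarray] = None
    n: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.concentration_um = np.asarray(self.concentration_um, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
        if np.any(self.concentration_um <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(self.response < 0):
            raise ValueError("responses must be non-negative")
        order = np.argsort(self.concentration_um)
        self.concentration_um = self.concentration_um[order]
        self.response = self.response[order]
        if self.se is not None:
            self.se = self.se[order]
        if self.n is not None:
            self.n = np.asarray(self.n)[order]


@dataclass
class DoseResponseFit:
    variant: str
    ph: float
    ec50: float  # μM
    hill: float
    top: float
    ec50_stderr: Optional[float] = None
    rmse: Optional[float] = None
    warnings: list[str] = field(default_factory=list)
    ph_dependency_ratio: Optional[float] = None

    def predict(self, conc_um) -> np.ndarray:
        c = np.asarray(conc_um, dtype=float)
        return hill_curve(c, self.top, self.ec50, self.hill)


def hill_curve(c: np.ndarray, top: float, ec50: float, h: float) -> np.ndarray:
    """Hill activation curve with bottom fixed at zero."""
    c = np.asarray(c, dtype=float)
    return top * c**h / (ec50**h + c**h)


def fit_hill(table: ResponseTable) -> DoseResponseFit:
    """Fit the zero-bottom Hill model by (weighted) least squares.

    Raises :class:`FitError` for unusable inputs (all-zero responses or
    monotone-decreasing data, which indicate an antagonist-mode experiment);
    warns — via the fit's ``warnings`` list — when fewer than four distinct
    concentrations are available or the tested range does not bracket the
    fitted EC50.
    """
    c, r = table.concentration_um, table.response
    if np.all(r == 0):
        raise FitError(f"{table.variant} pH {table.ph}: all responses zero (no signal)")
    # Spearman-style monotonicity probe on the raw points
    if len(r) >= 3 and np.all(np.diff(r) <= 0) and r[0] > r[-1]:
        raise FitError(
            f"{table.variant} pH {table.ph}: responses decrease with dose; "
            "this looks like antagonist-mode data (use antagonism_index)"
        )
    warn: list[str] = []
    if len(np.unique(c)) < 4:
        warn.append("fewer than 4 distinct concentrations")

    sigma = table.se if table.se is not None and np.all(table.se > 0) else None
    top0 = float(r.max())
    # midpoint guess: concentration whose response is closest to half-plateau
    ec0 = float(c[np.argmin(np.abs(r - top0 / 2))])
    p0 = (top0 if top0 > 0 else 1.0, ec0, 1.0)
    bounds = ([1e-9, 1e-9, 0.3], [np.inf, np.inf, 5.0])
    try:
        popt, pcov = curve_fit(
            hill_curve, c, r, p0=p0, sigma=sigma, absolute_sigma=sigma is not None,
            bounds=bounds, maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"{table.variant} pH {table.ph}: no convergence ({exc})")
    top, ec50, h = (float(v) for v in popt)
    ec50_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else None
    resid = hill_curve(c, *popt) - r
    rmse = float(np.sqrt(np.mean(resid**2)))
    if not (c.min() <= ec50 <= c.max()):
        warn.append(f"fitted EC50 {ec50:.3g} outside tested range")
    return DoseResponseFit(
        variant=table.variant, ph=table.ph, ec50=ec50, hill=h, top=top,
        ec50_stderr=ec50_se, rmse=rmse, warnings=warn,
    )


def ph_dependency(
    fit_acidic: DoseResponseFit,
    fit_neutral: DoseResponseFit,
    ref_conc_um: Optional[float] = None,
) -> float:
    """Ratio of predicted responses (acidic / neutral) at a reference dose.

    A ratio near 1 marks a pH-insensitive variant; a ratio well above 1 marks
    pH-dependent agonism.  ``ref_conc_um`` defaults to a dose far above both
    EC50s (plateau comparison).  Returns ``inf`` when the neutral response
    vanishes at the reference dose.
    """
    if fit_acidic.variant != fit_neutral.variant:
        raise ValueError(
            f"fits are for different variants: {fit_acidic.variant} vs "
            f"{fit_neutral.variant}"
        )
    if ref_conc_um is None:
        ref_conc_um = 100.0 * max(fit_acidic.ec50, fit_neutral.ec50)
    r_acid = float(fit_acidic.predict(ref_conc_um))
    r_neut = float(fit_neutral.predict(ref_conc_um))
    if r_neut == 0:
        return math.inf
    return r_acid / r_neut


def antagonism_index(
    mix_table: ResponseTable,
    agonist_alone: ResponseTable,
    at_concentration_um: Optional[float] = None,
) -> float:
    """Fractional suppression of the agonist response by a co-applied protein.

    ``index = 1 − response(agonist + test) / response(agonist alone)``;
    positive values mean antagonism.  The mixture response is read at
    ``at_concentration_um`` of the test protein (default: the highest tested
    dose); the agonist-alone response is the mean of its table.  Both tables
    must refer to the same pH.
    """
    if mix_table.ph != agonist_alone.ph:
        raise ValueError(
            f"pH mismatch: mixture at {mix_table.ph}, agonist alone at "
            f"{agonist_alone.ph}"
        )
    baseline = float(np.mean(agonist_alone.response))
    if baseline == 0:
        raise FitError("agonist-alone response is zero; index undefined")
    if at_concentration_um is None:
        at_concentration_um = float(mix_table.concentration_um.max())
    i = int(np.argmin(np.abs(mix_table.concentration_um - at_concentration_um)))
    return 1.0 - float(mix_table.response[i]) / baseline


def read_response_tables(path) -> list[ResponseTable]:
    """Read `variant,ph,concentration_um,response[,se[,n]]` CSV into tables."""
    df = pd.read_csv(path, comment="#")
    required = {"variant", "ph", "concentration_um", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    tables = []
    for (variant, ph), grp in df.groupby(["variant", "ph"], sort=True):
        tables.append(
            ResponseTable(
                variant=str(variant),
                ph=float(ph),
                concentration_um=grp["concentration_um"].to_numpy(),
                response=grp["response"].to_numpy(),
                se=grp["se"].to_numpy() if "se" in grp else None,
                n=grp["n"].to_numpy() if "n" in grp else None,
            )
        )
    return tables


def write_fits(fits: Sequence[DoseResponseFit], path) -> None:
    rows = [
        {
            "variant": f.variant,
            "ph": f.ph,
            "ec50_um": f.ec50,
            "ec50_stderr": f.ec50_stderr,
            "hill": f.hill,
            "top": f.top,
            "rmse": f.rmse,
            "ph_dependency_ratio": f.ph_dependency_ratio,
            "model": "hill_bottom0",  # fitted functional form, for provenance
        }
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
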