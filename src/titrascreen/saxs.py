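"""Small-angle X-ray scattering: Guinier analysis and Kratky transforms.

The Guinier approximation ``ln I(q) = ln I(0) − q²Rg²/3`` holds at low
momentum transfer (q = 4π sin θ / λ); for globular particles the usual
validity window is q·Rg ≲ 1.3.  :func:`guinier_fit` selects that window
automatically: it starts from the lowest usable q values and extends the
upper bound while the limit is respected, refitting until the Rg estimate
stabilises.  The Kratky transform ``q² I(q)`` vs ``q`` distinguishes compact
(single maximum then decay) from extended or disordered scatterers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "SAXSProfile",
    "GuinierFit",
    "read_saxs",
    "write_saxs",
    "guinier_fit",
    "kratky",
    "compare_profiles",
]

DEFAULT_QRG_LIMIT = 1.3
BEAMSTOP_Q_CUTOFF = 0.025  # Å⁻¹; low-q points shadowed by the beam stop


@dataclass
class SAXSProfile:
    q: np.ndarray  # Å⁻¹, strictly increasing, > 0
    intensity: np.ndarray  # arbitrary units
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.q) and (np.any(np.diff(self.q) <= 0) or np.any(self.q <= 0)):
            raise ValueError("q must be strictly increasing and positive")

    def __len__(self) -> int:
        return len(self.q)

    def truncated(self, q_min: Optional[float] = None, q_max: Optional[float] = None):
        mask = np.ones(len(self.q), dtype=bool)
        if q_min is not None:
            mask &= self.q >= q_min
        if q_max is not None:
            mask &= self.q <= q_max
        return SAXSProfile(
            self.q[mask],
            self.intensity[mask],
            self.sigma[mask] if self.sigma is not None else None,
        )


@dataclass
class GuinierFit:
    rg: float  # Å
    i0: float  # forward scattering
    q_range: tuple[float, float]
    qrg_max: float
    r_squared: float
    rg_stderr: Optional[float] = None
    n_points: int = 0


class GuinierError(ValueError):
    """No q window satisfies the Guinier validity limit."""


def read_saxs(path, beamstop_cutoff: Optional[float] = None) -> SAXSProfile:
    """Read a 2- or 3-column (q, I[, σ]) text profile.

    ``beamstop_cutoff`` drops all points with q below the cutoff (points in
    the shadow of the beam stop carry no information about the particle).
    """
    raw = np.genfromtxt(Path(path), comments="#", delimiter=None)
    if raw.ndim == 1:
        raw = raw.reshape(1, -1)
    if np.isnan(raw).all() or raw.shape[1] < 2:
        # fall back to comma-separated
        raw = np.genfromtxt(Path(path), comments="#", delimiter=",")
        if raw.ndim == 1:
            raw = raw.reshape(1, -1)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns (q, I)")
    q, i = raw[:, 0], raw[:, 1]
    sigma = raw[:, 2] if raw.shape[1] >= 3 else None
    prof = SAXSProfile(q, i, sigma)
    if beamstop_cutoff is not None:
        prof = prof.truncated(q_min=beamstop_cutoff)
    return prof


def write_saxs(profile: SAXSProfile, path) -> None:
    cols = [profile.q, profile.intensity]
    header = "q(1/A) I(q)"
    if profile.sigma is not None:
        cols.append(profile.sigma)
        header += " sigma"
    np.savetxt(Path(path), np.column_stack(cols), header=header, fmt="%.8e")


def _linfit(q2: np.ndarray, ln_i: np.ndarray, w: Optional[np.ndarray]):
    """Weighted straight-line fit of ln I on q²; returns slope, intercept, cov."""
    if w is None:
        w = np.ones_like(q2)
    W = np.diag(w)
    X = np.column_stack([q2, np.ones_like(q2)])
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ ln_i)
    resid = ln_i - X @ beta
    dof = max(len(q2) - 2, 1)
    cov = np.linalg.inv(xtwx) * float(resid @ (w * resid)) / dof
    return beta[0], beta[1], cov, resid


def guinier_fit(
    profile: SAXSProfile,
    qrg_limit: float = DEFAULT_QRG_LIMIT,
    min_points: int = 5,
    rtol: float = 1e-4,
) -> GuinierFit:
    """Automatic-window Guinier fit.

    Starting from the ``min_points`` lowest usable q values, the upper bound
    is extended point by point while ``q_max · Rg ≤ qrg_limit`` holds for the
    refitted Rg, iterating until the Rg estimate changes by less than
    ``rtol`` relative.  Raises :class:`GuinierError` when no window
    satisfies the limit (e.g. a flat, Rg→0 profile).
    """
    usable = profile.intensity > 0
    q = profile.q[usable]
    i = profile.intensity[usable]
    s = profile.sigma[usable] if profile.sigma is not None else None
    if len(q) < min_points:
        raise GuinierError(f"only {len(q)} usable points (need {min_points})")

    ln_i = np.log(i)
    q2 = q**2
    # σ_lnI = σ_I / I propagation
    w = (i / s) ** 2 if s is not None and np.all(s > 0) else None

    def fit_first(n: int):
        slope, icpt, cov, resid = _linfit(
            q2[:n], ln_i[:n], w[:n] if w is not None else None
        )
        return slope, icpt, cov, resid

    n = min_points
    slope, icpt, cov, resid = fit_first(n)
    if slope >= 0:
        raise GuinierError("non-negative Guinier slope; Rg not defined")
    rg = math.sqrt(-3.0 * slope)
    if q[n - 1] * rg > qrg_limit:
        raise GuinierError(
            f"even the smallest window violates q·Rg <= {qrg_limit:g}"
        )

    # fixed-point iteration: window q_max·Rg <= limit, refit, repeat
    for _ in range(100):
        n_new = int(np.searchsorted(q, qrg_limit / rg, side="right"))
        n_new = min(max(n_new, min_points), len(q))
        slope_n, icpt_n, cov_n, resid_n = fit_first(n_new)
        if slope_n >= 0:
            break  # extension degenerate; keep the last valid fit
        rg_new = math.sqrt(-3.0 * slope_n)
        slope, icpt, cov, resid = slope_n, icpt_n, cov_n, resid_n
        converged = abs(rg_new - rg) <= rtol * rg and n_new == n
        rg, n = rg_new, n_new
        if converged:
            break

    # curvature guard: real form factors bend downward beyond the strict
    # Guinier regime, biasing Rg upward.  Shrink the window while the q⁴
    # deviation from the straight line exceeds the noise floor of the data,
    # so low-noise profiles get a conservative window and noisy profiles
    # keep the full globular-convention window.
    def curvature(m: int):
        X = np.column_stack([np.ones(m), q2[:m], q2[:m] ** 2])
        ww = w[:m] if w is not None else np.ones(m)
        sw = np.sqrt(ww)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], ln_i[:m] * sw, rcond=None)
        resid_q = ln_i[:m] - X @ coef
        return abs(coef[2]) * q2[m - 1] ** 2, float(np.sqrt(np.mean(resid_q**2)))

    curv_floor = 1e-4  # ln-intensity units; below any measurable deviation
    while n > min_points:
        delta, noise_rmse = curvature(n)
        if delta <= max(curv_floor, 2.0 * noise_rmse):
            break
        n -= 1
        slope, icpt, cov, resid = fit_first(n)
        if slope >= 0:
            raise GuinierError("degenerate window during curvature trim")
        rg = math.sqrt(-3.0 * slope)

    ln_pred = slope * q2[:n] + icpt
    ss_res = float(np.sum((ln_i[:n] - ln_pred) ** 2))
    ss_tot = float(np.sum((ln_i[:n] - ln_i[:n].mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    # σ_Rg via error propagation from the slope variance: Rg = sqrt(-3 b)
    slope_var = float(cov[0, 0])
    rg_stderr = 1.5 * math.sqrt(slope_var) / rg if slope_var > 0 else None
    return GuinierFit(
        rg=rg,
        i0=float(math.exp(icpt)),
        q_range=(float(q[0]), float(q[n - 1])),
        qrg_max=float(q[n - 1] * rg),
        r_squared=r2,
        rg_stderr=rg_stderr,
        n_points=n,
    )


def kratky(profile: SAXSProfile) -> np.ndarray:
    """Kratky transform: array of (q, q²·I(q)) rows."""
    return np.column_stack([profile.q, profile.q**2 * profile.intensity])


def compare_profiles(
    a: SAXSProfile,
    b: SAXSProfile,
    qrg_limit: float = DEFAULT_QRG_LIMIT,
) -> dict:
    """Size / shape comparison of two profiles.

    Returns ΔRg = |Rg_a − Rg_b| with its propagated uncertainty and a reduced
    χ² between the scaled Kratky curves on the common q grid (profile *b* is
    interpolated onto *a*'s grid and scaled by a least-squares factor).
    """
    q_lo = max(a.q.min(), b.q.min())
    q_hi = min(a.q.max(), b.q.max())
    if q_lo >= q_hi:
        raise ValueError("profiles have disjoint q ranges")

    fit_a = guinier_fit(a, qrg_limit)
    fit_b = guinier_fit(b, qrg_limit)
    d_rg = abs(fit_a.rg - fit_b.rg)
    var = sum((f.rg_stderr or 0.0) ** 2 for f in (fit_a, fit_b))
    d_rg_sigma = math.sqrt(var) if var > 0 else None

    mask = (a.q >= q_lo) & (a.q <= q_hi)
    qa = a.q[mask]
    ka = qa**2 * a.intensity[mask]
    kb = qa**2 * np.interp(qa, b.q, b.intensity)
    scale = float(np.dot(ka, kb) / np.dot(kb, kb)) if np.dot(kb, kb) > 0 else 1.0
    diff = ka - scale * kb
    if a.sigma is not None and b.sigma is not None:
        sa = qa**2 * a.sigma[mask]
        sb = qa**2 * np.interp(qa, b.q, b.sigma) * scale
        denom = sa**2 + sb**2
        denom[denom == 0] = np.inf
        chi2 = float(np.sum(diff**2 / denom))
    else:
        chi2 = float(np.sum(diff**2) / max(np.var(ka), 1e-300))
    dof = max(len(qa) - 1, 1)
    return {
        "rg_a": fit_a.rg,
        "rg_b": fit_b.rg,
        "delta_rg": d_rg,
        "delta_rg_sigma": d_rg_sigma,
        "size_difference_detected": (
            bool(d_rg > 3 * d_rg_sigma) if d_rg_sigma else None
        ),
        "kratky_chi2_reduced": chi2 / dof,
        "q_overlap": (float(q_lo), float(q_hi)),
        "scale": scale,
    }
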