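"""Spin-relaxation analysis: R1/R2 decay fits, R2/R1 ratios, and apparent
correlation times from the steady-state 15N[1H] heteronuclear nOe.

R1 and R2 are obtained by mono-exponential fits to peak-height decay series,
I(t) = I0 exp(-R t).  No correction is applied for possible changes of fast
amide-water exchange; the sequence-dependent R2 variation analysed here is
far larger than that effect.

The nOe ratio O = I_sat / I_ref reports ps-ns backbone motion.  For the
15N-1H dipolar pair, ignoring chemical-shift-anisotropy contributions, the
nOe depends on field and correlation time only through the dimensionless
product x = f_H * tau_n (1H frequency in Hz times correlation time in s):

    O(x) = 0.782804 - (0.010000683009 + 0.5132297763 x^2)
                      / (0.002123332299 + 0.1102575629 x^2 + x^4)

O is strictly increasing in x, from the extreme-narrowing limit ~ -3.927
(x -> 0) to the slow-tumbling limit 0.782804 (x -> inf), so an apparent
correlation time tau_n is recovered per residue by monotone root bracketing.
tau_n is the apparent correlation time of the N-H bond vector of a
disordered chain, deliberately distinct from the global tumbling time tau_c
of a folded protein.  Normalizing through x makes measurements at different
fields directly comparable: the same motion gives different nOe values at
500 and 900 MHz but inverts to the same tau_n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

# Constants of the dipolar nOe closed form (dimensionless in x = fH * tau_n).
NOE_PLATEAU = 0.782804
_A = 0.010000683009
_B = 0.5132297763
_C = 0.002123332299
_D = 0.1102575629

#: Open interval of physically attainable 15N[1H] nOe ratios.
NOE_MIN = NOE_PLATEAU - _A / _C  # ~ -3.9272, extreme narrowing
NOE_MAX = NOE_PLATEAU


class FitError(RuntimeError):
    """Raised when a relaxation decay cannot be fit to a positive rate."""


@dataclass
class DecaySeries:
    """Peak-height decay of one residue: delays (ms) vs intensities."""

    residue_index: int
    delays_ms: np.ndarray
    intensities: np.ndarray
    field_mhz: float
    rate_kind: str = "R2"  # R1 | R2

    def __post_init__(self) -> None:
        self.delays_ms = np.asarray(self.delays_ms, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.delays_ms.shape != self.intensities.shape:
            raise ValueError("delays and intensities differ in length")
        if (self.delays_ms < 0).any():
            raise ValueError("negative delay")
        if not np.isfinite(self.intensities).all():
            raise ValueError("non-finite intensity")
        if self.rate_kind not in ("R1", "R2"):
            raise ValueError(f"rate_kind must be R1 or R2, got {self.rate_kind!r}")

    @property
    def delays_s(self) -> np.ndarray:
        return self.delays_ms / 1000.0


@dataclass(frozen=True)
class RateEstimate:
    """Fitted relaxation rate for one residue."""

    residue_index: int
    rate: float  # s^-1
    se: float
    i0: float
    field_mhz: float
    rate_kind: str


def fit_rate(series: DecaySeries) -> RateEstimate:
    """Nonlinear least-squares fit of I(t) = I0 exp(-R t), R in s^-1.

    The starting point comes from a log-linear regression on the positive
    intensities; the SE is the square root of the covariance diagonal.
    Scale-invariant: multiplying all intensities by a constant changes I0
    only.
    """
    t = series.delays_s
    y = series.intensities
    if len(np.unique(t)) < 3:
        raise FitError(
            f"residue {series.residue_index}: need >= 3 distinct delays"
        )
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (math.exp(intercept), max(-slope, 1e-3))
    else:
        p0 = (float(np.max(np.abs(y))) or 1.0, 1.0)
    try:
        popt, pcov = curve_fit(
            lambda tt, i0, r: i0 * np.exp(-r * tt), t, y, p0=p0, maxfev=10000
        )
    except RuntimeError as exc:
        raise FitError(
            f"residue {series.residue_index}: decay fit did not converge "
            f"(delays {series.delays_ms.tolist()} ms)"
        ) from exc
    i0, rate = popt
    if rate <= 0 or i0 <= 0:
        raise FitError(
            f"residue {series.residue_index}: non-physical optimum "
            f"I0={i0:.3g}, R={rate:.3g} s^-1"
        )
    se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    return RateEstimate(
        residue_index=series.residue_index,
        rate=float(rate),
        se=se,
        i0=float(i0),
        field_mhz=series.field_mhz,
        rate_kind=series.rate_kind,
    )


def fit_rates(series_list) -> pd.DataFrame:
    """Fit a collection of decay series; one row per residue."""
    rows = [fit_rate(s) for s in series_list]
    return pd.DataFrame(
        [
            {
                "residue_index": r.residue_index,
                "rate": r.rate,
                "se": r.se,
                "i0": r.i0,
                "field_mhz": r.field_mhz,
                "rate_kind": r.rate_kind,
            }
            for r in rows
        ]
    )


def r2_over_r1(rates: pd.DataFrame) -> pd.DataFrame:
    """Per-residue R2/R1 with first-order propagated SE.

    ``rates`` is a frame as returned by :func:`fit_rates` containing both
    R1 and R2 entries at the same field.  Residues missing either partner
    are skipped.
    """
    out = []
    r1 = rates[rates["rate_kind"] == "R1"].set_index("residue_index")
    r2 = rates[rates["rate_kind"] == "R2"].set_index("residue_index")
    for idx in sorted(set(r1.index) & set(r2.index)):
        a, b = r2.loc[idx], r1.loc[idx]
        if a["field_mhz"] != b["field_mhz"]:
            continue
        ratio = a["rate"] / b["rate"]
        rel = math.hypot(a["se"] / a["rate"], b["se"] / b["rate"])
        out.append(
            {
                "residue_index": idx,
                "ratio": ratio,
                "se": abs(ratio) * rel,
                "field_mhz": a["field_mhz"],
            }
        )
    return pd.DataFrame(out, columns=["residue_index", "ratio", "se", "field_mhz"])


def noe_ratio(i_sat: float, i_ref: float) -> float:
    """O = I_sat / I_ref.  Values outside the attainable interval are the
    caller's to flag (see :func:`noe_attainable`); they indicate artifacts
    such as overlapped or vanishing reference peaks."""
    if i_ref == 0:
        raise ZeroDivisionError("reference intensity is zero")
    return i_sat / i_ref


def noe_attainable(noe: float) -> bool:
    """Whether a ratio lies in the open physical interval (~ -3.927, 0.782804)."""
    return NOE_MIN < noe < NOE_MAX


def noe_forward(tau_n_ns: float, field_mhz: float) -> float:
    """Dipolar-pair nOe ratio for correlation time tau_n (ns) at a 1H
    frequency (MHz).  Vectorized over tau_n."""
    tau = np.asarray(tau_n_ns, dtype=float)
    if (tau <= 0).any() or field_mhz <= 0:
        raise ValueError("tau_n and field must be positive")
    x2 = (field_mhz * 1e6 * tau * 1e-9) ** 2
    out = NOE_PLATEAU - (_A + _B * x2) / (_C + _D * x2 + x2**2)
    return float(out) if np.isscalar(tau_n_ns) else out


def noe_invert(noe: float, field_mhz: float, noe_se: float | None = None):
    """Apparent correlation time tau_n (ns) from an nOe ratio.

    Solves O(x) = noe for x = fH*tau_n by monotone bracketing on the physical
    branch (O is strictly increasing in x).  With ``noe_se`` given, returns
    ``(tau_n, tau_se)`` where the uncertainty is propagated through the local
    derivative of the forward map.
    """
    if field_mhz <= 0:
        raise ValueError("field must be positive")
    if not noe_attainable(noe):
        bound = "upper bound 0.782804" if noe >= NOE_MAX else f"lower bound {NOE_MIN:.4f}"
        raise ValueError(
            f"nOe ratio {noe:.4f} outside the attainable interval "
            f"({NOE_MIN:.4f}, {NOE_MAX:.6f}); violates {bound}"
        )
    fh = field_mhz * 1e6

    def g(x: float) -> float:
        x2 = x * x
        return NOE_PLATEAU - (_A + _B * x2) / (_C + _D * x2 + x2 * x2) - noe

    lo, hi = 1e-8, 1.0
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e8:  # pragma: no cover - unreachable inside attainable range
            raise RuntimeError("bracket expansion failed")
    x = brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    tau_ns = x / fh * 1e9
    if noe_se is None:
        return tau_ns
    # dO/dtau at the solution, by centered difference on the forward map
    h = max(tau_ns * 1e-6, 1e-9)
    slope = (noe_forward(tau_ns + h, field_mhz) - noe_forward(tau_ns - h, field_mhz)) / (2 * h)
    return tau_ns, abs(noe_se / slope)


def tau_profile(noe_table: pd.DataFrame) -> pd.DataFrame:
    """Invert a table of nOe measurements to per-residue tau_n (ns).

    ``noe_table`` columns: residue_index, i_sat, i_ref, field_mhz (or a
    precomputed ``noe`` column).  Rows outside the attainable interval are
    flagged and carry NaN tau_n rather than being silently clipped.
    """
    rows = []
    for row in noe_table.itertuples(index=False):
        noe = getattr(row, "noe", None)
        if noe is None or (isinstance(noe, float) and math.isnan(noe)):
            noe = noe_ratio(row.i_sat, row.i_ref)
        if noe_attainable(noe):
            tau = noe_invert(noe, row.field_mhz)
            flag = ""
        else:
            tau = float("nan")
            flag = "outside attainable nOe range"
        rows.append(
            {
                "residue_index": row.residue_index,
                "field_mhz": row.field_mhz,
                "noe": noe,
                "tau_n_ns": tau,
                "flag": flag,
            }
        )
    return pd.DataFrame(
        rows, columns=["residue_index", "field_mhz", "noe", "tau_n_ns", "flag"]
    )
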