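"""Fast-exchange transport-factor binding analysis from 15N R2 titrations.

A transport factor (e.g. the karyopherin Kap95) carries several hydrophobic
pockets that bind FG motifs transiently.  Because exchange between free and
bound FG repeats is much faster than the relevant NMR frequency differences,
every observed transverse rate is a population-weighted average,

    Robs = R0 (1 - f) + Rb f,

with R0 the free-state and Rb the bound-state R2 and f the bound fraction of
the observed protein.  With the observed FG protein at concentration L and
the transport factor at Tf (both uM), single-site-equivalent binding with
ligand depletion gives the quadratic solution

    f = [(Kd + L + Tf) - sqrt((Kd + L + Tf)^2 - 4 L Tf)] / (2 L),

evaluated here in the numerically stable conjugate form 2 Tf / (S + sqrt(...)).
Any exchange (Rex) contribution to Robs is neglected, which is justified in
the very-fast-exchange limit; the fitted Kd is therefore a lower bound on the
gross dissociation constant.  The gross Kd of a chain carrying n equivalent
motifs scales to a per-site constant Kd * n.

Fitting is two-stage: a coarse chi-square grid over (Kd, Rb) — whose single-
minimum structure is asserted, not assumed — followed by nonlinear
least-squares refinement from the grid minimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

TITRATION_COLUMNS = ["point_id", "L_uM", "Tf_uM", "group", "observable",
                     "observable_se"]


class NonIdentifiableError(RuntimeError):
    """Raised when the chi-square surface carries no binding information."""


@dataclass
class TitrationSeries:
    """Observables across (L, Tf) points, plus free-state (Tf = 0) rates.

    ``data`` columns: point_id, L_uM, Tf_uM, group, observable,
    observable_se (NaN allowed -> unweighted fit).  ``r0`` maps each group
    to its free-protein R2 measured without transport factor.
    """

    data: pd.DataFrame
    r0: dict[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in TITRATION_COLUMNS if c not in self.data.columns]
        if missing == ["observable_se"]:
            self.data = self.data.assign(observable_se=np.nan)
            missing = []
        if missing:
            raise ValueError(f"titration table missing columns: {missing}")
        if (self.data["L_uM"] < 0).any() or (self.data["Tf_uM"] < 0).any():
            raise ValueError("negative concentration")
        if not (self.data["Tf_uM"] > 0).any():
            raise ValueError("need at least one point with Tf > 0")
        counts = self.data.groupby("group")["point_id"].nunique()
        self.incomplete_groups = sorted(counts[counts < counts.max()].index)

    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    def track(self, group: str) -> pd.DataFrame:
        sub = self.data[self.data["group"] == group]
        if sub.empty:
            raise KeyError(f"no titration track for group {group!r}")
        return sub.sort_values("point_id").reset_index(drop=True)


def bound_fraction(kd_uM, L_uM, tf_uM):
    """Bound fraction of the observed protein under ligand depletion.

    Stable conjugate form f = 2 Tf / (S + sqrt(S^2 - 4 L Tf)), S = Kd+L+Tf;
    exact in the limits Kd=0 (stoichiometric) and Tf=0 (f=0).  Vectorized.
    """
    kd = np.asarray(kd_uM, dtype=float)
    L = np.asarray(L_uM, dtype=float)
    tf = np.asarray(tf_uM, dtype=float)
    if (kd < 0).any() or (L < 0).any() or (tf < 0).any():
        raise ValueError("concentrations and Kd must be non-negative")
    s = kd + L + tf
    disc = s * s - 4.0 * L * tf
    # disc >= (kd + |L - tf|)^2 >= 0 algebraically; clip rounding error only
    disc = np.maximum(disc, 0.0)
    denom = s + np.sqrt(disc)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, 2.0 * tf / np.where(denom > 0, denom, 1.0), 0.0)
    f = np.clip(f, 0.0, 1.0)
    return float(f) if np.isscalar(kd_uM) and np.isscalar(L_uM) and np.isscalar(tf_uM) else f


def r_obs(r0, rb, f):
    """Fast-exchange population average Robs = R0 (1-f) + Rb f."""
    f = np.asarray(f, dtype=float)
    if (f < -1e-12).any() or (f > 1 + 1e-12).any():
        raise ValueError("bound fraction outside [0, 1]")
    out = np.asarray(r0, dtype=float) * (1.0 - f) + np.asarray(rb, dtype=float) * f
    return float(out) if out.ndim == 0 else out


@dataclass
class BindingFit:
    """Estimated binding parameters for one titration track."""

    group: str
    kd_uM: float
    kd_se: float
    rb: float
    rb_se: float
    r0: float
    chi2: float
    n_points: int
    n_sites: int
    method: str = "grid+nonlinear"
    grid_kd: np.ndarray | None = field(default=None, repr=False)
    grid_rb: np.ndarray | None = field(default=None, repr=False)
    chi2_surface: np.ndarray | None = field(default=None, repr=False)
    n_profile_minima: int | None = None  # minima of the Rb-profiled chi2 along Kd

    @property
    def per_site_kd_uM(self) -> float:
        """Per-site constant: gross Kd scaled by the motif count, exactly."""
        return self.n_sites * self.kd_uM

    def summary(self) -> dict:
        return {
            "group": self.group,
            "Kd_uM": self.kd_uM,
            "Kd_se_uM": self.kd_se,
            "Rb_s-1": self.rb,
            "Rb_se_s-1": self.rb_se,
            "R0_s-1": self.r0,
            "chi2": self.chi2,
            "n_points": self.n_points,
            "n_sites": self.n_sites,
            "per_site_Kd_uM": self.per_site_kd_uM,
            "method": self.method,
        }


def grid_chi2_surface(
    L, tf, y, sigma, r0, kd_grid, rb_grid
) -> np.ndarray:
    """Chi-square over the (Kd, Rb) grid; shape (len(kd_grid), len(rb_grid))."""
    f = bound_fraction(kd_grid[:, None], L[None, :], tf[None, :])  # (K, P)
    model = r0 * (1.0 - f[:, None, :]) + rb_grid[None, :, None] * f[:, None, :]
    resid = (model - y[None, None, :]) / sigma[None, None, :]
    return (resid**2).sum(axis=2)


def count_grid_minima(surface: np.ndarray) -> int:
    """Strict interior local minima by 4-neighbor comparison."""
    s = surface
    interior = s[1:-1, 1:-1]
    is_min = (
        (interior < s[:-2, 1:-1])
        & (interior < s[2:, 1:-1])
        & (interior < s[1:-1, :-2])
        & (interior < s[1:-1, 2:])
    )
    return int(is_min.sum())


def profile_chi2_kd(L, tf, y, sigma, r0, kd_grid):
    """Chi-square profiled over Rb, per Kd grid point.

    Rb enters the fast-exchange model linearly, so for each Kd the optimal
    Rb is the exact weighted least-squares solution; the resulting
    one-dimensional profile is smooth and suitable for a neighbor-comparison
    unimodality assertion (the full discrete surface scallops along its
    curved valley).  Returns (chi2_profile, rb_hat) arrays over ``kd_grid``.
    """
    w = 1.0 / sigma**2
    f = bound_fraction(kd_grid[:, None], L[None, :], tf[None, :])  # (K, P)
    base = r0 * (1.0 - f)
    num = (w[None, :] * f * (y[None, :] - base)).sum(axis=1)
    den = (w[None, :] * f * f).sum(axis=1)
    rb_hat = np.divide(num, den, out=np.full_like(num, np.nan),
                       where=den > 0)
    resid = (base + rb_hat[:, None] * f - y[None, :]) * np.sqrt(w)[None, :]
    return (resid**2).sum(axis=1), rb_hat


def count_profile_minima(profile: np.ndarray) -> int:
    """Strict interior local minima of a 1-D chi-square profile."""
    p = profile[np.isfinite(profile)]
    interior = p[1:-1]
    return int(((interior < p[:-2]) & (interior < p[2:])).sum())


def fit_binding(
    series: TitrationSeries,
    group: str,
    n_sites: int = 1,
    kd_bounds: tuple[float, float] = (0.1, 1e4),
    rb_max_factor: float = 100.0,
    grid_size: int = 200,
    keep_surface: bool = True,
) -> BindingFit:
    """Estimate (Kd, Rb) for one titration track with fixed free-state R0.

    Stage 1 scans a log-spaced Kd grid x linear Rb grid in [R0, factor*R0]
    and records the chi-square surface; stage 2 refines from the grid
    minimum by nonlinear least squares.  SEs come from the fit covariance.
    Raises :class:`NonIdentifiableError` when the track carries no
    Tf-dependent signal (flat surface along Kd).
    """
    track = series.track(group)
    if group not in series.r0:
        raise KeyError(f"no free-state R0 for group {group!r}")
    r0 = float(series.r0[group])
    if len(track) < 3:
        raise NonIdentifiableError(f"group {group!r}: need >= 3 titration points")

    L = track["L_uM"].to_numpy(float)
    tf = track["Tf_uM"].to_numpy(float)
    y = track["observable"].to_numpy(float)
    sigma = track["observable_se"].to_numpy(float)
    if not np.isfinite(sigma).all() or (sigma <= 0).any():
        sigma = np.ones_like(y)  # unweighted fall-back

    kd_grid = np.geomspace(kd_bounds[0], kd_bounds[1], grid_size)
    rb_grid = np.linspace(r0, rb_max_factor * r0, grid_size)
    surface = grid_chi2_surface(L, tf, y, sigma, r0, kd_grid, rb_grid)
    ik, ir = np.unravel_index(np.argmin(surface), surface.shape)
    profile, _ = profile_chi2_kd(L, tf, y, sigma, r0, kd_grid)
    n_minima = count_profile_minima(profile)

    # identifiability: chi2 must actually vary along the Kd axis
    kd_profile = surface.min(axis=1)
    span = kd_profile.max() - kd_profile.min()
    scale = max(float(np.median(kd_profile)), 1e-12)
    if span / scale < 1e-6 or np.ptp(y) == 0:
        raise NonIdentifiableError(
            f"group {group!r}: chi-square surface flat along Kd "
            f"(relative span {span / scale:.2e}); observable carries no "
            "titration response"
        )

    def model(conc, kd, rb):
        Lc, tfc = conc
        return r_obs(r0, rb, bound_fraction(kd, Lc, tfc))

    try:
        popt, pcov = curve_fit(
            model,
            (L, tf),
            y,
            p0=(kd_grid[ik], rb_grid[ir]),
            sigma=sigma,
            absolute_sigma=True,
            bounds=([1e-6, r0], [1e7, 1e4]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise NonIdentifiableError(
            f"group {group!r}: nonlinear refinement failed from grid minimum "
            f"Kd={kd_grid[ik]:.3g} uM, Rb={rb_grid[ir]:.3g} s^-1"
        ) from exc
    kd, rb = (float(v) for v in popt)
    kd_se, rb_se = (float(np.sqrt(pcov[i, i])) for i in range(2))
    resid = (model((L, tf), kd, rb) - y) / sigma
    return BindingFit(
        group=group,
        kd_uM=kd,
        kd_se=kd_se,
        rb=rb,
        rb_se=rb_se,
        r0=r0,
        chi2=float((resid**2).sum()),
        n_points=len(y),
        n_sites=n_sites,
        grid_kd=kd_grid if keep_surface else None,
        grid_rb=rb_grid if keep_surface else None,
        chi2_surface=surface if keep_surface else None,
        n_profile_minima=n_minima,
    )


def fit_per_residue(
    series: TitrationSeries,
    groups: list[str] | None = None,
    n_sites: int = 1,
    **kwargs,
) -> dict[str, BindingFit]:
    """Independent (Kd, Rb) fit per residue-type group.

    Groups whose track is non-identifiable raise individually; callers that
    want partial results catch :class:`NonIdentifiableError` per group.
    """
    groups = groups if groups is not None else series.groups()
    return {g: fit_binding(series, g, n_sites=n_sites, **kwargs) for g in groups}


def attenuation_profile(
    bound: pd.DataFrame, free: pd.DataFrame
) -> pd.DataFrame:
    """Per-residue attenuation a = 1 - I/I0 on transport-factor addition.

    Input frames carry columns residue_index, intensity (and optionally
    intensity_se).  Residues with free intensity <= 0 are flagged and
    excluded; negative attenuations (intensity gain) are flagged but kept.
    """
    b = bound.set_index("residue_index")
    f = free.set_index("residue_index")
    common = sorted(set(b.index) & set(f.index))
    if set(b.index) != set(f.index):
        only = sorted(set(b.index) ^ set(f.index))
        raise ValueError(f"residue sets differ between spectra: {only}")
    rows = []
    for idx in common:
        i0 = float(f.loc[idx, "intensity"])
        i1 = float(b.loc[idx, "intensity"])
        if i0 <= 0:
            rows.append((idx, np.nan, np.nan, "non-positive free intensity"))
            continue
        a = 1.0 - i1 / i0
        se = np.nan
        if "intensity_se" in b.columns and "intensity_se" in f.columns:
            s1 = float(b.loc[idx, "intensity_se"])
            s0 = float(f.loc[idx, "intensity_se"])
            if np.isfinite(s1) and np.isfinite(s0):
                se = abs(i1 / i0) * math.hypot(s1 / i1 if i1 else 0.0, s0 / i0)
        rows.append((idx, a, se, "intensity gain" if a < 0 else ""))
    return pd.DataFrame(
        rows, columns=["residue_index", "attenuation", "se", "flag"]
    )


@dataclass
class ReversibilityReport:
    """Comparison of attenuation profiles reached by different mixing paths."""

    passed: bool
    max_deviation: float
    tolerance: float
    offending: list[int]

    def __str__(self) -> str:
        verdict = "reversible" if self.passed else "NOT reversible"
        return (
            f"{verdict}: max |delta attenuation| = {self.max_deviation:.4f} "
            f"(tolerance {self.tolerance}), offending residues "
            f"{self.offending or 'none'}"
        )


def reversibility_check(
    profile_direct: pd.DataFrame,
    profile_diluted: pd.DataFrame,
    tolerance: float = 0.05,
) -> ReversibilityReport:
    """Declare the complex reversible when per-residue attenuations agree.

    An equilibrium (fast-exchange) complex formed by direct admixture or by
    dilution from excess transport factor must give the same profile at
    matched final concentrations; an irreversible complex does not.
    """
    a = profile_direct.set_index("residue_index")["attenuation"]
    b = profile_diluted.set_index("residue_index")["attenuation"]
    if set(a.index) != set(b.index):
        raise ValueError("mismatched residue sets between profiles")
    dev = (a - b).abs().dropna()
    offending = sorted(int(i) for i in dev[dev > tolerance].index)
    max_dev = float(dev.max()) if len(dev) else 0.0
    return ReversibilityReport(
        passed=not offending,
        max_deviation=max_dev,
        tolerance=tolerance,
        offending=offending,
    )
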