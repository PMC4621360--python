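"""Synthetic-data generation for every input class the pipeline consumes.

Each simulator emulates the statistical structure the analyses assume for
disordered FG-repeat measurements:

* chemical shifts scattered tightly around the random-coil reference (flat
  delta-delta profile), with an optional injected helix/sheet segment for
  classifier testing;
* mono-exponential peak-height decays on the published CPMG delay grids;
* nOe ratios generated through the dipolar closed form from a tau_n profile
  (~0.9 ns in buffer, ~1.17 ns in cell) at several spectrometer fields;
* sequence-dependent R2 elevation centered on the Phe positions of FG/FSFG
  motifs (up to ~sixfold over the spacer baseline, the signature of
  transient interactions with a proteinaceous milieu);
* fast-exchange R2 titrations and attenuation profiles following the
  population-average binding model, with designated inert spacer residues
  (the K332 analogue) left untouched.

All randomness flows from one seeded generator per call; identical
configuration and seed give byte-identical serialized output.  Ground truth
is always returned (and written) alongside the data and is never consumed by
the analysis operations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import relaxation
from .constructs import ConstructSequence, find_motifs, get_construct
from .secondary_shifts import RandomCoilReference, SHIFT_COLUMNS, ShiftTable
from .titration import TitrationSeries, bound_fraction, r_obs

#: Published 15N R2 titration design: Kap95 fixed at 20 uM, observed FSFG-K
#: varied from 12.5 to 1200 uM (seven molar ratios).
TITRATION_DESIGN: tuple[tuple[float, float], ...] = (
    (12.5, 20.0),
    (20.0, 20.0),
    (80.0, 20.0),
    (140.0, 20.0),
    (220.0, 20.0),
    (575.0, 20.0),
    (1200.0, 20.0),
)

#: Published R2 delay grids (ms) per FSFG:Kap95 molar ratio.
DELAY_GRIDS_MS: dict[str, tuple[float, ...]] = {
    "short": (0.0, 32.64, 65.28, 97.92, 130.56, 163.2),  # 1:1 and 0.625:1
    "4:1": (0.0, 81.6, 163.2, 244.8, 326.4, 408.0),
    "7:1": (0.0, 81.6, 163.2, 244.8, 326.4, 489.6),
    "long": (0.0, 81.6, 163.2, 326.4, 489.6, 652.8),  # 60:1, 28.75:1, 11:1
    # free-protein multi-milieu survey grid (ten delays)
    "survey": (0.0, 32.64, 65.28, 97.92, 130.56, 163.20, 195.84, 228.48,
               261.12, 326.40),
}


def delay_grid_for_ratio(L_uM: float, tf_uM: float) -> tuple[float, ...]:
    """The published delay grid used at a given FSFG:Kap95 molar ratio."""
    ratio = L_uM / tf_uM
    if ratio <= 1.0:
        return DELAY_GRIDS_MS["short"]
    if ratio <= 4.0:
        return DELAY_GRIDS_MS["4:1"]
    if ratio <= 7.0:
        return DELAY_GRIDS_MS["7:1"]
    return DELAY_GRIDS_MS["long"]


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian noise magnitudes per observable class."""

    intensity_frac: float = 0.02  # fraction of I0, peak-height decays
    r2_sd: float = 0.3  # s^-1, on simulated Robs/R2 profiles
    noe_sd: float = 0.0  # on the nOe ratio directly
    shift_sd_frac: float = 0.2  # fraction of the reference SD, per nucleus

    def __post_init__(self) -> None:
        for name in ("intensity_frac", "r2_sd", "noe_sd", "shift_sd_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TruthParams:
    """Generating parameters; defaults are the study conditions.

    tau_n 0.9 ns (buffer) / 1.17 ns (in cell); gross Kd 36.1 uM with bound
    R2 25.5 s^-1 over six equivalent FSFG sites; per-motif-position Kd
    values 31/55/44/17 uM for the F/S/F/G positions; free-state R2 baseline
    4.0 s^-1 (typical for a disordered chain at these fields) with up to
    sixfold motif-centered elevation in interacting milieus.
    """

    tau_buffer_ns: float = 0.9
    tau_cell_ns: float = 1.17
    kd_uM: float = 36.1
    rb: float = 25.5
    r0: float = 4.0
    n_sites: int = 6
    group_kds_uM: tuple[tuple[str, float], ...] = (
        ("Fsfg", 31.0),
        ("fSfg", 55.0),
        ("fsFg", 44.0),
        ("fsfG", 17.0),
    )
    r2_baseline: float = 4.0
    r1_baseline: float = 1.4
    r2_fold: float = 6.0  # max/baseline R2 ratio at motif centers
    kernel_halfwidth: int = 2  # residues; interface is the FG +/- 2-4 shell
    attenuation_max: float = 0.9  # motif-center attenuation at saturation


@dataclass(frozen=True)
class SimulationConfig:
    """Seeded, fully serializable description of one synthetic data set."""

    seed: int = 0
    construct_id: str = "fsfg-k-his"
    motif: str = "FSFG"
    fields_mhz: tuple[float, ...] = (500.0, 800.0, 900.0)
    titration_design: tuple[tuple[float, float], ...] = TITRATION_DESIGN
    noise: NoiseModel = field(default_factory=NoiseModel)
    truth: TruthParams = field(default_factory=TruthParams)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def construct(self) -> ConstructSequence:
        return get_construct(self.construct_id)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def motif_kernel(
    construct: ConstructSequence | str,
    motif: str = "FSFG",
    halfwidth: int = 2,
) -> np.ndarray:
    """Triangular interaction kernel peaked (=1) at the Phe positions of each
    motif, decaying symmetrically to 0 beyond ``halfwidth`` residues."""
    seq = construct.sequence if isinstance(construct, ConstructSequence) else construct
    centers = []
    for m in find_motifs(seq, motif):
        for k, aa in enumerate(motif):
            if aa == "F":
                centers.append(m.start + k)
    if not centers and motif:  # motifs without F: use motif centers
        centers = [(m.start + m.end) // 2 for m in find_motifs(seq, motif)]
    kernel = np.zeros(len(seq))
    pos = np.arange(1, len(seq) + 1)
    for c in centers:
        kernel = np.maximum(
            kernel, np.clip(1.0 - np.abs(pos - c) / (halfwidth + 1.0), 0.0, 1.0)
        )
    return kernel


def pick_inert_spacer(
    construct: ConstructSequence, motif: str = "FSFG", residue_type: str = "K"
) -> int:
    """A spacer residue of the given type maximally distant from all motifs
    (the K332 analogue: a lysine that shows no attenuation)."""
    kernel = motif_kernel(construct, motif, halfwidth=4)
    best, best_key = None, None
    motifs = find_motifs(construct, motif)
    for i in range(1, len(construct.sequence) + 1):
        if construct.sequence[i - 1] != residue_type or kernel[i - 1] > 0:
            continue
        dist = min(abs(i - m.start) for m in motifs) if motifs else i
        if best is None or dist > best_key:
            best, best_key = i, dist
    if best is None:
        raise ValueError(f"no inert {residue_type!r} spacer found")
    return best


def simulate_decay(
    config: SimulationConfig,
    r_true: float,
    delays_ms=None,
    residue_index: int = 1,
    i0: float = 1.0,
    field_mhz: float = 500.0,
    rate_kind: str = "R2",
    rng: np.random.Generator | None = None,
) -> relaxation.DecaySeries:
    """I(t) = I0 exp(-R t) on a published delay grid, plus Gaussian noise."""
    rng = rng if rng is not None else config.rng()
    delays = np.asarray(
        DELAY_GRIDS_MS["short"] if delays_ms is None else delays_ms, dtype=float
    )
    clean = i0 * np.exp(-r_true * delays / 1000.0)
    noisy = clean + rng.normal(0.0, config.noise.intensity_frac * i0, delays.shape)
    return relaxation.DecaySeries(
        residue_index=residue_index,
        delays_ms=delays,
        intensities=noisy,
        field_mhz=field_mhz,
        rate_kind=rate_kind,
    )


def simulate_noe(
    config: SimulationConfig,
    tau_profile_ns,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Saturated/reference intensity pairs per residue per configured field.

    The underlying ratio comes from the dipolar closed form at each field;
    noise is applied to the ratio through the saturated intensity with
    I_ref = 1.
    """
    rng = rng if rng is not None else config.rng()
    tau = np.asarray(tau_profile_ns, dtype=float)
    rows = []
    for f in config.fields_mhz:
        noe = relaxation.noe_forward(tau, f)
        noe = noe + rng.normal(0.0, config.noise.noe_sd, tau.shape)
        for i, (t, o) in enumerate(zip(tau, np.atleast_1d(noe)), start=1):
            rows.append(
                {
                    "residue_index": i,
                    "i_sat": float(o),
                    "i_ref": 1.0,
                    "field_mhz": f,
                    "tau_true_ns": float(t),
                }
            )
    return pd.DataFrame(rows)


def simulate_sequence_r2(
    config: SimulationConfig,
    construct: ConstructSequence | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-residue R1/R2 profile with motif-centered R2 elevation.

    R2 = baseline * (1 + (fold - 1) * kernel): a fold of 6 gives the
    sixfold max/min variation seen in interacting milieus; a fold of 1
    gives the flat buffer-like profile.  R1 stays flat.
    """
    rng = rng if rng is not None else config.rng()
    construct = construct if construct is not None else config.construct()
    t = config.truth
    kernel = motif_kernel(construct, config.motif, t.kernel_halfwidth)
    r2 = t.r2_baseline * (1.0 + (t.r2_fold - 1.0) * kernel)
    n = len(kernel)
    r2_noisy = r2 + rng.normal(0.0, config.noise.r2_sd, n)
    r1 = np.full(n, t.r1_baseline) + rng.normal(
        0.0, config.noise.r2_sd * t.r1_baseline / t.r2_baseline, n
    )
    return pd.DataFrame(
        {
            "residue_index": np.arange(1, n + 1),
            "residue_type": list(construct.sequence),
            "r1": r1,
            "r2": r2_noisy,
            "r2_true": r2,
            "kernel": kernel,
        }
    )


def simulate_titration(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[TitrationSeries, dict]:
    """Fast-exchange R2 titration tracks plus the generating truth.

    Tracks: "FSFG" — the aggregate motif track generated with the gross
    (Kd, Rb); one track per motif position (Fsfg/fSfg/fsFg/fsfG) with its
    own Kd; and "spacer", Tf-independent (bound fraction identically 0).
    """
    rng = rng if rng is not None else config.rng()
    t = config.truth
    tracks: dict[str, float | None] = {"FSFG": t.kd_uM, "spacer": None}
    tracks.update(dict(t.group_kds_uM))

    rows = []
    for point_id, (L, tf) in enumerate(config.titration_design):
        for group, kd in tracks.items():
            f = 0.0 if kd is None else bound_fraction(kd, L, tf)
            clean = r_obs(t.r0, t.rb, f)
            rows.append(
                {
                    "point_id": point_id,
                    "L_uM": L,
                    "Tf_uM": tf,
                    "group": group,
                    "observable": clean + rng.normal(0.0, config.noise.r2_sd),
                    "observable_se": config.noise.r2_sd if config.noise.r2_sd > 0 else np.nan,
                }
            )
    series = TitrationSeries(
        data=pd.DataFrame(rows, columns=TITRATION_COLUMNS_ORDER),
        r0={g: t.r0 for g in tracks},
    )
    truth = {
        "kd_uM": {g: kd for g, kd in tracks.items() if kd is not None},
        "rb": t.rb,
        "r0": t.r0,
        "n_sites": t.n_sites,
        "design": list(map(list, config.titration_design)),
        "noise_r2_sd": config.noise.r2_sd,
    }
    return series, truth


TITRATION_COLUMNS_ORDER = ["point_id", "L_uM", "Tf_uM", "group", "observable",
                           "observable_se"]


def simulate_attenuation(
    config: SimulationConfig,
    tf_uM: float = 50.0,
    L_uM: float = 25.0,
    rng: np.random.Generator | None = None,
    irreversible: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired free/bound per-residue intensity tables.

    Attenuation is a symmetric motif-centered kernel scaled by the bound
    fraction at (L, Tf); the designated inert spacer (K332 analogue) sits at
    kernel 0 by construction.  With ``irreversible=True`` the bound table is
    the sum-of-endpoints pattern a non-equilibrium complex would give
    (attenuation at half the saturated amplitude everywhere on the motifs,
    regardless of concentrations) for reversibility-check testing.
    """
    rng = rng if rng is not None else config.rng()
    construct = config.construct()
    t = config.truth
    kernel = motif_kernel(construct, config.motif, t.kernel_halfwidth)
    f = bound_fraction(t.kd_uM, L_uM, tf_uM)
    amp = t.attenuation_max * (0.5 if irreversible else f)
    atten = amp * kernel
    n = len(kernel)
    free_i = np.ones(n)
    bound_i = 1.0 - atten
    sd = config.noise.intensity_frac
    free = pd.DataFrame(
        {
            "residue_index": np.arange(1, n + 1),
            "intensity": free_i + rng.normal(0.0, sd, n),
            "intensity_se": np.full(n, sd if sd > 0 else np.nan),
        }
    )
    bound = pd.DataFrame(
        {
            "residue_index": np.arange(1, n + 1),
            "intensity": bound_i + rng.normal(0.0, sd, n),
            "intensity_se": np.full(n, sd if sd > 0 else np.nan),
        }
    )
    truth = {
        "kd_uM": t.kd_uM,
        "L_uM": L_uM,
        "Tf_uM": tf_uM,
        "bound_fraction": f,
        "attenuation_true": atten.tolist(),
        "inert_spacer": pick_inert_spacer(construct, config.motif),
        "irreversible": irreversible,
    }
    return free, bound, truth


def simulate_shift_table(
    config: SimulationConfig,
    reference: RandomCoilReference,
    inject: tuple[int, int, float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> ShiftTable:
    """Observed CA/CB shifts = neighbor-corrected reference + scaled noise.

    ``inject=(start, end, dCA, dCB)`` adds a structured segment (e.g.
    +2/-2 ppm for helix) for classifier testing; noise sigma is
    ``shift_sd_frac`` times each reference SD, well below the SD itself for
    the null (disordered) simulation.
    """
    rng = rng if rng is not None else config.rng()
    seq = config.construct().sequence
    rows = []
    for i, aa in enumerate(seq, start=1):
        nxt = seq[i] if i < len(seq) else None
        for nucleus in ("CA", "CB"):
            mean, sd = reference.mean_sd(aa, nucleus, nxt)
            if not np.isfinite(mean):
                continue  # glycine CB
            shift = mean + rng.normal(0.0, config.noise.shift_sd_frac * sd)
            if inject is not None:
                start, end, dca, dcb = inject
                if start <= i <= end:
                    shift += dca if nucleus == "CA" else dcb
            rows.append(
                {
                    "residue_index": i,
                    "residue_type": aa,
                    "nucleus": nucleus,
                    "shift_ppm": shift,
                    "ambiguous": False,
                    "status": "observed",
                }
            )
    return ShiftTable(pd.DataFrame(rows, columns=SHIFT_COLUMNS))


def write_bundle(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Write a full synthetic input bundle in the pipeline's TSV dialects.

    Emits shifts.tsv, decay.tsv, noe.tsv, titration.tsv, r0.tsv,
    free_intensity.tsv, bound_intensity.tsv and truth.json; returns the path
    map.  Deterministic: one generator seeded from the config drives every
    file in a fixed order.
    """
    from pathlib import Path

    from . import io as fio
    from .secondary_shifts import load_random_coil

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    meta = {"seed": config.seed, "construct": config.construct_id}
    paths: dict[str, str] = {}
    truth_all: dict = {"seed": config.seed}

    # shifts (null, disordered)
    table = simulate_shift_table(config, load_random_coil(), rng=rng)
    fio.write_tsv(table.data, out / "shifts.tsv", meta)
    paths["shifts"] = str(out / "shifts.tsv")

    # decay series: R2 from the motif-elevation profile, flat R1
    prof = simulate_sequence_r2(config, rng=rng)
    rows = []
    for r in prof.itertuples(index=False):
        for kind, rate in (("R2", r.r2_true), ("R1", config.truth.r1_baseline)):
            d = simulate_decay(
                config, rate, DELAY_GRIDS_MS["survey"],
                residue_index=int(r.residue_index), rate_kind=kind, rng=rng,
            )
            for t, i in zip(d.delays_ms, d.intensities):
                rows.append(
                    {
                        "residue_index": d.residue_index,
                        "delay_ms": t,
                        "intensity": i,
                        "field_mhz": d.field_mhz,
                        "rate_kind": kind,
                    }
                )
    fio.write_tsv(pd.DataFrame(rows), out / "decay.tsv", meta)
    paths["decay"] = str(out / "decay.tsv")
    truth_all["r2_profile"] = prof["r2_true"].tolist()

    # nOe at every configured field from a flat buffer-like tau profile
    n = len(config.construct().sequence)
    noe = simulate_noe(config, np.full(n, config.truth.tau_buffer_ns), rng=rng)
    fio.write_tsv(
        noe[["residue_index", "i_sat", "i_ref", "field_mhz"]],
        out / "noe.tsv", meta,
    )
    paths["noe"] = str(out / "noe.tsv")
    truth_all["tau_n_ns"] = config.truth.tau_buffer_ns

    # titration + free-state rates
    series, truth_t = simulate_titration(config, rng=rng)
    fio.write_tsv(series.data, out / "titration.tsv", meta)
    r0df = pd.DataFrame(
        {"group": sorted(series.r0), "r0": [series.r0[g] for g in sorted(series.r0)]}
    )
    fio.write_tsv(r0df, out / "r0.tsv", meta)
    paths["titration"] = str(out / "titration.tsv")
    paths["r0"] = str(out / "r0.tsv")
    truth_all["titration"] = truth_t

    # attenuation pair
    free, bound, truth_a = simulate_attenuation(config, rng=rng)
    fio.write_tsv(free, out / "free_intensity.tsv", meta)
    fio.write_tsv(bound, out / "bound_intensity.tsv", meta)
    paths["free_intensity"] = str(out / "free_intensity.tsv")
    paths["bound_intensity"] = str(out / "bound_intensity.tsv")
    truth_all["attenuation"] = truth_a

    import json

    (out / "truth.json").write_text(
        json.dumps(truth_all, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    paths["truth"] = str(out / "truth.json")
    return paths
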