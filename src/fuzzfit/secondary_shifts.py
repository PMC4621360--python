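"""Secondary chemical-shift disorder profiling for IDPs.

The degree of residual secondary structure in a disordered chain is read out
from the difference of the Calpha and Cbeta deviations from random-coil
values,

    delta_delta = (dCA_obs - dCA_rc) - (dCB_obs - dCB_rc),

which is ~ +4 ppm inside alpha-helices, ~ -4 ppm inside beta-strands and ~ 0
for random coil.  The propagated standard error combines the dispersions of
the two random-coil reference values in quadrature.  A chain is called
disordered when the profile shows no run of consecutive same-sign deviations
exceeding their standard errors.

Assignments of repeat proteins are often incomplete because near-identical
repeats overlap; ``extend_assignments`` duplicates shifts from the assigned
position whose sequence neighborhood best matches each unassigned position,
mirroring standard practice for degenerate repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .constructs import ConstructSequence, STANDARD_AA

NUCLEI = ("CA", "CB", "C", "N", "H", "HA")

SHIFT_COLUMNS = ["residue_index", "residue_type", "nucleus", "shift_ppm",
                 "ambiguous", "status"]


@dataclass
class ShiftTable:
    """Observed per-residue chemical shifts.

    ``data`` columns: residue_index (1-based), residue_type (one-letter),
    nucleus, shift_ppm, ambiguous (bool), status ("observed" or "extended").
    At most one entry per (residue_index, nucleus).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SHIFT_COLUMNS if c not in self.data.columns]
        if "ambiguous" in missing:
            self.data = self.data.assign(ambiguous=False)
            missing.remove("ambiguous")
        if "status" in missing:
            self.data = self.data.assign(status="observed")
            missing.remove("status")
        if missing:
            raise ValueError(f"shift table missing columns: {missing}")
        dup = self.data.duplicated(subset=["residue_index", "nucleus"])
        if dup.any():
            where = self.data.loc[dup, ["residue_index", "nucleus"]]
            raise ValueError(
                f"duplicate shift entries:\n{where.to_string(index=False)}"
            )
        bad = set(self.data["nucleus"]) - set(NUCLEI)
        if bad:
            raise ValueError(f"unknown nuclei: {sorted(bad)}")
        self.data = self.data.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "ShiftTable":
        """Build from (residue_index, residue_type, nucleus, shift_ppm[, ambiguous]) tuples."""
        rows = []
        for rec in records:
            idx, aa, nuc, ppm, *rest = rec
            rows.append(
                {
                    "residue_index": int(idx),
                    "residue_type": aa,
                    "nucleus": nuc,
                    "shift_ppm": float(ppm),
                    "ambiguous": bool(rest[0]) if rest else False,
                    "status": "observed",
                }
            )
        return cls(pd.DataFrame(rows, columns=SHIFT_COLUMNS))

    def get(self, residue_index: int, nucleus: str) -> pd.Series | None:
        hit = self.data[
            (self.data["residue_index"] == residue_index)
            & (self.data["nucleus"] == nucleus)
        ]
        if hit.empty:
            return None
        return hit.iloc[0]

    def assigned_indices(self, nuclei=("CA", "CB")) -> set[int]:
        mask = self.data["nucleus"].isin(nuclei)
        return set(self.data.loc[mask, "residue_index"].astype(int))

    def check_against_sequence(self, construct: ConstructSequence) -> None:
        """Raise if any entry's residue type disagrees with the construct."""
        for row in self.data.itertuples(index=False):
            expected = construct.residue(int(row.residue_index))
            if row.residue_type != expected:
                raise ValueError(
                    f"residue {row.residue_index}: table says "
                    f"{row.residue_type!r}, sequence has {expected!r}"
                )


@dataclass
class RandomCoilReference:
    """Random-coil shift reference: per residue-type/nucleus mean and SD.

    ``pre_proline`` holds the dominant sequence correction: ppm added to the
    reference mean of a residue immediately preceding a proline.
    """

    name: str
    table: pd.DataFrame  # residue, nucleus, mean_ppm, sd_ppm
    pre_proline: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        covered = set(t.loc[t["mean_ppm"].notna(), "residue"])
        missing = STANDARD_AA - covered
        if missing:
            raise ValueError(f"reference {self.name!r} missing residues: "
                             f"{sorted(missing)}")
        sds = t.loc[t["sd_ppm"].notna(), "sd_ppm"]
        if (sds <= 0).any():
            raise ValueError(f"reference {self.name!r} has non-positive SDs")
        self._lookup = {
            (row.residue, row.nucleus): (row.mean_ppm, row.sd_ppm)
            for row in t.itertuples(index=False)
        }

    def mean_sd(
        self, residue_type: str, nucleus: str, next_residue: str | None = None,
        corrections: bool = True,
    ) -> tuple[float, float]:
        """Reference mean and SD; NaN mean marks a nucleus that does not exist
        (glycine Cbeta).  Raises for residue types absent from the table."""
        try:
            mean, sd = self._lookup[(residue_type, nucleus)]
        except KeyError:
            raise KeyError(
                f"reference {self.name!r} has no entry for residue "
                f"{residue_type!r} nucleus {nucleus!r}"
            ) from None
        if corrections and next_residue == "P":
            mean = mean + self.pre_proline.get(nucleus, 0.0)
        return mean, sd


#: ppm added to the random-coil mean of a residue followed by proline.
PRE_PROLINE_CORRECTION = {"CA": -1.85, "CB": 0.0}


def load_random_coil(name: str = "wishart1995", path=None) -> RandomCoilReference:
    """Load the packaged default reference, or a user table from ``path``.

    A user table must be TSV with columns residue, nucleus, mean_ppm, sd_ppm.
    """
    if path is None:
        path = resources.files("fuzzfit") / "data" / "random_coil.tsv"
    table = pd.read_csv(path, sep="\t", comment="#")
    return RandomCoilReference(name=name, table=table,
                               pre_proline=dict(PRE_PROLINE_CORRECTION))


@dataclass
class SecondaryShiftProfile:
    """Per-residue delta_delta = dd(CA) - dd(CB) with propagated SE.

    ``data`` columns: residue_index, residue_type, delta_delta, se, status
    (observed | extended | ambiguous | missing).  Glycine, which has no
    Cbeta, contributes its Calpha deviation alone.
    """

    data: pd.DataFrame
    reference_name: str = ""

    def defined(self) -> pd.DataFrame:
        return self.data[self.data["delta_delta"].notna()]


def secondary_shift(
    observed: ShiftTable,
    reference: RandomCoilReference,
    sequence: ConstructSequence | str | None = None,
    neighbor_corrections: bool = True,
) -> SecondaryShiftProfile:
    """Compute the disorder profile delta_delta = ddCA - ddCB per residue.

    With a sequence supplied the profile covers every position (unobserved
    ones as "missing") and pre-proline corrections can be applied; without
    one, only observed positions appear and corrections are off.
    """
    seq = sequence.sequence if isinstance(sequence, ConstructSequence) else sequence
    if seq is None:
        neighbor_corrections = False
        indices = sorted(observed.assigned_indices())
        types = {}
        for row in observed.data.itertuples(index=False):
            types[int(row.residue_index)] = row.residue_type
    else:
        indices = range(1, len(seq) + 1)
        types = {i: seq[i - 1] for i in indices}

    rows = []
    for i in indices:
        aa = types[i]
        nxt = seq[i] if (seq is not None and i < len(seq)) else None
        ca = observed.get(i, "CA")
        cb = observed.get(i, "CB")
        need_cb = aa != "G"
        if ca is None or (need_cb and cb is None):
            rows.append((i, aa, np.nan, np.nan, "missing"))
            continue
        status = str(ca["status"])
        if bool(ca["ambiguous"]) or (cb is not None and bool(cb["ambiguous"])):
            status = "ambiguous"
        elif cb is not None and str(cb["status"]) == "extended":
            status = "extended"
        rc_ca, sd_ca = reference.mean_sd(aa, "CA", nxt, neighbor_corrections)
        dd = float(ca["shift_ppm"]) - rc_ca
        var = sd_ca**2
        if need_cb:
            rc_cb, sd_cb = reference.mean_sd(aa, "CB", nxt, neighbor_corrections)
            dd -= float(cb["shift_ppm"]) - rc_cb
            var += sd_cb**2
        rows.append((i, aa, dd, float(np.sqrt(var)), status))

    df = pd.DataFrame(
        rows, columns=["residue_index", "residue_type", "delta_delta", "se",
                       "status"]
    )
    return SecondaryShiftProfile(df, reference_name=reference.name)


@dataclass(frozen=True)
class SignificantRun:
    start: int
    end: int
    sign: int

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class DisorderCall:
    """Result of the run-based disorder classification."""

    runs: list[SignificantRun]
    run_length: int
    per_residue: pd.DataFrame  # residue_index, significant, in_run

    @property
    def disordered(self) -> bool:
        return not self.runs


def classify_disorder(
    profile: SecondaryShiftProfile, run_length: int = 3
) -> DisorderCall:
    """Flag runs of >= run_length consecutive residues whose |delta_delta|
    exceeds its SE with consistent sign; the chain is disordered iff none
    exist.  Ambiguous and missing residues are excluded and break runs.
    """
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    d = profile.data.sort_values("residue_index")
    runs: list[SignificantRun] = []
    flags = []
    cur: list[int] = []
    cur_sign = 0

    def close() -> None:
        nonlocal cur, cur_sign
        if len(cur) >= run_length:
            runs.append(SignificantRun(cur[0], cur[-1], cur_sign))
        cur, cur_sign = [], 0

    prev_index = None
    for row in d.itertuples(index=False):
        i = int(row.residue_index)
        usable = row.status in ("observed", "extended") and np.isfinite(
            row.delta_delta
        )
        sig = bool(usable and abs(row.delta_delta) > row.se)
        flags.append((i, sig))
        contiguous = prev_index is not None and i == prev_index + 1
        prev_index = i
        if not sig or not contiguous and cur:
            close()
        if sig:
            sign = 1 if row.delta_delta > 0 else -1
            if cur and sign != cur_sign:
                close()
            if not cur:
                cur_sign = sign
            cur.append(i)
    close()

    per_residue = pd.DataFrame(flags, columns=["residue_index", "significant"])
    in_run = np.zeros(len(per_residue), dtype=bool)
    for r in runs:
        in_run |= per_residue["residue_index"].between(r.start, r.end).to_numpy()
    per_residue["in_run"] = in_run
    return DisorderCall(runs=runs, run_length=run_length, per_residue=per_residue)


def _window(seq: str, center: int, half: int) -> str:
    """Centered window, 1-based center; out-of-range padded with '-'."""
    chars = []
    for i in range(center - half, center + half + 1):
        chars.append(seq[i - 1] if 1 <= i <= len(seq) else "-")
    return "".join(chars)


def extend_assignments(
    observed: ShiftTable,
    construct: ConstructSequence | str,
    window: int = 9,
) -> ShiftTable:
    """Duplicate CA/CB shifts of assigned residues onto unassigned positions
    of the same residue type whose centered sequence window is most similar.

    Similarity is positionwise identity over the window; ties break first by
    smallest residue-index distance, then by lowest donor index.  Extended
    entries never overwrite observed ones.  Positions with no same-type
    assigned donor are left missing.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    seq = construct.sequence if isinstance(construct, ConstructSequence) else construct

    assigned = observed.assigned_indices(("CA", "CB"))
    donors_by_type: dict[str, list[int]] = {}
    for j in sorted(assigned):
        donors_by_type.setdefault(seq[j - 1], []).append(j)

    new_rows = []
    for i in range(1, len(seq) + 1):
        if i in assigned:
            continue
        candidates = donors_by_type.get(seq[i - 1], [])
        if not candidates:
            continue
        wi = _window(seq, i, half)
        best = min(
            candidates,
            key=lambda j: (
                -sum(a == b for a, b in zip(wi, _window(seq, j, half))),
                abs(i - j),
                j,
            ),
        )
        for nucleus in ("CA", "CB"):
            entry = observed.get(best, nucleus)
            if entry is None:
                continue
            new_rows.append(
                {
                    "residue_index": i,
                    "residue_type": seq[i - 1],
                    "nucleus": nucleus,
                    "shift_ppm": float(entry["shift_ppm"]),
                    "ambiguous": bool(entry["ambiguous"]),
                    "status": "extended",
                }
            )
    if not new_rows:
        return ShiftTable(observed.data.copy())
    extended = pd.concat(
        [observed.data, pd.DataFrame(new_rows, columns=SHIFT_COLUMNS)],
        ignore_index=True,
    )
    return ShiftTable(extended)
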