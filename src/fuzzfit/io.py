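"""File formats: TSV dialects, minimal NMR-STAR v3 chemical-shift loops,
and run configuration.

TSV dialect: UTF-8, tab-separated, '#' comment lines, mandatory header row.
Readers type- and unit-check the documented columns and preserve unknown
columns; writers emit exactly what the readers consume, plus '#' metadata
headers (seed, config hash) that round-trip as comments.

The NMR-STAR reader handles exactly what chemical-shift depositions need: it
locates the ``_Atom_chem_shift`` loop of a v3 document and extracts residue
index, residue type (three-letter), atom name and shift value, ignoring all
other saveframes and loops.  (Written here because no general NMR-STAR
parser is part of this package's dependency set; the subset of the grammar
involved — one loop, whitespace-separated tokens, quoted strings — is small
and fully covered by round-trip tests.)
"""

from __future__ import annotations

import hashlib
import json
import shlex
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .relaxation import DecaySeries
from .secondary_shifts import SHIFT_COLUMNS, ShiftTable
from .titration import TITRATION_COLUMNS, TitrationSeries

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

_DIALECTS = {
    "shifts": ["residue_index", "residue_type", "nucleus", "shift_ppm"],
    "decay": ["residue_index", "delay_ms", "intensity", "field_mhz",
              "rate_kind"],
    "noe": ["residue_index", "i_sat", "i_ref", "field_mhz"],
    "titration": TITRATION_COLUMNS[:5],  # observable_se optional
    "intensity": ["residue_index", "intensity"],
    "r0": ["group", "r0"],
}


def _read_tsv(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = _DIALECTS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing mandatory column(s) {missing} for kind {kind!r}"
        )
    return df


def write_tsv(df: pd.DataFrame, path, header_meta: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (header_meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n",
                  float_format="%.10g")


def read_peak_tsv(path, kind: str):
    """Read one of the documented TSV dialects into its typed container.

    kinds: shifts -> ShiftTable; decay -> list[DecaySeries]; noe/intensity ->
    DataFrame; titration -> DataFrame (combine with an r0 file via
    :func:`read_titration`).
    """
    if kind not in _DIALECTS:
        raise ValueError(f"unknown kind {kind!r}; choose from {sorted(_DIALECTS)}")
    df = _read_tsv(path, kind)
    if kind == "shifts":
        if "ambiguous" not in df.columns:
            df["ambiguous"] = False
        if "status" not in df.columns:
            df["status"] = "observed"
        dup = df.duplicated(subset=["residue_index", "nucleus"])
        if dup.any():
            raise ValueError(f"{path}: duplicate (residue_index, nucleus) keys")
        return ShiftTable(df[SHIFT_COLUMNS].copy())
    if kind == "decay":
        out = []
        for (res, fld, rk), sub in df.groupby(
            ["residue_index", "field_mhz", "rate_kind"], sort=True
        ):
            out.append(
                DecaySeries(
                    residue_index=int(res),
                    delays_ms=sub["delay_ms"].to_numpy(float),
                    intensities=sub["intensity"].to_numpy(float),
                    field_mhz=float(fld),
                    rate_kind=str(rk),
                )
            )
        return out
    return df


def read_titration(points_path, r0_path) -> TitrationSeries:
    """Assemble a TitrationSeries from a points file and a free-state file."""
    points = _read_tsv(points_path, "titration")
    if "observable_se" not in points.columns:
        points["observable_se"] = np.nan
    r0 = _read_tsv(r0_path, "r0")
    return TitrationSeries(
        data=points, r0=dict(zip(r0["group"], r0["r0"].astype(float)))
    )


# ---------------------------------------------------------------------------
# NMR-STAR v3 chemical-shift loop (read/write)

_STAR_TAGS = [
    "_Atom_chem_shift.ID",
    "_Atom_chem_shift.Seq_ID",
    "_Atom_chem_shift.Comp_ID",
    "_Atom_chem_shift.Atom_ID",
    "_Atom_chem_shift.Val",
]


def read_shift_star(path) -> ShiftTable:
    """Parse the atom chemical-shift loop of an NMR-STAR v3 document.

    Maps backbone nuclei (CA, CB, C, N, H, HA); other atoms and all
    unrelated loops/saveframes are ignored.  Raises with line context on a
    malformed loop.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        if lines[i].strip() == "loop_":
            tags = []
            j = i + 1
            while j < len(lines) and lines[j].strip().startswith("_"):
                tags.append(lines[j].strip())
                j += 1
            if any(t.startswith("_Atom_chem_shift.") for t in tags):
                return _parse_shift_loop(lines, tags, j)
        i += 1
    raise ValueError(f"{path}: no _Atom_chem_shift loop found")


def _parse_shift_loop(lines, tags, start) -> ShiftTable:
    def col(name: str) -> int:
        full = f"_Atom_chem_shift.{name}"
        try:
            return tags.index(full)
        except ValueError:
            raise ValueError(f"shift loop lacks required tag {full}") from None

    idx_seq, idx_comp, idx_atom, idx_val = (
        col("Seq_ID"), col("Comp_ID"), col("Atom_ID"), col("Val")
    )
    rows = []
    for ln, line in enumerate(lines[start:], start=start + 1):
        stripped = line.strip()
        if stripped in ("stop_",):
            break
        if not stripped or stripped.startswith("#"):
            continue
        tokens = shlex.split(stripped)
        if len(tokens) != len(tags):
            raise ValueError(
                f"line {ln}: expected {len(tags)} values, got {len(tokens)}: "
                f"{stripped!r}"
            )
        atom = tokens[idx_atom].upper()
        if atom not in ("CA", "CB", "C", "N", "H", "HA"):
            continue
        comp = tokens[idx_comp].upper()
        aa = THREE_TO_ONE.get(comp, comp if len(comp) == 1 else None)
        if aa is None:
            raise ValueError(f"line {ln}: unknown residue {tokens[idx_comp]!r}")
        try:
            rows.append(
                {
                    "residue_index": int(tokens[idx_seq]),
                    "residue_type": aa,
                    "nucleus": atom,
                    "shift_ppm": float(tokens[idx_val]),
                    "ambiguous": False,
                    "status": "observed",
                }
            )
        except ValueError as exc:
            raise ValueError(f"line {ln}: {exc}: {stripped!r}") from None
    return ShiftTable(pd.DataFrame(rows, columns=SHIFT_COLUMNS))


def write_shift_star(table: ShiftTable, path, entry_id: str = "synthetic") -> None:
    """Write a minimal NMR-STAR v3 document holding one chemical-shift loop."""
    out = [
        f"data_{entry_id}",
        "",
        "save_assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_category   assigned_chemical_shifts",
        "",
        "   loop_",
    ]
    out += [f"      {t}" for t in _STAR_TAGS]
    out.append("")
    for n, row in enumerate(
        table.data.sort_values(["residue_index", "nucleus"]).itertuples(index=False),
        start=1,
    ):
        three = ONE_TO_THREE[row.residue_type]
        out.append(
            f"      {n} {int(row.residue_index)} {three} {row.nucleus} "
            f"{row.shift_ppm:.3f}"
        )
    out += ["   stop_", "save_", ""]
    Path(path).write_text("\n".join(out), encoding="utf-8")


# ---------------------------------------------------------------------------
# Run configuration

@dataclass
class RunConfig:
    """Configuration of one pipeline run; fully serializable, embedded in
    outputs together with its hash so equal configs give equal results."""

    out_dir: str
    seed: int = 0
    construct_id: str = "fsfg-k-his"
    reference: str = "wishart1995"
    shifts_path: str | None = None
    extend: bool = True
    run_length: int = 3
    decay_path: str | None = None
    noe_path: str | None = None
    titration_path: str | None = None
    r0_path: str | None = None
    n_sites: int = 6
    kd_bounds: tuple[float, float] = (0.1, 1e4)
    per_group: bool = True
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses_asdict(self)
        d["kd_bounds"] = list(d["kd_bounds"])
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def dataclasses_asdict(obj) -> dict:
    import dataclasses

    return dataclasses.asdict(obj)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "kd_bounds" in data:
        data["kd_bounds"] = tuple(data["kd_bounds"])
    return RunConfig(**data)
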