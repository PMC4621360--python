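"""Registry and sequence arithmetic for FG-repeat nucleoporin constructs.

The constructs studied here are fragments of the yeast nucleoporin Nsp1 —
the Asn-rich N-terminal FG region ("FG-N", Nsp1 48-172) and the charged,
regularly spaced FSFG region ("FSFG-K", Nsp1 274-397 or 284-397) — alone and
as fusions, optionally tetramerized through the p53 tetramerization domain to
mimic attachment and crowding inside the nuclear pore.

Coordinates are 1-based inclusive throughout, matching NMR assignment
convention.  Each construct carries labeled regions; regions derived from
Nsp1 carry a reference start so that local indices can be reported in Nsp1
numbering (e.g. the well-resolved spacer lysine K332).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Mass of one water molecule (Da), added once per free peptide chain.
WATER_MASS = 18.0153

NON_REFERENCE = "non-reference"


def _data_path(name: str):
    return resources.files("fuzzfit") / "data" / name


def load_average_masses() -> dict[str, float]:
    """Average residue masses (Da) for the 20 standard amino acids."""
    df = pd.read_csv(_data_path("average_masses.tsv"), sep="\t", comment="#")
    return dict(zip(df["residue"], df["mass_da"]))


_AVERAGE_MASSES: dict[str, float] | None = None


def _masses() -> dict[str, float]:
    global _AVERAGE_MASSES
    if _AVERAGE_MASSES is None:
        _AVERAGE_MASSES = load_average_masses()
    return _AVERAGE_MASSES


@dataclass(frozen=True)
class Region:
    """A labeled interval of a construct, 1-based inclusive.

    ``ref_start`` is the Nsp1 residue number of the first residue of the
    region, for regions lifted from the Nsp1 sequence; tag/linker regions
    have no reference numbering.
    """

    label: str
    start: int
    end: int
    ref_start: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"region {self.label!r}: invalid span {self.start}-{self.end}"
            )

    def __contains__(self, local_index: int) -> bool:
        return self.start <= local_index <= self.end


@dataclass(frozen=True)
class MotifAnnotation:
    """An exact motif occurrence; slicing the sequence reproduces the motif."""

    motif_type: str
    start: int
    end: int


@dataclass(frozen=True)
class ConstructSequence:
    """One registered construct: sequence, oligomer count and region map."""

    id: str
    sequence: str
    n_chains: int = 1
    regions: tuple[Region, ...] = ()
    stated_residues: int | None = None
    stated_mass_da: float | None = None

    def __post_init__(self) -> None:
        for pos, aa in enumerate(self.sequence, start=1):
            if aa not in STANDARD_AA:
                raise ValueError(
                    f"construct {self.id!r}: unknown residue code {aa!r} "
                    f"at position {pos}"
                )
        if self.n_chains < 1:
            raise ValueError(f"construct {self.id!r}: n_chains must be >= 1")
        n = len(self.sequence)
        ordered = sorted(self.regions, key=lambda r: r.start)
        for r in ordered:
            if r.end > n:
                raise ValueError(
                    f"construct {self.id!r}: region {r.label!r} exceeds "
                    f"sequence length {n}"
                )
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"construct {self.id!r}: regions {a.label!r} and "
                    f"{b.label!r} overlap"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, local_index: int) -> str:
        if not 1 <= local_index <= len(self.sequence):
            raise IndexError(
                f"position {local_index} outside 1..{len(self.sequence)}"
            )
        return self.sequence[local_index - 1]


def count_residues(construct: ConstructSequence) -> int:
    """Number of residues in one monomer chain."""
    return len(construct.sequence)


def average_mass(construct: ConstructSequence | str) -> float:
    """Average mass (Da) of one monomer chain: residue masses plus one water.

    Raises ``ValueError`` naming the offending position for unknown codes.
    """
    seq = construct.sequence if isinstance(construct, ConstructSequence) else construct
    if not seq:
        return 0.0
    masses = _masses()
    total = WATER_MASS
    for pos, aa in enumerate(seq, start=1):
        try:
            total += masses[aa]
        except KeyError:
            raise ValueError(
                f"unknown residue code {aa!r} at position {pos}"
            ) from None
    return total


def assembled_mass(construct: ConstructSequence) -> float:
    """Mass (kDa) of the assembled oligomer: n_chains x monomer mass."""
    return construct.n_chains * average_mass(construct) / 1000.0


def find_motifs(
    construct: ConstructSequence | str, pattern: str
) -> list[MotifAnnotation]:
    """All (possibly overlapping) exact occurrences of ``pattern``, 1-based.

    Overlaps are reported; downstream per-site scaling should count
    non-overlapping canonical motifs (for the FSFG-K repeat region the six
    FSFG motifs do not overlap, so the distinction is moot there).
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    seq = construct.sequence if isinstance(construct, ConstructSequence) else construct
    out = []
    for m in re.finditer(f"(?={re.escape(pattern)})", seq):
        start = m.start() + 1
        out.append(MotifAnnotation(pattern, start, start + len(pattern) - 1))
    return out


def map_to_reference(construct: ConstructSequence, local_index: int) -> int | str:
    """Map a local 1-based index to Nsp1 reference numbering.

    Residues inside a region that carries ``ref_start`` map to
    ``ref_start + (local_index - region.start)``; residues in tag/linker
    regions (or outside any region) return the ``NON_REFERENCE`` label.
    """
    if not 1 <= local_index <= len(construct.sequence):
        raise IndexError(
            f"position {local_index} outside 1..{len(construct.sequence)}"
        )
    for region in construct.regions:
        if local_index in region:
            if region.ref_start is None:
                return NON_REFERENCE
            return region.ref_start + (local_index - region.start)
    return NON_REFERENCE


def _parse_regions(spec: str) -> tuple[Region, ...]:
    regions = []
    for chunk in filter(None, spec.split(";")):
        label, span = chunk.split(":")
        ref_start = None
        if "@" in span:
            span, ref = span.split("@")
            ref_start = int(ref)
        start, end = (int(x) for x in span.split("-"))
        regions.append(Region(label, start, end, ref_start))
    return tuple(regions)


def load_registry() -> dict[str, ConstructSequence]:
    """Load the packaged construct registry (sequences verbatim as published)."""
    df = pd.read_csv(_data_path("constructs.tsv"), sep="\t", comment="#")
    registry: dict[str, ConstructSequence] = {}
    for row in df.itertuples(index=False):
        registry[row.id] = ConstructSequence(
            id=row.id,
            sequence=row.sequence,
            n_chains=int(row.n_chains),
            regions=_parse_regions(row.regions),
            stated_residues=int(row.stated_residues),
            stated_mass_da=float(row.stated_mass_da),
        )
    return registry


def get_construct(construct_id: str) -> ConstructSequence:
    registry = load_registry()
    try:
        return registry[construct_id]
    except KeyError:
        raise KeyError(
            f"unknown construct {construct_id!r}; known: {sorted(registry)}"
        ) from None


def validate_registry(
    registry: dict[str, ConstructSequence] | None = None,
) -> pd.DataFrame:
    """Check each registry row against its stated residue count and mass.

    Rows where the printed sequence disagrees with the stated numbers are
    flagged, never silently corrected: the registry is a verbatim record of
    the published table, typos included.
    """
    registry = registry if registry is not None else load_registry()
    records = []
    for c in registry.values():
        mass = average_mass(c)
        count_ok = c.stated_residues is None or len(c) == c.stated_residues
        mass_ok = c.stated_mass_da is None or abs(mass - c.stated_mass_da) <= 1.0
        records.append(
            {
                "id": c.id,
                "n_residues": len(c),
                "stated_residues": c.stated_residues,
                "mass_da": round(mass, 1),
                "stated_mass_da": c.stated_mass_da,
                "count_consistent": count_ok,
                "mass_consistent": mass_ok,
                "flag": "" if count_ok and mass_ok else "printed sequence "
                "disagrees with stated residue count and/or mass",
            }
        )
    return pd.DataFrame.from_records(records)
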