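"""Core domain types shared across the pipeline.

All residue positions are 1-based native (canonical-sequence) coordinates;
alignment columns are 1-based; intervals are closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
VALID_AA = STANDARD_AA | {"X"}
GAP = "-"

SIGNIFICANCE_CLASSES = {
    "pathogenic",
    "likely_pathogenic",
    "benign",
    "likely_benign",
    "other",
}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class ProteinEntry:
    """One canonical protein sequence belonging to a family."""

    uid: str
    sequence: str
    family_id: str
    organism: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.uid}: empty sequence")
        bad = set(self.sequence) - VALID_AA
        if bad:
            raise ValueError(f"{self.uid}: non-standard residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FamilyAlignment:
    """A family multiple sequence alignment (gapped rows, '-' gaps).

    Invariant: every row has the same length and ungapping a row yields the
    member's canonical sequence.
    """

    family_id: str
    members: list[tuple[str, str]]  # (uid, gapped sequence), file order

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise FormatError(
                f"family {self.family_id}: alignments need >= 2 members"
            )
        lengths = {len(row) for _, row in self.members}
        if len(lengths) != 1:
            raise FormatError(
                f"family {self.family_id}: unequal alignment row lengths {sorted(lengths)}"
            )
        self._col_of: dict[str, dict[int, int]] = {}

    @property
    def n_columns(self) -> int:
        return len(self.members[0][1])

    @property
    def uids(self) -> list[str]:
        return [uid for uid, _ in self.members]

    def row(self, uid: str) -> str:
        for u, r in self.members:
            if u == uid:
                return r
        raise KeyError(uid)

    def ungapped(self, uid: str) -> str:
        return self.row(uid).replace(GAP, "")

    def column_of(self, uid: str, native_position: int) -> int:
        """1-based alignment column where a member's native position lands."""
        if uid not in self._col_of:
            table: dict[int, int] = {}
            pos = 0
            for col, ch in enumerate(self.row(uid), start=1):
                if ch != GAP:
                    pos += 1
                    table[pos] = col
            self._col_of[uid] = table
        return self._col_of[uid][native_position]

    def column_residues(self, column: int) -> list[str]:
        """Residues (or gaps) of every member at a 1-based column."""
        return [row[column - 1] for _, row in self.members]

    def validate_against(self, entries: dict[str, ProteinEntry]) -> None:
        for uid, row in self.members:
            if uid in entries and row.replace(GAP, "") != entries[uid].sequence:
                raise FormatError(
                    f"family {self.family_id}: ungapped row for {uid} "
                    "does not match canonical sequence"
                )


@dataclass(frozen=True)
class PTMObservation:
    """One experimentally observed PTM on one protein residue."""

    uid: str
    native_position: int
    residue: str
    ptm_type: str
    known_function: bool = False
    source_count: int = 0

    def __post_init__(self) -> None:
        if self.native_position < 1:
            raise ValueError("native_position is 1-based and must be >= 1")
        if not self.known_function and self.source_count != 0:
            # source counts only attach to known-function observations
            object.__setattr__(self, "source_count", 0)
        if self.source_count < 0:
            raise ValueError("source_count must be non-negative")


class Atom(NamedTuple):
    res_index: int  # author residue number within the chain
    name: str  # e.g. CA, CB
    element: str  # e.g. C, N, O, S
    x: float
    y: float
    z: float


@dataclass
class StructureChain:
    """One x-ray chain: atoms plus the resolved-residue one-letter sequence.

    ``residue_map`` (resolved residue index -> canonical native position) is
    filled by :func:`ptmfp.io.map_resolved_to_canonical`; it stays ``None``
    for chains that fail the noncanonical-sequence filter.
    """

    structure_id: str
    chain_id: str
    atoms: list[Atom]
    residues: list[tuple[int, str]]  # (res_index, one-letter aa), ordered
    residue_map: dict[int, int] | None = None
    rejection_reason: str | None = None

    @property
    def resolved_residue_count(self) -> int:
        return len(self.residues)

    @property
    def resolved_sequence(self) -> str:
        return "".join(aa for _, aa in self.residues)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]


@dataclass
class DisorderTrack:
    """Per-residue intrinsic-disorder tendencies in [0, 1].

    Values > 0.5 indicate structural disorder.
    """

    uid: str
    tendencies: list[float]

    def __post_init__(self) -> None:
        for v in self.tendencies:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{self.uid}: disorder tendency {v} outside [0,1]")

    def __getitem__(self, native_position: int) -> float:
        return self.tendencies[native_position - 1]


@dataclass(frozen=True)
class VariantRecord:
    """One missense substitution with a clinical-significance class."""

    uid: str
    native_position: int
    ref_aa: str
    alt_aa: str
    significance: str

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref_aa and alt_aa must differ")
        if self.significance not in SIGNIFICANCE_CLASSES:
            raise ValueError(f"unknown significance {self.significance!r}")
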