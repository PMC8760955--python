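"""Domain model for IMGT-numbered antibody variable-domain sequences.

Provides the position/region machinery (IMGT positions 1-128 with insertion
codes, FR/CDR assignment), the :class:`NumberedSequence` record, quality
filtering, fixed-length one-hot encoding for classifiers, and CSV/FASTA I/O.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from functools import total_ordering
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "ALPHABET",
    "Chain",
    "Region",
    "ImgtPosition",
    "NumberedSequence",
    "FilterReport",
    "assign_region",
    "is_framework",
    "framework_positions",
    "cdr_positions",
    "quality_filter",
    "encode",
    "decode",
    "default_universe",
    "read_numbered_csv",
    "write_numbered_csv",
    "read_fasta",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP  # 21 states per position

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


class Chain(str, Enum):
    """Antibody variable-domain chain class."""

    HEAVY = "heavy"
    KAPPA = "kappa"
    LAMBDA = "lambda"

    @property
    def is_light(self) -> bool:
        return self is not Chain.HEAVY


class Region(str, Enum):
    FR1 = "FR1"
    CDR1 = "CDR1"
    FR2 = "FR2"
    CDR2 = "CDR2"
    FR3 = "FR3"
    CDR3 = "CDR3"
    FR4 = "FR4"

    @property
    def is_framework(self) -> bool:
        return self.value.startswith("FR")


# IMGT unique-numbering region boundaries (inclusive), identical for all chains.
REGION_BOUNDS: dict[Region, tuple[int, int]] = {
    Region.FR1: (1, 26),
    Region.CDR1: (27, 38),
    Region.FR2: (39, 55),
    Region.CDR2: (56, 65),
    Region.FR3: (66, 104),
    Region.CDR3: (105, 117),
    Region.FR4: (118, 128),
}

_POSITION_RE = re.compile(r"^(\d{1,3})([A-Z]?)$")


@total_ordering
@dataclass(frozen=True)
class ImgtPosition:
    """A position code in the IMGT unique numbering (1-128, optional insertion).

    Ordering follows the IMGT scheme: insertion codes at a position sort
    after that integer position (111 < 111A < 111B), except at position 112
    where CDR3 insertions count inward and therefore sort in reverse,
    *before* the plain position (111B < 112B < 112A < 112).
    """

    number: int
    insertion: Optional[str] = None

    def __post_init__(self) -> None:
        if not 1 <= self.number <= 128:
            raise ValueError(f"IMGT position number out of range [1,128]: {self.number}")
        if self.insertion is not None and (
            len(self.insertion) != 1 or not self.insertion.isalpha() or not self.insertion.isupper()
        ):
            raise ValueError(f"invalid insertion code: {self.insertion!r}")

    @classmethod
    def parse(cls, code: str) -> "ImgtPosition":
        m = _POSITION_RE.match(str(code).strip())
        if not m:
            raise ValueError(f"malformed IMGT position code: {code!r}")
        return cls(int(m.group(1)), m.group(2) or None)

    def sort_key(self) -> tuple[int, int, int]:
        if self.insertion is None:
            return (self.number, 0, 0)
        if self.number == 112:  # inward-counting CDR3 insertions
            return (self.number, -1, -ord(self.insertion))
        return (self.number, 1, ord(self.insertion))

    def __lt__(self, other: "ImgtPosition") -> bool:
        if not isinstance(other, ImgtPosition):
            return NotImplemented
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        return f"{self.number}{self.insertion or ''}"


def assign_region(pos: ImgtPosition) -> Region:
    """Map an IMGT position to its FR/CDR region."""
    if not isinstance(pos, ImgtPosition):
        pos = ImgtPosition.parse(pos)
    for region, (lo, hi) in REGION_BOUNDS.items():
        if lo <= pos.number <= hi:
            return region
    raise ValueError(f"position outside IMGT range: {pos}")


def is_framework(pos: ImgtPosition) -> bool:
    return assign_region(pos).is_framework


@dataclass(frozen=True)
class NumberedSequence:
    """An IMGT-numbered variable-domain sequence.

    ``residues`` maps each occupied :class:`ImgtPosition` to one of the 20
    standard amino acids; iteration order is IMGT order regardless of the
    order the mapping was built in.
    """

    id: str
    chain: Chain
    residues: Mapping[ImgtPosition, str]
    species: Optional[str] = None
    v_gene: Optional[str] = None
    source: Optional[str] = None
    _positions: tuple[ImgtPosition, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        ordered = dict(sorted(self.residues.items(), key=lambda kv: kv[0].sort_key()))
        for pos, aa in ordered.items():
            if aa not in _AA_INDEX or aa == GAP:
                raise ValueError(
                    f"sequence {self.id!r}: residue {aa!r} at {pos} is not a standard amino acid"
                )
        object.__setattr__(self, "residues", ordered)
        object.__setattr__(self, "_positions", tuple(ordered))
        object.__setattr__(self, "chain", Chain(self.chain))

    @property
    def positions(self) -> tuple[ImgtPosition, ...]:
        return self._positions

    def framework_positions(self) -> tuple[ImgtPosition, ...]:
        return tuple(p for p in self._positions if is_framework(p))

    def cdr_positions(self) -> tuple[ImgtPosition, ...]:
        return tuple(p for p in self._positions if not is_framework(p))

    def residue_at(self, pos: ImgtPosition) -> Optional[str]:
        return self.residues.get(pos)

    def with_substitution(self, pos: ImgtPosition, residue: str, new_id: Optional[str] = None) -> "NumberedSequence":
        """Return a copy with one residue replaced (no indels)."""
        if pos not in self.residues:
            raise KeyError(f"position {pos} absent from sequence {self.id!r}")
        new = dict(self.residues)
        new[pos] = residue
        return NumberedSequence(
            id=new_id or self.id,
            chain=self.chain,
            residues=new,
            species=self.species,
            v_gene=self.v_gene,
            source=self.source,
        )

    def sequence_str(self) -> str:
        """Amino-acid string in IMGT order (gaps omitted)."""
        return "".join(self.residues[p] for p in self._positions)

    def residue_items(self) -> tuple[tuple[ImgtPosition, str], ...]:
        return tuple(self.residues.items())


def framework_positions(positions: Iterable[ImgtPosition]) -> list[ImgtPosition]:
    return [p for p in positions if is_framework(p)]


def cdr_positions(positions: Iterable[ImgtPosition]) -> list[ImgtPosition]:
    return [p for p in positions if not is_framework(p)]


# --------------------------------------------------------------------------
# Quality filtering
# --------------------------------------------------------------------------

_CYS_POSITIONS = (ImgtPosition(23), ImgtPosition(104))

#: FR1 positions a record must occupy; chains' germline templates cover 1-26
#: fully, so the default requirement is the full FR1 range.
DEFAULT_FR1_REQUIRED: frozenset[ImgtPosition] = frozenset(ImgtPosition(n) for n in range(1, 27))


@dataclass
class FilterReport:
    kept: list[NumberedSequence]
    removed: list[tuple[str, str]]  # (sequence id, reason)

    REASONS = ("duplicate", "cysteine_error", "missing_fr1")

    def removal_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in self.REASONS}
        for _, reason in self.removed:
            counts[reason] += 1
        return counts


def quality_filter(
    seqs: Sequence[NumberedSequence],
    required_fr1: frozenset[ImgtPosition] = DEFAULT_FR1_REQUIRED,
) -> FilterReport:
    """Remove duplicates, cysteine errors and FR1-truncated records.

    A record is a duplicate if its residue map is position-wise identical to
    an earlier record; a cysteine error is any residue other than C at IMGT
    23 or 104; missing-FR1 means any required FR1 position is unoccupied.
    """
    chains = {s.chain for s in seqs}
    if len(chains) > 1:
        raise ValueError(f"quality_filter requires a single chain type, got {sorted(c.value for c in chains)}")
    kept: list[NumberedSequence] = []
    removed: list[tuple[str, str]] = []
    seen: set[tuple[tuple[ImgtPosition, str], ...]] = set()
    for seq in seqs:
        key = seq.residue_items()
        if key in seen:
            removed.append((seq.id, "duplicate"))
            continue
        if any(seq.residue_at(p) != "C" for p in _CYS_POSITIONS):
            removed.append((seq.id, "cysteine_error"))
            continue
        if any(p not in seq.residues for p in required_fr1):
            removed.append((seq.id, "missing_fr1"))
            continue
        seen.add(key)
        kept.append(seq)
    return FilterReport(kept=kept, removed=removed)


# --------------------------------------------------------------------------
# One-hot encoding
# --------------------------------------------------------------------------

def default_universe(
    seqs: Iterable[NumberedSequence], include_insertions: bool = False
) -> list[ImgtPosition]:
    """Sorted union of positions across sequences (insertions excluded by default)."""
    positions: set[ImgtPosition] = set()
    for s in seqs:
        positions.update(s.positions)
    if not include_insertions:
        positions = {p for p in positions if p.insertion is None}
    return sorted(positions, key=ImgtPosition.sort_key)


def encode(seq: NumberedSequence, universe: Sequence[ImgtPosition]) -> np.ndarray:
    """One-hot encode over ``universe``: 21 states per position (20 aa + gap).

    Positions absent from the sequence encode as the gap state. Positions
    present in the sequence but outside the universe are rejected unless
    they are insertion codes, which the default universe deliberately drops.
    """
    uindex = {p: i for i, p in enumerate(universe)}
    offenders = [str(p) for p in seq.positions if p not in uindex and p.insertion is None]
    if offenders:
        raise ValueError(
            f"sequence {seq.id!r} has positions outside the encoding universe: {', '.join(offenders)}"
        )
    vec = np.zeros(len(universe) * len(ALPHABET), dtype=np.float64)
    gap_idx = _AA_INDEX[GAP]
    for i in range(len(universe)):
        vec[i * len(ALPHABET) + gap_idx] = 1.0
    for pos, aa in seq.residues.items():
        i = uindex.get(pos)
        if i is None:
            continue  # insertion code excluded from universe
        base = i * len(ALPHABET)
        vec[base + gap_idx] = 0.0
        vec[base + _AA_INDEX[aa]] = 1.0
    return vec


def decode(
    vector: np.ndarray,
    universe: Sequence[ImgtPosition],
    id: str = "decoded",
    chain: Chain = Chain.HEAVY,
) -> dict[ImgtPosition, str]:
    """Inverse of :func:`encode` on the universe: residue map, gaps dropped."""
    n_states = len(ALPHABET)
    if vector.shape != (len(universe) * n_states,):
        raise ValueError("vector length does not match universe")
    residues: dict[ImgtPosition, str] = {}
    for i, pos in enumerate(universe):
        block = vector[i * n_states : (i + 1) * n_states]
        state = int(np.argmax(block))
        if ALPHABET[state] != GAP:
            residues[pos] = ALPHABET[state]
    return residues


# --------------------------------------------------------------------------
# I/O: numbered-sequence CSV and FASTA
# --------------------------------------------------------------------------

CSV_FIELDS = ("id", "chain", "imgt_position", "residue", "species", "v_gene")


def read_numbered_csv(path) -> list[NumberedSequence]:
    """Read the numbered-sequence CSV dialect (one residue per row)."""
    records: dict[str, dict] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        missing = {"id", "chain", "imgt_position", "residue"} - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: missing required CSV columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            sid = row["id"]
            try:
                pos = ImgtPosition.parse(row["imgt_position"])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            aa = (row["residue"] or "").strip().upper()
            if aa not in _AA_INDEX or aa == GAP:
                raise ValueError(f"{path}:{lineno}: residue {aa!r} is not a standard amino acid")
            rec = records.setdefault(
                sid,
                {
                    "chain": row["chain"],
                    "species": (row.get("species") or None),
                    "v_gene": (row.get("v_gene") or None),
                    "residues": {},
                },
            )
            if pos in rec["residues"]:
                raise ValueError(f"{path}:{lineno}: duplicate position {pos} for sequence {sid!r}")
            rec["residues"][pos] = aa
    return [
        NumberedSequence(
            id=sid,
            chain=Chain(rec["chain"]),
            residues=rec["residues"],
            species=rec["species"],
            v_gene=rec["v_gene"],
            source=str(path),
        )
        for sid, rec in records.items()
    ]


def write_numbered_csv(path, seqs: Sequence[NumberedSequence]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_FIELDS)
        for seq in seqs:
            for pos, aa in seq.residues.items():
                writer.writerow([seq.id, seq.chain.value, str(pos), aa, seq.species or "", seq.v_gene or ""])


Numberer = Callable[[str, str], NumberedSequence]


def read_fasta(path, numberer: Optional[Numberer] = None) -> list[NumberedSequence]:
    """Read a FASTA file and number each record with ``numberer(seq_str, id)``.

    Numbering (IMGT alignment) is delegated entirely to the callable; this
    package does not implement it.
    """
    if numberer is None:
        raise ValueError(
            "no numberer configured: reading plain FASTA requires a numbering callable "
            "(e.g. an ANARCI wrapper); alternatively provide a pre-numbered CSV"
        )
    from Bio import SeqIO

    return [numberer(str(rec.seq), rec.id) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, seqs: Sequence[NumberedSequence]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n{seq.sequence_str()}\n")
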