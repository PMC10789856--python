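"""Readers/writers for the plain-text formats the pipeline touches.

FASTA (multi-record, gap ``-``), Newick with optional internal support
labels, and tab-separated gene-neighbourhood tables.  All parsers validate
strictly and report the offending location; the only silent repair is the
missing-branch-length -> 0 warning in the Newick reader.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, TextIO

from .errors import FastaParseError, NeighborhoodTableError
from .tree import PhyloTree


class Molecule(str, enum.Enum):
    PROTEIN = "protein"
    DNA = "dna"


PROTEIN_STATES = "ARNDCQEGHILKMFPSTWYV"  # PAML state order
DNA_STATES = "ACGT"
GAP = "-"
AMBIGUITY = {Molecule.PROTEIN: "X", Molecule.DNA: "N"}
CORE_ALPHABET = {Molecule.PROTEIN: set(PROTEIN_STATES), Molecule.DNA: set(DNA_STATES)}
FULL_ALPHABET = {
    mol: CORE_ALPHABET[mol] | {GAP, AMBIGUITY[mol]} for mol in Molecule
}


@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence; residues are stored upper-case."""

    id: str
    molecule: Molecule
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - FULL_ALPHABET[self.molecule]
        if bad:
            raise ValueError(
                f"sequence {self.id!r} has illegal {self.molecule.value} "
                f"characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """Equal-length sequence records sharing one molecule type."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self):
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        if len(records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in alignment")
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        molecules = {r.molecule for r in records}
        if len(molecules) != 1:
            raise ValueError("mixed molecule types in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def molecule(self) -> Molecule:
        return self.records[0].molecule

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def get(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)

    def take_columns(self, columns: Iterable[int]) -> "Alignment":
        cols = list(columns)
        return Alignment(tuple(
            SequenceRecord(r.id, r.molecule, "".join(r.residues[c] for c in cols))
            for r in self.records
        ))


@dataclass
class GeneNeighborhood:
    """Ordered neighbours around a focal gene; offsets are signed gene ranks
    (... -2, -1, +1, +2 ...), not base pairs."""

    focal_id: str
    chromosome: str
    neighbors: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.focal_id:
            raise ValueError("focal_id must be non-empty")
        offsets = [off for _, off in self.neighbors]
        if any(off == 0 for off in offsets):
            raise ValueError(f"{self.focal_id}: neighbour offset 0 is invalid")
        if len(set(offsets)) != len(offsets):
            raise ValueError(f"{self.focal_id}: duplicate neighbour offsets")
        if any(not sym for sym, _ in self.neighbors):
            raise ValueError(f"{self.focal_id}: empty neighbour symbol")
        self.neighbors = sorted(self.neighbors, key=lambda sn: sn[1])

    def symbols(self, window: int | None = None) -> list[str]:
        """Neighbour symbols, optionally truncated to |offset| <= window."""
        if window is not None and window < 1:
            raise ValueError("window must be >= 1")
        return [sym for sym, off in self.neighbors
                if window is None or abs(off) <= window]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source: TextIO | str, molecule: Molecule | str) -> list[SequenceRecord]:
    """Parse FASTA text into records; gaps are retained, order preserved.

    Raises :class:`FastaParseError` (with a line number) on duplicate ids,
    empty sequences, or characters outside the molecule alphabet.
    """
    molecule = Molecule(molecule)
    if isinstance(source, str):
        source = io.StringIO(source)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    alphabet = FULL_ALPHABET[molecule]

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"record {header!r} has no sequence", header_line)
        records.append(SequenceRecord(header, molecule, seq))

    lineno = 0
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0] if line[1:].split() else ""
            if not header:
                raise FastaParseError("empty FASTA header", lineno)
            if header in seen:
                raise FastaParseError(
                    f"duplicate id {header!r} (first seen at line {seen[header]})",
                    lineno)
            seen[header] = lineno
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise FastaParseError("sequence data before first '>' header", lineno)
            bad = set(line.upper()) - alphabet
            if bad:
                raise FastaParseError(
                    f"illegal {molecule.value} character(s) {sorted(bad)} "
                    f"in record {header!r}", lineno)
            chunks.append(line)
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], width: int = 60) -> str:
    """Serialize records deterministically; ``width`` residues per line."""
    if width < 1:
        raise ValueError("width must be >= 1")
    out: list[str] = []
    for rec in records:
        out.append(f">{rec.id}")
        for i in range(0, len(rec.residues), width):
            out.append(rec.residues[i:i + width])
    return "\n".join(out) + ("\n" if out else "")


def read_alignment(source: TextIO | str, molecule: Molecule | str) -> Alignment:
    return Alignment(tuple(read_fasta(source, molecule)))


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(source: TextIO | str) -> PhyloTree:
    """Parse a single Newick string (unquoted labels, no comments).

    Internal numeric labels are kept as support annotations.  Missing branch
    lengths become 0 with a warning; negative lengths are an error.
    """
    if not isinstance(source, str):
        source = source.read()
    return PhyloTree.from_newick(source)


def write_newick(tree: PhyloTree, precision: int = 6) -> str:
    """Serialize a tree; branch lengths with ``precision`` decimals."""
    return tree.to_newick(precision=precision)


# ---------------------------------------------------------------------------
# Neighbourhood tables
# ---------------------------------------------------------------------------

_NEIGHBOR_COLUMNS = ["focal_id", "chromosome", "symbol", "offset"]


def read_neighborhood_table(source: TextIO | str) -> list[GeneNeighborhood]:
    """Read a TSV with header ``focal_id  chromosome  symbol  offset`` and
    group rows into :class:`GeneNeighborhood` objects (input order of focal
    genes is preserved)."""
    if isinstance(source, str):
        source = io.StringIO(source)
    lines = [ln.rstrip("\n") for ln in source]
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not body:
        raise NeighborhoodTableError("empty table: header row required")
    head_no, head = body[0]
    columns = head.split("\t")
    if columns != _NEIGHBOR_COLUMNS:
        raise NeighborhoodTableError(
            f"line {head_no}: expected header {_NEIGHBOR_COLUMNS}, got {columns}")
    grouped: dict[str, GeneNeighborhood] = {}
    seen_offsets: set[tuple[str, int]] = set()
    for lineno, line in body[1:]:
        fields = line.split("\t")
        if len(fields) != 4:
            raise NeighborhoodTableError(
                f"line {lineno}: expected 4 tab-separated columns, got {len(fields)}")
        focal, chrom, symbol, offset_s = (f.strip() for f in fields)
        try:
            offset = int(offset_s)
        except ValueError:
            raise NeighborhoodTableError(
                f"line {lineno}: non-integer offset {offset_s!r}") from None
        if offset == 0:
            raise NeighborhoodTableError(f"line {lineno}: offset must be non-zero")
        if not symbol:
            raise NeighborhoodTableError(f"line {lineno}: empty symbol")
        if (focal, offset) in seen_offsets:
            raise NeighborhoodTableError(
                f"line {lineno}: duplicate offset {offset} for focal gene {focal!r}")
        seen_offsets.add((focal, offset))
        if focal not in grouped:
            grouped[focal] = GeneNeighborhood(focal, chrom, [])
        elif grouped[focal].chromosome != chrom:
            raise NeighborhoodTableError(
                f"line {lineno}: focal gene {focal!r} listed on two chromosomes")
        grouped[focal].neighbors.append((symbol, offset))
    out = []
    for nb in grouped.values():
        # re-run invariant checks and sorting after accumulation
        out.append(GeneNeighborhood(nb.focal_id, nb.chromosome, nb.neighbors))
    return out


def write_neighborhood_table(neighborhoods: Iterable[GeneNeighborhood]) -> str:
    rows = ["\t".join(_NEIGHBOR_COLUMNS)]
    for nb in neighborhoods:
        for sym, off in nb.neighbors:
            rows.append(f"{nb.focal_id}\t{nb.chromosome}\t{sym}\t{off}")
    return "\n".join(rows) + "\n"
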