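"""Local-synteny orthology evidence: shared-neighbour counts and Jaccard
indices between candidate orthologue neighbourhoods, diagnostic "witness"
neighbours unique to one reference, and a one-to-one assignment with an
explicit ambiguity flag.

Comparison is membership-based on normalized symbol sets (case-insensitive,
with an explicit synonym map for cross-species homologue naming); gene
order and orientation are ignored.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import GeneNeighborhood

BRUTE_FORCE_LIMIT = 8
DEFAULT_WINDOW = 10
DEFAULT_EPSILON = 0.05


def normalize_symbols(symbols: Iterable[str],
                      synonym_map: Mapping[str, str] | None = None) -> frozenset:
    """Upper-case symbols and collapse synonyms onto canonical names."""
    canon = {k.upper(): v.upper() for k, v in (synonym_map or {}).items()}
    out = set()
    for sym in symbols:
        s = sym.upper()
        out.add(canon.get(s, s))
    return frozenset(out)


def shared_neighbors(q: GeneNeighborhood, r: GeneNeighborhood,
                     synonym_map: Mapping[str, str] | None = None,
                     window: int | None = None
                     ) -> tuple[int, float, list[str]]:
    """(count, Jaccard, shared symbols) between two neighbourhoods."""
    qs = normalize_symbols(q.symbols(window), synonym_map)
    rs = normalize_symbols(r.symbols(window), synonym_map)
    if not qs or not rs:
        empty = q.focal_id if not qs else r.focal_id
        raise ValueError(f"empty neighbourhood for {empty!r} within window")
    inter = qs & rs
    union = qs | rs
    return len(inter), len(inter) / len(union), sorted(inter)


@dataclass
class SyntenyMatrix:
    """Query x reference shared-neighbour evidence."""

    queries: list[str]
    references: list[str]
    counts: np.ndarray
    jaccard: np.ndarray
    shared: list[list[list[str]]]

    def __post_init__(self):
        shape = (len(self.queries), len(self.references))
        self.counts = np.asarray(self.counts, dtype=int)
        self.jaccard = np.asarray(self.jaccard, dtype=float)
        if self.counts.shape != shape or self.jaccard.shape != shape:
            raise ValueError("matrix shapes do not match label counts")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")
        if ((self.jaccard < 0) | (self.jaccard > 1)).any():
            raise ValueError("Jaccard values must lie in [0, 1]")
        if ((self.counts == 0) != (self.jaccard == 0)).any():
            raise ValueError("Jaccard must be 0 exactly when the count is 0")

    def to_tsv(self, precision: int = 4) -> str:
        lines = ["query\treference\tshared_count\tjaccard\tshared_symbols"]
        for i, q in enumerate(self.queries):
            for j, r in enumerate(self.references):
                lines.append("\t".join([
                    q, r, str(int(self.counts[i, j])),
                    f"{self.jaccard[i, j]:.{precision}f}",
                    ",".join(self.shared[i][j]),
                ]))
        return "\n".join(lines) + "\n"


def synteny_matrix(queries: Sequence[GeneNeighborhood],
                   references: Sequence[GeneNeighborhood],
                   window: int = DEFAULT_WINDOW,
                   synonym_map: Mapping[str, str] | None = None) -> SyntenyMatrix:
    """All query x reference cells, neighbourhoods truncated to ``window``
    gene ranks on each side before comparison."""
    if window < 1:
        raise ValueError("window must be >= 1")
    nq, nr = len(queries), len(references)
    counts = np.zeros((nq, nr), dtype=int)
    jacc = np.zeros((nq, nr))
    shared: list[list[list[str]]] = [[[] for _ in range(nr)] for _ in range(nq)]
    for i, q in enumerate(queries):
        for j, r in enumerate(references):
            c, jc, syms = shared_neighbors(q, r, synonym_map, window)
            counts[i, j] = c
            jacc[i, j] = jc
            shared[i][j] = syms
    return SyntenyMatrix([q.focal_id for q in queries],
                         [r.focal_id for r in references],
                         counts, jacc, shared)


def find_diagnostic_neighbors(references: Sequence[GeneNeighborhood],
                              window: int | None = None,
                              synonym_map: Mapping[str, str] | None = None
                              ) -> dict[str, frozenset]:
    """Per reference, the neighbour symbols appearing in no other
    reference's neighbourhood ("witness genes")."""
    if len(references) < 2:
        raise ValueError("need at least 2 references")
    sets = {r.focal_id: normalize_symbols(r.symbols(window), synonym_map)
            for r in references}
    out = {}
    for rid, rset in sets.items():
        others = frozenset().union(*(s for k, s in sets.items() if k != rid))
        out[rid] = rset - others
    return out


@dataclass
class OrthologyAssignment:
    """Best injective query->reference mapping by total Jaccard, with
    near-optimal alternatives and an ambiguity flag."""

    mapping: dict[str, str | None]
    total_score: float
    ambiguous: bool
    alternatives: list[dict[str, str | None]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "mapping": self.mapping,
            "total_score": self.total_score,
            "ambiguous": self.ambiguous,
            "alternatives": self.alternatives,
        }, indent=2, sort_keys=True)


def assign_orthologs(matrix: SyntenyMatrix,
                     epsilon: float = DEFAULT_EPSILON) -> OrthologyAssignment:
    """Exhaustive search over injective assignments (dimensions capped at
    ``BRUTE_FORCE_LIMIT``).  Queries whose best cell is 0 stay unassigned.
    The result is flagged ambiguous when another complete mapping scores
    within ``epsilon`` of the optimum, or when some assigned query's top
    two cells differ by less than ``epsilon``."""
    nq, nr = len(matrix.queries), len(matrix.references)
    if min(nq, nr) == 0:
        raise ValueError("empty synteny matrix")
    if max(nq, nr) > BRUTE_FORCE_LIMIT:
        raise ValueError(
            f"assignment is exhaustive and capped at {BRUTE_FORCE_LIMIT}x"
            f"{BRUTE_FORCE_LIMIT}")
    jac = matrix.jaccard
    scored: list[tuple[float, tuple[int | None, ...]]] = []
    if nq <= nr:
        # every query receives a distinct reference
        for combo in itertools.permutations(range(nr), nq):
            score = sum(jac[i, c] for i, c in enumerate(combo))
            scored.append((score, tuple(combo)))
    else:
        # more queries than references: leftover queries stay unassigned
        for rows in itertools.permutations(range(nq), nr):
            assignment: list[int | None] = [None] * nq
            for c, i in enumerate(rows):
                assignment[i] = c
            score = sum(jac[i, c] for i, c in enumerate(assignment)
                        if c is not None)
            scored.append((score, tuple(assignment)))

    best_score = max(s for s, _ in scored)
    # drop zero-Jaccard pairings from the winning mapping: no evidence
    def materialize(assignment: tuple[int | None, ...]) -> dict[str, str | None]:
        return {matrix.queries[i]:
                (matrix.references[c] if c is not None and jac[i, c] > 0 else None)
                for i, c in enumerate(assignment)}

    winners = [a for s, a in scored if s == best_score]
    winners.sort(key=lambda a: tuple(-1 if c is None else c for c in a))
    best = winners[0]
    near = {tuple(sorted(materialize(a).items(), key=lambda kv: kv[0]))
            for s, a in scored if s >= best_score - epsilon}
    alternatives = [dict(items)
                    for items in sorted(near, key=lambda t: repr(t))
                    if dict(items) != materialize(best)]

    ambiguous = bool(alternatives) and best_score > 0
    if not ambiguous and best_score > 0:
        # per-query top-two gap
        for i in range(nq):
            row = np.sort(jac[i])[::-1]
            if len(row) >= 2 and row[0] > 0 and (row[0] - row[1]) < epsilon:
                ambiguous = True
                break
    return OrthologyAssignment(mapping=materialize(best),
                               total_score=float(best_score),
                               ambiguous=ambiguous,
                               alternatives=alternatives)


def read_synonym_map(source) -> dict[str, str]:
    """Two-column TSV ``variant<TAB>canonical`` -> dict."""
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()
    out: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"synonym map line {lineno}: expected 2 columns")
        out[fields[0].strip()] = fields[1].strip()
    return out
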