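"""Relative timing of a gene duplication from branch-length ratios.

On an outgroup-rooted tree, ``a`` is the ingroup-side child of the root
(where the ingroup lineage begins after the outgroup split), ``b`` is the
most recent common ancestor of the two paralogue groups, and ``c`` stands
for the present-day paralogue tips.  The statistic is the ratio of the mean
b->tip path length (``bc``) to the a->b path length (``ab``): large ratios
indicate an ancient duplication (scenario I), small ratios a recent one
(scenario II).

``ab`` deliberately excludes the outgroup stem, which makes the ratio
independent of both the outgroup branch length and the exact position of
the root along that branch.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .distances import SubstitutionModelSpec
from .errors import TimingError, WgdTimingError
from .io_formats import Alignment, Molecule
from .njtree import nj_from_alignment, root_with_outgroup
from .tree import Node, PhyloTree

AB_FLOOR = 1e-9


class Classification(str, enum.Enum):
    ANCIENT = "ancient"
    RECENT = "recent"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class Thresholds:
    """Classification cut-offs on the bc/ab ratio."""

    ancient: float = 1.0
    recent: float = 0.5

    def __post_init__(self):
        if self.recent > self.ancient:
            raise ValueError("recent threshold must not exceed ancient threshold")


@dataclass(frozen=True)
class ParalogLabeling:
    """Partition of tip labels into the two paralogue groups, the outgroup,
    and everything else."""

    paralog_1: frozenset
    paralog_2: frozenset
    outgroup: frozenset
    other: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "paralog_1", frozenset(self.paralog_1))
        object.__setattr__(self, "paralog_2", frozenset(self.paralog_2))
        object.__setattr__(self, "outgroup", frozenset(self.outgroup))
        object.__setattr__(self, "other", frozenset(self.other))
        groups = [self.paralog_1, self.paralog_2, self.outgroup]
        if any(not g for g in groups):
            raise ValueError("paralog_1, paralog_2 and outgroup must be non-empty")
        all_groups = groups + [self.other]
        total = sum(len(g) for g in all_groups)
        union = frozenset().union(*all_groups)
        if len(union) != total:
            raise ValueError("labeling groups must be disjoint")

    @property
    def paralog_tips(self) -> frozenset:
        return self.paralog_1 | self.paralog_2

    def group_of(self, tip: str) -> str:
        for name in ("paralog_1", "paralog_2", "outgroup", "other"):
            if tip in getattr(self, name):
                return name
        return "other"


@dataclass
class TimingResult:
    node_a: Node
    node_b: Node
    ab: float
    bc_per_tip: dict[str, float]
    bc: float
    ratio: float
    classification: Classification
    outgroup_used: frozenset
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ab": self.ab,
            "bc": self.bc,
            "bc_per_tip": dict(sorted(self.bc_per_tip.items())),
            "ratio": self.ratio,
            "classification": self.classification.value,
            "outgroup": sorted(self.outgroup_used),
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------

def locate_timing_nodes(tree: PhyloTree, labeling: ParalogLabeling
                        ) -> tuple[Node, Node, list[str]]:
    """Find node a (root's ingroup-side child) and node b (MRCA of both
    paralogue groups).  Returns any monophyly warnings alongside."""
    if not tree.rooted or len(tree.root.children) != 2:
        raise TimingError("timing needs a tree rooted with the outgroup")
    tips = set(tree.tip_labels)
    present = labeling.paralog_tips & tips
    if not (labeling.paralog_1 & tips) or not (labeling.paralog_2 & tips):
        raise TimingError("both paralogue groups must have tips in the tree")
    tipsets = tree.tipsets()
    og_in_tree = labeling.outgroup & tips
    if not og_in_tree:
        raise TimingError("no outgroup tips in the tree")
    left, right = tree.root.children
    if tipsets[id(left)] == frozenset(og_in_tree):
        ingroup_child = right
    elif tipsets[id(right)] == frozenset(og_in_tree):
        ingroup_child = left
    else:
        raise TimingError(
            "the root does not separate exactly the outgroup tips "
            f"{sorted(og_in_tree)}; re-root with root_with_outgroup first")
    # an inserted root sits at an arbitrary point on the outgroup branch, so
    # the real outgroup-split node is its ingroup-side child; an explicitly
    # rooted input tree's root IS that divergence node
    node_a = ingroup_child if tree.root_is_insertion else tree.root
    node_b = tree.mrca(sorted(present))
    if node_b is node_a or node_b is tree.root:
        raise TimingError(
            "duplication node coincides with the ingroup root: ab undefined")
    # require node_b strictly below node_a
    anc = node_b.parent
    while anc is not None and anc is not node_a:
        anc = anc.parent
    if anc is None:
        raise TimingError("duplication node is not below the ingroup root")

    warnings = []
    # each paralogue group should descend from separate children of node_b
    child_of: dict[str, int] = {}
    for k, child in enumerate(node_b.children):
        for tip in tipsets[id(child)]:
            child_of[tip] = k
    for name, group in (("paralog_1", labeling.paralog_1),
                        ("paralog_2", labeling.paralog_2)):
        kids = {child_of[t] for t in group & tips if t in child_of}
        if len(kids) != 1:
            warnings.append(
                f"{name} tips are not confined to a single child of the "
                "duplication node (non-monophyletic duplication)")
    return node_a, node_b, warnings


def compute_timing(tree: PhyloTree, labeling: ParalogLabeling,
                   thresholds: Thresholds = Thresholds()) -> TimingResult:
    """The bc/ab statistic on an outgroup-rooted tree."""
    node_a, node_b, warns = locate_timing_nodes(tree, labeling)
    ab = tree.path_length(node_a, node_b)
    if ab <= AB_FLOOR:
        raise TimingError(f"degenerate stem: ab = {ab} <= {AB_FLOOR}")
    tipsets = tree.tipsets()
    below_b = tipsets[id(node_b)]
    bc_per_tip: dict[str, float] = {}
    for tip in sorted(labeling.paralog_tips & set(tree.tip_labels)):
        if tip not in below_b:
            warns.append(f"tip {tip!r} not descended from the duplication node; "
                         "excluded from bc")
            continue
        bc_per_tip[tip] = tree.path_length(node_b, tip)
    if not bc_per_tip:
        raise TimingError("no paralogue tips below the duplication node")
    bc = sum(bc_per_tip.values()) / len(bc_per_tip)
    ratio = bc / ab
    return TimingResult(node_a=node_a, node_b=node_b, ab=ab,
                        bc_per_tip=bc_per_tip, bc=bc, ratio=ratio,
                        classification=classify_duplication(ratio, thresholds),
                        outgroup_used=frozenset(labeling.outgroup),
                        warnings=warns)


def classify_duplication(ratio: float,
                         thresholds: Thresholds = Thresholds()) -> Classification:
    """ancient if ratio >= thresholds.ancient, recent if <= thresholds.recent."""
    if not math.isfinite(ratio) or ratio <= 0:
        raise TimingError(f"ratio must be finite and positive, got {ratio}")
    if ratio >= thresholds.ancient:
        return Classification.ANCIENT
    if ratio <= thresholds.recent:
        return Classification.RECENT
    return Classification.INDETERMINATE


# ---------------------------------------------------------------------------
# Multi-case report
# ---------------------------------------------------------------------------

@dataclass
class TimingCase:
    """One duplication-pair analysis: a tree (or an alignment from which a
    tree is inferred) plus paralogue groups and one or more outgroup sets."""

    name: str
    paralog_1: frozenset
    paralog_2: frozenset
    outgroups: Mapping[str, frozenset]  # outgroup configuration name -> tips
    tree: PhyloTree | None = None
    alignment: Alignment | None = None
    model: SubstitutionModelSpec | None = None
    molecule: Molecule | None = None

    def __post_init__(self):
        if (self.tree is None) == (self.alignment is None):
            raise ValueError("exactly one of tree/alignment must be given")
        if self.alignment is not None and self.model is None:
            raise ValueError("alignment cases need a distance model")
        if not self.outgroups:
            raise ValueError("at least one outgroup configuration is required")
        if self.molecule is None and self.alignment is not None:
            self.molecule = self.alignment.molecule


REPORT_COLUMNS = ["case", "molecule", "outgroup", "ab", "bc", "ratio",
                  "classification", "concordance", "error"]


def timing_report(cases: Iterable[TimingCase],
                  thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """One row per case x outgroup configuration; per-case errors are
    reported in the table, not raised.  ``concordance`` is max/min ratio
    across the outgroup configurations of a case."""
    rows = []
    for case in cases:
        base_tree = case.tree
        if base_tree is None:
            base_tree, _ = nj_from_alignment(case.alignment, case.model)
        molecule = case.molecule.value if case.molecule else ""
        ratios: dict[str, float] = {}
        case_rows = []
        for og_name, og_tips in case.outgroups.items():
            row = {"case": case.name, "molecule": molecule, "outgroup": og_name,
                   "ab": float("nan"), "bc": float("nan"), "ratio": float("nan"),
                   "classification": "", "concordance": float("nan"), "error": ""}
            try:
                rooted = root_with_outgroup(base_tree, og_tips)
                labeling = ParalogLabeling(
                    paralog_1=case.paralog_1, paralog_2=case.paralog_2,
                    outgroup=og_tips,
                    other=frozenset(base_tree.tip_labels)
                    - case.paralog_1 - case.paralog_2 - frozenset(og_tips))
                result = compute_timing(rooted, labeling, thresholds)
            except WgdTimingError as exc:
                row["error"] = str(exc)
            else:
                row.update(ab=result.ab, bc=result.bc, ratio=result.ratio,
                           classification=result.classification.value)
                ratios[og_name] = result.ratio
            case_rows.append(row)
        if ratios:
            concordance = max(ratios.values()) / min(ratios.values())
            for row in case_rows:
                if not row["error"]:
                    row["concordance"] = concordance
        rows.extend(case_rows)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def report_to_json(report: pd.DataFrame) -> str:
    records = report.to_dict(orient="records")
    for rec in records:
        for key, value in rec.items():
            if isinstance(value, float) and math.isnan(value):
                rec[key] = None
    return json.dumps(records, indent=2)
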