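"""Synthetic gene families: duplication events at known heights relative to
an outgroup split, evolved under a reversible continuous-time Markov
substitution process (no indels), with optional per-branch rate multipliers
and duplicate loss.

Time conventions: heights are measured from the present (tips at height 0);
the outgroup splits at height ``A``, duplications at heights ``B < A``.
With the model scaled to unit rate, a branch of duration ``t`` accumulates
``t`` expected substitutions/site, so the exact relative-timing truth for a
duplication at ``B`` is ``B / (A - B)``.

Lineage naming: the ingroup starts as lineage ``P``; a duplication of
lineage ``L`` yields ``L1`` and ``L2`` (so two nested events give ``P1``,
``P21``, ``P22``).  Tips are ``s<i>_<lineage>``; the outgroup tip is ``OG``.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .distances import SubstitutionModelSpec, discrete_gamma_rates, uniform_model
from .errors import ScenarioError
from .io_formats import Alignment, Molecule, SequenceRecord, write_fasta
from .timing import ParalogLabeling
from .tree import Node, PhyloTree

OUTGROUP_LABEL = "OG"
ROOT_LINEAGE = "P"

PRESET_NAMES = ("ancient_2R", "recent_TSWGD", "sturgeon_LOR", "sturgeon_AOR")


@dataclass(frozen=True)
class DuplicationEvent:
    height: float
    lineage: str = ROOT_LINEAGE


@dataclass(frozen=True)
class TimingTruth:
    """Ground truth for one duplication: tip groups and the exact ratio."""

    name: str
    height: float
    ratio: float
    paralog_1: frozenset
    paralog_2: frozenset


@dataclass(frozen=True)
class WGDScenario:
    A: float
    seed: int
    duplication_events: tuple[DuplicationEvent, ...] = (DuplicationEvent(1.0),)
    n_species_per_clade: int = 1
    other_lineages: int = 1  # extra ingroup tips diverging at height A,
    # anchoring the outgroup-split node inside the unrooted topology
    loss_probability: float = 0.0
    rate_multipliers: Mapping[str, float] = field(default_factory=dict)
    clock_rate: float = 1.0  # substitutions/site per time unit; the bc/ab
    # truth is scale-invariant, so presets use < 1 to stay clear of
    # saturation at the preset depths
    sequence_length: int = 500
    molecule: Molecule = Molecule.PROTEIN
    model: SubstitutionModelSpec | None = None
    speciation_heights: tuple[float, ...] | None = None
    resolution: str = "ancestral"  # or "lineage_specific"
    name: str = "scenario"

    def __post_init__(self):
        if self.A <= 0:
            raise ScenarioError("outgroup-split height A must be > 0")
        if self.seed is None:
            raise ScenarioError("a seed is mandatory")
        if self.n_species_per_clade < 1:
            raise ScenarioError("n_species_per_clade must be >= 1")
        if not 0.0 <= self.loss_probability < 1.0:
            raise ScenarioError("loss_probability must lie in [0, 1)")
        if self.sequence_length < 1:
            raise ScenarioError("sequence_length must be >= 1")
        if self.clock_rate <= 0:
            raise ScenarioError("clock_rate must be > 0")
        if self.other_lineages < 0:
            raise ScenarioError("other_lineages must be >= 0")
        if self.resolution not in ("ancestral", "lineage_specific"):
            raise ScenarioError(f"unknown resolution {self.resolution!r}")
        if any(m <= 0 for m in self.rate_multipliers.values()):
            raise ScenarioError("rate multipliers must be > 0")
        for ev in self.duplication_events:
            if not 0.0 < ev.height < self.A:
                raise ScenarioError(
                    f"duplication height {ev.height} must lie in (0, A={self.A})")
        object.__setattr__(self, "molecule", Molecule(self.molecule))
        if self.model is None:
            object.__setattr__(self, "model", uniform_model(self.molecule))

    def resolved_model(self) -> SubstitutionModelSpec:
        assert self.model is not None
        return self.model


def preset_scenario(name: str, seed: int = 0, **overrides) -> WGDScenario:
    """Named scenarios bracketing the ancient (ratio 1.25) and recent
    (ratio 0.15) duplication regimes, plus the two sturgeon-style
    rediploidization tree shapes (LOR vs AOR)."""
    # the outgroup/other stems carry rate multipliers < 1: the statistic is
    # independent of their lengths, and shorter stems give much less noisy
    # junction placement in distance trees at these depths
    slow_stems = {"OG": 0.3, "other1": 0.3}
    presets = {
        "ancient_2R": dict(A=1.8, duplication_events=(DuplicationEvent(1.0),),
                           n_species_per_clade=3, rate_multipliers=slow_stems),
        "recent_TSWGD": dict(A=2.3, duplication_events=(DuplicationEvent(0.3),),
                             n_species_per_clade=2, clock_rate=0.5,
                             rate_multipliers=slow_stems),
        "sturgeon_LOR": dict(A=1.8, duplication_events=(DuplicationEvent(0.3),),
                             n_species_per_clade=2, speciation_heights=(0.6,),
                             resolution="lineage_specific", clock_rate=0.5),
        "sturgeon_AOR": dict(A=1.8, duplication_events=(DuplicationEvent(0.6),),
                             n_species_per_clade=2, speciation_heights=(0.3,),
                             clock_rate=0.5),
    }
    if name not in presets:
        raise ScenarioError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    kwargs = dict(presets[name])
    kwargs.update(overrides)
    return WGDScenario(seed=seed, name=name, **kwargs)


# ---------------------------------------------------------------------------
# True tree
# ---------------------------------------------------------------------------

def build_true_tree(scenario: WGDScenario) -> PhyloTree:
    """Time-unit tree implied by the scenario, losses already applied
    (reproducibly under the scenario seed).  The tree is ultrametric over
    the surviving tips."""
    tree = _assemble_tree(scenario)
    loss_rng = np.random.default_rng(_stream_seed(scenario.seed, "loss"))
    if scenario.loss_probability > 0:
        # loss applies to duplicate (paralogue-lineage) tips only
        ingroup_tips = sorted(t for t in tree.tip_labels
                              if t != OUTGROUP_LABEL and "_" in t)
        doomed = [t for t in ingroup_tips
                  if loss_rng.random() < scenario.loss_probability]
        if doomed:
            survivors = set(tree.tip_labels) - set(doomed)
            for _name, _height, g1, g2 in _event_groups(scenario,
                                                        set(tree.tip_labels)):
                for group in (g1, g2):
                    if group and not (group & survivors):
                        raise ScenarioError(
                            "all tips of one paralogue lost; degenerate scenario")
            tree = tree.prune_tips(doomed)
    return tree


_STREAMS = {"loss": 101, "evolve": 202}


def _stream_seed(seed: int, label: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), _STREAMS[label]])


def _assemble_tree(scenario: WGDScenario) -> PhyloTree:
    events = sorted(scenario.duplication_events, key=lambda e: -e.height)
    event_for: dict[str, DuplicationEvent] = {}
    live = {ROOT_LINEAGE: scenario.A}
    for ev in events:
        if ev.lineage not in live:
            raise ScenarioError(f"event targets unknown lineage {ev.lineage!r}")
        if ev.height >= live[ev.lineage]:
            raise ScenarioError(
                f"event at height {ev.height} predates the origin of "
                f"lineage {ev.lineage!r}")
        if ev.lineage in event_for:
            raise ScenarioError(f"lineage {ev.lineage!r} duplicated twice")
        event_for[ev.lineage] = ev
        live.pop(ev.lineage)
        live[ev.lineage + "1"] = ev.height
        live[ev.lineage + "2"] = ev.height

    n_sp = scenario.n_species_per_clade
    if scenario.resolution == "lineage_specific":
        if not events:
            raise ScenarioError("lineage_specific resolution needs an event")
        max_ev = max(ev.height for ev in events)
        sp_heights = _speciation_heights(scenario, n_sp, low=max_ev, high=scenario.A)

        def species_subtree(sp: int, origin: float) -> Node:
            return _lineage_clade(ROOT_LINEAGE, origin, event_for,
                                  species=[sp], sp_heights=(),
                                  species_tag=f"s{sp}")

        ingroup = _species_caterpillar(list(range(1, n_sp + 1)), scenario.A,
                                       sp_heights, species_subtree)
    else:
        min_origin = min(live.values())
        sp_heights = _speciation_heights(scenario, n_sp, low=0.0, high=min_origin)
        ingroup = _lineage_clade(ROOT_LINEAGE, scenario.A, event_for,
                                 species=list(range(1, n_sp + 1)),
                                 sp_heights=sp_heights)

    root = Node(label="root")
    root.add_child(ingroup)
    for i in range(scenario.other_lineages):
        root.add_child(Node(label=f"other{i + 1}", length=scenario.A))
    root.add_child(Node(label=OUTGROUP_LABEL, length=scenario.A))
    rooted = 1 + scenario.other_lineages == 1  # bifurcating only w/o others
    return PhyloTree(root, rooted=rooted)


def _speciation_heights(scenario: WGDScenario, n_sp: int,
                        low: float, high: float) -> tuple[float, ...]:
    if n_sp == 1:
        return ()
    if scenario.speciation_heights is not None:
        hs = tuple(sorted(scenario.speciation_heights, reverse=True))
        if len(hs) != n_sp - 1:
            raise ScenarioError(
                f"need {n_sp - 1} speciation heights, got {len(hs)}")
        if not all(low < h < high for h in hs):
            raise ScenarioError(
                f"speciation heights must lie in ({low}, {high})")
        return hs
    # evenly spaced strictly inside (low, high)
    step = (high - low) / n_sp
    return tuple(low + step * k for k in range(n_sp - 1, 0, -1))


def _species_caterpillar(species: Sequence[int], origin: float,
                         heights: tuple[float, ...], subtree) -> Node:
    if len(species) == 1:
        node = subtree(species[0], origin)
        return node
    h = heights[0]
    node = Node(label=f"sp_{'_'.join(str(s) for s in species)}",
                length=origin - h)
    first = subtree(species[0], h)
    rest = _species_caterpillar(species[1:], h, heights[1:], subtree)
    node.add_child(first)
    node.add_child(rest)
    return node


def _lineage_clade(lineage: str, origin: float,
                   event_for: Mapping[str, DuplicationEvent],
                   species: Sequence[int],
                   sp_heights: tuple[float, ...],
                   species_tag: str | None = None) -> Node:
    ev = event_for.get(lineage)
    if ev is not None:
        tag = f"dup_{species_tag}_{lineage}" if species_tag else f"dup_{lineage}"
        node = Node(label=tag, length=origin - ev.height)
        for child_lin in (lineage + "1", lineage + "2"):
            node.add_child(_lineage_clade(child_lin, ev.height, event_for,
                                          species, sp_heights, species_tag))
        return node

    def tip(sp: int, tip_origin: float) -> Node:
        return Node(label=f"s{sp}_{lineage}", length=tip_origin)

    if len(species) == 1:
        return tip(species[0], origin)
    return _species_caterpillar(species, origin, sp_heights, tip)


# ---------------------------------------------------------------------------
# Truth bookkeeping
# ---------------------------------------------------------------------------

def _event_groups(scenario: WGDScenario, tips: set[str]):
    """Yield (event name, height, group1 tips, group2 tips) over all
    duplication events, species-resolved in lineage_specific mode."""
    def lineage_of(tip: str) -> str:
        return tip.split("_", 1)[1] if "_" in tip else ""

    def species_of(tip: str) -> str:
        return tip.split("_", 1)[0]

    ingroup = {t for t in tips if t != OUTGROUP_LABEL}
    for ev in sorted(scenario.duplication_events, key=lambda e: -e.height):
        if scenario.resolution == "lineage_specific":
            for sp in range(1, scenario.n_species_per_clade + 1):
                g1 = frozenset(t for t in ingroup if species_of(t) == f"s{sp}"
                               and lineage_of(t).startswith(ev.lineage + "1"))
                g2 = frozenset(t for t in ingroup if species_of(t) == f"s{sp}"
                               and lineage_of(t).startswith(ev.lineage + "2"))
                yield (f"dup_s{sp}_{ev.lineage}", ev.height, g1, g2)
        else:
            g1 = frozenset(t for t in ingroup
                           if lineage_of(t).startswith(ev.lineage + "1"))
            g2 = frozenset(t for t in ingroup
                           if lineage_of(t).startswith(ev.lineage + "2"))
            yield (f"dup_{ev.lineage}", ev.height, g1, g2)


def scenario_truth(scenario: WGDScenario, tree: PhyloTree) -> list[TimingTruth]:
    """Exact B/(A-B) truth per duplication event over the surviving tips."""
    tips = set(tree.tip_labels)
    out = []
    for name, height, g1, g2 in _event_groups(scenario, tips):
        if not g1 or not g2:
            continue
        out.append(TimingTruth(name=name, height=height,
                               ratio=height / (scenario.A - height),
                               paralog_1=g1, paralog_2=g2))
    return out


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def expected_p_jc20(t: float) -> float:
    """Expected mismatch fraction after divergence ``t`` under the uniform
    20-state model: (19/20) (1 - exp(-20 t / 19))."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return (19.0 / 20.0) * (1.0 - math.exp(-20.0 * t / 19.0))


def evolve_alignment(tree: PhyloTree, model: SubstitutionModelSpec,
                     length: int, seed, rate_multipliers: Mapping[str, float]
                     | None = None) -> Alignment:
    """Evolve site-independent sequences down ``tree``; the root sequence is
    drawn from the equilibrium frequencies and each branch applies
    P(t x multiplier).  Byte-identical output for identical seeds."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if model.exchangeabilities is None:
        raise ValueError("evolution needs a full (ml_empirical-style) model")
    rng = np.random.default_rng(seed)
    multipliers = rate_multipliers or {}
    pi = model.frequencies
    k = model.n_states
    lam, right, left = model._eigensystem

    if model.alpha is not None:
        cats = discrete_gamma_rates(model.alpha, 4)
        site_rates = cats[rng.integers(0, 4, size=length)]
    else:
        site_rates = np.ones(length)

    def p_matrix(t: float) -> np.ndarray:
        p = (right * np.exp(lam * t)[np.newaxis, :]) @ left
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)

    states: dict[int, np.ndarray] = {}
    states[id(tree.root)] = rng.choice(k, size=length, p=pi)
    for node in tree.root.preorder():
        for child in node.children:
            mult = multipliers.get(child.label or "", 1.0)
            t = child.length * mult
            parent_states = states[id(node)]
            u = rng.random(length)
            child_states = np.empty(length, dtype=np.int64)
            for rate in np.unique(site_rates):
                mask = site_rates == rate
                cum = np.cumsum(p_matrix(t * rate), axis=1)
                rows = cum[parent_states[mask]]
                child_states[mask] = (rows < u[mask, np.newaxis]).sum(axis=1)
            states[id(child)] = np.minimum(child_states, k - 1)

    alphabet = np.array(list(model.states))
    records = tuple(
        SequenceRecord(tip.label, Molecule.PROTEIN if k == 20 else Molecule.DNA,
                       "".join(alphabet[states[id(tip)]]))
        for tip in tree.tips())
    return Alignment(records)


# ---------------------------------------------------------------------------
# Family assembly
# ---------------------------------------------------------------------------

@dataclass
class SimulatedFamily:
    scenario: WGDScenario
    true_tree: PhyloTree
    alignment: Alignment
    truth: list[TimingTruth]
    labeling: ParalogLabeling

    def write(self, outdir: str, precision: int = 6) -> dict[str, str]:
        """Emit FASTA / Newick / labeling TSV / truth JSON; returns paths."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "alignment": os.path.join(outdir, "alignment.fasta"),
            "tree": os.path.join(outdir, "true_tree.nwk"),
            "labeling": os.path.join(outdir, "labeling.tsv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        with open(paths["alignment"], "w") as fh:
            fh.write(write_fasta(self.alignment.records))
        with open(paths["tree"], "w") as fh:
            fh.write(self.true_tree.to_newick(precision=precision) + "\n")
        with open(paths["labeling"], "w") as fh:
            fh.write("tip\tgroup\n")
            for tip in self.true_tree.tip_labels:
                fh.write(f"{tip}\t{self.labeling.group_of(tip)}\n")
        with open(paths["truth"], "w") as fh:
            json.dump({
                "scenario": self.scenario.name,
                "A": self.scenario.A,
                "events": [
                    {"name": t.name, "height": t.height, "ratio": t.ratio,
                     "paralog_1": sorted(t.paralog_1),
                     "paralog_2": sorted(t.paralog_2)}
                    for t in self.truth],
            }, fh, indent=2)
        return paths


def simulate_family(scenario: WGDScenario) -> SimulatedFamily:
    """build_true_tree + evolve_alignment + truth/labeling assembly."""
    tree = build_true_tree(scenario)
    truth = scenario_truth(scenario, tree)
    if not truth:
        raise ScenarioError("scenario has no recoverable duplication event")
    subs_tree = tree.scale(scenario.clock_rate)  # time -> substitutions/site
    aln = evolve_alignment(subs_tree, scenario.resolved_model(),
                           scenario.sequence_length,
                           _stream_seed(scenario.seed, "evolve"),
                           scenario.rate_multipliers)
    primary = truth[0]
    tips = set(tree.tip_labels)
    labeling = ParalogLabeling(
        paralog_1=primary.paralog_1, paralog_2=primary.paralog_2,
        outgroup=frozenset([OUTGROUP_LABEL]),
        other=frozenset(tips) - primary.paralog_1 - primary.paralog_2
        - {OUTGROUP_LABEL})
    return SimulatedFamily(scenario=scenario, true_tree=tree, alignment=aln,
                           truth=truth, labeling=labeling)
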