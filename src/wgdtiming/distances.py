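"""Pairwise evolutionary distances with pairwise deletion of gap/ambiguous
columns, classic correction formulas, and an ML distance under an empirical
reversible substitution matrix (JTT shipped as packaged data).

Saturated pairs (correction formula leaving its domain, or the ML optimizer
hitting its upper bound) are flagged, never clipped: downstream NJ refuses
flagged matrices because silent clipping biases exactly the deep branches
the timing statistic divides by.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .data.jtt import JTT_EXCHANGEABILITIES, JTT_FREQUENCIES, JTT_STATE_ORDER
from .errors import SaturationError, UncomparablePairError
from .io_formats import (CORE_ALPHABET, DNA_STATES, Alignment,
                         Molecule, PROTEIN_STATES, SequenceRecord)

ML_BRACKET = (1e-6, 20.0)
ML_XATOL = 1e-6
_PURINES = {"A", "G"}


class CellStatus(str, enum.Enum):
    OK = "ok"
    SATURATED = "saturated"


class DistanceMethod(str, enum.Enum):
    P = "p"
    POISSON = "poisson"
    GAMMA = "gamma"
    KIMURA_PROTEIN = "kimura_protein"
    JC69 = "jc69"
    K2P = "k2p"
    ML_EMPIRICAL = "ml_empirical"


_PROTEIN_METHODS = {DistanceMethod.P, DistanceMethod.POISSON, DistanceMethod.GAMMA,
                    DistanceMethod.KIMURA_PROTEIN, DistanceMethod.ML_EMPIRICAL}
_DNA_METHODS = {DistanceMethod.P, DistanceMethod.POISSON, DistanceMethod.GAMMA,
                DistanceMethod.JC69, DistanceMethod.K2P, DistanceMethod.ML_EMPIRICAL}


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstitutionModelSpec:
    """A distance method plus, for ``ml_empirical``, the reversible rate
    matrix ingredients (symmetric exchangeabilities, equilibrium
    frequencies) and optional gamma rate-heterogeneity shape ``alpha``."""

    name: DistanceMethod
    alpha: float | None = None
    exchangeabilities: np.ndarray | None = None
    frequencies: np.ndarray | None = None
    states: str = PROTEIN_STATES

    def __post_init__(self):
        object.__setattr__(self, "name", DistanceMethod(self.name))
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("gamma shape alpha must be > 0")
        if self.name is DistanceMethod.ML_EMPIRICAL:
            if self.exchangeabilities is None or self.frequencies is None:
                raise ValueError("ml_empirical needs exchangeabilities and frequencies")
            k = len(self.states)
            s = np.asarray(self.exchangeabilities, dtype=float)
            pi = np.asarray(self.frequencies, dtype=float)
            if s.shape != (k, k):
                raise ValueError(f"exchangeability matrix must be {k}x{k}")
            if not np.allclose(s, s.T):
                raise ValueError("exchangeability matrix must be symmetric")
            if (s < 0).any() or (pi < 0).any():
                raise ValueError("exchangeabilities and frequencies must be >= 0")
            pi = pi / pi.sum()
            if abs(pi.sum() - 1.0) > 1e-12:
                raise ValueError("frequencies must sum to 1")
            object.__setattr__(self, "exchangeabilities", s)
            object.__setattr__(self, "frequencies", pi)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def rate_matrix(self) -> np.ndarray:
        """Reversible rate matrix Q with zero row sums, scaled so the
        expected substitution rate at equilibrium is 1."""
        s = self.exchangeabilities
        pi = self.frequencies
        q = s * pi[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    @cached_property
    def _eigensystem(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Eigendecomposition of the symmetrized rate matrix for fast P(t)."""
        pi = self.frequencies
        q = self.rate_matrix()
        rs = np.sqrt(pi)
        b = (q * rs[:, np.newaxis]) / rs[np.newaxis, :]
        lam, u = np.linalg.eigh((b + b.T) / 2.0)
        left = u.T * rs[np.newaxis, :]          # U^T . diag(sqrt pi)
        right = (u.T / rs[np.newaxis, :]).T     # diag(1/sqrt pi) . U
        return lam, right, left

    def transition_probabilities(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); for ``alpha`` set, averaged over 4 discrete
        equal-probability gamma rate categories."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        lam, right, left = self._eigensystem
        if self.alpha is None:
            rates: Iterable[float] = (1.0,)
        else:
            rates = discrete_gamma_rates(self.alpha, 4)
        p = np.zeros((self.n_states, self.n_states))
        rates = list(rates)
        for r in rates:
            p += (right * np.exp(lam * r * t)[np.newaxis, :]) @ left
        p /= len(rates)
        return np.clip(p, 0.0, None)


def jtt_model(alpha: float | None = None) -> SubstitutionModelSpec:
    """The JTT amino-acid replacement model with its published frequencies."""
    k = 20
    s = np.zeros((k, k))
    idx = 0
    for i in range(1, k):
        for j in range(i):
            s[i, j] = s[j, i] = JTT_EXCHANGEABILITIES[idx]
            idx += 1
    pi = np.array(JTT_FREQUENCIES, dtype=float)
    order = [JTT_STATE_ORDER.index(a) for a in PROTEIN_STATES]
    return SubstitutionModelSpec(DistanceMethod.ML_EMPIRICAL, alpha=alpha,
                                 exchangeabilities=s[np.ix_(order, order)],
                                 frequencies=pi[order], states=PROTEIN_STATES)


def uniform_model(molecule: Molecule | str = Molecule.PROTEIN,
                  alpha: float | None = None) -> SubstitutionModelSpec:
    """Equal exchangeabilities and frequencies (JC-type, 20 or 4 states)."""
    molecule = Molecule(molecule)
    states = PROTEIN_STATES if molecule is Molecule.PROTEIN else DNA_STATES
    k = len(states)
    s = np.ones((k, k)) - np.eye(k)
    pi = np.full(k, 1.0 / k)
    return SubstitutionModelSpec(DistanceMethod.ML_EMPIRICAL, alpha=alpha,
                                 exchangeabilities=s, frequencies=pi, states=states)


def model_spec(name: DistanceMethod | str, alpha: float | None = None,
               molecule: Molecule | str = Molecule.PROTEIN) -> SubstitutionModelSpec:
    """Convenience factory: closed-form methods carry no matrix; the
    ``ml_empirical`` name resolves to JTT for protein, uniform for DNA;
    ``ml_uniform`` forces the uniform (JC-type) ML model."""
    if name == "ml_uniform":
        return uniform_model(molecule, alpha=alpha)
    name = DistanceMethod(name)
    if name is DistanceMethod.ML_EMPIRICAL:
        if Molecule(molecule) is Molecule.PROTEIN:
            return jtt_model(alpha=alpha)
        return uniform_model(molecule, alpha=alpha)
    return SubstitutionModelSpec(name, alpha=alpha)


def discrete_gamma_rates(alpha: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability categories of a mean-1 gamma
    distribution (Yang's discrete-gamma construction)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    bounds = _gamma_dist.ppf(np.arange(ncat + 1) / ncat, a=alpha, scale=1.0 / alpha)
    upper = gammainc(alpha + 1.0, bounds[1:] * alpha)
    lower = gammainc(alpha + 1.0, bounds[:-1] * alpha)
    return ncat * (upper - lower)


# ---------------------------------------------------------------------------
# Column bookkeeping
# ---------------------------------------------------------------------------

def pairwise_valid_columns(a: SequenceRecord, b: SequenceRecord) -> list[int]:
    """Columns where neither sequence has a gap or ambiguity character
    (the per-pair "pairwise deletion" column set)."""
    if len(a) != len(b):
        raise ValueError("records are not aligned (unequal lengths)")
    if a.molecule is not b.molecule:
        raise ValueError("records have different molecule types")
    core = CORE_ALPHABET[a.molecule]
    cols = [i for i, (x, y) in enumerate(zip(a.residues, b.residues))
            if x in core and y in core]
    if not cols:
        raise UncomparablePairError([(a.id, b.id)])
    return cols


def p_distance(a: SequenceRecord, b: SequenceRecord,
               columns: Sequence[int] | None = None) -> float:
    """Observed proportion of differing residues over the valid columns."""
    cols = pairwise_valid_columns(a, b) if columns is None else columns
    diffs = sum(1 for i in cols if a.residues[i] != b.residues[i])
    return diffs / len(cols)


def transition_transversion_fractions(a: SequenceRecord, b: SequenceRecord
                                      ) -> tuple[float, float]:
    """(P, Q): transition and transversion mismatch fractions (DNA only)."""
    if a.molecule is not Molecule.DNA:
        raise ValueError("transition/transversion fractions need DNA records")
    cols = pairwise_valid_columns(a, b)
    ts = tv = 0
    for i in cols:
        x, y = a.residues[i], b.residues[i]
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    n = len(cols)
    return ts / n, tv / n


# ---------------------------------------------------------------------------
# Closed-form corrections
# ---------------------------------------------------------------------------

def correct_distance(p, method: DistanceMethod | str, alpha: float = 1.0) -> float:
    """Correct an observed difference proportion into substitutions/site.

    ``p`` is a scalar proportion, except for ``k2p`` where it is the
    ``(P, Q)`` transition/transversion pair.  Raises
    :class:`SaturationError` when the formula leaves its domain.
    """
    method = DistanceMethod(method)
    if method is DistanceMethod.K2P:
        ts, tv = p
        _check_fraction(ts)
        _check_fraction(tv)
        arg1 = 1.0 - 2.0 * ts - tv
        arg2 = 1.0 - 2.0 * tv
        if arg1 <= 0 or arg2 <= 0:
            raise SaturationError(f"k2p saturated at P={ts}, Q={tv}")
        return -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    _check_fraction(p)
    if method is DistanceMethod.P:
        return p
    if method is DistanceMethod.POISSON:
        if p >= 1.0:
            raise SaturationError(f"poisson saturated at p={p}")
        return -math.log1p(-p)
    if method is DistanceMethod.GAMMA:
        if alpha <= 0:
            raise ValueError("alpha must be > 0")
        if p >= 1.0:
            raise SaturationError(f"gamma saturated at p={p}")
        return alpha * ((1.0 - p) ** (-1.0 / alpha) - 1.0)
    if method is DistanceMethod.KIMURA_PROTEIN:
        arg = 1.0 - p - 0.2 * p * p
        if arg <= 0:
            raise SaturationError(f"kimura_protein saturated at p={p}")
        return -math.log(arg)
    if method is DistanceMethod.JC69:
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0:
            raise SaturationError(f"jc69 saturated at p={p}")
        return -0.75 * math.log(arg)
    raise ValueError(f"{method.value} has no closed-form correction")


def _check_fraction(p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"proportion out of [0, 1]: {p}")


# ---------------------------------------------------------------------------
# ML distance under an empirical matrix
# ---------------------------------------------------------------------------

def ml_distance_empirical(a: SequenceRecord, b: SequenceRecord,
                          model: SubstitutionModelSpec) -> tuple[float, CellStatus]:
    """Maximum-likelihood pairwise distance under a reversible empirical
    model, maximizing sum over columns of log(pi_x * P_xy(t)) on the
    bracket [1e-6, 20].  Returns (distance, status); the status is
    ``saturated`` when the optimizer is pinned at the upper bound."""
    if model.name is not DistanceMethod.ML_EMPIRICAL:
        raise ValueError("ml_distance_empirical needs an ml_empirical model")
    cols = pairwise_valid_columns(a, b)
    counts = _pair_counts(a, b, cols, model.states)
    return _ml_from_counts(counts, model)


def _pair_counts(a: SequenceRecord, b: SequenceRecord,
                 cols: Sequence[int], states: str) -> np.ndarray:
    index = {s: i for i, s in enumerate(states)}
    k = len(states)
    counts = np.zeros((k, k))
    for i in cols:
        counts[index[a.residues[i]], index[b.residues[i]]] += 1.0
    return counts


def _ml_from_counts(counts: np.ndarray,
                    model: SubstitutionModelSpec) -> tuple[float, CellStatus]:
    pi = model.frequencies
    log_pi_rows = np.log(pi)[:, np.newaxis]
    if counts.sum() == 0:
        raise UncomparablePairError([("?", "?")])
    if np.trace(counts) == counts.sum():
        return ML_BRACKET[0], CellStatus.OK  # identical pair: optimizer floor

    def neg_ll(t: float) -> float:
        p = model.transition_probabilities(t)
        with np.errstate(divide="ignore"):
            ll = counts * (np.log(np.clip(p, 1e-300, None)) + log_pi_rows)
        return -ll.sum()

    res = minimize_scalar(neg_ll, bounds=ML_BRACKET, method="bounded",
                          options={"xatol": ML_XATOL})
    d = float(res.x)
    if d >= ML_BRACKET[1] - 1e-3 and neg_ll(ML_BRACKET[1]) <= neg_ll(d) + 1e-9:
        return ML_BRACKET[1], CellStatus.SATURATED
    return d, CellStatus.OK


# ---------------------------------------------------------------------------
# Identity and matrix assembly
# ---------------------------------------------------------------------------

def percent_identity(a: SequenceRecord, b: SequenceRecord,
                     region: tuple[int, int] | None = None) -> float:
    """100 x (1 - p_distance) restricted to a half-open column interval."""
    if region is not None:
        start, stop = region
        if not (0 <= start < stop <= len(a)):
            raise ValueError(f"region {region} outside alignment of length {len(a)}")
        a = SequenceRecord(a.id, a.molecule, a.residues[start:stop])
        b = SequenceRecord(b.id, b.molecule, b.residues[start:stop])
    return 100.0 * (1.0 - p_distance(a, b))


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with per-cell saturation flags."""

    labels: list[str]
    values: np.ndarray
    saturated: np.ndarray  # boolean mask, symmetric, False on diagonal

    def __post_init__(self):
        n = len(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        self.saturated = np.asarray(self.saturated, dtype=bool)
        if self.values.shape != (n, n) or self.saturated.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.array_equal(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be exactly symmetric")
        if (np.diag(self.values) != 0).any() or np.diag(self.saturated).any():
            raise ValueError("diagonal must be 0 and unflagged")
        ok = ~self.saturated
        if not np.isfinite(self.values[ok]).all() or (self.values[ok] < 0).any():
            raise ValueError("ok cells must be finite and >= 0")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def has_saturation(self) -> bool:
        return bool(self.saturated.any())

    def status(self, i: int, j: int) -> CellStatus:
        return CellStatus.SATURATED if self.saturated[i, j] else CellStatus.OK

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_phylip(self, precision: int = 6) -> str:
        lines = [f" {self.n}"]
        for i, lbl in enumerate(self.labels):
            row = " ".join(f"{v:.{precision}f}" for v in self.values[i])
            lines.append(f"{lbl:<10s} {row}")
        return "\n".join(lines) + "\n"

    def to_tsv(self, precision: int = 6) -> str:
        lines = ["seq_a\tseq_b\tdistance\tstatus"]
        for i in range(self.n):
            for j in range(i + 1, self.n):
                lines.append("\t".join([
                    self.labels[i], self.labels[j],
                    f"{self.values[i, j]:.{precision}f}",
                    self.status(i, j).value,
                ]))
        return "\n".join(lines) + "\n"


def distance_matrix(alignment: Alignment,
                    model: SubstitutionModelSpec) -> DistanceMatrix:
    """All-pairs distances with pairwise deletion; saturated cells are
    flagged.  Raises :class:`UncomparablePairError` listing every pair
    without a single shared valid column."""
    method = model.name
    allowed = (_PROTEIN_METHODS if alignment.molecule is Molecule.PROTEIN
               else _DNA_METHODS)
    if method not in allowed:
        raise ValueError(
            f"method {method.value!r} not applicable to {alignment.molecule.value}")
    n = len(alignment)
    values = np.zeros((n, n))
    flags = np.zeros((n, n), dtype=bool)
    bad_pairs: list[tuple[str, str]] = []
    recs = alignment.records
    for i in range(n):
        for j in range(i + 1, n):
            a, b = recs[i], recs[j]
            try:
                d, sat = _pair_distance(a, b, model)
            except UncomparablePairError:
                bad_pairs.append((a.id, b.id))
                continue
            values[i, j] = values[j, i] = d
            flags[i, j] = flags[j, i] = sat
    if bad_pairs:
        raise UncomparablePairError(bad_pairs)
    return DistanceMatrix(list(alignment.ids), values, flags)


def _pair_distance(a: SequenceRecord, b: SequenceRecord,
                   model: SubstitutionModelSpec) -> tuple[float, bool]:
    if model.name is DistanceMethod.ML_EMPIRICAL:
        d, status = ml_distance_empirical(a, b, model)
        return d, status is CellStatus.SATURATED
    alpha = model.alpha if model.alpha is not None else 1.0
    if model.name is DistanceMethod.K2P:
        obs = transition_transversion_fractions(a, b)
    else:
        obs = p_distance(a, b)
    try:
        return correct_distance(obs, model.name, alpha=alpha), False
    except SaturationError:
        return float("nan"), True
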