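"""Genetic code, codon alignments, codon frequencies and reversible rate matrices.

The machinery here underlies every dN/dS computation in the package: a fixed
ordering of the 61 sense codons, Muse/Goldman–Yang style rate matrices
``q_ij = pi_j * {1, kappa, omega, omega*kappa}`` for single-nucleotide codon
changes, and transition probabilities ``P(t) = exp(Q t)`` computed through the
symmetrized eigendecomposition that time-reversibility affords.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("cladeshift")

NUCLEOTIDES = "ACGT"
#: Purine/pyrimidine partners: A<->G and C<->T changes are transitions.
_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}

#: Floor applied to stationary frequencies so Q stays irreducible.
FREQ_FLOOR = 1e-10


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino acid table with a fixed ordering of sense codons.

    Sense codons are ordered lexicographically over the alphabet A,C,G,T with
    stop codons removed; this ordering is the coordinate system for every
    frequency vector and rate matrix in the package.
    """

    name: str
    codon_to_aa: dict[str, str]  # 64 entries; stops map to "*"
    sense_codons: tuple[str, ...]

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c, aa in sorted(self.codon_to_aa.items()) if aa == "*")

    @property
    def n_sense(self) -> int:
        return len(self.sense_codons)

    def index(self, codon: str) -> int:
        return self._index_map()[codon]

    def _index_map(self) -> dict[str, int]:
        # cached on the instance via __dict__ despite frozen dataclass
        m = self.__dict__.get("_idx")
        if m is None:
            m = {c: i for i, c in enumerate(self.sense_codons)}
            object.__setattr__(self, "_idx", m)
        return m

    def is_synonymous(self, codon_a: str, codon_b: str) -> bool:
        return self.codon_to_aa[codon_a] == self.codon_to_aa[codon_b]


@lru_cache(maxsize=None)
def build_genetic_code(name: str = "standard") -> GeneticCode:
    """Build a :class:`GeneticCode` by name ("standard" only, at present)."""
    if name != "standard":
        raise ValueError(f"unknown genetic code: {name!r} (supported: 'standard')")
    table = CodonTable.unambiguous_dna_by_name["Standard"]
    codon_to_aa: dict[str, str] = {}
    for a in NUCLEOTIDES:
        for b in NUCLEOTIDES:
            for c in NUCLEOTIDES:
                codon = a + b + c
                if codon in table.stop_codons:
                    codon_to_aa[codon] = "*"
                else:
                    codon_to_aa[codon] = table.forward_table[codon]
    sense = tuple(c for c in sorted(codon_to_aa) if codon_to_aa[c] != "*")
    return GeneticCode(name=name, codon_to_aa=codon_to_aa, sense_codons=sense)


@lru_cache(maxsize=None)
def _code_masks(name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(single_step, is_transition, is_synonymous) boolean 61x61 masks."""
    code = build_genetic_code(name)
    n = code.n_sense
    single = np.zeros((n, n), dtype=bool)
    transi = np.zeros((n, n), dtype=bool)
    synon = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(code.sense_codons):
        for j, cj in enumerate(code.sense_codons):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            single[i, j] = True
            transi[i, j] = frozenset((ci[k], cj[k])) in _TRANSITION_PAIRS
            synon[i, j] = code.is_synonymous(ci, cj)
    return single, transi, synon


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

class Alignment:
    """A rectangular nucleotide alignment (gaps allowed), FASTA-backed."""

    def __init__(self, names: Sequence[str], seqs: Sequence[str]):
        if len(names) != len(seqs):
            raise ValueError("names and seqs must have equal length")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if list(names).count(n) > 1})
            raise ValueError(f"duplicate sequence names: {dup}")
        seqs = [s.upper() for s in seqs]
        if seqs and len({len(s) for s in seqs}) != 1:
            raise ValueError("sequences have unequal lengths; not an alignment")
        self.names = list(names)
        self.seqs = list(seqs)

    @property
    def n_seqs(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def sequence(self, name: str) -> str:
        return self.seqs[self.names.index(name)]

    def subset(self, names: Iterable[str]) -> "Alignment":
        keep = list(names)
        idx = {n: i for i, n in enumerate(self.names)}
        return type(self)(keep, [self.seqs[idx[n]] for n in keep])

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences found in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(s), id=n, description="") for n, s in zip(self.names, self.seqs)]
        SeqIO.write(records, str(path), "fasta")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.names == other.names
            and self.seqs == other.seqs
        )

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.n_seqs} seqs x {self.length} columns>"


class CodonAlignment(Alignment):
    """An in-frame codon alignment: length divisible by 3.

    Gapped alignments are accepted (the filtering cascade works on them); the
    numeric codon matrix used by the likelihood machinery requires a gap- and
    stop-free alignment and raises otherwise, naming the offending sequence
    and codon column.
    """

    def __init__(self, names: Sequence[str], seqs: Sequence[str],
                 code: GeneticCode | None = None):
        super().__init__(names, seqs)
        if self.length % 3 != 0:
            raise ValueError(
                f"alignment length {self.length} is not divisible by 3"
            )
        self.code = code or build_genetic_code("standard")
        self._matrix: np.ndarray | None = None

    @property
    def n_codons(self) -> int:
        return self.length // 3

    def codon(self, seq_index: int, codon_index: int) -> str:
        return self.seqs[seq_index][3 * codon_index: 3 * codon_index + 3]

    @property
    def is_gap_free(self) -> bool:
        return not any("-" in s for s in self.seqs)

    def codon_matrix(self) -> np.ndarray:
        """(n_seqs, n_codons) int array of sense-codon indices."""
        if self._matrix is None:
            idx = self.code._index_map()
            mat = np.empty((self.n_seqs, self.n_codons), dtype=np.int32)
            for i, (name, seq) in enumerate(zip(self.names, self.seqs)):
                for s in range(self.n_codons):
                    codon = seq[3 * s: 3 * s + 3]
                    j = idx.get(codon)
                    if j is None:
                        kind = "stop codon" if self.code.codon_to_aa.get(codon) == "*" \
                            else "gap/ambiguous codon"
                        raise ValueError(
                            f"{kind} {codon!r} in sequence {name!r} at codon column "
                            f"{s + 1}"
                        )
                    mat[i, s] = j
            self._matrix = mat
        return self._matrix


# ---------------------------------------------------------------------------
# Codon frequencies
# ---------------------------------------------------------------------------

@dataclass
class CodonFrequencies:
    """Stationary sense-codon frequencies under the F3X4 or Fcodon scheme."""

    scheme: str  # "F3X4" | "Fcodon"
    pi: np.ndarray  # over sense codons, sums to 1
    position_nuc_freqs: np.ndarray | None = None  # 3x4, F3X4 only
    code: GeneticCode = field(default_factory=lambda: build_genetic_code("standard"))

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (self.code.n_sense,):
            raise ValueError("pi must have one entry per sense codon")
        if np.any(self.pi < 0):
            raise ValueError("negative codon frequency")
        floored = self.pi < FREQ_FLOOR
        if floored.any():
            logger.info("flooring %d zero/near-zero codon frequencies at %g",
                        int(floored.sum()), FREQ_FLOOR)
            self.pi = np.maximum(self.pi, FREQ_FLOOR)
        self.pi = self.pi / self.pi.sum()


def f3x4_frequencies(position_nuc_freqs: np.ndarray,
                     code: GeneticCode | None = None) -> CodonFrequencies:
    """F3X4: codon frequency proportional to the product of position-specific
    nucleotide frequencies, renormalized over sense codons after stop removal."""
    code = code or build_genetic_code("standard")
    f = np.asarray(position_nuc_freqs, dtype=float)
    if f.shape != (3, 4):
        raise ValueError("position_nuc_freqs must be 3x4 (positions x ACGT)")
    f = f / f.sum(axis=1, keepdims=True)
    nt_idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
    pi = np.array([
        f[0, nt_idx[c[0]]] * f[1, nt_idx[c[1]]] * f[2, nt_idx[c[2]]]
        for c in code.sense_codons
    ])
    return CodonFrequencies("F3X4", pi / pi.sum(), position_nuc_freqs=f, code=code)


def estimate_frequencies(alignment: CodonAlignment, scheme: str = "F3X4") -> CodonFrequencies:
    """Estimate codon frequencies from a gap-free codon alignment.

    F3X4 counts nucleotides separately at the three codon positions; Fcodon
    uses the observed sense-codon proportions directly.
    """
    if alignment.n_seqs == 0 or alignment.n_codons == 0:
        raise ValueError("empty alignment")
    mat = alignment.codon_matrix()  # validates gap/stop-free
    code = alignment.code
    if scheme == "Fcodon":
        counts = np.bincount(mat.ravel(), minlength=code.n_sense).astype(float)
        return CodonFrequencies("Fcodon", counts / counts.sum(), code=code)
    if scheme == "F3X4":
        nt_idx = {n: i for i, n in enumerate(NUCLEOTIDES)}
        pos_counts = np.zeros((3, 4))
        for seq in alignment.seqs:
            for k in range(3):
                for nt in seq[k::3]:
                    pos_counts[k, nt_idx[nt]] += 1
        return f3x4_frequencies(pos_counts, code=code)
    raise ValueError(f"unknown frequency scheme: {scheme!r}")


# ---------------------------------------------------------------------------
# Rate matrices and transition probabilities
# ---------------------------------------------------------------------------

@dataclass
class CodonRateMatrix:
    """Unscaled reversible codon rate matrix with cached eigendecomposition.

    ``Q`` has zero row sums and satisfies detailed balance
    ``pi_i q_ij = pi_j q_ji``; time is rescaled externally (a shared mixture
    scale factor set by the model) so that branch lengths are expected
    substitutions per codon.
    """

    Q: np.ndarray
    pi: np.ndarray
    kappa: float
    omega: float
    scale_factor: float = 1.0

    def __post_init__(self):
        self._decomp: tuple | None = None

    @property
    def expected_rate(self) -> float:
        """Total substitution flux -sum_i pi_i q_ii (unscaled)."""
        return float(-np.dot(self.pi, np.diag(self.Q)))

    def _eig(self):
        if self._decomp is None:
            sq = np.sqrt(self.pi)
            B = (self.Q * sq[:, None]) / sq[None, :]
            B = 0.5 * (B + B.T)  # symmetrize away rounding noise
            lam, U = np.linalg.eigh(B)
            left = U.T * sq[None, :]        # U^T D^{1/2}
            right = (U.T / sq[None, :]).T   # D^{-1/2} U
            self._decomp = (lam, right, left)
        return self._decomp

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q * t * scale_factor), a stochastic matrix."""
        if t < 0:
            raise ValueError(f"negative branch length: {t}")
        lam, right, left = self._eig()
        P = (right * np.exp(lam * t * self.scale_factor)) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def build_rate_matrix(freqs: CodonFrequencies, kappa: float, omega: float) -> CodonRateMatrix:
    """Goldman–Yang style codon rate matrix.

    Off-diagonal rates for single-nucleotide codon changes are
    ``pi_j * {1, kappa, omega, omega*kappa}`` for synonymous transversions,
    synonymous transitions, nonsynonymous transversions and nonsynonymous
    transitions; multi-step changes are instantaneous-rate zero.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be positive, got {kappa}")
    if omega < 0:
        raise ValueError(f"omega must be non-negative, got {omega}")
    single, transi, synon = _code_masks(freqs.code.name)
    factor = np.where(transi, kappa, 1.0) * np.where(synon, 1.0, omega)
    Q = np.where(single, factor * freqs.pi[None, :], 0.0)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return CodonRateMatrix(Q=Q, pi=freqs.pi.copy(), kappa=kappa, omega=omega)


def substitution_flux(freqs: CodonFrequencies, kappa: float, omega: float) -> tuple[float, float]:
    """(total, synonymous) expected substitution flux of the unscaled matrix."""
    single, transi, synon = _code_masks(freqs.code.name)
    factor = np.where(transi, kappa, 1.0) * np.where(synon, 1.0, omega)
    R = np.where(single, factor * freqs.pi[None, :], 0.0)
    flux = freqs.pi[:, None] * R
    return float(flux.sum()), float(flux[synon].sum())
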