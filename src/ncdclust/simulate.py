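"""Synthetic genome evolution under eleven classical genomic operators.

Descendant genomes are derived from random ancestral genomes by repeated
application of the operators that drive genomic variability: crossing
over, mutation, translocation, insertion, deletion, transposition,
inversion, repetition, symmetrization, palindromization and circular
permutation.  Clades are sets of descendants of a common ancestor; each
descendant receives a Poisson-distributed number of events per operator.
Because none of the operators are given formal definitions in the
clustering literature that motivates them, the definitions used here
follow standard genome-rearrangement usage:

- mutation: single-base substitution to a different base
- insertion / deletion: a random segment inserted / an existing segment removed
- inversion: a segment replaced by its reverse complement
- repetition: tandem duplication of a segment in place
- translocation: a segment excised and reinserted elsewhere
- transposition: a segment copied elsewhere (original kept)
- symmetrization: a segment replaced by its mirror (reversal, no complement)
- palindromization: a segment followed by its own reverse complement
- circular permutation: the whole sequence rotated by a random offset
- crossing over: exchange of suffixes with a partner genome at a random point

The default rates are moderate: enough events that descendants of
different ancestors stay clearly more distant than descendants of the same
ancestor under a compression distance, which is the regime the clustering
pipeline is designed for.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .seqio import Sequence

__all__ = ["EvoConfig", "OPERATORS", "random_genome", "apply_operator", "simulate_phylogeny"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

OPERATORS: tuple[str, ...] = (
    "crossing_over",
    "mutation",
    "translocation",
    "insertion",
    "deletion",
    "transposition",
    "inversion",
    "repetition",
    "symmetrization",
    "palindromization",
    "circular_permutation",
)

#: Events per descendant genome under the default regime (20 kb genomes):
#: ~0.5% point substitutions plus a handful of each structural event.
DEFAULT_RATES: dict[str, float] = {
    "crossing_over": 1.0,
    "mutation": 100.0,
    "translocation": 2.0,
    "insertion": 2.0,
    "deletion": 2.0,
    "transposition": 2.0,
    "inversion": 2.0,
    "repetition": 2.0,
    "symmetrization": 1.0,
    "palindromization": 1.0,
    "circular_permutation": 1.0,
}


@dataclasses.dataclass(frozen=True)
class EvoConfig:
    """Configuration of a simulated radiation from common ancestors."""

    n_ancestors: int = 3
    clade_size: int = 8
    genome_length: int = 20_000
    operator_rates: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_RATES)
    )
    segment_length: tuple[int, int] = (50, 500)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ancestors < 1 or self.clade_size < 1:
            raise ValueError("n_ancestors and clade_size must be >= 1")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        unknown = set(self.operator_rates) - set(OPERATORS)
        if unknown:
            raise ValueError(f"unknown operators: {sorted(unknown)}")
        if any(r < 0 for r in self.operator_rates.values()):
            raise ValueError("operator rates must be non-negative")
        lo, hi = self.segment_length
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid segment length range {self.segment_length}")


def random_genome(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform ACGT genome of the given length."""
    if length < 1:
        raise ValueError("genome length must be >= 1")
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _segment(n: int, seg_range: tuple[int, int], rng: np.random.Generator) -> tuple[int, int]:
    """Random (start, length) of a segment that fits inside a length-n genome."""
    lo, hi = seg_range
    length = min(int(rng.integers(lo, hi + 1)), n)
    start = int(rng.integers(0, n - length + 1))
    return start, length


def apply_operator(
    seq: str,
    op_name: str,
    rng: np.random.Generator,
    seg_range: tuple[int, int] = (50, 500),
    partner: str | None = None,
) -> str | tuple[str, str]:
    """Apply one genomic operator to *seq* and return the derived sequence.

    ``crossing_over`` is binary: it needs a *partner* and returns the pair
    of recombinants ``(new_seq, new_partner)``.  All other operators are
    unary and return a single string.
    """
    n = len(seq)
    if op_name not in OPERATORS:
        raise ValueError(f"unknown operator {op_name!r}")
    if op_name == "crossing_over":
        if partner is None:
            raise ValueError("crossing_over requires a partner sequence")
        point = int(rng.integers(1, n)) if n > 1 else 0
        point2 = min(point, len(partner))
        return seq[:point] + partner[point2:], partner[:point2] + seq[point:]
    if op_name == "mutation":
        i = int(rng.integers(0, n))
        alternatives = [b for b in "ACGT" if b != seq[i]]
        return seq[:i] + alternatives[int(rng.integers(0, len(alternatives)))] + seq[i + 1 :]
    if op_name == "circular_permutation":
        off = int(rng.integers(0, n))
        return seq[off:] + seq[:off]
    if op_name == "insertion":
        start = int(rng.integers(0, n + 1))
        lo, hi = seg_range
        length = int(rng.integers(lo, hi + 1))
        return seq[:start] + random_genome(length, rng) + seq[start:]
    start, length = _segment(n, seg_range, rng)
    if length > n:
        raise ValueError(f"segment length {length} exceeds sequence length {n}")
    seg = seq[start : start + length]
    rest = seq[:start] + seq[start + length :]
    if op_name == "deletion":
        return rest if rest else seq  # never delete the whole genome
    if op_name == "inversion":
        return seq[:start] + _revcomp(seg) + seq[start + length :]
    if op_name == "symmetrization":
        return seq[:start] + seg[::-1] + seq[start + length :]
    if op_name == "repetition":
        return seq[:start] + seg + seg + seq[start + length :]
    if op_name == "palindromization":
        return seq[: start + length] + _revcomp(seg) + seq[start + length :]
    if op_name == "translocation":
        dest = int(rng.integers(0, len(rest) + 1))
        return rest[:dest] + seg + rest[dest:]
    if op_name == "transposition":
        dest = int(rng.integers(0, n + 1))
        return seq[:dest] + seg + seq[dest:]
    raise AssertionError(op_name)


def simulate_phylogeny(config: EvoConfig | None = None) -> tuple[list[Sequence], dict[str, int]]:
    """Simulate clades of descendants from independent random ancestors.

    Returns the shuffled list of descendant sequences (ids carry no clade
    information) and the ground-truth map from id to clade index.  Each
    descendant starts as a copy of its clade's ancestor and receives
    ``Poisson(rate)`` events of every operator, applied in a randomized
    order; crossing over recombines the descendant with a fresh copy of the
    ancestor, keeping the descendant lineage inside its clade.
    Deterministic for a fixed seed.
    """
    config = config or EvoConfig()
    rng = np.random.default_rng(config.seed)
    ancestors = [random_genome(config.genome_length, rng) for _ in range(config.n_ancestors)]
    genomes: list[str] = []
    clades: list[int] = []
    for clade_i, anc in enumerate(ancestors):
        for _ in range(config.clade_size):
            g = anc
            events: list[str] = []
            for op in OPERATORS:
                rate = config.operator_rates.get(op, 0.0)
                events.extend([op] * int(rng.poisson(rate)))
            order = rng.permutation(len(events))
            for k in order:
                op = events[int(k)]
                if op == "crossing_over":
                    g, _ = apply_operator(g, op, rng, config.segment_length, partner=anc)
                else:
                    g = apply_operator(g, op, rng, config.segment_length)
            genomes.append(g)
            clades.append(clade_i)
    # shuffle so that ids encode nothing about the truth
    perm = rng.permutation(len(genomes))
    width = len(str(len(genomes) - 1))
    seqs = [
        Sequence(f"g{str(i).zfill(width)}", genomes[int(k)]) for i, k in enumerate(perm)
    ]
    truth = {f"g{str(i).zfill(width)}": clades[int(k)] for i, k in enumerate(perm)}
    return seqs, truth
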