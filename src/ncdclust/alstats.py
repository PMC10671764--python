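"""Pentamer-enrichment z-statistics against the AL ancestral RNA ring.

The AL ring is a 22-base candidate ancestral RNA whose hairpin head
fragments into a small set of pentamers.  Given a nucleotide sequence of
length n, the statistic counts the occurrences O of those pentamers over
the P = n - 4 sliding windows and standardizes against a binomial null:

    E = P * p,   sigma = sqrt(P * p * (1 - p)),   z = (O - E) / sigma

Two parameter modes are provided.  ``"printed"`` keeps the published
constants exactly as printed: a set of ten pentamers with p = 9/1024 (the
source text says "nine pentamers" but prints ten — both are preserved so
published values can be approached).  ``"consistent"`` sets
p = |pentamers| / 1024, which makes the null well-calibrated and is what
the statistical property tests use.

AL-pair statistics extend this to amino acids: every ordered pair of codon
start offsets on the circular ring at most ``max_span`` nucleotides apart
defines an AL-pair of translated residues; successive residue pairs of a
protein are then scored against this pair set under a binomial null.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter

import numpy as np
from Bio.Seq import Seq

from .seqio import Sequence

__all__ = [
    "AL_PENTAMERS",
    "AL_RING",
    "AL_RING_22",
    "ALParams",
    "ALResult",
    "count_pentamer_hits",
    "al_proximity",
    "al_proximity_profile",
    "enumerate_al_pairs",
    "al_pair_statistic",
    "ALPairReport",
]

#: The published AL pentamer set (ten 5-mers, DNA alphabet).
AL_PENTAMERS: frozenset[str] = frozenset(
    {
        "ATTCA", "TTCAA", "TCAAG", "CAAGA", "AAGAT",
        "AGATG", "GATGA", "AATGA", "ATGAA", "TGAAT",
    }
)

#: The AL ring exactly as printed (23 characters, DNA-normalized; contains
#: an anomalous extra T).
AL_RING: str = "AATGGTACTTGCCATTCAAGATG"

#: The 22-mer with the anomalous T removed, matching the derived ring length.
AL_RING_22: str = "AATGGTACTGCCATTCAAGATG"

_PURINES = {"A", "G"}


def _degenerate_image(pentamer: str) -> str:
    """Purine/pyrimidine family image: R = A/G, Y = C/T, swapped within family."""
    swap = {"A": "G", "G": "A", "C": "T", "T": "C"}
    return "".join(swap[c] for c in pentamer)


@dataclasses.dataclass(frozen=True)
class ALParams:
    """Parameters of the pentamer-proximity statistic.

    mode : "printed" keeps the printed p = 9/1024 with the ten printed
        pentamers; "consistent" sets p = |pentamers|/1024.
    circular : scan all n start positions on a circular sequence instead of
        the n - 4 linear windows.
    degenerate : additionally match each pentamer's purine/pyrimidine
        family image (off by default).
    """

    pentamers: frozenset[str] = AL_PENTAMERS
    mode: str = "printed"
    circular: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("printed", "consistent"):
            raise ValueError(f"mode must be 'printed' or 'consistent', got {self.mode!r}")
        for pent in self.pentamers:
            if len(pent) != 5:
                raise ValueError(f"pentamer {pent!r} does not have length 5")

    @property
    def match_set(self) -> frozenset[str]:
        if not self.degenerate:
            return self.pentamers
        return self.pentamers | {_degenerate_image(p) for p in self.pentamers}

    @property
    def p(self) -> float:
        if self.mode == "printed":
            return 9 / 1024
        return len(self.match_set) / 1024


@dataclasses.dataclass(frozen=True)
class ALResult:
    """Observed/expected pentamer counts and the standardized z-score."""

    O: int
    P: int
    E: float
    sigma: float
    z: float


def count_pentamer_hits(seq: Sequence | str, params: ALParams | None = None) -> int:
    """Number of window start positions whose 5-mer is in the pentamer set.

    Linear mode scans the n - 4 windows ``[0, n-5]``; circular mode scans
    all n starts with wraparound.  Overlapping matches all count.
    """
    params = params or ALParams()
    s = seq.residues if isinstance(seq, Sequence) else seq
    n = len(s)
    if params.circular:
        if n < 1:
            raise ValueError("empty sequence")
        text = s + s[:4]
        starts = n
    else:
        if n < 5:
            raise ValueError(f"sequence length {n} < 5: no pentamer window exists")
        text = s
        starts = n - 4
    match = params.match_set
    return sum(1 for i in range(starts) if text[i : i + 5] in match)


def al_proximity(seq: Sequence | str, params: ALParams | None = None) -> ALResult:
    """Pentamer-proximity z-score of a sequence under the binomial null."""
    params = params or ALParams()
    s = seq.residues if isinstance(seq, Sequence) else seq
    n = len(s)
    P = n if params.circular else n - 4
    if P < 1:
        raise ValueError(f"sequence length {n} leaves no window: statistic undefined")
    O = count_pentamer_hits(s, params)
    p = params.p
    E = P * p
    sigma = float(np.sqrt(P * p * (1 - p)))
    return ALResult(O=O, P=P, E=E, sigma=sigma, z=(O - E) / sigma)


def al_proximity_profile(
    seq: Sequence | str,
    window: int,
    step: int | None = None,
    params: ALParams | None = None,
) -> list[tuple[int, float]]:
    """Sliding-window z-profile: ``[(start, z), ...]`` over half-open
    0-based windows of the given length.

    A window longer than the sequence yields an empty list with a warning;
    a step beyond the sequence end leaves just the leading window.
    """
    if window < 5:
        raise ValueError("window must be at least 5")
    step = step or window
    s = seq.residues if isinstance(seq, Sequence) else seq
    n = len(s)
    if window > n:
        warnings.warn(f"window {window} exceeds sequence length {n}: empty profile")
        return []
    out = []
    for start in range(0, n - window + 1, step):
        res = al_proximity(s[start : start + window], params)
        out.append((start, res.z))
    return out


# ---------------------------------------------------------------------------
# AL-pair (amino-acid) statistics

def _translate_codon(codon: str) -> str:
    aa = str(Seq(codon).translate())
    return aa  # Biopython renders STOP as '*'


def enumerate_al_pairs(
    ring: Sequence | str, max_span: int = 12
) -> Counter[tuple[str, str, int]]:
    """All ordered AL-pairs ``(aa_i, aa_j, span)`` on the circular ring.

    A codon starts at every offset of the circular ring; for each ordered
    offset pair (i, j) with ``1 <= (j - i) mod n <= max_span`` the pair of
    translated codons is emitted with its span.  STOP codons appear as
    ``'*'``.  The multiset has exactly ``n * max_span`` entries.
    """
    s = ring.residues if isinstance(ring, Sequence) else ring
    n = len(s)
    if n == 0:
        raise ValueError("empty ring")
    ring3 = s + s  # enough wraparound for codons and spans <= n
    codons = [_translate_codon((ring3 + ring3)[i : i + 3]) for i in range(n)]
    pairs: Counter[tuple[str, str, int]] = Counter()
    for i in range(n):
        for span in range(1, max_span + 1):
            j = (i + span) % n
            pairs[(codons[i], codons[j], span)] += 1
    return pairs


@dataclasses.dataclass(frozen=True)
class ALPairReport:
    """Binomial z-report of AL-pair content in a protein sequence."""

    O: int
    P: int
    E: float
    sigma: float
    z: float
    matched: tuple[tuple[int, str, str, tuple[int, ...]], ...]
    n_distinct_pairs: int


_AA = set("ACDEFGHIKLMNPQRSTVWY")
# unordered pairs with identity over the 20 amino acids
_N_UNORDERED_PAIRS = 20 * 21 // 2


def al_pair_statistic(
    protein: Sequence | str,
    ring: Sequence | str = AL_RING_22,
    max_span: int = 12,
) -> ALPairReport:
    """Score successive residue pairs of a protein against the AL-pair set.

    O counts positions whose unordered successive-residue pair occurs among
    the ring's AL-pairs (STOP-containing pairs can never match).  The null
    is binomial with p = (distinct unordered AL amino-acid pairs) / 210,
    210 being the number of unordered amino-acid pairs with identity.
    """
    aa_seq = protein.residues if isinstance(protein, Sequence) else protein
    if len(aa_seq) < 2:
        raise ValueError("protein must have at least 2 residues")
    bad = set(aa_seq) - _AA
    if bad:
        raise ValueError(f"non-amino-acid symbols in protein: {sorted(bad)}")
    ring_pairs = enumerate_al_pairs(ring, max_span)
    spans_by_pair: dict[frozenset[str] | tuple[str, str], set[int]] = {}
    for (a, b, span), _count in ring_pairs.items():
        if a == "*" or b == "*":
            continue
        key = tuple(sorted((a, b)))
        spans_by_pair.setdefault(key, set()).add(span)
    n_distinct = len(spans_by_pair)
    p = n_distinct / _N_UNORDERED_PAIRS
    P = len(aa_seq) - 1
    matched = []
    O = 0
    for i in range(P):
        key = tuple(sorted((aa_seq[i], aa_seq[i + 1])))
        if key in spans_by_pair:
            O += 1
            matched.append((i, aa_seq[i], aa_seq[i + 1], tuple(sorted(spans_by_pair[key]))))
    E = P * p
    sigma = float(np.sqrt(P * p * (1 - p)))
    z = (O - E) / sigma if sigma > 0 else float("nan")
    return ALPairReport(O, P, E, sigma, z, tuple(matched), n_distinct)
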