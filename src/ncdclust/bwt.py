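"""Reversible Burrows-Wheeler transform over cyclic rotations, plus the
run-length serialization whose octet length is the compressor cost.

The transform here is the *cyclic* (sentinel-free) variant: the n rotations
of the input are sorted lexicographically, the last character of each sorted
rotation forms the transformed string F, and the 0-based rank s of the
original rotation makes the pair (F, s) exactly invertible.  Run-length
encoding then serializes F as the decimal rank followed by an explicit
decimal count and character for every run (a count of 1 is written out), so
the cost of a run is ``digits(count) + 1`` octets and the total cost is
``digits(s) + sum(digits(count_i) + 1)``.

Rotation sorting uses prefix doubling (Manber-Myers) on numpy arrays, which
handles multi-megabase genomes; a naive rotation-sort oracle for testing
lives in the test suite.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "BWTResult",
    "RLEString",
    "bwt_forward",
    "bwt_inverse",
    "rle_encode",
    "rle_decode",
    "compressed_length",
]

# below this length plain Python rotation sort beats numpy setup cost
_SMALL_N = 48


@dataclasses.dataclass(frozen=True)
class BWTResult:
    """Transformed string F plus the rank s of the original rotation.

    ``s`` is the 0-based index of the input among its lexicographically
    sorted rotations; for periodic inputs (duplicate rotations) it is the
    smallest sorted index holding the original rotation.
    """

    F: str
    s: int

    def __post_init__(self) -> None:
        if not self.F:
            raise ValueError("BWT of an empty string is undefined")
        if not 0 <= self.s < len(self.F):
            raise ValueError(f"rank s={self.s} out of range for |F|={len(self.F)}")


@dataclasses.dataclass(frozen=True)
class RLEString:
    """Run-length serialization of a BWT result.

    ``runs`` is an ordered list of ``(count, symbol)`` with adjacent symbols
    distinct; ``serialized`` is the decimal rank followed by decimal count +
    symbol for every run; ``octet_length`` is its character count.
    """

    runs: tuple[tuple[int, str], ...]
    s: int

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("RLEString needs at least one run")
        for count, sym in self.runs:
            if count < 1:
                raise ValueError(f"run count must be positive, got {count}")
            if len(sym) != 1:
                raise ValueError(f"run symbol must be one character, got {sym!r}")
        for (_, a), (_, b) in zip(self.runs, self.runs[1:]):
            if a == b:
                raise ValueError("adjacent runs must have distinct symbols")

    @property
    def serialized(self) -> str:
        return str(self.s) + "".join(f"{c}{sym}" for c, sym in self.runs)

    @property
    def octet_length(self) -> int:
        return len(str(self.s)) + sum(len(str(c)) + 1 for c, _ in self.runs)


def _sort_rotations_small(S: str) -> list[int]:
    n = len(S)
    SS = S + S
    return sorted(range(n), key=lambda i: (SS[i : i + n], i))


def _sort_rotations_numpy(S: str) -> np.ndarray:
    """Order of rotation start offsets by prefix doubling on the cyclic string."""
    n = len(S)
    codes = np.frombuffer(S.encode("latin-1"), dtype=np.uint8).astype(np.int64)
    _, rank = np.unique(codes, return_inverse=True)
    k = 1
    idx = np.arange(n)
    while k < n:
        second = rank[(idx + k) % n]
        order = np.lexsort((second, rank))
        pair = np.stack([rank[order], second[order]])
        new_rank = np.empty(n, dtype=np.int64)
        changed = np.empty(n, dtype=bool)
        changed[0] = True
        changed[1:] = (pair[0, 1:] != pair[0, :-1]) | (pair[1, 1:] != pair[1, :-1])
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:  # all distinct
            break
        k *= 2
    # periodic strings leave ties; break by start offset for a stable order
    return np.lexsort((idx, rank))


def bwt_forward(S: str) -> BWTResult:
    """Burrows-Wheeler transform of *S* over its cyclic rotations.

    Returns the last column F of the sorted rotation matrix together with
    the rank of the original rotation.  Raises ``ValueError`` on the empty
    string.
    """
    n = len(S)
    if n == 0:
        raise ValueError("cannot transform an empty string")
    if n <= _SMALL_N:
        order = _sort_rotations_small(S)
        F = "".join(S[(i - 1) % n] for i in order)
        s = order.index(0)
        return BWTResult(F, s)
    order = _sort_rotations_numpy(S)
    codes = np.frombuffer(S.encode("latin-1"), dtype=np.uint8)
    F = codes[(order - 1) % n].tobytes().decode("latin-1")
    s = int(np.nonzero(order == 0)[0][0])
    return BWTResult(F, s)


def bwt_inverse(r: BWTResult) -> str:
    """Reconstruct the original string from (F, s) by LF-mapping.

    Equal characters keep their relative order (stable sort), which makes
    the inversion insensitive to the rank convention for periodic strings.
    """
    F, s = r.F, r.s
    n = len(F)
    codes = np.frombuffer(F.encode("latin-1"), dtype=np.uint8)
    T = np.argsort(codes, kind="stable")
    out = bytearray(n)
    j = s
    for i in range(n):
        j = int(T[j])
        out[i] = codes[j]
    return out.decode("latin-1")


def rle_encode(r: BWTResult) -> RLEString:
    """Run-length encode a BWT result (explicit count for every run)."""
    runs: list[tuple[int, str]] = []
    F = r.F
    i = 0
    while i < len(F):
        j = i
        while j < len(F) and F[j] == F[i]:
            j += 1
        runs.append((j - i, F[i]))
        i = j
    return RLEString(tuple(runs), r.s)


def rle_decode(e: RLEString) -> BWTResult:
    """Expand runs back into the transformed string (exact inverse of
    :func:`rle_encode`)."""
    F = "".join(sym * count for count, sym in e.runs)
    return BWTResult(F, e.s)


def parse_rle(text: str, n: int) -> RLEString:
    """Parse serialized RLE text given the original sequence length *n*.

    The serialization writes the rank and the first run count as adjacent
    decimal digits, so the split is recovered by requiring the run counts to
    sum to *n* and the rank to be a valid rotation index.  Raises
    ``ValueError`` if no split (or more than one) is consistent.
    """
    candidates: list[RLEString] = []
    for cut in range(1, len(text)):
        head = text[:cut]
        if not head.isdigit():
            break
        s = int(head)
        if s >= n:
            continue
        runs = _parse_runs(text[cut:])
        if runs is not None and sum(c for c, _ in runs) == n:
            try:
                candidates.append(RLEString(tuple(runs), s))
            except ValueError:
                continue
    if not candidates:
        raise ValueError(f"cannot parse RLE text {text!r} for length {n}")
    if len(candidates) > 1:
        raise ValueError(f"ambiguous RLE text {text!r} for length {n}")
    return candidates[0]


def _parse_runs(body: str) -> list[tuple[int, str]] | None:
    runs: list[tuple[int, str]] = []
    i = 0
    while i < len(body):
        j = i
        while j < len(body) and body[j].isdigit():
            j += 1
        if j == i or j >= len(body):
            return None
        runs.append((int(body[i:j]), body[j]))
        i = j + 1
    return runs or None


def compressed_length(S: str) -> int:
    """Octet length of RLE(BWT(S)) — the compressor's cost function C(S).

    Computed without materializing the serialized text: digits of the rank
    plus ``digits(count) + 1`` per run.
    """
    if not S:
        raise ValueError("cannot compress an empty string")
    r = bwt_forward(S)
    codes = np.frombuffer(r.F.encode("latin-1"), dtype=np.uint8)
    boundaries = np.nonzero(np.diff(codes))[0]
    starts = np.concatenate(([0], boundaries + 1))
    ends = np.concatenate((boundaries + 1, [len(codes)]))
    counts = ends - starts
    digits = np.floor(np.log10(counts)).astype(int) + 1
    return len(str(r.s)) + int(np.sum(digits + 1))
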