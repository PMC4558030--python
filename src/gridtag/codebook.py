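"""Encoding and enumeration of 25-bit parity-checked fiducial tag codes.

A tag is a 5x5 binary matrix (1 = white, 0 = black) carrying a 15-bit
identity (an integer 1..32767) and a 10-bit error check.  The identity bits
occupy a 5x3 block, the check bits the remaining 5x2 block.  The check is
built from five parity bits over fixed cell groups of the identity block —
its three columns and its first-3/last-2 row groups — and the five bits are
then repeated in reverse to give ten.  Because every identity bit sits in
one column group and one row group, and each check bit appears twice,
single-module read errors are always detected (never corrected).

Tags are printed and photographed at unknown orientation, so a usable code
must self-check in exactly one of its four 90-degree rotations, and a usable
code *set* additionally requires a minimum Hamming distance between any
candidate and every rotation of every code already in the set.  The exact
bit-layout conventions below (fill order, check placement, parity groups)
are frozen project-wide; they are the calibration that makes the enumerated
set sizes reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

GRID = 5
ID_BITS = 15
CHECK_BITS = 10
N_IDS = (1 << ID_BITS) - 1        # 32767 usable identities (0 is reserved)
ID_SPACE = 1 << ID_BITS           # 32768 raw 15-bit combinations
LAYOUT_VERSION = 1

# Parity groups over the identity bit string (index 0 = most significant).
# The identity block is filled column-major, so bits 0-4 are its first
# column, 5-9 the second, 10-14 the third; stride-5 index sets are its
# rows.  The five check bits are, in their fixed order: parity of column 2,
# column 1, rows 1-3, column 3, rows 4-5 of the 5x3 block.  This ordering
# is part of the calibrated convention: together with the fill orders below
# it reproduces both published code-set sizes (7,515 and 110) exactly.
_PARITY_GROUPS: tuple[tuple[int, ...], ...] = (
    (5, 6, 7, 8, 9),                      # column 2
    (0, 1, 2, 3, 4),                      # column 1
    (0, 1, 2, 5, 6, 7, 10, 11, 12),       # rows 1-3
    (10, 11, 12, 13, 14),                 # column 3
    (3, 4, 8, 9, 13, 14),                 # rows 4-5
)

# Cell positions (row, col) of identity bit i and check bit j in the 5x5:
# both blocks fill column-major, so the second check column is the first
# one mirrored vertically (c10 = c5 followed by reversed c5).
_ID_CELLS = [(i % 5, i // 5) for i in range(ID_BITS)]
_CHECK_CELLS = [(j % 5, 3 + j // 5) for j in range(CHECK_BITS)]

_ID_ROWS = np.array([rc[0] for rc in _ID_CELLS])
_ID_COLS = np.array([rc[1] for rc in _ID_CELLS])
_CK_ROWS = np.array([rc[0] for rc in _CHECK_CELLS])
_CK_COLS = np.array([rc[1] for rc in _CHECK_CELLS])
_POW25 = (1 << np.arange(25, dtype=np.uint64)).astype(np.uint32)


def _check_id(tag_id: int) -> int:
    tag_id = int(tag_id)
    if not 1 <= tag_id <= N_IDS:
        raise ValueError(f"tag id must be in 1..{N_IDS}, got {tag_id}")
    return tag_id


def _id_bits(ids: np.ndarray) -> np.ndarray:
    """(N, 15) identity bits, most significant first."""
    return ((ids[:, None] >> np.arange(ID_BITS - 1, -1, -1)) & 1).astype(np.uint8)


def _check_from_bits(bits15: np.ndarray) -> np.ndarray:
    """(N, 10) check bits from (N, 15) identity bits."""
    c5 = np.stack([(bits15[:, list(g)].sum(axis=1) & 1).astype(np.uint8)
                   for g in _PARITY_GROUPS], axis=1)
    return np.concatenate([c5, c5[:, ::-1]], axis=1)


def _matrices_for_ids(ids: np.ndarray) -> np.ndarray:
    """(N, 5, 5) canonical tag matrices for an array of identities."""
    bits15 = _id_bits(ids)
    c10 = _check_from_bits(bits15)
    full = np.zeros((len(ids), GRID, GRID), dtype=np.uint8)
    full[:, _ID_ROWS, _ID_COLS] = bits15
    full[:, _CK_ROWS, _CK_COLS] = c10
    return full


def _parity_pass(mats: np.ndarray) -> np.ndarray:
    """(N,) bool: does each 5x5 satisfy the parity self-check as-is?"""
    bits15 = mats[:, _ID_ROWS, _ID_COLS]
    c10 = mats[:, _CK_ROWS, _CK_COLS]
    return (c10 == _check_from_bits(bits15)).all(axis=1)


def _pack(mats: np.ndarray) -> np.ndarray:
    """(N,) uint32: each 5x5 packed row-major into 25 bits."""
    return mats.reshape(len(mats), 25).astype(np.uint32) @ _POW25


def id_to_data_matrix(tag_id: int) -> np.ndarray:
    """Place the 15-bit identity of ``tag_id`` into its 5x3 data matrix.

    The binary expansion is left-padded to 15 bits and fills the block
    column-major, most significant bit at the top-left; the least
    significant bit lands in the bottom-right cell.
    """
    tag_id = _check_id(tag_id)
    return _id_bits(np.array([tag_id]))[0].reshape(3, 5).T


def parity_check_bits(data: np.ndarray) -> np.ndarray:
    """10-bit error check of a 5x3 data matrix.

    The first five bits are parities (1 = odd, 0 = even) of fixed cell
    groups of the matrix — its three columns interleaved with its
    first-3-rows and last-2-rows groups, in the calibrated order — and
    bits 6-10 repeat bits 1-5 in reverse.
    """
    data = np.asarray(data)
    if data.shape != (5, 3):
        raise ValueError(f"data matrix must be 5x3, got {data.shape}")
    if not np.isin(data, (0, 1)).all():
        raise ValueError("data matrix cells must be 0 or 1")
    return _check_from_bits(data.T.reshape(1, 15))[0]


@dataclass(frozen=True)
class TagCode:
    """One tag: identity, 25-bit sequence, and canonical 5x5 matrix."""
    id: int
    bits: tuple[int, ...]
    matrix: np.ndarray

    def __post_init__(self):
        if len(self.bits) != 25:
            raise ValueError("a tag code has exactly 25 bits")
        if tuple(int(b) for b in self.matrix.reshape(25)) != self.bits:
            raise ValueError("bits and matrix are inconsistent")

    @property
    def bit_string(self) -> str:
        return "".join(str(b) for b in self.bits)


def assemble_tag(tag_id: int) -> TagCode:
    """Build the canonical tag for ``tag_id`` (identity plus error check)."""
    tag_id = _check_id(tag_id)
    matrix = _matrices_for_ids(np.array([tag_id]))[0]
    return TagCode(tag_id, tuple(int(b) for b in matrix.reshape(25)), matrix)


def disassemble(matrix: np.ndarray) -> int:
    """Read the identity encoded in the 5x3 block of a canonical matrix."""
    matrix = np.asarray(matrix)
    bits15 = matrix[_ID_ROWS, _ID_COLS].astype(np.uint64)
    return int(bits15 @ (1 << np.arange(ID_BITS - 1, -1, -1, dtype=np.uint64)))


def rotate_tag(matrix: np.ndarray, k: int) -> np.ndarray:
    """Rotate a 5x5 matrix by k quarter turns counter-clockwise."""
    return np.rot90(np.asarray(matrix), k % 4)


class MatrixValidation(NamedTuple):
    """Outcome of the orientation-uniqueness self-check."""
    valid: bool
    orientation: int | None    # quarter turns (CCW) to canonical, if valid
    id: int | None


def validate_matrix(matrix: np.ndarray) -> MatrixValidation:
    """Check the parity self-test in all four rotations.

    A matrix is valid only when the check passes in exactly one rotation;
    symmetric patterns (e.g. all-zero) pass in several and are rejected, as
    are patterns passing in none.
    """
    matrix = np.asarray(matrix, dtype=np.uint8)
    if matrix.shape != (GRID, GRID):
        raise ValueError(f"matrix must be 5x5, got {matrix.shape}")
    passing = [k for k in range(4)
               if _parity_pass(rotate_tag(matrix, k)[None])[0]]
    if len(passing) != 1:
        return MatrixValidation(False, None, None)
    k = passing[0]
    return MatrixValidation(True, k, disassemble(rotate_tag(matrix, k)))


def min_rotational_hamming(a, b) -> int:
    """Minimum Hamming distance between ``a`` and any rotation of ``b``.

    Accepts TagCode or raw 5x5 matrices.  Symmetric in its arguments: a
    shared rotation leaves bit disagreements unchanged, so rotating either
    operand explores the same set of relative orientations.
    """
    ma = a.matrix if isinstance(a, TagCode) else np.asarray(a, dtype=np.uint8)
    mb = b.matrix if isinstance(b, TagCode) else np.asarray(b, dtype=np.uint8)
    pa = _pack(ma[None])[0]
    rb = np.stack([rotate_tag(mb, k) for k in range(4)])
    return int(np.bitwise_count(_pack(rb) ^ pa).min())


@dataclass
class Codebook:
    """Ordered set of tag codes with a minimum rotational Hamming distance."""
    codes: list[TagCode]
    min_hamming: int = 0
    _by_id: dict[int, TagCode] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._by_id = {c.id: c for c in self.codes}
        if len(self._by_id) != len(self.codes):
            raise ValueError("duplicate ids in codebook")

    @property
    def ids(self) -> list[int]:
        return [c.id for c in self.codes]

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self):
        return iter(self.codes)

    def __contains__(self, tag_id: int) -> bool:
        return int(tag_id) in self._by_id

    def __getitem__(self, tag_id: int) -> TagCode:
        return self._by_id[int(tag_id)]

    def subset(self, n: int) -> "Codebook":
        """The first ``n`` codes (scan order is preserved)."""
        return Codebook(self.codes[:n], self.min_hamming)


def enumerate_codebook(min_hamming: int = 3,
                       id_range: tuple[int, int] = (1, N_IDS)) -> Codebook:
    """Enumerate the usable code set by an ascending greedy scan.

    Identities are scanned in ascending order.  A candidate is kept iff
    (a) its matrix self-checks in exactly one of the four rotations, and
    (b) its canonical bits are at Hamming distance >= ``min_hamming`` from
    all four rotations of every previously kept code.  With
    ``min_hamming=0`` the distance filter is inactive and the result is
    exactly the uniquely-orientable codes.
    """
    if min_hamming < 0:
        raise ValueError(f"min_hamming must be >= 0, got {min_hamming}")
    lo, hi = int(id_range[0]), int(id_range[1])
    lo = max(lo, 1)
    hi = min(hi, N_IDS)
    if hi < lo:
        return Codebook([], min_hamming)

    ids = np.arange(lo, hi + 1)
    mats = _matrices_for_ids(ids)
    passes = np.zeros(len(ids), dtype=np.int64)
    for k in range(4):
        passes += _parity_pass(np.rot90(mats, k, axes=(1, 2)))
    uniq = passes == 1
    ids, mats = ids[uniq], mats[uniq]

    if min_hamming > 0:
        rots = np.stack([_pack(np.rot90(mats, k, axes=(1, 2)))
                         for k in range(4)], axis=1)
        can = rots[:, 0]
        pool = np.empty(4 * len(can), dtype=np.uint32)
        n_pool = 0
        keep = []
        for i in range(len(can)):
            if (n_pool == 0 or
                    int(np.bitwise_count(pool[:n_pool] ^ can[i]).min()) >= min_hamming):
                pool[n_pool:n_pool + 4] = rots[i]
                n_pool += 4
                keep.append(i)
        ids, mats = ids[keep], mats[keep]

    codes = [TagCode(int(i), tuple(int(b) for b in m.reshape(25)), m)
             for i, m in zip(ids, mats)]
    return Codebook(codes, min_hamming)


def save_codebook(cb: Codebook, path: str | Path) -> None:
    """Write a codebook as CSV: header ``id,bits`` plus ``#`` metadata lines."""
    path = Path(path)
    lines = [f"# gridtag codebook, layout_version={LAYOUT_VERSION}",
             f"# min_hamming={cb.min_hamming}",
             "id,bits"]
    lines += [f"{c.id},{c.bit_string}" for c in cb.codes]
    path.write_text("\n".join(lines) + "\n")


def load_codebook(path: str | Path) -> Codebook:
    """Read a codebook file, re-validating every code.

    Raises ``ValueError`` naming the offending line for malformed rows,
    bit strings that fail their own parity check, or duplicate ids.
    """
    path = Path(path)
    min_hamming = 0
    codes: list[TagCode] = []
    seen: set[int] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "min_hamming=" in line:
                min_hamming = int(line.split("min_hamming=")[1])
            continue
        if line == "id,bits":
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id,bits', got {raw!r}")
        try:
            tag_id = int(parts[0])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: bad id {parts[0]!r}") from None
        bits = parts[1].strip()
        if len(bits) != 25 or set(bits) - {"0", "1"}:
            raise ValueError(f"{path}:{lineno}: bits must be 25 chars of 0/1")
        if tag_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate id {tag_id}")
        matrix = np.array([int(b) for b in bits], dtype=np.uint8).reshape(5, 5)
        if not _parity_pass(matrix[None])[0]:
            raise ValueError(f"{path}:{lineno}: parity check fails for id {tag_id}")
        if disassemble(matrix) != tag_id:
            raise ValueError(f"{path}:{lineno}: bits decode to id "
                             f"{disassemble(matrix)}, not {tag_id}")
        seen.add(tag_id)
        codes.append(TagCode(tag_id, tuple(int(b) for b in bits), matrix))
    return Codebook(codes, min_hamming)
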