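"""Independent brute-force reference for the codebook enumeration.

Everything here is plain Python on nested lists and ints — no numpy, no
shared code with the package — and rotations/parities are recomputed from
scratch at every step.  Used to cross-check the vectorised enumeration on a
prefix of the id range.
"""

GROUPS = [
    [5, 6, 7, 8, 9],                      # column 2 of the 5x3 data block
    [0, 1, 2, 3, 4],                      # column 1
    [0, 1, 2, 5, 6, 7, 10, 11, 12],       # rows 1-3
    [10, 11, 12, 13, 14],                 # column 3
    [3, 4, 8, 9, 13, 14],                 # rows 4-5
]


def tag_matrix(tag_id):
    bits = [int(ch) for ch in format(tag_id, "015b")]
    c5 = [sum(bits[i] for i in g) % 2 for g in GROUPS]
    c10 = c5 + c5[::-1]
    # identity bits fill columns 0-2 top-to-bottom, check bits columns 3-4
    rows = []
    for r in range(5):
        rows.append([bits[r], bits[5 + r], bits[10 + r],
                     c10[r], c10[5 + r]])
    return rows


def rot90(mat):
    """One quarter turn counter-clockwise (as displayed)."""
    return [[mat[c][4 - r] for c in range(5)] for r in range(5)]


def parity_ok(mat):
    bits = [mat[r][c] for c in range(3) for r in range(5)]
    check = [mat[r][3 + c] for c in range(2) for r in range(5)]
    c5 = [sum(bits[i] for i in g) % 2 for g in GROUPS]
    return check == c5 + c5[::-1]


def unique_orientation(mat):
    n_pass = 0
    m = [row[:] for row in mat]
    for _ in range(4):
        if parity_ok(m):
            n_pass += 1
        m = rot90(m)
    return n_pass == 1


def pack(mat):
    v = 0
    for r in range(5):
        for c in range(5):
            v = (v << 1) | mat[r][c]
    return v


def min_dist_to(mat, accepted_packed):
    best = 99
    me = pack(mat)
    for rots in accepted_packed:
        for r in rots:
            d = bin(me ^ r).count("1")
            best = min(best, d)
    return best


def enumerate_naive(min_hamming, id_max):
    kept = []
    accepted_packed = []
    for tag_id in range(1, id_max + 1):
        mat = tag_matrix(tag_id)
        if not unique_orientation(mat):
            continue
        if min_hamming > 0 and accepted_packed:
            if min_dist_to(mat, accepted_packed) < min_hamming:
                continue
        kept.append(tag_id)
        rots = []
        m = [row[:] for row in mat]
        for _ in range(4):
            rots.append(pack(m))
            m = rot90(m)
        accepted_packed.append(rots)
    return kept


def count_unique_naive(id_max):
    return sum(unique_orientation(tag_matrix(i)) for i in range(1, id_max + 1))
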