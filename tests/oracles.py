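"""Independent test oracles: Smith-Waterman local DP, brute-force k-mer
matching, ungapped identity, dinucleotide shuffle.

Kept deliberately naive and separate from the package implementation.
"""

from __future__ import annotations

import numpy as np


def smith_waterman_identity_positions(
    ref: str, test: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> set[int]:
    """Reference positions aligned to an identical test base in the best
    local alignment (linear gap penalty).

    Tie-breaking is deterministic: the end cell is the first maximum in
    row-major order; traceback prefers diagonal, then up, then left, and
    stops at the first zero cell.
    """
    n, m = len(ref), len(test)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        row = H[i]
        prev = H[i - 1]
        a = ref[i - 1]
        for j in range(1, m + 1):
            s = match if (a == test[j - 1] and a != "N") else mismatch
            row[j] = max(0, prev[j - 1] + s, prev[j] + gap, row[j - 1] + gap)
    end = np.unravel_index(np.argmax(H), H.shape)  # first max, row-major
    i, j = int(end[0]), int(end[1])
    ident: set[int] = set()
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if (ref[i - 1] == test[j - 1] and ref[i - 1] != "N") else mismatch
        if H[i, j] == max(0, H[i - 1, j - 1]) + s:
            if s == match:
                ident.add(i - 1)
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
    return ident


def brute_force_kmer_hits(ref: str, test: str, k: int) -> set[tuple[int, int, str]]:
    """All exact k-mer matches between ref and either strand of test, by
    quadratic enumeration.  Minus-strand test positions are in
    reverse-complement coordinates."""
    comp = str.maketrans("ACGTN", "TGCAN")
    rc = test.translate(comp)[::-1]
    hits = set()
    for i in range(len(ref) - k + 1):
        q = ref[i : i + k]
        if "N" in q:
            continue
        for strand, s in (("+", test), ("-", rc)):
            for j in range(len(s) - k + 1):
                if s[j : j + k] == q and "N" not in q:
                    hits.add((i, j, strand))
    return hits


def ungapped_identity_positions(ref: str, test: str) -> set[int]:
    """Positions identical under direct (no-indel) global comparison."""
    return {
        i for i, (a, b) in enumerate(zip(ref, test)) if a == b and a != "N"
    }


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Composition-preserving shuffle of non-overlapping dinucleotides."""
    pairs = [seq[i : i + 2] for i in range(0, len(seq) - 1, 2)]
    tail = seq[len(pairs) * 2 :]
    order = rng.permutation(len(pairs))
    return "".join(pairs[i] for i in order) + tail


def mutate_with_divergence(
    seq: str, p_sub: float, n_indels: int, rng: np.random.Generator,
    indel_max: int = 3,
) -> str:
    """Substitute at rate p_sub and apply up to n_indels short indels."""
    bases = "ACGT"
    chars = list(seq)
    for i in np.nonzero(rng.random(len(chars)) < p_sub)[0]:
        orig = bases.find(chars[i])
        chars[i] = bases[(orig + 1 + int(rng.integers(3))) % 4]
    for _ in range(n_indels):
        length = int(rng.integers(1, indel_max + 1))
        pos = int(rng.integers(10, max(11, len(chars) - 10)))
        if rng.random() < 0.5:
            del chars[pos : pos + length]
        else:
            chars[pos:pos] = [bases[b] for b in rng.integers(0, 4, size=length)]
    return "".join(chars)
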