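"""K-mer seeded, BLAT-style local alignment of a test sequence to a reference.

The pipeline is: exact k-mer seeding on both strands (default k of 9 and 11),
diagonal merging of seeds into ungapped runs, x-drop extension, chaining of
colinear blocks, and per-reference-base conservation calls.  All reference
coordinates are 0-based half-open; minus-strand test coordinates are reported
on the original (plus) orientation of the test sequence, so within a minus
chain the test intervals decrease as reference coordinates increase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from evofoot.seqio import SeqRecord, reverse_complement


@dataclass(frozen=True)
class AlignParams:
    """Tuning knobs for seeding, extension and chaining.

    Extension is ungapped with scores ``match_score``/``mismatch_score`` and
    terminates once the running score falls more than ``x_drop`` below its
    maximum; the block is trimmed back to the last strict improvement, which
    reproduces the end-trimming of a local (Smith-Waterman style) aligner on
    ungapped segments.
    """

    k_values: tuple[int, ...] = (9, 11)
    max_chain_gap: int = 500
    min_block_len: int = 6
    min_chain_matches: int = 20
    x_drop: int = 1
    match_score: int = 1
    mismatch_score: int = -1
    max_kmer_hits: int = 32  # seeds from k-mers more frequent than this are skipped
    max_block_overlap: int = 20  # chaining tolerates this much block overlap (trimmed)
    gap_score: int = -2  # linear gap penalty for the junction/end fill-in DP
    fill_max: int = 200  # junction gaps wider than this (either sequence) are left unfilled
    end_fill: int = 128  # how far chain-terminal DP refinement may look

    def __post_init__(self) -> None:
        if not self.k_values:
            raise ValueError("k_values must be non-empty")
        if any(k < 4 for k in self.k_values):
            raise ValueError(f"every seed length must be >= 4: {self.k_values}")
        for name in ("max_chain_gap", "min_block_len", "min_chain_matches", "x_drop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Seed:
    """An exact k-mer match; test_pos is in reverse-complement coordinates
    for minus-strand seeds."""

    ref_pos: int
    test_pos: int
    strand: str
    length: int


@dataclass(frozen=True)
class MatchBlock:
    """Ungapped aligned segment. Test coordinates are on the original test
    orientation regardless of strand; lengths on both sequences are equal."""

    ref_start: int
    ref_end: int
    test_start: int
    test_end: int
    strand: str
    n_ident: int

    def __post_init__(self) -> None:
        if self.ref_end - self.ref_start != self.test_end - self.test_start:
            raise ValueError("ungapped block must have equal ref and test lengths")
        if not (0 <= self.n_ident <= self.ref_end - self.ref_start):
            raise ValueError("n_ident out of range")

    def __len__(self) -> int:
        return self.ref_end - self.ref_start


@dataclass(frozen=True)
class ChainedAlignment:
    """Colinear same-strand blocks, non-overlapping and increasing on the
    reference; score is the total number of identical bases."""

    species_id: str
    blocks: tuple[MatchBlock, ...]
    strand: str
    score: int

    @property
    def ref_start(self) -> int:
        return self.blocks[0].ref_start

    @property
    def ref_end(self) -> int:
        return self.blocks[-1].ref_end


@dataclass(frozen=True)
class SpeciesMatch:
    """Per-reference-base conservation calls for one test species."""

    species_id: str
    conserved: np.ndarray  # bool, length = reference length
    chains: tuple[ChainedAlignment, ...]


def build_kmer_index(test: SeqRecord, k: int) -> dict[str, list[tuple[int, str]]]:
    """Index every overlapping k-mer of the test sequence and of its reverse
    complement.  Minus-strand positions are in reverse-complement coordinates.
    K-mers containing N are omitted."""
    seq = test.residues
    if k > len(seq):
        raise ValueError(f"k ({k}) exceeds test sequence length ({len(seq)})")
    index: dict[str, list[tuple[int, str]]] = {}
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((i, strand))
    return index


def find_seeds(
    ref: SeqRecord, index: dict[str, list[tuple[int, str]]], k: int,
    max_kmer_hits: int | None = None,
) -> list[Seed]:
    """Exact k-mer matches of the reference against both strands of the
    indexed test sequence.  Over-represented k-mers (more than
    ``max_kmer_hits`` index entries) are skipped as seeds."""
    seq = ref.residues
    seeds: list[Seed] = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        entries = index.get(kmer)
        if not entries:
            continue
        if max_kmer_hits is not None and len(entries) > max_kmer_hits:
            continue
        for pos, strand in entries:
            seeds.append(Seed(ref_pos=i, test_pos=pos, strand=strand, length=k))
    return seeds


def _merge_runs(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or abutting [start, end) intervals."""
    intervals.sort()
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _extend_run(
    ref: str, work: str, diag: int, start: int, end: int, params: AlignParams
) -> tuple[int, int]:
    """X-drop extend an exact run along its diagonal in both directions.

    The extension walks while the score stays within ``x_drop`` of its running
    maximum and trims back to the furthest strict improvement.  N matches
    nothing, including N.
    """
    match, mismatch, x_drop = params.match_score, params.mismatch_score, params.x_drop
    lo_work = diag  # work position of ref position 0 is ref_pos - diag
    # rightward
    score = best = 0
    best_end = end
    p = end
    while p < len(ref) and p - diag < len(work):
        a, b = ref[p], work[p - diag]
        score += match if (a == b and a != "N") else mismatch
        p += 1
        if score > best:
            best, best_end = score, p
        elif best - score > x_drop:
            break
    # leftward
    score = best = 0
    best_start = start
    p = start - 1
    while p >= 0 and p - diag >= 0:
        a, b = ref[p], work[p - diag]
        score += match if (a == b and a != "N") else mismatch
        if score > best:
            best, best_start = score, p
        elif best - score > x_drop:
            break
        p -= 1
    return best_start, best_end


def _count_ident(ref: str, work: str, diag: int, start: int, end: int) -> int:
    return sum(
        1
        for p in range(start, end)
        if ref[p] == work[p - diag] and ref[p] != "N"
    )


def _strand_blocks(
    ref: str, work: str, seeds: Iterable[Seed], params: AlignParams
) -> list[tuple[int, int, int, int]]:
    """Seeds -> merged, extended, scored blocks as (ref_start, ref_end, diag,
    n_ident) in working (strand-projected) coordinates."""
    by_diag: dict[int, list[tuple[int, int]]] = {}
    for s in seeds:
        by_diag.setdefault(s.ref_pos - s.test_pos, []).append(
            (s.ref_pos, s.ref_pos + s.length)
        )
    blocks: list[tuple[int, int, int, int]] = []
    for diag, runs in by_diag.items():
        extended = [
            _extend_run(ref, work, diag, s, e, params) for s, e in _merge_runs(runs)
        ]
        for s, e in _merge_runs(extended):
            if e - s >= params.min_block_len:
                blocks.append((s, e, diag, _count_ident(ref, work, diag, s, e)))
    return blocks


def _chain_blocks(
    blocks: list[tuple[int, int, int, int]], params: AlignParams
) -> list[list[tuple[int, int, int, int]]]:
    """Greedy best-chain extraction over a colinearity DP (score = total
    identities, overlaps penalized by their length)."""
    chains: list[list[tuple[int, int, int, int]]] = []
    remaining = sorted(blocks)
    while remaining:
        n = len(remaining)
        best_score = [0.0] * n
        prev = [-1] * n
        for i, (si, ei, di, idi) in enumerate(remaining):
            best_score[i] = idi
            for j in range(i):
                sj, ej, dj, idj = remaining[j]
                if sj >= si:
                    continue
                test_i, test_j_end = si - di, ej - dj
                ref_gap = si - ej
                test_gap = test_i - test_j_end
                overlap = max(-ref_gap, -test_gap, 0)
                if sj - dj >= test_i or test_j_end >= ei - di:
                    continue
                if test_gap < -params.max_block_overlap:
                    continue
                if ref_gap > params.max_chain_gap or test_gap > params.max_chain_gap:
                    continue
                if overlap > params.max_block_overlap:
                    continue
                cand = best_score[j] + idi - overlap
                if cand > best_score[i]:
                    best_score[i], prev[i] = cand, j
        end = int(np.argmax(best_score))
        chain_idx = []
        at = end
        while at != -1:
            chain_idx.append(at)
            at = prev[at]
        chain_idx.reverse()
        chains.append([remaining[i] for i in chain_idx])
        used = set(chain_idx)
        remaining = [b for i, b in enumerate(remaining) if i not in used]
    return chains


_PAD = 8  # anchor this many confidently aligned bases inside flanking blocks


def _dp_runs(
    a: str, b: str, params: AlignParams, anchored_end: bool, mirrored: bool = False
) -> tuple[list[tuple[int, int, int]], int]:
    """Align window ``a`` (reference side) against ``b`` with a linear-gap DP
    anchored at (0, 0).

    With ``anchored_end`` the alignment must consume both windows entirely
    (junction fill); otherwise it ends at the best-scoring cell, provided the
    score is positive (terminal extension).  Returns maximal diagonal runs as
    (a_start, a_end, diag) plus the path score.  Traceback prefers diagonal,
    then gap-in-b, then gap-in-a, mirroring a conventional local-DP
    traceback; with ``mirrored`` (windows fed in reversed) the preference
    order is flipped so gap placement matches the unreversed convention.
    """
    n, m = len(a), len(b)
    match, mismatch, gap = params.match_score, params.mismatch_score, params.gap_score
    NEG = -(10**9)
    H = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    H[0, 0] = 0
    H[0, 1:] = gap * np.arange(1, m + 1)
    H[1:, 0] = gap * np.arange(1, n + 1)
    for i in range(1, n + 1):
        ai = a[i - 1]
        prev, row = H[i - 1], H[i]
        for j in range(1, m + 1):
            s = match if (ai == b[j - 1] and ai != "N") else mismatch
            row[j] = max(prev[j - 1] + s, prev[j] + gap, row[j - 1] + gap)
    if anchored_end:
        ei, ej = n, m
    else:
        flat = int(np.argmax(H))  # first maximum in row-major order
        ei, ej = divmod(flat, m + 1)
        if H[ei, ej] <= 0:
            return [], 0
    score = int(H[ei, ej])
    runs: list[tuple[int, int, int]] = []
    i, j = ei, ej
    while i > 0 or j > 0:
        s = (
            match if (i > 0 and j > 0 and a[i - 1] == b[j - 1] and a[i - 1] != "N")
            else mismatch
        )
        can_diag = i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s
        can_up = i > 0 and H[i, j] == H[i - 1, j] + gap
        can_left = j > 0 and H[i, j] == H[i, j - 1] + gap
        if mirrored:
            step = "l" if can_left else ("u" if can_up else "d")
        else:
            step = "d" if can_diag else ("u" if can_up else "l")
        if step == "d":
            if runs and runs[-1][0] == i and runs[-1][2] == i - j:
                runs[-1] = (i - 1, runs[-1][1], i - j)
            else:
                runs.append((i - 1, i, i - j))
            i, j = i - 1, j - 1
        elif step == "u":
            i -= 1
        else:
            j -= 1
    runs.reverse()
    return runs, score


def _refine_chain(
    chain: list[tuple[int, int, int, int]], ref: str, work: str, params: AlignParams
) -> list[tuple[int, int, int]]:
    """DP fill-in at chain junctions and ends, in working coordinates.

    Junctions narrower than ``fill_max`` on both sequences are re-aligned
    between anchors placed ``_PAD`` bases inside the flanking blocks; chain
    ends are extended by a free-end DP bounded by ``end_fill``.  Wide gaps
    (divergent spacers) are intentionally left unaligned.
    """
    runs: list[tuple[int, int, int]] = []
    cut = chain[0][0]  # left boundary of the part of the current block kept as-is
    # left terminal extension
    s0, e0, d0 = chain[0][0], chain[0][1], chain[0][2]
    anchor = min(s0 + _PAD, e0)
    rl = max(0, anchor - params.end_fill)
    wl = max(0, anchor - d0 - params.end_fill)
    if anchor > 0 and anchor - d0 > 0:
        ext, score = _dp_runs(
            ref[rl:anchor][::-1], work[wl : anchor - d0][::-1], params,
            anchored_end=False, mirrored=True,
        )
        if ext:
            for a_s, a_e, diag in reversed(ext):
                runs.append((anchor - a_e, anchor - a_s, d0 - diag))
            cut = anchor
    for idx, (s, e, d, _) in enumerate(chain):
        left = max(cut, s)
        if idx + 1 < len(chain):
            s2, e2, d2 = chain[idx + 1][0], chain[idx + 1][1], chain[idx + 1][2]
            # window covers the inter-block region (or overlap) plus anchors
            a0 = max(left, min(e, s2) - _PAD)
            a1 = min(e2, max(e, s2) + _PAD)
            w0, w1 = a0 - d, a1 - d2
            if (
                a0 < a1 and w0 < w1
                and a1 - a0 <= params.fill_max + 2 * _PAD
                and w1 - w0 <= params.fill_max + 2 * _PAD
            ):
                if left < a0:
                    runs.append((left, a0, d))
                fill, _ = _dp_runs(ref[a0:a1], work[w0:w1], params, anchored_end=True)
                for f_s, f_e, f_d in fill:
                    runs.append((a0 + f_s, a0 + f_e, (a0 + f_s) - (w0 + f_s - f_d)))
                cut = a1
            else:
                if left < e:
                    runs.append((left, e, d))
                cut = -(10**12)
        else:
            # right terminal extension
            anchor = max(e - _PAD, left)
            if left < anchor:
                runs.append((left, anchor, d))
            rr = min(len(ref), anchor + params.end_fill)
            wr = min(len(work), anchor - d + params.end_fill)
            ext, score = _dp_runs(
                ref[anchor:rr], work[anchor - d : wr], params, anchored_end=False
            )
            if ext:
                for a_s, a_e, diag in ext:
                    runs.append((anchor + a_s, anchor + a_e, d + diag))
            elif anchor < e:
                runs.append((anchor, e, d))
    merged: list[tuple[int, int, int]] = []
    for r in runs:
        if r[0] >= r[1]:
            continue
        if merged and merged[-1][2] == r[2] and r[0] <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(r[1], merged[-1][1]), r[2])
        else:
            merged.append(r)
    return merged


def _materialize_chain(
    species_id: str,
    strand: str,
    runs: list[tuple[int, int, int]],
    ref: str,
    work: str,
    test_len: int,
) -> ChainedAlignment | None:
    """Trim overlaps, recompute identities and convert working coordinates to
    original test orientation."""
    blocks: list[MatchBlock] = []
    prev_ref_end = prev_work_end = -(10**12)
    total = 0
    for s, e, diag in runs:
        ws, we = s - diag, e - diag
        trim = max(prev_ref_end - s, prev_work_end - ws, 0)
        s, ws = s + trim, ws + trim
        if s >= e:
            continue
        n_ident = _count_ident(ref, work, diag, s, e)
        if strand == "+":
            t0, t1 = ws, we
        else:
            t0, t1 = test_len - we, test_len - ws
        blocks.append(
            MatchBlock(
                ref_start=s, ref_end=e, test_start=t0, test_end=t1,
                strand=strand, n_ident=n_ident,
            )
        )
        total += n_ident
        prev_ref_end, prev_work_end = e, we
    if not blocks:
        return None
    return ChainedAlignment(
        species_id=species_id, blocks=tuple(blocks), strand=strand, score=total
    )


def chain_and_extend(
    seeds: Sequence[Seed], ref: SeqRecord, test: SeqRecord, params: AlignParams
) -> list[ChainedAlignment]:
    """Merge seeds along diagonals, x-drop extend, and chain colinear blocks
    per strand.  Chains scoring below ``min_chain_matches`` identical bases
    are discarded; the result is sorted by score descending (ties: leftmost
    reference start, then plus strand first)."""
    rc = reverse_complement(test.residues)
    out: list[ChainedAlignment] = []
    for strand, work in (("+", test.residues), ("-", rc)):
        strand_seeds = [s for s in seeds if s.strand == strand]
        if not strand_seeds:
            continue
        blocks = _strand_blocks(ref.residues, work, strand_seeds, params)
        for chain in _chain_blocks(blocks, params):
            seeded_score = sum(b[3] for b in chain)
            if seeded_score < params.min_chain_matches:
                continue
            runs = _refine_chain(chain, ref.residues, work, params)
            ca = _materialize_chain(test.id, strand, runs, ref.residues, work, len(test))
            if ca is not None and ca.score >= params.min_chain_matches:
                out.append(ca)
    out.sort(key=lambda c: (-c.score, c.ref_start, c.strand != "+"))
    return out


def _work_pos(block: MatchBlock, test_len: int, ref_pos: int) -> int:
    """Working-strand test position aligned to ref_pos within the block."""
    offset = ref_pos - block.ref_start
    if block.strand == "+":
        return block.test_start + offset
    return (test_len - block.test_end) + offset


def align_species(
    ref: SeqRecord, test: SeqRecord, params: AlignParams | None = None
) -> SpeciesMatch:
    """Project one test species onto the reference.

    A reference base is conserved for the species iff it lies inside a block
    of a retained chain and the aligned test base is identical (N matches
    nothing).  Where chains overlap on the reference the higher-scoring chain
    claims the base (ties: lower reference start, then plus strand).
    """
    params = params or AlignParams()
    seeds: list[Seed] = []
    for k in params.k_values:
        if k > len(test):
            continue
        index = build_kmer_index(test, k)
        seeds.extend(find_seeds(ref, index, k, max_kmer_hits=params.max_kmer_hits))
    chains = chain_and_extend(seeds, ref, test, params)
    n = len(ref)
    conserved = np.zeros(n, dtype=bool)
    claimed = np.zeros(n, dtype=bool)
    rc = reverse_complement(test.residues)
    for chain in chains:  # already sorted best-first
        work = test.residues if chain.strand == "+" else rc
        for block in chain.blocks:
            for p in range(block.ref_start, block.ref_end):
                if claimed[p]:
                    continue
                claimed[p] = True
                t = work[_work_pos(block, len(test), p)]
                conserved[p] = ref.residues[p] == t and ref.residues[p] != "N"
    return SpeciesMatch(species_id=test.id, conserved=conserved, chains=tuple(chains))
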