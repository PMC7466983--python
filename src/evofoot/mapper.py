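"""Cross-taxon CSB mapping: presence, order/orientation and sharing.

Each reference CSB is aligned locally against both strands of a distant
target contig.  A qualifying match (identity and coverage above thresholds)
marks the CSB as ultraconserved in that taxon; order analysis over the best
match per CSB detects transpositions (lost colinearity) and minority-strand
matches (microinversions).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Sequence

from evofoot.align import AlignParams, Seed, build_kmer_index, chain_and_extend, find_seeds
from evofoot.csb import CSB
from evofoot.seqio import GenomicInterval, SeqRecord


@dataclass(frozen=True)
class UCSBMatch:
    csb_id: str
    target_id: str
    target_interval: GenomicInterval
    strand: str
    identity: float  # identical bases / aligned CSB bases
    coverage: float  # aligned CSB bases / CSB length

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"identity out of range: {self.identity}")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError(f"coverage out of range: {self.coverage}")


@dataclass(frozen=True)
class ColinearityReport:
    matches: tuple[UCSBMatch, ...]  # sorted by reference CSB start
    is_colinear: bool
    majority_strand: str
    inversions: tuple[str, ...]  # csb_ids on the minority strand
    missing: tuple[str, ...]  # csb_ids with no qualifying match


@dataclass(frozen=True)
class SharingTable:
    """Per-CSB presence across two distant targets."""

    categories: dict[str, str]  # csb_id -> both|target1_only|target2_only|neither

    def counts(self) -> dict[str, int]:
        c = Counter(self.categories.values())
        return {
            k: c.get(k, 0) for k in ("both", "target1_only", "target2_only", "neither")
        }


def map_csb(
    csb: CSB,
    target: SeqRecord,
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
    params: AlignParams | None = None,
) -> list[UCSBMatch]:
    """Local alignments of one CSB against both strands of a target contig.

    Returns qualifying matches best first (identity, then coverage, then
    leftmost target start).  An empty list means the CSB is absent.
    """
    params = params or AlignParams()
    if len(csb) < min(params.k_values):
        raise ValueError(
            f"CSB {csb.csb_id} ({len(csb)} bp) is shorter than the minimum "
            f"seed length {min(params.k_values)}"
        )
    if params.min_chain_matches > len(csb):
        # short queries can never reach the default chain threshold
        params = replace(params, min_chain_matches=len(csb))
    query = SeqRecord(id=csb.csb_id, residues=csb.residues)
    seeds: list[Seed] = []
    for k in params.k_values:
        if k > len(target) or k > len(query):
            continue
        index = build_kmer_index(target, k)
        seeds.extend(find_seeds(query, index, k, max_kmer_hits=params.max_kmer_hits))
    matches = []
    for chain in chain_and_extend(seeds, query, target, params):
        aligned = sum(len(b) for b in chain.blocks)
        if aligned == 0:
            continue
        identity = chain.score / aligned
        coverage = aligned / len(csb)
        if identity < min_identity or coverage < min_coverage:
            continue
        t_start = min(b.test_start for b in chain.blocks)
        t_end = max(b.test_end for b in chain.blocks)
        matches.append(
            UCSBMatch(
                csb_id=csb.csb_id,
                target_id=target.id,
                target_interval=GenomicInterval(target.id, t_start, t_end, chain.strand),
                strand=chain.strand,
                identity=identity,
                coverage=coverage,
            )
        )
    matches.sort(key=lambda m: (-m.identity, -m.coverage, m.target_interval.start))
    return matches


def best_matches(per_csb: dict[str, list[UCSBMatch]]) -> list[UCSBMatch]:
    """Retain one best match per CSB (identity, then coverage, then leftmost
    target start)."""
    best = []
    for csb_id, ms in per_csb.items():
        if not ms:
            continue
        best.append(
            min(ms, key=lambda m: (-m.identity, -m.coverage, m.target_interval.start))
        )
    return best


def analyze_colinearity(
    matches: Sequence[UCSBMatch], csbs: Sequence[CSB]
) -> ColinearityReport:
    """Order/orientation analysis of at most one match per CSB.

    Matches are sorted by reference CSB start; the majority strand is
    computed (tie goes to plus); colinearity requires the majority-strand
    target starts to be strictly monotone — increasing for a plus majority,
    decreasing for minus.  Minority-strand CSBs are reported as inversions.
    """
    ids = [m.csb_id for m in matches]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate csb_ids in matches: {dupes}")
    order = {c.csb_id: c.interval.start for c in csbs}
    unknown = [i for i in ids if i not in order]
    if unknown:
        raise ValueError(f"matches reference unknown csb_ids: {unknown}")
    ordered = tuple(sorted(matches, key=lambda m: order[m.csb_id]))
    missing = tuple(c.csb_id for c in csbs if c.csb_id not in set(ids))
    if not ordered:
        return ColinearityReport(
            matches=(), is_colinear=True, majority_strand="+",
            inversions=(), missing=missing,
        )
    n_plus = sum(1 for m in ordered if m.strand == "+")
    majority = "+" if n_plus >= len(ordered) - n_plus else "-"
    inversions = tuple(m.csb_id for m in ordered if m.strand != majority)
    starts = [m.target_interval.start for m in ordered if m.strand == majority]
    if majority == "-":
        starts = starts[::-1]
    is_colinear = all(a < b for a, b in zip(starts, starts[1:]))
    return ColinearityReport(
        matches=ordered,
        is_colinear=is_colinear,
        majority_strand=majority,
        inversions=inversions,
        missing=missing,
    )


def classify_sharing(
    csbs: Sequence[CSB],
    matches_t1: dict[str, list[UCSBMatch]],
    matches_t2: dict[str, list[UCSBMatch]],
) -> SharingTable:
    """Assign each CSB a two-target presence category."""
    categories = {}
    for c in csbs:
        in1 = bool(matches_t1.get(c.csb_id))
        in2 = bool(matches_t2.get(c.csb_id))
        categories[c.csb_id] = (
            "both" if in1 and in2
            else "target1_only" if in1
            else "target2_only" if in2
            else "neither"
        )
    return SharingTable(categories=categories)


def format_match_tsv(matches: Sequence[UCSBMatch]) -> str:
    lines = ["csb_id\ttarget_id\ttarget_start\ttarget_end\tstrand\tidentity\tcoverage"]
    for m in matches:
        lines.append(
            f"{m.csb_id}\t{m.target_id}\t{m.target_interval.start}\t"
            f"{m.target_interval.end}\t{m.strand}\t{m.identity:.4f}\t{m.coverage:.4f}"
        )
    return "\n".join(lines) + "\n"


def format_colinearity_summary(report: ColinearityReport) -> str:
    lines = [
        f"n_ucsbs\t{len(report.matches)}",
        f"is_colinear\t{str(report.is_colinear).lower()}",
        f"majority_strand\t{report.majority_strand}",
        f"n_inversions\t{len(report.inversions)}",
        f"inversions\t{','.join(report.inversions) or '.'}",
        f"missing\t{','.join(report.missing) or '.'}",
    ]
    return "\n".join(lines) + "\n"
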