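"""Conserved sequence block (CSB) calling and clustering.

CSBs are maximal uppercase runs of an evoprint mask, optionally bridged over
isolated single-base interruptions, filtered by a minimum length.  Clusters
group CSBs separated by at most G bp of spacer; long poorly conserved spacers
split clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from evofoot.conservation import EvoPrintResult
from evofoot.seqio import GenomicInterval


@dataclass(frozen=True)
class CallerParams:
    L_min: int = 10  # minimum CSB length (bp)
    G: int = 100  # maximum intra-cluster gap (bp)
    max_interruptions: int = 0  # isolated lowercase bases bridged per CSB

    def __post_init__(self) -> None:
        if self.L_min < 0 or self.G < 0 or self.max_interruptions < 0:
            raise ValueError("caller parameters must be non-negative")


@dataclass(frozen=True)
class CSB:
    csb_id: str
    interval: GenomicInterval
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != self.interval.span:
            raise ValueError("CSB residues must span the interval exactly")

    def __len__(self) -> int:
        return self.interval.span


@dataclass(frozen=True)
class CSBCluster:
    cluster_id: str
    csbs: tuple[CSB, ...]
    max_gap_allowed: int

    @property
    def start(self) -> int:
        return self.csbs[0].interval.start

    @property
    def end(self) -> int:
        return self.csbs[-1].interval.end

    @property
    def span(self) -> int:
        return self.end - self.start


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) intervals of consecutive True."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def call_csbs(ep: EvoPrintResult, params: CallerParams | None = None) -> list[CSB]:
    """Maximal conserved runs of length >= L_min, left to right.

    With ``max_interruptions`` > 0, up to that many isolated (single-base)
    lowercase interruptions are bridged into one CSB.
    """
    params = params or CallerParams()
    runs = _true_runs(np.asarray(ep.mask, dtype=bool))
    merged: list[tuple[int, int]] = []
    i = 0
    while i < len(runs):
        start, end = runs[i]
        used = 0
        while (
            i + 1 < len(runs)
            and runs[i + 1][0] - end == 1
            and used < params.max_interruptions
        ):
            used += 1
            end = runs[i + 1][1]
            i += 1
        merged.append((start, end))
        i += 1
    csbs = []
    for start, end in merged:
        if end - start >= params.L_min:
            csbs.append(
                CSB(
                    csb_id=f"csb_{len(csbs) + 1:04d}",
                    interval=GenomicInterval(ep.ref_id, start, end, "+"),
                    residues=ep.ref_residues[start:end],
                )
            )
    return csbs


def cluster_csbs(
    csbs: Sequence[CSB], params: CallerParams | None = None
) -> list[CSBCluster]:
    """Greedy left-to-right clustering: a gap greater than G bp between
    consecutive CSBs starts a new cluster."""
    params = params or CallerParams()
    starts = [c.interval.start for c in csbs]
    if starts != sorted(starts):
        raise ValueError("CSBs must be sorted by start position")
    clusters: list[list[CSB]] = []
    for c in csbs:
        if clusters and c.interval.start - clusters[-1][-1].interval.end <= params.G:
            clusters[-1].append(c)
        else:
            clusters.append([c])
    return [
        CSBCluster(
            cluster_id=f"cluster_{i + 1:04d}", csbs=tuple(group),
            max_gap_allowed=params.G,
        )
        for i, group in enumerate(clusters)
    ]


def csbs_to_bed_rows(csbs: Sequence[CSB]) -> list[tuple[GenomicInterval, str, int]]:
    """BED6 rows (interval, name, score=length) for CSB export."""
    return [(c.interval, c.csb_id, len(c)) for c in csbs]


def format_cluster_tsv(clusters: Sequence[CSBCluster]) -> str:
    lines = ["cluster_id\tn_csbs\tstart\tend\tspan"]
    for cl in clusters:
        lines.append(f"{cl.cluster_id}\t{len(cl.csbs)}\t{cl.start}\t{cl.end}\t{cl.span}")
    return "\n".join(lines) + "\n"
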