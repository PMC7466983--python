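"""Conservation profiles, strict/relaxed evoprints, and species scorecards.

A profile stacks per-species conservation calls over the reference; an
evoprint collapses it into a single cased sequence the length of the
reference: uppercase where at most R test species fail to conserve the base,
lowercase elsewhere.  R = 0 is the strict print; R = 1 is the usual relaxed
print ("conserved in all or all but one").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from evofoot.align import AlignParams, SpeciesMatch, align_species
from evofoot.seqio import SeqRecord


@dataclass(frozen=True)
class ConservationProfile:
    """Boolean conservation matrix: one row per test species, one column per
    reference base."""

    ref_id: str
    ref_residues: str
    species: tuple[str, ...]
    conserved: np.ndarray  # shape (n_species, ref_len), bool

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species ids in profile")
        if self.conserved.shape != (len(self.species), len(self.ref_residues)):
            raise ValueError(
                f"conserved matrix shape {self.conserved.shape} does not match "
                f"{len(self.species)} species x {len(self.ref_residues)} bases"
            )

    @property
    def n_species(self) -> int:
        return len(self.species)


@dataclass(frozen=True)
class EvoPrintResult:
    ref_id: str
    ref_residues: str
    species: tuple[str, ...]
    missing_count: np.ndarray  # int, per reference position
    R: int
    mask: np.ndarray  # bool: missing_count <= R
    missing_species: tuple[tuple[str, ...], ...]  # per position

    def __len__(self) -> int:
        return len(self.ref_residues)


@dataclass(frozen=True)
class Scorecard:
    """Conserved-base count per species; identical species score the full
    reference length (= self_score), divergence lowers the score."""

    ref_id: str
    self_score: int
    scores: dict[str, int]


def build_profile(
    ref: SeqRecord, tests: Sequence[SeqRecord], params: AlignParams | None = None
) -> ConservationProfile:
    """Align every test species to the reference and stack the per-base calls."""
    if not tests:
        raise ValueError("at least one test species is required")
    ids = [t.id for t in tests]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate species ids: {ids}")
    params = params or AlignParams()
    rows = [align_species(ref, t, params).conserved for t in tests]
    return ConservationProfile(
        ref_id=ref.id,
        ref_residues=ref.residues,
        species=tuple(ids),
        conserved=np.vstack(rows),
    )


def make_evoprint(profile: ConservationProfile, R: int = 0) -> EvoPrintResult:
    """Collapse the profile under relaxation parameter R (max species allowed
    to miss a base while it still counts as conserved)."""
    if R < 0:
        raise ValueError("R must be non-negative")
    if R >= profile.n_species:
        raise ValueError(
            f"R ({R}) must be smaller than the number of species ({profile.n_species})"
        )
    missing = (~profile.conserved).sum(axis=0).astype(int)
    mask = missing <= R
    sp = np.array(profile.species)
    missing_species = tuple(
        tuple(sp[~profile.conserved[:, p]]) for p in range(profile.conserved.shape[1])
    )
    return EvoPrintResult(
        ref_id=profile.ref_id,
        ref_residues=profile.ref_residues,
        species=profile.species,
        missing_count=missing,
        R=R,
        mask=mask,
        missing_species=missing_species,
    )


def render_evoprint(ep: EvoPrintResult) -> str:
    """Cased single-sequence view: uppercase where the mask is true, lowercase
    elsewhere.  Same length as the reference."""
    return "".join(
        c.upper() if m else c.lower() for c, m in zip(ep.ref_residues, ep.mask)
    )


def format_evoprint(ep: EvoPrintResult, width: int = 60, annotate: bool = False) -> str:
    """Wrapped text with a 1-based position ruler, and optionally a per-line
    annotation naming the single missing species wherever exactly one species
    fails to conserve a base."""
    cased = render_evoprint(ep)
    lines = []
    for i in range(0, len(cased), width):
        chunk = cased[i : i + width]
        lines.append(f"{i + 1:>10}  {chunk}")
        if annotate:
            notes = [
                f"{i + j + 1}:{ep.missing_species[i + j][0]}"
                for j in range(len(chunk))
                if ep.missing_count[i + j] == 1
            ]
            if notes:
                lines.append(f"{'':>10}  # all-but-one: " + " ".join(notes))
    return "\n".join(lines) + "\n"


def scorecard(profile: ConservationProfile) -> Scorecard:
    """Per-species conserved-base counts against the reference."""
    counts = profile.conserved.sum(axis=1)
    return Scorecard(
        ref_id=profile.ref_id,
        self_score=len(profile.ref_residues),
        scores={s: int(c) for s, c in zip(profile.species, counts)},
    )


def format_scorecard(card: Scorecard) -> str:
    """TSV rendering: species, score, score/self_score."""
    lines = ["species\tscore\tfraction"]
    for s, score in card.scores.items():
        lines.append(f"{s}\t{score}\t{score / card.self_score:.4f}")
    return "\n".join(lines) + "\n"


def format_missing_track(ep: EvoPrintResult) -> str:
    """Bedgraph-like per-base missing-species count over the reference."""
    lines = []
    run_start = 0
    for p in range(1, len(ep) + 1):
        if p == len(ep) or ep.missing_count[p] != ep.missing_count[run_start]:
            lines.append(
                f"{ep.ref_id}\t{run_start}\t{p}\t{int(ep.missing_count[run_start])}"
            )
            run_start = p
    return "\n".join(lines) + "\n"
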