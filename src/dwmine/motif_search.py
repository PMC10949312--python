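"""P-loop candidate detection by exact ABEGO pattern matching.

A Walker-A/P-loop is a strand-to-helix junction whose backbone conformation
reads as a beta run entering a GAG turn followed by helix; the two default
14-letter patterns live in :mod:`dwmine.config`. Matching is exact and
overlapping; geometric validation happens downstream against a reference
fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_PATTERNS
from .structure_io import Structure

_VALID = set("ABEGO")


@dataclass
class MotifMatch:
    start_index: int
    length: int
    pattern: str
    ca_coords: np.ndarray          # (length, 3)
    rmsd_to_ref: float | None = None
    structure_id: str = ""
    start_seqnum: int | None = None  # author numbering of first residue

    @property
    def end_index(self) -> int:
        """Exclusive end residue index."""
        return self.start_index + self.length

    def overlaps(self, other: "MotifMatch") -> bool:
        return self.start_index < other.end_index and other.start_index < self.end_index


def find_motifs(
    abego: str,
    s: Structure,
    patterns: tuple[str, ...] = DEFAULT_PATTERNS,
) -> list[MotifMatch]:
    """All (possibly overlapping) pattern occurrences, sorted by position."""
    for p in patterns:
        if not p or set(p) - _VALID:
            raise ValueError(f"invalid ABEGO pattern: {p!r}")
    if len(abego) != len(s.residues):
        raise ValueError("ABEGO string length does not match residue count")
    matches: list[MotifMatch] = []
    for pattern in patterns:
        start = abego.find(pattern)
        while start != -1:
            matches.append(
                MotifMatch(
                    start_index=start,
                    length=len(pattern),
                    pattern=pattern,
                    ca_coords=s.ca_coords(start, start + len(pattern)),
                    structure_id=s.id,
                    start_seqnum=s.residues[start].seqnum,
                )
            )
            start = abego.find(pattern, start + 1)
    matches.sort(key=lambda m: (m.start_index, m.pattern))
    return matches


def dedupe_overlaps(matches: list[MotifMatch]) -> list[MotifMatch]:
    """Resolve overlapping matches, keeping the best fit to the reference.

    Among mutually overlapping matches the smallest ``rmsd_to_ref`` wins
    (ties to the smaller start index), so one physical loop is never counted
    twice. Requires RMSDs to have been computed already.
    """
    if any(
        a.rmsd_to_ref is None or b.rmsd_to_ref is None
        for i, a in enumerate(matches)
        for b in matches[i + 1 :]
        if a.overlaps(b)
    ):
        raise ValueError("dedupe_overlaps requires rmsd_to_ref on overlapping matches")
    # greedy over overlap groups: matches are sorted by start_index
    group: list[MotifMatch] = []
    out: list[MotifMatch] = []

    def flush() -> None:
        if group:
            out.append(min(group, key=lambda m: (m.rmsd_to_ref, m.start_index)))
            group.clear()

    for m in matches:
        if group and not any(m.overlaps(g) for g in group):
            flush()
        group.append(m)
    flush()
    return out
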