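"""Two-fold symmetry metrics and MSA conservation analysis.

For a pseudo-symmetric dual-domain protein the two halves are compared by
direct structural alignment (sequence identity over aligned pairs) and by
net side-chain charge. Conservation comes from a multiple sequence
alignment: rows with too many deletions against the representative sequence
are dropped (they are usually fragments matching only the P-loop consensus),
then per-column Shannon entropy in nats is computed over the 20 amino acids
with gaps excluded, and the lowest-entropy positions inside a residue window
(e.g. a ligand tunnel) are reported as the conserved set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .align_cluster import AlignmentResult, align_pair
from .structure_io import Structure

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}  # His excluded
MAX_ENTROPY = math.log(20.0)


@dataclass
class Msa:
    names: list[str]
    rows: list[str]           # equal-length aligned sequences over AA + '-'
    ref_row: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty MSA")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("MSA rows have unequal lengths")
        if not 0 <= self.ref_row < len(self.rows):
            raise ValueError("ref_row out of range")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass
class SiteEntry:
    resnum: int        # 1-based position in the ungapped representative
    aa: str            # representative residue at that position
    entropy: float     # nats, in [0, ln 20]; nan if flagged
    coverage: float    # non-gap fraction of the column
    flagged: bool = False


@dataclass
class ConservationProfile:
    entries: list[SiteEntry] = field(default_factory=list)

    def in_window(self, first: int, last: int) -> list[SiteEntry]:
        return [e for e in self.entries if first <= e.resnum <= last]


def read_msa(path: str | Path, ref_name: str | None = None) -> Msa:
    """Read an aligned FASTA or A3M file (lowercase insertion states dropped)."""
    from Bio import SeqIO

    path = Path(path)
    names, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if path.suffix.lower() == ".a3m":
            seq = "".join(c for c in seq if not c.islower())
        names.append(rec.id)
        rows.append(seq.upper().replace(".", "-"))
    if not rows:
        raise ValueError(f"no sequences in {path}")
    ref_row = 0
    if ref_name is not None:
        try:
            ref_row = names.index(ref_name)
        except ValueError as exc:
            raise ValueError(f"reference {ref_name!r} not in MSA") from exc
    return Msa(names, rows, ref_row)


def filter_msa(m: Msa, max_gaps: int = 10) -> Msa:
    """Drop rows with more than ``max_gaps`` deletions against the representative.

    Gaps are counted only over columns where the representative row has a
    residue, so insertions private to other rows do not count. The
    representative itself is always kept.
    """
    ref = m.rows[m.ref_row]
    ref_cols = [i for i, c in enumerate(ref) if c != "-"]
    names, rows = [], []
    for k, row in enumerate(m.rows):
        gaps = sum(1 for i in ref_cols if row[i] == "-")
        if k == m.ref_row or gaps <= max_gaps:
            names.append(m.names[k])
            rows.append(row)
    return Msa(names, rows, ref_row=names.index(m.names[m.ref_row]))


def site_entropy(m: Msa) -> ConservationProfile:
    """Shannon entropy per representative-occupied column, gaps excluded."""
    if len(m.rows) < 2:
        raise ValueError("entropy requires at least 2 rows")
    ref = m.rows[m.ref_row]
    entries: list[SiteEntry] = []
    resnum = 0
    n_rows = len(m.rows)
    for col, ref_char in enumerate(ref):
        if ref_char == "-":
            continue
        resnum += 1
        counts: dict[str, int] = {}
        non_gap = 0
        for row in m.rows:
            c = row[col]
            if c == "-":
                continue
            non_gap += 1
            if c in AA20:
                counts[c] = counts.get(c, 0) + 1
        coverage = non_gap / n_rows
        total = sum(counts.values())
        if total == 0:
            entries.append(SiteEntry(resnum, ref_char, float("nan"), coverage, flagged=True))
            continue
        probs = np.array(list(counts.values()), float) / total
        entropy = float(-(probs * np.log(probs)).sum())
        entries.append(SiteEntry(resnum, ref_char, entropy, coverage))
    return ConservationProfile(entries)


def top_conserved(
    p: ConservationProfile,
    window: tuple[int, int],
    n: int = 10,
) -> list[int]:
    """The ``n`` lowest-entropy residue positions inside ``window`` (inclusive).

    Returned in ascending entropy, ties broken by residue number. If the
    window holds fewer than ``n`` usable positions, all are returned.
    """
    candidates = [e for e in p.in_window(*window) if not e.flagged]
    if len(candidates) < n:
        logger.warning(
            "window %s has only %d usable positions (requested %d)",
            window, len(candidates), n,
        )
    candidates.sort(key=lambda e: (e.entropy, e.resnum))
    return [e.resnum for e in candidates[:n]]


def resolve_ranges(s: Structure, ranges: list[tuple[int, int]]) -> list[int]:
    """Residue indices for a union of author-numbered inclusive ranges."""
    out = []
    for first, last in ranges:
        out.extend(r.index for r in s.residues if first <= r.seqnum <= last)
    return sorted(set(out))


@dataclass
class HalfAlignment:
    identity: float          # percent over aligned pairs
    tm: float                # min-normalized TM of the half-vs-half alignment
    alignment: AlignmentResult
    low_similarity: bool     # TM < 0.5: identity is not meaningful


def half_alignment(
    s: Structure,
    left: list[tuple[int, int]],
    right: list[tuple[int, int]],
    author_numbering: bool = True,
) -> HalfAlignment:
    """Structurally align the two halves of a structure and score identity.

    ``left``/``right`` are unions of inclusive residue ranges (author
    numbering by default, 0-based indices otherwise). The halves must be
    disjoint and at least 20 residues each.
    """
    if author_numbering:
        li = resolve_ranges(s, left)
        ri = resolve_ranges(s, right)
    else:
        li = sorted({i for a, b in left for i in range(a, b + 1)})
        ri = sorted({i for a, b in right for i in range(a, b + 1)})
    if set(li) & set(ri):
        raise ValueError("the two halves overlap")
    if len(li) < 20 or len(ri) < 20:
        raise ValueError("each half must contain at least 20 residues")
    sl = s.subset(li, new_id=f"{s.id}|L")
    sr = s.subset(ri, new_id=f"{s.id}|R")
    res = align_pair(sl, sr)
    if not res.pairs:
        return HalfAlignment(0.0, 0.0, res, True)
    same = sum(1 for a, b in res.pairs if sl.residues[a].aa == sr.residues[b].aa)
    identity = 100.0 * same / len(res.pairs)
    tm = res.tm("min")
    return HalfAlignment(identity, tm, res, tm < 0.5)


def half_identity(
    s: Structure,
    split: tuple[list[tuple[int, int]], list[tuple[int, int]]],
    author_numbering: bool = True,
) -> float:
    """Percent sequence identity between the two halves (see half_alignment)."""
    return half_alignment(s, split[0], split[1], author_numbering).identity


def net_charge(s: Structure, residue_range: tuple[int, int] | list[tuple[int, int]] | None = None,
               author_numbering: bool = True) -> int:
    """count(K)+count(R)-count(D)-count(E) over a residue range (His excluded)."""
    if residue_range is None:
        residues = s.residues
    else:
        ranges = residue_range if isinstance(residue_range, list) else [residue_range]
        if author_numbering:
            idx = resolve_ranges(s, ranges)
        else:
            idx = sorted({i for a, b in ranges for i in range(a, b + 1)})
        residues = [s.residues[i] for i in idx]
    return sum(_CHARGE.get(r.aa, 0) for r in residues)


def export_profile_tsv(p: ConservationProfile, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(e.resnum, e.aa, e.entropy, e.coverage) for e in p.entries],
        columns=["resnum", "aa", "entropy", "coverage"],
    ).to_csv(path, sep="\t", index=False)
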