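"""Orchestration of the mining funnel over structures and directories.

Per structure: conformation string -> motif matches -> reference-RMSD filter
-> overlap dedupe -> hydrogen bonds -> sheet graph -> do multiple P-loop
candidates share one continuous sheet. Failures are isolated per file so a
directory sweep never dies on one bad model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .abego import abego_string
from .config import Config
from .motif_search import MotifMatch, dedupe_overlaps, find_motifs
from .sheet_topology import build_sheet_graph, detect_hbonds, ploops_share_sheet
from .structure_io import Structure, StructureError, mean_plddt, read_structure
from .superpose import ReferenceFragment, filter_by_reference

logger = logging.getLogger(__name__)

TSV_COLUMNS = [
    "structure_id", "n_motif_matches", "n_pass_rmsd", "shares_sheet",
    "sheet_size", "mean_plddt", "failed_stage",
]


@dataclass
class ScanRecord:
    structure_id: str
    n_motif_matches: int = 0
    n_pass_rmsd: int = 0
    shares_sheet: bool = False
    sheet_size: int = 0
    mean_plddt: float = float("nan")
    failed_stage: str = ""
    matches: list[MotifMatch] = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return bool(self.failed_stage)


def scan_structure(s: Structure, ref: ReferenceFragment, config: Config | None = None) -> ScanRecord:
    """Run the whole per-structure funnel and fill a ScanRecord."""
    config = config or Config()
    rec = ScanRecord(structure_id=s.id)
    stage = "mean_plddt"
    try:
        rec.mean_plddt = mean_plddt(s)
        stage = "abego"
        abego = abego_string(s, config.bins)
        stage = "find_motifs"
        matches = find_motifs(abego, s, config.patterns)
        rec.n_motif_matches = len(matches)
        stage = "filter_by_reference"
        passed = filter_by_reference(matches, ref, config.rmsd_threshold)
        stage = "dedupe_overlaps"
        passed = dedupe_overlaps(passed)
        rec.n_pass_rmsd = len(passed)
        rec.matches = passed
        if len(passed) >= 2:
            stage = "detect_hbonds"
            hbonds = detect_hbonds(s, config.hbond_cutoff, config.nh_bond_length)
            stage = "build_sheet_graph"
            graph = build_sheet_graph(hbonds, s, config.min_strand_length)
            stage = "ploops_share_sheet"
            shared = ploops_share_sheet(passed, graph)
            rec.shares_sheet = bool(shared)
            if shared:
                biggest = max(shared, key=lambda sheet: len(graph.sheets[sheet]))
                rec.sheet_size = len(graph.sheets[biggest])
    except Exception as exc:
        logger.warning("scan of %s failed at stage %s: %s", s.id, stage, exc)
        rec.failed_stage = stage
    return rec


def scan_directory(
    paths: list[str | Path] | str | Path,
    ref: ReferenceFragment,
    config: Config | None = None,
) -> tuple[list[ScanRecord], dict[str, int]]:
    """Scan many structure files; deterministic order, per-file failure isolation.

    Returns the records sorted by structure id and the funnel summary counts.
    """
    config = config or Config()
    if isinstance(paths, (str, Path)):
        root = Path(paths)
        paths = sorted(p for p in root.iterdir()
                       if p.suffix.lower() in (".pdb", ".cif", ".mmcif", ".ent"))
    records: list[ScanRecord] = []
    n_unreadable = 0
    for p in paths:
        try:
            s = read_structure(p)
        except StructureError as exc:
            logger.warning("unreadable file %s: %s", p, exc)
            n_unreadable += 1
            continue
        records.append(scan_structure(s, ref, config))
    records.sort(key=lambda r: r.structure_id)
    summary = summarize(records)
    summary["n_unreadable"] = n_unreadable
    return records, summary


def summarize(records: list[ScanRecord]) -> dict[str, int]:
    return {
        "n_scanned": len(records),
        "n_failed": sum(r.failed for r in records),
        "n_multi_motif": sum(r.n_motif_matches >= 2 for r in records),
        "n_multi_pass_rmsd": sum(r.n_pass_rmsd >= 2 for r in records),
        "n_shares_sheet": sum(r.shares_sheet for r in records),
    }


def records_to_frame(records: list[ScanRecord]) -> pd.DataFrame:
    rows = [
        {k: getattr(r, k) for k in TSV_COLUMNS}
        for r in records
    ]
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_scan_outputs(records: list[ScanRecord], tsv_path: str | Path,
                       json_path: str | Path | None = None) -> None:
    """TSV table of records plus a JSON side-car with per-match details."""
    records_to_frame(records).to_csv(tsv_path, sep="\t", index=False)
    if json_path is None:
        return
    detail = {}
    for r in records:
        detail[r.structure_id] = [
            {
                "start_index": m.start_index,
                "start_seqnum": m.start_seqnum,
                "pattern": m.pattern,
                "rmsd_to_ref": m.rmsd_to_ref,
            }
            for m in r.matches
        ]
    Path(json_path).write_text(json.dumps(detail, indent=1))
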