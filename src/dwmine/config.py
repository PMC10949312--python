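"""Pipeline configuration.

All thresholds used along the mining funnel live here with their standard
values as defaults, so a whole run is reproducible from one object. Values
may be overridden programmatically or from a TOML file via
:func:`load_config`.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field


# The two 14-letter backbone-conformation patterns describing a P-loop
# (Walker-A) motif: a three-residue-or-longer beta run entering a
# left-handed/right-handed GAG turn followed by the start of the helix that
# grips the phosphates.
DEFAULT_PATTERNS: tuple[str, str] = ("BBBEBBGAGAAAAA", "BBBBBBGAGAAAAA")


@dataclass(frozen=True)
class AbegoBins:
    """Torsion-bin boundaries for the ABEGO alphabet (degrees).

    The alphabet partitions the Ramachandran torus: for phi < 0, A when
    ``a_psi_low < psi <= a_psi_high`` else B; for phi >= 0, G when
    ``g_psi_low < psi <= g_psi_high`` else E; O whenever the peptide bond is
    cis (``|omega| < cis_omega``). Alternative bin conventions can be swapped
    in here.
    """

    a_psi_low: float = -100.0
    a_psi_high: float = 50.0
    g_psi_low: float = -100.0
    g_psi_high: float = 100.0
    cis_omega: float = 90.0


@dataclass
class Config:
    # motif search
    patterns: tuple[str, ...] = DEFAULT_PATTERNS
    rmsd_threshold: float = 2.0           # Angstrom, vs reference P-loop
    # hydrogen bonds / sheets
    hbond_cutoff: float = -0.5            # kcal/mol, Kabsch-Sander energy
    nh_bond_length: float = 1.0           # Angstrom, reconstructed amide H
    min_strand_length: int = 1
    # clustering
    tm_threshold: float = 0.5
    tm_normalization: str = "min"         # min | max | avg | query
    # conservation
    max_gaps: int = 10
    # constellation search
    constellation_rmsd: float = 1.0       # Angstrom
    prune_tolerance: float = 1.5          # Angstrom, pairwise CB-CB pruning
    exchange_sets: dict[str, str] = field(default_factory=dict)
    # ABEGO bins
    bins: AbegoBins = field(default_factory=AbegoBins)


def load_config(path: str | None = None) -> Config:
    """Build a Config, optionally overriding defaults from a TOML file."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    bins = data.pop("bins", None)
    for key, value in data.items():
        if not hasattr(cfg, key):
            raise KeyError(f"unknown config key: {key}")
        if key == "patterns":
            value = tuple(value)
        setattr(cfg, key, value)
    if bins:
        cfg.bins = dataclasses.replace(cfg.bins, **bins)
    return cfg
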