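"""Versioned numerical configuration.

Every threshold, radius set and energy parameter used by the analysis lives
here under one namespace per module, so a report can echo the exact values it
was produced with. ``defaults()`` returns a fresh deep copy; CLI flags and
config files override individual keys.
"""

from __future__ import annotations

import copy
import hashlib
import json
from typing import Any, Dict

#: van der Waals radii, Å (Bondi 1964 set, heavy atoms found in proteins).
#: Unknown elements raise — no silent default radius.
VDW_RADII_BONDI = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "H": 1.10,  # hydrogens are dropped on input; listed for completeness
}

#: Reference maximum accessible surface areas per residue, Å²
#: (theoretical Gly-X-Gly tripeptide maxima, Tien et al. 2013).
MAX_ASA_TIEN_2013 = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

#: Atomic solvation parameters, kcal mol^-1 Å^-2, five atom classes
#: (Eisenberg & McLachlan 1986). Positive for apolar atoms: burying carbon
#: surface is favourable, burying charged nitrogen/oxygen is costly.
ASP_EISENBERG_MCLACHLAN = {
    "C": 0.016,
    "N/O": -0.006,
    "O-": -0.024,
    "N+": -0.050,
    "S": 0.021,
}

#: Approximate side-chain van der Waals volumes, Å³ (Zamyatnin-style), used
#: only by the substitution-tolerance classifier.
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

_DEFAULTS: Dict[str, Any] = {
    "io": {
        "vdw_set": "bondi1964",
        "drop_hydrogens": True,
        "drop_hetero": True,
    },
    "topology": {
        "stack_rmsd": 1.0,        # Å, translation-only CA RMSD linking stacked chains
        "stack_dist_scale": 4.9,  # Å, rise scale; link requires centroid dist < 1.5x
        "sym_rmsd": 2.0,          # Å, CA RMSD for C2 detection
        "sym_rung_search": 2,     # rung-offset search half-width
        "min_common_residues": 10,
        "rung_ref": None,         # residue number used as rung reference (None = CA centroid)
    },
    "geometry": {
        "pair_rmsd_warn": 2.0,    # Å, warn if consecutive-rung superposition exceeds this
        "edge_tail_range": (19, 49),
        "arch_range": (50, 64),
        "face_tail_range": (65, 94),
    },
    "conformation": {
        "hbond_energy_cutoff": -0.5,  # kcal/mol, Kabsch-Sander
        "cis_max_abs_omega": 30.0,    # deg
        "trans_min_abs_omega": 150.0, # deg
        "chain_break_ca_dist": 4.5,   # Å
    },
    "sasa": {
        "probe_A": 1.4,
        "n_points": 1920,         # deterministic golden-spiral sphere points per atom
    },
    "burial": {
        "buried_max_rel": 0.10,
        "exposed_min_rel": 0.40,
        "max_asa_set": "tien2013_theoretical",
    },
    "contacts": {
        "hbond_max_A": 3.5,
        "ionic_max_A": 4.0,
        "hydrophobic_max_A": 4.5,
        "min_cluster_size": 3,
        "exclude_seq_sep": 2,     # same-chain neighbours |Δseq| <= 2 are not interface contacts
        "donor_angle_min_deg": 90.0,
    },
    "stability": {
        "asp_set": "eisenberg_mclachlan_1986",
        "e_hb": -0.6,             # kcal/mol per buried backbone H-bond
        "include_sidechain_hbonds": False,
        "buried_rel_asa": 0.10,   # residue counts as buried for the H-bond term below this
    },
    "sequence": {
        "matrix": "BLOSUM62",
        "gap_open": -11.0,
        "gap_extend": -1.0,
        "volume_tolerance_A3": 40.0,
    },
    "synthetic": {
        "ca_spacing_A": 3.8,
    },
}


def defaults() -> Dict[str, Any]:
    """Fresh deep copy of the default configuration."""
    return copy.deepcopy(_DEFAULTS)


def merged(overrides: Dict[str, Any] | None = None) -> Dict[str, Any]:
    """Defaults with a (possibly nested) override mapping applied."""
    cfg = defaults()
    if overrides:
        for section, values in overrides.items():
            if section not in cfg:
                cfg[section] = values
            elif isinstance(values, dict):
                cfg[section].update(values)
            else:
                cfg[section] = values
    return cfg


def config_hash(cfg: Dict[str, Any]) -> str:
    """Stable short hash of a configuration for report headers."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def vdw_radius(element: str) -> float:
    """Bondi radius for an element; unknown elements are an error."""
    el = element.strip().upper()
    try:
        return VDW_RADII_BONDI[el]
    except KeyError:
        raise KeyError(f"no van der Waals radius for element {element!r} "
                       f"(known: {sorted(VDW_RADII_BONDI)})") from None
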