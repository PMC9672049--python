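"""Coordinate and sequence I/O.

mmCIF/PDB parsing is delegated to gemmi; this module reduces a parsed
structure to the package's single-conformer, hydrogen-free, heavy-atom data
model (author residue numbering preserved) and writes analysis reports as
JSON or TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Dict, Iterable, List, Optional

import gemmi
import numpy as np
import pandas as pd

from .core import Atom, Chain, FibrilAssembly, Residue, SequenceRecord, StructureError, THREE_TO_ONE


def _coor_format(fmt: str) -> "gemmi.CoorFormat":
    return {
        "auto": gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }[fmt]


def _pick_altloc(atoms: List[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc identifier order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def read_structure(path: str | Path, format: str = "auto",
                   drop_hydrogens: bool = True, drop_hetero: bool = True) -> FibrilAssembly:
    """Read an mmCIF or PDB coordinate file into a :class:`FibrilAssembly`.

    Waters and hetero compounds are excluded by default; hydrogens are always
    dropped when ``drop_hydrogens`` (all downstream contact and SASA
    definitions are heavy-atom based). Protofilament/rung maps are left
    unassigned — fill them with :func:`crossbeta.topology.assign_topology`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("auto", "pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=_coor_format(format))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError with record context
        raise StructureError(f"cannot parse {path.name}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise StructureError(f"{path.name}: no models")
    model = st[0]

    chains: List[Chain] = []
    serial = 0
    for gchain in model:
        residues: List[Residue] = []
        for gres in gchain:
            if gres.is_water():
                continue
            is_aa = gres.name in THREE_TO_ONE
            has_bb = all(any(a.name == n for a in gres) for n in ("N", "CA", "C"))
            if drop_hetero and not (is_aa or has_bb):
                continue
            by_name: Dict[str, List[gemmi.Atom]] = {}
            for a in gres:
                if drop_hydrogens and a.element.is_hydrogen:
                    continue
                by_name.setdefault(a.name, []).append(a)
            atoms: List[Atom] = []
            for name in by_name:
                ga = _pick_altloc(by_name[name])
                serial += 1
                atoms.append(Atom(
                    serial=serial, name=name,
                    element=ga.element.name.upper(),
                    coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    occupancy=ga.occ, bfactor=ga.b_iso,
                ))
            if atoms:
                residues.append(Residue(seq_id=gres.seqid.num, name=gres.name, atoms=atoms))
        if residues:
            chains.append(Chain(chain_id=gchain.name, residues=residues))
    if not chains:
        raise StructureError(f"{path.name}: no polymer chains with heavy atoms")
    return FibrilAssembly(chains=chains, label=path.stem)


def write_structure(assembly: FibrilAssembly, path: str | Path, format: str = "auto") -> Path:
    """Write the assembly back out as PDB or mmCIF (by extension when auto)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    st = gemmi.Structure()
    st.name = assembly.label or "fibril"
    model = gemmi.Model("1")
    for chain in assembly.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_id, " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = a.occupancy
                ga.b_iso = a.bfactor
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))
    return path


def read_fasta(path: str | Path) -> List[SequenceRecord]:
    """Read FASTA records; sequences uppercased, whitespace stripped."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path.name}: empty FASTA file")
    records: List[SequenceRecord] = []
    header: Optional[str] = None
    seq_parts: List[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(seq_parts)
        records.append(SequenceRecord(id=header, sequence=seq))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].split()[0] if line[1:].strip() else "unnamed"
            seq_parts = []
        else:
            if header is None:
                raise ValueError(f"{path.name}: sequence data before first header")
            seq_parts.append(line.replace(" ", ""))
    flush()
    if not records:
        raise ValueError(f"{path.name}: no FASTA records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")
    return path


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.9g}")  # >= 6 significant digits
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(report: Dict[str, Any], path: str | Path, format: str = "json") -> Path:
    """Serialize an analysis report (JSON, or TSV for flat/tabular reports)."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_to_jsonable(report), indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        rows = []
        for key, val in report.items():
            if isinstance(val, dict):
                for k2, v2 in val.items():
                    rows.append({"section": key, "key": k2, "value": v2})
            elif isinstance(val, (list, tuple)):
                for i, v2 in enumerate(val):
                    rows.append({"section": key, "key": str(i), "value": v2})
            else:
                rows.append({"section": "", "key": key, "value": val})
        pd.DataFrame(rows, columns=["section", "key", "value"]).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path: str | Path) -> Dict[str, Any]:
    return json.loads(Path(path).read_text())
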