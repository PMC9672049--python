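"""Model/Results front-end over the analysis pipeline.

``FibrilModel`` wraps one coordinate model (an assembly or a file path) plus
configuration; ``fit()`` runs topology assignment, screw estimation,
conformational analysis, burial, contact detection and stability in order
and returns a ``FibrilResults`` carrying the estimates, per-stage
diagnostics and a ``summary()`` table. ``compare()`` builds the multi-
structure comparison table (identity, ΔG_sol, ΔG_diss, buried area, spans).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import conformation, contacts, geometry, io, sasa, stability, topology
from .config import config_hash, merged
from .core import FibrilAssembly

__version__ = "0.1.0"


class FibrilModel:
    """One fibril coordinate model prepared for analysis.

    Parameters
    ----------
    data : FibrilAssembly or path
        Parsed assembly or a coordinate file (mmCIF/PDB).
    config : dict, optional
        Nested overrides of :func:`crossbeta.config.defaults`.
    """

    def __init__(self, data: Union[FibrilAssembly, str, Path],
                 config: Optional[dict] = None):
        if isinstance(data, (str, Path)):
            self.assembly = io.read_structure(data)
        else:
            self.assembly = data
        self.config = merged(config)

    @classmethod
    def from_file(cls, path: Union[str, Path], config: Optional[dict] = None) -> "FibrilModel":
        return cls(io.read_structure(path), config=config)

    def fit(self, segments: Optional[Sequence[tuple]] = None,
            skip_energies: bool = False) -> "FibrilResults":
        """Run the full pipeline and return results.

        ``segments``: residue ranges for tilt analysis (defaults to the
        configured edge-tail / arch / face-tail windows). ``skip_energies``
        skips the SASA-based stages for a fast geometric pass.
        """
        asm = self.assembly
        cfg = self.config
        if not asm.has_topology:
            topology.assign_topology(asm, cfg)
        sym = topology.detect_symmetry(asm, cfg)

        helical = None
        warnings: List[str] = []
        multi_rung = any(len(asm.rungs_of_protofilament(p)) >= 2
                         for p in range(asm.n_protofilaments))
        if multi_rung and asm.axis_dir is not None:
            helical = geometry.estimate_screw(asm, cfg)
            warnings.extend(helical.warnings)

        interior = asm.interior_chain_ids()
        ref_chain = None
        for c in interior:
            if asm.rung_of[c] == 0:
                ref_chain = c
                break
        if ref_chain is None:
            ref_chain = interior[0] if interior else asm.chains[0].chain_id

        spans: Dict[str, float] = {}
        layers: Dict[str, float] = {}
        if asm.axis_dir is not None:
            for c in asm.chains:
                spans[c.chain_id] = geometry.axial_span(asm, c.chain_id)
                if helical is not None:
                    layers[c.chain_id] = spans[c.chain_id] / helical.rise_A

        seg_cfg = cfg["geometry"]
        if segments is None:
            segments = [seg_cfg["edge_tail_range"], seg_cfg["arch_range"],
                        seg_cfg["face_tail_range"]]
        tilts = []
        if asm.axis_dir is not None:
            for rng in segments:
                try:
                    tilts.append(geometry.segment_tilt(asm, ref_chain, tuple(rng)))
                except Exception as exc:
                    warnings.append(f"segment {rng}: {exc}")

        ss = conformation.assign_beta(asm, ref_chain, cfg)
        omegas = conformation.classify_omega(asm, ref_chain, cfg)

        burial = None
        contact_records = None
        clusters = None
        footprint = None
        energy = None
        dgd = None
        if not skip_energies:
            burial = sasa.classify_burial(asm, ref_chain, config=cfg)
            contact_records = contacts.detect_contacts(asm, ref_chain, cfg,
                                                       require_interior=False)
            clusters = contacts.cluster_hydrophobics(contact_records, config=cfg)
            footprint = contacts.stagger_footprint(contact_records)
            try:
                energy = stability.dG_sol(asm, ref_chain, cfg)
            except Exception as exc:
                warnings.append(f"dG_sol: {exc}")
            try:
                dgd = stability.dG_diss(asm, config=cfg)
            except Exception as exc:
                warnings.append(f"dG_diss: {exc}")

        return FibrilResults(
            model=self, label=asm.label, symmetry=sym,
            reference_chain=ref_chain, helical=helical,
            axial_spans=spans, layer_crossings=layers, segment_tilts=tilts,
            secondary_structure=ss, omegas=omegas, burial=burial,
            contacts=contact_records, hydrophobic_clusters=clusters,
            stagger=footprint, energy=energy, dG_diss=dgd,
            warnings=warnings, config_hash=config_hash(cfg),
        )


@dataclass
class FibrilResults:
    """Estimates and diagnostics from one fitted fibril model."""

    model: FibrilModel
    label: str
    symmetry: str
    reference_chain: str
    helical: Optional[geometry.HelicalParameters]
    axial_spans: Dict[str, float]
    layer_crossings: Dict[str, float]
    segment_tilts: List[geometry.SegmentGeometry]
    secondary_structure: conformation.SecondaryStructure
    omegas: List[conformation.OmegaRecord]
    burial: Optional[sasa.BurialClass]
    contacts: Optional[List[contacts.ContactRecord]]
    hydrophobic_clusters: Optional[List[contacts.HydrophobicCluster]]
    stagger: Optional[Dict[str, Dict[int, int]]]
    energy: Optional[stability.EnergyReport]
    dG_diss: Optional[float]
    warnings: List[str] = field(default_factory=list)
    config_hash: str = ""

    @property
    def assembly(self) -> FibrilAssembly:
        return self.model.assembly

    def cis_residues(self) -> List[int]:
        return [o.residue for o in self.omegas if o.isomer == "cis"]

    def to_report(self) -> Dict[str, Any]:
        """JSON-serializable report of every fitted quantity."""
        asm = self.assembly
        rep: Dict[str, Any] = {
            "label": self.label,
            "config_hash": self.config_hash,
            "thresholds": self.model.config,
            "n_chains": len(asm.chains),
            "n_protofilaments": asm.n_protofilaments if asm.has_topology else None,
            "residues_per_chain": len(asm.chain(self.reference_chain)),
            "symmetry": self.symmetry,
            "reference_chain": self.reference_chain,
            "warnings": self.warnings,
        }
        if self.helical is not None:
            rep.update({
                "twist_deg": self.helical.twist_deg,
                "rise_A": self.helical.rise_A,
                "crossover_A": self.helical.crossover_A,
                "handedness": self.helical.handedness,
            })
        rep["axial_span_A"] = self.axial_spans
        rep["layer_crossing"] = self.layer_crossings
        rep["segment_tilts"] = [
            {"range": list(t.residue_range), "tilt_deg": t.tilt_deg,
             "axial_span_A": t.axial_span_A} for t in self.segment_tilts]
        rep["n_strands"] = self.secondary_structure.n_strands
        rep["strands"] = [list(s) for s in self.secondary_structure.strands]
        rep["cis_peptides"] = self.cis_residues()
        if self.burial is not None:
            rep["burial"] = self.burial.labels
        if self.contacts is not None:
            from collections import Counter
            counts = Counter((c.kind, c.interface) for c in self.contacts)
            rep["contact_counts"] = {f"{k}/{i}": n for (k, i), n in sorted(counts.items())}
            rep["n_hydrophobic_clusters"] = len(self.hydrophobic_clusters or [])
            rep["stagger_footprint"] = {
                iface: {str(k): v for k, v in sorted(hist.items())}
                for iface, hist in (self.stagger or {}).items()}
        if self.energy is not None:
            rep["dG_sol"] = self.energy.dG_sol_chain
            rep["dG_sol_hbond_term"] = self.energy.hbond_term
            rep["n_hbonds_buried"] = self.energy.n_hbonds_buried
        if self.dG_diss is not None:
            rep["dG_diss"] = self.dG_diss
        return rep

    def summary(self) -> str:
        """Human-readable summary table."""
        lines = [f"Fibril analysis: {self.label}",
                 "=" * 40,
                 f"chains                 {len(self.assembly.chains)}",
                 f"protofilaments         {self.assembly.n_protofilaments}",
                 f"symmetry               {self.symmetry}",
                 f"reference chain        {self.reference_chain} "
                 f"({len(self.assembly.chain(self.reference_chain))} residues)"]
        if self.helical is not None:
            h = self.helical
            lines += [f"twist                  {h.twist_deg:+.2f} deg/rung ({h.handedness}-handed)",
                      f"rise                   {h.rise_A:.2f} A/rung",
                      f"crossover (180 deg)    {h.crossover_A:.0f} A"]
        if self.reference_chain in self.axial_spans:
            lines.append(f"chain axial span       {self.axial_spans[self.reference_chain]:.1f} A")
        if self.reference_chain in self.layer_crossings:
            lines.append(f"layer crossing         {self.layer_crossings[self.reference_chain]:.2f} rungs")
        for t in self.segment_tilts:
            lines.append(f"tilt {t.residue_range[0]:>3}-{t.residue_range[1]:<3}"
                         f"           {t.tilt_deg:.1f} deg")
        lines.append(f"beta strands           {self.secondary_structure.n_strands}")
        cis = self.cis_residues()
        lines.append(f"cis peptide bonds      {cis if cis else 'none'}")
        if self.energy is not None:
            lines.append(f"dG_sol                 {self.energy.dG_sol_chain:.1f} kcal/mol "
                         f"(H-bond term {self.energy.hbond_term:.1f})")
        if self.dG_diss is not None:
            lines.append(f"dG_diss                {self.dG_diss:.1f} kcal/mol")
        if self.warnings:
            lines.append(f"warnings               {len(self.warnings)}")
        return "\n".join(lines)


def compare(results: Sequence[FibrilResults]) -> pd.DataFrame:
    """Comparison table across fitted structures."""
    rows = []
    for r in results:
        row: Dict[str, Any] = {
            "label": r.label,
            "symmetry": r.symmetry,
            "residues_per_chain": len(r.assembly.chain(r.reference_chain)),
            "n_strands": r.secondary_structure.n_strands,
        }
        if r.helical is not None:
            row.update(twist_deg=r.helical.twist_deg, rise_A=r.helical.rise_A,
                       crossover_A=r.helical.crossover_A)
        if r.reference_chain in r.axial_spans:
            row["axial_span_A"] = r.axial_spans[r.reference_chain]
        if r.energy is not None:
            row["dG_sol"] = r.energy.dG_sol_chain
        if r.dG_diss is not None:
            row["dG_diss"] = r.dG_diss
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(paths: Sequence[Union[str, Path, FibrilAssembly]],
                 config: Optional[dict] = None,
                 out_dir: Optional[Union[str, Path]] = None,
                 report_format: str = "json") -> Dict[str, Any]:
    """Fit every structure, write per-structure reports plus a comparison
    table (when ≥ 2 structures), and return the combined report dict."""
    cfg = merged(config)
    fitted: List[FibrilResults] = []
    for p in paths:
        model = FibrilModel(p, config=cfg)
        fitted.append(model.fit())
    combined: Dict[str, Any] = {
        "config_hash": config_hash(cfg),
        "structures": {r.label: r.to_report() for r in fitted},
    }
    if len(fitted) >= 2:
        combined["comparison"] = compare(fitted).to_dict(orient="records")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ext = "json" if report_format == "json" else "tsv"
        io.write_report(combined, out_dir / f"fibril_report.{ext}", report_format)
    return combined
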