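"""File writers: survey CSV/JSON, pseudo-atom PDB, OBJ mesh, ChimeraX
marker script.

The PDB file is a coarse-grained carrier: one HETATM pseudo-atom per
capsomer center (chain A, residue number = 1-based site index, element
C, occupancy 1.00) with the symmetry class encoded in the B-factor
column: 0.00 pentamer, 1.00 general-position hexamer, 2.00 hexamer on a
global 2-fold axis, 3.00 hexamer on a global 3-fold axis.  All writers
are deterministic — identical inputs produce byte-identical files (no
timestamps, fixed float formats, LF line endings).
"""

from __future__ import annotations

import json
from pathlib import Path

import gemmi
import pandas as pd

from .capsid_builder import (
    FIVEFOLD,
    GENERAL,
    THREEFOLD,
    TWOFOLD,
    CapsidLattice,
    FacetMesh,
)
from .symmetry_census import SurveyReport

__all__ = [
    "CLASS_BFACTOR",
    "write_survey_csv",
    "read_survey_csv",
    "write_survey_json",
    "write_pdb",
    "write_obj",
    "write_cxc",
]

CLASS_BFACTOR = {FIVEFOLD: 0.0, GENERAL: 1.0, TWOFOLD: 2.0, THREEFOLD: 3.0}

CSV_COLUMNS = ["T", "h", "k", "centered_hexamer", "n_pentamers", "n_hexamers",
               "n_hex_on_3fold", "n_hex_on_2fold", "all_skew_compatible"]


def write_survey_csv(report: SurveyReport, path) -> None:
    df = report.to_frame()[CSV_COLUMNS]
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.6g")


def read_survey_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_survey_json(report: SurveyReport, path) -> None:
    payload = {
        "t_max": report.t_max,
        "summary": {
            "centered": report.n_centered,
            "all_skew": report.n_all_skew,
            "centered_t": report.centered_t,
            "all_skew_t": report.all_skew_t,
        },
        "rows": [
            {
                "T": r.T,
                "representations": [list(s) for s in r.representations],
                "has_hexamers": r.has_hexamers,
                "centered_hexamer": r.centered_hexamer_geometric,
                "n_pentamers": r.n_pentamers,
                "n_hexamers": r.n_hexamers,
                "n_hex_on_3fold": r.n_hexamers_on_3fold,
                "n_hex_on_2fold": r.n_hexamers_on_2fold,
                "all_skew_compatible": r.all_skew_compatible,
            }
            for r in report.rows
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def capsid_to_structure(capsid: CapsidLattice) -> gemmi.Structure:
    """Represent the capsomer centers as a gemmi Structure of HETATM
    pseudo-atoms."""
    st = gemmi.Structure()
    st.name = f"T{capsid.T} capsid lattice"
    st.raw_remarks = [
        "REMARK 300 COARSE-GRAINED CASPAR-KLUG CAPSID LATTICE",
        f"REMARK 300 T={capsid.T} H={capsid.step.h} K={capsid.step.k} "
        f"RADIUS={capsid.radius:.3f} HANDEDNESS={capsid.handedness.upper()}",
        "REMARK 300 ONE PSEUDO-ATOM PER CAPSOMER CENTER",
        "REMARK 300 B-FACTOR CLASS: 0 PENTAMER, 1 HEXAMER GENERAL,",
        "REMARK 300 2 HEXAMER ON 2-FOLD AXIS, 3 HEXAMER ON 3-FOLD AXIS",
    ]
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for i, site in enumerate(capsid.sites):
        res = gemmi.Residue()
        res.name = "PEN" if site.kind == "pentamer" else "HEX"
        res.seqid = gemmi.SeqId(i + 1, " ")
        res.het_flag = "H"
        atom = gemmi.Atom()
        atom.name = "C"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*site.position)
        atom.occ = 1.0
        atom.b_iso = CLASS_BFACTOR[site.symmetry_class]
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(capsid: CapsidLattice, path) -> None:
    capsid_to_structure(capsid).write_pdb(str(path))


def write_obj(mesh: FacetMesh, path) -> None:
    """Wavefront OBJ with v/f records, 1-based indices."""
    lines = ["# faceted capsid lattice mesh"]
    for v in mesh.vertices:
        lines.append(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    for a, b, c in mesh.triangles:
        lines.append(f"f {a + 1} {b + 1} {c + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


_CXC_COLORS = {FIVEFOLD: "hot pink", GENERAL: "cornflower blue",
               TWOFOLD: "orange", THREEFOLD: "red"}


def write_cxc(capsid: CapsidLattice, path, marker_radius: float | None = None) -> None:
    """ChimeraX-style command script placing one marker per capsomer,
    colored by symmetry class."""
    r = marker_radius if marker_radius is not None else capsid.radius / 20.0
    lines = [f"# T={capsid.T} capsid lattice markers"]
    for site in capsid.sites:
        x, y, z = site.position
        color = _CXC_COLORS[site.symmetry_class]
        lines.append(
            f"marker #1 position {x:.3f},{y:.3f},{z:.3f} radius {r:.3f} "
            f"color {color}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
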