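"""File I/O: monomer PDB structures, FASTA, descriptor tables, CG frames.

All geometry is converted to nanometres on read (PDB and MDAnalysis report
Å). Descriptor tables are delimited text with the column names
``sequence, length, ap, is_assembled, has_beta_strand,
hydrophobic_moment, net_charge`` and an explicit missing-value token.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import ANGSTROM_TO_NM, SLOT_NAMES, Peptide, StructureModel

__all__ = [
    "read_structure_pdb", "read_fasta", "write_fasta",
    "read_descriptor_table", "write_descriptor_table",
    "read_sasa_series", "read_bead_frame", "read_bead_class_table",
    "BeadFrame", "DEFAULT_BEAD_CLASSES",
]

TABLE_COLUMNS = ("sequence",) + SLOT_NAMES

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def read_structure_pdb(path, ss_labels: str) -> StructureModel:
    """Read a single-peptide monomer PDB (first model, chain-agnostic).

    ``ss_labels`` is the per-residue DSSP-style letter string; secondary
    structure is an input, never computed here. Coordinates convert Å → nm.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = PDBParser(QUIET=True).get_structure("pep", str(path))[0]
    seq, n, ca, c, cb = [], [], [], [], []
    for chain in model:
        for res in chain:
            if res.id[0] != " " or res.resname not in _THREE_TO_ONE:
                continue
            if not all(a in res for a in ("N", "CA", "C")):
                raise ValueError(f"residue {res.resname}{res.id[1]} missing backbone atoms")
            seq.append(_THREE_TO_ONE[res.resname])
            n.append(res["N"].coord)
            ca.append(res["CA"].coord)
            c.append(res["C"].coord)
            cb.append(res["CB"].coord if "CB" in res else (np.nan,) * 3)
    if not seq:
        raise ValueError(f"no canonical residues found in {path}")
    to_nm = lambda x: np.asarray(x, dtype=float) * ANGSTROM_TO_NM
    return StructureModel("".join(seq), to_nm(n), to_nm(ca), to_nm(c),
                          to_nm(cb), ss_labels)


def read_fasta(path) -> list[Peptide]:
    from Bio import SeqIO

    return [Peptide(str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, peptides, ids=None) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for i, p in enumerate(peptides):
        seq = p.sequence if isinstance(p, Peptide) else str(p)
        name = ids[i] if ids is not None else f"pep{i + 1}"
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_descriptor_table(path, sep: str = "\t", na_token: str = "NA") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, na_values=[na_token], keep_default_na=False)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"descriptor table missing columns {sorted(missing)}")
    df["sequence"] = df["sequence"].str.upper()
    return df


def write_descriptor_table(df: pd.DataFrame, path, sep: str = "\t",
                           na_token: str = "NA") -> None:
    df.to_csv(path, sep=sep, index=False, na_rep=na_token)


def read_sasa_series(path) -> np.ndarray:
    """Two-column (time, SASA) text series; '#'/'@' comment lines skipped.

    Returns the SASA column (nm²), time-ordered as stored.
    """
    times, values = [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line[0] in "#@;":
            continue
        parts = line.split()
        times.append(float(parts[0]))
        values.append(float(parts[1]))
    order = np.argsort(times, kind="stable")
    return np.asarray(values, dtype=float)[order]


#: Default radii (nm) and masses (u) by coarse-grained bead size class:
#: regular (R), small (S), tiny (T). Radii are half the LJ sigma of each
#: class; masses are the standard MARTINI values.
DEFAULT_BEAD_CLASSES: dict[str, tuple[float, float]] = {
    "R": (0.235, 72.0),
    "S": (0.205, 54.0),
    "T": (0.170, 36.0),
}


class BeadFrame:
    """Bead positions (nm) under an orthorhombic periodic box.

    ``radii`` (nm) and ``masses`` (u) come from a bead-class lookup.
    """

    def __init__(self, positions: np.ndarray, box: np.ndarray,
                 radii: np.ndarray, masses: np.ndarray):
        self.positions = np.asarray(positions, dtype=float)
        self.box = np.asarray(box, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.masses = np.asarray(masses, dtype=float)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if self.radii.shape != (n,) or np.any(self.radii <= 0):
            raise ValueError("radii must be N positive values")
        if self.masses.shape != (n,) or np.any(self.masses <= 0):
            raise ValueError("masses must be N positive values")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite positions")

    def __len__(self) -> int:
        return len(self.positions)


def read_bead_class_table(path, sep: str = "\t") -> dict[str, str]:
    """Map atom/bead names to size classes from a two-column table."""
    df = pd.read_csv(path, sep=sep)
    if not {"name", "bead_class"} <= set(df.columns):
        raise ValueError("bead class table needs columns: name, bead_class")
    return dict(zip(df["name"].astype(str), df["bead_class"].astype(str)))


def read_bead_frame(path, name_to_class: dict[str, str],
                    class_table: dict[str, tuple[float, float]] | None = None,
                    ) -> BeadFrame:
    """Read a GRO/PDB coordinate frame into a :class:`BeadFrame`.

    Bead radii and masses are assigned via ``name_to_class`` and the
    class lookup; an unknown bead name or class raises rather than
    silently defaulting.
    """
    import MDAnalysis as mda

    class_table = DEFAULT_BEAD_CLASSES if class_table is None else class_table
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    positions = u.atoms.positions * ANGSTROM_TO_NM
    box = u.dimensions[:3] * ANGSTROM_TO_NM
    radii, masses = [], []
    for name in u.atoms.names:
        if name not in name_to_class:
            raise KeyError(f"bead name {name!r} not in class map")
        cls = name_to_class[name]
        if cls not in class_table:
            raise KeyError(f"unknown bead class {cls!r}")
        r, m = class_table[cls]
        radii.append(r)
        masses.append(m)
    return BeadFrame(positions, box, np.array(radii), np.array(masses))
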