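"""Read PDB files into Cα traces with secondary-structure labels.

Only the information the alignment pipeline consumes is extracted: one
Cα coordinate per residue, the one-letter amino-acid code, the author
residue number, and a three-letter secondary-structure alphabet

    H  α-helix          (any PDB helix class)
    E  β-strand/sheet
    L  loop, turn, coil, or undetermined

assigned from the file's HELIX and SHEET records.  PDB parsing itself is
delegated to gemmi; this module owns only the reduction to a trace and
the label-assignment rules.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, replace

import gemmi
import numpy as np

__all__ = ["SSEType", "CalphaTrace", "parse_structure", "assign_sse", "load_trace"]


class SSEType(enum.Enum):
    """Three-letter secondary-structure alphabet."""

    H = "H"  # alpha-helix
    E = "E"  # beta-sheet / beta-strand
    L = "L"  # loop, turn, coil, or undetermined

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class ChainNotFoundError(KeyError):
    """Requested chain identifier is absent from the file."""


class EmptyTraceError(ValueError):
    """No Cα atoms could be extracted for the requested chain."""


@dataclass
class CalphaTrace:
    """Cα backbone trace of a single protein chain.

    ``coords``, ``residues``, ``sse`` and ``seq_ids`` are parallel arrays
    of length q ≥ 1.  Internal indexing is 0-based throughout; ``seq_ids``
    keeps the author residue numbers purely for reporting.
    """

    structure_id: str
    chain_id: str
    coords: np.ndarray  # (q, 3) float64, Å
    residues: list[str]  # one-letter codes, 'X' for non-standard
    sse: list[SSEType]
    seq_ids: list[int]
    skipped: int = 0  # residues dropped for missing Cα

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        q = len(self.coords)
        if q < 1:
            raise EmptyTraceError("empty trace")
        if not (len(self.residues) == len(self.sse) == len(self.seq_ids) == q):
            raise ValueError("parallel arrays of a trace must share one length")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinate in trace")

    def __len__(self) -> int:
        return len(self.coords)


def parse_structure(pdb_text: str, chain_id: str) -> CalphaTrace:
    """Extract the Cα trace of one chain from PDB text.

    One entry is produced per residue that has a Cα atom, in sequence
    order.  Residues lacking a Cα are skipped and counted in
    ``trace.skipped``.  For altloc ambiguity the first-listed conformer
    wins; non-standard residues get code ``'X'``.  Only the first model
    of a multi-model (NMR) file is read.  Secondary structure is set to
    all-``L``; call :func:`assign_sse` to label it from the same text.

    Raises ``ChainNotFoundError`` if the chain is absent and
    ``EmptyTraceError`` if it contains no Cα atoms.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ChainNotFoundError(f"chain {chain_id!r} not found")
    model = st[0]
    chain = model.find_chain(chain_id)
    if chain is None:
        raise ChainNotFoundError(f"chain {chain_id!r} not found")

    coords: list[tuple[float, float, float]] = []
    residues: list[str] = []
    seq_ids: list[int] = []
    skipped = 0
    for res in chain:
        ca = None
        for atom in res:
            if atom.name == "CA" and atom.element.name == "C":
                ca = atom  # first-listed conformer kept
                break
        if ca is None:
            skipped += 1
            continue
        coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
        residues.append(_THREE_TO_ONE.get(res.name, "X"))
        seq_ids.append(res.seqid.num)
    if not coords:
        raise EmptyTraceError("empty trace")
    q = len(coords)
    return CalphaTrace(
        structure_id=st.name or "",
        chain_id=chain_id,
        coords=np.array(coords),
        residues=residues,
        sse=[SSEType.L] * q,
        seq_ids=seq_ids,
        skipped=skipped,
    )


def _record_ranges(pdb_text: str, chain_id: str):
    """Yield ('H'|'E', first_seqid, last_seqid) from HELIX/SHEET records."""
    st = gemmi.read_pdb_string(pdb_text)
    for helix in st.helices:
        try:
            if helix.start.chain_name != chain_id:
                continue
            yield "H", helix.start.res_id.seqid.num, helix.end.res_id.seqid.num
        except Exception:  # malformed record: warn and drop
            warnings.warn("malformed HELIX record ignored", stacklevel=3)
    for sheet in st.sheets:
        for strand in sheet.strands:
            try:
                if strand.start.chain_name != chain_id:
                    continue
                yield "E", strand.start.res_id.seqid.num, strand.end.res_id.seqid.num
            except Exception:
                warnings.warn("malformed SHEET record ignored", stacklevel=3)


def assign_sse(pdb_text: str, trace: CalphaTrace) -> CalphaTrace:
    """Label each trace residue H/E/L from the file's HELIX/SHEET records.

    Residues covered by a HELIX record (any of the ten PDB helix classes)
    become H, those covered by a SHEET record become E, everything else
    stays L.  Where records overlap, HELIX takes precedence over SHEET.
    Returns a new trace of identical length.
    """
    labels = [SSEType.L] * len(trace)
    ranges = list(_record_ranges(pdb_text, trace.chain_id))
    # apply sheets first so helices overwrite on overlap
    for kind in ("E", "H"):
        for k, first, last in ranges:
            if k != kind:
                continue
            for i, seqid in enumerate(trace.seq_ids):
                if first <= seqid <= last:
                    labels[i] = SSEType(kind)
    return replace(trace, sse=labels)


def load_trace(pdb_text: str, chain_id: str) -> CalphaTrace:
    """parse_structure + assign_sse in one call."""
    return assign_sse(pdb_text, parse_structure(pdb_text, chain_id))
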