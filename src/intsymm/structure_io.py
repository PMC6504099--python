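"""Structure reading/writing, chain selection, Ca trace extraction and a
Ca-only secondary-structure assignment.

File parsing goes through gemmi (PDB and mmCIF).  Only polymer ATOM records
are kept; waters and hetero compounds are excluded.  Residues lacking a Ca
atom are dropped with a warning, since every downstream stage operates on the
Ca trace.  Author residue numbering (with insertion codes) is the external
coordinate system; internally, positions are 0-based indices into the trace.
Only the first model of multi-model files is used.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import EmptySelectionError, FormatError, TooShortError

logger = logging.getLogger(__name__)

MIN_TRACE_LEN = 8

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def one_letter(resname: str) -> str:
    return _THREE_TO_ONE.get(resname.upper(), "X")


@dataclass(frozen=True)
class ResidueLabel:
    """Author-numbering identifier of one residue."""

    chain: str
    number: int
    icode: str = ""
    name: str = "ALA"

    def __str__(self):
        return f"{self.chain}{self.number}{self.icode}"


@dataclass
class Residue:
    label: ResidueLabel
    atoms: dict  # atom name -> xyz (3,) array


@dataclass
class Structure:
    """A chain selection: ordered polymer residues with their atoms."""

    source_id: str
    residues: list  # of Residue

    def __len__(self):
        return len(self.residues)


@dataclass
class CoordinateTrace:
    """Ordered Ca coordinates plus residue identifiers for one selection."""

    coords: np.ndarray  # (n, 3)
    labels: list  # of ResidueLabel

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.coords) != len(self.labels):
            raise ValueError("coords and labels must have equal length")

    def __len__(self):
        return len(self.labels)

    def subtrace(self, indices) -> "CoordinateTrace":
        idx = np.asarray(indices, dtype=int)
        return CoordinateTrace(self.coords[idx], [self.labels[i] for i in idx])


@dataclass
class SSEAnnotation:
    """Per-residue secondary-structure state and element count."""

    states: list  # 'H' | 'E' | 'C' per residue
    count: int


_SELECTOR_RE = re.compile(r"^(?P<chain>[A-Za-z0-9]+)(?::(?P<start>-?\d+)-(?P<end>-?\d+))?$")


def _parse_selector(selector: str | None):
    if selector is None or selector == "":
        return None, None, None
    m = _SELECTOR_RE.match(selector)
    if m is None:
        raise FormatError(f"cannot parse selector {selector!r}")
    start = int(m.group("start")) if m.group("start") is not None else None
    end = int(m.group("end")) if m.group("end") is not None else None
    return m.group("chain"), start, end


def _best_ca(residue: gemmi.Residue):
    """Highest-occupancy Ca atom of a residue, or None."""
    best, best_occ = None, -1.0
    for atom in residue:
        if atom.name == "CA" and atom.element.name != "Ca":
            if atom.occ > best_occ:
                best, best_occ = atom, atom.occ
    return best


def load_structure(path, selector: str | None = None) -> Structure:
    """Read a PDB/mmCIF file and return the selected polymer residues.

    ``selector`` is "<chain>" or "<chain>:<start>-<end>" in author numbering
    (inclusive).  ``None`` selects the first chain.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise FormatError(f"cannot read structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"no models in {path}")
    st.setup_entities()
    model = st[0]
    chain_id, start, end = _parse_selector(selector)
    residues: list[Residue] = []
    for chain in model:
        if chain_id is not None and chain.name != chain_id:
            continue
        if chain_id is None and residues:
            break  # first chain only when unselected
        for res in chain:
            if res.is_water() or res.het_flag != "A":
                continue
            num = res.seqid.num
            if start is not None and not (start <= num <= end):
                continue
            atoms = {}
            seen = {}
            for atom in res:
                if atom.name in seen and atom.occ <= seen[atom.name]:
                    continue
                seen[atom.name] = atom.occ
                atoms[atom.name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            label = ResidueLabel(chain.name, num, res.seqid.icode.strip(), res.name)
            residues.append(Residue(label, atoms))
    if not residues:
        raise EmptySelectionError(f"selector {selector!r} matched nothing in {path}")
    return Structure(source_id=_stem(path), residues=residues)


def _stem(path) -> str:
    s = str(path)
    s = s.rsplit("/", 1)[-1]
    for ext in (".pdb", ".cif", ".ent", ".mmcif"):
        if s.lower().endswith(ext):
            return s[: -len(ext)]
    return s


def extract_ca_trace(structure: Structure) -> CoordinateTrace:
    """One point per residue with a Ca atom, in sequence order."""
    coords, labels = [], []
    for res in structure.residues:
        if "CA" not in res.atoms:
            logger.warning("residue %s lacks a CA atom; dropped", res.label)
            continue
        coords.append(res.atoms["CA"])
        labels.append(res.label)
    if len(coords) < MIN_TRACE_LEN:
        raise TooShortError(
            f"only {len(coords)} residues with Ca (need >= {MIN_TRACE_LEN})"
        )
    return CoordinateTrace(np.array(coords), labels)


# ---------------------------------------------------------------------------
# Ca-only secondary structure
# ---------------------------------------------------------------------------

#: canonical helical Ca distance windows (A)
HELIX_D13 = (4.7, 5.9)
HELIX_D14 = (5.4, 7.0)
#: minimum sustained d(i, i+2) for an extended strand (A)
STRAND_D13 = 5.5


def assign_secondary_structure(
    trace: CoordinateTrace, min_sse_len: int = 4
) -> SSEAnnotation:
    """Coarse helix/strand/coil assignment from Ca geometry only.

    A residue is helical when its i->i+3 and i->i+4 Ca distances both fall in
    the canonical helical ranges; strand when the local i->i+2 distances are
    sustained above the extended-conformation minimum.  Runs shorter than
    ``min_sse_len`` become coil; the SSE count is the number of maximal
    non-coil runs remaining.
    """
    X = trace.coords
    n = len(X)
    states = ["C"] * n

    def d(i, j):
        return float(np.linalg.norm(X[i] - X[j]))

    for i in range(n):
        if i + 4 < n:
            d13, d14 = d(i, i + 3), d(i, i + 4)
            if HELIX_D13[0] <= d13 <= HELIX_D13[1] and HELIX_D14[0] <= d14 <= HELIX_D14[1]:
                for j in range(i, min(i + 5, n)):
                    states[j] = "H"
    for i in range(n):
        if states[i] == "H":
            continue
        left = d(i - 1, i + 1) if 1 <= i < n - 1 else None
        right = d(i, i + 2) if i + 2 < n else None
        checks = [v for v in (left, right) if v is not None]
        if checks and all(v >= STRAND_D13 for v in checks):
            states[i] = "E"

    # suppress runs shorter than min_sse_len
    i = 0
    while i < n:
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        if states[i] != "C" and j - i < min_sse_len:
            for m in range(i, j):
                states[m] = "C"
        i = j

    count = 0
    prev = "C"
    for s in states:
        if s != "C" and s != prev:
            count += 1
        prev = s
    # merged adjacent H/E runs count separately already via state change
    return SSEAnnotation(states, count)


# ---------------------------------------------------------------------------
# writers (fixtures and round-trips)
# ---------------------------------------------------------------------------

def _to_gemmi(structure: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = structure.source_id
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for res in structure.residues:
        cname = res.label.chain
        if cname not in chains:
            chains[cname] = gemmi.Chain(cname)
        g = gemmi.Residue()
        g.name = res.label.name
        g.seqid = gemmi.SeqId(res.label.number, res.label.icode or " ")
        for aname, xyz in res.atoms.items():
            atom = gemmi.Atom()
            atom.name = aname
            atom.element = gemmi.Element("C" if aname == "CA" else aname[0])
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            atom.b_iso = 0.0
            g.add_atom(atom)
        chains[cname].add_residue(g)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_pdb(structure: Structure, path) -> None:
    _to_gemmi(structure).write_pdb(str(path))


def write_cif(structure: Structure, path) -> None:
    _to_gemmi(structure).make_mmcif_document().write_file(str(path))
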