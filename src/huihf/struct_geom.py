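"""Dimer-model geometry for HU homodimers.

Reads two-chain Cα models (PDB), maps residues onto the 90-column core
frame, and computes the measurement suite characterising the HU fold:
inter-helix-axis angles (helix 1 vs 2 and 2 vs 3 within a monomer, helix 2
vs helix 2' across the dimer), inter-chain Cα distances (between the
C-terminal residues of the two helices 2, and at the β2 strand ends /
β5 strand starts that frame the DNA-binding platform), and rigid-body
superposition RMSD.

All coordinates are in nanometres; PDB Ångströms are converted on read.
Helix axes are total-least-squares lines (principal axis of the centred
Cα cloud) and inter-axis angles are undirected, reported in [0, 90]°.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import gemmi
import numpy as np

from .seq_core import CORE_LENGTH, CoreAlignedSequence

logger = logging.getLogger("huihf.struct_geom")

ANGSTROM_PER_NM = 10.0

#: Default secondary-structure spans on the core frame (1-based, inclusive).
#: Helix 1 is 12 residues and helix 2 is 21 residues long.  Block
#: boundaries are calibration data and can be overridden.
DEFAULT_SPANS: dict[str, tuple[int, int]] = {
    "a1": (2, 13),
    "a2": (17, 37),
    "b1": (41, 46),
    "b2": (48, 56),
    "b3": (57, 63),
    "b4": (64, 70),
    "b5": (73, 80),
    "a3": (84, 90),
}

#: Inter-chain distance measurement columns: C-termini of beta strand 2
#: plus neighbours, and N-termini of beta strand 5 plus neighbours.
B2_COLUMNS = (54, 55, 56)
B5_COLUMNS = (73, 74, 75)


@dataclass
class SecondaryStructureSpans:
    spans: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SPANS)
    )

    def __post_init__(self) -> None:
        ordered = sorted(self.spans.values())
        for (lo, hi) in ordered:
            if not (1 <= lo <= hi <= CORE_LENGTH):
                raise ValueError(f"span ({lo}, {hi}) outside [1, 90]")
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ordered, ordered[1:]):
            if b_lo <= a_hi:
                raise ValueError("secondary-structure spans overlap")

    def __getitem__(self, name: str) -> tuple[int, int]:
        return self.spans[name]


@dataclass
class Residue:
    number: int
    aa: str
    xyz: np.ndarray  # (3,), nm


@dataclass
class ChainTrace:
    chain_id: str
    residues: list[Residue]
    #: per-residue core column (1..90) or None for extension/insertion
    core_columns: list[int | None] | None = None

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.stack([r.xyz for r in self.residues])

    def column_xyz(self) -> dict[int, np.ndarray]:
        if self.core_columns is None:
            raise ValueError("chain has no core mapping; run map_core first")
        return {
            col: res.xyz
            for col, res in zip(self.core_columns, self.residues)
            if col is not None
        }


@dataclass
class DimerModel:
    model_id: str
    chains: list[ChainTrace]

    def __post_init__(self) -> None:
        if len(self.chains) != 2:
            raise ValueError(f"expected dimer, got {len(self.chains)} chain(s)")
        for ch in self.chains:
            xyz = ch.coords()
            if not np.all(np.isfinite(xyz)):
                raise ValueError(f"chain {ch.chain_id}: non-finite coordinates")
            if ch.core_columns is not None:
                cols = [c for c in ch.core_columns if c is not None]
                if any(b <= a for a, b in zip(cols, cols[1:])):
                    raise ValueError("core-column mapping must be increasing")

    @property
    def mapped(self) -> bool:
        return all(ch.core_columns is not None for ch in self.chains)


@dataclass
class HelixAxis:
    direction: np.ndarray  # unit 3-vector
    centroid: np.ndarray   # nm

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("axis direction must be a unit vector")


@dataclass
class GeometryReport:
    """The per-model measurement set.  Angles in degrees, distances in nm.
    Missing measurements (span unresolvable in a chain) are None."""
    model_id: str
    angle_a1a2: tuple[float | None, float | None]
    angle_a2a3: tuple[float | None, float | None]
    angle_a2a2_cross: float | None
    dist_h2C: float | None
    dist_b2: tuple[float | None, float | None, float | None]
    dist_b5: tuple[float | None, float | None, float | None]

    def as_dict(self) -> dict[str, float | None]:
        d: dict[str, float | None] = {"model_id": self.model_id}  # type: ignore[dict-item]
        d["angle_a1a2_A"], d["angle_a1a2_B"] = self.angle_a1a2
        d["angle_a2a3_A"], d["angle_a2a3_B"] = self.angle_a2a3
        d["angle_a2a2_cross"] = self.angle_a2a2_cross
        d["dist_h2C"] = self.dist_h2C
        for col, v in zip(B2_COLUMNS, self.dist_b2):
            d[f"dist_b2_{col}"] = v
        for col, v in zip(B5_COLUMNS, self.dist_b5):
            d[f"dist_b5_{col}"] = v
        return d


# ---------------------------------------------------------------------------
# model reading
# ---------------------------------------------------------------------------

def read_model(pdb_text: str, model_id: str = "model") -> DimerModel:
    """Parse a two-chain protein PDB into a Cα trace model (nm).

    Only the first MODEL is read; waters and other non-amino-acid HETATM
    residues are ignored.  A missing Cα anywhere is an error listing the
    offending residues.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    if len(structure) == 0:
        raise ValueError("empty PDB")
    model = structure[0]
    structure.setup_entities()

    chains: list[ChainTrace] = []
    missing: list[str] = []
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            ca = res.find_atom("CA", "*")
            if ca is None:
                missing.append(f"{chain.name}/{res.name}{res.seqid.num}")
                continue
            one = gemmi.find_tabulated_residue(res.name).one_letter_code.upper()
            residues.append(
                Residue(
                    number=res.seqid.num,
                    aa=one,
                    xyz=np.array([ca.pos.x, ca.pos.y, ca.pos.z]) / ANGSTROM_PER_NM,
                )
            )
        if residues:
            chains.append(ChainTrace(chain_id=chain.name, residues=residues))
    if missing:
        raise ValueError(f"residues missing CA atoms: {', '.join(missing)}")
    if len(chains) != 2:
        raise ValueError(f"expected dimer, got {len(chains)} protein chain(s)")
    chains.sort(key=lambda ch: ch.chain_id)
    return DimerModel(model_id=model_id, chains=chains)


def map_core(model: DimerModel, aligned: CoreAlignedSequence) -> DimerModel:
    """Label every residue of both chains with its core column.

    The chain sequence must equal the aligned raw sequence (homodimer:
    the same alignment applies to both chains).  Residues belonging to
    terminal extensions or insertions get no column.
    """
    labels: list[int | None] = [None] * len(aligned.n_ext)
    for col in range(1, CORE_LENGTH + 1):
        if aligned.core[col - 1] != "-":
            labels.append(col)
        if col in aligned.insertions:
            labels.extend([None] * len(aligned.insertions[col]))
    labels.extend([None] * len(aligned.c_ext))

    for ch in model.chains:
        seq = ch.sequence
        if seq != aligned.raw_seq:
            for pos, (a, b) in enumerate(zip(seq, aligned.raw_seq)):
                if a != b:
                    raise ValueError(
                        f"chain {ch.chain_id} mismatches aligned sequence at "
                        f"position {pos + 1}: {a} != {b}"
                    )
            raise ValueError(
                f"chain {ch.chain_id} length {len(seq)} != aligned "
                f"length {len(aligned.raw_seq)}"
            )
        ch.core_columns = list(labels)
    mapped = [c for c in labels if c is not None]
    if len(mapped) < 80:
        raise ValueError(f"only {len(mapped)} core columns mapped (need >= 80)")
    return model


# ---------------------------------------------------------------------------
# axes, angles, distances
# ---------------------------------------------------------------------------

def fit_axis(coords: np.ndarray | Sequence[np.ndarray]) -> HelixAxis:
    """Total-least-squares line through Cα points (principal axis of the
    centred cloud).  The direction sign points toward increasing residue
    number (first to last point)."""
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if len(pts) < 5:
        raise ValueError(f"need at least 5 points to fit an axis, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-12:
        raise ValueError("degenerate point cloud: no principal axis")
    direction = vt[0]
    if np.dot(direction, pts[-1] - pts[0]) < 0:
        direction = -direction
    return HelixAxis(direction=direction / np.linalg.norm(direction),
                     centroid=centroid)


def interaxis_angle(a: HelixAxis, b: HelixAxis) -> float:
    """Undirected angle between two axes, in degrees, in [0, 90]."""
    c = abs(float(np.dot(a.direction, b.direction)))
    return math.degrees(math.acos(min(c, 1.0)))


def _span_axis(
    colmap: Mapping[int, np.ndarray], span: tuple[int, int]
) -> HelixAxis | None:
    pts = [colmap[c] for c in range(span[0], span[1] + 1) if c in colmap]
    if len(pts) < 5:
        return None
    return fit_axis(np.stack(pts))


def _pair_distance(
    a: Mapping[int, np.ndarray], b: Mapping[int, np.ndarray], col: int
) -> float | None:
    if col not in a or col not in b:
        return None
    return float(np.linalg.norm(a[col] - b[col]))


def geometry_report(
    model: DimerModel,
    spans: SecondaryStructureSpans | None = None,
) -> GeometryReport:
    """Compute the full angle/distance measurement set of a mapped dimer.

    Any measurement whose span has fewer than 5 mapped residues, or whose
    column is unmapped in either chain, is reported as None rather than
    fabricated.
    """
    if not model.mapped:
        raise ValueError("model must be core-mapped; run map_core first")
    spans = spans or SecondaryStructureSpans()
    maps = [ch.column_xyz() for ch in model.chains]

    axes = {
        (name, i): _span_axis(maps[i], spans[name])
        for name in ("a1", "a2", "a3")
        for i in (0, 1)
    }

    def angle(n1: str, n2: str, i: int, j: int) -> float | None:
        a, b = axes[(n1, i)], axes[(n2, j)]
        if a is None or b is None:
            return None
        return interaxis_angle(a, b)

    h2_cterm = spans["a2"][1]
    return GeometryReport(
        model_id=model.model_id,
        angle_a1a2=(angle("a1", "a2", 0, 0), angle("a1", "a2", 1, 1)),
        angle_a2a3=(angle("a2", "a3", 0, 0), angle("a2", "a3", 1, 1)),
        angle_a2a2_cross=angle("a2", "a2", 0, 1),
        dist_h2C=_pair_distance(maps[0], maps[1], h2_cterm),
        dist_b2=tuple(_pair_distance(maps[0], maps[1], c) for c in B2_COLUMNS),
        dist_b5=tuple(_pair_distance(maps[0], maps[1], c) for c in B5_COLUMNS),
    )


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal proper rotation aligning centred P onto centred Q."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose_rmsd(
    a: DimerModel,
    b: DimerModel,
    columns: Sequence[int] | None = None,
) -> float:
    """Minimal Cα RMSD (nm) between two mapped dimers after optimal rigid
    superposition (rotation + translation, no reflection), over the common
    mapped core columns of both chains (optionally restricted)."""
    if not (a.mapped and b.mapped):
        raise ValueError("both models must be core-mapped")
    pa, pb = [], []
    used_cols: set[int] = set()
    for i in (0, 1):
        ma, mb = a.chains[i].column_xyz(), b.chains[i].column_xyz()
        common = sorted(set(ma) & set(mb))
        if columns is not None:
            common = [c for c in common if c in set(columns)]
        used_cols.update(common)
        pa.extend(ma[c] for c in common)
        pb.extend(mb[c] for c in common)
    if len(used_cols) < 3:
        raise ValueError(
            f"need >= 3 common mapped columns, got {len(used_cols)}"
        )
    P = np.stack(pa)
    Q = np.stack(pb)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    R = _kabsch_rotation(Pc, Qc)
    diff = Pc @ R.T - Qc
    return float(np.sqrt((diff ** 2).sum() / len(P)))


# ---------------------------------------------------------------------------
# PDB writing (Cα traces)
# ---------------------------------------------------------------------------

_AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR",
}


def write_pdb(model: DimerModel) -> str:
    """Serialise a Cα trace dimer as PDB text (coordinates nm -> Å)."""
    lines = [f"REMARK   1 {model.model_id}"]
    serial = 1
    for ch in model.chains:
        for res in ch.residues:
            x, y, z = res.xyz * ANGSTROM_PER_NM
            lines.append(
                f"ATOM  {serial:5d}  CA  {_AA3[res.aa]:>3s} {ch.chain_id:1s}"
                f"{res.number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                f"           C"
            )
            serial += 1
        lines.append(f"TER   {serial:5d}      {_AA3[ch.residues[-1].aa]:>3s} "
                     f"{ch.chain_id:1s}{ch.residues[-1].number:4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
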