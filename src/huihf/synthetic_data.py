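"""Seeded generators emulating the statistical structure of the inputs.

Three generators cover the three analysis layers:

* ``generate_family`` -- clade-structured 90-column core families with a
  controlled per-column identity, indel events concentrated in the known
  hotspot regions, and charged terminal extensions (optionally carrying
  PAKKA repeats).  Columns mutate i.i.d.; phylogenetic correlation is
  deliberately not modelled.
* ``generate_dimer`` -- two-chain Cα scaffolds with exactly prescribed
  helix-axis angles and inter-chain distances.  The dimer is built with
  C2 symmetry about the z axis, so every inter-chain distance reduces to
  twice a radial coordinate and every target can be hit by construction;
  fitted (principal-axis) helix directions are placed exactly, making
  the geometry measurement suite a round-trip.
* ``generate_emsa`` / ``generate_ladder`` -- titration band fractions
  drawn from the finite-lattice cooperative binding model at
  depletion-consistent free-ligand concentrations, with truncated
  Gaussian quantification noise; ladders report the highest complex
  visible above a detection threshold (default 5% of lane signal).

All randomness flows through a single integer seed per spec.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from . import binding, struct_geom
from .binding import EmsaTitration, LadderExperiment, LatticeBindingModel
from .seq_core import (
    AMINO_ACIDS,
    CORE_LENGTH,
    DEFAULT_REGIONS,
    CoreAlignedSequence,
)
from .struct_geom import ChainTrace, DimerModel, Residue, SecondaryStructureSpans

logger = logging.getLogger("huihf.synthetic_data")

#: E. coli HU alpha subunit (90 aa) -- the default base consensus for
#: synthetic families and the default residue identities of dimer scaffolds.
HU_ALPHA_ECOLI = (
    "MNKTQLIDVIAEKAELSKTQAKAALESTLAAITESLKEGDAVQLVGFGTFKVNHRAERTG"
    "RNPQTGKEIKIAAANVPAFVSGKALKDAVK"
)
#: E. coli HU beta subunit (90 aa); shares 62/90 core positions with HU alpha.
HU_BETA_ECOLI = (
    "MNKSQLIDKIAAGADISKAAAGRALDAIIASVTESLKEGDDVALVGFGTFAVKERAARTG"
    "RNPQTGKEITIAAAKVPSFRAGKALKDAVN"
)

_FILLER = "AGSTQNV"  # neutral filler: no K/R/D/E and no P, so no stray PAKKA


# ---------------------------------------------------------------------------
# sequence families
# ---------------------------------------------------------------------------

@dataclass
class TerminalSpec:
    side: str                   # "N" or "C"
    length: int = 111
    count_K: int = 29
    count_R: int = 5
    count_D: int = 0
    count_E: int = 1
    pakka_repeats: int = 2

    def __post_init__(self) -> None:
        if self.side not in ("N", "C"):
            raise ValueError("side must be 'N' or 'C'")
        consumed = (
            5 * self.pakka_repeats
            + (self.count_K - 2 * self.pakka_repeats)
            + self.count_R + self.count_D + self.count_E
        )
        if self.count_K < 2 * self.pakka_repeats:
            raise ValueError("count_K smaller than lysines inside PAKKA blocks")
        if consumed > self.length:
            raise ValueError("terminal composition exceeds its length")


@dataclass
class SeqFamilySpec:
    """Generator conditions for one synthetic clade family.

    Defaults reflect the family-wide statistics: ~10% of sequences carry
    an insert (80% of inserts a single residue), insertion hotspots split
    34/18/15% across the helix-1/2 loop, helix-2/strand-1 turn and arm
    tip, and ~3.4% of sequences carry a (mostly single-column, mostly
    loop) deletion.
    """
    consensus: str = HU_ALPHA_ECOLI
    n_sequences: int = 50
    identity: float = 0.69
    insertion_prob: float = 0.10
    region_weights: dict[str, float] = field(
        default_factory=lambda: {
            "loop_a1_a2": 0.34,
            "turn_a2_b1": 0.18,
            "arm_tip": 0.15,
            "other": 0.33,
        }
    )
    insert_len_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.80, 2: 0.15, 3: 0.05}
    )
    deletion_prob: float = 0.034
    deletion_region_weights: dict[str, float] = field(
        default_factory=lambda: {
            "loop_a1_a2": 0.70,
            "turn_a2_b1": 0.07,
            "arm_tip": 0.0,
            "other": 0.23,
        }
    )
    n_terminal: TerminalSpec | None = None
    c_terminal: TerminalSpec | None = None
    name: str = "synthetic"
    group: str = "HU"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.consensus) != CORE_LENGTH:
            raise ValueError("consensus must be 90 residues")
        if not 0.0 < self.identity <= 1.0:
            raise ValueError("identity fraction must lie in (0, 1]")
        for weights in (self.region_weights, self.deletion_region_weights):
            if abs(sum(weights.values()) - 1.0) > 1e-9:
                raise ValueError("region weights must sum to 1")


def _region_columns(region: str) -> list[int]:
    if region == "other":
        taken = set()
        for lo, hi in DEFAULT_REGIONS.values():
            taken.update(range(lo, hi + 1))
        return [c for c in range(1, CORE_LENGTH) if c not in taken]
    lo, hi = DEFAULT_REGIONS[region]
    return list(range(lo, min(hi, CORE_LENGTH - 1) + 1))


def _pick(rng: np.random.Generator, weights: dict) -> object:
    keys = list(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def make_terminus(spec: TerminalSpec, rng: np.random.Generator) -> str:
    """A terminal extension with exact length, K/R/D/E counts and PAKKA
    repeat count.  Loose residues avoid P, so the only PAKKA occurrences
    are the intact blocks."""
    loose_k = spec.count_K - 2 * spec.pakka_repeats
    loose = (
        ["K"] * loose_k + ["R"] * spec.count_R
        + ["D"] * spec.count_D + ["E"] * spec.count_E
    )
    n_filler = spec.length - 5 * spec.pakka_repeats - len(loose)
    # PAKKA blocks consume 2 A per block; filler may add more A freely
    loose += [
        _FILLER[i] for i in rng.integers(0, len(_FILLER), size=n_filler)
    ]
    tokens = ["PAKKA"] * spec.pakka_repeats + loose
    order = rng.permutation(len(tokens))
    ext = "".join(tokens[i] for i in order)
    assert len(ext) == spec.length
    return ext


def mutate_consensus(
    consensus: str, identity: float, rng: np.random.Generator
) -> str:
    """Mutate each column independently with probability 1 - identity to a
    uniformly chosen different residue."""
    out = list(consensus)
    for c in range(len(out)):
        if rng.random() < 1.0 - identity:
            choices = [a for a in AMINO_ACIDS if a != out[c]]
            out[c] = choices[rng.integers(0, 19)]
    return "".join(out)


def generate_family(spec: SeqFamilySpec) -> list[CoreAlignedSequence]:
    """Generate a seeded clade family of core-aligned sequences."""
    rng = np.random.default_rng(spec.seed)
    seqs = []
    for i in range(spec.n_sequences):
        core = list(mutate_consensus(spec.consensus, spec.identity, rng))
        insertions: dict[int, str] = {}
        if rng.random() < spec.deletion_prob:
            region = _pick(rng, spec.deletion_region_weights)
            cols = _region_columns(region)
            core[cols[rng.integers(0, len(cols))] - 1] = "-"
        if rng.random() < spec.insertion_prob:
            region = _pick(rng, spec.region_weights)
            cols = _region_columns(region)
            anchor = cols[rng.integers(0, len(cols))]
            length = _pick(rng, spec.insert_len_dist)
            insertions[anchor] = "".join(
                AMINO_ACIDS[j] for j in rng.integers(0, 20, size=length)
            )
        n_ext = make_terminus(spec.n_terminal, rng) if spec.n_terminal else ""
        c_ext = make_terminus(spec.c_terminal, rng) if spec.c_terminal else ""
        seqs.append(
            CoreAlignedSequence.from_parts(
                id=f"{spec.name}_{i:03d}",
                core="".join(core),
                insertions=insertions,
                n_ext=n_ext,
                c_ext=c_ext,
                organism=f"synthetic organism {i}",
                group=spec.group,
                clade=spec.name,
            )
        )
    return seqs


def generate_clade_consensi(
    n_clades: int,
    inter_identity: float = 0.65,
    base: str = HU_ALPHA_ECOLI,
    seed: int = 0,
) -> list[str]:
    """Derive distinct clade consensus sequences from a base, each at the
    given expected identity to the base (pairwise identity between two
    derived clades is correspondingly lower)."""
    rng = np.random.default_rng(seed)
    return [mutate_consensus(base, inter_identity, rng) for _ in range(n_clades)]


# ---------------------------------------------------------------------------
# dimer scaffolds
# ---------------------------------------------------------------------------

@dataclass
class DimerGeomSpec:
    """Targets of the geometry measurement suite (degrees / nm) plus the
    ideal-helix parameters used for the Cα traces."""
    angle_a1a2: float = 62.7
    angle_a2a3: float = 63.7
    angle_a2a2_cross: float = 83.5
    dist_h2C: float = 3.33
    dist_b2: tuple[float, float, float] = (2.48, 2.90, 2.64)
    dist_b5: tuple[float, float, float] = (3.12, 2.67, 3.42)
    rise: float = 0.15          # nm per residue
    radius: float = 0.23        # nm
    twist: float = 100.0        # degrees per residue
    sequence: str = HU_ALPHA_ECOLI
    n_ext: str = ""
    model_id: str = "synthetic_dimer"
    seed: int = 0

    def __post_init__(self) -> None:
        for ang in (self.angle_a1a2, self.angle_a2a3, self.angle_a2a2_cross):
            if not 0.0 < ang < 90.0:
                raise ValueError(f"angle {ang} outside (0, 90) degrees")
        for d in (self.dist_h2C, *self.dist_b2, *self.dist_b5):
            if d <= 0:
                raise ValueError("distances must be positive")
        if len(self.sequence) != CORE_LENGTH:
            raise ValueError("sequence must be 90 residues")


def _ideal_helix(n_res: int, rise: float, radius: float, twist: float) -> np.ndarray:
    j = np.arange(n_res)
    theta = np.radians(twist) * j
    return np.stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * j], axis=1
    )


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array(
        [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], dtype=float
    )
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def _rotate_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K


def _place_helix(
    n_res: int,
    direction: np.ndarray,
    cterm_at: np.ndarray,
    spec: DimerGeomSpec,
) -> np.ndarray:
    """Ideal helix whose *fitted* principal axis equals ``direction``
    exactly and whose C-terminal Cα sits at ``cterm_at``."""
    pts = _ideal_helix(n_res, spec.rise, spec.radius, spec.twist)
    axis = struct_geom.fit_axis(pts)
    R = _rotation_between(axis.direction, np.asarray(direction, dtype=float))
    pts = pts @ R.T
    return pts + (np.asarray(cterm_at, dtype=float) - pts[-1])


def _direction_at_angle(
    ref: np.ndarray, angle_deg: float, azimuth: float
) -> np.ndarray:
    """A unit vector at ``angle_deg`` from ``ref``, azimuth chosen around it."""
    ref = ref / np.linalg.norm(ref)
    perp = np.cross(ref, [0.0, 1.0, 0.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(ref, [1.0, 0.0, 0.0])
    perp /= np.linalg.norm(perp)
    perp = _rotate_about(ref, azimuth) @ perp
    return _rotate_about(perp, math.radians(angle_deg)) @ ref


def generate_dimer(spec: DimerGeomSpec) -> tuple[DimerModel, str]:
    """Build a C2-symmetric Cα dimer scaffold hitting the geometry targets.

    Chain B is chain A rotated 180 degrees about z, so inter-chain
    distances equal twice the radial (xy) distance of the corresponding
    chain-A atom, and the helix-2/helix-2' crossing angle is set by the
    inclination of the helix-2 axis to z.  Returns the model (already
    core-mapped) and its PDB text.
    """
    rng = np.random.default_rng(spec.seed)
    spans = SecondaryStructureSpans()
    a1_lo, a1_hi = spans["a1"]
    a2_lo, a2_hi = spans["a2"]
    a3_lo, a3_hi = spans["a3"]

    alpha = math.radians(spec.angle_a2a2_cross) / 2.0
    d2 = np.array([math.sin(alpha), 0.0, math.cos(alpha)])

    coords = np.zeros((CORE_LENGTH, 3))
    placed = np.zeros(CORE_LENGTH, dtype=bool)

    def put(col: int, xyz: np.ndarray) -> None:
        coords[col - 1] = xyz
        placed[col - 1] = True

    # helix 2: C-terminal residue at radius dist_h2C / 2
    h2 = _place_helix(
        a2_hi - a2_lo + 1, d2, np.array([spec.dist_h2C / 2.0, 0.0, 0.0]), spec
    )
    for col, xyz in zip(range(a2_lo, a2_hi + 1), h2):
        put(col, xyz)

    # helix 1: fitted axis at the target angle to helix 2, C-term feeding
    # into the helix-2 N-terminus
    d1 = _direction_at_angle(d2, spec.angle_a1a2, rng.uniform(0, 2 * math.pi))
    h1 = _place_helix(
        a1_hi - a1_lo + 1, d1, coords[a2_lo - 1] - 1.2 * d2 + 0.5 * d1, spec
    )
    for col, xyz in zip(range(a1_lo, a1_hi + 1), h1):
        put(col, xyz)

    # helix 3: near the helix-2 C-terminal region
    d3 = _direction_at_angle(d2, spec.angle_a2a3, rng.uniform(0, 2 * math.pi))
    h3 = _place_helix(
        a3_hi - a3_lo + 1, d3, coords[a2_hi - 1] + 0.8 * d2 + 0.9 * d3, spec
    )
    for col, xyz in zip(range(a3_lo, a3_hi + 1), h3):
        put(col, xyz)

    # DNA-binding arm anchors: inter-chain distance targets become radii
    arm_z = coords[a2_hi - 1][2] - 1.0
    for cols, dists, z0, dz in (
        ((54, 55, 56), spec.dist_b2, arm_z, -0.31),
        ((73, 74, 75), spec.dist_b5, arm_z - 0.45, 0.12),
    ):
        for k, (col, d) in enumerate(zip(cols, dists)):
            put(col, np.array([d / 2.0, 0.0, z0 + k * dz]))

    # everything else: linear interpolation between the nearest placed
    # neighbours (chain ends extrapolate along the local direction)
    anchor_cols = [c for c in range(1, CORE_LENGTH + 1) if placed[c - 1]]
    first, last = anchor_cols[0], anchor_cols[-1]
    for col in range(1, CORE_LENGTH + 1):
        if placed[col - 1]:
            continue
        if col < first:
            step = coords[first - 1] - coords[first]
            xyz = coords[first - 1] + (first - col) * 0.38 * step / (
                np.linalg.norm(step) or 1.0
            )
        elif col > last:
            step = coords[last - 1] - coords[last - 2]
            xyz = coords[last - 1] + (col - last) * 0.38 * step / (
                np.linalg.norm(step) or 1.0
            )
        else:
            lo = max(c for c in anchor_cols if c < col)
            hi = min(c for c in anchor_cols if c > col)
            t = (col - lo) / (hi - lo)
            xyz = (1 - t) * coords[lo - 1] + t * coords[hi - 1]
        put(col, xyz)

    c2z = np.diag([-1.0, -1.0, 1.0])

    seq = spec.n_ext + spec.sequence
    n_off = len(spec.n_ext)
    ext_pts = [
        coords[0] - (k + 1) * 0.38 * (coords[1] - coords[0])
        / np.linalg.norm(coords[1] - coords[0])
        for k in reversed(range(n_off))
    ]
    all_a = np.vstack([np.array(ext_pts).reshape(-1, 3), coords])

    chains = []
    for chain_id, xform in (("A", np.eye(3)), ("B", c2z)):
        residues = [
            Residue(number=i + 1, aa=seq[i], xyz=xform @ all_a[i])
            for i in range(len(seq))
        ]
        cols: list[int | None] = [None] * n_off + list(range(1, CORE_LENGTH + 1))
        chains.append(
            ChainTrace(chain_id=chain_id, residues=residues, core_columns=cols)
        )
    model = DimerModel(model_id=spec.model_id, chains=chains)
    return model, struct_geom.write_pdb(model)


# ---------------------------------------------------------------------------
# EMSA simulation
# ---------------------------------------------------------------------------

@dataclass
class EmsaSimSpec:
    model: LatticeBindingModel
    dna_total: float = 200e-9
    protein_totals: tuple[float, ...] | None = None   # None -> auto 10-90%
    noise_sd: float = 0.02
    n_points: int = 8
    dna_label: str = "ds"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.dna_total <= 0:
            raise ValueError("dna_total must be positive")


def saturation(model: LatticeBindingModel, dna_total: float, P: float) -> float:
    L = binding.solve_free_ligand(model, dna_total, P)
    return binding.mean_occupancy(model, L) / model.kmax


def pick_protein_totals(
    model: LatticeBindingModel,
    dna_total: float,
    n_points: int = 8,
    span: tuple[float, float] = (0.10, 0.90),
) -> np.ndarray:
    """Geometrically spaced total protein concentrations whose end points
    hit the requested fractional lattice saturation."""
    def solve(target: float) -> float:
        lo, hi = 1e-15, 1e-3
        while saturation(model, dna_total, hi) < target:
            hi *= 10.0
            if hi > 1.0:
                raise RuntimeError("cannot reach requested saturation")
        return optimize.brentq(
            lambda P: saturation(model, dna_total, P) - target, lo, hi,
            rtol=1e-10,
        )

    p_lo, p_hi = solve(span[0]), solve(span[1])
    return np.geomspace(p_lo, p_hi, n_points)


def generate_emsa(spec: EmsaSimSpec) -> EmsaTitration:
    """Simulated titration band fractions from the lattice model with
    truncated Gaussian noise, renormalised per lane."""
    rng = np.random.default_rng(spec.seed)
    model = spec.model
    if spec.protein_totals is None:
        protein_totals = pick_protein_totals(model, spec.dna_total, spec.n_points)
    else:
        protein_totals = np.asarray(spec.protein_totals, dtype=float)
    pred = binding.predicted_fractions(model, spec.dna_total, protein_totals)
    if spec.noise_sd > 0:
        pred = np.clip(pred + rng.normal(0.0, spec.noise_sd, pred.shape), 0.0, None)
        pred /= pred.sum(axis=1, keepdims=True)
    return EmsaTitration(
        dna_label=spec.dna_label,
        dna_length=model.N,
        dna_total=spec.dna_total,
        protein_totals=protein_totals,
        fractions=pred,
    )


def generate_ladder(
    n: int,
    K: float,
    omega: float,
    lengths: Sequence[int] = tuple(range(20, 49)),
    protein_totals: Sequence[float] = tuple(200e-9 * 2 ** k for k in range(5)),
    dna_total: float = 200e-9,
    detection_threshold: float = 0.05,
) -> LadderExperiment:
    """Maximum visible complex count per duplex length: the largest k
    whose occupancy probability reaches the detection threshold at any of
    the tested protein concentrations.  The default series doubles from
    200 nM until no further complex appears on a 48-bp duplex, mimicking
    a titration run to saturation of the ladder."""
    entries = []
    for N in lengths:
        best = 0
        for P in protein_totals:
            model = LatticeBindingModel(n=n, K=K, omega=omega, N=N)
            L = binding.solve_free_ligand(model, dna_total, P)
            p = binding.lattice_partition(model, L).p_k
            visible = np.nonzero(p >= detection_threshold)[0]
            if len(visible):
                best = max(best, int(visible.max()))
        entries.append((int(N), best))
    return LadderExperiment(entries=entries)
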