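"""Branched-DNA construct assembly and classification.

EMSA substrates are built by annealing up to four synthetic
oligonucleotides.  Annealing is modelled as exact antiparallel
Watson-Crick string matching: the longest complementary match of at
least 8 bp between unpaired regions is paired first, repeatedly, with
deterministic tie-breaks.  Thermodynamics (melting, mismatches,
hairpins) is deliberately ignored -- the oligo sets are designed for
unique pairing.

The resulting base-pair topology is classified into the standard EMSA
structure categories: ds (full duplex), n (nicked duplex), A1/A3/A7
(bulges of 1/3/7 unpaired bases), ov (single-strand overhang), fork
(two tails at one duplex end), J (four-way junction), iJ (junction
lacking one strand) and inv (strand displacement/invasion).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

logger = logging.getLogger("huihf.constructs")

MIN_MATCH = 8

#: the 48-mer duplex template of the truncation series
D48 = "AGTCTAGAGTGCAGTTGAGTCCTTGCTACGACGGATCCCTTAGGTCAG"
#: anneals to the 5' 20 nt of D-48, leaving a 28-nt 3' overhang
J24_RGT = "ACTCAACTGCACTCTAGACT"

STRUCTURE_LABELS = (
    "ds", "n", "A1", "A3", "A7", "J", "fork", "ov", "iJ", "inv", "unknown"
)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class NoStableAssembly(ValueError):
    pass


@dataclass(frozen=True)
class Oligo:
    name: str
    seq: str
    labeled: bool = False   # carries the 5'-HEX fluorophore

    def __post_init__(self) -> None:
        if set(self.seq) - set("ACGT"):
            raise ValueError(f"{self.name}: alphabet must be ACGT")
        if len(self.seq) < 8:
            raise ValueError(f"{self.name}: oligo shorter than 8 nt")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DuplexSegment:
    """An antiparallel paired run: strand_i[start_i + t] pairs
    strand_j[start_j + length - 1 - t] for t in 0..length-1."""
    strand_i: int
    start_i: int
    strand_j: int
    start_j: int
    length: int


@dataclass
class Assembly:
    strands: list[Oligo]
    segments: list[DuplexSegment] = field(default_factory=list)
    #: pairing[s][p] = (other strand index, other position) or None
    pairing: list[list[tuple[int, int] | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pairing:
            self.pairing = [[None] * len(o) for o in self.strands]
        self.validate()

    def validate(self) -> None:
        """Independent base-by-base check: every recorded pair is a
        reciprocal Watson-Crick complement and no base is paired twice."""
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        seen: set[tuple[int, int]] = set()
        for s, row in enumerate(self.pairing):
            for p, mate in enumerate(row):
                if mate is None:
                    continue
                ms, mp = mate
                if self.pairing[ms][mp] != (s, p):
                    raise ValueError("pairing is not reciprocal")
                if comp[self.strands[s].seq[p]] != self.strands[ms].seq[mp]:
                    raise ValueError(
                        f"non-complementary pair {s}:{p} -- {ms}:{mp}"
                    )
                if (s, p) in seen:
                    raise ValueError("base paired twice")
                seen.add((s, p))

    def unpaired_runs(self) -> list[tuple[int, int, int, bool]]:
        """Maximal unpaired runs as (strand, start, length, terminal)."""
        runs = []
        for s, row in enumerate(self.pairing):
            start = None
            for p, mate in enumerate(row):
                if mate is None and start is None:
                    start = p
                elif mate is not None and start is not None:
                    runs.append((s, start, p - start, start == 0))
                    start = None
            if start is not None:
                runs.append((s, start, len(row) - start, True))
        return runs

    def fully_paired(self, s: int) -> bool:
        return all(m is not None for m in self.pairing[s])

    def partner_strands(self, s: int) -> set[int]:
        return {m[0] for m in self.pairing[s] if m is not None}


# ---------------------------------------------------------------------------
# annealing
# ---------------------------------------------------------------------------

def _longest_matches(a: Oligo, b: Oligo, paired_a, paired_b):
    """All maximal exact antiparallel complementary runs between unpaired
    regions of a and b, as (length, start_a, start_b) with
    a[start_a .. start_a+len-1] pairing b reversed from start_b+len-1."""
    rc_b = revcomp(b.seq)   # rc index q <-> b position len(b)-1-q
    La, Lb = len(a), len(b)
    best: list[tuple[int, int, int]] = []
    prev = [0] * (Lb + 1)
    for p in range(La):
        cur = [0] * (Lb + 1)
        for q in range(Lb):
            bpos = Lb - 1 - q
            if (
                a.seq[p] == rc_b[q]
                and paired_a[p] is None
                and paired_b[bpos] is None
            ):
                cur[q + 1] = prev[q] + 1
        prev = cur
        for q in range(Lb):
            if cur[q + 1] and (
                p == La - 1
                or q == Lb - 1
                or a.seq[p + 1] != rc_b[q + 1]
                or paired_a[p + 1] is not None
                or paired_b[Lb - 2 - q] is not None
            ):
                L = cur[q + 1]
                start_a = p - L + 1
                start_b = Lb - 1 - q
                best.append((L, start_a, start_b))
    return best


def anneal(oligos: Sequence[Oligo], min_match: int = MIN_MATCH) -> Assembly:
    """Greedy maximal annealing of 1-4 oligos.

    Repeatedly pairs the longest exact antiparallel complementary run of
    at least ``min_match`` bp between unpaired regions.  Strand order is
    canonicalised (labelled strand first, then by name/sequence), so the
    result does not depend on input order; residual ties break toward the
    earliest position on the first (labelled) strand.
    """
    if not 1 <= len(oligos) <= 4:
        raise ValueError("anneal takes 1-4 oligos")
    strands = sorted(oligos, key=lambda o: (not o.labeled, o.name, o.seq))
    asm = Assembly(strands=list(strands))

    while True:
        candidates: list[tuple[int, int, int, int, int]] = []
        for i in range(len(strands)):
            for j in range(i + 1, len(strands)):
                for L, sa, sb in _longest_matches(
                    strands[i], strands[j], asm.pairing[i], asm.pairing[j]
                ):
                    if L >= min_match:
                        candidates.append((-L, i, sa, j, sb))
        if not candidates:
            break
        negL, i, sa, j, sb = min(candidates)
        L = -negL
        for t in range(L):
            asm.pairing[i][sa + t] = (j, sb + L - 1 - t)
            asm.pairing[j][sb + L - 1 - t] = (i, sa + t)
        asm.segments.append(
            DuplexSegment(strand_i=i, start_i=sa, strand_j=j, start_j=sb, length=L)
        )

    if len(strands) >= 2 and not asm.segments:
        raise NoStableAssembly(
            f"no stable assembly: no complementary match >= {min_match} bp"
        )
    asm.validate()
    return asm


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _same_duplex_end(asm: Assembly, run_a, run_b) -> bool:
    """True if two terminal tails emanate from the same physical end of a
    shared duplex segment (antiparallel: 'before' on one strand aligns
    with 'after' on the other)."""
    (sa, start_a, len_a, _), (sb, start_b, len_b, _) = run_a, run_b
    before_a = start_a == 0 and len_a < len(asm.strands[sa])
    before_b = start_b == 0 and len_b < len(asm.strands[sb])
    return before_a != before_b


def classify_structure(asm: Assembly) -> str:
    """Rule-based structure label from the base-pair topology."""
    ns = len(asm.strands)
    runs = asm.unpaired_runs()
    terminal = [r for r in runs if r[3]]
    internal = [r for r in runs if not r[3]]
    degrees = [len(asm.partner_strands(s)) for s in range(ns)]

    if ns == 2:
        if not runs:
            return "ds"
        if len(runs) == 1 and internal:
            m = internal[0][2]
            return f"A{m}" if m in (1, 3, 7) else "unknown"
        if len(runs) == 1 and terminal:
            return "ov"
        if len(runs) == 2 and len(terminal) == 2:
            sa, sb = terminal[0][0], terminal[1][0]
            if sa != sb and _same_duplex_end(asm, terminal[0], terminal[1]):
                return "fork"
        return "unknown"

    if ns == 3:
        is_path = sorted(degrees) == [1, 1, 2]
        if not is_path:
            return "unknown"
        center = degrees.index(2)
        if not runs:
            return "n"
        if asm.fully_paired(center) and len(internal) == 1 and not terminal:
            return "inv"
        if internal:
            return "unknown"
        return "iJ"

    if ns == 4:
        is_cycle = degrees == [2, 2, 2, 2]
        if is_cycle and not runs:
            return "J"
        return "unknown"

    return "unknown"


# ---------------------------------------------------------------------------
# truncation series
# ---------------------------------------------------------------------------

def truncation_series(
    template: Oligo, lengths: Sequence[int]
) -> list[Assembly]:
    """Blunt duplexes from 3'-truncations of a template: for each length L
    the 5' L-prefix annealed to its exact reverse complement."""
    out = []
    for L in lengths:
        if L < MIN_MATCH:
            raise ValueError(f"length {L} below the {MIN_MATCH}-bp minimum")
        if L > len(template):
            raise ValueError(f"length {L} exceeds template length {len(template)}")
        prefix = template.seq[:L]
        top = Oligo(name=f"{template.name}-{L}", seq=prefix, labeled=template.labeled)
        bottom = Oligo(name=f"{template.name}-{L}.rc", seq=revcomp(prefix))
        out.append(anneal([top, bottom]))
    return out
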