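"""Core-alignment layer for HU/IHF family sequences.

The HU/IHF family (bacterial histone-like nucleoid-associated proteins) is
analysed here on a fixed 90-column "core" alignment frame.  Every family
member is decomposed into

* a 90-symbol core (amino acids or ``-`` for a deleted column),
* insertions (residue runs sitting between two core columns),
* N- and C-terminal extensions (residues outside the core).

On top of that representation this module provides pairwise identity with
the indel-event rule, a Fitch (1966) similarity distance, PCA/PCoA
embeddings of the distance matrix, position-specific score-matrix (PSSM)
profiles per clade, group/clade classification, an insertion/deletion
hotspot census and terminal-extension composition statistics.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger("huihf.seq_core")

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
CORE_LENGTH = 90

#: 1-based column spans (inclusive) of the indel hotspot regions on the core.
#: The spans are calibration data, not constants: secondary-structure block
#: boundaries on the core frame are approximate.
DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "loop_a1_a2": (14, 16),
    "turn_a2_b1": (38, 40),
    "arm_tip": (60, 68),
}

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def splice_core(core: str, insertions: Mapping[int, str]) -> str:
    """Reassemble the core-covered part of a sequence: gaps removed,
    insertion runs spliced back in after their anchor column."""
    if len(core) != CORE_LENGTH:
        raise ValueError(f"core must be {CORE_LENGTH} symbols, got {len(core)}")
    parts = []
    for col in range(1, CORE_LENGTH + 1):
        sym = core[col - 1]
        if sym != GAP:
            parts.append(sym)
        if col in insertions:
            parts.append(insertions[col])
    return "".join(parts)


@dataclass
class CoreAlignedSequence:
    """A family member decomposed on the 90-column core frame.

    ``insertions[c]`` holds residues sitting between core columns ``c`` and
    ``c + 1`` (anchor columns 1..89).  ``raw_seq`` must reconstruct as
    ``n_ext + spliced core + c_ext``.
    """

    id: str
    raw_seq: str
    core: str
    insertions: dict[int, str] = field(default_factory=dict)
    n_ext: str = ""
    c_ext: str = ""
    organism: str = ""
    taxonomy: tuple[str, ...] = ()
    group: str | None = None
    clade: str | None = None

    def __post_init__(self) -> None:
        if len(self.core) != CORE_LENGTH:
            raise ValueError(
                f"core must be {CORE_LENGTH} symbols, got {len(self.core)}"
            )
        bad = set(self.core) - set(AMINO_ACIDS) - {GAP}
        if bad:
            raise ValueError(f"invalid core symbols: {sorted(bad)}")
        for col, run in self.insertions.items():
            if not 1 <= col <= CORE_LENGTH - 1:
                raise ValueError(f"insertion anchor {col} outside [1, 89]")
            if not run:
                raise ValueError(f"empty insertion at column {col}")
        expected = self.n_ext + splice_core(self.core, self.insertions) + self.c_ext
        if expected != self.raw_seq:
            raise ValueError(
                f"{self.id}: raw_seq does not reconstruct from parts"
            )

    @classmethod
    def from_parts(
        cls,
        id: str,
        core: str,
        insertions: Mapping[int, str] | None = None,
        n_ext: str = "",
        c_ext: str = "",
        **kwargs,
    ) -> "CoreAlignedSequence":
        ins = dict(insertions or {})
        raw = n_ext + splice_core(core, ins) + c_ext
        return cls(id=id, raw_seq=raw, core=core, insertions=ins,
                   n_ext=n_ext, c_ext=c_ext, **kwargs)

    def core_as_indices(self) -> np.ndarray:
        """Core encoded as ints 0..19, -1 for gap."""
        return np.array([_AA_INDEX.get(s, -1) for s in self.core], dtype=np.int64)


@dataclass
class CladeProfile:
    """Position-specific score matrix summarising one clade.

    ``freq`` are residue frequencies per column (gap excluded, rows sum
    to 1); ``score`` are log2-odds against a uniform 21-symbol background
    for the 20 residues plus the gap state; ``conservation`` is the
    fraction of members carrying the consensus residue.
    """

    name: str
    n_members: int
    freq: np.ndarray          # (90, 20)
    score: np.ndarray         # (90, 21); column 20 = gap
    consensus: str            # 90 symbols
    conservation: np.ndarray  # (90,)
    group: str | None = None
    clade: str | None = None

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.score = np.asarray(self.score, dtype=float)
        self.conservation = np.asarray(self.conservation, dtype=float)
        if self.freq.shape != (CORE_LENGTH, 20):
            raise ValueError("freq must be (90, 20)")
        if self.score.shape != (CORE_LENGTH, 21):
            raise ValueError("score must be (90, 21)")
        if len(self.consensus) != CORE_LENGTH:
            raise ValueError("consensus must be 90 symbols")
        if not np.allclose(self.freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("per-column frequencies must sum to 1")


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12, equal_nan=False):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        vals = self.values[finite]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("distances must lie in [0, 1]")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=1e-12
        ):
            raise ValueError("distance matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclass
class Embedding:
    ids: tuple[str, ...]
    coords: np.ndarray                 # (n, k)
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.explained_variance_ratio = np.asarray(
            self.explained_variance_ratio, dtype=float
        )
        evr = self.explained_variance_ratio
        if np.any(evr < -1e-12) or np.any(evr > 1 + 1e-9):
            raise ValueError("explained-variance fractions must lie in [0, 1]")
        if np.any(np.diff(evr) > 1e-9):
            raise ValueError("explained-variance fractions must be non-increasing")


@dataclass
class RegionIndelStats:
    insertion_rate: float          # fraction of sequences with >=1 insertion event here
    deletion_rate: float           # fraction of sequences with >=1 deletion event here
    insert_fraction: float         # share of all insertion events falling here
    insert_length_hist: dict[int, int] = field(default_factory=dict)


@dataclass
class IndelCensus:
    regions: dict[str, RegionIndelStats]
    n_sequences: int
    insertion_rate: float          # overall: fraction of sequences with an insert
    deletion_rate: float
    single_residue_insert_fraction: float


@dataclass
class TerminalStats:
    side: str
    length: int
    count_K: int
    count_R: int
    count_D: int
    count_E: int
    pakka_hits: tuple[int, ...]


@dataclass
class Classification:
    group: str | None
    clade: str | None
    margin: float
    ambiguous: bool
    scores: dict[str, float]
    best_profile: str


# ---------------------------------------------------------------------------
# Fitch (1966) similarity table
# ---------------------------------------------------------------------------

def load_fitch_table() -> pd.DataFrame:
    """Embedded Fitch (1966) residue-similarity table (binary: residues in
    the same similarity class score 1, otherwise 0)."""
    with resources.files("huihf.data").joinpath(
        "fitch1966_similarity.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)


_FITCH_CACHE: np.ndarray | None = None


def _fitch_matrix() -> np.ndarray:
    global _FITCH_CACHE
    if _FITCH_CACHE is None:
        df = load_fitch_table()
        df = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]
        _FITCH_CACHE = df.to_numpy(dtype=float)
    return _FITCH_CACHE


# ---------------------------------------------------------------------------
# profile building and classification
# ---------------------------------------------------------------------------

def build_profile(
    members: Sequence[CoreAlignedSequence],
    pseudocount: float = 1.0,
    name: str = "profile",
    group: str | None = None,
    clade: str | None = None,
) -> CladeProfile:
    """Build a clade PSSM from aligned members.

    Symbol frequencies use an additive pseudocount over the 21-symbol
    alphabet (20 residues + gap); scores are log2-odds against a uniform
    1/21 background.  The consensus takes the per-column modal residue,
    ties broken toward the lexicographically smallest residue;
    conservation is the (pseudocount-free) fraction of members matching
    the consensus.
    """
    if len(members) < 2:
        raise ValueError("need at least 2 members to build a profile")
    for m in members:
        if len(m.core) != CORE_LENGTH:
            raise ValueError(f"{m.id}: core length != {CORE_LENGTH}")

    n = len(members)
    counts = np.zeros((CORE_LENGTH, 21), dtype=float)
    for m in members:
        for c, sym in enumerate(m.core):
            j = _AA_INDEX.get(sym, 20)
            counts[c, j] += 1.0

    p21 = (counts + pseudocount) / (n + 21 * pseudocount)
    score = np.log2(p21 * 21.0)

    res_counts = counts[:, :20]
    freq = (res_counts + pseudocount) / (
        res_counts.sum(axis=1, keepdims=True) + 20 * pseudocount
    )

    consensus_chars = []
    conservation = np.zeros(CORE_LENGTH)
    for c in range(CORE_LENGTH):
        best = int(np.argmax(res_counts[c]))  # argmax takes first (lexicographic) tie
        consensus_chars.append(AMINO_ACIDS[best])
        conservation[c] = res_counts[c, best] / n
    consensus = "".join(consensus_chars)

    return CladeProfile(
        name=name, n_members=n, freq=freq, score=score,
        consensus=consensus, conservation=conservation,
        group=group, clade=clade,
    )


def score_core(s: CoreAlignedSequence, profile: CladeProfile) -> float:
    """Sum of profile log-odds over the 90 core columns (gap state scored
    with the profile's gap column)."""
    idx = s.core_as_indices()
    idx = np.where(idx < 0, 20, idx)
    return float(profile.score[np.arange(CORE_LENGTH), idx].sum())


def classify_sequence(
    s: CoreAlignedSequence,
    profiles: Sequence[CladeProfile],
    margin_threshold: float = 5.0,
) -> Classification:
    """Assign a sequence to the best-scoring clade profile.

    The margin is best minus second-best score; assignments with a margin
    below ``margin_threshold`` (score units, i.e. bits here) are flagged
    ambiguous.
    """
    if not profiles:
        raise ValueError("empty profile list")
    scores = {p.name: score_core(s, p) for p in profiles}
    ranked = sorted(profiles, key=lambda p: (-scores[p.name], p.name))
    best = ranked[0]
    margin = (
        scores[best.name] - scores[ranked[1].name] if len(ranked) > 1 else math.inf
    )
    return Classification(
        group=best.group,
        clade=best.clade or best.name,
        margin=margin,
        ambiguous=margin < margin_threshold,
        scores=scores,
        best_profile=best.name,
    )


# ---------------------------------------------------------------------------
# profile-to-sequence core alignment
# ---------------------------------------------------------------------------

_NEG = -1e30


def align_to_core(
    raw_seq: str,
    reference_profile: CladeProfile,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    id: str = "query",
    **kwargs,
) -> CoreAlignedSequence:
    """Thread a raw sequence onto the 90-column core of a reference profile.

    Global over the core with free end gaps on the sequence: all 90 columns
    are either matched or deleted, while unaligned sequence prefix/suffix
    become the N-/C-terminal extensions at no cost.  Insertions (sequence
    residues between consecutive core columns) and deletions (skipped
    columns) carry affine penalties (``gap_open`` for the first residue of
    a run, ``gap_extend`` for each subsequent one).
    """
    seq = raw_seq.upper()
    if len(seq) < 30:
        raise ValueError(f"sequence shorter than 30 residues ({len(seq)})")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"invalid residues: {sorted(bad)}")
    S = reference_profile.score[:, :20]
    if not np.all(np.isfinite(S)):
        raise ValueError("profile has non-finite column scores")

    m = len(seq)
    sidx = [_AA_INDEX[a] for a in seq]
    ncol = CORE_LENGTH

    # M[c][i]: column c matched to residue i (1-based); D[c][i]: column c
    # deleted having consumed i residues; I[c][i]: last event an insertion
    # anchored after column c.  Free sequence end gaps: M[0][i] = 0.
    M = np.full((ncol + 1, m + 1), _NEG)
    D = np.full((ncol + 1, m + 1), _NEG)
    I = np.full((ncol + 1, m + 1), _NEG)
    # traceback: 0=M, 1=D, 2=I, 3=start (free prefix)
    ptrM = np.zeros((ncol + 1, m + 1), dtype=np.int8)
    ptrD = np.zeros((ncol + 1, m + 1), dtype=np.int8)
    ptrI = np.zeros((ncol + 1, m + 1), dtype=np.int8)

    M[0, :] = 0.0
    ptrM[0, :] = 3
    for c in range(1, ncol + 1):
        # deletion of column c with zero residues consumed so far
        opts = (M[c - 1, 0] - gap_open, D[c - 1, 0] - gap_extend, _NEG)
        D[c, 0] = max(opts)
        ptrD[c, 0] = int(np.argmax(opts))
        for i in range(1, m + 1):
            sc = S[c - 1, sidx[i - 1]]
            opts = (M[c - 1, i - 1], D[c - 1, i - 1], I[c - 1, i - 1])
            j = int(np.argmax(opts))
            M[c, i] = opts[j] + sc
            ptrM[c, i] = j
            opts = (M[c - 1, i] - gap_open, D[c - 1, i] - gap_extend,
                    I[c - 1, i] - gap_open)
            j = int(np.argmax(opts))
            D[c, i] = opts[j]
            ptrD[c, i] = j
            if 1 <= c <= ncol - 1:
                opts = (M[c, i - 1] - gap_open, D[c, i - 1] - gap_open,
                        I[c, i - 1] - gap_extend)
                j = int(np.argmax(opts))
                I[c, i] = opts[j]
                ptrI[c, i] = j
    # free suffix: end at best i in column 90
    endM = np.argmax(M[ncol])
    endD = np.argmax(D[ncol])
    if M[ncol, endM] >= D[ncol, endD]:
        state, i = 0, int(endM)
    else:
        state, i = 1, int(endD)
    c_ext = seq[i:]

    core = [GAP] * ncol
    insertions: dict[int, list[str]] = {}
    c = ncol
    while c > 0 or state == 2:
        if state == 0:  # match
            core[c - 1] = seq[i - 1]
            prev = int(ptrM[c, i])
            i -= 1
            c -= 1
            state = prev
        elif state == 1:  # deletion, core[c-1] stays GAP
            prev = int(ptrD[c, i])
            c -= 1
            state = prev
        else:  # insertion anchored after column c
            insertions.setdefault(c, []).insert(0, seq[i - 1])
            prev = int(ptrI[c, i])
            i -= 1
            state = prev
    n_ext = seq[:i]

    ins = {k: "".join(v) for k, v in insertions.items()}
    return CoreAlignedSequence(
        id=id, raw_seq=seq, core="".join(core), insertions=ins,
        n_ext=n_ext, c_ext=c_ext, **kwargs,
    )


# ---------------------------------------------------------------------------
# identity and distance
# ---------------------------------------------------------------------------

def core_identity(a: CoreAlignedSequence, b: CoreAlignedSequence) -> int:
    """Identity count on the 90-column core with the indel-event rule.

    Counts columns carrying equal non-gap residues; every insertion event
    not shared identically by both sequences subtracts one, with a floor
    at zero.  One event is one contiguous inserted run regardless of its
    length.  Deleted (gap) columns simply fail the residue match and need
    no extra penalty.
    """
    ident = sum(
        1 for x, y in zip(a.core, b.core) if x == y and x != GAP
    )
    anchors = set(a.insertions) | set(b.insertions)
    penalty = sum(
        1 for c in anchors if a.insertions.get(c) != b.insertions.get(c)
    )
    return max(ident - penalty, 0)


def fitch_distance(alignment: Sequence[CoreAlignedSequence]) -> DistanceMatrix:
    """Pairwise distances d = sqrt(1 - s), with s the mean per-column
    Fitch (1966) similarity over columns where both sequences carry a
    residue.  All-gap pairs yield NaN (flagged missing)."""
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences")
    sim = _fitch_matrix()
    idx = np.stack([s.core_as_indices() for s in alignment])
    n = len(alignment)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mask = (idx[i] >= 0) & (idx[j] >= 0)
            if not mask.any():
                d[i, j] = d[j, i] = np.nan
                logger.warning(
                    "all-gap pair (%s, %s): distance undefined",
                    alignment[i].id, alignment[j].id,
                )
                continue
            s = sim[idx[i, mask], idx[j, mask]].mean()
            d[i, j] = d[j, i] = math.sqrt(max(1.0 - s, 0.0))
    return DistanceMatrix(ids=tuple(s.id for s in alignment), values=d)


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def pca_embed(dm: DistanceMatrix, k: int = 3, method: str = "pca") -> Embedding:
    """Embed sequences from their distance matrix.

    ``method='pca'`` (default) runs principal component analysis on the
    rows of the distance matrix, i.e. each sequence is represented by its
    vector of distances to all others.  ``method='pcoa'`` performs
    classical principal coordinates analysis (double-centered squared
    distances).  Deterministic up to component sign; signs are fixed so
    the largest-magnitude loading of each component is positive.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 sequences to embed")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must lie in [1, {n - 1}]")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains missing values")

    if method == "pca":
        pca = PCA(n_components=k, svd_solver="full")
        with np.errstate(invalid="ignore"):  # zero-variance input
            coords = pca.fit_transform(dm.values)
        # zero total variance (all sequences identical) -> all fractions 0
        evr = np.nan_to_num(pca.explained_variance_ratio_)
        axes = pca.components_
    elif method == "pcoa":
        D2 = dm.values ** 2
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        B = -0.5 * J @ D2 @ J
        w, v = np.linalg.eigh(B)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        pos = np.clip(w, 0.0, None)
        coords = v[:, :k] * np.sqrt(pos[:k])
        total = pos.sum()
        evr = pos[:k] / total if total > 0 else np.zeros(k)
        axes = v[:, :k].T
    else:
        raise ValueError(f"unknown method {method!r}")

    for j in range(coords.shape[1]):
        pivot = np.argmax(np.abs(axes[j]))
        if axes[j, pivot] < 0:
            coords[:, j] *= -1.0
    return Embedding(ids=dm.ids, coords=coords, explained_variance_ratio=evr)


# ---------------------------------------------------------------------------
# indel census and terminal statistics
# ---------------------------------------------------------------------------

def _region_of(col: int, regions: Mapping[str, tuple[int, int]]) -> str:
    for name, (lo, hi) in regions.items():
        if lo <= col <= hi:
            return name
    return "other"


def _deletion_runs(core: str) -> list[tuple[int, int]]:
    """Maximal gap runs as (start_col, length), 1-based."""
    runs = []
    start = None
    for c, sym in enumerate(core, start=1):
        if sym == GAP and start is None:
            start = c
        elif sym != GAP and start is not None:
            runs.append((start, c - start))
            start = None
    if start is not None:
        runs.append((start, CORE_LENGTH - start + 1))
    return runs


def indel_census(
    alignment: Sequence[CoreAlignedSequence],
    regions: Mapping[str, tuple[int, int]] | None = None,
) -> IndelCensus:
    """Census of insertion/deletion events per hotspot region.

    One insertion event is one contiguous inserted run (anchored between
    two columns); one deletion event is one maximal gap run, assigned to
    the region of its first column.  Rates are fractions of sequences
    carrying at least one event; region insert fractions partition all
    observed insertion events and sum to 1 whenever any is observed.
    """
    regions = dict(regions or DEFAULT_REGIONS)
    spans = sorted(regions.values())
    for (a_lo, a_hi), (b_lo, b_hi) in zip(spans, spans[1:]):
        if b_lo <= a_hi:
            raise ValueError("region spans overlap")
    for lo, hi in regions.values():
        if not (1 <= lo <= hi <= CORE_LENGTH):
            raise ValueError("region span outside [1, 90]")

    names = list(regions) + ["other"]
    ins_events: Counter[str] = Counter()
    ins_seqs: dict[str, set[int]] = {r: set() for r in names}
    del_seqs: dict[str, set[int]] = {r: set() for r in names}
    length_hist: dict[str, Counter[int]] = {r: Counter() for r in names}
    n_ins_total = 0
    n_single = 0
    seq_has_ins = 0
    seq_has_del = 0

    for i, s in enumerate(alignment):
        if s.insertions:
            seq_has_ins += 1
        dels = _deletion_runs(s.core)
        if dels:
            seq_has_del += 1
        for col, run in s.insertions.items():
            r = _region_of(col, regions)
            ins_events[r] += 1
            ins_seqs[r].add(i)
            length_hist[r][len(run)] += 1
            n_ins_total += 1
            if len(run) == 1:
                n_single += 1
        for col, _length in dels:
            del_seqs[_region_of(col, regions)].add(i)

    n = len(alignment)
    out = {}
    for r in names:
        out[r] = RegionIndelStats(
            insertion_rate=len(ins_seqs[r]) / n if n else 0.0,
            deletion_rate=len(del_seqs[r]) / n if n else 0.0,
            insert_fraction=ins_events[r] / n_ins_total if n_ins_total else 0.0,
            insert_length_hist=dict(length_hist[r]),
        )
    return IndelCensus(
        regions=out,
        n_sequences=n,
        insertion_rate=seq_has_ins / n if n else 0.0,
        deletion_rate=seq_has_del / n if n else 0.0,
        single_residue_insert_fraction=(n_single / n_ins_total) if n_ins_total else 0.0,
    )


def terminal_stats(s: CoreAlignedSequence, side: str) -> TerminalStats:
    """Length, charged-residue counts and (possibly overlapping) PAKKA
    motif hit offsets of the chosen terminal extension."""
    if side not in ("N", "C"):
        raise ValueError("side must be 'N' or 'C'")
    ext = s.n_ext if side == "N" else s.c_ext
    hits = []
    start = 0
    while True:
        pos = ext.find("PAKKA", start)
        if pos < 0:
            break
        hits.append(pos)
        start = pos + 1
    return TerminalStats(
        side=side,
        length=len(ext),
        count_K=ext.count("K"),
        count_R=ext.count("R"),
        count_D=ext.count("D"),
        count_E=ext.count("E"),
        pakka_hits=tuple(hits),
    )
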