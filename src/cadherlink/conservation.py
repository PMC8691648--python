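"""Cross-species conservation profiling of cadherin ectodomain families.

Global pairwise alignment (Needleman-Wunsch with affine gaps, Gotoh
recurrences), percent-identity matrices under three normalizations,
per-EC-repeat identity profiles, a deterministic progressive MSA over a
UPGMA guide tree, and per-column conservation scores binned into the
familiar 1-9 grade scale.

Scoring defaults are BLOSUM62 with gap open 10 and gap extend 0.5 (a gap of
length L costs 10 + (L-1)*0.5).  Traceback ties break diagonal > up > left,
so alignments are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .sequence_annotation import ECRepeatAnnotation, ProteinRecord

__all__ = [
    "Alignment",
    "IdentityMatrix",
    "ConservationProfile",
    "AlignParams",
    "EmptySequence",
    "EmptyFamily",
    "UnknownReference",
    "RepeatCountMismatch",
    "pairwise_align",
    "percent_identity",
    "identity_matrix",
    "per_repeat_profile",
    "build_msa",
    "conservation_profile",
]

GAP = "-"
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class EmptySequence(ValueError):
    pass


class EmptyFamily(ValueError):
    pass


class UnknownReference(KeyError):
    pass


class RepeatCountMismatch(ValueError):
    pass


@dataclass(frozen=True)
class AlignParams:
    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix: object = field(default_factory=lambda: _BLOSUM62)

    def score(self, a: str, b: str) -> float:
        try:
            return float(self.matrix[a, b])
        except (KeyError, IndexError):
            return float(self.matrix["X", "X"])


@dataclass
class Alignment:
    ids: list
    rows: list  # equal-length gapped strings
    score: float

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, id_: str) -> str:
        try:
            return self.rows[self.ids.index(id_)]
        except ValueError as exc:
            raise UnknownReference(id_) from exc

    def ungapped(self, id_: str) -> str:
        return self.row(id_).replace(GAP, "")


@dataclass
class IdentityMatrix:
    ids: list
    values: np.ndarray  # symmetric, percent, diagonal 100

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class ConservationProfile:
    positions: np.ndarray  # 1-based reference residue numbers
    scores: np.ndarray  # modal-residue fraction in [0, 1]
    grades: np.ndarray  # 1..9, equal-width bins


# ---------------------------------------------------------------------------
# profile-capable Gotoh alignment
# ---------------------------------------------------------------------------

def _column_score(col_a: Sequence[str], col_b: Sequence[str], params: AlignParams) -> float:
    """Mean substitution score over non-gap residue pairs of two profile
    columns (0 when every pair involves a gap)."""
    total, n = 0.0, 0
    for x in col_a:
        if x == GAP:
            continue
        for y in col_b:
            if y == GAP:
                continue
            total += params.score(x, y)
            n += 1
    return total / n if n else 0.0


def _align_profiles(
    prof_a: list, prof_b: list, params: AlignParams
) -> tuple[list, float]:
    """Gotoh affine-gap global alignment of two profiles (lists of columns).

    Returns merged columns and the optimal score.  Tie-break on traceback:
    diagonal, then up (gap in B), then left (gap in A).
    """
    n, m = len(prof_a), len(prof_b)
    na, nb = len(prof_a[0]) if n else 1, len(prof_b[0]) if m else 1
    open_, ext = params.gap_open, params.gap_extend
    NEG = -1e30

    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in B (consume A)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -open_ - (i - 1) * ext
    for j in range(1, m + 1):
        Iy[0, j] = -open_ - (j - 1) * ext

    S = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            S[i, j] = _column_score(prof_a[i], prof_b[j], params)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best_prev + S[i - 1, j - 1]
            Ix[i, j] = max(
                M[i - 1, j] - open_, Ix[i - 1, j] - ext, Iy[i - 1, j] - open_
            )
            Iy[i, j] = max(
                M[i, j - 1] - open_, Iy[i, j - 1] - ext, Ix[i, j - 1] - open_
            )

    # traceback, diagonal > up > left
    i, j = n, m
    states = [M[n, m], Ix[n, m], Iy[n, m]]
    state = int(np.argmax(states))
    score = float(states[state])
    merged: list = []
    gap_a, gap_b = [GAP] * na, [GAP] * nb
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            merged.append(list(prof_a[i - 1]) + list(prof_b[j - 1]))
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 and i > 0:
            merged.append(list(prof_a[i - 1]) + gap_b)
            cands = [M[i - 1, j] - open_, Ix[i - 1, j] - ext, Iy[i - 1, j] - open_]
            # prefer M, then Ix, then Iy among ties
            state = next(k for k in (0, 1, 2) if np.isclose(cands[k], Ix[i, j]))
            i -= 1
        else:
            merged.append(gap_a + list(prof_b[j - 1]))
            cands = [M[i, j - 1] - open_, Iy[i, j - 1] - ext, Ix[i, j - 1] - open_]
            k = next(k for k in (0, 1, 2) if np.isclose(cands[k], Iy[i, j]))
            state = {0: 0, 1: 2, 2: 1}[k]
            j -= 1
    merged.reverse()
    return merged, score


def pairwise_align(
    a: str, b: str, params: Optional[AlignParams] = None
) -> Alignment:
    """Optimal global alignment of two sequences under BLOSUM62 + affine gaps."""
    if not a or not b:
        raise EmptySequence("cannot align an empty sequence")
    params = params or AlignParams()
    cols, score = _align_profiles([[c] for c in a], [[c] for c in b], params)
    row_a = "".join(col[0] for col in cols)
    row_b = "".join(col[1] for col in cols)
    return Alignment(ids=["a", "b"], rows=[row_a, row_b], score=score)


# ---------------------------------------------------------------------------
# percent identity
# ---------------------------------------------------------------------------

IDENTITY_MODES = ("aligned_columns", "shorter_sequence", "full_alignment")


def percent_identity(aln: Alignment, mode: str = "aligned_columns") -> float:
    """Percent identity of a two-row alignment.

    aligned_columns (default): identities / columns of the trimmed core
        (terminal-overhang columns, where either row is gapped at the ends,
        are excluded; internal gap columns count in the denominator).
    shorter_sequence: identities / length of the shorter ungapped sequence.
    full_alignment: identities / total alignment columns.
    """
    if len(aln.rows) != 2:
        raise ValueError("percent_identity needs a two-row alignment")
    if mode not in IDENTITY_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    ra, rb = aln.rows
    both = [i for i in range(len(ra)) if ra[i] != GAP and rb[i] != GAP]
    identities = sum(1 for i in both if ra[i] == rb[i])
    if mode == "shorter_sequence":
        denom = min(len(ra.replace(GAP, "")), len(rb.replace(GAP, "")))
    elif mode == "full_alignment":
        denom = len(ra)
    else:
        denom = (both[-1] - both[0] + 1) if both else 0
    return 100.0 * identities / denom if denom else 0.0


def identity_matrix(
    records: Sequence[ProteinRecord],
    mode: str = "aligned_columns",
    params: Optional[AlignParams] = None,
) -> IdentityMatrix:
    ids = [r.id for r in records]
    n = len(records)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = pairwise_align(records[i].sequence, records[j].sequence, params)
            vals[i, j] = vals[j, i] = percent_identity(aln, mode)
    return IdentityMatrix(ids=ids, values=vals)


def per_repeat_profile(
    family: Sequence[ProteinRecord],
    annotations: Sequence[Sequence[ECRepeatAnnotation]],
    mode: str = "aligned_columns",
    params: Optional[AlignParams] = None,
) -> tuple[dict, float]:
    """Mean pairwise percent identity per repeat index across all species
    pairs, plus the grand mean over repeats (the family's average identity).

    Every record must carry the same repeat count; repeat i of one species
    is compared with repeat i of every other.
    """
    counts = {len(a) for a in annotations}
    if len(counts) != 1:
        raise RepeatCountMismatch(f"repeat counts differ: {sorted(counts)}")
    n_rep = counts.pop()
    profile: dict[int, float] = {}
    for k in range(n_rep):
        pis = []
        for i in range(len(family)):
            for j in range(i + 1, len(family)):
                sa = family[i].sequence[annotations[i][k].start - 1 : annotations[i][k].end]
                sb = family[j].sequence[annotations[j][k].start - 1 : annotations[j][k].end]
                pis.append(percent_identity(pairwise_align(sa, sb, params), mode))
        profile[k + 1] = float(np.mean(pis))
    grand = float(np.mean(list(profile.values())))
    return profile, grand


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def build_msa(
    family: Sequence[ProteinRecord], params: Optional[AlignParams] = None
) -> Alignment:
    """Progressive multiple alignment: UPGMA guide tree on pairwise identity
    distances (100 - %id), then profile-profile merges in tree order.
    Deterministic; distance ties resolve by the linkage's stable ordering of
    lexicographically sorted ids."""
    if not family:
        raise EmptyFamily("no sequences")
    params = params or AlignParams()
    order = sorted(range(len(family)), key=lambda i: family[i].id)
    records = [family[i] for i in order]
    if len(records) == 1:
        r = records[0]
        return Alignment(ids=[r.id], rows=[r.sequence], score=0.0)

    idm = identity_matrix(records, params=params)
    dist = 100.0 - idm.values
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(dist, checks=False), method="average")

    # each node: (profile columns, member ids in row order)
    nodes: dict[int, tuple[list, list]] = {
        i: ([[c] for c in r.sequence], [r.id]) for i, r in enumerate(records)
    }
    score = 0.0
    nxt = len(records)
    for a, b, _, _ in Z:
        pa, ia = nodes.pop(int(a))
        pb, ib = nodes.pop(int(b))
        merged, s = _align_profiles(pa, pb, params)
        nodes[nxt] = (merged, ia + ib)
        score += s
        nxt += 1
    profile, ids = nodes.popitem()[1]
    rows = ["".join(col[k] for col in profile) for k in range(len(ids))]
    return Alignment(ids=ids, rows=rows, score=score)


# ---------------------------------------------------------------------------
# conservation profile
# ---------------------------------------------------------------------------

def conservation_profile(msa: Alignment, reference_id: str) -> ConservationProfile:
    """Per-column modal-residue fraction at every non-gap reference column,
    linearly binned into integer grades 1 (variable) .. 9 (invariant)."""
    ref_row = msa.row(reference_id)  # raises UnknownReference
    n_rows = len(msa.rows)
    positions, scores = [], []
    ref_pos = 0
    for col_idx, ref_char in enumerate(ref_row):
        if ref_char == GAP:
            continue
        ref_pos += 1
        col = [row[col_idx] for row in msa.rows]
        residues = [c for c in col if c != GAP]
        modal = max(residues.count(c) for c in set(residues))
        positions.append(ref_pos)
        scores.append(modal / n_rows)
    scores_arr = np.asarray(scores)
    grades = np.minimum(9, 1 + np.floor(scores_arr * 9.0).astype(int))
    return ConservationProfile(
        positions=np.asarray(positions), scores=scores_arr, grades=grades
    )
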