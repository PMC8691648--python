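"""Alignment, percent identity, MSA and conservation profiles."""

import itertools

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from cadherlink.conservation import (
    AlignParams,
    Alignment,
    EmptyFamily,
    EmptySequence,
    RepeatCountMismatch,
    UnknownReference,
    _align_profiles,
    build_msa,
    conservation_profile,
    identity_matrix,
    pairwise_align,
    per_repeat_profile,
    percent_identity,
)
from cadherlink.sequence_annotation import ProteinRecord, segment_repeats
from cadherlink.synthetic_data import FamilyConfig, generate_family

BLOSUM62 = substitution_matrices.load("BLOSUM62")


# ---------------------------------------------------------------------------
# independent alignment oracle: exhaustive path enumeration
# ---------------------------------------------------------------------------

def enumerate_best_score(a, b, params):
    """Best global alignment score by enumerating every monotone path
    (diagonal/up/left move sequence) and scoring its columns directly,
    with gap runs costing open + (L-1)*extend."""
    best = -np.inf
    for path in _paths(len(a), len(b)):
        score = 0.0
        i = j = 0
        prev = None
        for move in path:
            if move == "D":
                score += params.score(a[i], b[j])
                i += 1
                j += 1
            else:
                score -= params.gap_extend if move == prev else params.gap_open
                if move == "U":
                    i += 1
                else:
                    j += 1
            prev = move
        best = max(best, score)
    return best


def _paths(n, m):
    if n == 0 and m == 0:
        yield ()
        return
    if n > 0:
        for p in _paths(n - 1, m):
            yield p + ("U",)
    if m > 0:
        for p in _paths(n, m - 1):
            yield p + ("L",)
    if n > 0 and m > 0:
        for p in _paths(n - 1, m - 1):
            yield p + ("D",)


@pytest.mark.parametrize("seed", range(12))
def test_alignment_score_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    alphabet = list("ACDE")
    la, lb = rng.integers(1, 7, size=2)
    a = "".join(rng.choice(alphabet, size=la))
    b = "".join(rng.choice(alphabet, size=lb))
    params = AlignParams()
    aln = pairwise_align(a, b, params)
    assert aln.score == pytest.approx(enumerate_best_score(a, b, params))
    # rows ungap back to their inputs
    assert aln.rows[0].replace("-", "") == a
    assert aln.rows[1].replace("-", "") == b


def test_single_gap_alignment():
    aln = pairwise_align("ACDE", "ACE")
    assert sum(r.count("-") for r in aln.rows) == 1
    assert aln.score == pytest.approx(
        enumerate_best_score("ACDE", "ACE", AlignParams())
    )


@pytest.mark.parametrize("seed", range(5))
def test_score_matches_biopython_global_affine(seed):
    """Independent route: Biopython's PairwiseAligner under the same
    BLOSUM62 + affine-gap convention gives the same optimal score."""
    rng = np.random.default_rng(100 + seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    a = "".join(rng.choice(aas, size=rng.integers(8, 20)))
    b = "".join(rng.choice(aas, size=rng.integers(8, 20)))
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = BLOSUM62
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    assert pairwise_align(a, b).score == pytest.approx(aligner.score(a, b))


def test_identity_alignment_no_gaps_and_diagonal_score():
    aln = pairwise_align("ACDE", "ACDE")
    assert aln.rows == ["ACDE", "ACDE"]
    assert aln.score == pytest.approx(sum(BLOSUM62[c, c] for c in "ACDE"))


def test_empty_sequence_raises():
    with pytest.raises(EmptySequence):
        pairwise_align("", "ACDE")


# ---------------------------------------------------------------------------
# percent identity
# ---------------------------------------------------------------------------

def test_percent_identity_trivial_cases():
    assert percent_identity(pairwise_align("ACDE", "ACDE")) == 100.0
    aln = Alignment(ids=["a", "b"], rows=["AAAA", "AATT"], score=0.0)
    assert percent_identity(aln) == 50.0


def test_percent_identity_modes_with_terminal_overhang():
    aln = Alignment(ids=["a", "b"], rows=["AAAA--", "AATTTT"], score=0.0)
    # trimmed core = columns 1-4; 2 identities
    assert percent_identity(aln, "aligned_columns") == 50.0
    assert percent_identity(aln, "shorter_sequence") == 50.0
    assert percent_identity(aln, "full_alignment") == pytest.approx(100 * 2 / 6)


def test_percent_identity_symmetric(rng):
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(5):
        a = "".join(rng.choice(aas, size=30))
        b = "".join(rng.choice(aas, size=28))
        ab = percent_identity(pairwise_align(a, b))
        ba = percent_identity(pairwise_align(b, a))
        assert ab == pytest.approx(ba)


def test_identity_matrix_invariants(canonical_family):
    records, truth = canonical_family
    idm = identity_matrix(records)
    assert np.allclose(np.diag(idm.values), 100.0)
    assert np.allclose(idm.values, idm.values.T)
    # no indels in the generator: alignment identity equals the recount
    assert np.allclose(idm.values, truth.identity_matrix, atol=1e-9)


# ---------------------------------------------------------------------------
# per-repeat profiles
# ---------------------------------------------------------------------------

def test_identical_family_profile_is_100():
    records, _ = generate_family(
        FamilyConfig(repeat_count=3, species_count=4, substitution_rate=0.0, seed=1)
    )
    anns = [segment_repeats(r, 3) for r in records]
    profile, grand = per_repeat_profile(records, anns)
    assert all(v == pytest.approx(100.0) for v in profile.values())
    assert grand == pytest.approx(100.0)


def test_profile_recovers_generator_identity_within_tolerance():
    cfg = FamilyConfig(repeat_count=3, species_count=5,
                       substitution_rate=0.35, invariant_fraction=0.0, seed=7)
    records, truth = generate_family(cfg)
    anns = [segment_repeats(r, 3) for r in records]
    _, grand = per_repeat_profile(records, anns)
    off_diag = truth.identity_matrix[~np.eye(len(records), dtype=bool)]
    assert grand == pytest.approx(off_diag.mean(), abs=5.0)


def test_grand_mean_decreases_with_substitution_rate():
    grands = []
    for rate in (0.05, 0.2, 0.5):
        records, _ = generate_family(
            FamilyConfig(repeat_count=2, species_count=4, substitution_rate=rate,
                         invariant_fraction=0.0, seed=42)
        )
        anns = [segment_repeats(r, 2) for r in records]
        grands.append(per_repeat_profile(records, anns)[1])
    assert grands[0] > grands[1] > grands[2]


def test_repeat_count_mismatch_raises(canonical_family):
    records, _ = canonical_family
    anns = [segment_repeats(r, 3) for r in records]
    anns[0] = anns[0][:2]
    with pytest.raises(RepeatCountMismatch):
        per_repeat_profile(records, anns)


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def test_msa_of_identical_sequences_is_gap_free():
    recs = [ProteinRecord(f"s{i}", "na", "ACDEFGHIKL") for i in range(4)]
    msa = build_msa(recs)
    assert all(r == "ACDEFGHIKL" for r in msa.rows)


def test_msa_of_two_sequences_equals_pairwise():
    a, b = "ACDEFGHIKL", "ACDFGHIKL"
    msa = build_msa([ProteinRecord("a", "na", a), ProteinRecord("b", "na", b)])
    aln = pairwise_align(a, b)
    assert sorted([msa.row("a"), msa.row("b")]) == sorted(aln.rows)


def test_msa_column_count_matches_best_merge_order():
    """On a tiny instance, the UPGMA-guided merge produces as few columns
    as the best over all sequential merge orders (exhaustive oracle)."""
    seqs = {"a": "ACDEFG", "b": "ACEFG", "c": "ACDEFG", "d": "AQDEFG"}
    params = AlignParams()
    best = np.inf
    for order in itertools.permutations(seqs):
        prof = [[c] for c in seqs[order[0]]]
        for name in order[1:]:
            prof, _ = _align_profiles(prof, [[c] for c in seqs[name]], params)
        best = min(best, len(prof))
    msa = build_msa([ProteinRecord(k, "na", v) for k, v in seqs.items()])
    assert msa.n_columns == best


def test_msa_empty_family_raises():
    with pytest.raises(EmptyFamily):
        build_msa([])


def test_msa_rows_ungap_to_inputs(mixed_family):
    records, _ = mixed_family
    msa = build_msa(records[:3])
    for rec in records[:3]:
        assert msa.ungapped(rec.id) == rec.sequence


# ---------------------------------------------------------------------------
# conservation profiles
# ---------------------------------------------------------------------------

def test_conservation_profile_extremes():
    rows = ["A" * 5, "A" * 5, "A" * 5]
    msa = Alignment(ids=["a", "b", "c"], rows=rows, score=0.0)
    prof = conservation_profile(msa, "a")
    assert np.all(prof.scores == 1.0)
    assert np.all(prof.grades == 9)

    aas = "ACDEFGHIKLMNPQRSTVWY"
    msa = Alignment(ids=[f"s{i}" for i in range(20)],
                    rows=[c for c in aas], score=0.0)
    prof = conservation_profile(msa, "s0")
    assert prof.scores[0] == pytest.approx(0.05)
    assert prof.grades[0] == 1


def test_grades_monotone_in_scores(mixed_family):
    records, _ = mixed_family
    msa = build_msa(records)
    prof = conservation_profile(msa, records[0].id)
    order = np.argsort(prof.scores)
    assert np.all(np.diff(prof.grades[order]) >= 0)


def test_invariant_sites_grade_9():
    cfg = FamilyConfig(repeat_count=2, species_count=6, substitution_rate=0.3,
                       invariant_fraction=0.15, seed=13)
    records, truth = generate_family(cfg)
    msa = build_msa(records)
    ref = records[0].id
    prof = conservation_profile(msa, ref)
    # no indels: reference position == sequence position
    by_pos = dict(zip(prof.positions.tolist(), prof.grades.tolist()))
    for p in truth.invariant_sites:
        assert by_pos[p] == 9


def test_unknown_reference_raises():
    msa = Alignment(ids=["a"], rows=["ACD"], score=0.0)
    with pytest.raises(UnknownReference):
        conservation_profile(msa, "zz")
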