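"""Sequence layer: core alignment, identity, distances, embedding,
profiles, classification, indel census and terminal statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from huihf import seq_core as sc
from huihf import synthetic_data as sd

AA = sc.AMINO_ACIDS


# ---------------------------------------------------------------------------
# the decomposed representation
# ---------------------------------------------------------------------------

class TestCoreAlignedSequence:
    def test_reconstruction_invariant(self):
        s = sc.CoreAlignedSequence.from_parts(
            "x", sd.HU_ALPHA_ECOLI[:14] + "-" + sd.HU_ALPHA_ECOLI[15:],
            insertions={20: "AW"}, n_ext="MK", c_ext="KKA",
        )
        assert s.raw_seq == "MK" + sc.splice_core(s.core, s.insertions) + "KKA"

    def test_rejects_wrong_core_length(self):
        with pytest.raises(ValueError, match="90"):
            sc.CoreAlignedSequence.from_parts("x", "ACDEF")

    def test_rejects_inconsistent_raw_seq(self):
        with pytest.raises(ValueError, match="reconstruct"):
            sc.CoreAlignedSequence(
                id="x", raw_seq="A" * 90, core=sd.HU_ALPHA_ECOLI
            )

    @pytest.mark.parametrize("anchor", [0, 90, 95])
    def test_rejects_out_of_range_insertion_anchor(self, anchor):
        with pytest.raises(ValueError, match="anchor"):
            sc.CoreAlignedSequence.from_parts(
                "x", sd.HU_ALPHA_ECOLI, insertions={anchor: "A"}
            )


# ---------------------------------------------------------------------------
# profile-to-core alignment
# ---------------------------------------------------------------------------

class TestAlignToCore:
    def test_consensus_aligns_to_itself(self, profile):
        al = sc.align_to_core(profile.consensus, profile)
        assert al.core == profile.consensus
        assert al.insertions == {}
        assert al.n_ext == "" and al.c_ext == ""

    def test_n_terminal_extension_of_six(self, profile):
        # mirrors a six-residue N-terminal extension outside the core
        al = sc.align_to_core("MWKLHG" + profile.consensus, profile)
        assert al.core == profile.consensus
        assert al.n_ext == "MWKLHG"
        assert al.c_ext == ""

    def test_c_terminal_extension(self, profile):
        al = sc.align_to_core(profile.consensus + "PAKKAPAKKA", profile)
        assert al.core == profile.consensus
        assert al.c_ext == "PAKKAPAKKA"

    def test_single_insert_recovered_at_every_anchor(self, profile):
        """Brute force over all single-insert placements: the DP must place
        the inserted residue at the generating anchor (the unique
        max-scoring representation)."""
        cons = profile.consensus
        for anchor in (5, 14, 44, 83):
            raw = cons[:anchor] + "W" + cons[anchor:]
            al = sc.align_to_core(raw, profile)
            assert al.core == cons
            assert al.insertions == {anchor: "W"}, anchor

    def test_alignment_maximises_score_over_single_insert_oracle(self, profile):
        """Independent oracle: enumerate every single-insert representation
        of the query and score it directly; the DP's representation must
        reach the maximum."""
        cons = profile.consensus
        anchor = 30
        raw = cons[:anchor] + "W" + cons[anchor:]
        al = sc.align_to_core(raw, profile)

        def rep_score(core: str, insertions: dict[int, str]) -> float:
            s = sum(
                profile.score[c, AA.index(core[c])] for c in range(90)
            )
            return s - 11.0 * len(insertions) - 1.0 * sum(
                len(v) - 1 for v in insertions.values()
            )

        best = max(
            rep_score(raw[:a] + raw[a + 1 :], {a: raw[a]}) for a in range(1, 90)
        )
        assert rep_score(al.core, al.insertions) == pytest.approx(best)

    def test_deleted_column_recovered(self, profile):
        cons = profile.consensus
        raw = cons[:40] + cons[41:]  # column 41 missing
        al = sc.align_to_core(raw, profile)
        assert al.core.count("-") == 1
        assert al.core[40] == "-"
        assert al.insertions == {}

    def test_rejects_short_sequence(self, profile):
        with pytest.raises(ValueError, match="shorter than 30"):
            sc.align_to_core("MNKTQLIDVIAEKAELSKTQ", profile)

    def test_rejects_non_finite_profile(self, profile):
        bad = sc.CladeProfile(
            name="bad", n_members=2, freq=profile.freq,
            score=np.full((90, 21), np.nan), consensus=profile.consensus,
            conservation=profile.conservation,
        )
        with pytest.raises(ValueError, match="finite"):
            sc.align_to_core(profile.consensus, bad)


# ---------------------------------------------------------------------------
# identity with the indel-event rule
# ---------------------------------------------------------------------------

class TestCoreIdentity:
    def test_self_identity_is_90(self, hu_alpha):
        assert sc.core_identity(hu_alpha, hu_alpha) == 90

    def test_ecoli_hu_alpha_beta_is_62(self, hu_alpha, hu_beta):
        # the two E. coli HU subunits share 62 of 90 core positions
        assert sc.core_identity(hu_alpha, hu_beta) == 62

    def test_one_insertion_event_costs_one(self, hu_alpha):
        with_ins = sc.CoreAlignedSequence.from_parts(
            "ins", sd.HU_ALPHA_ECOLI, insertions={14: "W"}
        )
        assert sc.core_identity(hu_alpha, with_ins) == 89

    def test_multi_residue_insertion_is_one_event(self, hu_alpha):
        with_ins = sc.CoreAlignedSequence.from_parts(
            "ins", sd.HU_ALPHA_ECOLI, insertions={14: "WAGH"}
        )
        assert sc.core_identity(hu_alpha, with_ins) == 89

    def test_shared_insertion_not_penalised(self):
        a = sc.CoreAlignedSequence.from_parts(
            "a", sd.HU_ALPHA_ECOLI, insertions={14: "W"}
        )
        b = sc.CoreAlignedSequence.from_parts(
            "b", sd.HU_ALPHA_ECOLI, insertions={14: "W"}
        )
        assert sc.core_identity(a, b) == 90

    def test_differing_insertions_at_same_anchor_penalised_once(self):
        a = sc.CoreAlignedSequence.from_parts(
            "a", sd.HU_ALPHA_ECOLI, insertions={14: "W"}
        )
        b = sc.CoreAlignedSequence.from_parts(
            "b", sd.HU_ALPHA_ECOLI, insertions={14: "G"}
        )
        assert sc.core_identity(a, b) == 89

    def test_floor_at_zero(self):
        a = sc.CoreAlignedSequence.from_parts(
            "a", "-" * 90 if False else "A" * 90,
            insertions={c: "W" for c in range(1, 90)},
        )
        b = sc.CoreAlignedSequence.from_parts("b", "C" * 90)
        assert sc.core_identity(a, b) == 0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_range(self, seed):
        r = np.random.default_rng(seed)
        def rand():
            core = "".join(AA[i] for i in r.integers(0, 20, 90))
            ins = {}
            for _ in range(r.integers(0, 3)):
                ins[int(r.integers(1, 90))] = AA[r.integers(0, 20)]
            return sc.CoreAlignedSequence.from_parts("x", core, insertions=ins)
        a, b = rand(), rand()
        ab, ba = sc.core_identity(a, b), sc.core_identity(b, a)
        assert ab == ba
        assert 0 <= ab <= 90


# ---------------------------------------------------------------------------
# Fitch distance
# ---------------------------------------------------------------------------

# Distances computed with seqinr 4.2.36 dist.alignment(matrix="similarity")
# on the four cores below (seeded rng, two gap columns in the fourth).
SEQINR_SEQS = [
    "CSQKKVCQFCMYRSRSMDTLMIEWSPKTMKLFCNVCVTGPESRICYKVQSSEILLAMERQWRIYKHWICLSELDQLHFNQWKETPRCHST",
    "KTTIVGFQPDTETASSSQLRGSNLMNADFDKQQLVNCSNPNNCNSHPAHKYFGKYVAFTCVGWGKQDNMSYQKKKTHEHADCSRQLREWM",
    "WELQLKEIFHQPPIYCHDHYIWLQLGSYGSGRSKRGCCKWDLRFRHTNMELVASLRQKHPDNCPPCSKSAELEHQDQDENSEGWYNKHPN",
    "CSQKKVCQFC-YRSRSMDTLMIEWSPKTMKLFCNVCVTGPESRICYKVQS-EILLAMERQWRIYKHWICLSELDQLHFNQWKETPRCHST",
]
SEQINR_DIST = np.array(
    [
        [0.0, 0.774596669241, 0.795822425754, 0.0],
        [0.774596669241, 0.0, 0.781735959971, 0.768706114786],
        [0.795822425754, 0.781735959971, 0.0, 0.790569415042],
        [0.0, 0.768706114786, 0.790569415042, 0.0],
    ]
)


class TestFitchDistance:
    def test_matches_seqinr_reference(self):
        seqs = [
            sc.CoreAlignedSequence.from_parts(f"s{i}", s)
            for i, s in enumerate(SEQINR_SEQS)
        ]
        dm = sc.fitch_distance(seqs)
        np.testing.assert_allclose(dm.values, SEQINR_DIST, atol=1e-12)

    def test_matches_per_column_oracle(self, rng):
        """Direct column-by-column brute force on a random pair."""
        table = sc.load_fitch_table()
        cores = [
            "".join(AA[i] for i in rng.integers(0, 20, 90)) for _ in range(2)
        ]
        seqs = [
            sc.CoreAlignedSequence.from_parts(f"s{i}", c)
            for i, c in enumerate(cores)
        ]
        sims = [table.loc[a, b] for a, b in zip(*cores)]
        expected = math.sqrt(1.0 - sum(sims) / 90)
        assert sc.fitch_distance(seqs).values[0, 1] == pytest.approx(
            expected, abs=1e-12
        )

    def test_identical_sequences_distance_zero(self, hu_alpha):
        other = sc.CoreAlignedSequence.from_parts("copy", sd.HU_ALPHA_ECOLI)
        assert sc.fitch_distance([hu_alpha, other]).values[0, 1] == 0.0

    def test_totally_dissimilar_distance_one(self):
        # A/G class vs D/E class: similarity 0 at every column
        a = sc.CoreAlignedSequence.from_parts("a", "AG" * 45)
        b = sc.CoreAlignedSequence.from_parts("b", "DE" * 45)
        assert sc.fitch_distance([a, b]).values[0, 1] == 1.0

    def test_all_gap_pair_flagged_missing(self):
        a = sc.CoreAlignedSequence.from_parts("a", "A" + "-" * 89)
        b = sc.CoreAlignedSequence.from_parts("b", "-" * 89 + "A")
        dm = sc.fitch_distance([a, b])
        assert np.isnan(dm.values[0, 1])

    def test_gap_columns_excluded_from_mean(self):
        gapped = "".join(
            "-" if i in (10, 50) else s for i, s in enumerate(SEQINR_SEQS[0])
        )
        a = sc.CoreAlignedSequence.from_parts("a", SEQINR_SEQS[0])
        b = sc.CoreAlignedSequence.from_parts("b", gapped)
        assert sc.fitch_distance([a, b]).values[0, 1] == 0.0


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

class TestPcaEmbed:
    def _dm(self, values, ids=None):
        n = len(values)
        return sc.DistanceMatrix(
            ids=tuple(ids or [f"s{i}" for i in range(n)]),
            values=np.asarray(values, dtype=float),
        )

    def test_identical_sequences_embed_at_origin(self):
        dm = self._dm(np.zeros((4, 4)))
        emb = sc.pca_embed(dm, k=2)
        np.testing.assert_allclose(emb.coords, 0.0, atol=1e-12)

    def test_two_groups_separate_on_first_component(self):
        # two groups of duplicated sequences: within-group distance 0
        d = np.zeros((6, 6))
        d[:3, 3:] = 0.8
        d[3:, :3] = 0.8
        emb = sc.pca_embed(self._dm(d), k=2)
        g1, g2 = emb.coords[:3, 0], emb.coords[3:, 0]
        assert np.ptp(g1) == pytest.approx(0.0, abs=1e-9)
        assert np.ptp(g2) == pytest.approx(0.0, abs=1e-9)
        assert abs(g1[0] - g2[0]) > 0.1

    def test_matches_eigendecomposition_oracle(self, rng):
        """Dense eigensolver oracle on a hand-built 5x5 distance matrix."""
        raw = rng.uniform(0.1, 0.9, size=(5, 5))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = self._dm(d)
        emb = sc.pca_embed(dm, k=4)

        X = d - d.mean(axis=0)
        cov = X.T @ X / (len(d) - 1)
        w = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected_evr = w[:4] / w.sum()
        np.testing.assert_allclose(
            emb.explained_variance_ratio, expected_evr, atol=1e-9
        )
        # coordinates reproduce the centered matrix's pairwise geometry
        np.testing.assert_allclose(
            np.linalg.norm(emb.coords[:, None] - emb.coords[None], axis=-1),
            np.linalg.norm(X[:, None] - X[None], axis=-1),
            atol=1e-9,
        )

    def test_total_variance_conserved(self, family):
        dm = sc.fitch_distance(family)
        n = len(family)
        emb = sc.pca_embed(dm, k=n - 1)
        X = dm.values - dm.values.mean(axis=0)
        total_var = (X ** 2).sum() / (n - 1)
        evr_total = emb.explained_variance_ratio.sum()
        var_from_coords = (emb.coords ** 2).sum() / (n - 1)
        assert var_from_coords == pytest.approx(total_var * evr_total, rel=1e-9)
        assert evr_total == pytest.approx(1.0, abs=1e-9)

    def test_pcoa_option(self, family):
        dm = sc.fitch_distance(family)
        emb = sc.pca_embed(dm, k=3, method="pcoa")
        assert emb.coords.shape == (len(family), 3)
        assert np.all(np.diff(emb.explained_variance_ratio) <= 1e-9)

    def test_rejects_too_few_sequences(self):
        dm = self._dm(np.zeros((2, 2)))
        with pytest.raises(ValueError, match="at least 3"):
            sc.pca_embed(dm, k=1)


# ---------------------------------------------------------------------------
# profiles and classification
# ---------------------------------------------------------------------------

class TestBuildProfile:
    def test_identical_members_fully_conserved(self):
        members = [
            sc.CoreAlignedSequence.from_parts(f"m{i}", sd.HU_ALPHA_ECOLI)
            for i in range(5)
        ]
        prof = sc.build_profile(members)
        assert prof.consensus == sd.HU_ALPHA_ECOLI
        np.testing.assert_allclose(prof.conservation, 1.0)
        np.testing.assert_allclose(prof.freq.sum(axis=1), 1.0, atol=1e-12)

    def test_even_split_ties_to_lexicographically_smaller(self):
        a = sc.CoreAlignedSequence.from_parts("a", "W" * 90)
        b = sc.CoreAlignedSequence.from_parts("b", "C" * 90)
        prof = sc.build_profile([a, b])
        assert prof.consensus == "C" * 90
        np.testing.assert_allclose(prof.conservation, 0.5)

    def test_consensus_recovery_under_mutation(self):
        """10 members mutated at 10% per column recover the generating
        consensus at nearly every column (binomial bound)."""
        fam = sd.generate_family(
            sd.SeqFamilySpec(
                n_sequences=10, identity=0.9, insertion_prob=0.0,
                deletion_prob=0.0, seed=11,
            )
        )
        prof = sc.build_profile(fam)
        matches = sum(
            a == b for a, b in zip(prof.consensus, sd.HU_ALPHA_ECOLI)
        )
        assert matches >= 85

    def test_rejects_single_member(self, hu_alpha):
        with pytest.raises(ValueError, match="at least 2"):
            sc.build_profile([hu_alpha])


class TestClassifySequence:
    def _profiles(self, seed=3):
        consensi = sd.generate_clade_consensi(3, inter_identity=0.65, seed=seed)
        groups = ["HU", "IHF_A", "IHF_B"]
        profs = []
        for cons, grp in zip(consensi, groups):
            fam = sd.generate_family(
                sd.SeqFamilySpec(
                    consensus=cons, n_sequences=15, identity=0.85,
                    insertion_prob=0.0, deletion_prob=0.0,
                    name=f"{grp}_clade", group=grp, seed=seed + hash(grp) % 100,
                )
            )
            profs.append(
                sc.build_profile(fam, name=f"{grp}_clade", group=grp,
                                 clade=f"{grp}_clade")
            )
        return profs

    def test_consensus_beats_shuffled_profile(self, profile, rng):
        shuffled_members = [
            sc.CoreAlignedSequence.from_parts(
                f"r{i}",
                "".join(rng.permutation(list(profile.consensus))),
            )
            for i in range(5)
        ]
        shuffled = sc.build_profile(shuffled_members, name="shuffled")
        query = sc.CoreAlignedSequence.from_parts("q", profile.consensus)
        res = sc.classify_sequence(query, [profile, shuffled])
        assert res.best_profile == profile.name
        assert res.margin > 0

    def test_ecoli_hu_alpha_assigned_to_hu_group(self, hu_alpha):
        profs = self._profiles()
        hu_prof = next(p for p in profs if p.group == "HU")
        # rebuild the HU profile around the real sequence's clade
        fam = sd.generate_family(
            sd.SeqFamilySpec(n_sequences=15, identity=0.85, insertion_prob=0.0,
                             deletion_prob=0.0, name="HU_eco", seed=5)
        )
        profs[profs.index(hu_prof)] = sc.build_profile(
            fam, name="HU_eco", group="HU", clade="HU_eco"
        )
        res = sc.classify_sequence(hu_alpha, profs)
        assert res.group == "HU"

    def test_equal_scores_flagged_ambiguous(self, profile):
        other = sc.CladeProfile(
            name="twin", n_members=profile.n_members, freq=profile.freq,
            score=profile.score, consensus=profile.consensus,
            conservation=profile.conservation, group="IHF_A",
        )
        query = sc.CoreAlignedSequence.from_parts("q", profile.consensus)
        res = sc.classify_sequence(query, [profile, other])
        assert res.ambiguous
        assert res.margin == pytest.approx(0.0, abs=1e-12)

    def test_rejects_empty_profile_list(self, hu_alpha):
        with pytest.raises(ValueError, match="empty"):
            sc.classify_sequence(hu_alpha, [])


# ---------------------------------------------------------------------------
# indel census
# ---------------------------------------------------------------------------

class TestIndelCensus:
    def test_clean_alignment_has_zero_rates(self, family):
        census = sc.indel_census(family)
        assert census.insertion_rate == 0.0
        assert census.deletion_rate == 0.0
        for stats in census.regions.values():
            assert stats.insertion_rate == 0.0
            assert stats.insert_fraction == 0.0

    def test_counting_rates_and_single_fraction(self):
        seqs = [
            sc.CoreAlignedSequence.from_parts(
                f"m{i}", sd.HU_ALPHA_ECOLI,
                insertions={15: "W"} if i < 10 else {},
            )
            for i in range(100)
        ]
        census = sc.indel_census(seqs)
        assert census.insertion_rate == pytest.approx(0.10)
        assert census.single_residue_insert_fraction == 1.0
        assert census.regions["loop_a1_a2"].insert_fraction == 1.0
        assert census.regions["loop_a1_a2"].insertion_rate == pytest.approx(0.10)

    def test_region_fractions_partition_all_inserts(self):
        fam = sd.generate_family(
            sd.SeqFamilySpec(n_sequences=200, insertion_prob=0.3, seed=2)
        )
        census = sc.indel_census(fam)
        total = sum(st.insert_fraction for st in census.regions.values())
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_deletions_counted_by_region(self):
        gapped = sd.HU_ALPHA_ECOLI[:14] + "-" + sd.HU_ALPHA_ECOLI[15:]
        seqs = [
            sc.CoreAlignedSequence.from_parts("g", gapped),
            sc.CoreAlignedSequence.from_parts("c", sd.HU_ALPHA_ECOLI),
        ]
        census = sc.indel_census(seqs)
        assert census.regions["loop_a1_a2"].deletion_rate == pytest.approx(0.5)

    def test_rejects_overlapping_regions(self, family):
        with pytest.raises(ValueError, match="overlap"):
            sc.indel_census(family, {"a": (10, 20), "b": (15, 25)})


# ---------------------------------------------------------------------------
# terminal statistics
# ---------------------------------------------------------------------------

class TestTerminalStats:
    def test_empty_extension(self, hu_alpha):
        stats = sc.terminal_stats(hu_alpha, "C")
        assert stats.length == 0
        assert (stats.count_K, stats.count_R, stats.count_D, stats.count_E) == (
            0, 0, 0, 0,
        )
        assert stats.pakka_hits == ()

    def test_pakka_repeat_counting(self):
        s = sc.CoreAlignedSequence.from_parts(
            "x", sd.HU_ALPHA_ECOLI, c_ext="PAKKAPAKKA"
        )
        stats = sc.terminal_stats(s, "C")
        assert stats.pakka_hits == (0, 5)
        assert stats.count_K == 4

    def test_actinobacteria_like_terminus_round_trip(self):
        """A generated C-terminus with the Actinobacteria HU composition
        (111 residues, 29 K, 5 R) echoes its parameters exactly."""
        spec = sd.TerminalSpec(side="C", length=111, count_K=29, count_R=5,
                               count_D=0, count_E=1, pakka_repeats=2)
        ext = sd.make_terminus(spec, np.random.default_rng(0))
        s = sc.CoreAlignedSequence.from_parts("x", sd.HU_ALPHA_ECOLI, c_ext=ext)
        stats = sc.terminal_stats(s, "C")
        assert stats.length == 111
        assert stats.count_K == 29
        assert stats.count_R == 5
        assert stats.count_D == 0
        assert stats.count_E == 1
        assert len(stats.pakka_hits) == 2
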