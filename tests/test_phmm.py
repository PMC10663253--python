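"""Profile construction and Viterbi scoring, checked against an exhaustive
path-enumeration oracle on tiny models."""

import math

import numpy as np
import pytest

from mepsurvey import (
    CalibrationError,
    FamilyAlignment,
    FamilySpec,
    ModelError,
    build_profile,
    calibrate_evalue,
    make_family,
)
from mepsurvey.phmm import (
    AMINO_ACIDS,
    ProfileHMM,
    encode_peptide,
    read_profile,
    sample_background_peptide,
    write_profile,
)


def _lg(p):
    return math.log2(p) if p > 0 else -1.0e300


def enumerate_best_path(model, peptide):
    """Exhaustive enumeration over all state paths and substrings.

    Grammar: free flank, B -> M1|D1, M->M/I/D, I->I/M, D->D/M, exit from
    M_M/D_M, free flank. Inserts emit background (log-odds 0); match
    emissions are scored in log2 odds against the background.
    """
    M = model.n_match_states
    xi = encode_peptide(peptide)
    L = len(xi)
    lo = np.zeros((M, 21))
    lo[:, :20] = np.log2(model.match_emissions) - np.log2(model.background)
    best = [-math.inf]

    def from_state(k, state, pos, score):
        if k == M:
            best[0] = max(best[0], score)
            return
        if state == "M" or state == "D":
            t_m = model.t_mm[k] if state == "M" else model.t_dm[k]
            t_d = model.t_md[k] if state == "M" else model.t_dd[k]
            if pos < L:
                from_state(k + 1, "M", pos + 1, score + _lg(t_m) + lo[k, xi[pos]])
            from_state(k + 1, "D", pos, score + _lg(t_d))
        if state == "M" and k >= 1:
            c = 1
            while pos + c < L:
                cost = _lg(model.t_mi[k]) + (c - 1) * _lg(model.t_ii[k])
                from_state(
                    k + 1, "M", pos + c + 1,
                    score + cost + _lg(model.t_im[k]) + lo[k, xi[pos + c]],
                )
                c += 1

    for start in range(L + 1):
        if start < L:
            from_state(1, "M", start + 1, _lg(model.t_mm[0]) + lo[0, xi[start]])
        from_state(1, "D", start, _lg(model.t_md[0]))
    return best[0]


def random_tiny_model(rng, M):
    emis = rng.dirichlet(np.full(20, 0.5), size=M)
    t_mm = np.zeros(M)
    t_mi = np.zeros(M)
    t_md = np.zeros(M)
    t_im = np.zeros(M)
    t_ii = np.zeros(M)
    t_dm = np.zeros(M)
    t_dd = np.zeros(M)
    b = rng.dirichlet([1.0, 1.0])
    t_mm[0], t_md[0] = b
    for k in range(1, M):
        t_mm[k], t_mi[k], t_md[k] = rng.dirichlet([2.0, 1.0, 1.0])
        t_im[k], t_ii[k] = rng.dirichlet([2.0, 1.0])
        t_dm[k], t_dd[k] = rng.dirichlet([2.0, 1.0])
    return ProfileHMM(
        family_id="tiny",
        match_emissions=emis,
        insert_emissions=np.full(20, 0.05),
        background=np.full(20, 0.05),
        t_mm=t_mm, t_mi=t_mi, t_md=t_md,
        t_im=t_im, t_ii=t_ii, t_dm=t_dm, t_dd=t_dd,
    )


class TestBuildProfile:
    def test_identical_sequences_counting_with_pseudocounts(self):
        aln = FamilyAlignment("f", [(f"s{i}", "MKV") for i in range(5)])
        m = build_profile(aln, pseudocount=0.1)
        assert m.n_match_states == 3
        iM = AMINO_ACIDS.index("M")
        assert m.match_emissions[0, iM] == pytest.approx((5 + 0.1) / (5 + 20 * 0.1))

    def test_gap_majority_column_dropped(self):
        rows = ["MKV", "MKV", "M-V", "M-V", "M-V"]  # col 1: 60% gaps
        aln = FamilyAlignment("f", [(f"s{i}", r) for i, r in enumerate(rows)])
        assert build_profile(aln).n_match_states == 2
        rows = ["MKV", "MKV", "MKV", "M-V", "M-V"]  # col 1: 40% gaps
        aln = FamilyAlignment("f", [(f"s{i}", r) for i, r in enumerate(rows)])
        assert build_profile(aln).n_match_states == 3

    def test_all_gap_columns_is_model_error(self):
        aln = FamilyAlignment("f", [("a", "--"), ("b", "--"), ("c", "M-")])
        with pytest.raises(ModelError):
            build_profile(aln)

    def test_match_state_count_matches_column_oracle(self):
        aln, _ = make_family(
            FamilySpec("DxrII", ancestor_length=80, n_members=7,
                       divergence=0.15, indel_rate=0.1, seed=3)
        )
        seqs = [s for _, s in aln.aligned_sequences]
        expected = sum(
            1 for c in range(aln.columns)
            if sum(s[c] == "-" for s in seqs) / len(seqs) <= 0.5
        )
        assert build_profile(aln).n_match_states == expected

    def test_emissions_and_transitions_normalized(self, tiny_family):
        aln, _ = tiny_family
        m = build_profile(aln)
        assert np.allclose(m.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert m.t_mm[0] + m.t_md[0] == pytest.approx(1.0, abs=1e-9)
        M = m.n_match_states
        for k in range(1, M):
            assert m.t_mm[k] + m.t_mi[k] + m.t_md[k] == pytest.approx(1.0, abs=1e-9)
            assert m.t_im[k] + m.t_ii[k] == pytest.approx(1.0, abs=1e-9)
            assert m.t_dm[k] + m.t_dd[k] == pytest.approx(1.0, abs=1e-9)


class TestViterbi:
    @pytest.mark.parametrize("seed", range(12))
    def test_equals_exhaustive_enumeration_on_tiny_models(self, seed):
        r = np.random.default_rng(seed)
        M = int(r.integers(1, 5))
        L = int(r.integers(0, 7))
        model = random_tiny_model(r, M)
        pep = "".join(AMINO_ACIDS[i] for i in r.integers(0, 20, size=L))
        got = model.bit_score(pep)
        want = enumerate_best_path(model, pep)
        assert got == pytest.approx(want, abs=1e-9)

    def test_enumeration_agreement_with_x_residues(self):
        r = np.random.default_rng(99)
        model = random_tiny_model(r, 3)
        pep = "MXKX"
        assert model.bit_score(pep) == pytest.approx(
            enumerate_best_path(model, pep), abs=1e-9
        )

    def test_consensus_beats_single_residue_mutants(self):
        aln = FamilyAlignment("f", [(f"s{i}", "MKVLWA") for i in range(8)])
        m = build_profile(aln)
        consensus = "MKVLWA"
        s0 = m.bit_score(consensus)
        for i in range(len(consensus)):
            for sub in "RDE":
                if sub == consensus[i]:
                    continue
                mutant = consensus[:i] + sub + consensus[i + 1 :]
                assert m.bit_score(mutant) < s0

    def test_empty_peptide_scores_all_delete_path(self, tiny_family):
        aln, _ = tiny_family
        m = build_profile(aln)
        want = math.log2(m.t_md[0]) + sum(
            math.log2(m.t_dd[k]) for k in range(1, m.n_match_states)
        )
        assert m.bit_score("") == pytest.approx(want, abs=1e-9)

    def test_invariant_to_x_flank_padding(self, tiny_family):
        aln, tr = tiny_family
        m = build_profile(aln)
        pep = tr.positives[0][1]
        assert m.bit_score("XXXX" + pep + "XX") == pytest.approx(
            m.bit_score(pep), abs=1e-9
        )

    def test_reversal_generally_changes_score(self, tiny_family):
        aln, tr = tiny_family
        m = build_profile(aln)
        pep = tr.positives[0][1]
        assert m.bit_score(pep) != pytest.approx(m.bit_score(pep[::-1]), abs=1.0)

    def test_planted_members_separate_from_background(self, tiny_family):
        """Members at 20% extra divergence outscore length-matched background
        peptides in >= 99% of trials."""
        aln, tr = tiny_family
        m = build_profile(aln)
        r = np.random.default_rng(42)
        ancestor = tr.positives[0][1]
        wins = 0
        n_trials = 1000
        from mepsurvey.synthetic_data import _mutate

        for _ in range(n_trials):
            member = _mutate(r, ancestor, 0.2)
            bg = sample_background_peptide(r, len(member))
            wins += m.bit_score(member) > m.bit_score(bg)
        assert wins >= 0.99 * n_trials


class TestEvalueCalibration:
    def test_fit_is_deterministic_and_monotone(self, tiny_family):
        aln, _ = tiny_family
        m1 = calibrate_evalue(build_profile(aln), n_random=150, seed=5,
                              database_size=1000.0)
        m2 = calibrate_evalue(build_profile(aln), n_random=150, seed=5,
                              database_size=1000.0)
        assert m1.evalue_params == m2.evalue_params
        scores = np.linspace(-80, 300, 50)
        evs = [m1.evalue(s) for s in scores]
        assert all(a >= b for a, b in zip(evs, evs[1:]))

    def test_median_random_score_has_evalue_near_half_database(self, tiny_family):
        aln, _ = tiny_family
        m = build_profile(aln)
        rng = np.random.default_rng(11)
        scores = [
            m.bit_score(sample_background_peptide(rng, 60)) for _ in range(400)
        ]
        calibrate_evalue(m, n_random=400, length=60, seed=11, database_size=1.0)
        med = float(np.median(scores))
        assert m.evalue(med) == pytest.approx(0.5, abs=0.08)

    def test_degenerate_scores_raise(self):
        aln = FamilyAlignment("f", [(f"s{i}", "MMMM") for i in range(3)])
        m = build_profile(aln)
        m.match_emissions[:] = np.full(20, 1 / 20)  # flat model: constant scores
        m._cost_cache = None
        with pytest.raises(CalibrationError):
            calibrate_evalue(m, n_random=100, seed=1)

    def test_n_random_floor(self, tiny_family):
        aln, _ = tiny_family
        with pytest.raises(CalibrationError):
            calibrate_evalue(build_profile(aln), n_random=10, seed=1)


class TestSerialization:
    def test_profile_round_trip(self, tmp_path, tiny_family):
        aln, tr = tiny_family
        m = calibrate_evalue(build_profile(aln), n_random=120, seed=2)
        p = tmp_path / "fam.phmm"
        write_profile(m, p)
        back = read_profile(p)
        pep = tr.positives[3][1]
        assert back.family_id == m.family_id
        assert back.bit_score(pep) == pytest.approx(m.bit_score(pep), abs=1e-12)
        assert back.evalue_params == pytest.approx(m.evalue_params)


class TestAgainstHMMER:
    def test_separation_agrees_with_pyhmmer(self, tiny_family):
        """Independent cross-check: a HMMER-family profile built from the
        same alignment must rank every family member above every shuffled
        or random negative, as ours does (absolute scores differ by design)."""
        pyhmmer = pytest.importorskip("pyhmmer")
        aln, tr = tiny_family
        ours = build_profile(aln)
        abc = pyhmmer.easel.Alphabet.amino()
        msa = pyhmmer.easel.TextMSA(
            name=b"fam",
            sequences=[
                pyhmmer.easel.TextSequence(name=s_id.encode(), sequence=seq)
                for s_id, seq in aln.aligned_sequences
            ],
        )
        builder = pyhmmer.plan7.Builder(abc)
        hmm, _, _ = builder.build_msa(msa.digitize(abc), pyhmmer.plan7.Background(abc))
        pipeline = pyhmmer.plan7.Pipeline(abc, bit_cutoffs=None)

        def hmmer_score(seq):
            seqs = [pyhmmer.easel.TextSequence(name=b"q", sequence=seq).digitize(abc)]
            hits = pipeline.search_hmm(hmm, pyhmmer.easel.DigitalSequenceBlock(abc, seqs))
            return hits[0].score if len(hits) else -1000.0

        pos = [s for _, s in tr.positives]
        neg = [s for _, s in tr.negatives][:8]
        for scorer in (ours.bit_score, hmmer_score):
            assert min(scorer(p) for p in pos) > max(scorer(n) for n in neg)
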