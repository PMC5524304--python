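import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from ohnocne.codon_evolution import (
    CODONS,
    N_CODONS,
    CodonAlignment,
    ModelSpec,
    build_rate_matrix,
    fit,
    log_likelihood,
    lrt,
    simulate,
)
from ohnocne.errors import ValidationError
from ohnocne.io_formats import read_labeled_tree

EQUAL = np.full(N_CODONS, 1.0 / N_CODONS)
TRIPLE = "((A:0.08,B:0.12):0.05,C:0.2);"


class TestRateMatrix:
    def test_neutral_equal_frequencies_symmetric_rates(self):
        Q = build_rate_matrix(1.0, 1.0, EQUAL)
        off = Q[~np.eye(N_CODONS, dtype=bool)]
        nonzero = off[off > 0]
        assert np.allclose(nonzero, nonzero[0])

    def test_omega_zero_kills_nonsynonymous(self):
        from ohnocne.codon_evolution import _IS_NONSYN, _PAIR_I, _PAIR_J

        Q = build_rate_matrix(2.0, 0.0, EQUAL)
        assert np.all(Q[_PAIR_I[_IS_NONSYN], _PAIR_J[_IS_NONSYN]] == 0)
        assert np.any(Q[_PAIR_I[~_IS_NONSYN], _PAIR_J[~_IS_NONSYN]] > 0)

    def test_rows_sum_to_zero_and_unit_scaling(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(N_CODONS))
        Q = build_rate_matrix(2.5, 0.3, pi)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert -np.dot(pi, np.diag(Q)) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_frequencies(self):
        with pytest.raises(ValidationError):
            build_rate_matrix(2.0, 0.5, np.ones(N_CODONS))


class TestLogLikelihood:
    def test_zero_branches_identical_sequences(self):
        seq = "".join(CODONS[i] for i in [0, 5, 17, 60, 33])
        aln = CodonAlignment(["A", "B"], [seq, seq])
        ll = log_likelihood(
            aln, "(A:0.0,B:0.0);", ModelSpec("A", "equal"), kappa=2.0, omegas=0.4
        )
        assert ll == pytest.approx(5 * np.log(1 / N_CODONS), abs=1e-8)

    def test_matches_exhaustive_state_sum(self):
        """Pruning equals brute-force summation over internal-node states."""
        spec = ModelSpec("A", "equal")
        kappa, omega = 2.0, 0.3
        aln = simulate(TRIPLE, spec, kappa=kappa, omegas=omega, n_codons=10, seed=7)
        ll = log_likelihood(aln, TRIPLE, spec, kappa=kappa, omegas=omega)

        # independent route: scipy expm + explicit sum over root/internal states
        Q = build_rate_matrix(kappa, omega, EQUAL)
        lt = read_labeled_tree(TRIPLE)
        lengths = {"A": 0.08, "B": 0.12, "C": 0.2, "internal": 0.05}
        P = {k: expm(Q * t) for k, t in lengths.items()}
        mat = {t: [CODONS.index(s[k : k + 3]) for k in range(0, len(s), 3)]
               for t, s in zip(aln.taxa, aln.sequences)}
        total = 0.0
        for site in range(aln.n_codons):
            xa, xb, xc = mat["A"][site], mat["B"][site], mat["C"][site]
            lik = 0.0
            for root in range(N_CODONS):
                for inner in range(N_CODONS):
                    lik += (
                        (1 / N_CODONS)
                        * P["internal"][root, inner]
                        * P["A"][inner, xa]
                        * P["B"][inner, xb]
                        * P["C"][root, xc]
                    )
            total += np.log(lik)
        assert ll == pytest.approx(total, abs=1e-8)

    def test_model_c_with_equal_omegas_equals_model_a(self):
        nwk = "((a1#a:0.1,a2#a:0.1)#a:0.05,(b1#b:0.1,b2#b:0.1)#b:0.05,o:0.2);"
        aln = simulate(nwk, ModelSpec("C", "equal"), kappa=2.0,
                       omegas=[0.1, 0.4, 0.2], n_codons=50, seed=3)
        llA = log_likelihood(aln, nwk, ModelSpec("A", "equal"), kappa=2.0, omegas=0.25)
        llC = log_likelihood(aln, nwk, ModelSpec("C", "equal"), kappa=2.0,
                             omegas=[0.25, 0.25, 0.25])
        assert llC == pytest.approx(llA, abs=1e-10)

    def test_taxon_mismatch_rejected(self):
        aln = CodonAlignment(["A", "X"], ["ATG", "ATG"])
        with pytest.raises(ValidationError):
            log_likelihood(aln, TRIPLE, ModelSpec("A"), kappa=2.0, omegas=0.2)


class TestSimulate:
    def test_deterministic_under_seed(self):
        spec = ModelSpec("A", "equal")
        a1 = simulate(TRIPLE, spec, kappa=2.0, omegas=0.2, n_codons=30, seed=5)
        a2 = simulate(TRIPLE, spec, kappa=2.0, omegas=0.2, n_codons=30, seed=5)
        a3 = simulate(TRIPLE, spec, kappa=2.0, omegas=0.2, n_codons=30, seed=6)
        assert a1.sequences == a2.sequences
        assert a1.sequences != a3.sequences

    def test_zero_branch_lengths_copy_root(self):
        aln = simulate("(A:0.0,B:0.0,C:0.0);", ModelSpec("A", "equal"),
                       kappa=2.0, omegas=0.2, n_codons=40, seed=2)
        assert aln.sequences[0] == aln.sequences[1] == aln.sequences[2]

    def test_equilibrium_composition(self):
        aln = simulate("(A:0.1,B:0.1);", ModelSpec("A", "equal"), kappa=2.0,
                       omegas=0.3, n_codons=10_000, seed=9)
        counts = np.zeros(N_CODONS)
        for s in aln.sequences:
            for k in range(0, len(s), 3):
                counts[CODONS.index(s[k : k + 3])] += 1
        freqs = counts / counts.sum()
        assert np.max(np.abs(freqs - 1 / N_CODONS)) < 0.01

    def test_no_stop_codons_emitted(self):
        aln = simulate(TRIPLE, ModelSpec("A", "equal"), kappa=2.0, omegas=1.0,
                       n_codons=200, seed=1)
        for s in aln.sequences:
            for k in range(0, len(s), 3):
                assert s[k : k + 3] not in ("TAA", "TAG", "TGA")


class TestFitAndLrt:
    def test_recovers_omega_single_replicate(self):
        nwk = "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);"
        spec = ModelSpec("A", "equal")
        aln = simulate(nwk, spec, kappa=2.0, omegas=0.2, n_codons=500, seed=42)
        f = fit(aln, nwk, spec, init={"kappa": 2.0, "omegas": [0.3]}, n_restarts=1)
        assert f.omegas["omega"] == pytest.approx(0.2, abs=0.06)
        assert f.converged

    def test_nested_models_never_lose_likelihood(self):
        nwk = "((a1#a:0.2,a2#a:0.2)#a:0.1,(b1#b:0.2,b2#b:0.2)#b:0.1,o:0.3);"
        specA, specB = ModelSpec("A", "equal"), ModelSpec("B", "equal")
        aln = simulate(nwk, specA, kappa=2.0, omegas=0.2, n_codons=150, seed=8)
        fA = fit(aln, nwk, specA, init={"kappa": 2.0, "omegas": [0.2]}, n_restarts=1)
        fB = fit(aln, nwk, specB,
                 init={"kappa": fA.kappa, "omegas": [fA.omegas["omega"]] * 2,
                       "branch_lengths": fA.branch_lengths},
                 n_restarts=1)
        assert fB.lnL >= fA.lnL - 1e-4
        r = lrt(fA, fB)
        assert r.statistic >= 0 and r.df == 1

    def test_lrt_identical_fits(self):
        nwk = "((a1#a:0.2,a2#a:0.2)#a:0.1,(b1#b:0.2,b2#b:0.2)#b:0.1,o:0.3);"
        aln = simulate(nwk, ModelSpec("A", "equal"), kappa=2.0, omegas=0.2,
                       n_codons=50, seed=4)
        fA = fit(aln, nwk, ModelSpec("A", "equal"), n_restarts=1)
        fB_same = fit(aln, nwk, ModelSpec("B", "equal"), n_restarts=1)
        r = lrt(fA, fB_same)
        assert r.p_value == pytest.approx(chi2.sf(r.statistic, 1))

    def test_chi2_quantile_identity(self):
        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_non_nested_pair_rejected(self):
        nwk = "((a1#a:0.2,a2#a:0.2)#a:0.1,(b1#b:0.2,b2#b:0.2)#b:0.1,o:0.3);"
        aln = simulate(nwk, ModelSpec("A", "equal"), kappa=2.0, omegas=0.2,
                       n_codons=30, seed=4)
        f = fit(aln, nwk, ModelSpec("A", "equal"), n_restarts=1)
        with pytest.raises(ValidationError):
            lrt(f, f)

    def test_free_parameter_counts(self):
        nwk = "((a1#a:0.2,a2#a:0.2)#a:0.1,(b1#b:0.2,b2#b:0.2)#b:0.1,o:0.3);"
        aln = simulate(nwk, ModelSpec("A", "equal"), kappa=2.0, omegas=0.2,
                       n_codons=30, seed=4)
        fA = fit(aln, nwk, ModelSpec("A", "equal"), n_restarts=1)
        fC = fit(aln, nwk, ModelSpec("C", "equal"), n_restarts=1)
        assert fC.free_parameter_count - fA.free_parameter_count == 2


class TestRootHandling:
    def test_bifurcating_root_collapses_to_one_edge(self):
        """Root edges merge (pulley principle): likelihood matches a version of
        the tree where the combined length sits on one side of the root."""
        spec = ModelSpec("A", "equal")
        aln = simulate(TRIPLE, spec, kappa=2.0, omegas=0.3, n_codons=30, seed=1)
        ll = log_likelihood(aln, "((A:0.08,B:0.12):0.05,C:0.2);", spec,
                            kappa=2.0, omegas=0.3)
        ll_shifted = log_likelihood(aln, "((A:0.08,B:0.12):0.25,C:0.0);", spec,
                                    kappa=2.0, omegas=0.3)
        assert ll == pytest.approx(ll_shifted, abs=1e-10)

    def test_root_edge_class_conflict_resolves_to_tagged(self):
        """With one tagged and one background root edge, the merged unrooted
        edge keeps the paralog tag (its length is the sum of both)."""
        nwk = "((a1#a:0.1,a2#a:0.1)#a:0.2,((b1#b:0.1,b2#b:0.1)#b:0.1,o:0.3):0.05);"
        aln = simulate(nwk, ModelSpec("C", "equal"), kappa=2.0,
                       omegas=[0.1, 0.5, 0.1], n_codons=30, seed=2)
        merged = "((a1#a:0.1,a2#a:0.1)#a:0.25,((b1#b:0.1,b2#b:0.1)#b:0.1,o:0.3):0.0);"
        ll = log_likelihood(aln, nwk, ModelSpec("C", "equal"), kappa=2.0,
                            omegas=[0.1, 0.5, 0.1])
        ll_merged = log_likelihood(aln, merged, ModelSpec("C", "equal"), kappa=2.0,
                                   omegas=[0.1, 0.5, 0.1])
        assert ll == pytest.approx(ll_merged, abs=1e-10)

    def test_conflicting_paralog_tags_at_root_rejected(self):
        nwk = "((a1#a:0.1,a2#a:0.1)#a:0.2,(b1#b:0.1,b2#b:0.1)#b:0.1);"
        aln = simulate("((a1:0.1,a2:0.1):0.2,(b1:0.1,b2:0.1):0.1);",
                       ModelSpec("A", "equal"), kappa=2.0, omegas=0.2,
                       n_codons=10, seed=3)
        with pytest.raises(ValidationError):
            log_likelihood(aln, nwk, ModelSpec("C", "equal"), kappa=2.0,
                           omegas=[0.1, 0.2, 0.3])


class TestCodonAlignment:
    def test_rejects_stop_codons(self):
        with pytest.raises(ValidationError):
            CodonAlignment(["A"], ["ATGTAA"])

    def test_rejects_ragged(self):
        with pytest.raises(ValidationError):
            CodonAlignment(["A", "B"], ["ATGATG", "ATG"])

    def test_fasta_round_trip(self, tmp_path):
        aln = CodonAlignment(["x", "y"], ["ATGAAA", "ATGCCC"])
        p = tmp_path / "a.fa"
        aln.to_fasta(p)
        back = CodonAlignment.from_fasta(p)
        assert back.taxa == aln.taxa and back.sequences == aln.sequences

    def test_f3x4_sums_to_one(self):
        aln = CodonAlignment(["x", "y"], ["ATGAAA", "ATGCCC"])
        pi = aln.f3x4_frequencies()
        assert pi.sum() == pytest.approx(1.0)
        assert (pi > 0).all()
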