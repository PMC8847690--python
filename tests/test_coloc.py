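import itertools

import numpy as np
import pytest
from scipy.linalg import toeplitz
from scipy.special import logsumexp

from pleioscan.coloc import (AssocVector, ColocPriors, _config_label,
                             approx_conditional_z, coloc_pairwise,
                             condition_assoc, conditional_coloc_probability,
                             detect_secondary_signal, moloc_trivariate,
                             qtl_colocalize, trivariate_configurations,
                             wakefield_log_abf)
from pleioscan.sumstats import LDTable


class TestWakefieldABF:
    def test_null_effect_is_pure_shrinkage(self):
        lbf = wakefield_log_abf(0.0, 0.1, 0.2)
        r = 0.04 / (0.04 + 0.01)
        assert lbf == pytest.approx(0.5 * np.log(1 - r))
        assert lbf < 0

    def test_direct_evaluation(self):
        # beta=0.5, se=0.1, prior_sd=0.2 -> r=0.8, z=5
        lbf = wakefield_log_abf(0.5, 0.1, 0.2)
        assert lbf == pytest.approx(10 + 0.5 * np.log(0.2), abs=1e-10)
        assert lbf == pytest.approx(9.1953, abs=1e-4)

    def test_degenerate_prior_gives_zero(self):
        assert wakefield_log_abf(3.0, 0.1, 0.0) == 0.0


def brute_force_pairwise(lbf1, lbf2, priors):
    n = len(lbf1)
    logs = {"H0": [0.0], "H1": [], "H2": [], "H3": [], "H4": []}
    for i in range(n):
        logs["H1"].append(np.log(priors.p1) + lbf1[i])
        logs["H2"].append(np.log(priors.p2) + lbf2[i])
        logs["H4"].append(np.log(priors.p12) + lbf1[i] + lbf2[i])
        for j in range(n):
            if i != j:
                logs["H3"].append(np.log(priors.p1) + np.log(priors.p2)
                                  + lbf1[i] + lbf2[j])
    out = {k: logsumexp(v) for k, v in logs.items()}
    vals = np.array(list(out.values()))
    pp = np.exp(vals - logsumexp(vals))
    return dict(zip(out, pp / pp.sum()))


def brute_force_trivariate(lbfs, priors):
    n = len(lbfs[0])
    gp = {1: np.log(priors.tri_p1), 2: np.log(priors.tri_p2),
          3: np.log(priors.tri_p3)}
    logs = {}
    for config in trivariate_configurations():
        if not config:
            logs[config] = 0.0
            continue
        terms = []
        for assign in itertools.product(range(n), repeat=len(config)):
            if len(set(assign)) < len(assign):
                continue
            val = sum(gp[len(g)] for g in config)
            for g, i in zip(config, assign):
                val += sum(lbfs[t][i] for t in g)
            terms.append(val)
        logs[config] = logsumexp(terms)
    vals = np.array(list(logs.values()))
    pp = np.exp(vals - logsumexp(vals))
    return dict(zip(logs, pp / pp.sum()))


def _vec(label, beta, se=0.1):
    n = len(beta)
    return AssocVector(label, [f"v{i}" for i in range(n)],
                       np.asarray(beta, float), np.full(n, se))


class TestEnumerationEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_pairwise_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        priors = ColocPriors()
        b1, b2 = rng.normal(0, 0.25, (2, n))
        a, b = _vec("a", b1), _vec("b", b2)
        res = coloc_pairwise(a, b, priors)
        ref = brute_force_pairwise(wakefield_log_abf(b1, 0.1, 0.15),
                                   wakefield_log_abf(b2, 0.1, 0.15), priors)
        for k in ref:
            assert res.pp[k] == pytest.approx(ref[k], abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_trivariate_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        priors = ColocPriors()
        betas = rng.normal(0, 0.25, (3, n))
        betas[:, 4] += 0.4  # a partially shared signal
        vecs = [_vec(l, b) for l, b in zip("abc", betas)]
        res = moloc_trivariate(*vecs, priors=priors)
        ref = brute_force_trivariate(
            [wakefield_log_abf(b, 0.1, 0.15) for b in betas], priors)
        for config, p in ref.items():
            assert res.pp[_config_label(config, ("a", "b", "c"))] == \
                pytest.approx(p, abs=1e-10)

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(5)
        a, b, c = (_vec(l, rng.normal(0, 0.3, 30)) for l in "abc")
        assert sum(coloc_pairwise(a, b).pp.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(moloc_trivariate(a, b, c).pp.values()) == pytest.approx(1.0, abs=1e-12)


class TestPairwiseBehaviour:
    def test_shared_strong_signal_colocalizes(self):
        rng = np.random.default_rng(0)
        n = 50
        b1 = rng.normal(0, 0.02, n)
        b2 = rng.normal(0, 0.02, n)
        b1[25] = 0.8  # z = 8 at the shared variant in both traits
        b2[25] = 0.8
        res = coloc_pairwise(_vec("a", b1), _vec("b", b2))
        assert res.conditional_prob >= 0.8
        assert res.verdict == "colocalized"

    def test_all_null_favors_h0(self):
        rng = np.random.default_rng(1)
        res = coloc_pairwise(_vec("a", rng.normal(0, 0.02, 50)),
                             _vec("b", rng.normal(0, 0.02, 50)))
        assert res.pp["H0"] > 0.9

    def test_distinct_signals_favor_h3(self):
        rng = np.random.default_rng(2)
        b1 = rng.normal(0, 0.02, 50)
        b2 = rng.normal(0, 0.02, 50)
        b1[10] = 0.8
        b2[40] = 0.8
        res = coloc_pairwise(_vec("a", b1), _vec("b", b2))
        assert res.pp["H3"] > 0.8
        assert res.verdict == "distinct"

    def test_raising_shared_prior_never_decreases_pp4(self):
        rng = np.random.default_rng(3)
        b1 = rng.normal(0, 0.1, 30)
        b2 = rng.normal(0, 0.1, 30)
        last = -1.0
        for p12 in (1e-6, 1e-5, 1e-4):
            res = coloc_pairwise(_vec("a", b1), _vec("b", b2),
                                 ColocPriors(p12=p12))
            assert res.pp["H4"] >= last
            last = res.pp["H4"]

    def test_single_variant_window_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            coloc_pairwise(_vec("a", [0.5]), _vec("b", [0.4]))


class TestTrivariate:
    def test_full_sharing_recovered(self):
        rng = np.random.default_rng(4)
        betas = rng.normal(0, 0.02, (3, 40))
        betas[:, 20] = 0.8
        vecs = [_vec(l, b) for l, b in zip("abc", betas)]
        res = moloc_trivariate(*vecs)
        assert res.conditional_prob >= 0.8
        top = max(res.pp, key=res.pp.get)
        assert top == "a+b+c"

    def test_null_third_trait_marginalizes_to_pairwise(self):
        rng = np.random.default_rng(6)
        betas = rng.normal(0, 0.02, (3, 40))
        betas[0, 20] = 0.7
        betas[1, 20] = 0.7
        vecs = [_vec(l, b) for l, b in zip("abc", betas)]
        res3 = moloc_trivariate(*vecs)
        top = max(res3.pp, key=res3.pp.get)
        assert top == "a+b"
        res2 = coloc_pairwise(vecs[0], vecs[1])
        # P(a and b share a causal variant), c marginalized
        shared_ab = sum(p for label, p in res3.pp.items() if label != "null"
                        and any({"a", "b"} <= set(g.split("+"))
                                for g in label.split(";")))
        assert shared_ab == pytest.approx(res2.pp["H4"], abs=0.05)


class TestConditionalProbability:
    @pytest.mark.parametrize("pp4,pp3,expected", [(0.4, 0.1, 0.8), (0.0, 0.5, 0.0)])
    def test_ratio(self, pp4, pp3, expected):
        assert conditional_coloc_probability(pp4, pp3) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        assert conditional_coloc_probability(0.0, 0.0) is None


class TestApproxConditional:
    def test_zero_ld_identity(self):
        assert approx_conditional_z(3.2, 5.0, 0.0) == pytest.approx(3.2)

    def test_direct_evaluation(self):
        assert approx_conditional_z(6.0, 5.0, 0.8) == pytest.approx(2.0 / 0.6)

    def test_collinear_raises(self):
        with pytest.raises(ValueError, match="collinear"):
            approx_conditional_z(6.0, 6.0, 1.0 - 1e-9)

    def test_conditioning_with_zero_ld_leaves_coloc_unchanged(self):
        rng = np.random.default_rng(7)
        b1 = rng.normal(0, 0.1, 20)
        b2 = rng.normal(0, 0.1, 20)
        a, b = _vec("a", b1), _vec("b", b2)
        base = coloc_pairwise(a, b)
        conditioned = condition_assoc(b, "v5", LDTable())  # empty table: r=0
        b_kept = AssocVector("b", conditioned.ids, conditioned.beta, conditioned.se)
        # only the conditioned variant itself changes (set to zero residual)
        keep = [i for i, vid in enumerate(b.ids) if vid != "v5"]
        np.testing.assert_allclose(b_kept.beta[keep], b.beta[keep])


class TestSecondarySignalRescue:
    def _window(self, rho=0.85, n=30, shared_idx=8, extra_idx=24,
                shared_nc=5.0, extra_nc=9.0):
        """Noise-free window: traits share a causal variant, trait b carries
        an extra, stronger independent signal that violates the one-causal
        assumption."""
        Sigma = toeplitz(rho ** np.arange(n))
        lam_a = np.zeros(n)
        lam_a[shared_idx] = shared_nc
        lam_b = lam_a.copy()
        lam_b[extra_idx] = extra_nc
        za, zb = Sigma @ lam_a, Sigma @ lam_b
        ids = [f"v{i}" for i in range(n)]
        se = np.full(n, 0.02)
        ld = LDTable()
        for i in range(n):
            for j in range(i + 1, n):
                r = rho ** (j - i)
                if r * r > 1e-4:
                    ld.add(ids[i], ids[j], r * r, r=r)
        a = AssocVector("a", ids, za * se, se)
        b = AssocVector("b", ids, zb * se, se)
        return a, b, ld, ids

    def test_conditioning_on_secondary_signal_rescues_colocalization(self):
        a, b, ld, ids = self._window()
        before = coloc_pairwise(a, b)
        assert before.conditional_prob < 0.8
        b_cond = condition_assoc(b, ids[24], ld)
        after = coloc_pairwise(a, b_cond)
        assert after.conditional_prob >= 0.8
        assert after.conditional_prob > before.conditional_prob

    def test_detection_flags_the_unlinked_strong_variant(self):
        import pandas as pd
        from pleioscan.significance import z_to_p
        a, b, ld, ids = self._window()
        df = pd.DataFrame({"variant_id": ids, "p_b": z_to_p(b.z)})
        hit = detect_secondary_signal(df, ["b"], ids[8], ld)
        assert hit is not None
        trait, vid = hit
        assert trait == "b"
        assert ld.r2(vid, ids[8]) < 0.1


class TestQtlColoc:
    def _locus(self, panel, entry):
        from pleioscan.loci import Locus
        from pleioscan.multitrait import ScanDefinition
        return Locus(scan=ScanDefinition(("PAD", "CAD")),
                     sentinel_id=entry["variant_ids"].split(",")[0],
                     chrom=entry["chrom"], pos=entry["pos"], p_multi=1e-10)

    def _gwas_vec(self, panel, trait):
        from pleioscan.sumstats import harmonize_panel
        hp = harmonize_panel(panel.scans)
        k = hp.trait_index(trait)
        eaf = hp.eaf
        se = 1.0 / np.sqrt(2.0 * hp.n[:, k] * eaf * (1 - eaf))
        return AssocVector(trait, hp.index["variant_id"].to_numpy(),
                           hp.z[:, k] * se, se, trait_kind="case_control",
                           chrom=hp.index["chrom"].astype(str).to_numpy(),
                           pos=hp.index["pos"].to_numpy())

    @pytest.mark.parametrize("colocalized,expected", [(True, "colocalized"),
                                                      (False, "distinct")])
    def test_generator_truth_table(self, planted_panel, colocalized, expected):
        from pleioscan.simulate import simulate_molecular_qtl
        _, pairs, truth = simulate_molecular_qtl(
            planted_panel, 0, colocalized=colocalized, effect_size=8.0, seed=3)
        entry = planted_panel.truth.loci[0]
        locus = self._locus(planted_panel, entry)
        gwas = {t: self._gwas_vec(planted_panel, t) for t in ("PAD", "CAD")}
        records = qtl_colocalize(locus, gwas, pairs)
        assert len(records) == 1
        assert records[0].result.verdict == expected
        assert records[0].concordance in {"+/+", "+/-", "-/+", "-/-"}
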