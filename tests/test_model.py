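"""Beta-binomial mixture: pmf, EM fit, tau_i0, censuses, classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from xci_allelic import model, simulate
from xci_allelic.errors import InputError
from xci_allelic.model import (MixtureFit, MixtureParams, betabin_pmf,
                               classification_census, classify_gene,
                               error_rate_from_quals, escape_census,
                               fit_mixture, per_snp_concordance,
                               tau_inactivation)


def quadrature_pmf(k, n, mu, rho):
    """Oracle: integrate binomial(k; n, p) against Beta(p; a, b)."""
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    val, _ = integrate.quad(
        lambda p: stats.binom.pmf(k, n, p) * stats.beta.pdf(p, a, b), 0, 1,
        limit=200)
    return val


class TestBetaBinomial:
    def test_binomial_limit(self):
        assert betabin_pmf(1, 2, 0.5, 0.0) == pytest.approx(0.5, abs=1e-12)

    def test_normalisation(self):
        p = betabin_pmf(np.arange(31), 30, 0.2, 0.1)
        assert p.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_quadrature(self):
        assert betabin_pmf(5, 20, 0.3, 0.2) == pytest.approx(
            quadrature_pmf(5, 20, 0.3, 0.2), abs=1e-6)

    def test_log_space_stability_large_n(self):
        lp = model.betabin_logpmf(50, 100_000, 0.001, 0.05)
        assert np.isfinite(lp)

    @pytest.mark.parametrize("k,n,mu,rho", [(0, 5, 0.5, 0.3), (5, 5, 0.9, 0.5)])
    def test_edge_counts(self, k, n, mu, rho):
        assert betabin_pmf(k, n, mu, rho) == pytest.approx(
            quadrature_pmf(k, n, mu, rho), abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(InputError):
            betabin_pmf(3, 2, 0.5, 0.1)  # k > n
        with pytest.raises(InputError):
            betabin_pmf(1, 2, 1.5, 0.1)  # mu out of range
        with pytest.raises(InputError):
            betabin_pmf(1, 2, 0.5, 1.0)  # rho out of range


class TestErrorRate:
    @pytest.mark.parametrize("qualsum,reads,expected", [
        (30.0, 1, 0.001),   # phred 30
        (40.0, 2, 0.01),    # mean phred 20
        (0.0, 0, 0.001),    # fallback default
    ])
    def test_phred_definition(self, qualsum, reads, expected):
        assert error_rate_from_quals(qualsum, reads) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(InputError):
            error_rate_from_quals(-1.0, 1)


def default_fit(pi0=0.85, mu0=0.001, rho0=0.01, mu1=0.35, rho1=0.1):
    p = MixtureParams(pi0=pi0, mu0=mu0, rho0=rho0, mu1=mu1, rho1=rho1)
    return MixtureFit(params=p, tau=np.array([]), loglik=0.0)


class TestFitMixture:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(12)
        k, n, qual, _ = simulate.simulate_counts(
            rng, 500, pi0=0.85, mu0=0.005, rho0=0.01, mu1=0.35, rho1=0.15,
            depth_mean=200.0, phred_mean=23.0)
        fit = fit_mixture(k, n, qual)
        assert fit.converged
        assert fit.params.pi0 == pytest.approx(0.85, abs=0.05)
        assert fit.params.mu1 == pytest.approx(0.35, abs=0.05)

    def test_loglik_monotone(self):
        rng = np.random.default_rng(4)
        k, n, qual, _ = simulate.simulate_counts(
            rng, 300, pi0=0.8, mu0=0.002, rho0=0.01, mu1=0.3, rho1=0.1)
        fit = fit_mixture(k, n, qual)
        assert (np.diff(fit.loglik_trace) >= -1e-8).all()

    def test_all_zero_k_degenerate(self):
        n = np.full(50, 100)
        fit = fit_mixture(np.zeros(50), n, np.zeros(50))
        assert fit.degenerate
        assert np.nanmin(fit.tau) == 1.0

    def test_single_component_data(self):
        """With every gene inactivated, virtually all tau_i0 stay high."""
        rng = np.random.default_rng(9)
        n = np.maximum(rng.negative_binomial(5, 5 / 205.0, size=500), 1)
        k = rng.binomial(n, 0.001)
        qual = simulate._qualsum(rng, k, 30.0, 3.0)
        fit = fit_mixture(k, n, qual)
        assert np.mean(fit.tau > 0.5) >= 0.99

    def test_too_few_genes_rejected(self):
        with pytest.raises(InputError):
            fit_mixture([1] * 5, [10] * 5, [30.0] * 5)

    def test_component_order_enforced(self, standard_run):
        for fit in standard_run["fits"].values():
            assert fit.params.mu0 < fit.params.mu1
            assert 0 < fit.params.pi0 < 1


class TestTau:
    def test_zero_xi_reads_not_significant(self):
        # direction check: 0 Xi reads in 27 cannot be significant escape
        tau = tau_inactivation(0, 27, 0.0, default_fit())
        assert tau > 0.05

    def test_balanced_expression_significant(self):
        tau = tau_inactivation(500, 1000, 500 * 30.0, default_fit(mu1=0.5))
        assert tau <= 0.05

    def test_monotone_in_k_exhaustive(self):
        fit = default_fit()
        n = 50
        taus = tau_inactivation(np.arange(n + 1), np.full(n + 1, n),
                                np.arange(n + 1) * 30.0, fit)
        assert (np.diff(taus) <= 1e-12).all()

    def test_zero_total_not_evaluable(self):
        assert np.isnan(tau_inactivation(0, 0, 0.0, default_fit()))

    def test_range_and_permutation_invariance(self, standard_run):
        merged = standard_run["merged"]
        tau = merged["tau_i0"].dropna()
        assert ((tau >= 0) & (tau <= 1)).all()
        fit = standard_run["fits"][("clone1", "hF")]
        sub = merged[(merged.clone == "clone1") & (merged.timepoint == "hF")]
        perm = sub.sample(frac=1, random_state=0)
        tau_perm = tau_inactivation(perm["xi_reads"].to_numpy(),
                                    perm["total_reads"].to_numpy(),
                                    perm["xi_qualsum"].to_numpy(), fit)
        assert np.allclose(tau_perm, perm["tau_i0"].to_numpy(), equal_nan=True)


class TestEscapeCensus:
    def test_empty_filter(self):
        df = pd.DataFrame({"gene_id": ["G1"], "clone": ["c1"],
                           "total_reads": [5], "tau_i0": [0.01]})
        df2 = pd.concat([df, df.assign(clone="c2", total_reads=4)])
        assert escape_census(df2) == (0, 0)

    def test_counts(self):
        rows = []
        for i in range(10):
            for c in ("c1", "c2"):
                rows.append({"gene_id": f"G{i}", "clone": c, "total_reads": 100,
                             "tau_i0": 0.01 if (i < 3 and c == "c1") else 0.9})
        assert escape_census(pd.DataFrame(rows)) == (3, 10)

    def test_generator_escape_fraction(self, standard_run, standard_bundle):
        """Census on pre-fusion data recovers the planted escape fraction
        within sampling error."""
        merged = standard_run["merged"]
        pre = merged[merged.timepoint == "hF"][["gene_id", "clone", "total_reads", "tau_i0"]]
        n_esc, n_tot = escape_census(pre)
        truth_frac = (standard_bundle["truth_genes"]["class"] == "escape").mean()
        se = np.sqrt(truth_frac * (1 - truth_frac) / n_tot)
        assert abs(n_esc / n_tot - truth_frac) <= 4 * se


class TestConcordance:
    def _snps(self, pattern, k_sig=40, n=100):
        rows = []
        for g, flags in pattern.items():
            for f in flags:
                rows.append({"gene_id": g, "xa_count": n - (k_sig if f else 0),
                             "xi_count": k_sig if f else 0,
                             "xi_qualsum": 30.0 * (k_sig if f else 0)})
        return pd.DataFrame(rows)

    def test_full_agreement(self):
        snps = self._snps({"G1": [True, True], "G2": [False, False]})
        gene_tau = pd.Series({"G1": 0.001, "G2": 0.99})
        assert per_snp_concordance(snps, gene_tau, default_fit()) == 1.0

    def test_one_discordant_of_fifty(self):
        pattern = {f"G{i}": [False, False] for i in range(25)}
        snps = self._snps(pattern)
        # one SNP flipped to significant within an otherwise silent gene
        snps.loc[0, ["xa_count", "xi_count", "xi_qualsum"]] = [60, 40, 1200.0]
        gene_tau = pd.Series({g: 0.99 for g in pattern})
        assert per_snp_concordance(snps, gene_tau, default_fit()) == pytest.approx(0.98)

    def test_high_concordance_on_generator(self, standard_run, standard_bundle):
        """Without SNP-level heterogeneity, per-SNP calls agree with the
        gene-level call at essentially every SNP."""
        from xci_allelic import quantify
        b = standard_bundle
        man = b["manifest"]
        ids = man[(man.clone == "clone1") & (man.timepoint == "hF")]["sample_id"]
        counts = None
        for s in ids:
            c = quantify.count_sample(b["pileups"][s], standard_run["phased"], True)
            if counts is None:
                counts = c
            else:
                cols = ["xa_count", "xi_count", "xi_qualsum"]
                counts[cols] += c[cols]
        merged = standard_run["merged"]
        gene_tau = (merged[(merged.clone == "clone1") & (merged.timepoint == "hF")]
                    .set_index("gene_id")["tau_i0"])
        conc = per_snp_concordance(counts, gene_tau,
                                   standard_run["fits"][("clone1", "hF")])
        assert conc >= 0.95


SIG, NS, MISS = 0.01, 0.9, None


def series(vals):
    """(hF, day0, day4, day6) tau values for one clone."""
    tps = ("hF", "day0", "day4", "day6")
    tau = {}
    n = {}
    for tp, v in zip(tps, vals):
        if v is not None:
            tau[("c1", tp)] = v
            n[("c1", tp)] = 100
    return tau, n


class TestClassification:
    def test_reactivated(self):
        tau, n = series([NS, NS, SIG, NS])
        assert classify_gene(tau, n) == "reactivated"

    def test_active(self):
        tau, n = series([SIG, NS, NS, SIG])
        assert classify_gene(tau, n) == "active"

    def test_inactive(self):
        tau, n = series([NS, NS, NS, NS])
        assert classify_gene(tau, n) == "inactive"

    def test_coverage_filter(self):
        tau, n = series([NS, NS, SIG, SIG])
        n = {k: 5 for k in n}  # below the 20-read threshold everywhere
        assert classify_gene(tau, n) == "not_evaluated"

    def test_strict_mode_requires_both_post_days(self):
        tau, n = series([NS, NS, SIG, MISS])
        assert classify_gene(tau, n) == "reactivated"
        assert classify_gene(tau, n, strict=True) == "not_evaluated"

    def test_exhaustive_decision_table(self):
        """Every combination of (significant / not / missing) across the four
        timepoints maps to a defined class; significance anywhere post-fusion
        forces active or reactivated according to the pre-fusion state."""
        for combo in itertools.product([SIG, NS, MISS], repeat=4):
            tau, n = series(combo)
            cls = classify_gene(tau, n)
            assert cls in {"active", "reactivated", "inactive", "not_evaluated"}
            pre_obs = [v for v in combo[:2] if v is not None]
            post_obs = [v for v in combo[2:] if v is not None]
            if not pre_obs or not post_obs:
                assert cls == "not_evaluated"
                continue
            pre_sig = any(v <= 0.05 for v in pre_obs)
            post_sig = any(v <= 0.05 for v in post_obs)
            expected = ("active" if pre_sig and post_sig else
                        "reactivated" if post_sig else "inactive")
            assert cls == expected

    def test_census(self):
        calls = pd.DataFrame({"class": ["active"] * 2 + ["reactivated"] + ["inactive"] * 3})
        c = classification_census(calls)
        assert (c["active"], c["reactivated"], c["inactive"]) == (2, 1, 3)
        assert c["n_evaluable"] == 6

    def test_census_empty(self):
        c = classification_census(pd.DataFrame({"class": []}))
        assert c["n_evaluable"] == 0
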