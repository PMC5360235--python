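import numpy as np
import pandas as pd
import pytest

from conftest import random_codon_counts
from ribostall.stall import (
    StallCallConfig,
    call_sensitive,
    center_of_density,
    cfr_curve,
    cod_change_zscores,
    differential_downstream,
    dmax,
    downstream_boundary,
    downstream_counts,
    null_dmax,
)


# --- independent brute-force oracles -------------------------------------

def brute_dmax(ct, cv):
    """Scan every codon; keep the signed value of max |divergence|,
    3'-most on ties."""
    best_mag, best_codon, best_val = -1.0, 0, 0.0
    for c in range(len(ct)):
        d = ct[c] - cv[c]
        if abs(d) >= best_mag:  # ties resolve to the later (3'-most) codon
            best_mag, best_codon, best_val = abs(d), c + 1, d
    return best_val, best_codon


def brute_downstream(counts, boundary):
    return sum(int(counts[k - 1]) for k in range(1, len(counts) + 1)
               if k > boundary)


def brute_center(counts, omit_first):
    num = den = 0
    for k in range(omit_first + 1, len(counts) + 1):
        num += k * counts[k - 1]
        den += counts[k - 1]
    return num / den


class TestCFR:
    def test_worked_example(self):
        np.testing.assert_allclose(cfr_curve(np.array([2, 0, 3, 5])),
                                   [0.2, 0.2, 0.5, 1.0])

    def test_all_reads_at_first_codon(self):
        np.testing.assert_allclose(cfr_curve(np.array([4, 0, 0])), 1.0)

    def test_uniform_counts_linear(self):
        np.testing.assert_allclose(cfr_curve(np.ones(10)),
                                   np.arange(1, 11) / 10)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            cfr_curve(np.zeros(5))

    def test_monotone_and_ends_at_one(self, rng):
        for _ in range(100):
            c = cfr_curve(random_codon_counts(rng, 50))
            assert (np.diff(c) >= 0).all()
            assert c[-1] == pytest.approx(1.0)


class TestDmax:
    def test_identical_curves_give_zero(self, rng):
        a = cfr_curve(random_codon_counts(rng, 40))
        d, _ = dmax(a, a)
        assert d == 0.0

    def test_tie_resolves_to_three_prime_codon(self):
        t = np.array([0.5, 0.75, 1.0])
        v = np.array([0.25, 0.5, 1.0])
        d, codon = dmax(t, v)
        assert d == pytest.approx(0.25) and codon == 2

    def test_antisymmetric_under_condition_swap(self, rng):
        for _ in range(50):
            a = cfr_curve(random_codon_counts(rng, 30))
            b = cfr_curve(random_codon_counts(rng, 30))
            da, ca = dmax(a, b)
            db, cb = dmax(b, a)
            assert da == pytest.approx(-db) and ca == cb

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 60))
            a = cfr_curve(random_codon_counts(rng, n))
            b = cfr_curve(random_codon_counts(rng, n))
            assert dmax(a, b) == pytest.approx(brute_dmax(a, b))

    def test_mismatched_spans_rejected(self):
        with pytest.raises(ValueError):
            dmax(np.ones(3), np.ones(4))


class TestBoundary:
    def test_z_gate_uses_dmax_codon(self):
        assert downstream_boundary(2.5, 34) == 34

    def test_below_gate_uses_default(self):
        assert downstream_boundary(1.0, 34) == 50

    def test_gate_boundary_inclusive(self):
        assert downstream_boundary(2.0, 17) == 17


class TestDownstreamCounts:
    def test_worked_example(self):
        assert downstream_counts(np.array([1, 2, 3, 4]), 2) == 7

    def test_boundary_at_or_past_end_gives_zero(self):
        assert downstream_counts(np.array([1, 2, 3]), 3) == 0
        assert downstream_counts(np.array([1, 2, 3]), 7) == 0

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 80))
            counts = random_codon_counts(rng, n, total=100)
            b = int(rng.integers(0, n + 2))
            assert downstream_counts(counts, b) == brute_downstream(counts, b)


class TestCenterOfDensity:
    def test_uniform_counts_mean_is_midpoint(self):
        assert center_of_density(np.ones(99)) == pytest.approx(50.0)

    def test_point_mass_returns_that_codon(self):
        v = np.zeros(60)
        v[41] = 9
        assert center_of_density(v) == 42.0

    def test_empty_span_rejected(self):
        with pytest.raises(ValueError):
            center_of_density(np.zeros(10))

    def test_matches_brute_force_with_omission(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 80))
            counts = random_codon_counts(rng, n, total=500) + 1
            omit = int(rng.integers(0, n - 1))
            assert center_of_density(counts, omit) == pytest.approx(
                brute_center(counts, omit))


class TestDifferentialDownstream:
    def _design(self):
        return pd.DataFrame(
            {"condition": ["treatment"] * 3 + ["vehicle"] * 3},
            index=[f"s{i}" for i in range(6)])

    def test_identical_columns_give_zero_fold_change(self, rng):
        base = rng.integers(50, 500, size=40)
        counts = pd.DataFrame({f"s{i}": base for i in range(6)},
                              index=[f"g{i}" for i in range(40)])
        res = differential_downstream(counts, self._design())
        np.testing.assert_allclose(res["log2_fold_change"], 0.0, atol=1e-5)
        assert not res["significant_decrease"].any()

    def test_halved_counts_recover_minus_one(self, rng):
        # halve a minority of genes so size factors stay anchored by the rest
        n, n_down = 300, 40
        mu = rng.lognormal(6, 0.5, size=n)
        fold = np.ones(n)
        fold[:n_down] = 0.5
        cols = {}
        for i in range(3):
            cols[f"s{i}"] = rng.poisson(mu * fold)    # treatment
        for i in range(3, 6):
            cols[f"s{i}"] = rng.poisson(mu)           # vehicle
        counts = pd.DataFrame(cols, index=[f"g{i}" for i in range(n)])
        res = differential_downstream(counts, self._design())
        down = res.iloc[:n_down]
        assert down["log2_fold_change"].median() == pytest.approx(-1.0, abs=0.1)
        assert down["significant_decrease"].mean() > 0.9
        assert res.iloc[n_down:]["significant_decrease"].mean() < 0.02

    def test_all_zero_gene_excluded_and_reported(self, rng):
        counts = pd.DataFrame(
            rng.integers(10, 100, size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(6)])
        counts.loc["g2"] = 0
        res = differential_downstream(counts, self._design())
        assert not res.loc["g2", "tested"]
        assert res.drop("g2")["tested"].all()

    def test_single_replicate_rejected(self):
        design = pd.DataFrame({"condition": ["treatment", "vehicle"]},
                              index=["a", "b"])
        counts = pd.DataFrame({"a": [1], "b": [2]}, index=["g"])
        with pytest.raises(ValueError):
            differential_downstream(counts, design)


def _counts_to_maps(rng, mus, n_reps):
    """NB-ish replicate codon maps from per-gene per-codon means."""
    maps = []
    for _ in range(n_reps):
        maps.append({g: rng.poisson(mu) for g, mu in mus.items()})
    return maps


class TestCallSensitive:
    def test_recovers_implanted_stall_and_skips_null_genes(self, rng):
        n_genes, n_codons = 400, 200
        stall_gene, stall_codon, readthrough, amp = "g0007", 30, 0.3, 8.0
        mus_v, mus_t = {}, {}
        for i in range(n_genes):
            g = f"g{i:04d}"
            level = rng.lognormal(0.5, 0.8)
            mu = np.full(n_codons, level)
            mus_v[g] = mu
            if g == stall_gene:
                mt = mu.copy()
                mt[stall_codon - 1] *= 1 + amp
                mt[stall_codon:] *= readthrough
                mus_t[g] = mt
            else:
                mus_t[g] = mu
        # ensure the stalled gene has usable depth
        mus_v[stall_gene] = np.full(n_codons, 4.0)
        mus_t[stall_gene] = np.full(n_codons, 4.0)
        mus_t[stall_gene][stall_codon - 1] *= 1 + amp
        mus_t[stall_gene][stall_codon:] *= readthrough
        t_maps = _counts_to_maps(rng, mus_t, 3)
        v_maps = _counts_to_maps(rng, mus_v, 3)
        res = call_sensitive(t_maps, v_maps,
                             StallCallConfig(bin_size=100, min_reads=32))
        assert res.loc[stall_gene, "sensitive"]
        called = [int(c) for c in
                  str(res.loc[stall_gene, "stall_codons"]).split(",")]
        assert any(abs(c - stall_codon) <= 2 for c in called)
        # no more than a stray false call among the 399 null genes
        assert res.drop(stall_gene)["sensitive"].sum() <= 1

    def test_stall_without_downstream_loss_not_called(self, rng):
        # a pile-up with unchanged downstream flux (readthrough 1) must not
        # be called sensitive: there is no decrease to detect
        n_genes, n_codons = 400, 150
        gene = "g0003"
        mus = {f"g{i:04d}": np.full(n_codons, rng.lognormal(1.0, 0.5))
               for i in range(n_genes)}
        mus_t = {g: m.copy() for g, m in mus.items()}
        mus_t[gene] = mus[gene].copy()
        mus_t[gene][29] *= 9.0  # peak only
        res = call_sensitive(_counts_to_maps(rng, mus_t, 3),
                             _counts_to_maps(rng, mus, 3),
                             StallCallConfig(bin_size=100, min_reads=32))
        assert gene in res.index
        assert not res.loc[gene, "sensitive"]


class TestNullDmax:
    def test_same_counts_give_all_zero(self, rng):
        cm = {f"g{i}": random_codon_counts(rng, 50) + 1 for i in range(20)}
        res = null_dmax([cm], [cm], min_reads=1, bin_size=20)
        np.testing.assert_allclose(res["dmax"], 0.0)

    def test_null_dmax_shrinks_with_expression(self, rng):
        # CFR sampling noise scales as 1/sqrt(reads): high-expression genes
        # have stochastically smaller null divergences
        maps_a, maps_b = {}, {}
        depths = {}
        for i in range(400):
            g = f"g{i}"
            depth = int(rng.choice([50, 5000]))
            depths[g] = depth
            p = np.ones(100) / 100
            maps_a[g] = rng.multinomial(depth, p)
            maps_b[g] = rng.multinomial(depth, p)
        res = null_dmax([maps_a], [maps_b], min_reads=1, bin_size=100)
        med_hi = res.loc[[g for g in res.index if depths[g] == 5000],
                         "dmax"].abs().median()
        med_lo = res.loc[[g for g in res.index if depths[g] == 50],
                         "dmax"].abs().median()
        assert med_hi < med_lo


class TestCodChange:
    def test_early_stall_shift_decays_with_omission(self, rng):
        # implanted early stall: treatment mean position shifts 5'
        # (delta < 0) and the shift shrinks as leading codons are omitted
        n_codons = 400
        mu_v = np.full(n_codons, 3.0)
        mu_t = mu_v.copy()
        mu_t[29] *= 9
        mu_t[30:] *= 0.3
        t_maps = _counts_to_maps(rng, {"g0": mu_t}, 3)
        v_maps = _counts_to_maps(rng, {"g0": mu_v}, 3)
        deltas = []
        for omit in (0, 50, 100, 150):
            res = cod_change_zscores(t_maps, v_maps, omit_first=omit,
                                     min_reads=8, bin_size=10)
            deltas.append(res.loc["g0", "delta"])
        assert deltas[0] < 0
        assert abs(deltas[0]) > abs(deltas[1]) > abs(deltas[2])
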