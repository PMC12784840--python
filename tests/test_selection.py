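"""ENC, expected-ENC curve, neutrality regression and PR2 coordinates."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from mitocub import (
    compute_enc, enc_ratio, expected_enc, fit_neutrality, positional_composition,
    pr2_coordinates,
)
from mitocub.codon import CodonCounts
from mitocub.genetic_code import TABLE5
from mitocub.selection import UndefinedStatisticError, attach_expected

from conftest import make_gene


def counts_from(d, label="u"):
    return CodonCounts(label=label, counts=dict(d), total=sum(d.values()))


def enc_bruteforce(counts):
    """Independent evaluation of Wright's homozygosity-class formula.

    Deliberately re-derived from the F-hat definitions rather than calling
    the implementation: per amino acid F = (n*sum(p^2)-1)/(n-1) for n >= 2,
    F = 0 or n < 2 treated as missing; class means; missing classes filled
    with the mean of available class means; ENC = 2 + sum N_k / F_k.
    """
    per_class = {2: [], 4: [], 6: [], 8: []}
    for aa, fam in TABLE5.synonymous_families.items():
        ns = [counts.get(c, 0) for c in sorted(fam)]
        n = sum(ns)
        if n < 2:
            continue
        f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if f > 0:
            per_class[len(fam)].append(f)
    means = {k: sum(v) / len(v) for k, v in per_class.items() if v}
    if not means:
        return None
    fill = sum(means.values()) / len(means)
    n_k = {2: 10, 4: 6, 6: 1, 8: 1}
    return min(61.0, 2.0 + sum(n_k[k] / means.get(k, fill) for k in n_k))


class TestENC:
    def test_maximal_bias_gives_amino_acid_count(self):
        """One codon per amino acid (each seen >= twice) -> every F = 1 ->
        ENC = 2 + 10 + 6 + 1 + 1 = 20."""
        d = {}
        for fam in TABLE5.synonymous_families.values():
            d[sorted(fam)[0]] = 2
        assert compute_enc(counts_from(d)).enc_observed == pytest.approx(20.0)

    def test_two_family_toy_matches_bruteforce(self):
        d = {"TTT": 2, "TTC": 2, "GGA": 1, "GGC": 1, "GGG": 1, "GGT": 1}
        r = compute_enc(counts_from(d))
        assert r.enc_observed == pytest.approx(enc_bruteforce(d), abs=1e-9)

    def test_oracle_equivalence_random_tables(self):
        """Implementation == brute-force F-hat oracle on random small tables."""
        rng = np.random.default_rng(2024)
        codons = list(TABLE5.analyzed_codons)
        for _ in range(60):
            n_codons = int(rng.integers(20, 500))
            drawn = rng.choice(len(codons), size=n_codons)
            d = {}
            for i in drawn:
                d[codons[i]] = d.get(codons[i], 0) + 1
            expected = enc_bruteforce(d)
            got = compute_enc(counts_from(d)).enc_observed
            assert got == pytest.approx(expected, abs=1e-9)

    def test_monotone_under_family_skew(self):
        """Concentrating one family's usage (totals fixed) never raises ENC."""
        base = {c: 6 for c in TABLE5.analyzed_codons}
        prev = compute_enc(counts_from(base)).enc_observed
        fam = sorted(TABLE5.synonymous_families["G"])
        for shift in range(1, 7):
            d = dict(base)
            d[fam[0]] += 3 * shift
            for c in fam[1:]:
                d[c] -= shift
            cur = compute_enc(counts_from(d)).enc_observed
            assert cur <= prev + 1e-12
            prev = cur

    def test_all_classes_missing_is_signalled(self):
        with pytest.raises(UndefinedStatisticError):
            compute_enc(counts_from({"TTT": 1}))  # n < 2 everywhere

    def test_clipping_at_61(self):
        d = {c: 1000 for c in TABLE5.analyzed_codons}  # perfectly even, F ~ 1/k
        r = compute_enc(counts_from(d))
        assert r.enc_observed <= 61.0
        assert compute_enc(counts_from(d), clip=False).enc_observed >= r.enc_observed


class TestExpectedENC:
    @pytest.mark.parametrize("gc3s,value", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_printed_formula_values(self, gc3s, value):
        assert expected_enc(gc3s) == pytest.approx(value)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_enc(1.2)

    def test_symmetry_and_maximum_about_half(self):
        """2 + s + 29/(s^2+(1-s)^2) minus the linear term is symmetric in s
        about 0.5, and the curve peaks there."""
        grid = np.linspace(0.0, 1.0, 101)
        vals = [expected_enc(s) for s in grid]
        for s in grid:
            assert (expected_enc(s) - s) == pytest.approx(
                expected_enc(1.0 - s) - (1.0 - s), abs=1e-12)
        assert max(vals) == pytest.approx(expected_enc(0.5))


class TestENCRatio:
    @pytest.mark.parametrize("obs,exp,val", [
        (40.0, 40.0, 0.0),
        (61.0, 60.5, 1.0),
        (31.0, 60.5, -59.0),
    ])
    def test_formula(self, obs, exp, val):
        assert enc_ratio(obs, exp) == pytest.approx(val)

    def test_expected_61_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            enc_ratio(50.0, 61.0)

    def test_attach_expected_fills_both_fields(self):
        d = {c: 5 for c in TABLE5.analyzed_codons}
        r = attach_expected(compute_enc(counts_from(d)), 0.3)
        assert r.enc_expected == pytest.approx(expected_enc(0.3))
        assert r.enc_ratio == pytest.approx(
            (r.enc_observed - r.enc_expected) / (61 - r.enc_expected))


class TestNeutrality:
    def test_perfect_collinearity(self):
        pts = [(x, x) for x in (0.1, 0.2, 0.3, 0.4)]
        fit = fit_neutrality(pts)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_ols_oracle(self):
        """Closed-form OLS on four constructed points: slope = Sxy/Sxx."""
        pts = [(0.2, 0.30), (0.25, 0.31), (0.30, 0.34), (0.35, 0.35)]
        fit = fit_neutrality(pts)
        assert fit.slope == pytest.approx(0.36)          # 0.0045 / 0.0125
        assert fit.intercept == pytest.approx(0.226)
        assert fit.r_squared == pytest.approx(fit.pearson_r ** 2, abs=1e-12)
        assert fit.ci_low <= fit.slope <= fit.ci_high

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_neutrality([(0.1, 0.2), (0.2, 0.3)])

    def test_zero_variance_in_gc3(self):
        with pytest.raises(UndefinedStatisticError):
            fit_neutrality([(0.2, 0.1), (0.2, 0.2), (0.2, 0.3)])

    def test_verdicts_track_ci_position(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0.1, 0.5, 40)
        flat = fit_neutrality(zip(x, 0.3 + 0.01 * rng.standard_normal(40)))
        assert flat.verdict == "selection-constrained"
        steep = fit_neutrality(zip(x, 2.0 * x + 0.005 * rng.standard_normal(40)))
        assert steep.verdict == "positive/relaxed"
        neutral = fit_neutrality(zip(x, x + 0.05 * rng.standard_normal(40)))
        assert neutral.verdict == "neutral-compatible"


class TestPR2:
    def test_parity_center(self):
        g = make_gene(["GGA", "GGT", "GGG", "GGC"])  # Gly: A/T/G/C thirds once each
        p = pr2_coordinates(positional_composition(g))
        assert (p.a3_ratio, p.g3_ratio) == (0.5, 0.5)

    def test_direct_ratios(self):
        g = make_gene(["GGA"] * 3 + ["GGT"] + ["GGG"] + ["GGC"] * 3)
        p = pr2_coordinates(positional_composition(g))
        assert p.a3_ratio == pytest.approx(0.75)
        assert p.g3_ratio == pytest.approx(0.25)

    def test_fourfold_default_vs_all_sites(self):
        # Phe (2-fold) thirds contribute only in "all" mode
        g = make_gene(["TTT", "TTT", "GGA", "GGC"])
        four = pr2_coordinates(positional_composition(g), sites="fourfold")
        allm = pr2_coordinates(positional_composition(g), sites="all")
        assert four.t3 == 0 and allm.t3 == 2

    def test_zero_denominator_flagged(self):
        g = make_gene(["GGG", "GGG"])
        p = pr2_coordinates(positional_composition(g))
        assert p.a3_ratio is None and p.g3_ratio == 1.0

    def test_invariant_to_gene_order_and_duplication(self, synthetic_genes):
        genes, _ = synthetic_genes
        comps = [positional_composition(g) for g in genes]
        pts = [(pr2_coordinates(c).a3_ratio, pr2_coordinates(c).g3_ratio)
               for c in comps]
        rev = [(pr2_coordinates(c).a3_ratio, pr2_coordinates(c).g3_ratio)
               for c in reversed(comps)]
        assert sorted(map(str, pts)) == sorted(map(str, rev))
        # duplicating the gene set leaves the neutrality slope unchanged
        xy = [(c.gc3, c.gc12) for c in comps]
        a, b = fit_neutrality(xy), fit_neutrality(xy + xy)
        assert a.slope == pytest.approx(b.slope)
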