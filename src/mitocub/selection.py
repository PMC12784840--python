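"""Mutation-vs-selection diagnostics for codon usage.

Three classical tools:

* **Wright's effective number of codons (ENC)** — summarizes how far a gene
  departs from uniform synonymous usage.  For amino acid *a* with *n_a*
  occurrences and within-family usage fractions *p_i*, the codon
  homozygosity is ``F_a = (n_a * sum(p_i^2) - 1) / (n_a - 1)``; F values are
  averaged within each degeneracy class k and combined as
  ``ENC = 2 + sum_k N_k / F_k`` where N_k is the number of amino acids of
  degeneracy k (under the invertebrate mitochondrial code: N_2=10, N_4=6,
  N_6=1 for Leu, N_8=1 for Ser; the leading 2 counts Met and Trp).  Genes
  shaped only by mutation pressure fall on the expected curve
  ``ENC_exp = 2 + GC3s + 29 / (GC3s^2 + (1-GC3s)^2)``; selection pulls
  observed values below it.  The ENC ratio
  ``(ENC_obs - ENC_exp) / (61 - ENC_exp)`` expresses the deviation on a
  common scale.

* **Neutrality regression** — GC12 (mean GC of codon positions 1 and 2)
  regressed on GC3 across a species' genes.  Slope near 1: mutation pressure
  moves all positions together; slope near 0: selection decouples
  non-synonymous from synonymous sites.

* **PR2 parity coordinates** — A3/(A3+T3) against G3/(G3+C3) at third
  positions of fourfold-degenerate families; (0.5, 0.5) is the no-asymmetry
  point under parity rule 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .genetic_code import TABLE5, CodonTable5

ENC_CEILING = 61.0


class UndefinedStatisticError(ValueError):
    """A diagnostic is undefined for this input (signalled, never silent)."""


@dataclass(frozen=True)
class ENCResult:
    label: str
    enc_observed: float
    f_by_class: dict               # degeneracy k -> mean homozygosity F_k (may include imputed)
    imputed_classes: tuple         # ks whose F was imputed from the cross-class mean
    enc_expected: float | None = None
    enc_ratio: float | None = None


@dataclass(frozen=True)
class NeutralityFit:
    species: str
    n_genes: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    ci_low: float
    ci_high: float
    pearson_r: float
    verdict: str                   # neutral-compatible | selection-constrained | positive/relaxed


@dataclass(frozen=True)
class PR2Point:
    label: str
    a3_ratio: float | None         # A3/(A3+T3); None when the denominator is 0
    g3_ratio: float | None         # G3/(G3+C3)
    a3: int
    t3: int
    g3: int
    c3: int


def codon_homozygosity(family_counts) -> float | None:
    """F_a for one synonymous family from its codon counts.

    Returns ``None`` when n_a < 2 (the estimator divides by n_a - 1) or when
    F_a is exactly 0 (a perfectly even tiny family), both unusable in the
    class average.
    """
    n = sum(family_counts)
    if n < 2:
        return None
    s = sum((c / n) ** 2 for c in family_counts)
    f = (n * s - 1) / (n - 1)
    return None if f == 0 else f


def compute_enc(counts, code: CodonTable5 = TABLE5, clip: bool = True) -> ENCResult:
    """Observed ENC from a codon tally.

    Degeneracy classes with no computable family homozygosity are imputed
    with the mean of the available class means; the result is clipped to the
    conventional ceiling of 61.
    """
    classes = code.degeneracy_classes()
    n_by_class = {k: len(aas) for k, aas in classes.items()}

    f_means: dict = {}
    for k, aas in classes.items():
        fs = []
        for aa in aas:
            fam = sorted(code.synonymous_families[aa])
            f = codon_homozygosity([counts.counts.get(c, 0) for c in fam])
            if f is not None:
                fs.append(f)
        if fs:
            f_means[k] = sum(fs) / len(fs)

    if not f_means:
        raise UndefinedStatisticError(f"{counts.label}: no degeneracy class has a computable F")

    imputed = tuple(k for k in n_by_class if k not in f_means)
    cross_mean = sum(f_means.values()) / len(f_means)
    full = {k: f_means.get(k, cross_mean) for k in n_by_class}

    enc = 2.0 + sum(n_by_class[k] / full[k] for k in n_by_class)
    if clip:
        enc = min(enc, ENC_CEILING)
    return ENCResult(label=counts.label, enc_observed=enc,
                     f_by_class=full, imputed_classes=imputed)


def expected_enc(gc3s: float) -> float:
    """Mutation-drift expectation of ENC at a given GC3s."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"GC3s must lie in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s ** 2 + (1.0 - gc3s) ** 2)


def enc_ratio(enc_observed: float, enc_expected_: float) -> float:
    """Deviation of observed from expected ENC, scaled by the room below 61."""
    if enc_expected_ == ENC_CEILING:
        raise UndefinedStatisticError("ENC ratio undefined when expected ENC equals 61")
    return (enc_observed - enc_expected_) / (ENC_CEILING - enc_expected_)


def attach_expected(result: ENCResult, gc3s: float | None) -> ENCResult:
    """Return a copy of *result* with expected ENC and ENC ratio filled in."""
    if gc3s is None:
        return result
    exp = expected_enc(gc3s)
    ratio = enc_ratio(result.enc_observed, exp) if exp != ENC_CEILING else None
    return ENCResult(result.label, result.enc_observed, result.f_by_class,
                     result.imputed_classes, exp, ratio)


def fit_neutrality(points, species: str = "") -> NeutralityFit:
    """OLS of GC12 on GC3 over one species' genes.

    ``points`` is an iterable of (gc3, gc12) pairs, one per gene.  The 95%
    CI for the slope uses the t distribution with n-2 df; the verdict
    compares the CI with the neutral slope of 1.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise ValueError(f"{species or 'fit'}: need >=3 genes, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.ptp(x) == 0:
        raise UndefinedStatisticError(f"{species or 'fit'}: zero variance in GC3")

    res = sps.linregress(x, y)
    n = len(pts)
    tcrit = sps.t.ppf(0.975, n - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)

    if ci[0] <= 1.0 <= ci[1]:
        verdict = "neutral-compatible"
    elif ci[1] < 1.0:
        verdict = "selection-constrained"
    else:
        verdict = "positive/relaxed"

    return NeutralityFit(
        species=species, n_genes=n,
        slope=res.slope, intercept=res.intercept,
        r_squared=res.rvalue ** 2, p_value=res.pvalue,
        ci_low=ci[0], ci_high=ci[1],
        pearson_r=res.rvalue, verdict=verdict,
    )


def pr2_coordinates(stats, sites: str = "fourfold") -> PR2Point:
    """Parity-rule-2 coordinates for one gene.

    ``sites="fourfold"`` (default) uses third positions of fourfold
    families only — the positions where parity rule 2 applies cleanly;
    ``sites="all"`` uses every synonymous third position.
    """
    if sites == "fourfold":
        a, t, g, c = stats.ff_a3, stats.ff_t3, stats.ff_g3, stats.ff_c3
    elif sites == "all":
        a, t, g, c = stats.a3s, stats.t3s, stats.g3s, stats.c3s
    else:
        raise ValueError(f"unknown PR2 site mode {sites!r}")
    return PR2Point(
        label=stats.label,
        a3_ratio=a / (a + t) if a + t else None,
        g3_ratio=g / (g + c) if g + c else None,
        a3=a, t3=t, g3=g, c3=c,
    )


def write_enc_table(results, path) -> None:
    with open(path, "w") as fh:
        fh.write("unit\tENC\tENC_expected\tENC_ratio\timputed_classes\n")
        for r in results:
            exp = "" if r.enc_expected is None else f"{r.enc_expected:.4f}"
            rat = "" if r.enc_ratio is None else f"{r.enc_ratio:.4f}"
            imp = ",".join(str(k) for k in r.imputed_classes)
            fh.write(f"{r.label}\t{r.enc_observed:.4f}\t{exp}\t{rat}\t{imp}\n")


def write_neutrality_table(fits, path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tn_genes\tslope\tintercept\tR2\tp_value\t"
                 "ci_low\tci_high\tpearson_r\tverdict\n")
        for f in fits:
            fh.write(f"{f.species}\t{f.n_genes}\t{f.slope:.4f}\t{f.intercept:.4f}\t"
                     f"{f.r_squared:.4f}\t{f.p_value:.4g}\t{f.ci_low:.4f}\t"
                     f"{f.ci_high:.4f}\t{f.pearson_r:.4f}\t{f.verdict}\n")


def write_pr2_table(points, path) -> None:
    with open(path, "w") as fh:
        fh.write("unit\tA3_ratio\tG3_ratio\tA3\tT3\tG3\tC3\n")
        for p in points:
            a = "" if p.a3_ratio is None else f"{p.a3_ratio:.4f}"
            g = "" if p.g3_ratio is None else f"{p.g3_ratio:.4f}"
            fh.write(f"{p.label}\t{a}\t{g}\t{p.a3}\t{p.t3}\t{p.g3}\t{p.c3}\n")
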