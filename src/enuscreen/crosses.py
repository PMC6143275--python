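"""Exact statistics for Mendelian validation crosses.

Each candidate suppressor gene is tested by crossing carriers of a
CRISPR-induced null allele on the F5 L/L background into the sensitized
F5 L/+ Tfpi +/- stock and scoring surviving F5 L/L Tfpi +/- ("rescue")
offspring for the modifier allele. This module computes expected offspring
genotype fractions under independent Mendelian segregation, Fisher exact
tests in which segregation of the modifier allele among non-rescue
littermates is assumed Mendelian, a companion exact binomial test, a
penetrance estimate with exact confidence interval, and the analytic /
Monte-Carlo power calculation for detecting suppressor genes by mutation
burden in a multi-gene screen.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CrossDesign",
    "PowerModel",
    "FisherResult",
    "PenetranceEstimate",
    "GenePowerResult",
    "expected_genotype_fractions",
    "rescue_fraction",
    "rescue_with_allele_fraction",
    "rescue_allele_fisher",
    "binomial_allele_test",
    "penetrance_estimate",
    "suppressor_gene_power",
    "load_cross_table",
    "bundled_cross_table",
]

LOCI = ("F5", "Tfpi", "mod")
_VALID_ALLELES = {
    "F5": {"L", "+"},
    "Tfpi": {"+", "-"},
    "mod": None,  # any symbol; "+" is wildtype
}


def _parse_genotype(locus: str, genotype: str) -> tuple[str, str]:
    parts = genotype.split("/")
    if len(parts) != 2 or not all(parts):
        raise ValueError(f"invalid {locus} genotype {genotype!r} (expected 'a/b')")
    allowed = _VALID_ALLELES[locus]
    if allowed is not None and not set(parts) <= allowed:
        raise ValueError(f"impossible {locus} genotype {genotype!r}")
    return parts[0], parts[1]


@dataclass(frozen=True)
class CrossDesign:
    """A validation cross: two parental genotypes and observed rescue counts.

    ``parent1``/``parent2`` map locus ("F5", "Tfpi", "mod") to a genotype
    string like "L/L", "+/-", "+/ins1". Loci absent from a parent default to
    wildtype. ``rescues_with``/``rescues_without`` count surviving rescue
    offspring with and without the modifier allele.
    """

    name: str
    parent1: dict[str, str]
    parent2: dict[str, str]
    n_total: int
    rescues_with: int
    rescues_without: int

    def __post_init__(self) -> None:
        for parent in (self.parent1, self.parent2):
            for locus, gt in parent.items():
                if locus not in LOCI:
                    raise ValueError(f"unknown locus {locus!r}")
                _parse_genotype(locus, gt)
        if self.rescues_with < 0 or self.rescues_without < 0:
            raise ValueError("rescue counts must be non-negative")
        if self.rescues_with + self.rescues_without > self.n_total:
            raise ValueError("observed rescues exceed total offspring")

    def genotype(self, parent: dict[str, str], locus: str) -> tuple[str, str]:
        default = {"F5": "+/+", "Tfpi": "+/+", "mod": "+/+"}[locus]
        return _parse_genotype(locus, parent.get(locus, default))

    @property
    def n_rescues(self) -> int:
        return self.rescues_with + self.rescues_without


def expected_genotype_fractions(cross: CrossDesign) -> dict[tuple[str, str, bool], float]:
    """Mendelian offspring fractions under independent segregation of the loci.

    Keys are (F5 genotype, Tfpi genotype, carries-modifier-allele); each
    parent transmits either allele of each locus with probability 1/2 and
    the loci segregate independently. Fractions sum to 1 over the partition.
    """
    fractions: dict[tuple[str, str, bool], float] = {}
    g1 = {locus: cross.genotype(cross.parent1, locus) for locus in LOCI}
    g2 = {locus: cross.genotype(cross.parent2, locus) for locus in LOCI}
    for i in range(2):
        for j in range(2):
            for k in range(2):
                for l in range(2):  # noqa: E741
                    for m in range(2):
                        for n in range(2):
                            f5 = "/".join(sorted((g1["F5"][i], g2["F5"][j])))
                            tfpi = "/".join(sorted((g1["Tfpi"][k], g2["Tfpi"][l])))
                            carrier = g1["mod"][m] != "+" or g2["mod"][n] != "+"
                            key = (f5, tfpi, carrier)
                            fractions[key] = fractions.get(key, 0.0) + 1 / 64
    return fractions


def rescue_fraction(cross: CrossDesign) -> float:
    """Fraction of offspring with the rescue genotype (F5 L/L, Tfpi +/-)."""
    return sum(
        f for (f5, tfpi, _), f in expected_genotype_fractions(cross).items()
        if f5 == "L/L" and set(tfpi.split("/")) == {"+", "-"}
    )


def rescue_with_allele_fraction(cross: CrossDesign) -> float:
    """Fraction of offspring that are rescue genotype AND modifier carriers."""
    return sum(
        f for (f5, tfpi, carrier), f in expected_genotype_fractions(cross).items()
        if f5 == "L/L" and set(tfpi.split("/")) == {"+", "-"} and carrier
    )


@dataclass
class FisherResult:
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    degenerate: bool = False


def rescue_allele_fisher(cross: CrossDesign, odd_to_carrier: bool = True) -> FisherResult:
    """Two-sided Fisher exact test of the modifier allele among rescues.

    Non-rescue littermates are not all individually genotyped; Mendelian
    segregation of the modifier allele is assumed for them, so the
    2x2 table [rescue, non-rescue] x [with allele, without] splits the
    non-rescues as evenly as possible (odd animal to the carrier column by
    default; the choice moves the p-value by < 0.005 on realistic counts).
    Two-sided p sums the probabilities of all tables at most as likely as
    the observed one. A zero rescue margin returns p = 1, flagged degenerate.
    """
    non_rescues = cross.n_total - cross.n_rescues
    half, odd = divmod(non_rescues, 2)
    nr_with = half + (odd if odd_to_carrier else 0)
    nr_without = non_rescues - nr_with
    table = ((cross.rescues_with, cross.rescues_without), (nr_with, nr_without))
    flat = [x for row in table for x in row]
    row_degenerate = cross.n_rescues == 0 or non_rescues == 0
    col_degenerate = (table[0][0] + table[1][0] == 0) or (table[0][1] + table[1][1] == 0)
    if row_degenerate or col_degenerate:
        return FisherResult(p_value=1.0, table=table, degenerate=True)
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return FisherResult(p_value=p, table=table)


def binomial_allele_test(rescues_with: int, rescues_without: int) -> float:
    """Exact two-sided binomial test of allele carriage among rescues at 1/2.

    Companion to the Fisher construction: under no rescue effect each
    surviving rescue carries the modifier allele with probability 1/2. The
    two-sided p sums the probabilities of all outcomes no more likely than
    the observed one (minimum-likelihood method).
    """
    n = rescues_with + rescues_without
    if n < 1:
        raise ValueError("need at least one genotyped rescue")
    return float(stats.binomtest(rescues_with, n, 0.5, alternative="two-sided").pvalue)


@dataclass
class PenetranceEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    expected_carriers: float
    observed: int


def penetrance_estimate(cross: CrossDesign, alpha: float = 0.05) -> PenetranceEstimate:
    """Penetrance of rescue among modifier-carrying F5 L/L Tfpi +/- offspring.

    Observed rescues-with-allele divided by the Mendelian expected count of
    rescue-genotype modifier carriers (n_total x expected fraction, e.g.
    n/8 for a het x het-modifier design), with a Clopper-Pearson interval
    computed on the rounded expected denominator.
    """
    frac = rescue_with_allele_fraction(cross)
    if frac <= 0:
        raise ValueError("cross design yields no rescue-with-allele offspring")
    expected = cross.n_total * frac
    estimate = cross.rescues_with / expected
    nobs = max(int(round(expected)), 1)
    k = min(cross.rescues_with, nobs)
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, nobs - k + 1))
    hi = 1.0 if k == nobs else float(stats.beta.ppf(1 - alpha / 2, k + 1, nobs - k))
    return PenetranceEstimate(
        estimate=float(estimate), ci_low=lo, ci_high=hi,
        expected_carriers=float(expected), observed=cross.rescues_with,
    )


@dataclass(frozen=True)
class PowerModel:
    """Screen-scale burden power model: n mice spread over G suppressor genes."""

    n_mice: int = 107
    n_suppressor_genes: int = 30
    threshold_k: int = 5

    def __post_init__(self) -> None:
        if self.n_mice < 1 or self.n_suppressor_genes < 1:
            raise ValueError("n_mice and n_suppressor_genes must be positive")
        if self.threshold_k < 0:
            raise ValueError("threshold_k must be >= 0")


@dataclass
class GenePowerResult:
    mean_per_gene: float
    expected_genes_at_k: float
    mode: str
    mc_se: float | None = None


def suppressor_gene_power(
    model: PowerModel,
    mode: str = "analytic",
    n_sim: int = 100_000,
    seed: int | None = None,
) -> GenePowerResult:
    """Expected number of suppressor genes hit >= k times in the screen.

    If every one of n mice carries its rescue mutation in one of G genes
    (uniform assignment), each gene averages n/G hits and the expected
    number of genes with at least k hits is G * P(Bin(n, 1/G) >= k)
    analytically; Monte-Carlo mode draws multinomial screens and agrees
    within simulation error.
    """
    n, G, k = model.n_mice, model.n_suppressor_genes, model.threshold_k
    mean = n / G
    if mode == "analytic":
        expected = float(G * stats.binom.sf(k - 1, n, 1.0 / G)) if k > 0 else float(G)
        return GenePowerResult(mean_per_gene=mean, expected_genes_at_k=expected, mode=mode)
    if mode == "montecarlo":
        rng = np.random.default_rng(seed)
        per_rep = np.zeros(n_sim)
        chunk = 10_000
        done = 0
        i = 0
        while done < n_sim:
            c = min(chunk, n_sim - done)
            draws = rng.multinomial(n, np.full(G, 1.0 / G), size=c)
            per_rep[done:done + c] = (draws >= k).sum(axis=1)
            done += c
            i += 1
        expected = float(per_rep.mean())
        se = float(per_rep.std(ddof=1) / np.sqrt(n_sim))
        return GenePowerResult(mean_per_gene=mean, expected_genes_at_k=expected,
                               mode=mode, mc_se=se)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# cross tables

_CROSS_COLUMNS = [
    "name", "parent1_f5", "parent1_tfpi", "parent1_mod",
    "parent2_f5", "parent2_tfpi", "parent2_mod",
    "n_total", "rescues_with", "rescues_without",
]


def load_cross_table(path: str | Path) -> list[CrossDesign]:
    """Read a cross TSV (one row per cross) into CrossDesign objects."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_CROSS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cross table missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples():
        out.append(
            CrossDesign(
                name=str(r.name_ if hasattr(r, "name_") else r.name),
                parent1={"F5": r.parent1_f5, "Tfpi": r.parent1_tfpi, "mod": r.parent1_mod},
                parent2={"F5": r.parent2_f5, "Tfpi": r.parent2_tfpi, "mod": r.parent2_mod},
                n_total=int(r.n_total),
                rescues_with=int(r.rescues_with),
                rescues_without=int(r.rescues_without),
            )
        )
    return out


def bundled_cross_table() -> list[CrossDesign]:
    """The packaged validation-cross count table (six CRISPR candidate-gene
    crosses plus the Plcb4 frameshift validation cross)."""
    ref = importlib.resources.files("enuscreen").joinpath("data/validation_crosses.tsv")
    with importlib.resources.as_file(ref) as path:
        return load_cross_table(path)
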