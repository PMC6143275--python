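"""Per-gene deleterious mutation burden test.

The null model throws the cohort's M deleterious candidate variants into
genes with probability proportional to each gene's coding-length share of
the full gene universe. Per-gene enrichment p-values come from Monte-Carlo
permutations of that multinomial null (with an exact binomial marginal as an
analytic cross-check), and Benjamini-Hochberg q-values are reported under
two universes: the genes actually carrying mutations, and the full annotated
gene set (the more stringent normalization).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from enuscreen.filtering import CandidateSet
from enuscreen.simulate import Annotation, CHROMOSOMES

__all__ = [
    "GeneCounts",
    "BurdenResult",
    "count_per_gene",
    "gene_probabilities",
    "permutation_pvalues",
    "binomial_oracle_pvalues",
    "bh_fdr",
    "burden_analysis",
    "burden_table",
    "manhattan_plot",
]

DEFAULT_N_PERM = 1_000_000
DEFAULT_FDR_LINES = (0.1, 0.25, 0.8)

_CHROM_INDEX = {c: i for i, c in enumerate(CHROMOSOMES)}


@dataclass
class GeneCounts:
    """Observed deleterious candidate counts per gene over a gene universe."""

    counts: dict[str, int]
    annotation: Annotation

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(self.annotation.by_id)
        if unknown:
            raise ValueError(f"counted genes absent from annotation: {sorted(unknown)[:5]}")
        if any(k < 0 for k in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def M(self) -> int:
        return int(sum(self.counts.values()))

    def k(self, gene_id: str) -> int:
        return int(self.counts.get(gene_id, 0))

    def observed_genes(self) -> list[str]:
        return [g for g, k in self.counts.items() if k > 0]


def count_per_gene(candidates: CandidateSet, annotation: Annotation) -> GeneCounts:
    """Sum deleterious candidates for every gene (absent genes count zero)."""
    counts: dict[str, int] = {}
    for c in candidates.candidates:
        if not c.deleterious:
            continue
        if c.gene_id is None or c.gene_id not in annotation.by_id:
            raise ValueError(
                f"deleterious candidate at {c.chrom}:{c.pos} has gene "
                f"{c.gene_id!r} not present in the annotation"
            )
        counts[c.gene_id] = counts.get(c.gene_id, 0) + 1
    return GeneCounts(counts=counts, annotation=annotation)


def gene_probabilities(annotation: Annotation) -> pd.Series:
    """p_g = cds_length_g / total cds length over the full universe."""
    return annotation.probabilities()


def permutation_pvalues(
    counts: GeneCounts,
    probs: pd.Series,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    chunk_size: int = 20_000,
) -> dict[str, float]:
    """Monte-Carlo upper-tail p-values under the length-weighted multinomial null.

    Each permutation throws all M variants into genes in one M-trial
    multinomial draw (distributionally identical to per-variant placement).
    Genes without observed mutations have p = 1 by construction, so each
    draw is taken over the observed genes plus a single lumped cell for the
    rest of the universe — marginally identical for every reported gene and
    conserving M exactly. The add-one Monte-Carlo correction
    p = (b + 1) / (N + 1) keeps every p-value positive.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if abs(float(probs.sum()) - 1.0) > 1e-9:
        raise ValueError("gene probabilities must sum to 1")
    M = counts.M
    out = {g: 1.0 for g in probs.index}
    if M == 0:
        warnings.warn("no deleterious candidates: all burden p-values are 1", stacklevel=2)
        return out
    obs = counts.observed_genes()
    if not obs:
        return out
    k = np.array([counts.k(g) for g in obs])
    p_obs = probs.loc[obs].to_numpy(dtype=float)
    p_rest = max(1.0 - p_obs.sum(), 0.0)
    pvec = np.append(p_obs, p_rest)
    pvec = pvec / pvec.sum()
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(obs), dtype=np.int64)
    remaining = n_perm
    while remaining > 0:
        c = min(chunk_size, remaining)
        draws = rng.multinomial(M, pvec, size=c)
        if not (draws.sum(axis=1) == M).all():  # conservation of M, every draw
            raise AssertionError("multinomial permutation failed to conserve M")
        exceed += (draws[:, : len(obs)] >= k).sum(axis=0)
        remaining -= c
    for g, b in zip(obs, exceed):
        out[g] = float((b + 1) / (n_perm + 1))
    return out


def binomial_oracle_pvalues(counts: GeneCounts, probs: pd.Series) -> dict[str, float]:
    """Exact marginal of the permutation null: P(Bin(M, p_g) >= k_g)."""
    M = counts.M
    out = {}
    for g in probs.index:
        k = counts.k(g)
        out[g] = 1.0 if k == 0 else float(stats.binom.sf(k - 1, M, float(probs.loc[g])))
    return out


def bh_fdr(pvalues: Mapping[str, float], m_universe: int) -> dict[str, float]:
    """Benjamini-Hochberg step-up q-values with an explicit universe multiplier.

    q_(i) = min_{j >= i} m * p_(j) / j over the p-values sorted ascending,
    so the universe (the BH multiplier m) can exceed the number of tested
    genes — e.g. normalizing the observed-gene p-values to the full
    annotated gene set. Capped at 1.
    """
    n = len(pvalues)
    if m_universe < n:
        raise ValueError("m_universe must be >= the number of p-values")
    if n == 0:
        return {}
    genes = sorted(pvalues, key=lambda g: (pvalues[g], g))
    p = np.array([pvalues[g] for g in genes], dtype=float)
    q_raw = m_universe * p / np.arange(1, n + 1)
    q = np.minimum.accumulate(q_raw[::-1])[::-1]
    q = np.minimum(q, 1.0)
    return {g: float(v) for g, v in zip(genes, q)}


@dataclass
class BurdenResult:
    counts: GeneCounts
    probs: pd.Series = field(repr=False)
    p_perm: dict[str, float] = field(repr=False)
    p_binom: dict[str, float] = field(repr=False)
    q_obs: dict[str, float] = field(repr=False)
    q_full: dict[str, float] = field(repr=False)
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0


def burden_analysis(
    candidates_or_counts: CandidateSet | GeneCounts,
    annotation: Annotation | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> BurdenResult:
    """Full burden pipeline: counts -> permutation + analytic p -> dual-universe q.

    The observed-universe BH normalizes over genes carrying at least one
    deleterious candidate; the full-universe BH uses every annotated gene as
    the multiplier (genes with k = 0 have p = 1 and are excluded from the
    ranked list but counted in the multiplier).
    """
    if isinstance(candidates_or_counts, GeneCounts):
        counts = candidates_or_counts
    else:
        if annotation is None:
            raise ValueError("annotation required when passing a CandidateSet")
        counts = count_per_gene(candidates_or_counts, annotation)
    ann = counts.annotation
    probs = gene_probabilities(ann)
    p_perm = permutation_pvalues(counts, probs, n_perm=n_perm, seed=seed)
    p_binom = binomial_oracle_pvalues(counts, probs)
    obs = counts.observed_genes()
    p_obs = {g: p_perm[g] for g in obs}
    q_obs = bh_fdr(p_obs, m_universe=len(obs)) if obs else {}
    q_full = bh_fdr(p_obs, m_universe=ann.n_genes) if obs else {}
    return BurdenResult(
        counts=counts, probs=probs, p_perm=p_perm, p_binom=p_binom,
        q_obs=q_obs, q_full=q_full, n_perm=n_perm, seed=seed,
    )


def burden_table(
    result: BurdenResult,
    fdr_lines: tuple[float, ...] = DEFAULT_FDR_LINES,
) -> pd.DataFrame:
    """Ranked per-gene report: one row per gene with >= 1 deleterious candidate.

    Genes are ordered by chromosome and position; columns carry the observed
    count, -log10 permutation p, the analytic p, both q-values, and a flag
    per requested FDR line (observed-universe q below the line).
    """
    rows = []
    for g in result.counts.observed_genes():
        gene = result.counts.annotation.by_id[g]
        rows.append(
            {
                "gene_id": g,
                "chrom": gene.chromosome,
                "pos": gene.start,
                "cds_length": gene.cds_length,
                "k": result.counts.k(g),
                "p_g": float(result.probs.loc[g]),
                "p_perm": result.p_perm[g],
                "p_binom": result.p_binom[g],
                "neg_log10_p": float(-np.log10(result.p_perm[g])),
                "q_obs": result.q_obs[g],
                "q_full": result.q_full[g],
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    for line in fdr_lines:
        df[f"fdr_{line:g}"] = df["q_obs"] < line
    df["_c"] = df["chrom"].map(_CHROM_INDEX)
    df = df.sort_values(["_c", "pos"]).drop(columns="_c").reset_index(drop=True)
    return df


def manhattan_plot(table: pd.DataFrame, path: str | Path, fdr_lines: tuple[float, ...] = DEFAULT_FDR_LINES) -> None:
    """Manhattan-style enrichment plot: genes by genomic order, -log10 p on y,
    dot size proportional to mutation count, dashed lines at the FDR cuts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if table.empty:
        raise ValueError("burden table is empty")
    df = table.reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(10, 4))
    colors = df["chrom"].map(lambda c: "C0" if _CHROM_INDEX.get(c, 0) % 2 == 0 else "C1")
    ax.scatter(df.index, df["neg_log10_p"], s=8 * df["k"], c=colors, alpha=0.7, lw=0)
    # draw each FDR line at the largest -log10 p whose q exceeds the cut
    for line, style in zip(fdr_lines, ("gray", "gray", "red")):
        sig = df[df["q_obs"] < line]
        if not sig.empty:
            y = -np.log10(df.loc[sig.index, "p_perm"]).min()
            ax.axhline(y, color=style, ls=":", lw=1, label=f"FDR {line:g}")
    ax.set_xlabel("genes in genomic order")
    ax.set_ylabel("-log10 permutation p")
    if ax.get_legend_handles_labels()[0]:
        ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
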