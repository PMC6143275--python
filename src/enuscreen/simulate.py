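"""Synthetic ENU suppressor-screen cohorts with ground truth.

Generates G1 cohorts whose variant calls carry the statistical structure of a
sensitized dominant ENU screen: per-genome Poisson exonic mutation load, the
ENU substitution spectrum (T/A->C/G and T/A->A/T dominated), a consequence
class mix, absence of paternally derived X-linked mutations in males, shared
artifact calls across unrelated mice, rare spontaneous de novo mutations, and
suppressor genes with incomplete penetrance plus a background phenocopy rate.
Every emitted variant is keyed in a truth table by origin (ENU, de novo, or
artifact), so downstream filtering and burden stages can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from enuscreen.linkage import Individual, Pedigree

__all__ = [
    "SUBSTITUTION_CLASSES",
    "CONSEQUENCE_CLASSES",
    "DELETERIOUS_CLASSES",
    "CHROMOSOMES",
    "TFPI_CHROMOSOME",
    "SpectrumConfig",
    "ScreenConfig",
    "GeneModel",
    "Annotation",
    "SimVariant",
    "SimMouse",
    "ScreenCohort",
    "build_annotation",
    "simulate_g1_mouse",
    "simulate_screen",
    "simulate_rescue_cohort",
    "simulate_sib_group",
    "simulate_rescue_pedigree",
    "write_cohort",
]

# Strand-collapsed single-nucleotide substitution classes.
SUBSTITUTION_CLASSES = (
    "T/A->C/G",
    "T/A->A/T",
    "T/A->G/C",
    "C/G->T/A",
    "C/G->A/T",
    "C/G->G/C",
)

CONSEQUENCE_CLASSES = (
    "nonsynonymous",
    "UTR",
    "synonymous",
    "splice",
    "stopgain",
    "stoploss",
    "INDEL",
)

# Classes counted as potentially deleterious in the burden analysis:
# missense, nonsense, splice-altering SNVs and out-of-frame INDELs.
# Stoploss and UTR/synonymous changes are excluded (see filtering module).
DELETERIOUS_CLASSES = frozenset({"nonsynonymous", "stopgain", "splice", "INDEL"})

CHROMOSOMES = tuple(str(i) for i in range(1, 20)) + ("X",)
_CHROM_INDEX = {c: i for i, c in enumerate(CHROMOSOMES)}
TFPI_CHROMOSOME = "2"  # Tfpi (and Plcb4) reside on mouse chromosome 2

# The three printed spectrum values (0.47, 0.24, 0.008) are fixed; the
# remaining 0.282 is split across the unreported classes (non-literature
# defaults, configurable).
DEFAULT_SUBSTITUTION_PROBS = {
    "T/A->C/G": 0.47,
    "T/A->A/T": 0.24,
    "T/A->G/C": 0.10,
    "C/G->T/A": 0.13,
    "C/G->A/T": 0.052,
    "C/G->G/C": 0.008,
}

# Nonsynonymous 47%, UTR 31%, synonymous 15%, remainder 7% split across
# splice/stopgain/stoploss/INDEL so the deleterious fraction lands near the
# observed ~51% (3,481 / 6,771).
DEFAULT_CLASS_PROBS = {
    "nonsynonymous": 0.47,
    "UTR": 0.31,
    "synonymous": 0.15,
    "splice": 0.02,
    "stopgain": 0.015,
    "stoploss": 0.005,
    "INDEL": 0.03,
}

# Representative ref/alt pairs for each strand-collapsed class (one per
# strand orientation; the simulator picks an orientation at random).
_SUBSTITUTION_ALLELES = {
    "T/A->C/G": (("T", "C"), ("A", "G")),
    "T/A->A/T": (("T", "A"), ("A", "T")),
    "T/A->G/C": (("T", "G"), ("A", "C")),
    "C/G->T/A": (("C", "T"), ("G", "A")),
    "C/G->A/T": (("C", "A"), ("G", "T")),
    "C/G->G/C": (("C", "G"), ("G", "C")),
}

_INDEL_ALLELES = (("A", "AT"), ("AT", "A"), ("C", "CAG"), ("CAG", "C"))

_PROB_TOL = 1e-9


def _validate_probs(probs: Mapping[str, float], keys: Sequence[str], name: str) -> None:
    if set(probs) != set(keys):
        raise ValueError(f"{name} must have exactly the keys {sorted(keys)}")
    vals = np.array([probs[k] for k in keys], dtype=float)
    if (vals < 0).any():
        raise ValueError(f"{name} probabilities must be non-negative")
    if abs(vals.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"{name} probabilities must sum to 1 (got {vals.sum():.12f})")


@dataclass(frozen=True)
class SpectrumConfig:
    """Mutation spectrum of the simulated screen.

    Parameters
    ----------
    substitution_probs : strand-collapsed SNV class -> probability.
    class_probs : consequence class -> probability (includes INDEL).
    exonic_rate_lambda : mean exonic ENU variants per G1 genome (Poisson).
    """

    substitution_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSTITUTION_PROBS)
    )
    class_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROBS)
    )
    exonic_rate_lambda: float = 65.0

    def __post_init__(self) -> None:
        _validate_probs(self.substitution_probs, SUBSTITUTION_CLASSES, "substitution_probs")
        _validate_probs(self.class_probs, CONSEQUENCE_CLASSES, "class_probs")
        if not self.exonic_rate_lambda > 0:
            raise ValueError("exonic_rate_lambda must be positive")

    @classmethod
    def default(cls) -> "SpectrumConfig":
        return cls()


@dataclass(frozen=True)
class ScreenConfig:
    """Cohort-level parameters of the simulated screen.

    Defaults mirror the study conditions: 107 G1 mice, ~33% suppressor
    penetrance, ~2% phenocopy (background survival) rate, spontaneous de novo
    rate 5.4e-9 per bp per generation, 77X mean exome coverage with 4% of
    calls under-covered, and an even sex ratio.
    """

    n_g1_mice: int = 107
    suppressor_genes: Mapping[str, float] = field(default_factory=dict)
    phenocopy_rate: float = 0.02
    de_novo_rate: float = 5.4e-9
    artifact_rate: float = 175.0
    depth_mean: float = 77.0
    low_coverage_fraction: float = 0.04
    female_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_g1_mice < 1:
            raise ValueError("n_g1_mice must be >= 1")
        for name in ("phenocopy_rate", "de_novo_rate", "low_coverage_fraction", "female_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for gene, pen in self.suppressor_genes.items():
            if not 0.0 <= pen <= 1.0:
                raise ValueError(f"penetrance for {gene} must lie in [0, 1]")
        if self.artifact_rate < 0 or self.depth_mean <= 0:
            raise ValueError("artifact_rate must be >= 0 and depth_mean > 0")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its coding length and genomic interval (0-based half-open)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds_length: int

    def __post_init__(self) -> None:
        if self.cds_length < 1:
            raise ValueError("cds_length must be >= 1")
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")
        if self.chromosome not in _CHROM_INDEX:
            raise ValueError(f"unknown chromosome {self.chromosome!r}")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


class Annotation:
    """Gene annotation table with interval lookup and length-share probabilities."""

    COLUMNS = ("gene_id", "chrom", "start", "end", "strand", "cds_length")

    def __init__(self, genes: Sequence[GeneModel]):
        if not genes:
            raise ValueError("annotation must contain at least one gene")
        self.genes = tuple(genes)
        self.by_id = {g.gene_id: g for g in self.genes}
        if len(self.by_id) != len(self.genes):
            raise ValueError("duplicate gene ids in annotation")
        self._gene_ids = np.array([g.gene_id for g in self.genes])
        self._cds = np.array([g.cds_length for g in self.genes], dtype=float)
        self._chroms = np.array([g.chromosome for g in self.genes])
        # per-chromosome sorted interval arrays for point lookup
        self._lookup: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom in CHROMOSOMES:
            mask = self._chroms == chrom
            if not mask.any():
                continue
            starts = np.array([g.start for g, m in zip(self.genes, mask) if m])
            ends = np.array([g.end for g, m in zip(self.genes, mask) if m])
            ids = self._gene_ids[mask]
            order = np.argsort(starts)
            self._lookup[chrom] = (starts[order], ends[order], ids[order])

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> np.ndarray:
        return self._gene_ids

    @property
    def total_cds_length(self) -> float:
        return float(self._cds.sum())

    def probabilities(self, chromosomes: Iterable[str] | None = None) -> pd.Series:
        """Per-gene placement probability proportional to coding length.

        With ``chromosomes`` given, the universe is restricted to those
        contigs and renormalized (used for male mice, whose single maternal X
        carries no paternally induced ENU variants).
        """
        if chromosomes is None:
            w = self._cds
            ids = self._gene_ids
        else:
            keep = np.isin(self._chroms, list(chromosomes))
            if not keep.any():
                raise ValueError("no genes on requested chromosomes")
            w = self._cds[keep]
            ids = self._gene_ids[keep]
        total = w.sum()
        if total <= 0:
            raise ValueError("total CDS length must be positive")
        return pd.Series(w / total, index=ids)

    def locate(self, chrom: str, pos: int) -> str | None:
        """Gene id whose interval contains 1-based position ``pos``, or None."""
        entry = self._lookup.get(chrom)
        if entry is None:
            return None
        starts, ends, ids = entry
        i = int(np.searchsorted(starts, pos - 1, side="right")) - 1
        if i >= 0 and starts[i] <= pos - 1 < ends[i]:
            return str(ids[i])
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chromosome for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "cds_length": [g.cds_length for g in self.genes],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Annotation":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        missing = set(cls.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"annotation file missing columns: {sorted(missing)}")
        genes = [
            GeneModel(
                gene_id=str(r.gene_id),
                chromosome=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
                cds_length=int(r.cds_length),
            )
            for r in df.itertuples()
        ]
        return cls(genes)


@dataclass
class SimVariant:
    """A simulated variant call, possibly shared by several carriers."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene_id: str | None
    csq_class: str
    sub_class: str | None  # None for INDELs and other non-SNV calls
    origin: str  # ENU | de_novo | artifact
    carriers: tuple[str, ...]
    depths: dict[str, int]
    zygosity: str = "het"
    phase_with_tfpi: bool | None = None

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def deleterious(self) -> bool:
        return self.csq_class in DELETERIOUS_CLASSES


@dataclass
class SimMouse:
    mouse_id: str
    sex: str  # "F" or "M"
    generation: str = "G1"
    sire: str = "G0"
    dam: str = "G0_dam"
    f5: str = "L/L"
    tfpi: str = "+/-"
    rescue_status: bool = False
    sibling_group: str | None = None
    variants: list[SimVariant] = field(default_factory=list)


@dataclass
class ScreenCohort:
    """A simulated (or assembled) screen cohort plus cohort-level artifact calls."""

    mice: list[SimMouse]
    artifacts: list[SimVariant]
    annotation: Annotation
    config: ScreenConfig
    spectrum: SpectrumConfig

    @property
    def mouse_ids(self) -> list[str]:
        return [m.mouse_id for m in self.mice]

    def all_variants(self) -> list[SimVariant]:
        """All variant calls merged across mice by (chrom, pos, ref, alt).

        Variants generated independently in several mice at the same locus
        (e.g. stem-cell-shared sibling variants) merge into one multi-carrier
        call, exactly as a joint caller would report them.
        """
        merged: dict[str, SimVariant] = {}
        for mouse in self.mice:
            for v in mouse.variants:
                if v.key in merged:
                    prev = merged[v.key]
                    prev.carriers = tuple(sorted(set(prev.carriers) | set(v.carriers)))
                    prev.depths.update(v.depths)
                else:
                    merged[v.key] = replace(
                        v, carriers=tuple(v.carriers), depths=dict(v.depths)
                    )
        for v in self.artifacts:
            merged[v.key] = replace(v, carriers=tuple(v.carriers), depths=dict(v.depths))
        return sorted(
            merged.values(), key=lambda v: (_CHROM_INDEX[v.chrom], v.pos, v.ref, v.alt)
        )

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for v in self.all_variants():
            rows.append(
                {
                    "key": v.key,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "origin": v.origin,
                    "gene_id": v.gene_id if v.gene_id is not None else ".",
                    "csq_class": v.csq_class,
                    "sub_class": v.sub_class if v.sub_class is not None else ".",
                    "deleterious": int(v.deleterious),
                    "n_carriers": len(v.carriers),
                    "carriers": ",".join(v.carriers),
                }
            )
        return pd.DataFrame(rows)

    def pedigree_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": ["SCREEN"] * len(self.mice),
                "id": [m.mouse_id for m in self.mice],
                "sire": [m.sire for m in self.mice],
                "dam": [m.dam for m in self.mice],
                "sex": [m.sex for m in self.mice],
                "rescue": [int(m.rescue_status) for m in self.mice],
            }
        )


def build_annotation(
    n_genes: int,
    length_law: Mapping[str, float] | None = None,
    seed: int = 0,
    giant_gene: bool = True,
) -> Annotation:
    """Draw a synthetic gene annotation.

    CDS lengths follow a log-normal law (default median ~1.2 kb, matching the
    scale of mammalian coding genes, ~35 Mb total across 20,586 genes); one
    gene may be flagged as a Ttn-like giant (~1e5 bp CDS) so multi-hit
    behaviour of very long genes is represented. Genes are laid out
    non-overlapping along 19 autosomes plus X (X receiving ~4% of genes).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    law = {"dist": "lognormal", "mu": 7.1, "sigma": 0.8}
    if length_law:
        law.update(length_law)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA11]))
    if law["dist"] != "lognormal":
        raise ValueError(f"unsupported length law {law['dist']!r}")
    lengths = np.maximum(
        90, np.round(rng.lognormal(law["mu"], law["sigma"], size=n_genes))
    ).astype(int)
    if giant_gene and n_genes > 1:
        lengths[0] = 100_000  # Ttn-like outlier
    weights = np.full(len(CHROMOSOMES), 0.96 / 19)
    weights[-1] = 0.04  # X
    chroms = rng.choice(len(CHROMOSOMES), size=n_genes, p=weights)
    order = rng.permutation(n_genes)  # shuffle so the giant gene is not always first
    genes: list[GeneModel] = []
    cursor = {c: 10_000 for c in CHROMOSOMES}
    width = len(str(n_genes))
    for rank, i in enumerate(order):
        chrom = CHROMOSOMES[chroms[i]]
        start = cursor[chrom]
        end = start + int(lengths[i])
        cursor[chrom] = end + 10_000
        genes.append(
            GeneModel(
                gene_id=f"g{i + 1:0{width}d}",
                chromosome=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                cds_length=int(lengths[i]),
            )
        )
    genes.sort(key=lambda g: g.gene_id)
    return Annotation(genes)


def _draw_depth(rng: np.random.Generator, cfg: ScreenConfig) -> int:
    if rng.random() < cfg.low_coverage_fraction:
        return int(rng.integers(0, 6))
    return int(rng.poisson(cfg.depth_mean))


def _draw_position(
    rng: np.random.Generator, gene: GeneModel, occupied: set[tuple[str, int]]
) -> int:
    # rejection-sample a globally unused position so independently simulated
    # single-carrier variants never collide into spurious shared calls
    for _ in range(1000):
        pos = int(gene.start + 1 + rng.integers(gene.end - gene.start))
        if (gene.chromosome, pos) not in occupied:
            occupied.add((gene.chromosome, pos))
            return pos
    raise RuntimeError(f"could not place variant in saturated gene {gene.gene_id}")


def _alleles_for(rng: np.random.Generator, csq: str, sub: str | None) -> tuple[str, str]:
    if csq == "INDEL":
        return _INDEL_ALLELES[int(rng.integers(len(_INDEL_ALLELES)))]
    assert sub is not None
    pair = _SUBSTITUTION_ALLELES[sub]
    return pair[int(rng.integers(2))]


def _draw_variant(
    rng: np.random.Generator,
    cfg: ScreenConfig,
    spectrum: SpectrumConfig,
    gene: GeneModel,
    carrier: str,
    origin: str,
    occupied: set[tuple[str, int]],
    sub_probs: np.ndarray | None = None,
) -> SimVariant:
    csq = str(rng.choice(CONSEQUENCE_CLASSES, p=[spectrum.class_probs[c] for c in CONSEQUENCE_CLASSES]))
    if csq == "INDEL":
        sub = None
    elif sub_probs is None:
        sub = str(
            rng.choice(
                SUBSTITUTION_CLASSES,
                p=[spectrum.substitution_probs[c] for c in SUBSTITUTION_CLASSES],
            )
        )
    else:
        sub = str(rng.choice(SUBSTITUTION_CLASSES, p=sub_probs))
    ref, alt = _alleles_for(rng, csq, sub)
    pos = _draw_position(rng, gene, occupied)
    phase = None
    if origin == "de_novo" and gene.chromosome == TFPI_CHROMOSOME:
        phase = bool(rng.integers(2))
    return SimVariant(
        chrom=gene.chromosome,
        pos=pos,
        ref=ref,
        alt=alt,
        gene_id=gene.gene_id,
        csq_class=csq,
        sub_class=sub,
        origin=origin,
        carriers=(carrier,),
        depths={carrier: _draw_depth(rng, cfg)},
        phase_with_tfpi=phase,
    )


def simulate_g1_mouse(
    cfg: ScreenConfig,
    spectrum: SpectrumConfig,
    annotation: Annotation,
    sex: str,
    rng: np.random.Generator,
    mouse_id: str = "G1-1",
    occupied: set[tuple[str, int]] | None = None,
) -> SimMouse:
    """Simulate one G1 mouse: Poisson(lambda) ENU variants plus de novo calls.

    ENU variants land in genes with probability proportional to coding-length
    share. Males inherit their single X from the unmutagenized dam, so their
    ENU variants are restricted to autosomes.
    """
    if annotation.n_genes == 0:
        raise ValueError("annotation must be non-empty")
    if sex not in ("F", "M"):
        raise ValueError("sex must be 'F' or 'M'")
    if occupied is None:
        occupied = set()
    if sex == "M":
        try:
            probs = annotation.probabilities(chromosomes=[c for c in CHROMOSOMES if c != "X"])
        except ValueError:  # all genes on X: males carry nothing
            probs = None
    else:
        probs = annotation.probabilities()
    mouse = SimMouse(mouse_id=mouse_id, sex=sex)
    n_enu = int(rng.poisson(spectrum.exonic_rate_lambda)) if probs is not None else 0
    if n_enu:
        gene_ids = rng.choice(probs.index.to_numpy(), size=n_enu, p=probs.to_numpy())
        for gid in gene_ids:
            gene = annotation.by_id[str(gid)]
            mouse.variants.append(
                _draw_variant(rng, cfg, spectrum, gene, mouse_id, "ENU", occupied)
            )
    # spontaneous de novo mutations from either unmutagenized parent, placed
    # uniformly over annotated intervals; substitution class uniform (the de
    # novo spectrum is not ENU-skewed)
    n_dn = int(rng.poisson(cfg.de_novo_rate * annotation.total_cds_length))
    if n_dn:
        all_probs = annotation.probabilities()
        uniform_sub = np.full(len(SUBSTITUTION_CLASSES), 1 / len(SUBSTITUTION_CLASSES))
        gene_ids = rng.choice(all_probs.index.to_numpy(), size=n_dn, p=all_probs.to_numpy())
        for gid in gene_ids:
            gene = annotation.by_id[str(gid)]
            mouse.variants.append(
                _draw_variant(
                    rng, cfg, spectrum, gene, mouse_id, "de_novo", occupied,
                    sub_probs=uniform_sub,
                )
            )
    return mouse


def _assign_rescue(
    mouse: SimMouse, cfg: ScreenConfig, rng: np.random.Generator
) -> None:
    suppressed = False
    for v in mouse.variants:
        if v.gene_id in cfg.suppressor_genes and v.deleterious:
            if rng.random() < cfg.suppressor_genes[v.gene_id]:
                suppressed = True
    phenocopy = rng.random() < cfg.phenocopy_rate
    mouse.rescue_status = bool(suppressed or phenocopy)


def simulate_screen(
    cfg: ScreenConfig,
    spectrum: SpectrumConfig | None = None,
    annotation: Annotation | None = None,
) -> ScreenCohort:
    """Simulate a full G1 screen cohort with ground-truth variant origins.

    A mouse is a rescue iff it carries a deleterious variant in a suppressor
    gene and that gene's penetrance Bernoulli succeeds, or a phenocopy
    Bernoulli (background survival) succeeds. Artifact calls shared by >= 2
    mice are injected at ``cfg.artifact_rate`` per cohort.

    Each mouse consumes its own RNG substream spawned from the master seed, so
    enlarging the cohort leaves earlier mice unchanged.
    """
    spectrum = spectrum or SpectrumConfig.default()
    if annotation is None:
        annotation = build_annotation(2_000, seed=cfg.seed)
    unknown = set(cfg.suppressor_genes) - set(annotation.by_id)
    if unknown:
        raise ValueError(f"suppressor genes absent from annotation: {sorted(unknown)}")
    master = np.random.SeedSequence(cfg.seed)
    mice_ss, artifact_ss = master.spawn(2)
    occupied: set[tuple[str, int]] = set()
    mice = []
    width = len(str(cfg.n_g1_mice))
    for i, child in enumerate(mice_ss.spawn(cfg.n_g1_mice)):
        rng = np.random.default_rng(child)
        sex = "F" if rng.random() < cfg.female_fraction else "M"
        mouse = simulate_g1_mouse(
            cfg, spectrum, annotation, sex, rng,
            mouse_id=f"G1-{i + 1:0{width}d}", occupied=occupied,
        )
        _assign_rescue(mouse, cfg, rng)
        mice.append(mouse)
    artifacts = _simulate_artifacts(
        cfg, spectrum, annotation, [m.mouse_id for m in mice],
        np.random.default_rng(artifact_ss), occupied,
    )
    return ScreenCohort(mice=mice, artifacts=artifacts, annotation=annotation,
                        config=cfg, spectrum=spectrum)


def simulate_rescue_cohort(
    cfg: ScreenConfig,
    spectrum: SpectrumConfig | None = None,
    annotation: Annotation | None = None,
    max_g1: int | None = None,
) -> tuple[ScreenCohort, int]:
    """Simulate G1 mice until ``cfg.n_g1_mice`` rescues are collected.

    Emulates the ascertainment of the sequenced cohort: only mice surviving
    with the rescue phenotype are kept (true suppressor carriers plus
    phenocopies), so suppressor genes are enriched in the returned cohort in
    proportion to penetrance and the phenocopy rate. Returns the cohort and
    the total number of G1 mice screened. ``max_g1`` bounds the search
    (default 1,000 times the target).
    """
    spectrum = spectrum or SpectrumConfig.default()
    if annotation is None:
        annotation = build_annotation(2_000, seed=cfg.seed)
    unknown = set(cfg.suppressor_genes) - set(annotation.by_id)
    if unknown:
        raise ValueError(f"suppressor genes absent from annotation: {sorted(unknown)}")
    if max_g1 is None:
        max_g1 = 1_000 * cfg.n_g1_mice
    master = np.random.SeedSequence(cfg.seed)
    mice_ss, artifact_ss = master.spawn(2)
    occupied: set[tuple[str, int]] = set()
    rescues: list[SimMouse] = []
    screened = 0
    width = len(str(cfg.n_g1_mice))
    while len(rescues) < cfg.n_g1_mice:
        if screened >= max_g1:
            raise RuntimeError(
                f"screened {screened} G1 mice but found only {len(rescues)} rescues; "
                f"raise max_g1 or the rescue rate"
            )
        (child,) = mice_ss.spawn(1)  # lazy spawn: deterministic, unbounded
        rng = np.random.default_rng(child)
        sex = "F" if rng.random() < cfg.female_fraction else "M"
        mouse = simulate_g1_mouse(cfg, spectrum, annotation, sex, rng,
                                  mouse_id=f"G1-{len(rescues) + 1:0{width}d}",
                                  occupied=occupied)
        screened += 1
        _assign_rescue(mouse, cfg, rng)
        if mouse.rescue_status:
            rescues.append(mouse)
        else:
            # return the unselected mouse's positions to the pool
            for v in mouse.variants:
                occupied.discard((v.chrom, v.pos))
    artifacts = _simulate_artifacts(
        cfg, spectrum, annotation, [m.mouse_id for m in rescues],
        np.random.default_rng(artifact_ss), occupied,
    )
    cohort = ScreenCohort(mice=rescues, artifacts=artifacts, annotation=annotation,
                          config=cfg, spectrum=spectrum)
    return cohort, screened


def _simulate_artifacts(
    cfg: ScreenConfig,
    spectrum: SpectrumConfig,
    annotation: Annotation,
    mouse_ids: Sequence[str],
    rng: np.random.Generator,
    occupied: set[tuple[str, int]],
) -> list[SimVariant]:
    if cfg.artifact_rate == 0 or len(mouse_ids) < 2:
        return []
    n_art = int(rng.poisson(cfg.artifact_rate))
    spans = {c: 10_000 for c in CHROMOSOMES}
    for g in annotation.genes:
        spans[g.chromosome] = max(spans[g.chromosome], g.end + 50_000)
    chrom_list = list(CHROMOSOMES)
    out: list[SimVariant] = []
    sub_p = [spectrum.substitution_probs[c] for c in SUBSTITUTION_CLASSES]
    for _ in range(n_art):
        chrom = chrom_list[int(rng.integers(len(chrom_list)))]
        pos = int(rng.integers(1, spans[chrom] + 1))
        while (chrom, pos) in occupied:
            pos = int(rng.integers(1, spans[chrom] + 1))
        occupied.add((chrom, pos))
        gene_id = annotation.locate(chrom, pos)
        if gene_id is None:
            csq = "intergenic"
        else:
            csq = str(rng.choice(CONSEQUENCE_CLASSES,
                                 p=[spectrum.class_probs[c] for c in CONSEQUENCE_CLASSES]))
        sub = None if csq == "INDEL" else str(rng.choice(SUBSTITUTION_CLASSES, p=sub_p))
        ref, alt = _alleles_for(rng, "INDEL" if csq == "INDEL" else "SNV", sub)
        k = min(len(mouse_ids), 2 + int(rng.poisson(1.0)))
        carriers = tuple(sorted(rng.choice(mouse_ids, size=k, replace=False)))
        out.append(
            SimVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt, gene_id=gene_id,
                csq_class=csq, sub_class=sub, origin="artifact",
                carriers=carriers,
                depths={c: _draw_depth(rng, cfg) for c in carriers},
            )
        )
    return out


def simulate_sib_group(
    cfg: ScreenConfig,
    spectrum: SpectrumConfig,
    annotation: Annotation,
    n_sibs: int = 2,
    same_stem_cell: bool = False,
    seed: int = 0,
    group_id: str = "sib1",
) -> list[SimMouse]:
    """Simulate a G1 sibship from one ENU-treated sire.

    With ``same_stem_cell`` the sibs descend from a single mutagenized
    spermatogonial stem cell: a shared mutation pool of expected size
    2*lambda is drawn once and each sib inherits each pool variant with
    probability 1/2, so any two sibs share ~50% of their variant lists.
    Otherwise each sib receives an independent private mutation set
    (different stem cells), sharing ~0%.
    """
    if n_sibs < 2:
        raise ValueError("a sibship needs >= 2 members")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51B]))
    occupied: set[tuple[str, int]] = set()
    ids = [f"{group_id}-{i + 1}" for i in range(n_sibs)]
    mice = []
    if same_stem_cell:
        pool_size = int(rng.poisson(2 * spectrum.exonic_rate_lambda))
        probs = annotation.probabilities()
        pool = []
        for gid in rng.choice(probs.index.to_numpy(), size=pool_size, p=probs.to_numpy()):
            pool.append(
                _draw_variant(rng, cfg, spectrum, annotation.by_id[str(gid)],
                              "pool", "ENU", occupied)
            )
        for mid in ids:
            mouse = SimMouse(mouse_id=mid, sex="F" if rng.random() < 0.5 else "M",
                             sibling_group=group_id)
            for v in pool:
                if rng.random() < 0.5:
                    mouse.variants.append(
                        replace(v, carriers=(mid,), depths={mid: _draw_depth(rng, cfg)})
                    )
            mice.append(mouse)
    else:
        for mid in ids:
            sex = "F" if rng.random() < 0.5 else "M"
            mouse = simulate_g1_mouse(cfg, spectrum, annotation, sex, rng,
                                      mouse_id=mid, occupied=occupied)
            mouse.sibling_group = group_id
            mice.append(mouse)
    return mice


def simulate_rescue_pedigree(
    founder: SimMouse | str,
    n_offspring_per_generation: int,
    theta_marker_trait: float,
    generations: int = 2,
    rng: np.random.Generator | int | None = None,
    penetrance: float = 1.0,
    phenocopy_rate: float = 0.0,
) -> Pedigree:
    """Expand a rescue pedigree from a doubly heterozygous founder.

    The founder carries the Tfpi-null-linked trait allele and a marker (e.g.
    a candidate suppressor variant) in cis. Each breeding rescue is crossed to
    an external F5 L/L mate; offspring inherit the (trait, marker) haplotype
    with recombination probability ``theta_marker_trait``. Offspring are
    rescues iff they carry the trait allele and either the marker-suppressor
    plus a penetrance success, or a phenocopy success. Rescue offspring
    carrying both alleles breed the next generation.
    """
    theta = float(theta_marker_trait)
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(0 if rng is None else int(rng))
    founder_id = founder if isinstance(founder, str) else founder.mouse_id
    founder_sex = "F" if not isinstance(founder, str) and founder.sex == "F" else "M"
    ped = Pedigree()
    ped.add(
        Individual(iid=founder_id, sire=None, dam=None, sex=founder_sex,
                   generation=1, rescue=True, has_trait=True, has_marker=True,
                   transmitting_parent=None)
    )
    ped.phase[founder_id] = True  # cis
    breeders = [founder_id]
    counter = 0
    # gamete law for a cis doubly-het parent:
    #   (trait, marker) w.p. (1-theta)/2 ; (+, +) w.p. (1-theta)/2
    #   (trait, +) w.p. theta/2          ; (+, marker) w.p. theta/2
    for gen in range(2, generations + 2):
        next_breeders = []
        for parent in breeders:
            psex = ped.individuals[parent].sex
            for _ in range(n_offspring_per_generation):
                counter += 1
                iid = f"{founder_id}.{gen}.{counter}"
                recomb = rng.random() < theta
                trait = rng.random() < 0.5
                marker = trait != recomb
                rescue = trait and (
                    (marker and rng.random() < penetrance)
                    or rng.random() < phenocopy_rate
                )
                child = Individual(
                    iid=iid,
                    sire=parent if psex == "M" else "F5LL-ext",
                    dam=parent if psex == "F" else "F5LL-ext",
                    sex="F" if rng.random() < 0.5 else "M",
                    generation=gen,
                    rescue=bool(rescue),
                    has_trait=bool(trait),
                    has_marker=bool(marker),
                    transmitting_parent=parent,
                )
                ped.add(child)
                if rescue and trait and marker:
                    ped.phase[iid] = True  # both alleles arrived on one gamete
                    next_breeders.append(iid)
        breeders = next_breeders
        if not breeders:
            break
    return ped


# ---------------------------------------------------------------------------
# serialization


def write_cohort(
    cohort: ScreenCohort,
    vcf_path: str | Path,
    truth_path: str | Path,
    annotation_path: str | Path,
    ped_path: str | Path | None = None,
) -> dict[str, str]:
    """Write a cohort as multi-sample VCF v4.2 plus truth/annotation/PED TSVs.

    The VCF carries one sample column per mouse with per-sample GT and DP;
    carriers are heterozygous (0/1), non-carriers homozygous reference with
    the nominal mean coverage. INFO fields GENE/CSQ/SUB hold the annotation
    join (omitted for intergenic calls). Round-trips losslessly through
    :func:`enuscreen.filtering.load_variants`.
    """
    if not cohort.mice:
        raise ValueError("cohort must contain at least one mouse")
    vcf_path, truth_path, annotation_path = Path(vcf_path), Path(truth_path), Path(annotation_path)
    samples = cohort.mouse_ids
    ref_dp = int(round(cohort.config.depth_mean))
    lines = [
        "##fileformat=VCFv4.2",
        "##source=enuscreen",
    ]
    for c in CHROMOSOMES:
        lines.append(f"##contig=<ID={c}>")
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id from annotation join">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">',
        '##INFO=<ID=SUB,Number=1,Type=String,Description="Strand-collapsed substitution class">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for v in cohort.all_variants():
        info = []
        if v.gene_id is not None:
            info.append(f"GENE={v.gene_id}")
        if v.csq_class != "intergenic":
            info.append(f"CSQ={v.csq_class}")
        if v.sub_class is not None:
            info.append(f"SUB={v.sub_class.replace('->', '_')}")
        carrier_set = set(v.carriers)
        fields = [
            v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS",
            ";".join(info) if info else ".", "GT:DP",
        ]
        for s in samples:
            if s in carrier_set:
                fields.append(f"0/1:{v.depths[s]}")
            else:
                fields.append(f"0/0:{ref_dp}")
        lines.append("\t".join(fields))
    vcf_path.write_text("\n".join(lines) + "\n")
    cohort.truth_table().to_csv(truth_path, sep="\t", index=False)
    cohort.annotation.to_tsv(annotation_path)
    paths = {"vcf": str(vcf_path), "truth": str(truth_path), "annotation": str(annotation_path)}
    if ped_path is not None:
        cohort.pedigree_frame().to_csv(ped_path, sep="\t", index=False)
        paths["ped"] = str(ped_path)
    return paths
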