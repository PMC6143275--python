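"""ENU candidate-variant filtering and cohort summary statistics.

The candidate filter re-creates the screen's in-house pipeline: variants
present in more than one rescue mouse are declared non-ENU (strain or calling
artifacts) and removed, and the survivors must be heterozygous singleton
calls with carrier depth of at least 6 reads. The module also provides the
cohort spectrum summaries (consequence classes, substitution classes,
per-chromosome sex asymmetry, per-mouse loads), sibling shared-variant
analysis, and the common-stem-cell origin test for G1 sibships.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from enuscreen.simulate import Annotation, CHROMOSOMES

__all__ = [
    "VariantRecord",
    "CandidateVariant",
    "CandidateSet",
    "SpectrumSummary",
    "SibGroup",
    "VcfParseError",
    "SampleIdError",
    "load_variants",
    "filter_enu_candidates",
    "classify_deleterious",
    "spectrum_summary",
    "sib_shared_variants",
    "stemcell_origin_test",
]

# Deleterious per the burden definition: missense, nonsense, splice-altering
# SNVs, out-of-frame INDELs. Stoploss (and in-frame events) excluded by
# default; synonyms cover external annotation vocabularies.
_DELETERIOUS = {"nonsynonymous", "missense", "stopgain", "nonsense", "splice", "INDEL", "frameshift"}
_NON_DELETERIOUS = {"UTR", "synonymous", "stoploss", "intergenic", "other"}

REMOVAL_REASONS = ("shared", "not_het", "low_depth")


class VcfParseError(ValueError):
    pass


class SampleIdError(KeyError):
    pass


@dataclass
class VariantRecord:
    """One multi-sample variant call with the annotation join applied."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, str]  # sample -> hom_ref | het | hom_alt | missing
    depths: dict[str, int]
    gene_id: str | None = None
    csq_class: str | None = None
    sub_class: str | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def het_carriers(self) -> list[str]:
        return [s for s, g in self.genotypes.items() if g == "het"]

    def called_carriers(self) -> list[str]:
        """Samples with a called non-reference genotype (missing != presence)."""
        return [s for s, g in self.genotypes.items() if g in ("het", "hom_alt")]


@dataclass(frozen=True)
class CandidateVariant:
    """A putative ENU mutation: unique heterozygous call with adequate depth."""

    mouse_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    csq_class: str
    sub_class: str | None
    depth: int
    deleterious: bool


@dataclass
class CandidateSet:
    candidates: list[CandidateVariant]
    removed: list[tuple[VariantRecord, str]]
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.candidates)

    def removal_counts(self) -> dict[str, int]:
        out = {r: 0 for r in REMOVAL_REASONS}
        for _, reason in self.removed:
            out[reason] += 1
        return out

    def per_mouse_counts(self, mouse_ids: Sequence[str] | None = None) -> pd.Series:
        counts: dict[str, int] = {}
        for c in self.candidates:
            counts[c.mouse_id] = counts.get(c.mouse_id, 0) + 1
        idx = list(mouse_ids) if mouse_ids is not None else sorted(counts)
        return pd.Series([counts.get(m, 0) for m in idx], index=idx, dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mouse_id": [c.mouse_id for c in self.candidates],
                "chrom": [c.chrom for c in self.candidates],
                "pos": [c.pos for c in self.candidates],
                "ref": [c.ref for c in self.candidates],
                "alt": [c.alt for c in self.candidates],
                "gene_id": [c.gene_id or "." for c in self.candidates],
                "csq_class": [c.csq_class for c in self.candidates],
                "sub_class": [c.sub_class or "." for c in self.candidates],
                "depth": [c.depth for c in self.candidates],
                "deleterious": [int(c.deleterious) for c in self.candidates],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_records(self) -> list[VariantRecord]:
        """Re-express retained candidates as single-sample records (the filter
        is idempotent over this view)."""
        return [
            VariantRecord(
                chrom=c.chrom, pos=c.pos, ref=c.ref, alt=c.alt,
                genotypes={c.mouse_id: "het"}, depths={c.mouse_id: c.depth},
                gene_id=c.gene_id, csq_class=c.csq_class, sub_class=c.sub_class,
            )
            for c in self.candidates
        ]


def classify_deleterious(candidate, include_stoploss: bool = False) -> bool:
    """True iff the consequence class is potentially protein-damaging.

    The operative list is missense/nonsynonymous, nonsense/stopgain,
    splice-altering, and out-of-frame INDEL/frameshift. Stoploss is treated
    as non-deleterious by default (toggleable, since usage in the field is
    inconsistent).
    """
    csq = candidate if isinstance(candidate, str) else candidate.csq_class
    if csq in _DELETERIOUS:
        return True
    if csq == "stoploss":
        return include_stoploss
    if csq in _NON_DELETERIOUS:
        return False
    raise ValueError(f"unknown consequence class {csq!r}")


def load_variants(
    vcf_path: str | Path,
    annotation_path: str | Path | None = None,
    annotation: Annotation | None = None,
    expected_samples: Sequence[str] | None = None,
) -> list[VariantRecord]:
    """Read a multi-sample VCF (v4.2, GT/DP) into annotated records.

    Positions stay 1-based as in the VCF. Gene and consequence class come
    from the INFO fields when present, otherwise from a position-in-interval
    join against the annotation (class ``intergenic`` when no gene overlaps).
    Multi-allelic rows are rejected.
    """
    from cyvcf2 import VCF

    if annotation is None and annotation_path is not None:
        annotation = Annotation.from_tsv(annotation_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if expected_samples is not None:
        unknown = set(samples) ^ set(expected_samples)
        if unknown:
            raise SampleIdError(f"sample ids do not match cohort: {sorted(unknown)}")
    records: list[VariantRecord] = []
    for i, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise VcfParseError(
                f"multi-allelic record #{i} at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT)}); split or normalize first"
            )
        gt_types = rec.gt_types  # 0 hom_ref, 1 het, 2 unknown, 3 hom_alt
        dp = rec.format("DP")
        genotypes: dict[str, str] = {}
        depths: dict[str, int] = {}
        for j, s in enumerate(samples):
            code = int(gt_types[j])
            genotypes[s] = {0: "hom_ref", 1: "het", 2: "missing", 3: "hom_alt"}[code]
            d = int(dp[j][0]) if dp is not None and dp[j][0] >= 0 else 0
            depths[s] = d
        gene = rec.INFO.get("GENE")
        if gene is None and annotation is not None:
            gene = annotation.locate(rec.CHROM, rec.POS)
        csq = rec.INFO.get("CSQ")
        if csq is None:
            csq = "intergenic" if gene is None else None
        sub = rec.INFO.get("SUB")
        records.append(
            VariantRecord(
                chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
                genotypes=genotypes, depths=depths, gene_id=gene,
                csq_class=csq,
                sub_class=sub.replace("_", "->") if sub else None,
            )
        )
    return records


def filter_enu_candidates(
    records: Iterable[VariantRecord],
    min_depth: int = 6,
    include_stoploss: bool = False,
) -> CandidateSet:
    """Retain unique heterozygous calls with carrier depth >= ``min_depth``.

    Variants called non-reference in more than one mouse are removed as
    non-ENU (``shared``); a remaining call must be heterozygous in its single
    carrier (``not_het`` otherwise) with the carrier's DP at or above the
    cutoff (``low_depth`` otherwise). Removal reasons partition the removed
    set and the filter is idempotent.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    retained: list[CandidateVariant] = []
    removed: list[tuple[VariantRecord, str]] = []
    for rec in records:
        carriers = rec.called_carriers()
        if len(carriers) >= 2:
            removed.append((rec, "shared"))
            continue
        het = rec.het_carriers()
        if len(het) != 1:
            removed.append((rec, "not_het"))
            continue
        carrier = het[0]
        if rec.depths.get(carrier, 0) < min_depth:
            removed.append((rec, "low_depth"))
            continue
        csq = rec.csq_class if rec.csq_class is not None else "intergenic"
        retained.append(
            CandidateVariant(
                mouse_id=carrier, chrom=rec.chrom, pos=rec.pos, ref=rec.ref,
                alt=rec.alt, gene_id=rec.gene_id, csq_class=csq,
                sub_class=rec.sub_class, depth=rec.depths[carrier],
                deleterious=classify_deleterious(csq, include_stoploss),
            )
        )
    return CandidateSet(
        candidates=retained,
        removed=removed,
        params={"min_depth": min_depth, "include_stoploss": include_stoploss},
    )


@dataclass
class SpectrumSummary:
    class_counts: pd.Series
    class_fractions: pd.Series
    sub_counts: pd.Series
    sub_fractions: pd.Series
    per_mouse: pd.Series
    per_mouse_deleterious: pd.Series
    mean_per_mouse: float
    mean_deleterious_per_mouse: float
    chrom_sex_means: pd.DataFrame
    x_female_male_ratio: float | None


def spectrum_summary(
    candidates: CandidateSet,
    sexes: Mapping[str, str],
) -> SpectrumSummary:
    """Cohort-level candidate spectrum (consequence, substitution, sex by chromosome).

    ``sexes`` maps every cohort mouse id (including mice with zero retained
    candidates) to "F"/"M". Substitution fractions are over SNV candidates
    only. The X-linked female/male per-mouse ratio floors the male total at a
    pseudocount of one variant so the expected male count of zero does not
    divide out.
    """
    mice = list(sexes)
    cand = candidates.candidates
    class_counts = pd.Series(
        [sum(1 for c in cand if c.csq_class == k)
         for k in sorted({c.csq_class for c in cand})],
        index=sorted({c.csq_class for c in cand}),
        dtype=int,
    )
    total = int(class_counts.sum())
    class_fractions = class_counts / total if total else class_counts.astype(float)
    snvs = [c for c in cand if c.sub_class is not None]
    sub_index = sorted({c.sub_class for c in snvs})
    sub_counts = pd.Series(
        [sum(1 for c in snvs if c.sub_class == k) for k in sub_index],
        index=sub_index, dtype=int,
    )
    sub_fractions = sub_counts / len(snvs) if snvs else sub_counts.astype(float)
    per_mouse = candidates.per_mouse_counts(mice)
    del_counts: dict[str, int] = {m: 0 for m in mice}
    for c in cand:
        if c.deleterious and c.mouse_id in del_counts:
            del_counts[c.mouse_id] += 1
    per_mouse_del = pd.Series(del_counts, dtype=int).reindex(mice)
    chrom_sex = pd.DataFrame(0.0, index=list(CHROMOSOMES), columns=["F", "M"])
    n_by_sex = {s: max(sum(1 for m in mice if sexes[m] == s), 1) for s in ("F", "M")}
    for c in cand:
        sex = sexes.get(c.mouse_id)
        if sex in ("F", "M") and c.chrom in chrom_sex.index:
            chrom_sex.loc[c.chrom, sex] += 1
    x_totals = chrom_sex.loc["X"].copy()
    chrom_sex["F"] /= n_by_sex["F"]
    chrom_sex["M"] /= n_by_sex["M"]
    ratio = None
    if any(sexes[m] == "F" for m in mice) and any(sexes[m] == "M" for m in mice):
        female_mean = x_totals["F"] / n_by_sex["F"]
        male_mean = max(x_totals["M"], 1.0) / n_by_sex["M"]  # pseudocount floor
        ratio = float(female_mean / male_mean)
    return SpectrumSummary(
        class_counts=class_counts,
        class_fractions=class_fractions,
        sub_counts=sub_counts,
        sub_fractions=sub_fractions,
        per_mouse=per_mouse,
        per_mouse_deleterious=per_mouse_del,
        mean_per_mouse=float(per_mouse.mean()),
        mean_deleterious_per_mouse=float(per_mouse_del.mean()),
        chrom_sex_means=chrom_sex,
        x_female_male_ratio=ratio,
    )


@dataclass(frozen=True)
class SibGroup:
    group_id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a sib group needs >= 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError("sib group members must be distinct")


def _check_disjoint(groups: Sequence[SibGroup]) -> None:
    seen: set[str] = set()
    for g in groups:
        overlap = seen & set(g.members)
        if overlap:
            raise ValueError(f"sib groups overlap on {sorted(overlap)}")
        seen |= set(g.members)


@dataclass
class SharedSibVariant:
    record: VariantRecord
    group_id: str
    carriers: tuple[str, ...]
    protein_altering: bool


def sib_shared_variants(
    records: Iterable[VariantRecord],
    groups: Sequence[SibGroup],
) -> list[SharedSibVariant]:
    """Heterozygous variants shared within (and only within) one sibship.

    A shared variant's het carrier set must have >= 2 members and be wholly
    contained in a single sib group; variants also seen in any unrelated
    mouse are excluded (those are cohort artifacts, not inherited sib
    variants). Deleterious-class hits are flagged protein-altering.
    """
    _check_disjoint(groups)
    member_to_group = {m: g for g in groups for m in g.members}
    out: list[SharedSibVariant] = []
    for rec in records:
        het = rec.het_carriers()
        if len(het) < 2:
            continue
        gset = {member_to_group.get(m) for m in het}
        if len(gset) != 1 or None in gset:
            continue
        group = gset.pop()
        csq = rec.csq_class or "intergenic"
        out.append(
            SharedSibVariant(
                record=rec,
                group_id=group.group_id,
                carriers=tuple(sorted(het)),
                protein_altering=classify_deleterious(csq),
            )
        )
    return out


@dataclass
class StemCellOriginResult:
    group_id: str
    shared_count: int
    member_counts: dict[str, int]
    fraction: float
    plausible: bool  # common spermatogonial stem cell origin


def stemcell_origin_test(
    group: SibGroup,
    records: Iterable[VariantRecord],
) -> StemCellOriginResult:
    """Test whether G1 sibs plausibly derive from one mutagenized stem cell.

    Sibs from the same ENU-treated spermatogonial stem cell are expected to
    share ~50% of their induced variants; observed sharing of 10% or less is
    taken as inconsistent with common origin. The sharing fraction is the
    number of variants heterozygous in >= 2 group members divided by the
    smaller member's variant count (strictly greater than 0.10 -> plausible).
    """
    records = list(records)
    member_counts = {
        m: sum(1 for rec in records if rec.genotypes.get(m) == "het")
        for m in group.members
    }
    if min(member_counts.values()) == 0:
        raise ValueError(
            f"sharing fraction undefined: member(s) with zero candidate variants in "
            f"group {group.group_id!r}"
        )
    shared = sum(
        1 for rec in records
        if sum(1 for m in group.members if rec.genotypes.get(m) == "het") >= 2
    )
    fraction = shared / min(member_counts.values())
    return StemCellOriginResult(
        group_id=group.group_id,
        shared_count=shared,
        member_counts=member_counts,
        fraction=float(fraction),
        plausible=fraction > 0.10,
    )
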