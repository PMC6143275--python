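"""Two-point linkage and co-segregation statistics for rescue pedigrees.

Implements the meiosis bookkeeping and LOD arithmetic used to test whether a
marker (typically an ENU-induced coding variant) travels with the rescue
trait: classification of informative meioses into recombinants and
non-recombinants, the two-point LOD curve over a recombination-fraction grid,
Haldane/Kosambi map-function conversion, exact co-segregation tests, and a
Monte-Carlo estimate of linkage power for a pedigree of given size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Individual",
    "Pedigree",
    "MeiosisTally",
    "LinkageResult",
    "CosegregationResult",
    "PowerEstimate",
    "PhaseUnknownError",
    "informative_meioses",
    "lod_score",
    "lod_two_point",
    "theta_from_distance",
    "cosegregation_test",
    "linkage_power",
]

GENOME_WIDE_LOD = 3.3  # genome-wide significance threshold for two-point LOD

_EXTERNAL_MATES = ("F5LL-ext",)


class PhaseUnknownError(ValueError):
    """Marker/trait phase of a transmitting parent is not recorded."""


class DegenerateTableError(ValueError):
    """A contingency table with no observations cannot be tested."""


@dataclass
class Individual:
    iid: str
    sire: str | None
    dam: str | None
    sex: str
    generation: int
    rescue: bool | None = None
    has_trait: bool | None = None  # carries the Tfpi-null-linked trait allele
    has_marker: bool | None = None
    transmitting_parent: str | None = None


class Pedigree:
    """A rescue pedigree with marker genotypes and phase annotations.

    ``phase[parent]`` is True when the parent's marker allele is in cis with
    the trait allele, False for trans; transmitting parents absent from
    ``phase`` are treated as phase-unknown.
    """

    def __init__(self) -> None:
        self.individuals: dict[str, Individual] = {}
        self.phase: dict[str, bool] = {}

    def add(self, ind: Individual) -> None:
        if ind.iid in self.individuals:
            raise ValueError(f"duplicate individual id {ind.iid!r}")
        for parent in (ind.sire, ind.dam):
            if parent is not None and parent not in self.individuals and parent not in _EXTERNAL_MATES:
                raise ValueError(
                    f"parent {parent!r} of {ind.iid!r} is neither in the pedigree "
                    f"nor a recorded external F5 L/L mate"
                )
        self.individuals[ind.iid] = ind

    def __len__(self) -> int:
        return len(self.individuals)

    def members(self) -> list[Individual]:
        return list(self.individuals.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family": "PED",
                "id": i.iid,
                "sire": i.sire or "0",
                "dam": i.dam or "0",
                "sex": i.sex,
                "rescue": "" if i.rescue is None else int(i.rescue),
                "trait": "" if i.has_trait is None else int(i.has_trait),
                "marker": "" if i.has_marker is None else int(i.has_marker),
            }
            for i in self.members()
        ]
        return pd.DataFrame(rows)


@dataclass
class MeiosisTally:
    """Recombinant / non-recombinant counts over informative meioses."""

    nr: int = 0
    r: int = 0
    label: str = ""
    uninformative: int = 0

    def __post_init__(self) -> None:
        if self.nr < 0 or self.r < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.nr + self.r

    def __add__(self, other: "MeiosisTally") -> "MeiosisTally":
        return MeiosisTally(
            nr=self.nr + other.nr,
            r=self.r + other.r,
            label=self.label or other.label,
            uninformative=self.uninformative + other.uninformative,
        )


def informative_meioses(
    ped: Pedigree, group: str | None = None
) -> MeiosisTally:
    """Classify each offspring of a phase-known doubly heterozygous parent.

    A meiosis is non-recombinant when the offspring received the parental
    (trait, marker) haplotype intact — both alleles or neither under cis
    phase — and recombinant otherwise. Offspring of parents that are not
    doubly heterozygous, or with missing genotypes, are counted as
    uninformative. ``group`` restricts the tally to ``"rescues"`` or
    ``"littermates"``.

    Raises :class:`PhaseUnknownError` if a doubly heterozygous transmitting
    parent has no recorded phase (callers may then run both assumptions).
    """
    tally = MeiosisTally(label=group or "all")
    for ind in ped.members():
        tp = ind.transmitting_parent
        if tp is None:
            continue
        if group == "rescues" and ind.rescue is not True:
            continue
        if group == "littermates" and ind.rescue is not False:
            continue
        parent = ped.individuals.get(tp)
        if parent is None or not (parent.has_trait and parent.has_marker):
            tally.uninformative += 1
            continue
        if tp not in ped.phase:
            raise PhaseUnknownError(f"phase unknown for transmitting parent {tp!r}")
        if ind.has_trait is None or ind.has_marker is None:
            tally.uninformative += 1
            continue
        cis = ped.phase[tp]
        together = ind.has_marker == ind.has_trait
        if together == cis:
            tally.nr += 1
        else:
            tally.r += 1
    return tally


def lod_score(nr: int | np.ndarray, r: int | np.ndarray, theta: float | np.ndarray) -> np.ndarray:
    """Two-point LOD at recombination fraction theta.

    LOD(theta) = log10[ (1-theta)^NR * theta^R / 0.5^(NR+R) ]
               = NR*log10(2(1-theta)) + R*log10(2*theta).
    """
    theta = np.asarray(theta, dtype=float)
    nr = np.asarray(nr)
    r = np.asarray(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_r = np.where(r > 0, r * np.log10(2 * theta), 0.0)
    return nr * np.log10(2 * (1 - theta)) + term_r


@dataclass
class LinkageResult:
    theta_hat: float
    max_lod: float
    curve: pd.DataFrame = field(repr=False)
    threshold: float = GENOME_WIDE_LOD

    @property
    def significant(self) -> bool:
        return self.max_lod >= self.threshold


def default_theta_grid() -> np.ndarray:
    # [1e-6, 0.001, 0.002, ..., 0.5]: reproducible theta-hat to 3 decimals
    # without evaluating log(0)
    return np.concatenate([[1e-6], np.arange(0.001, 0.5 + 1e-12, 0.001)])


def lod_two_point(
    tally: MeiosisTally,
    theta_grid: np.ndarray | None = None,
    threshold: float = GENOME_WIDE_LOD,
) -> LinkageResult:
    """Maximize the two-point LOD over a theta grid.

    With zero recombinants the maximum is the theta -> 0 limit,
    NR * log10(2), reported at theta_hat = 0.
    """
    if tally.n < 1:
        raise ValueError("tally must contain at least one informative meiosis")
    grid = default_theta_grid() if theta_grid is None else np.asarray(theta_grid, float)
    lods = lod_score(tally.nr, tally.r, grid)
    curve = pd.DataFrame({"theta": grid, "lod": lods})
    if tally.r == 0:
        max_lod = float(tally.nr * np.log10(2.0))
        return LinkageResult(theta_hat=0.0, max_lod=max_lod, curve=curve, threshold=threshold)
    i = int(np.argmax(lods))
    return LinkageResult(
        theta_hat=float(grid[i]), max_lod=float(lods[i]), curve=curve, threshold=threshold
    )


def theta_from_distance(distance_cm: float, map_function: str = "haldane") -> float:
    """Convert a map distance in centimorgans to a recombination fraction.

    Haldane: theta = (1 - exp(-2d)) / 2; Kosambi: theta = tanh(2d) / 2,
    with d in Morgans. Both are bounded by 0.5.
    """
    if distance_cm < 0:
        raise ValueError("map distance must be non-negative")
    d = distance_cm / 100.0
    if map_function == "haldane":
        return float(0.5 * (1.0 - np.exp(-2.0 * d)))
    if map_function == "kosambi":
        return float(0.5 * np.tanh(2.0 * d))
    raise ValueError(f"unknown map function {map_function!r}")


@dataclass
class CosegregationResult:
    fisher_p: float
    binomial_p: float
    table: tuple[tuple[int, int], tuple[int, int]]
    theta_expected: float


def cosegregation_test(
    rescues: MeiosisTally,
    littermates: MeiosisTally,
    theta_expected: float,
) -> CosegregationResult:
    """Two exact tests of marker/trait co-segregation in rescues.

    (a) Two-sided Fisher exact on the 2x2 [rescues, littermates] x
    [recombinant, non-recombinant] table, and (b) the exact binomial
    probability of observing at most the rescue recombinant count among
    rescue meioses when recombinants arise at ``theta_expected``. For zero
    rescue recombinants the binomial term is (1 - theta)^NR exactly.

    Both p-values are reported; the construction behind any single printed
    co-segregation p-value is not uniquely determined, so neither test is
    privileged.
    """
    if not 0.0 < theta_expected <= 0.5:
        raise ValueError("theta_expected must lie in (0, 0.5]")
    if rescues.n == 0 and littermates.n == 0:
        raise DegenerateTableError("no informative meioses in either group")
    if rescues.n == 0:
        raise DegenerateTableError("no informative rescue meioses")
    table = ((rescues.r, rescues.nr), (littermates.r, littermates.nr))
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    binomial_p = float(stats.binom.cdf(rescues.r, rescues.n, theta_expected))
    return CosegregationResult(
        fisher_p=fisher_p, binomial_p=binomial_p, table=table,
        theta_expected=float(theta_expected),
    )


@dataclass
class PowerEstimate:
    power: float
    ci_low: float
    ci_high: float
    n_sim: int
    n_meioses: int
    lod_threshold: float


def linkage_power(
    ped_structure: dict,
    n_markers: int,
    marker_positions: list[float] | np.ndarray,
    theta_true: float,
    n_sim: int = 10_000,
    lod_threshold: float = GENOME_WIDE_LOD,
    seed: int | None = None,
    penetrance: float = 1.0,
    phenocopy_rate: float = 0.02,
    map_cm_max: float = 200.0,
) -> PowerEstimate:
    """Monte-Carlo power of two-point linkage mapping in a rescue pedigree.

    The pedigree is summarized by its informative meiosis count
    (``ped_structure`` maps ``n_sibships``/``sibship_size`` or gives
    ``n_meioses`` directly). Each replicate transmits the suppressor allele
    through every meiosis, assigns the rescue phenotype with the given
    penetrance and phenocopy rate, then genotypes each marker. The suppressor
    lies at ``theta_true`` from the nearest marker (the one with the smallest
    map coordinate); other markers combine that with their Haldane map
    distance to the nearest marker under no interference. Power is
    the fraction of replicates whose maximum two-point LOD (marker vs
    phenotype) reaches ``lod_threshold``, with a Clopper-Pearson 95% CI.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if not 0.0 <= theta_true <= 0.5:
        raise ValueError("theta_true must lie in [0, 0.5]")
    positions = np.asarray(marker_positions, dtype=float)
    if len(positions) != n_markers:
        raise ValueError("marker_positions length must equal n_markers")
    if (positions < 0).any() or (positions > map_cm_max).any():
        raise ValueError("marker positions outside map")
    if "n_meioses" in ped_structure:
        n_meioses = int(ped_structure["n_meioses"])
    else:
        n_meioses = int(ped_structure["n_sibships"]) * int(ped_structure["sibship_size"])
    if n_meioses < 1:
        raise ValueError("pedigree must yield at least one meiosis")
    # the trait locus sits at theta_true from the nearest marker; every other
    # marker combines that with its map distance to the nearest marker under
    # no interference: theta = t1 + t2 - 2*t1*t2 (so theta_true = 0.5 leaves
    # the whole marker set unlinked)
    nearest = int(np.argmin(positions))
    thetas = np.empty(len(positions))
    for i, pos in enumerate(positions):
        t2 = theta_from_distance(abs(pos - positions[nearest]))
        thetas[i] = theta_true + t2 - 2 * theta_true * t2
    # numerical floor: theta=0 markers are scored via the R=0 limit anyway
    thetas = np.clip(thetas, 1e-9, 0.5)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sim):
        s = rng.random(n_meioses) < 0.5  # suppressor transmitted
        pheno = (s & (rng.random(n_meioses) < penetrance)) | (
            rng.random(n_meioses) < phenocopy_rate
        )
        best = -np.inf
        for theta_m in thetas:
            m = s ^ (rng.random(n_meioses) < theta_m)
            nr = int((m == pheno).sum())
            r = n_meioses - nr
            if r == 0:
                lod = nr * np.log10(2.0)
            else:
                t_hat = max(min(r / n_meioses, 0.5), 1e-9)
                lod = float(lod_score(nr, r, t_hat))
            best = max(best, lod)
        if best >= lod_threshold:
            hits += 1
    power = hits / n_sim
    lo, hi = _clopper_pearson(hits, n_sim)
    return PowerEstimate(power=power, ci_low=lo, ci_high=hi, n_sim=n_sim,
                         n_meioses=n_meioses, lod_threshold=lod_threshold)


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
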