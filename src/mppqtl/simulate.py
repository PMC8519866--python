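"""Simulator for multiparental breeding designs (diallel, NAM, MAGIC).

Founder genomes are haploid allele sequences over a genetic map (founders are
fully inbred). Offspring genomes are represented as founder mosaics: per
chromosome and haplotype, an ordered list of junctions giving the founder of
origin of each segment. Meiosis draws a Poisson number of crossovers per
chromosome (mean = length in Morgan, no interference) with uniform positions.
Populations are advanced by single seed descent: each line is founded by an
independent F2 seed and selfed once per generation until the final generation.

The default study emulates a 4-founder setup on a 5-chromosome, 462-marker
map with three major QTLs (additive effect 0.4) and 24 minor QTLs (effect
0.1), N = 300 F6 offspring and 5% missing genotypes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import GeneticMap, uniform_map

__all__ = [
    "Family",
    "CrossingPlan",
    "FounderMosaic",
    "GenotypeTable",
    "QTLArchitecture",
    "SimulatedTrait",
    "make_crossing_plan",
    "simulate_meiosis",
    "advance_population",
    "realize_genotypes",
    "minor_qtl_positions",
    "assign_qtl_architecture",
    "simulate_phenotype",
    "expected_qtl_variance",
    "synthetic_founders",
    "default_map",
    "default_architecture",
    "default_plan",
    "simulate_study",
]

DESIGNS = ("diallel", "nam", "magic")


class DesignError(ValueError):
    """Raised for unsupported or inconsistent crossing designs."""


# ---------------------------------------------------------------------------
# crossing plans
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Family:
    family_id: str
    parents: tuple[int, ...]  # founder indices involved
    size: int


@dataclass(frozen=True)
class CrossingPlan:
    design_type: str
    families: tuple[Family, ...]
    final_generation: int
    n_founders: int

    @property
    def n_individuals(self) -> int:
        return sum(f.size for f in self.families)

    @property
    def n_families(self) -> int:
        return len(self.families)

    def individual_ids(self) -> list[str]:
        return [
            f"{fam.family_id}_{i + 1:03d}"
            for fam in self.families
            for i in range(fam.size)
        ]

    def family_labels(self) -> np.ndarray:
        return np.array(
            [fam.family_id for fam in self.families for _ in range(fam.size)]
        )


def make_crossing_plan(
    design_type: str,
    n_founders: int,
    family_sizes: int | list[int],
    final_generation: int = 6,
    central_founder: int | None = None,
) -> CrossingPlan:
    """Enumerate the families of a diallel, NAM or MAGIC design.

    Diallel: all unordered founder pairs, in lexicographic order. NAM: the
    central founder crossed with every other founder. MAGIC: one family from
    a balanced funnel over all founders (founder count must be a power of 2).
    ``family_sizes`` may be a single per-family size or one size per family.
    """
    design_type = design_type.lower()
    if design_type not in DESIGNS:
        raise DesignError(f"unsupported design {design_type!r}")
    if n_founders < 2:
        raise DesignError("need at least 2 founders")
    if final_generation < 1:
        raise DesignError("final generation must be >= 1")

    if design_type == "diallel":
        parent_sets = [tuple(p) for p in itertools.combinations(range(n_founders), 2)]
        name = "Diallel"
    elif design_type == "nam":
        if central_founder is None:
            raise DesignError("NAM requires a designated central founder")
        if not 0 <= central_founder < n_founders:
            raise DesignError("central founder index out of range")
        parent_sets = [
            (central_founder, j) for j in range(n_founders) if j != central_founder
        ]
        name = "NAM"
    else:  # magic
        if n_founders & (n_founders - 1) != 0:
            raise DesignError("MAGIC requires a power-of-2 founder count")
        parent_sets = [tuple(range(n_founders))]
        name = "MAGIC"

    if isinstance(family_sizes, int):
        sizes = [family_sizes] * len(parent_sets)
    else:
        sizes = list(family_sizes)
        if len(sizes) != len(parent_sets):
            raise DesignError(
                f"{len(parent_sets)} families but {len(sizes)} family sizes"
            )
    if any(s < 1 for s in sizes):
        raise DesignError("family sizes must be positive")

    fams = tuple(
        Family(f"{name}{i + 1}", parents, size)
        for i, (parents, size) in enumerate(zip(parent_sets, sizes))
    )
    return CrossingPlan(design_type, fams, final_generation, n_founders)


# ---------------------------------------------------------------------------
# meiosis and mosaics
# ---------------------------------------------------------------------------

# A haplotype of one chromosome is (bounds, origins): ``bounds`` are segment
# end positions in cM (ascending, last == chromosome length), ``origins`` the
# founder index of each segment. A diploid chromosome is a (hap, hap) pair.

Haplotype = tuple[np.ndarray, np.ndarray]


@dataclass
class FounderMosaic:
    """True founder-origin genome of one offspring (junction representation)."""

    individual_id: str
    family_id: str
    chroms: list[tuple[Haplotype, Haplotype]]  # aligned with map.chromosomes

    def n_junctions(self) -> float:
        """Junction count averaged over the two haplotypes."""
        total = 0.0
        for hap_a, hap_b in self.chroms:
            total += (len(hap_a[1]) - 1 + len(hap_b[1]) - 1) / 2.0
        return total

    def origins_at(self, gmap: GeneticMap) -> np.ndarray:
        """(2, n_markers) founder origin of each haplotype at each marker."""
        out = np.empty((2, gmap.n_markers), dtype=np.int64)
        for ci, chrom in enumerate(gmap.chromosomes):
            pos = gmap.positions(chrom)
            sl = gmap.chrom_slice(chrom)
            hap_a, hap_b = self.chroms[ci]
            for h, (bounds, origins) in enumerate((hap_a, hap_b)):
                idx = np.clip(
                    np.searchsorted(bounds, pos, side="right"),
                    0,
                    len(origins) - 1,
                )
                out[h, sl] = origins[idx]
        return out


def _simplify(bounds: np.ndarray, origins: np.ndarray) -> Haplotype:
    """Merge adjacent segments with equal origin and drop empty segments."""
    keep = np.ones(len(origins), dtype=bool)
    starts = np.concatenate(([0.0], bounds[:-1]))
    keep &= bounds > starts  # drop zero-length segments
    b, o = bounds[keep], origins[keep]
    if len(o) > 1:
        change = np.concatenate((o[:-1] != o[1:], [True]))
        b, o = b[change], o[change]
    return b, o


def _slice_hap(hap: Haplotype, lo: float, hi: float) -> tuple[list, list]:
    """Segments of ``hap`` restricted to the interval (lo, hi]."""
    bounds, origins = hap
    first = int(np.searchsorted(bounds, lo, side="right"))
    first = min(first, len(origins) - 1)
    out_b, out_o = [], []
    for i in range(first, len(origins)):
        out_b.append(min(bounds[i], hi))
        out_o.append(origins[i])
        if bounds[i] >= hi:
            break
    return out_b, out_o


def simulate_meiosis(
    chrom_pair: tuple[Haplotype, Haplotype],
    length_cm: float,
    rng: np.random.Generator,
) -> Haplotype:
    """One gamete of one chromosome.

    Crossover count ~ Poisson(length in Morgan), positions i.i.d. uniform;
    the gamete starts from a fair random haplotype and alternates at each
    crossover (no interference). A zero-length chromosome recombines never.
    """
    hap_a, hap_b = chrom_pair
    current = int(rng.integers(2))
    n_xo = int(rng.poisson(length_cm / 100.0)) if length_cm > 0 else 0
    if n_xo == 0:
        src = (hap_a, hap_b)[current]
        return np.asarray(src[0], float).copy(), np.asarray(src[1]).copy()
    cuts = np.sort(rng.uniform(0.0, length_cm, size=n_xo))
    edges = np.concatenate((cuts, [length_cm]))
    lo = 0.0
    out_b: list[float] = []
    out_o: list[int] = []
    for hi in edges:
        if hi > lo:
            b, o = _slice_hap((hap_a, hap_b)[current], lo, hi)
            out_b.extend(b)
            out_o.extend(o)
        current = 1 - current
        lo = hi
    return _simplify(np.asarray(out_b, float), np.asarray(out_o, np.int64))


def _founder_genome(
    founder: int, gmap: GeneticMap
) -> list[tuple[Haplotype, Haplotype]]:
    chroms = []
    for c in gmap.chromosomes:
        length = gmap.chrom_length(c)
        hap: Haplotype = (np.array([length]), np.array([founder], np.int64))
        chroms.append((hap, (hap[0].copy(), hap[1].copy())))
    return chroms


def _cross(
    mother: list[tuple[Haplotype, Haplotype]],
    father: list[tuple[Haplotype, Haplotype]],
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> list[tuple[Haplotype, Haplotype]]:
    lengths = [gmap.chrom_length(c) for c in gmap.chromosomes]
    return [
        (
            simulate_meiosis(mc, length, rng),
            simulate_meiosis(fc, length, rng),
        )
        for mc, fc, length in zip(mother, father, lengths)
    ]


def advance_population(
    plan: CrossingPlan,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> list[FounderMosaic]:
    """True offspring genomes at the plan's final generation.

    Per family the F1 comes from the designated cross (MAGIC runs the
    two-way and four-way funnel crosses first). Each line then descends from
    an independent F2 seed and is selfed by single seed descent, one selfing
    per generation, until the final generation.
    """
    out: list[FounderMosaic] = []
    for fam in plan.families:
        for i in range(fam.size):
            genome = _family_f1(fam, plan.design_type, gmap, rng)
            for _ in range(plan.final_generation - 1):
                genome = _cross(genome, genome, gmap, rng)  # selfing
            out.append(FounderMosaic(f"{fam.family_id}_{i + 1:03d}", fam.family_id, genome))
    return out


def _family_f1(
    fam: Family,
    design_type: str,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> list[tuple[Haplotype, Haplotype]]:
    if design_type in ("diallel", "nam") or len(fam.parents) == 2:
        a, b = fam.parents
        ga, gb = _founder_genome(a, gmap), _founder_genome(b, gmap)
        # founders are inbred: the F1 is (hap of a, hap of b), no randomness
        return [(ca[0], cb[0]) for ca, cb in zip(ga, gb)]
    # MAGIC funnel: pair founders, cross, and repeat until one hybrid remains
    pool = [_founder_genome(p, gmap) for p in fam.parents]
    first_round = True
    while len(pool) > 1:
        nxt = []
        for j in range(0, len(pool), 2):
            if first_round:
                # inbred x inbred: deterministic two-way hybrid
                nxt.append(
                    [
                        (ca[0], cb[0])
                        for ca, cb in zip(pool[j], pool[j + 1])
                    ]
                )
            else:
                nxt.append(_cross(pool[j], pool[j + 1], gmap, rng))
        pool = nxt
        first_round = False
    return pool[0]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Offspring x marker allele-dosage matrix (copies of allele 2; NaN missing)."""

    individuals: list[str]
    family_labels: np.ndarray
    dosages: np.ndarray  # (N, n_markers) float, NaN for missing
    gmap: GeneticMap

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.individuals, columns=self.gmap.markers
        )

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.dosages).mean())


def realize_genotypes(
    mosaics: list[FounderMosaic],
    founders: np.ndarray,
    gmap: GeneticMap,
    missing_rate: float = 0.05,
    rng: np.random.Generator | None = None,
) -> GenotypeTable:
    """Read observed dosages off the founder alleles under each origin.

    ``founders`` is the (P, n_markers) haploid allele matrix over {1, 2}.
    Entries are masked missing independently at ``missing_rate``.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    if missing_rate > 0 and rng is None:
        raise ValueError("rng required when missing_rate > 0")
    n = len(mosaics)
    dos = np.empty((n, gmap.n_markers))
    for i, mos in enumerate(mosaics):
        orig = mos.origins_at(gmap)
        alleles = founders[orig, np.arange(gmap.n_markers)]
        dos[i] = (alleles == 2).sum(axis=0)
    if missing_rate > 0:
        mask = rng.random(dos.shape) < missing_rate
        dos[mask] = np.nan
    fams = np.array([m.family_id for m in mosaics])
    return GenotypeTable([m.individual_id for m in mosaics], fams, dos, gmap)


# ---------------------------------------------------------------------------
# QTL architecture and phenotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QTLArchitecture:
    """Positions, effects and founder allele configurations of simulated QTLs."""

    majors: pd.DataFrame  # marker, chrom, pos_cm, effect
    minors: pd.DataFrame  # marker, chrom, pos_cm, effect
    founder_alleles: pd.DataFrame  # QTL marker x founder, alleles in {1,2}
    null_chrom: str

    @property
    def qtl_markers(self) -> list[str]:
        return list(self.majors["marker"]) + list(self.minors["marker"])


def minor_qtl_positions(
    major_pos: float,
    chrom_length: float,
    start_cm: float = 20.0,
    step_cm: float = 10.0,
) -> list[float]:
    """Positions of minor QTLs flanking a major QTL.

    Starting ``start_cm`` above and below the major position, minors are
    placed outward at ``step_cm`` intervals and truncated at the chromosome
    ends.
    """
    below, above = [], []
    d = start_cm
    while True:
        placed = False
        if major_pos - d >= 0:
            below.append(major_pos - d)
            placed = True
        if major_pos + d <= chrom_length:
            above.append(major_pos + d)
            placed = True
        if not placed:
            break
        d += step_cm
    return sorted(below) + above


def assign_qtl_architecture(
    gmap: GeneticMap,
    founders: np.ndarray,
    major_markers: list[str],
    major_effect: float = 0.4,
    minor_effect: float = 0.1,
    minor_grid: dict[str, list[float]] | None = None,
    null_chrom: str | None = None,
    start_cm: float = 20.0,
    step_cm: float = 10.0,
) -> QTLArchitecture:
    """Place major and minor QTLs on the map.

    Major QTLs must sit at map markers on distinct chromosomes; minors flank
    each major per :func:`minor_qtl_positions` (snapped to the nearest
    marker). ``minor_grid`` adds minors at explicit positions on chromosomes
    that carry no major (e.g. a 10 cM grid). ``null_chrom`` carries no QTLs
    and is used for false-positive accounting.
    """
    maj_rows = []
    for m in major_markers:
        maj_rows.append(
            {
                "marker": m,
                "chrom": gmap.chrom_of(m),
                "pos_cm": gmap.pos_of(m),
                "effect": major_effect,
            }
        )
    majors = pd.DataFrame(maj_rows)
    if majors["chrom"].duplicated().any():
        raise ValueError("major QTLs must sit on distinct chromosomes")

    min_rows = []
    for _, row in majors.iterrows():
        chrom = row["chrom"]
        for pos in minor_qtl_positions(
            row["pos_cm"], gmap.chrom_length(chrom), start_cm, step_cm
        ):
            min_rows.append({"chrom": chrom, "pos_cm": pos})
    for chrom, positions in (minor_grid or {}).items():
        for pos in positions:
            min_rows.append({"chrom": str(chrom), "pos_cm": float(pos)})

    # snap minor positions to the nearest map marker
    seen = set(major_markers)
    minors = []
    for row in min_rows:
        pos = gmap.positions(row["chrom"])
        sl = gmap.chrom_slice(row["chrom"])
        j = int(np.argmin(np.abs(pos - row["pos_cm"]))) + sl.start
        marker = gmap.markers[j]
        if marker in seen:
            continue
        seen.add(marker)
        minors.append(
            {
                "marker": marker,
                "chrom": row["chrom"],
                "pos_cm": float(gmap.table["pos_cm"].iloc[j]),
                "effect": minor_effect,
            }
        )
    minors_df = pd.DataFrame(minors).sort_values(["chrom", "pos_cm"]).reset_index(drop=True)

    if null_chrom is None:
        with_qtl = set(majors["chrom"]) | set(minors_df["chrom"])
        free = [c for c in gmap.chromosomes if c not in with_qtl]
        if not free:
            raise ValueError("no QTL-free chromosome available for null_chrom")
        null_chrom = free[-1]
    elif null_chrom in set(majors["chrom"]) | set(minors_df["chrom"]):
        raise ValueError(f"null chromosome {null_chrom!r} carries QTLs")

    qtl_markers = list(majors["marker"]) + list(minors_df["marker"])
    idx = [gmap.marker_index(m) for m in qtl_markers]
    fa = pd.DataFrame(
        founders[:, idx].T,
        index=qtl_markers,
        columns=[f"P{j + 1}" for j in range(founders.shape[0])],
    )
    return QTLArchitecture(majors, minors_df, fa, str(null_chrom))


@dataclass
class SimulatedTrait:
    """Phenotypes and the genotype indicators that generated them."""

    y: np.ndarray
    z_major: np.ndarray  # (N, n_major) in {1, 0, -1}
    z_minor: np.ndarray
    residual_sd: float
    realized_h2_major: float


def simulate_phenotype(
    mosaics: list[FounderMosaic],
    founders: np.ndarray,
    architecture: QTLArchitecture,
    gmap: GeneticMap,
    major_effect: float | None = None,
    minor_effect: float | None = None,
    residual_sd: float = 1.0,
    rng: np.random.Generator | None = None,
    residuals: np.ndarray | None = None,
) -> SimulatedTrait:
    """Additive phenotype: Y = sum_major a*z + sum_minor b*z + eps.

    The indicator z is +1 for genotype 11, -1 for 22 and 0 at residual
    heterozygotes; eps ~ N(0, residual_sd^2) unless ``residuals`` is given.
    """
    true = realize_genotypes(mosaics, founders, gmap, missing_rate=0.0)

    def z_at(markers: list[str]) -> np.ndarray:
        idx = [gmap.marker_index(m) for m in markers]
        return 1.0 - true.dosages[:, idx]  # dosage 0 -> +1, 1 -> 0, 2 -> -1

    z_major = z_at(list(architecture.majors["marker"]))
    z_minor = z_at(list(architecture.minors["marker"]))
    a_eff = (
        architecture.majors["effect"].to_numpy()
        if major_effect is None
        else np.full(z_major.shape[1], float(major_effect))
    )
    b_eff = (
        architecture.minors["effect"].to_numpy()
        if minor_effect is None
        else np.full(z_minor.shape[1], float(minor_effect))
    )
    genetic_major = z_major @ a_eff
    genetic_minor = z_minor @ b_eff
    if residuals is None:
        if rng is None:
            raise ValueError("rng required unless residuals are supplied")
        residuals = rng.normal(0.0, residual_sd, size=len(mosaics))
    y = genetic_major + genetic_minor + residuals
    var_y = float(np.var(y)) if len(y) > 1 else np.nan
    h2 = float(np.var(genetic_major) / var_y) if var_y and var_y > 0 else np.nan
    return SimulatedTrait(y, z_major, z_minor, residual_sd, h2)


def expected_qtl_variance(
    plan: CrossingPlan,
    founder_alleles: np.ndarray,
    effect: float,
    total_variance: float | None = None,
) -> tuple[float, float]:
    """Expected genetic variance of one QTL: a^2 {E[Z^2] - E[Z]^2}.

    ``founder_alleles`` gives each founder's allele (1 or 2) at the QTL.
    In the inbred limit Z is +1 (genotype 11) or -1 (genotype 22); the
    frequency of genotype 11 follows from the design: per biparental family
    it is 1, 1/2 or 0 according to how many parents carry allele 1, and in a
    MAGIC family it equals the carrier fraction among founders. Families are
    weighted by size. Returns (variance, percent of ``total_variance``
    explained); the percentage is NaN when no total is supplied.
    """
    alleles = np.asarray(founder_alleles)
    freq11 = 0.0
    n_total = plan.n_individuals
    for fam in plan.families:
        carriers = np.mean(alleles[list(fam.parents)] == 1)
        if len(fam.parents) == 2:
            f_fam = {0.0: 0.0, 0.5: 0.5, 1.0: 1.0}[float(carriers)]
        else:
            f_fam = float(carriers)
        freq11 += fam.size / n_total * f_fam
    e_z = 2.0 * freq11 - 1.0
    var = effect**2 * (1.0 - e_z**2)
    pct = 100.0 * var / total_variance if total_variance else float("nan")
    return float(var), float(pct)


# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: chromosome layout of the default 462-marker map: chromosomes 1-4 carry 88
#: markers at 1 cM spacing (0..87 cM), chromosome 5 carries 110 (0..109 cM).
DEFAULT_CHROM_MARKERS = {"1": 88, "2": 88, "3": 88, "4": 88, "5": 110}
DEFAULT_MAJOR_MARKERS = ["m1_44", "m2_44", "m3_44"]
#: minor QTLs on chromosome 4 sit on a 10 cM grid (6 QTLs)
DEFAULT_MINOR_GRID = {"4": [19.0, 29.0, 39.0, 49.0, 59.0, 69.0]}
#: founders homozygous for the trait-increasing allele at each major QTL
DEFAULT_MAJOR_CARRIERS = {"m1_44": (0, 1), "m2_44": (0,), "m3_44": (0, 1, 2)}


def default_map() -> GeneticMap:
    """The 5-chromosome, 462-marker map used by the default study."""
    return uniform_map({c: n - 1 for c, n in DEFAULT_CHROM_MARKERS.items()})


def synthetic_founders(
    gmap: GeneticMap,
    n_founders: int = 4,
    rng: np.random.Generator | None = None,
    major_carriers: dict[str, tuple[int, ...]] | None = None,
    polymorphic_markers: list[str] | None = None,
) -> np.ndarray:
    """Synthetic inbred founder genomes: i.i.d. Bernoulli(0.5) alleles.

    ``major_carriers`` overwrites designated markers so that exactly the
    listed founders carry allele 1 (the trait-increasing allele).
    ``polymorphic_markers`` are redrawn until at least two founder alleles
    differ, so designated QTLs actually segregate somewhere.
    """
    if rng is None:
        rng = np.random.default_rng()
    alleles = rng.integers(1, 3, size=(n_founders, gmap.n_markers))
    for marker in polymorphic_markers or []:
        j = gmap.marker_index(marker)
        while len(set(alleles[:, j])) == 1:
            alleles[:, j] = rng.integers(1, 3, size=n_founders)
    for marker, carriers in (major_carriers or {}).items():
        j = gmap.marker_index(marker)
        alleles[:, j] = 2
        alleles[list(carriers), j] = 1
    return alleles


def default_architecture(
    gmap: GeneticMap, founders: np.ndarray
) -> QTLArchitecture:
    """Three major QTLs mid-chromosome on chromosomes 1-3 plus 24 minors."""
    arch = assign_qtl_architecture(
        gmap,
        founders,
        DEFAULT_MAJOR_MARKERS,
        minor_grid=DEFAULT_MINOR_GRID,
        null_chrom="5",
    )
    return arch


def default_plan(design: str, final_generation: int = 6) -> CrossingPlan:
    """Study-size plan: diallel 6x50, NAM 3x100 (central founder P1), MAGIC 1x300."""
    design = design.lower()
    if design == "diallel":
        return make_crossing_plan("diallel", 4, 50, final_generation)
    if design == "nam":
        return make_crossing_plan("nam", 4, 100, final_generation, central_founder=0)
    if design == "magic":
        return make_crossing_plan("magic", 4, 300, final_generation)
    raise DesignError(f"unsupported design {design!r}")


def simulate_study(
    design: str,
    rng: np.random.Generator,
    n_per_family: int | None = None,
    missing_rate: float = 0.05,
    major_effect: float = 0.4,
    minor_effect: float = 0.1,
    residual_sd: float = 1.0,
    final_generation: int = 6,
):
    """One full replicate of the default study for one design.

    Returns (plan, founders, architecture, mosaics, genotypes, trait).
    Founder genomes are redrawn per replicate; the three major QTL carrier
    patterns are fixed, minor QTL markers are guaranteed polymorphic.
    """
    gmap = default_map()
    plan = default_plan(design, final_generation)
    if n_per_family is not None:
        plan = CrossingPlan(
            plan.design_type,
            tuple(Family(f.family_id, f.parents, n_per_family) for f in plan.families),
            plan.final_generation,
            plan.n_founders,
        )
    probe = synthetic_founders(gmap, 4, rng, DEFAULT_MAJOR_CARRIERS)
    arch = default_architecture(gmap, probe)
    founders = synthetic_founders(
        gmap,
        4,
        rng,
        DEFAULT_MAJOR_CARRIERS,
        polymorphic_markers=list(arch.minors["marker"]),
    )
    arch = default_architecture(gmap, founders)
    mosaics = advance_population(plan, gmap, rng)
    genotypes = realize_genotypes(mosaics, founders, gmap, missing_rate, rng)
    trait = simulate_phenotype(
        mosaics,
        founders,
        arch,
        gmap,
        major_effect=major_effect,
        minor_effect=minor_effect,
        residual_sd=residual_sd,
        rng=rng,
    )
    return plan, founders, arch, mosaics, genotypes, trait
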