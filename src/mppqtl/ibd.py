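"""Founder-origin (IBD) reconstruction by hidden Markov model decoding.

Offspring of the supported designs are (nearly) fully inbred, so each locus
carries a single hidden founder-origin state. Along a chromosome the state
changes with a continuous Markov kernel over map distance d (in Morgan):

    T(i -> j) = exp(-rho * d) * 1{i = j} + (1 - exp(-rho * d)) * pi_j

where rho is the expected junction density per Morgan of the design (the
accumulated recombination of the breeding scheme) and pi the initial state
distribution (uniform over the family's founders). rho is calibrated per
design by simulating the pedigree and counting realised junctions.

Emissions compare the observed allele dosage with each candidate founder's
homozygous genotype, allowing a genotyping error rate e; missing and (rare
residual) heterozygous dosages are uninformative. Posterior probabilities
come from a scaled forward-backward pass per chromosome; twice the posterior
is the genetic predictor used in QTL mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap
from .simulate import CrossingPlan, advance_population, Family, GenotypeTable

__all__ = [
    "OriginHMM",
    "IBDTensor",
    "calibrate_junction_density",
    "build_hmm",
    "posterior_origins",
    "ibd_posteriors",
    "genetic_predictors",
    "ibd_quality",
]


@dataclass(frozen=True)
class OriginHMM:
    """HMM for one family: states are the founder indices of that family."""

    states: tuple[int, ...]  # founder indices admissible for the family
    pi: np.ndarray  # initial distribution over states
    rho: float  # expected junctions per Morgan
    error: float  # genotyping error rate
    founders: np.ndarray  # (P, n_markers) alleles in {1, 2}
    gmap: GeneticMap
    usable: np.ndarray  # markers with complete founder data

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("junction density rho must be positive")
        if not 0.0 <= self.error < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("initial distribution must sum to 1")

    def transition(self, d_morgan: float) -> np.ndarray:
        """Transition matrix over a map distance of ``d_morgan`` Morgan."""
        if d_morgan < 0:
            raise ValueError("negative map distance")
        s = np.exp(-self.rho * d_morgan)
        k = len(self.states)
        return s * np.eye(k) + (1.0 - s) * np.tile(self.pi, (k, 1))


@dataclass
class IBDTensor:
    """Posterior founder-origin probabilities, offspring x marker x founder.

    Probabilities are zero for founders outside an offspring's family and
    sum to one over founders at every (offspring, marker).
    """

    individuals: list[str]
    gmap: GeneticMap
    n_founders: int
    probs: np.ndarray  # (N, n_markers, P)

    def predictors(self, marker: str) -> np.ndarray:
        """N x P genetic predictor matrix: twice the origin posterior."""
        return genetic_predictors(self, marker)

    def quality(self) -> np.ndarray:
        return ibd_quality(self)


def calibrate_junction_density(
    plan: CrossingPlan,
    gmap: GeneticMap,
    n_calibration: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """Estimate rho: realised junctions per Morgan per offspring genome.

    Simulates the plan's pedigree with ``n_calibration`` offspring in total
    (spread over families) and averages the junction count of the two
    haplotypes of each offspring. A selfed biparental line approaches the
    classical limit of 2 junctions per Morgan as generations accumulate.
    """
    if rng is None:
        rng = np.random.default_rng()
    genome_morgan = gmap.total_length_morgan()
    if genome_morgan <= 0:
        raise ValueError("zero-length genome: cannot calibrate junction density")
    per_fam = max(1, int(np.ceil(n_calibration / plan.n_families)))
    small = CrossingPlan(
        plan.design_type,
        tuple(Family(f.family_id, f.parents, per_fam) for f in plan.families),
        plan.final_generation,
        plan.n_founders,
    )
    mosaics = advance_population(small, gmap, rng)
    mean_junctions = float(np.mean([m.n_junctions() for m in mosaics]))
    return mean_junctions / genome_morgan


def build_hmm(
    family: Family,
    founders: np.ndarray,
    gmap: GeneticMap,
    rho: float,
    error: float = 0.005,
) -> OriginHMM:
    """HMM for one family; markers with missing founder data are excluded."""
    states = tuple(dict.fromkeys(family.parents))
    usable = ~np.any(
        np.isnan(founders.astype(float))[list(states), :], axis=0
    )
    pi = np.full(len(states), 1.0 / len(states))
    return OriginHMM(states, pi, float(rho), float(error), founders, gmap, usable)


def _emissions(
    hmm: OriginHMM, dosages: np.ndarray, marker_idx: np.ndarray
) -> np.ndarray:
    """(n_ind, n_markers, n_states) emission probabilities.

    Observed dosage 0/2 is compared with each founder's homozygous dosage;
    missing and heterozygous observations are uninformative (emit 1).
    """
    e = hmm.error
    founder_dos = (hmm.founders[list(hmm.states)][:, marker_idx] == 2) * 2.0
    obs = dosages[:, None, :]  # (n_ind, 1, m)
    informative = ~np.isnan(obs) & (obs != 1.0)
    match = obs == founder_dos[None, :, :]
    em = np.where(informative, np.where(match, 1.0 - e, e), 1.0)
    em = np.transpose(em, (0, 2, 1))  # (n_ind, m, states)
    # an observation incompatible with every admissible founder (possible
    # only at e = 0) carries no usable information: emit 1 for all states
    dead = em.sum(axis=2) == 0.0
    if dead.any():
        em[dead] = 1.0
    return em


def posterior_origins(
    hmm: OriginHMM, dosages: np.ndarray
) -> np.ndarray:
    """Forward-backward posteriors for one family's offspring.

    ``dosages``: (n_ind, n_markers) observed dosage over the full map, NaN
    for missing. Returns (n_ind, n_markers, n_states) posteriors at usable
    markers; unusable markers (missing founder data) get NaN.
    """
    n_ind = dosages.shape[0]
    k = len(hmm.states)
    out = np.full((n_ind, hmm.gmap.n_markers, k), np.nan)
    for chrom in hmm.gmap.chromosomes:
        sl = hmm.gmap.chrom_slice(chrom)
        idx = np.arange(sl.start, sl.stop)[hmm.usable[sl]]
        if idx.size == 0:
            continue
        pos = hmm.gmap.table["pos_cm"].to_numpy()[idx]
        d = np.diff(pos) / 100.0  # Morgan
        stay = np.exp(-hmm.rho * d)
        em = _emissions(hmm, dosages[:, idx], idx)
        m = idx.size
        # scaled forward pass; each f_t is normalised so sum_j f_t[j] = 1
        fwd = np.empty((n_ind, m, k))
        f = hmm.pi[None, :] * em[:, 0, :]
        fwd[:, 0, :] = f / f.sum(axis=1, keepdims=True)
        for t in range(1, m):
            pred = stay[t - 1] * fwd[:, t - 1, :] + (1.0 - stay[t - 1]) * hmm.pi
            f = pred * em[:, t, :]
            fwd[:, t, :] = f / f.sum(axis=1, keepdims=True)
        # backward pass, renormalised per step for stability
        bwd = np.empty((n_ind, m, k))
        bwd[:, m - 1, :] = 1.0
        for t in range(m - 2, -1, -1):
            nxt = em[:, t + 1, :] * bwd[:, t + 1, :]
            b = stay[t] * nxt + (1.0 - stay[t]) * (nxt @ hmm.pi)[:, None]
            bwd[:, t, :] = b / b.sum(axis=1, keepdims=True)
        post = fwd * bwd
        post /= post.sum(axis=2, keepdims=True)
        out[:, idx, :] = post
    return out


def ibd_posteriors(
    plan: CrossingPlan,
    founders: np.ndarray,
    genotypes: GenotypeTable,
    rho: float | dict[str, float],
    error: float = 0.005,
) -> IBDTensor:
    """Decode every family of a design into one posterior tensor.

    Diallel and NAM families are decoded independently with a uniform prior
    over their two parents; a MAGIC family uses all founders. ``rho`` may be
    one density for all families or a per-family mapping.
    """
    gmap = genotypes.gmap
    n_founders = founders.shape[0]
    probs = np.zeros((len(genotypes.individuals), gmap.n_markers, n_founders))
    row = 0
    for fam in plan.families:
        fam_rho = rho[fam.family_id] if isinstance(rho, dict) else rho
        hmm = build_hmm(fam, founders, gmap, fam_rho, error)
        rows = slice(row, row + fam.size)
        post = posterior_origins(hmm, genotypes.dosages[rows])
        for si, founder in enumerate(hmm.states):
            probs[rows, :, founder] = post[:, :, si]
        # unusable markers: fall back to the family prior
        bad = ~hmm.usable
        if bad.any():
            probs[rows][:, bad, :] = 0.0
            for si, founder in enumerate(hmm.states):
                probs[rows, bad, founder] = hmm.pi[si]
        row += fam.size
    return IBDTensor(list(genotypes.individuals), gmap, n_founders, probs)


def genetic_predictors(tensor: IBDTensor, marker: str) -> np.ndarray:
    """N x P predictor matrix: twice the founder-origin posterior.

    Rows sum to 2 (the expected count of alleles from each founder in a
    diploid).
    """
    j = tensor.gmap.marker_index(marker)
    return 2.0 * tensor.probs[:, j, :]


def ibd_quality(tensor: IBDTensor) -> np.ndarray:
    """Per-marker reconstruction quality.

    The maximum posterior per offspring, averaged over offspring, per
    marker. Values near 1 mean the parental origin is essentially known.
    """
    if tensor.probs.size == 0:
        raise ValueError("empty tensor")
    return tensor.probs.max(axis=2).mean(axis=0)
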