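"""Analytic expectations for heterozygosity decay in full-sib lines.

The probability that an ancestral heterozygous locus remains heterozygous
after t filial generations of brother-sister mating follows the linear
recursion

    P_t = P_{t-1} / 2 + P_{t-2} / 4,    P_0 = 1,  P_1 = 3/4,

equivalently P = 1 - F with the classical inbreeding-coefficient recursion
F_t = (1 + 2 F_{t-1} + F_{t-2}) / 4; the first sib-mated offspring
generation carries F = 1/4.  Asymptotically P decays by the golden-ratio
factor (1 + sqrt(5)) / 4 ~ 0.809 per generation, giving ~2 surviving loci
per 100,000 at generation 50.  Steady-state heterozygosity under recurrent
mutation is pi_s = 4 Ne mu (Ne = 2 for a sib-mating line), which for
mu = 30e-9 over a 500-Mb region predicts ~120 heterosites per strain and
~1,900 across a 16-strain panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "InbreedingParams",
    "HeterozygosityTrajectory",
    "sib_mating_trajectory",
    "equilibrium_heterozygosity",
    "residual_ancestral_het",
    "miscall_probability_bound",
    "parallel_enrichment",
    "ParallelStats",
]

#: asymptotic per-generation retention factor of the sib-mating recursion
SIB_DECAY_RATE = (1.0 + math.sqrt(5.0)) / 4.0


@dataclass(frozen=True)
class InbreedingParams:
    """mu per bp per generation, effective size, region length, panel size."""

    mu: float = 30e-9
    Ne: float = 2.0
    L: int = 500_000_000
    n_strains: int = 16
    generations: int = 50

    def __post_init__(self) -> None:
        if self.mu < 0 or self.Ne < 1 or self.L < 1:
            raise ValueError("require mu >= 0, Ne >= 1, L >= 1")


@dataclass(frozen=True)
class HeterozygosityTrajectory:
    """P_t for t = 0..T: probability an ancestral het locus is still het."""

    P: np.ndarray

    def __post_init__(self) -> None:
        if self.P[0] != 1.0 or (np.diff(self.P) > 1e-15).any() or (self.P < 0).any():
            raise ValueError("trajectory must start at 1 and be nonincreasing")

    @property
    def generations(self) -> int:
        return self.P.size - 1

    def fixed_fraction(self, t: int | None = None) -> float:
        """1 - P_t: fraction of ancestral het loci fixed by generation t."""
        return 1.0 - float(self.P[t if t is not None else -1])


def sib_mating_trajectory(generations: int) -> HeterozygosityTrajectory:
    """Iterate the full-sib recursion for the given number of generations."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    P = np.empty(generations + 1)
    P[0] = 1.0
    if generations >= 1:
        P[1] = 0.75
    for t in range(2, generations + 1):
        P[t] = P[t - 1] / 2.0 + P[t - 2] / 4.0
    return HeterozygosityTrajectory(P=P)


def equilibrium_heterozygosity(params: InbreedingParams) -> dict[str, float]:
    """pi_s = 4 Ne mu and the implied heterosite counts.

    Returns per-site equilibrium heterozygosity, the expected steady-state
    heterosite count per strain over ``L`` bases, and the panel total over
    ``n_strains`` strains.
    """
    pi_s = 4.0 * params.Ne * params.mu
    per_strain = pi_s * params.L
    return {
        "pi_s": pi_s,
        "per_strain": per_strain,
        "panel": per_strain * params.n_strains,
    }


def residual_ancestral_het(
    ancestral_rate: float,
    generations: int = 50,
    p_remaining: float | None = None,
) -> dict[str, float]:
    """Genome-wide residual ancestral heterozygosity after inbreeding.

    ``ancestral_rate`` is the per-position ancestral (founder)
    heterozygosity, e.g. 1/1500.  ``p_remaining`` overrides the recursion
    value P_T, allowing the conventional rounded residual 2e-5 at
    generation 50 to be used for a conservative '1 in N' bound.  Returns the
    residual fraction and its reciprocal.
    """
    if not (0.0 < ancestral_rate <= 1.0):
        raise ValueError("ancestral_rate must lie in (0, 1]")
    if p_remaining is None:
        p_remaining = float(sib_mating_trajectory(generations).P[-1])
    fraction = ancestral_rate * p_remaining
    return {
        "fraction": fraction,
        "one_in": math.inf if fraction == 0 else 1.0 / fraction,
        "p_remaining": p_remaining,
    }


def miscall_probability_bound(phred: float, n_allele_calls: int) -> float:
    """Independence upper bound on jointly miscalling n alleles at a Phred.

    Each call errs with probability at most 10^(-phred/10); assuming
    independent errors the joint probability is that raised to the number of
    minor-allele calls (e.g. 8 calls for 4 homozygous strains).
    """
    if phred < 0 or n_allele_calls < 1:
        raise ValueError("require phred >= 0 and n_allele_calls >= 1")
    return float((10.0 ** (-phred / 10.0)) ** n_allele_calls)


@dataclass
class ParallelStats:
    """Concordance of heterosites with variants in other strains."""

    n_heterosites: int
    obs_het_hom: float  # fraction of heterosites that are a homosite elsewhere
    exp_het_hom: float
    fold_het_hom: float
    obs_het_het: float  # fraction of heterosites heterozygous elsewhere too
    exp_het_het: float
    fold_het_het: float
    per_strain: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "n_heterosites": self.n_heterosites,
            "obs_het_hom": self.obs_het_hom,
            "exp_het_hom": self.exp_het_hom,
            "fold_het_hom": self.fold_het_hom,
            "obs_het_het": self.obs_het_het,
            "exp_het_het": self.exp_het_het,
            "fold_het_het": self.fold_het_het,
        }


def _fold(obs: float, exp: float) -> float:
    if obs == 0:
        return 0.0
    return math.inf if exp == 0 else obs / exp


def parallel_enrichment(
    het_positions_by_strain: dict[str, set],
    hom_positions_by_strain: dict[str, set],
    L: int,
) -> ParallelStats:
    """Observed vs stochastic positional concordance of recent heterosites.

    For every heterosite of each strain, checks whether the identical
    position carries (a) a minor-allele homosite or (b) a heterosite in at
    least one *other* strain.  The stochastic expectation places each
    heterosite uniformly over ``L`` positions, so the per-heterosite hit
    probability is (number of qualifying target positions) / L; fold
    enrichment is observed / expected.  Positions may be plain integers or
    (contig, position) tuples.
    """
    all_positions = [
        p for s in (het_positions_by_strain, hom_positions_by_strain) for v in s.values() for p in v
    ]
    numeric = [p for p in all_positions if isinstance(p, (int, np.integer))]
    if numeric and L <= max(numeric):
        raise ValueError(f"L={L} smaller than maximum position {max(numeric)}")
    strains = sorted(set(het_positions_by_strain) | set(hom_positions_by_strain))
    per_strain: dict[str, dict[str, float]] = {}
    n_total = 0
    hits_hom = hits_het = 0
    exp_hom_sum = exp_het_sum = 0.0
    for s in strains:
        hets = het_positions_by_strain.get(s, set())
        other_homs: set = set()
        other_hets: set = set()
        for o in strains:
            if o == s:
                continue
            other_homs |= hom_positions_by_strain.get(o, set())
            other_hets |= het_positions_by_strain.get(o, set())
        n = len(hets)
        oh = sum(1 for p in hets if p in other_homs)
        ohh = sum(1 for p in hets if p in other_hets)
        e_hom = len(other_homs) / L
        e_het = len(other_hets) / L
        per_strain[s] = {
            "n_heterosites": n,
            "obs_het_hom": oh / n if n else 0.0,
            "exp_het_hom": e_hom,
            "obs_het_het": ohh / n if n else 0.0,
            "exp_het_het": e_het,
        }
        n_total += n
        hits_hom += oh
        hits_het += ohh
        exp_hom_sum += n * e_hom
        exp_het_sum += n * e_het
    obs_hom = hits_hom / n_total if n_total else 0.0
    obs_het = hits_het / n_total if n_total else 0.0
    exp_hom = exp_hom_sum / n_total if n_total else 0.0
    exp_het = exp_het_sum / n_total if n_total else 0.0
    return ParallelStats(
        n_heterosites=n_total,
        obs_het_hom=obs_hom,
        exp_het_hom=exp_hom,
        fold_het_hom=_fold(obs_hom, exp_hom),
        obs_het_het=obs_het,
        exp_het_het=exp_het,
        fold_het_het=_fold(obs_het, exp_het),
        per_strain=per_strain,
    )
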