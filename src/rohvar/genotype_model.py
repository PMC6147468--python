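"""Bayesian diploid genotype calling from biallelic read pileups.

For a site with ``r`` reference and ``a`` alternate reads, the likelihood of
each genotype H in {hom-ref, het, hom-alt} is binomial with per-read
alternate probability eps, 0.5, 1-eps respectively (symmetric sequencing
error eps). Combined with a prior P(H|G) over the three genotypes, the
posterior is

    P(H | G, R) = P(H|G) P(R|H) / P(R|G),   P(R|G) = sum_H P(H|G) P(R|H)

and the call is H* = argmax_H P(H|G,R), made only when the site has at
least ``min_reads`` reads; an exact posterior tie yields a no-call rather
than an arbitrary pick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.stats import binom


def _binom_pmf(k: int, n: int, p: float) -> float:
    """Direct-formula binomial pmf.

    The product form keeps the ref/alt symmetry bitwise exact (float
    multiplication commutes), which the library pmf does not guarantee;
    exact ties between the mirrored homozygote likelihoods must survive so
    the caller can refuse to break them. Falls back to the log-space pmf
    when the direct product under- or overflows.
    """
    try:
        val = math.comb(n, k) * p**k * (1.0 - p) ** (n - k)
    except OverflowError:
        return float(np.exp(binom.logpmf(k, n, p)))
    if val > 0.0:
        return val
    return float(np.exp(binom.logpmf(k, n, p)))

GENOTYPES = ("hom_ref", "het", "hom_alt")
#: integer codes used across the package: 0 hom-ref, 1 het, 2 hom-alt, -9 missing
GENOTYPE_CODE = {"hom_ref": 0, "het": 1, "hom_alt": 2}
MISSING = -9

UNIFORM_PRIOR: Mapping[str, float] = {g: 1.0 / 3.0 for g in GENOTYPES}


class GenotypeModelError(ValueError):
    pass


@dataclass(frozen=True)
class ReadPileup:
    """Reference/alternate read counts at one site for one sample."""

    ref_count: int
    alt_count: int
    error_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise GenotypeModelError("read counts must be non-negative")
        if not 0.0 < self.error_rate < 0.5:
            raise GenotypeModelError("error_rate must lie in the open interval (0, 0.5)")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class GenotypePosterior:
    prior: Mapping[str, float]
    likelihood: Mapping[str, float]
    posterior: Mapping[str, float]
    map_genotype: Optional[str]
    total_reads: int

    def __post_init__(self) -> None:
        for m in (self.prior, self.likelihood, self.posterior):
            if set(m) != set(GENOTYPES):
                raise GenotypeModelError("mappings must cover exactly the three genotypes")
        if abs(sum(self.posterior.values()) - 1.0) > 1e-9:
            raise GenotypeModelError("posterior does not sum to 1")


def genotype_posterior(
    pileup: ReadPileup, prior: Mapping[str, float] = UNIFORM_PRIOR
) -> GenotypePosterior:
    """Posterior over the three diploid genotypes given a pileup."""
    if set(prior) != set(GENOTYPES):
        raise GenotypeModelError("prior must cover exactly the three genotypes")
    ptot = float(sum(prior.values()))
    if ptot <= 0.0:
        raise GenotypeModelError("prior has zero total mass")
    prior = {g: float(prior[g]) / ptot for g in GENOTYPES}

    n, a, r = pileup.total, pileup.alt_count, pileup.ref_count
    eps = pileup.error_rate
    # hom-alt evaluated as the mirrored binomial in the ref count with the
    # same eps: analytically identical to Binom(a; n, 1-eps) and bitwise
    # symmetric under ref<->alt (1 - (1 - eps) is not eps in floats)
    lik = {
        "hom_ref": _binom_pmf(a, n, eps),
        "het": _binom_pmf(a, n, 0.5),
        "hom_alt": _binom_pmf(r, n, eps),
    }
    evidence = sum(prior[g] * lik[g] for g in GENOTYPES)
    if evidence <= 0.0:
        # numerically vanished likelihoods: fall back to log-space
        loglik = {
            "hom_ref": binom.logpmf(a, n, eps),
            "het": binom.logpmf(a, n, 0.5),
            "hom_alt": binom.logpmf(r, n, eps),
        }
        logs = {
            g: (np.log(prior[g]) if prior[g] > 0 else -np.inf) + loglik[g]
            for g in GENOTYPES
        }
        mx = max(logs.values())
        w = {g: np.exp(l - mx) if np.isfinite(l) else 0.0 for g, l in logs.items()}
        z = sum(w.values())
        post = {g: w[g] / z for g in GENOTYPES}
    else:
        post = {g: prior[g] * lik[g] / evidence for g in GENOTYPES}

    best = max(post.values())
    winners = [g for g in GENOTYPES if post[g] == best]
    map_g = winners[0] if len(winners) == 1 else None
    return GenotypePosterior(
        prior=prior, likelihood=lik, posterior=post, map_genotype=map_g, total_reads=n
    )


def call_genotype(posterior: GenotypePosterior, min_reads: int = 2) -> Optional[str]:
    """MAP genotype when supported by at least ``min_reads`` reads, else no-call.

    Exact posterior ties are no-calls: a tie carries no evidence to prefer
    either genotype and a forced pick would contaminate downstream
    segregation filtering.
    """
    if posterior.total_reads < min_reads:
        return None
    return posterior.map_genotype


def call_pileup(
    pileup: ReadPileup,
    prior: Mapping[str, float] = UNIFORM_PRIOR,
    min_reads: int = 2,
) -> int:
    """Convenience: pileup -> integer genotype code (MISSING on no-call)."""
    call = call_genotype(genotype_posterior(pileup, prior), min_reads=min_reads)
    return MISSING if call is None else GENOTYPE_CODE[call]
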