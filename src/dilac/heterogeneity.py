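"""Binomial homogeneity model and the mixed-state depletion statistic.

If every cell in a population imports each molecule of the target amino acid
independently with the same probability P, the number of imported (light)
residues among the n target sites of a peptide follows Binomial(n, P).  The
population-level P is recovered from the observed state fractions as the
mean number of imported sites divided by n.  Distinct producer and consumer
subpopulations instead put all mass on the fully-heavy and fully-light
states, so the observed mixed fraction falls far below the binomial
expectation; the ratio expected/observed mixed is the depletion statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

from .errors import UnnormalizedProfileError

_SUM_TOL = 1e-6


def _as_fractions(fractions: Sequence[float]) -> np.ndarray:
    arr = np.asarray(fractions, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("fractions must be a 1-D array over states k = 0..n")
    if np.any(arr < -1e-12):
        raise UnnormalizedProfileError("negative state fraction")
    if abs(arr.sum() - 1.0) > _SUM_TOL:
        raise UnnormalizedProfileError(f"state fractions sum to {arr.sum():.6f}, not 1")
    return arr


def import_probability(fractions: Sequence[float]) -> float:
    """Per-site import probability P = sum_k k*f_k / n.

    ``fractions`` are ordered by the number k of imported (light) residues,
    k = 0 (producer) .. n (consumer).
    """
    arr = _as_fractions(fractions)
    n = arr.size - 1
    return float(np.dot(np.arange(n + 1), arr) / n)


def expected_distribution(p: float, n_sites: int) -> np.ndarray:
    """Binomial pmf over k = 0..n imported sites under homogeneity."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"P must be in [0, 1], got {p}")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    k = np.arange(n_sites + 1)
    # defining formula C(n,k) p^k (1-p)^(n-k); robust at the p = 0/1 boundaries
    with np.errstate(invalid="ignore"):
        pmf = special.comb(n_sites, k) * p**k * (1.0 - p) ** (n_sites - k)
    return pmf


def mixed_fraction(fractions: Sequence[float]) -> float:
    """Total mass on intermediate states 0 < k < n."""
    arr = np.asarray(fractions, dtype=float)
    return float(arr[1:-1].sum())


@dataclass(frozen=True)
class HomogeneityModel:
    p: float
    n_sites: int

    @property
    def expected_fractions(self) -> np.ndarray:
        return expected_distribution(self.p, self.n_sites)


@dataclass(frozen=True)
class HeterogeneityResult:
    p_hat: float
    n_sites: int
    expected_mixed: float
    observed_mixed: float
    depletion_ratio: float  # expected / observed; +inf when observed mixed is 0
    observed_mixed_zero: bool
    chi2: Optional[float]
    p_value: Optional[float]
    dof: Optional[int]
    verdict: str  # "heterogeneous" | "homogeneous"


def depletion_test(
    observed: Sequence[float],
    m: Optional[float] = None,
    ratio_threshold: float = 2.0,
    alpha: float = 0.05,
) -> HeterogeneityResult:
    """Compare the observed mixed-state fraction with the homogeneous expectation.

    ``observed`` are the state fractions over k = 0..n; n is inferred from the
    length.  With an effective observation count ``m`` a chi-square
    goodness-of-fit of observed counts against the fitted binomial is attached
    (df = n - 1: n+1 categories, one constraint, one estimated parameter).
    The verdict is "heterogeneous" when the depletion ratio exceeds
    ``ratio_threshold`` or, when the test is run, p < alpha.
    """
    arr = _as_fractions(observed)
    n = arr.size - 1
    p_hat = import_probability(arr)
    expected = expected_distribution(p_hat, n)
    exp_mixed = mixed_fraction(expected)
    obs_mixed = mixed_fraction(arr)

    zero = obs_mixed <= 0.0
    ratio = math.inf if zero else exp_mixed / obs_mixed

    chi2 = p_value = dof = None
    if m is not None:
        if m <= 0:
            raise ValueError("effective count m must be positive")
        dof = n - 1
        if dof >= 1:
            obs_counts = arr * m
            exp_counts = expected * m
            support = exp_counts > 0
            if np.any(~support & (obs_counts > 0)):
                chi2 = math.inf  # observed mass on a zero-expectation state
            else:
                chi2 = float(
                    ((obs_counts[support] - exp_counts[support]) ** 2 / exp_counts[support]).sum()
                )
            p_value = float(stats.chi2.sf(chi2, dof)) if math.isfinite(chi2) else 0.0

    heterogeneous = ratio > ratio_threshold
    if p_value is not None:
        heterogeneous = heterogeneous or p_value < alpha
    return HeterogeneityResult(
        p_hat=p_hat,
        n_sites=n,
        expected_mixed=float(exp_mixed),
        observed_mixed=float(obs_mixed),
        depletion_ratio=float(ratio) if not zero else math.inf,
        observed_mixed_zero=zero,
        chi2=chi2,
        p_value=p_value,
        dof=dof,
        verdict="heterogeneous" if heterogeneous else "homogeneous",
    )
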