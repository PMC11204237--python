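"""Genome-track colocalization via the index of overlapping (IO).

The statistic asks whether the records of track B (here: lincRNA loci) sit
unusually close to — in fact inside — the records of track A (here: genes),
relative to a permutation null that swaps stretch lengths between pairs.

For each A record, the nearest B record is found by center distance, giving
pair ``k`` with center distance ``L_k`` and stretch lengths ``a_k, b_k``::

    IO_k = (L_k - (a_k + b_k)/2) / (L_k + (a_k + b_k)/2)

IO_k is -1 when the centers coincide, 0 when the center distance equals the
mean combined half-length, and approaches +1 for remote stretches. The null
is the *complete* pairwise permutation: for every unordered pair (k, k')
the combined lengths are swapped while the distances stay in place,

    IO_kk' = 1/2 [ (L_k - s_k'/2)/(L_k + s_k'/2) + (L_k' - s_k/2)/(L_k' + s_k/2) ]

with ``s = a + b``. The observed mean IO is compared to the mean of IO_kk'
over all K(K-1)/2 swaps; their difference ΔI, divided by an effective
standard deviation, yields a z-like statistic ζ that is approximately
standard Gaussian under the null, so significance uses two-sided normal
tails.

Two variance estimates for ΔI are computed:

* ``var_delta_approx`` — the additive approximation
  σ²(I)/K + 2 σ²(I_kk')/K − 2 Cov, with Cov the empirical covariance term
  between observed and permuted indices. This uses the *total* variance of
  the permutation kernel and systematically overstates Var(ΔI) (calibration
  simulations give sd(ζ) ≈ 0.67 under the null).
* ``var_delta`` — the exact first-order U-statistic (Hájek projection)
  variance: ΔI is the U-statistic with kernel
  h(k,k') = (IO_k + IO_k')/2 − IO_kk', so
  Var(ΔI) ≈ (4/K) Var( h̄₁ ) with h̄₁(k) the mean of h(k, ·). This is the
  variance ζ is normalised by; under null simulations ζ is then standard
  Gaussian to within sampling error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _st

from .intervals import GenomicInterval, Track

__all__ = [
    "ColocalizationParams",
    "NeighborPair",
    "PermutationSummary",
    "ColocalizationResult",
    "NoPairsError",
    "DegenerateVarianceError",
    "io_index",
    "pair_nearest_neighbors",
    "permuted_pair_io",
    "permutation_summary",
    "zeta_statistic",
    "z_to_pvalue",
    "colocalize",
]


class NoPairsError(ValueError):
    """No nearest-neighbor pairs survived pairing/filtering."""


class DegenerateVarianceError(ArithmeticError):
    """The effective variance of ΔI is not positive; ζ is undefined.

    Happens with very small K or when all pairs are identical (every
    variance component is exactly zero)."""


@dataclass(frozen=True)
class ColocalizationParams:
    """Tuning knobs of the colocalization statistic.

    max_pair_size
        Pairs whose center distance L exceeds this are discarded (bp).
        The 100 kb default restricts the analysis to genuinely local
        neighbor relationships.
    alpha
        Two-sided significance level for the colocalization call.
    direction
        ``"a"``: each A record takes its nearest B record (default; B
        records may serve several A records). ``"b"``: roles swapped.
    """

    max_pair_size: float = 100_000.0
    alpha: float = 0.05
    direction: str = "a"

    def __post_init__(self) -> None:
        if self.max_pair_size <= 0:
            raise ValueError("max_pair_size must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.direction not in {"a", "b"}:
            raise ValueError("direction must be 'a' or 'b'")


def io_index(L: float, a: float, b: float) -> float:
    """Index of overlapping for one nearest-neighbor pair.

    ``L`` is the distance between stretch centers (bp, >= 0); ``a`` and
    ``b`` are the stretch lengths. Returns -1 exactly when L = 0, grows
    strictly with L at fixed lengths, and stays below +1 for any finite
    lengths.
    """
    if L < 0:
        raise ValueError(f"center distance L must be >= 0, got {L}")
    if a < 0 or b < 0:
        raise ValueError("stretch lengths must be non-negative")
    half = (a + b) / 2.0
    denom = L + half
    if denom == 0.0:
        raise ZeroDivisionError("IO undefined for L = 0 with zero-length stretches (0/0)")
    return (L - half) / denom


@dataclass(frozen=True)
class NeighborPair:
    """One nearest-neighbor pair: an A stretch, its nearest B stretch, and
    the derived quantities entering the statistic."""

    a_iv: GenomicInterval
    b_iv: GenomicInterval
    L: float
    a: int
    b: int
    io: float

    @classmethod
    def from_intervals(cls, a_iv: GenomicInterval, b_iv: GenomicInterval) -> "NeighborPair":
        L = abs(a_iv.center - b_iv.center)
        return cls(a_iv, b_iv, L, a_iv.length, b_iv.length, io_index(L, a_iv.length, b_iv.length))


def permuted_pair_io(pair_k: NeighborPair, pair_k2: NeighborPair) -> float:
    """Symmetrized length-swapped index for one unordered pair of pairs.

    The combined lengths of the two pairs are exchanged while each center
    distance stays in place; the two swapped values are averaged, so the
    result is symmetric in its arguments.
    """
    s_k = (pair_k.a + pair_k.b) / 2.0
    s_k2 = (pair_k2.a + pair_k2.b) / 2.0
    d1 = pair_k.L + s_k2
    d2 = pair_k2.L + s_k
    if d1 == 0.0 or d2 == 0.0:
        raise ZeroDivisionError("permuted IO undefined: zero denominator after length swap")
    return 0.5 * ((pair_k.L - s_k2) / d1 + (pair_k2.L - s_k) / d2)


def pair_nearest_neighbors(
    A: Track, B: Track, params: ColocalizationParams = ColocalizationParams()
) -> list[NeighborPair]:
    """Pair every A record with the same-chromosome B record whose center is
    nearest to its own.

    B records may be reused by several A records. A records on chromosomes
    absent from B are dropped, as are pairs with center distance above
    ``params.max_pair_size``. Distance ties are broken toward the B record
    with the smaller start (then smaller end), which makes the output
    deterministic.
    """
    if len(A) == 0 or len(B) == 0:
        raise NoPairsError("both tracks must be non-empty")
    if params.direction == "b":
        A, B = B, A

    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in B:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    # sort B candidates by (center, start, end) so that, among records at a
    # tied distance, the first occurrence of a center has the smallest start
    b_sorted: dict[str, tuple[np.ndarray, list[GenomicInterval]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: (iv.center, iv.start, iv.end))
        b_sorted[chrom] = (np.array([iv.center for iv in ivs]), ivs)

    pairs: list[NeighborPair] = []
    for a_iv in A:
        entry = b_sorted.get(a_iv.chrom)
        if entry is None:
            continue
        centers, ivs = entry
        c = a_iv.center
        j = int(np.searchsorted(centers, c))
        best: Optional[GenomicInterval] = None
        best_d = math.inf
        for cand in (j - 1, j):
            if 0 <= cand < len(ivs):
                # first occurrence of this center → smallest start among ties
                first = int(np.searchsorted(centers, centers[cand], side="left"))
                d = abs(centers[first] - c)
                if d < best_d or (d == best_d and best is not None and (
                    (ivs[first].start, ivs[first].end) < (best.start, best.end)
                )):
                    best, best_d = ivs[first], d
        if best is None or best_d > params.max_pair_size:
            continue
        pairs.append(NeighborPair.from_intervals(a_iv, best))
    if not pairs:
        raise NoPairsError(
            "no nearest-neighbor pairs found; check chromosome naming of the two "
            "tracks and the max_pair_size setting"
        )
    return pairs


@dataclass(frozen=True)
class PermutationSummary:
    """Aggregates of the observed indices and the complete permutation null."""

    K: int
    io_mean: float
    io_perm_mean: float
    delta_i: float
    var_io: float
    var_io_perm: float
    cov: float
    var_delta: float          # first-order U-statistic (projection) variance of ΔI
    var_delta_approx: float   # additive approximation σ²(I)/K + 2σ²(I_kk')/K − 2Cov


def _summary_from_arrays(L: np.ndarray, s: np.ndarray) -> PermutationSummary:
    """Vectorized aggregates over all K(K-1)/2 length swaps.

    O(K²) time and memory (a K×K matrix); fine for the K ≤ a few thousand
    regime of gene-scale tracks.
    """
    K = L.size
    if K < 2:
        raise ValueError("permutation null requires at least 2 pairs")
    io = (L - s / 2.0) / (L + s / 2.0)
    io_mean = float(io.mean())

    M = (L[:, None] - s[None, :] / 2.0) / (L[:, None] + s[None, :] / 2.0)
    P = 0.5 * (M + M.T)  # P[k, k'] = IO_kk'; symmetric, diagonal unused
    iu = np.triu_indices(K, 1)
    perm = P[iu]
    perm_mean = float(perm.mean())
    delta_i = io_mean - perm_mean

    var_io = float(io.var())
    var_perm = float(perm.var())

    dev = io - io_mean
    C = P - perm_mean
    np.fill_diagonal(C, 0.0)
    # 2/(K²(K−1)) Σ_{k<k'} [(I_k−Ī)(P_kk'−⟨I⟩_p) + (I_k'−Ī)(P_kk'−⟨I⟩_p)]
    cov = float((dev @ C.sum(axis=1)) * 2.0 / (K * K * (K - 1)))

    var_approx = var_io / K + 2.0 * var_perm / K - 2.0 * cov

    # Hájek projection of the U-statistic ΔI = mean over pairs of
    # h(k,k') = (I_k + I_k')/2 − P_kk'
    H = 0.5 * (io[:, None] + io[None, :]) - P
    np.fill_diagonal(H, 0.0)
    h1 = H.sum(axis=1) / (K - 1)
    var_proj = 4.0 / K * float(h1.var(ddof=1))

    return PermutationSummary(
        K=K,
        io_mean=io_mean,
        io_perm_mean=perm_mean,
        delta_i=delta_i,
        var_io=var_io,
        var_io_perm=var_perm,
        cov=cov,
        var_delta=var_proj,
        var_delta_approx=var_approx,
    )


def permutation_summary(pairs: Sequence[NeighborPair]) -> PermutationSummary:
    """Observed-mean / permuted-mean aggregates for a set of pairs.

    ``delta_i`` equals ``io_mean - io_perm_mean`` identically (the same
    quantity computed once; the double-sum form is checked against a naive
    oracle in the test suite).
    """
    if len(pairs) < 2:
        raise ValueError("permutation null undefined for fewer than 2 pairs")
    L = np.array([p.L for p in pairs], dtype=float)
    s = np.array([p.a + p.b for p in pairs], dtype=float)
    return _summary_from_arrays(L, s)


def zeta_statistic(summary: PermutationSummary) -> tuple[float, float]:
    """Effective standard deviation of ΔI and the normalised statistic ζ.

    Uses the projection variance (see module docstring); raises
    :class:`DegenerateVarianceError` when it is not positive, which also
    covers the all-pairs-identical case where every variance term vanishes.
    """
    if not (summary.var_delta > 0.0) or not math.isfinite(summary.var_delta):
        raise DegenerateVarianceError(
            f"effective variance of ΔI is {summary.var_delta!r} (K={summary.K}); "
            "ζ and p are undefined — tracks may be constant or K too small"
        )
    sigma_eff = math.sqrt(summary.var_delta)
    return sigma_eff, summary.delta_i / sigma_eff


def z_to_pvalue(z: float) -> float:
    """Two-sided standard-normal tail probability, 2·Φ(−|z|)."""
    if not math.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * _st.norm.sf(abs(z)))


@dataclass(frozen=True)
class ColocalizationResult:
    """Full output of one two-track colocalization analysis."""

    K: int
    io_mean: float
    io_perm_mean: float
    delta_i: float
    var_io: float
    var_io_perm: float
    cov: float
    sigma_eff: float
    sigma_eff_approx: float
    zeta: float
    p_two_sided: float
    colocalized: bool
    n_track_a: int = 0
    n_track_b: int = 0
    n_b_records_used: int = 0  # distinct B records serving as nearest neighbors

    def to_row(self) -> dict:
        return {
            "IO": self.io_mean,
            "z(IO)": self.zeta,
            "colocalization": "+" if self.colocalized else "-",
            "p(IO)": self.p_two_sided,
            "pairs": self.K,
            "n_a_records": self.n_track_a,
            "n_b_records": self.n_track_b,
        }


def colocalize(
    A: Track, B: Track, params: ColocalizationParams = ColocalizationParams()
) -> ColocalizationResult:
    """Run the full chain: pairing → permutation summary → ζ → p.

    ``colocalized`` is True when the two-sided p is at or below
    ``params.alpha`` *and* the mean IO is negative, i.e. B centers lie
    inside their paired A stretches on average.
    """
    pairs = pair_nearest_neighbors(A, B, params)
    summary = permutation_summary(pairs)
    sigma_eff, zeta = zeta_statistic(summary)
    p = z_to_pvalue(zeta)
    sigma_approx = (
        math.sqrt(summary.var_delta_approx) if summary.var_delta_approx > 0 else float("nan")
    )
    return ColocalizationResult(
        K=summary.K,
        io_mean=summary.io_mean,
        io_perm_mean=summary.io_perm_mean,
        delta_i=summary.delta_i,
        var_io=summary.var_io,
        var_io_perm=summary.var_io_perm,
        cov=summary.cov,
        sigma_eff=sigma_eff,
        sigma_eff_approx=sigma_approx,
        zeta=zeta,
        p_two_sided=p,
        colocalized=(p <= params.alpha) and (summary.io_mean < 0.0),
        n_track_a=len(A),
        n_track_b=len(B),
        n_b_records_used=len({(p_.b_iv.chrom, p_.b_iv.start, p_.b_iv.end) for p_ in pairs}),
    )
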