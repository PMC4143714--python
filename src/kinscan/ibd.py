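"""Pairwise IBD estimation from unlinked biallelic SNP genotypes.

The relatedness of a pair is summarized by p = (p0, p1, p2), the
probability that a randomly sampled autosomal marker carries 0, 1 or 2
alleles shared identically by descent.  With genotypes G_m and IBD
state D_m at marker m, the log-likelihood of p is the marker mixture

    L(p) = sum_m log sum_i P(G_m | D_m = i) p_i,

maximized over the 2-simplex by EM.  A method-of-moments estimator from
identity-by-state (IBS) counts — the approach PLINK takes — is provided
as a comparator; it is faster but noisier than the MLE.

All conditional probabilities assume Hardy-Weinberg equilibrium and
marker independence (markers should be LD-pruned upstream).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .pedio import MISSING, GenotypeMatrix


class IBDVector(NamedTuple):
    """A point (p0, p1, p2) on the 2-simplex."""

    p0: float
    p1: float
    p2: float

    @classmethod
    def from_array(cls, arr) -> "IBDVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (3,):
            raise ValueError("IBD vector must have three components")
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError(f"IBD components outside [0, 1]: {arr}")
        if abs(arr.sum() - 1.0) > 1e-12:
            raise ValueError(f"IBD components sum to {arr.sum()}, not 1")
        return cls(*np.clip(arr, 0.0, 1.0))


def kinship_from_ibd(ibd) -> float:
    """Kinship coefficient phi = p1/4 + p2/2 of an IBD distribution."""
    p0, p1, p2 = ibd
    return p1 / 4.0 + p2 / 2.0


class MonomorphicMarkerError(ValueError):
    """Conditional probabilities need a frequency strictly inside (0, 1)."""


class NoDataError(ValueError):
    """The pair shares no usable markers (commark = 0)."""


@dataclass
class PairGenotypeData:
    """Aligned genotypes of one pair over jointly usable markers.

    Markers missing in either member, or with an undefined/monomorphic
    frequency, are dropped; ``commark`` is the number of markers that
    actually enter the likelihood.
    """

    g1: np.ndarray
    g2: np.ndarray
    freqs: np.ndarray
    marker_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.g1 = np.asarray(self.g1, dtype=np.int8)
        self.g2 = np.asarray(self.g2, dtype=np.int8)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if not (self.g1.shape == self.g2.shape == self.freqs.shape):
            raise ValueError("pair genotype vectors and frequencies must align")

    @property
    def commark(self) -> int:
        return self.g1.size


def make_pair_data(geno: GenotypeMatrix, freqs: np.ndarray, i: int, j: int) -> PairGenotypeData:
    """Extract jointly non-missing, polymorphic markers for pair (i, j)."""
    g1, g2 = geno.codes[i], geno.codes[j]
    freqs = np.asarray(freqs, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING) & usable_freq_mask(freqs)
    idx = np.flatnonzero(ok)
    return PairGenotypeData(g1[idx], g2[idx], freqs[idx], marker_index=idx)


def usable_freq_mask(freqs: np.ndarray) -> np.ndarray:
    """Markers whose frequency supports the conditional model."""
    freqs = np.asarray(freqs, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0)


# ---------------------------------------------------------------------------
# conditional genotype-pair probabilities


def pair_prob_table(freqs: np.ndarray) -> np.ndarray:
    """P(G1, G2 | D = d) for every marker, genotype pair and IBD state.

    Returns an array of shape (M, 9, 3): axis 1 indexes the unordered
    genotype pair as ``3*g1 + g2`` (minor-allele dosages), axis 2 the
    IBD state d.  With minor frequency q and major frequency p = 1 - q,
    under HWE:

    * d = 0: the genotypes are independent, P(g1) P(g2);
    * d = 1: one allele is shared, e.g. P(2,2|1) = q^3, P(1,1|1) = pq;
    * d = 2: both alleles shared, P(g, g | 2) = P(g), zero off-diagonal.
    """
    q = np.asarray(freqs, dtype=float)
    if np.any(~usable_freq_mask(q)):
        raise MonomorphicMarkerError("allele frequencies must lie strictly in (0, 1)")
    p = 1.0 - q
    hwe = np.stack([p * p, 2 * p * q, q * q], axis=-1)  # (M, 3): P(g)
    M = q.shape[0]
    table = np.zeros((M, 9, 3))
    # d = 0: independence
    for g1 in range(3):
        for g2 in range(3):
            table[:, 3 * g1 + g2, 0] = hwe[:, g1] * hwe[:, g2]
    # d = 1: one shared allele
    d1 = {
        (0, 0): p ** 3, (0, 1): p * p * q, (1, 0): p * p * q,
        (1, 1): p * q, (1, 2): p * q * q, (2, 1): p * q * q,
        (2, 2): q ** 3, (0, 2): np.zeros(M), (2, 0): np.zeros(M),
    }
    for (g1, g2), val in d1.items():
        table[:, 3 * g1 + g2, 1] = val
    # d = 2: identical genotypes
    for g in range(3):
        table[:, 3 * g + g, 2] = hwe[:, g]
    return table


def genotype_pair_prob(g1: int, g2: int, d: int, freq: float) -> float:
    """P(G1 = g1, G2 = g2 | D = d) at one marker of minor frequency ``freq``."""
    if g1 not in (0, 1, 2) or g2 not in (0, 1, 2):
        raise ValueError("genotype dosages must be 0, 1 or 2")
    if d not in (0, 1, 2):
        raise ValueError("IBD state must be 0, 1 or 2")
    return float(pair_prob_table(np.array([freq]))[0, 3 * g1 + g2, d])


def _cond_probs(pair: PairGenotypeData) -> np.ndarray:
    """(commark, 3) conditional probabilities for the pair's markers."""
    if pair.commark == 0:
        raise NoDataError("pair shares no usable markers")
    table = pair_prob_table(pair.freqs)
    cat = 3 * pair.g1.astype(np.intp) + pair.g2.astype(np.intp)
    return table[np.arange(pair.commark), cat, :]


def loglik(pair: PairGenotypeData, ibd) -> float:
    """Mixture log-likelihood of an IBD distribution for a pair.

    Returns -inf when some marker has zero probability under every IBD
    state with positive weight (an impossible relationship).
    """
    c = _cond_probs(pair)
    mix = c @ np.asarray(ibd, dtype=float)
    if np.any(mix <= 0.0):
        return -np.inf
    return float(np.log(mix).sum())


# ---------------------------------------------------------------------------
# EM maximum-likelihood estimation


class EMResult(NamedTuple):
    ibd: IBDVector
    loglik: float
    n_iter: int
    converged: bool


def em_mle(pair: PairGenotypeData, init=(1 / 3, 1 / 3, 1 / 3), tol: float = 1e-6,
           max_iter: int = 1000) -> EMResult:
    """Maximize the mixture likelihood over the IBD simplex by EM.

    E-step: posterior marker weights w_im = p_i c_im / sum_j p_j c_jm;
    M-step: p_i <- mean_m w_im.  Iteration stops when the log-likelihood
    improves by less than ``tol``.  The estimate is unconstrained on the
    simplex (no "possible triangle" restriction), so boundary solutions
    such as (0, 0, 1) for duplicates are attainable.
    """
    init = np.asarray(init, dtype=float)
    if np.any(init <= 0) or abs(init.sum() - 1.0) > 1e-9:
        raise ValueError("init must lie strictly inside the simplex")
    c = _cond_probs(pair)  # (M, 3)
    p = init.copy()
    ll_prev = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mix = c @ p
        if np.any(mix <= 0.0):
            # impossible under current p (can only occur at iteration 1
            # with a degenerate init, which the precondition excludes)
            return EMResult(IBDVector.from_array(p), -np.inf, it, False)
        ll = float(np.log(mix).sum())
        w = (c * p) / mix[:, None]
        p = w.mean(axis=0)
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        if ll - ll_prev < tol and it > 1:
            converged = True
            break
        ll_prev = ll
    return EMResult(IBDVector.from_array(p), loglik(pair, p), it, converged)


def _em_step(cond: np.ndarray, maskf: np.ndarray, commark: np.ndarray,
             p: np.ndarray, want_ll: bool = True) -> tuple[np.ndarray, np.ndarray | None]:
    """One EM update for a batch; optionally the log-likelihood at ``p``.

    Arithmetic runs in ``cond``'s dtype (float32 in the scan path); the
    log-likelihood sum accumulates in float64.
    """
    mix = np.einsum("kmd,kd->km", cond, p)
    bad = mix <= 0.0
    if bad.any():
        mix = np.where(bad, np.asarray(1.0, dtype=mix.dtype), mix)
    ll = None
    if want_ll:
        with np.errstate(invalid="ignore"):
            ll = (np.log(mix) * maskf).sum(axis=1, dtype=np.float64)
        ll[np.any(bad & (maskf > 0), axis=1)] = -np.inf
    s = np.einsum("km,kmd->kd", maskf / mix, cond) * p
    pnew = np.clip(s / commark[:, None], 0.0, None)
    pnew /= pnew.sum(axis=1, keepdims=True)
    return pnew, ll


def em_mle_batch(cond: np.ndarray, mask: np.ndarray, tol: float = 1e-6,
                 max_iter: int = 1000,
                 init: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized, accelerated EM over many pairs sharing a marker panel.

    ``cond`` has shape (n_pairs, M, 3) with conditional probabilities;
    ``mask`` (n_pairs, M) marks usable markers (rows of ``cond`` at
    masked-out markers must be 1 so they contribute nothing to the
    log-likelihood).  Returns (estimates (n_pairs, 3), loglik, n_cycles).

    Convergence near simplex boundaries (e.g. unrelated pairs) is slow
    for plain EM, so each cycle takes two EM steps and a SQUAREM-style
    extrapolation, falling back to the plain double step whenever the
    extrapolated point does not improve the log-likelihood; the
    monotonicity and fixed point of EM are preserved, and iteration
    stops once a cycle improves the log-likelihood by less than ``tol``
    (a stricter criterion than the single-step rule, since a cycle
    contains at least two EM steps).
    """
    n = cond.shape[0]
    commark = mask.sum(axis=1).astype(cond.dtype)
    if np.any(commark == 0):
        raise NoDataError("some pair shares no usable markers")
    maskf = mask.astype(cond.dtype)
    p_out = np.full((n, 3), 1.0 / 3.0)
    ll_out = np.full(n, -np.inf)
    cycles_out = np.zeros(n, dtype=int)
    idx = np.arange(n)
    ca, mf, cm = cond, maskf, commark
    if init is None:
        p = np.full((n, 3), 1.0 / 3.0, dtype=cond.dtype)
    else:
        # warm start (e.g. from a moment estimate), pulled strictly
        # inside the simplex; the mixture log-likelihood is concave in
        # p, so the maximizer does not depend on the starting point
        p = (0.9 * np.asarray(init, dtype=cond.dtype) + np.asarray(0.1 / 3.0, dtype=cond.dtype))
        p /= p.sum(axis=1, keepdims=True)
    ll_prev = np.full(n, -np.inf)
    max_cycles = max(1, max_iter // 2)
    for cycle in range(1, max_cycles + 1):
        p1, _ = _em_step(ca, mf, cm, p, want_ll=False)
        p2, ll1 = _em_step(ca, mf, cm, p1)
        r = p1 - p
        v = (p2 - p1) - r
        vn = np.sqrt((v * v).sum(axis=1))
        rn = np.sqrt((r * r).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(vn > 0, -rn / vn, -1.0)
        alpha = np.minimum(alpha, -1.0)
        pe = p - 2 * alpha[:, None] * r + (alpha ** 2)[:, None] * v
        pe = np.clip(pe, 0.0, None)
        tot = pe.sum(axis=1, keepdims=True)
        pe = np.where(tot > 0, pe / np.where(tot > 0, tot, 1.0), p2)
        ps, lle = _em_step(ca, mf, cm, pe)
        # accept the stabilized extrapolation only where it beats the
        # plain double step's starting point
        good = lle >= ll1
        p_next = np.where(good[:, None], ps, p2)
        ll_here = np.where(good, lle, ll1)  # ll at pe or p1; next EM only improves
        done = (ll_here - ll_prev) < tol
        done &= cycle > 1
        ll_prev = ll_here
        p = p_next
        if done.any() or cycle == max_cycles:
            sel = done if cycle < max_cycles else np.ones(len(idx), dtype=bool)
            gi = idx[sel]
            p_out[gi] = p[sel]
            # exact likelihood at the returned estimate
            mix = np.einsum("kmd,kd->km", ca[sel].astype(np.float64), p[sel].astype(np.float64))
            with np.errstate(divide="ignore"):
                ll_out[gi] = (np.log(np.maximum(mix, 1e-300)) * mf[sel]).sum(axis=1)
            cycles_out[gi] = cycle
            keep = ~sel
            if not keep.any():
                break
            idx, ca, mf, cm = idx[keep], ca[keep], mf[keep], cm[keep]
            p, ll_prev = p[keep], ll_prev[keep]
    return p_out, ll_out, cycles_out


# ---------------------------------------------------------------------------
# method of moments (PLINK-style comparator)


class MoMResult(NamedTuple):
    ibd: IBDVector
    raw: np.ndarray


def _ibs_state(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Identity-by-state (0, 1 or 2 shared alleles) per marker."""
    diff = np.abs(g1.astype(np.int16) - g2.astype(np.int16))
    return (2 - diff).astype(np.int8)


def mom_estimate(pair: PairGenotypeData) -> MoMResult:
    """Method-of-moments IBD estimate from IBS counts.

    The observed numbers of IBS-0 and IBS-1 markers are equated to their
    expectations given (p0, p1, p2) and the per-marker allele
    frequencies, and solved sequentially: p0 from IBS 0 (only possible
    when IBD is 0), then p1 from IBS 1, then p2 by complement.  The raw
    solution can leave [0, 1]; the ``ibd`` field carries the PLINK-style
    truncation to the simplex (renormalized), ``raw`` the untruncated
    solution.
    """
    if pair.commark == 0:
        raise NoDataError("pair shares no usable markers")
    q = pair.freqs
    p = 1.0 - q
    e_ibs0_d0 = 2.0 * (p * q) ** 2
    e_ibs1_d0 = 4.0 * p ** 3 * q + 4.0 * p * q ** 3
    e_ibs1_d1 = 2.0 * p * p * q + 2.0 * p * q * q
    s0, s1_d0, s1_d1 = e_ibs0_d0.sum(), e_ibs1_d0.sum(), e_ibs1_d1.sum()
    if s0 < 1e-8 or s1_d1 < 1e-8:
        warnings.warn("ill-conditioned moment estimate: markers nearly monomorphic",
                      stacklevel=2)
        s0 = max(s0, 1e-8)
        s1_d1 = max(s1_d1, 1e-8)
    ibs = _ibs_state(pair.g1, pair.g2)
    n0 = float((ibs == 0).sum())
    n1 = float((ibs == 1).sum())
    p0 = n0 / s0
    p1 = (n1 - p0 * s1_d0) / s1_d1
    p2 = 1.0 - p0 - p1
    raw = np.array([p0, p1, p2])
    est = np.clip(raw, 0.0, 1.0)
    tot = est.sum()
    est = est / tot if tot > 0 else np.array([1.0, 0.0, 0.0])
    return MoMResult(IBDVector.from_array(est), raw)


# ---------------------------------------------------------------------------
# batched estimation over many pairs of a genotype matrix


def estimate_pairs(geno: GenotypeMatrix, freqs: np.ndarray, pair_indices,
                   estimator: str = "em", tol: float = 1e-6, max_iter: int = 1000,
                   chunk_size: int = 512, dtype=np.float32) -> dict[str, np.ndarray]:
    """Estimate IBD for many pairs sharing one marker panel.

    ``pair_indices`` is a sequence of (row_i, row_j) into ``geno``.
    Returns a dict with ``commark`` and, per requested estimator
    ("em", "mom" or "both"), the (n_pairs, 3) estimates plus EM
    log-likelihoods.  EM runs vectorized in chunks.
    """
    if estimator not in ("em", "mom", "both"):
        raise ValueError(f"unknown estimator {estimator!r}")
    pairs = np.asarray(pair_indices, dtype=np.intp)
    n_pairs = pairs.shape[0]
    freqs = np.asarray(freqs, dtype=float)
    valid_m = usable_freq_mask(freqs)
    table = pair_prob_table(np.where(valid_m, freqs, 0.5)).astype(dtype)
    table[~valid_m, :, :] = 1.0  # neutral rows for unusable markers
    M = freqs.size
    q = np.where(valid_m, freqs, 0.5)
    pf = 1.0 - q
    e_ibs0_d0 = np.where(valid_m, 2.0 * (pf * q) ** 2, 0.0)
    e_ibs1_d0 = np.where(valid_m, 4.0 * pf ** 3 * q + 4.0 * pf * q ** 3, 0.0)
    e_ibs1_d1 = np.where(valid_m, 2.0 * pf * pf * q + 2.0 * pf * q * q, 0.0)
    out_em = np.full((n_pairs, 3), np.nan)
    out_ll = np.full(n_pairs, np.nan)
    out_mom = np.full((n_pairs, 3), np.nan)
    out_mom_raw = np.full((n_pairs, 3), np.nan)
    commark = np.zeros(n_pairs, dtype=int)
    ar = np.arange(M)
    for lo in range(0, n_pairs, chunk_size):
        hi = min(lo + chunk_size, n_pairs)
        g1 = geno.codes[pairs[lo:hi, 0]]
        g2 = geno.codes[pairs[lo:hi, 1]]
        mask = (g1 != MISSING) & (g2 != MISSING) & valid_m[None, :]
        commark[lo:hi] = mask.sum(axis=1)
        # vectorized moment estimate (warm start for EM, and the
        # comparator estimates when requested)
        ibs = 2 - np.abs(g1.astype(np.int16) - g2.astype(np.int16))
        maskf = mask.astype(float)
        s0 = np.maximum(maskf @ e_ibs0_d0, 1e-8)
        s1_0 = maskf @ e_ibs1_d0
        s1_1 = np.maximum(maskf @ e_ibs1_d1, 1e-8)
        n0 = ((ibs == 0) & mask).sum(axis=1)
        n1 = ((ibs == 1) & mask).sum(axis=1)
        m0 = n0 / s0
        m1 = (n1 - m0 * s1_0) / s1_1
        raw = np.stack([m0, m1, 1.0 - m0 - m1], axis=1)
        trunc = np.clip(raw, 0.0, 1.0)
        tot = trunc.sum(axis=1, keepdims=True)
        trunc = np.where(tot > 0, trunc / np.where(tot > 0, tot, 1.0),
                         np.array([1.0, 0.0, 0.0]))
        if estimator in ("em", "both"):
            cat = np.where(mask, 3 * g1.astype(np.intp) + g2.astype(np.intp), 0)
            cond = table[ar[None, :], cat, :]
            cond[~mask] = 1.0
            p, ll, _ = em_mle_batch(cond, mask, tol=tol, max_iter=max_iter,
                                    init=trunc)
            out_em[lo:hi] = p
            out_ll[lo:hi] = ll
        if estimator in ("mom", "both"):
            out_mom[lo:hi] = trunc
            out_mom_raw[lo:hi] = raw
    out: dict[str, np.ndarray] = {"commark": commark}
    if estimator in ("em", "both"):
        out["em"] = out_em
        out["em_loglik"] = out_ll
    if estimator in ("mom", "both"):
        out["mom"] = out_mom
        out["mom_raw"] = out_mom_raw
    return out
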