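"""Maximum likelihood ratio testing of putative relationships.

For a pair with putative (null) relationship R0 and a set A of
alternative relationship types, the statistic is

    MLRT = max_{R1 in A} log L(R1) - log L(R0),

with each likelihood evaluated at the relationship's prior IBD
distribution.  Twice the statistic does not follow a chi-squared
distribution (the alternatives are a discrete set, not a nested
parametric family), so significance is assessed empirically: genotypes
for pairs truly related as R0 are simulated — by i.i.d. per-marker IBD
draws (unlinked mode) or by gene-dropping through the canonical minimal
pedigree with Haldane recombination (linked mode) — and the p-value is
the add-one rank of the observed statistic in the simulated sample.

Relationship types sharing an IBD prior (half-sib, grandparent-
grandchild, avuncular; first cousin, half-avuncular) have identical
likelihoods and are not separable by this test; results carry the
equivalence-class label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ibd import PairGenotypeData, loglik, pair_prob_table
from .pedigree import (CATALOG_BY_CODE, CODE_MZ, CODE_OTHER,
                       RELATIONSHIP_CATALOG, RelationshipType, equivalence_class)
from .simulate import simulate_pair_linked, simulate_pair_unlinked


def default_alternatives(null_code: int) -> list[int]:
    """All catalogued relationship types except the null."""
    return [r.code for r in RELATIONSHIP_CATALOG
            if r.prior_ibd is not None and r.code != null_code]


def reltype_label(code: int) -> str:
    """Display label; likelihood-equivalent types are reported jointly."""
    cls = equivalence_class(code)
    if len(cls) == 1:
        return CATALOG_BY_CODE[code].abbreviation
    return "/".join(CATALOG_BY_CODE[c].abbreviation for c in sorted(cls))


@dataclass
class MLRTResult:
    """Outcome of the relationship test for one pair."""

    null_reltype: int
    statistic: float
    p_null: float
    plausible_reltype: int
    plausible_label: str
    p_plausible: float | None
    n_reps: int
    seed: int
    impossible_null: bool = False


def _prior(code: int) -> np.ndarray:
    rel = CATALOG_BY_CODE.get(code)
    if rel is None or rel.prior_ibd is None:
        raise ValueError(f"relationship code {code} has no defined IBD prior")
    return np.asarray(rel.prior_ibd)


def mlrt_statistic(pair: PairGenotypeData, null_code: int, alternatives=None,
                   unrestricted: bool = False) -> tuple[float, int]:
    """MLRT statistic and best alternative for one pair.

    The statistic may be negative (the null fits best).  If the null
    likelihood is -inf (genotypes impossible under R0, e.g. opposite
    homozygotes under parent-offspring), the statistic is +inf.  Ties
    among alternatives resolve to the smallest code.

    With ``unrestricted=True`` the alternative set additionally
    includes the EM-maximized likelihood over the whole IBD simplex, so
    the statistic becomes log L(p-hat) - log L(R0) >= 0; the reported
    best alternative remains the best-fitting catalogued type.
    """
    if alternatives is None:
        alternatives = default_alternatives(null_code)
    alternatives = sorted(set(alternatives) - {null_code})
    if not alternatives:
        raise ValueError("alternative set must be nonempty and exclude the null")
    ll0 = loglik(pair, _prior(null_code))
    lls = np.array([loglik(pair, _prior(c)) for c in alternatives])
    best = int(np.argmax(lls))  # argmax takes the first (smallest code) on ties
    ll_alt = lls[best]
    if unrestricted:
        from .ibd import em_mle
        ll_alt = max(ll_alt, em_mle(pair).loglik)
    stat = np.inf if np.isinf(ll0) and ll0 < 0 else float(ll_alt - ll0)
    return stat, alternatives[best]


def _batch_statistics(g1: np.ndarray, g2: np.ndarray, freqs: np.ndarray,
                      null_code: int, alt_codes: list[int],
                      unrestricted: bool = False) -> np.ndarray:
    """MLRT statistics for replicate genotype pairs (reps, M)."""
    table = pair_prob_table(freqs)  # (M, 9, 3)
    cat = 3 * g1.astype(np.intp) + g2.astype(np.intp)
    probs = table[np.arange(freqs.size)[None, :], cat, :]  # (reps, M, 3)
    priors = np.stack([_prior(c) for c in [null_code] + list(alt_codes)])  # (K+1, 3)
    mix = probs @ priors.T  # (reps, M, K+1)
    with np.errstate(divide="ignore"):
        ll = np.where(mix > 0, np.log(np.maximum(mix, 1e-300)), -np.inf).sum(axis=1)
    ll0 = ll[:, 0]
    best = ll[:, 1:].max(axis=1)
    if unrestricted:
        from .ibd import em_mle_batch
        mask = np.ones(probs.shape[:2], dtype=bool)
        _, ll_mle, _ = em_mle_batch(probs.astype(np.float32), mask)
        best = np.maximum(best, ll_mle)
    stat = best - ll0
    stat[np.isneginf(ll0)] = np.inf
    return stat


class UnsupportedNullError(ValueError):
    """The null relationship has no simulable generating model."""


def simulate_null_mlrt(null_code: int, freqs, reps: int, seed,
                       cm=None, chromosomes=None, linked: bool = False,
                       alternatives=None, unrestricted: bool = False) -> np.ndarray:
    """Sample of MLRT statistics under the null relationship.

    Per replicate a genotype pair truly related as ``null_code`` is
    generated over the given marker panel and its statistic computed
    with the same alternative set used for the observed pair.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rel = CATALOG_BY_CODE.get(null_code)
    if rel is None or rel.prior_ibd is None:
        raise UnsupportedNullError(f"cannot simulate under relationship code {null_code}")
    if alternatives is None:
        alternatives = default_alternatives(null_code)
    alternatives = sorted(set(alternatives) - {null_code})
    freqs = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(seed)
    if linked:
        g1, g2 = simulate_pair_linked(null_code, freqs, cm, chromosomes,
                                      seed=rng, size=reps)
    elif null_code == CODE_MZ:
        g1, _ = simulate_pair_unlinked((0, 0, 1), freqs, seed=rng, size=reps)
        g2 = g1
    else:
        g1, g2 = simulate_pair_unlinked(rel.prior_ibd, freqs, seed=rng, size=reps)
    if g1.ndim == 1:
        g1, g2 = g1[None, :], g2[None, :]
    return _batch_statistics(g1, g2, freqs, null_code, alternatives,
                             unrestricted=unrestricted)


def _p_value(observed: float, null_sample: np.ndarray) -> float:
    """Add-one empirical p-value; never 0 and never above 1."""
    reps = null_sample.size
    return float((1 + np.sum(null_sample >= observed)) / (reps + 1))


def mlrt_test(pair: PairGenotypeData, null_code: int, alternatives=None,
              reps: int = 1000, seed: int = 0, cm=None, chromosomes=None,
              linked: bool = False, test_plausible: bool = True,
              unrestricted: bool = False) -> MLRTResult:
    """Full relationship test for one pair.

    Computes the observed statistic, its empirical p-value against the
    simulated null, and then re-tests the best alternative ("plausible"
    type) as its own null with its own simulation.  When the plausible
    type is MZ twins and the genotypes are identical, the plausible
    p-value is reported as None (no meaningful null simulation for an
    exact duplicate).
    """
    stat, best = mlrt_statistic(pair, null_code, alternatives,
                                unrestricted=unrestricted)
    ss = np.random.SeedSequence(seed)
    s_null, s_alt = (int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2))
    null_sample = simulate_null_mlrt(null_code, pair.freqs, reps, s_null,
                                     cm=cm, chromosomes=chromosomes, linked=linked,
                                     alternatives=alternatives,
                                     unrestricted=unrestricted)
    p_null = _p_value(stat, null_sample)
    p_plaus: float | None = None
    if test_plausible:
        identical = bool(np.array_equal(pair.g1, pair.g2))
        if best == CODE_MZ and identical:
            p_plaus = None
        else:
            alt2 = None
            if alternatives is not None:
                alt2 = sorted(set(alternatives) | {null_code})
            stat2, _ = mlrt_statistic(pair, best, alt2, unrestricted=unrestricted)
            sample2 = simulate_null_mlrt(best, pair.freqs, reps, s_alt,
                                         cm=cm, chromosomes=chromosomes,
                                         linked=linked, alternatives=alt2,
                                         unrestricted=unrestricted)
            p_plaus = _p_value(stat2, sample2)
    return MLRTResult(
        null_reltype=null_code,
        statistic=stat,
        p_null=p_null,
        plausible_reltype=best,
        plausible_label=reltype_label(best),
        p_plausible=p_plaus,
        n_reps=reps,
        seed=seed,
        impossible_null=bool(np.isinf(stat)),
    )
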