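"""Synthetic genotype and study generation.

Three layers:

* :func:`simulate_pair_unlinked` — genotype pairs whose per-marker IBD
  state is drawn i.i.d. from a given (p0, p1, p2);
* :func:`gene_drop` — founder-allele transmission through a pedigree
  with Haldane-model recombination along a cM map (no interference,
  sex-averaged distances);
* :func:`make_synthetic_study` — a full multi-family study with planted
  pedigree errors (sample duplicates, parent misassignments, cryptic
  cross-family relatedness) and an exact truth table of every genotyped
  pair whose true relationship differs from the recorded one.

Markers are simulated free of LD (emulating post-pruning panels) with
founder minor-allele frequencies drawn Uniform(0.05, 0.5) by default,
the regime left by a 5% MAF filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pedio
from .pedio import MISSING, GenotypeMatrix
from .pedigree import (CATALOG_BY_CODE, CODE_AV, CODE_FC, CODE_FS, CODE_GPC,
                       CODE_HAV, CODE_HFC, CODE_HS, CODE_HSFC, CODE_MZ,
                       CODE_OTHER, CODE_PO, CODE_UN, Key, Pedigree,
                       PedigreeError)

DEFAULT_FREQ_RANGE = (0.05, 0.5)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def draw_marker_freqs(n_markers: int, seed, freq_range=DEFAULT_FREQ_RANGE) -> np.ndarray:
    """Minor-allele frequencies ~ Uniform over ``freq_range``."""
    rng = _rng(seed)
    lo, hi = freq_range
    return rng.uniform(lo, hi, size=n_markers)


def uniform_genetic_map(n_markers: int, n_chromosomes: int = 22,
                        total_cm: float = 3500.0) -> pd.DataFrame:
    """An evenly spaced autosomal marker map (marker table layout).

    Markers are split as evenly as possible over ``n_chromosomes``
    chromosomes of equal genetic length summing to ``total_cm``, with
    bp positions at 1 Mb per cM for bookkeeping.
    """
    per = np.full(n_chromosomes, n_markers // n_chromosomes)
    per[: n_markers % n_chromosomes] += 1
    chrom_len = total_cm / n_chromosomes
    rows = []
    k = 0
    for c in range(n_chromosomes):
        n = int(per[c])
        if n == 0:
            continue
        cm = np.linspace(0.0, chrom_len, n)
        for x in cm:
            rows.append((f"snp{k + 1}", str(c + 1), int(round(x * 1e6)) + 1, x))
            k += 1
    tab = pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp", "position_cm"])
    tab["allele_minor"] = "1"
    tab["allele_major"] = "2"
    tab["freq_minor"] = np.nan
    tab["n_missing"] = 0
    return tab[pedio.MARKER_COLUMNS]


# ---------------------------------------------------------------------------
# unlinked pair simulation


def simulate_pair_unlinked(ibd, freqs, n_markers: int | None = None, seed=None,
                           size: int = 1):
    """Genotype pairs with i.i.d. per-marker IBD states.

    For each marker an IBD state D is drawn from ``ibd``; shared alleles
    are drawn once and copied, remaining alleles independently from HWE
    at the marker's minor frequency.  Returns (g1, g2) dosage arrays of
    shape (size, M), squeezed to (M,) when ``size`` is 1.
    """
    rng = _rng(seed)
    ibd = np.asarray(ibd, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if n_markers is not None and freqs.size != n_markers:
        freqs = np.resize(freqs, n_markers)
    M = freqs.size
    d = rng.choice(3, size=(size, M), p=ibd)
    # four base allele draws; sharing overwrites
    a1 = rng.random((size, M)) < freqs
    a2 = rng.random((size, M)) < freqs
    b1 = rng.random((size, M)) < freqs
    b2 = rng.random((size, M)) < freqs
    b1 = np.where(d >= 1, a1, b1)  # one shared allele
    b2 = np.where(d == 2, a2, b2)  # both shared
    g1 = a1.astype(np.int8) + a2.astype(np.int8)
    g2 = b1.astype(np.int8) + b2.astype(np.int8)
    if size == 1:
        return g1[0], g2[0]
    return g1, g2


# ---------------------------------------------------------------------------
# gene dropping


def _chromosome_blocks(chromosomes) -> list[np.ndarray]:
    """Index blocks of consecutive markers per chromosome label."""
    chromosomes = np.asarray(chromosomes)
    blocks = []
    start = 0
    for i in range(1, len(chromosomes) + 1):
        if i == len(chromosomes) or chromosomes[i] != chromosomes[start]:
            blocks.append(np.arange(start, i))
            start = i
    return blocks


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, blocks, thetas, rng) -> np.ndarray:
    """One recombinant haplotype per replicate from a parent's pair.

    ``hap_a``/``hap_b`` have shape (size, M).  Within each chromosome
    the source haplotype starts at random and switches between adjacent
    markers with the Haldane recombination fractions ``thetas``.
    """
    size, M = hap_a.shape
    src = np.empty((size, M), dtype=np.int8)
    for blk, th in zip(blocks, thetas):
        start = rng.integers(0, 2, size=(size, 1))
        if blk.size > 1:
            switch = (rng.random((size, blk.size - 1)) < th).astype(np.int8)
            states = np.concatenate([start, switch], axis=1)
            src[:, blk] = np.cumsum(states, axis=1) % 2
        else:
            src[:, blk] = start
    return np.where(src == 0, hap_a, hap_b)


def haldane_theta(d_cm: np.ndarray) -> np.ndarray:
    """Haldane map function: theta = (1 - exp(-2d)) / 2, d in Morgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass
class GeneDropResult:
    """Haplotypes (and optionally founder-allele labels) per member."""

    haplotypes: dict[Key, tuple[np.ndarray, np.ndarray]]
    labels: dict[Key, tuple[np.ndarray, np.ndarray]] | None = None

    def genotypes(self, key: Key) -> np.ndarray:
        h1, h2 = self.haplotypes[key]
        return h1.astype(np.int8) + h2.astype(np.int8)

    def ibd_states(self, a: Key, b: Key) -> np.ndarray:
        """Per-marker IBD count between two members from allele labels."""
        if self.labels is None:
            raise ValueError("gene drop was run without IBD tracking")
        a1, a2 = self.labels[a]
        b1, b2 = self.labels[b]
        # matching size of the two label multisets
        s11, s12 = a1 == b1, a1 == b2
        s21, s22 = a2 == b1, a2 == b2
        both = (s11 & s22) | (s12 & s21)
        any_ = s11 | s12 | s21 | s22
        return both.astype(np.int8) + any_.astype(np.int8)


def gene_drop(ped: Pedigree, freqs, cm=None, chromosomes=None, seed=None,
              size: int = 1, track_ibd: bool = False, linked: bool = True) -> GeneDropResult:
    """Drop founder alleles through a pedigree.

    Founder haplotypes are Bernoulli(freq) per marker; each non-founder
    receives one recombinant haplotype from each parent.  ``linked``
    requires ``cm`` (and optionally ``chromosomes``); unlinked mode
    transmits each marker independently (free recombination).  ``size``
    gives the number of independent replicate drops, vectorized.
    """
    rng = _rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    M = freqs.size
    if linked:
        if cm is None:
            raise ValueError("linked gene drop requires cM positions")
        cm = np.asarray(cm, dtype=float)
        if chromosomes is None:
            chromosomes = np.zeros(M, dtype=int)
        blocks = _chromosome_blocks(chromosomes)
        thetas = [haldane_theta(np.diff(cm[blk])) for blk in blocks]
    members = list(ped.father)  # includes dummies; all get haplotypes
    members.sort(key=lambda k: (ped._depth(k), k))
    haps: dict[Key, tuple[np.ndarray, np.ndarray]] = {}
    labels: dict[Key, tuple[np.ndarray, np.ndarray]] | None = {} if track_ibd else None
    next_label = 0
    for key in members:
        fa, mo = ped.parents(key)
        hk = []
        lk = []
        for parent in (fa, mo):
            if parent is None:
                hk.append((rng.random((size, M)) < freqs).astype(np.int8))
                if track_ibd:
                    lk.append(np.full((size, M), next_label, dtype=np.int32))
                    next_label += 1
            else:
                pa, pb = haps[parent]
                if linked:
                    # one source pattern reused for alleles and labels
                    src = _meiosis(
                        np.zeros((size, M), dtype=np.int8),
                        np.ones((size, M), dtype=np.int8),
                        blocks, thetas, rng,
                    )
                else:
                    src = rng.integers(0, 2, size=(size, M), dtype=np.int8)
                hk.append(np.where(src == 0, pa, pb))
                if track_ibd:
                    la, lb = labels[parent]
                    lk.append(np.where(src == 0, la, lb))
        haps[key] = (hk[0], hk[1])
        if track_ibd:
            labels[key] = (lk[0], lk[1])
    return GeneDropResult(haps, labels)


# ---------------------------------------------------------------------------
# canonical minimal pedigrees for each catalogued relationship


def canonical_pedigree(code: int) -> tuple[Pedigree, Key, Key]:
    """Minimal pedigree realizing a catalogued relationship.

    Returns (pedigree, a, b) where (a, b) is the focal pair.  MZ twins
    have no structural pedigree: the pair is the same simulated
    individual duplicated, represented here as the degenerate case of a
    single founder paired with itself downstream (callers special-case
    code 11).
    """
    ped = Pedigree()
    F = "0"

    def a_(iid, fa=None, mo=None, sex=0):
        return ped.add((F, iid), fa, mo, sex=sex, genotyped=False)

    if code == CODE_UN:
        x = a_("x"); y = a_("y")
        return ped, x, y
    if code == CODE_PO:
        f = a_("f", sex=1); m = a_("m", sex=2)
        c = a_("c", f, m)
        return ped, f, c
    if code == CODE_FS:
        f = a_("f", sex=1); m = a_("m", sex=2)
        c1 = a_("c1", f, m); c2 = a_("c2", f, m)
        return ped, c1, c2
    if code == CODE_HS:
        f = a_("f", sex=1); m1 = a_("m1", sex=2); m2 = a_("m2", sex=2)
        c1 = a_("c1", f, m1); c2 = a_("c2", f, m2)
        return ped, c1, c2
    if code == CODE_GPC:
        gf = a_("gf", sex=1); gm = a_("gm", sex=2)
        p = a_("p", gf, gm, sex=1); s = a_("s", sex=2)
        c = a_("c", p, s)
        return ped, gf, c
    if code == CODE_AV:
        f = a_("f", sex=1); m = a_("m", sex=2)
        u = a_("u", f, m, sex=1); p = a_("p", f, m, sex=2)
        s = a_("s", sex=1)
        n = a_("n", s, p)
        return ped, u, n
    if code == CODE_FC:
        f = a_("f", sex=1); m = a_("m", sex=2)
        p1 = a_("p1", f, m, sex=1); p2 = a_("p2", f, m, sex=1)
        s1 = a_("s1", sex=2); s2 = a_("s2", sex=2)
        k1 = a_("k1", p1, s1); k2 = a_("k2", p2, s2)
        return ped, k1, k2
    if code == CODE_HAV:
        f = a_("f", sex=1); m1 = a_("m1", sex=2); m2 = a_("m2", sex=2)
        u = a_("u", f, m1, sex=1); p = a_("p", f, m2, sex=2)
        s = a_("s", sex=1)
        n = a_("n", s, p)
        return ped, u, n
    if code == CODE_HFC:
        f = a_("f", sex=1); m1 = a_("m1", sex=2); m2 = a_("m2", sex=2)
        p1 = a_("p1", f, m1, sex=1); p2 = a_("p2", f, m2, sex=1)
        s1 = a_("s1", sex=2); s2 = a_("s2", sex=2)
        k1 = a_("k1", p1, s1); k2 = a_("k2", p2, s2)
        return ped, k1, k2
    if code == CODE_HSFC:
        f = a_("f", sex=1); m = a_("m", sex=2)
        b1 = a_("b1", f, m, sex=1); b2 = a_("b2", f, m, sex=1)
        w = a_("w", sex=2)
        x = a_("x", b1, w); y = a_("y", b2, w)
        return ped, x, y
    raise PedigreeError(f"no canonical pedigree for relationship code {code}")


def simulate_pair_linked(code: int, freqs, cm, chromosomes=None, seed=None,
                         size: int = 1):
    """Genotype pairs for a relationship by linked gene-dropping.

    Uses the canonical minimal pedigree with Haldane recombination along
    the cM map; marker-level LD is absent but linkage within the pair's
    IBD segments is retained.  MZ twins are a duplicated individual.
    """
    rng = _rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    if code == CODE_MZ:
        M = freqs.size
        a1 = (rng.random((size, M)) < freqs).astype(np.int8)
        a2 = (rng.random((size, M)) < freqs).astype(np.int8)
        g = a1 + a2
        out = (g, g.copy())
    else:
        ped, a, b = canonical_pedigree(code)
        drop = gene_drop(ped, freqs, cm=cm, chromosomes=chromosomes, seed=rng,
                         size=size, linked=True)
        out = (drop.genotypes(a), drop.genotypes(b))
    if size == 1:
        return out[0][0], out[1][0]
    return out


# ---------------------------------------------------------------------------
# synthetic study with planted errors


@dataclass
class ErrorPlan:
    """Planted pedigree errors, referencing generated individual keys.

    * ``duplicates``: individuals to clone (identical genotypes,
      distinct id recorded as a sibling, or as a same-family founder if
      the source has no recorded parents);
    * ``parent_swaps``: (child, true_father) — genotype transmission is
      rewired to ``true_father`` (``None`` = a new hidden, ungenotyped
      outsider) while the recorded pedigree keeps the original father;
    * ``cryptic_links``: (a, b, true_code) — two recorded-unrelated true
      founders whose haplotypes are generated jointly under the
      canonical pedigree of ``true_code``.
    """

    duplicates: list[Key] = field(default_factory=list)
    parent_swaps: list[tuple[Key, Key | None]] = field(default_factory=list)
    cryptic_links: list[tuple[Key, Key, int]] = field(default_factory=list)

    def touched(self) -> list[Key]:
        out = list(self.duplicates)
        out += [c for c, _ in self.parent_swaps]
        for a, b, _ in self.cryptic_links:
            out += [a, b]
        return out

    def validate(self, keys: set[Key]) -> None:
        touched = self.touched()
        for k in touched:
            if k not in keys:
                raise ValueError(f"error plan references unknown individual {k}")
        if len(touched) != len(set(touched)):
            raise ValueError("error plan applies more than one event to an individual")


@dataclass
class SyntheticStudy:
    """Output bundle of :func:`make_synthetic_study`."""

    records: pd.DataFrame
    genotypes: GenotypeMatrix
    markers: pd.DataFrame  # freq_minor holds the generating frequencies
    recorded: Pedigree
    truth: pd.DataFrame

    def write(self, ped_path, map_path, truth_path=None) -> None:
        pedio.write_pedmap(ped_path, map_path, self.records, self.genotypes, self.markers)
        if truth_path is not None:
            self.truth.to_csv(truth_path, sep="\t", index=False)


def _build_family(ped_rec: Pedigree, ped_true: Pedigree, fid: str,
                  n_generations: int = 3, n_children: int = 3) -> dict[str, str]:
    """One multigeneration family added to recorded and true pedigrees.

    A founder couple has ``n_children`` children per couple for
    ``n_generations`` offspring generations; every child in a
    non-terminal generation marries a new founder.  The wife of the
    first generation-1 couple additionally has one child by a second
    husband (a genuine recorded half-sib group, available for
    parent-swap plants).  Returns a layout dict of structurally
    interesting individual ids:

    * ``hs_child`` / ``second_husband`` / ``first_husband`` — the
      remarriage child, its recorded father, and the father of its
      recorded half-sibs;
    * ``leaf_child`` — a childless last-generation member (duplicate
      target);
    * ``swap_leaf`` — a childless member whose father has a full sib
      (so a hidden-father swap breaks an avuncular pair);
    * ``leaf_spouse`` — a married-in founder whose children are all
      childless (cryptic-link target without grandchild leakage).
    """

    def add(iid, fa=None, mo=None, sex=0):
        for p in (ped_rec, ped_true):
            p.add((fid, iid), fa and (fid, fa), mo and (fid, mo), sex=sex)
        return iid

    n = 0

    def nid():
        nonlocal n
        n += 1
        return f"I{n}"

    gf = add(nid(), sex=1)
    gm = add(nid(), sex=2)
    couples = [(gf, gm)]
    layout: dict[str, str] = {}
    children_of: dict[tuple[str, str], list[str]] = {}
    blood: set[str] = set()  # members descended from the founder couple
    terminal_parents: list[tuple[str, str]] = []
    for gen in range(1, n_generations + 1):
        next_couples = []
        last = gen == n_generations
        if last:
            terminal_parents = couples
        for (fa, mo) in couples:
            kids = children_of.setdefault((fa, mo), [])
            for _ in range(n_children):
                sex = 1 if (n % 2 == 0) else 2
                child = add(nid(), fa, mo, sex=sex)
                kids.append(child)
                blood.add(child)
                if not last:
                    spouse = add(nid(), sex=2 if sex == 1 else 1)
                    next_couples.append((child, spouse) if sex == 1 else (spouse, child))
        if gen == 1 and next_couples:
            # remarriage: the first generation-1 couple's wife has one
            # child by a second husband
            fa1, mo1 = next_couples[0]
            h2 = add(nid(), sex=1)
            hs_child = add(nid(), h2, mo1, sex=1)
            layout.update(hs_child=hs_child, second_husband=h2, first_husband=fa1)
        couples = next_couples
    if terminal_parents:
        # a terminal couple whose father is blood (has full sibs) gives
        # a leaf whose hidden-father swap breaks an avuncular pair
        for fa, mo in terminal_parents:
            if fa in blood and layout.get("swap_leaf") is None:
                layout["swap_leaf"] = children_of[(fa, mo)][0]
            if ped_rec.is_founder((fid, mo)) and layout.get("leaf_spouse") is None:
                layout["leaf_spouse"] = mo
            elif ped_rec.is_founder((fid, fa)) and layout.get("leaf_spouse") is None:
                layout["leaf_spouse"] = fa
        layout["leaf_child"] = children_of[terminal_parents[-1]][-1]
    return layout


def make_synthetic_study(n_families: int = 20, family_depth: int = 3,
                         n_unrelated: int = 141, n_markers: int = 50_000,
                         error_plan: ErrorPlan | None = None, seed: int = 0,
                         n_children: int = 3, freq_range=DEFAULT_FREQ_RANGE,
                         linked: bool = False) -> SyntheticStudy:
    """Generate a multi-family SNP study with planted pedigree errors.

    ``n_families`` families of ``family_depth`` offspring generations
    plus ``n_unrelated`` singleton individuals are genotyped at
    ``n_markers`` LD-free autosomal markers (uniform cM map, founder
    frequencies ~ Uniform over ``freq_range``).  The recorded pedigree
    is written as ped/map; genotypes follow the *true* pedigree, which
    differs by the events in ``error_plan``.  The truth table lists
    every genotyped pair whose true relationship differs from the
    recorded one (recorded and true codes plus the true IBD prior).

    By default transmission is per-marker independent (free
    recombination), so each pair's realized genome-wide IBD equals its
    pedigree expectation up to binomial noise; ``linked=True`` transmits
    whole recombinant haplotypes along the cM map instead, which adds
    the realized-relatedness variance of finite genomes.
    """
    if min(n_families, family_depth, n_markers) < 1 or n_unrelated < 0:
        raise ValueError("study dimensions must be positive")
    plan = error_plan or ErrorPlan()
    rng = np.random.default_rng(seed)

    ped_rec, ped_true = Pedigree(), Pedigree()
    for f in range(n_families):
        _build_family(ped_rec, ped_true, f"F{f + 1:02d}", family_depth, n_children)
    for u in range(n_unrelated):
        key = (f"U{u + 1:03d}", "I1")
        for p in (ped_rec, ped_true):
            p.add(key, sex=1 + u % 2)
    keys = set(ped_rec.members())
    plan.validate(keys)

    markers = uniform_genetic_map(n_markers)
    freqs = draw_marker_freqs(n_markers, rng, freq_range)

    # --- apply events to the structures ------------------------------
    hidden_n = 0
    for child, true_father in plan.parent_swaps:
        if true_father is None:
            hidden_n += 1
            true_father = ped_true.add((child[0], f"__outsider{hidden_n}"),
                                       sex=1, genotyped=False)
        elif true_father not in keys:
            raise ValueError(f"error plan references unknown individual {true_father}")
        ped_true.father[child] = true_father
        ped_true._invalidate()
    # cryptic links: joint founder haplotypes planted after the drop
    for a, b, code in plan.cryptic_links:
        for k in (a, b):
            if not ped_true.is_founder(k):
                raise ValueError(f"cryptic link target {k} is not a true founder")
        if code == CODE_MZ or CATALOG_BY_CODE.get(code, CATALOG_BY_CODE[CODE_OTHER]).prior_ibd is None:
            raise ValueError(f"cryptic link needs a structural relationship, got code {code}")

    # --- genotypes by gene drop on the true pedigree ------------------
    cm = markers["position_cm"].to_numpy()
    chroms = markers["chromosome"].to_numpy()
    drop = gene_drop(ped_true, freqs, cm=cm, chromosomes=chroms, seed=rng,
                     size=1, linked=linked)
    # overwrite cryptic founders' haplotypes with jointly generated ones
    for a, b, code in plan.cryptic_links:
        cped, ca, cb = canonical_pedigree(code)
        cdrop = gene_drop(cped, freqs, cm=cm, chromosomes=chroms, seed=rng,
                          size=1, linked=linked)
        drop.haplotypes[a] = cdrop.haplotypes[ca]
        drop.haplotypes[b] = cdrop.haplotypes[cb]
        if not (ped_true.is_founder(a) and ped_true.is_founder(b)):
            raise ValueError("cryptic link targets must be true founders")
    # note: descendants of cryptic founders must be re-dropped so the
    # planted haplotypes propagate
    redrop = set()
    for a, b, _ in plan.cryptic_links:
        redrop.update({a, b})
    if redrop:
        order = sorted(ped_true.father, key=lambda k: (ped_true._depth(k), k))
        affected = set(redrop)
        for k in order:
            fa, mo = ped_true.parents(k)
            if fa in affected or mo in affected:
                affected.add(k)
                if fa is not None:
                    src_f = (rng.integers(0, 2, size=(1, n_markers), dtype=np.int8)
                             if not linked else
                             _meiosis(np.zeros((1, n_markers), np.int8),
                                      np.ones((1, n_markers), np.int8),
                                      _chromosome_blocks(chroms),
                                      [haldane_theta(np.diff(cm[blk]))
                                       for blk in _chromosome_blocks(chroms)], rng))
                    src_m = (rng.integers(0, 2, size=(1, n_markers), dtype=np.int8)
                             if not linked else
                             _meiosis(np.zeros((1, n_markers), np.int8),
                                      np.ones((1, n_markers), np.int8),
                                      _chromosome_blocks(chroms),
                                      [haldane_theta(np.diff(cm[blk]))
                                       for blk in _chromosome_blocks(chroms)], rng))
                    fh = drop.haplotypes[fa]
                    mh = drop.haplotypes[mo]
                    drop.haplotypes[k] = (
                        np.where(src_f == 0, fh[0], fh[1]),
                        np.where(src_m == 0, mh[0], mh[1]),
                    )

    # --- assemble output individuals ---------------------------------
    out_keys = ped_rec.members()
    genos = {k: drop.genotypes(k)[0] for k in out_keys}

    # duplicates: clone genotypes, record as sibling (or co-founder)
    dup_of: dict[Key, Key] = {}
    for target in plan.duplicates:
        dkey = (target[0], f"{target[1]}D")
        fa, mo = ped_rec.parents(target)
        if fa in ped_rec._dummy:
            fa = None
        if mo in ped_rec._dummy:
            mo = None
        ped_rec.add(dkey, fa, mo, sex=ped_rec.sex[target])
        genos[dkey] = genos[target].copy()
        dup_of[dkey] = target
        out_keys = sorted(out_keys + [dkey])

    codes = np.stack([genos[k] for k in out_keys]).astype(np.int8)
    # orient to the realized sample-minor allele so that written files
    # re-read with identical codes; the generating frequency follows the
    # relabelling (it is the model frequency of the counted allele)
    sample_freq = codes.mean(axis=0) / 2.0
    flip = sample_freq > 0.5
    codes[:, flip] = 2 - codes[:, flip]
    freqs = np.where(flip, 1.0 - freqs, freqs)
    geno = GenotypeMatrix(list(out_keys), codes)

    # --- recorded ped records -----------------------------------------
    recs = []
    for k in out_keys:
        fa, mo = ped_rec.parents(k)
        fa = "0" if fa is None or fa in ped_rec._dummy else fa[1]
        mo = "0" if mo is None or mo in ped_rec._dummy else mo[1]
        recs.append((k[0], k[1], fa, mo, ped_rec.sex[k] or 1, 0))
    records = pd.DataFrame(recs, columns=pedio.PED_COLUMNS)
    markers = markers.copy()
    # the marker table carries the generating (founder) frequencies;
    # re-reading the written files yields sample estimates instead
    markers["freq_minor"] = freqs
    markers["allele_minor"] = "1"
    markers["allele_major"] = "2"

    # --- cryptic links realized in the true pedigree ------------------
    # (for truth computation: graft the canonical ancestors onto a copy)
    for a, b, code in plan.cryptic_links:
        cped, ca, cb = canonical_pedigree(code)
        remap = {}
        for m in cped.members():
            if m in (ca, cb):
                continue
            remap[m] = ped_true.add(("__link", f"{a[0]}.{a[1]}.{m[1]}"),
                                    sex=cped.sex[m], genotyped=False)
        for focal, orig in ((a, ca), (b, cb)):
            fa, mo = cped.parents(orig)
            ped_true.father[focal] = remap.get(fa)
            ped_true.mother[focal] = remap.get(mo)
        for m, new in remap.items():
            fa, mo = cped.parents(m)
            if fa is not None and fa in remap:
                ped_true.father[new] = remap[fa]
            if mo is not None and mo in remap:
                ped_true.mother[new] = remap[mo]
        ped_true._invalidate()

    truth = _truth_table(ped_rec, ped_true, plan, dup_of, out_keys)
    return SyntheticStudy(records, geno, markers, ped_rec, truth)


def _true_relation(ped_true: Pedigree, dup_of: dict[Key, Key], a: Key, b: Key):
    """(code, prior) of the true relationship, resolving duplicates."""
    sa, sb = dup_of.get(a, a), dup_of.get(b, b)
    if sa == sb:  # a duplicate paired with its source (or another copy)
        r = CATALOG_BY_CODE[CODE_MZ]
        return r.code, np.asarray(r.prior_ibd)
    rel = ped_true.classify_relationship(sa, sb)
    try:
        prior = ped_true.prior_ibd(sa, sb)
    except PedigreeError:
        prior = np.array([np.nan] * 3)
    return rel.code, prior


def _truth_table(ped_rec: Pedigree, ped_true: Pedigree, plan: ErrorPlan,
                 dup_of: dict[Key, Key], out_keys) -> pd.DataFrame:
    """Exact table of genotyped pairs whose true and recorded relations differ.

    Compares pedigree-implied priors over the closure of individuals
    touched by the plan (plus their descendants and duplicates) against
    every genotyped individual.
    """
    touched = set(plan.touched()) | set(dup_of)
    # descendants (parent links are identical in both pedigrees for
    # everyone below the touched individuals)
    out_set = set(out_keys)
    changed = True
    while changed:
        changed = False
        for k in out_set:
            if k in touched:
                continue
            fa, mo = ped_rec.parents(k)
            if fa in touched or mo in touched:
                touched.add(k)
                changed = True
    rows = []
    seen = set()
    for t in sorted(touched & out_set):
        for k in out_keys:
            if k == t:
                continue
            a, b = (t, k) if t <= k else (k, t)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            rec = ped_rec.classify_relationship(a, b)
            tcode, tprior = _true_relation(ped_true, dup_of, a, b)
            try:
                rprior = ped_rec.prior_ibd(a, b)
            except PedigreeError:
                rprior = np.array([np.nan] * 3)
            differs = rec.code != tcode
            if not differs and np.all(np.isfinite(tprior)) and np.all(np.isfinite(rprior)):
                differs = bool(np.max(np.abs(tprior - rprior)) > 1e-9)
            if differs:
                rows.append((a[0], a[1], b[0], b[1], rec.code, tcode,
                             *np.round(tprior, 6)))
    return pd.DataFrame(
        rows,
        columns=["fid1", "iid1", "fid2", "iid2", "recorded_reltype",
                 "true_reltype", "true_p0", "true_p1", "true_p2"],
    )


def default_error_plan(n_families: int = 20, family_depth: int = 3,
                       n_unrelated: int = 141, n_children: int = 3) -> ErrorPlan:
    """The study-mirroring plan of seven planted errors.

    Two sample duplicates recorded as full sibs, two true-full-sib pairs
    recorded as half-sibs (transmission rewired to the first husband of
    the remarried mother), one putative-avuncular individual whose true
    father is an undocumented outsider, and two cryptic related pairs
    (one half-sib pair between a family founder and a singleton, one
    first-cousin pair between two singletons).

    Requires ``n_families >= 3`` and ``n_unrelated >= 3``; the targets
    are chosen deterministically from the generated id layout.
    """
    if n_families < 3 or n_unrelated < 3:
        raise ValueError("the default plan needs >= 3 families and >= 3 singletons")
    layout = _family_layout(family_depth, n_children)
    needed = ("hs_child", "first_husband", "leaf_child", "swap_leaf", "leaf_spouse")
    if any(layout.get(k) is None for k in needed):
        raise ValueError("the default plan needs >= 2 offspring generations "
                         "and >= 2 children per couple")
    plan = ErrorPlan()
    # duplicates: leaf-generation children (childless) of families 1, 2
    plan.duplicates = [("F01", layout["leaf_child"]), ("F02", layout["leaf_child"])]
    # true-FS recorded-HS: rewire the remarriage child's transmission to
    # the mother's first husband in families 1 and 2
    plan.parent_swaps = [
        (("F01", layout["hs_child"]), ("F01", layout["first_husband"])),
        (("F02", layout["hs_child"]), ("F02", layout["first_husband"])),
        # recorded-AV truly-UN: leaf child of family 3 fathered by an outsider
        (("F03", layout["swap_leaf"]), None),
    ]
    plan.cryptic_links = [
        (("F01", layout["leaf_spouse"]), ("U001", "I1"), CODE_HS),
        (("U002", "I1"), ("U003", "I1"), CODE_FC),
    ]
    return plan


def _family_layout(n_generations: int, n_children: int) -> dict[str, str]:
    """Ids of structurally interesting members of a generated family.

    The id layout is deterministic given the dimensions, so a dry build
    of a probe family yields it.
    """
    probe_rec, probe_true = Pedigree(), Pedigree()
    return _build_family(probe_rec, probe_true, "P", n_generations, n_children)
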