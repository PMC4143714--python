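"""Pedigree representation, kinship recursion and relationship catalog.

A :class:`Pedigree` is a directed family graph of (family id, individual
id) keys with father/mother links.  Kinship coefficients are computed by
the classical recursion (founders pairwise unrelated and non-inbred),
and pairwise prior IBD distributions (p0, p1, p2) follow for non-inbred
pairs.  Each pair is classified into the standard catalog of
relationship types; the three types sharing the (0.5, 0.5, 0) prior and
the two sharing (0.75, 0.25, 0) are disambiguated structurally.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Key = tuple[str, str]

PRIOR_TOL = 1e-9  # catalog-matching tolerance; recursion is exact up to float rounding

CODE_MZ, CODE_FS, CODE_HS, CODE_GPC, CODE_AV = 11, 1, 2, 3, 4
CODE_FC, CODE_UN, CODE_HAV, CODE_HFC, CODE_HSFC, CODE_PO = 5, 6, 7, 8, 9, 10
CODE_OTHER = 99


@dataclass(frozen=True)
class RelationshipType:
    """One row of the relationship catalog."""

    code: int
    abbreviation: str
    name: str
    prior_ibd: tuple[float, float, float] | None
    kinship: float | None


#: The catalog of pairwise relationship types with their IBD priors
#: (p0, p1, p2) and kinship coefficients phi = p1/4 + p2/2.
RELATIONSHIP_CATALOG: tuple[RelationshipType, ...] = (
    RelationshipType(CODE_MZ, "MZ", "MZ-twin", (0.0, 0.0, 1.0), 0.5),
    RelationshipType(CODE_PO, "PO", "parent-offspring", (0.0, 1.0, 0.0), 0.25),
    RelationshipType(CODE_FS, "FS", "full-sib", (0.25, 0.5, 0.25), 0.25),
    RelationshipType(CODE_HSFC, "HSFC", "half-sib+first cousin", (0.375, 0.5, 0.125), 0.1875),
    RelationshipType(CODE_HS, "HS", "half-sib", (0.5, 0.5, 0.0), 0.125),
    RelationshipType(CODE_GPC, "GPC", "grandparent-grandchild", (0.5, 0.5, 0.0), 0.125),
    RelationshipType(CODE_AV, "AV", "avuncular", (0.5, 0.5, 0.0), 0.125),
    RelationshipType(CODE_FC, "FC", "first cousin", (0.75, 0.25, 0.0), 0.0625),
    RelationshipType(CODE_HAV, "HAV", "half-avuncular", (0.75, 0.25, 0.0), 0.0625),
    RelationshipType(CODE_HFC, "HFC", "half-first cousin", (0.875, 0.125, 0.0), 0.03125),
    RelationshipType(CODE_UN, "UN", "unrelated", (1.0, 0.0, 0.0), 0.0),
    RelationshipType(CODE_OTHER, "OT", "other types", None, None),
)

CATALOG_BY_CODE = {r.code: r for r in RELATIONSHIP_CATALOG}

#: codes whose priors coincide and cannot be separated by genotype likelihood
EQUIVALENCE_CLASSES = ({CODE_HS, CODE_GPC, CODE_AV}, {CODE_FC, CODE_HAV})


def equivalence_class(code: int) -> frozenset[int]:
    """Codes sharing the given code's IBD prior (likelihood-equivalent)."""
    for cls in EQUIVALENCE_CLASSES:
        if code in cls:
            return frozenset(cls)
    return frozenset({code})


class PedigreeError(ValueError):
    pass


class UnsupportedPedigreeError(PedigreeError):
    """Raised for configurations outside the 3-state IBD model (inbreeding)."""


class Pedigree:
    """Directed family graph with parent links and kinship recursion.

    Members are keyed by (family id, individual id).  Half-specified
    parent pairs are normalized by creating a unique dummy founder for
    the absent parent, so the kinship recursion is total.  Founders are
    additionally given hidden dummy parents internally, which makes the
    prior-IBD parent formula uniform; dummies never appear in member
    listings.
    """

    def __init__(self) -> None:
        self.father: dict[Key, Key | None] = {}
        self.mother: dict[Key, Key | None] = {}
        self.sex: dict[Key, int] = {}
        self.genotyped: dict[Key, bool] = {}
        self._dummy: set[Key] = set()
        self._n_dummy = 0
        self._depth_cache: dict[Key, int] | None = None
        self._kin_cache: dict[tuple[Key, Key], float] = {}

    # -- construction -------------------------------------------------

    def add(self, key: Key, father: Key | None = None, mother: Key | None = None,
            sex: int = 0, genotyped: bool = True) -> Key:
        if key in self.father:
            raise PedigreeError(f"duplicate member {key}")
        if (father is None) != (mother is None):
            # normalize half-specified parents with a unique dummy founder
            if father is None:
                father = self._new_dummy(key[0], sex=1)
            else:
                mother = self._new_dummy(key[0], sex=2)
        self.father[key] = father
        self.mother[key] = mother
        self.sex[key] = sex
        self.genotyped[key] = genotyped
        self._invalidate()
        return key

    def _new_dummy(self, fid: str, sex: int) -> Key:
        self._n_dummy += 1
        key = (fid, f"__dummy{self._n_dummy}")
        self.father[key] = None
        self.mother[key] = None
        self.sex[key] = sex
        self.genotyped[key] = False
        self._dummy.add(key)
        return key

    def _invalidate(self) -> None:
        self._depth_cache = None
        self._kin_cache.clear()

    @classmethod
    def from_records(cls, records: pd.DataFrame, genotyped_keys=None) -> "Pedigree":
        """Build from a six-column ped-record table.

        Parent ids of '0' mean absent.  Parents referenced but not
        present as rows are added as ungenotyped founders.
        """
        ped = cls()
        rows = list(records.itertuples(index=False))
        keys = {(r.fid, r.iid) for r in rows}
        # first pass: referenced-but-absent parents become founders
        for r in rows:
            for pid, sx in ((r.father, 1), (r.mother, 2)):
                if pid not in ("0", 0, None) and (r.fid, str(pid)) not in keys:
                    ped.add((r.fid, str(pid)), sex=sx, genotyped=False)
                    keys.add((r.fid, str(pid)))
        for r in rows:
            fa = None if r.father in ("0", 0, None) else (r.fid, str(r.father))
            mo = None if r.mother in ("0", 0, None) else (r.fid, str(r.mother))
            if genotyped_keys is None:
                gt = True
            else:
                gt = (r.fid, r.iid) in genotyped_keys
            ped.add((r.fid, r.iid), fa, mo, sex=int(r.sex), genotyped=gt)
        return ped

    # -- structure ----------------------------------------------------

    def members(self, genotyped_only: bool = False) -> list[Key]:
        out = [k for k in self.father if k not in self._dummy]
        if genotyped_only:
            out = [k for k in out if self.genotyped[k]]
        return sorted(out)

    def parents(self, key: Key) -> tuple[Key | None, Key | None]:
        return self.father[key], self.mother[key]

    def is_founder(self, key: Key) -> bool:
        return self.father[key] is None

    def _depth(self, key: Key) -> int:
        """Generation depth (founders 0); detects parent-link cycles."""
        if self._depth_cache is None:
            self._depth_cache = {}
        cache = self._depth_cache
        if key in cache:
            return cache[key]
        # iterative DFS with cycle detection
        state: dict[Key, int] = {}
        stack = [key]
        while stack:
            k = stack[-1]
            if k in cache:
                stack.pop()
                continue
            st = state.get(k, 0)
            if st == 0:
                state[k] = 1
                for p in (self.father[k], self.mother[k]):
                    if p is not None and p not in cache:
                        if state.get(p) == 1:
                            raise PedigreeError(f"pedigree cycle involving {p}")
                        stack.append(p)
            else:
                stack.pop()
                ps = [p for p in (self.father[k], self.mother[k]) if p is not None]
                cache[k] = 0 if not ps else 1 + max(cache[p] for p in ps)
                state[k] = 2
        return cache[key]

    def is_ancestor(self, a: Key, b: Key) -> bool:
        """True if ``a`` is a strict ancestor of ``b``."""
        seen = set()
        stack = [p for p in self.parents(b) if p is not None]
        while stack:
            k = stack.pop()
            if k == a:
                return True
            if k in seen:
                continue
            seen.add(k)
            stack.extend(p for p in self.parents(k) if p is not None)
        return False

    # -- kinship ------------------------------------------------------

    def inbreeding(self, key: Key) -> float:
        fa, mo = self.parents(key)
        if fa is None or mo is None:
            return 0.0
        return self.kinship(fa, mo)

    def kinship(self, a: Key, b: Key) -> float:
        """Kinship coefficient phi(a, b) by the classical recursion.

        phi(a, a) = (1 + f_a)/2; for distinct individuals the recursion
        descends through the parents of the deeper member, which is
        never an ancestor of the other.
        """
        if a not in self.father:
            raise KeyError(f"unknown individual {a}")
        if b not in self.father:
            raise KeyError(f"unknown individual {b}")
        return self._kinship(a, b)

    def _kinship(self, a: Key, b: Key) -> float:
        if a == b:
            fa, mo = self.parents(a)
            f = 0.0 if fa is None or mo is None else self._kinship(fa, mo)
            return 0.5 * (1.0 + f)
        pair = (a, b) if a <= b else (b, a)
        cached = self._kin_cache.get(pair)
        if cached is not None:
            return cached
        # descend through the deeper member (never an ancestor of the other)
        if self._depth(a) < self._depth(b):
            a, b = b, a
        fa, mo = self.parents(a)
        if fa is None or mo is None:
            val = 0.0  # both founders (equal depth 0), distinct => unrelated
        else:
            val = 0.5 * (self._kinship(fa, b) + self._kinship(mo, b))
        self._kin_cache[pair] = val
        return val

    def _parents_augmented(self, key: Key) -> tuple[Key, Key]:
        """Parents of ``key``, materializing hidden dummies for founders."""
        fa, mo = self.parents(key)
        if fa is None:
            fa = self._new_dummy(key[0], sex=1)
            mo = self._new_dummy(key[0], sex=2)
            self.father[key] = fa
            self.mother[key] = mo
            self._invalidate()
        return self.father[key], self.mother[key]

    def prior_ibd(self, a: Key, b: Key) -> np.ndarray:
        """Pedigree-implied IBD distribution (p0, p1, p2) for a pair.

        Valid for non-inbred pairs: with parents (Fa, Ma) and (Fb, Mb),
        p2 = phi(Fa,Fb) phi(Ma,Mb) + phi(Fa,Mb) phi(Ma,Fb),
        p1 = 4 phi(a,b) - 2 p2, p0 = 1 - p1 - p2.
        """
        if a == b:
            raise PedigreeError("prior IBD is defined for distinct individuals")
        for k in (a, b):
            if self.inbreeding(k) > PRIOR_TOL:
                raise UnsupportedPedigreeError(
                    f"{k} is inbred; the 3-state IBD model assumes non-inbred pairs"
                )
        fa, ma = self._parents_augmented(a)
        fb, mb = self._parents_augmented(b)
        p2 = self._kinship(fa, fb) * self._kinship(ma, mb) + \
            self._kinship(fa, mb) * self._kinship(ma, fb)
        p1 = 4.0 * self._kinship(a, b) - 2.0 * p2
        p0 = 1.0 - p1 - p2
        return np.array([p0, p1, p2])

    # -- classification -----------------------------------------------

    def _share_parents(self, a: Key, b: Key) -> int:
        """Number of distinct real (non-dummy) parents shared by a and b."""
        pa = {p for p in self.parents(a) if p is not None and p not in self._dummy}
        pb = {p for p in self.parents(b) if p is not None and p not in self._dummy}
        return len(pa & pb)

    def _is_grandparent(self, a: Key, b: Key) -> bool:
        for p in self.parents(b):
            if p is None or p in self._dummy:
                continue
            if a in set(self.parents(p)):
                return True
        return False

    def _is_sib_of_parent(self, a: Key, b: Key, full: bool) -> bool:
        """True if ``a`` is a full (or half) sib of a parent of ``b``."""
        for p in self.parents(b):
            if p is None or p in self._dummy or p == a:
                continue
            shared = self._share_parents(a, p)
            if full and shared == 2:
                return True
            if not full and shared == 1:
                return True
        return False

    def classify_relationship(self, a: Key, b: Key) -> RelationshipType:
        """Match the pair's prior IBD to the catalog, breaking IBD ties
        by pedigree structure.

        (0.5, 0.5, 0): grandparent-grandchild if one is a grandparent of
        the other, half-sib if exactly one parent is shared, avuncular
        if one is a full sib of a parent of the other.  (0.75, 0.25, 0):
        half-avuncular if one is a half-sib of a parent of the other,
        else first cousin.  Pairs matching no catalog row - and inbred
        pairs, outside the 3-state model - are coded 99 ("other").
        """
        try:
            prior = self.prior_ibd(a, b)
        except UnsupportedPedigreeError as exc:
            warnings.warn(f"pair ({a}, {b}) outside 3-state model: {exc}", stacklevel=2)
            return CATALOG_BY_CODE[CODE_OTHER]
        matches = [
            r for r in RELATIONSHIP_CATALOG
            if r.prior_ibd is not None and r.code != CODE_MZ
            and np.allclose(prior, r.prior_ibd, atol=PRIOR_TOL, rtol=0.0)
        ]
        if not matches:
            return CATALOG_BY_CODE[CODE_OTHER]
        codes = {r.code for r in matches}
        if codes == {CODE_HS, CODE_GPC, CODE_AV}:
            if self._is_grandparent(a, b) or self._is_grandparent(b, a):
                return CATALOG_BY_CODE[CODE_GPC]
            if self._share_parents(a, b) == 1:
                return CATALOG_BY_CODE[CODE_HS]
            if self._is_sib_of_parent(a, b, full=True) or self._is_sib_of_parent(b, a, full=True):
                return CATALOG_BY_CODE[CODE_AV]
            warnings.warn(
                f"pair ({a}, {b}) matches (0.5, 0.5, 0) but no catalog structure",
                stacklevel=2,
            )
            return CATALOG_BY_CODE[CODE_OTHER]
        if codes == {CODE_FC, CODE_HAV}:
            if self._is_sib_of_parent(a, b, full=False) or self._is_sib_of_parent(b, a, full=False):
                return CATALOG_BY_CODE[CODE_HAV]
            return CATALOG_BY_CODE[CODE_FC]
        return matches[0]


def enumerate_pairs(pedigrees, within: bool = True, across: bool = True,
                    genotyped_only: bool = True) -> list[tuple[Key, Key]]:
    """Deduplicated, deterministically ordered unordered pairs.

    ``pedigrees`` may be a single :class:`Pedigree` (possibly holding
    several families) or an iterable of them.  Within-family pairs share
    a family id; across-family pairs do not.
    """
    if not (within or across):
        raise ValueError("at least one of within/across must be requested")
    if isinstance(pedigrees, Pedigree):
        pedigrees = [pedigrees]
    members: list[Key] = []
    for ped in pedigrees:
        members.extend(ped.members(genotyped_only=genotyped_only))
    members = sorted(set(members))
    out = []
    for a, b in itertools.combinations(members, 2):
        same = a[0] == b[0]
        if (same and within) or (not same and across):
            out.append((a, b))
    return out
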