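"""Reading, writing and filtering of PLINK-dialect text genotype data.

A dataset is held as three aligned objects:

* a pedigree-record :class:`pandas.DataFrame` with the six leading ped
  columns (``fid iid father mother sex phenotype``),
* a :class:`GenotypeMatrix` of minor-allele dosage codes, and
* a marker table :class:`pandas.DataFrame` (one row per SNP) with columns
  ``marker_id, chromosome, position_bp, position_cm, allele_minor,
  allele_major, freq_minor, n_missing``.

Genotypes are coded as the number of copies of the *minor* allele
(0, 1, 2), with ``MISSING`` (-1) whenever either allele in the ped file
is ``0``.  All filters are inclusive at their thresholds and idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: sentinel for a missing genotype in a dosage matrix
MISSING: int = -1

PED_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]
MARKER_COLUMNS = [
    "marker_id",
    "chromosome",
    "position_bp",
    "position_cm",
    "allele_minor",
    "allele_major",
    "freq_minor",
    "n_missing",
]


class MalformedFileError(ValueError):
    """A ped/map file does not follow the expected column layout."""


class DuplicateKeyError(ValueError):
    """Two ped rows share the same (family id, individual id) key."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers minor-allele dosage codes.

    ``codes`` is an ``int8`` array with entries in {0, 1, 2, MISSING},
    rows aligned with ``individuals`` (a list of (fid, iid) tuples) and
    columns aligned with the accompanying marker table.
    """

    individuals: list[tuple[str, str]]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.individuals):
            raise ValueError(
                f"codes shape {self.codes.shape} inconsistent with "
                f"{len(self.individuals)} individuals"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes outside {0, 1, 2, missing}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def missing_rate(self) -> np.ndarray:
        """Per-individual fraction of missing genotypes."""
        if self.n_markers == 0:
            return np.zeros(self.n_individuals)
        return (self.codes == MISSING).mean(axis=1)

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            [self.individuals[i] for i in index], self.codes[index]
        )

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(list(self.individuals), self.codes[:, index])


def _orient_alleles(a1: np.ndarray, a2: np.ndarray, line_offset: int = 0):
    """Determine minor/major alleles and dosage codes for one marker.

    ``a1``/``a2`` are string arrays of the two allele calls per
    individual; '0' marks a missing call.  The minor allele is the less
    frequent of the two observed symbols; ties broken lexicographically
    so orientation is reproducible.
    """
    n = len(a1)
    stacked = np.concatenate([a1, a2])
    present = stacked != "0"
    symbols, counts = np.unique(stacked[present], return_counts=True)
    if len(symbols) > 2:
        raise MalformedFileError(
            f"marker with more than two alleles: {sorted(symbols)}"
        )
    codes = np.full(n, MISSING, dtype=np.int8)
    missing = (a1 == "0") | (a2 == "0")
    if len(symbols) == 0:  # marker entirely missing
        return "0", "0", codes, int(missing.sum())
    if len(symbols) == 1:
        minor, major = "0", symbols[0]
        codes[~missing] = 0
        return minor, major, codes, int(missing.sum())
    order = np.lexsort((symbols, counts))  # ascending count, then symbol
    minor, major = symbols[order[0]], symbols[order[1]]
    ok = ~missing
    codes[ok] = (a1[ok] == minor).astype(np.int8) + (a2[ok] == minor).astype(np.int8)
    return minor, major, codes, int(missing.sum())


def read_map(map_path) -> pd.DataFrame:
    """Read a PLINK text map (3 or 4 columns) into a marker table.

    Four columns are ``chrom id cM bp``; three columns omit cM.  A cM
    column that is all zeros is treated as absent (NaN).
    """
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 4:
                chrom, mid, cm, bp = parts
                rows.append((chrom, mid, float(cm), int(bp)))
            elif len(parts) == 3:
                chrom, mid, bp = parts
                rows.append((chrom, mid, np.nan, int(bp)))
            else:
                raise MalformedFileError(
                    f"{map_path}: line {ln}: expected 3 or 4 columns, got {len(parts)}"
                )
    tab = pd.DataFrame(rows, columns=["chromosome", "marker_id", "position_cm", "position_bp"])
    if tab["marker_id"].duplicated().any():
        dup = tab["marker_id"][tab["marker_id"].duplicated()].iloc[0]
        raise DuplicateKeyError(f"duplicate marker id {dup!r}")
    if (tab["position_cm"].fillna(0.0) == 0.0).all():
        tab["position_cm"] = np.nan
    tab["allele_minor"] = ""
    tab["allele_major"] = ""
    tab["freq_minor"] = np.nan
    tab["n_missing"] = 0
    return tab[MARKER_COLUMNS]


def read_pedmap(ped_path, map_path):
    """Read a ped/map pair into (records, genotypes, marker table).

    The ped file is whitespace-delimited with six leading columns
    (fid iid father mother sex phenotype) followed by two allele columns
    per marker.  Genotypes are oriented to minor-allele dosage; a
    genotype is missing iff either allele is '0'.
    """
    markers = read_map(map_path)
    n_markers = len(markers)
    keys: set[tuple[str, str]] = set()
    recs = []
    allele_rows = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise MalformedFileError(
                    f"{ped_path}: line {ln}: expected {6 + 2 * n_markers} "
                    f"columns for {n_markers} markers, got {len(parts)}"
                )
            fid, iid = parts[0], parts[1]
            if (fid, iid) in keys:
                raise DuplicateKeyError(f"duplicate individual ({fid}, {iid})")
            keys.add((fid, iid))
            recs.append(parts[:6])
            allele_rows.append(parts[6:])
    records = pd.DataFrame(recs, columns=PED_COLUMNS)
    records["sex"] = records["sex"].astype(int)
    n = len(records)
    codes = np.full((n, n_markers), MISSING, dtype=np.int8)
    if n:
        alleles = np.array(allele_rows)  # n x 2M strings
        minors, majors, nmiss = [], [], []
        for m in range(n_markers):
            mi, ma, col, nm = _orient_alleles(alleles[:, 2 * m], alleles[:, 2 * m + 1])
            codes[:, m] = col
            minors.append(mi)
            majors.append(ma)
            nmiss.append(nm)
        markers["allele_minor"] = minors
        markers["allele_major"] = majors
        markers["n_missing"] = nmiss
    geno = GenotypeMatrix(list(zip(records["fid"], records["iid"])), codes)
    markers["freq_minor"] = estimate_allele_freqs(geno)
    return records, geno, markers


def write_pedmap(ped_path, map_path, records: pd.DataFrame, geno: GenotypeMatrix,
                 markers: pd.DataFrame) -> None:
    """Write records/genotypes/markers back to PLINK text ped/map files."""
    with open(map_path, "w") as fh:
        for _, r in markers.iterrows():
            cm = r["position_cm"]
            cm = 0.0 if pd.isna(cm) else float(cm)
            fh.write(f"{r['chromosome']}\t{r['marker_id']}\t{cm:g}\t{int(r['position_bp'])}\n")
    minor = markers["allele_minor"].to_numpy()
    major = markers["allele_major"].to_numpy()
    # allele strings per dosage code; missing -> "0 0"
    with open(ped_path, "w") as fh:
        for i, (_, r) in enumerate(records.iterrows()):
            lead = [r["fid"], r["iid"], r["father"], r["mother"], str(int(r["sex"])), str(r["phenotype"])]
            row = geno.codes[i]
            out = []
            for m, c in enumerate(row):
                if c == MISSING:
                    out.append("0 0")
                elif c == 0:
                    out.append(f"{major[m]} {major[m]}")
                elif c == 1:
                    out.append(f"{minor[m]} {major[m]}")
                else:
                    out.append(f"{minor[m]} {minor[m]}")
            fh.write(" ".join(lead + out) + "\n")


def write_marker_table(path, markers: pd.DataFrame) -> None:
    """Write a marker/frequency table as tab-separated text with header."""
    markers.to_csv(path, sep="\t", index=False)


def autosomal_marker_mask(markers: pd.DataFrame) -> np.ndarray:
    """True for markers on autosomes (chromosome labels 1-22).

    Sex chromosomes and mitochondria (X, Y, XY, MT, 23-26) are excluded
    from all pairwise analyses: the likelihood model assumes autosomal
    diploid sharing.
    """
    def is_autosome(label) -> bool:
        s = str(label).lower().removeprefix("chr")
        return s.isdigit() and 1 <= int(s) <= 22

    return markers["chromosome"].map(is_autosome).to_numpy()


def estimate_allele_freqs(geno: GenotypeMatrix, individual_mask=None) -> np.ndarray:
    """Minor-allele frequency per marker from dosage codes.

    freq = (sum of codes) / (2 * number of non-missing genotypes).
    Markers with no non-missing genotype get NaN (unusable downstream).
    ``individual_mask`` restricts the computation to a subset of rows
    (e.g. founders only).
    """
    codes = geno.codes
    if individual_mask is not None:
        codes = codes[np.asarray(individual_mask)]
    ok = codes != MISSING
    n_ok = ok.sum(axis=0)
    total = np.where(ok, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_ok > 0, total / (2.0 * np.maximum(n_ok, 1)), np.nan)
    return freq


def filter_individuals_by_missingness(geno: GenotypeMatrix, max_missing_rate: float) -> GenotypeMatrix:
    """Retain individuals whose missing-genotype fraction is <= threshold."""
    if not 0.0 <= max_missing_rate <= 1.0:
        raise ValueError("max_missing_rate must be in [0, 1]")
    keep = np.flatnonzero(geno.missing_rate() <= max_missing_rate)
    if keep.size == 0:
        warnings.warn("all individuals removed by missingness filter", stacklevel=2)
    return geno.take_individuals(keep)


def filter_markers_maf(markers: pd.DataFrame, min_maf: float) -> np.ndarray:
    """Indices of markers with freq_minor >= min_maf.

    Monomorphic markers (frequency 0 or undefined) are always dropped
    when ``min_maf`` is positive.
    """
    freq = markers["freq_minor"].to_numpy(dtype=float)
    if min_maf <= 0:
        return np.flatnonzero(~np.isnan(freq))
    return np.flatnonzero(np.nan_to_num(freq, nan=-1.0) >= min_maf)


def _r2_matrix(codes: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage columns.

    Missing entries are handled by pairwise-complete observation; a
    constant column has r^2 = 0 with everything.
    """
    n, m = codes.shape
    x = codes.astype(float)
    miss = codes == MISSING
    if not miss.any():
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(x, rowvar=False)
        r2 = np.nan_to_num(c, nan=0.0) ** 2
        np.fill_diagonal(r2, 1.0)
        return r2
    r2 = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            ok = ~(miss[:, a] | miss[:, b])
            if ok.sum() < 2:
                continue
            xa, xb = x[ok, a], x[ok, b]
            sa, sb = xa.std(), xb.std()
            if sa == 0 or sb == 0:
                continue
            r = np.corrcoef(xa, xb)[0, 1]
            r2[a, b] = r2[b, a] = 0.0 if np.isnan(r) else r * r
    np.fill_diagonal(r2, 1.0)
    return r2


def ld_prune(geno: GenotypeMatrix, markers: pd.DataFrame, window_size: int = 200,
             step: int = 50, r2_max: float = 0.2) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns retained marker indices.

    Within each window of ``window_size`` markers (advanced by ``step``)
    per chromosome, while any retained pair has squared dosage
    correlation > ``r2_max``, the member with the lower minor-allele
    frequency is removed (ties: the later marker in genome order).
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    freq = markers["freq_minor"].to_numpy(dtype=float)
    retained = np.ones(len(markers), dtype=bool)
    for chrom in pd.unique(markers["chromosome"]):
        idx = np.flatnonzero((markers["chromosome"] == chrom).to_numpy())
        nc = len(idx)
        start = 0
        while start < nc:
            win = idx[start:start + window_size]
            live = [j for j in win if retained[j]]
            if len(live) >= 2:
                sub = geno.codes[:, live]
                r2 = _r2_matrix(sub)
                k = len(live)
                changed = True
                while changed:
                    changed = False
                    for a in range(k):
                        if not retained[live[a]]:
                            continue
                        for b in range(a + 1, k):
                            if not retained[live[b]]:
                                continue
                            if r2[a, b] > r2_max:
                                fa, fb = freq[live[a]], freq[live[b]]
                                # remove lower MAF; tie -> later genome order
                                drop = live[b] if (fb < fa or fb == fa) else live[a]
                                retained[drop] = False
                                changed = True
                                break
                        if changed:
                            break
            if start + window_size >= nc:
                break
            start += step
    return np.flatnonzero(retained)


def read_reference_map(path) -> pd.DataFrame:
    """Read a reference genetic map: 3 columns (chrom, bp, cM).

    Whitespace- or tab-separated; a single header line is tolerated.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise MalformedFileError(
                    f"{path}: line {ln}: expected 3 columns (chrom, bp, cM)")
            try:
                rows.append((parts[0], int(parts[1]), float(parts[2])))
            except ValueError:
                if ln == 1:  # header line
                    continue
                raise MalformedFileError(
                    f"{path}: line {ln}: non-numeric bp/cM") from None
    return pd.DataFrame(rows, columns=["chromosome", "position_bp", "position_cm"])


def interpolate_genetic_map(markers: pd.DataFrame, reference_map: pd.DataFrame) -> pd.DataFrame:
    """Fill position_cm by linear interpolation against anchor triples.

    ``reference_map`` needs columns ``chromosome, position_bp,
    position_cm`` with cM monotone in bp within each chromosome.
    Outside the anchor range positions are clamped to the nearest
    anchor's cM.
    """
    out = markers.copy()
    cm = np.empty(len(markers))
    for chrom, grp in markers.groupby("chromosome", sort=False):
        ref = reference_map[reference_map["chromosome"] == chrom]
        if ref.empty:
            raise ValueError(f"reference map has no anchors for chromosome {chrom!r}")
        ref = ref.sort_values("position_bp")
        rb = ref["position_bp"].to_numpy(dtype=float)
        rc = ref["position_cm"].to_numpy(dtype=float)
        if np.any(np.diff(rc) < 0):
            raise ValueError(f"reference cM not monotone in bp on chromosome {chrom!r}")
        cm[grp.index.to_numpy()] = np.interp(grp["position_bp"].to_numpy(dtype=float), rb, rc)
    out["position_cm"] = cm
    return out


def subsample_markers(marker_index, n_target: int, seed: int) -> np.ndarray:
    """Uniform random marker subset without replacement, genome-sorted."""
    marker_index = np.asarray(marker_index)
    if n_target > marker_index.size:
        raise ValueError(
            f"cannot subsample {n_target} markers from {marker_index.size}"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(marker_index, size=n_target, replace=False)
    return np.sort(pick)
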