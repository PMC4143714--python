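import numpy as np
import pandas as pd
import pytest

from kinscan import pedio, simulate
from kinscan.pedigree import Pedigree


@pytest.fixture
def toy_pedmap(tmp_path):
    """Two individuals, two markers, written as plain ped/map text."""
    ped = tmp_path / "toy.ped"
    map_ = tmp_path / "toy.map"
    ped.write_text(
        "FAM1 A 0 0 1 0 A A A C\n"
        "FAM1 B 0 0 2 0 A C C C\n"
    )
    map_.write_text(
        "1 snp1 0 1000\n"
        "1 snp2 0 2000\n"
    )
    return ped, map_


@pytest.fixture
def random_dataset():
    """A 10-individual x 50-marker dataset with some missingness."""
    rng = np.random.default_rng(42)
    freqs = rng.uniform(0.1, 0.5, 50)
    codes = (rng.random((10, 50, 2)) < freqs[None, :, None]).sum(axis=2).astype(np.int8)
    codes[rng.random((10, 50)) < 0.05] = pedio.MISSING
    geno = pedio.GenotypeMatrix([("F1", f"I{i}") for i in range(10)], codes)
    # orient to the sample minor allele so written files re-read identically
    est = pedio.estimate_allele_freqs(geno)
    flip = est > 0.5
    codes[:, flip] = np.where(codes[:, flip] == pedio.MISSING,
                              pedio.MISSING, 2 - codes[:, flip])
    geno = pedio.GenotypeMatrix(geno.individuals, codes)
    markers = simulate.uniform_genetic_map(50)
    markers["freq_minor"] = pedio.estimate_allele_freqs(geno)
    markers["allele_minor"] = "1"
    markers["allele_major"] = "2"
    records = pd.DataFrame(
        [("F1", f"I{i}", "0", "0", 1 + i % 2, 0) for i in range(10)],
        columns=pedio.PED_COLUMNS,
    )
    return records, geno, markers


def nuclear_family(n_children=2):
    """Father, mother and children C0..C(n-1)."""
    ped = Pedigree()
    f = ped.add(("F", "dad"), sex=1)
    m = ped.add(("F", "mom"), sex=2)
    kids = [ped.add(("F", f"C{i}"), f, m) for i in range(n_children)]
    return ped, f, m, kids
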