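# kinscan

Detection of pedigree errors and cryptic relatedness from genome-wide
SNP genotypes, for family-based and population genetic studies.

Recorded pedigrees are frequently wrong — undocumented nonpaternity,
adoptions, sample duplications and swaps — and "unrelated" panels often
contain hidden relatives.  Both inflate false positives or destroy
power in linkage and association analyses.  `kinscan` estimates, for
every pair of genotyped individuals, the probability distribution
p = (p0, p1, p2) of sharing 0, 1 or 2 alleles identical by descent
(IBD) at a random autosomal marker, compares it with the relationship
the pedigree implies, and tests discrepancies formally.

The core is the marker-mixture likelihood

    L(p) = Σ_m log Σ_{i=0,1,2} P(G_m | D_m = i) p_i

maximized over the IBD simplex by EM, where G_m is the pair's genotype
at SNP m and P(G_m | D_m = i) are the Hardy-Weinberg conditional
probabilities at the marker's allele frequency.  The kinship
coefficient follows as φ = p1/4 + p2/2.  A faster but noisier
method-of-moments estimator from identity-by-state counts (the
approach PLINK's `--genome` takes) is included as a comparator.
Putative relationships are tested with the maximum likelihood ratio
test

    MLRT = max_{R1 ∈ A} log L(R1) − log L(R0),

whose null distribution is calibrated by simulation (gene-dropping
with Haldane recombination in linked mode), since 2·MLRT is not
chi-squared — the alternatives form a discrete catalog (MZ twin,
parent-offspring, full sib, half-sib, grandparent-grandchild,
avuncular, first cousin, half-avuncular, half-first cousin,
half-sib+first cousin, unrelated), not a nested family.

A synthetic-study generator produces multigeneration families plus an
unrelated panel with planted errors (duplicates, parent
misassignments, cryptic links) and an exact truth table, so the whole
pipeline is testable end to end without access-restricted data.

## Worked example

Generate a small study — 3 families (two offspring generations, one
remarriage each) plus 12 unrelated singletons at 20,000 SNPs — with
seven planted errors, scan every pair, and flag outliers:

```python
from kinscan import simulate, cli

plan = simulate.default_error_plan(3, 2, 12, 2)
study = simulate.make_synthetic_study(n_families=3, family_depth=2,
                                      n_unrelated=12, n_markers=20_000,
                                      error_plan=plan, seed=1, n_children=2)
study.write("demo.ped", "demo.map", "demo.truth.tsv")

result = cli.scan_data(study.records, study.genotypes, study.markers)
flagged = cli.flag_outliers(result)          # distance > 0.1 from prior
print(len(result), len(flagged), len(study.truth))
```

prints `1225 34 34`: of 1225 pairs scanned, exactly the 34 pairs whose
true relationship differs from the recorded one are flagged.  The
first flagged rows:

```
FID1 IID1 FID2 IID2  reltype  commark     p0     p1     p2  distance
 F01   I1  F01   I8        6    20000 0.5018 0.4954 0.0029  0.702584
 F01  I10  F01   I8        2    20000 0.2752 0.4622 0.2626  0.227956
 F01  I10 U001   I1        6    20000 0.7450 0.2499 0.0051  0.357036
 F01  I12  F01 I12D        1    20000 0.0000 0.0000 1.0000  0.559017
```

Reading these: I8's recorded father is not his biological one, so his
recorded-unrelated pair with grandmother I1 estimates at the
grandparental (0.5, 0.5, 0) instead of (1, 0, 0); his recorded
half-sib I10 estimates at full-sib sharing (0.25, 0.5, 0.25); the
married-in founder I10 and singleton U001 are cryptic half-sibs; and
I12/I12D — a planted sample duplicate recorded as a full sib — hits the
MZ-twin vertex (0.0000, 0.0000, 1.0000).  `commark` is the number of
SNPs genotyped in both members, the effective sample size per pair.

The duplicate can then be tested formally:

```python
r = cli.test_pair("demo.ped", "demo.map", "F01", "I12", "F01", "I12D",
                  reps=999, seed=1)
```

which reports `null reltype 1 (FS)  p=0.001  plausible 11 (MZ)  p=N/A`:
the full-sib null is rejected at the resolution of 999 replicates, the
best-fitting alternative is MZ twin, and no plausible-type p-value
exists for an exact genotype duplicate.

The same workflow is available from the shell:

```sh
kinscan simulate --families 3 --depth 2 --children 2 --unrelated 12 \
        --markers 20000 --seed 1 --plant-errors \
        --ped demo.ped --map demo.map --truth demo.truth.tsv
kinscan scan --geno demo.ped --map demo.map --out report.tsv
kinscan test-pair --geno demo.ped --map demo.map F01 I12 F01 I12D --reps 999
kinscan prune --geno raw.ped --map raw.map --maf 0.05 --out-prefix pruned
```

Note that scanning written files re-estimates allele frequencies from
the sample; at a few dozen individuals this adds visible apparent
relatedness (see `docs/methods.md`), which is why the in-memory example
above uses the generator's founder frequencies.

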