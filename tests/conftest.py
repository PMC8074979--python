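import numpy as np
import pytest

from popkit.datatypes import GenotypeMatrix, SequenceAlignment


@pytest.fixture
def toy_matrix():
    """6 individuals x 8 sites, two localities, ancestral allele 0."""
    rng = np.random.default_rng(42)
    geno = rng.integers(0, 3, size=(6, 8)).astype(np.int8)
    return GenotypeMatrix(
        individuals=[f"ind{i}" for i in range(6)],
        localities=["north"] * 3 + ["south"] * 3,
        chrom=np.array(["chr1"] * 4 + ["chr2"] * 4, dtype=object),
        pos=np.array([100, 200, 5000, 40000, 100, 900, 1800, 70000]),
        geno=geno,
        alleles=np.array([("A", "C")] * 8, dtype=object),
        outgroup=np.zeros(8, dtype=np.int8),
    )


@pytest.fixture
def small_alignment():
    return SequenceAlignment(
        names=["s1", "s2", "s3", "s4"],
        sequences=["ACGTACGT", "ACGTACGA", "ACGTACGA", "TCGTACGA"],
        localities=["north", "north", "south", "south"],
    )


def brute_force_pi(sequences):
    """Independent double-loop nucleotide diversity with pairwise deletion."""
    n = len(sequences)
    total, pairs = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            diff = used = 0
            for a, b in zip(sequences[i], sequences[j]):
                if a in "N-" or b in "N-":
                    continue
                used += 1
                diff += a != b
            if used:
                total += diff / used
                pairs += 1
    return total / pairs


def brute_force_hudson(geno, idx1, idx2):
    """Per-site Hudson components by explicit loops; returns (num, den) lists."""
    nums, dens = [], []
    n_sites = geno.shape[1]
    for s in range(n_sites):
        def freq(idx):
            alleles = []
            for i in idx:
                g = geno[i, s]
                if g >= 0:
                    alleles += [1] * int(g) + [0] * (2 - int(g))
            return alleles
        a1, a2 = freq(idx1), freq(idx2)
        if len(a1) < 2 or len(a2) < 2:
            nums.append(float("nan"))
            dens.append(float("nan"))
            continue
        p1 = sum(a1) / len(a1)
        p2 = sum(a2) / len(a2)
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (len(a1) - 1)
               - p2 * (1 - p2) / (len(a2) - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        nums.append(num)
        dens.append(den)
    return np.array(nums), np.array(dens)


def random_matrix(rng, n_ind=8, n_sites=60, missing_rate=0.1, n_loc=2):
    geno = rng.integers(0, 3, size=(n_ind, n_sites)).astype(np.int8)
    geno[rng.random(geno.shape) < missing_rate] = -1
    locs = [f"loc{i % n_loc}" for i in range(n_ind)]
    return GenotypeMatrix(
        individuals=[f"i{k}" for k in range(n_ind)],
        localities=locs,
        chrom=np.array(["chr1"] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1) * 10,
        geno=geno,
        outgroup=np.zeros(n_sites, dtype=np.int8),
    )
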