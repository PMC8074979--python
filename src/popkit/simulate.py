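"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: island-model
coalescent genotypes (panmixia vs. structure), mitochondrial haplotypes
mutated on a coalescent tree, pedigree genotypes for relatedness, per-scaffold
depth profiles with halved X depth in males, and fragmented toy genomes for
scaffolding.

The coalescent engine is a discrete-event structured Kingman coalescent.
Time is scaled so that a within-deme pair coalesces at rate 1; each lineage
migrates at rate M/2 (M = 4Nm) to a uniformly chosen other deme; mutations
fall on branches at rate theta/2 per lineage per unit time under the
infinite-sites model, so the expected pairwise diversity of a panmictic
sample is exactly theta per block.  Blocks are independent trees with no
intra-block recombination, matching the granularity at which the downstream
block jackknife operates.  Lineages are represented as leaf-set bitmasks, so
a mutation is a bitmask of derived carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .datatypes import GenotypeMatrix, DepthProfile, SequenceAlignment

DEFAULT_LOCALITIES = ("SouthAfrica", "WestAustralia", "SouthAustralia", "NewZealand")

BASES = np.array(list("ACGT"))


def spawn_seeds(seed: int, n: int) -> list:
    """Derive ``n`` independent child seeds (< 2**31) from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# structured Kingman coalescent
# ---------------------------------------------------------------------------

@dataclass
class CoalescentParams:
    """Island-model coalescent settings for one simulated dataset.

    ``theta`` is the scaled mutation rate per block (4*N*mu*L for diploid
    nuclear data, 2*N*mu*L for haploid mitochondria); ``migration_rate`` is
    the scaled rate 4Nm between deme pairs.  ``samples_per_deme`` counts
    haploid genomes and must be even so they pair into diploids.
    """

    n_demes: int = 1
    samples_per_deme: int = 8
    theta: float = 5.0
    migration_rate: float = 1.0
    n_blocks: int = 100
    block_length_bp: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.migration_rate < 0:
            raise ValueError("migration_rate must be >= 0")
        if min(self.n_demes, self.samples_per_deme, self.n_blocks,
               self.block_length_bp) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_demes > 1 and self.migration_rate == 0:
            raise ValueError(
                "migration_rate must be > 0 with multiple demes "
                "(isolated demes never find a common ancestor)"
            )


def _coalescent_branches(rng: np.random.Generator, n_demes: int,
                         samples_per_deme: int, migration_rate: float):
    """Simulate one structured-coalescent tree.

    Returns a list of (leafset bitmask, branch duration) for every non-root
    lineage, from which mutations can be dropped.
    """
    leafsets = []
    demes = []
    births = []
    k = 0
    for d in range(n_demes):
        for _ in range(samples_per_deme):
            leafsets.append(1 << k)
            demes.append(d)
            births.append(0.0)
            k += 1
    branches = []
    t = 0.0
    mig = migration_rate / 2.0
    while len(leafsets) > 1:
        counts = np.bincount(demes, minlength=n_demes)
        coal_rates = counts * (counts - 1) / 2.0
        total_coal = coal_rates.sum()
        total_mig = mig * len(leafsets) if n_demes > 1 else 0.0
        total = total_coal + total_mig
        t += rng.exponential(1.0 / total)
        if rng.random() * total < total_coal:
            d = rng.choice(n_demes, p=coal_rates / total_coal)
            members = [i for i, dd in enumerate(demes) if dd == d]
            i, j = rng.choice(len(members), size=2, replace=False)
            i, j = members[i], members[j]
            if i > j:
                i, j = j, i
            branches.append((leafsets[i], t - births[i]))
            branches.append((leafsets[j], t - births[j]))
            leafsets[i] |= leafsets[j]
            births[i] = t
            del leafsets[j], demes[j], births[j]
        else:
            i = rng.integers(len(leafsets))
            dest = rng.integers(n_demes - 1)
            if dest >= demes[i]:
                dest += 1
            demes[i] = int(dest)
    return branches


def _drop_mutations(rng: np.random.Generator, branches, theta: float):
    """Poisson mutations on branches; returns list of carrier bitmasks."""
    durations = np.array([b[1] for b in branches])
    total_len = durations.sum()
    n_mut = rng.poisson(theta / 2.0 * total_len)
    if n_mut == 0:
        return []
    which = rng.choice(len(branches), size=n_mut, p=durations / total_len)
    return [branches[i][0] for i in which]


def simulate_island_genotypes(params: CoalescentParams,
                              localities: Optional[list] = None) -> GenotypeMatrix:
    """Simulate diploid genotypes under the n-island coalescent.

    Each block is one independent tree; consecutive haploid samples within a
    deme are paired into diploids.  Allele 1 is the derived allele and the
    per-site outgroup/ancestral track is allele 0, so four-taxon patterns can
    be polarised directly.  Identical seeds give identical output.
    """
    if params.samples_per_deme % 2:
        raise ValueError("samples_per_deme must be even to pair into diploids")
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    n_hap = params.n_demes * params.samples_per_deme
    n_ind = n_hap // 2
    per_deme_ind = params.samples_per_deme // 2
    if localities is None:
        localities = [f"deme{d}" for d in range(params.n_demes)]
    ind_names = []
    ind_locs = []
    for d in range(params.n_demes):
        for i in range(per_deme_ind):
            ind_names.append(f"{localities[d]}_ind{i}")
            ind_locs.append(localities[d])

    chroms, poss, cols = [], [], []
    for b in range(params.n_blocks):
        branches = _coalescent_branches(
            rng, params.n_demes, params.samples_per_deme, params.migration_rate
        )
        masks = _drop_mutations(rng, branches, params.theta)
        n_mut = len(masks)
        if n_mut == 0:
            continue
        if n_mut > params.block_length_bp:
            raise ValueError("more mutations than available positions in block")
        positions = np.sort(
            rng.choice(params.block_length_bp, size=n_mut, replace=False) + 1
        )
        for p, m in zip(positions, masks):
            col = np.fromiter(
                (((m >> (2 * i)) & 1) + ((m >> (2 * i + 1)) & 1) for i in range(n_ind)),
                dtype=np.int8, count=n_ind,
            )
            chroms.append(f"block{b}")
            poss.append(int(p))
            cols.append(col)
    n_sites = len(cols)
    geno = (np.column_stack(cols) if n_sites
            else np.zeros((n_ind, 0), dtype=np.int8))
    alleles = np.array([("A", "C")] * n_sites, dtype=object).reshape(n_sites, 2)
    return GenotypeMatrix(
        individuals=ind_names,
        localities=ind_locs,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        geno=geno,
        alleles=alleles,
        outgroup=np.zeros(n_sites, dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# mitochondrial haplotypes
# ---------------------------------------------------------------------------

def simulate_mito_haplotypes(n_samples: int, theta: float, seq_length: int,
                             seed: int = 0,
                             localities=DEFAULT_LOCALITIES) -> SequenceAlignment:
    """Haploid sequences mutated on a single coalescent tree.

    Mutations are placed at distinct uniform positions of a random ancestral
    sequence (infinite sites on a finite sequence); the derived state is a
    uniformly chosen different base.  Locality labels are assigned
    round-robin.  Expected per-site nucleotide diversity is theta/seq_length.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    branches = _coalescent_branches(rng, 1, n_samples, 0.0)
    masks = _drop_mutations(rng, branches, theta)
    if len(masks) > seq_length:
        raise ValueError(
            f"{len(masks)} mutations cannot be placed at distinct positions of a "
            f"{seq_length}-bp sequence; increase seq_length"
        )
    ancestral = rng.choice(BASES, size=seq_length)
    seqs = np.tile(ancestral, (n_samples, 1))
    if masks:
        sites = rng.choice(seq_length, size=len(masks), replace=False)
        for pos, mask in zip(sites, masks):
            derived = rng.choice([b for b in BASES if b != ancestral[pos]])
            carriers = [i for i in range(n_samples) if (mask >> i) & 1]
            seqs[carriers, pos] = derived
    names = [f"mt{i:02d}" for i in range(n_samples)]
    locs = [localities[i % len(localities)] for i in range(n_samples)]
    return SequenceAlignment(
        names=names,
        sequences=["".join(row) for row in seqs],
        localities=locs,
    )


# ---------------------------------------------------------------------------
# pedigrees
# ---------------------------------------------------------------------------

@dataclass
class PedigreeSpec:
    """Founders in Hardy-Weinberg plus Mendelian matings.

    ``matings`` is a list of (parent_a, parent_b, n_offspring) referring to
    previously defined individuals (founders are ``F0``, ``F1``, ...;
    offspring of mating m are ``O{m}_0``, ...).  Founder allele frequencies
    are drawn uniformly from ``allele_freq_range`` per site.
    """

    founders: int = 200
    matings: list = field(default_factory=list)
    allele_freq_range: tuple = (0.1, 0.9)
    n_sites: int = 20_000

    def __post_init__(self):
        if self.n_sites < 1 or self.founders < 1:
            raise ValueError("founders and n_sites must be >= 1")
        names = {f"F{i}" for i in range(self.founders)}
        for m, (pa, pb, n_off) in enumerate(self.matings):
            if pa not in names or pb not in names:
                raise ValueError(f"mating {m} references unknown parent {pa!r}/{pb!r}")
            if n_off < 1:
                raise ValueError("n_offspring must be >= 1")
            names |= {f"O{m}_{k}" for k in range(n_off)}


def simulate_pedigree_genotypes(spec: PedigreeSpec, seed: int = 0):
    """Genotypes for a pedigree plus the truth parent map.

    Returns ``(GenotypeMatrix, parents)`` where ``parents`` maps each
    individual to its (parent_a, parent_b) tuple or ``None`` for founders.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lo, hi = spec.allele_freq_range
    freqs = rng.uniform(lo, hi, size=spec.n_sites)
    genos = {}
    parents = {}
    for i in range(spec.founders):
        name = f"F{i}"
        genos[name] = (rng.random((2, spec.n_sites)) < freqs).sum(axis=0).astype(np.int8)
        parents[name] = None
    for m, (pa, pb, n_off) in enumerate(spec.matings):
        for k in range(n_off):
            name = f"O{m}_{k}"
            allele_a = (rng.random(spec.n_sites) * 2 < genos[pa]).astype(np.int8)
            allele_b = (rng.random(spec.n_sites) * 2 < genos[pb]).astype(np.int8)
            genos[name] = allele_a + allele_b
            parents[name] = (pa, pb)
    names = list(genos)
    gm = GenotypeMatrix(
        individuals=names,
        localities=["pedigree"] * len(names),
        chrom=np.array(["chr1"] * spec.n_sites, dtype=object),
        pos=np.arange(1, spec.n_sites + 1, dtype=np.int64),
        geno=np.vstack([genos[n] for n in names]),
    )
    return gm, parents


# ---------------------------------------------------------------------------
# depth profiles for sexing
# ---------------------------------------------------------------------------

@dataclass
class DepthSimParams:
    """Poisson depth model: autosomes at lambda_auto in both sexes, X at
    lambda_auto/2 in males and lambda_auto in females."""

    lambda_auto: float = 10.0
    n_x_scaffolds: int = 100
    n_auto_scaffolds: int = 100
    n_ambiguous: int = 0
    scaffold_length_bp: int = 100_000
    sexes: tuple = ("male", "female")
    seed: int = 0

    def __post_init__(self):
        if self.lambda_auto <= 0:
            raise ValueError("lambda_auto must be > 0")
        if min(self.n_x_scaffolds, self.n_auto_scaffolds, self.n_ambiguous) < 0:
            raise ValueError("scaffold counts must be >= 0")
        if self.scaffold_length_bp < 1:
            raise ValueError("scaffold_length_bp must be >= 1")
        bad = set(self.sexes) - {"male", "female"}
        if bad:
            raise ValueError(f"unknown sexes: {sorted(bad)}")


def simulate_depth_profiles(params: DepthSimParams) -> list:
    """One DepthProfile per individual in ``params.sexes`` (truth order kept).

    Per-scaffold mean depth is Poisson(lambda * L) / L, i.e. the average of L
    base-level Poisson draws, so it concentrates tightly around lambda.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    L = params.scaffold_length_bp
    scaffolds = (
        [(f"X{i}", "x_linked") for i in range(params.n_x_scaffolds)]
        + [(f"A{i}", "autosomal") for i in range(params.n_auto_scaffolds)]
        + [(f"U{i}", "ambiguous") for i in range(params.n_ambiguous)]
    )
    profiles = []
    for idx, sex in enumerate(params.sexes):
        depths = {}
        for name, cls in scaffolds:
            lam = params.lambda_auto
            if cls == "x_linked" and sex == "male":
                lam /= 2.0
            depths[name] = rng.poisson(lam * L) / L
        profiles.append(DepthProfile(
            individual=f"ind{idx:03d}_{sex}",
            scaffold_depths=depths,
            scaffold_class={name: cls for name, cls in scaffolds},
            scaffold_length={name: L for name, _ in scaffolds},
        ))
    return profiles


# ---------------------------------------------------------------------------
# toy genomes and fragmentation
# ---------------------------------------------------------------------------

def random_genome(length: int, seed: int = 0) -> str:
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return "".join(rng.choice(BASES, size=length))


REVCOMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(REVCOMP)[::-1]


def fragment_genome(genome: str, n_contigs: int, seed: int = 0,
                    flip_fraction: float = 0.5, min_contig_bp: int = 800):
    """Cut a genome into contigs and scramble orientations.

    Cut positions are uniform subject to every contig being at least
    ``min_contig_bp`` long.  Assemblers emit size-filtered contigs, and a
    contig shorter than (smallest insert - 2 x read length) — 700 bp for a
    1 kb library of 150 bp reads — can be skipped entirely by every mate-pair
    library, so its adjacencies are unresolvable by any link-based
    scaffolder; the default floor keeps every contig resolvable.
    Returns ``(contigs, layout)``: ``contigs`` maps contig id to its (possibly
    reverse-complemented) sequence; ``layout`` is the truth, a list of
    ``(contig_id, genome_start, strand)`` in genome order with strand ``+``
    meaning the stored contig equals the genome slice.  Concatenating the
    strand-corrected contigs in layout order restores the genome exactly.
    """
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    min_contig_bp = min(min_contig_bp, max(len(genome) // n_contigs, 1))
    if n_contigs * min_contig_bp > len(genome):
        raise ValueError("n_contigs exceeds genome length")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if n_contigs == 1:
        cuts = []
    else:
        # uniform partition with a floor: spread the slack, then re-add the floor
        slack = len(genome) - n_contigs * min_contig_bp
        u = np.sort(rng.integers(0, slack + 1, size=n_contigs - 1))
        cuts = [int(x) + (i + 1) * min_contig_bp for i, x in enumerate(u)]
    bounds = [0] + list(cuts) + [len(genome)]
    contigs = {}
    layout = []
    for i in range(n_contigs):
        start, end = int(bounds[i]), int(bounds[i + 1])
        seq = genome[start:end]
        strand = "+"
        if rng.random() < flip_fraction:
            seq = reverse_complement(seq)
            strand = "-"
        cid = f"contig{i:03d}"
        contigs[cid] = seq
        layout.append((cid, start, strand))
    return contigs, layout


def restore_from_layout(contigs: dict, layout: list) -> str:
    """Invert :func:`fragment_genome` using the truth layout."""
    parts = []
    for cid, _start, strand in sorted(layout, key=lambda t: t[1]):
        seq = contigs[cid]
        parts.append(seq if strand == "+" else reverse_complement(seq))
    return "".join(parts)
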