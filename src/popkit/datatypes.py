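"""Core in-memory containers shared across the pipeline.

Genotypes are stored as counts of the site's "allele 1" per individual
(0, 1, 2; ``-1`` for missing).  Which physical allele plays the role of
allele 1 is a per-site convention: readers normalise to the whole-sample
minor allele (ties broken lexicographically), while the coalescent
simulator emits the derived allele as allele 1 and records the ancestral
state so that four-taxon site patterns can be polarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

MISSING = -1

VALID_ALPHABET = set("ACGTN-")


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes with positions and locality labels.

    Attributes
    ----------
    individuals : list of str
        Ordered sample names.
    localities : list of str
        Sampling-locality label per individual (parallel to ``individuals``).
    chrom : np.ndarray of str
        Chromosome / block label per site.
    pos : np.ndarray of int
        1-based position per site, strictly increasing within a chromosome.
    geno : np.ndarray, shape (n_individuals, n_sites), int8
        Count of allele 1 per individual per site; ``-1`` = missing.
    alleles : np.ndarray, shape (n_sites, 2), optional
        Physical bases for (allele 0, allele 1).
    outgroup : np.ndarray of int8, optional
        Per-site outgroup/ancestral allele coded in the same 0/1 space as
        ``geno`` (``-1`` where undefined).  Used to polarise ABBA/BABA
        patterns.
    """

    individuals: list
    localities: list
    chrom: np.ndarray
    pos: np.ndarray
    geno: np.ndarray
    alleles: Optional[np.ndarray] = None
    outgroup: Optional[np.ndarray] = None

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.outgroup is not None:
            self.outgroup = np.asarray(self.outgroup, dtype=np.int8)
        if len(self.individuals) != len(self.localities):
            raise ValueError("individuals and localities differ in length")
        if self.geno.shape != (len(self.individuals), len(self.pos)):
            raise ValueError(
                f"genotype array shape {self.geno.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.pos)} sites"
            )
        if len(self.chrom) != len(self.pos):
            raise ValueError("chrom and pos differ in length")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")
        bad = (self.geno < -1) | (self.geno > 2)
        if np.any(bad):
            raise ValueError("genotypes must be in {0,1,2} or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_sites(self) -> int:
        return int(self.geno.shape[1])

    def take_sites(self, idx) -> "GenotypeMatrix":
        """New matrix restricted to the site indices ``idx`` (order kept)."""
        idx = np.asarray(idx)
        return replace(
            self,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            geno=self.geno[:, idx],
            alleles=None if self.alleles is None else self.alleles[idx],
            outgroup=None if self.outgroup is None else self.outgroup[idx],
        )

    def index_of(self, name: str) -> int:
        try:
            return self.individuals.index(name)
        except ValueError:
            raise KeyError(f"unknown individual {name!r}") from None

    def allele_freq(self) -> np.ndarray:
        """Whole-sample frequency of allele 1 per site (NaN if all missing)."""
        obs = self.geno >= 0
        n_alleles = 2 * obs.sum(axis=0)
        counts = np.where(obs, self.geno, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, counts / np.maximum(n_alleles, 1), np.nan)


@dataclass
class SequenceAlignment:
    """Equal-length named sequences over {A,C,G,T,N,-}."""

    names: list
    sequences: list
    localities: Optional[list] = None

    def __post_init__(self):
        if len(self.names) != len(self.sequences):
            raise ValueError("names and sequences differ in length")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if self.names.count(n) > 1})
            raise ValueError(f"duplicate sequence names: {dupes}")
        self.sequences = [s.upper() for s in self.sequences]
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            off = next(
                n for n, s in zip(self.names, self.sequences)
                if len(s) != len(self.sequences[0])
            )
            raise ValueError(
                f"unequal sequence lengths (record {off!r} differs)"
            )
        for name, seq in zip(self.names, self.sequences):
            extra = set(seq) - VALID_ALPHABET
            if extra:
                raise ValueError(f"invalid characters {sorted(extra)} in {name!r}")
        if self.localities is not None and len(self.localities) != len(self.names):
            raise ValueError("localities and names differ in length")

    @property
    def n(self) -> int:
        return len(self.names)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def array(self) -> np.ndarray:
        """(n, length) array of single characters."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n, self.length).astype("U1")


@dataclass
class DepthProfile:
    """Per-scaffold mean read depth for one individual, with scaffold classes.

    ``scaffold_class`` values: ``x_linked``, ``autosomal``, ``ambiguous``.
    ``scaffold_length`` enables length-weighted depth means.
    """

    individual: str
    scaffold_depths: dict
    scaffold_class: dict
    scaffold_length: Optional[dict] = None

    def __post_init__(self):
        if set(self.scaffold_depths) != set(self.scaffold_class):
            raise ValueError("scaffold_class must cover exactly the scaffolds with depths")
        bad = {v for v in self.scaffold_class.values()} - {"x_linked", "autosomal", "ambiguous"}
        if bad:
            raise ValueError(f"unknown scaffold classes: {sorted(bad)}")
        if any(d < 0 for d in self.scaffold_depths.values()):
            raise ValueError("depths must be non-negative")


@dataclass
class SexCall:
    individual: str
    ratio: float
    call: str  # male | female | undetermined


@dataclass
class RelatednessResult:
    pair: tuple
    r: float
    n_sites: int


@dataclass
class DiversityResult:
    n: int
    n_haplotypes: int
    h: float
    pi: float
    n_pairwise_sites: dict = field(default_factory=dict)


@dataclass
class ModelEvidence:
    """A model's log marginal likelihood with its estimator SD."""

    name: str
    log_marginal_likelihood: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class DStatResult:
    h1: str
    h2: str
    h3: str
    outgroup: str
    n_abba: float
    n_baba: float
    d: float
    se: float
    z: float
    n_blocks: int
    topology_class: Optional[str] = None  # correct | incorrect | within_locality


@dataclass
class TopologyTestResult:
    grouping: tuple
    topology_class: str
    d_values: np.ndarray
    z_values: np.ndarray
    wilcoxon_p_d: float
    wilcoxon_p_z: float
    # class-level structure call: one-sided signed-rank test of the class's
    # |Z| values against the conventional |Z| > 3 significance threshold
    wilcoxon_p_structure: float
    prop_significant: float
    n_quartets: int


@dataclass
class WindowStat:
    chrom: str
    start: int  # half-open [start, end) in bp
    end: int
    n_sites: int
    fst: float
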