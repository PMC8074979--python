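"""Sex determination from X:autosome depth ratios and pairwise relatedness.

In mammals a male carries one X against two autosomal copies, so his mean
read depth on X-linked scaffolds is about half his autosomal depth; a female
shows a ratio near one.  Scaffolds homologous to both X and Y are labelled
ambiguous and excluded.  Depth means are length-weighted across scaffolds
when lengths are available (recorded in the call).

Relatedness uses the standard allele-frequency moment estimator of the
relatedness coefficient r: 1 for an individual against itself (or a
monozygotic twin), 0.5 for parent-offspring or full siblings, ~0 for
unrelated pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import DepthProfile, GenotypeMatrix, RelatednessResult, SexCall

logger = logging.getLogger("popkit")

FEMALE_BAND = (0.8, 1.2)
MALE_BAND = (0.35, 0.65)


def _weighted_mean_depth(profile: DepthProfile, cls: str) -> float:
    ids = [s for s, c in profile.scaffold_class.items() if c == cls]
    if not ids:
        raise ValueError(f"no usable {cls} scaffolds for {profile.individual!r}")
    depths = np.array([profile.scaffold_depths[s] for s in ids], dtype=float)
    if profile.scaffold_length is not None:
        w = np.array([profile.scaffold_length[s] for s in ids], dtype=float)
    else:
        w = np.ones(len(ids))
    return float(np.average(depths, weights=w))


def call_sex(profile: DepthProfile, female_band=FEMALE_BAND,
             male_band=MALE_BAND) -> SexCall:
    """Classify one individual from its X:autosome mean-depth ratio.

    Ambiguous scaffolds are excluded.  The call is ``female`` when the ratio
    falls in ``female_band``, ``male`` in ``male_band``, otherwise
    ``undetermined`` (deliberately wide bands with an abstention zone rather
    than a single hard threshold).
    """
    x = _weighted_mean_depth(profile, "x_linked")
    auto = _weighted_mean_depth(profile, "autosomal")
    if auto == 0:
        raise ValueError(f"zero autosomal depth for {profile.individual!r}")
    ratio = x / auto
    if female_band[0] <= ratio <= female_band[1]:
        call = "female"
    elif male_band[0] <= ratio <= male_band[1]:
        call = "male"
    else:
        call = "undetermined"
    return SexCall(individual=profile.individual, ratio=ratio, call=call)


def relatedness(gm: GenotypeMatrix, pair, min_sites: int = 100) -> RelatednessResult:
    """Moment estimate of the relatedness coefficient for one pair.

    r-hat = mean over usable sites of (g_i - 2p)(g_j - 2p) / (2p(1-p)) with p
    the whole-sample allele frequency; sites missing in either individual or
    monomorphic in the sample are skipped.  Requires at least ``min_sites``
    usable sites.
    """
    i = gm.index_of(pair[0]) if isinstance(pair[0], str) else int(pair[0])
    j = gm.index_of(pair[1]) if isinstance(pair[1], str) else int(pair[1])
    p = gm.allele_freq()
    gi = gm.geno[i].astype(float)
    gj = gm.geno[j].astype(float)
    ok = (gm.geno[i] >= 0) & (gm.geno[j] >= 0) & ~np.isnan(p) & (p > 0) & (p < 1)
    n_sites = int(ok.sum())
    if n_sites < min_sites:
        raise ValueError(
            f"only {n_sites} usable polymorphic sites for pair "
            f"({gm.individuals[i]}, {gm.individuals[j]}); need >= {min_sites}"
        )
    pe = p[ok]
    r = float(np.mean((gi[ok] - 2 * pe) * (gj[ok] - 2 * pe) / (2 * pe * (1 - pe))))
    return RelatednessResult(
        pair=(gm.individuals[i], gm.individuals[j]), r=r, n_sites=n_sites
    )


def relatedness_all_pairs(gm: GenotypeMatrix, min_sites: int = 100) -> list:
    """Relatedness estimates for every individual pair."""
    from itertools import combinations
    return [
        relatedness(gm, (a, b), min_sites=min_sites)
        for a, b in combinations(gm.individuals, 2)
    ]
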