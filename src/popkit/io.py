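"""Readers and writers for the formats the pipeline touches.

VCF support is deliberately a small dialect: ``CHROM``, ``POS``, ``REF``,
``ALT`` and the ``GT`` field are used, everything else is ignored.  An
optional ``AA=`` INFO entry carries the ancestral allele used to polarise
four-taxon site patterns.  Multiallelic records are dropped (and counted)
rather than decomposed; phasing separators are accepted but ignored.

On reading, genotypes are re-oriented so that allele 1 is the whole-sample
minor allele (ties broken lexicographically by base), the convention the
rest of the pipeline assumes.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from cyvcf2 import VCF

from .datatypes import MISSING, DepthProfile, GenotypeMatrix, SequenceAlignment

logger = logging.getLogger("popkit")


# ---------------------------------------------------------------------------
# genotype matrices
# ---------------------------------------------------------------------------

def orient_to_minor(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Re-code every site so allele 1 is the whole-sample minor allele.

    At frequency ties (0.5) the lexicographically smaller base becomes
    allele 1 when allele letters are known; otherwise the current allele 1
    is kept.  The outgroup track is flipped consistently.
    """
    freq = gm.allele_freq()
    flip = freq > 0.5
    if gm.alleles is not None:
        tie = np.isclose(freq, 0.5)
        # At a tie, ensure allele 1 is the lexicographically smaller base.
        a = gm.alleles
        flip = flip | (tie & (a[:, 1] > a[:, 0]))
    geno = gm.geno.copy()
    obs = geno >= 0
    geno[:, flip] = np.where(obs[:, flip], 2 - geno[:, flip], MISSING)
    alleles = None
    if gm.alleles is not None:
        alleles = gm.alleles.copy()
        alleles[flip] = alleles[flip][:, ::-1]
    outgroup = None
    if gm.outgroup is not None:
        outgroup = gm.outgroup.copy()
        known = outgroup >= 0
        outgroup[known & flip] = 1 - outgroup[known & flip]
    return GenotypeMatrix(
        individuals=list(gm.individuals),
        localities=list(gm.localities),
        chrom=gm.chrom,
        pos=gm.pos,
        geno=geno,
        alleles=alleles,
        outgroup=outgroup,
    )


def read_genotypes(path, format: str = "vcf", locality_map: Optional[dict] = None,
                   orient_minor: bool = True) -> GenotypeMatrix:
    """Load a genotype matrix from a VCF or TSV file.

    ``locality_map`` maps every individual name to its sampling locality;
    names that are not in the file raise.  Multiallelic sites are dropped
    with a logged count.
    """
    if format == "vcf":
        gm = _read_vcf(path)
    elif format == "tsv":
        gm = _read_geno_tsv(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    if locality_map is not None:
        unknown = set(locality_map) - set(gm.individuals)
        if unknown:
            raise ValueError(f"locality_map names unknown individuals: {sorted(unknown)}")
        missing = set(gm.individuals) - set(locality_map)
        if missing:
            raise ValueError(f"locality_map missing individuals: {sorted(missing)}")
        gm.localities = [locality_map[i] for i in gm.individuals]
    if orient_minor:
        gm = orient_to_minor(gm)
    return gm


def _read_vcf(path) -> GenotypeMatrix:
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, genos, alleles, anc = [], [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = var.gt_types.astype(np.int8)  # 0,1,2 = ALT count; 3 = missing
        gt[gt == 3] = MISSING
        chroms.append(var.CHROM)
        poss.append(var.POS)
        genos.append(gt)
        alleles.append((var.REF, var.ALT[0]))
        aa = var.INFO.get("AA")
        if aa is None:
            anc.append(MISSING)
        elif aa == var.REF:
            anc.append(0)
        elif aa == var.ALT[0]:
            anc.append(1)
        else:
            anc.append(MISSING)
    if n_multi:
        logger.info("dropped %d multiallelic site(s) from %s", n_multi, path)
    n_sites = len(poss)
    geno = (np.array(genos, dtype=np.int8).T if n_sites
            else np.zeros((len(samples), 0), dtype=np.int8))
    out = np.array(anc, dtype=np.int8)
    return GenotypeMatrix(
        individuals=samples,
        localities=["unknown"] * len(samples),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        geno=geno,
        alleles=np.array(alleles, dtype=object).reshape(n_sites, 2),
        outgroup=out if n_sites and np.any(out >= 0) else None,
    )


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal VCF v4.2 (GT only, optional AA INFO)."""
    a = gm.alleles
    if a is None:
        a = np.array([("A", "C")] * gm.n_sites, dtype=object).reshape(gm.n_sites, 2)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(gm.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.individuals) + "\n")
        code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(gm.n_sites):
            info = "."
            if gm.outgroup is not None and gm.outgroup[j] >= 0:
                info = f"AA={a[j, gm.outgroup[j]]}"
            gts = "\t".join(code[int(g)] for g in gm.geno[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{a[j,0]}\t{a[j,1]}\t.\t.\t"
                     f"{info}\tGT\t{gts}\n")


def _read_geno_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = [c for c in ("chrom", "pos", "allele0", "allele1", "ancestral") if c in df.columns]
    if "chrom" not in meta or "pos" not in meta:
        raise ValueError("genotype TSV needs 'chrom' and 'pos' columns")
    inds = [c for c in df.columns if c not in meta]
    geno = df[inds].to_numpy(dtype=float).T
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    alleles = None
    outgroup = None
    if "allele0" in df.columns and "allele1" in df.columns:
        alleles = df[["allele0", "allele1"]].to_numpy(dtype=object)
        if "ancestral" in df.columns:
            anc = df["ancestral"].to_numpy(dtype=object)
            outgroup = np.where(
                anc == alleles[:, 0], 0, np.where(anc == alleles[:, 1], 1, MISSING)
            ).astype(np.int8)
    return GenotypeMatrix(
        individuals=inds,
        localities=["unknown"] * len(inds),
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        geno=geno,
        alleles=alleles,
        outgroup=outgroup,
    )


def write_geno_tsv(gm: GenotypeMatrix, path) -> None:
    data = {"chrom": gm.chrom, "pos": gm.pos}
    if gm.alleles is not None:
        data["allele0"] = gm.alleles[:, 0]
        data["allele1"] = gm.alleles[:, 1]
        if gm.outgroup is not None:
            anc = np.where(
                gm.outgroup >= 0,
                gm.alleles[np.arange(gm.n_sites), np.clip(gm.outgroup, 0, 1)],
                ".",
            )
            data["ancestral"] = anc
    df = pd.DataFrame(data)
    for i, name in enumerate(gm.individuals):
        col = gm.geno[i].astype(object)
        col[gm.geno[i] == MISSING] = ""
        df[name] = col
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def read_fasta_alignment(path) -> SequenceAlignment:
    """Read an aligned FASTA; unequal lengths or duplicate names raise."""
    names, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        names.append(rec.id)
        seqs.append(str(rec.seq).upper())
    return SequenceAlignment(names=names, sequences=seqs)


def read_fasta(path) -> dict:
    """Read a FASTA into an ordered name -> sequence dict (no length checks)."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(records, path, width: int = 60) -> None:
    """Write name -> sequence pairs as 60-column wrapped FASTA."""
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_alignment_fasta(aln: SequenceAlignment, path) -> None:
    write_fasta(zip(aln.names, aln.sequences), path)


# ---------------------------------------------------------------------------
# depth tables
# ---------------------------------------------------------------------------

def read_depth_profiles(depths_path, classes_path) -> list:
    """Load per-individual depth profiles.

    ``depths_path``: TSV with columns individual, scaffold, mean_depth
    (optionally length).  ``classes_path``: TSV with columns scaffold, class.
    """
    depths = pd.read_csv(depths_path, sep="\t")
    classes = pd.read_csv(classes_path, sep="\t")
    cls = dict(zip(classes["scaffold"], classes["class"]))
    profiles = []
    for ind, sub in depths.groupby("individual", sort=False):
        sd = dict(zip(sub["scaffold"], sub["mean_depth"]))
        missing = set(sd) - set(cls)
        if missing:
            raise ValueError(f"scaffolds without class labels: {sorted(missing)[:5]}")
        lengths = (dict(zip(sub["scaffold"], sub["length"]))
                   if "length" in sub.columns else None)
        profiles.append(DepthProfile(
            individual=str(ind),
            scaffold_depths=sd,
            scaffold_class={s: cls[s] for s in sd},
            scaffold_length=lengths,
        ))
    return profiles


def write_depth_profiles(profiles, depths_path, classes_path) -> None:
    rows, crows, seen = [], [], set()
    for p in profiles:
        for s, d in p.scaffold_depths.items():
            row = {"individual": p.individual, "scaffold": s, "mean_depth": d}
            if p.scaffold_length is not None:
                row["length"] = p.scaffold_length[s]
            rows.append(row)
            if s not in seen:
                seen.add(s)
                crows.append({"scaffold": s, "class": p.scaffold_class[s]})
    pd.DataFrame(rows).to_csv(depths_path, sep="\t", index=False)
    pd.DataFrame(crows).to_csv(classes_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trees and networks
# ---------------------------------------------------------------------------

def write_newick(newick: str, path) -> None:
    with open(path, "w") as fh:
        fh.write(newick.rstrip() + "\n")


def read_newick(path):
    """Parse a newick file into a Bio.Phylo tree."""
    from Bio import Phylo
    return Phylo.read(str(path), "newick")


def write_network_tsv(network, edges_path, nodes_path) -> None:
    """Serialise a haplotype network as edge-list + node-table TSVs."""
    erows = [
        {"node_a": a, "node_b": b, "mutations": w}
        for a, b, w in network.edge_list()
    ]
    nrows = []
    for node_id, (members, locs) in sorted(network.nodes.items()):
        nrows.append({
            "node": node_id,
            "members": ",".join(members),
            "localities": ",".join(f"{k}:{v}" for k, v in sorted(locs.items())),
        })
    pd.DataFrame(erows).to_csv(edges_path, sep="\t", index=False)
    pd.DataFrame(nrows).to_csv(nodes_path, sep="\t", index=False)
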