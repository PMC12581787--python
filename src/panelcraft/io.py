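"""Readers, writers and the shared in-memory data model.

Every module in the package exchanges data through the containers defined
here: :class:`VariantTable` (per-SNP records + diploid genotype codes),
:class:`GenotypeMatrix` (samples x SNPs code matrix), :class:`GenomeSequence`
(chromosome strings with 1-based inclusive fetch) and :class:`FeatureTable`
(gene models with exon/CDS intervals).

Conventions (single source of truth for the whole package):

* genotype codes count ALT alleles: 0, 1, 2; missing is :data:`MISSING` (-1);
* coordinates are 1-based and inclusive (VCF/GFF convention);
* only diploid genotypes are accepted; phased separators are treated as
  unphased;
* io never imputes — missing stays missing until a caller decides otherwise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

#: missing genotype code (int8-safe sentinel)
MISSING: int = -1

MANIFEST_COLUMNS = ["chrom", "pos", "ref", "alt", "source", "probe_start", "probe_seq"]


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed; carries file/line context."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Ordered per-SNP records with per-sample diploid genotype codes.

    ``genotypes`` has shape ``(n_records, n_samples)`` with entries in
    {0, 1, 2, MISSING}. Positions are strictly increasing within each
    chromosome (checked by :meth:`validate`).
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    qual: np.ndarray
    genotypes: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.qual = np.asarray(self.qual, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[0] != len(self.pos):
            raise ValueError("genotypes must be (n_records, n_samples)")
        if self.genotypes.shape[1] != len(self.samples):
            raise ValueError("genotype columns do not match sample list")

    @property
    def n_records(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def ids(self) -> np.ndarray:
        """SNP identifiers as '<chrom>_<pos>' strings."""
        return np.array([f"{c}_{p}" for c, p in zip(self.chrom, self.pos)], dtype=object)

    def subset(self, index) -> "VariantTable":
        """Row subset preserving order (boolean mask or integer indices)."""
        index = np.asarray(index)
        return VariantTable(
            self.chrom[index], self.pos[index], self.ref[index], self.alt[index],
            self.qual[index], self.genotypes[index], list(self.samples),
        )

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per record, ignoring missing calls; NaN if
        a record has no calls."""
        g = self.genotypes.astype(float)
        g[g == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            p = np.nanmean(g, axis=1) / 2.0
        return np.minimum(p, 1.0 - p)

    def missing_rate(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    def validate(self) -> None:
        if np.any(self.ref == self.alt):
            raise ValueError("ref == alt at some record")
        ok = (self.genotypes >= MISSING) & (self.genotypes <= 2)
        if not ok.all():
            raise ValueError("genotype codes must be in {0,1,2,missing}")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def sort(self) -> "VariantTable":
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return self.subset(order)

    def to_genotype_matrix(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.genotypes.T.copy(), list(self.samples), list(self.ids()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "ref": self.ref,
             "alt": self.alt, "qual": self.qual}
        )


@dataclass
class GenotypeMatrix:
    """``n_samples x m_snps`` matrix of genotype codes {0,1,2,MISSING}."""

    matrix: np.ndarray
    sample_ids: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("matrix shape inconsistent with ID vectors")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    def maf(self) -> np.ndarray:
        g = self.matrix.astype(float)
        g[g == MISSING] = np.nan
        with np.errstate(invalid="ignore"):
            p = np.nanmean(g, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def mean_imputed(self) -> np.ndarray:
        """Float copy with missing entries replaced by the column mean
        (monomorphic all-missing columns get 0)."""
        g = self.matrix.astype(float)
        g[g == MISSING] = np.nan
        col = np.nanmean(np.where(np.isnan(g), np.nan, g), axis=0)
        col = np.where(np.isnan(col), 0.0, col)
        idx = np.where(np.isnan(g))
        g[idx] = col[idx[1]]
        return g

    def subset_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        ids = [self.snp_ids[i] for i in np.arange(self.n_snps)[index]] \
            if index.dtype == bool else [self.snp_ids[i] for i in index]
        return GenotypeMatrix(self.matrix[:, index], list(self.sample_ids), ids)

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        ids = list(np.asarray(self.sample_ids, dtype=object)[index])
        return GenotypeMatrix(self.matrix[index], ids, list(self.snp_ids))


@dataclass
class GenomeSequence:
    """Per-chromosome DNA strings over {A,C,G,T,N} with 1-based fetch."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sequences)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return bases ``start..end`` inclusive (1-based); out-of-range is an
        error — callers that tolerate truncation must clamp explicitly."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        seq = self.sequences[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(
                f"range {start}-{end} outside {chrom} (length {len(seq)})"
            )
        return seq[start - 1:end]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]]  # (start, end, frame)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e, _ in self.cds)


@dataclass
class FeatureTable:
    """Gene models keyed by chromosome for interval queries."""

    genes: list[GeneModel]
    _by_chrom: dict[str, list[GeneModel]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_chrom = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        return [g for g in self._by_chrom.get(chrom, []) if g.contains(pos)]

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf(path: str | os.PathLike, biallelic_only: bool = True) -> VariantTable:
    """Read a VCF 4.x into a :class:`VariantTable`.

    Multi-allelic records are dropped when ``biallelic_only`` is set.
    Missing genotypes (``./.``) map to :data:`MISSING`; phased calls are
    treated as unphased. Non-diploid calls raise ``ValueError``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc

    samples = list(vcf.samples)
    chrom, pos, ref, alt, qual, geno = [], [], [], [], [], []
    lineno = 0
    try:
        for v in vcf:
            lineno += 1
            if biallelic_only and len(v.ALT) != 1:
                continue
            if len(v.ALT) == 0:
                continue
            if samples:
                alleles = v.genotypes  # [[a, b, phased], ...]
                if any(len(call) != 3 for call in alleles):
                    raise ValueError(
                        f"non-diploid genotype at record {lineno} "
                        f"({v.CHROM}:{v.POS}); only diploid data are supported"
                    )
                codes = np.empty(len(samples), dtype=np.int8)
                for i, (a, b, _ph) in enumerate(alleles):
                    if a < 0 or b < 0:
                        codes[i] = MISSING
                    else:
                        codes[i] = (a > 0) + (b > 0)
            else:
                codes = np.zeros(0, dtype=np.int8)
            chrom.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(v.ALT[0])
            qual.append(np.nan if v.QUAL is None else float(v.QUAL))
            geno.append(codes)
    except ValueError:
        raise
    except Exception as exc:
        raise VcfParseError(
            f"malformed VCF record near data line {lineno + 1} of {path}: {exc}"
        ) from exc

    genotypes = np.array(geno, dtype=np.int8) if geno else np.zeros(
        (0, len(samples)), dtype=np.int8
    )
    vt = VariantTable(
        np.array(chrom, dtype=object), np.array(pos), np.array(ref, dtype=object),
        np.array(alt, dtype=object), np.array(qual), genotypes, samples,
    ).sort()
    return vt


def write_vcf(vt: VariantTable, path: str | os.PathLike) -> None:
    """Write a minimal VCF 4.2 (GT-only) — used to export simulated data."""
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen = []
        for c in vt.chrom:
            if c not in seen:
                seen.append(c)
        for c in seen:
            fh.write(f"##contig=<ID={c}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if vt.samples:
            header += ["FORMAT"] + list(vt.samples)
        fh.write("\t".join(header) + "\n")
        for i in range(vt.n_records):
            q = "." if np.isnan(vt.qual[i]) else f"{vt.qual[i]:g}"
            row = [str(vt.chrom[i]), str(vt.pos[i]), ".", str(vt.ref[i]),
                   str(vt.alt[i]), q, "PASS", "."]
            if vt.samples:
                row.append("GT")
                row.extend(code_to_gt[int(g)] for g in vt.genotypes[i])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | os.PathLike) -> GenomeSequence:
    """Read a FASTA file; duplicate sequence names are an error."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper()
    return GenomeSequence(sequences)


def write_fasta(genome: GenomeSequence, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff(path: str | os.PathLike) -> FeatureTable:
    """Read gene/exon/CDS models from a GFF3 file.

    Exons and CDS are grouped under their gene (via Parent chains); a CDS
    outside its gene's span is an error. Minus-strand intervals are stored
    unreversed with the strand recorded.
    """
    import gffutils

    if os.path.getsize(path) == 0:
        return FeatureTable([])
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons: list[tuple[int, int]] = []
        cds: list[tuple[int, int, int]] = []
        for f in db.children(gene, featuretype="exon"):
            exons.append((f.start, f.end))
        for f in db.children(gene, featuretype="CDS"):
            if f.start < gene.start or f.end > gene.end:
                raise ValueError(
                    f"CDS {f.start}-{f.end} outside gene {gene.id} span"
                )
            frame = 0 if f.frame in (None, ".") else int(f.frame)
            cds.append((f.start, f.end, frame))
        exons.sort()
        cds.sort()
        if not exons and cds:
            exons = [(s, e) for s, e, _ in cds]
        genes.append(
            GeneModel(gene.id, gene.seqid, gene.strand, gene.start, gene.end,
                      exons, cds)
        )
    return FeatureTable(genes)


def write_gff(features: FeatureTable, path: str | os.PathLike) -> None:
    """Write gene/exon/CDS models as GFF3 (used by the simulator)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in features.genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tpanelcraft\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tpanelcraft\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tpanelcraft\texon\t{s}\t{e}\t.\t{g.strand}\t.\tParent={mrna}\n"
                )
            for s, e, frame in g.cds:
                fh.write(
                    f"{g.chrom}\tpanelcraft\tCDS\t{s}\t{e}\t.\t{g.strand}\t{frame}\tParent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# panel manifests and trees
# ---------------------------------------------------------------------------


def write_panel_manifest(manifest, path: str | os.PathLike) -> None:
    """Write a panel manifest as TSV; design metadata goes into '#key=value'
    comment lines so the file round-trips."""
    df = manifest.table if hasattr(manifest, "table") else manifest
    meta = getattr(manifest, "metadata", {}) or {}
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_panel_manifest(path: str | os.PathLike):
    from .panel import PanelManifest  # local import: avoid cycle

    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#") and "=" in line and not line.startswith("#chrom"):
            k, _, v = line[1:].rstrip("\n").partition("=")
            meta[k] = v
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    return PanelManifest(df, metadata=meta)


def write_newick(tree, path: str | os.PathLike) -> None:
    """Write a scikit-bio ``TreeNode`` in Newick format."""
    tree.write(str(path), format="newick")


def read_newick(path: str | os.PathLike):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")


# ---------------------------------------------------------------------------
# small tables
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Phenotype TSV: first column sample ID, remaining columns traits."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def read_groups(path: str | os.PathLike) -> pd.Series:
    """Group/population assignment TSV: sample <tab> group."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
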