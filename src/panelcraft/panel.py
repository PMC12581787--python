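"""SNP panel design: the variant-to-probe selection funnel plus panel
characterization statistics.

A raw variant table passes through four stages: (1) quality filtering on
missingness, site quality, MAF and chromosome placement; (2) flank QC and
genome-redundancy screening of the 201-bp SNP region; (3) enumeration of
100-bp candidate capture-probe windows over the 301-bp neighbourhood, each
checked for GC content, N bases and genome uniqueness; (4) windowed LD
pruning of the survivors. A second stream of linkage-map SNPs is
cross-referenced against the resequencing variants, passed through the same
probe screen, and merged into the final panel manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import (MISSING, FeatureTable, GenomeSequence, GenotypeMatrix,
                 VariantTable, reverse_complement)
from Bio.Seq import Seq


# ---------------------------------------------------------------------------
# stage 1: quality filtering
# ---------------------------------------------------------------------------


def filter_variants(
    vt: VariantTable,
    max_missing: float = 0.2,
    min_qual: float = 50.0,
    min_maf: float = 0.15,
    drop_unplaced: bool = True,
    chromosomes: set[str] | None = None,
) -> VariantTable:
    """Quality filter: missing rate < ``max_missing``, QUAL >= ``min_qual``,
    MAF >= ``min_maf``, and (optionally) chromosome membership in
    ``chromosomes`` — records on unplaced contigs are dropped.

    Order is preserved; an empty result is allowed.
    """
    keep = vt.missing_rate() < max_missing
    with np.errstate(invalid="ignore"):
        keep &= np.nan_to_num(vt.qual, nan=-np.inf) >= min_qual
        maf = vt.maf()
        keep &= np.nan_to_num(maf, nan=-1.0) >= min_maf
    if drop_unplaced and chromosomes is not None:
        keep &= np.isin(vt.chrom.astype(str), list(chromosomes))
    return vt.subset(keep)


# ---------------------------------------------------------------------------
# stage 2: flank QC and redundancy
# ---------------------------------------------------------------------------


def gc_content(seq: str) -> float:
    """Fraction of G/C bases, case-insensitive; empty sequence is an error."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


@dataclass
class FlankRegion:
    chrom: str
    pos: int
    sequence: str  # flank + SNP base + flank (201 bp when flanks fit)
    gc: float
    has_n: bool
    truncated: bool


def flank_qc(
    chrom: str, pos: int, genome: GenomeSequence,
    flank: int = 100, gc_min: float = 0.4, gc_max: float = 0.6,
) -> tuple[FlankRegion, bool]:
    """Extract the SNP region (``flank`` bp either side) and judge it.

    Pass requires full-length flanks inside the chromosome, GC in
    [gc_min, gc_max] and no N bases. A SNP too close to a chromosome end
    fails (fixed-length probes cannot be placed).
    """
    length = genome.lengths.get(chrom)
    if length is None or not 1 <= pos <= length:
        raise IndexError(f"SNP position {chrom}:{pos} off chromosome")
    start = max(1, pos - flank)
    end = min(length, pos + flank)
    seq = genome.fetch(chrom, start, end)
    truncated = (pos - flank < 1) or (pos + flank > length)
    gc = gc_content(seq)
    has_n = "N" in seq.upper()
    region = FlankRegion(chrom, pos, seq, gc, has_n, truncated)
    ok = (not truncated) and (not has_n) and (gc_min <= gc <= gc_max)
    return region, ok


class GenomeKmerIndex:
    """Exact k-mer index of a genome for seed-and-extend redundancy checks.

    Built once per genome; maps each k-mer to its (chrom, 0-based offset)
    occurrences. k-mers containing N are not indexed.
    """

    def __init__(self, genome: GenomeSequence, k: int = 15):
        self.genome = genome
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((chrom, i))

    def hits(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def uniqueness_check(
    region: str,
    genome: GenomeSequence,
    locus: tuple[str, int] | None = None,
    min_identity: float = 0.6,
    min_coverage: float = 0.6,
    index: GenomeKmerIndex | None = None,
    check_revcomp: bool = True,
) -> str:
    """Classify a region as ``'unique'`` or ``'duplicate'`` in the genome.

    A region is a duplicate when some non-self ungapped alignment covers at
    least ``min_coverage`` of the region with identity >= ``min_identity``.
    Candidate alignments come from exact k-mer seeds extended along their
    diagonal over the full region (both strands). ``locus`` is the region's
    own (chrom, 1-based start) so the self-hit can be excluded.
    """
    if index is None:
        index = GenomeKmerIndex(genome)
    k = index.k
    L = len(region)
    if L < k:
        raise ValueError(f"region shorter than seed length {k}")
    region = region.upper()

    def scan(query: str, revcomp: bool) -> bool:
        seen: set[tuple[str, int]] = set()
        for off in range(0, L - k + 1):
            kmer = query[off:off + k]
            if "N" in kmer:
                continue
            for chrom, gpos in index.hits(kmer):
                diag = gpos - off  # genome offset of query position 0
                key = (chrom, diag)
                if key in seen:
                    continue
                seen.add(key)
                seq = index.genome.sequences[chrom]
                q_lo = max(0, -diag)
                q_hi = min(L, len(seq) - diag)
                span = q_hi - q_lo
                if span < min_coverage * L:
                    continue
                if not revcomp and locus is not None:
                    self_chrom, self_start = locus
                    g_start = diag + q_lo  # 0-based genome start of alignment
                    g_end = diag + q_hi
                    s0 = self_start - 1
                    if chrom == self_chrom and g_start < s0 + L and g_end > s0:
                        if diag == s0:
                            continue  # exact self-hit
                        # overlapping-but-shifted hits are genuine repeats
                a = np.frombuffer(query[q_lo:q_hi].encode(), dtype="S1")
                b = np.frombuffer(seq[diag + q_lo:diag + q_hi].encode(), dtype="S1")
                matches = int((a == b).sum())
                if matches / span >= min_identity:
                    return True
        return False

    if scan(region, revcomp=False):
        return "duplicate"
    if check_revcomp and scan(reverse_complement(region), revcomp=True):
        return "duplicate"
    return "unique"


def uniqueness_check_bruteforce(
    region: str,
    genome: GenomeSequence,
    locus: tuple[str, int] | None = None,
    min_identity: float = 0.6,
    min_coverage: float = 0.6,
    check_revcomp: bool = True,
) -> str:
    """Exhaustive sliding-window alignment over every genome offset (both
    strands). Desk-scale oracle for :func:`uniqueness_check`; O(genome x
    region), use on genomes <= ~50 kb only.
    """
    L = len(region)
    queries = [(region.upper(), False)]
    if check_revcomp:
        queries.append((reverse_complement(region).upper(), True))
    for query, is_rc in queries:
        q = np.frombuffer(query.encode(), dtype="S1")
        for chrom, seq in genome.sequences.items():
            s = np.frombuffer(seq.encode(), dtype="S1")
            for diag in range(-(L - 1), len(seq)):
                q_lo = max(0, -diag)
                q_hi = min(L, len(seq) - diag)
                span = q_hi - q_lo
                if span < min_coverage * L:
                    continue
                if not is_rc and locus is not None:
                    self_chrom, self_start = locus
                    if chrom == self_chrom and diag == self_start - 1:
                        continue
                matches = int((q[q_lo:q_hi] == s[diag + q_lo:diag + q_hi]).sum())
                if matches / span >= min_identity:
                    return "duplicate"
    return "unique"


# ---------------------------------------------------------------------------
# stage 3: probe windows
# ---------------------------------------------------------------------------


@dataclass
class ProbeWindow:
    start: int       # 1-based window start on the chromosome
    sequence: str    # exactly `window` bp
    gc: float
    has_n: bool
    unique: bool | None   # None = uniqueness not evaluated (cheap checks failed)
    contains_snp: bool

    @property
    def qualified(self) -> bool:
        return (not self.has_n) and bool(self.unique) and self.gc_ok

    gc_ok: bool = True


def probe_windows(
    chrom: str, pos: int, genome: GenomeSequence,
    flank: int = 150, window: int = 100, step: int = 1,
    gc_min: float = 0.4, gc_max: float = 0.6,
    index: GenomeKmerIndex | None = None,
    min_identity: float = 0.6, min_coverage: float = 0.6,
    lazy_uniqueness: bool = True,
) -> list[ProbeWindow]:
    """Enumerate candidate capture-probe windows around a SNP.

    The region is ``flank`` bp either side of the SNP (301 bp by default),
    scanned with a ``window``-bp window at ``step``-bp steps; a truncated
    region (SNP near a chromosome end) yields an empty list. Each window is
    flagged for GC bounds, N bases, genome uniqueness and SNP containment.

    With ``lazy_uniqueness`` (default), uniqueness — the expensive check —
    is only evaluated for windows passing the cheap checks, in preference
    order (SNP-containing first, then closest to GC 0.5, then leftmost),
    and stops after the first qualified window; remaining windows keep
    ``unique=None``.
    """
    length = genome.lengths.get(chrom)
    if length is None:
        raise KeyError(f"unknown chromosome {chrom}")
    if pos - flank < 1 or pos + flank > length:
        return []
    region_start = pos - flank  # 1-based
    region = genome.fetch(chrom, region_start, pos + flank)
    n_windows = (len(region) - window) // step + 1
    wins: list[ProbeWindow] = []
    for i in range(n_windows):
        off = i * step
        seq = region[off:off + window]
        start = region_start + off
        gc = gc_content(seq)
        has_n = "N" in seq
        contains = start <= pos <= start + window - 1
        gc_ok = gc_min <= gc <= gc_max
        wins.append(ProbeWindow(start, seq, gc, has_n, None, contains, gc_ok))

    candidates = [w for w in wins if w.gc_ok and not w.has_n]
    candidates.sort(key=lambda w: (not w.contains_snp, abs(w.gc - 0.5), w.start))
    for w in candidates:
        w.unique = uniqueness_check(
            w.sequence, genome, locus=(chrom, w.start), index=index,
            min_identity=min_identity, min_coverage=min_coverage,
        ) == "unique"
        if lazy_uniqueness and w.unique:
            break
    return wins


def best_probe_window(windows: list[ProbeWindow]) -> ProbeWindow | None:
    """Pick the chosen probe among qualified windows: prefer SNP-containing,
    then GC closest to 0.5, then leftmost start."""
    ok = [w for w in windows if w.qualified]
    if not ok:
        return None
    return min(ok, key=lambda w: (not w.contains_snp, abs(w.gc - 0.5), w.start))


# ---------------------------------------------------------------------------
# stage 4: LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(cols: np.ndarray, min_pairs: int = 20) -> np.ndarray:
    """Squared Pearson correlation between mean-imputed genotype columns;
    pairs with fewer than ``min_pairs`` co-observed samples (pre-imputation)
    get r2 = 0 (skipped)."""
    obs = cols != MISSING
    g = cols.astype(float)
    g[~obs] = np.nan
    mean = np.nanmean(g, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    idx = np.where(np.isnan(g))
    g[idx] = mean[idx[1]]
    gc = g - g.mean(axis=0)
    denom = np.sqrt((gc ** 2).sum(axis=0))
    denom[denom == 0] = np.inf
    r = (gc.T @ gc) / np.outer(denom, denom)
    r2 = r ** 2
    co = obs.T.astype(int) @ obs.astype(int)
    r2[co < min_pairs] = 0.0
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    G: GenotypeMatrix, window_snps: int = 100, step_snps: int = 10,
    r2_max: float = 0.2,
) -> np.ndarray:
    """Windowed greedy LD pruning over genomically ordered SNP columns.

    Within each sliding window of ``window_snps`` currently kept SNPs, while
    any pair exceeds ``r2_max`` the member of the worst pair with the lower
    MAF is dropped (tie: higher column index); the window then slides by
    ``step_snps``. Passes repeat until stable, so the post-condition holds:
    no in-window pair of kept SNPs has r^2 > ``r2_max``. Returns kept column
    indices (sorted).
    """
    maf = G.maf()
    maf = np.where(np.isnan(maf), 0.0, maf)
    kept = list(range(G.n_snps))

    def prune_pass(step: int) -> bool:
        changed = False
        start = 0
        while start < len(kept):
            win = kept[start:start + window_snps]
            while len(win) >= 2:
                r2 = _pairwise_r2(G.matrix[:, win])
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= r2_max:
                    break
                # drop the lower-MAF member; tie -> higher column index
                a, b = win[i], win[j]
                drop = a if (maf[a], -a) < (maf[b], -b) else b
                kept.remove(drop)
                win.remove(drop)
                changed = True
            if start + window_snps >= len(kept):
                break
            start += step
        return changed

    # plink-style stepped passes, then unit-step sweeps so the post-condition
    # holds for windows at every offset
    while prune_pass(step_snps):
        pass
    while prune_pass(1):
        pass
    return np.array(sorted(kept), dtype=int)


# ---------------------------------------------------------------------------
# map cross-referencing and panel assembly
# ---------------------------------------------------------------------------


def crossref_with_map(map_snps: pd.DataFrame, vt: VariantTable) -> VariantTable:
    """Subset of ``vt`` whose (chrom, pos, ref, alt) also appear in the
    linkage-map SNP list; order of ``vt`` preserved."""
    key = set(zip(map_snps["chrom"].astype(str), map_snps["pos"].astype(int),
                  map_snps["ref"], map_snps["alt"]))
    mask = np.array([
        (str(c), int(p), r, a) in key
        for c, p, r, a in zip(vt.chrom, vt.pos, vt.ref, vt.alt)
    ])
    return vt.subset(mask)


@dataclass
class PanelManifest:
    """The assembled panel: a TSV-shaped table plus design metadata.

    Columns: chrom, pos, ref, alt, source, probe_start, probe_seq.
    Loci are unique by (chrom, pos) and sorted.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ["chrom", "pos", "ref", "alt", "source"]:
            if col not in self.table.columns:
                raise ValueError(f"manifest missing column {col!r}")
        if "probe_start" not in self.table.columns:
            self.table["probe_start"] = pd.NA
        if "probe_seq" not in self.table.columns:
            self.table["probe_seq"] = pd.NA
        self.table = (
            self.table[["chrom", "pos", "ref", "alt", "source",
                        "probe_start", "probe_seq"]]
            .astype({"chrom": str, "pos": "int64"})
            .sort_values(["chrom", "pos"], kind="stable")
            .reset_index(drop=True)
        )
        if self.table.duplicated(["chrom", "pos"]).any():
            raise ValueError("manifest loci not unique by (chrom, pos)")

    def __len__(self) -> int:
        return len(self.table)

    def per_chromosome_counts(self) -> pd.Series:
        return self.table.groupby("chrom", sort=True)["pos"].count()


def candidates_to_frame(vt: VariantTable, source: str,
                        probes: dict[int, ProbeWindow] | None = None) -> pd.DataFrame:
    probes = probes or {}
    rows = []
    for i in range(vt.n_records):
        w = probes.get(i)
        rows.append((vt.chrom[i], int(vt.pos[i]), vt.ref[i], vt.alt[i], source,
                     w.start if w else pd.NA, w.sequence if w else pd.NA))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "source",
                                       "probe_start", "probe_seq"])


def assemble_panel(stream_reseq: pd.DataFrame, stream_map: pd.DataFrame,
                   metadata: dict | None = None) -> PanelManifest:
    """Merge the resequencing-derived and linkage-map-derived candidate
    streams into a final panel.

    Loci appearing in both streams are kept once with their source labels
    merged; conflicting alleles at a shared locus are an error.
    Final size = |A| + |B| - |A ∩ B|.
    """
    merged = pd.concat([stream_reseq, stream_map], ignore_index=True)
    merged["chrom"] = merged["chrom"].astype(str)
    for col in ("probe_start", "probe_seq"):
        if col not in merged.columns:
            merged[col] = pd.NA
    dup_mask = merged.duplicated(["chrom", "pos"], keep=False)
    unique_part = merged[~dup_mask]
    out_rows = [unique_part]
    if dup_mask.any():
        resolved = []
        for (c, p), grp in merged[dup_mask].groupby(["chrom", "pos"], sort=False):
            if len(set(grp["ref"])) > 1 or len(set(grp["alt"])) > 1:
                raise ValueError(f"allele mismatch at shared locus {c}:{p}")
            row = grp.iloc[0].copy()
            row["source"] = "+".join(sorted(set(grp["source"])))
            probed = grp.dropna(subset=["probe_seq"])
            if len(probed):
                row["probe_start"] = probed.iloc[0]["probe_start"]
                row["probe_seq"] = probed.iloc[0]["probe_seq"]
            resolved.append(row)
        out_rows.append(pd.DataFrame(resolved))
    return PanelManifest(pd.concat(out_rows, ignore_index=True),
                         metadata=metadata or {})


# ---------------------------------------------------------------------------
# panel characterization
# ---------------------------------------------------------------------------


@dataclass
class PanelSummary:
    adjacent_distances: dict[str, np.ndarray]
    mean_adjacent_distance: float
    n_pairs_over_threshold: int
    fraction_over_threshold: float  # as a fraction of within-chrom adjacent pairs
    per_chromosome_counts: pd.Series
    count_length_correlation: float
    effect_class_proportions: dict[str, float] | None = None

    @property
    def percent_over_threshold(self) -> float:
        return 100.0 * self.fraction_over_threshold


def panel_summary(
    manifest: PanelManifest, chrom_lengths: dict[str, int],
    gap_threshold: int = 500_000,
    effect_classes: dict[str, float] | None = None,
) -> PanelSummary:
    """Adjacent-SNP spacing, per-chromosome counts and their correlation with
    chromosome length. Adjacent pairs are computed within chromosomes only;
    the over-threshold fraction is over all within-chromosome adjacent pairs."""
    dists: dict[str, np.ndarray] = {}
    all_d = []
    for c, grp in manifest.table.groupby("chrom", sort=True):
        d = np.diff(np.sort(grp["pos"].to_numpy()))
        dists[c] = d
        all_d.append(d)
    flat = np.concatenate(all_d) if all_d else np.array([])
    if flat.size == 0:
        raise ValueError("need >= 2 SNPs on at least one chromosome")
    counts = manifest.per_chromosome_counts()
    lengths = pd.Series(chrom_lengths)
    common = counts.index.intersection(lengths.index)
    if len(common) >= 3:
        corr = float(stats.pearsonr(counts[common], lengths[common])[0])
    else:
        corr = float("nan")
    n_over = int((flat > gap_threshold).sum())
    return PanelSummary(
        adjacent_distances=dists,
        mean_adjacent_distance=float(flat.mean()),
        n_pairs_over_threshold=n_over,
        fraction_over_threshold=n_over / flat.size,
        per_chromosome_counts=counts,
        count_length_correlation=corr,
        effect_class_proportions=effect_classes,
    )


# ---------------------------------------------------------------------------
# effect classification
# ---------------------------------------------------------------------------

EFFECT_CLASSES = ("intergenic", "intronic", "utr", "synonymous", "nonsynonymous")


def classify_effect(chrom: str, pos: int, ref: str, alt: str,
                    features: FeatureTable, genome: GenomeSequence) -> str:
    """Classify a biallelic SNP against gene models.

    Outside all genes -> intergenic; inside a gene but no exon -> intronic;
    in an exon but not CDS -> utr; in CDS the ref and alt codons are built
    strand-aware from the spliced CDS and translated — identical amino acids
    -> synonymous, else nonsynonymous.
    """
    hits = features.genes_at(chrom, pos)
    if not hits:
        return "intergenic"
    best = "intronic"
    for gene in hits:
        if gene.in_cds(pos):
            return _cds_effect(gene, pos, ref, alt, genome)
        if gene.in_exon(pos):
            best = "utr"
    return best


def _cds_effect(gene, pos: int, ref: str, alt: str,
                genome: GenomeSequence) -> str:
    # spliced CDS in genomic order
    parts = [genome.fetch(gene.chrom, s, e) for s, e, _ in gene.cds]
    cds_seq = "".join(parts)
    # offset of the SNP within the spliced CDS (genomic order)
    offset = 0
    for s, e, _ in gene.cds:
        if s <= pos <= e:
            offset += pos - s
            break
        offset += e - s + 1
    else:
        raise ValueError("position not in CDS")
    if cds_seq[offset].upper() != ref.upper():
        # tolerate ref mismatches (e.g. simulated alt on the reference base)
        pass
    alt_seq = cds_seq[:offset] + alt + cds_seq[offset + 1:]
    if gene.strand == "-":
        frame = gene.cds[-1][2]  # translation starts at the genomic 3' end
        cds_tx = reverse_complement(cds_seq)
        alt_tx = reverse_complement(alt_seq)
        off_tx = len(cds_seq) - 1 - offset
    else:
        frame = gene.cds[0][2]
        cds_tx, alt_tx, off_tx = cds_seq, alt_seq, offset
    cds_tx = cds_tx[frame:]
    alt_tx = alt_tx[frame:]
    off_tx -= frame
    if off_tx < 0:
        return "utr"  # SNP in the trimmed frame prefix
    codon_i = off_tx // 3
    ref_codon = cds_tx[codon_i * 3: codon_i * 3 + 3]
    alt_codon = alt_tx[codon_i * 3: codon_i * 3 + 3]
    if len(ref_codon) < 3:
        return "utr"  # trailing partial codon
    aa_ref = str(Seq(ref_codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


# ---------------------------------------------------------------------------
# funnel orchestration
# ---------------------------------------------------------------------------


@dataclass
class FunnelReport:
    """Stage-by-stage candidate counts of a panel design run."""

    stages: dict[str, int] = field(default_factory=dict)

    def log(self, stage: str, count: int) -> None:
        self.stages[stage] = count

    def to_json(self) -> str:
        import json

        return json.dumps(self.stages, indent=2)


def design_panel(
    vt: VariantTable,
    genome: GenomeSequence,
    map_snps: pd.DataFrame | None = None,
    max_missing: float = 0.2, min_qual: float = 50.0, min_maf: float = 0.15,
    chromosomes: set[str] | None = None,
    flank: int = 100, probe_flank: int = 150, window: int = 100, step: int = 1,
    gc_min: float = 0.4, gc_max: float = 0.6,
    min_identity: float = 0.6, min_coverage: float = 0.6,
    prune_window: int = 100, prune_step: int = 10, r2_max: float = 0.2,
    kmer_k: int = 15,
) -> tuple[PanelManifest, FunnelReport]:
    """Run the full two-stream selection funnel and return the manifest plus
    a stage-count report."""
    report = FunnelReport()
    report.log("reseq_raw", vt.n_records)

    stage1 = filter_variants(vt, max_missing, min_qual, min_maf,
                             drop_unplaced=chromosomes is not None,
                             chromosomes=chromosomes)
    report.log("reseq_quality_filtered", stage1.n_records)

    index = GenomeKmerIndex(genome, k=kmer_k)

    def probe_screen(table: VariantTable, tag: str):
        flank_keep, region_probes = [], {}
        for i in range(table.n_records):
            try:
                _, ok = flank_qc(table.chrom[i], int(table.pos[i]), genome,
                                 flank=flank, gc_min=gc_min, gc_max=gc_max)
            except IndexError:
                ok = False
            if not ok:
                continue
            region = genome.fetch(table.chrom[i],
                                  int(table.pos[i]) - flank,
                                  int(table.pos[i]) + flank)
            verdict = uniqueness_check(
                region, genome, locus=(table.chrom[i], int(table.pos[i]) - flank),
                min_identity=min_identity, min_coverage=min_coverage, index=index,
            )
            if verdict == "unique":
                flank_keep.append(i)
        t2 = table.subset(np.array(flank_keep, dtype=int))
        report.log(f"{tag}_unique_regions", t2.n_records)
        probe_keep, probes = [], {}
        for j in range(t2.n_records):
            wins = probe_windows(t2.chrom[j], int(t2.pos[j]), genome,
                                 flank=probe_flank, window=window, step=step,
                                 gc_min=gc_min, gc_max=gc_max, index=index,
                                 min_identity=min_identity,
                                 min_coverage=min_coverage)
            best = best_probe_window(wins)
            if best is not None:
                probes[len(probe_keep)] = best
                probe_keep.append(j)
        t3 = t2.subset(np.array(probe_keep, dtype=int))
        report.log(f"{tag}_probe_qualified", t3.n_records)
        return t3, probes

    stage3, probes_reseq = probe_screen(stage1, "reseq")

    kept_idx = ld_prune(stage3.to_genotype_matrix(), prune_window, prune_step, r2_max)
    stage4 = stage3.subset(kept_idx)
    probes4 = {new: probes_reseq[old] for new, old in enumerate(kept_idx)}
    report.log("reseq_pruned", stage4.n_records)
    reseq_frame = candidates_to_frame(stage4, "reseq", probes4)

    if map_snps is not None and len(map_snps):
        report.log("map_raw", len(map_snps))
        shared = crossref_with_map(map_snps, vt)
        report.log("map_crossref", shared.n_records)
        map_probe, probes_map = probe_screen(shared, "map")
        map_frame = candidates_to_frame(map_probe, "linkage_map", probes_map)
    else:
        map_frame = pd.DataFrame(columns=reseq_frame.columns)

    manifest = assemble_panel(reseq_frame, map_frame, metadata={
        "min_qual": min_qual, "min_maf": min_maf, "max_missing": max_missing,
        "gc_min": gc_min, "gc_max": gc_max, "r2_max": r2_max,
    })
    report.log("panel_total", len(manifest))
    return manifest, report
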