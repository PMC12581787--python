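"""Synthetic genomes, structured genotypes and heritable phenotypes.

The generator emulates the study design every downstream stage expects:
a multi-chromosome reference with planted near-duplicate segments (so the
probe-uniqueness filter has true positives), a diversity panel of a few
hundred diploid accessions split into subpopulations whose allele
frequencies diverge under a Balding–Nichols model to a target F_ST, local
LD induced by founder-haplotype block copying, uniform genotype
missingness, and quantitative phenotypes y = Xb + Wa + e with an exactly
rescaled heritability.

Everything is driven by a mandatory integer seed; the same seed and config
give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .io import MISSING, GenomeSequence, GenotypeMatrix, VariantTable, FeatureTable, GeneModel

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults mirror a camellia-style diversity panel at desk scale:
    220 accessions in 4 clusters over 15 chromosomes, divergence F_ST 0.25,
    5 kb LD blocks, 2% missing calls, 50 QTN at heritability 0.4.
    """

    n_chrom: int = 15
    chrom_length: int = 100_000
    n_samples: int = 220
    n_snps: int = 5_000
    n_subpops: int = 4
    fst_target: float = 0.25
    ld_block_bp: int = 5_000
    n_founder_haplotypes: int = 10
    maf_low: float = 0.1
    maf_high: float = 0.9
    missing_rate: float = 0.02
    n_qtn: int = 50
    h2_target: float = 0.4
    n_duplicate_segments: int = 5
    duplicate_length: int = 300
    duplicate_similarity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fst_target", "missing_rate", "h2_target", "duplicate_similarity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be in [0, 1]")
        if self.n_qtn > self.n_snps:
            raise ValueError("n_qtn cannot exceed n_snps")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class DuplicateSegment:
    """A planted near-copy: source and target coordinates (1-based incl.)."""

    src_chrom: str
    src_start: int
    dst_chrom: str
    dst_start: int
    length: int
    similarity: float


@dataclass
class TruthTable:
    """Ground truth of a simulation run, for recovery tests."""

    subpop_labels: np.ndarray | None = None
    subpop_freqs: np.ndarray | None = None
    duplicates: list[DuplicateSegment] = field(default_factory=list)
    qtn_indices: np.ndarray | None = None
    qtn_effects: np.ndarray | None = None
    sigma_g2: float | None = None
    sigma_e2: float | None = None
    h2_realized: float | None = None

    def recompute_h2(self) -> float | None:
        if self.sigma_g2 is None or self.sigma_e2 is None:
            return None
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def simulate_genome(config: SimConfig) -> tuple[GenomeSequence, list[DuplicateSegment]]:
    """Random uniform-composition chromosomes with planted duplicate pairs.

    Each duplicate copies a random segment to another random location
    (possibly another chromosome) with per-base mismatch rate
    ``1 - duplicate_similarity``; coordinates are recorded and returned.
    """
    if config.chrom_length < 10_000:
        raise ValueError("chromosome length must be >= 10 kb")
    if config.duplicate_length > config.chrom_length:
        raise ValueError("duplicate length exceeds chromosome length")
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    seqs = {
        c: rng.integers(0, 4, size=config.chrom_length) for c in chroms
    }
    duplicates: list[DuplicateSegment] = []
    L = config.duplicate_length
    for _ in range(config.n_duplicate_segments):
        src_c, dst_c = rng.choice(chroms, size=2, replace=True)
        src_s = int(rng.integers(0, config.chrom_length - L))
        # keep target disjoint from source when on the same chromosome
        for _attempt in range(100):
            dst_s = int(rng.integers(0, config.chrom_length - L))
            if src_c != dst_c or abs(dst_s - src_s) >= L:
                break
        segment = seqs[src_c][src_s:src_s + L].copy()
        n_mis = rng.binomial(L, 1.0 - config.duplicate_similarity)
        if n_mis:
            where = rng.choice(L, size=n_mis, replace=False)
            segment[where] = (segment[where] + rng.integers(1, 4, size=n_mis)) % 4
        seqs[dst_c][dst_s:dst_s + L] = segment
        duplicates.append(
            DuplicateSegment(src_c, src_s + 1, dst_c, dst_s + 1, L,
                             config.duplicate_similarity)
        )
    genome = GenomeSequence({c: "".join(BASES[v]) for c, v in seqs.items()})
    return genome, duplicates


def simulate_population(
    config: SimConfig, genome: GenomeSequence,
    duplicates: list[DuplicateSegment] | None = None,
) -> tuple[VariantTable, TruthTable]:
    """Structured diploid genotypes at random genome positions.

    Subpopulation allele frequencies follow a Balding–Nichols model: with
    ancestral frequency p and divergence F, each subpopulation draws its
    frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), which has expectation p and
    variance F p(1-p) — hitting the target F_ST in expectation. LD comes
    from a founder-haplotype pool per (subpopulation, block): each
    individual's two block haplotypes are copies of random founders.
    """
    rng = np.random.default_rng(config.seed + 1)
    # candidate positions: non-N sites across all chromosomes
    sites: list[tuple[str, int]] = []
    for c, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        good = np.nonzero(arr != b"N")[0]
        sites.extend((c, int(p) + 1) for p in good)
    if config.n_snps > len(sites):
        raise ValueError("n_snps exceeds available non-N sites")
    pick = rng.choice(len(sites), size=config.n_snps, replace=False)
    chosen = sorted((sites[i] for i in pick))
    chrom = np.array([c for c, _ in chosen], dtype=object)
    pos = np.array([p for _, p in chosen], dtype=np.int64)

    m, n, S = config.n_snps, config.n_samples, config.n_subpops
    p_anc = rng.uniform(config.maf_low, config.maf_high, size=m)
    F = config.fst_target
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_sub = rng.beta(a, b, size=(S, m))
    else:
        p_sub = np.tile(p_anc, (S, 1))

    labels = np.repeat(np.arange(S), int(np.ceil(n / S)))[:n]
    # block index per SNP from position (blocks do not span chromosomes)
    block = np.zeros(m, dtype=int)
    b_id = 0
    for c in dict.fromkeys(chrom):
        idx = np.nonzero(chrom == c)[0]
        blk = pos[idx] // max(config.ld_block_bp, 1)
        _, local = np.unique(blk, return_inverse=True)
        block[idx] = local + b_id
        b_id += local.max() + 1 if len(local) else 0

    K = config.n_founder_haplotypes
    geno = np.zeros((m, n), dtype=np.int8)
    for s in range(S):
        members = np.nonzero(labels == s)[0]
        if len(members) == 0:
            continue
        for b in range(b_id):
            snps = np.nonzero(block == b)[0]
            if len(snps) == 0:
                continue
            # founder pool whose allele frequency matches p_sub exactly (up to
            # stochastic rounding): avoids founder-drift inflating F_ST while
            # keeping LD from haplotype sharing
            p_target = p_sub[s, snps]
            counts = np.floor(K * p_target).astype(int)
            counts += rng.random(len(snps)) < (K * p_target - np.floor(K * p_target))
            ranks = np.argsort(np.argsort(rng.random((K, len(snps))), axis=0), axis=0)
            founders = (ranks < counts[None, :]).astype(np.int8)
            pick1 = rng.integers(0, K, size=len(members))
            pick2 = rng.integers(0, K, size=len(members))
            geno[np.ix_(snps, members)] = (founders[pick1] + founders[pick2]).T

    if config.missing_rate > 0:
        mask = rng.random((m, n)) < config.missing_rate
        geno[mask] = MISSING

    ref_base = np.array(
        [genome.fetch(c, p, p) for c, p in zip(chrom, pos)], dtype=object
    )
    alt_choices = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG", "N": "ACG"}
    alt_base = np.array(
        [alt_choices[r][rng.integers(0, 3)] for r in ref_base], dtype=object
    )
    qual = rng.uniform(50, 5000, size=m)
    vt = VariantTable(chrom, pos, ref_base, alt_base, qual, geno,
                      [f"S{i:04d}" for i in range(n)])
    truth = TruthTable(subpop_labels=labels, subpop_freqs=p_sub,
                       duplicates=list(duplicates or []))
    return vt, truth


def simulate_phenotype(
    G: GenotypeMatrix, n_qtn: int, h2_target: float, seed: int,
    truth: TruthTable | None = None,
) -> tuple[np.ndarray, TruthTable]:
    """Additive phenotype y = W_qtn a + e with exact realized heritability.

    QTN columns are sampled among polymorphic SNPs, effects are i.i.d.
    standard normal, and the noise is rescaled so that
    var(genetic)/var(total) equals ``h2_target`` exactly in the sample.
    """
    rng = np.random.default_rng(seed)
    maf = G.maf()
    poly = np.nonzero(maf > 0)[0]
    if len(poly) < n_qtn:
        raise ValueError("not enough polymorphic SNPs for the requested QTN count")
    qtn = np.sort(rng.choice(poly, size=n_qtn, replace=False))
    effects = rng.standard_normal(n_qtn)
    W = G.mean_imputed()[:, qtn]
    g = W @ effects
    g = g - g.mean()
    var_g = g.var()
    if var_g == 0:
        raise ValueError("monomorphic QTN set produced zero genetic variance")
    if h2_target >= 1.0:
        e = np.zeros_like(g)
    else:
        e = rng.standard_normal(G.n_samples)
        e = e - e.mean()
        if h2_target <= 0.0:
            g = np.zeros_like(g)
            effects = np.zeros_like(effects)
            var_g = 0.0
            e = e / e.std()
        else:
            target_var_e = var_g * (1.0 - h2_target) / h2_target
            e = e / e.std() * np.sqrt(target_var_e)
    y = g + e
    out = truth if truth is not None else TruthTable()
    out.qtn_indices = qtn
    out.qtn_effects = effects
    out.sigma_g2 = float(var_g)
    out.sigma_e2 = float(e.var())
    tot = out.sigma_g2 + out.sigma_e2
    out.h2_realized = out.sigma_g2 / tot if tot > 0 else 0.0
    return y, out


def simulate_linkage_map(
    vt: VariantTable, n_map: int, overlap_fraction: float, seed: int,
) -> "pd.DataFrame":
    """A linkage-map SNP list sharing exactly round(overlap * n_map) loci
    with ``vt``; the rest are novel loci absent from the table."""
    import pandas as pd

    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = round(overlap_fraction * n_map)
    n_shared = min(n_shared, vt.n_records)
    shared = rng.choice(vt.n_records, size=n_shared, replace=False)
    rows = [
        (vt.chrom[i], int(vt.pos[i]), vt.ref[i], vt.alt[i]) for i in shared
    ]
    existing = set(zip(vt.chrom, vt.pos))
    chroms = list(dict.fromkeys(vt.chrom)) or ["chr1"]
    max_pos = int(vt.pos.max()) if vt.n_records else 1_000_000
    while len(rows) < n_map:
        c = chroms[rng.integers(0, len(chroms))]
        p = int(rng.integers(1, max_pos + 1_000))
        if (c, p) in existing:
            continue
        existing.add((c, p))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        rows.append((c, p, ref, alt))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def simulate_f1(
    parent_a: np.ndarray, parent_b: np.ndarray, n_offspring: int, seed: int,
) -> GenotypeMatrix:
    """F1 offspring genotypes: one allele drawn per parent per locus.

    Parents are genotype-code vectors over the same loci; a missing parent
    call gives a missing offspring call at that locus.
    """
    a = np.asarray(parent_a, dtype=np.int8)
    b = np.asarray(parent_b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("parents must share loci")
    rng = np.random.default_rng(seed)
    m = len(a)
    out = np.empty((n_offspring, m), dtype=np.int8)
    pa = a / 2.0
    pb = b / 2.0
    for k in range(n_offspring):
        ga = (rng.random(m) < pa).astype(np.int8)
        gb = (rng.random(m) < pb).astype(np.int8)
        out[k] = ga + gb
    out[:, (a == MISSING) | (b == MISSING)] = MISSING
    return GenotypeMatrix(out, [f"F1_{k:03d}" for k in range(n_offspring)],
                          [f"L{j}" for j in range(m)])


def toy_gene_models(genome: GenomeSequence, genes_per_chrom: int = 3,
                    seed: int = 0) -> FeatureTable:
    """Simple single-transcript gene models (2 exons, 1 CDS block each) so
    effect classification has something to hit on simulated genomes."""
    rng = np.random.default_rng(seed)
    genes = []
    i = 0
    for c, length in genome.lengths.items():
        for _ in range(genes_per_chrom):
            span = int(rng.integers(2_000, 5_000))
            start = int(rng.integers(1, max(2, length - span)))
            end = start + span - 1
            e1 = (start, start + span // 3)
            e2 = (start + span // 2, end)
            cds_len = ((e2[1] - e2[0] + 1) // 3) * 3
            cds = [(e2[0], e2[0] + cds_len - 1, 0)]
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"gene{i:04d}", c, strand, start, end,
                                   [e1, e2], cds))
            i += 1
    return FeatureTable(genes)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
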