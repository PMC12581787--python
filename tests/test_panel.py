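"""The SNP-selection funnel: filters, redundancy, probes, pruning, assembly,
panel characterization and effect classification."""

import numpy as np
import pandas as pd
import pytest

import panelcraft as pc
from panelcraft.io import (MISSING, FeatureTable, GeneModel, GenomeSequence,
                           VariantTable, reverse_complement)
from panelcraft.panel import (GenomeKmerIndex, _pairwise_r2, assemble_panel,
                              best_probe_window, candidates_to_frame,
                              uniqueness_check_bruteforce)
from tests.conftest import make_gm


def random_variant_table(rng, n_records=100, n_samples=30, chroms=("chr1", "chr2")):
    chrom = np.repeat(chroms, n_records // len(chroms))
    pos = np.concatenate([
        np.sort(rng.choice(50_000, n_records // len(chroms), replace=False)) + 1
        for _ in chroms
    ])
    geno = rng.choice([0, 1, 2, MISSING], size=(n_records, n_samples),
                      p=[0.4, 0.25, 0.25, 0.1]).astype(np.int8)
    return VariantTable(
        chrom, pos, np.array(["A"] * n_records, dtype=object),
        np.array(["G"] * n_records, dtype=object),
        rng.uniform(0, 200, n_records), geno,
        [f"s{i}" for i in range(n_samples)],
    )


class TestFilterVariants:
    def test_matches_bruteforce_predicates(self):
        rng = np.random.default_rng(0)
        vt = random_variant_table(rng)
        out = pc.filter_variants(vt, max_missing=0.2, min_qual=50,
                                 min_maf=0.15, drop_unplaced=True,
                                 chromosomes={"chr1"})
        expect = []
        for i in range(vt.n_records):
            g = vt.genotypes[i]
            obs = g[g != MISSING]
            miss = (g == MISSING).mean()
            if len(obs) == 0:
                continue
            p = obs.mean() / 2
            maf = min(p, 1 - p)
            if miss < 0.2 and vt.qual[i] >= 50 and maf >= 0.15 \
                    and vt.chrom[i] == "chr1":
                expect.append((vt.chrom[i], vt.pos[i]))
        got = list(zip(out.chrom, out.pos))
        assert got == expect

    def test_maf_threshold(self):
        # MAF 0.10 removed at min_maf 0.15; monomorphic removed always
        geno = np.array([[0] * 18 + [1, 1],     # alt freq 0.05 -> maf 0.05
                         [0] * 20,              # monomorphic
                         [0] * 10 + [2] * 10])  # maf 0.5
        vt = VariantTable(np.array(["c"] * 3), np.array([1, 2, 3]),
                          np.array(list("ACG")), np.array(list("TGA")),
                          np.array([99.0] * 3), geno.astype(np.int8),
                          [f"s{i}" for i in range(20)])
        out = pc.filter_variants(vt, drop_unplaced=False)
        assert list(out.pos) == [3]


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [
        ("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5), ("acgt", 0.5),
    ])
    def test_values(self, seq, expected):
        assert pc.gc_content(seq) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pc.gc_content("")


class TestFlankQc:
    def make_genome(self, core="ACGT" * 200):
        return GenomeSequence({"c1": core})

    def test_gc_pass_and_fail(self):
        g = self.make_genome()
        region, ok = pc.flank_qc("c1", 400, g, flank=100)
        assert len(region.sequence) == 201
        assert region.gc == pytest.approx(0.5, abs=0.01)
        assert ok
        at_genome = GenomeSequence({"c1": "AT" * 400})
        _, ok = pc.flank_qc("c1", 400, at_genome, flank=100)
        assert not ok  # GC 0 outside [0.4, 0.6]

    def test_n_base_fails(self):
        seq = "ACGT" * 100 + "N" + "ACGT" * 100
        _, ok = pc.flank_qc("c1", 380, GenomeSequence({"c1": seq}), flank=100)
        assert not ok

    def test_truncated_flank_fails(self):
        g = self.make_genome()
        region, ok = pc.flank_qc("c1", 50, g, flank=100)
        assert region.truncated and not ok

    def test_off_chromosome_is_error(self):
        with pytest.raises(IndexError):
            pc.flank_qc("c1", 10_000, self.make_genome(), flank=100)


class TestUniqueness:
    def test_planted_verbatim_copy_is_duplicate(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 20_000))
        region = seq[5000:5201]
        seq2 = seq[:12_000] + region + seq[12_201:]
        g = GenomeSequence({"c1": seq2})
        assert pc.uniqueness_check(region, g, locus=("c1", 5001)) == "duplicate"
        assert uniqueness_check_bruteforce(region, g, locus=("c1", 5001)) \
            == "duplicate"

    def test_random_region_is_unique_and_agrees_with_bruteforce(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 20_000))
        g = GenomeSequence({"c1": seq})
        for start in (1000, 7000, 15_000):
            region = seq[start:start + 201]
            fast = pc.uniqueness_check(region, g, locus=("c1", start + 1))
            slow = uniqueness_check_bruteforce(region, g, locus=("c1", start + 1))
            assert fast == slow == "unique"

    def test_half_identity_copy_stays_unique(self):
        # planted copy with every other base mutated (50% identity < 60%)
        rng = np.random.default_rng(3)
        seq = list("".join(rng.choice(list("ACGT"), 20_000)))
        region = "".join(seq[5000:5201])
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
        copy = list(region)
        for i in range(0, len(copy), 2):
            copy[i] = rot[copy[i]]
        seq[12_000:12_201] = copy
        g = GenomeSequence({"c1": "".join(seq)})
        assert uniqueness_check_bruteforce(region, g, locus=("c1", 5001)) == "unique"
        assert pc.uniqueness_check(region, g, locus=("c1", 5001)) == "unique"

    def test_high_similarity_copy_agrees_with_bruteforce(self):
        rng = np.random.default_rng(4)
        seq = list("".join(rng.choice(list("ACGT"), 20_000)))
        region = "".join(seq[3000:3201])
        rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
        copy = list(region)
        for i in rng.choice(201, size=20, replace=False):  # 90% identity
            copy[i] = rot[copy[i]]
        seq[10_000:10_201] = copy
        g = GenomeSequence({"c1": "".join(seq)})
        assert pc.uniqueness_check(region, g, locus=("c1", 3001)) == "duplicate"
        assert uniqueness_check_bruteforce(region, g, locus=("c1", 3001)) \
            == "duplicate"

    def test_reverse_complement_copy_detected(self):
        rng = np.random.default_rng(5)
        seq = list("".join(rng.choice(list("ACGT"), 20_000)))
        region = "".join(seq[3000:3201])
        seq[10_000:10_201] = reverse_complement(region)
        g = GenomeSequence({"c1": "".join(seq)})
        assert pc.uniqueness_check(region, g, locus=("c1", 3001)) == "duplicate"

    def test_region_shorter_than_seed_rejected(self):
        g = GenomeSequence({"c1": "ACGT" * 5000})
        with pytest.raises(ValueError, match="seed length"):
            pc.uniqueness_check("ACGT", g)


class TestProbeWindows:
    def setup_method(self):
        rng = np.random.default_rng(6)
        self.seq = "".join(rng.choice(list("ACGT"), 20_000))
        self.genome = GenomeSequence({"c1": self.seq})
        self.index = GenomeKmerIndex(self.genome)

    def test_window_count_is_length_minus_window_plus_one(self):
        wins = pc.probe_windows("c1", 5000, self.genome, index=self.index)
        assert len(wins) == 301 - 100 + 1 == 202
        assert all(len(w.sequence) == 100 for w in wins)

    def test_snp_containment_count(self):
        wins = pc.probe_windows("c1", 5000, self.genome, index=self.index)
        assert sum(w.contains_snp for w in wins) == 100
        # windows 52..151 (1-indexed over the enumeration) contain the SNP
        flags = [w.contains_snp for w in wins]
        assert flags[50] is False and flags[51] is True
        assert flags[150] is True and flags[151] is False

    def test_all_n_region_yields_no_qualified_window(self):
        g = GenomeSequence({"c1": "ACGT" * 100 + "N" * 400 + "ACGT" * 100})
        wins = pc.probe_windows("c1", 600, g, index=GenomeKmerIndex(g))
        assert all(not w.qualified for w in wins)
        assert best_probe_window(wins) is None

    def test_truncated_region_empty(self):
        wins = pc.probe_windows("c1", 100, self.genome, index=self.index)
        assert wins == []

    def test_best_window_prefers_snp_containment(self):
        wins = pc.probe_windows("c1", 5000, self.genome, index=self.index,
                                lazy_uniqueness=False)
        best = best_probe_window(wins)
        if any(w.qualified and w.contains_snp for w in wins):
            assert best.contains_snp


class TestLdPrune:
    def test_duplicate_columns_keep_exactly_one(self):
        rng = np.random.default_rng(7)
        col = rng.choice([0, 1, 2], size=80).astype(np.int8)
        G = make_gm(np.column_stack([col, col]))
        kept = pc.ld_prune(G, r2_max=0.2)
        assert len(kept) == 1

    def test_independent_columns_all_kept(self):
        rng = np.random.default_rng(8)
        G = make_gm(rng.choice([0, 1, 2], size=(500, 30)))
        kept = pc.ld_prune(G, r2_max=0.2)
        assert len(kept) == 30

    def test_postcondition_no_inwindow_pair_above_threshold(self, small_sim):
        G = small_sim["G"]
        window, r2_max = 50, 0.2
        kept = pc.ld_prune(G, window_snps=window, step_snps=5, r2_max=r2_max)
        sub = G.subset_snps(kept)
        # brute-force scan of every in-window pair of the kept set
        for start in range(0, sub.n_snps - 1):
            end = min(start + window, sub.n_snps)
            r2 = _pairwise_r2(sub.matrix[:, start:end])
            assert r2.max() <= r2_max + 1e-12

    def test_deterministic(self, small_sim):
        G = small_sim["G"]
        k1 = pc.ld_prune(G)
        k2 = pc.ld_prune(G)
        np.testing.assert_array_equal(k1, k2)


class TestCrossrefAndAssembly:
    def frame(self, n, chrom="chr1", start=0, source="reseq"):
        return pd.DataFrame({
            "chrom": [chrom] * n, "pos": np.arange(start, start + n) * 10 + 10,
            "ref": ["A"] * n, "alt": ["G"] * n, "source": [source] * n,
        })

    def test_disjoint_sets_empty_crossref(self, small_sim):
        vt = small_sim["vt"]
        lm = pd.DataFrame({"chrom": ["chrX"], "pos": [1], "ref": ["A"],
                           "alt": ["G"]})
        assert pc.crossref_with_map(lm, vt).n_records == 0

    def test_identical_sets_full_crossref(self, small_sim):
        vt = small_sim["vt"]
        lm = pd.DataFrame({"chrom": vt.chrom, "pos": vt.pos, "ref": vt.ref,
                           "alt": vt.alt})
        assert pc.crossref_with_map(lm, vt).n_records == vt.n_records

    def test_panel_assembly_arithmetic(self):
        # disjoint streams of the published funnel sizes combine additively
        a = self.frame(20_476, chrom="chr1")
        b = self.frame(424, chrom="chr2", source="linkage_map")
        manifest = assemble_panel(a, b)
        assert len(manifest) == 20_900

    def test_identical_streams_collapse(self):
        a = self.frame(50)
        m = assemble_panel(a, a.assign(source="linkage_map"))
        assert len(m) == 50
        assert set(m.table["source"]) == {"linkage_map+reseq"}

    def test_known_overlap(self):
        a = self.frame(100)
        b = self.frame(100, start=70, source="linkage_map")  # 30 shared loci
        assert len(assemble_panel(a, b)) == 100 + 100 - 30

    def test_allele_mismatch_rejected(self):
        a = self.frame(5)
        b = self.frame(5, source="linkage_map")
        b.loc[2, "alt"] = "T"
        with pytest.raises(ValueError, match="allele mismatch"):
            assemble_panel(a, b)


class TestPanelSummary:
    def manifest(self, positions, chrom="chr1"):
        n = len(positions)
        df = pd.DataFrame({"chrom": [chrom] * n, "pos": positions,
                           "ref": ["A"] * n, "alt": ["G"] * n,
                           "source": ["reseq"] * n})
        return pc.PanelManifest(df)

    def test_single_large_gap(self):
        s = pc.panel_summary(self.manifest([1_000, 601_000]), {"chr1": 700_000})
        assert s.n_pairs_over_threshold == 1
        assert s.fraction_over_threshold == 1.0
        assert s.mean_adjacent_distance == 600_000

    def test_published_gap_fraction_arithmetic(self):
        # 20 900 SNPs over 15 chromosomes -> 20 885 adjacent pairs; 1 216
        # gaps above 500 kb gives 5.82%
        rng = np.random.default_rng(9)
        per_chrom = 20_900 // 15
        rem = 20_900 - per_chrom * 14
        frames = []
        n_large_total = 1_216
        large_per_chrom = [n_large_total // 15 + (1 if i < n_large_total % 15 else 0)
                           for i in range(15)]
        for i in range(15):
            n = rem if i == 14 else per_chrom
            n_large = large_per_chrom[i]
            gaps = np.full(n - 1, 10_000)
            gaps[rng.choice(n - 1, size=n_large, replace=False)] = 600_000
            pos = 1 + np.concatenate([[0], np.cumsum(gaps)])
            frames.append(pd.DataFrame({
                "chrom": [f"chr{i+1}"] * n, "pos": pos, "ref": ["A"] * n,
                "alt": ["G"] * n, "source": ["reseq"] * n}))
        m = pc.PanelManifest(pd.concat(frames, ignore_index=True))
        s = pc.panel_summary(m, {f"chr{i+1}": 10_000_000 + i * 500_000
                                 for i in range(15)})
        assert len(m) == 20_900
        assert s.n_pairs_over_threshold == 1_216
        assert s.percent_over_threshold == pytest.approx(5.82, abs=0.005)

    def test_density_proportional_counts_correlate_with_length(self):
        rng = np.random.default_rng(10)
        frames = []
        lengths = {}
        for i in range(8):
            L = int(2e6 * (i + 1))
            lengths[f"c{i}"] = L
            n = max(2, int(L / 50_000))
            pos = np.sort(rng.choice(L, size=n, replace=False)) + 1
            frames.append(pd.DataFrame({
                "chrom": [f"c{i}"] * n, "pos": pos, "ref": ["A"] * n,
                "alt": ["G"] * n, "source": ["reseq"] * n}))
        s = pc.panel_summary(pc.PanelManifest(pd.concat(frames)), lengths)
        assert s.count_length_correlation > 0.9
        assert s.per_chromosome_counts.sum() == sum(len(f) for f in frames)


class TestClassifyEffect:
    def make_world(self):
        #          1         2         3
        # 123456789012345678901234567890123456
        # gene on +: CDS 11..22 (ATG GCT TAT TAA)
        seq = "A" * 10 + "ATGGCTTATTAA" + "C" * 14
        genome = GenomeSequence({"c1": seq})
        gene = GeneModel("g1", "c1", "+", 5, 30, [(5, 30)], [(11, 22, 0)])
        return genome, FeatureTable([gene])

    def test_intergenic(self):
        genome, ft = self.make_world()
        assert pc.classify_effect("c1", 2, "A", "G", ft, genome) == "intergenic"

    def test_utr_and_intronic(self):
        genome, ft = self.make_world()
        assert pc.classify_effect("c1", 7, "A", "G", ft, genome) == "utr"
        intron_gene = GeneModel("g2", "c1", "+", 5, 30, [(5, 10), (20, 30)], [])
        ft2 = FeatureTable([intron_gene])
        assert pc.classify_effect("c1", 15, "G", "A", ft2, genome) == "intronic"

    def test_synonymous_third_position(self):
        genome, ft = self.make_world()
        # codon 2 = GCT (Ala) at 14..16; GCT->GCC stays Ala
        assert pc.classify_effect("c1", 16, "T", "C", ft, genome) == "synonymous"

    def test_nonsynonymous_first_position(self):
        genome, ft = self.make_world()
        # codon 1 = ATG at 11..13; ATG->GTG is Met->Val
        assert pc.classify_effect("c1", 11, "A", "G", ft, genome) == "nonsynonymous"

    def test_minus_strand_with_translation_oracle(self):
        from Bio.Seq import Seq

        # minus-strand CDS: genomic 11..22 whose revcomp is ATGGCTTATTAA
        rc = str(Seq("ATGGCTTATTAA").reverse_complement())
        seq = "A" * 10 + rc + "C" * 14
        genome = GenomeSequence({"c1": seq})
        gene = GeneModel("g1", "c1", "-", 5, 30, [(5, 30)], [(11, 22, 0)])
        ft = FeatureTable([gene])
        # mutate the genomic base that is the first codon position (ATG->GTG):
        # transcript pos 0 maps to genomic 22; alt on the genome strand is the
        # complement of G, i.e. C
        got = pc.classify_effect("c1", 22, seq[21], "C", ft, genome)
        # independent check by explicit six-frame-style translation
        alt_seq = seq[:21] + "C" + seq[22:]
        prot_ref = str(Seq(seq[10:22]).reverse_complement().translate())
        prot_alt = str(Seq(alt_seq[10:22]).reverse_complement().translate())
        assert prot_ref != prot_alt
        assert got == "nonsynonymous"


class TestFunnel:
    def test_stage_monotonicity_and_report(self, small_sim):
        vt, genome = small_sim["vt"], small_sim["genome"]
        lm = pc.simulate_linkage_map(vt, n_map=50, overlap_fraction=0.5, seed=3)
        manifest, report = pc.design_panel(
            vt, genome, map_snps=lm, chromosomes=set(genome.chromosomes))
        s = report.stages
        assert s["reseq_quality_filtered"] <= s["reseq_raw"]
        assert s["reseq_unique_regions"] <= s["reseq_quality_filtered"]
        assert s["reseq_probe_qualified"] <= s["reseq_unique_regions"]
        assert s["reseq_pruned"] <= s["reseq_probe_qualified"]
        assert s["map_crossref"] <= s["map_raw"]
        assert len(manifest) == s["panel_total"]
        assert len(manifest) <= s["reseq_pruned"] + s["map_probe_qualified"]

    def test_manifest_probe_rows_have_sequences(self, small_sim):
        vt, genome = small_sim["vt"], small_sim["genome"]
        manifest, _ = pc.design_panel(vt, genome,
                                      chromosomes=set(genome.chromosomes))
        probed = manifest.table.dropna(subset=["probe_seq"])
        assert len(probed) == len(manifest)
        assert probed["probe_seq"].str.len().eq(100).all()
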