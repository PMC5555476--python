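import numpy as np
import pandas as pd
import pytest

from crisprscreen import (
    CandidateGuide,
    FilterConfig,
    GeneModel,
    GenomeSiteIndex,
    LibraryDesignError,
    apply_filters,
    assign_ranks,
    classify_offtargets,
    enumerate_candidates,
    load_gene_models,
    read_variant_positions,
    select_library,
)
from crisprscreen.library_design import DEFAULT_RANK_RULE, revcomp
from crisprscreen.synthetic import (
    SynthGenomeSpec,
    make_genome,
    write_gtf,
    write_vcf,
)


# -- independent brute-force enumeration, written against the stated geometry,
#    not the production scan -------------------------------------------------

def brute_force_candidates(seq, exons):
    """Every (strand, protospacer, cut) whose blunt cut (between protospacer
    positions 17 and 18) has both flanking bases inside a coding exon."""
    found = []
    n = len(seq)
    for i in range(n - 22):  # 23-mer window protospacer+PAM, plus strand
        window = seq[i:i + 23]
        if window[21:23] == "GG":
            cut = i + 16  # base at protospacer position 17 (0-based)
            if any(s <= cut and cut + 1 <= e - 1 for s, e in exons):
                found.append(("+", window[:20], cut))
        rc = revcomp(window)
        if rc[21:23] == "GG":
            cut = i + 23 - 18  # position 18 counted from the far end
            if any(s <= cut and cut + 1 <= e - 1 for s, e in exons):
                found.append(("-", rc[:20], cut))
    return sorted(found)


def make_candidate(protospacer, **kw):
    defaults = dict(pam="AGG", chrom="chr1", strand="+", cut_site=100,
                    target_gene="G1", target_exon=1,
                    gc_fraction=(protospacer.count("G")
                                 + protospacer.count("C")) / len(protospacer))
    defaults.update(kw)
    return CandidateGuide(protospacer=protospacer, **defaults)


class TestEnumerateCandidates:
    def test_no_pam_no_candidates(self):
        seq = "AT" * 100  # no GG and no CC anywhere
        model = GeneModel(gene="G1", chrom="chr1", strand="+",
                          coding_exons=((20, 180),), gene_body=(20, 180))
        assert enumerate_candidates({"chr1": seq}, [model]) == []

    def test_matches_brute_force_on_random_genome(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        exons = ((100, 400), (700, 1000), (1500, 1800))
        model = GeneModel(gene="G1", chrom="chr1", strand="+",
                          coding_exons=exons, gene_body=(100, 1800))
        cands = enumerate_candidates({"chr1": seq}, [model])
        got = sorted((c.strand, c.protospacer, c.cut_site) for c in cands)
        assert got == brute_force_candidates(seq, exons)
        assert len(got) > 20  # non-trivial genome

    def test_cut_site_outside_cds_rejected(self):
        # PAM placed so the cut lands 2 bp outside the exon boundary
        seq = list("AT" * 150)
        proto = "ACTACTACTACTACTACTAC"  # no GG/CC anywhere
        site = proto + "AGG"
        seq[100:123] = site  # cut bond between 116 and 117
        seq = "".join(seq)
        inside = GeneModel(gene="G1", chrom="chr1", strand="+",
                           coding_exons=((100, 140),), gene_body=(100, 140))
        outside = GeneModel(gene="G2", chrom="chr1", strand="+",
                            coding_exons=((119, 140),), gene_body=(119, 140))
        assert len(enumerate_candidates({"chr1": seq}, [inside])) == 1
        assert enumerate_candidates({"chr1": seq}, [outside]) == []

    def test_exon_beyond_chromosome_is_error(self):
        model = GeneModel(gene="G1", chrom="chr1", strand="+",
                          coding_exons=((0, 500),), gene_body=(0, 500))
        with pytest.raises(LibraryDesignError, match="beyond"):
            enumerate_candidates({"chr1": "ACGT" * 50}, [model])

    def test_exon_number_recorded_in_transcription_order(self):
        genome = make_genome(SynthGenomeSpec(n_genes=2, seed=4))
        cands = enumerate_candidates(genome.sequences, genome.models)
        minus = [m for m in genome.models if m.strand == "-"]
        for m in minus:
            # exon 1 of a minus-strand gene is the rightmost interval
            first_exon = m.coding_exons[0]
            for c in cands:
                if c.target_gene == m.gene and c.target_exon == 1:
                    assert first_exon[0] <= c.cut_site < first_exon[1]


class TestApplyFilters:
    @pytest.mark.parametrize("proto,reason", [
        ("ATATATCGCATATATCGCAT", "gc"),            # 7/20 = 35% GC
        ("ACGCACGTTTTACGCAGCAC", "homopolymer"),   # TTTT run
        ("ACCGGTACGCACGTACGCAC", "restriction_site"),  # AgeI site, forward
        ("ACGCAGAGACGTACGCATAC", "restriction_site"),  # BsmBI on reverse strand
    ])
    def test_rejection_reasons(self, proto, reason):
        kept, rejected = apply_filters([make_candidate(proto)])
        assert not kept
        assert rejected[0].rejection_reason == reason

    def test_clean_guide_retained(self):
        kept, rejected = apply_filters([make_candidate("ACGCATGTCGATCGTAGCAC")])
        assert len(kept) == 1 and not rejected

    def test_restriction_site_spanning_pam(self):
        # protospacer ends ACC, PAM TGG -> ACCTGG no; use ACCGG|T? site ACCGGT
        proto = "CGATCGTAGCACGCATACCG"
        cand = make_candidate(proto, pam="GTG")
        kept, rejected = apply_filters([cand])
        assert rejected and rejected[0].rejection_reason == "restriction_site"

    def test_snp_overlap_rejected(self):
        cand = make_candidate("ACGCATGTCGATCGTAGCAC", strand="+", cut_site=100)
        # plus-strand footprint is [84, 107)
        kept, rejected = apply_filters([cand], snps={"chr1": {90}})
        assert rejected and rejected[0].rejection_reason == "snp"
        kept, rejected = apply_filters([cand], snps={"chr1": {83, 107}})
        assert kept and not rejected

    def test_snp_filter_can_be_disabled(self):
        cand = make_candidate("ACGCATGTCGATCGTAGCAC")
        kept, _ = apply_filters([cand], FilterConfig(snp_filter=False),
                                snps={"chr1": {100}})
        assert kept


def plant(seq_len, plants, seed=0):
    """Linear chromosome with given (pos, sequence) insertions."""
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("AT"), size=seq_len)))  # PAM-free floor
    for pos, s in plants:
        seq[pos:pos + len(s)] = s
    return "".join(seq)


PROTO = "ACGCATGTCGATCGTAGCAC"


def mism(proto, positions, to="G"):
    s = list(proto)
    for p in positions:
        s[p] = to if s[p] != to else "C"
    return "".join(s)


class TestClassifyOfftargets:
    GENE = GeneModel(gene="G1", chrom="chr1", strand="+",
                     coding_exons=((80, 140),), gene_body=(80, 200))
    OTHER = GeneModel(gene="G2", chrom="chr1", strand="+",
                      coding_exons=((600, 650),), gene_body=(560, 700))

    def site(self, proto):
        return proto + "AGG"

    def cand(self):
        return make_candidate(PROTO, cut_site=116, chrom="chr1")

    def classify(self, plants, models=None):
        seq = plant(2000, plants)
        idx = GenomeSiteIndex({"chr1": seq})
        return classify_offtargets(self.cand(), idx, models or [self.GENE, self.OTHER])

    def test_unique_clean_hit_is_class2(self):
        assert self.classify([(100, self.site(PROTO))]) == 2

    def test_two_target_hits_class1(self):
        cls = self.classify([(100, self.site(PROTO)),
                             (160, self.site(mism(PROTO, [0, 5])))])
        assert cls == 1  # second hit is inside the target gene body (intron)

    def test_two_intergenic_offtargets_class3(self):
        cls = self.classify([(100, self.site(PROTO)),
                             (900, self.site(mism(PROTO, [3]))),
                             (1200, self.site(mism(PROTO, [4, 9])))])
        assert cls == 3

    def test_three_intergenic_offtargets_class4(self):
        cls = self.classify([(100, self.site(PROTO)),
                             (900, self.site(mism(PROTO, [3]))),
                             (1200, self.site(mism(PROTO, [4, 9]))),
                             (1500, self.site(mism(PROTO, [11])))])
        assert cls == 4

    def test_four_intergenic_offtargets_excluded(self):
        plants = [(100, self.site(PROTO))] + [
            (800 + 200 * i, self.site(mism(PROTO, [i + 1]))) for i in range(4)
        ]
        assert self.classify(plants) == "excluded"

    def test_hit_in_other_gene_intron_excluded(self):
        cls = self.classify([(100, self.site(PROTO)),
                             (565, self.site(mism(PROTO, [2])))])  # G2 intron
        assert cls == "excluded"

    def test_mismatch_budget_respected(self):
        # three mismatches is outside the budget: still a clean unique hit
        cls = self.classify([(100, self.site(PROTO)),
                             (900, self.site(mism(PROTO, [1, 2, 3])))])
        assert cls == 2

    def test_missing_target_site_is_error(self):
        seq = plant(500, [])
        idx = GenomeSiteIndex({"chr1": seq})
        with pytest.raises(LibraryDesignError):
            classify_offtargets(self.cand(), idx, [self.GENE])


class TestAssignRanks:
    @pytest.mark.parametrize("cls,score,rank", [
        (1, 0.5, 1),
        (1, 0.9, 1),
        (2, 0.9, 2),
        (3, 0.9, 2),
        (4, 0.9, 3),
        (2, 0.5, 4),
        (3, 0.0, 4),
        (4, 0.5, 5),
        (2, -0.5, 5),
        (2, -1.5, None),
        (1, -0.2, 5),
        ("excluded", 2.0, None),
    ])
    def test_first_qualifying_tier(self, cls, score, rank):
        c = make_candidate("ACGT" * 5)
        c.offtarget_class = cls
        c.seq_score = score
        assign_ranks([c])
        assert c.rank == rank


def ranked(gene, exon, score, proto, rank=2):
    c = make_candidate(proto, target_gene=gene, target_exon=exon)
    c.seq_score = score
    c.offtarget_class = 2
    c.rank = rank
    return c


def rand_proto(rng):
    return "".join(rng.choice(list("ACGT"), size=20))


class TestSelectLibrary:
    def test_five_exons_four_distinct(self):
        rng = np.random.default_rng(0)
        cands = [ranked("G1", e, float(e), rand_proto(rng)) for e in range(1, 6)]
        lib = select_library(cands)
        assert len(lib.selected) == 4
        assert len({c.target_exon for c in lib.selected}) == 4
        # highest scores win: exon 1 (score 1.0) is the one left out
        assert {c.target_exon for c in lib.selected} == {2, 3, 4, 5}

    def test_unranked_gene_is_untargeted(self):
        c = make_candidate("ACGT" * 5, target_gene="G1")
        c.seq_score = -2.0
        c.offtarget_class = 2
        assign_ranks([c])
        lib = select_library([c])
        assert lib.untargeted_genes == ["G1"]
        assert not lib.selected

    def test_single_exon_descending_score(self):
        rng = np.random.default_rng(1)
        cands = [ranked("G1", 1, s, rand_proto(rng))
                 for s in (0.3, 0.9, 0.5, 0.7, 0.2, 0.6)]
        lib = select_library(cands)
        scores = [c.seq_score for c in lib.selected]
        assert scores == sorted(scores, reverse=True)[:4] == [0.9, 0.7, 0.6, 0.5]

    def test_exon_diversity_preferred_within_rank(self):
        rng = np.random.default_rng(2)
        # exon 1 has the top two scores; exon 2's best should still enter round 2
        cands = [ranked("G1", 1, 0.99, rand_proto(rng)),
                 ranked("G1", 1, 0.98, rand_proto(rng)),
                 ranked("G1", 2, 0.90, rand_proto(rng))]
        lib = select_library(cands, guides_per_gene=2)
        assert [c.target_exon for c in lib.selected] == [1, 2]

    def test_duplicate_protospacer_goes_to_first_gene(self):
        shared = "ACGCATGTCGATCGTAGCAC"
        cands = [ranked("G1", 1, 0.9, shared), ranked("G2", 1, 0.9, shared)]
        lib = select_library(cands, guides_per_gene=1)
        assert [c.target_gene for c in lib.selected] == ["G1"]
        assert ("G2", shared) in lib.conflicts
        assert "G2" in lib.untargeted_genes

    def test_size_bound_and_uniqueness(self):
        rng = np.random.default_rng(3)
        cands = []
        for g in range(5):
            for e in range(1, 4):
                for _ in range(3):
                    cands.append(ranked(f"G{g}", e, float(rng.random()),
                                        rand_proto(rng)))
        controls = [("CTRL1", "A" * 20), ("CTRL2", "C" * 20)]
        lib = select_library(cands, controls=controls)
        assert lib.size <= 4 * 5 + len(controls)
        protos = [c.protospacer for c in lib.selected]
        assert len(protos) == len(set(protos))
        assert lib.size == len(lib.selected) + len(lib.controls)

    def test_selected_guides_satisfy_their_tier(self):
        rng = np.random.default_rng(4)
        cands = []
        for g in range(4):
            for _ in range(8):
                c = make_candidate(rand_proto(rng), target_gene=f"G{g}",
                                   target_exon=int(rng.integers(1, 4)))
                c.offtarget_class = int(rng.choice([1, 2, 3, 4]))
                c.seq_score = float(rng.uniform(-1.5, 2))
                cands.append(c)
        assign_ranks(cands)
        lib = select_library(cands)
        for c in lib.selected:
            tier = next(t for t in DEFAULT_RANK_RULE if t.rank == c.rank)
            assert tier.admits(c.offtarget_class, c.seq_score)

    def test_raising_scores_never_lowers_rank(self):
        rng = np.random.default_rng(5)
        cands = []
        for _ in range(10):
            c = make_candidate(rand_proto(rng), target_gene="G1",
                               target_exon=int(rng.integers(1, 3)))
            c.offtarget_class = int(rng.choice([1, 2, 3, 4]))
            c.seq_score = float(rng.uniform(-1.0, 1.5))
            cands.append(c)
        assign_ranks(cands)
        before = {c.protospacer: c.rank for c in cands if c.rank}
        for c in cands:
            c.seq_score += 0.3
            c.selection_round = None
        assign_ranks(cands)
        for c in cands:
            if c.protospacer in before:
                assert c.rank is not None and c.rank <= before[c.protospacer]

    def test_selection_deterministic(self):
        rng = np.random.default_rng(6)
        protos = [rand_proto(rng) for _ in range(20)]
        def build():
            cands = [ranked(f"G{i % 3}", (i % 4) + 1, (i * 7 % 11) / 10, p)
                     for i, p in enumerate(protos)]
            lib = select_library(cands)
            return [(c.target_gene, c.protospacer, c.rank, c.selection_round)
                    for c in lib.selected]
        assert build() == build()


class TestModelIO:
    def test_gtf_roundtrip_and_canonical_transcript(self, tmp_path):
        genome = make_genome(SynthGenomeSpec(n_genes=3, seed=1))
        gtf = tmp_path / "m.gtf"
        write_gtf(genome.models, gtf)
        models = load_gene_models(gtf)
        assert [m.gene for m in models] == [m.gene for m in genome.models]
        for got, want in zip(models, genome.models):
            assert got.strand == want.strand
            assert got.coding_exons == want.coding_exons
            assert got.gene_body == want.gene_body

    def test_longest_cds_transcript_wins(self, tmp_path):
        gtf = tmp_path / "two_tx.gtf"
        lines = [
            'chr1\tx\tCDS\t11\t40\t.\t+\t0\tgene_id "G"; transcript_id "t1";',
            'chr1\tx\tCDS\t11\t100\t.\t+\t0\tgene_id "G"; transcript_id "t2";',
            'chr1\tx\tCDS\t151\t200\t.\t+\t0\tgene_id "G"; transcript_id "t2";',
        ]
        gtf.write_text("\n".join(lines) + "\n")
        (model,) = load_gene_models(gtf)
        assert model.coding_exons == ((10, 100), (150, 200))
        assert model.gene_body == (10, 200)

    def test_variant_positions_from_vcf(self, tmp_path):
        seqs = {"chr1": "ACGT" * 25}
        vcf = tmp_path / "v.vcf"
        write_vcf({"chr1": [5, 50]}, seqs, vcf)
        pos = read_variant_positions(vcf)
        assert pos == {"chr1": {5, 50}}
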