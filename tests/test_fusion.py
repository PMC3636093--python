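import numpy as np
import pytest

from breakscan import fusion
from breakscan.models import ChimericHit, FusionCandidate, GeneModel, MatePair, Read


def mk_read(chrom="chr1", start=0, end=50, strand="+", mapped=True, seq=""):
    return Read(chrom=chrom, start=start, end=end, strand=strand, mapped=mapped, sequence=seq)


def mk_pair(pid, r1, r2):
    return MatePair(pair_id=pid, read1=r1, read2=r2)


@pytest.fixture
def anchor():
    return GeneModel("ANCH", "chr1", "+", ((1000, 1500), (2000, 2500)))


@pytest.fixture
def partner():
    return GeneModel("PART", "chr2", "+", ((500, 900), (1200, 1600)))


class TestExtract:
    def test_both_reads_in_anchor_excluded(self, anchor):
        p = mk_pair("a", mk_read(start=1100, end=1150), mk_read(start=2100, end=2150))
        assert fusion.extract_anchored_pairs([p], anchor) == []

    def test_cross_chromosome_mate_included(self, anchor):
        p = mk_pair("b", mk_read(start=1100, end=1150), mk_read(chrom="chr2", start=600, end=650))
        assert fusion.extract_anchored_pairs([p], anchor) == [p]

    def test_unmapped_mate_included_for_rescue(self, anchor):
        p = mk_pair("c", mk_read(start=1100, end=1150), mk_read(mapped=False, start=0, end=0, seq="ACGT"))
        (kept,) = fusion.extract_anchored_pairs([p], anchor)
        assert not kept.read2.mapped and kept.read2.sequence == "ACGT"

    def test_intronic_only_read_not_anchored(self, anchor):
        # read falls between the anchor's exons: no exon overlap, not anchored
        p = mk_pair("d", mk_read(start=1600, end=1650), mk_read(chrom="chr2", start=600, end=650))
        assert fusion.extract_anchored_pairs([p], anchor) == []


class TestNominate:
    def test_support_counting(self, anchor, partner):
        other = GeneModel("OTHER", "chr3", "+", ((0, 1000),))
        models = [anchor, partner, other]
        pairs = [
            mk_pair(f"p{i}", mk_read(start=1100, end=1150), mk_read(chrom="chr2", start=600, end=650))
            for i in range(5)
        ] + [mk_pair("q", mk_read(start=1100, end=1150), mk_read(chrom="chr3", start=10, end=60))]
        noms = fusion.nominate_partners(pairs, models, anchor)
        assert [(n.partner_id, len(n.pairs)) for n in noms] == [("PART", 5), ("OTHER", 1)]

    def test_overlapping_genes_both_assigned_ambiguous(self, anchor, partner):
        overlap = GeneModel("OVL", "chr2", "-", ((700, 1000),))
        models = [anchor, partner, overlap]
        p = mk_pair("p", mk_read(start=1100, end=1150), mk_read(chrom="chr2", start=820, end=870))
        noms = fusion.nominate_partners([p], models, anchor)
        assert sorted(n.partner_id for n in noms) == ["OVL", "PART"]
        assert all(n.ambiguous for n in noms)

    def test_intergenic_mates_binned(self, anchor, partner):
        p = mk_pair("p", mk_read(start=1100, end=1150), mk_read(chrom="chr9", start=3_450_000, end=3_450_050))
        (nom,) = fusion.nominate_partners([p], [anchor, partner], anchor)
        assert nom.partner_id == "chr9:3400000-3500000" and nom.partner_model is None


class TestReadthrough:
    def models(self):
        a = GeneModel("A", "chr1", "+", ((1000, 2000),))
        b = GeneModel("B", "chr1", "+", ((3000, 4000),))  # adjacent, same strand
        c = GeneModel("C", "chr1", "-", ((5000, 6000),))  # adjacent, opposite strand
        d = GeneModel("D", "chr1", "+", ((8000, 9000),))  # same strand, B..C intervene
        return [a, b, c, d]

    def run(self, anchor_id, partner_id):
        models = self.models()
        by_id = {m.gene_id: m for m in models}
        nom = fusion.Nomination(partner_id, by_id[partner_id], pairs=[])
        return fusion.readthrough_filter([nom], models, by_id[anchor_id])

    def test_adjacent_same_strand_removed(self):
        assert self.run("A", "B") == []

    def test_adjacent_opposite_strand_retained(self):
        assert len(self.run("B", "C")) == 1

    def test_same_strand_with_intervening_gene_retained(self):
        assert len(self.run("A", "D")) == 1


class TestRescue:
    def setup_genes(self, seed=0, n_exons=10, exon_len=60):
        rng = np.random.default_rng(seed)
        tx = {}
        genes = {}
        pos = 0
        for gid in ("A", "B"):
            exons = tuple((pos + k * exon_len, pos + (k + 1) * exon_len) for k in range(n_exons))
            genes[gid] = GeneModel(gid, "chrS", "+", exons)
            tx[gid] = "".join(rng.choice(list("ACGT"), size=n_exons * exon_len))
            pos += n_exons * exon_len + 500
        return genes, tx

    def junction_read(self, tx, genes, i, j, L=50, left=25):
        e5 = genes["A"].exon_tx_bounds()[i - 1][1]
        s3 = genes["B"].exon_tx_bounds()[j - 1][0]
        return tx["A"][e5 - left : e5] + tx["B"][s3 : s3 + (L - left)]

    def test_exact_junction_read_hits(self):
        genes, tx = self.setup_genes()
        read = self.junction_read(tx, genes, 4, 2)
        (hit,) = fusion.rescue_chimeric_reads([("r", read)], genes["A"], genes["B"], tx)
        assert (hit.exon5_index, hit.exon3_index, hit.mismatches) == (4, 2, 0)

    def test_revcomp_read_hits(self):
        genes, tx = self.setup_genes()
        read = fusion.revcomp(self.junction_read(tx, genes, 4, 2))
        (hit,) = fusion.rescue_chimeric_reads([("r", read)], genes["A"], genes["B"], tx)
        assert (hit.exon5_index, hit.exon3_index) == (4, 2)

    def test_three_mismatches_rejected(self):
        genes, tx = self.setup_genes()
        read = list(self.junction_read(tx, genes, 4, 2))
        for k in (5, 20, 40):
            read[k] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[k]]
        hits = fusion.rescue_chimeric_reads([("r", "".join(read))], genes["A"], genes["B"], tx,
                                            max_mismatches=2, try_revcomp=False)
        assert hits == []

    def test_random_read_matches_brute_force(self):
        genes, tx = self.setup_genes(seed=5)
        rng = np.random.default_rng(17)
        read = "".join(rng.choice(list("ACGT"), size=75))

        def brute_force(read, max_mm=2):
            L = len(read)
            best = None
            for i in range(1, 11):
                e5 = genes["A"].exon_tx_bounds()[i - 1][1]
                left = tx["A"][max(0, e5 - (L - 1)) : e5]
                for j in range(1, 11):
                    s3 = genes["B"].exon_tx_bounds()[j - 1][0]
                    junc = left + tx["B"][s3 : s3 + (L - 1)]
                    mid = len(left)
                    for off in range(max(0, mid - L + 1), min(mid, len(junc) - L) + 1):
                        for variant in (read, fusion.revcomp(read)):
                            mm = sum(a != b for a, b in zip(variant, junc[off : off + L]))
                            if mm <= max_mm and (best is None or (mm, i, j) < best):
                                best = (mm, i, j)
            return best

        oracle = brute_force(read)
        hits = fusion.rescue_chimeric_reads([("r", read)], genes["A"], genes["B"], tx)
        got = None if not hits else (hits[0].mismatches, hits[0].exon5_index, hits[0].exon3_index)
        assert got == oracle == None  # a random 75-mer should hit nothing


class TestSupportInsert:
    def make_candidate(self, g5, g3, n_pairs, insert=250, chim=()):
        # place pairs so the predicted insert equals `insert`: the two reads
        # (50 nt each) sit (insert-100)/2 transcript nt away from the junction
        j5 = g5.exon_tx_bounds()[0][1]  # junction after exon 1
        gap = (insert - 100) // 2
        pairs = []
        for k in range(n_pairs):
            r1_end = g5.span[0] + j5 - gap
            r2_start = g3.span[0] + gap
            pairs.append(
                mk_pair(
                    f"p{k}",
                    mk_read(chrom=g5.chrom, start=r1_end - 50, end=r1_end),
                    mk_read(chrom=g3.chrom, start=r2_start, end=r2_start + 50),
                )
            )
        nom = fusion.Nomination(g3.gene_id, g3, pairs=pairs)
        return fusion.support_and_insert_filter(nom, g5, g3, chim, min_support=2)

    @pytest.fixture
    def g5(self):
        return GeneModel("F5", "chr1", "+", ((0, 300), (300, 600)))

    @pytest.fixture
    def g3(self):
        return GeneModel("F3", "chr2", "+", ((0, 300), (300, 600)))

    def test_single_pair_removed(self, g5, g3):
        assert self.make_candidate(g5, g3, 1) is None

    def test_median_insert_500_removed(self, g5, g3):
        assert self.make_candidate(g5, g3, 5, insert=500) is None

    def test_good_candidate_retained(self, g5, g3):
        cand = self.make_candidate(g5, g3, 5, insert=250)
        assert cand is not None
        assert cand.median_insert == pytest.approx(250)
        assert cand.junction == (1, 1)

    def test_chimeric_reads_pool_toward_support(self, g5, g3):
        chim = [ChimericHit("c0", 1, 1, 0)]
        cand = self.make_candidate(g5, g3, 1, chim=chim)
        assert cand is not None and cand.support == 2
        assert cand.junction == (1, 1)  # junction taken from the chimeric read


class TestFrame:
    def make_pair_of_genes(self, utr5=30, cds5_len=360, utr3=30):
        # gene5: exon1 = utr5 + cds5_len coding, junction after exon 1
        e1 = utr5 + cds5_len
        g5 = GeneModel("F5", "chr1", "+", ((0, e1), (e1, e1 + 200)),
                       cds=((utr5, e1), (e1, e1 + 100)))
        g3 = GeneModel("F3", "chr2", "+", ((0, 200), (200, 500)),
                       cds=((utr3, 200), (200, 470)))
        return g5, g3

    def candidate(self, junction):
        return FusionCandidate("F5", "F3", [1, 2], [], junction, 250.0)

    def test_in_frame(self):
        # 360 coding nt from gene5 (multiple of 3), gene3 joined at phase 0
        g5, _ = self.make_pair_of_genes(utr5=30, cds5_len=360)
        g3 = GeneModel("F3", "chr2", "+", ((0, 200), (200, 500)), cds=((200, 470),))
        assert fusion.predict_frame(self.candidate((1, 2)), g5, g3) == "in_frame"

    def test_out_of_frame(self):
        g5 = GeneModel("F5", "chr1", "+", ((0, 391), (391, 591)), cds=((30, 391),))  # 361 coding nt
        g3 = GeneModel("F3", "chr2", "+", ((0, 200), (200, 500)), cds=((200, 470),))
        assert fusion.predict_frame(self.candidate((1, 2)), g5, g3) == "out_of_frame"

    def test_junction_in_gene3_utr_unknown(self):
        g5 = GeneModel("F5", "chr1", "+", ((0, 390), (390, 590)), cds=((30, 390),))
        g3 = GeneModel("F3", "chr2", "+", ((0, 200), (200, 500)), cds=((350, 470),))
        cand = self.candidate((1, 1))  # junction at gene3 exon1 start: 5' UTR
        assert fusion.predict_frame(cand, g5, g3) == "unknown"
        assert "internal ATG" in cand.notes

    def test_missing_cds_unknown(self):
        g5 = GeneModel("F5", "chr1", "+", ((0, 390), (390, 590)))
        g3 = GeneModel("F3", "chr2", "+", ((0, 200), (200, 500)), cds=((30, 200),))
        assert fusion.predict_frame(self.candidate((1, 2)), g5, g3) == "unknown"
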