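import itertools
import math

import numpy as np
import pytest

from dupmodes.genome_io import Gene, GenomeAnnotation
from dupmodes.seq_divergence import (
    CODON_TO_AA,
    STOP_CODONS,
    CodonAlignment,
    codon_backtranslate,
    jukes_cantor,
    jukes_cantor_mu,
    nei_gojobori,
    promoter_duplicated,
    promoter_extract,
    promoter_identity,
    synonymous_sites,
)
from dupmodes.synthetic_data import (
    PlantedPair,
    SimulationConfig,
    simulate_sequences,
)
from dupmodes.dup_classifier import DuplicationMode


def _brute_pathway_counts(ca, cb):
    """Independent oracle: enumerate substitution orderings directly."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    totals = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return None
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


class TestBacktranslate:
    def test_gap_expands_to_codon_gap(self):
        aln = codon_backtranslate("M-K", "MAK", "ATGAAA", "ATGGCTAAA")
        assert aln.seq_a == "ATG---AAA"
        assert aln.seq_b == "ATGGCTAAA"

    def test_identical_cds_align_identically(self):
        aln = codon_backtranslate("MKF", "MKF", "ATGAAATTT", "ATGAAATTT")
        assert aln.seq_a == aln.seq_b == "ATGAAATTT"

    def test_trailing_stop_is_trimmed(self):
        aln = codon_backtranslate("MK", "MK", "ATGAAATAA", "ATGAAA")
        assert aln.seq_a == "ATGAAA"

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            codon_backtranslate("M*K", "MKK", "ATGTAAAAA", "ATGAAAAAA")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            codon_backtranslate("MK", "MK", "ATGAAAGG", "ATGAAA")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_backtranslation_reencodes_original_proteins(self, seed):
        rng = np.random.default_rng(seed)
        sense = sorted(CODON_TO_AA)
        codons_a = [sense[i] for i in rng.integers(0, len(sense), 20)]
        codons_b = [sense[i] for i in rng.integers(0, len(sense), 20)]
        prot_a = "".join(CODON_TO_AA[c] for c in codons_a)
        prot_b = "".join(CODON_TO_AA[c] for c in codons_b)
        aln = codon_backtranslate(prot_a, prot_b, "".join(codons_a), "".join(codons_b))
        assert aln.seq_a == "".join(codons_a)
        retranslated = "".join(
            CODON_TO_AA[aln.seq_a[i:i + 3]] for i in range(0, len(aln.seq_a), 3)
        )
        assert retranslated == prot_a


class TestNeiGojobori:
    def test_identical_sequences_have_zero_rates(self):
        res = nei_gojobori(CodonAlignment("ATGAAATTT", "ATGAAATTT"))
        assert res.ka == pytest.approx(0.0) and res.ks == pytest.approx(0.0)
        assert res.ka_valid and res.ks_valid

    def test_hand_counted_fourfold_case(self):
        # GGN is glycine for any N: S = 1 per codon, Sd = 1, pS = 1/3
        res = nei_gojobori(CodonAlignment("GGGGGGGGG", "GGAGGGGGG"))
        assert res.S == pytest.approx(3.0)
        assert res.Sd == pytest.approx(1.0)
        assert res.ka == pytest.approx(0.0, abs=1e-12)
        assert res.ks == pytest.approx(-0.75 * math.log(5 / 9), abs=1e-9)

    def test_two_difference_codons_match_pathway_oracle(self, rng):
        sense = sorted(CODON_TO_AA)
        checked = 0
        while checked < 60:
            ca = sense[rng.integers(0, len(sense))]
            pos = list(rng.choice(3, size=2, replace=False))
            cb = list(ca)
            for p in pos:
                choices = [n for n in "ACGT" if n != ca[p]]
                cb[p] = choices[rng.integers(0, 3)]
            cb = "".join(cb)
            if cb in STOP_CODONS or cb == ca:
                continue
            expected = _brute_pathway_counts(ca, cb)
            res = nei_gojobori(CodonAlignment(ca, cb))
            if expected is None:
                continue
            assert (res.Sd, res.Nd) == pytest.approx(expected, abs=1e-12)
            checked += 1

    def test_symmetry_and_codon_permutation_invariance(self, rng):
        a = "ATGAAATTTGGGCCC"
        b = "ATGAAGTTCGGACCA"
        r1 = nei_gojobori(CodonAlignment(a, b))
        r2 = nei_gojobori(CodonAlignment(b, a))
        assert (r1.ka, r1.ks) == pytest.approx((r2.ka, r2.ks), abs=1e-12)
        perm = rng.permutation(5)
        ap = "".join(a[3 * i:3 * i + 3] for i in perm)
        bp = "".join(b[3 * i:3 * i + 3] for i in perm)
        r3 = nei_gojobori(CodonAlignment(ap, bp))
        assert (r3.ka, r3.ks) == pytest.approx((r1.ka, r1.ks), abs=1e-12)

    def test_synonymous_only_simulation_gives_zero_ka(self):
        cfg = SimulationConfig(
            seed=8,
            n_codons=150,
            mode_p_syn={DuplicationMode.WGD: 0.3},
            mode_p_nonsyn={DuplicationMode.WGD: 0.0},
        )
        seqs = simulate_sequences(cfg, [PlantedPair("a", "b", DuplicationMode.WGD)])
        res = nei_gojobori(CodonAlignment(seqs.cds["a"], seqs.cds["b"]))
        assert res.ka == pytest.approx(0.0, abs=1e-12)
        assert res.ks > 0

    def test_gapped_and_stop_codons_are_skipped(self):
        aln = CodonAlignment("ATG---GGG", "ATGAAAGGA")
        res = nei_gojobori(aln)
        assert res.n_codons == 2  # the gap column pair is excluded

    def test_agrees_with_independent_ng86_implementation(self):
        # cross-check against Biopython's NG86, an implementation this
        # module shares no code with
        codonalign = pytest.importorskip("Bio.codonalign")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        cfg = SimulationConfig(seed=9, n_codons=120)
        seqs = simulate_sequences(cfg, [PlantedPair("a", "b", DuplicationMode.DISPERSED)])
        res = nei_gojobori(CodonAlignment(seqs.cds["a"], seqs.cds["b"]))
        dn, ds = cal_dn_ds(CodonSeq(seqs.cds["a"]), CodonSeq(seqs.cds["b"]), method="NG86")
        assert res.ka == pytest.approx(dn, abs=1e-9)
        assert res.ks == pytest.approx(ds, abs=1e-9)

    def test_synonymous_site_counts_sum_sensibly(self):
        # every codon contributes 3 sites split between S and N
        for codon in ("GGG", "ATG", "TGG", "CTT"):
            s = synonymous_sites(codon)
            assert 0.0 <= s <= 3.0
        assert synonymous_sites("ATG") == pytest.approx(0.0)  # Met: no synonyms
        assert synonymous_sites("GGG") == pytest.approx(1.0)


class TestJukesCantor:
    def test_closed_form_values(self):
        assert jukes_cantor(0.0) == pytest.approx(0.0)
        assert jukes_cantor(0.1) == pytest.approx(0.10732, abs=1e-5)

    def test_domain_boundary(self):
        with pytest.raises(ValueError):
            jukes_cantor(0.75)

    def test_mu_identical_and_invalid(self):
        assert jukes_cantor_mu("ACGT", "ACGT").mu == pytest.approx(0.0)
        res = jukes_cantor_mu("AAAA", "CCCC")
        assert not res.valid and res.mu is None

    def test_mu_ignores_gap_columns(self):
        res = jukes_cantor_mu("AC-GT", "ACCGA")
        assert res.n_sites == 4 and res.p == pytest.approx(0.25)

    def test_mu_zero_ungapped_columns_is_error(self):
        with pytest.raises(ValueError):
            jukes_cantor_mu("----", "ACGT")

    def test_monotone_in_p(self):
        ps = np.linspace(0, 0.74, 50)
        mus = [jukes_cantor(p) for p in ps]
        assert all(b > a for a, b in zip(mus, mus[1:]))

    def test_estimator_recovery_on_simulated_promoters(self):
        # 100 replicate promoter pairs mutated at p = 0.1 per site
        expected = -0.75 * math.log(1 - 0.4 / 3)
        mus = []
        for seed in range(100):
            cfg = SimulationConfig(seed=seed, promoter_length=1000, promoter_p=0.1)
            seqs = simulate_sequences(cfg, [PlantedPair("a", "b", DuplicationMode.WGD)])
            mus.append(jukes_cantor_mu(seqs.promoter["a"], seqs.promoter["b"]).mu)
        mus = np.array(mus)
        se = mus.std(ddof=1) / math.sqrt(len(mus))
        assert abs(mus.mean() - expected) < 3 * se


class TestPromoters:
    @pytest.fixture
    def genome(self):
        ann = GenomeAnnotation(
            [
                Gene("up", "chr1", 100, 400, "+", 1),
                Gene("target", "chr1", 1001, 1600, "+", 2),
                Gene("minus", "chr1", 2001, 2600, "-", 2),
                Gene("next", "chr1", 3001, 3600, "+", 1),
                Gene("lonely", "chr2", 5000, 5600, "+", 1),
                Gene("edge", "chr3", 500, 900, "+", 1),
            ],
            {"chr1": 4000, "chr2": 10_000, "chr3": 1000},
        )
        rng = np.random.default_rng(0)
        seqs = {
            c: "".join("ACGT"[i] for i in rng.integers(0, 4, n))
            for c, n in (("chr1", 4000), ("chr2", 10_000), ("chr3", 1000))
        }
        return ann, seqs

    def test_truncated_by_upstream_gene(self, genome):
        ann, seqs = genome
        prom = promoter_extract("target", ann, seqs)
        assert len(prom) == 600  # gene "up" ends 600 bp before the TSS
        assert prom == seqs["chr1"][400:1000]

    def test_full_kilobase_when_unobstructed(self, genome):
        ann, seqs = genome
        prom = promoter_extract("lonely", ann, seqs)
        assert len(prom) == 1000
        assert prom == seqs["chr2"][3999:4999]

    def test_minus_strand_is_downstream_revcomp(self, genome):
        ann, seqs = genome
        prom = promoter_extract("minus", ann, seqs)
        # region 2601..3000 (next gene starts at 3001), reverse-complemented
        raw = seqs["chr1"][2600:3000]
        comp = raw.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert prom == comp

    def test_chromosome_edge_clips(self, genome):
        ann, seqs = genome
        prom = promoter_extract("edge", ann, seqs)
        assert len(prom) == 499
        assert prom == seqs["chr3"][:499]


class TestPromoterIdentity:
    def test_identical_promoters_duplicated(self):
        dup, ident = promoter_duplicated("ACGTACGT", "ACGTACGT")
        assert dup and ident == pytest.approx(1.0)

    def test_disjoint_alphabets_not_duplicated(self):
        dup, ident = promoter_duplicated("A" * 30, "C" * 30)
        assert not dup and ident == pytest.approx(0.0)

    def test_boundary_is_strict(self):
        # 9 matches in 20 aligned columns: exactly 45% -> NOT duplicated
        a = "A" * 9 + "C" * 11
        b = "A" * 9 + "G" * 11
        assert promoter_identity(a, b, aligned=True) == pytest.approx(0.45)
        dup, _ = promoter_duplicated(a, b, aligned=True)
        assert not dup
        # one more match tips it over
        a2 = "A" * 10 + "C" * 10
        b2 = "A" * 10 + "G" * 10
        assert promoter_identity(a2, b2, aligned=True) == pytest.approx(0.5)
        dup2, _ = promoter_duplicated(a2, b2, aligned=True)
        assert dup2

    def test_gap_columns_count_in_denominator(self):
        # global alignment of ACGT vs ACG: 3 matches over 4 columns
        ident = promoter_identity("ACGT", "ACG")
        assert ident == pytest.approx(0.75)

    def test_empty_promoter_is_undetermined(self):
        assert promoter_duplicated("", "ACGT") is None
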