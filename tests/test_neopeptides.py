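"""Transcript reconstruction, translation, digestion, novelty, binding."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicetope import neopeptides as np_
from splicetope import splice_events as se
from splicetope import synthetic_data as syn

from conftest import CODON_ORACLE, oracle_translate


class TestSelectProductive:
    def _events(self):
        return pd.DataFrame(
            [
                {"event_id": "SE:1", "event_type": "SE", "delta_psi": -0.3},
                {"event_id": "SE:2", "event_type": "SE", "delta_psi": +0.3},
                {"event_id": "RI:1", "event_type": "RI", "delta_psi": +0.2},
                {"event_id": "RI:2", "event_type": "RI", "delta_psi": -0.2},
                {"event_id": "MXE:1", "event_type": "MXE", "delta_psi": -0.5},
            ]
        )

    def test_only_se_exclusion_and_ri_inclusion_selected(self):
        out = np_.select_productive_events(self._events())
        assert set(out["event_id"]) == {"SE:1", "RI:1"}
        variants = dict(zip(out["event_id"], out["variant"]))
        assert variants == {"SE:1": "SE_exclusion", "RI:1": "RI_inclusion"}


def _simple_gene(exon_lens, intron_lens, strand="+", utr=12, seed=0):
    """Hand-built single-gene genome with the CDS spanning all exons."""
    rng = np.random.default_rng(seed)
    total_cds = sum(exon_lens)
    assert total_cds % 3 == 0
    n_aa = total_cds // 3 - 1
    protein = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVWY"), size=n_aa - 1))
    cds = syn._backtranslate(protein, rng) + "TAA"
    chunks, pos = [], 0
    for L in exon_lens:
        chunks.append(cds[pos:pos + L])
        pos += L
    utr5 = syn._random_dna(utr, rng)
    utr3 = syn._random_dna(utr, rng)
    exon_seqs = [utr5 + chunks[0]] + chunks[1:-1] + [chunks[-1] + utr3]
    introns = [syn._random_dna(L, rng) for L in intron_lens]
    local, cursor, local_exons = [], 0, []
    for i, es in enumerate(exon_seqs):
        local_exons.append((cursor, cursor + len(es)))
        local.append(es)
        cursor += len(es)
        if i < len(introns):
            local.append(introns[i])
            cursor += len(introns[i])
    gene_local = "".join(local)
    L = len(gene_local)
    off = 25
    from splicetope._seq import revcomp

    chrom = syn._random_dna(off, rng) + (
        gene_local if strand == "+" else revcomp(gene_local)
    ) + syn._random_dna(25, rng)
    if strand == "+":
        exons = [(off + s, off + e) for s, e in local_exons]
        cds_iv = [
            (off + s + (utr if i == 0 else 0), off + e - (utr if i == len(exon_seqs) - 1 else 0))
            for i, (s, e) in enumerate(local_exons)
        ]
    else:
        exons = [(off + L - e, off + L - s) for s, e in local_exons]
        cds_iv = [
            (off + L - e + (utr if i == len(exon_seqs) - 1 else 0),
             off + L - s - (utr if i == 0 else 0))
            for i, (s, e) in enumerate(local_exons)
        ]
    model = np_.GeneModel("g1", "g1.t1", "c", strand, exons, cds_iv)
    return {"c": chrom}, model, protein


class TestReconstruct:
    def test_in_frame_se_exclusion_deletes_contiguous_residues(self):
        genome, model, protein = _simple_gene([90, 60, 90], [70, 70])
        exon = sorted(model.exons)[1]
        ev = {"event_type": "SE", "strand": model.strand,
              "exonStart_0base": exon[0], "exonEnd": exon[1],
              "event_id": "SE:0"}
        alt = np_.reconstruct_transcript(ev, model, genome)
        canonical = model.protein(genome)
        assert not alt.frameshifted and not alt.premature_stop
        assert len(alt.protein) == len(canonical) - 20
        assert alt.protein == canonical[:30] + canonical[50:]

    def test_61nt_exon_exclusion_causes_frameshift(self):
        genome, model, _ = _simple_gene([90, 61, 89], [70, 70])
        exon = sorted(model.exons)[1]
        ev = {"event_type": "SE", "strand": model.strand,
              "exonStart_0base": exon[0], "exonEnd": exon[1], "event_id": "SE:0"}
        alt = np_.reconstruct_transcript(ev, model, genome)
        assert alt.frameshifted

    def test_ri_inclusion_inserts_intron_base_by_base(self):
        genome, model, _ = _simple_gene([90, 60, 90], [72, 70])
        intron = model.introns()[0]
        up, down = sorted(model.exons)[0], sorted(model.exons)[1]
        ev = {"event_type": "RI", "strand": "+",
              "upstreamES": up[0], "upstreamEE": up[1],
              "downstreamES": down[0], "downstreamEE": down[1],
              "riExonStart_0base": up[0], "riExonEnd": down[1], "event_id": "RI:0"}
        alt = np_.reconstruct_transcript(ev, model, genome)
        chrom = genome["c"]
        expected = (
            chrom[up[0]:up[1]] + chrom[intron[0]:intron[1]] + chrom[down[0]:down[1]]
            + chrom[sorted(model.exons)[2][0]:sorted(model.exons)[2][1]]
        )
        assert alt.sequence == expected
        assert not alt.frameshifted  # 72 nt intron, in frame

    def test_unannotated_exon_is_reconciliation_error(self):
        genome, model, _ = _simple_gene([90, 60, 90], [70, 70])
        ev = {"event_type": "SE", "strand": "+", "exonStart_0base": 1,
              "exonEnd": 50, "event_id": "SE:x"}
        with pytest.raises(np_.ReconciliationError):
            np_.reconstruct_transcript(ev, model, genome)

    def test_translating_unaltered_chain_reproduces_canonical(self, study):
        # regression guard for coordinate arithmetic
        for gid, m in study.models.items():
            cds_seq = m.cds_seq(study.genome)
            assert np_.translate_cds(cds_seq) == study.proteome[gid]


class TestTranslate:
    def test_minimal_example(self):
        assert np_.translate_cds("ATGAAATAG") == "MK"

    def test_random_cds_agree_with_codon_oracle(self, rng):
        codons = [c for c, aa in CODON_ORACLE.items() if aa != "*"]
        for _ in range(100):
            n = int(rng.integers(5, 60))
            seq = "ATG" + "".join(rng.choice(codons, size=n)) + "TAA"
            assert np_.translate_cds(seq) == oracle_translate(seq)

    def test_ri_in_utr_leaves_protein_unchanged(self):
        genome, model, _ = _simple_gene([90, 60, 90], [70, 70])
        # an intron wholly 3' of the stop codon cannot alter the product:
        # simulate by checking premature flag logic on the in-frame case
        intron = model.introns()[1]
        up, down = sorted(model.exons)[1], sorted(model.exons)[2]
        ev = {"event_type": "RI", "strand": "+",
              "upstreamES": up[0], "upstreamEE": up[1],
              "downstreamES": down[0], "downstreamEE": down[1],
              "riExonStart_0base": up[0], "riExonEnd": down[1], "event_id": "RI:0"}
        alt = np_.reconstruct_transcript(ev, model, genome)
        assert alt.start_tx is not None
        assert np_.translate_canonical(alt) == alt.protein


class TestDigest:
    def test_closed_form_count_for_distinct_residues(self):
        protein = "ACDEFGHIKLMNPQRSTVWY"  # 20 distinct residues
        peps = np_.digest_kmers(protein)
        assert len(peps) == sum(len(protein) - k + 1 for k in range(8, 15))

    def test_homopolymer_deduplicates_to_one(self):
        assert np_.digest_kmers("AAAAAAAA") == {"AAAAAAAA"}

    def test_below_minimum_length_is_empty(self):
        assert np_.digest_kmers("ACDEFGH") == set()

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=0, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_digest_is_idempotent_and_order_invariant(self, protein):
        peps = np_.digest_kmers(protein)
        assert all(8 <= len(p) <= 14 for p in peps)
        assert all(p in protein for p in peps)
        assert np_.digest_kmers(protein) == peps


class TestNovelty:
    def test_canonical_substring_is_not_novel(self, study):
        frag = study.proteome["gene1"][5:15]
        (cand,) = np_.novelty_filter([frag], study.proteome)
        assert cand.novel is False

    def test_planted_junction_peptides_are_novel(self, study):
        cands = np_.novelty_filter(study.planted_peptides, study.proteome)
        assert all(c.novel for c in cands)

    def test_equals_naive_all_pairs_scan(self, rng, study):
        peps = list(np_.digest_kmers(study.proteome["gene2"], 9, 9))[:50]
        peps += ["W" * 9, "ACDEFGHIK"]
        cands = np_.novelty_filter(peps, study.proteome)
        for c in cands:
            naive = not any(c.peptide in p for p in study.proteome.values())
            assert c.novel == naive


class TestBinding:
    def test_toy_scorer_background_median_ranks_near_fifty(self, study):
        cand = pd.DataFrame({"peptide": ["ACDEFGHIK"]})
        out = np_.predict_binding(cand, backend="toy", proteome=study.proteome, seed=1)
        bg_scores = sorted(
            np_.toy_score(p)
            for p in np_._sample_background(study.proteome, 1000, 9,
                                            np.random.default_rng(1))
        )
        med = bg_scores[500]
        # a peptide scoring exactly at the background median ranks mid-pack
        s = np_.toy_score("ACDEFGHIK")
        frac_above = np.mean([b > s for b in bg_scores])
        assert out["percent_rank"].iloc[0] == pytest.approx(
            100 * (1 + frac_above * 1000) / 1001
        )

    def test_anchor_matched_9mer_is_strong_binder(self, study):
        cand = pd.DataFrame({"peptide": ["ALDEFGHIV"]})  # L at P2, V at P9
        out = np_.predict_binding(cand, backend="toy", proteome=study.proteome, seed=2)
        assert out["binder_class"].iloc[0] == "strong"

    def test_netmhcpan_parser_round_trip(self, tmp_path):
        table = tmp_path / "netmhcpan.txt"
        table.write_text(
            "# NetMHCpan version 4.1\n"
            "---------------------------\n"
            "Pos MHC Peptide Score %Rank\n"
            "1 HLA-A*02:01 ALDEFGHIV 0.91 0.21\n"
            "2 HLA-A*02:01 ACDEFGHIK 0.05 41.2\n"
        )
        cand = pd.DataFrame({"peptide": ["ALDEFGHIV", "ACDEFGHIK"]})
        out = np_.predict_binding(cand, backend="netmhcpan", netmhcpan_table=table)
        assert list(out["percent_rank"]) == [0.21, 41.2]
        assert list(out["binder_class"]) == ["strong", "non-binder"]

    def test_malformed_backend_output_names_the_line(self, tmp_path):
        table = tmp_path / "bad.txt"
        table.write_text("Pos MHC Peptide Score %Rank\n1 HLA-A*02:01\n")
        with pytest.raises(ValueError, match="line 2"):
            np_.parse_netmhcpan(table)


class TestLogo:
    def test_identical_peptides_reach_maximal_information(self):
        freq, ic = np_.peptide_logo_matrix(["ALDEFGHIV"] * 25)
        assert np.allclose(ic, np.log2(20))
        assert np.allclose(freq.sum(axis=1), 1.0)

    def test_uniform_random_residues_have_vanishing_information(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        peps = ["".join(rng.choice(aas, size=9)) for _ in range(100_000)]
        _, ic = np_.peptide_logo_matrix(peps)
        assert (ic < 0.1).all()

    def test_mixed_lengths_are_rejected(self):
        with pytest.raises(ValueError):
            np_.peptide_logo_matrix(["ALDEFGHIV", "ALDEFGHI"])


class TestEndToEnd:
    def test_candidates_contain_planted_and_no_canonical_substrings(
        self, study, study_events
    ):
        sig = se.classify_direction(se.filter_significant(study_events))
        cands = np_.find_neopeptide_candidates(
            sig, study.models, study.genome, study.proteome
        )
        assert set(study.planted_peptides) <= set(cands["peptide"])
        joined = "|".join(study.proteome.values())
        assert not any(p in joined for p in cands["peptide"])

    def test_mirrored_genome_leaves_peptide_set_unchanged(self, study, study_events):
        sig = se.classify_direction(se.filter_significant(study_events))
        cands = np_.find_neopeptide_candidates(
            sig, study.models, study.genome, study.proteome
        )
        mirrored, mmodels = syn.mirror_genome(study.genome, study.models)
        lengths = {c: len(s) for c, s in study.genome.chrom_sequences.items()}
        msig = syn.mirror_events(sig, lengths)
        mcands = np_.find_neopeptide_candidates(
            msig, mmodels, mirrored, syn.proteome_from_models(mirrored, mmodels)
        )
        assert set(mcands["peptide"]) == set(cands["peptide"])
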