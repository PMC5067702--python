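import numpy as np
import pandas as pd
import pytest

from ncontext.annotation import AnnotationSet, GenomicFeature
from ncontext.context import (
    AlignmentScoring,
    assign_parental_genes,
    filter_de_targets,
    find_antisense_targets,
    find_lincrna_neighbors,
    local_align,
    read_blast_tab,
)
from ncontext.synthetic import SimulationConfig, generate_annotation, generate_sequences


def sw_affine_reference(q, s, match=2.0, mismatch=-3.0, gap_open=5.0, gap_ext=2.0):
    """Independent Smith–Waterman with affine gaps (Gotoh three-state DP).

    A gap of length k costs gap_open + k*gap_ext, matching the package's
    scoring convention.  Returns the best local score.
    """
    n, m = len(q), len(s)
    NEG = -1e9
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in q (horizontal)
    F = np.full((n + 1, m + 1), NEG)  # gap in s (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if q[i - 1] == s[j - 1] else mismatch
            E[i][j] = max(H[i][j - 1] - gap_open - gap_ext, E[i][j - 1] - gap_ext)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_ext, F[i - 1][j] - gap_ext)
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def brute_force_neighbors(features, linc_ids, deg_ids, window):
    """All-pairs scan with the boundary-gap convention."""
    by_id = {f.feature_id: f for f in features}
    out = set()
    for lid in linc_ids:
        linc = by_id[lid]
        for tid in deg_ids:
            t = by_id[tid]
            if t.chrom != linc.chrom or t.biotype != "protein_coding":
                continue
            if t.end < linc.start:
                gap = linc.start - t.end
            elif t.start > linc.end:
                gap = t.start - linc.end
            else:
                gap = 0
            if gap <= window:
                out.add((lid, tid, gap))
    return out


def _feat(fid, chrom, start, end, strand="+", biotype="protein_coding"):
    return GenomicFeature(fid, fid, chrom, start, end, strand, biotype)


class TestLincrnaNeighbors:
    def _ann(self, *feats):
        return AnnotationSet(feats)

    def test_published_worked_example_distance(self):
        # lincRNA chr1:1,000,000-1,010,000; coding DEG at a 274,577 bp gap
        ann = self._ann(
            _feat("L", "1", 1_000_000, 1_010_000, biotype="lincRNA"),
            _feat("T", "1", 1_284_577, 1_290_000),
        )
        out = find_lincrna_neighbors(ann, ["L"], ["T"], 3_000_000)
        assert len(out) == 1
        a = out[0]
        assert (a.distance, a.side, a.mb_bin) == (274577, "right", "<=1MB")

    def test_overlapping_target_distance_zero(self):
        ann = self._ann(
            _feat("L", "1", 1000, 5000, biotype="lincRNA"),
            _feat("T", "1", 4000, 9000),
        )
        out = find_lincrna_neighbors(ann, ["L"], ["T"], 3_000_000)
        assert out[0].distance == 0
        assert out[0].side == "overlap"

    def test_window_boundary_inclusive(self):
        # IN at exactly 3,000,000 gap; OUT at 3,000,001
        ann2 = self._ann(
            _feat("L", "1", 5_000_000, 5_001_000, biotype="lincRNA"),
            _feat("IN", "1", 5_001_000 + 3_000_000, 5_001_000 + 3_000_000 + 10),
            _feat("OUT", "1", 1, 5_000_000 - 3_000_001),
        )
        out = find_lincrna_neighbors(ann2, ["L"], ["IN", "OUT"], 3_000_000)
        assert [a.target_id for a in out] == ["IN"]

    def test_sorted_closest_first_with_mb_bins(self):
        ann = self._ann(
            _feat("L", "1", 10_000_000, 10_010_000, biotype="lincRNA"),
            _feat("FAR", "1", 12_510_000, 12_520_000),
            _feat("NEAR", "1", 10_020_000, 10_030_000),
        )
        out = find_lincrna_neighbors(ann, ["L"], ["FAR", "NEAR"], 3_000_000)
        assert [a.target_id for a in out] == ["NEAR", "FAR"]
        assert [a.mb_bin for a in out] == ["<=1MB", "<=3MB"]

    def test_non_deg_and_non_coding_excluded(self):
        ann = self._ann(
            _feat("L", "1", 1000, 2000, biotype="lincRNA"),
            _feat("T", "1", 3000, 4000),
            _feat("P", "1", 5000, 6000, biotype="pseudogene"),
        )
        out = find_lincrna_neighbors(ann, ["L"], ["P"], 3_000_000)
        assert out == []

    def test_invalid_window_errors(self):
        with pytest.raises(ValueError):
            find_lincrna_neighbors(AnnotationSet(), [], [], 0)

    def test_start_to_start_mode(self):
        ann = self._ann(
            _feat("L", "1", 1_000_000, 1_010_000, biotype="lincRNA"),
            _feat("T", "1", 1_300_000, 1_310_000),
        )
        out = find_lincrna_neighbors(
            ann, ["L"], ["T"], 3_000_000, distance_mode="start_to_start"
        )
        assert out[0].distance == 300_000

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            feats = []
            for i in range(200):
                start = int(rng.integers(1, 20_000_000))
                end = start + int(rng.integers(100, 50_000))
                feats.append(
                    _feat(
                        f"G{i}", f"chr{int(rng.integers(1, 4))}", start, end,
                        biotype="protein_coding" if i >= 20 else "lincRNA",
                    )
                )
            ann = AnnotationSet(feats)
            linc_ids = [f"G{i}" for i in range(20)]
            deg_ids = [f"G{i}" for i in range(20, 200) if rng.random() < 0.5]
            window = int(rng.integers(100_000, 4_000_000))
            got = {
                (a.ncrna_id, a.target_id, a.distance)
                for a in find_lincrna_neighbors(ann, linc_ids, deg_ids, window)
            }
            assert got == brute_force_neighbors(feats, linc_ids, deg_ids, window)


class TestAntisenseTargets:
    def test_opposite_strand_overlap_worked_example(self):
        ann = AnnotationSet(
            [
                _feat("A", "2", 100, 500, strand="-", biotype="antisense"),
                _feat("G", "2", 300, 900, strand="+"),
            ]
        )
        out = find_antisense_targets(ann, ["A"], ["G"])
        assert len(out) == 1
        assert out[0].overlap_bp == 201  # [300,500] inclusive

    def test_same_strand_no_association(self):
        ann = AnnotationSet(
            [
                _feat("A", "2", 100, 500, strand="+", biotype="antisense"),
                _feat("G", "2", 300, 900, strand="+"),
            ]
        )
        assert find_antisense_targets(ann, ["A"], ["G"]) == []

    def test_different_chromosome_no_association(self):
        ann = AnnotationSet(
            [
                _feat("A", "2", 100, 500, strand="-", biotype="antisense"),
                _feat("G", "3", 100, 500, strand="+"),
            ]
        )
        assert find_antisense_targets(ann, ["A"], ["G"]) == []

    def test_min_overlap_threshold(self):
        ann = AnnotationSet(
            [
                _feat("A", "2", 100, 500, strand="-", biotype="antisense"),
                _feat("G", "2", 500, 900, strand="+"),
            ]
        )
        assert len(find_antisense_targets(ann, ["A"], ["G"], min_overlap=1)) == 1
        assert find_antisense_targets(ann, ["A"], ["G"], min_overlap=2) == []

    def test_matches_brute_force_and_translation_invariant(self, rng):
        for _ in range(100):
            feats = []
            for i in range(60):
                start = int(rng.integers(1, 100_000))
                end = start + int(rng.integers(100, 5_000))
                feats.append(
                    _feat(
                        f"F{i}", f"chr{int(rng.integers(1, 3))}", start, end,
                        strand="+" if rng.random() < 0.5 else "-",
                        biotype="antisense" if i < 15 else "protein_coding",
                    )
                )
            as_ids = [f"F{i}" for i in range(15)]
            coding_ids = [f"F{i}" for i in range(15, 60)]
            by_id = {f.feature_id: f for f in feats}
            expected = set()
            for a in as_ids:
                fa = by_id[a]
                for c in coding_ids:
                    fc = by_id[c]
                    if (
                        fa.chrom == fc.chrom
                        and fa.strand != fc.strand
                        and min(fa.end, fc.end) - max(fa.start, fc.start) + 1 >= 1
                    ):
                        expected.add((a, c))
            got = {
                (x.ncrna_id, x.target_id)
                for x in find_antisense_targets(AnnotationSet(feats), as_ids, coding_ids)
            }
            assert got == expected
            # chromosome-wide translation leaves overlaps unchanged
            shift = int(rng.integers(1, 10_000))
            shifted = AnnotationSet(
                GenomicFeature(
                    f.feature_id, f.gene_name, f.chrom,
                    f.start + shift, f.end + shift, f.strand, f.biotype,
                )
                for f in feats
            )
            got2 = {
                (x.ncrna_id, x.target_id)
                for x in find_antisense_targets(shifted, as_ids, coding_ids)
            }
            assert got2 == got


class TestLocalAlign:
    def test_perfect_match_score_identity(self):
        hit = local_align("ACGT", "ACGT")
        assert (hit.score, hit.identity, hit.length) == (8.0, 1.0, 4)

    def test_best_local_block_trims_mismatch(self):
        hit = local_align("ACGT", "ACGA")
        assert hit.score == 6.0  # "ACG" block, 3 matches x 2

    def test_no_similarity_returns_none(self):
        assert local_align("AAAA", "TTTT") is None

    def test_self_score_is_match_times_length(self, rng):
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 40))))
            hit = local_align(seq, seq)
            assert hit.score == 2.0 * len(seq)
            assert hit.identity == 1.0

    def test_symmetric_in_query_and_subject(self, rng):
        for _ in range(30):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 30))))
            ha, hb = local_align(a, b), local_align(b, a)
            assert (ha is None) == (hb is None)
            if ha is not None:
                assert ha.score == hb.score

    def test_invalid_symbol_errors(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            local_align("ACGU", "ACGT")

    def test_matches_independent_dp_on_random_pairs(self, rng):
        for _ in range(150):
            a = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 25))))
            b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 25))))
            expected = sw_affine_reference(a, b)
            hit = local_align(a, b)
            got = 0.0 if hit is None else hit.score
            assert got == expected


class TestReadBlastTab:
    LINE = "PSG1\tGENE7\t95.00\t480\t20\t2\t1\t480\t5\t484\t1e-100\t350.1\n"

    def test_identity_converted_to_fraction(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.LINE)
        hits = read_blast_tab(p)
        assert hits[0].identity == pytest.approx(0.95)
        assert hits[0].score == pytest.approx(350.1)
        assert hits[0].length == 480

    def test_empty_file_empty_list(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert read_blast_tab(p) == []

    def test_wrong_column_count_reports_line(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(self.LINE + "\t".join(["x"] * 11) + "\n")
        with pytest.raises(ValueError, match=":2:"):
            read_blast_tab(p)


class TestAssignParentalGenes:
    def _mutated_copy(self, rng, seq, rate):
        out = []
        for ch in seq:
            if rng.random() < rate:
                out.append(rng.choice([b for b in "ACGT" if b != ch]))
            else:
                out.append(ch)
        return "".join(out)

    def test_mutated_copy_assigned_to_true_parent(self, rng):
        coding = {
            f"C{i}": "".join(rng.choice(list("ACGT"), size=400)) for i in range(10)
        }
        pseudo = {"P1": self._mutated_copy(rng, coding["C3"], 0.05)}
        res = assign_parental_genes(pseudo_seqs=pseudo, coding_seqs=coding)
        assert [a.target_id for a in res.associations] == ["C3"]
        assert res.associations[0].identity > 0.9

    def test_identical_parents_force_ambiguity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=300))
        coding = {"A": seq, "B": seq}
        pseudo = {"P1": seq}
        res = assign_parental_genes(pseudo_seqs=pseudo, coding_seqs=coding)
        assert res.associations == []
        assert res.ambiguous == ["P1"]
        first = assign_parental_genes(
            pseudo_seqs=pseudo, coding_seqs=coding, tie_policy="first"
        )
        assert [a.target_id for a in first.associations] == ["A"]

    def test_random_sequence_unassigned(self, rng):
        coding = {
            f"C{i}": "".join(rng.choice(list("ACGT"), size=300)) for i in range(5)
        }
        pseudo = {"P1": "".join(rng.choice(list("ACGT"), size=300))}
        res = assign_parental_genes(pseudo_seqs=pseudo, coding_seqs=coding)
        assert res.associations == []
        assert res.unassigned == ["P1"]

    def test_hit_list_route_equivalent_to_ranking(self):
        from ncontext.context import AlignmentHit

        hits = [
            AlignmentHit("P1", "A", 100.0, 0.9, 200),
            AlignmentHit("P1", "B", 90.0, 0.95, 200),
            AlignmentHit("P2", "A", 30.0, 0.9, 40),  # below min_score
        ]
        res = assign_parental_genes(hits=hits)
        assert [(a.ncrna_id, a.target_id) for a in res.associations] == [("P1", "A")]
        assert res.unassigned == ["P2"]

    def test_planted_parent_recovery_mutation_010_with_20_distractors(self):
        cfg = SimulationConfig(
            n_coding=28,  # 8 parents + 20 distractors
            n_lincrna=0,
            n_antisense=0,
            n_pseudogene=8,
            pseudogene_mutation_rate=0.10,
            pseudogene_indel_rate=0.01,
            seed=17,
        )
        ann, truth = generate_annotation(cfg)
        seqs = generate_sequences(ann, truth, cfg)
        coding = {
            f.feature_id: seqs[f.feature_id]
            for f in ann
            if f.biotype == "protein_coding"
        }
        pseudo = {p: seqs[p] for p in truth.planted_parents}
        res = assign_parental_genes(pseudo_seqs=pseudo, coding_seqs=coding)
        correct = sum(
            1
            for a in res.associations
            if truth.planted_parents[a.ncrna_id] == a.target_id
        )
        assert correct / len(pseudo) >= 0.95


class TestFilterDeTargets:
    def _deg(self):
        return pd.DataFrame(
            {
                "feature": ["T1", "T1", "T2"],
                "tissue": ["SN", "SN", "DRG"],
                "interval": ["I2", "I3", "I1"],
                "de": [True, False, False],
            }
        )

    def test_de_target_annotated_and_retained(self):
        from ncontext.context import TargetAssociation

        assoc = TargetAssociation("L1", "T1", "neighbor", distance=10)
        out = filter_de_targets([assoc], self._deg())
        assert len(out) == 1
        assert out[0].target_de is True
        assert out[0].de_evidence == (("SN", "I2"),)

    def test_never_de_target_dropped_unless_keep_all(self):
        from ncontext.context import TargetAssociation

        assoc = TargetAssociation("L1", "T2", "neighbor", distance=10)
        assert filter_de_targets([assoc], self._deg()) == []
        kept = filter_de_targets([assoc], self._deg(), keep_all=True)
        assert kept[0].target_de is False

    def test_empty_input_empty_output(self):
        assert filter_de_targets([], self._deg()) == []
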