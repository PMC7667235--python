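import numpy as np
import pytest
from Bio.Seq import Seq

from c4origins import supermatrix as sm
from c4origins import synthetic as syn
from c4origins.io_formats import Alignment, Orthogroup


def brute_force_longest_orf(seq: str, require_start: bool = True):
    """Independent 6-frame exhaustive ORF scan used as oracle: enumerate all
    (start, stop) codon-aligned windows per frame and strand, keep the
    longest valid coding stretch."""
    stops = {"TAA", "TAG", "TGA"}
    best = None
    rc = str(Seq(seq).reverse_complement())
    for s in (seq, rc):
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, len(s) - 2, 3)]
            n = len(codons)
            boundaries = [-1] + [i for i, c in enumerate(codons) if c in stops]
            for b in boundaries:
                stop_next = next((i for i in range(b + 1, n) if codons[i] in stops), n)
                if require_start:
                    start = next(
                        (i for i in range(b + 1, stop_next) if codons[i] == "ATG"), None
                    )
                else:
                    start = b + 1 if b + 1 < stop_next else None
                if start is None:
                    continue
                coding = codons[start:stop_next]
                if not coding:
                    continue
                protein = str(Seq("".join(coding)).translate())
                if best is None or len(protein) > len(best):
                    best = protein
    return best


class TestLongestOrf:
    def test_constructed_example(self):
        r = sm.longest_orf("TTTATGAAATAAGG")
        assert r.protein == "MK"
        assert r.cds == "ATGAAATAA"
        assert (r.strand, r.start, r.end) == ("+", 3, 12)

    def test_strand_symmetry(self):
        fwd = sm.longest_orf("TTTATGAAATAAGG")
        rev = sm.longest_orf(str(Seq("TTTATGAAATAAGG").reverse_complement()))
        assert rev.protein == fwd.protein
        assert rev.strand == "-"

    def test_picks_longer_orf(self):
        short = "ATG" + "GCT" * 9 + "TAA"  # 10 aa
        long = "ATG" + "GCT" * 24 + "TAA"  # 25 aa
        seq = short + "CC" + long
        assert len(sm.longest_orf(seq).protein) == 25

    def test_no_orf_errors(self):
        with pytest.raises(ValueError):
            sm.longest_orf("CCC", require_start=True)

    def test_agrees_with_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(12)
        checked = 0
        for _ in range(1000):
            n = int(rng.integers(30, 601))
            seq = "".join("ACGT"[i] for i in rng.integers(4, size=n))
            oracle = brute_force_longest_orf(seq)
            if oracle is None:
                with pytest.raises(ValueError):
                    sm.longest_orf(seq)
                continue
            got = sm.longest_orf(seq)
            assert len(got.protein) == len(oracle)
            checked += 1
        assert checked > 900

    def test_stop_to_stop_mode(self):
        seq = "TTTAAACCCGGG"  # no ATG anywhere
        r = sm.longest_orf(seq, require_start=False)
        assert len(r.protein) >= 3


class TestAlignedOverlap:
    def test_disjoint(self):
        a = "A" * 50 + "-" * 50
        b = "-" * 55 + "A" * 45
        assert sm.aligned_overlap(a, b) == 0.0

    def test_partial(self):
        a = "A" * 70 + "-" * 30
        b = "-" * 50 + "A" * 50
        assert sm.aligned_overlap(a, b) == pytest.approx(20 / 50)

    def test_identity_and_symmetry(self):
        a = "AAAA----"
        b = "--AAAA--"
        assert sm.aligned_overlap(a, a) == 1.0
        assert sm.aligned_overlap(a, b) == sm.aligned_overlap(b, a)

    def test_all_gap_error(self):
        with pytest.raises(ValueError):
            sm.aligned_overlap("----", "AA--")


class TestResolveMulticopy:
    def test_fragments_merged_union(self):
        a = "MKL" + "-" * 7
        b = "-" * 5 + "QWERT"
        res = sm.resolve_multicopy([("f1", a), ("f2", b)])
        assert res.action == "merged_fragments"
        assert res.row == "MKL--QWERT"

    def test_paralogs_dropped(self):
        res = sm.resolve_multicopy([("p1", "MKLMKLMKL-"), ("p2", "MKLMKLMKLM")])
        assert res.action == "dropped_paralogs"
        assert res.row is None

    def test_one_overlapping_pair_drops_all(self):
        f1 = "AAAA" + "-" * 8
        f2 = "-" * 6 + "CCCC--"
        f3 = "-" * 5 + "GGGG---"  # overlaps f2 by 3 of 4
        res = sm.resolve_multicopy([("a", f1), ("b", f2), ("c", f3)])
        assert res.action == "dropped_paralogs"

    def test_generator_truth_recovered(self):
        cfg = syn.FamilyConfig(n_species=10, n_families=50, fragment_prob=0.3,
                               paralog_prob=0.3, seed=21)
        ogs, _, _, truth = syn.gen_gene_families(cfg)
        expected = {"single": "single", "fragments": "merged_fragments",
                    "paralogs": "dropped_paralogs"}
        for og in ogs:
            for sp, ids in og.members.items():
                if len(ids) < 2:
                    continue
                rows = [(i, og.alignment.get(i)) for i in ids]
                res = sm.resolve_multicopy(rows)
                label = truth[(truth["og_id"] == og.og_id)
                              & (truth["species"] == sp)]["label"].iloc[0]
                assert res.action == expected[label]


class TestFilterOrthogroups:
    def _og(self, og_id, n_present, n_total, length=150, n_multi=0):
        species = [f"sp{i:02d}" for i in range(n_total)]
        members = {sp: [] for sp in species}
        ids, rows = [], []
        for i in range(n_present):
            sp = species[i]
            if i < n_multi:  # give this species two overlapping paralogs
                for k in (1, 2):
                    sid = f"{sp}_{og_id}_{k}"
                    members[sp].append(sid)
                    ids.append(sid)
                    rows.append("M" * length)
            else:
                sid = f"{sp}_{og_id}"
                members[sp].append(sid)
                ids.append(sid)
                rows.append("M" * length)
        aln = Alignment(ids=ids, seqs=rows, alphabet="protein")
        return Orthogroup(og_id=og_id, members=members, alignment=aln)

    def test_rejection_reasons_in_order(self):
        cfg = sm.FilterConfig(n_species_total=53)
        ogs = [
            self._og("OG_few", 39, 53),
            self._og("OG_multi", 46, 53, n_multi=6),  # 40 remain after paralog drops
            self._og("OG_short", 45, 53, length=99),
            self._og("OG_ok", 45, 53),
        ]
        kept, report = sm.filter_orthogroups(ogs, cfg)
        assert report.reasons["OG_few"] == "too_few_species"
        assert report.reasons["OG_multi"] == "too_many_multicopy"
        assert report.reasons["OG_short"] == "too_short"
        assert report.decisions["OG_ok"] == "kept"
        assert [og.og_id for og, _ in kept] == ["OG_ok"]

    def test_every_og_accounted_once(self):
        cfg = sm.FilterConfig(n_species_total=53)
        ogs = [self._og(f"OG{i}", 45, 53) for i in range(5)]
        _, report = sm.filter_orthogroups(ogs, cfg)
        assert sorted(report.decisions) == sorted(o.og_id for o in ogs)

    def test_boundary_multicopy_fraction(self):
        # 5 of 53 = 9.4% passes, 6 of 53 = 11.3% fails
        cfg = sm.FilterConfig(n_species_total=53)
        ok = self._og("OG5", 45, 53, n_multi=5)
        bad = self._og("OG6", 46, 53, n_multi=6)
        _, report = sm.filter_orthogroups([ok, bad], cfg)
        assert report.decisions["OG5"] == "kept"
        assert report.reasons["OG6"] == "too_many_multicopy"

    def test_merged_fragments_count_as_present(self):
        # 40th species present only as two non-overlapping fragments
        cfg = sm.FilterConfig(n_species_total=53)
        og = self._og("OG_frag", 39, 53)
        sp = "sp39"
        frag_a = "M" * 75 + "-" * 75
        frag_b = "-" * 80 + "M" * 70
        og.members[sp] = ["sp39_f1", "sp39_f2"]
        og.alignment = Alignment(
            ids=og.alignment.ids + ["sp39_f1", "sp39_f2"],
            seqs=og.alignment.seqs + [frag_a, frag_b],
            alphabet="protein",
        )
        kept, report = sm.filter_orthogroups([og], cfg)
        assert report.decisions["OG_frag"] == "kept"
        assert report.resolutions[("OG_frag", sp)] == "merged_fragments"

    def test_generator_batch_recovery(self):
        cfg_gen = syn.FamilyConfig(n_species=20, n_families=60, presence_prob=0.95,
                                   fragment_prob=0.05, paralog_prob=0.05,
                                   protein_length=(90, 200), seed=4)
        ogs, _, _, truth = syn.gen_gene_families(cfg_gen)
        cfg = sm.FilterConfig(n_species_total=20, min_species_present=0.75,
                              max_multi_frac=0.15, min_aln_len_aa=100)
        kept, report = sm.filter_orthogroups(ogs, cfg)
        # independently recompute the expected kept set from truth labels
        expected = []
        for og in ogs:
            n_multi = sum(1 for ids in og.members.values() if len(ids) > 1)
            dropped = set(
                truth[(truth["og_id"] == og.og_id) & (truth["label"] == "paralogs")]["species"]
            )
            present = sum(1 for sp, ids in og.members.items() if ids and sp not in dropped)
            if present < 15 or n_multi / 20 > 0.15 or og.alignment.column_count < 100:
                continue
            expected.append(og.og_id)
        assert [og.og_id for og, _ in kept] == expected


class TestBacktranslate:
    def test_gap_column(self):
        aln = Alignment(ids=["x"], seqs=["M-K"], alphabet="protein")
        out = sm.backtranslate(aln, {"x": "ATGAAA"})
        assert out.seqs == ["ATG---AAA"]

    def test_trailing_stop_stripped(self):
        aln = Alignment(ids=["x"], seqs=["MK"], alphabet="protein")
        out = sm.backtranslate(aln, {"x": "ATGAAATAA"})
        assert out.seqs == ["ATGAAA"]

    def test_mismatch_reports_position(self):
        aln = Alignment(ids=["x"], seqs=["MK"], alphabet="protein")
        with pytest.raises(ValueError, match="position 2"):
            sm.backtranslate(aln, {"x": "ATGCGT"})  # translates MR


class TestTrim:
    def _aln(self, rows):
        return Alignment(ids=[f"s{i}" for i in range(len(rows))], seqs=rows,
                         alphabet="nucleotide")

    def test_half_gapped_column_kept(self):
        rows = ["AAATTT", "AAA---", "---TTT", "AAATTT"]
        out = sm.trim_codon_columns(self._aln(rows), 0.5)
        assert out.alignment.column_count == 6  # both codons at 2/4 >= 0.5

    def test_quarter_column_removed(self):
        rows = ["AAATTT", "AAA---", "AAA---", "AAA---"]
        out = sm.trim_codon_columns(self._aln(rows), 0.5)
        assert out.alignment.column_count == 3
        assert out.kept_codons == (0,)

    def test_threshold_limits(self):
        rows = ["AAATTT", "AAA---"]
        assert sm.trim_codon_columns(self._aln(rows), 0.0).alignment.column_count == 6
        assert sm.trim_codon_columns(self._aln(rows), 1.0).alignment.column_count == 3

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n, c = int(rng.integers(2, 8)), int(rng.integers(2, 15))
            rows = []
            for _ in range(n):
                codons = [
                    "---" if rng.random() < 0.4 else "ATG" for _ in range(c)
                ]
                codons.append("ATG")  # anchor column so the trim never empties
                rows.append("".join(codons))
            aln = self._aln(rows)
            once = sm.trim_codon_columns(aln, 0.5).alignment
            twice = sm.trim_codon_columns(once, 0.5).alignment
            assert once.seqs == twice.seqs

    def test_frame_preserved(self):
        with pytest.raises(ValueError):
            sm.trim_codon_columns(self._aln(["AAAA", "AAAA"]), 0.5)


class TestConcatenate:
    def test_widths_and_partitions(self):
        a1 = Alignment(ids=["s1", "s2"], seqs=["ATG" * 100, "CCC" * 100])
        a2 = Alignment(ids=["s1", "s3"], seqs=["GGG" * 50, "TTT" * 50])
        m = sm.concatenate({"og1": a1, "og2": a2}, ["s1", "s2", "s3"])
        assert m.alignment.column_count == 450
        assert [(p.start, p.end) for p in m.partitions] == [(1, 300), (301, 450)]

    def test_absent_species_padded(self):
        a1 = Alignment(ids=["s1"], seqs=["ATG" * 100])
        a2 = Alignment(ids=["s1", "s2"], seqs=["GGG" * 50, "TTT" * 50])
        m = sm.concatenate({"og1": a1, "og2": a2}, ["s1", "s2"])
        row = m.alignment.get("s2")
        assert row[:300] == "-" * 300
        assert row[300:] == "TTT" * 50

    def test_round_trip_slicing(self):
        rng = np.random.default_rng(5)
        alns = {}
        roster = [f"sp{i}" for i in range(6)]
        for k in range(4):
            width = int(rng.integers(2, 10)) * 3
            present = [sp for sp in roster if rng.random() < 0.8] or roster[:1]
            rows = [
                "".join("ACGT"[i] for i in rng.integers(4, size=width))
                for _ in present
            ]
            alns[f"og{k}"] = Alignment(ids=present, seqs=rows)
        m = sm.concatenate(alns, roster)
        for og_id, aln in alns.items():
            sliced = m.partition_alignment(og_id)
            for sid, seq in aln:
                assert sliced.get(sid) == seq
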