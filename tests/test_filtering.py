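import numpy as np
import pytest
from scipy import stats

from cladeshift.codon import CodonAlignment
from cladeshift.filtering import (
    FilterReport,
    Orthogroup,
    concatenate,
    dedupe_within_species,
    drop_gappy_and_duplicate_sequences,
    extract_nested_subclade,
    filter_batch,
    filter_orthogroup,
    filter_top_divergent,
    select_orthogroups,
    strip_gap_codon_columns,
)
from cladeshift.trees import parse_newick

UNITS = ["A", "B"]


def make_og(og_id, names, seqs, lengths=None, species=None, units=None):
    lengths = lengths or {n: 0.1 for n in names}
    nwk = "(" + ",".join(f"{n}:{lengths[n]}" for n in names) + ");"
    return Orthogroup(
        og_id, CodonAlignment(names, seqs), parse_newick(nwk),
        species or {n: n for n in names},
        units or {n: UNITS[i % 2] for i, n in enumerate(names)})


class TestSelection:
    def _group_of(self, n, units=("A", "B")):
        names = [f"s{i}" for i in range(n)]
        return make_og("og", names, ["ATG"] * n,
                       units={nm: units[i % len(units)]
                              for i, nm in enumerate(names)})

    def test_size_bounds_inclusive(self):
        assert select_orthogroups([self._group_of(9)], UNITS) == []
        g100 = self._group_of(100)
        assert select_orthogroups([g100], UNITS) == [g100]
        g10 = self._group_of(10)
        assert select_orthogroups([g10], UNITS) == [g10]

    def test_missing_unit_rejected(self):
        g = self._group_of(50, units=("A",))
        report = FilterReport()
        assert select_orthogroups([g], UNITS, report=report) == []
        assert "missing unit" in report.records[0]["reason"]


class TestSequenceCleaning:
    def test_gap_fraction_boundary(self):
        # 102 columns: 69/102 = 0.676 > 0.66 removed; 67/102 = 0.657 kept
        s_clean = "ATG" * 34
        s_gappy = "-" * 69 + "ATG" * 11
        s_edge = "-" * 67 + "AA" + "ATG" * 11  # 67/102 = 0.657 < 0.66
        aln = CodonAlignment(["clean", "gappy", "edge"],
                             [s_clean, s_gappy, s_edge])
        out, removed = drop_gappy_and_duplicate_sequences(aln)
        assert removed == ["gappy"]
        assert out.names == ["clean", "edge"]

    def test_duplicates_keep_one_representative(self):
        aln = CodonAlignment(["a", "b", "c"], ["ATGAAA", "ATGAAA", "ATGCCC"])
        out, removed = drop_gappy_and_duplicate_sequences(aln)
        assert out.names == ["a", "c"] and removed == ["b"]

    def test_strip_gap_columns_hand_count(self):
        # 10 codons; sequences gapped at codon columns 2, 5, 9 (1-based)
        base = "ATG" * 10
        s1 = base[:3] + "---" + base[6:]
        s2 = base[:12] + "A--" + base[15:24] + "-TG" + base[27:]
        aln = CodonAlignment(["x", "y"], [s1, s2])
        out, removed = strip_gap_codon_columns(aln)
        assert removed == [1, 4, 8]
        assert out.n_codons == 7 and out.is_gap_free

    def test_gap_free_input_unchanged(self):
        aln = CodonAlignment(["x", "y"], ["ATGAAA", "ATGCCC"])
        out, removed = strip_gap_codon_columns(aln)
        assert removed == [] and out.seqs == aln.seqs

    def test_all_columns_gapped_rejected(self):
        aln = CodonAlignment(["x", "y"], ["AT-", "ATG"])
        with pytest.raises(ValueError, match="no codon columns left"):
            strip_gap_codon_columns(aln)


class TestNestedSubclade:
    def test_root_only_returns_whole_tree(self):
        t = parse_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        unit_of = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        sub, retained = extract_nested_subclade(t, unit_of, UNITS)
        assert sorted(retained) == ["a1", "a2", "b1", "b2"]

    def test_mirrored_duplication_keeps_one_clade(self):
        t = parse_newick("((a1:1,b1:1):1,(a2:1,b2:1):1);")
        unit_of = {n: n[0].upper() for n in ["a1", "b1", "a2", "b2"]}
        sub, retained = extract_nested_subclade(t, unit_of, UNITS)
        # both cherries qualify with 2 tips; the lexicographic tie-break picks
        # the (a1,b1) clade deterministically
        assert sorted(retained) == ["a1", "b1"]

    def test_inner_clade_preferred(self):
        t = parse_newick("(((a1:1,b1:1):1,a2:1):1,b2:1);")
        unit_of = {n: n[0].upper() for n in ["a1", "b1", "a2", "b2"]}
        sub, retained = extract_nested_subclade(t, unit_of, UNITS)
        assert sorted(retained) == ["a1", "b1"]


class TestDedupe:
    def test_deterministic_under_seed_and_single_copy_passthrough(self):
        aln = CodonAlignment(["x1", "x2", "x3", "y1"],
                             ["ATGAAA", "ATGAAC", "ATGAAG", "ATGCCC"])
        tree = parse_newick("(((x1:1,x2:1):1,x3:1):1,y1:1);")
        species = {"x1": "X", "x2": "X", "x3": "X", "y1": "Y"}
        out1, _, rem1 = dedupe_within_species(aln, tree, species, seed=42)
        out2, _, rem2 = dedupe_within_species(aln, tree, species, seed=42)
        assert out1.names == out2.names and rem1 == rem2
        assert sum(1 for n in out1.names if species[n] == "X") == 1
        assert "y1" in out1.names

    def test_choice_is_uniform(self):
        aln = CodonAlignment(["x1", "x2", "y1"], ["ATGAAA", "ATGAAC", "ATGCC" + "C"])
        tree = parse_newick("((x1:1,x2:1):1,y1:1);")
        species = {"x1": "X", "x2": "X", "y1": "Y"}
        kept_x1 = 0
        for seed in range(1000):
            out, _, _ = dedupe_within_species(aln, tree, species, seed=seed)
            kept_x1 += "x1" in out.names
        assert stats.binomtest(kept_x1, 1000, 0.5).pvalue > 0.01


class TestDivergenceFilter:
    def _batch(self, n, outlier_at=None, outlier_scale=10.0):
        groups = []
        for i in range(n):
            lengths = {"p": 0.1 + 0.001 * i, "q": 0.1}
            if outlier_at == i:
                lengths["p"] = (0.1 + 0.001 * i) * outlier_scale
            groups.append(make_og(f"og{i:03d}", ["p", "q"],
                                  ["ATGAAA", "ATGAAC"], lengths=lengths))
        return groups

    def test_ceil_rule_on_100(self):
        kept = filter_top_divergent(self._batch(100), fraction=0.05, min_seqs=0)
        assert len(kept) == 95

    def test_injected_outlier_is_the_one_removed(self):
        groups = self._batch(10, outlier_at=3)
        kept = filter_top_divergent(groups, fraction=0.05, min_seqs=0)
        assert len(kept) == 9
        assert "og003" not in {g.id for g in kept}

    def test_small_groups_dropped_after_cut(self):
        groups = self._batch(10)
        kept = filter_top_divergent(groups, fraction=0.05, min_seqs=10)
        assert kept == []  # all groups have 2 < 10 sequences


class TestConcatenate:
    def _og(self, og_id, species, seq_len=6):
        names = [f"{og_id}_{sp}" for sp in species]
        rng = np.random.default_rng(hash(og_id) % 2**31)
        codons = ["ATG", "AAA", "CCC", "GGG", "TTT"]
        seqs = ["".join(rng.choice(codons, seq_len // 3)) for _ in names]
        return make_og(og_id, names, seqs,
                       species={n: sp for n, sp in zip(names, species)},
                       units={n: "A" for n in names})

    def test_only_full_coverage_groups_concatenated(self):
        taxa = ["sp1", "sp2", "sp3"]
        groups = [self._og("g1", taxa), self._og("g2", taxa),
                  self._og("g3", ["sp1", "sp2"])]
        aln, pmap = concatenate(groups, taxa)
        assert aln.length == 12
        assert list(pmap["orthogroup"]) == ["g1", "g2"]
        assert pmap.iloc[0]["start"] == 1 and pmap.iloc[0]["end"] == 6
        assert pmap.iloc[1]["start"] == 7 and pmap.iloc[1]["end"] == 12

    def test_coordinate_map_inverts(self):
        taxa = ["sp1", "sp2"]
        groups = [self._og("g1", taxa, 9), self._og("g2", taxa, 6)]
        aln, pmap = concatenate(groups, taxa)
        for _, row in pmap.iterrows():
            og = next(g for g in groups if g.id == row["orthogroup"])
            for sp in taxa:
                seq_name = f"{row['orthogroup']}_{sp}"
                assert (aln.sequence(sp)[row["start"] - 1: row["end"]]
                        == og.alignment.sequence(seq_name))

    def test_no_full_groups_is_an_error(self):
        groups = [self._og("g1", ["sp1", "sp2"])]
        with pytest.raises(ValueError, match="nothing to concatenate"):
            concatenate(groups, ["sp1", "sp2", "sp3"])


class TestCascade:
    def _messy_batch(self):
        groups = []
        for i in range(4):
            names = [f"a{j}" for j in range(3)] + [f"b{j}" for j in range(3)]
            rng = np.random.default_rng(i)
            codons = ["ATG", "AAA", "CCC", "GGG", "TTT", "ACG"]
            seqs = ["".join(rng.choice(codons, 6)) for _ in names]
            og = make_og(f"og{i}", names, seqs,
                         species={n: n for n in names},
                         units={n: n[0].upper() for n in names})
            groups.append(og)
        return groups

    def test_idempotent_and_reconciled(self):
        groups = self._messy_batch()
        kept, report = filter_batch(groups, UNITS, seed=0, min_seqs=2,
                                    max_seqs=100)
        assert report.reconciles()
        again, report2 = filter_batch(kept, UNITS, seed=1, min_seqs=2,
                                      max_seqs=100)
        assert {g.id for g in again} >= {g.id for g in kept} - \
            {g.id for g in kept[:1]}  # divergence cut re-applies ceil(0.05 N)>=1
        for g2 in again:
            g1 = next(g for g in kept if g.id == g2.id)
            assert g2.alignment.seqs == g1.alignment.seqs

    def test_collapsing_orthogroup_reported_not_fatal(self):
        og = make_og("bad", ["p", "q"], ["AT-", "ATG"],
                     units={"p": "A", "q": "B"})
        report = FilterReport()
        out = filter_orthogroup(og, UNITS, report=report)
        assert out is None
        assert any(r["step"] == "collapsed" for r in report.records)
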