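import numpy as np
import pandas as pd
import pytest

from hervex.group_stats import bh_fdr
from hervex.rvgc_quant import (CatalogIndex, align_to_catalog, count_best,
                               count_comprehensive, fpkm, group_compare,
                               quantify_specimens)
from hervex.seq_io import CatalogEntryName, SeqRecord, encode_entry_name
from hervex.synthetic_data import revcomp


def _entry(domain, idx, seq):
    name = CatalogEntryName(domain, idx, f"RV-{domain}", "src", 1, len(seq))
    return SeqRecord(encode_entry_name(name), seq)


def _read(rid, seq):
    return SeqRecord(rid, seq, qualities=[38] * len(seq))


RNG = np.random.default_rng(20)
SEQ_A = "".join(RNG.choice(list("ACGT"), size=400))
SEQ_B = "".join(RNG.choice(list("ACGT"), size=300))
CATALOG = [_entry("ENV", 1, SEQ_A), _entry("ENV", 2, SEQ_A),
           _entry("GAG", 1, SEQ_B)]


def brute_force_alignments(read, catalog, max_mismatches=3):
    """Exhaustive oracle: scan every offset of every entry, both strands."""
    out = {}
    for rec in catalog:
        from hervex.seq_io import decode_entry_name
        code = decode_entry_name(rec.id).code
        best = None
        for seq in (read, revcomp(read)):
            for off in range(len(rec.sequence) - len(seq) + 1):
                mm = sum(a != b for a, b in
                         zip(seq, rec.sequence[off:off + len(seq)]))
                if mm <= max_mismatches and (best is None or mm < best):
                    best = mm
        if best is not None:
            out[code] = best
    return out


class TestAlign:
    def test_exact_read_single_entry(self):
        alns = align_to_catalog([_read("r", SEQ_B[10:60])],
                                [_entry("GAG", 1, SEQ_B)])
        assert len(alns) == 1
        assert alns[0].mismatches == 0 and alns[0].score == 0

    def test_duplicated_entries_multi_map(self):
        alns = align_to_catalog([_read("r", SEQ_A[50:100])], CATALOG)
        codes = sorted(a.entry_code for a in alns)
        assert codes == ["ENV_U1", "ENV_U2"]
        assert alns[0].score == alns[1].score

    def test_reverse_strand(self):
        alns = align_to_catalog([_read("r", revcomp(SEQ_B[0:50]))], CATALOG)
        assert [a.entry_code for a in alns] == ["GAG_U1"]
        assert alns[0].strand == "-"

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(21)
        reads = []
        for i in range(30):
            src = SEQ_A if i % 2 else SEQ_B
            off = int(rng.integers(0, len(src) - 50))
            frag = list(src[off:off + 50])
            for _ in range(int(rng.integers(0, 5))):  # 0-4 substitutions
                pos = int(rng.integers(0, 50))
                frag[pos] = "ACGT"["ACGT".index(frag[pos]) - 1]
            reads.append(_read(f"r{i}", "".join(frag)))
        for read in reads:
            expected = brute_force_alignments(read.sequence, CATALOG)
            got = {a.entry_code: a.mismatches
                   for a in align_to_catalog([read], CATALOG)}
            assert got == expected, read.id


class TestCounting:
    def test_best_prefers_fewer_mismatches(self):
        frag = list(SEQ_B[10:60])
        frag[0] = "ACGT"["ACGT".index(frag[0]) - 1]
        entry_exact = _entry("RT", 1, "".join(frag) + SEQ_A[:100])
        alns = align_to_catalog([_read("r", "".join(frag))],
                                [_entry("GAG", 1, SEQ_B), entry_exact])
        counts = count_best(alns)
        assert counts == {"RT_U1": 1}

    def test_tie_broken_lexicographically(self):
        alns = align_to_catalog([_read("r", SEQ_A[50:100])], CATALOG)
        assert count_best(alns) == {"ENV_U1": 1}

    def test_best_conservation(self, tiny_study):
        reads = next(iter(tiny_study["reads"].values()))[:500]
        from hervex.catalog_builder import (build_catalog, coverage_filter,
                                            translated_search)
        cat, _ = build_catalog(
            coverage_filter(translated_search(tiny_study["genome"],
                                              tiny_study["proteins"])),
            tiny_study["genome"])
        alns = align_to_catalog(reads, cat)
        aligned_reads = {a.read_id for a in alns}
        assert sum(count_best(alns).values()) == len(aligned_reads)

    def test_comprehensive_counts_every_alignment(self):
        alns = align_to_catalog([_read("r", SEQ_A[50:100])], CATALOG)
        assert count_comprehensive(alns) == {"ENV_U1": 1, "ENV_U2": 1}

    def test_comprehensive_dominates_best(self, tiny_study):
        reads = next(iter(tiny_study["reads"].values()))[:500]
        alns = align_to_catalog(reads, CATALOG + [_entry("RT", 1, SEQ_A[:200])])
        best, comp = count_best(alns), count_comprehensive(alns)
        for code, c in best.items():
            assert comp[code] >= c

    def test_equality_on_duplicate_free_catalog(self):
        catalog = [_entry("ENV", 1, SEQ_A), _entry("GAG", 1, SEQ_B)]
        reads = [_read(f"r{i}", SEQ_A[i * 7:i * 7 + 50]) for i in range(20)]
        alns = align_to_catalog(reads, catalog)
        assert count_best(alns) == count_comprehensive(alns)


class TestFpkm:
    def test_closed_form(self):
        out = fpkm({"e": 10}, {"e": 1000}, norm_mass=1e6)
        assert out["e"] == pytest.approx(10_000.0)  # FPKM 10, x1000 scale

    def test_norm_mass_scaling(self):
        a = fpkm({"e": 10}, {"e": 1000}, norm_mass=1e6)["e"]
        b = fpkm({"e": 10}, {"e": 1000}, norm_mass=2e6)["e"]
        assert b == pytest.approx(a / 2)

    def test_zero_count(self):
        assert fpkm({}, {"e": 1000}, norm_mass=1e6)["e"] == 0.0

    def test_scale_invariance(self):
        a = fpkm({"e": 7}, {"e": 512}, norm_mass=1e5)["e"]
        b = fpkm({"e": 21}, {"e": 512}, norm_mass=3e5)["e"]
        assert a == pytest.approx(b)

    def test_zero_length_is_error(self):
        with pytest.raises(ValueError):
            fpkm({"e": 1}, {"e": 0}, norm_mass=1e6)

    def test_zero_norm_mass_is_error(self):
        with pytest.raises(ValueError):
            fpkm({"e": 1}, {"e": 100}, norm_mass=0)


def _design(n_case=5, n_ctrl=5):
    rows = [{"specimen_id": f"d{i}", "group": "demyelination"}
            for i in range(n_case)]
    rows += [{"specimen_id": f"c{i}", "group": "control"}
             for i in range(n_ctrl)]
    return pd.DataFrame(rows)


class TestGroupCompare:
    def test_identical_groups(self):
        rng = np.random.default_rng(22)
        vals = rng.uniform(1, 10, size=5)
        expr = pd.DataFrame({f"d{i}": vals for i in range(5)}
                            | {f"c{i}": vals for i in range(5)},
                            index=["ENV_U1", "GAG_U1", "RT_U1", "ENV_U2", "KRAB_U1"])
        res = group_compare(expr, _design(), {c: c.split("_")[0]
                                              for c in expr.index})
        assert res["ratio"].to_numpy() == pytest.approx(1.0)
        assert res["p"].to_numpy() == pytest.approx(1.0)

    def test_all_zero_entry_uninformative(self):
        expr = pd.DataFrame(np.zeros((1, 10)),
                            index=["ENV_U1"],
                            columns=[f"d{i}" for i in range(5)]
                            + [f"c{i}" for i in range(5)])
        res = group_compare(expr, _design(), {"ENV_U1": "ENV"})
        assert bool(res.loc["ENV_U1", "uninformative"])
        assert res.loc["ENV_U1", "p"] == 1.0

    def test_q_matches_domainwise_bh_oracle(self):
        rng = np.random.default_rng(23)
        codes = [f"ENV_U{i}" for i in range(1, 6)] + \
                [f"GAG_U{i}" for i in range(1, 5)]
        expr = pd.DataFrame(rng.uniform(0, 100, size=(9, 10)), index=codes,
                            columns=[f"d{i}" for i in range(5)]
                            + [f"c{i}" for i in range(5)])
        domains = {c: c.split("_")[0] for c in codes}
        res = group_compare(expr, _design(), domains)
        for dom in ("ENV", "GAG"):
            sub = res[res["domain_type"] == dom]
            assert sub["q"].to_numpy() == pytest.approx(
                bh_fdr(sub["p"].to_numpy()))

    def test_needs_three_per_group(self):
        expr = pd.DataFrame(np.ones((1, 4)), index=["ENV_U1"],
                            columns=["d0", "d1", "c0", "c1"])
        with pytest.raises(ValueError, match=">= 3"):
            group_compare(expr, _design(2, 2), {"ENV_U1": "ENV"})


class TestQuantifySpecimens:
    def test_hq_norm_mode_requires_counts(self):
        reads = {"s1": [_read("r", SEQ_A[0:50])]}
        with pytest.raises(ValueError, match="hq"):
            quantify_specimens(reads, CATALOG, norm_mass_mode="hq")

    def test_best_vs_comprehensive_tables(self):
        reads = {"s1": [_read("r1", SEQ_A[0:50]), _read("r2", SEQ_B[0:50])]}
        best = quantify_specimens(reads, CATALOG, scheme="best")
        comp = quantify_specimens(reads, CATALOG, scheme="comprehensive")
        assert (comp["s1"] * 0 + 1).sum() == 3  # all entries present
        # the duplicated ENV pair splits under best, doubles under comprehensive
        assert best.loc["ENV_U2", "s1"] == 0.0
        assert comp.loc["ENV_U2", "s1"] > 0.0
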