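"""Consensus call-set construction, twin partition, filters, SV merging."""

import numpy as np
import pytest

from twinclock.consensus import (
    SomaticVariant,
    SvCall,
    classify_shared_unique,
    filter_vaf_depth,
    intersect_callers,
    merge_sv_calls,
    normalize_allele,
    read_caller_vcf,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1,length=100000>
##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic">
##FILTER=<ID=LowQual,Description="Low quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="DP">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR\tNORMAL
"""


def _vcf(tmp_path, name, records):
    path = tmp_path / name
    path.write_text(VCF_HEADER + "".join(r + "\n" for r in records))
    return path


def _rec(pos, ref="A", alt="T", filt="PASS", info="SOMATIC", t="0/1:25,15:40",
         n="0/0:40,0:40"):
    return f"chr1\t{pos}\t.\t{ref}\t{alt}\t60\t{filt}\t{info}\tGT:AD:DP\t{t}\t{n}"


def _var(pos, ref="A", alt="T", **kw):
    defaults = dict(tumor_alt=15, tumor_depth=40, germline_alt=0,
                    germline_depth=40)
    defaults.update(kw)
    return SomaticVariant(chrom="chr1", pos=pos, ref=ref, alt=alt, **defaults)


class TestReadCallerVcf:
    def test_pass_and_somatic_dialect(self, tmp_path):
        path = _vcf(tmp_path, "a.vcf", [
            _rec(100),                          # PASS + SOMATIC -> kept
            _rec(200, filt="LowQual"),          # filtered -> dropped
            _rec(300, info="."),                # PASS but not somatic -> dropped
        ])
        got = read_caller_vcf(path, "pass_and_somatic")
        assert [v.pos for v in got] == [100]

    def test_strict_pass_dialect_ignores_somatic_flag(self, tmp_path):
        path = _vcf(tmp_path, "a.vcf", [_rec(100, info="."), _rec(200, filt="LowQual")])
        got = read_caller_vcf(path, "strict_pass")
        assert [v.pos for v in got] == [100]

    def test_record_counts_and_allele_counts(self, tmp_path):
        records = [_rec(100 * (i + 1)) for i in range(7)]
        records += [_rec(1000 * (i + 1), filt="LowQual") for i in range(3)]
        got = read_caller_vcf(_vcf(tmp_path, "a.vcf", records), "pass_and_somatic")
        assert len(got) == 7
        assert got[0].tumor_alt == 15 and got[0].tumor_depth == 40
        assert got[0].germline_alt == 0 and got[0].germline_depth == 40

    def test_multiallelic_split(self, tmp_path):
        rec = ("chr1\t500\t.\tA\tT,G\t60\tPASS\tSOMATIC\tGT:AD:DP\t"
               "0/1:20,10,10:40\t0/0:40,0,0:40")
        got = read_caller_vcf(_vcf(tmp_path, "a.vcf", [rec]), "pass_and_somatic")
        assert [(v.pos, v.alt, v.tumor_alt) for v in got] == [(500, "T", 10),
                                                              (500, "G", 10)]

    def test_unknown_dialect(self, tmp_path):
        path = _vcf(tmp_path, "a.vcf", [_rec(100)])
        with pytest.raises(ValueError, match="dialect"):
            read_caller_vcf(path, "lenient")


class TestIntersectCallers:
    def test_three_of_three_required(self):
        a, b, c = [_var(100), _var(200)], [_var(100), _var(300)], [_var(100)]
        got = intersect_callers(a, b, c)
        assert [v.pos for v in got] == [100]
        assert got[0].caller_flags == (True, True, True)

    def test_set_arithmetic_sizes(self):
        common = [_var(p) for p in range(1, 7)]
        a = common + [_var(p) for p in (10, 11, 12, 13)]
        b = common + [_var(p) for p in (20, 21)]
        c = common + [_var(p) for p in (30, 31, 32)]
        assert len(intersect_callers(a, b, c)) == 6

    def test_order_invariant_and_idempotent(self):
        a = [_var(p) for p in (1, 2, 3)]
        b = [_var(p) for p in (2, 3, 4)]
        c = [_var(p) for p in (2, 3, 5)]
        first = intersect_callers(a, b, c)
        assert first == intersect_callers(c, a, b)
        assert intersect_callers(first, first, first) == first


class TestClassifySharedUnique:
    def test_identical_sets(self):
        s = [_var(p) for p in (1, 2, 3)]
        part = classify_shared_unique(s, list(s))
        assert len(part.shared) == 3 and not part.unique_a and not part.unique_b

    def test_disjoint_sets(self):
        part = classify_shared_unique([_var(1)], [_var(2)])
        assert not part.shared
        assert [v.pos for v in part.unique_a] == [1]
        assert [v.pos for v in part.unique_b] == [2]

    def test_partition_conserves_inputs(self):
        a = [_var(p) for p in (1, 2, 3, 4)]
        b = [_var(p) for p in (3, 4, 5)]
        part = classify_shared_unique(a, b)
        assert len(part.shared) + len(part.unique_a) == len(a)
        assert len(part.shared) + len(part.unique_b) == len(b)
        rebuilt_a = {v.pos for v in part.shared} | {v.pos for v in part.unique_a}
        assert rebuilt_a == {v.pos for v in a}

    def test_padding_normalization_reconciles_representations(self):
        # same substitution padded differently by two callers
        a = [_var(100, ref="CAG", alt="CTG")]
        b = [_var(101, ref="A", alt="T")]
        part = classify_shared_unique(a, b, normalized=True)
        assert len(part.shared) == 1
        literal = classify_shared_unique(a, b, normalized=False)
        assert not literal.shared


def test_normalize_allele_trims_to_minimal_representation():
    assert normalize_allele(100, "ATT", "AT") == (100, "AT", "A")
    assert normalize_allele(100, "CAG", "CTG") == (101, "A", "T")
    assert normalize_allele(100, "A", "T") == (100, "A", "T")


class TestFilterVafDepth:
    def test_boundary_rules(self):
        variants = [
            _var(1, germline_alt=3, germline_depth=50),            # gVAF 0.06
            _var(2, tumor_alt=4, tumor_depth=45),                  # tVAF 0.089
            _var(3, tumor_alt=5, tumor_depth=19),                  # depth 19
            _var(4, tumor_alt=2, tumor_depth=20),                  # tVAF 0.10/20: kept
            _var(5, tumor_alt=0, tumor_depth=0),                   # no coverage
            _var(6, multiplicity=0),                               # multiplicity 0
            _var(7, germline_alt=2, germline_depth=40),            # gVAF 0.05: kept
        ]
        kept, log = filter_vaf_depth(variants)
        assert [v.pos for v in kept] == [4, 7]
        reasons = dict(zip(log["pos"], log["reason"]))
        assert reasons == {1: "germline VAF", 2: "tumor VAF", 3: "depth",
                           5: "no coverage", 6: "multiplicity zero"}

    def test_tightening_thresholds_is_monotone(self):
        rng = np.random.default_rng(0)
        variants = [
            _var(i, tumor_alt=int(a), tumor_depth=int(d),
                 germline_alt=int(g), germline_depth=40)
            for i, (a, d, g) in enumerate(zip(
                rng.integers(0, 20, 200), rng.integers(20, 60, 200),
                rng.integers(0, 4, 200)))
            if a <= d
        ]
        base = len(filter_vaf_depth(variants)[0])
        for kw in (dict(germline_vaf_max=0.02), dict(tumor_vaf_min=0.2),
                   dict(min_depth=30)):
            assert len(filter_vaf_depth(variants, **kw)[0]) <= base


class TestMergeSvCalls:
    def _sv(self, pos1, pos2, caller, svtype="DEL", ao=0):
        return SvCall("chr1", pos1, "chr1", pos2, svtype, caller,
                      normal_alt_evidence=ao)

    def test_both_callers_within_slop_retained(self):
        out = merge_sv_calls([self._sv(1000, 5000, "manta")],
                             [self._sv(1150, 5100, "lumpy")])
        assert len(out) == 1

    def test_single_caller_needs_changepoint(self):
        sv = [self._sv(1000, 5000, "manta")]
        assert merge_sv_calls(sv, [], [("chr1", 1100)]) != []
        assert merge_sv_calls(sv, [], [("chr1", 2000)]) == []
        assert merge_sv_calls(sv, [], None) == []

    def test_normal_evidence_vetoes(self):
        out = merge_sv_calls([self._sv(1000, 5000, "manta", ao=1)],
                             [self._sv(1000, 5000, "lumpy", ao=1)])
        assert out == []

    def test_breakpoints_outside_slop_do_not_match(self):
        out = merge_sv_calls([self._sv(1000, 5000, "manta")],
                             [self._sv(1300, 5000, "lumpy")])
        assert out == []

    def test_svtype_must_match(self):
        out = merge_sv_calls([self._sv(1000, 5000, "manta", svtype="DEL")],
                             [self._sv(1000, 5000, "lumpy", svtype="DUP")])
        assert out == []

    def test_transitive_chains_merge_to_one_call(self):
        out = merge_sv_calls(
            [self._sv(1000, 5000, "manta")],
            [self._sv(1180, 5000, "lumpy"), self._sv(1360, 5000, "lumpy")])
        assert len(out) == 1
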