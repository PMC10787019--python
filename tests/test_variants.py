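import json

import pytest

from tetrasig.io import IntervalSet
from tetrasig.variants import (
    FilterParams,
    VariantError,
    VariantRecord,
    VariantSet,
    apply_filters,
    intersect_callsets,
    read_vcf,
    write_vcf,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n'
    "##contig=<ID=chr1>\n"
)


def write_lines(tmp_path, body, samples=("s1", "s2")):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    p = tmp_path / "t.vcf"
    p.write_text(VCF_HEADER + cols + "\n" + body)
    return p


def rec(chrom="chr1", pos=100, ref="A", alts=("T",), depth=30, gts=("0/1", "0/0"), **kw):
    return VariantRecord(chrom, pos, ref, tuple(alts), depth=depth, genotypes=tuple(gts), **kw)


# ------------------------------------------------------------- VCF IO

def test_info_dp(tmp_path):
    p = write_lines(tmp_path, "chr1\t10\t.\tA\tT\t.\t.\tDP=37\tGT\t0/1\t0/0\n")
    vs = read_vcf(p)
    assert vs.records[0].depth == 37


def test_format_dp_summation(tmp_path):
    p = write_lines(tmp_path, "chr1\t10\t.\tA\tT\t.\t.\t.\tGT:DP\t0/1:10\t0/0:12\n")
    vs = read_vcf(p)
    assert vs.records[0].depth == 22
    assert vs.records[0].sample_depths == (10, 12)


def test_depth_unknown_flagged(tmp_path):
    p = write_lines(tmp_path, "chr1\t10\t.\tA\tT\t.\t.\t.\tGT\t0/1\t0/0\n")
    vs = read_vcf(p)
    assert vs.records[0].depth is None


def test_multiple_alts(tmp_path):
    p = write_lines(tmp_path, "chr1\t10\t.\tA\tT,C\t.\t.\tDP=20\tGT\t0/1\t0/2\n")
    vs = read_vcf(p)
    assert vs.records[0].alts == ("T", "C")


def test_malformed_line_number(tmp_path):
    p = write_lines(tmp_path, "chr1\t10\t.\tA\n")
    with pytest.raises(VariantError, match=":7:"):
        read_vcf(p)


def test_non_integer_pos(tmp_path):
    p = write_lines(tmp_path, "chr1\txx\t.\tA\tT\t.\t.\tDP=5\tGT\t0/1\t0/0\n")
    with pytest.raises(VariantError, match="POS"):
        read_vcf(p)


def test_missing_genotypes_fraction(tmp_path):
    p = write_lines(tmp_path, "chr1\t10\t.\tA\tT\t.\t.\tDP=30\tGT\t./.\t0/1\n")
    vs = read_vcf(p)
    assert vs.records[0].missing_fraction == pytest.approx(0.5)


def test_write_read_roundtrip(tmp_path):
    vs = VariantSet([rec(pos=10), rec(pos=50, alts=("T", "C"), gts=("./.", "1/2")),
                     rec(pos=90, depth=None)], samples=("s1", "s2"))
    p = tmp_path / "rt.vcf"
    write_vcf(vs, p)
    back = read_vcf(p)
    for a, b in zip(vs.records, back.records):
        assert (a.chrom, a.pos, a.ref, a.alts, a.depth, a.genotypes) == \
               (b.chrom, b.pos, b.ref, b.alts, b.depth, b.genotypes)


# ------------------------------------------------------------- intersection

def test_intersect_disjoint():
    a = VariantSet([rec(pos=10)])
    b = VariantSet([rec(pos=20)])
    out = intersect_callsets(a, b)
    assert len(out) == 0 and out.provenance == "intersection"


def test_intersect_identical():
    a = VariantSet([rec(pos=10), rec(pos=20)])
    out = intersect_callsets(a, VariantSet(list(a.records)))
    assert out.records == a.records


def test_intersect_alt_mismatch():
    a = VariantSet([rec(pos=10, alts=("A",), ref="G")])
    b = VariantSet([rec(pos=10, alts=("T",), ref="G")])
    assert len(intersect_callsets(a, b)) == 0


def test_intersect_takes_a_annotations():
    a = VariantSet([rec(pos=10, depth=50)])
    b = VariantSet([rec(pos=10, depth=99)])
    assert intersect_callsets(a, b).records[0].depth == 50


def test_intersect_unsorted_error():
    a = VariantSet([rec(pos=20), rec(pos=10)])
    with pytest.raises(VariantError, match="not sorted"):
        intersect_callsets(a, VariantSet([]))


# ------------------------------------------------------------- filter cascade

def clean_records():
    return [rec(pos=p) for p in (100, 200, 300)]


def test_depth_below_five_removed():
    vs = VariantSet([rec(pos=100, depth=4)] + [rec(pos=p) for p in (200, 300)])
    rep = apply_filters(vs, FilterParams())
    assert rep.removed["depth"] == 1 and len(rep.survivors) == 2


def test_depth_above_thousand_removed():
    vs = VariantSet([rec(pos=100, depth=1001), rec(pos=200, depth=1000), rec(pos=300, depth=5)])
    rep = apply_filters(vs, FilterParams())
    assert rep.removed["depth"] == 1 and len(rep.survivors) == 2


def test_depth_unknown_counted_separately():
    vs = VariantSet([rec(pos=100, depth=None), rec(pos=200, depth=3), rec(pos=300)])
    rep = apply_filters(vs, FilterParams())
    assert rep.removed["depth"] == 2 and rep.depth_unknown == 1


def test_proximity_both_members_removed():
    vs = VariantSet([rec(pos=100), rec(pos=103), rec(pos=300)])
    rep = apply_filters(vs, FilterParams())
    assert rep.removed["proximity"] == 2
    assert [r.pos for r in rep.survivors.records] == [300]


def test_proximity_against_original_input():
    # the pos=103 record fails depth, but still disqualifies pos=100
    vs = VariantSet([rec(pos=100), rec(pos=103, depth=1), rec(pos=300)])
    rep = apply_filters(vs, FilterParams())
    assert rep.removed["depth"] == 1 and rep.removed["proximity"] == 1
    assert [r.pos for r in rep.survivors.records] == [300]


def test_exactly_five_bp_is_kept():
    vs = VariantSet([rec(pos=100), rec(pos=105), rec(pos=300)])
    rep = apply_filters(vs, FilterParams())
    assert rep.removed["proximity"] == 0


def test_non_biallelic_removed():
    vs = VariantSet([rec(pos=100, alts=("T", "C")), rec(pos=300)])
    rep = apply_filters(vs, FilterParams())
    assert rep.removed["biallelic"] == 1


def test_missing_rate_rule():
    vs = VariantSet([rec(pos=100, gts=("./.", "0/1")), rec(pos=300, gts=("0/1", "0/1"))])
    rep = apply_filters(vs, FilterParams())
    assert rep.removed["missing"] == 1  # 50% > 40%


def test_repeat_mask_rule():
    mask = IntervalSet.from_intervals([("chr1", 90, 110)])  # 1-based 91..110
    vs = VariantSet([rec(pos=100), rec(pos=300)])
    rep = apply_filters(vs, FilterParams(repeat_mask=mask))
    assert rep.removed["repeat"] == 1
    assert [r.pos for r in rep.survivors.records] == [300]


def test_conservation_partition():
    from tetrasig.simulate import simulate_vcf
    res = simulate_vcf(500, seed=11)
    rep = apply_filters(res.variants, FilterParams(repeat_mask=res.repeat_mask))
    assert rep.input_count == sum(rep.removed.values()) + len(rep.survivors)


def test_rerun_bit_identical():
    from tetrasig.simulate import simulate_vcf
    res = simulate_vcf(300, seed=13)
    params = FilterParams(repeat_mask=res.repeat_mask)
    r1 = apply_filters(res.variants, params)
    r2 = apply_filters(res.variants, params)
    assert json.dumps(r1.to_dict(), sort_keys=True) == json.dumps(r2.to_dict(), sort_keys=True)
    assert r1.reasons == r2.reasons


def test_rule_order_never_changes_surviving_set():
    """Per-rule counts depend on cascade order; the surviving set does not."""
    import itertools
    from tetrasig.simulate import simulate_vcf

    res = simulate_vcf(120, seed=17)
    params = FilterParams(repeat_mask=res.repeat_mask)
    baseline = apply_filters(res.variants, params)
    base_keys = {(r.chrom, r.pos) for r in baseline.survivors.records}

    records = res.variants.records
    all_pos = {}
    for r in records:
        all_pos.setdefault(r.chrom, []).append(r.pos)

    def fails(r, rule):
        if rule == "depth":
            return r.depth is None or r.depth < 5 or r.depth > 1000
        if rule == "biallelic":
            return not r.is_biallelic
        if rule == "missing":
            return r.missing_fraction > 0.40
        if rule == "repeat":
            return res.repeat_mask.contains_1based(r.chrom, r.pos)
        return any(q != r.pos and abs(q - r.pos) < 5 for q in all_pos[r.chrom])

    for order in itertools.permutations(["depth", "biallelic", "missing", "repeat", "proximity"]):
        surv = {(r.chrom, r.pos) for r in records if not any(fails(r, rule) for rule in order)}
        assert surv == base_keys


def test_filter_params_validation():
    with pytest.raises(VariantError):
        FilterParams(depth_min=10, depth_max=5)
    with pytest.raises(VariantError):
        FilterParams(max_missing=1.5)
    with pytest.raises(VariantError):
        FilterParams(min_spacing=0)
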