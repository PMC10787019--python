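import io as _io
import numpy as np
import pytest

from tetrasig.io import write_fasta
from tetrasig.kmers import canonical_kmer, count_kmers_assembly, revcomp
from tetrasig.simulate import (
    GenomeMap,
    SimulationConfig,
    SimulationError,
    VcfSimSpec,
    simulate_polyploid_genome,
    simulate_reads,
    simulate_vcf,
)


def mismatch_fraction(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b)) / len(a)


# ------------------------------------------------------------- genome simulation

def test_auto_counts_and_lengths():
    cfg = SimulationConfig(mode="auto", n_groups=2, chrom_len=50_000, seed=1)
    genome, truth = simulate_polyploid_genome(cfg)
    assert len(genome.records) == 8
    assert all(len(r.seq) == 50_000 for r in genome.records)
    assert truth["mode"] == "auto"
    groups = genome.groups()
    assert set(groups) == {"g1", "g2"} and all(len(v) == 4 for v in groups.values())


def test_within_group_divergence_matches_rate(small_auto_genome):
    """Pairwise mismatch between two haplotypes ~= 2*d_hap (outside repeat decay),
    within a generous binomial window."""
    genome, truth, cfg = small_auto_genome
    g1 = [r for r in genome.records if genome.labels[r.id][0] == "g1"]
    frac = mismatch_fraction(g1[0].seq, g1[1].seq)
    # two independent mutation draws; sites hit twice may coincide -> slightly below 2d
    expected = 2 * cfg.d_hap
    sd = np.sqrt(expected * (1 - expected) / cfg.chrom_len)
    assert abs(frac - expected) < 5 * sd + 2 * cfg.d_hap**2 * cfg.chrom_len / cfg.chrom_len


def test_determinism_byte_identical(tmp_path):
    cfg = SimulationConfig(mode="auto", n_groups=1, chrom_len=5_000, repeat_len=100,
                           repeat_copies=10, seed=42)
    out = []
    for run in range(2):
        genome, _ = simulate_polyploid_genome(cfg)
        p = tmp_path / f"g{run}.fa"
        genome.write(p, tmp_path / f"m{run}.tsv")
        out.append(p.read_bytes())
    assert out[0] == out[1]


def test_within_group_closer_than_between(small_auto_genome):
    genome, _, _ = small_auto_genome
    by_group = genome.groups()
    seqs = {r.id: r.seq for r in genome.records}
    within, between = [], []
    ids = list(seqs)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            f = mismatch_fraction(seqs[a], seqs[b])
            (within if genome.labels[a][0] == genome.labels[b][0] else between).append(f)
    assert max(within) < min(between)


def test_allo_subgenome_repeat_density(small_allo_genome):
    """Subgenome repeat k-mers land on every chromosome of their subgenome and are
    >=2x denser there than on the other subgenome."""
    genome, truth, cfg = small_allo_genome
    k = 13
    table = count_kmers_assembly(genome, k)
    subs = genome.subgenome_labels()
    for sub in ("A", "B"):
        motif = truth["repeat_motifs"][sub]
        own = [c for c in subs if subs[c] == sub]
        other = [c for c in subs if subs[c] != sub]
        kmers = {canonical_kmer(motif[i:i + k]) for i in range(len(motif) - k + 1)}
        own_total = other_total = 0
        for km in kmers:
            for c in own:
                own_total += table.count(km, c)
            for c in other:
                other_total += table.count(km, c)
        per_chrom = [sum(table.count(km, c) for km in kmers) for c in own]
        assert all(v > 0 for v in per_chrom)
        assert own_total >= 2 * other_total


def test_config_validation():
    with pytest.raises(SimulationError):
        SimulationConfig(mode="allo", d_hap=0.05, d_sub=0.01)
    with pytest.raises(SimulationError):
        SimulationConfig(mode="diploid", n_haplotypes=4)
    with pytest.raises(SimulationError):
        SimulationConfig(chrom_len=1000, repeat_len=200)
    with pytest.raises(SimulationError):
        SimulationConfig(mode="nope")


def test_genomemap_label_mismatch():
    from tetrasig.io import SequenceRecord
    with pytest.raises(SimulationError, match="disagree"):
        GenomeMap([SequenceRecord("c1", "ACGT")], {"c2": ("g1", 1, None)})


def test_genomemap_file_roundtrip(tmp_path, small_auto_genome):
    genome, _, _ = small_auto_genome
    fa, mp = tmp_path / "g.fa", tmp_path / "g.tsv"
    genome.write(fa, mp)
    back = GenomeMap.from_files(fa, mp)
    assert back.labels == genome.labels
    assert [r.id for r in back.records] == [r.id for r in genome.records]


# ------------------------------------------------------------- reads

def test_read_count_arithmetic(small_auto_genome):
    genome, _, cfg = small_auto_genome
    reads = simulate_reads(genome, 5, read_len=100, seed=0)
    expected_per_chrom = round(5 * cfg.chrom_len / 100)
    assert len(reads) == expected_per_chrom * len(genome.records)


def test_error_free_reads_are_substrings(small_auto_genome):
    genome, _, _ = small_auto_genome
    one = GenomeMap(records=genome.records[:1],
                    labels={genome.records[0].id: genome.labels[genome.records[0].id]})
    reads = simulate_reads(one, 0.5, read_len=80, error_rate=0.0, seed=2)
    seq = genome.records[0].seq
    for _, rseq, _ in reads[:50]:
        assert rseq in seq or revcomp(rseq) in seq


def test_read_len_longer_than_chromosome():
    from tetrasig.io import SequenceRecord
    g = GenomeMap([SequenceRecord("c1", "ACGT" * 20)], {"c1": ("g1", 1, None)})
    with pytest.raises(SimulationError, match="read_len"):
        simulate_reads(g, 1, read_len=100)


def test_reads_deterministic(small_auto_genome):
    genome, _, _ = small_auto_genome
    r1 = simulate_reads(genome, 1, read_len=50, error_rate=0.01, seed=7)
    r2 = simulate_reads(genome, 1, read_len=50, error_rate=0.01, seed=7)
    assert r1 == r2


# ------------------------------------------------------------- VCF simulation

def test_vcf_truth_depth_rule():
    spec = VcfSimSpec(p_low_depth=0.5, p_high_depth=0.0, p_depth_unknown=0.0,
                      p_multiallelic=0.0, p_high_missing=0.0, repeat_fraction=0.0,
                      p_close_pair=0.0)
    res = simulate_vcf(50, spec, seed=1)
    for rec, rule in zip(res.variants.records, res.truth):
        if rec.depth is not None and rec.depth < 5:
            assert rule == "depth"
        else:
            assert rule == "pass"


def test_vcf_truth_close_pairs():
    spec = VcfSimSpec(p_low_depth=0.0, p_high_depth=0.0, p_depth_unknown=0.0,
                      p_multiallelic=0.0, p_high_missing=0.0, repeat_fraction=0.0,
                      p_close_pair=0.4)
    res = simulate_vcf(40, spec, seed=2)
    pos = {}
    for rec in res.variants.records:
        pos.setdefault(rec.chrom, []).append(rec.pos)
    for rec, rule in zip(res.variants.records, res.truth):
        close = any(q != rec.pos and abs(q - rec.pos) < 5 for q in pos[rec.chrom])
        assert (rule == "proximity") == close


def test_vcf_truth_oracle_rederivation():
    """Truth table equals an independent re-derivation from the emitted records."""
    res = simulate_vcf(1000, seed=7)
    pos = {}
    for rec in res.variants.records:
        pos.setdefault(rec.chrom, []).append(rec.pos)
    for rec, rule in zip(res.variants.records, res.truth):
        if rec.depth is None or rec.depth < 5 or rec.depth > 1000:
            expect = "depth"
        elif len(rec.alts) != 1:
            expect = "biallelic"
        elif rec.missing_fraction > 0.40:
            expect = "missing"
        elif res.repeat_mask.contains_1based(rec.chrom, rec.pos):
            expect = "repeat"
        elif any(q != rec.pos and abs(q - rec.pos) < 5 for q in pos[rec.chrom]):
            expect = "proximity"
        else:
            expect = "pass"
        assert rule == expect


def test_vcf_sim_sorted_and_deterministic():
    r1 = simulate_vcf(200, seed=3)
    r2 = simulate_vcf(200, seed=3)
    assert r1.variants.is_sorted()
    assert r1.variants.records == r2.variants.records
    assert r1.truth == r2.truth


def test_vcf_sim_contradictory_spec():
    with pytest.raises(SimulationError):
        VcfSimSpec(p_low_depth=0.6, p_high_depth=0.5)
    with pytest.raises(SimulationError):
        VcfSimSpec(repeat_fraction=1.5)
    with pytest.raises(SimulationError):
        simulate_vcf(0)
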