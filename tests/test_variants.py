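"""VCF reading, per-clone evidence, and the somatic filter cascades."""

import numpy as np
import pytest

from radmut.variants import (
    ALL_RULES,
    CloneCohort,
    CloneSupport,
    VariantRecord,
    apply_mappability_mask,
    attributed_table,
    compute_vaf,
    convert_inversion_breakends,
    filter_indels,
    filter_snvs,
    filter_svs,
    load_bed_mask,
    read_cohort_vcf,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GNOMAD_AF,Number=1,Type=Float,Description="pop AF">
##INFO=<ID=MAPPABLE,Number=0,Type=Flag,Description="mappable">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="sv type">
##INFO=<ID=END,Number=1,Type=Integer,Description="sv end">
##FILTER=<ID=LowQual,Description="low qual">
##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="genotype quality">
##FORMAT=<ID=SR,Number=1,Type=Integer,Description="split reads">
##contig=<ID=chr1,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tPR1A\tPR1B\tPR1C
"""

TREATMENTS = {"PR1A": "proton", "PR1B": "helium", "PR1C": "control"}


def write_vcf(tmp_path, body: str):
    p = tmp_path / "cohort.vcf"
    p.write_text(VCF_HEADER + body)
    return p


def test_read_cohort_vcf_field_mapping(tmp_path):
    body = (
        "chr1\t100\t.\tA\tC\t60\tPASS\tMAPPABLE\tGT:AD:DP:GQ\t"
        "0/1:20,20:40:60\t0/0:40,0:40:60\t0/0:40,0:40:60\n"
    )
    cohort = read_cohort_vcf(write_vcf(tmp_path, body), TREATMENTS)
    assert len(cohort.variants) == 1
    v = cohort.variants[0]
    sup = v.per_clone["PR1A"]
    assert (sup.alt_reads, sup.depth, sup.genotyped) == (20, 40, True)
    assert not v.per_clone["PR1B"].genotyped
    assert v.mappable and v.caller_pass and v.pop_af is None
    assert v.genotyped_clones() == ["PR1A"]


def test_read_cohort_vcf_multiallelic_rows_split(tmp_path):
    body = (
        "chr1\t200\t.\tA\tC,G\t60\tPASS\tMAPPABLE\tGT:AD:DP:GQ\t"
        "0/1:20,15,5:40:60\t0/0:40,0,0:40:60\t0/0:40,0,0:40:60\n"
    )
    cohort = read_cohort_vcf(write_vcf(tmp_path, body), TREATMENTS)
    assert len(cohort.variants) == 2
    assert all(v.multiallelic for v in cohort.variants)
    assert [v.alt for v in cohort.variants] == ["C", "G"]
    assert cohort.variants[0].per_clone["PR1A"].alt_reads == 15
    assert cohort.variants[1].per_clone["PR1A"].alt_reads == 5


def test_read_cohort_vcf_empty_body_and_sample_mismatch(tmp_path):
    cohort = read_cohort_vcf(write_vcf(tmp_path, ""), TREATMENTS)
    assert cohort.variants == []
    with pytest.raises(ValueError, match="samples"):
        read_cohort_vcf(write_vcf(tmp_path, ""), {"X": "control"})


def _sup(alt=0, depth=40, gq=60, genotyped=False, sr=None):
    return CloneSupport(alt_reads=alt, depth=depth, genotype_quality=gq,
                       genotyped=genotyped, split_reads=sr)


def _cohort(variants):
    clones = [{"clone_id": c, "treatment": t} for c, t in TREATMENTS.items()]
    return CloneCohort("TEST", clones, variants)


def _snv(pos=100, alt_reads=20, genotyped_in=("PR1A",), caller_pass=True,
         mappable=True, pop_af=None, multiallelic=False, gq=60):
    per = {c: _sup() for c in TREATMENTS}
    for c in genotyped_in:
        per[c] = _sup(alt=alt_reads, genotyped=True, gq=gq)
    return VariantRecord("chr1", pos, "A", "C", "SNV", caller_pass, per,
                         pop_af=pop_af, mappable=mappable,
                         multiallelic=multiallelic)


def test_compute_vaf():
    v = _snv(alt_reads=20)
    assert compute_vaf(v, "PR1A") == 0.5
    v = _snv(alt_reads=10)
    assert compute_vaf(v, "PR1A") == 0.25
    v = _snv(alt_reads=0, genotyped_in=())
    assert compute_vaf(v, "PR1B") == 0.0
    v.per_clone["PR1B"].depth = 0
    with pytest.raises(ValueError, match="zero depth"):
        compute_vaf(v, "PR1B")


@pytest.mark.parametrize(
    "record,kept",
    [
        (_snv(), True),
        (_snv(caller_pass=False), False),                 # rule 1
        (_snv(mappable=False), False),                    # rule 2
        (_snv(pop_af=0.002), False),                      # rule 3: AF >= 0.1%
        (_snv(pop_af=0.0005), True),                      # below threshold
        (_snv(genotyped_in=("PR1A", "PR1B")), False),     # rule 4
        (_snv(multiallelic=True), False),                 # rule 5
        (_snv(alt_reads=2), True),                        # rule 6 boundary
        (_snv(alt_reads=1), False),                       # rule 6
    ],
)
def test_snv_filter_rules(record, kept):
    out = filter_snvs(_cohort([record]))
    assert (len(out.variants) == 1) == kept
    if kept:
        assert out.variants[0].attributed_clone == record.genotyped_clones()[0]


def _indel(gq=60, others_one=0, others_two=0):
    per = {"PR1A": _sup(alt=20, genotyped=True, gq=gq)}
    others = ["PR1B", "PR1C"]
    per["PR1B"] = _sup(alt=2 if others_two >= 1 else (1 if others_one >= 1 else 0))
    per["PR1C"] = _sup(alt=2 if others_two >= 2 else (1 if others_one >= 2 else 0))
    return VariantRecord("chr1", 50, "AT", "A", "DEL", True, per, mappable=True)


def test_indel_gq_boundary():
    assert len(filter_indels(_cohort([_indel(gq=9)])).variants) == 0
    assert len(filter_indels(_cohort([_indel(gq=10)])).variants) == 1


def test_indel_cross_clone_support_rules():
    """More than two other clones with >=1 read, or more than one with >=2,
    marks a putative germline leak; boundaries are strict."""
    treatments = {f"c{i}": "control" for i in range(6)}
    clones = [{"clone_id": c, "treatment": "control"} for c in treatments]

    def indel(n_one=0, n_two=0):
        per = {"c0": _sup(alt=20, genotyped=True)}
        i = 1
        for _ in range(n_two):
            per[f"c{i}"] = _sup(alt=2); i += 1
        for _ in range(n_one):
            per[f"c{i}"] = _sup(alt=1); i += 1
        while i < 6:
            per[f"c{i}"] = _sup(); i += 1
        return VariantRecord("chr1", 50, "AT", "A", "DEL", True, per)

    def run(v):
        return len(filter_indels(CloneCohort("T", clones, [v])).variants)

    assert run(indel(n_one=3)) == 0       # 3 others with one read: removed
    assert run(indel(n_one=2)) == 1       # exactly 2: retained
    assert run(indel(n_two=2)) == 0       # 2 others with two reads: removed
    assert run(indel(n_two=1)) == 1       # exactly 1: retained


def _sv(sr=5, genotyped_in=("PR1A",)):
    per = {c: _sup(sr=0) for c in TREATMENTS}
    for c in genotyped_in:
        per[c] = _sup(alt=15, genotyped=True, sr=sr)
    return VariantRecord("chr1", 500, "N", "<DEL>", "SV_DEL", True, per,
                         sv_end=5500, mappable=True)


def test_sv_split_read_rule_and_rule4():
    assert len(filter_svs(_cohort([_sv(sr=2)])).variants) == 1
    assert len(filter_svs(_cohort([_sv(sr=1)])).variants) == 0
    assert len(filter_svs(_cohort([_sv(genotyped_in=("PR1A", "PR1B"))])).variants) == 0


def _random_cohort(seed, n=60):
    rng = np.random.default_rng(seed)
    variants = []
    names = list(TREATMENTS)
    for i in range(n):
        per = {}
        geno = rng.random(3) < 0.4
        for j, c in enumerate(names):
            alt = int(rng.integers(0, 30))
            per[c] = CloneSupport(alt_reads=alt, depth=40,
                                  genotype_quality=float(rng.integers(0, 90)),
                                  genotyped=bool(geno[j]))
        variants.append(
            VariantRecord("chr1", 10 + i, "A", "C", "SNV",
                          bool(rng.random() < 0.8), per,
                          pop_af=float(rng.random() * 0.01) if rng.random() < 0.5 else None,
                          mappable=bool(rng.random() < 0.9),
                          multiallelic=bool(rng.random() < 0.2))
        )
    return _cohort(variants)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_filter_idempotent_subset_and_rule_monotonicity(seed):
    cohort = _random_cohort(seed)
    once = filter_snvs(cohort)
    twice = filter_snvs(once)
    key = lambda v: (v.chrom, v.pos, v.ref, v.alt)
    assert [key(v) for v in twice.variants] == [key(v) for v in once.variants]
    all_keys = {key(v) for v in cohort.variants}
    kept = {key(v) for v in once.variants}
    assert kept <= all_keys
    for v in once.variants:
        assert v.attributed_clone is not None
        assert 2 / 40 <= compute_vaf(v, v.attributed_clone) <= 1
    # dropping any one rule yields a superset
    for rule in ALL_RULES:
        relaxed = filter_snvs(cohort, rules=ALL_RULES - {rule})
        assert kept <= {key(v) for v in relaxed.variants}


def test_mappability_mask_half_open_intersection(tmp_path):
    bed = tmp_path / "mask.bed"
    bed.write_text("chr1\t99\t200\n")
    mask = load_bed_mask(bed)
    # 1-based position 100 -> 0-based 99: inside; 1-based 201 -> 200: outside
    inside = _snv(pos=100, mappable=False)
    edge = _snv(pos=200)     # 0-based 199: last covered base
    outside = _snv(pos=201)  # 0-based 200: excluded (half-open)
    out = apply_mappability_mask(_cohort([inside, edge, outside]), mask)
    assert [v.mappable for v in out.variants] == [True, True, False]


def test_breakend_pair_converts_to_inversion():
    per = {c: _sup() for c in TREATMENTS}
    a = VariantRecord("chr1", 1000, "A", "A]chr1:5000]", "BND", True, dict(per))
    b = VariantRecord("chr1", 5000, "T", "T]chr1:1000]", "BND", True, dict(per))
    snv = _snv()
    out = convert_inversion_breakends([a, b, snv])
    invs = [v for v in out if v.var_class == "SV_INV"]
    assert len(invs) == 1
    assert (invs[0].pos, invs[0].sv_end) == (1000, 5000)
    assert snv in out


def test_attributed_table_contents():
    cohort = _cohort([_snv(alt_reads=10)])
    table = attributed_table(filter_snvs(cohort))
    assert list(table["clone"]) == ["PR1A"]
    assert table["vaf"].iloc[0] == 0.25
    assert table["treatment"].iloc[0] == "proton"


def test_invariant_validation_errors():
    with pytest.raises(ValueError, match="alt_reads > depth"):
        VariantRecord("chr1", 1, "A", "C", "SNV", True,
                      {"PR1A": CloneSupport(alt_reads=50, depth=40)})
    with pytest.raises(ValueError, match="position"):
        VariantRecord("chr1", 0, "A", "C", "SNV", True, {})
    with pytest.raises(ValueError, match="duplicate"):
        CloneCohort("T", [{"clone_id": "a", "treatment": "x"}] * 2, [])
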