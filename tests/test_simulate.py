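"""Synthetic cohort generator: determinism, truth consistency, VAF model."""

import numpy as np
import pandas as pd
import pytest

from radmut.classify import GenomeAccessor, classify_indel_83, classify_snv_96
from radmut.signatures import cosine_similarity
from radmut.simulate import (
    CloneDesign,
    ClusterSpec,
    GenomeIndex,
    SimDesign,
    make_toy_genome,
    make_truth_signatures,
    simulate_clone,
    simulate_cohort,
    write_fasta,
)
from radmut.variants import VariantRecord, filter_cohort, read_cohort_vcf


def test_toy_genome_determinism_and_length():
    a = make_toy_genome({"chr1": 100_000}, seed=1)
    b = make_toy_genome({"chr1": 100_000}, seed=1)
    assert a == b
    assert len(a["chr1"]) == 100_000
    c = make_toy_genome({"chr1": 100_000}, seed=2)
    assert c != a
    with pytest.raises(ValueError):
        make_toy_genome({"chr1": 0}, seed=1)


def test_toy_genome_gc_content_and_trinucleotides():
    seqs = make_toy_genome({"chr1": 100_000}, gc_fraction=0.5, seed=3)
    s = seqs["chr1"]
    gc = (s.count("G") + s.count("C")) / len(s)
    assert abs(gc - 0.5) < 0.02
    tris = {s[i:i + 3] for i in range(len(s) - 2)}
    assert len(tris) == 64


def test_fasta_round_trip(tmp_path):
    seqs = make_toy_genome({"chrA": 5_000}, seed=9)
    path = tmp_path / "g.fa"
    write_fasta(seqs, path)
    from pyfaidx import Fasta

    fa = Fasta(str(path))
    assert str(fa["chrA"][:]) == seqs["chrA"]


@pytest.fixture(scope="module")
def mini_world():
    seqs = make_toy_genome({"chr1": 400_000, "chr2": 200_000}, seed=17)
    return seqs, GenomeIndex(seqs), make_truth_signatures()


def test_single_spectrum_clone_reproduces_spectrum(mini_world):
    seqs, index, spectra = mini_world
    clone = CloneDesign("S1", "A549", "control", n_snv=10_000, n_indel=0,
                        del_ins_ratio=1.0, exposures={"SBS_oxid": 1.0},
                        clusters=[], sv_counts={})
    variants = simulate_clone(index, clone, spectra, seed=5)
    counts = pd.Series(0.0, index=spectra.index)
    for v in variants:
        counts[v.category] += 1
    assert cosine_similarity(counts.values, spectra["SBS_oxid"].values) >= 0.99


def test_vaf_binomial_means_by_ploidy(mini_world):
    seqs, index, spectra = mini_world
    rng = np.random.default_rng(0)
    from radmut.simulate import _reads

    for ploidy, mean in [("diploid-het", 0.5), ("haploid", 1.0)]:
        vafs = []
        for _ in range(5000):
            alt, depth = _reads(rng, 40, mean)
            vafs.append(alt / depth)
        assert abs(np.mean(vafs) - mean) < 0.01 or mean == 0.5
    # diploid draws are conditioned on >= 2 alt reads; at depth 40 the
    # truncation shifts the mean by far less than 0.01
    vafs = [a / d for a, d in ( _reads(rng, 40, 0.5) for _ in range(5000))]
    assert abs(np.mean(vafs) - 0.5) < 0.01


def test_injected_shower_is_recovered_as_kataegis(mini_world):
    seqs, index, spectra = mini_world
    clone = CloneDesign("K1", "A549", "helium", n_snv=50, n_indel=0,
                        del_ins_ratio=1.0, exposures={"SBS_oxid": 1.0},
                        clusters=[ClusterSpec(6, 3000, "C>T")], sv_counts={})
    variants = simulate_clone(index, clone, spectra, seed=8)
    from radmut.clusters import find_clusters

    clustered = [v for v in variants if v.cluster_id]
    assert len(clustered) == 6
    by_chrom = {}
    for v in variants:
        if v.var_class == "SNV":
            by_chrom.setdefault(v.chrom, []).append(v.pos)
    cl = find_clusters(by_chrom, "K1")
    assert any(c.size >= 6 and c.cluster_class == "kataegis_like"
               for c in cl.components)


def test_cluster_members_have_requested_class(mini_world):
    seqs, index, spectra = mini_world
    from radmut.classify import classify_snv_6

    clone = CloneDesign("K2", "A549", "helium", n_snv=0, n_indel=0,
                        del_ins_ratio=1.0, exposures={"SBS_oxid": 1.0},
                        clusters=[ClusterSpec(2, 800, "T>C")], sv_counts={})
    variants = simulate_clone(index, clone, spectra, seed=3)
    assert all(classify_snv_6(v.ref, v.alt) == "T>C" for v in variants)


def test_design_validation():
    with pytest.raises(ValueError, match="sum"):
        CloneDesign("x", "A", "control", 10, 0, 1.0, {"SBS_oxid": 0.7})
    good = CloneDesign("x", "A", "control", 10, 0, 1.0, {"SBS_oxid": 1.0})
    with pytest.raises(ValueError, match="duplicate"):
        SimDesign(layout={"chr1": 1000}, clones=[good, good])


def test_cohort_outputs_and_truth_conservation(small_sim):
    sim = small_sim
    assert len(sim.vcf_paths) == 2  # one VCF per cell line
    truth = sim.truth
    assert truth["clone"].nunique() == 6
    for line, path in sim.vcf_paths.items():
        body = [l for l in path.read_text().splitlines()
                if l and not l.startswith("#")]
        expected = (truth.cell_line == line).sum() + sim.n_contaminants[line]
        assert len(body) == expected


def test_filters_remove_exactly_the_contaminants(small_sim):
    sim = small_sim
    design = pd.read_csv(sim.design_path, sep="\t")
    for line, path in sim.vcf_paths.items():
        sub = design[design.cell_line == line]
        cohort = read_cohort_vcf(path, dict(zip(sub.clone_id, sub.treatment)),
                                 cell_line=line)
        filtered = filter_cohort(cohort)
        n_truth = (sim.truth.cell_line == line).sum()
        assert len(filtered.variants) == n_truth
        # attributed clone matches truth record-for-record
        truth_keys = {(r.chrom, r.pos, r.ref, r.alt): r.clone
                      for r in sim.truth[sim.truth.cell_line == line].itertuples()}
        for v in filtered.variants:
            assert truth_keys[(v.chrom, v.pos, v.ref, v.alt)] == v.attributed_clone


def test_simulation_is_byte_deterministic(small_design, tmp_path):
    a = simulate_cohort(small_design, tmp_path / "a", seed=77)
    b = simulate_cohort(small_design, tmp_path / "b", seed=77)
    for line in a.vcf_paths:
        assert a.vcf_paths[line].read_text() == b.vcf_paths[line].read_text()
    assert a.fasta_path.read_text() == b.fasta_path.read_text()
    c = simulate_cohort(small_design, tmp_path / "c", seed=78)
    assert c.truth.shape != a.truth.shape or not c.truth.equals(a.truth)


def test_round_trip_classification_of_truth(small_sim):
    """classify(simulate) recovers the true category for all SNVs and
    >= 99% of indels."""
    genome = GenomeAccessor(small_sim.genome)
    snv_bad = ind_bad = ind_tot = 0
    for r in small_sim.truth.itertuples():
        if r.var_class == "SNV":
            rec = VariantRecord(r.chrom, r.pos, r.ref, r.alt, "SNV", True, {})
            assert classify_snv_96(rec, genome) == r.category
        elif r.var_class in ("INS", "DEL"):
            rec = VariantRecord(r.chrom, r.pos, r.ref, r.alt, r.var_class,
                                True, {})
            ind_tot += 1
            if classify_indel_83(rec, genome) != r.category:
                ind_bad += 1
    assert ind_tot > 0 and ind_bad / ind_tot <= 0.01
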