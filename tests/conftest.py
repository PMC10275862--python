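import numpy as np
import pandas as pd
import pytest

from radmut.classify import GenomeAccessor
from radmut.simulate import (
    CloneDesign,
    ClusterSpec,
    SimDesign,
    default_design,
    make_toy_genome,
    make_truth_signatures,
    simulate_catalog,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def toy_genome():
    """Small deterministic genome for classification tests."""
    return make_toy_genome({"chr1": 60_000, "chr2": 40_000}, seed=101)


@pytest.fixture(scope="session")
def genome(toy_genome):
    return GenomeAccessor(toy_genome)


@pytest.fixture(scope="session")
def truth_signatures():
    return make_truth_signatures()


@pytest.fixture(scope="session")
def small_design():
    """Compact 6-clone cohort over a 2 Mb genome for fast I/O round trips."""
    clones = []
    plan = [("control", 1), ("helium", 1), ("proton", 1)]
    for line, ploidy in (("A549", "diploid-het"), ("HAP1", "haploid")):
        for treatment, n in plan:
            for i in range(n):
                clones.append(
                    CloneDesign(
                        clone_id=f"{line}_{treatment[:2].upper()}{i + 1}",
                        cell_line=line,
                        treatment=treatment,
                        n_snv=150,
                        n_indel=40,
                        del_ins_ratio=2.0,
                        exposures={"SBS_oxid": 0.5, "SBS_clock": 0.3,
                                   "SBS_bulky": 0.2},
                        clusters=[ClusterSpec(2, 800)],
                        sv_counts={"DEL": 2, "INS": 1, "DUP": 1, "INV": 1},
                        sv_len_log10=(3.2, 0.3),
                        ploidy=ploidy,
                    )
                )
    return SimDesign(layout={"chr1": 1_200_000, "chr2": 800_000}, clones=clones)


@pytest.fixture(scope="session")
def small_sim(small_design, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_sim")
    return simulate_cohort(small_design, out, seed=404)


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The full 21-clone study-shaped cohort (shared across end-to-end tests)."""
    out = tmp_path_factory.mktemp("default_sim")
    return simulate_cohort(default_design(), out, seed=20)


@pytest.fixture(scope="session")
def recovery_catalog(truth_signatures):
    """21-clone multinomial catalog from the three truth spectra with sparse
    exposures and 2,000-5,000 mutations per clone, plus its ground truth."""
    rng = np.random.default_rng(55)
    clones = [f"c{i:02d}" for i in range(21)]
    E = pd.DataFrame(
        rng.dirichlet([0.5] * 3, size=21).T,
        index=truth_signatures.columns, columns=clones,
    )
    burdens = pd.Series(rng.integers(2000, 5001, size=21), index=clones)
    catalog = simulate_catalog(truth_signatures, E, burdens, seed=56)
    return {"catalog": catalog, "exposures": E, "burdens": burdens}
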