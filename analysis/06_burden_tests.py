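"""Randomization tests of mutation burdens, deletion:insertion balance,
signature exposures and clustered-mutation counts between treatment
groups, with Benjamini-Hochberg correction within each statistic family.

Labels of all 21 clones are shuffled globally (100,000 iterations by
default); both one-sided empirical p-values p = (r+1)/(n+1) are computed
per comparison and min(p_ge, p_le) is reported as the headline p.
"""

import argparse
from pathlib import Path

import pandas as pd

from radmut.burden import Comparison, adjust_results, del_ins_ratio, permutation_test
from radmut.catalogs import read_count_matrix


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="scratch/cohort")
    ap.add_argument("--results", default="results")
    ap.add_argument("--iters", type=int, default=100_000)
    ap.add_argument("--seed", type=int, default=7)
    args = ap.parse_args()

    res = Path(args.results)
    design = pd.read_csv(Path(args.cohort) / "design.tsv", sep="\t")
    clustered = pd.read_csv(res / "05_clustered_per_clone.tsv", sep="\t")
    m96 = read_count_matrix(res / "03_sbs96_matrix.tsv")
    m83 = read_count_matrix(res / "03_id83_matrix.tsv")
    exposures = read_count_matrix(res / "04_exposures_own_clones.tsv")

    labels = design.set_index("clone_id")[["cell_line", "treatment"]]
    labels.index.name = "clone"

    del_rows = m83.index.str.contains(":Del:")
    stats = {
        "snv_burden": m96.sum(),
        "indel_burden": m83.sum(),
        "deletion_burden": m83.loc[del_rows].sum(),
        "insertion_burden": m83.loc[~del_rows].sum(),
        "ids_del_ins_ratio": pd.Series({
            c: del_ins_ratio(int(m83.loc[del_rows, c].sum()),
                             int(m83.loc[~del_rows, c].sum())).ratio
            for c in m83.columns
        }),
        "clustered_mutations": clustered.set_index("clone")["clustered_mutations"],
    }
    families = {name: "burdens" for name in stats}
    for sig in exposures.index:
        stats[f"exposure_{sig}"] = exposures.loc[sig]
        families[f"exposure_{sig}"] = "SNV-signatures"

    comparisons = [Comparison("treatment", a, b)
                   for a, b in (("proton", "control"), ("helium", "control"),
                                ("proton", "helium"))]
    results = []
    for name, values in stats.items():
        values = values.reindex(labels.index).astype(float)
        results += permutation_test(values, labels, comparisons,
                                    n_iter=args.iters, seed=args.seed,
                                    statistic_name=name)
    adjust_results(results, family_of=lambda r: families[r.statistic_name])
    out = pd.DataFrame(
        [{"statistic": r.statistic_name, "group_a": r.group_a,
          "group_b": r.group_b, "observed_diff": round(r.observed_diff, 4),
          "p_ge": r.p_ge, "p_le": r.p_le, "p": r.p_min, "q": round(r.q, 4)}
         for r in results]
    )
    out.to_csv(res / "06_permutation_results.tsv", sep="\t", index=False)
    flagged = out[out.p <= 0.1].sort_values("p")
    print(f"{len(out)} comparisons; {len(flagged)} with unadjusted p <= 0.1:")
    print(flagged.to_string(index=False))


if __name__ == "__main__":
    main()
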