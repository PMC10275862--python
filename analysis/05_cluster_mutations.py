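"""Detect clustered point mutations (inter-mutation distance < 1 kb,
graph components), split omikli-like pairs from kataegis-like showers
(size > 5), and compare the clustered 6-class spectrum with the global
spectrum.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from radmut.burden import compare_lengths
from radmut.classify import classify_snv_6
from radmut.clusters import (
    classify_components,
    clustered_spectrum,
    find_clusters,
    intermutation_distances,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="scratch/cohort")
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    cohort_dir = Path(args.cohort)
    design = pd.read_csv(cohort_dir / "design.tsv", sep="\t")
    clone_rows, dist_rows = [], []
    spectra = {"clustered": None, "global": None}
    agg_clustered = {}
    agg_global = {}
    for line in design.cell_line.unique():
        table = pd.read_csv(cohort_dir / f"{line}.filtered.tsv", sep="\t")
        snvs = table[table.var_class == "SNV"]
        for clone, g in snvs.groupby("clone"):
            treatment = g.treatment.iloc[0]
            by_chrom = {c: list(cg.pos) for c, cg in g.groupby("chrom")}
            cl = find_clusters(by_chrom, clone)
            counts = classify_components(cl.components)
            clone_rows.append(
                {"clone": clone, "cell_line": line, "treatment": treatment,
                 "clustered_mutations": cl.clustered_mutation_count,
                 "omikli_like": counts["omikli_like"],
                 "kataegis_like": counts["kataegis_like"]}
            )
            for d in intermutation_distances(cl.components):
                dist_rows.append({"clone": clone, "treatment": treatment,
                                  "distance_bp": d})
            alleles = {(r.chrom, r.pos): (r.ref, r.alt) for r in g.itertuples()}
            spec = clustered_spectrum(cl.components, alleles)
            for k, v in spec.items():
                agg_clustered[k] = agg_clustered.get(k, 0) + v
            for r in g.itertuples():
                k = classify_snv_6(r.ref, r.alt)
                agg_global[k] = agg_global.get(k, 0) + 1

    res = Path(args.results)
    res.mkdir(exist_ok=True)
    per_clone = pd.DataFrame(clone_rows)
    per_clone.to_csv(res / "05_clustered_per_clone.tsv", sep="\t", index=False)
    dists = pd.DataFrame(dist_rows)
    dists.to_csv(res / "05_intermutation_distances.tsv", sep="\t", index=False)
    spec_df = pd.DataFrame({
        "clustered": pd.Series(agg_clustered) / max(sum(agg_clustered.values()), 1),
        "global": pd.Series(agg_global) / max(sum(agg_global.values()), 1),
    }).round(4)
    spec_df.to_csv(res / "05_clustered_vs_global_spectrum.tsv", sep="\t",
                   index_label="MutationType")

    print(per_clone.groupby("treatment")[
        ["clustered_mutations", "omikli_like", "kataegis_like"]].sum().to_string())
    he = np.log10(dists[dists.treatment == "helium"].distance_bp)
    co = np.log10(dists[dists.treatment == "control"].distance_bp)
    t, p = compare_lengths(he, co)
    print(f"log10 inter-mutation distance helium vs control: t={t:.2f}, p={p:.3g}")
    print("Clustered vs global 6-class spectrum:")
    print(spec_df.to_string())


if __name__ == "__main__":
    main()
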