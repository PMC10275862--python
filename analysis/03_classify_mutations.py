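"""Classify the filtered mutations: SBS96 / 6-class SNV spectra, ID83
indel spectrum, SV classes with lengths; write the count matrices that
feed signature extraction and burden statistics.
"""

import argparse
from pathlib import Path

import pandas as pd
from pyfaidx import Fasta

from radmut.classify import (
    GenomeAccessor,
    build_count_matrix,
    classify_indel_83,
    classify_snv_96,
    classify_sv,
    collapse_96_to_6,
)
from radmut.variants import VariantRecord


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", default="scratch/cohort")
    ap.add_argument("--results", default="results")
    args = ap.parse_args()

    cohort_dir = Path(args.cohort)
    genome = GenomeAccessor(Fasta(str(cohort_dir / "genome.fa")))
    design = pd.read_csv(cohort_dir / "design.tsv", sep="\t")
    snv96, id83, sv_rows = [], [], []
    for line in design.cell_line.unique():
        table = pd.read_csv(cohort_dir / f"{line}.filtered.tsv", sep="\t")
        for r in table.itertuples():
            rec = VariantRecord(r.chrom, int(r.pos), r.ref, r.alt, r.var_class,
                                True, {},
                                sv_end=None if pd.isna(r.sv_end) else int(r.sv_end))
            if r.var_class == "SNV":
                snv96.append((r.clone, classify_snv_96(rec, genome)))
            elif r.var_class in ("INS", "DEL"):
                id83.append((r.clone, classify_indel_83(rec, genome)))
            else:
                s = classify_sv(rec)
                sv_rows.append({"clone": r.clone, "cell_line": line,
                                "sv_class": s.sv_class, "length": s.length})

    clone_order = list(design.clone_id)
    res = Path(args.results)
    res.mkdir(exist_ok=True)
    m96 = build_count_matrix(snv96, 96, clone_order)
    m96.to_csv(res / "03_sbs96_matrix.tsv", sep="\t", index_label="MutationType")
    m83 = build_count_matrix(id83, 83, clone_order)
    m83.to_csv(res / "03_id83_matrix.tsv", sep="\t", index_label="MutationType")
    m6 = m96.groupby(collapse_96_to_6).sum()
    (m6 / m6.sum()).round(4).to_csv(res / "03_six_class_fractions.tsv", sep="\t",
                                    index_label="MutationType")
    pd.DataFrame(sv_rows).to_csv(res / "03_sv_lengths.tsv", sep="\t", index=False)
    print(f"SBS96 matrix {m96.shape}, column sums "
          f"{int(m96.sum().min())}-{int(m96.sum().max())} SNVs/clone")
    print(f"ID83 matrix {m83.shape}; {len(sv_rows)} SVs")
    print("6-class fraction means:",
          (m6.sum(axis=1) / m6.values.sum()).round(3).to_dict())


if __name__ == "__main__":
    main()
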