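"""Mutation category catalogs and reference-signature I/O.

Category orders follow the COSMIC layout: SBS96 rows ordered by pyrimidine
mutation type (C>A, C>G, C>T, T>A, T>C, T>G), then 5' flank, then 3' flank;
ID83 rows ordered as 1-bp deletions (C, T channels), 1-bp insertions,
longer deletions at repeats, longer insertions at repeats, and finally
microhomology-flanked deletions.
"""

from __future__ import annotations

import pandas as pd

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SBS6_CATEGORIES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def _sbs96() -> list[str]:
    labels = []
    for sub in SBS6_CATEGORIES:
        for five in BASES:
            for three in BASES:
                labels.append(f"{five}[{sub}]{three}")
    return labels


SBS96_CATEGORIES: tuple[str, ...] = tuple(_sbs96())


def _id83() -> list[str]:
    labels = []
    # 1-bp deletions / insertions in pyrimidine channels (A->T, G->C folded);
    # the trailing number is the COSMIC homopolymer bin: for deletions the run
    # length including the deleted base minus one (capped at 5 = "6+"), for
    # insertions the number of identical bases already present (capped at 5).
    for base in ("C", "T"):
        labels += [f"1:Del:{base}:{i}" for i in range(6)]
    for base in ("C", "T"):
        labels += [f"1:Ins:{base}:{i}" for i in range(6)]
    # >=2-bp deletions / insertions at tandem repeats; R bins count repeat
    # units analogously (deletions include the deleted copy, minus one).
    for length in (2, 3, 4, 5):
        labels += [f"{length}:Del:R:{i}" for i in range(6)]
    for length in (2, 3, 4, 5):
        labels += [f"{length}:Ins:R:{i}" for i in range(6)]
    # deletions with flanking microhomology
    for length, max_mh in ((2, 1), (3, 2), (4, 3), (5, 5)):
        labels += [f"{length}:Del:M:{m}" for m in range(1, max_mh + 1)]
    return labels


ID83_CATEGORIES: tuple[str, ...] = tuple(_id83())
assert len(ID83_CATEGORIES) == 83

SV_CLASSES = ("DEL", "INS", "DUP", "INV")

SCHEME_CATEGORIES = {
    6: SBS6_CATEGORIES,
    96: SBS96_CATEGORIES,
    83: ID83_CATEGORIES,
}


def read_reference_catalog(path) -> pd.DataFrame:
    """Read a reference signature catalog TSV.

    First column holds category labels (SBS96 or ID83 row convention),
    remaining columns are named signatures. Returns a DataFrame indexed by
    category with each signature column normalized to sum to 1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"reference catalog {path} has no signature columns")
    if (df.values < 0).any():
        raise ValueError("reference catalog contains negative entries")
    return df / df.sum(axis=0)


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a categories x clones count matrix as TSV (COSMIC layout)."""
    matrix.to_csv(path, sep="\t", index_label="MutationType")


def read_count_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
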