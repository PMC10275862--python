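"""Mutation classification: 6- and 96-class SNV spectra, the 83-class
indel scheme, SV classes, and count-matrix construction.

SNVs are tallied strand-symmetrically on the pyrimidine strand: a purine
reference base is reverse-complemented together with its context. Indels
are left-normalized, then binned by length, tandem-repeat content of the
reference, and (for non-repeat deletions) flanking microhomology, matching
the standard 83-category catalog row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalogs import (
    BASES,
    COMPLEMENT,
    ID83_CATEGORIES,
    SBS6_CATEGORIES,
    SBS96_CATEGORIES,
    SCHEME_CATEGORIES,
    revcomp,
)
from .variants import DEL, INS, SNV, CloneCohort, VariantRecord

PURINES = {"A", "G"}


class GenomeAccessor:
    """Uniform 1-based genome slicing over a pyfaidx.Fasta or a plain dict
    of chromosome strings."""

    def __init__(self, genome):
        self._g = genome

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Inclusive 1-based [start, end]."""
        if start < 1:
            raise ValueError(f"flank before contig start at {chrom}:{start}")
        if isinstance(self._g, dict):
            seq = self._g[chrom][start - 1 : end]
        else:
            seq = str(self._g[chrom][start - 1 : end])
        if len(seq) < end - start + 1:
            raise ValueError(f"flank beyond contig end at {chrom}:{end}")
        return seq.upper()

    def length(self, chrom: str) -> int:
        return len(self._g[chrom])

    def chromosomes(self) -> list[str]:
        return list(self._g.keys())


def classify_snv_6(ref: str, alt: str) -> str:
    """Collapse an SNV to one of the six pyrimidine-strand classes."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"non-ACGT allele {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref == alt")
    if ref in PURINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    label = f"{ref}>{alt}"
    assert label in SBS6_CATEGORIES
    return label


def classify_snv_96(record: VariantRecord, genome: GenomeAccessor) -> str:
    """SBS96 label ``X[R>A]Y`` from the trinucleotide context around an SNV."""
    tri = genome.fetch(record.chrom, record.pos - 1, record.pos + 1)
    if tri[1] != record.ref.upper():
        raise ValueError(
            f"reference mismatch at {record.chrom}:{record.pos}: "
            f"genome {tri[1]} vs record {record.ref}"
        )
    return sbs96_label(tri, record.alt)


def sbs96_label(trinucleotide: str, alt: str) -> str:
    tri, alt = trinucleotide.upper(), alt.upper()
    if tri[1] in PURINES:
        tri, alt = revcomp(tri), COMPLEMENT[alt]
    label = f"{tri[0]}[{tri[1]}>{alt}]{tri[2]}"
    if label not in SBS96_CATEGORIES:
        raise ValueError(f"bad SBS96 label {label}")
    return label


def collapse_96_to_6(label96: str) -> str:
    return label96[2:5]


# --- indels ---------------------------------------------------------------

@dataclass
class NormalizedIndel:
    kind: str      # "Ins" or "Del"
    seq: str       # inserted or deleted sequence
    start: int     # 1-based first deleted base (Del) / first base after anchor (Ins)


def _trim_alleles(ref: str, alt: str) -> tuple[str, str, int]:
    """Strip shared suffix then prefix; return (ref', alt', prefix_len)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    k = 0
    while k < min(len(ref), len(alt)) and ref[k] == alt[k]:
        k += 1
    return ref[k:], alt[k:], k


def normalize_indel(record: VariantRecord, genome: GenomeAccessor,
                    max_len: int = 500) -> NormalizedIndel:
    """Reduce a VCF-anchored indel to its inserted/deleted sequence and
    left-normalize (shift to the smallest start with an identical
    haplotype) so repeat counting is unambiguous."""
    ref, alt = record.ref.upper(), record.alt.upper()
    page = genome.fetch(record.chrom, record.pos, record.pos + len(ref) - 1)
    if page != ref:
        raise ValueError(
            f"reference mismatch at {record.chrom}:{record.pos}: {page} vs {ref}"
        )
    r, a, k = _trim_alleles(ref, alt)
    if r and a:
        raise ValueError(f"not a clean indel: {ref}>{alt}")
    seq = r or a
    kind = "Del" if r else "Ins"
    if len(seq) > max_len:
        raise ValueError(f"indel longer than configured maximum ({len(seq)} > {max_len})")
    start = record.pos + k  # first deleted base, or first base displaced by insertion
    # rotate leftwards while the preceding reference base equals the last
    # base of the event sequence
    while start > 1 and genome.fetch(record.chrom, start - 1, start - 1) == seq[-1]:
        seq = seq[-1] + seq[:-1]
        start -= 1
    return NormalizedIndel(kind=kind, seq=seq, start=start)


def _count_copies_right(genome: GenomeAccessor, chrom: str, start: int, seq: str) -> int:
    """Consecutive exact copies of seq in the reference starting at start."""
    n, L = 0, len(seq)
    pos = start
    clen = genome.length(chrom)
    while pos + L - 1 <= clen and genome.fetch(chrom, pos, pos + L - 1) == seq:
        n += 1
        pos += L
    return n


def _microhomology(genome: GenomeAccessor, chrom: str, start: int, seq: str) -> int:
    """Longest flanking identity of a deleted segment: prefix of the deleted
    sequence matching immediately after it, or suffix matching immediately
    before it (capped at len(seq) - 1)."""
    L = len(seq)
    clen = genome.length(chrom)
    right = 0
    for k in range(1, L):
        end = start + L + k - 1
        if end > clen or genome.fetch(chrom, start + L, end) != seq[:k]:
            break
        right = k
    left = 0
    for k in range(1, L):
        s = start - k
        if s < 1 or genome.fetch(chrom, s, start - 1) != seq[-k:]:
            break
        left = k
    return max(left, right)


_MH_CAP = {2: 1, 3: 2, 4: 3, 5: 5}


def classify_indel_83(record: VariantRecord, genome: GenomeAccessor) -> str:
    """ID83 category of a small insertion or deletion.

    1-bp events are binned by the homopolymer run of the affected base
    (pyrimidine-folded channel labels); longer events by tandem-repeat unit
    count of the event sequence; deletions with a single copy and flanking
    microhomology go to the microhomology bins.
    """
    ni = normalize_indel(record, genome)
    L = len(ni.seq)
    lbin = min(L, 5)
    if L == 1:
        base = ni.seq
        channel = COMPLEMENT[base] if base in PURINES else base
        if ni.kind == "Del":
            run = _count_copies_right(genome, record.chrom, ni.start, base)
            label = f"1:Del:{channel}:{min(run, 6) - 1}"
        else:
            existing = _count_copies_right(genome, record.chrom, ni.start, base)
            label = f"1:Ins:{channel}:{min(existing, 5)}"
    elif ni.kind == "Ins":
        existing = _count_copies_right(genome, record.chrom, ni.start, ni.seq)
        label = f"{lbin}:Ins:R:{min(existing, 5)}"
    else:
        copies = _count_copies_right(genome, record.chrom, ni.start, ni.seq)
        if copies >= 2:
            label = f"{lbin}:Del:R:{min(copies, 6) - 1}"
        else:
            mh = _microhomology(genome, record.chrom, ni.start, ni.seq)
            if mh >= 1:
                label = f"{lbin}:Del:M:{min(mh, _MH_CAP[lbin])}"
            else:
                label = f"{lbin}:Del:R:0"
    assert label in ID83_CATEGORIES, label
    return label


# --- structural variants --------------------------------------------------

@dataclass
class SvSummary:
    clone_id: str | None
    sv_class: str  # DEL, INS, DUP, INV
    length: int | None


def classify_sv(record: VariantRecord) -> SvSummary:
    mapping = {"SV_DEL": "DEL", "SV_INS": "INS", "SV_DUP": "DUP", "SV_INV": "INV"}
    if record.var_class not in mapping:
        raise ValueError(f"unknown SV type {record.var_class!r}")
    cls = mapping[record.var_class]
    if cls == "INS":
        if record.alt.startswith("<") or len(record.alt) <= len(record.ref):
            length = None
        else:
            length = len(record.alt) - len(record.ref)
    else:
        length = record.sv_end - record.pos
    return SvSummary(clone_id=record.attributed_clone, sv_class=cls, length=length)


# --- count matrices -------------------------------------------------------

def build_count_matrix(
    labeled: list[tuple[str, str]], scheme: int, clone_ids: list[str] | None = None
) -> pd.DataFrame:
    """Tally (clone_id, category) pairs into a categories x clones matrix.

    Zero-count categories and clones are retained so matrices from different
    cohorts align row-for-row with the reference catalogs.
    """
    cats = SCHEME_CATEGORIES[scheme]
    if clone_ids is None:
        clone_ids = sorted({c for c, _ in labeled})
    m = pd.DataFrame(0, index=list(cats), columns=list(clone_ids), dtype=int)
    for clone, cat in labeled:
        if cat not in m.index:
            raise ValueError(f"category {cat!r} not in the {scheme}-class scheme")
        m.loc[cat, clone] += 1
    return m


def classify_cohort_snvs(cohort: CloneCohort, genome: GenomeAccessor) -> list[tuple[str, str]]:
    """(clone, SBS96 label) for every attributed SNV of a filtered cohort."""
    out = []
    for v in cohort.variants:
        if v.var_class == SNV and v.attributed_clone:
            out.append((v.attributed_clone, classify_snv_96(v, genome)))
    return out


def classify_cohort_indels(cohort: CloneCohort, genome: GenomeAccessor) -> list[tuple[str, str]]:
    out = []
    for v in cohort.variants:
        if v.var_class in (INS, DEL) and v.attributed_clone:
            out.append((v.attributed_clone, classify_indel_83(v, genome)))
    return out
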