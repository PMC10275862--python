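"""Reading multi-sample VCFs and the somatic filter cascades.

One cohort = all clonally expanded cultures of a single cell line, jointly
genotyped so that a clone-private mutation is genotyped in exactly one
sample. Filters retain clone-private, well-supported, mappable, rare
variants; indels and SVs carry extra evidence rules on top of the six core
rules applied to SNVs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from cyvcf2 import VCF

SNV = "SNV"
INS = "INS"
DEL = "DEL"
SV_CLASSES = ("SV_DEL", "SV_INS", "SV_DUP", "SV_INV")

ALL_RULES = frozenset({1, 2, 3, 4, 5, 6})


@dataclass
class CloneSupport:
    """Per-clone read evidence for one variant."""

    alt_reads: int = 0
    depth: int = 0
    genotype_quality: float | None = None
    genotyped: bool = False
    split_reads: int | None = None


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based (VCF convention)
    ref: str
    alt: str
    var_class: str
    caller_pass: bool
    per_clone: dict[str, CloneSupport]
    sv_end: int | None = None
    pop_af: float | None = None
    mappable: bool = True
    multiallelic: bool = False
    attributed_clone: str | None = None
    raw_line: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.var_class == SNV and (
            len(self.ref) != 1 or len(self.alt) != 1 or self.ref == self.alt
        ):
            raise ValueError(f"not an SNV: {self.ref}>{self.alt}")
        if self.var_class in SV_CLASSES and self.sv_end is not None and self.sv_end < self.pos:
            raise ValueError("sv_end must be >= pos")
        for clone, sup in self.per_clone.items():
            if sup.alt_reads > sup.depth:
                raise ValueError(
                    f"alt_reads > depth for clone {clone} at {self.chrom}:{self.pos}"
                )

    def genotyped_clones(self) -> list[str]:
        return [c for c, s in self.per_clone.items() if s.genotyped]


@dataclass
class CloneCohort:
    cell_line: str
    clones: list[dict]  # {clone_id, treatment}
    variants: list[VariantRecord] = field(default_factory=list)

    def __post_init__(self):
        ids = [c["clone_id"] for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate clone ids")
        known = set(ids)
        for v in self.variants:
            extra = set(v.per_clone) - known
            if extra:
                raise ValueError(f"per-clone evidence for undeclared clones: {extra}")

    @property
    def clone_ids(self) -> list[str]:
        return [c["clone_id"] for c in self.clones]

    def treatment_of(self, clone_id: str) -> str:
        for c in self.clones:
            if c["clone_id"] == clone_id:
                return c["treatment"]
        raise KeyError(clone_id)


@dataclass(frozen=True)
class FormatKeys:
    """Names of the per-sample FORMAT fields to read."""

    allele_depth: str = "AD"
    depth: str = "DP"
    genotype_quality: str = "GQ"
    split_reads: str = "SR"


@dataclass(frozen=True)
class InfoKeys:
    pop_af: str = "GNOMAD_AF"
    mappable: str = "MAPPABLE"
    sv_type: str = "SVTYPE"
    sv_end: str = "END"


def _var_class(ref: str, alt: str, svtype: str | None) -> str:
    if svtype is not None:
        mapping = {"DEL": "SV_DEL", "INS": "SV_INS", "DUP": "SV_DUP", "INV": "SV_INV",
                   "BND": "BND"}
        if svtype not in mapping:
            raise ValueError(f"unknown SV type {svtype!r}")
        return mapping[svtype]
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    if len(ref) > len(alt):
        return DEL
    return INS


def read_cohort_vcf(
    path,
    clone_treatments: dict[str, str],
    cell_line: str | None = None,
    format_keys: FormatKeys = FormatKeys(),
    info_keys: InfoKeys = InfoKeys(),
) -> CloneCohort:
    """Read a jointly genotyped multi-sample VCF into a :class:`CloneCohort`.

    Emits one record per row per alternate allele; rows with several ALT
    alleles are flagged multiallelic. Missing annotations stay missing
    (``pop_af=None``) rather than being defaulted.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    missing = set(samples) ^ set(clone_treatments)
    if missing:
        raise ValueError(
            f"VCF samples {samples} do not match design clones "
            f"{sorted(clone_treatments)}"
        )
    clones = [{"clone_id": s, "treatment": clone_treatments[s]} for s in samples]
    # if the file carries no mappability annotation at all, leave every
    # record mappable rather than silently failing filter 2
    has_mappable = vcf.contains(info_keys.mappable)

    records: list[VariantRecord] = []
    for v in vcf:
        alts = v.ALT
        if not alts:
            continue
        multi = len(alts) > 1
        svtype = v.INFO.get(info_keys.sv_type)
        pop_af = v.INFO.get(info_keys.pop_af)
        mappable = bool(v.INFO.get(info_keys.mappable, False)) if has_mappable else True
        sv_end = v.INFO.get(info_keys.sv_end)
        caller_pass = v.FILTER is None  # cyvcf2: None means PASS

        ad = v.format(format_keys.allele_depth)
        dp = v.format(format_keys.depth)
        gq = v.format(format_keys.genotype_quality)
        sr = v.format(format_keys.split_reads) if svtype is not None else None
        gt_types = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt

        raw = str(v).rstrip("\n")
        for ai, alt in enumerate(alts):
            per_clone: dict[str, CloneSupport] = {}
            for si, sample in enumerate(samples):
                alt_reads = 0
                if ad is not None:
                    val = ad[si][ai + 1] if ad.shape[1] > ai + 1 else ad[si][-1]
                    alt_reads = int(val) if val >= 0 else 0
                depth = 0
                if dp is not None:
                    d = int(dp[si][0])
                    depth = d if d >= 0 else 0
                depth = max(depth, alt_reads)
                gqv = None
                if gq is not None:
                    g = float(gq[si][0])
                    gqv = g if g >= 0 else None
                srv = None
                if sr is not None:
                    s = int(sr[si][0])
                    srv = s if s >= 0 else 0
                per_clone[sample] = CloneSupport(
                    alt_reads=alt_reads,
                    depth=depth,
                    genotype_quality=gqv,
                    genotyped=gt_types[si] in (1, 3),
                    split_reads=srv,
                )
            records.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    var_class=_var_class(v.REF, alt, svtype),
                    caller_pass=caller_pass,
                    per_clone=per_clone,
                    sv_end=int(sv_end) if sv_end is not None else None,
                    pop_af=float(pop_af) if pop_af is not None else None,
                    mappable=mappable,
                    multiallelic=multi,
                    raw_line=raw,
                )
            )
    vcf.close()
    return CloneCohort(
        cell_line=cell_line or Path(path).stem.split(".")[0],
        clones=clones,
        variants=records,
    )


def compute_vaf(record: VariantRecord, clone: str) -> float:
    """Variant allele fraction = alt_reads / depth for one clone."""
    sup = record.per_clone[clone]
    if sup.depth == 0:
        raise ValueError(f"VAF undefined at zero depth ({record.chrom}:{record.pos}, {clone})")
    return sup.alt_reads / sup.depth


def load_bed_mask(path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED (0-based half-open) mappability mask into per-chrom intervals."""
    mask: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split()[:3]
            mask.setdefault(chrom, []).append((int(start), int(end)))
    for iv in mask.values():
        iv.sort()
    return mask


def apply_mappability_mask(cohort: CloneCohort, mask: dict) -> CloneCohort:
    """Set each record's ``mappable`` flag by intersecting its (1-based)
    position against 0-based half-open BED intervals."""
    import bisect

    out = []
    for v in cohort.variants:
        ivs = mask.get(v.chrom, [])
        p0 = v.pos - 1
        i = bisect.bisect_right([s for s, _ in ivs], p0) - 1
        hit = i >= 0 and ivs[i][0] <= p0 < ivs[i][1]
        out.append(replace(v, mappable=hit))
    return CloneCohort(cohort.cell_line, cohort.clones, out)


# --- filter cascades ------------------------------------------------------

def _core_rules_pass(v: VariantRecord, af_max: float, rules: frozenset[int]) -> bool:
    """Rules 1-5 shared by all variant classes (rule 6 is class-specific)."""
    if 1 in rules and not v.caller_pass:
        return False
    if 2 in rules and not v.mappable:
        return False
    if 3 in rules and v.pop_af is not None and v.pop_af >= af_max:
        return False
    if 4 in rules and len(v.genotyped_clones()) != 1:
        return False
    if 5 in rules and v.multiallelic:
        return False
    return True


def _attributed(v: VariantRecord) -> str | None:
    g = v.genotyped_clones()
    return g[0] if len(g) == 1 else None


def filter_snvs(
    cohort: CloneCohort, af_max: float = 0.001, min_alt_reads: int = 2,
    rules: frozenset[int] = ALL_RULES,
) -> CloneCohort:
    """Six-rule SNV cascade: caller PASS, mappable, population AF < af_max
    (or absent), genotyped in exactly one clone, biallelic, and >= 2
    alt-supporting reads in the genotyped clone."""
    kept = []
    for v in cohort.variants:
        if v.var_class != SNV:
            continue
        if not _core_rules_pass(v, af_max, rules):
            continue
        clone = _attributed(v)
        if 6 in rules:
            if clone is None or v.per_clone[clone].alt_reads < min_alt_reads:
                continue
        kept.append(replace(v, attributed_clone=clone))
    return CloneCohort(cohort.cell_line, cohort.clones, kept)


def filter_indels(
    cohort: CloneCohort, af_max: float = 0.001, gq_min: float = 10,
    min_alt_reads: int = 2, rules: frozenset[int] = ALL_RULES,
) -> CloneCohort:
    """SNV cascade plus indel evidence rules: genotype quality >= gq_min in
    the genotyped clone; drop if more than two other clones have >= 1
    supporting read, or more than one other clone has >= 2 (putative
    germline leakage)."""
    kept = []
    for v in cohort.variants:
        if v.var_class not in (INS, DEL):
            continue
        if not _core_rules_pass(v, af_max, rules):
            continue
        clone = _attributed(v)
        if 6 in rules and (clone is None or v.per_clone[clone].alt_reads < min_alt_reads):
            continue
        if clone is None:
            continue
        gq = v.per_clone[clone].genotype_quality
        if gq is None or gq < gq_min:
            continue
        others = [s for c, s in v.per_clone.items() if c != clone]
        if sum(1 for s in others if s.alt_reads >= 1) > 2:
            continue
        if sum(1 for s in others if s.alt_reads >= 2) > 1:
            continue
        kept.append(replace(v, attributed_clone=clone))
    return CloneCohort(cohort.cell_line, cohort.clones, kept)


def filter_svs(
    cohort: CloneCohort, af_max: float = 0.001, sr_min: int = 2,
    rules: frozenset[int] = ALL_RULES,
) -> CloneCohort:
    """Rules 1-5 plus >= sr_min supporting split-reads in the genotyped
    clone; no spanning-read requirement."""
    kept = []
    for v in cohort.variants:
        if v.var_class not in SV_CLASSES:
            continue
        if not _core_rules_pass(v, af_max, rules):
            continue
        clone = _attributed(v)
        if clone is None:
            continue
        sr = v.per_clone[clone].split_reads
        if sr is None or sr < sr_min:
            continue
        kept.append(replace(v, attributed_clone=clone))
    return CloneCohort(cohort.cell_line, cohort.clones, kept)


def filter_cohort(cohort: CloneCohort, af_max: float = 0.001) -> CloneCohort:
    """All three cascades, concatenated."""
    snv = filter_snvs(cohort, af_max)
    ind = filter_indels(cohort, af_max)
    sv = filter_svs(cohort, af_max)
    return CloneCohort(
        cohort.cell_line, cohort.clones, snv.variants + ind.variants + sv.variants
    )


# --- breakend utilities ---------------------------------------------------

_BND_RE = re.compile(r"([\[\]])(?P<chrom>[^:\[\]]+):(?P<pos>\d+)([\[\]])")


def convert_inversion_breakends(variants: list[VariantRecord]) -> list[VariantRecord]:
    """Collapse mated breakend (BND) pairs with inverted orientation on one
    chromosome into single inversion records.

    Two mates a < b produce one SV_INV with pos = a, sv_end = b. Bracket
    notation of the form ``N]chr:pos]`` / ``N[chr:pos[`` is parsed from ALT;
    non-breakend records pass through unchanged.
    """
    out, bnds = [], []
    for v in variants:
        if v.var_class == "BND":
            m = _BND_RE.search(v.alt)
            if m and m.group("chrom") == v.chrom:
                bnds.append((v, int(m.group("pos"))))
            # interchromosomal breakends are not inversions; drop
        else:
            out.append(v)
    seen = set()
    for v, mate_pos in bnds:
        key = (v.chrom, min(v.pos, mate_pos), max(v.pos, mate_pos))
        if key in seen:
            continue
        seen.add(key)
        out.append(
            replace(
                v,
                var_class="SV_INV",
                pos=key[1],
                sv_end=key[2],
                alt="<INV>",
            )
        )
    return out


# --- output ---------------------------------------------------------------

def attributed_table(cohort: CloneCohort):
    """Per-clone TSV-ready table of attributed variants."""
    import pandas as pd

    rows = []
    for v in cohort.variants:
        clone = v.attributed_clone or _attributed(v)
        if clone is None:
            continue
        try:
            vaf = compute_vaf(v, clone)
        except ValueError:
            vaf = float("nan")
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "var_class": v.var_class,
                "sv_end": v.sv_end,
                "clone": clone,
                "treatment": cohort.treatment_of(clone),
                "cell_line": cohort.cell_line,
                "vaf": vaf,
            }
        )
    cols = ["chrom", "pos", "ref", "alt", "var_class", "sv_end", "clone",
            "treatment", "cell_line", "vaf"]
    return pd.DataFrame(rows, columns=cols)


def write_filtered_vcf(cohort: CloneCohort, template_vcf_path, out_path) -> None:
    """Write retained records back out as VCF, reusing the template header."""
    vcf = VCF(str(template_vcf_path))
    header = vcf.raw_header
    vcf.close()
    seen = set()
    with open(out_path, "w") as fh:
        fh.write(header)
        for v in cohort.variants:
            if v.raw_line and v.raw_line not in seen:
                seen.add(v.raw_line)
                fh.write(v.raw_line + "\n")
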