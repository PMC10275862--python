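"""Synthetic clone-cohort simulator with full ground truth.

Emulates the study shape: three cell lines, each with one untreated control
and helium/proton-irradiated clonally expanded cultures (21 clones), SNVs
drawn from exposure-weighted mixtures of trinucleotide signature spectra
and placed at context-matched sites, indels placed at sequence-compatible
sites per 83-category spectra with a treatment-dependent deletion excess,
structural variants per class with log-normal lengths, injected mutation
clusters (pairs and >5-mutation showers), and ploidy-dependent VAF peaks
(1.0 haploid, 0.5 diploid-het, 0.25 tetraploid-het) from binomial read
sampling at fixed depth. Every emitted VCF record is mirrored in a truth
table, plus optional contaminant records violating each filter rule
exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalogs import COMPLEMENT, SBS96_CATEGORIES, revcomp

_B2I = {"A": 0, "C": 1, "G": 2, "T": 3}
_I2B = np.array(list("ACGT"))

VAF_BY_PLOIDY = {"haploid": 1.0, "diploid-het": 0.5, "tetraploid-het": 0.25}


# --- toy genome -----------------------------------------------------------

def make_toy_genome(layout: dict[str, int], gc_fraction: float = 0.42,
                    seed: int = 0) -> dict[str, str]:
    """Random genome with the requested GC content; deterministic given the
    seed. Contigs of >= 10 kb are regenerated (bounded retries) until every
    trinucleotide occurs at least once."""
    if any(n < 1 for n in layout.values()):
        raise ValueError("zero-length contig")
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2,
                  gc_fraction / 2, (1 - gc_fraction) / 2])
    rng = np.random.default_rng(seed)
    seqs = {}
    for chrom, length in layout.items():
        for _ in range(10):
            arr = rng.choice(4, size=length, p=p)
            seq = "".join(_I2B[arr])
            if length < 10_000 or _all_trinucs_present(arr):
                break
        seqs[chrom] = seq
    return seqs


def _all_trinucs_present(arr: np.ndarray) -> bool:
    code = arr[:-2] * 16 + arr[1:-1] * 4 + arr[2:]
    return np.unique(code).size == 64


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    try:
        from pyfaidx import Faidx

        Faidx(str(path))
    except Exception:
        pass


# --- genome indexes -------------------------------------------------------

def _tri_code(tri: str) -> int:
    return _B2I[tri[0]] * 16 + _B2I[tri[1]] * 4 + _B2I[tri[2]]


class GenomeIndex:
    """Site lookup tables: trinucleotide-context positions (for
    context-matched SNV placement) and homopolymer runs (for 1-bp indels)."""

    def __init__(self, seqs: dict[str, str]):
        self.seqs = seqs
        self.chroms = list(seqs)
        self._codes: dict[str, np.ndarray] = {}
        self._site_cache: dict[tuple[str, int], np.ndarray] = {}
        for chrom, seq in seqs.items():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            enc = np.zeros(arr.size, dtype=np.uint8)
            for b, i in _B2I.items():
                enc[arr == ord(b)] = i
            self._codes[chrom] = (
                enc[:-2].astype(np.int16) * 16 + enc[1:-1] * 4 + enc[2:]
            )

    def run_at(self, chrom: str, pos0: int) -> tuple[int, int]:
        """(start0, length) of the homopolymer run containing position pos0."""
        seq = self.seqs[chrom]
        b = seq[pos0]
        s = pos0
        while s > 0 and seq[s - 1] == b:
            s -= 1
        e = pos0
        while e + 1 < len(seq) and seq[e + 1] == b:
            e += 1
        return s, e - s + 1

    def context_sites(self, chrom: str, tri: str) -> np.ndarray:
        """1-based center positions whose trinucleotide equals ``tri``."""
        key = (chrom, _tri_code(tri))
        if key not in self._site_cache:
            self._site_cache[key] = (
                np.nonzero(self._codes[chrom] == key[1])[0].astype(np.int32) + 2
            )
        return self._site_cache[key]

    def category_pool(self, category96: str) -> list[tuple[str, np.ndarray]]:
        """All placement sites for one SBS96 category: pyrimidine-centred
        contexts as written, plus their reverse complements."""
        ctx = category96[0] + category96[2] + category96[6]
        pools = []
        for chrom in self.chroms:
            for tri in (ctx, revcomp(ctx)):
                sites = self.context_sites(chrom, tri)
                if sites.size:
                    pools.append((chrom, sites))
        return pools


# --- design ---------------------------------------------------------------

@dataclass
class ClusterSpec:
    size: int
    span: int
    mutation_class: str = "C>T"  # 6-class label of member SNVs


@dataclass
class CloneDesign:
    clone_id: str
    cell_line: str
    treatment: str  # control | helium | proton
    n_snv: int
    n_indel: int
    del_ins_ratio: float
    exposures: dict[str, float]
    clusters: list[ClusterSpec] = field(default_factory=list)
    sv_counts: dict[str, int] = field(default_factory=dict)  # DEL/INS/DUP/INV
    sv_len_log10: tuple[float, float] = (4.0, 0.4)  # mean, sd of log10 length
    ploidy: str = "diploid-het"
    depth: int = 40

    def __post_init__(self):
        total = sum(self.exposures.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"exposures of {self.clone_id} sum to {total}, not 1")
        if self.n_snv < 0 or self.n_indel < 0:
            raise ValueError("negative burden")


@dataclass
class SimDesign:
    layout: dict[str, int]
    clones: list[CloneDesign]
    gc_fraction: float = 0.42
    contaminants: bool = True

    def __post_init__(self):
        ids = [c.clone_id for c in self.clones]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate clone ids in design")

    @property
    def cell_lines(self) -> list[str]:
        seen = []
        for c in self.clones:
            if c.cell_line not in seen:
                seen.append(c.cell_line)
        return seen


# --- truth signature spectra ----------------------------------------------

def make_truth_signatures(seed: int = 11) -> pd.DataFrame:
    """Three synthetic SBS96 spectra with distinct 6-class character:
    an oxidative-damage-like C>A signature, a clock-like C>T/T>C
    signature, and a bulky-adduct-like T>A signature."""
    rng = np.random.default_rng(seed)
    designs = {
        "SBS_oxid": {"C>A": 0.82, "C>G": 0.06, "C>T": 0.04, "T>A": 0.02,
                     "T>C": 0.04, "T>G": 0.02},
        "SBS_clock": {"C>A": 0.04, "C>G": 0.03, "C>T": 0.55, "T>A": 0.03,
                      "T>C": 0.32, "T>G": 0.03},
        "SBS_bulky": {"C>A": 0.05, "C>G": 0.03, "C>T": 0.05, "T>A": 0.75,
                      "T>C": 0.07, "T>G": 0.05},
    }
    cols = {}
    for name, six in designs.items():
        vec = np.zeros(96)
        for block, (cls, w) in enumerate(six.items()):
            ctx = rng.dirichlet(np.full(16, 0.8))
            vec[block * 16 : (block + 1) * 16] = w * ctx
        cols[name] = vec / vec.sum()
    return pd.DataFrame(cols, index=list(SBS96_CATEGORIES))


def make_reference_catalog(signatures: pd.DataFrame, n_decoys: int = 5,
                           seed: int = 23) -> pd.DataFrame:
    """Reference catalog: the truth spectra under reference names plus
    random Dirichlet decoy signatures."""
    rng = np.random.default_rng(seed)
    ref = {f"REF{i + 1}": signatures.iloc[:, i].values
           for i in range(signatures.shape[1])}
    for j in range(n_decoys):
        ref[f"DECOY{j + 1}"] = rng.dirichlet(np.full(len(signatures), 0.3))
    return pd.DataFrame(ref, index=signatures.index)


def simulate_catalog(
    signatures: pd.DataFrame,
    exposures: pd.DataFrame,
    burdens: pd.Series,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial count catalog from per-clone signature mixtures.

    ``exposures``: signatures x clones fractional activities (columns sum
    to 1); ``burdens``: total mutations per clone.
    """
    rng = np.random.default_rng(seed)
    S = signatures.values
    out = {}
    for clone in exposures.columns:
        p = S @ exposures[clone].reindex(signatures.columns).values
        p = p / p.sum()
        out[clone] = rng.multinomial(int(burdens[clone]), p)
    return pd.DataFrame(out, index=signatures.index)


# --- default study design -------------------------------------------------

# deletion categories: 1-bp slippage-type vs longer / microhomology-flanked
_DEL_1BP = {"1:Del:T:1": 0.30, "1:Del:T:2": 0.20, "1:Del:T:5": 0.10,
            "1:Del:C:1": 0.25, "1:Del:C:2": 0.15}
_DEL_LONG = {"2:Del:R:0": 0.25, "3:Del:R:0": 0.20, "2:Del:M:1": 0.20,
             "3:Del:M:1": 0.15, "5:Del:M:2": 0.10, "4:Del:R:1": 0.10}
_INS_SPECTRUM = {"1:Ins:T:0": 0.30, "1:Ins:T:1": 0.20, "1:Ins:C:0": 0.25,
                 "1:Ins:T:5": 0.05, "2:Ins:R:0": 0.12, "3:Ins:R:0": 0.08}

# fraction of deletions drawn from the longer/microhomology block: treated
# clones shift toward radiation-style deletions
_LONG_DEL_FRACTION = {"control": 0.20, "helium": 0.40, "proton": 0.50}

_EXPOSURE_BASE = {
    "A549": {"SBS_oxid": 0.55, "SBS_clock": 0.30, "SBS_bulky": 0.15},
    "HAP1": {"SBS_oxid": 0.60, "SBS_clock": 0.25, "SBS_bulky": 0.15},
    "MCF7": {"SBS_oxid": 0.35, "SBS_clock": 0.55, "SBS_bulky": 0.10},
}
_EXPOSURE_SHIFT = {"control": 0.0, "helium": 0.05, "proton": 0.10}

_PLOIDY = {"A549": "diploid-het", "HAP1": "haploid", "MCF7": "tetraploid-het"}

_SNV_BURDEN = {"control": 1000, "helium": 1000, "proton": 1100}
_INDEL_BURDEN = {"control": 150, "helium": 180, "proton": 280}
_DEL_INS_RATIO = {"control": 1.5, "helium": 2.5, "proton": 4.0}
_SV_COUNTS = {
    "control": {"DEL": 4, "INS": 2, "DUP": 3, "INV": 2},
    "helium": {"DEL": 8, "INS": 2, "DUP": 3, "INV": 3},
    "proton": {"DEL": 10, "INS": 2, "DUP": 3, "INV": 3},
}
_SV_LEN = {"control": (4.3, 0.4), "helium": (4.0, 0.4), "proton": (3.7, 0.4)}
_CLUSTERS = {
    "control": [ClusterSpec(2, 800)],
    "helium": [ClusterSpec(2, 800)] * 6 + [ClusterSpec(6, 3000)] * 2,
    "proton": [ClusterSpec(2, 800)] * 5 + [ClusterSpec(6, 3000)],
}

DEFAULT_LAYOUT = {"chr1": 22_000_000, "chr2": 20_000_000, "chr3": 18_000_000}


def default_design() -> SimDesign:
    """The study-shaped cohort: 3 cell lines x (1 control + 2 helium +
    4 proton) = 21 clones, with treatment-dependent deletion excess and
    injected clusters and cell-line-specific VAF peaks."""
    clones = []
    plan = [("control", 1), ("helium", 2), ("proton", 4)]
    for line in ("A549", "HAP1", "MCF7"):
        for treatment, n in plan:
            for i in range(n):
                exp = dict(_EXPOSURE_BASE[line])
                shift = _EXPOSURE_SHIFT[treatment]
                exp["SBS_bulky"] += shift
                exp["SBS_oxid"] -= shift
                clones.append(
                    CloneDesign(
                        clone_id=f"{line}_{treatment[:2].upper()}{i + 1}",
                        cell_line=line,
                        treatment=treatment,
                        n_snv=_SNV_BURDEN[treatment],
                        n_indel=_INDEL_BURDEN[treatment],
                        del_ins_ratio=_DEL_INS_RATIO[treatment],
                        exposures=exp,
                        clusters=list(_CLUSTERS[treatment]),
                        sv_counts=dict(_SV_COUNTS[treatment]),
                        sv_len_log10=_SV_LEN[treatment],
                        ploidy=_PLOIDY[line],
                    )
                )
    return SimDesign(layout=dict(DEFAULT_LAYOUT), clones=clones)


# --- per-clone simulation -------------------------------------------------

@dataclass
class SimVariant:
    chrom: str
    pos: int                    # 1-based
    ref: str
    alt: str
    var_class: str              # SNV, INS, DEL, SV_*
    clone_id: str
    category: str               # SBS96 / ID83 label or SV class
    vaf_mean: float
    sv_end: int | None = None
    cluster_id: str = ""
    info_extra: dict = field(default_factory=dict)


def _sample_snvs(index: GenomeIndex, clone: CloneDesign,
                 spectra: pd.DataFrame, rng) -> list[SimVariant]:
    mix = np.zeros(96)
    for sig, frac in clone.exposures.items():
        mix += frac * spectra[sig].values
    mix /= mix.sum()
    counts = rng.multinomial(clone.n_snv, mix)
    vaf = VAF_BY_PLOIDY[clone.ploidy]
    out = []
    for ci, n in enumerate(counts):
        if n == 0:
            continue
        cat = SBS96_CATEGORIES[ci]
        pools = index.category_pool(cat)
        sizes = np.array([s.size for _, s in pools])
        total = sizes.sum()
        if total < n:
            raise ValueError(f"not enough sites for category {cat}")
        picks = rng.choice(total, size=n, replace=False)
        offsets = np.cumsum(sizes)
        ctx = cat[0] + cat[2] + cat[6]
        alt_pyr = cat[4]
        for p in picks:
            k = int(np.searchsorted(offsets, p, side="right"))
            chrom, sites = pools[k]
            pos = int(sites[p - (offsets[k - 1] if k else 0)])
            base = index.seqs[chrom][pos - 1]
            alt = alt_pyr if base == ctx[1] else COMPLEMENT[alt_pyr]
            out.append(
                SimVariant(chrom, pos, base, alt, "SNV", clone.clone_id,
                           cat, vaf)
            )
    return out


def _inject_clusters(index: GenomeIndex, clone: CloneDesign, rng,
                     used: set) -> list[SimVariant]:
    out = []
    vaf = VAF_BY_PLOIDY[clone.ploidy]
    want = {"C>T": ("C", "T"), "C>A": ("C", "A"), "C>G": ("C", "G"),
            "T>A": ("T", "A"), "T>C": ("T", "C"), "T>G": ("T", "G")}
    for k, spec in enumerate(clone.clusters):
        pyr_ref, pyr_alt = want[spec.mutation_class]
        bases = {pyr_ref, COMPLEMENT[pyr_ref]}
        step = max(min(spec.span // max(spec.size - 1, 1), 950), 50)
        for _ in range(200):
            chrom = index.chroms[rng.integers(len(index.chroms))]
            seq = index.seqs[chrom]
            start = int(rng.integers(2, len(seq) - spec.span - 100))
            positions = []
            ok = True
            cursor = start
            for _m in range(spec.size):
                p = cursor
                while p < cursor + 49 and seq[p - 1] not in bases:
                    p += 1
                if seq[p - 1] not in bases or (chrom, p) in used:
                    ok = False
                    break
                positions.append(p)
                cursor = p + step
            if ok and all(b - a < 1000 for a, b in zip(positions, positions[1:])):
                cid = f"{clone.clone_id}_cl{k}"
                for p in positions:
                    used.add((chrom, p))
                    base = seq[p - 1]
                    alt = pyr_alt if base == pyr_ref else COMPLEMENT[pyr_alt]
                    tri = seq[p - 2 : p + 1]
                    from .classify import sbs96_label

                    out.append(
                        SimVariant(chrom, p, base, alt, "SNV", clone.clone_id,
                                   sbs96_label(tri, alt), vaf, cluster_id=cid)
                    )
                break
        else:
            raise ValueError(f"could not place cluster {spec} for {clone.clone_id}")
    return out


def _del_category_at(seq: str, start0: int, L: int) -> str | None:
    """ID83 category of deleting seq[start0:start0+L], or None if the site
    is not left-aligned / runs off the contig."""
    if start0 < 1 or start0 + L + 6 * L >= len(seq):
        return None
    sub = seq[start0 : start0 + L]
    if seq[start0 - 1] == sub[-1]:
        return None  # not left-aligned
    copies = 1
    p = start0 + L
    while seq[p : p + L] == sub:
        copies += 1
        p += L
    if L == 1:
        ch = COMPLEMENT[sub] if sub in "AG" else sub
        return f"1:Del:{ch}:{min(copies, 6) - 1}"
    if copies >= 2:
        return f"{min(L, 5)}:Del:R:{min(copies, 6) - 1}"
    mh = 0
    for k in range(1, L):
        if seq[start0 + L : start0 + L + k] == sub[:k]:
            mh = k
        else:
            break
    cap = {2: 1, 3: 2, 4: 3, 5: 5}[min(L, 5)]
    if mh >= 1:
        return f"{min(L, 5)}:Del:M:{min(mh, cap)}"
    return f"{min(L, 5)}:Del:R:0"


def _place_deletion(index: GenomeIndex, category: str, rng,
                    used: set, max_tries: int = 50_000):
    parts = category.split(":")
    L = int(parts[0])
    if L == 1:
        ch, b = parts[2], int(parts[3])
        for _ in range(max_tries):
            base = ch if rng.random() < 0.5 else COMPLEMENT[ch]
            chrom = index.chroms[rng.integers(len(index.chroms))]
            seq = index.seqs[chrom]
            p0 = int(rng.integers(2, len(seq) - 10))
            if seq[p0] != base:
                continue
            s0, ln = index.run_at(chrom, p0)
            if (b < 5 and ln != b + 1) or (b == 5 and ln < 6) or s0 < 1:
                continue
            if any((chrom, s0 + d) in used for d in range(0, 2)):
                continue
            return chrom, s0, seq[s0 - 1] + seq[s0], seq[s0 - 1]
        raise ValueError(f"no site for {category}")
    for _ in range(max_tries):
        chrom = index.chroms[rng.integers(len(index.chroms))]
        seq = index.seqs[chrom]
        s0 = int(rng.integers(1, len(seq) - 8 * L))
        if _del_category_at(seq, s0, L) != category:
            continue
        if any((chrom, s0 + d) in used for d in range(-1, L + 1)):
            continue
        return chrom, s0, seq[s0 - 1 : s0 + L], seq[s0 - 1]
    raise ValueError(f"no site found for deletion category {category}")


def _place_insertion(index: GenomeIndex, category: str, rng,
                     used: set, max_tries: int = 50_000):
    parts = category.split(":")
    L = int(parts[0])
    if L == 1:
        ch, b = parts[2], int(parts[3])
        for _ in range(max_tries):
            base = ch if rng.random() < 0.5 else COMPLEMENT[ch]
            if b == 0:
                chrom = index.chroms[rng.integers(len(index.chroms))]
                seq = index.seqs[chrom]
                a0 = int(rng.integers(1, len(seq) - 3))
                if seq[a0] == base or seq[a0 + 1] == base:
                    continue
                s0 = a0 + 1
            else:
                chrom = index.chroms[rng.integers(len(index.chroms))]
                seq = index.seqs[chrom]
                p0 = int(rng.integers(2, len(seq) - 10))
                if seq[p0] != base:
                    continue
                s0, ln = index.run_at(chrom, p0)
                if (b < 5 and ln != b) or (b == 5 and ln < 5) or s0 < 1:
                    continue
                a0 = s0 - 1
            if any((chrom, a0 + d) in used for d in range(0, 2)):
                continue
            return chrom, a0, seq[a0], seq[a0] + base
        raise ValueError(f"no site for {category}")
    b = int(parts[3])
    for _ in range(max_tries):
        chrom = index.chroms[rng.integers(len(index.chroms))]
        seq = index.seqs[chrom]
        a0 = int(rng.integers(1, len(seq) - 8 * L))
        if b == 0:
            unit = "".join(_I2B[rng.integers(0, 4, size=L)])
            if len(set(unit)) == 1:
                continue  # homopolymer units collide with 1-bp channels
            if seq[a0] == unit[-1] or seq[a0 + 1 : a0 + 1 + L] == unit:
                continue
        else:
            unit = seq[a0 + 1 : a0 + 1 + L]
            if len(set(unit)) == 1 or seq[a0] == unit[-1]:
                continue
            copies = 0
            p = a0 + 1
            while seq[p : p + L] == unit:
                copies += 1
                p += L
            if (b < 5 and copies != b) or (b == 5 and copies < 5):
                continue
        if any((chrom, a0 + d) in used for d in range(0, 2)):
            continue
        return chrom, a0, seq[a0], seq[a0] + unit
    raise ValueError(f"no site found for insertion category {category}")


def _sample_indels(index: GenomeIndex, clone: CloneDesign, rng,
                   used: set) -> list[SimVariant]:
    n_del = int(rng.binomial(clone.n_indel,
                             clone.del_ins_ratio / (1 + clone.del_ins_ratio)))
    n_ins = clone.n_indel - n_del
    long_frac = _LONG_DEL_FRACTION.get(clone.treatment, 0.3)
    vaf = VAF_BY_PLOIDY[clone.ploidy]
    out = []

    def draw(spectrum: dict[str, float], n: int) -> list[str]:
        cats = list(spectrum)
        p = np.array([spectrum[c] for c in cats], dtype=float)
        p /= p.sum()
        counts = rng.multinomial(n, p)
        cat_list = []
        for c, k in zip(cats, counts):
            cat_list += [c] * int(k)
        return cat_list

    n_long = int(rng.binomial(n_del, long_frac))
    del_cats = draw(_DEL_1BP, n_del - n_long) + draw(_DEL_LONG, n_long)
    ins_cats = draw(_INS_SPECTRUM, n_ins)
    for cat in del_cats:
        chrom, s0, ref, alt = _place_deletion(index, cat, rng, used)
        for d in range(-1, len(ref)):
            used.add((chrom, s0 + d))
        out.append(SimVariant(chrom, s0, ref, alt, "DEL", clone.clone_id,
                              cat, vaf))
    for cat in ins_cats:
        chrom, a0, ref, alt = _place_insertion(index, cat, rng, used)
        used.add((chrom, a0))
        used.add((chrom, a0 + 1))
        out.append(SimVariant(chrom, a0 + 1, ref, alt, "INS", clone.clone_id,
                              cat, vaf))
    return out


def _sample_svs(index: GenomeIndex, clone: CloneDesign, rng) -> list[SimVariant]:
    out = []
    vaf = VAF_BY_PLOIDY[clone.ploidy]
    mu, sd = clone.sv_len_log10
    for sv_class, n in clone.sv_counts.items():
        for _ in range(n):
            chrom = index.chroms[rng.integers(len(index.chroms))]
            seq = index.seqs[chrom]
            if sv_class == "INS":
                pos = int(rng.integers(100, len(seq) - 100))
                out.append(
                    SimVariant(chrom, pos, seq[pos - 1], "<INS>", "SV_INS",
                               clone.clone_id, "INS", vaf,
                               info_extra={"SVTYPE": "INS"})
                )
                continue
            length = max(50, int(round(10 ** rng.normal(mu, sd))))
            length = min(length, len(seq) // 4)
            pos = int(rng.integers(100, len(seq) - length - 100))
            out.append(
                SimVariant(chrom, pos, seq[pos - 1], f"<{sv_class}>",
                           f"SV_{sv_class}", clone.clone_id, sv_class, vaf,
                           sv_end=pos + length,
                           info_extra={"SVTYPE": sv_class, "END": pos + length})
            )
    return out


def simulate_clone(index: GenomeIndex, clone: CloneDesign,
                   spectra: pd.DataFrame, seed: int) -> list[SimVariant]:
    """All variants of one clone with truth categories and cluster ids."""
    rng = np.random.default_rng(seed)
    used: set = set()
    clustered = _inject_clusters(index, clone, rng, used)
    snvs = _sample_snvs(index, clone, spectra, rng)
    snvs = [v for v in snvs if (v.chrom, v.pos) not in used]
    for v in snvs:
        used.add((v.chrom, v.pos))
    indels = _sample_indels(index, clone, rng, used)
    svs = _sample_svs(index, clone, rng)
    return clustered + snvs + indels + svs


# --- VCF emission ---------------------------------------------------------

_VCF_HEADER_META = """\
##fileformat=VCFv4.2
##INFO=<ID=GNOMAD_AF,Number=1,Type=Float,Description="Population allele frequency">
##INFO=<ID=MAPPABLE,Number=0,Type=Flag,Description="Position in uniquely mappable region">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Structural variant type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of structural variant">
##FILTER=<ID=LowQual,Description="Failed caller filters">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=SR,Number=1,Type=Integer,Description="Alt-supporting split reads">
"""


def _reads(rng, depth: int, vaf: float, minimum: int = 2) -> tuple[int, int]:
    """Binomial alt reads at fixed depth, conditioned on detectability."""
    for _ in range(1000):
        alt = int(rng.binomial(depth, vaf))
        if alt >= minimum:
            return alt, depth
    return minimum, depth


def _format_sample(gt: str, alt: int, depth: int, gq: int,
                   sr: int | None, n_alts: int = 1) -> str:
    ad = ",".join([str(depth - alt)] + [str(alt)] + ["0"] * (n_alts - 1))
    f = f"{gt}:{ad}:{depth}:{gq}"
    if sr is not None:
        f += f":{sr}"
    return f


def _carrier_gt(ploidy: str) -> str:
    return "1/1" if ploidy == "haploid" else "0/1"


class _Row:
    __slots__ = ("chrom", "pos", "ref", "alts", "filter", "info", "fmt", "samples")

    def __init__(self, chrom, pos, ref, alts, filt, info, fmt, samples):
        self.chrom, self.pos, self.ref = chrom, pos, ref
        self.alts, self.filter, self.info = alts, filt, info
        self.fmt, self.samples = fmt, samples

    def render(self) -> str:
        info = ";".join(self.info) if self.info else "."
        return "\t".join(
            [self.chrom, str(self.pos), ".", self.ref, ",".join(self.alts),
             "60", self.filter, info, self.fmt] + self.samples
        )


def _variant_row(v: SimVariant, clone_ids: list[str], designs: dict, rng) -> _Row:
    is_sv = v.var_class.startswith("SV_")
    fmt = "GT:AD:DP:GQ:SR" if is_sv else "GT:AD:DP:GQ"
    info = ["MAPPABLE"]
    for key, val in v.info_extra.items():
        info.append(f"{key}={val}" if val is not True else key)
    samples = []
    for cid in clone_ids:
        d = designs[cid]
        if cid == v.clone_id:
            alt, depth = _reads(rng, d.depth, v.vaf_mean)
            sr = max(2, int(rng.binomial(depth // 2, v.vaf_mean))) if is_sv else None
            samples.append(_format_sample(_carrier_gt(d.ploidy), alt, depth, 60, sr))
        else:
            sr = 0 if is_sv else None
            samples.append(_format_sample("0/0", 0, d.depth, 60, sr))
    return _Row(v.chrom, v.pos, v.ref, [v.alt], "PASS", info, fmt, samples)


def _contaminant_rows(index: GenomeIndex, clone_ids: list[str],
                      designs: dict, rng) -> list[_Row]:
    """One otherwise-valid record per filter rule, violating just that rule:
    caller filter, mappability, population AF, multi-clone genotyping,
    multiallelic, low support, indel GQ, indel cross-clone support (two
    flavours), and SV split-read support."""

    def base_at(margin=1000):
        chrom = index.chroms[rng.integers(len(index.chroms))]
        pos = int(rng.integers(margin, len(index.seqs[chrom]) - margin))
        ref = index.seqs[chrom][pos - 1]
        alt = {"A": "C", "C": "A", "G": "T", "T": "G"}[ref]
        return chrom, pos, ref, alt

    rows = []
    first = clone_ids[0]
    d0 = designs[first]

    def snv_row(filt="PASS", info=("MAPPABLE",), carriers=(0,), alt_reads=20,
                n_alts=1, gq=60):
        chrom, pos, ref, alt = base_at()
        second = next(b for b in "ACGT" if b not in (ref, alt))
        alts = [alt] + [second] * (n_alts - 1)
        samples = []
        for i, cid in enumerate(clone_ids):
            d = designs[cid]
            if i in carriers:
                samples.append(_format_sample(
                    _carrier_gt(d.ploidy), alt_reads, d.depth, gq, None, n_alts))
            else:
                samples.append(_format_sample("0/0", 0, d.depth, 60, None, n_alts))
        return _Row(chrom, pos, ref, alts, filt, list(info), "GT:AD:DP:GQ", samples)

    rows.append(snv_row(filt="LowQual"))                       # rule 1
    rows.append(snv_row(info=()))                              # rule 2 (not mappable)
    rows.append(snv_row(info=("MAPPABLE", "GNOMAD_AF=0.01")))  # rule 3
    rows.append(snv_row(carriers=(0, 1)))                      # rule 4
    rows.append(snv_row(n_alts=2))                             # rule 5
    rows.append(snv_row(alt_reads=1))                          # rule 6

    def indel_row(gq=60, other_one=0, other_two=0):
        chrom, pos, ref, alt = base_at()
        ref2 = ref + index.seqs[chrom][pos]
        samples = []
        others_assigned = 0
        for i, cid in enumerate(clone_ids):
            d = designs[cid]
            if i == 0:
                samples.append(_format_sample(_carrier_gt(d.ploidy), 20, d.depth, gq, None))
            elif others_assigned < other_two:
                samples.append(_format_sample("0/0", 2, d.depth, 60, None))
                others_assigned += 1
            elif others_assigned < other_two + other_one:
                samples.append(_format_sample("0/0", 1, d.depth, 60, None))
                others_assigned += 1
            else:
                samples.append(_format_sample("0/0", 0, d.depth, 60, None))
        return _Row(chrom, pos, ref2, [ref], "PASS", ["MAPPABLE"], "GT:AD:DP:GQ", samples)

    rows.append(indel_row(gq=5))           # indel GQ rule
    if len(clone_ids) >= 4:                # needs 3 non-carrier clones
        rows.append(indel_row(other_one=3))  # >2 other clones with >=1 read
    if len(clone_ids) >= 3:                # needs 2 non-carrier clones
        rows.append(indel_row(other_two=2))  # >1 other clone with >=2 reads

    # SV with a single supporting split read
    chrom, pos, ref, _ = base_at(margin=20_000)
    samples = []
    for i, cid in enumerate(clone_ids):
        d = designs[cid]
        if i == 0:
            samples.append(_format_sample(_carrier_gt(d.ploidy), 15, d.depth, 60, 1))
        else:
            samples.append(_format_sample("0/0", 0, d.depth, 60, 0))
    rows.append(_Row(chrom, pos, ref, ["<DEL>"], "PASS",
                     ["MAPPABLE", "SVTYPE=DEL", f"END={pos + 5000}"],
                     "GT:AD:DP:GQ:SR", samples))
    return rows


def write_cohort_vcf(path, layout: dict[str, int], clone_ids: list[str],
                     rows: list[_Row]) -> None:
    chrom_order = {c: i for i, c in enumerate(layout)}
    rows = sorted(rows, key=lambda r: (chrom_order[r.chrom], r.pos, r.ref, r.alts[0]))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER_META)
        for chrom, length in layout.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(clone_ids) + "\n")
        for r in rows:
            fh.write(r.render() + "\n")


@dataclass
class CohortSim:
    design: SimDesign
    genome: dict[str, str]
    truth: pd.DataFrame
    vcf_paths: dict[str, Path]
    fasta_path: Path
    design_path: Path
    truth_path: Path
    n_contaminants: dict[str, int]


def simulate_cohort(design: SimDesign, out_dir, seed: int = 0) -> CohortSim:
    """Simulate the whole cohort and write FASTA, per-cell-line VCFs, a
    design TSV and the truth table. Deterministic given the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    genome_seed = int(master.integers(0, 2**31 - 1))
    genome = make_toy_genome(design.layout, design.gc_fraction, seed=genome_seed)
    index = GenomeIndex(genome)
    spectra = make_truth_signatures()

    fasta_path = out / "genome.fa"
    write_fasta(genome, fasta_path)

    truth_rows = []
    vcf_paths: dict[str, Path] = {}
    n_contaminants: dict[str, int] = {}
    for line in design.cell_lines:
        line_clones = [c for c in design.clones if c.cell_line == line]
        clone_ids = [c.clone_id for c in line_clones]
        designs = {c.clone_id: c for c in line_clones}
        rows: list[_Row] = []
        row_rng = np.random.default_rng(int(master.integers(0, 2**31 - 1)))
        for clone in line_clones:
            clone_seed = int(master.integers(0, 2**31 - 1))
            variants = simulate_clone(index, clone, spectra, clone_seed)
            for v in variants:
                rows.append(_variant_row(v, clone_ids, designs, row_rng))
                truth_rows.append(
                    {
                        "cell_line": line,
                        "clone": v.clone_id,
                        "treatment": clone.treatment,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": v.alt,
                        "var_class": v.var_class,
                        "category": v.category,
                        "cluster_id": v.cluster_id,
                        "vaf_mean": v.vaf_mean,
                        "sv_end": v.sv_end,
                    }
                )
        if design.contaminants:
            cont = _contaminant_rows(index, clone_ids, designs, row_rng)
            n_contaminants[line] = len(cont)
            rows += cont
        else:
            n_contaminants[line] = 0
        vcf_path = out / f"{line}.vcf"
        write_cohort_vcf(vcf_path, design.layout, clone_ids, rows)
        vcf_paths[line] = vcf_path

    truth = pd.DataFrame(truth_rows)
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)
    design_path = out / "design.tsv"
    pd.DataFrame(
        [
            {
                "clone_id": c.clone_id,
                "cell_line": c.cell_line,
                "treatment": c.treatment,
                "ploidy": c.ploidy,
                "depth": c.depth,
                "n_snv": c.n_snv,
                "n_indel": c.n_indel,
                "del_ins_ratio": c.del_ins_ratio,
            }
            for c in design.clones
        ]
    ).to_csv(design_path, sep="\t", index=False)
    return CohortSim(
        design=design,
        genome=genome,
        truth=truth,
        vcf_paths=vcf_paths,
        fasta_path=fasta_path,
        design_path=design_path,
        truth_path=truth_path,
        n_contaminants=n_contaminants,
    )
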