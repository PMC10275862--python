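"""Independent constructor of one exemplar indel per 83-category.

Builds, by direct string assembly, a reference sequence containing exactly
one indel of the requested category, following the published convention:
1-bp events binned by homopolymer run (deletions count the run including
the deleted base; insertions count pre-existing copies), longer events by
tandem-repeat unit count, and non-repeat deletions by flanking
microhomology. Deliberately re-implemented here, separately from the
package classifier, so the two can be compared.
"""

# repeat units / deletion bodies chosen so that a 'G' flank can never
# extend a run, form an extra copy, or add microhomology
_UNITS = {2: "CA", 3: "CTA", 4: "CTTA", 5: "CTTAA"}
_MH_BODY = {2: "CT", 3: "CTA", 4: "CTTA", 5: "CTTAC"}
_MH_BODY_LONG = "CTTACT"  # length-6 body for the "5+" bin with MH 5

_PAD = "GAG"


def build_exemplar(category: str):
    """Return (sequence, pos, ref, alt) — a VCF-style anchored indel whose
    ID83 category is exactly ``category`` when classified against the
    returned sequence."""
    length_s, kind, sub, bin_s = category.split(":")
    length, b = int(length_s), int(bin_s)
    anchor_pos = len(_PAD)  # 1-based position of the final pad base 'G'

    if length == 1 and kind == "Del":
        run = b + 1 if b < 5 else 7
        seq = _PAD + sub * run + _PAD
        return seq, anchor_pos, "G" + sub, "G"
    if length == 1 and kind == "Ins":
        run = b if b < 5 else 6
        seq = _PAD + sub * run + _PAD
        return seq, anchor_pos, "G", "G" + sub
    if kind == "Ins":  # tandem-repeat insertions, unit length 2-5
        unit = _UNITS[length]
        copies = b if b < 5 else 6
        seq = _PAD + unit * copies + _PAD
        return seq, anchor_pos, "G", "G" + unit
    if sub == "R":  # tandem-repeat deletions
        unit = _UNITS[length]
        copies = b + 1 if b < 5 else 7
        seq = _PAD + unit * copies + _PAD
        return seq, anchor_pos, "G" + unit, "G"
    # microhomology deletions: body, then its m-prefix, then a mismatching G
    body = _MH_BODY_LONG if (length, b) == (5, 5) else _MH_BODY[length]
    seq = _PAD + body + body[:b] + "G" + _PAD
    return seq, anchor_pos, "G" + body, "G"
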