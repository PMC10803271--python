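"""Trinucleotide-context conventions for single-base-substitution catalogs.

Catalogs use the standard 96-channel convention: substitutions are expressed
on the pyrimidine strand (reference base C or T), each with its 5' and 3'
flanking base, ordered C>A, C>G, C>T, T>A, T>C, T>G and within each
substitution by 5' then 3' flank (A, C, G, T).
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in "ACGT"
    for three in "ACGT"
)

CONTEXT_INDEX = {ctx: i for i, ctx in enumerate(CONTEXTS_96)}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def context_label(trinuc: str, alt: str) -> str:
    """Pyrimidine-strand context label for a SNV.

    ``trinuc`` is the reference trinucleotide centred on the variant site and
    ``alt`` the alternate base, both on the forward genomic strand. Purine
    reference bases are reverse-complemented onto the pyrimidine strand.
    """
    if len(trinuc) != 3:
        raise ValueError(f"need a trinucleotide, got {trinuc!r}")
    ref = trinuc[1]
    if ref in "GA":
        trinuc = revcomp(trinuc)
        alt = COMPLEMENT[alt]
        ref = trinuc[1]
    if ref == alt:
        raise ValueError("ref and alt are identical")
    return f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"


def pyrimidine_trinuc(trinuc: str) -> str:
    """Normalize a trinucleotide so its centre base is a pyrimidine."""
    return trinuc if trinuc[1] in "CT" else revcomp(trinuc)
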