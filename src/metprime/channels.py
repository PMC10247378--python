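"""Mutation-context channel conventions.

Channel name generation for the three COSMIC context layouts used throughout
the pipeline: 96 single-base-substitution (SBS) channels, 78 doublet-base-
substitution (DBS) channels and 83 small insertion/deletion (ID) channels.
Channel order is deterministic and documented here; every context-count
matrix in the package uses these orderings.
"""

from __future__ import annotations

from functools import lru_cache

BASES = "ACGT"
PYRIMIDINE_REFS = ("C", "T")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def sbs96_channels() -> tuple[str, ...]:
    """The 96 SBS channels, e.g. ``A[C>T]G``.

    Ordered by substitution (C>A, C>G, C>T, T>A, T>C, T>G), then 5' base,
    then 3' base — the COSMIC plotting order.
    """
    out = []
    for ref in PYRIMIDINE_REFS:
        for alt in BASES:
            if alt == ref:
                continue
            for five in BASES:
                for three in BASES:
                    out.append(f"{five}[{ref}>{alt}]{three}")
    return tuple(out)


@lru_cache(maxsize=None)
def dbs78_channels() -> tuple[str, ...]:
    """The 78 DBS channels, e.g. ``AC>CA``.

    Ten reference doublets; alternate doublets differ from the reference at
    both positions; palindromic references (AT, CG, GC, TA) have their
    reverse-complement-equivalent alternates collapsed (lexicographically
    smaller representative kept), giving 6*9 + 4*6 = 78 channels.
    """
    refs = ["AC", "AT", "CC", "CG", "CT", "GC", "TA", "TC", "TG", "TT"]
    out = []
    for ref in refs:
        palindromic = revcomp(ref) == ref
        seen = set()
        for a0 in BASES:
            if a0 == ref[0]:
                continue
            for a1 in BASES:
                if a1 == ref[1]:
                    continue
                alt = a0 + a1
                if palindromic:
                    rep = min(alt, revcomp(alt))
                    if rep in seen:
                        continue
                    seen.add(rep)
                    alt = rep
                out.append(f"{ref}>{alt}")
    return tuple(out)


@lru_cache(maxsize=None)
def id83_channels() -> tuple[str, ...]:
    """The 83 ID channels in COSMIC naming, e.g. ``1:Del:C:0``.

    12 one-base deletions, 12 one-base insertions, 24 repeat-mediated
    deletions, 24 repeat-mediated insertions and 11 microhomology deletions.
    """
    out = []
    for ref in ("C", "T"):  # 1bp deletions by homopolymer length 1..6+
        out.extend(f"1:Del:{ref}:{n}" for n in range(6))
    for ref in ("C", "T"):  # 1bp insertions
        out.extend(f"1:Ins:{ref}:{n}" for n in range(6))
    for size in ("2", "3", "4", "5"):  # longer deletions at repeats
        out.extend(f"{size}:Del:R:{n}" for n in range(6))
    for size in ("2", "3", "4", "5"):  # longer insertions at repeats
        out.extend(f"{size}:Ins:R:{n}" for n in range(6))
    for size, mhmax in (("2", 1), ("3", 2), ("4", 3), ("5", 5)):
        out.extend(f"{size}:Del:M:{n}" for n in range(1, mhmax + 1))
    return tuple(out)


def channels_for(mutation_type: str) -> tuple[str, ...]:
    try:
        return {
            "SBS": sbs96_channels(),
            "DBS": dbs78_channels(),
            "ID": id83_channels(),
        }[mutation_type]
    except KeyError:
        raise ValueError(f"unknown mutation type: {mutation_type!r}") from None


def parse_sbs_channel(channel: str) -> tuple[str, str, str]:
    """Split ``A[C>T]G`` into (trinucleotide context, ref, alt)."""
    five, rest = channel[0], channel[2:]
    ref, alt, three = rest[0], rest[2], rest[4]
    return five + ref + three, ref, alt
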