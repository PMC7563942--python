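"""Canonical miRNA seed-site detection in 3'UTR sequences.

miRNA targeting is dominated by Watson-Crick pairing between the miRNA
"seed" (nucleotides 2-7, counted 5'→3') and a complementary stretch of the
target 3'UTR.  The canonical site hierarchy, strongest first:

* ``8mer``    — seed match extended by a match to miRNA nt 8 *and* an A in
  the UTR opposite miRNA nt 1;
* ``7mer-m8`` — seed match plus the nt-8 match;
* ``7mer-A1`` — seed match plus the opposite-position-1 A;
* ``6mer``    — the bare seed match.

Because the duplex is antiparallel, the UTR site read 5'→3' is the reverse
complement of the miRNA seed: the nt-8 match sits immediately 5' of the
core site on the UTR and the position-1 A immediately 3' of it.  Each core
match is reported once, under its strongest applicable type.  G:U wobble
pairs can optionally be accepted inside the complementary stretch; the
position-1 A is an identity requirement on the UTR and is never relaxed.

Sequences may be given as RNA or DNA; matching is alphabet-agnostic (T is
treated as U), so re-encoding a sequence never changes the reported sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AlphabetError, ValidationError

__all__ = ["NucSequence", "SeedSite", "reverse_complement", "find_seed_sites"]

_RNA = set("ACGU")
_DNA = set("ACGT")
_COMPLEMENT_RNA = str.maketrans("ACGU", "UGCA")
_COMPLEMENT_DNA = str.maketrans("ACGT", "TGCA")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")  # strongest first


@dataclass(frozen=True)
class NucSequence:
    """A nucleotide sequence stored 5'→3' with an explicit alphabet tag."""

    id: str
    seq: str
    alphabet: str = field(default="")

    def __post_init__(self):
        seq = self.seq.upper()
        object.__setattr__(self, "seq", seq)
        if not seq:
            raise AlphabetError(f"{self.id}: empty sequence")
        letters = set(seq)
        if "U" in letters and "T" in letters:
            raise AlphabetError(f"{self.id}: U and T mixed in one sequence")
        alphabet = self.alphabet
        if not alphabet:
            alphabet = "RNA" if "U" in letters else "DNA"
        if alphabet == "RNA" and not letters <= _RNA:
            raise AlphabetError(f"{self.id}: invalid RNA residues {letters - _RNA}")
        if alphabet == "DNA" and not letters <= _DNA:
            raise AlphabetError(f"{self.id}: invalid DNA residues {letters - _DNA}")
        if alphabet not in ("RNA", "DNA"):
            raise AlphabetError(f"{self.id}: unknown alphabet {alphabet!r}")
        object.__setattr__(self, "alphabet", alphabet)

    def as_rna(self) -> str:
        return self.seq.replace("T", "U")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SeedSite:
    """One seed-complementary site on a UTR.

    ``start``/``end`` are 0-based half-open offsets on the UTR; the
    human-readable report uses 1-based inclusive coordinates
    (``start_1based = start + 1``, ``end_1based = end``).
    """

    utr_id: str
    site_type: str
    start: int
    end: int
    matched_seq: str

    def __post_init__(self):
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}
        if self.site_type not in expected:
            raise ValidationError(f"unknown site type {self.site_type!r}")
        if self.end - self.start != expected[self.site_type]:
            raise ValidationError(
                f"{self.site_type} site must span {expected[self.site_type]} nt"
            )

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end


def reverse_complement(seq: NucSequence) -> NucSequence:
    """Reverse complement preserving the RNA/DNA alphabet."""
    table = _COMPLEMENT_RNA if seq.alphabet == "RNA" else _COMPLEMENT_DNA
    return NucSequence(
        id=seq.id, seq=seq.seq.translate(table)[::-1], alphabet=seq.alphabet
    )


def _pairs(mirna_base: str, utr_base: str, allow_gu: bool) -> bool:
    """Can the miRNA base pair with the UTR base (both given as RNA)?"""
    if (mirna_base, utr_base) in (("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")):
        return True
    return allow_gu and (mirna_base, utr_base) in (("G", "U"), ("U", "G"))


def find_seed_sites(
    mirna: NucSequence, utr: NucSequence, allow_gu: bool = False
) -> list[SeedSite]:
    """Scan a 3'UTR for canonical seed sites of a miRNA.

    The UTR is scanned for 6-nt windows pairing with miRNA positions 2-7
    (remember the antiparallel geometry: UTR window position ``i+k`` pairs
    with miRNA position ``7−k``).  Each window is then classified by
    whether the flanking UTR base 5' of the window pairs with miRNA nt 8
    and whether the base 3' of the window is an A, and reported once with
    the strongest type.  Sites are returned in UTR order.
    """
    if len(mirna) < 8:
        raise ValidationError("miRNA must be at least 8 nt for seed classification")
    if len(utr) < 6:
        raise ValidationError("UTR must be at least 6 nt")
    m = mirna.as_rna()
    u = utr.as_rna()
    sites = []
    for i in range(len(u) - 5):
        # core: UTR[i..i+5] pairs miRNA nt 7..2
        if not all(_pairs(m[6 - k], u[i + k], allow_gu) for k in range(6)):
            continue
        m8 = i >= 1 and _pairs(m[7], u[i - 1], allow_gu)
        a1 = i + 6 < len(u) and u[i + 6] == "A"
        if m8 and a1:
            site_type, start, end = "8mer", i - 1, i + 7
        elif m8:
            site_type, start, end = "7mer-m8", i - 1, i + 6
        elif a1:
            site_type, start, end = "7mer-A1", i, i + 7
        else:
            site_type, start, end = "6mer", i, i + 6
        sites.append(
            SeedSite(
                utr_id=utr.id,
                site_type=site_type,
                start=start,
                end=end,
                matched_seq=utr.seq[start:end],
            )
        )
    return sites
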