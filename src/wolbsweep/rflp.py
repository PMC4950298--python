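"""In-silico PCR-RFLP haplotyping of COI amplicons.

The assay amplifies a 546-bp fragment of the mitochondrial *COI* gene and
digests it with HaeIII (GG^CC, blunt cut after the second base).  The two
haplotypes differ by a single synonymous transition that creates or
destroys the restriction site: HT2 is cut into 342- and 204-bp fragments,
HT1 stays undigested at 546 bp.  Anything else on the gel is flagged
``unknown`` (would go to sequencing in the wet lab).

Site search is an exact scan on the given strand; IUPAC ambiguity codes in
the sequence never match the motif (conservative no-cut), so poor-quality
sequence cannot produce a spurious cut.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC_CODES",
    "Amplicon",
    "Enzyme",
    "HAEIII",
    "Assay",
    "COI_ASSAY",
    "DigestResult",
    "digest",
    "call_haplotype",
    "type_amplicon",
    "type_fasta",
]

IUPAC_CODES = set("ACGTRYSWKMBDHVN")


@dataclass(frozen=True)
class Amplicon:
    """A pre-trimmed PCR product (uppercase nucleotides, IUPAC allowed)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValueError(f"amplicon {self.id!r} has an empty sequence")
        bad = set(self.seq) - IUPAC_CODES
        if bad:
            raise ValueError(f"amplicon {self.id!r} has non-IUPAC characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    @classmethod
    def from_record(cls, record: SeqRecord) -> "Amplicon":
        return cls(record.id, str(record.seq))


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: recognition motif and cut offset within it."""

    name: str
    motif: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.motif) < 1:
            raise ValueError("motif must be non-empty")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError("cut offset must lie within the motif")


#: HaeIII: GG^CC, blunt cut between GG and CC.
HAEIII = Enzyme("HaeIII", "GGCC", 2)


@dataclass(frozen=True)
class Assay:
    """Expected fragment profile of a diagnostic digest.

    ``tolerance`` is the gel-resolution slack (bp) allowed when matching
    fragment sizes; agarose calls are approximate.
    """

    enzyme: Enzyme = HAEIII
    amplicon_length: int = 546
    cut_fragments: tuple[int, ...] = (342, 204)
    tolerance: int = 5


#: The COI HaeIII assay: 546 bp; HT2 cuts to 342 + 204, HT1 is uncut.
COI_ASSAY = Assay()


@dataclass(frozen=True)
class DigestResult:
    """Fragments (5'->3' order), cut positions, and the haplotype call."""

    fragments: tuple[int, ...]
    cut_positions: tuple[int, ...]
    call: str | None = None

    def __post_init__(self) -> None:
        if list(self.cut_positions) != sorted(set(self.cut_positions)):
            raise ValueError("cut positions must be strictly increasing")


def digest(seq: Amplicon | str, enzyme: Enzyme = HAEIII) -> DigestResult:
    """Cut at every exact motif occurrence on the given strand.

    Fragment lengths always sum to the input length.  An empty sequence
    yields an empty result with zero fragments.
    """
    s = seq.seq if isinstance(seq, Amplicon) else seq.upper()
    if not s:
        return DigestResult((), ())
    cuts = [i + enzyme.cut_offset for i in _find_all(s, enzyme.motif)]
    cuts = [c for c in cuts if 0 < c < len(s)]
    bounds = [0, *cuts, len(s)]
    fragments = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(fragments, tuple(cuts))


def _find_all(s: str, motif: str) -> Iterator[int]:
    i = s.find(motif)
    while i != -1:
        yield i
        i = s.find(motif, i + 1)


def call_haplotype(result: DigestResult, assay: Assay = COI_ASSAY) -> str:
    """HT1/HT2/unknown from a digest's fragment profile.

    HT1: a single fragment of (about) full amplicon length.  HT2: the
    fragment multiset matches the assay's cut profile within the gel
    tolerance.  Anything else: unknown.
    """
    tol = assay.tolerance
    frags = sorted(result.fragments)
    if len(frags) == 1:
        return "HT1" if abs(frags[0] - assay.amplicon_length) <= tol else "unknown"
    expected = sorted(assay.cut_fragments)
    if len(frags) == len(expected) and all(
        abs(f - e) <= tol for f, e in zip(frags, expected)
    ):
        return "HT2"
    return "unknown"


def type_amplicon(seq: Amplicon | str, assay: Assay = COI_ASSAY) -> DigestResult:
    """Digest and call in one step; the result carries the call."""
    result = digest(seq, assay.enzyme)
    return replace(result, call=call_haplotype(result, assay))


def type_fasta(path: str | Path, assay: Assay = COI_ASSAY) -> pd.DataFrame:
    """Type every record of a FASTA file; tidy report (id, fragments, call)."""
    rows = []
    for record in SeqIO.parse(str(path), "fasta"):
        result = type_amplicon(Amplicon.from_record(record), assay)
        rows.append(
            {
                "id": record.id,
                "length": len(record.seq),
                "fragments": "+".join(map(str, result.fragments)),
                "n_cuts": len(result.cut_positions),
                "call": result.call,
            }
        )
    return pd.DataFrame(rows, columns=["id", "length", "fragments", "n_cuts", "call"])
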