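"""i-motif sequence model: repeat notation, tract/loop regions, C:C+ pairing.

An intramolecular i-motif is formed by four cytosine tracts connected by
three loops (named loop1, loop2, loop3 reading 5'->3').  The four tracts
assemble into two parallel-stranded duplexes (tracts 1+3 and tracts 2+4)
held together by hemi-protonated C:C+ base pairs, and the two duplexes
intercalate in an antiparallel fashion.

This module parses the compact repeat notation used for model i-motifs,
e.g. ``d[(CCCTTT)3CCC]``, locates tracts and loops on the expanded
sequence, and enumerates the C:C+ pair topology under a chosen
intercalation register.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass
from pathlib import Path

from .errors import SequenceParseError

__all__ = [
    "IMotifSequence",
    "RegionMap",
    "CCPair",
    "CCPairTopology",
    "REGISTERS",
    "parse_imotif_notation",
    "assign_regions",
    "build_cc_pair_topology",
    "load_sequence",
]

_NOTATION_RE = re.compile(
    r"^d?\[\(([ACGT]+)\)(\d+)([ACGT]*)\]$", flags=re.IGNORECASE
)

#: Supported intercalation registers for :func:`build_cc_pair_topology`.
#: ``aligned``: the i-th cytosine of tract 1 pairs the i-th of tract 3
#: (likewise 2/4).  ``shifted``: partners are offset by one position
#: cyclically, so e.g. the pair C2c:C4a exists for tract length 3.
REGISTERS = ("aligned", "shifted")


@dataclass(frozen=True)
class IMotifSequence:
    """An expanded i-motif sequence with located tracts and loops.

    Residue spans are 1-based and inclusive, 5'->3'.
    """

    name: str
    notation: str
    sequence: str
    tracts: tuple[tuple[int, int], ...]
    loops: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.tracts) != 4:
            raise SequenceParseError(
                f"{self.name!r}: need exactly 4 C-tracts, found {len(self.tracts)}"
            )
        if len(self.loops) != 3:
            raise SequenceParseError(
                f"{self.name!r}: need exactly 3 loops, found {len(self.loops)}"
            )
        lengths = {hi - lo + 1 for lo, hi in self.tracts}
        if len(lengths) != 1:
            raise SequenceParseError(
                f"{self.name!r}: unequal tract lengths {sorted(lengths)}"
            )
        # tracts and loops must alternate and tile the whole sequence
        spans = []
        for i in range(3):
            spans.append(self.tracts[i])
            spans.append(self.loops[i])
        spans.append(self.tracts[3])
        cursor = 1
        for lo, hi in spans:
            if lo != cursor or hi < lo:
                raise SequenceParseError(
                    f"{self.name!r}: tract/loop spans do not tile the sequence"
                )
            cursor = hi + 1
        if cursor != len(self.sequence) + 1:
            raise SequenceParseError(
                f"{self.name!r}: spans do not cover the full sequence"
            )
        for lo, hi in self.tracts:
            if set(self.sequence[lo - 1 : hi]) != {"C"}:
                raise SequenceParseError(
                    f"{self.name!r}: non-cytosine residue inside tract {lo}-{hi}"
                )

    @property
    def tract_length(self) -> int:
        lo, hi = self.tracts[0]
        return hi - lo + 1

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def loop_sequences(self) -> tuple[str, ...]:
        return tuple(self.sequence[lo - 1 : hi] for lo, hi in self.loops)


@dataclass(frozen=True)
class RegionMap:
    """Per-residue region labels: ``core`` or ``loop1``/``loop2``/``loop3``."""

    labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.labels)

    def residues(self, region: str) -> tuple[int, ...]:
        """1-based residue indices carrying ``region``.

        ``region`` may be ``core``, ``loopN``, ``loop`` (union of all
        loops) or ``whole``.
        """
        if region == "whole":
            return tuple(range(1, len(self.labels) + 1))
        if region == "loop":
            return tuple(
                i + 1 for i, lab in enumerate(self.labels) if lab.startswith("loop")
            )
        return tuple(i + 1 for i, lab in enumerate(self.labels) if lab == region)


@dataclass(frozen=True)
class CCPair:
    """One C:C+ base pair between duplex partner tracts.

    Positions within a tract are 0-based internally; display names use
    the field convention C<tract><letter> with letters a, b, c ... 5'->3',
    e.g. ``C2c:C4a``.
    """

    tract_i: int
    pos_i: int
    tract_j: int
    pos_j: int

    @property
    def name(self) -> str:
        letters = string.ascii_lowercase
        return (
            f"C{self.tract_i}{letters[self.pos_i]}:"
            f"C{self.tract_j}{letters[self.pos_j]}"
        )

    def residue_indices(self, seq: IMotifSequence) -> tuple[int, int]:
        """1-based residue indices of the two paired cytosines."""
        lo_i = seq.tracts[self.tract_i - 1][0]
        lo_j = seq.tracts[self.tract_j - 1][0]
        return lo_i + self.pos_i, lo_j + self.pos_j


@dataclass(frozen=True)
class CCPairTopology:
    pairs: tuple[CCPair, ...]
    register: str

    def __len__(self) -> int:
        return len(self.pairs)

    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.pairs)

    def by_name(self, name: str) -> CCPair:
        for p in self.pairs:
            if p.name == name:
                return p
        raise KeyError(f"no pair named {name!r}")


def _normalise_notation(text: str) -> str:
    # drop whitespace and the subscript markers sometimes used in print
    return text.strip().replace("_", "").replace(" ", "")


def _find_tracts(sequence: str) -> list[tuple[int, int]]:
    """Maximal runs of >=2 consecutive C, as 1-based inclusive spans."""
    return [
        (m.start() + 1, m.end()) for m in re.finditer(r"C{2,}", sequence)
    ]


def parse_imotif_notation(text: str, name: str | None = None) -> IMotifSequence:
    """Parse repeat notation or a plain DNA string into an :class:`IMotifSequence`.

    Accepts ``d[(<unit>)<n><tail>]`` (the leading ``d`` and subscript
    underscores are optional) or a plain A/C/G/T sequence.  Tracts are
    located on the expanded sequence as maximal runs of two or more
    consecutive cytosines; exactly four equal-length tracts separated by
    three non-empty loops are required.

    >>> s = parse_imotif_notation("d[(CCCTTT)3CCC]")
    >>> s.sequence
    'CCCTTTCCCTTTCCCTTTCCC'
    >>> s.tracts
    ((1, 3), (7, 9), (13, 15), (19, 21))
    """
    raw = text
    text = _normalise_notation(text)
    m = _NOTATION_RE.match(text)
    if m:
        unit, count, tail = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
        if count < 1:
            raise SequenceParseError(f"repeat count must be >=1 in {raw!r}")
        sequence = unit * count + tail
    elif re.fullmatch(r"[ACGT]+", text, flags=re.IGNORECASE):
        sequence = text.upper()
    else:
        raise SequenceParseError(
            f"cannot interpret {raw!r}: neither repeat notation d[(unit)nTail] "
            "nor a plain A/C/G/T sequence"
        )

    tracts = _find_tracts(sequence)
    if len(tracts) != 4:
        raise SequenceParseError(
            f"{raw!r}: expected four C-tracts (runs of >=2 C), found {len(tracts)}"
        )
    lengths = {hi - lo + 1 for lo, hi in tracts}
    if len(lengths) != 1:
        raise SequenceParseError(f"{raw!r}: unequal C-tract lengths {sorted(lengths)}")
    if tracts[0][0] != 1 or tracts[-1][1] != len(sequence):
        raise SequenceParseError(
            f"{raw!r}: sequence must start and end with a C-tract"
        )
    loops = tuple(
        (tracts[i][1] + 1, tracts[i + 1][0] - 1) for i in range(3)
    )
    for lo, hi in loops:
        if hi < lo:
            raise SequenceParseError(f"{raw!r}: empty loop between adjacent tracts")
    return IMotifSequence(
        name=name or raw.strip(),
        notation=raw.strip(),
        sequence=sequence,
        tracts=tuple(tracts),
        loops=loops,
    )


def assign_regions(seq: IMotifSequence) -> RegionMap:
    """Label every residue ``core`` (inside a tract) or ``loopN``."""
    labels = ["core"] * seq.n_residues
    for n, (lo, hi) in enumerate(seq.loops, start=1):
        for i in range(lo, hi + 1):
            labels[i - 1] = f"loop{n}"
    return RegionMap(labels=tuple(labels))


def build_cc_pair_topology(
    seq: IMotifSequence, register: str = "aligned"
) -> CCPairTopology:
    """Enumerate C:C+ pairs between duplex partner tracts (1-3 and 2-4).

    ``aligned`` pairs position i of a tract with position i of its
    partner; ``shifted`` offsets the partner by one position cyclically
    (position i pairs position (i+1) mod L), which produces pair names
    such as ``C2c:C4a`` at tract length 3.  Both conventions yield
    2 x tract-length pairs with every cytosine in at most one pair.
    """
    if register not in REGISTERS:
        raise SequenceParseError(
            f"unsupported register {register!r}; choose from {REGISTERS}"
        )
    L = seq.tract_length
    pairs: list[CCPair] = []
    for ti, tj in ((1, 3), (2, 4)):
        for k in range(L):
            kj = k if register == "aligned" else (k + 1) % L
            pairs.append(CCPair(tract_i=ti, pos_i=k, tract_j=tj, pos_j=kj))
    return CCPairTopology(pairs=tuple(pairs), register=register)


def load_sequence(source: str | Path, name: str | None = None) -> IMotifSequence:
    """Load a sequence from repeat notation, a plain string, or a FASTA file.

    If ``source`` names an existing file it is read as FASTA and the
    first record is used; otherwise it is parsed directly.
    """
    path = Path(str(source))
    if path.exists() and path.is_file():
        from Bio import SeqIO

        try:
            record = next(SeqIO.parse(str(path), "fasta"))
        except StopIteration:
            raise SequenceParseError(f"{path}: no FASTA records found") from None
        return parse_imotif_notation(str(record.seq), name=name or record.id)
    return parse_imotif_notation(str(source), name=name)
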