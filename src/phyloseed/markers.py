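"""Core of a low-copy nuclear marker mining pipeline: longest-ORF detection,
copy-number screening from precomputed similarity-hit tables, and selection of
amplifiable windows in alignments.

External search/alignment/tree tools are consumed as files (BLAST
outfmt-6-style hit tables, FASTA alignments); running them is out of scope,
which keeps this module testable offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "OrfResult",
    "Hit",
    "HitTable",
    "longest_orf",
    "copy_number_screen",
    "find_amplicon_windows",
    "AmpliconWindow",
]

_VALID = set("ACGTN")
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfResult:
    """An ATG-initiated open reading frame on either strand.

    ``start``/``end`` are 0-based half-open coordinates on the *input* strand;
    for minus-strand ORFs they delimit the region whose reverse complement is
    the reading frame.  ``frame`` is +1/+2/+3 or -1/-2/-3.
    """

    frame: int
    start: int
    end: int
    terminated: bool  # ends at a stop codon (False: ran off the sequence end)

    @property
    def length(self) -> int:
        return self.end - self.start


def longest_orf(sequence: str, allow_unterminated: bool = False) -> OrfResult | None:
    """Longest ATG-initiated ORF over all six reading frames.

    By default an ORF must end at a stop codon; with ``allow_unterminated``
    an ORF may run off the 3' end of its frame (flagged ``terminated=False``).
    Ties are broken plus strand first, then lowest start coordinate.
    Returns None when no ORF exists.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        raise ValueError("sequence must be at least 3 nt")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid nucleotide characters: {sorted(bad)}")
    n = len(seq)
    rc = str(Seq(seq).reverse_complement())
    candidates: list[tuple[int, int, int, int, bool]] = []
    # (-length, strand_order, start, frame, terminated) for sorting
    for strand, s in ((1, seq), (-1, rc)):
        for off in range(3):
            i = off
            while i + 3 <= n:
                if s[i : i + 3] == "ATG":
                    j = i + 3
                    terminated = False
                    while j + 3 <= n:
                        if s[j : j + 3] in _STOPS:
                            j += 3
                            terminated = True
                            break
                        j += 3
                    if terminated or allow_unterminated:
                        if strand == 1:
                            start, end = i, j
                        else:  # map back to input-strand coordinates
                            start, end = n - j, n - i
                        frame = strand * (off + 1)
                        candidates.append(
                            (-(j - i), 0 if strand == 1 else 1, start, frame, terminated)
                        )
                    # skip to after this ORF in the same frame
                    i = j
                else:
                    i += 3
    if not candidates:
        return None
    neg_len, _, start, frame, terminated = min(candidates)
    return OrfResult(
        frame=frame, start=start, end=start - neg_len, terminated=terminated
    )


@dataclass(frozen=True)
class Hit:
    subject: str
    assembly: str
    evalue: float
    start: int = 0
    end: int = 0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("e-values must be non-negative")


@dataclass(frozen=True)
class HitTable:
    query: str
    hits: tuple[Hit, ...] = field(default_factory=tuple)

    @classmethod
    def from_rows(cls, query: str, rows: Iterable[tuple]) -> "HitTable":
        """Rows of (assembly, subject, evalue[, start, end])."""
        hits = []
        for k, row in enumerate(rows):
            try:
                assembly, subject, evalue = row[0], row[1], float(row[2])
                start = int(row[3]) if len(row) > 3 else 0
                end = int(row[4]) if len(row) > 4 else 0
            except (IndexError, TypeError, ValueError) as exc:
                raise ValueError(f"malformed hit table row {k + 1}: {row!r}") from exc
            hits.append(
                Hit(subject=subject, assembly=assembly, evalue=evalue, start=start, end=end)
            )
        return cls(query=query, hits=tuple(hits))


def copy_number_screen(
    table: HitTable, evalue_cutoff: float = 1e-6, min_seqs: int = 4
) -> str:
    """Classify a candidate locus from its similarity hits.

    Hits are filtered at ``evalue_cutoff``; loci with fewer than ``min_seqs``
    retained hits are 'insufficient' (too few sequences to build a useful
    alignment/tree), loci with more than one retained hit in any single
    assembly are 'multi-copy-suspect', and the rest are 'candidate-low-copy'.
    """
    kept = [h for h in table.hits if h.evalue <= evalue_cutoff]
    if len(kept) < min_seqs:
        return "insufficient"
    per_assembly: dict[str, int] = {}
    for h in kept:
        per_assembly[h.assembly] = per_assembly.get(h.assembly, 0) + 1
    if any(c > 1 for c in per_assembly.values()):
        return "multi-copy-suspect"
    return "candidate-low-copy"


@dataclass(frozen=True)
class AmpliconWindow:
    """Candidate amplicon: alignment-column window plus conserved flanks."""

    start: int  # column index of the first window column (0-based)
    end: int  # half-open column end
    ungapped_min: int  # shortest ungapped sequence span inside the window
    variable_sites: int
    flank_identity: float


def _pairwise_identity(cols: Sequence[str]) -> float:
    """Mean pairwise identity over alignment columns (gap counts as mismatch)."""
    total = 0
    same = 0
    for col in cols:
        m = len(col)
        for a in range(m):
            for b in range(a + 1, m):
                total += 1
                if col[a] == col[b] and col[a] != "-":
                    same += 1
    return same / total if total else 1.0


def find_amplicon_windows(
    alignment: Sequence[str],
    min_len: int = 400,
    max_len: int = 750,
    flank_len: int = 25,
    flank_identity: float = 0.9,
) -> list[AmpliconWindow]:
    """Candidate PCR-amplifiable windows in a nucleotide alignment.

    A window qualifies when every sequence's ungapped span inside it lies in
    ``[min_len, max_len]`` and the ``flank_len`` columns on each side have
    mean pairwise identity >= ``flank_identity`` (conserved primer sites).
    Windows are ranked by the number of internal variable columns,
    descending; maximal non-overlapping candidates are reported.
    """
    if len(alignment) < 2:
        raise ValueError("need at least two aligned sequences")
    L = len(alignment[0])
    if any(len(s) != L for s in alignment):
        raise ValueError("ragged alignment: sequences differ in length")
    aln = [s.upper() for s in alignment]
    cols = ["".join(s[c] for s in aln) for c in range(L)]
    col_identity = [_pairwise_identity([c]) for c in cols]
    variable = [len({b for b in c if b != "-"}) > 1 for c in cols]

    def flank_ok(lo: int, hi: int) -> float | None:
        if lo < flank_len or hi + flank_len > L:
            return None
        left = col_identity[lo - flank_len : lo]
        right = col_identity[hi : hi + flank_len]
        ident = (sum(left) + sum(right)) / (2 * flank_len)
        return ident if ident >= flank_identity else None

    results: list[AmpliconWindow] = []
    # scan window end positions greedily: for each start, grow until the
    # shortest ungapped span exceeds max_len
    ungapped = [[0] * (L + 1) for _ in aln]
    for si, s in enumerate(aln):
        for c in range(L):
            ungapped[si][c + 1] = ungapped[si][c] + (s[c] != "-")

    starts = range(flank_len, L - flank_len)
    for lo in starts:
        for hi in range(lo + min_len, min(L - flank_len, lo + max_len * 2) + 1):
            spans = [ug[hi] - ug[lo] for ug in ungapped]
            if min(spans) > max_len:
                break
            if min(spans) < min_len or max(spans) > max_len:
                continue
            ident = flank_ok(lo, hi)
            if ident is None:
                continue
            nvar = sum(variable[lo:hi])
            results.append(
                AmpliconWindow(
                    start=lo,
                    end=hi,
                    ungapped_min=min(spans),
                    variable_sites=nvar,
                    flank_identity=ident,
                )
            )
    results.sort(key=lambda w: (-w.variable_sites, w.start, w.end))
    # drop overlapping lower-ranked windows
    chosen: list[AmpliconWindow] = []
    for w in results:
        if all(w.end <= c.start or w.start >= c.end for c in chosen):
            chosen.append(w)
    return chosen
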