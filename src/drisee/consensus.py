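"""Per-bin alignment, consensus calling and per-column event classification.

Each ADR bin's non-prefix regions are star-aligned: a seed (the most
frequent non-prefix string) anchors pairwise global alignments of every
member, the pairwise gap patterns are merged into one column space, and a
per-column majority vote yields the consensus — the internal reference
standard against which every member read is scored. One refinement pass
re-aligns all members to that consensus. The procedure is deterministic:
member order never changes the result.

Pairwise alignment is Needleman–Wunsch with linear gap costs, delegated
to Bio.Align.PairwiseAligner; the first optimal alignment it enumerates
is taken, which is deterministic for fixed inputs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align

from drisee.binning import PrefixBin

GAP = "-"
MASKED = "N"  # consensus symbol for columns where N holds the plurality

DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP = -2.0


class EmptyBinError(ValueError):
    """All members of a bin have empty non-prefix regions; skip the bin."""


@dataclass
class AlignedPair:
    """A pairwise global alignment; removing gaps recovers the inputs."""

    query_gapped: str
    target_gapped: str
    score: float


@dataclass
class PositionEvent:
    """One classified read base at one ungapped consensus position.

    ``kind`` is one of match / substitution / insertion / deletion;
    match and substitution carry the consensus base (substitutions are
    keyed by the consensus base: an error at a consensus-A position
    counts toward the A substitution class).
    """

    consensus_index: int  # 1-based in the ungapped consensus
    kind: str
    base: str | None = None


@dataclass
class BinAlignment:
    """Gapped rows of a bin's non-prefix regions plus their consensus.

    ``consensus`` is a gapped string over {A,C,G,T,-,N}: ``-`` marks
    insertion columns (majority of members have no base there) and ``N``
    marks masked columns (N plurality; excluded from all tallies). Every
    row has the same gapped length as the consensus.
    """

    prefix: str
    prefix_length: int
    consensus: str
    rows: list[str]

    @property
    def abundance(self) -> int:
        return len(self.rows)

    def ungapped_consensus(self) -> str:
        return self.consensus.replace(GAP, "")


def _make_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def align_pair_global(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> AlignedPair:
    """Optimal global (Needleman–Wunsch) alignment of ``a`` against ``b``
    under linear gap scoring; deterministic tie-breaking."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(match, mismatch, gap)
    aln = aligner.align(a, b)[0]
    return AlignedPair(query_gapped=str(aln[0]), target_gapped=str(aln[1]), score=aln.score)


def call_consensus(columns: Sequence[Mapping[str, int]]) -> str:
    """Majority-vote consensus over per-column {A,C,G,T,N,-} counts.

    Per column: the winning base (ties broken A<C<G<T) is the consensus
    unless gaps outnumber it — then the column is an insertion column
    (``-``, no consensus base); a base wins a base-vs-gap tie. N votes
    never elect a base; a column where N outnumbers both the best base
    and the gaps is masked (``N``) and excluded from all tallies.
    """
    if not columns:
        raise ValueError("need at least one column")
    out = []
    for col in columns:
        base, base_count = min(
            ((b, col.get(b, 0)) for b in "ACGT"),
            key=lambda item: (-item[1], item[0]),
        )
        gaps = col.get(GAP, 0)
        ns = col.get("N", 0)
        if ns > base_count and ns > gaps:
            out.append(MASKED)
        elif gaps > base_count:
            out.append(GAP)
        else:
            out.append(base)
    return "".join(out)


def classify_read_column(
    consensus_symbol: str, read_symbol: str, consensus_index: int
) -> PositionEvent | None:
    """Classify one read symbol against its consensus column.

    ``consensus_index`` is the 1-based ungapped consensus position of the
    column (for insertion columns: the nearest preceding base position,
    left-anchored, 1 if none precedes). Masked columns, and gaps inside
    insertion columns, yield no event.
    """
    if consensus_symbol == MASKED:
        return None
    if consensus_symbol == GAP:  # insertion column
        if read_symbol == GAP:
            return None
        return PositionEvent(consensus_index=consensus_index, kind="insertion")
    if read_symbol == consensus_symbol:
        return PositionEvent(consensus_index=consensus_index, kind="match", base=consensus_symbol)
    if read_symbol == GAP:
        return PositionEvent(consensus_index=consensus_index, kind="deletion", base=consensus_symbol)
    return PositionEvent(
        consensus_index=consensus_index, kind="substitution", base=consensus_symbol
    )


def _pick_seed(suffixes: Sequence[str]) -> str:
    """Most frequent non-empty suffix; ties by length (longest), then
    lexicographic — independent of member order."""
    counts = Counter(s for s in suffixes if s)
    return min(counts.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))[0]


def _star_align(
    suffixes: Sequence[str], target: str, aligner: Align.PairwiseAligner
) -> list[str]:
    """Align every suffix to ``target`` and merge the pairwise gap
    patterns into a common column space.

    Insertions relative to the target are grouped by junction (the count
    of target bases already consumed); each junction's width is the
    maximum insertion length over members, and shorter insertions are
    left-aligned within their junction block.
    """
    pairs: list[tuple[str, str] | None] = []
    for s in suffixes:
        if not s:
            pairs.append(None)  # empty non-prefix region: all-gap row
        elif s == target:
            pairs.append((s, target))  # fast path, same result as aligning
        else:
            aln = aligner.align(s, target)[0]
            pairs.append((str(aln[0]), str(aln[1])))

    n_junctions = len(target) + 1
    master_ins = [0] * n_junctions
    per_member_ins: list[list[int] | None] = []
    for pair in pairs:
        if pair is None:
            per_member_ins.append(None)
            continue
        _, t_gapped = pair
        ins = [0] * n_junctions
        consumed = 0
        for tc in t_gapped:
            if tc == GAP:
                ins[consumed] += 1
            else:
                consumed += 1
        per_member_ins.append(ins)
        for j, k in enumerate(ins):
            if k > master_ins[j]:
                master_ins[j] = k

    total_cols = len(target) + sum(master_ins)
    rows = []
    for pair, ins in zip(pairs, per_member_ins):
        if pair is None:
            rows.append(GAP * total_cols)
            continue
        s_gapped, t_gapped = pair
        row: list[str] = []
        buf: list[str] = []
        consumed = 0
        for sc, tc in zip(s_gapped, t_gapped):
            if tc == GAP:
                buf.append(sc)
            else:
                row.extend(buf)
                row.extend(GAP * (master_ins[consumed] - len(buf)))
                buf = []
                row.append(sc)
                consumed += 1
        row.extend(buf)
        row.extend(GAP * (master_ins[len(target)] - len(buf)))
        rows.append("".join(row))
    return rows


def _column_counts(rows: Sequence[str]) -> list[Counter]:
    ncols = len(rows[0])
    cols = [Counter() for _ in range(ncols)]
    for row in rows:
        for i, c in enumerate(row):
            cols[i][c] += 1
    return cols


def build_bin_alignment(
    bin_: PrefixBin,
    l: int,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap: float = DEFAULT_GAP,
) -> BinAlignment:
    """Star-align a bin's non-prefix regions and call their consensus.

    Seeds on the most frequent non-prefix string, star-aligns all members
    to it, majority-votes a consensus, then performs exactly one
    refinement pass (re-align all members to that consensus and re-vote).
    Raises :class:`EmptyBinError` when every member ends at the prefix.
    """
    if bin_.abundance < 2:
        raise ValueError(f"bin {bin_.prefix!r}: need at least 2 members")
    if any(len(m.bases) < l for m in bin_.members):
        raise ValueError(f"bin {bin_.prefix!r}: member shorter than prefix length {l}")
    suffixes = [m.bases[l:] for m in bin_.members]
    if not any(suffixes):
        raise EmptyBinError(f"bin {bin_.prefix!r}: all non-prefix regions are empty")

    aligner = _make_aligner(match, mismatch, gap)

    seed = _pick_seed(suffixes)
    rows = _star_align(suffixes, seed, aligner)
    consensus = call_consensus(_column_counts(rows))

    # one refinement pass against the voted consensus
    refined_target = consensus.replace(GAP, "")
    if refined_target:  # degenerate all-insertion consensus: keep seed round
        rows = _star_align(suffixes, refined_target, aligner)
        consensus = call_consensus(_column_counts(rows))

    return BinAlignment(
        prefix=bin_.prefix, prefix_length=l, consensus=consensus, rows=rows
    )
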