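"""Error profiles: per-position event counts and their summaries.

An :class:`ErrorProfile` counts, per 1-based reported read position,
matches by base, substitutions by consensus base, insertions and
deletions, accumulated over all reads of all considered ADR bins.
Positions 1..l are the prefix — pure matches by construction, present so
whole-read profiles can be plotted, but never entering summary
statistics: only the non-prefix bases carry error information.

Two summary forms are computed. The count-weighted form (``Total_err``)
divides each class's event count by the grand total of events over
non-prefix positions. The position-averaged form (``Total_avg_err``)
averages each position's percent error over all covered non-prefix
positions, weighting every position equally regardless of coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from drisee.consensus import GAP, MASKED, BinAlignment, classify_read_column
from drisee.seqio import SequenceRead, phred_to_error_percent

EVENT_COLUMNS = [
    "match_A",
    "match_T",
    "match_C",
    "match_G",
    "match_N",
    "subst_A",
    "subst_T",
    "subst_C",
    "subst_G",
    "insertion",
    "deletion",
]

_SUBST_OF = {"A": "subst_A", "T": "subst_T", "C": "subst_C", "G": "subst_G"}
_MATCH_OF = {"A": "match_A", "T": "match_T", "C": "match_C", "G": "match_G", "N": "match_N"}

SUMMARY_COMPONENTS = ["A_subst", "T_subst", "C_subst", "G_subst", "InDel"]


@dataclass
class ErrorProfile:
    """Per-position event counts; index is the 1-based reported position
    (prefix positions 1..l, then consensus positions l+1, l+2, ...)."""

    counts: pd.DataFrame
    prefix_length: int

    def coverage(self) -> pd.Series:
        """Total classified events per position."""
        return self.counts.sum(axis=1)

    def nonprefix(self) -> pd.DataFrame:
        return self.counts.loc[self.counts.index > self.prefix_length]


@dataclass
class ProfileSummary:
    """Per-type and total error percentages, count-weighted and
    position-averaged; in both forms Total is the sum of the five
    components (A/T/C/G substitutions and InDel)."""

    weighted: dict[str, float]
    averaged: dict[str, float]


def _empty_counts(n_positions: int) -> pd.DataFrame:
    return pd.DataFrame(
        0,
        index=pd.RangeIndex(1, n_positions + 1),
        columns=EVENT_COLUMNS,
        dtype=np.int64,
    )


def tally_bin(alignment: BinAlignment) -> ErrorProfile:
    """Tally every (read row, column) of a bin alignment into a profile.

    Prefix positions 1..l receive match counts of the prefix base times
    the bin abundance. Non-prefix columns are classified per read against
    the consensus symbol; ungapped consensus position i reports at l+i.
    Terminal gaps (a read starting after or ending before the consensus)
    are not deletions — read-length variation is not per-base error — and
    masked columns contribute nothing.
    """
    l = alignment.prefix_length
    n_cons = len(alignment.ungapped_consensus())
    counts = _empty_counts(l + n_cons)
    arr = {c: counts[c].to_numpy() for c in EVENT_COLUMNS}

    for p, base in enumerate(alignment.prefix, start=1):
        arr[_MATCH_OF[base]][p - 1] += alignment.abundance

    # per-row span of real bases; columns outside are terminal gaps
    spans = []
    for row in alignment.rows:
        stripped = row.strip(GAP)
        if not stripped:
            spans.append(None)
        else:
            first = len(row) - len(row.lstrip(GAP))
            spans.append((first, first + len(stripped) - 1))

    cons_index = 0  # 1-based ungapped consensus position of current column
    for c, sym in enumerate(alignment.consensus):
        if sym != GAP:
            cons_index += 1
        anchor = max(cons_index, 1)
        for row, span in zip(alignment.rows, spans):
            if span is None or not (span[0] <= c <= span[1]):
                continue
            event = classify_read_column(sym, row[c], anchor)
            if event is None:
                continue
            pos = l + event.consensus_index - 1  # 0-based into arrays
            if event.kind == "match":
                arr[_MATCH_OF[event.base]][pos] += 1
            elif event.kind == "substitution":
                arr[_SUBST_OF[event.base]][pos] += 1
            elif event.kind == "insertion":
                arr["insertion"][pos] += 1
            else:
                arr["deletion"][pos] += 1

    for c in EVENT_COLUMNS:
        counts[c] = arr[c]
    return ErrorProfile(counts=counts, prefix_length=l)


def aggregate_profiles(profiles: Iterable[ErrorProfile]) -> ErrorProfile:
    """Element-wise sum of profiles (same prefix length); positions absent
    from shorter profiles contribute zero."""
    profiles = list(profiles)
    if not profiles:
        return ErrorProfile(counts=_empty_counts(0), prefix_length=0)
    lengths = {p.prefix_length for p in profiles}
    if len(lengths) > 1:
        raise ValueError(f"mixed prefix lengths: {sorted(lengths)}")
    total = profiles[0].counts
    for p in profiles[1:]:
        total = total.add(p.counts, fill_value=0)
    return ErrorProfile(
        counts=total.astype(np.int64), prefix_length=profiles[0].prefix_length
    )


def normalize_profile(profile: ErrorProfile) -> pd.DataFrame:
    """Per-position percentages: each count over the position's total
    events, times 100. Zero-coverage positions are all-NaN rows (no data,
    not zero error); every covered row sums to 100."""
    if profile.counts.empty:
        raise ValueError("cannot normalize an empty profile")
    cov = profile.coverage()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = profile.counts.div(cov.where(cov > 0), axis=0) * 100.0
    return pct


def summarize(profile: ErrorProfile) -> ProfileSummary:
    """Count-weighted and position-averaged error summaries over the
    non-prefix positions; InDel merges insertions and deletions and Total
    is the sum of the five components in each form."""
    np_counts = profile.nonprefix()
    cov = np_counts.sum(axis=1)
    covered = np_counts.loc[cov > 0]
    if covered.empty:
        raise ValueError("no covered non-prefix positions to summarize")

    grand = covered.to_numpy().sum()
    weighted = {
        "A_subst": float(100.0 * covered["subst_A"].sum() / grand),
        "T_subst": float(100.0 * covered["subst_T"].sum() / grand),
        "C_subst": float(100.0 * covered["subst_C"].sum() / grand),
        "G_subst": float(100.0 * covered["subst_G"].sum() / grand),
        "InDel": float(
            100.0 * (covered["insertion"].sum() + covered["deletion"].sum()) / grand
        ),
    }
    weighted["Total"] = sum(weighted.values())

    row_tot = covered.sum(axis=1)
    n_pos = len(covered)
    averaged = {
        "A_subst": float((100.0 * covered["subst_A"] / row_tot).mean()),
        "T_subst": float((100.0 * covered["subst_T"] / row_tot).mean()),
        "C_subst": float((100.0 * covered["subst_C"] / row_tot).mean()),
        "G_subst": float((100.0 * covered["subst_G"] / row_tot).mean()),
        "InDel": float(
            (100.0 * (covered["insertion"] + covered["deletion"]) / row_tot).mean()
        ),
    }
    averaged["Total"] = sum(averaged.values())
    return ProfileSummary(weighted=weighted, averaged=averaged)


def total_error_by_position(profile: ErrorProfile) -> pd.Series:
    """Per-position total error percent (substitutions + insertions +
    deletions over all events at that position); NaN where uncovered."""
    pct = normalize_profile(profile)
    err_cols = ["subst_A", "subst_T", "subst_C", "subst_G", "insertion", "deletion"]
    return pct[err_cols].sum(axis=1, min_count=1)


def phred_profile(reads: Iterable[SequenceRead]) -> pd.Series:
    """Mean Phred-implied percent error per 1-based read position, over
    all reads covering that position."""
    sums: list[float] = []
    ns: list[int] = []
    seen = False
    for read in reads:
        seen = True
        if read.quals is None:
            raise ValueError(f"read {read.id!r} has no quality scores")
        if len(read.quals) > len(sums):
            pad = len(read.quals) - len(sums)
            sums.extend([0.0] * pad)
            ns.extend([0] * pad)
        for i, q in enumerate(read.quals):
            sums[i] += phred_to_error_percent(q)
            ns[i] += 1
    if not seen:
        raise ValueError("empty read stream")
    values = np.array(sums) / np.array(ns)
    return pd.Series(values, index=pd.RangeIndex(1, len(values) + 1))


def compare_profiles(drisee: pd.Series, phred: pd.Series) -> pd.DataFrame:
    """Position-aligned comparison of duplicate-inferred vs Phred-implied
    percent error over the overlap of covered positions."""
    if drisee.empty or phred.empty:
        raise ValueError("both profiles must be non-empty")
    d = drisee.dropna()
    p = phred.dropna()
    common = d.index.intersection(p.index)
    if common.empty:
        raise ValueError("profiles share no covered positions")
    out = pd.DataFrame(
        {
            "position": common,
            "drisee_percent": d.loc[common].to_numpy(),
            "phred_percent": p.loc[common].to_numpy(),
        }
    )
    out["difference"] = out["drisee_percent"] - out["phred_percent"]
    return out.reset_index(drop=True)
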