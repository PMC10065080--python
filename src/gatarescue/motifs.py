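"""IUPAC consensus motif scanning and composite-element grammars.

Scans peak sequences for single consensus motifs (default families: the
GATA-binding WGATAR, the E-box CANNTG, ETS AGGAAR, and EBF TCCCNNGGGA),
for E-box--spacer--WGATAR composite elements with a 6-14 bp spacer, and for
tandem double-WGATAR pairs with up to a 5 bp spacer, then compares peak
classes with proportion and rank statistics.

Conventions: coordinates are 0-based on the forward strand; a minus-strand
hit is a window whose reverse complement matches the consensus, reported at
its forward coordinates; a palindromic window that matches on both strands
is collapsed to a single plus-strand hit; spacers count the bases strictly
between the two component footprints; sequence ``N`` matches only the
consensus code ``N``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .chromatin import proportion_test, rank_tests

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}
_COMPLEMENT_CODE = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_COMPLEMENT_SEQ = str.maketrans("ACGTN", "TGCAN")


class MotifHit(NamedTuple):
    seq_id: str
    motif: str
    start: int
    strand: str
    match: str


class CompositeHit(NamedTuple):
    seq_id: str
    motif: str
    start: int          # start of the 5'-most component on the forward strand
    strand: str
    left_start: int     # forward coordinates of the two components
    right_start: int
    spacer: int
    match: str


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC consensus with a both-strands flag."""

    name: str
    consensus: str
    both_strands: bool = True

    def __post_init__(self):
        c = self.consensus.upper()
        bad = set(c) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"non-IUPAC codes in consensus: {sorted(bad)}")
        if len(c) < 4:
            raise ValueError("consensus must be at least 4 bases")
        object.__setattr__(self, "consensus", c)


WGATAR = MotifPattern("WGATAR", "WGATAR")
EBOX = MotifPattern("Ebox", "CANNTG")
ETS = MotifPattern("ETS", "AGGAAR")
EBF = MotifPattern("EBF", "TCCCNNGGGA")
DEFAULT_PATTERNS = (WGATAR, EBOX, ETS, EBF)


def reverse_complement_consensus(consensus: str) -> str:
    return consensus.upper().translate(_COMPLEMENT_CODE)[::-1]


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT_SEQ)[::-1]


def _validate_sequence(seq: str) -> str:
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in "ACGTN":
            raise ValueError(f"invalid character {ch!r} at position {i}")
    return seq


def _consensus_regex(consensus: str) -> re.Pattern:
    # Sequence N matches only code N; other codes expand to explicit classes.
    parts = []
    for code in consensus.upper():
        allowed = IUPAC_SETS[code]
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return re.compile(f"(?=({''.join(parts)}))")


def scan_iupac(seq: str, pattern: MotifPattern, seq_id: str = "") -> list[MotifHit]:
    """All (overlapping) matches of an IUPAC consensus in one sequence.

    With ``both_strands`` the reverse complement of the consensus is also
    scanned on the forward sequence; those hits are reported on the minus
    strand at forward coordinates. A position matching on both strands
    yields one plus-strand hit.
    """
    seq = _validate_sequence(seq)
    hits: dict[int, MotifHit] = {}
    for m in _consensus_regex(pattern.consensus).finditer(seq):
        hits[m.start()] = MotifHit(seq_id, pattern.name, m.start(), "+", m.group(1))
    if pattern.both_strands:
        rc = reverse_complement_consensus(pattern.consensus)
        for m in _consensus_regex(rc).finditer(seq):
            hits.setdefault(
                m.start(), MotifHit(seq_id, pattern.name, m.start(), "-", m.group(1))
            )
    return [hits[k] for k in sorted(hits)]


def scan_composite(
    seq: str,
    left: MotifPattern = EBOX,
    right: MotifPattern = WGATAR,
    spacer_min: int = 6,
    spacer_max: int = 14,
    both_strands: bool = True,
    seq_id: str = "",
) -> list[CompositeHit]:
    """Composite left--spacer--right elements (default E-box...WGATAR, 6-14 bp).

    Both components must lie on the same strand with the left element 5' of
    the right element on that strand; the spacer is the gap between their
    footprints, bounds inclusive. All overlapping composites are reported.
    """
    if not 0 <= spacer_min <= spacer_max:
        raise ValueError("need 0 <= spacer_min <= spacer_max")
    seq = _validate_sequence(seq)
    name = f"{left.name}-{right.name}"
    out: list[CompositeHit] = []
    strands = ("+", "-") if both_strands else ("+",)
    for strand in strands:
        if strand == "+":
            lpat, rpat = left.consensus, right.consensus
        else:
            # On the minus strand 5'->3' runs right-to-left in forward
            # coordinates: the right component appears first as a reverse
            # complement, then the left component.
            lpat, rpat = (
                reverse_complement_consensus(right.consensus),
                reverse_complement_consensus(left.consensus),
            )
        lhits = [(m.start(), m.group(1)) for m in _consensus_regex(lpat).finditer(seq)]
        rhits = [(m.start(), m.group(1)) for m in _consensus_regex(rpat).finditer(seq)]
        llen = len(lpat)
        for ls, _lm in lhits:
            for rs, _rm in rhits:
                spacer = rs - (ls + llen)
                if spacer_min <= spacer <= spacer_max:
                    if strand == "+":
                        left_fwd, right_fwd = ls, rs
                    else:
                        left_fwd, right_fwd = rs, ls
                    end = rs + len(rpat)
                    out.append(
                        CompositeHit(
                            seq_id, name, ls, strand, left_fwd, right_fwd,
                            spacer, seq[ls:end],
                        )
                    )
    out.sort(key=lambda h: (h.start, h.strand))
    return out


def scan_double(
    seq: str,
    pattern: MotifPattern = WGATAR,
    spacer_max: int = 5,
    orientations: Iterable[str] = ("++", "--", "+-"),
    seq_id: str = "",
) -> list[CompositeHit]:
    """Tandem motif pairs with a gap of at most ``spacer_max`` bases.

    Pairs are ordered by forward coordinate and must not overlap;
    ``orientations`` lists the allowed (first, second) strand combinations —
    the default admits same-strand tandems and convergent pairs.
    """
    if spacer_max < 0:
        raise ValueError("spacer_max must be nonnegative")
    hits = scan_iupac(seq, pattern, seq_id=seq_id)
    allowed = set(orientations)
    m = len(pattern.consensus)
    out = []
    for i, first in enumerate(hits):
        for second in hits[i + 1 :]:
            spacer = second.start - (first.start + m)
            if spacer < 0:
                continue
            if spacer > spacer_max:
                break
            if first.strand + second.strand in allowed:
                out.append(
                    CompositeHit(
                        seq_id,
                        f"2x{pattern.name}",
                        first.start,
                        first.strand + second.strand,
                        first.start,
                        second.start,
                        spacer,
                        seq[first.start : second.start + m],
                    )
                )
    return out


def hits_to_frame(hits: Iterable) -> pd.DataFrame:
    rows = [h._asdict() for h in hits]
    if not rows:
        return pd.DataFrame(columns=list(MotifHit._fields))
    return pd.DataFrame(rows)


def peak_set_motif_stats(
    sequences_by_class: Mapping[str, Mapping[str, str]],
    patterns: Iterable[MotifPattern] = DEFAULT_PATTERNS,
    include_composite: bool = True,
    include_double: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class motif presence statistics and pairwise enrichment tests.

    For each peak class and motif (plus, optionally, the E-box--WGATAR
    composite and the double-WGATAR grammar): the fraction of peaks with at
    least one hit and the hit density per kb. Every pair of classes is then
    compared per motif with the two-proportion continuity-corrected test on
    presence counts and a two-sided Mann-Whitney test on per-peak hit counts.
    """
    if any(len(seqs) == 0 for seqs in sequences_by_class.values()):
        raise ValueError("every class needs at least one sequence")

    scanners: list[tuple[str, callable]] = [
        (p.name, (lambda s, sid, p=p: scan_iupac(s, p, seq_id=sid))) for p in patterns
    ]
    if include_composite:
        scanners.append(
            ("Ebox-WGATAR", lambda s, sid: scan_composite(s, seq_id=sid))
        )
    if include_double:
        scanners.append(("2xWGATAR", lambda s, sid: scan_double(s, seq_id=sid)))

    stat_rows = []
    per_seq_counts: dict[tuple[str, str], np.ndarray] = {}
    for cls, seqs in sequences_by_class.items():
        total_kb = sum(len(s) for s in seqs.values()) / 1000.0
        for motif, scanner in scanners:
            counts = np.array([len(scanner(s, sid)) for sid, s in seqs.items()])
            per_seq_counts[(cls, motif)] = counts
            stat_rows.append(
                {
                    "class": cls,
                    "motif": motif,
                    "n_peaks": len(counts),
                    "n_with_hit": int((counts > 0).sum()),
                    "frac_with_hit": float((counts > 0).mean()),
                    "pct_with_hit": 100.0 * float((counts > 0).mean()),
                    "hits_per_kb": float(counts.sum() / total_kb) if total_kb else np.nan,
                }
            )
    stats_df = pd.DataFrame(stat_rows)

    classes = list(sequences_by_class)
    test_rows = []
    for i, c1 in enumerate(classes):
        for c2 in classes[i + 1 :]:
            for motif, _ in scanners:
                k1, k2 = per_seq_counts[(c1, motif)], per_seq_counts[(c2, motif)]
                z, p_prop = proportion_test(
                    int((k1 > 0).sum()), len(k1), int((k2 > 0).sum()), len(k2)
                )
                _, p_rank = rank_tests(k1, k2, kind="mann_whitney_two_sample")
                test_rows.append(
                    {
                        "class_1": c1,
                        "class_2": c2,
                        "motif": motif,
                        "frac_1": float((k1 > 0).mean()),
                        "frac_2": float((k2 > 0).mean()),
                        "proportion_z": z,
                        "proportion_p": p_prop,
                        "rank_p": p_rank,
                    }
                )
    return stats_df, pd.DataFrame(test_rows)
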