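"""Sequence-level utilities: classical NLS candidate scanning, peptide
extraction, and a charge-hydropathy disorder proxy.

The classical nuclear-localization-signal patterns follow the standard
consensus: monopartite K(K/R)X(K/R) and bipartite
(K/R)(K/R)-X(10-12)-[3 basic of 5].  The disorder proxy applies a windowed
charge-hydropathy boundary rule; it is a coarse convenience, not a
machine-learned disorder predictor.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .constants import AA1, KYTE_DOOLITTLE, RESIDUE_CHARGE
from .structure import Chain, Residue, StructureError

_BASIC = set("KR")


@dataclass
class MotifHit:
    kind: str                 # monopartite_cnls | bipartite_cnls | fg
    start: int                # 1-based inclusive
    end: int
    matched: str
    score: float              # basic-residue fraction in the window

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError("invalid hit coordinates")


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise StructureError("empty sequence")
    bad = sorted(set(sequence) - set(AA1) - {"X"})
    if bad:
        raise StructureError(f"non-amino-acid characters in sequence: {bad}")


def _basic_fraction(s: str) -> float:
    return sum(c in _BASIC for c in s) / len(s)


def find_cnls_candidates(sequence: str) -> list[MotifHit]:
    """All classical-NLS candidate windows (overlaps reported, deterministic)."""
    _validate_sequence(sequence)
    hits: list[MotifHit] = []
    for m in re.finditer(r"(?=(K[KR].[KR]))", sequence):
        s = m.start() + 1
        matched = m.group(1)
        hits.append(MotifHit("monopartite_cnls", s, s + 3, matched,
                             _basic_fraction(matched)))
    n = len(sequence)
    for i in range(n - 1):
        if sequence[i] in _BASIC and sequence[i + 1] in _BASIC:
            for spacer in (10, 11, 12):
                j = i + 2 + spacer          # 0-based start of the 5-window
                if j + 5 > n:
                    continue
                window = sequence[j:j + 5]
                if sum(c in _BASIC for c in window) >= 3:
                    matched = sequence[i:j + 5]
                    hits.append(MotifHit("bipartite_cnls", i + 1, j + 5,
                                         matched, _basic_fraction(matched)))
    hits.sort(key=lambda h: (h.start, h.end, h.kind))
    return hits


def extract_peptide(sequence_or_chain, start: int, end: int):
    """Extract an inclusive 1-based range from a sequence, or the residues
    with author numbers in [start, end] from a Chain (numbering preserved)."""
    if start > end or start < 1:
        raise StructureError(f"invalid range {start}-{end}")
    if isinstance(sequence_or_chain, str):
        seq = sequence_or_chain
        if end > len(seq):
            raise StructureError(
                f"range {start}-{end} out of bounds for length {len(seq)}")
        return seq[start - 1:end]
    if isinstance(sequence_or_chain, Chain):
        chain = sequence_or_chain
        picked = [r for r in chain.residues if start <= r.author_number <= end]
        if not picked:
            raise StructureError(
                f"no residues numbered {start}-{end} in chain {chain.id}")
        import copy
        return Chain(id=chain.id, residues=[copy.deepcopy(r) for r in picked])
    raise TypeError("expected a sequence string or a Chain")


def disorder_proxy(sequence: str, window: int = 21):
    """Windowed charge-hydropathy disorder call.

    For each residue, over a centered window (truncated at the ends), the
    mean Kyte-Doolittle hydropathy rescaled to [0, 1] is compared with the
    boundary (|mean net charge| + 1.151) / 2.785; residues below the
    boundary are called disordered.  Returns (scores, calls) where score is
    boundary minus rescaled hydropathy (positive = disordered).
    """
    _validate_sequence(sequence)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    n = len(sequence)
    if n < window:
        raise StructureError(f"sequence shorter than window ({n} < {window})")
    hyd = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in sequence])
    chg = np.array([RESIDUE_CHARGE.get(c, 0.0) for c in sequence])
    half = window // 2
    scores = np.empty(n)
    calls = np.empty(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        h01 = (hyd[lo:hi].mean() + 4.5) / 9.0
        q = abs(chg[lo:hi].mean())
        boundary = (q + 1.151) / 2.785
        scores[i] = boundary - h01
        calls[i] = h01 < boundary
    return scores, calls


def chain_fg_hits(sequence: str) -> list[MotifHit]:
    """FG dipeptides as MotifHit records (see fg.find_fg_motifs)."""
    from .fg import find_fg_motifs
    return [MotifHit("fg", p, p + 1, sequence[p - 1:p + 1], 0.0)
            for p in find_fg_motifs(sequence)]
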