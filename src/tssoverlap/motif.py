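"""PWM scanning of promoter sequences.

A PFM converts to a log-odds PWM with a total pseudocount split by the
background: for column j and base b,

    pwm[b, j] = log2( ((count + pseudocount * bg_b) / (colsum + pseudocount)) / bg_b )

with a uniform background and pseudocount 0.8 by default.  A window's
relative score is min-max normalised over all possible words,
``(raw - score_min) / (score_max - score_min)``; hits are reported at a
relative score of at least 0.95, the conventional "95% significance
score" of PWM scanning tools.  Both strands are scanned; a reverse
strand hit is reported on the forward coordinates of its window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .models import ALPHABET, Pfm

DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_REL_MIN = 0.95

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT_ROWS = np.array([3, 2, 1, 0])  # A<->T, C<->G


@dataclass
class Pwm:
    motif_id: str
    matrix: np.ndarray  # 4 x L log-odds
    score_min: float
    score_max: float

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    chrom: str
    start: int  # forward-strand window start, 0-based
    strand: str
    raw_score: float
    rel_score: float

    @property
    def end(self) -> int:
        return self.start  # end requires motif length; see scan()


def pfm_to_pwm(
    pfm: Pfm,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: Sequence[float] | None = None,
) -> Pwm:
    """Log-odds PWM with per-column min/max attainable scores."""
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0) or np.any(bg <= 0):
        raise ValueError("background must be 4 positive probabilities summing to 1")
    counts = pfm.counts
    if counts.shape[1] < 1:
        raise ValueError("zero-length matrix")
    colsum = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    mat = np.log2(probs / bg[:, None])
    return Pwm(
        motif_id=pfm.motif_id,
        matrix=mat,
        score_min=float(mat.min(axis=0).sum()),
        score_max=float(mat.max(axis=0).sum()),
    )


def encode_sequence(seq: str) -> np.ndarray:
    """ACGT -> 0..3; any other symbol (N etc.) -> -1."""
    arr = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype=np.uint8) == ord(base)] = idx
    return arr


def _window_scores(encoded: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Score every length-L window; windows containing non-ACGT get NaN."""
    L = matrix.shape[1]
    n = len(encoded) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for j in range(L):
        col = encoded[j : j + n]
        bad = col < 0
        valid &= ~bad
        scores += matrix[np.clip(col, 0, 3), j]
    scores[~valid] = np.nan
    return scores


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def scan(
    sequence: str,
    pwm: Pwm,
    rel_min: float = DEFAULT_REL_MIN,
    both_strands: bool = True,
    chrom: str = "",
    offset: int = 0,
) -> list[MotifHit]:
    """All windows with relative score >= rel_min, both strands.

    ``offset`` shifts reported window starts onto genomic coordinates
    (the sequence's genomic start).  Sequences shorter than the motif
    yield an empty list; windows containing N are skipped.
    """
    L = pwm.length
    span = pwm.score_max - pwm.score_min
    encoded = encode_sequence(sequence)
    hits: list[MotifHit] = []

    def collect(strand: str, matrix: np.ndarray) -> None:
        scores = _window_scores(encoded, matrix)
        for i, raw in enumerate(scores):
            if np.isnan(raw):
                continue
            rel = 1.0 if span == 0 else (raw - pwm.score_min) / span
            if rel >= rel_min:
                hits.append(
                    MotifHit(
                        motif_id=pwm.motif_id,
                        chrom=chrom,
                        start=offset + i,
                        strand=strand,
                        raw_score=float(raw),
                        rel_score=float(rel),
                    )
                )

    collect("+", pwm.matrix)
    if both_strands:
        # Scoring the reverse strand of window i equals scoring the forward
        # sequence with the reverse-complemented matrix.
        rc_matrix = pwm.matrix[_COMPLEMENT_ROWS][:, ::-1]
        collect("-", rc_matrix)
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_many(
    sequences: dict[str, str],
    pwms: Sequence[Pwm],
    rel_min: float = DEFAULT_REL_MIN,
    offsets: dict[str, int] | None = None,
) -> list[MotifHit]:
    """Scan every sequence with every PWM; sequence names become chroms."""
    out = []
    for name, seq in sequences.items():
        off = 0 if offsets is None else offsets.get(name, 0)
        for pwm in pwms:
            out.extend(scan(seq, pwm, rel_min=rel_min, chrom=name, offset=off))
    return out


def hits_to_bed(hits: Sequence[MotifHit], motif_lengths: dict[str, int]) -> list[str]:
    """BED6+2 lines (extra columns: rel_score, raw_score)."""
    lines = []
    for h in hits:
        L = motif_lengths[h.motif_id]
        lines.append(
            f"{h.chrom}\t{h.start}\t{h.start + L}\t{h.motif_id}\t0\t{h.strand}"
            f"\t{h.rel_score:.6f}\t{h.raw_score:.6f}"
        )
    return lines
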