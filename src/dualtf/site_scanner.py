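"""PWM scanning of CRM sequences into discrete binding-site maps.

A PWM is scored as log-odds in bits against a background base composition.
Scanning a CRM keeps every window, on either strand, whose score reaches a
bits threshold; each kept window becomes a :class:`TFBS` carrying a
normalized affinity ``q = score / s_max`` where ``s_max`` is the best score
the matrix can award.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DNA_ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(DNA_ALPHABET)}
_COMPLEMENT_INDEX = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT order

#: Uniform base composition.
UNIFORM_BACKGROUND = np.full(4, 0.25)

#: D. melanogaster intergenic composition (A, C, G, T).
DMEL_BACKGROUND = np.array([0.297, 0.203, 0.203, 0.297])

BACKGROUNDS = {"uniform": UNIFORM_BACKGROUND, "dmel": DMEL_BACKGROUND}

#: Default scan threshold in bits.
DEFAULT_THRESHOLD_BITS = 9.0

#: Floor substituted for zero probability cells before taking log-odds.
PSEUDOCOUNT = 1e-3


@dataclass(frozen=True)
class PWM:
    """Position weight matrix with derived log-odds scores (base 2).

    Parameters
    ----------
    name:
        TF identifier; must be unique within a scan panel.
    probs:
        ``L x 4`` row-stochastic matrix over A, C, G, T.
    background:
        Length-4 background frequencies summing to 1.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        background = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError(f"PWM {self.name!r}: probs must be L x 4, got {probs.shape}")
        if probs.shape[0] < 1:
            raise ValueError(f"PWM {self.name!r}: empty matrix")
        if np.any(probs < 0):
            raise ValueError(f"PWM {self.name!r}: negative probabilities")
        row_sums = probs.sum(axis=1)
        bad = np.where(np.abs(row_sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValueError(
                f"PWM {self.name!r}: row {bad[0]} sums to {row_sums[bad[0]]:.6g}, not 1"
            )
        if background.shape != (4,) or abs(background.sum() - 1.0) > 1e-6:
            raise ValueError(f"PWM {self.name!r}: background must be 4 frequencies summing to 1")
        if np.any(background <= 0):
            raise ValueError(f"PWM {self.name!r}: background frequencies must be positive")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", background)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """``L x 4`` log-odds matrix in bits; zero cells floored at PSEUDOCOUNT."""
        p = np.where(self.probs > 0, self.probs, PSEUDOCOUNT)
        return np.log2(p / self.background)

    @property
    def s_max(self) -> float:
        """Best achievable score: per-position maximum log-odds, summed."""
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        """Sequence picking the per-position argmax of the log-odds matrix."""
        return "".join(DNA_ALPHABET[i] for i in self.log_odds.argmax(axis=1))

    def with_background(self, background: np.ndarray) -> "PWM":
        return PWM(self.name, self.probs, np.asarray(background, dtype=float))

    def reverse_complement(self) -> "PWM":
        rc_bg = self.background[_COMPLEMENT_INDEX]
        return PWM(self.name, self.probs[::-1, _COMPLEMENT_INDEX], rc_bg)


@dataclass(frozen=True, order=True)
class TFBS:
    """One predicted binding site on a CRM (0-based, half-open interval)."""

    start: int
    tf: str
    strand: str
    score: float
    q: float
    length: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0.0 < self.q <= 1.0 + 1e-12:
            raise ValueError(f"normalized affinity q={self.q} outside (0, 1]")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def center(self) -> float:
        return self.start + self.length / 2.0


@dataclass
class TFBSMap:
    """Per-CRM lists of predicted sites, each sorted by start coordinate."""

    sites: dict[str, list[TFBS]]

    def __post_init__(self) -> None:
        for crm, lst in self.sites.items():
            self.sites[crm] = sorted(lst)

    def __getitem__(self, crm: str) -> list[TFBS]:
        return self.sites[crm]

    def __iter__(self):
        return iter(self.sites)

    def items(self):
        return self.sites.items()


def encode_dna(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes; unknown letters become -1."""
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(seq), -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[raw == ord(base)] = idx
    return out


def reverse_complement(seq: str) -> str:
    table = str.maketrans("ACGTacgt", "TGCAtgca")
    return seq.translate(table)[::-1]


def log_odds_score(pwm: PWM, window: str) -> float:
    """Score one window of length ``pwm.length`` as a sum of per-position bits."""
    if len(window) != pwm.length:
        raise ValueError(f"window length {len(window)} != PWM length {pwm.length}")
    codes = encode_dna(window)
    if np.any(codes < 0):
        pos = int(np.where(codes < 0)[0][0])
        raise ValueError(f"ambiguous base {window[pos]!r} at position {pos}")
    return float(pwm.log_odds[np.arange(pwm.length), codes].sum())


def _window_scores(log_odds: np.ndarray, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores of all windows plus a validity mask (no ambiguous base)."""
    L = log_odds.shape[0]
    n_win = codes.size - L + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = np.all(windows >= 0, axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = log_odds[np.arange(L), safe].sum(axis=1)
    return scores, valid


def scan_crm(
    pwm: PWM,
    seq: str,
    t: float = DEFAULT_THRESHOLD_BITS,
    background: np.ndarray | None = None,
    return_skipped: bool = False,
):
    """Scan both strands of ``seq``, keeping windows scoring at least ``t`` bits.

    Reverse-strand windows are scored on their reverse complement; the reported
    ``start`` is always the forward-strand offset of the window. Overlapping
    sites are retained. Windows containing an ambiguous base are skipped and
    counted.
    """
    if not np.isfinite(t):
        raise ValueError("threshold t must be finite")
    if background is not None:
        pwm = pwm.with_background(background)
    codes = encode_dna(seq)
    sites: list[TFBS] = []
    n_skipped = 0
    if len(seq) >= pwm.length:
        s_max = pwm.s_max
        for strand, matrix in (("+", pwm.log_odds), ("-", pwm.reverse_complement().log_odds)):
            scores, valid = _window_scores(matrix, codes)
            n_skipped += int((~valid).sum())
            for start in np.where(valid & (scores >= t))[0]:
                score = float(scores[start])
                sites.append(
                    TFBS(
                        start=int(start),
                        tf=pwm.name,
                        strand=strand,
                        score=score,
                        q=min(score / s_max, 1.0),
                        length=pwm.length,
                    )
                )
    sites.sort()
    if return_skipped:
        return sites, n_skipped
    return sites


def build_tfbs_map(
    crms: Iterable[tuple[str, str]] | "SequenceSetLike",
    pwms: Sequence[PWM],
    t: float = DEFAULT_THRESHOLD_BITS,
) -> TFBSMap:
    """Scan every CRM with every PWM and merge the hits into one map.

    ``crms`` is anything yielding ``(id, sequence)`` pairs (a ``SequenceSet``
    works). PWM names must be distinct. CRMs with no site for any TF are
    allowed and logged.
    """
    records = list(crms.records if hasattr(crms, "records") else crms)
    names = [p.name for p in pwms]
    if len(set(names)) != len(names):
        raise ValueError("PWM names must be distinct")
    out: dict[str, list[TFBS]] = {}
    for crm_id, seq in records:
        hits: list[TFBS] = []
        for pwm in pwms:
            hits.extend(scan_crm(pwm, seq, t))
        if not hits and pwms:
            logger.warning("CRM %s has no site above %.3g bits for any TF", crm_id, t)
        out[crm_id] = sorted(hits)
    return TFBSMap(out)
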