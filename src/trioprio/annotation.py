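"""Coding-coordinate arithmetic and predictor-score classification.

Maps HGVS c.-style coding positions to codon (amino-acid) indices, classifies
deletion-insertion events by their net length change, and binarizes SIFT and
PROVEAN scores with the conventional thresholds (SIFT <= 0.05 damaging;
PROVEAN < -2.5 deleterious).

Only the two HGVS forms ``c.NX>Y`` (substitution) and ``c.N_MdelXXinsYY``
(deletion-insertion) are parsed; anything else raises an explicit
"unsupported HGVS form" error.  Residue letters are carried from annotation
tables, never computed: translating them needs transcript sequences, which are
out of scope here.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "CodingChange",
    "cds_to_codon",
    "classify_delins",
    "sift_classify",
    "provean_classify",
    "parse_hgvs_c",
    "SIFT_DAMAGING_MAX",
    "PROVEAN_DELETERIOUS_THRESHOLD",
]

#: SIFT scores at or below this are called damaging.
SIFT_DAMAGING_MAX = 0.05
#: PROVEAN delta alignment scores strictly below this are called deleterious.
PROVEAN_DELETERIOUS_THRESHOLD = -2.5


@dataclass(frozen=True)
class CodingChange:
    """A coding-DNA change: 1-based CDS span plus deleted/inserted strings."""

    cds_start: int
    cds_end: int
    deleted: str = ""
    inserted: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.cds_start <= self.cds_end):
            raise ValueError(f"need cds_end >= cds_start >= 1, got "
                             f"{self.cds_start}_{self.cds_end}")

    @property
    def codon_start(self) -> int:
        return cds_to_codon(self.cds_start)

    @property
    def net_length_change(self) -> int:
        return len(self.inserted) - len(self.deleted)


def cds_to_codon(cds_pos: int) -> int:
    """1-based codon index of a 1-based CDS position: ``ceil(pos / 3)``.

    CDS positions 1-3 fall in codon 1, 4-6 in codon 2, and so on; this is the
    reading-frame identity behind amino-acid position columns in variant
    tables (e.g. c.1919 -> residue 640).
    """
    if cds_pos < 1:
        raise ValueError(f"CDS position must be >= 1, got {cds_pos}")
    return math.ceil(cds_pos / 3)


def classify_delins(change: CodingChange) -> str:
    """Classify a coding change by length arithmetic.

    ``substitution`` when the deleted and inserted strings have equal length;
    otherwise ``frameshift`` when the net length change is not a multiple of
    three, else ``inframe_delins``.

    A delins whose net change is -1 or +1 is a frameshift by this arithmetic
    even if an annotation table reports a single amino-acid change for it;
    such inconsistencies in upstream tables are reported as-is, never
    silently reconciled.
    """
    if len(change.deleted) == len(change.inserted):
        return "substitution"
    if change.net_length_change % 3 != 0:
        return "frameshift"
    return "inframe_delins"


def sift_classify(score: Optional[float]) -> str:
    """Binarize a SIFT score: ``damaging`` iff score <= 0.05, else ``tolerated``.

    Missing scores are ``unknown``.  Scores must lie in [0, 1].
    """
    if score is None:
        return "unknown"
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"SIFT score {score} outside [0,1]")
    return "damaging" if score <= SIFT_DAMAGING_MAX else "tolerated"


def provean_classify(score: Optional[float],
                     threshold: float = PROVEAN_DELETERIOUS_THRESHOLD) -> str:
    """Binarize a PROVEAN score: ``deleterious`` iff score < threshold.

    The conventional binary split defines only "< threshold" and
    "> threshold"; a score exactly at the threshold is called ``neutral``, the
    conservative (non-deleterious) choice.  Missing scores are ``unknown``.
    """
    if score is None:
        return "unknown"
    return "deleterious" if score < threshold else "neutral"


_SUB_RE = re.compile(r"^c\.(\d+)([ACGTN])>([ACGTN])$")
_DELINS_RE = re.compile(r"^c\.(\d+)_(\d+)del([ACGTN]+)ins([ACGTN]+)$")


def parse_hgvs_c(name: str) -> CodingChange:
    """Parse ``c.NX>Y`` or ``c.N_MdelXXinsYY`` into a :class:`CodingChange`.

    The deleted string's length must match the stated CDS span.  Any other
    HGVS form raises ``ValueError("unsupported HGVS form: ...")``.
    """
    name = name.strip()
    m = _SUB_RE.match(name)
    if m:
        pos = int(m.group(1))
        return CodingChange(pos, pos, deleted=m.group(2), inserted=m.group(3))
    m = _DELINS_RE.match(name)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        deleted, inserted = m.group(3), m.group(4)
        if end - start + 1 != len(deleted):
            raise ValueError(f"deleted length {len(deleted)} does not match span "
                             f"{start}_{end} in {name!r}")
        return CodingChange(start, end, deleted=deleted, inserted=inserted)
    raise ValueError(f"unsupported HGVS form: {name!r}")
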