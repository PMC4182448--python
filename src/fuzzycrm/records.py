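"""Genomic binding-site records.

All coordinates follow the BED convention: 0-based, half-open intervals
``[start, end)``. Formats using other conventions (GFF3) are converted on
read by :mod:`fuzzycrm.formats`.
"""
from __future__ import annotations

from dataclasses import dataclass

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class TFBSRecord:
    """One transcription factor binding site annotation.

    Parameters
    ----------
    tf_label
        Identifier of the transcription factor (or motif) bound at this site.
    chrom
        Sequence (chromosome/scaffold) name.
    start, end
        0-based half-open genomic interval; ``start < end``.
    strand
        ``+``, ``-`` or ``.`` (unknown). Carried through for output; the
        clustering and mining stages never condition on strand.
    score
        Optional unitless score (e.g. from a PWM scanner).
    """

    tf_label: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.tf_label:
            raise ValueError("tf_label must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.tf_label!r}: "
                "need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "TFBSRecord") -> bool:
        """Half-open interval overlap on the same chromosome.

        Abutting sites (``[0,10)`` and ``[10,20)``) do not overlap.
        """
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )
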