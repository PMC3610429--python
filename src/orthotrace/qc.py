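"""Input-eligibility and sequence-quality filters applied before orthology inference.

Two independent screens are implemented:

* a CDS/protein consistency check on paired FASTA input — an entry is eligible
  only if its CDS length is exactly three times the protein length, with or
  without one trailing stop codon, its id is unique, and it pairs one-to-one
  across the two files;
* a protein-quality filter that drops sequences shorter than 10 residues or
  with more than 20% stop symbols (``'*'``).

Both thresholds are strict inequalities; boundary cases (length exactly 10,
stop fraction exactly 20%) are kept.  Violations are always reported in the
:class:`QCReport`, never silently dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

MIN_PROTEIN_LENGTH = 10
MAX_STOP_FRACTION = 0.20

REASONS = (
    "short_protein",
    "high_stop_fraction",
    "cds_mismatch",
    "duplicate_id",
    "count_mismatch",
)


@dataclass
class QCReport:
    """Outcome of a QC screen: kept ids plus per-record removal reasons."""

    kept: set[str] = field(default_factory=set)
    removed: list[tuple[str, str]] = field(default_factory=list)
    count_mismatch: bool = False

    def __post_init__(self) -> None:
        removed_ids = {gid for gid, _ in self.removed}
        if self.kept & removed_ids:
            raise ValueError("kept and removed sets overlap")

    @property
    def removed_ids(self) -> set[str]:
        return {gid for gid, _ in self.removed}

    def reason_counts(self) -> dict[str, int]:
        return dict(Counter(reason for _, reason in self.removed))

    def as_rows(self) -> list[tuple[str, str]]:
        rows = [(gid, "kept") for gid in sorted(self.kept)]
        rows += sorted(self.removed)
        return rows


def _protein_core_length(seq: str) -> int:
    """Protein length with a single terminal stop symbol not counted."""
    return len(seq) - 1 if seq.endswith("*") else len(seq)


def validate_pgap_inputs(
    cds_records: Sequence[tuple[str, str]],
    protein_records: Sequence[tuple[str, str]],
    strict: bool = False,
) -> QCReport:
    """Check the CDS/protein eligibility criteria for paired FASTA input.

    An entry is kept iff its CDS length equals ``3*L`` or ``3*(L+1)`` for
    protein length ``L`` (one terminal stop codon tolerated; ``strict=True``
    accepts only ``3*(L+1)``), its id occurs exactly once in each file, and
    it has exactly one CDS-protein pairing.  ``count_mismatch`` is set when
    the two files differ in record totals.
    """
    prot_ids = [gid for gid, _ in protein_records]
    cds_ids = [gid for gid, _ in cds_records]
    dup = {gid for gid, n in Counter(prot_ids).items() if n > 1}
    dup |= {gid for gid, n in Counter(cds_ids).items() if n > 1}
    cds_len = {gid: len(seq) for gid, seq in cds_records}

    report = QCReport(count_mismatch=len(prot_ids) != len(cds_ids))
    seen: set[str] = set()
    for gid, seq in protein_records:
        if gid in seen:
            continue  # reported once
        seen.add(gid)
        if gid in dup:
            report.removed.append((gid, "duplicate_id"))
            continue
        if gid not in cds_len:
            report.removed.append((gid, "cds_mismatch"))
            continue
        L = _protein_core_length(seq)
        allowed = {3 * (L + 1)} if strict else {3 * L, 3 * (L + 1)}
        if cds_len[gid] in allowed:
            report.kept.add(gid)
        else:
            report.removed.append((gid, "cds_mismatch"))
    # CDS-only entries have no protein partner
    prot_set = set(prot_ids)
    for gid in cds_ids:
        if gid not in prot_set and gid not in dup:
            report.removed.append((gid, "cds_mismatch"))
        elif gid in dup and gid not in seen:
            report.removed.append((gid, "duplicate_id"))
            seen.add(gid)
    return report


def filter_quality(
    protein_records: Iterable[tuple[str, str]],
) -> QCReport:
    """Drop poor-quality proteins: length < 10 or > 20% stop symbols.

    A zero-length sequence is removed as ``short_protein`` (its stop
    fraction is undefined).
    """
    report = QCReport()
    for gid, seq in protein_records:
        n = len(seq)
        if n < MIN_PROTEIN_LENGTH:
            report.removed.append((gid, "short_protein"))
        elif seq.count("*") / n > MAX_STOP_FRACTION:
            report.removed.append((gid, "high_stop_fraction"))
        else:
            report.kept.add(gid)
    return report
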