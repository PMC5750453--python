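"""Three-group literature-support classification of candidate genes.

Genes are grouped by how often they were co-mentioned with allergy-related
terms in publications before versus since a cutoff year (the year the
first GWAS of an allergy-related trait appeared): group 1, frequently
co-cited before the cutoff; group 2, frequently co-cited only since; group
3, rarely or never co-cited.  Group 1 takes precedence over group 2, so a
gene well established before the cutoff stays in group 1 regardless of its
later count.
"""

from __future__ import annotations

from collections import Counter

from .errors import ValidationError
from .types import CitationRecord


def classify(record: CitationRecord, min_count: int = 5) -> int:
    """Group number (1, 2 or 3) for one gene.

    Group 1 if ``n_before >= min_count``; else group 2 if
    ``n_since >= min_count``; else group 3.
    """
    if min_count < 1:
        raise ValidationError(f"min_count must be at least 1: {min_count}")
    if record.n_before >= min_count:
        return 1
    if record.n_since >= min_count:
        return 2
    return 3


def group_sizes(
    records: list[CitationRecord], min_count: int = 5
) -> tuple[int, int, int]:
    """Sizes of the three groups; raises on duplicate genes."""
    dupes = [g for g, n in Counter(r.gene for r in records).items() if n > 1]
    if dupes:
        raise ValidationError(f"duplicate gene(s) in citation records: {dupes}")
    counts = Counter(classify(r, min_count) for r in records)
    return counts.get(1, 0), counts.get(2, 0), counts.get(3, 0)
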