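"""Haplotype-based linkage disequilibrium, greedy clumping and proxy search.

LD is computed from phased haplotypes, so r-squared is the exact squared
correlation of the two 0/1 allele indicator columns:

    r^2 = (p_ab - p_a * p_b)^2 / (p_a (1 - p_a) p_b (1 - p_b))

where ``p_ab`` is the frequency of haplotypes carrying the alternate allele
at both sites.  Clumping is the standard greedy, P-value-ordered reduction
of an association list to approximately independent index SNPs: variants
are visited in ascending P order, each unassigned variant becomes an index,
and every remaining unassigned variant on the same chromosome within the
window whose r^2 with the index exceeds the threshold joins its clump.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import MonomorphicSnpError, SnpLookupError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class HaplotypePanel:
    """Reference panel of phased haplotypes; the sole source of LD.

    Parameters
    ----------
    snp_ids
        Unique variant identifiers, one per column of ``H``.
    chrom
        Chromosome label per SNP.
    pos
        1-based base-pair coordinate per SNP; non-decreasing within each
        chromosome.
    alleles
        (ref, alt) allele pair per SNP.  ``H`` counts the alt allele.
    H
        Haplotype-by-SNP matrix of 0/1 alt-allele indicators, at least two
        rows.  Missingness must be resolved by the reader; the panel itself
        never holds missing values.
    ancestry_label
        Free-text provenance tag (e.g. "EUR").
    """

    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    alleles: list[tuple[str, str]]
    H: np.ndarray
    ancestry_label: str = ""
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.H = np.asarray(self.H)
        if self.H.ndim != 2:
            raise ValidationError("H must be a 2-D haplotype-by-SNP matrix")
        if self.H.shape[0] < 2:
            raise ValidationError("panel needs at least 2 haplotypes")
        if self.H.shape[1] != len(self.snp_ids):
            raise ValidationError("H column count does not match snp_ids")
        if len(self.alleles) != len(self.snp_ids) or len(self.chrom) != len(self.snp_ids) or len(self.pos) != len(self.snp_ids):
            raise ValidationError("per-SNP metadata lengths disagree")
        if not np.isin(self.H, (0, 1)).all():
            raise ValidationError("haplotype matrix entries must be 0 or 1")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("snp_ids must be unique")
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom.astype(str) == c]
            if np.any(np.diff(p) < 0):
                raise ValidationError(f"positions not non-decreasing on chromosome {c}")
        self.H = self.H.astype(np.uint8)
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_haplotypes(self) -> int:
        return self.H.shape[0]

    @property
    def n_snps(self) -> int:
        return self.H.shape[1]

    def index(self, snp: str) -> int:
        try:
            return self._index[snp]
        except KeyError:
            raise SnpLookupError(f"SNP {snp!r} not in panel") from None

    def __contains__(self, snp: str) -> bool:
        return snp in self._index

    def column(self, snp: str) -> np.ndarray:
        return self.H[:, self.index(snp)]


@dataclass
class Clump:
    """One group of correlated variants led by its most significant member."""

    index_snp: str
    members: list[str]
    index_p: float


def allele_freq(panel: HaplotypePanel, snp: str) -> float:
    """Alternate-allele frequency of ``snp``: the mean of its 0/1 column."""
    return float(panel.column(snp).mean())


def pairwise_r2(panel: HaplotypePanel, a: str, b: str) -> float:
    """Squared haplotype correlation between two polymorphic SNPs.

    Symmetric in its arguments.  Raises :class:`MonomorphicSnpError` for a
    monomorphic site, where LD is undefined (not zero).
    """
    ca, cb = panel.column(a), panel.column(b)
    pa, pb = float(ca.mean()), float(cb.mean())
    if pa in (0.0, 1.0):
        raise MonomorphicSnpError(f"LD undefined: {a!r} is monomorphic")
    if pb in (0.0, 1.0):
        raise MonomorphicSnpError(f"LD undefined: {b!r} is monomorphic")
    pab = float((ca & cb).mean())
    d = pab - pa * pb
    return d * d / (pa * (1.0 - pa) * pb * (1.0 - pb))


def _check_variants(
    variants: list[tuple[str, float]],
    panel: HaplotypePanel,
    missing: str,
) -> list[tuple[str, float]]:
    kept = []
    for snp, p in variants:
        if not (0.0 < p <= 1.0):
            raise ValidationError(f"P-value out of (0, 1] for {snp!r}: {p}")
        if snp not in panel:
            if missing == "error":
                raise SnpLookupError(f"variant {snp!r} absent from panel")
            logger.warning("dropping variant %s: absent from panel", snp)
            continue
        kept.append((snp, float(p)))
    return kept


def greedy_clump(
    variants: list[tuple[str, float]],
    panel: HaplotypePanel,
    r2_threshold: float = 0.05,
    window_bp: int | None = 1_000_000,
    missing: str = "drop",
) -> list[Clump]:
    """Greedy P-value-ordered LD clumping.

    Parameters
    ----------
    variants
        (snp_id, P-value) pairs; each variant must be present in the panel
        (or is dropped with a warning when ``missing="drop"``, the default).
    r2_threshold
        A variant joins an index's clump when its r^2 with the index is
        strictly greater than this value (independence is r^2 at or below
        the threshold).
    window_bp
        Half-window in base pairs around the index within which variants
        are considered; ``None`` disables the window (whole chromosome).
    missing
        "drop" (default) or "error" for variants absent from the panel.

    Returns
    -------
    list of :class:`Clump`, one per index SNP, in the order indices were
    chosen (ascending P).  Equal-P ties are broken by (chrom, pos, id) so
    the result is deterministic.
    """
    if not (0.0 < r2_threshold < 1.0):
        raise ValidationError(f"r2_threshold must be in (0, 1): {r2_threshold}")
    kept = _check_variants(variants, panel, missing)
    order = sorted(
        kept,
        key=lambda t: (t[1], str(panel.chrom[panel.index(t[0])]), int(panel.pos[panel.index(t[0])]), t[0]),
    )
    assigned: set[str] = set()
    clumps: list[Clump] = []
    for snp, p in order:
        if snp in assigned:
            continue
        i = panel.index(snp)
        members = [snp]
        assigned.add(snp)
        for other, _ in order:
            if other in assigned:
                continue
            j = panel.index(other)
            if str(panel.chrom[j]) != str(panel.chrom[i]):
                continue
            if window_bp is not None and abs(int(panel.pos[j]) - int(panel.pos[i])) > window_bp:
                continue
            if pairwise_r2(panel, snp, other) > r2_threshold:
                members.append(other)
                assigned.add(other)
        clumps.append(Clump(index_snp=snp, members=members, index_p=p))
    return clumps


def best_proxy(
    target: str,
    candidates: list[str],
    panel: HaplotypePanel,
    r2_min: float,
) -> tuple[str, float] | None:
    """Best LD proxy for ``target`` among ``candidates``.

    Returns the candidate with maximal r^2 to the target if that r^2 is at
    least ``r2_min``, else ``None``.  Ties are broken by smaller base-pair
    distance to the target, then lexicographic identifier.  Candidates
    absent from the panel or monomorphic are skipped with a warning; an
    empty candidate list yields ``None``.
    """
    ti = panel.index(target)
    tpos = int(panel.pos[ti])
    scored: list[tuple[float, int, str]] = []
    for c in candidates:
        if c not in panel:
            logger.warning("proxy candidate %s absent from panel; skipped", c)
            continue
        try:
            r2 = pairwise_r2(panel, target, c)
        except MonomorphicSnpError:
            logger.warning("proxy candidate %s monomorphic; skipped", c)
            continue
        scored.append((r2, abs(int(panel.pos[panel.index(c)]) - tpos), c))
    if not scored:
        return None
    # max r2; ties -> smaller distance, then lexicographic id
    best = min(scored, key=lambda t: (-t[0], t[1], t[2]))
    if best[0] >= r2_min:
        return best[2], best[0]
    return None
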