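"""Proteome-wide sliding-window motif scanning and site reporting.

Every serine/threonine position of every protein is tested against the
requested stringency tiers; each candidate site is reported once, labelled
with the most stringent tier it satisfies.  Per-tier tallies are
cumulative — a site matched at ``strict`` also counts toward the
``relaxed`` and ``permissive`` totals — so the report always satisfies the
nesting ``proteins(strict) ⊆ proteins(relaxed) ⊆ proteins(permissive)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ampkscan.motif import (
    BASIC,
    HYDROPHOBIC,
    MAX_OFFSET,
    MIN_OFFSET,
    PHOSPHOACCEPTOR,
    STANDARD_AA,
    TIER_RANK,
    TIERS,
    ConsensusMotif,
    build_motif,
)
from ampkscan.proteome_io import ProteinRecord

#: Fixed column order of the site TSV.
SITE_COLUMNS = (
    "protein_id",
    "gene_symbol",
    "position",
    "residue",
    "tier",
    "window",
    "window_start",
)

WINDOW_SPAN = MAX_OFFSET - MIN_OFFSET + 1  # 11


@dataclass(frozen=True)
class SiteMatch:
    """One predicted phosphosite.

    ``position`` is the 1-based residue index of the phosphoacceptor in
    the full protein; ``window`` is the -6..+4 subsequence actually present
    (terminal truncation shortens it) and ``window_start`` the 1-based
    index of its first residue.
    """

    protein_id: str
    position: int
    residue: str
    tier: str
    window: str
    window_start: int
    gene_symbol: str | None = None

    @property
    def padded_window(self) -> str:
        """The window padded with '-' for absent terminal positions."""
        pad_left = self.window_start - (self.position + MIN_OFFSET)
        pad_right = WINDOW_SPAN - pad_left - len(self.window)
        return "-" * pad_left + self.window + "-" * pad_right


@dataclass
class ScanReport:
    """Aggregated result of scanning a protein collection."""

    sites: list[SiteMatch]
    n_records: int
    tiers: tuple[str, ...]
    per_protein_counts: dict[str, int] = field(default_factory=dict)
    #: cumulative: proteins with >= 1 site at this tier or stricter
    tier_protein_counts: dict[str, int] = field(default_factory=dict)
    #: cumulative: sites at this tier or stricter
    tier_site_counts: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """One row per site, in the fixed diffable column order."""
        return pd.DataFrame(
            [
                {
                    "protein_id": s.protein_id,
                    "gene_symbol": s.gene_symbol,
                    "position": s.position,
                    "residue": s.residue,
                    "tier": s.tier,
                    "window": s.window,
                    "window_start": s.window_start,
                }
                for s in self.sites
            ],
            columns=list(SITE_COLUMNS),
        )

    def summary_frame(self) -> pd.DataFrame:
        """Per-tier totals: proteins with >= 1 site, and total sites."""
        return pd.DataFrame(
            {
                "tier": list(self.tiers),
                "proteins_with_site": [
                    self.tier_protein_counts.get(t, 0) for t in self.tiers
                ],
                "total_sites": [self.tier_site_counts.get(t, 0) for t in self.tiers],
            }
        )


def scan_protein(record: ProteinRecord, motif: ConsensusMotif) -> list[SiteMatch]:
    """All phosphoacceptor positions of one protein matching one motif.

    Sites are returned in ascending position order; overlapping matches
    are all reported and no position is reported twice.
    """
    sites: list[SiteMatch] = []
    seq = record.sequence
    n = len(seq)
    for i, aa in enumerate(seq):
        if aa not in PHOSPHOACCEPTOR:
            continue
        lo = max(0, i + MIN_OFFSET)
        hi = min(n, i + MAX_OFFSET + 1)
        window = seq[lo:hi]
        if motif.matches(window, i - lo):
            sites.append(
                SiteMatch(
                    protein_id=record.protein_id,
                    position=i + 1,
                    residue=aa,
                    tier=motif.tier,
                    window=window,
                    window_start=lo + 1,
                    gene_symbol=record.gene_symbol,
                )
            )
    return sites


def scan_proteome(
    records: Sequence[ProteinRecord],
    tiers: Iterable[str] = TIERS,
    require_full_window: bool | None = None,
    per_tier_rows: bool = False,
) -> ScanReport:
    """Scan a protein collection with one or more stringency tiers.

    Parameters
    ----------
    records : sequence of ProteinRecord
    tiers : iterable of tier labels
        Tiers to scan with; each site is labelled with the most stringent
        matching tier among these.
    require_full_window : bool, optional
        Passed through to :func:`ampkscan.motif.build_motif` (affects the
        permissive tier's default full-window policy).
    per_tier_rows : bool
        When true, a site is emitted once per matching tier instead of
        once with its best tier (the cumulative tallies are unchanged).

    Returns
    -------
    ScanReport
        Sites in deterministic order (input record order, then position)
        plus per-protein and cumulative per-tier tallies.
    """
    ordered = sorted(set(tiers), key=lambda t: _tier_rank(t))
    motifs = [build_motif(t, require_full_window) for t in ordered]
    sites: list[SiteMatch] = []
    per_protein: dict[str, int] = {}
    tier_sites = {t: 0 for t in ordered}
    tier_proteins: dict[str, set[str]] = {t: set() for t in ordered}
    for rec in records:
        best_by_pos: dict[int, SiteMatch] = {}
        rows_by_pos: dict[int, list[SiteMatch]] = {}
        for motif in motifs:  # most stringent first
            for site in scan_protein(rec, motif):
                best_by_pos.setdefault(site.position, site)
                rows_by_pos.setdefault(site.position, []).append(site)
        # cumulative tallies: a site counts at its best tier and every
        # looser requested tier, so the nesting invariant is structural
        for site in best_by_pos.values():
            for t in ordered:
                if _tier_rank(t) >= _tier_rank(site.tier):
                    tier_sites[t] += 1
                    tier_proteins[t].add(rec.protein_id)
        for pos in sorted(best_by_pos):
            if per_tier_rows:
                sites.extend(rows_by_pos[pos])
            else:
                sites.append(best_by_pos[pos])
        if best_by_pos:
            per_protein[rec.protein_id] = len(best_by_pos)
    return ScanReport(
        sites=sites,
        n_records=len(records),
        tiers=tuple(ordered),
        per_protein_counts=per_protein,
        tier_protein_counts={t: len(tier_proteins[t]) for t in ordered},
        tier_site_counts=tier_sites,
    )


def _tier_rank(tier: str) -> int:
    if tier not in TIER_RANK:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    return TIER_RANK[tier]


def expected_match_count(
    length: int, tier: str, frequencies: Mapping[str, float], tol: float = 1e-9
) -> float:
    """Expected number of complete-window matches in one i.i.d. sequence.

    Under an i.i.d. residue model with background frequencies ``f`` there
    are ``L - 10`` complete 11-residue windows, each matching
    independently of position with probability

    - strict:      ``p_basic^2 * p_hydrophobic^2 * p_ST``
    - relaxed:     ``p_ST * p_hydrophobic * (1 - (1 - p_hydrophobic)^2)``
      (inclusion-exclusion over the hydrophobic residue at -5 or -4)
    - permissive:  ``p_ST``

    where ``p_basic = f_R + f_K + f_H``, ``p_hydrophobic = f_M + f_L +
    f_I + f_F + f_V`` and ``p_ST = f_S + f_T``.  Truncated terminal
    windows (which only the relaxed tier can match) are not counted.

    Raises
    ------
    ValueError
        If the frequencies do not sum to 1 within ``tol`` over the
        standard alphabet, or the tier is unknown.
    """
    total = sum(frequencies.get(aa, 0.0) for aa in STANDARD_AA)
    if abs(total - 1.0) > tol:
        raise ValueError(
            f"background frequencies sum to {total!r}, not 1 within {tol}"
        )
    p_b = sum(frequencies.get(aa, 0.0) for aa in BASIC)
    p_h = sum(frequencies.get(aa, 0.0) for aa in HYDROPHOBIC)
    p_st = sum(frequencies.get(aa, 0.0) for aa in PHOSPHOACCEPTOR)
    n_windows = max(0, length - (WINDOW_SPAN - 1))
    if tier == "strict":
        p = p_b**2 * p_h**2 * p_st
    elif tier == "relaxed":
        p = p_st * p_h * (1.0 - (1.0 - p_h) ** 2)
    elif tier == "permissive":
        p = p_st
    else:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    return n_windows * p
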