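"""Synthetic proteomes with planted consensus sites of known tier.

The generator draws i.i.d. amino-acid sequences from a configurable
background (approximate vertebrate proteome frequencies by default,
uniform as an option) and can overwrite 11-residue windows with motif
instances sampled *exactly* at a requested stringency tier: a planted
"relaxed" site matches the relaxed predicate but provably not the strict
one, and so on.  Together with the closed-form background match
expectation this gives every scanning and network operation a ground
truth without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from typing import Mapping, Sequence

import numpy as np
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
    build_motif,
)
from ampkscan.proteome_io import ProteinRecord
from ampkscan.scanner import WINDOW_SPAN

ALPHABET = tuple(sorted(STANDARD_AA))


def default_frequencies() -> dict[str, float]:
    """Approximate vertebrate background frequencies, normalized."""
    with resources.files("ampkscan.data").joinpath("aa_frequencies.json").open() as fh:
        raw = json.load(fh)["frequencies"]
    total = sum(raw.values())
    return {aa: v / total for aa, v in raw.items()}


def uniform_frequencies() -> dict[str, float]:
    return {aa: 1.0 / len(ALPHABET) for aa in ALPHABET}


def _validate_frequencies(frequencies: Mapping[str, float]) -> np.ndarray:
    unknown = set(frequencies) - set(ALPHABET)
    if unknown:
        raise ValueError(f"frequencies for non-standard residues: {sorted(unknown)}")
    p = np.array([frequencies.get(aa, 0.0) for aa in ALPHABET], dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("background frequencies must be non-negative and sum to 1")
    return p


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted site: where it is and what tier it is."""

    protein_id: str
    position: int  # 1-based phosphoacceptor index
    tier: str
    window: str


def generate_background(
    n: int,
    length_range: tuple[int, int] = (50, 300),
    frequencies: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[ProteinRecord]:
    """Generate ``n`` i.i.d. background proteins.

    Lengths are uniform over ``length_range`` (inclusive); sequences are
    reproducible for a given seed.  Record ids are ``synp0001`` ….
    """
    p = _validate_frequencies(frequencies or default_frequencies())
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    alphabet = np.array(ALPHABET)
    records = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=p))
        records.append(
            ProteinRecord(
                protein_id=f"synp{i + 1:04d}",
                sequence=seq,
                description="synthetic background protein",
                source="plain",
            )
        )
    return records


def _sample_residue(rng: np.random.Generator, members: frozenset[str], p: np.ndarray) -> str:
    idx = [i for i, aa in enumerate(ALPHABET) if aa in members]
    w = p[idx]
    if w.sum() <= 0:
        w = np.ones(len(idx))
    return ALPHABET[idx[int(rng.choice(len(idx), p=w / w.sum()))]]


def sample_window(tier: str, rng: np.random.Generator, p: np.ndarray) -> str:
    """Sample an 11-mer matching exactly ``tier`` (and no stricter tier).

    Constrained positions are drawn from the background restricted to the
    required class; unconstrained positions from the full background.
    Rejection guarantees tier-exactness for relaxed and permissive.
    """
    strict = build_motif("strict")
    relaxed = build_motif("relaxed")
    center = -MIN_OFFSET
    for _ in range(10_000):
        chars = [
            ALPHABET[int(rng.choice(len(ALPHABET), p=p))] for _ in range(WINDOW_SPAN)
        ]
        chars[center] = _sample_residue(rng, PHOSPHOACCEPTOR, p)
        if tier == "strict":
            chars[center - 6] = _sample_residue(rng, BASIC, p)
            chars[center - 5] = _sample_residue(rng, HYDROPHOBIC, p)
            chars[center - 4] = _sample_residue(rng, BASIC, p)
            chars[center + 4] = _sample_residue(rng, HYDROPHOBIC, p)
            return "".join(chars)
        if tier == "relaxed":
            chars[center + 4] = _sample_residue(rng, HYDROPHOBIC, p)
            window = "".join(chars)
            if relaxed.matches(window, center) and not strict.matches(window, center):
                return window
            continue
        if tier == "permissive":
            window = "".join(chars)
            if not relaxed.matches(window, center):
                return window
            continue
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    raise RuntimeError(f"rejection sampling failed for tier {tier!r}")


def plant_sites(
    records: Sequence[ProteinRecord],
    tier: str,
    n_sites: int,
    seed: int = 0,
    frequencies: Mapping[str, float] | None = None,
) -> tuple[list[ProteinRecord], list[PlantedSite]]:
    """Overwrite random non-overlapping 11-mers with tier-exact motif windows.

    Returns new records (inputs are not mutated) plus the ground-truth
    table.  Raises if the collection cannot host ``n_sites``
    non-overlapping complete windows.
    """
    if tier not in TIER_RANK:
        raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")
    p = _validate_frequencies(frequencies or default_frequencies())
    rng = np.random.default_rng(seed)
    seqs = {r.protein_id: list(r.sequence) for r in records}
    occupied: dict[str, list[tuple[int, int]]] = {r.protein_id: [] for r in records}
    truth: list[PlantedSite] = []
    order = [r.protein_id for r in records]
    for _ in range(n_sites):
        placed = False
        for _attempt in range(2000):
            pid = order[int(rng.integers(len(order)))]
            seq = seqs[pid]
            if len(seq) < WINDOW_SPAN:
                continue
            center = int(rng.integers(-MIN_OFFSET, len(seq) - MAX_OFFSET))
            lo, hi = center + MIN_OFFSET, center + MAX_OFFSET
            if any(not (hi < a or lo > b) for a, b in occupied[pid]):
                continue
            window = sample_window(tier, rng, p)
            seq[lo : hi + 1] = list(window)
            occupied[pid].append((lo, hi))
            truth.append(PlantedSite(pid, center + 1, tier, window))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place {n_sites} non-overlapping site(s); "
                f"placed {len(truth)} before running out of capacity"
            )
    out = [
        ProteinRecord(
            r.protein_id,
            "".join(seqs[r.protein_id]),
            r.description,
            r.gene_symbol,
            r.source,
            list(r.warnings),
        )
        for r in records
    ]
    truth.sort(key=lambda s: (order.index(s.protein_id), s.position))
    return out, truth


def embed_peptide(
    record: ProteinRecord, peptide: str, center_in_peptide: int, position: int
) -> ProteinRecord:
    """Overwrite part of a synthetic protein with a peptide at a chosen residue.

    Places ``peptide`` so that its ``center_in_peptide``-th residue
    (1-based) lands at 1-based ``position`` of the protein.  Used to build
    synthetic full-length stand-ins that carry a known assay peptide at a
    realistic residue number.
    """
    start = position - center_in_peptide
    if start < 0 or start + len(peptide) > len(record.sequence):
        raise ValueError(
            f"peptide of length {len(peptide)} does not fit at position {position} "
            f"in a protein of length {len(record.sequence)}"
        )
    seq = record.sequence[:start] + peptide.upper() + record.sequence[start + len(peptide):]
    return ProteinRecord(
        record.protein_id, seq, record.description, record.gene_symbol, record.source
    )


def truth_frame(truth: Sequence[PlantedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"protein_id": t.protein_id, "position": t.position, "tier": t.tier, "window": t.window}
            for t in truth
        ],
        columns=["protein_id", "position", "tier", "window"],
    )


def make_annotation_fixture(
    records: Sequence[ProteinRecord],
    categories: Sequence[str] = (
        "transcription",
        "translation",
        "cell migration",
        "protein transport",
        "energy homeostasis",
    ),
    seed: int = 0,
    multi_category_rate: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Random annotations and associations with a planted hub.

    Every protein gets one category (a second with probability
    ``multi_category_rate``).  One protein — the hub — is connected to
    every other protein carrying its category, while random extra edges
    avoid pairs inside that category, so the hub's within-category degree
    is maximal by construction.

    Returns
    -------
    (annotations, associations, hub_id)
    """
    if not records:
        raise ValueError("need at least one record")
    rng = np.random.default_rng(seed)
    ids = [r.protein_id for r in records]
    cats = list(categories)
    assigned: dict[str, list[str]] = {}
    for pid in ids:
        chosen = [cats[int(rng.integers(len(cats)))]]
        if len(cats) > 1 and rng.random() < multi_category_rate:
            other = cats[int(rng.integers(len(cats)))]
            if other not in chosen:
                chosen.append(other)
        assigned[pid] = chosen
    hub = ids[int(rng.integers(len(ids)))]
    hub_cat = assigned[hub][0]
    # guarantee the hub category has company
    members = [pid for pid in ids if hub_cat in assigned[pid]]
    for pid in ids:
        if len(members) >= min(3, len(ids)):
            break
        if pid not in members:
            assigned[pid].append(hub_cat)
            members.append(pid)
    edges: list[tuple[str, str, str]] = []
    seen: set[frozenset[str]] = set()
    for pid in members:
        if pid != hub:
            edges.append((hub, pid, "association"))
            seen.add(frozenset((hub, pid)))
    n_random = len(ids)
    for _ in range(n_random * 4):
        if len(edges) >= len(members) - 1 + n_random:
            break
        a, b = (ids[int(rng.integers(len(ids)))] for _ in range(2))
        if a == b or frozenset((a, b)) in seen:
            continue
        if hub_cat in assigned[a] and hub_cat in assigned[b]:
            continue  # keep the hub's within-category degree maximal
        edges.append((a, b, "association"))
        seen.add(frozenset((a, b)))
    annotations = pd.DataFrame(
        [
            {"protein_id": pid, "category": cat, "evidence": "synthetic"}
            for pid in ids
            for cat in assigned[pid]
        ],
        columns=["protein_id", "category", "evidence"],
    )
    associations = pd.DataFrame(edges, columns=["protein_a", "protein_b", "type"])
    return annotations, associations, hub
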