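"""Position-constrained degenerate motifs for kinase consensus sequences.

The AMPK substrate consensus is written in the field as
``βϕβXXX[S/T]XXXϕ``, where β is a basic residue (R, K, H), ϕ is a
hydrophobic residue (M, L, I, F, V), X is any residue, and the central
serine or threonine (offset 0) is the phosphoacceptor.  Reported substrates
frequently deviate from the full pattern: the basic residues at -6 and -4
may be absent, and the -5 hydrophobic residue may sit at -4 instead.  This
module encodes the full consensus and those documented variants as three
nested stringency tiers:

``strict``
    the complete pattern — basic at -6 and -4, hydrophobic at -5 and +4,
    S/T at the center.
``relaxed``
    basic residues optional; a hydrophobic residue at -5 *or* -4 and at +4,
    S/T at the center.  This is the minimal superset of the documented
    variant forms.
``permissive``
    only the central S/T is constrained; by default a complete 11-residue
    window must still be present, so the count of candidate windows stays
    bounded.

Every window matched at ``strict`` is matched at ``relaxed``, and every
window matched at ``relaxed`` (with a full window) at ``permissive``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity codes that satisfy an "any" constraint.  Selenocysteine (U),
#: pyrrolysine (O) and the stop marker never satisfy any constraint class,
#: so they cannot create spurious sites.
AMBIGUOUS_AA = frozenset("XBZ")

BASIC = frozenset("RKH")
HYDROPHOBIC = frozenset("MLIFV")
PHOSPHOACCEPTOR = frozenset("ST")

#: Named residue classes.  ``any`` covers the 20 standard codes plus the
#: ambiguity codes X/B/Z; the three named classes are pairwise disjoint.
RESIDUE_CLASSES: dict[str, frozenset[str]] = {
    "basic": BASIC,
    "hydrophobic": HYDROPHOBIC,
    "phosphoacceptor": PHOSPHOACCEPTOR,
    "any": STANDARD_AA | AMBIGUOUS_AA,
}

TIERS = ("strict", "relaxed", "permissive")
#: Stringency rank; lower is more stringent.
TIER_RANK = {tier: i for i, tier in enumerate(TIERS)}

MIN_OFFSET, MAX_OFFSET = -6, 4


def classify_residue(aa: str) -> set[str]:
    """Return the named residue classes containing ``aa``.

    Parameters
    ----------
    aa : str
        A single one-letter amino-acid code; matching is case-insensitive.

    Returns
    -------
    set of str
        Subset of ``{"basic", "hydrophobic", "phosphoacceptor"}``; empty
        for residues in no named class (``any`` is never reported).

    Raises
    ------
    ValueError
        If ``aa`` is not a single alphabetic character.
    """
    if not isinstance(aa, str) or len(aa) != 1:
        raise ValueError(f"expected a single residue character, got {aa!r}")
    if not aa.isalpha():
        raise ValueError(f"residue code must be a letter, got {aa!r}")
    up = aa.upper()
    return {
        name
        for name, members in RESIDUE_CLASSES.items()
        if name != "any" and up in members
    }


@dataclass(frozen=True)
class PositionConstraint:
    """One constraint at an offset relative to the phosphoacceptor.

    ``allowed`` names one or more residue classes; the constraint is
    satisfied when the residue at ``offset`` belongs to any of them.  A
    non-required constraint never vetoes a match — it documents the
    canonical pattern at that position but tolerates absence or mismatch.
    """

    offset: int
    allowed: tuple[str, ...]
    required: bool = True

    def __post_init__(self) -> None:
        if not MIN_OFFSET <= self.offset <= MAX_OFFSET:
            raise ValueError(f"offset {self.offset} outside {MIN_OFFSET}..{MAX_OFFSET}")
        for name in self.allowed:
            if name not in RESIDUE_CLASSES:
                raise ValueError(f"unknown residue class {name!r}")

    def satisfied_by(self, aa: str) -> bool:
        up = aa.upper()
        return any(up in RESIDUE_CLASSES[name] for name in self.allowed)


@dataclass(frozen=True)
class ConsensusMotif:
    """An 11-position degenerate motif (offsets -6..+4) with a tier label.

    Attributes
    ----------
    tier : str
        One of ``strict``, ``relaxed``, ``permissive``.
    constraints : tuple of PositionConstraint
        Exactly one constraint per offset, ordered -6..+4.  Offset 0 is
        always a required phosphoacceptor.
    require_one_of : tuple of groups
        Cross-position disjunctions: each group is a tuple of
        ``(offset, class_name)`` pairs of which at least one must be
        satisfied by a present residue.  Used by the relaxed tier for the
        hydrophobic residue at -5 or -4.
    require_full_window : bool
        When true, every offset -6..+4 must be present (no terminal
        truncation).  Default policy for the permissive tier.
    """

    tier: str
    constraints: tuple[PositionConstraint, ...]
    require_one_of: tuple[tuple[tuple[int, str], ...], ...] = ()
    require_full_window: bool = False

    def __post_init__(self) -> None:
        offsets = [c.offset for c in self.constraints]
        if offsets != list(range(MIN_OFFSET, MAX_OFFSET + 1)):
            raise ValueError("constraints must cover offsets -6..+4 exactly once, in order")
        center = self.constraints[-MIN_OFFSET]
        if center.allowed != ("phosphoacceptor",) or not center.required:
            raise ValueError("offset 0 must be a required phosphoacceptor")

    @property
    def required_offsets(self) -> frozenset[int]:
        return frozenset(c.offset for c in self.constraints if c.required)

    def constraint_at(self, offset: int) -> PositionConstraint:
        return self.constraints[offset - MIN_OFFSET]

    def matches(self, window: str, center_index: int) -> bool:
        """Test the window with its phosphoacceptor at 0-based ``center_index``.

        Offsets falling outside the window (terminal truncation) are
        treated as absent: absent required positions fail the match, absent
        optional positions do not.
        """
        if not 0 <= center_index < len(window):
            raise ValueError(
                f"center index {center_index} outside window of length {len(window)}"
            )
        if len(window) > MAX_OFFSET - MIN_OFFSET + 1:
            raise ValueError(f"window longer than 11 residues: {window!r}")
        if not window.isalpha():
            raise ValueError(f"window contains non-letter characters: {window!r}")
        up = window.upper()

        def residue_at(offset: int) -> str | None:
            i = center_index + offset
            return up[i] if 0 <= i < len(up) else None

        if self.require_full_window:
            for offset in range(MIN_OFFSET, MAX_OFFSET + 1):
                if residue_at(offset) is None:
                    return False
        for c in self.constraints:
            if not c.required:
                continue
            aa = residue_at(c.offset)
            if aa is None or not c.satisfied_by(aa):
                return False
        for group in self.require_one_of:
            ok = False
            for offset, class_name in group:
                aa = residue_at(offset)
                if aa is not None and aa in RESIDUE_CLASSES[class_name]:
                    ok = True
                    break
            if not ok:
                return False
        return True

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tier": self.tier,
            "constraints": [
                {"offset": c.offset, "allowed": list(c.allowed), "required": c.required}
                for c in self.constraints
            ],
            "require_one_of": [
                [[offset, name] for offset, name in group]
                for group in self.require_one_of
            ],
            "require_full_window": self.require_full_window,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ConsensusMotif":
        return cls(
            tier=d["tier"],
            constraints=tuple(
                PositionConstraint(c["offset"], tuple(c["allowed"]), c["required"])
                for c in d["constraints"]
            ),
            require_one_of=tuple(
                tuple((int(offset), name) for offset, name in group)
                for group in d.get("require_one_of", [])
            ),
            require_full_window=bool(d.get("require_full_window", False)),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ConsensusMotif":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _constraints(layout: Mapping[int, tuple[tuple[str, ...], bool]]) -> tuple[PositionConstraint, ...]:
    return tuple(
        PositionConstraint(offset, *layout.get(offset, (("any",), False)))
        for offset in range(MIN_OFFSET, MAX_OFFSET + 1)
    )


def build_motif(tier: str, require_full_window: bool | None = None) -> ConsensusMotif:
    """Build the consensus motif for a stringency tier.

    Parameters
    ----------
    tier : {"strict", "relaxed", "permissive"}
        Stringency tier.
    require_full_window : bool, optional
        Override the tier's default full-window policy.  Defaults to
        ``True`` for the permissive tier (keeps the candidate set the set
        of complete 11-mers) and ``False`` otherwise (strict forces a full
        window anyway through its required terminal positions; relaxed must
        tolerate a missing -6 so N-terminal-proximal variant sites match).
    """
    if tier == "strict":
        constraints = _constraints(
            {
                -6: (("basic",), True),
                -5: (("hydrophobic",), True),
                -4: (("basic",), True),
                0: (("phosphoacceptor",), True),
                4: (("hydrophobic",), True),
            }
        )
        full = False if require_full_window is None else require_full_window
        return ConsensusMotif("strict", constraints, (), full)
    if tier == "relaxed":
        constraints = _constraints(
            {
                -6: (("basic",), False),
                -5: (("hydrophobic",), False),
                -4: (("hydrophobic", "basic"), False),
                0: (("phosphoacceptor",), True),
                4: (("hydrophobic",), True),
            }
        )
        full = False if require_full_window is None else require_full_window
        return ConsensusMotif(
            "relaxed",
            constraints,
            (((-5, "hydrophobic"), (-4, "hydrophobic")),),
            full,
        )
    if tier == "permissive":
        constraints = _constraints({0: (("phosphoacceptor",), True)})
        full = True if require_full_window is None else require_full_window
        return ConsensusMotif("permissive", constraints, (), full)
    raise ValueError(f"unknown tier {tier!r}; expected one of {TIERS}")


def match_window(window: str, center: int, motif: ConsensusMotif) -> bool:
    """Test a peptide window against a motif.

    Parameters
    ----------
    window : str
        Peptide of length <= 11.
    center : int
        1-based position within ``window`` of the residue aligned to the
        phosphoacceptor offset 0.
    motif : ConsensusMotif
    """
    if not 1 <= center <= len(window):
        raise ValueError(
            f"center {center} is not a 1-based position within a window of "
            f"length {len(window)}"
        )
    return motif.matches(window, center - 1)


def best_tier(
    window: str, center: int, motifs: Sequence[ConsensusMotif]
) -> str | None:
    """Most stringent tier among ``motifs`` matching the window, or None."""
    for motif in sorted(motifs, key=lambda m: TIER_RANK.get(m.tier, len(TIERS))):
        if match_window(window, center, motif):
            return motif.tier
    return None
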