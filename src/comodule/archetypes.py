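"""Combination-effect expression archetypes shared by the simulator and the trait stage.

A four-arm drug-combination study (vehicle, drug A alone, drug B alone,
combination) admits nine qualitative expression patterns across the arms —
"archetypes".  Each archetype is encoded here as one numeric value per arm,
the single source of truth used both to plant module signal in synthetic
data and to build the per-sample trait vectors that module eigengenes are
correlated against.  The encoding is linear: "Additive" is the sum of the
two single-drug effects, and an "X-dominant synergy" is a combination
effect exceeding drug X's own effect.
"""

from __future__ import annotations

import numpy as np

#: Treatment arms, in canonical order.
ARMS: tuple[str, ...] = ("vehicle", "drugA", "drugB", "combo")

#: The nine archetype/trait names, in canonical order (archetypes 1-9).
TRAIT_NAMES: tuple[str, ...] = (
    "Treatment",            # 1: changed by any treatment
    "A-only",               # 2: changed only by drug A alone
    "B-only",               # 3: changed only by drug B alone
    "with-A",               # 4: changed whenever drug A is present
    "with-B",               # 5: changed whenever drug B is present
    "Combo-only",           # 6: changed only by the combination
    "Additive",             # 7: single effects summing in the combination
    "A-dominant-synergy",   # 8: A effect amplified by the combination
    "B-dominant-synergy",   # 9: B effect amplified by the combination
)

#: Trait names flagging a combination benefit (archetypes 6-9); modules whose
#: top trait is one of these are candidate carriers of the potentiating effect.
POTENTIATING_TRAITS: tuple[str, ...] = TRAIT_NAMES[5:9]

#: Archetype pattern values, rows = TRAIT_NAMES order, columns = ARMS order.
ARCHETYPE_PATTERNS: np.ndarray = np.array(
    [
        [0, 1, 1, 1],  # Treatment
        [0, 1, 0, 0],  # A-only
        [0, 0, 1, 0],  # B-only
        [0, 1, 0, 1],  # with-A
        [0, 0, 1, 1],  # with-B
        [0, 0, 0, 1],  # Combo-only
        [0, 1, 1, 2],  # Additive
        [0, 1, 0, 2],  # A-dominant-synergy
        [0, 0, 1, 2],  # B-dominant-synergy
    ],
    dtype=float,
)
ARCHETYPE_PATTERNS.setflags(write=False)


def archetype_pattern(archetype: int) -> np.ndarray:
    """Return the per-arm pattern vector for archetype 1..9 (ARMS order)."""
    if not 1 <= int(archetype) <= len(TRAIT_NAMES):
        raise ValueError(f"archetype must be in 1..{len(TRAIT_NAMES)}, got {archetype}")
    return ARCHETYPE_PATTERNS[int(archetype) - 1]


def pattern_for_samples(archetype: int, arms: "list[str] | np.ndarray") -> np.ndarray:
    """Expand an archetype pattern to one value per sample given each sample's arm."""
    pat = archetype_pattern(archetype)
    index = {arm: i for i, arm in enumerate(ARMS)}
    try:
        return np.array([pat[index[a]] for a in arms], dtype=float)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown arm {exc.args[0]!r}; expected one of {ARMS}") from None
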