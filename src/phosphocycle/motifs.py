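"""Phosphorylation-site consensus motif annotation.

Motifs are defined on the unmodified ±6 sequence window as positional
constraints relative to the phosphoacceptor. The registry is data-driven so
alternative consensus definitions (e.g. a different Aurora rule) are a config
edit, not a code change:

* ``minimal_cdk`` / ``pSP`` / ``pTP`` — proline at +1 (the minimal Cdk
  consensus), split by acceptor.
* ``full_cdk`` / ``pSPxKR`` / ``pTPxKR`` — additionally a basic residue (K/R)
  at +3 (S/T-P-x-K/R).
* ``aurora`` — basic residues at −2 and −3 ([R/K]-[R/K]-x-S/T).

Padding characters never satisfy a constraint, so motifs requiring residues
outside the protein can never match.
"""

from __future__ import annotations

from dataclasses import dataclass

from .site_tables import PAD_CHAR, WINDOW_FLANK, WINDOW_LENGTH

ACCEPTORS = frozenset("STY")
BASIC_RESIDUES = "KR"

# name -> (allowed acceptors, ((offset, allowed residues), ...))
DEFAULT_MOTIF_REGISTRY: dict[str, tuple[str, tuple[tuple[int, str], ...]]] = {
    "minimal_cdk": ("ST", ((1, "P"),)),
    "pSP": ("S", ((1, "P"),)),
    "pTP": ("T", ((1, "P"),)),
    "full_cdk": ("ST", ((1, "P"), (3, "KR"))),
    "pSPxKR": ("S", ((1, "P"), (3, "KR"))),
    "pTPxKR": ("T", ((1, "P"), (3, "KR"))),
    "aurora": ("ST", ((-2, "KR"), (-3, "KR"))),
}


class InvalidWindowError(ValueError):
    pass


@dataclass(frozen=True)
class MotifAnnotation:
    """Motif label set and basic-residue context of one phosphosite window."""

    acceptor: str
    labels: frozenset[str]
    basic_context_count: int
    site_id: str | None = None


def _check_window(window: str) -> None:
    if len(window) != WINDOW_LENGTH:
        raise InvalidWindowError(
            f"window must be {WINDOW_LENGTH} residues, got {len(window)}"
        )


def classify_acceptor(window: str) -> str:
    """Return the phosphoacceptor (centre residue); error unless S, T or Y."""
    _check_window(window)
    center = window[WINDOW_FLANK]
    if center not in ACCEPTORS:
        raise InvalidWindowError(f"window centre {center!r} is not S, T or Y")
    return center


def _matches(window: str, acceptors: str, constraints) -> bool:
    if window[WINDOW_FLANK] not in acceptors:
        return False
    for offset, allowed in constraints:
        residue = window[WINDOW_FLANK + offset]
        if residue == PAD_CHAR or residue not in allowed:
            return False
    return True


def count_basic_context(window: str, exclude_offsets: frozenset[int] = frozenset()) -> int:
    """Count K/R among the 12 flanking positions.

    ``exclude_offsets`` removes motif-defining positions from the count so
    that e.g. the +3 K/R of a full Cdk site is not double-reported as basic
    context.
    """
    _check_window(window)
    return sum(
        1
        for offset in range(-WINDOW_FLANK, WINDOW_FLANK + 1)
        if offset != 0
        and offset not in exclude_offsets
        and window[WINDOW_FLANK + offset] in BASIC_RESIDUES
    )


def annotate_motifs(
    window: str,
    registry: dict | None = None,
    site_id: str | None = None,
) -> MotifAnnotation:
    """Assign zero or more consensus motif labels to a window.

    Pure function of the window (and registry): the same window always yields
    the same annotation.
    """
    acceptor = classify_acceptor(window)
    registry = DEFAULT_MOTIF_REGISTRY if registry is None else registry
    labels = frozenset(
        name
        for name, (acceptors, constraints) in registry.items()
        if _matches(window, acceptors, constraints)
    )
    motif_offsets = frozenset(
        offset
        for name in labels
        for offset, _ in registry[name][1]
    )
    return MotifAnnotation(
        acceptor=acceptor,
        labels=labels,
        basic_context_count=count_basic_context(window, motif_offsets),
        site_id=site_id,
    )


def registry_from_config(config: dict) -> dict[str, tuple[str, tuple[tuple[int, str], ...]]]:
    """Build a registry from its serialized form.

    Expected shape: ``{name: {"acceptors": "ST", "constraints": [[1, "P"], ...]}}``.
    """
    registry = {}
    for name, entry in config.items():
        constraints = tuple((int(off), str(res)) for off, res in entry["constraints"])
        for off, _ in constraints:
            if off == 0 or abs(off) > WINDOW_FLANK:
                raise ValueError(f"motif {name!r}: offset {off} outside the ±{WINDOW_FLANK} window")
        registry[name] = (str(entry["acceptors"]), constraints)
    return registry
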