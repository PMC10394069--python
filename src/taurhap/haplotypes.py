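"""Mitochondrial haplogroup assignment from diagnostic-variant panels.

A consensus is typed by reading the state of every panel variant: derived,
ancestral, or uncallable (N).  A clade matches when every *callable* variant
of its panel — and of each loaded ancestor's panel — is derived, and at
least ``min_completeness`` of each panel's positions are callable.
Uncallable positions never count for or against a panel (missing is not
ancestral).  The assigned label is the most-derived matching clade; several
maximal matches yield status "ambiguous", none "unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .consensus import ConsensusSequence
from .panels import DiagnosticPanel, PanelConfigError, PanelSet
from .reference import ReferenceGenome

DERIVED, ANCESTRAL, UNCALLABLE = "derived", "ancestral", "uncallable"


@dataclass
class MtCall:
    specimen_id: str
    haplogroup: str | None
    status: str                   # assigned | ambiguous | unassigned
    completeness: float           # min over the assigned (or all) panel chain
    panel_states: dict            # panel -> list of (variant, state)
    matched_panels: tuple = ()


def _consensus_base(consensus, pos: int) -> str:
    if isinstance(consensus, ConsensusSequence):
        return consensus.base_at(pos)
    return consensus[pos - 1]


def detect_diagnostics(consensus, ref: ReferenceGenome,
                       panel: DiagnosticPanel) -> list:
    """State of each panel variant on the consensus: derived/ancestral/uncallable.

    The consensus must share the reference coordinate frame (the aligned form
    produced by the consensus caller, or any reference-length string).
    """
    if not isinstance(consensus, ConsensusSequence) and len(consensus) != len(ref):
        raise ValueError(
            "consensus must be in reference coordinates (aligned form); "
            f"got length {len(consensus)} vs reference {len(ref)}")
    states = []
    for v in panel.variants:
        if not 1 <= v.position <= len(ref):
            raise PanelConfigError(
                f"panel {panel.haplogroup}: position {v.position} out of range")
        base = _consensus_base(consensus, v.position)
        if base == "N":
            states.append((v, UNCALLABLE))
        elif base == v.alt:
            states.append((v, DERIVED))
        else:
            states.append((v, ANCESTRAL))
    return states


def _panel_matches(states, min_completeness: float) -> bool:
    callable_states = [s for _v, s in states if s != UNCALLABLE]
    completeness = len(callable_states) / len(states) if states else 0.0
    if completeness < min_completeness or not callable_states:
        return False
    return all(s == DERIVED for s in callable_states)


def assign_mt_haplogroup(consensus, ref: ReferenceGenome, panels: PanelSet,
                         min_completeness: float = 0.8,
                         specimen_id: str = "") -> MtCall:
    """Assign the most-derived clade whose panel chain fully matches."""
    if not panels.names():
        raise PanelConfigError("no panels loaded")
    panel_states = {name: detect_diagnostics(consensus, ref, panels[name])
                    for name in panels.names()}
    self_match = {name: _panel_matches(panel_states[name], min_completeness)
                  for name in panels.names()}
    matches = {name for name in panels.names()
               if self_match[name] and all(self_match[a] for a in panels.ancestors(name))}

    # most-derived: drop any match that is an ancestor of another match
    maximal = {name for name in matches
               if not any(name in panels.ancestors(other)
                          for other in matches if other != name)}

    def chain_completeness(name):
        vals = []
        for n in [name] + panels.ancestors(name):
            st = panel_states[n]
            vals.append(sum(1 for _v, s in st if s != UNCALLABLE) / len(st) if st else 0.0)
        return min(vals)

    if len(maximal) == 1:
        label = next(iter(maximal))
        # hierarchy soundness: every ancestor of the assignment matched
        assert all(self_match[a] for a in panels.ancestors(label))
        return MtCall(specimen_id, label, "assigned", chain_completeness(label),
                      panel_states, tuple(sorted(matches)))
    if len(maximal) > 1:
        return MtCall(specimen_id, None, "ambiguous",
                      min(chain_completeness(n) for n in maximal),
                      panel_states, tuple(sorted(matches)))
    overall = (min((sum(1 for _v, s in st if s != UNCALLABLE) / len(st))
                   for st in panel_states.values() if st)
               if panel_states else 0.0)
    return MtCall(specimen_id, None, "unassigned", overall, panel_states, ())
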