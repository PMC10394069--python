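"""Diagnostic-variant panels defining mitochondrial haplogroups.

A haplogroup is defined by the derived states of a small set of diagnostic
variants; clades nest (e.g. T1a/T1b/T1d below T1, T1 and T3 below the
ancestral T123), so a sequence belonging to a sub-clade carries the derived
alleles of its whole ancestral chain. Panels are user-editable configuration
rather than code: apart from the published T1b pair of control/coding-region
transitions at 7,542 and 16,022, bovine haplogroup-defining positions are
not reproduced here, and the shipped default panel file is synthetic.

The classifier and the read simulator consume the same panel file, so
closed-loop tests (simulate a haplogroup, recover its label) are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
VARIANT_CLASSES = {"transition", "transversion", "insertion", "deletion"}


class PanelConfigError(ValueError):
    """Raised for malformed or inconsistent panel configuration."""


@dataclass(frozen=True)
class DiagnosticVariant:
    position: int          # 1-based on the panel's reference
    ref: str
    alt: str
    variant_class: str = "transition"

    def __post_init__(self):
        if self.position < 1:
            raise PanelConfigError(f"variant position must be >= 1, got {self.position}")
        if self.ref == self.alt:
            raise PanelConfigError(f"ref and derived allele identical at {self.position}")
        if self.variant_class not in VARIANT_CLASSES:
            raise PanelConfigError(f"unknown variant class {self.variant_class!r}")
        if self.variant_class == "transition" and (self.ref, self.alt) not in _TRANSITIONS:
            raise PanelConfigError(
                f"{self.ref}->{self.alt} at {self.position} is not a transition"
            )


@dataclass(frozen=True)
class DiagnosticPanel:
    haplogroup: str
    variants: tuple
    parent: str | None = None

    def positions(self) -> list[int]:
        return [v.position for v in self.variants]


class PanelSet:
    """A collection of panels with an acyclic parent hierarchy."""

    def __init__(self, panels: list[DiagnosticPanel]):
        self.panels: dict[str, DiagnosticPanel] = {}
        for p in panels:
            if p.haplogroup in self.panels:
                raise PanelConfigError(f"duplicate panel {p.haplogroup}")
            self.panels[p.haplogroup] = p
        self._check_acyclic()

    def _check_acyclic(self):
        for name in self.panels:
            seen = set()
            cur = name
            while cur is not None:
                if cur in seen:
                    raise PanelConfigError(f"cyclic parent links at {cur}")
                seen.add(cur)
                cur = self.panels[cur].parent if cur in self.panels else None

    def __iter__(self):
        return iter(self.panels.values())

    def __contains__(self, name):
        return name in self.panels

    def __getitem__(self, name) -> DiagnosticPanel:
        try:
            return self.panels[name]
        except KeyError:
            raise PanelConfigError(f"unknown haplogroup label {name!r}") from None

    def names(self) -> list[str]:
        return list(self.panels)

    def ancestors(self, name: str) -> list[str]:
        """Ancestral chain of `name`, nearest first, restricted to loaded panels.

        A parent label that is not itself a loaded panel terminates the chain:
        a panel can be used stand-alone without its ancestors being loaded.
        """
        chain = []
        cur = self[name].parent
        while cur is not None and cur in self.panels:
            chain.append(cur)
            cur = self.panels[cur].parent
        return chain

    def chain_variants(self, name: str) -> list[DiagnosticVariant]:
        """Variants of `name` plus all loaded ancestors (derived-state set)."""
        out = list(self[name].variants)
        for anc in self.ancestors(name):
            out.extend(self.panels[anc].variants)
        return out

    def all_positions(self) -> set[int]:
        return {v.position for p in self for v in p.variants}

    def validate_against(self, ref) -> None:
        """Check positions are within the reference and ref alleles match."""
        for p in self:
            for v in p.variants:
                if v.position > len(ref):
                    raise PanelConfigError(
                        f"panel {p.haplogroup}: position {v.position} outside "
                        f"reference of length {len(ref)}"
                    )
                if v.variant_class in ("transition", "transversion") and \
                        ref.base(v.position) != v.ref:
                    raise PanelConfigError(
                        f"panel {p.haplogroup}: reference has {ref.base(v.position)} "
                        f"at {v.position}, panel expects {v.ref}"
                    )


def load_panels(path: str | Path) -> PanelSet:
    """Load a panel file (YAML; schema: panels: [{haplogroup, parent, variants: [{position, ref, alt, class}]}])."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "panels" not in doc:
        raise PanelConfigError(f"{path}: expected a mapping with a 'panels' key")
    panels = []
    for entry in doc["panels"]:
        try:
            variants = tuple(
                DiagnosticVariant(
                    position=int(v["position"]),
                    ref=str(v["ref"]).upper(),
                    alt=str(v["alt"]).upper(),
                    variant_class=str(v.get("class", "transition")),
                )
                for v in entry.get("variants", [])
            )
            panels.append(
                DiagnosticPanel(
                    haplogroup=str(entry["haplogroup"]),
                    parent=entry.get("parent"),
                    variants=variants,
                )
            )
        except (KeyError, TypeError) as exc:
            raise PanelConfigError(f"{path}: malformed panel entry {entry!r}") from exc
    return PanelSet(panels)


def default_panel_path() -> Path:
    return Path(__file__).parent / "data" / "mt_panels.yaml"


def default_panels() -> PanelSet:
    return load_panels(default_panel_path())
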