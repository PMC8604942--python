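"""The published worked-example event catalogue.

Ten parental/derived sequence pairs over inverted repeats in yeast coding
genes (the published spacer-inversion catalogue), shipped as a frozen
fixture with per-row arm/spacer lengths, carrier strains, reading-frame
anchors and the reported per-codon replacements.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass
from functools import lru_cache


@dataclass(frozen=True)
class CatalogueReplacement:
    from_aa: str
    to_aa: str
    from_codon: str
    to_codon: str

    @property
    def synonymous(self) -> bool:
        return self.from_aa == self.to_aa


@dataclass(frozen=True)
class CatalogueEvent:
    """One published parental/derived pair and its annotations."""

    gene: str
    arm_len: int
    spacer_len: int
    strains: tuple[str, ...]
    parental: str  # as printed (spacer lowercase); upper-case for analysis
    derived: str
    frame_offset: int
    replacements: tuple[CatalogueReplacement, ...]


@lru_cache(maxsize=1)
def load_events() -> tuple[CatalogueEvent, ...]:
    text = (
        importlib.resources.files("tswitch.data")
        .joinpath("published_events.json")
        .read_text()
    )
    payload = json.loads(text)
    events = []
    for row in payload["events"]:
        events.append(
            CatalogueEvent(
                gene=row["gene"],
                arm_len=row["arm_len"],
                spacer_len=row["spacer_len"],
                strains=tuple(row["strains"]),
                parental=row["parental"],
                derived=row["derived"],
                frame_offset=row["frame_offset"],
                replacements=tuple(
                    CatalogueReplacement(
                        from_aa=r["from_aa"],
                        to_aa=r["to_aa"],
                        from_codon=r["from_codon"],
                        to_codon=r["to_codon"],
                    )
                    for r in row["replacements"]
                ),
            )
        )
    return tuple(events)


def event_by_gene(gene: str) -> CatalogueEvent:
    for ev in load_events():
        if ev.gene == gene:
            return ev
    raise KeyError(gene)
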