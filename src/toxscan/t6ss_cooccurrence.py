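"""Genome-level T6SS classification and marker co-occurrence.

A genome is called T6SS-positive when its proteome carries at least 9 of the
11 core-component COG profiles (COG3516, COG3517, COG3157, COG3521, COG3522,
COG3455, COG3523, COG3518, COG3519, COG3520, COG3515).  VgrG (COG3501) is
correlated with T6SS but tracked separately and does not count toward the 9
unless explicitly included for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import FeatureTable
from .neighborhood import round_percent
from .profile_search import DomainHit

CORE_COGS = frozenset(
    {"COG3516", "COG3517", "COG3157", "COG3521", "COG3522", "COG3455",
     "COG3523", "COG3518", "COG3519", "COG3520", "COG3515"}
)
VGRG_COG = "COG3501"
MIN_COMPONENTS = 9


@dataclass(frozen=True)
class T6SSCall:
    assembly_id: str
    components_present: frozenset[str]
    vgrg_present: bool
    include_vgrg: bool = False

    def __post_init__(self) -> None:
        if not self.components_present <= CORE_COGS:
            raise ValueError("components_present must be core COG labels")

    @property
    def n_components(self) -> int:
        return len(self.components_present) + (
            1 if self.include_vgrg and self.vgrg_present else 0
        )

    @property
    def is_t6ss(self) -> bool:
        return self.n_components >= MIN_COMPONENTS


def detect_components(
    assembly_id: str,
    protein_assemblies: Mapping[str, str],
    annotations: pd.DataFrame,
    include_vgrg: bool = False,
) -> T6SSCall:
    """Call T6SS presence for one assembly from COG-labelled annotations.

    ``protein_assemblies`` maps protein_id -> assembly_id (from the feature
    table); a component is present when >= 1 protein of the assembly carries
    its label.  Unknown COG labels never count toward the 9.
    """
    if assembly_id not in set(protein_assemblies.values()):
        raise KeyError(f"unknown assembly {assembly_id!r}")
    present: set[str] = set()
    vgrg = False
    for pid, name in zip(annotations["protein_id"], annotations["domain_name"]):
        if protein_assemblies.get(pid) != assembly_id:
            continue
        if name in CORE_COGS:
            present.add(name)
        elif name == VGRG_COG:
            vgrg = True
    return T6SSCall(
        assembly_id=assembly_id,
        components_present=frozenset(present),
        vgrg_present=vgrg,
        include_vgrg=include_vgrg,
    )


def classify_genomes(
    feature_table: FeatureTable,
    annotations: pd.DataFrame,
    include_vgrg: bool = False,
) -> dict[str, T6SSCall]:
    """T6SS calls for every assembly in the feature table."""
    protein_assemblies = {
        f.protein_id: f.assembly_id for f in feature_table
    }
    return {
        asm: detect_components(asm, protein_assemblies, annotations, include_vgrg)
        for asm in feature_table.assemblies()
    }


def cooccurrence(
    marker_hits: Iterable[tuple[str, DomainHit]] | Iterable[str],
    calls: Mapping[str, T6SSCall],
) -> tuple[int, int, float | None]:
    """(n marker genomes, n of them T6SS-positive, percent).

    ``marker_hits`` is either an iterable of assembly ids (one per kept
    marker hit) or of (assembly_id, hit) pairs; percent is over distinct
    assemblies with >= 1 kept marker hit, None when there are none.
    """
    assemblies = set()
    for item in marker_hits:
        assemblies.add(item[0] if isinstance(item, tuple) else item)
    for asm in assemblies:
        if asm not in calls:
            raise KeyError(f"no T6SS call for assembly {asm!r}")
    n = len(assemblies)
    if n == 0:
        return 0, 0, None
    n_pos = sum(calls[a].is_t6ss for a in assemblies)
    return n, n_pos, round_percent(n_pos, n)


def calls_to_frame(calls: Mapping[str, T6SSCall]) -> pd.DataFrame:
    rows = [
        dict(
            assembly_id=c.assembly_id,
            n_components=len(c.components_present),
            components=",".join(sorted(c.components_present)),
            vgrg_present=c.vgrg_present,
            is_t6ss=c.is_t6ss,
        )
        for c in sorted(calls.values(), key=lambda c: c.assembly_id)
    ]
    return pd.DataFrame(
        rows,
        columns=["assembly_id", "n_components", "components", "vgrg_present",
                 "is_t6ss"],
    )
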