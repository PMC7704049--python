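"""Recurrent nonnative states: extraction, clustering, and substructures.

Snapshots assigned to a kinetic cluster can carry contacts absent from the
native map.  These are extracted (with a one-cell Manhattan buffer around
native contacts, so that slightly register-shifted native contacts are not
miscalled nonnative), grouped into recurrent classes by contact-map Hamming
distance, and summarized as frequency-averaged maps whose persistent
(>= 10%) contacts are themselves decomposed into nonnative substructures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import networkx as nx
import numpy as np

from .contacts import (
    ContactMap,
    ContactParams,
    Snapshot,
    SubstructureDecomposition,
    _pairwise_contacts,
    identify_substructures,
)

__all__ = [
    "NonnativeMap",
    "NonnativeClass",
    "extract_nonnative_map",
    "cluster_nonnative_states",
    "nonnative_substructures",
    "NONNATIVE_SUBSTRUCTURE_PARAMS",
]

#: Parameter set used on the nonnative-frequency-map path: same island size
#: as the native analysis but a tighter hop radius.
NONNATIVE_SUBSTRUCTURE_PARAMS = ContactParams(d_c=6.5, min_sep=3, c=7, h=3, f=1.7)


@dataclass(frozen=True)
class NonnativeMap:
    """Nonnative contacts of one snapshot."""

    contacts: frozenset
    snapshot_id: str = ""
    cluster: str = ""

    def __len__(self) -> int:
        return len(self.contacts)


def extract_nonnative_map(
    snapshot: Snapshot,
    native: ContactMap,
    params: Optional[ContactParams] = None,
    relaxed: bool = False,
    snapshot_id: str = "",
    cluster: str = "",
) -> NonnativeMap:
    """Contacts of a snapshot that are not (near-)native.

    A snapshot contact is nonnative when its Manhattan distance on the
    contact map from every native contact is at least 2; with
    ``relaxed=True`` only literal native contacts are excluded (useful for
    clusters where near-native register shifts are themselves of interest).
    """
    params = params or native.params
    observed = _pairwise_contacts(snapshot.coords, params.d_c, params.min_sep)
    native_pairs = native.pairs
    if relaxed:
        keep = observed - native_pairs
    else:
        keep = {
            (i, j)
            for (i, j) in observed
            if all(abs(i - a) + abs(j - b) >= 2 for (a, b) in native_pairs)
        }
    return NonnativeMap(frozenset(keep), snapshot_id=snapshot_id, cluster=cluster)


@dataclass
class NonnativeClass:
    """One recurrent class of nonnative states within a cluster."""

    member_ids: List[str]
    frequency: Dict[tuple, float]  # contact -> occurrence fraction in class

    def __len__(self) -> int:
        return len(self.member_ids)


def cluster_nonnative_states(
    maps: Sequence[NonnativeMap], hamming_threshold: int = 10
) -> List[NonnativeClass]:
    """Group snapshots into recurrent nonnative classes.

    The Hamming distance between two maps is the size of the symmetric
    difference of their contact sets; maps closer than ``hamming_threshold``
    are adjacent and classes are the connected components.  Classes are
    returned largest first (ties by smallest member id).
    """
    if not maps:
        raise ValueError("need at least one nonnative map")
    g = nx.Graph()
    g.add_nodes_from(range(len(maps)))
    for a in range(len(maps)):
        for b in range(a + 1, len(maps)):
            d = len(maps[a].contacts ^ maps[b].contacts)
            if d < hamming_threshold:
                g.add_edge(a, b)
    classes = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        ids = [maps[i].snapshot_id or str(i) for i in members]
        freq: Dict[tuple, float] = {}
        for i in members:
            for c in maps[i].contacts:
                freq[c] = freq.get(c, 0.0) + 1.0
        n = len(members)
        freq = {c: v / n for c, v in freq.items()}
        classes.append(NonnativeClass(member_ids=ids, frequency=freq))
    classes.sort(key=lambda cl: (-len(cl.member_ids), cl.member_ids))
    return classes


def nonnative_substructures(
    cls: NonnativeClass,
    min_freq: float = 0.10,
    params: ContactParams = NONNATIVE_SUBSTRUCTURE_PARAMS,
) -> SubstructureDecomposition:
    """Substructures among a class's persistent nonnative contacts.

    Contacts present in at least ``min_freq`` of the class's snapshots are
    kept and decomposed with the island rule (default c = 7, h = 3).
    """
    if not cls.frequency and not cls.member_ids:
        raise ValueError("empty nonnative class")
    kept = frozenset(c for c, f in cls.frequency.items() if f >= min_freq)
    return identify_substructures(ContactMap(kept, params), params)
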