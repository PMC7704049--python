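"""Native contact maps, substructure decomposition, and topological configurations.

The coarse-graining strategy: a protein's native contact map (CA pairs within a
distance cutoff, separated in sequence) is decomposed into *substructures* --
islands of contiguous contacts that are expected to form and break
cooperatively during folding.  A snapshot is then assigned a *topological
configuration*: the subset of substructures currently formed, judged by
comparing the mean CA distance over each substructure's contacts against its
native reference value.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "NativeStructure",
    "ContactParams",
    "ContactMap",
    "Substructure",
    "TopologicalConfiguration",
    "Snapshot",
    "SubstructureDecomposition",
    "compute_native_contacts",
    "identify_substructures",
    "assign_configuration",
    "config_hamming",
    "mean_contact_distance",
    "PROTEIN_G_PRESET",
]

EMPTY_LABEL = "∅"  # ∅ -- no substructure formed


@dataclass(frozen=True)
class NativeStructure:
    """An equilibrated native structure reduced to its CA trace.

    Residues are indexed 0..L-1 contiguously; coordinates are in Angstroms.
    """

    coords: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (L, 3)")
        if coords.shape[0] < 2:
            raise ValueError("a structure needs at least 2 residues")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def length(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class ContactParams:
    """Parameters of the contact-map / substructure analysis.

    d_c       -- CA-CA distance cutoff in Angstroms (strict: d < d_c)
    min_sep   -- minimum sequence separation j - i of a contact
    c         -- minimum island size (contacts) to count as a substructure
    h         -- maximum Manhattan hop on the contact map joining island members
    f         -- formation factor: substructure formed iff <d> <= f * <d0>
    """

    d_c: float = 6.5
    min_sep: int = 3
    c: int = 7
    h: int = 5
    f: float = 1.7

    def __post_init__(self) -> None:
        if self.d_c <= 0:
            raise ValueError("d_c must be positive")
        if self.min_sep < 1:
            raise ValueError("min_sep must be >= 1")
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if self.h < 1:
            raise ValueError("h must be >= 1")
        if self.f < 1:
            raise ValueError("f must be >= 1")


#: Protein-G-like preset: 6.5 A / min_sep 3 for the substructure map, c=7,
#: h=5, f=1.7; the native-contact *count* uses the stricter 6 A / min_sep 8.
PROTEIN_G_PRESET = {
    "substructure_map": ContactParams(d_c=6.5, min_sep=3, c=7, h=5, f=1.7),
    "native_count": ContactParams(d_c=6.0, min_sep=8, c=7, h=5, f=1.7),
}


@dataclass(frozen=True)
class ContactMap:
    """A set of native contacts (i, j), i < j, on the canonical half-map."""

    pairs: frozenset
    params: ContactParams

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs))

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.pairs


@dataclass(frozen=True)
class Substructure:
    """A cooperative island of native contacts with its reference geometry."""

    label: str
    contacts: frozenset
    d0_mean: float  # mean native CA distance over the island's contacts, A

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass(frozen=True)
class SubstructureDecomposition:
    """Result of island detection: surviving substructures + leftovers."""

    substructures: tuple
    unassigned: frozenset

    def __iter__(self):
        return iter(self.substructures)

    def __len__(self) -> int:
        return len(self.substructures)


@dataclass(frozen=True)
class TopologicalConfiguration:
    """Which substructures (by alphabetic position) are formed in a snapshot."""

    bits: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", tuple(int(bool(b)) for b in self.bits))

    @property
    def label(self) -> str:
        formed = [string.ascii_lowercase[i] for i, b in enumerate(self.bits) if b]
        return "".join(formed) if formed else EMPTY_LABEL

    @classmethod
    def from_label(cls, label: str, n_substructures: int) -> "TopologicalConfiguration":
        bits = [0] * n_substructures
        if label not in ("", EMPTY_LABEL):
            for ch in label:
                idx = string.ascii_lowercase.index(ch)
                if idx >= n_substructures:
                    raise ValueError(
                        f"label {label!r} references substructure {ch!r} beyond "
                        f"universe of size {n_substructures}"
                    )
                bits[idx] = 1
        return cls(tuple(bits))

    def __str__(self) -> str:
        return self.label


@dataclass(frozen=True)
class Snapshot:
    """One sampled conformation plus the bookkeeping the pipeline needs."""

    coords: np.ndarray
    trajectory_id: str = ""
    mc_step: int = 0
    condition_id: str = ""
    energy: float = np.nan  # unbiased energy E0, simulation units
    natives: int = 0  # native-contact count N

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if self.mc_step < 0:
            raise ValueError("mc_step must be >= 0")


def _pairwise_contacts(coords: np.ndarray, d_c: float, min_sep: int) -> set:
    """All (i, j), i < j, with j - i >= min_sep and |r_i - r_j| < d_c."""
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    n = coords.shape[0]
    ii, jj = np.triu_indices(n, k=min_sep)
    keep = dist[ii, jj] < d_c
    return {(int(i), int(j)) for i, j in zip(ii[keep], jj[keep])}


def compute_native_contacts(
    structure: NativeStructure, params: ContactParams
) -> ContactMap:
    """Contact map of the native structure: CA pairs closer than d_c with
    sequence separation >= min_sep (strict distance inequality)."""
    if structure.length < params.min_sep + 1:
        warnings.warn(
            "no contacts possible: structure shorter than min_sep + 1",
            stacklevel=2,
        )
        return ContactMap(frozenset(), params)
    pairs = _pairwise_contacts(structure.coords, params.d_c, params.min_sep)
    return ContactMap(frozenset(pairs), params)


def identify_substructures(
    cmap: ContactMap, params: Optional[ContactParams] = None
) -> SubstructureDecomposition:
    """Decompose a contact map into islands of >= c contacts connected by
    Manhattan hops of at most h, labelled a, b, c, ... by ascending minimum
    residue index.  Contacts in no surviving island are reported unassigned.

    Reference distances d0 are not known from the map alone; they are filled
    by :func:`attach_reference_distances` (or computed directly via
    :func:`decompose_structure`).
    """
    params = params or cmap.params
    contacts = sorted(cmap.pairs)
    if not contacts:
        return SubstructureDecomposition((), frozenset())
    g = nx.Graph()
    g.add_nodes_from(contacts)
    for a_idx in range(len(contacts)):
        i, j = contacts[a_idx]
        for b_idx in range(a_idx + 1, len(contacts)):
            ip, jp = contacts[b_idx]
            if abs(i - ip) + abs(j - jp) <= params.h:
                g.add_edge(contacts[a_idx], contacts[b_idx])
    comps = [frozenset(comp) for comp in nx.connected_components(g)]
    surviving = [comp for comp in comps if len(comp) >= params.c]
    # alphabetic labels by ascending minimum residue index (ties: min j)
    surviving.sort(key=lambda comp: min(comp))
    if len(surviving) > 26:
        raise ValueError(
            f"{len(surviving)} substructures exceed the single-letter label "
            "space; raise c or h"
        )
    subs = tuple(
        Substructure(string.ascii_lowercase[k], comp, d0_mean=np.nan)
        for k, comp in enumerate(surviving)
    )
    assigned = set().union(*surviving) if surviving else set()
    unassigned = frozenset(set(contacts) - assigned)
    return SubstructureDecomposition(subs, unassigned)


def mean_contact_distance(coords: np.ndarray, contacts: Iterable) -> float:
    """Arithmetic mean CA-CA distance over a set of contact pairs."""
    pairs = np.asarray(sorted(contacts), dtype=int)
    d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
    return float(d.mean())


def attach_reference_distances(
    decomposition: SubstructureDecomposition, structure: NativeStructure
) -> SubstructureDecomposition:
    """Fill each substructure's native reference mean distance <d0>."""
    subs = tuple(
        Substructure(
            s.label, s.contacts, mean_contact_distance(structure.coords, s.contacts)
        )
        for s in decomposition.substructures
    )
    return SubstructureDecomposition(subs, decomposition.unassigned)


def decompose_structure(
    structure: NativeStructure, params: ContactParams
) -> SubstructureDecomposition:
    """Convenience: native contacts -> islands -> reference distances."""
    cmap = compute_native_contacts(structure, params)
    return attach_reference_distances(identify_substructures(cmap, params), structure)


def assign_configuration(
    snapshot: Snapshot,
    substructures: Sequence[Substructure],
    f: Optional[float] = None,
) -> TopologicalConfiguration:
    """Assign a snapshot to a topological configuration.

    A substructure is deemed formed when its snapshot-mean contact distance
    <d> satisfies <d> <= f * <d0>.
    """
    if f is None:
        f = 1.7
    coords = snapshot.coords
    n_res = coords.shape[0]
    bits = []
    for sub in substructures:
        for (i, j) in sub.contacts:
            if i >= n_res or j >= n_res:
                raise ValueError(
                    f"snapshot lacks coordinates for residue {max(i, j)} "
                    f"referenced by substructure {sub.label!r}"
                )
        if not np.isfinite(sub.d0_mean):
            raise ValueError(
                f"substructure {sub.label!r} has no reference distance <d0>"
            )
        d_mean = mean_contact_distance(coords, sub.contacts)
        bits.append(1 if d_mean <= f * sub.d0_mean else 0)
    return TopologicalConfiguration(tuple(bits))


def config_hamming(
    a: TopologicalConfiguration, b: TopologicalConfiguration
) -> int:
    """Number of substructures by which two configurations differ."""
    if len(a.bits) != len(b.bits):
        raise ValueError(
            f"configurations live in different substructure universes "
            f"({len(a.bits)} vs {len(b.bits)} substructures)"
        )
    return int(sum(x != y for x, y in zip(a.bits, b.bits)))


def label_hamming(a: str, b: str, n_substructures: int) -> int:
    """Hamming distance between two configuration *labels*."""
    return config_hamming(
        TopologicalConfiguration.from_label(a, n_substructures),
        TopologicalConfiguration.from_label(b, n_substructures),
    )
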