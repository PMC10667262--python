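"""Calpha model of mature glucocerebrosidase and variant proximity search.

The GCase crystal structure (e.g. PDB 1ogs) numbers the *mature* protein,
while variants are named on the full translation product including the
39-residue signal peptide; this module applies the offset automatically, so
all public I/O uses full-translation numbering.

A VUS is "proximal" to a known pathogenic variant when the two sites are at
most ``seq_window`` residue positions apart in sequence (evaluated on the
translation product, signal peptide included) or their Calpha atoms are
strictly closer than ``ca_cutoff`` angstroms in the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np

from gba1pd.variants import (
    SIGNAL_PEPTIDE_LENGTH,
    VariantClass,
    parse_hgvs_p,
    to_mature_numbering,
)

__all__ = [
    "StructureModel",
    "ProximityConfig",
    "ProximityHit",
    "MapStatus",
    "MappedSite",
    "load_ca_model",
    "map_site",
    "ca_distance",
    "find_proximal_pathogenic",
]


@dataclass
class StructureModel:
    """Calpha-only chain model in mature-protein numbering."""

    chain_id: str
    positions: np.ndarray  # (n,) int, strictly increasing mature positions
    residue_names: tuple[str, ...]
    coordinates: np.ndarray  # (n, 3) float angstroms
    gaps: tuple[int, ...] = ()  # residues present but lacking a Calpha atom

    def __post_init__(self) -> None:
        if len(self.positions) and not np.all(np.diff(self.positions) > 0):
            raise ValueError("residue positions must be strictly increasing")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("non-finite coordinates in model")
        self._index = {int(p): i for i, p in enumerate(self.positions)}

    def __len__(self) -> int:
        return len(self.positions)

    def has_mature(self, mature_pos: int) -> bool:
        return mature_pos in self._index

    def coord(self, mature_pos: int) -> np.ndarray:
        try:
            return self.coordinates[self._index[mature_pos]]
        except KeyError:
            raise KeyError(f"mature position {mature_pos} not in model") from None

    def residue_name(self, mature_pos: int) -> str:
        return self.residue_names[self._index[mature_pos]]


def load_ca_model(pdb: Union[str, Path], chain: str = "A") -> StructureModel:
    """Parse a PDB file (path or text) into a Calpha model of one chain.

    Alternate locations are resolved to the highest occupancy (first listed
    on ties); residues without a Calpha atom are recorded as gaps.
    Insertion codes are rejected — they do not occur in GCase structures.
    """
    import gemmi

    text = pdb
    if isinstance(pdb, Path) or (isinstance(pdb, str) and "\n" not in pdb and Path(pdb).exists()):
        text = Path(pdb).read_text()
    structure = gemmi.read_pdb_string(text)
    if not len(structure):
        raise ValueError("no models in PDB input")
    model = structure[0]
    target = None
    for ch in model:
        if ch.name == chain:
            target = ch
            break
    if target is None or len(target) == 0:
        raise ValueError(f"no ATOM records for chain {chain!r}")

    positions: list[int] = []
    names: list[str] = []
    coords: list[tuple[float, float, float]] = []
    gaps: list[int] = []
    for residue in target:
        info = gemmi.find_tabulated_residue(residue.name)
        if not (residue.het_flag == "A" or (info is not None and info.is_amino_acid())):
            continue
        icode = residue.seqid.icode
        if icode and icode.strip():
            raise ValueError(f"insertion code at residue {residue.seqid.num}")
        cas = [a for a in residue if a.name == "CA"]
        if not cas:
            gaps.append(residue.seqid.num)
            continue
        best = max(cas, key=lambda a: a.occ)  # max() keeps the first on ties
        positions.append(residue.seqid.num)
        names.append(residue.name)
        coords.append((best.pos.x, best.pos.y, best.pos.z))
    if not positions and not gaps:
        raise ValueError(f"no amino-acid residues in chain {chain!r}")
    return StructureModel(
        chain_id=chain,
        positions=np.asarray(positions, dtype=int),
        residue_names=tuple(names),
        coordinates=np.asarray(coords, dtype=float).reshape(len(positions), 3),
        gaps=tuple(gaps),
    )


class MapStatus(Enum):
    MAPPED = "mapped"
    UNMAPPED_SIGNAL_PEPTIDE = "unmapped_signal_peptide"
    MISSING_DENSITY = "missing_density"


@dataclass(frozen=True)
class MappedSite:
    status: MapStatus
    mature_position: Optional[int] = None
    residue_name: Optional[str] = None


def map_site(position_full: int, model: Optional[StructureModel] = None) -> MappedSite:
    """Map a full-translation position onto the (optional) mature model."""
    mature = to_mature_numbering(position_full)
    if mature is None:
        return MappedSite(MapStatus.UNMAPPED_SIGNAL_PEPTIDE)
    if model is not None and not model.has_mature(mature):
        return MappedSite(MapStatus.MISSING_DENSITY, mature_position=mature)
    name = model.residue_name(mature) if model is not None else None
    return MappedSite(MapStatus.MAPPED, mature_position=mature, residue_name=name)


def ca_distance(model: StructureModel, mature_i: int, mature_j: int) -> float:
    """Euclidean Calpha-Calpha distance in angstroms."""
    return float(np.linalg.norm(model.coord(mature_i) - model.coord(mature_j)))


@dataclass
class ProximityConfig:
    seq_window: int = 2
    ca_cutoff: float = 5.0  # strict less-than, in angstroms

    def __post_init__(self) -> None:
        if self.seq_window <= 0 or self.ca_cutoff <= 0:
            raise ValueError("proximity thresholds must be positive")


@dataclass(frozen=True)
class ProximityHit:
    vus_hgvs_p: str
    neighbor_hgvs_p: str
    neighbor_class: Optional[VariantClass]
    seq_distance: int
    ca_dist: Optional[float]
    evidence: str  # "sequence", "spatial" or "both"


def find_proximal_pathogenic(
    vus_hgvs_p: str,
    known_pathogenic: Union[Mapping[str, VariantClass], Iterable[str]],
    model: Optional[StructureModel] = None,
    config: Optional[ProximityConfig] = None,
) -> list[ProximityHit]:
    """Find known pathogenic variants near a VUS in sequence or space.

    The sequence rule applies to every pair (signal-peptide positions
    included); the spatial rule only to pairs whose mature positions are both
    present in the model.  Returns an empty list for an isolated VUS.
    """
    config = config or ProximityConfig()
    if not isinstance(known_pathogenic, Mapping):
        known_pathogenic = {name: None for name in known_pathogenic}
    vus_pos = parse_hgvs_p(vus_hgvs_p).position
    vus_mature = to_mature_numbering(vus_pos)
    hits: list[ProximityHit] = []
    for neighbor, klass in known_pathogenic.items():
        if neighbor == vus_hgvs_p:
            continue
        npos = parse_hgvs_p(neighbor).position
        seq_dist = abs(vus_pos - npos)
        seq_hit = seq_dist <= config.seq_window
        spatial: Optional[float] = None
        spatial_hit = False
        if model is not None and vus_mature is not None:
            nmature = to_mature_numbering(npos)
            if nmature is not None and model.has_mature(vus_mature) and model.has_mature(nmature):
                spatial = ca_distance(model, vus_mature, nmature)
                spatial_hit = spatial < config.ca_cutoff
        if seq_hit or spatial_hit:
            evidence = "both" if (seq_hit and spatial_hit) else ("sequence" if seq_hit else "spatial")
            hits.append(
                ProximityHit(
                    vus_hgvs_p=vus_hgvs_p,
                    neighbor_hgvs_p=neighbor,
                    neighbor_class=klass,
                    seq_distance=seq_dist,
                    ca_dist=spatial,
                    evidence=evidence,
                )
            )
    return hits
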