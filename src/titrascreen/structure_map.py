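"""Mapping of screened residues onto a 3D structure.

Distances are heavy-atom minimum distances: the shift-perturbation reasoning
is about through-space contacts, so the closest approach of any two heavy
atoms — not Cβ–Cβ or centroid distance — is the relevant quantity.  Two
conventions are used by default and both are configurable:

* ``8.0 Å`` for "near a histidine" (ring protonation can perturb amides well
  beyond van der Waals contact),
* ``5.0 Å`` for membership in the subunit–subunit interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

import gemmi

from .titration import CSPRecord, ResidueKey

__all__ = [
    "StructureModel",
    "ProximityReport",
    "load_structure",
    "his_proximity",
    "interface_residues",
    "interface_partition",
]

NEAR_HIS_CUTOFF = 8.0  # Å
INTERFACE_CUTOFF = 5.0  # Å


@dataclass
class Residue3D:
    subunit: str
    residue_number: int
    residue_type: str
    coords: np.ndarray  # (n_heavy_atoms, 3) in Å

    @property
    def key(self) -> ResidueKey:
        return (self.subunit, self.residue_number)


@dataclass
class StructureModel:
    """Heavy-atom model keyed by (subunit, residue_number)."""

    residues: dict[ResidueKey, Residue3D] = field(default_factory=dict)
    missing_residues: list[ResidueKey] = field(default_factory=list)

    def subunits(self) -> list[str]:
        return sorted({k[0] for k in self.residues})

    def keys_of(self, subunit: str) -> list[ResidueKey]:
        return sorted(k for k in self.residues if k[0] == subunit)

    def his_keys(self) -> list[ResidueKey]:
        return sorted(
            k for k, r in self.residues.items() if r.residue_type in ("H", "HIS")
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body copy (for invariance checks and synthetic layouts)."""
        out = StructureModel(missing_residues=list(self.missing_residues))
        for k, r in self.residues.items():
            out.residues[k] = Residue3D(
                r.subunit, r.residue_number, r.residue_type,
                r.coords @ rotation.T + translation,
            )
        return out


@dataclass
class ProximityReport:
    subunit: str
    residue_number: int
    min_dist_to_his: Optional[float]  # Å; None when coordinates are absent
    nearest_his: Optional[ResidueKey]
    near_his: bool
    interface_flag: bool = False

    @property
    def key(self) -> ResidueKey:
        return (self.subunit, self.residue_number)


_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


def load_structure(
    path,
    chain_map: Mapping[str, str],
    residue_offset: Mapping[str, int] | None = None,
) -> StructureModel:
    """Load heavy atoms of the mapped chains from a PDB or mmCIF file.

    Parameters
    ----------
    path
        PDB or mmCIF file; the format is detected from the contents.
    chain_map
        Chain label → subunit label, e.g. ``{"C": "NAS", "D": "NBS"}``.
    residue_offset
        Optional per-subunit offset added to author residue numbers so the
        model numbering matches the 1-based per-subunit assignment numbering.

    Alternate locations are resolved to the highest-occupancy conformer;
    hydrogens are dropped; residues without any heavy atom are recorded in
    ``missing_residues``.
    """
    st = gemmi.read_structure(str(Path(path)), format=gemmi.CoorFormat.Detect)
    st.setup_entities()
    st.remove_hydrogens()
    model = st[0]
    available = [ch.name for ch in model]
    offsets = dict(residue_offset or {})

    out = StructureModel()
    for chain_label, subunit in chain_map.items():
        chain = None
        for ch in model:
            if ch.name == chain_label:
                chain = ch
                break
        if chain is None:
            raise KeyError(
                f"chain {chain_label!r} not in structure; available: {available}"
            )
        off = offsets.get(subunit, 0)
        for res in chain:
            if res.is_water():
                continue
            num = res.seqid.num + off
            # keep highest-occupancy altloc per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            if not best:
                out.missing_residues.append((subunit, num))
                continue
            coords = np.array(
                [[a.pos.x, a.pos.y, a.pos.z] for a in best.values()], dtype=float
            )
            rtype = _ONE.get(res.name.upper(), "X")
            out.residues[(subunit, num)] = Residue3D(subunit, num, rtype, coords)
    if not out.residues:
        raise ValueError(f"no residues loaded from {path} with map {dict(chain_map)}")
    return out


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum pairwise distance between two heavy-atom coordinate sets."""
    diff = a[:, None, :] - b[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).min())


def his_proximity(
    model: StructureModel,
    residues: Iterable[ResidueKey] | None = None,
    his_set: Iterable[ResidueKey] | None = None,
    cutoff: float = NEAR_HIS_CUTOFF,
) -> list[ProximityReport]:
    """Minimum heavy-atom distance from each query residue to any histidine.

    ``his_set`` defaults to all histidines of the model; ``residues`` defaults
    to every residue.  A residue lacking coordinates yields a report with an
    absent distance.
    """
    his_keys = sorted(his_set) if his_set is not None else model.his_keys()
    if not his_keys:
        raise ValueError("his_set is empty and the model contains no histidine")
    query = sorted(residues) if residues is not None else sorted(model.residues)

    his_coords = []
    his_index = []
    for k in his_keys:
        if k not in model.residues:
            raise KeyError(f"histidine {k} not present in the model")
        c = model.residues[k].coords
        his_coords.append(c)
        his_index.extend([k] * len(c))
    his_xyz = np.vstack(his_coords)
    tree = cKDTree(his_xyz)

    reports = []
    for k in query:
        res = model.residues.get(k)
        if res is None or len(res.coords) == 0:
            reports.append(ProximityReport(k[0], k[1], None, None, False))
            continue
        d, idx = tree.query(res.coords)
        i = int(np.argmin(d))
        reports.append(
            ProximityReport(
                k[0],
                k[1],
                float(d[i]),
                his_index[int(idx[i])],
                bool(d[i] <= cutoff),
            )
        )
    return reports


def interface_residues(
    model: StructureModel, cutoff: float = INTERFACE_CUTOFF
) -> set[ResidueKey]:
    """Residues with any heavy atom within `cutoff` of the other subunit."""
    subs = model.subunits()
    if len(subs) != 2:
        raise ValueError(f"need exactly two subunits, found {subs}")
    a_keys, b_keys = model.keys_of(subs[0]), model.keys_of(subs[1])

    def stack(keys: Sequence[ResidueKey]) -> tuple[np.ndarray, list[ResidueKey]]:
        xyz, owner = [], []
        for k in keys:
            c = model.residues[k].coords
            xyz.append(c)
            owner.extend([k] * len(c))
        return np.vstack(xyz), owner

    a_xyz, a_owner = stack(a_keys)
    b_xyz, b_owner = stack(b_keys)
    pairs = cKDTree(a_xyz).query_ball_tree(cKDTree(b_xyz), r=cutoff)
    out: set[ResidueKey] = set()
    for ia, hits in enumerate(pairs):
        if hits:
            out.add(a_owner[ia])
            out.update(b_owner[ib] for ib in hits)
    return out


def interface_partition(
    screen: Iterable[CSPRecord],
    proximity: Iterable[ProximityReport],
    functional_labels: Mapping[ResidueKey, str],
    model: StructureModel | None = None,
) -> dict:
    """Split functionally annotated residues into the two receptor interfaces.

    Residues labelled ``pH_dependency`` form the pH-dependent *activation*
    interface; residues labelled ``affinity`` form the pH-independent
    *affinity* interface.  With a model supplied, pairwise heavy-atom
    distance summaries (intra-set max, inter-set min) quantify the spatial
    separation of the two sets.
    """
    allowed = {"pH_dependency", "affinity", "none"}
    bad = {v for v in functional_labels.values() if v not in allowed}
    if bad:
        raise ValueError(f"unknown effect labels: {sorted(bad)}; allowed {allowed}")

    activation = sorted(k for k, v in functional_labels.items() if v == "pH_dependency")
    affinity = sorted(k for k, v in functional_labels.items() if v == "affinity")

    out: dict = {
        "activation_interface": activation,
        "affinity_interface": affinity,
    }
    screen_by_key = {r.key: r for r in screen}
    prox_by_key = {p.key: p for p in proximity}
    out["activation_near_his"] = [
        k for k in activation if prox_by_key.get(k) and prox_by_key[k].near_his
    ]
    out["affinity_near_his"] = [
        k for k in affinity if prox_by_key.get(k) and prox_by_key[k].near_his
    ]
    out["activation_groups"] = {
        k: screen_by_key[k].group for k in activation if k in screen_by_key
    }

    if model is not None and activation and affinity:
        def pair_dists(keys_a, keys_b):
            vals = []
            for i, ka in enumerate(keys_a):
                for kb in (keys_b if keys_a is not keys_b else keys_a[i + 1:]):
                    if ka == kb:
                        continue
                    ra, rb = model.residues.get(ka), model.residues.get(kb)
                    if ra is None or rb is None:
                        continue
                    vals.append(_min_dist(ra.coords, rb.coords))
            return vals

        intra = pair_dists(activation, activation) + pair_dists(affinity, affinity)
        inter = pair_dists(activation, affinity)
        out["max_intra_set_distance"] = max(intra) if intra else None
        out["min_inter_set_distance"] = min(inter) if inter else None
        out["spatially_separated"] = (
            bool(inter and intra and min(inter) > max(intra))
            if inter and intra
            else None
        )
    return out
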